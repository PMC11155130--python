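"""Stage 2: five-score consensus filter, cross-reference, conservation, domains."""

import numpy as np
import pytest

from wsdecipher.io_formats import (
    AnnotatedVariant,
    DomainInterval,
    DomainTable,
    ProteinAlignment,
)
from wsdecipher.variant_filtering import (
    FilterThresholds,
    build_variant_report,
    conservation_check,
    consensus_filter,
    crossref_known,
    domain_localization,
    filter_table,
    stage_counts,
)
from wsdecipher.synthetic_data import SimulationConfig, generate_variant_table


def variant(gene="PAX3", vid="rs1", change="p.Arg156Cys", **scores):
    defaults = dict(sift=0.0005, polyphen2_hvar=0.998, mutationtaster=1.0,
                    cadd_phred=29.1, gerp_rs=5.2)
    defaults.update(scores)
    return AnnotatedVariant(gene=gene, variant_id=vid, protein_change=change, **defaults)


def aln(*rows, ref="Homo_sapiens"):
    ids = tuple(f"sp{i}" if i else ref for i in range(len(rows)))
    return ProteinAlignment(ids=ids, sequences=dict(zip(ids, rows)), reference_id=ref)


class TestConsensusFilter:
    def test_all_thresholds_satisfied(self):
        assert consensus_filter(variant()).overall_pass

    def test_boundary_semantics(self):
        # SIFT admits equality; CADD and GERP++ require strict >
        d = consensus_filter(
            variant(sift=0.001, polyphen2_hvar=0.958, mutationtaster=1.0,
                    cadd_phred=25.0, gerp_rs=4.0)
        )
        assert d.verdicts["sift"] == "pass"
        assert d.verdicts["polyphen2_hvar"] == "pass"
        assert d.verdicts["cadd_phred"] == "fail"
        assert d.verdicts["gerp_rs"] == "fail"
        assert not d.overall_pass

    def test_missing_score_fails_closed(self):
        d = consensus_filter(variant(sift=None))
        assert d.verdicts["sift"] == "missing" and not d.overall_pass

    def test_random_vectors_match_comparison_oracle(self):
        rng = np.random.default_rng(10)
        t = FilterThresholds()
        for i in range(200):
            s = dict(
                sift=float(rng.uniform(0, 0.01)),
                polyphen2_hvar=float(rng.uniform(0.9, 1.0)),
                mutationtaster=float(rng.choice([1.0, 0.999, 0.5])),
                cadd_phred=float(rng.uniform(20, 30)),
                gerp_rs=float(rng.uniform(3, 5)),
            )
            expect = (
                s["sift"] <= 0.001 and s["polyphen2_hvar"] > 0.957
                and abs(s["mutationtaster"] - 1) <= 1e-9
                and s["cadd_phred"] > 25 and s["gerp_rs"] > 4
            )
            assert consensus_filter(variant(vid=f"rs{i}", **s), t).overall_pass == expect

    def test_relaxing_thresholds_never_shrinks_survivors(self):
        rng = np.random.default_rng(11)
        variants = [
            variant(
                vid=f"rs{i}",
                sift=float(rng.uniform(0, 0.01)),
                polyphen2_hvar=float(rng.uniform(0.9, 1.0)),
                cadd_phred=float(rng.uniform(20, 30)),
                gerp_rs=float(rng.uniform(3, 5)),
            )
            for i in range(100)
        ]
        strict, _ = filter_table(variants)
        relaxed, _ = filter_table(
            variants,
            FilterThresholds(sift_max=0.005, polyphen2_hvar_min=0.95,
                             cadd_phred_min=22.0, gerp_rs_min=3.5),
        )
        assert {v.variant_id for v in strict} <= {v.variant_id for v in relaxed}


class TestFilterTableAndCrossref:
    def test_survivors_preserve_input_order(self):
        vs = [variant(vid=f"rs{i}", sift=(0.0005 if i % 3 == 0 else 0.5)) for i in range(10)]
        survivors, counts = filter_table(vs)
        assert [v.variant_id for v in survivors] == ["rs0", "rs3", "rs6", "rs9"]
        assert counts == {"PAX3": 4}

    def test_all_missing_table_has_no_survivors(self):
        vs = [
            AnnotatedVariant(gene="G", variant_id=f"rs{i}", protein_change="p.A10V")
            for i in range(5)
        ]
        survivors, counts = filter_table(vs)
        assert survivors == [] and counts == {}

    def test_crossref_partition_arithmetic(self):
        survivors = [variant(vid=f"rs{i}") for i in range(57)]
        known_ids = [f"rs{i}" for i in range(16)]
        known, novel = crossref_known(survivors, known_ids)
        assert len(known) == 16 and len(novel) == 41
        assert len(known) + len(novel) == len(survivors)

    def test_empty_known_list_keeps_all_novel(self):
        survivors = [variant(vid="rs1")]
        known, novel = crossref_known(survivors, [])
        assert known == [] and len(novel) == 1

    def test_random_overlap_matches_set_difference_oracle(self):
        rng = np.random.default_rng(12)
        survivors = [variant(vid=f"rs{i}") for i in range(40)]
        known_ids = {f"rs{i}" for i in rng.choice(60, size=25, replace=False)}
        known, novel = crossref_known(survivors, known_ids)
        assert {v.variant_id for v in novel} == {f"rs{i}" for i in range(40)} - known_ids


class TestConservation:
    def test_identical_column_is_conserved(self):
        a = aln("MRAV", "MRAV", "MRAV")
        assert conservation_check(variant(change="p.Arg2Cys"), a) is True

    def test_one_divergent_row_not_conserved_under_strict_identity(self):
        a = aln("MRAV", "MKAV", "MRAV")
        assert conservation_check(variant(change="p.Arg2Cys"), a) is False
        # a relaxed fraction accepts the 2/3 majority
        assert conservation_check(variant(change="p.Arg2Cys"), a, 0.6) is True

    def test_gap_in_column_breaks_conservation(self):
        a = aln("MRAV", "M-AV")
        assert conservation_check(variant(change="p.Arg2Cys"), a) is False

    def test_reference_residue_mismatch_not_evaluable(self):
        a = aln("MRAV", "MRAV")
        assert conservation_check(variant(change="p.Lys2Cys"), a) is None

    def test_position_beyond_reference_errors(self):
        a = aln("MRAV", "MRAV")
        with pytest.raises(ValueError, match="beyond"):
            conservation_check(variant(change="p.Arg9Cys"), a)

    def test_reference_gaps_shift_columns(self):
        # reference residue 2 sits in alignment column 3
        a = aln("M--RAV", "MKKRAV")
        assert conservation_check(variant(change="p.Arg2Cys"), a) is True

    def test_random_alignment_matches_column_tally_oracle(self):
        rng = np.random.default_rng(13)
        length, n_rows = 20, 5
        ref = "".join(rng.choice(list("ACDEFGHIK"), size=length))
        rows = [ref]
        for _ in range(n_rows - 1):
            chars = list(ref)
            for j in range(length):
                if rng.random() < 0.3:
                    chars[j] = str(rng.choice(list("ACDEFGHIK-")))
            rows.append("".join(chars))
        a = aln(*rows)
        from wsdecipher.io_formats import _AA3TO1

        inv = {v: k for k, v in _AA3TO1.items()}
        for pos in range(1, length + 1):
            col = [r[pos - 1] for r in rows]
            expect = "-" not in col and len(set(col)) == 1
            v = variant(change=f"p.{inv[ref[pos - 1]]}{pos}{inv['C' if ref[pos-1] != 'C' else 'A']}")
            assert conservation_check(v, a) is expect


class TestDomains:
    PAX3_DOMAINS = DomainTable(
        intervals=(
            DomainInterval("PAX3", "paired domain", 1, 128),
            DomainInterval("PAX3", "homeodomain", 219, 278),
        )
    )

    def test_variant_in_paired_domain(self):
        assert domain_localization(variant(change="p.Val114Met"), self.PAX3_DOMAINS) == "paired domain"

    def test_variant_between_domains_is_none(self):
        assert domain_localization(variant(change="p.Arg156Cys"), self.PAX3_DOMAINS) is None

    def test_overlapping_domains_first_match_by_start_end_name(self):
        overlapping = DomainTable(
            intervals=(
                DomainInterval("PAX3", "zzz", 100, 200),
                DomainInterval("PAX3", "aaa", 100, 150),
            )
        )
        assert domain_localization(variant(change="p.Val114Met"), overlapping) == "aaa"

    def test_random_positions_match_interval_scan_oracle(self):
        rng = np.random.default_rng(14)
        intervals = []
        for i in range(15):
            s = int(rng.integers(1, 300))
            intervals.append(DomainInterval("PAX3", f"d{i}", s, s + int(rng.integers(0, 60))))
        table = DomainTable(intervals=tuple(intervals))
        ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end, iv.domain))
        from wsdecipher.io_formats import _AA3TO1

        inv = {v: k for k, v in _AA3TO1.items()}
        for _ in range(50):
            pos = int(rng.integers(1, 360))
            expect = next(
                (iv.domain for iv in ordered if iv.start <= pos <= iv.end), None
            )
            v = variant(change=f"p.{inv['A']}{pos}{inv['V']}")
            assert domain_localization(v, table) == expect


class TestVariantReport:
    def test_planted_bundle_recovered_exactly(self, sim_config):
        table_df, known, alignments, domains, gt = generate_variant_table(sim_config)
        import wsdecipher.io_formats as io_formats

        variants = [
            AnnotatedVariant(
                gene=r["Gene.refGene"], variant_id=r["avsnp147"],
                protein_change=r["AAChange.refGene"],
                **{
                    k: (None if r[c] == "." else float(r[c]))
                    for k, c in (
                        ("sift", "SIFT_score"), ("polyphen2_hvar", "Polyphen2_HVAR_score"),
                        ("mutationtaster", "MutationTaster_score"),
                        ("cadd_phred", "CADD_phred"), ("gerp_rs", "GERP++_RS"),
                    )
                },
            )
            for _, r in table_df.iterrows()
        ]
        reports = build_variant_report(variants, None, known, alignments, domains)
        finals = sorted(r.variant.variant_id for r in reports if r.final_candidate)
        planted = sorted(
            v for vs in gt["planted_final_variants"].values() for v in vs
        )
        assert finals == planted

        # each decoy is rejected at its designed stage
        by_id = {r.variant.variant_id: r for r in reports}
        for vid, stage in gt["decoy_stages"].items():
            r = by_id[vid]
            assert not r.final_candidate
            if stage.startswith("score:"):
                assert not r.filter_pass
            elif stage == "known":
                assert r.filter_pass and r.known_pathogenic
            elif stage == "conservation":
                assert r.filter_pass and not r.known_pathogenic and r.conserved is False
            elif stage == "domain":
                assert r.conserved is True and r.domain is None

        # stage counts are non-increasing along the pipeline
        for counts in stage_counts(reports).values():
            assert (
                counts["n_variants"] >= counts["filter_pass"] >= counts["novel"]
                >= counts["conserved"] >= counts["final"]
            )

    def test_empty_table_gives_empty_report(self):
        assert build_variant_report([], None, [], {}, DomainTable(intervals=())) == []

    def test_failing_only_conservation_recorded(self):
        a = aln("MRAV", "MKAV")
        domains = DomainTable(intervals=(DomainInterval("PAX3", "d", 1, 4),))
        reports = build_variant_report(
            [variant(change="p.Arg2Cys")], None, [], {"PAX3": a}, domains
        )
        r = reports[0]
        assert r.filter_pass and not r.known_pathogenic
        assert r.conserved is False and not r.final_candidate

    def test_gene_without_alignment_not_evaluable_and_excluded(self):
        domains = DomainTable(intervals=(DomainInterval("PAX3", "d", 1, 300),))
        reports = build_variant_report([variant()], None, [], {}, domains)
        assert reports[0].conserved is None and not reports[0].final_candidate
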