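"""Consensus deleteriousness filtering and candidate-variant nomination.

Stage 2 of the pipeline.  Each annotated variant is evaluated against fixed
cutoffs on five deleteriousness predictors; a variant passes only when *all
five* verdicts pass (missing scores fail closed).  Survivors are partitioned
against a known-pathogenic list, checked for evolutionary conservation at
their residue in a cross-species protein alignment, and localized to protein
functional domains.  The final candidates are the variants that

    pass the five-score filter AND are novel AND are conserved AND lie in a
    domain.

Default cutoffs: SIFT <= 0.001, PolyPhen2-HVAR > 0.957, MutationTaster = 1
(within 1e-9), CADD-phred > 25, GERP++ RS > 4.  Boundary semantics are exact:
only SIFT admits equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import (
    GAP,
    AnnotatedVariant,
    DomainTable,
    ProteinAlignment,
    logger,
)

PASS, FAIL, MISSING = "pass", "fail", "missing"

SCORE_FIELDS = ("sift", "polyphen2_hvar", "mutationtaster", "cadd_phred", "gerp_rs")


@dataclass(frozen=True)
class FilterThresholds:
    """Cutoffs for the five-predictor consensus filter.

    Comparison directions are fixed: SIFT passes at or below ``sift_max``;
    PolyPhen2-HVAR, CADD-phred and GERP++ RS pass strictly above their minima;
    MutationTaster passes when its converted score equals
    ``mutationtaster_eq`` within ``mutationtaster_tol``.
    """

    sift_max: float = 0.001
    polyphen2_hvar_min: float = 0.957
    mutationtaster_eq: float = 1.0
    cadd_phred_min: float = 25.0
    gerp_rs_min: float = 4.0
    mutationtaster_tol: float = 1e-9


@dataclass(frozen=True)
class FilterDecision:
    """Per-score verdicts for one variant; overall pass iff all five pass."""

    variant: AnnotatedVariant
    verdicts: Mapping[str, str]  # score field -> pass/fail/missing

    @property
    def overall_pass(self) -> bool:
        return all(self.verdicts[f] == PASS for f in SCORE_FIELDS)


@dataclass
class VariantReport:
    """Staged verdicts for one variant along the nomination pipeline.

    ``conserved`` is ``None`` when conservation could not be evaluated
    (no alignment for the gene, unparsed protein change, or a reference
    residue mismatch); a final candidate requires an affirmative verdict at
    every stage.
    """

    variant: AnnotatedVariant
    filter_pass: bool
    known_pathogenic: bool
    conserved: bool | None
    domain: str | None
    final_candidate: bool = field(init=False)

    def __post_init__(self) -> None:
        self.final_candidate = bool(
            self.filter_pass
            and not self.known_pathogenic
            and self.conserved is True
            and self.domain is not None
        )


def consensus_filter(
    variant: AnnotatedVariant, thresholds: FilterThresholds | None = None
) -> FilterDecision:
    """Evaluate the five predictor cutoffs for one variant (fail-closed)."""
    t = thresholds or FilterThresholds()

    def verdict(value: float | None, ok: bool) -> str:
        if value is None:
            return MISSING
        return PASS if ok else FAIL

    v = variant
    verdicts = {
        "sift": verdict(v.sift, v.sift is not None and v.sift <= t.sift_max),
        "polyphen2_hvar": verdict(
            v.polyphen2_hvar,
            v.polyphen2_hvar is not None and v.polyphen2_hvar > t.polyphen2_hvar_min,
        ),
        "mutationtaster": verdict(
            v.mutationtaster,
            v.mutationtaster is not None
            and abs(v.mutationtaster - t.mutationtaster_eq) <= t.mutationtaster_tol,
        ),
        "cadd_phred": verdict(
            v.cadd_phred, v.cadd_phred is not None and v.cadd_phred > t.cadd_phred_min
        ),
        "gerp_rs": verdict(v.gerp_rs, v.gerp_rs is not None and v.gerp_rs > t.gerp_rs_min),
    }
    return FilterDecision(variant=variant, verdicts=verdicts)


def filter_table(
    variants: Sequence[AnnotatedVariant], thresholds: FilterThresholds | None = None
) -> tuple[list[AnnotatedVariant], dict[str, int]]:
    """Apply the consensus filter to a variant table.

    Returns the survivors in input order and per-gene survivor counts
    (genes sorted lexicographically).
    """
    survivors = [v for v in variants if consensus_filter(v, thresholds).overall_pass]
    counts: dict[str, int] = {}
    for v in survivors:
        counts[v.gene] = counts.get(v.gene, 0) + 1
    return survivors, dict(sorted(counts.items()))


def crossref_known(
    survivors: Sequence[AnnotatedVariant], known_ids: Iterable[str]
) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant]]:
    """Partition survivors into (known-pathogenic, novel) by exact variant-ID
    match; |known| + |novel| = |survivors|."""
    known_set = {k.strip() for k in known_ids}
    known = [v for v in survivors if v.variant_id in known_set]
    novel = [v for v in survivors if v.variant_id not in known_set]
    return known, novel


def conservation_check(
    variant: AnnotatedVariant,
    alignment: ProteinAlignment,
    min_identity_fraction: float = 1.0,
) -> bool | None:
    """Is the variant's residue conserved across the alignment?

    The variant's 1-based protein position is mapped to the alignment column
    holding that reference residue.  The column is conserved iff no sequence
    is gapped there and the modal residue's fraction is >=
    ``min_identity_fraction`` (default 1.0: strict identity across all rows).
    Returns ``None`` (not evaluable, with a warning) when the protein change
    is unparsed or the stated reference amino acid disagrees with the
    alignment's reference sequence; raises if the position exceeds the
    reference's ungapped length.
    """
    if variant.aa_pos is None:
        logger.warning("%s: protein change %r not parseable; conservation not evaluable",
                       variant.variant_id, variant.protein_change)
        return None
    col = alignment.column_for_reference_position(variant.aa_pos)
    column = alignment.column(col)
    ref_residue = alignment.sequences[alignment.reference_id][col]
    if variant.aa_ref is not None and ref_residue != variant.aa_ref:
        logger.warning(
            "%s: stated reference residue %s does not match alignment residue %s at "
            "position %d; conservation not evaluable",
            variant.variant_id, variant.aa_ref, ref_residue, variant.aa_pos,
        )
        return None
    if GAP in column:
        return False
    counts: dict[str, int] = {}
    for c in column:
        counts[c] = counts.get(c, 0) + 1
    modal = max(counts.values())
    return modal / len(column) >= min_identity_fraction


def domain_localization(
    variant: AnnotatedVariant, domains: DomainTable
) -> str | None:
    """Name of the first domain interval (by start, end, name) enclosing the
    variant's residue, or ``None`` when outside every interval (or the
    protein position is unknown).  Bounds are 1-based inclusive."""
    if variant.aa_pos is None:
        return None
    candidates = sorted(
        domains.for_protein(variant.gene), key=lambda iv: (iv.start, iv.end, iv.domain)
    )
    for iv in candidates:
        if iv.start <= variant.aa_pos <= iv.end:
            return iv.domain
    return None


def build_variant_report(
    variants: Sequence[AnnotatedVariant],
    thresholds: FilterThresholds | None,
    known_ids: Iterable[str],
    alignments: Mapping[str, ProteinAlignment],
    domains: DomainTable,
    min_identity_fraction: float = 1.0,
) -> list[VariantReport]:
    """Run the full nomination pipeline over a variant table.

    Stages in order: five-score consensus filter, known-pathogenic
    cross-reference, conservation in the gene's alignment, domain
    localization.  Conservation and domain verdicts are only computed for
    filter-passing novel variants (the later stages cannot resurrect a
    variant).  ``alignments`` maps gene symbol to its cross-species MSA; a
    gene without an alignment yields a not-evaluable conservation verdict.
    """
    known_set = {k.strip() for k in known_ids}
    reports: list[VariantReport] = []
    for v in variants:
        decision = consensus_filter(v, thresholds)
        known = v.variant_id in known_set
        conserved: bool | None = None
        domain: str | None = None
        if decision.overall_pass and not known:
            aln = alignments.get(v.gene)
            if aln is None:
                logger.warning("%s: no alignment for gene %s; conservation not evaluable",
                               v.variant_id, v.gene)
            else:
                conserved = conservation_check(v, aln, min_identity_fraction)
            if conserved:
                domain = domain_localization(v, domains)
        reports.append(
            VariantReport(
                variant=v,
                filter_pass=decision.overall_pass,
                known_pathogenic=known,
                conserved=conserved,
                domain=domain,
            )
        )
    return reports


def stage_counts(reports: Sequence[VariantReport]) -> dict[str, dict[str, int]]:
    """Per-gene counts at each pipeline stage (non-increasing along stages)."""
    genes = sorted({r.variant.gene for r in reports})
    out: dict[str, dict[str, int]] = {}
    for g in genes:
        rs = [r for r in reports if r.variant.gene == g]
        survivors = [r for r in rs if r.filter_pass]
        novel = [r for r in survivors if not r.known_pathogenic]
        conserved = [r for r in novel if r.conserved is True]
        final = [r for r in rs if r.final_candidate]
        out[g] = {
            "n_variants": len(rs),
            "filter_pass": len(survivors),
            "novel": len(novel),
            "conserved": len(conserved),
            "final": len(final),
        }
    return out


def report_frame(reports: Sequence[VariantReport]) -> pd.DataFrame:
    """Flatten variant reports into a deterministic table."""
    rows = []
    for r in reports:
        rows.append(
            {
                "gene": r.variant.gene,
                "variant_id": r.variant.variant_id,
                "protein_change": r.variant.protein_change,
                "filter_pass": r.filter_pass,
                "known_pathogenic": r.known_pathogenic,
                "conserved": "NA" if r.conserved is None else str(r.conserved),
                "domain": r.domain if r.domain is not None else "NA",
                "final_candidate": r.final_candidate,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "variant_id", "protein_change", "filter_pass",
            "known_pathogenic", "conserved", "domain", "final_candidate",
        ],
    )


def decisions_frame(
    variants: Sequence[AnnotatedVariant], thresholds: FilterThresholds | None = None
) -> pd.DataFrame:
    """Per-score verdict table for every variant."""
    rows = []
    for v in variants:
        d = consensus_filter(v, thresholds)
        row = {"gene": v.gene, "variant_id": v.variant_id}
        row.update({f: d.verdicts[f] for f in SCORE_FIELDS})
        row["overall_pass"] = d.overall_pass
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["gene", "variant_id", *SCORE_FIELDS, "overall_pass"]
    )
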