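"""End-to-end orchestration: one structured config, three stages, one report.

Stages run in order prioritize -> filter-variants -> associate; each can be
toggled off, in which case its outputs are simply omitted.  All enabled
stages' inputs are validated *before* any computation (fail-fast), outputs
are written to a temporary directory and moved into place only on success,
and the run report records per-stage summaries, the config echo and SHA-256
checksums of every input so a run is fully reproducible.
"""

from __future__ import annotations

import datetime
import hashlib
import shutil
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io_formats import (
    logger,
    read_alignment,
    read_cohort_table,
    read_domain_table,
    read_edge_list,
    read_gene_phenotype_map,
    read_known_variant_ids,
    read_tsv,
    read_variant_table,
    write_json,
    write_tsv,
)
from .gene_prioritization import EvidenceTable, run_prioritization
from .variant_filtering import (
    FilterThresholds,
    build_variant_report,
    decisions_frame,
    report_frame,
    stage_counts,
)
from .association_analysis import (
    DEFAULT_GENES,
    association_table,
    distribution_summaries,
    phi_matrix,
    prevalence_table,
    sex_difference_tests,
)


@dataclass
class RunConfig:
    """Paths, stage toggles and thresholds for one pipeline run."""

    out_dir: str = "ws_run"
    seed: int = 0
    stages: tuple[str, ...] = ("prioritize", "filter-variants", "associate")

    # prioritize
    seeds_path: str | None = None
    ppi_paths: tuple[str, ...] = ()
    gene_phenotype_path: str | None = None
    evidence_path: str | None = None
    required_flags: tuple[str, ...] = ()
    weight_threshold: float = 0.2
    top_n: int | None = None

    # filter-variants
    variants_path: str | None = None
    known_path: str | None = None
    msa_paths: dict[str, str] = field(default_factory=dict)  # gene -> aligned FASTA
    msa_reference_id: str = "Homo_sapiens"
    domains_path: str | None = None
    min_identity_fraction: float = 1.0
    sift_max: float = 0.001
    polyphen2_hvar_min: float = 0.957
    mutationtaster_eq: float = 1.0
    cadd_phred_min: float = 25.0
    gerp_rs_min: float = 4.0

    # associate
    cohort_path: str | None = None
    association_genes: tuple[str, ...] = DEFAULT_GENES
    alpha: float = 0.05

    def __post_init__(self) -> None:
        known_stages = {"prioritize", "filter-variants", "associate"}
        bad = set(self.stages) - known_stages
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")
        if not 0.0 <= self.weight_threshold <= 1.0:
            raise ValueError("weight_threshold outside [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha outside (0, 1)")
        if not 0.0 < self.min_identity_fraction <= 1.0:
            raise ValueError("min_identity_fraction outside (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("stages", "ppi_paths", "required_flags", "association_genes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def thresholds(self) -> FilterThresholds:
        return FilterThresholds(
            sift_max=self.sift_max,
            polyphen2_hvar_min=self.polyphen2_hvar_min,
            mutationtaster_eq=self.mutationtaster_eq,
            cadd_phred_min=self.cadd_phred_min,
            gerp_rs_min=self.gerp_rs_min,
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _required_inputs(config: RunConfig) -> dict[str, str]:
    """Map input label -> path for every enabled stage."""
    req: dict[str, str] = {}
    if "prioritize" in config.stages:
        req["seeds"] = config.seeds_path or ""
        req["gene_phenotype"] = config.gene_phenotype_path or ""
        for i, p in enumerate(config.ppi_paths):
            req[f"ppi_{i}"] = p
        if len(config.ppi_paths) < 2:
            raise ValueError("prioritize stage needs >= 2 PPI edge lists")
        if config.evidence_path:
            req["evidence"] = config.evidence_path
    if "filter-variants" in config.stages:
        req["variants"] = config.variants_path or ""
        req["known"] = config.known_path or ""
        req["domains"] = config.domains_path or ""
        for gene, p in config.msa_paths.items():
            req[f"msa_{gene}"] = p
    if "associate" in config.stages:
        req["cohort"] = config.cohort_path or ""
    return req


def _read_seed_list(path: str | Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip().upper() for line in fh if line.strip()]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and write a combined run report.

    Validation of every enabled stage's inputs happens before any stage runs;
    outputs are staged in a temporary directory and moved into ``out_dir``
    only on success, so a failed run leaves no partial outputs behind.
    Returns the run report (also written as ``run_report.json``).
    """
    required = _required_inputs(config)
    missing = [f"{label}: {path!r}" for label, path in required.items()
               if not path or not Path(path).is_file()]
    if missing:
        raise FileNotFoundError("missing input file(s): " + "; ".join(missing))

    report: dict = {
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "input_checksums": {label: _sha256(path) for label, path in sorted(required.items())},
        "stages": {},
    }

    out_dir = Path(config.out_dir)
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(prefix=".ws_run_", dir=out_dir.parent))
    try:
        if "prioritize" in config.stages:
            report["stages"]["prioritize"] = _run_prioritize(config, tmp)
        if "filter-variants" in config.stages:
            report["stages"]["filter_variants"] = _run_filter(config, tmp)
        if "associate" in config.stages:
            report["stages"]["associate"] = _run_associate(config, tmp)
        write_json(report, tmp / "run_report.json")
        if out_dir.exists():
            shutil.rmtree(out_dir)
        tmp.replace(out_dir)
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    logger.info("pipeline finished; outputs in %s", out_dir)
    return report


def _run_prioritize(config: RunConfig, out: Path) -> dict:
    seeds = _read_seed_list(config.seeds_path)
    networks = [
        read_edge_list(p, source_name=Path(p).stem) for p in config.ppi_paths
    ]
    annotations = read_gene_phenotype_map(config.gene_phenotype_path)
    evidence = None
    if config.evidence_path:
        evidence = EvidenceTable.from_frame(read_tsv(config.evidence_path))
    result = run_prioritization(
        seeds,
        networks,
        annotations,
        threshold=config.weight_threshold,
        evidence=evidence,
        required_flags=config.required_flags,
        top_n=config.top_n,
    )
    sets = result["sets"]
    write_tsv(pd.DataFrame({"gene": sorted(sets.set_a)}), out / "set_A.tsv")
    write_tsv(result["weights"], out / "weights.tsv")
    write_tsv(pd.DataFrame({"gene": sorted(sets.set_b)}), out / "set_B.tsv")
    candidates = sorted(sets.high_priority if sets.high_priority is not None
                        else sets.preliminary)
    write_tsv(pd.DataFrame({"gene": candidates}), out / "candidates.tsv")
    write_tsv(result["shared_phenotypes"], out / "shared_phenotypes.tsv")
    return {
        "n_ws": result["n_ws"],
        "partner_set_sizes": result["partner_set_sizes"],
        "set_a_size": len(sets.set_a),
        "set_b_size": len(sets.set_b),
        "preliminary": sorted(sets.preliminary),
        "high_priority": sorted(sets.high_priority) if sets.high_priority is not None else None,
        "total_shared_terms": result["total_shared_terms"],
    }


def _run_filter(config: RunConfig, out: Path) -> dict:
    variants = read_variant_table(config.variants_path)
    known = read_known_variant_ids(config.known_path)
    alignments = {
        gene.upper(): read_alignment(path, config.msa_reference_id)
        for gene, path in config.msa_paths.items()
    }
    domains = read_domain_table(config.domains_path)
    thresholds = config.thresholds()
    reports = build_variant_report(
        variants, thresholds, known, alignments, domains,
        min_identity_fraction=config.min_identity_fraction,
    )
    write_tsv(decisions_frame(variants, thresholds), out / "decisions.tsv")
    write_tsv(report_frame(reports), out / "report.tsv")
    counts = stage_counts(reports)
    write_json(counts, out / "summary.json")
    return {
        "n_variants": len(variants),
        "stage_counts": counts,
        "final_candidates": sorted(
            r.variant.variant_id for r in reports if r.final_candidate
        ),
    }


def _run_associate(config: RunConfig, out: Path) -> dict:
    cohort = read_cohort_table(config.cohort_path)
    genes = [g for g in config.association_genes if g in cohort.gene_vocabulary]
    write_tsv(prevalence_table(cohort, genes=genes or None), out / "prevalence.tsv")
    group_df, pair_df = association_table(cohort, genes=genes)
    write_tsv(group_df, out / "group_tests.tsv")
    write_tsv(pair_df, out / "pairwise_tests.tsv")
    mat, mask, _ = phi_matrix(cohort, alpha=config.alpha)
    write_tsv(mat.reset_index(names="phenotype"), out / "phi_matrix.tsv")
    write_tsv(mask.reset_index(names="phenotype"), out / "phi_significant.tsv")
    try:
        sex_df = sex_difference_tests(cohort)
        write_tsv(sex_df, out / "sex_tests.tsv")
        n_sex_sig = int((sex_df["p"] < config.alpha).sum())
    except ValueError as exc:
        logger.warning("sex-difference tests skipped: %s", exc)
        n_sex_sig = None
    dists = distribution_summaries(cohort)
    for name, df in dists.items():
        write_tsv(df, out / f"distribution_{name}.tsv")
    summary = {
        "n_patients": len(cohort),
        "strata": genes,
        "n_group_tests": int(len(group_df)),
        "n_significant_group_tests": int((group_df["p"] < config.alpha).sum()),
        "n_significant_sex_tests": n_sex_sig,
    }
    write_json(summary, out / "summary.json")
    return summary
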