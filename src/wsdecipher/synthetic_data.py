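"""Seeded synthetic-data generators for every pipeline input.

Each generator emulates the statistical structure of one external resource —
PPI edge lists, gene-phenotype annotations, an annotated variant table with
its companion known-pathogenic list / cross-species MSA / domain table, and a
curated patient cohort — while retaining the planted ground truth, so that
every pipeline stage can be exercised and verified offline.

Design: one integer master seed drives an independent child stream per
generator (``default_rng([seed, k])`` with a fixed ``k`` per generator), so
adding or re-running one generator never perturbs the others; a fixed seed
yields byte-identical output files.

Planted structure
-----------------
* PPI trio: the planted consensus genes are adjacent to a seed gene in all
  three networks; decoy partners appear in exactly one or two networks, so
  the consensus recovers the planted set exactly.
* Annotations: the seed genes' term sets union to a P_ws of configured size
  (default 70); each planted gene overlaps it in exactly its target N_g terms.
  Background genes stay at or below the selection boundary (N_g <= 14) and
  high-weight decoys clear it without being PPI partners, so set A ∩ set B is
  exactly the planted gene set.
* Variant bundle: planted final variants pass all five score cutoffs, are
  absent from the known list, sit at fully conserved alignment columns inside
  a domain; decoys each fail at exactly one designed stage, and background
  variants sit at non-conserved columns so chance all-pass score vectors
  cannot reach the final set.
* Cohort: gene by mixture draw; each phenotype Bernoulli with the per-gene
  planted prevalence, then masked unrecorded at the missingness rate;
  designated phenotype pairs are drawn with a planted phi coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ABSENT,
    PRESENT,
    UNRECORDED,
    CohortTable,
    DomainInterval,
    DomainTable,
    PhenotypeAnnotationMap,
    PPINetwork,
    ProteinAlignment,
    write_alignment,
    write_cohort_table,
    write_domain_table,
    write_edge_list,
    write_gene_phenotype_map,
    write_json,
    write_tsv,
    logger,
)

WS_SEED_GENES = ("PAX3", "MITF", "SOX10", "SNAI2", "EDNRB", "EDN3", "KITLG")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Cross-species MSA rows (reference first).
MSA_SPECIES = (
    "Homo_sapiens",
    "Macaca_mulatta",
    "Pan_troglodytes",
    "Mus_musculus",
    "Equus_caballus",
    "Sus_scrofa",
    "Canis_lupus_familiaris",
)

#: 13 common phenotype columns used by the cohort generator.
DEFAULT_PHENOTYPES = (
    "hearing_impairment",
    "iris_pigmentary_abnormality",
    "white_forelock",
    "telecanthus",
    "synophrys",
    "broad_nasal_root",
    "skin_freckles",
    "premature_graying_hair",
    "hypopigmented_skin_patches",
    "aganglionic_megacolon",
    "constipation",
    "underdeveloped_nasal_alae",
    "wide_nasal_bridge",
)

#: Per-gene phenotype prevalence defaults for the three major genes, with a
#: single shared profile for the minor genes.  Magnitudes follow the reported
#: genotype-phenotype gradients (hearing impairment highest under SOX10,
#: telecanthus/white forelock under PAX3, freckles/premature graying under
#: MITF, megacolon essentially SOX10-specific).
DEFAULT_PREVALENCE: dict[str, dict[str, float]] = {
    "PAX3": {
        "hearing_impairment": 0.72, "iris_pigmentary_abnormality": 0.80,
        "white_forelock": 0.55, "telecanthus": 0.90, "synophrys": 0.55,
        "broad_nasal_root": 0.65, "skin_freckles": 0.20,
        "premature_graying_hair": 0.25, "hypopigmented_skin_patches": 0.40,
        "aganglionic_megacolon": 0.0, "constipation": 0.05,
        "underdeveloped_nasal_alae": 0.25, "wide_nasal_bridge": 0.30,
    },
    "MITF": {
        "hearing_impairment": 0.80, "iris_pigmentary_abnormality": 0.65,
        "white_forelock": 0.35, "telecanthus": 0.08, "synophrys": 0.40,
        "broad_nasal_root": 0.45, "skin_freckles": 0.70,
        "premature_graying_hair": 0.43, "hypopigmented_skin_patches": 0.40,
        "aganglionic_megacolon": 0.0, "constipation": 0.05,
        "underdeveloped_nasal_alae": 0.0, "wide_nasal_bridge": 0.0,
    },
    "SOX10": {
        "hearing_impairment": 0.97, "iris_pigmentary_abnormality": 0.80,
        "white_forelock": 0.25, "telecanthus": 0.08, "synophrys": 0.10,
        "broad_nasal_root": 0.20, "skin_freckles": 0.10,
        "premature_graying_hair": 0.20, "hypopigmented_skin_patches": 0.35,
        "aganglionic_megacolon": 0.36, "constipation": 0.45,
        "underdeveloped_nasal_alae": 0.0, "wide_nasal_bridge": 0.0,
    },
    "_minor": {ph: 0.3 for ph in DEFAULT_PHENOTYPES},
}

#: Cohort gene-mixture proportions (reported composition of the 443 cases).
DEFAULT_GENE_MIXTURE: dict[str, float] = {
    "PAX3": 138 / 443, "MITF": 161 / 443, "SOX10": 124 / 443,
    "EDNRB": 13 / 443, "EDN3": 4 / 443, "SNAI2": 2 / 443, "KITLG": 1 / 443,
}

DEFAULT_SUBTYPE_PROBS: dict[str, dict[str, float]] = {
    "PAX3": {"WS1": 0.72, "WS2": 0.17, "WS3": 0.035, "WS4": 0.0, "unclassified": 0.075},
    "MITF": {"WS1": 0.07, "WS2": 0.86, "WS3": 0.0, "WS4": 0.01, "unclassified": 0.06},
    "SOX10": {"WS1": 0.05, "WS2": 0.68, "WS3": 0.0, "WS4": 0.21, "unclassified": 0.06},
    "_minor": {"WS1": 0.05, "WS2": 0.45, "WS3": 0.0, "WS4": 0.45, "unclassified": 0.05},
}

DEFAULT_VARIANT_TYPE_PROBS: dict[str, dict[str, float]] = {
    "PAX3": {"nonsense": 0.15, "frameshift": 0.30, "missense": 0.32, "splicing": 0.10,
             "gross deletion": 0.07, "in-frame deletion": 0.04, "other": 0.02},
    "MITF": {"nonsense": 0.45, "frameshift": 0.22, "missense": 0.12, "splicing": 0.11,
             "gross deletion": 0.02, "in-frame deletion": 0.06, "other": 0.02},
    "SOX10": {"nonsense": 0.25, "frameshift": 0.28, "missense": 0.22, "splicing": 0.10,
              "gross deletion": 0.10, "in-frame deletion": 0.04, "other": 0.01},
    "_minor": {"nonsense": 0.2, "frameshift": 0.3, "missense": 0.3, "splicing": 0.1,
               "gross deletion": 0.05, "in-frame deletion": 0.04, "other": 0.01},
}

DEFAULT_DE_NOVO_RATE: dict[str, float] = {
    "PAX3": 0.12, "MITF": 0.20, "SOX10": 0.62, "_minor": 0.15,
}

COUNTRIES = ("China", "France", "Germany", "Japan", "USA", "Brazil", "India", "Turkey")

#: Synthetic protein lengths and domain layouts consumed by the variant
#: generator (coordinates 1-based inclusive; loosely shaped like the real
#: domain architectures but entirely synthetic).
DEFAULT_PROTEINS: dict[str, dict] = {
    "PAX3": {
        "length": 479,
        "domains": [("paired domain", 34, 161), ("homeodomain", 219, 278),
                    ("transactivation domain", 300, 479)],
    },
    "MITF": {
        "length": 419,
        "domains": [("transactivation domain", 110, 130), ("b-HLH-Zip", 198, 290)],
    },
    "SOX10": {
        "length": 466,
        "domains": [("dimerization domain", 61, 101), ("HMG", 102, 180),
                    ("K2 domain", 233, 306), ("transactivation domain", 400, 466)],
    },
}


@dataclass
class SimulationConfig:
    """Every knob of the synthetic-data generators, with study defaults.

    Probabilities live in [0, 1]; the cohort gene mixture must sum to 1
    within 1e-9.
    """

    seed: int = 0

    # --- PPI trio ---
    seed_genes: tuple[str, ...] = WS_SEED_GENES
    planted_consensus_genes: tuple[str, ...] = ("SIN3A", "EP300", "CHD7", "KIT")
    ppi_source_names: tuple[str, ...] = ("ppi_db1", "ppi_db2", "ppi_db3")
    # decoy one-hop partners per source, present in exactly 1-2 sources
    extra_partner_counts: tuple[int, ...] = (262, 163, 148)
    decoy_share_rate: float = 0.25  # chance a decoy partner is shared by two sources
    n_background_edges: int = 300  # edges among non-seed background genes

    # --- phenotype annotations ---
    n_ws_terms: int = 70
    planted_gene_overlaps: Mapping[str, int] = field(
        default_factory=lambda: {"SIN3A": 17, "EP300": 16, "CHD7": 15, "KIT": 15}
    )
    n_offtarget_terms: int = 20  # extra non-P_ws terms per planted gene
    n_background_genes: int = 500
    max_background_overlap: int = 14  # keeps background genes out of set B
    n_high_weight_decoys: int = 10  # in set B but never in set A

    # --- variant bundle ---
    proteins: Mapping[str, dict] = field(default_factory=lambda: dict(DEFAULT_PROTEINS))
    planted_final_counts: Mapping[str, int] = field(
        default_factory=lambda: {"PAX3": 20, "MITF": 7, "SOX10": 5}
    )
    n_known_decoys_per_gene: int = 2  # pass scores but sit on the known list
    n_background_variants_per_gene: int = 50
    score_pass_probability: float = 0.3  # per score, background variants
    score_missing_rate: float = 0.05  # per score cell, background variants
    n_ref_gap_columns: int = 6  # alignment columns gapped in the reference

    # --- cohort ---
    n_patients: int = 443
    gene_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_MIXTURE)
    )
    prevalence: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(p) for g, p in DEFAULT_PREVALENCE.items()}
    )
    phenotypes: tuple[str, ...] = DEFAULT_PHENOTYPES
    missingness_rate: float = 0.08
    sex_missing_rate: float = 0.27
    male_fraction: float = 0.5
    inheritance_missing_rate: float = 0.45
    de_novo_rate: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DE_NOVO_RATE)
    )
    subtype_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(p) for g, p in DEFAULT_SUBTYPE_PROBS.items()}
    )
    variant_type_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(p) for g, p in DEFAULT_VARIANT_TYPE_PROBS.items()}
    )
    # (phenotype_x, phenotype_y, phi): y is re-drawn conditional on x so the
    # pair carries the planted phi at the per-gene marginals
    planted_phi: tuple[tuple[str, str, float], ...] = (
        ("telecanthus", "broad_nasal_root", 0.40),
        ("synophrys", "broad_nasal_root", 0.56),
    )

    def __post_init__(self) -> None:
        total = sum(self.gene_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"gene mixture proportions sum to {total}, expected 1")
        for name, val in (
            ("decoy_share_rate", self.decoy_share_rate),
            ("score_pass_probability", self.score_pass_probability),
            ("score_missing_rate", self.score_missing_rate),
            ("missingness_rate", self.missingness_rate),
            ("sex_missing_rate", self.sex_missing_rate),
            ("male_fraction", self.male_fraction),
            ("inheritance_missing_rate", self.inheritance_missing_rate),
        ):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        for gene, n_g in self.planted_gene_overlaps.items():
            if n_g > self.n_ws_terms:
                raise ValueError(
                    f"target N_g={n_g} for {gene} exceeds N_ws={self.n_ws_terms}"
                )

    def rng(self, stream: int) -> np.random.Generator:
        """Independent child stream ``stream`` of the master seed."""
        return np.random.default_rng([int(self.seed), int(stream)])


_STREAM_PPI, _STREAM_PHENO, _STREAM_VARIANTS, _STREAM_COHORT = 1, 2, 3, 4


def _profile(mapping: Mapping[str, object], gene: str) -> object:
    """Per-gene entry with a '_minor' fallback."""
    return mapping[gene] if gene in mapping else mapping["_minor"]


# ---------------------------------------------------------------------------
# PPI trio
# ---------------------------------------------------------------------------

def generate_ppi_trio(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[list[PPINetwork], dict]:
    """Three PPI networks whose consensus one-hop partner set is exactly the
    planted gene list.  Decoy partners sit in one or two sources only."""
    rng = config.rng(_STREAM_PPI)
    k = len(config.ppi_source_names)
    if len(config.extra_partner_counts) != k:
        raise ValueError("extra_partner_counts must match the number of sources")
    seeds = [g.upper() for g in config.seed_genes]
    planted = [g.upper() for g in config.planted_consensus_genes]

    per_source: list[set[tuple[str, str]]] = [set() for _ in range(k)]

    def add_edge(i: int, a: str, b: str) -> None:
        per_source[i].add((a, b) if a < b else (b, a))

    # planted consensus partners: adjacent to >= 1 seed in every source
    for gene in planted:
        for i in range(k):
            n_links = 1 + rng.integers(0, 3)
            for s in rng.choice(seeds, size=min(n_links, len(seeds)), replace=False):
                add_edge(i, gene, str(s))

    # decoy partners: each present in exactly one or two sources
    needs = list(config.extra_partner_counts)
    decoy_idx = 0
    while any(n > 0 for n in needs):
        decoy_idx += 1
        gene = f"GP{decoy_idx:04d}"
        open_sources = [i for i in range(k) if needs[i] > 0]
        if len(open_sources) >= 2 and rng.random() < config.decoy_share_rate:
            chosen = rng.choice(open_sources, size=2, replace=False)
        else:
            chosen = [open_sources[int(rng.integers(0, len(open_sources)))]]
        for i in chosen:
            needs[i] -= 1
            seed = str(rng.choice(seeds))
            add_edge(int(i), gene, seed)

    # background edges among non-seed, non-partner genes (present everywhere)
    background = [f"BG{j:04d}" for j in range(2 * config.n_background_edges)]
    for _ in range(config.n_background_edges):
        a, b = rng.choice(len(background), size=2, replace=False)
        for i in range(k):
            add_edge(i, background[a], background[b])

    networks = [
        PPINetwork(source_name=name, edges=frozenset(per_source[i]))
        for i, name in enumerate(config.ppi_source_names)
    ]
    ground_truth = {
        "planted_consensus_genes": sorted(planted),
        "per_source_partner_counts": [
            len(config.planted_consensus_genes) + c for c in config.extra_partner_counts
        ],
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for net in networks:
            write_edge_list(net, out_dir / f"{net.source_name}.tsv")
    return networks, ground_truth


# ---------------------------------------------------------------------------
# Phenotype annotations
# ---------------------------------------------------------------------------

def generate_phenotype_annotations(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[PhenotypeAnnotationMap, dict]:
    """Gene-phenotype annotations where the seed genes' union is a P_ws of
    exactly ``n_ws_terms`` terms and each planted gene overlaps it in exactly
    its target N_g terms."""
    rng = config.rng(_STREAM_PHENO)
    seeds = [g.upper() for g in config.seed_genes]
    p_ws = [f"HP:{7000000 + i:07d}" for i in range(config.n_ws_terms)]
    offtarget_pool = [f"HP:{8000000 + i:07d}" for i in range(2000)]

    ann: dict[str, set[str]] = {}
    # each P_ws term annotated to >= 1 seed so the union is exactly P_ws
    for term in p_ws:
        members = [s for s in seeds if rng.random() < 0.30]
        if not members:
            members = [str(rng.choice(seeds))]
        for s in members:
            ann.setdefault(s, set()).add(term)
    for s in seeds:  # every seed also carries a few private off-P_ws terms
        ann.setdefault(s, set())

    def off_terms(n: int) -> list[str]:
        idx = rng.choice(len(offtarget_pool), size=n, replace=False)
        return [offtarget_pool[i] for i in idx]

    planted = {g.upper(): n for g, n in config.planted_gene_overlaps.items()}
    for gene, n_g in planted.items():
        overlap_idx = rng.choice(config.n_ws_terms, size=n_g, replace=False)
        ann[gene] = {p_ws[i] for i in overlap_idx} | set(off_terms(config.n_offtarget_terms))

    decoys = [f"HW{j:03d}" for j in range(config.n_high_weight_decoys)]
    for gene in decoys:
        n_g = int(rng.integers(config.max_background_overlap + 1, config.n_ws_terms + 1))
        overlap_idx = rng.choice(config.n_ws_terms, size=n_g, replace=False)
        ann[gene] = {p_ws[i] for i in overlap_idx} | set(off_terms(5))

    for j in range(config.n_background_genes):
        gene = f"BG{j:04d}"
        n_g = int(rng.integers(0, config.max_background_overlap + 1))
        terms: set[str] = set(off_terms(int(rng.integers(3, 25))))
        if n_g:
            overlap_idx = rng.choice(config.n_ws_terms, size=n_g, replace=False)
            terms |= {p_ws[i] for i in overlap_idx}
        if terms:
            ann[gene] = terms

    annotations = PhenotypeAnnotationMap(
        annotations={g: frozenset(ts) for g, ts in ann.items() if ts},
        vocabulary=frozenset(t for ts in ann.values() for t in ts),
    )
    ground_truth = {
        "n_ws": config.n_ws_terms,
        "p_ws": sorted(p_ws),
        "planted_gene_overlaps": dict(sorted(planted.items())),
        "high_weight_decoys": decoys,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_gene_phenotype_map(annotations, out_dir / "gene_phenotype.tsv")
    return annotations, ground_truth


# ---------------------------------------------------------------------------
# Variant bundle (table + known list + MSA + domains)
# ---------------------------------------------------------------------------

def _pass_scores(rng: np.random.Generator) -> dict[str, float]:
    return {
        "sift": float(rng.uniform(0.0, 0.001)),
        "polyphen2_hvar": float(rng.uniform(0.958, 1.0)),
        "mutationtaster": 1.0,
        "cadd_phred": float(rng.uniform(25.5, 45.0)),
        "gerp_rs": float(rng.uniform(4.1, 6.5)),
    }


def _fail_score(rng: np.random.Generator, key: str) -> float:
    return {
        "sift": float(rng.uniform(0.01, 1.0)),
        "polyphen2_hvar": float(rng.uniform(0.0, 0.95)),
        "mutationtaster": float(rng.uniform(0.0, 0.9)),
        "cadd_phred": float(rng.uniform(0.0, 24.0)),
        "gerp_rs": float(rng.uniform(-3.0, 3.9)),
    }[key]


_AA1TO3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}

SCORE_COLUMNS = {
    "sift": "SIFT_score",
    "polyphen2_hvar": "Polyphen2_HVAR_score",
    "mutationtaster": "MutationTaster_score",
    "cadd_phred": "CADD_phred",
    "gerp_rs": "GERP++_RS",
}


def generate_variant_table(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, frozenset[str], dict[str, ProteinAlignment], DomainTable, dict]:
    """Variant table plus known list, per-gene MSA and domain table.

    Planted final variants survive every nomination stage; per gene there is
    at least one decoy rejected at each stage (one per failing score, a
    known-pathogenic hit, a non-conserved residue, an out-of-domain residue).
    Background variants draw each score as pass/fail independently but sit at
    non-conserved columns, so the final candidate set equals the planted set
    by construction.
    """
    rng = config.rng(_STREAM_VARIANTS)
    rows: list[dict] = []
    known_ids: set[str] = set()
    alignments: dict[str, ProteinAlignment] = {}
    domain_rows: list[DomainInterval] = []
    planted_ids: dict[str, list[str]] = {}
    decoy_stage: dict[str, str] = {}
    vid_counter = 0

    def next_id() -> str:
        nonlocal vid_counter
        vid_counter += 1
        return f"rs9{vid_counter:06d}"

    for gene in sorted(config.proteins):
        spec = config.proteins[gene]
        length = int(spec["length"])
        domains = [(str(n), int(s), int(e)) for n, s, e in spec["domains"]]
        for name, start, end in domains:
            domain_rows.append(DomainInterval(protein=gene, domain=name, start=start, end=end))
        in_domain = sorted({p for _, s, e in domains for p in range(s, e + 1)})
        out_domain = sorted(set(range(1, length + 1)) - set(in_domain))

        ref = "".join(rng.choice(list(AMINO_ACIDS), size=length))

        n_final = int(config.planted_final_counts.get(gene, 0))
        final_pos = sorted(
            int(p) for p in rng.choice(in_domain, size=n_final, replace=False)
        )
        remaining_in = sorted(set(in_domain) - set(final_pos))
        known_pos = sorted(
            int(p) for p in rng.choice(remaining_in, size=config.n_known_decoys_per_gene,
                                       replace=False)
        )
        remaining_in = sorted(set(remaining_in) - set(known_pos))
        nonconserved_pos = int(rng.choice(remaining_in))
        outdomain_pos = int(rng.choice(out_domain))
        score_decoy_pos = [
            int(p) for p in rng.choice(
                sorted(set(remaining_in) - {nonconserved_pos}), size=5, replace=False
            )
        ]

        # conserved positions: everything except designated variable columns
        taken = set(final_pos) | set(known_pos) | {outdomain_pos} | set(score_decoy_pos)
        variable_pool = sorted(set(range(1, length + 1)) - taken)
        n_variable = max(1, length // 5)
        variable_pos = {nonconserved_pos} | {
            int(p) for p in rng.choice(variable_pool, size=n_variable, replace=False)
        }

        # build the MSA: non-reference rows mutate (or gap) variable columns
        rows_aln: dict[str, list[str]] = {sp: list(ref) for sp in MSA_SPECIES}
        for pos in sorted(variable_pos):
            n_mut = int(rng.integers(1, len(MSA_SPECIES)))  # >= 1 non-ref row differs
            movers = rng.choice(MSA_SPECIES[1:], size=n_mut, replace=False)
            for sp in movers:
                if rng.random() < 0.15:
                    rows_aln[str(sp)][pos - 1] = "-"
                else:
                    alt = str(rng.choice([a for a in AMINO_ACIDS if a != ref[pos - 1]]))
                    rows_aln[str(sp)][pos - 1] = alt
        # reference-gap columns exercise position -> column mapping
        for _ in range(config.n_ref_gap_columns):
            col = int(rng.integers(0, len(rows_aln[MSA_SPECIES[0]]) + 1))
            for sp in MSA_SPECIES:
                char = "-" if sp == MSA_SPECIES[0] else str(rng.choice(list(AMINO_ACIDS)))
                rows_aln[sp].insert(col, char)
        alignments[gene] = ProteinAlignment(
            ids=MSA_SPECIES,
            sequences={sp: "".join(chars) for sp, chars in rows_aln.items()},
            reference_id=MSA_SPECIES[0],
        )

        def change(pos: int) -> str:
            ref_aa = ref[pos - 1]
            alt = str(rng.choice([a for a in AMINO_ACIDS if a != ref_aa]))
            return f"p.{_AA1TO3[ref_aa]}{pos}{_AA1TO3[alt]}"

        def add_row(pos: int, scores: dict[str, float | str], vid: str | None = None) -> str:
            vid = vid or next_id()
            rows.append({"Gene.refGene": gene, "avsnp147": vid,
                         "AAChange.refGene": f"{gene}:NM_000000:exon1:c.0:{change(pos)}",
                         **{SCORE_COLUMNS[k]: v for k, v in scores.items()}})
            return vid

        planted_ids[gene] = [add_row(p, _pass_scores(rng)) for p in final_pos]
        for p in known_pos:
            vid = add_row(p, _pass_scores(rng))
            known_ids.add(vid)
            decoy_stage[vid] = "known"
        for key, p in zip(SCORE_COLUMNS, score_decoy_pos):
            scores = _pass_scores(rng)
            scores[key] = _fail_score(rng, key)
            decoy_stage[add_row(p, scores)] = f"score:{key}"
        decoy_stage[add_row(nonconserved_pos, _pass_scores(rng))] = "conservation"
        decoy_stage[add_row(outdomain_pos, _pass_scores(rng))] = "domain"

        variable_list = sorted(variable_pos - {nonconserved_pos})
        for _ in range(config.n_background_variants_per_gene):
            pos = int(rng.choice(variable_list))
            scores: dict[str, float | str] = {}
            for key in SCORE_COLUMNS:
                if rng.random() < config.score_missing_rate:
                    scores[key] = "."
                elif rng.random() < config.score_pass_probability:
                    scores[key] = _pass_scores(rng)[key]
                else:
                    scores[key] = _fail_score(rng, key)
            add_row(pos, scores)

    # padding entries on the known list that never appear in the table
    for _ in range(10):
        known_ids.add(next_id())

    table = pd.DataFrame(rows)
    domains_table = DomainTable(intervals=tuple(domain_rows))
    ground_truth = {
        "planted_final_variants": {g: sorted(v) for g, v in planted_ids.items()},
        "decoy_stages": dict(sorted(decoy_stage.items())),
        "n_known_ids": len(known_ids),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_tsv(table, out_dir / "variants.tsv")
        with open(out_dir / "known_variants.tsv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write("variant_id\n")
            for vid in sorted(known_ids):
                fh.write(vid + "\n")
        for gene, aln in alignments.items():
            write_alignment(aln, out_dir / f"msa_{gene}.fasta")
        write_domain_table(domains_table, out_dir / "domains.tsv")
    return table, frozenset(known_ids), alignments, domains_table, ground_truth


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _planted_pair_cells(px: float, py: float, phi: float) -> tuple[float, float]:
    """Conditional P(y=1 | x=1) and P(y=1 | x=0) realizing a target phi at
    the given marginals.

    A phi outside the Frechet-feasible range for these marginals is clamped
    to the nearest attainable value (binary marginals bound the achievable
    correlation; e.g. phi = 0.4 is unattainable at marginals 0.08 and 0.45).
    """
    if not (0.0 < px < 1.0 and 0.0 < py < 1.0):
        raise ValueError("planted-phi marginals must be interior")
    sd = np.sqrt(px * (1 - px) * py * (1 - py))
    p11_lo = max(0.0, px + py - 1.0)
    p11_hi = min(px, py)
    phi_lo = (p11_lo - px * py) / sd
    phi_hi = (p11_hi - px * py) / sd
    clamped = min(max(phi, phi_lo), phi_hi)
    if clamped != phi:
        logger.info("planted phi %.3f clamped to %.3f at marginals (%.3f, %.3f)",
                    phi, clamped, px, py)
    p11 = px * py + clamped * sd
    return p11 / px, (py - p11) / (1 - px)


def generate_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[CohortTable, dict]:
    """Synthetic patient cohort drawn from the planted per-gene prevalences.

    Per patient: gene by mixture draw; each phenotype Bernoulli at the
    planted per-gene prevalence, then masked unrecorded independently per
    cell; sex, subtype, variant type and inheritance drawn per config.
    Planted-phi pairs are drawn jointly (the second phenotype conditional on
    the first) so the pair carries the target phi at the per-gene marginals.
    """
    rng = config.rng(_STREAM_COHORT)
    genes = sorted(config.gene_mixture)
    probs = np.array([config.gene_mixture[g] for g in genes])
    phenos = list(config.phenotypes)
    dependent = {y for _, y, _ in config.planted_phi}
    records: list[dict] = []
    for i in range(config.n_patients):
        gene = str(genes[int(rng.choice(len(genes), p=probs))])
        prev = _profile(config.prevalence, gene)
        status: dict[str, bool] = {}
        for ph in phenos:
            if ph in dependent:
                continue
            status[ph] = bool(rng.random() < float(prev.get(ph, 0.0)))
        for x, y, phi in config.planted_phi:
            px, py = float(prev.get(x, 0.0)), float(prev.get(y, 0.0))
            if 0.0 < px < 1.0 and 0.0 < py < 1.0:
                py_given_x1, py_given_x0 = _planted_pair_cells(px, py, phi)
                p = py_given_x1 if status[x] else py_given_x0
            else:
                p = py
            status[y] = bool(rng.random() < p)

        subtype_probs = _profile(config.subtype_probs, gene)
        st_names = sorted(subtype_probs)
        subtype = str(st_names[int(rng.choice(len(st_names),
                                              p=_normalized(subtype_probs, st_names)))])
        vt_probs = _profile(config.variant_type_probs, gene)
        vt_names = sorted(vt_probs)
        variant_type = str(vt_names[int(rng.choice(len(vt_names),
                                                   p=_normalized(vt_probs, vt_names)))])
        if rng.random() < config.sex_missing_rate:
            sex = UNRECORDED
        else:
            sex = "male" if rng.random() < config.male_fraction else "female"
        if rng.random() < config.inheritance_missing_rate:
            inheritance = UNRECORDED
        else:
            dn = float(_profile(config.de_novo_rate, gene))
            inheritance = "de novo" if rng.random() < dn else "familial"

        rec = {
            "patient_id": f"P{i + 1:04d}",
            "family_id": f"F{int(rng.integers(1, max(2, config.n_patients // 2))):04d}",
            "country": str(rng.choice(COUNTRIES)),
            "sex": sex,
            "age": int(rng.integers(0, 65)),
            "subtype": subtype,
            "gene": gene,
            "variant": f"c.{int(rng.integers(1, 1500))}N>N",
            "variant_type": variant_type,
            "inheritance": inheritance,
        }
        for ph in phenos:
            if rng.random() < config.missingness_rate:
                rec[ph] = UNRECORDED
            else:
                rec[ph] = PRESENT if status[ph] else ABSENT
        records.append(rec)

    df = pd.DataFrame(records)
    cohort = CohortTable(
        data=df, phenotypes=phenos, gene_vocabulary=frozenset(g.upper() for g in genes)
    )
    ground_truth = {
        "gene_mixture": {g: config.gene_mixture[g] for g in genes},
        "prevalence": {g: dict(_profile(config.prevalence, g)) for g in genes},
        "planted_phi": [list(t) for t in config.planted_phi],
        "missingness_rate": config.missingness_rate,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort_table(cohort, out_dir / "cohort.tsv")
    return cohort, ground_truth


def _normalized(probs: Mapping[str, float], names: Sequence[str]) -> np.ndarray:
    arr = np.array([float(probs[n]) for n in names])
    total = arr.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"probabilities sum to {total}, expected 1")
    return arr / total


def exact_cohort(
    gene_subtype_counts: Mapping[tuple[str, str], int],
    variant_type_counts: Mapping[str, int] | None = None,
    inheritance_counts: Mapping[str, int] | None = None,
    phenotype_counts: Mapping[str, object] | None = None,
) -> CohortTable:
    """Deterministic cohort with exact marginal counts (no randomness).

    ``gene_subtype_counts`` maps (gene, subtype) to a patient count and fixes
    the cohort size.  ``variant_type_counts`` / ``inheritance_counts`` assign
    those categories to rows in order (remaining rows unrecorded).
    ``phenotype_counts`` maps a phenotype column to either a
    ``(n_present, n_absent, n_unrecorded)`` triple summing to the cohort size
    (assigned across all rows in order) or a ``{gene: triple}`` dict whose
    triples sum to that gene's size (rows of unlisted genes unrecorded).
    Cross-tabulations between columns are incidental; only the stated margins
    are exact, which is all the printed-count arithmetic uses.
    """
    rows: list[dict] = []
    for (gene, subtype), n in sorted(gene_subtype_counts.items()):
        for _ in range(n):
            rows.append({"gene": gene.upper(), "subtype": subtype})
    total = len(rows)
    for i, row in enumerate(rows):
        row["patient_id"] = f"P{i + 1:04d}"

    def assign(counts: Mapping[str, int], column: str, indices: Sequence[int]) -> None:
        stated = sum(counts.values())
        if stated > len(indices):
            raise ValueError(f"{column}: counts sum to {stated} > {len(indices)} rows")
        it = iter(indices)
        for code, n in counts.items():
            for _ in range(n):
                rows[next(it)][column] = code
        for i in it:
            rows[i][column] = UNRECORDED

    if variant_type_counts is not None:
        assign(variant_type_counts, "variant_type", range(total))
    if inheritance_counts is not None:
        assign(inheritance_counts, "inheritance", range(total))

    phenotypes: list[str] = []
    for ph, spec in (phenotype_counts or {}).items():
        phenotypes.append(ph)
        if isinstance(spec, Mapping):
            listed: set[int] = set()
            for gene, (n_p, n_a, n_u) in spec.items():
                idx = [i for i, r in enumerate(rows) if r["gene"] == gene.upper()]
                if n_p + n_a + n_u != len(idx):
                    raise ValueError(
                        f"{ph}/{gene}: triple sums to {n_p + n_a + n_u}, stratum has {len(idx)}"
                    )
                assign({PRESENT: n_p, ABSENT: n_a, UNRECORDED: n_u}, ph, idx)
                listed |= set(idx)
            for i in set(range(total)) - listed:
                rows[i][ph] = UNRECORDED
        else:
            n_p, n_a, n_u = spec
            if n_p + n_a + n_u != total:
                raise ValueError(f"{ph}: triple sums to {n_p + n_a + n_u}, cohort has {total}")
            assign({PRESENT: n_p, ABSENT: n_a, UNRECORDED: n_u}, ph, range(total))

    df = pd.DataFrame(rows)
    ordered = ["patient_id", "gene", "subtype"]
    for col in ("variant_type", "inheritance"):
        if col in df.columns:
            ordered.append(col)
    df = df[ordered + phenotypes]
    return CohortTable(
        data=df,
        phenotypes=phenotypes,
        gene_vocabulary=frozenset(g.upper() for g, _ in gene_subtype_counts),
    )


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

def generate_all(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Emit every synthetic input file plus ground_truth.json; returns the
    combined ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _, gt_ppi = generate_ppi_trio(config, out_dir)
    _, gt_pheno = generate_phenotype_annotations(config, out_dir)
    _, _, _, _, gt_var = generate_variant_table(config, out_dir)
    _, gt_cohort = generate_cohort(config, out_dir)
    with open(out_dir / "seed_genes.txt", "w", encoding="utf-8", newline="\n") as fh:
        for g in config.seed_genes:
            fh.write(g + "\n")
    ground_truth = {
        "seed": config.seed,
        "seed_genes": list(config.seed_genes),
        "ppi": gt_ppi,
        "phenotype_annotations": gt_pheno,
        "variants": gt_var,
        "cohort": gt_cohort,
    }
    write_json(ground_truth, out_dir / "ground_truth.json")
    return ground_truth
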