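"""Candidate disease-gene prioritization by PPI consensus and phenotype similarity.

Stage 1 of the pipeline.  Two candidate sets are built around a panel of seed
(known causative) genes:

* **set A** — genes that directly interact with at least one seed gene in
  *every* supplied protein-protein interaction source (full intersection of
  per-source one-hop partner sets);
* **set B** — genes whose phenotype-similarity weight

  .. math:: W_g = N_g / N_{ws}

  strictly exceeds a threshold (default 0.2), where :math:`P_{ws}` is the
  union of phenotype terms annotated to the seed genes, :math:`N_{ws}` its
  cardinality, and :math:`N_g = |P_g \\cap P_{ws}|` the gene's overlap with it.

The preliminary candidates are A ∩ B; an optional boolean evidence filter
(e.g. "mutations cause hearing impairment in mouse") narrows them to the
high-priority candidates.  Seed genes are excluded from every candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import PhenotypeAnnotationMap, PPINetwork, logger


@dataclass(frozen=True)
class PhenotypeSet:
    """A set of phenotype-term IDs with its cardinality N_ws."""

    terms: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class GeneWeight:
    """Per-gene phenotype overlap N_g and similarity weight W_g = N_g / N_ws."""

    gene: str
    n_overlap: int
    weight: float
    shared_terms: frozenset[str]

    def __post_init__(self) -> None:
        assert len(self.shared_terms) == self.n_overlap


@dataclass(frozen=True)
class CandidateGeneSets:
    """The four nested candidate sets of the prioritization stage."""

    set_a: frozenset[str]
    set_b: frozenset[str]
    preliminary: frozenset[str]
    high_priority: frozenset[str] | None = None


@dataclass(frozen=True)
class EvidenceTable:
    """Per-gene named boolean evidence flags (e.g. mouse-knockout phenotypes)."""

    flags: Mapping[str, Mapping[str, bool]]  # gene -> flag name -> bool
    flag_names: frozenset[str] = field(default=frozenset())

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "EvidenceTable":
        """Build from a DataFrame with a 'gene' column and boolean flag columns."""
        names = [c for c in df.columns if c != "gene"]
        flags = {
            str(row["gene"]).strip().upper(): {n: bool(row[n]) for n in names}
            for _, row in df.iterrows()
        }
        return EvidenceTable(flags=flags, flag_names=frozenset(names))


def _normset(genes: Iterable[str]) -> frozenset[str]:
    return frozenset(g.strip().upper() for g in genes)


def direct_partners(seeds: Iterable[str], network: PPINetwork) -> frozenset[str]:
    """All genes adjacent to >= 1 seed in the network, excluding the seeds.

    One-hop neighbors only; seeds absent from the network contribute nothing.
    """
    seed_set = _normset(seeds)
    if not seed_set:
        raise ValueError("seeds must be nonempty")
    partners: set[str] = set()
    for a, b in network.edges:
        if a in seed_set:
            partners.add(b)
        if b in seed_set:
            partners.add(a)
    return frozenset(partners - seed_set)


def consensus_partners(partner_sets: Sequence[Iterable[str]]) -> frozenset[str]:
    """Exact intersection of per-source partner sets (>= 2 sources required)."""
    if len(partner_sets) < 2:
        raise ValueError(f"consensus requires >= 2 partner sets, got {len(partner_sets)}")
    sets = [_normset(s) for s in partner_sets]
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def ws_phenotype_union(
    seeds: Iterable[str], annotations: PhenotypeAnnotationMap
) -> PhenotypeSet:
    """Union of the seed genes' phenotype sets (P_ws).

    Seeds without annotation are skipped with a warning; if no seed is
    annotated the union is undefined and an error is raised.
    """
    seed_set = sorted(_normset(seeds))
    terms: set[str] = set()
    annotated = 0
    for seed in seed_set:
        p_g = annotations.terms(seed)
        if not p_g:
            logger.warning("seed gene %s has no phenotype annotation; skipped", seed)
            continue
        annotated += 1
        terms |= p_g
    if annotated == 0:
        raise ValueError("no seed gene carries phenotype annotations; P_ws undefined")
    return PhenotypeSet(terms=frozenset(terms))


def phenotype_weight(
    gene: str, p_ws: PhenotypeSet, annotations: PhenotypeAnnotationMap
) -> GeneWeight:
    """Compute N_g and W_g = N_g / N_ws for one gene.

    A gene absent from the annotations gets N_g = 0, W_g = 0.
    """
    if p_ws.size == 0:
        raise ValueError("N_ws must be > 0")
    gene = gene.strip().upper()
    shared = annotations.terms(gene) & p_ws.terms
    return GeneWeight(
        gene=gene,
        n_overlap=len(shared),
        weight=len(shared) / p_ws.size,
        shared_terms=frozenset(shared),
    )


def score_all_genes(
    p_ws: PhenotypeSet,
    annotations: PhenotypeAnnotationMap,
    genes: Iterable[str] | None = None,
) -> list[GeneWeight]:
    """Score every annotated gene (or a given subset) against P_ws."""
    pool = sorted(_normset(genes)) if genes is not None else sorted(annotations.annotations)
    return [phenotype_weight(g, p_ws, annotations) for g in pool]


def select_set_b(
    weights: Iterable[GeneWeight],
    seeds: Iterable[str],
    threshold: float = 0.2,
    top_n: int | None = None,
) -> frozenset[str]:
    """Genes with W_g strictly greater than ``threshold``, seeds excluded.

    ``top_n`` optionally further truncates to the n highest-weight genes
    (ties broken lexicographically); off by default.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    seed_set = _normset(seeds)
    selected = [w for w in weights if w.weight > threshold and w.gene not in seed_set]
    if top_n is not None:
        selected = sorted(selected, key=lambda w: (-w.weight, w.gene))[:top_n]
    return frozenset(w.gene for w in selected)


def prioritize(
    set_a: Iterable[str], set_b: Iterable[str], seeds: Iterable[str] = ()
) -> CandidateGeneSets:
    """Intersect sets A and B into the preliminary candidate set."""
    seed_set = _normset(seeds)
    a = _normset(set_a) - seed_set
    b = _normset(set_b) - seed_set
    return CandidateGeneSets(set_a=a, set_b=b, preliminary=a & b)


def evidence_filter(
    preliminary: Iterable[str],
    evidence: EvidenceTable,
    required_flags: Sequence[str],
) -> frozenset[str]:
    """Keep genes whose evidence flags are all true for ``required_flags``.

    Unknown flag names are an error; genes absent from the evidence table are
    excluded (logged).  An empty requirement list is the identity.
    """
    unknown = [f for f in required_flags if f not in evidence.flag_names]
    if unknown:
        raise ValueError(f"unknown evidence flag(s): {unknown}")
    genes = _normset(preliminary)
    if not required_flags:
        return genes
    kept: set[str] = set()
    for gene in sorted(genes):
        row = evidence.flags.get(gene)
        if row is None:
            logger.info("gene %s absent from evidence table; excluded", gene)
            continue
        if all(row[f] for f in required_flags):
            kept.add(gene)
    return frozenset(kept)


def shared_phenotype_counts(
    candidates: Iterable[str],
    p_ws: PhenotypeSet,
    annotations: PhenotypeAnnotationMap,
) -> tuple[pd.DataFrame, int]:
    """Per-candidate N_g with the sorted shared-term list, plus the total
    number of distinct P_ws terms shared by any candidate."""
    rows = []
    union: set[str] = set()
    for gene in sorted(_normset(candidates)):
        gw = phenotype_weight(gene, p_ws, annotations)
        union |= gw.shared_terms
        rows.append(
            {
                "gene": gene,
                "n_shared": gw.n_overlap,
                "weight": gw.weight,
                "shared_terms": ",".join(sorted(gw.shared_terms)),
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "n_shared", "weight", "shared_terms"])
    return df, len(union)


def run_prioritization(
    seeds: Sequence[str],
    networks: Sequence[PPINetwork],
    annotations: PhenotypeAnnotationMap,
    threshold: float = 0.2,
    evidence: EvidenceTable | None = None,
    required_flags: Sequence[str] = (),
    top_n: int | None = None,
) -> dict:
    """End-to-end stage 1: returns sets, weights table and shared-term table."""
    partner_sets = [direct_partners(seeds, net) for net in networks]
    set_a = consensus_partners(partner_sets)
    p_ws = ws_phenotype_union(seeds, annotations)
    weights = score_all_genes(p_ws, annotations)
    set_b = select_set_b(weights, seeds, threshold=threshold, top_n=top_n)
    sets = prioritize(set_a, set_b, seeds)
    high_priority: frozenset[str] | None = None
    if evidence is not None and required_flags:
        high_priority = evidence_filter(sets.preliminary, evidence, required_flags)
        sets = CandidateGeneSets(
            set_a=sets.set_a,
            set_b=sets.set_b,
            preliminary=sets.preliminary,
            high_priority=high_priority,
        )
    shared_df, total_shared = shared_phenotype_counts(sets.preliminary, p_ws, annotations)
    weights_df = pd.DataFrame(
        [
            {"gene": w.gene, "n_overlap": w.n_overlap, "weight": w.weight}
            for w in sorted(weights, key=lambda w: w.gene)
        ],
        columns=["gene", "n_overlap", "weight"],
    )
    return {
        "n_ws": p_ws.size,
        "p_ws": sorted(p_ws.terms),
        "partner_set_sizes": [len(s) for s in partner_sets],
        "sets": sets,
        "weights": weights_df,
        "shared_phenotypes": shared_df,
        "total_shared_terms": total_shared,
    }
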