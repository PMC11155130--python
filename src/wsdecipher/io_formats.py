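"""Readers and writers for the external files the pipeline consumes and emits.

Every loader validates its schema strictly and normalizes gene symbols
(uppercase, surrounding whitespace stripped; an optional alias table may be
applied before normalization).  All writers emit UTF-8, LF-terminated TSV or
JSON with deterministic ordering so that repeated runs are byte-identical.

Conventions
-----------
* Protein coordinates are 1-based and inclusive throughout.
* Missing numeric score cells ("." or blank) parse to ``None``, never 0.
* Phenotype status in cohort tables is ternary: ``present`` / ``absent`` /
  ``unrecorded``; denominators downstream use recorded patients only.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("wsdecipher")

GAP = "-"

#: Canonical ternary codes used in memory.
PRESENT, ABSENT, UNRECORDED = "present", "absent", "unrecorded"

#: Cohort metadata columns recognized by :func:`read_cohort_table`; every
#: other column is treated as a phenotype unless ``phenotype_columns`` says
#: otherwise.
COHORT_METADATA_COLUMNS = (
    "patient_id",
    "family_id",
    "country",
    "sex",
    "age",
    "subtype",
    "gene",
    "variant",
    "variant_type",
    "inheritance",
)

SEX_CODES = ("male", "female", UNRECORDED)
SUBTYPE_CODES = ("WS1", "WS2", "WS3", "WS4", "unclassified")
VARIANT_TYPE_CODES = (
    "nonsense",
    "frameshift",
    "missense",
    "splicing",
    "gross deletion",
    "in-frame deletion",
    "other",
)
INHERITANCE_CODES = ("de novo", "familial", UNRECORDED)


class SchemaError(ValueError):
    """Raised when an input file violates its declared schema."""


# ---------------------------------------------------------------------------
# Symbol normalization
# ---------------------------------------------------------------------------

def normalize_symbol(symbol: str, alias_map: Mapping[str, str] | None = None) -> str:
    """Uppercase and strip a gene symbol, optionally resolving an alias.

    Alias keys and values are compared case-insensitively; normalization is
    idempotent provided alias values are canonical (not themselves aliases).
    """
    sym = symbol.strip().upper()
    if alias_map:
        sym = {k.strip().upper(): v.strip().upper() for k, v in alias_map.items()}.get(sym, sym)
    return sym


def _norm(symbol: str, alias_map: Mapping[str, str] | None = None) -> str:
    # internal fast path: alias maps are pre-normalized by their loaders
    sym = symbol.strip().upper()
    if alias_map and sym in alias_map:
        sym = alias_map[sym]
    return sym


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Load an optional two-column (alias, canonical) TSV."""
    out: dict[str, str] = {}
    for lineno, fields in _iter_tsv(path):
        if len(fields) != 2:
            raise SchemaError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
        out[fields[0].strip().upper()] = fields[1].strip().upper()
    return out


def _iter_tsv(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


# ---------------------------------------------------------------------------
# Protein-protein interaction networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PPINetwork:
    """Undirected gene-symbol interaction set from one PPI source.

    Edges are stored as sorted 2-tuples of uppercase symbols; self-loops are
    dropped at load time and the edge set is deduplicated.
    """

    source_name: str
    edges: frozenset[tuple[str, str]]

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(g for e in self.edges for g in e)

    def neighbors(self, gene: str) -> set[str]:
        gene = gene.strip().upper()
        out: set[str] = set()
        for a, b in self.edges:
            if a == gene:
                out.add(b)
            elif b == gene:
                out.add(a)
        return out


_EDGE_HEADER = re.compile(r"^(gene|protein|symbol|interactor|node|source|target)", re.IGNORECASE)


def read_edge_list(
    path: str | Path,
    source_name: str,
    alias_map: Mapping[str, str] | None = None,
) -> PPINetwork:
    """Load a two-column gene-symbol TSV into a :class:`PPINetwork`.

    An optional single header row is detected by its first field matching a
    common column-name pattern (``gene``/``protein``/``symbol``/...).
    Self-loop rows are dropped (count logged); duplicate unordered pairs
    collapse to one edge.
    """
    edges: set[tuple[str, str]] = set()
    self_loops = 0
    first = True
    for lineno, fields in _iter_tsv(path):
        if len(fields) != 2:
            raise SchemaError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
        if first and _EDGE_HEADER.match(fields[0]):
            first = False
            continue
        first = False
        a, b = _norm(fields[0], alias_map), _norm(fields[1], alias_map)
        if not a or not b:
            raise SchemaError(f"{path}: line {lineno}: empty gene symbol")
        if a == b:
            self_loops += 1
            continue
        edges.add((a, b) if a < b else (b, a))
    if self_loops:
        logger.info("%s: dropped %d self-loop edge(s)", path, self_loops)
    return PPINetwork(source_name=source_name, edges=frozenset(edges))


def write_edge_list(network: PPINetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Gene -> phenotype annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeAnnotationMap:
    """Mapping gene -> set of phenotype-term IDs with a term vocabulary.

    Genes with empty term sets are absent rather than present-but-empty.
    """

    annotations: Mapping[str, frozenset[str]]
    vocabulary: frozenset[str]

    def terms(self, gene: str) -> frozenset[str]:
        """The gene's phenotype set P_g (empty if unannotated)."""
        return self.annotations.get(gene.strip().upper(), frozenset())

    def __contains__(self, gene: str) -> bool:
        return gene.strip().upper() in self.annotations


def read_gene_phenotype_map(
    path: str | Path,
    alias_map: Mapping[str, str] | None = None,
) -> PhenotypeAnnotationMap:
    """Load a (gene, phenotype-term-ID) TSV, one pair per row.

    Extra trailing columns (as in HPO ``genes_to_phenotype`` exports) are
    ignored; duplicate pairs collapse.
    """
    ann: dict[str, set[str]] = {}
    first = True
    for lineno, fields in _iter_tsv(path):
        if len(fields) < 2:
            raise SchemaError(f"{path}: line {lineno}: expected >=2 columns, got {len(fields)}")
        if first and _EDGE_HEADER.match(fields[0]):
            first = False
            continue
        first = False
        gene, term = _norm(fields[0], alias_map), fields[1].strip()
        if not gene or not term:
            raise SchemaError(f"{path}: line {lineno}: empty gene or term field")
        ann.setdefault(gene, set()).add(term)
    vocab = frozenset(t for ts in ann.values() for t in ts)
    return PhenotypeAnnotationMap(
        annotations={g: frozenset(ts) for g, ts in ann.items()},
        vocabulary=vocab,
    )


def write_gene_phenotype_map(annotations: PhenotypeAnnotationMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gene in sorted(annotations.annotations):
            for term in sorted(annotations.annotations[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# Annotated variants (ANNOVAR-multianno dialect)
# ---------------------------------------------------------------------------

_AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V",
}

_PCHANGE_RE = re.compile(
    r"p\.(?P<ref>[A-Z][a-z]{2}|[A-Z])(?P<pos>\d+)(?P<alt>[A-Z][a-z]{2}|[A-Z])"
)


def parse_protein_change(text: str) -> tuple[str, int, str] | None:
    """Parse a simple ``p.<ref><pos><alt>`` substitution from ``text``.

    Accepts one- or three-letter amino-acid codes and returns one-letter
    ``(ref, position, alt)``; ``None`` when no substitution pattern matches
    (frameshifts, stops and other HGVS classes pass through unparsed).
    The last ``p.`` token is used so ANNOVAR ``AAChange`` strings like
    ``PAX3:NM_181457:exon2:c.C466T:p.Arg156Cys`` work directly.
    """
    match = None
    for match in _PCHANGE_RE.finditer(text):
        pass
    if match is None:
        return None
    ref, pos, alt = match.group("ref"), int(match.group("pos")), match.group("alt")
    if len(ref) == 3:
        if ref not in _AA3TO1:
            return None
        ref = _AA3TO1[ref]
    if len(alt) == 3:
        if alt not in _AA3TO1:
            return None
        alt = _AA3TO1[alt]
    if pos < 1:
        return None
    return ref, pos, alt


@dataclass
class AnnotatedVariant:
    """One variant with its five deleteriousness-predictor scores.

    Score fields are ``None`` when the annotation is missing; SIFT,
    PolyPhen2-HVAR and MutationTaster live in [0, 1], CADD-phred is
    nonnegative and GERP++ RS is an unconstrained real.
    """

    gene: str
    variant_id: str
    protein_change: str
    sift: float | None = None
    polyphen2_hvar: float | None = None
    mutationtaster: float | None = None
    cadd_phred: float | None = None
    gerp_rs: float | None = None

    aa_ref: str | None = field(default=None, repr=False)
    aa_pos: int | None = field(default=None, repr=False)
    aa_alt: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        parsed = parse_protein_change(self.protein_change or "")
        if parsed is not None:
            self.aa_ref, self.aa_pos, self.aa_alt = parsed
        for name, lo, hi in (
            ("sift", 0.0, 1.0),
            ("polyphen2_hvar", 0.0, 1.0),
            ("mutationtaster", 0.0, 1.0),
            ("cadd_phred", 0.0, None),
        ):
            val = getattr(self, name)
            if val is not None and (val < lo or (hi is not None and val > hi)):
                raise SchemaError(f"{self.variant_id}: {name}={val} outside legal range")


#: Accepted column spellings per logical field (case-insensitive).
VARIANT_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "gene": ("gene.refgene", "gene", "gene_symbol", "genename"),
    "variant_id": ("avsnp147", "avsnp150", "avsnp", "variant_id", "id"),
    "protein_change": ("aachange.refgene", "aachange", "protein_change", "aa_change", "hgvsp"),
    "sift": ("sift_score",),
    "polyphen2_hvar": ("polyphen2_hvar_score",),
    "mutationtaster": ("mutationtaster_score", "mutationtaster"),
    "cadd_phred": ("cadd_phred",),
    "gerp_rs": ("gerp++_rs", "gerp_rs", "gerp.._rs"),
}

_MT_CATEGORICAL = {"A": 1.0, "D": 1.0, "N": 0.0, "P": 0.0}


def _parse_score(cell: str, *, categorical: bool = False) -> tuple[float | None, bool]:
    """Return (value, unparseable) for one score cell."""
    cell = cell.strip()
    if cell in {"", ".", "NA", "na", "NaN"}:
        return None, False
    if categorical and cell.upper() in _MT_CATEGORICAL:
        return _MT_CATEGORICAL[cell.upper()], False
    try:
        return float(cell), False
    except ValueError:
        return None, True


def read_variant_table(
    path: str | Path,
    alias_map: Mapping[str, str] | None = None,
    mutationtaster_categorical: bool = False,
) -> list[AnnotatedVariant]:
    """Load an ANNOVAR-multianno-style variant TSV.

    Mandatory columns (matched case-insensitively against
    :data:`VARIANT_COLUMN_ALIASES`): gene, variant id, amino-acid change and
    the five predictor score columns.  ``"."``/blank score cells become
    missing; unparseable cells also become missing, with a logged count.
    With ``mutationtaster_categorical`` the MutationTaster column may hold
    ANNOVAR prediction codes instead of scores ("A"/"D" deleterious -> 1.0,
    "N"/"P" benign -> 0.0).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    lower = {c.lower(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for logical, names in VARIANT_COLUMN_ALIASES.items():
        for name in names:
            if name in lower:
                resolved[logical] = lower[name]
                break
        else:
            raise SchemaError(
                f"{path}: missing mandatory column '{logical}' "
                f"(accepted names: {', '.join(names)})"
            )

    variants: list[AnnotatedVariant] = []
    unparseable = 0
    for _, row in df.iterrows():
        scores: dict[str, float | None] = {}
        for key in ("sift", "polyphen2_hvar", "mutationtaster", "cadd_phred", "gerp_rs"):
            val, bad = _parse_score(
                row[resolved[key]],
                categorical=mutationtaster_categorical and key == "mutationtaster",
            )
            scores[key] = val
            unparseable += bad
        variants.append(
            AnnotatedVariant(
                gene=_norm(row[resolved["gene"]], alias_map),
                variant_id=row[resolved["variant_id"]].strip(),
                protein_change=row[resolved["protein_change"]].strip(),
                **scores,
            )
        )
    if unparseable:
        logger.warning("%s: %d unparseable score cell(s) treated as missing", path, unparseable)
    return variants


def read_known_variant_ids(path: str | Path) -> frozenset[str]:
    """Load a one-column list of known-pathogenic variant IDs (ClinVar/DVD-like)."""
    ids: set[str] = set()
    first = True
    for lineno, fields in _iter_tsv(path):
        vid = fields[0].strip()
        if first and vid.lower() in {"variant_id", "id", "avsnp147", "avsnp"}:
            first = False
            continue
        first = False
        if not vid:
            raise SchemaError(f"{path}: line {lineno}: empty variant id")
        ids.add(vid)
    return frozenset(ids)


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TernaryEncoding:
    """How a cohort file spells present / absent / unrecorded phenotype cells."""

    present: frozenset[str] = frozenset({"1"})
    absent: frozenset[str] = frozenset({"0"})
    unrecorded: frozenset[str] = frozenset({"", "NA", "na", "."})

    def decode(self, cell: str) -> str | None:
        cell = cell.strip()
        if cell in self.present:
            return PRESENT
        if cell in self.absent:
            return ABSENT
        if cell in self.unrecorded:
            return UNRECORDED
        return None


@dataclass
class CohortTable:
    """Patients x (metadata + ternary phenotype matrix).

    ``data`` holds one row per patient with the metadata columns of
    :data:`COHORT_METADATA_COLUMNS` plus one ternary column per phenotype in
    ``phenotypes``.  Patient IDs are unique; every phenotype cell is one of
    ``present`` / ``absent`` / ``unrecorded``.
    """

    data: pd.DataFrame
    phenotypes: list[str]
    gene_vocabulary: frozenset[str]

    def __len__(self) -> int:
        return len(self.data)

    def recorded(self, phenotype: str) -> pd.DataFrame:
        """Rows whose status for ``phenotype`` is recorded (present or absent)."""
        if phenotype not in self.phenotypes:
            raise KeyError(f"unknown phenotype column: {phenotype}")
        return self.data[self.data[phenotype] != UNRECORDED]


def read_cohort_table(
    path: str | Path,
    phenotype_columns: Sequence[str] | None = None,
    encoding: TernaryEncoding | None = None,
    gene_vocabulary: Iterable[str] | None = None,
) -> CohortTable:
    """Load and validate a patient cohort TSV.

    ``phenotype_columns`` defaults to every column not in
    :data:`COHORT_METADATA_COLUMNS`.  Any cell in a phenotype column that is
    not a legal ternary code raises :class:`SchemaError` naming row and
    column; a duplicate ``patient_id`` is an error.  Per-column unrecorded
    counts are logged.
    """
    encoding = encoding or TernaryEncoding()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "patient_id" not in df.columns:
        raise SchemaError(f"{path}: missing mandatory column 'patient_id'")
    if "gene" not in df.columns:
        raise SchemaError(f"{path}: missing mandatory column 'gene'")
    dupes = df["patient_id"][df["patient_id"].duplicated()]
    if len(dupes):
        raise SchemaError(f"{path}: duplicate patient_id: {sorted(set(dupes))}")

    if phenotype_columns is None:
        phenotypes = [c for c in df.columns if c not in COHORT_METADATA_COLUMNS]
    else:
        phenotypes = list(phenotype_columns)
        missing = [c for c in phenotypes if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: phenotype column(s) not found: {missing}")

    df = df.copy()
    df["gene"] = df["gene"].map(lambda g: g.strip().upper())
    vocab = (
        frozenset(g.strip().upper() for g in gene_vocabulary)
        if gene_vocabulary is not None
        else frozenset(df["gene"])
    )
    illegal_genes = sorted(set(df["gene"]) - vocab)
    if illegal_genes:
        raise SchemaError(f"{path}: gene(s) outside declared vocabulary: {illegal_genes}")

    for col, codes in (
        ("sex", SEX_CODES),
        ("subtype", SUBTYPE_CODES + (UNRECORDED,)),
        ("variant_type", VARIANT_TYPE_CODES + (UNRECORDED,)),
        ("inheritance", INHERITANCE_CODES),
    ):
        if col in df.columns:
            df[col] = df[col].map(lambda s: s.strip() or UNRECORDED)
            bad = sorted(set(df[col]) - set(codes))
            if bad:
                raise SchemaError(f"{path}: column '{col}': illegal code(s) {bad}")

    for col in phenotypes:
        decoded = []
        for i, cell in enumerate(df[col]):
            val = encoding.decode(cell)
            if val is None:
                raise SchemaError(
                    f"{path}: row {i + 2}, column '{col}': illegal ternary code {cell!r}"
                )
            decoded.append(val)
        df[col] = decoded
        n_unrec = sum(v == UNRECORDED for v in decoded)
        if n_unrec:
            logger.info("%s: column '%s': %d unrecorded cell(s)", path, col, n_unrec)

    return CohortTable(data=df, phenotypes=phenotypes, gene_vocabulary=vocab)


def write_cohort_table(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort back out with the default ternary codes (1/0/blank)."""
    df = cohort.data.copy()
    codes = {PRESENT: "1", ABSENT: "0", UNRECORDED: ""}
    for col in cohort.phenotypes:
        df[col] = df[col].map(codes)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Protein alignment and domain tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinAlignment:
    """A cross-species protein MSA with a designated reference sequence.

    Sequences are equal-length gapped strings; ``-`` is the gap character.
    """

    ids: tuple[str, ...]
    sequences: Mapping[str, str]
    reference_id: str

    @property
    def length(self) -> int:
        return len(self.sequences[self.reference_id])

    @property
    def reference_ungapped_length(self) -> int:
        return sum(1 for c in self.sequences[self.reference_id] if c != GAP)

    def column_for_reference_position(self, position: int) -> int:
        """0-based alignment column of the ``position``-th (1-based) non-gap
        reference residue."""
        if position < 1:
            raise ValueError(f"position must be >= 1, got {position}")
        seen = 0
        for col, char in enumerate(self.sequences[self.reference_id]):
            if char != GAP:
                seen += 1
                if seen == position:
                    return col
        raise ValueError(
            f"position {position} beyond reference ungapped length "
            f"{self.reference_ungapped_length}"
        )

    def column(self, col: int) -> list[str]:
        return [self.sequences[sid][col] for sid in self.ids]


def read_alignment(path: str | Path, reference_id: str) -> ProteinAlignment:
    """Load an aligned FASTA; all sequences must share one length and the
    reference id must be present."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SchemaError(f"{path}: empty alignment")
    seqs = {r.id: str(r.seq).upper() for r in records}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise SchemaError(f"{path}: ragged alignment (lengths {sorted(lengths)})")
    if reference_id not in seqs:
        raise SchemaError(f"{path}: reference id '{reference_id}' not in alignment")
    return ProteinAlignment(
        ids=tuple(r.id for r in records), sequences=seqs, reference_id=reference_id
    )


def write_alignment(alignment: ProteinAlignment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for sid in alignment.ids:
            fh.write(f">{sid}\n{alignment.sequences[sid]}\n")


@dataclass(frozen=True)
class DomainInterval:
    protein: str
    domain: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive


@dataclass(frozen=True)
class DomainTable:
    """Protein functional-domain intervals; overlaps are allowed and logged."""

    intervals: tuple[DomainInterval, ...]

    def for_protein(self, protein: str) -> list[DomainInterval]:
        protein = protein.strip().upper()
        return [iv for iv in self.intervals if iv.protein == protein]


def read_domain_table(path: str | Path) -> DomainTable:
    """Load a 4-column (protein, domain, start, end) TSV; 1-based inclusive."""
    intervals: list[DomainInterval] = []
    first = True
    for lineno, fields in _iter_tsv(path):
        if len(fields) != 4:
            raise SchemaError(f"{path}: line {lineno}: expected 4 columns, got {len(fields)}")
        if first and not fields[2].strip().isdigit():
            first = False
            continue
        first = False
        try:
            start, end = int(fields[2]), int(fields[3])
        except ValueError as exc:
            raise SchemaError(f"{path}: line {lineno}: non-integer coordinate") from exc
        if start < 1 or start > end:
            raise SchemaError(f"{path}: line {lineno}: bad interval [{start}, {end}]")
        intervals.append(
            DomainInterval(
                protein=fields[0].strip().upper(),
                domain=fields[1].strip(),
                start=start,
                end=end,
            )
        )
    by_protein: dict[str, list[DomainInterval]] = {}
    for iv in intervals:
        by_protein.setdefault(iv.protein, []).append(iv)
    for protein, ivs in by_protein.items():
        ivs = sorted(ivs, key=lambda iv: (iv.start, iv.end))
        for a, b in zip(ivs, ivs[1:]):
            if b.start <= a.end:
                logger.info("%s: overlapping domains on %s: %s / %s", path, protein, a.domain, b.domain)
    return DomainTable(intervals=tuple(intervals))


def write_domain_table(domains: DomainTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for iv in domains.intervals:
            fh.write(f"{iv.protein}\t{iv.domain}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Deterministic report serialization
# ---------------------------------------------------------------------------

def format_float(x: float) -> str:
    """Fixed 6-significant-digit float formatting used by all writers."""
    return f"{x:.6g}"


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as UTF-8 LF TSV with fixed float formatting."""
    df.to_csv(
        path, sep="\t", index=False, lineterminator="\n", float_format="%.6g", na_rep="NA"
    )


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def write_json(obj: object, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> object:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_report(result: Mapping[str, object] | pd.DataFrame, path: str | Path) -> None:
    """Serialize a stage result deterministically (TSV for tables, JSON otherwise)."""
    path = Path(path)
    if isinstance(result, pd.DataFrame):
        write_tsv(result, path)
    else:
        write_json(result, path)
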