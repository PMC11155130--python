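"""Genotype-phenotype association statistics on a curated cohort table.

Stage 3 of the pipeline.  All phenotype statuses are ternary (present /
absent / unrecorded) and every denominator counts recorded patients only, so
prevalences are reported as k/n fractions with n below the cohort size.

Tests follow standard categorical practice: two-sided Pearson chi-square
without continuity correction as the default, switching to a two-sided exact
test (Fisher for 2x2, Freeman-Halton for 2x3) whenever any expected cell
count falls below 5.  Raw p-values are reported; multiplicity adjustment is
available but off by default.  Pairwise binary co-occurrence is measured by
the phi coefficient, with its p-value from the same chi-square (for a 2x2
table, chi2 = n * phi^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io_formats import ABSENT, PRESENT, UNRECORDED, CohortTable, logger

DEFAULT_GENES = ("PAX3", "MITF", "SOX10")

PEARSON_CHI2 = "pearson_chi2"
FISHER_EXACT = "fisher_exact"

#: Expected-count rule: switch to the exact test below this value.
EXPECTED_COUNT_RULE = 5.0

#: Enumeration bounds for the exact tests.
FISHER_MAX_N_2X2 = 2000
FISHER_MAX_N_2X3 = 500


@dataclass(frozen=True)
class PrevalenceCell:
    """Prevalence of one phenotype in one stratum over recorded patients."""

    phenotype: str
    stratum: str
    n_present: int
    n_recorded: int

    @property
    def proportion(self) -> float | None:
        if self.n_recorded == 0:
            return None
        return self.n_present / self.n_recorded

    def as_fraction_string(self) -> str:
        """Clinical-report-style ``k/n (x.xx%)`` rendering; 'NA' when nothing recorded."""
        if self.n_recorded == 0:
            return "NA"
        return f"{self.n_present}/{self.n_recorded} ({100 * self.proportion:.2f}%)"


@dataclass(frozen=True)
class AssociationResult:
    """Group and pairwise tests of one phenotype's prevalence across strata."""

    phenotype: str
    strata: tuple[str, ...]
    table: tuple[tuple[int, ...], ...]  # rows: present/absent; cols: strata
    test_used: str
    p_group: float
    pairwise: tuple[tuple[str, str, str, float], ...]  # (a, b, test, p)


@dataclass(frozen=True)
class PhiResult:
    """Phi co-occurrence of two ternary phenotypes over doubly-recorded patients.

    ``phi`` is ``None`` (undefined) when any margin of the 2x2 table is zero;
    the p-value comes from the uncorrected Pearson chi-square on the same
    table and is likewise ``None`` when undefined.
    """

    phenotype_a: str
    phenotype_b: str
    a: int  # both present
    b: int  # a present, b absent
    c: int  # a absent, b present
    d: int  # both absent
    phi: float | None
    p: float | None


# ---------------------------------------------------------------------------
# Core categorical tests
# ---------------------------------------------------------------------------

def pearson_chi2(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square test of independence on an r x c table.

    Returns (statistic, df, p) with statistic = sum (O-E)^2 / E,
    df = (r-1)(c-1), and an upper-tail chi-square p-value.  A zero row or
    column margin is an error (expected counts must be positive).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError(f"need an r x c table with r, c >= 2, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValueError("negative counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero row or column margin; expected counts must be > 0")
    expected = np.outer(row, col) / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


def _log_table_prob(table: np.ndarray, logfact_row: float, logfact_col: float,
                    logfact_n: float) -> np.ndarray:
    """Multivariate hypergeometric log-probability of margin-fixed tables."""
    return logfact_row + logfact_col - logfact_n - gammaln(table + 1).sum(axis=(-2, -1))


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided exact test on a 2x2 or 2x3 count table by full enumeration.

    All tables with the observed margins are enumerated under the
    (multivariate) hypergeometric null; the two-sided p-value is the total
    probability of tables whose probability does not exceed the observed
    table's (with 1e-12 relative slack to absorb floating-point ties).  For
    2x2 this is the classic Fisher rule; for 2x3 it is the Freeman-Halton
    test.  Enumeration is bounded (n <= 2000 for 2x2, n <= 500 for 2x3);
    larger tables raise with an instruction to use the chi-square test.
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2 or obs.shape[0] != 2 or obs.shape[1] not in (2, 3):
        raise ValueError(f"fisher_exact supports 2x2 and 2x3 tables, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValueError("negative counts")
    n = int(obs.sum())
    max_n = FISHER_MAX_N_2X2 if obs.shape[1] == 2 else FISHER_MAX_N_2X3
    if n > max_n:
        raise ValueError(
            f"table total {n} exceeds the enumeration bound {max_n}; "
            "use pearson_chi2 instead"
        )
    if n == 0:
        return 1.0
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)

    logfact_row = float(gammaln(row + 1).sum())
    logfact_col = float(gammaln(col + 1).sum())
    logfact_n = float(gammaln(n + 1))

    if obs.shape[1] == 2:
        # one free cell: n11 ranges over the hypergeometric support
        lo = max(0, row[0] - col[1])
        hi = min(row[0], col[0])
        n11 = np.arange(lo, hi + 1)
        tables = np.stack(
            [n11, row[0] - n11, col[0] - n11, col[1] - row[0] + n11], axis=-1
        ).reshape(-1, 2, 2)
    else:
        # two free cells (n11, n12); vectorized grid filtered for validity
        n11 = np.arange(0, min(row[0], col[0]) + 1)
        n12 = np.arange(0, min(row[0], col[1]) + 1)
        g11, g12 = np.meshgrid(n11, n12, indexing="ij")
        g13 = row[0] - g11 - g12
        valid = (g13 >= 0) & (g13 <= col[2]) & (col[0] - g11 >= 0) & (col[1] - g12 >= 0)
        g11, g12, g13 = g11[valid], g12[valid], g13[valid]
        tables = np.stack(
            [g11, g12, g13, col[0] - g11, col[1] - g12, col[2] - g13], axis=-1
        ).reshape(-1, 2, 3)

    logp = _log_table_prob(tables, logfact_row, logfact_col, logfact_n)
    logp_obs = float(_log_table_prob(obs[None], logfact_row, logfact_col, logfact_n)[0])
    # include tables at most as probable as the observed one (relative slack)
    mask = logp <= logp_obs + np.log1p(1e-12)
    return float(min(1.0, np.exp(logp[mask]).sum()))


def _expected_counts(obs: np.ndarray) -> np.ndarray:
    return np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()


def select_test(obs: np.ndarray, force: str | None = None) -> str:
    """Expected-count rule: exact test if any expected cell < 5, else chi-square."""
    if force in (PEARSON_CHI2, FISHER_EXACT):
        return force
    if (_expected_counts(obs) < EXPECTED_COUNT_RULE).any():
        return FISHER_EXACT
    return PEARSON_CHI2


def _run_test(obs: np.ndarray, force: str | None = None) -> tuple[str, float]:
    test = select_test(obs, force)
    if test == FISHER_EXACT:
        return test, fisher_exact(obs)
    _, _, p = pearson_chi2(obs)
    return test, p


# ---------------------------------------------------------------------------
# Cohort-level statistics
# ---------------------------------------------------------------------------

def prevalence(
    cohort: CohortTable,
    phenotype: str,
    gene: str | None = None,
    stratum_label: str | None = None,
) -> PrevalenceCell:
    """Prevalence of one phenotype over recorded patients, optionally within
    one gene stratum."""
    rows = cohort.recorded(phenotype)
    label = stratum_label or (gene if gene is not None else "all")
    if gene is not None:
        rows = rows[rows["gene"] == gene.strip().upper()]
    n_recorded = len(rows)
    n_present = int((rows[phenotype] == PRESENT).sum())
    if n_recorded == 0:
        logger.info("prevalence of %s in %s: nothing recorded", phenotype, label)
    return PrevalenceCell(
        phenotype=phenotype, stratum=label, n_present=n_present, n_recorded=n_recorded
    )


def prevalence_table(
    cohort: CohortTable,
    phenotypes: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Prevalence of every phenotype overall and per gene stratum."""
    phenotypes = list(phenotypes) if phenotypes is not None else cohort.phenotypes
    genes = list(genes) if genes is not None else sorted(cohort.gene_vocabulary)
    rows = []
    for ph in phenotypes:
        cells = [prevalence(cohort, ph)] + [prevalence(cohort, ph, gene=g) for g in genes]
        for cell in cells:
            rows.append(
                {
                    "phenotype": ph,
                    "stratum": cell.stratum,
                    "n_present": cell.n_present,
                    "n_recorded": cell.n_recorded,
                    "proportion": cell.proportion,
                    "fraction": cell.as_fraction_string(),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["phenotype", "stratum", "n_present", "n_recorded", "proportion", "fraction"],
    )


def _present_absent_table(
    cohort: CohortTable, phenotype: str, strata: Sequence[str]
) -> tuple[list[str], np.ndarray]:
    """Build the 2 x k present/absent table over recorded patients; strata
    with nothing recorded are dropped with a warning."""
    recorded = cohort.recorded(phenotype)
    kept: list[str] = []
    cols: list[list[int]] = []
    for g in strata:
        sub = recorded[recorded["gene"] == g.strip().upper()]
        if len(sub) == 0:
            logger.warning("stratum %s has no recorded %s status; dropped", g, phenotype)
            continue
        kept.append(g.strip().upper())
        cols.append(
            [int((sub[phenotype] == PRESENT).sum()), int((sub[phenotype] == ABSENT).sum())]
        )
    obs = np.array(cols, dtype=np.int64).T if cols else np.empty((2, 0), dtype=np.int64)
    return kept, obs


def group_association_test(
    cohort: CohortTable,
    phenotype: str,
    genes: Sequence[str] = DEFAULT_GENES,
    force_test: str | None = None,
) -> AssociationResult:
    """Compare one phenotype's prevalence across gene strata.

    Builds the 2 x k present/absent table over recorded patients, applies the
    expected-count test-selection rule for the group comparison, and runs the
    same rule on every pairwise 2x2 sub-table.  Raw (unadjusted) p-values.
    """
    kept, obs = _present_absent_table(cohort, phenotype, genes)
    if len(kept) < 2:
        raise ValueError(
            f"group test for {phenotype}: need >= 2 strata with recorded status, "
            f"got {len(kept)}"
        )
    # a phenotype uniformly present (or absent) in every stratum carries no
    # contrast; report p = 1 rather than erroring on the zero margin
    if (obs.sum(axis=1) == 0).any():
        test, p = PEARSON_CHI2, 1.0
    else:
        test, p = _run_test(obs, force_test)
    pairwise: list[tuple[str, str, str, float]] = []
    for i, j in combinations(range(len(kept)), 2):
        sub = obs[:, [i, j]]
        if (sub.sum(axis=1) == 0).any():
            ptest, pp = PEARSON_CHI2, 1.0
        else:
            ptest, pp = _run_test(sub, force_test)
        pairwise.append((kept[i], kept[j], ptest, pp))
    return AssociationResult(
        phenotype=phenotype,
        strata=tuple(kept),
        table=tuple(tuple(int(x) for x in row) for row in obs),
        test_used=test,
        p_group=p,
        pairwise=tuple(pairwise),
    )


def association_table(
    cohort: CohortTable,
    phenotypes: Sequence[str] | None = None,
    genes: Sequence[str] = DEFAULT_GENES,
    adjust: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group and pairwise association tests for many phenotypes.

    ``adjust`` optionally applies Bonferroni ("bonferroni") or
    Benjamini-Hochberg ("bh") correction across the group p-values; raw
    p-values are always retained.
    """
    phenotypes = list(phenotypes) if phenotypes is not None else cohort.phenotypes
    group_rows, pair_rows = [], []
    for ph in phenotypes:
        try:
            res = group_association_test(cohort, ph, genes=genes)
        except ValueError as exc:
            logger.warning("skipping group test for %s: %s", ph, exc)
            continue
        group_rows.append(
            {
                "phenotype": ph,
                "strata": ",".join(res.strata),
                "test_used": res.test_used,
                "p": res.p_group,
            }
        )
        for a, b, test, p in res.pairwise:
            pair_rows.append(
                {"phenotype": ph, "stratum_a": a, "stratum_b": b, "test_used": test, "p": p}
            )
    group_df = pd.DataFrame(group_rows, columns=["phenotype", "strata", "test_used", "p"])
    pair_df = pd.DataFrame(
        pair_rows, columns=["phenotype", "stratum_a", "stratum_b", "test_used", "p"]
    )
    if adjust and len(group_df):
        from statsmodels.stats.multitest import multipletests

        method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[adjust]
        group_df["p_adjusted"] = multipletests(group_df["p"], method=method)[1]
    return group_df, pair_df


# ---------------------------------------------------------------------------
# Phi co-occurrence
# ---------------------------------------------------------------------------

def phi_correlation(
    cohort: CohortTable, phenotype_a: str, phenotype_b: str
) -> PhiResult:
    """Phi coefficient between two phenotypes over patients with both recorded.

    phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)); undefined (None) when any
    margin is zero.  The p-value is the uncorrected Pearson chi-square on the
    same 2x2 table (chi2 = n * phi^2, df = 1).
    """
    df = cohort.data
    both = df[(df[phenotype_a] != UNRECORDED) & (df[phenotype_b] != UNRECORDED)]
    if phenotype_a not in cohort.phenotypes or phenotype_b not in cohort.phenotypes:
        raise KeyError(f"unknown phenotype column: {phenotype_a!r} or {phenotype_b!r}")
    pa = both[phenotype_a] == PRESENT
    pb = both[phenotype_b] == PRESENT
    a = int((pa & pb).sum())
    b = int((pa & ~pb).sum())
    c = int((~pa & pb).sum())
    d = int((~pa & ~pb).sum())
    denom2 = (a + b) * (c + d) * (a + c) * (b + d)
    if denom2 == 0:
        phi, p = None, None
    else:
        phi = (a * d - b * c) / np.sqrt(denom2)
        _, _, p = pearson_chi2([[a, b], [c, d]])
    return PhiResult(
        phenotype_a=phenotype_a, phenotype_b=phenotype_b, a=a, b=b, c=c, d=d,
        phi=None if phi is None else float(phi), p=p,
    )


def phi_matrix(
    cohort: CohortTable, phenotypes: Sequence[str] | None = None, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, list[PhiResult]]:
    """Symmetric phi matrix over all phenotype pairs plus a significance mask.

    The diagonal is 1 by convention; undefined off-diagonal cells are NaN in
    the matrix and False in the mask.
    """
    phenotypes = list(phenotypes) if phenotypes is not None else cohort.phenotypes
    if len(phenotypes) < 2:
        raise ValueError("phi matrix needs >= 2 phenotypes")
    k = len(phenotypes)
    mat = np.full((k, k), np.nan)
    mask = np.zeros((k, k), dtype=bool)
    np.fill_diagonal(mat, 1.0)
    results: list[PhiResult] = []
    for i, j in combinations(range(k), 2):
        res = phi_correlation(cohort, phenotypes[i], phenotypes[j])
        results.append(res)
        if res.phi is not None:
            mat[i, j] = mat[j, i] = res.phi
            sig = res.p is not None and res.p < alpha
            mask[i, j] = mask[j, i] = sig
    mat_df = pd.DataFrame(mat, index=phenotypes, columns=phenotypes)
    mask_df = pd.DataFrame(mask, index=phenotypes, columns=phenotypes)
    return mat_df, mask_df, results


# ---------------------------------------------------------------------------
# Sex differences and distribution summaries
# ---------------------------------------------------------------------------

def sex_difference_tests(
    cohort: CohortTable, phenotypes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-phenotype 2x2 (present/absent x male/female) tests over patients
    with recorded sex and recorded phenotype status."""
    phenotypes = list(phenotypes) if phenotypes is not None else cohort.phenotypes
    if "sex" not in cohort.data.columns:
        raise ValueError("cohort has no 'sex' column")
    rows = []
    for ph in phenotypes:
        sub = cohort.recorded(ph)
        sub = sub[sub["sex"].isin(["male", "female"])]
        males = sub[sub["sex"] == "male"]
        females = sub[sub["sex"] == "female"]
        if len(males) == 0 or len(females) == 0:
            raise ValueError(f"sex test for {ph}: need >= 1 recorded patient per sex")
        obs = np.array(
            [
                [int((males[ph] == PRESENT).sum()), int((females[ph] == PRESENT).sum())],
                [int((males[ph] == ABSENT).sum()), int((females[ph] == ABSENT).sum())],
            ],
            dtype=np.int64,
        )
        if (obs.sum(axis=1) == 0).any():
            test, p = PEARSON_CHI2, 1.0
        else:
            test, p = _run_test(obs)
        rows.append(
            {
                "phenotype": ph,
                "male_present": int(obs[0, 0]),
                "male_recorded": int(obs[:, 0].sum()),
                "female_present": int(obs[0, 1]),
                "female_recorded": int(obs[:, 1].sum()),
                "test_used": test,
                "p": p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "phenotype", "male_present", "male_recorded",
            "female_present", "female_recorded", "test_used", "p",
        ],
    )


def distribution_summaries(cohort: CohortTable) -> dict[str, pd.DataFrame]:
    """Gene-by-subtype and variant-type-by-gene count tables with percentages.

    Overall gene shares use the total cohort as the denominator; per-subtype
    shares use that subtype's total.  Denominators are stated in the output.
    """
    df = cohort.data
    out: dict[str, pd.DataFrame] = {}

    if len(df) == 0:
        out["gene_by_subtype"] = pd.DataFrame(
            columns=["gene", "n_total", "pct_total"]
        )
        out["variant_type_by_gene"] = pd.DataFrame(
            columns=["variant_type", "n_total", "pct_total"]
        )
        return out

    n_total = len(df)
    genes = sorted(df["gene"].unique())
    rows = []
    subtypes = sorted(df["subtype"].unique()) if "subtype" in df.columns else []
    for g in genes:
        sub = df[df["gene"] == g]
        row: dict[str, object] = {
            "gene": g,
            "n_total": len(sub),
            "pct_total": 100.0 * len(sub) / n_total,
        }
        for st in subtypes:
            st_total = int((df["subtype"] == st).sum())
            n = int((sub["subtype"] == st).sum())
            row[f"n_{st}"] = n
            row[f"pct_of_{st}"] = 100.0 * n / st_total if st_total else float("nan")
            row[f"denom_{st}"] = st_total
        rows.append(row)
    out["gene_by_subtype"] = pd.DataFrame(rows)

    if "subtype" in df.columns:
        st_rows = [
            {
                "subtype": st,
                "n": int((df["subtype"] == st).sum()),
                "pct_total": 100.0 * int((df["subtype"] == st).sum()) / n_total,
                "denominator": n_total,
            }
            for st in subtypes
        ]
        out["subtype_distribution"] = pd.DataFrame(st_rows)

    if "variant_type" in df.columns:
        # class shares are over patients with a recorded variant type
        recorded = df[df["variant_type"] != UNRECORDED]
        n_recorded = len(recorded)
        vtypes = sorted(recorded["variant_type"].unique())
        vt_rows = []
        for vt in vtypes:
            sub = recorded[recorded["variant_type"] == vt]
            row = {
                "variant_type": vt,
                "n_total": len(sub),
                "pct_total": 100.0 * len(sub) / n_recorded if n_recorded else float("nan"),
                "denominator": n_recorded,
            }
            for g in genes:
                g_total = int((recorded["gene"] == g).sum())
                n = int((sub["gene"] == g).sum())
                row[f"n_{g}"] = n
                row[f"pct_of_{g}"] = 100.0 * n / g_total if g_total else float("nan")
            vt_rows.append(row)
        out["variant_type_by_gene"] = pd.DataFrame(vt_rows)

    if "inheritance" in df.columns:
        inh_rows = [
            {
                "inheritance": code,
                "n": int((df["inheritance"] == code).sum()),
                "pct_total": 100.0 * int((df["inheritance"] == code).sum()) / n_total,
                "denominator": n_total,
            }
            for code in sorted(df["inheritance"].unique())
        ]
        out["inheritance_distribution"] = pd.DataFrame(inh_rows)

    return out


def inheritance_association(
    cohort: CohortTable, genes: Sequence[str] = DEFAULT_GENES
) -> AssociationResult:
    """De novo vs familial comparison across gene strata (unrecorded excluded)."""
    df = cohort.data
    if "inheritance" not in df.columns:
        raise ValueError("cohort has no 'inheritance' column")
    recorded = df[df["inheritance"] != UNRECORDED]
    kept, cols = [], []
    for g in genes:
        sub = recorded[recorded["gene"] == g.strip().upper()]
        if len(sub) == 0:
            logger.warning("stratum %s has no recorded inheritance; dropped", g)
            continue
        kept.append(g.strip().upper())
        cols.append(
            [int((sub["inheritance"] == "de novo").sum()),
             int((sub["inheritance"] == "familial").sum())]
        )
    if len(kept) < 2:
        raise ValueError("inheritance test: need >= 2 strata with recorded inheritance")
    obs = np.array(cols, dtype=np.int64).T
    if (obs.sum(axis=1) == 0).any():
        test, p = PEARSON_CHI2, 1.0
    else:
        test, p = _run_test(obs)
    pairwise = []
    for i, j in combinations(range(len(kept)), 2):
        sub = obs[:, [i, j]]
        if (sub.sum(axis=1) == 0).any():
            ptest, pp = PEARSON_CHI2, 1.0
        else:
            ptest, pp = _run_test(sub)
        pairwise.append((kept[i], kept[j], ptest, pp))
    return AssociationResult(
        phenotype="de_novo_inheritance",
        strata=tuple(kept),
        table=tuple(tuple(int(x) for x in row) for row in obs),
        test_used=test,
        p_group=p,
        pairwise=tuple(pairwise),
    )
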