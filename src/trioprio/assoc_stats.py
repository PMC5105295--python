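"""Case-control replication statistics on 2x3 genotype count tables.

All tests operate on a :class:`GenotypeCountTable` — cases and controls
counted over the three genotype classes (hom-ref, het, hom-alt) at a biallelic
locus:

* Hardy-Weinberg equilibrium chi-square goodness of fit (1 df, allele
  frequency estimated from the data, no continuity correction).
* Exact Fisher tests by fixed-margin enumeration: the 2x3 genotype table and
  the collapsed 2x2 allele table.  The two-sided p-value follows the
  point-probability ("minlike") criterion: sum the multivariate
  hypergeometric probabilities of every table with the observed margins whose
  probability does not exceed that of the observed table (relative tie
  tolerance 1e-7).  Exact enumeration is cheap at cohort scale (n <= 250).
* Cochran-Armitage trend test with default additive scores (0, 1, 2), in
  asymptotic (1-df chi-square) and Monte-Carlo permutation modes.  The
  permutation null fixes both margins, so case rows are resampled from the
  multivariate hypergeometric distribution of the pooled genotype vector; the
  p-value uses the add-one estimator (r + 1) / (R + 1), which is a valid
  p-value and never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "GenotypeCountTable",
    "AssociationResult",
    "HWEResult",
    "hwe_chisq",
    "fisher_exact_2x3",
    "fisher_exact_allele_2x2",
    "armitage_trend",
    "genotype_frequencies",
]

#: Relative tolerance for probability ties in the minlike criterion.
TIE_RTOL = 1e-7


@dataclass(frozen=True)
class GenotypeCountTable:
    """Counts of (hom-ref, het, hom-alt) genotypes among cases and controls."""

    cases: tuple[int, int, int]
    controls: tuple[int, int, int]

    def __post_init__(self) -> None:
        for arm, counts in (("cases", self.cases), ("controls", self.controls)):
            if len(counts) != 3:
                raise ValueError(f"{arm} must have 3 genotype counts")
            if any(c < 0 or int(c) != c for c in counts):
                raise ValueError(f"{arm} counts must be non-negative integers")
        object.__setattr__(self, "cases", tuple(int(c) for c in self.cases))
        object.__setattr__(self, "controls", tuple(int(c) for c in self.controls))

    @property
    def n_cases(self) -> int:
        return sum(self.cases)

    @property
    def n_controls(self) -> int:
        return sum(self.controls)

    @property
    def column_totals(self) -> tuple[int, int, int]:
        return tuple(a + b for a, b in zip(self.cases, self.controls))

    def allele_counts(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """Collapse genotypes to (ref, alt) allele counts per arm."""
        def collapse(row: tuple[int, int, int]) -> tuple[int, int]:
            n_rr, n_ra, n_aa = row
            return (2 * n_rr + n_ra, n_ra + 2 * n_aa)
        return collapse(self.cases), collapse(self.controls)

    def require_positive_margins(self) -> None:
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError("both case and control row sums must be positive")


@dataclass(frozen=True)
class AssociationResult:
    method: str
    p_value: float
    statistic: Optional[float] = None
    mc_reps: Optional[int] = None
    seed: Optional[int] = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0,1]")


@dataclass(frozen=True)
class HWEResult:
    chi2: float
    df: int
    p_value: float
    allele_freq: float
    flags: tuple[str, ...] = ()


def hwe_chisq(genotype_counts: Sequence[int]) -> HWEResult:
    """Chi-square goodness-of-fit test for Hardy-Weinberg proportions.

    With counts (n_AA, n_Aa, n_aa), the A-allele frequency is estimated as
    p = (2 n_AA + n_Aa) / 2n and the observed counts compared with the HWE
    expectations (n p^2, 2 n p (1-p), n (1-p)^2) on 1 degree of freedom (one
    parameter estimated), no continuity correction.  A monomorphic sample
    fits HWE trivially: chi2 = 0, flagged "monomorphic".
    """
    n_aa_hom, n_het, n_alt_hom = (int(c) for c in genotype_counts)
    n = n_aa_hom + n_het + n_alt_hom
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p_hat = (2 * n_aa_hom + n_het) / (2 * n)
    if p_hat in (0.0, 1.0):
        return HWEResult(chi2=0.0, df=1, p_value=1.0, allele_freq=p_hat,
                         flags=("monomorphic",))
    expected = np.array([n * p_hat ** 2, 2 * n * p_hat * (1 - p_hat),
                         n * (1 - p_hat) ** 2])
    observed = np.array([n_aa_hom, n_het, n_alt_hom], dtype=float)
    mask = expected > 0
    chi2 = float(np.sum((observed[mask] - expected[mask]) ** 2 / expected[mask]))
    return HWEResult(chi2=chi2, df=1, p_value=float(stats.chi2.sf(chi2, 1)),
                     allele_freq=p_hat)


def _fixed_margin_tables(row1_total: int, col_totals: Sequence[int]):
    """Enumerate every first row (a_0..a_k) compatible with fixed margins.

    Returns an integer array of shape (n_tables, k) — the second row is
    implied by the column totals.
    """
    cols = list(col_totals)
    rows: list[tuple[int, ...]] = []

    def rec(prefix: list[int], remaining: int, j: int) -> None:
        if j == len(cols) - 1:
            if 0 <= remaining <= cols[j]:
                rows.append(tuple(prefix + [remaining]))
            return
        tail_capacity = sum(cols[j + 1:])
        lo = max(0, remaining - tail_capacity)
        hi = min(cols[j], remaining)
        for a in range(lo, hi + 1):
            rec(prefix + [a], remaining - a, j + 1)

    rec([], row1_total, 0)
    return np.array(rows, dtype=np.int64)


def _exact_fisher_2xk(row1: Sequence[int], row2: Sequence[int], method: str) -> AssociationResult:
    """Two-sided exact test on a 2xK table via minlike fixed-margin enumeration."""
    row1 = np.asarray(row1, dtype=np.int64)
    row2 = np.asarray(row2, dtype=np.int64)
    n1, n2 = int(row1.sum()), int(row2.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both row sums must be positive")
    cols = row1 + row2
    keep = cols > 0
    row1, cols = row1[keep], cols[keep]
    if len(cols) <= 1:
        # single nonzero genotype column: margins determine the table
        return AssociationResult(method=method, p_value=1.0, statistic=None,
                                 flags=("degenerate",))
    tables = _fixed_margin_tables(n1, cols)
    # log multivariate hypergeometric probability of each candidate first row
    log_binom_cols = (gammaln(cols + 1)[None, :]
                      - gammaln(tables + 1) - gammaln(cols[None, :] - tables + 1))
    n = n1 + n2
    log_denom = gammaln(n + 1) - gammaln(n1 + 1) - gammaln(n - n1 + 1)
    logp = log_binom_cols.sum(axis=1) - log_denom
    obs_idx = np.flatnonzero((tables == row1[None, :]).all(axis=1))[0]
    logp_obs = logp[obs_idx]
    p = float(np.exp(logp[logp <= logp_obs + np.log1p(TIE_RTOL)]).sum())
    return AssociationResult(method=method, p_value=min(p, 1.0),
                             statistic=float(np.exp(logp_obs)))


def fisher_exact_2x3(table: GenotypeCountTable) -> AssociationResult:
    """Exact two-sided Fisher test on the 2x3 case/control genotype table.

    All tables sharing the observed row and column margins are enumerated and
    those no more probable than the observed table (within relative tolerance
    1e-7) contribute to p.  All-zero genotype columns drop out of the
    enumeration; a table with a single nonzero column is fully determined by
    its margins and yields p = 1.
    """
    table.require_positive_margins()
    return _exact_fisher_2xk(table.cases, table.controls, "fisher_exact_2x3")


def fisher_exact_allele_2x2(table: GenotypeCountTable) -> AssociationResult:
    """Exact two-sided Fisher test on the collapsed 2x2 allele-count table."""
    table.require_positive_margins()
    case_alleles, control_alleles = table.allele_counts()
    return _exact_fisher_2xk(case_alleles, control_alleles, "fisher_exact_allele_2x2")


def _trend_statistic(case_rows: np.ndarray, col_totals: np.ndarray,
                     scores: np.ndarray) -> np.ndarray:
    """Cochran-Armitage trend chi-square for one or many candidate case rows."""
    n = int(col_totals.sum())
    r1 = case_rows.sum(axis=-1)
    t = case_rows @ scores
    s1 = float(col_totals @ scores)
    s2 = float(col_totals @ (scores ** 2))
    var_term = n * s2 - s1 ** 2
    num = (n * t - r1 * s1) ** 2
    denom = r1 * (n - r1) * var_term
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, n * num / denom, 0.0)


def armitage_trend(table: GenotypeCountTable, scores: Sequence[float] = (0, 1, 2),
                   mode: str = "asymptotic", reps: int = 100_000,
                   seed: Optional[int] = None) -> AssociationResult:
    """Cochran-Armitage test for trend across scored genotype categories.

    ``asymptotic`` mode refers the classical 1-df trend chi-square to its
    chi-square tail.  ``monte_carlo`` permutes case/control labels over the
    pooled genotypes ``reps`` times (equivalently, redraws the case row from
    the multivariate hypergeometric null with both margins fixed) and returns
    p = (1 + #{permuted statistic >= observed}) / (reps + 1).

    If the genotype scores have zero variance under the observed margins the
    statistic is undefined; p = 1 is returned flagged "zero_score_variance".
    """
    table.require_positive_margins()
    scores = np.asarray(scores, dtype=float)
    cols = np.asarray(table.column_totals, dtype=np.int64)
    n = int(cols.sum())
    s1 = float(cols @ scores)
    if n * float(cols @ scores ** 2) - s1 ** 2 <= 0:
        return AssociationResult(method=f"armitage_{mode}", p_value=1.0,
                                 statistic=None, flags=("zero_score_variance",))
    observed = np.asarray(table.cases, dtype=np.int64)
    stat = float(_trend_statistic(observed[None, :], cols, scores)[0])
    if mode == "asymptotic":
        return AssociationResult(method="armitage_asymptotic",
                                 p_value=max(float(stats.chi2.sf(stat, 1)),
                                             np.finfo(float).tiny),
                                 statistic=stat)
    if mode != "monte_carlo":
        raise ValueError(f"unknown mode {mode!r}")
    if reps < 1:
        raise ValueError("reps must be >= 1 for monte_carlo mode")
    rng = np.random.default_rng(seed)
    # The trend chi-square is symmetric in the two rows, so permuting labels
    # is equivalent to redrawing either arm; drawing the smaller arm makes the
    # p-value bit-for-bit invariant under a case/control label swap.
    m = min(table.n_cases, table.n_controls)
    perm_rows = rng.multivariate_hypergeometric(cols, m, size=reps)
    perm_stats = _trend_statistic(perm_rows, cols, scores)
    exceed = int(np.sum(perm_stats >= stat - 1e-12))
    p = (1 + exceed) / (reps + 1)
    return AssociationResult(method="armitage_monte_carlo", p_value=p,
                             statistic=stat, mc_reps=reps, seed=seed)


def genotype_frequencies(table: GenotypeCountTable, decimals: int = 0):
    """Per-arm genotype frequencies as percentages (rows sum to ~100)."""
    out = {}
    for arm, counts in (("cases", table.cases), ("controls", table.controls)):
        total = sum(counts)
        if total <= 0:
            raise ValueError(f"{arm} row sum must be positive")
        out[arm] = tuple(round(100.0 * c / total, decimals) for c in counts)
    return out
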