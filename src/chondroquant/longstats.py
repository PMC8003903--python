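"""Longitudinal repeated-measures statistics over the cohort table.

The ladder per measure: a normality gate selects the nonparametric branch
(Friedman omnibus, Wilcoxon signed-rank post-hoc, effect size r = |Z|/sqrt(n))
or the parametric branch (one-way within-subject ANOVA, paired t, Cohen's
d_z).  The omnibus runs at alpha = 0.05; the three pairwise comparisons run
only when the omnibus is significant and are judged strictly against the
Bonferroni-corrected alpha = 0.017.

Friedman and Wilcoxon p-values are exact (full enumeration of within-row
orderings / sign assignments, via dynamic programming) whenever feasible,
falling back to the usual chi-square / normal approximations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsConfig",
    "StatResult",
    "FriedmanResult",
    "WilcoxonResult",
    "RMAnovaResult",
    "PairedTResult",
    "shapiro_wilk",
    "friedman",
    "wilcoxon_signed_rank",
    "rm_anova",
    "paired_t",
    "effect_size",
    "run_severity_analysis",
    "cohort_matrix",
]

TIMEPOINTS = ("KL1", "KL2", "KL3")
PAIRS = (("KL1", "KL2"), ("KL1", "KL3"), ("KL2", "KL3"))


# ---------------------------------------------------------------------------
# elementary tests


def shapiro_wilk(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p.  Constant input is degenerate and rejected."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.ptp(v) == 0:
        raise ValueError("degenerate: constant input")
    w, p = sps.shapiro(v)
    return float(w), float(p)


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float  # tie-corrected chi-square statistic
    df: int
    pvalue: float
    method: str  # 'exact' or 'chisq'
    n: int
    k: int


def _rank_rows(matrix: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, matrix)


@lru_cache(maxsize=64)
def _friedman_exact_tail(row_ranks_key: tuple) -> tuple[tuple, tuple, int]:
    """Distribution of sum-of-squared column rank sums under row permutation.

    ``row_ranks_key`` is a tuple of per-row scaled (x2, integer) sorted rank
    tuples.  Returns (support S values, counts, total) where S uses the
    scaled ranks.  Counts are exact integers over the k!^n assignments.
    """
    k = len(row_ranks_key[0])
    states: dict[tuple, int] = {(0,) * (k - 1): 1}
    total_scaled = 0
    for row in row_ranks_key:
        total_scaled += sum(row)
        perms = list(itertools.permutations(row))
        new: dict[tuple, int] = {}
        for state, cnt in states.items():
            for perm in perms:
                key = tuple(s + r for s, r in zip(state, perm[:-1]))
                new[key] = new.get(key, 0) + cnt
        states = new
    dist: dict[int, int] = {}
    for state, cnt in states.items():
        last = total_scaled - sum(state)
        s_val = sum(c * c for c in state) + last * last
        dist[s_val] = dist.get(s_val, 0) + cnt
    support = tuple(sorted(dist))
    counts = tuple(dist[s] for s in support)
    return support, counts, sum(counts)


def friedman(matrix: np.ndarray, method: str = "auto") -> FriedmanResult:
    """Friedman repeated-measures test on an (n subjects x k conditions) matrix.

    The statistic is the tie-corrected chi-square form.  The p-value is
    exact -- the full permutation distribution over within-row orderings --
    when ``k == 3`` and ``n <= 40`` (or on request), otherwise from the
    chi-square approximation with k-1 degrees of freedom.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x conditions)")
    n, k = m.shape
    if n < 2 or k < 3:
        raise ValueError("need n >= 2 subjects and k >= 3 conditions")
    if not np.isfinite(m).all():
        raise ValueError("missing cells: Friedman requires complete rows")

    ranks = _rank_rows(m)
    rj = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float(rj @ rj) - 3.0 * n * (k + 1)
    # tie correction
    tie_term = 0.0
    for row in m:
        _, cnts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(cnts**3 - cnts))
    corr = 1.0 - tie_term / (n * k * (k * k - 1))
    if corr <= 0:  # every row constant
        return FriedmanResult(0.0, k - 1, 1.0, "chisq", n, k)
    stat = chi2 / corr

    use_exact = method == "exact" or (method == "auto" and k == 3 and n <= 40)
    if use_exact:
        key = tuple(tuple(sorted(np.rint(2 * sps.rankdata(row)).astype(int))) for row in m)
        support, counts, total = _friedman_exact_tail(key)
        s_obs = int(np.rint(np.sum((2 * rj) ** 2)))
        tail = sum(c for s, c in zip(support, counts) if s >= s_obs)
        return FriedmanResult(stat, k - 1, tail / total, "exact", n, k)
    return FriedmanResult(stat, k - 1, float(sps.chi2.sf(stat, k - 1)), "chisq", n, k)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # min(W+, W-)
    pvalue: float
    z: float  # normal-approximation Z (no continuity correction)
    n_used: int  # pairs remaining after zero removal
    method: str  # 'exact' or 'approx'
    degenerate: bool = False


def _signed_rank_dist(ranks: tuple[int, ...]) -> np.ndarray:
    """Counts of W+ values over all sign assignments (integer ranks)."""
    total = sum(ranks)
    c = np.zeros(total + 1, dtype=np.float64)
    c[0] = 1.0
    for r in ranks:
        c[r:] = c[r:] + c[:-r]
    return c


def wilcoxon_signed_rank(
    x: np.ndarray,
    y: np.ndarray | None = None,
    mode: str = "auto",
    zero_method: str = "wilcox",
    exact_cutoff: int = 25,
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples (or differences).

    Zero differences are dropped (Wilcoxon's convention; ``zero_method=
    "pratt"`` keeps them in the ranking).  With no ties in |d| and
    ``n <= exact_cutoff`` the p-value is exact: ``P(W+ <= w) + P(W+ >= T-w)``
    with ``w = min(W+, W-)``, enumerated over all 2^n sign assignments.
    Otherwise the normal approximation with tie correction is used.
    """
    d = np.asarray(x, dtype=float) if y is None else np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("differences must be finite")
    nonzero = d != 0
    if not nonzero.any():
        return WilcoxonResult(0.0, np.nan, 0.0, 0, "degenerate", degenerate=True)

    if zero_method == "wilcox":
        dd = d[nonzero]
        ranks = sps.rankdata(np.abs(dd))
    elif zero_method == "pratt":
        ranks_all = sps.rankdata(np.abs(d))
        dd = d[nonzero]
        ranks = ranks_all[nonzero]
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")
    n = len(dd)
    w_plus = float(ranks[dd > 0].sum())
    w_minus = float(ranks[dd < 0].sum())
    w = min(w_plus, w_minus)
    total = w_plus + w_minus

    # normal approximation Z (always computed; feeds the effect size)
    mu = total / 2.0
    _, cnts = np.unique(np.abs(dd), return_counts=True)
    tie_corr = float(np.sum(cnts**3 - cnts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    if zero_method == "pratt":
        nz = int((~nonzero).sum())
        var -= nz * (nz + 1) * (2 * nz + 1) / 24.0
    z = 0.0 if var == 0 else (w_plus - mu) / np.sqrt(var)

    no_ties = len(cnts) == n and zero_method == "wilcox"
    use_exact = mode == "exact" or (mode == "auto" and no_ties and n <= exact_cutoff)
    if use_exact:
        if not no_ties:
            raise ValueError("exact mode requires untied |differences| and wilcox zeros")
        int_ranks = tuple(int(round(r)) for r in ranks)
        dist = _signed_rank_dist(int_ranks)
        tot = dist.sum()
        wi = int(round(w))
        ti = int(round(total))
        p = (dist[: wi + 1].sum() + dist[ti - wi :].sum()) / tot
        return WilcoxonResult(w, min(1.0, float(p)), float(z), n, "exact")
    p = 2.0 * sps.norm.sf(abs(z)) if var > 0 else np.nan
    return WilcoxonResult(w, min(1.0, float(p)), float(z), n, "approx", degenerate=var == 0)


@dataclass(frozen=True)
class RMAnovaResult:
    f: float
    df1: float
    df2: float
    pvalue: float
    epsilon: float = 1.0  # Greenhouse-Geisser epsilon if applied


def rm_anova(matrix: np.ndarray, gg_correction: bool = False) -> RMAnovaResult:
    """One-way within-subject ANOVA on an (n subjects x k conditions) matrix.

    Decomposes total SS into time, subject and error; F = MS_time/MS_error
    with (k-1, (n-1)(k-1)) df.  Sphericity is assumed unless
    ``gg_correction`` scales both df by the Greenhouse-Geisser epsilon.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need n >= 2 subjects and k >= 2 conditions")
    if not np.isfinite(m).all():
        raise ValueError("missing cells: rm_anova requires complete rows")

    gm = m.mean()
    col_means = m.mean(axis=0)
    row_means = m.mean(axis=1)
    ss_time = n * float(((col_means - gm) ** 2).sum())
    ss_subj = k * float(((row_means - gm) ** 2).sum())
    ss_tot = float(((m - gm) ** 2).sum())
    ss_err = max(ss_tot - ss_time - ss_subj, 0.0)

    df1, df2 = float(k - 1), float((n - 1) * (k - 1))
    eps = 1.0
    if gg_correction:
        # epsilon from the double-centered covariance of conditions
        s = np.cov(m, rowvar=False, ddof=1)
        j = np.eye(k) - np.ones((k, k)) / k
        sc = j @ s @ j
        num = np.trace(sc) ** 2
        den = (k - 1) * float(np.sum(sc * sc))
        eps = float(np.clip(num / den if den > 0 else 1.0, 1.0 / (k - 1), 1.0))
    tol = 1e-12 * max(ss_tot, 1e-300)  # guards float dust on constant columns
    if ss_err <= tol:
        if ss_time <= tol:
            return RMAnovaResult(0.0, df1 * eps, df2 * eps, 1.0, eps)
        return RMAnovaResult(np.inf, df1 * eps, df2 * eps, 0.0, eps)
    f = (ss_time / df1) / (ss_err / df2)
    p = float(sps.f.sf(f, df1 * eps, df2 * eps))
    return RMAnovaResult(float(f), df1 * eps, df2 * eps, p, eps)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    pvalue: float
    degenerate: bool = False


def paired_t(x: np.ndarray, y: np.ndarray) -> PairedTResult:
    """Two-sided paired t-test."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if len(d) < 2:
        raise ValueError("need n >= 2 pairs")
    sd = float(d.std(ddof=1))
    if sd == 0:
        return PairedTResult(np.nan, len(d) - 1, np.nan, degenerate=True)
    t = float(d.mean() / (sd / np.sqrt(len(d))))
    p = 2.0 * float(sps.t.sf(abs(t), len(d) - 1))
    return PairedTResult(t, len(d) - 1, p)


def effect_size(x: np.ndarray, y: np.ndarray, family: str = "parametric") -> float:
    """Standardized pairwise effect size.

    Parametric: Cohen's d_z = mean(d) / sd(d).  Nonparametric:
    r = |Z| / sqrt(n) from the Wilcoxon normal approximation, with n the
    number of non-zero pairs.  NaN when degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if family == "parametric":
        d = x - y
        sd = float(d.std(ddof=1))
        return np.nan if sd == 0 else float(d.mean() / sd)
    if family == "nonparametric":
        res = wilcoxon_signed_rank(x, y, mode="approx")
        if res.degenerate or res.n_used == 0:
            return np.nan
        return abs(res.z) / np.sqrt(res.n_used)
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# severity analysis driver


@dataclass
class StatsConfig:
    alpha: float = 0.05
    bonferroni_alpha: float = 0.017  # printed value, strict comparison
    gate: str = "family"  # 'family' (by measure suffix) or 'shapiro'
    family_map: dict = field(
        default_factory=lambda: {"T2": "nonparametric", "thickness": "parametric"}
    )
    shapiro_alpha: float = 0.05
    exact_cutoff_n: int = 25
    gg_correction: bool = False


@dataclass
class StatResult:
    measure: str
    comparison: str  # 'omnibus' or e.g. 'KL1-KL2'
    test: str
    statistic: float
    pvalue: float
    n: int
    significant: bool
    effect_size: float | None = None  # post-hoc comparisons only
    alpha: float = 0.05


def cohort_matrix(table: pd.DataFrame, measure: str) -> tuple[np.ndarray, int]:
    """(n x 3) complete-case matrix for one measure; returns (matrix, n_dropped)."""
    sub = table[table["measure"] == measure]
    pivot = sub.pivot_table(index="knee", columns="timepoint", values="value", aggfunc="first")
    missing = [tp for tp in TIMEPOINTS if tp not in pivot.columns]
    if missing:
        raise ValueError(f"measure {measure!r} lacks timepoints {missing}")
    pivot = pivot[list(TIMEPOINTS)]
    complete = pivot.dropna()
    return complete.to_numpy(dtype=float), int(len(pivot) - len(complete))


def _measure_family(measure: str, cfg: StatsConfig, matrix: np.ndarray) -> str:
    if cfg.gate == "family":
        for suffix, family in cfg.family_map.items():
            if measure.endswith(suffix):
                return family
        return "nonparametric"
    if cfg.gate == "shapiro":
        # center each timepoint, pool, test residual normality
        resid = (matrix - matrix.mean(axis=0)).ravel()
        try:
            _, p = shapiro_wilk(resid)
        except ValueError:
            return "nonparametric"
        return "nonparametric" if p < cfg.shapiro_alpha else "parametric"
    raise ValueError(f"unknown gate {cfg.gate!r}")


def run_severity_analysis(
    table: pd.DataFrame, config: StatsConfig | None = None
) -> pd.DataFrame:
    """Run the omnibus + gated post-hoc ladder for every measure.

    Input is a long-format cohort table with columns knee, timepoint,
    measure, value.  Output is one row per test: the omnibus per measure,
    plus the three pairwise comparisons when (and only when) the omnibus is
    significant at alpha.  Pairwise significance uses the Bonferroni alpha
    strictly (p < 0.017) and carries an effect size.
    """
    cfg = config or StatsConfig()
    required = {"knee", "timepoint", "measure", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    results: list[StatResult] = []
    for measure in sorted(table["measure"].unique()):
        matrix, _ = cohort_matrix(table, measure)
        n = len(matrix)
        if n < 2:
            continue
        family = _measure_family(measure, cfg, matrix)
        if family == "nonparametric":
            omni = friedman(matrix)
            results.append(
                StatResult(measure, "omnibus", "friedman", omni.statistic, omni.pvalue,
                           n, omni.pvalue < cfg.alpha, None, cfg.alpha)
            )
            omnibus_sig = omni.pvalue < cfg.alpha
            if omnibus_sig:
                for a, b in PAIRS:
                    ia, ib = TIMEPOINTS.index(a), TIMEPOINTS.index(b)
                    res = wilcoxon_signed_rank(
                        matrix[:, ia], matrix[:, ib], exact_cutoff=cfg.exact_cutoff_n
                    )
                    es = effect_size(matrix[:, ia], matrix[:, ib], "nonparametric")
                    p = res.pvalue
                    sig = (not res.degenerate) and p < cfg.bonferroni_alpha
                    results.append(
                        StatResult(measure, f"{a}-{b}", "wilcoxon", res.statistic, p,
                                   n, sig, es, cfg.bonferroni_alpha)
                    )
        else:
            omni = rm_anova(matrix, gg_correction=cfg.gg_correction)
            results.append(
                StatResult(measure, "omnibus", "rm_anova", omni.f, omni.pvalue,
                           n, omni.pvalue < cfg.alpha, None, cfg.alpha)
            )
            if omni.pvalue < cfg.alpha:
                for a, b in PAIRS:
                    ia, ib = TIMEPOINTS.index(a), TIMEPOINTS.index(b)
                    res = paired_t(matrix[:, ia], matrix[:, ib])
                    es = effect_size(matrix[:, ia], matrix[:, ib], "parametric")
                    sig = (not res.degenerate) and res.pvalue < cfg.bonferroni_alpha
                    results.append(
                        StatResult(measure, f"{a}-{b}", "paired_t", res.t, res.pvalue,
                                   n, sig, es, cfg.bonferroni_alpha)
                    )
    return pd.DataFrame([vars(r) for r in results])
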