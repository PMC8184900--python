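"""Nonparametric analysis pipeline for localization sessions.

Implements the full statistical battery used to evaluate the
sonification: per-subject/group success tables, the 2-SD outlier rule,
Wilcoxon signed-rank and rank-sum tests with mid-rank ties,
tie-corrected variance and a 0.5 continuity correction (the convention
that reproduces the published group statistics), Kruskal–Wallis and
Friedman tests, Bonferroni adjustment, nonparametric equivalence
testing (two one-sided signed-rank tests against ±1 SE bounds, with a
distribution-free Hodges–Lehmann CI), learning curves, binned error
rates, per-cell heat maps, and the word spatial-bias screen.

The rank tests are implemented here rather than delegated because the
reproduced numbers depend on the exact convention set (zero-difference
drop, mid-ranks, tie-corrected variance, continuity correction, exact
enumeration at small n); scipy serves as an independent cross-check in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .core import GridSpec
from .design import SessionLog

__all__ = [
    "Alternative",
    "TestResult",
    "SuccessTable",
    "EquivalenceResult",
    "DegenerateDataError",
    "group_summary",
    "summarize_success",
    "exclude_outliers",
    "wilcoxon_signed_rank",
    "mann_whitney_z",
    "kruskal_wallis",
    "friedman_test",
    "bonferroni_adjust",
    "equivalence_tost",
    "median_diff_ci",
    "signed_rank_null_cdf",
    "cumulative_success",
    "binned_error_rate",
    "cell_heatmap",
    "spatial_bias_screen",
]

Alternative = Literal["two-sided", "greater", "less"]


class DegenerateDataError(ValueError):
    """The data admit no test (e.g. all differences are zero)."""


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    z: float | None
    df: int | None
    p: float
    alternative: Alternative
    method: str = "normal-approx"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p={self.p} outside [0, 1]")


# ---------------------------------------------------------------------------
# success tables


def group_summary(rates: Sequence[float]) -> dict[str, float]:
    """Group mean / sample SD (n-1) / SE / median of per-subject rates."""
    v = np.asarray(rates, dtype=float)
    if v.size < 1:
        raise ValueError("at least one rate is required")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": sd,
        "se": sd / float(np.sqrt(v.size)),
        "median": float(np.median(v)),
    }


@dataclass
class SuccessTable:
    """Per-subject and group success rates, all in percent."""

    per_subject: pd.DataFrame  # index subject_id; overall/row/col columns
    per_cell: dict[str, np.ndarray]  # subject_id -> n_rows x n_cols percent matrix
    group: dict[str, float]
    grid: GridSpec

    @property
    def overall(self) -> np.ndarray:
        return self.per_subject["overall"].to_numpy()


def summarize_success(logs: list[SessionLog], grid: GridSpec = GridSpec()) -> SuccessTable:
    """Success table from response logs.

    Per subject: overall %, row-correct %, col-correct %, and the
    per-cell percent matrix; group stats (mean, sample SD, SE, median)
    are computed over the per-subject overall rates.
    """
    if not logs or any(len(log) == 0 for log in logs):
        raise ValueError("each log must be non-empty")
    rows = []
    per_cell: dict[str, np.ndarray] = {}
    for log in logs:
        correct = np.array([r.correct for r in log.records], dtype=float)
        row_ok = np.array([r.response.row == r.spec.cell.row for r in log.records], dtype=float)
        col_ok = np.array([r.response.col == r.spec.cell.col for r in log.records], dtype=float)
        hits = np.zeros((grid.n_rows, grid.n_cols))
        seen = np.zeros((grid.n_rows, grid.n_cols))
        for r in log.records:
            seen[r.spec.cell.row, r.spec.cell.col] += 1
            hits[r.spec.cell.row, r.spec.cell.col] += r.correct
        with np.errstate(invalid="ignore"):
            per_cell[log.subject_id] = 100.0 * hits / seen
        rows.append({
            "subject_id": log.subject_id,
            "overall": 100.0 * correct.mean(),
            "row": 100.0 * row_ok.mean(),
            "col": 100.0 * col_ok.mean(),
        })
    per_subject = pd.DataFrame(rows).set_index("subject_id")
    return SuccessTable(
        per_subject=per_subject,
        per_cell=per_cell,
        group=group_summary(per_subject["overall"].to_numpy()),
        grid=grid,
    )


def exclude_outliers(rates: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass low-performance outlier rule.

    A subject is excluded when their rate lies more than 2 sample SDs
    *below* the group mean, with mean and SD computed over all subjects
    (candidates included).  Returns ``(kept, excluded)`` index arrays.
    """
    v = np.asarray(rates, dtype=float)
    if v.size < 3:
        raise ValueError("outlier screening needs at least 3 subjects")
    cutoff = v.mean() - 2.0 * v.std(ddof=1)
    excluded = np.flatnonzero(v < cutoff)
    kept = np.flatnonzero(v >= cutoff)
    return kept, excluded


# ---------------------------------------------------------------------------
# rank tests


def _tie_term(ranked_values: np.ndarray) -> float:
    """Sum of t^3 - t over groups of tied values."""
    _, counts = np.unique(ranked_values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _continuity(diff: float, alternative: Alternative) -> float:
    """0.5 continuity correction for a discrete rank statistic.

    Directional for one-sided alternatives (P(W >= w) ~ P(N > w - 0.5));
    toward the null mean for the two-sided case.
    """
    if alternative == "greater":
        return 0.5
    if alternative == "less":
        return -0.5
    return 0.5 * float(np.sign(diff))


def signed_rank_null_cdf(n: int) -> np.ndarray:
    """Exact null CDF of W+ (sum of positive ranks) for untied ranks 1..n."""
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for k in range(1, n + 1):
        counts[k:] += counts[:-k].copy()
    return counts.cumsum() / counts.sum()


def _exact_signed_rank_p(ranks: np.ndarray, w_pos: float, alternative: Alternative) -> float:
    """Exact p by enumeration over all 2^n sign assignments (handles ties)."""
    # distribution of W+ over sign patterns; ranks may be half-integers,
    # so work on doubled ranks to stay integral
    doubled = np.round(2 * ranks).astype(int)
    dist = np.zeros(doubled.sum() + 1)
    dist[0] = 1.0
    for r in doubled:
        new = dist.copy()
        new[r:] += dist[: dist.size - r]
        dist = new
    dist /= dist.sum()
    w2 = int(round(2 * w_pos))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    if alternative == "greater":
        return float(p_ge)
    if alternative == "less":
        return float(p_le)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    values: Sequence[float],
    mu: float = 0.0,
    alternative: Alternative = "two-sided",
    method: Literal["auto", "approx", "exact"] = "approx",
) -> TestResult:
    """One-sample / paired Wilcoxon signed-rank test against ``mu``.

    Zero differences are dropped; ties in ``|d|`` receive mid-ranks;
    the normal approximation uses the tie-corrected variance
    ``n(n+1)(2n+1)/24 - sum(t^3 - t)/48`` and a 0.5 continuity
    correction toward the null mean.  ``method="exact"`` (or "auto"
    with n <= 12) enumerates all sign assignments instead.
    """
    d = np.asarray(values, dtype=float) - mu
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all differences are zero")
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if method == "auto":
        method = "exact" if n <= 12 else "approx"
    mean_w = n * (n + 1) / 4.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(np.abs(d)) / 48.0
    if var_w <= 0:
        raise DegenerateDataError("zero variance: all |differences| identical and cancelling")
    diff = w_pos - mean_w
    z = (diff - _continuity(diff, alternative)) / np.sqrt(var_w) if diff != 0 else 0.0
    if method == "exact":
        p = _exact_signed_rank_p(ranks, w_pos, alternative)
    elif alternative == "greater":
        p = float(norm.sf(z))
    elif alternative == "less":
        p = float(norm.cdf(z))
    else:
        p = float(2.0 * norm.sf(abs(z)))
    return TestResult("wilcoxon-signed-rank", w_pos, float(z), None, min(p, 1.0),
                      alternative, method=f"{method}")


def _exact_rank_sum_p(pooled_ranks: np.ndarray, n1: int, w1: float,
                      alternative: Alternative) -> float:
    """Exact rank-sum p by enumeration over all choose(N, n1) assignments."""
    idx = range(pooled_ranks.size)
    sums = np.array([pooled_ranks[list(c)].sum() for c in combinations(idx, n1)])
    p_le = float(np.mean(sums <= w1 + 1e-12))
    p_ge = float(np.mean(sums >= w1 - 1e-12))
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney_z(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Alternative = "two-sided",
    method: Literal["auto", "approx", "exact"] = "approx",
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test for independent samples.

    Mid-ranks for ties; normal approximation with tie-corrected
    variance and 0.5 continuity correction.  ``alternative="greater"``
    means x tends larger than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w1 = float(ranks[:n1].sum())
    big_n = n1 + n2
    mean_w = n1 * (big_n + 1) / 2.0
    tie = _tie_term(pooled)
    var_w = n1 * n2 * (big_n + 1) / 12.0 - n1 * n2 * tie / (12.0 * big_n * (big_n - 1))
    if var_w <= 0:
        raise DegenerateDataError("zero variance: all pooled observations identical")
    diff = w1 - mean_w
    z = (diff - _continuity(diff, alternative)) / np.sqrt(var_w) if diff != 0 else 0.0
    if method == "auto":
        method = "exact" if big_n <= 10 else "approx"
    if method == "exact":
        p = _exact_rank_sum_p(ranks, n1, w1, alternative)
    elif alternative == "greater":
        p = float(norm.sf(z))
    elif alternative == "less":
        p = float(norm.cdf(z))
    else:
        p = float(2.0 * norm.sf(abs(z)))
    return TestResult("wilcoxon-rank-sum", w1, float(z), None, min(p, 1.0),
                      alternative, method=method)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test across >= 2 independent groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError("all observations identical")
    big_n = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (big_n * (big_n + 1)) * h - 3.0 * (big_n + 1)
    correction = 1.0 - _tie_term(pooled) / (big_n**3 - big_n)
    h /= correction
    df = len(groups) - 1
    return TestResult("kruskal-wallis", float(h), None, df,
                      float(chi2.sf(h, df)), "two-sided", method="chi2")


def friedman_test(matrix: np.ndarray) -> TestResult:
    """Friedman test on a subjects x conditions matrix.

    Within-subject mid-ranks; chi-square statistic with the standard
    tie correction; df = k - 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    n, k = m.shape
    ranks = np.apply_along_axis(rankdata, 1, m)
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    # tie correction: scale by the within-row tie factor
    tie_sum = sum(_tie_term(row) for row in m)
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if correction <= 0:
        raise DegenerateDataError("all rows constant: no within-subject ranking")
    stat /= correction
    df = k - 1
    return TestResult("friedman", float(stat), None, df,
                      float(chi2.sf(stat, df)), "two-sided", method="chi2")


def bonferroni_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni-adjusted p values: ``min(p * m, 1)``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


# ---------------------------------------------------------------------------
# equivalence


@dataclass(frozen=True)
class EquivalenceResult:
    """Two one-sided signed-rank tests of the paired-difference
    distribution against symmetric bounds, plus distribution-free CIs.

    The verdict follows the CI-within-bounds criterion: the conditions
    are equivalent when the 95% CI of the median difference lies inside
    ``[bound_lower, bound_upper]``.
    """

    delta: np.ndarray  # per-pair differences, proportions
    delta_median: float
    bound_upper: float
    bound_lower: float
    z_upper: float
    z_lower: float
    p_upper: float
    p_lower: float
    ci90: tuple[float, float]
    ci95: tuple[float, float]
    equivalent: bool


def median_diff_ci(
    delta: Sequence[float],
    confidence: float = 0.95,
    method: Literal["walsh", "bootstrap"] = "walsh",
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Distribution-free CI for the median (pseudo-median) difference.

    ``method="walsh"``: order statistics of the Walsh averages
    ``(d_i + d_j)/2`` at exact signed-rank critical values (the
    Hodges-Lehmann / Tukey construction).  ``method="bootstrap"``:
    seeded percentile bootstrap of the sample median.
    """
    d = np.asarray(delta, dtype=float)
    n = d.size
    if n < 3:
        raise ValueError("CI needs at least 3 differences")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    alpha = 1.0 - confidence
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        meds = np.median(rng.choice(d, size=(n_boot, n), replace=True), axis=1)
        return (float(np.quantile(meds, alpha / 2)), float(np.quantile(meds, 1 - alpha / 2)))
    walsh = np.sort([(d[i] + d[j]) / 2.0 for i in range(n) for j in range(i, n)])
    cdf = signed_rank_null_cdf(n)
    # largest k with P(W <= k) <= alpha/2; CI = [W_(k+1), W_(M-k)] in
    # 1-based order statistics of the Walsh averages
    k = int(np.searchsorted(cdf, alpha / 2.0, side="right")) - 1
    m = walsh.size
    if k < 0:
        return (float(walsh[0]), float(walsh[-1]))
    return (float(walsh[k]), float(walsh[m - k - 1]))


def equivalence_tost(
    fwd: Sequence[float],
    bwd: Sequence[float],
    bounds: float | None = None,
) -> EquivalenceResult:
    """Nonparametric equivalence of two success-rate distributions.

    Inputs are per-subject percentages, paired by subject index.  The
    per-pair differences ``delta = (fwd - bwd)/100`` are tested against
    symmetric bounds (default: one SE of the forward distribution,
    expressed as a proportion) with two one-sided signed-rank tests,
    and the verdict is the CI-within-bounds criterion on the 95% CI of
    the median difference.
    """
    f = np.asarray(fwd, dtype=float)
    b = np.asarray(bwd, dtype=float)
    if f.size != b.size:
        raise ValueError(f"cannot pair {f.size} forward with {b.size} backward subjects")
    if f.size < 3:
        raise ValueError("equivalence testing needs at least 3 pairs")
    delta = (f - b) / 100.0
    if np.all(delta == 0):
        raise DegenerateDataError("all paired differences are zero")
    if bounds is None:
        bounds = group_summary(f)["se"] / 100.0
    upper = wilcoxon_signed_rank(delta, mu=bounds, alternative="less")
    lower = wilcoxon_signed_rank(delta, mu=-bounds, alternative="greater")
    ci90 = median_diff_ci(delta, 0.90)
    ci95 = median_diff_ci(delta, 0.95)
    equivalent = (-bounds <= ci95[0]) and (ci95[1] <= bounds)
    return EquivalenceResult(
        delta=delta,
        delta_median=float(np.median(delta)),
        bound_upper=float(bounds),
        bound_lower=float(-bounds),
        z_upper=upper.z,
        z_lower=lower.z,
        p_upper=upper.p,
        p_lower=lower.p,
        ci90=ci90,
        ci95=ci95,
        equivalent=bool(equivalent),
    )


# ---------------------------------------------------------------------------
# learning curves, error bins, heat maps, bias screen


def cumulative_success(log: SessionLog) -> np.ndarray:
    """Running proportion of correct responses after each trial."""
    if len(log) == 0:
        raise ValueError("empty log")
    correct = np.array([r.correct for r in log.records], dtype=float)
    return np.cumsum(correct) / np.arange(1, correct.size + 1)


def binned_error_rate(logs: list[SessionLog], bin_size: int = 10) -> np.ndarray:
    """Mean error percentage per bin of ``bin_size`` trials, across subjects.

    A 90-trial session yields nine bins.  Log lengths must be divisible
    by ``bin_size``; a final partial bin is an error rather than a
    silent truncation.
    """
    if not logs:
        raise ValueError("at least one log is required")
    per_subject = []
    for log in logs:
        errors = np.array([not r.correct for r in log.records], dtype=float)
        if errors.size % bin_size != 0:
            raise ValueError(
                f"log length {errors.size} leaves a partial bin at bin_size={bin_size}"
            )
        per_subject.append(100.0 * errors.reshape(-1, bin_size).mean(axis=1))
    lengths = {len(p) for p in per_subject}
    if len(lengths) != 1:
        raise ValueError("logs have differing numbers of bins")
    return np.mean(per_subject, axis=0)


def cell_heatmap(logs: list[SessionLog], grid: GridSpec = GridSpec()) -> np.ndarray:
    """Mean per-cell success proportion across subjects (n_rows x n_cols)."""
    if not logs:
        raise ValueError("at least one log is required")
    table = summarize_success(logs, grid)
    stack = np.stack(list(table.per_cell.values()))
    if np.isnan(stack).any():
        missing = np.argwhere(np.isnan(stack))
        raise ValueError(
            f"cell(s) never presented in some log (e.g. subject {missing[0][0]}, "
            f"cell ({missing[0][1]},{missing[0][2]}))"
        )
    return stack.mean(axis=0) / 100.0


def build_report(
    forward_logs: list[SessionLog],
    backward_logs: list[SessionLog],
    grid: GridSpec = GridSpec(),
    bin_size: int = 10,
) -> dict:
    """Full analysis report for a forward/backward study.

    Success tables per condition, the one-sample test of each condition
    against the chance level, the between-condition rank-sum test, the
    equivalence analysis, cumulative-success curves, binned error
    rates, and per-cell heat maps, as a JSON-serializable dict.
    """
    from .core import chance_level

    chance_pct = 100.0 * chance_level(grid)
    report: dict = {"chance_level_pct": chance_pct, "conditions": {}}
    tables = {}
    for name, logs in (("forward", forward_logs), ("backward", backward_logs)):
        table = summarize_success(logs, grid)
        tables[name] = table
        vs_chance = wilcoxon_signed_rank(table.overall, mu=chance_pct, alternative="greater")
        report["conditions"][name] = {
            "per_subject": table.per_subject.reset_index().to_dict(orient="records"),
            "group": table.group,
            "vs_chance": {"z": vs_chance.z, "p": vs_chance.p, "W": vs_chance.statistic},
            "heatmap": cell_heatmap(logs, grid).tolist(),
            "binned_error_pct": binned_error_rate(logs, bin_size).tolist(),
            "mean_cumulative_success": np.mean(
                [cumulative_success(log) for log in logs], axis=0
            ).tolist(),
        }
    rank_sum = mann_whitney_z(tables["forward"].overall, tables["backward"].overall)
    eq = equivalence_tost(tables["forward"].overall, tables["backward"].overall)
    report["forward_vs_backward"] = {"z": rank_sum.z, "p": rank_sum.p}
    report["equivalence"] = {
        "delta_median": eq.delta_median,
        "bound_upper": eq.bound_upper,
        "bound_lower": eq.bound_lower,
        "z_upper": eq.z_upper,
        "z_lower": eq.z_lower,
        "p_upper": eq.p_upper,
        "p_lower": eq.p_lower,
        "ci90": list(eq.ci90),
        "ci95": list(eq.ci95),
        "equivalent": eq.equivalent,
    }
    return report


def spatial_bias_screen(
    ratings: dict[str, Sequence[float]],
    alpha: float = 0.05,
) -> dict[str, dict[str, object]]:
    """Word-level spatial-bias screen from slider ratings on [-1, 1].

    Each word's ratings (midpoint 0 = unbiased) are tested with a
    two-sided one-sample signed-rank test against 0 (exact enumeration
    at n <= 12).  Significant words are flagged "high" (median > 0) or
    "low"; words whose ratings are all zero are degenerate and flagged
    "none".
    """
    out: dict[str, dict[str, object]] = {}
    for word, r in ratings.items():
        r = np.asarray(r, dtype=float)
        if r.size < 3:
            raise ValueError(f"word {word!r} has fewer than 3 ratings")
        try:
            res = wilcoxon_signed_rank(r, mu=0.0, alternative="two-sided", method="auto")
        except DegenerateDataError:
            out[word] = {"bias_flag": "none", "p": 1.0, "median": 0.0}
            continue
        med = float(np.median(r))
        flag = "none"
        if res.p < alpha and med != 0:
            flag = "high" if med > 0 else "low"
        out[word] = {"bias_flag": flag, "p": res.p, "median": med}
    return out
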