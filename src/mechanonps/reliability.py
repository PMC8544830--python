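"""Reliability and between-device comparison statistics.

Intra-/inter-user reliability over repeated processing of the same raw
recording: candidate cell events are aligned across observations by window
start time; agreement on the save/skip decision is quantified by raw percent
agreement and Fleiss's kappa (with its large-sample variance, z test and
Landis & Koch interpretation bands); agreement on the continuous phenotypes
(wCDI, tau) by a scaled-tolerance percent agreement and the intraclass
correlation ICC(A,1) — two-way model, single rater, absolute agreement.

Between-device / between-site comparisons: Lilliefors normality (Monte Carlo
null), Kruskal-Wallis omnibus, pairwise Wilcoxon rank-sum on mean ranks with
a Tukey-Kramer (studentized range) critical value, pairwise two-sample
Kolmogorov-Smirnov with Bonferroni correction, and Pearson chi-squared with
Cramer's V for categorical recovery data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ObservationMatrix",
    "FleissKappaResult",
    "ICCResult",
    "align_observations",
    "percent_agreement_savedecision",
    "save_decisions_to_counts",
    "fleiss_kappa",
    "landis_koch_label",
    "icc_a1",
    "value_percent_agreement",
    "cramers_v",
    "lilliefors_mc",
    "pairwise_ranksum_tukey",
    "pairwise_ks_bonferroni",
    "compare_groups",
    "compare_categorical",
    "reliability_report",
    "type_i_error_simulation",
]

#: lower band edges of the conventional agreement interpretation
#: (below 0: poor)
LANDIS_KOCH_BANDS = (
    (0.0, "slight"), (0.21, "fair"), (0.41, "moderate"),
    (0.61, "substantial"), (0.81, "almost perfect"),
)


# ---------------------------------------------------------------------------
# observation alignment

@dataclass
class ObservationMatrix:
    """Cells x observations: save/skip decisions and saved phenotype values.

    Only cells saved in at least one observation of the comparison group are
    represented (all-skip rows cannot arise by construction).
    """

    saved: pd.DataFrame                      # bool, cells x observations
    values: dict[str, pd.DataFrame]          # variable -> cells x observations

    @property
    def n_cells(self) -> int:
        return len(self.saved)

    @property
    def n_observations(self) -> int:
        return self.saved.shape[1]


def align_observations(tables: list[pd.DataFrame],
                       observation_names: list[str] | None = None,
                       time_tolerance_ms: float = 5.0,
                       variables: tuple[str, ...] = ("wcdi", "tau_ms"),
                       trace_ids: list[str] | None = None) -> ObservationMatrix:
    """Match saved cells across observations of the same trace by start time.

    Window start times across all observations are pooled and clustered
    (single-linkage on the sorted times with link distance
    ``time_tolerance_ms``); each cluster is one candidate cell.  An
    observation "saved" a cell iff it has an event in that cluster.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 observations")
    if trace_ids is not None and len(set(trace_ids)) > 1:
        raise ValueError(
            f"observations come from different traces: {sorted(set(trace_ids))}")
    if observation_names is None:
        observation_names = [f"obs{i}" for i in range(len(tables))]
    tol_s = time_tolerance_ms / 1000.0

    pooled = np.sort(np.unique(np.concatenate(
        [t["window_start_s"].to_numpy(dtype=float) for t in tables])))
    if len(pooled) == 0:
        raise ValueError("no saved cells in any observation")
    boundaries = np.flatnonzero(np.diff(pooled) > tol_s)
    cluster_edges = np.concatenate(([0], boundaries + 1, [len(pooled)]))
    centers = np.array([pooled[a:b].mean()
                        for a, b in zip(cluster_edges[:-1], cluster_edges[1:])])

    n_cells = len(centers)
    saved = pd.DataFrame(False, index=range(n_cells), columns=observation_names)
    values = {v: pd.DataFrame(np.nan, index=range(n_cells),
                              columns=observation_names) for v in variables}
    starts = np.array([pooled[a] for a in cluster_edges[:-1]])
    ends = np.array([pooled[b - 1] for b in cluster_edges[1:]])
    for name, tab in zip(observation_names, tables):
        t = tab["window_start_s"].to_numpy(dtype=float)
        idx = np.searchsorted(starts, t + tol_s / 2, side="right") - 1
        idx = np.clip(idx, 0, n_cells - 1)
        for row, cell in zip(tab.itertuples(index=False), idx):
            saved.loc[cell, name] = True
            for v in variables:
                if v in tab.columns:
                    values[v].loc[cell, name] = getattr(row, v)
    return ObservationMatrix(saved=saved, values=values)


def percent_agreement_savedecision(matrix: ObservationMatrix | pd.DataFrame) -> float:
    """% of candidate cells on which all observations made the same decision."""
    saved = matrix.saved if isinstance(matrix, ObservationMatrix) else matrix
    if saved.shape[1] < 2:
        raise ValueError("need at least 2 observations")
    arr = saved.to_numpy(dtype=bool)
    unanimous = np.all(arr == arr[:, :1], axis=1)
    return 100.0 * float(unanimous.mean())


def save_decisions_to_counts(saved: pd.DataFrame) -> np.ndarray:
    """Items x 2 category-count table (saved, skipped) for Fleiss's kappa."""
    arr = saved.to_numpy(dtype=bool)
    n_saved = arr.sum(axis=1)
    return np.column_stack([n_saved, arr.shape[1] - n_saved])


# ---------------------------------------------------------------------------
# agreement statistics

def landis_koch_label(kappa: float) -> str:
    if kappa < 0:
        return "poor"
    label = LANDIS_KOCH_BANDS[0][1]
    for lo, name in LANDIS_KOCH_BANDS:
        if kappa >= lo:
            label = name
    return label


@dataclass(frozen=True)
class FleissKappaResult:
    kappa: float
    se: float
    z: float
    p: float
    ci95: tuple[float, float]
    label: str

    @property
    def percent_above_chance(self) -> float:
        """100 * kappa: chance-corrected agreement expressed as a percentage."""
        return 100.0 * self.kappa


def fleiss_kappa(counts: np.ndarray) -> FleissKappaResult:
    """Fleiss's kappa for multi-rater categorical agreement.

    ``counts`` is items x categories with a constant number of raters per
    item.  kappa = (P_bar - Pe_bar) / (1 - Pe_bar); the standard error is the
    Fleiss (1971) large-sample expression under the null of chance agreement,
    giving the z test and a normal-approximation 95 % CI.
    """
    m = np.asarray(counts, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("counts must be items x categories with >= 2 categories")
    raters = m.sum(axis=1)
    n = raters[0]
    if n < 2 or not np.all(raters == n):
        raise ValueError("every item needs the same number (>= 2) of raters")
    big_n = m.shape[0]
    p_j = m.sum(axis=0) / (big_n * n)
    p_bar = float(np.mean((np.sum(m * m, axis=1) - n) / (n * (n - 1))))
    pe = float(np.sum(p_j ** 2))
    if pe >= 1.0:
        raise ValueError("all items in one category: kappa undefined")
    kappa = (p_bar - pe) / (1.0 - pe)
    var = (2.0 / (big_n * n * (n - 1))) * (
        pe - (2 * n - 3) * pe ** 2 + 2 * (n - 2) * float(np.sum(p_j ** 3))
    ) / (1.0 - pe) ** 2
    se = math.sqrt(max(var, 0.0))
    z = kappa / se if se > 0 else math.inf * np.sign(kappa)
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    ci = (kappa - 1.959963984540054 * se, kappa + 1.959963984540054 * se)
    return FleissKappaResult(kappa=float(kappa), se=se, z=float(z), p=float(p),
                             ci95=ci, label=landis_koch_label(kappa))


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    p: float
    f: float
    df1: float
    df2: float
    n: int
    k: int


def _twoway_mean_squares(y: np.ndarray) -> tuple[float, float, float]:
    n, k = y.shape
    grand = y.mean()
    msr = k * np.sum((y.mean(axis=1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((y.mean(axis=0) - grand) ** 2) / (k - 1)
    sse = np.sum((y - y.mean(axis=1, keepdims=True)
                  - y.mean(axis=0, keepdims=True) + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def _twoway_mean_squares_na(y: np.ndarray) -> tuple[float, float, float, int, int]:
    """Adjusted (type-III-style) mean squares on available entries only.

    Fits the additive two-way model by least squares on the observed cells
    and forms row/column mean squares from the increase in residual sum of
    squares when the corresponding effect is dropped.  Exact for complete
    data; an approximation under light missingness.
    """
    n, k = y.shape
    obs = ~np.isnan(y)
    rows, cols = np.nonzero(obs)
    yy = y[obs]
    n_obs = len(yy)

    def design(use_rows: bool, use_cols: bool) -> np.ndarray:
        parts = [np.ones((n_obs, 1))]
        if use_rows:
            d = np.zeros((n_obs, n - 1))
            for i, r in enumerate(rows):
                if r > 0:
                    d[i, r - 1] = 1.0
            parts.append(d)
        if use_cols:
            d = np.zeros((n_obs, k - 1))
            for i, c in enumerate(cols):
                if c > 0:
                    d[i, c - 1] = 1.0
            parts.append(d)
        return np.hstack(parts)

    def sse(x: np.ndarray) -> float:
        resid = yy - x @ np.linalg.lstsq(x, yy, rcond=None)[0]
        return float(resid @ resid)

    sse_full = sse(design(True, True))
    ss_rows = sse(design(False, True)) - sse_full
    ss_cols = sse(design(True, False)) - sse_full
    df_e = n_obs - n - k + 1
    if df_e < 1:
        raise ValueError("not enough observed entries for a two-way fit")
    return (ss_rows / (n - 1), ss_cols / (k - 1), sse_full / df_e, n, k)


def icc_a1(values: pd.DataFrame | np.ndarray, alpha: float = 0.05,
           missing: str = "complete") -> ICCResult:
    """ICC(A,1): two-way model, single rater, absolute agreement.

    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)`` from the two-way
    ANOVA mean squares, with the McGraw & Wong F-based confidence interval
    and the p-value for the null ICC = 0 from ``F = MSR / MSE``.

    ``missing='complete'`` drops rows with any missing value;
    ``missing='pairwise'`` keeps all rows and estimates the mean squares
    from the observed entries of an unbalanced two-way fit.
    """
    y = values.to_numpy(dtype=float) if isinstance(values, pd.DataFrame) \
        else np.asarray(values, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("need a cells x observations matrix with >= 2 columns")
    if missing == "complete":
        y = y[~np.isnan(y).any(axis=1)]
        n, k = y.shape
        if n < 3:
            raise ValueError("need >= 3 complete rows")
        msr, msc, mse = _twoway_mean_squares(y)
    elif missing == "pairwise":
        msr, msc, mse, n, k = _twoway_mean_squares_na(y)
        if n < 3:
            raise ValueError("need >= 3 rows")
    else:
        raise ValueError("missing must be 'complete' or 'pairwise'")
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0 or (msr == 0 and mse == 0):
        raise ValueError("degenerate variance: ICC undefined")
    icc = (msr - mse) / denom

    df_e = (n - 1) * (k - 1)
    f_obs = msr / mse if mse > 0 else math.inf
    p = float(stats.f.sf(f_obs, n - 1, df_e)) if np.isfinite(f_obs) else 0.0

    # McGraw & Wong (1996) F-based CI for ICC(A,1), Satterthwaite df
    fc = msc / mse if mse > 0 else math.inf
    if np.isfinite(fc) and icc < 1:
        term = n * (1 + (k - 1) * icc) - k * icc
        vn = df_e * (k * icc * fc + term) ** 2
        vd = (n - 1) * k ** 2 * icc ** 2 * fc ** 2 + term ** 2
        v = vn / vd if vd > 0 else df_e
        f2u = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2l = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lb = (n * (msr - f2u * mse)
              / (f2u * (k * msc + (k * n - k - n) * mse) + n * msr))
        ub = (n * (f2l * msr - mse)
              / (k * msc + (k * n - k - n) * mse + n * f2l * msr))
    else:
        lb = ub = icc
    return ICCResult(icc=float(icc), ci95=(float(lb), float(ub)), p=p,
                     f=float(f_obs), df1=float(n - 1), df2=float(df_e),
                     n=n, k=k)


def value_percent_agreement(values: pd.DataFrame | np.ndarray,
                            base_tolerance: float = 1e-10) -> float:
    """% of cells on which all observations found an equivalent value.

    Two values are equivalent when their difference is within
    ``base_tolerance`` times the minimum absolute value observed for the
    phenotype.  A cell agrees only if it was saved (non-missing) in every
    observation and all its values are pairwise equivalent.
    """
    y = values.to_numpy(dtype=float) if isinstance(values, pd.DataFrame) \
        else np.asarray(values, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("need a cells x observations matrix with >= 2 columns")
    finite = np.abs(y[np.isfinite(y)])
    tol = base_tolerance * (float(finite.min()) if len(finite) else 0.0)
    complete = ~np.isnan(y).any(axis=1)
    spread = np.nanmax(y, axis=1) - np.nanmin(y, axis=1)
    agree = complete & (spread <= tol)
    return 100.0 * float(agree.mean())


def cramers_v(table: np.ndarray | pd.DataFrame) -> float:
    """Effect size for an r x c contingency table: sqrt(chi2 / (n (m - 1)))."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    if n <= 0:
        raise ValueError("empty contingency table")
    chi2 = stats.chi2_contingency(t, correction=False)[0]
    m = min(t.shape) - 1
    if m < 1:
        raise ValueError("table needs at least 2 rows and 2 columns")
    return float(math.sqrt(chi2 / (n * m)))


# ---------------------------------------------------------------------------
# distribution comparisons

def lilliefors_mc(x: np.ndarray, n_draws: int = 10_000,
                  seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Lilliefors test for normality with a Monte-Carlo null distribution.

    KS distance between the standardized sample and the standard normal CDF,
    with mean and sd estimated from the data; the p-value is calibrated by
    ``n_draws`` seeded draws of normal samples of the same size.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    def ks_stat(sample: np.ndarray) -> float:
        z = np.sort((sample - sample.mean()) / sample.std(ddof=1))
        cdf = stats.norm.cdf(z)
        i = np.arange(1, len(z) + 1)
        return float(max(np.max(i / len(z) - cdf),
                         np.max(cdf - (i - 1) / len(z))))

    d_obs = ks_stat(x)
    null = rng.standard_normal((n_draws, n))
    z = np.sort((null - null.mean(axis=1, keepdims=True))
                / null.std(axis=1, ddof=1, keepdims=True), axis=1)
    cdf = stats.norm.cdf(z)
    i = np.arange(1, n + 1) / n
    d_null = np.maximum((i - cdf).max(axis=1), (cdf - (i - 1 / n)).max(axis=1))
    p = (1.0 + float(np.sum(d_null >= d_obs))) / (n_draws + 1.0)
    return d_obs, p


def pairwise_ranksum_tukey(groups: dict[str, np.ndarray],
                           alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise mean-rank comparisons with a Tukey-Kramer critical value.

    Dunn-type comparisons on the pooled ranks (tie-corrected), with the
    studentized-range distribution (k groups, infinite df) supplying the
    familywise critical value — the post-hoc procedure conventionally paired
    with a Kruskal-Wallis omnibus test.
    """
    names = list(groups)
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 groups")
    sizes = {g: len(groups[g]) for g in names}
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    big_n = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, start = {}, 0
    for g in names:
        mean_ranks[g] = float(ranks[start:start + sizes[g]].mean())
        start += sizes[g]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var_factor = (big_n * (big_n + 1) / 12.0) * (1.0 - tie_term / (big_n ** 3 - big_n))
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        se = math.sqrt(var_factor * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        diff = mean_ranks[g1] - mean_ranks[g2]
        q = abs(diff) / se * math.sqrt(2.0)
        p = float(stats.studentized_range.sf(q, k, np.inf))
        rows.append({"group1": g1, "group2": g2,
                     "mean_rank_diff": diff, "se": se, "p": p,
                     "significant": p < alpha})
    return pd.DataFrame(rows)


def pairwise_ks_bonferroni(groups: dict[str, np.ndarray],
                           alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise two-sample KS tests at a Bonferroni-adjusted level."""
    names = list(groups)
    n_pairs = len(names) * (len(names) - 1) // 2
    if n_pairs < 1:
        raise ValueError("need at least 2 groups")
    alpha_adj = alpha / n_pairs
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        res = stats.ks_2samp(groups[g1], groups[g2], method="asymp")
        rows.append({"group1": g1, "group2": g2, "stat": float(res.statistic),
                     "p": float(res.pvalue), "alpha_adjusted": alpha_adj,
                     "significant": res.pvalue < alpha_adj})
    return pd.DataFrame(rows)


def compare_groups(records: pd.DataFrame, value_col: str,
                   group_col: str = "device_id", alpha: float = 0.05,
                   lilliefors_draws: int = 10_000, seed: int = 0,
                   exclude_erroneous: bool = True) -> dict:
    """Full between-group comparison suite for one continuous phenotype.

    Per-group Lilliefors normality, Kruskal-Wallis omnibus, pairwise
    rank-sum comparisons with a Tukey-Kramer critical value, and pairwise
    KS tests with Bonferroni correction.  Erroneous-flagged records are
    excluded by default.
    """
    df = records
    if exclude_erroneous and "erroneous" in df.columns:
        df = df[~df["erroneous"].astype(bool)]
    df = df.dropna(subset=[value_col])
    groups = {str(g): sub[value_col].to_numpy(dtype=float)
              for g, sub in df.groupby(group_col)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) < 3 for v in groups.values()):
        raise ValueError("every group needs at least 3 records")
    rng = np.random.default_rng(seed)
    normality = pd.DataFrame([
        {"group": g, "n": len(v),
         **dict(zip(("stat", "p"), lilliefors_mc(v, lilliefors_draws, rng)))}
        for g, v in groups.items()])
    h, p_kw = stats.kruskal(*groups.values())
    return {
        "variable": value_col,
        "groups": {g: len(v) for g, v in groups.items()},
        "normality": normality,
        "kruskal": {"H": float(h), "p": float(p_kw)},
        "pairwise_rank": pairwise_ranksum_tukey(groups, alpha),
        "pairwise_ks": pairwise_ks_bonferroni(groups, alpha),
    }


def compare_categorical(records: pd.DataFrame, cat_col: str,
                        group_col: str = "device_id",
                        exclude_erroneous: bool = True) -> dict:
    """Pearson chi-squared + Cramer's V on group x category frequencies."""
    df = records
    if exclude_erroneous and "erroneous" in df.columns:
        df = df[~df["erroneous"].astype(bool)]
    table = pd.crosstab(df[group_col], df[cat_col])
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return {"variable": cat_col, "table": table, "chi2": float(chi2),
            "p": float(p), "dof": int(dof),
            "cramers_v": cramers_v(table.to_numpy())}


def reliability_report(matrix: ObservationMatrix,
                       icc_missing: str = "complete") -> dict:
    """Save/skip agreement plus per-variable value agreement and ICC."""
    kap = fleiss_kappa(save_decisions_to_counts(matrix.saved))
    report = {
        "n_cells": matrix.n_cells,
        "n_observations": matrix.n_observations,
        "percent_agreement": percent_agreement_savedecision(matrix),
        "kappa": kap.kappa, "kappa_se": kap.se, "kappa_z": kap.z,
        "kappa_p": kap.p, "kappa_ci95": list(kap.ci95),
        "percent_above_chance": kap.percent_above_chance,
        "landis_koch_label": kap.label,
        "variables": {},
    }
    for var, vals in matrix.values.items():
        entry = {"value_percent_agreement": value_percent_agreement(vals)}
        try:
            icc = icc_a1(vals, missing=icc_missing)
            entry.update(icc=icc.icc, icc_ci95=list(icc.ci95), icc_p=icc.p)
        except ValueError as exc:
            entry.update(icc=None, icc_error=str(exc))
        report["variables"][var] = entry
    return report


def type_i_error_simulation(n_groups: int = 7, n_per_group: int = 150,
                            n_reps: int = 500, seed: int = 0,
                            alpha: float = 0.05,
                            sigma_log: float = 0.3) -> dict:
    """Null calibration of the device-comparison suite.

    All groups are drawn from one lognormal wCDI-like distribution; reports
    the Kruskal-Wallis rejection rate (should be ~ alpha) and the familywise
    error rate of the Bonferroni-corrected pairwise KS tests (should be
    <= alpha).
    """
    rng = np.random.default_rng(seed)
    n_pairs = n_groups * (n_groups - 1) // 2
    alpha_adj = alpha / n_pairs
    kw_rej = 0
    ks_fw = 0
    for _ in range(n_reps):
        data = np.exp(sigma_log * rng.standard_normal((n_groups, n_per_group)))
        if stats.kruskal(*data).pvalue < alpha:
            kw_rej += 1
        any_sig = False
        for i, j in itertools.combinations(range(n_groups), 2):
            if stats.ks_2samp(data[i], data[j], method="asymp").pvalue < alpha_adj:
                any_sig = True
                break
        ks_fw += any_sig
    return {
        "n_reps": n_reps,
        "kw_rejection_rate": kw_rej / n_reps,
        "ks_familywise_error_rate": ks_fw / n_reps,
        "alpha": alpha,
        "ks_alpha_adjusted": alpha_adj,
    }
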