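"""Replicate-noise calibration for stoichiometry measurements.

Two measurements of the same biology (replicate vs replicate, or two
control conditions) disagree by sampling noise alone. This module
quantifies that disagreement — Pearson concordance, Bland–Altman mean
difference and 95% limits of agreement (LoA, mean ± 1.96·SD of the
per-site differences) — as a function of the minimum-coverage threshold,
so a threshold can be chosen that balances precision against site
retention, and so the control-vs-control LoA can serve downstream as an
empirical null band for calling differential sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.distributions.empirical_distribution import ECDF

from .pileup import SITE_KEY, SiteTable

__all__ = [
    "FitResult",
    "BlandAltmanResult",
    "DeltaSummary",
    "DEFAULT_SWEEP_GRID",
    "join_paired_sites",
    "fit_concordance",
    "bland_altman",
    "sweep_coverage_thresholds",
    "suggest_threshold",
    "delta_distribution",
]

PAIR_COLUMNS = SITE_KEY + ["f_a", "f_b", "cov_a", "cov_b", "delta", "log2fc"]

#: default coverage-threshold sweep: 0..200 by 10, plus 25 and 50
DEFAULT_SWEEP_GRID = tuple(sorted(set(range(0, 201, 10)) | {25, 50}))


@dataclass(frozen=True)
class FitResult:
    """Pearson correlation and least-squares line of f_B on f_A."""

    r: float | None
    p_value: float | None
    slope: float | None
    intercept: float | None
    n: int

    @property
    def r2(self) -> float | None:
        return None if self.r is None else self.r ** 2


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference and 95% limits of agreement (sample SD, n−1)."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pct_within: float
    n: int

    @property
    def half_width(self) -> float:
        return 1.96 * self.sd_diff


@dataclass
class DeltaSummary:
    """Distributional view of the per-site differences."""

    delta_bins: np.ndarray
    delta_counts: np.ndarray
    delta_ecdf: ECDF
    log2fc_ecdf: ECDF | None
    n_dropped_nonfinite: int


def join_paired_sites(
    table_a: SiteTable,
    table_b: SiteTable,
    min_valid_cov: int = 50,
    drop_zero_both: bool = True,
) -> pd.DataFrame:
    """Inner-join two site tables into per-site stoichiometry pairs.

    Keeps sites with valid coverage >= ``min_valid_cov`` in *both*
    samples; pairs with stoichiometry zero in both samples are excluded
    by default (they carry no information about modification change).
    Returns a DataFrame with ``delta = f_b − f_a`` and ``log2fc =
    log2(f_b / f_a)`` (NaN when either stoichiometry is zero).
    """
    if table_a.tau != table_b.tau:
        raise ValueError(
            f"tau mismatch: {table_a.tau} vs {table_b.tau}; "
            "tables are not comparable"
        )
    a = table_a.df[table_a.df["valid_cov"] >= min_valid_cov]
    b = table_b.df[table_b.df["valid_cov"] >= min_valid_cov]
    pairs = a.merge(b, on=SITE_KEY, suffixes=("_a", "_b"), how="inner")
    pairs = pairs.rename(columns={"valid_cov_a": "cov_a", "valid_cov_b": "cov_b"})
    if drop_zero_both:
        pairs = pairs[(pairs["f_a"] > 0) | (pairs["f_b"] > 0)]
    pairs = pairs.dropna(subset=["f_a", "f_b"])
    pairs = pairs.assign(delta=pairs["f_b"] - pairs["f_a"])
    with np.errstate(divide="ignore", invalid="ignore"):
        l2 = np.log2(pairs["f_b"].to_numpy() / pairs["f_a"].to_numpy())
    l2[~np.isfinite(l2)] = np.nan
    pairs = pairs.assign(log2fc=l2)
    return pairs[PAIR_COLUMNS].reset_index(drop=True)


def fit_concordance(pairs: pd.DataFrame) -> FitResult:
    """Pearson r (two-sided t-test p, n−2 df) and least-squares fit.

    With a constant input vector the correlation is undefined; the result
    carries None with a warning rather than NaN surprises downstream.
    """
    x = pairs["f_a"].to_numpy(dtype=float)
    y = pairs["f_b"].to_numpy(dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input vector: correlation undefined")
        slope = intercept = None
        if np.ptp(x) > 0:  # regression still defined for constant y
            fit = stats.linregress(x, y)
            slope, intercept = float(fit.slope), float(fit.intercept)
        return FitResult(None, None, slope, intercept, n)
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return FitResult(
        float(r), float(p), float(fit.slope), float(fit.intercept), n
    )


def bland_altman(pairs: pd.DataFrame | Sequence[float]) -> BlandAltmanResult:
    """Bland–Altman agreement: mean difference ± 1.96·SD of differences.

    Accepts a pairs table (uses its ``delta`` column) or a raw vector of
    differences. ``pct_within`` is counted directly on the same
    differences, bounds inclusive.
    """
    if isinstance(pairs, pd.DataFrame):
        d = pairs["delta"].to_numpy(dtype=float)
    else:
        d = np.asarray(pairs, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < 2:
        raise ValueError("Bland–Altman requires at least 2 differences")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    low, high = mean - 1.96 * sd, mean + 1.96 * sd
    within = float(np.mean((d >= low) & (d <= high)))
    return BlandAltmanResult(mean, sd, low, high, within, int(d.size))


def sweep_coverage_thresholds(
    table_a: SiteTable,
    table_b: SiteTable,
    t_grid: Sequence[int] = DEFAULT_SWEEP_GRID,
    drop_zero_both: bool = True,
) -> pd.DataFrame:
    """Recompute concordance and agreement at each coverage threshold.

    Returns one row per threshold T with columns ``T, n_sites, r, R2,
    mean_diff, loa_low, loa_high``. Thresholds that retain fewer than 3
    pairs get null statistics with a warning. R² is the squared Pearson
    correlation coefficient.
    """
    grid = list(t_grid)
    if not grid:
        raise ValueError("empty threshold grid")
    if any(t < 0 for t in grid) or grid != sorted(grid):
        raise ValueError("grid must be sorted and non-negative")
    rows = []
    for t in grid:
        pairs = join_paired_sites(
            table_a, table_b, min_valid_cov=t, drop_zero_both=drop_zero_both
        )
        n = len(pairs)
        if n < 3:
            warnings.warn(f"threshold {t}: only {n} pairs; null statistics")
            rows.append((t, n, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        fit = fit_concordance(pairs)
        ba = bland_altman(pairs)
        rows.append(
            (
                t, n,
                np.nan if fit.r is None else fit.r,
                np.nan if fit.r2 is None else fit.r2,
                ba.mean_diff, ba.loa_low, ba.loa_high,
            )
        )
    return pd.DataFrame(
        rows, columns=["T", "n_sites", "r", "R2", "mean_diff", "loa_low", "loa_high"]
    )


def suggest_threshold(
    sweep: pd.DataFrame, rel_tol: float = 0.10, min_sites: int = 50
) -> int | None:
    """Flag the smallest T whose LoA half-width is within ``rel_tol`` of
    the sweep's asymptote (the half-width at the largest threshold that
    still retains ``min_sites`` pairs — sparser rows are too noisy to
    anchor the asymptote).

    Advisory only — the choice is reported for the analyst to confirm,
    since it trades precision against how many sites survive.
    """
    sw = sweep.dropna(subset=["loa_low", "loa_high"])
    sw = sw[sw["n_sites"] >= min_sites]
    if sw.empty:
        return None
    hw = (sw["loa_high"] - sw["loa_low"]) / 2.0
    asymptote = hw.iloc[-1]
    ok = hw <= asymptote * (1.0 + rel_tol)
    return int(sw.loc[ok, "T"].iloc[0]) if ok.any() else None


def delta_distribution(
    pairs: pd.DataFrame,
    n_bins: int = 41,
    pseudocount: float | None = None,
) -> DeltaSummary:
    """Histogram and ECDF of Δ, plus ECDF of log2 fold change.

    Under the default policy pairs where either stoichiometry is zero are
    dropped from the log2FC ECDF and counted in ``n_dropped_nonfinite``.
    Passing a ``pseudocount`` eps computes log2((f_b+eps)/(f_a+eps))
    instead, keeping every pair.
    """
    if pairs.empty:
        raise ValueError("pairs is empty")
    delta = pairs["delta"].to_numpy(dtype=float)
    counts, bins = np.histogram(delta, bins=n_bins, range=(-1.0, 1.0))
    d_ecdf = ECDF(delta)
    if pseudocount is not None:
        l2 = np.log2(
            (pairs["f_b"].to_numpy() + pseudocount)
            / (pairs["f_a"].to_numpy() + pseudocount)
        )
        dropped = 0
    else:
        l2 = pairs["log2fc"].to_numpy(dtype=float)
        dropped = int(np.sum(~np.isfinite(l2)))
        l2 = l2[np.isfinite(l2)]
    if l2.size == 0:
        warnings.warn("no finite log2 fold changes; empty ECDF")
        fc_ecdf = None
    else:
        fc_ecdf = ECDF(l2)
    return DeltaSummary(bins, counts, d_ecdf, fc_ecdf, dropped)
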