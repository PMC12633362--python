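"""Simulation studies that characterize the pipeline's behavior.

Each function runs the package end to end under stated synthetic
conditions and returns summary numbers with closed-form expectations
(binomial sampling theory) to compare against:

* estimator recovery — bias and RMSE of site stoichiometry vs the
  binomial standard error sqrt(f(1-f)/n);
* two-replicate null — Bland–Altman band geometry vs the theoretical
  half-width 1.96·sqrt(2·f(1-f)/n) for a difference of two proportions;
* threshold sweep — median band half-width and site retention as the
  coverage floor rises;
* classification operating characteristics — false-flag rate of a null
  comparison against an independently estimated band, and sensitivity
  to an injected stoichiometry shift;
* conversion-sequencing recovery — non-conversion rate vs
  f + (1-f)(1-c), and power of the paired per-snRNA test.

Seeds are taken explicitly so studies are reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import (
    BlandAltmanResult,
    bland_altman,
    join_paired_sites,
    sweep_coverage_thresholds,
)
from .crown import per_snrna_condition_stats
from .differential import NullBand, classify_sites
from .pileup import PileupConfig, SiteTable, pileup_calls
from .simulate import (
    CrownSimConfig,
    NanoporeSimConfig,
    simulate_crown_counts,
    simulate_nanopore_calls,
)

__all__ = [
    "binomial_site_table",
    "estimator_recovery",
    "two_replicate_null",
    "sweep_seed_medians",
    "null_flag_rate",
    "injected_shift_sensitivity",
    "crown_recovery_deviations",
    "crown_shift_test",
]


def binomial_site_table(
    f_true, coverage, rng: np.random.Generator, tau: float = 0.99
) -> SiteTable:
    """Site table under the pure measurement model: n_mod ~ Binom(n, f).

    Fixed coverage, every call confident — the no-basecaller-error limit
    used to study sampling noise in isolation.
    """
    f = np.asarray(f_true, dtype=float)
    cov = np.broadcast_to(np.asarray(coverage, dtype=int), f.shape)
    n_mod = rng.binomial(cov, f)
    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos0": 10 * np.arange(f.size),
            "strand": "+",
            "n_mod": n_mod.astype(np.int64),
            "n_canon": (cov - n_mod).astype(np.int64),
            "n_fail": np.zeros(f.size, dtype=np.int64),
        }
    )
    return SiteTable(df, tau=tau).finalize()


def estimator_recovery(
    n_sites: int = 2000,
    coverage_mean: float = 100.0,
    min_valid_cov: int = 50,
    seed: int = 0,
) -> dict:
    """Run simulate -> pileup and measure stoichiometry recovery.

    Error-free basecalling (epsilon = 0) so the only noise is binomial
    read sampling plus the confident-call thinning. Returns mean bias,
    its standard error, the RMSE, and the binomial-theory RMSE
    sqrt(mean(f(1-f)/n_valid)).
    """
    cfg = NanoporeSimConfig(
        n_sites=n_sites, coverage_mean=coverage_mean, epsilon=0.0, seed=seed
    )
    calls, truth = simulate_nanopore_calls(cfg)
    table = pileup_calls(calls, PileupConfig(tau=cfg.tau))
    joined = table.df.merge(truth, on=["chrom", "pos0", "strand"])
    joined = joined[joined["valid_cov"] >= min_valid_cov]
    err = joined["f"] - joined["f_true"]
    f = joined["f_true"].to_numpy()
    n = joined["valid_cov"].to_numpy()
    rmse = float(np.sqrt(np.mean(err**2)))
    rmse_theory = float(np.sqrt(np.mean(f * (1 - f) / n)))
    return {
        "n_sites": int(len(joined)),
        "bias": float(err.mean()),
        "bias_se": float(err.std(ddof=1) / np.sqrt(len(err))),
        "rmse": rmse,
        "rmse_theory": rmse_theory,
        "rmse_ratio": rmse / rmse_theory,
    }


def two_replicate_null(
    n_sites: int = 5000,
    coverage: int = 100,
    f: float = 0.3,
    seed: int = 0,
) -> tuple[BlandAltmanResult, float]:
    """Bland–Altman band for two replicates of one shared truth.

    Constant stoichiometry and fixed coverage give the closed-form
    half-width 1.96·sqrt(2·f(1-f)/n); returns (result, that expectation).
    """
    rng = np.random.default_rng([seed, 0xBA])
    truth = np.full(n_sites, f)
    a = binomial_site_table(truth, coverage, rng)
    b = binomial_site_table(truth, coverage, rng)
    pairs = join_paired_sites(a, b, min_valid_cov=0)
    ba = bland_altman(pairs)
    expected_hw = 1.96 * np.sqrt(2 * f * (1 - f) / coverage)
    return ba, float(expected_hw)


def sweep_seed_medians(
    n_seeds: int = 10,
    n_sites: int = 1200,
    coverage_mean: float = 80.0,
    t_grid=(0, 25, 50, 75, 100),
    seed: int = 0,
) -> pd.DataFrame:
    """Median sweep behavior over seeds on two-replicate null data.

    For each seed, simulates two replicates of the same truth through
    the full call->pileup->join path and sweeps the coverage floor;
    reports the per-threshold median LoA half-width and median retained
    site count across seeds. With truth independent of coverage both
    should be non-increasing in the threshold.
    """
    rows = []
    for s in range(n_seeds):
        cfg = NanoporeSimConfig(
            n_sites=n_sites, coverage_mean=coverage_mean, seed=seed + s
        )
        a = pileup_calls(simulate_nanopore_calls(cfg, replicate=0)[0])
        b = pileup_calls(simulate_nanopore_calls(cfg, replicate=1)[0])
        sweep = sweep_coverage_thresholds(a, b, t_grid=list(t_grid))
        sweep["half_width"] = (sweep["loa_high"] - sweep["loa_low"]) / 2
        sweep["seed"] = s
        rows.append(sweep)
    stacked = pd.concat(rows, ignore_index=True)
    return (
        stacked.groupby("T")[["half_width", "n_sites"]]
        .median()
        .reset_index()
        .rename(columns={"half_width": "median_half_width",
                         "n_sites": "median_n_sites"})
    )


def _uniform_truth(rng: np.random.Generator, n_sites: int) -> np.ndarray:
    return rng.uniform(0.2, 0.8, n_sites)


def null_flag_rate(
    n_seeds: int = 10,
    n_sites: int = 5000,
    coverage: int = 100,
    seed: int = 0,
) -> float:
    """Mean fraction of sites flagged in null comparisons.

    Per seed: estimate the band from one control-vs-control pair, then
    classify an independent null pair of the same design against it.
    The band is a 95% interval, so ~5% of sites should be flagged.
    """
    rates = []
    for s in range(n_seeds):
        rng = np.random.default_rng([seed + s, 0x11AF])
        f = _uniform_truth(rng, n_sites)
        band_pairs = join_paired_sites(
            binomial_site_table(f, coverage, rng),
            binomial_site_table(f, coverage, rng),
            min_valid_cov=50,
        )
        band = NullBand.from_bland_altman(bland_altman(band_pairs))
        test_pairs = join_paired_sites(
            binomial_site_table(f, coverage, rng),
            binomial_site_table(f, coverage, rng),
            min_valid_cov=50,
        )
        labels = classify_sites(test_pairs, band)
        rates.append(float((labels != "unchanged").mean()))
    return float(np.mean(rates))


def injected_shift_sensitivity(
    delta: float = 0.2,
    coverage: int = 250,
    n_sites: int = 2000,
    n_injected: int = 300,
    band: NullBand = NullBand(-0.066, 0.066),
    seed: int = 0,
) -> float:
    """Sensitivity to an injected stoichiometry shift.

    Mid-range truths, fixed coverage at or above 200 reads, classified
    against the published-scale null band; returns the fraction of
    injected sites labeled "increased".
    """
    rng = np.random.default_rng([seed, 0x5E45])
    f = rng.uniform(0.3, 0.6, n_sites)
    f_shift = f.copy()
    hit = rng.choice(n_sites, n_injected, replace=False)
    f_shift[hit] = np.clip(f_shift[hit] + delta, 0, 1)
    ctrl = binomial_site_table(f, coverage, rng)
    treat = binomial_site_table(f_shift, coverage, rng)
    pairs = join_paired_sites(ctrl, treat, min_valid_cov=50)
    labels = classify_sites(pairs, band).to_numpy()
    hit_pos = np.isin(pairs["pos0"].to_numpy(), 10 * hit)
    return float((labels[hit_pos] == "increased").mean())


def crown_recovery_deviations(
    coverage: int = 10_000,
    conversion_efficiency: float = 0.9,
    f_values=(0.1, 0.3, 0.6),
    seed: int = 0,
) -> pd.DataFrame:
    """Non-conversion rate vs the expectation f + (1-f)(1-c).

    Returns one row per stoichiometry with the simulated rate, the
    expectation, and the deviation in units of the binomial SD.
    """
    cfg = CrownSimConfig(
        tss={f"X{i}": f for i, f in enumerate(f_values)},
        conversion_efficiency=conversion_efficiency,
        coverage=coverage,
        base_error=0.0,
        replicates=1,
        seed=seed,
    )
    reps, truth = simulate_crown_counts(cfg)
    tab = reps[0].merge(truth[["gene_id", "f_true"]], on="gene_id")
    c = conversion_efficiency
    tab["expected"] = tab["f_true"] + (1 - tab["f_true"]) * (1 - c)
    tab["binom_sd"] = np.sqrt(tab["expected"] * (1 - tab["expected"]) / coverage)
    tab["dev_sd"] = (tab["non_conversion"] - tab["expected"]).abs() / tab["binom_sd"]
    return tab[["gene_id", "f_true", "non_conversion", "expected", "dev_sd"]]


def crown_shift_test(
    shift: float = 0.2,
    n_snrna: int = 28,
    coverage: int = 1000,
    replicates: int = 3,
    seed: int = 0,
):
    """Power check: paired per-snRNA test under a global m6Am increase."""
    truth = {f"RNU-{i}": f for i, f in enumerate(
        np.linspace(0.05, 0.6, n_snrna))}
    ctrl_cfg = CrownSimConfig(
        tss=truth, coverage=coverage, replicates=replicates, seed=seed
    )
    treat_cfg = CrownSimConfig(
        tss={g: min(1.0, f + shift) for g, f in truth.items()},
        coverage=coverage, replicates=replicates, seed=seed + 7919,
    )
    ctrl, _ = simulate_crown_counts(ctrl_cfg)
    treat, _ = simulate_crown_counts(treat_cfg)
    return per_snrna_condition_stats(ctrl, treat)
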