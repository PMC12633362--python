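"""Synthetic data with the statistical structure the analysis assumes.

Three generators mirror the three measurement processes:

* nanopore per-read m6A calls — per-site true stoichiometry drawn from a
  zero-inflated Beta mixture (most sites unmodified or lowly modified,
  long right tail), negative-binomial coverage, and a basecaller that
  emits a confident call with probability q and, when confident, the
  correct class with probability 1−ε; call probabilities fall uniformly
  inside the pass/fail bands around the dual confidence threshold, which
  is all the downstream filter can see;
* conversion-sequencing TSS base counts — A/(A+G) with conversion
  efficiency c < 1 leaking (1−f)(1−c) unconverted starts into the A pile
  and a base-error rate leaking reads into other bases;
* dependency matrices in the portal layout with designated dependent
  lines.

Randomness is counter-based: one global seed plus fixed integer stream
keys (replicate, site) feed ``numpy.random.default_rng``, so any site's
draws are reproducible independent of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NanoporeSimConfig",
    "EffectSpec",
    "CrownSimConfig",
    "simulate_truth",
    "inject_effect",
    "simulate_nanopore_calls",
    "simulate_crown_counts",
    "simulate_start_records",
    "simulate_dependency_matrix",
]

_TRUTH_STREAM = 0x7A0  # stream key for truth draws, distinct from reads


@dataclass(frozen=True)
class NanoporeSimConfig:
    """Study conditions for the nanopore measurement simulator.

    Defaults: 2000 sites, negative-binomial coverage with mean 100 and
    dispersion 10, truth mixture 0.3·δ₀ + 0.7·Beta(1.2, 2.5) (low-skewed
    stoichiometries with a long right tail), confident-call pass rate
    0.95, confident-call error rate 0.002, confidence band at 0.99.
    """

    n_sites: int = 2000
    coverage_mean: float = 100.0
    coverage_dispersion: float = 10.0
    pi0: float = 0.3
    beta_a: float = 1.2
    beta_b: float = 2.5
    q_pass: float = 0.95
    epsilon: float = 0.002
    tau: float = 0.99
    chrom: str = "chr1"
    strand: str = "+"
    site_spacing: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pi0", "q_pass", "epsilon"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        if not 0.5 < self.tau <= 1.0:
            raise ValueError("tau must be in (0.5, 1]")


@dataclass(frozen=True)
class EffectSpec:
    """Sites to perturb and the additive shift applied to their truth."""

    delta: float
    sites: tuple[int, ...] | None = None
    fraction: float | None = None

    def __post_init__(self) -> None:
        if (self.sites is None) == (self.fraction is None):
            raise ValueError("give exactly one of sites or fraction")


def simulate_truth(config: NanoporeSimConfig) -> pd.DataFrame:
    """Draw per-site true stoichiometries and site coordinates."""
    rng = np.random.default_rng([config.seed, _TRUTH_STREAM])
    zero = rng.random(config.n_sites) < config.pi0
    f = rng.beta(config.beta_a, config.beta_b, size=config.n_sites)
    f[zero] = 0.0
    return pd.DataFrame(
        {
            "site_index": np.arange(config.n_sites),
            "chrom": config.chrom,
            "pos0": np.arange(config.n_sites) * config.site_spacing + 2,
            "strand": config.strand,
            "f_true": f,
        }
    )


def inject_effect(
    truth: pd.DataFrame, spec: EffectSpec, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Shift the truth at chosen sites, clipping to [0,1].

    Returns the new truth table and the affected site indices. A spec
    given as a fraction selects sites without replacement using ``seed``.
    """
    out = truth.copy()
    if spec.sites is not None:
        idx = np.asarray(spec.sites, dtype=int)
        if len(idx) == 0:
            import warnings

            warnings.warn("empty effect spec: truth unchanged")
            return out, idx
        missing = set(idx) - set(out["site_index"])
        if missing:
            raise KeyError(f"effect sites not in truth: {sorted(missing)}")
    else:
        rng = np.random.default_rng([seed, 0x5E1])
        k = int(round(spec.fraction * len(out)))
        idx = np.sort(
            rng.choice(out["site_index"].to_numpy(), size=k, replace=False)
        )
    mask = out["site_index"].isin(idx)
    out.loc[mask, "f_true"] = np.clip(
        out.loc[mask, "f_true"] + spec.delta, 0.0, 1.0
    )
    return out, idx


def simulate_nanopore_calls(
    config: NanoporeSimConfig,
    effect: EffectSpec | None = None,
    replicate: int = 0,
    truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a per-read call table and the truth behind it.

    Two calls with the same config but different ``replicate`` share the
    truth (drawn from the config seed) while reads are independent — the
    replicate structure the calibration analysis relies on. Returns
    ``(calls, truth)`` where calls has columns read_id, chrom, pos0,
    strand, p_mod.
    """
    if truth is None:
        truth = simulate_truth(config)
        if effect is not None:
            truth, _ = inject_effect(truth, effect, seed=config.seed)
    tau = config.tau
    k = config.coverage_dispersion
    p_nb = k / (k + config.coverage_mean)
    read_ids: list[str] = []
    chroms: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    strands: list[np.ndarray] = []
    probs: list[np.ndarray] = []
    for row in truth.itertuples(index=False):
        rng = np.random.default_rng(
            [config.seed, 1 + replicate, int(row.site_index)]
        )
        cov = int(rng.negative_binomial(k, p_nb))
        if cov == 0:
            continue
        is_mod = rng.random(cov) < row.f_true
        confident = rng.random(cov) < config.q_pass
        flipped = rng.random(cov) < config.epsilon
        called_mod = np.where(flipped, ~is_mod, is_mod)
        p = np.empty(cov)
        m = confident & called_mod
        c = confident & ~called_mod
        fl = ~confident
        p[m] = rng.uniform(tau, 1.0, size=int(m.sum()))
        p[c] = rng.uniform(0.0, 1.0 - tau, size=int(c.sum()))
        p[fl] = rng.uniform(1.0 - tau, tau, size=int(fl.sum()))
        read_ids.extend(
            f"rep{replicate}:s{row.site_index}:r{j}" for j in range(cov)
        )
        chroms.append(np.repeat(row.chrom, cov))
        positions.append(np.repeat(np.int64(row.pos0), cov))
        strands.append(np.repeat(row.strand, cov))
        probs.append(p)
    if not probs:
        calls = pd.DataFrame(
            columns=["read_id", "chrom", "pos0", "strand", "p_mod"]
        )
    else:
        calls = pd.DataFrame(
            {
                "read_id": read_ids,
                "chrom": np.concatenate(chroms),
                "pos0": np.concatenate(positions),
                "strand": np.concatenate(strands),
                "p_mod": np.concatenate(probs),
            }
        )
    return calls, truth


@dataclass(frozen=True)
class CrownSimConfig:
    """Conversion-sequencing simulator conditions.

    ``tss``: mapping gene_id -> true m6Am stoichiometry. Conversion
    efficiency c in (0,1]; per-TSS coverage; base-error rate leaking
    reads to non-A/G bases; replicate count.
    """

    tss: Mapping[str, float] = field(
        default_factory=lambda: {f"RNU-{i}": f for i, f in enumerate(
            [0.05, 0.15, 0.3, 0.5, 0.7, 0.85]
        )}
    )
    conversion_efficiency: float = 0.98
    coverage: int = 1000
    base_error: float = 0.001
    replicates: int = 3
    chrom: str = "chrU"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.conversion_efficiency <= 1.0:
            raise ValueError("conversion efficiency must be in (0,1]")
        if any(not 0.0 <= f <= 1.0 for f in self.tss.values()):
            raise ValueError("true stoichiometries must be in [0,1]")


def _crown_probs(f: float, c: float, err: float) -> tuple[float, float, float]:
    # a read stays A if methylated or unconverted; error sends it elsewhere
    p_a = (f + (1.0 - f) * (1.0 - c)) * (1.0 - err)
    p_other = err
    return p_a, 1.0 - p_a - p_other, p_other


def simulate_crown_counts(
    config: CrownSimConfig,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Per-replicate TSS base-count tables plus the truth table."""
    genes = list(config.tss)
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "chrom": config.chrom,
            "pos0": np.arange(len(genes)) * 100 + 10,
            "strand": "+",
            "f_true": [config.tss[g] for g in genes],
        }
    )
    reps = []
    for rep in range(config.replicates):
        rows = []
        for i, row in enumerate(truth.itertuples(index=False)):
            rng = np.random.default_rng([config.seed, 2, rep, i])
            p_a, p_g, p_o = _crown_probs(
                row.f_true, config.conversion_efficiency, config.base_error
            )
            n_a, n_g, n_o = rng.multinomial(config.coverage, [p_a, p_g, p_o])
            denom = n_a + n_g
            rows.append(
                (row.gene_id, row.chrom, row.pos0, row.strand,
                 int(n_a), int(n_g), int(n_o),
                 n_a / denom if denom else np.nan)
            )
        reps.append(
            pd.DataFrame(
                rows,
                columns=["gene_id", "chrom", "pos0", "strand",
                         "n_A", "n_G", "n_other", "non_conversion"],
            )
        )
    return reps, truth


def simulate_start_records(
    config: CrownSimConfig,
    replicate: int = 0,
    softclip_rate: float = 0.05,
) -> pd.DataFrame:
    """Per-read aligned-start records for one replicate.

    Expands the same multinomial base draws into read-level records and
    sprinkles in 5'-softclipped mate-1 reads (which the quantifier must
    ignore); mate-2 records are not emitted since only read1 anchors the
    start nucleotide.
    """
    counts, truth = simulate_crown_counts(config)
    tab = counts[replicate]
    rows = []
    for i, row in enumerate(tab.itertuples(index=False)):
        rng = np.random.default_rng([config.seed, 3, replicate, i])
        bases = ["A"] * row.n_A + ["G"] * row.n_G + ["C"] * row.n_other
        clipped = rng.random(len(bases)) < softclip_rate
        for j, base in enumerate(bases):
            rows.append(
                (row.chrom, row.pos0, row.strand, 1, 0, base,
                 f"rep{replicate}:{row.gene_id}:r{j}")
            )
        # softclipped decoys with arbitrary bases, to be filtered out
        for j in range(int(clipped.sum())):
            rows.append(
                (row.chrom, row.pos0, row.strand, 1, 1, "G",
                 f"rep{replicate}:{row.gene_id}:clip{j}")
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos0", "strand", "mate", "softclip5", "base",
                 "read_id"],
    )


def simulate_dependency_matrix(
    n_lines: int,
    genes: Sequence[str],
    essential_map: Mapping[str, Sequence[str]],
    seed: int = 0,
    aml_fraction: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Dependency matrices in the portal layout plus a lineage map.

    Lines are named ACH-SIM0001..; ``essential_map`` designates, per
    gene, the lines that depend on it (probability ~ U(0.8,1), effect
    ~ N(−1,0.1)); all other lines get probability ~ U(0,0.3) and effect
    ~ N(0,0.1). Returns (effect matrix, probability matrix, lineage map).
    """
    lines = [f"ACH-SIM{i:04d}" for i in range(n_lines)]
    for gene, dep in essential_map.items():
        dep = list(dep)
        if len(dep) != len(set(dep)):
            raise ValueError(f"duplicate line ids for gene {gene!r}")
        missing = set(dep) - set(lines)
        if missing:
            raise KeyError(f"unknown line ids for {gene!r}: {sorted(missing)}")
    rng = np.random.default_rng([seed, 4])
    eff = pd.DataFrame(index=pd.Index(lines, name="ModelID"))
    prob = pd.DataFrame(index=pd.Index(lines, name="ModelID"))
    for gene in genes:
        dep = set(essential_map.get(gene, ()))
        is_dep = np.array([ln in dep for ln in lines])
        p = np.where(
            is_dep,
            rng.uniform(0.8, 1.0, n_lines),
            rng.uniform(0.0, 0.3, n_lines),
        )
        e = np.where(
            is_dep,
            rng.normal(-1.0, 0.1, n_lines),
            rng.normal(0.0, 0.1, n_lines),
        )
        eff[gene] = e
        prob[gene] = p
    n_aml = int(round(aml_fraction * n_lines))
    lineage = pd.DataFrame(
        {
            "ModelID": lines,
            "lineage": ["AML"] * n_aml + ["other"] * (n_lines - n_aml),
        }
    )
    return eff, prob, lineage
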