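"""Two-condition comparison and classification against an empirical null.

A site is called changed only when its stoichiometry difference exceeds
the replicate-derived null band (the control-vs-control Bland–Altman
limits of agreement, e.g. ±0.066 at a 50-read floor): increased when
``delta > loa_high``, decreased when ``delta < loa_low``, unchanged
otherwise (strict inequalities — a difference exactly at the band edge
has not exceeded baseline variability). No per-site hypothesis test is
performed; classification is descriptive against the band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import (
    BlandAltmanResult,
    DeltaSummary,
    FitResult,
    bland_altman,
    delta_distribution,
    fit_concordance,
    join_paired_sites,
)
from .pileup import SITE_KEY, SiteTable

__all__ = [
    "NullBand",
    "ComparisonReport",
    "compare_conditions",
    "classify_sites",
    "subset_sites",
    "read_bed6",
    "cross_method_compare",
]

LABELS = ("increased", "decreased", "unchanged")


@dataclass(frozen=True)
class NullBand:
    """Empirical null interval for Δ stoichiometry.

    Normally the limits of agreement of an independent control-vs-control
    comparison. ``borrowed`` marks a band imported from another
    experiment because no same-condition replicates existed.
    """

    loa_low: float
    loa_high: float
    borrowed: bool = False

    def __post_init__(self) -> None:
        if not self.loa_low < self.loa_high:
            raise ValueError("null band requires loa_low < loa_high")

    @classmethod
    def from_bland_altman(
        cls, ba: BlandAltmanResult, borrowed: bool = False
    ) -> "NullBand":
        return cls(ba.loa_low, ba.loa_high, borrowed=borrowed)


@dataclass
class ComparisonReport:
    pairs: pd.DataFrame
    fit: FitResult | None
    ba: BlandAltmanResult | None
    delta_summary: DeltaSummary | None
    min_valid_cov: int
    null_band: NullBand | None = None
    notes: tuple[str, ...] = ()

    def label_counts(self) -> dict[str, int]:
        if "label" not in self.pairs:
            return {}
        vc = self.pairs["label"].value_counts()
        return {lbl: int(vc.get(lbl, 0)) for lbl in LABELS}

    def summary(self) -> dict:
        out: dict = {"n_pairs": len(self.pairs), "min_valid_cov": self.min_valid_cov}
        if self.fit is not None:
            out["fit"] = {
                "r": self.fit.r, "p_value": self.fit.p_value,
                "slope": self.fit.slope, "intercept": self.fit.intercept,
                "n": self.fit.n,
            }
        if self.ba is not None:
            out["bland_altman"] = {
                "mean_diff": self.ba.mean_diff, "sd_diff": self.ba.sd_diff,
                "loa_low": self.ba.loa_low, "loa_high": self.ba.loa_high,
                "pct_within": self.ba.pct_within,
            }
        if self.null_band is not None:
            out["null_band"] = {
                "loa_low": self.null_band.loa_low,
                "loa_high": self.null_band.loa_high,
                "borrowed": self.null_band.borrowed,
            }
            out["labels"] = self.label_counts()
        if self.notes:
            out["notes"] = list(self.notes)
        return out


def classify_sites(pairs: pd.DataFrame, null_band: NullBand) -> pd.Series:
    """Label each pair increased/decreased/unchanged against the band."""
    delta = pairs["delta"].to_numpy(dtype=float)
    labels = np.where(
        delta > null_band.loa_high,
        "increased",
        np.where(delta < null_band.loa_low, "decreased", "unchanged"),
    )
    return pd.Series(labels, index=pairs.index, name="label")


def compare_conditions(
    ctrl: SiteTable,
    treat: SiteTable,
    min_valid_cov: int = 50,
    null_band: NullBand | None = None,
    drop_zero_both: bool = True,
) -> ComparisonReport:
    """Full two-condition comparison at a coverage floor.

    Joins the tables (delta = treat − ctrl), fits concordance, runs
    Bland–Altman, summarizes the Δ/log2FC distributions, and — when a
    null band is supplied — classifies every site against it. A relaxed
    floor below 50 reads is allowed but noted as noisier.
    """
    notes: list[str] = []
    if min_valid_cov < 50:
        notes.append(
            f"relaxed coverage floor ({min_valid_cov} reads): stoichiometry "
            "estimates are substantially noisier"
        )
    if null_band is not None and null_band.borrowed:
        notes.append(
            "null band borrowed from another comparison (no same-condition "
            "replicates available)"
        )
    pairs = join_paired_sites(
        ctrl, treat, min_valid_cov=min_valid_cov, drop_zero_both=drop_zero_both
    )
    if len(pairs) < 3:
        warnings.warn(f"only {len(pairs)} pairs; emitting null statistics")
        return ComparisonReport(
            pairs, None, None, None, min_valid_cov, null_band, tuple(notes)
        )
    fit = fit_concordance(pairs)
    ba = bland_altman(pairs)
    summary = delta_distribution(pairs)
    if null_band is not None:
        pairs = pairs.assign(label=classify_sites(pairs, null_band))
    return ComparisonReport(
        pairs, fit, ba, summary, min_valid_cov, null_band, tuple(notes)
    )


def read_bed6(path) -> pd.DataFrame:
    """Parse a BED6 file (0-based half-open) into a regions table."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(
                    f"{path}:{lineno}: BED6 requires 6 columns, got {len(parts)}"
                )
            chrom, start, end, name, score, strand = parts[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if strand not in {"+", "-"}:
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            rows.append((chrom, start_i, end_i, name, score, strand))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


def subset_sites(pairs: pd.DataFrame, regions: pd.DataFrame | str) -> pd.DataFrame:
    """Keep pairs whose site falls in any region on the matching strand.

    ``regions`` is a BED6 table (or path); intervals are 0-based
    half-open. Used e.g. to pull out the m6A sites of a single gene.
    """
    if isinstance(regions, (str, bytes)):
        regions = read_bed6(regions)
    if regions.empty or pairs.empty:
        return pairs.iloc[0:0]
    keep = np.zeros(len(pairs), dtype=bool)
    chrom = pairs["chrom"].to_numpy()
    pos = pairs["pos0"].to_numpy()
    strand = pairs["strand"].to_numpy()
    for reg in regions.itertuples(index=False):
        keep |= (
            (chrom == reg.chrom)
            & (pos >= reg.start)
            & (pos < reg.end)
            & (strand == reg.strand)
        )
    return pairs[keep].reset_index(drop=True)


def cross_method_compare(
    nanopore: SiteTable,
    external: pd.DataFrame,
    min_external_f: float = 0.05,
    min_valid_cov: int = 50,
) -> ComparisonReport:
    """Compare nanopore stoichiometries with an orthogonal method's table.

    ``external`` needs columns ``chrom, pos0, strand, f``. Reference
    datasets such as GLORI only report sites above a stoichiometry floor
    (0.05), so both sides are filtered to ``f > min_external_f`` to keep
    the comparison symmetric. delta = nanopore − external.
    """
    need = set(SITE_KEY + ["f"])
    if not need <= set(external.columns):
        raise ValueError(f"external table must have columns {sorted(need)}")
    nano = nanopore.df[nanopore.df["valid_cov"] >= min_valid_cov]
    ext = external[external["f"] > min_external_f]
    nano = nano[nano["f"] > min_external_f]
    pairs = ext.merge(nano, on=SITE_KEY, suffixes=("_a", "_b"), how="inner")
    if pairs.empty:
        raise ValueError("no shared sites between methods after filtering")
    pairs = pairs.rename(columns={"valid_cov": "cov_b"})
    pairs["cov_a"] = np.nan
    pairs = pairs.assign(delta=pairs["f_b"] - pairs["f_a"])
    with np.errstate(divide="ignore", invalid="ignore"):
        l2 = np.log2(pairs["f_b"].to_numpy() / pairs["f_a"].to_numpy())
    l2[~np.isfinite(l2)] = np.nan
    pairs = pairs.assign(log2fc=l2)
    pairs = pairs[
        SITE_KEY + ["f_a", "f_b", "cov_a", "cov_b", "delta", "log2fc"]
    ].reset_index(drop=True)
    fit = fit_concordance(pairs) if len(pairs) >= 3 else None
    ba = bland_altman(pairs) if len(pairs) >= 3 else None
    summary = delta_distribution(pairs) if len(pairs) >= 3 else None
    return ComparisonReport(
        pairs, fit, ba, summary, min_valid_cov,
        notes=(f"cross-method join, both f > {min_external_f}",),
    )
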