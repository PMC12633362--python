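"""CROWN-seq-style m6Am quantification at transcription-start nucleotides.

Glyoxal/nitrite conversion deaminates unmethylated 2'-O-methyladenosine
at the transcription start nucleotide to inosine, read as G after
sequencing, while m6Am resists conversion and stays A. The per-TSS
non-conversion rate r = A/(A+G) therefore estimates m6Am stoichiometry.
Reads are first converted in silico (read1 A→G, read2 T→C) so they align
to a converted reference; only read1 alignments without a 5' softclip
anchor the start nucleotide reliably and are counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TssAnnotation",
    "PairedTResult",
    "convert_reads_in_silico",
    "read_start_records",
    "read_tss_bed",
    "tss_nonconversion",
    "per_snrna_condition_stats",
    "correct_for_conversion",
]

_CONVERT_R1 = str.maketrans("A", "G")
_CONVERT_R2 = str.maketrans("T", "C")
_VALID_BASES = frozenset("ACGTN")

#: columns of an aligned-start record table
START_RECORD_COLUMNS = [
    "chrom", "pos0", "strand", "mate", "softclip5", "base", "read_id",
]


@dataclass(frozen=True)
class TssAnnotation:
    chrom: str
    pos0: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")


@dataclass(frozen=True)
class PairedTResult:
    """Paired t-test on per-unit condition means."""

    mean_delta: float
    t: float | None
    p_value: float | None
    n: int
    n_excluded: int


def convert_reads_in_silico(seq: str, mate: int) -> str:
    """Apply the conversion-aware substitution (read1 A→G, read2 T→C)."""
    if mate not in (1, 2):
        raise ValueError(f"mate must be 1 or 2, got {mate!r}")
    up = seq.upper()
    if not set(up) <= _VALID_BASES:
        bad = sorted(set(up) - _VALID_BASES)
        raise ValueError(f"invalid characters in sequence: {bad}")
    return up.translate(_CONVERT_R1 if mate == 1 else _CONVERT_R2)


def read_start_records(path) -> pd.DataFrame:
    """Read an aligned-start-record TSV.

    Columns: chrom, pos0, strand, mate (1/2), softclip5 (0/1), base
    (observed base at the TSS), read_id. '#'-prefixed lines are skipped.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ValueError(
                    f"{path}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            chrom, pos0, strand, mate, clip, base, read_id = parts
            if base.upper() not in _VALID_BASES:
                raise ValueError(f"{path}:{lineno}: bad base {base!r}")
            rows.append(
                (chrom, int(pos0), strand, int(mate), int(clip),
                 base.upper(), read_id)
            )
    return pd.DataFrame(rows, columns=START_RECORD_COLUMNS)


def read_tss_bed(path) -> list[TssAnnotation]:
    """Read TSS annotations from BED6 (name column = gene id)."""
    from .differential import read_bed6

    bed = read_bed6(path)
    return [
        TssAnnotation(r.chrom, int(r.start), r.strand, r.name)
        for r in bed.itertuples(index=False)
    ]


def tss_nonconversion(
    records: pd.DataFrame,
    annotations: list[TssAnnotation],
    min_valid_cov: int = 50,
) -> pd.DataFrame:
    """Per-TSS base counts and non-conversion rate r = A/(A+G).

    Counts only mate-1 records without a 5' softclip whose mapped 5' end
    equals an annotated TSS. Bases other than A/G (sequencing error) go
    to ``n_other`` and stay out of the denominator. TSSs with
    A+G coverage below ``min_valid_cov`` are excluded; records at
    unannotated positions are ignored but tallied in ``df.attrs``.
    """
    need = set(START_RECORD_COLUMNS)
    if not need <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(need)}")
    dup = records.duplicated(subset=["read_id", "chrom", "pos0", "strand"])
    if dup.any():
        rid = records.loc[dup, "read_id"].iloc[0]
        raise ValueError(f"duplicate read {rid!r} at the same TSS")
    usable = records[(records["mate"] == 1) & (records["softclip5"] == 0)]
    ann_index = {(a.chrom, a.pos0, a.strand): a.gene_id for a in annotations}
    keys = list(zip(usable["chrom"], usable["pos0"], usable["strand"]))
    annotated = np.array([k in ann_index for k in keys], dtype=bool)
    n_unannotated = int((~annotated).sum())
    usable = usable[annotated]

    rows = []
    grouped = usable.groupby(["chrom", "pos0", "strand"], sort=True)
    counts = {k: g["base"].value_counts() for k, g in grouped}
    for ann in annotations:
        key = (ann.chrom, ann.pos0, ann.strand)
        vc = counts.get(key, pd.Series(dtype=int))
        n_a = int(vc.get("A", 0))
        n_g = int(vc.get("G", 0))
        n_other = int(vc.sum()) - n_a - n_g
        denom = n_a + n_g
        if denom < min_valid_cov:
            continue
        rows.append(
            (ann.gene_id, ann.chrom, ann.pos0, ann.strand,
             n_a, n_g, n_other, n_a / denom if denom else np.nan)
        )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "pos0", "strand",
                 "n_A", "n_G", "n_other", "non_conversion"],
    )
    out.attrs["n_unannotated_records"] = n_unannotated
    return out


def per_snrna_condition_stats(
    ctrl: list[pd.DataFrame],
    treat: list[pd.DataFrame],
) -> tuple[pd.DataFrame, PairedTResult]:
    """Per-snRNA condition means and a paired t-test across snRNAs.

    Each input list holds one non-conversion table per replicate (output
    of :func:`tss_nonconversion`). For every snRNA present with at least
    one qualifying replicate in *both* conditions, replicate-level
    non-conversion rates are averaged per condition; the paired t-test
    (n−1 df) is run on the per-snRNA differences (treat − ctrl). snRNAs
    missing from either condition are excluded and counted. A
    zero-variance difference vector leaves t defined but p null with a
    degenerate-case warning (|t| would be infinite under the model).
    """

    def condition_means(tables: list[pd.DataFrame]) -> pd.Series:
        stacked = pd.concat(tables, ignore_index=True)
        return stacked.groupby("gene_id")["non_conversion"].mean()

    m_ctrl = condition_means(ctrl)
    m_treat = condition_means(treat)
    shared = sorted(set(m_ctrl.index) & set(m_treat.index))
    n_excluded = len(set(m_ctrl.index) ^ set(m_treat.index))
    per = pd.DataFrame(
        {
            "gene_id": shared,
            "mean_ctrl": m_ctrl.loc[shared].to_numpy(),
            "mean_treat": m_treat.loc[shared].to_numpy(),
        }
    )
    per["delta"] = per["mean_treat"] - per["mean_ctrl"]
    d = per["delta"].to_numpy(dtype=float)
    if len(d) == 0:
        raise ValueError("no snRNA present in both conditions")
    mean_delta = float(np.mean(d))
    if len(d) < 2:
        warnings.warn("single shared snRNA: t-test undefined")
        return per, PairedTResult(mean_delta, None, None, len(d), n_excluded)
    if np.std(d, ddof=1) == 0:
        if mean_delta == 0:
            # all differences identically zero: t = 0/0 -> define t = 0
            return per, PairedTResult(0.0, 0.0, None, len(d), n_excluded)
        warnings.warn("zero-variance differences: p-value degenerate")
        return per, PairedTResult(mean_delta, None, None, len(d), n_excluded)
    t_res = stats.ttest_rel(per["mean_treat"], per["mean_ctrl"])
    return per, PairedTResult(
        mean_delta, float(t_res.statistic), float(t_res.pvalue),
        len(d), n_excluded,
    )


def correct_for_conversion(r: float, c: float) -> float:
    """Back out stoichiometry from a non-conversion rate.

    With conversion efficiency c < 1, unmethylated starts fail to
    convert at rate 1−c, so E[r] = f + (1−f)(1−c). Inverting and
    clamping: f̂ = clip((r − (1−c)) / c, 0, 1). Off by default in the
    pipeline — raw non-conversion rates are the primary readout.
    """
    if not 0.0 < c <= 1.0:
        raise ValueError(f"conversion efficiency must be in (0,1], got {c}")
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"non-conversion rate must be in [0,1], got {r}")
    return float(np.clip((r - (1.0 - c)) / c, 0.0, 1.0))
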