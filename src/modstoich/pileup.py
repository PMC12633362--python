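"""Confidence-filtered per-read modification pileup.

Direct RNA nanopore basecallers emit, for every candidate adenosine on
every read, a probability that the base carries m6A. A read call is only
usable when it is confident in *either* direction: we keep it as modified
when ``p_mod >= tau`` and as canonical when ``1 - p_mod >= tau`` (default
``tau = 0.99`` for both classes); everything in between is discarded as a
failed call. Site-level stoichiometry is then the fraction of modified
calls among the confident ("valid") coverage at that site.

Coordinates are 0-based half-open throughout and strand is explicit, so
site tables serialize directly to a bedMethyl dialect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MOD",
    "CANON",
    "FAIL",
    "PerReadCall",
    "PileupConfig",
    "SiteTable",
    "classify_call",
    "classify_calls",
    "pileup_calls",
    "merge_site_tables",
    "filter_by_coverage",
    "motif_mask",
    "read_calls_table",
    "calls_from_modbam",
    "write_bedmethyl",
    "read_bedmethyl",
]

MOD = "MOD"
CANON = "CANON"
FAIL = "FAIL"

#: index columns identifying a genomic site
SITE_KEY = ["chrom", "pos0", "strand"]

_VALID_STRANDS = frozenset({"+", "-"})


@dataclass(frozen=True)
class PerReadCall:
    """One read's modification probability at one candidate site."""

    read_id: str
    chrom: str
    pos0: int
    strand: str
    p_mod: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_mod <= 1.0:
            raise ValueError(f"p_mod must be in [0,1], got {self.p_mod!r}")
        if self.pos0 < 0:
            raise ValueError(f"pos0 must be >= 0, got {self.pos0}")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class PileupConfig:
    """Pileup parameters.

    tau
        Dual confidence threshold applied symmetrically to the modified
        and canonical classes. Must exceed 0.5 or the classes overlap.
    min_valid_cov
        Coverage floor used downstream; the pileup itself retains
        below-floor sites (coverage filtering is a separate step).
    """

    tau: float = 0.99
    min_valid_cov: int = 50

    def __post_init__(self) -> None:
        if not 0.5 < self.tau <= 1.0:
            raise ValueError(f"tau must be in (0.5, 1], got {self.tau}")
        if self.min_valid_cov < 0:
            raise ValueError("min_valid_cov must be >= 0")


@dataclass
class SiteTable:
    """Per-site confident-call counts and stoichiometry.

    ``df`` has one row per site with columns ``chrom, pos0, strand,
    n_mod, n_canon, n_fail``; derived columns ``valid_cov`` and ``f``
    (stoichiometry, NaN where valid coverage is zero) are maintained by
    :meth:`finalize`.
    """

    df: pd.DataFrame
    sample: str = ""
    tau: float = 0.99
    genome_build: str = ""
    merged_from: tuple[str, ...] = field(default_factory=tuple)

    def finalize(self) -> "SiteTable":
        df = self.df.copy()
        for col in ("n_mod", "n_canon", "n_fail"):
            if col not in df:
                df[col] = 0
            df[col] = df[col].astype(np.int64)
        df["valid_cov"] = df["n_mod"] + df["n_canon"]
        with np.errstate(invalid="ignore", divide="ignore"):
            df["f"] = np.where(
                df["valid_cov"] > 0, df["n_mod"] / df["valid_cov"], np.nan
            )
        dup = df.duplicated(subset=SITE_KEY)
        if dup.any():
            raise ValueError("duplicate site keys in SiteTable")
        self.df = df.reset_index(drop=True)
        return self

    @property
    def n_sites(self) -> int:
        return len(self.df)

    def keyed(self) -> pd.DataFrame:
        """Site-key-indexed view, used for joins."""
        return self.df.set_index(SITE_KEY)


def classify_call(p_mod: float, tau: float = 0.99) -> str:
    """Classify a single call as MOD, CANON, or FAIL.

    MOD iff ``p_mod >= tau``; CANON iff ``1 - p_mod >= tau``; FAIL
    otherwise. Thresholds are inclusive: a call exactly at the pass mark
    passes.
    """
    if not 0.0 <= p_mod <= 1.0:
        raise ValueError(f"p_mod must be in [0,1], got {p_mod!r}")
    if not 0.5 < tau <= 1.0:
        raise ValueError(f"tau must be in (0.5, 1], got {tau}")
    if p_mod >= tau:
        return MOD
    if (1.0 - p_mod) >= tau:
        return CANON
    return FAIL


def classify_calls(p_mod: np.ndarray, tau: float = 0.99) -> np.ndarray:
    """Vectorized :func:`classify_call` over an array of probabilities."""
    p = np.asarray(p_mod, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p_mod values must be in [0,1]")
    if not 0.5 < tau <= 1.0:
        raise ValueError(f"tau must be in (0.5, 1], got {tau}")
    return np.select([p >= tau, (1.0 - p) >= tau], [MOD, CANON], default=FAIL)


def _calls_frame(calls: Iterable[PerReadCall] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        df = calls.copy()
    else:
        df = pd.DataFrame(
            [(c.read_id, c.chrom, c.pos0, c.strand, c.p_mod) for c in calls],
            columns=["read_id", "chrom", "pos0", "strand", "p_mod"],
        )
    missing = {"read_id", "chrom", "pos0", "strand", "p_mod"} - set(df.columns)
    if missing:
        raise ValueError(f"calls table missing columns: {sorted(missing)}")
    bad = ~df["strand"].isin(_VALID_STRANDS)
    if bad.any():
        raise ValueError(
            f"malformed strand value {df.loc[bad, 'strand'].iloc[0]!r}"
        )
    return df


def pileup_calls(
    calls: Iterable[PerReadCall] | pd.DataFrame,
    config: PileupConfig = PileupConfig(),
    sample: str = "",
    genome_build: str = "",
) -> SiteTable:
    """Tabulate per-read calls into a per-site :class:`SiteTable`.

    Calls may arrive in any order. A duplicate (read_id, site) pair is an
    upstream fault (e.g. demultiplexing) and raises rather than being
    silently deduplicated. All sites are retained regardless of coverage;
    apply :func:`filter_by_coverage` separately.
    """
    df = _calls_frame(calls)
    if df.empty:
        empty = pd.DataFrame(
            columns=SITE_KEY + ["n_mod", "n_canon", "n_fail"]
        ).astype({"pos0": np.int64})
        return SiteTable(
            empty, sample=sample, tau=config.tau, genome_build=genome_build
        ).finalize()

    dup = df.duplicated(subset=["read_id"] + SITE_KEY, keep=False)
    if dup.any():
        rid = df.loc[dup, "read_id"].iloc[0]
        raise ValueError(f"duplicate call for read {rid!r} at the same site")

    label = classify_calls(df["p_mod"].to_numpy(), config.tau)
    df = df.assign(
        n_mod=(label == MOD).astype(np.int64),
        n_canon=(label == CANON).astype(np.int64),
        n_fail=(label == FAIL).astype(np.int64),
    )
    counts = (
        df.groupby(SITE_KEY, sort=True)[["n_mod", "n_canon", "n_fail"]]
        .sum()
        .reset_index()
    )
    return SiteTable(
        counts, sample=sample, tau=config.tau, genome_build=genome_build
    ).finalize()


def merge_site_tables(tables: Sequence[SiteTable]) -> SiteTable:
    """Merge replicate site tables by summing counts per site.

    Mirrors merging replicate alignments before a single pileup: counts
    add element-wise and stoichiometry is recomputed from the summed
    counts. All inputs must share ``tau`` (counts built under different
    filters are not comparable).
    """
    if not tables:
        raise ValueError("nothing to merge")
    tau = tables[0].tau
    build = tables[0].genome_build
    for t in tables[1:]:
        if t.tau != tau:
            raise ValueError(f"tau mismatch in merge: {t.tau} != {tau}")
        if t.genome_build and build and t.genome_build != build:
            raise ValueError("genome build mismatch in merge")
    frames = [t.df[SITE_KEY + ["n_mod", "n_canon", "n_fail"]] for t in tables]
    merged = (
        pd.concat(frames, ignore_index=True)
        .groupby(SITE_KEY, sort=True)
        .sum()
        .reset_index()
    )
    labels = tuple(
        lbl for t in tables for lbl in (t.merged_from or (t.sample,)) if lbl
    )
    return SiteTable(
        merged,
        sample="+".join(dict.fromkeys(labels)) if labels else "",
        tau=tau,
        genome_build=build,
        merged_from=labels,
    ).finalize()


def filter_by_coverage(table: SiteTable, min_valid_cov: int) -> SiteTable:
    """Keep sites whose valid coverage meets the floor (inclusive)."""
    if min_valid_cov < 0:
        raise ValueError("min_valid_cov must be >= 0")
    kept = table.df[table.df["valid_cov"] >= min_valid_cov]
    return replace(table, df=kept.reset_index(drop=True)).finalize()


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _matches_iupac(kmer: str, motif: str) -> bool:
    return len(kmer) == len(motif) and all(
        b in _IUPAC[m] for b, m in zip(kmer.upper(), motif)
    )


def motif_mask(table: SiteTable, reference, motif: str = "DRACH") -> SiteTable:
    """Keep sites whose strand-oriented sequence context matches a motif.

    ``reference`` is a :class:`pyfaidx.Fasta` (or a path to an indexed
    FASTA). The motif is an odd-length IUPAC string with A at the center
    (DRACH by default, the m6A consensus). Minus-strand sites are checked
    against the reverse complement of the plus-strand k-mer. Sites too
    close to a contig end for a full k-mer are dropped.
    """
    motif = motif.upper()
    if len(motif) % 2 != 1 or motif[len(motif) // 2] != "A":
        raise ValueError("motif must have odd length with central A")
    if isinstance(reference, (str, bytes)):
        import pyfaidx

        reference = pyfaidx.Fasta(str(reference))
    half = len(motif) // 2
    keep = []
    for row in table.df.itertuples(index=False):
        if row.chrom not in reference:
            raise KeyError(f"chromosome {row.chrom!r} absent from reference")
        contig = reference[row.chrom]
        start, end = row.pos0 - half, row.pos0 + half + 1
        if start < 0 or end > len(contig):
            keep.append(False)
            continue
        kmer = str(contig[start:end]).upper()
        if row.strand == "-":
            kmer = kmer.translate(_COMPLEMENT)[::-1]
        keep.append(_matches_iupac(kmer, motif))
    kept = table.df[np.asarray(keep, dtype=bool)] if keep else table.df
    return replace(table, df=kept.reset_index(drop=True)).finalize()


# ---------------------------------------------------------------------------
# I/O


def read_calls_table(path) -> pd.DataFrame:
    """Read a per-read call TSV (read_id, chrom, pos0, strand, p_mod).

    Lines starting with ``#`` are treated as headers/comments. Malformed
    rows raise with their 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 tab-separated columns, "
                    f"got {len(parts)}"
                )
            read_id, chrom, pos0, strand, p_mod = parts
            try:
                pos0_i = int(pos0)
                p = float(p_mod)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{path}:{lineno}: p_mod {p} outside [0,1]")
            if strand not in _VALID_STRANDS:
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            rows.append((read_id, chrom, pos0_i, strand, p))
    return pd.DataFrame(
        rows, columns=["read_id", "chrom", "pos0", "strand", "p_mod"]
    )


def write_calls_table(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\tchrom\tpos0\tstrand\tp_mod\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.read_id}\t{row.chrom}\t{row.pos0}\t{row.strand}\t"
                f"{row.p_mod:.6g}\n"
            )


def calls_from_modbam(path, mod_code: str = "a") -> pd.DataFrame:
    """Extract per-read calls from alignments carrying MM/ML base-mod tags.

    Adapter for modified-base-tagged SAM/BAM produced by a modification-
    aware basecaller plus an aligner. ML qualities (0-255 bins) are
    converted to probabilities by the midpoint of each bin,
    ``(q + 0.5) / 256``. Only primary, mapped reads contribute; query
    positions without a reference mapping (insertions/clips) are skipped.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for read in bam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            mods = read.modified_bases
            if not mods:
                continue
            qpos_to_ref = dict(read.get_aligned_pairs(matches_only=True))
            strand = "-" if read.is_reverse else "+"
            for (_canon, _strandflag, code), sites in mods.items():
                if str(code) != mod_code:
                    continue
                for qpos, qual in sites:
                    refpos = qpos_to_ref.get(qpos)
                    if refpos is None:
                        continue
                    rows.append(
                        (
                            read.query_name,
                            read.reference_name,
                            int(refpos),
                            strand,
                            (qual + 0.5) / 256.0,
                        )
                    )
    return pd.DataFrame(
        rows, columns=["read_id", "chrom", "pos0", "strand", "p_mod"]
    )


def write_bedmethyl(table: SiteTable, path) -> None:
    """Write a SiteTable as bedMethyl-style TSV (one row per site).

    Column order is fixed: chrom, start, end(start+1), mod code "a",
    valid_cov, strand, start, end, color, valid_cov, percent modified
    (2 decimals), n_mod, n_canon, 0, 0, n_fail, 0, 0. Counts are
    bit-exact integers; stoichiometry is recomputed from counts on read,
    so the 2-decimal percent column is display-only.
    """
    with open(path, "w") as fh:
        for row in table.df.itertuples(index=False):
            pct = 100.0 * row.f if row.valid_cov > 0 else 0.0
            start, end = int(row.pos0), int(row.pos0) + 1
            fields = [
                row.chrom, start, end, "a", int(row.valid_cov), row.strand,
                start, end, "255,0,0", int(row.valid_cov), f"{pct:.2f}",
                int(row.n_mod), int(row.n_canon), 0, 0, int(row.n_fail), 0, 0,
            ]
            fh.write("\t".join(str(x) for x in fields) + "\n")


def read_bedmethyl(path, sample: str = "", tau: float = 0.99) -> SiteTable:
    """Read a bedMethyl-style TSV written by :func:`write_bedmethyl`."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 18:
                raise ValueError(
                    f"{path}:{lineno}: expected 18 columns, got {len(parts)}"
                )
            chrom, start, end, _code = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if end != start + 1:
                raise ValueError(
                    f"{path}:{lineno}: single-base records required "
                    f"(end={end} != start+1)"
                )
            strand = parts[5]
            if strand not in _VALID_STRANDS:
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            n_mod, n_canon, n_fail = int(parts[11]), int(parts[12]), int(parts[15])
            rows.append((chrom, start, strand, n_mod, n_canon, n_fail))
    df = pd.DataFrame(
        rows, columns=SITE_KEY + ["n_mod", "n_canon", "n_fail"]
    )
    if df.empty:
        df = df.astype({"pos0": np.int64}, errors="ignore")
    return SiteTable(df, sample=sample, tau=tau).finalize()
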