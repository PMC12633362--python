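# Methods

## Measurement model

A modification-aware basecaller emits, for read *i* at candidate site
*s*, a probability p_is that the base is m⁶A. We classify each call with
a dual confidence threshold τ:

* modified (MOD) iff p ≥ τ,
* canonical (CANON) iff 1 − p ≥ τ,
* failed (FAIL) otherwise.

τ defaults to 0.99 and must exceed 0.5 (below that the two confident
classes would overlap). Both boundaries are inclusive: a call exactly at
the pass mark passes. Site stoichiometry is

    f̂_s = n_mod / (n_mod + n_canon)

over the *valid coverage* n = n_mod + n_canon; FAIL calls are excluded
from the denominator by default because they carry no confident class
(a variant including them would only deflate f̂ by an arbitrary factor;
the valid-coverage definition keeps f̂ an unbiased binomial proportion
when the filter is class-symmetric). f̂ is undefined (NaN) at zero valid
coverage. Coordinates are 0-based half-open with explicit strand, and
site tables serialize to an 18-column bedMethyl dialect whose integer
count fields round-trip exactly; stoichiometry is always recomputed
from counts on read, so the 2-decimal percent column is display-only.

Replicates are merged by summing per-site counts — the in-memory
equivalent of pooling replicate alignments before one pileup — and
stoichiometry is recomputed from the sums. Merging requires equal τ.
Duplicate (read, site) observations raise rather than dedupe silently:
they indicate an upstream demultiplexing fault, not data.

Motif masking keeps sites whose strand-oriented k-mer context matches
an odd-length IUPAC motif with central A (default DRACH, the m⁶A
consensus); minus-strand sites are checked against the reverse
complement and sites within half a motif of a contig end are dropped.

## Replicate calibration and the empirical null band

With true stoichiometry f and valid coverages n₁, n₂ in two replicates,
the difference of the two proportion estimates has variance
f(1−f)(1/n₁ + 1/n₂); at equal coverage n the SD is √(2f(1−f)/n).
Bland–Altman agreement summarizes the measured per-site differences
d_s = f̂_B − f̂_A by their mean d̄ and the 95% limits of agreement
d̄ ± 1.96·s_d, with s_d the sample SD (n−1 denominator — the standard
Bland–Altman convention). The fraction of differences inside the limits
is counted directly (bounds inclusive) and reported alongside.

The coverage-threshold sweep recomputes the paired join, Pearson
concordance (R² reported as squared Pearson r) and the limits of
agreement at each minimum-coverage T; the default grid is 0–200 in
steps of 10 plus {25, 50}. Threshold *selection* is advisory, not
automated: `suggest_threshold` flags the smallest T whose half-width is
within 10% of the half-width at the largest T still retaining ≥50
pairs (sparser rows are too noisy to anchor the asymptote), and the
analyst confirms. The pipeline's working convention is a 50-read floor,
which puts the per-site binomial SD at ≤ √(0.25/50) ≈ 0.07.

Pairing excludes sites absent from either table, sites under the
coverage floor in either sample, and — by default — sites with zero
stoichiometry in both samples, which are uninformative about change and
would otherwise pile up mass at Δ = 0. log₂ fold changes are undefined
when either f is 0; the default policy drops those pairs from the
log2FC distribution and reports the dropped count (a pseudocount
option, ε = 0.01, exists but is off by default since no principled ε is
available). The Δ sign convention is B − A (treated − control);
comparisons wanting the opposite sign swap their inputs.

## Differential classification

A control-vs-control Bland–Altman interval measured under the same
coverage floor serves as the empirical null band for Δf. Each paired
site is labeled

* increased iff Δ > loa_high,
* decreased iff Δ < loa_low,
* unchanged otherwise,

with strict inequalities — a difference exactly at the edge has not
exceeded baseline variability. The band is used as published, including
any mean offset, rather than recentred at zero: the offset is itself
part of the measured between-sample variability. Because the band is a
95% interval, an independent null comparison flags ≈5% of sites; that
false-flag rate is a property, not a defect, and the package reports
label counts rather than calling any single flagged site significant.
Comparisons at a relaxed floor (e.g. 10 reads) and comparisons whose
band is borrowed from another experiment (single-replicate designs)
carry explicit warnings in the report notes.

Cross-method comparison against an orthogonal stoichiometry table
(e.g. chemical-deamination data) filters *both* sides to f > 0.05,
because such reference sets only report sites above that floor and an
asymmetric filter would bias the joined set.

## Conversion-based m⁶Am quantification

Conversion chemistry deaminates unmethylated 2′-O-methyladenosine at
the transcription-start nucleotide to inosine (sequenced as G), while
m⁶Am resists. Reads are converted in silico (read1 A→G, read2 T→C) for
alignment against a converted reference — alignment itself is out of
scope; the package consumes aligned start records. Only mate-1 records
without a 5′ softclip whose mapped 5′ end equals an annotated TSS are
counted, since a clipped or internal 5′ end does not anchor the start
nucleotide. The non-conversion rate is r = n_A/(n_A + n_G); other bases
are sequencing error and stay out of the denominator. TSSs under a
50-read A+G floor in a replicate are excluded from that replicate.

With conversion efficiency c < 1, E[r] = f + (1−f)(1−c); the optional
`correct_for_conversion` inverts this (clamped to [0,1]) but is off by
default — raw non-conversion rates are the primary readout, and c is
rarely known precisely. Condition comparison averages replicate-level
rates per snRNA, then runs a paired two-sided t-test (n−1 df) on the
per-snRNA differences of condition means; each annotated TSS gene id is
one pairing unit. Zero-variance differences leave t/p degenerate (p
reported as null with a warning; t = 0 when all differences are zero).

## Dependency screens and viability

Dependency matrices follow the portal CSV layout (rows = cell lines,
columns = "SYMBOL (ENTREZID)"); gene lookup matches the symbol prefix
with an exact-match fallback. A line is dependent iff its dependency
probability is strictly greater than 0.5. Lines with a missing value
for the gene are excluded from numerator and denominator — a line
without a score cannot be classified, which also explains why RNAi and
CRISPR denominators differ per gene in combined releases. Lineage
subsets (e.g. AML) come from an explicit annotation file, not
hard-coded names. MTT viability is
100 · mean(treated absorbance)/mean(control absorbance), requiring a
positive control mean; it is scale-invariant by construction.

## Synthetic data

The nanopore simulator draws, per site: true stoichiometry from
π₀·δ₀ + (1−π₀)·Beta(a, b) with defaults π₀ = 0.3, a = 1.2, b = 2.5 — a
low-skewed distribution with a long right tail, qualitatively matching
transcriptome-wide m⁶A; coverage from a negative binomial with mean 100
and dispersion 10; and per read: modified ~ Bernoulli(f), a confident
call with probability q = 0.95, correct class with probability
1 − ε (ε = 0.002). Call probabilities are uniform within the relevant
band — [τ, 1] for confident-modified, [0, 1−τ] for confident-canonical,
(1−τ, τ) for failed — rather than Beta-shaped, because the downstream
filter only sees the band membership; this keeps the model minimal and
analytically tractable. Randomness is counter-based (global seed +
integer stream keys per replicate and site), so identical configs give
byte-identical outputs regardless of iteration order, and replicates of
one config share the truth while drawing independent reads.

What the simulator deliberately omits: alignment artifacts, positional
or motif-dependent basecaller bias, read-length and poly(A) structure,
correlated errors within a read, and transcript-abundance structure
beyond the coverage distribution. Passing tests therefore demonstrate
that the *statistical* pipeline is correct and calibrated under its
stated measurement model, not that any particular basecaller achieves
ε = 0.002 on real signal.

The conversion simulator draws base counts from a multinomial with
P(A) = (f + (1−f)(1−c))·(1−err), default c = 0.98, err = 0.001,
coverage 1000, three replicates. The dependency simulator gives
designated dependent lines probability ~ U(0.8, 1) and gene effect
~ N(−1, 0.1), others U(0, 0.3) and N(0, 0.1), with 10% of lines
labeled AML in the lineage map.

## Problem sizes and numerical choices

The simulation studies use 2,000 sites at mean coverage 100 for
estimator recovery, 5,000 sites at fixed coverage 100 for null-band
geometry, 10 seeds × 1,200 sites for the threshold-sweep medians, and
10 seeds × 5,000 sites for the null flag rate — sizes at which the
binomial-theory comparisons have comfortable Monte-Carlo margins while
the whole study runs in seconds. Ties at classification boundaries are
resolved by the strict-inequality rule above; degenerate inputs
(constant vectors, <2 differences, <3 pairs, zero valid coverage)
return explicit nulls with warnings rather than NaN propagation.

## Known limitations

Stoichiometry is per genomic site, not per isoform; sites on
overlapping transcripts are aggregated. The null band is
coverage-dependent — a band calibrated at a 50-read floor is
anti-conservative for lower-coverage comparisons, which is why the
relaxed 10-read mode warns loudly. The modified-base-tag alignment
adapter reads MM/ML-style tags via pysam and converts 256-bin qualities
to probabilities by bin midpoints, which quantizes p near the 0.99
threshold by ±0.002. Real-screen analyses depend on the user supplying
the (large) portal release files; the package ships only the layout
logic and a simulator for it.
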