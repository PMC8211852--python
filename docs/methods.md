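# Methods

This note documents the models behind each module, the defaults and why,
what the synthetic cohorts do and do not emulate, and the numerically
delicate choices. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic Hi-C cohorts (`neoloopscan.simulate`)

A cis contact map is generated from a multiplicative intensity on bin
pairs:

    E[count(i,j)] ∝ decay(|i−j|) · compartment(i,j) · tad(i,j) · loop(i,j)

with `decay(d) = (d+1)^α` (default exponent α = −1, the canonical
power-law of polymer contact frequency; the +1 caps the diagonal so no
pixel diverges). The compartment factor is a symmetric checkerboard:
`strength` when two bins share an A/B label, `1/strength` otherwise. TADs
multiply their intra-domain block, loops multiply a single pixel. Counts
are Poisson-sampled per bin pair at a target cis depth and emitted as
pairs-format records at bin midpoints, so re-binning at the generation
resolution is exact and coarser re-binning conserves totals. All
randomness flows from one root seed through derived per-sample streams;
identical seeds give byte-identical cohorts.

Rearrangements add junction contacts: a bin at derivative-distance `da`
bins from breakpoint A and `db` from breakpoint B receives expectation
`clonal_fraction · A0 · (da+db+1)^−1`, where `A0` is the sample's own
diagonal amplitude — the fused fragments behave as one contiguous
chromosome in the rearranged cell fraction, which is exactly the signal
the reassembly step later exploits. Neo-loops multiply single junction
pixels. Chimeric junction reads place both segments on the exact
breakpoints with the bridge-linker flag false; religation decoys are
uniformly placed with the flag true, exercising the linker filter.

Fusion geometry: an event is `(chrom_a, bp_a, flank_a) + (chrom_b, bp_b,
flank_b)`. Fragment A keeps its `flank_a` side and must end at `bp_a`
(so a kept right flank is reverse-oriented); fragment B starts at `bp_b`
(a kept left flank is reverse-oriented). The four flank combinations
therefore enumerate all two-fragment orientations; "inverted" is the
derived property that one fragment is reverse-oriented, and an
intra-chromosomal event with a reverse-oriented fragment is an inversion
junction.

What the simulator does **not** emulate: restriction-fragment structure,
read-level sequences, mappability/GC coverage bias (so KR balancing is
near-neutral on synthetic maps), trans background contacts away from
junctions, sub-compartments, and biological (super-Poisson) between-sample
variability of structure strength. Passing planted-truth tests therefore
demonstrates correctness of the estimators under the stated generative
model, not robustness to artifacts real maps may carry.

Simulation scales (chosen once as field-realistic desk-scale conditions):
per-sample maps use 1–5 × 10⁶ cis contacts on 12–50-Mb toy chromosomes,
the within-region equivalent of a few-hundred-million-read-pair genome-wide
library; pooled-condition analyses (loop calling) use 10⁷. Differential
cohorts are 4 vs 4 samples; the bundled demo is 2 vs 2.

## Contact matrices (`neoloopscan.matrix`)

Internal coordinates are 0-based half-open bins; pairs text is 1-based,
BED 0-based (conversion happens only at I/O). Binning uses
`(pos−1)//binsize`, folds pairs to canonical orientation and conserves
totals exactly.

KR balancing implements the Knight–Ruiz inner–outer Newton iteration with
a Sinkhorn fallback if Newton stalls; weights are scaled so balanced row
sums equal 1, which makes the 2×2 closed form exact and gives the scale
equivariance `w(cM) = w(M)/√c`. Defaults: relative row-sum tolerance
1e−6, 300 outer iterations. Bins with zero marginal, or marginal below the
1st percentile of nonzero marginals, are masked first; the percentile cut
carries a 1e−4 relative slack so an already balanced matrix (all marginals
tied at 1 within tolerance) is not re-masked — without it, re-balancing is
not idempotent.

Expected-by-distance is the mean (optionally balanced) value per diagonal
offset over unmasked pairs. Cross-sample comparison scales each matrix by
`target / cis_total` (default target 10⁶).

## Compartments (`neoloopscan.compartments`)

Per chromosome: observed/expected → Pearson correlation matrix over
unmasked bins → leading eigenvector. The eigenvector sign is arbitrary, so
it is oriented against a user-supplied per-bin activity proxy (the
simulator provides gene density; on real data any proxy such as gene
density or accessibility works) — GC content is deliberately not assumed.
Positive → A. Consensus per group is a strict majority: label A (or B)
only when the agreeing sample fraction strictly exceeds 0.7 ("over 70%"
read literally; the threshold is a parameter). Bins masked in ≥50% of
samples are dropped; switches are only called between bins labeled A or B
in both groups.

## Domains (`neoloopscan.domains`)

Insulation at bin i is the mean of the w×w square of upstream×downstream
bins (window 1 Mb → w = 25 at 40-kb bins), log2-scaled to the chromosome
mean (the "mean" metric). The delta track is mean(left 200-kb span) −
mean(right span); a boundary is a downward zero crossing of delta, placed
at the insulation minimum of the crossing pair, kept when the local delta
amplitude (max over the left span minus min over the right span) exceeds
the noise threshold 0.1.

The per-sample relative insulation value at a merged boundary — needed for
the cross-sample t-test — is defined as that sample's delta amplitude at
the boundary bin. (The boundary-scoring tool this mirrors does not print
its formula; this explicit substitute is validated against planted truth
only.) Boundaries within 1 bin merge to the position with maximal pooled
strength. Differential boundaries: two-sided Welch t on the per-sample
amplitudes, BH FDR < 0.01, plus |group difference| above the median of all
boundaries' |differences|.

Consensus TADs are delimited by boundaries detected in ≥2 conditions;
domains shorter than 3 bins are discarded (minimum size is a package
choice). The domain score is `intra / touching` on raw counts (diagonal
counted once; the ratio is scale-invariant, so raw vs balanced is
immaterial on synthetic maps; a flag exposes balanced counts).
Differential D-scores: Welch t, BH FDR < 0.01, |log2 FC| above its 70%
quantile, direction = sign of the case/control ratio.

## Loops (`neoloopscan.loops`)

Calling is a four-background local-enrichment scheme: donut (outer radius
5, inner 2 bins), lower-left quadrant, horizontal and vertical 3-wide
stripes. Each background's expectation is the decay expectation at the
pixel rescaled by the neighborhood observed/expected ratio; the Poisson
tail is taken against the most conservative (largest) background.
Decisions: count ≥ 4, observed > 1.75× donut and lower-left, > 1.5× the
stripes, and BH q < 0.1. Two numerically load-bearing choices:

- **BH universe.** The correction runs over *all* pixels in the tested
  distance band (here up to 3 Mb), not only pixels passing the enrichment
  pre-filter. Correcting only pre-selected candidates is strongly
  anti-conservative (selection inflates significance); the band-wide
  correction keeps null maps clean.
- **Count quantum.** Poisson inference needs genuine counts. If every
  entry is an integer multiple of the smallest nonzero entry (as after any
  global rescaling), that quantum is divided out first. This makes the
  call set exactly invariant under global scaling `c·M` and keeps
  depth-normalized inputs honest; heterogeneously re-weighted (balanced)
  values are left as-is.

Merging collapses calls within the merge distance (15 kb at 5-kb bins,
20 kb at 10-kb) to the strongest pixel; a coarse-resolution call within
the coarse merge distance of a finer call is absorbed by the finer one.

APA sums observed/expected submatrices (flank 10 bins) over loops at least
flank+2 bins off the diagonal, divides by the contributing count, and
scores center / mean of the four 3×3 corner blocks.

Differential loops: per-sample strength is the 3×3 anchor-neighborhood sum
on cis-depth-normalized maps, tested on log(x+1) within the <150-kb and
>150-kb strata with BH FDR < 0.1 per stratum. The test is a **moderated
t**: per-loop variances at n = 4 vs 4 are too unstable for a plain Welch
test (planted 2× gains went largely undetected), so variances are shrunk
toward the stratum mean with prior df 20 — the same information-sharing
idea the count-model differential callers this step follows use. The
permutation-null flagged fraction stays at the nominal level (tested).

CTCF orientation: per anchor, the highest-scoring stranded motif within
anchor ± pad; convergent = upstream +, downstream −. For loops on
reassembled maps, motif strands inside reverse-oriented fragments are
flipped before classification. Summary fractions are reported over both
denominators (loops with motifs at both anchors, and all loops), since the
field convention varies.

## Rearrangements (`neoloopscan.rearrangements`)

Block detection is a deliberately simple coarse-to-fine scan (not a port
of the iterative-expected breakfinder): per chromosome pair the expected
trans intensity is the pair's own uniform background; 1-Mb blocks with
observed/expected ≥ 5 and BH-corrected Poisson tail < 0.01 are refined to
the enriched fine pixels (searching one coarse block beyond the boundary,
so hot pixels straddling it are kept) and merged when adjacent. Any block
overlapping a significant block in any control is flagged
`control_present` and excluded downstream.

Refinement keeps linker-free reads whose segments fall within the block ±
500 kb, takes the modal exact coordinate pair, and requires support
strictly greater than 3 ("more than three" read strictly; parameter).
Flanks come from the majority segment strands (`+` on A ⇒ left flank,
`+` on B ⇒ right flank); a strand tie leaves the candidate unrefined
rather than guessing.

Reassembly extracts the two fragments (default flank 4 Mb, clipped at
chromosome ends, snapped to bin boundaries), reverses fragments whose kept
flank points away from the junction, and pushes cis and trans contacts
through the coordinate transform — a bijection on the covered intervals
(property-tested, including reverse-oriented fragments). The
`junction_continuity` statistic (Pearson correlation of junction-crossing
pixels with the contiguous-decay model within a 30-bin band) identifies
the true fusion configuration among the alternatives.

Neo-loop detection runs the loop caller on the reassembled matrix, keeps
junction-spanning calls, and requires ≥2× enrichment over the control
average mapped through the same transform (scaled to the sample's total).
The 2× default substitutes for what was historically a manual curation
step; when the control is empty at a pixel the comparison is skipped and
the call flagged `control_comparable=False`. Anchors are mapped back to
native coordinates and flagged for overlap with pre-existing loop anchors
and CTCF sites.

Annotation: nearest gene and distance per breakpoint (0 inside a gene
body ⇒ coding), novelty iff no known breakpoint within 100 kb on the same
chromosome, compartment label at the breakpoint bin, and expression status
of the nearest gene (up iff FPKM > 1 and ≥ 2× the control mean; down
symmetric).

## Integration (`neoloopscan.integration`)

Virtual 4C is the depth-normalized matrix row at the viewpoint bin (10-kb
default grid); group profiles are sample means and the difference track is
group1 − group2. Region scores are means over region bins (robust to
region length; a sum would conflate length with signal), compared by Welch
t with BH over regions.

Per-gene structural p values (D-score, loop strength) combine by Fisher's
method (χ², 2 df per component; a missing component passes the other
through); Stouffer is available as a parameter since the combination
method is a genuinely open choice. The signed structural score is
−log10(combined p) × direction sign, and its Pearson correlation with
expression logFC is the structure–expression summary.

DEG association: genes failing the read filter (strictly more than 20% of
samples below 5 reads, or mean reads < 2 — the ambiguous filter sentence
is resolved this way and parameterized) are dropped; DE requires FDR <
0.01 and |FC| > 2. Structure attaches by gene-body bin overlap (majority
label) for compartment switches, TSS-containing TAD for D-scores, and
promoter-window (TSS ± 5 kb) anchor overlap for loops. Each class with ≥3
members is tested against structurally stable genes by a one-sided
Wilcoxon rank-sum test in its expected direction (B-to-A / increased /
enhanced ⇒ up; the mirror classes ⇒ down; boundary changes two-sided).

## Pipeline (`neoloopscan.pipeline`)

One JSON config drives simulate → matrices (+KR) → compartments → domains
→ loops → SV/neo-loops → integration. The manifest records per-stage input
and output SHA-256 checksums, wall time and the seed; a completed stage
with unchanged inputs is skipped on rerun, and identical config + seed
reproduce identical output checksums (tested). The expression stage
computes logFC/p/FDR from the simulated table with a Welch t on log2 FPKM
— on real cohorts a dedicated DE table (e.g. from a count-model caller)
should be supplied instead; only the thresholds and filters are applied
here.

## Known limitations

- The Poisson pixel test assumes independent counts; real Hi-C has
  correlated neighboring pixels and over-dispersion, so FDRs on real data
  are approximate.
- Only two-fragment derivatives are modeled; multi-way rearrangements and
  CNVs are out of scope.
- The clonal fraction of patient rearrangements is unknown in general; the
  simulator exposes it as a free parameter and detection is exercised down
  to 0.5.
- Compartment orientation needs an activity proxy; with a misleading proxy
  the A/B labels (not the eigenvector) would flip.
- Block detection's uniform trans background is appropriate for the
  simulator's translocation-only trans structure; real maps with strong
  trans territories may need the iterative expected model of dedicated SV
  callers.
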