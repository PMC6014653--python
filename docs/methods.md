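# Methods

This note documents the models, the numerical choices and the synthetic-data
conditions the package is validated under, and what its passing tests do and
do not establish about real data.

## Craniometric affinity

Groups are rows of a table of mean measurements (mm) over a fixed 16-variable
panel (Martin numbers M1, M8, M9, M17, M43(1), M43c, M45, M46b, M46c, M48,
M51, M52, M54, M55, M57, M57a). Each column is z-standardized across the
groups present in the loaded table (mean 0, unit variance, `n−1`
denominator); the Q-mode correlation between two groups is the Pearson
correlation of their standardized 16-vectors across measurements, and
`d = 1 − r` is the network distance. Design choices, stated because the
method is often cited without them:

- The standardization population is *all groups in the table*. Subsetting the
  table changes the z-scores and hence the affinities; users comparing
  against a published matrix should load the same group set.
- Correlation is computed between groups across measurements (Q-mode), not
  between measurements across groups (R-mode).
- Groups with any missing panel cell are excluded with a warning by default;
  column-mean imputation is available behind an explicit flag. No
  sample-size weighting is applied to group means.
- A zero-variance column is an error naming the offending code, not a silent
  drop: it would make the z-score undefined.

Affinity is affine-invariant per measurement (scale/location changes of a
column cancel in the z-scores); this is property-tested.

## NeighborNet

The circular ordering is built by the standard agglomeration: clusters hold
one or two active nodes; the cluster pair to merge minimizes
`(m−2)·d(A,B) − R(A) − R(B)` on cluster-averaged distances; which nodes link
across the chosen pair minimizes the same criterion over the mixed entity
set (other clusters plus the individual nodes of A∪B); merged paths are
reduced three nodes at a time with the weights 2/3–1/3 reduction formulas,
and unwinding the reduction stack yields the ordering. Tie-breaks take the
lowest-index pair, and orderings are canonicalized by placing the
lexicographically smallest taxon first with its smaller neighbour second, so
reruns and taxon permutations give identical output.

All `n(n−1)/2` splits whose one side is a contiguous arc of the ordering are
candidates; weights solve `min ‖Aw − d‖², w ≥ 0` by Lawson–Hanson NNLS
(`scipy.optimize.nnls`, iteration cap `10·n_splits`). Splits below 1e−9 are
dropped — numerical zero, deliberately *not* a display filter. Verified
properties: exact reconstruction (≤ 1e−8) of circularly decomposable
distances; on additive metrics the nonzero splits equal the
neighbor-joining tree's bipartitions with branch-length weights (scikit-bio
NJ as the independent oracle); perturbing any positive weight by ±1e−4 never
reduces the residual. The Nexus writer emits TAXA and SPLITS blocks
(CYCLE + weighted splits) with deterministic record order; drawing/layout is
out of scope.

## Mitochondrial model

Coordinates are 1-based on a circular reference. Variants use anchor
notation (`C150T`; insertions `T310TC`; deletions `GCA513G`), and alignment
diffs left-align indels through repeats (VCF-style), with a floor that keeps
successive tokens non-overlapping. Whole-genome diffs use edlib global
alignment.

The bundled reference is a deterministic synthetic 16,569 bp sequence (fixed
seed, ~44% GC), *not* the genuine rCRS; the bundled demo haplotree treats
that reference as the root state. Macrohaplogroup diagnostics sit at their
published coordinates (N: 8701, 9540, 10398, 10873, 15301; R: 12705, 16223;
M: 489, 10400, 14783, 15043) with alleles derived from the synthetic
reference; all other defining variants are synthetic placeholders. Genuine
rCRS polarity (in which the reference itself sits inside R) is intentionally
not modelled; a real PhyloTree import is supported as a TSV format but not
bundled.

Haplogroup assignment scores each node as
`matched − penalty·missing` over its root-to-node defining variants
(`penalty = 1`), assigns the argmax, breaks ties toward the shallower node
with an ambiguity flag, and reports unexplained variants as extras. A path
diagnostic absent from the call set counts as missing — the back-mutation /
masked-site convention. The APLP caller descends the tree only through nodes
positively supported by a covered derived panel allele and stops at any
contradiction; no coverage of any non-root node yields `N.D.` (both
amplification failure and ambiguous patterns map to `N.D.`).

## Read pipeline

Thresholds (defined once in `PipelineConfig`): merge quality 25, merged
length ≥ 35, mapq ≥ 20, pileup base quality ≥ 30, consensus depth ≥ 3,
masking above 30% mismatch (a site at exactly 30% is still called),
contamination length cutoff 40.

Merging locates the mate overlap by shared 12-mers, scores it by matches
minus mismatches (accepting ≥ 11 bp overlaps with ≥ 75% identity), keeps the
higher-quality base at conflicts (quality `|q1 − q2|`) and the max quality
at agreements, then trims terminal Ns and sub-threshold bases. How many
bases such trimming removed from each end is recorded, because a trimmed
terminus no longer exposes the molecular fragment end (the damage modules
skip those termini).

The mapper seeds 13-mers every 7 bases on both strands against the doubled
(circularized) reference, extends candidates with edlib, scores alignments
(+1 match, −1 mismatch, −2 gap open, −1 extend), and assigns mapping quality
37 to a unique best locus, 0 to ties — a declared simplification whose only
relevant behaviour is its interaction with the mapq ≥ 20 filter. Gaps within
3 bases of a read end are realigned as substitutions: edit-distance
alignment ties terminal substitutions with terminal indels, and resolving
toward indels would strip reference context off exactly the bases carrying
the deamination signal. The two-stage nuclear-then-mitochondrial remapping
of full aDNA workflows is deliberately replaced by direct mitochondrial
mapping: there is no nuclear decoy at this scale.

Duplicates share (start, end, strand) — merged single-end semantics — and
the highest summed base quality survives. Consensus indels are called at
≥ 50% of covering reads and depth ≥ 3. The mismatch-fraction denominator is
Q30-passing bases, matching the pileup definition. Masked-site rescue
re-reads haplotree-diagnostic SNP positions that were masked: if the pileup
majority at such a position equals the derived allele (depth ≥ 1) the
variant is restored, mirroring the manual re-identification step of ancient
mtDNA workflows; non-diagnostic masked sites stay masked.

## Damage and contamination

The deamination model is `d(i) = D·κ^i + ε` for C→T at 5' offset `i` and,
double-strand library symmetry assumed, G→A mirrored at the 3' end.
Profiles, PMD-style scores (per-read log likelihood ratio of damage vs
error-only; strand-symmetric by construction) and the estimators all work in
read orientation so both strands contribute. Positions where the sample's
own consensus differs from the reference are excluded from damage contexts —
real variants otherwise masquerade as a flat "damage" floor.

Contamination is estimated from reads of length ≥ 40 as a two-component
mixture fit by maximum likelihood and refined by EM:

- the endogenous component damages each terminal context at `D·κ^i + ε_e`;
- the contaminant component shows a flat floor `ε_c` (its own private
  variants inflate it slightly above the endogenous `ε_e`, which is why the
  floors are separate parameters);
- fragment length enters as a second channel, because undamaged modern
  contaminants are typically longer than endogenous ancient fragments — the
  same argument used to dismiss a contaminant lineage by the lengths of its
  carrier reads. To keep the mixture identifiable the channels are
  asymmetric: the endogenous length density is a fixed nonparametric
  plug-in (smoothed histogram over reads carrying terminal damage at
  offsets 0–2, an almost purely endogenous subset since damage and length
  are independent within a class, corrected for the small contaminant
  leakage into that subset), while the contaminant length component is a
  parametric lognormal fit jointly with the mixture weight. Leaving both
  densities free would let any shape misfit masquerade as a phantom
  component. With negligible contaminant mass, or indistinguishable length
  distributions, the refit reduces to the damage-only estimate.

The background floor is initialised from deep interior offsets (12–24),
where decayed damage is negligible. The 95% interval is a nonparametric
bootstrap over reads (500 resamples) refitting the mixture weight with the
components held at their point estimates; reports round to 0.5% steps
(`6.5% [4.5–8.5%]`). Because the components are not re-estimated per
resample, the interval understates the full uncertainty when read counts
are low — at a few thousand usable fragments the point estimate itself
carries roughly ±5–10 percentage points, tightening to a point or two by
~20,000 fragments. Fewer than 200 terminal C/G contexts is an
insufficient-data condition, not an estimate. This estimator deliberately
replaces iterative Bayesian consensus-based schemes with a transparent
single-pass likelihood; consensus-based second-stage estimation is out of
scope.

The variant-read-length flag partitions reads covering a site into carriers
of the alternate allele, damage-authentic reads (a C→T/G→A within 3 bases of
either terminus), and the rest; it fires when carriers' mean length exceeds
the damaged reads' by > 20% with a one-sided rank-sum p < 0.05. The 20%
margin is a declared default for a judgement the source workflows made
qualitatively.

## Radiocarbon

`L(t) = exp(−(m−μ(t))²/(2(s²+σ(t)²)))/√(s²+σ(t)²)` on the curve's 1-year
interpolated grid, normalized to sum 1. HPD ranges accumulate grid cells by
decreasing density until ≥ 95.4%, merge contiguous runs, and report
(older, younger) intervals oldest-first; multi-modal regions give multiple
intervals, and table summaries report the outer envelope for comparison with
single printed ranges. Calibration software internals (rounding,
normalization conventions) are not replicated; a ±10-year agreement band
against published single ranges is the declared contract, absorbing their
1-vs-5-year rounding. The genuine IntCal13 file is an optional external
input; bundled tests run on analytic synthetic curves (identity curve →
Gaussian posterior; sinusoidal wiggle → disjoint HPD intervals).

## Synthetic data: what it emulates, and what it does not

Craniometric tables: group mean = `α·μ_B + (1−α)·μ_A` plus between-group
drift (SD 1 mm) and within-group sampling noise (SD 4 mm / √n, n = 20).
The ancestral means are plausible Martin-measurement magnitudes (M1 ≈ 180 mm
…) with a few-mm layer contrast; all recovery logic uses generator truth,
never these constants. Default: 10 populations, half per layer.

Reads: fragment starts uniform on the circle, lengths lognormal (median
60 bp, σ = 0.35, minimum 35 — "very short" ancient-fragment conditions),
truncated at `2·read_length − 12` so every pair collapses; strands
randomized; damage applied per the model above (defaults D = 0.3, κ = 0.5,
ε = 0.01); contaminant fragments drawn undamaged from a second genome with
a longer length model (median 120 bp); adapters appear by read-through;
qualities are Phred 37 with 1% of bases at 20 (so the Q30 filter is
exercised) and substitution errors drawn at the quality-implied rates.

Not emulated: mappability/NUMT artefacts, index hopping between libraries,
UDG treatment, strand-specific library chemistry beyond the double-strand
symmetry, reference bias, heteroplasmy. Tests passing on this generator
therefore validate the algorithmic contracts, not performance on real
capture data.

Problem sizes used by the test suite and the acceptance script — 20,000
fragments for estimator grids, 50 end-to-end runs at 20× over the 16.6 kb
reference, 100 seeded craniometric tables of 10 groups — are desk-scale
choices that keep each statistical check well-powered while a full run
remains a few minutes on one core.

## Known limitations

- The mapper is not a general short-read aligner: no affine-gap DP over the
  whole reference, no base-quality-aware scoring, a two-valued mapq.
- The contamination estimator assumes contaminants are undamaged; a
  deaminated ancient contaminant (e.g. cross-sample hopping) would be
  absorbed into the endogenous component.
- The demo haplotree is a teaching-scale stand-in; calls on real data
  require a genuine haplotree import and the genuine rCRS.
- Q-mode affinities depend on the comparative group set; the package makes
  that explicit rather than hiding it.
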