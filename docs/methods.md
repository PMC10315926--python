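# Methods

## Quantification model and normalization

A 6-plex TMT experiment measures, for every protein group and biological
replicate, six corrected reporter intensities — one channel per strain (wild
type plus five knockout mutants), with the channel-to-strain assignment
rotated between replicates to decouple label bias from strain identity. A
protein enters the analysis if it carries quantitative information (nonzero
WT intensity and at least one nonzero mutant intensity) in at least *k*
replicates (default *k* = 2); decoy and contaminant rows never do.

Per replicate, the raw ratio of a protein in mutant *m* is its *m*-channel
intensity divided by its WT-channel intensity. Because the six samples are
pooled at an equal ratio before MS, the bulk of these ratios must sit near
1; each replicate × mutant ratio vector is therefore divided by its
arithmetic mean, which recentres the slice at exactly 1 (asserted to 1e-9).
The arithmetic mean of linear ratios — rather than a median or a
log-space mean — is used deliberately: it is the estimator implied by the
equal-mixing argument. Cells with a zero WT or mutant intensity are
missing, never imputed; the ≥ *k*-replicate rule is the sparsity control.

Replicate agreement is summarized as the squared Pearson correlation of
log₂ intensities per strain over proteins quantified in both members of a
pair (a log-ratio variant is available via a switch; which scale the
convention refers to is genuinely ambiguous, and log-intensities are the
stricter check since they are not shared-denominator correlated).

## Empirical fold-change threshold

Let *m* = max(*r*, 1/*r*) be the fold-change magnitude of a normalized
ratio *r*. If a fraction F(t) of all magnitudes (pooled over proteins,
mutants, replicates) lies below a candidate threshold *t*, then — under the
assumption that the bulk of the proteome is unchanged — calls beyond *t*
carry an estimated false-discovery rate of 1 − F(t). `derive_threshold`
exposes both directions of this duality: the FDR estimate at a given *t*,
and the smallest *t* on the grid {1.01, 1.02, …, 3.00} whose exceedance is
at most a target *q*. The magnitude convention counts a ratio of 1/1.4 as a
1.4-fold change; a signed variant (literal "ratios smaller than t") is
available by flag. The 2-decimal grid matches the reporting precision of
thresholds like 1.30.

## DEP calling

For each protein × mutant with coverage ≥ 2, the log₂ normalized ratios
across replicates are tested against 0 with a two-sided one-sample
Student's *t*-test; the replicate-aggregated fold change is the mean of the
log₂ ratios (geometric mean on the linear scale; a median switch exists
because targeted-peptide summaries conventionally use medians). A protein
is a DEP iff *p* < α **and** max(FC, 1/FC) > *t* (defaults α = 0.05,
*t* = 1.3). The one-sample-on-ratios form was chosen over a two-sample test
on intensities because the entire downstream analysis is phrased in
mutant/WT ratios; a switch is not offered since the two-sample form would
also need its own normalization path. No multiple-testing correction is
applied by default, matching the raw-α convention of the thresholds above;
Benjamini–Hochberg is available (`bh=True`, via
`scipy.stats.false_discovery_control`). Identical replicates (zero sample
variance) get *p* = 1 at mean 0 and *p* = 0 otherwise; proteins below
coverage are reported *untested*, which downstream consumers must not
conflate with "not significant".

## Overlap, network, clustering

Venn accounting assigns each protein in the union of the five DEP sets to
the region given by its exact membership signature; region counts therefore
sum to the union size by construction, and the test suite checks every
instance against an independent brute-force enumeration. The regulatory
network places the five knocked-out regulators as hubs and connects each to
its DEPs, keeping only proteins differentially expressed in ≥ 2 mutants;
edges carry the direction and log₂ fold change.

Sample clustering operates on the protein × (strain × replicate) matrix of
log₂ intensities: each replicate channel is scaled to equal mean intensity
over retained proteins (equal-loading normalization), and each protein row
is z-scored across the 18 sample columns. Agglomeration is
average-linkage on Euclidean distances (the common default in
Perseus-style workflows; both are configurable), with columns sorted
lexicographically beforehand so ties break deterministically. The tree is
cut at the number of strains and summarized by cluster purity (fraction of
samples agreeing with their cluster's majority strain). The pipeline
clusters on the DEP union by default: with a planted-truth generator, the
null proteins carry nothing but noise, and distances accumulated over ~1800
noise rows would swamp the between-strain signal carried by a few hundred
informative rows. Real proteomes are pervaded by sub-threshold regulation,
so this is a property of the synthetic truth model, not of the method;
clustering on all rows is one flag away (`cluster_on_deps=False`).

## Enrichment

One-sided (over-representation) Fisher's exact test: for a DEP set of size
*n* from a background of *N* quantified proteins, a term annotating *K* of
them and *k* of the DEPs, *p* = P(X ≥ *k*) for X ~ Hypergeometric(N, K, n),
computed with `scipy.stats.hypergeom.sf`; the enrichment factor is
(k/n)/(K/N) and a term passes at *p* < 0.05 and EF > 1.5. The background is
the set of proteins passing the ≥ *k*-replicate filter — the universe the
test statistic was actually computed on; using all identified proteins
instead would inflate enrichment of well-quantified categories. Up- and
downregulated sets are disjoint by construction and tested independently.

## PRM occupancy

Peptide abundance is the summed peak area of its (≤ 6) transitions.
For the occupancy of one phosphosite in two conditions A and B, write
*a*, *b* for the occupancies and P_A, P_B for total protein. The
phosphopeptide pool is proportional to occupancy × protein, the
unmodified-counterpart pool to (1 − occupancy) × protein, with a common
(unknown) response factor per peptide species that cancels in A/B ratios:

    x = a P_A / (b P_B),   y = (1 − a) P_A / ((1 − b) P_B),   z = P_A / P_B.

Eliminating P_A/P_B: a = (x/z) b and 1 − a = (y/z)(1 − b), hence

    b = (y − z) / (y − x),   a = (x / z) · b,

the unique inverse of the model, degenerate exactly when x = y (no
contrast). All counterpart peptides, including miscleavage forms, are
summed before the ratio is formed (summing, not averaging, is what makes
the response factors cancel for a pool measured by the same instrument
settings). The total-protein ratio *z* is an opaque scalar input
(immunoblot-derived); how it was normalized upstream is outside the model.
With matched replicate counts the occupancies are solved per replicate and
summarized as mean ± SD, matching the error-bar convention of targeted
assays; estimates are clipped to [0, 1] with the pre-clip range check kept
as a flag, since out-of-range solutions diagnose inconsistent inputs.

## Synthetic-data generator

The generator is the test bed: it emulates the study design with known
truth, so recovery can be measured exactly.

- **Proteome**: `n_proteins` = 2000 (the order of a quantified
  cyanobacterial proteome), abundances log-normal with log₂ mean 20 and
  sd 2 (~4 orders of magnitude, reporter-intensity scale ~10⁶).
- **Planted truth**: a region plan maps mutant subsets to exact counts;
  the default plants 4 proteins shared by all five mutants plus
  11/60/14/25/97 mutant-specific ones (the overlap skeleton of the
  motivating panel). Effect sizes are uniform on log₂ magnitude [1.0, 2.5]
  (≥ 2-fold — clearly above the 1.3 threshold, as expected of true
  regulatory targets), sign shared across mutants within a region.
- **Reporter noise**: multiplicative log-normal per channel, the standard
  model for reporter ions (scale-free in ratios). The default channel
  sigma (0.1335 in log₂) is calibrated so that a null protein's mutant/WT
  ratio — the difference of two channel noises — has the spread observed in
  practice: ~95.5% of fold-change magnitudes below 1.3. This one number
  couples the generator to the threshold analysis; everything downstream
  (replicate R² ≈ 0.99, DEP power, cluster purity) follows from it.
- **Co-isolation interference**: observed_c = (1 − f)·signal_c +
  f·mean(signal), a convex mixing of each channel with the pooled
  channel mean of the same spectrum. This is the simplest mechanism that
  conserves total signal and reproduces the monotone compression of
  isobaric ratios toward 1 (a 26-fold change reads below 10-fold at
  f = 0.3). Default f = 0: the recovery benchmarks are defined without
  compression, which is studied explicitly by varying f.
- **Labeling reshuffle**: a cyclic rotation of the strain → channel map per
  replicate — the alternating-order idea without committing to an
  unspecified exact pattern.
- **PRM scenario**: occupancies (0.70, 0.04) for the two conditions and a
  total-protein ratio of 1.5, chosen so the implied phosphopeptide ratio is
  (0.70/0.04)·1.5 = 26.25, the ~26-fold regime of the motivating assay.
  Transition areas split a peptide's pool over 6 fixed fractions with
  log-normal noise at 5% CV (mean-one parametrization, so expectations are
  unbiased).
- **Seeding**: one global seed; every stage draws from a named substream
  (`SeedSequence(seed, spawn_key=hash(stage))`), so each table is
  reproducible independently of generation order.

What the generator does **not** emulate: peptide-level variation and
roll-up, isotope-impurity cross-talk between channels, missing-value
mechanisms beyond optional uniform dropout, intensity-dependent variance,
batch effects between replicates, or sub-threshold pervasive regulation.
Passing recovery tests therefore demonstrates correctness of the analysis
logic under the stated noise model, not robustness to every pathology of
real reporter-ion data.

## Numerical choices and degenerate inputs

- Normalization and z-score invariants are asserted to 1e-9; the occupancy
  round-trip to 1e-10; Fisher p-values agree with an exact
  integer-arithmetic tail sum to < 1e-10 for all tables with N ≤ 60.
- Threshold grid {1.01, …, 3.00}; exceedance is non-increasing in *t*, so
  the smallest qualifying grid point is well defined.
- Zero-variance guards: constant replicate vectors in the *t*-tests (p ∈
  {0, 1} by mean), constant columns under correlation distance (dropped),
  zero-SD rows before z-scoring (dropped).
- File round-trips parse floats with `float_precision="round_trip"`, so
  write → read → write is byte-identical.

## Problem sizes

Defaults were chosen to mirror the study design at full scale (2000
proteins × 6 channels × 3 replicates); simulation-based checks average over
20 seeds for threshold calibration and DEP operating characteristics, 10
seeds for noisy occupancy recovery. The whole acceptance computation runs
in seconds on one core.

## Known limitations

- The FDR estimate from the ratio distribution assumes the bulk is null;
  with many large true changes it is conservative-biased upward (visible in
  the worked example: 7.3% at t = 1.3 on planted data versus 4.5% on a pure
  null).
- The network is descriptive (hub membership only), not an inferred
  regulatory graph.
- Enrichment treats terms as flat labels; no ontology propagation.
- The occupancy model assumes exactly one modified site per counterpart
  pool and no other modifications redistributing the peptide forms.
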