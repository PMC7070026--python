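# Methods

## Positioning statistics

For a focal base, `d_i` is the absolute distance to each MNase-seq fragment
midpoint with `|midpoint − site| ≤ 95` (closed bound; 95 bp is half the
~191.4-bp nucleosome repeat length, so the window spans one nucleosome's
worth of midpoints). `d_mean` is their mean, `d_var` the sample variance
(n−1 denominator). With no midpoint in the window the statistics are
*missing*, never 0; with one midpoint `d_var` is missing. A site is usable
when it has ≥10 midpoints and, if a mappability track is supplied, a
mappability value ≥90 at the focal base — the filter is applied per base,
with the window option left to the caller, because a per-base rule is the
minimal interpretation of a regional filter.

Two implementations exist: `site_positioning_stats` (per site, sorted-array
slice) and `batch_positioning_stats` (prefix sums over the sorted midpoint
array, used at genome scale). The per-site path is verified against a
brute-force full-scan oracle; the batch path is verified against the
per-site path to 1e−8.

`d_mean` is binned into the five categories `[0,18] [19,36] [37,54] [55,73]
[74,95]`. The printed integer intervals leave gaps for real-valued means;
we map `d_mean` to bin k iff `d_mean ∈ (upper(k−1), upper(k)]` with
`upper = (18, 36, 54, 73, 95)`, which reproduces the integer behaviour and
assigns e.g. 18.5 to bin 2.

Fragment midpoints for even-length fragments are `start + (length−1)//2`
(left of center); occupancy is the 10-bp-binned ratio of observed midpoint
coverage to a simulated control (uniform, or reweighted by the GC content
of the 5-mer at candidate fragment starts), bins anchored at coordinate 0,
with zero-control bins propagated as missing.

Stability terciles split dyads into equal thirds by score; remainders go to
the lower-score groups first and ties break by (chrom, pos), making labels
invariant to input order. The genome partition gives strong regions
precedence over rotational ones; the three classes tile the workspace
exactly.

## Regression model

One row per candidate site: mutated sites (y=1) and uniformly sampled
non-mutated usable controls (y=0), about ten controls per event.
Covariates: strand-normalized context bases at offsets ±1..±5 (sites with
reference T/G are reverse-complemented so the reference is A/C; the site
class is AT, CpG or non-CpG C/G), the five-level `d_mean_bin`,
`log_d_var = ln(d_var + 1)` (natural log; the +1 offset handles d_var = 0
and is exposed as a parameter), occupancy, per-track means over ±10 bp
(missing bases skipped; rows with missing modeled values dropped and
counted), and repeat status with precedence Alu > L1 > other_repeat >
nonrepeat. Reference levels: base A at every offset, bin 1, nonrepeat.

The fit is a MAP estimate under independent Student-t priors on
standardized coefficients — scale 2.5, df 1 (a Cauchy) for predictors,
scale 10 for the intercept. Binary columns are centered; continuous
columns are centered and rescaled to SD 0.5, so the prior is
weakly-informative regardless of input units. The optimizer is IRLS with
an EM update of per-coefficient prior variances,
`σ_j² = (β_j² + ν s_j²)/(1 + ν)`, each step solving a ridge-penalized
weighted least-squares system; convergence at max |Δβ| < 1e−8 or 200
iterations (non-convergence is flagged, never silent). The heavy-tailed
prior keeps estimates finite under complete separation — routine when
events are ~1e−4 of sites — while leaving well-identified coefficients at
their MLE (verified against an unpenalized fit as the prior scale → ∞).

Likelihood-ratio scans compare the full model to reduced models missing one
variable. Both log-likelihoods are the *unpenalized* binomial
log-likelihood evaluated at the MAP estimates of each model — the natural
deviance comparison for penalized fits; numerically negative statistics
are clamped at 0 (warning beyond IRLS noise). Degrees of freedom = number
of design columns removed; p from the chi-square upper tail; BH correction
within each stratum's scan by default (pooling across strata by flag,
since either family is defensible). McFadden pseudo-R² =
1 − loglik(model)/loglik(intercept-only); the drop without a variable is
reported as a percent of the full model's value, floored at 0. SNV strata
(AT / CpG / non-CpG C/G) are fitted separately; pairwise context
interactions (all two-way products of context dummies) are available by
flag.

## Spectra and signatures

SNVs are classified into the canonical 96 types on the pyrimidine strand;
trinucleotide counting is likewise strand-collapsed, skipping N bases and
contig-edge bases. Correction to the genome background is
`F'_i = F_i / N_tri(i) × N_tri,genome(i)`; a nonzero count with zero
context occurrences is an impossible input and raises. Per-type enrichment
uses the two-sided Fisher exact test on the raw-count table
`[[F_r, N_r−F_r], [F_g−F_r, (N_g−N_r)−(F_g−F_r)]]`, BH across the 96
types; the direction is the sign of the odds ratio minus one, computed
from the same raw counts. Signature refitting solves
`argmin_{w≥0} ‖Sw − spectrum‖₂` (NNLS); corrected non-integer spectra are
fed in as-is, while Fisher tests only ever see raw integers. The signature
matrix is a user input; synthetic matrices serve the tests.

## Enrichment and escape ratios

Randomization enrichment re-places every event uniformly in the workspace
(chromosome-preserving; interval events keep their length and stay inside
one segment) 10,000 times. The empirical p uses the +1 correction so it is
never 0, two-sided as twice the smaller tail capped at 1; the fold CI is
observed / [97.5, 2.5] percentiles of the sampled counts.

Meta-profiles bin event offsets (bin 0 starting at the anchor, negative
offsets upstream) as events per bp per anchor, or average a signal track
ignoring missing bases; anchors too close to contig edges are dropped and
counted. Signal mode rasterizes the track to a per-base array per
chromosome — appropriate at the Mb scales this package targets.

The escape-ratio profile computes per-bin densities for both cohorts over
the mappability-filtered dyads (when a track is supplied, the full ±800 bp
must be covered at the threshold), background densities from an equal
number of random 1600-bp windows under the same constraint, and
`R_i = (m_i^A/m_i^B)/(m̄^A/m̄^B)`. Bins with zero cohort-B counts are
missing unless a +0.5 pseudocount is requested. The companion Fisher test
counts each cohort's mutations in dyad ±95 bp versus all considered
regions (dyad ± window).

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions; their defaults are fixed once:

- **Genome**: first-order Markov chain, GC 0.41 and CpG
  observed/expected 0.25 (human-like), default 1 Mb chromosomes.
- **Landscape**: dyad spacing ~ Normal(NRL = 191.4, NRL/10) truncated
  positive; per-dyad midpoint jitter is Gaussian with SD σ_k drawn
  uniformly from 3–35 bp (no generative model for midpoint scatter is
  established, so Gaussian is our explicit choice); 50 fragments per dyad,
  147-bp fragments. "Strong" regions are dyad ±73 bp for the lowest-σ
  tercile, mirroring a three-way equal-size stability split.
- **Mutations**: each site mutated independently with probability
  `logistic(Xβ*)`; the intercept is solved so the expected count matches
  the target. Substitution alts are uniform over the three alternatives
  with an optional CpG→TpG weight.
- **Paired cohorts**: per-bp Bernoulli profile around each dyad plus
  Poisson uniform background; recorded truth
  `R_i = (r_p(i)/r_d(i))/(b_p/b_d)`. Note that the *estimator's*
  background windows sample the realized genome — which includes the
  elevated dyad territory — so with dense dyads the estimated plateau sits
  slightly below the generative truth (e.g. ≈1.85 for a truth of 2 when
  dyad windows cover ~8% of the genome). This mirrors the real analysis,
  where strong-nucleosome territory is part of the genomic background, and
  is why recovery is asserted through per-bin count-based CIs rather than
  point equality.
- **Signature mixtures**: multinomial draw from S·w placed at uniformly
  chosen positions with the matching collapsed trinucleotide context,
  without position reuse.
- **Tracks**: moving-average-of-white-noise fields with a stated bandwidth
  (or constants); mappability clipped to [0, 100].

What the synthetic data does *not* emulate: MNase sequence bias, diploid
genomes, read-level errors, realistic repeat structure, regional
mutation-rate heterogeneity beyond the modeled covariates, and linkage
between tracks. Passing tests therefore demonstrate correctness of the
estimators and calibration of the tests under the stated generative
models — not robustness to every artifact of real MNase-seq or variant
calls.

## Problem sizes and numerical choices

The test and acceptance batteries use 200-kb genomes for calibration loops
(200 replicates of the null LRT scan at ~20,000 sites and 400 events;
100–200 replicates of the spectrum null at 800 SNVs) and 1-Mb genomes with
~5,000 events and 10× controls for the 20-replicate coefficient-recovery
battery — sizes chosen so each battery completes in minutes while keeping
every estimate's Monte-Carlo error well inside the asserted tolerances.
Randomization enrichment uses 10,000 samples. All randomness flows from a
single seed per run; reruns are byte-identical. IRLS weights are floored
at 1e−10, probabilities clipped away from {0,1} in log-likelihoods via
log1p/logaddexp forms, and d_var values are floored at 0 against prefix-sum
rounding.

## Known limitations

- The per-bin ratio of small Poisson counts is upward-biased; aggregate
  counts before taking ratios when bins are sparse (the profile output
  retains raw counts for exactly this purpose).
- `gc_weighted` control fragments model composition only through the
  GC count of the 5-mer at the fragment start.
- The CLI `regress` subcommand consumes a prebuilt feature table; control
  sampling and table assembly are library calls
  (`sample_control_sites`, `assemble_feature_table`).
- Interval-mode randomization enrichment counts an event as overlapping if
  any of its bases intersects the annotation (binary overlap, not
  base-weighted).
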