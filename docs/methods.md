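# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data generator, and the limits of what the test suite
demonstrates.

## Normalization model

Non-zero long-range contact counts are modelled per chromosome and pair
class (AND / XOR, fitted separately because double ChIP enrichment inflates
AND counts) as zero-truncated Poisson (ZTP):

    P(Y = y | Y > 0) = e^{-μ} μ^y / (y! (1 − e^{-μ})),   y ≥ 1,
    log μ = β0 + β1·FL + β2·GC + β3·MS + β4·IP.

Covariates are pair-level log-products log(x_i · x_j) of per-bin effective
fragment length (FL), GC content (GC), mappability (MS), and short-range
(≤ 1 Kb) read abundance (IP, the ChIP-efficiency proxy).  Bin-pair tables
may carry these covariates precomputed, or they can be joined from a
per-bin feature table (`pair_covariates_from_features`).

Fitting is Newton–Raphson on the ZTP log-likelihood.  The log link is the
canonical parameterization of this family, so the observed and expected
information coincide: the gradient is X′(y − E[Y|Y>0]) and the information
X′ diag(Var(Y|Y>0)) X with E[Y|Y>0] = μ/(1 − e^{−μ}) and
Var(Y|Y>0) = E(1 + μ − E).  Iteration starts from an ordinary Poisson GLM,
uses step-halving when a step would decrease the likelihood (with an
acceptance slack of 1e-10·(1+|ℓ|) to absorb float cancellation on large
samples), and declares convergence when the gradient infinity-norm drops
below 1e-8 (at most 100 iterations).  Safeguards:

- fewer than 50 bin pairs: the fit is refused and the chromosome/class is
  skipped with a warning (the MLE is too unstable to normalize against);
- covariate columns that are identically zero are dropped and their
  coefficients pinned at 0, so intercept-only data remain fittable;
  genuinely collinear designs raise an error naming the culprit columns;
- a linear predictor above 700 aborts with an overflow diagnostic;
- when the fitted mean collapses toward 0 (mean count ≈ 1, the boundary of
  the ZTP family) the fit converges but a diagnostic warning flags weak
  identification.

**Fitted values.**  The "fitted" quantity entering the normalized value
log2(1 + observed/fitted) is the truncated mean E[Y | Y > 0], not raw μ:
the model describes only non-zero counts, so its expectation under the
truncation is the like-for-like prediction for an observed count.  Raw μ is
available via `np.exp(X @ fit.beta)` if a user prefers it; the two differ
by < 1e-9 relative once μ ≥ 30.

## Matrix construction and smoothing

The anchor-by-offset matrix has one row per union anchor bin and m columns
at signed offsets ±1..±m/2 (no offset-0 column), m = 2·binning
distance/resolution.  Every pair end that is a union anchor receives the
pair's value at the signed offset to the other end, so an AND pair
populates two cells (one per anchor row) and an XOR pair one.  Cells never
observed stay 0, which downstream code treats as "missing" via joint-zero
removal.  Pairs separated by more than the binning distance are dropped;
1 Mb is the default because longer-range contacts are sparse and noisy.

Smoothing replaces each cell by the mean of the 2d+1 cells within ±d
columns of the same row; windows extending past the matrix edge are
zero-padded and the divisor stays 2d+1, which shrinks values near the
±binning-distance edges.  The offset-0 gap is not a column: offsets −1 and
+1 are adjacent in the window.  Smoothing is implemented as a direct
convolution rather than a running sum so that all-zero windows remain
exactly zero — otherwise ~1e-17 residues would leak through the later
joint-zero removal and perturb stratum membership.

## Score

Stratum k concatenates the −k and +k columns (length 2N), removes
positions zero in both samples (N_k remain), and computes the Pearson
correlation r_k and weight w_k ∝ N_k σ(a′_k) σ(b′_k) with population (1/N_k)
standard deviations.  Population rather than sample moments matter only for
the weights (the ratio cancels in r_k).  A stratum with N_k < 2 or zero
variance in either vector is *undefined*: it receives weight 0 and is
excluded from the weight denominator, so defined weights still sum to 1.
If every stratum is undefined the score is reported as missing (NaN), never
silently zero.  Genome-level aggregation is the unweighted arithmetic mean
over chromosomes with defined scores; the across-chromosome SD is reported
alongside.

## Smoothing-parameter tuning

For candidate d = 0, 1, 2, …: draw ten independent subsamples of 25% of
one sample's non-zero matrix cells (without replacement), zero the rest,
restrict the second sample to the same positions, score the pair at
smoothing d, and average the ten scores.  Stop at the first d whose
successor improves the average by less than 1% *relative* (scores are
unit-bounded, so a relative criterion is scale-appropriate); ties stop.
The subsampling operates on matrix cells, not raw reads — the cell is the
unit the score sees.  Tuning is intended to run once per study, preferably
on a dissimilar (non-replicate) pair, and the chosen d is reused for every
comparison.  A hard cap (default d = 20) guards against non-plateauing
trajectories.  All draws derive from one seed, so tuning is deterministic.

## Resampling

*Downsampling* redraws each (chromosome, class) table's counts from
Multinomial(floor(n·factor), v/n) and drops bins that fall to zero, leaving
covariates untouched.  *Pseudo-replicates* pool two same-condition samples
over the union of their bin pairs and split each pooled count
Binomial(c, 0.5) into two artificial samples; they re-enter the pipeline at
the normalization step like any real sample.  Per-file sub-seeds are stable
SHA-256 hashes of (master seed, sample, chromosome, class), so adding a
sample to a study never perturbs another sample's draws.

## Silhouette evaluation

Correlations are not ratio-scale, so the score matrix is min-max scaled to
[0, 1] using the off-diagonal entries only (the self-similarity diagonal
would otherwise anchor the maximum); the diagonal is then set to 1.  The
silhouette is computed directly on similarities: a(i) is the mean scaled
similarity of sample i to its own cluster's other members, b(i) the largest
mean similarity to any rival cluster, s(i) = (a−b)/max(a, b); the mean over
samples is reported, with s(i) = 0 for singleton clusters (flagged).  Good
clustering drives the mean toward 1.

## Synthetic-data generator

The generator emulates a complete multi-sample study.  Per condition it
draws an anchor set as a core shared by all conditions (sized to hit a
target pairwise Jaccard overlap exactly, within rounding) plus private
anchors.  For each candidate anchor–offset cell the log mean combines:
standardized bias covariates with coefficients `beta_true`; a
condition-shared background field (Normal, sd 0.5) standing in for
compartment/TAD-scale contact structure that real cell types share; a
sparse loop field (2% of cells, Gamma-distributed amplitudes, mean 1.5 on
the log scale), half drawn from a study-wide pool on the core anchors and
half condition-private; an AND-pair enrichment boost (0.7); power-law
distance decay (exponent 1); and per-replicate log-normal noise (sd 0.3).
Counts are Poisson draws globally rescaled to an expected total depth, with
zero outcomes dropped — exactly the zero-truncated support the
normalization models.  Defaults (2 chromosomes × 2,000 bins at 10 Kb,
Jaccard 0.54, depth 2×10⁵ per sample) run the full pipeline in seconds.

`simulate_ztp_pairs` is a separate, stripped generator — iid Normal(0, 0.5)
covariates, exact inverse-CDF ZTP draws, no decay/loops/noise — used as the
parameter-recovery oracle for the regression fit.

Deliberately not modelled: restriction-fragment structure, ligation
artifacts, trans contacts, copy-number effects, and peak-calling noise
(peaks are emitted as intervals that exactly recover the simulated anchors,
including multi-bin peaks spanning bin boundaries).  Passing tests
demonstrate internal consistency and the expected orderings on this
generative model, not performance on any real library.

## Study designs used by the checks

Two standing designs, chosen to mirror the two ways real studies define
anchors:

- *Discriminability* (pseudo ≥ replicate ≥ non-replicate ordering):
  two conditions × two replicates, each condition with its own anchors
  (Jaccard 0.54), one chromosome.  Cross-condition scores land near or
  below zero here because anchors private to one condition contribute
  one-sided strata.
- *Clustering/degradation*: three conditions × three replicates sharing
  one anchor set (as when anchors are defined from the union of all cell
  types' 1D peaks), depth 5×10⁵, smoothing d = 3, silhouette computed on
  the min-max-scaled score matrix.  Depth reduction uses multinomial
  downsampling at factors 1.0 → 0.2; the monotone-degradation check
  averages the silhouette over three study seeds because a single study's
  trajectory carries visible Monte-Carlo noise.

## Known limitations

- Whether AND pairs should populate one or both anchor rows is a design
  choice; both-rows is this package's contract (the matrix is
  anchor-centric and both ends are anchors).
- The zero-padded smoothing window biases values within d columns of the
  ±binning-distance edges toward zero.
- Matrices are stored dense; at default scales (tens of thousands of
  anchors × a few hundred offsets) this is a few hundred MB at most, but
  extreme resolutions may warrant a sparse backend.
- The tuning stopping rule compares consecutive means without a
  significance test; with ten subsamples the trajectory is smooth in
  practice, but a noisy pair near the 1% threshold can stop one unit early
  or late.
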