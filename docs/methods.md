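# Methods

## The neutral community model

The model treats each larval gut as a local community of fixed size *N*
assembled from a shared metacommunity by stochastic birth–death drift and
immigration. Immigration happens with probability *m* per death event. At
stationarity the local relative abundance *x* of a taxon whose metacommunity
mean relative abundance is *p* follows a beta distribution,

    x ~ Beta(N·m·p, N·m·(1−p)),

and a taxon is *detected* in a sample when *x* exceeds a detection limit *d*.
The predicted detection frequency is the upper tail

    freq_pred(p) = 1 − I_d(N·m·p, N·m·(1−p)),

with I the regularized incomplete beta CDF (`scipy.special.betainc`).

**Inputs of the fit.** From a taxon-by-sample count table, after excluding
taxa with zero counts across all samples of the group, we compute per taxon
the mean of per-sample relative abundances (*p*) and the fraction of samples
with a nonzero count (freq); *N* is the mean per-sample total count. These
definitions follow the convention of the widely used `sncm.fit` script
lineage; both are plain arithmetic and can be overridden by calling
`fit_m` directly with alternative summaries.

**Detection limit.** *d* defaults to 1/*N* — presence scored at a single
read, the standard convention for count data. It is configurable in
`fit_neutral(..., d=...)`.

**Estimation.** *m* is the only fitted parameter. It minimizes
Σᵢ (freqᵢ − freq_pred(pᵢ))² by bounded least squares
(`scipy.optimize.least_squares`, m ∈ (10⁻⁶, 1−10⁻⁶)) from four starting
points (0.001, 0.01, 0.1, 0.5); the objective is one-dimensional and smooth,
so the multistart is belt-and-braces against flat regions, and the procedure
is deterministic given the data.

**Diagnostics.** R² = 1 − SSE/SST on the frequency scale;
RMSE = √(SSE/(n−1)); AIC and BIC from a Gaussian residual log-likelihood with
k = 2 parameters (m and the residual σ): AIC = 2k − 2lnL,
BIC = k·ln(n) − 2lnL. The likelihood is a reporting convention for comparing
fits, not a claim that residuals are Gaussian.

**Classification.** Around each taxon's prediction we place a 95% Wilson
score interval with "successes" = freq_pred × n_samples (non-integer counts
are used as-is, matching the script lineage). Observed frequency strictly
above the upper bound → **Above**; strictly below the lower bound →
**Below**; on the closed interval → **Neutral**. The boundary convention is
closed because a frequency on the bound falls within the interval.

A monotonicity caveat: freq_pred is non-decreasing in *p* everywhere, and
non-decreasing in *m* only where *p* > *d*. Below the detection limit a
larger *m* concentrates local abundance around a value under *d* and
detection legitimately falls. The property tests encode exactly this.

**Stringent filter.** Four predicates applied in order, each with an audit
count: (1) p > 0.01; (2) partition ∈ {Above, Below}; (3) freq ≥ 0.2;
(4) |freq − freq_pred| > 0.05. Stage 4 is stated ambiguously in the script
lineage this reproduces ("absolute deviation from predicted detection
frequency (freq.pred > 0.05)"); we implement the absolute-deviation reading
as the default and keep the literal `freq_pred > 0.05` behind
`FilterConfig(literal_stage4=True)`.

## Demultiplexing

Reads are assigned to a sample only when the sample's forward barcode occurs
in the first 100 bp and the reverse complement of its reverse barcode in the
last 100 bp. Matching is exact by default; an optional Hamming-mismatch
tolerance is available (`max_mismatches`) because nanopore reads are noisy —
the default stays at 0 to keep assignment conservative. Reads are searched in
both orientations (nanopore libraries are strand-mixed); the orientation is
recorded, and trimmed output is reported in the original read's frame, so
demultiplexing a read and its reverse complement give reverse-complementary
trims of the same sample. When two different samples' barcode pairs both
match, the read is reported `ambiguous` rather than resolved by score —
with exact matching the tie is irresolvable. The inclusive 1,000–2,000 bp
length filter is applied after trimming. Quality strings travel through
trimming in coordinate lock-step with the sequence.

## Community statistics

Shannon diversity uses the natural log (configurable via `base`). Pairwise
group comparisons use two-sided Wilcoxon rank-sum tests
(`scipy.stats.mannwhitneyu`, exact for small tie-free samples, normal
approximation with tie correction otherwise) with Benjamini–Hochberg q-values
over the full pair set. Spearman correlations are computed on mid-ranks
(tie-aware), with significance from the t-approximation
t = ρ√((n−2)/(1−ρ²)) and Bonferroni correction over the number of taxa
tested. Prevalence for core-taxon selection is counted over all samples in
the supplied table; sub-setting by metadata is the caller's job
(`FeatureTable.groupby_metadata`).

## Heritability

Narrow-sense heritability is the slope of ordinary least squares of family
mean offspring phenotype on the mid-parent value (mean of the two parents):
h² = b_op. Families are unweighted by default since the design collects a
fixed offspring cohort per pair; weighting by offspring count is available.
The OLS slope standard error is reported as an addition beyond the classic
estimate. Degenerate designs (fewer than 3 families, all mid-parent values
identical) raise errors rather than returning meaningless slopes.

## Synthetic data: what it emulates, what it does not

The community generator draws metacommunity abundances from a log-normal
(μ = 0, σ = 2 — a heavy-tailed rank-abundance curve typical of amplicon
surveys), per-sample depths from a rounded Normal(15,000, 5,500) truncated at
1,000 reads (a realistic nanopore 16S per-sample yield), and counts through
the same beta-binomial detection process the fit assumes. That choice is
deliberate: it makes parameter recovery a well-posed oracle. A misspecified
Dirichlet-multinomial generator is available
(`generating_model="dirichlet_multinomial"`) for robustness exploration only.

Deviant injection: "Above" taxa are drawn from taxa whose neutral-expected
detection frequency is low-to-middle (0.15–0.6, widening if the band is
sparse) and forced present in ~98% of samples; "Below" taxa from the
high-expected-frequency band (≥ 0.85) and zeroed in a random 60% of the
samples where they occurred. The bands exist so the injected signal is
detectable in principle — a taxon already detected everywhere cannot be made
more-detected.

The read generator produces perfect barcodes and uniform-random inserts:
no homopolymer errors, quality models or chimeras. Passing demultiplexing
tests therefore shows the assignment/trimming/filter logic is correct, not
that real noisy nanopore reads would assign at the same rate. The pedigree
generator is purely additive — no dominance, maternal effects or
common-environment covariance — so recovery tests validate the estimator, not
the biology of any particular population.

Problem sizes in the test suite and acceptance script (60 samples × 1,500
taxa, 10–20 seeds, 10,000 reads, 200 families) are chosen so the full
validation runs in well under a minute while keeping estimator error bands
tight; they match the scale of a single sub-line × generation analysis in a
real experiment.

## Numerical choices and known limitations

- Wilson bounds are clipped exactly to 0 (resp. 1) at 0-of-n (resp. n-of-n)
  to avoid floating-point dust from catastrophic cancellation.
- The m estimator shows a small upward finite-sample bias (~10% relative at
  60 samples) because the plug-in p and freq are themselves noisy; it
  shrinks with sample count and is well inside the ±15% recovery band the
  tests assert.
- `relative_abundance` rejects zero-total samples by name instead of
  propagating NaNs.
- Ambiguous barcode matches are never resolved by proximity or score.
- The pipeline manifest records config hash and per-file sha256 checksums;
  reruns with identical configs are checksum-identical, which the tests
  assert.
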