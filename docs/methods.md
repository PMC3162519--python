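# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical conventions a maintainer would need to
reproduce behavior exactly.

## Expression scores and preprocessing

Expression is assumed pre-normalized and log-scale. Clinical covariates
(receptor status, age, batch, …) are regressed out gene by gene and the
residuals carried forward; the default fit is a Huber M-estimator
(tuning constant 1.345, IRLS, max 50 iterations, coefficient tolerance
1e-8 — the conventional 95%-efficiency robust-regression default), with
OLS as the alternative. Categorical covariates are one-hot encoded with
the first level dropped. Probes mapping to one gene are collapsed by
averaging so multi-probe genes do not carry extra weight at one locus.
Genes without genomic annotation are kept through preprocessing (network
stages do not need positions) but excluded from chromosome tracks.

The expression score is the two-sample t-statistic (group 1 − group 0),
pooled-variance by default, Welch optional. Genes with pooled variance
below 1e-12 score 0 and are flagged rather than producing numerical
noise. Both groups must contain at least two samples.

## Wavelet smoothing

The neighboring score is the reconstruction from the level-s
approximation of an undecimated (stationary) wavelet transform, so each
gene keeps exactly one smoothed value and the result is
translation-invariant. Implementation: symmetric-reflection pre-padding
(both to shield the transform's periodic boundary handling and to reach
the required multiple-of-2^s length), stationary transform, detail
coefficients zeroed, inverse transform, crop. For an orthogonal filter
this operator equals convolution with a mass-one kernel (for Haar at
level s, a triangular kernel of width 2^(s+1) − 1); the test suite
checks equality with an independently constructed cascade kernel to
1e-8. Level 0 is the identity. Smoothing operates on gene index, not bp
distance: scores are equally spaced samples in track order and probe
density varies by platform.

Defaults are Haar with s = 3 paired with run length n = 5; s = 5 pairs
with n = 10. Higher scaling levels spread a single differential gene
over more neighbors, so the run-length requirement must grow with s;
the pairing is exposed as configuration, as is the filter family. The
Gaussian comparator convolves with a normalized Gaussian kernel over
gene index (reflect-padded, truncated at 4σ); bandwidth 0 is the
identity.

## Permutation null and the FDR statistic

The null is built by permuting phenotype labels over samples B times
(default 1000; B = 200 in the simulation studies below), recomputing all
scores and smoothing with identical settings, and pooling the random NS
per chromosome. Permutation b draws from a stream seeded by (seed, b),
so enlarging B never reshuffles earlier permutations. The permuted
scores are computed by a closed-form vectorization (group sums and sums
of squares via matrix products), verified in tests against direct
per-permutation t-statistics.

Two per-gene significance statistics are provided:

* `tail` (default): for NS > 0, the fraction of pooled random NS greater
  than or equal to the observed value; symmetrically for NS < 0; NS = 0
  maps to 1. Exact zeros are printed as such; an optional pseudocount
  flag reports (count+1)/(total+1) instead.
* `excess`: the expected number of null NS per permutation at least as
  extreme as the observed value, divided by the observed number at least
  as extreme on that chromosome, capped at 1 — an excess-over-null
  (empirical false-discovery) ratio in the spirit of permutation-based
  differential-expression methods.

The distinction matters for calibration. The `tail` statistic is a
per-gene empirical p-value: at α = 0.01 about 2% of genes exceed the
threshold under a pure null (both tails), and because smoothing
autocorrelates NS over ~2^(s+1) neighboring genes, those exceedances
arrive in runs that regularly reach the n = 5 run-length requirement. A
5,000-gene null study therefore yields on the order of ten spurious
regions under `tail`. The `excess` statistic compares the *count* of
observed exceedances with its null expectation, which is ≈ 1 under label
exchangeability wherever there is no signal, so pure-noise tracks are
essentially never called (zero false regions in ≥ 95% of seeded null
replicates) while strong segments still reach tiny values. Single-study
calls made with the `tail` default should be treated as candidates and
filtered by cross-study recurrence, which is the framework's guard
against study-specific artifacts; `excess` is the choice when a single
study must stand alone.

Region calling takes maximal runs of ≥ n consecutive genes with
same-sign NS and FDR strictly below α (every run member must qualify —
the strictest reading). Region coordinates anchor at the first and last
member gene; emitted BED uses the 0-based half-open convention with the
strand column carrying the sign.

## Recurrent regions

Alignment works per chromosome and sign on bp coverage: each study's
regions are first flattened so one study never counts twice, maximal
intervals covered by ≥ k studies form cores, each core is expanded to
the union of the study regions intersecting it, and overlapping expanded
intervals are merged so same-sign recurrent regions are disjoint.
Expansion is deliberately not transitive beyond the core: a region
joins only if it touches a ≥ k-coverage locus. Gains and losses are
aligned independently and may overlap. Gene membership uses closed
intervals on the single-point gene position. Raising k can only shrink
the recurrent set; k = 1 reduces to the per-sign union.

## Bayesian networks

Whether a downstream gene is regulated by one, both or neither of two
co-localized candidates — conditioned on everything else measured — is a
model-selection problem over DAGs, so regulator identification is
implemented directly as structure learning. Expression is discretized
per gene into L = 3 rank-based quantile levels (under/normal/over; any
monotone transform of a gene gives identical levels; constant genes map
to the middle level and are flagged), keeping the BIC of multinomial
local conditionals closed-form. The family score is the maximum-
likelihood multinomial log-likelihood minus ½·(L−1)·L^|parents|·log N;
the total decomposes over families.

The search is a Metropolis walk from the empty graph with add/delete/
reverse moves, rejecting proposals that create cycles or exceed
max_parents (default 3, a tractability bound at desk scale); acceptance
probability min(1, exp(ΔBIC)) with natural log and no annealing. The
default chain length is 15·n² proposals for n nodes. Ensembles use
consecutive seeds (default 100 chains at desk scale; 1000 matches the
original protocol); the consensus keeps directed edges appearing in
strictly more than 30% of chains, a threshold chosen as the separator of
the bimodal edge-occurrence histogram such ensembles produce.
Cross-study combination is the union of directed links with frequency =
max over inputs (preserving the strongest single-study support for the
loop-breaking tie-break); the union may contain cycles, including
two-cycles from conflicting orientations. Loop breaking repeatedly finds
a directed cycle (depth-first from the lexicographically smallest node,
neighbors in sorted order, for determinism) and removes its
minimum-frequency edge, ties going to the lexicographically smallest
(parent, child) pair; edges outside every cycle are never touched.

## Key driver analysis

HLN(g) is the number of distinct nodes reachable from g by directed
paths of length ≤ h, excluding g. h defaults to the network diameter
(the longest finite shortest directed path). Reference statistics —
mean and sample standard deviation of HLN sizes and out-degrees — are
computed over **all** network nodes; candidacy is restricted to the
supplied gene set (typically genes in amplified recurrent regions, since
amplification is the hallmark of dominant drivers). The threshold
multiplier is 1 standard deviation for both statistics, configurable.
Thresholds are strict inequalities, so degenerate networks with zero
spread call no drivers. Cyclic input is rejected; run loop breaking
first.

## Viability signatures and enrichment

The hit cutoff is median − k·sd (sample sd, n−1; k = 1.5 default) of the
relevant score distribution, with strict `<` at the boundary. V1
thresholds an across-cell-line combined score; the combination rule is
pluggable (default: per-gene median across lines; mean, min, or any
callable) because a single canonical rule does not exist for multi-line
screens. Per-line signatures apply the same rule within each line; V2 is
the union of V1 with all of them, so V1 ⊆ V2 holds by construction.
Fold enrichment is the in-target hit rate over the background hit rate,
with an exact hypergeometric upper-tail p-value; it is invariant under
duplication of all counts.

## Synthetic data

`simulate_study` emulates exactly the structure the region caller
assumes: i.i.d. Gaussian baseline (unit sd), mean shifts of δ pooled-sd
units confined to planted segments and to the case group, uniform 100 kb
gene spacing, optional global covariate effects. Defaults (5,000 genes
on 20 chromosomes, 50 samples per group, δ = 1, 30-gene segments in the
recovery studies) describe a desk-scale analogue of a two-outcome
microarray cohort. It does **not** emulate correlated co-expression
outside CNV segments, heavy-tailed arrays, probe-density variation,
missing values, or dosage effects that scale with amplitude rather than
shift the mean — so passing recovery/calibration tests demonstrate
correctness of the inference machinery under its own model, not
performance on real arrays. `simulate_dag_expression` plants root hub
regulators with fixed fan-out plus sparse extra edges among non-hubs and
draws linear-Gaussian data with |β| ∈ [0.8, 1.2]; real regulatory
networks are neither linear nor this cleanly layered, and the truth DAG
(not a learned one) is used where only the driver-calling logic is under
test.

## Problem sizes and numerical conventions

Simulation studies use 5,000 genes, 50 + 50 samples and B = 200
permutations with 20 (calibration) or 10 (recovery) replicates;
structure-search studies use 3-node data with 300 samples and 50–100
chains — sizes chosen so the full suite and the acceptance script each
complete in well under a minute while keeping Monte-Carlo error small
relative to the tested margins. Numerical conventions: pooled-variance
guard at 1e-12; position ties in track ordering break on gene ID;
empirical-FDR counts use closed tail inequalities (≥ / ≤); BIC in
natural log; RNG throughout is numpy's PCG64 via `default_rng`, with
derived streams (seed, index) wherever a count parameter may change.

## Known limitations

* The `tail` FDR default is a per-gene empirical p-value, not a
  corrected false-discovery rate; single-study calls under it include
  clustered noise runs (see above) and rely on recurrence filtering.
* BIC scoring requires discretization; a continuous Gaussian score is
  not implemented in this version.
* Consensus frequencies are interpreted per ensemble of equal-length
  chains; mixing diagnostics are not computed.
* Interval alignment assumes co-annotated genome builds; no liftover.
* The across-cell-line combination rule for V1 is a modelling choice;
  results on real screens should report which rule was used.
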