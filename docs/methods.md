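# Methods

## Scope and data model

The package analyses two kinds of features × samples tables from a
factorial soil-profile mesocosm design (soil type × depth layer ×
growth stage × replicate): OTU read counts from amplicon sequencing and
probe signal intensities from a functional gene array, aggregated to
gene categories. All stages operate on the `FeatureTable` container
(non-negative matrix, feature annotations, sample metadata); networks
are `networkx` graphs with signed, weighted edges.

## Preprocessing

**Rarefaction** draws each sample down to a common depth without
replacement (one multivariate-hypergeometric draw per sample). Each
sample uses an RNG stream keyed by (seed, sample id), so results do not
depend on sample order or on which other samples are present. Samples
below the target depth are dropped with a warning.

**Prevalence filter**: a feature must have a nonzero count in at least
`min_occurrence` samples (default 4) of the sample group being
analysed — occurrence is evaluated within the group (e.g. one depth
layer), not across the whole study.

**SNR filter**: array probes are kept when
(signal − background mean)/background sd ≥ 2. The boundary case is
kept: the filter removes probes *below* the threshold.

**lnMR normalization**: x ↦ ln(x+1)/M. The divisor M is, by default,
the mean over samples of the per-sample total raw intensity — a single
global scalar, which keeps samples on a common scale. The phrase "mean
total signal intensity of each sample" admits a per-sample reading as
well, so a `per_sample=True` variant (divide by the sample's own total)
is provided rather than guessing intent. Zeros map to zero and
within-sample rank order is preserved under both variants.

## Diversity

Shannon entropy is reported in natural log: with ~4·10⁴ detected genes
the published index magnitudes (≈10.3) are only consistent with nats.
Simpson-family output includes Gini–Simpson (1−Σp²), inverse Simpson
(1/Σp²) and Simpson evenness (inverse Simpson / richness), because
published "Simpson" columns are ambiguous between the first two.
Gene-set overlap uses shared% = 100·|A∩B|/|A∪B| (pairwise union
denominator) and endemic% = 100·|A∖∪others|/|A| (own-size denominator);
these are the conventions that reproduce the published percentages from
the published counts (e.g. 34397/(40612+36860−34397) = 79.85%,
2264/40612 = 5.57%).

## pMENs and the RMT threshold

The similarity matrix is Pearson correlation across samples of
ln(relative abundance + pseudocount), the pseudocount being half the
smallest nonzero relative abundance; the transform is configurable
because the upstream convention is not fixed in the literature this
follows. Zero-variance features are excluded rather than given
undefined correlations.

The cutoff scan runs over |r| ∈ [0.30, 0.99] in steps of 0.01 (published
thresholds are printed to 2 d.p.). At each candidate the matrix is
hard-thresholded, restricted to non-isolated features, and its
eigenvalue spectrum is unfolded: degenerate eigenvalues (equal within
1e-8) are collapsed — disconnected subgraphs produce exactly repeated
eigenvalues whose zero spacings would contaminate the statistics — and a
cubic smoothing spline fitted to the empirical cumulative spectral
function maps λᵢ to unfolded levels with unit mean spacing (enforced
exactly by a final normalization). Goodness of fit of the spacing
sample against Poisson e^(−s) and the Wigner surmise
(π/2)·s·e^(−πs²/4) uses a χ² test on equiprobable bins with expected
counts ≥ 5. The chosen threshold is the smallest cutoff whose NNSD is
consistent with Poisson (p > 0.05) and inconsistent with Wigner — the
GOE→Poisson transition. When no candidate qualifies the scan reports a
diagnostic instead of a cutoff; at least 20 distinct eigenvalues are
required for a test.

On planted-module data the transition point depends on where the noise
floor of the empirical correlations sits. With 500 samples the noise
floor is low, and the chosen cutoff can land anywhere between the scan
minimum and the planted correlation; what is invariant — and what the
tests assert — is that the chosen cutoff severs the planted blocks from
each other and module detection recovers them (Rand index > 0.9).

Modules come from greedy modularity maximization (networkx CNM) on
|weight|, so strong negative associations bind as strongly as positive
ones; module labels are ordered by each module's smallest member for
determinism. Reported modularity Q = Σ(e\_mm − a\_m²) is computed on the
unweighted graph by default (weighted variant flagged). Node roles use
Zᵢ (z-score of within-module degree over the node's module; 0 when the
module has no degree spread) and Pᵢ = 1 − Σₘ(kᵢₘ/kᵢ)², with the
classification Zᵢ > 2.5 ∧ Pᵢ < 0.62 → module hub, Zᵢ > 2.5 ∧ Pᵢ > 0.62
→ network hub, Zᵢ < 2.5 ∧ Pᵢ > 0.62 → connector, else peripheral. The
quoted cutoffs are strict, leaving boundary values formally unassigned;
boundary cases fall to the peripheral-side category.

Two degree conventions coexist deliberately: pMEN summaries use
avgK = 2L/N (mean node degree), bipartite taxa–function summaries use
average degree = E/N (edges per node). Both are labelled explicitly
because both appear in published summary tables of this kind.

## Ensemble taxa–function networks

Each feature pair is scored by Pearson and Spearman correlation (on
per-sample relative abundances), Bray–Curtis dissimilarity and
symmetrized KL divergence. BC and KL compare the two features'
*profiles across samples* normalized to unit sum — without this, a
cross-table scale difference (a taxon's share vs a category's share)
dominates the dissimilarity and carries no association signal. KL uses
a pseudocount (default 1e-6; set it to 1/total-count for count tables)
and the symmetric form D(p‖q) + D(q‖p).

**ReBoot null**: each permutation shuffles feature profiles across
samples independently and then renormalizes every sample's composition
to unit sum before rescoring, so that associations induced purely by
the closed-sum constraint are present in the null and cancel. The
pipeline permutes all features at once per iteration (each pair's
marginal null is the same as permuting just that pair) so that one
permutation stream is shared by all pairs and all four measures — the
shared stream is what makes the Brown covariance estimable.

**p-values**: two-sided z of the observed score against the null mean
and sd, floored at 1/(n_perm+1). A bootstrap stability veto (resample
samples with replacement, default 100×) declares a pair non-significant
when its bootstrap 95% interval covers the null mean. These mechanics
are configurable; the permutation-with-renormalization step is the part
that matters for compositionality.

**Brown combination**: X = −2Σln pᵢ is referred to a scaled χ²
(c = Var/2E, df = 2E²/Var, E = 2k,
Var = 4k + 2Σcov(−2 ln pᵢ, −2 ln pⱼ)); with zero covariance this is
exactly Fisher's method. The covariance is estimated empirically from
the per-measure null p-values across the shared permutation stream —
the four measures are computed on identical data and are strongly
dependent, so assuming independence would badly overstate the combined
evidence.

**Filters**: retained edges need support (p < 0.05) from ≥ 2 of the 4
measures, a correlation coefficient (Pearson or Spearman — "coefficient"
is meaningless for the unbounded KL) above 0.8 in magnitude, and
combined p < 0.05. A Benjamini–Hochberg option across pairs exists but
defaults off: the Brown p of four strongly dependent measures is
floor-limited near the single-measure permutation floor, so at 50–100
permutations BH across hundreds of pairs rejects everything regardless
of effect size, while the 0.8-coefficient cutoff already keeps the
realized false-edge rate far below nominal (measured 0/10⁴ pairs on
independent tables). Edge sign comes from the larger-magnitude of the
two correlation measures.

## Synthetic data generator

Taxon abundances are a multivariate-normal latent log-abundance field
with block correlation: contiguous modules at `within_module_rho`
(default 0.8), `cross_module_rho` (default 0) between modules, and
optional `n_background_taxa` that are uncorrelated with everything and
carry singleton module labels. Non-PSD requests are repaired by
shrinking all off-diagonal entries ×0.95 until the spectrum is
non-negative. Per-taxon means are N(0, `means_sd`) (log-normal
abundance spread); an optional depth gradient shifts a taxon subset's
means per layer. Counts are one multinomial draw per sample with
probabilities ∝ exp(latent) at `sequencing_depth` (default 42364 reads,
the rarefaction depth typical of the bacterial libraries this design
emulates) — the closed column sum makes the data compositional by
construction, which is precisely the artifact ReBoot exists to correct.
Array categories are either pure scanner noise N(background_mean,
background_sd) or coupled to one taxon:
signal = background_mean + signal_gain·(w·z + √(1−w²)·ε), where z is
the taxon's standardized *closed* log abundance — the scale on which
the association is observable in compositional data — so the planted
correlation is exactly w = `coupling_strength` before clipping.
Negative intensities are clipped at 0 (scanners report non-negative
signal); at the default background parameters clipping is a >5σ event.

What the generator does **not** emulate: read-level error and chimeras,
taxonomy assignment, probe-level cross-hybridization, overdispersion
beyond multinomial, batch effects, or realistic rank-abundance tails.
Passing recovery tests therefore demonstrate the *algorithms* recover
planted structure through compositional counting noise — not that the
method is robust to every artifact of real surveys.

A note on the 2-block recovery scenario: when the entire community sits
in two correlated blocks, compositional closure manufactures strong
(−0.4 to −0.7) cross-block correlations and no threshold can separate
the blocks — an instructive artifact, not an algorithm failure. The
recovery scenario therefore embeds the two 20-taxon guilds in a
120-taxon community (80 background taxa, `means_sd` 0.5), which keeps
the closure distortion below the planted signal, as in real communities
where no single guild dominates the compositional denominator.

## Problem sizes and determinism

Simulation-based checks use 48-sample studies (the emulated design) for
calibration/power (50–200 replicates at 50 permutations + 50
bootstraps) and 500-sample single-condition draws for correlation-
fidelity and RMT-recovery checks (10 seeds); these sizes give stable
rates while keeping a full run in minutes on one core. Every stochastic
step takes an explicit seed; the pipeline derives per-stage and
per-sample substreams from one global seed via hashing, so stage order,
sample order and parallel execution cannot change results. The run
manifest records parameters and SHA-256 checksums of all outputs.

## Known limitations

- The RMT scan needs ≥ 20 distinct eigenvalues after thresholding;
  very small communities (or very high cutoffs) fall back to an
  explicit threshold override.
- The Brown covariance is estimated from the same permutation stream
  used for the per-measure p-values; at n_perm = 50 it is noisy, which
  is conservative in practice (over-estimated dependence widens the
  combined p).
- `detect_modules` is the CNM greedy optimizer: deterministic and fast,
  but it can miss the modularity optimum on small graphs by up to the
  usual greedy gap (tests bound it at 0.05 on 8-node graphs).
- Published similarity thresholds for real OTU data (0.74–0.85) are
  reference configuration, not reproducible targets, since the
  underlying survey data are not deposited.
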