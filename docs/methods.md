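# Methods

## Model

The object of inference is the population frequency p of a selected
("adaptive") haplotype tagged by a panel of SNPs assumed to be in complete
linkage — every read overlapping any panel site is a draw from the same
two-allele system. For one individual with diploid genotype G ∈ {0, 1, 2}
copies of the haplotype, each retained read supports the adaptive allele
with probability

| G | P(read supports) |
|---|------------------|
| 2 | 1 − ε            |
| 1 | 1/2              |
| 0 | ε                |

where ε is the per-read probability that the observed base misrepresents
the underlying haplotype allele, lumping together sequencing error and
post-mortem C→T/G→A deamination. Reads are conditionally independent given
G, so pooling over panel sites gives a binomial likelihood B(r, t, q) for r
supporting reads out of t. Genotype posteriors use a flat prior by default
(binomial coefficients cancel; the posterior is the normalised likelihood
triple) and the posterior is invariant to positive rescaling of any prior.

For a group of N individuals, genotypes are marginalised under
Hardy–Weinberg proportions, giving the mixture log-likelihood

    l(p) = Σᵢ log[ p² B(rᵢ,tᵢ,1−ε) + 2p(1−p) B(rᵢ,tᵢ,1/2) + (1−p)² B(rᵢ,tᵢ,ε) ].

No inbreeding coefficient is modelled — the HWE weights are the model.
Individuals with tᵢ = 0 contribute log 1 = 0; a whole-group zero-coverage
cohort yields a flat likelihood and is reported as degenerate (p̂ = 0.5,
interval [0, 1], flagged) rather than silently estimated.

## Parameters that matter

* **ε (per-read error), default 0.01, dimensionless.** A conservative
  aDNA mismatch rate covering base-calling error plus residual
  deamination after partial-UDG treatment. It is user-configurable
  everywhere, and `epsilon_sweep` exposes posterior sensitivity across
  0.001–0.05. ε is per-read and shared across sites; a transition-specific
  ε is not modelled in the estimator (the simulator can generate it, which
  is exactly how mis-specification can be probed).
* **Coverage rule for hard calls, default ≥ 4 reads per panel site.**
  The literal per-site reading is strict at typical aDNA depths, so a
  pooled-total mode (`mode="total"`) is provided; neither is asserted to
  be the only defensible rule, and the choice is a explicit argument.
* **Call threshold, default 0 (pure MAP).** No posterior cutoff is applied
  unless requested.
* **CI level, default 0.95.**

## Estimation and numerics

* **MLE.** l(p) is not guaranteed unimodal, so the maximiser is a dense
  grid (step 1e-4) followed by golden-section refinement inside the best
  bracket; ties break to the smallest p; if refinement fails to improve on
  the grid point the grid point is kept. A vectorised batch variant
  (coarse 4e-3 grid with two zoom stages to 1e-5) serves the
  many-SNP selection-test path; a dedicated test holds the two paths
  together within 2e-4.
* **Stability.** All binomial terms are computed as log-pmfs; the
  per-individual mixture is evaluated with a max-shift so deep coverage
  cannot underflow, and ε = 0 is valid (0⁰ = 1).
* **Confidence intervals.** Profile likelihood by default:
  {p : 2[l(p̂) − l(p)] ≤ χ²₁(level)}, found by bisection (tolerance 1e-6)
  on each side of p̂ and truncated at [0, 1]. The published analysis this
  mirrors does not state its interval construction, so exact reproduction
  of any printed bounds is not claimed; a seeded percentile bootstrap over
  individuals (default 2000 resamples) is available for comparison.
* **Time bins.** Closed intervals in cal B.P.; the shipped preset
  (>2500, 2400–1900, 1600–700, modern) is non-contiguous, and dates in the
  gaps are excluded and reported, never snapped. Dates are point values;
  calibration uncertainty is not propagated.

## Selection test

The statistic is the older→newer difference of ML frequency estimates,
computed identically for the focal locus and for each background SNP on the
same individuals. The p-value is one-sided for an increase with the add-one
correction, p = (1 + #{null ≥ observed}) / (1 + M), hence always in (0, 1].
Background SNPs with an all-zero-coverage bin are dropped and counted —
keeping them would shrink the null toward zero change. Optional frequency
matching retains only background SNPs whose older-bin estimate is within a
tolerance of the focal one, since drift magnitude depends on starting
frequency; the default is no matching (background SNPs "randomly chosen").
The published analysis's exact null construction is not documented in its
main text, so this construction is this package's own definition and no
agreement with any printed p-value is claimed.

## Synthetic data

The generator emulates the data structure the estimators assume:

* genotypes Binomial(2, p_bin) per individual (HWE within bin);
* per-SNP depth Poisson with a per-individual mean λ; λ is either fixed or
  drawn log-uniformly from a (low, high) range to mimic the order-of-
  magnitude coverage spread of capture aDNA data (the study preset uses
  0.05–5×);
* reads supporting the adaptive allele Binomial(depth, q_G) with q as in
  the model table; an optional `damage_delta` adds a symmetric error
  increment on transition SNPs — a deliberate simplification of
  strand-resolved deamination, sufficient for ε-sensitivity studies;
* background SNPs start Uniform(0.05, 0.95) and drift by Wright–Fisher
  binomial resampling of 2Ne gametes per generation, with 0 and 1
  absorbing; bin-date gaps convert to generations at 29 years/generation
  (configurable);
* a single seed feeds a splittable SeedSequence with one stream per
  individual, so identical configurations give byte-identical fixtures.

What the simulator does **not** reproduce: reference bias, contamination,
within-read error correlation, strand-asymmetric damage, recombination
against the panel (complete linkage is assumed exactly), and non-HWE
structure such as inbreeding or relatedness. Passing tests therefore show
the estimators are correct under their own assumptions, not that those
assumptions hold for any particular excavation.

The study preset (`study_config`) fixes the simulated design to the
published cohort it stands in for: bins of 19/24/37/33 individuals at
generating frequencies 0.36/0.47/0.59/0.86. It is a synthetic stand-in —
the study's per-individual read counts are not bundled — so recovery of the
generating truth, not of any printed estimate, is the testable claim.

## Validation designs (sizes used)

* Oracle agreement: 200 random cohorts (N ≤ 30, per-individual t ≤ 8)
  against a 1e-5-step brute-force grid; agreement within 2e-4 for the MLE
  and both profile bounds.
* Interval coverage: 500 cohorts of N = 50 at p = 0.4, mean one read per
  individual, ε = 0.01; nominal 95% coverage within ±3%.
* Trajectory recovery: 100 replicates of three bins × 200 individuals at
  λ = 2, ε = 0.005, frequencies 0.36/0.47/0.59; truth inside the 95% CI in
  ≥ 90% per bin.
* Type-I error: 1000 drift-only replicates with the focal SNP exchangeable
  with 500 background SNPs (two bins of 25 individuals, λ = 1, ε = 0.01,
  Ne = 10 000, 52 generations between bins — roughly 1500 years at 29
  years/generation); rejection rate at α = 0.05 within [0.03, 0.07]. The
  exchangeability argument makes the expected rate ⌊α(M+1)⌋/(M+1) ≈ 0.0499
  regardless of estimator details; discreteness from tied estimates can
  only push it down.

## Design choices where the design was open

* The mpileup converter handles text, not BAM: mapping-quality filtering
  and any end-masking of damaged termini must happen upstream, because
  read-relative position is not recoverable from mpileup text. Bases
  matching neither ref nor the adaptive allele count toward t by default
  (they are evidence against the haplotype under the error model);
  `strict_biallelic=True` restricts t to ref/alt.
* Missing (individual, SNP) count rows mean zero coverage; writers omit
  all-zero rows.
* Chromosome names must match verbatim between panel and pileup — no
  "chr" normalisation, to avoid silent mismatches.
* The per-site ≥ 4-read rule and the pooled-total rule are both
  implemented because the calling rule's scope (every position vs. pooled)
  is ambiguous in the analysis this package mirrors; neither is asserted
  as the original intent.

## Known limitations

* ε and p are not jointly estimated; a badly wrong ε biases p̂ (the sweep
  utility quantifies this).
* Profile intervals rely on asymptotic χ² calibration; at very small N or
  extreme p the bootstrap alternative is the better check.
* The selection test conditions on the realised sampling design; it does
  not model ascertainment of the background SNP set.
* Wright–Fisher drift between bins treats bins as point times at their
  interval midpoints.
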