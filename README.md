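# adnahap

Adaptive-haplotype frequency trajectories from low-coverage ancient-DNA
read counts.

`adnahap` is built for the kind of question raised by the Tibetan *EPAS1*
locus: a selected haplotype, tagged by a panel of fully linked SNPs, whose
population frequency you want to track through time using ancient genomes
sequenced at anywhere from 0.01× to 10× coverage. At such depths individual
genotypes are often unknowable, so the package works directly with read
counts throughout:

* **Genotype posteriors.** With the panel SNPs in complete linkage, reads
  are pooled across sites into (r, t) — reads supporting the adaptive
  haplotype out of the total. Given G copies of the haplotype and a
  per-read error rate ε (sequencing error plus post-mortem deamination),
  the read-count likelihood is binomial, B(r, t, q) with q = 1−ε, ½, ε for
  G = 2, 1, 0, and a flat-prior Bayesian posterior over G follows by
  normalising the three likelihoods. Hard calls use the
  maximum-a-posteriori genotype gated on a coverage rule (by default at
  least four reads at every panel site).
* **Frequency estimation.** For a group of N individuals, the haplotype
  frequency p is estimated by maximising the Hardy–Weinberg mixture
  log-likelihood

      l(p) = Σᵢ log[ p² B(rᵢ,tᵢ,1−ε) + 2p(1−p) B(rᵢ,tᵢ,½) + (1−p)² B(rᵢ,tᵢ,ε) ]

  over p ∈ [0, 1] (dense grid plus golden-section refinement), with
  profile-likelihood 95% intervals (bootstrap optional). Zero-coverage
  individuals are handled exactly: they contribute nothing.
* **Trajectories.** Individuals are assigned to closed time bins in
  calibrated years B.P. and the per-bin estimates form the trajectory; the
  shipped preset uses the four groups older than 2500 B.P., 2400–1900 B.P.,
  1600–700 B.P. and present-day.
* **Selection test.** The focal older→newer frequency change is compared
  with the same statistic computed for genome-wide background SNPs on the
  same individuals; the one-sided add-one empirical p-value
  (1 + #{null ≥ observed}) / (1 + M) asks whether drift alone could
  produce the rise.
* **Synthetic data.** A seeded generator produces cohorts with HWE
  genotypes, Poisson per-SNP depth and the ε error process, plus neutral
  backgrounds drifting under Wright–Fisher — so every stage is testable
  end to end without sequence data, and the selection test can be
  calibrated under a drift-only null.

## Worked example

```python
from adnahap import (ErrorModel, estimate_trajectory, frequency_change,
                     study_bins, simulate_cohort, study_config)

counts, meta, panel, truth = simulate_cohort(study_config(seed=1))
traj = estimate_trajectory(counts, meta, panel, study_bins(), ErrorModel(0.01))
print(traj.to_frame()[["bin", "p_hat", "ci_low", "ci_high", "n"]].round(3))
print(f"change: {frequency_change(traj, 'older_2500', '1600_700'):+.3f}")
```

prints

```
       bin  p_hat  ci_low  ci_high  n
older_2500  0.370   0.215    0.545 19
 2400_1900  0.386   0.241    0.546 24
  1600_700  0.653   0.531    0.764 37
    modern  0.853   0.740    0.932 33
change: +0.283
```

The simulated cohort was generated at frequencies 0.36 / 0.47 / 0.59 / 0.86
with 19 / 24 / 37 / 33 individuals per bin and realistically sparse
coverage; each estimate recovers its generating value within the 95%
interval, and the +0.28 rise between the oldest ancient bin and the most
recent one is the statistic fed to the selection test.

The same pipeline runs from the shell on TSV inputs:

```sh
adnahap simulate --outdir fixture --background --seed 1
adnahap call --panel fixture/panel.tsv --counts fixture/counts.tsv \
             --meta fixture/meta.tsv --outdir calls
adnahap trajectory --panel fixture/panel.tsv --counts fixture/counts.tsv \
                   --meta fixture/meta.tsv --outdir traj
adnahap seltest --panel fixture/panel.tsv --counts fixture/counts.tsv \
                --meta fixture/meta.tsv \
                --background fixture/background_counts.tsv --outdir sel
```

`adnahap convert` turns single-sample `samtools mpileup` text into the
counts format under a base-quality ≥ 30 filter (mapping quality must be
filtered when producing the pileup).

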