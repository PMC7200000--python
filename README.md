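# gartergen

Genetic and demographic monitoring analyses for small, fragmented
wildlife populations — built around the combined SNP + trapping study
design used for the endangered San Francisco gartersnake
(*Thamnophis sirtalis tetrataenia*), and applicable to any system
where per-site SNP panels and closed-population capture histories are
collected together.

For conservation practitioners the package answers four linked
questions per site:

1. **How many adults are there (Na)?** A Bayesian closed-population
   capture–mark–recapture model with data augmentation: observed
   capture histories are padded with all-zero pseudo-histories to a
   pool M, inclusion indicators z ~ Bernoulli(ψ) make abundance
   N = Σz a posterior quantity, and capture probability is
   logit-linear in air temperature, sex, body size (SVL), a
   previous-capture response, and date/site/individual random effects
   (priors: p̄ ~ U(0,1), β ~ N(0, 3.16), σ ~ half-Cauchy(1)). Reported
   as the posterior mode with a 95% highest-posterior-density
   interval, plus sex-ratio posteriors. A Huggins
   conditional-likelihood estimator (Horvitz–Thompson N̂ = Σ 1/p̂*ᵢ) is
   available as an alternative.
2. **What is the effective size (Ne)?** Single-sample LD estimation
   from Burrows composite r² over unlinked SNP pairs (with the
   standard sampling-expectation correction and random-mating
   coefficients, jackknife-across-individuals CIs, Pcrit rare-allele
   screening), and the moment-based temporal method
   N̂e = t / (2(F̂c − 1/(2S₀) − 1/(2Sₜ))) when two sampling periods
   exist. Weak drift signals map to INF, never to negative estimates.
3. **How distinct and diverse are the sites?** Per-site Ho, He,
   nucleotide diversity π, rarefied allelic richness; pairwise and
   global Weir–Cockerham θ with permutation significance and
   Bonferroni correction; Mantel isolation-by-distance against
   great-circle distances.
4. **Who should rescue whom?** The genetic-rescue framework: for each
   recipient and four donor scenarios (nearest neighbor, max Ne, max
   He, max Na within the recipient's regional cluster), the mean
   inbreeding coefficient F = 1 − Ho(recipient)/He(donor), plus
   erosion flags (isolated; Na < 100 and Ne < 100; F > 10%).

A forward Wright–Fisher simulator (individual-based for LD,
frequency-based for speed) and a capture-history simulator make every
estimator testable against known truth without field data; the
published per-site summary tables of the gartersnake monitoring
program are bundled as a realistic worked example.

## Worked example

Rescue assessment from the bundled published site summaries:

```python
from gartergen.datasets import (load_focal_sites, load_diversity_summary,
                                preferred_ne_points)
from gartergen.rescue import rescue_table

table = rescue_table(load_focal_sites(), load_diversity_summary(),
                     preferred_ne_points())
print(table[table.recipient.isin(["Pacifica", "Mindego"])].to_string(index=False))
```

```
recipient   region scenario          source    F  isolated  small  F_gt_threshold
 Pacifica northern neighbor         Skyline 0.28      True   True            True
 Pacifica northern   max_Ne       San Bruno 0.21      True   True            True
 Pacifica northern   max_He Crystal Springs 0.28      True   True            True
 Pacifica northern   max_Na       San Bruno 0.21      True   True            True
  Mindego southern neighbor       Pescadero 0.13      True  False            True
  Mindego southern   max_Ne       Pescadero 0.13      True  False            True
  Mindego southern   max_He       Pescadero 0.13      True  False            True
  Mindego southern   max_Na            self  NaN      True  False            True
```

Pacifica's observed heterozygosity sits 21–28% below the expected
heterozygosity of every candidate donor in its cluster and the site is
small and isolated — the strongest rescue candidate. Mindego is
marginal (F = 0.13 against Pescadero); `self`/NaN marks a scenario
whose optimal donor is the recipient itself.

Abundance from simulated capture histories (truth N = 100, 10 daily
occasions, p = 0.2), and LD-based Ne from a simulated population of 50:

```python
import gartergen as gg
from gartergen.cmr import build_augmented_data, constant_p_config, fit_cmr, summarize_abundance

ds, truth = gg.simulate_capture_histories(
    gg.CaptureSimConfig(n_true=100, n_occasions=10, p_intercept=0.2, seed=1))
post = fit_cmr(build_augmented_data(ds, 300),
               constant_p_config(chains=3, iterations=4000, burn_in=1000,
                                 thin=2, seed=1), diagnostics=False)
print(summarize_abundance(post).to_string(index=False))

wf = gg.WrightFisherConfig(deme_sizes=[50], n_loci=200, generations=15,
                           sampling=[(15, 0, 30)], seed=4, mode="individual")
est = gg.ld_ne(gg.simulate_wright_fisher(wf)[(15, 0)], "deme0", pcrit=0.05)
print(f"LD Ne = {est.ne:.1f} (95% CI {est.ci_lower:.1f}-{est.ci_upper:.1f})")
```

```
 site  mode  hpdi_lower  hpdi_upper       mean
site1   104          96         115 105.341333
LD Ne = 53.5 (95% CI 31.5-157.8)
```

90 of the 100 true individuals were captured at least once; the
posterior mode 104 and HPDI [96, 115] bracket the truth. The LD
estimate 53.5 recovers the simulated Ne = 50 from a sample of 30
diploids at 200 unlinked loci (the wide, right-skewed CI is
characteristic of LD-based Ne at this sample size).

The same analyses are available from a console script — `gartergen
simulate`, `filter`, `diversity`, `fst`, `ibd`, `ne-ld`,
`ne-temporal`, `cmr-fit`, `cmr-summary`, `rescue`, and a YAML-driven
`run-all` that produces CSV tables plus a run manifest with seed and
config hash.

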