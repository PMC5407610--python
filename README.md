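# tibetscan

Selection scans, archaic-introgression statistics and coalescent simulation
for studying high-altitude adaptation in Tibetan populations — and, more
generally, for any two-population contrast with an archaic reference
genome.

Tibetan highlanders carry some of the clearest signatures of recent
positive selection in humans (*EPAS1*, *EGLN1*), and part of that adaptive
variation entered the population by admixture from a Denisovan-related
archaic lineage. Analysing such data requires three pieces working
together, and this package provides all of them as a tested, reusable
pipeline:

1. **A demographic simulator** (`tibetscan.simulate`): the fitted
   two-population Han–Tibetan history (split ~54 kya with strong gene flow
   until ~9.4 kya, exponential growth epochs), with optional Denisovan and
   Neanderthal admixture pulses and conditioned selective-sweep scenarios
   over a grid of selection coefficients s ∈ {0.02, 0.03, 0.04}, onset
   times (0–400 generations) and end frequencies (0.2–0.8).
2. **A composite selection scan** (`tibetscan.selection`,
   `tibetscan.cms`): the five component statistics iHS, XP-EHH, ΔiHH,
   F_ST (Hudson and Weir–Cockerham) and ΔDAF, combined per site in a
   naive-Bayes composite score

   CMS(x) = Σᵢ ln [ π fₛₑₗ(sᵢ) / (π fₛₑₗ(sᵢ) + (1−π) f₀(sᵢ)) ],

   with densities fₛₑₗ, f₀ learned from sweep and neutral simulations,
   empirical p-values against a simulated null, Benjamini–Hochberg
   q-values, 200-kb window aggregation and PBS for indels.
3. **Introgression statistics** (`tibetscan.introgression`,
   `tibetscan.dating`): the ABBA-BABA D statistic with 1-Mb block
   bootstrap, the window-level U statistic and the normalized D* (D divided
   by its within-U-group standard deviation), an S*-style dynamic-program
   scan for archaic haplotypes, a Q-style simultaneous estimator of the
   Denisovan and Neanderthal admixture fractions (m_D, m_N), permutation
   overlap tests against the scan's top windows, simulation-ML sweep
   dating, and gene-tree/population divergence-time estimation.

QC filters (`tibetscan.qc`) and window-resampling GO enrichment
(`tibetscan.enrichment`) round out the pipeline. Everything operates on
phased biallelic VCF plus a sample→population map, or directly on the
in-memory `HaplotypePanel`/`SiteFrequencyTable` containers.

## Worked example

```python
from tibetscan import (build_model, simulate_neutral, allele_counts,
                       genomewide_fst, site_fst, exact_binomial_ci)

model = build_model()                      # fitted point estimates
print(f"Han-Tibetan split: {model.divergence_time_years:.0f} years ago")

panel = simulate_neutral(model, sequence_length=2_000_000, seed=7)
d_t, _ = allele_counts(panel, "TIB")
d_h, _ = allele_counts(panel, "HAN")
fst = genomewide_fst(d_t, 54, d_h, 124, "hudson")
print(f"Hudson F_ST over {panel.n_sites} simulated sites: {fst:.4f}")

print(f"single-site F_ST (38/54 vs 0/124): {site_fst(38, 54, 0, 124):.3f}")
ci = exact_binomial_ci(1, 54)
print(f"rare-variant frequency {ci.point:.2%}, 95% CI [{ci.lower:.2%}, {ci.upper:.2%}]")
```

prints

```
Han-Tibetan split: 54007 years ago
Hudson F_ST over 9591 simulated sites: 0.0124
single-site F_ST (38/54 vs 0/124): 0.698
rare-variant frequency 1.85%, 95% CI [0.05%, 9.89%]
```

The split time is the fitted T2 + T3 = 54,007 years. The 2-Mb simulated
F_ST (0.0124) fluctuates around the model's genome-scale prediction of
~0.0147 (200 Mb brings it within ±0.003). The single-site F_ST of 0.698 is
the differentiation of a variant at derived frequency 38/54 in one sample
and absent from 124 comparison chromosomes, and the Clopper–Pearson
interval is the exact 95% CI for one carrier chromosome among 54.

## Command line

`tibetscan` exposes the pipeline stages as subcommands; all accept
`--seed`, `--out-dir` and an optional `--config` YAML overriding the
packaged defaults (`src/tibetscan/data/default_config.yaml`):

```sh
tibetscan simulate --scenario sweep --length 600000 --seed 11 --out-dir sim/
tibetscan scan-cms --vcf sim/panel.vcf --popmap sim/populations.tsv \
    --seed 11 --out-dir scan/
tibetscan scan-introgression --vcf arch/panel.vcf --popmap arch/populations.tsv \
    --archaic-track DEN arch/den_track.tsv --seed 5 --out-dir intro/
tibetscan date --vcf sim/panel.vcf --popmap sim/populations.tsv \
    --position 300000 --seed 11 --out-dir age/
tibetscan enrich --windows scan/cms_windows.tsv --genes genes.tsv \
    --terms terms.tsv --seed 1 --out enrich.tsv
```

Every artifact carries a provenance header (package version, seed,
parameters).

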