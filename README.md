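# cnr — copy-number-ratio comparative analysis for plant gene families

`cnr` asks a comparative-genomics question: **is a gene family expanded in
one plant life form relative to others, once genome size and shared
evolutionary history are accounted for?**  The motivating application is
DNA-repair gene families compared across trees, perennial herbs and annual
herbs — long-lived trees are expected to invest more in genome maintenance —
but every stage is generic.

## The statistics at the core

**Copy-number ratio.**  Raw family sizes scale with genome size, so counts
are normalized twice.  With `L_ij` the copy number of family `j` in species
`i`, `L_total,i` the species' total gene count, `N_j = Σ_i L_ij` and
`N_total = Σ_i L_total,i`:

    r_ij = (L_ij / L_total,i) / (N_j / N_total)

`r_ij` is dimensionless and, for every family, its gene-total-weighted mean
across species is exactly 1.

**PGLS with Pagel's λ.**  Related species are not independent samples.  The
per-family regression of `r_·j` on life form (trees as baseline) uses
generalized least squares with residual covariance `σ² V(λ)`, where
`V(λ)` has the Brownian-motion tip covariances (shared root-to-MRCA branch
length) off the diagonal, scaled by λ ∈ [0, 1].  λ is estimated by maximum
likelihood (grid + bounded refinement); coefficients are tested with
two-sided t statistics on `n − p` degrees of freedom.

**Screening.**  Per-contrast p-values across families receive Storey
q-values (π₀ estimated from the p-value histogram with a cubic smoother;
equal to Benjamini–Hochberg when π₀ = 1).  A family is flagged as *expanded
in trees* when both herb contrasts are negative with q < 0.05.  Species
profiles are also Ward-clustered (Ward.D2 on Euclidean distances) with
two-sided Fisher life-form enrichment tests and one-sample t tests of
cluster mean ratios against 1.  For tree species with known mean height
growth rates (m/year, an inverse longevity proxy), the ratio of selected
families is regressed on `ln(growth rate)` by the same PGLS machinery.

A seeded synthetic-data generator (`cnr simulate` / `cnr.simulate_bundle`)
produces the whole input stack — Yule tree, phylogenetically clumped life
forms, latent-Gaussian copy numbers with a planted tree-expanded family,
heterogeneous genome totals, growth rates anti-coupled to the planted
family — so the full pipeline is testable without any database download.

## Worked example

```bash
cnr simulate --seed 7 --out demo
cnr screen  --counts demo/counts.tsv --species demo/species.tsv \
            --tree demo/tree.nwk --out demo/screen.tsv
cnr growth  --counts demo/counts.tsv --species demo/species.tsv \
            --growth demo/growth.tsv --tree demo/tree.nwk \
            --families fam001 --out demo/growth_screen.tsv
```

prints

```
wrote bundle to demo
screened 121 families; 1 flagged as expanded in trees: fam001
growth screen on 23 tree species written to demo/growth_screen.tsv
```

`demo/truth.json` confirms `fam001` is the planted family.  In
`demo/screen.tsv` its row reads

```
lambda_hat = 0.243   perennial_herb_coef = -0.445 (q = 1.5e-4)
                     annual_herb_coef    = -0.434 (q = 2.8e-4)
expanded_in_trees = True
```

i.e. both herb groups carry roughly 0.44 fewer ratio units than trees — the
planted latent effect of −0.5 after count rounding and normalization — and
the residual phylogenetic signal is modest.  The growth screen on the 23
tree species gives a slope of −0.995 (SE 0.132, q = 2.2e-7): slow-growing
trees carry significantly more copies, as planted.

The same analyses are available as library functions (`compute_ratios`,
`run_family_screen`, `run_growth_screen`, `cluster_report`, `pgls_fit`,
`qvalues`, …); the CLI is a thin wrapper.

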