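# ibescape

Landscape-genomics analysis of isolation-by-distance (IBD) versus
isolation-by-environment (IBE) for GBS-derived SNP panels.

Páramo plants such as the *Espeletia* species complex occur as distinct
ecotypes — cloud-forest (F), wet-depression (W) and dry-slope (D)
populations — co-occurring within localities scattered along the northern
Andes. Two processes can structure their genomes: geographic isolation
(genetic differentiation grows with distance, IBD) and ecological isolation
(differentiation tracks habitat contrast independent of geography, IBE).
`ibescape` implements the full analysis chain used to separate the two
signals, for population geneticists working with sparse reduced-representation
genotype matrices:

* **Filtering** — the GBS rule set: mean read count per locus > 5, minor
  allele frequency (MAF) > 5%, genotype call rate ≥ 72%, plus an explicit
  sample-exclusion list.
* **Structure summaries** — principal coordinates (classical scaling of
  1 − IBS allele sharing), hierarchical AMOVA
  (locality / habitat-within-locality / within-population), and Evanno's
  ΔK = |L″(K)|/s(K) from externally supplied clustering log-likelihoods.
* **Genome–environment association (GEA)** — per-SNP dosage regressed on a
  fixed factor (categorical locality, or ordinal frost / soil-moisture
  habitat rank) with a phylogenetic covariate, tested by partial *F*.
  Both ordinary least squares (GLM) and a single-random-effect mixed model
  (MLM) with an identity-by-state kinship are provided; the mixed model
  profiles δ = σ²ₑ/σ²_g by REML after one eigendecomposition of the kinship
  (EMMA), either per locus or once under the null (P3D). Strict Bonferroni
  thresholds α/n select associated markers.
* **Divergence and gene flow** — pairwise Weir–Cockerham *F*_ST
  (θ̂ = Σa / Σ(a+b+c) over loci), Rousset linearization *F*_ST/(1 − *F*_ST),
  migrants per generation from the island-model equilibrium
  *F*_ST = 1/(1 + 4*N*m), and migration-network group contrasts
  (among habitats within locality vs. within habitat across localities).
* **IBD/IBE contrasts** — great-circle geographic distances, habitat-rank
  ecological distances, and one-sided permutation Mantel tests for every
  dataset partition (population subsets × marker subsets), reported with
  per-dataset Bonferroni thresholds α/N_PW.
* **Synthetic data** — a Balding–Nichols generator that reproduces the study
  design (6 localities, 3 habitats, 19 populations, 162 samples, 1,273 SNPs)
  with distance-structured drift and planted habitat-shifted loci, and a
  two-deme Wright–Fisher simulator for validating the migration estimator.

## Worked example

Simulate a dataset with the study's design and run the full pipeline:

```python
import ibescape as ib

config = ib.espeletia_config(seed=42)
G, S, truth = ib.simulate_dataset(config)
report = ib.run_pipeline(ib.RunConfig(seed=42, model_family="glm"), G=G, S=S)
```

With seed 42 this prints (via `report.counts` and the `ibd_ibe` table):

```
loci kept after filtering: 1018 / 1273
populations: 19
association scans run: 9
dataset partitions: 11
Mantel tests: 33
entire dataset: r(genetic, geographic) = 0.97 (p = 0.0010)
habitat contrast, frost-associated markers: r(genetic, frost) = 0.88 (p = 0.0050), r(genetic, geographic) = -0.18 (p = 0.9331)
```

Reading the numbers: across all 19 populations, linearized *F*_ST correlates
strongly with geographic distance (IBD; the permutation p is at the floor
attainable with 1,000 permutations). Restricting to the two localities where
habitats are contrasted and to the frost-associated markers, the correlation
moves to the frost-rank distance while the geographic correlation vanishes —
the IBE signature emerging once IBD is controlled by design. The 11 dataset
partitions and 33 Mantel tests mirror the partition series of the study
design (the locality-contrast × moisture-associated combination drops out for
lack of polymorphism).

The same analysis is available from the shell:

```sh
ibescape simulate --seed 42 --preset espeletia --out-dir sim/
ibescape run --config run.yaml --seed 42
```

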