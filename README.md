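# soilnet

Analysis toolkit linking the **temporal stability of experimental plant
communities** to the **topology of their soil microbial co-occurrence
networks**.

The setting is a long-running mesocosm experiment: plant communities sown on
two soil origins (natural grassland vs abandoned arable), censused annually
for 13 years with natural species invasion starting partway through, and
profiled at the end for soil chemistry and prokaryote (16S) / fungal (ITS)
OTU communities.  The question is whether plant communities whose
aboveground productivity is stable over time sit on soils whose prokaryote
and fungal networks respond *independently* of each other (decoupled), and
whether plant effects reach the microbiome directly or via soil chemistry.

## The computational chain

1. **Plant metrics** (`soilnet.plants`) — Shannon diversity
   H = −Σ pₛ ln pₛ; temporal stability μ/σ (inverse coefficient of
   variation of productivity, first census year dropped); invasion impact
   (value₂₀₁₂ − value₂₀₁₁; 2013 − 2011 for diversity) and developmental
   trajectories (standardized slope of value on year, 2012–2019).
2. **OTU preparation** (`soilnet.prep`) — rare-OTU filtering (< 100 total
   reads or present in < 5 samples), rarefaction without replacement,
   multi-rarefied Shannon, the centered log-ratio transform, and the habitat
   **specialisation index**

       SIᵢ = σᵢ/μᵢ − √(K/Nᵢ)

   (coefficient of variation of OTU *i*'s reads across samples minus an
   under-sampling correction; K habitat classes, Nᵢ total reads), with
   community-weighted means, box-plot-fence generalist/specialist calls and
   ln-response-ratio enrichment between the soils.
3. **Network inference** (`soilnet.netinfer`) — per-OTU L1-penalized
   neighborhood regressions on clr data, symmetrized by the "or" rule with
   max-magnitude signed weights; penalty chosen by **StARS** stability
   selection (edge instability 2θ(1−θ) over subsamples, monotonized mean
   ≤ 0.05).
4. **Signed clustering** (`soilnet.clustering`) — spin-glass-style simulated
   annealing of the signed modularity
   Q = (w⁺Q⁺ − w⁻Q⁻)/(w⁺ + w⁻), positive and negative edges equally
   weighted (γ⁺ = γ⁻ = 1), clusters numbered by prevalence; exact
   enumeration oracle for small graphs.
5. **Null models** (`soilnet.nulls`) — degree-preserving double-edge-swap
   rewiring with the signed weight multiset permuted onto the new edges;
   empirical p = proportion of rewired statistics smaller than observed.
6. **Coupling** (`soilnet.coupling`) — per mesocosm, the **coupling beta**:
   the standardized slope (= Pearson r) between the relative reads of
   rank-matched prokaryote and fungal clusters 1–9; Bonferroni-corrected
   mixed-model correlation tables; ln(stability) ~ beta with soil as a
   random factor (type-III Wald χ²).
7. **Path models** (`soilnet.sem`) — piecewise structural equation models:
   per-equation standardized regressions with a sowing-density random
   intercept, Shipley d-separation tests (Fisher's C = −2Σ ln p,
   df = 2k), AICc backward elimination, and the 2×2×2
   **relative-contribution ledger** (year/past × overall/compositional ×
   direct/indirect, each |β| weighted by the microbial pool's relative
   size and scaled by candidate-pathway counts).
8. **Synthetic data** (`soilnet.synthetic`) — a generator that emulates all
   of the above with planted ground truth: cluster blocks, per-soil
   prokaryote–fungal coupling ρ, habitat specialists with a known fold
   change, and a known plant → chemistry → microbiome path structure.

## Worked example

The numbered drivers under `analysis/` run the whole chain on a synthetic
dataset (60 mesocosms, 150 + 150 OTUs, seed 1):

```bash
python analysis/01_simulate.py      --seed 1
python analysis/02_plant_metrics.py
python analysis/03_prepare_otus.py  --seed 1
python analysis/04_networks.py      --seed 1
python analysis/05_coupling.py
python analysis/06_null_models.py   --seed 1
python analysis/07_path_models.py
```

Output of steps 2, 4, 5 and 6 on this seed:

```
Shannon diversity 2011 -> 2013: 1.983 -> 2.335 (invasion pulse)
mean temporal stability by soil:
  abandoned: 7.62
  natural: 7.51

prokaryote: lambda* = 0.1696, 766 edges (116 negative), 14 clusters, Q = 0.765, ARI vs planted blocks = 0.746
fungal:     lambda* = 0.1713, 736 edges (75 negative),  14 clusters, Q = 0.798, ARI vs planted blocks = 0.755

coupling beta over 9 rank-matched cluster pairs: mean 0.502, range [-0.563, 0.931]
cross-domain correlations: 61 of 196 significant at per-test alpha 0.0018 (28 clusters)
ln(stability) ~ coupling beta: slope -0.099, Wald chi2 1.095, p 0.295 (n = 60)

prokaryote: Q = 0.717 vs null mean 0.359 over 99 rewires -> p_upper = 0.000 (denser clustering than chance)
fungal:     Q = 0.758 vs null mean 0.364 over 99 rewires -> p_upper = 0.000 (denser clustering than chance)
```

Reading this: the invasion pulse lifts diversity by ~0.35 nats; the
inference chain recovers the planted cluster blocks well (ARI ≈ 0.75) and
both networks are significantly more modular than degree-matched rewirings;
the mean coupling beta of 0.50 reflects the generator's planted ρ = 0.4
plus the shared cluster-size profile of the two domains.  The
stability–coupling slope is null here because the default generator plants
no stability→coupling link — `tests/test_acceptance.py` shows the test
recovering a planted slope of −2 when one exists.

The same chain is scriptable through the `soilnet` CLI
(`soilnet simulate`, `soilnet run-all --config <yaml>`, ...) or the library
API.

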