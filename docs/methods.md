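# Methods

This note documents the models, defaults and design choices behind the
package, in the order of the analysis chain.

## Plant community descriptors

Shannon diversity uses natural logarithms over positive biomass shares.
Temporal stability is the inverse coefficient of variation μ/σ of total
aboveground productivity across census years, with the **sample** (n−1)
standard deviation and the first census year excluded by default —
establishing communities fluctuate disproportionately, and whether "first
year" means one or two early harvests is immaterial here because the
generator emits one census per year.  Constant series raise a
degenerate-series error instead of returning infinity: every downstream
model requires finite responses.

Past parameters: the invasion impact is the plain difference between the
last pre-invasion census (2011) and the first invaded one (2012); plant
diversity reacts over two seasons, so its impact window is 2011→2013.
Developmental trajectories are standardized slopes of the 2012–2019
series, computed on centered years; the standardized slope of a simple
regression equals the Pearson correlation of value with year, which the
tests assert numerically.

## OTU preparation

Filtering keeps OTUs with ≥ 100 total reads **and** presence (count > 0) in
≥ 5 samples; the quoted exclusions are strict "less than", so the
boundaries are retained.  Rarefaction is a multivariate hypergeometric
subsample (without replacement) to the smallest sample total by default;
retained sample sums equal the depth exactly, and shallower samples are
dropped with a warning.  The clr transform is ln(x + pc) minus the
per-sample mean log, pseudocount 1 by default (0 allowed on positive
tables, where clr is scale-invariant).

The specialisation index SIᵢ = σᵢ/μᵢ − √(K/Nᵢ) is computed on rarefied
counts across **all** samples of both habitats, σ the sample (n−1)
standard deviation — the convention is not dictated by the index itself,
so the package uses the same (n−1) convention as the plant metrics and the
invariant suite recomputes the identity from the stored σ, μ, K, N at
1e−12.  OTUs with zero reads after rarefaction are excluded and listed.
Cluster-level generalist/specialist and enrichment calls both
operationalize "no overlap with the distribution extreme" as the box-plot
fences Q1 − 1.5·IQR and Q3 + 1.5·IQR — the only fence rule the source
analysis states — with the median as the sign's central tendency for
enrichment and the cluster mean SI for specialisation.  Enrichment ratios
are computed on habitat-summed rarefied counts with pseudocount 1; per-OTU
(not per-sample) ratios feed the cluster fences.

## Network inference

Neighborhood selection regresses each OTU's clr profile on all others with
an L1 penalty (scikit-learn's coordinate descent on standardized columns).
An undirected edge exists when either directed coefficient is nonzero
("or" rule); its weight is the larger-magnitude coefficient with its sign —
the symmetrization rule is not specified by the field's standard tooling
output, so the package fixes this one.  At λ = 0 with n > p the
neighborhoods reduce to OLS partial regressions, which the tests use as an
unpenalized oracle.

StARS: 20 log-spaced penalties from λ_max (largest absolute pairwise
correlation — the smallest penalty with an empty graph) down to 0.01·λ_max;
subsamples of 80 % drawn without replacement (999 by default, scaled down
to 20–50 in desk-scale runs); per-edge instability 2θ(1−θ) averaged over
all p(p−1)/2 possible edges; the mean curve is monotonized along the path
and the **smallest** penalty whose monotonized instability stays ≤ 0.05 is
selected — the densest graph that is still stable, which is the canonical
selection rule and the only one consistent with a nondecreasing
monotonized curve.  The final network is refit on the full data at the
selected penalty (whether to reuse path weights or refit is a genuinely
open choice; refitting avoids subsample noise in the weights).

## Signed clustering

Partition quality is Q = (w⁺Q⁺ − w⁻Q⁻)/(w⁺ + w⁻) with Q± ordinary
weighted modularities of the positive/negative subgraphs and resolution
parameters γ⁺ = γ⁻ = 1 — present/absent and positive/negative edges get
equal importance.  Optimization is simulated annealing over single-node
moves (geometric cooling, 30 temperatures, 2·p moves per temperature, 5
restarts, unconstrained cluster count) followed by a greedy local pass;
move evaluation is incremental (O(degree) per move) and the final Q is
re-verified against the direct evaluation.  On all ≤ 8-node suite graphs
the annealer attains the exhaustive-enumeration optimum exactly.  Clusters
are renumbered by descending total relative reads (node count when no
abundances are supplied), ties broken by the smallest member id — this
prevalence ordering is what makes "cluster k prokaryote vs cluster k
fungal" a meaningful rank-matched pair downstream.

## Null models

Rewiring uses double edge swaps (10 per edge by default, a standard
burn-in), which preserve every degree exactly and keep the graph simple;
the original multiset of signed weights is then randomly permuted onto the
new edge set, preserving the weight distribution the coupling statistic
depends on — weight handling under rewiring is otherwise unspecified.
Cluster detection is re-run on every rewired replicate.  The empirical p is
reported in the literal one-tailed form "proportion of randomized
statistics **smaller** than observed" (ties conservatively counted as not
smaller), together with its complement, so callers can test either tail.

## Coupling statistics

The coupling beta standardizes both rank-matched cluster-abundance vectors
(after the transform policy) and takes the simple-regression slope, which
equals their Pearson correlation — so the regression direction is
immaterial and |β| ≤ 1 by construction.  Default 9 cluster pairs, fewer
when a domain has fewer clusters (min 3).

Transform policy (shared with the path models): fit, Shapiro–Wilk on the
residuals at α = 0.05; if non-normal try ln (positive responses only),
then sqrt; the first passing transform is kept, none otherwise.

Bonferroni: the per-test α is family α divided by a denominator that
defaults to the **cluster count** of the soil — the only denominator that
reproduces both printed thresholds (0.05/30 → 0.0017, 0.05/28 → 0.0018)
— with the pair-count denominator available as an option.  Note the
cluster-count denominator divides by fewer than the number of tests when
pairs exceed clusters and is then anti-conservative; the type-I
calibration suite therefore exercises the pair-count mode, and the
cluster-count mode is reserved for reproducing the original thresholds.

The stability–coupling test fits ln(stability) ~ beta with a random
intercept on soil; the Wald χ² is (estimate/SE)², which equals the
type-III statistic for a single fixed effect, with p from χ²(1).

### Mixed-model engine

All random-intercept fits go through a dedicated profile-ML fitter
(`soilnet.lmm`): with one grouping factor the covariance is
σₑ²(I + γZZ'), and for fixed γ the GLS estimate, profiled σₑ² and
log-likelihood are closed-form, leaving a bounded one-dimensional search
over log γ.  This is exact for the single-variance-component models used
throughout, markedly faster than a general mixed-model optimizer in the
thousands-of-small-fits regime of backward elimination, and it is
cross-checked against statsmodels' MixedLM (ML) in the test suite.
Fixed-effect p-values are Wald z; random intercepts are honored when the
grouping has ≥ 2 levels (≥ 3 observations per level in the path models),
otherwise plain least squares.

## Path models

Each model is a DAG over standardized observed variables, fit equation by
equation with the sowing-density random intercept, by ML so AICc values
are comparable across elimination steps.  Equation AICc uses
k = fixed effects (incl. intercept) + residual variance (+ the random
intercept variance when mixed); the model AICc sums component equations,
with endogenous variables lacking retained parents contributing
intercept-only equations so the sum stays comparable — "dropping" a
variable is thus its edge set going empty rather than its equation leaving
the ledger of fits.

The d-separation basis set contains one claim per missing edge: for each
non-adjacent pair (x before y topologically), x ⫫ y given
parents(x) ∪ parents(y), including pairs of exogenous variables; each
claim is tested as the p-value of x in the regression of y on x plus the
conditioning set, and combined as Fisher's C = −2Σ ln p with 2k degrees of
freedom.  The basis set is verified against brute-force d-separation on
small DAGs.

Backward elimination removes, at each step, the retained edge with the
largest p (ties: smaller |β|), refits the affected equation, records the
model AICc, and returns the AICc-minimal model along the full path to the
empty graph, with the complete history.

Model construction mirrors the field design: per soil, three base models
(year, past-overall, past-compositional plant parameters, each against the
eight chemical mediators — total N, organic C, pH, available P, NO₃, NH₄,
NO₂, belowground productivity) are eliminated separately and merged as the
**union** of retained plant→chemistry edges (how to merge differing
retained sets is open; the union is the permissive choice, letting the
final elimination re-decide).  Each microbial variable then gets one model:
the merged base plus all chemistry→microbe and direct plant→microbe
candidates, eliminated again.  Candidate ("potential") pathway counts for
the ledger are taken **pre-elimination**, and a > 5 %-of-total filter for
reporting dominant pathways is available on the ledger frame.

Contributions use absolute standardized effects — the grouped comparison
is about magnitude, not direction — of significant (p < 0.05) retained
paths: direct |β|·size, indirect |β_plant→chem · β_chem→microbe|·size,
where size is the microbial variable's mean relative abundance (its share
of the community it is measured in).  Group sums are scaled by candidate
counts; the conservation identity Σ scaled·count = Σ raw is asserted.
Heteroscedasticity weighting by per-soil variance structures is
deliberately not implemented; fits are unweighted.

## Synthetic generator

The generator's defaults are the study conditions: 2 soils × 30 mesocosms
(n = 60), annual censuses 2007–2019 with invasion onset 2012, 12 sown + 8
invader species, 150 OTUs in 5 clusters per domain, sequencing depth
negative-binomial around 5000 reads, coupling ρ = 0.4 in both soils, 20 %
specialists at fold change 8.

Plant series: species shares are a softmax of per-species logits that
drift as a random walk and concentrate slowly (diversity declines);
invaders enter at the onset year with their own logits (diversity jumps;
invader share > 0 only after onset); total productivity is year-stationary
log-normal noise around 600 g.  Three latent compositional axes are
emitted directly as AR(1) series with a soil offset and an onset shock on
axis 1 — they stand in for ordination scores, which are pipeline inputs,
not computations.

Chemistry: each variable is a linear combination of standardized plant
summaries via the configured path coefficients, plus a soil offset and
Gaussian noise (variance topped up toward 1 so coefficients read as
standardized effects), then shifted to plausible field units.

Microbes: cluster latent factors per mesocosm, with prokaryote cluster k
and fungal cluster k sharing a factor at correlation ρ per soil —
coupling is planted at rank-matched cluster level because that is what the
coupling beta measures.  Chemistry and direct plant effects enter the
factors additively.  Cluster log-masses add a geometric base profile
(ratio 0.65, keeping prevalence ranks stable) and scale the factors by
`cluster_signal_sd`; OTUs split their cluster's mass evenly, modulated by
a fixed per-OTU effect, a soil-dependent specialist offset of
±½·ln(fold change), and per-sample log-normal noise (`nb_dispersion`).
Counts are one multinomial per sample conditioned on a negative-binomial
depth, so totals match the drawn depth exactly and the data are
compositional, which is exactly what the clr-based inference assumes.

What the generator does **not** emulate: phylogenetic structure and
taxonomy, sequencing error and chimeras, mesocosm-level temporal
autocorrelation in the microbiome (one sampling time point), real
ecological interactions (no Lotka–Volterra dynamics), and any
stability→coupling causal link under the defaults — so a null
stability–coupling slope on default synthetic data is correct behavior,
and passing recovery tests certify the estimators, not the ecology.

## Problem sizes in tests and the acceptance script

Desk-scale runs shrink the expensive knobs, never the logic: StARS uses
20–50 subsamples (default 999), rewiring ensembles R = 99 (default 1000),
cluster counts 3–5, OTU counts 40–150, and the recovery suites run 10–30
seeded replicates.  The path-model recovery scenarios use a focused
candidate set of six plant variables (the full fifteen leave the saturated
microbial equation with 6 residual degrees of freedom at n = 30, where
direct-vs-mediated attribution is essentially noise) and compare the
ledger's **raw** group sums — the potential-pathway scaling divides
indirect groups by roughly eightfold more candidates than direct groups,
so the scaled comparison would measure the scaling convention rather than
recovery.  In the mediated scenario the plant→chemistry effects are kept
at 0.7 so the mediator remains statistically distinguishable from the
plant variable it carries; chemistry→microbe effects of 1.2 on the latent
log scale realize as observed standardized betas around 0.6–0.7 after the
compositional count layer dilutes them.

## Known limitations

- Networks in the bundled pipeline are inferred per domain across both
  soils; the per-soil variant is a matter of subsetting samples first (as
  the field design does) and the analysis drivers document the joint
  choice.
- Mixed-model p-values are Wald z (large-sample); with n = 30 and many
  predictors they are approximate, as in any piecewise-SEM workflow at
  this scale.
- The d-sep basis set includes exogenous–exogenous pairs; correlated
  exogenous plant parameters therefore depress the model p even when the
  directed structure is right.  Fisher's C is reported for transparency,
  not used for selection (AICc is).
- The spin-glass annealer is exact on the small-graph suite but heuristic
  in general; restarts mitigate, and the modularity of any returned
  partition is exact.
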