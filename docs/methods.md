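# Methods

`cellumend` links three strands of analysis around cellulose-decomposing
soil communities: (i) community-level genomic traits and functional-gene
response ratios, (ii) community comparison and assembly statistics with
co-occurrence networks, and (iii) a microbial-enzyme decomposition model
whose calibration can be informed by cellulose-decomposing gene
abundances.  All inputs can be generated synthetically, so the whole
pipeline is testable without field data.  This note documents the
models, the defaults and the design choices that were genuinely open.

## Decomposition model

### Pools and fluxes

Eleven carbon pools, all in mg C g⁻¹ soil: particulate organic matter
split into an oxidative-enzyme substrate `P1` and a hydrolytic-enzyme
substrate `P2`; mineral-associated organic matter `M`; dissolved
organic carbon `D`; DOC adsorbed to minerals `Q`; active and dormant
microbial biomass `BA`, `BD`; enzyme pools `EP1`, `EP2` (attacking P1
and P2) and `EM` (attacking M); and cumulative respired carbon
`CO2_cum`, carried as a pool so conservation is an algebraic identity.

Fluxes (superscript T marks rates scaled by temperature and moisture,
see below):

| flux | expression | from → to |
|---|---|---|
| POM decomposition | `F_Pi = Vpiᵀ·EPi·Pi/(Kpi+Pi)` | Pi → D (fraction fD) and M (1−fD) |
| MOM decomposition | `F_M = Vmᵀ·EM·M/(Km+M)` | M → D |
| uptake | `U = (Vdᵀ+mRᵀ)·BA·D/(Kd+D)/Ec` | D → BA (Ec·U) and CO2 ((1−Ec)·U) |
| maintenance | `mRᵀ·BA` | BA → CO2 |
| enzyme production | `pEP·mRᵀ·BA` per pool | BA → EP1, EP2, EM |
| enzyme turnover | `rE·EPx` | EPx → D |
| mortality | `γ·BA` | BA → P2 (fMort_P2) and D (rest) |
| adsorption / desorption | `Kads·D·(1−Q/Qmax)`, `Kdes·Q/Qmax` | D ↔ Q |
| dormancy (optional) | `dorm_rate·(1−D/(Kd+D))·BA`, `dorm_rate·(D/(Kd+D))·BD` | BA ↔ BD |
| litter input | `I·(fI_P1, fI_P2, fI_D)` | external → P1, P2, D |

Heterotrophic respiration is `Rh = (1−Ec)·U + mRᵀ·BA`.  Every flux
leaves exactly one pool and enters exactly one pool or the CO2 sink, so
`Σpools(t) − Σpools(0) = Σ input` exactly; the acceptance suite checks
this to 1e−8 relative (it holds to ~1e−13, pure rounding).

This is one concrete, mass-balanced member of the microbial-enzyme
model family.  The structural commitments — three SOM pools with
dedicated enzyme pools, Michaelis–Menten kinetics, Q10 temperature
response, an adsorbed-DOC buffer and a dormancy switch — are fixed;
details such as the mortality split (half to P2, half to D) and the
litter-input partition (0.35/0.45/0.20 to P1/P2/D) are conventions,
exposed as parameters.

### Environmental scaling

All maximal rates (`Vp1, Vp2, Vm, Vd, mR`) are multiplied by
`Q10^((T−Tref)/10)` and by a moisture factor `f_W = min(1, (W/W_opt)^b)`
with `W_opt = 0.40` v/v and `b = 0.25`.  The flat exponent is
deliberate: with the study's paired forcing (+1.8 °C and −17% moisture
under warming) a steep moisture response (b ≳ 0.5) makes the moisture
penalty outweigh the Q10 gain and warming *suppresses* respiration,
the opposite of what warming manipulations of this kind report.  With
b = 0.25 the simulated warming response is a 9% rise in respiration and
increases in biomass, active biomass and all three pool-specific
decomposition rates — the qualitative pattern the synthetic conditions
are meant to emulate.  `b` and `W_opt` are ordinary parameters for
users with a different moisture regime.

### Integration

Classical RK4 with forcing held constant within each day; default two
substeps per day.  A day producing a negative pool (possible when DOC
is drawn down fast) is re-integrated with doubled substeps, up to eight
doublings.  Intermediate RK stages clamp negative pool values to zero
inside the derivative only.  At two substeps per day the cumulative
respiration over a simulated year differs from a run at twice the
resolution by ~4e−6 relative; at four substeps per day the halving
difference is ~1e−7.  Calibration batteries use one substep per day
(error far below the 10% observation noise they fit); convergence
tests use four.

Default parameters are round numbers typical of the model family
(e.g. `Ec = 0.4`, `mR = 0.01 d⁻¹`, `Q10 = 2`), with `Tref = 16.3` °C
(the site's mean annual temperature) and litter input ~5 µg C g⁻¹ d⁻¹.
Under constant forcing the model approaches a fixed point; because the
dormant pool exchanges carbon on multi-millennial timescales, the
documented reference set for the steady-state check uses fast kinetics
and dormancy off (16 000 days to |ΔRh| < 1e−6 per 100 days).

## Calibration

The objective is `J = Σ wᵢ(1−Jᵢ)` with `J1`, `J2` the coefficients of
determination of simulated vs observed daily respiration and microbial
biomass carbon, and `J3` the Pearson (optionally Spearman)
correlation between the simulated hydrolytic enzyme pool EP2 and an
observed cellulose-gene abundance series at the sampling dates.
`w3 = 0` is the traditional mode (tMEND); `w3 > 0` the gene-informed
mode (gMEND).  R² values can be negative for poor fits and are floored
(default −1) before aggregation.  The weighted-sum combination and
equal default weights are this package's choice; no canonical
combination rule exists for this family of objectives.

Minimization is Shuffled Complex Evolution (SCE-UA): Latin-hypercube
initialization, partition into complexes, competitive simplex evolution
(reflection → contraction → random replacement) inside each complex,
periodic shuffling.  Out-of-bounds reflections are resampled uniformly
inside the bounds.  Every evaluated point is recorded; the optimizer is
deterministic given its seed.

Parameter uncertainty uses the critical objective function index:
`J_crit = J_min·(1 + p/(n−p)·F₁₋α(p, n−p))` with `p` calibrated
parameters and `n` observations (the gene series counts toward `n`
only in gene-informed mode); the feasible set is every evaluated point
with `J ≤ J_crit` and per-parameter uncertainty is the coefficient of
variation over that set.

Two documented parameter subsets are used in the test batteries rather
than the full 13-parameter bound table:

* **Recovery subset** `(Vd, Ec, mR, Q10)` — each has a distinct
  signature (uptake level, respiration yield, baseline maintenance,
  temperature sensitivity), so noise-free observations identify them
  essentially exactly; pairs such as `(Vp2, Kp2)` are
  ratio-identifiable only and would not meet a 10% recovery bound.
* **Uncertainty subset** `(Vd, Ec, rE, pEP)` — includes the enzyme
  turnover `rE`, which shapes the EP2 trajectory and is therefore the
  parameter the gene correlation constrains most, and `pEP`, which
  scales EP2 without changing its shape (a scale the correlation is
  deliberately blind to).

With a gene series that tracks EP2 (noise 0.1 × signal sd), the mean
COFI coefficient of variation under the gene-informed objective is
smaller than under the traditional one on the ~20-seed batteries the
tests run; the margin is modest and individual seeds can go either way.

## Synthetic data

The generators define the study-shaped conditions everything is tested
under.

* **Communities.** Four groups (warmed/control × litterbag/soil) of 12
  samples.  Each habitat has an equal-sized taxon set; litterbag and
  soil sets overlap by `shared_fraction = 0.79` of their size.  A
  global log-normal species-abundance distribution (σ = 1.5) gives
  per-taxon means; samples are Dirichlet-multinomial draws
  (concentration 50, sequencing depth 30 236) around the group mean.
  Litterbag groups divide the concentration by `dispersion_scale²`
  (default 1.5), reproducing the higher within-group dispersion of
  litterbag communities.  Enrichment effects multiply chosen taxa's
  means in chosen groups before closure, so planted fold-changes are
  compositional like everything else.
* **Trait reference.** A configurable fraction of taxa (default the
  21.56% genome-match rate typical of 16S-to-complete-genome mapping)
  carries integer rrn copy numbers and uniform genome size / GC values.
  Trait values are *not* correlated with habitat, so litterbag–soil
  trait contrasts in synthetic runs are null — the generator emulates
  data structure, not the field result.
* **Probe tables.** Log-normal probe intensities (log-scale sd 0.2),
  Bernoulli detection, per-gene fold-changes planted via an effect map;
  gene-level abundance is the sum over the gene's probes.
* **Forcing.** Sinusoidal temperature (mean 16.3 °C, amplitude 9 °C)
  and constant-mean moisture with Gaussian noise; warmed and control
  arms generated from one design share the same weather noise — they
  are the same field — so the warming contrast is exactly +1.8 °C and
  ×0.83 moisture.  Litter input follows a seasonal sinusoid truncated
  at zero.
* **Observations.** Respiration and biomass are model trajectories with
  multiplicative log-normal noise; the gene series is a positive affine
  map of EP2 plus additive noise scaled to the signal spread, so its
  noise-free correlation with EP2 is exactly 1.

What the generators do **not** emulate: phylogenetic structure, taxon
co-occurrence beyond shared means (so synthetic co-occurrence networks
are sparse and nearly random), trait–habitat covariance, probe
cross-hybridization, and autocorrelated weather.  Passing tests
demonstrate that the *methods* behave correctly under known structure,
not that field effect sizes are reproduced.

## Statistics

* **Distances.** Bray–Curtis on abundances, Sørensen (Dice) on
  presence/absence, via `scipy.spatial.distance`.
* **Ordination and dispersion.** Classical scaling (PCoA) by
  eigendecomposition of the double-centred squared-distance matrix,
  negative eigenvalues reported.  Distance-to-centroid dispersion
  embeds samples in the full PCoA space and applies the
  real² − imaginary² correction on axes with negative eigenvalues; the
  group comparison is a one-way F on the distances with a permutation
  p-value (distances shuffled among groups).
* **Stochasticity ratio (tNST).** Implemented exactly as the
  proportion-of-exceedance statistic: for every within-group pair and
  null replicate, both samples are randomized — richness preserved,
  taxa drawn without replacement with probability proportional to
  occurrence frequency in the group, the sample's own abundance values
  reassigned to the drawn taxa — and tNST is the fraction of
  comparisons where the observed Bray–Curtis exceeds the null one.
  Output is tagged "exceedance-proportion tNST": the published NST family
  includes several null models and weighting schemes, and this module
  deliberately implements only this exceedance form.  Self-consistency:
  communities assembled by the null process itself score 0.5 ± 0.05 at
  the 12-samples-per-group design (smaller groups bias the estimate
  upward because occurrence frequencies are estimated from the data).
* **Mantel / partial Mantel / MRM.** Pearson correlation (or OLS) on
  off-diagonal vectors; partial variants residualize on the third
  matrix.  Significance permutes rows/columns of one matrix jointly;
  p-values use the add-one estimator, so the smallest attainable p is
  1/(1+permutations).  Variance partitioning is hierarchical: abiotic
  share = R² of the abiotic-only model, biotic share = R² increment of
  the full model, remainder unexplained — the three sum to one by
  construction.
* **Response ratios.** RR = ln(mean_t/mean_c) with delta-method
  standard error `SE² = s_t²/(n_t·x̄_t²) + s_c²/(n_c·x̄_c²)`.  The
  interval uses a Student-t critical value with Welch–Satterthwaite
  degrees of freedom rather than 1.96: at n = 12 per group the normal
  interval covers ~93.6% and fails a 95% ± 1.5% coverage check, while
  the t interval is nominal.  Genes with a zero control mean but
  detected under treatment are reported as `treatment_only` (no finite
  RR), mirroring how such genes are flagged in warming contrasts.
  Probe preprocessing: per-group prevalence filter (< 3 detections out
  of 12 → undetected in that group), `ln(1+x)` transform (zeros stay
  zero), then per-sample sums scaled up to the maximum sample sum.

## Networks

Taxa detected in at least 6 of 12 samples enter; Spearman correlations
are computed on `ln(relative abundance + pseudocount)` with the
pseudocount set to half the smallest nonzero relative abundance; edges
keep `|r| ≥ threshold` with the sign stored as an attribute and
topology computed on the unweighted skeleton.  The threshold is either
fixed or chosen by the random-matrix-theory criterion: scan candidate
thresholds, and accept the smallest whose thresholded matrix has a
nearest-neighbour eigenvalue spacing distribution consistent with the
Poisson law (χ² goodness of fit, p > 0.05) after degenerate-eigenvalue
merging and polynomial unfolding of the spectral staircase.  Spectra
with too few distinct eigenvalues (fully fragmented networks) are
treated as Poisson-consistent.  Module detection is greedy modularity
maximization; geodesic distance is averaged over the largest connected
component.  Compositional closure is worth remembering when reading
signs: with very few taxa, relative abundances are anti-correlated by
construction.

## Reproducibility

Every random operation takes an explicit seed; the pipeline splits one
global seed per stage through `numpy.random.SeedSequence`, and a rerun
with the same configuration is bit-identical (the run directory's
manifest records the config hash and per-file SHA-256).  The demo
configuration exercises all stages in well under a minute at reduced
sizes (120 taxa, 200 probes, 2-year forcing, 120-evaluation SCE);
`scripts/acceptance.py` uses study-scale communities (500 taxa, depth
30 236, 12 samples per group, 3-year forcing) with calibration budgets
of 250–1500 evaluations.

## Known limitations

* The flux topology is one member of its model family; users fitting
  real observations should review the mortality split, input partition
  and moisture response against their site.
* The RMT threshold's χ² binning and unfolding polynomial degree are
  conventions; fixed-threshold mode is provided for strict
  reproducibility across implementations.
* tNST here is the exceedance-proportion statistic only; it is not
  numerically comparable to NST values from packages implementing other
  null models.
* COFI uncertainty is conditional on the optimizer's evaluation
  history: a short SCE run samples the near-optimal region sparsely and
  the CV is correspondingly coarse.
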