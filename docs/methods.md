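# Methods

## The settlement model

The model tracks the composition of a two-lineage metapopulation on an
ordered set of coastal sites, index 0 southernmost.  One generation
comprises reproduction, larval dispersal and saturated (lottery)
settlement:

1. adults at site `i` release larvae in proportion to their net fecundity
   `w_T(i)`: `R` for the lineage favored at `i`, `R (1 − Δw)` for the
   other, with favor switching at the break latitude `b` (northern lineage
   favored at latitudes ≥ `b` under the default orientation; the tie at
   exactly `b` goes to the northern side);
2. larvae disperse according to the connectivity matrix `C[i, j]`;
3. each site is fully recolonised by its arriving pool, so the new
   northern fraction is `f′(j) = L_N(j) / (L_N(j) + L_S(j))`.

Because only the composition of the pool matters, trajectories are exactly
invariant to `R` (verified to machine precision in the tests), and any row
scaling of `C` that is uniform within a row — including the offshore-loss
deficit — cancels from the dynamics.  Sites whose larval pool is empty
keep their previous composition: the model tracks composition, not
abundance.  Selection acts at the natal site (on fecundity), not at
settlement.  Dynamics are deterministic (infinite-population frequencies);
there is no drift, so "loss" of a lineage is declared when its fraction
falls below 1e-3 at every site.  An adult-turnover parameter `τ ∈ (0, 1]`
blends old and settler composition; the default `τ = 1` (non-overlapping
generations) is used throughout because the saturated limit makes results
growth-rate-invariant and fixed points do not depend on `τ`.

Steady states are found by iterating until the maximum site-wise change is
below `tol = 1e-8` or 5000 generations; non-convergence is reported in the
result object, never raised.

### Washout and the persistence threshold

With advection (mean displacement `μ` per generation, spread `σ`) and no
selection, the upstream lineage takes the whole domain: uniform
frequencies are neutral fixed points, and the final state is controlled by
upstream composition.  With a fitness step, a two-sided cline persists
only above a threshold differential.  A continuum estimate follows from
the washout condition for a rare favored type: growth `1/(1 − Δw)` must
exceed `exp(μ²/(2σ²))`, giving `Δw* ≈ 0.165` for the package's standard
kernel (`μ = 15` km, `σ = 25` km); on the discrete 10-km grid with a
finite favored region the measured threshold (bisection, reported by the
acceptance script) is ≈ 0.25.  Fitted differentials below this threshold
cannot hold any cline against this current field — the central
qualitative result the model exists to demonstrate.

## Fitting the fitness differential

The misfit is the sum of squared differences between modelled and observed
northern fractions at the observation sites, each observation row
contributing one term (repeat surveys of a site are passed as additional
observation sets).  Observed sites are matched to the nearest model
latitude within 0.25°; sample-size weighting (`n_j / Σn`) is available but
off by default.  Because exactly one parameter is free per candidate
break, the default optimiser is bounded scalar minimisation on
`Δw ∈ [0, 0.95]` (at `Δw = 1` the disfavored lineage is sterile and the
map degenerates); a Powell option is retained.  The best point ever
evaluated — always including `Δw = 0` — is returned, so the fitted misfit
never exceeds the neutral misfit.  Steady states for fitting start from
`f0 = 0.5` everywhere (configurable).  A break is flagged `improved` only
when the fitted misfit beats the neutral misfit by more than 1%; breaks
far upstream of the observed transition fail this flag, reproducing the
flat-misfit instability regime where the neutral fit and a very strong
differential are equally poor.

## Synthetic data: what it emulates and what it does not

* **Connectivity.**  A Gaussian advection–diffusion kernel in alongshore
  displacement, rows scaled to `1 − loss` before truncation at absorbing
  domain edges.  It emulates the first two moments of hydrodynamic
  connectivity (net downstream transport, spread, offshore loss) but none
  of the eddy structure, interannual variability or alongshore
  heterogeneity of a real current field; the readers accept arbitrary
  externally produced matrices.
* **Observed clines.**  A logistic (sigmoid) true cline with binomial
  per-site sampling.  The default logistic scale of 50 km emulates a
  lineage turnover completing over a few hundred km of coast, i.e. a
  transition from modest minority frequency to fixation across roughly
  three degrees of latitude.
* **Genotypes.**  Lineage allele frequencies follow a Balding–Nichols
  pair (common ancestral frequency uniform on [0.1, 0.9], divergence
  `F`), with idealised Mendelian hybrid classes (F1, F2, backcrosses),
  unlinked loci, mitotype equal to the maternal lineage (configurable for
  hybrids), MCAR missingness, and optional northern-panel ascertainment
  (loci monomorphic in the pooled pure-northern sample are redrawn).  An
  optional logit random walk of per-site frequencies along the grid
  creates within-lineage stepping-stone structure for
  isolation-by-distance tests (default walk SD 0.3 per step in those
  tests).  Real SNP panels add genotyping error, linkage and
  non-equilibrium site histories that are not modelled, so passing tests
  show estimator correctness, not field realism.
* **COI.**  Two haplotype backbones differing at `round(d · L)` positions
  (default `d = 0.034`, `L = 600`), with the SpeI site ACTAGT intact in a
  configurable lineage and disrupted by a single substitution in the
  other, plus low-rate within-lineage polymorphism constrained never to
  flip the digest.  Which lineage carries the site is a required
  configuration key everywhere downstream, since it is an empirical
  property of the assay.

All generators are pure functions of their arguments including the seed.

## Statistics

* **QC** is a two-stage filter applied in a fixed order: loci with a
  missing fraction strictly greater than 0.50 over all individuals are
  dropped first; individuals missing strictly more than 0.25 of the
  *remaining* loci are dropped second.  Both thresholds are strict
  inequalities, and the order matters (tests pin it on an adversarial
  fixture).  The filter is idempotent.
* **Gst.**  Per locus, `Hs` is the mean within-population expected
  heterozygosity and `Ht` the total expected heterozygosity; multilocus
  `Gst = (ΣHt − ΣHs)/ΣHt` over loci with data in both populations.  Both
  the raw Nei decomposition and the Nei–Chesser small-sample corrected
  estimator are computed; the corrected form is the default because the
  raw estimator is biased upward at field sample sizes.  Significance
  uses data-by-location permutations (individuals reassigned between the
  two sites at observed sample sizes), one-tailed, with the add-one
  convention `p = (1 + hits)/(B + 1)`.
* **Mantel.**  Pearson correlation over off-diagonal upper-triangle
  pairs; one-tailed permutation p by jointly permuting rows and columns of
  the second matrix, exhaustively enumerated whenever `n!` fits within
  the permutation budget (so 4-site problems always enumerate all 24
  relabellings).  Distances are great-circle (haversine) km between site
  coordinates; an alongshore path metric was considered and rejected as
  the default because site coordinates, not a coastline, are the
  package's input.  Partitioned analyses subset individuals by mitotype
  and recompute Gst within the lineage.
* **Cytonuclear disequilibrium.**  Allelic `D = P(A,M) − p_A p_M` over
  the `2n` allele-by-mitotype entries; genotypic `D1/D2/D3` over
  individuals.  The identities `D1 + D2 + D3 = 0`, `D = D1 + D2/2` and
  `|D| ≤ 1/4` hold exactly and are property-tested.  The allelic p-value
  is a two-sided Fisher exact test (conditional hypergeometric); the
  genotypic p-value is the Freeman–Halton exact test on the 3×2 table,
  enumerated fully when the table total is ≤ 200 and otherwise estimated
  by seeded Monte Carlo over at least 1e5 margin-preserving tables with
  the add-one convention.  Multiple testing uses plain Bonferroni over
  the testable loci.  Outlier-locus detection is *not* reimplemented
  (island-model outlier scans misbehave under isolation by distance);
  flags are consumed as external input and intersected with the
  Bonferroni-significant CND loci.

## Numerical and design choices

* Coordinates are decimal degrees, negative south/west; site index 0 is
  always southernmost and positive displacement is northward.
* Missing genotypes are coded −9 (STRUCTURE convention); the CSV dialect
  also accepts NA.
* Kernel construction normalises over a padded (effectively unbounded)
  grid so interior row sums equal `1 − loss` to 1e-12; edge rows sum to
  less (absorbing boundaries).
* The pipeline derives per-stage seeds from one master seed via
  `(seed · 1000003 + crc32(stage_name)) mod 2³¹`, so a full run is
  byte-reproducible and stages can be rerun in isolation.
* Problem sizes in the shipped demo and acceptance script (60–100 sites,
  tens of loci, hundreds of individuals, 10-seed recovery replicates)
  were chosen as the smallest sizes at which every property of interest
  is comfortably resolved.

## Known limitations

* The settlement model has no drift, age structure, seasonal release
  timing or explicit larval mortality schedule beyond the kernel's
  row-sum deficit; generations are discrete and annual.
* The fit is least-squares over a scalar parameter per break; no joint
  kernel-plus-fitness inference and no likelihood/Bayesian machinery.
* Parameter recovery for the fitted differential is only identifiable
  when the generating differential exceeds the kernel's persistence
  threshold: below it every `Δw` in the collapse region reproduces the
  same all-upstream steady state and the misfit surface is flat, so no
  optimiser can recover the generating value.  The test suite
  demonstrates recovery above the threshold (break located to within two
  sites, `Δw` to within 0.03) and documents the degenerate regime below
  it.
* In-silico mitotyping is perfectly accurate by construction; real
  restriction assays misclassify at a low rate that can be emulated only
  through the generator's within-lineage polymorphism, not through a
  calibrated confusion model.
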