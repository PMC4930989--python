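# coastcline

Tools for asking a classic seascape-genetics question: when two diverged
lineages of a coastal invertebrate meet along a one-dimensional shore with
a strong alongshore current, can their joint distribution persist under
larval dispersal alone, or does it require a spatial fitness difference
between the lineages?

The package is built around the situation of an intertidal barnacle on an
eastern-boundary coast: a northward (Humboldt-like) mean flow carries
larvae downstream, a southern mitochondrial lineage dominates the upstream
end of the range and a northern lineage the downstream end, and the
transition between them sits near a major biogeographic boundary.  It is
aimed at population geneticists and larval ecologists who have (i) per-site
lineage frequencies (mitotype counts or nuclear assignment probabilities),
(ii) a site-by-site larval connectivity matrix from a hydrodynamic model —
or want a tunable synthetic stand-in — and (iii) a SNP panel with
per-individual mitotypes.

## The model

Habitat is saturated (lottery competition): each generation, every site is
recolonised by its arriving larval pool.  Writing `f_j` for the
northern-lineage fraction at site `j` and `C[i, j]` for the probability
that a larva released at `i` settles at `j`, the larval supply of lineage
`T` at `j` is

```
L_T(j) = Σ_i C[i, j] · f_T(i) · w_T(i),     f_N = f,  f_S = 1 − f
```

where `w_T(i)` is the net fecundity of lineage `T` at its natal site: `R`
for the locally favored lineage and `R·(1 − Δw)` for the other, the favor
switching at a break latitude `b` (a step function).  The update

```
f′(j) = L_N(j) / (L_N(j) + L_S(j))
```

is iterated to a steady state; in this saturated limit the results are
invariant to `R`.  The fitness differential `Δw` is fitted by least
squares: the misfit `Σ_j (f_model(j) − f_obs(j))²` is minimised over `Δw`
at each candidate break latitude, giving misfit and optimal-`Δw` profiles
along the coast.

Around the model sit the statistics used to establish the cline itself:

* two-stage missing-data QC (drop loci >50% missing, then individuals
  missing >25% of the remaining loci);
* in-silico SpeI restriction typing of COI sequences (the recognition site
  ACTAGT is lineage-diagnostic) and per-site lineage frequencies;
* pairwise Nei/Nei–Chesser `Gst` with data-by-location permutation tests
  and latitudinal region means;
* Mantel isolation-by-distance on great-circle distances, optionally
  within each mitotype partition;
* Asmussen–Basten cytonuclear disequilibria (allelic `D`, genotypic
  `D1/D2/D3`) with exact tests and Bonferroni correction, plus an overlap
  report against externally supplied outlier-locus flags.

A synthetic-data module generates every input — advective settlement
kernels, sampled sigmoid clines, two-lineage genotypes with hybrid classes
and northern-panel ascertainment bias, COI haplotypes with the diagnostic
SpeI site — so the full analysis is testable without external data.

## Worked example

Run the shipped end-to-end demo (60 sites, synthetic inputs):

```sh
coastcline run --seed 0 --out artifacts
```

which prints:

```
coastcline run report: artifacts
master seed: 0; stages: connectivity, cline, genotypes, qc, gst, mantel, cnd, fit
QC: retained 128 individuals, 60 loci (59 variable); removed 0 loci, 0 individuals
cline: 30 sites; southernmost s000 f_N=0.0, northernmost s058 f_N=1.0
Gst: max pairwise 0.086; region means {'magellanic': -0.0, 'peruvian': None, 'transitional': 0.015}
Mantel IBD: r=0.9257 p=0.08333 (24 perms)
CND: 28 of 59 testable loci significant after Bonferroni
fit: best break -43.2913 deg, dw_opt=0.2516, misfit=0.03274 (neutral misfit 4.946667)
```

Reading the output: SpeI typing of the synthetic COI sample reconstructs a
cline running from all-southern (f_N = 0) in the south to all-northern in
the north.  Pairwise `Gst` between the cline ends reaches 0.086 and the
within-run Mantel correlation of `Gst` with distance is strongly positive.
About half the SNPs are in significant cytonuclear disequilibrium with the
mitotype, as expected when the two lineages are diverged and mitotype
tracks ancestry.  The break scan places the fitness step at −43.3°, near
the centre of the generated transition, with an optimal differential
`Δw ≈ 0.25`; the neutral model (`Δw = 0`) fits two orders of magnitude
worse (misfit 4.95 vs 0.03) — the cline cannot be held by this current
field without selection.

The same machinery answers the persistence question directly: with the
package's standard 100-site kernel (mean displacement 15 km/generation,
spread 25 km, 30% offshore loss) and no fitness differential, a step cline
collapses to the upstream (southern) lineage in 66 generations, while with
the fitted differential a stable two-sided cline forms from uniform 50/50
initial frequencies.

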