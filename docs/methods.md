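# Methods

This note documents the statistical models, the simulator that provides
ground truth, the numerical choices, and the limits of what the validation
suite demonstrates.

## The nursery model

The target design is a spaced-plant selection nursery of a wind-pollinated,
self-incompatible perennial grass: candidate genets planted on a square
grid at 0.91 m spacing, organized in half-sib families of 9 planted
adjacently, with a remainder of bi-parental F1 genets; a subset of interior
plants ("mothers") is sampled for open-pollinated progeny, with the mother
of every progeny known and every candidate father genotyped. All analyses
treat genotypes as diploid biallelic dosages (0/1/2 with missing). The
species is hexaploid, but genotype calls of the kind this pipeline consumes
are diploid-coded SNPs, and analyzing them as such matches how parentage
and mating-system tools are actually applied to this crop.

## Simulator

`nursery_sim` draws per-locus founder allele frequencies from a bounded
law (default: uniform on [0.04, 0.25], matching the post-filter minor
allele frequency range of the motivating dataset, 2,500 loci). Each
half-sib family shares one simulated dam with independent sires, giving
the within-family relatedness the adjacent-planting design implies without
modeling the previous breeding cycle. Progeny are generated mother by
mother: with probability `s` (selfing rate, default 0 — the crop is
near-obligate outcrossing) the father is the mother herself; otherwise a
candidate is drawn with probability proportional to a distance kernel
evaluated at the mother–candidate distance. Kernels: exponential
`exp(−d/a)` (default scale 3.5 m, which puts most pollination within
10 m on this grid), exponential-power `exp(−(d/a)^b)`, and uniform.
Genotype calls are degraded by a symmetric dosage flip (each call replaced
by one of the two wrong dosages with probability ε, default 0.01) and
missingness (default 5% per call). Everything drawn is recorded in
`NurseryTruth` (true father or SELF, realized distance, kernel, founder
frequencies).

What the simulator does **not** emulate: pollen-cloud physics, wind
direction, flowering-phenology overlap, linkage between loci, allele-
frequency differences between the parental and pollen populations, or
read-level genotyping artifacts (allele dropout, depth-dependent error).
Recovery tests against this simulator therefore demonstrate correctness of
the estimators under the stated model, not robustness to real-data
artifacts such as LD between nearby loci or systematically miscalled
heterozygotes.

A single `numpy` Generator seeded from the config drives each run;
sub-stage seeds are derived deterministically, so identical configs give
byte-identical outputs.

## Paternity likelihood

For one locus with pool frequency `p`, error rate `ε`, and observed calls
(offspring, mother, candidate), the likelihood integrates over true
genotypes: each observed call is correct with probability 1 − ε and one of
the two wrong dosages with ε/2 each; true genotypes get Hardy–Weinberg
priors at `p`; transmission is Mendelian; the alternative hypothesis
replaces the candidate by a pollen allele drawn Bernoulli(`p`). The LOD is
the natural-log ratio summed over loci typed in all three individuals
(missing calls skip the locus; no imputation — the conservative substitute
for the LD-based imputation sometimes applied upstream, and a visible
config decision). ε defaults to 0.10 for assignment, the conventional
conservative setting when the mistyping allowance is matched to the
missing-data allowance; the simulator's actual error is a separate knob.

Confidence calibration simulates offspring of random candidate pairs under
the typing model (typed fraction taken from the data, true father hidden
with probability 1 − 749/771 ≈ 0.03 by default, mirroring the genotyped
fraction of planted genets), scores each against all candidates, and picks
the smallest LOD cutoffs whose accepted sets are ≥95% / ≥80% correct.
Assignment requires the cutoff plus at least 300 shared typed loci. The
mother is scored as a candidate too, so selfing shows up naturally; exact
LOD ties fall back to the larger locus count and otherwise stay unassigned
with a tie flag. Δ (the gap to the runner-up) is reported but never used:
with nine half-sibs of the true father planted adjacent, Δ-based rules
reject exactly the assignments a half-sib structure makes hardest.

Numerical choices: per-locus log-ratio tables over all 4×4×4 observed-call
combinations are precomputed, so batch scoring is three float32 matrix
products against one-hot candidate dosage masks; ln 0 is floored at −1e7
and any LOD below −1e6 is reported as −∞ by the scalar API (the ε = 0
opposing-homozygote case).

## Mixed-mating model

Progeny likelihood: `P = s·Π_l P_self(g_l | mother) + (1−s)·Π_l
P_out(g_l | mother, p_l)` with the same error mixture applied to the
offspring call and the mother's true genotype integrated against its
posterior per progeny (a composite-likelihood treatment; the exact joint
over the progeny array would couple all progeny of a family through the
mother's genotype and is unnecessary here because mothers are genotyped at
thousands of loci). Pollen-pool frequencies are plug-in estimates from the
candidate population, not jointly estimated — the pool is fully genotyped
in this design.

`t_m = 1 − ŝ` with ŝ from Newton–Raphson on [0, 1] (bounded-Brent
fallback, boundary checks). The likelihood in `s` is concave, so the
grid-search cross-check in the tests is a safety net, not a crutch.
An `allow_negative_s` flag relaxes the lower bound to −0.05 for users who
want the upward-biased behavior familiar from progeny-array software;
the default stays in [0, 1] because the unconstrained mixture likelihood
is unbounded as s → −∞ whenever no progeny is an unambiguous self.

`t_s` averages per-locus ML estimates. These *are* allowed below zero
(down to a feasibility limit keeping all mixture probabilities positive):
a single locus carries little information, and truncating each noisy
per-locus estimate at zero before averaging would bias `t_s` downward by
several percent (measured at ~0.1 with 600 loci on simulated fully
outcrossed data). Letting the noise cancel is the same consideration that
leads progeny-array estimators to bound outcrossing rates above 1 rather
than at 1.

`r_p` is fit by ML on outcrossed sib pairs: pair likelihood
`r_p · P(shared father drawn once from the pool) + (1 − r_p) · P(fathers
independent)`, maximized on [0, 1]; with thousands of loci the per-pair
log-ratio essentially classifies each pair, so the estimate approaches the
fraction of full-sib pairs. When a paternity table is available the direct
identity-probability estimate `Σx(x−1)/(n(n−1))` (mean over families) is
reported alongside as a cross-check of the two routes. Bootstrap: families
resampled with replacement (default 1,000), point estimates from the full
data, SDs from the resamples; the `r_p ≠ 0` p-value is a bootstrap
percentile test (the fraction of resamples at zero), labeled as such.

## Dispersal and distance bins

Effective dispersal is the Euclidean mother–father distance of assigned
progeny; selfing events are excluded from distance summaries (they would
put mass at 0 and distort the mean squared distance) and counted
separately. The axial spread is `σ_pollen = √(M/2)` with `M` the mean
squared parent-pair distance. Bearings are measured clockwise from North
and binned into 16 compass sectors of 22.5°. Distance bins are
left-closed, right-open `[3k, 3k+3)` — the boundary convention is tested.
The K–S test compares realized distances against the available candidate
distances pooled across mothers (a per-mother weighting is exposed as an
option). The Shannon/rarefaction "community" of a bin is its vector of
progeny counts per assigned father — the fathers-as-species reading, the
only one under which a bin with two fathers gives rarefaction ≈ 2; the
rarefaction reference depth defaults to the smallest bin's progeny count.
Per-bin "genetic distance" is mean pairwise IBS dissimilarity (1 − shared-
allele fraction), with 1 − VanRaden relationship available by flag; per-bin
Nei's D is the mean over progeny pairs treating each genet as a
one-individual population.

LSD mean separation uses the one-way ANOVA residual variance, pairwise
t comparisons at α = 0.05 without multiple-testing correction (the
conventional default of the agronomic implementations), and an
insert-and-absorb compact letter display; zero residual variance falls
back to exact-equality classes.

## Genomic prediction

Single-environment GBLUP: `y = μ + Zb + e`, `b ~ N(0, σ_b² I)` on
training-frequency-centered dosages, variance components by REML profiled
over `δ = σ_e²/σ_u²` with one eigendecomposition of the VanRaden
relationship matrix; marker effects are back-solved so the marker-effect
and relationship-matrix forms give identical predictions (tested to float
tolerance). The genotype-by-environment machinery of production breeding
models is deliberately out of scope: this module's role is to supply
progeny trait predictions for the distance-bin comparison, and a
single-environment fit is sufficient for that purpose. Degenerate fits hit
a shrinkage floor with a warning rather than failing.

## Validation scale and determinism

The recovery suite runs at the full nursery scale (749 candidates, 2,500
loci, 15 mothers, ~850 progeny, 10,000-offspring calibration), which
completes in well under a minute per stage on one CPU; the kernel-scale
monotonicity check uses 5 scales × 10 replicate nurseries and compares
per-scale mean σ_pollen by rank. Bootstrap and calibration sizes are
scaled down in unit tests (20–200 resamples) and run at full size (1,000 /
10,000) in the acceptance script. All stochastic components take explicit
seeds; every test and the acceptance script are deterministic.

## Known limitations

- Likelihoods assume unlinked loci and a homogeneous pollen pool; both are
  approximations for real GBS data in structured nurseries.
- The symmetric dosage-flip error model cannot represent allele-specific
  dropout, the dominant GBS artifact; ε functions as an effective error
  rate.
- Mothers must be genotyped and present among the candidates; maternity is
  never inferred.
- The mating model's mother-genotype integration is composite rather than
  joint across the progeny array.
- Nei's D between single individuals is a heuristic reading of a
  population-level statistic, retained because per-bin progeny sets are
  the objects being compared.
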