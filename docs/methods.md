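# Methods

This note documents the models implemented in `andromix`, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical choices that matter.

## Forward Wright–Fisher simulation with partial selfing

`synthetic_data.simulate_selfing_population` evolves N diploid
hermaphrodites for a burn-in of `n_generations` (default 10N, enough for
mutation–drift equilibrium from a monomorphic start). Each offspring is
produced by selfing with probability `selfing_rate`, otherwise by two
distinct uniformly drawn parents; no explicit males are modelled (male
fitness is outside scope — outcrossing is simply an event rate). Gametes
carry Poisson(r·L) crossovers at uniform positions and Poisson(μ·L)
infinite-sites mutations at unique integer positions (collisions
resampled). A forward model was chosen over a coalescent deliberately:
partial selfing, isogenic-line establishment and recent crosses are
mechanically explicit, and at the scales used (N ≈ 100–200, L ≈ 0.15–1 Mb)
a simulation takes seconds.

Defaults: N = 200, L = 1 Mb, μ = r = 1e-7 per bp per generation,
selfing_rate = 0.9. These give a few hundred segregating sites in a
40-strain sample and place the half-decay distance well inside the window
at low selfing rates.

**Isogenic lines.** Sampled individuals are selfed `inbreed_generations`
(default 10) times and one gamete is emitted per line, mirroring how
strains are established from single wild hermaphrodites. Line
heterozygosity halves each selfing generation, and the simulation records
the realised population inbreeding coefficient F = 1 − H_obs/H_exp in
provenance metadata; at equilibrium it matches the classical
F = S/(2 − S) (0.818 at S = 0.9, verified over seeds in the tests).

**Windows as chromosomes.** `n_contigs` independent replicate windows
emulate separate chromosomes (the real data span six). Windows are
simulated independently — strains are *nominally* the same lines across
windows, which is adequate because within-lineage strains are
exchangeable; the model does not maintain a shared pedigree across
windows, so strain-level quantities that depend on genome-wide identity
(e.g. exact kinship) are not meaningful in multi-window runs, while
lineage-level structure is.

**Admixture.** `simulate_admixed_mosaic` founds each admixed strain as an
F1 between one haplotype from each source pool, then selfs it
`generations_since_cross` times with per-contig Poisson crossovers and
independent assortment between contigs, recording per-site true ancestry.
De-novo mutation over these few generations is negligible against standing
divergence and is omitted. For admixture experiments the per-contig
crossover rate is set to ~1 per meiosis (nematode meiosis has
approximately one obligate crossover per chromosome pair) so that admixed
genomes are genuine multi-block mosaics; with the background per-bp rate on
a sub-Mb window, ancestry would fix to one source before junctions accrue,
which is an artefact of compressing a genome into a short window rather
than a property of admixed strains.

**Male-count experiment.** Each strain × temperature × replicate draws a
Poisson total brood (default mean 1000 offspring per plate set of ten
hermaphrodites) split binomially with
logit(p_male) = baseline + interaction(climate group, temperature) +
strain effect, strain effects N(0, 0.5²) on the logit scale. The default
baseline logit −4 gives ≈1.8% males, in the low-percent range typical of
spontaneous male production. Hermaphrodite counts are rounded to the
nearest 50 (minimum 50) as on real plates where hermaphrodites clump;
male counts are exact. The default design uses the 11-locality → 4
climate-group pooling (cold: NB, CC, CK; mid-cold: PA, TB, SS; mid-warm:
CO, TK, PL, GE; warm: SB) with 6 strains per locality and 3 replicates.
`antagonistic_interaction(scale)` encodes the reversal pattern of
interest: cold-climate strains make more males when reared warm,
mid-warm-climate strains when reared cold.

What the generators do **not** emulate: genotyping error and missingness
structure of real variant calls, selection (all variation is neutral),
population growth or bottlenecks, a genetic map (crossovers are uniform),
male genetics (XO/XX), and between-window linkage. Passing tests therefore
demonstrate correctness of the inference machinery under the stated
models, not robustness to every feature of field data.

## LD decay

r² between two biallelic sites is D²/(p₁q₁p₂q₂) on complete cases per
pair, equal to the squared Pearson correlation of the 0/1 vectors (used as
an independent oracle in the tests, never as the implementation). Pairs
with fewer than `min_pair_n` (default 4) complete cases are skipped;
between-contig pairs are never formed. **Singletons are excluded by
default** (`min_mac=2`): a singleton's r² with any site is bounded near
1/(n−1) and flat in distance, and in highly selfing samples — where most
polymorphism is private mutation picked up during line establishment —
that flat noise dominates the pair cloud and destabilises the decay fit.
`min_mac=1` restores bare polymorphism filtering.

The decay regression minimises Σ(r²_obs − E(r²)(ρd, n))² over ρ ≥ 0 on the
raw pair cloud (a log-binned variant is available behind `binned=True` for
variance stabilisation). The minimisation is deterministic: a 60-point
log-spaced grid over ρ (plus the ρ = 0 boundary) followed by bounded
scalar refinement on log₁₀ρ. Noiseless curves are recovered to 1e-6
relative; ρ = 0 at the boundary means no measurable decay and yields an
infinite half-decay sentinel.

The half-decay distance solves E(r²)(ρd, n) = ½·E(r²)(0, n) by bisection
(tolerance 1 bp) on the strictly decreasing curve. "Original value" is the
fitted curve's C → 0 limit at the sample's n. In the n → ∞ limit the
crossing reduces to the quadratic 5C² + 43C − 110 = 0, C½ ≈ 2.063; C½
depends on n only weakly for n ≳ 50. When the sampling floor 1/n exceeds
the half target (n ≤ 4) the half-decay is undefined and reported infinite.

Contig "length" for the longest-k selection is the observed SNP span
(max − min site position), since assembly lengths are not carried by a
genotype file; ties break lexicographically.

## Chunk painting

The copying model is a hidden Markov chain over donor identities: uniform
initial distribution; between consecutive sites g bp apart the chain
switches with probability 1 − exp(−recomb_scale·g), landing uniformly on
any donor; emission 1 − θ on allele match, θ on mismatch, 1 on missing.
Physical distance times `recomb_scale` proxies the genetic map. Chunks are
maximal same-donor runs, so a switch landing on the current donor does not
open a chunk; the expected chunk count for donor j is P(state₁ = j) plus
the expected number of intervals entering j from elsewhere. Forward–
backward runs in scaled (per-site normalised) form for speed and is
verified in the tests against brute-force path enumeration (≤ 1e-6,
machine precision in practice) and a log-space reference. Consequences of
the chunk convention worth noting: as recomb_scale → 0 total chunks → 1;
as recomb_scale → ∞ the ceiling is 1 + (L−1)(1 − 1/K) for K donors, not
the number of sites.

This is intentionally a simplified analogue of full chromosome-painting
machinery: haploid only, no per-donor copying propensities, no MCMC
clustering of the coancestry matrix — lineage labels are known for
synthetic data, so the aggregated lineage × lineage view replaces
cluster inference.

Parameter estimation is coordinate ascent: θ ← posterior expected mismatch
fraction (the Baum–Welch emission update), then recomb_scale by bounded
likelihood search on the log scale, each accepted only if the total
log-likelihood does not decrease (monotonicity asserted to 1e-6; defaults
recomb_scale = 1e-5 per bp, θ = 0.05, 10 rounds).

A strain is an admixture candidate when its largest foreign-lineage share
of row chunk counts exceeds 0.25 (configurable). The threshold sits midway
between the foreign share of pure strains (≲0.15, driven by residual
deep coancestry plus chunks copied from admixed donors' foreign tracts)
and that of 50/50 mosaics (≈0.4–0.5); both bands are measured in the
acceptance tests rather than assumed.

## Permutation interaction test

Strain-level percent males (per-replicate 100·males/(males+hermaphrodites),
averaged over replicates; the denominator is configurable because field
practice varies) are arranged as a strains × temperatures matrix. The
statistic is the variance of the double-centred climate-group × temperature
cell means — a pure interaction measure, invariant to group and temperature
main effects. The null distribution permutes temperature labels within
strain, which is exactly exchangeable under "no temperature effect of any
kind within strain" and conditions on strain (hence locality and group)
identity; p = (1 + #{perm ≥ obs})/(1 + n_perm). This replaces a
nested-random-effects GLMM on purpose: the permutation scheme needs no
distributional assumptions on the strain effects and is exactly calibrated
at the design sizes used (type-I error within Monte-Carlo error of 0.05 at
α = 0.05 over 400 null datasets; power > 0.8 against the antagonistic
pattern at unit logit scale — both measured by the acceptance checks). Failed plates (zero offspring) are excluded with a warning; strains
not observed under every temperature drop out of the test (they cannot be
permuted within strain).

## Problem sizes and determinism

All randomness flows from integer seeds through `numpy` generators; equal
seed and configuration give bit-identical outputs, across all simulators.
The acceptance script and tests use desk-scale problem sizes chosen to make
the Monte-Carlo bands tight relative to the assertions: 10 seeds per
selfing level at N = 200/1 Mb for the LD sweep, 20 seeds for equilibrium F
and noisy-ρ recovery, three 40-strain two-lineage batches for admixture
detection, 400 null and 50 alternative datasets for test calibration.
Half-decay distances larger than the simulated window are reported as
censored at the window length in sweep tables (the fitted ρ is 0 or
indistinguishable from it; "no decay within the window" is the scientific
statement).

## Known limitations

- The LD window (1 Mb) bounds measurable half-decay; deeply selfing
  populations saturate it by design.
- Multi-window simulations do not share pedigrees across windows (see
  above); use single-window runs when genome-wide strain identity matters.
- The copying model's switch intensity uses physical distance; a genetic
  map, if available, would replace `recomb_scale·g` directly.
- The admixture flag aggregates over the whole genome; it detects mosaic
  strains, not the locations of introgressed tracts (the per-site
  posteriors are available from `paint_haplotype` for that purpose).
- `estimate_painting_params` maximises a composite likelihood (each
  recipient painted against all others); its θ is well calibrated on
  copying-model data but recomb_scale is identified only up to the real
  data's map-length scale.
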