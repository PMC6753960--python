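# Methods

## Population model and simulator

`metadiv.wfsim` is an individual-based forward simulator of a neutral,
diploid, single-chromosome sequence. Generations are discrete and
non-overlapping. Gametes are formed by copying one of the parent's two
haplotypes, switching template strand independently with probability `rec`
at each of the `seq_len − 1` boundaries between consecutive sites, and then
flipping each site independently with probability `mu`.

* **Mutation is a symmetric two-state flip** (ancestral ↔ derived). This
  keeps every site biallelic, so a five-site marker window has at most
  2⁵ = 32 haplotype alleles, and it handles recurrent mutation
  consistently — at the study's per-site rate (μ = 5 × 10⁻⁵ with
  N = 4,000, i.e. θ = 4Nμ = 0.8 per site) back-mutation is not negligible.
  The corresponding diffusion equilibrium is a Beta(θ, θ) allele-frequency
  distribution with mean heterozygosity

      E[2pq] = θ / (1 + 2θ)  (= 0.3077 at θ = 0.8),

  which is the closed form the calibration tests use. (The familiar
  infinite-alleles value θ/(1+θ) does not apply to a two-state model.)
* **Mating** in the ancestral and deme-drift phases is monoecious and
  random with replacement (selfing probability 1/N). Sexes are assigned
  only when founders are sampled for management, 50/50 within each deme.
* **History**: one ancestral deme (default N = 4,000) evolves for 5,000
  generations from a monomorphic start, five demes (2,000; 100; 100; 100;
  100) are then founded by disjoint uniform draws and drift independently
  for 25 generations, and 40 founders (20 per sex) are sampled per deme.

Haplotypes are stored bit-packed (8 sites/byte); this is purely an
implementation choice (the full-scale ancestral phase runs in minutes on
one core) and is invisible through the API, which exposes 0/1 arrays.
Per-generation mutation and crossover positions are drawn by pooled
binomial counts with deduplication; at the rates involved the collision
probability is far below Monte-Carlo resolution.

**Scaling.** `SimParams.scale` multiplies `mu` and `rec` while profiles
divide population sizes and generation counts by the same factor, holding
θ = 4Nμ, ρ = 4Nc and drift time T/N fixed — the quantities that determine
the population-genetic expectations being tested.

## Markers

Marker loci are the fixed, non-overlapping windows of five consecutive
sites (polymorphic or not), giving seq_len/5 candidate loci; the 5-bit
window pattern is the allele, leftmost site most significant. Management
uses every n-th *segregating* locus (≥ 2 pooled alleles), starting at the
first; monomorphic loci are excluded from management but included in
whole-genome measurement.

## Diversity statistics

All statistics weight demes equally, regardless of census size.

* `H_S` = deme-mean of `1 − Σ p²` per locus; `D_G` = Nei minimum distance
  `Σ(p_i − p_j)²/2` averaged over all n² ordered deme pairs (self-pairs
  zero). With this denominator `H_T = H_S + D_G` equals, exactly, the
  heterozygosity of the equally-weighted pooled frequencies — the identity
  the tests assert at 1e-12.
* `A_S` = deme-mean allele count minus one; `D_A` = symmetrized private-
  allele count `(|i\j| + |j\i|)/2` averaged over unordered pairs, so
  `A_T = A_S + D_A` equals the mean pair-union allele count minus one.
* `K` is reported per locus (mean over loci), with the raw pooled total as
  a secondary column, keeping it on the same scale as `A_T`.
* `F` is observed marker homozygosity per individual (identity in state,
  which subsumes identity by descent), averaged over individuals.
* `VarFreq` is the population (biased) variance of the pooled frequencies
  over each locus's *baseline* allele set — the alleles present at
  management start — with lost alleles entering as p = 0.
* Plan statistics: `nMates` counts matings with offspring; `VarContFem`
  is the population variance of per-female offspring counts over all
  candidate females; `VarMigrants` the population variance across demes of
  incoming migrant counts; `Migrants` the realized mean migrants per deme.

## Optimizer

A plan assigns each offspring a natal deme, a sire and dam from that deme,
and a destination deme; per-destination totals equal the configured deme
size (40 at full scale). Objectives are evaluated on the expected progeny:

* `maxHT`: `D_G + λ·H_S` on expected progeny frequencies
  `p′ = Σ_k g_k x_k / 2N` (g = gamete counts, x = dosage/2);
* `maxAT`: `D_A + λ·A_S` with expected allele counts from per-allele
  retention probabilities `R = 1 − P_loss`, where a heterozygous carrier
  transmitting g gametes contributes `(1/2)^g` to the loss probability, a
  homozygous carrier zero and a non-carrier one; demes and alleles are
  treated as independent (the exact joint law is combinatorially
  infeasible; this is the standard expected-loss approximation);
* `maxK`: the per-locus mean of `Σ_a (1 − Π_d P_loss(a, d))`, i.e. the
  expected number of alleles surviving anywhere.

**Search** is simulated annealing with Metropolis acceptance, geometric
cooling (default 0.95 every 200 moves, 30,000 iterations) and an initial
temperature auto-calibrated from 100 probe moves so a typical worsening
move starts near 50% acceptance. The best plan visited is returned, and it
is updated only on strict improvement, so ties retain the incumbent;
zero-delta moves are still *accepted* by the chain (exp(0) = 1) because the
allelic objectives have large plateaus that the walk must cross. The paper
trail behind these constants is thin by construction: they are package
defaults, overridable via `AnnealSchedule`, and validated by the
exhaustive-search acceptance test (annealed plans recover the brute-force
optimum on small instances in ≥ 95% of seeded runs).

**Moves.** Four elementary moves, chosen uniformly: (a) reassign one
offspring's mating (for migrants, the origin deme is also re-drawn);
(b) replace the sire or dam of one whole mating; (c) swap the destinations
of two offspring from different natal demes when that preserves the
migrant count; (d) relocate a migration — one migrant becomes a resident
of its destination while a resident elsewhere becomes a migrant from a
random other deme. Move (d) exists because (a)–(c) alone leave the plan
graph disconnected in small cases (with two demes and one migrant, the
state "deme 0 exports" cannot reach "deme 1 exports": every cross-natal
offspring pair shares a destination, so move (c) never applies). A
breadth-coverage test verifies the move set reaches every feasible plan of
a tiny instance. All moves preserve per-destination totals and the exact
total migrant count.

**Migration budget.** The budget is a population-wide total,
`B = round(m × n_demes)` migrants per generation, realized exactly — not a
per-deme cap. A per-deme hard cap of one with mean one would force the
variance of migrant numbers to zero, contradicting the reported nonzero
`VarMigrants`, and fractional levels (0.4, 2) are only meaningful as
means. The `RND` control performs no migration; its fast inbreeding rise
in isolated demes is the intended baseline behaviour.

## Management loop

Each generation: optimize (or randomize) the plan on the managed loci,
realize progeny by Mendelian sampling — each offspring draws one of each
parent's two locus alleles independently per locus (no recombination
within a 5-SNP locus, free recombination between loci), no mutation — then
measure statistics on the managed loci (few-marker scenario) or on every
locus (whole-genome scenario). Offspring sexes fill each deme's 50/50
quota uniformly at random after counts are fixed; parents are discarded
(discrete generations). Disabling mutation during the 25 managed
generations makes the no-new-allele invariant exactly testable and changes
the managed-marker dynamics negligibly.

## Replication harness and profiles

`run_study` executes the full factorial of methods × λ × migration levels
× marker scenarios over `n_base_replicates × n_samplings` runs. Every unit
of work draws its generator from the master seed plus its own coordinates
(`SeedSequence` spawn keys), so outputs are byte-identical regardless of
execution order. Means and standard errors (sample SD/√runs) are
aggregated per cell and generation.

* **paper profile**: the full-scale conditions above, 10 × 10 runs,
  scenarios (every 100th segregating locus measured on itself; every 10th
  measured genome-wide), λ = 1, one migrant per deme per generation.
* **desk profile** (CI-scale): ancestral phase scaled by 10 (N = 400, 500
  generations, μ and c × 10, so θ = 0.8 per site is preserved), demes
  (200, 10, 10, 10, 10) for 25 generations, 8 founders per deme, every
  200th segregating locus managed and measured, annealing 2,500
  iterations, 5 × 10 = 50 runs. These sizes were chosen once as the
  smallest design that still resolves the method orderings (maxHT highest
  H_T; maxK ≥ maxAT highest K; maxAT lowest F among optimizers; RND worst
  everywhere) with clear margins when averaged over the 50 runs.

## What the synthetic data does and does not emulate

The generator reproduces the study's neutral history: mutation–drift
equilibrium in a large ancestral deme, unequal founder bottlenecks,
independent drift, and equal-sized sexed founder samples. It does not
model selection, dominance, demographic stochasticity in deme sizes,
overlapping generations, multiple chromosomes, or four-state nucleotides.
Passing tests therefore demonstrate the correctness and the comparative
behaviour of the *management machinery* under neutral expectations; they
do not certify performance on real data with selection or pedigree
structure.

## Known limitations and observed discrepancies

* At the stated full-scale parameters the per-site θ is 0.8, so after
  5,000 generations essentially every site is polymorphic in a 400-copy
  founder sample (we measure ~99.5% of sites, hence ~2,000 of 2,000
  five-site windows segregating). A segregating count of ~1,200 of 2,000
  is not reachable from these rates under any standard one- or two-state
  mutation model; reproducing it would require an undocumented detail of
  the original sequence-simulator configuration. The full-scale acceptance
  check records this discrepancy rather than adjusting parameters to it.
* The full 10 × 10 full-scale replication is an hours-scale computation;
  the in-suite full-scale check uses one base population and four
  samplings and scales the standard-error estimate to the 100-run design
  (SD/√100). Standard errors estimated from four runs carry wide
  chi-square uncertainty and omit the between-base-population variance
  component.
* Expected allelic objectives use independence across demes and alleles;
  exact joint retention probabilities are not computed.
* `D_G`/`D_A` averaging denominators follow the conventions stated above,
  chosen so that the partition identities hold exactly; other software may
  normalize pair averages differently (e.g. excluding self-pairs), which
  rescales `D_G` by n²/(n²−n) without affecting orderings.
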