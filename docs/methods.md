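# Methods

## Problem setting

A biallelic SNP array measures, for each sample at each SNP, a pair of
allele intensity summaries (s^A, s^B). Copy-number aberrations shift these
pairs off the three normal genotype clusters (AA, AB, BB) along a grid:
one grid step per allele copy. `haplocn` models a cohort of such samples
jointly, phasing each sample's two haplotypes against a population
haplotype model while classifying every locus into one of six per-haplotype
allelic states — A⁻, A, A⁺, B⁻, B, B⁺ — and finally converts signals into
fractional allele-, haplotype- and region-level copy numbers.

## State space

A haplotype's state couples an allele identity (A/B) with a copy-number
class (loss/normal/gain, i.e. 0/1/2 copies of that allele). Gains and
losses are assumed not to abut: a gain state may transit only to gain or
normal states, a loss state only to loss or normal states. This leaves 28
of the 36 ordered transitions between adjacent loci. A sample's hidden
state is the ordered pair of its haplotypes' states (36 genotypic states);
pair transitions factor as the product of the two haplotypes' independent
transitions (both haplotypes follow the same population model).

## Transition structure

**Two-locus haplotype proportions.** For each consecutive locus pair the
3×3 cohort genotype table N[g,h] is reduced to proportions of the four
haplotype sets A–A, A–B, B–A, B–B. Eight cells phase unambiguously; the
double heterozygote splits between A–A/B–B and A–B/B–A with probability q:

    h_AA = 2N₁₁ + N₁₂ + N₂₁ + qN₂₂            α = h / 2N
    h_AB = 2N₁₃ + N₁₂ + N₂₃ + (1−q)N₂₂
    h_BA = 2N₃₁ + N₂₁ + N₃₂ + (1−q)N₂₂        q ← α_AA α_BB / (α_AA α_BB + α_AB α_BA)
    h_BB = 2N₃₃ + N₂₃ + N₃₂ + qN₂₂

starting at q₀ = 0.5 and stopping when |Δq| < 10⁻⁵ (cap 1000 iterations).
Convergence is judged on q because that is the only latent quantity; the
α's are deterministic in q. When a row marginal of the resulting joint
table vanishes, the conditional row is set to (0.5, 0.5) and flagged so the
chain stays stochastic.

**Haplotype tree with dynamic merging.** The conditional tables label a
per-chromosome probabilistic tree: level j holds nodes for the allele
carried at locus j, branches carry conditional (C) and joint (J)
probabilities, and node counts M are expected haplotype counts (2N × path
probability — fractional, since phases are probabilistic before the first
global iteration). Nodes at a level are compared by the maximal absolute
difference of their parallel descendants' conditionals and merged greedily,
smallest score first, whenever the score falls below √(1/M_u + 1/M_v) —
roughly twice the standard deviation of that difference under purely random
transitions. Merged conditionals are count-weighted averages; descendants
merge recursively in parallel. Two representation choices follow from the
pairwise estimation:

- *Same-label merging.* Only nodes carrying the same allele label are
  merged, because the label is what the state recognition emits from.
- *Label-level aggregation for decoding.* Since branch probabilities come
  from pairwise tables, all same-label contexts at a level carry identical
  forward distributions and merge to width ≤ 2 immediately; the decoder
  therefore consumes each level's count-weighted 2×2 allele-transition
  table, which is exact for these trees. The merge machinery is still a
  real, tested operation on multi-context trees (e.g. trees re-estimated
  from externally phased haplotypes with longer memory).

**Six-state branching with distance decay.** Each binary conditional
C[x→y] is distributed over the allowed six-state transitions that collapse
to x→y. Copy-number persistence decays exponentially with the inter-SNP
distance d: from a normal state the share ρ_norm = exp(−d/D_norm) stays
normal and (1−ρ_norm)/2 goes to each of the gain and loss targets
(symmetric split); from an aberrant state ρ_var = exp(−d/D_var) stays
aberrant and 1−ρ_var returns to normal. Defaults D_norm = 10⁸ bp and
D_var = 10⁵ bp encode that normal stretches are vastly longer than aberrant
ones. Every row of the expanded matrix sums to 1 and forbidden gain↔loss
entries are exactly 0. The class prior at a chromosome's first locus uses
the chromosome's mean inter-SNP spacing as the distance argument.

## Emission models

The 36 genotypic states partition into 11 groups (M0–M10) whose expected
signals coincide (e.g. M1 = {AA, A⁻A⁺, A⁺A⁻, A⁺B⁻, B⁻A⁺}: about two A
copies, essentially no B). Each group is a bivariate normal in (s^A, s^B).
At initiation the AA/AB/BB seed clusters anchor a rectangular grid: A-axis
coordinates a_hi > a_mid > a_lo from the three seed A-means, B-axis
likewise; M0 and M10 extrapolate one grid step beyond M1 and M9, so
dist(M1,M0) = dist(M1,M4) and dist(M9,M10) = dist(M9,M8). Covariances are
inherited from the nearest seed cluster (ties to AB), preserving
cluster-specific noise anisotropy without extra free parameters. Seeds
whose grid coordinates are not strictly ordered are flagged and fall back
to the cohort-median geometry. After each decoding pass, every model's
mean/covariance is re-estimated from its member signals per SNP across
samples; groups with fewer than two members are re-seeded by re-extending
the grid from the updated M1/M5/M9 (which keep their previous parameters
when themselves under-populated). Degenerate covariances receive a ridge
of 10⁻⁶ · trace/2.

## Decoding and global iteration

Viterbi decoding runs per sample per chromosome in log space (no underflow
for chromosome sizes up to ~10⁵ loci). Per-locus candidate states are
restricted to the member states of the Mahalanobis-nearest model — the
restriction that makes the 36-state space cheap — with an automatic
widening to all 36 states at loci where no candidate is reachable (e.g. a
gain group directly abutting a loss group). Ties resolve to the
lexicographically smaller ordered pair, making output deterministic.

The driver alternates tree construction and recognition (default 2 global
iterations): after a pass, emission parameters are refreshed from the
decoded assignments, and the binary conditional tables are re-estimated
from the phased haplotype allele counts (aberrant states collapse to their
allele), with the decay redistribution reapplied on top.

## Regions and copy numbers

Aberrant runs (either haplotype gained, resp. lost) become candidate
regions, filtered in the documented order: singletons dropped; merge across
gaps of ≤2 SNPs; drop regions with >4/5 low-confidence SNPs (signal inside
the union of the 99% χ²₂ Mahalanobis ellipses of M1/M5/M9 — the "shaded"
normal region; the quantile is configurable); regions of <4 SNPs tolerate
no shaded SNP. Fractional allele copy numbers interpolate on the grid,
n̂^A = (s^A − μ^A(M9)) / max(μ^A(M5)−μ^A(M9), μ^A(M1)−μ^A(M5)) clipped at
0 (copy numbers are physical counts), symmetrically for B; the max makes
the estimate conservative when the two per-copy increments disagree, and a
non-positive increment flags the SNP's estimate as missing. Haplotype copy
numbers average n̂^A or n̂^B along each phased haplotype; the region total
averages n̂^A + n̂^B.

**Event calling and rounding.** Fractional totals are rounded with the
convention that [0.5, 1.5] is one copy and other half-points round toward
the normal band (2.5 → 2). `call_event` labels a region by the strict
fractional thresholds (total > 3 gain, < 1 loss). The pipeline's reported
region list instead uses the rounded convention (rounded total ≥ 3 or ≤ 1)
as its keep rule: a single-copy gain has expected total exactly 3.0, and
the strict rule would suppress half of such events at the boundary, whereas
the rounded rule treats everything outside the rounded-normal band as an
event. Both behaviors are exposed; the choice affects only which regions
are written out.

## Simulator

`haplocn.simulator` generates cohorts with known truth, emulating a
haploid-pairing design: a pool of 45 haploid chromosomes (drawn from 4
founder haplotypes per LD block, block lengths geometric with mean 20 SNPs)
each carries 3 implanted events of 10–50 SNPs (gain:loss 1:1); 90 diploids
pair two distinct haploids sampled with replacement, so events recombine
across samples and occasionally overlap between homologues — the situation
haplotype phasing is for. SNP spacing is irregular with mean ≈3 kb.
Signals are drawn from the bivariate normal of the true genotypic state's
model on a unit-per-copy grid with isotropic noise SD 0.2 (cluster
separation 5 SD); input genotype calls come from a naive
nearest-normal-cluster caller, so aberrant loci enter the pipeline with
realistic call errors. One fixed seed determines the cohort byte-for-byte.

What the simulator does **not** emulate: real probe noise is neither
isotropic nor homoscedastic, wave/GC artifacts and batch effects are
absent, LD has no long-range structure across block boundaries, and seed
cluster parameters are exact rather than estimated. Passing the end-to-end
tests therefore demonstrates correctness of the inference machinery under
its own model assumptions, not calling accuracy on real arrays. One known
granularity limit is inherited from the model itself: M0/M10 have a single
center for total copies 3 and 4, so a double gain of the same allele emits
at the 3-copy center while its true total is 4; such overlap SNPs
legitimately count against the copy-number accuracy ratios.

Calls are scored at four nested levels — Rregion (called regions
overlapping a true event, among called), Rtotal (correct rounded total,
among overlapping), Rspecific (both rounded allele copy numbers correct,
per SNP in correct-total regions), Rhap (correct haplotype assignment,
among correct-allelic SNPs, under the better of the two global haplotype
labelings per region, since labels are arbitrary up to swap).

## Numerical choices and defaults

| parameter | default | meaning |
| --- | --- | --- |
| `d_norm` | 10⁸ bp | normal-state persistence scale |
| `d_var` | 10⁵ bp | aberrant-state persistence scale |
| `shaded_quantile` | 0.99 | χ²₂ radius of the normal ellipses |
| `global_iterations` | 2 | tree/recognition alternations |
| `restrict` | true | Mahalanobis group restriction in Viterbi |
| EM tolerance | 10⁻⁵ on q | two-locus EM stopping rule |
| ridge | 10⁻⁶·tr/2 | covariance regularization |

Tie-breaks are all deterministic: Mahalanobis imputation prefers the
lowest genotype code, group selection the lowest model id, covariance
inheritance the AB cluster, and first-locus Viterbi ties the
lexicographically smaller ordered pair. Re-running any entry point with
the same inputs and configuration reproduces its output exactly.

Test and acceptance problem sizes are chosen to exercise every code path
at desk scale: exact-decoding equivalence on 4-locus/36-state instances
(checked against full-path enumeration), EM recovery at n = 500, and the
default 90 × 2000 cohort for end-to-end recovery.

## Limitations

- Only biallelic SNP probes are modeled; copy-number-only probes carry no
  allelic information and are out of scope.
- No tumor-purity deconvolution: fractional copy numbers quantify the
  aberration's magnitude but are not decomposed into clonal fractions.
- Only the Viterbi path is produced; no forward–backward posteriors or
  per-region confidence probabilities.
- Upstream normalization (GC-wave correction, batch effects) and genotype
  cluster estimation are the caller's input contract, not its job.
- Transition memory beyond adjacent loci enters only through the tree
  merging; with pairwise-estimated tables the effective model is
  first-order per haplotype.
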