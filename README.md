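# haplocn

Haplotype-specific copy-number inference from biallelic SNP-array
intensities.

Genotyping arrays report, at every SNP, a pair of allele intensity summaries
(s^A, s^B). Most CNV callers reduce this pair to a total-intensity and an
allelic-ratio track and return integer copy numbers per segment. `haplocn`
instead works directly in (s^A, s^B) space and answers a finer question:
**which of the two homologous chromosomes carries the amplification or
deletion, and by how much?** It reports CNV segments, the phased
copy-number haplotypes across them, and fractional allele-specific copy
numbers — useful for heterogeneous tumor samples, where a mixture of cells
produces non-integer average copy numbers.

## The model

Each haplotype occupies one of six allelic states per SNP:
A⁻, A, A⁺, B⁻, B, B⁺ (deletion, single copy, amplification of either
allele). Adjacent gains and losses are assumed not to abut, which leaves
28 of the 6×6 ordered transitions between consecutive loci. A sample's
hidden state is the ordered pair of its two haplotypes' states (36
genotypic states), and decoding is by the Viterbi algorithm over an HMM
whose two ingredients are:

- **Transitions — a localized haplotype-cluster tree.** For every pair of
  consecutive loci the four haplotype-set proportions α(A–A), α(A–B),
  α(B–A), α(B–B) are estimated from the cohort's 3×3 genotype counts by the
  classic two-locus phase EM (double heterozygotes split by a phase
  probability q, initialized at 0.5, iterated to |Δq| < 10⁻⁵). The
  resulting conditional probabilities label the branches of a per-chromosome
  probabilistic tree; nodes whose forward distributions differ by less than
  √(1/M_u + 1/M_v) (twice the random-transition standard deviation, with
  M the haplotype counts) are merged, variable-length-Markov-chain style.
  The merged binary tree is then branched into the six states with
  distance-decayed persistence exp(−d/D), D = 10⁸ bp for normal states and
  10⁵ bp for aberrant ones. The pair transition probability is the product
  of the two haplotypes' independent tree transitions.
- **Emissions — eleven bivariate normal genotype groups.** The 36 genotypic
  states partition into 11 groups (M0–M10) with indistinguishable expected
  signals. Group centers are seeded on the rectangular grid through the
  AA/AB/BB genotype clusters (one grid step per allele copy; M0/M10
  extrapolate one step beyond M1/M9) and re-estimated after each decoding
  pass. To keep decoding fast, per-locus candidate states are restricted to
  the group nearest the observed signal in Mahalanobis distance.

Decoded aberrant runs are filtered (singletons dropped; same-direction
regions separated by ≤2 SNPs merged; regions dominated — >4/5 — by SNPs
inside the "shaded" normal-cluster region dropped; short regions tolerate
no shaded SNP), and fractional copy numbers are interpolated on the grid:
n̂^A = (s^A − μ^A_BB)/Δ^A with Δ^A the larger of the two per-copy A-axis
increments, and symmetrically for B. Haplotype copy numbers average n̂^A or
n̂^B along each phased haplotype.

## Worked example

The package ships a cohort simulator that emulates the haploid-pairing
design used to benchmark phasing: haploid chromosomes with block-structured
LD carry implanted gain/loss segments (3 per haploid, 10–50 SNPs) and are
paired at random into 90 diploids of 2000 SNPs:

```sh
haplocn simulate --seed 7 --out cohort/
haplocn call --signals cohort/signals.tsv --genotypes cohort/genotypes.tsv \
             --seeds cohort/seeds.tsv --out calls/
haplocn evaluate --calls calls/calls.tsv --regions calls/regions.bedlike.tsv \
                 --truth cohort/truth.tsv
```

which prints

```
metric  ratio     numerator  denominator
Rregion 0.990215  506        511
Rtotal  0.990119  501        506
Rspecific 0.970103 15413     15888
Rhap    0.854538  13171      15413
```

Reading the nested ratios: 506 of the 511 called regions overlap a true
event; 501 of those get the rounded total copy number right; 97% of the
SNPs inside those regions get both allele-specific copy numbers right; and
85% of *those* SNPs are assigned to the correct parental haplotype. The
region table itself looks like

```
sample  chrom  start  end     ...  direction  cn_hap1   cn_hap2   total_cn  n_snps
sim001  1      19921  168993  ...  loss       0.976068  0.755262  1.04739   50
```

a 50-SNP single-copy deletion: one haplotype retains ≈1 copy, the other is
largely lost, total ≈1.

The same is available as a library:

```python
from haplocn import SimConfig, simulate_cohort, run_pipeline, evaluate_calls

cohort = simulate_cohort(SimConfig(seed=7))
result = run_pipeline(cohort.signals, cohort.genotypes, cohort.seeds)
print(evaluate_calls(result, cohort.truth).as_dict())
```

Input formats (tab-delimited `signals.tsv`, `genotypes.tsv`, `seeds.tsv`)
are documented in `haplocn/signal_io.py`; any upstream genotyping tool that
provides per-SNP allele intensities plus rough AA/AB/BB calls and cluster
parameters can feed the caller.

## Documentation

See `docs/methods.md` for the statistical model, parameter defaults, the
simulator's scope, and known limitations.
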