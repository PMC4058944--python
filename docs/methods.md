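# Methods

## Problem setting

During pregnancy, cell-free DNA (cfDNA) in maternal plasma is a mixture of
maternal-origin fragments (fraction `1 - r`) and fetal-origin fragments
(fraction `r`). With deep plasma sequencing (~78x), phased parental
genotypes, and a maternal-only WGS sample, a de novo fetal CNV is visible in
two weak signals simultaneously: the allele-count balance at SNP loci shifts
by roughly `r/2`, and the local fragment density changes by a factor
`1 ± r/2`. Neither signal alone is reliable for events much below a
megabase; the model here fuses them.

## State space

At every SNP the fetus carries a multiset of parental haplotypes drawn from
`{M_A, M_B, P_A, P_B}` — a *phased inheritance pattern* (PP). Enumerating
all configurations compatible with normal inheritance, a single-haplotype
duplication, or a single-parent deletion gives 20 states: 4 normal
(`|PP| = 2`), 6 maternal and 6 paternal duplications (`|PP| = 3`), 2
maternal and 2 paternal deletions (`|PP| = 1`). Duplication states with two
distinct haplotypes from one parent (e.g. `M_A M_B P_A`) are kept distinct
from homozygous ones (`M_A M_A P_A`) because their expected allele
distributions differ. The canonical state order (normal, maternal dup,
paternal dup, maternal del, paternal del) indexes every matrix in the
package.

## Emission model

Observed plasma counts `{k_A, k_C, k_G, k_T}` at a SNP are scored per
pattern as independent Gaussians with variance equal to the mean (a Poisson
approximation chosen for robustness over the exact multinomial):

    k_x ~ N(mu_x, mu_x),   mu_x = p_x * (total mapped reads)

with

    p_x = sum_i [M_i = x] m_i (1 - r') + sum_{y in PP} [y = x] r'/|PP|
    r'  = (|PP| r/2) / (|PP| r/2 + 1 - r)

`r'` is the locally adjusted fetal fraction: an extra (missing) fetal copy
adds (removes) fetal molecules, changing the effective admixture at the
locus. The maternal haplotype weights

    m_i = (alpha + #reads on M_i in the maternal sample) /
          (2 alpha + total informative maternal reads)

absorb genuine maternal imbalance (e.g. maternal CNVs) while the pseudocount
`alpha` suppresses binomial measurement noise.

Numerical choices:

- **Pseudocount default** `alpha = 1.0 x` genome-wide mean per-site maternal
  depth. The weights enter the emission as point values, so their sampling
  error (sd ~0.09 at 32x) is otherwise interpreted as signal; the
  duplication classes, having three distinct maternal configurations, absorb
  that noise preferentially and produce sustained false duplication calls.
  A pseudocount on the order of the per-site depth (shrinking weights about
  half-way toward 1/2) suppresses this while a true maternal CNV (allele
  fraction shifts of 1/3 or 1/2 at tens of reads) still moves the weights
  substantially. Configurable via `default_alpha(..., factor=)` or the
  `alpha` parameter.
- **Expectation floor**: each `mu_x` is floored at 0.5 reads and the vector
  rescaled to preserve the total, so sequencing-error reads on nucleotides
  carried by no haplotype get finite log-density instead of `-inf` (which
  would make decoding degenerate). Probabilities still sum to 1 after the
  rescale.
- The Gaussian is evaluated as a continuous density at the integer counts;
  no continuity correction.
- Sites where both parents are homozygous for the same allele carry no
  allelic-ratio information; their emission row is constant across states so
  only the coverage prior acts there.
- Ties in Viterbi are broken toward the lower canonical state index.

## Fetal fraction

`r` is estimated at loci where the parents are homozygous for different
alleles: every paternal-allele read there is fetal, with expected fraction
`r/2`. The estimator is twice the **median** per-site paternal-allele
fraction (median rather than mean, for robustness to mapping artefacts and
CNVs), clamped to (0.005, 0.5), requiring at least 50 covered informative
sites. On simulated data at depth 78 with 5000+ informative sites it is
accurate to about +/-0.005. Note that a large CNV inflates the genome-wide
estimate if it spans a sizable share of the analysed region; estimate `r` on
as much CNV-free genome as possible.

## Coverage model

The genome is tiled with non-overlapping windows, one SNP each, breakpoints
midway between adjacent SNPs. Fragment counts are scaled to a 1 kb
equivalent (`N * 1000/|W|`), and each window's *window ratio value* is

    WRV_i = N_{W_i} / sum of N_W over the k = 200 windows with GC content
            closest to W_i

which cancels both sequencing depth and GC bias. A reference plasma sample
(a second, independent plasma library — plasma-to-plasma coverage agrees far
better than plasma-to-WGS) provides `WRV_i^R`; scaling its numerator by
`1 + (|PP| - 2) r/2` gives the expectation under each copy count, and

    Pr[WRV_i^S | |PP|]  ∝  N(WRV_i^{R,|PP|} - WRV_i^S; 0, sigma_noise)

normalised over `|PP| in {1,2,3}` is the per-window copy-number prior.

- **sigma_noise** is `1.4826 x MAD` of the genome-wide copy-2 residuals
  `WRV^R - WRV^S` (floored at 1e-6): a robust scale, so true CNVs and the
  heavy tail of plasma coverage do not inflate it. Requires >= 1000 windows.
- `k = 200` neighbours is configurable; the neighbour search errors rather
  than silently shrinking `k` when too few windows exist. The bulk
  implementation finds the neighbour run on the GC-sorted axis in
  O(n log n); ties are deterministic.
- The prior is normalised over the three copy counts and applied equally to
  every state of that copy count (states of equal `|PP|` receive equal
  density, so normalising over all 20 patterns would differ only by class
  multiplicities, which the row renormalisation absorbs anyway).

## HMM and decoding

The base transition matrix uses three fixed rates: 0.01 between distinct
states of the same class (phasing errors / recombination within haplotype
blocks of a few hundred SNPs), 0.0001 from each normal state into each CNV
state (one CNV start per ~10^4 SNP loci), 0.001 from each CNV state back to
each normal state (events spanning ~10^3 loci). Transitions between two
different CNV classes are 0 — two CNVs cannot be adjacent — and the
self-transition absorbs each row's remainder. The 0.0001 rate is read
per target state; a `split_start` flag divides it across the 16 CNV states
instead. The initial distribution is uniform over the 4 normal states.

The coverage prior enters by multiplying every transition probability *into*
a state by that state's copy-count prior, then renormalising each row to
sum to 1 (position-specific matrices). A consequence of the row
renormalisation worth knowing: along a sustained within-class path the
prior largely cancels, so the coverage signal mostly modulates event entry
and exit rather than accumulating per site. With the uniform prior the
matrix reduces exactly to the base matrix, so `ratios_only` mode is the
special case of skipping injection.

Decoding is Viterbi (single best path) in log space; calls are maximal runs
of CNV-class states, with boundaries at the midpoints to flanking SNPs and
a score equal to the mean per-SNP emission log-odds versus the best normal
state. A 3-state coverage-only baseline (normal/dup/del over fixed-size
bins, WRV residual densities as emissions, same start/end rates) is
provided for ablation; it cannot see parental origin, so its calls are
scored as generic `dup`/`del`.

## Evaluation

A true event is *recalled* when the union of same-class predictions covers
at least 50% of its length; a predicted call is *correct* when it overlaps
a same-class true event. Recall and precision are reported per class and
overall.

## Synthetic data generator

The generator emulates a deeply sequenced pregnancy trio:

- SNP positions: exponential spacing, mean 1 kb (configurable).
- Parental haplotypes: biallelic SNPs with population alternate-allele
  frequencies from a symmetric Beta(0.8, 0.8) (bimodal, U-shaped — most
  variants near fixation, as in real site-frequency spectra).
- Fetal haplotypes: one haplotype per parent with recombination at
  1e-8/bp per meiosis (~1 event per 100 Mb; essentially none at the 20 Mb
  scale used in experiments).
- Maternal sample: Poisson depth 32, multinomial allele counts, per-base
  error 0.002.
- Plasma: total depth negative-binomial around 78 with variance/mean = 3
  (cfDNA is strongly overdispersed relative to Poisson), allele counts
  multinomial with the emission-model probabilities under the true pattern.
- Window fragment counts: mean from depth and a smooth unimodal GC-bias
  multiplier; negative-binomial noise (variance/mean = 3); an independent
  reference plasma with its own noise; and — important for realism of the
  coverage channel — an independent smooth multiplicative *coverage wave*
  per sample (sd 2.5%, correlation length 200 kb). Without the wave,
  i.i.d. window noise averages out under large fixed-size bins and a
  coverage-only caller becomes unrealistically sensitive; real plasma
  libraries carry regional biases that do not average out, which is why
  small windows plus a reference sample are needed in the first place.

CNVs are introduced at allele-count level with the read-removal
probabilities a read-level pipeline would use (Bernoulli thinning per count
unit): deletions remove counts with probability
`(r/2) / (N_m (1-r)/2 + N_f r/2)` when the deleted haplotype carries the
allele (probability `r/2` for error alleles carried by no haplotype, never
otherwise); duplications add Poisson(regional depth x r/2) counts on the
duplicated haplotype's allele and inflate window counts by `1 + r/2` in
expectation; fetal-fraction down-sampling removes each count with
probability `r_del * p_f`, `r_del = 1 - ((1-r)/r)(r'/(1-r'))`. Planted
duplications default to the *transmitted* haplotype — a de novo CNV arises
on the gamete's chromosome — while an explicit target haplotype is
supported; duplicating an untransmitted haplotype produces allele ratios
nearly indistinguishable from the opposite-type deletion (the dup/del
ambiguity that motivates the coverage prior) and is typically mis-typed.

What the generator does **not** emulate: read-level artefacts (mapping
ambiguity, duplicates), mappability and assembly-gap structure, inherited
parental CNVs, maternal mosaicism, and the full heavy tail of real plasma
coverage. Passing spike-in tests on this generator therefore demonstrates
correctness and statistical power of the model under its own assumptions,
not clinical performance.

## Experiment sizes

The packaged experiments use 20 Mb regions (20 000 SNPs) with 40 replicates
per size range and one planted event per replicate, cycling the four CNV
classes — enough for per-class recall estimates at ~10% resolution while a
full battery runs in a few minutes on one CPU. Observed behaviour on these
runs: recall 100% for 400 kb–5 Mb events and ~70% for 50–400 kb events at
r = 0.13 (maternal duplications hardest, paternal events easiest), ~2 false
calls per CNV-free 20 Mb genome, coverage-only recall at 300 kb bins near
zero for sub-400 kb events, and fetal-fraction down-sampling 0.13 -> 0.10
recovered within +/-0.01.

## Known limitations

- The Gaussian variance-equals-mean emission ignores the extra dispersion
  of plasma depth; it is deliberately conservative.
- The coverage prior's effect is boundary-dominated (see above); a model
  with explicit per-position coverage emissions would accumulate depth
  evidence along events but breaks the HMM independence structure at larger
  window sizes.
- One reference plasma sample; a panel would reduce reference-specific
  bias.
- Inherited paternal CNVs are not modelled (maternal ones are absorbed by
  the maternal weights).
- Fixed transition constants; no training.
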