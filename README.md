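# plasmacnv

Non-invasive detection of **de novo fetal copy-number variants (CNVs)** from
deep maternal-plasma cfDNA sequencing, for researchers working on
sequencing-based prenatal screening.

Maternal plasma contains a mixture of maternal DNA (fraction `1 - r`) and
fetal DNA (fraction `r`, typically 5–15%). A fetal duplication or deletion of
a parental haplotype leaves two faint, complementary footprints in plasma:
it shifts the **allelic ratios** at SNP loci (by roughly `r/2`), and it
changes the local **depth of coverage** (by a factor `1 ± r/2`). `plasmacnv`
combines both signals in a single hidden Markov model:

- **States** are the 20 *phased inheritance patterns* — the possible
  multisets of parental haplotypes `{M_A, M_B, P_A, P_B}` the fetus can carry
  at a locus: 4 normal, 6 maternal duplications, 6 paternal duplications,
  2 maternal deletions, 2 paternal deletions. The copy count `|PP|` of a
  pattern is 2, 3 or 1 respectively.
- **Emissions** are the plasma nucleotide counts `{k_A, k_C, k_G, k_T}` at
  each SNP, modelled as independent Gaussians `k_x ~ N(mu_x, mu_x)` with
  `mu_x = p_x · #reads`, where `p_x` mixes the maternal haplotype weights
  `m_i (1 - r')` with the fetal contribution `r'/|PP|` per inherited
  haplotype, and `r' = |PP| r/2 / (|PP| r/2 + 1 - r)` is the copy-count-
  adjusted fetal fraction.
- **Transitions** use three fixed rates (0.01 within a class, 0.0001 to start
  a CNV, 0.001 to end one; two CNVs are never adjacent) and are modulated
  per position by a coverage-derived prior: window ratio values
  `WRV_i = N_{W_i} / Σ_{W ∈ 200 GC-nearest windows} N_W` of the studied
  plasma are compared against a scaled reference-plasma WRV per copy count,
  `WRV_i^{R,|PP|} = WRV_i^R (1 + (|PP| − 2) r/2)`, under zero-mean Gaussian
  noise with robustly estimated scale.

Viterbi decoding yields a per-SNP inheritance pattern; runs of CNV states
become BED calls. The package also ships a synthetic trio/plasma generator
with count-level CNV spike-in and fetal-fraction down-sampling, so the whole
method is testable without access to clinical sequencing data.

## Worked example

```python
from plasmacnv import (HmmCnvCaller, PlantedCnv, TrioSimConfig,
                       plant_cnv, simulate_trio, evaluate_calls, CnvCall)

# a synthetic 20 Mb pregnancy trio: 78x plasma, 32x maternal WGS, r = 13%
cfg = TrioSimConfig(n_snps=20_000, r=0.13, seed=1)
snp, win, truth = simulate_trio(cfg)

# plant a 1 Mb de novo maternal deletion at 8-9 Mb
cnv = PlantedCnv("maternal_del", 8_000_000, 9_000_000)
snp, win, truth = plant_cnv(snp, win, truth, cnv, cfg.r, seed_or_rng=2)

caller = HmmCnvCaller().fit(snp, win)   # estimates r, alpha, sigma_noise
print(round(caller.fetal_fraction_, 3), round(caller.sigma_noise_, 6))
for call in caller.call(snp, win):
    print(call.chrom, call.start, call.end, call.ip_class, call.n_snps)
```

Output:

```
0.125 0.000663
chr1 8020913 8996311 maternal_del 1011
```

The fitted fetal fraction (12.5%) is recovered from opposite-homozygote
sites; the planted 8.0–9.0 Mb deletion is called as a maternal deletion
spanning 1011 SNPs and covering ~98% of the true event (a hit under the
same-type ≥50%-span rule used throughout).

The same pipeline is available from the shell:

```bash
plasmacnv simulate --n-snps 20000 --out-prefix sim --seed 1
plasmacnv spike --snp-table sim.snps.tsv --window-table sim.windows.tsv \
    --cnv-class maternal_del --start 8000000 --end 9000000
plasmacnv call --snp-table sim.snps.tsv --window-table sim.windows.tsv \
    --mode combined --out calls.bed
plasmacnv evaluate --truth sim.truth.bed --calls calls.bed
```

## Layout

- `plasmacnv.patterns` — the 20-state phased-inheritance state space
- `plasmacnv.allele_model` — plasma allele distribution and emissions
- `plasmacnv.coverage_model` — WRVs, GC-neighbour normalisation, priors
- `plasmacnv.hmm` — transition structure, Viterbi, calls, evaluation
- `plasmacnv.simulate` — synthetic trio generator, spike-in, down-sampling
- `plasmacnv.caller` — sklearn-style `HmmCnvCaller` / `CoverageOnlyCnvCaller`
- `plasmacnv.io` / `plasmacnv.cli` — TSV/VCF/BED formats and the CLI

See `docs/methods.md` for the model assumptions, parameter choices and known
limitations.
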