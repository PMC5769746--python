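# rtquant

Quantitative analysis of reverse-transcriptase (RT) enzymes from two bench
assays that are usually reduced by ad-hoc scripts:

1. **Processivity from gel densitometry.** A single-cycle (single-turnover)
   primer-extension reaction, run with a trap that prevents a dissociated RT
   from rebinding, yields a product-length distribution on a denaturing gel.
   From one lane's intensity trace, `rtquant` subtracts background with a
   1-D rolling-ball (grayscale opening with a semicircular structuring
   element), calibrates pixel position against a single-stranded DNA ladder
   by ordinary least squares of log10(length) on pixel, and reports the
   intensity-weighted median product length *m* — the *macroscopic
   processivity*. With expected full-length product *L*, the
   uniform-dissociation model gives

   - incomplete fraction  f = (L − m) / L
   - per-nucleotide dissociation probability  p = f / L
   - per-nucleotide processivity  1 − p
   - N50 template length (half of initiated extensions terminate early)
     N50 = 0.5 / p, with the exact geometric-survival alternative
     ln 2 / (−ln(1 − p)) reported alongside.

2. **Misincorporation frequency from dual-UMI single-molecule consensus.**
   Each RT product carries a random 15-nt unique molecular identifier (UMI)
   at both ends; after PCR and paired-end sequencing, reads sharing the
   combined 30-nt key are the progeny of one molecule. A change is accepted
   as an RT error only when the identical substitution or indel appears in
   *every* read of a group with ≥ 3 read pairs, after trimming to the
   analysis windows and discarding any read with a base below Q20. PCR and
   sequencer errors, being absent from at least one read of a group, are
   rejected by construction. The report gives

   - substitution frequency = substituted nt / (qualifying products × nt per
     product)
   - indel frequency = indel events / qualifying products (N.A. when no
     event is observed).

A synthetic-data module generates RT libraries, explicit-lineage PCR pools,
paired FASTQ with a ground-truth error manifest, and rendered gel lanes with
known calibration, so both pipelines are validated by parameter recovery
without any external dataset.

## Worked example: processivity

```python
from rtquant import processivity_model

est = processivity_model(622, 616)   # full-length cDNA 622 nt, median 616 nt
print(f"incomplete fraction   {100 * est.incomplete_fraction:.3f}%")
print(f"p(dissociation)/nt    {est.p_dissoc:.3g}")
print(f"processivity/nt       {est.per_nt_processivity_pct:.3f}%")
print(f"N50 (uniform model)   {est.n50_uniform:,.0f} nt")
```

prints

```
incomplete fraction   0.965%
p(dissociation)/nt    1.55e-05
processivity/nt       99.998%
N50 (uniform model)   32,240 nt
```

i.e. on a 622-nt template whose median product is 616 nt, 0.965% of
initiated extensions terminate early; spread evenly over the template that
is a 1.55 × 10⁻⁵ dissociation probability per nucleotide (99.998%
per-nucleotide processivity), and a template of ~32,240 nt would be needed
before half of the initiated extensions fail to finish.

## Worked example: fidelity

```sh
rtquant simulate-reads --out-dir sim/ --n-molecules 200 --reads 3000 --seed 9
rtquant fidelity --r1 sim/r1.fastq --r2 sim/r2.fastq --ref sim/reference.fa \
                 --window-r1 0:130 --window-r2 130:260 --out-dir fid/
```

```
Dual-UMI consensus misincorporation analysis
==============================================
total reads              3,000
unique products          280
products with >=3 reads  199
nucleotide/product       260
total nucleotides        51,740
substitution frequency   7.7e-05
indel frequency          5.0e-03
naive per-read frequency 2.3e-03
```

The library was simulated with a true RT substitution rate of 1 × 10⁻⁴ and a
sequencing error rate of 1 × 10⁻³: the consensus estimate (7.7 × 10⁻⁵) sits
at the truth's scale while the naive per-read estimate (2.3 × 10⁻³) is
dominated by sequencer noise — the bias the UMI consensus removes.

Gel lanes work the same way (`rtquant simulate-gel`, `rtquant processivity`);
every command writes a `run_config.json` manifest so a run can be reproduced
exactly from its output directory.

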