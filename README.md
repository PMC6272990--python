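# bandpop

Population-genetic analysis of **dominant-marker band matrices** — the 0/1
presence/absence fingerprints produced by SSR, ISSR, RAPD, AFLP and
intron-targeted (IT-ISJ) marker systems scored from gels. The package
reimplements, as a tested and reusable pipeline, the full analysis used in
diversity surveys of the forage grass *Dactylis glomerata* and its
subspecies: marker-efficiency statistics, POPGENE-style diversity with the
Shannon partition, Dice-distance neighbor-joining trees with bootstrap
support, and one-way distance AMOVA with permutation tests. Because raw gel
scores are rarely deposited, a Balding–Nichols simulator generates band
matrices with known truth so every estimator has a parameter-recovery test.

It is aimed at plant germplasm and population-genetics researchers who work
with band data and want scriptable, reproducible versions of the statistics
classically computed with POPGENE, AMOVA 1.55, NTSYS-pc and Darwin.

## The statistics

With band *i* present at proportion *p<sub>i</sub>* (pooled over samples):

- **PIC** of a locus with allele frequencies *P<sub>j</sub>*:
  PIC = 1 − Σ *P<sub>j</sub>*². Per primer, the default treats each distinct
  multiband fingerprint as one allele (`pattern` mode); a per-band
  biallelic mode is available.
- **Ibav** = (1/n) Σ [1 − 2·|0.5 − *p<sub>i</sub>*|] — average band
  informativeness, maximal at *p<sub>i</sub>* = 0.5.
- **EMR** = mean number of polymorphic bands per primer;
  **MI** = Ibav × EMR, the marker-index efficiency score.
- **Diversity per band locus** under HWE with null-allele frequency
  q = √(1 − presence frequency), p = 1 − q:
  Na ∈ {1,2}, Ne = 1/(p²+q²), He = 1 − p² − q²,
  I = −(p ln p + q ln q). Group rows are locus means; the pooled total
  gives **It**, the mean of group values **Is**, and
  **S′ = (It − Is)/It** the between-group share (Is/It + S′ = 1).
- **Dice similarity** 2a/(2a+b+c) between profiles; 1 − Dice feeds a
  canonical Saitou–Nei **neighbor-joining** tree, with clade support from
  resampling band columns.
- **AMOVA** partitions squared Euclidean distances (= mismatching band
  counts) into among/within-group variance components σ²<sub>a</sub>,
  σ²<sub>w</sub>, with Φ<sub>ST</sub> = σ²<sub>a</sub>/(σ²<sub>a</sub>+σ²<sub>w</sub>)
  and a permutation p-value on the group assignment.

## Worked example

```python
import bandpop as bp

matrix, metadata, truth = bp.simulate_band_matrix(bp.SimulationConfig(seed=42))
report = bp.group_diversity(matrix, metadata.group_map("subspecies"))
print(f"It = {report.it_total:.3f}  Is = {report.is_within:.3f}  "
      f"Is/It = {report.is_over_it:.3f}  S' = {report.s_prime:.3f}")
```

prints

```
It = 0.553  Is = 0.398  Is/It = 0.719  S' = 0.281
```

i.e. at the default divergence (F = 0.2) about 72% of the Shannon
diversity of the simulated 20-accession collection lies within subspecies
and 28% between them — the same partition regime the real *Dactylis*
collection shows. The `examples/` directory holds one short script per
capability (simulation, efficiency, diversity, tree with bootstrap, AMOVA,
full pipeline); each prints its numbers with a note on what they mean.

A thin CLI mirrors the stages:

```sh
bandpop simulate --n-pops 20 --divergence 0.2 --seed 1 --out sim/
bandpop amova --matrix sim/matrix.tsv --primer-systems sim/primers.tsv \
              --metadata sim/metadata.tsv --groups subspecies --seed 1
bandpop run --config pipeline.yaml
```

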