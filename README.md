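# brewtime

Label-free proteomics time-course analysis for brewing fermentations.

`brewtime` is a tested, reusable implementation of the analysis chain used to
profile yeast proteome dynamics across commercial fermentation batches:

* **Quantification** — in-silico tryptic digestion (cleave after K/R, not
  before P, zero missed cleavages), peptides filtered to the 7–40 residue
  detectability window, and a per-protein correction factor
  `1 / Σ(in-range peptide lengths)` that converts residue-weighted PSM counts
  into parts-per-million abundances (each sample column sums to 10⁶).
* **Normalisation** — two-unique-peptide and both-replicate detection
  filters, replicate summing, `log2` + per-sample median centring, and
  row-mean normalisation (`log2(value / row mean)`).
* **Replicate QC** — per-time-point replicate Pearson r and single-replicate
  detection counts; all-by-all sample and protein similarity matrices over
  pairwise-complete observations.
* **Differential expression** — pairwise two-sided Student t-tests between
  time points, Benjamini–Hochberg adjustment per comparison, and the DEP
  rule `q < 0.05 ∧ |log2FC| ≥ 1`; DEP count matrices for all-by-all,
  consecutive, and batch-matched comparison schemes.
* **Trajectory clustering** — two-fold change filter, average-linkage
  clustering on correlation distance (1 − Pearson r), cluster extraction by
  dendrogram node depth (with oversized clusters re-cut deeper) or by a
  height threshold, and hypergeometric term enrichment over user-supplied
  annotation sets (GMT).
* **Pathway perturbation** — differential reaction perturbation scores
  (DRPS: the largest abundance span, max − min across samples, over a
  reaction's measured entities) and pathway scores
  `DPPS = sqrt(Σ DRPS² / n_reactions)`, plus entity-removal re-ranking to
  expose pathways carried by a few driver enzymes.
* **Co-regulation** — protein-complex member coverage, interacting vs
  non-interacting pair correlation distributions with a one-sided rank-sum
  shift test, and per-compartment correlation distributions with
  multi-localised proteins counted in every compartment.

A synthetic fermentation generator (`brewtime.synthetic`) emulates the study
design — 2 batches × 17 time points × 2 replicates, ~2,600 log-normally
distributed proteins, replicate Pearson r in 0.84–0.94, per-replicate
dropout, planted trajectory classes, batch shifts, and co-regulated
complexes — so every downstream stage is testable against known ground truth
without any external download.

## Worked example

```python
from brewtime.synthetic import SimulationConfig, simulate_timecourse
from brewtime.quantify import sum_replicates, row_mean_normalize
from brewtime.qc import replicate_qc, protein_correlation
from brewtime.coregulation import ComplexCatalog, pair_correlation_split

matrix, metadata, truth = simulate_timecourse(SimulationConfig(seed=42))
print("matrix:", matrix.data.shape, "measurements:", matrix.n_measurements())

rep = replicate_qc(matrix, metadata)
print(rep.head(3).to_string(index=False))
print("mean replicate r: %.3f" % rep.pearson_r.mean())

rmn = row_mean_normalize(sum_replicates(matrix, metadata))
corr = protein_correlation(rmn)
catalog = ComplexCatalog({c: set(m) for c, m in truth.complexes.items()})
inter, non = pair_correlation_split(corr, catalog)
print("interacting median r %.3f vs non-interacting %.3f (p=%.2e)"
      % (inter.median, non.median, inter.p_value))
```

prints

```
matrix: (2600, 34) measurements: 82171
batch time_point  pearson_r  n_overlap  n_single_replicate
   B1         0h   0.894812       2230                 370
   B1         6h   0.896259       2253                 347
   B1        24h   0.891611       2250                 350
mean replicate r: 0.893
interacting median r 0.696 vs non-interacting 0.000 (p=7.23e-127)
```

The 34 sample columns are 17 time points × 2 replicates; replicate
correlations sit inside the calibrated 0.84–0.94 band, roughly 360 proteins
per time point are seen in only one replicate, and the planted complexes
produce a strongly right-shifted correlation distribution for interacting
pairs (median 0.70 against ~0 for unrelated pairs).

## Command line

```sh
brewtime simulate --seed 1 --out sim/              # fixture with ground truth
brewtime run --config config.yaml --out results/   # full pipeline + manifest
brewtime quantify ppm --fasta p.fasta --psm psm.tsv --out ppm.tsv
brewtime qc correlate --intensity m.tsv --axis samples --out corr.tsv
brewtime diffexp --intensity centered.tsv --metadata meta.tsv --pairs all --out de/
brewtime cluster --intensity rmn.tsv --depth 3 --out clusters/
brewtime pathway score --intensity rmn.tsv --model pathways.json --top 100 --out rank.tsv
brewtime pathway leave-out --intensity rmn.tsv --model pathways.json \
    --remove BAT1,BAT2,PDC5 --out shift.tsv
brewtime coregulation complexes --intensity rmn.tsv --catalog complexes.gmt --out coreg/
```

`brewtime run` executes every stage in order and writes a `manifest.json`
with the package version, parameters, seed, per-stage row counts, and a
SHA-256 digest of every artifact; two runs with the same config are
byte-identical.

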