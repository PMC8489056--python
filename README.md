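# refstab

Reference-gene stability analysis and relative quantification for RT-qPCR.

Quantitative RT-PCR expression measurements are only as good as the
reference genes used to normalize them, and no gene is universally
stable: candidates must be validated for each species and experimental
condition.  `refstab` implements the complete candidate-screening
workflow used in entomological and plant expression studies — for
example, selecting reference genes across the developmental stages of an
insect before profiling wax-biosynthesis (fatty acyl-CoA reductase)
target genes:

* **Comparative ΔCq** — a gene's stability score is the mean standard
  deviation of its pairwise Cq differences, SD(Cq_j − Cq_k), against all
  other candidates.
* **geNorm** — relative quantities q = 2^−ΔCq (or E-corrected), pairwise
  log-ratio spreads combined into the stability value *M*, classical
  stepwise-exclusion ranking, and the pairwise-variation curve
  V(n/n+1) with the V < 0.15 rule for the optimal number of reference
  genes.
* **NormFinder** — a variance-components model on log expression that
  separates intragroup variance σ²ᵢg from intergroup deviations dᵢg and
  combines them into a stability value
  SV = (1/K) Σ_g (|d̃ᵢg| + √(σ̂²ᵢg/n_g)).
* **BestKeeper** — raw-Cq descriptives, the per-sample geometric-mean
  index, and Pearson correlations of every candidate with the index and
  with each other.
* **Consensus** — geometric mean of the four method ranks, the
  comprehensive ranking popularized by RefFinder-style tools.
* **2^−ΔΔCq quantification** — single- or multi-gene references,
  sample- or group-level calibrators, efficiency correction, and
  geometric-mean between-run (plate) correction factors.
* **Standard curves** — dilution-series fits with
  E% = (10^(−1/slope) − 1) × 100.
* **ORF utilities** — ATG-initiated, stop-terminated ORF discovery on
  both strands, translation, and degenerate motif scanning (e.g. the
  FAR-family NADPH motif `TGXXGF` and active-site `YXXXK`).
* **Synthetic data** — a seeded generator drawing Cq values from the
  variance-component model the stability methods assume
  (Cq = μᵢ + L_s + δᵢg + ηᵢs + ε), with known per-gene true stability
  √(τᵢ² + σᵢ²) for recovery testing.

## Worked example

Generate a study-shaped dataset (7 candidate genes, 8 developmental
stage/sex groups, 3 biological × 3 technical replicates) and rank the
candidates:

```python
import refstab as rs

ds = rs.generate_cq_dataset(rs.default_config(seed=7))
m = rs.collapse_replicates(ds.records, meta=ds.meta)
results = rs.ReferenceGeneStability(m).fit()
print(results.summary())
```

```
Reference-gene stability analysis
======================================================================
genes: 7   samples: 24   dropped (incomplete): 0

      deltacq_sd  deltacq_rank  genorm_M  genorm_rank  normfinder_SV  normfinder_rank  bestkeeper_r  bestkeeper_rank  consensus_geomean  consensus_rank
gene
g2        0.5862             1    0.5862            1         0.1672                1        0.9213                1             1.0000               1
g1        0.5950             2    0.5950            2         0.1821                2        0.8723                2             2.0000               2
g3        0.6790             3    0.6790            3         0.3002                3        0.7127                5             3.4087               3
g5        0.7348             4    0.7348            4         0.4273                5        0.7979                3             3.9360               4
g4        0.7372             5    0.7372            5         0.4082                4        0.7207                4             4.4721               5
g7        1.0875             7    1.0875            7         0.5971                6        0.6184                6             6.4807               6
g6        1.0353             6    1.0353            6         0.7151                7        0.4320                7             6.4807               7

Pairwise variation V(n/n+1): V2/3=0.1349, V3/4=0.1242, V4/5=0.1027, V5/6=0.1492, V6/7=0.1440
optimal number of reference genes (V < 0.15): 2
recommended panel: g2, g1
```

The generator built `g1` and `g2` as the most stable genes (true
stabilities 0.1 and 0.25 cycles); all four algorithms place them on top,
the consensus ranks them 1–2, and V2/3 = 0.135 < 0.15 says two reference
genes suffice for normalization.  Columns: the ΔCq mean pair SD and
geNorm *M* are in cycles-equivalent log2 units (lower = more stable),
NormFinder SV combines intra- and intergroup variation (lower = more
stable), and the BestKeeper *r* is each gene's correlation with the
geometric-mean index (higher = more stable).

The same pipeline runs from the shell:

```bash
refstab simulate --seed 7 --out-cq cq.csv --out-meta meta.csv
refstab report --cq cq.csv --meta meta.csv --out report.json
refstab quantify --cq cq.csv --meta meta.csv \
    --targets far1 --refs g1,g2 --calibrator N1 --out folds.csv
```

Real data enter as long CSV (`sample,gene,rep,plate,Cq`) or wide CSV
(first column `sample`, one column per gene), with metadata
`sample,group,biological_rep`.  "Undetermined"/empty wells become
missing values; technical replicates are averaged (spreads over 0.5
cycles are flagged); each algorithm runs on the complete-case submatrix.

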