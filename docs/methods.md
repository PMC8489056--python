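# Methods

This note documents the statistical procedures implemented in `refstab`,
the conventions chosen where the published method descriptions are
ambiguous, and what the synthetic-data generator does and does not
emulate.

## Data model

Quantification cycle (Cq) is the PCR cycle at which fluorescence crosses
the quantification threshold; it is a log2-scale abundance measure
(one cycle ≈ one doubling at 100% efficiency).  Raw data are per-well
records (sample, gene, technical replicate, plate, Cq).  Technical
replicates are collapsed by the **arithmetic mean of Cq** — Cq is
already logarithmic, so the arithmetic mean corresponds to a geometric
mean of quantities; averaging quantities instead would be wrong-scale.
Cells whose replicate range exceeds 0.5 cycles (configurable) are
flagged, never deleted, so a re-run from the same inputs reproduces the
same matrix.  Missing Cq ("Undetermined", empty wells) is never imputed:
every algorithm receives the complete-case submatrix over its gene set,
and the number of dropped samples is reported.  Imputing Cq would
manufacture stability where there is none.

## Standard curves and efficiency

For a dilution series, mean Cq per level is regressed (OLS) on log10 of
the relative template amount; amplification efficiency is

    E% = (10^(−1/slope) − 1) × 100,

so a perfectly doubling assay has slope −1/log10(2) = −3.3219 and
E = 100%.  Replicates are averaged per level before regression (pooled
per-well regression is available via a flag; on balanced noiseless data
the two coincide).  A positive slope is physically meaningless and is
flagged, but the efficiency is still reported so the caller can see the
magnitude of the problem.

## Comparative ΔCq

For each ordered gene pair (j, k), ΔCq_s = Cq_js − Cq_ks per sample; the
pair's dispersion is the sample SD (n−1 denominator, as everywhere in
this package) of ΔCq over samples, and gene j's score is the mean of its
G−1 pair dispersions.  Within-sample differencing cancels any shared
per-sample term, so the score is exactly invariant to RNA-loading
shifts.  Ranks ascend by score; ties break by input gene order,
deterministically.

## geNorm

Cq is transformed to relative quantities q_gs = B^(Cq_min,g − Cq_gs)
with B = 1 + E/100 (default E = 100%, i.e. q = 2^−ΔCq with the
minimum-Cq sample as calibrator at q = 1).  For a pair (j, k) the
variation is the SD over samples of log2(q_j/q_k); M_j is the mean of
gene j's pairwise variations.  Two reporting modes are provided:

* **single-pass** — M computed once on the full panel.  This gives every
  gene a distinct value and is the shape of published four-method
  comparison tables (a stepwise run necessarily ties the final pair).
* **stepwise** — the classical procedure: recompute M on the remaining
  panel, drop the highest-M gene (ties: the later gene in input order),
  repeat until two genes remain; each gene is reported with its M at
  exclusion, and the final two share the top of the ranking.

Genes whose full-panel M exceeds 1.5 are flagged unstable (the
conventional ceiling).  The optimal panel size uses normalization
factors NF_n,s = geometric mean of the top-n genes' q; V(n/n+1) is the
SD over samples of log2(NF_n/NF_{n+1}), and the optimal n is the
smallest with V < 0.15 (all G genes if the threshold is never met —
e.g. under an impossible threshold of 0).  The 0.15 cutoff is the
field's convention for "adding one more reference gene no longer
improves normalization"; the smallest qualifying n is preferred.  Note
V(2/3) is dominated by the third-ranked gene's instability, so the rule
recommends two genes exactly when every alternative third gene is
materially less stable than the best pair.

With E = 100%, log2 q differences equal −ΔCq differences, so on a
complete matrix the single-pass M coincides with the comparative-ΔCq
pair-SD score; the two columns differ once per-gene efficiencies are
supplied.  For G = 3, M_j reduces to the mean of gene j's two pair SDs.

## NormFinder

The model for log-scale expression of gene i in sample j of group g is

    x_igj = α_i + β_gj + d_ig + ε_igj,   ε ~ N(0, σ²_ig),

where β absorbs everything shared by all genes in a sample (loading and
any common regulation) and d_ig is the gene × group interaction —
systematic condition-dependent regulation, the defining defect of a bad
reference gene.  Because every step below is invariant to per-gene
affine recoding and to per-sample shifts, the implementation runs
directly on x = −Cq; any 2^±ΔCq quantity transform would give identical
results (published workflow descriptions disagree on the sign of that
exponent, which is immaterial here for exactly this reason).

Estimation (G genes, K groups, n_g samples per group):

1. sample-center: z = x minus the per-sample mean over genes;
2. per gene × group mean d̂_ig and variance s²_ig of z; the d̂ are then
   centered per gene (across groups) and per group (across genes),
   making them the two-way interaction residuals, which sum to zero
   within every group;
3. intragroup variance, correcting for the variance contributed by the
   shared centering (identified only for G ≥ 3, hence the G ≥ 3
   requirement):
   σ̂²_ig = max(0, [s²_ig − Σ_i' s²_i'g/(G²(1−1/G))]/(1−2/G));
4. common intergroup variance (method of moments, floored at 0):
   γ̂² = Σ d̂²_ig/((G−1)(K−1)) − (1/GK) Σ σ̂²_ig/n_g;
5. shrinkage of each deviation toward zero in proportion to its
   sampling noise: d̃_ig = d̂_ig · γ̂²/(γ̂² + σ̂²_ig/n_g);
6. stability value SV_i = (1/K) Σ_g (|d̃_ig| + √(σ̂²_ig/n_g)).

With a single group, steps 4–5 are skipped and SV_i = √σ̂²_i1, which
converges to the generator's true residual SD (verified by simulation
at n = 200).  Results report both the raw centered deviations (which
satisfy the per-group zero-sum invariant) and the shrunken deviations
that enter SV (which do not, since shrinkage weights are gene-specific).

## BestKeeper

BestKeeper works on raw Cq and deliberately keeps the shared per-sample
component: a good reference gene should covary with total template
amount.  The index is the per-sample geometric mean of all candidates'
Cq.  Per gene we report geometric/arithmetic mean, min, max, the
dispersion — mean absolute deviation from the mean by default (the
original tool's "SD (±Cq)" is an average deviation), classical n−1 SD as
an option, both always present in the output — CV%, and the Pearson r
(with two-sided p, via `scipy.stats.pearsonr`) against the index and
against every other candidate.  The ranking column uses r against the
index, descending (one r per gene, the shape of published tables);
zero-variance genes have undefined r and rank last with a flag.  Genes
with dispersion above 1 cycle are flagged "inconsistent" but never
auto-excluded.  Note the two BestKeeper outputs measure different axes:
the dispersion estimates a gene's own total variability (and tracks the
generator's true stability closely in recovery runs), while r measures
covariation with the panel consensus and is deliberately sensitive to
loading variation; on designs where loading spread is comparable to the
gene instabilities the r-based ordering discriminates less sharply.

## Consensus ranking

The comprehensive ranking is the unweighted geometric mean of each
gene's four method ranks, with tied positions receiving average ranks;
final order ascends by geometric mean, ties broken by input order.  This
is the documented, reproducible aggregation rule.  Web tools that
integrate the same four algorithms have been observed to apply
undocumented weighting, so their printed aggregate values need not be
reproducible from their own printed ranks; reports therefore always
carry the per-method ranks alongside the aggregate.

## Relative quantification

ΔCq_s = Cq_target,s − Cq_ref,s, with the reference Cq of a multi-gene
panel taken as the arithmetic mean of the genes' Cq (equal to log2 of
the geometric mean of their quantities, the geNorm-recommended rule).
Fold change is 2^−(ΔCq_s − ΔCq_cal); the calibrator is a sample, a group
(mean ΔCq over its samples), or — for plotting several targets on one
shared baseline — an explicit baseline ΔCq ("shared-calibrator" mode).
The Livak form assumes E = 100%; per-gene efficiency correction
(base 1 + E/100) is available behind a flag.  Between-run correction
divides each quantity by its plate's factor, the geometric mean of the
plate's shared calibrator quantities relative to the across-plate
geometric mean; factors are normalized to unit geometric mean so the
overall scale is untouched.  Group-level summaries are computed over
biological replicates; hypothesis testing is left to standard
statistical routines.

## ORF and motif utilities

ORFs are ATG-initiated, stop-terminated readings in the three frames of
both strands, translated with the standard genetic code (insect nuclear
CDS); a codon containing N is untranslatable and splits the reading.
Readings without a stop codon are not reported, and each stop reports
the ORF from its first upstream ATG (the longest-protein convention of
common ORF finders).  Coordinates are 0-based half-open including the
stop codon, so a CDS of L nt encodes L/3 − 1 residues — e.g. 1,590 and
1,497 nt CDS encode 529 and 498 amino acids.  Motif scanning treats X as
any residue and reports all, possibly overlapping, 0-based match starts.

## Synthetic data

The generator draws

    Cq_igjr = μ_i + L_gj + δ_ig + η_igj + p_plate + ε_igjr

with loading L ~ N(0, loading_sd²) shared by all genes in a sample,
group effects δ ~ N(0, τ_i²) drawn independently per gene × group
(condition-dependent regulation — what M and SV punish), sample effects
η ~ N(0, σ_i²), optional plate shifts, and technical noise
ε ~ N(0, tech_sd²) per well.  A gene's true stability is √(τ_i² + σ_i²),
and the truth object records it together with the realized loading
effects (so injected target genes can share them) and true fold
patterns.  All randomness flows from one explicit seed through a named
generator; no global state.

Defaults mirror the developmental-stage screening design this package
was built around: 7 genes × 8 stage/sex groups × 3 biological × 3
technical replicates, loading_sd = 0.5 cycles, tech_sd = 0.1 cycles,
true stabilities evenly spanning 0.1–1.0 cycles (split equally between
τ and σ), baselines at 16.4–21.5 cycles matching the observed median Cq
range of typical insect reference-gene panels.  Target genes are
injected with Cq lowered by log2(fold) per group, sharing the dataset's
loading effects.

What the generator does **not** emulate: amplification-curve shape and
per-well efficiency variation, inhibitor effects, heavy-tailed or
correlated noise, pipetting dropouts, and degradation gradients.
Passing recovery tests therefore show the algorithms are implemented
correctly and identify stability under the variance-component model
they assume — not that any particular real dataset satisfies that
model.

## Problem sizes and numerical choices

Recovery experiments use 100 simulated studies of the default design and
report medians; property checks use 100 random 5 × 8 matrices against
brute-force oracles.  These sizes give stable medians in seconds on one
CPU.  Variance estimates are floored at zero; SDs use the n−1
denominator throughout; ranking ties break by input order everywhere, so
every pipeline output is a deterministic function of (input, seed).  The
V(2/3) < 0.15 recovery scenario takes the default panel and makes its
two most stable genes near-noiseless (total SD 0.02 cycles), leaving
the remaining five at their default graded instabilities (0.4–1.0
cycles): a panel whose alternatives are all maximally unstable would
push V(2/3) above the threshold by construction, since V(2/3) is
dominated by the third-ranked gene.

## Known limitations

* The RefFinder-style aggregate reproduces the documented
  geometric-mean rule, not any particular web tool's hidden weighting.
* The NormFinder SV combination rule follows the original
  variance-decomposition publication; vendor binaries may differ in
  floors and small-sample corrections.
* BestKeeper's regression of genes on the index and its spreadsheet
  layout are out of scope; instrument-native file formats (RDML) are
  not parsed.
* Efficiency estimation is curve-based only (no per-well fluorescence
  modelling).
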