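# Methods

This note documents the models, conventions and numerical choices behind
`ctcdll3`, in the order data flows through the pipeline.

## IF gating model (`ifquant`)

An imaging event is one segmented object from whole-slide scanning of a
CTC-enriched, leukocyte-depleted blood product: per-channel mean intensity
over the nuclear and cytoplasmic masks on the 8-bit scale, cell area in
µm², and per-channel exposure factors (actual/reference exposure).
Channels are the nuclear stain, an epithelial cocktail (EpCAM/pan-CK/CK19),
DLL3, and a hematopoietic cocktail (CD45/CD66b/CD16).

**Normalization.** Intensities are divided by the channel's exposure
factor, assuming a linear detector; the threshold set (including the DLL3
cutoff of 20) is applied to normalized values. Saturated values (255) are
retained rather than censored — every gate sits far below saturation.

**Decision order.** (1) hematopoietic signal above the exclusion threshold
→ leukocyte; (2) a non-nucleated (nuclear signal below the nucleation
threshold) or sub-minimum-area event carrying any tumor-marker signal →
fragment; (3) otherwise the epithelial/DLL3 marker combination decides
between the three CTC classes and negative. Every gate uses strict `>`:
"exceeds a threshold of 20" is read literally, so an event at exactly 20.0
is negative, and the same strictness is applied uniformly. The six labels
partition the table by construction.

**Thresholds.** Only the DLL3 cutoff (20) and the reference volume (20 mL)
are fixed by the assay definition. The epithelial, hematopoietic-exclusion
and nucleation thresholds and the minimum intact area are assay
calibration constants; the shipped defaults (20, 40, 15, 30 µm²) were set
once with `calibrate_threshold` on the synthetic positive/negative control
populations (the analogue of calibrating on control cell lines and
leukocyte preparations) and are fully configurable.

**Fragments.** Circulating tumor fragments are described morphologically
(fragmented cytoplasm, extruding or absent nuclei); no numeric rule
exists. The surrogate here — tumor-marker-positive AND (anucleate OR
sub-minimum area) — is the simplest testable reading and is a stand-in,
not a validated definition.

**Enumeration.** Scaled count = raw count × (reference volume / actual
volume); raw counts stay integral, scaled counts are real. The per-patient
DLL3-positive CTC fraction is DLL3-only + dual CTCs over all CTC-class
events.

## Patient stratification and predictive metrics (`cohort`)

Patients are stratified at a 25% DLL3-positive CTC fraction. The published
wording ("fewer than 25%" vs "more than 25%") leaves exactly 25%
undefined; this package assigns the boundary to Pos, and the cutoff is a
parameter. The >75% High sub-flag follows the same convention in reverse
(strictly above). Patients with zero CTCs have an undefined fraction and
are excluded from stratification with a logged reason.

Sensitivity, specificity and PPV of the Pos stratum for clinical benefit
(PR or SD) carry exact Clopper–Pearson intervals from Beta quantiles. The
sidedness rule is: two-sided (1−α) when the point estimate is interior;
one-sided (1−α/2) — the closed forms (α/2)^(1/n) and 1−(α/2)^(1/n) — when
the estimate is exactly 100% or 0%. This mixed-reporting convention
reproduces all five published bounds (55–98, 59, 72), which is the
evidence that the exact method is the right one; no other method was
needed. Display rounding is nearest-integer percent; internal values keep
full precision.

Rank statistics are thin wrappers over scipy/statsmodels with fixed
conventions: Wilcoxon rank-sum exact for combined n ≤ 20 without ties and
the tie-corrected normal approximation otherwise; Holm step-down
(monotone, running-maximum) for multiplicity; Spearman with average ranks
on ties; two-sided p throughout; fully degenerate inputs (all observations
identical) report p = 1 with a flag rather than erroring.

## Single-cell stages (`scxpr`)

**QC.** Cell filters are strict as printed: genes > 500, UMIs > 1,000,
mitochondrial fraction < 0.1 (so a cell at exactly 500/1,000/0.10 is
removed); the CTC mode relaxes the floors to 300/500; the optional
low-capture filter keeps cells detecting ≥ 5% of all genes. The gene
filter (detected in ≥ 4 cells, i.e. excluding genes seen in ≤ 3 cells)
runs after the cell filter. Mitochondrial genes are identified by the
`MT-` symbol prefix (configurable). Filtering is implemented directly on
the AnnData because the inclusive filters in standard toolkits do not
honor the strict boundaries.

**Signature scores.** Per cell, genes are ranked by descending expression
with average ranks on ties; undetected genes share the capped rank
r_max + 1 and all ranks are capped there; U′ = Σ(signature ranks) −
n(n+1)/2 and score = 1 − U′/(n·r_max), clipped to [0, 1]. r_max defaults
to 1500, the customary cap for this scoring family. One deliberate
convention: a cell detecting *none* of the signature genes scores exactly
0 (the raw formula would give the small residue (n−1)/(2·r_max)). Scores
are rank-based and therefore invariant under any strictly monotone
per-cell transform, which also makes the raw-vs-normalized-input question
moot except for tie structure.

**Subtype assignment** is the argmax over the four signature scores; exact
ties are broken by the fixed prevalence order A > N > P > I and flagged.

**Epitope calls** use the ≥ 1 UMI rule (DLL3, SEZ6, B7H3 = CD276). The
printed keratin names "CK 4, 5, 6, 8, 10, 13, 18" map to
KRT4/5/6A/8/10/13/18 (CK6 resolved to the canonical KRT6A paralog).

**Dropout bounds.** A DLL3-negative cell detecting ≥ k_min (default 2)
Notch-pathway genes — which are coregulated with DLL3 — is a candidate
technical false negative. Because the exact published correction algorithm
is not specified in the main text, this operation deliberately reports
bounds, observed ≤ corrected ≤ observed + candidate fraction, rather than
presenting a point correction as the published algorithm.

**Venn accounting** enumerates every region of the ≤ 4-set positivity
partition; percentages are reported against the any-positive denominator
(as in the published coexpression diagrams) with a total-denominator
variant also available. **Pseudobulk** is the per-group sum of raw counts
(optionally per-million scaled), conserving global gene totals.

## CNV inference (`cnv`)

A deliberate simplification of HMM-based inference tools — the downstream
use is only the per-cell total score and the normal-cluster rule, both of
which are reproduced:

1. library-size normalize to a fixed depth (10⁴) and take log2(1 + x);
2. subtract the per-gene mean over the reference (immune/stromal) cells,
   making the reference mean exactly zero at this stage;
3. moving average over a genomic window within each chromosome (window an
   odd gene count, default 101, truncated at chromosome edges);
4. re-center each cell by its own median (removes per-cell global shifts,
   e.g. from detection-efficiency variation);
5. clip to ±1 log2 unit.

Total CNV score = Σ genes |processed value|. A cluster is called normal
when its median score is at or below the 0.25 quantile of all scores
(non-strict, so a degenerate all-zero input is normal) AND no single
sample contributes more than 75% of its cells; single-sample inputs skip
the mixing criterion with a warning. None of these four constants is
published; all are configurable.

## Synthetic-data generator (`synth`)

The generator defines the study conditions under which the pipeline is
validated; its defaults are fixed once.

**IF cohorts.** Event classes (DLL3-only / epithelial-only / dual CTC,
leukocyte, fragment, background) are drawn per patient and timepoint:
CTC counts Poisson with mean `ctc_abundance` × volume/20 (default 300 per
20 mL, the scale of a CTC-high SCLC draw), DLL3-positive with the
patient's generative fraction, 16% of positives also epithelial (matching
the published 11% dual / 58% DLL3-only / 31% epithelial-only class split);
leukocyte carryover Poisson (default 200/slide); fragment bursts only at
on-treatment timepoints (default mean 10⁴, the published up-to-50,000
scale); marker-positive background events at 0.18/mL as measured in
healthy donors. Intensities are class-conditional normals clipped to
[0, 255] — positives centered at 120–160 (sd 25–30), negatives at ~4
(sd 3), placing the classes well clear of the default gates the way
control-line calibration does; areas are normals with leukocyte mean
61 µm², CTC mean 77.7 µm², fragments ~15 µm². Per-slide exposure factors
(default 1) scale recorded intensities linearly.

**Count matrices.** A fixed gene universe (the subtype/epitope/Notch/
epithelial signature symbols, 13 MT- genes, filler genes) is assigned
round-robin to chromosomes with 1-kb spacing. Base rates are gamma-drawn;
subtype signature genes are floored at 2× the median rate (lineage TFs
and their programs are dependably expressed) and multiplied by
`signature_effect` (default 8) in their subtype's cells; Notch genes sit
low at baseline (0.3× median; the Notch-off neuroendocrine state) and are
lifted (1 + 9·ρ)-fold in truly DLL3-positive cells, ρ the coregulation
parameter (default 0.8); mitochondrial rates are pinned so their expected
library share is 5%. Designated DLL3-positive cells (default fraction
0.35, the published tumor-cohort median) carry 1 + Poisson(3) DLL3
transcripts, so truth equals pre-dropout detectability exactly. CNV
blocks multiply the rates of their genes in the affected tumor
populations. Library sizes are log-normal (median 5,000 UMIs, σ = 0.35);
counts are Poisson.

**Detection loss** is per-molecule binomial thinning with probability
`dropout` (default 0.3) modulated by a log-normal per-cell efficiency
latent, plus optional whole-gene zeroing (`gene_dropout`) used to inject
DLL3 technical false negatives for the correction analysis. The
per-molecule model was chosen over whole-gene Bernoulli zeroing because
(a) it is how detection loss actually behaves — abundant transcripts
rarely vanish entirely — and (b) whole-gene zeroing at rate 0.3 destroys
~9% of 4-gene-signature cells outright, which no scoring method can
recover; the Notch/DLL3 relationship is carried by expression
coregulation, which is what makes dropped-DLL3 cells recognizable from
their Notch signal at all.

**What the generator does not emulate:** ambient RNA, doublets, batch and
chemistry effects, spatial intensity artifacts, channel cross-talk, or
segmentation errors. Passing tests therefore demonstrate correctness of
the analysis logic under the stated generative models, not robustness of
the assay to those real-data artifacts.

## Problem sizes

The shipped tests and the acceptance script use cohorts of 8–20 patients
at ~260–300 CTCs each, count matrices of 300–5,000 cells × 800–2,000
genes, 100-seed recovery sweeps, 10,000-replicate interval-coverage
simulations and 51-gene CNV windows (the 101-gene default assumes
genome-scale annotations; the synthetic genomes carry 200 genes per
chromosome). These sizes were chosen so the statistical assertions have
comfortable margins while the whole suite runs in well under a minute per
module.

## Known limitations

- The fragment rule and the gating thresholds other than DLL3-20 are
  package conventions, not published constants.
- The dropout assessment brackets the corrected DLL3 fraction; it does not
  reproduce the unpublished correction algorithm.
- The CNV stage has no HMM state calling or subclone tree; it should not
  be used for breakpoint-level inference.
- Clustering is taken as an input to tumor-cell calling (population truth
  or an external clustering); the package does not cluster.
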