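# Methods

## Overview

`ribocontrast` quantifies transcription- and translation-level gene
expression changes in a three-group behavioural design — homecage
baseline, immediate shock (stimulus without association) and contextual
fear conditioning (context–shock association) — from paired ribosome
footprint and total-mRNA libraries, and separates association-specific
genes by subtracting the immediate-shock response from the CFC response.
All statistics operate on per-gene counts against a single
representative transcript per gene; isoform-level quantification is out
of scope.

## Quantification model

RPKM is computed from raw counts as `count · 10⁹ / (length · library
size)`. Translational efficiency is the per-replicate ratio of footprint
RPKM to total-mRNA RPKM for the same (group, replicate) pair; group TE
is the natural-scale mean over replicates (a geometric-mean variant is
available via `log_scale_mean=True`). Any RPKM of zero, or TE built from
one, is carried as an explicit undefined flag and excluded from every
log2-based analysis — undefined is a state, not a number.

Cross-library normalization defaults to **median-of-ratios** scaling
(per-library factor = median of ratios to the per-gene geometric mean,
over genes expressed everywhere). Quantile normalization is selectable
(`normalization: quantile`), but it is not the default because it is
biased precisely in this design: when a minority of genes is strongly
induced in the stimulated groups they occupy the top ranks of those
libraries, the rank-to-reference mapping then compresses unregulated
high-expression genes by tens of percent, and spurious down-calls
follow. Median-of-ratios is insensitive to a regulated minority. The
method used is recorded in every run summary.

## Differential calling

Per-gene ratios vs homecage (group-mean RPKM for the transcription
level, group TE for the translation level) are thresholded at
ratio > 1.5 (up) and ratio < 0.667 (down), strict inequalities, so a
boundary value is unchanged. With n = 2 replicates no per-gene variance
test is fitted; instead, when count matrices are supplied the caller
applies a reliability guard: the |log2 ratio| must also exceed 3× its
standard error, computed by the delta method with per-count variance
`1/c + α` on the log scale, where the negative-binomial dispersion α is
pooled from replicate pairs via `E[(c₁−c₂)²] = 2μ + 2αμ²` on
size-factor-scaled counts. The guard suppresses calls on genes whose
coverage makes a 1.5-fold excursion indistinguishable from noise, while
leaving well-measured genes governed by the fold cutoff alone; planted
effects of 1.5 log2 units remain fully detectable. At the default study
conditions (1000 genes, 10⁶ reads/library) the 3×SE point of a
TE contrast sits near 200 reads per library, which is where precision
would otherwise erode.

Venn regions are direction-aware: *shared* requires the same-direction
call in both stimulated groups; *CFC-only* ("CFC minus immediate
shock") is called in CFC and not called in that direction in immediate
shock. Gene lists are emitted sorted.

## Footprint QC

* **Length**: histogram plus the fraction of reads in the canonical
  28–32 nt window.
* **P-site offsets**: per read length, the offset in [10, 15] that
  maximizes codon-start meta-coverage — the number of reads whose
  5′ end + offset lands on the first nucleotide of an in-frame CDS
  codon. The start-codon column alone is not used because footprints
  spread along the CDS leave it only a handful of reads per minor
  length; codon-start coverage has the same maximizer in expectation
  with full power. The inherent period-3 ambiguity (12 vs 15) and all
  other ties resolve toward the canonical offset 12. Lengths with fewer
  than 100 reads fall back to 12 with a warning.
* **Frame fractions**: P-site position modulo 3 relative to the CDS
  start, counted only for P-sites inside the CDS.
* **Periodicity score**: on the mean-removed metagene profile
  (CDS side of a −20..+60 window around the start), spectral power at
  period 3 divided by summed power at periods 2–6. The score lies in
  [0, 1]; a flat (noise-only) profile scores near 1/5, strong
  3-periodicity near 1. This score is an artifact-defined metric chosen
  for interpretability, not a published statistic.
* **Replicate correlation**: squared Pearson correlation of log2 RPKM
  between replicate libraries, genes undefined in either member
  excluded pairwise.
* **PCA / clustering**: genes undefined in any sample are excluded,
  log2 values standardized per gene (mean 0, SD 1; zero-variance genes
  excluded and counted), samples embedded by PCA and clustered by
  complete linkage on Euclidean distances of the same standardized
  matrix.

## UTR analysis

Per-region length, GC%, and minimum free energy. The MFE is a
Nussinov-style dynamic program over nested structures with pair
energies G–C = −3, A–U = −2, G–U = −1 kcal/mol and a minimum hairpin
loop of 3 unpaired nt; temperature is implicit in the fixed constants.
This is a structure-propensity score, adequate for the *relative*
group comparisons the pipeline makes; it is not a nearest-neighbour
thermodynamic model and its absolute values are not comparable to
mfold/ViennaRNA energies. One useful symmetry of this model: the MFE is
invariant under sequence reversal (every nested structure mirrors, each
pair maps to itself). It is *not* invariant under A↔U/G↔C exchange,
because the wobble pair G–U maps to the non-pair C–A.

uORFs are AUG..in-frame-stop spans lying entirely inside the 5′UTR,
minimum 2 codons including the stop; each AUG contributes at most one
uORF (its first in-frame stop), and overlapping/nested uORFs from
distinct AUGs are all reported. TOP positivity requires a leading C
followed by ≥ 4 consecutive pyrimidines. The motif registry is
configurable; the defaults are 4 5′ motif types (uORF, TOP, a PAS-like
hexamer, a ≥8 nt pyrimidine tract) and 9 3′ motif types (PAS, AU-rich
element requiring ≥2 copies, CPE, Musashi element, Brd-box, K-box,
GY-box, a 15-LOX-DICE-like element, ≥6 nt UA-rich tract), giving the
motif-type factor 3 and 8 degrees of freedom respectively in the
two-way ANOVA. The exact motif identities beyond uORF and TOP are a
documented package choice, recorded in the run summary.

Group statistics: per scalar feature, two-sided Student's t-tests
between group pairs; per region, a two-way ANOVA without replication on
the motif × group table of presence percentages (one observation per
cell; both factors tested against the residual mean square), with
Bonferroni-adjusted group contrasts. Presence/absence, not hit counts,
feeds the percentages.

## Validation-assay analytics

* **Polysome traces**: peaks on a moving-average-smoothed copy; the
  monosome/polysome boundaries are the valleys flanking the 80S peak,
  the trace end closes the polysome region; manual boundaries override
  detection. Areas by trapezoidal integration with interpolated
  endpoints; the default synthetic grid step (0.05, ≤ σ/10 of the
  narrowest peak) keeps the area ratio within 0.2% of the analytic
  Gaussian value.
* **Heavy/light polysome qPCR**: relative abundance per fraction =
  `2^(Ct_spike − Ct_gene)` × a per-fraction total-RNA balance factor
  (an explicit input column); heavy/light ratios per replicate,
  averaged with SEM. Missing spike-in is a hard error because the
  normalization is undefined without it.
* **ΔΔCt**: `(Ct_gene,E − Ct_LC,E) − (Ct_gene,B − Ct_LC,B)` against the
  baseline condition, fold change `2^(−ΔΔCt)`, PCR efficiency fixed at
  2.0 per cycle (an efficiency-correction flag is reserved but not
  implemented).
* **Freezing**: 100 × frozen intervals / total intervals, default 60
  five-second intervals over a five-minute test.
* **Group tests**: one-way ANOVA with Tukey or Bonferroni post-hoc, or
  a two-group t-test; all reported with degrees of freedom.

## The synthetic-data generator

The generator emulates the target study design: 3 groups × 2
replicates × 2 assays = 12 libraries of 10⁶ reads over 1000 genes by
default. Planted classes and default proportions: a shared
immediate-early-gene class (4%, mRNA +1.5 log2 in both stimulated
groups), CFC-only and shock-only DEG and DTG classes (5% each, ±1.5
log2 at the respective level, signs random per gene), ribosomal
proteins (6%, short transcripts, −0.5 log2 constitutive TE offset, 80%
TOP-planted), mitochondrial ribosomal proteins (3%) and null genes
(67%). Effects below log2 1.5 for the planted "callable" classes are
rejected at configuration time. Baseline abundances are log-normal
(meanlog 3, sdlog 1); counts are negative-binomial with dispersion
α = 0.005 (variance μ + αμ²), which reproduces the high
between-replicate correlation of deep bulk libraries (log2-RPKM
R² ≈ 0.985–0.99 at default depth) while leaving room to degrade it via
the dispersion knob. Footprint expected counts multiply in the TE
effect, so footprint = mRNA × TE by construction. Footprint lengths are
drawn on 26–34 nt with mode 29; a read's P-site lands in frame 0 with
probability 0.85 (default), uniformly over CDS codons, and boundary
clamping shifts whole codons so the frame signal is preserved.

5′UTRs honour the planted uORF/TOP flags exactly: planted motifs are
embedded by construction (uORF cassettes of 2–4 codons at offset ≥ 8;
TOP tracts of C + 4–8 pyrimidines terminated by a purine), and
non-planted sequences are repaired by mutating the G of any accidental
uORF's AUG to C (a change that cannot create a new AUG). Rejection
sampling alone cannot deliver uORF-free UTRs at realistic lengths — a
random 150 nt UTR almost surely contains an AUG with an in-frame stop —
so the repair step is what makes "planted flag ⇔ scanner hit" an exact
identity on generated data.

What the generator does **not** emulate: rRNA/tRNA contamination,
adapter artefacts, alignment error, isoform structure, UMI/duplication
structure, start-codon ramp enrichment, and the pooling-vs-biological
variance decomposition of replicates (a single dispersion knob stands
in). Passing recovery tests therefore demonstrates the pipeline's
correctness on idealized count data with known truth, not robustness to
upstream artefacts of real libraries.

All generator outputs are pure functions of (config, seed); component
streams derive child seeds deterministically from the global seed, so
each stage is independently reproducible.

## Problem sizes and numerical choices

The test suite and acceptance script use 1000 genes × 12 libraries ×
10⁶ reads for recovery, 10⁵ reads for footprint QC, 200 random
sequences ≤ 12 nt for the folding oracle and 1000 random UTRs for the
motif oracles; these sizes give stable statistics while keeping a full
run in minutes on one CPU. Folding is capped at 4000 nt (warning above,
folded on the full length). Boundary ratio values are unchanged by
definition; tie-breaks (longest-UTR transcript, P-site offsets) are
deterministic and documented at the function level. TSV output uses
empty fields for undefined values and a fixed float format so identical
runs are byte-identical.

## Known limitations

* The fold-change caller is not a shrinkage estimator; with n = 2 it
  inherits the variance of the ratio of two small means, tempered only
  by the SE guard.
* The MFE model ignores stacking, loop-size energies and dangles;
  only relative comparisons between gene groups are meaningful.
* The two-way motif ANOVA has no within-cell replication, so
  interaction cannot be separated from residual.
* Boundary detection on polysome traces assumes the canonical
  40S < 60S < 80S < polysome peak order and at least four resolvable
  peaks; anything else requires manual boundaries.
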