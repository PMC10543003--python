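# Methods

## Scope and data model

`brewtime` analyses replicated label-free proteomics time courses of the
kind produced by sampling a fermenting yeast population: two production
batches separated by serial repitching, each sampled repeatedly through
fermentation, cold crash, and (for the later batch) conditioning.  All
matrices are proteins × samples; a missing value is `NaN`, never zero — a
zero spectral count is informative, an undetected protein is not.  Every
`AbundanceMatrix` carries a processing-state tag
(`raw → ppm / replicate_summed → log2_centered / row_mean_normalized`) and
stages refuse inputs at the wrong state rather than guessing.

## Spectral-count quantification (ppm)

Proteins are digested in silico with trypsin: cleavage C-terminal to K or R,
suppressed when the next residue is proline, zero missed cleavages.  Zero
missed cleavages is deliberate: the correction factor requires a unique,
non-overlapping peptide tiling of the protein, which missed cleavages would
destroy.  Peptides of 7–40 residues (inclusive) are considered detectable;
the per-protein correction factor is `1 / Σ(in-range peptide lengths)`.
A protein with no in-range peptide has no defined factor and is excluded
from ppm with a logged warning rather than being given factor 0 (which would
silently divide by zero).

Per sample, a protein's weight is `Σ_peptides PSM × peptide length ×
correction factor`.  Multiplying each PSM by its peptide's length converts
counts to observed residues; dividing by the protein's total detectable
length normalises protein size out, leaving a molar-like relative estimate.
Weights are scaled by 10⁶ and divided by the sample total, so every defined
column sums to 10⁶ (relative tolerance 10⁻⁶ in the invariant tests; the
implementation is exact up to float rounding).  The factor is isolated in a
single `CorrectionFactor` value so an alternative algebraic convention is a
one-line change.  Contaminant/decoy entries (`CON__`/`REV__` prefixes) are
dropped at read time and therefore never enter the experiment-total
denominator.

## Detection filters and normalisation

Before differential testing, proteins identified by fewer than two unique
peptides are removed, and a value is kept at a time point only when observed
in both replicates; nothing is imputed.  Replicate summing, used for
trajectory-level analyses, is intentionally more permissive: a value seen in
one replicate stands alone, because summing exists to maximise the number of
proteins retained.  Intensities are treated as log-normal throughout:
`log2_median_center` takes log2 and subtracts each sample's median (location
equalisation), `row_mean_normalize` expresses each value as
`log2(value / row mean)` so a protein's profile reads as fold change
relative to its own average.

## Replicate QC and similarity

All correlations are Pearson over pairwise-complete observations with a
minimum overlap of 3; pairs below the overlap threshold, and zero-variance
vectors, yield *missing* correlations rather than zeros, so undefined
quantities cannot leak into distribution summaries.  Replicate agreement is
assessed on log2 intensities (the raw scale is log-normal, and a handful of
high-abundance proteins would otherwise dominate r).  Protein–protein
correlations are computed on replicate-summed, row-mean-normalised profiles
across all time points of both batches; per-row affine changes do not affect
Pearson r, so this equals correlation of the summed log2 profiles.

## Differential expression

Each pair of time points is compared with a two-sided Student t-test (pooled
variance; Welch available as an option — no variant is canonical for this
design).  `log2FC = mean(A) − mean(B)`.  P-values are BH-adjusted *per
comparison*, matching per-volcano presentation; a global mode across all
pairs is available.  A protein is a DEP when `q < 0.05` and `|log2FC| ≥ 1`.
Zero-variance proteins are flagged and excluded from the BH pool — their
p-value is neither 0 nor 1, it is undefined.  With two replicates per group
the test has df = 2; no moderated-variance shrinkage is applied (the method
being reproduced uses a plain t-test), which is a real power limitation at
this design and is visible on synthetic data (see *Limitations*).

## Trajectory clustering and enrichment

Rows passing the two-fold filter (max |log2 ratio| ≥ 1 at some time point;
the boundary is inclusive) are clustered by average-linkage agglomeration on
correlation distance 1 − r, the standard metric for expression profiles
(Euclidean is an option).  Pairs with undefined correlation receive the
maximal distance 2 so the tree stays defined under missingness.

Two cluster-extraction modes are exposed:

* **node depth** (default): descend d levels from the root; every node
  reached at depth d, or leaf reached earlier, is one cluster (a balanced
  tree gives 2^d clusters; depth 3 gives the canonical eight).  Clusters
  larger than 500 members are re-cut at depth 5 from the root.
* **height**: remove the k − 1 highest merges to obtain exactly k clusters.

The depth cut reproduces the published cluster anatomy on balanced trees but
is sensitive to tree shape: when one trajectory class is far from all
others (as happens whenever one archetype is anticorrelated with the rest),
the top split isolates it and the depth cut then divides it internally
before nearer classes separate.  The height cut is insensitive to this and
is what the planted-trajectory recovery check uses; with four planted
archetypes at effect 2 log2 units and replicate noise 0.3 it recovers the
classes essentially perfectly (ARI ≈ 1.0), whereas the depth cut that
yields four clusters plateaus near ARI 0.7 for topological reasons, not
noise.

Enrichment is a generic one-sided hypergeometric over-representation test
over user-supplied term sets, BH-corrected across terms and filtered at
q < 0.05.  The universe defaults to all detected proteins (standard ORA
practice), not the genome; no GO DAG propagation is attempted.

## Pathway perturbation (DRPS / DPPS)

Scores are computed on row-mean-normalised log2 abundances.  For an entity,
the span is `max − min` across samples, which equals the maximum absolute
difference over all sample pairs (the parameter-free reading of "maximum of
differences between samples"); a reaction's DRPS is the largest span over
its measured entities and 0 when none is measured.  The pathway score is
`DPPS = sqrt(Σ DRPS² / n_reactions)` where `n_reactions` is the *model's*
reaction count — unmeasured reactions stay in the denominator, so sparsely
covered pathways are not inflated, and a coverage column lets users filter
low-coverage pathways.  Entities in several pathways contribute to each
independently.  Ties in the ranking break alphabetically by pathway id.
`leave_out_rerank` recomputes all scores with a set of entities masked and
reports per-pathway rank shifts, exposing pathways whose score rides on a
few driver enzymes.

## Co-regulation

"Interacting" means co-membership in at least one catalogued complex
(complex variants are discrete complexes; binary interactions can be given
as two-member complexes).  Interacting and non-interacting r distributions
are compared with a one-sided Wilcoxon rank-sum test (interacting higher) —
the test is an addition of this package, the underlying comparison is a
distribution shift.  Pairs with undefined r are excluded from both groups
and counted separately.  The non-interacting background is all other defined
pairs; matched sampling is not applied by default.

## The synthetic generator

Every value is `2**(baseline + trajectory + batch shift + complex factor +
replicate noise)`: effects are additive in log2 space, matching the
log-normal intensity model.  Defaults encode the emulated study design:

| parameter | default | rationale |
|---|---|---|
| proteins | 2,600 | detected-proteome scale |
| time points | 17 (7 + 10) | two batches; 3 conditioning points in the repitched batch |
| replicates | 2 | independent duplicates per time point |
| baseline log2 | N(20, 2) | LFQ-like dynamic range (~6 orders of magnitude) |
| replicate noise sd | 0.72 log2 | calibrated so replicate Pearson r sits mid-band in 0.84–0.94 |
| dropout rate | 0.14 | ≈ 360 single-replicate detections per time point out of 2,600 |
| trajectory classes | 4 × 150 at 2 log2 | early peak, late rise, flat-then-drop, monotone decline |
| batch shift | 50 proteins, +1.5 log2 in B15 | repitching-associated abundance shift |
| complexes | 20 × size 5, loading 0.9 | co-regulated modules |

The replicate-noise calibration follows from the variance decomposition
r ≈ V_between / (V_between + σ²_noise): with between-protein log2 variance
≈ 4.3 (baseline sd 2 plus planted effects), σ_noise = 0.72 puts r near 0.89
and the full band 0.84–0.94 corresponds to σ ∈ [0.52, 0.90], so the default
sits comfortably inside it across seeds.

Trajectory archetypes are functions of batch-normalised time in [0, 1]
(early peak: Gaussian bump at 0.15; late rise / flat-then-drop: sharp
logistics at 0.75–0.8; monotone decline: early exponential decay).  The
shapes were chosen to be mutually distinguishable under correlation distance
(max between-class |r| ≈ 0.5, except the late pair which is intentionally
anticorrelated); four equally spaced linear ramps would not be separable at
realistic noise and would make any clustering check vacuous.

Complexes share a latent per-time-point factor: member effect
`= A·(ρ·λ_t + sqrt(1 − ρ²)·η_t)` with amplitude A = 1.5 log2 and loading ρ,
giving within-complex correlation that rises smoothly with ρ and vanishes at
ρ = 0 — the dial used by the co-regulation power checks.

Dropout marks a value missing (never zero) in exactly one replicate of a
time point, abundance-independent (MCAR) by default; an abundance-weighted
mode (MNAR) is available since real missingness is plausibly
intensity-dependent but the deposited evidence does not determine the
mechanism.  One `numpy` generator seeded once drives every draw, so equal
configs give bit-identical outputs.

PSM counts are drawn multinomially per sample over all detectable peptides
with probability ∝ protein abundance × peptide length — the inverse of the
ppm model.  Aggregated to proteins, selection probability is ∝ abundance ×
detectable length and columns sum exactly to the requested depth.

### What the generator does not emulate

Heteroscedastic per-protein measurement error (noise is homoscedastic in
log2), intensity-dependent missingness by default, correlated batch
processing artefacts, peptide-level interference/shared peptides, and
retention-time or spectral-level structure.  Passing tests therefore show
the *arithmetic and inference machinery* behaves as specified under the
stated noise model, not that biological conclusions transfer to any real
fermentation dataset.

## Problem sizes and numerical choices

Verification runs use deliberately modest sizes: 100 random ppm instances
(up to 1,000 proteins), 10⁴ random digests, 500 random pathway models, 1,000
two-group datasets of 1,000 proteins for the FDR study, 500 proteins for
trajectory recovery, and 100 null runs at 300 proteins for the co-regulation
null; the default 2,600-protein design is exercised end-to-end by the
pipeline checks.  Ties in hierarchical clustering follow SciPy's
deterministic merge order; equal DPPS ranks break alphabetically; BH is the
statsmodels step-up implementation verified against a hand-written oracle.
All tolerances used by the tests: ppm column sums 10⁻⁶ relative, oracle
agreements 10⁻¹² (float reduction order is the only divergence), correlation
oracles 10⁻¹².

## Limitations

* With two replicates per group (df = 2) and the calibrated homoscedastic
  replicate noise, the plain t-test plus fold-change gate detects almost
  nothing on synthetic data at the default noise level — real data escape
  this because most proteins have far smaller measurement error than the
  global calibration implies.  The FDR/power guarantees are demonstrated at
  n = 3 per group with sd 0.3.
* The depth-based dendrogram cut reproduces published cluster counts only on
  near-balanced trees; use the height mode when the number of clusters is
  the quantity of interest.
* DRPS uses the full sample span and is therefore sensitive to single
  outlier samples; no robust variant is provided.
* Protein groups are atomic identifiers; no razor-peptide reassignment is
  attempted.
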