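# Methods

## Biological setting and model

KEAP1 targets the transcription factor NRF2 (*NFE2L2*) for degradation;
loss-of-function *KEAP1* alterations, gain-of-function *NFE2L2* exon-2
alterations (point mutations in the DLG/ETGE degron motifs, or skipping of
exon 2, which removes the KEAP1-binding Neh2 domain), *CUL3* mutations and
*NFE2L2* amplification can all leave the pathway constitutively active.
The downstream consequence exploited here is transcriptional: target-gene
overexpression overwhelms splicing fidelity and produces reads on
junctions absent from reference annotation ("abnormal" junctions).

The classifier treats each selected abnormal junction, together with the
annotated junctions sharing one of its boundary coordinates (the same
splice site), as a *junction pair*. Per sample, the pair yields the
abnormal count k and the location total n = k + Σ(normal counts).
Conditional on n, k is modeled per class as beta-binomial: a binomial
whose success probability is Beta(α, β)-distributed. The beta layer is
essential — junction fractions vary between samples far beyond binomial
noise, and a plain binomial naive Bayes would be wildly overconfident.
Naive-Bayes independence across features is assumed; it is wrong in detail
(features co-respond to the same pathway) but is exactly what the
per-feature clipping is for: no single junction, however extreme, can move
the score by more than ±clip_bound.

The NRF2 score of a sample is

    score = ln P(Active) − ln P(Inactive)
          + Σ_j clip( ln f(k_j | n_j; α̂_Aj, β̂_Aj)
                    − ln f(k_j | n_j; α̂_Ij, β̂_Ij), ±clip_bound )

A sample is called Active when score ≥ threshold. Features with n = 0
contribute exactly 0 (the pmf of an empty trial is 1 under both classes);
nothing is imputed.

## Sample labeling

Mutation classes are ranked (oncogenic *KEAP1* > *NFE2L2* exon-2 hotspot >
non-oncogenic *KEAP1* > exon-2 non-hotspot > exon-2 skipping > *CUL3* >
*NFE2L2* CNA > other-exon *NFE2L2*); a sample's representative class is
the highest-ranked one present, while its label is determined by the best
functionality present: any Functional class ⇒ Active, else any Uncertain
class ⇒ Ambiguous, else Inactive. The two resolutions are deliberately
independent — under the post-evaluation map an Uncertain class can outrank
a Functional one, and the sample must still be Active.

Oncogenicity and hotspot status are consumed as input annotation, never
recomputed; a missing annotation column defaults to "Unannotated", which
routes *KEAP1* mutations to the non-oncogenic class and *NFE2L2* exon-2
mutations to the non-hotspot class. Noncoding alterations (silent, UTR,
intron, flank) never confer a class. *NFE2L2* records without exon
information fall back to the other-exon class with a logged warning.

Exon-2 skipping is called from raw junction reads: ≥ 2 reads on any
junction joining an exon-1 end coordinate (177264531, 177263402,
177263436, 177263528 on chr2, covering the annotated isoform boundaries)
to an exon-3/4 start coordinate (177233340, 177232584, 177232563). Raw
counts are used deliberately — the two-read rule is a detection-limit
criterion, not a relative-abundance one. *NFE2L2* amplification requires a
copy-number segment that contains the gene span entirely with
Segment_Mean > log2(3/2) ≈ 0.585. Gene spans are configuration
(`sjactiv.regions`, hg38 defaults), since copy-number calls only need an
interval containing the gene. Samples with more than 20,000 mutations are
excluded (strictly more; the boundary sample is retained).

## Feature selection

Per cancer-type cohort with at least two Active samples:

1. candidate abnormal junctions: unannotated, summed raw count ≥ 10 in
   the cohort (a per-sample-max reading is available via
   `count_filter_mode`);
2. normalization, used only here: counts-per-million per sample with the
   denominator the sample's total over ALL junctions, then each junction
   divided by its cohort-mean CPM. Dividing by the mean CPM rather than a
   raw-count mean keeps both stages on one scale;
3. one-sided rank test, alternative Active > Inactive, on the normalized
   values. The groups are unpaired, so the two-sample Mann–Whitney test is
   the appropriate rank test. For small groups (≤ 20,000 group
   assignments, which covers both group sizes ≤ 8) the p-value is computed
   exactly by enumerating midrank sums over all assignments — correct
   under ties, where the classical exact tables are not; larger groups use
   the tie-corrected normal approximation with continuity correction;
4. Bonferroni correction with m = the cohort's candidate count (selection
   is defined per cancer type), selection at adjusted p ≤ 0.001.

Selections are unioned across cohorts keyed by abnormal-junction identity
(provenance kept, deterministic (chrom, start, end) order) and each
junction is bound to all annotated junctions sharing its donor or acceptor
coordinate; the pair's n aggregates every partner at the location.
Junctions with no annotated partner are dropped with a logged reason.

By construction the selected set is monotone: raising the count filter or
lowering α can only shrink it.

## Fitting and scoring

Per feature and class, (α, β) maximize the beta-binomial log-likelihood.
Optimization runs over (ln α, ln β) with the analytic digamma gradient
(L-BFGS-B), bounded to [1e-6, 1e6], starting from method-of-moments
estimates. Numerical choices:

* the parameter cap 1e6 encodes the binomial limit (intra-class
  correlation 1/(α+β+1) ≤ 1e-6); the floor handles all-zero features,
  whose fitted mean falls below 1/(max n + 1);
* boundary tie-break: when the likelihood at the cap (at the fitted mean)
  is within 1e-6 of the interior optimum — as happens whenever the data
  are at-or-under binomially dispersed, where the likelihood is flat in
  α+β — the fit is reported at the cap rather than wherever the gradient
  test stopped;
* if the optimizer fails, the moment estimates are kept and flagged
  (`converged=False`).

Defaults: clip_bound 10, threshold 10, equal class priors (prior
log-ratio 0, so 0 is the natural threshold; empirical priors shift every
score by exactly ln(N_A/N_I) and are available by flag). Clipping is
applied to the per-feature log-ratio contribution. Automatic thresholding
by Youden's index is implemented nowhere on the default path — the
operating point is a fixed, interpretable margin on the log-ratio scale.

Two-fold cross-validation splits each class in half from a caller-supplied
seed; each half trains a model (feature selection rerun inside the
training half by default, so no selection leakage; a fixed feature list
can be supplied instead) and scores the other half, so every sample is
scored exactly once. Confusion counts are tallied at the threshold with
Active positive; specificity = TN/(TN+FP), precision = TP/(TP+FP),
recall = TP/(TP+FN), reported as two-decimal percentages and NaN (never a
silent 0) on empty denominators. The precision-recall curve places a point
at every distinct score threshold and integrates the area with nonlinear
PR interpolation (false positives linear in true positives between
operating points, precision integrated exactly over recall), the standard
continuous convention for PR curves.

## Reintegration of Uncertain classes

A model fitted on Active/Inactive samples scores the held-out Ambiguous
samples; per representative mutation class, the fraction at or above the
threshold decides: > 40% ⇒ Functional, < 10% ⇒ Non-Functional, otherwise
the class remains Uncertain and its samples stay excluded. Both boundaries
are strict — exactly 40.00% or 10.00% keeps a class Uncertain. After
updating the functionality map, every sample is re-resolved through the
hierarchy (a sample of a dissolved Non-Functional class falls back to its
next class, or to Inactive), and selection + fitting rerun on the updated
labels. One round is performed; with no boundary crossings the relabeling
is a fixed point. Reclassification operates at mutation-class granularity,
not per protein variant — a known limitation, as heterogeneous variants
within a class share one verdict.

## Synthetic data

The generator emulates exactly the structure the classifier assumes. Per
feature, the Inactive-class mean abnormal fraction is drawn uniformly from
[0.01, 0.04] at concentration α+β = 50 (intra-class correlation ≈ 0.02);
the Active mean is `effect` × the Inactive mean at the same concentration.
Location coverage n is negative-binomial per (sample, feature) with mean
200 and shape 5 — coverage is outside the classifier's model, so its form
only needs to be realistically dispersed. Each abnormal junction has an
annotated partner carrying n − k at the shared donor coordinate; decoy
unannotated junctions are drawn identically for both classes; annotated
background junctions give the per-sample totals realistic bulk. Mutation
and segment tables are generated consistently with the intended labels
(oncogenic *KEAP1* records for Active samples; *CUL3* records or *NFE2L2*
amplification segments for Ambiguous ones), and labels are then *derived*
from those tables through the labeling code, not asserted.

Defaults (60 Active, 600 Inactive, 30 Ambiguous, 40 features, 20 decoys,
effect 3, Ambiguous samples Active-like with probability 0.8, two cohort
strata) give a strongly separable problem with the 1:10 class imbalance
typical of pathway activation in pan-cancer data; they are sized so the
full pipeline runs in seconds on one CPU. Everything is deterministic in
the mandatory seed.

What the generator does **not** emulate: real genomic coordinates and gene
structure, correlated features (all features are conditionally
independent, matching the naive-Bayes assumption rather than challenging
it), cohort-specific effect heterogeneity, sequencing-depth gradients
between samples, or annotation errors. Passing tests therefore demonstrate
the correctness of the machinery and its behavior under the assumed
generative model — not the classifier's operating characteristics on real
tumor data, which depend on how far real junction counts deviate from
beta-binomial structure.

## Degenerate inputs and tie-breaks

Empty feature lists refuse to fit with a clear error; a model with zero
features still scores (prior-only). Features with no informative sample in
one class are dropped at fit time, logged. All-tied rank-test inputs give
p = 1. Junction tables are validated row-by-row with line numbers in
errors; per-sample totals are always recomputed from the matrix, never
trusted from metadata. Model JSON round-trips bit-exactly (full-precision
floats) and refuses unknown format versions, naming both versions.
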