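# Methods

## Scope and model

`pegrank` designs prime-editing reagents. Given a desired edit (ref →
alt at a genomic position), it enumerates every candidate combination of

* **pegRNA spacer** — 20-nt protospacer with an NGG PAM on either strand,
  whose SpCas9 nick (between protospacer positions 17/18, 3 nt 5′ of the
  PAM) lies 5′ of the edit;
* **3′ extension** — RTT (reverse-transcription template, encoding the
  edited strand from the nick) followed by PBS (primer binding site,
  complementary to the protospacer-side of the nick), over a grid of
  lengths;
* **ngRNA** — optional second nick on the non-edited strand (PE3), with
  PE3b status when the ngRNA spacer matches only the edited sequence;

scores 23 features per design, predicts editing efficiency with a
gradient-boosted tree model, and ranks candidates.

## Coordinate conventions

All nick/edit arithmetic happens in *oriented* coordinates (the PAM
strand read 5′→3′; minus-strand candidates work on the reverse
complement of the window). `target_pos` is the 1-based distance from the
nick to the first edited base, so the classic HEK3 +1 edit has
`target_pos = 1`. `target_end_flank = rtt_len − (target_pos − 1) −
len(new allele)` counts downstream homology after the edit on the RTT.
`ngrna_pos` is the signed nick-to-nick distance along the PAM strand
(positive = 3′ of the pegRNA nick).

Indels are VCF-normalized with one anchor base. Because left-alignment
is orientation-dependent for repeat-ambiguous indels, the minimal edit
is re-normalized on each strand's own alleles; this makes enumeration
exactly symmetric under reverse complement (a property the tests
assert), at the cost that `target_pos` for an ambiguous indel is defined
per strand rather than globally.

## Enumeration parameters

Defaults (all configurable via `DesignConfig` or a key=value file):
PBS length 8–17 nt, RTT length 10–30 nt, ngRNA window ±150 nt,
minimum downstream homology (`min_end_flank`) 5 nt, search window
±200 nt around the edit, `max_target_pos = rtt_max − min_end_flank`.
These spans cover the ranges explored in the original prime-editing
literature. Extensions whose RTT starts with C are *flagged*, never
filtered — the efficiency model learns that penalty through the folding
features. PE2 (no ngRNA) designs are always emitted alongside PE3
designs; each is scored by its own model.

The scaffold defaults to the 76-nt SpCas9 sgRNA scaffold; with a 20-nt
spacer its G61 sits at full-pegRNA position 81, the position whose
pairing with a first-extension C is the canonical efficiency killer.

## RNA-folding disruption score

The full pegRNA (spacer + scaffold + extension, T→U) is folded at
equilibrium and the base-pair probability matrix P(i,j) computed. The
disruption score of extension position *i* (counted 5′→3′ from the
scaffold junction, continuing into the PBS when the RTT is shorter
than *i*) is

    D(i) = max_j P(i, j),   j over the scaffold positions.

High D(i) means that extension position is likely to sequester a
scaffold base and deform the structure Cas9 binds. D(1)..D(10) enter the
model; a 16-position profile (with Spearman correlation against observed
efficiency and a permutation p-value) is available as an analysis
operation.

Engines:

* `simple` — an exact McCaskill partition function over a deliberately
  minimal model: every Watson–Crick or GU pair contributes energy −1
  (kT = 1), no stacking, hairpin loops ≥ 3 nt. Inside recursion
  `Z(i,j) = Z(i,j−1) + Σ_k pair(k,j)·w·Z(k+1,j−1)·Z(i,k−1)`, outside
  pass by pushing each pair's exterior weight onto the interval it
  encloses. Small enough that tests verify it to 1e−9 against exhaustive
  enumeration of all structures for sequences ≤ 14 nt.
* `nearest_neighbor` (default; alias `vienna`) — ViennaRNA's
  Turner-model partition function via the Python bindings, 37 °C.
* `external` — shells out to `RNAplfold` with a full-length window
  (global fold) and parses the dot plot, for parity with pipelines that
  standardize on that tool.

Folding is computed on the whole pegRNA with a single global window
rather than a sliding one: at pegRNA lengths (≈120–180 nt) the two
coincide and the global fold has fewer knobs. Sequences are capped at
500 nt. Matrices are cached per (sequence, engine).

## Features (23)

cas9_score; pbs_len, rtt_len; pbs_gc, rtt_gc (fractions); is_dPAM
(edit breaks the pegRNA PAM — rechecked literally on the edited
sequence, so deletions that shift a new GG into place count as intact);
is_PE3b; n_sub, n_ins, n_del (from the minimal alleles; complex alleles
resolved by optimal global alignment, match +1 / mismatch −1 / gap open
−2 / extend −1, ties toward substitutions); target_pos, ngrna_pos,
target_end_flank; fold_d1..fold_d10. The PE2 model uses the 21 features
that exist without an ngRNA; in full vectors PE2 designs carry
`ngrna_pos = 0`, `is_PE3b = 0`. The ordered schema is hashed and
enforced at prediction time.

Cas9 activity is pluggable: a `TableScorer` reads per-spacer scores
produced by any external activity predictor (the fidelity path), and a
`SurrogateScorer` — a fixed position-nucleotide weight matrix plus GC-
and poly-T penalties squashed to [0,1] — keeps the pipeline fully
self-contained and deterministic. The surrogate is a documented
heuristic of this package, not a reimplementation of any published
predictor.

## Efficiency model

XGBoost regression (squared error) on percent-scale efficiency.
Evaluation is grouped nested CV: outer 5-fold split over *target
mutations* (group id = position + target allele) so no mutation appears
on both sides, inner 3-fold grouped CV tuning hyperparameters by
randomized search over the grid max_depth {2,5,9,14}, learning_rate
{0.01,0.1}, min_child_weight {1,5,10}, colsample_bylevel/bytree
{0.2,0.6,1}, subsample {0.2,0.6,1}, reg_alpha {0,0.1,1}, reg_lambda
{0,1,2}. The full grid has 3,888 points; the randomized search is capped
(default 60 candidates, configurable to exhaustive) with Spearman as the
selection metric. Boosting runs a fixed 300 rounds (depth and the
sampling parameters do the regularizing; chosen as a desk-scale default
and recorded in the model file). Group leakage is asserted
programmatically in every fold; the final model refits all rows with the
most-selected parameter set. One seed drives fold assignment, candidate
sampling and tree fitting. An external train/test split (one label per
row) is supported for screens that ship their own split.

Attribution is exact TreeSHAP through XGBoost's `pred_contribs`,
summarized as mean |SHAP| per feature; the ten folding features are also
reported as one aggregate. Models persist as a single JSON file
(schema + config + seed + CV report + booster); load→predict is
bit-identical to in-memory prediction.

## Ranking

Designs sort by predicted efficiency (PE3 model when an ngRNA is
present, PE2 model otherwise). Ties break deterministically: shorter
RTT, then PBS length closest to 13, then ngRNA nick closest to +60
(PE2 designs use a fixed stand-in of 60 for that term), then
lexicographic extension sequence. Default output keeps the top 3 designs
per variant (configurable, or the full table); undesignable variants go
to a skip table with a reason.

## Synthetic data

`make_toy_locus` builds five deterministic ~240-nt contigs with
engineered PAM placements: a single + strand site (target_pos 10), a
multi-site contig (two + and one − strand spacers), a PAM-free contig,
a PE3b-capable contig (opposite-strand protospacer overlapping the
edit) and a PAM-disrupting edit (SNV on the first PAM G, target_pos 5).
Background sequence is generated GG/CC-free so the engineered sites are
the only PAMs.

`simulate_training_table` emulates an efficiency screen: random 421-nt
loci (edit mix 60% SNV / 20% ins / 20% del, indels ≤ 3 nt), real
enumerated designs, real extracted features, and

    efficiency = clip(40 + Σ_f effect_f · z(feature_f) + N(0, σ²), 0, 100)

with σ = 5 and effects (percentage points per SD): cas9_score +12,
fold_d1 −8, pbs_gc +7, is_dPAM +6, target_pos −6, target_end_flank +4,
and deliberately weak n_sub/n_ins/n_del at −0.5 — qualitatively the
ordering the efficiency literature reports, with Cas9 activity and
first-position folding on top. Default scale: 50 loci × 40 designs =
2,000 rows. The generator reproduces the *structure* of a screen
(grouped designs, correlated features, additive signal); it does not
reproduce real-data properties such as nonlinear feature interactions,
batch effects, cell-type dependence or measurement error correlated
within replicates — so passing recovery tests demonstrates protocol
correctness, not real-world predictive accuracy.

## Numerical choices and degenerate inputs

Non-ACGT bases inside a design window abort that variant with a logged
skip (ambiguity codes poison PAM scanning). Windows truncate at contig
ends; a window too small to hold any spacer is an error. Spacer contexts
nearer than 4 nt to the window edge are N-padded for the activity
scorer. Constant feature columns in the simulator drop their effect with
a warning; constant D(i) columns report correlation as NaN. Predictions
clip to [0, 100]. Degenerate-probability guards: P matrices are
symmetric with row sums ≤ 1 and a zero band below the minimum loop.

## Problem sizes used in tests

Folding oracle: 200 random sequences ≤ 14 nt (exhaustive enumeration
stays in the tens of thousands of structures). Enumeration oracle: 100
random 80-nt windows. ML protocol: the full 2,000-row screen with a
16-candidate inner search (8 for the null screen) — the randomized-search
cap trades a marginal amount of tuning quality for tractable runtimes
and is the package's desk-scale default for its own test battery; the
library default remains 60.

## Known limitations

NGG PAMs only (no SpCas9-NG/SpRY), no dual-pegRNA designs, no off-target
or unwanted-editing assessment, no chromatin/cell-type features, no
pseudoknots or RNA-DNA hybrid thermodynamics in the folding model. The
shipped models in examples are trained on synthetic screens; training on
real screens requires assembling the documented training-table schema
(group_id, 23 features, efficiency %) from published data.
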