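# Methods and design rationale

This document records the numeric conventions and design decisions of
`hmmode` in enough detail to re-derive every quantity the package computes.
Defaults quoted here are the constructor defaults of `PipelineConfig` and
`CalibrationConfig`.

## 1. Profile architecture and estimation

A profile has `M` match states over the 20 standard amino acids, with
per-node insert emissions and the seven HMMER transition groups
(`m→m, m→i, m→d, i→m, i→i, d→m, d→d`). Node 0 holds the begin-state
transitions; `d→*` at node 0 and transitions out of node `M` follow the
HMMER3 file conventions (fields fixed to the values the format requires).

**Match column assignment.** An alignment column becomes a match state when
its residue occupancy is at least `symfrac` (default 0.5), the same rule and
default as `hmmbuild`. A degenerate alignment with no match column raises an
error rather than producing an empty model.

**Sequence weighting.** Position-based weights (Henikoff-style) are computed
over the match columns, so redundant training sequences do not dominate the
counts.

**Priors.** Weighted counts receive a symmetric Dirichlet pseudocount
`alpha` (default 1.0) per residue and per transition. `alpha = 0` is allowed
for exact maximum-likelihood estimates; transition groups with zero total
count then fall back to a uniform distribution instead of 0/0.

**Entropy-targeted effective sequence number.** Raw counts from a few dozen
sequences overstate certainty. Before adding priors, the count matrix is
scaled by a single factor chosen (by bisection) so that the mean per-column
relative entropy of the resulting emission estimates against the background
is at the target of **0.59 bits/column** — the same mechanism and default
target as `hmmbuild --eent` for amino-acid models. The scale is applied in
the pipeline and calibration paths; the bare `build_profile` leaves it off
unless `eweight_target` is passed, so unit tests can reason about raw
counts.

The same weighting is applied to the **false-positive count matrices** used
for emission modification (section 3). This matters: with ~30 FP sequences
per column, the *sampling* relative entropy between two draws from the same
underlying distribution is ≈0.46 bits in expectation — already above the
0.3-bit modification cutoff — so unweighted FP estimates would tag nearly
every column as discriminative and tilt the whole model against noise. With
the entropy target applied, only columns with genuine distributional
differences survive the cutoff. (This was diagnosed empirically: without it,
cross-validated thresholds on overlap fixtures collapsed to large negative
values and held-out sensitivity dropped below 0.2.)

**Background.** The uniform background (1/20 per residue) is used for both
estimation and scoring. Synthetic fixtures are generated against the same
background, so a composition-matched null is exact here; real-data use
could substitute an empirical background via `ProfileHMM.background`.

## 2. Scoring

Scoring is **single-hit local Viterbi** in bits: one pass through a
contiguous run of profile nodes, with uniform entry into any match state and
uniform exit from any match state. Entry and exit each cost
`log2(1/(M·L))` for a profile of `M` nodes against a sequence of length `L`.
Charging the full `M·L` normalisation on both ends centres the score so
that random background sequences score clearly below 0 bits — the zero-bit
default reporting floor is then a meaningful null boundary, and the no-FP
calibration branch can use 0 as its threshold. (HMMER's multihit grammar
distributes these costs differently; this package deliberately uses the
simpler symmetric single-hit form and documents it here because scores are
not meant to be numerically comparable to `hmmsearch` scores.)

Insert emissions equal the background, so inserts are score-neutral except
for their transition costs. A brute-force path-enumeration oracle in the
test suite verifies the implementation exactly on small models.

## 3. Emission modification

1. **FP detection.** Each subfamily profile scans all other subfamilies'
   training sequences; sequences scoring at or above the reporting floor
   (0 bits) are false positives. If more than `fp_cap` (default 200) are
   found, a seeded uniform sample of 200 is kept — enough to estimate
   20-dimensional per-column distributions, while bounding the cost of the
   cross-validation loop.
2. **Column mapping.** FP counts must be expressed in the coordinate system
   of the TP profile's match states. The default mode aligns each FP
   sequence to the TP profile by Viterbi and accumulates its residues into
   the match states its path visits (`align-to-profile`). The alternative
   mode builds an FP profile and aligns it to the TP profile
   column-by-column with a global DP over per-column Jensen–Shannon
   divergences (`profile-profile`). When the FP "alignment" is implied by
   Viterbi paths, match-column assignment uses `symfrac = 1e-9`: the columns
   already correspond to TP match states by construction, and the usual 0.5
   occupancy rule would spuriously drop sparsely-visited terminal columns.
3. **Modification.** For each match state where
   `RE(e_TP ‖ e_FP) ≥ re_cutoff` (default **0.3 bits**), emissions are
   re-weighted as `e′(a) ∝ e_TP(a)^(1+λ) · e_FP(a)^(−λ)` with tilt
   `λ = tilt` (default 1.0), floored at 1e−6 before renormalisation. States
   below the cutoff, and states with no mapped FP counts, are untouched.
   Relative entropies are computed on the floored, renormalised estimates,
   so they are always finite.

The 0.3-bit cutoff separates the two planted column classes cleanly once FP
counts are entropy-weighted; raising `λ` monotonically increases the
TP-vs-FP score separation on training data at the cost of generality, and is
exposed as a config knob rather than tuned automatically.

## 4. Threshold calibration

`calibrate` branches on the training score configuration of the *unmodified*
model:

* **`no_fp`** — no false positive reaches the reporting floor. The
  threshold is **0 bits** (the null boundary of the scorer) and the model is
  left unmodified.
* **`separable`** — false positives exist but `max(FP) < min(TP)`. The
  model is left unmodified and the threshold is the midpoint
  `(max(FP) + min(TP))/2`. No cross-validation is run. *Known limitation:*
  training sequences sit inside their own profile and score systematically
  above held-out members, so the midpoint inherits that optimism; on
  fixtures with a large generalisation gap the separable branch can have
  poor held-out sensitivity (see the worked example in the README). It is
  kept because it is the defined behaviour for this configuration; users
  who observe it can lower the threshold or force the overlap machinery by
  supplying harder negatives.
* **`overlap_modified`** — the score ranges overlap. Positives and FPs are
  split into `k = 10` stratified folds (k is lowered with a warning when a
  class has fewer than k members). For each fold, the model is **rebuilt
  and re-modified from the training fold only** (`remodify_per_fold`), the
  held-out fold is scored, and a confusion curve is evaluated on a shared
  candidate grid (midpoints between adjacent distinct scores of the pooled
  training scores, plus sentinels). The threshold maximising the
  **fold-averaged MCC curve** is chosen; ties resolve to the **higher**
  threshold (prefer specificity at equal MCC). An alternative
  `threshold_rule = "fold_mean"` (mean of per-fold argmax thresholds) is
  available but the averaged-curve rule is the default because it is robust
  to folds whose individual curves have degenerate plateaus.

MCC is defined as 0 when its denominator is 0; sensitivity/specificity are
`None` when their class is empty. Exhaustive-search oracles for the
threshold optimiser and `sklearn.metrics.matthews_corrcoef` cross-checks are
in the test suite.

The chosen threshold is stored as the **GA** (gathering) cutoff of the
emitted profile, with TC ≥ GA ≥ NC ordering enforced by the writer, so
`hmmode scan --cut-ga` and any HMMER-compatible consumer gate identically.

## 5. Clustering

Families can be pre-split by Markov clustering of a similarity graph
(k-mer similarity or imported BLAST tabular rows; asymmetric BLAST pairs are
max-symmetrised). Self-loops are set to each node's maximum incident weight,
expansion/inflation iterate to convergence (inflation default 2.0), and
clusters are read off as connected components of the limit matrix. The
test suite verifies exact recovery of planted block partitions.

## 6. Serialisation

Profiles are written as HMMER3/f ASCII: probabilities as negative natural
logs with `*` for probability 0, a COMPO line, the node-0 insert/transition
pair, and per-node match/insert/transition triplets. Fields use **6 decimal
places** so that a write→read round trip reproduces every probability to
within 1e−6 (5 decimals would only give ~5e−6 after exponentiation). The
writer validates models before writing (row sums within 5e−4, no
non-finite entries, cutoff ordering), and the reader reports line numbers on
format errors. `pyhmmer` is used in the tests as an independent oracle that
the emitted files parse and preserve emissions and cutoffs.

## 7. Synthetic data

`generate_superfamily` plants two disjoint column classes in a common
ancestor: **fold columns** (conserved across all subfamilies, fraction
`fold_frac`) and **function columns** (conserved within a subfamily,
different between subfamilies, fraction `func_frac`), each held with
probability `p_cons` per sequence; all remaining positions are background
noise, with optional insertions (`indel_rate`). Same seed ⇒ byte-identical
output; a config echo allows exact regeneration. A BLAST-like tabular
emitter feeds the clustering importer.

The generator is deliberately minimal: i.i.d. columns, uniform background,
no substitution-matrix structure, no domain architecture. It is designed to
reproduce the one phenomenon the method targets — shared-signal
cross-recognition with a small discriminative column set — not to imitate
real protein families. Results on it demonstrate the mechanism, not
real-world performance.

## 8. Study fixtures and seeds

The acceptance fixtures use 2 subfamilies × 45 sequences of length 120
(`fold_frac 0.45`, `func_frac 0.06`, `p_cons 0.85`), 30 training / 15
held-out per subfamily — parameters chosen so that the default profiles'
training scores genuinely overlap and the cross-validated branch engages.
All randomness is driven by explicit seeds; derived per-family and per-fold
seeds are produced by a fixed integer recurrence and kept below 2³¹ so they
are valid for any 32-bit seeded generator.
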