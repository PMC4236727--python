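"""Discrimination-threshold calibration by cross-validated MCC.

The calibrated cutoff for a subfamily profile depends on how its
true-positive (TP) and false-positive (FP) training scores relate:

* no FPs at all -> the default threshold of zero bits;
* all FP scores below all TP scores -> the midpoint of the gap, which
  classifies the training data with sensitivity = specificity = 1 (the
  gathering-threshold situation);
* overlapping scores -> the emissions are modified against the FPs and
  the threshold is chosen as the maximum of the fold-averaged MCC curve
  from 10-fold cross-validation over the positive training set.

The chosen threshold is written into the profile's GA cutoff so external
cutoff-aware scanners honor it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .hmm_io import ProfileHMM, set_cutoff
from .profiles import (
    Alignment,
    LabeledSeq,
    ScoreSet,
    build_profile,
    score_sequence,
    search,
)
from .discrimination import (
    DEFAULT_LAMBDA,
    DEFAULT_RE_CUTOFF,
    find_false_positives,
    map_columns,
    modify_emissions,
    sample_fps,
)


@dataclass
class ConfusionCounts:
    """2x2 confusion counts for a binary classification."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_at(scores: ScoreSet, t: float) -> ConfusionCounts:
    """Counts at threshold *t*: a sequence is called positive iff bits >= t."""
    tp = fp = tn = fn = 0
    for _, label, bits in scores.entries:
        called = bits >= t
        if label == "positive":
            tp += called
            fn += not called
        else:
            fp += called
            tn += not called
    return ConfusionCounts(tp, fp, tn, fn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    if c.total == 0:
        raise ValueError("cannot compute MCC on all-zero counts")
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def sensitivity_specificity(c: ConfusionCounts) -> Tuple[Optional[float], Optional[float]]:
    """(Se, Sp) = (tp/(tp+fn), tn/(tn+fp)); None where undefined."""
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return se, sp


def _candidate_thresholds(values: np.ndarray) -> List[float]:
    """Midpoints between adjacent distinct scores, plus -inf/+inf sentinels."""
    distinct = np.unique(values)
    mids = [(a + b) / 2.0 for a, b in zip(distinct[:-1], distinct[1:])]
    return [-math.inf] + mids + [math.inf]


def best_threshold(scores: ScoreSet) -> Tuple[float, float]:
    """Threshold maximizing MCC over midpoint candidates; ties -> higher t.

    Favoring the higher threshold on ties favors specificity.
    """
    pos = scores.positives()
    neg = scores.negatives()
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(
            "best_threshold needs both classes; use the separable/no-FP branches"
        )
    all_scores = np.concatenate([pos, neg])
    best_t, best_m = -math.inf, -math.inf
    for t in _candidate_thresholds(all_scores):
        m = mcc(confusion_at(scores, t))
        if m > best_m or (m == best_m and t > best_t):
            best_t, best_m = t, m
    return best_t, best_m


@dataclass
class ThresholdResult:
    """Outcome of threshold calibration for one profile."""

    threshold: float
    branch: str  # no_fp | separable | overlap_modified
    fold_thresholds: List[float] = field(default_factory=list)
    mcc_curve: List[Tuple[float, float]] = field(default_factory=list)
    train_se: Optional[float] = None
    train_sp: Optional[float] = None
    train_mcc: Optional[float] = None
    n_folds: int = 0

    def __post_init__(self):
        if not math.isfinite(self.threshold):
            raise ValueError("calibrated threshold must be finite")
        if self.branch not in ("no_fp", "separable", "overlap_modified"):
            raise ValueError(f"unknown branch {self.branch!r}")
        if self.branch == "no_fp" and self.threshold != 0.0:
            raise ValueError("no_fp branch must use the default threshold of 0")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("key\tvalue\n")
            fh.write(f"threshold\t{self.threshold:.4f}\n")
            fh.write(f"branch\t{self.branch}\n")
            fh.write(f"n_folds\t{self.n_folds}\n")
            for k, v in (
                ("train_se", self.train_se),
                ("train_sp", self.train_sp),
                ("train_mcc", self.train_mcc),
            ):
                fh.write(f"{k}\t{v if v is None else format(v, '.4f')}\n")
            for i, t in enumerate(self.fold_thresholds, 1):
                fh.write(f"fold_{i}_threshold\t{t:.4f}\n")


def threshold_from_scores(scores: ScoreSet) -> ThresholdResult:
    """Branch decision and threshold from a single labelled score set.

    This is the adapter entry point for externally computed scores: with
    no negatives the default zero threshold applies; with separated
    classes the midpoint of (lowest TP score, highest FP score) is a
    gathering-style cutoff; overlapping classes fall back to the best-MCC
    threshold (no cross-validation is possible without the sequences).
    """
    pos = scores.positives()
    neg = scores.negatives()
    if len(pos) == 0:
        raise ValueError("score set has no positives")
    if len(neg) == 0:
        result = ThresholdResult(threshold=0.0, branch="no_fp")
    elif neg.max() < pos.min():
        t = (pos.min() + neg.max()) / 2.0
        result = ThresholdResult(threshold=t, branch="separable")
    else:
        t, m = best_threshold(scores)
        if not math.isfinite(t):
            t = float(np.concatenate([pos, neg]).max() + 1.0)
        result = ThresholdResult(threshold=t, branch="overlap_modified")
    c = confusion_at(scores, result.threshold)
    se, sp = sensitivity_specificity(c)
    result.train_se, result.train_sp = se, sp
    result.train_mcc = mcc(c) if (len(pos) and len(neg)) else None
    return result


def _fold_indices(n: int, k: int, rng, strata: Optional[Sequence] = None):
    """Seeded k-fold assignment, stratified by *strata* labels when given."""
    folds = [[] for _ in range(k)]
    if strata is None:
        order = rng.permutation(n)
        for pos, idx in enumerate(order):
            folds[pos % k].append(int(idx))
    else:
        strata = np.asarray(strata)
        offset = 0
        for s in np.unique(strata):
            members = np.where(strata == s)[0]
            members = members[rng.permutation(len(members))]
            for pos, idx in enumerate(members):
                folds[(pos + offset) % k].append(int(idx))
            offset += len(members)
    return [sorted(f) for f in folds]


@dataclass
class CalibrationConfig:
    """Tunable parameters of the calibration stage."""

    symfrac: float = 0.5
    alpha: float = 1.0
    tilt: float = DEFAULT_LAMBDA
    re_cutoff: float = DEFAULT_RE_CUTOFF
    fp_cap: int = 200
    mapping_mode: str = "align-to-profile"
    report_threshold: float = 0.0
    # entropy-weighting target (bits/column) for profile building; None = raw
    eweight_target: float = 0.59
    # re-modify emissions inside every fold (no information leakage); the
    # cheaper variant modifies once on the full set and only CVs the cutoff
    remodify_per_fold: bool = True
    # alternative reading of the averaged-MCC rule: statistical mode of the
    # per-fold argmax thresholds, binned to 0.5 bits
    threshold_rule: str = "mean_curve"  # or "fold_mode"


def calibrate(
    positives: Sequence[LabeledSeq],
    negatives: Sequence[LabeledSeq],
    tp_aln: Alignment,
    k: int = 10,
    seed: int = 0,
    config: Optional[CalibrationConfig] = None,
    strata: Optional[Sequence] = None,
    name: str = "profile",
) -> Tuple[ProfileHMM, ThresholdResult]:
    """Full calibration of one subfamily profile.

    Builds the TP profile from *tp_aln*, scans *negatives* for false
    positives, applies the three-way branch logic, and returns the final
    (possibly emission-modified) profile with its GA cutoff set to the
    calibrated threshold, together with the :class:`ThresholdResult`.
    """
    if len(positives) < 2:
        raise ValueError("calibration needs at least 2 positive sequences")
    cfg = config or CalibrationConfig()
    rng = np.random.default_rng(seed)

    # normalize to the two-class training contract regardless of the
    # subfamily labels the caller's records carry
    pos_ids = {p.id for p in positives}
    positives = [LabeledSeq(p.id, p.seq, "positive") for p in positives]
    neg_pool = [
        LabeledSeq(s.id, s.seq, "negative")
        for s in negatives
        if s.id not in pos_ids
    ]

    model = build_profile(
        tp_aln, symfrac=cfg.symfrac, alpha=cfg.alpha, name=name,
        eweight_target=cfg.eweight_target,
    )

    fp_scores = (
        find_false_positives(model, neg_pool, cfg.report_threshold)
        if neg_pool
        else ScoreSet([])
    )
    tp_scores = search(model, list(positives), report_threshold=-math.inf)

    if len(fp_scores.entries) == 0:
        result = ThresholdResult(threshold=0.0, branch="no_fp")
        c = confusion_at(
            ScoreSet(tp_scores.entries + fp_scores.entries), 0.0
        )
        result.train_se, result.train_sp = sensitivity_specificity(c)
        return set_cutoff(model, "GA", 0.0), result

    min_tp = tp_scores.positives().min()
    max_fp = fp_scores.negatives().max()
    if max_fp < min_tp:
        t = (min_tp + max_fp) / 2.0
        result = ThresholdResult(threshold=t, branch="separable")
        c = confusion_at(ScoreSet(tp_scores.entries + fp_scores.entries), t)
        result.train_se, result.train_sp = sensitivity_specificity(c)
        result.train_mcc = mcc(c)
        return set_cutoff(model, "GA", t), result

    # --- overlap: modify emissions, cross-validate the threshold ----------
    fp_id_scores = dict((sid, b) for sid, _, b in fp_scores.entries)
    fp_seqs = [n for n in neg_pool if n.id in fp_id_scores]
    fp_seqs = sample_fps(fp_seqs, cap=cfg.fp_cap, seed=int(rng.integers(2**31)))

    n_pos = len(positives)
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positives; lowering fold count from {k} to {n_pos}"
        )
        k = n_pos
    folds = _fold_indices(n_pos, k, rng, strata=strata)

    # when not re-modifying per fold, modify once on the full training set
    full_mod = None
    if not cfg.remodify_per_fold:
        fp_em, dmap = map_columns(
            model, fp_seqs, mode=cfg.mapping_mode,
            alpha=cfg.alpha, re_cutoff=cfg.re_cutoff,
            eweight_target=cfg.eweight_target,
        )
        full_mod = modify_emissions(model, fp_em, dmap, tilt=cfg.tilt)

    fold_scoresets: List[ScoreSet] = []
    fold_thresholds: List[float] = []
    for fold in folds:
        held_out = [positives[i] for i in fold]
        train = [positives[i] for i in range(n_pos) if i not in set(fold)]
        if not held_out or len(train) < 2:
            continue
        if cfg.remodify_per_fold:
            fold_aln = tp_aln.subset([s.id for s in train])
            fold_model = build_profile(
                fold_aln, symfrac=cfg.symfrac, alpha=cfg.alpha, name=model.name,
                eweight_target=cfg.eweight_target,
            )
            fp_em, dmap = map_columns(
                fold_model, fp_seqs, mode=cfg.mapping_mode,
                alpha=cfg.alpha, re_cutoff=cfg.re_cutoff,
                eweight_target=cfg.eweight_target,
            )
            fold_mod = modify_emissions(fold_model, fp_em, dmap, tilt=cfg.tilt)
        else:
            fold_mod = full_mod
        entries = []
        for rec in held_out:
            entries.append((rec.id, "positive", score_sequence(fold_mod, rec.seq)))
        for rec in fp_seqs:
            entries.append((rec.id, "negative", score_sequence(fold_mod, rec.seq)))
        ss = ScoreSet(entries)
        fold_scoresets.append(ss)
        try:
            t_fold, _ = best_threshold(ss)
        except ValueError:
            t_fold = 0.0
        fold_thresholds.append(t_fold)

    # shared threshold grid: midpoints of all scores pooled over folds,
    # with finite sentinels just outside the observed range
    pooled = np.concatenate(
        [np.array([b for _, _, b in ss.entries]) for ss in fold_scoresets]
    )
    distinct = np.unique(pooled)
    grid = [distinct.min() - 1.0]
    grid += [(a + b) / 2.0 for a, b in zip(distinct[:-1], distinct[1:])]
    grid.append(distinct.max() + 1.0)

    curves = np.array(
        [[mcc(confusion_at(ss, t)) for t in grid] for ss in fold_scoresets]
    )
    mean_curve = curves.mean(axis=0)

    if cfg.threshold_rule == "fold_mode":
        finite = [t for t in fold_thresholds if math.isfinite(t)]
        binned = np.round(np.array(finite) / 0.5) * 0.5
        values, counts = np.unique(binned, return_counts=True)
        best = values[counts == counts.max()].max()
        threshold = float(best)
    else:
        best_m = mean_curve.max()
        # ties toward the higher threshold (favoring specificity)
        threshold = float(max(t for t, m in zip(grid, mean_curve) if m == best_m))

    # final model: re-modify on the full positive set
    fp_em, dmap = map_columns(
        model, fp_seqs, mode=cfg.mapping_mode,
        alpha=cfg.alpha, re_cutoff=cfg.re_cutoff,
        eweight_target=cfg.eweight_target,
    )
    final_model = modify_emissions(model, fp_em, dmap, tilt=cfg.tilt)
    final_model = set_cutoff(final_model, "GA", threshold)

    train_entries = [
        (rec.id, "positive", score_sequence(final_model, rec.seq))
        for rec in positives
    ] + [
        (rec.id, "negative", score_sequence(final_model, rec.seq))
        for rec in fp_seqs
    ]
    c = confusion_at(ScoreSet(train_entries), threshold)
    result = ThresholdResult(
        threshold=threshold,
        branch="overlap_modified",
        fold_thresholds=fold_thresholds,
        mcc_curve=list(zip(grid, mean_curve.tolist())),
        n_folds=len(fold_scoresets),
    )
    result.train_se, result.train_sp = sensitivity_specificity(c)
    result.train_mcc = mcc(c)
    return final_model, result
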