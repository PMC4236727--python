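"""Emission-probability modification against false-positive training data.

A subfamily's profile inevitably retrieves sequences from sister
subfamilies because the superfamily fold conserves many of the same
columns.  This module identifies those false positives, estimates what
they emit at each match state of the true-positive profile, measures the
per-column relative entropy between the two emission distributions, and
exponentially tilts the true-positive emissions away from the
false-positive ones at the discriminating columns — suppressing the
fold-shared signal while preserving the function-specific one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .hmm_io import ProfileHMM, UNIFORM_BACKGROUND
from .profiles import (
    Alignment,
    LabeledSeq,
    ScoreSet,
    _entropy_weight_scale,
    build_profile,
    score_sequence,
    viterbi_path,
)

#: Probability floor wherever a log or ratio is taken.
EPS = 1e-6

#: Default relative-entropy cutoff (bits) for calling a column discriminating.
DEFAULT_RE_CUTOFF = 0.3

#: Default tilt exponent.
DEFAULT_LAMBDA = 1.0


@dataclass
class DiscriminationMap:
    """TP-to-FP match-column pairing with per-column relative entropy.

    ``pairs`` holds one entry per TP match state, in increasing state
    order: (TP state index 1-based, paired FP state index or None, RE in
    bits or None for unpaired states).
    """

    pairs: List[Tuple[int, Optional[int], Optional[float]]]
    re_cutoff: float = DEFAULT_RE_CUTOFF

    def __post_init__(self):
        last = 0
        for tp_idx, _, re_bits in self.pairs:
            if tp_idx <= last:
                raise ValueError("TP state indices must be strictly increasing")
            last = tp_idx
            if re_bits is not None and re_bits < -1e-12:
                raise ValueError("relative entropy must be non-negative")

    def modified_states(self) -> List[int]:
        """TP state indices whose RE meets the cutoff."""
        return [
            tp
            for tp, fp, re_bits in self.pairs
            if fp is not None and re_bits is not None and re_bits >= self.re_cutoff
        ]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("tp_state\tfp_state\tre_bits\tmodified\n")
            for tp, fp, re_bits in self.pairs:
                mod = int(
                    fp is not None
                    and re_bits is not None
                    and re_bits >= self.re_cutoff
                )
                fh.write(
                    f"{tp}\t{fp if fp is not None else 'NA'}\t"
                    f"{re_bits:.4f}\t{mod}\n"
                    if re_bits is not None
                    else f"{tp}\tNA\tNA\t0\n"
                )


def relative_entropy(p, q, floor: float = EPS) -> float:
    """Kullback-Leibler divergence sum(p * log2(p/q)) in bits.

    Both distributions are floored at *floor* and renormalized first, so
    the result is always finite and non-negative.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    for name, d in (("p", p), ("q", q)):
        if abs(d.sum() - 1.0) > 1e-6:
            raise ValueError(f"distribution {name} does not sum to 1")
        if np.any(d < 0):
            raise ValueError(f"distribution {name} has negative entries")
    p = np.maximum(p, floor)
    p = p / p.sum()
    q = np.maximum(q, floor)
    q = q / q.sum()
    return float(np.sum(p * np.log2(p / q)))


def find_false_positives(
    tp_model: ProfileHMM,
    negatives: Sequence[LabeledSeq],
    report_threshold: float = 0.0,
) -> ScoreSet:
    """Negatives that the TP profile retrieves at or above the threshold."""
    entries = []
    for rec in negatives:
        bits = score_sequence(tp_model, rec.seq)
        if bits >= report_threshold:
            entries.append((rec.id, "negative", bits))
    return ScoreSet(entries).sorted()


def sample_fps(
    fps: Sequence[LabeledSeq], cap: int = 200, seed: int = 0
) -> List[LabeledSeq]:
    """Cap the FP training set at *cap* by uniform sampling (reproducible)."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    fps = list(fps)
    if len(fps) <= cap:
        return fps
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(fps), size=cap, replace=False)
    return [fps[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# column correspondence
# ---------------------------------------------------------------------------

def _fp_counts_by_viterbi(tp_model: ProfileHMM, fp_seqs, alpha: float):
    """Accumulate FP residue counts per TP match state via Viterbi paths."""
    from .profiles import _AA_INDEX  # shared residue index

    M = tp_model.M
    counts = np.zeros((M, 20))
    for rec in fp_seqs:
        _, path = viterbi_path(tp_model, rec.seq)
        for state, node, pos in path:
            if state == "M" and pos is not None:
                c = rec.seq[pos].upper()
                if c in _AA_INDEX:
                    counts[node - 1, _AA_INDEX[c]] += 1.0
    return counts


def _profile_profile_pairs(tp_em: np.ndarray, fp_em: np.ndarray):
    """Globally align two column-profile series by dynamic programming.

    The column distance is the Jensen-Shannon divergence between emission
    rows; a flat gap penalty leaves dissimilar columns unpaired.  Returns
    a list of (tp_index, fp_index) 0-based pairs on the optimal path.
    """

    def jsd(p, q):
        m = 0.5 * (p + q)
        return 0.5 * relative_entropy(p, m) + 0.5 * relative_entropy(q, m)

    n, m = tp_em.shape[0], fp_em.shape[0]
    gap = -0.6  # bits; below the match score of two unrelated columns
    S = np.full((n + 1, m + 1), -np.inf)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 diag, 2 up, 3 left
    S[0, 0] = 0.0
    for i in range(1, n + 1):
        S[i, 0] = S[i - 1, 0] + gap
        ptr[i, 0] = 2
    for j in range(1, m + 1):
        S[0, j] = S[0, j - 1] + gap
        ptr[0, j] = 3
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            match = S[i - 1, j - 1] + (1.0 - 2.0 * jsd(tp_em[i - 1], fp_em[j - 1]))
            up = S[i - 1, j] + gap
            left = S[i, j - 1] + gap
            best = max(match, up, left)
            S[i, j] = best
            ptr[i, j] = 1 if best == match else (2 if best == up else 3)
    pairs = []
    i, j = n, m
    while i > 0 or j > 0:
        if ptr[i, j] == 1:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif ptr[i, j] == 2:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def map_columns(
    tp_model: ProfileHMM,
    fp_seqs: Sequence[LabeledSeq],
    mode: str = "align-to-profile",
    fp_aln: Optional[Alignment] = None,
    alpha: float = 1.0,
    re_cutoff: float = DEFAULT_RE_CUTOFF,
    floor: float = EPS,
    eweight_target: Optional[float] = None,
):
    """Pair TP and FP match columns and estimate FP emissions per TP state.

    In the default ``align-to-profile`` mode every FP sequence is aligned
    to the TP model by Viterbi and its residues accumulated per TP match
    state, so the column correspondence is exact by construction.  In
    ``profile-profile`` mode an FP profile is built from an FP alignment
    (supplied, or implied by the Viterbi paths when absent) and the two
    column-profile series are paired by global dynamic programming over a
    column-distance score.

    Returns ``(fp_emissions, dmap)``: an (M, 20) array of FP emission
    distributions (background rows for unpaired states) and the
    :class:`DiscriminationMap`.
    """
    if not fp_seqs:
        raise ValueError("no false-positive sequences supplied")
    M = tp_model.M
    bg = tp_model.background
    fp_emissions = np.tile(bg, (M, 1))
    pairs: List[Tuple[int, Optional[int], Optional[float]]] = []

    if mode == "align-to-profile":
        counts = _fp_counts_by_viterbi(tp_model, fp_seqs, alpha)
        if eweight_target is not None:
            # same effective-count correction as profile building: raw FP
            # counts are noise-peaked at uninformative columns, and the
            # resulting spurious relative entropy would mark nearly every
            # column as discriminating
            counts = counts * _entropy_weight_scale(counts, alpha, bg, eweight_target)
        n_j = counts.sum(axis=1)
        for j in range(M):
            if n_j[j] == 0:
                pairs.append((j + 1, None, None))
                continue
            fp_emissions[j] = (counts[j] + alpha * bg) / (n_j[j] + alpha)
            re_bits = relative_entropy(
                tp_model.match_emissions[j], fp_emissions[j], floor
            )
            pairs.append((j + 1, j + 1, re_bits))
    elif mode == "profile-profile":
        # columns of the Viterbi-implied alignment correspond to TP match
        # states by construction, so every occupied column is kept (local
        # alignments ending early would otherwise drop terminal columns
        # below the default symfrac)
        fp_symfrac = 0.5
        if fp_aln is None:
            fp_aln = _implied_fp_alignment(tp_model, fp_seqs)
            fp_symfrac = 1e-9
        fp_model = build_profile(
            fp_aln, symfrac=fp_symfrac, alpha=alpha, background=bg,
            name=f"{tp_model.name}_FP", eweight_target=eweight_target,
        )
        col_pairs = dict(
            _profile_profile_pairs(
                tp_model.match_emissions, fp_model.match_emissions
            )
        )
        for j in range(M):
            if j in col_pairs:
                fj = col_pairs[j]
                fp_emissions[j] = fp_model.match_emissions[fj]
                re_bits = relative_entropy(
                    tp_model.match_emissions[j], fp_emissions[j], floor
                )
                pairs.append((j + 1, fj + 1, re_bits))
            else:
                pairs.append((j + 1, None, None))
    else:
        raise ValueError(f"unknown column-mapping mode {mode!r}")

    return fp_emissions, DiscriminationMap(pairs, re_cutoff=re_cutoff)


def _implied_fp_alignment(tp_model: ProfileHMM, fp_seqs) -> Alignment:
    """FP alignment whose columns are the TP match states (Viterbi-implied).

    Insert-state residues are dropped: the alignment only needs columns
    comparable to the TP profile's match states.
    """
    M = tp_model.M
    rows = []
    for rec in fp_seqs:
        _, path = viterbi_path(tp_model, rec.seq)
        row = ["-"] * M
        for state, node, pos in path:
            if state == "M" and pos is not None:
                row[node - 1] = rec.seq[pos].upper()
        rows.append((rec.id, "".join(row)))
    if len(rows) == 1:
        # build_profile needs >= 2 rows; duplicate the single sequence
        rows.append((rows[0][0] + "_dup", rows[0][1]))
    return Alignment(rows)


# ---------------------------------------------------------------------------
# emission modification
# ---------------------------------------------------------------------------

def modify_emissions(
    tp_model: ProfileHMM,
    fp_emissions: np.ndarray,
    dmap: DiscriminationMap,
    tilt: float = DEFAULT_LAMBDA,
    re_cutoff: Optional[float] = None,
    floor: float = EPS,
) -> ProfileHMM:
    """Tilt TP emissions away from FP emissions at discriminating states.

    At every paired match state whose relative entropy meets the cutoff,
    the emission distribution becomes

        e'(a)  proportional to  e_TP(a)^(1 + tilt) / e_FP(a)^tilt

    with all terms floored at *floor* and the row renormalized.  States
    below the cutoff, unpaired states, insert emissions and transitions
    are untouched.  ``tilt = 0`` is the identity.
    """
    if tilt < 0:
        raise ValueError("tilt must be >= 0")
    if re_cutoff is None:
        re_cutoff = dmap.re_cutoff
    fp_emissions = np.asarray(fp_emissions, dtype=float)
    if fp_emissions.shape != (tp_model.M, 20):
        raise ValueError("fp_emissions shape does not match the model")

    new_match = tp_model.match_emissions.copy()
    if tilt > 0:
        for tp_idx, fp_idx, re_bits in dmap.pairs:
            if fp_idx is None or re_bits is None or re_bits < re_cutoff:
                continue
            j = tp_idx - 1
            p = np.maximum(tp_model.match_emissions[j], floor)
            q = np.maximum(fp_emissions[j], floor)
            tilted = np.power(p, 1.0 + tilt) / np.power(q, tilt)
            new_match[j] = tilted / tilted.sum()

    out = replace(tp_model, match_emissions=new_match)
    out.validate()
    return out
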