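"""Profile construction from multiple alignments and local Viterbi scoring.

The scorer is a single-hit local-local Viterbi: any model segment may align
to any sequence segment.  Entry (begin state to any match state at any
sequence position) and exit (any match state at any position to the end
state) each cost a fixed log2(1/(M*L)) bits — uniform over the M*L
alignment cells at both ends.  Unaligned flanking residues are scored by
the null model, i.e. they contribute nothing to the log-odds score.
Charging both ends is the ln(mn)-style multiple-testing centering familiar
from local-alignment statistics: it cancels the inflation that maximizing
over all start/end cells gives to chance alignments, so unrelated random
sequences score well below 0 bits and the 0-bit reporting floor behaves
like a significance gate.  All scores are in bits (log base 2), matching
the semantics of GA-style cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio import AlignIO, SeqIO

from .hmm_io import AMINO_ACIDS, UNIFORM_BACKGROUND, ProfileHMM

GAP_CHARS = "-."

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Floor applied wherever a log of a probability is taken.
LOG_FLOOR = 1e-6


class DegenerateAlignmentError(ValueError):
    """Raised when an alignment cannot support any match column."""


class SequenceError(ValueError):
    """Raised for empty sequences or symbols outside the alphabet."""


@dataclass
class Alignment:
    """A protein multiple alignment: ordered (id, aligned string) rows."""

    rows: List[Tuple[str, str]]

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows have unequal lengths")
        for rid, s in self.rows:
            if all(c in GAP_CHARS for c in s):
                raise ValueError(f"row {rid!r} is all gaps")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> List[str]:
        return [rid for rid, _ in self.rows]

    def subset(self, ids: Iterable[str]) -> "Alignment":
        """Rows restricted to *ids*, dropping columns that become all-gap."""
        keep = set(ids)
        rows = [(rid, s) for rid, s in self.rows if rid in keep]
        if len(rows) < 2:
            raise ValueError("subset leaves fewer than 2 rows")
        cols = [
            j
            for j in range(len(rows[0][1]))
            if any(s[j] not in GAP_CHARS for _, s in rows)
        ]
        return Alignment([(rid, "".join(s[j] for j in cols)) for rid, s in rows])


def read_alignment(path, fmt: str = "fasta") -> Alignment:
    """Load an alignment from aligned FASTA or Stockholm."""
    msa = AlignIO.read(path, fmt)
    return Alignment([(rec.id, str(rec.seq).upper()) for rec in msa])


@dataclass
class LabeledSeq:
    """A sequence with a binary training label ('positive' or 'negative')."""

    id: str
    seq: str
    label: str = "positive"


def read_fasta(path, label: str = "positive") -> List[LabeledSeq]:
    return [
        LabeledSeq(rec.id, str(rec.seq).upper(), label)
        for rec in SeqIO.parse(path, "fasta")
    ]


@dataclass
class ScoreSet:
    """Labelled per-sequence bit scores from a profile scan."""

    entries: List[Tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self):
        for sid, label, bits in self.entries:
            if label not in ("positive", "negative"):
                raise ValueError(f"label must be positive/negative, got {label!r}")
            if not np.isfinite(bits):
                raise ValueError(f"non-finite score for {sid!r}")

    def positives(self) -> np.ndarray:
        return np.array([b for _, lab, b in self.entries if lab == "positive"])

    def negatives(self) -> np.ndarray:
        return np.array([b for _, lab, b in self.entries if lab == "negative"])

    def sorted(self) -> "ScoreSet":
        return ScoreSet(sorted(self.entries, key=lambda e: (-e[2], e[0])))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tlabel\tbits\n")
            for sid, label, bits in self.entries:
                fh.write(f"{sid}\t{label}\t{bits:.4f}\n")

    @classmethod
    def from_tsv(cls, path) -> "ScoreSet":
        """Adapter for externally computed bit scores (id, label, bits TSV)."""
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("id\t"):
                    continue
                sid, label, bits = line.split("\t")
                entries.append((sid, label, float(bits)))
        return cls(entries)


# ---------------------------------------------------------------------------
# profile building
# ---------------------------------------------------------------------------

def assign_match_columns(aln: Alignment, symfrac: float = 0.5) -> np.ndarray:
    """Boolean mask of match columns: non-gap fraction >= symfrac (inclusive)."""
    if not 0 < symfrac <= 1:
        raise ValueError("symfrac must lie in (0, 1]")
    nongap = np.array(
        [
            sum(1 for _, s in aln.rows if s[j] not in GAP_CHARS)
            for j in range(aln.n_columns)
        ],
        dtype=float,
    )
    mask = nongap / len(aln.rows) >= symfrac
    if not mask.any():
        raise DegenerateAlignmentError(
            "no column reaches the symfrac occupancy threshold"
        )
    return mask


def position_based_weights(aln: Alignment) -> np.ndarray:
    """Henikoff position-based sequence weights, normalized to mean 1."""
    n = len(aln.rows)
    w = np.zeros(n)
    for j in range(aln.n_columns):
        col = [s[j] for _, s in aln.rows]
        residues = [c for c in col if c not in GAP_CHARS]
        if not residues:
            continue
        counts = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        r = len(counts)
        for i, c in enumerate(col):
            if c not in GAP_CHARS:
                w[i] += 1.0 / (r * counts[c])
    if w.sum() == 0:
        return np.ones(n)
    return w * n / w.sum()


#: Entropy-weighting target: mean match-state relative entropy in bits per
#: column, the conventional value for amino-acid profiles.
EWEIGHT_TARGET_RE = 0.59


def _entropy_weight_scale(
    em_counts: np.ndarray, alpha: float, background: np.ndarray, target: float
) -> float:
    """Count-scaling factor kappa so mean column RE meets the target.

    Maximum-likelihood emissions from a few dozen sequences memorize the
    training set (uninformative columns get spuriously peaked estimates and
    training sequences score far above held-out ones).  Scaling all counts
    by kappa in (0, 1] before smoothing — chosen so the mean relative
    entropy of the smoothed emissions against the background drops to the
    target — removes that in-sample bias while leaving genuinely conserved
    columns peaked.  Returns 1.0 when the profile is already at or below
    the target.
    """

    def mean_re(kappa: float) -> float:
        c = kappa * em_counts
        e = (c + alpha * background) / (c.sum(axis=1) + alpha)[:, None]
        e = np.maximum(e, LOG_FLOOR)
        e = e / e.sum(axis=1, keepdims=True)
        return float(np.mean(np.sum(e * np.log2(e / background), axis=1)))

    if mean_re(1.0) <= target:
        return 1.0
    lo, hi = 0.0, 1.0
    for _ in range(50):
        mid = (lo + hi) / 2
        if mean_re(mid) > target:
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2


def build_profile(
    aln: Alignment,
    symfrac: float = 0.5,
    alpha: float = 1.0,
    background: Optional[np.ndarray] = None,
    name: str = "profile",
    use_weights: bool = False,
    eweight_target: Optional[float] = None,
) -> ProfileHMM:
    """Estimate a profile HMM from a multiple alignment.

    Match-state emissions for column j are the background-smoothed
    frequencies ``(c_j(a) + alpha * bg(a)) / (n_j + alpha)``; insert
    emissions are the background; transitions are counted from each row's
    implied match/insert/delete path and smoothed the same way against a
    uniform prior over each state's legal successors.

    With ``eweight_target`` set (in bits per column; the pipeline uses
    :data:`EWEIGHT_TARGET_RE`), residue and transition counts are first
    scaled down so the mean match-column relative entropy against the
    background meets the target — the standard effective-sequence-number
    correction that stops profiles from memorizing their training set.
    """
    if background is None:
        background = UNIFORM_BACKGROUND
    background = np.asarray(background, dtype=float)
    mask = assign_match_columns(aln, symfrac)
    match_cols = np.where(mask)[0]
    M = len(match_cols)
    weights = position_based_weights(aln) if use_weights else np.ones(len(aln.rows))

    em_counts = np.zeros((M, 20))
    # transition counts per node 0..M over the 7 slots
    tr_counts = np.zeros((M + 1, 7))
    _STATE_M, _STATE_I, _STATE_D = 0, 1, 2
    # slot lookup: (from_state, to_state) -> column in the 7-slot layout
    slot = {
        (_STATE_M, _STATE_M): 0,
        (_STATE_M, _STATE_I): 1,
        (_STATE_M, _STATE_D): 2,
        (_STATE_I, _STATE_M): 3,
        (_STATE_I, _STATE_I): 4,
        (_STATE_D, _STATE_M): 5,
        (_STATE_D, _STATE_D): 6,
    }

    for (rid, row), wt in zip(aln.rows, weights):
        # walk the row as a path through the model; begin node acts as a match
        state, node = _STATE_M, 0
        jm = 0  # next match node index
        for j, c in enumerate(row):
            is_gap = c in GAP_CHARS
            if mask[j]:
                jm += 1
                new_state = _STATE_D if is_gap else _STATE_M
                tr_counts[node, slot[(state, new_state)]] += wt
                state, node = new_state, jm
                if not is_gap:
                    if c not in _AA_INDEX:
                        if c == "X":
                            continue  # ambiguous residue: no emission count
                        raise SequenceError(
                            f"row {rid!r} column {j + 1}: unknown symbol {c!r}"
                        )
                    em_counts[jm - 1, _AA_INDEX[c]] += wt
            else:
                if not is_gap:
                    tr_counts[node, slot[(state, _STATE_I)]] += wt
                    state = _STATE_I
        # exit: transition to the (virtual) match at node M+1
        tr_counts[node, slot[(state, _STATE_M)]] += wt

    if eweight_target is not None:
        kappa = _entropy_weight_scale(em_counts, alpha, background, eweight_target)
        em_counts = kappa * em_counts
        tr_counts = kappa * tr_counts

    n_j = em_counts.sum(axis=1)
    match_em = (em_counts + alpha * background) / (n_j + alpha)[:, None]
    insert_em = np.tile(background, (M, 1))

    def _group(counts_vec):
        # alpha = 0 with an unobserved group would divide 0 by 0; such a
        # group carries no evidence, so it falls back to uniform
        denom = counts_vec.sum() + alpha
        if denom == 0:
            return np.full(len(counts_vec), 1.0 / len(counts_vec))
        return (counts_vec + alpha / len(counts_vec)) / denom

    transitions = np.zeros((M + 1, 7))
    for k in range(M + 1):
        # match-out: node M has no delete successor (m->d forced to 0)
        opts = [0, 1] if k == M else [0, 1, 2]
        transitions[k, opts] = _group(tr_counts[k, opts])
        # insert-out
        transitions[k, [3, 4]] = _group(tr_counts[k, [3, 4]])
        # delete-out: begin and final nodes use the fixed (1, 0) convention
        if k == 0 or k == M:
            transitions[k, 5] = 1.0
        else:
            transitions[k, [5, 6]] = _group(tr_counts[k, [5, 6]])

    model = ProfileHMM(
        name=name,
        match_emissions=match_em,
        insert_emissions=insert_em,
        transitions=transitions,
        background=background.copy(),
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# local Viterbi scoring
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    if not seq:
        raise SequenceError("empty sequence")
    try:
        return np.array([_AA_INDEX[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise SequenceError(f"unknown symbol {exc.args[0]!r} in sequence")


def _log2(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log2(x)


class _ScoringTables:
    """Per-model log-odds tables reused across many sequence scans."""

    def __init__(self, model: ProfileHMM):
        bg = np.maximum(model.background, LOG_FLOOR)
        self.M = model.M
        self.match_odds = _log2(model.match_emissions) - _log2(bg)[None, :]
        self.insert_odds = _log2(model.insert_emissions) - _log2(bg)[None, :]
        t = model.transitions
        # internal transitions out of nodes 1..M-1 (index k = node k+1... kept
        # 1-based below for clarity); node-0 row is replaced by uniform entry
        self.ltmm = _log2(t[:, 0])
        self.ltmi = _log2(t[:, 1])
        self.ltmd = _log2(t[:, 2])
        self.ltim = _log2(t[:, 3])
        self.ltii = _log2(t[:, 4])
        self.ltdm = _log2(t[:, 5])
        self.ltdd = _log2(t[:, 6])
        self.log2_M = np.log2(self.M)


_tables_cache: dict = {}


def _tables_for(model: ProfileHMM) -> _ScoringTables:
    key = id(model)
    cached = _tables_cache.get(key)
    if cached is None or cached[0] is not model:
        cached = (model, _ScoringTables(model))
        _tables_cache.clear()
        _tables_cache[key] = cached
    return cached[1]


def score_sequence(model: ProfileHMM, seq: str) -> float:
    """Bit score of the best local alignment of *seq* to *model*."""
    score, _ = _viterbi(model, seq, want_path=False)
    return score


def viterbi_path(model: ProfileHMM, seq: str):
    """Best local alignment and its score.

    Returns ``(bits, path)`` where path is a list of ``(state, node,
    seq_index)`` triples, state one of 'M', 'I', 'D', seq_index 0-based
    (or None for delete states), in path order.
    """
    return _viterbi(model, seq, want_path=True)


def _viterbi(model: ProfileHMM, seq: str, want_path: bool):
    tab = _tables_for(model)
    M = tab.M
    x = _encode(seq)
    L = len(x)
    NEG = -np.inf
    # uniform entry/exit over the M*L alignment cells (see module docstring)
    end_cost = -(tab.log2_M + np.log2(L))

    VM = np.full(M + 1, NEG)
    VI = np.full(M + 1, NEG)
    VD = np.full(M + 1, NEG)
    best = NEG
    best_cell = None

    if want_path:
        ptrM = np.zeros((L + 1, M + 1), dtype=np.int8)
        ptrI = np.zeros((L + 1, M + 1), dtype=np.int8)
        ptrD = np.zeros((L + 1, M + 1), dtype=np.int8)
    # pointer codes: 0 = entry, 1 = from M, 2 = from I, 3 = from D

    for i in range(1, L + 1):
        a = x[i - 1]
        em = tab.match_odds[:, a]  # length M, node j -> em[j-1]
        # candidates into M_j (vector over j=1..M)
        cand = np.stack(
            [
                np.full(M, end_cost),
                VM[:-1] + tab.ltmm[:-1],
                VI[:-1] + tab.ltim[:-1],
                VD[:-1] + tab.ltdm[:-1],
            ]
        )
        # the begin-node row of the transition table is not used for entry:
        # entry is uniform over match states, so mask node-0 continuations
        cand[1, 0] = NEG
        cand[2, 0] = NEG
        cand[3, 0] = NEG
        choice = np.argmax(cand, axis=0)
        VMnew = np.full(M + 1, NEG)
        VMnew[1:] = em + cand[choice, np.arange(M)]

        candI = np.stack([VM[1:] + tab.ltmi[1:], VI[1:] + tab.ltii[1:]])
        choiceI = np.argmax(candI, axis=0)
        VInew = np.full(M + 1, NEG)
        VInew[1:] = tab.insert_odds[:, a] + candI[choiceI, np.arange(M)]

        VDnew = np.full(M + 1, NEG)
        if want_path:
            # candidate rows already follow the pointer code order
            # (0 = entry, 1 = from M, 2 = from I, 3 = from D)
            ptrM[i, 1:] = choice
            ptrI[i, 1:] = choiceI + 1
        for j in range(2, M + 1):
            dm = VMnew[j - 1] + tab.ltmd[j - 1]
            dd = VDnew[j - 1] + tab.ltdd[j - 1]
            if dm >= dd:
                VDnew[j] = dm
                if want_path:
                    ptrD[i, j] = 1
            else:
                VDnew[j] = dd
                if want_path:
                    ptrD[i, j] = 3
        VM, VI, VD = VMnew, VInew, VDnew
        row_best = VM[1:].max()
        if row_best > best:
            best = row_best
            best_cell = (i, int(VM[1:].argmax()) + 1)

    best = best + end_cost

    if not want_path:
        return best, None

    if best_cell is None or not np.isfinite(best):
        return best, []

    # traceback
    path = []
    i, j = best_cell
    state = "M"
    while True:
        if state == "M":
            path.append(("M", j, i - 1))
            code = ptrM[i, j]
            i -= 1
            if code == 0:
                break
            state = {1: "M", 2: "I", 3: "D"}[code]
            j -= 1  # all predecessors of M_j sit at node j-1
        elif state == "I":
            path.append(("I", j, i - 1))
            code = ptrI[i, j]
            i -= 1
            state = {1: "M", 2: "I"}[code]
        else:  # D
            path.append(("D", j, None))
            code = ptrD[i, j]
            j -= 1
            state = {1: "M", 3: "D"}[code]
    path.reverse()
    return best, path


def search(
    model: ProfileHMM,
    pool: Sequence[LabeledSeq],
    report_threshold: float = 0.0,
) -> ScoreSet:
    """Scan *pool* against *model*, reporting hits at or above the threshold."""
    if not pool:
        raise ValueError("empty sequence pool")
    entries = []
    for rec in pool:
        bits = score_sequence(model, rec.seq)
        if bits >= report_threshold:
            entries.append((rec.id, rec.label, bits))
    return ScoreSet(entries).sorted()
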