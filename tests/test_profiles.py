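"""profiles_and_scoring: building arithmetic, local Viterbi vs brute force."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hmmode.hmm_io import AMINO_ACIDS, UNIFORM_BACKGROUND, ProfileHMM
from hmmode.profiles import (
    Alignment,
    DegenerateAlignmentError,
    LabeledSeq,
    ScoreSet,
    SequenceError,
    assign_match_columns,
    build_profile,
    position_based_weights,
    score_sequence,
    search,
    viterbi_path,
)

from conftest import random_model

AA = {a: i for i, a in enumerate(AMINO_ACIDS)}


# --- Alignment / match columns -------------------------------------------

def test_alignment_invariants():
    with pytest.raises(ValueError):
        Alignment([("only", "ACD")])
    with pytest.raises(ValueError):
        Alignment([("a", "ACD"), ("b", "AC")])
    with pytest.raises(ValueError):
        Alignment([("a", "---"), ("b", "ACD")])


def test_match_columns_boundary_inclusive():
    # 4 rows, middle column has exactly 2 gaps: 0.5 occupancy is a match
    aln = Alignment([("a", "A-C"), ("b", "AAC"), ("c", "A-C"), ("d", "AAC")])
    mask = assign_match_columns(aln, symfrac=0.5)
    assert mask.tolist() == [True, True, True]


def test_all_gap_column_not_match():
    aln = Alignment([("a", "A-C"), ("b", "A-C")])
    assert assign_match_columns(aln, 0.5).tolist() == [True, False, True]


def test_degenerate_alignment_errors():
    aln = Alignment([("a", "A--"), ("b", "-C-"), ("c", "--D")])
    with pytest.raises(DegenerateAlignmentError):
        assign_match_columns(aln, symfrac=0.5)


# --- build_profile --------------------------------------------------------

def test_identical_sequences_alpha0_point_mass():
    aln = Alignment([("a", "ACDEF"), ("b", "ACDEF")])
    m = build_profile(aln, alpha=0.0)
    assert m.M == 5
    for j, res in enumerate("ACDEF"):
        expect = np.zeros(20)
        expect[AA[res]] = 1.0
        assert np.allclose(m.match_emissions[j], expect)


def test_large_alpha_approaches_background():
    aln = Alignment([("a", "AAAA"), ("b", "AAAA")])
    m = build_profile(aln, alpha=1e8)
    assert np.abs(m.match_emissions - UNIFORM_BACKGROUND).max() < 1e-6


def test_hand_computed_smoothed_emissions(toy_alignment):
    # 3 sequences ACDE/ACDF/AGDE, alpha=1, uniform background:
    # column 1: c(A)=3 -> (3 + 1/20) / (3 + 1) = 0.7625
    m = build_profile(toy_alignment, alpha=1.0)
    assert m.M == 4
    assert m.match_emissions[0, AA["A"]] == pytest.approx((3 + 0.05) / 4)
    # column 2: c(C)=2, c(G)=1
    assert m.match_emissions[1, AA["C"]] == pytest.approx((2 + 0.05) / 4)
    assert m.match_emissions[1, AA["G"]] == pytest.approx((1 + 0.05) / 4)
    # unobserved residue
    assert m.match_emissions[1, AA["W"]] == pytest.approx(0.05 / 4)


def test_gapped_alignment_transitions():
    # gap in a match column creates a delete path; counted transitions
    # include one m->d and one d->m event
    aln = Alignment([("a", "ACD"), ("b", "A-D"), ("c", "ACD")])
    m = build_profile(aln, alpha=0.0)
    assert m.M == 3
    # node 1: 2 of 3 rows go m->m, 1 goes m->d
    assert m.transitions[1, 0] == pytest.approx(2 / 3)
    assert m.transitions[1, 2] == pytest.approx(1 / 3)
    # node 2 delete-out: the one delete path returns to match
    assert m.transitions[2, 5] == pytest.approx(1.0)


def test_insert_column_counts():
    # lowercase-free: a non-match column (3 of 4 gaps) becomes an insert
    aln = Alignment(
        [("a", "AC-E"), ("b", "AC-E"), ("c", "AC-E"), ("d", "ACDE")]
    )
    m = build_profile(aln, alpha=0.0)
    assert m.M == 3  # the sparse column fails symfrac 0.5
    # row d passes through insert after node 2: m->i then i->m observed
    assert m.transitions[2, 1] > 0
    assert m.transitions[2, 3] > 0


def test_eweight_reduces_information(toy_alignment):
    raw = build_profile(toy_alignment, alpha=1.0)
    ew = build_profile(toy_alignment, alpha=1.0, eweight_target=0.2)

    def mean_re(m):
        e = np.maximum(m.match_emissions, 1e-6)
        e = e / e.sum(axis=1, keepdims=True)
        return np.mean(np.sum(e * np.log2(e / UNIFORM_BACKGROUND), axis=1))

    assert mean_re(ew) < mean_re(raw)
    assert mean_re(ew) == pytest.approx(0.2, abs=0.02)
    ew.validate()


def test_position_based_weights_mean_one(toy_alignment):
    w = position_based_weights(toy_alignment)
    assert w.shape == (3,)
    assert w.mean() == pytest.approx(1.0)
    # weighting must not break any documented invariant
    build_profile(toy_alignment, use_weights=True).validate()


def test_unknown_symbol_rejected():
    aln = Alignment([("a", "ACZ"), ("b", "ACD")])
    with pytest.raises(SequenceError):
        build_profile(aln)


# --- brute-force Viterbi oracle ------------------------------------------

def brute_force_score(model: ProfileHMM, seq: str) -> float:
    """Exhaustive enumeration of all legal single-hit local paths.

    Grammar mirrors the scorer's contract: entry into any match state at
    any sequence position and exit from any match state each cost
    log2(1/(M*L)); emissions are log-odds against the background; internal
    transitions use the model's node tables (the begin-node row is not
    part of local entry).
    """
    M = model.M
    x = [AA[c] for c in seq.upper()]
    L = len(x)
    bg = np.maximum(model.background, 1e-6)
    with np.errstate(divide="ignore"):
        em = np.log2(model.match_emissions) - np.log2(bg)[None, :]
        ei = np.log2(model.insert_emissions) - np.log2(bg)[None, :]
        lt = np.log2(model.transitions)
    end_cost = -math.log2(M * L)
    best = [-math.inf]

    def step(state, j, i, acc):
        # state in {"M","I","D"}, j = node (1-based), i = residues consumed
        if state == "M":
            best[0] = max(best[0], acc + end_cost)  # exit
            if j < M and i < L:
                step("M", j + 1, i + 1, acc + lt[j, 0] + em[j, x[i]])
            if i < L:
                step("I", j, i + 1, acc + lt[j, 1] + ei[j - 1, x[i]])
            if j < M:
                step("D", j + 1, i, acc + lt[j, 2])
        elif state == "I":
            if j < M and i < L:
                step("M", j + 1, i + 1, acc + lt[j, 3] + em[j, x[i]])
            if i < L:
                step("I", j, i + 1, acc + lt[j, 4] + ei[j - 1, x[i]])
        else:  # D
            if j < M and i < L:
                step("M", j + 1, i + 1, acc + lt[j, 5] + em[j, x[i]])
            if j < M:
                step("D", j + 1, i, acc + lt[j, 6])

    for j0 in range(1, M + 1):
        for i0 in range(L):
            step("M", j0, i0 + 1, end_cost + em[j0 - 1, x[i0]])
    return best[0]


def test_viterbi_equals_brute_force(rng):
    for trial in range(25):
        M = int(rng.integers(1, 5))
        L = int(rng.integers(1, 7))
        model = random_model(rng, M=M)
        seq = "".join(
            np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=L)]
        )
        got = score_sequence(model, seq)
        want = brute_force_score(model, seq)
        assert got == pytest.approx(want, abs=1e-9), (trial, M, L, seq)


def test_viterbi_path_score_matches_and_is_legal(rng):
    model = random_model(rng, M=4)
    seq = "ACDEFG"
    bits, path = viterbi_path(model, seq)
    assert bits == pytest.approx(score_sequence(model, seq))
    assert path[0][0] == "M" and path[-1][0] == "M"
    nodes = [n for s, n, _ in path]
    assert all(b - a in (0, 1) for a, b in zip(nodes, nodes[1:]))
    # emitted positions strictly increase
    positions = [p for s, _, p in path if p is not None]
    assert positions == sorted(set(positions))


def test_self_consensus_dominates_point_mutants():
    s = "ACDEFGHIKL"
    aln = Alignment([("a", s), ("b", s)])
    model = build_profile(aln, alpha=1.0)
    base = score_sequence(model, s)
    for pos in (0, 4, 9):
        for repl in "WY":
            if s[pos] == repl:
                continue
            mutant = s[:pos] + repl + s[pos + 1 :]
            assert score_sequence(model, mutant) <= base


def test_background_emissions_score_nonpositive():
    M = 5
    match = np.tile(UNIFORM_BACKGROUND, (M, 1))
    trans = np.zeros((M + 1, 7))
    trans[:, 0:3] = [0.8, 0.1, 0.1]
    trans[M, 0:3] = [0.9, 0.1, 0.0]
    trans[:, 3:5] = [0.5, 0.5]
    trans[:, 5] = 1.0
    model = ProfileHMM("flat", match.copy(), match.copy(), trans)
    model.validate()
    assert score_sequence(model, "ACDEFGHIKL") <= 0.0


def test_score_monotone_in_consensus_emission():
    aln = Alignment([("a", "ACDE"), ("b", "ACDE")])
    model = build_profile(aln, alpha=1.0)
    boosted = model.match_emissions.copy()
    j, a = 0, AA["A"]
    boosted[j, a] += 0.1
    boosted[j] /= boosted[j].sum()
    import dataclasses

    up = dataclasses.replace(model, match_emissions=boosted)
    assert score_sequence(up, "ACDE") >= score_sequence(model, "ACDE")


def test_score_errors():
    model = random_model(np.random.default_rng(0), M=3)
    with pytest.raises(SequenceError):
        score_sequence(model, "")
    with pytest.raises(SequenceError):
        score_sequence(model, "ACB")


# --- search ---------------------------------------------------------------

def test_search_reports_all_training_positives():
    train, _ = __import__("conftest").overlap_split()
    pos = [s for s in train if s.label == "subfam1"]
    pos = [LabeledSeq(s.id, s.seq, "positive") for s in pos]
    aln = Alignment([(s.id, s.seq) for s in pos])
    model = build_profile(aln)
    hits = search(model, pos, report_threshold=0.0)
    assert len(hits.entries) == len(pos)
    bits = [b for _, _, b in hits.entries]
    assert bits == sorted(bits, reverse=True)


def test_search_infinite_threshold_empty():
    model = random_model(np.random.default_rng(1), M=3)
    pool = [LabeledSeq("a", "ACDEF", "positive")]
    assert search(model, pool, report_threshold=math.inf).entries == []


def test_search_equals_per_sequence_oracle(rng):
    train, _ = __import__("conftest").overlap_split()
    pos = [s for s in train if s.label == "subfam1"][:10]
    neg = [
        LabeledSeq(s.id, s.seq, "negative")
        for s in train
        if s.label == "subfam2"
    ][:10]
    aln = Alignment([(s.id, s.seq) for s in pos])
    model = build_profile(aln, eweight_target=0.59)
    reported = {sid for sid, lab, b in search(model, neg).entries}
    expected = {s.id for s in neg if score_sequence(model, s.seq) >= 0.0}
    assert reported == expected


# --- ScoreSet -------------------------------------------------------------

def test_scoreset_tsv_round_trip(tmp_path):
    ss = ScoreSet([("a", "positive", 10.0), ("b", "negative", -2.5)])
    path = tmp_path / "scores.tsv"
    ss.to_tsv(path)
    back = ScoreSet.from_tsv(path)
    assert back.positives().tolist() == [10.0]
    assert back.negatives().tolist() == [-2.5]


def test_scoreset_rejects_bad_labels():
    with pytest.raises(ValueError):
        ScoreSet([("a", "maybe", 1.0)])


# --- property tests -------------------------------------------------------

@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_build_profile_always_valid(seed):
    """Profiles from random ungapped alignments satisfy every invariant."""
    r = np.random.default_rng(seed)
    n, L = int(r.integers(2, 6)), int(r.integers(2, 10))
    aa = np.array(list(AMINO_ACIDS))
    rows = [
        (f"s{i}", "".join(aa[r.integers(0, 20, size=L)])) for i in range(n)
    ]
    model = build_profile(Alignment(rows), alpha=float(r.uniform(0.1, 3)))
    model.validate()


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_viterbi_brute_force_property(seed):
    r = np.random.default_rng(seed)
    model = random_model(r, M=int(r.integers(1, 4)))
    L = int(r.integers(1, 6))
    seq = "".join(np.array(list(AMINO_ACIDS))[r.integers(0, 20, size=L)])
    assert score_sequence(model, seq) == pytest.approx(
        brute_force_score(model, seq), abs=1e-9
    )
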