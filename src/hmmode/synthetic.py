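"""Synthetic superfamily generator with planted fold and function signals.

A protein superfamily shares a fold: many columns are conserved across all
subfamilies and carry no information about which subfamily a sequence
belongs to.  Each subfamily additionally conserves its own residues at a
smaller set of function (specificity) columns.  The generator plants both
kinds of signal with known truth so every pipeline stage — clustering,
profile building, false-positive pickup, emission modification and
threshold calibration — can be tested without any external data.

Columns are of three kinds, drawn disjointly along the sequence:

* fold columns: all subfamilies emit the shared superfamily consensus
  residue with probability ``p_cons`` (uniform over the 20 residues
  otherwise);
* function columns: a single shared set of positions at which every
  subfamily has its own consensus residue, distinct across subfamilies,
  emitted with probability ``p_cons``;
* the rest: uniform background.

Optional insertions (geometric length, mean 2) are added after emission,
never adjacent to a function column, so planted column indices remain
mappable through the recorded gap structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import yaml

from .hmm_io import AMINO_ACIDS
from .profiles import LabeledSeq


@dataclass
class SyntheticFamilySet:
    """Generated sequences with planted-signal ground truth."""

    sequences: List[LabeledSeq]
    truth: Dict[str, str]  # sequence id -> subfamily label
    planted_fold_columns: List[int]
    planted_function_columns: List[int]
    function_residues: Dict[str, Dict[int, str]]  # subfamily -> column -> residue
    generator_config: dict

    def subfamily(self, label: str) -> List[LabeledSeq]:
        return [s for s in self.sequences if self.truth[s.id] == label]

    def labels(self) -> List[str]:
        seen = []
        for s in self.sequences:
            lab = self.truth[s.id]
            if lab not in seen:
                seen.append(lab)
        return seen

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.sequences:
                fh.write(f">{rec.id}\n{rec.seq}\n")

    def write_truth_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tsubfamily\n")
            for rec in self.sequences:
                fh.write(f"{rec.id}\t{self.truth[rec.id]}\n")

    def write_config(self, path) -> None:
        """Echo the generator parameters for exact re-generation."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.generator_config, fh, sort_keys=True)


def generate_superfamily(
    n_subfamilies: int = 2,
    n_per_subfamily: int = 30,
    length: int = 120,
    fold_frac: float = 0.4,
    func_frac: float = 0.1,
    p_cons: float = 0.9,
    indel_rate: float = 0.0,
    seed: int = 0,
    background: Optional[np.ndarray] = None,
) -> SyntheticFamilySet:
    """Generate a superfamily of labelled subfamily sequences.

    Fold columns make up ``fold_frac`` of the length, function columns
    ``func_frac``; both are conserved at rate ``p_cons`` (must exceed 0.5
    so consensus residues dominate).  With ``indel_rate`` > 0, each
    eligible inter-column boundary receives an insertion with that
    probability.
    """
    if n_subfamilies < 1 or n_per_subfamily < 1 or length < 2:
        raise ValueError("counts and length must be positive (length >= 2)")
    if fold_frac < 0 or func_frac < 0 or fold_frac + func_frac > 1:
        raise ValueError("fold_frac + func_frac must lie in [0, 1]")
    if not 0.5 < p_cons <= 1:
        raise ValueError("p_cons must lie in (0.5, 1]")
    if not 0 <= indel_rate < 1:
        raise ValueError("indel_rate must lie in [0, 1)")
    if n_subfamilies > 20:
        raise ValueError("at most 20 subfamilies (distinct residues per column)")

    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    if background is None:
        bg = np.full(20, 1 / 20)
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (20,) or abs(bg.sum() - 1) > 1e-6:
            raise ValueError("background must be a 20-vector summing to 1")

    n_fold = int(round(fold_frac * length))
    n_func = int(round(func_frac * length))
    cols = rng.permutation(length)
    fold_cols = sorted(int(c) for c in cols[:n_fold])
    func_cols = sorted(int(c) for c in cols[n_fold : n_fold + n_func])

    consensus = aa[rng.choice(20, size=length, p=bg)]
    labels = [f"subfam{s + 1}" for s in range(n_subfamilies)]
    func_residues: Dict[str, Dict[int, str]] = {lab: {} for lab in labels}
    for c in func_cols:
        picks = rng.choice(20, size=n_subfamilies, replace=False)
        for lab, r in zip(labels, picks):
            func_residues[lab][c] = str(aa[r])

    func_set = set(func_cols)
    fold_set = set(fold_cols)
    sequences: List[LabeledSeq] = []
    truth: Dict[str, str] = {}
    for lab in labels:
        for i in range(n_per_subfamily):
            chars = []
            for j in range(length):
                if j in func_set:
                    target = func_residues[lab][j]
                elif j in fold_set:
                    target = str(consensus[j])
                else:
                    target = None
                if target is not None and rng.random() < p_cons:
                    chars.append(target)
                else:
                    chars.append(str(aa[rng.choice(20, p=bg)]))
                # insertion after column j, never adjacent to a function column
                if (
                    indel_rate > 0
                    and j not in func_set
                    and (j + 1) not in func_set
                    and rng.random() < indel_rate
                ):
                    ins_len = int(rng.geometric(0.5))  # mean 2
                    ins = aa[rng.choice(20, size=ins_len, p=bg)]
                    chars.extend(str(c) for c in ins)
            sid = f"{lab}_seq{i + 1}"
            sequences.append(LabeledSeq(sid, "".join(chars), lab))
            truth[sid] = lab

    config = dict(
        n_subfamilies=n_subfamilies,
        n_per_subfamily=n_per_subfamily,
        length=length,
        fold_frac=fold_frac,
        func_frac=func_frac,
        p_cons=p_cons,
        indel_rate=indel_rate,
        seed=seed,
    )
    return SyntheticFamilySet(
        sequences=sequences,
        truth=truth,
        planted_fold_columns=fold_cols,
        planted_function_columns=func_cols,
        function_residues=func_residues,
        generator_config=config,
    )


def make_blast_like_table(fams: SyntheticFamilySet, k: int = 3) -> List[str]:
    """Pairwise 12-column tabular rows with shared-k-mer bit scores.

    The bit-score column is 100 times the shared-k-mer fraction (distinct
    shared k-mers over the smaller sequence's k-mer count), symmetric by
    construction; one row per unordered pair with a non-zero score.
    """
    rows: List[str] = []
    seqs = fams.sequences
    kmer_sets = [
        {rec.seq[i : i + k] for i in range(len(rec.seq) - k + 1)} for rec in seqs
    ]
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            shared = len(kmer_sets[i] & kmer_sets[j])
            if not shared:
                continue
            sim = shared / min(len(kmer_sets[i]), len(kmer_sets[j]))
            bits = 100.0 * sim
            a, b = seqs[i], seqs[j]
            alen = min(len(a.seq), len(b.seq))
            rows.append(
                "\t".join(
                    [
                        a.id,
                        b.id,
                        f"{100.0 * sim:.2f}",
                        str(alen),
                        str(max(0, alen - shared)),
                        "0",
                        "1",
                        str(len(a.seq)),
                        "1",
                        str(len(b.seq)),
                        f"{10.0 ** (-bits / 10.0):.2e}",
                        f"{bits:.1f}",
                    ]
                )
            )
    return rows
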