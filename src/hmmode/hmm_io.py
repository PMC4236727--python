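"""Reading, writing and editing profile HMMs in the HMMER3 ASCII format.

A :class:`ProfileHMM` stores probabilities (not negative logs); the file
format's negative natural-log fields are converted on the way in and out,
with the ``*`` sentinel mapping to probability zero exactly in both
directions.  The dialect targeted is the ``HMMER3/f`` layout: a format tag
line, a block of ``KEY value`` header lines, the two ``HMM`` header lines,
a ``COMPO`` line, a node-0 insert-emission/transition pair, then one
match/insert/transition line triplet per node, terminated by ``//``.

Optional statistics lines (``STATS ...``) and unrecognised header lines are
carried verbatim as opaque metadata so that externally built profiles
survive a read/modify/write cycle.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, TextIO

import numpy as np

#: Canonical amino-acid alphabet, in the order used by profile files.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Uniform background distribution over the 20 residues.
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)

_FORMAT_TAG = "HMMER3/f"
_CUTOFF_KINDS = ("GA", "TC", "NC")

# transition column order in the file and in ProfileHMM.transitions
TRANS_NAMES = ("mm", "mi", "md", "im", "ii", "dm", "dd")


class HMMFormatError(ValueError):
    """Raised when a profile file cannot be parsed."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class HMMValidationError(ValueError):
    """Raised when a ProfileHMM violates its invariants."""


@dataclass
class ProfileHMM:
    """A profile hidden Markov model over the 20 amino acids.

    Parameters
    ----------
    name:
        Model identifier (the ``NAME`` header field).
    match_emissions:
        ``(M, 20)`` array of match-state emission probabilities, one row
        per match state, each row summing to 1.
    insert_emissions:
        ``(M, 20)`` array of insert-state emission probabilities.
    transitions:
        ``(M + 1, 7)`` array; row ``k`` holds node ``k``'s outgoing
        probabilities in the order m->m, m->i, m->d, i->m, i->i, d->m,
        d->d.  Row 0 is the begin node (its match-out group are the
        B->M1 / B->I0 / B->D1 probabilities, its delete group is the
        fixed (1, 0) convention).  Row M's m->d and d->d are 0 by
        convention, so every group still sums to 1.
    background:
        20-vector of background residue probabilities (the ``COMPO``
        line and the null model used for log-odds scoring).
    cutoffs:
        Optional GA/TC/NC bit-score cutoffs, each a (sequence, domain)
        pair.
    insert0_emissions:
        Node-0 insert emissions; defaults to ``background`` when absent.
    metadata:
        Extra header lines (key -> remainder) preserved verbatim.
    stats_lines:
        ``STATS ...`` lines preserved verbatim (never recomputed here).
    node_annotations:
        Per-node trailing annotation fields (map, cons, rf, mm, cs) as
        read from the file; regenerated when absent.
    """

    name: str
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    cutoffs: dict = field(default_factory=dict)
    alphabet: str = AMINO_ACIDS
    insert0_emissions: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)
    stats_lines: tuple = ()
    node_annotations: Optional[list] = None

    def __post_init__(self):
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)

    @property
    def M(self) -> int:
        """Number of match states."""
        return self.match_emissions.shape[0]

    def validate(self, atol: float = 1e-9) -> None:
        """Check all structural invariants, raising HMMValidationError."""
        if len(self.alphabet) != 20 or self.alphabet != AMINO_ACIDS:
            raise HMMValidationError("alphabet must be the 20 canonical amino acids")
        M = self.M
        if M < 1:
            raise HMMValidationError("model must have at least one match state")
        for label, arr in (
            ("match_emissions", self.match_emissions),
            ("insert_emissions", self.insert_emissions),
            ("transitions", self.transitions),
            ("background", self.background),
        ):
            # NaN compares False everywhere, so it must be rejected explicitly
            if not np.all(np.isfinite(arr)):
                raise HMMValidationError(f"{label} contains non-finite entries")
        for label, arr, nrows in (
            ("match_emissions", self.match_emissions, M),
            ("insert_emissions", self.insert_emissions, M),
        ):
            if arr.shape != (nrows, 20):
                raise HMMValidationError(f"{label} must have shape ({nrows}, 20)")
            if np.any(arr < 0) or np.any(arr > 1):
                raise HMMValidationError(f"{label} entries must lie in [0, 1]")
            bad = np.where(np.abs(arr.sum(axis=1) - 1.0) > atol)[0]
            if bad.size:
                raise HMMValidationError(
                    f"{label} row {bad[0] + 1} does not sum to 1"
                )
        if self.transitions.shape != (M + 1, 7):
            raise HMMValidationError(f"transitions must have shape ({M + 1}, 7)")
        if np.any(self.transitions < 0) or np.any(self.transitions > 1):
            raise HMMValidationError("transition entries must lie in [0, 1]")
        for lo, hi, label in ((0, 3, "match"), (3, 5, "insert"), (5, 7, "delete")):
            sums = self.transitions[:, lo:hi].sum(axis=1)
            bad = np.where(np.abs(sums - 1.0) > atol)[0]
            if bad.size:
                raise HMMValidationError(
                    f"node {bad[0]} {label}-outgoing transitions do not sum to 1"
                )
        bg_tol = max(atol, 1e-6)
        if self.background.shape != (20,) or abs(self.background.sum() - 1.0) > bg_tol:
            raise HMMValidationError("background must be a 20-vector summing to 1")
        self._validate_cutoff_order(self.cutoffs)

    @staticmethod
    def _validate_cutoff_order(cutoffs: dict) -> None:
        # Pfam convention: TC >= GA >= NC on the sequence score
        ga, tc, nc = (cutoffs.get(k) for k in ("GA", "TC", "NC"))
        if ga is not None and nc is not None and ga[0] < nc[0]:
            raise HMMValidationError("GA cutoff below NC cutoff")
        if tc is not None and ga is not None and tc[0] < ga[0]:
            raise HMMValidationError("TC cutoff below GA cutoff")
        if tc is not None and nc is not None and tc[0] < nc[0]:
            raise HMMValidationError("TC cutoff below NC cutoff")


def set_cutoff(model: ProfileHMM, kind: str, bits) -> ProfileHMM:
    """Return a copy of *model* with the GA, TC or NC cutoff set.

    ``bits`` may be a single number (used for both the sequence and the
    domain slot) or a (sequence, domain) pair.
    """
    kind = kind.upper()
    if kind not in _CUTOFF_KINDS:
        raise HMMValidationError(f"unknown cutoff kind {kind!r}")
    if np.isscalar(bits):
        pair = (float(bits), float(bits))
    else:
        pair = (float(bits[0]), float(bits[1]))
    if not all(math.isfinite(v) for v in pair):
        raise HMMValidationError(f"{kind} cutoff must be finite, got {pair}")
    cutoffs = dict(model.cutoffs)
    cutoffs[kind] = pair
    ProfileHMM._validate_cutoff_order(cutoffs)
    return replace(model, cutoffs=cutoffs)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _prob_field(p: float) -> str:
    """Format one probability as a negative-natural-log field ('*' for 0).

    Six decimals in log space bound the probability round-trip error by
    5e-7, comfortably inside the documented 1e-6 fidelity; parsers accept
    any decimal width.
    """
    if p == 0.0:
        return f"{'*':>8}"
    return f"{max(0.0, -math.log(p)):8.6f}"


def _prob_line(probs) -> str:
    return "  ".join(_prob_field(p) for p in probs)


def write_hmm(model: ProfileHMM, dest: Optional[TextIO] = None) -> str:
    """Serialize *model* as HMMER3 ASCII text; also written to *dest* if given."""
    # 5-decimal negative-log serialization perturbs row sums by ~1e-5, so a
    # model read back from disk must still pass validation here.
    model.validate(atol=5e-4)
    out = io.StringIO()
    w = out.write
    w(f"{_FORMAT_TAG} [hmmode | profile writer]\n")
    w(f"NAME  {model.name}\n")
    w(f"LENG  {model.M}\n")
    w("ALPH  amino\n")
    for key, value in model.metadata.items():
        w(f"{key:<5} {value}\n")
    if "RF" not in model.metadata:
        w("RF    no\n")
    if "MM" not in model.metadata:
        w("MM    no\n")
    if "CONS" not in model.metadata:
        w("CONS  no\n")
    if "CS" not in model.metadata:
        w("CS    no\n")
    if "MAP" not in model.metadata:
        w("MAP   no\n")
    for kind in _CUTOFF_KINDS:
        if kind in model.cutoffs:
            seq_bits, dom_bits = model.cutoffs[kind]
            w(f"{kind}    {seq_bits:.2f} {dom_bits:.2f};\n")
    for line in model.stats_lines:
        w(line.rstrip("\n") + "\n")
    w("HMM          " + "        ".join(model.alphabet) + "   \n")
    w("            m->m     m->i     m->d     i->m     i->i     d->m     d->d\n")
    w("  COMPO   " + _prob_line(model.background) + "\n")
    ins0 = model.insert0_emissions
    if ins0 is None:
        ins0 = model.background
    w("          " + _prob_line(ins0) + "\n")
    w("          " + _prob_line(model.transitions[0]) + "\n")
    for j in range(1, model.M + 1):
        ann = ""
        if model.node_annotations is not None:
            ann = "".join(f" {a:>6}" if i == 0 else f" {a}"
                          for i, a in enumerate(model.node_annotations[j - 1]))
        else:
            ann = f" {j:>6} - - - -"
        w(f"{j:7d}   " + _prob_line(model.match_emissions[j - 1]) + ann + "\n")
        w("          " + _prob_line(model.insert_emissions[j - 1]) + "\n")
        w("          " + _prob_line(model.transitions[j]) + "\n")
    w("//\n")
    text = out.getvalue()
    if dest is not None:
        dest.write(text)
    return text


def write_hmm_file(models, path) -> None:
    """Write one or more models to *path* as a (possibly multi-model) file."""
    if isinstance(models, ProfileHMM):
        models = [models]
    with open(path, "w") as fh:
        for m in models:
            write_hmm(m, fh)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _parse_prob(tok: str, lineno: int) -> float:
    if tok == "*":
        return 0.0
    try:
        return math.exp(-float(tok))
    except ValueError:
        raise HMMFormatError(f"non-numeric probability field {tok!r}", lineno)


def _parse_prob_fields(tokens, n, lineno):
    if len(tokens) < n:
        raise HMMFormatError(
            f"expected {n} probability fields, found {len(tokens)}", lineno
        )
    return np.array([_parse_prob(t, lineno) for t in tokens[:n]])


_KNOWN_HEADER = {"NAME", "LENG", "ALPH", "RF", "MM", "CONS", "CS", "MAP"}


def iter_hmm(source) -> Iterator[ProfileHMM]:
    """Yield every model in a HMMER3 ASCII stream (path, text or file-like)."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    elif isinstance(source, str) and "\n" in source:
        lines = source.splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()

    i = 0
    n = len(lines)
    while i < n:
        while i < n and not lines[i].strip():
            i += 1
        if i >= n:
            return
        if not lines[i].startswith("HMMER3"):
            raise HMMFormatError(
                f"expected a HMMER3 format tag, found {lines[i][:40]!r}", i + 1
            )
        if not lines[i].startswith(_FORMAT_TAG):
            raise HMMFormatError(
                f"unsupported HMMER3 dialect {lines[i].split()[0]!r}", i + 1
            )
        i += 1
        name = None
        leng = None
        cutoffs = {}
        metadata = {}
        stats_lines = []
        while i < n and not lines[i].startswith("HMM "):
            line = lines[i]
            if not line.strip():
                i += 1
                continue
            key = line.split(None, 1)[0]
            rest = line.split(None, 1)[1] if len(line.split(None, 1)) > 1 else ""
            if key == "NAME":
                name = rest.strip()
            elif key == "LENG":
                try:
                    leng = int(rest.strip())
                except ValueError:
                    raise HMMFormatError(f"bad LENG value {rest!r}", i + 1)
            elif key == "ALPH":
                if rest.strip().lower() != "amino":
                    raise HMMFormatError(
                        f"unsupported alphabet {rest.strip()!r}", i + 1
                    )
            elif key in _CUTOFF_KINDS:
                toks = rest.replace(";", "").split()
                if len(toks) != 2:
                    raise HMMFormatError(f"bad {key} cutoff line", i + 1)
                cutoffs[key] = (float(toks[0]), float(toks[1]))
            elif key == "STATS":
                stats_lines.append(line)
            elif key in _KNOWN_HEADER:
                pass  # layout flags; regenerated on write
            else:
                metadata[key] = rest
            i += 1
        if i >= n:
            raise HMMFormatError("missing HMM header block", n)
        if name is None or leng is None:
            raise HMMFormatError("header missing NAME or LENG", i + 1)
        i += 2  # the two HMM header lines
        if i >= n:
            raise HMMFormatError("truncated model: no COMPO line", n)

        toks = lines[i].split()
        if not toks or toks[0] != "COMPO":
            raise HMMFormatError("expected COMPO line", i + 1)
        background = _parse_prob_fields(toks[1:], 20, i + 1)
        i += 1
        insert0 = _parse_prob_fields(lines[i].split(), 20, i + 1)
        i += 1
        trans0 = _parse_prob_fields(lines[i].split(), 7, i + 1)
        i += 1

        match_em = np.zeros((leng, 20))
        insert_em = np.zeros((leng, 20))
        transitions = np.zeros((leng + 1, 7))
        transitions[0] = trans0
        annotations = []
        for j in range(1, leng + 1):
            if i >= n or lines[i].strip() == "//":
                raise HMMFormatError(
                    f"model ends after {j - 1} nodes but LENG is {leng}",
                    i + 1 if i < n else n,
                )
            toks = lines[i].split()
            try:
                node_idx = int(toks[0])
            except (ValueError, IndexError):
                raise HMMFormatError(f"expected node {j} line", i + 1)
            if node_idx != j:
                raise HMMFormatError(
                    f"expected node {j}, found node {node_idx}", i + 1
                )
            match_em[j - 1] = _parse_prob_fields(toks[1:], 20, i + 1)
            annotations.append(tuple(toks[21:]) if len(toks) > 21 else (str(j), "-", "-", "-", "-"))
            i += 1
            insert_em[j - 1] = _parse_prob_fields(lines[i].split(), 20, i + 1)
            i += 1
            transitions[j] = _parse_prob_fields(lines[i].split(), 7, i + 1)
            i += 1
        if i >= n or lines[i].strip() != "//":
            raise HMMFormatError("missing // terminator", i + 1 if i < n else n)
        i += 1

        model = ProfileHMM(
            name=name,
            match_emissions=match_em,
            insert_emissions=insert_em,
            transitions=transitions,
            background=background,
            cutoffs=cutoffs,
            insert0_emissions=insert0,
            metadata=metadata,
            stats_lines=tuple(stats_lines),
            node_annotations=annotations,
        )
        yield model


def read_hmm(source) -> ProfileHMM:
    """Read exactly one model from a HMMER3 ASCII stream."""
    it = iter_hmm(source)
    try:
        model = next(it)
    except StopIteration:
        raise HMMFormatError("no model found in stream")
    return model
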