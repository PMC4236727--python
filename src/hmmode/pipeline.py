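"""End-to-end workflow: cluster, build, refine, scan, evaluate.

Each stage is a plain function over a :class:`PipelineConfig`, so the
command-line interface stays a thin wrapper and any two-command split of
the pipeline reproduces the one-shot run exactly (all randomness flows
from the config seed).

Input contract: a FASTA of training sequences plus a two-column TSV
mapping sequence id to subfamily label.  Pre-computed alignments may be
supplied per subfamily; otherwise equal-length subfamily sequences are
treated as already aligned column-for-column (the synthetic generator
emits such sets), and unequal lengths without an alignment are an error —
alignment construction is deliberately out of scope.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .hmm_io import ProfileHMM, iter_hmm, write_hmm_file
from .profiles import (
    Alignment,
    LabeledSeq,
    ScoreSet,
    build_profile,
    read_alignment,
    read_fasta,
    score_sequence,
    SequenceError,
)
from .clustering import kmer_similarity, mcl_cluster, write_assignments, import_blast_tab
from .calibration import (
    CalibrationConfig,
    ConfusionCounts,
    ThresholdResult,
    calibrate,
    mcc,
    sensitivity_specificity,
)

logger = logging.getLogger("hmmode")


@dataclass
class PipelineConfig:
    """All tunable parameters of one pipeline run (YAML-serializable)."""

    sequences: str = ""
    truth: str = ""
    workdir: str = "hmmode_out"
    alignments: Dict[str, str] = field(default_factory=dict)
    blast_table: Optional[str] = None

    symfrac: float = 0.5
    alpha: float = 1.0
    k_folds: int = 10
    fp_cap: int = 200
    tilt: float = 1.0
    re_cutoff: float = 0.3
    inflation: float = 2.0
    report_threshold: float = 0.0
    eweight_target: Optional[float] = 0.59
    seed: int = 0

    clustering: bool = False
    mapping_mode: str = "align-to-profile"
    remodify_per_fold: bool = True
    threshold_rule: str = "mean_curve"

    def validate(self) -> None:
        if not 0 < self.symfrac <= 1:
            raise ValueError("symfrac must lie in (0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.fp_cap < 1:
            raise ValueError("fp_cap must be >= 1")
        if self.tilt < 0:
            raise ValueError("tilt must be >= 0")
        if self.re_cutoff < 0:
            raise ValueError("re_cutoff must be >= 0")
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.mapping_mode not in ("align-to-profile", "profile-profile"):
            raise ValueError(f"unknown mapping_mode {self.mapping_mode!r}")
        if self.threshold_rule not in ("mean_curve", "fold_mode"):
            raise ValueError(f"unknown threshold_rule {self.threshold_rule!r}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def calibration_config(self) -> CalibrationConfig:
        return CalibrationConfig(
            symfrac=self.symfrac,
            alpha=self.alpha,
            tilt=self.tilt,
            re_cutoff=self.re_cutoff,
            fp_cap=self.fp_cap,
            mapping_mode=self.mapping_mode,
            report_threshold=self.report_threshold,
            eweight_target=self.eweight_target,
            remodify_per_fold=self.remodify_per_fold,
            threshold_rule=self.threshold_rule,
        )


def _family_seed(base_seed: int, index: int) -> int:
    # stable per-family seed stream, kept below 2**31
    return (base_seed * 1000003 + 7919 * (index + 1)) % (2**31)


def read_truth(path) -> Dict[str, str]:
    truth = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("id\t") or line.startswith("#"):
                continue
            sid, label = line.split("\t")[:2]
            truth[sid] = label
    return truth


def load_families(config: PipelineConfig) -> Dict[str, List[LabeledSeq]]:
    """Group the training FASTA into per-subfamily sequence lists."""
    records = read_fasta(config.sequences)
    truth = read_truth(config.truth)
    families: Dict[str, List[LabeledSeq]] = {}
    for rec in records:
        if rec.id not in truth:
            logger.warning("sequence %s has no truth label; skipped", rec.id)
            continue
        label = truth[rec.id]
        families.setdefault(label, []).append(
            LabeledSeq(rec.id, rec.seq, label)
        )
    return families


def family_alignment(
    config: PipelineConfig, label: str, members: Sequence[LabeledSeq]
) -> Alignment:
    """Alignment for one subfamily: supplied file, or equal-length columns."""
    if label in config.alignments:
        path = config.alignments[label]
        fmt = "stockholm" if path.endswith((".sto", ".stk")) else "fasta"
        return read_alignment(path, fmt)
    lengths = {len(m.seq) for m in members}
    if len(lengths) != 1:
        raise ValueError(
            f"subfamily {label!r} has unequal sequence lengths and no "
            "pre-computed alignment was supplied"
        )
    return Alignment([(m.id, m.seq) for m in members])


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def cmd_cluster(config: PipelineConfig) -> Dict[str, List[set]]:
    """Split each labelled family into MCL clusters of similar sequences.

    With clustering toggled off this is an identity pass-through: each
    family is a single cluster.
    """
    config.validate()
    families = load_families(config)
    os.makedirs(config.workdir, exist_ok=True)
    out: Dict[str, List[set]] = {}
    for label in sorted(families):
        members = families[label]
        if not config.clustering:
            out[label] = [set(m.id for m in members)]
            continue
        if config.blast_table:
            graph = import_blast_tab(config.blast_table)
            fam_ids = {m.id for m in members}
            sub = type(graph)()
            for m in members:
                sub.add_node(m.id)
            for (a, b), w in graph.edges.items():
                if a in fam_ids and b in fam_ids:
                    sub.add_edge(a, b, w)
            graph = sub
        else:
            graph = kmer_similarity(members)
        clusters = mcl_cluster(graph, inflation=config.inflation)
        logger.info(
            "family %s: %d sequences -> %d clusters (inflation %.2f)",
            label, len(members), len(clusters), config.inflation,
        )
        write_assignments(
            clusters, os.path.join(config.workdir, f"clusters_{label}.tsv")
        )
        out[label] = clusters
    return out


def cmd_build(config: PipelineConfig) -> Dict[str, ProfileHMM]:
    """Build one default (unmodified) profile per subfamily."""
    config.validate()
    families = load_families(config)
    os.makedirs(config.workdir, exist_ok=True)
    profiles: Dict[str, ProfileHMM] = {}
    for label in sorted(families):
        members = families[label]
        if len(members) < 2:
            raise ValueError(
                f"subfamily {label!r} has {len(members)} sequence(s); "
                "at least 2 are required to build a profile"
            )
        aln = family_alignment(config, label, members)
        model = build_profile(
            aln, symfrac=config.symfrac, alpha=config.alpha, name=label,
            eweight_target=config.eweight_target,
        )
        profiles[label] = model
        logger.info("built profile %s (M=%d, %d sequences)", label, model.M, len(members))
    write_hmm_file(
        [profiles[k] for k in sorted(profiles)],
        os.path.join(config.workdir, "profiles_default.hmm"),
    )
    return profiles


def cmd_refine(
    config: PipelineConfig,
) -> Dict[str, Tuple[ProfileHMM, ThresholdResult]]:
    """Calibrate every subfamily profile: emission modification + GA cutoff.

    Writes the modified profiles as a concatenated HMMER3 database with GA
    lines, plus per-profile threshold reports.
    """
    config.validate()
    families = load_families(config)
    os.makedirs(config.workdir, exist_ok=True)
    strata_by_family: Dict[str, Optional[List]] = {}
    if config.clustering:
        clusters = cmd_cluster(config)
        for label, cl in clusters.items():
            assign = {}
            for ci, members in enumerate(cl):
                for sid in members:
                    assign[sid] = ci
            strata_by_family[label] = assign

    results: Dict[str, Tuple[ProfileHMM, ThresholdResult]] = {}
    cc = config.calibration_config()
    for idx, label in enumerate(sorted(families)):
        members = families[label]
        negatives = [
            s for other, group in families.items() if other != label for s in group
        ]
        aln = family_alignment(config, label, members)
        strata = None
        if label in strata_by_family and strata_by_family[label] is not None:
            strata = [strata_by_family[label].get(m.id, -1) for m in members]
        seed = _family_seed(config.seed, idx)
        logger.info("calibrating %s with seed %d", label, seed)
        model, result = calibrate(
            members,
            negatives,
            aln,
            k=config.k_folds,
            seed=seed,
            config=cc,
            strata=strata,
            name=label,
        )
        logger.info(
            "profile %s: branch=%s threshold=%.3f bits (folds=%d)",
            label, result.branch, result.threshold, result.n_folds,
        )
        result.to_tsv(os.path.join(config.workdir, f"threshold_{label}.tsv"))
        results[label] = (model, result)
    write_hmm_file(
        [results[k][0] for k in sorted(results)],
        os.path.join(config.workdir, "profiles_mode.hmm"),
    )
    return results


def cmd_scan(
    config: PipelineConfig,
    queries: Sequence[LabeledSeq],
    use_cutoff: bool = True,
    profile_db: Optional[str] = None,
) -> pd.DataFrame:
    """Classify query sequences against the profile database.

    Each query is assigned to the best-scoring profile among those whose
    GA cutoff it meets (``use_cutoff=True``) or among those it hits at the
    default zero-bit reporting floor (``use_cutoff=False``); queries
    meeting no profile stay ``unclassified``.  Returns the classification
    table; the per-profile hit list is available via :func:`scan_hits`.
    """
    hits = scan_hits(config, queries, use_cutoff=use_cutoff, profile_db=profile_db)
    rows = []
    for q in queries:
        passing = hits[(hits["query"] == q.id) & hits["passes"]]
        if len(passing):
            best = passing.loc[passing["bits"].idxmax()]
            rows.append((q.id, best["profile"], float(best["bits"])))
        else:
            rows.append((q.id, "unclassified", float("nan")))
    return pd.DataFrame(rows, columns=["query", "assigned", "bits"])


def scan_hits(
    config: PipelineConfig,
    queries: Sequence[LabeledSeq],
    use_cutoff: bool = True,
    profile_db: Optional[str] = None,
) -> pd.DataFrame:
    """All query-vs-profile scores with cutoff pass/fail flags."""
    if profile_db is None:
        profile_db = os.path.join(config.workdir, "profiles_mode.hmm")
    models = list(iter_hmm(profile_db))
    rows = []
    for q in queries:
        for model in models:
            try:
                bits = score_sequence(model, q.seq)
            except SequenceError as exc:
                logger.warning("query %s skipped: %s", q.id, exc)
                break
            if use_cutoff:
                ga = model.cutoffs.get("GA")
                floor = ga[0] if ga is not None else 0.0
            else:
                floor = 0.0
            rows.append((q.id, model.name, bits, bits >= floor))
    return pd.DataFrame(rows, columns=["query", "profile", "bits", "passes"])


def cmd_evaluate(
    classification: pd.DataFrame, truth: Dict[str, str]
) -> pd.DataFrame:
    """Per-subfamily Se/Sp/MCC and accuracy from a classification table.

    Accuracy for a subfamily is the fraction of its sequences assigned to
    it (unclassified counts against accuracy but is never a
    misclassification into another subfamily).
    """
    labels = sorted(set(truth.values()))
    rows = []
    for label in labels:
        tp = fp = tn = fn = 0
        for _, rec in classification.iterrows():
            t = truth.get(rec["query"])
            if t is None:
                continue
            assigned = rec["assigned"] == label
            if t == label:
                tp += assigned
                fn += not assigned
            else:
                fp += assigned
                tn += not assigned
        c = ConfusionCounts(tp, fp, tn, fn)
        se, sp = sensitivity_specificity(c)
        total = tp + fn
        rows.append(
            (
                label,
                total,
                tp,
                100.0 * tp / total if total else float("nan"),
                se,
                sp,
                mcc(c) if c.total else float("nan"),
            )
        )
    return pd.DataFrame(
        rows, columns=["subfamily", "total", "predicted", "accuracy", "se", "sp", "mcc"]
    )
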