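"""Qualitative signatures: discovery, single-sample classification, scoring.

A qualitative signature is a list of oriented gene pairs
``(gene_low_in_case, gene_high_in_case)``.  A sample votes for the case class
on a pair iff its expression of the low gene is strictly below that of the
high gene; the sample label is the winner-takes-all majority over pairs.  A
single-pair signature reduces exactly to the rule "call the sample a case
when E(low) < E(high)" — the form of the ICAM2/OSTF1 rheumatoid-arthritis
rule this package generalises.

Discovery restricts stable-pair mining to a user-supplied gene set (e.g. the
T-cell-related genes of the rheumatoid-arthritis study), intersects the
per-class sets into reversed pairs, and orients each survivor so the case
rule reads ``E(low) < E(high)``.

Tie policy: a pair with equal expression votes for the control class (the
case rule requires strict inequality), and an exact vote tie in a multi-pair
signature is labelled control for the same reason.  A sample in which no pair
is evaluable receives the distinct outcome ``"unclassifiable"``.

The continuous companion to the binary rule is ``score_sample``:
``log2(E(high)/E(low))``, positive when the pair favours the case class.  It
underlies ROC curves but never the label, and — unlike the binary rule — it
is *not* invariant to per-sample monotone transforms.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_preprocess import ExpressionMatrix, GeneSetCollection
from .reo_core import I_LT_J, find_reversed_pairs, mine_stable_pairs

__all__ = [
    "UNCLASSIFIABLE",
    "SignaturePair",
    "QualitativeSignature",
    "ClassificationResult",
    "discover_signature",
    "classify_sample",
    "classify_matrix",
    "score_sample",
]

UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class SignaturePair:
    """One oriented signature pair: low/high refer to the case class."""

    low_in_case: str
    high_in_case: str
    freq_control: float | None = None
    freq_case: float | None = None

    def __post_init__(self) -> None:
        if self.low_in_case == self.high_in_case:
            raise ValueError("signature pair genes must be distinct")


@dataclass
class QualitativeSignature:
    """A (possibly multi-pair) winner-takes-all signature.

    ``pairs`` may be empty to represent a discovery run that found no
    reversed pair; classification then refuses to run.  Multi-pair signatures
    are a majority-vote generalisation of the single-pair rule and are marked
    as such in ``provenance``.
    """

    pairs: list[SignaturePair]
    case_label: str = "case"
    control_label: str = "control"
    provenance: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for p in self.pairs:
            for g in (p.low_in_case, p.high_in_case):
                if g not in out:
                    out.append(g)
        return out

    def is_empty(self) -> bool:
        return len(self.pairs) == 0

    def to_dict(self) -> dict:
        return {
            "case_label": self.case_label,
            "control_label": self.control_label,
            "pairs": [
                {
                    "low_in_case": p.low_in_case,
                    "high_in_case": p.high_in_case,
                    "freq_control": p.freq_control,
                    "freq_case": p.freq_case,
                }
                for p in self.pairs
            ],
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, data: Mapping) -> "QualitativeSignature":
        pairs = [
            SignaturePair(
                low_in_case=p["low_in_case"],
                high_in_case=p["high_in_case"],
                freq_control=p.get("freq_control"),
                freq_case=p.get("freq_case"),
            )
            for p in data["pairs"]
        ]
        return cls(
            pairs=pairs,
            case_label=data.get("case_label", "case"),
            control_label=data.get("control_label", "control"),
            provenance=dict(data.get("provenance", {})),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "QualitativeSignature":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ClassificationResult:
    """Vote bookkeeping for one sample; votes always sum to the pair count."""

    sample_id: str
    votes_case: int
    votes_control: int
    ties_or_missing: int
    label: str
    score: float


def discover_signature(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    gene_sets: GeneSetCollection | Sequence[str],
    threshold: float = 0.85,
    case_label: str = "case",
    control_label: str = "control",
    min_evaluable: int | None = None,
) -> QualitativeSignature:
    """Mine per-class stable pairs within a gene set and keep reversed pairs.

    Each surviving pair is oriented so the case rule is ``E(low) < E(high)``.
    An empty signature is a valid outcome and is returned as such.
    """
    if isinstance(gene_sets, GeneSetCollection):
        restrict = sorted(gene_sets.union())
    else:
        restrict = sorted(set(gene_sets))
    present = [g for g in restrict if g in matrix.values.index]
    if not present:
        raise ValueError("no gene-set gene is present in the matrix")

    control_samples = [s for s, v in labels.items() if v == control_label and s in matrix.values.columns]
    case_samples = [s for s, v in labels.items() if v == case_label and s in matrix.values.columns]
    if not control_samples or not case_samples:
        raise ValueError(
            f"both classes must be present (control={len(control_samples)}, case={len(case_samples)})"
        )

    set_control = mine_stable_pairs(
        matrix, control_samples, threshold=threshold, genes=present,
        min_evaluable=min_evaluable, class_label=control_label,
    )
    set_case = mine_stable_pairs(
        matrix, case_samples, threshold=threshold, genes=present,
        min_evaluable=min_evaluable, class_label=case_label,
    )
    report = find_reversed_pairs(set_control, set_case)

    pairs: list[SignaturePair] = []
    for rp in report.reversed_pairs:
        if rp.direction_case == I_LT_J:  # case has gene_i below gene_j
            low, high = rp.gene_i, rp.gene_j
        else:
            low, high = rp.gene_j, rp.gene_i
        pairs.append(
            SignaturePair(
                low_in_case=low,
                high_in_case=high,
                freq_control=rp.freq_control,
                freq_case=rp.freq_case,
            )
        )

    provenance = {
        "threshold": threshold,
        "min_evaluable": min_evaluable,
        "gene_universe_size": len(present),
        "n_control_samples": len(control_samples),
        "n_case_samples": len(case_samples),
        "n_stable_control": len(set_control),
        "n_stable_case": len(set_case),
        "n_reversed": len(report.reversed_pairs),
        "n_same_direction": len(report.same_direction),
        "multi_pair_extension": len(pairs) > 1,
    }
    return QualitativeSignature(
        pairs=pairs,
        case_label=case_label,
        control_label=control_label,
        provenance=provenance,
    )


def _pair_vote(sample: Mapping[str, float], pair: SignaturePair) -> str:
    lo = sample.get(pair.low_in_case, math.nan)
    hi = sample.get(pair.high_in_case, math.nan)
    if isinstance(lo, float) and math.isnan(lo) or isinstance(hi, float) and math.isnan(hi):
        return "missing"
    if lo < hi:
        return "case"
    if lo > hi:
        return "control"
    return "tie"


def score_sample(
    sample: Mapping[str, float] | pd.Series,
    pair: SignaturePair,
    return_method: bool = False,
):
    """Continuous margin for one pair: ``log2(E(high)/E(low))``.

    Positive scores favour the case class.  With non-positive expression the
    ratio is undefined; the score falls back to the difference
    ``E(high) - E(low)`` and the method flag says so.
    """
    if isinstance(sample, pd.Series):
        sample = sample.to_dict()
    lo = sample.get(pair.low_in_case, math.nan)
    hi = sample.get(pair.high_in_case, math.nan)
    if math.isnan(lo) or math.isnan(hi):
        score, method = math.nan, "missing"
    elif lo > 0 and hi > 0:
        score, method = math.log2(hi / lo), "log2_ratio"
    else:
        score, method = hi - lo, "difference"
    return (score, method) if return_method else score


def classify_sample(
    sample: Mapping[str, float] | pd.Series,
    signature: QualitativeSignature,
    sample_id: str = "",
) -> ClassificationResult:
    """Winner-takes-all label for a single sample.

    Ties on a pair vote control; an exact overall vote tie is labelled
    control; a sample with no evaluable pair is ``"unclassifiable"``.
    """
    if signature.is_empty():
        raise ValueError("cannot classify with an empty signature")
    if isinstance(sample, pd.Series):
        sample = sample.to_dict()
    votes_case = votes_control = ties_or_missing = 0
    scores: list[float] = []
    for pair in signature.pairs:
        vote = _pair_vote(sample, pair)
        if vote == "case":
            votes_case += 1
        elif vote == "control":
            votes_control += 1
        else:
            ties_or_missing += 1
        s = score_sample(sample, pair)
        if not math.isnan(s):
            scores.append(s)
    if votes_case == 0 and votes_control == 0 and not scores and ties_or_missing == len(signature.pairs):
        # every pair missing a gene
        label = UNCLASSIFIABLE
    elif votes_case > votes_control:
        label = signature.case_label
    else:
        label = signature.control_label
    score = float(np.mean(scores)) if scores else math.nan
    return ClassificationResult(
        sample_id=sample_id,
        votes_case=votes_case,
        votes_control=votes_control,
        ties_or_missing=ties_or_missing,
        label=label,
        score=score,
    )


def classify_matrix(
    matrix: ExpressionMatrix, signature: QualitativeSignature
) -> pd.DataFrame:
    """Classify every sample; returns a frame indexed by sample ID."""
    rows = []
    for sample_id in matrix.sample_ids:
        sample = matrix.values[sample_id].to_dict()
        res = classify_sample(sample, signature, sample_id=sample_id)
        rows.append(
            {
                "sample_id": res.sample_id,
                "votes_case": res.votes_case,
                "votes_control": res.votes_control,
                "ties_or_missing": res.ties_or_missing,
                "label": res.label,
                "score": res.score,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
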