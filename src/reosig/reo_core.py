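"""Within-sample relative expression ordering (REO) and stable-pair mining.

The REO of a gene pair (i, j) in one sample is the binary relation
``E_i > E_j`` or ``E_i < E_j`` between the two genes' expression values.  It
depends only on the within-sample comparison, so it is invariant to any
strictly monotone per-sample transformation — the property that makes
REO-based signatures robust to batch effects and normalisation choices.

A *highly stable pair* within one class is a pair whose REO direction is the
same in at least a threshold fraction (85% by convention) of that class's
samples.  Pairs stable in both classes with opposite directions — *reversed
pairs* — are the raw material for qualitative diagnostic signatures.

Conventions
-----------
* Pairs are keyed canonically: ``gene_i < gene_j`` lexicographically, with the
  direction stored relative to that order.
* Ties (``E_i == E_j``) count toward no direction but do count in the
  evaluable denominator, so ties erode stability rather than inflate it.
* Samples missing either gene are excluded from the denominator; a
  ``min_evaluable`` guard (default: half the class size, rounded up) prevents
  pairs supported by very few samples.
* The stability threshold comparison is inclusive (>= threshold).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_preprocess import ExpressionMatrix

__all__ = [
    "I_GT_J",
    "I_LT_J",
    "TIE",
    "MISSING",
    "StablePair",
    "StablePairSet",
    "ReversedPair",
    "ReversedPairReport",
    "encode_reo",
    "ReoEncoding",
    "mine_stable_pairs",
    "find_reversed_pairs",
]

I_GT_J = "i_gt_j"
I_LT_J = "i_lt_j"
TIE = "tie"
MISSING = "missing"

# float guard for inclusive threshold comparison on ratios like 17/20
_EPS = 1e-9


@dataclass(frozen=True, slots=True)
class StablePair:
    """A canonically ordered gene pair with its majority REO direction."""

    gene_i: str
    gene_j: str
    direction: str
    support: int
    evaluable: int

    def __post_init__(self) -> None:
        if self.gene_i == self.gene_j:
            raise ValueError("pair genes must be distinct")
        if self.gene_i > self.gene_j:
            raise ValueError("pair must be in canonical (lexicographic) order")
        if self.direction not in (I_GT_J, I_LT_J):
            raise ValueError(f"bad direction {self.direction!r}")
        if not 0 <= self.support <= self.evaluable:
            raise ValueError("support must lie in [0, evaluable]")

    @property
    def frequency(self) -> float:
        return self.support / self.evaluable

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_i, self.gene_j)


@dataclass
class StablePairSet:
    """All stable pairs mined from one class at one threshold."""

    class_label: str
    threshold: float
    min_evaluable: int
    pairs: dict[tuple[str, str], StablePair] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs.values())

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.pairs

    def get(self, gene_i: str, gene_j: str) -> StablePair | None:
        return self.pairs.get((gene_i, gene_j))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_i": p.gene_i,
                "gene_j": p.gene_j,
                "direction": p.direction,
                "support": p.support,
                "evaluable": p.evaluable,
                "frequency": p.frequency,
                "class": self.class_label,
                "threshold": self.threshold,
            }
            for p in sorted(self.pairs.values(), key=lambda p: p.key)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "gene_i",
                "gene_j",
                "direction",
                "support",
                "evaluable",
                "frequency",
                "class",
                "threshold",
            ],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StablePairSet":
        frame = pd.read_csv(path, sep="\t", dtype={"gene_i": str, "gene_j": str})
        if frame.empty:
            raise ValueError(f"{path}: empty stable-pair table")
        class_label = str(frame["class"].iloc[0])
        threshold = float(frame["threshold"].iloc[0])
        out = cls(class_label=class_label, threshold=threshold, min_evaluable=0)
        for row in frame.itertuples(index=False):
            pair = StablePair(
                str(row.gene_i), str(row.gene_j), row.direction, int(row.support), int(row.evaluable)
            )
            out.pairs[pair.key] = pair
        return out


class ReoEncoding:
    """Per-sample ordering oracle over a matrix (optionally a gene subset).

    ``state(gene_i, gene_j, sample)`` answers one of ``i_gt_j``, ``i_lt_j``,
    ``tie`` or ``missing`` relative to the argument order; answers depend only
    on within-sample comparisons.
    """

    def __init__(self, matrix: ExpressionMatrix, genes: Sequence[str] | None = None):
        if genes is None:
            genes = matrix.gene_ids
        sub = matrix.subset_genes(list(genes))
        self._values = sub.values.to_numpy(dtype=float)
        self._gene_index = {g: k for k, g in enumerate(sub.gene_ids)}
        self._sample_index = {s: k for k, s in enumerate(sub.sample_ids)}
        self.gene_ids = sub.gene_ids
        self.sample_ids = sub.sample_ids

    def _locate(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def state(self, gene_i: str, gene_j: str, sample: str) -> str:
        gi, gj = self._locate(gene_i), self._locate(gene_j)
        try:
            s = self._sample_index[sample]
        except KeyError:
            raise KeyError(f"unknown sample {sample!r}") from None
        xi, xj = self._values[gi, s], self._values[gj, s]
        if math.isnan(xi) or math.isnan(xj):
            return MISSING
        if xi > xj:
            return I_GT_J
        if xi < xj:
            return I_LT_J
        return TIE

    def states(self, gene_i: str, gene_j: str) -> pd.Series:
        """REO state of one pair across every sample."""
        return pd.Series(
            [self.state(gene_i, gene_j, s) for s in self.sample_ids],
            index=self.sample_ids,
            name=f"{gene_i}|{gene_j}",
        )


def encode_reo(matrix: ExpressionMatrix, genes: Sequence[str] | None = None) -> ReoEncoding:
    """Build the per-sample pairwise ordering oracle for ``matrix``."""
    return ReoEncoding(matrix, genes)


def _pairwise_counts(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Counts of strict orderings and of jointly observed samples.

    Returns ``gt`` with ``gt[a, b]`` = number of samples where gene a's value
    strictly exceeds gene b's (both observed), and ``ev`` = number of samples
    where both are observed (ties included).  Accumulated sample-by-sample so
    memory stays at O(genes^2).
    """
    g, n = X.shape
    gt = np.zeros((g, g), dtype=np.int32)
    ev = np.zeros((g, g), dtype=np.int32)
    for s in range(n):
        x = X[:, s]
        ok = ~np.isnan(x)
        both = ok[:, None] & ok[None, :]
        np.add(ev, both, out=ev, casting="unsafe")
        # NaN comparisons are False, so masking by `both` is already implied
        np.add(gt, x[:, None] > x[None, :], out=gt, casting="unsafe")
    return gt, ev


def mine_stable_pairs(
    matrix: ExpressionMatrix,
    class_samples: Sequence[str],
    threshold: float = 0.85,
    genes: Sequence[str] | None = None,
    min_evaluable: int | None = None,
    class_label: str = "",
) -> StablePairSet:
    """Exhaustively mine highly stable gene pairs within one class.

    A canonical pair (i, j) is reported with direction ``d`` iff the fraction
    of evaluable samples ordered as ``d`` is >= ``threshold`` and the number
    of evaluable samples is >= ``min_evaluable``.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1] (<=0.5 is direction-ambiguous)")
    if len(class_samples) == 0:
        raise ValueError("class_samples is empty")
    sub = matrix.subset_samples(list(class_samples))
    if genes is not None:
        sub = sub.subset_genes(list(genes))
    order = sorted(sub.gene_ids)
    sub = sub.subset_genes(order)
    n = len(class_samples)
    if min_evaluable is None:
        min_evaluable = math.ceil(n / 2)

    X = sub.values.to_numpy(dtype=float)
    gt, ev = _pairwise_counts(X)
    g = len(order)
    iu, ju = np.triu_indices(g, k=1)
    e = ev[iu, ju]
    a = gt[iu, ju]  # i > j counts
    b = gt[ju, iu]  # j > i counts

    usable = (e >= max(min_evaluable, 1)) & (e > 0)
    hit_gt = usable & (a + _EPS >= threshold * e)
    hit_lt = usable & (b + _EPS >= threshold * e)

    out = StablePairSet(class_label=class_label, threshold=threshold, min_evaluable=min_evaluable)
    genes_arr = np.asarray(order, dtype=object)
    for mask, direction, support in ((hit_gt, I_GT_J, a), (hit_lt, I_LT_J, b)):
        idx = np.nonzero(mask)[0]
        for k in idx:
            gi = genes_arr[iu[k]]
            gj = genes_arr[ju[k]]
            out.pairs[(gi, gj)] = StablePair(gi, gj, direction, int(support[k]), int(e[k]))
    return out


@dataclass(frozen=True, slots=True)
class ReversedPair:
    """A pair stable in both classes with opposite REO directions."""

    gene_i: str
    gene_j: str
    direction_control: str
    direction_case: str
    freq_control: float
    freq_case: float
    support_control: int
    evaluable_control: int
    support_case: int
    evaluable_case: int


@dataclass
class ReversedPairReport:
    """Opposite-direction overlap of two per-class stable-pair sets.

    ``reversed_pairs`` holds the signature candidates; ``same_direction``
    holds pairs stable in both classes with the same ordering (exposed because
    they are the bulk of any real overlap and useful for diagnostics).
    """

    reversed_pairs: list[ReversedPair]
    same_direction: list[tuple[StablePair, StablePair]]
    provenance: dict = field(default_factory=dict)

    def reversed_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_i": p.gene_i,
                "gene_j": p.gene_j,
                "direction_control": p.direction_control,
                "direction_case": p.direction_case,
                "freq_control": p.freq_control,
                "freq_case": p.freq_case,
            }
            for p in self.reversed_pairs
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "gene_i",
                "gene_j",
                "direction_control",
                "direction_case",
                "freq_control",
                "freq_case",
            ],
        )


def find_reversed_pairs(
    set_control: StablePairSet, set_case: StablePairSet
) -> ReversedPairReport:
    """Intersect two per-class stable-pair sets into reversed and same-direction overlaps."""
    provenance: dict = {
        "threshold_control": set_control.threshold,
        "threshold_case": set_case.threshold,
        "n_stable_control": len(set_control),
        "n_stable_case": len(set_case),
        "warnings": [],
    }
    if set_control.threshold != set_case.threshold:
        msg = (
            f"stable-pair sets mined at different thresholds "
            f"({set_control.threshold} vs {set_case.threshold})"
        )
        provenance["warnings"].append(msg)
        warnings.warn(msg, stacklevel=2)

    rev: list[ReversedPair] = []
    same: list[tuple[StablePair, StablePair]] = []
    for key in sorted(set_control.pairs.keys() & set_case.pairs.keys()):
        pc = set_control.pairs[key]
        pa = set_case.pairs[key]
        if pc.direction == pa.direction:
            same.append((pc, pa))
        else:
            rev.append(
                ReversedPair(
                    gene_i=pc.gene_i,
                    gene_j=pc.gene_j,
                    direction_control=pc.direction,
                    direction_case=pa.direction,
                    freq_control=pc.frequency,
                    freq_case=pa.frequency,
                    support_control=pc.support,
                    evaluable_control=pc.evaluable,
                    support_case=pa.support,
                    evaluable_case=pa.evaluable,
                )
            )
    provenance["n_reversed"] = len(rev)
    provenance["n_same_direction"] = len(same)
    return ReversedPairReport(reversed_pairs=rev, same_direction=same, provenance=provenance)
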