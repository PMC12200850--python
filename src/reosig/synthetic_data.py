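"""Synthetic two-class expression cohorts with planted, known structure.

The generator emulates the statistical structure a relative-expression-
ordering pipeline assumes in a case/control transcriptome study: positive
right-skewed intensities (log-normal per gene), class-specific differential
expression, correlated gene modules, per-sample monotone distortions standing
in for batch/normalisation effects, and missing values.  Crucially it plants
*reversed pairs* — gene pairs ordered one way in a controllable fraction of
control samples and the opposite way in case samples — so signature discovery
can be validated against a known truth.

Planting mechanism: for each planted pair and each sample, a Bernoulli draw
at the intended stability decides whether the sample conforms to its class
direction; the two genes' values are swapped whenever the realised ordering
disagrees.  This controls the ordering frequency exactly, independent of the
marginals (both genes share a common location so the swap is distribution-
neutral).  Monotone distortion is applied after planting, so within-sample
orderings are preserved by construction; missingness is applied last,
completely at random.

All randomness flows through a single :class:`numpy.random.Generator` seeded
from ``rng_seed``: identical config gives a bit-identical cohort.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io_preprocess import ExpressionMatrix, write_labels, write_matrix

__all__ = [
    "MonotoneDistortion",
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "apply_monotone_distortion",
]

IDENTITY_DISTORTION = ((1.0, 1.0), (0.0, 0.0), (1.0, 1.0))


@dataclass(frozen=True)
class MonotoneDistortion:
    """Per-sample transform ``x -> a * x**c + b`` with a, c > 0.

    Ranges are sampled uniformly per sample.  ``b`` is lifted if needed so
    every transformed value stays strictly positive.  The identity ranges
    ((1,1), (0,0), (1,1)) are the default: distortion is opt-in.
    """

    scale_range: tuple[float, float] = IDENTITY_DISTORTION[0]
    shift_range: tuple[float, float] = IDENTITY_DISTORTION[1]
    power_range: tuple[float, float] = IDENTITY_DISTORTION[2]

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("scale_range", self.scale_range),
            ("shift_range", self.shift_range),
            ("power_range", self.power_range),
        ):
            if lo > hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")
        if self.scale_range[0] <= 0:
            raise ValueError("scale_range must be strictly positive")
        if self.power_range[0] <= 0:
            raise ValueError("power_range must be strictly positive")


@dataclass
class SyntheticCohortConfig:
    """All generator knobs.

    ``planted_reversed_pairs`` entries are
    ``(gene_i, gene_j, stability_control, stability_case)`` with gene indices
    into the simulated gene list (``gene_i < gene_j``); the planted class
    directions are gene_i > gene_j in controls and gene_i < gene_j in cases.
    Default sample sizes mirror a typical discovery cohort of 53 controls and
    112 cases; the default cohort carries no planted signal.
    """

    n_genes: int = 200
    n_samples_per_class: tuple[int, int] = (53, 112)  # (control, case)
    planted_reversed_pairs: list[tuple[int, int, float, float]] = field(default_factory=list)
    planted_stable_pairs_per_class: int = 0
    n_de_genes: int = 0
    de_log_fold_change: float = 1.0
    n_correlated_modules: int = 0
    module_size: int = 10
    module_correlation: float = 0.8
    monotone_distortion: MonotoneDistortion = field(default_factory=MonotoneDistortion)
    missing_rate: float = 0.0
    noise_sd: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.monotone_distortion, dict):
            self.monotone_distortion = MonotoneDistortion(
                scale_range=tuple(self.monotone_distortion.get("scale_range", IDENTITY_DISTORTION[0])),
                shift_range=tuple(self.monotone_distortion.get("shift_range", IDENTITY_DISTORTION[1])),
                power_range=tuple(self.monotone_distortion.get("power_range", IDENTITY_DISTORTION[2])),
            )
        self.n_samples_per_class = tuple(self.n_samples_per_class)
        self.planted_reversed_pairs = [tuple(p) for p in self.planted_reversed_pairs]
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if min(self.n_samples_per_class) < 1:
            raise ValueError("each class needs at least 1 sample")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_correlated_modules and not 0.0 < self.module_correlation < 1.0:
            raise ValueError("module_correlation must be in (0, 1)")
        used: set[int] = set()
        for entry in self.planted_reversed_pairs:
            if len(entry) != 4:
                raise ValueError("planted pair must be (gene_i, gene_j, stab_control, stab_case)")
            gi, gj, sh, sc = entry
            if gi == gj:
                raise ValueError("planted pair genes must be distinct")
            if not (0 <= gi < self.n_genes and 0 <= gj < self.n_genes):
                raise ValueError("planted pair gene index out of range")
            if gi in used or gj in used:
                raise ValueError("a gene may appear in at most one planted pair")
            used.update((gi, gj))
            for s in (sh, sc):
                if not 0.0 <= s <= 1.0:
                    raise ValueError("planted stabilities must lie in [0, 1]")
        reserved = (
            len(used)
            + 2 * self.planted_stable_pairs_per_class
            + self.n_de_genes
            + self.n_correlated_modules * self.module_size
        )
        if reserved > self.n_genes:
            raise ValueError(
                f"planted structure needs {reserved} distinct genes but n_genes={self.n_genes}; "
                "planted pairs, stable pairs, DE genes and modules are kept disjoint so "
                "no DE constraint can contradict a planted pair direction"
            )

    def to_dict(self) -> dict:
        out = asdict(self)
        out["monotone_distortion"] = {
            "scale_range": list(self.monotone_distortion.scale_range),
            "shift_range": list(self.monotone_distortion.shift_range),
            "power_range": list(self.monotone_distortion.power_range),
        }
        out["n_samples_per_class"] = list(self.n_samples_per_class)
        out["planted_reversed_pairs"] = [list(p) for p in self.planted_reversed_pairs]
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticCohortConfig":
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticCohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class SyntheticCohort:
    """A generated cohort plus the planted truth it must be judged against."""

    matrix: ExpressionMatrix
    labels: pd.Series
    truth: dict
    config: SyntheticCohortConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "matrix": out_dir / "matrix.tsv",
            "labels": out_dir / "labels.tsv",
            "truth": out_dir / "truth.json",
        }
        write_matrix(self.matrix, paths["matrix"])
        write_labels(self.labels, paths["labels"])
        paths["truth"].write_text(json.dumps(self.truth, indent=2, sort_keys=True) + "\n")
        return paths


def _gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes - 1)))
    return [f"G{str(i).zfill(width)}" for i in range(n_genes)]


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate a labelled two-class cohort per ``config``.

    Pipeline order: log-normal baseline (with correlated modules) ->
    differential expression -> planted same-direction stable pairs ->
    planted reversed pairs -> per-sample monotone distortion ->
    missingness.  Identical config (including seed) gives an identical
    cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n_ctrl, n_case = config.n_samples_per_class
    n_total = n_ctrl + n_case
    genes = _gene_ids(config.n_genes)

    # gene-index bookkeeping: planted structures occupy disjoint index blocks
    planted_idx: set[int] = set()
    for gi, gj, _, _ in config.planted_reversed_pairs:
        planted_idx.update((gi, gj))
    free = iter(i for i in range(config.n_genes) if i not in planted_idx)
    stable_pairs = [
        (next(free), next(free)) for _ in range(config.planted_stable_pairs_per_class)
    ]
    de_idx = [next(free) for _ in range(config.n_de_genes)]
    modules = [
        [next(free) for _ in range(config.module_size)]
        for _ in range(config.n_correlated_modules)
    ]

    meanlog = rng.uniform(1.0, 4.0, size=config.n_genes)
    for gi, gj, _, _ in config.planted_reversed_pairs:
        common = (meanlog[gi] + meanlog[gj]) / 2  # shared location: swaps are distribution-neutral
        meanlog[gi] = meanlog[gj] = common
    for gi, gj in stable_pairs:
        common = (meanlog[gi] + meanlog[gj]) / 2
        meanlog[gi] = meanlog[gj] = common

    Z = rng.standard_normal((config.n_genes, n_total))
    r = config.module_correlation
    for module in modules:
        factor = rng.standard_normal(n_total)
        Z[module] = np.sqrt(r) * factor + np.sqrt(1.0 - r) * Z[module]
    X = np.exp(meanlog[:, None] + config.noise_sd * Z)

    case_cols = slice(n_ctrl, n_total)
    de_signs = rng.choice([-1, 1], size=config.n_de_genes)
    for idx, sign in zip(de_idx, de_signs):
        X[idx, case_cols] *= 2.0 ** (sign * config.de_log_fold_change)

    for gi, gj in stable_pairs:  # enforce gene_i > gene_j in every sample, both classes
        swap = X[gi] < X[gj]
        X[gi][swap], X[gj][swap] = X[gj][swap].copy(), X[gi][swap].copy()

    for gi, gj, s_ctrl, s_case in config.planted_reversed_pairs:
        lo_idx, hi_idx = min(gi, gj), max(gi, gj)
        conform_ctrl = rng.random(n_ctrl) < s_ctrl
        conform_case = rng.random(n_case) < s_case
        # control direction: gene_lo > gene_hi ; case direction: gene_lo < gene_hi
        want_lo_gt_hi = np.concatenate([conform_ctrl, ~conform_case])
        is_lo_gt_hi = X[lo_idx] > X[hi_idx]
        swap = want_lo_gt_hi != is_lo_gt_hi
        X[lo_idx][swap], X[hi_idx][swap] = X[hi_idx][swap].copy(), X[lo_idx][swap].copy()

    assert (X > 0).all(), "pre-missingness values must be strictly positive"

    sample_ids = [f"CTRL{str(k).zfill(3)}" for k in range(n_ctrl)] + [
        f"CASE{str(k).zfill(3)}" for k in range(n_case)
    ]
    labels = pd.Series(
        ["control"] * n_ctrl + ["case"] * n_case, index=sample_ids, name="label"
    )

    X = _distort(X, config.monotone_distortion, rng)

    if config.missing_rate > 0:
        mask = rng.random(X.shape) < config.missing_rate
        X = X.copy()
        X[mask] = np.nan

    frame = pd.DataFrame(X, index=genes, columns=sample_ids)
    matrix = ExpressionMatrix(frame, labels)

    truth = {
        "reversed_pairs": [
            {
                "gene_i": genes[min(gi, gj)],
                "gene_j": genes[max(gi, gj)],
                "direction_control": "i_gt_j",
                "direction_case": "i_lt_j",
                "low_in_case": genes[min(gi, gj)],
                "high_in_case": genes[max(gi, gj)],
                "stability_control": s_ctrl,
                "stability_case": s_case,
            }
            for gi, gj, s_ctrl, s_case in config.planted_reversed_pairs
        ],
        "stable_pairs": [
            {
                "gene_i": genes[min(gi, gj)],
                "gene_j": genes[max(gi, gj)],
                "direction": "i_gt_j" if gi < gj else "i_lt_j",
            }
            for gi, gj in stable_pairs
        ],
        "de_genes": [
            {"gene": genes[idx], "sign": int(sign)} for idx, sign in zip(de_idx, de_signs)
        ],
        "modules": [
            {"name": f"module_{m}", "genes": [genes[i] for i in module]}
            for m, module in enumerate(modules)
        ],
    }
    return SyntheticCohort(matrix=matrix, labels=labels, truth=truth, config=config)


def _distort(X: np.ndarray, distortion: MonotoneDistortion, rng: np.random.Generator) -> np.ndarray:
    """Apply ``x -> a * x**c + b`` per sample (column); rank-preserving."""
    n_total = X.shape[1]
    a = rng.uniform(*distortion.scale_range, size=n_total)
    b = rng.uniform(*distortion.shift_range, size=n_total)
    c = rng.uniform(*distortion.power_range, size=n_total)
    Y = a[None, :] * np.power(X, c[None, :]) + b[None, :]
    # lift the shift where it would push values non-positive
    with np.errstate(invalid="ignore"):
        mins = np.nanmin(Y, axis=0)
    bad = mins <= 0
    if bad.any():
        Y[:, bad] -= mins[bad][None, :]
        Y[:, bad] += 1e-6
    return Y


def apply_monotone_distortion(
    matrix: ExpressionMatrix,
    config: SyntheticCohortConfig | MonotoneDistortion,
    rng: np.random.Generator | int | None = None,
) -> ExpressionMatrix:
    """Per-sample monotone distortion of an expression matrix.

    ``config`` may be a full cohort config (its distortion block and seed are
    used) or a bare :class:`MonotoneDistortion` (pass ``rng`` or an int seed).
    Input values must be strictly positive; missing values pass through.
    Within-sample ranks are unchanged by construction.
    """
    if isinstance(config, SyntheticCohortConfig):
        distortion = config.monotone_distortion
        if rng is None:
            rng = np.random.default_rng(config.rng_seed)
    else:
        distortion = config
    if rng is None:
        rng = np.random.default_rng(0)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    X = matrix.values.to_numpy(dtype=float)
    observed = ~np.isnan(X)
    if (X[observed] <= 0).any():
        raise ValueError("monotone distortion requires strictly positive input values")
    Y = _distort(X, distortion, rng)
    frame = pd.DataFrame(Y, index=matrix.gene_ids, columns=matrix.sample_ids)
    return ExpressionMatrix(frame, matrix.labels)
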