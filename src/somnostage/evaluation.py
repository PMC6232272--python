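"""Agreement metrics between reference and predicted hypnograms.

Cohen's kappa is the primary metric: chance-corrected agreement,
kappa = (p_o - p_e) / (1 - p_e), a number <= 1 that can be negative; values
above 0.8 are considered excellent agreement. Per-stage kappas binarize
both sequences to stage-vs-rest. A stage absent from the reference of a
recording leaves that recording's per-stage kappa undefined, and such
recordings are excluded from the stage's aggregate mean and standard
deviation (e.g. N3 is not always reached during MSLT naps) rather than
contributing a silent zero. F1 scores are reported alongside for
comparability with other work.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .core import STAGES, stage_index, stages_to_indices

_N = len(STAGES)


@dataclass
class ConfusionMatrix:
    """5x5 epoch counts, reference rows x prediction columns."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (_N, _N):
            raise ValueError("confusion matrix must be 5x5")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class AgreementReport:
    """Agreement between one reference and one predicted hypnogram."""

    confusion: ConfusionMatrix
    accuracy: float
    kappa: float
    per_stage_kappa: dict[str, Optional[float]]
    per_class_f1: dict[str, Optional[float]]
    n_epochs: int

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.counts.tolist(),
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "per_stage_kappa": self.per_stage_kappa,
            "per_class_f1": self.per_class_f1,
            "n_epochs": self.n_epochs,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def confusion(reference: Sequence[str], predicted: Sequence[str]) -> ConfusionMatrix:
    """counts[i][j] = number of epochs scored i by the reference, j by the model."""
    if len(reference) != len(predicted):
        raise ValueError(f"length mismatch: reference {len(reference)} vs predicted {len(predicted)}")
    ref = stages_to_indices(reference)
    pred = stages_to_indices(predicted)
    counts = np.zeros((_N, _N), dtype=np.int64)
    np.add.at(counts, (ref, pred), 1)
    return ConfusionMatrix(counts)


def cohen_kappa(cm: Union[ConfusionMatrix, np.ndarray]) -> float:
    """kappa = (p_o - p_e) / (1 - p_e) with p_o = trace/total and
    p_e = sum_k row_k * col_k / total^2. Returns 1 for perfect agreement
    even when p_e = 1 (both raters constant and identical)."""
    counts = cm.counts if isinstance(cm, ConfusionMatrix) else np.asarray(cm)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(counts) / total
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum()) / total**2
    if np.isclose(p_e, 1.0):
        return 1.0 if np.isclose(p_o, 1.0) else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def per_stage_kappa(reference: Sequence[str], predicted: Sequence[str]) -> dict[str, Optional[float]]:
    """Stage-vs-rest kappa per stage; None where the reference lacks the stage."""
    if len(reference) != len(predicted):
        raise ValueError("length mismatch between reference and prediction")
    ref = stages_to_indices(reference)
    pred = stages_to_indices(predicted)
    out: dict[str, Optional[float]] = {}
    for s, stage in enumerate(STAGES):
        if not np.any(ref == s):
            out[stage] = None  # undefined: never silently zero
            continue
        r = (ref == s).astype(np.int64)
        p = (pred == s).astype(np.int64)
        cm2 = np.zeros((2, 2), dtype=np.int64)
        np.add.at(cm2, (r, p), 1)
        out[stage] = cohen_kappa(cm2)
    return out


def f1_per_class(cm: ConfusionMatrix) -> dict[str, Optional[float]]:
    """F1 = 2 P R / (P + R) per class; None when the class is absent from
    both raters, 0.0 when present but precision and recall are both zero."""
    counts = cm.counts
    out: dict[str, Optional[float]] = {}
    for k, stage in enumerate(STAGES):
        tp = counts[k, k]
        ref_n = counts[k, :].sum()
        pred_n = counts[:, k].sum()
        if ref_n == 0 and pred_n == 0:
            out[stage] = None
            continue
        if tp == 0:
            out[stage] = 0.0
            continue
        precision = tp / pred_n
        recall = tp / ref_n
        out[stage] = float(2 * precision * recall / (precision + recall))
    return out


def agreement_report(reference: Sequence[str], predicted: Sequence[str]) -> AgreementReport:
    cm = confusion(reference, predicted)
    return AgreementReport(
        confusion=cm,
        accuracy=float(np.trace(cm.counts) / cm.total),
        kappa=cohen_kappa(cm),
        per_stage_kappa=per_stage_kappa(reference, predicted),
        per_class_f1=f1_per_class(cm),
        n_epochs=cm.total,
    )


@dataclass
class StageAggregate:
    """Across-recording mean +- sd of one stage's kappa with exclusions."""

    mean: Optional[float]
    sd: Optional[float]
    n_included: int
    n_excluded: int


def aggregate(reports: Sequence[AgreementReport]) -> dict[str, StageAggregate]:
    """Per-stage mean and sample standard deviation over recordings.

    Recordings whose reference lacks a stage do not enter that stage's
    aggregate; their count is reported. A stage undefined in every
    recording yields an undefined (None) aggregate. Recordings are
    weighted equally regardless of epoch count.
    """
    if len(reports) < 1:
        raise ValueError("at least one report is required")
    out: dict[str, StageAggregate] = {}
    for stage in STAGES:
        vals = [r.per_stage_kappa[stage] for r in reports]
        present = [v for v in vals if v is not None]
        n_exc = len(vals) - len(present)
        if not present:
            out[stage] = StageAggregate(None, None, 0, n_exc)
            continue
        mean = float(np.mean(present))
        sd = float(np.std(present, ddof=1)) if len(present) > 1 else None
        out[stage] = StageAggregate(mean, sd, len(present), n_exc)
    return out


def plot_hypnograms(
    reference: Sequence[str],
    predicted: Sequence[str],
    epoch_len_s: int,
    path: Union[str, Path],
) -> None:
    """Reference-vs-predicted hypnogram panel (stages W, R, N1, N2, N3 top-down)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = ["W", "R", "N1", "N2", "N3"]  # conventional plotting order
    level = {s: -i for i, s in enumerate(order)}
    fig, axes = plt.subplots(2, 1, figsize=(10, 4), sharex=True)
    for ax, stages, title in ((axes[0], reference, "reference"), (axes[1], predicted, "predicted")):
        t = np.arange(len(stages)) * epoch_len_s / 3600.0
        y = [level[s] for s in stages]
        ax.step(t, y, where="post", lw=0.8)
        ax.set_yticks([-i for i in range(len(order))], order)
        ax.set_ylabel(title)
    axes[1].set_xlabel("time (h)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
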