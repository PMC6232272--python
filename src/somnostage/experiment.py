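"""Experiment orchestration: subject-disjoint splits and training regimes.

Reproduces the study design around the classifiers: recordings are split
by participant into training/validation/test parts (70/15/15), so all
recordings of one subject travel together; a mixed regime adds a fixed
number of patient recordings (whole patients) to the healthy training set
and evaluates on the held-out healthy and patient recordings.

``run_experiment`` wires the full pipeline — generate or load, preprocess,
extract features where needed, train, predict, smooth, evaluate — and
writes reports plus a manifest (config hash, seed, versions) so every
report is traceable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import __version__
from .classical import (
    estimate_transition_model,
    median_smooth,
    predict_proba,
    train_rf,
    viterbi_smooth,
)
from .core import Hypnogram, Recording, n_stage_transitions
from .evaluation import AgreementReport, agreement_report, aggregate
from .features import extract_features
from .neural import (
    CNNLSTMConfig,
    LSTMConfig,
    build_cnn_lstm,
    build_feature_lstm,
    make_feature_data,
    make_raw_data,
    predict_stages,
    train_network,
)
from .synthetic_psg import DatasetEntry, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RosterEntry:
    subject_id: str
    recording_id: str
    cohort: str  # healthy | patient_night | patient_mslt
    recording: Optional[Recording] = None
    hypnogram: Optional[Hypnogram] = None


@dataclass
class Roster:
    entries: list[RosterEntry]

    def __post_init__(self) -> None:
        ids = [e.recording_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("recording ids must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def subjects(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.subject_id not in seen:
                seen.append(e.subject_id)
        return seen

    def by_subject(self) -> dict[str, list[RosterEntry]]:
        out: dict[str, list[RosterEntry]] = {}
        for e in self.entries:
            out.setdefault(e.subject_id, []).append(e)
        return out

    def get(self, recording_id: str) -> RosterEntry:
        for e in self.entries:
            if e.recording_id == recording_id:
                return e
        raise KeyError(recording_id)

    @staticmethod
    def from_dataset(entries: Sequence[DatasetEntry]) -> "Roster":
        return Roster(
            [RosterEntry(e.subject_id, e.recording_id, e.cohort, e.recording, e.hypnogram) for e in entries]
        )


@dataclass
class SplitPlan:
    """Disjoint train/validation/test recording-id sets, subject-disjoint.

    ``allow_overlap`` marks the one sanctioned exception: the mixed-regime
    reading in which all healthy recordings train and the healthy test part
    is re-used for evaluation (see :func:`build_mixed_training`).
    """

    train: list[str]
    validation: list[str]
    test: list[str]
    fractions: tuple[float, float, float]
    seed: int
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if self.allow_overlap:
            return
        parts = [set(self.train), set(self.validation), set(self.test)]
        if parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2]:
            raise ValueError("split parts must be disjoint")


def split_by_subject(
    roster: Roster,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitPlan:
    """Subject-disjoint split with largest-remainder subject allocation.

    Subjects are shuffled under the seed, then the number of subjects per
    part is fixed by largest-remainder rounding of the fractions so the
    recording counts best match them (18 subjects x 3 recordings at
    70/15/15 gives exactly 36/9/9 recordings). All recordings of one
    subject land in the same part.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    groups = roster.by_subject()
    subjects = list(groups)
    n_parts_needed = sum(f > 0 for f in fractions)
    if len(subjects) < n_parts_needed:
        raise ValueError(f"need at least {n_parts_needed} subjects for {n_parts_needed} nonempty parts")
    rng = np.random.default_rng(seed)
    rng.shuffle(subjects)
    quotas = [len(subjects) * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    for _ in range(len(subjects) - sum(counts)):
        k = int(np.argmax(remainders))
        counts[k] += 1
        remainders[k] = -1.0
    # guarantee a subject in every nonempty part
    for k, f in enumerate(fractions):
        if f > 0 and counts[k] == 0:
            donor = int(np.argmax(counts))
            counts[donor] -= 1
            counts[k] += 1
    bounds = np.cumsum([0] + counts)
    parts = [subjects[bounds[i] : bounds[i + 1]] for i in range(3)]
    ids = [[e.recording_id for s in part for e in groups[s]] for part in parts]
    return SplitPlan(train=ids[0], validation=ids[1], test=ids[2], fractions=tuple(fractions), seed=seed)


def build_mixed_training(
    healthy_plan: SplitPlan,
    patient_roster: Roster,
    n_patient_train_recordings: int = 19,
    seed: int = 0,
    healthy_training: str = "all",
) -> SplitPlan:
    """Mixed-dataset regime: healthy training plus whole-patient recordings.

    Patient subjects are shuffled and assigned whole to training until the
    requested recording count is reached (the nearest achievable count on
    subject boundaries, with a warning if inexact). The returned plan's
    test set is the healthy test set plus all remaining patient recordings;
    the validation part carries over from the healthy plan.

    With the default ``healthy_training='all'`` every healthy recording
    enters training (54 + 19 = 73 recordings in the reference design, the
    printed study totals); note the healthy part of the evaluation set is
    then not subject-disjoint from training, so healthy-set scores are
    optimistic and the patient part carries the regime's conclusions.
    ``healthy_training='train'`` restricts to the healthy training part,
    keeping the healthy evaluation subject-disjoint.
    """
    if healthy_training not in ("all", "train"):
        raise ValueError("healthy_training must be 'all' or 'train'")
    groups = patient_roster.by_subject()
    subjects = list(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(subjects)
    train_ids: list[str] = []
    taken: set[str] = set()
    count = 0
    for s in subjects:
        k = len(groups[s])
        if abs(count + k - n_patient_train_recordings) < abs(count - n_patient_train_recordings):
            train_ids += [e.recording_id for e in groups[s]]
            taken.add(s)
            count += k
        if count >= n_patient_train_recordings:
            break
    if count != n_patient_train_recordings:
        logger.warning(
            "could not reach %d patient training recordings on subject boundaries; using %d",
            n_patient_train_recordings,
            count,
        )
    rest = [e.recording_id for s in subjects if s not in taken for e in groups[s]]
    healthy_train = (
        list(healthy_plan.train) + list(healthy_plan.validation) + list(healthy_plan.test)
        if healthy_training == "all"
        else list(healthy_plan.train)
    )
    return SplitPlan(
        train=healthy_train + train_ids,
        validation=[] if healthy_training == "all" else list(healthy_plan.validation),
        test=list(healthy_plan.test) + rest,
        fractions=healthy_plan.fractions,
        seed=seed,
        allow_overlap=healthy_training == "all",
    )


# ---------------------------------------------------------------------------
# Experiment runner
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one training-and-evaluation run."""

    method: str = "rf+hmm"  # rf | rf+mf | rf+hmm | lstm:<units><u|b> | cnnlstm:<plain|residual>
    seed: int = 0
    n_subjects: int = 12
    recordings_per_subject: int = 1
    profile_name: str = "healthy"
    duration_min: Optional[float] = None
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    n_trees: int = 500
    n_iterations: int = 50
    batches_per_iteration: int = 100
    batch_size: int = 32
    sequence_len: int = 8
    width_multiplier: float = 1.0
    out_dir: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)

    def manifest_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    reports: dict[str, AgreementReport]
    predictions: dict[str, list[str]]
    manifest: dict

    @property
    def aggregates(self):
        return aggregate(list(self.reports.values()))


def _parse_method(method: str, cfg: ExperimentConfig):
    if method in ("rf", "rf+mf", "rf+hmm"):
        return ("rf", method)
    if method.startswith("lstm:"):
        spec = method.split(":", 1)[1]
        units = int(spec[:-1])
        bidirectional = spec.endswith("b")
        return (
            "lstm",
            LSTMConfig(units_per_layer=units, bidirectional=bidirectional, sequence_len=cfg.sequence_len),
        )
    if method.startswith("cnnlstm:"):
        kind = method.split(":", 1)[1]
        return (
            "cnnlstm",
            CNNLSTMConfig(conv_block=kind, sequence_len=cfg.sequence_len, width_multiplier=cfg.width_multiplier),
        )
    raise ValueError(f"unknown method {method!r}")


def run_experiment(config: ExperimentConfig, roster: Optional[Roster] = None) -> ExperimentResult:
    """Generate (or take) a roster, split, train, predict, smooth, evaluate.

    Returns per-test-recording agreement reports plus a manifest carrying
    the config hash, seed and package versions. Identical config and seed
    produce identical reports.
    """
    kind, method_cfg = _parse_method(config.method, config)
    if roster is None:
        logger.info("generating synthetic dataset: %d subjects x %d (%s)", config.n_subjects, config.recordings_per_subject, config.profile_name)
        roster = Roster.from_dataset(
            generate_dataset(
                config.n_subjects,
                config.recordings_per_subject,
                config.profile_name,
                seed=config.seed,
                duration_min=config.duration_min,
            )
        )
    plan = split_by_subject(roster, config.fractions, seed=config.seed)
    train_entries = [roster.get(i) for i in plan.train]
    val_entries = [roster.get(i) for i in plan.validation]
    test_entries = [roster.get(i) for i in plan.test]

    predictions: dict[str, list[str]] = {}
    if kind == "rf":
        feats = {e.recording_id: extract_features(e.recording, e.hypnogram.epoch_len_s) for e in roster.entries}
        import numpy as _np

        train_X = _np.concatenate([feats[e.recording_id].values for e in train_entries])
        train_y = [s for e in train_entries for s in e.hypnogram.stages]
        from .features import FEATURE_NAMES, FeatureMatrix

        fm = FeatureMatrix(train_X, FEATURE_NAMES, train_entries[0].hypnogram.epoch_len_s)
        model = train_rf(fm, train_y, n_trees=config.n_trees, seed=config.seed)
        tm = estimate_transition_model([e.hypnogram for e in train_entries])
        for e in test_entries:
            post = predict_proba(model, feats[e.recording_id])
            if method_cfg == "rf+hmm":
                stages = viterbi_smooth(post, tm)
            elif method_cfg == "rf+mf":
                stages = median_smooth(post.argmax_stages())
            else:
                stages = post.argmax_stages()
            predictions[e.recording_id] = stages
    else:
        if kind == "lstm":
            model = build_feature_lstm(method_cfg, seed=config.seed)
            make = lambda e: make_feature_data(e.recording, e.hypnogram, method_cfg.input_kind)
        else:
            model = build_cnn_lstm(method_cfg, seed=config.seed)
            make = lambda e: make_raw_data(e.recording, e.hypnogram)
        train_data = [make(e) for e in train_entries]
        val_data = [make(e) for e in val_entries] or train_data
        model, curves = train_network(
            model,
            train_data,
            val_data,
            n_iterations=config.n_iterations,
            seed=config.seed,
            batches_per_iteration=config.batches_per_iteration,
            batch_size=config.batch_size,
        )
        for e in test_entries:
            stages, _ = predict_stages(model, make(e))
            predictions[e.recording_id] = stages

    reports = {
        e.recording_id: agreement_report(e.hypnogram.stages[: len(predictions[e.recording_id])], predictions[e.recording_id])
        for e in test_entries
    }
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.manifest_hash(),
        "seed": config.seed,
        "somnostage_version": __version__,
        "numpy_version": np.__version__,
        "split": {"train": plan.train, "validation": plan.validation, "test": plan.test},
    }
    result = ExperimentResult(config=config, reports=reports, predictions=predictions, manifest=manifest)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (out / "reports.json").write_text(
            json.dumps({k: r.to_dict() for k, r in reports.items()}, indent=2)
        )
        from .io_preproc import write_hypnogram_csv

        for e in test_entries:
            hyp = Hypnogram(predictions[e.recording_id], e.hypnogram.epoch_len_s)
            write_hypnogram_csv(hyp, out / f"{e.recording_id}_predicted.csv")
    return result


def transition_counts(result: ExperimentResult) -> dict[str, int]:
    """Stage-transition counts of each predicted test hypnogram."""
    return {rid: n_stage_transitions(stages) for rid, stages in result.predictions.items()}
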