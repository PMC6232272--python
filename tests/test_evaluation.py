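"""Agreement metric tests: kappa formula, exclusion rules, aggregation."""

from __future__ import annotations

import numpy as np
import pytest

from somnostage.core import STAGES
from somnostage.evaluation import (
    AgreementReport,
    ConfusionMatrix,
    agreement_report,
    aggregate,
    cohen_kappa,
    confusion,
    f1_per_class,
    per_stage_kappa,
)


class TestConfusion:
    def test_identical_sequences_are_diagonal(self):
        seq = ["W", "N1", "N2", "N3", "R", "N2"]
        cm = confusion(seq, seq)
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))
        assert cm.total == 6

    def test_direct_counts(self):
        cm = confusion(["W", "W", "N1"], ["W", "N1", "N1"])
        assert cm.counts[0, 0] == 1 and cm.counts[0, 1] == 1 and cm.counts[1, 1] == 1

    def test_row_sums_are_reference_counts(self):
        ref = ["W", "W", "N2", "R", "R", "R"]
        cm = confusion(ref, ["N1"] * 6)
        assert cm.counts.sum(axis=1).tolist() == [2, 0, 1, 0, 3]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(["W"], ["W", "N1"])


class TestCohenKappa:
    def test_perfect_agreement(self):
        seq = ["W", "N1", "N2", "R"] * 3
        assert cohen_kappa(confusion(seq, seq)) == 1.0

    def test_two_class_hand_example(self):
        """p_o = 0.8, p_e = 0.5 -> kappa = 0.6."""
        cm = np.zeros((5, 5), dtype=np.int64)
        cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1] = 45, 5, 15, 35
        assert cohen_kappa(ConfusionMatrix(cm)) == pytest.approx(0.6)

    def test_constant_rater_gives_zero(self):
        assert cohen_kappa(confusion(["W"] * 10, ["W", "N1"] * 5)) == pytest.approx(0.0)

    def test_permutation_invariance(self, rng):
        ref = [STAGES[i] for i in rng.integers(0, 5, 100)]
        pred = [STAGES[i] for i in rng.integers(0, 5, 100)]
        perm = {a: b for a, b in zip(STAGES, np.roll(STAGES, 2))}
        k1 = cohen_kappa(confusion(ref, pred))
        k2 = cohen_kappa(confusion([perm[s] for s in ref], [perm[s] for s in pred]))
        assert k1 == pytest.approx(k2)

    def test_shuffled_labels_centre_on_zero(self, rng):
        ref = [STAGES[i] for i in rng.integers(0, 5, 300)]
        pred = np.array(ref)
        kappas = []
        for _ in range(1000):
            rng.shuffle(pred)
            kappas.append(cohen_kappa(confusion(ref, list(pred))))
        assert abs(np.mean(kappas)) < 0.02

    def test_observed_agreement_reconstructs_from_kappa(self, rng):
        ref = [STAGES[i] for i in rng.integers(0, 5, 200)]
        pred = [STAGES[i] for i in rng.integers(0, 5, 200)]
        cm = confusion(ref, pred)
        k = cohen_kappa(cm)
        p_o = np.trace(cm.counts) / cm.total
        p_e = float((cm.counts.sum(1) * cm.counts.sum(0)).sum()) / cm.total**2
        assert k * (1 - p_e) + p_e == pytest.approx(p_o)


class TestKappaProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    pairs = st.lists(
        st.tuples(st.sampled_from(STAGES), st.sampled_from(STAGES)), min_size=1, max_size=80
    )

    @given(pairs)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_kappa_at_most_one_and_label_permutation_invariant(self, pairs):
        ref = [a for a, _ in pairs]
        pred = [b for _, b in pairs]
        k = cohen_kappa(confusion(ref, pred))
        assert k <= 1.0 + 1e-12
        perm = dict(zip(STAGES, np.roll(STAGES, 1)))
        k2 = cohen_kappa(confusion([perm[s] for s in ref], [perm[s] for s in pred]))
        assert k == pytest.approx(k2)


class TestPerStageKappa:
    def test_identical_all_stage_sequences(self):
        seq = ["W", "N1", "N2", "N3", "R"] * 2
        assert all(v == 1.0 for v in per_stage_kappa(seq, seq).values())

    def test_absent_reference_stage_flagged_undefined(self):
        """A recording that never reaches N3 leaves kappa_N3 undefined."""
        ref = ["W", "N1", "N2", "R"] * 3
        out = per_stage_kappa(ref, ref)
        assert out["N3"] is None
        assert out["W"] == 1.0

    def test_rem_binarization_hand_example(self):
        out = per_stage_kappa(["W", "W", "R", "R"], ["W", "R", "R", "R"])
        assert out["R"] == pytest.approx(0.5)


class TestF1:
    def test_perfect_agreement(self):
        seq = ["W", "N1", "N2", "N3", "R"]
        assert all(v == 1.0 for v in f1_per_class(confusion(seq, seq)).values())

    def test_absent_in_both_flagged(self):
        out = f1_per_class(confusion(["W", "N1"], ["W", "N1"]))
        assert out["N3"] is None

    def test_two_class_hand_example(self):
        """precision 35/40, recall 35/50 -> F1 ~ 0.778."""
        cm = np.zeros((5, 5), dtype=np.int64)
        cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1] = 45, 5, 15, 35
        out = f1_per_class(ConfusionMatrix(cm))
        assert out["N1"] == pytest.approx(2 * (0.875 * 0.7) / 1.575, abs=1e-3)


class TestAggregate:
    def _report(self, kappas):
        seq = ["W", "N1", "N2", "N3", "R"]
        rep = agreement_report(seq, seq)
        rep.per_stage_kappa = dict(zip(STAGES, kappas))
        return rep

    def test_single_report_mean_no_sd(self):
        agg = aggregate([self._report([0.8, 0.4, 0.7, 0.9, 0.85])])
        assert agg["W"].mean == pytest.approx(0.8)
        assert agg["W"].sd is None

    def test_two_reports_sample_sd(self):
        agg = aggregate([self._report([0.8] * 5), self._report([0.6] * 5)])
        assert agg["W"].mean == pytest.approx(0.7)
        assert agg["W"].sd == pytest.approx(0.1414, abs=1e-4)

    def test_undefined_entries_excluded(self):
        a = self._report([0.8, 0.4, 0.7, None, 0.85])
        b = self._report([0.6, 0.5, 0.9, 0.9, 0.75])
        agg = aggregate([a, b])
        assert agg["N3"].mean == pytest.approx(0.9)
        assert agg["N3"].n_excluded == 1
        assert agg["W"].n_included == 2

    def test_stage_undefined_everywhere_flagged(self):
        agg = aggregate([self._report([0.8, 0.4, 0.7, None, 0.85])])
        assert agg["N3"].mean is None


class TestReport:
    def test_report_roundtrip_fields(self, tmp_path):
        rep = agreement_report(["W", "N1", "N2"], ["W", "N1", "N1"])
        rep.to_json(tmp_path / "r.json")
        import json

        back = json.loads((tmp_path / "r.json").read_text())
        assert back["n_epochs"] == 3
        assert back["accuracy"] == pytest.approx(2 / 3)
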