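import itertools

import numpy as np
import pytest

from ppsn.cohort import MarkerPanel, PatientRecord
from ppsn.roc import HIGH_ABNORMAL, LOW_ABNORMAL, CutoffSpec, RocError
from ppsn.score import (
    PANEL_DEFINITION,
    MissingScoreError,
    PanelCutoffs,
    classify,
    derive_panel_cutoffs,
    derive_score_threshold,
    score_patient,
)
from ppsn.synth import generate, paper_calibrated_config


def fixed_cutoffs():
    """Unit-valued panel: every marker dichotomized at 0.5 in its direction."""
    specs = tuple(
        CutoffSpec(marker=m, timepoint=tp, cutoff=0.5, direction=d,
                   youden_j=0.5, auc=0.7, auc_p=0.01)
        for tp, m, d in PANEL_DEFINITION
    )
    return PanelCutoffs(cutoffs=specs)


def record_from_pattern(pattern):
    """Build a patient whose j-th marker is abnormal iff pattern[j]."""
    vals = {}
    for bit, (tp, m, d) in zip(pattern, PANEL_DEFINITION):
        abnormal = bool(bit)
        v = (1.0 if abnormal else 0.0) if d == HIGH_ABNORMAL else (0.0 if abnormal else 1.0)
        vals[(tp, m)] = v
    def panel(tp):
        names = [m for t, m, _ in PANEL_DEFINITION if t == tp]
        kwargs = {m: vals[(tp, m)] for m in names}
        if tp == "pre":
            kwargs["platelet_count"] = 20.0  # stored but never scored
        return MarkerPanel(**kwargs)
    return PatientRecord(patient_id="X", pre=panel("pre"), post=panel("post"))


class TestPanelStructure:
    def test_exactly_seven_fixed_triples(self):
        assert len(PANEL_DEFINITION) == 7
        assert sum(d == HIGH_ABNORMAL for _, _, d in PANEL_DEFINITION) == 2
        # platelet only enters post-treatment
        assert ("pre", "platelet_count", LOW_ABNORMAL) not in PANEL_DEFINITION
        assert ("post", "platelet_count", LOW_ABNORMAL) in PANEL_DEFINITION

    def test_wrong_triples_rejected(self):
        specs = list(fixed_cutoffs().cutoffs)
        specs[0], specs[1] = specs[1], specs[0]
        with pytest.raises(ValueError):
            PanelCutoffs(cutoffs=tuple(specs))


class TestScorePatient:
    def test_all_abnormal_scores_seven(self):
        r = record_from_pattern([1] * 7)
        assert score_patient(r, fixed_cutoffs()).score == 7

    def test_all_normal_scores_zero(self):
        r = record_from_pattern([0] * 7)
        assert score_patient(r, fixed_cutoffs()).score == 0

    def test_single_abnormal_marker(self):
        r = record_from_pattern([1, 0, 0, 0, 0, 0, 0])
        res = score_patient(r, fixed_cutoffs())
        assert res.score == 1 and res.n_markers_available == 7

    def test_every_pattern_sums_indicators(self):
        """Brute force over all 2^7 abnormality patterns: the score is the
        indicator sum and every value 0..7 is achieved."""
        seen = set()
        for pattern in itertools.product([0, 1], repeat=7):
            res = score_patient(record_from_pattern(pattern), fixed_cutoffs())
            assert res.score == sum(pattern)
            seen.add(res.score)
        assert seen == set(range(8))

    def test_missing_panel_decrements_availability(self):
        r = record_from_pattern([1] * 7)
        r = PatientRecord(patient_id="X", pre=None, post=r.post)
        res = score_patient(r, fixed_cutoffs())
        assert res.n_markers_available == 4
        assert res.score == 4  # the four post markers are abnormal

    def test_all_missing_raises(self):
        r = PatientRecord(patient_id="X")
        with pytest.raises(MissingScoreError):
            score_patient(r, fixed_cutoffs())

    def test_monotone_in_single_marker(self):
        base = record_from_pattern([0, 1, 0, 1, 0, 1, 0])
        worse = record_from_pattern([1, 1, 0, 1, 0, 1, 0])
        cuts = fixed_cutoffs()
        assert score_patient(worse, cuts).score >= score_patient(base, cuts).score

    def test_boundary_value_counts_abnormal(self):
        # inclusive rule: value exactly at the cutoff is abnormal
        cuts = fixed_cutoffs()
        pre = MarkerPanel(neutrophil_pct=0.5, lymphocyte_pct=1.0,
                          lymphocyte_count=1.0, platelet_count=1.0)
        post = MarkerPanel(neutrophil_pct=0.0, lymphocyte_pct=1.0,
                           lymphocyte_count=1.0, platelet_count=1.0)
        r = PatientRecord(patient_id="B", pre=pre, post=post)
        assert score_patient(r, cuts).score == 1


class TestDeriveCutoffs:
    def test_recovers_generative_truth_in_separable_regime(self):
        """When classes separate cleanly at the true thresholds, the median
        Youden cutoff over replicates lands within one inter-observation gap
        of the generative truth for every marker."""
        from tests.conftest import separable_config

        recovered = {j: [] for j in range(7)}
        gaps = {j: [] for j in range(7)}
        for seed in range(40):
            config = separable_config(seed)
            cohort = generate(config)
            cuts = derive_panel_cutoffs(cohort)
            for j, (spec, m) in enumerate(zip(cuts.cutoffs, config.markers)):
                vals = np.sort(
                    [v for v in cohort.marker_values(m.timepoint, m.name) if v is not None]
                )
                i = int(np.searchsorted(vals, m.cutoff))
                gap = max(vals[min(i, vals.size - 1)] - vals[max(i - 1, 0)], 0.01)
                recovered[j].append(spec.cutoff)
                gaps[j].append(gap)
        config = separable_config(0)
        for j, m in enumerate(config.markers):
            err = abs(float(np.median(recovered[j])) - m.cutoff)
            assert err <= float(np.median(gaps[j])), (m.timepoint, m.name, err)

    def test_null_marker_auc_near_half(self, rng):
        # a marker independent of the outcome carries no signal
        config = paper_calibrated_config(seed=3).model_copy(
            update={"latent_effect": 0.0, "n": 600, "missing_pre_fraction": 0.0}
        )
        cohort = generate(config)
        cuts = derive_panel_cutoffs(cohort)
        for spec in cuts.cutoffs:
            assert abs(spec.auc - 0.5) < 0.08

    def test_structure_contract(self, calibrated_cohort):
        cuts = derive_panel_cutoffs(calibrated_cohort)
        assert tuple((c.timepoint, c.marker, c.direction) for c in cuts.cutoffs) == PANEL_DEFINITION
        assert all(c.auc >= 0.0 for c in cuts.cutoffs)
        assert len(cuts.n_used) == 7

    def test_single_class_names_marker(self, calibrated_cohort):
        with pytest.raises(RocError, match="neutrophil_pct"):
            derive_panel_cutoffs(calibrated_cohort, [True] * len(calibrated_cohort))


class TestScoreThreshold:
    def test_separated_scores_threshold_four(self):
        scores = [0, 1, 2, 3, 4, 5, 6, 7]
        outcome = [False] * 4 + [True] * 4
        th = derive_score_threshold(scores, outcome)
        assert th.threshold == 4 and th.youden_j == 1.0

    def test_uninformative_scores_j_zero(self):
        scores = [1, 2, 3, 1, 2, 3]
        outcome = [True, True, True, False, False, False]
        th = derive_score_threshold(scores, outcome)
        assert th.youden_j == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_distribution_raises(self):
        with pytest.raises(ValueError):
            derive_score_threshold([4, 4, 4, 4], [True, False, True, False])


class TestClassify:
    @pytest.mark.parametrize("score, threshold, expected", [
        (4, 4, "high"),
        (3, 4, "low"),
        (0, 1, "low"),
        (7, 4, "high"),
    ])
    def test_high_iff_score_reaches_threshold(self, score, threshold, expected):
        from ppsn.score import PpsnResult
        res = PpsnResult(patient_id="X", score=score, n_markers_available=7)
        assert classify(res, threshold) == expected
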