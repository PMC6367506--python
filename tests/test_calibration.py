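"""CPT fitting from labelled samples, freezing and threshold recalibration."""

import numpy as np
import pytest

from pathscore import (
    CalibrationError,
    CalibrationSet,
    EvidenceVector,
    FrozenModelError,
    GeneEvidenceRecord,
    PathwayModel,
    ProbesetNode,
    Sample,
    TargetGeneNode,
    evidence_from_intensities,
    fit_probeset_cpts,
    freeze,
    infer_activity,
    make_example_model,
    rank_candidate_genes,
    recalibrate_threshold,
    set_discretization_thresholds,
    simulate_dataset,
    SimulationConfig,
)


def _sample(sid, value, ps="PS1"):
    return Sample(sid, {ps: value})


def _calib(high_ids, low_ids, ps="PS1", high_value=2000.0, low_value=50.0,
           active_ids=None):
    """Samples with a controllable high/low intensity; labels from active_ids."""
    samples = [_sample(s, high_value, ps) for s in high_ids]
    samples += [_sample(s, low_value, ps) for s in low_ids]
    active_ids = set(active_ids if active_ids is not None else high_ids)
    labels = {s.sample_id: ("active" if s.sample_id in active_ids else "inactive")
              for s in samples}
    return CalibrationSet(samples=samples, labels=labels)


@pytest.fixture
def skeleton():
    return PathwayModel(
        "SKEL",
        [
            TargetGeneNode(
                "G1",
                [ProbesetNode("PS1", log2_threshold=8.0)],
                p_up_given_active=0.9,
                p_up_given_inactive=0.1,
            )
        ],
    )


class TestFitProbesetCpts:
    def test_laplace_count_formula(self, skeleton):
        # 10 active samples, probeset high in 9 -> (9+1)/(10+2)
        active = [f"a{i}" for i in range(10)]
        samples = [_sample(s, 2000.0) for s in active[:9]] + [_sample(active[9], 50.0)]
        samples += [_sample("i1", 50.0), _sample("i2", 50.0)]
        labels = {s.sample_id: ("active" if s.sample_id.startswith("a") else "inactive")
                  for s in samples}
        calib = CalibrationSet(samples=samples, labels=labels)
        fitted = fit_probeset_cpts(skeleton, calib, pseudocount=1.0)
        assert fitted.probeset("PS1").p_high_given_up == pytest.approx(10 / 12)
        assert fitted.probeset("PS1").p_high_given_down == pytest.approx(1 / 4)

    def test_down_regulated_gene_swaps_class_to_state_mapping(self):
        skeleton = PathwayModel(
            "SKEL",
            [
                TargetGeneNode(
                    "G1",
                    [ProbesetNode("PS1", log2_threshold=8.0)],
                    direction="down_regulated",
                    p_up_given_active=0.1,
                    p_up_given_inactive=0.9,
                )
            ],
        )
        # active samples are low (the gene is down when the pathway is active)
        calib = _calib(high_ids=["i1", "i2"], low_ids=["a1", "a2"], active_ids=["a1", "a2"])
        fitted = fit_probeset_cpts(skeleton, calib, pseudocount=1.0)
        # up state <- inactive samples (high): 2 of 2 high
        assert fitted.probeset("PS1").p_high_given_up == pytest.approx(3 / 4)
        assert fitted.probeset("PS1").p_high_given_down == pytest.approx(1 / 4)

    def test_symmetric_counts_make_probeset_uninformative(self, skeleton):
        calib = _calib(high_ids=["a1", "a2", "i1", "i2"], low_ids=[],
                       active_ids=["a1", "a2"])
        fitted = fit_probeset_cpts(skeleton, calib, pseudocount=1.0)
        ps = fitted.probeset("PS1")
        assert ps.p_high_given_up == ps.p_high_given_down == pytest.approx(3 / 4)
        # likelihood ratio 1 -> posterior stays at the prior
        r = infer_activity(fitted, EvidenceVector({"PS1": 1.0}))
        assert r.probability_active == pytest.approx(fitted.prior_active, abs=1e-12)

    def test_large_pseudocount_shrinks_to_half(self, skeleton):
        calib = _calib(high_ids=["a1"], low_ids=["i1"])
        fitted = fit_probeset_cpts(skeleton, calib, pseudocount=1e9)
        assert fitted.probeset("PS1").p_high_given_up == pytest.approx(0.5, abs=1e-6)
        assert fitted.probeset("PS1").p_high_given_down == pytest.approx(0.5, abs=1e-6)

    def test_probabilities_strictly_inside_unit_interval(self, skeleton):
        calib = _calib(high_ids=["a1", "a2"], low_ids=["i1", "i2"])
        fitted = fit_probeset_cpts(skeleton, calib, pseudocount=0.5)
        for ps in [fitted.probeset("PS1")]:
            assert 0.0 < ps.p_high_given_down < ps.p_high_given_up < 1.0

    def test_sample_order_invariance(self, skeleton):
        rng = np.random.default_rng(3)
        samples = [
            _sample(f"s{i}", float(rng.uniform(10, 5000))) for i in range(12)
        ]
        labels = {f"s{i}": ("active" if i % 2 else "inactive") for i in range(12)}
        calib_fwd = CalibrationSet(samples=samples, labels=labels)
        calib_rev = CalibrationSet(samples=samples[::-1], labels=labels)
        f1 = fit_probeset_cpts(skeleton, calib_fwd)
        f2 = fit_probeset_cpts(skeleton, calib_rev)
        assert f1.probeset("PS1").p_high_given_up == f2.probeset("PS1").p_high_given_up
        assert f1.probeset("PS1").p_high_given_down == f2.probeset("PS1").p_high_given_down

    def test_frozen_skeleton_rejected(self, skeleton):
        calib = _calib(high_ids=["a1"], low_ids=["i1"])
        with pytest.raises(FrozenModelError):
            fit_probeset_cpts(freeze(skeleton), calib)

    def test_probeset_absent_everywhere_rejected_by_name(self, skeleton):
        samples = [Sample("a1", {"OTHER": 5.0}), Sample("i1", {"OTHER": 5.0})]
        calib = CalibrationSet(samples=samples, labels={"a1": "active", "i1": "inactive"})
        with pytest.raises(CalibrationError, match="PS1"):
            fit_probeset_cpts(skeleton, calib)

    def test_single_class_rejected(self):
        samples = [_sample("a1", 10.0), _sample("a2", 10.0)]
        with pytest.raises(CalibrationError, match="class"):
            CalibrationSet(samples=samples, labels={"a1": "active", "a2": "active"})


class TestDiscretizationThresholds:
    def test_midpoint_of_class_medians(self, skeleton):
        # single sample per class at intensities 3 and 15:
        # (log2(4) + log2(16)) / 2 = 3.0
        calib = _calib(high_ids=["a1"], low_ids=["i1"], high_value=15.0, low_value=3.0)
        out = set_discretization_thresholds(skeleton, calib)
        assert out.probeset("PS1").log2_threshold == pytest.approx(3.0, abs=1e-12)

    def test_identical_class_medians_leave_common_median(self, skeleton):
        calib = _calib(high_ids=["a1"], low_ids=["i1"], high_value=255.0, low_value=255.0)
        out = set_discretization_thresholds(skeleton, calib)
        assert out.probeset("PS1").log2_threshold == pytest.approx(8.0)

    def test_skeleton_not_mutated(self, skeleton):
        calib = _calib(high_ids=["a1"], low_ids=["i1"])
        set_discretization_thresholds(skeleton, calib)
        assert skeleton.probeset("PS1").log2_threshold == 8.0


class TestFreeze:
    def test_probability_edits_rejected_after_freeze(self, skeleton):
        frozen = freeze(skeleton)
        with pytest.raises(FrozenModelError):
            frozen.set_probeset_cpt("PS1", p_high_given_up=0.7)
        with pytest.raises(FrozenModelError):
            frozen.set_gene_cpt("G1", p_up_given_active=0.8)
        with pytest.raises(FrozenModelError):
            frozen.set_prior(0.4)

    def test_thresholds_may_still_be_added(self, skeleton):
        frozen = freeze(skeleton)
        frozen.set_threshold("brain", 5.0)  # re-thresholding keeps the model
        assert frozen.thresholds["brain"] == 5.0

    def test_freeze_is_idempotent(self, skeleton):
        once = freeze(skeleton)
        twice = freeze(once)
        assert twice.frozen and twice == once


class TestRecalibrateThreshold:
    def test_separable_groups_midpoint(self):
        t = recalibrate_threshold([-3, -2, 4, 5], ["inactive", "inactive", "active", "active"])
        assert t == pytest.approx(1.0)

    def test_symmetric_perfect_separation_prefers_zero(self):
        t = recalibrate_threshold([-2, -1, 1, 2], ["inactive", "inactive", "active", "active"])
        assert t == 0.0

    def test_objective_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for objective in ("accuracy", "youden"):
            for _ in range(25):
                n = int(rng.integers(4, 12))
                scores = list(np.round(rng.normal(0, 3, size=n), 2))
                labels = ["active" if rng.random() < 0.5 else "inactive" for _ in range(n)]
                if len(set(labels)) < 2:
                    labels[0], labels[1] = "active", "inactive"
                t = recalibrate_threshold(scores, labels, objective)

                def value(th):
                    tp = sum(s > th for s, l in zip(scores, labels) if l == "active")
                    tn = sum(s <= th for s, l in zip(scores, labels) if l == "inactive")
                    na = labels.count("active")
                    ni = labels.count("inactive")
                    if objective == "accuracy":
                        return (tp + tn) / n
                    return tp / na + tn / ni - 1.0

                # exhaustive scan over a fine grid spanning the scores
                grid = np.linspace(min(scores) - 1, max(scores) + 1, 4001)
                assert value(t) == pytest.approx(max(value(g) for g in grid), abs=1e-12)

    def test_interleaved_classes_reach_majority_accuracy(self):
        scores = [0, 1, 2, 3, 4, 5]
        labels = ["active", "inactive"] * 3
        t = recalibrate_threshold(scores, labels, "accuracy")
        accuracy = sum(
            (s > t) == (l == "active") for s, l in zip(scores, labels)
        ) / len(scores)
        assert accuracy >= 0.5

    def test_single_class_rejected(self):
        with pytest.raises(CalibrationError):
            recalibrate_threshold([1, 2], ["active", "active"])


class TestRankCandidateGenes:
    def test_unit_weights_sum_components(self):
        record = GeneEvidenceRecord(
            "GLI1",
            {c: 1.0 for c in (
                "response_element_motif",
                "promoter_functionality",
                "tf_binding_in_vivo",
                "tf_binding_in_vitro",
                "differential_expression",
            )},
        )
        ranked = rank_candidate_genes([record], corroboration_bonus=0.0)
        assert ranked == [("GLI1", 5.0)]

    def test_zero_weights_alphabetical(self):
        records = [
            GeneEvidenceRecord("PTCH1", {"tf_binding_in_vivo": 3.0}),
            GeneEvidenceRecord("BCL2", {"tf_binding_in_vivo": 1.0}),
        ]
        ranked = rank_candidate_genes(
            records, weights={"tf_binding_in_vivo": 0.0}, corroboration_bonus=0.0
        )
        assert [g for g, _ in ranked] == ["BCL2", "PTCH1"]
        assert all(t == 0.0 for _, t in ranked)

    def test_corroboration_breaks_equal_components(self):
        a = GeneEvidenceRecord("A", {"differential_expression": 2.0}, n_groups=1)
        b = GeneEvidenceRecord("B", {"differential_expression": 2.0}, n_groups=3)
        ranked = rank_candidate_genes([a, b])
        assert [g for g, _ in ranked] == ["B", "A"]

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            rank_candidate_genes(
                [GeneEvidenceRecord("A", {"differential_expression": 1.0})],
                weights={"differential_expression": -1.0},
            )


class TestCalibrationSeparatesClasses:
    def test_calibrated_model_separates_simulated_classes(self):
        truth = make_example_model()
        matrix, calib = simulate_dataset(
            truth, SimulationConfig(n_active=30, n_inactive=30, seed=9)
        )
        skeleton = make_example_model()
        fitted = freeze(
            fit_probeset_cpts(set_discretization_thresholds(skeleton, calib), calib)
        )
        scores = {"active": [], "inactive": []}
        for sample in matrix.samples:
            ev = evidence_from_intensities(fitted, sample.intensities)
            scores[calib.labels[sample.sample_id]].append(
                infer_activity(fitted, ev).log2odds
            )
        assert np.mean(scores["active"]) > np.mean(scores["inactive"])
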