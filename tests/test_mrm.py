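import numpy as np
import pytest
from scipy.stats import spearmanr

from immunopep.mrm import (
    LibrarySpectrum,
    TransitionMeasurement,
    relative_abundance,
    spectral_dot_product,
    validate_detections,
)
from immunopep.pipeline import example_mrm_spec
from immunopep.simulate import simulate_mrm, transitions_from_frame


LIB = LibrarySpectrum("PEP", {"y3": 81.0, "y4": 36.0, "y5": 9.0})


class TestSpectralDotProduct:
    def test_identical_spectra_give_one(self):
        assert spectral_dot_product(LIB.intensities, LIB) == pytest.approx(1.0)

    def test_uniform_scaling_invariance_and_symmetry(self):
        obs = {"y3": 810.0, "y4": 360.0, "y5": 90.0}
        assert spectral_dot_product(obs, LIB) == pytest.approx(1.0)
        a = {"y3": 100.0, "y4": 25.0, "y5": 4.0}
        assert spectral_dot_product(a, LIB) == pytest.approx(
            spectral_dot_product(LIB.intensities, LibrarySpectrum("PEP", a))
        )

    def test_hand_evaluated_value(self):
        # sqrt areas (10,5,2) vs (9,6,3): 126 / (sqrt(129)*sqrt(126)) = 0.988
        obs = {"y3": 100.0, "y4": 25.0, "y5": 4.0}
        assert spectral_dot_product(obs, LIB) == pytest.approx(0.9883, abs=1e-3)

    def test_disjoint_fragments_need_two_shared(self):
        with pytest.raises(ValueError, match="shared"):
            spectral_dot_product({"b2": 10.0, "b3": 5.0}, LIB)

    def test_partial_overlap_padded_with_zeros(self):
        obs = {"y3": 81.0, "y4": 36.0, "b2": 50.0}
        assert spectral_dot_product(obs, LIB) < 1.0


def transitions(pep, exp, rt, areas, triggered=False):
    return [
        TransitionMeasurement(pep, f"y{k+3}", exp, rt + off, area, triggered)
        for k, (off, area) in enumerate(areas)
    ]


class TestValidateDetections:
    def lib(self):
        return {"PEPA": LibrarySpectrum("PEPA", {"y3": 100.0, "y4": 50.0, "y5": 25.0, "y6": 10.0})}

    def base(self, exp, rt, scale=1.0, triggered=False, distort=None):
        # per-transition RT offsets sum to zero so the group mean RT equals rt
        areas = [(0.0, 100.0 * scale), (0.05, 50.0 * scale), (-0.05, 25.0 * scale), (0.0, 10.0 * scale)]
        if distort:
            areas = [(off, a * d) for (off, a), d in zip(areas, distort)]
        return transitions("PEPA", exp, rt, areas, triggered)

    def test_ms2_trigger_in_same_experiment_confirms(self):
        res = validate_detections(self.base("e1", 30.0, triggered=True), self.lib())
        assert res == [r for r in res if r.basis == "ms2_confirmed"] and res[0].validated

    def test_rescue_at_boundaries_inclusive_rt_strict_dotp(self):
        # confirmed anchor at RT 30; candidate at delta 1.4 min passes with
        # matching pattern; delta 1.6 fails; perfect pattern means dotp = 1 > 0.7
        trans = self.base("e1", 30.0, triggered=True) + self.base("e2", 31.4) + self.base("e3", 31.6)
        res = {r.experiment: r for r in validate_detections(trans, self.lib())}
        assert res["e2"].basis == "rt_dotp_rescued" and res["e2"].validated
        assert res["e3"].basis == "rejected" and "RT" in res["e3"].reason

    def test_rt_window_exactly_inclusive(self):
        trans = self.base("e1", 30.0, triggered=True) + self.base("e2", 31.5)
        res = {r.experiment: r for r in validate_detections(trans, self.lib())}
        assert res["e2"].rt_delta == pytest.approx(1.5)
        assert res["e2"].validated  # window is inclusive at exactly 1.5 min

    def test_good_dotp_but_far_rt_rejected(self):
        trans = self.base("e1", 30.0, triggered=True) + self.base("e2", 32.0)
        res = {r.experiment: r for r in validate_detections(trans, self.lib())}
        assert not res["e2"].validated and "RT" in res["e2"].reason

    def test_low_dotp_rejected(self):
        distorted = self.base("e2", 30.2, distort=[0.01, 1.0, 8.0, 20.0])
        trans = self.base("e1", 30.0, triggered=True) + distorted
        res = {r.experiment: r for r in validate_detections(trans, self.lib())}
        assert not res["e2"].validated and res["e2"].dotp <= 0.7

    def test_non_coeluting_transitions_rejected(self):
        bad = transitions("PEPA", "e1", 30.0, [(0.0, 100.0), (0.5, 50.0), (-0.4, 25.0), (0.1, 10.0)], True)
        res = validate_detections(bad, self.lib())
        assert res[0].basis == "rejected" and "co-elut" in res[0].reason

    def test_no_confirmed_anchor_anywhere_rejects(self):
        res = validate_detections(self.base("e1", 30.0), self.lib())
        assert not res[0].validated and "MS/MS" in res[0].reason

    def test_wrong_transition_count_raises(self):
        trans = transitions("PEPA", "e1", 30.0, [(0.0, 1.0), (0.0, 1.0)])
        with pytest.raises(ValueError, match="3-4"):
            validate_detections(trans, self.lib())


class TestRelativeAbundance:
    def test_single_detection_has_proportion_one(self):
        trans = transitions("PEPA", "e1", 30.0, [(0.0, 500.0), (0.0, 300.0), (0.0, 200.0)], True)
        lib = {"PEPA": LibrarySpectrum("PEPA", {"y3": 5.0, "y4": 3.0, "y5": 2.0})}
        det = validate_detections(trans, lib)
        rec = relative_abundance(det, trans, {"e1": 1000.0})[0]
        assert rec.normalised_abundance == pytest.approx(1.0)
        assert rec.proportion_of_max == 1.0

    def test_normalisation_removes_loading_differences(self):
        t1 = transitions("PEPA", "e1", 30.0, [(0.0, 500.0), (0.0, 300.0), (0.0, 200.0)], True)
        t2 = transitions("PEPA", "e2", 30.1, [(0.0, 250.0), (0.0, 150.0), (0.0, 100.0)], True)
        lib = {"PEPA": LibrarySpectrum("PEPA", {"y3": 5.0, "y4": 3.0, "y5": 2.0})}
        trans = t1 + t2
        det = validate_detections(trans, lib)
        recs = {r.experiment: r for r in relative_abundance(det, trans, {"e1": 2000.0, "e2": 1000.0})}
        assert recs["e1"].normalised_abundance == pytest.approx(0.5)
        assert recs["e2"].normalised_abundance == pytest.approx(0.5)
        assert recs["e1"].proportion_of_max == recs["e2"].proportion_of_max == 1.0

    def test_missing_or_nonpositive_b2m_raises(self):
        trans = transitions("PEPA", "e1", 30.0, [(0.0, 1.0), (0.0, 1.0), (0.0, 1.0)], True)
        lib = {"PEPA": LibrarySpectrum("PEPA", {"y3": 1.0, "y4": 1.0, "y5": 1.0})}
        det = validate_detections(trans, lib)
        with pytest.raises(KeyError):
            relative_abundance(det, trans, {})
        with pytest.raises(ValueError):
            relative_abundance(det, trans, {"e1": 0.0})

    def test_scale_invariance_of_proportions(self):
        spec = example_mrm_spec(3)
        sim = simulate_mrm(spec)
        trans = transitions_from_frame(sim.transitions)
        det = validate_detections(trans, sim.library)
        base = relative_abundance(det, trans, sim.norm_factors)
        exp0 = sorted(sim.norm_factors)[0]
        scaled = [
            TransitionMeasurement(t.peptide, t.fragment, t.experiment, t.rt_min,
                                  t.area * (7.0 if t.experiment == exp0 else 1.0), t.ms2_triggered)
            for t in trans
        ]
        norms = {e: (v * 7.0 if e == exp0 else v) for e, v in sim.norm_factors.items()}
        again = relative_abundance(validate_detections(scaled, sim.library), scaled, norms)
        a = {(r.peptide, r.experiment): r.proportion_of_max for r in base}
        b = {(r.peptide, r.experiment): r.proportion_of_max for r in again}
        assert a.keys() == b.keys()
        assert all(abs(a[k] - b[k]) < 1e-9 for k in a)


class TestEndToEndRecovery:
    def test_zero_noise_recovers_truth_exactly(self):
        spec = example_mrm_spec(5)
        spec.lognormal_sd = 0.0
        sim = simulate_mrm(spec)
        trans = transitions_from_frame(sim.transitions)
        recs = relative_abundance(validate_detections(trans, sim.library), trans, sim.norm_factors)
        for r in recs:
            truth = sim.truth[r.peptide][r.experiment] / max(sim.truth[r.peptide].values())
            assert r.proportion_of_max == pytest.approx(truth, abs=1e-12)

    def test_rank_correlation_above_09_at_lognormal_sd_02(self):
        spec = example_mrm_spec(5)
        assert spec.lognormal_sd == 0.2
        sim = simulate_mrm(spec)
        trans = transitions_from_frame(sim.transitions)
        recs = relative_abundance(validate_detections(trans, sim.library), trans, sim.norm_factors)
        est, truth = [], []
        for r in recs:
            est.append(r.proportion_of_max)
            truth.append(sim.truth[r.peptide][r.experiment] / max(sim.truth[r.peptide].values()))
        rho = spearmanr(est, truth).statistic
        assert rho > 0.9

    def test_never_triggered_far_rt_peptide_rejected(self):
        spec = example_mrm_spec(5)
        pep = sorted(spec.truth)[0]
        spec.never_triggered = frozenset({pep})
        spec.rt_means = {pep: 10.0}
        sim = simulate_mrm(spec)
        det = validate_detections(transitions_from_frame(sim.transitions), sim.library)
        mine = [d for d in det if d.peptide == pep]
        assert mine and all(not d.validated for d in mine)
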