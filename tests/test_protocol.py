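import dataclasses

import numpy as np
import pytest

from amygsim.circuit import CircuitState
from amygsim.params import CircuitParams, NoiseSpec
from amygsim.plasticity import PlasticWeights
from amygsim.protocol import (SessionConfig, SessionResult, TrialRecord,
                              apply_condition, build_schedule, make_config,
                              reactivation_count, run_session,
                              run_sessions_batch, run_trial,
                              trials_to_acquisition, trials_to_extinction)


class TestSchedule:
    def test_default_structure(self):
        schedule = build_schedule(make_config("naive"))
        assert len(schedule) == 60
        phases = [s.phase for s in schedule]
        assert phases[:15] == ["acquisition"] * 15
        assert phases[15:25] == ["rest"] * 10
        assert phases[25:] == ["extinction"] * 35

    def test_phase_input_contract(self):
        """Context only in acquisition, mPFC only in extinction, CS in both,
        shock only in acquisition; rest trials are silent and non-plastic."""
        for spec in build_schedule(make_config("naive")):
            i = spec.inputs
            if spec.phase == "acquisition":
                assert (i.i_thal, i.i_hip, i.i_pfc, i.us) == (1.0, 1.0, 0.0, 1)
                assert spec.plasticity_on
            elif spec.phase == "rest":
                assert (i.i_thal, i.i_hip, i.i_pfc, i.us) == (0.0, 0.0, 0.0, 0)
                assert not spec.plasticity_on
            else:
                assert (i.i_thal, i.i_hip, i.i_pfc, i.us) == (1.0, 0.0, 1.0, 0)
                assert spec.plasticity_on

    def test_no_rest_concatenation(self):
        schedule = build_schedule(make_config("naive", n_rest=0))
        assert schedule[14].phase == "acquisition"
        assert schedule[15].phase == "extinction"


class TestConditions:
    def test_naive_is_calibrated_table(self):
        assert apply_condition(CircuitParams(), "naive") == CircuitParams()

    def test_acute_overlay(self):
        p = apply_condition(CircuitParams(), "acute")
        assert (p.w_ba_inhib, p.w_la_inhib, p.w_cea_inhib) == (0.25, 1.5, 2.5)
        # the shared BLA->CeAOn weight is reduced for both afferents
        assert p.w_baf_cea == p.w_la_cea == 0.4
        assert p.w_bae_cea == 0.6
        assert p.w_la_baf == 0.49  # untouched

    def test_chronic_overlay(self):
        p = apply_condition(CircuitParams(), "chronic")
        assert p.w_cea_inhib == 2.5
        assert p.dr_cea == -0.5
        assert p.w_la_baf == 0.6
        assert p.w_bae_cea == 0.98  # untouched

    def test_unknown_condition_and_key(self):
        with pytest.raises(KeyError):
            make_config("drunk")
        from amygsim.params import apply_overrides
        with pytest.raises(KeyError):
            apply_overrides(CircuitParams(), {"W_nonexistent": 1.0})


def _fake_result(u_on_by_trial, n_acq=15, n_rest=10, n_ext=35):
    config = make_config("naive")
    records = []
    for i, u_on in enumerate(u_on_by_trial):
        phase = ("acquisition" if i < n_acq
                 else "rest" if i < n_acq + n_rest else "extinction")
        records.append(TrialRecord(i, phase, 0.1, 0.1, 0.1, u_on, 0.1,
                                   u_on, 1 - u_on, PlasticWeights()))
    return SessionResult(config, tuple(records), None, None)


class TestCriteria:
    def test_acquisition_counting_convention(self):
        """Crossing on acquisition trial index 5 counts as 6 trials."""
        u_on = [0.1] * 5 + [0.7] + [0.9] * 54
        assert trials_to_acquisition(_fake_result(u_on), 0.5) == 6

    def test_acquisition_never_reached(self):
        assert trials_to_acquisition(_fake_result([0.1] * 60), 0.5) is None

    def test_extinction_elapsed_from_recall(self):
        """First crossing on global trial 33 = 8 extinction trials elapsed."""
        u_on = [0.1] * 5 + [0.9] * 20 + [0.8] * 8 + [0.05] * 27
        assert trials_to_extinction(_fake_result(u_on), 0.2) == 8

    def test_extinction_without_phase(self):
        u_on = [0.1] * 15 + [0.05] * 10
        result = _fake_result(u_on, n_ext=0)
        assert trials_to_extinction(result, 0.2) is None

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            trials_to_acquisition(_fake_result([0.1] * 60), 0.0)

    def test_reactivation_count(self):
        u_on = ([0.9] * 15 + [0.1] * 10
                + [0.8] * 3 + [0.05] + [0.1, 0.7, 0.1, 0.9] + [0.1] * 28)
        assert reactivation_count(_fake_result(u_on), 0.5) == 2


class TestRunTrial:
    def test_rest_trial_preserves_weights(self, fast_integration):
        config = make_config("naive").replace(integration=fast_integration)
        schedule = build_schedule(config)
        rest = schedule[15]
        w0 = PlasticWeights(0.5, 0.4, 0.3)
        rng = np.random.default_rng(0)
        _, w1, rec = run_trial(CircuitState(), w0, rest, config, rng)
        assert w1 == w0
        assert rec.phase == "rest"

    def test_alpha_zero_freezes_weights(self, fast_integration):
        from amygsim.params import LearningParams
        config = make_config("naive").replace(integration=fast_integration,
                                              learning=LearningParams(alpha=0.0))
        acq = build_schedule(config)[0]
        w0 = PlasticWeights(0.2, 0.2, 0.2)
        _, w1, _ = run_trial(CircuitState(), w0, acq, config,
                             np.random.default_rng(0))
        assert w1 == w0

    def test_untrained_acquisition_trial_full_surprise(self):
        """With zero weights and no noise the CeAOn readout stays at the
        baseline cascade value, so the prediction error is nearly maximal."""
        config = make_config("naive").replace(
            noise=NoiseSpec(enabled=False))
        acq = build_schedule(config)[0]
        _, _, rec = run_trial(CircuitState(), PlasticWeights(), acq, config,
                              np.random.default_rng(0))
        assert rec.readout < 0.05
        assert rec.error > 0.95


class TestRunSession:
    def test_record_count_and_bounds(self, naive_session):
        assert len(naive_session.records) == 60
        for rec in naive_session.records:
            assert 0.0 <= rec.u_on <= 1.0
            assert min(rec.weights.as_array()) >= 0.0

    def test_fear_weights_frozen_during_extinction(self, naive_session):
        """Extinction does not depress the potentiated fear afferents."""
        pre = naive_session.records[24].weights
        for rec in naive_session.phase_records("extinction"):
            assert rec.weights.w_thal_la == pre.w_thal_la
            assert rec.weights.w_hip_baf == pre.w_hip_baf

    def test_extinction_weight_only_grows_in_extinction(self, naive_session):
        for rec in naive_session.records[:25]:
            assert rec.weights.w_pfc_bae == 0.0
        ext = naive_session.phase_records("extinction")
        w = [rec.weights.w_pfc_bae for rec in ext]
        assert all(b >= a for a, b in zip(w, w[1:]))
        assert w[-1] > 0.0

    def test_fear_weights_nondecreasing_without_noise(
            self, deterministic_naive_session):
        acq = deterministic_naive_session.phase_records("acquisition")
        for name in ("w_thal_la", "w_hip_baf"):
            vals = [getattr(r.weights, name) for r in acq]
            assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_batch_matches_single_session(self, fast_integration):
        """A session embedded in a batch sees the same noise stream as the
        standalone run (numerically identical up to BLAS summation order)."""
        config = make_config("naive", seed=11).replace(integration=fast_integration)
        single = run_session(config)
        batch = run_sessions_batch(config, [11, 12])
        for a, b in zip(batch[0].records, single.records):
            assert a.phase == b.phase and a.index == b.index
            assert np.allclose(a.mean_state(), b.mean_state(), atol=1e-9)
            assert a.error == pytest.approx(b.error, abs=1e-9)
            assert np.allclose(a.weights.as_array(), b.weights.as_array(),
                               atol=1e-9)

    def test_determinism_same_seed(self, fast_integration):
        config = make_config("naive", seed=5).replace(integration=fast_integration)
        assert run_session(config).records == run_session(config).records

    def test_criteria_deterministic_without_noise(self):
        config = make_config("naive", seed=1).replace(noise=NoiseSpec(sd=0.0))
        a = run_session(config)
        b = run_session(config.replace(seed=99))  # seed irrelevant at sd=0
        assert a.trials_to_acquisition == b.trials_to_acquisition
        assert a.trials_to_extinction == b.trials_to_extinction
        assert isinstance(a.trials_to_acquisition, int)

    def test_extinction_count_independent_of_rest_length(self):
        base = make_config("naive", seed=1).replace(noise=NoiseSpec(sd=0.0))
        long_rest = run_session(base)
        short_rest = run_session(base.replace(n_rest=3))
        assert long_rest.trials_to_extinction == short_rest.trials_to_extinction


class TestConfigValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SessionConfig(n_acq=-1)

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            SessionConfig(ext_threshold=0.0)
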