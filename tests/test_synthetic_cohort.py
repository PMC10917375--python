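"""Paradigm generation and cohort ground-truth structure."""

import numpy as np
import pandas as pd
import pytest

from dcmpeb.model_core import simulate_bold
from dcmpeb.synthetic_cohort import (GO, NOGO, REPORTED_INTRINSIC, CohortSpec,
                                     ParadigmSpec, behavior_table,
                                     default_truth_template, generate_behavior,
                                     generate_cohort, generate_paradigm,
                                     synthetic_posteriors, write_events_tsv)


class TestParadigm:
    def test_trial_counts_are_exact(self, design_events):
        _, events = design_events
        per_run = events.groupby(["run", "trial_type"]).size()
        for run in (0, 1):
            assert per_run[run, "nogo"] == 36     # 6 NoGo blocks x 6 trials
            assert per_run[run, "go"] == 180      # 6x18 + 6x12

    def test_within_block_proportions(self, design_events):
        _, events = design_events
        nogo_blocks = events[events.block_type == "nogo"]
        frac = (nogo_blocks.trial_type == "nogo").groupby(
            [nogo_blocks.run, nogo_blocks.block]).mean()
        assert np.allclose(frac, 6 / 18)          # 33.3% NoGo within block
        go_blocks = events[events.block_type == "go"]
        assert (go_blocks.trial_type == "go").all()  # 100% Go

    def test_input_functions_cover_blocks(self, paradigm, design_events):
        design, _ = design_events
        on_s = design.inputs.sum(axis=1) * design.microtime_dt
        expected = paradigm.go_blocks_per_run * paradigm.block_duration_s
        assert np.allclose(on_s[:, GO], expected)
        assert np.allclose(on_s[:, NOGO], expected)

    def test_mean_centering_bounds(self, design):
        raw = design.inputs
        assert raw.min() >= 0 and raw.max() <= 1
        centered = design.centered_inputs()
        assert centered.min() >= -1 and centered.max() <= 1
        assert np.allclose(centered.mean(axis=(0, 1)), 0.0, atol=1e-12)

    def test_no_nogo_blocks_give_zero_nogo_input(self):
        spec = ParadigmSpec(n_runs=1, blocks_per_run=4, go_blocks_per_run=4,
                            nogo_blocks_per_run=0)
        design, events = generate_paradigm(spec)
        assert np.all(design.inputs[:, :, NOGO] == 0)
        assert (events.trial_type == "go").all()

    def test_same_seed_reproduces_design(self, paradigm):
        d1, e1 = generate_paradigm(paradigm)
        d2, e2 = generate_paradigm(paradigm)
        assert np.array_equal(d1.inputs, d2.inputs)
        pd.testing.assert_frame_equal(e1, e2)


class TestTruthTemplate:
    def test_reported_intrinsic_signs(self, template):
        expected = {(3, 0): -1, (2, 3): 1, (0, 1): 1,
                    (1, 0): -1, (2, 1): 1, (3, 2): 1}
        for (i, j), sign in expected.items():
            assert np.sign(template.A[i, j]) == sign, (i, j)
        assert set(expected) == set(REPORTED_INTRINSIC)

    def test_self_connection_log_signs(self, template):
        d = np.diag(template.A)
        assert d[0] < 0 and d[1] < 0 and d[3] < 0   # IFG, Cau, Thal
        assert d[2] > 0                              # GP

    def test_nogo_modulation_stronger_than_go(self, template):
        for tgt, src in [(1, 0), (3, 0)]:           # IFG->Cau, IFG->Thal
            assert template.B[NOGO, tgt, src] < template.B[GO, tgt, src] <= 0 \
                or abs(template.B[NOGO, tgt, src]) > abs(template.B[GO, tgt, src])
        assert template.B[NOGO, 1, 2] < 0 < template.B[GO, 1, 2]  # GP->Cau

    def test_driving_inputs(self, template):
        assert np.all(template.C[:, NOGO] > 0)
        assert template.C[0, GO] > 0
        assert np.allclose(template.C[1:, GO], 0.0)

    def test_template_is_dynamically_stable(self, template, short_design):
        ts = simulate_bold(template, short_design)
        assert np.all(np.isfinite(ts.values))
        assert np.abs(ts.values).max() < 20.0


class TestCohort:
    def test_pure_function_of_seed(self, short_paradigm):
        spec = CohortSpec(n_subjects=3, n_female=2, master_seed=9)
        a = generate_cohort(spec, short_paradigm)
        b = generate_cohort(spec, short_paradigm)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.timeseries.values, sb.timeseries.values)
            assert np.array_equal(sa.true_params.A, sb.true_params.A)
            assert sa.nogo_accuracy == sb.nogo_accuracy

    def test_zero_effects_give_identical_parameters(self, short_paradigm):
        spec = CohortSpec(n_subjects=3, n_female=1, subject_sd=0.0,
                          sex_effects={}, performance_slopes={},
                          master_seed=1)
        subs = generate_cohort(spec, short_paradigm)
        for s in subs[1:]:
            assert np.allclose(s.true_params.A, subs[0].true_params.A)
            assert np.allclose(s.true_params.B, subs[0].true_params.B)
            assert np.allclose(s.true_params.C, subs[0].true_params.C)

    def test_sex_effect_recovered_in_truth_at_scale(self, short_paradigm):
        # female - male difference of true A[GP, Thal] ~ configured -0.1
        spec = CohortSpec(n_subjects=120, n_female=60, subject_sd=0.05,
                          master_seed=77)
        subs = generate_cohort(spec, short_paradigm)
        vals = np.array([s.true_params.A[2, 3] for s in subs])
        female = np.array([s.sex == "F" for s in subs])
        diff = vals[female].mean() - vals[~female].mean()
        se = 0.05 * np.sqrt(1 / 60 + 1 / 60)
        assert abs(diff - (-0.1)) < 3 * se

    def test_noise_matches_requested_snr(self, short_paradigm, short_design):
        spec = CohortSpec(n_subjects=2, subject_sd=0.0, snr=2.0,
                          sex_effects={}, performance_slopes={},
                          master_seed=4)
        subs = generate_cohort(spec, short_paradigm)
        clean = simulate_bold(subs[0].true_params, short_design).values
        resid = subs[0].timeseries.values - clean
        snr = clean.std(axis=0) / resid.std(axis=0)
        assert np.all(np.abs(snr - 2.0) < 0.5)


class TestBehavior:
    def test_perfect_accuracy_means_no_errors(self, design_events, rng):
        _, events = design_events
        t = generate_behavior(events, 100.0, 100.0, rng)
        assert t.correct.all()
        go = t[t.trial_type == "go"]
        nogo = t[t.trial_type == "nogo"]
        assert (go.response == 1).all()
        assert (nogo.response == 0).all()
        assert nogo.rt_ms.isna().all()

    def test_realized_accuracy_within_binomial_error(self, design_events, rng):
        _, events = design_events
        t = generate_behavior(events, 98.47, 70.34, rng)
        go = t[t.trial_type == "go"]
        nogo = t[t.trial_type == "nogo"]
        n_go, n_nogo = len(go), len(nogo)
        assert abs(go.correct.mean() - 0.9847) < 3 * np.sqrt(0.9847 * 0.0153 / n_go)
        assert abs(nogo.correct.mean() - 0.7034) < 3 * np.sqrt(0.7034 * 0.2966 / n_nogo)

    def test_rt_mean_near_configured_value(self, rng):
        events = pd.DataFrame({"onset": np.arange(1000) * 2.0,
                               "duration": 0.0, "trial_type": "go"})
        t = generate_behavior(events, 100.0, 100.0, rng, rt_mean_ms=314.44)
        rt = t.rt_ms.dropna()
        assert abs(rt.mean() - 314.44) < 3 * rt.std() / np.sqrt(len(rt))

    def test_rt_only_for_responded_trials(self, design_events, rng):
        _, events = design_events
        t = generate_behavior(events, 90.0, 60.0, rng)
        assert t.loc[t.response == 1, "rt_ms"].notna().all()
        assert t.loc[t.response == 0, "rt_ms"].isna().all()

    def test_events_tsv_has_bids_columns(self, tmp_path, design_events, rng):
        _, events = design_events
        t = generate_behavior(events, 95.0, 70.0, rng)
        path = tmp_path / "events.tsv"
        write_events_tsv(t, path)
        back = pd.read_csv(path, sep="\t", na_values="n/a")
        assert list(back.columns)[:3] == ["onset", "duration", "trial_type"]
        assert len(back) == len(t)


class TestBehaviorTable:
    def test_one_row_per_subject_with_bounds(self, small_cohort):
        bt = behavior_table(small_cohort)
        assert len(bt) == len(small_cohort)
        assert bt.go_accuracy.between(0, 100).all()
        assert bt.nogo_accuracy.between(0, 100).all()


class TestSyntheticPosteriors:
    def test_means_center_on_truth(self, small_cohort):
        posts = synthetic_posteriors(small_cohort, error_sd=1e-9, seed=0)
        pm = posts[0].param_map
        for s, post in zip(small_cohort, posts):
            assert np.allclose(post.mean, pm.pack(s.true_params), atol=1e-6)
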