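"""OP / SA / MIX selection schemes and the RNR echo picker."""

import numpy as np
import pytest

from liverfcm import (
    InputError,
    MultiEchoStack,
    NoiseEstimationError,
    OPGrid,
    PhantomConfig,
    RNRProfile,
    compute_rnr,
    default_threshold_grid,
    generate_phantom,
    op_search,
    sa_choose,
    sa_run,
    select_te_rnr_max,
)
from tests.conftest import TE20


class TestThresholdGrid:
    def test_fifty_levels_0_to_098_step_002(self):
        grid = default_threshold_grid()
        assert len(grid) == 50
        assert grid[0] == 0.0
        assert grid[-1] == pytest.approx(0.98)
        assert np.allclose(np.diff(grid), 0.02)


class TestRNR:
    def test_direct_formula(self):
        echoes = np.zeros((3, 4, 4))
        echoes[:, 1:3, 1:3] = 10.0
        echoes[1, 1, 1] = 110.0  # echo 1 range inside ROI: 110 - 10 = 100
        stack = MultiEchoStack(echoes=echoes, te_ms=np.array([1.0, 2.0, 3.0]))
        roi = np.zeros((4, 4), bool)
        roi[1:3, 1:3] = True
        prof = compute_rnr(stack, roi, noise_estimator=5.0)
        assert prof.rnr[1] == pytest.approx(20.0)
        assert prof.rnr[0] == 0.0  # constant ROI -> zero range

    def test_zero_noise_sd_rejected(self):
        stack = MultiEchoStack(echoes=np.ones((3, 4, 4)), te_ms=np.array([1.0, 2.0, 3.0]))
        with pytest.raises(NoiseEstimationError):
            compute_rnr(stack, np.ones((4, 4), bool), noise_estimator=0.0)

    def test_argmax_and_tie_break(self):
        prof = RNRProfile(rnr=np.array([3.0, 9.0, 7.0]), noise_sd=np.ones(3), argmax_te=1)
        assert select_te_rnr_max(prof) == 1
        prof = RNRProfile(rnr=np.array([5.0, 5.0, 2.0]), noise_sd=np.ones(3), argmax_te=0)
        assert select_te_rnr_max(prof) == 0  # earliest on ties

    def test_faster_decay_selects_earlier_echo(self):
        # higher iron -> image contrast collapses sooner -> lower RNR-max TE
        def sa_te(r2):
            cfg = PhantomConfig(shape=(48, 48), parenchyma_r2star=r2, seed=5)
            st = generate_phantom(cfg)
            return select_te_rnr_max(compute_rnr(st.stack, st.roi))

        assert sa_te(900.0) < sa_te(120.0)


@pytest.fixture(scope="module")
def op_result(severe_study):
    study, _, lic = severe_study
    return study, op_search(study.stack, lic, study.roi, study.truth)


class TestOPScheme:
    def test_enumerates_1000_candidates_per_mode(self, op_result):
        _, res = op_result
        assert res.n_candidates == {"1D-FCM": 1000, "2D-FCM": 1000}
        counts = res.candidates.groupby("method").size()
        assert counts["1D-FCM"] == 1000 and counts["2D-FCM"] == 1000

    def test_best_is_grid_minimum(self, op_result):
        # exhaustive check: the reported best per mode equals the scored
        # candidate-table minimum
        _, res = op_result
        for method, best in (("1D-FCM", res.best_1d), ("2D-FCM", res.best_2d)):
            scored = res.candidates.query("method == @method").dropna(
                subset=["d_tsa_pct"])
            assert best.d_tsa_pct == pytest.approx(scored["d_tsa_pct"].min())
            assert (scored["d_tsa_pct"] >= best.d_tsa_pct - 1e-12).all()

    def test_mix_takes_better_component(self, op_result):
        _, res = op_result
        assert res.mix.d_tsa_pct == min(res.best_1d.d_tsa_pct, res.best_2d.d_tsa_pct)
        assert res.mix.selected_from in ("1D-FCM", "2D-FCM")

    def test_candidate_scores_match_direct_rescoring(self, op_result):
        # spot-check the vectorised threshold scoring against accuracy_report
        from liverfcm import accuracy_report

        study, res = op_result
        rep = accuracy_report(res.best_2d.mask, study.truth)
        assert rep.d_tsa_pct == pytest.approx(res.best_2d.d_tsa_pct, abs=1e-9)
        assert rep.tsa_vessels_pct == pytest.approx(res.best_2d.tsa_vessels_pct)

    def test_reference_required(self, severe_study):
        study, _, lic = severe_study
        with pytest.raises(InputError):
            op_search(study.stack, lic, study.roi, None)

    def test_reduced_grid_cardinality(self, severe_study):
        study, _, lic = severe_study
        grid = OPGrid(te_indices=(0, 5, 10), thresholds=np.array([0.0, 0.5]))
        res = op_search(study.stack, lic, study.roi, study.truth, grid=grid)
        assert res.n_candidates == {"1D-FCM": 6, "2D-FCM": 6}


@pytest.fixture(scope="module")
def sa_result(severe_study):
    study, _, lic = severe_study
    return study, sa_run(study.stack, lic, study.roi, reference=study.truth,
                         selection="reference-auto")


class TestSAScheme:
    def test_fifty_candidates_per_mode(self, sa_result):
        _, res = sa_result
        assert len(res.candidates_1d) == 50
        assert len(res.candidates_2d) == 50

    def test_te_fixed_at_rnr_max(self, sa_result):
        study, res = sa_result
        assert res.te_index == select_te_rnr_max(compute_rnr(study.stack, study.roi))
        assert all(o.te_index == res.te_index
                   for o in res.candidates_1d + res.candidates_2d)

    def test_auto_choice_never_beats_op(self, severe_study, op_result, sa_result):
        # SA explores a subset of the OP grid
        _, op_res = op_result
        _, sa_res = sa_result
        assert sa_res.chosen.d_tsa_pct >= op_res.mix.d_tsa_pct - 1e-9

    def test_auto_choice_is_gallery_minimum(self, sa_result):
        _, res = sa_result
        pool = res.candidates_1d + res.candidates_2d
        assert res.chosen.d_tsa_pct == min(o.d_tsa_pct for o in pool)
        assert res.chosen.method == "MIX-FCM"

    def test_deterministic_gallery(self, severe_study):
        study, _, lic = severe_study
        a = sa_run(study.stack, lic, study.roi, reference=study.truth,
                   selection="reference-auto")
        b = sa_run(study.stack, lic, study.roi, reference=study.truth,
                   selection="reference-auto")
        assert a.te_index == b.te_index
        assert np.array_equal(a.chosen.mask.labels, b.chosen.mask.labels)

    def test_interactive_export_defers_choice(self, severe_study):
        study, _, lic = severe_study
        res = sa_run(study.stack, lic, study.roi, selection="interactive-export")
        assert res.chosen is None
        picked = sa_choose(res, "2D", 31)
        assert picked.u0 == pytest.approx(0.62)
        assert picked.selected_from == "2D-FCM"

    def test_auto_requires_reference(self, severe_study):
        study, _, lic = severe_study
        with pytest.raises(InputError):
            sa_run(study.stack, lic, study.roi, selection="reference-auto")

    def test_bad_gallery_pick_rejected(self, sa_result):
        _, res = sa_result
        with pytest.raises(InputError):
            sa_choose(res, "3D", 0)
        with pytest.raises(InputError):
            sa_choose(res, "1D", 50)
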