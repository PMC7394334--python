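"""Dose-component detection, core screening, truncation and chi-squared selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdfe.errors import DegenerateInputError
from tdfe.hosvd import HOSVDResult, hosvd
from tdfe.io import ExpressionTensor
from tdfe.selection import (
    bh_adjust,
    choose_truncation,
    find_dose_component,
    score_mode,
    screen_core,
    select_features,
)


def _result_from_core(core):
    """HOSVDResult wrapper for tests that only touch the core tensor."""
    svs = []
    for m in range(core.ndim):
        g = np.moveaxis(core, m, 0).reshape(core.shape[m], -1)
        svs.append(np.sqrt((g**2).sum(axis=1)))
    return HOSVDResult(core=core, factors=[], singular_values=svs)


class TestFindDoseComponent:
    def test_planted_linear_signal_puts_dose_ramp_in_component_two(self, planted):
        tensor, _ = planted
        res = hosvd(tensor)
        rep = find_dose_component(res, tensor.dose_levels)
        assert rep.chosen_k1 == 2
        assert abs(rep.correlations[1]) > 0.99

    def test_override_wins(self, planted):
        tensor, _ = planted
        rep = find_dose_component(hosvd(tensor), tensor.dose_levels, override=3)
        assert rep.chosen_k1 == 3 and rep.overridden

    def test_all_constant_tensor_is_degenerate(self):
        t = ExpressionTensor(
            np.ones((6, 4, 5)), np.arange(1.0, 7.0),
            [f"c{i}" for i in range(4)], [f"g{i}" for i in range(5)],
        )
        with pytest.raises(DegenerateInputError):
            find_dose_component(hosvd(t), t.dose_levels)

    def test_log_dose_covariate(self, planted):
        tensor, _ = planted
        rep = find_dose_component(hosvd(tensor), tensor.dose_levels, covariate="log_dose")
        assert rep.chosen_k1 == 2  # doses are geometric, so log-dose is linear too

    def test_fewer_than_three_doses_rejected(self, planted):
        tensor, _ = planted
        with pytest.raises(ValueError):
            find_dose_component(hosvd(tensor), tensor.dose_levels[:2])


class TestScreenCore:
    def test_zero_entry_has_p_one_and_sigma_entry_has_known_tail(self):
        # slice [0, 1, -1]: sample sd = 1, so the entries give stats 0, 1, 1
        core = np.zeros((2, 3, 1))
        core[1, :, 0] = [0.0, 1.0, -1.0]
        scr = screen_core(_result_from_core(core), k1_star=2)
        p = scr.table.sort_values(["k2", "k3"])["p"].to_numpy()
        assert p[0] == pytest.approx(1.0)
        # chi-squared(1) upper tail at 1, frozen from numerical integration
        assert p[1] == pytest.approx(0.3173105079, abs=1e-9)
        assert scr.sigma_g == pytest.approx(1.0)

    def test_equal_magnitudes_tie_everywhere(self):
        core = np.zeros((1, 2, 2))
        core[0] = [[1.0, -1.0], [1.0, -1.0]]
        scr = screen_core(_result_from_core(core), k1_star=1)
        assert scr.table["p"].nunique() == 1
        assert scr.table["p_adj"].nunique() == 1

    def test_zero_variance_slice_is_degenerate(self):
        core = np.ones((2, 3, 3))
        with pytest.raises(DegenerateInputError):
            screen_core(_result_from_core(core), k1_star=1)

    def test_invalid_component_rejected(self):
        with pytest.raises(ValueError):
            screen_core(_result_from_core(np.ones((2, 2, 2))), k1_star=5)


class TestChooseTruncation:
    def test_rank_one_core_keeps_default(self):
        core = np.zeros((6, 8, 8))
        core[0, 0, 0] = 1.0
        assert choose_truncation(_result_from_core(core)) == (6, 6)

    def test_escalates_until_contribution_threshold(self):
        # diagonal core energies: 0.90 inside K=6, 0.96 inside K=7
        energies = [0.5, 0.1, 0.1, 0.1, 0.05, 0.05, 0.06, 0.04]
        core = np.zeros((1, 8, 8))
        for k, e in enumerate(energies):
            core[0, k, k] = np.sqrt(e)
        res = _result_from_core(core)
        assert choose_truncation(res, default_K=6, K_max=8) == (7, 7)

    def test_falls_back_to_k_max_with_warning(self, caplog):
        core = np.zeros((1, 10, 10))
        np.fill_diagonal(core[0], 1.0)  # flat spectrum: 10% per component
        with caplog.at_level("WARNING"):
            assert choose_truncation(_result_from_core(core), default_K=6, K_max=8) == (8, 8)
        assert any("cumulative contribution" in r.message for r in caplog.records)

    def test_override_reproduces_k_eight_exception(self):
        core = np.zeros((6, 9, 9))
        core[0, 0, 0] = 1.0
        assert choose_truncation(_result_from_core(core), override=8) == (8, 8)

    def test_k_max_beyond_core_dims_is_capped(self):
        core = np.zeros((3, 4, 4))
        core[0, 0, 0] = 1.0
        assert choose_truncation(_result_from_core(core), default_K=6, K_max=20) == (4, 4)


class TestScoreMode:
    def test_matches_hand_computed_statistics(self):
        # per-component sample sds: 1.29099445, 0.81649658
        factor = np.array([[1.0, 2.0, 3.0, 4.0], [0.0, 1.0, 0.0, -1.0]])
        s, p, sd = score_mode(factor, K=2)
        np.testing.assert_allclose(sd, [1.2909944487, 0.8164965809], rtol=1e-9)
        np.testing.assert_allclose(s, [0.6, 3.9, 5.4, 11.1], rtol=1e-9)
        # chi-squared(2) upper tail is exactly exp(-S/2); values frozen from that
        # (comparison at the accuracy of the library's incomplete-gamma tail)
        np.testing.assert_allclose(
            p,
            [0.7408182206817179, 0.1422740715865536, 0.0672055127397498, 0.0038874573103572],
            rtol=1e-7,
        )

    def test_zero_loadings_give_p_one(self):
        factor = np.array([[0.0, 1.0, -1.0], [0.0, 2.0, -2.0]])
        s, p, _ = score_mode(factor, K=2)
        assert s[0] == 0.0 and p[0] == 1.0

    def test_chi2_six_df_quantile(self):
        # S = 12.592 at 6 df sits at the 5% tail (frozen independent value)
        from scipy.stats import chi2

        assert chi2.sf(12.592, 6) == pytest.approx(0.0499924582, abs=1e-9)

    def test_sign_flip_invariance(self, rng):
        factor = rng.normal(size=(4, 20))
        s1, _, _ = score_mode(factor, 4)
        factor[2] *= -1
        s2, _, _ = score_mode(factor, 4)
        np.testing.assert_allclose(s1, s2, rtol=1e-12)

    def test_zero_variance_component_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            score_mode(np.array([[1.0, 1.0, 1.0]]), 1)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            score_mode(np.ones((2, 3)), 3)


class TestBhAdjust:
    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_ties_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_reference_step_up(self, pvals):
        # independent oracle: sort, multiply by n/rank, running min from the top
        p = np.asarray(pvals)
        order = np.argsort(p, kind="stable")
        n = len(p)
        scaled = p[order] * n / np.arange(1, n + 1)
        ref_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
        ref = np.empty(n)
        ref[order] = np.minimum(ref_sorted, 1.0)
        np.testing.assert_allclose(bh_adjust(p), ref, rtol=1e-10)
        assert np.all(bh_adjust(p) >= p - 1e-15)


class TestSelectFeatures:
    def test_threshold_one_selects_everything(self, planted):
        tensor, _ = planted
        sel = select_features(
            hosvd(tensor), tensor.dose_levels, tensor.compound_ids, tensor.gene_ids,
            threshold=1.0,
        )
        assert len(sel.selected_compounds) == len(tensor.compound_ids)
        assert len(sel.selected_genes) == len(tensor.gene_ids)

    def test_pure_noise_selects_almost_nothing(self, noise_tensor):
        t = noise_tensor
        sel = select_features(hosvd(t), t.dose_levels, t.compound_ids, t.gene_ids)
        assert len(sel.selected_compounds) <= 2
        assert len(sel.selected_genes) <= 6  # <= 5% of 120

    def test_selection_flag_matches_adjusted_threshold(self, planted):
        tensor, _ = planted
        sel = select_features(
            hosvd(tensor), tensor.dose_levels, tensor.compound_ids, tensor.gene_ids
        )
        for table in (sel.compound_table, sel.gene_table):
            np.testing.assert_array_equal(
                table["selected"], table["p_adj"] < sel.threshold
            )

    def test_permutation_invariance_of_scores(self, planted, rng):
        tensor, _ = planted
        sel1 = select_features(
            hosvd(tensor), tensor.dose_levels, tensor.compound_ids, tensor.gene_ids
        )
        perm = rng.permutation(len(tensor.compound_ids))
        shuffled = ExpressionTensor(
            tensor.values[:, perm, :],
            tensor.dose_levels,
            [tensor.compound_ids[i] for i in perm],
            tensor.gene_ids,
        )
        sel2 = select_features(
            hosvd(shuffled), shuffled.dose_levels, shuffled.compound_ids, shuffled.gene_ids
        )
        a = sel1.compound_table.set_index("compound")["S"].sort_index()
        b = sel2.compound_table.set_index("compound")["S"].sort_index()
        np.testing.assert_allclose(a, b, rtol=1e-6)

    def test_explicit_k2_k3_decoupling(self, planted):
        tensor, _ = planted
        sel = select_features(
            hosvd(tensor), tensor.dose_levels, tensor.compound_ids, tensor.gene_ids,
            K2=3, K3=5,
        )
        assert (sel.K2, sel.K3) == (3, 5)
        assert len(sel.sigma_k2) == 3 and len(sel.sigma_k3) == 5
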