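"""Design-matrix construction and residualization contracts."""

import numpy as np
import pandas as pd
import pytest

from fcbench import denoise
from fcbench.denoise import (all_strategies, aroma_regress, assemble_design,
                             cosine_basis, expand_motion, get_strategy,
                             gsr_block, residualize, select_acompcor)
from fcbench.synthetic import simulate_confounds


class TestStrategyTable:
    def test_sixteen_distinct_strategies(self):
        specs = all_strategies()
        assert len(specs) == 16
        assert len({s.id for s in specs}) == 16

    def test_gsr_half_mirrors_base_half(self):
        specs = {s.id: s for s in all_strategies()}
        for i in range(1, 9):
            base, gsr = specs[i], specs[i + 8]
            assert not base.gsr and gsr.gsr
            assert (base.hmp, base.compcor, base.aroma) == \
                   (gsr.hmp, gsr.compcor, gsr.aroma)

    def test_aroma_strategies_pair_with_fixed_acompcor_and_no_hmp(self):
        for s in all_strategies():
            if s.aroma != "none":
                assert s.compcor == "a_fixed10"
                assert s.hmp is None


class TestMotionExpansion:
    def test_hmp24_has_24_columns(self, rng):
        motion = rng.standard_normal((50, 6))
        assert expand_motion(motion, "HMP24").shape == (50, 24)

    def test_zero_motion_expands_to_zeros(self):
        out = expand_motion(np.zeros((10, 6)), "HMP24")
        assert (out.to_numpy() == 0).all()

    def test_derivative_and_square_columns_by_hand(self):
        motion = np.zeros((4, 6))
        motion[:, 0] = (0, 1, 2, 3)
        out = expand_motion(motion, "HMP24")
        np.testing.assert_array_equal(out["trans_x_derivative1"], (0, 1, 1, 1))
        np.testing.assert_array_equal(out["trans_x_power2"], (0, 1, 4, 9))
        np.testing.assert_array_equal(out["trans_x_derivative1_power2"],
                                      (0, 1, 1, 1))

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError):
            expand_motion(np.zeros((10, 5)), "HMP12")


class TestGSRBlock:
    def test_exactly_four_columns(self, rng):
        assert gsr_block(rng.standard_normal(30)).shape[1] == 4

    def test_constant_series_kills_derivative_columns(self):
        out = gsr_block(np.full(10, 3.0)).to_numpy()
        assert (out[:, 1] == 0).all() and (out[:, 3] == 0).all()
        assert (out[:, 2] == 9.0).all()

    def test_hand_example_with_derivative_of_square(self):
        out = gsr_block(np.array([1.0, 2.0, 3.0])).to_numpy()
        np.testing.assert_array_equal(out[:, 0], (1, 2, 3))
        np.testing.assert_array_equal(out[:, 1], (0, 1, 1))
        np.testing.assert_array_equal(out[:, 2], (1, 4, 9))
        np.testing.assert_array_equal(out[:, 3], (0, 3, 5))  # diff of squares


class TestCosineBasis:
    def test_column_count_follows_duration_formula(self):
        # floor(2 * 120 * 2.5 / 128) = 4 drift columns
        basis = cosine_basis(120, 2.5)
        assert basis.shape == (120, 4)

    def test_columns_mutually_orthogonal(self):
        X = cosine_basis(240, 2.0).to_numpy()
        gram = X.T @ X
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-10

    def test_short_scan_yields_no_columns_with_warning(self):
        with pytest.warns(UserWarning):
            basis = cosine_basis(40, 2.0, cutoff=128)
        assert basis.shape[1] == 0

    def test_basis_is_deterministic(self):
        pd.testing.assert_frame_equal(cosine_basis(100, 2.0),
                                      cosine_basis(100, 2.0))


class TestCompCorSelection:
    def test_var50_uses_cumulative_share_prefix(self, rng):
        comps = pd.DataFrame(rng.standard_normal((30, 4)))
        out = select_acompcor(comps, np.array([0.3, 0.25, 0.2, 0.1]), "a_var50")
        assert out.shape[1] == 2  # 0.3 + 0.25 = 0.55 >= 0.50

    def test_fixed10_truncates_with_warning(self, rng):
        comps = pd.DataFrame(rng.standard_normal((30, 7)))
        shares = np.linspace(0.3, 0.05, 7)
        with pytest.warns(UserWarning):
            out = select_acompcor(comps, shares, "a_fixed10")
        assert out.shape[1] == 7

    def test_single_component_with_full_share(self, rng):
        comps = pd.DataFrame(rng.standard_normal((30, 1)))
        out = select_acompcor(comps, np.array([1.0]), "a_var50")
        assert out.shape[1] == 1

    def test_unsorted_shares_rejected(self, rng):
        comps = pd.DataFrame(rng.standard_normal((30, 3)))
        with pytest.raises(ValueError):
            select_acompcor(comps, np.array([0.2, 0.5, 0.1]), "a_var50")


@pytest.fixture(scope="module")
def confounds():
    return simulate_confounds(240, 2.0, 0.1, seed=5)


class TestDesignAssembly:
    def test_24hmp_strategy_has_24_nuisance_regressors(self, confounds):
        design = assemble_design(get_strategy(1), confounds)
        assert design.n_nuisance() == 24

    def test_24hmp_gsr_strategy_has_28_nuisance_regressors(self, confounds):
        design = assemble_design(get_strategy(9), confounds)
        assert design.n_nuisance() == 28

    def test_gsr_twin_differs_by_exactly_four_columns(self, confounds):
        d2 = assemble_design(get_strategy(2), confounds)
        d10 = assemble_design(get_strategy(10), confounds)
        extra = set(d10.frame.columns) - set(d2.frame.columns)
        assert len(extra) == 4
        assert all(d10.provenance[c] == "gsr" for c in extra)

    def test_intercept_and_cosines_present_for_every_strategy(self, confounds):
        for spec in all_strategies():
            design = assemble_design(spec, confounds)
            rules = set(design.provenance.values())
            assert "intercept" in rules and "cosine" in rules

    def test_missing_columns_named_in_error(self, confounds):
        crippled = type(confounds)(
            confounds.data.drop(columns=["global_signal"]),
            confounds.acompcor_shares, confounds.aroma_noise_flags)
        with pytest.raises(ValueError, match="global_signal"):
            assemble_design(get_strategy(9), crippled)


class TestResidualize:
    def test_intercept_only_demeans(self, rng):
        Y = rng.standard_normal((40, 3))
        out = residualize(Y, np.ones((40, 1)))
        np.testing.assert_allclose(out, Y - Y.mean(axis=0), atol=1e-12)

    def test_signal_in_design_span_is_annihilated(self, rng):
        X = np.column_stack([np.ones(30), rng.standard_normal((30, 2))])
        Y = X @ rng.standard_normal((3, 4))
        assert np.abs(residualize(Y, X)).max() < 1e-10

    def test_matches_explicit_projector(self, rng):
        X = np.column_stack([np.ones(25), rng.standard_normal((25, 3))])
        Y = rng.standard_normal((25, 5))
        P = np.eye(25) - X @ np.linalg.inv(X.T @ X) @ X.T
        np.testing.assert_allclose(residualize(Y, X), P @ Y, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, confounds, rng):
        Y = rng.standard_normal((240, 6))
        design = assemble_design(get_strategy(5), confounds)
        resid = residualize(Y, design)
        X = design.matrix
        inner = np.abs(X.T @ resid).max()
        assert inner / (np.abs(Y).max() * 240) < 1e-8


class TestAroma:
    def _components(self, rng, orthogonal):
        noise = rng.standard_normal((60, 2))
        if orthogonal:
            signal = rng.standard_normal((60, 2))
            signal -= noise @ np.linalg.lstsq(noise, signal, rcond=None)[0]
        else:
            signal = 0.7 * noise + 0.3 * rng.standard_normal((60, 2))
        return np.hstack([noise, signal]), np.array([True, True, False, False])

    def test_orthogonal_components_make_modes_agree(self, rng):
        C, flags = self._components(rng, orthogonal=True)
        Y = rng.standard_normal((60, 3))
        agg = aroma_regress(Y, C, flags, "aggressive")
        non = aroma_regress(Y, C, flags, "nonaggressive")
        np.testing.assert_allclose(agg, non, atol=1e-10)

    def test_no_noise_components_returns_input(self, rng):
        Y = rng.standard_normal((60, 3))
        C = rng.standard_normal((60, 4))
        out = aroma_regress(Y, C, np.zeros(4, bool), "aggressive")
        np.testing.assert_array_equal(out, Y)

    def test_nonaggressive_removes_less_variance_when_correlated(self, rng):
        C, flags = self._components(rng, orthogonal=False)
        Y = C @ rng.standard_normal((4, 3)) + 0.5 * rng.standard_normal((60, 3))
        agg = aroma_regress(Y, C, flags, "aggressive")
        non = aroma_regress(Y, C, flags, "nonaggressive")
        assert (non**2).sum() > (agg**2).sum()


def test_cleaned_series_uncorrelated_with_every_design_column(study):
    """End-to-end: residualized ROI series decorrelated from the design."""
    scan, conf = study.dataset[0]
    for sid in (1, 5, 16):
        spec = get_strategy(sid)
        cleaned = denoise.clean_scan(spec, scan.timeseries, conf)
        X = assemble_design(spec, conf).matrix
        Xc = X - X.mean(axis=0)
        Yc = cleaned - cleaned.mean(axis=0)
        denom = np.outer(np.linalg.norm(Xc, axis=0) + 1e-30,
                         np.linalg.norm(Yc, axis=0) + 1e-30)
        corr = np.abs(Xc.T @ Yc) / denom
        assert corr.max() < 1e-6
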