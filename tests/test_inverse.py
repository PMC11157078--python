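"""Objective functions, weighting, grid search and trim-factor selection."""

import numpy as np
import pytest

from indentfit import references
from indentfit.curves import ForceDisplacementRecord, evaluate_fit, fit_force_displacement
from indentfit.inverse_id import (
    ReferenceSet,
    combined_objective,
    force_residual,
    grid_search,
    node_weights,
    select_trim_factor,
    surface_residual,
    total_objective,
    x_trim_position,
)
from indentfit.tof_surface import MeanSurfaceDisplacement


class TestResidualTerms:
    def test_force_residual_values(self):
        assert force_residual(5.0, 5.0) == 0.0
        assert force_residual(10.0, 5.0) == 1.0
        assert force_residual(9.0, 8.53) == pytest.approx(0.003036, abs=2e-6)

    def test_force_residual_rejects_zero_reference(self):
        with pytest.raises(ValueError):
            force_residual(1.0, 0.0)

    def test_node_weights(self):
        assert node_weights([42.0]) == pytest.approx([1.0])
        np.testing.assert_allclose(node_weights([10.0, 20.0]), [2 / 3, 1 / 3])
        np.testing.assert_allclose(node_weights([7.0] * 5), 0.2)

    def test_node_weights_always_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            r = rng.uniform(6.0, 110.0, rng.integers(1, 40))
            assert node_weights(r).sum() == pytest.approx(1.0, abs=1e-12)

    def test_combined_objective_endpoints_and_linearity(self):
        assert combined_objective(0.2, 0.4, 1.0) == 0.2
        assert combined_objective(0.2, 0.4, 0.0) == 0.4
        assert combined_objective(0.2, 0.4, 0.5) == pytest.approx(0.3)
        # exact linearity in eta
        rng = np.random.default_rng(1)
        for _ in range(10):
            ff, fu, eta = rng.uniform(0, 2, 3)
            eta = eta / 2
            lhs = combined_objective(ff, fu, eta)
            assert lhs == eta * ff + (1 - eta) * fu

    def test_total_objective(self):
        assert total_objective([0.3] * 4) == pytest.approx(0.3)
        assert total_objective([0.06, 0.27, 0.37, 0.42]) == pytest.approx(0.28)
        base = np.array([0.1, 0.2, 0.3, 0.4])
        bumped = base.copy()
        bumped[2] += 0.4
        assert total_objective(bumped) == pytest.approx(total_objective(base) + 0.1)

    def test_x_trim_is_root_of_reference_cubic(self):
        msd = references.surface_displacement("R3", 25.0)
        xt = x_trim_position(msd, 0.5)
        assert msd.x_min < xt < msd.x_max
        assert msd(xt) == pytest.approx(-0.5, abs=1e-9)

    def test_surface_residual_exact_cases(self):
        msd = references.surface_displacement("R3", 25.0)
        r = np.linspace(12.0, 50.0, 12)
        u_ref = msd(r)
        assert surface_residual(r, u_ref, msd, 0.5) == 0.0
        # uniform 10 % over-displacement: relative error squared, weights sum 1
        assert surface_residual(r, 1.1 * u_ref, msd, 0.5) == pytest.approx(0.01)


def _direct_reference(solution, fit):
    """Reference set whose surfaces are cubics of the solution's own profile."""
    msds = []
    for d in sorted(solution.snapshots):
        snap = solution.snapshot(d)
        r, uz = snap["r"], snap["uz"]
        sel = (r >= 10.0) & (uz < -0.3)
        co = np.polyfit(r[sel], uz[sel], 3)
        roots = np.roots(co)
        real = np.sort(roots[np.abs(roots.imag) < 1e-8].real)
        inrange = real[(real > 10.0) & (real <= 110.0)]
        x_max = float(inrange[0]) if inrange.size else 80.0
        msds.append(
            MeanSurfaceDisplacement("SYN", d, tuple(co), 10.0, x_max,
                                    float(evaluate_fit(fit, d)))
        )
    depths = tuple(sorted(solution.snapshots))
    return ReferenceSet("SYN", fit, tuple(msds), depths, depths[-1], delta_trim=0.5)


@pytest.fixture(scope="module")
def truth_reference(solution_truth_n1):
    d = np.linspace(0.0, 25.0, 300)
    f = np.interp(d, solution_truth_n1.delta_history, solution_truth_n1.reaction_history)
    fit = fit_force_displacement(ForceDisplacementRecord("SYN", "P", "T", d, f))
    return _direct_reference(solution_truth_n1, fit)


class TestGridSearch:
    def test_planted_parameters_recovered_exactly(self, truth_reference):
        """Self-consistency: noiseless references identify the planted cell."""
        surf = grid_search(
            truth_reference,
            c_values=np.arange(8.0, 12.5, 1.0),
            m_values=np.arange(16.0, 25.0, 2.0),
            mesh_N=1,
        )
        assert surf.p_res == (10.0, 20.0)
        assert surf.min_F_tot < 0.01
        assert not surf.failures.any()

    def test_eta_extremes_shift_valley_orientation(self, truth_reference):
        """Surface-only valleys are flat in c; force-only valleys flat in m."""
        surf = grid_search(
            truth_reference,
            c_values=np.arange(8.0, 12.5, 1.0),
            m_values=np.arange(16.0, 25.0, 2.0),
            mesh_N=1,
        )
        s0 = grid_search(truth_reference, surf.c_values, surf.m_values,
                         eta=0.0, raw_columns=surf.raw)
        s1 = grid_search(truth_reference, surf.c_values, surf.m_values,
                         eta=1.0, raw_columns=surf.raw)
        # eta=0: F is c-independent (exactly constant along columns)
        assert np.allclose(np.ptp(s0.F_tot, axis=0), 0.0, atol=1e-12)
        # eta=1: much larger spread across c than eta=0
        assert np.ptp(s1.F_tot, axis=0).max() > 1e-3


class TestTrimSelection:
    def test_degenerate_surfaces_select_lowest_candidate(self, truth_reference):
        """References matched exactly by one column are trim-insensitive."""
        # fabricate forward columns that reproduce the reference cubic exactly
        r = np.linspace(10.5, 60.0, 30)
        cols = {}
        for m, f_scale in ((10.0, 1.0), (12.0, 1.3)):
            col = {}
            for k, d in enumerate(truth_reference.delta_levels):
                msd = truth_reference.surfaces[k]
                col[d] = (truth_reference.f_ref(d) / 9.0 * f_scale, r, msd(r))
            cols[m] = col
        ev = select_trim_factor(
            truth_reference,
            c_values=np.arange(8.0, 11.0, 1.0),
            m_values=np.array([10.0, 12.0]),
            candidates=np.array([0.3, 0.4, 0.5]),
            raw_columns=cols,
        )
        assert ev.selected == pytest.approx(0.3)
        for name in ("depth_sd", "high_fraction", "circularity", "c_res", "m_res"):
            assert ev.targets[name] == pytest.approx(0.3)
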