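"""Normalisation, induction window, Hill fitting and derived parameters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import SENSOR_PARAMS, grid_search_sse
from sensormine.doseresponse import (
    DoseResponseDataset,
    DynamicRangeUndefinedError,
    FitError,
    HillFitResult,
    IntracellularSample,
    PlateTimeCourse,
    build_dose_response,
    dynamic_range,
    extract_induction_window,
    fit_hill,
    fold_induction,
    hill,
    intracellular_concentration,
    normalize_measurements,
    read_plate_table,
    relative_response,
    write_plate_table,
)
from sensormine.fixtures import SimSpec, simulate_plate_timecourse


def course(fl, od, times=None, is_blank=False, well="w1", conc=0.0, **kw):
    times = np.arange(len(fl)) * 5.0 if times is None else np.asarray(times, float)
    return PlateTimeCourse(
        well_id=well, system_id="s", inducer="none" if is_blank or conc == 0 else "x",
        concentration=conc, times=times, fluorescence=np.asarray(fl, float),
        absorbance=np.asarray(od, float), is_blank=is_blank, **kw,
    )


class TestNormalisation:
    def test_blank_corrected_od_normalised_value(self):
        """(200 - 100) / (1.1 - 0.1) = 100 AFU/OD."""
        blank = course([100, 100], [0.1, 0.1], is_blank=True, well="b")
        sample = course([150, 200], [0.6, 1.1], well="s1", conc=1e-6)
        out = normalize_measurements([blank, sample])
        norm = next(c for c in out if not c.is_blank).normalized
        assert norm[1] == pytest.approx(100.0)
        assert norm[0] == pytest.approx((150 - 100) / 0.5)

    def test_fluorescence_equal_to_blank_normalises_to_zero(self):
        blank = course([100, 100], [0.1, 0.1], is_blank=True, well="b")
        sample = course([100, 100], [1.1, 1.1], well="s1", conc=1e-6)
        out = normalize_measurements([blank, sample])
        assert np.allclose(next(c for c in out if not c.is_blank).normalized, 0.0)

    def test_low_biomass_points_masked(self):
        blank = course([100, 100], [0.1, 0.1], is_blank=True, well="b")
        sample = course([120, 200], [0.105, 1.1], well="s1", conc=1e-6)  # corrected OD 0.005
        out = normalize_measurements([blank, sample], od_floor=0.01)
        norm = next(c for c in out if not c.is_blank).normalized
        assert np.isnan(norm[0]) and np.isfinite(norm[1])

    def test_no_blank_wells_is_an_error(self):
        with pytest.raises(ValueError, match="blank"):
            normalize_measurements([course([1, 2], [0.2, 0.3], conc=1e-6)])

    def test_all_points_masked_names_the_well(self):
        blank = course([100, 100], [0.1, 0.1], is_blank=True, well="b")
        sample = course([120, 130], [0.105, 0.105], well="deadwell", conc=1e-6)
        with pytest.raises(ValueError, match="deadwell"):
            normalize_measurements([blank, sample])


class TestInductionWindow:
    def _normalised(self, times):
        n = len(times)
        c = course(np.linspace(100, 200, n), np.full(n, 1.0), times=times, conc=2e-6)
        c.normalized = np.linspace(10, 20, n)
        return c

    def test_exact_grid_hit(self):
        c = self._normalised(np.arange(0, 125, 5.0))
        conc, val = extract_induction_window(c, t_window=80)
        assert conc == 2e-6
        assert val == c.normalized[16]  # t = 80 is sample 16 on a 5-min grid

    def test_nearest_sample_on_irregular_grid(self):
        c = self._normalised(np.arange(0, 120, 7.0))
        _, val = extract_induction_window(c, t_window=80)
        assert val == c.normalized[11]  # t = 77 is nearest to 80

    def test_series_not_covering_window_is_an_error(self):
        c = self._normalised(np.arange(0, 65, 5.0))
        with pytest.raises(ValueError, match="no sample"):
            extract_induction_window(c, t_window=80)

    def test_unnormalised_course_is_an_error(self):
        c = course([1, 2], [0.2, 0.3], conc=1e-6)
        with pytest.raises(ValueError, match="normalise"):
            extract_induction_window(c)


class TestHillModel:
    def test_endpoint_identities(self):
        b_min, b_max, km, h = 50.0, 500.0, 2.12e-6, 0.66
        assert hill(0.0, b_max, km, h, b_min) == b_min
        assert hill(km, b_max, km, h, b_min) == pytest.approx(b_min + b_max / 2)

    def test_monotone_nondecreasing_in_concentration(self):
        grid = np.geomspace(1e-9, 1e-1, 500)
        for _, km, h in SENSOR_PARAMS.values():
            vals = hill(grid, 1.0, km, h, 0.0)
            assert np.all(np.diff(vals) >= 0)


def synthetic_dataset(mu, km, h, b_min=100.0, noise_cv=0.0, seed=0, n_rep=3):
    spec = SimSpec(hill=(b_min, mu * b_min, km, h), noise_cv=noise_cv,
                   n_replicates=n_rep, seed=seed)
    courses = normalize_measurements(simulate_plate_timecourse(spec))
    (ds,) = build_dose_response(courses)
    return ds


class TestHillFit:
    @pytest.mark.parametrize("name", ["NahR_salicylate", "BenM_benzoate", "SauR_sulfonatoacetate"])
    def test_noiseless_parameter_recovery(self, name):
        """Noise-free data generated from the Hill law refits to the
        generating parameters to well under 0.1% relative error."""
        mu, km, h = SENSOR_PARAMS[name]
        ds = synthetic_dataset(mu, km, h)
        fit = fit_hill(ds)
        assert fit.converged
        assert fit.K_m == pytest.approx(km, rel=1e-3)
        assert fit.h == pytest.approx(h, rel=1e-3)
        mu_hat, _ = dynamic_range(fit, ds.uninduced_sd)
        assert mu_hat == pytest.approx(mu, rel=1e-3)

    def test_flat_response_flagged_degenerate(self):
        conc = np.concatenate([[0.0], np.geomspace(1e-6, 1e-3, 6)])
        ds = DoseResponseDataset("flat", conc, np.full_like(conc, 42.0),
                                 np.zeros_like(conc, dtype=int))
        fit = fit_hill(ds)
        assert fit.degenerate
        if fit.converged and fit.b_min > 0:
            # fitted amplitude collapses: saturating/basal output ratio ~ 1
            assert (fit.b_max + fit.b_min) / fit.b_min == pytest.approx(1.0, abs=0.05)

    def test_too_few_concentrations_is_an_error(self):
        conc = np.array([0.0, 1e-6, 1e-5, 1e-4])
        ds = DoseResponseDataset("few", conc, np.array([1.0, 2, 3, 4]),
                                 np.zeros(4, dtype=int))
        with pytest.raises(FitError, match="4 distinct"):
            fit_hill(ds)

    def test_non_finite_values_are_an_error(self):
        conc = np.concatenate([[0.0], np.geomspace(1e-6, 1e-3, 6)])
        rfp = np.ones_like(conc)
        rfp[3] = np.nan
        with pytest.raises(FitError, match="non-finite"):
            fit_hill(DoseResponseDataset("bad", conc, rfp, np.zeros_like(conc, dtype=int)))

    def test_fit_sse_beats_coarse_grid_oracle(self):
        """The optimiser's SSE never exceeds an exhaustive coarse grid
        search with closed-form linear parameters at each node."""
        rng = np.random.default_rng(5)
        for _ in range(3):
            mu = rng.uniform(5, 300)
            km = 10 ** rng.uniform(-6, -2)
            h = rng.uniform(0.5, 2.5)
            ds = synthetic_dataset(mu, km, h, noise_cv=0.1, seed=int(rng.integers(2**31)))
            fit = fit_hill(ds)
            assert fit.converged
            assert fit.sse <= grid_search_sse(ds.concentrations, ds.rfp) + 1e-9


class TestDynamicRange:
    def test_equal_levels_with_zero_sd(self):
        fit = HillFitResult(8.0, 0.0, 8.0, 0.0, 1e-6, 0.0, 1.0, 0.0, converged=True)
        mu, sd = dynamic_range(fit, 0.0)
        assert (mu, sd) == (1.0, 0.0)

    def test_error_propagation_hand_case(self):
        """mu = 8/1 = 8; sigma = 8 * sqrt((0.4/8)^2) = 0.4."""
        fit = HillFitResult(8.0, 0.4, 1.0, 0.0, 1e-6, 0.0, 1.0, 0.0, converged=True)
        mu, sd = dynamic_range(fit, 0.0)
        assert mu == pytest.approx(8.0)
        assert sd == pytest.approx(0.4)

    def test_both_uncertainty_terms_combine_in_quadrature(self):
        fit = HillFitResult(8.0, 0.4, 1.0, 0.0, 1e-6, 0.0, 1.0, 0.0, converged=True)
        mu, sd = dynamic_range(fit, 0.1)
        assert sd == pytest.approx(8.0 * np.sqrt((0.4 / 8) ** 2 + (0.1 / 1) ** 2))

    def test_nonpositive_basal_level_undefined(self):
        fit = HillFitResult(8.0, 0.4, 0.0, 0.0, 1e-6, 0.0, 1.0, 0.0, converged=True)
        with pytest.raises(DynamicRangeUndefinedError):
            dynamic_range(fit, 0.0)


class TestRelativeResponse:
    def test_endpoints(self):
        ds = synthetic_dataset(8.0, 201e-6, 0.75)
        fit = fit_hill(ds)
        rel = relative_response(ds, fit)
        uninduced = rel[ds.concentrations == 0, 1]
        assert np.allclose(uninduced, 0.0, atol=1e-6)
        # at the top concentration (100x K_m) the response equals the Hill
        # saturation fraction 100^h / (1 + 100^h), not quite 100%
        top = rel[np.argmax(rel[:, 0]), 1]
        h = 0.75
        expected = 100.0 * 100**h / (1 + 100**h)
        assert top == pytest.approx(expected, rel=1e-3)

    def test_invariant_under_common_rescaling(self):
        ds = synthetic_dataset(8.0, 201e-6, 0.75)
        fit = fit_hill(ds)
        rel = relative_response(ds, fit)
        scaled = DoseResponseDataset(ds.system_id, ds.concentrations, ds.rfp * 3.7,
                                     ds.replicate)
        fit2 = fit_hill(scaled)
        rel2 = relative_response(scaled, fit2)
        assert np.allclose(rel[:, 1], rel2[:, 1], rtol=1e-6)

    def test_fallback_sets_highest_concentration_to_hundred(self):
        """Without a converged fit the observed response at the highest
        tested concentration defines 100%."""
        ds = synthetic_dataset(8.0, 201e-6, 0.75)
        rel = relative_response(ds, fit=None)
        top_rows = ds.concentrations == ds.concentrations.max()
        assert np.mean(rel[top_rows, 1]) == pytest.approx(100.0)


class TestScalarFormulas:
    @pytest.mark.parametrize(
        "induced,uninduced,expected",
        [(5.0, 5.0, 1.0), (0.0, 5.0, 0.0), (212.6, 0.2, 1063.0)],
    )
    def test_fold_induction(self, induced, uninduced, expected):
        assert fold_induction(induced, uninduced) == pytest.approx(expected)

    def test_fold_induction_requires_positive_basal(self):
        with pytest.raises(ValueError):
            fold_induction(1.0, 0.0)

    def test_intracellular_dilution_hand_case(self):
        """0.1105 g pellet -> 0.1 mL; with 0.1 mL solvent the extract is
        diluted exactly twofold."""
        s = IntracellularSample(pellet_wet_mass_g=0.1105, v_solvent_ml=0.1,
                                c_extract_molar=1e-3)
        assert s.v_pellet_ml == pytest.approx(0.1)
        assert intracellular_concentration(s) == pytest.approx(2e-3)

    def test_zero_solvent_recovers_extract_concentration(self):
        s = IntracellularSample(pellet_wet_mass_g=0.2, v_solvent_ml=0.0,
                                c_extract_molar=5e-4)
        assert intracellular_concentration(s) == pytest.approx(5e-4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(mass=st.floats(1e-3, 10), solvent=st.floats(0, 10), conc=st.floats(1e-9, 1))
    def test_intracellular_concentration_never_below_extract(self, mass, solvent, conc):
        s = IntracellularSample(pellet_wet_mass_g=mass, v_solvent_ml=solvent,
                                c_extract_molar=conc)
        assert intracellular_concentration(s) >= conc


def test_plate_table_round_trip(tmp_path):
    spec = SimSpec(seed=9, noise_cv=0.05)
    courses = simulate_plate_timecourse(spec)
    path = tmp_path / "plate.tsv"
    write_plate_table(courses, path)
    back = read_plate_table(path)
    assert len(back) == len(courses)
    orig = {c.well_id: c for c in courses}
    for c in back:
        o = orig[c.well_id]
        assert c.system_id == o.system_id and c.is_blank == o.is_blank
        assert np.allclose(c.times, o.times)
        assert np.allclose(c.fluorescence, o.fluorescence)
        assert np.allclose(c.absorbance, o.absorbance)
        assert c.concentration == pytest.approx(o.concentration)
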