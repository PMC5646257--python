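"""Founder back-calculation chain, dilution utilities and growth-rate fit."""

import math

import numpy as np
import pytest

from straindrift.errors import CensoredInputError, DataError
from straindrift.founder import (
    BackCalcInput,
    ConversionConstants,
    ReactorGeometry,
    back_calculate_founders,
    cells_from_protein,
    count_doublings,
    dilution_rate,
    fit_generation_time,
    infer_volume,
    producer_cells,
    total_area,
    two_sig_figs,
    washout_expected,
)
from straindrift.synthetic import ReactorParams, simulate_reactor


class TestChainComponents:
    @pytest.mark.parametrize(
        "geom,expected",
        [
            (ReactorGeometry(), 336.0),
            (ReactorGeometry(n_slides=0), 231.0),
            (ReactorGeometry(100, 10, 3), 130.0),
        ],
    )
    def test_total_area(self, geom, expected):
        assert total_area(geom) == pytest.approx(expected)

    def test_cells_from_protein_reference_point(self):
        cells = cells_from_protein(4.5, 336.0, ConversionConstants())
        assert cells == pytest.approx(5.4e9, rel=0.01)

    def test_zero_protein_zero_cells_and_linearity(self):
        c = ConversionConstants()
        assert cells_from_protein(0.0, 336.0, c) == 0.0
        assert cells_from_protein(9.0, 336.0, c) == pytest.approx(
            2 * cells_from_protein(4.5, 336.0, c)
        )

    def test_protein_per_cell_scaling(self):
        base = cells_from_protein(4.5, 336.0, ConversionConstants(protein_per_cell=278.0))
        halved = cells_from_protein(4.5, 336.0, ConversionConstants(protein_per_cell=556.0))
        assert halved == pytest.approx(base / 2, rel=1e-12)

    def test_producer_fraction(self):
        assert producer_cells(5.44e9, 0.24) == pytest.approx(4.1e9, rel=0.01)
        assert producer_cells(100.0, 0.0) == 100.0
        assert producer_cells(100.0, 0.5) == 50.0

    @pytest.mark.parametrize(
        "elapsed,gen,mode,expected",
        [
            (120.0, 6.8, "nearest", 18.0),
            (13.6, 6.8, "nearest", 2.0),
            (120.0, 6.8, "floor", 17.0),
            (120.0, 6.8, "continuous", 120.0 / 6.8),
        ],
    )
    def test_count_doublings(self, elapsed, gen, mode, expected):
        assert count_doublings(elapsed, gen, mode) == pytest.approx(expected)


class TestBackCalculation:
    def test_reference_chain(self):
        result = back_calculate_founders(BackCalcInput(4.5, 120.0, 6.8, 0.24))
        assert result.total_cells == pytest.approx(5.4e9, rel=0.01)
        assert result.producer_cells == pytest.approx(4.1e9, rel=0.01)
        assert result.doublings == 18
        assert result.founder_cells == pytest.approx(1.6e4, rel=0.02)
        assert two_sig_figs(result.founder_cells) == "1.6e+04"

    def test_zero_elapsed_time_identity(self):
        r = back_calculate_founders(
            BackCalcInput(4.5, 0.0, 6.8, 0.0), rounding="continuous"
        )
        assert r.founder_cells == pytest.approx(r.producer_cells)

    def test_censored_input_refused(self):
        with pytest.raises(CensoredInputError):
            back_calculate_founders(BackCalcInput(1.0, 120.0, 6.8, 0.0))

    def test_forward_backward_round_trip(self):
        """Back-calculation inverts the forward reactor model exactly in
        continuous mode at any pre-capacity time point."""
        params = ReactorParams(carrying_capacity=1e6)
        founders = 1.6e4
        traj = simulate_reactor(params, founders, duration=168.0, sample_every=12.0)
        geom = ReactorGeometry(params.vessel_area, params.slide_area, params.n_slides)
        constants = ConversionConstants(params.protein_per_cell, params.detection_limit)
        checked = 0
        for _, row in traj[~traj["censored"]].iterrows():
            r = back_calculate_founders(
                BackCalcInput(row["protein_ug_per_cm2"], row["time_h"],
                              params.generation_time, 0.0),
                geom, constants, rounding="continuous",
            )
            assert r.founder_cells == pytest.approx(founders, rel=1e-9)
            checked += 1
        assert checked >= 3

    def test_monotone_in_time_and_protein(self):
        base = BackCalcInput(4.5, 120.0, 6.8, 0.0)
        later = BackCalcInput(4.5, 140.0, 6.8, 0.0)
        richer = BackCalcInput(9.0, 120.0, 6.8, 0.0)
        f = lambda i: back_calculate_founders(i, rounding="continuous").founder_cells
        assert f(later) < f(base) < f(richer)


class TestDilution:
    def test_volume_inference_and_consistency(self):
        volume = infer_volume(0.70, 0.112)
        assert volume == pytest.approx(375.0)
        assert dilution_rate(0.95, volume) == pytest.approx(0.152, abs=5e-4)

    def test_inverse_identity(self):
        assert dilution_rate(0.7, 375.0) * 375.0 / 60.0 == pytest.approx(0.7)

    def test_washout_advisory(self):
        # ln(2)/6.8 = 0.102 1/h, so D = 0.112 exceeds the maximal growth
        # rate (biofilm retention, not planktonic growth, sustains the reactor)
        assert washout_expected(0.112, 6.8)
        assert not washout_expected(0.09, 6.8)


class TestGenerationTimeFit:
    def test_noiseless_exponential_recovered_exactly(self):
        t = np.arange(0, 40, 4.0)
        od = 0.02 * 2 ** (t / 6.8)
        assert fit_generation_time(t, od) == pytest.approx(6.8, rel=1e-9)

    def test_noisy_mean_within_five_percent(self):
        rng = np.random.default_rng(99)
        t = np.arange(0, 40, 4.0)
        estimates = []
        for _ in range(100):
            od = 0.2 * 2 ** (t / 6.8) + rng.normal(0, 0.01, size=t.size)
            estimates.append(fit_generation_time(t, od, window=(0, t.size)))
        assert np.mean(estimates) == pytest.approx(6.8, rel=0.05)

    def test_flat_series_is_an_error(self):
        t = np.arange(0, 40, 4.0)
        with pytest.raises(DataError, match="growth"):
            fit_generation_time(t, np.full(t.size, 0.5))

    def test_too_few_points_is_an_error(self):
        with pytest.raises(DataError):
            fit_generation_time([0, 4], [0.1, 0.2])

    def test_window_search_ignores_lag_and_stationary_phases(self):
        t = np.arange(0, 80, 4.0)
        od = np.where(t < 12, 0.02, np.minimum(0.02 * 2 ** ((t - 12) / 6.8), 1.0))
        est = fit_generation_time(t, od)
        assert est == pytest.approx(6.8, rel=0.05)
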