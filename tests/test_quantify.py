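import math

import numpy as np
import pandas as pd
import pytest

from stedcount import (cluster_density, dimer_peak_width,
                       estimate_labeling_efficiency, forward_fractions,
                       invert_dimer_fraction)

GRID = np.arange(0.05, 1.0, 0.1)  # excludes the degenerate LE = 0.5


class TestLabelingEfficiency:
    def test_symmetric_fractions_give_half(self):
        assert estimate_labeling_efficiency(0.3, 0.3).le == pytest.approx(0.5)

    def test_direct_ratio(self):
        assert estimate_labeling_efficiency(0.25, 0.75).le == pytest.approx(0.75)

    def test_zero_sum_rejected(self):
        with pytest.raises(ValueError):
            estimate_labeling_efficiency(0.0, 0.0)

    def test_se_propagation_matches_monte_carlo(self, rng):
        f1, f2, s1, s2 = 0.4, 0.6, 0.03, 0.04
        est = estimate_labeling_efficiency(f1, f2, s1, s2)
        draws = [estimate_labeling_efficiency(a, b).le
                 for a, b in zip(rng.normal(f1, s1, 20000),
                                 rng.normal(f2, s2, 20000))]
        assert est.se == pytest.approx(np.std(draws), rel=0.05)


class TestDimerPeakWidth:
    def test_analytic_value(self):
        assert dimer_peak_width(1.0) == pytest.approx(math.sqrt(2.0))

    def test_monomer_scale_value(self):
        assert dimer_peak_width(0.9) == pytest.approx(0.9 * math.sqrt(2.0))

    def test_ratio_identity_for_random_widths(self, rng):
        for w in rng.uniform(0.01, 50.0, 50):
            assert dimer_peak_width(w) / w == pytest.approx(math.sqrt(2.0))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dimer_peak_width(0.0)


class TestForwardFractions:
    def test_no_dimers(self):
        f1, f2, f3 = forward_fractions(0.0, 0.3)
        assert (f1, f2, f3) == pytest.approx((0.7, 0.3, 0.0))

    def test_direct_substitution_factor2(self):
        """Cross-checked by enumerating a dimer's four label states:
        at F=LE=0.5, P(both)=1/8, P(exactly one)=2/8+monomer 1/4 = 0.5,
        P(none)=1/8+1/4 = 0.375."""
        assert forward_fractions(0.5, 0.5, "factor2") == pytest.approx(
            (0.375, 0.5, 0.125))
        assert sum(forward_fractions(0.5, 0.5, "factor2")) == pytest.approx(1.0)

    def test_direct_substitution_as_printed(self):
        fracs = forward_fractions(0.5, 0.5, "as_printed")
        assert sum(fracs) == pytest.approx(1.0 - 0.5 * 0.25)

    def test_factor2_sums_to_one_on_grid(self):
        for F in GRID:
            for le in GRID:
                assert sum(forward_fractions(F, le, "factor2")) == pytest.approx(
                    1.0, abs=1e-14)

    def test_as_printed_deficit_is_exact(self):
        for F in GRID:
            for le in GRID:
                total = sum(forward_fractions(F, le, "as_printed"))
                assert total == pytest.approx(1.0 - F * le * (1.0 - le), abs=1e-14)

    def test_f3_monotone_in_both_arguments(self):
        prev_rows = None
        f3 = np.array([[forward_fractions(F, le)[2] for le in GRID] for F in GRID])
        assert (np.diff(f3, axis=0) > 0).all()  # increasing in F
        assert (np.diff(f3, axis=1) > 0).all()  # increasing in LE

    def test_domain_validated(self):
        with pytest.raises(ValueError):
            forward_fractions(1.2, 0.5)


class TestInvertDimerFraction:
    def test_round_trip_is_identity_on_grid(self):
        for convention in ("factor2", "as_printed"):
            for F in GRID:
                for le in GRID:
                    f1, f2, f3 = forward_fractions(F, le, convention)
                    est = invert_dimer_fraction(f1, f2, f3, le, convention)
                    for value in est.per_peak:
                        assert value == pytest.approx(F, abs=1e-9)
                    assert est.mean == pytest.approx(F, abs=1e-9)

    def test_degenerate_second_peak_at_half_le(self):
        """Under factor2 at LE=1/2 the second peak carries no information
        about F; the other two peaks still invert exactly."""
        f1, f2, f3 = forward_fractions(0.5, 0.5, "factor2")
        est = invert_dimer_fraction(f1, f2, f3, 0.5, "factor2")
        assert est.degenerate[1]
        assert math.isnan(est.per_peak[1])
        assert est.per_peak[0] == pytest.approx(0.5)
        assert est.per_peak[2] == pytest.approx(0.5)
        assert est.mean == pytest.approx(0.5)

    def test_reported_aggregate_of_printed_per_peak_values(self):
        """Aggregating per-peak estimates 56%, 52%, 58% gives a 55% mean at
        integer precision, with ~7% SE from the per-peak 8/5/17% SEs."""
        mean = np.mean([0.56, 0.52, 0.58])
        assert round(100 * mean) == 55
        se = math.sqrt(0.08 ** 2 + 0.05 ** 2 + 0.17 ** 2) / 3
        assert 100 * se == pytest.approx(7.0, abs=1.0)

    def test_clipping_flagged(self):
        est = invert_dimer_fraction(0.01, 0.2, 0.9, 0.6)
        assert est.clipped[2]  # f3=0.9 at LE=0.6 implies F=2.5 -> clipped to 1
        assert est.per_peak[2] == 1.0

    def test_unidentifiable_le_rejected(self):
        with pytest.raises(ValueError):
            invert_dimer_fraction(0.2, 0.5, 0.3, 0.0)
        with pytest.raises(ValueError):
            invert_dimer_fraction(0.2, 0.5, 0.3, 1.0)

    def test_se_propagation_matches_monte_carlo(self, rng):
        F, le = 0.55, 0.6
        f1, f2, f3 = forward_fractions(F, le)
        ses = (0.02, 0.03, 0.015)
        est = invert_dimer_fraction(f1, f2, f3, le, fraction_ses=ses, le_se=0.02)
        draws = []
        for _ in range(4000):
            d = invert_dimer_fraction(
                max(f1 + rng.normal(0, ses[0]), 0.0),
                max(f2 + rng.normal(0, ses[1]), 0.0),
                max(f3 + rng.normal(0, ses[2]), 0.0),
                float(np.clip(le + rng.normal(0, 0.02), 0.05, 0.95)))
            draws.append(d.mean)
        # no-correlation aggregation is conservative: SE >= observed spread / 2
        assert est.mean_se == pytest.approx(np.std(draws), rel=0.6)


class TestClusterDensity:
    def test_exact_division(self):
        spots = pd.DataFrame({"row": np.arange(12), "col": np.arange(12)})
        mask = np.ones((20, 20), bool)  # 400 px at 100 nm -> 4 um^2
        report = cluster_density(spots, mask, pixel_size_nm=100.0)
        assert report.area_um2 == pytest.approx(4.0)
        assert report.density_per_um2 == pytest.approx(3.0)

    def test_empty_table(self):
        report = cluster_density(pd.DataFrame(columns=["row", "col"]),
                                 np.ones((10, 10), bool), 100.0)
        assert report.density_per_um2 == 0.0

    def test_spots_outside_mask_not_counted(self):
        spots = pd.DataFrame({"row": [1, 5], "col": [1, 5]})
        mask = np.zeros((10, 10), bool)
        mask[:3, :3] = True
        report = cluster_density(spots, mask, 100.0)
        assert report.n_spots == 1

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            cluster_density(pd.DataFrame(columns=["row", "col"]),
                            np.zeros((5, 5), bool), 100.0)

    def test_recovers_simulated_density(self, rng):
        """Known emitter density recovered within 3 SE on a clean field."""
        from stedcount import SimulationConfig, build_spot_table, make_receptor_field
        cfg = SimulationConfig(seed=33, noise="none", field_size=(256, 256))
        n_units = 150
        image, _ = make_receptor_field(n_units, 0.0, 1.0, cfg)
        spots = build_spot_table(image, prominence=10.0)
        mask = np.ones(cfg.field_size, bool)
        report = cluster_density(spots, mask, cfg.pixel_size_nm)
        true_density = n_units / report.area_um2
        se = math.sqrt(n_units) / report.area_um2
        assert abs(report.density_per_um2 - true_density) < 3 * se
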