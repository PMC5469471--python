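"""Moisture standardization, moving averages, and community strata."""

import numpy as np
import pytest

import meadowpack as mp
from meadowpack.io import Dataset, MeadowPair, PlotSample
from meadowpack.stratify import (
    DEFAULT_GRID,
    assign_strata,
    min_plots_filter,
    moving_average_cover,
    standardize_vwc,
)


def _plot(mid, idx, vwc, species=True, bare=10.0):
    return PlotSample(
        meadow_id=mid, transect_index=1, plot_index=idx, vwc_mean=vwc,
        bare_ground_pct=bare, litter_pct=10.0, total_veg_pct=70.0,
        has_species_data=species,
    )


class TestStandardize:
    def test_three_point_example(self):
        axis = standardize_vwc([_plot("A", i, v) for i, v in
                                enumerate([10.0, 20.0, 30.0])])
        assert axis.z.to_numpy() == pytest.approx([-1.0, 0.0, 1.0])

    def test_location_invariance(self):
        vals = [4.0, 9.0, 23.0, 15.0]
        a = standardize_vwc([_plot("A", i, v) for i, v in enumerate(vals)])
        b = standardize_vwc(
            [_plot("A", i, v + 5.0) for i, v in enumerate(vals)]
        )
        assert a.z.to_numpy() == pytest.approx(b.z.to_numpy())

    def test_per_meadow_standardization(self, rng):
        plots = [
            _plot("A", i, v)
            for i, v in enumerate(rng.uniform(5, 15, size=20))
        ] + [
            _plot("B", i, v)
            for i, v in enumerate(rng.uniform(30, 60, size=25))
        ]
        axis = standardize_vwc(plots)
        for mid in ("A", "B"):
            z = axis.z.xs(mid, level="meadow_id").to_numpy()
            assert z.mean() == pytest.approx(0.0, abs=1e-12)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_meadow_warns(self):
        with pytest.warns(UserWarning, match="zero VWC variance"):
            axis = standardize_vwc([_plot("A", i, 12.0) for i in range(4)])
        assert (axis.z.to_numpy() == 0).all()


class TestMovingAverage:
    def test_constant_signal(self, rng):
        z = rng.uniform(-2, 2, size=200)
        curve = moving_average_cover(np.full(200, 40.0), z)
        assert np.nanmin(curve) == pytest.approx(40.0)
        assert np.nanmax(curve) == pytest.approx(40.0)

    def test_empty_window_missing(self):
        curve = moving_average_cover(
            np.array([10.0]), np.array([0.0]), grid=np.array([1.0]),
            window_width=0.25,
        )
        assert np.isnan(curve[0])

    def test_matches_naive_oracle(self, rng):
        z = rng.uniform(-3, 3, size=300)
        cover = rng.uniform(0, 80, size=300)
        curve = moving_average_cover(cover, z, window_width=0.25)
        for i, g in enumerate(DEFAULT_GRID):
            mask = np.abs(z - g) <= 0.125
            if mask.any():
                assert curve[i] == pytest.approx(cover[mask].mean())
            else:
                assert np.isnan(curve[i])

    def test_step_transition_width(self, rng):
        z = np.linspace(-1, 1, 2001)
        cover = np.where(z < 0, 0.0, 50.0)
        grid = np.linspace(-1, 1, 401)
        curve = moving_average_cover(cover, z, grid=grid, window_width=0.25)
        # away from the step the curve is flat at the plateau values
        assert np.nanmax(np.abs(curve[grid < -0.13])) == 0.0
        assert np.nanmin(curve[grid > 0.13]) == pytest.approx(50.0)

    def test_bad_window_fatal(self):
        with pytest.raises(ValueError):
            moving_average_cover(np.ones(3), np.zeros(3), window_width=0.0)


class TestStrata:
    def _axis(self, zs):
        plots = [_plot("A", i, 50.0 + v) for i, v in enumerate(zs)]
        axis = standardize_vwc(plots)
        return axis

    def test_interval_membership(self):
        axis = self._axis([-30, -3, 0, 3, 30])
        strata = assign_strata(axis, breaks=(-0.5, 0.5))
        z = axis.z.to_numpy()
        lab = strata.stratum.to_numpy()
        for zi, li in zip(z, lab):
            if zi < -0.5:
                assert li == "Dry"
            elif zi >= 0.5:
                assert li == "Wet"
            else:
                assert li == "Intermediate"

    def test_boundary_goes_wetter(self):
        import pandas as pd
        from meadowpack.stratify import CommunityStrata, MoistureAxis

        z = pd.Series(
            [0.5, -0.5],
            index=pd.MultiIndex.from_tuples(
                [("A", 1), ("A", 2)], names=["meadow_id", "plot_index"]
            ),
        )
        axis = MoistureAxis(z=z, meadow_stats=None)
        strata = assign_strata(axis, breaks=(-0.5, 0.5))
        assert strata.stratum_for("A", 1) == "Wet"
        assert strata.stratum_for("A", 2) == "Intermediate"

    def test_uniform_proportions(self, rng):
        import pandas as pd
        from meadowpack.stratify import MoistureAxis

        z = pd.Series(
            rng.uniform(-3, 3, size=30000),
            index=pd.MultiIndex.from_arrays(
                [["A"] * 30000, range(30000)],
                names=["meadow_id", "plot_index"],
            ),
        )
        strata = assign_strata(MoistureAxis(z=z, meadow_stats=None), (-1.0, 1.0))
        frac = strata.stratum.value_counts(normalize=True)
        for s in ("Dry", "Intermediate", "Wet"):
            assert frac[s] == pytest.approx(1 / 3, abs=0.02)

    def test_monotone_affine_invariance(self, rng):
        vals = rng.uniform(5, 40, size=30)
        a = standardize_vwc([_plot("A", i, v) for i, v in enumerate(vals)])
        b = standardize_vwc(
            [_plot("A", i, 3.0 * v + 7.0) for i, v in enumerate(vals)]
        )
        sa = assign_strata(a).stratum.to_numpy()
        sb = assign_strata(b).stratum.to_numpy()
        assert (sa == sb).all()

    def test_every_plot_assigned_once(self, null_dataset):
        axis = standardize_vwc(null_dataset.plots)
        strata = assign_strata(axis)
        assert len(strata.stratum) == len(null_dataset.plots)
        assert set(strata.stratum.unique()) <= {"Dry", "Intermediate", "Wet"}


class TestMinPlotsFilter:
    def test_two_wet_plots_drops_cell(self):
        # stock meadow has only 2 wet plots; control has plenty
        plots = (
            [_plot("S", i, 10.0 + z, species=True)
             for i, z in enumerate([-2, -1.5, -1.2, 0, 0.1, 2.0, 2.1])]
            + [_plot("C", i, 10.0 + z, species=True)
               for i, z in enumerate([-2, -1.5, -1.2, 0, 0.1, 0.2,
                                      2.0, 2.1, 2.2])]
        )
        ds = Dataset(meadows={}, stock_use={}, plots=plots, subplots=[])
        axis = standardize_vwc(plots)
        strata = assign_strata(axis, breaks=(-0.5, 0.5))
        pair = MeadowPair("P1", "S", "C", 1, 0.0)
        retained = min_plots_filter([pair], strata, ds, required=3)
        wet_s = sum(
            1 for (m, p), s in strata.stratum.items()
            if m == "S" and s == "Wet"
        )
        assert wet_s == 2
        assert ("P1", "Wet") not in retained
        assert ("P1", "All") in retained

    def test_exactly_three_retained(self):
        plots = (
            [_plot("S", i, 10.0 + z) for i, z in
             enumerate([-2, -1.6, -1.4, 1.2, 1.4, 1.6])]
            + [_plot("C", i, 10.0 + z) for i, z in
               enumerate([-2, -1.6, -1.4, 1.2, 1.4, 1.6])]
        )
        ds = Dataset(meadows={}, stock_use={}, plots=plots, subplots=[])
        axis = standardize_vwc(plots)
        strata = assign_strata(axis, breaks=(-0.5, 0.5))
        pair = MeadowPair("P1", "S", "C", 1, 0.0)
        retained = min_plots_filter([pair], strata, ds, required=3)
        assert ("P1", "Dry") in retained and ("P1", "Wet") in retained

    def test_matches_brute_force_recount(self, null_dataset, small_pairs):
        axis = standardize_vwc(null_dataset.plots)
        strata = assign_strata(axis)
        for species_only in (False, True):
            retained = min_plots_filter(
                small_pairs, strata, null_dataset, required=3,
                species_only=species_only,
            )
            # independent recount straight from the raw lists
            expected = set()
            for pair in small_pairs:
                for st in ("Dry", "Intermediate", "Wet", "All"):
                    ok = True
                    for mid in (pair.stock_meadow_id, pair.control_meadow_id):
                        n = 0
                        for p in null_dataset.plots_for(mid):
                            if species_only and not p.has_species_data:
                                continue
                            s = strata.stratum_for(mid, p.plot_index)
                            if st == "All" or s == st:
                                n += 1
                        if n < 3:
                            ok = False
                    if ok:
                        expected.add((pair.pair_id, st))
            assert retained == expected
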