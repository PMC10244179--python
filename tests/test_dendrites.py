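"""Local dendritic events: projection, classification, spatial profiles, rates."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alloptical import GeneratorConfig, make_dendrite_recording
from alloptical.dendrites import (
    classify_event,
    dunns_test,
    event_rate_by_stimulus,
    event_spatial_profile,
    fwhm_of_curve,
    project_mask_to_line,
)

FR = 10.0
UM = 0.5


def _line(n=20):
    return np.column_stack([np.arange(n) * UM, np.full(n, 2.0)])


class TestProjection:
    def test_two_mask_pixels_average_into_one_bin(self):
        line = _line(4)
        mask = np.array([[0.0, 1.5], [0.0, 2.5]])  # both nearest line px 0
        movie = np.zeros((3, 8, 8))
        movie[:, 3, 0] = 1.0  # y=1.5 -> row 3
        movie[:, 5, 0] = 3.0  # y=2.5 -> row 5
        prof, geo = project_mask_to_line(movie, mask, line, UM, FR, transform=False)
        assert np.allclose(prof[0], 2.0)

    def test_single_bright_pixel_lands_in_nearest_bin(self):
        line = _line(10)
        mask = np.array([[3.0, 1.5]])  # nearest line pixel index 6 (x=3.0)
        movie = np.zeros((2, 8, 12))
        movie[:, 3, 6] = 7.0
        prof, _ = project_mask_to_line(movie, mask, line, UM, FR, transform=False)
        assert prof[6, 0] == 7.0
        assert np.all(np.isnan(prof[[0, 1, 2], 0]))  # empty bins flagged

    def test_uniform_movie_gives_flat_dff(self):
        line = _line(6)
        mask = np.vstack([_line(6) + [0.0, dy] for dy in (-0.5, 0.0, 0.5)])
        movie = np.full((600, 10, 10), 4.0)
        prof, _ = project_mask_to_line(movie, mask, line, UM, FR, normalize=False)
        assert np.nanmax(np.abs(prof)) < 1e-9

    def test_mass_conservation_per_frame(self):
        rng = np.random.default_rng(0)
        line = _line(10)
        mask = np.vstack([_line(10) + [0.0, dy] for dy in (-0.5, 0.0, 0.5)])
        movie = rng.uniform(1, 2, size=(4, 10, 12))
        prof, _ = project_mask_to_line(movie, mask, line, UM, FR, transform=False)
        counts = np.full(10, 3.0)
        mask_px = np.round(mask / UM).astype(int)
        total_mask = movie[:, mask_px[:, 1], mask_px[:, 0]].sum(axis=1)
        assert np.allclose((prof.T * counts).sum(axis=1), total_mask)


class TestClassify:
    GEO = np.arange(21) * 1.0  # 20 µm branch, proximal end at 0
    POS = np.array([4.0, 10.0, 16.0])

    def _call(self, spines, branch_idx):
        branch = np.zeros(21, dtype=bool)
        branch[branch_idx] = True
        return classify_event(spines, branch, self.GEO, self.POS)

    def test_single_spine(self):
        c = self._call([True, False, False], [])
        assert c.event_class == "single-spine"

    def test_local_event(self):
        c = self._call([False, True, True], np.arange(10, 17))
        assert c.event_class == "local"
        assert c.active_interval_um == (10.0, 16.0)

    def test_global_event(self):
        c = self._call([True, True, True], np.arange(21))
        assert c.event_class == "global"

    def test_proximal_activity_blocks_local(self):
        c = self._call([False, True, True], np.r_[np.arange(10, 17), [0, 1]])
        assert c.event_class != "local"

    def test_monotone_never_demotes_local_to_none(self):
        base = self._call([False, True, True], np.arange(10, 17))
        assert base.event_class == "local"
        more = self._call([True, True, True], np.arange(4, 17))
        assert more.event_class in ("local", "global", "single-spine")
        assert more.event_class != "none"


class TestSpatialProfile:
    def test_noiseless_gaussian_fwhm_closed_form(self):
        x = np.arange(0, 40, 0.5)
        prof = np.exp(-((x - 20.0) ** 2) / (2 * 2.0**2))
        ep = event_spatial_profile([(x, prof)])
        assert ep.fwhm_um == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 2.0, abs=0.05)

    def test_fwhm_invariant_to_amplitude_and_translation(self):
        x = np.arange(0, 60, 0.5)
        a = np.exp(-((x - 20.0) ** 2) / (2 * 3.0**2))
        b = 5.0 * np.exp(-((x - 35.0) ** 2) / (2 * 3.0**2))
        fa = event_spatial_profile([(x, a)]).fwhm_um
        fb = event_spatial_profile([(x, b)]).fwhm_um
        assert fa == pytest.approx(fb, abs=0.05)

    def test_symmetric_input_fits_symmetric_profile(self):
        x = np.arange(0, 40, 0.5)
        prof = np.exp(-((x - 20.0) ** 2) / (2 * 2.5**2))
        ep = event_spatial_profile([(x, prof)])
        fine = ep.offset_um
        fit = ep.fit_profile
        # compare the fitted curve to its mirror about the peak offset
        pk = fine[np.argmax(fit)]
        mirrored = np.interp(2 * pk - fine, fine, fit, left=np.nan, right=np.nan)
        ok = np.isfinite(mirrored)
        assert np.nanmax(np.abs(fit[ok] - mirrored[ok])) < 1e-4

    def test_generator_default_width_recovered(self):
        from alloptical.studies import local_event_fwhm

        out = local_event_fwhm(seed=2)
        sigma = GeneratorConfig().local_event_sigma_um
        assert out["value"] == pytest.approx(2 * np.sqrt(2 * np.log(2)) * sigma,
                                             abs=1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            event_spatial_profile([])

    def test_fwhm_of_curve_triangle(self):
        x = np.array([0.0, 1, 2, 3, 4])
        y = np.array([0.0, 0.5, 1.0, 0.5, 0.0])
        assert fwhm_of_curve(x, y) == pytest.approx(2.0)


class TestEventRates:
    @staticmethod
    def _tables(rates_by_stim, n_branches=3, n_trials=4):
        ev_rows, tr_rows = [], []
        trial = 0
        for stim, rate in rates_by_stim.items():
            for _ in range(n_trials):
                tr_rows.append((trial, stim))
                for b in range(n_branches):
                    ev_rows.append((b, trial, rate))
                trial += 1
        return (
            pd.DataFrame(ev_rows, columns=["branch_id", "trial", "n_events"]),
            pd.DataFrame(tr_rows, columns=["trial", "stimulus"]),
        )

    def test_identical_rates_null(self):
        ev, tr = self._tables({"a": 1.0, "b": 1.0, "c": 1.0})
        out = event_rate_by_stimulus(ev, tr)
        assert out["p"] == pytest.approx(1.0)

    def test_kruskal_h_matches_enumeration_oracle(self):
        samples = {
            "a": np.zeros(3),
            "b": np.ones(3),
            "c": np.zeros(3),
        }
        h_obs, _ = stats.kruskal(*samples.values())
        assert h_obs == pytest.approx(8.0)
        # exact permutation oracle: positions of the three 1s among 9 slots
        count = 0
        total = 0
        vals = np.concatenate(list(samples.values()))
        for pos in itertools.combinations(range(9), 3):
            perm = np.zeros(9)
            perm[list(pos)] = 1.0
            h = stats.kruskal(perm[:3], perm[3:6], perm[6:])[0]
            count += h >= h_obs - 1e-9
            total += 1
        assert count / total == pytest.approx(1 / 28)

    def test_inverse_stimulus_hosts_most_events_in_generator(self):
        per_stim = {}
        for seed in range(4):
            cfg = dataclasses.replace(
                GeneratorConfig(), seed=seed, render_movie=True,
                n_local_events=60, n_stim_trials=5, n_blank_trials=5,
            )
            rec = make_dendrite_recording(cfg)
            mt = rec.ground_truth["movie_trials"]
            for stim, g in mt.groupby("stimulus"):
                per_stim.setdefault(stim, []).append(g["n_events"].mean())
        means = {k: np.mean(v) for k, v in per_stim.items()}
        assert max(means, key=means.get) == "inverse"

    def test_dunns_pairwise_detects_separated_group(self):
        rng = np.random.default_rng(0)
        out = dunns_test(
            {"a": rng.normal(0, 1, 15), "b": rng.normal(0, 1, 15),
             "c": rng.normal(5, 1, 15)}
        )
        row_ab = out.query("group_a == 'a' and group_b == 'b'")
        assert row_ab.p.iloc[0] > 0.05
        assert out.query("group_b == 'c' or group_a == 'c'").p.max() < 0.01
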