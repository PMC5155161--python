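import numpy as np
import pandas as pd
import pytest

import spaint
from spaint import analysis
from spaint.analysis import (
    ClusterParams,
    assign_spectra,
    cluster_localizations,
    compute_on_times,
    estimate_mean_on_time,
    localization_density,
    spectral_histogram,
)


def _table(xy, frames=None, **cols):
    df = pd.DataFrame(
        {
            "frame": frames if frames is not None else np.zeros(len(xy), dtype=int),
            "x_px": xy[:, 0],
            "y_px": xy[:, 1],
        }
    )
    for k, v in cols.items():
        df[k] = v
    return df


class TestClustering:
    def test_dense_blob_plus_isolated_noise(self, rng):
        blob = rng.uniform(-0.2, 0.2, size=(15, 2)) + [50.0, 50.0]
        noise = rng.uniform(0, 40, size=(5, 2))
        t = _table(np.vstack([blob, noise]))
        labels = cluster_localizations(t)
        assert (labels[:15] == labels[0]).all() and labels[0] >= 0
        assert (labels[15:] == -1).all()
        # brute-force density check: every blob point has >= 10 neighbors in eps
        from scipy.spatial.distance import cdist

        d = cdist(blob, blob)
        assert ((d <= 0.5).sum(axis=1) >= 10).all()

    def test_sparse_uniform_field_is_all_noise(self, rng):
        t = _table(rng.uniform(0, 102, size=(20, 2)))
        labels = cluster_localizations(t)
        assert (labels == -1).all()

    def test_min_points_one_clusters_everything(self, rng):
        t = _table(rng.uniform(0, 102, size=(20, 2)))
        labels = cluster_localizations(t, ClusterParams(eps_px=0.5, min_points=1))
        assert (labels >= 0).all()

    def test_invariant_under_reordering_and_translation(self, rng):
        pts = np.vstack(
            [rng.normal([30, 30], 0.15, size=(20, 2)), rng.normal([60, 55], 0.15, size=(14, 2))]
        )
        labels = cluster_localizations(_table(pts))
        perm = rng.permutation(len(pts))
        labels_perm = cluster_localizations(_table(pts[perm]))
        # same partition after inverting the permutation
        assert len(set(labels)) == len(set(labels_perm))
        for c in set(labels):
            members = set(np.nonzero(labels == c)[0])
            mapped = {int(np.nonzero(perm == m)[0][0]) for m in members}
            ref = labels_perm[list(mapped)]
            assert len(set(ref)) == 1
        labels_shift = cluster_localizations(_table(pts + [1000.0, -500.0]))
        np.testing.assert_array_equal(labels, labels_shift)

    def test_empty_table_empty_labels(self):
        assert len(cluster_localizations(_table(np.empty((0, 2))))) == 0


class TestSpectralAssignment:
    @pytest.mark.parametrize("lam_true", [560.0, 600.0, 640.0, 680.0])
    def test_unbiased_across_passband(self, lam_true):
        """Assignment bias < 1 nm for site wavelengths across the NR range.

        Sites sit in distinct detector columns so each spectral window sees
        exactly one emitter.
        """
        sites = np.column_stack(
            [8.0 + 6.0 * np.arange(16), np.full(16, 10.0), np.full(16, lam_true)]
        )
        sample = spaint.SampleGeometry(
            kind="bead_field", binding_site_map=sites, binding_rate_per_site=1.5
        )
        stack = spaint.simulate_spaint_stack(
            sample, n_frames=150, spatial_size_px=(20, 112), seed=int(lam_true)
        )
        table = spaint.localize_stack(stack)
        d = stack.dispersion_truth
        model = spaint.CalibrationModel(d.beta0, d.beta1, d.beta2, d.beta3, 0.0, 999)
        out = assign_spectra(table, stack, model)
        lam = out.wavelength_nm.dropna()
        assert len(lam) > 100
        assert lam.mean() == pytest.approx(lam_true, abs=1.0)

    def test_site_wavelength_recovered_on_luv_stack(self, luv_stack, luv_localizations):
        d = luv_stack.dispersion_truth
        model = spaint.CalibrationModel(d.beta0, d.beta1, d.beta2, d.beta3, 0.0, 999)
        out = assign_spectra(luv_localizations, luv_stack, model)
        lam = out.wavelength_nm.dropna()
        assert lam.mean() == pytest.approx(635.0, abs=4.0)
        assert 0.0 < out.attrs["fraction_assigned"] <= 1.0

    def test_window_out_of_bounds_reason_code(self, luv_stack):
        # a localization whose spectral window would leave the detector
        t = _table(np.array([[2.0, float(luv_stack.shape[0]) - 1.0]]), photons=[1000.0])
        d = luv_stack.dispersion_truth
        model = spaint.CalibrationModel(d.beta0, d.beta1, d.beta2, d.beta3, 0.0, 999)
        out = assign_spectra(t, luv_stack, model)
        assert np.isnan(out.wavelength_nm.iloc[0])
        assert out.qc_reason.iloc[0] == "window_oob"


class TestOnTimes:
    def test_single_and_multi_frame_events(self):
        t = _table(
            np.array([[10.0, 10.0], [30.0, 30.0], [30.05, 30.0], [30.0, 30.05]]),
            frames=[0, 4, 5, 6],
        )
        on, ev = compute_on_times(t, frame_period_s=0.05)
        assert sorted(on) == pytest.approx([0.05, 0.15])
        assert len(set(ev)) == 2

    def test_gap_breaks_event(self):
        t = _table(np.array([[10.0, 10.0], [10.0, 10.0]]), frames=[0, 2])
        on, ev = compute_on_times(t, max_gap_frames=0, frame_period_s=0.05)
        assert len(on) == 2
        on_gap, ev_gap = compute_on_times(t, max_gap_frames=1, frame_period_s=0.05)
        assert len(on_gap) == 1 and on_gap[0] == pytest.approx(0.15)

    def test_exponential_on_time_recovered(self, rng):
        """tau_on = 60 ms at 50 ms frames, discretization-corrected within 15%.

        Oracle: events spanning ceil(tau/dt) frames have mean observed on-time
        dt / (1 - exp(-dt/tau)); the estimator inverts that relation.
        """
        tau, dt, n_events = 0.060, 0.05, 800
        taus = rng.exponential(tau, n_events)
        spans = np.maximum(1, np.ceil(taus / dt).astype(int))
        rows, f = [], 0
        for k, span in enumerate(spans):
            x = 5.0 + 7.0 * (k % 100)
            y = 5.0 + 7.0 * (k // 100)
            for s in range(span):
                rows.append((f + s, x, y))
            f += span + 2
        t = pd.DataFrame(rows, columns=["frame", "x_px", "y_px"])
        on, _ = compute_on_times(t, frame_period_s=dt)
        assert len(on) == n_events
        est = estimate_mean_on_time(on, dt)
        assert est == pytest.approx(tau, rel=0.15)


class TestDensityAndHistogram:
    def test_density_arithmetic(self):
        assert localization_density(100, 1.0, 10.0) == pytest.approx(10.0)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            localization_density(10, 0.0, 1.0)

    def test_event_count_linear_in_binding_rate(self):
        """Simulated event counts vs binding rate: linear with R^2 > 0.99."""
        rates = [0.4, 0.8, 1.6, 3.2]
        counts = []
        grid = np.arange(5) * 8.0 + 8.0
        sites = np.column_stack(
            [np.tile(grid, 5), np.repeat(grid, 5), np.full(25, 620.0)]
        )
        for r in rates:
            sample = spaint.SampleGeometry(
                kind="bead_field", binding_site_map=sites, binding_rate_per_site=r
            )
            stack = spaint.simulate_spaint_stack(sample, n_frames=200, seed=21)
            counts.append(stack.ground_truth["event_id"].nunique())
        r2 = np.corrcoef(rates, counts)[0, 1] ** 2
        assert r2 > 0.99

    def test_identical_wavelengths_have_zero_sd(self):
        counts, edges, mean, sd = spectral_histogram(np.full(50, 612.0))
        assert sd == 0.0 and mean == pytest.approx(612.0)
        assert counts.sum() == 50

    def test_two_population_mixture_resolved(self, rng):
        lam = np.concatenate(
            [rng.normal(600.0, 3.0, 400), rng.normal(650.0, 3.0, 400)]
        )
        counts, edges, mean, sd = spectral_histogram(lam)
        centers = 0.5 * (edges[:-1] + edges[1:])
        lo = lam[lam < 625.0]
        hi = lam[lam >= 625.0]
        assert lo.mean() == pytest.approx(600.0, abs=3.0)
        assert hi.mean() == pytest.approx(650.0, abs=3.0)
        # histogram is genuinely bimodal: a dip between the modes
        mid = counts[(centers > 615) & (centers < 635)].max()
        assert mid < 0.3 * counts.max()

    def test_membrane_like_summary_statistics(self, rng):
        lam = rng.normal(602.0, 5.5, 5000)
        _, _, mean, sd = spectral_histogram(lam)
        assert mean == pytest.approx(602.0, abs=0.5)
        assert sd == pytest.approx(5.5, abs=0.3)


class TestClusterSummaries:
    def test_luv_summaries(self, luv_stack, luv_localizations):
        t = luv_localizations
        labels = cluster_localizations(t)
        summaries = analysis.summarize_clusters(t, labels)
        assert len(summaries) >= 10
        diams = np.array([s.diameter_nm for s in summaries])
        assert diams.mean() == pytest.approx(110.0, abs=20.0)
        for s in summaries:
            assert s.n_localizations >= ClusterParams().min_points
            assert s.localizations_per_frame > 0
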