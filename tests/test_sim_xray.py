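"""Simulator: spectrum, phantom, forward projection, PIP sampling, datasets."""

import math

import numpy as np
import pandas as pd
import pytest

from pipshift import sim_xray as sx


def uniform_phantom(m_frac=1.0, r_mm=sx.REF_THICKNESS_MM, shape=(16, 16)):
    thick = np.full(shape, r_mm)
    return sx.Phantom(thick, np.full(shape, m_frac), np.ones(shape, bool), "young")


def constant_atten(m):
    f = lambda e: np.full_like(np.asarray(e, float), m)
    return sx.AttenuationModel(f, f)


def nominal_pips(**over):
    base = dict(tube_current_kev=30.0, exposure_uas=60000.0, relative_exposure=5400.0,
                detector_temp_c=25.0, exposure_time_ms=600.0, organ_dose_mgy=0.012,
                entrance_dose_mgy=6.0, pixel_padding_limit=350.0,
                positioner_angle_deg=0.0, body_thickness_mm=sx.REF_THICKNESS_MM,
                compression_force_n=80.0, focal_spot_mm=0.3)
    base.update(over)
    return sx.PIPVector(**base)


# ---------------------------------------------------------------------------
# spectrum
# ---------------------------------------------------------------------------


class TestSpectrum:
    def test_single_bin_is_delta_at_peak(self):
        sp = sx.make_spectrum(30, 1)
        assert sp.energies.tolist() == [30.0]
        assert sp.weights.tolist() == [1.0]

    def test_weights_normalized(self):
        sp = sx.make_spectrum(30, 8)
        assert sp.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(sp.energies) > 0)

    def test_triangular_formula_hand_computed(self):
        # independent evaluation of the documented shape: centers at
        # peak*(k+1/2)/n, weight proportional to (peak - E_k)
        peak, n = 30.0, 8
        centers = [peak * (k + 0.5) / n for k in range(n)]
        raw = [peak - e for e in centers]
        expected = [r / sum(raw) for r in raw]
        sp = sx.make_spectrum(peak, n)
        np.testing.assert_allclose(sp.energies, centers, rtol=1e-12)
        np.testing.assert_allclose(sp.weights, expected, rtol=1e-12)

    @pytest.mark.parametrize("peak,bins", [(0, 4), (-3, 4), (30, 0)])
    def test_invalid_parameters(self, peak, bins):
        with pytest.raises(sx.InvalidParameterError):
            sx.make_spectrum(peak, bins)


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------


def flood_fill_components(mask):
    """Brute-force 8-connected component count (independent oracle)."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    n = 0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and not seen[i, j]:
                n += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            x, y = a + da, b + db
                            if (0 <= x < mask.shape[0] and 0 <= y < mask.shape[1]
                                    and mask[x, y] and not seen[x, y]):
                                seen[x, y] = True
                                stack.append((x, y))
    return n


class TestPhantom:
    def test_deterministic_for_fixed_seed(self):
        a = sx.make_phantom("young", (64, 64), 5)
        b = sx.make_phantom("young", (64, 64), 5)
        np.testing.assert_array_equal(a.glandular_fraction, b.glandular_fraction)
        np.testing.assert_array_equal(a.thickness_map, b.thickness_map)

    def test_young_denser_than_old_at_matched_seed(self):
        y = sx.make_phantom("young", (64, 64), 1)
        o = sx.make_phantom("old", (64, 64), 1)
        fy = y.glandular_fraction[y.tissue_mask].mean()
        fo = o.glandular_fraction[o.tissue_mask].mean()
        assert fy > fo

    def test_single_connected_component(self):
        ph = sx.make_phantom("old", (64, 64), 7)
        assert flood_fill_components(ph.tissue_mask) == 1

    def test_touches_left_edge_and_invariants(self):
        ph = sx.make_phantom("young", (48, 48), 3)
        assert ph.tissue_mask[:, 0].any()
        assert np.all(ph.thickness_map >= 0)
        assert np.all((ph.glandular_fraction >= 0) & (ph.glandular_fraction <= 1))
        assert np.all(ph.glandular_fraction[~ph.tissue_mask] == 0)

    def test_grid_too_small_rejected(self):
        with pytest.raises(sx.InvalidParameterError):
            sx.make_phantom("young", (8, 8), 0)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


class TestProject:
    def test_zero_attenuation_gives_entrance_intensity(self):
        raw = sx.project(uniform_phantom(), nominal_pips(), sx.make_spectrum(30, 1),
                         constant_atten(0.0))
        np.testing.assert_allclose(raw.pixels, 60.0, rtol=1e-12)

    def test_uniform_closed_form_polychromatic(self):
        m, r, theta = 0.03, 40.0, 30.0
        sp = sx.make_spectrum(28, 8)
        pips = nominal_pips(positioner_angle_deg=theta, body_thickness_mm=r)
        ph = uniform_phantom(r_mm=sx.REF_THICKNESS_MM)
        raw = sx.project(ph, pips, sp, constant_atten(m))
        e0 = sx.E0_PER_UAS * pips.exposure_uas
        expected = (e0 * math.cos(math.radians(theta)) ** 2
                    * np.sum(sp.weights * np.exp(-m * r)))
        np.testing.assert_allclose(raw.pixels, expected, rtol=1e-10)

    @pytest.mark.parametrize("theta", [0.0, 30.0, 60.0])
    def test_cos_squared_ratio_law(self, theta):
        sp = sx.make_spectrum(30, 4)
        ph = uniform_phantom(m_frac=0.5)
        at = sx.AttenuationModel.power_law()
        g0 = sx.project(ph, nominal_pips(positioner_angle_deg=0.0), sp, at).pixels
        gt = sx.project(ph, nominal_pips(positioner_angle_deg=theta), sp, at).pixels
        np.testing.assert_allclose(gt / g0, math.cos(math.radians(theta)) ** 2,
                                   rtol=1e-12)

    def test_monotone_decreasing_in_thickness(self):
        ph = sx.make_phantom("young", (32, 32), 2)
        sp = sx.make_spectrum(30, 8)
        at = sx.AttenuationModel.power_law()
        thin = sx.project(ph, nominal_pips(body_thickness_mm=40.0), sp, at).pixels
        thick = sx.project(ph, nominal_pips(body_thickness_mm=60.0), sp, at).pixels
        inside = ph.tissue_mask
        assert np.all(thick[inside] < thin[inside])
        np.testing.assert_allclose(thick[~inside], thin[~inside])

    def test_monotone_increasing_in_exposure(self):
        ph = uniform_phantom(m_frac=0.5)
        sp = sx.make_spectrum(30, 4)
        at = sx.AttenuationModel.power_law()
        lo = sx.project(ph, nominal_pips(exposure_uas=30000.0), sp, at).pixels
        hi = sx.project(ph, nominal_pips(exposure_uas=60000.0), sp, at).pixels
        assert np.all(hi > lo)

    def test_noise_reproducible_under_seed(self):
        ph = uniform_phantom()
        sp = sx.make_spectrum(30, 4)
        at = sx.AttenuationModel.power_law()
        nm = sx.NoiseModel(gaussian_sd=2.0, poisson_scale=10.0)
        a = sx.project(ph, nominal_pips(), sp, at, nm, seed=9).pixels
        b = sx.project(ph, nominal_pips(), sp, at, nm, seed=9).pixels
        c = sx.project(ph, nominal_pips(), sp, at, nm, seed=10).pixels
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_inverse_square_flag(self):
        ph = uniform_phantom(m_frac=0.0)
        sp = sx.make_spectrum(30, 1)
        at = constant_atten(0.0)
        g_off = sx.project(ph, nominal_pips(), sp, at).pixels
        g_on = sx.project(ph, nominal_pips(), sp, at, inverse_square=True,
                          source_distance_m=2.0).pixels
        np.testing.assert_allclose(g_on, g_off / 4.0, rtol=1e-12)


class TestDisplay:
    def test_air_maps_to_zero_and_opaque_to_255(self):
        pips = nominal_pips()
        sp = sx.make_spectrum(30, 1)
        air = sx.air_intensity(pips, sp)
        raw = sx.RawImage(np.array([[air, 0.0]]))
        disp = sx.to_display(raw, air)
        assert disp[0, 0] == 0 and disp[0, 1] == 255


# ---------------------------------------------------------------------------
# PIP sampling
# ---------------------------------------------------------------------------


class TestSamplePips:
    def test_exact_linear_link_correlates_perfectly(self):
        prof, _ = sx.default_hospitals()
        prof = sx.HospitalProfile(
            prof.name, prof.pip_means, prof.pip_sds,
            derived_links=(("exposure_uas", "entrance_dose_mgy", 1e-4, 0.0),))
        df = sx.sample_pips(prof, 1000, seed=0)
        corr = np.corrcoef(df["exposure_uas"], df["entrance_dose_mgy"])[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_profile_repeats_means(self):
        prof, _ = sx.default_hospitals()
        zero_sds = {f: 0.0 for f in sx.PIP_FIELDS}
        prof = sx.HospitalProfile("Z", prof.pip_means, zero_sds, derived_links=())
        df = sx.sample_pips(prof, 50, seed=1)
        for f in sx.PIP_FIELDS:
            assert df[f].nunique() == 1

    def test_two_profiles_recoverable_by_clustering(self):
        from sklearn.cluster import KMeans
        a, b = sx.default_hospitals()
        xa = sx.sample_pips(a, 2500, seed=1)[list(sx.PIP_FIELDS)].to_numpy()
        xb = sx.sample_pips(b, 2500, seed=2)[list(sx.PIP_FIELDS)].to_numpy()
        x = np.vstack([xa, xb])
        x = (x - x.mean(0)) / x.std(0)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(x)
        truth = np.repeat([0, 1], 2500)
        agree = max((km.labels_ == truth).mean(), (km.labels_ != truth).mean())
        assert agree > 0.99


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def binned_mi(x, y, bins=16):
    """Histogram mutual information between a continuous column and a binary
    label (independent oracle, plug-in estimator)."""
    edges = np.quantile(x, np.linspace(0, 1, bins + 1))
    xb = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, bins - 1)
    joint = np.zeros((bins, 2))
    for xi, yi in zip(xb, y):
        joint[xi, yi] += 1
    joint /= joint.sum()
    px = joint.sum(1, keepdims=True)
    py = joint.sum(0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (px * py))
    return float(np.nansum(terms))


def permutation_mi_threshold(x, y, n_perm=200, seed=0):
    """95th percentile of the binned MI under label permutation."""
    rng = np.random.default_rng(seed)
    null = [binned_mi(x, rng.permutation(y)) for _ in range(n_perm)]
    return np.quantile(null, 0.95)


class TestGenerateDataset:
    def test_counts_and_exact_class_balance(self, small_dataset):
        ds = small_dataset
        assert ds.images.shape == (200, 64, 64)
        assert len(ds.pips) == 200
        for dom in ("A", "B"):
            sub = ds.pips[ds.pips["domain"] == dom]
            assert len(sub) == 100
            assert sub["label"].sum() == 50

    def test_byte_identical_reruns(self, small_dataset):
        cfg = small_dataset.config
        again = sx.generate_dataset(cfg)
        np.testing.assert_array_equal(small_dataset.images, again.images)
        pd.testing.assert_frame_equal(small_dataset.pips, again.pips)

    def test_label_independent_of_pips(self):
        # labels are assigned by row position while PIP rows are i.i.d. draws,
        # so every column's MI with the label should sit inside the
        # permutation null
        table = sx.sample_pips(sx.default_hospitals()[0], 5000, seed=5)
        labels = np.repeat([1, 0], 2500)
        for col in ("exposure_uas", "body_thickness_mm", "positioner_angle_deg"):
            x = table[col].to_numpy()
            assert binned_mi(x, labels) <= permutation_mi_threshold(x, labels)
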