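import math

import numpy as np
import pytest

from ventpack.core import Mask3D, Volume3D
from ventpack.spherepack import cluster_metrics, pack_spheres
from ventpack.texture import (
    TextureConfig,
    catalog_feature_names,
    catalog_manifest,
    extract_catalog,
    firstorder_features,
    shape_features,
    wavelet_subbands,
)


class TestFirstOrder:
    def test_constant_roi_limits(self):
        arr = np.full((4, 4, 2), 7.0)
        roi = np.ones((4, 4, 2), dtype=bool)
        f = firstorder_features(arr, roi)
        assert f["Mean"] == 7.0
        assert f["Variance"] == 0.0
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0

    def test_range_statistics(self):
        arr = np.zeros((10, 10, 1))
        arr.ravel()[:100] = np.arange(1, 101)
        roi = np.ones((10, 10, 1), dtype=bool)
        f = firstorder_features(arr, roi)
        assert f["Mean"] == pytest.approx(50.5)
        assert f["Range"] == pytest.approx(99.0)
        assert f["Median"] == pytest.approx(50.5)

    def test_random_roi_matches_direct_statistics(self, rng):
        arr = rng.normal(10, 4, (6, 6, 3))
        roi = rng.random((6, 6, 3)) > 0.3
        roi[0, 0, 0] = True
        f = firstorder_features(arr, roi)
        x = arr[roi]
        assert f["Mean"] == pytest.approx(x.mean(), rel=1e-12)
        assert f["Variance"] == pytest.approx(x.var(), rel=1e-12)
        assert f["Energy"] == pytest.approx((x**2).sum(), rel=1e-12)
        assert f["Skewness"] == pytest.approx(
            ((x - x.mean()) ** 3).mean() / x.std() ** 3, rel=1e-10
        )
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt((x**2).mean()), rel=1e-12)


class TestShape:
    def test_single_voxel_zero_axes(self):
        arr = np.zeros((5, 5, 5), dtype=bool)
        arr[2, 2, 2] = True
        f = shape_features(Mask3D(arr))
        assert f["MajorAxisLength"] == 0.0
        assert f["Maximum3DDiameter"] == 0.0

    def test_two_voxels_closed_form(self):
        # two voxels 10 mm apart on one axis: population variance 25 mm^2
        arr = np.zeros((5, 1, 1), dtype=bool)
        arr[1, 0, 0] = arr[3, 0, 0] = True
        f = shape_features(Mask3D(arr, (5.0, 5.0, 5.0)))
        assert f["MajorAxisLength"] == pytest.approx(20.0)
        assert f["Maximum3DDiameter"] == pytest.approx(10.0)

    def test_rotation_invariance_of_major_axis(self):
        arr = np.zeros((9, 9, 9), dtype=bool)
        arr[2:7, 4, 4] = True
        rot = np.zeros((9, 9, 9), dtype=bool)
        rot[4, 2:7, 4] = True
        a = shape_features(Mask3D(arr))
        b = shape_features(Mask3D(rot))
        assert a["MajorAxisLength"] == pytest.approx(b["MajorAxisLength"])
        assert a["VoxelVolume"] == b["VoxelVolume"]

    def test_eigen_oracle_on_random_blob(self, rng):
        arr = rng.random((7, 7, 4)) > 0.5
        arr[0, 0, 0] = True
        spacing = (2.0, 3.0, 5.0)
        f = shape_features(Mask3D(arr, spacing))
        pts = np.argwhere(arr) * np.asarray(spacing)
        lam = np.sort(np.linalg.eigvalsh(np.cov(pts.T, bias=True)))[::-1]
        assert f["MajorAxisLength"] == pytest.approx(4 * math.sqrt(max(lam[0], 0)))
        assert f["LeastAxisLength"] == pytest.approx(4 * math.sqrt(max(lam[2], 0)))


class TestWavelet:
    def test_constant_image_zero_detail(self):
        arr = np.full((8, 8, 3), 11.0)
        bands = wavelet_subbands(arr, "haar")
        assert np.allclose(bands.LH, 0)
        assert np.allclose(bands.HL, 0)
        assert np.allclose(bands.HH, 0)
        assert bands.LL.shape == arr.shape

    def test_vertical_step_energy_in_hl_only(self):
        # step across the second in-plane axis = a vertical edge
        arr = np.zeros((8, 8, 1))
        arr[:, 4:, 0] = 10.0
        bands = wavelet_subbands(arr, "haar")
        assert (bands.HL**2).sum() > 0
        assert np.allclose(bands.LH, 0)
        assert np.allclose(bands.HH, 0)

    def test_haar_step_matches_direct_filter(self):
        """Single-level haar SWT of a 1-D step: the detail coefficient is
        (high-pass filter) . (signal window) at each position."""
        arr = np.zeros((1, 4, 1))
        arr[0, :, 0] = [0.0, 0.0, 6.0, 6.0]
        bands = wavelet_subbands(arr, "haar")
        # haar dec_hi = [-1, 1]/sqrt(2) (pywt convention), periodized shift
        import pywt

        (cA, cD) = pywt.swt(np.array([0.0, 0.0, 6.0, 6.0]), "haar", level=1)[0]
        # the slice is padded to two identical rows, so the row-direction
        # low-pass contributes a factor sqrt(2)
        assert np.allclose(bands.HL[0, :, 0], np.sqrt(2) * cD)
        assert np.allclose(bands.LL[0, :, 0], np.sqrt(2) * cA)

    def test_linearity(self, rng):
        arr = rng.normal(size=(6, 6, 2))
        b1 = wavelet_subbands(arr, "coif1")
        b3 = wavelet_subbands(3.0 * arr, "coif1")
        for name in ("LL", "LH", "HL", "HH"):
            assert np.allclose(3.0 * b1[name], b3[name], atol=1e-10)

    def test_odd_shapes_handled(self, rng):
        arr = rng.normal(size=(7, 9, 2))
        bands = wavelet_subbands(arr, "haar")
        assert bands.LL.shape == arr.shape


class TestCatalog:
    def test_counts_and_order(self):
        names = catalog_feature_names()
        assert len(names) == 496
        assert sum(n.startswith("wavelet-") for n in names) == 376
        assert sum(n.startswith("shape_") for n in names) == 14
        assert sum(n.startswith("custom_") for n in names) == 12
        assert len(set(names)) == 496

    def test_manifest_covers_catalog(self):
        man = catalog_manifest()
        assert [m["name"] for m in man] == catalog_feature_names()
        families = {m["family"] for m in man}
        assert families == {"firstorder", "glcm", "glrlm", "glszm", "gldm",
                            "ngtdm", "shape", "custom"}

    def test_extraction_deterministic_and_complete(self, demo_case):
        roi = demo_case.truth_thoracic
        packing = pack_spheres(demo_case.truth_defect)
        metrics = cluster_metrics(packing, roi.count)
        fv1 = extract_catalog(demo_case.he3, roi, metrics, 7.5, TextureConfig())
        fv2 = extract_catalog(demo_case.he3, roi, metrics, 7.5, TextureConfig())
        assert fv1.values == fv2.values
        assert fv1.names == catalog_feature_names()
        assert fv1["custom_VDP_percent"] == 7.5
        assert fv1["custom_CDD1"] == metrics.cdd1

    def test_missing_defect_metrics_sentinel(self, demo_case):
        with pytest.warns(UserWarning, match="custom features"):
            fv = extract_catalog(demo_case.he3, demo_case.truth_thoracic, None, None)
        assert math.isnan(fv["custom_VDCP_percent"])
        assert math.isnan(fv["custom_VDP_percent"])
        assert len(fv) == 496
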