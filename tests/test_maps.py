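"""Phantom generation, voxel-wise map fitting, comparison protocol, NIfTI I/O."""

import numpy as np
import pytest

from t2relax import (
    QuantMap,
    compare_to_reference,
    fit_map,
    make_phantom,
    read_stack,
    timing_harness,
    write_quantmap,
)
from t2relax.maps import PHANTOM_TES


class TestPhantom:
    def test_truth_within_configured_range_and_monotone_depth(self):
        truth, _ = make_phantom((32, 32), sigma=0.0, rng=0)
        vals = truth.t2_map[truth.mask]
        assert vals.min() >= 20.0 and vals.max() <= 60.0
        # depth-wise stratification: T2 grows with radius (bone -> surface)
        rows, cols = truth.mask.shape
        yy, xx = np.mgrid[0:rows, 0:cols]
        r = np.hypot((yy - (rows - 1) / 2) / rows, (xx - (cols - 1) / 2) / cols)
        order = np.argsort(r[truth.mask])
        t2_sorted = truth.t2_map[truth.mask][order]
        assert np.all(np.diff(t2_sorted) >= -1e-9)

    def test_seeded_reproducibility(self):
        _, a = make_phantom((24, 24), sigma=50.0, rng=5)
        _, b = make_phantom((24, 24), sigma=50.0, rng=5)
        np.testing.assert_array_equal(a.stack, b.stack)

    def test_seven_echo_scheme(self):
        truth, _ = make_phantom((24, 24), sigma=0.0, rng=0)
        np.testing.assert_allclose(truth.te, PHANTOM_TES)
        assert truth.te[0] == 10.0 and truth.te[-1] == 70.0

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_phantom((8, 8))


@pytest.fixture(scope="module")
def noise_free():
    return make_phantom((24, 24), sigma=0.0, rng=1)


class TestFitMap:
    @pytest.mark.parametrize("method", ["lse", "olse"])
    def test_noise_free_recovery(self, noise_free, method):
        truth, obs = noise_free
        fitted = fit_map(obs, method=method)
        m = obs.mask
        np.testing.assert_allclose(fitted.t2_map[m], truth.t2_map[m], rtol=1e-5)
        assert np.all(np.isnan(fitted.t2_map[~m]))
        assert fitted.meta["n_fallback"] == 0

    def test_nclse_noise_free_recovery_with_zero_sigma(self, noise_free):
        truth, obs = noise_free
        fitted = fit_map(obs, method="nclse", sigma=0.0)
        m = obs.mask
        np.testing.assert_allclose(fitted.t2_map[m], truth.t2_map[m], rtol=1e-6)

    def test_single_voxel_mask(self, noise_free):
        truth, obs = noise_free
        one = np.zeros_like(obs.mask)
        i, j = np.argwhere(obs.mask)[0]
        one[i, j] = True
        sub = QuantMap(stack=obs.stack, te=obs.te, mask=one)
        fitted = fit_map(sub, method="lse")
        assert np.isfinite(fitted.t2_map[i, j])
        assert np.isnan(fitted.t2_map[~one]).all()

    def test_mask_equivariance(self, noise_free):
        # fitting a sub-mask equals the restriction of the full fit
        truth, obs = noise_free
        full = fit_map(obs, method="lse")
        half = obs.mask.copy()
        half[:, half.shape[1] // 2:] = False
        sub = QuantMap(stack=obs.stack, te=obs.te, mask=half)
        part = fit_map(sub, method="lse")
        np.testing.assert_allclose(part.t2_map[half], full.t2_map[half], rtol=1e-12)

    def test_unknown_method_and_missing_requirements(self, noise_free):
        _, obs = noise_free
        with pytest.raises(ValueError):
            fit_map(obs, method="magic")
        with pytest.raises(ValueError):
            fit_map(obs, method="nn")  # no model supplied
        bare = QuantMap(stack=obs.stack, te=obs.te, mask=obs.mask)
        with pytest.raises(ValueError):
            fit_map(bare, method="nclse")  # no sigma anywhere


class TestCompareToReference:
    def test_reference_vs_itself_is_zero(self):
        truth, obs = make_phantom((24, 24), sigma=0.0, rng=2)
        fit = fit_map(obs, method="lse")
        table = compare_to_reference(fit, fit)
        assert table.data.iloc[0].median_arqe == 0.0
        assert table.data.iloc[0].arqe_p97_5 == 0.0

    def test_single_voxel_rqe(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[8, 8] = True
        stack = np.ones((16, 16, 5))
        te = np.arange(10.0, 60.0, 10.0)
        pred = QuantMap(stack=stack, te=te, mask=mask,
                        t2_map=np.where(mask, 62.0, np.nan), method="nn")
        ref = QuantMap(stack=stack, te=te, mask=mask,
                       t2_map=np.where(mask, 50.0, np.nan), method="lse")
        table = compare_to_reference(pred, ref)
        assert table.data.iloc[0].median_rqe == pytest.approx(24.0)
        assert table.data.iloc[0].n == 1

    def test_mask_mismatch_rejected(self):
        truth, obs = make_phantom((24, 24), sigma=0.0, rng=3)
        fit = fit_map(obs, method="lse")
        other = QuantMap(stack=obs.stack, te=obs.te, mask=~obs.mask,
                         t2_map=np.zeros_like(fit.t2_map), method="lse")
        with pytest.raises(ValueError):
            compare_to_reference(fit, other)

    def test_concatenation_across_specimens(self):
        maps = [make_phantom((20, 20), sigma=0.0, rng=s) for s in (4, 5)]
        fits = [fit_map(obs, method="lse") for _, obs in maps]
        table = compare_to_reference(fits, fits)
        assert table.data.iloc[0].n == sum(m[0].mask.sum() for m in maps)


class TestTimingHarness:
    def test_reports_mean_over_repeats(self):
        _, obs = make_phantom((16, 16), sigma=0.0, rng=6)
        out = timing_harness(obs, {"lse": {}}, repeats=3)
        assert set(out) == {"lse"} and out["lse"] > 0

    def test_empty_method_list(self):
        _, obs = make_phantom((16, 16), sigma=0.0, rng=6)
        assert timing_harness(obs, {}, repeats=1) == {}


class TestNiftiRoundTrip:
    def test_bit_exact_roundtrip(self, tmp_path):
        import json

        import nibabel as nib

        truth, obs = make_phantom((24, 24), sigma=20.0, rng=7)
        fitted = fit_map(obs, method="lse")
        paths = write_quantmap(fitted, tmp_path)
        back = np.asarray(nib.load(paths["T2"]).dataobj)
        np.testing.assert_array_equal(back, fitted.t2_map)
        # full stack round trip through read_stack
        stack_path = tmp_path / "stack.nii.gz"
        nib.save(nib.Nifti1Image(obs.stack, np.eye(4)), str(stack_path))
        qm = read_stack(stack_path, paths["tes"])
        np.testing.assert_array_equal(qm.stack, obs.stack)
        np.testing.assert_allclose(qm.te, obs.te)
        np.testing.assert_array_equal(qm.meta["affine"], np.eye(4))
        assert json.loads(paths["tes"].read_text()) == list(obs.te)
        assert paths["report"].exists()
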