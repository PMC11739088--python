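"""MIND descriptor: convolutional form vs direct definition, invariances."""

import numpy as np
import pytest

from sctkit.mind import MINDConfig, N8_OFFSETS, mind_descriptor, mind_loss, patch_distance
from sctkit.nn import Tensor
from sctkit.nn.functional import mind_descriptor_t, mind_loss_t
from sctkit.phantom import PhantomSpec, generate_pair
from sctkit.preprocess import mr_to_net, ct_to_net


def direct_patch_distance(img: np.ndarray, offset, patch_size: int = 3) -> np.ndarray:
    """Literal double-loop sum of squared patch differences (interior only
    valid; boundary handled by index clipping like the replicate pad)."""
    h, w = img.shape
    r = patch_size // 2
    dy, dx = offset

    def at(y, x):
        return img[min(max(y, 0), h - 1), min(max(x, 0), w - 1)]

    out = np.zeros_like(img, dtype=float)
    for y in range(h):
        for x in range(w):
            s = 0.0
            for py in range(-r, r + 1):
                for px in range(-r, r + 1):
                    yy = min(max(y + py, 0), h - 1)
                    xx = min(max(x + px, 0), w - 1)
                    s += (img[yy, xx] - at(yy + dy, xx + dx)) ** 2
            out[y, x] = s
    return out


def direct_mind(img: np.ndarray, cfg: MINDConfig = MINDConfig()) -> np.ndarray:
    """From-scratch descriptor implementing the definition literally."""
    dp = np.stack([direct_patch_distance(img, off, cfg.patch_size) for off in cfg.offsets])
    v = dp.mean(axis=0)
    v = np.maximum(v, max(cfg.variance_floor * v.mean(), 1e-12))
    desc = np.exp(-dp / v)
    if cfg.normalization == "max_one":
        desc /= desc.max(axis=0, keepdims=True)
    else:
        desc /= len(cfg.offsets)
    return desc


class TestPatchDistance:
    def test_constant_image_gives_zero(self):
        assert np.allclose(patch_distance(np.full((10, 10), 3.0), (1, 0)), 0.0)

    @pytest.mark.parametrize("offset", [(1, 0), (0, 1), (-1, 1), (1, 1)])
    def test_convolution_equals_direct_double_loop(self, rng, offset):
        img = rng.normal(size=(12, 12))
        conv = patch_distance(img, offset)
        direct = direct_patch_distance(img, offset)
        assert np.abs(conv - direct)[2:-2, 2:-2].max() < 1e-6

    def test_single_bright_pixel_hand_case(self):
        """One bright pixel on zeros, 3x3 patch, offset (1,0): the distance at
        a pixel counts how often the bright pixel enters exactly one of the
        two compared patches."""
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        dp = patch_distance(img, (1, 0))
        direct = direct_patch_distance(img, (1, 0))
        assert np.allclose(dp, direct, atol=1e-9)
        # the squared-difference image has a 1 at (3,4) and (4,4); a pixel's
        # distance counts how many of those fall inside its 3x3 box
        assert dp[2, 4] == pytest.approx(1.0)   # box sees (3,4) only
        assert dp[5, 4] == pytest.approx(1.0)   # box sees (4,4) only
        assert dp[3, 4] == pytest.approx(2.0)   # box sees both
        assert dp[4, 4] == pytest.approx(2.0)
        assert dp[2, 1] == pytest.approx(0.0)   # far away: identical patches

    def test_patch_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            patch_distance(np.zeros((2, 2)), (1, 0))


class TestDescriptor:
    def test_constant_image_all_channels_one_under_max_norm(self):
        desc = mind_descriptor(np.full((12, 12), 5.0))
        assert np.allclose(desc, 1.0)

    def test_affine_intensity_invariance(self, rng):
        img = rng.normal(size=(16, 16))
        d1 = mind_descriptor(img)
        d2 = mind_descriptor(4.0 * img + 17.0)
        assert np.abs(d1 - d2).max() < 1e-5

    def test_matches_from_scratch_oracle(self, rng):
        img = rng.normal(size=(14, 14))
        assert np.abs(mind_descriptor(img) - direct_mind(img)).max() < 1e-6

    def test_channels_in_unit_interval_with_max_one(self, rng):
        desc = mind_descriptor(rng.normal(size=(16, 16)))
        assert desc.min() > 0.0 and desc.max() <= 1.0
        assert np.allclose(desc.max(axis=0), 1.0)

    def test_sum_inv_n_normalization(self, rng):
        cfg = MINDConfig(normalization="sum_inv_n")
        desc = mind_descriptor(rng.normal(size=(12, 12)), cfg)
        assert desc.max() <= 1.0 / 8 + 1e-12

    def test_translation_equivariance_on_interior(self, rng):
        img = rng.normal(size=(20, 20))
        shifted = np.roll(img, 2, axis=1)
        d = mind_descriptor(img)
        ds = mind_descriptor(shifted)
        assert np.abs(np.roll(d, 2, axis=2) - ds)[:, 4:-4, 4:-4].max() < 1e-10


class TestLoss:
    def test_identical_images_zero(self, rng):
        img = rng.normal(size=(12, 12))
        assert mind_loss(img, img) == 0.0

    def test_affine_restyle_is_nearly_free(self, rng):
        img = rng.normal(size=(16, 16))
        assert mind_loss(img, 3.0 * img + 100.0) <= 1e-5

    def test_geometry_perturbation_costs_more_than_restyle(self, phantom_spec):
        """Same-geometry cross-modality pair scores lower than a geometry-
        perturbed one: the loss responds to structure, not style."""
        mr, ct, _ = generate_pair(phantom_spec, 0)
        a = mr_to_net(mr)
        b = ct_to_net(ct)
        b_perturbed = np.roll(b, 3, axis=0)
        assert mind_loss(a, b) < mind_loss(a, b_perturbed)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            mind_loss(np.zeros((8, 8)), np.zeros((9, 9)))


class TestDifferentiableMirror:
    def test_tensor_descriptor_equals_numpy(self, rng):
        img = rng.normal(size=(12, 12))
        t = mind_descriptor_t(Tensor(img[None, None]))
        assert np.abs(t.data[0] - mind_descriptor(img)).max() < 1e-6

    def test_tensor_loss_equals_numpy(self, rng):
        a, b = rng.normal(size=(2, 12, 12))
        lt = mind_loss_t(Tensor(a[None, None]), Tensor(b[None, None])).item()
        assert lt == pytest.approx(mind_loss(a, b), abs=1e-9)

    def test_loss_gradient_matches_finite_differences(self, rng):
        a = Tensor(rng.normal(size=(1, 1, 8, 8)), requires_grad=True)
        b = Tensor(rng.normal(size=(1, 1, 8, 8)))
        mind_loss_t(a, b).backward()
        eps = 1e-6
        i = (0, 0, 3, 4)
        a.data[i] += eps
        up = mind_loss_t(Tensor(a.data), b).item()
        a.data[i] -= 2 * eps
        dn = mind_loss_t(Tensor(a.data), b).item()
        a.data[i] += eps
        assert a.grad[i] == pytest.approx((up - dn) / (2 * eps), abs=1e-6)
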