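"""Phantom generator: determinism, discrepancy bookkeeping, dose properties."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, special

from sctkit.phantom import (
    BACKGROUND,
    GAS,
    PhantomSpec,
    generate_cohort,
    generate_dose,
    generate_pair,
    generate_structures,
)


def test_fixed_seed_is_bit_identical(phantom_spec):
    mr1, ct1, lm1 = generate_pair(phantom_spec, 0)
    mr2, ct2, lm2 = generate_pair(phantom_spec, 0)
    assert np.array_equal(mr1.values, mr2.values)
    assert np.array_equal(ct1.values, ct2.values)
    assert np.array_equal(lm1.labels, lm2.labels)


def test_zero_discrepancy_gives_identical_gas_sets():
    spec = PhantomSpec(grid_size=64, discrepancy_level=0.0, seed=3)
    _, _, lm = generate_pair(spec)
    assert np.array_equal(lm.labels == GAS, lm.mr_labels == GAS)
    assert lm.n_unique_gas == 0


def test_half_discrepancy_flags_exactly_half_the_pockets():
    spec = PhantomSpec(grid_size=64, discrepancy_level=0.5, n_gas_pockets=8, seed=7)
    _, _, lm = generate_pair(spec)
    assert len(lm.gas_pockets) == 8
    assert lm.n_unique_gas == 4
    # the two views differ only where modality-unique gas was painted
    diff = lm.labels != lm.mr_labels
    assert diff.any()
    assert np.all((lm.labels[diff] == GAS) | (lm.mr_labels[diff] == GAS))


def test_ct_values_within_clip_range_and_mr_nonnegative(phantom_pair):
    mr, ct, _ = phantom_pair
    assert ct.values.min() >= -1024.0 and ct.values.max() <= 3071.0
    assert mr.values.min() >= 0.0


def test_single_body_component_and_single_spine(phantom_pair):
    _, _, lm = phantom_pair
    body = lm.labels != BACKGROUND
    _, n_body = ndimage.label(body)
    assert n_body == 1
    _, n_spine = ndimage.label(lm.labels == 5)
    assert n_spine == 1


def test_invalid_spec_rejected():
    with pytest.raises(ValueError):
        generate_pair(PhantomSpec(grid_size=8))
    with pytest.raises(ValueError):
        generate_pair(PhantomSpec(discrepancy_level=1.5))


class TestDose:
    def test_max_equals_prescription_and_nonnegative(self, phantom_spec, phantom_pair):
        _, _, lm = phantom_pair
        dose = generate_dose(phantom_spec, lm, prescribed_max_gy=25.0)
        assert dose.values.max() == pytest.approx(25.0)
        assert dose.values.min() >= 0.0

    def test_absent_target_label_raises(self, phantom_spec, phantom_pair):
        _, _, lm = phantom_pair
        with pytest.raises(ValueError):
            generate_dose(phantom_spec, lm, target_label=99)

    def test_integral_matches_truncated_gaussian_quadrature(self, phantom_spec, phantom_pair):
        """With gas attenuation off, the dose is a pure sum of Gaussians whose
        grid integral must match the closed-form truncated-Gaussian integral
        (product of erf terms per blob) within 1%."""
        _, _, lm = phantom_pair
        dose = generate_dose(phantom_spec, lm, gas_attenuation=0.0, prescribed_max_gy=25.0)

        # reconstruct blob parameters from the same seeded stream the generator uses
        rng = np.random.default_rng([phantom_spec.seed & 0x7FFFFFFF, 4])
        ys, xs = np.nonzero(lm.labels == 3)
        n = lm.labels.shape[0]
        mm = phantom_spec.spacing_mm
        analytic = 0.0
        blobs = []
        for _ in range(3):
            k = rng.integers(0, len(ys))
            cy, cx = float(ys[k]), float(xs[k])
            sy = rng.uniform(8.0, 15.0) / mm
            sx = rng.uniform(8.0, 15.0) / mm
            amp = rng.uniform(0.5, 1.0)
            blobs.append((cy, cx, sy, sx, amp))

        def trunc_integral(c, s):  # integral of exp(-0.5((x-c)/s)^2) over pixel centres' span
            a, b = -0.5 - c, (n - 0.5) - c
            return s * np.sqrt(np.pi / 2) * (special.erf(b / (s * np.sqrt(2))) - special.erf(a / (s * np.sqrt(2))))

        unscaled_max_field = np.zeros((n, n))
        yy, xx = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float), indexing="ij")
        for cy, cx, sy, sx, amp in blobs:
            unscaled_max_field += amp * np.exp(-0.5 * (((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2))
            analytic += amp * trunc_integral(cy, sy) * trunc_integral(cx, sx)
        scale = 25.0 / unscaled_max_field.max()
        assert dose.values.sum() == pytest.approx(scale * analytic, rel=0.01)

    def test_gas_attenuation_lowers_dose_near_gas(self, phantom_spec, phantom_pair):
        _, _, lm = phantom_pair
        plain = generate_dose(phantom_spec, lm, gas_attenuation=0.0)
        att = generate_dose(phantom_spec, lm, gas_attenuation=0.3)
        # normalized to the same max; total energy near gas is removed
        assert att.values.sum() != plain.values.sum()


def test_structures_nested_and_nonempty(phantom_pair):
    _, _, lm = phantom_pair
    s = generate_structures(lm)
    assert s["GTV"].any() and s["kidney"].any() and s["spine"].any()
    assert np.all(s["PTV"][s["GTV"]])  # PTV contains GTV


class TestCohort:
    def test_counts_and_manifest(self, tmp_path):
        spec = PhantomSpec(grid_size=32, seed=5, discrepancy_level=0.5)
        manifest = generate_cohort(spec, 3, 1, 2, tmp_path, write_dose=False)
        assert len(manifest) == 6
        assert (manifest["split"] == "train").sum() == 3
        assert (manifest["split"] == "test").sum() == 2
        on_disk = pd.read_csv(tmp_path / "manifest.csv")
        assert len(on_disk) == 6

    def test_same_seed_identical_manifests(self, tmp_path):
        spec = PhantomSpec(grid_size=32, seed=5)
        m1 = generate_cohort(spec, 2, 1, 2, tmp_path / "a", write_dose=False)
        m2 = generate_cohort(spec, 2, 1, 2, tmp_path / "b", write_dose=False)
        assert m1.drop(columns=["mr_path", "ct_path", "dose_path", "dose_mr_path"]).equals(
            m2.drop(columns=["mr_path", "ct_path", "dose_path", "dose_mr_path"])
        )

    def test_group_split_is_half_half_of_test(self, tmp_path):
        spec = PhantomSpec(grid_size=32, seed=5, discrepancy_level=0.5)
        manifest = generate_cohort(spec, 1, 1, 4, tmp_path, write_dose=False)
        test_groups = manifest.loc[manifest["split"] == "test", "group"]
        assert (test_groups == 1).sum() == 2 and (test_groups == 2).sum() == 2
        assert (manifest.loc[manifest["split"] != "test", "group"] == 0).all()
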