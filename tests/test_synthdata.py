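"""Tests of the synthetic feature-table and phantom-volume generators."""

import numpy as np
import pytest

from radstab.stability import icc3, repeatability
from radstab.synthdata import (
    PhantomSpec,
    Protocol,
    VarianceComponents,
    calibrated_measurements,
    clinical_layout,
    generate_phantom_volume,
    make_study_fixture,
    phantom_layout,
    rider_layout,
    simulate_feature_table,
)

SPHERE_VOLUME = 4.0 / 3.0 * np.pi * 18.5**3  # 37 mm sphere, ~26,522 mm^3


class TestSimulateFeatureTable:
    def test_deterministic_for_fixed_seed(self):
        layout = rider_layout(5)
        comp = VarianceComponents(1.0, 0.5, 1.0)
        a = simulate_feature_table(layout, comp, 3, seed=42)
        b = simulate_feature_table(layout, comp, 3, seed=42)
        assert a.equals(b)
        c = simulate_feature_table(layout, comp, 3, seed=43)
        assert not a["value"].equals(c["value"])

    def test_zero_residual_gives_perfect_icc(self):
        """With no residual noise, consistency ICC is exactly 1 regardless
        of arbitrarily large per-column (rater) offsets."""
        comp = VarianceComponents(subject_var=2.0, rater_var=50.0, residual_var=0.0)
        table = simulate_feature_table(rider_layout(20), comp, 4, seed=1)
        res = repeatability(table)["repeatability[pooled]"]
        assert np.allclose(res["icc"], 1.0, atol=1e-12)

    def test_closed_form_recovery_half(self):
        """subject_var == residual_var -> mean estimated ICC ~ 0.5.

        200 independent features on a 2-column layout act as 200 Monte-
        Carlo replicates; the mean must sit within 3 MC standard errors
        (and the spec's +-0.02 band) of sigma_s^2/(sigma_s^2+sigma_e^2)."""
        comp = VarianceComponents(subject_var=1.0, rater_var=0.3, residual_var=1.0)
        table = simulate_feature_table(rider_layout(300), comp, 200, seed=7)
        est = repeatability(table)["repeatability[pooled]"]["icc"].to_numpy()
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 0.5) < max(3 * se, 0.02)

    def test_rater_offsets_leave_icc_unchanged(self):
        comp = VarianceComponents(1.0, 0.0, 1.0)
        table = simulate_feature_table(clinical_layout(30), comp, 2, seed=5)
        base = repeatability_free_icc(table)
        bumped = table.copy()
        offsets = {p: 100.0 * i for i, p in enumerate(bumped["protocol"].unique())}
        bumped["value"] = bumped["value"] + bumped["protocol"].map(offsets)
        assert np.allclose(repeatability_free_icc(bumped), base, atol=1e-10)

    @pytest.mark.parametrize(
        "kwargs, message",
        [
            (dict(n_features=0), "n_features"),
            (dict(n_features=2, subjects=1), "subjects"),
        ],
    )
    def test_bad_counts_named_in_error(self, kwargs, message):
        comp = VarianceComponents(1.0, 0.0, 1.0)
        n_features = kwargs.get("n_features", 2)
        layout = rider_layout(kwargs.get("subjects", 5))
        with pytest.raises(ValueError, match=message):
            simulate_feature_table(layout, comp, n_features, seed=0)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError, match="residual_var"):
            VarianceComponents(1.0, 0.0, -0.1)


def repeatability_free_icc(table):
    """Helper: per-feature ICC with protocols as columns (k=3)."""
    out = []
    for _, sub in table.groupby("feature"):
        m = sub.pivot_table(index="subject", columns="protocol", values="value")
        out.append(icc3(m.to_numpy()).icc)
    return np.array(out)


class TestCalibratedMeasurements:
    @pytest.mark.parametrize("target", [0.95, 0.85, 0.5, 0.0, -0.3])
    def test_sample_icc_is_exact(self, target):
        m = calibrated_measurements(np.random.default_rng(3), 40, 3, target, rater_sd=1.0)
        assert icc3(m).icc == pytest.approx(target, abs=1e-10)


class TestPhantomVolume:
    def test_noise_free_intensities(self, noise_free_phantom):
        vol, mask = noise_free_phantom
        assert vol.values.max() == pytest.approx(4 * 100.0)
        assert vol.values[0, 0, 0] == 100.0  # corner: pure background
        outside_far = vol.values[mask.values == 0]
        assert outside_far.min() == 100.0

    def test_mask_volume_matches_analytic_sphere(self, noise_free_phantom):
        _, mask = noise_free_phantom
        measured = mask.values.sum() * mask.voxel_volume()
        # one supersampled-voxel shell around the sphere surface
        shell = 4 * np.pi * 18.5**2 * max(mask.spacing) / 3.0
        assert abs(measured - SPHERE_VOLUME) < shell

    def test_deterministic_and_noise_only_differs(self):
        spec = PhantomSpec()
        proto = Protocol("P5", 300, 2.0, 0.86)
        v1, m1 = generate_phantom_volume(spec, proto, 1, seed=9)
        v1b, _ = generate_phantom_volume(spec, proto, 1, seed=9)
        v2, m2 = generate_phantom_volume(spec, proto, 2, seed=9)
        assert np.array_equal(v1.values, v1b.values)
        assert np.array_equal(m1.values, m2.values)
        # different timepoint: same deterministic signal, different noise
        clean, _ = generate_phantom_volume(
            PhantomSpec(noise_reference=0.0), proto, 1, seed=9
        )
        d1 = v1.values - clean.values
        d2 = v2.values - clean.values
        assert not np.array_equal(d1, d2)
        assert abs(d1.mean()) < 1.0 and abs(d2.mean()) < 1.0

    def test_noise_std_scales_inverse_sqrt_exposure(self):
        """Empirical noise std follows 1/sqrt(mA x slice thickness):
        log-log regression slope within 5% of -0.5."""
        spec = PhantomSpec()
        clean_cache = {}
        products, stds = [], []
        for i, (ma, th) in enumerate([(100, 2.0), (100, 5.0), (200, 2.0), (200, 5.0), (300, 2.0), (300, 5.0)]):
            proto = Protocol(f"P{i + 1}", ma, th, 0.86)
            noisy, _ = generate_phantom_volume(spec, proto, 1, seed=11)
            if th not in clean_cache:
                clean_cache[th] = generate_phantom_volume(
                    PhantomSpec(noise_reference=0.0), proto, 1, seed=11
                )[0].values
            resid = noisy.values - clean_cache[th]
            products.append(ma * th)
            stds.append(resid.std())
        slope = np.polyfit(np.log(products), np.log(stds), 1)[0]
        assert slope == pytest.approx(-0.5, rel=0.05)

    def test_sphere_larger_than_fov_rejected(self):
        spec = PhantomSpec(interior_length=30.0)
        with pytest.raises(ValueError, match="does not fit"):
            generate_phantom_volume(spec, Protocol("P1", 100, 2.0, 0.86), 1, 0)


class TestStudyFixtures:
    def test_phantom_layout_has_36_slots(self):
        assert phantom_layout().n_slots == 36

    def test_phantom_fixture_slot_labels(self):
        slots = make_study_fixture("phantom", seed=0, spec=PhantomSpec(interior_length=48.0))
        assert len(slots) == 36
        labels = {(s.scanner, s.protocol.name, s.timepoint) for s in slots}
        assert len(labels) == 36
        assert {s.scanner for s in slots} == {"scanner1", "scanner2", "scanner3"}
        assert {s.protocol.name for s in slots} == {f"P{i}" for i in range(1, 7)}
        # GE scanner reconstructs thin slices at 2.5 mm
        ge = [s for s in slots if s.scanner == "scanner3" and s.protocol.name == "P1"]
        assert ge[0].protocol.slice_thickness_mm == 2.5

    def test_clinical_fixture_shape_and_truth(self):
        fx = make_study_fixture("clinical", seed=1)
        assert fx.table["subject"].nunique() == 104
        assert set(fx.table["protocol"].unique()) == {"BLDCT5", "WBCECT2", "NCCTT2"}
        assert len(fx.volumes) == 104
        assert (fx.truth["kind"] == "volume_proxy").sum() == 6
        assert len(fx.truth) == 60
        # volumes in the plausible clinical range
        assert fx.volumes.between(14, 486).all()

    def test_rider_fixture_shape(self):
        fx = make_study_fixture("rider", seed=1)
        assert fx.table["subject"].nunique() == 32
        assert sorted(fx.table["timepoint"].unique()) == [1, 2]

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError, match="clinical.*phantom.*rider"):
            make_study_fixture("nope", seed=0)
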