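"""Experiment orchestration: repeatability, reproducibility, collinearity,
commonality, selection and category summaries on designed fixtures."""

import numpy as np
import pandas as pd
import pytest

from radstab.stability import (
    category_summary,
    clinical_reproducibility,
    commonality,
    feature_correlation_matrix,
    inter_scanner,
    intra_scanner,
    repeatability,
    select_stable,
    volume_collinearity,
)
from radstab.synthdata import (
    VarianceComponents,
    make_clinical_fixture,
    make_rider_fixture,
    phantom_layout,
    rider_layout,
    simulate_feature_table,
)

import oracles


@pytest.fixture(scope="module")
def clinical_fx():
    return make_clinical_fixture(seed=11)


@pytest.fixture(scope="module")
def rider_fx():
    return make_rider_fixture(seed=12)


class TestRepeatability:
    def test_identical_retest_gives_icc_one(self):
        comp = VarianceComponents(1.0, 0.2, 0.5)
        table = simulate_feature_table(rider_layout(6), comp, 5, seed=3)
        # overwrite the retest with the test values: perfect repeatability
        wide = table.pivot_table(
            index=["subject", "scanner", "protocol", "feature"],
            columns="timepoint",
            values="value",
        )
        wide[2] = wide[1]
        dup = wide.stack().rename("value").reset_index()
        res = repeatability(dup)["repeatability[pooled]"]
        assert np.allclose(res["icc"], 1.0, atol=1e-12)

    def test_tiered_rider_classification_counts_exact(self, rider_fx):
        res = repeatability(rider_fx.table)["repeatability[pooled]"]
        merged = res.join(rider_fx.truth)
        counts = merged.groupby("designed_class")["classification"].apply(
            lambda s: (s == s.name).sum() if hasattr(s, "name") else 0
        )
        for cls in ("good", "moderate", "poor"):
            designed = (rider_fx.truth["designed_class"] == cls).sum()
            observed = (res["classification"] == cls).sum()
            assert observed == designed, cls
        # and each feature's estimate equals its designed tier exactly
        assert np.allclose(merged["icc"], merged["true_icc"], atol=1e-9)

    def test_pure_noise_feature_classified_poor(self):
        fx = make_rider_fixture(seed=5, tiers={0.95: 2, 0.0: 1})
        res = repeatability(fx.table)["repeatability[pooled]"]
        assert res.loc["f002", "classification"] == "poor"
        assert res.loc["f002", "icc"] == pytest.approx(0.0, abs=1e-9)

    def test_missing_timepoint_rejected(self, clinical_fx):
        with pytest.raises(ValueError, match="timepoint"):
            repeatability(clinical_fx.table)  # single-timepoint table


class TestReproducibility:
    def test_offset_protocol_column_gives_icc_one(self, clinical_fx):
        """One protocol equal to another plus a constant: the consistency
        ICC of the pair is exactly 1 (column offsets carry no penalty).
        A slope other than 1 would *not* give 1 — consistency is invariant
        to per-column shifts and to one affine map of the whole matrix,
        not to per-column rescaling."""
        table = clinical_fx.table.copy()
        wide = table.pivot_table(index=["subject", "feature"], columns="protocol", values="value")
        wide["WBCECT2"] = wide["BLDCT5"] + 10.0
        table = (
            wide.stack().rename("value").reset_index()
            .assign(scanner="scanner2", timepoint=1)
        )
        res = clinical_reproducibility(table, pair=("BLDCT5", "WBCECT2"))
        assert np.allclose(res["icc"], 1.0, atol=1e-9)

    def test_tiered_clinical_classification_counts_exact(self, clinical_fx):
        res = clinical_reproducibility(clinical_fx.table)
        truth = clinical_fx.truth
        for cls in ("good", "moderate", "poor"):
            designed = (truth["designed_class"] == cls).sum()
            observed = (res["classification"] == cls).sum()
            assert observed == designed, cls

    def test_unknown_protocol_label_listed(self, clinical_fx):
        with pytest.raises(ValueError, match="BLDCT5"):
            clinical_reproducibility(clinical_fx.table, pair=("NOPE", "BLDCT5"))

    def test_subject_permutation_invariance(self, clinical_fx):
        base = clinical_reproducibility(clinical_fx.table)["icc"]
        table = clinical_fx.table.copy()
        subjects = sorted(table["subject"].unique())
        rng = np.random.default_rng(0)
        mapping = dict(zip(subjects, rng.permutation(subjects)))
        table["subject"] = table["subject"].map(mapping)
        permuted = clinical_reproducibility(table)["icc"]
        assert np.allclose(base, permuted, atol=1e-12)

    def test_intra_and_inter_scanner_on_phantom_style_table(self):
        comp = VarianceComponents(2.0, 0.5, 0.5)
        layout = phantom_layout()
        layout = type(layout)(layout.scanners, layout.protocols, 2, 8)
        table = simulate_feature_table(layout, comp, 4, seed=9)
        med_intra, per_intra = intra_scanner(table)
        assert set(per_intra) == {"scanner1", "scanner2", "scanner3"}
        expected = pd.DataFrame({k: v["icc"] for k, v in per_intra.items()}).median(axis=1)
        assert np.allclose(med_intra["icc"], expected, atol=1e-12)
        med_inter, per_inter = inter_scanner(table)
        assert set(per_inter) == {f"P{i}" for i in range(1, 7)}


class TestVolumeCollinearity:
    def test_monotone_and_antitone(self, clinical_fx):
        table = clinical_fx.table[clinical_fx.table["feature"] == "f000"].copy()
        vol_map = clinical_fx.volumes
        sq = table.copy()
        sq["feature"] = "vol_sq"
        sq["value"] = sq["subject"].map(vol_map) ** 2
        neg = table.copy()
        neg["feature"] = "vol_neg"
        neg["value"] = -neg["subject"].map(vol_map)
        res = volume_collinearity(pd.concat([sq, neg]), vol_map)
        assert res.loc["vol_sq", "rho"] == pytest.approx(1.0)
        assert res.loc["vol_neg", "rho"] == pytest.approx(-1.0)

    def test_designed_proxies_flagged(self, clinical_fx):
        res = volume_collinearity(clinical_fx.table, clinical_fx.volumes)
        proxies = clinical_fx.truth.index[clinical_fx.truth["kind"] == "volume_proxy"]
        assert (res.loc[proxies, "rho"] > 0.9).all()
        others = clinical_fx.truth.index[clinical_fx.truth["kind"] == "tier"]
        assert (res.loc[others, "rho"].abs() < 0.9).all()

    def test_against_rank_oracle(self, clinical_fx, rng):
        sub = clinical_fx.table[
            (clinical_fx.table["feature"] == "f000")
            & (clinical_fx.table["protocol"] == "BLDCT5")
        ].set_index("subject")["value"]
        v = clinical_fx.volumes.loc[sub.index]
        rho = oracles.spearman_bruteforce(sub.tolist(), v.tolist())
        res = volume_collinearity(
            clinical_fx.table[clinical_fx.table["feature"] == "f000"], clinical_fx.volumes
        )
        assert res.loc["f000", "rho[BLDCT5]"] == pytest.approx(rho, abs=1e-12)

    def test_missing_volumes_rejected(self, clinical_fx):
        with pytest.raises(ValueError, match="missing"):
            volume_collinearity(clinical_fx.table, clinical_fx.volumes.iloc[:10])


class TestCommonality:
    def test_disjoint_and_identical_sets(self):
        regions = commonality({"A": {"x", "y"}, "B": {"z"}})
        assert regions[frozenset({"A", "B"})]["count"] == 0
        regions = commonality({"A": {"x", "y"}, "B": {"x", "y"}})
        assert regions[frozenset({"A", "B"})]["count"] == 2
        assert regions[frozenset({"A"})]["count"] == 0

    def test_three_sets_hand_enumeration(self):
        a = {1, 2, 3, 4}
        b = {3, 4, 5}
        c = {4, 5, 6}
        regions = commonality({"A": a, "B": b, "C": c})
        assert regions[frozenset({"A", "B", "C"})]["members"] == [4]
        assert regions[frozenset({"A", "B"})]["members"] == [3]
        assert regions[frozenset({"B", "C"})]["members"] == [5]
        assert regions[frozenset({"A"})]["members"] == [1, 2]
        assert regions[frozenset({"C"})]["members"] == [6]
        assert regions[frozenset({"A", "C"})]["members"] == []


class TestSelection:
    @pytest.fixture(scope="class")
    def designed(self):
        """Matched tier structure across the repeatability (rider-style)
        and reproducibility (clinical) groups; the clinical fixture adds 6
        volume proxies (f054-f059) which the rider-style table covers with
        an extra high tier, so the proxies survive step 1 and must be
        removed by the collinearity filter."""
        tiers = {0.95: 18, 0.85: 18, 0.5: 18}
        clin = make_clinical_fixture(seed=21, tiers=dict(tiers))
        rid = make_rider_fixture(seed=22, tiers={**tiers, 0.96: 6})
        rep = repeatability(rid.table)
        rpr = {"clinical[all protocols]": clinical_reproducibility(clin.table)}
        coll = volume_collinearity(clin.table, clin.volumes)
        return clin, rid, rep, rpr, coll

    def test_designed_answer_exact(self, designed):
        clin, rid, rep, rpr, coll = designed
        stable = select_stable(rep, rpr, coll)
        expected = {f"f{i:03d}" for i in range(18)}  # the 0.95/0.95 tier
        assert set(stable.index) == expected
        assert list(stable["median_icc"]) == sorted(stable["median_icc"], reverse=True)

    def test_no_collinearity_filter_keeps_proxies(self, designed):
        _, _, rep, rpr, coll = designed
        stable = select_stable(rep, rpr, collinearity=None)
        expected = {f"f{i:03d}" for i in range(18)} | {f"f{i:03d}" for i in range(54, 60)}
        assert set(stable.index) == expected

    def test_unreachable_threshold_empty(self, designed):
        _, _, rep, rpr, coll = designed
        assert select_stable(rep, rpr, coll, icc_threshold=1.01).empty


class TestCategorySummary:
    def test_worked_example(self):
        stable = pd.DataFrame(
            {"median_icc": [0.9571, 0.9333, 0.9084], "category": ["TA"] * 3}
        )
        out = category_summary(stable)
        assert out.loc["TA", "median_icc"] == 0.933
        assert out.loc["TA", "std"] == 0.024
        assert out.loc["TA", "count"] == 3

    def test_single_member_and_identical_values(self):
        one = pd.DataFrame({"median_icc": [0.95], "category": ["WF"]})
        assert category_summary(one).loc["WF", "std"] == 0.0
        same = pd.DataFrame({"median_icc": [0.9, 0.9, 0.9], "category": ["LOG"] * 3})
        out = category_summary(same)
        assert out.loc["LOG", "median_icc"] == 0.9 and out.loc["LOG", "std"] == 0.0


class TestCorrelationMatrix:
    def test_symmetric_unit_diagonal(self, clinical_fx):
        m = feature_correlation_matrix(clinical_fx.table, top=10)
        assert np.allclose(m, m.T, atol=1e-12)
        assert np.allclose(np.diag(m), 1.0)
        assert (m.abs() <= 1.0 + 1e-12).all().all()

    def test_three_feature_hand_case(self):
        rows = []
        xs = [1.0, 2.0, 3.0, 4.0]
        for i, s in enumerate(["a", "b", "c", "d"]):
            rows.append((s, "sc", "P", 1, "fA", xs[i]))
            rows.append((s, "sc", "P", 1, "fB", xs[i] ** 3))  # monotone in fA
            rows.append((s, "sc", "P", 1, "fC", -xs[i]))
        table = pd.DataFrame(
            rows, columns=["subject", "scanner", "protocol", "timepoint", "feature", "value"]
        )
        m = feature_correlation_matrix(table, features=["fA", "fB", "fC"])
        assert m.loc["fA", "fB"] == pytest.approx(1.0)
        assert m.loc["fA", "fC"] == pytest.approx(-1.0)
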