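"""CSF normalization, disc statistics, group profiles, long tables."""

import numpy as np
import pandas as pd
import pytest

from discsignal import (
    LabelMap,
    Volume,
    aggregate_group_profiles,
    build_long_table,
    disc_signal_stats,
    generate_phantom,
    normalize_to_csf,
    process_subject,
    PhantomConfig,
)
from discsignal.geometry import SubregionPartition
from discsignal.quantification import DiscProfile, NormalizedVolume


def tiny_pair():
    data = np.full((3, 4, 4), 100.0)
    labels = np.zeros((3, 4, 4), dtype=np.int32)
    labels[:, 3, :] = 99  # CSF plane
    data[:, 3, :] = 200.0
    schema = {0: "background", 1: "T1-T2", 99: "csf"}
    return Volume(data, (1.0, 1.0, 1.0)), LabelMap(labels, schema, (1.0, 1.0, 1.0))


def manual_partition(voxels, bins, n_bins=5):
    return SubregionPartition(
        1, n_bins, np.asarray(voxels, dtype=np.int32), np.asarray(bins, dtype=np.int32),
        {0: (1.0, 0.0)}, "image",
    )


class TestNormalize:
    def test_definition(self):
        vol, lab = tiny_pair()
        norm = normalize_to_csf(vol, lab)
        assert norm.csf_mean == 200.0
        assert norm.csf_voxel_count == 12
        assert np.allclose(norm.data[0, 0, 0], 0.5)
        assert abs(norm.data[lab.data == 99].mean() - 1.0) < 1e-12

    def test_scale_invariance(self):
        vol, lab = tiny_pair()
        a = normalize_to_csf(vol, lab)
        b = normalize_to_csf(Volume(vol.data * 3.7, vol.spacing), lab)
        assert np.max(np.abs(a.data - b.data)) < 1e-12

    def test_missing_or_zero_csf(self):
        vol, lab = tiny_pair()
        empty = LabelMap(np.zeros_like(lab.data), lab.label_schema, lab.spacing)
        with pytest.raises(ValueError, match="no CSF"):
            normalize_to_csf(vol, empty)
        zeroed = Volume(np.zeros_like(vol.data), vol.spacing)
        with pytest.raises(ValueError, match="non-positive"):
            normalize_to_csf(zeroed, lab)


class TestDiscStats:
    def test_two_bin_toy(self):
        data = np.zeros((1, 4, 1))
        data[0, :3, 0] = [0.2, 0.4, 0.6]
        norm = NormalizedVolume(data, 1.0, 1)
        part = manual_partition([[0, 0, 0], [0, 1, 0], [0, 2, 0]], [1, 1, 2])
        prof = disc_signal_stats(norm, part, "s", "T1-T2")
        means = prof.per_subregion[5]["mean"]
        assert np.isclose(means[0], 0.3) and np.isclose(means[1], 0.6)
        assert np.isclose(prof.whole_region_mean, 0.4)
        # empty bins carry count 0 and missing mean
        assert prof.per_subregion[5]["n_voxels"].tolist() == [2, 1, 0, 0, 0]
        assert prof.per_subregion[5]["mean"].isna().tolist() == [False, False, True, True, True]

    def test_constant_disc_has_zero_sd(self):
        data = np.full((1, 6, 1), 0.7)
        norm = NormalizedVolume(data, 1.0, 1)
        part = manual_partition([[0, i, 0] for i in range(6)], [1, 1, 2, 2, 3, 3])
        prof = disc_signal_stats(norm, part, "s", "T1-T2")
        sub = prof.per_subregion[5]
        assert np.allclose(sub["mean"].dropna(), 0.7)
        assert np.allclose(sub["sd"].dropna(), 0.0)

    def test_matches_brute_force_accumulation(self, rng):
        """Binned statistics equal an explicit per-voxel accumulation."""
        cfg = PhantomConfig(noise_sigma=5.0, sigma_b=0.0, sigma_e=0.0)
        for seed in range(3):
            vol, lab, _ = generate_phantom(cfg, seed, "control")
            ex = process_subject(vol, lab, "s")
            norm = normalize_to_csf(vol, lab)
            for prof, part in zip(ex.profiles[:4], ex.partitions[:4]):
                acc = {b: [] for b in range(1, 26)}
                for v, b in zip(part.voxels, part.bins):
                    acc[int(b)].append(norm.data[v[0], v[1], v[2]])
                for b in range(1, 26):
                    row = prof.per_subregion[25].iloc[b - 1]
                    if acc[b]:
                        assert np.isclose(row["mean"], np.mean(acc[b]), rtol=0, atol=1e-12)
                        assert np.isclose(row["sd"], np.std(acc[b]), rtol=0, atol=1e-10)
                    else:
                        assert row["n_voxels"] == 0

    def test_weighted_mean_identity(self, noise_free_extraction):
        for prof in noise_free_extraction.profiles:
            sub = prof.per_subregion[5]
            weighted = (sub["mean"] * sub["n_voxels"]).sum() / sub["n_voxels"].sum()
            assert abs(prof.whole_region_mean - weighted) < 1e-9

    def test_fine_coarse_consistency(self, noise_free_extraction):
        for prof in noise_free_extraction.profiles:
            fine, coarse = prof.per_subregion[25], prof.per_subregion[5]
            for k in range(5):
                blk = fine.iloc[5 * k : 5 * (k + 1)]
                w = (blk["mean"] * blk["n_voxels"]).sum() / blk["n_voxels"].sum()
                assert abs(coarse["mean"][k] - w) < 1e-9

    def test_monotone_nucleus_response(self, noise_free_config):
        """Raising only the voxels of bins 2–4 raises exactly those means."""
        vol, lab, _ = generate_phantom(noise_free_config, 0, "control")
        ex = process_subject(vol, lab, "s")
        part = ex.partitions[8]
        prof = ex.profiles[8]
        norm = normalize_to_csf(vol, lab)
        coarse_bins = (part.bins - 1) // 5 + 1
        boosted = vol.data.copy()
        nucleus = part.voxels[(coarse_bins >= 2) & (coarse_bins <= 4)]
        boosted[nucleus[:, 0], nucleus[:, 1], nucleus[:, 2]] += 50.0
        prof2 = process_subject(Volume(boosted, vol.spacing), lab, "s").profiles[8]
        m1, m2 = prof.per_subregion[5]["mean"], prof2.per_subregion[5]["mean"]
        assert (m2[1:4] > m1[1:4]).all()
        assert np.allclose(m2[[0, 4]], m1[[0, 4]], atol=1e-12)

    def test_grid_mismatch_rejected(self):
        norm = NormalizedVolume(np.zeros((1, 2, 2)), 1.0, 1)
        part = manual_partition([[0, 5, 0]], [1])
        with pytest.raises(ValueError, match="grid"):
            disc_signal_stats(norm, part)


def make_profiles(values):
    """values: dict subject -> dict level -> 25 bin means (constant here)."""
    profiles = []
    for sid, levels in values.items():
        for level, mean in levels.items():
            df = pd.DataFrame(
                {"bin": range(1, 26), "mean": mean, "sd": 0.0, "n_voxels": 10}
            )
            df5 = pd.DataFrame(
                {"bin": range(1, 6), "mean": mean, "sd": 0.0, "n_voxels": 50}
            )
            profiles.append(
                DiscProfile(sid, 1, level, mean, 0.0, 250, {25: df, 5: df5})
            )
    return profiles


def manifest_for(subjects):
    return pd.DataFrame(
        {
            "subject_id": list(subjects),
            "group": [("climber" if s.startswith("cl") else "control") for s in subjects],
            "image_path": "x",
            "labelmap_path": "y",
        }
    )


class TestGroupAggregation:
    def test_single_subject_per_group(self):
        profiles = make_profiles({"cl1": {"L1-L2": 0.3}, "co1": {"L1-L2": 0.4}})
        gps = aggregate_group_profiles(profiles, manifest_for(["cl1", "co1"]))
        by = {(g.group, g.level): g for g in gps}
        assert np.allclose(by[("climber", "L1-L2")].median, 0.3)
        assert np.allclose(
            by[("control", "L1-L2")].q75 - by[("control", "L1-L2")].q25, 0.0
        )

    def test_median_of_three(self):
        profiles = make_profiles(
            {"co1": {"L1-L2": 0.2}, "co2": {"L1-L2": 0.3}, "co3": {"L1-L2": 0.7},
             "cl1": {"L1-L2": 0.1}}
        )
        gps = aggregate_group_profiles(profiles, manifest_for(["co1", "co2", "co3", "cl1"]))
        ctrl = [g for g in gps if g.group == "control"][0]
        assert np.allclose(ctrl.median, 0.3)
        assert (ctrl.q25 <= ctrl.median).all() and (ctrl.median <= ctrl.q75).all()

    def test_empty_group_rejected(self):
        profiles = make_profiles({"cl1": {"L1-L2": 0.3}})
        man = manifest_for(["cl1", "co1"])  # control subject has no profiles
        with pytest.raises(ValueError, match="control"):
            aggregate_group_profiles(profiles, man)


class TestLongTable:
    def test_cardinality(self):
        profiles = make_profiles(
            {"cl1": {"L1-L2": 0.3, "L2-L3": 0.4}, "co1": {"L1-L2": 0.5, "L2-L3": 0.6}}
        )
        man = manifest_for(["cl1", "co1"])
        assert len(build_long_table(profiles, man, 5)) == 20
        assert len(build_long_table(profiles, man, 25)) == 100
        assert len(build_long_table(profiles, man, "all")) == 4

    def test_whole_region_cardinality_17_discs(self):
        levels = {f"D{i}": 0.3 for i in range(17)}
        profiles = make_profiles({"cl1": dict(levels), "co1": dict(levels)})
        man = manifest_for(["cl1", "co1"])
        assert len(build_long_table(profiles, man, "all")) == 34

    def test_duplicate_rejected(self):
        profiles = make_profiles({"cl1": {"L1-L2": 0.3}})
        profiles += make_profiles({"cl1": {"L1-L2": 0.3}})
        with pytest.raises(ValueError, match="duplicate"):
            build_long_table(profiles, manifest_for(["cl1"]), 5)

    def test_csv_round_trip_exact(self, tmp_path):
        profiles = make_profiles({"cl1": {"L1-L2": 1 / 3}, "co1": {"L1-L2": 2 / 7}})
        tbl = build_long_table(profiles, manifest_for(["cl1", "co1"]), 5)
        p = tmp_path / "t.csv"
        tbl.to_csv(p, index=False)
        back = pd.read_csv(p, dtype={"subregion": str})
        assert np.array_equal(back["mean_signal"].to_numpy(), tbl["mean_signal"].to_numpy())


def test_pipeline_scale_invariance(noise_free_config):
    """normalize → stats is exactly invariant to global intensity scaling."""
    vol, lab, _ = generate_phantom(noise_free_config, 0, "control")
    ex1 = process_subject(vol, lab, "s")
    ex2 = process_subject(Volume(vol.data * 3.7, vol.spacing), lab, "s")
    for p1, p2 in zip(ex1.profiles, ex2.profiles):
        assert abs(p1.whole_region_mean - p2.whole_region_mean) < 1e-12
        for nb in (5, 25):
            d = np.nanmax(
                np.abs(p1.per_subregion[nb]["mean"] - p2.per_subregion[nb]["mean"])
            )
            assert d < 1e-12
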