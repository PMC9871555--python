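"""Fragment confirmation: matching, replicate support, feature matrices."""

import numpy as np
import pandas as pd
import pytest

from pmifusion import (
    KineticsParams,
    build_feature_matrix,
    filter_by_replicate_support,
    match_fragments,
    organ_membership_summary,
    simulate_cohort,
    standardize,
)
from pmifusion.peaks import UNASSIGNED, FeatureMatrix, assign_to_catalog


def peak_table(rows):
    """rows: (sample_id, migration_s, mass_kda, height)"""
    return pd.DataFrame(
        rows,
        columns=["sample_id", "migration_time_s", "molecular_mass_kda", "peak_height"],
    )


def partition(peaks, catalog):
    """Set of frozensets of (sample, migration) per fragment."""
    groups = {}
    for idx, fid in catalog.assignment.items():
        key = (peaks.at[idx, "sample_id"], peaks.at[idx, "migration_time_s"])
        groups.setdefault(fid, set()).add(key)
    return {frozenset(v) for k, v in groups.items() if k != UNASSIGNED}


def oracle_partition(peaks, tolerance):
    """Exhaustive clustering oracle: merge every pair within tolerance
    (transitively) and verify each cluster is mean-consistent."""
    times = peaks["migration_time_s"].to_numpy()
    n = len(times)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            mid = 0.5 * (times[i] + times[j])
            if abs(times[i] - times[j]) / mid < tolerance:
                parent[find(j)] = find(i)
    clusters = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    for members in clusters.values():
        mean = times[members].mean()
        assert all(abs(times[m] - mean) / mean < tolerance for m in members)
    idx = peaks.index.to_numpy()
    return {
        frozenset(
            (peaks.at[idx[m], "sample_id"], peaks.at[idx[m], "migration_time_s"])
            for m in members
        )
        for members in clusters.values()
    }


def random_separated_instance(rng, tolerance=0.02):
    """<=30 peaks in clusters separated by > 2x tolerance."""
    n_clusters = rng.integers(1, 7)
    centers = [20.0]
    for _ in range(n_clusters - 1):
        centers.append(centers[-1] * (1 + tolerance * rng.uniform(2.5, 8.0)))
    rows, total = [], 0
    for c, center in enumerate(centers):
        k = int(rng.integers(1, 6))
        if total + k > 30:
            k = 30 - total
        for i in range(k):
            t = center * (1 + tolerance * rng.uniform(-0.2, 0.2))
            rows.append((f"s{c}_{i}", t, 50.0, 100.0))
        total += k
        if total >= 30:
            break
    return peak_table(rows)


class TestMatchFragments:
    def test_single_peak_single_fragment(self):
        catalog = match_fragments(peak_table([("a", 20.68, 14.2, 100.0)]))
        assert len(catalog.fragments) == 1
        assert list(catalog.assignment) == [1]

    def test_two_percent_rule_on_reference_migrations(self):
        # 20.68 vs 20.95 s: 1.3% apart -> one fragment
        close = match_fragments(
            peak_table([("a", 20.68, 14.2, 10.0), ("b", 20.95, 14.3, 10.0)])
        )
        assert len(close.fragments) == 1
        # 20.68 vs 21.34 s: 3.2% apart -> two fragments
        far = match_fragments(
            peak_table([("a", 20.68, 14.2, 10.0), ("b", 21.34, 17.6, 10.0)])
        )
        assert len(far.fragments) == 2

    def test_same_sample_peaks_never_merge(self):
        # the instrument resolved both peaks in one electropherogram
        catalog = match_fragments(
            peak_table([("a", 20.95, 15.5, 10.0), ("a", 21.34, 17.6, 10.0)])
        )
        assert len(catalog.fragments) == 2

    def test_fragment_numbering_follows_migration_order(self):
        catalog = match_fragments(
            peak_table(
                [("a", 30.0, 90.0, 5.0), ("b", 20.0, 15.0, 5.0), ("c", 25.0, 40.0, 5.0)]
            )
        )
        assert list(catalog.fragments["mean_migration"]) == [20.0, 25.0, 30.0]
        assert list(catalog.fragments["fragment_id"]) == [1, 2, 3]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle_on_separated_clusters(self, seed):
        rng = np.random.default_rng(seed)
        peaks = random_separated_instance(rng)
        catalog = match_fragments(peaks, 0.02)
        assert partition(peaks, catalog) == oracle_partition(peaks, 0.02)

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_stable_under_input_shuffle(self, seed):
        rng = np.random.default_rng(100 + seed)
        peaks = random_separated_instance(rng)
        shuffled = peaks.sample(frac=1.0, random_state=seed).reset_index(drop=True)
        assert partition(peaks, match_fragments(peaks)) == partition(
            shuffled, match_fragments(shuffled)
        )

    def test_assigned_peaks_respect_tolerance(self):
        rng = np.random.default_rng(42)
        rows = [
            (f"s{i}", 25.0 * (1 + rng.uniform(-0.03, 0.03)), 40.0, 10.0)
            for i in range(40)
        ]
        peaks = peak_table(rows)
        catalog = match_fragments(peaks, 0.02)
        means = catalog.fragments.set_index("fragment_id")["mean_migration"]
        for idx, fid in catalog.assignment.items():
            if fid == UNASSIGNED:
                continue
            dev = abs(peaks.at[idx, "migration_time_s"] - means[fid]) / means[fid]
            assert dev < 0.02

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            match_fragments(peak_table([]))
        with pytest.raises(ValueError):
            match_fragments(peak_table([("a", -1.0, 10.0, 1.0)]))
        with pytest.raises(ValueError):
            match_fragments(peak_table([("a", 20.0, 10.0, 1.0)]), tolerance=0.5)


class TestCatalogRecovery:
    def test_zero_jitter_cohort_recovers_reference_catalog(
        self, zero_noise_cohort, reference_catalog
    ):
        peaks, manifest = zero_noise_cohort
        catalog = match_fragments(peaks, manifest=manifest)
        assert len(catalog.fragments) == 45
        recovered = [catalog.organs_of(f) for f in catalog.fragments["fragment_id"]]
        expected = [frozenset(f.organs) for f in reference_catalog]
        assert recovered == expected

    def test_recovered_migrations_match_reference(
        self, zero_noise_cohort, reference_catalog
    ):
        peaks, manifest = zero_noise_cohort
        catalog = match_fragments(peaks, manifest=manifest)
        np.testing.assert_allclose(
            catalog.fragments["mean_migration"].to_numpy(),
            [f.mean_migration for f in reference_catalog],
            rtol=1e-9,
        )


class TestReplicateSupport:
    def manifest_for(self, samples, organ="kidney", day=0):
        return pd.DataFrame(
            {
                "sample_id": samples,
                "rat_id": [f"r{i}" for i in range(len(samples))],
                "organ": organ,
                "pmi_day": day,
                "cohort": "train",
            }
        )

    def test_fragment_in_all_replicates_is_retained(self):
        samples = [f"s{i}" for i in range(6)]
        peaks = peak_table([(s, 25.0, 40.0, 10.0) for s in samples])
        manifest = self.manifest_for(samples)
        catalog = filter_by_replicate_support(
            match_fragments(peaks), peaks, manifest
        )
        assert len(catalog.fragments) == 1

    def test_fragment_in_at_most_4_of_6_is_removed(self):
        samples = [f"s{i}" for i in range(6)]
        rows = [(s, 25.0, 40.0, 10.0) for s in samples]
        rows += [(s, 30.0, 80.0, 10.0) for s in samples[:4]]  # only 4/6 support
        peaks = peak_table(rows)
        manifest = self.manifest_for(samples)
        catalog = filter_by_replicate_support(
            match_fragments(peaks), peaks, manifest
        )
        assert len(catalog.fragments) == 1
        assert catalog.fragments["mean_migration"].iloc[0] == pytest.approx(25.0)
        # removed fragment's peaks become unassigned
        assert (catalog.assignment == UNASSIGNED).sum() == 4

    def test_support_at_one_timepoint_suffices(self):
        # present 5/6 at day 0 but 0/6 at day 7 -> still retained
        day0 = self.manifest_for([f"a{i}" for i in range(6)], day=0)
        day7 = self.manifest_for([f"b{i}" for i in range(6)], day=7)
        day7["rat_id"] = [f"q{i}" for i in range(6)]
        manifest = pd.concat([day0, day7], ignore_index=True)
        peaks = peak_table([(f"a{i}", 25.0, 40.0, 10.0) for i in range(5)])
        catalog = filter_by_replicate_support(
            match_fragments(peaks), peaks, manifest
        )
        assert len(catalog.fragments) == 1

    def test_zero_noise_simulation_loses_nothing(self, zero_noise_cohort):
        peaks, manifest = zero_noise_cohort
        catalog = match_fragments(peaks, manifest=manifest)
        filtered = filter_by_replicate_support(catalog, peaks, manifest)
        assert len(filtered.fragments) == 45

    def test_small_replicate_groups_warn_and_skip(self):
        samples = [f"s{i}" for i in range(3)]
        peaks = peak_table([(s, 25.0, 40.0, 10.0) for s in samples])
        manifest = self.manifest_for(samples)
        with pytest.warns(UserWarning, match="min_support"):
            catalog = filter_by_replicate_support(
                match_fragments(peaks), peaks, manifest
            )
        assert len(catalog.fragments) == 0


class TestOrganMembershipSummary:
    def test_reference_combinatorics(self, reference_catalog):
        summary = organ_membership_summary(reference_catalog)
        assert summary["total"] == 45
        assert summary["per_organ"] == {
            "lung": 21,
            "liver": 22,
            "kidney": 19,
            "muscle": 23,
        }
        assert summary["shared_by"][4] == 4
        assert summary["shared_by"][3] == 7
        assert summary["shared_by"][2] == 14
        assert summary["exclusive"] == {
            "lung": 3,
            "liver": 7,
            "kidney": 3,
            "muscle": 7,
        }


class TestFeatureMatrix:
    def test_zero_fill_and_max_rule(self):
        samples = [f"s{i}" for i in range(6)]
        rows = [(s, 25.0, 40.0, 100.0) for s in samples]
        rows += [(s, 30.0, 80.0, 50.0) for s in samples[:5]]
        rows.append(("s0", 25.1, 40.0, 250.0))
        peaks = peak_table(rows)
        manifest = TestReplicateSupport().manifest_for(samples)
        catalog = filter_by_replicate_support(match_fragments(peaks), peaks, manifest)
        # plant a duplicate assignment: the extra s0 peak maps to fragment 1
        catalog.assignment.iloc[-1] = 1
        fm = build_feature_matrix(catalog, peaks, manifest, "kidney")
        assert fm.X.shape == (6, 2)
        assert fm.X.loc["s0", 1] == 250.0  # taller duplicate kept
        assert fm.X.loc["s5", 2] == 0.0  # undetected fragment -> 0

    def test_default_cohort_shapes(self, zero_noise_cohort):
        peaks, manifest = zero_noise_cohort
        catalog = match_fragments(peaks, manifest=manifest)
        fm = build_feature_matrix(catalog, peaks, manifest, "kidney")
        assert fm.X.shape == (84, 19)  # 19 kidney fragments
        assert (fm.X.to_numpy() > 0).all()  # no dropout at zero noise
        assert set(fm.y) == set(manifest["pmi_day"])

    def test_missing_sample_raises(self, zero_noise_cohort):
        peaks, manifest = zero_noise_cohort
        catalog = match_fragments(peaks, manifest=manifest)
        ghost = manifest.iloc[:1].assign(
            sample_id="ghost", rat_id="ghost_rat", organ="kidney"
        )
        bad_manifest = pd.concat([manifest, ghost], ignore_index=True)
        with pytest.raises(ValueError, match="ghost"):
            build_feature_matrix(catalog, peaks, bad_manifest, "kidney")


class TestAssignToCatalog:
    def test_external_peaks_assigned_to_training_fragments(
        self, reference_catalog, default_design
    ):
        kin = KineticsParams(seed=21).zero_noise()
        peaks, manifest = simulate_cohort(default_design, reference_catalog, kin)
        catalog = match_fragments(peaks, manifest=manifest)
        ext_peaks, ext_manifest = simulate_cohort(
            default_design, reference_catalog, kin, cohort="external", external=True
        )
        assignment = assign_to_catalog(catalog, ext_peaks, ext_manifest)
        assert (assignment != UNASSIGNED).all()
        # zero jitter: each external peak lands on the fragment with its
        # exact reference migration time
        means = catalog.fragments.set_index("fragment_id")["mean_migration"]
        for idx, fid in assignment.items():
            assert ext_peaks.at[idx, "migration_time_s"] == pytest.approx(means[fid])

    def test_unmatched_peaks_are_dropped(self):
        peaks = peak_table([(f"s{i}", 25.0, 40.0, 10.0) for i in range(3)])
        catalog = match_fragments(peaks)
        stray = peak_table([("x", 35.0, 120.0, 10.0)])
        assignment = assign_to_catalog(catalog, stray)
        assert (assignment == UNASSIGNED).all()


class TestStandardize:
    def build(self, X, cohort="train"):
        frame = pd.DataFrame(X, columns=[1, 2])
        frame.index = [f"{cohort}{i}" for i in range(len(frame))]
        meta = pd.DataFrame(
            {"rat_id": frame.index, "organ": "lung", "cohort": cohort},
            index=frame.index,
        )
        y = pd.Series(0, index=frame.index)
        return FeatureMatrix(frame, y, meta, "lung")

    def test_train_columns_become_zscores(self):
        train = self.build([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        train_t, _, _ = standardize(train, [])
        np.testing.assert_allclose(train_t.X[1].mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(train_t.X[1].std(ddof=0), 1.0)
        # constant column passes through centered
        np.testing.assert_allclose(train_t.X[2].to_numpy(), 0.0)

    def test_external_round_trips_through_scaler(self):
        train = self.build([[1.0, 5.0], [2.0, 6.0], [3.0, 9.0]])
        external = self.build([[4.0, 7.0], [0.5, 5.5]], cohort="external")
        _, (external_t,), scaler = standardize(train, [external])
        back = scaler.inverse_transform(external_t.X)
        pd.testing.assert_frame_equal(back, external.X)
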