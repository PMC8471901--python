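"""Per-day Ward clustering, label alignment and consensus assignment."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import aquamon as am


def separated_day_table(n_per_cluster=6, p=20, gap=50.0, noise=0.1, seed=0,
                        day=4):
    """One day's seed spectra with three widely separated planted groups."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(3, p)) * gap
    rows, seed_ids, truth = [], [], []
    sid = 1
    for c in range(3):
        for _ in range(n_per_cluster):
            rows.append(centers[c] + noise * rng.normal(size=p))
            seed_ids.append(sid)
            truth.append(c + 1)
            sid += 1
    meta = pd.DataFrame({"sample_type": "s", "seed_id": seed_ids, "day": day})
    table = am.SpectraTable(700.0 + np.arange(p), np.array(rows), meta)
    return table, pd.Series(truth, index=seed_ids)


class TestWardClusterDay:
    def test_separated_groups_recovered_exactly(self):
        table, truth = separated_day_table()
        labels, _ = am.ward_cluster_day(table, k=3)
        assert adjusted_rand_score(truth, labels.loc[truth.index]) == 1.0

    def test_duplicated_spectra_share_a_cluster(self):
        table, _ = separated_day_table(n_per_cluster=4, seed=1)
        values = table.values.copy()
        values[1] = values[0]  # identical seeds
        t2 = am.SpectraTable(table.wavelengths, values, table.meta)
        labels, _ = am.ward_cluster_day(t2, k=3)
        assert labels.iloc[0] == labels.iloc[1]

    def test_linkage_heights_monotone_nondecreasing(self):
        table, _ = separated_day_table(seed=2)
        _, Z = am.ward_cluster_day(table, k=3)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_errors_on_duplicates_and_too_few_seeds(self):
        table, _ = separated_day_table(n_per_cluster=1)
        meta = table.meta.copy()
        meta["seed_id"] = [1, 1, 2]
        dup = am.SpectraTable(table.wavelengths, table.values, meta)
        with pytest.raises(ValueError, match="one row per seed"):
            am.ward_cluster_day(dup, k=3)
        tiny = table.select_rows(np.array([True, True, False]))
        with pytest.raises(ValueError, match="fewer seeds"):
            am.ward_cluster_day(tiny, k=3)


class TestAlignLabels:
    def test_pure_relabelings_align_perfectly(self):
        base = pd.Series([1, 1, 2, 2, 3, 3], index=range(1, 7))
        perm_map = {1: 3, 2: 1, 3: 2}
        days = pd.DataFrame({4: base, 6: base.map(perm_map),
                             8: base.map({1: 2, 2: 3, 3: 1})})
        aligned = am.align_labels(days)
        for day in (6, 8):
            pd.testing.assert_series_equal(aligned[day], base,
                                           check_names=False)

    def test_self_alignment_is_identity(self):
        base = pd.Series([2, 3, 1, 2], index=range(1, 5))
        days = pd.DataFrame({4: base})
        aligned = am.align_labels(days, reference_day=4)
        pd.testing.assert_series_equal(aligned[4], base, check_names=False)

    def test_tie_resolved_to_lexicographically_smallest_permutation(self):
        # day 6 matches the reference equally well (1 seed) under the
        # identity and under swapping 1<->2; the identity must win.
        ref = pd.Series([1, 2], index=[1, 2])
        other = pd.Series([1, 1], index=[1, 2])
        aligned = am.align_labels(pd.DataFrame({4: ref, 6: other}))
        assert list(aligned[6]) == [1, 1]

    def test_missing_seeds_pass_through_as_nan(self):
        ref = pd.Series([1, 2, 3], index=[1, 2, 3])
        other = pd.Series([2.0, 1.0, np.nan], index=[1, 2, 3])
        aligned = am.align_labels(pd.DataFrame({4: ref, 6: other}))
        assert np.isnan(aligned[6].loc[3])
        assert aligned[6].loc[1] == 1 and aligned[6].loc[2] == 2


class TestConsensusAssign:
    def test_unanimous_seed_has_no_tie(self):
        days = pd.DataFrame({d: pd.Series([2, 1], index=[1, 2])
                             for d in range(4, 28, 2)})
        out = am.consensus_assign(days)
        assert out.consensus.loc[1] == 2
        assert out.tie_flags == ()
        assert out.appearance_counts.loc[1, 2] == 12

    def test_tie_broken_to_lowest_label_and_flagged(self):
        cols = {d: pd.Series([1], index=[7]) for d in (4, 6, 8)}
        cols.update({d: pd.Series([2], index=[7]) for d in (10, 12, 14)})
        out = am.consensus_assign(pd.DataFrame(cols))
        assert out.consensus.loc[7] == 1
        assert out.tie_flags == (7,)

    def test_consensus_equals_per_day_labels_when_all_days_agree(self):
        base = pd.Series([3, 1, 2, 2], index=range(1, 5))
        for n_days in (1, 5, 12):
            days = pd.DataFrame({d: base for d in range(n_days)})
            out = am.consensus_assign(days)
            pd.testing.assert_series_equal(out.consensus, base,
                                           check_names=False)

    def test_label_noise_recovery_and_noise_monotonicity(self):
        n_seeds, n_days = 28, 12
        truth = pd.Series(np.arange(n_seeds) % 3 + 1,
                          index=np.arange(1, n_seeds + 1))
        accuracies = {}
        for noise in (0.2, 0.45):
            acc = []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                cols = {}
                for d in range(n_days):
                    lab = truth.copy()
                    flip = rng.random(n_seeds) < noise
                    lab[flip] = rng.integers(1, 4, size=int(flip.sum()))
                    cols[d] = lab
                out = am.consensus_assign(am.align_labels(pd.DataFrame(cols)))
                acc.append(float((out.consensus == truth).mean()))
            accuracies[noise] = float(np.mean(acc))
        assert accuracies[0.2] >= 0.95
        assert accuracies[0.45] <= accuracies[0.2]

    def test_relabeling_invariance_of_whole_chain(self):
        rng = np.random.default_rng(3)
        truth = pd.Series(rng.integers(1, 4, size=12), index=range(1, 13))
        cols = {d: truth.map({1: 2, 2: 3, 3: 1}) if d % 4 == 0 else truth
                for d in range(4, 12, 2)}
        out = am.consensus_assign(am.align_labels(pd.DataFrame(cols)))
        assert adjusted_rand_score(out.consensus, truth) == 1.0


class TestClusterSeedsAndProfiles:
    def test_full_chain_perfect_recovery_in_high_separation_limit(self):
        tables = []
        for day in (4, 6, 8):
            t, truth = separated_day_table(seed=4, day=day)
            tables.append(t)
        values = np.vstack([t.values for t in tables])
        meta = pd.concat([t.meta for t in tables], ignore_index=True)
        table = am.SpectraTable(tables[0].wavelengths, values, meta)
        out = am.cluster_seeds(table, k=3)
        assert adjusted_rand_score(out.consensus.loc[truth.index], truth) == 1.0

    def test_single_cluster_profile_equals_global_average(self):
        t, _ = separated_day_table(n_per_cluster=4, seed=5)
        assignment = am.consensus_assign(
            pd.DataFrame({4: pd.Series(1, index=t.meta["seed_id"])}))
        profiles, d2 = am.cluster_profiles(t, assignment, d2_window=11)
        assert profiles.n_rows == 1
        np.testing.assert_allclose(profiles.values[0], t.values.mean(axis=0))
        assert d2.values.shape == profiles.values.shape

    def test_singleton_cluster_profile_is_that_seed(self):
        t, _ = separated_day_table(n_per_cluster=1, seed=6)
        labels = pd.Series([1, 2, 3], index=t.meta["seed_id"])
        assignment = am.consensus_assign(pd.DataFrame({4: labels}))
        profiles, _ = am.cluster_profiles(t, assignment, d2_window=11)
        for i, c in enumerate(profiles.meta["cluster"]):
            seed = labels.index[list(labels).index(c)]
            row = t.values[list(t.meta["seed_id"]).index(seed)]
            np.testing.assert_allclose(profiles.values[i], row)

    def test_planted_band_difference_located(self):
        # three clusters differing only in a band at 760 nm
        rng = np.random.default_rng(7)
        wl = np.arange(700.0, 821.0)
        shape = np.exp(-((wl - 760.0) ** 2) / (2 * 5.0 ** 2))
        rows, seeds, labels = [], [], []
        for sid in range(1, 19):
            c = (sid - 1) % 3 + 1
            rows.append(0.2 * c * shape + 0.001 * rng.normal(size=wl.size))
            seeds.append(sid)
            labels.append(c)
        meta = pd.DataFrame({"sample_type": "s", "seed_id": seeds, "day": 4})
        t = am.SpectraTable(wl, np.array(rows), meta)
        assignment = am.consensus_assign(
            pd.DataFrame({4: pd.Series(labels, index=seeds)}))
        profiles, _ = am.cluster_profiles(t, assignment, d2_window=11)
        spread = profiles.values.max(axis=0) - profiles.values.min(axis=0)
        assert abs(wl[np.argmax(spread)] - 760.0) <= 2.0

    def test_uncovered_seed_rejected(self):
        t, _ = separated_day_table(n_per_cluster=2, seed=8)  # seeds 1..6
        partial = pd.Series([1, 2, 1], index=[1, 2, 3])
        assignment = am.consensus_assign(pd.DataFrame({4: partial}))
        with pytest.raises(ValueError, match="does not cover"):
            am.cluster_profiles(t, assignment)
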