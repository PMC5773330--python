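import itertools

import numpy as np
import pandas as pd
import pytest

from phylodisp import (ScenarioConfig, build_communities, classify_pattern,
                       generate_scenario, mntd, mpd, ses, ses_table,
                       simulate_tree)
from phylodisp.dispersion import SIZE_CLASSES
from phylodisp.tree_ops import DistanceMatrix


def brute_mpd(abund, dist):
    labels = [s for s, n in abund.items() if n > 0]
    num = den = 0.0
    for a in labels:
        for b in labels:
            if a == b:
                continue
            d = dist.to_dataframe().loc[a, b]
            num += abund[a] * abund[b] * d
            den += abund[a] * abund[b]
    return num / den


def brute_mntd(abund, dist):
    df = dist.to_dataframe()
    labels = [s for s, n in abund.items() if n > 0]
    num = den = 0.0
    for a in labels:
        nearest = min(df.loc[a, b] for b in labels if b != a)
        num += abund[a] * nearest
        den += abund[a]
    return num / den


@pytest.fixture(scope="module")
def pool6():
    tree = simulate_tree(6, depth=10.0, seed=6)
    return tree.cophenetic()


@pytest.fixture(scope="module")
def pool8():
    tree = simulate_tree(8, depth=10.0, seed=8)
    return tree.cophenetic()


class TestMetrics:
    def test_pair_community(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert mpd({"A": 1, "B": 1}, dm) == pytest.approx(2.0)
        assert mntd({"A": 1, "B": 1}, dm) == pytest.approx(2.0)
        # conspecific pairs are excluded, so extra abundance changes nothing
        assert mpd({"A": 2, "B": 1}, dm) == pytest.approx(2.0)

    def test_mntd_three_species_by_hand(self):
        vals = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        dm = DistanceMatrix(("A", "B", "C"), vals)
        assert mntd({"A": 1, "B": 1, "C": 1}, dm) == pytest.approx((2 + 2 + 4) / 3)

    def test_fewer_than_two_species_rejected(self, pool6):
        with pytest.raises(ValueError):
            mpd({pool6.labels[0]: 3}, pool6)

    def test_exhaustive_small_communities_match_brute_force(self, pool6):
        """MPD and MNTD agree with explicit double-loop oracles on every
        community of 2..6 species drawn from a 6-species pool."""
        rng = np.random.default_rng(1)
        for k in range(2, 7):
            for combo in itertools.combinations(pool6.labels, k):
                abund = {s: int(rng.integers(1, 6)) for s in combo}
                assert mpd(abund, pool6) == pytest.approx(
                    brute_mpd(abund, pool6), abs=1e-12)
                assert mntd(abund, pool6) == pytest.approx(
                    brute_mntd(abund, pool6), abs=1e-12)

    def test_label_order_invariance(self, pool6):
        abund = {pool6.labels[i]: c for i, c in enumerate([3, 1, 0, 2, 5, 1])}
        perm = np.random.default_rng(3).permutation(pool6.n)
        shuffled = DistanceMatrix(tuple(np.array(pool6.labels)[perm]),
                                  pool6.values[np.ix_(perm, perm)])
        assert mpd(abund, shuffled) == pytest.approx(mpd(abund, pool6), abs=1e-12)
        assert mntd(abund, shuffled) == pytest.approx(mntd(abund, pool6), abs=1e-12)


class TestSES:
    def test_full_pool_equal_abundance_degenerate(self, pool6):
        """The whole pool at equal abundance is invariant under label
        shuffling, so the null SD collapses and the SES is flagged."""
        abund = {s: 1 for s in pool6.labels}
        r = ses(abund, pool6, "mpd", n_null=99, seed=0)
        assert r.null_sd == 0.0
        assert r.undefined

    def test_matches_exhaustive_enumeration(self, pool8):
        """SES null mean/SD from 999 draws agree with exact enumeration over
        all injective label assignments of a 5-species community."""
        labels = pool8.labels[:5]
        abund = {s: c for s, c in zip(labels, (1, 3, 2, 1, 4))}
        counts = np.array([1, 3, 2, 1, 4], float)
        exact = []
        for perm in itertools.permutations(range(pool8.n), 5):
            ix = np.array(perm)
            d = pool8.values[np.ix_(ix, ix)]
            w = np.outer(counts, counts)
            np.fill_diagonal(w, 0.0)
            exact.append((w * d).sum() / w.sum())
        exact = np.array(exact)
        r = ses(abund, pool8, "mpd", n_null=999, seed=42)
        se = exact.std() / np.sqrt(999)
        assert r.null_mean == pytest.approx(exact.mean(), abs=4 * se)
        assert r.null_sd == pytest.approx(exact.std(ddof=1), rel=0.15)
        z_exact = (r.obs - exact.mean()) / exact.std(ddof=1)
        assert r.ses == pytest.approx(z_exact, abs=0.3)

    def test_rank_consistent_with_nulls(self, pool8):
        abund = {s: 1 for s in pool8.labels[:4]}
        r = ses(abund, pool8, "mntd", n_null=199, seed=7)
        assert 1 <= r.rank <= r.n_null + 1
        # rank/(n+1) must sit on the same side of 0.5 as the SES sign
        if r.ses > 0.5:
            assert r.rank > 100
        if r.ses < -0.5:
            assert r.rank < 100

    def test_consistent_relabeling_invariance(self, pool8):
        """Renaming species identically in abundances and distances leaves
        the SES unchanged."""
        abund = {s: c for s, c in zip(pool8.labels[:4], (2, 1, 1, 3))}
        r1 = ses(abund, pool8, "mpd", n_null=99, seed=5)
        ren = {s: f"x_{s}" for s in pool8.labels}
        dm2 = DistanceMatrix(tuple(ren[s] for s in pool8.labels), pool8.values)
        r2 = ses({ren[s]: c for s, c in abund.items()}, dm2, "mpd",
                 n_null=99, seed=5)
        assert r1.ses == pytest.approx(r2.ses, abs=1e-12)
        assert r1.obs == pytest.approx(r2.obs, abs=1e-12)


class TestBuildCommunities:
    @pytest.fixture(scope="class")
    def stems(self):
        cfg = ScenarioConfig(n_species=15, n_stems=3000, seed=13,
                             conserved_k_min=None, trait_tree_corr_min=None)
        return generate_scenario(cfg).stems

    def test_grid_size_50m(self, stems):
        comm = build_communities(stems, 50.0, "all", 300.0)
        assert comm.n_cells == 36

    def test_all_class_conserves_stems(self, stems):
        comm = build_communities(stems, 20.0, "all", 300.0)
        assert comm.matrix.to_numpy().sum() == len(stems)

    def test_boundary_size_class_logic(self):
        stems = pd.DataFrame({
            "stem_id": [1, 2],
            "species": ["sp1", "sp1"],
            "x": [0.0, 10.0], "y": [0.0, 10.0],
            "dbh": [3.0, 12.0],      # species max dbh 12 -> canopy
        })
        small = build_communities(stems, 50.0, "small", 300.0)
        medium = build_communities(stems, 50.0, "medium", 300.0)
        large = build_communities(stems, 50.0, "large", 300.0)
        assert small.matrix["sp1"].sum() == 1
        assert medium.matrix["sp1"].sum() == 0
        assert large.matrix["sp1"].sum() == 1

    def test_size_classes_partition_canopy_stems(self, stems):
        """Summed over the three size classes, canopy-species stem counts
        equal their total counts (conservation)."""
        max_dbh = stems.groupby("species")["dbh"].max()
        canopy = max_dbh.index[max_dbh > 10.0]
        total = np.zeros(len(canopy))
        for sc in ("small", "medium", "large"):
            comm = build_communities(stems, 30.0, sc, 300.0)
            total += comm.matrix[canopy].to_numpy().sum(axis=0)
        expected = stems[stems.species.isin(canopy)].groupby("species").size()
        np.testing.assert_array_equal(total, expected[canopy].to_numpy())

    def test_out_of_plot_rejected(self):
        stems = pd.DataFrame({"stem_id": [1], "species": ["a"],
                              "x": [301.0], "y": [0.0], "dbh": [2.0]})
        with pytest.raises(ValueError, match="outside"):
            build_communities(stems, 50.0, "all", 300.0)

    def test_unknown_size_class(self, stems):
        with pytest.raises(ValueError, match="size class"):
            build_communities(stems, 50.0, "huge", 300.0)

    def test_known_classes(self):
        assert SIZE_CLASSES == ("small", "medium", "large", "all")


class TestClassifyPattern:
    @pytest.mark.parametrize("value,expected", [
        (-1.3, "clustered"), (0.2, "overdispersed"),
        (0.0, None), (float("nan"), None)])
    def test_sign_rule(self, value, expected):
        assert classify_pattern(value) == expected


def test_ses_table_records_sparse_cells(pool8):
    from phylodisp.dispersion import CommunityTable, GridSpec
    grid = GridSpec(20.0, 10.0)
    mat = pd.DataFrame(0, index=pd.Index(grid.cell_ids(), name="cell_id"),
                       columns=list(pool8.labels))
    mat.iloc[0, :3] = [2, 1, 1]
    mat.iloc[1, 0] = 5      # one species only -> undefined
    comm = CommunityTable(grid, "all", mat)
    tab = ses_table(comm, pool8, "mpd", n_null=99, seed=0)
    assert np.isfinite(tab.iloc[0]["ses"])
    assert np.isnan(tab.iloc[1]["ses"])
    assert np.isnan(tab.iloc[2]["ses"])  # empty cell
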