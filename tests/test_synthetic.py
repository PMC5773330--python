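import numpy as np
import pandas as pd
import pytest

from phylodisp import (ScenarioConfig, TraitSpec, assemble_stems,
                       generate_scenario, simulate_landscape, simulate_traits,
                       simulate_tree)
from phylodisp.synthetic import scenario_preset


def yule_lineages_at_half_depth(n, n_trees, seed):
    """Independent birth-process oracle: simulate Yule split times directly
    and count lineages alive at half the (conditioned) total time."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_trees):
        times = [0.0]          # root split: 2 lineages at t=0
        t, k = 0.0, 2
        while k < n:
            t += rng.exponential(1.0 / k)
            times.append(t)
            k += 1
        t_end = t + rng.exponential(1.0 / n)
        half = t_end / 2.0
        out.append(2 + sum(1 for s in times[1:] if s <= half))
    return np.mean(out)


class TestSimulateTree:
    def test_two_tip_cherry(self):
        t = simulate_tree(2, depth=7.0, seed=0)
        df = t.cophenetic().to_dataframe()
        assert df.iloc[0, 1] == pytest.approx(14.0)
        assert t.depth == pytest.approx(7.0)

    def test_deterministic(self):
        a = simulate_tree(15, depth=3.0, seed=9).to_newick()
        b = simulate_tree(15, depth=3.0, seed=9).to_newick()
        assert a == b

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            simulate_tree(1, seed=0)

    def test_lineage_count_matches_birth_process(self):
        """Mean lineage count at half depth agrees with a direct birth-process
        simulation (independent oracle) within 15%."""
        n, reps = 30, 200
        counts = []
        for s in range(reps):
            tree = simulate_tree(n, depth=1.0, seed=s)
            half = 0.5
            c = 0
            dt = tree.dendropy_tree
            depths = {}
            for node in dt.preorder_node_iter():
                if node is dt.seed_node:
                    depths[node] = 0.0
                else:
                    depths[node] = depths[node.parent_node] + node.edge.length
            for node in dt.preorder_node_iter():
                if node is dt.seed_node:
                    continue
                top = depths[node.parent_node]
                if top <= half < depths[node]:
                    c += 1
            counts.append(c)
        oracle = yule_lineages_at_half_depth(n, reps, seed=12345)
        assert np.mean(counts) == pytest.approx(oracle, rel=0.15)


class TestSimulateTraits:
    def test_lambda_one_equals_brownian(self, tree50):
        a = simulate_traits(tree50, [TraitSpec("x", "brownian")], seed=4)
        b = simulate_traits(tree50, [TraitSpec("x", "lambda", lam=1.0)], seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown trait model"):
            TraitSpec("x", "ou")

    def test_lambda_zero_uncorrelated_with_brownian(self, tree50):
        """With lambda=0 the trait shares no covariance with tree structure:
        its correlation with an independent Brownian trait averages zero."""
        cors = []
        for s in range(300):
            tt = simulate_traits(
                tree50,
                [TraitSpec("star", "lambda", lam=0.0), TraitSpec("bm", "brownian")],
                seed=s)
            cors.append(np.corrcoef(tt["star"], tt["bm"])[0, 1])
        assert abs(np.mean(cors)) < 0.05

    def test_shuffled_destroys_signal(self, tree50):
        from phylodisp import blomberg_k
        k_bm, k_sh = [], []
        for s in range(200):
            tt = simulate_traits(
                tree50, [TraitSpec("a", "brownian"), TraitSpec("b", "shuffled")],
                seed=s)
            k_bm.append(blomberg_k(tree50, tt["a"]))
            k_sh.append(blomberg_k(tree50, tt["b"]))
        assert np.mean(k_sh) < 0.6 * np.mean(k_bm)


def moran_i(values, coords, d_lo, d_hi):
    """Moran's I for the neighbour class d_lo < d <= d_hi (oracle)."""
    v = values - values.mean()
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    w = ((d > d_lo) & (d <= d_hi)).astype(float)
    np.fill_diagonal(w, 0.0)
    n = len(v)
    return (n / w.sum()) * (v @ (w @ v)) / (v @ v)


class TestSimulateLandscape:
    def test_zero_noise_equals_trend(self):
        a = simulate_landscape(ScenarioConfig(env_noise_sd=1e-12, seed=3))
        b = simulate_landscape(ScenarioConfig(env_noise_sd=1.0, seed=3))
        # soil trend surfaces are smooth polynomials; with noise "off" the
        # residual from a refit quadratic must vanish
        x, y = a["x"] / 300.0, a["y"] / 300.0
        X = np.column_stack([np.ones(len(a)), x, y, x * y, x ** 2, y ** 2])
        for col in ("ph", "total_n"):
            beta, res, *_ = np.linalg.lstsq(X, a[col], rcond=None)
            assert np.abs(a[col] - X @ beta).max() < 1e-6
            assert np.abs(b[col] - X @ beta).max() > 1e-3

    def test_deterministic(self):
        a = simulate_landscape(ScenarioConfig(seed=8))
        b = simulate_landscape(ScenarioConfig(seed=8))
        pd.testing.assert_frame_equal(a, b)

    def test_aspect_range(self):
        env = simulate_landscape(ScenarioConfig(seed=1))
        assert ((env["aspect"] >= 0) & (env["aspect"] < 360)).all()

    def test_positive_decaying_autocorrelation(self):
        """Moran's I of the generated surfaces is positive at short range and
        decreases with distance class."""
        env = simulate_landscape(ScenarioConfig(seed=21))
        coords = env[["x", "y"]].to_numpy()
        ms = []
        for col in ("elevation", "ph"):
            v = env[col].to_numpy()
            ii = [moran_i(v, coords, lo, hi)
                  for lo, hi in ((0, 25), (25, 65), (65, 120))]
            ms.append(ii)
            assert ii[0] > 0
        mean_by_class = np.mean(ms, axis=0)
        assert mean_by_class[0] > mean_by_class[1] > mean_by_class[2]


class TestAssembleStems:
    def _small_cfg(self, **kw):
        base = dict(n_species=10, n_stems=500, plot_size=300.0, env_cell=100.0,
                    trait_specs=(TraitSpec("conserved", "brownian"),
                                 TraitSpec("labile", "shuffled")),
                    conserved_k_min=None, trait_tree_corr_min=None)
        base.update(kw)
        return ScenarioConfig(**base)

    def test_stems_inside_plot_and_dbh_floor(self):
        sc = generate_scenario(self._small_cfg(seed=2))
        s = sc.stems
        assert ((s.x >= 0) & (s.x < 300) & (s.y >= 0) & (s.y < 300)).all()
        assert (s.dbh >= 1.0).all()
        assert set(s.species) <= set(sc.tree.tip_labels)

    def test_determinism(self):
        a = generate_scenario(self._small_cfg(seed=5)).stems
        b = generate_scenario(self._small_cfg(seed=5)).stems
        pd.testing.assert_frame_equal(a, b)

    def test_huge_sigma_reduces_filtering_to_neutral(self):
        """With an effectively flat filter kernel the species x cell table is
        statistically independent (chi-square rejections at the nominal
        rate)."""
        from scipy.stats import chi2_contingency
        rejections = 0
        reps = 120
        for s in range(reps):
            cfg = self._small_cfg(assembly="filtering", sigma_f=1e6, seed=s)
            sc = generate_scenario(cfg)
            cells = (np.floor(sc.stems.y / 100).astype(int) * 3
                     + np.floor(sc.stems.x / 100).astype(int))
            table = pd.crosstab(cells, sc.stems.species)
            p = chi2_contingency(table.to_numpy())[1]
            rejections += p < 0.05
        # 95% binomial band around 0.05 at 120 reps
        assert 0.005 <= rejections / reps <= 0.12

    def test_limiting_similarity_degenerate_radius_falls_back(self):
        cfg = self._small_cfg(assembly="limiting_similarity", r_s=1e3, seed=3)
        sc = generate_scenario(cfg)
        assert sc.stems.attrs["n_fallback"] > 0
        # richness above 1 was still forced somewhere despite total conflict
        assert sc.stems.species.nunique() > 1

    def test_missing_filter_trait_rejected(self):
        cfg = self._small_cfg(assembly="filtering", filter_trait="nope", seed=0)
        tree = simulate_tree(10, seed=0)
        traits = simulate_traits(tree, cfg.trait_specs, seed=0)
        env = simulate_landscape(cfg)
        with pytest.raises(ValueError, match="filter trait"):
            assemble_stems(tree, traits, env, cfg)


class TestScenarioConditioning:
    def test_conserved_traits_meet_signal_floor(self):
        """The mechanism scenarios hold their premise: every Brownian trait
        in a generated filtering scenario has realized K >= the floor."""
        from phylodisp import blomberg_k
        sc = generate_scenario(scenario_preset("filtering", seed=31))
        for name in ("conserved", "trait_b2", "trait_b3"):
            assert blomberg_k(sc.tree, sc.traits[name]) >= 1.0

    def test_preset_unknown(self):
        with pytest.raises(ValueError, match="unknown preset"):
            scenario_preset("drift")


def test_filtering_on_conserved_trait_clusters_cells():
    """End-to-end recovery: a strongly filtered community shows negative
    SES.MPD in >90% of 20-m cells."""
    import phylodisp as pdp
    sc = generate_scenario(scenario_preset("filtering", seed=3))
    comm = pdp.build_communities(sc.stems, 20.0, "all", 300.0)
    tab = pdp.ses_table(comm, sc.tree.cophenetic(), "mpd", n_null=199, seed=53)
    frac_neg = (tab.ses.dropna() < 0).mean()
    assert frac_neg > 0.90
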