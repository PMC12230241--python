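import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sdlscreen import shrna, synthdata
from sdlscreen.errors import ConfigError, DataError

from conftest import make_tensor, two_arm_trajectory


def random_tensor(rng, n_hairpins=30, n_genes=10, timepoints=(0, 8, 16), n_reps=2,
                  loc=10.0, scale=2.0):
    traj = {}
    genes = {}
    for i in range(n_hairpins):
        hp = f"hp{i:03d}"
        genes[hp] = f"g{i % n_genes}"
        traj[hp] = {
            (arm, t, r): rng.normal(loc, scale)
            for arm in ("induced", "uninduced")
            for t in timepoints
            for r in range(1, n_reps + 1)
        }
    return make_tensor(traj, genes)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        traj = {f"h{i}": two_arm_trajectory([v, v, v], [v, v, v])
                for i, v in enumerate([9.0, 10.0, 11.0])}
        t = make_tensor(traj)
        out = shrna.quantile_normalize(t)
        pd.testing.assert_frame_equal(out.values, t.values)

    def test_two_column_example(self):
        # columns [1,2,3] and [4,5,6] -> both become [2.5,3.5,4.5]
        t = make_tensor({
            "h1": {("induced", 0, 1): 1.0, ("uninduced", 0, 1): 4.0,
                   ("induced", 8, 1): 1.0, ("uninduced", 8, 1): 4.0},
            "h2": {("induced", 0, 1): 2.0, ("uninduced", 0, 1): 5.0,
                   ("induced", 8, 1): 2.0, ("uninduced", 8, 1): 5.0},
            "h3": {("induced", 0, 1): 3.0, ("uninduced", 0, 1): 6.0,
                   ("induced", 8, 1): 3.0, ("uninduced", 8, 1): 6.0},
        })
        out = shrna.quantile_normalize(t)
        for col in out.values.columns:
            assert list(out.values[col]) == [2.5, 3.5, 4.5]

    def test_sorted_columns_identical_invariant(self, rng):
        t = random_tensor(rng)
        out = shrna.quantile_normalize(t)
        arr = out.values.to_numpy()
        ref = np.sort(arr[:, 0])
        for j in range(arr.shape[1]):
            np.testing.assert_allclose(np.sort(arr[:, j]), ref, atol=1e-12)

    def test_row_order_preserved(self, rng):
        t = random_tensor(rng)
        out = shrna.quantile_normalize(t)
        # ranks within each column are preserved
        for col in t.values.columns:
            orig = t.values[col].rank()
            new = out.values[col].rank()
            pd.testing.assert_series_equal(orig, new)

    def test_tie_convention(self):
        # tied input values map to the mean of the implicated row means
        t = make_tensor({
            "h1": {("induced", 0, 1): 1.0, ("uninduced", 0, 1): 1.0,
                   ("induced", 8, 1): 1.0, ("uninduced", 8, 1): 1.0},
            "h2": {("induced", 0, 1): 1.0, ("uninduced", 0, 1): 2.0,
                   ("induced", 8, 1): 1.0, ("uninduced", 8, 1): 2.0},
            "h3": {("induced", 0, 1): 5.0, ("uninduced", 0, 1): 3.0,
                   ("induced", 8, 1): 5.0, ("uninduced", 8, 1): 3.0},
        })
        out = shrna.quantile_normalize(t)
        # reference distribution: row means of sorted columns = [1, 1.5, 4]
        col = out.values["induced_T0_R1"]
        assert col["h1"] == pytest.approx(1.25)  # mean of ref[0], ref[1]
        assert col["h2"] == pytest.approx(1.25)
        assert col["h3"] == pytest.approx(4.0)


# ---------------------------------------------------------------------------
# hairpin filtering
# ---------------------------------------------------------------------------

class TestFilterHairpins:
    def test_t0_below_background_dropped(self):
        t = make_tensor({
            "low": two_arm_trajectory([7.9, 9.0, 9.0], [9.1, 9.0, 9.0]),
            "ok": two_arm_trajectory([9.0, 9.0, 9.0], [9.0, 9.0, 9.0]),
        })
        kept, dropped = shrna.filter_hairpins(t)
        assert list(kept.values.index) == ["ok"]
        assert dropped.iloc[0]["hairpin"] == "low"
        assert "T0 below background" in dropped.iloc[0]["reason"]

    def test_all_above_floor_retained(self):
        t = make_tensor({
            "a": two_arm_trajectory([8.0, 8.5, 9.0], [8.0, 8.0, 8.0]),
        })
        kept, dropped = shrna.filter_hairpins(t)
        assert len(kept.values) == 1 and dropped.empty

    def test_later_timepoint_rule(self):
        t = make_tensor({
            "neg": two_arm_trajectory([9.0, -0.5, 9.0], [9.0, 9.0, 9.0]),
        })
        kept, dropped = shrna.filter_hairpins(t)
        assert kept.values.empty
        assert "later timepoint below floor" in dropped.iloc[0]["reason"]

    def test_brute_force_oracle(self, rng):
        t = random_tensor(rng, n_hairpins=60, loc=8.5, scale=2.5)
        kept, _ = shrna.filter_hairpins(t, t0_floor=8.0, later_floor=6.0)
        # independent row-wise re-check of both rules
        expected = []
        for hp in t.values.index:
            row_ok = True
            for col in t.values.columns:
                tp = t.samples.loc[col, "timepoint"]
                v = t.values.loc[hp, col]
                if tp == 0 and v < 8.0:
                    row_ok = False
                if tp != 0 and v < 6.0:
                    row_ok = False
            if row_ok:
                expected.append(hp)
        assert list(kept.values.index) == expected


# ---------------------------------------------------------------------------
# WDC
# ---------------------------------------------------------------------------

def naive_wdc(induced: np.ndarray, uninduced: np.ndarray, epsilon: float) -> float:
    """Independent double-loop evaluation of the printed formula for one
    replicate: sum_t eps^{t+1} (x_{t+1} - x_t), treatment minus control."""
    total = 0.0
    for t in range(len(induced) - 1):
        total += epsilon ** (t + 1) * (induced[t + 1] - induced[t])
    for t in range(len(uninduced) - 1):
        total -= epsilon ** (t + 1) * (uninduced[t + 1] - uninduced[t])
    return total


class TestWdcHairpin:
    def test_identical_arms_zero(self):
        t = make_tensor({"h": two_arm_trajectory([10, 8, 6], [10, 8, 6])})
        table = shrna.wdc_hairpin(t, shrna.WDCConfig())
        assert table.loc["h", "wdc"] == pytest.approx(0.0)

    def test_worked_example(self):
        # eps=0.5, induced [10,8,6], uninduced flat: 0.5*(-2) + 0.25*(-2) = -1.5
        t = make_tensor({"h": two_arm_trajectory([10, 8, 6], [10, 10, 10])})
        table = shrna.wdc_hairpin(t, shrna.WDCConfig(epsilon=0.5))
        assert table.loc["h", "wdc"] == pytest.approx(-1.5)

    def test_increasing_induced_positive(self):
        t = make_tensor({"h": two_arm_trajectory([10, 11, 12], [10, 10, 10])})
        table = shrna.wdc_hairpin(t, shrna.WDCConfig())
        assert table.loc["h", "wdc"] > 0

    def test_oracle_equivalence(self, rng):
        t = random_tensor(rng, n_hairpins=20, n_reps=2)
        cfg = shrna.WDCConfig(epsilon=0.7)
        table = shrna.wdc_hairpin(t, cfg)
        tps = t.timepoints
        for hp in t.values.index:
            per_rep = []
            for r in (1, 2):
                ind = np.array([t.column("induced", tp, r)[hp] for tp in tps])
                unind = np.array([t.column("uninduced", tp, r)[hp] for tp in tps])
                per_rep.append(naive_wdc(ind, unind, 0.7))
            assert table.loc[hp, "wdc"] == pytest.approx(np.mean(per_rep), abs=1e-12)

    def test_linearity_in_increments(self, rng):
        # scaling all increments by c scales wdc by c
        base = rng.normal(10, 1, 3)
        inc_i = rng.normal(0, 1, 2)
        inc_u = rng.normal(0, 1, 2)
        for c in (2.0, -0.5):
            t1 = make_tensor({"h": two_arm_trajectory(
                np.concatenate([[base[0]], base[0] + np.cumsum(inc_i)]),
                np.concatenate([[base[0]], base[0] + np.cumsum(inc_u)]))})
            tc = make_tensor({"h": two_arm_trajectory(
                np.concatenate([[base[0]], base[0] + np.cumsum(c * inc_i)]),
                np.concatenate([[base[0]], base[0] + np.cumsum(c * inc_u)]))})
            cfg = shrna.WDCConfig()
            w1 = shrna.wdc_hairpin(t1, cfg).loc["h", "wdc"]
            wc = shrna.wdc_hairpin(tc, cfg).loc["h", "wdc"]
            assert wc == pytest.approx(c * w1, abs=1e-10)

    def test_arm_swap_antisymmetry(self, rng):
        t = random_tensor(rng, n_hairpins=15)
        cfg = shrna.WDCConfig()
        fwd = shrna.wdc_hairpin(t, cfg)["wdc"]
        rev = shrna.wdc_hairpin(
            t, cfg, arm_treatment="uninduced", arm_control="induced"
        )["wdc"]
        np.testing.assert_allclose(fwd, -rev, atol=1e-12)

    def test_missing_arm_error(self):
        t = make_tensor({"h": two_arm_trajectory([10, 9, 8], [10, 10, 10])})
        with pytest.raises(DataError):
            shrna.wdc_hairpin(t, shrna.WDCConfig(), arm_treatment="cas9")


class TestWdcGene:
    @staticmethod
    def _scores(vals, gene="g1"):
        return pd.DataFrame(
            {"gene": gene, "wdc": vals},
            index=[f"h{i}" for i in range(len(vals))],
        )

    def test_two_most_negative_average(self):
        out = shrna.wdc_gene(self._scores([-3, -1, -5, 0, 2]), shrna.WDCConfig())
        assert out.loc["g1", "wdc"] == pytest.approx(-4.0)
        assert out.loc["g1", "n_used"] == 2

    def test_single_hairpin_flagged(self):
        out = shrna.wdc_gene(self._scores([-2]), shrna.WDCConfig())
        assert out.loc["g1", "wdc"] == pytest.approx(-2.0)
        assert bool(out.loc["g1", "underpowered"])

    def test_all_positive(self):
        out = shrna.wdc_gene(self._scores([1, 2, 3]), shrna.WDCConfig())
        assert out.loc["g1", "wdc"] == pytest.approx(1.5)


# ---------------------------------------------------------------------------
# p values
# ---------------------------------------------------------------------------

class TestPermutation:
    def test_add_one_rule(self):
        # observed deeper than every possible null draw -> p = 1 / (B + 1)
        scores = pd.DataFrame(
            {"gene": ["x"] * 100, "wdc": list(np.linspace(0, 1, 100))},
            index=[f"h{i}" for i in range(100)],
        )
        cfg = shrna.WDCConfig(n_permutations=999, seed=1)
        genes = pd.DataFrame(
            {"wdc": [-100.0], "n_hairpins": [2]}, index=pd.Index(["g"], name="gene")
        )
        p = shrna.permutation_pvalues(scores, genes, cfg)
        assert p["g"] == pytest.approx(1.0 / 1000.0)

    def test_median_symmetry(self, rng):
        # single-hairpin gene at the pool median, k=1 -> p ~ 0.5
        vals = rng.normal(size=401)
        vals[0] = np.median(vals)
        scores = pd.DataFrame(
            {"gene": ["g"] + [f"x{i}" for i in range(400)], "wdc": vals},
            index=[f"h{i}" for i in range(401)],
        )
        cfg = shrna.WDCConfig(n_permutations=2000, k_aggregate=1, seed=2)
        genes = shrna.wdc_gene(scores, cfg)
        p = shrna.permutation_pvalues(scores, genes, cfg)
        assert p["g"] == pytest.approx(0.5, abs=0.05)

    def test_exhaustive_enumeration_oracle(self):
        # pool of 5 scores, gene of 2 hairpins, k=2: exact null by C(5,2)
        pool = np.array([-2.0, -1.0, 0.0, 1.0, 3.0])
        obs = -1.2
        exact = [np.mean(pair) for pair in itertools.combinations(pool, 2)]
        p_exact = np.mean([v <= obs for v in exact])  # exhaustive tail frequency
        # sampled null approximates the enumeration as B grows (the add-one
        # correction contributes only 1/(B+1) at B = 10,000)
        scores = pd.DataFrame(
            {"gene": ["g", "g", "a", "b", "c"], "wdc": [-2.0, -0.4, 0.0, 1.0, 3.0]},
            index=[f"h{i}" for i in range(5)],
        )
        scores["wdc"] = pool  # pool is the full set of hairpin scores
        cfg = shrna.WDCConfig(n_permutations=10000, seed=3)
        genes = pd.DataFrame(
            {"wdc": [obs], "n_hairpins": [2]}, index=pd.Index(["g"], name="gene")
        )
        p_sampled = shrna.permutation_pvalues(scores, genes, cfg)["g"]
        assert p_sampled == pytest.approx(p_exact, abs=0.02)

    def test_null_uniformity(self, rng):
        # genes drawn from the null pool -> p uniform on (0, 1)
        n_genes, m = 500, 4
        vals = rng.normal(size=n_genes * m)
        scores = pd.DataFrame(
            {"gene": np.repeat([f"g{i}" for i in range(n_genes)], m), "wdc": vals},
            index=[f"h{i}" for i in range(n_genes * m)],
        )
        cfg = shrna.WDCConfig(n_permutations=1000, seed=4)
        genes = shrna.wdc_gene(scores, cfg)
        p = shrna.permutation_pvalues(scores, genes, cfg)
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_pool_too_small_error(self):
        scores = pd.DataFrame(
            {"gene": ["g", "g"], "wdc": [-1.0, 0.0]}, index=["h1", "h2"]
        )
        genes = pd.DataFrame(
            {"wdc": [-0.5], "n_hairpins": [5]}, index=pd.Index(["g"], name="gene")
        )
        with pytest.raises(DataError):
            shrna.permutation_pvalues(scores, genes, shrna.WDCConfig())


class TestTTest:
    def test_identical_arms_p_one(self, rng):
        traj = {}
        genes = {}
        for i in range(5):
            vals = rng.normal(10, 1, 3)
            traj[f"h{i}"] = two_arm_trajectory(vals, vals, replicates=(1, 2))
            genes[f"h{i}"] = "g"
        t = make_tensor(traj, genes)
        scores = shrna.wdc_hairpin(t, shrna.WDCConfig())
        p = shrna.ttest_pvalues(t, scores, shrna.WDCConfig())
        assert p["g"] == pytest.approx(1.0)

    def test_large_separation(self):
        # textbook check: Welch/Student t on fixed numbers
        traj, genes = {}, {}
        for i in range(5):
            traj[f"h{i}"] = two_arm_trajectory(
                [10.0, 8.0 - 0.1 * i, 6.0], [10.0, 10.0 + 0.05 * i, 10.0],
                replicates=(1, 2))
            genes[f"h{i}"] = "g"
        t = make_tensor(traj, genes)
        cfg = shrna.WDCConfig()
        scores = shrna.wdc_hairpin(t, cfg)
        p = shrna.ttest_pvalues(t, scores, cfg)
        # oracle: recompute observations directly and run scipy on them
        wcc = shrna.weighted_cumulative_change(t, cfg.epsilon)
        a = wcc[[c for c in wcc.columns if c[0] == "induced"]].to_numpy().ravel()
        b = wcc[[c for c in wcc.columns if c[0] == "uninduced"]].to_numpy().ravel()
        expected = stats.ttest_ind(a, b).pvalue
        assert p["g"] == pytest.approx(expected, rel=1e-12)
        assert p["g"] < 0.001

    def test_zero_variance_flagged(self):
        traj, genes = {}, {}
        for i in range(3):
            traj[f"h{i}"] = two_arm_trajectory([10, 10, 10], [10, 10, 10])
            genes[f"h{i}"] = "g"
        t = make_tensor(traj, genes)
        scores = shrna.wdc_hairpin(t, shrna.WDCConfig())
        p = shrna.ttest_pvalues(t, scores, shrna.WDCConfig())
        assert np.isnan(p["g"])


class TestCallHits:
    @staticmethod
    def _table(wdc, p_perm, p_t):
        return pd.DataFrame(
            {"wdc": [wdc], "p_perm": [p_perm], "p_ttest": [p_t]},
            index=pd.Index(["g"], name="gene"),
        )

    def test_hit(self):
        out = shrna.call_hits(self._table(-2.5, 0.01, 0.02), shrna.WDCConfig())
        assert bool(out.loc["g", "hit"])

    def test_perm_fails(self):
        out = shrna.call_hits(self._table(-2.5, 0.2, 0.01), shrna.WDCConfig())
        assert not bool(out.loc["g", "hit"])

    def test_fold_fails(self):
        out = shrna.call_hits(self._table(-0.5, 0.001, 0.001), shrna.WDCConfig())
        assert not bool(out.loc["g", "hit"])

    def test_nan_p_never_hit(self):
        out = shrna.call_hits(self._table(-2.5, np.nan, 0.01), shrna.WDCConfig())
        assert not bool(out.loc["g", "hit"])


# ---------------------------------------------------------------------------
# QC and evaluation
# ---------------------------------------------------------------------------

class TestReplicateCorrelation:
    def test_duplicated_replicate(self, rng):
        traj, genes = {}, {}
        for i in range(10):
            vals = rng.normal(10, 1, 3)
            traj[f"h{i}"] = two_arm_trajectory(vals, vals, replicates=(1, 2))
            genes[f"h{i}"] = f"g{i}"
        t = make_tensor(traj, genes)
        out = shrna.replicate_correlation(t)
        np.testing.assert_allclose(out["pearson_r"], 1.0, atol=1e-12)

    def test_negated_centered_replicate(self, rng):
        traj = {}
        vals = rng.normal(0, 1, 10)
        for i in range(10):
            traj[f"h{i}"] = {
                ("induced", t, 1): vals[i] for t in (0, 8)
            } | {
                ("induced", t, 2): -vals[i] for t in (0, 8)
            } | {
                ("uninduced", t, r): vals[i] for t in (0, 8) for r in (1, 2)
            }
        t = make_tensor(traj)
        out = shrna.replicate_correlation(t)
        ind = out[out["arm"] == "induced"]
        np.testing.assert_allclose(ind["pearson_r"], -1.0, atol=1e-12)

    def test_default_screen_above_09(self, default_screen):
        out = shrna.replicate_correlation(default_screen.tensor)
        assert (out["pearson_r"] > 0.9).all()

    def test_constant_column_flagged(self):
        traj = {f"h{i}": {("induced", t, r): 5.0 for t in (0, 8) for r in (1, 2)}
                | {("uninduced", t, r): float(i) for t in (0, 8) for r in (1, 2)}
                for i in range(4)}
        t = make_tensor(traj)
        out = shrna.replicate_correlation(t)
        assert out.loc[out["arm"] == "induced", "undefined"].all()


class TestEvaluatePerformance:
    def test_perfect_separation(self):
        table = pd.DataFrame(
            {"wdc": [-3, -2.5, -2, 1, 2, 3]},
            index=pd.Index([f"g{i}" for i in range(6)], name="gene"),
        )
        refs = shrna.ReferenceGeneSets({"g0", "g1", "g2"}, {"g3", "g4", "g5"})
        assert shrna.evaluate_performance(table, refs)["f_max"] == pytest.approx(1.0)

    def test_uninformative_ranking_f_two_thirds(self, rng):
        # balanced classes, ranking independent of labels: at full recall
        # precision = 0.5 so F = 2/3; F_max converges there for large n
        n = 2000
        table = pd.DataFrame(
            {"wdc": rng.normal(size=n)},
            index=pd.Index([f"g{i}" for i in range(n)], name="gene"),
        )
        refs = shrna.ReferenceGeneSets(
            {f"g{i}" for i in range(0, n, 2)}, {f"g{i}" for i in range(1, n, 2)}
        )
        f = shrna.evaluate_performance(table, refs)["f_max"]
        assert f == pytest.approx(2.0 / 3.0, abs=0.03)

    def test_empty_overlap_error(self):
        table = pd.DataFrame({"wdc": [-1.0]}, index=pd.Index(["g"], name="gene"))
        with pytest.raises(DataError):
            shrna.evaluate_performance(table, shrna.ReferenceGeneSets({"x"}, {"y"}))


class TestCumulativeSignalComparison:
    def test_constant_tensor(self):
        t = make_tensor({f"h{i}": two_arm_trajectory([10, 10, 10], [10, 10, 10])
                         for i in range(8)},
                        {f"h{i}": "g" for i in range(8)})
        out = shrna.cumulative_signal_comparison(t, {"g"})
        assert out.loc["induced", "fold_change"] == pytest.approx(1.0)
        assert out.loc["induced", "ks_p"] > 0.9

    def test_halved_signal_fold_two(self, rng):
        traj, genes = {}, {}
        for i in range(10):
            v = rng.normal(10, 1)
            traj[f"h{i}"] = two_arm_trajectory([v, v, v - 1.0], [v, v, v])
            genes[f"h{i}"] = "g"
        t = make_tensor(traj, genes)
        out = shrna.cumulative_signal_comparison(t, {"g"})
        assert out.loc["induced", "fold_change"] == pytest.approx(2.0, abs=1e-9)
        assert out.loc["uninduced", "fold_change"] == pytest.approx(1.0, abs=1e-9)

    def test_empty_gene_set_error(self, default_screen):
        with pytest.raises(DataError):
            shrna.cumulative_signal_comparison(default_screen.tensor, {"nope"})


# ---------------------------------------------------------------------------
# config validation and recovery
# ---------------------------------------------------------------------------

def test_config_validation():
    with pytest.raises(ConfigError):
        shrna.WDCConfig(epsilon=0.0)
    with pytest.raises(ConfigError):
        shrna.WDCConfig(epsilon=1.5)
    with pytest.raises(ConfigError):
        shrna.WDCConfig(k_aggregate=0)
    with pytest.raises(ConfigError):
        shrna.WDCConfig(n_permutations=10)


def test_parameter_recovery(default_screen_scored):
    """Default screen: sdl sensitivity >= 0.9 at scale-matched threshold,
    false-positive rate on non-essential genes <= alpha + 2 binomial sd."""
    sim, cfg, res = default_screen_scored
    gs = res["gene_scores"]
    truth = sim.truth.reindex(gs.index)
    hits = gs["hit"]
    n_sdl = int((truth == "sdl").sum())
    sens = float((hits & (truth == "sdl")).sum()) / n_sdl
    assert sens >= 0.9
    n_ne = int((truth == "non_essential").sum())
    fpr = float((hits & (truth == "non_essential")).sum()) / n_ne
    assert fpr <= cfg.alpha + 2 * np.sqrt(cfg.alpha * (1 - cfg.alpha) / n_ne)
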