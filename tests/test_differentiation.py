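"""Weir-Cockerham F-statistics, AMOVA, PCoA and Evanno delta-K."""

import numpy as np
import pandas as pd
import pytest

from dinpop import differentiation as diff
from dinpop import simulate
from dinpop.datamodel import ClusterLikelihoodTrace, DistanceMatrix, ValidationError
from dinpop.simulate import SimConfig
from tests.conftest import make_table


def fixed_difference_table(n=10):
    rows = [(f"a{k}", "P1", 2, [("x", "x")]) for k in range(n)] + \
        [(f"b{k}", "P2", 2, [("y", "y")]) for k in range(n)]
    return make_table(rows, ["L1"])


def brute_force_theta(table, locus="L1"):
    """Independent re-derivation of the single-locus two-allele estimator,
    written directly from the textbook component formulas (scalar arithmetic,
    no shared code with the implementation)."""
    pops = table.populations
    j = table.locus_index(locus)
    alleles = sorted({a for row in table.calls for c in [row[j]] if c for a in c})
    n_i, p_i, h_i = [], {a: [] for a in alleles}, {a: [] for a in alleles}
    for pop in pops:
        rows = [i for i in table.individuals_in(pop) if table.calls[i][j]]
        n_i.append(len(rows))
        for a in alleles:
            cnt = sum(table.calls[i][j].count(a) for i in rows)
            het = sum(
                1 for i in rows
                if 0 < table.calls[i][j].count(a) < len(table.calls[i][j])
            )
            p_i[a].append(cnt / (2 * len(rows)))
            h_i[a].append(het / len(rows))
    r = len(n_i)
    nbar = sum(n_i) / r
    nc = (sum(n_i) - sum(x * x for x in n_i) / sum(n_i)) / (r - 1)
    A = B = C = 0.0
    for a in alleles:
        pbar = sum(n * p for n, p in zip(n_i, p_i[a])) / sum(n_i)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i[a])) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(n_i, h_i[a])) / sum(n_i)
        A += (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                            / (nbar - 1))
        B += (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                    - (2 * nbar - 1) / (4 * nbar) * hbar)
        C += hbar / 2
    return A / (A + B + C)


class TestWcFstats:
    def test_fixed_difference_theta_is_one(self):
        res = diff.wc_fstats(fixed_difference_table())
        assert res.f_st == pytest.approx(1.0)

    def test_identical_populations_theta_near_zero(self):
        rows = []
        for pop in ("P1", "P2"):
            for k in range(10):
                call = ("x", "y") if k % 2 else ("x", "x")
                rows.append((f"{pop}_{k}", pop, 2, [call]))
        res = diff.wc_fstats(make_table(rows, ["L1"]))
        assert res.f_st <= 1e-9

    def test_matches_hand_computed_components(self):
        """Implementation agrees with an independent scalar re-derivation on
        an asymmetric 2-population x 10-individual fixture."""
        rows = (
            [(f"a{k}", "P1", 2, [("x", "x")]) for k in range(6)]
            + [(f"ah{k}", "P1", 2, [("x", "y")]) for k in range(4)]
            + [(f"bh{k}", "P2", 2, [("x", "y")]) for k in range(2)]
            + [(f"b{k}", "P2", 2, [("y", "y")]) for k in range(8)]
        )
        t = make_table(rows, ["L1"])
        assert diff.wc_fstats(t).f_st == pytest.approx(brute_force_theta(t))

    def test_multilocus_theta_is_component_sum_ratio(self):
        rng = np.random.default_rng(0)
        cfg = SimConfig(n_demes=3, n_individuals=10, n_ssr_loci=3,
                        tetraploid_demes=(), fst=0.2)
        t, _ = simulate.simulate_ssr(cfg, seed=9)
        res = diff.wc_fstats(t)
        per = res.per_locus
        expected = per.a.sum() / (per.a + per.b + per.c).sum()
        assert res.f_st == pytest.approx(expected)
        # and NOT the mean of per-locus ratios (generic data)
        assert res.f_st != pytest.approx(per.f_st.mean(), abs=1e-12)

    def test_single_population_is_error(self):
        rows = [(f"a{k}", "P1", 2, [("x", "y")]) for k in range(5)]
        with pytest.raises(ValidationError):
            diff.wc_fstats(make_table(rows, ["L1"]))

    def test_tetraploid_table_flagged_approximate(self):
        cfg = SimConfig(n_demes=3, n_individuals=8, n_ssr_loci=2)
        t, _ = simulate.simulate_ssr(cfg, seed=3)
        assert diff.wc_fstats(t).approximate_for_tetraploids


class TestPairwiseFst:
    def test_fixed_difference_pair(self):
        dm = diff.pairwise_fst(fixed_difference_table())
        assert dm.values[0, 1] == pytest.approx(1.0)

    def test_outlier_deme_has_maximal_pairs(self):
        cfg = SimConfig(n_demes=4, n_individuals=15, n_ssr_loci=4,
                        tetraploid_demes=(), fst=0.05)
        t, _ = simulate.simulate_ssr(cfg, seed=21)
        # make P4 an outlier: replace its calls with a fixed private allele
        j_all = range(len(t.loci))
        for i in t.individuals_in("P4"):
            for j in j_all:
                t.calls[i][j] = ("z", "z")
        dm = diff.pairwise_fst(t)
        idx = dm.labels.index("P4")
        others = [v for k, v in enumerate(dm.values[idx]) if k != idx]
        rest = dm.values[np.ix_([k for k in range(4) if k != idx],
                                [k for k in range(4) if k != idx])]
        assert min(others) > rest.max()


class TestAmova:
    def test_percentages_sum_to_100(self):
        cfg = SimConfig(n_demes=4, n_individuals=8, n_ssr_loci=3,
                        tetraploid_demes=(), fst=0.15)
        t, _ = simulate.simulate_ssr(cfg, seed=2)
        res = diff.amova(t, n_permutations=0)
        assert res.pct_among + res.pct_within == pytest.approx(100.0, abs=1e-9)

    def test_fully_fixed_demes_all_variance_among(self):
        res = diff.amova(fixed_difference_table(), n_permutations=0)
        assert res.pct_among == pytest.approx(100.0)
        assert res.phi_st == pytest.approx(1.0)

    def test_panmictic_variance_within(self):
        rng = np.random.default_rng(8)
        phis = []
        for s in range(20):
            cfg = SimConfig(n_demes=4, n_individuals=10, n_ssr_loci=4,
                            n_alleles=6, tetraploid_demes=(), fst=0.001)
            t, _ = simulate.simulate_ssr(cfg, seed=300 + s)
            phis.append(diff.amova(t, n_permutations=0).phi_st)
        assert abs(np.mean(phis)) < 0.01

    def test_structured_data_significant(self):
        cfg = SimConfig(n_demes=3, n_individuals=10, n_ssr_loci=4,
                        tetraploid_demes=(), fst=0.3)
        t, _ = simulate.simulate_ssr(cfg, seed=4)
        res = diff.amova(t, n_permutations=199, seed=5)
        assert res.p_value == pytest.approx(1 / 200)

    def test_singleton_population_excluded(self):
        rows = [(f"a{k}", "P1", 2, [("x", "y")]) for k in range(5)] + \
            [(f"b{k}", "P2", 2, [("x", "x")]) for k in range(5)] + \
            [("lone", "P3", 2, [("y", "y")])]
        with pytest.warns(UserWarning, match="P3"):
            res = diff.amova(make_table(rows, ["L1"]), n_permutations=0)
        assert res.df_among == 1


class TestPcoa:
    def test_collinear_points_one_axis(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        d = np.abs(x[:, None] - x[None])
        res = diff.pcoa(DistanceMatrix(list("abcd"), d))
        assert res.pct_variance[0] == pytest.approx(100.0)
        # recovered coordinates reproduce the distances
        rec = np.abs(res.coordinates.iloc[:, 0].values[:, None]
                     - res.coordinates.iloc[:, 0].values[None])
        np.testing.assert_allclose(rec, d, atol=1e-9)

    def test_euclidean_input_no_negative_eigenvalues(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = diff.pcoa(DistanceMatrix([f"s{i}" for i in range(8)], d))
        assert res.eigenvalues.min() > -1e-8

    def test_permuting_input_permutes_coordinates(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"s{i}" for i in range(6)]
        res = diff.pcoa(DistanceMatrix(labels, d))
        perm = [3, 1, 5, 0, 2, 4]
        res_p = diff.pcoa(DistanceMatrix([labels[i] for i in perm],
                                         d[np.ix_(perm, perm)]))
        a = res.coordinates.loc[labels].values
        b = res_p.coordinates.loc[labels].values
        # same subspace up to per-axis sign flips
        for k in range(min(a.shape[1], b.shape[1])):
            assert np.allclose(a[:, k], b[:, k], atol=1e-8) or \
                np.allclose(a[:, k], -b[:, k], atol=1e-8)


class TestEvannoDeltaK:
    def test_linear_likelihood_gives_zero(self):
        trace = ClusterLikelihoodTrace(
            {k: [-100.0 * k + r for r in (0.0, 0.5, 1.0)] for k in range(1, 6)}
        )
        df, _ = diff.evanno_delta_k(trace)
        assert np.allclose(df.delta_k, 0.0)

    @pytest.mark.parametrize("kink", [2, 3])
    def test_single_kink_detected(self, kink):
        rng = np.random.default_rng(kink)
        runs = {
            k: list(-50.0 * abs(k - kink) - 500 + rng.normal(0, 0.5, 3))
            for k in range(1, 7)
        }
        _, best = diff.evanno_delta_k(ClusterLikelihoodTrace(runs))
        assert best == kink

    def test_zero_sd_yields_na_with_warning(self):
        trace = ClusterLikelihoodTrace(
            {1: [-300.0, -301.0], 2: [-200.0, -200.0], 3: [-190.0, -189.0]}
        )
        with pytest.warns(UserWarning, match="zero SD"):
            df, _ = diff.evanno_delta_k(trace)
        assert np.isnan(df.loc[df.K == 2, "delta_k"]).all()

    def test_requirements_enforced(self):
        with pytest.raises(ValidationError):
            diff.evanno_delta_k(ClusterLikelihoodTrace({1: [-1.0, -2.0],
                                                        2: [-1.0, -2.0]}))
        with pytest.raises(ValidationError):
            diff.evanno_delta_k(ClusterLikelihoodTrace(
                {1: [-1.0, -2.0], 2: [-1.0], 3: [-1.0, -2.0]}))
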