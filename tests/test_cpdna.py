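"""Haplotype collapsing, neutrality statistics, and the statistical-parsimony
network, each checked against independent brute-force oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from dinpop import cpdna, simulate
from dinpop.datamodel import HaplotypeAlignment, ValidationError
from dinpop.simulate import SimConfig


def aln_from_strings(seqs, pops=None):
    pops = pops or ["P1"] * len(seqs)
    mat = np.array([list(s) for s in seqs])
    labels = [(f"s{i + 1}", p) for i, p in enumerate(pops)]
    return HaplotypeAlignment(mat, labels, [("r", 1, mat.shape[1])])


class TestMasking:
    def test_gap_free_identity(self, small_alignment):
        out = cpdna.mask_indel_sites(aln_from_strings(["ACGT", "ACGA"]))
        assert out.column_mask.all()

    def test_single_gap_excludes_whole_column(self, small_alignment):
        out = cpdna.mask_indel_sites(small_alignment)
        # column 7 holds a gap, column 9 an N (1-based)
        assert not out.column_mask[6]
        assert not out.column_mask[8]
        assert out.column_mask.sum() == 10

    def test_n_kept_when_disabled(self, small_alignment):
        out = cpdna.mask_indel_sites(small_alignment, mask_n=False)
        assert out.column_mask.sum() == 11

    def test_synthetic_gap_columns_masked(self):
        cfg = SimConfig(n_sequences=10, seq_length=100, n_mutations=5,
                        n_gap_columns=5)
        aln, truth = simulate.simulate_cpdna(cfg, seed=1)
        out = cpdna.mask_indel_sites(aln)
        assert out.column_mask.sum() == 95
        assert not out.column_mask[truth["gap_columns"]].any()


class TestVariableSitesAndCollapse:
    def test_identical_sequences(self):
        aln = aln_from_strings(["ACGT"] * 5)
        assert cpdna.variable_sites(aln) == []
        hs = cpdna.collapse_haplotypes(aln)
        assert hs.k == 1 and hs.frequencies == [5]

    def test_two_sequences_three_differences(self):
        aln = aln_from_strings(["AAAAAA", "ATATAA"])
        assert cpdna.variable_sites(aln) == [2, 4]

    def test_distinct_sequences_are_singletons(self):
        aln = aln_from_strings(["ACGT", "ACGA", "ACTT"])
        hs = cpdna.collapse_haplotypes(aln)
        assert hs.k == 3 and hs.frequencies == [1, 1, 1]

    def test_ids_by_first_occurrence_and_private_flags(self):
        aln = aln_from_strings(["AAAA", "AATA", "AAAA", "AATA"],
                               pops=["P1", "P1", "P1", "P2"])
        hs = cpdna.collapse_haplotypes(aln)
        assert hs.haplotype_ids == ["H1", "H2"]
        assert hs.members["H1"] == ["s1", "s3"]
        flags = hs.private_flags()
        assert flags["H1"] is True and flags["H2"] is False

    def test_collapse_matches_brute_force_on_random_alignments(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n, L = rng.integers(2, 12), rng.integers(5, 30)
            mat = rng.choice(list("ACGT"), size=(n, L))
            aln = HaplotypeAlignment(mat, [(f"s{i}", "P1") for i in range(n)],
                                     [("r", 1, int(L))])
            hs = cpdna.collapse_haplotypes(aln)
            brute = len({"".join(row) for row in mat})
            assert hs.k == brute
            assert sum(hs.frequencies) == n


class TestNucleotideStats:
    def test_identical_sequences(self):
        res = cpdna.nucleotide_stats(aln_from_strings(["ACGT"] * 4))
        assert res.s == 0 and res.pi == 0.0
        assert np.isnan(res.tajimas_d) and np.isnan(res.fus_fs)

    def test_pair_with_four_differences(self):
        res = cpdna.nucleotide_stats(aln_from_strings(["AAAAAA", "TTTTAA"]))
        assert res.pi == 4.0 and res.s == 4

    def test_pi_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        mat = rng.choice(list("ACGT"), size=(6, 40), p=[0.7, 0.1, 0.1, 0.1])
        aln = HaplotypeAlignment(mat, [(f"s{i}", "P1") for i in range(6)],
                                 [("r", 1, 40)])
        res = cpdna.nucleotide_stats(aln)
        pairs = list(itertools.combinations(range(6), 2))
        brute = np.mean([(mat[i] != mat[j]).sum() for i, j in pairs])
        assert res.pi == pytest.approx(brute)
        assert res.theta_w == pytest.approx(res.s / sum(1 / i for i in range(1, 6)))

    def test_pi_invariant_to_row_order(self):
        rng = np.random.default_rng(4)
        mat = rng.choice(list("ACGT"), size=(8, 30))
        aln = HaplotypeAlignment(mat, [(f"s{i}", "P1") for i in range(8)],
                                 [("r", 1, 30)])
        perm = rng.permutation(8)
        aln2 = HaplotypeAlignment(mat[perm],
                                  [(f"s{i}", "P1") for i in range(8)],
                                  [("r", 1, 30)])
        assert cpdna.nucleotide_stats(aln).pi == \
            pytest.approx(cpdna.nucleotide_stats(aln2).pi)


class TestTajimasD:
    def test_zero_when_pi_equals_watterson(self):
        n, s = 10, 7
        a1 = sum(1 / i for i in range(1, n))
        assert cpdna.tajimas_d(n, s, s / a1) == pytest.approx(0.0)

    def test_na_for_no_segregating_sites(self):
        assert np.isnan(cpdna.tajimas_d(10, 0, 0.0))

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            cpdna.tajimas_d(3, 2, 1.0)

    def test_sign_follows_frequency_spectrum(self):
        # excess rare variants (singleton columns) -> negative D
        seqs = ["A" * 20]
        for i in range(5):
            s = list("A" * 20)
            s[i] = "T"
            seqs.append("".join(s))
        res = cpdna.nucleotide_stats(aln_from_strings(seqs))
        assert res.tajimas_d < 0


class TestFusFs:
    def test_two_sequence_closed_form(self):
        # n=2, k=2, theta=1: P(K=2) = theta/(theta+1) = 1/2, Fs = ln(1) = 0
        assert cpdna.fus_fs(2, 1.0, 2) == pytest.approx(0.0)

    def test_na_cases(self):
        assert np.isnan(cpdna.fus_fs(10, 0.0, 3))
        assert np.isnan(cpdna.fus_fs(10, 2.0, 1))

    def test_k_obs_exceeding_n_rejected(self):
        with pytest.raises(ValidationError):
            cpdna.fus_fs(5, 1.0, 6)

    def test_stirling_rows_satisfy_rising_factorial_identity(self):
        # sum_k |s(n,k)| theta^k = (theta)_n, i.e. P(K >= 1) = 1
        for n, theta in [(5, 0.7), (12, 2.3), (30, 6.0)]:
            log_row = cpdna._log_stirling_row(n)
            ks = np.arange(n + 1)
            total = np.logaddexp.reduce(log_row[1:] + ks[1:] * math.log(theta))
            rising = sum(math.log(theta + i) for i in range(n))
            assert total == pytest.approx(rising, abs=1e-10)

    def test_log_space_agrees_with_exact_rational(self):
        for n, theta, k in [(10, 1.5, 4), (25, 3.0, 10), (61, 2.5, 17),
                            (61, 7.0, 2)]:
            assert cpdna.fus_fs(n, theta, k) == \
                pytest.approx(cpdna.fus_fs_exact(n, Fraction(theta), k),
                              rel=1e-9)

    def test_excess_haplotypes_give_negative_fs(self):
        # many haplotypes at modest pairwise diversity -> strongly negative
        assert cpdna.fus_fs(61, 1.5, 17) < -5


class TestParsimonyLimit:
    def test_limit_monotone_in_sequence_length(self):
        limits = [cpdna.parsimony_connection_limit(m)
                  for m in (50, 200, 600, 1650, 5000)]
        assert all(b >= a for a, b in zip(limits, limits[1:]))

    def test_one_step_always_admissible_at_realistic_lengths(self):
        for m in (60, 100, 600, 1650):
            assert cpdna.parsimony_connection_limit(m) >= 1

    def test_connection_limit_regression_1650(self):
        """Frozen value for the concatenated-spacer length (1650 kept sites)."""
        assert cpdna.parsimony_connection_limit(1650, confidence=0.95) == 12

    def test_probability_matches_monte_carlo_oracle(self):
        """Independent per-site Poisson/JC simulation reproduces P(j | m)."""
        rng = np.random.default_rng(12)
        m, j = 80, 3
        p = j / m
        d = -0.75 * math.log1p(-4 * p / 3)
        trials = 300_000
        hits = rng.poisson(d, size=(trials, m))
        # a site is visibly different with prob (3/4)(1 - (-1/3)^h)
        vis_prob = 0.75 * (1.0 - (-1 / 3.0) ** hits)
        visible = rng.random(hits.shape) < vis_prob
        cond = visible.sum(axis=1) == j
        parsimonious = (hits.sum(axis=1) == j) & ((hits <= 1).all(axis=1))
        mc = (parsimonious & cond).sum() / cond.sum()
        assert cpdna.parsimony_probability(j, m) == pytest.approx(mc, abs=0.02)


class TestTcsNetwork:
    def test_single_step_pair(self):
        hs = cpdna.collapse_haplotypes(aln_from_strings(["AAAA", "AATA"]))
        net = cpdna.build_tcs_network(hs, limit=5)
        assert [n.node_id for n in net.nodes] == ["H1", "H2"]
        assert net.edges == [("H1", "H2")]

    def test_two_step_chain_inserts_hypothetical_node(self):
        hs = cpdna.collapse_haplotypes(aln_from_strings(["AAAA", "AATT"]))
        net = cpdna.build_tcs_network(hs, limit=5)
        hypos = [n for n in net.nodes if not n.observed]
        assert len(hypos) == 1 and hypos[0].frequency == 0
        assert len(net.edges) == 2

    def test_three_haplotypes_on_chain_central_degree_two(self):
        hs = cpdna.collapse_haplotypes(
            aln_from_strings(["AAAA", "AATA", "AATT"]))
        net = cpdna.build_tcs_network(hs, limit=5)
        deg = {}
        for u, v in net.edges:
            deg[u] = deg.get(u, 0) + 1
            deg[v] = deg.get(v, 0) + 1
        assert deg["H2"] == 2
        assert all(not n.node_id.startswith("m") for n in net.nodes)

    def test_beyond_limit_stays_disconnected(self):
        hs = cpdna.collapse_haplotypes(aln_from_strings(["AAAAAA", "TTTTTT"]))
        net = cpdna.build_tcs_network(hs, limit=3)
        assert net.edges == []

    def test_random_sets_match_connectivity_oracle(self):
        """Chains realise exact pairwise distances; components equal the
        transitive closure of the <=limit distance graph."""
        rng = np.random.default_rng(8)
        for trial in range(15):
            n, L = int(rng.integers(3, 11)), 20
            mat = rng.choice(list("ACGT"), size=(n, L), p=[0.85, 0.05, 0.05, 0.05])
            aln = HaplotypeAlignment(mat, [(f"s{i}", "P1") for i in range(n)],
                                     [("r", 1, L)])
            hs = cpdna.collapse_haplotypes(aln)
            limit = 4
            net = cpdna.build_tcs_network(hs, limit)

            # forest property: edges = nodes - components (no cycles by design)
            import networkx as nx
            g = nx.Graph()
            g.add_nodes_from(n.node_id for n in net.nodes)
            g.add_edges_from(net.edges)
            assert g.number_of_edges() == g.number_of_nodes() - \
                nx.number_connected_components(g)

            # brute-force component structure of the <=limit graph
            brute = nx.Graph()
            brute.add_nodes_from(hs.haplotype_ids)
            for (i, a), (j, b) in itertools.combinations(
                    enumerate(hs.haplotype_ids), 2):
                dist = (hs.representatives[i] != hs.representatives[j]).sum()
                if dist <= limit:
                    brute.add_edge(a, b)
            obs_components = {
                frozenset(x for x in comp if not x.startswith("m"))
                for comp in nx.connected_components(g)
            }
            assert obs_components == set(
                map(frozenset, nx.connected_components(brute)))

            # every inserted chain length equals the joined pair's distance:
            # total edges == sum over spanning joins of their distances
            n_hypo = sum(1 for node in net.nodes if not node.observed)
            assert g.number_of_edges() == n_hypo + (
                hs.k - nx.number_connected_components(brute))

    def test_frequency_conservation(self):
        cfg = SimConfig(n_sequences=30, seq_length=200, n_mutations=12)
        aln, _ = simulate.simulate_cpdna(cfg, seed=17)
        hs = cpdna.collapse_haplotypes(cpdna.mask_indel_sites(aln))
        net = cpdna.build_tcs_network(hs, cpdna.parsimony_connection_limit(200))
        assert net.observed_frequency_total == 30


class TestNjFromPdistance:
    def test_identical_sequences_star_with_zero_lengths(self):
        aln = aln_from_strings(["ACGT"] * 4)
        tree, _ = cpdna.nj_from_pdistance(aln, boot=5, seed=0)
        lengths = [l for nbrs in tree.adjacency.values() for l in nbrs.values()]
        assert max(lengths) == 0.0

    def test_diverged_clades_recovered_with_high_support(self):
        rng = np.random.default_rng(10)
        base = rng.choice(list("ACGT"), size=60)
        other = base.copy()
        other[:20] = np.where(other[:20] == "A", "T", "A")
        seqs = []
        for k in range(3):
            s = base.copy()
            s[40 + k] = "C" if s[40 + k] != "C" else "G"
            seqs.append("".join(s))
        for k in range(3):
            s = other.copy()
            s[50 + k] = "C" if s[50 + k] != "C" else "G"
            seqs.append("".join(s))
        aln = aln_from_strings(seqs)
        tree, support = cpdna.nj_from_pdistance(aln, boot=100, seed=3)
        split = frozenset({"s4", "s5", "s6"})
        assert support[split] >= 99.0
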