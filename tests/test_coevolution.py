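import itertools

import numpy as np
import pandas as pd
import pytest

from rotormech import coevolution as coev
from rotormech import fixtures
from rotormech.coevolution import (Msa, PairedMSA, apc_correct, apc_mi,
                                   filter_redundancy, mfdca, mi_matrix,
                                   msa_shuffle_null, overlap_dynamics,
                                   pair_sequences, top_fraction)


def make_msa(rows, alphabet="AB", ids=None):
    mat = np.array([[alphabet.index(c) for c in r] for r in rows])
    return Msa(ids=ids or [f"s{i}" for i in range(len(rows))],
               matrix=mat, alphabet=alphabet)


class TestFilterRedundancy:
    def test_identical_rows_collapse(self):
        msa = make_msa(["AAB", "AAB", "ABB"], alphabet="AB")
        out = filter_redundancy(msa, 0.8)
        assert out.n_sequences == 2

    def test_diverse_rows_unchanged(self):
        msa = make_msa(["AAAA", "BBBB", "AABB"], alphabet="AB")
        out = filter_redundancy(msa, 0.8)
        assert out.n_sequences == 3

    def test_duplicated_synthetic_msa_restores_diversity(self, rng):
        base = ["".join(r) for r in
                rng.choice(list("ACDE"), size=(10, 12))]
        dup = [s for s in base for _ in range(5)]
        msa = make_msa(dup, alphabet="ACDE")
        out = filter_redundancy(msa, 0.8)
        assert out.n_sequences <= 10

    def test_output_is_fixed_point(self, rng):
        rows = ["".join(r) for r in rng.choice(list("AB"), size=(30, 8))]
        once = filter_redundancy(make_msa(rows, "AB"), 0.8)
        twice = filter_redundancy(once, 0.8)
        assert once.n_sequences == twice.n_sequences

    def test_gap_columns_excluded_from_identity(self):
        msa = make_msa(["AA--", "AABB"], alphabet="AB-")
        # identity over matched non-gap columns is 2/2 = 1.0
        out = filter_redundancy(msa, 0.8)
        assert out.n_sequences == 1


class TestPairSequences:
    def _meta(self, entries):
        return pd.DataFrame(entries, columns=["seq_id", "organism", "locus"])

    def test_single_pair_concatenated(self):
        a = make_msa(["AB"], ids=["a1"])
        b = make_msa(["BA"], ids=["b1"])
        meta = self._meta([("a1", "org1", 100), ("b1", "org1", 118)])
        p = pair_sequences(a, b, meta)
        assert p.n_sequences == 1
        assert p.sequences() == ["ABBA"]
        assert p.gene_distance[0] == 18
        assert p.boundary == 2

    def test_distant_pair_discarded(self):
        a = make_msa(["AB"], ids=["a1"])
        b = make_msa(["BA"], ids=["b1"])
        meta = self._meta([("a1", "org1", 100), ("b1", "org1", 250)])
        with pytest.raises(ValueError, match="no organism"):
            pair_sequences(a, b, meta, max_gene_distance=100)

    def test_paralog_matching_agrees_with_exhaustive_oracle(self, rng):
        for trial in range(5):
            la = rng.integers(0, 60, 4)
            lb = rng.integers(0, 60, 4)
            a = make_msa(["AB"] * 4, ids=[f"a{i}" for i in range(4)])
            b = make_msa(["BA"] * 4, ids=[f"b{i}" for i in range(4)])
            meta = self._meta(
                [(f"a{i}", "org", int(la[i])) for i in range(4)]
                + [(f"b{i}", "org", int(lb[i])) for i in range(4)])
            p = pair_sequences(a, b, meta, max_gene_distance=1000,
                               method="optimal")
            got = p.gene_distance.sum()
            best = min(sum(abs(la[i] - lb[perm[i]]) for i in range(4))
                       for perm in itertools.permutations(range(4)))
            assert got == best

    def test_missing_metadata_errors(self):
        a = make_msa(["AB"], ids=["a1"])
        b = make_msa(["BA"], ids=["b1"])
        with pytest.raises(ValueError, match="metadata missing"):
            pair_sequences(a, b, self._meta([("a1", "org1", 1)]))


def paired_from_matrix(mat, alphabet, boundary):
    mat = np.asarray(mat)
    return PairedMSA(ids=[f"s{i}" for i in range(len(mat))], matrix=mat,
                     alphabet=alphabet, boundary=boundary,
                     organisms=[f"o{i}" for i in range(len(mat))],
                     gene_distance=np.zeros(len(mat), int))


class TestMfdca:
    def test_two_column_case_matches_closed_form_oracle(self, rng):
        # hand-computable 2-column, 2-letter alignment
        mat = np.array([[0, 0]] * 40 + [[1, 1]] * 35 + [[0, 1]] * 15
                       + [[1, 0]] * 10)
        p = paired_from_matrix(mat, "AB", 1)
        pc, theta = 0.2, 1.01  # theta > 1: no reweighting (all weights 1)
        net = mfdca(p, pseudocount=pc, seqid_reweight=theta)

        # independent oracle: same mean-field equations from first principles
        n = len(mat)
        q = 2
        f1 = np.stack([np.bincount(mat[:, i], minlength=q) / n
                       for i in range(2)])
        f2 = np.zeros((q, q))
        for a, b in mat:
            f2[a, b] += 1.0 / n
        f1 = (1 - pc) * f1 + pc / q
        f2 = (1 - pc) * f2 + pc / q ** 2
        # C over the first q-1 states is a 2x2 matrix here
        C = np.array([
            [f1[0, 0] - f1[0, 0] ** 2, f2[0, 0] - f1[0, 0] * f1[1, 0]],
            [f2[0, 0] - f1[0, 0] * f1[1, 0], f1[1, 0] - f1[1, 0] ** 2]])
        e = -np.linalg.inv(C)[0, 1]
        W = np.exp(np.array([[e, 0.0], [0.0, 0.0]]))
        mu1 = np.ones(q) / q
        mu2 = np.ones(q) / q
        for _ in range(2000):
            mu1 = f1[0] / (W @ mu2)
            mu1 /= mu1.sum()
            mu2 = f1[1] / (W.T @ mu1)
            mu2 /= mu2.sum()
        pdir = W * np.outer(mu1, mu2)
        pdir /= pdir.sum()
        di = np.sum(pdir * np.log(pdir / np.outer(f1[0], f1[1])))
        assert net.scores[0, 1] == pytest.approx(di, abs=1e-8)

    def test_iid_columns_indistinguishable_from_null(self, rng):
        mat = rng.integers(0, 4, (400, 6))
        p = paired_from_matrix(mat, "ACDE", 3)
        net = mfdca(p)
        thr = msa_shuffle_null(p, n_shuffles=20, seed=0,
                               scorer=lambda m: mfdca(m))
        iu = np.triu_indices(6, k=1)
        assert (net.scores[iu] <= thr).mean() >= 0.8

    def test_planted_pair_is_top_inter_boundary(self):
        gt = fixtures.PottsGroundTruth(seed=17)
        sample = fixtures.sample_potts_msa(gt)
        net = mfdca(sample.paired)
        i, j, _ = gt.coupled_pairs[0]
        top = net.pair_scores(inter_only=True)[0]
        assert (top[0], top[1]) == (i, j)

    def test_zero_pseudocount_singular_matrix_errors(self):
        mat = np.array([[0, 0], [0, 0], [1, 1], [1, 1]])
        p = paired_from_matrix(mat, "AB", 1)
        with pytest.raises(ValueError, match="pseudocount"):
            mfdca(p, pseudocount=0.0)

    def test_di_and_apc_mi_agree_on_top_pair_across_seeds(self):
        hits = 0
        for seed in range(5):
            gt = fixtures.PottsGroundTruth(n_sequences=800, seed=100 + seed)
            sample = fixtures.sample_potts_msa(gt)
            di_top = mfdca(sample.paired).pair_scores(inter_only=True)[0][:2]
            mi_top = apc_mi(sample.paired).pair_scores(inter_only=True)[0][:2]
            hits += di_top == mi_top
        assert hits >= 4


class TestApcMi:
    def test_rank_one_background_suppressed(self, rng):
        # APC models the background as outer(row means); on a rank-one
        # matrix the residual is O(1/L) of the original scale and shrinks
        # as the alignment grows
        def residual(L):
            a = rng.uniform(0.5, 2.0, L)
            M = np.outer(a, a)
            np.fill_diagonal(M, 0.0)
            out = apc_correct(M)
            iu = np.triu_indices(L, k=1)
            return np.abs(out[iu]).max() / M[iu].max()

        r10, r40, r160 = residual(10), residual(40), residual(160)
        assert r40 < 0.1
        assert r160 < r40 < r10

    def test_matches_plugin_mi_plus_correction(self, rng):
        mat = rng.integers(0, 3, (200, 5))
        p = paired_from_matrix(mat, "ACD", 2)
        net = apc_mi(p)
        mi = mi_matrix(p)
        np.testing.assert_allclose(net.scores, apc_correct(mi), atol=1e-12)


class TestTopFractionAndNull:
    def _net(self, rng, L=46):
        s = rng.uniform(0, 1, (L, L))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 0)
        return coev.CouplingNetwork(scores=s, method="DI", boundary=L // 2)

    def test_fraction_edges(self, rng):
        net = self._net(rng)
        n_pairs = 46 * 45 // 2  # 1035
        assert top_fraction(net, 0.0).edges == []
        assert len(top_fraction(net, 1.0).edges) == n_pairs
        got = top_fraction(net, 0.015).edges
        assert len(got) == int(np.ceil(0.015 * n_pairs))
        iu = np.triu_indices(46, k=1)
        ranked = np.sort(net.scores[iu])[::-1]
        np.testing.assert_allclose([e[2] for e in got],
                                   ranked[:len(got)], atol=1e-12)

    def test_tail_fractions_reported(self, rng):
        net = self._net(rng)
        te = top_fraction(net, 0.015)
        assert 0.0 <= te.tail_fraction_3sigma <= te.tail_fraction_2sigma <= 1.0

    def test_shuffle_null_constant_columns_zero(self):
        mat = np.zeros((50, 4), dtype=int)
        mat[:, 2] = 1  # keep the alphabet honest but columns constant
        p = paired_from_matrix(mat, "AB", 2)
        assert msa_shuffle_null(p, n_shuffles=5, seed=0) == pytest.approx(
            0.0, abs=1e-12)

    def test_shuffle_null_seed_stability(self, rng):
        mat = rng.integers(0, 4, (300, 6))
        p = paired_from_matrix(mat, "ACDE", 3)
        t1 = msa_shuffle_null(p, n_shuffles=40, seed=1)
        t2 = msa_shuffle_null(p, n_shuffles=40, seed=2)
        assert abs(t1 - t2) <= 0.15 * max(t1, t2)


class TestOverlapDynamics:
    def test_contact_and_long_range_classification(self):
        s = fixtures.build_reference_trace((40,))
        col2res = {i: ("A", i + 1) for i in range(40)}
        edges = [(0, 2, 0.9),   # ~7 A apart -> contact
                 (0, 30, 0.8)]  # far along the rod -> long range
        nodes = [("A", 30)]
        rep = overlap_dynamics(edges, s, col2res, nodes, contact_cutoff=8.0)
        assert rep.n_interface_contact == 1
        assert rep.n_long_range == 1
        assert rep.n_long_range_adjacent == 1
        assert rep.rows[1]["class"] == "long_range"
        assert rep.rows[1]["adjacent_to_node"]

    def test_planted_contact_and_distal_pairs_labelled(self):
        # couple columns mapping to residues 1-3 (contact) and 1-35 (distal)
        gt = fixtures.PottsGroundTruth(
            length_a=4, length_b=4, q=4,
            coupled_pairs=((0, 4, 2.5), (1, 6, 2.5)),
            n_sequences=1500, seed=23)
        sample = fixtures.sample_potts_msa(gt)
        net = mfdca(sample.paired)
        inter = net.pair_scores(inter_only=True)[:2]
        assert {(e[0], e[1]) for e in inter} == {(0, 4), (1, 6)}
        s = fixtures.build_reference_trace((40,))
        col2res = {0: ("A", 1), 1: ("A", 2), 2: ("A", 3), 3: ("A", 4),
                   4: ("A", 2), 5: ("A", 20), 6: ("A", 35), 7: ("A", 38)}
        rep = overlap_dynamics([(e[0], e[1], e[2]) for e in inter], s,
                               col2res, dynamic_nodes=[("A", 34)])
        classes = {(r["col_i"], r["col_j"]): r["class"] for r in rep.rows}
        assert classes[(0, 4)] == "interface_contact"
        assert classes[(1, 6)] == "long_range"


class TestMsaIo:
    def test_fasta_round_trip(self, rng):
        mat = rng.integers(0, 21, (5, 8))
        msa = Msa(ids=[f"s{i}" for i in range(5)], matrix=mat)
        back = Msa.from_fasta(msa.to_fasta())
        np.testing.assert_array_equal(back.matrix, msa.matrix)
        assert back.ids == msa.ids

    def test_unknown_symbol_errors(self):
        with pytest.raises(ValueError, match="not in alphabet"):
            Msa.from_fasta(">x\nAZX*\n", alphabet="A")
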