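"""GCA/SCA diallel model, heterotic grouping, testers, NCII enumeration."""

import numpy as np
import pandas as pd
import pytest

from diallelgp import diallel, kinship, lmm
from diallelgp.diallel import (
    HeteroticPartition,
    SCAMatrix,
    choose_testers,
    complete_sca_matrix,
    enumerate_ncii,
    fit_diallel,
    heterotic_partition,
    partition_concordance,
)
from diallelgp.kinship import HybridDesign, KinshipMatrix


def _identity_setup(n_parents=8, rng=None):
    parents = [f"P{i:02d}" for i in range(n_parents)]
    Gp = KinshipMatrix(np.asarray(parents, dtype=object), np.eye(n_parents), "Gp")
    design = HybridDesign.full_diallel(parents)
    H = KinshipMatrix(design.cross_ids, np.eye(len(design)), "H")
    return parents, Gp, design, H


class TestFitDiallel:
    def test_identity_kernels_gca_tracks_marginal_means(self, rng):
        """Gp = I, H = I, balanced full diallel: GCA BLUPs are proportional
        to the centered parental marginal means."""
        parents, Gp, design, H = _identity_setup(8)
        effects = dict(zip(parents, rng.normal(0, 1.0, len(parents))))
        y = pd.Series(
            {cid: effects[a] + effects[b] for cid, (a, b) in zip(design.cross_ids, design.crosses)}
        )
        y += rng.normal(0, 0.05, len(y))
        means = lmm.AdjustedMeans(trait="t", values=y)
        fit = fit_diallel(means, design, Gp, H)
        marg = {
            p: np.mean([y[c] for c, (a, b) in zip(design.cross_ids, design.crosses) if p in (a, b)])
            for p in parents
        }
        marg = pd.Series(marg) - pd.Series(marg).mean()
        r = np.corrcoef(fit.gca.loc[parents], marg.loc[parents])[0, 1]
        assert r > 0.999

    def test_prediction_reproduces_mme_solution(self, rng):
        parents, Gp, design, H = _identity_setup(6)
        y = pd.Series(rng.normal(size=len(design)), index=design.cross_ids)
        means = lmm.AdjustedMeans(trait="t", values=y)
        fit = fit_diallel(means, design, Gp, H)
        Zp = np.zeros((len(design), len(parents)))
        for r_, (a, b) in enumerate(design.crosses):
            Zp[r_, parents.index(a)] = 1.0
            Zp[r_, parents.index(b)] = 1.0
        manual = (
            fit.fit.beta["intercept"]
            + Zp @ fit.gca.loc[parents].to_numpy()
            + fit.sca.loc[design.cross_ids].to_numpy()
        )
        # identical to the engine's fitted values from the same MME
        engine = (
            fit.fit.beta["intercept"]
            + fit.fit.blups["gca"].loc[parents].to_numpy() @ Zp.T
            + fit.fit.blups["sca"].loc[design.cross_ids].to_numpy()
        )
        np.testing.assert_allclose(manual, engine, atol=1e-12)

    def test_parent_in_no_cross_rejected(self, rng):
        parents, Gp, _, _ = _identity_setup(5)
        sub = HybridDesign.full_diallel(parents[:4])  # P04 appears nowhere
        Hs = KinshipMatrix(sub.cross_ids, np.eye(len(sub)), "H")
        y = pd.Series(rng.normal(size=len(sub)), index=sub.cross_ids)
        with pytest.raises(ValueError, match="no observed cross"):
            fit_diallel(lmm.AdjustedMeans("t", y), sub, Gp, Hs)

    def test_pure_gca_data_small_sca_variance(self, rng):
        """Simulated pure-GCA phenotypes leave the SCA component near zero
        in most replicates."""
        from diallelgp.genotypes import qc_hybrid_panel
        from diallelgp.kinship import gp_matrix, sca_kernel
        from diallelgp.synthetic_data import SimConfig, simulate_parents

        wins = 0
        reps = 8
        for rep in range(reps):
            cfg = SimConfig(
                n_lines=14, n_markers=300, n_pools=2, divergence=0.2,
                n_diallel_parents=14, seed=100 + rep,
            )
            G, _ = simulate_parents(cfg)
            Gh, _ = qc_hybrid_panel(G, maf_min=0.05)
            Gp = gp_matrix(Gh)
            design = HybridDesign.full_diallel(list(G.line_ids))
            H = sca_kernel(Gp, design)
            rng_i = np.random.default_rng(rep)
            alpha = rng_i.normal(size=Gh.n_markers)
            gvals = Gh.dosages @ alpha
            gvals = gvals / gvals.std()
            effects = dict(zip(G.line_ids, gvals))
            y = pd.Series(
                {c: effects[a] + effects[b] + rng_i.normal(0, 0.1)
                 for c, (a, b) in zip(design.cross_ids, design.crosses)}
            )
            fit = fit_diallel(lmm.AdjustedMeans("t", y), design, Gp, H)
            if fit.var_sca < 0.05 * fit.var_gca:
                wins += 1
        assert wins >= 0.75 * reps


class TestSCAMatrix:
    def test_full_diallel_matrix_is_blups(self, rng):
        parents, Gp, design, H = _identity_setup(6)
        y = pd.Series(rng.normal(size=len(design)), index=design.cross_ids)
        fit = fit_diallel(lmm.AdjustedMeans("t", y), design, Gp, H)
        S = complete_sca_matrix(fit, Gp, design)
        for cid, (a, b) in zip(design.cross_ids, design.crosses):
            i, j = parents.index(a), parents.index(b)
            assert S.values[i, j] == pytest.approx(fit.sca[cid])
        np.testing.assert_allclose(S.values, S.values.T)
        np.testing.assert_allclose(np.diag(S.values), 0.0)

    def test_unobserved_pairs_shrunk_with_identity_gp(self, rng):
        """With Gp = I the SCA kernel links no two distinct crosses, so
        unobserved pairs predict to exactly the prior mean 0."""
        parents, Gp, design, H = _identity_setup(6)
        observed = np.ones(len(design), dtype=bool)
        observed[-3:] = False
        design = HybridDesign(design.crosses, observed)
        Hobs = KinshipMatrix(
            design.subset(observed).cross_ids, np.eye(int(observed.sum())), "H"
        )
        y = pd.Series(
            rng.normal(size=int(observed.sum())),
            index=design.subset(observed).cross_ids,
        )
        fit = fit_diallel(lmm.AdjustedMeans("t", y), design, Gp, Hobs)
        S = complete_sca_matrix(fit, Gp, design)
        for a, b in np.array(design.crosses, dtype=object)[~observed]:
            i, j = parents.index(a), parents.index(b)
            assert abs(S.values[i, j]) < 0.51  # halved self-kernel shrinks hard

    def test_validation(self):
        with pytest.raises(ValueError, match="diagonal"):
            SCAMatrix(np.array(["a", "b"], dtype=object), np.array([[1.0, 0.0], [0.0, 0.0]]))


class TestPartition:
    def test_block_matrix_perfect_recovery(self):
        n = 20
        parents = np.array([f"P{i:02d}" for i in range(n)], dtype=object)
        S = np.zeros((n, n))
        S[:10, 10:] = 1.0
        S[10:, :10] = 1.0
        part = heterotic_partition(SCAMatrix(parents, S), k=2, seed=0)
        assert part.k == 2
        assert len(set(part.groups[:10])) == 1
        assert len(set(part.groups[10:])) == 1
        assert part.groups[0] != part.groups[-1]

    def test_two_nonempty_groups(self, rng):
        n = 12
        parents = np.array([f"P{i}" for i in range(n)], dtype=object)
        S = rng.normal(size=(n, n))
        S = 0.5 * (S + S.T)
        np.fill_diagonal(S, 0.0)
        part = heterotic_partition(SCAMatrix(parents, S), k=2, seed=1)
        assert len(part.members(1)) > 0 and len(part.members(2)) > 0

    def test_seed_determinism(self, rng):
        n = 16
        parents = np.array([f"P{i}" for i in range(n)], dtype=object)
        S = rng.normal(size=(n, n))
        S = 0.5 * (S + S.T)
        np.fill_diagonal(S, 0.0)
        a = heterotic_partition(SCAMatrix(parents, S), k=2, seed=5)
        b = heterotic_partition(SCAMatrix(parents, S), k=2, seed=5)
        np.testing.assert_array_equal(a.groups, b.groups)

    def test_k_exceeds_parents(self):
        parents = np.array(["a", "b"], dtype=object)
        S = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            heterotic_partition(SCAMatrix(parents, S), k=3)


class TestTesters:
    def _partition_with_fit(self, gca_values, rng, sca=None):
        parents = list(gca_values.index)
        n = len(parents)
        groups = np.array([1] * (n // 2) + [2] * (n - n // 2))
        part = HeteroticPartition(np.asarray(parents, dtype=object), groups)
        S = SCAMatrix(
            np.asarray(parents, dtype=object),
            np.zeros((n, n)) if sca is None else sca,
        )
        fit = type("F", (), {"gca": gca_values})()
        return part, fit, S

    def test_dominating_gca_elected(self, rng):
        parents = [f"P{i}" for i in range(8)]
        gca = pd.Series(rng.normal(0, 0.1, 8), index=parents)
        gca["P2"] += 10.0  # group 1 member dominates
        gca["P6"] += 10.0  # group 2 member dominates
        part, fit, S = self._partition_with_fit(gca, rng)
        out = choose_testers(part, fit, S)
        assert out.testers == {1: "P2", 2: "P6"}

    def test_tie_breaks_lexicographically(self, rng):
        parents = [f"P{i}" for i in range(6)]
        gca = pd.Series(np.zeros(6), index=parents)
        part, fit, S = self._partition_with_fit(gca, rng)
        out = choose_testers(part, fit, S)
        assert out.testers == {1: "P0", 2: "P3"}

    def test_matches_bruteforce_scoring(self, rng):
        """6-parent toy with explicit effect table: the elected tester
        matches exhaustive evaluation of mean(gca_i + gca_j + sca_ij)."""
        parents = [f"P{i}" for i in range(6)]
        gca = pd.Series(rng.normal(size=6), index=parents)
        S = rng.normal(size=(6, 6))
        S = 0.5 * (S + S.T)
        np.fill_diagonal(S, 0.0)
        part, fit, Sm = self._partition_with_fit(gca, rng, sca=S)
        out = choose_testers(part, fit, Sm)
        for g, members in ((1, parents[:3]), (2, parents[3:])):
            others = parents[3:] if g == 1 else parents[:3]
            scores = {
                m: np.mean(
                    [gca[m] + gca[o] + S[parents.index(m), parents.index(o)] for o in others]
                )
                for m in members
            }
            assert out.testers[g] == max(sorted(scores), key=lambda m: scores[m])

    def test_gca_rule(self, rng):
        parents = [f"P{i}" for i in range(6)]
        gca = pd.Series([3.0, 1.0, 2.0, 0.0, 5.0, 4.0], index=parents)
        part, fit, S = self._partition_with_fit(gca, rng)
        out = choose_testers(part, fit, S, rule="gca")
        assert out.testers == {1: "P0", 2: "P4"}


class TestNCII:
    def _partition(self, sizes):
        parents = np.array([f"P{i}" for i in range(sum(sizes))], dtype=object)
        groups = np.array([1] * sizes[0] + [2] * sizes[1])
        return HeteroticPartition(parents, groups)

    def test_counts_3x4(self):
        assert len(enumerate_ncii(self._partition((3, 4)))) == 12

    def test_counts_20x25(self):
        assert len(enumerate_ncii(self._partition((20, 25)))) == 500

    def test_no_within_group_pairs(self):
        part = self._partition((5, 6))
        design = enumerate_ncii(part)
        g = dict(zip(part.parents, part.groups))
        assert all(g[a] != g[b] for a, b in design.crosses)

    def test_observed_flags_carried(self):
        part = self._partition((2, 2))
        base = HybridDesign([("P0", "P2")], observed=np.array([True]))
        design = enumerate_ncii(part, base=base)
        flags = dict(zip([frozenset(c) for c in design.crosses], design.observed))
        assert flags[frozenset(("P0", "P2"))]
        assert not flags[frozenset(("P0", "P3"))]

    def test_three_groups_unsupported(self):
        parents = np.array(["a", "b", "c"], dtype=object)
        part = HeteroticPartition(parents, np.array([1, 2, 3]))
        with pytest.raises(ValueError):
            enumerate_ncii(part)


class TestPartitionConcordance:
    def _make(self, groups, testers=None):
        parents = np.array([f"P{i:02d}" for i in range(len(groups))], dtype=object)
        return HeteroticPartition(parents, np.asarray(groups), testers=testers)

    def test_identical(self):
        p = self._make([1] * 5 + [2] * 5, testers={1: "P00", 2: "P05"})
        r, coin = partition_concordance(p, p)
        assert r == pytest.approx(1.0)
        assert coin == 1.0

    def test_label_swap_aligned(self):
        groups = [1] * 5 + [2] * 5
        p1 = self._make(groups)
        p2 = self._make([3 - g for g in groups])
        r, _ = partition_concordance(p1, p2)
        assert r == pytest.approx(1.0)

    def test_matches_phi_coefficient(self):
        """45 parents, 2 lines moved: r equals the hand-computed phi of the
        2x2 contingency table."""
        g1 = np.array([1] * 22 + [2] * 23)
        g2 = g1.copy()
        g2[0], g2[22] = 2, 1
        p1, p2 = self._make(g1), self._make(g2)
        r, _ = partition_concordance(p1, p2)
        a = np.sum((g1 == 1) & (g2 == 1))
        b = np.sum((g1 == 1) & (g2 == 2))
        c = np.sum((g1 == 2) & (g2 == 1))
        d = np.sum((g1 == 2) & (g2 == 2))
        phi = (a * d - b * c) / np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
        assert r == pytest.approx(phi)

    def test_different_parent_sets(self):
        p1 = self._make([1, 1, 2, 2])
        p2 = HeteroticPartition(
            np.array(["X1", "X2", "X3", "X4"], dtype=object), np.array([1, 1, 2, 2])
        )
        with pytest.raises(ValueError):
            partition_concordance(p1, p2)
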