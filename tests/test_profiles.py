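"""Clustering, Mann-Whitney/effect-size machinery, BH adjustment, signatures."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

import physioage as pa
from physioage.cohort import CohortError
from physioage.profiles import mann_whitney_effect


def _em(phi: np.ndarray, ids=None) -> pa.ExplanationMatrix:
    n = len(phi)
    ids = pd.Index(range(n), name="id") if ids is None else ids
    return pa.ExplanationMatrix(
        phi=pd.DataFrame(phi, index=ids, columns=[f"v{i}" for i in range(phi.shape[1])]),
        base_value={"50-50": 0.0},
        flavor="contextualized",
        background_description="synthetic rows",
        ages=pd.Series(50, index=ids),
        predictions=pd.Series(0.0, index=ids),
        group_of=pd.Series("50-50", index=ids),
    )


class TestMannWhitney:
    def exact_p(self, x, y):
        """Two-sided p by enumerating all C(n1+n2, n1) labelings."""
        pooled = np.concatenate([x, y])
        n1 = len(x)
        ranks = rankdata(pooled)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        mu = n1 * len(y) / 2
        stat_obs = abs(u_obs - mu)
        count = total = 0
        for idx in combinations(range(len(pooled)), n1):
            u = rankdata(pooled)[list(idx)].sum() - n1 * (n1 + 1) / 2
            count += abs(u - mu) >= stat_obs - 1e-12
            total += 1
        return count / total

    def test_matches_enumeration_small_samples(self):
        rng = np.random.default_rng(0)
        for n1, n2 in [(3, 4), (5, 5), (6, 6), (4, 8)]:
            x = rng.normal(size=n1)
            y = rng.normal(0.8, 1, size=n2)
            u, z, r, p = mann_whitney_effect(x, y)
            assert p == pytest.approx(self.exact_p(x, y), abs=1e-12)
            # U and the effect-size deviate are consistent
            sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
            assert z == pytest.approx((u - n1 * n2 / 2) / sigma, abs=1e-12)
            assert r == pytest.approx(abs(z) / np.sqrt(n1 + n2), abs=1e-12)

    def test_fully_separated_ten_vs_ten(self):
        """All values in one sample above the other: U = 100, tie-free
        Z = 50/sqrt(175) = 3.78, r = 0.845."""
        x = np.arange(11.0, 21.0)
        y = np.arange(1.0, 11.0)
        u, z, r, p = mann_whitney_effect(x, y)
        assert u == 100.0
        assert z == pytest.approx(3.7796, abs=1e-4)
        assert r == pytest.approx(0.845, abs=1e-3)

    def test_constant_variable_degenerates(self):
        u, z, r, p = mann_whitney_effect(np.ones(8), np.ones(9))
        assert (z, r, p) == (0.0, 0.0, 1.0)


class TestBenjaminiHochberg:
    @staticmethod
    def reference_bh(p):
        """Independent step-up implementation."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            q[i] = running
        return q

    def test_matches_reference_on_random_vectors(self):
        rng = np.random.default_rng(1)
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(rng.integers(2, 40))
            np.testing.assert_allclose(
                multipletests(p, method="fdr_bh")[1], self.reference_bh(p), atol=1e-12
            )

    def test_q_never_below_p(self):
        rng = np.random.default_rng(2)
        phi = rng.normal(size=(120, 6))
        phi[:60, 0] += 1.0
        em = _em(phi)
        labels = pd.Series(np.repeat([1, 2], 60), index=em.phi.index)
        asg = pa.ClusterAssignment(labels=labels, k=2, linkage_record=np.empty((0, 4)))
        out = pa.signature_tests(em, asg)
        assert (out["q"] >= out["p"] - 1e-15).all()


class TestClustering:
    def test_planted_archetypes_recovered(self):
        rng = np.random.default_rng(3)
        n = 2000
        arch = rng.integers(0, 2, n)
        phi = rng.normal(0, 0.3, size=(n, 8))
        phi[:, 0] += np.where(arch == 1, 3.0, -3.0)
        asg = pa.cluster_explanations(_em(phi), k=2)
        assert adjusted_rand_score(arch, asg.labels.to_numpy()) >= 0.9

    def test_k_equals_n_isolates_everyone(self):
        phi = np.random.default_rng(4).normal(size=(12, 3))
        asg = pa.cluster_explanations(_em(phi), k=12)
        assert asg.labels.nunique() == 12

    def test_row_order_invariant_up_to_relabeling(self):
        rng = np.random.default_rng(5)
        phi = rng.normal(size=(150, 4))
        phi[:75] += 2.0
        em1 = _em(phi)
        perm = rng.permutation(150)
        em2 = _em(phi[perm], ids=pd.Index(perm, name="id"))
        a1 = pa.cluster_explanations(em1, k=3).labels.sort_index()
        a2 = pa.cluster_explanations(em2, k=3).labels.sort_index()
        assert adjusted_rand_score(a1.to_numpy(), a2.to_numpy()) == 1.0

    def test_ward_merge_heights_monotone(self):
        phi = np.random.default_rng(6).normal(size=(60, 5))
        Z = pa.cluster_explanations(_em(phi), k=3).linkage_record
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_k_beyond_n_rejected(self):
        with pytest.raises(CohortError):
            pa.cluster_explanations(_em(np.zeros((5, 2))), k=6)

    def test_silhouette_report_shape_and_range(self):
        rng = np.random.default_rng(12)
        phi = rng.normal(size=(120, 4))
        phi[:60] += 3.0
        report = pa.silhouette_report(_em(phi), k_values=range(2, 6))
        assert report["k"].tolist() == [2, 3, 4, 5]
        assert report["silhouette"].between(-1, 1).all()
        assert report["silhouette"].idxmax() == 0  # the planted split wins


class TestSignatures:
    def test_retained_flag_encodes_both_gates(self):
        """retained <=> (r >= 0.3 and q < alpha), including significant
        small effects that must fail the effect-size gate."""
        rng = np.random.default_rng(7)
        n = 800
        phi = rng.normal(size=(n, 5))
        phi[: n // 2, 0] += 2.0   # large effect
        phi[: n // 2, 1] += 0.18  # significant but small effect
        em = _em(phi)
        labels = pd.Series(np.repeat([1, 2], n // 2), index=em.phi.index)
        asg = pa.ClusterAssignment(labels=labels, k=2, linkage_record=np.empty((0, 4)))
        out = pa.signature_tests(em, asg, r_min=0.3, alpha=0.05)
        np.testing.assert_array_equal(
            out["retained"].to_numpy(), ((out["r"] >= 0.3) & (out["q"] < 0.05)).to_numpy()
        )
        small = out[out["variable"] == "v1"].iloc[0]
        assert small["q"] < 0.05 and small["r"] < 0.3 and not small["retained"]
        assert out[out["variable"] == "v0"].iloc[0]["retained"]

    def test_identical_distributions_not_retained(self):
        rng = np.random.default_rng(8)
        phi = rng.normal(size=(300, 4))
        em = _em(phi)
        labels = pd.Series(np.repeat([1, 2], 150), index=em.phi.index)
        asg = pa.ClusterAssignment(labels=labels, k=2, linkage_record=np.empty((0, 4)))
        out = pa.signature_tests(em, asg)
        assert not out["retained"].any()
        assert (out["r"] < 0.15).all()


class TestDecisionProfiles:
    def test_single_cluster_terminal_is_overall_mean(self, ctx_expl):
        labels = pd.Series(1, index=ctx_expl.phi.index)
        asg = pa.ClusterAssignment(labels=labels, k=1, linkage_record=np.empty((0, 4)))
        ranking = pa.rank_importance(ctx_expl)
        sig = pa.cluster_decision_profile(ctx_expl, asg, ranking)[0]
        # contextualized contributions are centered, so the average
        # individual of the whole cohort deviates by ~0 years
        assert abs(sig.decision_path["cumulative"].iloc[-1]) < 1e-3

    def test_terminal_value_permutation_invariant(self):
        rng = np.random.default_rng(9)
        phi = rng.normal(size=(100, 6))
        em = _em(phi)
        labels = pd.Series(np.repeat([1, 2], 50), index=em.phi.index)
        asg = pa.ClusterAssignment(labels=labels, k=2, linkage_record=np.empty((0, 4)))
        r1 = pa.rank_importance(em)
        shuffled = pa.ImportanceRanking(r1.table.sample(frac=1.0, random_state=1).reset_index(drop=True))
        s1 = pa.cluster_decision_profile(em, asg, r1)
        s2 = pa.cluster_decision_profile(em, asg, shuffled)
        for a, b in zip(s1, s2):
            assert a.decision_path["cumulative"].iloc[-1] == pytest.approx(
                b.decision_path["cumulative"].iloc[-1], abs=1e-12
            )

    def test_terminal_equals_cluster_mean_deviation(self):
        rng = np.random.default_rng(10)
        phi = rng.normal(size=(80, 4))
        em = _em(phi)
        labels = pd.Series(np.repeat([1, 2], 40), index=em.phi.index)
        asg = pa.ClusterAssignment(labels=labels, k=2, linkage_record=np.empty((0, 4)))
        for sig in pa.cluster_decision_profile(em, asg, pa.rank_importance(em)):
            members = labels[labels == sig.cluster].index
            expected = em.phi.loc[members].sum(axis=1).mean()
            assert sig.decision_path["cumulative"].iloc[-1] == pytest.approx(expected, abs=1e-6)

    def test_systematically_aged_cluster_is_all_positive(self):
        """A planted cluster whose members deviate positively on every key
        variable yields a signature of uniformly positive means."""
        rng = np.random.default_rng(11)
        phi = rng.normal(0, 0.2, size=(200, 5))
        phi[:100, :3] += 1.5
        em = _em(phi)
        labels = pd.Series(np.repeat([1, 2], 100), index=em.phi.index)
        asg = pa.ClusterAssignment(labels=labels, k=2, linkage_record=np.empty((0, 4)))
        tests = pa.signature_tests(em, asg)
        sig = pa.cluster_decision_profile(em, asg, pa.rank_importance(em), tests)[0]
        assert sig.retained_variables == ["v0", "v1", "v2"]
        assert all(sig.mean_phi[v] > 0 for v in sig.retained_variables)
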