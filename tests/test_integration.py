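"""Frailty stratification, correlation networks, pathway over-representation
and key-metabolite selection."""

import math

import numpy as np
import pandas as pd
import pytest

from centomics.cohort import CohortTable, PathwayMap, SampleMetadata
from centomics.integration import (
    CorrelationEdge,
    correlation_network,
    frailty_stratify,
    key_metabolite_select,
    pathway_ora,
)


class TestFrailtyStratify:
    def test_threshold_semantics(self):
        meta = [
            SampleMetadata("a", "CE", frailty_index=5),
            SampleMetadata("b", "CE", frailty_index=11),
            SampleMetadata("c", "CE", frailty_index=15),
            SampleMetadata("d", "CE", frailty_index=10),
            SampleMetadata("e", "YNG"),
        ]
        strata = frailty_stratify(meta, 11)
        assert strata == {"a": "HC", "b": "FC", "c": "FC", "d": "HC"}

    def test_no_centenarians_errors(self):
        with pytest.raises(ValueError, match="no centenarian"):
            frailty_stratify([SampleMetadata("x", "YNG")], 11)

    def test_default_bundle_split_sizes(self, bundle0):
        strata = frailty_stratify(bundle0.metadata, 11)
        counts = pd.Series(strata).value_counts()
        assert counts["HC"] == 81 and counts["FC"] == 64


def _tables_from(rng, n=60, n_met=5, n_gen=6):
    met = CohortTable(
        [f"m{j}" for j in range(n_met)], [f"s{i}" for i in range(n)],
        rng.lognormal(size=(n, n_met)), "metabolite",
    )
    gen = CohortTable(
        [f"g{j}" for j in range(n_gen)], [f"s{i}" for i in range(n)],
        rng.integers(1, 100, size=(n, n_gen)).astype(float), "gut_genus",
    )
    return met, gen


class TestCorrelationNetwork:
    def test_strong_pair_retained(self, rng):
        met, gen = _tables_from(rng)
        met.values[:, 0] = gen.values[:, 0] * 2 + rng.normal(0, 1e-6, 60)
        edges = correlation_network(met, gen, r_min=0.2, p_max=0.05)
        pairs = {(e.metabolite_id, e.genus_id) for e in edges}
        assert ("m0", "g0") in pairs
        top = [e for e in edges if (e.metabolite_id, e.genus_id) == ("m0", "g0")][0]
        # count ties keep the rank correlation just below 1
        assert top.rho == pytest.approx(1.0, abs=0.01)

    def test_impossible_threshold_empty(self, rng):
        met, gen = _tables_from(rng)
        assert correlation_network(met, gen, r_min=1.01, p_max=0.05) == []

    def test_symmetric_under_table_swap(self, rng):
        met, gen = _tables_from(rng)
        e1 = correlation_network(met, gen, r_min=0.1, p_max=0.2)
        e2 = correlation_network(
            CohortTable(gen.feature_ids, gen.sample_ids, gen.values, "metabolite"),
            CohortTable(met.feature_ids, met.sample_ids, met.values, "gut_genus"),
            r_min=0.1, p_max=0.2,
        )
        s1 = {(e.metabolite_id, e.genus_id, round(e.rho, 12)) for e in e1}
        s2 = {(e.genus_id, e.metabolite_id, round(e.rho, 12)) for e in e2}
        assert s1 == s2

    def test_matches_scalar_spearman(self, rng):
        import scipy.stats as sps

        met, gen = _tables_from(rng, n=30)
        edges = correlation_network(met, gen, r_min=0.0, p_max=1.0)
        for e in edges[:10]:
            i = met.feature_ids.index(e.metabolite_id)
            j = gen.feature_ids.index(e.genus_id)
            rho, p = sps.spearmanr(met.values[:, i], gen.values[:, j])
            assert e.rho == pytest.approx(rho, abs=1e-12)
            assert e.p == pytest.approx(p, abs=1e-9)

    def test_too_few_shared_samples(self, rng):
        met, gen = _tables_from(rng, n=4)
        with pytest.raises(ValueError, match="shared samples"):
            correlation_network(met, gen)

    def test_planted_key_pair_recovered(self, bundle0):
        truth = bundle0.truth
        met = bundle0.metabolites.subset_features([truth.key_metabolite])
        edges = correlation_network(met, bundle0.gut, r_min=0.2, p_max=0.05)
        pairs = {(e.metabolite_id, e.genus_id) for e in edges}
        assert (truth.key_metabolite, truth.key_genus) in pairs


def brute_force_ora_p(N, K, n, k):
    """P(overlap >= k) by direct summation of the hypergeometric pmf."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    ) / total


class TestPathwayOra:
    def test_closed_form_extreme_overlap(self):
        universe = {f"m{i}" for i in range(20)}
        selected = {f"m{i}" for i in range(5)}
        pm = PathwayMap(members={"p": set(selected)}, names={"p": "p"})
        row = pathway_ora(selected, universe, pm).iloc[0]
        assert row["p"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_zero_overlap_p_one(self):
        universe = {f"m{i}" for i in range(10)}
        pm = PathwayMap(members={"p": {"m0", "m1"}}, names={"p": "p"})
        row = pathway_ora({"m5", "m6"}, universe, pm).iloc[0]
        assert row["p"] == pytest.approx(1.0)

    def test_disjoint_pathway_dropped_with_warning(self):
        universe = {"m0", "m1"}
        pm = PathwayMap(members={"p": {"x"}}, names={"p": "p"})
        with pytest.warns(UserWarning, match="disjoint"):
            out = pathway_ora({"m0"}, universe, pm)
        assert out.empty

    def test_selected_outside_universe_rejected(self):
        pm = PathwayMap(members={"p": {"m0"}})
        with pytest.raises(ValueError, match="subset"):
            pathway_ora({"zz"}, {"m0"}, pm)

    @pytest.mark.parametrize("case", range(20))
    def test_matches_exhaustive_enumeration(self, case, rng):
        N = int(rng.integers(5, 31))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        universe = {f"m{i}" for i in range(N)}
        pathway = {f"m{i}" for i in rng.choice(N, size=K, replace=False)}
        selected = {f"m{i}" for i in rng.choice(N, size=n, replace=False)}
        pm = PathwayMap(members={"p": pathway}, names={"p": "p"})
        row = pathway_ora(selected, universe, pm).iloc[0]
        k = len(pathway & selected)
        assert row["overlap_k"] == k
        assert row["p"] == pytest.approx(brute_force_ora_p(N, K, n, k), rel=1e-9)


class TestKeyMetaboliteSelect:
    def _sig(self, rows):
        return pd.DataFrame(rows, columns=["feature_id", "label", "direction"])

    def test_all_three_clauses_required(self):
        sig = self._sig([
            ("mKey", "centenarian", "elevated"),
            ("mOral", "centenarian", "elevated"),
            ("mNoEdge", "centenarian", "elevated"),
            ("mNotCent", "family", "elevated"),
        ])
        hc = pd.DataFrame({
            "feature_id": ["mKey", "mOral", "mNoEdge", "mNotCent", "mDepleted"],
            "direction": ["elevated", "elevated", "elevated", "elevated", "depleted"],
        })
        edges = [
            CorrelationEdge("mKey", "gA", "gut_genus", 0.5, 1e-5, 1e-4),
            CorrelationEdge("mOral", "oB", "oral_genus", 0.6, 1e-6, 1e-5),
            CorrelationEdge("mNotCent", "gA", "gut_genus", 0.7, 1e-7, 1e-6),
            CorrelationEdge("mDepleted", "gA", "gut_genus", 0.7, 1e-7, 1e-6),
        ]
        out = key_metabolite_select(sig, hc, edges)
        assert out["feature_id"].tolist() == ["mKey"]

    def test_ranking_by_edge_count_then_rho(self):
        sig = self._sig([("m1", "centenarian", "elevated"),
                         ("m2", "centenarian", "elevated")])
        hc = pd.DataFrame({"feature_id": ["m1", "m2"],
                           "direction": ["elevated", "elevated"]})
        edges = [
            CorrelationEdge("m1", "g1", "gut_genus", 0.9, 1e-9, 1e-8),
            CorrelationEdge("m2", "g1", "gut_genus", 0.3, 1e-3, 1e-2),
            CorrelationEdge("m2", "g2", "gut_genus", 0.4, 1e-4, 1e-3),
        ]
        out = key_metabolite_select(sig, hc, edges)
        assert out["feature_id"].tolist() == ["m2", "m1"]  # edge count first

    def test_negative_rho_edges_excluded(self):
        sig = self._sig([("m1", "centenarian", "elevated")])
        hc = pd.DataFrame({"feature_id": ["m1"], "direction": ["elevated"]})
        edges = [CorrelationEdge("m1", "g1", "gut_genus", -0.8, 1e-9, 1e-8)]
        assert key_metabolite_select(sig, hc, edges).empty

    def test_missing_hc_markers_instructive_error(self):
        sig = self._sig([("m1", "centenarian", "elevated")])
        with pytest.raises(ValueError, match="frailty_stratify"):
            key_metabolite_select(sig, None, [])

    def test_stable_under_feature_reordering(self):
        sig = self._sig([("m2", "centenarian", "elevated"),
                         ("m1", "centenarian", "elevated")])
        hc = pd.DataFrame({"feature_id": ["m2", "m1"],
                           "direction": ["elevated", "elevated"]})
        edges = [
            CorrelationEdge("m1", "g1", "gut_genus", 0.5, 1e-5, 1e-4),
            CorrelationEdge("m2", "g2", "gut_genus", 0.5, 1e-5, 1e-4),
        ]
        out1 = key_metabolite_select(sig, hc, edges)
        out2 = key_metabolite_select(sig.iloc[::-1], hc.iloc[::-1], edges[::-1])
        pd.testing.assert_frame_equal(out1, out2)
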