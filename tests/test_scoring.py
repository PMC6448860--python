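"""Association score S, permutation Z, and candidate selection."""

import math
from itertools import permutations

import numpy as np
import pytest

from mgnet import (
    AssociationResult,
    PValueProfile,
    association_score,
    make_profiles,
    permutation_z,
    select_candidates,
)
from mgnet.errors import InputError, ScoreError


def exact_z_by_enumeration(drug_vals, disease_vals):
    """Independent oracle: enumerate every disease-value permutation."""
    terms = sorted(disease_vals)
    dvec = [disease_vals[t] for t in terms]
    shared = [i for i, t in enumerate(terms) if t in drug_vals]
    obs = -math.log10(sum(drug_vals[terms[i]] * dvec[i] for i in shared))
    scores = [
        -math.log10(sum(drug_vals[terms[i]] * perm[i] for i in shared))
        for perm in permutations(dvec)
    ]
    mean = sum(scores) / len(scores)
    var = sum((s - mean) ** 2 for s in scores) / len(scores)
    return (obs - mean) / math.sqrt(var) if var > 0 else None


class TestAssociationScore:
    def test_single_term_all_ones(self):
        s = association_score(
            PValueProfile("d", {"t": 1.0}), PValueProfile("x", {"t": 1.0})
        )
        assert s == 0.0

    def test_worked_two_term_example(self):
        s = association_score(
            PValueProfile("d", {"t1": 0.01, "t2": 0.5}),
            PValueProfile("x", {"t1": 0.02, "t2": 0.6}),
        )
        assert s == pytest.approx(-math.log10(0.3002), abs=1e-9)

    def test_k_ones_gives_negative_log_k(self):
        k = 5
        vals = {f"t{i}": 1.0 for i in range(k)}
        s = association_score(PValueProfile("d", vals), PValueProfile("x", dict(vals)))
        assert s == pytest.approx(-math.log10(k), abs=1e-12)

    def test_disjoint_profiles_raise(self):
        with pytest.raises(ScoreError):
            association_score(
                PValueProfile("d", {"a": 0.1}), PValueProfile("x", {"b": 0.1})
            )

    def test_profile_rejects_bad_p_and_floors_zero_like(self):
        with pytest.raises(InputError):
            PValueProfile("d", {"t": 1.5})
        prof = PValueProfile("d", {"t": 0.0})
        assert prof.values["t"] == 1e-300


class TestMakeProfiles:
    def test_adjacency_defines_drug_profiles(self, small_world):
        from mgnet import (
            GeneSetCollection,
            build_dgofn,
            enrich_terms,
            filter_drugs,
        )

        w = small_world
        lvl3 = GeneSetCollection(
            e for e in w.annotation if w.term_levels[e.set_id] == 3
        )
        sig = [
            r for r in enrich_terms(w.disease_genes, lvl3, w.universe) if r.significant
        ]
        net = build_dgofn(
            filter_drugs(w.drug_table, w.disease_genes), sig, lvl3, w.disease_genes
        )
        drug_profiles, disease = make_profiles(net, sig)
        assert set(drug_profiles) == set(net.drugs)
        for drug, prof in drug_profiles.items():
            assert prof.terms() == set(net.graph.neighbors(drug))
            for term in prof.terms():
                assert prof.values[term] == net.graph.edges[drug, term]["p"]
        assert disease.terms() == {r.term for r in sig}

    def test_empty_network_no_profiles(self):
        import networkx as nx

        from mgnet.dgofn import BipartiteNetwork

        net = BipartiteNetwork(
            graph=nx.Graph(), fdr=0.05, dropped_drugs=[], dropped_terms=[]
        )
        drug_profiles, _ = make_profiles(net, [])
        assert drug_profiles == {}


class TestPermutationZ:
    DRUG = {"A": 0.01, "B": 0.5, "C": 0.9}
    DISEASE = {"A": 0.02, "B": 0.6, "C": 0.8}

    def test_constant_disease_profile_z_undefined(self):
        res = permutation_z(
            PValueProfile("d", {"a": 0.1, "b": 0.9}),
            PValueProfile("x", {"a": 0.3, "b": 0.3}),
            mode="exact",
        )
        assert res.Z is None and res.perm_std == 0.0 and not res.z_defined

    def test_exact_matches_six_permutation_oracle(self):
        res = permutation_z(
            PValueProfile("d", self.DRUG), PValueProfile("x", self.DISEASE),
            mode="exact",
        )
        want = exact_z_by_enumeration(self.DRUG, self.DISEASE)
        assert res.n_perm == 6
        assert res.Z == pytest.approx(want, abs=1e-12)

    def test_monte_carlo_converges_to_exact(self):
        exact = permutation_z(
            PValueProfile("d", self.DRUG), PValueProfile("x", self.DISEASE),
            mode="exact",
        ).Z
        zs = [
            permutation_z(
                PValueProfile("d", self.DRUG), PValueProfile("x", self.DISEASE),
                n_perm=10_000, seed=s,
            ).Z
            for s in range(1, 21)
        ]
        se = np.std(zs, ddof=1) / np.sqrt(len(zs))
        assert abs(np.mean(zs) - exact) <= 3 * se

    def test_exact_invariant_under_term_relabeling(self):
        relabel = {"A": "Z9", "B": "Q2", "C": "M5"}
        base = permutation_z(
            PValueProfile("d", self.DRUG), PValueProfile("x", self.DISEASE),
            mode="exact",
        )
        renamed = permutation_z(
            PValueProfile("d", {relabel[t]: v for t, v in self.DRUG.items()}),
            PValueProfile("x", {relabel[t]: v for t, v in self.DISEASE.items()}),
            mode="exact",
        )
        assert renamed.Z == pytest.approx(base.Z, abs=1e-12)

    def test_seed_reproducibility(self):
        a = permutation_z(
            PValueProfile("d", self.DRUG), PValueProfile("x", self.DISEASE),
            n_perm=500, seed=99,
        )
        b = permutation_z(
            PValueProfile("d", self.DRUG), PValueProfile("x", self.DISEASE),
            n_perm=500, seed=99,
        )
        assert a.Z == b.Z and a.perm_mean == b.perm_mean

    def test_exact_mode_domain_cap(self):
        vals = {f"t{i}": 0.1 * (i + 1) / 10 for i in range(9)}
        with pytest.raises(InputError):
            permutation_z(
                PValueProfile("d", vals), PValueProfile("x", dict(vals)), mode="exact"
            )

    def test_shared_domain_mode(self):
        # disease has extra terms; shared-domain permutation only shuffles
        # the two shared values, so 2-element exact enumeration applies
        drug = PValueProfile("d", {"a": 0.01, "b": 0.5})
        disease = PValueProfile(
            "x", {"a": 0.02, "b": 0.6, "c": 0.9, "e": 0.8, "f": 0.7,
                  "g": 0.65, "h": 0.55, "i": 0.45, "j": 0.35}
        )
        res = permutation_z(drug, disease, mode="exact", perm_domain="shared")
        assert res.n_perm == 2 and res.Z is not None


class TestSelectCandidates:
    @staticmethod
    def _result(drug, z):
        return AssociationResult(
            drug=drug, S=1.0, perm_mean=0.0, perm_std=1.0, Z=z,
            n_perm=100, mode="monte-carlo", seed=0,
        )

    def test_none_above_threshold(self):
        assert select_candidates([self._result("D1", 1.0)]) == []

    def test_boundary_is_strict(self):
        assert select_candidates([self._result("D1", 1.96)]) == []
        assert len(select_candidates([self._result("D1", 1.9600001)])) == 1

    def test_sorted_by_z_then_id(self):
        results = [
            self._result("D2", 3.0), self._result("D1", 3.0),
            self._result("D3", 5.0), self._result("D4", None),
        ]
        assert [r.drug for r in select_candidates(results)] == ["D3", "D1", "D2"]
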