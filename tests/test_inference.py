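"""Resource diffusion on the substructure-drug-target network."""

import numpy as np
import pytest

from longinet.inference import (
    DEFAULT_SMARTS_DICTIONARY,
    InferenceParams,
    SubstructureDiffusion,
    build_tripartite,
    compute_substructure_profile,
    diffuse,
    initial_resource_vector,
    predict_dti_network,
    rank_candidate_targets,
    transfer_matrix,
)
from longinet.network import build_network


@pytest.fixture
def small_tripartite():
    net = build_network(
        [("d1", "T1"), ("d1", "T2"), ("d2", "T2"), ("d2", "T3")], "experimental"
    )
    return build_tripartite(net, {"d1": {"s1"}, "d2": {"s1", "s2"}})


class TestProfiles:
    def test_benzene_matches_aromatic_ring(self):
        profile = compute_substructure_profile("c1ccccc1")
        assert "aromatic_6_ring" in profile.keys

    def test_empty_dictionary_gives_empty_profile(self):
        assert compute_substructure_profile("CCO", {}).keys == frozenset()

    def test_deterministic(self):
        a = compute_substructure_profile("CC(=O)Oc1ccccc1C(=O)O")
        b = compute_substructure_profile("CC(=O)Oc1ccccc1C(=O)O")
        assert a.keys == b.keys

    def test_unparsable_rejected(self):
        with pytest.raises(ValueError):
            compute_substructure_profile("x((")

    def test_default_dictionary_patterns_all_valid(self):
        profile = compute_substructure_profile(
            "CC(=O)Oc1ccccc1C(=O)O", DEFAULT_SMARTS_DICTIONARY
        )
        assert {"ester", "carboxylic_acid", "aromatic_6_ring"} <= profile.keys


class TestTripartiteConstruction:
    def test_counts(self, small_tripartite):
        net = small_tripartite
        assert net.drugs == ["d1", "d2"]
        assert len(net.targets) == 3
        assert net.subs == ["s1", "s2"]
        assert net.n_dt_edges == 4
        assert net.n_ds_edges == 3

    def test_no_profiles_keeps_bipartite(self):
        dti = build_network([("d1", "T1")], "experimental")
        net = build_tripartite(dti, {})
        assert net.subs == []
        assert net.n_dt_edges == 1

    def test_nce_enters_with_only_substructure_edges(self):
        dti = build_network([("d1", "T1")], "experimental")
        net = build_tripartite(dti, {"d1": {"s1"}, "nce": {"s1"}}, nces=["nce"])
        assert "nce" in net.drugs
        assert net.drug_targets["nce"] == frozenset()
        assert net.drug_subs["nce"] == frozenset({"s1"})

    def test_unknown_profile_compound_rejected(self):
        dti = build_network([("d1", "T1")], "experimental")
        with pytest.raises(ValueError, match="NCE"):
            build_tripartite(dti, {"ghost": {"s1"}})


class TestInitialResource:
    def test_split_between_classes(self, small_tripartite):
        f0 = initial_resource_vector("d2", small_tripartite, alpha=0.1)
        net = small_tripartite
        assert f0[net.index("target", "T2")] == pytest.approx(0.45)
        assert f0[net.index("target", "T3")] == pytest.approx(0.45)
        assert f0[net.index("sub", "s1")] == pytest.approx(0.05)
        assert f0.sum() == pytest.approx(1.0)

    def test_nce_fallback_all_mass_to_substructures(self):
        dti = build_network([("d1", "T1")], "experimental")
        net = build_tripartite(
            dti, {"d1": {"s1"}, "nce": {"s1", "s2", "s3", "s4"}}, nces=["nce"]
        )
        f0 = initial_resource_vector("nce", net, alpha=0.1)
        for s in ("s1", "s2", "s3", "s4"):
            assert f0[net.index("sub", s)] == pytest.approx(0.25)

    def test_alpha_zero_boundary(self):
        dti = build_network([("d1", "T1")], "experimental")
        net = build_tripartite(dti, {"d1": {"s1", "s2", "s3"}})
        f0 = initial_resource_vector("d1", net, alpha=0.0)
        assert f0[net.index("target", "T1")] == pytest.approx(1.0)

    def test_isolated_drug_rejected(self):
        dti = build_network([("d1", "T1")], "experimental")
        dti.add_drug("lonely")
        net = build_tripartite(dti, {})
        with pytest.raises(ValueError, match="isolated"):
            initial_resource_vector("lonely", net)


class TestTransferMatrix:
    def test_columns_stochastic_at_gamma_zero(self, small_tripartite):
        W = transfer_matrix(small_tripartite, beta=0.3, gamma=0.0)
        sums = np.asarray(W.sum(axis=0)).ravel()
        assert np.allclose(sums, 1.0)

    def test_path_network_hand_matrix(self):
        # single drug linked to two targets, no substructures
        dti = build_network([("d", "t1"), ("d", "t2")], "experimental")
        net = build_tripartite(dti, {})
        W = transfer_matrix(net, beta=0.1, gamma=0.0).toarray()
        i_d = net.index("drug", "d")
        i_t1, i_t2 = net.index("target", "t1"), net.index("target", "t2")
        assert W[i_t1, i_d] == pytest.approx(0.5)
        assert W[i_t2, i_d] == pytest.approx(0.5)
        assert W[i_d, i_t1] == pytest.approx(1.0)
        assert W[i_d, i_t2] == pytest.approx(1.0)

    def test_degree_one_recipient_unscaled(self, small_tripartite):
        net = small_tripartite
        W0 = transfer_matrix(net, beta=0.1, gamma=0.0).toarray()
        Wg = transfer_matrix(net, beta=0.1, gamma=-0.7).toarray()
        # T1 and T3 have degree 1: their incoming entries are unchanged
        for t in ("T1", "T3"):
            i = net.index("target", t)
            assert np.allclose(Wg[i, :], W0[i, :])

    def test_hub_damping_direction(self, small_tripartite):
        net = small_tripartite
        W0 = transfer_matrix(net, beta=0.1, gamma=0.0).toarray()
        Wg = transfer_matrix(net, beta=0.1, gamma=-0.5).toarray()
        i_t2 = net.index("target", "T2")  # degree 2 hub
        j_d1 = net.index("drug", "d1")
        assert Wg[i_t2, j_d1] == pytest.approx(W0[i_t2, j_d1] * 2 ** -0.5)


class TestDiffusion:
    def test_k_zero_identity(self, small_tripartite):
        W = transfer_matrix(small_tripartite, 0.1, -0.5)
        f0 = initial_resource_vector("d1", small_tripartite)
        assert np.array_equal(diffuse(W, f0, 0), f0)

    def test_mass_conserved_at_gamma_zero(self, small_tripartite):
        W = transfer_matrix(small_tripartite, beta=0.1, gamma=0.0)
        f = initial_resource_vector("d1", small_tripartite)
        for k in (1, 2, 5, 10):
            assert abs(diffuse(W, f, k).sum() - 1.0) < 1e-10

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_matrix_power_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_drugs, n_targets, n_subs = 8, 12, 10
        edges = [
            (f"d{i}", f"t{j}")
            for i in range(n_drugs)
            for j in range(n_targets)
            if rng.random() < 0.3
        ]
        edges += [(f"d{i}", f"t{i % n_targets}") for i in range(n_drugs)]
        profiles = {
            f"d{i}": {f"s{j}" for j in range(n_subs) if rng.random() < 0.4}
            for i in range(n_drugs)
        }
        dti = build_network(edges, "experimental")
        net = build_tripartite(dti, profiles)
        W = transfer_matrix(net, beta=0.1, gamma=-0.5)
        f0 = initial_resource_vector("d0", net)
        dense = np.linalg.matrix_power(W.toarray(), 2) @ f0
        assert np.max(np.abs(diffuse(W, f0, 2) - dense)) < 1e-9

    def test_dimension_mismatch_rejected(self, small_tripartite):
        W = transfer_matrix(small_tripartite, 0.1, 0.0)
        with pytest.raises(ValueError, match="mismatch"):
            diffuse(W, np.ones(3), 1)


class TestRanking:
    def test_all_targets_known_gives_empty(self, small_tripartite):
        final = np.ones(small_tripartite.n_nodes)
        dti = build_network([("d", "t1")], "experimental")
        net = build_tripartite(dti, {})
        assert rank_candidate_targets("d", np.ones(net.n_nodes), net) == []

    def test_fewer_candidates_than_topn(self, small_tripartite):
        f0 = initial_resource_vector("d1", small_tripartite)
        W = transfer_matrix(small_tripartite, 0.1, -0.5)
        ranked = rank_candidate_targets(
            "d1", diffuse(W, f0, 2), small_tripartite, top_n=20
        )
        assert [t for t, _ in ranked] == ["T3"]

    def test_score_ties_break_lexicographically(self):
        dti = build_network(
            [("d1", "Tb"), ("d1", "Ta"), ("d2", "Tq")], "experimental"
        )
        net = build_tripartite(dti, {})
        final = np.zeros(net.n_nodes)
        final[net.index("target", "Ta")] = 0.5
        final[net.index("target", "Tb")] = 0.5
        ranked = rank_candidate_targets("d2", final, net, top_n=20)
        assert [t for t, _ in ranked[:2]] == ["Ta", "Tb"]

    def test_symmetric_targets_equal_scores(self):
        # t1 and t2 sit in isomorphic positions relative to d1
        dti = build_network(
            [("d1", "t0"), ("d2", "t0"), ("d2", "t1"), ("d2", "t2")],
            "experimental",
        )
        net = build_tripartite(dti, {})
        W = transfer_matrix(net, beta=0.1, gamma=-0.5)
        final = diffuse(W, initial_resource_vector("d1", net), 2)
        assert final[net.index("target", "t1")] == pytest.approx(
            final[net.index("target", "t2")]
        )


class TestBatchPrediction:
    def test_single_drug_matches_per_drug_path(self):
        dti = build_network([("d1", "t1"), ("d1", "t2"), ("d2", "t2")], "experimental")
        profiles = {"d1": {"s1"}, "d2": {"s1"}}
        batch = predict_dti_network(dti, profiles)
        net = build_tripartite(dti, profiles)
        W = transfer_matrix(net, 0.1, -0.5)
        solo = rank_candidate_targets(
            "d2", diffuse(W, initial_resource_vector("d2", net), 2), net
        )
        d2_rows = batch[batch["drug"] == "d2"]
        assert list(d2_rows["target"]) == [t for t, _ in solo]

    def test_pure_bipartite_predictions_without_profiles(self):
        dti = build_network(
            [("d1", "t1"), ("d2", "t1"), ("d2", "t2")], "experimental"
        )
        preds = predict_dti_network(dti, {})
        assert ("d1", "t2") in set(zip(preds["drug"], preds["target"]))

    def test_deterministic_and_nonnegative(self, planted_fixture):
        from longinet.simulate import GeneratorConfig, gen_compounds

        _, profiles, _ = gen_compounds(GeneratorConfig(seed=0, n_drugs=30))
        sub = {d: profiles[d] for d in list(profiles)[:30]}
        dti = build_network(
            [(d, t) for d in list(sub)[:10] for t in (f"T{hash(d) % 5}",)],
            "experimental",
        )
        model = SubstructureDiffusion(dti, {d: sub[d] for d in dti.drugs})
        a, b = model.predict(), model.predict()
        assert a.equals(b)
        assert (a["score"] >= 0).all()

    def test_odd_k_rejected(self):
        with pytest.raises(ValueError, match="even"):
            InferenceParams(k=3)

    def test_substructure_paths_lift_target_rank(self):
        # query shares a key with da (target tA) and nothing with db (tB);
        # tA must outrank tB for the default parameters
        dti = build_network(
            [("q", "t0"), ("da", "tA"), ("db", "tB")], "experimental"
        )
        profiles = {"q": {"s1"}, "da": {"s1"}, "db": {"s9"}}
        preds = predict_dti_network(dti, profiles)
        q_rows = preds[preds["drug"] == "q"].set_index("target")
        assert q_rows.loc["tA", "score"] > q_rows.loc["tB", "score"]
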