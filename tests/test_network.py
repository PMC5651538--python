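"""DTI filtering, network construction, statistics and comparisons."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longinet.network import (
    ActivityRecord,
    NoCarbonError,
    StandardizationError,
    annotate_aap_targets,
    build_network,
    cluster_compounds,
    compare_degree_distributions,
    dedup_compounds,
    extract_drug_subnetwork,
    filter_activity_records,
    merge_networks,
    network_stats,
    standardize_structure,
    tanimoto_distance,
)
from longinet.simulate import GeneratorConfig, gen_activity_records


def record(**overrides):
    base = dict(
        compound_id="c1",
        smiles="CCO",
        inchikey=None,
        uniprot="P00001",
        organism="Homo sapiens",
        activity_type="IC50",
        activity_value_um=1.0,
    )
    return ActivityRecord(**{**base, **overrides})


class TestStandardization:
    def test_salt_stripping(self):
        smiles, key = standardize_structure("CC(=O)[O-].[Na+]")
        assert "Na" not in smiles
        assert len(key) == 27

    def test_canonicalization_is_order_invariant(self):
        a, _ = standardize_structure("c1ccccc1O")
        b, _ = standardize_structure("Oc1ccccc1")
        assert a == b

    def test_no_carbon_rejected(self):
        with pytest.raises(NoCarbonError):
            standardize_structure("[Na+].[Cl-]")

    def test_unparsable_rejected(self):
        with pytest.raises(StandardizationError):
            standardize_structure("not_a_smiles((")

    def test_largest_carbon_fragment_kept(self):
        smiles, _ = standardize_structure("CCCCCCCC.[Cl-].C")
        assert smiles == "CCCCCCCC"


class TestFiltering:
    def test_boundary_value_inclusive(self):
        kept, log = filter_activity_records([record(activity_value_um=10.0)])
        assert len(kept) == 1 and log.empty

    @pytest.mark.parametrize(
        "override,criterion",
        [
            (dict(activity_value_um=15.0), "i"),
            (dict(activity_type="AC50"), "i"),
            (dict(organism="Rattus norvegicus"), "ii"),
            (dict(uniprot="  "), "iii"),
            (dict(smiles="not_a_smiles(("), "iv"),
            (dict(smiles="[Na+].[Cl-]"), "v"),
        ],
    )
    def test_first_failing_criterion_logged(self, override, criterion):
        kept, log = filter_activity_records([record(**override)])
        assert not kept
        assert log.loc[0, "failed_criterion"] == criterion

    def test_organism_match_normalizes_whitespace_and_case(self):
        kept, _ = filter_activity_records([record(organism="  homo   SAPIENS ")])
        assert len(kept) == 1

    def test_kept_records_standardized(self):
        kept, _ = filter_activity_records([record(smiles="OCC")])
        assert kept[0].smiles == "CCO"
        assert kept[0].inchikey and len(kept[0].inchikey) == 27

    def test_order_independent(self):
        records, _ = gen_activity_records(GeneratorConfig(seed=5))
        kept_fwd, _ = filter_activity_records(records)
        kept_rev, _ = filter_activity_records(records[::-1])
        assert {(r.compound_id, r.uniprot, r.activity_value_um) for r in kept_fwd} == {
            (r.compound_id, r.uniprot, r.activity_value_um) for r in kept_rev
        }

    def test_generator_labels_recovered_exactly(self):
        records, labels = gen_activity_records(GeneratorConfig(seed=7))
        kept, log = filter_activity_records(records)
        assert len(kept) == sum(labels)
        assert set(log["record_index"]) == {
            i for i, passed in enumerate(labels) if not passed
        }


class TestDedup:
    def test_same_inchikey_collapses_with_aliases(self):
        kept, _ = filter_activity_records(
            [record(compound_id="a", smiles="CCO"), record(compound_id="b", smiles="OCC")]
        )
        compounds = dedup_compounds(kept)
        assert len(compounds) == 1
        assert compounds[0].compound_id == "a"
        assert compounds[0].aliases == ["b"]

    def test_distinct_keys_stay_separate(self):
        kept, _ = filter_activity_records(
            [record(compound_id="a", smiles="CCO"), record(compound_id="b", smiles="CCCO")]
        )
        assert len(dedup_compounds(kept)) == 2

    def test_empty_input(self):
        assert dedup_compounds([]) == []


class TestNetworkConstruction:
    def test_merge_union_with_dual_provenance(self):
        exp = build_network(
            [("d1", "T1"), ("d1", "T2"), ("d2", "T1"), ("d2", "T3"), ("d3", "T1")],
            "experimental",
        )
        pred = build_network(
            [("d1", "T1"), ("d1", "T4"), ("d4", "T1")], "predicted"
        )
        merged = merge_networks(exp, pred)
        assert merged.n_edges == 7
        dual = [
            data for _, _, data in merged.edges() if len(data["provenance"]) == 2
        ]
        assert len(dual) == 1

    def test_merge_with_empty_is_identity(self):
        exp = build_network([("d1", "T1")], "experimental")
        empty = build_network([], "predicted")
        merged = merge_networks(exp, empty)
        assert merged.n_edges == exp.n_edges
        assert merged.drugs == exp.drugs

    def test_merge_commutes(self):
        a = build_network([("d1", "T1"), ("d2", "T2")], "experimental")
        b = build_network([("d1", "T1"), ("d3", "T3")], "predicted")
        ab, ba = merge_networks(a, b), merge_networks(b, a)
        edges_ab = {(d, t, frozenset(x["provenance"])) for d, t, x in ab.edges()}
        edges_ba = {(d, t, frozenset(x["provenance"])) for d, t, x in ba.edges()}
        assert edges_ab == edges_ba

    def test_duplicate_edge_stored_once(self):
        net = build_network([("d1", "T1"), ("d1", "T1")], "experimental")
        assert net.n_edges == 1

    def test_dangling_edge_rejected(self):
        net = build_network([("d1", "T1")], "experimental")
        with pytest.raises(ValueError, match="dangling"):
            net.add_edge("ghost", "T1", "experimental")


class TestNetworkStats:
    @pytest.mark.parametrize(
        "n_d,n_t,n_e,expected",
        [(2349, 732, 17223, 1.00), (224, 494, 2408, 2.17), (1, 1, 1, 100.0)],
    )
    def test_sparsity(self, n_d, n_t, n_e, expected):
        from longinet.network import NetworkStats

        stats = NetworkStats(
            n_d, n_t, 0, n_e, 100.0 * n_e / (n_d * n_t), n_e / n_d, {}, {}
        )
        assert stats.sparsity_pct_2dp == expected

    def test_stats_on_constructed_network(self, toy_network):
        stats = network_stats(toy_network)
        assert stats.n_drugs == 2 and stats.n_targets == 3 and stats.n_edges == 4
        assert stats.sparsity_pct == pytest.approx(100 * 4 / 6)
        assert sum(stats.drug_degrees.values()) == stats.n_edges
        assert sum(stats.target_degrees.values()) == stats.n_edges

    def test_degree_sums_match_edges_on_synthetic(self, planted_fixture):
        stats = network_stats(planted_fixture.net)
        assert sum(stats.drug_degrees.values()) == stats.n_edges
        assert sum(stats.target_degrees.values()) == stats.n_edges

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            network_stats(build_network([], "experimental"))


class TestAAPAnnotation:
    def test_flag_counts(self, toy_network):
        net, n_at = annotate_aap_targets(toy_network, {"GENE2"})
        assert n_at == 1
        assert net.is_aap_target("T2") and not net.is_aap_target("T1")

    def test_empty_aag_set(self, toy_network):
        _, n_at = annotate_aap_targets(toy_network, set())
        assert n_at == 0

    def test_all_targets_aap(self, toy_network):
        _, n_at = annotate_aap_targets(toy_network, {"GENE1", "GENE2", "GENE3"})
        assert n_at == 3

    def test_unmapped_target_warns(self):
        net = build_network([("d1", "T1")], "experimental")
        with pytest.warns(UserWarning):
            _, n_at = annotate_aap_targets(net, {"GENE1"})
        assert n_at == 0


class TestSubnetwork:
    def test_star_extraction(self):
        net = build_network(
            [("hub", f"T{i}") for i in range(6)] + [("other", "T0")],
            "experimental",
        )
        sub = extract_drug_subnetwork(net, ["hub"])
        assert sub.drugs == ["hub"]
        assert sub.n_edges == 6

    def test_shared_target_appears_once(self, toy_network):
        sub = extract_drug_subnetwork(toy_network, ["d1", "d2"])
        assert sub.targets == ["T1", "T2", "T3"]

    def test_unknown_drug_rejected(self, toy_network):
        with pytest.raises(KeyError, match="ghost"):
            extract_drug_subnetwork(toy_network, ["ghost"])


class TestRankSum:
    def test_exact_no_ties(self):
        # all 20 label assignments enumerable; observed rank-sum is maximal
        assert compare_degree_distributions([4, 5, 6], [1, 2, 3]) == pytest.approx(
            1 / 20
        )

    def test_symmetric_samples_at_least_half(self):
        p = compare_degree_distributions([1, 2, 3], [1, 2, 3])
        assert p >= 0.5

    def test_single_tied_pair_is_half(self):
        assert compare_degree_distributions([1], [1]) == pytest.approx(0.5)

    def test_less_is_complement_direction(self):
        p_greater = compare_degree_distributions([4, 5, 6], [1, 2, 3], "greater")
        p_less = compare_degree_distributions([1, 2, 3], [4, 5, 6], "less")
        assert p_less == pytest.approx(p_greater)

    def test_large_sample_shift_detected(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(6, size=200) + 1
        b = rng.poisson(2, size=200) + 1
        assert compare_degree_distributions(a, b, "greater") < 1e-10

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_degree_distributions([], [1])


class TestClustering:
    def test_identical_profiles_single_cluster(self):
        profiles = {f"c{i}": {"k1", "k2"} for i in range(5)}
        labels, medoids = cluster_compounds(profiles, k=1)
        assert set(labels.values()) == {0}
        assert medoids == ["c0"]

    def test_disjoint_groups_split_perfectly(self):
        profiles = {f"a{i}": {"k1", "k2"} for i in range(4)}
        profiles.update({f"b{i}": {"k3", "k4"} for i in range(4)})
        labels, _ = cluster_compounds(profiles, k=2)
        group_a = {labels[f"a{i}"] for i in range(4)}
        group_b = {labels[f"b{i}"] for i in range(4)}
        assert len(group_a) == 1 and len(group_b) == 1 and group_a != group_b

    def test_n_equals_k(self):
        profiles = {f"c{i}": {f"k{i}"} for i in range(4)}
        labels, medoids = cluster_compounds(profiles, k=4)
        assert sorted(labels.values()) == [0, 1, 2, 3]
        assert sorted(medoids) == sorted(profiles)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            cluster_compounds({"a": {"k"}}, k=2)

    @given(
        sets=st.lists(
            st.frozensets(st.integers(0, 10), max_size=6), min_size=2, max_size=8
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_tanimoto_identity_and_symmetry(self, sets):
        for x, y in itertools.combinations(sets, 2):
            assert tanimoto_distance(x, x) == 0.0
            assert tanimoto_distance(x, y) == pytest.approx(tanimoto_distance(y, x))
            assert 0.0 <= tanimoto_distance(x, y) <= 1.0
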