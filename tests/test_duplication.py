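"""Tandem clustering rules, override cases and the summary arithmetic."""

import numpy as np
import pytest

from bahdkit import OverrideRule, call_local, call_salicoid, classify, percent_of_family, summarize
from bahdkit.io_formats import GeneModel, SyntenyMap


def _gene(gene_id, start, end, status="family_full", region="LG_01"):
    return GeneModel(
        gene_id=gene_id,
        taxon="T",
        seq_region=region,
        start=start,
        end=end,
        status=status,
    )


def _clusters_as_sets(clusters):
    return sorted(sorted(c) for c in clusters.values())


class TestSalicoid:
    def test_only_pairs_fully_inside_family_flagged(self):
        synteny = SyntenyMap(ortholog_pairs=[("g1", "g7"), ("g2", "x9")])
        assert call_salicoid({"g1", "g2", "g7"}, synteny) == [("g1", "g7")]

    def test_pairs_are_unordered_and_unique(self):
        synteny = SyntenyMap(ortholog_pairs=[("b", "a"), ("a", "b")])
        assert synteny.ortholog_pairs == [("a", "b")]


class TestLocalClustering:
    def test_partial_and_transposon_models_do_not_break_arrays(self):
        models = [
            _gene("g1", 1000, 2000),
            _gene("p1", 2500, 2800, status="family_partial"),
            _gene("g2", 3000, 4000),
            _gene("t1", 4200, 4400, status="transposon"),
            _gene("g3", 5000, 6000),
        ]
        clusters = call_local({"g1", "g2", "g3"}, models)
        assert _clusters_as_sets(clusters) == [["g1", "g2", "g3"]]

    def test_any_other_model_breaks_the_array(self):
        models = [
            _gene("g1", 1000, 2000),
            _gene("x1", 2500, 2800, status="other"),
            _gene("g2", 3000, 4000),
        ]
        assert call_local({"g1", "g2"}, models) == {}

    def test_strand_is_ignored(self):
        models = [
            _gene("g1", 1000, 2000),
            GeneModel(
                gene_id="g2",
                taxon="T",
                seq_region="LG_01",
                start=3000,
                end=4000,
                strand="-",
            ),
        ]
        clusters = call_local({"g1", "g2"}, models)
        assert _clusters_as_sets(clusters) == [["g1", "g2"]]

    def test_translation_invariance_and_inserted_benign_models(self):
        rng = np.random.default_rng(31)
        base = [
            _gene("g1", 1000, 2000),
            _gene("g2", 3000, 4000),
            _gene("g3", 10**6, 10**6 + 1000),
        ]
        reference = _clusters_as_sets(call_local({"g1", "g2", "g3"}, base))
        for _ in range(20):
            shift = int(rng.integers(0, 10**6))
            shifted = [
                _gene(m.gene_id, m.start + shift, m.end + shift, m.status)
                for m in base
            ]
            extra_status = ["family_partial", "transposon"][int(rng.integers(0, 2))]
            shifted.append(
                _gene("extra", 2200 + shift, 2600 + shift, status=extra_status)
            )
            assert _clusters_as_sets(call_local({"g1", "g2", "g3"}, shifted)) == reference

    def test_clusters_are_maximal(self):
        models = [_gene(f"g{i}", 1000 * i, 1000 * i + 500) for i in range(1, 6)]
        clusters = call_local({m.gene_id for m in models}, models)
        assert len(clusters) == 1  # nothing mergeable remains


class TestOverrides:
    def test_two_gene_unit_merge(self):
        # two duplicated two-gene units: the rule alone sees an intervening
        # non-family model, the documented merge joins the array
        models = [
            _gene("u1a", 1000, 2000),
            _gene("u1b", 2500, 3500, status="other"),
            _gene("u2a", 4000, 5000),
            _gene("u2b", 5500, 6500, status="other"),
        ]
        family = {"u1a", "u2a"}
        assert call_local(family, models) == {}
        merged = call_local(
            family,
            models,
            [OverrideRule("force_merge", ("u1a", "u2a"), "two-gene duplication unit")],
        )
        assert _clusters_as_sets(merged) == [["u1a", "u2a"]]

    def test_tandem_array_split_into_two_blocks(self):
        # six consecutive members; an assembly-ambiguous intervening model
        # motivates splitting into a pair and a quadruplet
        models = [_gene(f"h{i}", 1000 * i, 1000 * i + 500) for i in range(1, 7)]
        family = {m.gene_id for m in models}
        assert len(call_local(family, models)) == 1
        split = call_local(
            family,
            models,
            [OverrideRule("force_split", ("h1", "h2"), "separate duplication blocks")],
        )
        assert _clusters_as_sets(split) == [["h1", "h2"], ["h3", "h4", "h5", "h6"]]

    def test_divergent_member_excluded_from_array(self):
        # a distant relative adjacent to a highly similar pair (across a
        # partial family model) is excluded by the documented override
        models = [
            _gene("a12", 1000, 2000),
            _gene("a13", 3000, 4000),
            _gene("part", 4200, 4500, status="family_partial"),
            _gene("a14", 5000, 6000),
        ]
        family = {"a12", "a13", "a14"}
        assert _clusters_as_sets(call_local(family, models)) == [["a12", "a13", "a14"]]
        excluded = call_local(
            family,
            models,
            [OverrideRule("exclude_from_cluster", ("a14",), "<40% similarity")],
        )
        assert _clusters_as_sets(excluded) == [["a12", "a13"]]

    def test_override_with_unknown_gene_errors(self):
        models = [_gene("g1", 1000, 2000)]
        with pytest.raises(KeyError, match="ghost"):
            call_local({"g1"}, models, [OverrideRule("force_merge", ("ghost",))])


class TestSummary:
    def test_percentages_round_like_published_values(self):
        assert percent_of_family(26, 100) == 26
        assert percent_of_family(36, 100) == 36
        assert percent_of_family(6, 18) == 33
        assert percent_of_family(21, 31) == 68
        assert percent_of_family(8, 9) == 89
        assert percent_of_family(0, 0) == 0

    def test_union_counting_of_recent_duplications(self):
        rng = np.random.default_rng(41)
        for _ in range(25):
            genes = [f"g{i}" for i in range(20)]
            pair_genes = list(rng.choice(genes, size=6, replace=False))
            pairs = [
                (pair_genes[0], pair_genes[1]),
                (pair_genes[2], pair_genes[3]),
                (pair_genes[4], pair_genes[5]),
            ]
            members = list(rng.choice(genes, size=5, replace=False))
            clusters = {"c1": set(members[:3]), "c2": set(members[3:])}
            calls = classify(genes, pairs, clusters)
            summary = summarize(
                calls, {g: "X" for g in genes}, {g: "none" for g in genes}, ["X"]
            )
            recent_oracle = len(set(pair_genes) | set(members))
            assert summary.loc["recent_duplication", "Genome"] == recent_oracle
            assert summary.loc["salicoid_duplication", "Genome"] == 6
            assert summary.loc["local_duplication", "Genome"] == 5

    def test_empty_family_gives_all_zero_summary(self):
        summary = summarize({}, {}, {}, ["Ia", "Ib"])
        assert (summary.to_numpy() == 0).all()


def test_fixture_truth_labels_recovered(fixture_genome, fixture_family):
    """End-to-end: planted duplication structure equals the classifier output."""
    family = fixture_family.accepted
    pairs = call_salicoid(family, fixture_genome.synteny)
    clusters = call_local(family, fixture_genome.models)
    calls = classify(family, pairs, clusters)
    truth = fixture_genome.truth.set_index("gene_id")
    for gene in family:
        row = truth.loc[gene]
        expected_partner = row["salicoid_partner"] or None
        assert calls[gene].salicoid_partner == expected_partner
        assert (calls[gene].local_cluster_id is not None) == bool(row["local_cluster"])
    # planted cluster co-membership is exactly recovered
    by_truth = {}
    for gene in family:
        label = truth.loc[gene, "local_cluster"]
        if label:
            by_truth.setdefault(label, set()).add(gene)
    assert sorted(map(sorted, by_truth.values())) == sorted(
        sorted(c) for c in clusters.values()
    )
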