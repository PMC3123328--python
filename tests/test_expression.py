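"""Presence filtering, probe selection, correlation statistics and dCt."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from bahdkit import (
    DuplicationCall,
    kruskal_dunn,
    pair_relation,
    presence_filter,
    qpcr_relative,
    spearman,
    spearman_matrix,
    transform_for_heatmap,
)
from bahdkit.expression import dedupe_probes, qpcr_table
from bahdkit.io_formats import ExpressionTable


def _table(values: dict, groups: dict, probe_genes: dict | None = None):
    df = pd.DataFrame(values).T
    probe_genes = probe_genes or {p: (f"gene_{p}",) for p in df.index}
    return ExpressionTable(values=df, sample_groups=groups, probe_genes=probe_genes)


GROUPS4 = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}


class TestPresenceFilter:
    def test_present_iff_some_group_mean_reaches_threshold(self):
        table = _table(
            {
                "hi": {"s1": 70, "s2": 50, "s3": 5, "s4": 15},  # A mean 60
                "lo": {"s1": 49.9, "s2": 49.9, "s3": 49.9, "s4": 49.9},
            },
            GROUPS4,
        )
        assert presence_filter(table, 50) == ["hi"]  # strict >= 50, 49.9 absent

    def test_raising_threshold_never_grows_present_set(self):
        rng = np.random.default_rng(7)
        values = {
            f"p{i}": {s: float(rng.uniform(0, 200)) for s in GROUPS4}
            for i in range(30)
        }
        table = _table(values, GROUPS4)
        previous = set(presence_filter(table, 0))
        for threshold in (10, 50, 100, 150, 500):
            current = set(presence_filter(table, threshold))
            assert current <= previous
            previous = current


class TestDedupeProbes:
    def test_keeps_highest_median_probe_per_gene(self):
        table = _table(
            {
                "pA": {"s1": 120, "s2": 120, "s3": 120, "s4": 120},
                "pB": {"s1": 80, "s2": 80, "s3": 80, "s4": 80},
                "pC": {"s1": 10, "s2": 10, "s3": 10, "s4": 10},
            },
            GROUPS4,
            probe_genes={"pA": ("g1",), "pB": ("g1",), "pC": ("g2",)},
        )
        reduced = dedupe_probes(table)
        assert sorted(reduced.values.index) == ["pA", "pC"]

    def test_multi_gene_probes_survive_flagged(self):
        table = _table(
            {"pm": {"s1": 5, "s2": 5, "s3": 5, "s4": 5}},
            GROUPS4,
            probe_genes={"pm": ("g1", "g2")},
        )
        reduced = dedupe_probes(table)
        assert reduced.multi_gene_probes == {"pm"}

    def test_matches_argmax_oracle_with_lexicographic_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            probes = {}
            probe_genes = {}
            for g in range(5):
                for p in range(int(rng.integers(1, 4))):
                    name = f"g{g}p{p}"
                    # integer intensities force occasional median ties
                    probes[name] = {
                        s: float(rng.integers(1, 6)) for s in GROUPS4
                    }
                    probe_genes[name] = (f"gene{g}",)
            table = _table(probes, GROUPS4, probe_genes=probe_genes)
            reduced = dedupe_probes(table)
            medians = table.values.median(axis=1)
            for gene in {g[0] for g in probe_genes.values()}:
                mine = [p for p in reduced.values.index if probe_genes[p][0] == gene]
                candidates = sorted(p for p in probes if probe_genes[p][0] == gene)
                best = max(medians[c] for c in candidates)
                oracle = min(c for c in candidates if medians[c] == best)
                assert mine == [oracle]


class TestTransforms:
    def test_abundance_is_log10(self):
        table = _table({"p": {"s1": 1000, "s2": 100, "s3": 10, "s4": 1}}, GROUPS4)
        values, flags = transform_for_heatmap(table, "abundance")
        assert values.loc["p", "s1"] == pytest.approx(3.0)
        assert flags.loc["p", "s3"] and flags.loc["p", "s4"]  # below 50

    def test_ratio_is_log2_with_quantitation_flag(self):
        table = _table(
            {
                "up": {"s1": 200, "s2": 200, "s3": 50, "s4": 50},
                "up_flagged": {"s1": 200, "s2": 200, "s3": 30, "s4": 30},
            },
            {"s1": "treat", "s2": "treat", "s3": "ctrl", "s4": "ctrl"},
        )
        ratios, flags = transform_for_heatmap(
            table, "ratio", contrasts=[("treat", "ctrl")]
        )
        assert ratios.loc["up", "treat_vs_ctrl"] == pytest.approx(2.0)
        assert not flags.loc["up", "treat_vs_ctrl"]
        # an up-regulation whose control side is below quantitation is flagged
        assert flags.loc["up_flagged", "treat_vs_ctrl"]


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [9, 6, 4, 1]) == pytest.approx(-1.0)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        base = spearman(x, y)
        assert spearman(np.exp(x), y) == pytest.approx(base)
        assert spearman(x, y**3) == pytest.approx(base)

    def test_tie_corrected_against_rank_pearson_oracle(self):
        rng = np.random.default_rng(5)
        from scipy.stats import rankdata

        for _ in range(50):
            x = rng.integers(0, 5, size=25).astype(float)  # heavy ties
            y = rng.integers(0, 5, size=25).astype(float)
            oracle = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
            assert spearman(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_matrix_agrees_with_pairwise_calls(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(6, 15)))
        matrix = spearman_matrix(df)
        for i, j in itertools.combinations(range(6), 2):
            assert matrix.iloc[i, j] == pytest.approx(
                spearman(df.iloc[i], df.iloc[j]), abs=1e-12
            )


class TestPairRelations:
    def _calls(self):
        calls = {}
        for g in ["c1", "c2", "c3"]:
            calls[g] = DuplicationCall(g, local_cluster_id="K", category="local")
        calls["c1"].salicoid_partner = "c6"
        calls["c1"].category = "both"
        calls["c6"] = DuplicationCall("c6", salicoid_partner="c1", category="salicoid")
        calls["z1"] = DuplicationCall("z1")
        calls["z2"] = DuplicationCall("z2")
        return calls

    def test_lone_survivor_vs_whole_array_is_salicoid(self):
        calls = self._calls()
        relations = [pair_relation("c6", g, calls) for g in ["c1", "c2", "c3"]]
        assert relations == ["salicoid"] * 3

    def test_cluster_members_local_and_unrelated_other(self):
        calls = self._calls()
        assert pair_relation("c1", "c2", calls) == "local"
        assert pair_relation("z1", "z2", calls) == "other"
        assert pair_relation("z1", "c2", calls) == "other"


class TestKruskalDunn:
    def test_identical_groups_h_zero_p_one(self):
        groups = {"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0], "c": [1.0, 1.0, 1.0]}
        result = kruskal_dunn(groups)
        assert result.statistic == 0.0
        assert result.pvalue == 1.0
        assert not result.dunn["significant"].any()

    def test_h_matches_brute_force_rank_computation(self):
        rng = np.random.default_rng(11)
        from scipy.stats import rankdata

        for _ in range(30):
            groups = {
                label: list(rng.integers(0, 8, size=int(rng.integers(3, 9))).astype(float))
                for label in "abc"
            }
            result = kruskal_dunn(groups)
            pooled = np.concatenate([groups[g] for g in sorted(groups)])
            ranks = rankdata(pooled)
            n = len(pooled)
            offset, h = 0, 0.0
            for g in sorted(groups):
                k = len(groups[g])
                h += ranks[offset : offset + k].sum() ** 2 / k
                offset += k
            h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
            _, tie_counts = np.unique(pooled, return_counts=True)
            correction = 1 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
            if correction == 0:
                continue
            assert result.statistic == pytest.approx(h / correction, abs=1e-9)

    def test_separated_groups_share_no_letter(self):
        rng = np.random.default_rng(12)
        groups = {
            "local": list(0.8 + 0.05 * rng.normal(size=20)),
            "salicoid": list(0.8 + 0.05 * rng.normal(size=20)),
            "other": list(0.0 + 0.05 * rng.normal(size=40)),
        }
        result = kruskal_dunn(groups)
        assert result.pvalue < 0.001
        assert result.letters["local"] == result.letters["salicoid"]
        assert set(result.letters["other"]) != set(result.letters["local"])

    def test_bonferroni_never_more_significant(self):
        rng = np.random.default_rng(13)
        groups = {label: list(rng.normal(size=10)) for label in "abcd"}
        plain = kruskal_dunn(groups, adjust="none")
        adjusted = kruskal_dunn(groups, adjust="bonferroni")
        assert (adjusted.dunn["p_adjusted"] >= plain.dunn["pvalue"] - 1e-12).all()


class TestQpcr:
    def test_closed_forms(self):
        assert qpcr_relative(21.0, [21.0, 21.0, 21.0]) == pytest.approx(1.0)
        assert qpcr_relative(20.0, [21.0, 21.0, 21.0]) == pytest.approx(2.0)
        assert qpcr_relative(20.0, [20.0, 21.0, 22.0]) == pytest.approx(2.0)

    def test_missing_housekeeping_gene_dropped(self):
        assert qpcr_relative(20.0, [21.0, 21.0, math.nan]) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            qpcr_relative(20.0, [math.nan, math.nan])

    def test_efficiency_parameter(self):
        # perfect doubling vs an arbitrary efficiency
        assert qpcr_relative(19.0, [21.0, 21.0], efficiency=1.5) == pytest.approx(
            1.5**2
        )

    def test_long_table_helper(self):
        ct = pd.DataFrame(
            {
                "sample": ["s1"] * 4,
                "gene": ["target", "hk1", "hk2", "hk3"],
                "ct": [20.0, 21.0, 21.0, 21.0],
            }
        )
        out = qpcr_table(ct, ["target"], ["hk1", "hk2", "hk3"])
        assert out.loc[0, "relative_expression"] == pytest.approx(2.0)
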