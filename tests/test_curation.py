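"""Membership filters against brute-force oracles and planted decoys."""

import re

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bahdkit import PipelineConfig, curate_family, global_identity, scan_hxxxd, score_dfgwg_like
from bahdkit.io_formats import GeneModel
from bahdkit.simulate import AA20

proteins_st = st.text(alphabet=AA20 + "X", min_size=0, max_size=80)


def _model(gene_id, anchored=True, region_length=None, start=1000):
    return GeneModel(
        gene_id=gene_id,
        taxon="T",
        seq_region="LG_01" if anchored else "scaffold_1",
        start=start,
        end=start + 999,
        status="family_full",
        anchored=anchored,
        region_length=region_length,
    )


class TestHxxxdScan:
    def test_known_positions(self):
        assert scan_hxxxd("AAHAAADAA") == [3]
        assert scan_hxxxd("HAAAD") == [1]
        assert scan_hxxxd("") == []
        assert scan_hxxxd("XAAAD") == []  # ambiguity codes never match

    @given(proteins_st)
    def test_agrees_with_regex_oracle(self, seq):
        oracle = [m.start() + 1 for m in re.finditer(r"(?=H...D)", seq)]
        assert scan_hxxxd(seq) == oracle

    def test_brute_force_on_random_kilomers(self):
        rng = np.random.default_rng(2)
        letters = np.array(list(AA20))
        for _ in range(50):
            seq = "".join(letters[rng.integers(0, 20, size=1000)])
            oracle = [
                i + 1
                for i in range(len(seq) - 4)
                if seq[i] == "H" and seq[i + 4] == "D"
            ]
            assert scan_hxxxd(seq) == oracle


class TestDfgwgScore:
    @pytest.mark.parametrize(
        "seq, score",
        [("AADFGWGAA", 5), ("AADFGLGAA", 4), ("AAAA", 0), ("QQQQQ", 0)],
    )
    def test_known_scores(self, seq, score):
        assert score_dfgwg_like(seq) == score

    @given(proteins_st)
    def test_agrees_with_window_enumeration(self, seq):
        windows = [seq[i : i + 5] for i in range(max(len(seq) - 4, 0))]
        oracle = max(
            (sum(a == b for a, b in zip(w, "DFGWG")) for w in windows), default=0
        )
        assert score_dfgwg_like(seq) == oracle


class TestGlobalIdentity:
    def test_identical_and_disjoint(self):
        assert global_identity("MKTL" * 20, "MKTL" * 20) == 1.0
        assert global_identity("AAAA", "WWWW") == 0.0

    def test_matches_dynamic_programming_oracle(self):
        # independent oracle: LCS length by textbook DP, over the longer length
        def lcs(a, b):
            prev = [0] * (len(b) + 1)
            for ch in a:
                cur = [0]
                for j, other in enumerate(b, 1):
                    cur.append(
                        prev[j - 1] + 1 if ch == other else max(prev[j], cur[j - 1])
                    )
                prev = cur
            return prev[-1]

        rng = np.random.default_rng(5)
        letters = np.array(list(AA20))
        for _ in range(20):
            a = "".join(letters[rng.integers(0, 20, size=int(rng.integers(20, 60)))])
            b = "".join(letters[rng.integers(0, 20, size=int(rng.integers(20, 60)))])
            assert global_identity(a, b) == pytest.approx(
                lcs(a, b) / max(len(a), len(b))
            )


class TestCurateFamily:
    def _inputs(self):
        good = "M" * 100 + "HAAAD" + "M" * 300 + "DFGWG" + "M" * 20
        models = [_model("good")]
        proteins = {"good": good}
        return models, proteins, good

    def test_short_protein_rejected_despite_both_motifs(self):
        models, proteins, _ = self._inputs()
        short = "M" * 100 + "HAAAD" + "M" * 100 + "DFGWG" + "M" * 40  # 250 aa
        models.append(_model("short", start=50000))
        proteins["short"] = short
        calls = curate_family(models, proteins, PipelineConfig())
        assert ("short", "too_short") in calls.rejected
        assert calls.accepted == ["good"]

    def test_exempt_gene_without_dfgwg_accepted_and_logged(self):
        models, proteins, _ = self._inputs()
        exempt_seq = "M" * 100 + "HAAAD" + "M" * 245  # 350 aa, no DFGWG-like window
        models.append(_model("clade2", start=50000))
        proteins["clade2"] = exempt_seq
        calls = curate_family(
            models, proteins, PipelineConfig(), clade2_exempt={"clade2"}
        )
        assert "clade2" in calls.accepted
        assert calls.exemptions_applied == ["clade2"]
        # without the exemption the same gene is rejected
        calls2 = curate_family(models, proteins, PipelineConfig())
        assert ("clade2", "dfgwg_below_min") in calls2.rejected

    def test_exempt_gene_absent_from_input_is_an_error(self):
        models, proteins, _ = self._inputs()
        with pytest.raises(KeyError):
            curate_family(models, proteins, clade2_exempt={"ghost"})

    def test_scaffold_copy_dropped_with_cited_match(self):
        models, proteins, good = self._inputs()
        models.append(_model("copy", anchored=False, region_length=15000))
        proteins["copy"] = good
        models.append(_model("unique", anchored=False, region_length=15000, start=3000))
        proteins["unique"] = "W" * 100 + "HAAAD" + "W" * 300 + "DFGWG" + "W" * 20
        calls = curate_family(models, proteins, PipelineConfig())
        assert ("copy", "scaffold_redundant") in calls.rejected
        assert calls.scaffold_matches["copy"][0] == "good"
        assert "unique" in calls.accepted  # no anchored match -> retained

    def test_long_scaffold_not_screened(self):
        models, proteins, good = self._inputs()
        models.append(_model("copy", anchored=False, region_length=50000))
        proteins["copy"] = good
        calls = curate_family(models, proteins, PipelineConfig())
        assert "copy" in calls.accepted

    def test_monotone_in_thresholds(self):
        models, proteins, _ = self._inputs()
        weak = "M" * 100 + "HAAAD" + "M" * 100 + "DFALG" + "M" * 50  # 260 aa, 3/5
        models.append(_model("weak", start=50000))
        proteins["weak"] = weak
        strict = curate_family(models, proteins, PipelineConfig())
        relaxed = curate_family(
            models,
            proteins,
            PipelineConfig(min_protein_length=200, dfgwg_min_match=2),
        )
        assert set(strict.accepted) <= set(relaxed.accepted)
        assert "weak" in relaxed.accepted

    def test_idempotent_on_accepted_set(self):
        models, proteins, _ = self._inputs()
        calls = curate_family(models, proteins, PipelineConfig())
        survivors = [m for m in models if m.gene_id in set(calls.accepted)]
        again = curate_family(
            survivors, {g: proteins[g] for g in calls.accepted}, PipelineConfig()
        )
        assert sorted(again.accepted) == sorted(calls.accepted)
        assert again.rejected == []


def test_each_decoy_class_rejected_for_its_own_reason(fixture_genome, fixture_family):
    truth_role = dict(
        zip(fixture_genome.truth["gene_id"], fixture_genome.truth["role"])
    )
    reasons = fixture_family.reason_of()
    expected_reason = {
        "no_hxxxd": "no_hxxxd",
        "low_dfgwg": "dfgwg_below_min",
        "too_short": "too_short",
        "scaffold_redundant": "scaffold_redundant",
    }
    for gene, reason in reasons.items():
        assert expected_reason[truth_role[gene]] == reason
    assert {truth_role[g] for g in reasons} == set(expected_reason)
    # and every planted family member is accepted
    family_truth = set(
        fixture_genome.truth.loc[
            fixture_genome.truth["role"] == "family", "gene_id"
        ]
    )
    assert set(fixture_family.accepted) == family_truth
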