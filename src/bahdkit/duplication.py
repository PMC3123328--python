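"""Duplication typing: whole-genome (salicoid) pairs and local tandem arrays.

Whole-genome duplicates are read from a synteny-derived ortholog-pair
table: a family gene is a salicoid duplicate iff it appears in a pair
whose other member is also in the family.  Local (tandem) duplicates are
family genes on one region separated by no intervening predicted gene
model — partial family models and transposon models do not count as
intervening, since such predictions are frequently spurious.  Manual
override rules (merge, split, exclude) capture the handful of cases
where assembly artefacts or two-gene duplication units defeat the
simple rule; overrides are applied after rule-based clustering and
logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import GeneModel, SyntenyMap

logger = logging.getLogger("bahdkit")

#: Statuses that do NOT break a tandem array when found between members.
NON_INTERVENING = frozenset({"family_partial", "transposon"})

CATEGORIES = ("salicoid", "local", "both", "none")

#: Row order of the duplication summary table.
SUMMARY_ROWS = (
    "total_genes",
    "recent_duplication",
    "recent_pct",
    "salicoid_duplication",
    "local_duplication",
    "retro_association",
    "retro_pct",
    "retro_both_sides",
    "retro_one_side",
)


@dataclass(frozen=True)
class OverrideRule:
    """A documented manual intervention in tandem-array clustering."""

    kind: str  # force_merge | force_split | exclude_from_cluster
    gene_ids: tuple[str, ...]
    justification: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("force_merge", "force_split", "exclude_from_cluster"):
            raise ValueError(f"unknown override kind {self.kind!r}")


@dataclass
class DuplicationCall:
    """Per-gene duplication status feeding the family summary."""

    gene_id: str
    salicoid_partner: str | None = None
    local_cluster_id: str | None = None
    category: str = "none"


def call_salicoid(
    family: Iterable[str], synteny: SyntenyMap
) -> list[tuple[str, str]]:
    """Ortholog pairs with both members inside the family."""
    fam = set(family)
    return [
        pair for pair in synteny.ortholog_pairs if pair[0] in fam and pair[1] in fam
    ]


def _intervening_models(
    left: GeneModel, right: GeneModel, region_models: Sequence[GeneModel]
) -> list[GeneModel]:
    """Models whose span lies strictly between the two genes' spans."""
    return [
        m
        for m in region_models
        if m.start > left.end and m.end < right.start
    ]


def call_local(
    family: Iterable[str],
    models: Sequence[GeneModel],
    overrides: Iterable[OverrideRule] = (),
) -> dict[str, set[str]]:
    """Cluster family genes into tandem arrays.

    Two neighbouring family genes on the same region are linked iff
    every annotated model strictly between their spans has a status in
    :data:`NON_INTERVENING`; clusters are the connected components of
    that relation.  Overrides are applied afterwards, in order; clusters
    that fall below two members are dissolved.
    """
    fam = set(family)
    known = {m.gene_id for m in models}
    for rule in overrides:
        unknown = set(rule.gene_ids) - known
        if unknown:
            raise KeyError(
                f"override {rule.kind} names unknown gene(s): {sorted(unknown)}"
            )

    by_region: dict[str, list[GeneModel]] = {}
    for m in sorted(models, key=GeneModel.sort_key):
        by_region.setdefault(m.seq_region, []).append(m)

    # union-find over family genes
    parent: dict[str, str] = {g: g for g in fam}

    def find(g: str) -> str:
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for region_models in by_region.values():
        fam_here = [m for m in region_models if m.gene_id in fam]
        for left, right in zip(fam_here, fam_here[1:]):
            between = _intervening_models(left, right, region_models)
            if all(m.status in NON_INTERVENING for m in between):
                union(left.gene_id, right.gene_id)

    clusters: dict[str, set[str]] = {}
    for g in fam:
        clusters.setdefault(find(g), set()).add(g)
    groups = [c for c in clusters.values() if len(c) > 1]

    for rule in overrides:
        targets = set(rule.gene_ids)
        if rule.kind == "exclude_from_cluster":
            groups = [c - targets for c in groups]
        elif rule.kind == "force_merge":
            merged = set(targets)
            rest = []
            for c in groups:
                if c & targets:
                    merged |= c
                else:
                    rest.append(c)
            groups = rest + [merged]
        elif rule.kind == "force_split":
            new_groups = []
            for c in groups:
                if c & targets:
                    new_groups.extend([c & targets, c - targets])
                else:
                    new_groups.append(c)
            groups = new_groups
        logger.info(
            "applied override %s on %s (%s)",
            rule.kind,
            ",".join(sorted(rule.gene_ids)),
            rule.justification or "no justification given",
        )
    groups = [c for c in groups if len(c) > 1]

    region_of = {m.gene_id: m.seq_region for m in models}
    out: dict[str, set[str]] = {}
    for c in sorted(groups, key=lambda c: sorted(c)):
        anchor = min(c)
        out[f"{region_of.get(anchor, 'NA')}:{anchor}"] = c
    return out


def classify(
    family: Iterable[str],
    salicoid_pairs: Iterable[tuple[str, str]],
    clusters: Mapping[str, set[str]],
) -> dict[str, DuplicationCall]:
    """Combine pair and cluster evidence into per-gene calls."""
    partner: dict[str, str] = {}
    for a, b in salicoid_pairs:
        partner.setdefault(a, b)
        partner.setdefault(b, a)
    cluster_of: dict[str, str] = {}
    for cid, members in clusters.items():
        for g in members:
            cluster_of[g] = cid
    calls = {}
    for gene in sorted(set(family)):
        has_sal = gene in partner
        has_loc = gene in cluster_of
        category = {
            (True, True): "both",
            (True, False): "salicoid",
            (False, True): "local",
            (False, False): "none",
        }[(has_sal, has_loc)]
        calls[gene] = DuplicationCall(
            gene_id=gene,
            salicoid_partner=partner.get(gene),
            local_cluster_id=cluster_of.get(gene),
            category=category,
        )
    return calls


def percent_of_family(count: int, total: int) -> int:
    """Integer percentage, rounded half away from zero (0 when empty)."""
    if total == 0:
        return 0
    return int(100.0 * count / total + 0.5)


def summarize(
    calls: Mapping[str, DuplicationCall],
    assignment: Mapping[str, str],
    flank_categories: Mapping[str, str],
    clade_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-clade and genome-wide duplication summary table.

    Rows: gene totals, recent duplications (salicoid or local, each gene
    counted once) with integer percentage, salicoid and local counts,
    retroelement-association counts (total with percentage, both-sides,
    one-side).  Columns: one per clade plus a Genome total.
    """
    clades = list(clade_order) if clade_order else sorted(set(assignment.values()))
    columns = {}
    for clade in clades + ["Genome"]:
        genes = [
            g for g in calls if clade == "Genome" or assignment.get(g) == clade
        ]
        n = len(genes)
        salicoid = sum(calls[g].category in ("salicoid", "both") for g in genes)
        local = sum(calls[g].category in ("local", "both") for g in genes)
        recent = sum(calls[g].category != "none" for g in genes)
        retro_both = sum(flank_categories.get(g) == "both" for g in genes)
        retro_one = sum(flank_categories.get(g) == "one" for g in genes)
        retro = retro_both + retro_one
        columns[clade] = {
            "total_genes": n,
            "recent_duplication": recent,
            "recent_pct": percent_of_family(recent, n),
            "salicoid_duplication": salicoid,
            "local_duplication": local,
            "retro_association": retro,
            "retro_pct": percent_of_family(retro, n),
            "retro_both_sides": retro_both,
            "retro_one_side": retro_one,
        }
    return pd.DataFrame(columns).reindex(list(SUMMARY_ROWS)).astype(int)


def calls_table(calls: Mapping[str, DuplicationCall]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "category": c.category,
            "salicoid_partner": c.salicoid_partner or "",
            "local_cluster_id": c.local_cluster_id or "",
        }
        for c in sorted(calls.values(), key=lambda c: c.gene_id)
    ]
    return pd.DataFrame(rows)


def load_overrides(path) -> list[OverrideRule]:
    """Read override rules from YAML (a list of kind/genes/justification)."""
    import yaml

    with open(path) as handle:
        raw = yaml.safe_load(handle) or []
    return [
        OverrideRule(
            kind=entry["kind"],
            gene_ids=tuple(entry["genes"]),
            justification=entry.get("justification", ""),
        )
        for entry in raw
    ]
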