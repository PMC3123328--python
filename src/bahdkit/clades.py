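"""Clade assignment and taxon-specific clade enumeration on labelled trees.

The phylogeny is an input (newick, rooted as written); clade labels are
propagated from user-supplied anchor tips by a most-recent-common-
ancestor rule, and lineage-specific family expansions are read off the
tree as maximal single-taxon clades above a size threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd


class CladeError(ValueError):
    """Raised when anchor sets are inconsistent with the tree."""


@dataclass
class LabelledTree:
    """A rooted tree whose tips carry (gene_id, taxon) labels.

    Tip labels double as gene ids; ``taxon_of`` maps each tip label to
    its taxon.  Internal node labels, when numeric, are read as bootstrap
    support for the clade they subtend.
    """

    tree: dendropy.Tree
    taxon_of: dict[str, str]

    @classmethod
    def from_newick(
        cls, source: str | Path, taxon_of: Mapping[str, str]
    ) -> "LabelledTree":
        text = str(source)
        if "(" not in text:  # a path, not newick data
            text = Path(source).read_text()
        try:
            tree = dendropy.Tree.get(data=text, schema="newick")
        except Exception as exc:
            raise CladeError(
                f"could not parse newick (tip labels must be unique): {exc}"
            ) from exc
        tree.is_rooted = True  # clades are read off the tree as written
        labels = [leaf.taxon.label.replace(" ", "_") for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise CladeError("tip labels are not unique")
        missing = [t for t in labels if t not in taxon_of]
        if missing:
            raise CladeError(f"tips without a taxon label: {missing[:5]}")
        return cls(tree=tree, taxon_of=dict(taxon_of))

    def tip_labels(self) -> list[str]:
        return [
            leaf.taxon.label.replace(" ", "_") for leaf in self.tree.leaf_node_iter()
        ]


def _leaf_sets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    """Leaf-label set below every node, computed in one postorder pass."""
    sets: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset({node.taxon.label.replace(" ", "_")})
        else:
            acc: set[str] = set()
            for child in node.child_nodes():
                acc |= sets[child]
            sets[node] = frozenset(acc)
    return sets


def assign_clades(
    ltree: LabelledTree, anchors: Mapping[str, Iterable[str]]
) -> dict[str, str]:
    """Assign every tip the label of its smallest anchor-containing clade.

    For each tip, each clade label is scored by the size of the smallest
    clade of the tree containing both the tip and all of that label's
    anchor tips (the MRCA of tip plus anchors); the tip inherits the
    label with the smallest such clade.  On a binary tree two candidate
    clades containing the same tip are nested, so ties are impossible;
    on polytomies equal-size ties break to the alphabetically first
    label.  Anchor sets that nest inconsistently — two labels resolving
    to the same anchor clade, or an anchor of one label falling strictly
    inside a smaller anchor clade of another — raise :class:`CladeError`.
    """
    sets = _leaf_sets(ltree.tree)
    all_leafsets = sorted(set(sets.values()), key=len)
    tips = set(ltree.tip_labels())

    anchor_sets: dict[str, set[str]] = {}
    anchor_clade: dict[str, frozenset[str]] = {}
    for clade, anchor_tips in anchors.items():
        anchor_set = set(anchor_tips)
        if not anchor_set:
            raise CladeError(f"clade {clade!r} has no anchors")
        missing = anchor_set - tips
        if missing:
            raise CladeError(f"clade {clade!r} anchors not in tree: {sorted(missing)}")
        anchor_sets[clade] = anchor_set
        anchor_clade[clade] = next(
            leaves for leaves in all_leafsets if anchor_set <= leaves
        )

    for c1, leaves1 in anchor_clade.items():
        for c2, leaves2 in anchor_clade.items():
            if c1 < c2 and leaves1 == leaves2:
                raise CladeError(f"clades {c1!r} and {c2!r} resolve to the same clade")
            if c1 == c2:
                continue
            if len(leaves2) < len(leaves1) and leaves2 < leaves1:
                stray = anchor_sets[c1] & leaves2
                if stray:
                    raise CladeError(
                        f"anchor(s) {sorted(stray)} of clade {c1!r} fall inside "
                        f"the smaller clade {c2!r}: inconsistent nesting"
                    )

    assignment: dict[str, str] = {}
    for tip in sorted(tips):
        candidates = []
        for clade, anchor_set in anchor_sets.items():
            needed = anchor_set | {tip}
            mrca = next(leaves for leaves in all_leafsets if needed <= leaves)
            candidates.append((len(mrca), clade))
        if candidates:
            assignment[tip] = min(candidates)[1]
    return assignment


def _node_support(node: dendropy.Node) -> float | None:
    label = node.label
    if label is None:
        return None
    try:
        return float(label)
    except ValueError:
        return None


def find_taxon_specific_clades(
    ltree: LabelledTree,
    min_size: int = 2,
    min_support: float | None = None,
) -> list[frozenset[str]]:
    """Enumerate maximal clades whose tips all belong to a single taxon.

    Returns the leaf-label sets of all clades with >= ``min_size`` tips
    sharing one taxon (and, if given, bootstrap support >=
    ``min_support`` on the clade's root node), keeping only clades not
    nested inside another qualifying clade.  The result is an antichain
    and is invariant under tip reordering.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    sets = _leaf_sets(ltree.tree)
    qualifying: dict[dendropy.Node, frozenset[str]] = {}
    for node, leaves in sets.items():
        if len(leaves) < min_size:
            continue
        taxa = {ltree.taxon_of[t] for t in leaves}
        if len(taxa) != 1:
            continue
        if min_support is not None:
            support = _node_support(node)
            if support is None or support < min_support:
                continue
        qualifying[node] = leaves
    maximal = []
    for node, leaves in qualifying.items():
        ancestor_qualifies = False
        parent = node.parent_node
        while parent is not None:
            if parent in qualifying:
                ancestor_qualifies = True
                break
            parent = parent.parent_node
        if not ancestor_qualifies:
            maximal.append(leaves)
    return sorted(maximal, key=lambda s: sorted(s))


def composition_summary(
    assignment: Mapping[str, str], taxon_of: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate clade membership against taxa.

    Returns (counts, per-clade taxon percentages, per-taxon clade
    percentages).  Percentage rows sum to 100 up to rounding; counts are
    conserved.
    """
    records = [
        {"gene": g, "clade": c, "taxon": taxon_of[g]} for g, c in assignment.items()
    ]
    df = pd.DataFrame(records)
    counts = pd.crosstab(df["clade"], df["taxon"])
    per_clade = counts.div(counts.sum(axis=1), axis=0) * 100.0
    per_taxon = (counts.T.div(counts.sum(axis=0), axis=0) * 100.0)
    return counts, per_clade, per_taxon
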