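"""Microarray mining and paralogue expression-divergence statistics.

Probes pass a presence filter (mean raw intensity >= 50 in at least one
experimental group), are deduplicated to one probe per gene (highest
median signal across samples), and log-transformed.  Expression
divergence between paralogues is quantified by Spearman's rank
correlation of log10 intensities across all arrays; correlations are
grouped by duplication relation (local, salicoid, other) and compared
with a Kruskal-Wallis rank test followed by Dunn's pairwise post-hoc
test.  A relative-quantification helper implements the dCt method with
a geometric-mean multi-gene reference for QPCR validation data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .duplication import DuplicationCall
from .io_formats import ExpressionTable, PipelineConfig


def presence_filter(table: ExpressionTable, threshold: float = 50.0) -> list[str]:
    """Probes whose mean raw intensity reaches the threshold in some group."""
    means = table.group_means()
    present = means.ge(threshold).any(axis=1)
    return sorted(means.index[present])


def dedupe_probes(table: ExpressionTable) -> ExpressionTable:
    """Reduce to one probe per gene, preferring the strongest signal.

    Single-gene probes compete per gene on median intensity across all
    samples (ties break to the lexicographically smallest probe id);
    multi-gene probes are retained as-is and stay flagged via
    ``multi_gene_probes``.
    """
    medians = table.values.median(axis=1)
    keep: set[str] = set(table.multi_gene_probes)
    by_gene: dict[str, list[str]] = {}
    for probe, genes in table.probe_genes.items():
        if len(genes) == 1 and probe in table.values.index:
            by_gene.setdefault(genes[0], []).append(probe)
    for gene, probes in by_gene.items():
        best = max(sorted(probes), key=lambda p: (medians[p], ))
        # max() keeps the first maximum of the sorted list -> smallest id on tie
        keep.add(best)
    kept = [p for p in table.values.index if p in keep]
    return ExpressionTable(
        values=table.values.loc[kept],
        sample_groups=dict(table.sample_groups),
        probe_genes={p: table.probe_genes[p] for p in kept},
    )


def transform_for_heatmap(
    table: ExpressionTable,
    mode: str = "abundance",
    contrasts: Sequence[tuple[str, str]] | None = None,
    quantitation_limit: float = 50.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log transforms for visualization, with below-quantitation flags.

    ``abundance`` mode returns log10 raw intensities (flagging cells
    below the quantitation limit).  ``ratio`` mode returns, for each
    (treatment, control) group contrast, log2 of the ratio of group-mean
    intensities; a ratio is flagged when the denominator side of an
    up-regulation (the control) or the numerator side of a
    down-regulation (the treatment) is below the quantitation limit.
    """
    if mode == "abundance":
        values = np.log10(table.values)
        flags = table.below_quantitation(quantitation_limit)
        return values, flags
    if mode != "ratio":
        raise ValueError(f"unknown mode {mode!r}")
    if not contrasts:
        raise ValueError("ratio mode needs (treatment, control) contrasts")
    means = table.group_means()
    ratio_cols, flag_cols = {}, {}
    for treatment, control in contrasts:
        name = f"{treatment}_vs_{control}"
        ratio = np.log2(means[treatment] / means[control])
        below_t = means[treatment] < quantitation_limit
        below_c = means[control] < quantitation_limit
        flag_cols[name] = np.where(ratio >= 0, below_c, below_t)
        ratio_cols[name] = ratio
    return pd.DataFrame(ratio_cols), pd.DataFrame(flag_cols, index=means.index)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rho: Pearson correlation of average (tie-corrected) ranks."""
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def spearman_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """All pairwise Spearman correlations between the rows of ``values``.

    Equivalent to calling :func:`spearman` on every row pair, computed
    as Pearson correlation of row-wise average ranks.
    """
    ranks = values.rank(axis=1)
    return pd.DataFrame(
        np.corrcoef(ranks.to_numpy()), index=values.index, columns=values.index
    )


def pair_relation(
    gene_a: str,
    gene_b: str,
    calls: Mapping[str, DuplicationCall],
) -> str:
    """Duplication relation of a gene pair: local, salicoid, or other.

    Local: the genes share a tandem cluster.  Salicoid: they are
    whole-genome-duplication partners, or one is the salicoid partner of
    some member of the other's cluster (so a lone salicoid survivor is
    compared against every member of its partner's tandem array).
    """
    ca, cb = calls[gene_a], calls[gene_b]
    if ca.local_cluster_id is not None and ca.local_cluster_id == cb.local_cluster_id:
        return "local"
    if ca.salicoid_partner == gene_b or cb.salicoid_partner == gene_a:
        return "salicoid"
    members_of: dict[str, list[str]] = {}
    for call in calls.values():
        if call.local_cluster_id is not None:
            members_of.setdefault(call.local_cluster_id, []).append(call.gene_id)
    if cb.local_cluster_id is not None:
        for member in members_of[cb.local_cluster_id]:
            if calls[member].salicoid_partner == gene_a:
                return "salicoid"
    if ca.local_cluster_id is not None:
        for member in members_of[ca.local_cluster_id]:
            if calls[member].salicoid_partner == gene_b:
                return "salicoid"
    return "other"


@dataclass
class CorrelationRecord:
    gene_a: str
    gene_b: str
    rho: float
    clade: str
    relation: str


def correlation_records(
    table: ExpressionTable,
    assignment: Mapping[str, str],
    calls: Mapping[str, DuplicationCall],
    log_transform: bool = True,
) -> list[CorrelationRecord]:
    """Within-clade pairwise Spearman correlations, tagged by relation.

    Correlations are computed on log10 intensities over all retained
    arrays; only single-gene probes participate (a probe matching
    several near-identical genes cannot separate their profiles).
    """
    gene_probe: dict[str, str] = {}
    for probe, genes in table.probe_genes.items():
        if len(genes) == 1 and probe in table.values.index:
            gene_probe[genes[0]] = probe
    values = np.log10(table.values) if log_transform else table.values
    by_clade: dict[str, list[str]] = {}
    for gene in sorted(gene_probe):
        if gene in assignment and gene in calls:
            by_clade.setdefault(assignment[gene], []).append(gene)
    records = []
    for clade in sorted(by_clade):
        genes = by_clade[clade]
        if len(genes) < 2:
            continue
        sub = values.loc[[gene_probe[g] for g in genes]]
        rho = spearman_matrix(sub)
        for i, j in itertools.combinations(range(len(genes)), 2):
            records.append(
                CorrelationRecord(
                    gene_a=genes[i],
                    gene_b=genes[j],
                    rho=float(rho.iloc[i, j]),
                    clade=clade,
                    relation=pair_relation(genes[i], genes[j], calls),
                )
            )
    return records


def records_table(records: Iterable[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": r.gene_a,
                "gene_b": r.gene_b,
                "rho": r.rho,
                "clade": r.clade,
                "relation": r.relation,
            }
            for r in records
        ]
    )


@dataclass
class KruskalDunnResult:
    """Kruskal-Wallis H with chi-square p, plus Dunn's pairwise results."""

    statistic: float
    pvalue: float
    group_sizes: dict[str, int]
    group_medians: dict[str, float]
    dunn: pd.DataFrame  # columns: group_a, group_b, z, pvalue, p_adjusted, significant
    letters: dict[str, str] = field(default_factory=dict)


def _dunn_pairwise(
    groups: Mapping[str, Sequence[float]], alpha: float, adjust: str
) -> pd.DataFrame:
    labels = sorted(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_rank, sizes = {}, {}
    offset = 0
    for g in labels:
        k = len(groups[g])
        mean_rank[g] = ranks[offset : offset + k].mean()
        sizes[g] = k
        offset += k
    # tie correction term for the rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    n_comparisons = len(labels) * (len(labels) - 1) // 2
    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = math.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p * n_comparisons) if adjust == "bonferroni" else p
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "z": z,
                "pvalue": p,
                "p_adjusted": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def _letter_groups(
    labels: Sequence[str], dunn: pd.DataFrame, medians: Mapping[str, float]
) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not distinct."""
    different = {
        frozenset((r.group_a, r.group_b)) for r in dunn.itertuples() if r.significant
    }
    ordered = sorted(labels, key=lambda g: -medians[g])
    letter_sets: list[set[str]] = []
    for g in ordered:
        placed = False
        for group in letter_sets:
            if all(frozenset((g, h)) not in different for h in group):
                group.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # drop letter sets fully contained in another
    letter_sets = [
        s
        for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {g: "" for g in labels}
    for letter, group in zip(alphabet, letter_sets):
        for g in group:
            out[g] += letter
    return out


def kruskal_dunn(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    adjust: str = "none",
) -> KruskalDunnResult:
    """Kruskal-Wallis one-way ANOVA on ranks with Dunn's post-hoc test.

    ``groups`` maps relation labels to correlation values.  The H
    statistic is tie-corrected with a chi-square p on k-1 df; Dunn's z
    statistics compare mean ranks with the pooled tie-corrected
    variance.  P-values are reported unadjusted by default
    (``adjust='bonferroni'`` multiplies by the number of comparisons).
    Identical data in all groups yields H = 0, p = 1.
    """
    labels = sorted(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    try:
        with np.errstate(invalid="ignore"):
            stat, p = stats.kruskal(*arrays)
    except ValueError:
        # all observations identical: no rank variation, nothing to test
        stat, p = 0.0, 1.0
    if math.isnan(stat):
        stat, p = 0.0, 1.0
    dunn = _dunn_pairwise(groups, alpha, adjust)
    medians = {g: float(np.median(groups[g])) for g in labels}
    letters = _letter_groups(labels, dunn, medians)
    return KruskalDunnResult(
        statistic=float(stat),
        pvalue=float(p),
        group_sizes={g: len(groups[g]) for g in labels},
        group_medians=medians,
        dunn=dunn,
        letters=letters,
    )


def qpcr_relative(
    ct_target: float,
    ct_housekeeping: Sequence[float],
    efficiency: float | Sequence[float] = 2.0,
) -> float:
    """Relative expression by the dCt method with a geometric-mean reference.

    The reference level is the geometric mean of ``efficiency**(-Ct)``
    over the housekeeping genes; relative expression is
    ``efficiency**(-ct_target)`` divided by that reference.  With a
    single shared efficiency E this reduces to
    ``E**(mean(Ct_housekeeping) - ct_target)``.  Housekeeping genes with
    missing Ct (NaN) are dropped from the reference.
    """
    cts = np.asarray(ct_housekeeping, dtype=float)
    if np.isscalar(efficiency) or isinstance(efficiency, (int, float)):
        effs = np.full(cts.shape, float(efficiency))
        target_eff = float(efficiency)
    else:
        effs = np.asarray(efficiency, dtype=float)[: len(cts)]
        target_eff = float(np.asarray(efficiency, dtype=float)[-1])
    keep = ~np.isnan(cts)
    if not keep.any():
        raise ValueError("no usable housekeeping Ct values")
    log_quantities = -cts[keep] * np.log(effs[keep])
    reference = math.exp(log_quantities.mean())
    return float(target_eff ** (-ct_target) / reference)


def qpcr_table(
    ct: pd.DataFrame,
    targets: Sequence[str],
    housekeeping: Sequence[str],
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Relative expression for each (sample, target) from a long Ct table."""
    rows = []
    for sample, sub in ct.groupby("sample"):
        ct_of = dict(zip(sub["gene"], sub["ct"]))
        hk = [ct_of.get(g, math.nan) for g in housekeeping]
        for target in targets:
            if target not in ct_of or math.isnan(ct_of[target]):
                continue
            rows.append(
                {
                    "sample": sample,
                    "gene": target,
                    "relative_expression": qpcr_relative(
                        ct_of[target], hk, efficiency
                    ),
                }
            )
    return pd.DataFrame(rows)
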