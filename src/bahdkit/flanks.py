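"""Retroelement association of family genes from flanking-window hits.

Each gene is flanked by two 10-kb windows on genome coordinates (the
lower-coordinate side is "up"); a labelled hit table records homology
hits found in those windows.  A flank is positive when it carries at
least ``flank_min_hits`` retrotransposon-class hits at or below the
E-value cutoff — a single hit is not taken as evidence.  Genes are then
categorized as flanked on both sides, one side, or neither.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .io_formats import GeneModel, PipelineConfig

FLANK_CATEGORIES = ("both", "one", "none")


def extract_flanks(
    gene: GeneModel,
    region_length: int | None = None,
    window: int = 10000,
) -> tuple[tuple[int, int] | None, tuple[int, int] | None]:
    """1-based inclusive upstream/downstream windows, clipped to the region.

    Upstream is ``[start - window, start - 1]`` and downstream
    ``[end + 1, end + window]``, clipped to ``[1, region_length]``; a
    flank that collapses (gene abutting the region edge) is None.
    """
    region_length = region_length if region_length is not None else gene.region_length
    up = (max(1, gene.start - window), gene.start - 1)
    down_end = gene.end + window
    if region_length is not None:
        down_end = min(region_length, down_end)
    down = (gene.end + 1, down_end)
    up_out = up if up[0] <= up[1] else None
    down_out = down if down[0] <= down[1] else None
    return up_out, down_out


def _flank_positive(side_hits: pd.DataFrame, config: PipelineConfig) -> bool:
    qualifying = side_hits[
        (side_hits["hit_class"] == "retrotransposon")
        & (side_hits["e_value"] <= config.flank_evalue_max)
    ]
    return len(qualifying) >= config.flank_min_hits


def classify_association(
    hits: pd.DataFrame,
    genes: Iterable[str],
    config: PipelineConfig | None = None,
) -> dict[str, str]:
    """Per-gene retroelement-association category.

    ``hits`` is a flank-hit table (see
    :func:`bahdkit.io_formats.read_flank_hits`); genes absent from it
    are ``none``.  Both flanks positive -> ``both``; exactly one ->
    ``one``; otherwise ``none``.
    """
    config = config or PipelineConfig()
    by_gene = dict(tuple(hits.groupby("gene_id"))) if len(hits) else {}
    out = {}
    for gene in sorted(set(genes)):
        sub = by_gene.get(gene)
        if sub is None:
            out[gene] = "none"
            continue
        positive = sum(
            _flank_positive(sub[sub["side"] == side], config)
            for side in ("up", "down")
        )
        out[gene] = {2: "both", 1: "one", 0: "none"}[positive]
    return out


def categories_table(categories: Mapping[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        sorted(categories.items()), columns=["gene_id", "retro_category"]
    )
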