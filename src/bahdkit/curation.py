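"""Family-membership curation by conserved protein motifs.

Membership in the acyltransferase family under study requires the
catalytic HXXXD motif (His, any three residues, Asp — absolutely
conserved) and a C-terminal DFGWG-like motif matching at least 3 of the
5 canonical residues (highly but not absolutely conserved).  Proteins
shorter than 300 aa are removed as likely pseudogenes, and candidates on
short unanchored scaffolds are dropped when they are near-identical
copies of an anchored family member (assembly redundancy).  An explicit
exemption list lifts the DFGWG requirement for loci whose reference
relatives genuinely lack the motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .io_formats import GeneModel, PipelineConfig

DFGWG = "DFGWG"

#: Rejection reasons, in the order filters are applied.
REASONS = ("no_hxxxd", "dfgwg_below_min", "too_short", "scaffold_redundant")


@dataclass
class FamilyCallSet:
    """Outcome of curation: accepted ids plus per-gene rejection reasons."""

    accepted: list[str] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)
    exemptions_applied: list[str] = field(default_factory=list)
    #: for scaffold_redundant rejections: gene -> (anchored match, identity)
    scaffold_matches: dict[str, tuple[str, float]] = field(default_factory=dict)

    def reason_of(self) -> dict[str, str]:
        return dict(self.rejected)

    def __post_init__(self) -> None:
        overlap = set(self.accepted) & {g for g, _ in self.rejected}
        if overlap:
            raise ValueError(f"genes both accepted and rejected: {sorted(overlap)}")


def scan_hxxxd(protein: str) -> list[int]:
    """Return all 1-based positions i with residue i == H and i+4 == D.

    Ambiguity codes (e.g. X) never satisfy the H or D positions; the
    three core residues are unconstrained.  An empty sequence yields an
    empty list.
    """
    positions = []
    for i in range(len(protein) - 4):
        if protein[i] == "H" and protein[i + 4] == "D":
            positions.append(i + 1)
    return positions


def score_dfgwg_like(protein: str) -> int:
    """Best positional match count (0..5) of any 5-mer window to DFGWG."""
    if len(protein) < 5:
        return 0
    best = 0
    for i in range(len(protein) - 4):
        matches = sum(protein[i + k] == DFGWG[k] for k in range(5))
        if matches > best:
            best = matches
            if best == 5:
                break
    return best


def _match_aligner() -> Align.PairwiseAligner:
    # Match-count scoring: the optimal global score equals the maximum
    # number of identically aligned residues (an LCS), independent of
    # which co-optimal alignment path the aligner happens to return.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = 0
    aligner.extend_gap_score = 0
    return aligner


def global_identity(a: str, b: str) -> float:
    """Global protein identity: max matched residues over the longer length.

    Defined via the maximum number of identical aligned residue pairs in
    a global alignment (no mismatch or gap penalty, i.e. the longest
    common subsequence), divided by the longer sequence length.  Two
    identical sequences score 1.0; unrelated proteins score well below
    the redundancy threshold.
    """
    if not a or not b:
        return 0.0
    matches = _match_aligner().score(a, b)
    return matches / max(len(a), len(b))


def remove_scaffold_redundancy(
    candidates: Sequence[str],
    models: Mapping[str, GeneModel],
    proteins: Mapping[str, str],
    config: PipelineConfig,
) -> tuple[list[str], dict[str, tuple[str, float]]]:
    """Drop short-scaffold candidates that duplicate an anchored family gene.

    A candidate on an unanchored region shorter than
    ``config.short_scaffold_max`` is removed iff its protein has global
    identity >= ``config.scaffold_identity_min`` to some anchored
    candidate; the best anchored match is recorded.
    """
    anchored = [g for g in candidates if models[g].anchored]
    kept: list[str] = []
    dropped: dict[str, tuple[str, float]] = {}
    for gene in candidates:
        model = models[gene]
        is_short_scaffold = (
            not model.anchored
            and model.region_length is not None
            and model.region_length < config.short_scaffold_max
        )
        if not is_short_scaffold:
            kept.append(gene)
            continue
        best_match, best_identity = None, 0.0
        for other in anchored:
            ident = global_identity(proteins[gene], proteins[other])
            if ident > best_identity:
                best_match, best_identity = other, ident
        if best_match is not None and best_identity >= config.scaffold_identity_min:
            dropped[gene] = (best_match, best_identity)
        else:
            kept.append(gene)
    return kept, dropped


def curate_family(
    models: Sequence[GeneModel],
    proteins: Mapping[str, str],
    config: PipelineConfig | None = None,
    clade2_exempt: Iterable[str] = (),
) -> FamilyCallSet:
    """Apply the membership filters to every candidate protein.

    A candidate is accepted iff it has an HXXXD motif, a DFGWG-like
    window matching >= ``dfgwg_min_match`` residues (unless exempt), is
    at least ``min_protein_length`` aa long, and is not a redundant
    short-scaffold copy of an anchored member.  Each rejected gene gets
    the first failing reason in that order.
    """
    config = config or PipelineConfig()
    exempt = set(clade2_exempt)
    model_of = {m.gene_id: m for m in models}
    candidates = [m.gene_id for m in models if m.gene_id in proteins]
    unknown_exempt = exempt - set(candidates)
    if unknown_exempt:
        raise KeyError(f"exempt genes absent from input: {sorted(unknown_exempt)}")

    result = FamilyCallSet()
    survivors: list[str] = []
    for gene in candidates:
        seq = proteins[gene]
        if not scan_hxxxd(seq):
            result.rejected.append((gene, "no_hxxxd"))
            continue
        dfgwg = score_dfgwg_like(seq)
        if dfgwg < config.dfgwg_min_match:
            if gene in exempt:
                result.exemptions_applied.append(gene)
            else:
                result.rejected.append((gene, "dfgwg_below_min"))
                continue
        if len(seq) < config.min_protein_length:
            result.rejected.append((gene, "too_short"))
            continue
        survivors.append(gene)

    kept, dropped = remove_scaffold_redundancy(survivors, model_of, proteins, config)
    for gene, match in dropped.items():
        result.rejected.append((gene, "scaffold_redundant"))
        result.scaffold_matches[gene] = match
    result.accepted = kept
    result.exemptions_applied = [g for g in result.exemptions_applied if g in kept]
    return result


def curation_table(result: FamilyCallSet, proteins: Mapping[str, str]):
    """Flatten a call set to a per-gene table for TSV output."""
    import pandas as pd

    reason = result.reason_of()
    rows = []
    for gene in sorted(set(result.accepted) | set(reason)):
        seq = proteins.get(gene, "")
        rows.append(
            {
                "gene_id": gene,
                "decision": "accepted" if gene in set(result.accepted) else "rejected",
                "reason": reason.get(gene, ""),
                "hxxxd_positions": ",".join(map(str, scan_hxxxd(seq))),
                "dfgwg_score": score_dfgwg_like(seq),
                "length": len(seq),
                "exemption": int(gene in set(result.exemptions_applied)),
            }
        )
    return pd.DataFrame(rows)
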