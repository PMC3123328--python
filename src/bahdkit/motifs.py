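"""Window-based conservation scoring on protein alignments.

Conservation is scanned in fixed-width windows (default 5 residues) of
a multiple sequence alignment.  Each column contributes a disorder
score of 1 minus its mean pairwise identity; window scores are column
means, standardized to z-scores over all windows so that strongly
conserved windows sit in the negative tail.  Candidate motif windows
(z at or below a threshold, chosen automatically unless overridden) are
merged, given a majority-rule consensus, and reported only when at
least one column carries more than 1.5 bits of information content —
the reporting floor that separates genuine conservation from alignment
noise.

The window score here is a tree-free mean pairwise identity; scoring
schemes that weight sequence pairs by phylogenetic distance exist, but
the reporting behaviour (which windows survive, and the bits floor) is
the contract of this module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .io_formats import PipelineConfig

logger = logging.getLogger("bahdkit")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP_CHARS = frozenset("-.")

MAX_IC_BITS = math.log2(20)

#: Recommended minimum alignment depth for stable window statistics.
MIN_RECOMMENDED_SEQUENCES = 25


def _as_rows(alignment) -> list[str]:
    """Accept a list of strings/SeqRecords or a MultipleSeqAlignment."""
    rows = []
    for item in alignment:
        seq = getattr(item, "seq", item)
        rows.append(str(seq).upper())
    if not rows:
        raise ValueError("empty alignment")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment is not rectangular")
    return rows


@dataclass
class AlignmentProfile:
    """Per-column composition and windowed conservation of an alignment."""

    n_sequences: int
    length: int
    counts: np.ndarray  # (length, 20) residue counts, gaps excluded
    gap_counts: np.ndarray  # (length,)
    column_ic: np.ndarray  # bits, (length,)
    window: int
    raw_scores: np.ndarray  # (n_windows,), NaN where the window is fully masked
    z_scores: np.ndarray  # (n_windows,), NaN where raw is NaN or degenerate
    masked_columns: np.ndarray  # bool (length,), >50% gaps or <2 residues
    degenerate: bool = False  # all window scores equal: z undefined


@dataclass
class MotifReport:
    """One reported motif region (0-based half-open alignment columns)."""

    start: int
    end: int
    consensus: str
    max_ic: float
    min_z: float
    context_start: int
    context_end: int
    context_consensus: str


def column_ic(composition: Iterable[float] | dict[str, float]) -> float:
    """Information content in bits of one alignment column.

    ``composition`` gives residue counts (a 20-vector in alphabetical
    amino-acid order, or a residue -> count mapping); gaps are excluded
    before computing frequencies.  IC = log2(20) minus the Shannon
    entropy of the residue frequencies; an all-gap (empty) column is 0
    by convention.
    """
    if isinstance(composition, dict):
        counts = np.zeros(20)
        for residue, count in composition.items():
            if residue in _AA_INDEX:
                counts[_AA_INDEX[residue]] = count
    else:
        counts = np.asarray(list(composition), dtype=float)
    total = counts.sum()
    if total <= 0:
        return 0.0
    freqs = counts[counts > 0] / total
    entropy = -(freqs * np.log2(freqs)).sum()
    return float(MAX_IC_BITS - entropy)


def _column_pairwise_identity(counts: np.ndarray, n_residues: int) -> float:
    """Probability two residues drawn from the column's composition match.

    The frequency-based form (sum of squared frequencies) rather than
    the finite-pair count, so the score is invariant under duplicating
    every sequence.
    """
    if n_residues < 2:
        return math.nan
    freqs = counts / n_residues
    return float((freqs**2).sum())


def profile_alignment(alignment, window: int = 5) -> AlignmentProfile:
    """Compute per-column and windowed conservation statistics.

    Columns with more than 50% gaps (or fewer than two residues) are
    masked out of window scores; a window whose columns are all masked
    scores NaN.  If every window has the same raw score (e.g. all
    sequences identical) z-scores are undefined and the profile is
    flagged degenerate.
    """
    rows = _as_rows(alignment)
    n, length = len(rows), len(rows[0])
    if window > length:
        raise ValueError(f"window ({window}) exceeds alignment length ({length})")
    if n < MIN_RECOMMENDED_SEQUENCES:
        logger.warning(
            "alignment has %d sequences; at least %d recommended for stable "
            "window statistics",
            n,
            MIN_RECOMMENDED_SEQUENCES,
        )

    counts = np.zeros((length, 20))
    gap_counts = np.zeros(length)
    for row in rows:
        for j, ch in enumerate(row):
            idx = _AA_INDEX.get(ch)
            if idx is None:
                gap_counts[j] += 1
            else:
                counts[j, idx] += 1

    ic = np.array([column_ic(counts[j]) for j in range(length)])
    n_res = counts.sum(axis=1)
    masked = (gap_counts > n / 2.0) | (n_res < 2)
    disorder = np.full(length, np.nan)
    for j in range(length):
        if not masked[j]:
            disorder[j] = 1.0 - _column_pairwise_identity(counts[j], int(n_res[j]))

    n_windows = length - window + 1
    raw = np.full(n_windows, np.nan)
    for w in range(n_windows):
        vals = disorder[w : w + window]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            raw[w] = vals.mean()

    valid = ~np.isnan(raw)
    z = np.full(n_windows, np.nan)
    degenerate = False
    if valid.sum() >= 2:
        mean, sd = raw[valid].mean(), raw[valid].std(ddof=0)
        if sd > 0:
            z[valid] = (raw[valid] - mean) / sd
        else:
            degenerate = True
    else:
        degenerate = True

    return AlignmentProfile(
        n_sequences=n,
        length=length,
        counts=counts,
        gap_counts=gap_counts,
        column_ic=ic,
        window=window,
        raw_scores=raw,
        z_scores=z,
        masked_columns=masked,
        degenerate=degenerate,
    )


def auto_threshold(
    n_windows: int, clamp: tuple[float, float] = (-2.5, -1.5)
) -> float:
    """Automatic z threshold for calling conserved windows.

    The default is the largest z at which the expected number of windows
    at or below it under a standard-normal null stays below one
    (a Bonferroni-style control: Phi^-1(1/n)), clamped to the plausible
    working range ``clamp``.
    """
    if n_windows < 1:
        raise ValueError("need at least one window")
    t = float(norm.ppf(1.0 / n_windows))
    lo, hi = clamp
    return min(max(t, lo), hi)


def motif_windows(
    profile: AlignmentProfile, threshold: float | None = None
) -> tuple[list[int], float | None]:
    """Window start indices with z at or below the threshold.

    Returns ``([], None)`` on degenerate profiles (no variance among
    windows, e.g. identical sequences).
    """
    if profile.degenerate:
        return [], None
    if threshold is None:
        n_valid = int((~np.isnan(profile.z_scores)).sum())
        threshold = auto_threshold(n_valid)
    hits = [
        w
        for w in range(len(profile.z_scores))
        if not math.isnan(profile.z_scores[w]) and profile.z_scores[w] <= threshold
    ]
    return hits, threshold


def _consensus(profile: AlignmentProfile, start: int, end: int) -> str:
    letters = []
    for j in range(start, end):
        col = profile.counts[j]
        if col.sum() == 0:
            letters.append("-")
        else:
            letters.append(AMINO_ACIDS[int(np.argmax(col))])
    return "".join(letters)


def report_motifs(
    profile: AlignmentProfile,
    config: PipelineConfig | None = None,
    threshold: float | None = None,
    mode: str = "multi",
) -> list[MotifReport]:
    """Merge qualifying windows into motifs and apply the reporting rules.

    Overlapping/adjacent windows below the z threshold become one motif
    region.  A motif is reported only if at least one of its columns has
    information content strictly above ``config.logo_report_bits``
    (default 1.5 bits).  The reported context is the region widened to
    25 columns in multi-clade mode or 10 in clade-specific mode,
    clipped at alignment ends.
    """
    config = config or PipelineConfig()
    if threshold is None:
        threshold = config.motif_z_threshold
    hits, threshold = motif_windows(profile, threshold)
    if not hits:
        return []
    context_width = 25 if mode == "multi" else 10

    regions: list[tuple[int, int]] = []
    for w in hits:
        start, end = w, w + profile.window
        if regions and start <= regions[-1][1]:
            regions[-1] = (regions[-1][0], max(regions[-1][1], end))
        else:
            regions.append((start, end))

    reports = []
    for start, end in regions:
        max_ic = float(profile.column_ic[start:end].max())
        if max_ic <= config.logo_report_bits:
            continue
        overlapping = [
            profile.z_scores[w]
            for w in hits
            if w < end and w + profile.window > start
        ]
        pad = max(context_width - (end - start), 0)
        ctx_start = max(0, start - pad // 2)
        ctx_end = min(profile.length, ctx_start + max(context_width, end - start))
        ctx_start = max(0, ctx_end - max(context_width, end - start))
        reports.append(
            MotifReport(
                start=start,
                end=end,
                consensus=_consensus(profile, start, end),
                max_ic=max_ic,
                min_z=float(min(overlapping)),
                context_start=ctx_start,
                context_end=ctx_end,
                context_consensus=_consensus(profile, ctx_start, ctx_end),
            )
        )
    return reports


def write_text_logo(profile: AlignmentProfile, path) -> None:
    """Write a per-column letter/bits stack as TSV (a text sequence logo)."""
    with open(path, "w") as handle:
        handle.write("column\tic_bits\tstack\n")
        for j in range(profile.length):
            col = profile.counts[j]
            total = col.sum()
            stack = ""
            if total > 0:
                freqs = col / total
                order = np.argsort(-freqs)
                parts = [
                    f"{AMINO_ACIDS[i]}:{freqs[i] * profile.column_ic[j]:.3f}"
                    for i in order
                    if freqs[i] > 0
                ]
                stack = ",".join(parts)
            handle.write(f"{j + 1}\t{profile.column_ic[j]:.4f}\t{stack}\n")
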