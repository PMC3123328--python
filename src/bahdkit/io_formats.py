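"""Readers, writers and configuration for the family-analysis pipeline.

The pipeline exchanges only plain-text formats: GFF3 for gene models,
FASTA for protein sequences, TSV for synteny/ortholog tables, expression
matrices, flank-hit tables and Ct tables, newick for trees and YAML for
configuration.  Coordinates are 1-based inclusive on disk (GFF3
convention) and on the :class:`GeneModel` container; any half-open
arithmetic is derived from the accessors here so the off-by-one risk
lives in a single module.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

logger = logging.getLogger("bahdkit")

#: Allowed gene-model status labels.  ``family_full`` and ``family_partial``
#: refer to full/partial members of the acyltransferase family under study;
#: ``transposon`` marks transposable-element models; everything else is
#: ``other``.  Partial family models and transposons do not count as
#: intervening genes when tandem arrays are delimited.
STATUS_LABELS = frozenset({"family_full", "family_partial", "transposon", "other"})

STRANDS = frozenset({"+", "-"})


class FormatError(ValueError):
    """Raised for malformed input files; message names file and line."""


@dataclass(frozen=True)
class GeneModel:
    """A located gene model, the unit of coordinate and duplication logic.

    ``start``/``end`` are 1-based inclusive base coordinates on
    ``seq_region`` (a linkage group or scaffold).  ``anchored`` is False
    for models on unanchored scaffolds, whose total length is carried in
    ``region_length`` so the short-scaffold redundancy rule can apply.
    """

    gene_id: str
    taxon: str
    seq_region: str
    start: int
    end: int
    strand: str = "+"
    status: str = "family_full"
    protein_length: int = 0
    anchored: bool = True
    region_length: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: end ({self.end}) < start ({self.start})"
            )
        if self.start < 1:
            raise FormatError(f"gene {self.gene_id}: start must be >= 1")
        if self.status not in STATUS_LABELS:
            raise FormatError(
                f"gene {self.gene_id}: unknown status label {self.status!r}"
            )
        if self.strand not in STRANDS:
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.protein_length < 0:
            raise FormatError(f"gene {self.gene_id}: negative protein_length")

    @property
    def interval0(self) -> tuple[int, int]:
        """The gene span as a 0-based half-open interval."""
        return self.start - 1, self.end

    def sort_key(self) -> tuple[str, int, int, str]:
        return (self.seq_region, self.start, self.end, self.gene_id)


def _attr_single(feature, key: str, lineno: int, path) -> str:
    values = feature.attributes.get(key, [])
    if len(values) != 1:
        raise FormatError(f"{path}:{lineno}: expected exactly one {key!r} attribute")
    return values[0]


def read_annotation(gff_path: str | Path) -> list[GeneModel]:
    """Read gene models from a GFF3 file.

    Each feature line must carry ``ID`` and ``status`` attributes; the
    optional ``taxon``, ``protein_length``, ``anchored`` and
    ``region_length`` attributes populate the corresponding fields.
    Models are returned sorted by (seq_region, start).
    """
    gff_path = Path(gff_path)
    models: list[GeneModel] = []
    seen: set[str] = set()
    with open(gff_path) as handle:
        for lineno, line in enumerate(handle, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if len(stripped.split("\t")) != 9:
                raise FormatError(
                    f"{gff_path}:{lineno}: malformed GFF3 line (expected 9 fields)"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises plain exceptions
                raise FormatError(
                    f"{gff_path}:{lineno}: malformed GFF3 line ({exc})"
                ) from exc
            gene_id = _attr_single(feat, "ID", lineno, gff_path)
            status = _attr_single(feat, "status", lineno, gff_path)
            if status not in STATUS_LABELS:
                raise FormatError(
                    f"{gff_path}:{lineno}: unknown status label {status!r}"
                )
            if gene_id in seen:
                raise FormatError(f"{gff_path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            attrs = feat.attributes
            taxon = attrs.get("taxon", ["unknown"])[0]
            protein_length = int(attrs.get("protein_length", ["0"])[0])
            anchored = attrs.get("anchored", ["1"])[0] not in ("0", "false", "False")
            region_length_raw = attrs.get("region_length", [None])[0]
            region_length = int(region_length_raw) if region_length_raw else None
            try:
                model = GeneModel(
                    gene_id=gene_id,
                    taxon=taxon,
                    seq_region=feat.seqid,
                    start=int(feat.start),
                    end=int(feat.end),
                    strand=feat.strand if feat.strand in STRANDS else "+",
                    status=status,
                    protein_length=protein_length,
                    anchored=anchored,
                    region_length=region_length,
                )
            except FormatError as exc:
                raise FormatError(f"{gff_path}:{lineno}: {exc}") from exc
            models.append(model)
    models.sort(key=GeneModel.sort_key)
    return models


def write_annotation(models: Iterable[GeneModel], gff_path: str | Path) -> None:
    """Write gene models as GFF3, one ``gene`` feature per model."""
    gff_path = Path(gff_path)
    with open(gff_path, "w") as handle:
        handle.write("##gff-version 3\n")
        for m in sorted(models, key=GeneModel.sort_key):
            attrs = [
                f"ID={m.gene_id}",
                f"taxon={m.taxon}",
                f"status={m.status}",
                f"protein_length={m.protein_length}",
                f"anchored={1 if m.anchored else 0}",
            ]
            if m.region_length is not None:
                attrs.append(f"region_length={m.region_length}")
            handle.write(
                f"{m.seq_region}\tbahdkit\tgene\t{m.start}\t{m.end}\t.\t"
                f"{m.strand}\t.\t{';'.join(attrs)}\n"
            )


def read_proteins(fasta_path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an id -> uppercase-sequence mapping."""
    proteins: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in proteins:
            raise FormatError(f"{fasta_path}: duplicate sequence id {record.id!r}")
        proteins[record.id] = str(record.seq).upper()
    return proteins


def write_fasta(sequences: Mapping[str, str], fasta_path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


# ---------------------------------------------------------------------------
# Synteny


@dataclass
class SyntenyMap:
    """Homeolog-pair information from a whole-genome-duplication survey.

    ``ortholog_pairs`` lists unordered gene-id pairs descending from the
    genome-wide duplication (the within-genome "ortholog" file of a
    synteny pipeline); ``segment_pairs`` optionally carries the duplicated
    segment intervals themselves.
    """

    ortholog_pairs: list[tuple[str, str]]
    segment_pairs: list[tuple[str, tuple[int, int], str, tuple[int, int]]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        canonical = []
        seen = set()
        for a, b in self.ortholog_pairs:
            if a == b:
                raise FormatError(f"self-pair {a!r} in ortholog table")
            pair = tuple(sorted((a, b)))
            if pair in seen:
                continue  # unordered pairs are unique
            seen.add(pair)
            canonical.append(pair)
        self.ortholog_pairs = canonical

    def partners(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for a, b in self.ortholog_pairs:
            out.setdefault(a, set()).add(b)
            out.setdefault(b, set()).add(a)
        return out

    def validate_against(self, models: Sequence[GeneModel]) -> None:
        known = {m.gene_id for m in models}
        for a, b in self.ortholog_pairs:
            for g in (a, b):
                if g not in known:
                    raise FormatError(
                        f"ortholog pair gene {g!r} absent from annotation"
                    )


def read_synteny(
    ort_path: str | Path, seg_path: str | Path | None = None
) -> SyntenyMap:
    """Read ortholog-pair (and optional segment-pair) TSV tables."""
    pairs: list[tuple[str, str]] = []
    with open(ort_path) as handle:
        for lineno, line in enumerate(handle, 1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{ort_path}:{lineno}: expected two columns")
            pairs.append((fields[0], fields[1]))
    segments = []
    if seg_path is not None:
        seg = pd.read_csv(seg_path, sep="\t")
        for row in seg.itertuples(index=False):
            segments.append(
                (
                    str(row.region_a),
                    (int(row.start_a), int(row.end_a)),
                    str(row.region_b),
                    (int(row.start_b), int(row.end_b)),
                )
            )
    return SyntenyMap(ortholog_pairs=pairs, segment_pairs=segments)


def write_synteny(synteny: SyntenyMap, ort_path: str | Path) -> None:
    with open(ort_path, "w") as handle:
        for a, b in sorted(synteny.ortholog_pairs):
            handle.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionTable:
    """Raw probe x sample intensities plus experiment metadata.

    ``values`` holds raw hybridization intensities (NaN where missing —
    missing cells are flagged, never silently zeroed), ``sample_groups``
    maps each sample to its experimental group, and ``probe_genes`` maps
    each probe to the gene id(s) its sequence matches (one-to-many is
    allowed and flagged, mirroring cross-hybridizing array probes).
    """

    values: pd.DataFrame
    sample_groups: dict[str, str]
    probe_genes: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        missing_groups = [s for s in self.values.columns if s not in self.sample_groups]
        if missing_groups:
            raise FormatError(f"samples without group labels: {missing_groups}")

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sample in self.values.columns:
            out.setdefault(self.sample_groups[sample], []).append(sample)
        return out

    @property
    def multi_gene_probes(self) -> set[str]:
        return {p for p, genes in self.probe_genes.items() if len(genes) > 1}

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def below_quantitation(self, limit: float) -> pd.DataFrame:
        """Per-cell flags for intensities below the quantitation limit."""
        return self.values < limit

    def group_means(self) -> pd.DataFrame:
        """Mean raw intensity per probe within each experimental group."""
        cols = {g: self.values[s].mean(axis=1) for g, s in self.groups.items()}
        return pd.DataFrame(cols)


def read_expression(
    tsv_path: str | Path,
    groups_path: str | Path,
    probes_path: str | Path,
) -> ExpressionTable:
    """Read an intensity matrix with its sample-group and probe-gene maps.

    The matrix header row holds sample ids; the first column holds probe
    ids.  Ragged rows and duplicate probe ids are errors.
    """
    tsv_path = Path(tsv_path)
    with open(tsv_path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        n_fields = len(header)
        probes_seen: set[str] = set()
        for lineno, line in enumerate(handle, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_fields:
                raise FormatError(
                    f"{tsv_path}:{lineno}: ragged row "
                    f"({len(fields)} fields, expected {n_fields})"
                )
            if fields[0] in probes_seen:
                raise FormatError(
                    f"{tsv_path}:{lineno}: duplicate probe id {fields[0]!r}"
                )
            probes_seen.add(fields[0])
    values = pd.read_csv(tsv_path, sep="\t", index_col=0)
    values = values.astype(float)

    groups_df = pd.read_csv(groups_path, sep="\t")
    sample_groups = dict(zip(groups_df.iloc[:, 0].astype(str), groups_df.iloc[:, 1].astype(str)))

    probes_df = pd.read_csv(probes_path, sep="\t")
    probe_genes: dict[str, tuple[str, ...]] = {}
    for probe, sub in probes_df.groupby(probes_df.columns[0], sort=True):
        probe_genes[str(probe)] = tuple(sorted(sub.iloc[:, 1].astype(str)))
    return ExpressionTable(values=values, sample_groups=sample_groups, probe_genes=probe_genes)


def write_expression(table: ExpressionTable, out_dir: str | Path, prefix: str = "expression") -> None:
    out_dir = Path(out_dir)
    table.values.to_csv(out_dir / f"{prefix}.tsv", sep="\t", float_format="%.6g")
    pd.DataFrame(
        sorted(table.sample_groups.items()), columns=["sample", "group"]
    ).to_csv(out_dir / f"{prefix}_groups.tsv", sep="\t", index=False)
    rows = [
        (probe, gene)
        for probe, genes in sorted(table.probe_genes.items())
        for gene in genes
    ]
    pd.DataFrame(rows, columns=["probe", "gene"]).to_csv(
        out_dir / f"{prefix}_probes.tsv", sep="\t", index=False
    )


def read_flank_hits(tsv_path: str | Path) -> pd.DataFrame:
    """Read a flanking-window hit table (gene, side, hit, E-value, class)."""
    df = pd.read_csv(tsv_path, sep="\t")
    required = {"gene_id", "side", "hit_id", "e_value", "hit_class"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{tsv_path}: missing columns {sorted(missing)}")
    if not df["side"].isin(["up", "down"]).all():
        raise FormatError(f"{tsv_path}: side must be 'up' or 'down'")
    if (df["e_value"] < 0).any():
        raise FormatError(f"{tsv_path}: negative E-value")
    if not df["hit_class"].isin(["retrotransposon", "other"]).all():
        raise FormatError(f"{tsv_path}: hit_class must be retrotransposon/other")
    return df


def read_ct_table(tsv_path: str | Path) -> pd.DataFrame:
    """Read a QPCR Ct table with columns sample, gene, ct."""
    df = pd.read_csv(tsv_path, sep="\t")
    required = {"sample", "gene", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{tsv_path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline, with their defaults.

    Defaults encode the published screening rules: a DFGWG-like window
    must match at least 3 of its 5 residues; proteins shorter than 300 aa
    are treated as likely pseudogenes; unanchored scaffolds shorter than
    20 kb are screened for redundant copies; retroelement association is
    read from 10-kb flanking windows requiring >=2 hits at E <= 1e-10 per
    flank; microarray probes need a mean raw intensity >= 50 in some
    experimental group to count as present; conservation is scanned in
    5-residue windows and motifs need a column above 1.5 bits to be
    reported.
    """

    dfgwg_min_match: int = 3
    min_protein_length: int = 300
    short_scaffold_max: int = 20000
    scaffold_identity_min: float = 0.95
    flank_window: int = 10000
    flank_evalue_max: float = 1e-10
    flank_min_hits: int = 2
    presence_intensity: float = 50.0
    motif_window: int = 5
    logo_report_bits: float = 1.5
    motif_z_threshold: float | None = None  # None -> automatic
    alpha: float = 0.05
    qpcr_efficiency: float = 2.0
    random_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls().with_overrides(**raw)

    def with_overrides(self, **overrides) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(self)}
        unknown = set(overrides) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        effective = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **effective)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def echo(self, log: logging.Logger | None = None) -> None:
        log = log or logger
        for key, value in sorted(self.as_dict().items()):
            log.info("config %s = %r", key, value)


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
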