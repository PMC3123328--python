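"""Synthetic genomes, alignments and expression data with known truth.

The generator emits every input the pipeline consumes — gene models,
protein FASTA, ortholog-pair tables, flank-hit tables, a labelled tree,
and expression matrices — from a declarative :class:`SimulationSpec`,
so that the curation filters, duplication classifiers and statistics
can be exercised against planted ground truth.  Generation is a pure
function of (spec, seed).

Family proteins carry a planted HXXXD motif and a C-terminal DFGWG;
decoy proteins are constructed so that each curation filter has a
guaranteed positive case: backgrounds excluding H (no HXXXD), excluding
D/F/G/W (DFGWG-like score at most 1 from the planted catalytic Asp),
truncated below 300 aa, or exact copies of an anchored member placed on
a short unanchored scaffold.

Rank correlation between duplicate pairs is planted through a Gaussian
copula: genes in a duplication group share a latent factor with loading
chosen so the implied Spearman correlation equals the requested value
(rho_s = (6/pi)*asin(r/2) for latent Pearson r, hence r = 2*sin(pi*
rho_s/6)); strictly positive intensities are obtained by mapping the
latent score through a log-normal.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import ExpressionTable, GeneModel, SyntenyMap

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_NO_H = AA20.replace("H", "")
AA_NO_DFGW = "".join(c for c in AA20 if c not in "DFGW")


class SpecError(ValueError):
    """Raised when a simulation spec is internally infeasible."""


@dataclass
class CladePlan:
    """Planted structure for one phylogenetic clade."""

    n_genes: int
    salicoid_pairs: int = 0
    #: salicoid pairs whose second member sits inside a local cluster
    #: (the lone-survivor-versus-tandem-array configuration)
    cross_pairs: int = 0
    local_clusters: list[int] = field(default_factory=list)
    retro_both: int = 0
    retro_one: int = 0
    #: members genuinely lack the DFGWG motif and enter the exemption list
    dfgwg_free: bool = False

    def validate(self, name: str) -> None:
        if self.n_genes < 0 or self.salicoid_pairs < 0 or self.cross_pairs < 0:
            raise SpecError(f"clade {name}: negative counts")
        if any(size < 2 for size in self.local_clusters):
            raise SpecError(f"clade {name}: local clusters need >= 2 genes")
        if self.cross_pairs > self.salicoid_pairs:
            raise SpecError(f"clade {name}: cross_pairs exceed salicoid_pairs")
        if self.cross_pairs > len(self.local_clusters):
            raise SpecError(f"clade {name}: more cross pairs than clusters")
        in_clusters = sum(self.local_clusters)
        singles_needed = 2 * self.salicoid_pairs - self.cross_pairs
        if in_clusters + singles_needed > self.n_genes:
            raise SpecError(
                f"clade {name}: {self.n_genes} genes cannot host "
                f"{in_clusters} cluster members plus {singles_needed} "
                "salicoid singletons"
            )
        if self.retro_both + self.retro_one > self.n_genes:
            raise SpecError(f"clade {name}: retro categories exceed gene count")


@dataclass
class DecoyPlan:
    """How many decoy candidates of each rejection class to generate."""

    no_hxxxd: int = 0
    low_dfgwg: int = 0
    too_short: int = 0
    scaffold_redundant: int = 0


@dataclass
class ExpressionPlan:
    """Shape and planted correlation structure of the expression matrix."""

    n_groups: int = 9
    n_replicates: int = 2
    rho_local: float = 0.8
    rho_salicoid: float = 0.8
    rho_other: float = 0.0
    baseline_log10: float = 2.7
    sigma_log10: float = 0.5

    def validate(self) -> None:
        for rho in (self.rho_local, self.rho_salicoid, self.rho_other):
            if not -1.0 <= rho <= 1.0:
                raise SpecError(f"planted rho {rho} outside [-1, 1]")
        if self.rho_other > min(self.rho_local, self.rho_salicoid):
            raise SpecError("rho_other must not exceed the duplicate-pair rho")
        if self.n_groups < 1 or self.n_replicates < 1:
            raise SpecError("need at least one group and one replicate")


@dataclass
class SimulationSpec:
    """Declarative description of a synthetic study."""

    clades: dict[str, CladePlan]
    decoys: DecoyPlan = field(default_factory=DecoyPlan)
    expression: ExpressionPlan = field(default_factory=ExpressionPlan)
    taxon: str = "Populus"
    protein_length: int = 460
    gene_length: int = 1500

    def validate(self) -> None:
        for name, plan in self.clades.items():
            plan.validate(name)
        self.expression.validate()
        if self.protein_length < 310:
            raise SpecError("protein_length must leave room for both motifs")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationSpec":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationSpec":
        clades = {
            name: CladePlan(**plan) for name, plan in raw.get("clades", {}).items()
        }
        spec = cls(
            clades=clades,
            decoys=DecoyPlan(**raw.get("decoys", {})),
            expression=ExpressionPlan(**raw.get("expression", {})),
            taxon=raw.get("taxon", "Populus"),
            protein_length=raw.get("protein_length", 460),
            gene_length=raw.get("gene_length", 1500),
        )
        spec.validate()
        return spec


def load_fixture_spec(name: str = "table1") -> SimulationSpec:
    """Load a spec shipped with the package (e.g. the seven-clade fixture)."""
    ref = importlib.resources.files("bahdkit") / "fixtures" / f"{name}.yaml"
    return SimulationSpec.from_dict(yaml.safe_load(ref.read_text()))


# ---------------------------------------------------------------------------
# Protein construction


def _random_protein(rng: np.random.Generator, length: int, alphabet: str) -> list[str]:
    letters = np.array(list(alphabet))
    return list(letters[rng.integers(0, len(letters), size=length)])


def _plant_hxxxd(seq: list[str], rng: np.random.Generator) -> None:
    pos = int(rng.integers(120, 180))
    seq[pos] = "H"
    seq[pos + 4] = "D"


def family_protein(
    rng: np.random.Generator, length: int, dfgwg: bool = True
) -> str:
    """A synthetic family member: HXXXD planted mid-sequence, DFGWG near C-term.

    With ``dfgwg=False`` the background excludes D/F/G/W entirely so the
    best DFGWG-like window is guaranteed to score at most 1 (from the
    planted catalytic Asp) — the construction for clade members that
    genuinely lack the motif.
    """
    alphabet = AA20 if dfgwg else AA_NO_DFGW
    seq = _random_protein(rng, length, alphabet)
    _plant_hxxxd(seq, rng)
    if dfgwg:
        pos = length - 30
        seq[pos : pos + 5] = list("DFGWG")
    return "".join(seq)


def decoy_protein(rng: np.random.Generator, length: int, decoy_class: str) -> str:
    if decoy_class == "no_hxxxd":
        seq = _random_protein(rng, length, AA_NO_H)
        seq[length - 30 : length - 25] = list("DFGWG")
        return "".join(seq)
    if decoy_class == "low_dfgwg":
        seq = _random_protein(rng, length, AA_NO_DFGW)
        _plant_hxxxd(seq, rng)
        return "".join(seq)
    if decoy_class == "too_short":
        seq = _random_protein(rng, 250, AA20)
        pos = int(rng.integers(50, 100))
        seq[pos] = "H"
        seq[pos + 4] = "D"
        seq[220:225] = list("DFGWG")
        return "".join(seq)
    raise ValueError(f"unknown decoy class {decoy_class!r}")


# ---------------------------------------------------------------------------
# Genome generation


@dataclass
class SyntheticGenome:
    """All generated inputs plus the planted ground truth."""

    models: list[GeneModel]
    proteins: dict[str, str]
    synteny: SyntenyMap
    flank_hits: pd.DataFrame
    truth: pd.DataFrame  # gene_id, clade, role, local_cluster, salicoid_partner, retro_category
    clade_of: dict[str, str]
    exempt: set[str]
    tree_newick: str
    anchors: dict[str, set[str]]
    taxon_of: dict[str, str]
    clade_order: list[str]

    @property
    def family_genes(self) -> list[str]:
        return sorted(self.truth[self.truth["role"] == "family"]["gene_id"])


def _retro_hits_for(
    gene: str,
    category: str,
    rng: np.random.Generator,
    rows: list[dict],
) -> None:
    def add(side: str, n: int, e_scale: float, hit_class: str) -> None:
        for k in range(n):
            rows.append(
                {
                    "gene_id": gene,
                    "side": side,
                    "hit_id": f"{gene}_{side}_h{k + 1}",
                    "e_value": float(10.0 ** -(e_scale + 10 * rng.random())),
                    "hit_class": hit_class,
                }
            )

    if category == "both":
        add("up", 2 + int(rng.integers(0, 2)), 15, "retrotransposon")
        add("down", 2 + int(rng.integers(0, 2)), 15, "retrotransposon")
    elif category == "one":
        positive = "up" if rng.random() < 0.5 else "down"
        negative = "down" if positive == "up" else "up"
        add(positive, 2 + int(rng.integers(0, 2)), 15, "retrotransposon")
        # the negative flank exercises the filters: a lone hit, or hits
        # failing the E-value cutoff, or non-retro hits
        style = int(rng.integers(0, 3))
        if style == 0:
            add(negative, 1, 15, "retrotransposon")
        elif style == 1:
            rows.append(
                {
                    "gene_id": gene,
                    "side": negative,
                    "hit_id": f"{gene}_{negative}_weak",
                    "e_value": 1e-5,
                    "hit_class": "retrotransposon",
                }
            )
            rows.append(
                {
                    "gene_id": gene,
                    "side": negative,
                    "hit_id": f"{gene}_{negative}_weak2",
                    "e_value": 1e-4,
                    "hit_class": "retrotransposon",
                }
            )
        else:
            add(negative, 2, 20, "other")
    elif category == "none":
        style = int(rng.integers(0, 3))
        if style == 0:
            add("up", 1, 15, "retrotransposon")
        elif style == 1:
            add("down", 2, 20, "other")
        # style 2: no hits at all


def generate_genome(spec: SimulationSpec, seed: int = 0) -> SyntheticGenome:
    """Generate a genome with planted family structure and decoys."""
    spec.validate()
    rng = np.random.default_rng(seed)
    models: list[GeneModel] = []
    proteins: dict[str, str] = {}
    ortholog_pairs: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    hit_rows: list[dict] = []
    exempt: set[str] = set()
    clade_order = list(spec.clades)
    gene_len = spec.gene_length

    aux_counter = [0]

    def aux_model(region: str, start: int, end: int, status: str, region_length=None):
        aux_counter[0] += 1
        models.append(
            GeneModel(
                gene_id=f"aux_{aux_counter[0]:04d}",
                taxon=spec.taxon,
                seq_region=region,
                start=start,
                end=end,
                status=status,
                protein_length=0,
                anchored=True,
                region_length=region_length,
            )
        )

    region_lengths: dict[str, int] = {}

    for clade_idx, clade in enumerate(clade_order, 1):
        plan = spec.clades[clade]
        region = f"LG_{clade_idx:02d}"
        gene_ids = [f"{clade}_g{i:02d}" for i in range(1, plan.n_genes + 1)]

        # role assignment: cluster members first, then salicoid singletons
        clusters: list[list[str]] = []
        cursor_idx = 0
        for size in plan.local_clusters:
            clusters.append(gene_ids[cursor_idx : cursor_idx + size])
            cursor_idx += size
        salicoid_partner: dict[str, str] = {}
        for p in range(plan.salicoid_pairs):
            if p < plan.cross_pairs:
                lone = gene_ids[cursor_idx]
                cursor_idx += 1
                partner = clusters[p][0]  # the array member carrying both labels
            else:
                lone, partner = gene_ids[cursor_idx], gene_ids[cursor_idx + 1]
                cursor_idx += 2
            salicoid_partner[lone] = partner
            salicoid_partner[partner] = lone
            ortholog_pairs.append((lone, partner))

        cluster_of: dict[str, int] = {}
        for c_idx, members in enumerate(clusters):
            for g in members:
                cluster_of[g] = c_idx

        retro_order = list(gene_ids)
        rng.shuffle(retro_order)
        retro_category = {g: "none" for g in gene_ids}
        for g in retro_order[: plan.retro_both]:
            retro_category[g] = "both"
        for g in retro_order[plan.retro_both : plan.retro_both + plan.retro_one]:
            retro_category[g] = "one"

        # layout: shuffle singleton genes and cluster blocks along the region
        units: list[tuple[str, object]] = [("cluster", c) for c in range(len(clusters))]
        units += [("single", g) for g in gene_ids if g not in cluster_of]
        rng.shuffle(units)
        cursor = 15000
        for unit_kind, payload in units:
            if unit_kind == "single":
                gene = str(payload)
                models.append(
                    GeneModel(
                        gene_id=gene,
                        taxon=spec.taxon,
                        seq_region=region,
                        start=cursor,
                        end=cursor + gene_len - 1,
                        status="family_full",
                        protein_length=spec.protein_length,
                        anchored=True,
                    )
                )
                cursor += gene_len + 12000
                aux_model(region, cursor, cursor + 900, "other")
                cursor += 13000
            else:
                members = clusters[int(payload)]
                for m_idx, gene in enumerate(members):
                    # one deliberate inversion per first cluster: strand is
                    # ignored by tandem clustering
                    strand = "-" if int(payload) == 0 and m_idx == 1 else "+"
                    models.append(
                        GeneModel(
                            gene_id=gene,
                            taxon=spec.taxon,
                            seq_region=region,
                            start=cursor,
                            end=cursor + gene_len - 1,
                            strand=strand,
                            status="family_full",
                            protein_length=spec.protein_length,
                            anchored=True,
                        )
                    )
                    cursor += gene_len
                    if m_idx < len(members) - 1:
                        # interleave a non-breaking model between some members
                        if int(payload) % 2 == 0 and m_idx == 0:
                            aux_model(region, cursor + 200, cursor + 700, "family_partial")
                        elif int(payload) % 2 == 1 and m_idx == 0:
                            aux_model(region, cursor + 200, cursor + 700, "transposon")
                        cursor += 1200
                cursor += 12000
                aux_model(region, cursor, cursor + 900, "other")
                cursor += 13000
        region_lengths[region] = cursor + 15000

        for gene in gene_ids:
            proteins[gene] = family_protein(
                rng, spec.protein_length, dfgwg=not plan.dfgwg_free
            )
            if plan.dfgwg_free:
                exempt.add(gene)
            _retro_hits_for(gene, retro_category[gene], rng, hit_rows)
            truth_rows.append(
                {
                    "gene_id": gene,
                    "clade": clade,
                    "role": "family",
                    "local_cluster": (
                        f"{clade}_c{cluster_of[gene]}" if gene in cluster_of else ""
                    ),
                    "salicoid_partner": salicoid_partner.get(gene, ""),
                    "retro_category": retro_category[gene],
                }
            )

    # decoy candidates for each rejection class
    decoy_region = "LG_90"
    cursor = 15000
    family_ids = [r["gene_id"] for r in truth_rows if r["role"] == "family"]
    decoy_ids: list[str] = []
    for decoy_class, count in (
        ("no_hxxxd", spec.decoys.no_hxxxd),
        ("low_dfgwg", spec.decoys.low_dfgwg),
        ("too_short", spec.decoys.too_short),
    ):
        for i in range(count):
            gene = f"decoy_{decoy_class}_{i + 1}"
            decoy_ids.append(gene)
            seq = decoy_protein(rng, spec.protein_length, decoy_class)
            proteins[gene] = seq
            models.append(
                GeneModel(
                    gene_id=gene,
                    taxon=spec.taxon,
                    seq_region=decoy_region,
                    start=cursor,
                    end=cursor + gene_len - 1,
                    status="other",
                    protein_length=len(seq),
                    anchored=True,
                )
            )
            cursor += gene_len + 12000
            aux_model(decoy_region, cursor, cursor + 900, "other")
            cursor += 13000
            truth_rows.append(
                {
                    "gene_id": gene,
                    "clade": "",
                    "role": decoy_class,
                    "local_cluster": "",
                    "salicoid_partner": "",
                    "retro_category": "none",
                }
            )
    region_lengths[decoy_region] = cursor + 15000

    for i in range(spec.decoys.scaffold_redundant):
        gene = f"decoy_scaffold_redundant_{i + 1}"
        source = family_ids[i % len(family_ids)] if family_ids else None
        if source is None:
            break
        decoy_ids.append(gene)
        proteins[gene] = proteins[source]  # exact redundant copy
        scaffold = f"scaffold_{i + 1}"
        models.append(
            GeneModel(
                gene_id=gene,
                taxon=spec.taxon,
                seq_region=scaffold,
                start=2000,
                end=2000 + gene_len - 1,
                status="other",
                protein_length=len(proteins[gene]),
                anchored=False,
                region_length=15000,
            )
        )
        truth_rows.append(
            {
                "gene_id": gene,
                "clade": "",
                "role": "scaffold_redundant",
                "local_cluster": "",
                "salicoid_partner": "",
                "retro_category": "none",
            }
        )

    # a decoy ortholog pair must never be salicoid-flagged
    if decoy_ids and family_ids:
        ortholog_pairs.append((decoy_ids[0], family_ids[0]))

    models.sort(key=GeneModel.sort_key)
    truth_columns = [
        "gene_id",
        "clade",
        "role",
        "local_cluster",
        "salicoid_partner",
        "retro_category",
    ]
    truth = (
        pd.DataFrame(truth_rows, columns=truth_columns)
        .sort_values("gene_id")
        .reset_index(drop=True)
    )
    clade_of = {
        r["gene_id"]: r["clade"] for r in truth_rows if r["role"] == "family"
    }

    # tree: one subtree per clade (gene ladder plus a reference anchor tip)
    def ladder(tips: Sequence[str]) -> str:
        out = tips[0]
        for tip in tips[1:]:
            out = f"({out},{tip})"
        return out

    subtrees = []
    anchors: dict[str, set[str]] = {}
    taxon_of: dict[str, str] = {}
    for clade in clade_order:
        tips = [r["gene_id"] for r in truth_rows if r["clade"] == clade]
        anchor = f"REF_{clade}"
        anchors[clade] = {anchor}
        taxon_of[anchor] = "reference"
        for t in tips:
            taxon_of[t] = spec.taxon
        subtrees.append(ladder([anchor] + tips) if tips else f"({anchor})")
    tree_newick = ladder(subtrees) + ";"

    hit_df = pd.DataFrame(
        hit_rows, columns=["gene_id", "side", "hit_id", "e_value", "hit_class"]
    )
    return SyntheticGenome(
        models=models,
        proteins=proteins,
        synteny=SyntenyMap(ortholog_pairs=ortholog_pairs),
        flank_hits=hit_df,
        truth=truth,
        clade_of=clade_of,
        exempt=exempt,
        tree_newick=tree_newick,
        anchors=anchors,
        taxon_of=taxon_of,
        clade_order=clade_order,
    )


# ---------------------------------------------------------------------------
# Expression generation


def _latent_loading(rho: float) -> float:
    """Latent Pearson correlation giving Spearman rho under the copula."""
    return 2.0 * math.sin(math.pi * rho / 6.0)


def generate_expression(
    spec: SimulationSpec, genome: SyntheticGenome, seed: int = 0
) -> ExpressionTable:
    """Expression matrix with the planted rank-correlation structure.

    Each duplication group (connected component of local clusters and
    salicoid pairs) shares a latent factor; gene scores are
    ``sqrt(r)*F + sqrt(1-r)*noise`` with loading r chosen so duplicate
    pairs achieve the planted Spearman correlation in expectation, and a
    global factor plants ``rho_other`` among unrelated genes.
    Intensities are strictly positive (log-normal around the baseline).
    """
    plan = spec.expression
    rng = np.random.default_rng(seed)
    fam = genome.truth[genome.truth["role"] == "family"]
    genes = list(fam["gene_id"])
    n_genes = len(genes)
    n_samples = plan.n_groups * plan.n_replicates
    samples = [
        f"G{g + 1:02d}_r{r + 1}"
        for g in range(plan.n_groups)
        for r in range(plan.n_replicates)
    ]
    sample_groups = {s: s.split("_")[0] for s in samples}

    # duplication components via union-find
    parent = {g: g for g in genes}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    cluster_members: dict[str, list[str]] = {}
    for row in fam.itertuples(index=False):
        if row.local_cluster:
            cluster_members.setdefault(row.local_cluster, []).append(row.gene_id)
        if row.salicoid_partner:
            union(row.gene_id, row.salicoid_partner)
    for members in cluster_members.values():
        for a, b in zip(members, members[1:]):
            union(a, b)

    r_local = _latent_loading(plan.rho_local)
    r_salicoid = _latent_loading(plan.rho_salicoid)
    r_other = _latent_loading(plan.rho_other) if plan.rho_other > 0 else 0.0

    in_cluster = {
        row.gene_id: bool(row.local_cluster) for row in fam.itertuples(index=False)
    }
    has_partner = {
        row.gene_id: bool(row.salicoid_partner) for row in fam.itertuples(index=False)
    }

    components: dict[str, int] = {}
    comp_ids: dict[str, int] = {}
    for g in genes:
        root = find(g)
        comp_ids.setdefault(root, len(comp_ids))
        components[g] = comp_ids[root]

    global_factor = rng.standard_normal(n_samples)
    comp_factors = rng.standard_normal((len(comp_ids), n_samples))
    z = np.empty((n_genes, n_samples))
    for i, g in enumerate(genes):
        if in_cluster[g]:
            r_g = r_local
        elif has_partner[g]:
            r_g = r_salicoid
        else:
            r_g = r_other
        r_g = max(r_g, r_other)
        shared = math.sqrt(max(r_g - r_other, 0.0)) * comp_factors[components[g]]
        noise = math.sqrt(max(1.0 - r_g, 0.0)) * rng.standard_normal(n_samples)
        z[i] = math.sqrt(r_other) * global_factor + shared + noise

    intensities = 10.0 ** (plan.baseline_log10 + plan.sigma_log10 * z)
    values = pd.DataFrame(
        intensities, index=[f"probe_{g}" for g in genes], columns=samples
    )
    probe_genes = {f"probe_{g}": (g,) for g in genes}
    return ExpressionTable(
        values=values, sample_groups=sample_groups, probe_genes=probe_genes
    )


# ---------------------------------------------------------------------------
# Alignment generation


def generate_alignment(
    n_seqs: int,
    length: int,
    planted: Mapping[int, str | None] | None = None,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """A flat-composition alignment with identical planted windows.

    Background cells are i.i.d. uniform over the 20 amino acids.
    ``planted`` maps 0-based start columns to either a literal motif
    string (e.g. ``"DFGWG"``) or None for a random conserved 5-mer; the
    planted columns are identical across all sequences.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(AA20))
    matrix = letters[rng.integers(0, 20, size=(n_seqs, length))]
    for start, motif in (planted or {}).items():
        if motif is None:
            motif = "".join(letters[rng.integers(0, 20, size=5)])
        if start + len(motif) > length:
            raise SpecError("planted window exceeds alignment length")
        for offset, ch in enumerate(motif):
            matrix[:, start + offset] = ch
    return [(f"seq_{i + 1}", "".join(row)) for i, row in enumerate(matrix)]
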