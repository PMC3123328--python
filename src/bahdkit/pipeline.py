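"""End-to-end orchestration: simulate inputs, run every stage, write reports.

``simulate_inputs`` materializes a :class:`~bahdkit.simulate.SimulationSpec`
to a directory of standard-format files; ``run_pipeline`` consumes such a
directory (synthetic or user-provided), chains curation, clade
assignment, duplication typing, flank classification, the summary table
and (when expression inputs are present) the correlation statistics, and
writes one TSV per stage plus a machine-readable run manifest.  Outputs
are deterministically ordered so identical (config, seed) runs are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clades import LabelledTree, assign_clades
from .curation import curate_family, curation_table
from .duplication import (
    calls_table,
    call_local,
    call_salicoid,
    classify,
    load_overrides,
    summarize,
)
from .expression import correlation_records, dedupe_probes, kruskal_dunn, presence_filter, records_table
from .flanks import categories_table, classify_association
from .io_formats import (
    PipelineConfig,
    read_annotation,
    read_expression,
    read_flank_hits,
    read_proteins,
    read_synteny,
    write_annotation,
    write_expression,
    write_fasta,
    write_synteny,
)
from .simulate import SimulationSpec, generate_expression, generate_genome

logger = logging.getLogger("bahdkit")


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage."""


def simulate_inputs(spec: SimulationSpec, seed: int, out_dir: str | Path) -> Path:
    """Generate a complete input directory from a simulation spec."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(spec, seed=seed)
    write_annotation(genome.models, out_dir / "annotation.gff3")
    write_fasta(genome.proteins, out_dir / "proteins.fasta")
    write_synteny(genome.synteny, out_dir / "orthologs.tsv")
    genome.flank_hits.to_csv(out_dir / "flank_hits.tsv", sep="\t", index=False)
    (out_dir / "tree.nwk").write_text(genome.tree_newick + "\n")
    with open(out_dir / "anchors.yaml", "w") as handle:
        yaml.safe_dump(
            {clade: sorted(tips) for clade, tips in genome.anchors.items()},
            handle,
            sort_keys=False,
        )
    (out_dir / "clade_order.txt").write_text("\n".join(genome.clade_order) + "\n")
    (out_dir / "exempt.txt").write_text("".join(f"{g}\n" for g in sorted(genome.exempt)))
    pd.DataFrame(
        sorted(genome.taxon_of.items()), columns=["tip", "taxon"]
    ).to_csv(out_dir / "taxa.tsv", sep="\t", index=False)
    genome.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    expression = generate_expression(spec, genome, seed=seed + 1)
    write_expression(expression, out_dir)
    return out_dir


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    out_dir: Path
    manifest: dict


def run_pipeline(
    config: PipelineConfig, input_dir: str | Path, out_dir: str | Path
) -> PipelineResult:
    """Run curation, clades, duplications, flanks, summary and statistics."""
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.echo(logger)
    manifest: dict = {
        "version": __version__,
        "seed": config.random_seed,
        "config": config.as_dict(),
        "stages": [],
    }

    def stage(name):
        def wrap(fn):
            try:
                result = fn()
            except Exception as exc:
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].append(name)
            return result

        return wrap

    @stage("curate")
    def curation_result():
        models = read_annotation(input_dir / "annotation.gff3")
        proteins = read_proteins(input_dir / "proteins.fasta")
        exempt_path = input_dir / "exempt.txt"
        exempt = (
            set(exempt_path.read_text().split()) if exempt_path.exists() else set()
        )
        calls = curate_family(models, proteins, config, clade2_exempt=exempt)
        curation_table(calls, proteins).to_csv(
            out_dir / "curation.tsv", sep="\t", index=False
        )
        return models, proteins, calls

    models, proteins, family_calls = curation_result
    family = sorted(family_calls.accepted)

    @stage("clades")
    def clade_result():
        taxa = pd.read_csv(input_dir / "taxa.tsv", sep="\t")
        taxon_of = dict(zip(taxa["tip"], taxa["taxon"]))
        with open(input_dir / "anchors.yaml") as handle:
            anchors = yaml.safe_load(handle) or {}
        if not anchors:
            return {}, []
        tree = LabelledTree.from_newick(
            (input_dir / "tree.nwk").read_text(), taxon_of
        )
        assignment = assign_clades(tree, anchors)
        assignment = {g: c for g, c in assignment.items() if g in set(family)}
        pd.DataFrame(
            sorted(assignment.items()), columns=["gene_id", "clade"]
        ).to_csv(out_dir / "clades.tsv", sep="\t", index=False)
        order_path = input_dir / "clade_order.txt"
        clade_order = (
            order_path.read_text().split() if order_path.exists() else sorted(anchors)
        )
        return assignment, clade_order

    assignment, clade_order = clade_result

    @stage("dups")
    def dup_result():
        synteny = read_synteny(input_dir / "orthologs.tsv")
        synteny.validate_against(models)
        overrides_path = input_dir / "overrides.yaml"
        overrides = (
            load_overrides(overrides_path) if overrides_path.exists() else []
        )
        pairs = call_salicoid(family, synteny)
        clusters = call_local(family, models, overrides)
        calls = classify(family, pairs, clusters)
        calls_table(calls).to_csv(
            out_dir / "duplication_calls.tsv", sep="\t", index=False
        )
        return calls

    calls = dup_result

    @stage("flanks")
    def flank_result():
        hits = read_flank_hits(input_dir / "flank_hits.tsv")
        categories = classify_association(hits, family, config)
        categories_table(categories).to_csv(
            out_dir / "flank_categories.tsv", sep="\t", index=False
        )
        return categories

    flank_categories = flank_result

    @stage("summary")
    def summary_result():
        table = summarize(calls, assignment, flank_categories, clade_order)
        table.to_csv(out_dir / "summary.tsv", sep="\t")
        return table

    summary = summary_result

    expr_path = input_dir / "expression.tsv"
    if expr_path.exists():

        @stage("expr")
        def expr_result():
            table = read_expression(
                expr_path,
                input_dir / "expression_groups.tsv",
                input_dir / "expression_probes.tsv",
            )
            present = presence_filter(table, config.presence_intensity)
            table = dedupe_probes(table)
            keep = [p for p in table.values.index if p in set(present)]
            from .io_formats import ExpressionTable

            table = ExpressionTable(
                values=table.values.loc[keep],
                sample_groups=table.sample_groups,
                probe_genes={p: table.probe_genes[p] for p in keep},
            )
            records = correlation_records(table, assignment, calls)
            records_table(records).to_csv(
                out_dir / "correlations.tsv", sep="\t", index=False, float_format="%.6f"
            )
            groups: dict[str, list[float]] = {}
            for r in records:
                groups.setdefault(r.relation, []).append(r.rho)
            report: dict = {"n_records": len(records)}
            if len(groups) >= 2 and all(len(v) for v in groups.values()):
                kw = kruskal_dunn(groups, alpha=config.alpha)
                report.update(
                    {
                        "kruskal_H": kw.statistic,
                        "kruskal_p": kw.pvalue,
                        "group_sizes": kw.group_sizes,
                        "group_medians": kw.group_medians,
                        "letters": kw.letters,
                        "dunn": kw.dunn.to_dict(orient="records"),
                    }
                )
            with open(out_dir / "kw_dunn.json", "w") as handle:
                json.dump(report, handle, indent=2, sort_keys=True)
            return report

        expr_result

    with open(out_dir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return PipelineResult(summary=summary, out_dir=out_dir, manifest=manifest)
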