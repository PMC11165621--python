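"""End-to-end orchestration: genomes in, ranked taxonomy out.

Stages run in order: per-genome summary -> genetic-code detection ->
ORF calling under each genome's own assigned code -> protein clustering
-> core extraction -> intergenomic similarity -> per-family core-protein
tree -> rank demarcation.  Every intermediate artifact is written to the
run directory along with the fully-resolved configuration, so a run is
reproducible from its output alone.  Mixed-code inputs are handled
per-genome, which is the point: a genome calling table 15 is translated
under table 15 and still shares one pangenome with its table-11
relatives.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import ani as ani_mod
from . import codes, io, pangenome, taxonomy
from .records import GenomeRecord, ProteinRecord

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunables of a pipeline run; serialised into the run directory."""

    input_fasta: str = ""
    annotations_tsv: str | None = None
    name_map_file: str | None = None  # key=value lines: placeholder -> chosen name
    output_dir: str = "phagetax_run"
    identity_threshold: float = 70.0
    core_low_threshold: float = 25.0
    species_threshold: float = 95.0
    genus_threshold: float = 70.0
    fragment_len: int = 3000
    min_fragment_identity: float = 80.0
    min_orf_len: int = 90
    max_overlap: int = 30
    delta_threshold: float = 10.0
    min_root_support: float = 95.0
    bootstrap_reps: int = 100
    coverage_threshold: float = 0.8
    seed: int = 0
    order_label: str = "order1"

    def validate(self) -> None:
        for name in ("identity_threshold", "core_low_threshold", "species_threshold",
                     "genus_threshold", "min_fragment_identity", "min_root_support"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if not 0 < self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must be in (0, 1]")
        if self.fragment_len < 100:
            raise ValueError("fragment_len must be >= 100")
        if self.min_orf_len < 3 or self.min_orf_len % 3:
            raise ValueError("min_orf_len must be >= 3 and divisible by 3")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunResult:
    """In-memory handles to the main artifacts of a completed run."""

    outdir: Path
    genomes: list[GenomeRecord]
    code_calls: list[codes.CodeCall]
    proteins: list[ProteinRecord]
    graph: pangenome.ProteinGraph
    matrix: pangenome.PangenomeMatrix
    similarity: ani_mod.SimilarityMatrix
    taxonomy: taxonomy.TaxonomyResult


def _read_name_map(path: str | Path) -> dict[str, str]:
    """Parse a key=value name map (placeholder label -> chosen name)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"name map line without '=': {line!r}")
        key, val = line.split("=", 1)
        out[key.strip()] = val.strip()
    return out


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


def run_all(config: RunConfig, genomes: list[GenomeRecord] | None = None,
            annotations: dict[str, str] | None = None) -> RunResult:
    """Execute the full pipeline and write all artifacts to the run directory."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("read")
        if genomes is None:
            genomes = io.read_fasta(config.input_fasta)
        io.genome_summary(genomes).to_csv(outdir / "genome_summary.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("read", str(e)) from e

    try:
        stage("codecheck")
        calls = [codes.call_code(g, config.delta_threshold, config.min_orf_len, config.max_overlap)
                 for g in genomes]
        pd.DataFrame(
            [dict(genome_id=c.genome_id, cc11=round(c.cc11, 2), cc15=round(c.cc15, 2),
                  delta=round(c.delta, 2), assigned_table=c.assigned_table) for c in calls]
        ).to_csv(outdir / "codecheck.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("codecheck", str(e)) from e

    try:
        stage("orfs")
        table_of = {c.genome_id: c.assigned_table for c in calls}
        proteins: list[ProteinRecord] = []
        for g in genomes:
            code = codes.GeneticCode.from_table(table_of[g.id])
            proteins.extend(codes.proteome(g, code, config.min_orf_len, config.max_overlap))
        io.write_fasta(proteins, outdir / "proteins.faa")
        pd.DataFrame(
            [dict(protein_id=p.id, genome_id=p.source_genome, start=p.coords[0],
                  end=p.coords[1], strand=p.strand, length_aa=len(p.seq)) for p in proteins]
        ).to_csv(outdir / "orfs.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("orfs", str(e)) from e

    try:
        stage("cluster")
        graph = pangenome.ProteinGraph(proteins, coverage_threshold=config.coverage_threshold)
        clusters = graph.clusters(config.identity_threshold)
        if annotations is None and config.annotations_tsv:
            ann = pd.read_csv(config.annotations_tsv, sep="\t")
            annotations = dict(zip(ann.iloc[:, 0], ann.iloc[:, 1]))
        if annotations:
            for cl in clusters:
                pangenome.cluster_function(cl, annotations)
        matrix = pangenome.presence_matrix(
            clusters, [g.id for g in genomes],
            protein_to_genome={p.id: p.source_genome for p in proteins},
            identity_threshold=config.identity_threshold,
            coverage_threshold=config.coverage_threshold)
        pd.DataFrame(
            [dict(cluster_id=c.cluster_id, protein_id=m, genome_id=m.split("|")[0],
                  function=c.function_label, tie=c.tie_flag)
             for c in clusters for m in c.members]
        ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        matrix.counts.to_csv(outdir / "pangenome_matrix.tsv", sep="\t")
    except Exception as e:  # noqa: BLE001
        raise StageError("cluster", str(e)) from e

    try:
        stage("core")
        core = pangenome.core_clusters(matrix, {g.id for g in genomes})
        pd.DataFrame(
            [dict(cluster_id=c.cluster_id, n_members=c.size, function=c.function_label)
             for c in core]
        ).to_csv(outdir / "core_clusters.tsv", sep="\t", index=False)
        if len(genomes) >= 2:
            dendro = pangenome.presence_absence_dendrogram(matrix)
            dendro.write(str(outdir / "presence_absence_dendrogram.nwk"))
    except Exception as e:  # noqa: BLE001
        raise StageError("core", str(e)) from e

    try:
        stage("ani")
        if len(genomes) < 2:
            raise ValueError(">=2 genomes required")
        sim = ani_mod.similarity_matrix(genomes, config.fragment_len, config.min_fragment_identity)
        sim.to_tsv(outdir / "similarity_matrix.tsv")
        pd.DataFrame(
            [dict(query=p.query_id, ref=p.ref_id, ani=round(p.ani, 3), af=round(p.af, 4),
                  s=round(p.s, 3)) for p in sim.pairs]
        ).to_csv(outdir / "similarity_pairs.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("ani", str(e)) from e

    try:
        stage("classify")
        name_map = None
        if config.name_map_file:
            name_map = _read_name_map(config.name_map_file)
        result = taxonomy.build_taxonomy(
            sim, matrix, proteins, graph=graph,
            species_threshold=config.species_threshold,
            genus_threshold=config.genus_threshold,
            min_root_support=config.min_root_support,
            bootstrap_reps=config.bootstrap_reps, seed=config.seed,
            order_label=config.order_label, name_map=name_map)
        result.table.to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
        result.wide_table().to_csv(outdir / "taxonomy_wide.tsv", sep="\t", index=False)
        for fam, phylo in result.family_trees.items():
            phylo.tree.write(str(outdir / f"tree_{fam}.nwk"))
            with open(outdir / f"core_alignment_{fam}.faa", "w") as fh:
                for taxon, row in zip(phylo.alignment.ids, phylo.alignment.rows):
                    fh.write(f">{taxon}\n{row}\n")
            phylo.partitions.to_csv(outdir / f"partitions_{fam}.tsv", sep="\t", index=False)
        with open(outdir / "diagnostics.json", "w") as fh:
            json.dump(result.diagnostics, fh, indent=2, default=str)
    except Exception as e:  # noqa: BLE001
        raise StageError("classify", str(e)) from e

    return RunResult(outdir=outdir, genomes=genomes, code_calls=calls, proteins=proteins,
                     graph=graph, matrix=matrix, similarity=sim, taxonomy=result)
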