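"""End-to-end orchestration: identify -> properties -> promoters/CREs ->
filter -> classify -> network -> hubs -> enrichment.

A run is a pure function of the config and the referenced input files; the
manifest records parameters, input checksums, per-stage row counts and
output checksums, so reruns of an identical config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment as enr
from . import expression as expr
from . import family as fam
from . import network as net
from . import promoter as prom
from . import properties as props
from . import synthetic
from .exceptions import ParameterError, TogcnError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths and thresholds for one pipeline run."""

    output_dir: str
    # inputs (stages without their inputs are skipped and noted in the manifest)
    expression_tsv: str | None = None
    sample_map_tsv: str | None = None
    tf_list: str | None = None
    blast_tsv: str | None = None
    hmm_tbl: str | None = None
    gff3: str | None = None
    genome_fasta: str | None = None
    protein_fasta: str | None = None
    motif_tsv: str | None = None
    term_map_tsv: str | None = None
    # thresholds (defaults match the study's printed values)
    identity_min: float = 30.0
    evalue_max: float = 1e-5
    tpm_min: float = 1.0
    pcc_min: float = 0.9
    rel_tol: float = 0.1
    alpha: float = 0.05
    upstream: int = 2000
    pair_scope: str = "tf_vs_nontf"
    family_prefix: str = "TCP"
    pka_table: str = "expasy"
    seed: int = 42

    def __post_init__(self):
        if not (0 < self.pcc_min <= 1):
            raise ParameterError("pcc_min must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ParameterError("alpha must be in (0, 1)")
        if self.tpm_min < 0 or self.rel_tol < 0:
            raise ParameterError("tpm_min and rel_tol must be nonnegative")
        if self.upstream <= 0:
            raise ParameterError("upstream must be positive")
        if self.identity_min <= 0 or self.evalue_max <= 0:
            raise ParameterError("identity_min and evalue_max must be positive")
        if self.pair_scope not in net.PAIR_SCOPES:
            raise ParameterError(f"pair_scope must be one of {net.PAIR_SCOPES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns (and writes) the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": asdict(config),
        "inputs": {},
        "stages": {},
    }
    for name, path in (
        ("expression_tsv", config.expression_tsv),
        ("sample_map_tsv", config.sample_map_tsv),
        ("tf_list", config.tf_list),
        ("blast_tsv", config.blast_tsv),
        ("hmm_tbl", config.hmm_tbl),
        ("gff3", config.gff3),
        ("genome_fasta", config.genome_fasta),
        ("protein_fasta", config.protein_fasta),
        ("motif_tsv", config.motif_tsv),
        ("term_map_tsv", config.term_map_tsv),
    ):
        if path is not None:
            manifest["inputs"][name] = _sha256(Path(path))

    def record(stage: str, rows: int, outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "rows": rows,
            "outputs": {p.name: _sha256(p) for p in outputs},
        }

    def stage(name):
        def wrap(fn):
            try:
                fn()
            except TogcnError as exc:
                log.error("stage %r failed: %s", name, exc)
                exc.add_note(f"in pipeline stage {name!r}")
                raise
            except Exception as exc:
                log.error("stage %r failed: %s", name, exc)
                raise TogcnError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    annotation = None
    candidates: set[str] | None = None

    if config.blast_tsv and config.hmm_tbl:
        @stage("identify")
        def _identify():
            nonlocal candidates, annotation
            blast = fam.parse_blast_table(config.blast_tsv)
            hmm = fam.parse_hmmer_table(config.hmm_tbl)
            candidates = fam.intersect_candidates(
                hmm, blast, identity_min=config.identity_min,
                evalue_max=config.evalue_max,
            )
            out = outdir / "family_candidates.txt"
            out.write_text("".join(f"{g}\n" for g in sorted(candidates)))
            outputs = [out]
            if config.gff3:
                annotation = fam.GenomeAnnotation.from_gff3(config.gff3)
                renaming = fam.rename_by_position(
                    candidates, annotation, prefix=config.family_prefix
                )
                rpath = outdir / "family_renaming.tsv"
                fam.write_renaming(renaming, rpath)
                outputs.append(rpath)
            record("identify", len(candidates), outputs)

    if config.protein_fasta:
        @stage("properties")
        def _properties():
            from Bio import SeqIO
            seqs = {
                rec.id: str(rec.seq).rstrip("*")
                for rec in SeqIO.parse(config.protein_fasta, "fasta")
            }
            table = props.compute_properties(seqs, pka_table=config.pka_table)
            path = outdir / "protein_properties.tsv"
            table.to_csv(path, sep="\t", index=False, float_format="%.4f")
            record("properties", len(table), [path])

    if config.genome_fasta and config.gff3:
        @stage("promoter")
        def _promoter():
            nonlocal annotation
            if annotation is None:
                annotation = fam.GenomeAnnotation.from_gff3(config.gff3)
            motifs = prom.load_motif_table(config.motif_tsv)
            promoters = prom.extract_promoters(
                config.genome_fasta, annotation, upstream=config.upstream
            )
            matches = prom.scan_all(promoters, motifs)
            mpath = outdir / "cre_matches.tsv"
            prom.write_matches(matches, motifs, mpath)
            per_gene, summary = prom.categorize_cres(matches)
            gpath = outdir / "cre_per_gene.tsv"
            spath = outdir / "cre_summary.tsv"
            per_gene.to_csv(gpath, sep="\t", index=False)
            summary.to_csv(spath, sep="\t", index=False)
            record("promoter", len(matches), [mpath, gpath, spath])

    matrix = None
    filtered = None
    means = None

    if config.expression_tsv and config.sample_map_tsv:
        @stage("expression")
        def _expression():
            nonlocal matrix, filtered, means
            matrix = expr.ExpressionMatrix.from_tsv(
                config.expression_tsv, config.sample_map_tsv
            )
            filtered = expr.filter_low_expression(matrix, tpm_min=config.tpm_min)
            fpath = outdir / "expression_filtered.tsv"
            smpath = outdir / "expression_filtered.samples.tsv"
            filtered.to_tsv(fpath, smpath)
            means = expr.treatment_means(filtered)
            mpath = outdir / "treatment_means.tsv"
            means.to_csv(mpath, sep="\t", index_label="gene_id")
            labels = expr.classify_patterns(means, rel_tol=config.rel_tol)
            lpath = outdir / "pattern_labels.tsv"
            labels.rename_axis("gene_id").to_csv(lpath, sep="\t", header=["pattern"])
            record("expression", len(filtered.gene_ids), [fpath, smpath, mpath, lpath])

    graph = None
    tf_ids: set[str] = set()

    if filtered is not None and config.tf_list:
        @stage("network")
        def _network():
            nonlocal graph, tf_ids
            tf_ids = {
                line.strip()
                for line in Path(config.tf_list).read_text().splitlines()
                if line.strip()
            }
            graph = net.build_edges(
                filtered, tf_ids, pcc_min=config.pcc_min,
                pair_scope=config.pair_scope,
            )
            baits = net.select_bait_genes(
                means, net.BaitCriterion(rel_tol=config.rel_tol)
            )
            bpath = outdir / "bait_genes.txt"
            bpath.write_text("".join(f"{g}\n" for g in sorted(baits)))
            baits_in_graph = baits & set(graph.nodes)
            if baits_in_graph:
                net.assign_levels_bfs(graph, baits_in_graph)
            epath = outdir / "network_edges.tsv"
            net.export_network(graph, epath, fmt="edgelist")
            spath = outdir / "network.sif"
            net.export_network(graph, spath, fmt="sif")
            hubs = net.hub_statistics(graph)
            hpath = outdir / "hub_statistics.tsv"
            hubs.to_csv(hpath, sep="\t", index=False)
            record(
                "network", graph.number_of_edges(),
                [bpath, epath, epath.with_suffix(epath.suffix + ".nodes.tsv"),
                 spath, hpath],
            )

    if graph is not None and config.term_map_tsv:
        @stage("enrichment")
        def _enrichment():
            term_map = enr.load_term_map(config.term_map_tsv)
            background = set(filtered.gene_ids)
            study = {
                n for tf in (tf_ids & set(graph.nodes))
                for n in graph.neighbors(tf)
                if n not in tf_ids
            }
            results = enr.enrich(study, background, term_map, alpha=config.alpha)
            rpath = outdir / "enrichment_results.tsv"
            results.to_csv(rpath, sep="\t", index=False, float_format="%.6g")
            record("enrichment", len(results), [rpath])

    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def demo(outdir: str | Path, seed: int = 42) -> dict:
    """One-command synthetic end-to-end run with planted ground truth.

    Generates every input (expression matrix, genome + annotation, homology
    hit tables, term map) under ``outdir/inputs``, writes the truth objects
    beside them, then executes the full pipeline into ``outdir/results``.
    """
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)

    matrix, etruth = synthetic.generate_expression(seed=seed)
    matrix.to_tsv(inputs / "expression.tsv", inputs / "samples.tsv")
    etruth.to_json(inputs / "expression_truth.json")
    (inputs / "tf_list.txt").write_text(
        "".join(f"{g}\n" for g in sorted(etruth.tf_ids))
    )

    fasta, gff, gtruth = synthetic.generate_genome(inputs, seed=seed)
    gtruth.to_json(inputs / "genome_truth.json")

    genome_genes = sorted(gtruth.planted_motif_positions)
    family = set(genome_genes[: len(genome_genes) // 2])
    decoys = {f"DEC{i:03d}" for i in range(1, 9)}
    blast, hmm, htruth = synthetic.generate_hit_tables(family, decoys, inputs, seed=seed)
    htruth.to_json(inputs / "hits_truth.json")

    term_map = _demo_term_map(etruth, matrix.gene_ids, seed=seed)
    term_map.to_csv(inputs / "term_map.tsv", sep="\t", index=False)

    config = PipelineConfig(
        output_dir=str(outdir / "results"),
        expression_tsv=str(inputs / "expression.tsv"),
        sample_map_tsv=str(inputs / "samples.tsv"),
        tf_list=str(inputs / "tf_list.txt"),
        blast_tsv=str(blast),
        hmm_tbl=str(hmm),
        gff3=str(gff),
        genome_fasta=str(fasta),
        term_map_tsv=str(inputs / "term_map.tsv"),
        seed=seed,
    )
    config.to_yaml(outdir / "config.yaml")
    return run_pipeline(config)


def _demo_term_map(
    truth: synthetic.SyntheticTruth, gene_ids: list[str], seed: int
) -> pd.DataFrame:
    """Synthetic gene -> term map with one term planted inside module 0."""
    import numpy as np

    rng = np.random.default_rng(seed + 1)
    module0 = sorted(
        g for g, m in truth.module_assignments.items()
        if m == 0 and g not in truth.tf_ids
    )
    rows = [
        {"gene_id": g, "term_id": "GO:PLANTED", "term_name": "planted salt response"}
        for g in module0
    ]
    pool = sorted(set(gene_ids) - truth.low_expression_ids)
    for t in range(1, 11):
        members = rng.choice(pool, size=12, replace=False)
        for g in members:
            rows.append({
                "gene_id": str(g),
                "term_id": f"GO:{t:07d}",
                "term_name": f"background term {t}",
            })
    return pd.DataFrame(rows)
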