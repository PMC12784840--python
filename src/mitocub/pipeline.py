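"""End-to-end orchestration: GenBank files in, analysis tables out.

Every number written here is produced by one of the library operations;
this layer only sequences them, names files, and records a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .genetic_code import TABLE5
from . import codon, ingest, selection, summary

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    inputs: list                   # GenBank file paths
    out_dir: Path
    per_gene_rscu: bool = True
    per_species_rscu: bool = True
    pr2_sites: str = "fourfold"    # fourfold | all
    clip_enc: bool = True
    cluster_rows: str = "species"  # species | codons
    seed: int = 0

    def __post_init__(self):
        if not self.inputs:
            raise ValueError("no input GenBank files")
        self.inputs = [Path(p) for p in self.inputs]
        self.out_dir = Path(self.out_dir)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_analysis(config: RunConfig) -> dict:
    """Run the full comparative codon-usage analysis.

    Returns a dict of output-file paths keyed by table name.  On any stage
    failure, partial outputs are removed and a :class:`StageError` naming
    the stage is raised.
    """
    out = config.out_dir
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}
    warnings: list = []

    try:
        # --- ingest ---------------------------------------------------
        try:
            records = [ingest.parse_genbank(p) for p in config.inputs]
            genes = []
            for rec in records:
                genes.extend(ingest.extract_pcgs(rec))
        except Exception as exc:
            raise StageError("extract", exc)
        outputs["gene_inventory"] = out / "gene_inventory.tsv"
        ingest.write_gene_inventory(genes, outputs["gene_inventory"])
        outputs["genes_fasta"] = out / "pcg_sequences.fasta"
        ingest.write_gene_fasta(genes, outputs["genes_fasta"])

        # --- codon counts / RSCU -------------------------------------
        try:
            gene_counts = codon.count_codons(genes, "per_gene")
            sp_counts = codon.count_codons(genes, "per_species_concatenated")
            gene_profiles = [codon.compute_rscu(c) for c in gene_counts]
            sp_profiles = [codon.compute_rscu(c) for c in sp_counts]
        except Exception as exc:
            raise StageError("rscu", exc)
        by_label = {c.label: c for c in gene_counts + sp_counts}
        if config.per_gene_rscu:
            outputs["rscu_per_gene"] = out / "rscu_per_gene.tsv"
            codon.write_rscu_table(gene_profiles, by_label, outputs["rscu_per_gene"])
        if config.per_species_rscu:
            outputs["rscu_per_species"] = out / "rscu_per_species.tsv"
            codon.write_rscu_table(sp_profiles, by_label, outputs["rscu_per_species"])

        matrix = summary.build_rscu_matrix(sp_profiles)
        outputs["rscu_matrix"] = out / "rscu_matrix.csv"
        summary.write_rscu_matrix_csv(matrix, outputs["rscu_matrix"])
        tree = summary.hierarchical_cluster(matrix,
                                            transpose=config.cluster_rows == "codons")
        outputs["cluster_tree"] = out / "rscu_cluster.nwk"
        outputs["cluster_tree"].write_text(tree.newick() + "\n")

        # --- composition / ENC ---------------------------------------
        try:
            comps = [codon.positional_composition(g) for g in genes]
            enc_results = []
            for cc, cs in zip(gene_counts, comps):
                r = selection.compute_enc(cc, clip=config.clip_enc)
                enc_results.append(selection.attach_expected(r, cs.gc3s))
        except Exception as exc:
            raise StageError("enc", exc)
        outputs["composition"] = out / "composition.tsv"
        codon.write_composition_table(comps, outputs["composition"])
        outputs["enc"] = out / "enc.tsv"
        selection.write_enc_table(enc_results, outputs["enc"])

        # --- neutrality ----------------------------------------------
        try:
            fits = []
            by_species: dict = {}
            for g, cs in zip(genes, comps):
                by_species.setdefault(g.species, []).append((cs.gc3, cs.gc12))
            for sp, pts in by_species.items():
                fits.append(selection.fit_neutrality(pts, species=sp))
        except Exception as exc:
            raise StageError("neutrality", exc)
        outputs["neutrality"] = out / "neutrality.tsv"
        selection.write_neutrality_table(fits, outputs["neutrality"])

        # --- PR2 ------------------------------------------------------
        try:
            pr2 = [selection.pr2_coordinates(cs, sites=config.pr2_sites) for cs in comps]
            dropped = [p.label for p in pr2 if p.a3_ratio is None or p.g3_ratio is None]
            if dropped:
                warnings.append(f"PR2 undefined (zero denominator) for: {', '.join(dropped)}")
        except Exception as exc:
            raise StageError("pr2", exc)
        outputs["pr2"] = out / "pr2.tsv"
        selection.write_pr2_table(pr2, outputs["pr2"])

        # --- summaries ------------------------------------------------
        try:
            stats = [
                summary.summarize([r.enc_observed for r in enc_results], "ENC"),
                summary.summarize([c.gc3s for c in comps if c.gc3s is not None], "GC3s"),
                summary.summarize([c.gc3 for c in comps], "GC3"),
                summary.summarize([c.gc12 for c in comps], "GC12"),
            ]
        except Exception as exc:
            raise StageError("summarize", exc)
        outputs["summary"] = out / "summary_stats.tsv"
        summary.write_summary_table(stats, outputs["summary"])

        manifest = {
            "tool": "mitocub",
            "version": __version__,
            "config": {
                "inputs": [str(p) for p in config.inputs],
                "pr2_sites": config.pr2_sites,
                "clip_enc": config.clip_enc,
                "cluster_rows": config.cluster_rows,
                "seed": config.seed,
            },
            "input_sha256": {p.name: _sha256(p) for p in config.inputs},
            "n_species": len(records),
            "n_genes": len(genes),
            "warnings": warnings,
            "outputs": {k: str(v) for k, v in outputs.items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        outputs["manifest"] = out / "manifest.json"
    except StageError:
        for p in outputs.values():
            Path(p).unlink(missing_ok=True)
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise
    return outputs
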