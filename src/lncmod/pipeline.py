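"""End-to-end orchestration: co-expression -> modules -> enrichment ->
semantics -> clustering -> validation, with reproducibility metadata.

A single master seed drives the whole run; per-stage seeds are derived
deterministically (SeedSequence over the master seed and a stable hash of
the stage name, reduced mod 2^31), so any stage can be re-run in
isolation with its own seed and reproduce the monolithic run's output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

import lncmod
from lncmod.coexpr import build_coexpression_network
from lncmod.data_io import read_expression, read_go, read_ppi, write_network
from lncmod.enrichment import enrich, enrichment_overlap_network
from lncmod.go_semantics import functional_homogeneity, information_content
from lncmod.lnc_clustering import association_matrix, filter_clusters, hierarchical_cluster
from lncmod.ppi_modules import _stable_hash, classify_modules, module_table
from lncmod.validation import null_connectivity_comparison

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run (YAML/JSON-serializable)."""

    expression: str
    gene_class: str
    ppi: list[str]
    obo: str
    annotations: str
    sample_group: str | None = None
    top_fraction: float | None = 0.001
    mr_cutoff: float | None = None
    reps: int = 1000
    alpha: float = 0.05
    min_module_size: int = 6
    min_cluster_size: int = 5
    n_clusters: int | None = None
    overlap_threshold: float = 0.85
    namespace: str = "biological_process"
    n_random_networks: int = 1000
    seed: int = 0
    outdir: str = "lncmod_out"

    def __post_init__(self) -> None:
        if (self.top_fraction is None) == (self.mr_cutoff is None):
            raise ValueError("set exactly one of top_fraction / mr_cutoff")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0 <= self.overlap_threshold <= 1:
            raise ValueError("overlap_threshold must lie in [0, 1]")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(master), _stable_hash(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.left), walk(node.right)
        dl = node.dist - node.left.dist
        dr = node.dist - node.right.dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(tree) + ";"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order, writing all tables and a run manifest.

    Returns a result bundle with the in-memory products of each stage.
    Re-running with the same config and seed reproduces every output file
    byte for byte.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {
        "expression": config.expression,
        "gene_class": config.gene_class,
        "obo": config.obo,
        "annotations": config.annotations,
        **{f"ppi_{i}": p for i, p in enumerate(config.ppi)},
    }
    if config.sample_group:
        inputs["sample_group"] = config.sample_group

    expr = read_expression(config.expression, config.gene_class, config.sample_group)
    ppi = read_ppi(config.ppi)
    go = read_go(config.obo, config.annotations)

    # --- co-expression network -------------------------------------------
    coexpr = build_coexpression_network(
        expr, top_fraction=config.top_fraction, mr_cutoff=config.mr_cutoff
    )
    coexpr.to_tsv(outdir / "coexpression.tsv")

    # --- PPI modules ------------------------------------------------------
    mrna_pool = expr.mrna_ids
    modules, discarded = classify_modules(
        coexpr.partner_sets,
        ppi,
        mrna_pool,
        alpha=config.alpha,
        min_size=config.min_module_size,
        reps=config.reps,
        seed=stage_seed(config.seed, "modules"),
    )
    module_table(modules).to_csv(outdir / "modules.tsv", sep="\t", index=False,
                                 float_format="%.10g")
    module_table(discarded).to_csv(outdir / "modules_discarded.tsv", sep="\t",
                                   index=False, float_format="%.10g")
    dense = [m for m in modules if m.klass == "dense"]

    # --- enrichment -------------------------------------------------------
    background = sorted(
        g for g in mrna_pool if go.gene_terms(g, config.namespace)
    )
    enrichments: dict[str, pd.DataFrame] = {}
    rows = []
    for m in dense:
        genes = sorted(set(m.members) & set(background))
        if len(genes) < 1:
            continue
        table = enrich(genes, go, background, config.namespace)
        enrichments[m.lnc_id] = table
        table = table.assign(lnc_id=m.lnc_id)
        rows.append(table)
    combined = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["lnc_id", "term", "p_raw", "p_adj"])
    )
    combined.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                    float_format="%.10g")
    for lnc, table in sorted(enrichments.items()):
        net = enrichment_overlap_network(table, threshold=config.overlap_threshold,
                                         alpha=config.alpha)
        if net.number_of_nodes():
            write_network(net, outdir / f"overlap_{lnc}.sif", "sif")

    # --- functional homogeneity ------------------------------------------
    ic = information_content(go, config.namespace)
    fm_rows = []
    for m in dense:
        annotated = [g for g in sorted(m.members) if go.gene_terms(g, config.namespace)]
        if len(annotated) < 2:
            continue
        score = functional_homogeneity(annotated, go, ic)
        fm_rows.append({"lnc_id": m.lnc_id, "fm": score.fm,
                        "n_annotated": len(score.gene_set)})
    pd.DataFrame(fm_rows, columns=["lnc_id", "fm", "n_annotated"]).to_csv(
        outdir / "functional_homogeneity.tsv", sep="\t", index=False,
        float_format="%.10g")

    # --- module clustering ------------------------------------------------
    clusters: dict[str, int] = {}
    if len(dense) >= 2:
        assoc = association_matrix({m.lnc_id: m.coexpressed_mrnas for m in dense})
        assoc.to_csv(outdir / "association.tsv", sep="\t", float_format="%.10g")
        Z, labels = hierarchical_cluster(assoc, n_clusters=config.n_clusters)
        with open(outdir / "dendrogram.nwk", "w") as fh:
            fh.write(_newick(Z, list(assoc.index)) + "\n")
        if labels:
            clusters, unassigned = filter_clusters(labels, config.min_cluster_size)
            with open(outdir / "clusters.tsv", "w") as fh:
                fh.write("lnc_id\tcluster\n")
                for lnc in sorted(labels):
                    fh.write(f"{lnc}\t{clusters.get(lnc, 'unassigned')}\n")

    # --- validation -------------------------------------------------------
    report = null_connectivity_comparison(
        coexpr, ppi, mrna_pool,
        n_random=config.n_random_networks,
        seed=stage_seed(config.seed, "validation"),
    )
    validation = {
        "frac_real": report.frac_real,
        "frac_null_mean": float(np.mean(report.frac_null)),
        "frac_null_q95": float(np.quantile(report.frac_null, 0.95)),
        "mean_ppi_real": report.mean_ppi_real,
        "mean_ppi_null_mean": float(np.mean(report.mean_ppi_null)),
        "density_real": report.density_real,
        "density_null_mean": float(np.mean(report.density_null)),
        "ks_mean_ppi": report.ks_mean_ppi,
        "ks_density": report.ks_density,
        "n_random": report.n_random,
    }
    with open(outdir / "validation.json", "w") as fh:
        json.dump(validation, fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = {
        "config": asdict(config),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in ("modules", "validation")},
        "inputs_sha256": {k: _sha256(v) for k, v in sorted(inputs.items())},
        "version": lncmod.__version__,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "coexpression": coexpr,
        "modules": modules,
        "discarded": discarded,
        "enrichments": enrichments,
        "clusters": clusters,
        "validation": validation,
        "manifest": manifest,
    }
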