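"""End-to-end orchestration: synth → preprocess → activation → model selection
→ fit → permutation significance → subcomponent split → retrieval comparison →
per-component characterization, with every artifact written under one run
directory together with a manifest (input checksums, seed, package version).

Identical config + seed reproduces every output byte for byte: all randomness
is fanned out from the global seed through a fixed per-stage offset scheme.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import characterize as chz
from . import genesets as gs
from . import preprocess as pp
from . import rcca
from . import retrieval as rtv
from . import synth
from .config import PipelineConfig
from .io import (
    read_annotations_tsv,
    read_gmt,
    read_matrix_tsv,
    save_model,
    sha256_file,
    write_annotations_tsv,
    write_gmt,
    write_matrix_tsv,
)

__all__ = ["run_pipeline", "stage_seed"]

log = logging.getLogger("chemcca")

# fixed offsets give each stage its own reproducible stream, independent of
# which optional stages run
_STAGE_OFFSETS = {
    "synth": 1,
    "gsea": 2,
    "cv": 3,
    "permutation": 4,
    "targets": 5,
}


def stage_seed(seed: int, stage: str) -> int:
    return (seed * 1000 + _STAGE_OFFSETS[stage]) % (2**31)


def _read_expression_long(path: Path) -> synth.ExpressionBatchCollection:
    """Long-format expression TSV: batch, sample_id, role, compound_id, genes..."""
    df = pd.read_csv(path, sep="\t", dtype={"batch": str, "sample_id": str, "role": str})
    meta_cols = ["batch", "sample_id", "role", "compound_id"]
    genes = [c for c in df.columns if c not in meta_cols]
    batches = []
    for batch_id, grp in df.groupby("batch", sort=True):
        treatments = grp[grp["role"] == "treatment"]
        controls = grp[grp["role"] == "control"]
        batches.append(
            synth.ExpressionBatch(
                batch_id=str(batch_id),
                treatments=treatments.set_index("sample_id")[genes].astype(float),
                treatment_compounds=dict(
                    zip(treatments["sample_id"], treatments["compound_id"].astype(str))
                ),
                controls=controls.set_index("sample_id")[genes].astype(float),
            )
        )
    return synth.ExpressionBatchCollection(batches=batches, gene_ids=genes, planted_de={})


def _write_expression_long(collection: synth.ExpressionBatchCollection, path: Path) -> None:
    rows = []
    for batch in collection.batches:
        for inst in batch.treatments.index:
            rows.append(
                {
                    "batch": batch.batch_id,
                    "sample_id": inst,
                    "role": "treatment",
                    "compound_id": batch.treatment_compounds[inst],
                    **batch.treatments.loc[inst].to_dict(),
                }
            )
        for inst in batch.controls.index:
            rows.append(
                {
                    "batch": batch.batch_id,
                    "sample_id": inst,
                    "role": "control",
                    "compound_id": "",
                    **batch.controls.loc[inst].to_dict(),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _log_stage(name: str, t0: float, **params) -> None:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    log.info("stage=%s elapsed=%.2fs %s", name, time.time() - t0, kv)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured pipeline; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    # ---- inputs -----------------------------------------------------------
    t0 = time.time()
    if config.run_synth:
        x, expr, collection, annotations, truth = synth.simulate_study(
            n_compounds=config.n_compounds,
            n_genes=config.n_genes,
            n_sets=config.n_sets,
            n_descriptors=config.n_descriptors,
            k=config.latent_k,
            correlations=tuple(config.planted_correlations),
            batches=config.batches,
            controls_per_batch=config.controls_per_batch,
            effect_scale=config.effect_scale,
            noise_sd=config.noise_sd,
            outlier_shift=config.outlier_shift,
            n_labels=config.n_labels,
            alignment=config.alignment,
            seed=stage_seed(config.seed, "synth"),
        )
        write_matrix_tsv(x, outdir / "descriptors.tsv", index_label="compound")
        _write_expression_long(expr, outdir / "expression.tsv")
        write_gmt(collection, outdir / "gene_sets.gmt")
        write_annotations_tsv(annotations, outdir / "annotations.tsv")
    else:
        x = read_matrix_tsv(config.descriptors_path)
        expr = _read_expression_long(Path(config.expression_path))
        collection = read_gmt(config.gene_sets_path)
        annotations = (
            read_annotations_tsv(config.annotations_path) if config.annotations_path else None
        )
    _log_stage("inputs", t0, compounds=len(x), synth=config.run_synth)

    # ---- preprocess -------------------------------------------------------
    t0 = time.time()
    responses = pp.build_responses(expr, fraction=config.variance_fraction)
    write_matrix_tsv(responses.values, outdir / "responses.tsv", index_label="compound")
    responses.provenance.to_csv(outdir / "response_provenance.tsv", sep="\t")
    _log_stage("preprocess", t0, genes=responses.values.shape[1])

    # ---- gene-set activation ---------------------------------------------
    t0 = time.time()
    usable = collection.restricted_to(list(responses.values.columns))
    results = {}
    for i, cid in enumerate(responses.values.index):
        results[cid] = gs.enrichment_scores(
            responses.values.loc[cid],
            usable,
            n_perm=config.gsea_n_perm,
            seed=(stage_seed(config.seed, "gsea") + i) % (2**31),
        )
    activation = gs.build_activation_matrix(results, usable)
    activation = activation.loc[list(x.index)]
    write_matrix_tsv(activation, outdir / "activation.tsv", index_label="compound")
    _log_stage("activation", t0, sets=activation.shape[1])

    # ---- model selection + fit -------------------------------------------
    t0 = time.time()
    grid = [tuple(g) for g in config.grid]
    if annotations is not None and len(grid) > 1:
        l1, l2, cv_table = rcca.select_regularization(
            x,
            activation,
            grid=grid,
            folds=min(config.folds, len(x)),
            annotations=annotations,
            seed=stage_seed(config.seed, "cv"),
            n_components=config.n_components,
        )
        cv_table.to_csv(outdir / "cv_grid.tsv", sep="\t", index=False)
    else:
        l1, l2 = grid[0]
    model = rcca.fit_rcca(x, activation, l1=l1, l2=l2, n_components=config.n_components)
    _log_stage("fit", t0, l1=l1, l2=l2, n_components=model.n_components)

    # ---- permutation significance ----------------------------------------
    t0 = time.time()
    p, p_raw = rcca.permutation_significance(
        x,
        activation,
        l1=l1,
        l2=l2,
        n_components=model.n_components,
        n_perm=config.n_perm,
        seed=stage_seed(config.seed, "permutation"),
    )
    model.perm_pvalues = p
    model.perm_pvalues_raw = p_raw
    save_model(model, outdir / "model.json")
    retained = rcca.retained_components(
        model, p_threshold=config.p_threshold, top=config.top_components
    )
    _log_stage("significance", t0, retained=len(retained))

    split = rcca.split_subcomponents(model, side=config.score_side)

    # ---- retrieval comparison --------------------------------------------
    if config.run_retrieval and annotations is not None:
        t0 = time.time()
        ks = tuple(k for k in config.retrieval_ks if k <= len(x) - 1)
        curves = rtv.compare_spaces(
            x,
            activation,
            responses.values,
            model,
            annotations,
            ks=ks,
            retained=retained or None,
        )
        rows = []
        for curve in curves:
            for k, m, sem in zip(curve.ks, curve.map_values, curve.sem_values):
                rows.append({"space": curve.space, "k": k, "map": m, "sem": sem})
        pd.DataFrame(rows).to_csv(outdir / "retrieval_curves.tsv", sep="\t", index=False)
        _log_stage("retrieval", t0, queries=curves[0].n_queries)

    # ---- characterization --------------------------------------------------
    if config.run_characterize:
        t0 = time.time()
        reports = []
        report_dir = outdir / "reports"
        report_dir.mkdir(exist_ok=True)
        for s in retained or range(min(model.n_components, config.top_components)):
            sets_ranked = chz.top_gene_sets(model, activation, s, k=config.k_sets)
            for side in ("A", "B"):
                if not split.side(s, side):
                    continue
                rep = chz.SubcomponentReport(component=s, side=side)
                rep.top_compounds = chz.top_compounds(split, s, side, k=config.k_compounds)
                rep.top_gene_sets = sets_ranked
                rep.significant_genes = chz.component_de_genes(
                    model, split, responses.values, activation, usable, s, side,
                    p_threshold=config.p_threshold,
                )
                rep.term_enrichment = chz.term_enrichment(
                    rep.top_genes(30), usable, list(responses.values.columns)
                )[:10]
                if annotations is not None and len(rep.top_compounds) >= 2:
                    rep.target_enrichment = chz.target_enrichment(
                        [c for c, _ in rep.top_compounds],
                        annotations,
                        n_draws=config.target_draws,
                        seed=stage_seed(config.seed, "targets"),
                    )
                reports.append(rep)
                _export_report(rep, report_dir)
        if reports:
            bio, overlap = chz.subcomponent_similarity(reports)
            bio.to_csv(outdir / "subcomponent_biological_similarity.tsv", sep="\t")
            overlap.to_csv(outdir / "subcomponent_compound_overlap.tsv", sep="\t")
        eye = chz.eye_diagram_table(
            model, split, activation, x, k_sets=config.k_sets, components=retained or None
        )
        eye.to_csv(outdir / "eye_diagram.tsv", sep="\t", index=False)
        _log_stage("characterize", t0, subcomponents=len(reports))

    _write_manifest(config, outdir)
    return outdir


def _export_report(rep, report_dir: Path) -> None:
    base = report_dir / f"subcomponent_{rep.label}"
    pd.DataFrame(rep.top_compounds, columns=["compound", "score"]).to_csv(
        f"{base}_top_compounds.tsv", sep="\t", index=False
    )
    pd.DataFrame(rep.top_gene_sets, columns=["gene_set", "association"]).to_csv(
        f"{base}_top_gene_sets.tsv", sep="\t", index=False
    )
    if rep.significant_genes is not None:
        rep.significant_genes.head(30).to_csv(f"{base}_top_genes.tsv", sep="\t")
    pd.DataFrame(rep.term_enrichment, columns=["term", "p"]).to_csv(
        f"{base}_top_terms.tsv", sep="\t", index=False
    )
    if rep.target_enrichment is not None:
        shared, statistic, p = rep.target_enrichment
        with open(f"{base}_targets.tsv", "w", encoding="utf-8") as fh:
            fh.write("shared_targets\tstatistic\tp\n")
            fh.write(f"{','.join(shared)}\t{statistic}\t{p}\n")


def _write_manifest(config: PipelineConfig, outdir: Path) -> None:
    checksums = {
        f.name: sha256_file(f)
        for f in sorted(outdir.glob("*"))
        if f.is_file() and f.name != "manifest.json"
    }
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "checksums": checksums,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")
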