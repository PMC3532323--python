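"""Batch-structured expression profiles → one differential response per compound.

Stages, in order: consolidate each batch's controls (dropping at most one
outlier control when three or more are available), subtract the consolidated
control from every treatment in the batch, discard the genes with the highest
variance across the pooled control measurements (variation unrelated to the
chemical treatments), and keep for each compound the single instance with the
largest response norm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import InputError, ParameterError
from .synth import ExpressionBatchCollection

__all__ = [
    "ResponseMatrix",
    "consolidate_controls",
    "outlier_control_index",
    "differential_expression",
    "filter_high_variance_genes",
    "select_strongest_instance",
    "build_responses",
]


@dataclass
class ResponseMatrix:
    """Compounds × genes log2 differential expression with instance provenance."""

    values: pd.DataFrame  # rows indexed by instance id (or compound id after selection)
    provenance: pd.DataFrame  # index aligned with values; columns: compound_id, batch_id, instance_id

    def __post_init__(self):
        if self.values.isna().any().any():
            raise InputError("response matrix contains missing values")
        if self.values.columns.duplicated().any():
            raise InputError("duplicate gene ids in response matrix")


def outlier_control_index(controls: pd.DataFrame) -> int | None:
    """Index (positional) of the control to drop, or None when < 3 controls.

    The outlier is the control with the largest summed Euclidean distance to
    the other controls; ties broken by row order.
    """
    if len(controls) < 3:
        return None
    vals = controls.to_numpy(dtype=float)
    diff = vals[:, None, :] - vals[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    return int(dist.sum(axis=1).argmax())


def consolidate_controls(controls: pd.DataFrame) -> pd.Series:
    """One robust control profile from a batch's control measurements.

    With ≥3 controls the single most distant control is removed and the rest
    averaged; with 1–2 controls the plain mean is returned (removal would be
    ill-posed with a single reference point).
    """
    if len(controls) == 0:
        raise InputError("empty control list")
    if controls.columns.duplicated().any():
        raise InputError("duplicate gene ids in control profiles")
    drop = outlier_control_index(controls)
    kept = controls.drop(index=controls.index[drop]) if drop is not None else controls
    return kept.mean(axis=0)


def differential_expression(
    treatments: pd.DataFrame, controls: pd.DataFrame
) -> pd.DataFrame:
    """Per-instance response = log2 treatment profile − consolidated control."""
    if len(controls) == 0:
        raise InputError("batch has no control profiles")
    if list(treatments.columns) != list(controls.columns):
        raise InputError("treatment and control gene ids do not match")
    reference = consolidate_controls(controls)
    return treatments.sub(reference, axis=1)


def filter_high_variance_genes(
    responses: ResponseMatrix, control_profiles: pd.DataFrame, fraction: float
) -> ResponseMatrix:
    """Drop the ceil(fraction × n_genes) genes most variable across pooled controls.

    Variance is computed over all control profiles pooled across batches; the
    retained genes keep their original order, and ties at the cutoff are
    broken by gene id so the result is deterministic.
    """
    if not 0 <= fraction < 1:
        raise ParameterError("fraction must lie in [0, 1)")
    if fraction == 0:
        return responses
    genes = list(responses.values.columns)
    if list(control_profiles.columns) != genes:
        raise InputError("control profiles and responses have different gene universes")
    n_drop = math.ceil(fraction * len(genes))
    var = control_profiles.var(axis=0, ddof=1)
    dropped = sorted(genes, key=lambda g: (-var[g], g))[:n_drop]
    kept = [g for g in genes if g not in set(dropped)]
    return ResponseMatrix(values=responses.values[kept], provenance=responses.provenance)


def select_strongest_instance(responses: ResponseMatrix) -> ResponseMatrix:
    """Keep, per compound, the instance with maximal response Euclidean norm.

    Exact ties go to the lexicographically smallest instance id.  The output
    is indexed by compound id and provenance records the instance kept.
    """
    norms = np.linalg.norm(responses.values.to_numpy(dtype=float), axis=1)
    best: dict[str, tuple[float, str]] = {}
    for inst, norm in zip(responses.values.index, norms):
        cid = responses.provenance.loc[inst, "compound_id"]
        key = (-norm, str(inst))
        if cid not in best or key < best[cid]:
            best[cid] = key
    kept_instances = [inst for (_, inst) in best.values()]
    values = responses.values.loc[kept_instances].copy()
    prov = responses.provenance.loc[kept_instances].copy()
    values.index = pd.Index(list(best.keys()), name="compound")
    prov.index = values.index
    order = sorted(values.index)
    return ResponseMatrix(values=values.loc[order], provenance=prov.loc[order])


def build_responses(
    collection: ExpressionBatchCollection, fraction: float = 0.05
) -> ResponseMatrix:
    """Full preprocessing pipeline over a batch collection."""
    frames, prov_rows, pooled_controls = [], [], []
    for batch in collection.batches:
        resp = differential_expression(batch.treatments, batch.controls)
        frames.append(resp)
        pooled_controls.append(batch.controls)
        for inst in resp.index:
            prov_rows.append(
                {
                    "instance_id": inst,
                    "compound_id": batch.treatment_compounds[inst],
                    "batch_id": batch.batch_id,
                }
            )
    values = pd.concat(frames, axis=0)
    provenance = pd.DataFrame(prov_rows).set_index(pd.Index(values.index))
    responses = ResponseMatrix(values=values, provenance=provenance)
    controls = pd.concat(pooled_controls, axis=0)
    responses = filter_high_variance_genes(responses, controls, fraction)
    return select_strongest_instance(responses)
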