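"""Synthetic data with the statistical structure the pipeline assumes.

Every generator is a pure function of its arguments, seed included, so any
downstream result is reproducible bit-for-bit.  The joint generator plants a
shared low-rank latent signal connecting a chemical-descriptor view and a
gene-set-activation view: per component s a bivariate-normal latent pair
(u_s, t_s) with a chosen correlation is drawn per compound, mapped through
unit-norm loading vectors into each view, and observation noise is added in
the orthogonal complement of the loading span.  Confining the noise to
directions carrying no signal makes the planted correlations the exact
population canonical correlations of the generated pair of views, which is
what "ground truth" has to mean for a recovery test.

Activations are squashed into (−1, 1) with a gently scaled error function:
bounded like real signed-activation profiles, but close to linear over the
bulk of the data so the latent geometry survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf
from sklearn.cluster import KMeans

from .genesets import GeneSetCollection
from .io import ParameterError
from .retrieval import AnnotationSet

__all__ = [
    "LatentTruth",
    "ExpressionBatch",
    "ExpressionBatchCollection",
    "simulate_joint_data",
    "latent_view",
    "simulate_expression_batches",
    "simulate_gene_sets",
    "simulate_annotations",
    "simulate_study",
]

SQUASH_SCALE = 3.0  # error-function squash: erf(x / (SQUASH_SCALE * sd(x)))


@dataclass(frozen=True)
class LatentTruth:
    """Generative ground truth behind a simulated descriptor/activation pair."""

    latent_scores: pd.DataFrame  # compounds × k, mean of the two views' latents
    chem_scores: pd.DataFrame  # compounds × k (u)
    bio_scores: pd.DataFrame  # compounds × k (t)
    chem_loadings: pd.DataFrame  # descriptors × k, unit-norm columns
    bio_loadings: pd.DataFrame  # gene-sets × k, unit-norm columns
    planted_correlations: tuple[float, ...]
    seed: int


@dataclass(frozen=True)
class ExpressionBatch:
    batch_id: str
    treatments: pd.DataFrame  # instances × genes (log2 scale)
    treatment_compounds: dict[str, str]  # instance id → compound id
    controls: pd.DataFrame  # controls × genes


@dataclass(frozen=True)
class ExpressionBatchCollection:
    batches: list[ExpressionBatch]
    gene_ids: list[str]
    planted_de: dict[str, tuple[frozenset[str], float]]  # compound → (genes, effect)
    outlier_controls: dict[str, int | None] = field(default_factory=dict)


def _unit_columns(arr: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(arr, axis=0)
    norms[norms == 0] = 1.0
    return arr / norms


def _orthonormal_loadings(rng: np.random.Generator, dim: int, k: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((dim, k)))
    return q[:, :k]


def _squash(raw: np.ndarray, scale: float = SQUASH_SCALE) -> np.ndarray:
    sd = raw.std()
    if sd == 0:
        return np.zeros_like(raw)
    return erf(raw / (scale * sd))


def simulate_joint_data(
    n: int,
    p: int,
    q: int,
    k: int,
    correlations: tuple[float, ...],
    noise_sd: float,
    seed: int,
    chem_loadings: np.ndarray | None = None,
    bio_loadings: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, LatentTruth]:
    """Generate aligned chemical (n×p) and biological (n×q) views.

    correlations[s] is the planted canonical correlation of component s.
    Custom loading matrices (p×k / q×k) may be supplied; their columns are
    normalized to unit length.  Noise is isotropic within the orthogonal
    complement of the loading span.
    """
    correlations = tuple(float(c) for c in correlations)
    if k > min(p, q):
        raise ParameterError(f"k={k} exceeds min(p, q)={min(p, q)}")
    if len(correlations) != k:
        raise ParameterError("need exactly k planted correlations")
    if any(c < 0 or c > 1 for c in correlations):
        raise ParameterError("planted correlations must lie in [0, 1]")
    if sorted(correlations, reverse=True) != list(correlations):
        raise ParameterError("planted correlations must be non-increasing")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal((n, k))
    z2 = rng.standard_normal((n, k))
    rho = np.asarray(correlations)
    u = z1
    t = rho * z1 + np.sqrt(1.0 - rho**2) * z2

    if chem_loadings is None:
        a = _orthonormal_loadings(rng, p, k)
    else:
        a = _unit_columns(np.asarray(chem_loadings, dtype=float).copy())
    if bio_loadings is None:
        b = _orthonormal_loadings(rng, q, k)
    else:
        b = _unit_columns(np.asarray(bio_loadings, dtype=float).copy())

    ex = rng.standard_normal((n, p))
    ey = rng.standard_normal((n, q))
    # project noise off the loading span so planted correlations are exact
    ex -= ex @ a @ np.linalg.pinv(a.T @ a) @ a.T
    ey -= ey @ b @ np.linalg.pinv(b.T @ b) @ b.T

    x = u @ a.T + noise_sd * ex
    y_raw = t @ b.T + noise_sd * ey
    y = _squash(y_raw)

    compounds = [f"cmp{i:04d}" for i in range(n)]
    descriptors = [f"desc{j:03d}" for j in range(p)]
    sets = [f"set{j:04d}" for j in range(q)]
    comp_idx = pd.Index(compounds, name="compound")
    truth = LatentTruth(
        latent_scores=pd.DataFrame((u + t) / 2.0, index=comp_idx),
        chem_scores=pd.DataFrame(u, index=comp_idx),
        bio_scores=pd.DataFrame(t, index=comp_idx),
        chem_loadings=pd.DataFrame(a, index=descriptors),
        bio_loadings=pd.DataFrame(b, index=sets),
        planted_correlations=correlations,
        seed=seed,
    )
    return (
        pd.DataFrame(x, index=comp_idx, columns=descriptors),
        pd.DataFrame(y, index=comp_idx, columns=sets),
        truth,
    )


def latent_view(
    latent: LatentTruth,
    n_features: int,
    noise_sd: float,
    seed: int,
    side: str = "bio",
    loadings: np.ndarray | None = None,
    squash: bool = False,
    feature_prefix: str = "feat",
) -> pd.DataFrame:
    """Materialize an extra observed view of an existing latent truth.

    Useful for building a gene-level space that shares the latent structure of
    the gene-set view (e.g. for four-way retrieval comparisons).
    """
    scores = {"bio": latent.bio_scores, "chem": latent.chem_scores, "mean": latent.latent_scores}[
        side
    ].to_numpy()
    k = scores.shape[1]
    rng = np.random.default_rng(seed)
    if loadings is None:
        g = _orthonormal_loadings(rng, n_features, k)
    else:
        g = _unit_columns(np.asarray(loadings, dtype=float).copy())
    e = rng.standard_normal((scores.shape[0], n_features))
    e -= e @ g @ np.linalg.pinv(g.T @ g) @ g.T
    raw = scores @ g.T + noise_sd * e
    if squash:
        raw = _squash(raw)
    cols = [f"{feature_prefix}{j:05d}" for j in range(n_features)]
    return pd.DataFrame(raw, index=latent.latent_scores.index, columns=cols)


def simulate_expression_batches(
    compounds: list[str],
    n_genes: int,
    batches: int,
    controls_per_batch: int,
    effect_size: float,
    outlier_shift: float,
    seed: int,
    planted_set_size: int = 20,
    noise_sd: float = 0.25,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
    planted_effects: dict[str, np.ndarray] | None = None,
) -> ExpressionBatchCollection:
    """Batch-structured log2 expression profiles with planted treatment effects.

    Each compound's treatment adds ``effect_size`` to a random planted gene
    set (or an arbitrary per-gene effect vector via ``planted_effects``).
    When a batch has ≥3 controls and ``outlier_shift`` ≠ 0, one control is
    shifted by ``outlier_shift`` on every gene and recorded, giving the
    control-consolidation stage a known outlier to flag.
    """
    if controls_per_batch < 1:
        raise ParameterError("controls_per_batch must be >= 1")
    if planted_effects is None and n_genes < planted_set_size:
        raise ParameterError("n_genes smaller than the planted gene-set size")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)

    batch_assignment: dict[str, list[str]] = {f"batch{b:03d}": [] for b in range(batches)}
    for i, cid in enumerate(compounds):
        batch_assignment[f"batch{i % batches:03d}"].append(cid)

    planted_de: dict[str, tuple[frozenset[str], float]] = {}
    out_batches: list[ExpressionBatch] = []
    outlier_controls: dict[str, int | None] = {}
    for batch_id, members in batch_assignment.items():
        batch_shift = rng.normal(0.0, 0.3, size=n_genes)
        ctrl = baseline + batch_shift + rng.normal(0.0, noise_sd, size=(controls_per_batch, n_genes))
        if outlier_shift != 0 and controls_per_batch >= 3:
            idx = int(rng.integers(controls_per_batch))
            ctrl[idx] += outlier_shift
            outlier_controls[batch_id] = idx
        else:
            outlier_controls[batch_id] = None
        rows, comp_map = [], {}
        for cid in members:
            if planted_effects is not None:
                effect = np.asarray(planted_effects[cid], dtype=float)
                genes_hit = frozenset(g for g, e in zip(genes, effect) if e != 0)
                planted_de[cid] = (genes_hit, float(np.max(np.abs(effect), initial=0.0)))
            else:
                hit_idx = rng.choice(n_genes, size=planted_set_size, replace=False)
                effect = np.zeros(n_genes)
                effect[hit_idx] = effect_size
                planted_de[cid] = (frozenset(genes[i] for i in hit_idx), effect_size)
            rows.append(baseline + batch_shift + effect + rng.normal(0.0, noise_sd, size=n_genes))
            inst = f"{cid}@{batch_id}"
            comp_map[inst] = cid
        treatments = pd.DataFrame(rows, index=list(comp_map), columns=genes)
        controls = pd.DataFrame(
            ctrl, index=[f"{batch_id}_ctl{i}" for i in range(controls_per_batch)], columns=genes
        )
        out_batches.append(
            ExpressionBatch(
                batch_id=batch_id,
                treatments=treatments,
                treatment_compounds=comp_map,
                controls=controls,
            )
        )
    return ExpressionBatchCollection(
        batches=out_batches, gene_ids=genes, planted_de=planted_de, outlier_controls=outlier_controls
    )


def simulate_gene_sets(
    gene_universe: list[str],
    n_sets: int,
    size_range: tuple[int, int],
    seed: int,
    name_prefix: str = "SYN_SET",
) -> GeneSetCollection:
    """Random gene sets sampled without replacement within each set."""
    if not gene_universe:
        raise ParameterError("gene universe is empty")
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ParameterError("invalid size range")
    if hi > len(gene_universe):
        raise ParameterError("max set size exceeds universe size")
    rng = np.random.default_rng(seed)
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(gene_universe), size=size, replace=False)
        sets[f"{name_prefix}_{i:04d}"] = frozenset(gene_universe[j] for j in members)
    return GeneSetCollection(sets=sets, universe=sorted(gene_universe))


def simulate_annotations(
    compounds: list[str],
    n_labels: int,
    latent: LatentTruth,
    alignment: float,
    seed: int,
) -> AnnotationSet:
    """Functional labels (stand-ins for targets/ATC codes) for the compounds.

    Compounds are clustered on their latent scores; with probability
    ``alignment`` a compound receives its cluster's label, otherwise a random
    label, so alignment=1 makes labels a deterministic function of the latent
    cluster and alignment=0 makes them independent of the structure.
    """
    if not 0 <= alignment <= 1:
        raise ParameterError("alignment must lie in [0, 1]")
    if n_labels == 0:
        if alignment > 0:
            raise ParameterError("n_labels=0 is incompatible with alignment > 0")
        return AnnotationSet(pairs=pd.DataFrame(columns=["compound_id", "label_id", "kind"]))
    rng = np.random.default_rng(seed)
    scores = latent.latent_scores.loc[compounds].to_numpy()
    km = KMeans(n_clusters=min(n_labels, len(compounds)), n_init=10, random_state=seed % (2**31))
    clusters = km.fit_predict(scores)
    rows = []
    for cid, cl in zip(compounds, clusters):
        if rng.random() < alignment:
            label = int(cl)
        else:
            label = int(rng.integers(n_labels))
        rows.append((cid, f"L{label:03d}", "target"))
    pairs = pd.DataFrame(rows, columns=["compound_id", "label_id", "kind"])
    return AnnotationSet(pairs=pairs)


def simulate_study(
    n_compounds: int = 60,
    n_genes: int = 600,
    n_sets: int = 30,
    n_descriptors: int = 20,
    k: int = 3,
    correlations: tuple[float, ...] = (0.9, 0.8, 0.7),
    batches: int = 6,
    controls_per_batch: int = 3,
    effect_scale: float = 1.5,
    noise_sd: float = 0.5,
    outlier_shift: float = 20.0,
    n_labels: int = 5,
    alignment: float = 0.9,
    seed: int = 0,
) -> tuple[pd.DataFrame, ExpressionBatchCollection, GeneSetCollection, AnnotationSet, LatentTruth]:
    """End-to-end coherent synthetic study.

    Descriptors and latent structure come from :func:`simulate_joint_data`;
    gene-level treatment effects are the bio latent scores pushed through
    set-structured gene loadings (sets tile the genome, each component loads
    on its own block of sets), so running the real preprocessing + enrichment
    stages recovers activation profiles correlated with the chemical view.
    """
    x, _, truth = simulate_joint_data(
        n_compounds, n_descriptors, n_sets, k, correlations, noise_sd, seed
    )
    compounds = list(x.index)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    set_size = n_genes // n_sets
    sets = {
        f"SYN_SET_{i:04d}": frozenset(genes[i * set_size : (i + 1) * set_size])
        for i in range(n_sets)
    }
    collection = GeneSetCollection(sets=sets, universe=genes)
    # component s drives a disjoint block of sets → block of genes
    sets_per_comp = n_sets // k
    gene_loadings = np.zeros((n_genes, k))
    for s in range(k):
        lo = s * sets_per_comp * set_size
        hi = (s + 1) * sets_per_comp * set_size
        gene_loadings[lo:hi, s] = 1.0
    effects = truth.bio_scores.to_numpy() @ (gene_loadings * effect_scale).T
    planted = {cid: effects[i] for i, cid in enumerate(compounds)}
    expr = simulate_expression_batches(
        compounds,
        n_genes,
        batches,
        controls_per_batch,
        effect_size=0.0,
        outlier_shift=outlier_shift,
        seed=seed + 1,
        noise_sd=0.25,
        planted_effects=planted,
    )
    annotations = simulate_annotations(compounds, n_labels, truth, alignment, seed=seed + 2)
    return x, expr, collection, annotations, truth
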