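"""Regularized canonical correlation analysis of chemical vs biological space.

The model seeks paired projections (w_s, v_s) of a descriptor matrix X (n×p)
and an activation matrix Y (n×q) maximizing the ridge-penalized correlation

    P_s = w'C_xy v / sqrt((w'C_xx w + l1·w'w) (v'C_yy v + l2·v'v)),

where C_xx = X'X/(n−1) etc. are centered feature-space covariances, subject to
unit variance of the training variates and uncorrelatedness (in the
regularized metric) between components.  The solution is the symmetric
eigenproblem of

    M = (C_xx + l1·I)^{-1/2} C_xy (C_yy + l2·I)^{-1} C_yx (C_xx + l1·I)^{-1/2};

canonical correlations are the square roots of its eigenvalues (clipped to
[0, 1]).  Ridge penalties make the problem well-posed when features are
collinear or outnumber samples.

Model selection follows a retrieval criterion: the (l1, l2) grid point whose
cross-validated component space best retrieves functionally similar compounds
(mean average precision against external annotations) wins.  Component
significance comes from a permutation test that breaks the row pairing of the
two spaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import InputError, ParameterError
from . import retrieval as _retrieval

__all__ = [
    "CcaModel",
    "ComponentSplit",
    "fit_rcca",
    "project",
    "select_regularization",
    "permutation_significance",
    "split_subcomponents",
    "retained_components",
]


class NumericalError(np.linalg.LinAlgError):
    """Singular regularized covariance; increase l1/l2."""


@dataclass
class CcaModel:
    chem_weights: pd.DataFrame  # descriptors × S
    bio_weights: pd.DataFrame  # gene-sets × S
    correlations: np.ndarray  # S, non-increasing, in [0, 1]
    chem_variates: pd.DataFrame  # compounds × S, unit training variance
    bio_variates: pd.DataFrame
    l1: float
    l2: float
    x_center: pd.Series
    x_scale: pd.Series
    y_center: pd.Series
    y_scale: pd.Series
    perm_pvalues: np.ndarray | None = None
    perm_pvalues_raw: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.chem_weights.shape[1]

    def chem_weights_original_scale(self) -> pd.DataFrame:
        """Weights expressed against the unstandardized descriptor columns."""
        return self.chem_weights.div(self.x_scale, axis=0)

    def to_dict(self) -> dict:
        return {
            "chem_weights": {
                "index": list(self.chem_weights.index),
                "values": self.chem_weights.to_numpy().tolist(),
            },
            "bio_weights": {
                "index": list(self.bio_weights.index),
                "values": self.bio_weights.to_numpy().tolist(),
            },
            "correlations": self.correlations.tolist(),
            "chem_variates": {
                "index": list(self.chem_variates.index),
                "values": self.chem_variates.to_numpy().tolist(),
            },
            "bio_variates": {
                "index": list(self.bio_variates.index),
                "values": self.bio_variates.to_numpy().tolist(),
            },
            "l1": self.l1,
            "l2": self.l2,
            "x_center": self.x_center.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_center": self.y_center.tolist(),
            "y_scale": self.y_scale.tolist(),
            "perm_pvalues": None if self.perm_pvalues is None else self.perm_pvalues.tolist(),
            "perm_pvalues_raw": None
            if self.perm_pvalues_raw is None
            else self.perm_pvalues_raw.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CcaModel":
        def frame(entry):
            return pd.DataFrame(entry["values"], index=entry["index"])

        cw = frame(d["chem_weights"])
        bw = frame(d["bio_weights"])
        return cls(
            chem_weights=cw,
            bio_weights=bw,
            correlations=np.asarray(d["correlations"], dtype=float),
            chem_variates=frame(d["chem_variates"]),
            bio_variates=frame(d["bio_variates"]),
            l1=float(d["l1"]),
            l2=float(d["l2"]),
            x_center=pd.Series(d["x_center"], index=cw.index),
            x_scale=pd.Series(d["x_scale"], index=cw.index),
            y_center=pd.Series(d["y_center"], index=bw.index),
            y_scale=pd.Series(d["y_scale"], index=bw.index),
            perm_pvalues=None
            if d.get("perm_pvalues") is None
            else np.asarray(d["perm_pvalues"], dtype=float),
            perm_pvalues_raw=None
            if d.get("perm_pvalues_raw") is None
            else np.asarray(d["perm_pvalues_raw"], dtype=float),
        )


@dataclass
class ComponentSplit:
    """Per component: compounds split by the sign of their canonical score."""

    scores: pd.DataFrame  # compounds × S
    members_a: list[list[str]] = field(default_factory=list)
    members_b: list[list[str]] = field(default_factory=list)

    def side(self, component: int, side: str) -> list[str]:
        return {"A": self.members_a, "B": self.members_b}[side][component]


def _inv_sqrt_and_inv(c: np.ndarray, ridge: float, what: str):
    cr = c + ridge * np.eye(c.shape[0])
    evals, evecs = np.linalg.eigh(cr)
    tol = max(evals.max(), 0) * 1e-10
    if evals.min() <= tol:
        raise NumericalError(
            f"regularized covariance of the {what} space is singular; "
            "increase the corresponding ridge penalty (l > 0)"
        )
    inv_sqrt = (evecs / np.sqrt(evals)) @ evecs.T
    inv = (evecs / evals) @ evecs.T
    return inv_sqrt, inv


def _fit_core(xc: np.ndarray, yc: np.ndarray, l1: float, l2: float, n_components: int):
    """rCCA on centered/scaled arrays; returns (W, V, correlations)."""
    n = xc.shape[0]
    cxx = xc.T @ xc / (n - 1)
    cyy = yc.T @ yc / (n - 1)
    cxy = xc.T @ yc / (n - 1)
    cxx_isqrt, _ = _inv_sqrt_and_inv(cxx, l1, "chemical")
    _, cyy_inv = _inv_sqrt_and_inv(cyy, l2, "biological")
    m = cxx_isqrt @ cxy @ cyy_inv @ cxy.T @ cxx_isqrt
    m = (m + m.T) / 2.0
    evals, evecs = np.linalg.eigh(m)
    order = np.argsort(evals)[::-1][:n_components]
    corr = np.sqrt(np.clip(evals[order], 0.0, 1.0))
    w = cxx_isqrt @ evecs[:, order]
    v = cyy_inv @ cxy.T @ w
    # normalize to unit training variance of each variate
    for s in range(w.shape[1]):
        sx = xc @ w[:, s]
        sy = yc @ v[:, s]
        sdx = sx.std(ddof=1)
        sdy = sy.std(ddof=1)
        if sdx > 0:
            w[:, s] /= sdx
        if sdy > 0:
            v[:, s] /= sdy
        # sign convention: largest-|entry| element of w_s positive
        i = np.argmax(np.abs(w[:, s]))
        if w[i, s] < 0:
            w[:, s] *= -1
            v[:, s] *= -1
    return w, v, corr


def _prepare(x: pd.DataFrame, y: pd.DataFrame, standardize_x: bool, scale_y: bool):
    if list(x.index) != list(y.index):
        raise InputError("X and Y compound ids are not aligned")
    if x.isna().any().any() or y.isna().any().any():
        raise InputError("NaN values in input matrices")
    x_center = x.mean(axis=0)
    x_scale = x.std(axis=0, ddof=1) if standardize_x else pd.Series(1.0, index=x.columns)
    x_scale = x_scale.replace(0.0, 1.0)
    y_center = y.mean(axis=0)
    y_scale = y.std(axis=0, ddof=1) if scale_y else pd.Series(1.0, index=y.columns)
    y_scale = y_scale.replace(0.0, 1.0)
    xc = ((x - x_center) / x_scale).to_numpy(dtype=float)
    yc = ((y - y_center) / y_scale).to_numpy(dtype=float)
    return xc, yc, x_center, x_scale, y_center, y_scale


def fit_rcca(
    x: pd.DataFrame,
    y: pd.DataFrame,
    l1: float = 0.0,
    l2: float = 0.0,
    n_components: int | None = None,
    standardize_x: bool = True,
    scale_y: bool = False,
) -> CcaModel:
    """Fit regularized CCA between aligned X (n×p) and Y (n×q).

    X columns are standardized by default (descriptor scales are
    heterogeneous); Y is centered only (activations are already bounded).
    """
    if l1 < 0 or l2 < 0:
        raise ParameterError("ridge penalties must be non-negative")
    p, q = x.shape[1], y.shape[1]
    if n_components is None:
        n_components = min(p, q)
    if n_components > min(p, q):
        raise ParameterError("n_components exceeds min(p, q)")
    xc, yc, x_center, x_scale, y_center, y_scale = _prepare(x, y, standardize_x, scale_y)
    w, v, corr = _fit_core(xc, yc, l1, l2, n_components)
    comp_cols = [f"comp{s + 1:02d}" for s in range(n_components)]
    model = CcaModel(
        chem_weights=pd.DataFrame(w, index=x.columns, columns=comp_cols),
        bio_weights=pd.DataFrame(v, index=y.columns, columns=comp_cols),
        correlations=corr,
        chem_variates=pd.DataFrame(xc @ w, index=x.index, columns=comp_cols),
        bio_variates=pd.DataFrame(yc @ v, index=y.index, columns=comp_cols),
        l1=float(l1),
        l2=float(l2),
        x_center=x_center,
        x_scale=x_scale,
        y_center=y_center,
        y_scale=y_scale,
    )
    return model


def project(
    model: CcaModel, x_new: pd.DataFrame | None = None, y_new: pd.DataFrame | None = None
) -> tuple[pd.DataFrame | None, pd.DataFrame | None]:
    """Project new compounds onto the fitted components using stored scaling."""
    chem = bio = None
    if x_new is not None:
        if list(x_new.columns) != list(model.chem_weights.index):
            raise InputError("descriptor names do not match the fitted model")
        xc = ((x_new - model.x_center) / model.x_scale).to_numpy(dtype=float)
        chem = pd.DataFrame(
            xc @ model.chem_weights.to_numpy(), index=x_new.index, columns=model.chem_weights.columns
        )
    if y_new is not None:
        if list(y_new.columns) != list(model.bio_weights.index):
            raise InputError("gene-set names do not match the fitted model")
        yc = ((y_new - model.y_center) / model.y_scale).to_numpy(dtype=float)
        bio = pd.DataFrame(
            yc @ model.bio_weights.to_numpy(), index=y_new.index, columns=model.bio_weights.columns
        )
    return chem, bio


def _fused(chem: pd.DataFrame, bio: pd.DataFrame) -> pd.DataFrame:
    fused = pd.concat(
        [chem.add_prefix("chem_"), bio.add_prefix("bio_")], axis=1
    )
    return fused


def select_regularization(
    x: pd.DataFrame,
    y: pd.DataFrame,
    grid: list[tuple[float, float]],
    folds: int,
    annotations,
    seed: int,
    n_components: int | None = None,
    k_retrieval: int = 10,
) -> tuple[float, float, pd.DataFrame]:
    """Pick (l1, l2) by cross-validated retrieval performance.

    For each grid point and fold, the model is fitted on the training
    compounds, everything is projected into the fused (chem ⊕ bio) component
    space, and mean average precision at ``k_retrieval`` is computed over the
    held-out annotated queries; the grid point with the highest fold-averaged
    MAP wins, ties going to the smaller l1 then smaller l2.
    """
    if folds < 2:
        raise ParameterError("folds must be >= 2")
    if not grid:
        raise ParameterError("empty regularization grid")
    n = len(x)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_ids = [perm[i::folds] for i in range(folds)]
    labeled = set(annotations.labeled_compounds())
    grid_sorted = sorted({(float(a), float(b)) for a, b in grid})
    records = []
    for l1, l2 in grid_sorted:
        fold_scores = []
        for held in fold_ids:
            test_mask = np.zeros(n, dtype=bool)
            test_mask[held] = True
            model = fit_rcca(
                x.iloc[~test_mask], y.iloc[~test_mask], l1=l1, l2=l2, n_components=n_components
            )
            chem, bio = project(model, x, y)
            fused = _fused(chem, bio)
            queries = [c for c in x.index[test_mask] if c in labeled]
            if not queries:
                continue
            sim, _ = _retrieval.similarity_matrix(fused)
            aps = []
            for qid in queries:
                relevant = annotations.relevant_for(qid, set(x.index))
                if not relevant:
                    continue
                ranking = _retrieval.rank_candidates(sim, qid)
                aps.append(
                    _retrieval.average_precision(ranking, relevant, min(k_retrieval, len(ranking)))
                )
            if aps:
                fold_scores.append(float(np.mean(aps)))
        score = float(np.mean(fold_scores)) if fold_scores else float("nan")
        records.append({"l1": l1, "l2": l2, "map": score})
    table = pd.DataFrame(records)
    valid = table.dropna(subset=["map"])
    if valid.empty:
        raise InputError("no annotated compounds available for CV scoring")
    best_score = valid["map"].max()
    top = valid[valid["map"] == best_score].sort_values(["l1", "l2"]).iloc[0]
    return float(top["l1"]), float(top["l2"]), table


def permutation_significance(
    x: pd.DataFrame,
    y: pd.DataFrame,
    l1: float,
    l2: float,
    n_components: int,
    n_perm: int = 1000,
    seed: int = 0,
    standardize_x: bool = True,
    scale_y: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-values per component.

    Rows of Y are permuted uniformly at random (breaking the compound pairing),
    the model is refitted with the same penalties, and each component's
    correlation is recorded.  Returns (p, p_raw) where
    p_s = (1 + #{perm ≥ observed}) / (n_perm + 1) and p_raw is the plain
    proportion of permuted correlations at or above the observed one.
    """
    if n_perm < 19:
        raise ParameterError("n_perm must be >= 19")
    xc, yc, *_ = _prepare(x, y, standardize_x, scale_y)
    _, _, observed = _fit_core(xc, yc, l1, l2, n_components)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_components)
    for _ in range(n_perm):
        perm = rng.permutation(len(yc))
        _, _, corr = _fit_core(xc, yc[perm], l1, l2, n_components)
        exceed += corr >= observed
    p = (1.0 + exceed) / (n_perm + 1.0)
    return p, exceed / n_perm


def split_subcomponents(model: CcaModel, side: str = "mean") -> ComponentSplit:
    """Split each component's compounds into A (positive score) and B (negative).

    ``side`` selects the score: the chemical variate, the biological variate,
    or their mean (default).  Compounds with exactly zero score join neither.
    """
    if side not in {"chem", "bio", "mean"}:
        raise ParameterError("side must be chem, bio or mean")
    if side == "chem":
        scores = model.chem_variates
    elif side == "bio":
        scores = model.bio_variates
    else:
        scores = (model.chem_variates + model.bio_variates) / 2.0
    split = ComponentSplit(scores=scores)
    for col in scores.columns:
        s = scores[col]
        split.members_a.append(list(s.index[s > 0]))
        split.members_b.append(list(s.index[s < 0]))
    return split


def retained_components(
    model: CcaModel, p_threshold: float = 0.05, top: int = 10
) -> list[int]:
    """Components kept for reporting: permutation p < threshold, then the top
    ``top`` by canonical correlation (components are already correlation-ordered)."""
    if model.perm_pvalues is None:
        raise InputError("model has no permutation p-values; run permutation_significance")
    sig = [s for s in range(model.n_components) if model.perm_pvalues[s] < p_threshold]
    return sig[:top]
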