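"""Per-component summaries: top gene sets and compounds, moderated-t gene
lists, term over-representation, component-pair similarity, and
target-enrichment resampling.

The association between a gene set and a component is the Pearson correlation
of the set's activation column with the component's biological canonical
variate.  Differentially expressed genes are the candidates drawn from the top
positively and negatively associated sets, tested across the subcomponent's
most active compounds with a variance-moderated one-sample t statistic
(Cyber-T-style: the per-gene variance is shrunk toward a background variance
pooled from genes of similar mean response).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import InputError, ParameterError
from .rcca import CcaModel, ComponentSplit
from .retrieval import AnnotationSet

__all__ = [
    "SubcomponentReport",
    "top_gene_sets",
    "top_compounds",
    "regularized_t",
    "windowed_background_variance",
    "component_de_genes",
    "term_enrichment",
    "tanimoto",
    "subcomponent_similarity",
    "target_enrichment",
    "eye_diagram_table",
]

DEFAULT_PRIOR_DF = 10.0
BACKGROUND_WINDOW = 101


@dataclass
class SubcomponentReport:
    component: int  # 0-based component index
    side: str  # "A" or "B"
    top_compounds: list[tuple[str, float]] = field(default_factory=list)
    top_gene_sets: list[tuple[str, float]] = field(default_factory=list)
    significant_genes: pd.DataFrame | None = None  # index gene; columns t, p
    term_enrichment: list[tuple[str, float]] = field(default_factory=list)
    target_enrichment: tuple[list[str], int, float] | None = None

    @property
    def label(self) -> str:
        return f"{self.component + 1}{self.side}"

    def top_genes(self, k: int = 30) -> list[str]:
        if self.significant_genes is None:
            return []
        return list(self.significant_genes.index[:k])


def top_gene_sets(
    model: CcaModel, y: pd.DataFrame, component: int, k: int = 10
) -> list[tuple[str, float]]:
    """Gene sets ranked by |correlation| with the component's biological variate."""
    variate = model.bio_variates.iloc[:, component].to_numpy()
    assoc = {}
    for name in y.columns:
        col = y[name].to_numpy(dtype=float)
        if col.std() == 0 or variate.std() == 0:
            assoc[name] = 0.0
        else:
            assoc[name] = float(np.corrcoef(col, variate)[0, 1])
    ranked = sorted(assoc, key=lambda n: (-abs(assoc[n]), n))
    return [(n, assoc[n]) for n in ranked[:k]]


def top_compounds(split: ComponentSplit, component: int, side: str, k: int = 20) -> list[tuple[str, float]]:
    """The side's compounds ranked by |canonical score|, at most k."""
    members = split.side(component, side)
    scores = split.scores.iloc[:, component]
    ranked = sorted(members, key=lambda c: (-abs(scores[c]), c))
    return [(c, float(scores[c])) for c in ranked[:k]]


def regularized_t(
    values: np.ndarray, background_var: float | np.ndarray, prior_df: float
) -> tuple[np.ndarray, np.ndarray]:
    """Variance-moderated one-sample t test of zero mean.

    values: (..., n) response samples per gene.  The moderated variance is
    s̃² = (prior_df·σ₀² + (n−1)·s²) / (prior_df + n − 1) with
    df = prior_df + n − 1, so prior_df = 0 recovers the ordinary Student t
    exactly and large prior_df defers to the background variance σ₀²
    (estimated from genes of similar mean expression).
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[-1]
    if n < 2:
        raise InputError("need at least 2 samples per gene")
    if prior_df < 0:
        raise ParameterError("prior_df must be non-negative")
    if prior_df + n - 2 <= 0:
        raise ParameterError("prior_df + n - 2 must be positive")
    mean = values.mean(axis=-1)
    s2 = values.var(axis=-1, ddof=1)
    mod = (prior_df * np.asarray(background_var) + (n - 1) * s2) / (prior_df + n - 1)
    df = prior_df + n - 1
    t = mean / np.sqrt(mod / n)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def windowed_background_variance(values: np.ndarray, window: int = BACKGROUND_WINDOW) -> np.ndarray:
    """Background variance per gene: mean sample variance over a sliding window
    of genes ordered by mean response (window truncated at the edges)."""
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=-1)
    s2 = values.var(axis=-1, ddof=1)
    order = np.argsort(mean, kind="stable")
    s2_sorted = pd.Series(s2[order])
    bg_sorted = s2_sorted.rolling(window, center=True, min_periods=1).mean().to_numpy()
    bg = np.empty_like(bg_sorted)
    bg[order] = bg_sorted
    return bg


def component_de_genes(
    model: CcaModel,
    split: ComponentSplit,
    responses: pd.DataFrame,
    y: pd.DataFrame,
    collection,
    component: int,
    side: str,
    p_threshold: float = 0.05,
    n_top_sets: int = 20,
    n_top_compounds: int = 10,
    prior_df: float = DEFAULT_PRIOR_DF,
) -> pd.DataFrame:
    """Significantly moved genes for one subcomponent.

    Candidates are the genes of the top ``n_top_sets`` positively and top
    ``n_top_sets`` negatively associated gene sets; each candidate is tested
    across the subcomponent's ``n_top_compounds`` most active compounds'
    responses and kept at p < ``p_threshold``, ranked by p.
    """
    variate = model.bio_variates.iloc[:, component].to_numpy()
    assoc = {}
    for name in y.columns:
        col = y[name].to_numpy(dtype=float)
        assoc[name] = 0.0 if col.std() == 0 else float(np.corrcoef(col, variate)[0, 1])
    pos = sorted((n for n in assoc if assoc[n] > 0), key=lambda n: (-assoc[n], n))[:n_top_sets]
    neg = sorted((n for n in assoc if assoc[n] < 0), key=lambda n: (assoc[n], n))[:n_top_sets]
    candidates = sorted(
        {g for name in (*pos, *neg) for g in collection.sets[name] if g in responses.columns}
    )
    chosen = [c for c, _ in top_compounds(split, component, side, k=n_top_compounds)]
    if len(chosen) < n_top_compounds:
        warnings.warn(
            f"subcomponent {component + 1}{side} has only {len(chosen)} compounds; using all",
            stacklevel=2,
        )
    if len(chosen) < 2 or not candidates:
        return pd.DataFrame(columns=["t", "p"])
    block = responses.loc[chosen]
    bg_all = windowed_background_variance(block.to_numpy().T)
    bg = pd.Series(bg_all, index=responses.columns)
    vals = block[candidates].to_numpy().T  # genes × compounds
    t, p = regularized_t(vals, bg[candidates].to_numpy(), prior_df)
    table = pd.DataFrame({"t": t, "p": p}, index=pd.Index(candidates, name="gene"))
    table = table[table["p"] < p_threshold].sort_values(["p", "gene"], kind="stable")
    return table


def term_enrichment(
    gene_list: list[str], term_collection, universe: list[str]
) -> list[tuple[str, float]]:
    """Hypergeometric upper-tail over-representation p per term, ascending."""
    uni = set(universe)
    genes = set(gene_list)
    if not genes <= uni:
        raise InputError("gene list is not contained in the universe")
    m = len(uni)
    n = len(genes)
    out = []
    for term, members in term_collection.sets.items():
        k_term = len(members & uni)
        overlap = len(members & genes)
        p = 1.0 if overlap == 0 else float(stats.hypergeom.sf(overlap - 1, m, k_term, n))
        out.append((term, p))
    return sorted(out, key=lambda tp: (tp[1], tp[0]))


def tanimoto(a: set[str], b: set[str]) -> float:
    """|a∩b| / |a∪b|; 0 when both sets are empty."""
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def subcomponent_similarity(
    reports: list[SubcomponentReport], n_genes: int = 30, n_compounds: int = 20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Biological (top-gene Tanimoto) and compound-overlap matrices over subcomponents."""
    labels = [r.label for r in reports]
    gsets = {r.label: set(r.top_genes(n_genes)) for r in reports}
    csets = {r.label: {c for c, _ in r.top_compounds[:n_compounds]} for r in reports}
    bio = pd.DataFrame(index=labels, columns=labels, dtype=float)
    overlap = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for a in labels:
        for b in labels:
            bio.loc[a, b] = tanimoto(gsets[a], gsets[b])
            overlap.loc[a, b] = len(csets[a] & csets[b])
    return bio, overlap.astype(int)


def target_enrichment(
    subcomponent_compounds: list[str],
    annotations: AnnotationSet,
    n_draws: int = 1000,
    seed: int = 0,
    statistic: str = "targets",
) -> tuple[list[str], int, float]:
    """Resampling test of target sharing among a subcomponent's compounds.

    statistic="targets": number of labels annotated to ≥2 list compounds;
    statistic="pairs": number of compound pairs sharing ≥1 label.  p is the
    (add-one corrected) fraction of same-size random draws from the annotated
    pool reaching the observed statistic.
    """
    if len(subcomponent_compounds) < 2:
        raise InputError("need at least 2 compounds for target enrichment")
    if statistic not in {"targets", "pairs"}:
        raise ParameterError("statistic must be 'targets' or 'pairs'")
    lm = annotations.label_map()
    pool = sorted(lm)

    def stat(compounds: list[str]) -> tuple[int, list[str]]:
        counts: dict[str, int] = {}
        for c in compounds:
            for lab in lm.get(c, set()):
                counts[lab] = counts.get(lab, 0) + 1
        shared = sorted(lab for lab, n in counts.items() if n >= 2)
        if statistic == "targets":
            return len(shared), shared
        pairs = sum(n * (n - 1) // 2 for n in counts.values())
        return pairs, shared

    observed, shared = stat(subcomponent_compounds)
    rng = np.random.default_rng(seed)
    size = min(len(subcomponent_compounds), len(pool))
    exceed = 0
    for _ in range(n_draws):
        draw = [pool[i] for i in rng.choice(len(pool), size=size, replace=False)]
        if stat(draw)[0] >= observed:
            exceed += 1
    p = (1.0 + exceed) / (n_draws + 1.0)
    return shared, observed, p


def eye_diagram_table(
    model: CcaModel,
    split: ComponentSplit,
    y: pd.DataFrame,
    x: pd.DataFrame,
    k_sets: int = 10,
    components: list[int] | None = None,
) -> pd.DataFrame:
    """Long-format association table behind the component "eye diagram".

    One row per (component, element): all descriptors get subcomponent-specific
    weights (mean standardized descriptor value over the side's members) and
    the top ``k_sets`` gene sets get overall component weights (correlation
    with the biological variate, side recorded as "both").
    """
    if components is None:
        components = list(range(model.n_components))
    x_std = (x - model.x_center) / model.x_scale
    rows = []
    for s in components:
        comp_label = s + 1
        for side in ("A", "B"):
            members = split.side(s, side)
            if not members:
                continue
            means = x_std.loc[members].mean(axis=0)
            for desc in x.columns:
                rows.append(
                    {
                        "component": comp_label,
                        "side": side,
                        "kind": "descriptor",
                        "element": desc,
                        "weight": float(means[desc]),
                    }
                )
        for name, weight in top_gene_sets(model, y, s, k=k_sets):
            rows.append(
                {
                    "component": comp_label,
                    "side": "both",
                    "kind": "gene-set",
                    "element": name,
                    "weight": weight,
                }
            )
    return pd.DataFrame(rows, columns=["component", "side", "kind", "element", "weight"])
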