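"""Retrieval-based quantitative validation of drug representations.

Each annotated compound is used in turn as a query; the remaining compounds
are ranked by Pearson-correlation similarity of their representation vectors,
and average precision of retrieving functionally similar compounds (sharing at
least one annotation label) is computed at a range of list depths.  Mean
average precision (MAP) curves let representations — raw chemical descriptors,
gene-set activations, gene-level responses, and the fused CCA component space
— be compared on equal footing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import InputError, ParameterError

__all__ = [
    "AnnotationSet",
    "RetrievalCurve",
    "similarity_matrix",
    "rank_candidates",
    "average_precision",
    "map_curve",
    "expected_random_ap",
    "random_baseline_map",
    "compare_spaces",
    "DEFAULT_KS",
]

DEFAULT_KS = tuple(range(5, 101, 5))


@dataclass(frozen=True)
class AnnotationSet:
    """Compound → functional-label relation (targets and/or class codes)."""

    pairs: pd.DataFrame  # columns: compound_id, label_id, kind

    def __post_init__(self):
        if self.pairs.duplicated(["compound_id", "label_id"]).any():
            raise InputError("duplicate (compound, label) pairs")

    def labels_for(self, compound: str) -> set[str]:
        sel = self.pairs["compound_id"] == compound
        return set(self.pairs.loc[sel, "label_id"])

    def label_map(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for cid, lid in zip(self.pairs["compound_id"], self.pairs["label_id"]):
            out.setdefault(cid, set()).add(lid)
        return out

    def labeled_compounds(self) -> list[str]:
        return sorted(set(self.pairs["compound_id"]))

    def relevant_for(
        self, query: str, pool: set[str], _label_map: dict[str, set[str]] | None = None
    ) -> set[str]:
        """Compounds in `pool` (query excluded) sharing ≥1 label with the query."""
        lm = self.label_map() if _label_map is None else _label_map
        labels = lm.get(query, set())
        if not labels:
            return set()
        return {c for c in pool if c != query and lm.get(c, set()) & labels}


@dataclass
class RetrievalCurve:
    space: str
    ks: tuple[int, ...]
    map_values: np.ndarray
    sem_values: np.ndarray
    n_queries: int


def similarity_matrix(representation: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pearson-correlation similarity between compounds' representation rows.

    Returns the symmetric unit-diagonal matrix and the ids of any
    zero-variance rows, whose similarity to every other compound is set to 0.
    """
    if representation.shape[0] < 2 or representation.shape[1] < 2:
        raise ParameterError("need at least 2 compounds and 2 features")
    vals = representation.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    flat = sd == 0
    safe = vals.copy()
    safe[flat] = np.random.default_rng(0).standard_normal(vals.shape[1])  # placeholder rows
    sim = np.corrcoef(safe)
    sim[flat, :] = 0.0
    sim[:, flat] = 0.0
    np.fill_diagonal(sim, 1.0)
    ids = representation.index
    return pd.DataFrame(sim, index=ids, columns=ids), list(ids[flat])


def rank_candidates(sim: pd.DataFrame, query: str) -> list[str]:
    """Candidates ordered by decreasing similarity to the query, ties by id."""
    s = sim.loc[query].drop(index=query)
    ids = np.asarray(s.index, dtype=object)
    order = np.lexsort((ids, -s.to_numpy()))
    return list(ids[order])


def _ap_at_ks(relevant_mask: np.ndarray, ks: tuple[int, ...]) -> np.ndarray:
    """AP at several depths for one ranked relevance mask (single pass)."""
    positions = np.nonzero(relevant_mask)[0]
    if positions.size == 0:
        return np.zeros(len(ks))
    prec = np.arange(1, positions.size + 1) / (positions + 1)
    cumprec = np.concatenate([[0.0], np.cumsum(prec)])
    out = np.empty(len(ks))
    for i, k in enumerate(ks):
        h = int(np.searchsorted(positions, k, side="left"))
        out[i] = cumprec[h] / h if h else 0.0
    return out


def average_precision(ranking: list[str], relevant: set[str], k: int) -> float:
    """AP@k: mean precision at the relevant hits within the top k; 0 if no hit."""
    if not relevant:
        raise InputError("empty relevant set; query should have been skipped upstream")
    if k > len(ranking):
        raise ParameterError("k exceeds ranking length")
    mask = np.fromiter((item in relevant for item in ranking), dtype=bool, count=len(ranking))
    return float(_ap_at_ks(mask, (k,))[0])


def map_curve(
    sim: pd.DataFrame,
    annotations: AnnotationSet,
    ks: tuple[int, ...] = DEFAULT_KS,
    space: str = "",
) -> RetrievalCurve:
    """Mean average precision (± SEM over queries) as a function of list depth.

    Queries are the compounds with at least one label shared with another
    compound in the matrix; relevance = sharing ≥1 label.
    """
    if list(ks) != sorted(set(ks)):
        raise ParameterError("ks must be strictly increasing")
    pool = set(sim.index)
    queries = []
    relevants = {}
    lm = annotations.label_map()
    for cid in annotations.labeled_compounds():
        if cid not in pool:
            continue
        rel = annotations.relevant_for(cid, pool, _label_map=lm)
        if rel:
            queries.append(cid)
            relevants[cid] = rel
    if not queries:
        raise InputError("no annotated compounds with shared labels to query")
    ids = np.asarray(sim.index, dtype=object)
    sim_vals = sim.to_numpy()
    id_pos = {c: i for i, c in enumerate(ids)}
    ks_eff = tuple(min(k, len(ids) - 1) for k in ks)
    ap = np.zeros((len(queries), len(ks)))
    for qi, qid in enumerate(queries):
        qpos = id_pos[qid]
        keep = np.ones(len(ids), dtype=bool)
        keep[qpos] = False
        cand_ids = ids[keep]
        order = np.lexsort((cand_ids, -sim_vals[qpos, keep]))
        rel = relevants[qid]
        mask = np.fromiter((c in rel for c in cand_ids[order]), dtype=bool, count=len(cand_ids))
        ap[qi] = _ap_at_ks(mask, ks_eff)
    return RetrievalCurve(
        space=space,
        ks=tuple(ks),
        map_values=ap.mean(axis=0),
        sem_values=ap.std(axis=0, ddof=1) / np.sqrt(len(queries)),
        n_queries=len(queries),
    )


def expected_random_ap(n_candidates: int, n_relevant: int, k: int) -> float:
    """Exact expected AP@k of a uniformly random ranking.

    The number of relevant items H among the top k is hypergeometric; given
    H = h, hit positions are a uniform h-subset of the k slots, so the
    expected mean precision has the closed form used here.
    """
    k = min(k, n_candidates)
    if n_relevant == 0:
        return 0.0
    hmax = min(k, n_relevant)
    h = np.arange(1, hmax + 1)
    ph = hypergeom.pmf(h, n_candidates, n_relevant, k)
    i = np.arange(1, k + 1)
    if k == 1:
        cond = np.ones_like(h, dtype=float)
    else:
        # E[mean precision | h hits]: hits are a uniform h-subset of k slots
        inv_i = np.sum(1.0 / i)
        frac = np.sum((i - 1) / i)
        cond = (inv_i + (h - 1) * frac / (k - 1)) / k
    return float(np.sum(ph * cond))


def random_baseline_map(
    sim_index: list[str], annotations: AnnotationSet, ks: tuple[int, ...] = DEFAULT_KS
) -> np.ndarray:
    """Analytic MAP of a random ranking, averaged over the same query set."""
    pool = set(sim_index)
    rows = []
    cache: dict[tuple[int, int], list[float]] = {}
    lm = annotations.label_map()
    for cid in annotations.labeled_compounds():
        if cid not in pool:
            continue
        rel = annotations.relevant_for(cid, pool, _label_map=lm)
        if rel:
            key = (len(pool) - 1, len(rel))
            if key not in cache:
                cache[key] = [expected_random_ap(*key, k) for k in ks]
            rows.append(cache[key])
    if not rows:
        raise InputError("no annotated compounds with shared labels")
    return np.asarray(rows).mean(axis=0)


def compare_spaces(
    x: pd.DataFrame,
    y_genesets: pd.DataFrame,
    y_genes: pd.DataFrame | None,
    model,
    annotations: AnnotationSet,
    ks: tuple[int, ...] = DEFAULT_KS,
    retained: list[int] | None = None,
) -> list[RetrievalCurve]:
    """MAP curves for the fused CCA space and each raw representation.

    The CCA representation concatenates chemical and biological variates of
    the retained components (all components when ``retained`` is None).
    """
    if retained is None:
        cols = list(model.chem_variates.columns)
    else:
        cols = [model.chem_variates.columns[s] for s in retained]
    fused = pd.concat(
        [model.chem_variates[cols].add_prefix("chem_"), model.bio_variates[cols].add_prefix("bio_")],
        axis=1,
    )
    spaces = [("cca", fused), ("chemical", x), ("gene_set", y_genesets)]
    if y_genes is not None:
        spaces.append(("gene", y_genes))
    curves = []
    for name, rep in spaces:
        sim, _ = similarity_matrix(rep)
        curves.append(map_curve(sim, annotations, ks=ks, space=name))
    return curves
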