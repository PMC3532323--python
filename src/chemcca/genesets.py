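"""Signed gene-set activation profiles from gene-level drug responses.

A compound's differential-expression profile is summarized per gene set with a
weighted Kolmogorov–Smirnov running-sum enrichment score (the standard GSEA
statistic with gene-permutation nulls), converted to an FDR q-value across the
collection, and finally mapped to a signed activation ``sign × (1 − q)`` in
[−1, 1]: +1 is the strongest positive activation, −1 the strongest negative
one, and 0 means no evidence of coordinated movement.

The scorer is deliberately simple and fully documented here; it is pluggable —
``build_activation_matrix`` accepts any per-compound table of (es, q), so
q-values computed by an external enrichment tool can be substituted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import InputError, ParameterError

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "enrichment_scores",
    "signed_activation",
    "build_activation_matrix",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets over a common gene universe."""

    sets: dict[str, frozenset[str]]
    universe: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.universe:
            object.__setattr__(
                self, "universe", sorted({g for s in self.sets.values() for g in s})
            )

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def restricted_to(self, genes: list[str]) -> "GeneSetCollection":
        """Intersect every set with `genes`; drop (with a warning) emptied sets."""
        gene_set = set(genes)
        kept: dict[str, frozenset[str]] = {}
        dropped = []
        for name, members in self.sets.items():
            inter = members & gene_set
            if inter:
                kept[name] = frozenset(inter)
            else:
                dropped.append(name)
        if dropped:
            warnings.warn(
                f"dropped {len(dropped)} gene set(s) disjoint from the universe: "
                + ", ".join(sorted(dropped)[:5]),
                stacklevel=2,
            )
        return GeneSetCollection(sets=kept, universe=sorted(gene_set))


@dataclass
class EnrichmentResult:
    """Per-set enrichment for one compound: signed ES, permutation p, FDR q."""

    table: pd.DataFrame  # index: set name; columns: es, p, q, sign

    def __post_init__(self):
        sign = np.where(self.table["es"].to_numpy() < 0, -1, 1)
        self.table["sign"] = sign


def _es_from_positions(positions: np.ndarray, weights: np.ndarray, n_genes: int) -> np.ndarray:
    """Signed extreme of the GSEA running sum for one or many hit-position sets.

    positions: (B, m) int array of 0-based hit ranks, sorted ascending per row.
    weights: (n_genes,) |response|^exponent in ranked order.
    Returns (B,) signed enrichment scores.
    """
    if positions.ndim == 1:
        positions = positions[None, :]
    B, m = positions.shape
    n_miss = n_genes - m
    hit_w = weights[positions]  # (B, m)
    cum_hit = np.cumsum(hit_w, axis=1)
    nr = cum_hit[:, -1:]
    nr = np.where(nr <= 0, 1.0, nr)  # all-zero weights: deviations stay 0
    j = np.arange(1, m + 1)
    # deviation just after the j-th hit and just before it
    miss_after = (positions + 1 - j) / max(n_miss, 1)
    dev_after = cum_hit / nr - miss_after
    cum_before = np.concatenate([np.zeros((B, 1)), cum_hit[:, :-1]], axis=1)
    miss_before = (positions - (j - 1)) / max(n_miss, 1)
    dev_before = cum_before / nr - miss_before
    pos_ext = dev_after.max(axis=1)
    neg_ext = dev_before.min(axis=1)
    return np.where(pos_ext >= -neg_ext, pos_ext, neg_ext)


def enrichment_scores(
    response: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 200,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> EnrichmentResult:
    """Score every gene set against one ranked response profile.

    Genes are ranked by response (descending, ties broken by gene id); the
    running sum increments by |response|^weight_exponent at set members and
    decrements by the miss fraction elsewhere; ES is the extreme deviation.
    The null is built per set size from ``n_perm`` random same-size gene sets,
    p is the two-sided permutation tail on |ES|, and q is the
    Benjamini–Hochberg FDR across the collection's sets.
    """
    if n_perm < 10:
        raise ParameterError("n_perm must be >= 10")
    missing = [g for g in collection.universe if g not in response.index]
    if missing:
        raise InputError(f"response does not cover the universe (e.g. {missing[0]!r})")
    usable = collection.restricted_to([g for g in response.index])

    order = sorted(response.index, key=lambda g: (-response[g], g))
    ranked = response.loc[order]
    n_genes = len(ranked)
    weights = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    rank_of = {g: i for i, g in enumerate(order)}

    rng = np.random.default_rng(seed)
    null_by_size: dict[int, np.ndarray] = {}
    names, es_vals, p_vals = [], [], []
    for name, members in usable.sets.items():
        pos = np.sort(np.fromiter((rank_of[g] for g in members), dtype=int))
        es = float(_es_from_positions(pos, weights, n_genes)[0])
        m = len(pos)
        if m not in null_by_size:
            draws = np.sort(
                np.stack([rng.choice(n_genes, size=m, replace=False) for _ in range(n_perm)]),
                axis=1,
            )
            null_by_size[m] = _es_from_positions(draws, weights, n_genes)
        null = null_by_size[m]
        p = (1.0 + np.sum(np.abs(null) >= abs(es))) / (n_perm + 1.0)
        names.append(name)
        es_vals.append(es)
        p_vals.append(p)
    q = multipletests(p_vals, method="fdr_bh")[1] if names else np.array([])
    table = pd.DataFrame(
        {"es": es_vals, "p": p_vals, "q": np.clip(q, 0.0, 1.0)}, index=pd.Index(names, name="set")
    )
    return EnrichmentResult(table=table)


def signed_activation(q: float | np.ndarray, sign: int | np.ndarray) -> float | np.ndarray:
    """Map an FDR q-value and direction to the signed activation sign × (1 − q)."""
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr < 0) or np.any(q_arr > 1):
        raise InputError("q-values must lie in [0, 1]")
    out = np.asarray(sign, dtype=float) * (1.0 - q_arr)
    return float(out) if np.isscalar(q) else out


def build_activation_matrix(
    results: dict[str, EnrichmentResult], collection: GeneSetCollection
) -> pd.DataFrame:
    """Assemble compounds × gene-sets signed activations.

    Sets dropped for any compound (emptied by universe intersection) are
    excluded for all compounds so every column is complete.
    """
    if not results:
        raise InputError("no enrichment results supplied")
    common: set[str] | None = None
    for res in results.values():
        names = set(res.table.index)
        common = names if common is None else common & names
    kept = [n for n in collection.names if n in (common or set())]
    if not kept:
        raise InputError("no gene set is shared by all compounds' enrichment results")
    for cid, res in results.items():
        extra = set(res.table.index) - set(collection.names)
        if extra:
            raise InputError(f"compound {cid!r} has sets absent from the collection: {extra}")
    rows = {}
    for cid, res in results.items():
        sub = res.table.loc[kept]
        rows[cid] = signed_activation(sub["q"].to_numpy(), sub["sign"].to_numpy())
    return pd.DataFrame.from_dict(rows, orient="index", columns=kept).sort_index()
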