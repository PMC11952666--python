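"""Gene-set enrichment (ORA and GSEA) and PCA-based sample QC.

* :func:`ora_test` — hypergeometric over-representation of a query id list
  against a named gene-set collection, BH-adjusted across terms;
* :func:`gsea_score` — weighted Kolmogorov-Smirnov running-sum enrichment of
  each set in a score-ranked feature list, with a gene-label permutation
  null, normalized enrichment scores (NES) and permutation p-values;
* :func:`pca_outlier_screen` — flags samples far from their group centroid
  in the PC1-PC2 plane.

Gene sets are read from / written to standard GMT (set name, description,
tab-separated members).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .diffabund import InputError, bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named sets of feature ids plus the scorable universe."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [name for name, members in self.sets.items() if not members]
        if empty:
            warnings.warn(f"dropping {len(empty)} empty gene sets")
            for name in empty:
                self.sets.pop(name)
                self.descriptions.pop(name, None)

    def __len__(self) -> int:
        return len(self.sets)

    def restricted_to(self, universe: set[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            sets={n: s & universe for n, s in self.sets.items()},
            descriptions=dict(self.descriptions),
        )


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            name, description, members = parts[0], parts[1], parts[2:]
            sets[name] = {m for m in members if m}
            desc[name] = description
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = sorted(collection.sets[name])
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + members) + "\n")


def apply_id_mapping(ids: Sequence[str], mapping: pd.DataFrame) -> list[str]:
    """Translate feature ids through an optional two-column mapping table
    (from, to); ids without a mapping are dropped with a logged count."""
    lut = dict(zip(mapping.iloc[:, 0], mapping.iloc[:, 1]))
    out = [lut[i] for i in ids if i in lut]
    n_lost = len(ids) - len(out)
    if n_lost:
        logger.info("apply_id_mapping: %d ids had no mapping", n_lost)
    return out


# ---------------------------------------------------------------------------
# over-representation (hypergeometric)
# ---------------------------------------------------------------------------

def ora_test(
    query: Sequence[str],
    collection: GeneSetCollection,
    universe: Sequence[str],
    p_cut: Optional[float] = None,
    q_cut: Optional[float] = None,
) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation per term.

    p = P(X >= k) with population N = |universe|, K = |set ∩ universe|,
    draws n = |query|, successes k = |query ∩ set|. Query ids outside the
    universe are dropped with a logged count. Results are BH-adjusted and
    sorted by p ascending (ties by term name); pass ``p_cut`` / ``q_cut``
    to keep only terms under those cutoffs.
    """
    uni = set(universe)
    if not uni:
        raise InputError("universe is empty")
    q_in = [x for x in dict.fromkeys(query) if x in uni]
    n_dropped = len(set(query)) - len(q_in)
    if n_dropped:
        logger.info("ora_test: dropped %d query ids outside the universe",
                    n_dropped)
    if not q_in:
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p", "q_bh"]
                            ).set_index("term")
    qset = set(q_in)
    N, n = len(uni), len(qset)
    rows = []
    for term in sorted(collection.sets):
        members = collection.sets[term] & uni
        K = len(members)
        if K == 0:
            continue
        k = len(qset & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"]
                       ).set_index("term")
    out["q_bh"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values(["p", "term"], kind="mergesort")
    if p_cut is not None:
        out = out[out["p"] < p_cut]
    if q_cut is not None:
        out = out[out["q_bh"] < q_cut]
    return out


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

def _enrichment_score(in_set: np.ndarray, weights: np.ndarray) -> float:
    """Signed max deviation of the weighted KS running sum.

    ``in_set`` is a boolean mask over the ranked list (descending scores),
    ``weights`` = |score| of each ranked feature.
    """
    n = in_set.size
    n_hit = int(in_set.sum())
    if n_hit == 0 or n_hit == n:
        return 0.0
    w_hit = np.where(in_set, weights, 0.0)
    total = w_hit.sum()
    if total <= 0:  # all member scores are zero: fall back to unweighted
        w_hit = in_set.astype(float)
        total = w_hit.sum()
    p_hit = np.cumsum(w_hit) / total
    p_miss = np.cumsum(~in_set) / (n - n_hit)
    dev = p_hit - p_miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i])


def gsea_score(
    ranking: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 200,
    seed: int = 0,
    min_size: int = 10,
    max_size: int = 500,
) -> pd.DataFrame:
    """Weighted KS enrichment of each set in a score-ranked feature list.

    ``ranking`` maps feature id -> ranking score (e.g. signed log2FC or t);
    features are ordered by score descending. The null distribution comes
    from ``n_perm`` seeded gene-label permutations (random same-size member
    sets); NES = ES / mean |null ES| over same-sign nulls; the permutation
    p-value counts same-sign nulls at least as extreme, with denominator
    n_perm + 1. BH adjustment across the tested sets.
    """
    scores = ranking.astype(float)
    if not np.isfinite(scores.to_numpy()).all():
        raise InputError("ranking scores must be finite")
    order = scores.sort_values(ascending=False, kind="mergesort")
    ids = order.index.to_numpy()
    weights = np.abs(order.to_numpy())
    pos = {f: i for i, f in enumerate(ids)}
    rng = np.random.default_rng(seed)
    n = len(ids)

    rows = []
    for term in sorted(collection.sets):
        members = [m for m in collection.sets[term] if m in pos]
        size = len(members)
        if size < min_size or size > max_size:
            logger.info("gsea_score: skipping %s (size %d outside [%d, %d])",
                        term, size, min_size, max_size)
            continue
        in_set = np.zeros(n, dtype=bool)
        in_set[[pos[m] for m in members]] = True
        es = _enrichment_score(in_set, weights)

        null_es = np.empty(n_perm)
        mask = np.zeros(n, dtype=bool)
        for b in range(n_perm):
            mask[:] = False
            mask[rng.choice(n, size=size, replace=False)] = True
            null_es[b] = _enrichment_score(mask, weights)
        same_sign = null_es * np.sign(es) > 0 if es != 0 else np.ones(n_perm, bool)
        denom_mean = np.abs(null_es[same_sign]).mean() if same_sign.any() else np.nan
        nes = es / denom_mean if denom_mean and np.isfinite(denom_mean) else np.nan
        n_extreme = int((same_sign & (np.abs(null_es) >= abs(es))).sum())
        p = (1 + n_extreme) / (n_perm + 1)
        rows.append((term, size, es, nes, p))

    out = pd.DataFrame(rows, columns=["term", "size", "ES", "NES", "p"]
                       ).set_index("term")
    out["q_bh"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["p", "term"], kind="mergesort")


# ---------------------------------------------------------------------------
# PCA sample screening
# ---------------------------------------------------------------------------

def pca_outlier_screen(
    matrix: pd.DataFrame,
    groups: Sequence[str] | pd.Series,
    k_sd: float = 3.0,
) -> pd.DataFrame:
    """Flag samples far from their group centroid in the PC1-PC2 plane.

    Features are standardized, samples are projected on the first two
    principal components, and a sample is flagged when its distance to its
    group centroid (coordinate-wise median, so one outlier cannot drag it)
    exceeds ``k_sd`` times the median within-group centroid distance.
    Groups with fewer than 3 samples are skipped with a warning. Flags are
    reported; removal is the caller's decision.
    """
    groups = pd.Series(np.asarray(groups), index=matrix.columns)
    x = matrix.to_numpy(float)
    sd = x.std(axis=1, ddof=1)
    x = x[sd > 0]
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    n_comp = min(2, z.shape[1], z.shape[0])
    coords = PCA(n_components=n_comp, svd_solver="full").fit_transform(z.T)
    if coords.shape[1] < 2:
        coords = np.column_stack([coords, np.zeros(len(coords))])

    out = pd.DataFrame({"group": groups.to_numpy(),
                        "pc1": coords[:, 0], "pc2": coords[:, 1]},
                       index=matrix.columns)
    out["dist"] = np.nan
    out["flagged"] = False
    for g in groups.unique():
        idx = out.index[out["group"] == g]
        if len(idx) < 3:
            warnings.warn(f"pca_outlier_screen: group {g!r} has fewer than 3 "
                          "samples; skipped")
            continue
        pts = out.loc[idx, ["pc1", "pc2"]].to_numpy()
        centroid = np.median(pts, axis=0)
        dist = np.linalg.norm(pts - centroid, axis=1)
        out.loc[idx, "dist"] = dist
        med = np.median(dist)
        if med > 0:
            out.loc[idx, "flagged"] = dist > k_sd * med
    return out
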