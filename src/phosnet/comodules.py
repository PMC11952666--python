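"""Signed weighted co-expression network modules, eigengenes and hubs.

The pipeline mirrors the standard signed WGCNA recipe on a feature x sample
log2 matrix:

* soft-threshold selection: the smallest power whose signed scale-free
  topology fit reaches R^2 >= 0.85 while mean connectivity stays below 100
  (with a plateau fallback when no power reaches the target);
* signed adjacency a_ij = ((1 + cor)/2)^beta, so anti-correlated features
  are unconnected;
* signed topological overlap (TOM) similarity and 1 - TOM dissimilarity;
* average-linkage hierarchical clustering with a dendrogram gap cut
  (no PAM-style reassignment, so module membership adheres strictly to the
  tree); clusters below the minimum size stay unassigned (module 0);
* module eigengenes (first principal component across samples, sign-aligned
  with the module mean profile), iterative merging of modules whose
  eigengenes correlate above 1 - merge_cut;
* module-trait Pearson statistics, per-feature module membership (MM),
  peptide significance (PS = correlation with the trait), and hub calling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .diffabund import InputError

logger = logging.getLogger(__name__)


@dataclass
class SoftThresholdScan:
    scan: pd.DataFrame  # power, signed_r2, slope, mean_k
    chosen_power: int
    reached_target: bool
    r2_target: float
    max_mean_k: float


@dataclass
class ModuleSet:
    labels: pd.Series  # feature -> module id (0 = unassigned)
    eigengenes: pd.DataFrame  # module x sample, unit norm
    variance_explained: dict[int, float]
    merge_history: list[tuple[int, int]]

    @property
    def module_ids(self) -> list[int]:
        return [m for m in sorted(self.labels.unique()) if m != 0]

    def sizes(self) -> dict[int, int]:
        return {m: int((self.labels == m).sum()) for m in self.module_ids}


# ---------------------------------------------------------------------------
# correlation and adjacency
# ---------------------------------------------------------------------------

def _feature_correlation(matrix: pd.DataFrame) -> np.ndarray:
    x = matrix.to_numpy(float)
    sd = np.nanstd(x, axis=1, ddof=1)
    if (sd == 0).any():
        raise InputError("zero-variance features must be dropped before "
                         "network construction")
    if np.isnan(x).any():
        # Pearson on complete pairwise observations
        cor = matrix.T.corr(min_periods=2).to_numpy()
    else:
        cor = np.corrcoef(x)
    return np.clip(cor, -1.0, 1.0)


def signed_adjacency(matrix: pd.DataFrame, power: float,
                     cor: Optional[np.ndarray] = None) -> np.ndarray:
    """a_ij = ((1 + cor(x_i, x_j)) / 2)^power with unit diagonal."""
    if power < 1:
        raise InputError("power must be >= 1")
    if cor is None:
        cor = _feature_correlation(matrix)
    a = ((1.0 + cor) / 2.0) ** power
    np.fill_diagonal(a, 1.0)
    return a


def connectivity(adjacency: np.ndarray) -> np.ndarray:
    """k_i = sum_{j != i} a_ij."""
    return adjacency.sum(axis=1) - np.diag(adjacency)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit of a connectivity distribution.

    Bins k into ``n_bins`` equal-width bins, regresses log10(frequency) on
    log10(mean k) over non-empty bins and returns (signed R^2, slope) with
    signed R^2 = -sign(slope) * R^2, so only decreasing degree distributions
    can score highly.
    """
    k = np.asarray(k, float)
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k, freq = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            mean_k.append(k[mask].mean())
            freq.append(mask.sum() / k.size)
    if len(mean_k) < 3:
        return 0.0, 0.0
    lx, ly = np.log10(np.asarray(mean_k)), np.log10(np.asarray(freq))
    if np.ptp(lx) == 0 or np.ptp(ly) == 0:
        return 0.0, 0.0
    res = stats.linregress(lx, ly)
    r2 = float(res.rvalue ** 2)
    slope = float(res.slope)
    return -np.sign(slope) * r2, slope


def pick_soft_threshold(
    matrix: pd.DataFrame,
    powers: Sequence[int] = tuple(range(1, 21)),
    r2_target: float = 0.85,
    max_mean_k: float = 100.0,
) -> SoftThresholdScan:
    """Scan candidate powers and choose the smallest satisfying both rules.

    Chosen power = smallest beta with signed R^2 >= r2_target and mean
    connectivity < max_mean_k. When no power reaches the target, fall back
    to the first power where the R^2 gain over the previous power drops
    below 0.01 (the plateau), with a warning.
    """
    if len(matrix) < 50:
        raise InputError("pick_soft_threshold expects >= 50 features")
    if matrix.shape[1] < 4:
        raise InputError("pick_soft_threshold expects >= 4 samples")
    sd = matrix.std(axis=1, ddof=1)
    if (sd == 0).any():
        logger.warning("pick_soft_threshold: dropping %d constant features",
                       int((sd == 0).sum()))
        matrix = matrix.loc[sd > 0]
    cor = _feature_correlation(matrix)
    base = (1.0 + cor) / 2.0
    np.fill_diagonal(base, 1.0)
    rows = []
    for beta in powers:
        a = base ** beta
        np.fill_diagonal(a, 1.0)
        k = connectivity(a)
        r2, slope = scale_free_fit(k)
        rows.append((int(beta), r2, slope, float(k.mean())))
    scan = pd.DataFrame(rows, columns=["power", "signed_r2", "slope", "mean_k"])

    ok = scan[(scan["signed_r2"] >= r2_target) & (scan["mean_k"] < max_mean_k)]
    if len(ok):
        chosen = int(ok["power"].iloc[0])
        reached = True
    else:
        # fall back to the standard sample-size default for signed networks
        # (the established practice when the fit never reaches the target),
        # restricted to powers that keep the mean connectivity in bounds
        reached = False
        n_samp = matrix.shape[1]
        default = 18 if n_samp < 20 else (16 if n_samp < 30 else 12)
        pool = scan[scan["mean_k"] < max_mean_k]
        if not len(pool):
            pool = scan
        idx = (pool["power"] - default).abs().idxmin()
        chosen = int(pool.loc[idx, "power"])
        warnings.warn(
            f"no power reached signed R^2 >= {r2_target} with mean k < "
            f"{max_mean_k}; falling back to the sample-size default "
            f"power {chosen}")
    return SoftThresholdScan(scan=scan, chosen_power=chosen,
                             reached_target=reached, r2_target=r2_target,
                             max_mean_k=max_mean_k)


# ---------------------------------------------------------------------------
# topological overlap
# ---------------------------------------------------------------------------

def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Signed topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    for i != j, TOM_ii = 1. Requires a symmetric adjacency in [0, 1] with
    unit diagonal.
    """
    a = np.asarray(adjacency, float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-12):
        raise InputError("adjacency must be symmetric")
    if not np.allclose(np.diag(a), 1.0):
        raise InputError("adjacency diagonal must be 1")
    k = connectivity(a)
    # (A @ A)_ij counts u = i and u = j terms, each contributing a_ij
    shared = a @ a - 2.0 * a  # = sum_{u != i,j} a_iu a_uj  (for i != j)
    num = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return tom


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

def _valley_cut(heights: np.ndarray, n_bins: int = 40, smooth: int = 5,
                density_frac: float = 0.25) -> Optional[float]:
    """Adaptive cut height: the midpoint of the widest low-density stretch
    of merge heights.

    Tight branches produce a dense band of low merge heights and the
    unclustered background a dense band of high ones; the widest run of
    height bins whose (smoothed) density falls below ``density_frac`` of
    the maximum separates the two. Returns None when no such run exists
    (no low-density valley, hence no branch structure).
    """
    hist, edges = np.histogram(heights, bins=n_bins)
    kernel = np.ones(smooth) / smooth
    dens = np.convolve(hist, kernel, mode="same")
    low = dens <= density_frac * dens.max()
    best, start = None, None
    for i in range(n_bins + 1):
        is_low = i < n_bins and low[i]
        if is_low and start is None:
            start = i
        elif not is_low and start is not None:
            if best is None or (i - start) > (best[1] - best[0]):
                best = (start, i)
            start = None
    if best is None:
        return None
    return float((edges[best[0]] + edges[best[1]]) / 2.0)


def detect_modules(diss_tom: np.ndarray, min_size: int = 50,
                   index: Optional[pd.Index] = None,
                   method: str = "average") -> pd.Series:
    """Average-linkage clustering of 1 - TOM with an adaptive valley cut.

    The dendrogram is cut at the midpoint of the widest low-density stretch
    of merge heights (see :func:`_valley_cut`): branch-internal merges sit
    below it, background merges above it, so each well-separated branch is
    taken whole. There is no PAM-style reassignment afterwards, so
    assignments adhere strictly to the dendrogram; a branch that gets split
    is rejoined later by eigengene merging. Clusters below ``min_size`` are
    unassigned (module 0); a dendrogram with no density valley (e.g. all
    merge heights identical) leaves everything unassigned.
    """
    d = np.asarray(diss_tom, float)
    if d.min() < -1e-12 or d.max() > 1 + 1e-12:
        raise InputError("dissimilarity must lie in [0, 1]")
    n = d.shape[0]
    if index is None:
        index = pd.RangeIndex(n)
    if min_size > n:
        warnings.warn("min_size exceeds the number of features; "
                      "all features unassigned")
        return pd.Series(0, index=index, name="module")
    link = linkage(squareform(d, checks=False), method=method)
    heights = link[:, 2]
    labels = np.zeros(n, dtype=int)
    if heights.max() - heights.min() <= 1e-12:
        return pd.Series(labels, index=index, name="module")
    cut = _valley_cut(heights)
    if cut is None:
        warnings.warn("no merge-height valley found; all features unassigned")
        return pd.Series(labels, index=index, name="module")
    raw = fcluster(link, t=cut, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    next_id = 1
    for cl in sizes.index:  # descending size; small clusters stay 0
        if sizes[cl] >= min_size:
            labels[raw == cl] = next_id
            next_id += 1
    if next_id == 1:
        warnings.warn("no cluster reached min_size; all features unassigned")
    return pd.Series(labels, index=index, name="module")


# ---------------------------------------------------------------------------
# eigengenes and merging
# ---------------------------------------------------------------------------

def _eigengene(matrix: pd.DataFrame) -> tuple[np.ndarray, float]:
    """First principal component (over samples) of standardized expression,
    sign-aligned with the module mean profile; returns (ME, var explained)."""
    x = matrix.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    if z.shape[0] == 1:
        me = z[0] / np.linalg.norm(z[0])
        return me, 1.0
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    var_expl = float(s[0] ** 2 / (s ** 2).sum())
    mean_profile = z.mean(axis=0)
    if np.dot(me, mean_profile - mean_profile.mean()) < 0:
        me = -me
    return me, var_expl


def eigengenes_and_merge(
    matrix: pd.DataFrame,
    labels: pd.Series,
    merge_cut: float = 0.25,
) -> ModuleSet:
    """Compute module eigengenes and merge modules whose eigengene
    dissimilarity (1 - cor) falls below ``merge_cut``, recomputing after
    every merge."""
    labels = labels.copy()
    merge_history: list[tuple[int, int]] = []

    def compute() -> tuple[pd.DataFrame, dict[int, float]]:
        mes, ve = {}, {}
        for m in sorted(labels.unique()):
            if m == 0:
                continue
            me, v = _eigengene(matrix.loc[labels.index[labels == m]])
            mes[m], ve[m] = me, v
        eg = pd.DataFrame(mes, index=matrix.columns).T
        eg.index.name = "module"
        return eg, ve

    eg, ve = compute()
    while len(eg) > 1:
        cors = np.corrcoef(eg.to_numpy())
        np.fill_diagonal(cors, -np.inf)
        i, j = np.unravel_index(np.argmax(cors), cors.shape)
        if 1.0 - cors[i, j] >= merge_cut:
            break
        a, b = int(eg.index[i]), int(eg.index[j])
        keep, drop = (a, b) if (labels == a).sum() >= (labels == b).sum() else (b, a)
        labels[labels == drop] = keep
        merge_history.append((drop, keep))
        eg, ve = compute()

    # renumber modules 1..K by descending size for stable output
    sizes = labels[labels != 0].value_counts()
    remap = {old: new for new, old in enumerate(sizes.index, start=1)}
    labels = labels.map(lambda m: remap.get(m, 0))
    eg.index = [remap[m] for m in eg.index]
    eg = eg.sort_index()
    ve = {remap[m]: v for m, v in ve.items()}
    return ModuleSet(labels=labels, eigengenes=eg,
                     variance_explained=ve, merge_history=merge_history)


# ---------------------------------------------------------------------------
# trait statistics, membership and hubs
# ---------------------------------------------------------------------------

def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    if n < 4:
        r = float(np.corrcoef(x, y)[0, 1]) if n >= 3 else np.nan
        return r, np.nan
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def module_trait_stats(module_set: ModuleSet, trait: Sequence[float] | pd.Series
                       ) -> pd.DataFrame:
    """Pearson r and two-sided t-distribution p (n - 2 df) between each
    module eigengene and the numeric trait."""
    trait = np.asarray(trait, float)
    if np.std(trait) == 0:
        warnings.warn("trait is constant; module-trait correlation undefined")
    rows = []
    for m in module_set.eigengenes.index:
        me = module_set.eigengenes.loc[m].to_numpy()
        r, p = _pearson_with_p(me, trait)
        rows.append((m, r, p, int((module_set.labels == m).sum())))
    return pd.DataFrame(rows, columns=["module", "r", "p", "size"]
                        ).set_index("module")


def membership_significance_hubs(
    matrix: pd.DataFrame,
    module_set: ModuleSet,
    trait: Sequence[float] | pd.Series,
    mm_cut: float = 0.8,
    ps_cut: float = 0.5,
) -> pd.DataFrame:
    """Per-feature module membership (MM), peptide significance (PS) and hub
    flags.

    MM_i = cor(x_i, eigengene of its own module); PS_i = cor(x_i, trait),
    signed. Hubs are assigned features with MM >= mm_cut and |PS| >= ps_cut,
    ranked by MM * |PS| descending with ties broken by feature id.
    """
    trait = np.asarray(trait, float)
    labels = module_set.labels
    x = matrix.to_numpy(float)
    n = x.shape[1]

    def cor_rows_with(v: np.ndarray) -> np.ndarray:
        vz = v - v.mean()
        v_sd = vz.std()
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = ((x - mu) * vz[None, :]).mean(axis=1) / (sd * v_sd)
        return c

    ps = cor_rows_with(trait) if np.std(trait) > 0 else np.full(len(matrix), np.nan)
    mm = np.full(len(matrix), np.nan)
    for m in module_set.eigengenes.index:
        members = (labels == m).to_numpy()
        if members.any():
            me = module_set.eigengenes.loc[m].to_numpy()
            mm[members] = cor_rows_with(me)[members]

    out = pd.DataFrame({"module": labels.to_numpy(), "MM": mm, "PS": ps},
                       index=matrix.index)
    out["hub"] = (out["module"] != 0) & (out["MM"] >= mm_cut) & \
                 (out["PS"].abs() >= ps_cut)
    out["hub_rank_score"] = np.where(out["hub"], out["MM"] * out["PS"].abs(), np.nan)
    return out


def hub_list(membership: pd.DataFrame) -> list[str]:
    hubs = membership[membership["hub"]].copy()
    hubs = hubs.sort_values(["hub_rank_score"], ascending=False, kind="mergesort")
    # ties broken by feature id: stable sort on id first, then score
    hubs = hubs.loc[hubs.index.sort_values()].sort_values(
        "hub_rank_score", ascending=False, kind="mergesort")
    return hubs.index.tolist()


# ---------------------------------------------------------------------------
# one-call pipeline
# ---------------------------------------------------------------------------

@dataclass
class NetworkAnalysis:
    scan: SoftThresholdScan
    module_set: ModuleSet
    trait_stats: pd.DataFrame
    membership: pd.DataFrame
    hubs: list[str]


def coexpression_analysis(
    matrix: pd.DataFrame,
    trait: Sequence[float] | pd.Series,
    min_size: int = 50,
    merge_cut: float = 0.25,
    powers: Sequence[int] = tuple(range(1, 21)),
    r2_target: float = 0.85,
    max_mean_k: float = 100.0,
    mm_cut: float = 0.8,
    ps_cut: float = 0.5,
    max_missing_frac: float = 0.2,
    power: Optional[int] = None,
) -> NetworkAnalysis:
    """Full signed network analysis: power scan, adjacency, TOM, modules,
    eigengene merging, trait statistics and hub identification.

    Features with more than ``max_missing_frac`` missing values or zero
    variance are excluded from network construction.
    """
    keep = matrix.isna().mean(axis=1) <= max_missing_frac
    matrix = matrix.loc[keep]
    sd = matrix.std(axis=1, ddof=1)
    matrix = matrix.loc[sd > 0]
    scan = pick_soft_threshold(matrix, powers=powers, r2_target=r2_target,
                               max_mean_k=max_mean_k)
    beta = power if power is not None else scan.chosen_power
    adj = signed_adjacency(matrix, beta)
    tom = tom_similarity(adj)
    labels = detect_modules(1.0 - tom, min_size=min_size, index=matrix.index)
    module_set = eigengenes_and_merge(matrix, labels, merge_cut=merge_cut)
    trait_stats = module_trait_stats(module_set, trait)
    membership = membership_significance_hubs(matrix, module_set, trait,
                                              mm_cut=mm_cut, ps_cut=ps_cut)
    return NetworkAnalysis(scan=scan, module_set=module_set,
                           trait_stats=trait_stats, membership=membership,
                           hubs=hub_list(membership))
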