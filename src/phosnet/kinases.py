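"""Kinase-substrate scoring and kinase activity inference.

Implements a PhosR-style workflow on two-group phosphoproteomic data:

* stable-site selection and batch correction anchored on those sites;
* protein-level normalization of phosphosite changes (log-space subtraction
  of the parent protein profile, with significance recomputed on the
  per-sample difference profile);
* per-kinase substrate scores integrating a sequence-motif component (mean
  log-odds against a kinase PSSM, mapped to a percentile) and a dynamics
  component (correlation of the site's standardized profile with the
  centroid of the kinase's annotated substrates), combined geometrically;
* adaptive-sampling positive-unlabeled (PU) learning: known substrates are
  positives, pseudo-negatives are repeatedly drawn from unlabeled sites with
  probability proportional to (1 - combined score), a regularized logistic
  classifier is fit each round, and sampling weights are adapted away from
  sites the ensemble currently scores high;
* kinase activity = mean standardized protein-normalized fold change of the
  kinase's top-N predicted substrates, with a one-sample t-test against 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .diffabund import InputError, bh_adjust, moderated_t
from .simdata import AMINO_ACIDS, CENTER, WINDOW_LEN

logger = logging.getLogger(__name__)

_PU_FEATURES = ("motif_score", "profile_score", "combined")


@dataclass
class KinaseActivity:
    kinase: str
    activity_score: float  # mean z of fc_norm over the substrate set
    p: float  # one-sample t-test vs 0 (NaN when n < 3)
    direction: str  # up | down | unchanged
    n_substrates: int


# ---------------------------------------------------------------------------
# stable sites and batch correction
# ---------------------------------------------------------------------------

def select_stable_sites(matrix: pd.DataFrame, fraction: float = 0.1) -> list[str]:
    """The ``fraction`` of sites with lowest across-sample variance after
    per-sample median centering; used as negative-control anchors."""
    if not 0.0 < fraction <= 1.0:
        raise InputError("fraction must lie in (0, 1]")
    if len(matrix) < 100:
        raise InputError("select_stable_sites expects >= 100 sites")
    centered = matrix - matrix.median(axis=0)
    var = centered.var(axis=1, ddof=1)
    n = max(1, int(round(fraction * len(matrix))))
    if fraction >= 1.0:
        n = len(matrix)
    order = var.sort_values(kind="mergesort")  # stable for ties
    return order.index[:n].tolist()


def batch_correct(
    matrix: pd.DataFrame,
    batches: Sequence | pd.Series,
    stable_sites: Sequence[str],
    center_samples: bool = False,
) -> pd.DataFrame:
    """Remove additive batch offsets estimated on stable sites.

    Offsets are anchored to the first batch (its offset is 0 by definition),
    so a dataset that already has no batch structure is returned unchanged
    and the correction is exactly idempotent. Per-sample median centering is
    available behind ``center_samples`` for matrices that also need
    column-level normalization.
    """
    batches = pd.Series(np.asarray(batches), index=matrix.columns)
    levels = list(pd.unique(batches))
    for b in levels:
        if (batches == b).sum() == 0:
            raise InputError(f"batch {b!r} has zero samples")
    stable = [s for s in stable_sites if s in matrix.index]
    if not stable:
        raise InputError("stable site set is empty (or disjoint from matrix)")
    x = matrix.copy()
    if center_samples:
        x = x - x.median(axis=0)
    if len(levels) < 2:
        return x
    ref_cols = batches.index[batches == levels[0]]
    ref_mean = x.loc[stable, ref_cols].to_numpy().mean()
    for b in levels[1:]:
        cols = batches.index[batches == b]
        offset = x.loc[stable, cols].to_numpy().mean() - ref_mean
        x.loc[:, cols] = x.loc[:, cols] - offset
    return x


# ---------------------------------------------------------------------------
# protein-level normalization
# ---------------------------------------------------------------------------

def site_minus_protein_profiles(
    phospho_matrix: pd.DataFrame,
    protein_matrix: pd.DataFrame,
    site_table: pd.DataFrame,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample (site - parent protein) difference profiles.

    Sites whose parent protein is undetected keep their raw profile; the
    returned boolean mask marks which sites were actually normalized.
    """
    common = [c for c in phospho_matrix.columns if c in protein_matrix.columns]
    if len(common) != len(phospho_matrix.columns):
        raise InputError("phospho and protein matrices must share samples")
    parents = site_table.loc[phospho_matrix.index, "protein_id"]
    has_parent = parents.isin(protein_matrix.index).to_numpy()
    diff = phospho_matrix.copy()
    matched = phospho_matrix.index[has_parent]
    diff.loc[matched] = (
        phospho_matrix.loc[matched].to_numpy()
        - protein_matrix.loc[parents[matched], common].to_numpy()
    )
    return diff, has_parent


def normalize_site_by_protein(
    phospho_matrix: pd.DataFrame,
    protein_matrix: pd.DataFrame,
    site_table: pd.DataFrame,
    groups: Sequence[str] | pd.Series,
) -> pd.DataFrame:
    """Subtract the parent protein profile from each site and re-test.

    ``fc_norm = fc_site - fc_parent`` on the log2 scale; significance is the
    moderated t on the per-sample (site - protein) difference profiles.
    Sites whose parent protein is undetected keep their unnormalized
    statistics and are flagged ``normalized=False``.
    """
    diff, has_parent = site_minus_protein_profiles(
        phospho_matrix, protein_matrix, site_table)
    parents = site_table.loc[phospho_matrix.index, "protein_id"]
    st = moderated_t(diff, groups)
    st = st.rename(columns={"log2fc": "fc_norm"})
    st["normalized"] = has_parent
    st["protein_id"] = parents.to_numpy()
    if (~has_parent).any():
        logger.info("normalize_site_by_protein: %d sites have undetected "
                    "parents and keep unnormalized fold changes",
                    int((~has_parent).sum()))
    return st


# ---------------------------------------------------------------------------
# substrate scoring
# ---------------------------------------------------------------------------

def motif_score(
    windows: Sequence[str],
    pssm: np.ndarray,
    background: Optional[np.ndarray] = None,
) -> pd.Series:
    """Percentile-ranked mean log-odds of each window under a kinase PSSM.

    Raw score = mean over the 15 positions of ``log(p_pos(aa) / q(aa))``;
    unknown residues contribute the background probability (log-odds 0).
    Scores are mapped to (0, 1] as average-rank / n among the supplied
    windows, so the per-position consensus window of the PSSM scores 1.0 in
    any set containing it.
    """
    pssm = np.asarray(pssm, dtype=float)
    if pssm.shape != (WINDOW_LEN, 20):
        raise InputError(f"PSSM must be {WINDOW_LEN}x20")
    q = np.full(20, 1.0 / 20.0) if background is None else np.asarray(background, float)
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    warned = False
    raw = np.empty(len(windows))
    floor = 1e-9  # zero PSSM entries (e.g. non-S/T centre) get a tiny mass
    logp = np.log(np.maximum(pssm, floor)) - np.log(q)
    for w_i, window in enumerate(windows):
        if len(window) != WINDOW_LEN:
            raise InputError(f"window {window!r} is not {WINDOW_LEN} residues")
        total = 0.0
        for pos, ch in enumerate(window):
            j = aa_index.get(ch)
            if j is None:
                if not warned:
                    logger.warning("motif_score: unknown residue %r scored at "
                                   "background probability", ch)
                    warned = True
                continue
            total += logp[pos, j]
        raw[w_i] = total / WINDOW_LEN
    ranks = stats.rankdata(raw, method="average")
    return pd.Series(ranks / len(raw), index=pd.Index(windows, name="window15"),
                     name="motif_score")


def consensus_window(pssm: np.ndarray) -> str:
    """Per-position argmax window of a PSSM (ties broken by alphabet order)."""
    pssm = np.asarray(pssm, float)
    return "".join(AMINO_ACIDS[j] for j in pssm.argmax(axis=1))


def standardize_profiles(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scoring across samples; zero-variance rows become all-zero."""
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    z = matrix.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def kinase_centroid(phospho_matrix: pd.DataFrame, annotated_sites: Sequence[str]
                    ) -> np.ndarray:
    """Standardized mean profile of a kinase's annotated substrates."""
    present = [s for s in annotated_sites if s in phospho_matrix.index]
    if not present:
        raise InputError("no annotated substrates found in the matrix")
    z = standardize_profiles(phospho_matrix.loc[present])
    c = z.mean(axis=0).to_numpy()
    sd = c.std(ddof=1)
    if sd > 0:
        c = (c - c.mean()) / sd
    return c


def profile_score(site_profiles: pd.DataFrame, centroid: np.ndarray) -> pd.Series:
    """(Pearson r + 1) / 2 between standardized site profiles and a centroid.

    Zero-variance site profiles score 0.5 (uninformative)."""
    z = standardize_profiles(site_profiles)
    c = np.asarray(centroid, float)
    c_sd = c.std(ddof=0)
    if c_sd == 0:
        return pd.Series(0.5, index=site_profiles.index, name="profile_score")
    cz = (c - c.mean()) / c_sd
    zm = z.to_numpy()
    sd = zm.std(axis=1, ddof=0)
    mu = zm.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = ((zm - mu[:, None]) * cz[None, :]).mean(axis=1) / np.where(sd > 0, sd, np.nan)
    score = (r + 1.0) / 2.0
    flat = ~np.isfinite(score)
    if flat.any():
        score = np.where(flat, 0.5, score)
    return pd.Series(np.clip(score, 0.0, 1.0), index=site_profiles.index,
                     name="profile_score")


def combined_substrate_score(motif: pd.Series | np.ndarray,
                             profile: pd.Series | np.ndarray,
                             weight: float = 0.5) -> np.ndarray:
    """Weighted geometric combination ``motif**w * profile**(1-w)``; monotone
    in both components, 0 whenever either component is 0 (for w in (0,1))."""
    if not 0.0 <= weight <= 1.0:
        raise InputError("weight must lie in [0, 1]")
    m = np.asarray(motif, float)
    p = np.asarray(profile, float)
    return m ** weight * p ** (1.0 - weight)


def score_substrates(
    phospho_matrix: pd.DataFrame,
    site_table: pd.DataFrame,
    pssms: pd.DataFrame,
    annotation: pd.DataFrame,
    weight: float = 0.5,
) -> pd.DataFrame:
    """Motif, profile and combined scores for every (site, kinase) pair.

    Returns a long DataFrame indexed by site_id with columns kinase,
    motif_score, profile_score, combined, annotated."""
    from .simdata import pssm_for

    sites = phospho_matrix.index
    windows = site_table.loc[sites, "window15"].tolist()
    frames = []
    for kin in pssms.index.get_level_values("kinase").unique():
        ms = motif_score(windows, pssm_for(pssms, kin)).to_numpy()
        ann = annotation.loc[annotation["kinase"] == kin, "site_id"]
        ann = [s for s in ann if s in phospho_matrix.index]
        try:
            centroid = kinase_centroid(phospho_matrix, ann)
            ps = profile_score(phospho_matrix, centroid).to_numpy()
        except InputError:
            ps = np.full(len(sites), 0.5)
        df = pd.DataFrame({
            "kinase": kin,
            "motif_score": ms,
            "profile_score": ps,
            "combined": combined_substrate_score(ms, ps, weight),
            "annotated": sites.isin(ann),
        }, index=sites)
        frames.append(df)
    return pd.concat(frames)


# ---------------------------------------------------------------------------
# positive-unlabeled substrate prediction
# ---------------------------------------------------------------------------

def pu_predict(
    scores: pd.DataFrame,
    n_rounds: int = 50,
    seed: int = 0,
    C: float = 1.0,
) -> pd.DataFrame:
    """Adaptive-sampling PU ensemble probabilities per (site, kinase).

    ``scores`` is the output of :func:`score_substrates`. Per kinase and per
    round: pseudo-negatives are sampled (without replacement, one per
    positive) from unlabeled sites with probability proportional to the
    current sampling weight (initialized to ``1 - combined``); a logistic
    classifier on (motif, profile, combined) is fit and scores all sites;
    weights are then multiplied by (1 - running mean probability), steering
    later rounds away from sites the ensemble already considers positive.
    ``pu_probability`` is the mean positive-class probability over rounds.

    With fewer positives than features + 1 the kinase falls back to the
    combined score with a warning.
    """
    out = scores.copy()
    out["pu_probability"] = np.nan
    rng = np.random.default_rng(seed)
    for kin, sub in scores.groupby("kinase", sort=True):
        X = sub.loc[:, list(_PU_FEATURES)].to_numpy(float)
        pos = sub["annotated"].to_numpy(bool)
        n_pos = int(pos.sum())
        if n_pos < len(_PU_FEATURES) + 1:
            warnings.warn(
                f"pu_predict: kinase {kin} has {n_pos} positives; falling "
                "back to ranking by combined score")
            mask = out["kinase"] == kin
            out.loc[mask, "pu_probability"] = out.loc[mask, "combined"].to_numpy()
            continue
        unlabeled = np.flatnonzero(~pos)
        weights = 1.0 - sub["combined"].to_numpy(float)[unlabeled]
        weights = np.clip(weights, 1e-6, None)
        prob_sum = np.zeros(len(sub))
        n_draw = min(n_pos, unlabeled.size)
        for b in range(n_rounds):
            w = weights / weights.sum()
            neg = unlabeled[rng.choice(unlabeled.size, size=n_draw,
                                       replace=False, p=w)]
            idx = np.concatenate([np.flatnonzero(pos), neg])
            y = np.concatenate([np.ones(n_pos), np.zeros(n_draw)])
            clf = LogisticRegression(C=C, solver="lbfgs", max_iter=1000)
            clf.fit(X[idx], y)
            prob_sum += clf.predict_proba(X)[:, 1]
            running = prob_sum / (b + 1)
            weights = np.clip(weights * (1.0 - running[unlabeled]), 1e-9, None)
        mask = out["kinase"] == kin
        out.loc[mask, "pu_probability"] = prob_sum / n_rounds
    return out


def rank_top_substrates(scores: pd.DataFrame, kinase: str, n_top: int,
                        key: str = "pu_probability") -> list[str]:
    """Top-N site ids for a kinase, sorted by ``key`` descending with ties
    broken by motif score then site id (lexicographic, ascending)."""
    if n_top <= 0:
        raise InputError("n_top must be positive")
    sub = scores[scores["kinase"] == kinase].copy()
    if sub.empty:
        raise InputError(f"no scores for kinase {kinase!r}")
    if n_top > len(sub):
        raise InputError(f"n_top={n_top} exceeds {len(sub)} scored sites")
    if key not in sub or sub[key].isna().all():
        key = "combined"
    sub = sub.reset_index().rename(columns={sub.index.name or "index": "site_id"})
    sub = sub.sort_values([key, "motif_score", "site_id"],
                          ascending=[False, False, True], kind="mergesort")
    return sub["site_id"].head(n_top).tolist()


# ---------------------------------------------------------------------------
# kinase activity
# ---------------------------------------------------------------------------

def kinase_activity(
    norm_stats: pd.DataFrame,
    substrate_sites: Sequence[str],
    kinase: str = "",
    p_cut: float = 0.05,
) -> KinaseActivity:
    """Aggregate standardized protein-normalized change over a substrate set.

    ``activity_score`` is the mean of the substrate fc_norm values expressed
    in SD units of all scored sites; the p-value is a one-sample t-test of
    the substrate fc_norm values against 0 (NA when fewer than 3 substrates).
    """
    present = [s for s in substrate_sites if s in norm_stats.index]
    if not present:
        raise InputError("substrate set is empty (or disjoint from stats)")
    all_fc = norm_stats["fc_norm"].to_numpy(float)
    mu, sd = np.nanmean(all_fc), np.nanstd(all_fc, ddof=1)
    vals = norm_stats.loc[present, "fc_norm"].to_numpy(float)
    vals = vals[np.isfinite(vals)]
    z = (vals - 0.0) / sd if sd > 0 else vals
    score = float(np.mean(z)) if vals.size else np.nan
    if vals.size < 3:
        p = np.nan
    elif np.allclose(vals, vals[0]):
        p = np.nan if vals[0] == 0 else 0.0
    else:
        p = float(stats.ttest_1samp(vals, 0.0).pvalue)
    if np.isfinite(p) and p < p_cut and score != 0:
        direction = "up" if score > 0 else "down"
    else:
        direction = "unchanged"
    return KinaseActivity(kinase=kinase, activity_score=score, p=p,
                          direction=direction, n_substrates=int(vals.size))


def kinase_activity_per_sample(
    norm_profiles: pd.DataFrame,
    substrate_sites: Sequence[str],
    standardize: bool = False,
) -> pd.Series:
    """Per-sample activity summary: mean substrate profile.

    Profiles are already on a common log2 scale, so the default aggregates
    them directly; per-site z-scoring (``standardize=True``, useful for
    heatmap display) divides each site by its total across-sample variance,
    which includes any genuine group effect and therefore shrinks true
    activity signal.
    """
    present = [s for s in substrate_sites if s in norm_profiles.index]
    if not present:
        raise InputError("substrate set is empty (or disjoint from profiles)")
    sub = norm_profiles.loc[present]
    if standardize:
        sub = standardize_profiles(sub)
    return sub.mean(axis=0)


def assign_sites_to_kinases(scores: pd.DataFrame,
                            key: str = "pu_probability") -> pd.Series:
    """Competitive site-to-kinase assignment: each site goes to the kinase
    scoring it highest (ties broken by kinase name order)."""
    if key not in scores or scores[key].isna().all():
        key = "combined"
    wide = scores.reset_index().pivot_table(
        index=scores.index.name or "index", columns="kinase", values=key)
    return wide.idxmax(axis=1)


def infer_kinase_activities(
    norm_stats: pd.DataFrame,
    scores: pd.DataFrame,
    n_top: int = 200,
    n_top_primary: Optional[Mapping[str, int]] = None,
    key: str = "pu_probability",
    p_cut: float = 0.05,
    norm_profiles: Optional[pd.DataFrame] = None,
    groups: Optional[pd.Series] = None,
    exclusive: bool = True,
) -> pd.DataFrame:
    """Top-N substrate ranking + activity test for every scored kinase.

    With ``exclusive`` (default) every site contributes only to the kinase
    that scores it highest, so strong substrates of one kinase cannot leak
    signal into another kinase's substrate set. When per-sample normalized
    profiles and group labels are supplied, the direction call uses a
    two-group t-test on the per-sample aggregated substrate profile -- this
    is calibrated against substrate-set selection effects, unlike the
    site-level one-sample test, which is still reported as ``p_site``.
    """
    owner = assign_sites_to_kinases(scores, key=key) if exclusive else None
    rows = []
    for kin in scores["kinase"].unique():
        sub = scores[scores["kinase"] == kin]
        if owner is not None:
            mine = set(owner.index[owner == kin])
            sub = sub[sub.index.isin(mine)]
        n = (n_top_primary or {}).get(kin, n_top)
        n = min(n, len(sub))
        if n == 0:
            rows.append((kin, np.nan, np.nan, np.nan, "unchanged", 0))
            continue
        subs = rank_top_substrates(sub, kin, n, key=key)
        act = kinase_activity(norm_stats, subs, kinase=kin, p_cut=p_cut)
        p, direction = act.p, act.direction
        if norm_profiles is not None and groups is not None:
            per_sample = kinase_activity_per_sample(norm_profiles, subs)
            g = np.asarray(groups)
            levels = pd.unique(g)
            case = "mutant" if "mutant" in levels else levels[-1]
            a = per_sample[g == case]
            b = per_sample[g != case]
            if len(a) >= 2 and len(b) >= 2 and (a.std() > 0 or b.std() > 0):
                t, p = stats.ttest_ind(a, b)
                direction = ("up" if t > 0 else "down") if p < p_cut else "unchanged"
        rows.append((kin, act.activity_score, p, act.p, direction,
                     act.n_substrates))
    return pd.DataFrame(rows, columns=["kinase", "activity_score", "p",
                                       "p_site", "direction", "n_substrates"]
                        ).set_index("kinase")


# ---------------------------------------------------------------------------
# consensus-substrate mapping
# ---------------------------------------------------------------------------

def map_consensus_substrates(
    site_stats: pd.DataFrame,
    annotation: pd.DataFrame,
    kinase: str,
    sd_hat: float,
    fdr_cut: float = 0.2,
    sd_multiple: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Intersect detected sites with a kinase's annotated substrates and
    classify each as trend-up / trend-down / flat at the relaxed thresholds
    (default FDR < 0.2 and |fc| > 1*SD)."""
    ann_sites = annotation.loc[annotation["kinase"] == kinase, "site_id"]
    matched = site_stats.index.intersection(ann_sites)
    fc_col = "fc_norm" if "fc_norm" in site_stats.columns else "log2fc"
    sub = site_stats.loc[matched].copy()
    fc = sub[fc_col].to_numpy(float) if len(sub) else np.array([])
    q = sub["q_bh"].to_numpy(float) if len(sub) else np.array([])
    thr = sd_multiple * sd_hat
    gate = q < fdr_cut
    cls = np.where(gate & (fc > thr), "trend-up",
                   np.where(gate & (fc < -thr), "trend-down", "flat"))
    sub["class"] = cls
    counts = {
        "n_matched": int(len(sub)),
        "n_trend_up": int((cls == "trend-up").sum()),
        "n_trend_down": int((cls == "trend-down").sum()),
        "n_flat": int((cls == "flat").sum()),
    }
    return sub, counts
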