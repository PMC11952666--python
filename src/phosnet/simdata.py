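"""Synthetic proteome / phosphoproteome generator with known ground truth.

Emulates the statistical structure of a two-group (control vs. mutant)
DIA-style quantitative proteomics experiment on the log2 scale:

* protein log2 intensities = baseline + module latent factor + group effect
  (for truly differential proteins) + batch offset + Gaussian noise;
* phosphosite log2 intensities track their parent protein profile, plus a
  site offset, a kinase-activity shift for substrates of shifted kinases,
  and a site-specific residual;
* phosphosite ±7-residue sequence windows are sampled from kinase position
  probability matrices (PSSMs) for true substrates and from background
  frequencies otherwise.

Everything is driven by a single seeded generator, so an identical
:class:`SimConfig` reproduces byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
WINDOW_LEN = 15
CENTER = WINDOW_LEN // 2  # phospho-acceptor position (0-based 7)

# acceptor composition used when a window is NOT generated by a kinase motif
_BACKGROUND_ACCEPTOR = {"S": 0.45, "T": 0.35, "Y": 0.20}
# acceptor composition of every kinase PSSM centre (all mass on S/T)
_MOTIF_ACCEPTOR = {"S": 0.75, "T": 0.25}


class ConfigurationError(ValueError):
    """Raised when a SimConfig (or derived request) is internally invalid."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic two-group experiment.

    All intensities are generated directly on the log2 scale. ``noise_sd``
    is the protein-level replicate residual SD; the phosphosite-specific
    residual defaults to half of it because a site measured in the same run
    shares most of the parent protein's measurement error.

    ``kinase_shifts`` maps kinase names to the absolute log2 fold change
    applied to their substrate sites in the mutant group. ``None`` resolves
    to the first kinase shifted up and the second shifted down by
    ``1 x noise_sd`` (a one-SD activity change in each direction).
    """

    n_per_group: int = 4
    n_proteins: int = 2000
    n_phosphosites: int = 1000
    n_kinases: int = 4
    frac_de: float = 0.1
    effect_log2fc: float = 2.0
    noise_sd: float = 0.5
    site_noise_sd: Optional[float] = None
    kinase_shifts: Optional[Mapping[str, float]] = None
    substrates_per_kinase: int = 30
    n_annotated_per_kinase: int = 10
    motif_entropy: float = 0.2
    n_modules: int = 3
    module_sizes: Sequence[int] = (200, 200, 200)
    latent_strength: float = 2.0
    module_trait_assoc: Optional[Sequence[float]] = None
    missing_rate: float = 0.0
    missing_mechanism: str = "mcar"  # or "censored"
    batch_effect_sd: float = 0.0
    n_batches: int = 1
    de_in_module: Optional[int] = None
    orthogonal_factors: bool = True
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_de", "missing_rate", "motif_entropy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must be in [0, 1]")
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if self.n_kinases < 1:
            raise ConfigurationError("n_kinases must be >= 1")
        if self.n_phosphosites < 1:
            raise ConfigurationError("n_phosphosites must be >= 1")
        if len(self.module_sizes) != self.n_modules:
            raise ConfigurationError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_proteins:
            raise ConfigurationError("module_sizes sum exceeds n_proteins")
        if self.missing_mechanism not in ("mcar", "censored"):
            raise ConfigurationError(
                f"unknown missing_mechanism {self.missing_mechanism!r}")
        if self.n_batches < 1:
            raise ConfigurationError("n_batches must be >= 1")

    # ---- resolved defaults -------------------------------------------------

    @property
    def resolved_site_noise_sd(self) -> float:
        return self.noise_sd / 2.0 if self.site_noise_sd is None else self.site_noise_sd

    def resolved_kinase_shifts(self) -> dict[str, float]:
        names = kinase_names(self.n_kinases)
        if self.kinase_shifts is not None:
            unknown = set(self.kinase_shifts) - set(names)
            if unknown:
                raise ConfigurationError(f"kinase_shifts for unknown kinases {sorted(unknown)}")
            out = {k: 0.0 for k in names}
            out.update(self.kinase_shifts)
            return out
        out = {k: 0.0 for k in names}
        out[names[0]] = +1.0 * self.noise_sd
        if self.n_kinases >= 2:
            out[names[1]] = -1.0 * self.noise_sd
        return out

    def resolved_trait_assoc(self) -> np.ndarray:
        if self.module_trait_assoc is not None:
            a = np.asarray(self.module_trait_assoc, dtype=float)
            if a.size != self.n_modules:
                raise ConfigurationError("module_trait_assoc length must equal n_modules")
            return a
        a = np.zeros(self.n_modules)
        if self.n_modules >= 1:
            a[0] = 3.0
        return a

    @classmethod
    def null(cls, **kwargs) -> "SimConfig":
        """A fully null configuration: no DE, no kinase shifts, and no block
        correlation, so per-feature test statistics are independent and
        exactly null-distributed."""
        base = dict(
            frac_de=0.0,
            kinase_shifts={},
            n_modules=0,
            module_sizes=(),
        )
        base.update(kwargs)
        return cls(**base)


def kinase_names(n: int) -> list[str]:
    return [f"KIN{i + 1}" for i in range(n)]


@dataclass
class GroundTruth:
    """What the generator actually planted, for scoring recovery."""

    de_labels: pd.Series  # protein_id -> {"up", "down", "null"}
    kinase_shifts: dict[str, float]  # kinase -> signed log2 shift
    substrate_map: dict[str, list[str]]  # kinase -> site ids
    module_labels: pd.Series  # protein_id -> module id (0 = unassigned)
    latent_factors: pd.DataFrame  # module x sample


@dataclass
class SimulatedDataset:
    config: SimConfig
    protein_matrix: pd.DataFrame  # proteins x samples, log2
    phospho_matrix: pd.DataFrame  # sites x samples, log2
    meta: pd.DataFrame  # sample, group, trait, batch
    site_table: pd.DataFrame  # site_id, protein_id, residue, position, window15
    pssms: pd.DataFrame  # (kinase, position) x residue probabilities
    annotation: pd.DataFrame  # kinase, site_id ("known" substrate pairs)
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# kinase motif models
# ---------------------------------------------------------------------------

def simulate_kinase_models(config: SimConfig, rng: Optional[np.random.Generator] = None
                           ) -> pd.DataFrame:
    """One 15-position x 20-residue PSSM per kinase.

    Each non-centre position puts probability ``1/20 + (1-motif_entropy)*19/20``
    on a kinase-specific preferred residue (uniform at ``motif_entropy=1``);
    the centre position carries all mass on S/T. Rows are indexed by
    (kinase, position 1..15) and each row sums to 1.
    """
    if config.n_kinases < 1:
        raise ConfigurationError("need at least one kinase")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    aa = list(AMINO_ACIDS)
    rows = []
    index = []
    p_dom = 1.0 / 20.0 + (1.0 - config.motif_entropy) * 19.0 / 20.0
    p_other = (1.0 - p_dom) / 19.0
    for kin in kinase_names(config.n_kinases):
        preferred = rng.integers(0, 20, size=WINDOW_LEN)
        for pos in range(WINDOW_LEN):
            if pos == CENTER:
                row = np.zeros(20)
                for res, p in _MOTIF_ACCEPTOR.items():
                    row[aa.index(res)] = p
            else:
                row = np.full(20, p_other)
                row[preferred[pos]] = p_dom
            rows.append(row)
            index.append((kin, pos + 1))
    pssms = pd.DataFrame(
        np.asarray(rows),
        index=pd.MultiIndex.from_tuples(index, names=["kinase", "position"]),
        columns=aa,
    )
    return pssms


def pssm_for(pssms: pd.DataFrame, kinase: str) -> np.ndarray:
    """Extract one kinase's 15x20 matrix as an array ordered by position."""
    sub = pssms.loc[kinase]
    return sub.sort_index().to_numpy()


def _sample_window(rng: np.random.Generator, pssm: Optional[np.ndarray]) -> str:
    """Draw a 15-mer from a PSSM, or from background if pssm is None."""
    chars = []
    for pos in range(WINDOW_LEN):
        if pos == CENTER:
            if pssm is None:
                res = rng.choice(list(_BACKGROUND_ACCEPTOR),
                                 p=list(_BACKGROUND_ACCEPTOR.values()))
            else:
                res = AMINO_ACIDS[rng.choice(20, p=pssm[pos])]
            chars.append(str(res))
        elif pssm is None:
            chars.append(AMINO_ACIDS[rng.integers(0, 20)])
        else:
            chars.append(AMINO_ACIDS[rng.choice(20, p=pssm[pos])])
    return "".join(chars)


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

def _sample_metadata(config: SimConfig) -> pd.DataFrame:
    n = config.n_per_group
    samples = [f"ctrl_{i + 1}" for i in range(n)] + [f"mut_{i + 1}" for i in range(n)]
    group = ["control"] * n + ["mutant"] * n
    trait = [0] * n + [1] * n
    # batches balanced across groups: round-robin within each group
    batch = [(i % config.n_batches) + 1 for i in range(n)] * 2
    return pd.DataFrame({"sample": samples, "group": group,
                         "trait": trait, "batch": batch}).set_index("sample")


def simulate_proteome(config: SimConfig, rng: Optional[np.random.Generator] = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the protein log2 intensity matrix plus ground truth.

    Returns ``(matrix, meta, ground_truth)``; the ground truth carries DE
    labels, module labels and latent factors (substrate_map is filled in by
    :func:`simulate_phosphoproteome`).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    meta = _sample_metadata(config)
    n_samp = len(meta)
    trait = meta["trait"].to_numpy(float)
    proteins = [f"P{i + 1:05d}" for i in range(config.n_proteins)]

    # module membership: first sum(module_sizes) proteins, in blocks
    module_labels = np.zeros(config.n_proteins, dtype=int)
    start = 0
    for m, size in enumerate(config.module_sizes, start=1):
        module_labels[start:start + size] = m
        start += size

    assoc = config.resolved_trait_assoc()
    latent = rng.standard_normal((config.n_modules, n_samp))
    if config.orthogonal_factors and 1 <= config.n_modules <= n_samp:
        # distinct modules = mutually orthogonal sample patterns; without
        # this, independent draws over few samples can be strongly
        # correlated by chance and two modules coalesce
        q, _ = np.linalg.qr(latent.T)
        latent = q.T[: config.n_modules]
        latent = latent / latent.std(axis=1, ddof=1, keepdims=True)
    latent = latent + assoc[:, None] * (trait[None, :] - 0.5)

    loadings = rng.uniform(0.5, 1.5, size=config.n_proteins) * config.latent_strength

    # truly differential proteins
    de = np.array(["null"] * config.n_proteins, dtype=object)
    n_de = int(round(config.frac_de * config.n_proteins))
    if config.frac_de > 0 and n_de < 1:
        warnings.warn("frac_de * n_proteins < 1: no DE proteins generated")
    if n_de >= 1:
        if config.de_in_module is not None:
            pool = np.flatnonzero(module_labels == config.de_in_module)
            if n_de > pool.size:
                raise ConfigurationError("de_in_module smaller than requested DE count")
            idx = rng.choice(pool, size=n_de, replace=False)
            de[idx] = "up"
        else:
            idx = rng.choice(config.n_proteins, size=n_de, replace=False)
            signs = rng.choice(["up", "down"], size=n_de)
            de[idx] = signs

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_proteins)
    x = np.tile(baseline[:, None], (1, n_samp))
    in_mod = module_labels > 0
    x[in_mod] += loadings[in_mod, None] * latent[module_labels[in_mod] - 1, :]
    effect = np.where(de == "up", config.effect_log2fc,
                      np.where(de == "down", -config.effect_log2fc, 0.0))
    x += effect[:, None] * trait[None, :]

    if config.batch_effect_sd > 0 and config.n_batches > 1:
        batch_idx = meta["batch"].to_numpy() - 1
        offsets = rng.normal(0.0, config.batch_effect_sd,
                             size=(config.n_proteins, config.n_batches))
        x += offsets[:, batch_idx]

    x += rng.normal(0.0, config.noise_sd, size=x.shape)
    x = _insert_missing(x, config, rng)

    matrix = pd.DataFrame(x, index=pd.Index(proteins, name="feature_id"),
                          columns=meta.index)
    gt = GroundTruth(
        de_labels=pd.Series(de, index=matrix.index, name="de_label"),
        kinase_shifts=config.resolved_kinase_shifts(),
        substrate_map={},
        module_labels=pd.Series(module_labels, index=matrix.index, name="module"),
        latent_factors=pd.DataFrame(
            latent, index=[f"M{m + 1}" for m in range(config.n_modules)],
            columns=meta.index),
    )
    return matrix, meta, gt


def _insert_missing(x: np.ndarray, config: SimConfig,
                    rng: np.random.Generator) -> np.ndarray:
    if config.missing_rate <= 0:
        return x
    if config.missing_mechanism == "mcar":
        mask = rng.random(x.shape) < config.missing_rate
    else:  # left-censored: lower intensities more likely to be missing
        order = x.ravel().argsort().argsort().reshape(x.shape)
        frac_above = order / max(x.size - 1, 1)  # 0 = lowest intensity
        prob = np.clip(2.0 * config.missing_rate * (1.0 - frac_above), 0, 1)
        mask = rng.random(x.shape) < prob
    out = x.copy()
    out[mask] = np.nan
    return out


# ---------------------------------------------------------------------------
# phosphoproteome
# ---------------------------------------------------------------------------

def simulate_phosphoproteome(
    config: SimConfig,
    protein_matrix: pd.DataFrame,
    meta: pd.DataFrame,
    ground_truth: GroundTruth,
    pssms: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate phosphosite intensities, windows and the known-substrate table.

    Each site's log2 profile is its parent protein's realised profile plus a
    constant site offset, the cognate kinase's activity shift in the mutant
    group (true substrates only), and a site-specific residual. Windows of
    kinase-generated sites are drawn from that kinase's PSSM; all other
    windows come from background frequencies.

    Returns ``(phospho_matrix, site_table, annotation)`` and fills
    ``ground_truth.substrate_map`` in place.
    """
    if config.n_phosphosites < 1:
        raise ConfigurationError("n_phosphosites must be >= 1")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n_sites = config.n_phosphosites
    names = kinase_names(config.n_kinases)
    shifts = ground_truth.kinase_shifts

    total_sub = config.substrates_per_kinase * config.n_kinases
    if total_sub > n_sites:
        raise ConfigurationError("substrates_per_kinase * n_kinases exceeds n_phosphosites")
    sub_idx = rng.choice(n_sites, size=total_sub, replace=False)
    site_kinase = np.array([None] * n_sites, dtype=object)
    for i, kin in enumerate(names):
        site_kinase[sub_idx[i * config.substrates_per_kinase:
                            (i + 1) * config.substrates_per_kinase]] = kin

    proteins = protein_matrix.index.to_numpy()
    parents = proteins[rng.integers(0, len(proteins), size=n_sites)]
    kin_arrays = {kin: pssm_for(pssms, kin) for kin in names}

    trait = meta["trait"].to_numpy(float)
    site_sd = config.resolved_site_noise_sd

    records = []
    rows = []
    seen: set[str] = set()
    prot_vals = protein_matrix.to_numpy()
    prot_pos = {p: i for i, p in enumerate(proteins)}
    for s in range(n_sites):
        kin = site_kinase[s]
        window = _sample_window(rng, kin_arrays[kin] if kin is not None else None)
        residue = window[CENTER]
        # unique site id on the parent protein
        while True:
            position = int(rng.integers(1, 2000))
            site_id = f"{parents[s]};{residue}{position}"
            if site_id not in seen:
                seen.add(site_id)
                break
        parent_profile = prot_vals[prot_pos[parents[s]]]
        offset = rng.normal(0.0, 1.0)
        shift = shifts.get(kin, 0.0) if kin is not None else 0.0
        profile = (parent_profile + offset + shift * trait
                   + rng.normal(0.0, site_sd, size=trait.size))
        rows.append(profile)
        records.append((site_id, parents[s], residue, position, window, kin))

    site_table = pd.DataFrame(
        records,
        columns=["site_id", "protein_id", "residue", "position", "window15", "kinase"],
    )
    matrix = pd.DataFrame(
        np.asarray(rows),
        index=pd.Index(site_table["site_id"], name="feature_id"),
        columns=meta.index,
    )
    matrix = pd.DataFrame(_insert_missing(matrix.to_numpy(), config, rng),
                          index=matrix.index, columns=matrix.columns)

    ground_truth.substrate_map = {
        kin: site_table.loc[site_table["kinase"] == kin, "site_id"].tolist()
        for kin in names
    }

    ann_rows = []
    for kin in names:
        subs = ground_truth.substrate_map[kin]
        n_ann = min(config.n_annotated_per_kinase, len(subs))
        chosen = rng.choice(len(subs), size=n_ann, replace=False)
        ann_rows.extend((kin, subs[i]) for i in sorted(chosen))
    annotation = pd.DataFrame(ann_rows, columns=["kinase", "site_id"])

    # the generating kinase is ground truth, not observable data
    site_table = site_table.drop(columns=["kinase"]).set_index("site_id")
    return matrix, site_table, annotation


# ---------------------------------------------------------------------------
# one-call orchestration
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator with one seed stream; fully deterministic."""
    rng = np.random.default_rng(config.seed)
    pssms = simulate_kinase_models(config, rng)
    protein_matrix, meta, gt = simulate_proteome(config, rng)
    phospho_matrix, site_table, annotation = simulate_phosphoproteome(
        config, protein_matrix, meta, gt, pssms, rng)
    return SimulatedDataset(
        config=config,
        protein_matrix=protein_matrix,
        phospho_matrix=phospho_matrix,
        meta=meta,
        site_table=site_table,
        pssms=pssms,
        annotation=annotation,
        ground_truth=gt,
    )


def to_raw_scale(log2_matrix: pd.DataFrame) -> pd.DataFrame:
    """Optional raw-intensity export (2**x); missing values stay missing."""
    return 2.0 ** log2_matrix
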