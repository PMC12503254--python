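"""Synthetic cohorts with planted sleep-biopsychosocial structure.

The real study population (770 young adults, many of them twins or
siblings) is access restricted, so every downstream stage is exercised on
generated data with known ground truth:

* family blocks — monozygotic pairs, dizygotic pairs, non-twin sibling
  pairs and singletons — whose members share a family-level latent, making
  naive permutation invalid and family-restricted permutation necessary;
* planted cross-block canonical correlations with known unit-norm weight
  vectors on each side;
* linear age/sex/education effects on both blocks;
* PSQI-like ordinal discretization of the sleep columns (0-3 by quartile
  cuts of the latent Gaussian);
* per-subject symmetric connectivity matrices whose designated edges depend
  linearly on the planted subject scores, the rest being pure noise.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import BlockMatrix, ConnectomeSet, FrameTrace

# quartile cut points of the standard normal; map a z-scored column to
# ordinal 0-3 like PSQI sub-component coding
_QUARTILE_CUTS = np.array([-0.6744897501960817, 0.0, 0.6744897501960817])

#: Fine-grained cortical networks and their coarse 7-network parents.
NETWORK17_TO_7 = {
    "VisCent": "Vis", "VisPeri": "Vis",
    "SomMotA": "SomMot", "SomMotB": "SomMot",
    "DorsAttnA": "DorsAttn", "DorsAttnB": "DorsAttn",
    "SalVentAttnA": "SalVentAttn", "SalVentAttnB": "SalVentAttn",
    "LimbicA": "Limbic", "LimbicB": "Limbic",
    "ContA": "Cont", "ContB": "Cont", "ContC": "Cont",
    "DefaultA": "Default", "DefaultB": "Default", "DefaultC": "Default",
    "TempPar": "Default",
}
NETWORK17_NAMES = list(NETWORK17_TO_7)

_SUBCORTICAL_BASE = [
    "Cerebellum", "Thalamus", "Caudate", "Putamen", "Pallidum",
    "Hippocampus", "Accumbens", "Amygdala", "VentralDC",
]


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults emulate the study conditions.

    ``noise_sd`` may be a single value or a ``(sleep, biopsychosocial)``
    pair; the defaults are calibrated so that planted canonical structure is
    detectable but not trivially strong.  ``family_mix`` gives the fraction
    of *subjects* in each relatedness class ``(MZ, DZ, SIB, SINGLETON)``;
    the pair classes take two subjects per family.
    """

    n_subjects: int = 770
    n_sleep_vars: int = 7
    n_bps_vars: int = 118
    planted_corrs: Sequence[float] = (0.7, 0.4)
    planted_weights_seed: int = 12345
    family_mix: Sequence[float] = (0.20, 0.20, 0.20, 0.40)
    within_family_rho: float = 0.5
    confound_effects: tuple[np.ndarray, np.ndarray] | None = None
    confound_scale: float = 0.1
    noise_sd: float | tuple[float, float] = (0.2, 0.3)
    discretize_sleep: bool = True
    n_parcels: int = 419
    n_subcortical: int = 19
    glm_betas: Mapping[tuple[int, int], float] = field(default_factory=dict)
    glm_component: int = 0
    connectome_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.n_subjects <= max(self.n_sleep_vars, self.n_bps_vars):
            raise ValueError("need more subjects than variables in either block")
        corrs = np.asarray(self.planted_corrs, dtype=float)
        if corrs.size and (np.any(corrs < 0) or np.any(corrs > 1)):
            raise ValueError("planted_corrs must lie in [0, 1]")
        if corrs.size and np.any(np.diff(corrs) > 0):
            raise ValueError("planted_corrs must be nonincreasing")
        mix = np.asarray(self.family_mix, dtype=float)
        if mix.shape != (4,) or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
            raise ValueError("family_mix must be 4 nonnegative proportions summing to 1")
        if not 0.0 <= self.within_family_rho <= 1.0:
            raise ValueError("within_family_rho must lie in [0, 1]")
        sx, sy = self.block_noise_sd
        if sx <= 0 or sy <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def k_true(self) -> int:
        return len(self.planted_corrs)

    @property
    def block_noise_sd(self) -> tuple[float, float]:
        if np.isscalar(self.noise_sd):
            return float(self.noise_sd), float(self.noise_sd)
        sx, sy = self.noise_sd
        return float(sx), float(sy)


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the phenotype generator.

    ``true_subject_scores`` holds the standardized per-component composite
    of the two latent score sides — the quantity the connectome generator
    links to designated edges.  Raw per-side latents are kept for
    calibration tests.
    """

    true_sleep_weights: np.ndarray
    true_bps_weights: np.ndarray
    true_corrs: np.ndarray
    true_subject_scores: np.ndarray
    sleep_latents: np.ndarray
    bps_latents: np.ndarray
    true_glm_betas: dict[tuple[int, int], float] = field(default_factory=dict)


def generate_cohort(cfg: SyntheticConfig) -> pd.DataFrame:
    """Build the family-structured subject table.

    Pair classes (MZ, DZ, SIB) whose allotted subject count is odd lose the
    odd subject to the singleton pool with a warning.  Age is uniform on
    [22, 36] years, sex Bernoulli(1/2), education an integer in [11, 17],
    matching the demographic ranges of the cohort the generator emulates.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    n = cfg.n_subjects
    mix = np.asarray(cfg.family_mix, dtype=float)
    targets = np.round(mix[:3] * n).astype(int)
    pair_counts = {}
    extra_singletons = 0
    for cls, target in zip(("MZ", "DZ", "SIB"), targets):
        if target % 2:
            warnings.warn(
                f"family_mix gives an odd subject count ({target}) for {cls} "
                "pairs; dropping one subject to the singleton pool",
                UserWarning,
                stacklevel=2,
            )
            extra_singletons += 1
        pair_counts[cls] = target // 2
    n_paired = 2 * sum(pair_counts.values())
    if n_paired > n:
        raise ValueError("family_mix pair classes exceed n_subjects")
    n_singleton = n - n_paired

    family_id, relatedness = [], []
    fam = 0
    for cls in ("MZ", "DZ", "SIB"):
        for _ in range(pair_counts[cls]):
            family_id += [f"F{fam:05d}"] * 2
            relatedness += [cls] * 2
            fam += 1
    for _ in range(n_singleton):
        family_id.append(f"F{fam:05d}")
        relatedness.append("SINGLETON")
        fam += 1

    cohort = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "family_id": family_id,
            "relatedness": relatedness,
            "age": rng.uniform(22.0, 36.0, n),
            "sex": rng.integers(0, 2, n),
            "education": rng.integers(11, 18, n),
        }
    )
    return cohort


def _familial_normals(
    rng: np.random.Generator, fam_codes: np.ndarray, n_fam: int, k: int, rho: float
) -> np.ndarray:
    """n x k standard normals with equicorrelation ``rho`` within family:
    each subject is sqrt(rho) * family latent + sqrt(1-rho) * own noise."""
    fam_part = rng.standard_normal((n_fam, k))
    own = rng.standard_normal((len(fam_codes), k))
    return np.sqrt(rho) * fam_part[fam_codes] + np.sqrt(1.0 - rho) * own


def _planted_weights(cfg: SyntheticConfig):
    wrng = np.random.default_rng(cfg.planted_weights_seed)
    k = cfg.k_true
    Wx = np.linalg.qr(wrng.standard_normal((cfg.n_sleep_vars, k)))[0]
    Wy = np.linalg.qr(wrng.standard_normal((cfg.n_bps_vars, k)))[0]
    if cfg.confound_effects is not None:
        Cx, Cy = cfg.confound_effects
        Cx = np.asarray(Cx, dtype=float)
        Cy = np.asarray(Cy, dtype=float)
    else:
        Cx = cfg.confound_scale * wrng.standard_normal((3, cfg.n_sleep_vars))
        Cy = cfg.confound_scale * wrng.standard_normal((3, cfg.n_bps_vars))
    return Wx, Wy, Cx, Cy


def generate_phenotypes(
    cfg: SyntheticConfig, cohort: pd.DataFrame
) -> tuple[BlockMatrix, BlockMatrix, SyntheticTruth]:
    """Generate the two phenotype blocks around planted latent structure.

    The sleep-side latent ``t_x`` and the unique part of the
    biopsychosocial-side latent both carry the within-family equicorrelation,
    so members of a family are correlated on both blocks with the same rho.
    ``t_y = r * t_x + sqrt(1 - r^2) * unique`` plants the requested canonical
    correlation per component.  Blocks are ``latents @ weights' + confound
    effects + iid noise``; sleep columns are then discretized to ordinal 0-3.
    """
    k = cfg.k_true
    if k > min(cfg.n_sleep_vars, cfg.n_bps_vars):
        raise ValueError("more planted components than variables in a block")
    rng = np.random.default_rng([cfg.seed, 2])
    n = len(cohort)

    fam_codes, _ = pd.factorize(cohort["family_id"])
    n_fam = fam_codes.max() + 1
    rho = cfg.within_family_rho
    tx = _familial_normals(rng, fam_codes, n_fam, k, rho)
    unique = _familial_normals(rng, fam_codes, n_fam, k, rho)
    r = np.asarray(cfg.planted_corrs, dtype=float)
    ty = r * tx + np.sqrt(1.0 - r**2) * unique

    Wx, Wy, Cx, Cy = _planted_weights(cfg)
    conf = cohort[["age", "sex", "education"]].to_numpy(float)
    conf_std = conf.std(axis=0)
    conf_std[conf_std == 0] = 1.0
    conf_z = (conf - conf.mean(axis=0)) / conf_std

    sx, sy = cfg.block_noise_sd
    Xv = tx @ Wx.T + conf_z @ Cx + sx * rng.standard_normal((n, cfg.n_sleep_vars))
    Yv = ty @ Wy.T + conf_z @ Cy + sy * rng.standard_normal((n, cfg.n_bps_vars))

    if cfg.discretize_sleep:
        Z = (Xv - Xv.mean(axis=0)) / Xv.std(axis=0)
        Xv = np.searchsorted(_QUARTILE_CUTS, Z).astype(float)

    composite = (tx + ty) / 2.0
    composite = (composite - composite.mean(axis=0)) / composite.std(axis=0)
    truth = SyntheticTruth(
        true_sleep_weights=Wx,
        true_bps_weights=Wy,
        true_corrs=r,
        true_subject_scores=composite,
        sleep_latents=tx,
        bps_latents=ty,
        true_glm_betas=dict(cfg.glm_betas),
    )
    X = BlockMatrix(
        Xv,
        [f"sleep_{j:02d}" for j in range(cfg.n_sleep_vars)],
        category=["sleep"] * cfg.n_sleep_vars,
        worse_direction=np.ones(cfg.n_sleep_vars, dtype=bool),
    )
    bps_categories = [
        "cognition", "mental health", "physical health",
        "personality", "affect", "lifestyle",
    ]
    Y = BlockMatrix(
        Yv,
        [f"bps_{j:03d}" for j in range(cfg.n_bps_vars)],
        category=[bps_categories[j % len(bps_categories)] for j in range(cfg.n_bps_vars)],
    )
    return X, Y, truth


def make_atlas(n_parcels: int = 419, n_subcortical: int = 19) -> pd.DataFrame:
    """Parcel-to-network assignment table.

    Cortical parcels are split into contiguous, near-equal blocks across the
    17 fine networks; the remaining parcels form the subcortical compartment
    (paired left/right structures plus brainstem).  Columns: ``parcel_id``,
    ``network17``, ``network7``, ``compartment``.
    """
    n_cortical = n_parcels - n_subcortical
    if n_cortical < len(NETWORK17_NAMES):
        raise ValueError(
            f"need at least {len(NETWORK17_NAMES)} cortical parcels, "
            f"got {n_cortical}"
        )
    if n_subcortical < 1:
        raise ValueError("need at least one subcortical parcel")
    sizes = np.full(len(NETWORK17_NAMES), n_cortical // len(NETWORK17_NAMES))
    sizes[: n_cortical % len(NETWORK17_NAMES)] += 1
    net17 = np.repeat(NETWORK17_NAMES, sizes)

    sub_names = []
    for side in ("L", "R"):
        sub_names += [f"{side}_{s}" for s in _SUBCORTICAL_BASE]
    sub_names.append("Brainstem")
    regions = [sub_names[i % len(sub_names)] for i in range(n_subcortical)]

    return pd.DataFrame(
        {
            "parcel_id": np.arange(n_parcels),
            "network17": list(net17) + ["Subcortex"] * n_subcortical,
            "network7": [NETWORK17_TO_7[x] for x in net17]
            + ["Subcortex"] * n_subcortical,
            "compartment": ["cortex"] * n_cortical + ["subcortex"] * n_subcortical,
            "region": list(net17) + regions,
        }
    )


def generate_connectomes(cfg: SyntheticConfig, truth: SyntheticTruth) -> ConnectomeSet:
    """Per-subject symmetric Fisher-z matrices linked to planted scores.

    Designated edges (``cfg.glm_betas``) equal ``beta * composite score``
    plus noise; all other edges are pure noise.  Matrices are symmetric with
    zero diagonal by construction.
    """
    atlas = make_atlas(cfg.n_parcels, cfg.n_subcortical)
    rng = np.random.default_rng([cfg.seed, 3])
    n = truth.true_subject_scores.shape[0]
    P = cfg.n_parcels
    score = truth.true_subject_scores[:, cfg.glm_component]

    iu = np.triu_indices(P, k=1)
    n_edges = len(iu[0])
    edges = cfg.connectome_noise_sd * rng.standard_normal((n, n_edges))
    if cfg.glm_betas:
        flat = {}
        for (i, j), beta in cfg.glm_betas.items():
            a, b = (i, j) if i < j else (j, i)
            if a == b or b >= P:
                raise ValueError(f"invalid edge ({i}, {j}) for {P} parcels")
            flat[a * P + b] = beta
        edge_keys = iu[0] * P + iu[1]
        for key, beta in flat.items():
            col = int(np.searchsorted(edge_keys, key))
            edges[:, col] += beta * score

    mats = np.zeros((n, P, P))
    mats[:, iu[0], iu[1]] = edges
    mats += mats.transpose(0, 2, 1)
    return ConnectomeSet(matrices=mats, atlas=atlas)


def generate_frame_traces(
    n_frames: int, outlier_frames: Sequence[int], seed: int
) -> FrameTrace:
    """Threshold fixture: FD and DVARS exceed the censoring thresholds
    exactly at ``outlier_frames`` and stay safely below them elsewhere."""
    outliers = np.asarray(list(outlier_frames), dtype=int)
    if outliers.size and (outliers.min() < 0 or outliers.max() >= n_frames):
        raise ValueError("outlier frame index out of bounds")
    rng = np.random.default_rng(seed)
    fd = rng.uniform(0.03, 0.15, n_frames)
    dvars = rng.uniform(40.0, 65.0, n_frames)
    if outliers.size:
        fd[outliers] = rng.uniform(0.3, 0.6, outliers.size)
        dvars[outliers] = rng.uniform(85.0, 120.0, outliers.size)
    return FrameTrace(fd=fd, dvars=dvars)
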