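"""Synthetic inputs with known ground truth for every pipeline stage.

Four families of generators:

* deterministic and random fractal masks with known box-counting dimension
  (Sierpinski carpet, random Cantor dust) — validation fixtures for the
  fractal estimators;
* tumor/necrosis intensity phantoms mimicking the post-contrast T1
  appearance of glioblastoma (bright enhancing rim, dark necrotic core,
  optional re-brightened "island" holes inside the necrosis) — inputs for
  the segmentation stage, with the true necrosis mask returned for scoring;
* survival cohorts with hazard ratios planted on dichotomized fractal
  features — inputs for the survival stage;
* expression matrices with a planted gene subset correlated with
  lacunarity at a chosen strength — inputs for the gene screen.

All generators are bit-reproducible under a fixed seed; random streams are
derived per operation (see :mod:`necrofract.util`), so adding one generator
call does not perturb the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from necrofract.errors import DegeneratePhantomError, ParameterError
from necrofract.util import derive_rng

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_sierpinski_carpet",
    "make_random_cantor",
    "make_tumor_phantom",
    "sample_phantom_specs",
    "make_cohort",
    "make_expression",
    "PLANTED_PREFIX",
]

#: gene-id prefix recording planted (lacunarity-correlated) status
PLANTED_PREFIX = "PLANTED_"

# intensity bands on a [0, 1] scale, mimicking post-contrast T1:
# bright enhancing rim, dark necrotic core, near-black background
RIM_LEVEL = 0.8
NECROSIS_LEVEL = 0.2
BACKGROUND_LEVEL = 0.05
NOISE_SIGMA = 0.05


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single tumor/necrosis phantom.

    ``boundary_roughness`` is the spectral exponent beta of the radial
    boundary perturbation r(theta) = r0 (1 + sum_k a_k cos(k theta + phi_k))
    with harmonic amplitudes a_k proportional to k**(-beta/2); beta = 0
    switches the perturbation off entirely, giving smooth disks.
    ``n_holes`` re-brightened disks are punched out of the necrotic core,
    creating gaps (raising lacunarity and lowering the box-counting
    dimension of the necrosis pattern).
    """

    canvas_size: int = 128
    boundary_roughness: float = 2.5
    n_holes: int = 6
    hole_radius_range: tuple[int, int] = (2, 6)
    necrosis_fraction: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.canvas_size < 32:
            raise ParameterError("canvas_size must be >= 32")
        if not 0.0 < self.necrosis_fraction < 1.0:
            raise ParameterError("necrosis_fraction must lie in (0, 1)")
        if self.n_holes < 0:
            raise ParameterError("n_holes must be >= 0")
        if self.boundary_roughness < 0:
            raise ParameterError("boundary_roughness must be >= 0")
        lo, hi = self.hole_radius_range
        if not 1 <= lo <= hi:
            raise ParameterError("hole_radius_range must satisfy 1 <= min <= max")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a planted-effect survival cohort.

    Hazard ratios act multiplicatively on an exponential baseline for the
    high-lacunarity (``lacunarity > lac_cut``) and low-FD (``fd < fd_cut``)
    groups. ``baseline_hazard`` is in events per day; the default of 1/400
    puts the reference-group median overall survival near 280 days, in the
    ballpark of glioblastoma cohorts.
    """

    n_patients: int = 60
    hr_lacunarity: float = 2.0
    hr_fd: float = 2.0
    baseline_hazard: float = 1.0 / 400.0
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ParameterError("n_patients must be >= 2")
        if self.hr_lacunarity <= 0 or self.hr_fd <= 0:
            raise ParameterError("hazard ratios must be > 0")
        if self.baseline_hazard <= 0:
            raise ParameterError("baseline_hazard must be > 0")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ParameterError("censor_rate must lie in [0, 1)")


# ---------------------------------------------------------------------------
# fractal validation masks
# ---------------------------------------------------------------------------

def make_sierpinski_carpet(order: int) -> np.ndarray:
    """Order-``order`` Sierpinski carpet as a boolean mask.

    The carpet is the canonical exactly-self-similar test pattern for
    box-counting: a 3^order square with 8^order foreground pixels and
    similarity dimension log 8 / log 3 ~ 1.8928.
    """
    if not 1 <= int(order) <= 6:
        raise ParameterError("order must be an integer in [1, 6]")
    cell = np.ones((3, 3), dtype=bool)
    cell[1, 1] = False
    mask = cell.copy()
    for _ in range(int(order) - 1):
        mask = np.kron(mask, cell)
    return mask


def make_random_cantor(
    subdivision_base: int,
    keep_prob: float,
    levels: int,
    seed: int,
) -> np.ndarray:
    """Random Cantor dust by recursive b x b subdivision.

    Each retained cell is subdivided into ``subdivision_base**2`` children,
    each kept independently with probability ``keep_prob``; the expected
    box-count slope is D = log(b^2 p) / log b.  A level that deletes every
    cell is resampled (and flagged with a warning) so the mask is never
    empty.
    """
    b = int(subdivision_base)
    p = float(keep_prob)
    levels = int(levels)
    if b < 2:
        raise ParameterError("subdivision_base must be >= 2")
    if not 0.0 < p <= 1.0:
        raise ParameterError("keep_prob must lie in (0, 1]")
    if levels < 1:
        raise ParameterError("levels must be >= 1")
    if b**2 * p < 1.0:
        raise ParameterError("b^2 * keep_prob must be >= 1 (non-degenerate dust)")
    if b**levels > 1024:
        raise ParameterError("b**levels must not exceed 1024")

    rng = derive_rng(seed, "random_cantor")
    mask = np.ones((1, 1), dtype=bool)
    for level in range(levels):
        expanded = np.kron(mask, np.ones((b, b), dtype=bool))
        for _ in range(1000):
            keep = rng.random(expanded.shape) < p
            new = expanded & keep
            if new.any():
                break
            warnings.warn(
                f"random Cantor dust went extinct at level {level}; resampling",
                RuntimeWarning,
                stacklevel=2,
            )
        else:  # pragma: no cover - p >= 1/b^2 makes this astronomically rare
            raise DegeneratePhantomError("dust extinct after 1000 resampling attempts")
        mask = new
    return mask


# ---------------------------------------------------------------------------
# tumor/necrosis intensity phantoms
# ---------------------------------------------------------------------------

def _star_convex_boundary(
    canvas: int,
    r0: float,
    beta: float,
    rng: np.random.Generator,
    n_harmonics: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Radius map and boundary radius r(theta) of a star-convex region."""
    k = np.arange(2, n_harmonics + 2)
    # amplitude envelope: vanishes at beta=0 (smooth disk), saturates ~0.12
    amp = 0.12 * (beta / (1.0 + beta)) * k ** (-beta / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=k.size)
    c = (canvas - 1) / 2.0
    rows, cols = np.mgrid[0:canvas, 0:canvas]
    theta = np.arctan2(rows - c, cols - c)
    radius = np.hypot(rows - c, cols - c)
    r_theta = r0 * (1.0 + np.sum(amp[:, None, None] * np.cos(k[:, None, None] * theta + phases[:, None, None]), axis=0))
    return radius, r_theta


def make_tumor_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate one post-contrast T1 slice: (intensity, tumor mask, necrosis truth).

    The tumor is a star-convex bright region; the necrotic core is a
    radially scaled copy of the same boundary occupying about
    ``necrosis_fraction`` of the tumor area; ``n_holes`` disks inside the
    core are re-brightened to rim intensity and removed from the truth
    mask. Gaussian noise (sigma 0.05) is added and intensities clipped to
    [0, 1].
    """
    rng = derive_rng(spec.seed, "tumor_phantom")
    n = spec.canvas_size
    r0 = 0.34 * n
    radius, r_theta = _star_convex_boundary(n, r0, spec.boundary_roughness, rng)
    tumor = radius <= r_theta

    # radial scaling of a star-convex region by s scales its area by s^2
    s = float(np.sqrt(spec.necrosis_fraction))
    rows, cols = np.mgrid[0:n, 0:n]
    necrosis = radius <= s * r_theta

    holes = np.zeros_like(necrosis)
    if spec.n_holes > 0:
        idx = np.flatnonzero(necrosis)
        if idx.size:
            centers = idx[rng.integers(0, idx.size, size=spec.n_holes)]
            lo, hi = spec.hole_radius_range
            radii = rng.integers(lo, hi + 1, size=spec.n_holes)
            for flat, radius in zip(centers, radii):
                hr, hc = divmod(int(flat), n)
                disk = (rows - hr) ** 2 + (cols - hc) ** 2 <= int(radius) ** 2
                holes |= disk
    necrosis_truth = necrosis & ~holes
    if not necrosis_truth.any():
        raise DegeneratePhantomError("necrosis region empty after hole punching")

    image = np.full((n, n), BACKGROUND_LEVEL)
    image[tumor] = RIM_LEVEL
    image[necrosis_truth] = NECROSIS_LEVEL
    image += rng.normal(0.0, NOISE_SIGMA, size=image.shape)
    np.clip(image, 0.0, 1.0, out=image)
    return image, tumor, necrosis_truth


def sample_phantom_specs(
    n_patients: int,
    seed: int,
    canvas_size: int = 128,
) -> list[PhantomSpec]:
    """Draw per-patient phantom parameters for a synthetic cohort.

    Patients vary in boundary roughness, necrotic fraction and above all
    in the number and size of holes punched into the core. Hole-riddled
    cores lose box-counting dimension and gain lacunarity, so the cohort
    reproduces the negative FD-lacunarity association seen in real
    necrosis patterns.
    """
    rng = derive_rng(seed, "phantom_specs")
    specs = []
    for i in range(int(n_patients)):
        n_holes = int(rng.integers(0, 15))
        specs.append(
            PhantomSpec(
                canvas_size=canvas_size,
                boundary_roughness=float(rng.uniform(0.5, 4.0)),
                n_holes=n_holes,
                hole_radius_range=(2, int(rng.integers(4, 9))),
                necrosis_fraction=float(rng.uniform(0.2, 0.5)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

def _uniform_censor_bound(rate: float, hazard: float) -> float:
    """Upper limit u of U(0, u) censoring achieving P(C < T) = rate for T ~ Exp(hazard)."""
    # P(censored) = E[exp(-hazard C)] = (1 - exp(-x)) / x with x = hazard*u,
    # which decreases from 1 (u -> 0) to 0 (u -> inf); bracket the root.
    def f(u: float) -> float:
        x = hazard * u
        return (1.0 - np.exp(-x)) / x - rate

    return float(optimize.brentq(f, 1e-9 / hazard, 1e6 / hazard))


def make_cohort(
    spec: CohortSpec,
    features: pd.DataFrame,
    fd_cut: float = 1.56,
    lac_cut: float = 0.46,
) -> pd.DataFrame:
    """Simulate clinical records around measured (or synthetic) fractal features.

    ``features`` must have one row per patient with columns ``fd`` and
    ``lacunarity`` (and optionally ``patient_id``).  Death time is
    exponential with hazard ``h = baseline * hr_fd^[fd<fd_cut] *
    hr_lacunarity^[lac>lac_cut]``; progression is the minimum of death and
    an independent Exp(1.5 h) progression process, so PFS <= OS and both
    endpoints follow exact proportional hazards at the planted ratios
    (the minimum of independent exponentials is exponential). Censoring
    is independent uniform, calibrated to the requested rate. Clinical
    covariates (age, KPS, volume, resection, adjuvant therapy) are drawn
    from simple seeded distributions spanning typical glioblastoma values.
    """
    features = pd.DataFrame(features).reset_index(drop=True)
    if len(features) != spec.n_patients:
        raise ParameterError(
            f"features has {len(features)} rows but spec.n_patients = {spec.n_patients}"
        )
    for col in ("fd", "lacunarity"):
        if col not in features.columns:
            raise ParameterError(f"features table lacks column {col!r}")

    rng = derive_rng(spec.seed, "cohort")
    n = spec.n_patients
    fd = features["fd"].to_numpy(float)
    lac = features["lacunarity"].to_numpy(float)
    hazard = (
        spec.baseline_hazard
        * spec.hr_fd ** (fd < fd_cut)
        * spec.hr_lacunarity ** (lac > lac_cut)
    )

    os_latent = rng.exponential(1.0 / hazard)
    pfs_latent = np.minimum(rng.exponential(1.0 / (1.5 * hazard)), os_latent)

    if spec.censor_rate > 0:
        u = _uniform_censor_bound(spec.censor_rate, float(np.mean(1.5 * hazard)))
        censor = rng.uniform(0.0, u, size=n)
        pfs_event = pfs_latent <= censor
        os_event = os_latent <= censor
        pfs_time = np.minimum(pfs_latent, censor)
        os_time = np.minimum(os_latent, censor)
    else:
        pfs_event = np.ones(n, dtype=bool)
        os_event = np.ones(n, dtype=bool)
        pfs_time = pfs_latent
        os_time = os_latent
    if not os_event.any():
        warnings.warn("all-censored cohort generated", RuntimeWarning, stacklevel=2)

    if "patient_id" in features.columns:
        pid = features["patient_id"].astype(str).to_numpy()
    else:
        pid = np.array([f"P{i:04d}" for i in range(n)])

    cohort = pd.DataFrame(
        {
            "patient_id": pid,
            "age": np.clip(np.round(rng.normal(50, 12, size=n)), 19, 76).astype(int),
            "kps": rng.choice([50, 60, 70, 80, 90, 100], size=n, p=[0.1, 0.2, 0.3, 0.2, 0.15, 0.05]),
            "volume_cm3": np.round(np.exp(rng.normal(np.log(45.0), 0.5, size=n)), 1),
            "gtr_flag": rng.random(n) < 0.56,
            "rt_tmz_flag": rng.random(n) < 0.91,
            "fd": fd,
            "lacunarity": lac,
            "pfs_time": np.maximum(np.round(pfs_time, 1), 0.1),
            "pfs_event": pfs_event,
            "os_time": np.maximum(np.round(os_time, 1), 0.1),
            "os_event": os_event,
        }
    )
    return cohort


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def make_expression(
    n_genes: int,
    n_correlated: int,
    rho: float,
    lacunarity: np.ndarray | pd.Series,
    seed: int,
) -> pd.DataFrame:
    """Genes x patients matrix with ``n_correlated`` genes planted at correlation ``rho``.

    Planted genes are ``rho * z + sqrt(1 - rho^2) * noise`` where ``z`` is
    the standardized lacunarity vector; the rest are independent standard
    normal noise. Planted status is recorded in the gene identifier
    (``PLANTED_*`` vs ``NULL_*``).
    """
    if not 0.0 < rho <= 1.0:
        raise ParameterError("rho must lie in (0, 1]")
    if n_correlated > n_genes:
        raise ParameterError("n_correlated must not exceed n_genes")
    if isinstance(lacunarity, pd.Series):
        patient_ids = [str(i) for i in lacunarity.index]
        lac = lacunarity.to_numpy(float)
    else:
        lac = np.asarray(lacunarity, float)
        patient_ids = [f"P{i:04d}" for i in range(lac.size)]
    if lac.size < 3:
        raise ParameterError("at least 3 patients are required")
    if np.std(lac) == 0:
        raise ParameterError("lacunarity vector has zero variance")

    rng = derive_rng(seed, "expression")
    z = (lac - lac.mean()) / lac.std()
    values = rng.standard_normal((n_genes, lac.size))
    values[:n_correlated] = rho * z + np.sqrt(1.0 - rho**2) * values[:n_correlated]
    gene_ids = [
        f"{PLANTED_PREFIX}{i:05d}" if i < n_correlated else f"NULL_{i:05d}"
        for i in range(n_genes)
    ]
    return pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=patient_ids)
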