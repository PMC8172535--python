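"""Synthetic stroke cohorts with planted ground truth.

Every downstream stage of the pipeline (parcellation, embedding,
regression, relevance reporting) is testable against cohorts generated
here: atlas phantoms on a small grid, territory-structured non-negative
lesion loads whose ``log1p`` has approximate non-negative rank ``n_atoms``,
covariates drawn to match the demographics of a hospital-based acute
ischemic stroke sample (~38% women, age ~65 (15) years, hypertension
~28%, diabetes ~20%, atrial fibrillation ~6% with a higher prevalence in
women, coronary artery disease ~8%), and an NIHSS-like severity outcome
generated from the severity model's own Gaussian linear likelihood with
sex-specific atom coefficients.

The generative chain is::

    scores_true (sparse, log-normal)  @  basis_true (blocky, row-normalized)
        -> log1p-scale lesion pattern  -> integer voxel loads
    z-scored scores_true + covariates -> NIHSS outcome (Gaussian noise)

so that NMF on ``log1p(loads)`` can recover ``basis_true`` and the
hierarchical model can recover the planted sex-specific coefficients from
the emitted oracle model input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .design import COMORBIDITIES, ModelInput
from .parcellation import LesionLoadMatrix
from .scheme import ParcelScheme, canonical_scheme

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_atlas_phantom",
    "generate_paired_atlases",
    "generate_basis",
    "generate_cohort",
    "write_fixture_masks",
]

# Sex-specific defaults follow the derivation-cohort characteristics table
# (female / male): hypertension 29.3/27.4%, diabetes 17.8/20.5%, atrial
# fibrillation 9.1/4.6%, coronary artery disease 6.7/8.1%.
_DEFAULT_PREVALENCES = {
    "hypertension": {"female": 0.293, "male": 0.274},
    "diabetes": {"female": 0.178, "male": 0.205},
    "atrial_fibrillation": {"female": 0.091, "male": 0.046},
    "coronary_artery_disease": {"female": 0.067, "male": 0.081},
}

# Default planted sex-specific atom effects (NIHSS units per unit z-score):
# a handful of atoms relevant in both sexes, several female-only effects,
# echoing the widespread-in-women pattern the model is built to detect.
_DEFAULT_BETA_FEMALE = (1.2, 0.0, 0.0, 2.6, 1.5, 0.0, 4.8, 7.0, 3.4, 2.0)
_DEFAULT_BETA_MALE = (0.0, 1.5, 0.0, 1.9, 0.0, 1.2, 3.2, 2.4, 0.0, 0.0)

_DEFAULT_COVARIATE_EFFECTS = {
    "age": 1.0, "age_sq": 0.3, "sex": 0.5, "hypertension": 0.3,
    "diabetes": 0.3, "atrial_fibrillation": 0.5,
    "coronary_artery_disease": 0.3, "log_wmhv": 0.4,
}


@dataclass
class SimConfig:
    """Ground-truth configuration of a synthetic cohort.

    Defaults mirror the demographics of a ~555-patient hospital cohort
    (38% women; female age 67.7 (16.3), male age 63.3 (13.5) years) with
    sex-specific comorbidity prevalences, ten lesion atoms over 129
    parcels, and a Gaussian severity likelihood with noise_sd in NIHSS
    units.
    """

    n_patients: int = 555
    frac_female: float = 0.38
    age_mean_f: float = 67.7
    age_sd_f: float = 16.3
    age_mean_m: float = 63.3
    age_sd_m: float = 13.5
    comorbidity_prevalences: dict = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in _DEFAULT_PREVALENCES.items()})
    n_atoms: int = 10
    n_parcels: int = 129
    beta_female: tuple | None = None
    beta_male: tuple | None = None
    covariate_effects: dict = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATE_EFFECTS))
    intercept: float = 4.0
    noise_sd: float = 2.0
    wmhv_mean_ml: float = 11.5
    wmhv_sd_ml: float = 13.5
    score_log_mean: float = 2.3
    score_log_sd: float = 0.5
    load_log_noise_sd: float = 0.05
    load_log_cap: float = 11.5  # caps single-parcel loads at ~100k voxels
    voxel_volume_ml: float = 0.001
    clip_outcome: bool = False
    seed: int = 0
    basis_seed: int | None = None  # shared across "twin" cohorts

    def __post_init__(self) -> None:
        if self.beta_female is None:
            self.beta_female = (_DEFAULT_BETA_FEMALE
                                if self.n_atoms == 10
                                else (0.0,) * self.n_atoms)
        if self.beta_male is None:
            self.beta_male = (_DEFAULT_BETA_MALE
                              if self.n_atoms == 10
                              else (0.0,) * self.n_atoms)
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_atoms < 1 or self.n_parcels < 1:
            raise ValueError("n_patients, n_atoms, n_parcels must be positive")
        if not 0 < self.frac_female < 1:
            raise ValueError("frac_female must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name, prev in self.comorbidity_prevalences.items():
            vals = (prev.values() if isinstance(prev, dict) else [prev])
            for v in vals:
                if not 0 < v < 1:
                    raise ValueError(f"prevalence of {name} must be in (0,1)")
        for vec, name in ((self.beta_female, "beta_female"),
                          (self.beta_male, "beta_male")):
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (self.n_atoms,):
                raise ValueError(f"{name} must have length n_atoms")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        scalars = [self.age_mean_f, self.age_sd_f, self.age_mean_m,
                   self.age_sd_m, self.intercept, self.noise_sd,
                   self.wmhv_mean_ml, self.wmhv_sd_ml,
                   *self.covariate_effects.values()]
        if not np.all(np.isfinite(scalars)):
            raise ValueError("config contains non-finite values")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SyntheticTruth:
    """Planted ground truth of one synthetic cohort.

    ``beta_true`` rows are indexed [male, female].  ``oracle_input`` is the
    exact design used to build the outcome (z-scored true scores and
    covariates), against which coefficient recovery is exact up to
    posterior uncertainty; end-to-end runs from raw loads are subject to
    NMF scale/rotation indeterminacy and are only checked qualitatively.
    """

    basis_true: np.ndarray = field(repr=False)
    scores_true: np.ndarray = field(repr=False)
    beta_true: np.ndarray = field(repr=False)
    covariate_beta_true: np.ndarray = field(repr=False)
    intercept_true: float = 0.0
    noise_sd_true: float = 1.0
    oracle_input: ModelInput | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if np.any(self.basis_true < 0) or np.any(self.scores_true < 0):
            raise ValueError("planted basis and scores must be non-negative")

    def to_json(self, path) -> None:
        payload = {
            "basis_true": self.basis_true.tolist(),
            "scores_true": self.scores_true.tolist(),
            "beta_true": self.beta_true.tolist(),
            "covariate_beta_true": self.covariate_beta_true.tolist(),
            "intercept_true": self.intercept_true,
            "noise_sd_true": self.noise_sd_true,
        }
        Path(path).write_text(json.dumps(payload))


def _partition_box(labels: np.ndarray, origin: tuple, shape: tuple,
                   block_labels: list[int]) -> None:
    """Recursively split a box into len(block_labels) contiguous blocks."""
    n = len(block_labels)
    if n == 1:
        sl = tuple(slice(o, o + s) for o, s in zip(origin, shape))
        labels[sl] = block_labels[0]
        return
    n1 = n // 2
    n2 = n - n1
    axis = int(np.argmax(shape))
    extent = shape[axis]
    other = int(np.prod(shape)) // extent
    target = extent * n1 / n
    # candidate split points ordered by closeness to the proportional split
    candidates = sorted(range(1, extent),
                        key=lambda s: (abs(s - target), s))
    for s1 in candidates:
        if s1 * other >= n1 and (extent - s1) * other >= n2:
            break
    else:  # pragma: no cover - guarded by caller's voxel-count check
        raise ValueError("cannot split box to hold all regions")
    shape_a = list(shape)
    shape_a[axis] = s1
    shape_b = list(shape)
    shape_b[axis] = extent - s1
    origin_b = list(origin)
    origin_b[axis] += s1
    _partition_box(labels, origin, tuple(shape_a), block_labels[:n1])
    _partition_box(labels, tuple(origin_b), tuple(shape_b), block_labels[n1:])


def generate_atlas_phantom(grid_dims, n_regions: int,
                           seed: int = 0) -> tuple[np.ndarray, ParcelScheme]:
    """Partition a grid into ``n_regions`` contiguous labeled blocks.

    Every voxel receives a label in 1..n_regions (no background); each
    region is a contiguous axis-aligned block and occurs at least once.
    The seed permutes the spatial assignment of labels.
    """
    grid_dims = tuple(int(d) for d in grid_dims)
    if len(grid_dims) != 3 or any(d < 2 for d in grid_dims):
        raise ValueError("grid_dims must be 3 integers, each >= 2")
    n_voxels = int(np.prod(grid_dims))
    if n_regions < 1 or n_regions > n_voxels:
        raise ValueError(
            f"n_regions={n_regions} exceeds voxel count {n_voxels}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(np.arange(1, n_regions + 1)))
    labels = np.zeros(grid_dims, dtype=np.int32)
    _partition_box(labels, (0, 0, 0), grid_dims, [int(v) for v in order])

    table = pd.DataFrame({
        "parcel_id": np.arange(1, n_regions + 1),
        "name": [f"Region {k}" for k in range(1, n_regions + 1)],
        "hemisphere": "bilateral",
        "tissue": "gm_cortical",
        "atlas_label": np.arange(1, n_regions + 1),
        "source_atlas": "gm",
    })
    return labels, ParcelScheme(table)


def generate_paired_atlases(grid_dims, scheme: ParcelScheme | None = None,
                            seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Phantom gray-matter and white-matter label volumes on one grid.

    The grid is split into two disjoint slabs along the last axis: the
    lower slab is partitioned into the scheme's gm parcels, the upper slab
    into its wm tracts.  Disjointness makes the fixture-mask round trip
    exact; the readout itself also supports overlapping atlases.
    """
    scheme = scheme or canonical_scheme()
    grid_dims = tuple(int(d) for d in grid_dims)
    n_gm = len(scheme.subset("gm"))
    n_wm = len(scheme.subset("wm"))
    nz = grid_dims[2]
    z_split = max(1, min(nz - 1, int(round(nz * n_gm / (n_gm + n_wm)))))
    gm_dims = (grid_dims[0], grid_dims[1], z_split)
    wm_dims = (grid_dims[0], grid_dims[1], nz - z_split)
    if int(np.prod(gm_dims)) < n_gm or int(np.prod(wm_dims)) < n_wm:
        raise ValueError("grid too small for the requested scheme")
    gm_block, _ = generate_atlas_phantom(gm_dims, n_gm, seed)
    wm_block, _ = generate_atlas_phantom(wm_dims, n_wm, seed + 1)
    gm_labels = np.asarray(scheme.subset("gm")["atlas_label"])
    wm_labels = np.asarray(scheme.subset("wm")["atlas_label"])
    gm = np.zeros(grid_dims, dtype=np.int32)
    wm = np.zeros(grid_dims, dtype=np.int32)
    gm[:, :, :z_split] = gm_labels[gm_block - 1]
    wm[:, :, z_split:] = wm_labels[wm_block - 1]
    return gm, wm


def generate_basis(n_atoms: int, n_parcels: int, block_structure: bool = True,
                   seed: int = 0) -> np.ndarray:
    """Non-negative atom basis with L2-normalized rows.

    With ``block_structure`` each atom's support is a contiguous block of
    parcels (a crude stand-in for a vascular territory) overlapping its
    neighbours by at most 30% of the block length, keeping pairwise row
    cosines small.
    """
    if n_atoms < 1 or n_parcels < 1:
        raise ValueError("n_atoms and n_parcels must be positive")
    if n_atoms > n_parcels:
        raise ValueError(f"n_atoms={n_atoms} exceeds n_parcels={n_parcels}")
    rng = np.random.default_rng(seed)
    basis = np.zeros((n_atoms, n_parcels))
    if block_structure:
        edges = np.round(np.linspace(0, n_parcels, n_atoms + 1)).astype(int)
        for k in range(n_atoms):
            start, end = edges[k], edges[k + 1]
            length = end - start
            overlap = int(0.15 * length)
            lo = max(0, start - overlap)
            hi = min(n_parcels, end + overlap)
            basis[k, lo:hi] = rng.lognormal(0.0, 0.5, hi - lo)
            # taper the overlap region so shared parcels carry little mass
            if lo < start:
                basis[k, lo:start] *= 0.2
            if hi > end:
                basis[k, end:hi] *= 0.2
    else:
        basis = rng.lognormal(0.0, 0.5, (n_atoms, n_parcels))
    norms = np.linalg.norm(basis, axis=1, keepdims=True)
    return basis / norms


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame,
                                                LesionLoadMatrix,
                                                SyntheticTruth]:
    """Draw a synthetic cohort from the planted generative model.

    Returns the clinical table, the integer lesion-load matrix and the
    :class:`SyntheticTruth` (including the oracle model input actually used
    to build the outcome).  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    k = config.n_atoms

    sex = rng.binomial(1, config.frac_female, n)  # female = 1
    age = np.empty(n)
    for s, (mu, sd) in ((1, (config.age_mean_f, config.age_sd_f)),
                        (0, (config.age_mean_m, config.age_sd_m))):
        idx = sex == s
        a, b = (18.0 - mu) / sd, (100.0 - mu) / sd
        age[idx] = stats.truncnorm.rvs(a, b, loc=mu, scale=sd,
                                       size=int(idx.sum()), random_state=rng)

    comorb = {}
    for name in COMORBIDITIES:
        prev = config.comorbidity_prevalences[name]
        if isinstance(prev, dict):
            p = np.where(sex == 1, prev["female"], prev["male"])
        else:
            p = np.full(n, prev)
        comorb[name] = rng.binomial(1, p)

    basis_seed = (config.basis_seed if config.basis_seed is not None
                  else config.seed + 10_000)
    basis_true = generate_basis(k, config.n_parcels, True, seed=basis_seed)
    scores_true = np.zeros((n, k))
    n_dominant = rng.integers(1, 3, n)  # 1 or 2 dominant atoms per patient
    for i in range(n):
        atoms = rng.choice(k, size=n_dominant[i], replace=False)
        scores_true[i, atoms] = rng.lognormal(config.score_log_mean,
                                              config.score_log_sd,
                                              n_dominant[i])

    log_pattern = scores_true @ basis_true
    noisy = log_pattern + rng.normal(0.0, config.load_log_noise_sd,
                                     log_pattern.shape)
    noisy = np.clip(noisy, None, config.load_log_cap)
    loads = np.rint(np.expm1(noisy)).clip(min=0).astype(np.int64)

    scheme = canonical_scheme() if config.n_parcels == 129 else \
        _generic_scheme(config.n_parcels)
    load_matrix = LesionLoadMatrix(
        patient_ids=[f"sub-{i:04d}" for i in range(n)],
        values=loads, scheme=scheme,
        voxel_volume_ml=config.voxel_volume_ml)
    lesion_volume = loads.sum(axis=1) * config.voxel_volume_ml

    mu_w, sd_w = _lognormal_params(config.wmhv_mean_ml, config.wmhv_sd_ml)
    wmhv = rng.lognormal(mu_w, sd_w, n)

    # oracle design: the exact standardized scores used to build the outcome
    score_sd = scores_true.std(axis=0)
    score_sd[score_sd == 0] = 1.0
    z_scores = (scores_true - scores_true.mean(axis=0)) / score_sd
    age_z = (age - age.mean()) / age.std()
    log_wmhv = np.log1p(wmhv)
    ce = config.covariate_effects
    covariate_beta = np.array([
        ce.get("age", 0.0), ce.get("age_sq", 0.0), ce.get("sex", 0.0),
        ce.get("hypertension", 0.0), ce.get("diabetes", 0.0),
        ce.get("atrial_fibrillation", 0.0),
        ce.get("coronary_artery_disease", 0.0), ce.get("log_wmhv", 0.0),
    ])
    covars = np.column_stack([
        age_z, age_z ** 2, sex, comorb["hypertension"], comorb["diabetes"],
        comorb["atrial_fibrillation"], comorb["coronary_artery_disease"],
        log_wmhv,
    ])
    beta_true = np.vstack([config.beta_male, config.beta_female])
    atom_effect = np.where(sex[:, None] == 1,
                           z_scores * beta_true[1],
                           z_scores * beta_true[0]).sum(axis=1)
    nihss = (config.intercept + atom_effect + covars @ covariate_beta
             + rng.normal(0.0, config.noise_sd, n))
    if config.clip_outcome:
        nihss = np.clip(np.rint(nihss), 0, 42)

    cohort = pd.DataFrame({
        "patient_id": load_matrix.patient_ids,
        "sex": sex,
        "age": age,
        **comorb,
        "wmh_volume_ml": wmhv,
        "lesion_volume_ml": lesion_volume,
        "nihss": nihss,
    })

    # the regression consumes a volume-residualized (hence mean-centered)
    # outcome, matching its Normal(0, 1) intercept prior; the oracle input
    # mirrors that by centering while keeping the exact planted scores
    oracle = ModelInput(
        outcome=nihss - nihss.mean(), atom_scores=z_scores, age_z=age_z,
        age_z_sq=age_z ** 2, sex=sex.astype(float),
        hypertension=comorb["hypertension"].astype(float),
        diabetes=comorb["diabetes"].astype(float),
        atrial_fibrillation=comorb["atrial_fibrillation"].astype(float),
        coronary_artery_disease=comorb["coronary_artery_disease"]
            .astype(float),
        log_wmhv=log_wmhv,
    )
    truth = SyntheticTruth(
        basis_true=basis_true, scores_true=scores_true, beta_true=beta_true,
        covariate_beta_true=covariate_beta,
        intercept_true=config.intercept, noise_sd_true=config.noise_sd,
        oracle_input=oracle,
    )
    return cohort, load_matrix, truth


def _generic_scheme(n_parcels: int) -> ParcelScheme:
    """All-gm scheme used when the parcel count is not the canonical 129."""
    table = pd.DataFrame({
        "parcel_id": np.arange(1, n_parcels + 1),
        "name": [f"Parcel {j}" for j in range(1, n_parcels + 1)],
        "hemisphere": "bilateral",
        "tissue": "gm_cortical",
        "atlas_label": np.arange(1, n_parcels + 1),
        "source_atlas": "gm",
    })
    return ParcelScheme(table)


def write_fixture_masks(loads: LesionLoadMatrix, gm_atlas: np.ndarray,
                        wm_atlas: np.ndarray, out_dir, seed: int = 0,
                        affine: np.ndarray | None = None) -> list[Path]:
    """Write per-patient binary NIfTI masks realizing a load matrix.

    For every patient and parcel, exactly ``loads[i, j]`` voxels are
    lesioned inside parcel ``j`` (a seeded random subset of the parcel's
    voxels).  On disjoint gm/wm phantom atlases the round trip through
    :func:`~lesionatoms.parcellation.compute_lesion_loads` reproduces the
    matrix exactly.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else np.asarray(affine)
    rng = np.random.default_rng(seed)
    scheme = loads.scheme

    atlases = {"gm": np.asarray(gm_atlas), "wm": np.asarray(wm_atlas)}
    parcel_voxels = []  # one entry per scheme row, in canonical column order
    for _, row in scheme.table.iterrows():
        atlas = atlases[row["source_atlas"]]
        flat = np.flatnonzero(atlas.ravel() == row["atlas_label"])
        parcel_voxels.append((row["parcel_id"], flat))

    grid = atlases["gm"].shape
    paths = []
    for i, pid in enumerate(loads.patient_ids):
        flat_mask = np.zeros(int(np.prod(grid)), dtype=np.uint8)
        for j, (parcel_id, voxels) in enumerate(parcel_voxels):
            count = int(loads.values[i, j])
            if count == 0:
                continue
            if count > voxels.size:
                raise ValueError(
                    f"patient {pid}: requested {count} voxels in parcel "
                    f"{parcel_id} but it has only {voxels.size}")
            chosen = rng.choice(voxels, size=count, replace=False)
            flat_mask[chosen] = 1
        img = nib.Nifti1Image(flat_mask.reshape(grid), affine)
        path = out_dir / f"{pid}_mask.nii.gz"
        nib.save(img, path)
        paths.append(path)
    return paths
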