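"""Region- and tract-wise lesion-load readout from binary lesion masks.

A lesion mask is a binary volume on the same grid as two integer label
atlases (one gray-matter, one white-matter).  The readout counts lesioned
voxels per parcel of a :class:`~lesionatoms.scheme.ParcelScheme`.  The two
atlases are independent label volumes, so one lesioned voxel may count
toward one gray-matter region *and* one white-matter tract (dual counting);
background voxels (label 0) count nowhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scheme import ParcelScheme

__all__ = [
    "LesionLoadMatrix",
    "compute_lesion_loads",
    "lesion_volume_ml",
    "region_group_comparison",
]


@dataclass
class LesionLoadMatrix:
    """Patients x parcels matrix of lesioned-voxel counts.

    ``values[i, j]`` is the number of lesioned voxels of patient
    ``patient_ids[i]`` inside parcel ``j`` of ``scheme`` (canonical column
    order).  ``voxel_volume_ml`` converts counts to milliliters.
    """

    patient_ids: list
    values: np.ndarray = field(repr=False)
    scheme: ParcelScheme = field(repr=False)
    voxel_volume_ml: float = 0.001

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (patients x parcels)")
        if len(self.patient_ids) != self.values.shape[0]:
            raise ValueError("patient_ids length must match rows of values")
        if self.values.shape[1] != self.scheme.n_parcels:
            raise ValueError(
                f"values has {self.values.shape[1]} columns but scheme has "
                f"{self.scheme.n_parcels} parcels")
        if np.any(self.values < 0):
            raise ValueError("lesion loads must be non-negative")
        if self.voxel_volume_ml <= 0:
            raise ValueError("voxel_volume_ml must be positive")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    def lesion_volumes_ml(self) -> np.ndarray:
        """Per-patient lesion volume: row sum of loads x voxel volume.

        Under gm/wm dual counting this can exceed the true voxel-wise
        volume; on disjoint phantom atlases it is exact.
        """
        return self.values.sum(axis=1) * self.voxel_volume_ml

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, index=pd.Index(self.patient_ids,
                                                      name="patient_id"),
                          columns=self.scheme.names)
        df.insert(0, "voxel_volume_ml", self.voxel_volume_ml)
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, scheme: ParcelScheme) -> "LesionLoadMatrix":
        df = pd.read_csv(path, index_col=0)
        vox = float(df.pop("voxel_volume_ml").iloc[0])
        return cls(list(df.index), df.to_numpy(), scheme, vox)


def _check_binary(mask: np.ndarray, what: str = "mask") -> np.ndarray:
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{what} must be strictly binary (0/1); "
                         f"found values {vals[:5]}")
    return mask.astype(bool)


def compute_lesion_loads(
    mask: np.ndarray,
    gm_atlas: np.ndarray,
    wm_atlas: np.ndarray,
    scheme: ParcelScheme,
    *,
    gm_affine: np.ndarray | None = None,
    wm_affine: np.ndarray | None = None,
    mask_affine: np.ndarray | None = None,
    atol: float = 1e-4,
) -> np.ndarray:
    """Count lesioned voxels per parcel.

    Parameters
    ----------
    mask : binary 3-D array
    gm_atlas, wm_atlas : integer 3-D label arrays on the same grid
    scheme : ParcelScheme mapping parcels to (source_atlas, atlas_label)
    gm_affine, wm_affine, mask_affine : optional 4x4 affines; when given,
        all pairs must agree within ``atol`` elementwise.

    Returns
    -------
    numpy.ndarray
        Integer vector of length ``scheme.n_parcels`` in canonical order.
    """
    mask = _check_binary(mask)
    gm_atlas = np.asarray(gm_atlas)
    wm_atlas = np.asarray(wm_atlas)
    for name, vol in (("gm_atlas", gm_atlas), ("wm_atlas", wm_atlas)):
        if vol.shape != mask.shape:
            raise ValueError(
                f"grid mismatch: {name} shape {vol.shape} vs mask "
                f"shape {mask.shape}")
    affines = {"mask": mask_affine, "gm_atlas": gm_affine,
               "wm_atlas": wm_affine}
    given = {k: np.asarray(v) for k, v in affines.items() if v is not None}
    if len(given) > 1:
        ref_name, ref = next(iter(given.items()))
        for name, aff in given.items():
            if not np.allclose(aff, ref, atol=atol):
                raise ValueError(
                    f"affine mismatch between {ref_name} and {name}")

    loads = np.zeros(scheme.n_parcels, dtype=np.int64)
    for src, atlas in (("gm", gm_atlas), ("wm", wm_atlas)):
        sub = scheme.subset(src)
        lesioned_labels = atlas[mask]
        counts = np.bincount(lesioned_labels.ravel(),
                             minlength=int(atlas.max()) + 2)
        for idx, label in zip(sub.index, sub["atlas_label"]):
            pos = scheme.table.index.get_loc(idx)
            if label < len(counts):
                loads[pos] = counts[label]
    return loads


def lesion_volume_ml(mask: np.ndarray, voxel_dims_mm) -> float:
    """Lesion volume in milliliters: voxel count x voxel volume / 1000."""
    voxel_dims_mm = np.asarray(voxel_dims_mm, dtype=float)
    if voxel_dims_mm.shape != (3,) or np.any(voxel_dims_mm <= 0):
        raise ValueError("voxel_dims_mm must be 3 positive scalars (mm)")
    mask = _check_binary(mask)
    return float(mask.sum()) * float(np.prod(voxel_dims_mm)) / 1000.0


def region_group_comparison(
    loads: LesionLoadMatrix,
    group_labels: np.ndarray,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Per-parcel group comparison of lesion frequency and lesion load.

    For each parcel: a two-sided Fisher exact test on affected-vs-not
    (load > 0) by group, and a two-sided two-sample t test on the loads of
    all patients.  With Bonferroni correction the per-test threshold is
    ``alpha / n_parcels`` for each test family.

    Returns a DataFrame with raw p-values and significance flags.
    """
    group_labels = np.asarray(group_labels).astype(int)
    if group_labels.shape != (loads.n_patients,):
        raise ValueError("group_labels must have one entry per patient")
    if len(np.unique(group_labels)) != 2:
        raise ValueError("group_labels must contain exactly two groups")
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")

    n_tests = loads.scheme.n_parcels
    threshold = alpha / n_tests if correction == "bonferroni" else alpha
    g1 = group_labels == 1
    g0 = ~g1
    rows = []
    for j in range(n_tests):
        col = loads.values[:, j]
        affected = col > 0
        table = [[int((affected & g1).sum()), int((~affected & g1).sum())],
                 [int((affected & g0).sum()), int((~affected & g0).sum())]]
        _, p_freq = stats.fisher_exact(table, alternative="two-sided")
        if np.all(col[g1] == col[g1][0]) and np.all(col[g0] == col[g0][0]) \
                and col[g1][0] == col[g0][0]:
            p_load = 1.0  # identical constant loads carry no evidence
        else:
            _, p_load = stats.ttest_ind(col[g1], col[g0], equal_var=True)
            p_load = 1.0 if np.isnan(p_load) else float(p_load)
        rows.append({
            "parcel_id": int(loads.scheme.table["parcel_id"].iloc[j]),
            "frequency_test_p": float(p_freq),
            "load_test_p": float(p_load),
            "significant_after_correction": bool(p_freq < threshold
                                                 or p_load < threshold),
        })
    return pd.DataFrame(rows)
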