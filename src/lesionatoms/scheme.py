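"""Canonical parcel scheme for region- and tract-wise lesion readout.

The readout grid used throughout the package is a fixed set of 129 parcels:
109 gray-matter parcels (47 cortical and 7 subcortical regions per
hemisphere, plus the brainstem) read from a gray-matter atlas, and 20
white-matter tracts (7 hemisphere-specific tract pairs plus 6
bilateral/midline tracts) read from a separate tract atlas.  A parcel scheme
maps each readout column to its atlas label, hemisphere and tissue class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["ParcelScheme", "canonical_scheme"]

_CORTICAL_NAMES = [
    "Frontal Pole",
    "Insular Cortex",
    "Superior Frontal Gyrus",
    "Middle Frontal Gyrus",
    "Inferior Frontal Gyrus, pars triangularis",
    "Inferior Frontal Gyrus, pars opercularis",
    "Precentral Gyrus",
    "Temporal Pole",
    "Superior Temporal Gyrus, anterior division",
    "Superior Temporal Gyrus, posterior division",
    "Middle Temporal Gyrus, anterior division",
    "Middle Temporal Gyrus, posterior division",
    "Middle Temporal Gyrus, temporooccipital part",
    "Inferior Temporal Gyrus, anterior division",
    "Inferior Temporal Gyrus, posterior division",
    "Inferior Temporal Gyrus, temporooccipital part",
    "Postcentral Gyrus",
    "Superior Parietal Lobule",
    "Supramarginal Gyrus, anterior division",
    "Supramarginal Gyrus, posterior division",
    "Angular Gyrus",
    "Lateral Occipital Cortex, superior division",
    "Lateral Occipital Cortex, inferior division",
    "Intracalcarine Cortex",
    "Frontal Medial Cortex",
    "Juxtapositional Lobule Cortex",
    "Subcallosal Cortex",
    "Paracingulate Gyrus",
    "Cingulate Gyrus, anterior division",
    "Cingulate Gyrus, posterior division",
    "Precuneous Cortex",
    "Cuneal Cortex",
    "Frontal Orbital Cortex",
    "Parahippocampal Gyrus, anterior division",
    "Parahippocampal Gyrus, posterior division",
    "Lingual Gyrus",
    "Temporal Fusiform Cortex, anterior division",
    "Temporal Fusiform Cortex, posterior division",
    "Temporal Occipital Fusiform Cortex",
    "Occipital Fusiform Gyrus",
    "Frontal Operculum Cortex",
    "Central Opercular Cortex",
    "Parietal Operculum Cortex",
    "Planum Polare",
    "Heschl's Gyrus",
    "Planum Temporale",
    "Occipital Pole",
]

_SUBCORTICAL_NAMES = [
    "Thalamus",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens",
]

_TRACT_PAIRED = [
    "Anterior thalamic radiation",
    "Corticospinal tract",
    "Cingulum (cingulate gyrus)",
    "Cingulum (hippocampus)",
    "Inferior fronto-occipital fasciculus",
    "Inferior longitudinal fasciculus",
    "Superior longitudinal fasciculus",
]

_TRACT_BILATERAL = [
    "Forceps major",
    "Forceps minor",
    "Uncinate fasciculus",
    "Superior longitudinal fasciculus (temporal part)",
    "Corpus callosum (body)",
    "Middle cerebellar peduncle",
]


@dataclass(frozen=True)
class ParcelScheme:
    """Mapping from readout columns to atlas labels.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per parcel with columns ``parcel_id``, ``name``,
        ``hemisphere`` (left/right/bilateral/midline), ``tissue``
        (gm_cortical/gm_subcortical/brainstem/wm_tract), ``atlas_label``
        and ``source_atlas`` (gm/wm).  Row order is the canonical column
        order of every lesion-load matrix.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"parcel_id", "name", "hemisphere", "tissue",
                    "atlas_label", "source_atlas"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"scheme table missing columns {sorted(missing)}")
        if self.table["parcel_id"].duplicated().any():
            raise ValueError("parcel_ids must be unique")
        for src, grp in self.table.groupby("source_atlas"):
            if grp["atlas_label"].duplicated().any():
                raise ValueError(f"atlas_label not unique within '{src}' atlas")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def names(self) -> list[str]:
        return list(self.table["name"])

    def subset(self, source_atlas: str) -> pd.DataFrame:
        """Rows read from one source atlas, in canonical order."""
        return self.table[self.table["source_atlas"] == source_atlas]

    def counts_by_tissue(self) -> dict[str, int]:
        return self.table["tissue"].value_counts().to_dict()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ParcelScheme":
        return cls(pd.read_csv(path))


def canonical_scheme() -> ParcelScheme:
    """Build the canonical 129-parcel scheme.

    Returns a scheme with 47 cortical + 7 subcortical gray-matter parcels
    per hemisphere, one brainstem parcel (109 gray-matter parcels in total,
    gm atlas labels 1..109) and 20 white-matter tracts (wm atlas labels
    1..20): seven left/right tract pairs and six bilateral or midline
    tracts.
    """
    rows = []
    gm_label = 0
    for hemi in ("left", "right"):
        for name in _CORTICAL_NAMES:
            gm_label += 1
            rows.append((f"{name} ({hemi[0].upper()})", hemi, "gm_cortical",
                         gm_label, "gm"))
        for name in _SUBCORTICAL_NAMES:
            gm_label += 1
            rows.append((f"{name} ({hemi[0].upper()})", hemi,
                         "gm_subcortical", gm_label, "gm"))
    gm_label += 1
    rows.append(("Brainstem", "midline", "brainstem", gm_label, "gm"))

    wm_label = 0
    for hemi in ("left", "right"):
        for name in _TRACT_PAIRED:
            wm_label += 1
            rows.append((f"{name} ({hemi[0].upper()})", hemi, "wm_tract",
                         wm_label, "wm"))
    for name in _TRACT_BILATERAL:
        wm_label += 1
        rows.append((name, "bilateral", "wm_tract", wm_label, "wm"))

    table = pd.DataFrame(rows, columns=["name", "hemisphere", "tissue",
                                        "atlas_label", "source_atlas"])
    table.insert(0, "parcel_id", range(1, len(table) + 1))
    return ParcelScheme(table)
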