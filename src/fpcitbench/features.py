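"""SBR computation and ML feature families from phantom volumes.

Three feature families feed the classifiers downstream:

* ``sbrs`` — the four regional striatal binding ratios plus age, straight
  from the cohort table;
* ``voxels`` — occipitally scaled, worst-side-flipped voxel intensities
  inside the loose striatal mask, plus age;
* ``pcs`` — the same voxel matrix, to be projected onto principal
  components inside each training fold (the projection itself is fitted by
  the classifier so no test information leaks into it).

The SBR of a region is (mean target uptake − mean reference uptake) /
mean reference uptake, with the occipital lobe as reference.  Flipping
mirrors a volume about the mid-sagittal plane whenever the left striatum is
not the side with the lowest summed uptake, so disease always presents on
the same side of the image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    DegenerateReferenceError,
    InvalidGeometryError,
    InvalidParameterError,
    MissingInputError,
)
from .synth import REGIONS, Cohort, PhantomVolume

__all__ = [
    "FeatureSet",
    "FEATURE_KINDS",
    "compute_sbr",
    "scale_to_occipital",
    "flip_if_needed",
    "extract_features",
    "sbr_table",
]

FEATURE_KINDS = ("sbrs", "voxels", "pcs")

#: column order of the SBR feature family (age last, like every family)
SBR_FEATURE_COLUMNS = tuple(f"sbr_{r}" for r in REGIONS) + ("age",)


@dataclass
class FeatureSet:
    """A subjects × features matrix with provenance metadata."""

    matrix: pd.DataFrame  # index = subject ids, columns = feature names
    feature_kind: str
    age_included: bool = True

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise InvalidParameterError(f"unknown feature kind {self.feature_kind!r}")
        if self.matrix.isna().any().any():
            raise InvalidParameterError("feature matrix contains missing values")

    @property
    def feature_names(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path, index_label="id")


def _occipital_mean(volume: PhantomVolume) -> float:
    occ = volume.masks["occipital"]
    if not occ.any():
        raise DegenerateReferenceError("occipital mask is empty")
    mean = float(volume.data[occ].mean())
    if mean <= 0:
        raise DegenerateReferenceError(f"occipital mean uptake {mean} is not positive")
    return mean


def compute_sbr(volume: PhantomVolume, region: str) -> float:
    """Specific binding ratio of ``region`` against the occipital reference."""
    if region not in volume.masks:
        raise InvalidParameterError(f"unknown region {region!r}")
    mask = volume.masks[region]
    if not mask.any():
        raise InvalidParameterError(f"region mask {region!r} is empty")
    ref = _occipital_mean(volume)
    target = float(volume.data[mask].mean())
    return (target - ref) / ref


def scale_to_occipital(volume: PhantomVolume) -> PhantomVolume:
    """Divide every voxel by the occipital ROI mean (output reference mean = 1)."""
    ref = _occipital_mean(volume)
    return PhantomVolume(
        data=volume.data / ref,
        voxel_size_mm=volume.voxel_size_mm,
        masks={k: v.copy() for k, v in volume.masks.items()},
    )


def flip_if_needed(volume: PhantomVolume) -> tuple[PhantomVolume, bool]:
    """Mirror the volume so the worst (lowest-uptake) striatum sits on the left.

    The left/right comparison sums uptake over putamen ∪ caudate per side.
    Exact ties are left unflipped.  Requires the mask layout to be
    mirror-symmetric about the mid-sagittal plane (axis 0).
    """
    m = volume.masks
    left = m["l_putamen"] | m["l_caudate"]
    right = m["r_putamen"] | m["r_caudate"]
    if not (left.any() and right.any()):
        raise InvalidGeometryError("both striatal sides must have non-empty masks")
    for l_name, r_name in (("l_putamen", "r_putamen"), ("l_caudate", "r_caudate")):
        if not np.array_equal(np.flip(m[l_name], axis=0), m[r_name]):
            raise InvalidGeometryError(
                f"masks {l_name}/{r_name} are not mirror images; cannot flip"
            )
    for name in ("occipital", "striatal_loose"):
        if not np.array_equal(np.flip(m[name], axis=0), m[name]):
            raise InvalidGeometryError(f"mask {name} is not mirror-symmetric; cannot flip")

    left_sum = float(volume.data[left].sum())
    right_sum = float(volume.data[right].sum())
    if left_sum <= right_sum:
        return volume, False
    flipped = PhantomVolume(
        data=np.flip(volume.data, axis=0).copy(),
        voxel_size_mm=volume.voxel_size_mm,
        masks={k: v.copy() for k, v in m.items()},
    )
    return flipped, True


VolumeSource = Mapping[str, PhantomVolume] | Callable[[str], PhantomVolume]


def _get_volume(volumes: VolumeSource, subject_id: str) -> PhantomVolume:
    if volumes is None:
        raise MissingInputError(f"volumes required but not provided (subject {subject_id})")
    if callable(volumes):
        vol = volumes(subject_id)
    else:
        vol = volumes.get(subject_id)
    if vol is None:
        raise MissingInputError(f"no volume for subject {subject_id}")
    return vol


def sbr_table(cohort: Cohort) -> pd.DataFrame:
    """Cohort SBRs + age as a DataFrame in canonical column order."""
    rows = {
        r.id: [r.sbr[reg] for reg in REGIONS] + [r.age] for r in cohort
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(SBR_FEATURE_COLUMNS))


def extract_features(
    cohort: Cohort,
    volumes: VolumeSource | None = None,
    kind: str = "sbrs",
) -> FeatureSet:
    """Build one of the three feature families for a cohort.

    ``sbrs`` needs only the cohort table.  ``voxels`` and ``pcs`` need a
    volume per subject; each volume is occipitally scaled, flipped
    worst-side-left, and reduced to the voxels inside the loose striatal
    mask.  Age is appended as the last column of every family.  Row order
    follows cohort order.
    """
    if kind not in FEATURE_KINDS:
        raise InvalidParameterError(f"unknown feature kind {kind!r}")
    if kind == "sbrs":
        return FeatureSet(matrix=sbr_table(cohort), feature_kind="sbrs")

    rows = []
    n_vox = None
    for record in cohort:
        vol = _get_volume(volumes, record.id)
        vol = scale_to_occipital(vol)
        vol, _ = flip_if_needed(vol)
        vox = vol.data[vol.masks["striatal_loose"]]
        if n_vox is None:
            n_vox = vox.size
        elif vox.size != n_vox:
            raise InvalidGeometryError(
                f"subject {record.id}: loose mask size {vox.size} != {n_vox}"
            )
        rows.append(np.concatenate([vox, [record.age]]))
    names = [f"vox_{i}" for i in range(n_vox)] + ["age"]
    matrix = pd.DataFrame(np.asarray(rows), index=cohort.ids, columns=names)
    return FeatureSet(matrix=matrix, feature_kind=kind)
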