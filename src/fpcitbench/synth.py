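"""Synthetic FP-CIT cohorts and striatal phantom volumes.

Real FP-CIT SPECT studies report four striatal binding ratios (SBRs) per
subject — left/right putamen and left/right caudate, each measured against an
occipital reference region — together with age, sex and a binary normal /
abnormal (pre-synaptic dopaminergic deficit) label.  This module generates
seeded cohorts with the statistical structure such data are assumed to have:

* SBRs decline linearly with age in the healthy population;
* disease lowers uptake, more in the putamen than the caudate;
* the disease effect is lateralised: a per-subject asymmetry factor makes one
  hemisphere worse than the other across both of its regions;
* independent Gaussian measurement noise per region, truncated positive.

Two presets bracket task difficulty: ``research`` emulates a screened
research database (large disease effect, low noise) and ``clinical`` a
heterogeneous clinical archive (smaller effect, doubled noise, wider age
spread).  The same generative densities drive :func:`estimate_bayes_rate`,
which brute-forces the best accuracy any classifier could reach on cohorts
drawn from a given parameterisation — the natural yardstick for everything
downstream.

Phantom volumes place ellipsoidal caudate/putamen ROIs and a cuboidal
occipital reference on a cubic grid in template space (registration is taken
as perfect), with ROI mean intensities constructed so that recomputing
(target − reference)/reference returns the subject's SBRs exactly at zero
noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.special import logsumexp

from .errors import InvalidGeometryError, InvalidParameterError

__all__ = [
    "REGIONS",
    "LABEL_NORMAL",
    "LABEL_ABNORMAL",
    "GeneratorParams",
    "PatientRecord",
    "Cohort",
    "PhantomGeometry",
    "PhantomVolume",
    "research_preset",
    "clinical_preset",
    "generate_cohort",
    "default_geometry",
    "generate_volume",
    "estimate_bayes_rate",
    "save_volume",
    "load_volume",
]

#: Region order used for every SBR vector in the package.
REGIONS = ("l_putamen", "r_putamen", "l_caudate", "r_caudate")

LABEL_NORMAL = "normal"
LABEL_ABNORMAL = "abnormal"

#: CSV schema for cohort tables.
COHORT_COLUMNS = (
    "id",
    "age",
    "sex",
    "label",
    "sbr_l_putamen",
    "sbr_r_putamen",
    "sbr_l_caudate",
    "sbr_r_caudate",
)

_SBR_FLOOR = 1e-6  # generated SBRs are truncated to stay positive


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic cohort generator.

    The healthy mean SBR of region *r* at age *a* is
    ``intercept_r + age_slope * a``.  Disease multiplies that mean by
    ``1 - drop_r * (1 + s * A)`` where ``drop_r`` is the putamen or caudate
    drop fraction, ``s`` is +1 on the left and -1 on the right, and
    ``A ~ N(0, asymmetry_sd)`` is drawn once per subject (the lateralisation
    of the deficit).  Independent ``N(0, noise_sd_r)`` measurement noise is
    then added and the result truncated positive.
    """

    n_normal: int = 209
    n_abnormal: int = 448
    age_mean_normal: float = 60.8
    age_sd_normal: float = 11.3
    age_mean_abnormal: float = 61.6
    age_sd_abnormal: float = 9.8
    sbr_intercept_putamen: float = 2.8
    sbr_intercept_caudate: float = 3.3
    age_slope: float = -0.005
    disease_putamen_drop: float = 0.55
    disease_caudate_drop: float = 0.35
    asymmetry_sd: float = 0.30
    noise_sd: float | Mapping[str, float] = 0.35
    male_frac_normal: float = 0.35
    male_frac_abnormal: float = 0.65
    separability_preset: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal < 0 or self.n_abnormal < 0:
            raise InvalidParameterError("cohort counts must be >= 0")
        for name in ("age_sd_normal", "age_sd_abnormal", "asymmetry_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        for sd in self.noise_sd_by_region().values():
            if sd < 0:
                raise InvalidParameterError("noise SDs must be >= 0")
        for name in ("disease_putamen_drop", "disease_caudate_drop"):
            d = getattr(self, name)
            if not 0.0 <= d < 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1)")
        if self.disease_caudate_drop > self.disease_putamen_drop:
            raise InvalidParameterError(
                "caudate drop must not exceed putamen drop (putamen-dominant disease)"
            )
        if not (0.0 <= self.male_frac_normal <= 1.0 and 0.0 <= self.male_frac_abnormal <= 1.0):
            raise InvalidParameterError("male fractions must lie in [0, 1]")
        if self.age_slope > 0:
            raise InvalidParameterError("age_slope must be <= 0 (SBRs decline with age)")

    # -- derived views -----------------------------------------------------
    def noise_sd_by_region(self) -> dict[str, float]:
        if isinstance(self.noise_sd, Mapping):
            missing = set(REGIONS) - set(self.noise_sd)
            if missing:
                raise InvalidParameterError(f"noise_sd missing regions: {sorted(missing)}")
            return {r: float(self.noise_sd[r]) for r in REGIONS}
        return {r: float(self.noise_sd) for r in REGIONS}

    def intercepts(self) -> np.ndarray:
        p, c = self.sbr_intercept_putamen, self.sbr_intercept_caudate
        return np.array([p, p, c, c])

    def drops(self) -> np.ndarray:
        p, c = self.disease_putamen_drop, self.disease_caudate_drop
        return np.array([p, p, c, c])

    def healthy_mean(self, age: float | np.ndarray) -> np.ndarray:
        """Healthy mean SBR per region at the given age(s); shape (..., 4)."""
        age = np.asarray(age, dtype=float)
        return self.intercepts() + self.age_slope * age[..., None]

    def replace(self, **kw) -> "GeneratorParams":
        return dataclasses.replace(self, **kw)


def research_preset(seed: int = 0, **overrides) -> GeneratorParams:
    """High-separability cohort shaped like a screened research database."""
    base = dict(
        n_normal=209,
        n_abnormal=448,
        age_mean_normal=60.8,
        age_sd_normal=11.3,
        age_mean_abnormal=61.6,
        age_sd_abnormal=9.8,
        disease_putamen_drop=0.55,
        disease_caudate_drop=0.35,
        noise_sd=0.35,
        asymmetry_sd=0.30,
        male_frac_normal=73 / 209,
        male_frac_abnormal=289 / 448,
        separability_preset="research",
        seed=seed,
    )
    base.update(overrides)
    return GeneratorParams(**base)


def clinical_preset(seed: int = 0, **overrides) -> GeneratorParams:
    """Low-separability cohort shaped like a heterogeneous clinical archive."""
    base = dict(
        n_normal=113,
        n_abnormal=191,
        age_mean_normal=68.7,
        age_sd_normal=12.4,
        age_mean_abnormal=68.7,
        age_sd_abnormal=13.3,
        disease_putamen_drop=0.45,
        disease_caudate_drop=0.25,
        noise_sd=0.70,  # doubled relative to the research preset
        asymmetry_sd=0.30,
        male_frac_normal=61 / 113,
        male_frac_abnormal=132 / 191,
        separability_preset="clinical",
        seed=seed,
    )
    base.update(overrides)
    return GeneratorParams(**base)


PRESETS = {"research": research_preset, "clinical": clinical_preset}


@dataclass(frozen=True)
class PatientRecord:
    """One subject: demographics, label, and the four regional SBRs."""

    id: str
    age: float
    sex: str
    label: str
    sbr: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise InvalidParameterError(f"record {self.id}: age must be > 0")
        if self.label not in (LABEL_NORMAL, LABEL_ABNORMAL):
            raise InvalidParameterError(f"record {self.id}: unknown label {self.label!r}")
        for r in REGIONS:
            if r not in self.sbr:
                raise InvalidParameterError(f"record {self.id}: missing SBR for {r}")
            if self.sbr[r] <= 0:
                raise InvalidParameterError(f"record {self.id}: SBR for {r} must be > 0")

    def sbr_vector(self) -> np.ndarray:
        return np.array([self.sbr[r] for r in REGIONS])


@dataclass
class Cohort:
    """An ordered collection of records plus its provenance."""

    records: list[PatientRecord]
    provenance: GeneratorParams | str | None = None

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise InvalidParameterError("cohort ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "id": r.id,
                "age": r.age,
                "sex": r.sex,
                "label": r.label,
                **{f"sbr_{reg}": r.sbr[reg] for reg in REGIONS},
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        import pandas as pd

        df = pd.read_csv(path)
        missing = set(COHORT_COLUMNS) - set(df.columns)
        if missing:
            raise InvalidParameterError(f"cohort CSV missing columns: {sorted(missing)}")
        records = [
            PatientRecord(
                id=str(row["id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                label=str(row["label"]),
                sbr={reg: float(row[f"sbr_{reg}"]) for reg in REGIONS},
            )
            for _, row in df.iterrows()
        ]
        return cls(records=records, provenance=str(path))


# ---------------------------------------------------------------------------
# cohort sampling


def _sample_class(
    params: GeneratorParams, label: str, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (ages, sexes, sbr matrix) for n subjects of one class."""
    abnormal = label == LABEL_ABNORMAL
    mu_age = params.age_mean_abnormal if abnormal else params.age_mean_normal
    sd_age = params.age_sd_abnormal if abnormal else params.age_sd_normal
    male_frac = params.male_frac_abnormal if abnormal else params.male_frac_normal

    ages = np.maximum(rng.normal(mu_age, sd_age, size=n), 1.0)
    sexes = np.where(rng.random(n) < male_frac, "M", "F")

    mean = params.healthy_mean(ages)  # (n, 4)
    if abnormal:
        asym = rng.normal(0.0, params.asymmetry_sd, size=n)
        side = np.array([+1.0, -1.0, +1.0, -1.0])  # L, R, L, R
        drop = np.clip(params.drops()[None, :] * (1.0 + side[None, :] * asym[:, None]), 0.0, 1.0)
        mean = mean * (1.0 - drop)
    noise = np.array([params.noise_sd_by_region()[r] for r in REGIONS])
    sbrs = mean + rng.normal(0.0, 1.0, size=(n, 4)) * noise[None, :]
    return ages, sexes, np.maximum(sbrs, _SBR_FLOOR)


def generate_cohort(params: GeneratorParams) -> Cohort:
    """Generate a seeded two-class cohort of SBR records.

    The same ``params`` and seed always produce a bit-identical cohort;
    records are ordered normals first, then abnormals.
    """
    rng = np.random.default_rng(params.seed)
    records: list[PatientRecord] = []
    counter = 0
    for label, n in ((LABEL_NORMAL, params.n_normal), (LABEL_ABNORMAL, params.n_abnormal)):
        ages, sexes, sbrs = _sample_class(params, label, n, rng)
        for i in range(n):
            counter += 1
            records.append(
                PatientRecord(
                    id=f"S{counter:04d}",
                    age=float(ages[i]),
                    sex=str(sexes[i]),
                    label=label,
                    sbr={reg: float(sbrs[i, j]) for j, reg in enumerate(REGIONS)},
                )
            )
    return Cohort(records=records, provenance=params)


# ---------------------------------------------------------------------------
# Bayes-rate oracle


def _log_gauss(x, mu, sd):
    return -0.5 * np.log(2 * np.pi * sd**2) - (x - mu) ** 2 / (2 * sd**2)


def class_log_likelihood(
    params: GeneratorParams,
    label: str,
    ages: np.ndarray,
    sbrs: np.ndarray,
    n_quad: int = 61,
) -> np.ndarray:
    """log p(age, sbr | class) under the generating densities.

    For the abnormal class the shared laterality factor ``A`` is integrated
    out with Gauss–Hermite quadrature.  SBR truncation at zero is ignored
    (it moves a negligible fraction of the mass for realistic parameters).
    """
    ages = np.asarray(ages, dtype=float)
    sbrs = np.asarray(sbrs, dtype=float)
    abnormal = label == LABEL_ABNORMAL
    mu_age = params.age_mean_abnormal if abnormal else params.age_mean_normal
    sd_age = params.age_sd_abnormal if abnormal else params.age_sd_normal
    ll_age = _log_gauss(ages, mu_age, sd_age)

    noise = np.array([params.noise_sd_by_region()[r] for r in REGIONS])
    healthy = params.healthy_mean(ages)  # (n, 4)

    if not abnormal or (params.disease_putamen_drop == 0 and params.disease_caudate_drop == 0):
        ll_sbr = _log_gauss(sbrs, healthy, noise[None, :]).sum(axis=1)
        return ll_age + ll_sbr

    if params.asymmetry_sd == 0:
        nodes = np.array([0.0])
        logw = np.array([0.0])
    else:
        t, w = np.polynomial.hermite.hermgauss(n_quad)
        nodes = np.sqrt(2.0) * params.asymmetry_sd * t
        logw = np.log(w) - 0.5 * np.log(np.pi)

    side = np.array([+1.0, -1.0, +1.0, -1.0])
    # drop_eff: (q, 4)
    drop_eff = np.clip(params.drops()[None, :] * (1.0 + side[None, :] * nodes[:, None]), 0.0, 1.0)
    # mean: (n, q, 4)
    mean = healthy[:, None, :] * (1.0 - drop_eff)[None, :, :]
    ll_nodes = _log_gauss(sbrs[:, None, :], mean, noise[None, None, :]).sum(axis=2)
    ll_sbr = logsumexp(ll_nodes + logw[None, :], axis=1)
    return ll_age + ll_sbr


def estimate_bayes_rate(
    params: GeneratorParams,
    n_mc: int = 20000,
    seed: int = 0,
    n_quad: int = 61,
) -> float:
    """Monte-Carlo estimate of the best achievable classification accuracy.

    Subjects are drawn from the generating densities with class priors given
    by the cohort counts; each is classified by the exact posterior (laterality
    integrated out by quadrature).  Posterior ties go to the class with the
    larger prior, and to ``normal`` when priors are equal.
    """
    if n_mc < 1000:
        raise InvalidParameterError("n_mc must be >= 1000")
    total = params.n_normal + params.n_abnormal
    if total == 0:
        raise InvalidParameterError("at least one subject per parameterisation required")
    p_ab = params.n_abnormal / total
    rng = np.random.default_rng(seed)
    n_ab = int(round(n_mc * p_ab))
    n_no = n_mc - n_ab

    correct = 0
    for label, n in ((LABEL_NORMAL, n_no), (LABEL_ABNORMAL, n_ab)):
        if n == 0:
            continue
        ages, _, sbrs = _sample_class(params, label, n, rng)
        ll_no = class_log_likelihood(params, LABEL_NORMAL, ages, sbrs, n_quad)
        ll_ab = class_log_likelihood(params, LABEL_ABNORMAL, ages, sbrs, n_quad)
        with np.errstate(divide="ignore"):
            score_ab = ll_ab + np.log(p_ab) if p_ab > 0 else np.full(n, -np.inf)
            score_no = ll_no + np.log(1 - p_ab) if p_ab < 1 else np.full(n, -np.inf)
        # strict inequality: ties (incl. the zero-effect case) go to the
        # larger prior, or to "normal" at exactly equal priors
        if p_ab > 0.5:
            pred_ab = score_ab >= score_no
        else:
            pred_ab = score_ab > score_no
        if label == LABEL_ABNORMAL:
            correct += int(pred_ab.sum())
        else:
            correct += int((~pred_ab).sum())
    return correct / n_mc


# ---------------------------------------------------------------------------
# phantom volumes

#: mask names beyond the four SBR regions
MASK_NAMES = REGIONS + ("occipital", "striatal_loose")


@dataclass
class PhantomGeometry:
    """Template-space ROI layout for phantom generation."""

    shape: tuple[int, int, int]
    voxel_size_mm: float
    background: float
    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        validate_geometry(self.masks, self.shape)


@dataclass
class PhantomVolume:
    """A 3-D activity grid with named ROI masks (template space)."""

    data: np.ndarray
    voxel_size_mm: float
    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if np.any(self.data < 0):
            raise InvalidParameterError("phantom intensities must be >= 0")
        validate_geometry(self.masks, self.data.shape)


def validate_geometry(masks: Mapping[str, np.ndarray], shape) -> None:
    """Enforce the ROI-layout invariants.

    The four striatal masks must be pairwise disjoint, the loose striatal
    mask must contain all of them, and the occipital reference must be
    disjoint from the loose mask.
    """
    missing = set(MASK_NAMES) - set(masks)
    if missing:
        raise InvalidGeometryError(f"missing masks: {sorted(missing)}")
    for name in MASK_NAMES:
        m = masks[name]
        if m.shape != tuple(shape):
            raise InvalidGeometryError(f"mask {name} shape {m.shape} != volume shape {tuple(shape)}")
        if m.dtype != bool:
            raise InvalidGeometryError(f"mask {name} must be boolean")
        if not m.any():
            raise InvalidGeometryError(f"mask {name} is empty")
    for i, a in enumerate(REGIONS):
        for b in REGIONS[i + 1 :]:
            if np.any(masks[a] & masks[b]):
                raise InvalidGeometryError(f"striatal masks {a} and {b} overlap")
    striatal_union = np.zeros(tuple(shape), dtype=bool)
    for r in REGIONS:
        striatal_union |= masks[r]
    if np.any(striatal_union & ~masks["striatal_loose"]):
        raise InvalidGeometryError("striatal_loose mask must contain all four striatal masks")
    if np.any(masks["occipital"] & masks["striatal_loose"]):
        raise InvalidGeometryError("occipital mask must be disjoint from striatal_loose")


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def default_geometry(
    size: int = 64, voxel_size_mm: float = 3.0, background: float = 100.0
) -> PhantomGeometry:
    """Build the default symmetric phantom layout on a ``size``³ grid.

    Axis 0 is left–right (left = low index), axis 1 anterior–posterior
    (occipital = high index), axis 2 inferior–superior.  All ROIs are placed
    mirror-symmetrically about the mid-sagittal plane so volumes can be
    flipped without remapping geometry.
    """
    if size < 24:
        raise InvalidGeometryError("grid too small for the default ROI layout")
    s = size / 64.0
    shape = (size, size, size)
    mid = (size - 1) / 2.0

    def mirrored(center):  # reflect about the mid-sagittal plane (axis 0)
        return (2 * mid - center[0], center[1], center[2])

    put_l = (21 * s, 38 * s, 32 * s)
    caud_l = (27 * s, 24 * s, 34 * s)
    put_r = mirrored(put_l)
    caud_r = mirrored(caud_l)
    put_radii = (4 * s, 6 * s, 5 * s)
    caud_radii = (3 * s, 5 * s, 4 * s)

    masks = {
        "l_putamen": _ellipsoid(shape, put_l, put_radii),
        "r_putamen": _ellipsoid(shape, put_r, put_radii),
        "l_caudate": _ellipsoid(shape, caud_l, caud_radii),
        "r_caudate": _ellipsoid(shape, caud_r, caud_radii),
    }
    # loose striatal mask: bounding box of the four ROIs plus a margin,
    # mirror-symmetric by construction
    union = masks["l_putamen"] | masks["r_putamen"] | masks["l_caudate"] | masks["r_caudate"]
    idx = np.argwhere(union)
    lo = np.maximum(idx.min(axis=0) - int(round(2 * s)), 0)
    hi = np.minimum(idx.max(axis=0) + int(round(2 * s)), size - 1)
    lo[0] = min(lo[0], size - 1 - hi[0])  # enforce exact mirror symmetry
    hi[0] = size - 1 - lo[0]
    loose = np.zeros(shape, dtype=bool)
    loose[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = True
    masks["striatal_loose"] = loose

    occ = np.zeros(shape, dtype=bool)
    y0, y1 = int(round(54 * s)), min(int(round(61 * s)), size - 1)
    x0 = int(round(20 * s))
    x1 = size - 1 - x0
    z0, z1 = int(round(26 * s)), int(round(38 * s))
    occ[x0 : x1 + 1, y0 : y1 + 1, z0 : z1 + 1] = True
    masks["occipital"] = occ

    return PhantomGeometry(shape=shape, voxel_size_mm=voxel_size_mm, background=background, masks=masks)


def generate_volume(
    record: PatientRecord,
    geometry: PhantomGeometry,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PhantomVolume:
    """Render one subject's SBRs into a phantom volume.

    Each striatal ROI is set to ``background * (1 + SBR)`` so that the SBR
    round-trips exactly at zero noise; additive Gaussian noise with SD
    ``noise_sd * background`` is then applied everywhere and the volume
    clipped non-negative.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    b = geometry.background
    vol = np.full(geometry.shape, b, dtype=float)
    for r in REGIONS:
        vol[geometry.masks[r]] = b * (1.0 + record.sbr[r])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sd * b, size=geometry.shape)
    vol = np.maximum(vol, 0.0)
    return PhantomVolume(
        data=vol,
        voxel_size_mm=geometry.voxel_size_mm,
        masks={k: v.copy() for k, v in geometry.masks.items()},
    )


# ---------------------------------------------------------------------------
# NIfTI I/O

#: bit flag per mask in the exported label map (masks may nest, so the map
#: is a bit field rather than exclusive labels)
MASK_BITS = {name: 1 << i for i, name in enumerate(MASK_NAMES)}


def save_volume(volume: PhantomVolume, path: str | Path, mask_path: str | Path | None = None) -> None:
    """Write a phantom as NIfTI-1, with masks as a bit-field label map + JSON sidecar."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag([volume.voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), affine), str(path))
    if mask_path is None:
        mask_path = path.with_name(path.name.replace(".nii", "_masks.nii"))
    mask_path = Path(mask_path)
    labels = np.zeros(volume.data.shape, dtype=np.int16)
    for name, bit in MASK_BITS.items():
        labels[volume.masks[name]] |= bit
    nib.save(nib.Nifti1Image(labels, affine), str(mask_path))
    sidecar = mask_path.with_suffix("").with_suffix(".json") if mask_path.suffix == ".gz" else mask_path.with_suffix(".json")
    sidecar.write_text(json.dumps(MASK_BITS, indent=2, sort_keys=True))


def load_volume(path: str | Path, mask_path: str | Path | None = None) -> PhantomVolume:
    """Read a phantom written by :func:`save_volume`."""
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    voxel = float(abs(img.affine[0, 0]))
    if mask_path is None:
        mask_path = path.with_name(path.name.replace(".nii", "_masks.nii"))
    mask_path = Path(mask_path)
    sidecar = mask_path.with_suffix(".json")
    bits = json.loads(sidecar.read_text())
    labels = np.asarray(nib.load(str(mask_path)).dataobj).astype(np.int64)
    masks = {name: (labels & bit) > 0 for name, bit in bits.items()}
    return PhantomVolume(data=data, voxel_size_mm=voxel, masks=masks)
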