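"""Synthetic geometric phantoms with analytically known morphometry.

Real T1-weighted cohorts with FreeSurfer references cannot be shipped, so the
package generates geometric stand-ins whose morphometry is known in closed
form:

* bright **ellipsoids** emulate subcortical nuclei — volume = 4/3·π·a·b·c;
* concentric spherical **shells** emulate the cortical band — thickness =
  r_outer − r_inner, and the mean curvature of the mid-surface (a sphere of
  radius r_mid = (r_inner + r_outer)/2) is 1/r_mid.

Rendering uses voxel-center containment (a voxel takes a primitive's
intensity iff its center lies inside), so a brute-force voxel count is an
exact oracle for the digitized volume.  Additive zero-mean Gaussian noise,
clipped at 0, stands in for MR magnitude noise.

``generate_cohort`` adds the statistical structure clinical evaluations need:
per-subject age/sex/group covariates, a linear age slope injected into the
shell thickness (default −0.004 mm/year, the cross-sectional cortical
atrophy rate the evaluation suite must recover), a standardized group effect
on a volume target, and rescan subjects whose repeated scans share geometry
and differ only in rendering noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .preprocess import VolumeGrid
from .targets import MorphometryVector, TargetRegistry, build_registry

__all__ = [
    "Ellipsoid",
    "Shell",
    "PhantomSpec",
    "PhantomSample",
    "SubjectRecord",
    "CohortConfig",
    "analytic_truth",
    "render",
    "generate_cohort",
    "write_cohort",
]

# Registry descriptors the default cohort binds its primitives to.  The
# ellipsoid plays the role of a lateral-ventricle-like volume target (the
# structure carrying the injected group effect); the shell feeds one
# thickness and one curvature parcellation.
DEFAULT_VOLUME_TARGET = ("Left-Lateral-Ventricle", "volume")
DEFAULT_THICKNESS_TARGET = ("precentral", "thickness")
DEFAULT_CURVATURE_TARGET = ("precentral", "curvature")


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    intensity: float = 100.0

    def __post_init__(self):
        if min(self.semi_axes) <= 0:
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")

    @property
    def volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c


@dataclass(frozen=True)
class Shell:
    center: tuple[float, float, float]
    inner_radius: float
    outer_radius: float
    intensity: float = 80.0

    def __post_init__(self):
        if not (self.outer_radius > self.inner_radius >= 0):
            raise ValueError(
                f"need outer > inner >= 0, got ({self.inner_radius}, {self.outer_radius})"
            )

    @property
    def thickness(self) -> float:
        return self.outer_radius - self.inner_radius

    @property
    def mean_curvature(self) -> float:
        return 2.0 / (self.inner_radius + self.outer_radius)


Primitive = Ellipsoid | Shell


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    age: float
    sex: str  # M | F
    group: str  # control | patient
    scan_ids: tuple[str, ...] = ("scan-0",)

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError("age must be positive")
        if not self.scan_ids:
            raise ValueError("scan_ids must be non-empty")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M/F, got {self.sex!r}")
        if self.group not in ("control", "patient"):
            raise ValueError(f"group must be control/patient, got {self.group!r}")


@dataclass
class PhantomSpec:
    """Primitives plus their binding to registry targets."""

    primitives: tuple[Primitive, ...]
    bindings: tuple[tuple[int, str, str], ...]  # (primitive index, name, category)
    noise_sd: float = 0.0
    background_intensity: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        seen = set()
        for _, name, category in self.bindings:
            key = (name, category)
            if key in seen:
                raise ValueError(f"descriptor {key} bound more than once")
            seen.add(key)


@dataclass
class PhantomSample:
    volume: VolumeGrid
    mask: np.ndarray
    truth: MorphometryVector
    covariates: SubjectRecord
    scan_id: str = "scan-0"


def analytic_truth(
    spec: PhantomSpec, registry: TargetRegistry | None = None
) -> MorphometryVector:
    """Closed-form morphometry of the bound primitives.

    Unbound registry descriptors are flagged absent (mask False), not zero.
    """
    registry = registry or build_registry()
    values = np.full(len(registry), np.nan)
    mask = np.zeros(len(registry), dtype=bool)
    for prim_idx, name, category in spec.bindings:
        prim = spec.primitives[prim_idx]
        if category == "volume":
            if not isinstance(prim, Ellipsoid):
                raise ValueError("volume targets must bind ellipsoids")
            val = prim.volume
        elif category == "thickness":
            if not isinstance(prim, Shell):
                raise ValueError("thickness targets must bind shells")
            val = prim.thickness
        elif category == "curvature":
            if not isinstance(prim, Shell):
                raise ValueError("curvature targets must bind shells")
            val = prim.mean_curvature
        else:  # pragma: no cover - PhantomSpec cannot hold other categories
            raise ValueError(f"unknown category {category!r}")
        i = registry.index_of(name, category)
        values[i] = val
        mask[i] = True
    return MorphometryVector(values, registry, mask)


def _inside(prim: Primitive, grid: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
    x, y, z = grid
    cx, cy, cz = prim.center
    if isinstance(prim, Ellipsoid):
        a, b, c = prim.semi_axes
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0
    r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
    return (r2 > prim.inner_radius**2) & (r2 <= prim.outer_radius**2)


def _extent_ok(prim: Primitive, edge: int) -> bool:
    if isinstance(prim, Ellipsoid):
        reach = max(prim.semi_axes)
    else:
        reach = prim.outer_radius
    return all(reach <= c <= edge - 1 - reach for c in prim.center)


def render(
    spec: PhantomSpec,
    edge: int = 64,
    seed: int | np.random.Generator | None = 0,
    covariates: SubjectRecord | None = None,
    scan_id: str = "scan-0",
    registry: TargetRegistry | None = None,
) -> PhantomSample:
    """Rasterize a phantom spec onto an ``edge``³ grid at 1 mm spacing.

    Later primitives overwrite earlier ones where they overlap.  Noise is
    additive zero-mean Gaussian with sd ``noise_sd``, clipped at 0;
    deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for prim in spec.primitives:
        if not _extent_ok(prim, edge):
            raise ValueError(f"primitive {prim} exceeds the {edge}^3 grid")
    ax = np.arange(edge, dtype=np.float64)
    grid = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    data = np.full((edge,) * 3, spec.background_intensity, dtype=np.float64)
    mask = np.zeros((edge,) * 3, dtype=bool)
    for prim in spec.primitives:
        inside = _inside(prim, grid)
        data[inside] = prim.intensity
        mask |= inside
    if spec.noise_sd > 0:
        data = np.clip(data + rng.normal(0.0, spec.noise_sd, data.shape), 0.0, None)
    truth = analytic_truth(spec, registry)
    covariates = covariates or SubjectRecord("phantom", 40.0, "F", "control")
    return PhantomSample(VolumeGrid(data), mask, truth, covariates, scan_id)


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the evaluation settings of the clinical analyses: a
    thickness age slope of −0.004 mm/year, a standardized group effect
    (Cohen's d) of +0.3 on the ventricle-like volume target, ages 6–84
    years, and a handful of rescan subjects whose scans share geometry.
    """

    n_controls: int = 100
    n_patients: int = 100
    age_range: tuple[float, float] = (6.0, 84.0)
    male_fraction: float = 0.45
    age_slope: float = -0.004  # mm/year on shell thickness
    group_effect_d: float = 0.3  # Cohen's d on the volume target, patient - control
    thickness_mean: float = 2.5  # mm at the reference age
    thickness_sd: float = 0.25  # between-subject biological sd, mm
    reference_age: float = 40.0
    volume_mean: float = 1150.0  # mm^3, ellipsoid target
    volume_sd: float = 280.0
    shell_radius_mean: float = 16.0  # voxels (= mm), mid-surface
    shell_radius_sd: float = 1.0
    noise_sd: float = 5.0  # rendering intensity noise
    n_rescan_subjects: int = 0
    rescan_range: tuple[int, int] = (3, 6)
    edge: int = 48
    render_volumes: bool = True

    def __post_init__(self):
        if self.n_controls < 0 or self.n_patients < 0:
            raise ValueError("group sizes must be non-negative")
        if self.age_range[0] <= 0 or self.age_range[1] <= self.age_range[0]:
            raise ValueError("invalid age range")


def _subject_spec(cfg: CohortConfig, record: SubjectRecord, rng: np.random.Generator) -> PhantomSpec:
    """Draw one subject's geometry so bound targets carry the configured
    covariate structure."""
    # Thickness: linear age trend + biological noise.
    thickness = (
        cfg.thickness_mean
        + cfg.age_slope * (record.age - cfg.reference_age)
        + rng.normal(0.0, cfg.thickness_sd)
    )
    thickness = max(thickness, 0.8)
    r_mid = max(rng.normal(cfg.shell_radius_mean, cfg.shell_radius_sd), 6.0)
    inner = r_mid - thickness / 2.0
    outer = r_mid + thickness / 2.0
    if inner <= 0:
        raise ValueError(f"infeasible shell geometry for subject {record.subject_id}")

    # Volume: group effect of d standard deviations on the mean.
    mu = cfg.volume_mean + (cfg.group_effect_d * cfg.volume_sd if record.group == "patient" else 0.0)
    vol = max(rng.normal(mu, cfg.volume_sd), 50.0)
    r_eq = (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0)
    # random volume-preserving anisotropy
    f1, f2 = np.exp(rng.normal(0.0, 0.08, size=2))
    axes = (r_eq * f1, r_eq * f2, r_eq / (f1 * f2))

    center = (cfg.edge - 1) / 2.0
    jitter = rng.uniform(-1.5, 1.5, size=3)
    ell_center = tuple(center + j for j in jitter)
    if max(axes) >= inner - 1.0:
        # nucleus must stay inside the shell cavity; shrink jitter if tight
        ell_center = (center, center, center)

    shell = Shell((center, center, center), inner, outer, intensity=80.0)
    ell = Ellipsoid(ell_center, axes, intensity=140.0)
    bindings = (
        (1, DEFAULT_VOLUME_TARGET[0], DEFAULT_VOLUME_TARGET[1]),
        (0, DEFAULT_THICKNESS_TARGET[0], DEFAULT_THICKNESS_TARGET[1]),
        (0, DEFAULT_CURVATURE_TARGET[0], DEFAULT_CURVATURE_TARGET[1]),
    )
    return PhantomSpec((shell, ell), bindings, noise_sd=cfg.noise_sd)


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    registry: TargetRegistry | None = None,
) -> list[PhantomSample]:
    """Generate a cohort of phantom samples under the configured conditions.

    Rescan subjects (the first ``n_rescan_subjects`` controls) get several
    scans sharing identical geometry — hence identical analytic truth — with
    independent rendering noise.  With ``render_volumes=False`` only truths
    and covariates are produced (volume/mask are None), which is enough for
    the statistical recovery analyses and much faster.
    """
    cfg = config or CohortConfig()
    registry = registry or build_registry()
    rng = np.random.default_rng(seed)

    records: list[SubjectRecord] = []
    sid = 0
    for group, n in (("control", cfg.n_controls), ("patient", cfg.n_patients)):
        for _ in range(n):
            age = float(rng.uniform(*cfg.age_range))
            sex = "M" if rng.random() < cfg.male_fraction else "F"
            n_scans = 1
            if group == "control" and len([r for r in records if len(r.scan_ids) > 1]) < cfg.n_rescan_subjects:
                n_scans = int(rng.integers(cfg.rescan_range[0], cfg.rescan_range[1] + 1))
            scan_ids = tuple(f"scan-{k}" for k in range(n_scans))
            records.append(SubjectRecord(f"sub-{sid:04d}", age, sex, group, scan_ids))
            sid += 1

    samples: list[PhantomSample] = []
    for record in records:
        spec = _subject_spec(cfg, record, rng)
        truth = analytic_truth(spec, registry)
        for scan_id in record.scan_ids:
            if cfg.render_volumes:
                sample = render(spec, edge=cfg.edge, seed=rng, covariates=record,
                                scan_id=scan_id, registry=registry)
            else:
                sample = PhantomSample(None, None, truth, record, scan_id)  # type: ignore[arg-type]
            samples.append(sample)
    return samples


def write_cohort(samples: Sequence[PhantomSample], outdir) -> None:
    """Write a cohort directory: NIfTI volumes+masks, truth and covariate
    CSVs, and a manifest JSON."""
    import pandas as pd

    from .preprocess import save_nifti

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    cov_rows = []
    for s in samples:
        stem = f"{s.covariates.subject_id}_{s.scan_id}"
        if s.volume is not None:
            save_nifti(s.volume, outdir / f"{stem}.nii.gz")
            save_nifti(VolumeGrid(s.mask.astype(np.float32)), outdir / f"{stem}_mask.nii.gz")
        df = s.truth.to_frame()
        df.insert(0, "subject_id", s.covariates.subject_id)
        df.insert(1, "scan_id", s.scan_id)
        rows.append(df[df["present"]])
        cov_rows.append(
            {
                "subject_id": s.covariates.subject_id,
                "scan_id": s.scan_id,
                "age": s.covariates.age,
                "sex": s.covariates.sex,
                "group": s.covariates.group,
            }
        )
    pd.concat(rows, ignore_index=True).to_csv(outdir / "truth.csv", index=False)
    pd.DataFrame(cov_rows).to_csv(outdir / "covariates.csv", index=False)
    manifest = {
        "n_samples": len(samples),
        "n_subjects": len({s.covariates.subject_id for s in samples}),
        "rendered": all(s.volume is not None for s in samples),
        "files": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
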