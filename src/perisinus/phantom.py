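"""Synthetic peri-sinus phantoms and lifespan cohorts.

The phantom emulates the T2-weighted contrast ordering of the peri-sinus
region: hyperintense subarachnoid CSF, intermediate PSD and AG, and
hypointense dura, sinus lumen and parenchymal surroundings.  Geometry is
deliberately schematic (a venous tube near the superior margin with
lateral PSD wings, a thin dura band, and ellipsoidal AGs protruding into
the lumen) — this is a test harness, not an anatomical simulation.

World axes follow the package convention (x right–left with midline at
x = 0, y anterior–posterior with +y anterior, z foot–head).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .volumes import LabelMap, Volume3D

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "PSDGrowth",
    "AGGrowth",
    "generate_phantom",
    "generate_cohort",
]

TISSUES = ("parenchyma", "csf", "dura", "lumen", "psd", "ag")

DEFAULT_MEANS = {
    "parenchyma": 45.0,
    "csf": 100.0,
    "dura": 20.0,
    "lumen": 25.0,
    "psd": 70.0,
    "ag": 70.0,
}


class PhantomSpecError(ValueError):
    """Raised when a phantom specification is geometrically inconsistent."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic peri-sinus phantom.

    AG ellipsoids are given as ``(center_mm, semi_axes_mm)`` pairs; each
    center must lie inside the sinus lumen so that the granulation
    protrudes into the venous channel.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (0.8, 0.8, 0.8)
    # sinus centerline: x = 0, z = const near the superior margin
    sinus_center_frac_z: float = 0.75
    sinus_radius_mm: float = 3.2
    sinus_radius_wobble: float = 0.12     # relative variation along y
    sinus_wobble_phase: float = 0.0
    psd_thickness_mm: float = 2.8         # radial thickness of the lateral wings
    psd_wing_frac: float = 0.4            # |x|/d threshold separating wing from dura cap
    dura_thickness_mm: float = 1.6
    csf_thickness_mm: float = 4.0
    ags: Optional[Sequence[tuple[tuple, tuple]]] = None   # None -> 3 default AGs
    intensity_means: dict = field(default_factory=lambda: dict(DEFAULT_MEANS))
    intensity_sds: dict = field(default_factory=lambda: {t: 0.0 for t in TISSUES})
    bias_amplitude: float = 0.1           # fractional multiplicative field strength
    noise_sd: float = 5.0                 # additive Gaussian noise (intensity units)
    # anterior/posterior boundary planes standing in for the central sulcus
    # and parieto-occipital fissure (world y, mm; +y anterior)
    central_plane_mm: float = 10.0
    parieto_occipital_plane_mm: float = -15.0
    seed: int = 0

    def __post_init__(self) -> None:
        m = self.intensity_means
        if not (m["csf"] > m["psd"] and m["csf"] > m["ag"]
                and m["psd"] > max(m["dura"], m["lumen"])
                and m["ag"] > max(m["dura"], m["lumen"])):
            raise PhantomSpecError(
                "intensity ordering violated: need CSF > PSD ~ AG > dura, lumen"
            )
        if abs(m["psd"] - m["ag"]) > 0.25 * m["psd"]:
            warnings.warn("PSD and AG means differ by more than 25%; the phantom "
                          "contrast model assumes they are close", stacklevel=2)

    # -- derived geometry -------------------------------------------------
    def affine(self) -> np.ndarray:
        """Voxel->world affine: isotropic scaling, midline at x = 0, y centred."""
        sx, sy, sz = self.spacing
        nx, ny, _ = self.grid_shape
        A = np.diag([sx, sy, sz, 1.0])
        A[0, 3] = -sx * (nx - 1) / 2.0
        A[1, 3] = -sy * (ny - 1) / 2.0
        return A

    def centerline_z(self) -> float:
        return self.sinus_center_frac_z * self.spacing[2] * (self.grid_shape[2] - 1)

    def radius_at(self, y: np.ndarray) -> np.ndarray:
        ly = self.spacing[1] * self.grid_shape[1]
        return self.sinus_radius_mm * (
            1.0 + self.sinus_radius_wobble
            * np.sin(2 * np.pi * y / ly + self.sinus_wobble_phase)
        )

    def default_ags(self, n: int = 3, rng: Optional[np.random.Generator] = None):
        """Place ``n`` AG ellipsoids on the centerline at distinct y positions."""
        rng = rng or np.random.default_rng(self.seed)
        ly = self.spacing[1] * self.grid_shape[1]
        zc = self.centerline_z()
        fracs = np.linspace(0.25, 0.75, n)
        ags = []
        for f in fracs:
            cy = (f - 0.5) * ly + rng.uniform(-2.0, 2.0)
            r = float(self.radius_at(np.array(cy)))
            cx = rng.uniform(-0.3, 0.3) * r
            cz = zc + rng.uniform(-0.3, 0.3) * r
            semi = (rng.uniform(1.4, 2.2), rng.uniform(2.0, 3.2), rng.uniform(1.4, 2.2))
            ags.append(((cx, cy, cz), semi))
        return ags

    @classmethod
    def randomized(cls, seed: int, **overrides) -> "PhantomSpec":
        """A spec with jittered geometry, for cohorts of distinct subjects."""
        rng = np.random.default_rng(seed)
        spec = cls(
            sinus_radius_mm=rng.uniform(2.7, 3.8),
            psd_thickness_mm=rng.uniform(2.2, 3.4),
            sinus_center_frac_z=rng.uniform(0.70, 0.80),
            sinus_radius_wobble=rng.uniform(0.05, 0.18),
            sinus_wobble_phase=rng.uniform(0, 2 * np.pi),
            seed=seed,
            **overrides,
        )
        n_ags = int(rng.integers(2, 5))
        return replace(spec, ags=spec.default_ags(n_ags, rng))


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    class_voxel_counts: dict
    ag_instances: list            # dicts: voxel_count, volume_mm3, centroid_mm
    central_plane_mm: float
    parieto_occipital_plane_mm: float
    psd_region_voxel_counts: dict  # frontal/parietal/occipital
    voxel_volume_mm3: float

    @property
    def ag_total_volume_mm3(self) -> float:
        return float(sum(a["volume_mm3"] for a in self.ag_instances))

    @property
    def ag_count(self) -> int:
        return len(self.ag_instances)


def generate_phantom(spec: PhantomSpec):
    """Generate ``(Volume3D, LabelMap, PhantomTruth)`` from a spec.

    The noiseless, bias-free image is exactly piecewise constant at the
    configured class means, so that label/image consistency is testable.
    """
    rng = np.random.default_rng(spec.seed)
    aff = spec.affine()
    shape = tuple(spec.grid_shape)
    probe = Volume3D(np.zeros(shape, dtype=np.float32), spec.spacing, aff, "template")
    X, Y, Z = probe.world_coords()

    zc = spec.centerline_z()
    r = spec.radius_at(Y)
    d = np.sqrt(X**2 + (Z - zc) ** 2)

    lumen = d <= r
    outer_psd = r + spec.psd_thickness_mm
    annulus = (d > r) & (d <= outer_psd)
    with np.errstate(invalid="ignore", divide="ignore"):
        wing = np.abs(X) >= spec.psd_wing_frac * d
    psd = annulus & wing
    dura = (annulus & ~wing) | ((d > outer_psd) & (d <= outer_psd + spec.dura_thickness_mm))
    csf = (d > outer_psd + spec.dura_thickness_mm) & (
        d <= outer_psd + spec.dura_thickness_mm + spec.csf_thickness_mm
    )

    tissue = np.zeros(shape, dtype=np.int8)  # 0 parenchyma
    tissue[csf] = 1
    tissue[dura] = 2
    tissue[lumen] = 3
    tissue[psd] = 4

    ags = spec.ags if spec.ags is not None else spec.default_ags(rng=rng)
    ag_masks = []
    for (cx, cy, cz), (a, b, c) in ags:
        rr = float(spec.radius_at(np.asarray(cy)))
        if np.hypot(cx, cz - zc) > rr:
            raise PhantomSpecError(
                f"AG center ({cx:.1f},{cy:.1f},{cz:.1f}) lies outside the sinus lumen"
            )
        e = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2
        m = (e <= 1.0) & lumen
        if not m.any():
            raise PhantomSpecError("AG ellipsoid does not intersect the voxel grid")
        ag_masks.append(m)
        tissue[m] = 5

    labels = np.zeros(shape, dtype=np.int16)
    labels[tissue == 3] = 1
    labels[tissue == 4] = 2
    labels[tissue == 5] = 3

    means = np.array([spec.intensity_means[t] for t in TISSUES], dtype=np.float64)
    sds = np.array([spec.intensity_sds[t] for t in TISSUES], dtype=np.float64)
    img = means[tissue]
    if np.any(sds > 0):
        img = img + rng.normal(0.0, 1.0, shape) * sds[tissue]

    if spec.bias_amplitude > 0:
        img = img * _bias_field(spec, X, Y, Z, rng)
    else:
        rng.normal(size=10)  # keep the noise stream aligned across amplitudes
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, shape)

    vol = Volume3D(img.astype(np.float32), spec.spacing, aff, "template")
    lab = LabelMap(labels, spec.spacing, aff, "template")

    vv = float(np.prod(spec.spacing))
    instances = []
    for m in ag_masks:
        idx = np.argwhere(m)
        centroid_vox = idx.mean(axis=0)
        centroid_mm = aff[:3, :3] @ centroid_vox + aff[:3, 3]
        instances.append({
            "voxel_count": int(m.sum()),
            "volume_mm3": float(m.sum() * vv),
            "centroid_mm": tuple(float(v) for v in centroid_mm),
        })

    psd_regions = {
        "frontal": int(np.sum((labels == 2) & (Y >= spec.central_plane_mm))),
        "parietal": int(np.sum((labels == 2) & (Y < spec.central_plane_mm)
                               & (Y >= spec.parieto_occipital_plane_mm))),
        "occipital": int(np.sum((labels == 2) & (Y < spec.parieto_occipital_plane_mm))),
    }
    truth = PhantomTruth(
        class_voxel_counts={c: int(np.sum(labels == c)) for c in range(4)},
        ag_instances=instances,
        central_plane_mm=spec.central_plane_mm,
        parieto_occipital_plane_mm=spec.parieto_occipital_plane_mm,
        psd_region_voxel_counts=psd_regions,
        voxel_volume_mm3=vv,
    )
    return vol, lab, truth


def _bias_field(spec: PhantomSpec, X, Y, Z, rng) -> np.ndarray:
    """Exponential of a random degree-<=3 polynomial, scaled so the peak
    log-field magnitude equals log(1 + bias_amplitude)."""
    def unit(c):
        c = c - c.mean()
        return c / (np.abs(c).max() + 1e-12)

    xh, yh, zh = unit(X), unit(Y), unit(Z)
    coeffs = rng.normal(size=10)
    b = (coeffs[0] * xh + coeffs[1] * yh + coeffs[2] * zh
         + coeffs[3] * xh * yh + coeffs[4] * yh * zh + coeffs[5] * xh * zh
         + coeffs[6] * xh**2 + coeffs[7] * zh**2
         + coeffs[8] * xh**3 + coeffs[9] * zh * yh**2)
    b = b - b.mean()
    peak = np.abs(b).max()
    if peak < 1e-12:
        return np.ones_like(b)
    b = b * (np.log1p(spec.bias_amplitude) / peak)
    return np.exp(b)


# ---------------------------------------------------------------------------
# lifespan cohorts
# ---------------------------------------------------------------------------

@dataclass
class PSDGrowth:
    """True generating model for PSD volume (cm^3) vs age and sex.

    volume = intercept + age*a + age2*a^2 + sex*male + age_sex*a*male.
    Defaults approximate lifetime totals of roughly 6-8 cm^3 by age 70
    with a faster male increase.
    """

    intercept: float = 2.0
    age: float = 0.08
    age2: float = -0.0004
    sex: float = 0.0
    age_sex: float = 0.02
    noise_sd: float = 0.8
    region_fracs: tuple[float, float, float] = (0.45, 0.37, 0.18)


@dataclass
class AGGrowth:
    """True generating model for AG count (Poisson) and total volume (mm^3)."""

    total_intercept: float = 5.0
    total_age: float = 0.64
    total_noise_sd: float = 8.0
    count_intercept: float = 2.0
    count_age: float = 0.1


@dataclass
class CohortSpec:
    """Specification of a synthetic lifespan cohort."""

    n_subjects: int = 200
    age_range: tuple[float, float] = (5.0, 100.0)
    male_fraction: float = 0.46
    sources: tuple[str, ...] = ("VGIP", "HCP-YA", "HCP-DA")
    source_sd: float = 0.3        # cm^3, random-intercept scale for PSD volume
    psd_growth: PSDGrowth = field(default_factory=PSDGrowth)
    ag_growth: AGGrowth = field(default_factory=AGGrowth)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        lo, hi = self.age_range
        if not (5.0 <= lo < hi <= 100.0):
            raise ValueError("age_range must lie within [5, 100]")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a per-subject covariate/metric table from the configured models.

    Source random intercepts are drawn once per source (scaled by
    ``source_sd``) and shared by all subjects of that source, matching a
    random-intercept mixed-model structure.  A fixed seed reproduces the
    table exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    g = spec.psd_growth

    age = rng.uniform(*spec.age_range, n)
    male = (rng.random(n) < spec.male_fraction).astype(int)
    src_idx = rng.integers(0, len(spec.sources), n)
    src_effects = rng.normal(0.0, 1.0, len(spec.sources)) * spec.source_sd

    mean_psd = (g.intercept + g.age * age + g.age2 * age**2
                + g.sex * male + g.age_sex * age * male)
    psd_total = mean_psd + src_effects[src_idx]
    if g.noise_sd > 0:
        psd_total = psd_total + rng.normal(0.0, g.noise_sd, n)
    psd_total = np.clip(psd_total, 0.0, None)

    fr = np.asarray(g.region_fracs, dtype=float)
    fr = fr / fr.sum()
    jitter = rng.normal(0.0, 0.02, (n, 3))
    fracs = np.clip(fr[None, :] + jitter, 0.02, None)
    fracs = fracs / fracs.sum(axis=1, keepdims=True)
    psd_regions = psd_total[:, None] * fracs

    a = spec.ag_growth
    lam = np.clip(a.count_intercept + a.count_age * age, 0.05, None)
    count = rng.poisson(lam)
    total = a.total_intercept + a.total_age * age
    if a.total_noise_sd > 0:
        total = total + rng.normal(0.0, a.total_noise_sd, n)
    total = np.clip(total, 0.0, None)
    total[count == 0] = 0.0

    avg = np.zeros(n)
    vmax = np.zeros(n)
    vmin = np.zeros(n)
    for i in range(n):
        if count[i] == 0:
            continue
        w = rng.gamma(1.5, 1.0, count[i])
        inst = total[i] * w / w.sum()
        avg[i], vmax[i], vmin[i] = inst.mean(), inst.max(), inst.min()

    icv = np.where(male == 1,
                   rng.normal(1500.0, 110.0, n),
                   rng.normal(1330.0, 100.0, n))
    icv = np.clip(icv, 800.0, None)

    return pd.DataFrame({
        "subject": [f"sub-{i:04d}" for i in range(n)],
        "age": age,
        "sex": np.where(male == 1, "male", "female"),
        "source": [spec.sources[j] for j in src_idx],
        "icv_cm3": icv,
        "psd_total_cm3": psd_total,
        "psd_frontal_cm3": psd_regions[:, 0],
        "psd_parietal_cm3": psd_regions[:, 1],
        "psd_occipital_cm3": psd_regions[:, 2],
        "ag_count": count,
        "ag_total_mm3": total,
        "ag_average_mm3": avg,
        "ag_max_mm3": vmax,
        "ag_min_mm3": vmin,
    })
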