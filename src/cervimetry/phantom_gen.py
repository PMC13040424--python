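"""Synthetic uterocervical phantoms and cohorts with known ground truth.

Phantoms
--------
A phantom is a set of nested tubes (canal inside inner stroma inside outer
stroma) voxelized around a straight or circular-arc centerline, with an
optional endocanal cyst (a sphere centred on the canal) and a bar-shaped
lower-uterine-segment reference region set at a prescribed utero-cervical
angle.  Every measurement of the biometry panel is known in closed form
from the construction parameters, so the phantom suite provides exact
oracles for the measurement pipeline.

Voxelization is by analytic inside-tests at voxel centres: a voxel belongs
to the canal iff its distance to the centerline at its own arc position is
at most the local canal radius r(s) (linear taper), with flat end caps.

Cohorts
-------
``make_cohort`` draws per-subject demographics and biometry with the
effect structure the downstream association battery expects: stroma
volume rising with maternal age and cervical length, os diameters and
utero-cervical angle falling with length, a logistic caesarean model with
a configurable per-cm^3 odds ratio on total cervical volume, and an
internal-vs-external os-diameter difference with configurable mean and
positive-fraction.  All generation is a pure function of (parameters,
seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.stats import norm

from .biometry_core import CervicalBiometry
from .volume_io import (
    LABEL_CANAL,
    LABEL_CYST,
    LABEL_INNER_STROMA,
    LABEL_OUTER_STROMA,
    LABEL_UTERUS,
    LabelVolume,
    UterineAxis,
)

__all__ = [
    "PhantomSpec",
    "CohortSimParams",
    "make_phantom",
    "random_phantom_spec",
    "make_cohort",
    "make_rating_replicates",
    "frustum_volume_mm3",
]


def frustum_volume_mm3(length: float, r1: float, r2: float) -> float:
    """Volume of a conical frustum (linear radius taper), mm^3."""
    return math.pi * length * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0


@dataclass(frozen=True)
class PhantomSpec:
    """Analytic description of one uterocervical phantom.

    ``curvature_radius=None`` gives a straight canal; otherwise the
    centerline is a circular arc of that radius (mm) with total arc
    length ``canal_length``.  ``cyst`` is ``(arc_fraction, radius_mm)``
    for an annular endocanal cyst sphere centred on the centerline.
    ``rotation`` applies a rigid xyz-Euler rotation (degrees) to the
    whole phantom before voxelization.
    """

    canal_length: float = 32.0
    canal_radius_internal: float = 2.0
    canal_radius_external: float = 2.0
    inner_stroma_thickness: float = 3.0
    outer_stroma_thickness: float = 4.0
    curvature_radius: float | None = None
    utero_cervical_angle: float = 140.0
    cyst: tuple[float, float] | None = None
    spacing: tuple[float, float, float] = (0.8, 0.8, 0.8)
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    uterus_bar_length: float = 30.0
    uterus_bar_radius: float = 3.0
    #: reserved for stochastic extensions; the geometry itself is
    #: noise-free, so volumes are identical across seeds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.canal_length <= 0:
            raise ValueError("canal_length must be > 0")
        if min(self.canal_radius_internal, self.canal_radius_external) <= 0:
            raise ValueError("canal radii must be > 0")
        if min(self.inner_stroma_thickness, self.outer_stroma_thickness) <= 0:
            raise ValueError("stroma thicknesses must be > 0")
        if not 0.0 < self.utero_cervical_angle < 180.0:
            raise ValueError("utero_cervical_angle must lie in (0, 180)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.curvature_radius is not None:
            if self.curvature_radius <= 0:
                raise ValueError("curvature_radius must be > 0 or None")
            if self.canal_length / self.curvature_radius >= math.pi:
                raise ValueError("arc subtends >= 180 degrees; reduce length "
                                 "or increase curvature_radius")
        if self.cyst is not None:
            frac, rad = self.cyst
            if not 0.0 < frac < 1.0:
                raise ValueError("cyst arc fraction must lie in (0, 1)")
            r_loc = self._canal_radius(frac * self.canal_length)
            if rad <= r_loc:
                raise ValueError(
                    f"cyst radius {rad} must exceed local canal radius {r_loc:.2f}")
            if rad > r_loc + self.inner_stroma_thickness:
                raise ValueError("cyst must stay within the inner stroma envelope")
            s_c = frac * self.canal_length
            if s_c - rad < 0 or s_c + rad > self.canal_length:
                raise ValueError("cyst sphere must not overhang the canal ends")

    # -- analytic centerline ------------------------------------------------
    def _canal_radius(self, s: float) -> float:
        t = s / self.canal_length
        return (1 - t) * self.canal_radius_internal + t * self.canal_radius_external

    def centerline_point(self, s):
        """Centerline position(s) at arc length ``s`` (local, unrotated frame)."""
        s = np.asarray(s, dtype=float)
        if self.curvature_radius is None:
            z = s
            x = np.zeros_like(s)
        else:
            rc = self.curvature_radius
            phi = s / rc
            x = rc * (1 - np.cos(phi))
            z = rc * np.sin(phi)
        return np.stack([x, np.zeros_like(s), z], axis=-1)

    @property
    def _chord_2pt(self) -> float:
        if self.curvature_radius is None:
            return self.canal_length
        rc = self.curvature_radius
        return 2 * rc * math.sin(self.canal_length / (2 * rc))

    @property
    def _chord_3pt(self) -> float:
        if self.curvature_radius is None:
            return self.canal_length
        rc = self.curvature_radius
        return 4 * rc * math.sin(self.canal_length / (4 * rc))

    def ground_truth(self) -> CervicalBiometry:
        """Closed-form biometry implied by the construction parameters."""
        r1, r2 = self.canal_radius_internal, self.canal_radius_external
        wall = self.inner_stroma_thickness + self.outer_stroma_thickness
        canal = frustum_volume_mm3(self.canal_length, r1, r2)
        total = frustum_volume_mm3(self.canal_length, r1 + wall, r2 + wall)
        cyst = 0.0
        if self.cyst is not None:
            frac, rad = self.cyst
            r_loc = self._canal_radius(frac * self.canal_length)
            # sphere minus its intersection with the coaxial canal cylinder
            cyst = (4 * math.pi / 3) * (rad**2 - r_loc**2) ** 1.5
        stroma = total - canal - cyst
        return CervicalBiometry(
            length_2pt=self._chord_2pt,
            length_3pt=self._chord_3pt,
            internal_os_diameter=2 * r1,
            external_os_diameter=2 * r2,
            utero_cervical_angle=self.utero_cervical_angle,
            total_volume=total / 1000.0,
            stroma_volume=stroma / 1000.0,
            canal_volume=canal / 1000.0,
            cyst_volume=cyst / 1000.0,
            meta={"arc_length_mm": self.canal_length},
        )


def _uterine_direction(spec: PhantomSpec) -> np.ndarray:
    """Unit direction (local frame) of the uterine axis away from the cervix.

    Chosen in the arc plane so that its angle with the internal→external
    2-point chord equals the specified utero-cervical angle.
    """
    chord = spec.centerline_point(spec.canal_length) - spec.centerline_point(0.0)
    v = chord / np.linalg.norm(chord)
    w = np.cross([0.0, 1.0, 0.0], v)  # in-plane perpendicular
    w /= np.linalg.norm(w)
    a = math.radians(spec.utero_cervical_angle)
    return math.cos(a) * v + math.sin(a) * w


def make_phantom(spec: PhantomSpec
                 ) -> tuple[LabelVolume, CervicalBiometry, UterineAxis]:
    """Voxelize a phantom; returns (volume, ground truth, uterine axis)."""
    rot = Rotation.from_euler("xyz", spec.rotation, degrees=True)
    sp = np.asarray(spec.spacing, dtype=float)

    # geometry extent: centerline samples +/- outer radius, bar, cyst
    wall = spec.inner_stroma_thickness + spec.outer_stroma_thickness
    r_out = max(spec.canal_radius_internal, spec.canal_radius_external) + wall
    samples = spec.centerline_point(np.linspace(0, spec.canal_length, 64))
    u_dir = _uterine_direction(spec)
    internal = spec.centerline_point(0.0)
    bar_gap = 2.0
    bar_a = internal + bar_gap * u_dir
    bar_b = internal + (bar_gap + spec.uterus_bar_length) * u_dir
    cloud = np.vstack([samples, bar_a[None], bar_b[None]])
    cloud = rot.apply(cloud)
    margin = r_out + spec.uterus_bar_radius + (spec.cyst[1] if spec.cyst else 0.0)
    lo = cloud.min(axis=0) - margin - 5 * sp
    hi = cloud.max(axis=0) + margin + 5 * sp

    shape = np.ceil((hi - lo) / sp).astype(int) + 1
    if np.prod(shape) > 4e8:
        raise ValueError(f"phantom grid {tuple(shape)} exceeds sane size")
    affine = np.eye(4)
    affine[:3, :3] = np.diag(sp)
    affine[:3, 3] = lo

    idx = np.indices(shape).reshape(3, -1).T
    world = idx * sp + lo
    local = rot.inv().apply(world)

    def tube_geom(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Arc position s and radial distance d to the centerline."""
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        if spec.curvature_radius is None:
            return z, np.hypot(x, y)
        rc = spec.curvature_radius
        rho = np.hypot(x - rc, z)
        phi = np.arctan2(z, rc - x)
        return rc * phi, np.hypot(rho - rc, y)

    def canal_r(s: np.ndarray, extra: float) -> np.ndarray:
        t = np.clip(s / spec.canal_length, 0.0, 1.0)
        return ((1 - t) * spec.canal_radius_internal
                + t * spec.canal_radius_external + extra)

    L = spec.canal_length
    s0, d0 = tube_geom(local)
    delta = 0.5 * float(np.linalg.norm(sp))  # half voxel diagonal

    # Boundary voxels are assigned by comparing the supersampled coverage
    # fraction against a fixed low-discrepancy threshold pattern (ordered
    # dithering, Roberts R3 sequence): voxel-count volumes are then
    # unbiased estimates of the analytic volumes irrespective of how the
    # phantom aligns with the lattice, while remaining deterministic and
    # preserving the nesting canal < inner stroma < outer stroma.
    g = 1.22074408460575947536
    thresh = (idx @ (1.0 / g ** np.array([1, 2, 3]))) % 1.0

    radii_extra = (0.0, spec.inner_stroma_thickness, wall)
    definite_in, definite_out, frac_needed = [], [], np.zeros(len(world), bool)
    for extra in radii_extra:
        r_c = canal_r(s0, extra)
        d_in = (d0 <= r_c - delta) & (s0 >= delta) & (s0 <= L - delta)
        d_out = (d0 >= r_c + delta) | (s0 <= -delta) | (s0 >= L + delta)
        definite_in.append(d_in)
        definite_out.append(d_out)
        frac_needed |= ~(d_in | d_out)
    cyst_centre = None
    if spec.cyst is not None:
        cfrac, crad = spec.cyst
        cyst_centre = rot.apply(spec.centerline_point(cfrac * L))
        d_sph = np.linalg.norm(world - cyst_centre, axis=1)
        sph_in = d_sph <= crad - delta
        sph_out = d_sph >= crad + delta
        frac_needed |= ~(sph_in | sph_out)

    ksub = 3
    offs = ((np.arange(ksub) + 0.5) / ksub - 0.5)
    sub_off = np.array(np.meshgrid(offs, offs, offs)).reshape(3, -1).T * sp
    nb = int(frac_needed.sum())
    fracs = [np.zeros(nb) for _ in radii_extra]
    frac_sph = np.zeros(nb)
    wb = world[frac_needed]
    for off in sub_off:
        pts = wb + off
        s_s, d_s = tube_geom(rot.inv().apply(pts))
        span = (s_s >= 0.0) & (s_s <= L)
        for fi, extra in enumerate(radii_extra):
            fracs[fi] += span & (d_s <= canal_r(s_s, extra))
        if cyst_centre is not None:
            frac_sph += np.linalg.norm(pts - cyst_centre, axis=1) <= spec.cyst[1]
    for f in fracs:
        f /= len(sub_off)
    frac_sph /= len(sub_off)

    tb = thresh[frac_needed]
    inside = []
    for fi in range(len(radii_extra)):
        mask = definite_in[fi].copy()
        sel = np.zeros(len(world), bool)
        sel[frac_needed] = fracs[fi] > tb
        mask |= sel & ~definite_out[fi]
        inside.append(mask)
    canal_mask, inner_mask, outer_mask = inside

    vox = np.zeros(len(world), dtype=np.int16)
    vox[outer_mask] = LABEL_OUTER_STROMA
    vox[inner_mask] = LABEL_INNER_STROMA
    vox[canal_mask] = LABEL_CANAL

    if cyst_centre is not None:
        in_sphere = np.linalg.norm(world - cyst_centre, axis=1) <= spec.cyst[1] - delta
        sel = np.zeros(len(world), bool)
        sel[frac_needed] = frac_sph > tb
        in_sphere |= sel
        vox[in_sphere & ~canal_mask] = LABEL_CYST

    # uterine reference bar: capsule around bar_a..bar_b, background only
    a_w, b_w = rot.apply(bar_a), rot.apply(bar_b)
    ab = b_w - a_w
    tt = np.clip((world - a_w) @ ab / (ab @ ab), 0.0, 1.0)
    dist_bar = np.linalg.norm(world - (a_w + tt[:, None] * ab), axis=1)
    vox[(dist_bar <= spec.uterus_bar_radius) & (vox == 0)] = LABEL_UTERUS

    volume = LabelVolume(voxels=vox.reshape(shape), affine=affine)
    axis = UterineAxis(point_a=a_w, point_b=b_w, source="sidecar")
    return volume, spec.ground_truth(), axis


def random_phantom_spec(rng: np.random.Generator,
                        spacing: float = 0.8,
                        allow_cyst: bool = True) -> PhantomSpec:
    """Draw a realistic randomized phantom for the recovery test suite.

    Dimensions span the late-gestation range: canal length 20-40 mm,
    canal radii 1.5-3.5 mm, walls a few mm, utero-cervical angle
    60-160 degrees, optional gentle curvature and an occasional cyst.
    """
    r_int = float(rng.uniform(1.6, 3.5))
    r_ext = float(rng.uniform(1.6, 3.5))
    length = float(rng.uniform(20.0, 40.0))
    curved = rng.random() < 0.5
    curvature = float(rng.uniform(30.0, 120.0)) if curved else None
    cyst = None
    if allow_cyst and rng.random() < 0.3:
        frac = float(rng.uniform(0.35, 0.65))
        t = frac
        r_loc = (1 - t) * r_int + t * r_ext
        cyst = (frac, float(r_loc + rng.uniform(0.8, 1.8)))
    return PhantomSpec(
        canal_length=length,
        canal_radius_internal=r_int,
        canal_radius_external=r_ext,
        inner_stroma_thickness=float(rng.uniform(2.0, 4.0)),
        outer_stroma_thickness=float(rng.uniform(2.5, 5.0)),
        curvature_radius=curvature,
        utero_cervical_angle=float(rng.uniform(60.0, 160.0)),
        cyst=cyst,
        spacing=(spacing,) * 3,
        rotation=tuple(rng.uniform(-45.0, 45.0, size=3)),
    )


# ---------------------------------------------------------------------------
# cohort simulation

DEFAULT_ETHNICITY_MIX = {
    "White": 0.55, "Black": 0.15, "Asian": 0.15, "Mixed": 0.08, "Other": 0.07,
}


@dataclass(frozen=True)
class CohortSimParams:
    """Parameters of the synthetic late-gestation cohort.

    Ranges follow the study population (maternal age 19-42 years, BMI
    18-32, gestational age ~35.7-40.1 weeks at scan); the caesarean
    odds ratio per cm^3 of total cervical volume defaults to 1.09 and
    the os-diameter difference to mean 3.5 mm with 81.8% of subjects
    having internal > external.  Effect magnitudes without a published
    value (length and age slopes, baselines, noise SDs) are generator
    defaults, not literature claims.
    """

    n: int = 100
    age_range: tuple[float, float] = (19.0, 42.0)
    bmi_range: tuple[float, float] = (18.0, 32.0)
    ga_range: tuple[float, float] = (35.71, 40.14)
    ethnicity_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ETHNICITY_MIX))
    nulliparous_frac: float = 0.85
    length_mean_mm: float = 30.0
    length_sd_mm: float = 6.0
    stroma_baseline_cm3: float = 35.0
    stroma_vol_age_slope: float = 0.4        # cm^3 per year, > 0 by default
    stroma_vol_length_slope: float = 0.5     # cm^3 per mm of cervical length
    stroma_noise_sd_cm3: float = 5.0
    canal_baseline_cm3: float = 1.5
    canal_vol_length_slope: float = 0.03
    canal_noise_sd_cm3: float = 0.4
    ext_os_baseline_mm: float = 8.0
    os_diam_length_slope: float = -0.15      # mm per mm of length
    os_noise_sd_mm: float = 1.5
    os_diff_mean_mm: float = 3.5
    internal_gt_external_frac: float = 0.818
    uca_baseline_deg: float = 110.0
    uca_length_slope: float = -1.0
    uca_noise_sd_deg: float = 10.0
    baseline_caesarean_prob: float = 0.25
    caesarean_or_per_cm3: float = 1.09
    baseline_induction_prob: float = 0.40
    induction_or_per_mm_ext_os: float = 0.83
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        probs = np.array(list(self.ethnicity_mix.values()))
        if np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("ethnicity probabilities must be >= 0 and sum to 1")
        for p in (self.baseline_caesarean_prob, self.baseline_induction_prob,
                  self.internal_gt_external_frac, self.nulliparous_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.caesarean_or_per_cm3 <= 0 or self.induction_or_per_mm_ext_os <= 0:
            raise ValueError("odds ratios must be positive")

    def null(self) -> "CohortSimParams":
        """Copy with every association effect set to zero (null cohort)."""
        from dataclasses import replace
        return replace(
            self,
            stroma_vol_age_slope=0.0, stroma_vol_length_slope=0.0,
            canal_vol_length_slope=0.0, os_diam_length_slope=0.0,
            uca_length_slope=0.0, caesarean_or_per_cm3=1.0,
            induction_or_per_mm_ext_os=1.0)


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def make_cohort(p: CohortSimParams) -> pd.DataFrame:
    """Simulate a cohort table; fully reproducible under ``p.seed``."""
    rng = np.random.default_rng(p.seed)
    n = p.n
    age = rng.uniform(*p.age_range, size=n)
    bmi = rng.uniform(*p.bmi_range, size=n)
    ga = rng.uniform(*p.ga_range, size=n)
    cats = list(p.ethnicity_mix)
    ethnicity = rng.choice(cats, size=n, p=list(p.ethnicity_mix.values()))
    parity = (rng.random(n) >= p.nulliparous_frac).astype(int)

    length = rng.normal(p.length_mean_mm, p.length_sd_mm, size=n)
    length = np.clip(length, 12.0, 55.0)
    age_c = age - np.mean(p.age_range)
    len_c = length - p.length_mean_mm

    stroma = (p.stroma_baseline_cm3
              + p.stroma_vol_age_slope * age_c
              + p.stroma_vol_length_slope * len_c
              + rng.normal(0.0, p.stroma_noise_sd_cm3, size=n))
    stroma = np.clip(stroma, 5.0, None)
    canal = (p.canal_baseline_cm3 + p.canal_vol_length_slope * len_c
             + rng.normal(0.0, p.canal_noise_sd_cm3, size=n))
    canal = np.clip(canal, 0.1, None)
    total = stroma + canal

    ext_os = (p.ext_os_baseline_mm + p.os_diam_length_slope * len_c
              + rng.normal(0.0, p.os_noise_sd_mm, size=n))
    ext_os = np.clip(ext_os, 0.5, None)
    # diff ~ N(mean, sd) with sd set so P(diff > 0) equals the target fraction
    if 0.0 < p.internal_gt_external_frac < 1.0 and p.os_diff_mean_mm != 0.0:
        diff_sd = abs(p.os_diff_mean_mm) / norm.ppf(p.internal_gt_external_frac)
    else:
        diff_sd = 1.0
    diff = rng.normal(p.os_diff_mean_mm, abs(diff_sd), size=n)
    int_os = np.clip(ext_os + diff, 0.2, None)

    uca = (p.uca_baseline_deg + p.uca_length_slope * len_c
           + rng.normal(0.0, p.uca_noise_sd_deg, size=n))
    uca = np.clip(uca, 5.0, 175.0)

    # binary outcomes from logistic models centred on the expected covariate
    mean_total = p.stroma_baseline_cm3 + p.canal_baseline_cm3
    eta_cs = (_logit(p.baseline_caesarean_prob)
              + math.log(p.caesarean_or_per_cm3) * (total - mean_total))
    caesarean = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta_cs))).astype(int)
    eta_ind = (_logit(p.baseline_induction_prob)
               + math.log(p.induction_or_per_mm_ext_os)
               * (ext_os - p.ext_os_baseline_mm))
    induced = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta_ind))).astype(int)

    return pd.DataFrame({
        "id": [f"S{i:05d}" for i in range(n)],
        "age": age, "bmi": bmi, "ethnicity": ethnicity,
        "ga_weeks": ga, "parity": parity,
        "length_2pt_mm": length,
        "stroma_vol_cm3": stroma, "canal_vol_cm3": canal,
        "total_vol_cm3": total,
        "int_os_diam_mm": int_os, "ext_os_diam_mm": ext_os,
        "uca_deg": uca,
        "caesarean": caesarean, "induced": induced,
    })


def make_rating_replicates(true_values: Sequence[float], rater_sd: float,
                           n_raters: int, seed: int = 0) -> np.ndarray:
    """Subjects x raters matrix: true value + iid Gaussian rater noise."""
    if rater_sd < 0:
        raise ValueError("rater_sd must be >= 0")
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    rng = np.random.default_rng(seed)
    truth = np.asarray(true_values, dtype=float)[:, None]
    return truth + rng.normal(0.0, rater_sd, size=(len(truth), n_raters))
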