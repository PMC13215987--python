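"""Synthetic abdominal-slice phantoms and simulated calibration cohorts.

An axial abdominal slice on opposed-phase T1 imaging shows a bright
subcutaneous fat (SAT) ring just under the skin, scattered bright visceral
fat (VAT) deposits around the central organs, darker lean tissue, a dark
background, and — when the patient's arms are in the field of view — two
small fat-rimmed limb cross-sections lateral to the body.  The phantom
reproduces this layout with full pixel-level ground truth so the whole
segmentation pipeline can be validated without patient data.

By default the SAT ring is thicker posteriorly.  Real subcutaneous fat is
rarely a concentric annulus, and the downstream VAT/SAT delineation rule
compares centroid-to-image-center distances, which is degenerate for a
perfectly symmetric ring; the asymmetric default keeps the rule well-posed.

The cohort simulator draws (automated area, subgroup indicators) records and
computes the reference-standard area from a linear bias model plus Gaussian
residual noise, mirroring the structure of the area-correction regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic abdominal slice.

    ``sat_ring_thickness_px`` is per quadrant (anterior, right, posterior,
    left); the posterior default is thicker so the SAT centroid is
    measurably off-center.  ``intensity_levels`` are the noiseless means for
    (background, lean, fat) in [0, 1]; fat must be brightest and background
    darkest, as on opposed-phase T1.
    """

    image_height_px: int = 128
    image_width_px: int = 192
    body_center_offset_px: tuple[float, float] = (0.0, 0.0)
    body_axes_px: tuple[float, float] = (52.0, 42.0)
    sat_ring_thickness_px: tuple[float, float, float, float] = (5.0, 5.0, 25.0, 5.0)
    n_vat_blobs: int = 4
    vat_blob_radius_range_px: tuple[float, float] = (2.0, 4.0)
    vat_scatter_radius_px: float = 9.5
    include_arms: bool = True
    intensity_levels: tuple[float, float, float] = (0.10, 0.30, 0.90)
    noise_sd: float = 0.0
    noise_model: str = "gaussian"  # or "rician"
    seed: int = 0

    def validate(self) -> None:
        bg, lean, fat = self.intensity_levels
        if not (fat > lean > bg):
            raise ValueError(
                "intensity_levels must satisfy fat > lean > background, "
                f"got {self.intensity_levels}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if min(self.sat_ring_thickness_px) <= 0:
            raise ValueError("SAT ring thickness must be positive")
        rmin, rmax = self.vat_blob_radius_range_px
        if not (0 < rmin <= rmax):
            raise ValueError("invalid VAT blob radius range")
        a, b = self.body_axes_px
        cr = (self.image_height_px - 1) / 2 + self.body_center_offset_px[0]
        cc = (self.image_width_px - 1) / 2 + self.body_center_offset_px[1]
        if cr - a < 0 or cr + a > self.image_height_px - 1:
            raise ValueError(
                f"body ellipse exceeds image rows: semi-axis {a} at row "
                f"center {cr} outside [0, {self.image_height_px - 1}]"
            )
        if cc - b < 0 or cc + b > self.image_width_px - 1:
            raise ValueError(
                f"body ellipse exceeds image cols: semi-axis {b} at col "
                f"center {cc} outside [0, {self.image_width_px - 1}]"
            )


@dataclass(frozen=True)
class CompartmentMasks:
    """Disjoint SAT/VAT binary masks; TAT is their union."""

    sat: np.ndarray
    vat: np.ndarray

    @property
    def tat(self) -> np.ndarray:
        return (self.sat | self.vat).astype(np.uint8)

    def validate(self) -> None:
        if self.sat.shape != self.vat.shape:
            raise ValueError("SAT and VAT masks differ in shape")
        if np.any(self.sat & self.vat):
            raise ValueError("SAT and VAT masks overlap")


def _quadrant_thickness(theta: np.ndarray, t: tuple[float, float, float, float]) -> np.ndarray:
    """Ring thickness by quadrant of the polar angle around the body center.

    theta = atan2(drow, dcol); anterior is up (negative rows), posterior down.
    """
    anterior, right, posterior, left = t
    out = np.empty_like(theta)
    deg = np.degrees(theta) % 360.0
    out[(deg >= 225) & (deg < 315)] = anterior  # -row direction
    out[(deg >= 315) | (deg < 45)] = right      # +col direction
    out[(deg >= 45) & (deg < 135)] = posterior  # +row direction
    out[(deg >= 135) & (deg < 225)] = left      # -col direction
    return out


def generate_slice_phantom(
    spec: PhantomSpec,
) -> tuple[np.ndarray, CompartmentMasks, np.ndarray, np.ndarray]:
    """Render a phantom slice with ground truth.

    Returns ``(image, masks, arm_mask, abdominal_mask)`` where ``image`` is
    float64 in [0, 1], ``masks`` holds the ground-truth SAT/VAT
    compartments, ``arm_mask`` marks all arm pixels (fat rim plus lean
    interior) and ``abdominal_mask`` the body cross-section (excludes arms).

    Identical spec (including seed) gives bit-identical output.  With
    ``noise_sd == 0`` the image takes exactly the three intensity levels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height_px, spec.image_width_px
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)

    cr = (h - 1) / 2 + spec.body_center_offset_px[0]
    cc = (w - 1) / 2 + spec.body_center_offset_px[1]
    a, b = spec.body_axes_px
    dr, dc = rows - cr, cols - cc

    body = (dr / a) ** 2 + (dc / b) ** 2 <= 1.0
    theta = np.arctan2(dr, dc)
    thick = _quadrant_thickness(theta, spec.sat_ring_thickness_px)
    inner_a, inner_b = a - thick, b - thick
    if np.any(inner_a <= 1) or np.any(inner_b <= 1):
        raise ValueError("SAT ring thickness leaves no lean interior")
    lean_region = (dr / inner_a) ** 2 + (dc / inner_b) ** 2 <= 1.0
    sat = body & ~lean_region

    vat = np.zeros((h, w), dtype=bool)
    placed: list[tuple[float, float, float]] = []
    rmin, rmax = spec.vat_blob_radius_range_px
    max_attempts = 1000
    for i in range(spec.n_vat_blobs):
        for _attempt in range(max_attempts):
            r = rng.uniform(rmin, rmax)
            # Visceral fat clusters centrally around the organs: blob
            # centers stay within a small scatter disk around the body
            # center so the SAT ring (centroid pushed off-center by its
            # posterior thickening) is always the peripheral compartment.
            rho = spec.vat_scatter_radius_px * np.sqrt(rng.random())
            phi = rng.uniform(0, 2 * np.pi)
            br = cr + rho * np.sin(phi)
            bc = cc + rho * np.cos(phi)
            blob = (rows - br) ** 2 + (cols - bc) ** 2 <= r**2
            grown = (rows - br) ** 2 + (cols - bc) ** 2 <= (r + 1.5) ** 2
            if np.any(grown & ~lean_region):
                continue
            if any(
                np.hypot(br - pr, bc - pc) <= r + prr + 2.0
                for pr, pc, prr in placed
            ):
                continue
            placed.append((br, bc, r))
            vat |= blob
            break
        else:
            raise RuntimeError(
                f"could not place VAT blob {i + 1}/{spec.n_vat_blobs} after "
                f"{max_attempts} attempts; reduce n_vat_blobs, radii, or "
                "vat_scatter_radius_px"
            )

    arm_mask = np.zeros((h, w), dtype=bool)
    arm_fat = np.zeros((h, w), dtype=bool)
    if spec.include_arms:
        # A wide gap keeps arms disconnected from the trunk even after the
        # abdominal-mask closing step downstream.
        gap = 26.0
        arm_ra, arm_rb = 18.0, 8.0
        if cc + b + gap + 2 * arm_rb > w - 1:
            raise ValueError("no lateral room for arms; widen the image")
        rim = 3.0
        for side in (-1, 1):
            ac = cc + side * (b + gap + arm_rb)
            ar = cr
            d2 = ((rows - ar) / arm_ra) ** 2 + ((cols - ac) / arm_rb) ** 2
            outer = d2 <= 1.0
            inner = ((rows - ar) / (arm_ra - rim)) ** 2 + (
                (cols - ac) / (arm_rb - rim)
            ) ** 2 <= 1.0
            arm_mask |= outer
            arm_fat |= outer & ~inner
        if np.any(arm_mask & body):
            raise ValueError("arms overlap the body ellipse; shrink body_axes_px")

    bg_level, lean_level, fat_level = spec.intensity_levels
    img = np.full((h, w), bg_level)
    img[body] = lean_level
    img[arm_mask] = lean_level
    img[sat | vat | arm_fat] = fat_level

    if spec.noise_sd > 0:
        if spec.noise_model == "gaussian":
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        else:  # rician: magnitude of complex Gaussian perturbation
            re = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
            im = rng.normal(0.0, spec.noise_sd, size=img.shape)
            img = np.hypot(re, im)
        img = np.clip(img, 0.0, 1.0)

    masks = CompartmentMasks(sat=sat.astype(np.uint8), vat=vat.astype(np.uint8))
    masks.validate()
    return img, masks, arm_mask.astype(np.uint8), body.astype(np.uint8)


@dataclass(frozen=True)
class CohortSimSpec:
    """Generator for synthetic calibration cohorts.

    The response (reference-standard area) is
    ``intercept + slope * area_auto + group_coef * indicator + N(0, sd)``
    where the indicator column is named by ``group_term`` ("obesity" or
    "adult").  Sex and age strata are drawn independently so that
    inverse-frequency Sex x Age weighting is exercised.

    Defaults mirror the published cohort structure: n=68 patients, 30/68
    male, 47/68 adult, with the VAT bias model's residual scale.
    """

    n: int = 68
    intercept: float = 7.224
    slope: float = 1.112
    group_coef: float = 7.583
    group_term: str = "obesity"
    residual_sd: float = 11.5
    predictor_range_cm2: tuple[float, float] = (5.0, 300.0)
    predictor_spacing: str = "uniform"  # or "even"
    group_assignment: str = "random"  # or "half": indicator 1 for second half
    frac_male: float = 30 / 68
    frac_adult: float = 47 / 68
    frac_obese: float = 0.25
    seed: int = 0
    predictor_name: str = "area_auto_cm2"
    response_name: str = "area_manual_cm2"

    def validate(self) -> None:
        if self.n < 3:
            raise ValueError("n must be at least the number of model terms (3)")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        for name in ("frac_male", "frac_adult", "frac_obese"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {f}")
        if self.group_term not in ("obesity", "adult"):
            raise ValueError(f"unknown group_term {self.group_term!r}")
        lo, hi = self.predictor_range_cm2
        if not (0 <= lo <= hi):
            raise ValueError("invalid predictor range")
        if self.predictor_spacing not in ("uniform", "even"):
            raise ValueError("predictor_spacing must be 'uniform' or 'even'")
        if self.group_assignment not in ("random", "half"):
            raise ValueError("group_assignment must be 'random' or 'half'")


def generate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Simulate a cohort table for the area-correction regressions.

    Columns: case_id, sex, age_category, obesity, the automated-area
    predictor and the noisy response.  With ``residual_sd == 0`` the
    response equals the linear predictor exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.predictor_range_cm2
    if spec.predictor_spacing == "even":
        area = np.linspace(lo, hi, spec.n)
    else:
        area = rng.uniform(lo, hi, size=spec.n)

    sex = np.where(rng.random(spec.n) < spec.frac_male, "male", "female")
    age = np.where(rng.random(spec.n) < spec.frac_adult, "adult", "child")
    obesity = (rng.random(spec.n) < spec.frac_obese).astype(int)

    if spec.group_assignment == "half":
        indicator = (np.arange(spec.n) >= spec.n - spec.n // 2).astype(int)
        if spec.group_term == "obesity":
            obesity = indicator
        else:
            age = np.where(indicator == 1, "adult", "child")
    elif spec.group_term == "obesity":
        # indicator 1 for exactly the simulated obese stratum
        indicator = obesity
    else:
        indicator = (age == "adult").astype(int)
    if spec.group_coef != 0 and (indicator.sum() == 0 or indicator.sum() == spec.n):
        raise ValueError(
            f"stratum for {spec.group_term!r} is empty on one side but its "
            "coefficient is nonzero; adjust the group fraction or n"
        )

    linpred = spec.intercept + spec.slope * area + spec.group_coef * indicator
    noise = rng.normal(0.0, spec.residual_sd, size=spec.n) if spec.residual_sd > 0 else 0.0
    return pd.DataFrame(
        {
            "case_id": [f"case_{i:04d}" for i in range(spec.n)],
            "sex": sex,
            "age_category": age,
            "obesity": obesity,
            spec.predictor_name: area,
            spec.response_name: linpred + noise,
        }
    )
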