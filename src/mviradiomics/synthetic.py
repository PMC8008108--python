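"""Synthetic quadriphasic CT phantom cohorts.

Generates reproducible liver phantoms carrying the statistical structure the
downstream analysis assumes: a lobulated tumor inside a liver ellipsoid,
vessel and bile-duct barrier tubes, and four co-registered contrast-phase
volumes (EAP/LAP/PVP/EP) that share anatomy but differ by per-tissue
contrast offsets.  MVI-positive cases additionally carry, on the
portal-venous-phase analog only (configurable):

* an additive intensity shift (``effect_intensity``) throughout the
  peritumoral shell within ``effect_shell_mm`` of the tumor margin, which
  raises first-order statistics (10th percentile, mean, median, RMS) there;
* speckle patches of a second gray-level population
  (``effect_heterogeneity``) in the same shell, which raises zone-size
  heterogeneity (lowers GLSZM gray-level non-uniformity dominance).

All random draws are made regardless of the case label and the label only
gates whether the class effects are applied, so a positive and a negative
generated from the same seed are voxel-matched except for the injected
effect.  Intensities are HU-like integers clipped to [-200, 400].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage


class GeometryError(ValueError):
    """Tumor cannot fit inside the liver with the required parenchyma margin."""


#: Per-tissue HU-like base intensities for each contrast phase.
TISSUE_INTENSITY: dict[str, dict[str, float]] = {
    "EAP": {"background": -100, "liver": 70, "tumor": 95, "vessel": 150, "duct": 30},
    "LAP": {"background": -100, "liver": 90, "tumor": 100, "vessel": 180, "duct": 30},
    "PVP": {"background": -100, "liver": 110, "tumor": 80, "vessel": 170, "duct": 30},
    "EP": {"background": -100, "liver": 95, "tumor": 85, "vessel": 120, "duct": 30},
}

INTENSITY_RANGE = (-200, 400)

#: Largest peritumoral distance the region analysis uses; the generator
#: guarantees at least this much parenchyma around the tumor.
MAX_PERITUMORAL_MM = 14.0

#: Intensity offset of the heterogeneity speckle population (larger than the
#: default 25-unit discretization bin so the patches occupy distinct gray
#: levels).
SPECKLE_DELTA = 40.0


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters for one synthetic cohort.

    Defaults emulate the study conditions: a 111-patient cohort with 57
    MVI-positive cases, the class effect carried by the portal venous phase
    within 12 mm of the tumor margin.
    """

    n_patients: int = 111
    prevalence: float = 57 / 111
    volume_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tumor_radius_mm: tuple[float, float] = (8.0, 12.0)
    effect_intensity: float = 50.0
    effect_heterogeneity: float = 0.3
    effect_shell_mm: float = 12.0
    effect_phases: tuple[str, ...] = ("PVP",)
    noise_sd: float = 5.0
    between_case_sd: float = 10.0
    tissue_contrast_sd: float = 10.0
    barrier_density: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing components must be positive")
        if not 0 <= self.effect_heterogeneity <= 1:
            raise ValueError("effect_heterogeneity must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.between_case_sd < 0:
            raise ValueError("between_case_sd must be >= 0")
        lo, hi = self.tumor_radius_mm
        if not 0 < lo <= hi:
            raise ValueError("tumor_radius_mm must be an increasing positive range")


@dataclass
class PhantomCase:
    """One synthetic patient: four phase volumes, anatomy masks, label."""

    case_id: str
    phase_volumes: dict[str, np.ndarray]
    liver_mask: np.ndarray
    tumor_mask: np.ndarray
    vessel_mask: np.ndarray
    bileduct_mask: np.ndarray
    spacing_mm: tuple[float, float, float]
    mvi_label: int
    chronological_index: int = 0
    spec: CohortSpec | None = None
    case_seed: int = 0

    def validate(self) -> None:
        shape = self.liver_mask.shape
        for name, m in (
            ("tumor", self.tumor_mask),
            ("vessel", self.vessel_mask),
            ("bileduct", self.bileduct_mask),
        ):
            if m.shape != shape:
                raise ValueError(f"{name} mask shape differs from liver mask")
        for p, vol in self.phase_volumes.items():
            if vol.shape != shape:
                raise ValueError(f"phase {p} volume shape differs from masks")
        if (self.tumor_mask & ~self.liver_mask).any():
            raise ValueError("tumor mask extends outside liver")
        if (self.vessel_mask & self.tumor_mask).any():
            raise ValueError("vessel mask intersects tumor")
        if self.mvi_label not in (0, 1):
            raise ValueError("mvi_label must be 0 or 1")


def _coord_grid_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _rasterize_tube(shape, spacing, path_mm, radius_mm):
    """Binary tube: voxels within radius_mm of a polyline (via EDT seed trick)."""
    seed = np.zeros(shape, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    for pt in path_mm:
        idx = np.round(np.asarray(pt) / spacing).astype(int)
        if np.all(idx >= 0) and np.all(idx < shape):
            seed[tuple(idx)] = True
    if not seed.any():
        return seed
    d = ndimage.distance_transform_edt(~seed, sampling=spacing)
    return d <= radius_mm


def generate_phantom(spec: CohortSpec, case_seed: int, label: int) -> PhantomCase:
    """Generate one phantom case, deterministic in ``(spec, case_seed, label)``.

    A label flip with the same seed changes only the injected class effect.
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, case_seed])
    shape = tuple(spec.volume_shape)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    extent = np.asarray(shape) * spacing
    center = extent / 2.0

    grid = _coord_grid_mm(shape, spacing)

    # liver: centered ellipsoid with mild random radius jitter
    liver_radii = 0.44 * extent * rng.uniform(0.96, 1.0, size=3)
    liver = (
        sum(((g - c) / r) ** 2 for g, c, r in zip(grid, center, liver_radii)) <= 1.0
    )

    # tumor: jittered sphere with a low-frequency boundary perturbation
    r_lo, r_hi = spec.tumor_radius_mm
    tumor_r = rng.uniform(r_lo, r_hi)
    margin = tumor_r + MAX_PERITUMORAL_MM
    slack = liver_radii.min() - margin
    if slack <= 0:
        raise GeometryError(
            f"tumor radius {tumor_r:.1f} mm + {MAX_PERITUMORAL_MM:.0f} mm "
            f"peritumoral margin does not fit inside the liver "
            f"(min liver radius {liver_radii.min():.1f} mm); enlarge "
            "volume_shape/spacing or reduce tumor_radius_mm"
        )
    offset = rng.uniform(-0.5, 0.5, size=3) * slack
    t_center = center + offset
    dist_t = np.sqrt(sum((g - c) ** 2 for g, c in zip(grid, t_center)))
    pert = ndimage.gaussian_filter(rng.normal(size=shape), sigma=3.0)
    pert *= 0.12 * tumor_r / max(float(np.abs(pert).max()), 1e-12)
    tumor = (dist_t <= tumor_r + pert) & liver

    # barrier tubes: vessels of mixed caliber plus thin bile ducts
    n_vessels = int(rng.poisson(spec.barrier_density))
    vessel = np.zeros(shape, dtype=bool)
    for _ in range(n_vessels):
        start = center + rng.uniform(-0.5, 0.5, size=3) * liver_radii
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        step = spacing.min()
        path = [start]
        for _ in range(40):
            direction = direction + 0.35 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            path.append(path[-1] + direction * step)
        radius = rng.choice([0.8, 1.2, 1.6, 2.2])
        vessel |= _rasterize_tube(shape, spacing, path, radius)
    duct = np.zeros(shape, dtype=bool)
    for _ in range(max(int(rng.poisson(spec.barrier_density / 2.0)), 0)):
        start = center + rng.uniform(-0.4, 0.4, size=3) * liver_radii
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        path = [start + i * direction * spacing.min() for i in range(30)]
        duct |= _rasterize_tube(shape, spacing, path, 0.7)
    vessel &= liver & ~tumor
    duct &= liver & ~tumor & ~vessel

    # peritumoral shell carrying the class effect
    dist_to_tumor = ndimage.distance_transform_edt(~tumor, sampling=spacing)
    shell = (dist_to_tumor <= spec.effect_shell_mm) & liver & ~tumor

    # heterogeneity speckle patches (drawn regardless of label)
    n_patches = int(round(spec.effect_heterogeneity * 20))
    speckle = np.zeros(shape, dtype=bool)
    shell_idx = np.argwhere(shell)
    if len(shell_idx) and n_patches:
        picks = rng.integers(0, len(shell_idx), size=n_patches)
        radii = rng.uniform(2.0, 4.0, size=n_patches)
        for pick, pr in zip(picks, radii):
            c_mm = shell_idx[pick] * spacing
            d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grid, c_mm)))
            speckle |= d <= pr
        speckle &= shell

    # between-patient variability, drawn regardless of label: one global HU
    # offset per case and phase (scanner/physiology), plus per-tissue
    # enhancement jitter (patients differ in tumor/parenchyma contrast)
    case_offset = {
        p: rng.normal(0.0, spec.between_case_sd) for p in TISSUE_INTENSITY
    }
    tissue_jitter = {
        p: {
            t: rng.normal(0.0, spec.tissue_contrast_sd)
            for t in ("liver", "tumor", "vessel", "duct")
        }
        for p in TISSUE_INTENSITY
    }
    noise = {p: rng.normal(0.0, spec.noise_sd, size=shape) for p in TISSUE_INTENSITY}

    phase_volumes: dict[str, np.ndarray] = {}
    for phase, tiss in TISSUE_INTENSITY.items():
        jit = tissue_jitter[phase]
        vol = np.full(shape, float(tiss["background"]))
        vol[liver] = tiss["liver"] + jit["liver"]
        vol[tumor] = tiss["tumor"] + jit["tumor"]
        vol[vessel] = tiss["vessel"] + jit["vessel"]
        vol[duct] = tiss["duct"] + jit["duct"]
        if label == 1 and phase in spec.effect_phases:
            vol[shell] += spec.effect_intensity
            if spec.effect_heterogeneity > 0:
                vol[speckle] += SPECKLE_DELTA
        vol += case_offset[phase] + noise[phase]
        phase_volumes[phase] = np.clip(np.round(vol), *INTENSITY_RANGE).astype(
            np.int16
        )

    case = PhantomCase(
        case_id=f"case{case_seed:04d}",
        phase_volumes=phase_volumes,
        liver_mask=liver,
        tumor_mask=tumor,
        vessel_mask=vessel,
        bileduct_mask=duct,
        spacing_mm=tuple(float(s) for s in spacing),
        mvi_label=int(label),
        chronological_index=case_seed,
        spec=spec,
        case_seed=case_seed,
    )
    case.validate()
    return case


def cohort_labels(spec: CohortSpec) -> np.ndarray:
    """Chronologically ordered label sequence with exactly
    ``round(n_patients * prevalence)`` positives."""
    n_pos = int(round(spec.n_patients * spec.prevalence))
    if n_pos == 0 or n_pos == spec.n_patients:
        raise ValueError(
            f"prevalence {spec.prevalence} yields {n_pos} positives out of "
            f"{spec.n_patients}; both classes must be represented"
        )
    labels = np.array([1] * n_pos + [0] * (spec.n_patients - n_pos))
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 0xC0F0])
    rng.shuffle(labels)
    return labels


def generate_cohort(spec: CohortSpec) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Generate a full cohort plus its label table.

    Cases carry a chronological index (their position in the generated
    sequence) so the chronological train/test split is well defined.
    """
    labels = cohort_labels(spec)
    cases = [
        generate_phantom(spec, case_seed=i, label=int(lab))
        for i, lab in enumerate(labels)
    ]
    table = pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "chronological_index": [c.chronological_index for c in cases],
            "mvi_label": [c.mvi_label for c in cases],
            "tumor_voxels": [int(c.tumor_mask.sum()) for c in cases],
            "seed": spec.seed,
        }
    )
    return cases, table
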