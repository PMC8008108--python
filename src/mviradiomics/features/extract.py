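"""Per-case feature extraction and phase concatenation.

A single region on a single contrast phase yields 94 named features
(19 first-order + 24 GLCM + 16 GLSZM + 16 GLRLM + 5 NGTDM + 14 GLDM).
Vectors from several phases are concatenated with phase-prefixed names into
the 15 possible phase-combination groups (4 singles, 6 pairs, 4 triples and
the full quadriphasic set), giving 94/188/282/376 columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalogue import ALL_FEATURE_NAMES, N_FEATURES
from .discretize import DEFAULT_BIN_WIDTH, discretize
from .firstorder import first_order_features
from .texture import (
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

#: Contrast phases in acquisition order: early arterial, late arterial,
#: portal venous, equilibrium.
PHASES: tuple[str, ...] = ("EAP", "LAP", "PVP", "EP")
_PHASE_INDEX = {p: i + 1 for i, p in enumerate(PHASES)}


@dataclass(frozen=True)
class PhaseCombo:
    """A non-empty subset of the four contrast phases."""

    phases: tuple[str, ...]

    def __post_init__(self):
        if not self.phases:
            raise ValueError("phase combo must be non-empty")
        unknown = set(self.phases) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phases: {sorted(unknown)}")
        if len(set(self.phases)) != len(self.phases):
            raise ValueError("duplicate phases in combo")
        # canonical acquisition order
        object.__setattr__(
            self, "phases", tuple(p for p in PHASES if p in self.phases)
        )

    @property
    def label(self) -> str:
        """Canonical label, e.g. ``Fpha3`` or ``Fpha3;4``."""
        return "Fpha" + ";".join(str(_PHASE_INDEX[p]) for p in self.phases)

    def __len__(self) -> int:
        return len(self.phases)

    def __iter__(self):
        return iter(self.phases)


def all_phase_combos() -> list[PhaseCombo]:
    """All 15 non-empty phase subsets (4 + 6 + 4 + 1)."""
    combos = []
    for r in range(1, len(PHASES) + 1):
        for subset in itertools.combinations(PHASES, r):
            combos.append(PhaseCombo(subset))
    return combos


@dataclass
class FeatureVector:
    """Named radiomic features for one (phase set, region) of one case."""

    values: dict[str, float]
    phases: tuple[str, ...]
    region: str
    bin_width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self):
        expected = N_FEATURES * len(self.phases)
        if len(self.values) != expected:
            raise ValueError(
                f"feature vector for {len(self.phases)} phase(s) must have "
                f"{expected} values, got {len(self.values)}"
            )

    @property
    def names(self) -> list[str]:
        return list(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=float)


def extract_features(
    image: np.ndarray,
    mask: np.ndarray,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> dict[str, float]:
    """Compute the 94-feature catalogue for one image/mask pair.

    Raises ``ValueError`` for degenerate regions (fewer than 2 voxels),
    naming the families that cannot be computed.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    n_vox = int(mask.sum())
    if n_vox < 2:
        raise ValueError(
            f"degenerate region ({n_vox} voxel(s)): first-order statistics, "
            "GLCM/GLSZM/GLRLM/NGTDM/GLDM all require >= 2 voxels"
        )
    voxel_volume = float(np.prod(spacing_mm))
    # crop to the mask bounding box: texture matrices only involve in-mask
    # voxels and their immediate neighbors, so this is exact and much faster
    bbox = tuple(
        slice(int(idx.min()), int(idx.max()) + 1) for idx in np.nonzero(mask)
    )
    image = image[bbox]
    mask = mask[bbox]
    vals = image[mask]
    levels = np.zeros(image.shape, dtype=np.int64)
    levels[mask] = discretize(vals, bin_width)

    out: dict[str, float] = {}
    for name, val in first_order_features(vals, voxel_volume, bin_width).items():
        out[f"firstorder_{name}"] = val
    for fam, fn in (
        ("glcm", glcm_features),
        ("glszm", glszm_features),
        ("glrlm", glrlm_features),
        ("ngtdm", ngtdm_features),
        ("gldm", gldm_features),
    ):
        for name, val in fn(levels, mask).items():
            out[f"{fam}_{name}"] = val
    assert tuple(out) == ALL_FEATURE_NAMES
    return out


def extract_case(
    case,
    regions,
    phase: str,
    region: str = "core",
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> FeatureVector:
    """Extract the 94 features of one phase volume within one region.

    Parameters
    ----------
    case : PhantomCase (or any object with ``phase_volumes`` and ``spacing_mm``).
    regions : RegionSet built for the case.
    phase : one of EAP/LAP/PVP/EP.
    region : region identifier understood by ``RegionSet.get`` —
        ``"core"``, ``"ring:<d>"`` or ``"combined:<d>"``.
    """
    if phase not in case.phase_volumes:
        raise KeyError(f"case has no phase {phase!r}")
    mask = regions.get(region)
    values = extract_features(
        case.phase_volumes[phase], mask, case.spacing_mm, bin_width
    )
    return FeatureVector(values=values, phases=(phase,), region=region,
                         bin_width=bin_width)


def concat_phases(
    per_phase: dict[str, FeatureVector], combo: PhaseCombo
) -> FeatureVector:
    """Concatenate per-phase vectors into one phase-prefixed vector."""
    missing = [p for p in combo if p not in per_phase]
    if missing:
        raise KeyError(f"missing phase vector(s): {missing}")
    regions = {per_phase[p].region for p in combo}
    if len(regions) != 1:
        raise ValueError(f"phase vectors tagged with different regions: {regions}")
    values: dict[str, float] = {}
    for p in combo:
        fv = per_phase[p]
        if fv.phases != (p,):
            raise ValueError("concat_phases expects single-phase vectors")
        for name, val in fv.values.items():
            values[f"{p}_{name}"] = val
    return FeatureVector(
        values=values,
        phases=tuple(combo),
        region=regions.pop(),
        bin_width=per_phase[combo.phases[0]].bin_width,
    )


def build_feature_matrix(
    case_vectors: dict[str, FeatureVector],
    labels: dict[str, int],
    chronological_index: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Assemble a cohort feature matrix (rows = cases, phase-prefixed columns).

    The returned frame carries ``mvi_label`` and ``chronological_index``
    columns and is sorted chronologically.
    """
    if set(case_vectors) != set(labels):
        raise ValueError("case ids of vectors and labels differ")
    rows = {cid: fv.to_series() for cid, fv in case_vectors.items()}
    df = pd.DataFrame(rows).T
    df["mvi_label"] = pd.Series(labels)
    if chronological_index is None:
        chronological_index = {cid: i for i, cid in enumerate(sorted(rows))}
    df["chronological_index"] = pd.Series(chronological_index)
    return df.sort_values("chronological_index")


def feature_columns(df: pd.DataFrame) -> list[str]:
    """Feature columns of a cohort matrix (everything but the metadata)."""
    return [c for c in df.columns if c not in ("mvi_label", "chronological_index")]
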