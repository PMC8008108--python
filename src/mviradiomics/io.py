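"""NIfTI and CSV persistence for cases and cohorts."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import PhantomCase

_MASKS = ("liver", "tumor", "vessel", "bileduct")


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def write_case(case: PhantomCase, out_dir: str | Path) -> Path:
    """Write one case as NIfTI files (one image per phase, one per mask)."""
    out = Path(out_dir) / case.case_id
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(case.spacing_mm)
    for phase, vol in case.phase_volumes.items():
        nib.save(nib.Nifti1Image(vol.astype(np.int16), aff),
                 out / f"{phase}.nii.gz")
    for name in _MASKS:
        mask = getattr(case, f"{name}_mask")
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), aff),
                 out / f"mask_{name}.nii.gz")
    return out


def read_case(
    case_dir: str | Path,
    mvi_label: int = 0,
    chronological_index: int = 0,
) -> PhantomCase:
    """Load a case directory written by :func:`write_case`.

    Validates that all images and masks share shape and affine and reads the
    voxel spacing from the NIfTI headers.
    """
    case_dir = Path(case_dir)
    phase_volumes = {}
    shapes, affines = {}, {}
    for f in sorted(case_dir.glob("*.nii.gz")):
        img = nib.load(f)
        data = np.asarray(img.dataobj)
        shapes[f.name] = data.shape
        affines[f.name] = img.affine
        name = f.name.replace(".nii.gz", "")
        if name.startswith("mask_"):
            phase_volumes[name] = data.astype(bool)
        else:
            phase_volumes[name] = data.astype(np.int16)
    if not phase_volumes:
        raise FileNotFoundError(f"no NIfTI files in {case_dir}")
    ref_name, ref_shape = next(iter(shapes.items()))
    for name, shape in shapes.items():
        if shape != ref_shape:
            raise ValueError(
                f"shape mismatch: {name} is {shape}, {ref_name} is {ref_shape}"
            )
        if not np.allclose(affines[name], affines[ref_name]):
            raise ValueError(f"affine mismatch between {name} and {ref_name}")
    spacing = tuple(float(s) for s in nib.affines.voxel_sizes(affines[ref_name]))
    masks = {m: phase_volumes.pop(f"mask_{m}") for m in _MASKS}
    case = PhantomCase(
        case_id=case_dir.name,
        phase_volumes=phase_volumes,
        liver_mask=masks["liver"],
        tumor_mask=masks["tumor"],
        vessel_mask=masks["vessel"],
        bileduct_mask=masks["bileduct"],
        spacing_mm=spacing,
        mvi_label=int(mvi_label),
        chronological_index=int(chronological_index),
    )
    case.validate()
    return case


def write_cohort(cases, table: pd.DataFrame, out_dir: str | Path) -> Path:
    """Write all cases plus the cohort label table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for case in cases:
        write_case(case, out)
    table.to_csv(out / "cohort.csv", index=False)
    return out


def read_cohort(cohort_dir: str | Path):
    """Load a cohort directory written by :func:`write_cohort`."""
    cohort_dir = Path(cohort_dir)
    table = pd.read_csv(cohort_dir / "cohort.csv")
    cases = [
        read_case(
            cohort_dir / row.case_id,
            mvi_label=int(row.mvi_label),
            chronological_index=int(row.chronological_index),
        )
        for row in table.itertuples()
    ]
    return cases, table
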