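"""Reading and writing the pipeline's file formats.

Images and masks travel as 8-bit grayscale PNG or single-slice NIfTI
(.nii/.nii.gz); masks use 0/255 in PNG and 0/1 in NIfTI, and necrosis
masks are written back in whatever format the input mask used. Seed
scribbles are PNG with reserved pixel values (1 = necrosis, 2 = tumor).
Cohorts are CSV, expression matrices TSV (genes in rows, header row of
patient ids) and gene sets standard GMT.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from necrofract.errors import ParameterError
from necrofract.segmentation import SeedLabels

COHORT_COLUMNS = [
    "patient_id",
    "age",
    "kps",
    "volume_cm3",
    "gtr_flag",
    "rt_tmz_flag",
    "fd",
    "lacunarity",
    "pfs_time",
    "pfs_event",
    "os_time",
    "os_event",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(_NIFTI_SUFFIXES)


def _nifti_slice(path: Path) -> np.ndarray:
    data = np.asanyarray(nib.load(str(path)).dataobj)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise ParameterError(f"{path}: expected a single-slice NIfTI, got shape {data.shape}")
    return data


def read_image(path: str | Path) -> np.ndarray:
    """Grayscale image as float in [0, 1] from PNG or single-slice NIfTI."""
    path = Path(path)
    if _is_nifti(path):
        data = _nifti_slice(path).astype(float)
        span = data.max() - data.min()
        return (data - data.min()) / span if span > 0 else np.zeros_like(data)
    data = iio.imread(path)
    if data.ndim == 3:
        data = data[..., 0]
    return data.astype(float) / 255.0


def read_mask(path: str | Path) -> np.ndarray:
    """Binary mask from 0/255 PNG or 0/1 single-slice NIfTI."""
    path = Path(path)
    data = _nifti_slice(path) if _is_nifti(path) else iio.imread(path)
    if data.ndim == 3:
        data = data[..., 0]
    return data > (0 if _is_nifti(path) else 127)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask, matching the convention implied by the suffix."""
    path = Path(path)
    mask = np.asarray(mask, bool)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.eye(4)), str(path))
    else:
        iio.imwrite(path, (mask.astype(np.uint8) * 255))


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG (or NIfTI float)."""
    path = Path(path)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(np.asarray(image, np.float32), np.eye(4)), str(path))
    else:
        iio.imwrite(path, np.round(np.clip(image, 0, 1) * 255).astype(np.uint8))


def read_seed_scribble(path: str | Path) -> SeedLabels:
    """Seed scribble PNG: pixel value 1 = necrosis seed, 2 = tumor seed."""
    data = iio.imread(Path(path))
    if data.ndim == 3:
        data = data[..., 0]
    return SeedLabels(
        necrosis_seeds=np.flatnonzero(data == 1),
        tumor_seeds=np.flatnonzero(data == 2),
    )


def write_seed_scribble(path: str | Path, seeds: SeedLabels, shape: tuple[int, int]) -> None:
    canvas = np.zeros(shape, dtype=np.uint8)
    canvas.flat[seeds.necrosis_seeds] = 1
    canvas.flat[seeds.tumor_seeds] = 2
    iio.imwrite(Path(path), canvas)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"cohort CSV lacks columns: {missing}")
    return df


def write_cohort(path: str | Path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression TSV: genes in rows, first column gene ids, header of patient ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(path: str | Path, expr: pd.DataFrame) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Named gene sets from a GMT file (set, description, members...)."""
    from gseapy.parser import read_gmt as _read_gmt

    sets = _read_gmt(str(path))
    if not sets:
        raise ParameterError(f"{path}: no gene sets parsed")
    return sets


def write_gmt(path: str | Path, sets: dict[str, list[str]], descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in sets:
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sets[name]]) + "\n")
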