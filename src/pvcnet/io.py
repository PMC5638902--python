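"""Standard-format I/O: NIfTI-1 volumes, TSV tables, YAML configs."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import Parcellation, VolumetricImage
from .quantify import IntensityMatrix


def read_volume(path: str | Path) -> VolumetricImage:
    """Read a 3-D NIfTI-1 volume (values, spacing, origin)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        raise ValueError(
            f"{path}: 4-D input; sum the temporal frames into a single 3-D "
            "volume first (dynamic PET frames are added together upstream)"
        )
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return VolumetricImage(np.asarray(data, dtype=float), spacing, origin)


def write_volume(image: VolumetricImage, path: str | Path) -> None:
    """Write as NIfTI-1 (float32 values, exact spacing in the affine)."""
    affine = np.diag(list(image.spacing) + [1.0])
    affine[:3, 3] = image.origin
    nib.save(nib.Nifti1Image(image.values.astype(np.float32), affine), str(path))


def write_parcellation(parc: Parcellation, nii_path: str | Path, tsv_path: str | Path) -> None:
    affine = np.diag(list(parc.spacing) + [1.0])
    affine[:3, 3] = parc.origin
    nib.save(nib.Nifti1Image(parc.labels.astype(np.int32), affine), str(nii_path))
    parc.regions.to_csv(tsv_path, sep="\t", index=False)


def read_parcellation(nii_path: str | Path, tsv_path: str | Path) -> Parcellation:
    img = nib.load(str(nii_path))
    labels = np.asarray(np.asanyarray(img.dataobj), dtype=np.int32)
    regions = pd.read_csv(tsv_path, sep="\t")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return Parcellation(labels=labels, regions=regions, spacing=spacing, origin=origin)


def write_intensity_matrix(
    matrix: IntensityMatrix, path: str | Path, config_hash: str = ""
) -> None:
    """Region rows x subject columns, header row of subject ids."""
    _write_tsv(matrix.to_frame().rename_axis("region").reset_index(), path, config_hash)


def read_intensity_matrix(path: str | Path, group: str = "") -> IntensityMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    return IntensityMatrix(
        values=df.drop(columns="region").to_numpy(dtype=float),
        region_labels=df["region"].to_numpy(dtype=int),
        subject_ids=[str(c) for c in df.columns if c != "region"],
        group=group,
    )


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str = "") -> None:
    """Write a TSV, prefixed with a provenance comment when a hash is given."""
    path = Path(path)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


_write_tsv = write_table
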