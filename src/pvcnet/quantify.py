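"""Regional quantification: intensity matrices, SUVR, trimmed means, group stats.

The regional mean matrix I (regions x subjects) is the bridge between image
space and network space: entry (s, t) is subject t's mask-weighted mean tracer
intensity over region s. SUVR volumes are tracer images divided by the mean
uptake of a reference region (the cerebellar-GM analogue in the phantom).

The 10% interquartile mean discards the extreme 5% at each tail before
averaging. Two normalizations are provided: ``"as_printed"`` evaluates
x_IQM = (9/10)/n * sum_{i=floor(0.05n+1)}^{ceil(0.95n)} x_(i) with the
(9/10)/n prefactor applied verbatim, which biases a constant input by a
factor 0.9*(kept/n); ``"mean_preserving"`` divides the trimmed sum by the
number of kept values instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import Parcellation, VolumetricImage


@dataclass
class IntensityMatrix:
    """Regions x subjects matrix of regional tracer values for one group."""

    values: np.ndarray
    region_labels: np.ndarray
    subject_ids: list[str]
    group: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_labels = np.asarray(self.region_labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("intensity matrix must be 2-D (regions x subjects)")
        m, n = self.values.shape
        if m < 1 or n < 1:
            raise ValueError("intensity matrix must be at least 1 x 1")
        if len(self.region_labels) != m:
            raise ValueError("region_labels length must match the number of rows")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length must match the number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity matrix contains non-finite entries")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.region_labels, columns=self.subject_ids
        )


def region_means(image: VolumetricImage, parcellation: Parcellation) -> np.ndarray:
    """Mean intensity of one image over every region (region-table order)."""
    labels = parcellation.labels
    labs = parcellation.region_labels
    counts = parcellation.voxel_counts()
    if (counts == 0).any():
        empty = labs[counts == 0]
        raise ValueError(f"empty region mask for labels {empty.tolist()}")
    return np.asarray(ndimage.mean(image.values, labels=labels, index=labs))


def region_mean_matrix(
    images: list[VolumetricImage],
    parcellation: Parcellation,
    subject_ids: list[str] | None = None,
    group: str = "",
) -> IntensityMatrix:
    """Regions x subjects matrix of mask-weighted regional means.

    The binary-mask weighted mean sum(w p)/sum(w) is used; a variant with an
    extra voxel-count factor in the denominator is sometimes written, but it
    breaks the constant-image sanity c -> c and is not implemented.
    """
    for img in images:
        if img.shape != parcellation.labels.shape:
            raise ValueError("image grid does not match the parcellation grid")
    cols = [region_means(img, parcellation) for img in images]
    if subject_ids is None:
        subject_ids = [f"subj_{i:03d}" for i in range(len(images))]
    return IntensityMatrix(
        values=np.column_stack(cols),
        region_labels=parcellation.region_labels,
        subject_ids=list(subject_ids),
        group=group,
    )


def suvr_normalize(image: VolumetricImage, reference_mask: np.ndarray) -> VolumetricImage:
    """Divide voxelwise by the mean over the reference region (SUVR)."""
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.shape != image.shape:
        raise ValueError("reference mask grid does not match the image grid")
    if not reference_mask.any():
        raise ValueError("reference mask is empty")
    ref = float(image.values[reference_mask].mean())
    if ref <= 0:
        raise ValueError(f"reference-region mean must be positive, got {ref}")
    return image.with_values(image.values / ref)


def interquartile_mean(values: np.ndarray, mode: str = "as_printed") -> float:
    """10% interquartile mean of a value vector (robust regional summary).

    ``as_printed`` applies the (9/10)/n prefactor verbatim (default);
    ``mean_preserving`` divides the trimmed sum by the kept count so a constant
    input c returns c.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = len(x)
    if n == 0:
        raise ValueError("interquartile_mean of an empty vector")
    lo = int(np.floor(0.05 * n + 1))  # 1-based first kept index
    hi = int(np.ceil(0.95 * n))  # 1-based last kept index
    kept = x[lo - 1 : hi]
    if mode == "as_printed":
        return float((9.0 / 10.0) / n * kept.sum())
    if mode == "mean_preserving":
        return float(kept.mean())
    raise ValueError(f"unknown mode {mode!r}")


def region_iqm_matrix(
    images: list[VolumetricImage],
    parcellation: Parcellation,
    subject_ids: list[str] | None = None,
    group: str = "",
    mode: str = "as_printed",
) -> IntensityMatrix:
    """Regions x subjects matrix of per-region 10% interquartile means."""
    labs = parcellation.region_labels
    counts = parcellation.voxel_counts()
    if (counts == 0).any():
        raise ValueError(f"empty region mask for labels {labs[counts == 0].tolist()}")
    cols = []
    for img in images:
        if img.shape != parcellation.labels.shape:
            raise ValueError("image grid does not match the parcellation grid")
        cols.append(
            [interquartile_mean(img.values[parcellation.labels == lab], mode) for lab in labs]
        )
    if subject_ids is None:
        subject_ids = [f"subj_{i:03d}" for i in range(len(images))]
    return IntensityMatrix(
        values=np.array(cols).T,
        region_labels=labs,
        subject_ids=list(subject_ids),
        group=group,
    )


def group_region_stats(matrix: IntensityMatrix, method: str) -> pd.DataFrame:
    """Across-subject mean, sample SD and CoV_s per region, as a tidy table.

    One row per (region, group, method); SD uses the n-1 denominator.
    """
    if matrix.n_subjects < 2:
        raise ValueError("group statistics require at least 2 subjects")
    mean = matrix.values.mean(axis=1)
    sd = matrix.values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov_s = np.where(mean != 0, sd / np.abs(mean), np.nan)
    return pd.DataFrame(
        {
            "region": matrix.region_labels,
            "group": matrix.group,
            "method": method,
            "mean": mean,
            "sd": sd,
            "cov_s": cov_s,
        }
    )
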