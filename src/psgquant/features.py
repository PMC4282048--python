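"""Per-cell measurements: N:C ratio, PSG puncta, bud scars, channel means.

The nuclear:cytoplasmic (N:C) ratio is the screen's core statistic: mean GFP
over the nucleus divided by mean GFP over the cytoplasm.  By default the
cytoplasm mean includes punctum pixels, so a PSG-bearing cell scores a lower
ratio; ``exclude_puncta`` in :func:`nc_ratio` provides the alternative.

Punctum detection is a Laplacian-of-Gaussian band-pass restricted to the
cytoplasm; bud-scar counting looks for ring-shaped Calcofluor White blobs in
an annulus around the cell boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max


class UndefinedMeasurementError(ValueError):
    """A measurement has no defined value (e.g. empty nucleus or cytoplasm)."""


@dataclass(frozen=True)
class Punctum:
    """One detected cytoplasmic spot, in the coordinates of the input raster."""

    center: tuple[int, int]  # (row, col)
    peak_intensity: float
    sigma_est_px: float
    cell_id: int | None = None


@dataclass(frozen=True)
class SpotParams:
    sigma_px: float = 3.0
    amplitude_factor_min: float = 2.0  # raw peak over cytoplasm median
    min_separation_px: int = 5
    nucleus_exclusion_px: int = 2  # dilate the nucleus by this much

    def __post_init__(self) -> None:
        if min(self.sigma_px, self.amplitude_factor_min, self.min_separation_px) <= 0:
            raise ValueError("SpotParams fields must be positive")


@dataclass(frozen=True)
class ScarParams:
    annulus_width_px: int = 7  # inward depth of the boundary band
    ring_sigma_px: float = 1.5  # half-thickness of the matched ring template
    peak_factor_min: float = 2.0  # matched-filter peak over the outline floor
    min_separation_px: int = 6
    max_count: int = 12
    ring_radius_px: float = 4.0
    floor_percentile: float = 5.0  # outline floor = this pct of ribbon response

    def __post_init__(self) -> None:
        if min(
            self.annulus_width_px,
            self.ring_sigma_px,
            self.peak_factor_min,
            self.min_separation_px,
            self.max_count,
        ) <= 0:
            raise ValueError("ScarParams fields must be positive")


def _validate_masks(cell_mask: np.ndarray, nucleus_mask: np.ndarray) -> None:
    if cell_mask.shape != nucleus_mask.shape:
        raise ValueError("cell and nucleus masks differ in shape")
    if np.any(nucleus_mask & ~cell_mask):
        raise ValueError("nucleus mask is not contained in the cell mask")


def nc_ratio(
    gfp: np.ndarray,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    *,
    exclude_puncta: bool = False,
    puncta: list[Punctum] | None = None,
    punctum_radius_px: float = 6.0,
) -> float:
    """Mean GFP over the nucleus divided by mean GFP over the cytoplasm.

    Raises :class:`UndefinedMeasurementError` on an empty nucleus or empty
    cytoplasm — callers must QC-flag such cells rather than defaulting the
    ratio.  With ``exclude_puncta`` the given puncta (discs of
    ``punctum_radius_px``) are removed from the cytoplasm before averaging.
    """
    _validate_masks(cell_mask, nucleus_mask)
    if not nucleus_mask.any():
        raise UndefinedMeasurementError("empty nucleus mask")
    cyto = cell_mask & ~nucleus_mask
    if exclude_puncta and puncta:
        yy, xx = np.mgrid[0 : cyto.shape[0], 0 : cyto.shape[1]]
        for p in puncta:
            py, px = p.center
            cyto &= (yy - py) ** 2 + (xx - px) ** 2 > punctum_radius_px**2
    if not cyto.any():
        raise UndefinedMeasurementError("empty cytoplasm mask")
    # cross-multiplied mean ratio: sums of float32 rasters are exact in
    # float64, so a uniform raster gives exactly 1.0
    sum_n = float(np.sum(gfp[nucleus_mask], dtype=np.float64))
    sum_c = float(np.sum(gfp[cyto], dtype=np.float64))
    if sum_c == 0:
        raise UndefinedMeasurementError("zero cytoplasm intensity")
    n_n = int(nucleus_mask.sum())
    n_c = int(cyto.sum())
    return (sum_n * n_c) / (sum_c * n_n)


def mean_channel_intensity(raster: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of ``raster`` over ``mask`` (e.g. the per-cell RFP
    new-synthesis index)."""
    if raster.shape != mask.shape:
        raise ValueError("raster and mask differ in shape")
    if not mask.any():
        raise UndefinedMeasurementError("empty mask")
    return float(raster[mask].mean())


def total_channel_intensity(raster: np.ndarray, mask: np.ndarray) -> float:
    """Summed intensity over ``mask`` (per-cell CFW total for age gating)."""
    if raster.shape != mask.shape:
        raise ValueError("raster and mask differ in shape")
    return float(raster[mask].sum())


def _estimate_sigma(
    raster: np.ndarray, center: tuple[int, int], background: float, window: int
) -> float:
    h, w = raster.shape
    cy, cx = center
    y0, y1 = max(cy - window, 0), min(cy + window + 1, h)
    x0, x1 = max(cx - window, 0), min(cx + window + 1, w)
    patch = np.maximum(raster[y0:y1, x0:x1] - background, 0.0)
    total = patch.sum()
    if total <= 0:
        return float("nan")
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    return float(math.sqrt(max((patch * d2).sum() / total, 1e-12) / 2.0))


def detect_psg_puncta(
    gfp: np.ndarray,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    params: SpotParams | None = None,
    *,
    cell_id: int | None = None,
) -> list[Punctum]:
    """Detect cytoplasmic proteasome-storage-granule puncta in one cell.

    Local maxima of the Laplacian-of-Gaussian response inside the cytoplasm
    (nucleus dilated by ``nucleus_exclusion_px`` is excluded) are accepted
    when the raw peak intensity reaches ``amplitude_factor_min`` times the
    cytoplasm median.  Returns puncta sorted by descending peak intensity.
    """
    params = params or SpotParams()
    _validate_masks(cell_mask, nucleus_mask)
    if not cell_mask.any():
        return []
    gfp = gfp.astype(np.float64)
    nuc_ex = (
        ndi.binary_dilation(nucleus_mask, iterations=params.nucleus_exclusion_px)
        if nucleus_mask.any() and params.nucleus_exclusion_px > 0
        else nucleus_mask
    )
    cyto = cell_mask & ~nuc_ex
    if not cyto.any():
        return []
    cyto_median = float(np.median(gfp[cyto]))

    # scale-normalized LoG band-pass; bright blobs give positive response
    response = -ndi.gaussian_laplace(gfp, params.sigma_px) * params.sigma_px**2
    peaks = peak_local_max(
        response,
        min_distance=max(int(params.min_separation_px), 1),
        threshold_abs=1e-9,
        exclude_border=False,
    )
    out: list[Punctum] = []
    threshold = params.amplitude_factor_min * cyto_median
    for py, px in peaks:
        if not cyto[py, px]:
            continue
        peak_raw = float(gfp[py, px])
        if peak_raw < threshold:
            continue
        sigma_est = _estimate_sigma(
            gfp, (int(py), int(px)), cyto_median, int(math.ceil(2 * params.sigma_px))
        )
        out.append(
            Punctum(
                center=(int(py), int(px)),
                peak_intensity=peak_raw,
                sigma_est_px=sigma_est,
                cell_id=cell_id,
            )
        )
    out.sort(key=lambda p: (-p.peak_intensity, p.center))
    return out


def _ring_template(radius: float, half_width: float) -> np.ndarray:
    """Normalized annulus kernel: mean over a ring of the scar's geometry."""
    r = int(math.ceil(radius + half_width))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d = np.hypot(yy, xx)
    k = (np.abs(d - radius) <= half_width).astype(np.float64)
    return k / k.sum()


def scar_reference_level(
    cfw: np.ndarray, cell_labels: np.ndarray, params: ScarParams | None = None
) -> float:
    """Field-level outline floor for :func:`count_bud_scars`.

    Pools the matched-filter response over the boundary ribbons of all cells
    and takes the 25th percentile: with typical scar loads most of the pooled
    boundary is scar-free outline, so this tracks the cell-wall level even for
    individual cells whose own boundary is covered in scars.
    """
    params = params or ScarParams()
    fg = cell_labels > 0
    if not fg.any():
        return 0.0
    response = ndi.convolve(
        cfw.astype(np.float64),
        _ring_template(params.ring_radius_px, params.ring_sigma_px),
        mode="constant",
    )
    dist_in = ndi.distance_transform_edt(fg)
    dist_out = ndi.distance_transform_edt(~fg)
    ribbon = (fg & (dist_in <= 2.0)) | ((~fg) & (dist_out <= 1.0))
    return float(np.percentile(response[ribbon], 25.0))


def count_bud_scars(
    cfw: np.ndarray,
    cell_mask: np.ndarray,
    params: ScarParams | None = None,
    *,
    exclude_mask: np.ndarray | None = None,
    reference_level: float | None = None,
) -> int:
    """Count Calcofluor-White bud-scar rings on the cell boundary.

    A matched annular filter (mean intensity over a ring of
    ``ring_radius_px`` +/- ``ring_sigma_px``) peaks at the centre of a scar
    ring while barely responding to the thin cell-wall outline.  Local maxima
    of the response inside the boundary band (from ``annulus_width_px`` deep
    inside the boundary to 2 px outside it) are accepted when they reach
    ``peak_factor_min`` times the outline floor — a low percentile of the
    response over the boundary ribbon, which tracks the outline level even
    when scars cover most of the boundary.  ``exclude_mask`` removes pixels
    belonging to other cells (their intensity is zeroed before filtering);
    the count saturates at ``max_count``.
    """
    params = params or ScarParams()
    if not cell_mask.any():
        raise UndefinedMeasurementError("empty cell mask")
    cfw = cfw.astype(np.float64)
    if exclude_mask is not None:
        cfw = np.where(exclude_mask, 0.0, cfw)

    dist_in = ndi.distance_transform_edt(cell_mask)
    dist_out = ndi.distance_transform_edt(~cell_mask)
    band = (cell_mask & (dist_in <= params.annulus_width_px)) | (
        (~cell_mask) & (dist_out <= 2.0)
    )
    ribbon = (cell_mask & (dist_in <= 2.0)) | ((~cell_mask) & (dist_out <= 1.0))
    if exclude_mask is not None:
        band &= ~exclude_mask
        ribbon &= ~exclude_mask

    response = ndi.convolve(
        cfw, _ring_template(params.ring_radius_px, params.ring_sigma_px), mode="constant"
    )
    if reference_level is None:
        reference_level = (
            float(np.percentile(response[ribbon], params.floor_percentile))
            if ribbon.any()
            else 0.0
        )
    threshold = params.peak_factor_min * max(reference_level, 1e-12)

    peaks = peak_local_max(
        response,
        min_distance=max(int(params.min_separation_px), 1),
        threshold_abs=1e-9,
        exclude_border=False,
    )
    count = 0
    for py, px in peaks:
        if not band[py, px]:
            continue
        if float(response[py, px]) >= threshold:
            count += 1
            if count >= params.max_count:
                break
    return count
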