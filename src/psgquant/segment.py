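"""Cell and nucleus segmentation from the GFP and DNA channels.

Cells are found on the GFP channel (every phenotype has cytoplasmic GFP, so
whole-cell signal is always present): Gaussian smoothing, a global Otsu
threshold, then a distance-transform watershed seeded at smoothed distance
maxima to split touching cells.  Small objects and border-touching cells are
removed.  Nuclei are thresholded on the DNA channel within each cell footprint
and relabelled with their parent cell id; at most one nucleus (the largest
component) is kept per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import clear_border, watershed

from .simulate import FieldImage


class SegmentationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CellSegParams:
    """Parameters for :func:`segment_cells`.

    ``min_area_px`` defaults to the area of a 1.2 um-radius disc at the
    field's pixel size.  ``threshold`` overrides the Otsu default.
    """

    smooth_sigma: float = 2.0
    threshold: float | None = None
    seed_min_distance: int = 15
    min_area_px: int | None = None
    clear_border: bool = True
    require_cells: bool = False
    min_contrast_sd: float = 5.0  # auto-threshold guard vs background noise


@dataclass(frozen=True)
class NucleusSegParams:
    smooth_sigma: float = 1.0
    threshold: float | None = None
    min_area_px: int = 20


@dataclass
class LabelMap:
    """Integer label raster; 0 is background, k > 0 is object k.

    For ``kind='nucleus'`` maps produced by :func:`segment_nuclei`, each
    nucleus id equals its parent cell id (a documented sparse id set when some
    cells have no detected nucleus).
    """

    labels: np.ndarray
    kind: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D raster")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.kind not in ("cell", "nucleus"):
            raise ValueError("kind must be 'cell' or 'nucleus'")

    @property
    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_objects(self) -> int:
        return int(len(self.ids))

    def mask(self, object_id: int) -> np.ndarray:
        return self.labels == object_id


def _default_min_area(pixel_size_um: float) -> int:
    r_px = 1.2 / pixel_size_um
    return int(round(np.pi * r_px**2))


def segment_cells(fieldimg: FieldImage, params: CellSegParams | None = None) -> LabelMap:
    """Segment whole cells from the GFP channel.

    Returns a ``kind='cell'`` label map with ids renumbered 1..K in order of
    the underlying watershed labels.  On an all-background image returns an
    empty map, unless ``params.require_cells`` is set, in which case a
    :class:`SegmentationError` is raised.
    """
    params = params or CellSegParams()
    if "gfp" not in fieldimg.channels:
        raise SegmentationError("field has no gfp channel")
    gfp = fieldimg.channels["gfp"].astype(np.float64)
    sm = ndi.gaussian_filter(gfp, params.smooth_sigma) if params.smooth_sigma > 0 else gfp

    min_area = (
        params.min_area_px
        if params.min_area_px is not None
        else _default_min_area(fieldimg.pixel_size_um)
    )

    if params.threshold is not None:
        thr = params.threshold
    elif np.ptp(sm) == 0:
        thr = np.inf  # constant image: nothing to segment
    else:
        thr = threshold_otsu(sm)
    fg = sm > thr
    # an automatic threshold on a signal-free image splits the noise; demand
    # real foreground/background contrast before trusting it
    if params.threshold is None and fg.any() and not fg.all():
        bg_vals = sm[~fg]
        contrast = float(sm[fg].mean() - bg_vals.mean())
        if contrast <= params.min_contrast_sd * max(float(bg_vals.std()), 1e-12):
            fg[:] = False
    fg = ndi.binary_fill_holes(fg)

    labels = np.zeros(fg.shape, dtype=np.int32)
    if fg.any():
        distance = ndi.distance_transform_edt(fg)
        blobs, _ = ndi.label(fg)
        peaks = peak_local_max(
            distance,
            min_distance=max(int(params.seed_min_distance), 1),
            labels=blobs,
            exclude_border=False,
        )
        markers = np.zeros(fg.shape, dtype=np.int32)
        for k, (py, px) in enumerate(peaks, start=1):
            markers[py, px] = k
        labels = watershed(-distance, markers, mask=fg).astype(np.int32)

    if params.clear_border:
        labels = clear_border(labels)

    # drop undersized objects, renumber 1..K preserving label order
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= max(min_area, 1))
    keep = keep[keep > 0]
    remap = np.zeros(counts.shape[0], dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
    labels = remap[labels]

    if params.require_cells and labels.max() == 0:
        raise SegmentationError("no cells found")
    prov = asdict(params)
    prov.update(threshold_used=float(thr) if np.isfinite(thr) else None, min_area_px=min_area)
    return LabelMap(labels=labels, kind="cell", provenance=prov)


def segment_nuclei(
    fieldimg: FieldImage,
    cells: LabelMap,
    params: NucleusSegParams | None = None,
) -> tuple[LabelMap, list[int]]:
    """Segment one nucleus per cell from the DNA channel.

    Thresholds the DNA channel (Otsu over within-cell pixels by default)
    restricted to each cell footprint and keeps the largest component, which
    is relabelled with the parent cell id.  Returns the nucleus map and the
    QC list of cell ids with no detected nucleus.
    """
    params = params or NucleusSegParams()
    if cells.kind != "cell":
        raise ValueError("cells must be a kind='cell' label map")
    if "dna" not in fieldimg.channels:
        raise SegmentationError("field has no dna channel")
    dna = fieldimg.channels["dna"].astype(np.float64)
    if dna.shape != cells.labels.shape:
        raise SegmentationError(
            f"shape mismatch: field {dna.shape} vs cells {cells.labels.shape}"
        )
    sm = ndi.gaussian_filter(dna, params.smooth_sigma) if params.smooth_sigma > 0 else dna

    inside = cells.labels > 0
    if params.threshold is not None:
        thr = params.threshold
    elif inside.any() and np.ptp(sm[inside]) > 0:
        thr = threshold_otsu(sm[inside])
    else:
        thr = np.inf

    nuclei = np.zeros_like(cells.labels)
    missing: list[int] = []
    slices = ndi.find_objects(cells.labels)
    for cid in cells.ids:
        slc = slices[cid - 1]
        if slc is None:
            missing.append(int(cid))
            continue
        cmask = cells.labels[slc] == cid
        cand = cmask & (sm[slc] > thr)
        if not cand.any():
            missing.append(int(cid))
            continue
        comp, n = ndi.label(cand)
        if n > 1:
            sizes = np.bincount(comp.ravel())[1:]
            cand = comp == (int(np.argmax(sizes)) + 1)
        if cand.sum() < params.min_area_px:
            missing.append(int(cid))
            continue
        nuclei[slc][cand] = cid
    prov = asdict(params)
    prov.update(threshold_used=float(thr) if np.isfinite(thr) else None)
    return LabelMap(labels=nuclei, kind="nucleus", provenance=prov), missing
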