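"""Categorical calls per cell: localization phenotype and replicative age.

Four localization phenotypes partition the population: ``NUCLEAR`` (nuclear
enrichment of proteasomes), ``PSG`` (cytoplasmic proteasome storage
granules), ``NUCLEAR_PSG`` (both) and ``EQUAL`` (neither).  Replicative age
is read from bud scars: virgins (``V``) have none, young mothers (``YM``)
1-2, old mothers (``OM``) more than two.

:func:`build_cell_table` composes segmentation and feature extraction into
the per-cell analysis table; cells failing QC carry flags instead of calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .features import (
    ScarParams,
    SpotParams,
    UndefinedMeasurementError,
    count_bud_scars,
    detect_psg_puncta,
    mean_channel_intensity,
    nc_ratio,
    scar_reference_level,
    total_channel_intensity,
)
from .segment import LabelMap
from .simulate import AGE_GROUPS, PHENOTYPES, FieldImage

#: stable column order of the per-cell table
CELL_TABLE_COLUMNS = [
    "cell_id",
    "field_id",
    "strain_id",
    "replicate_id",
    "area_px",
    "nc_ratio",
    "psg_count",
    "scar_count",
    "cfw_total",
    "rfp_mean",
    "age_group",
    "phenotype",
    "qc_flags",
]


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for the phenotype call.

    ``r_nuclear`` is the N:C ratio above which a cell counts as nuclear
    enriched (boundary value inclusive); ``psg_min_count`` the minimum number
    of detected puncta for a PSG-positive call.
    """

    r_nuclear: float = 1.5
    psg_min_count: int = 1

    def __post_init__(self) -> None:
        if self.r_nuclear <= 1:
            raise ValueError("r_nuclear must exceed 1")
        if self.psg_min_count < 1:
            raise ValueError("psg_min_count must be >= 1")


def assign_age_group(scar_count: int) -> str:
    """Map a bud-scar count to the replicative age group.

    0 scars -> ``V``; 1-2 -> ``YM``; more than two -> ``OM``.
    """
    if scar_count < 0:
        raise ValueError("scar_count must be >= 0")
    if scar_count == 0:
        return "V"
    if scar_count <= 2:
        return "YM"
    return "OM"


def classify_phenotype(
    nc_ratio_value: float, psg_count: int, thresholds: Thresholds | None = None
) -> str:
    """Four-way localization call from the N:C ratio and punctum count."""
    t = thresholds or Thresholds()
    if not (math.isfinite(nc_ratio_value) and nc_ratio_value > 0):
        raise ValueError(f"nc_ratio must be finite and positive, got {nc_ratio_value!r}")
    if psg_count < 0:
        raise ValueError("psg_count must be >= 0")
    nuclear = nc_ratio_value >= t.r_nuclear
    psg = psg_count >= t.psg_min_count
    if nuclear and psg:
        return "NUCLEAR_PSG"
    if nuclear:
        return "NUCLEAR"
    if psg:
        return "PSG"
    return "EQUAL"


def build_cell_table(
    fieldimg: FieldImage,
    cells: LabelMap,
    nuclei: LabelMap,
    *,
    no_nucleus: list[int] | None = None,
    spot_params: SpotParams | None = None,
    scar_params: ScarParams | None = None,
    thresholds: Thresholds | None = None,
    field_id: int | str = 0,
    strain_id: str | None = None,
    replicate_id: int | str | None = None,
    exclude_puncta_from_ratio: bool = False,
) -> pd.DataFrame:
    """One record per segmented cell, ordered by cell id.

    Feature failures become QC flags (``no_nucleus``, ``empty_cytoplasm``,
    ``undefined_ratio``), never abort the field; QC-flagged cells carry no
    phenotype or age group.  If the CFW channel is missing, scar counts and
    age groups are absent for all cells.
    """
    spot_params = spot_params or SpotParams()
    scar_params = scar_params or ScarParams()
    thresholds = thresholds or Thresholds()
    no_nucleus = set(no_nucleus or [])
    if replicate_id is None:
        replicate_id = field_id

    gfp = fieldimg.channels["gfp"]
    cfw = fieldimg.channels.get("cfw")
    rfp = fieldimg.channels.get("rfp")
    lab = cells.labels
    nlab = nuclei.labels
    if lab.shape != gfp.shape or nlab.shape != gfp.shape:
        raise ValueError("label maps do not match the field shape")

    scar_ref = scar_reference_level(cfw, lab, scar_params) if cfw is not None else None

    rows = []
    slices = ndi.find_objects(lab)
    pad = int(math.ceil(scar_params.annulus_width_px + 6))
    for cid in cells.ids:
        cid = int(cid)
        slc = slices[cid - 1]
        sl = (
            slice(max(slc[0].start - pad, 0), min(slc[0].stop + pad, lab.shape[0])),
            slice(max(slc[1].start - pad, 0), min(slc[1].stop + pad, lab.shape[1])),
        )
        cmask = lab[sl] == cid
        nmask = nlab[sl] == cid
        others = (lab[sl] > 0) & ~cmask
        flags: set[str] = set()
        if cid in no_nucleus or not nmask.any():
            flags.add("no_nucleus")
        if not (cmask & ~nmask).any():
            flags.add("empty_cytoplasm")

        ratio = np.nan
        psg_count: float = np.nan
        if not flags:
            puncta = detect_psg_puncta(gfp[sl], cmask, nmask, spot_params, cell_id=cid)
            psg_count = len(puncta)
            try:
                ratio = nc_ratio(
                    gfp[sl],
                    cmask,
                    nmask,
                    exclude_puncta=exclude_puncta_from_ratio,
                    puncta=puncta,
                )
            except UndefinedMeasurementError:
                flags.add("undefined_ratio")
                ratio = np.nan

        scar_count: float = np.nan
        cfw_total = np.nan
        if cfw is not None:
            scar_count = count_bud_scars(
                cfw[sl],
                cmask,
                scar_params,
                exclude_mask=others,
                reference_level=scar_ref,
            )
            # CFW integrated over the cell plus its boundary halo (scar rings
            # straddle the wall), excluding neighbouring cells
            dist_out = ndi.distance_transform_edt(~cmask)
            halo = (cmask | (dist_out <= scar_params.ring_radius_px + 2.0)) & ~others
            cfw_total = total_channel_intensity(cfw[sl], halo)

        rfp_mean = (
            mean_channel_intensity(rfp[sl], cmask) if rfp is not None else np.nan
        )

        age = assign_age_group(int(scar_count)) if cfw is not None and not flags else None
        phen = (
            classify_phenotype(ratio, int(psg_count), thresholds) if not flags else None
        )
        rows.append(
            (
                cid,
                field_id,
                strain_id,
                replicate_id,
                int(cmask.sum()),
                ratio,
                psg_count,
                scar_count,
                cfw_total,
                rfp_mean,
                age,
                phen,
                ";".join(sorted(flags)),
            )
        )
    return pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)
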