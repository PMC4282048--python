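"""Matching pipeline output against simulator ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segment import LabelMap
from .simulate import GroundTruth


def match_truth(cells: LabelMap, truth: GroundTruth) -> pd.DataFrame:
    """Map each truth cell to the segmented label containing its centre.

    Returns a frame with ``cell_id`` (truth id), ``label`` (segmented id, 0 if
    the centre fell on background) and ``jaccard`` (overlap of truth mask and
    segmented mask; NaN for unmatched cells).
    """
    lab = cells.labels
    rows = []
    for _, r in truth.cells.iterrows():
        cid = int(r.cell_id)
        y, x = int(round(r.y)), int(round(r.x))
        seg = int(lab[y, x]) if 0 <= y < lab.shape[0] and 0 <= x < lab.shape[1] else 0
        if seg > 0:
            tm = truth.cell_labels == cid
            sm = lab == seg
            jac = float((tm & sm).sum() / (tm | sm).sum())
        else:
            jac = np.nan
        rows.append((cid, seg, jac))
    return pd.DataFrame(rows, columns=["cell_id", "label", "jaccard"])


def merge_truth(
    records: pd.DataFrame, cells: LabelMap, truth: GroundTruth
) -> pd.DataFrame:
    """Join measured cell records with their ground-truth labels.

    ``records`` is a :func:`~psgquant.phenotype.build_cell_table` frame for
    the same field; the result carries ``true_phenotype``, ``true_age_group``,
    ``true_scar_count``, ``true_psg_count`` and ``jaccard`` columns alongside
    the measurements.  Truth cells whose centre fell on background and
    segmented labels claiming no truth centre are dropped.
    """
    m = match_truth(cells, truth)
    m = m[m.label > 0]
    t = truth.cells.rename(
        columns={
            "phenotype": "true_phenotype",
            "age_group": "true_age_group",
            "scar_count": "true_scar_count",
            "psg_count": "true_psg_count",
        }
    )[["cell_id", "true_phenotype", "true_age_group", "true_scar_count", "true_psg_count"]]
    m = m.merge(t, on="cell_id")
    merged = records.merge(
        m.rename(columns={"cell_id": "true_cell_id", "label": "cell_id"}), on="cell_id"
    )
    return merged
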