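"""Shared fixtures: simulated fields and analyzed cohorts."""

from __future__ import annotations

from dataclasses import replace

import pandas as pd
import pytest

from psgquant.io import RunConfig, analyze_field
from psgquant.simulate import default_wt_config, simulate_field
from psgquant.segment import segment_cells, segment_nuclei
from psgquant.phenotype import build_cell_table
from psgquant.validate import merge_truth

COHORT_SEEDS = list(range(400, 416))  # 16 fields x 150 cells ~ 2400 cells
NF_SEED = 500


def analyze_with_truth(fieldimg, truth, field_id=0):
    """Run the full per-field pipeline and join with ground truth."""
    cells = segment_cells(fieldimg)
    nuclei, missing = segment_nuclei(fieldimg, cells)
    records = build_cell_table(
        fieldimg, cells, nuclei, no_nucleus=missing, field_id=field_id,
        replicate_id=field_id,
    )
    return records, merge_truth(records, cells, truth), cells, nuclei


@pytest.fixture(scope="session")
def nf_field():
    """One noise-free default wild-type field with its ground truth."""
    cfg = replace(default_wt_config(), noise=None)
    return simulate_field(cfg, NF_SEED)


@pytest.fixture(scope="session")
def nf_analyzed(nf_field):
    fieldimg, truth = nf_field
    records, merged, cells, nuclei = analyze_with_truth(fieldimg, truth, field_id="nf")
    return {
        "field": fieldimg,
        "truth": truth,
        "records": records,
        "merged": merged,
        "cells": cells,
        "nuclei": nuclei,
    }


@pytest.fixture(scope="session")
def wt_cohort():
    """Default-noise wild-type cohort: pipeline records joined with truth.

    Sixteen fields at the default configuration (~2400 cells), the shared
    basis for prevalence-recovery and accuracy checks.
    """
    merged_all = []
    cfg = default_wt_config()
    for seed in COHORT_SEEDS:
        fieldimg, truth = simulate_field(cfg, seed)
        _, merged, _, _ = analyze_with_truth(fieldimg, truth, field_id=f"f{seed}")
        merged_all.append(merged)
    return pd.concat(merged_all, ignore_index=True)


@pytest.fixture(scope="session")
def screen_config():
    """Field configuration used for screen-scale simulations."""
    return replace(default_wt_config(), field_size_px=(640, 640), n_cells=40)


@pytest.fixture(scope="session")
def screen_run_config(screen_config):
    from psgquant.io import ScreenSettings

    return RunConfig(
        seed=777,
        sim=screen_config,
        screen=ScreenSettings(
            n_strains=96, rounds=3, hit_strains=("s007", "s041", "s077")
        ),
    )


@pytest.fixture(scope="session")
def screen_results(screen_run_config, tmp_path_factory):
    """Full 96-strain x 3-round screen with 3 planted hits."""
    from psgquant.io import run_screen

    out = tmp_path_factory.mktemp("screen")
    run_screen(screen_run_config, out)
    scores = pd.read_csv(out / "screen_scores.csv")
    hits = pd.read_csv(out / "hits.csv")["strain_id"].tolist()
    return {"scores": scores, "hits": hits, "planted": {"s007", "s041", "s077"}}
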