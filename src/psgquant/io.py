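"""File formats, run configuration and the end-to-end pipeline drivers.

Fields are stored as multi-page TIFF (one page per channel, channel names and
pixel size in the image metadata); tables as UTF-8 comma-separated CSV with a
header row and 6-decimal fractions.  Every output directory receives a JSON
echo of the effective configuration and the package version, so a run can be
reproduced byte-identically from its own outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, fields as dc_fields, is_dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .features import ScarParams, SpotParams
from .phenotype import Thresholds, build_cell_table
from .popstats import call_hits, paired_t_test, prevalence_table, score_screen
from .segment import CellSegParams, LabelMap, NucleusSegParams, segment_cells, segment_nuclei
from .simulate import (
    AGE_GROUPS,
    PHENOTYPES,
    FieldImage,
    GroundTruth,
    SimConfig,
    default_strain_ids,
    default_wt_config,
    field_seed,
    simulate_field,
    simulate_strain_library,
)

log = logging.getLogger("psgquant")

CHANNEL_ORDER = ("gfp", "dna", "cfw", "rfp")
FLOAT_FORMAT = "%.6f"


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------- TIFF I/O


def write_field_tiff(fieldimg: FieldImage, path: str | Path) -> None:
    """Write a field as a multi-page TIFF, one page per channel."""
    names = [c for c in CHANNEL_ORDER if c in fieldimg.channels]
    names += [c for c in fieldimg.channels if c not in names]
    stack = np.stack([fieldimg.channels[c] for c in names])
    meta = {
        "axes": "CYX",
        "channels": names,
        "pixel_size_um": fieldimg.pixel_size_um,
        **{f"user_{k}": v for k, v in fieldimg.metadata.items() if v is not None},
    }
    tifffile.imwrite(Path(path), stack, metadata=meta, photometric="minisblack")


def read_field_tiff(
    path: str | Path, channel_map: list[str] | None = None
) -> FieldImage:
    """Read a multi-page TIFF into a :class:`FieldImage`.

    Channel names come from the file's metadata when present, otherwise from
    the explicit ``channel_map`` (one name per page, in page order).  Missing
    ``cfw``/``rfp`` channels are allowed; downstream age and RFP features are
    then skipped with a logged warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ConfigError(f"{path}: expected a stack of 2D pages, got shape {arr.shape}")
    names = channel_map if channel_map is not None else meta.get("channels")
    if names is None:
        raise ConfigError(f"{path}: no channel metadata; pass an explicit channel_map")
    if len(names) != arr.shape[0]:
        raise ConfigError(
            f"{path}: {arr.shape[0]} pages but {len(names)} channel names {list(names)}"
        )
    if "gfp" not in names or "dna" not in names:
        raise ConfigError(f"{path}: gfp and dna channels are required, got {list(names)}")
    for c in ("cfw", "rfp"):
        if c not in names:
            log.warning("%s: no %s channel; %s-derived features will be skipped", path, c, c)
    pixel_size = float(meta.get("pixel_size_um", 0.1))
    metadata = {k[5:]: v for k, v in meta.items() if k.startswith("user_")}
    return FieldImage(
        channels={c: arr[i] for i, c in enumerate(names)},
        pixel_size_um=pixel_size,
        metadata=metadata,
    )


def write_labels_tiff(labelmap: LabelMap, path: str | Path) -> None:
    """Write a label map as a 16-bit single-page TIFF."""
    if labelmap.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label ids exceed 16-bit range")
    tifffile.imwrite(Path(path), labelmap.labels.astype(np.uint16))


def write_truth_csv(truth: GroundTruth, path: str | Path) -> None:
    """Ground-truth cells as CSV (one row per cell)."""
    cols = ["cell_id", "x", "y", "radius_px", "age_group", "scar_count", "phenotype", "psg_count"]
    truth.cells[cols].to_csv(Path(path), index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------- RunConfig


@dataclass(frozen=True)
class ScreenSettings:
    n_strains: int = 96
    rounds: int = 3
    hit_strains: tuple[str, ...] = ()
    z_threshold: float = 2.5
    min_cells: int = 20
    summary: str = "median"
    control_fields_per_round: int = 2


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible run needs; serialized next to its outputs."""

    seed: int = 0
    n_fields: int = 3
    input_dir: str | None = None  # analyze existing TIFFs instead of simulating
    channel_map: tuple[str, ...] | None = None
    sim: SimConfig = field(default_factory=default_wt_config)
    cell_seg: CellSegParams = field(default_factory=CellSegParams)
    nucleus_seg: NucleusSegParams = field(default_factory=NucleusSegParams)
    spot: SpotParams = field(default_factory=SpotParams)
    scar: ScarParams = field(default_factory=ScarParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    screen: ScreenSettings = field(default_factory=ScreenSettings)
    exclude_puncta_from_ratio: bool = False


_TUPLE_FIELDS = {"field_size_px", "cell_radius_um", "noise", "psg_count_range", "hit_strains", "channel_map"}


def _build_dataclass(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping")
    names = {f.name: f for f in dc_fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigError(f"unknown config key {path}.{sorted(unknown)[0]}")
    kwargs = {}
    for key, value in data.items():
        f = names[key]
        if is_dataclass(f.type) if isinstance(f.type, type) else False:
            kwargs[key] = _build_dataclass(f.type, value, f"{path}.{key}")
            continue
        sub = _NESTED.get((cls, key))
        if sub is not None and isinstance(value, dict):
            kwargs[key] = _build_dataclass(sub, value, f"{path}.{key}")
        elif key == "scar_count_law" and isinstance(value, dict):
            kwargs[key] = {k: tuple(v) for k, v in value.items()}
        elif key in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


_NESTED = {
    (RunConfig, "sim"): SimConfig,
    (RunConfig, "cell_seg"): CellSegParams,
    (RunConfig, "nucleus_seg"): NucleusSegParams,
    (RunConfig, "spot"): SpotParams,
    (RunConfig, "scar"): ScarParams,
    (RunConfig, "thresholds"): Thresholds,
    (RunConfig, "screen"): ScreenSettings,
}


def load_run_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected by name."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return _build_dataclass(RunConfig, data, "config")


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_effective_config(config, out_dir: str | Path, name: str = "config.json") -> None:
    out = {"psgquant_version": __version__, "config": _jsonable(config)}
    Path(out_dir, name).write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------- pipeline


def analyze_field(
    fieldimg: FieldImage,
    config: RunConfig | None = None,
    *,
    field_id: int | str = 0,
    strain_id: str | None = None,
    replicate_id: int | str | None = None,
) -> pd.DataFrame:
    """Segment one field and build its cell table."""
    config = config or RunConfig()
    cells = segment_cells(fieldimg, config.cell_seg)
    nuclei, missing = segment_nuclei(fieldimg, cells, config.nucleus_seg)
    return build_cell_table(
        fieldimg,
        cells,
        nuclei,
        no_nucleus=missing,
        spot_params=config.spot,
        scar_params=config.scar,
        thresholds=config.thresholds,
        field_id=field_id,
        strain_id=strain_id,
        replicate_id=replicate_id,
        exclude_puncta_from_ratio=config.exclude_puncta_from_ratio,
    )


def _age_pair_tests(prev: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests of per-replicate fractions between age groups."""
    rows = []
    pairs = [("V", "YM"), ("V", "OM"), ("YM", "OM")]
    for phen in PHENOTYPES:
        sub = prev[prev.phenotype == phen]
        wide = sub.pivot_table(
            index="replicate_id", columns="age_group", values="fraction", observed=True
        )
        for a, b in pairs:
            if a not in wide.columns or b not in wide.columns:
                continue
            paired = wide[[a, b]].dropna()
            if len(paired) < 2:
                continue
            res = paired_t_test(paired[a].to_numpy(), paired[b].to_numpy())
            rows.append(
                (
                    phen,
                    a,
                    b,
                    res.t_statistic,
                    res.degrees_of_freedom,
                    res.p_two_tailed,
                    res.n_pairs,
                    res.stars,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["phenotype", "group_a", "group_b", "t", "df", "p_two_tailed", "n_pairs", "stars"],
    )


def run_pipeline(config: RunConfig, out_dir: str | Path, *, strict: bool = False) -> Path:
    """Analyze replicate fields into cell tables, prevalences and tests.

    Fields come either from ``config.input_dir`` (every ``*.tif``/``*.tiff``
    in lexicographic order, one replicate per file) or from the simulator
    (``config.n_fields`` fields seeded from ``config.seed``).  Outputs:
    ``cells_<replicate>.csv``, ``cells.csv``, ``prevalence.csv``,
    ``tests.csv`` and ``config.json``.  Per-field failures are logged and
    skipped unless ``strict``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def iter_fields():
        if config.input_dir is not None:
            paths = sorted(Path(config.input_dir).glob("*.tif")) + sorted(
                Path(config.input_dir).glob("*.tiff")
            )
            if not paths:
                raise ConfigError(f"no TIFF fields found in {config.input_dir}")
            cmap = list(config.channel_map) if config.channel_map else None
            for p in paths:
                yield p.stem, read_field_tiff(p, cmap)
        else:
            for i in range(config.n_fields):
                fld, _ = simulate_field(config.sim, field_seed(config.seed, "field", i))
                yield f"field_{i:03d}", fld

    tables = []
    for rep_id, fld in iter_fields():
        t0 = time.perf_counter()
        try:
            rec = analyze_field(fld, config, field_id=rep_id, replicate_id=rep_id)
        except Exception:
            if strict:
                raise
            log.exception("field %s failed; skipping", rep_id)
            continue
        rec.to_csv(out / f"cells_{rep_id}.csv", index=False, float_format=FLOAT_FORMAT)
        log.info("analyzed %s: %d cells in %.2fs", rep_id, len(rec), time.perf_counter() - t0)
        tables.append(rec)
    if not tables:
        raise ConfigError("no fields analyzed")
    records = pd.concat(tables, ignore_index=True)
    records.to_csv(out / "cells.csv", index=False, float_format=FLOAT_FORMAT)

    passing = records[(records.qc_flags == "") & records.age_group.notna()]
    prev = prevalence_table(passing)
    prev.to_csv(out / "prevalence.csv", index=False, float_format=FLOAT_FORMAT)
    tests = _age_pair_tests(prev)
    tests.to_csv(out / "tests.csv", index=False, float_format=FLOAT_FORMAT)
    write_effective_config(config, out)
    return out


def run_screen(config: RunConfig, out_dir: str | Path) -> Path:
    """Simulate and score a knockout-library screen.

    Every strain is imaged once per round; wild-type control fields
    (``screen.control_fields_per_round`` per round) provide the reference
    N:C ratio distribution.  Outputs ``screen_scores.csv``, ``hits.csv`` and
    ``config.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sc = config.screen

    ctrl_tables = []
    for rnd in range(1, sc.rounds + 1):
        for j in range(sc.control_fields_per_round):
            fld, _ = simulate_field(
                config.sim, field_seed(config.seed, f"control_{j}", rnd)
            )
            rec = analyze_field(fld, config, field_id=f"control_{j}_r{rnd}", strain_id="WT")
            rec = rec[rec.qc_flags == ""].copy()
            rec["round"] = rnd
            ctrl_tables.append(rec)
    controls = pd.concat(ctrl_tables, ignore_index=True)

    strain_tables = []
    t0 = time.perf_counter()
    for strain, rnd, fld, _ in simulate_strain_library(
        config.sim, sc.n_strains, set(sc.hit_strains), sc.rounds, config.seed
    ):
        rec = analyze_field(fld, config, field_id=f"{strain}_r{rnd}", strain_id=strain)
        rec = rec[rec.qc_flags == ""].copy()
        rec["round"] = rnd
        strain_tables.append(rec)
    log.info(
        "screen: %d strains x %d rounds in %.1fs",
        sc.n_strains,
        sc.rounds,
        time.perf_counter() - t0,
    )
    strains = pd.concat(strain_tables, ignore_index=True)

    scores = score_screen(
        strains, controls, min_cells=sc.min_cells, summary=sc.summary
    )
    scores.to_csv(out / "screen_scores.csv", index=False, float_format=FLOAT_FORMAT)
    hits = call_hits(scores, z_threshold=sc.z_threshold)
    pd.DataFrame({"strain_id": hits}).to_csv(out / "hits.csv", index=False)
    write_effective_config(config, out)
    return out


def render_report(analysis_dir: str | Path) -> str:
    """Markdown report: prevalence by age group with significance stars."""
    analysis_dir = Path(analysis_dir)
    prev = pd.read_csv(analysis_dir / "prevalence.csv")
    tests_path = analysis_dir / "tests.csv"
    tests = pd.read_csv(tests_path) if tests_path.exists() else pd.DataFrame()

    lines = ["# Proteasome localization by replicative age", ""]
    n_reps = prev.replicate_id.nunique()
    lines.append(f"{n_reps} replicate(s); fractions are mean +/- sd across replicates.")
    lines.append("")
    lines.append("| phenotype | " + " | ".join(AGE_GROUPS) + " |")
    lines.append("|---" * (len(AGE_GROUPS) + 1) + "|")
    for phen in PHENOTYPES:
        cells = [phen]
        for age in AGE_GROUPS:
            sub = prev[(prev.phenotype == phen) & (prev.age_group == age)]
            if len(sub) == 0:
                cells.append("-")
            else:
                cells.append(f"{sub.fraction.mean():.3f} +/- {sub.fraction.std(ddof=1):.3f}")
        lines.append("| " + " | ".join(cells) + " |")
    if len(tests):
        lines += ["", "## Paired two-tailed t-tests between age groups", ""]
        lines.append("| phenotype | comparison | t | df | p | |")
        lines.append("|---|---|---|---|---|---|")
        for _, r in tests.iterrows():
            stars = r.stars if isinstance(r.stars, str) else ""
            lines.append(
                f"| {r.phenotype} | {r.group_a} vs {r.group_b} | {r.t:.3f} | "
                f"{int(r.df)} | {r.p_two_tailed:.4f} | {stars} |"
            )
        lines += ["", "*P<0.05, **P<0.01 (paired, two-tailed Student's t-test)"]
    return "\n".join(lines) + "\n"
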