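"""Synthetic fluorescence fields of starved yeast with per-cell ground truth.

Renders 2D multi-channel fields (maximum-projection style) of non-overlapping
elliptical cells.  Each cell carries a replicative-age group read out through
bud scars on the cell wall (Calcofluor White channel), and one of four
proteasome-localization phenotypes rendered into the GFP channel:

``NUCLEAR``
    proteasome enriched in the nucleus (nuclear intensity = rho x cytoplasm).
``PSG``
    1-3 bright cytoplasmic puncta (proteasome storage granules).
``NUCLEAR_PSG``
    both of the above.
``EQUAL``
    flat GFP over the whole cell.

The DNA channel marks nuclei, the CFW channel draws the cell-wall outline plus
one small bright ring per bud scar, and the optional RFP channel is a constant
baseline standing in for the near-absent synthesis of new proteasomes in
starvation.  A Gaussian PSF blur and Poisson + Gaussian read noise are applied
last; both can be disabled for analytically exact renders.

Every raster and every truth record is a deterministic function of
``(config, seed)``.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

AGE_GROUPS: tuple[str, ...] = ("V", "YM", "OM")
PHENOTYPES: tuple[str, ...] = ("NUCLEAR", "PSG", "NUCLEAR_PSG", "EQUAL")
#: phenotypes that carry cytoplasmic puncta / a nuclear-enriched GFP signal
PSG_BEARING: tuple[str, ...] = ("PSG", "NUCLEAR_PSG")
NUCLEAR_ENRICHED: tuple[str, ...] = ("NUCLEAR", "NUCLEAR_PSG")

_PROB_TOL = 1e-9


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap."""


def _check_prob_vector(vec: Mapping[str, float], keys: Sequence[str], name: str) -> None:
    missing = set(keys) - set(vec)
    if missing:
        raise ValueError(f"{name} missing entries for {sorted(missing)}")
    vals = [float(vec[k]) for k in keys]
    if any(v < 0 for v in vals):
        raise ValueError(f"{name} has negative probabilities")
    if abs(sum(vals) - 1.0) > _PROB_TOL:
        raise ValueError(f"{name} does not sum to 1 (got {sum(vals)!r})")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated field.

    Lengths are micrometres unless the name says ``_px``; intensities are in
    arbitrary camera units.  ``phenotype_prevalence`` maps each age group to a
    probability vector over the four phenotypes; ``scar_count_law`` maps each
    age group to an inclusive integer range of bud-scar counts.
    """

    field_size_px: tuple[int, int] = (1200, 1200)
    pixel_size_um: float = 0.1
    n_cells: int = 150
    cell_radius_um: tuple[float, float] = (2.5, 0.4)  # mean, sd
    cell_aspect_max: float = 1.15  # ellipse axis ratio drawn from U(1, max)
    nucleus_fraction: float = 0.4  # nucleus diameter / cell diameter
    age_group_weights: Mapping[str, float] = field(
        default_factory=lambda: {"V": 0.45, "YM": 0.30, "OM": 0.25}
    )
    phenotype_prevalence: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "V": {"NUCLEAR": 0.02, "PSG": 0.65, "NUCLEAR_PSG": 0.03, "EQUAL": 0.30},
            "YM": {"NUCLEAR": 0.03, "PSG": 0.60, "NUCLEAR_PSG": 0.04, "EQUAL": 0.33},
            "OM": {"NUCLEAR": 0.12, "PSG": 0.30, "NUCLEAR_PSG": 0.08, "EQUAL": 0.50},
        }
    )
    nuclear_enrichment_factor: float = 2.5  # rho: nucleus over cytoplasm
    psg_count_range: tuple[int, int] = (1, 3)
    psg_amplitude_factor: float = 4.0  # punctum peak over cytoplasm mean
    psg_sigma_px: float = 3.0
    scar_count_law: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"V": (0, 0), "YM": (1, 2), "OM": (3, 8)}
    )
    scar_ring_radius_px: float = 4.0
    psf_sigma_px: float = 1.0
    noise: tuple[float, float] | None = (1.0, 2.0)  # (poisson_scale, read_noise_sd)
    cell_baseline: float = 100.0
    baseline_cv: float = 0.05
    dna_intensity: float = 150.0
    cfw_outline_intensity: float = 60.0
    cfw_scar_intensity: float = 200.0
    rfp_enabled: bool = False
    rfp_baseline: float = 3.0
    min_gap_px: float = 8.0

    def __post_init__(self) -> None:
        h, w = self.field_size_px
        if h <= 0 or w <= 0:
            raise ValueError("field_size_px must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        mean_r, sd_r = self.cell_radius_um
        if mean_r <= 0 or sd_r < 0:
            raise ValueError("cell_radius_um must be (positive mean, nonneg sd)")
        if not (0 < self.nucleus_fraction < 1):
            raise ValueError("nucleus_fraction must lie in (0, 1)")
        if self.nuclear_enrichment_factor <= 1:
            raise ValueError("nuclear_enrichment_factor must exceed 1")
        if self.psg_amplitude_factor <= 1:
            raise ValueError("psg_amplitude_factor must exceed 1")
        if self.psg_sigma_px <= 0 or self.scar_ring_radius_px <= 0:
            raise ValueError("punctum and scar-ring scales must be positive")
        lo, hi = self.psg_count_range
        if lo < 1 or hi < lo:
            raise ValueError("psg_count_range must satisfy 1 <= lo <= hi")
        _check_prob_vector(self.age_group_weights, AGE_GROUPS, "age_group_weights")
        for age in AGE_GROUPS:
            if age not in self.phenotype_prevalence:
                raise ValueError(f"phenotype_prevalence missing age group {age}")
            _check_prob_vector(
                self.phenotype_prevalence[age], PHENOTYPES, f"phenotype_prevalence[{age}]"
            )
        law = self.scar_count_law
        for age in AGE_GROUPS:
            if age not in law:
                raise ValueError(f"scar_count_law missing age group {age}")
            slo, shi = law[age]
            if slo < 0 or shi < slo:
                raise ValueError(f"scar_count_law[{age}] must satisfy 0 <= lo <= hi")
        if not (law["V"] == (0, 0)):
            raise ValueError("virgin cells must have exactly 0 bud scars")
        if not (law["YM"][0] >= 1 and law["YM"][1] <= 2):
            raise ValueError("young mothers must have 1-2 bud scars")
        if not law["OM"][0] > 2:
            raise ValueError("old mothers must have more than 2 bud scars")
        if self.noise is not None:
            ps, rn = self.noise
            if ps < 0 or rn < 0:
                raise ValueError("noise levels must be non-negative")


@dataclass
class FieldImage:
    """One multi-channel field: named 2D rasters sharing a shape."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if arr.min() < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class GroundTruth:
    """Simulator-emitted per-cell truth for one field.

    ``cells`` has one row per cell: cell_id, x, y (centre, pixel coords),
    radius_px, rx, ry, theta, baseline, age_group, scar_count, phenotype,
    psg_count.  ``cell_labels`` / ``nucleus_labels`` are label rasters keyed by
    cell_id; ``puncta`` and ``scars`` give planted sub-cellular coordinates.
    """

    cells: pd.DataFrame
    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    puncta: pd.DataFrame
    scars: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_mask(self, cell_id: int) -> np.ndarray:
        return self.cell_labels == cell_id

    def nucleus_mask(self, cell_id: int) -> np.ndarray:
        return self.nucleus_labels == cell_id


def default_wt_config() -> SimConfig:
    """Canonical starved wild-type configuration.

    PSG prevalence per age group is 65% (virgins), 60% (young mothers) and
    30% (old mothers); nuclear enrichment rises with age.
    """
    return SimConfig()


def natB_like_config() -> SimConfig:
    """NatB-deficient profile: nuclear retention up, PSG formation lost."""
    return replace(
        default_wt_config(),
        phenotype_prevalence={
            "V": {"NUCLEAR": 0.30, "PSG": 0.02, "NUCLEAR_PSG": 0.01, "EQUAL": 0.67},
            "YM": {"NUCLEAR": 0.38, "PSG": 0.02, "NUCLEAR_PSG": 0.01, "EQUAL": 0.59},
            "OM": {"NUCLEAR": 0.55, "PSG": 0.01, "NUCLEAR_PSG": 0.01, "EQUAL": 0.43},
        },
    )


def natC_like_config() -> SimConfig:
    """NatC-deficient profile: nuclear retention up, PSG prevalence unchanged.

    The per-age PSG fractions equal the wild-type values; the extra nuclear
    mass comes out of the Equal class, and the enrichment factor itself is
    raised (stronger retention per cell).
    """
    return replace(
        default_wt_config(),
        nuclear_enrichment_factor=3.5,
        phenotype_prevalence={
            "V": {"NUCLEAR": 0.18, "PSG": 0.65, "NUCLEAR_PSG": 0.08, "EQUAL": 0.09},
            "YM": {"NUCLEAR": 0.20, "PSG": 0.60, "NUCLEAR_PSG": 0.11, "EQUAL": 0.09},
            "OM": {"NUCLEAR": 0.38, "PSG": 0.30, "NUCLEAR_PSG": 0.17, "EQUAL": 0.15},
        },
    )


def nuclear_retention_config(base: SimConfig | None = None) -> SimConfig:
    """Strong nuclear-retention profile used for planted screen hits.

    Models the appearance of screen-hit knockouts: the majority of cells keep
    proteasomes in the nucleus, PSG-only cells become rare.  Field geometry and
    noise are inherited from ``base`` (wild type by default).
    """
    base = base if base is not None else default_wt_config()
    prev = {
        age: {"NUCLEAR": 0.55, "PSG": 0.10, "NUCLEAR_PSG": 0.20, "EQUAL": 0.15}
        for age in AGE_GROUPS
    }
    return replace(
        base,
        phenotype_prevalence=prev,
        nuclear_enrichment_factor=max(base.nuclear_enrichment_factor, 3.0),
    )


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(int(seed) % (2**63))


def sample_cell_labels(
    config: SimConfig, n: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw per-cell truth labels (no imaging): age group, scars, phenotype.

    Used for cheap law-level checks and statistics on the configured
    prevalences without rendering any raster.
    """
    rng = _as_rng(seed)
    age_w = np.array([config.age_group_weights[a] for a in AGE_GROUPS], float)
    age_w = age_w / age_w.sum()
    rows = []
    lo_p, hi_p = config.psg_count_range
    for i in range(n):
        age = AGE_GROUPS[rng.choice(len(AGE_GROUPS), p=age_w)]
        slo, shi = config.scar_count_law[age]
        scars = int(rng.integers(slo, shi + 1))
        prev = config.phenotype_prevalence[age]
        pvec = np.array([prev[p] for p in PHENOTYPES], float)
        pvec = pvec / pvec.sum()
        phen = PHENOTYPES[rng.choice(len(PHENOTYPES), p=pvec)]
        npsg = int(rng.integers(lo_p, hi_p + 1)) if phen in PSG_BEARING else 0
        rows.append((i + 1, age, scars, phen, npsg))
    return pd.DataFrame(
        rows, columns=["cell_id", "age_group", "scar_count", "phenotype", "psg_count"]
    )


def _place_cells(config: SimConfig, rng: np.random.Generator) -> list[dict]:
    h, w = config.field_size_px
    mean_r, sd_r = config.cell_radius_um
    cells: list[dict] = []
    for _ in range(config.n_cells):
        for attempt in range(10_000):
            r_um = float(
                np.clip(rng.normal(mean_r, sd_r), mean_r - 2.5 * sd_r, mean_r + 2.5 * sd_r)
            )
            r_px = max(r_um / config.pixel_size_um, 3.0)
            aspect = float(rng.uniform(1.0, config.cell_aspect_max))
            rx, ry = r_px * aspect, r_px / aspect
            bound = max(rx, ry)
            margin = bound + 6.0
            if 2 * margin >= min(h, w):
                raise PlacementError("cells do not fit in the field")
            cy = float(rng.uniform(margin, h - margin))
            cx = float(rng.uniform(margin, w - margin))
            ok = True
            for c in cells:
                d = math.hypot(cx - c["x"], cy - c["y"])
                if d <= bound + c["bound"] + config.min_gap_px:
                    ok = False
                    break
            if ok:
                theta = float(rng.uniform(0.0, math.pi))
                cells.append(
                    {
                        "x": cx,
                        "y": cy,
                        "rx": rx,
                        "ry": ry,
                        "theta": theta,
                        "bound": bound,
                    }
                )
                break
        else:
            raise PlacementError(
                f"could not place cell {len(cells) + 1} of {config.n_cells} "
                "in 10000 attempts"
            )
    return cells


def _ellipse_masks(
    shape: tuple[int, int], cell: dict, nucleus_fraction: float
) -> tuple[slice, slice, np.ndarray, np.ndarray]:
    """Boolean cell and nucleus masks on a bounding crop of the field."""
    pad = int(math.ceil(cell["bound"])) + 3
    y0 = max(int(cell["y"]) - pad, 0)
    y1 = min(int(cell["y"]) + pad + 1, shape[0])
    x0 = max(int(cell["x"]) - pad, 0)
    x1 = min(int(cell["x"]) + pad + 1, shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - cell["y"]
    dx = xx - cell["x"]
    ct, st = math.cos(cell["theta"]), math.sin(cell["theta"])
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    q = (u / cell["rx"]) ** 2 + (v / cell["ry"]) ** 2
    cell_mask = q <= 1.0
    nucleus_mask = q <= nucleus_fraction**2
    return slice(y0, y1), slice(x0, x1), cell_mask, nucleus_mask


def _boundary_point(cell: dict, phi: float) -> tuple[float, float]:
    """Point on the ellipse boundary at parametric angle ``phi`` (x, y)."""
    ct, st = math.cos(cell["theta"]), math.sin(cell["theta"])
    u = cell["rx"] * math.cos(phi)
    v = cell["ry"] * math.sin(phi)
    return cell["x"] + u * ct - v * st, cell["y"] + u * st + v * ct


def _scar_angles(n: int, circumference: float, rng: np.random.Generator) -> np.ndarray:
    """Scar positions: jittered equal spacing with a minimum arc separation."""
    if n == 0:
        return np.empty(0)
    min_arc = 13.0  # px along the boundary; keeps rings resolvable
    rot = rng.uniform(0, 2 * math.pi)
    base = rot + 2 * math.pi * np.arange(n) / n
    slack = max(0.0, (2 * math.pi / n - min_arc * 2 * math.pi / circumference) / 2)
    jitter = rng.uniform(-slack, slack, size=n)
    return (base + jitter) % (2 * math.pi)


def _punctum_positions(
    cell: dict, n: int, nucleus_fraction: float, sigma: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Punctum centres in the cytoplasmic shell, pairwise separated."""
    pts: list[tuple[float, float]] = []
    margin = sigma + 2.0
    min_sep = max(8.0, 2.0 * sigma)
    for _ in range(n):
        best = None
        for attempt in range(500):
            phi = rng.uniform(0, 2 * math.pi)
            r_local = math.hypot(
                cell["rx"] * math.cos(phi), cell["ry"] * math.sin(phi)
            )
            u_lo = nucleus_fraction + margin / r_local
            u_hi = 1.0 - margin / r_local
            if u_hi <= u_lo:
                mid = 0.5 * (nucleus_fraction + 1.0)
                u_lo, u_hi = mid - 0.02, mid + 0.02
            u = rng.uniform(u_lo, u_hi)
            ct, st = math.cos(cell["theta"]), math.sin(cell["theta"])
            px = cell["x"] + u * (cell["rx"] * math.cos(phi) * ct - cell["ry"] * math.sin(phi) * st)
            py = cell["y"] + u * (cell["rx"] * math.cos(phi) * st + cell["ry"] * math.sin(phi) * ct)
            if all(math.hypot(px - qx, py - qy) >= min_sep for qx, qy in pts):
                best = (px, py)
                break
            if best is None:
                best = (px, py)  # closest fallback keeps the draw total
        pts.append(best)
    return pts


def _add_gaussian_spot(
    raster: np.ndarray, x: float, y: float, amplitude: float, sigma: float
) -> None:
    h, w = raster.shape
    r = int(math.ceil(4 * sigma))
    y0, y1 = max(int(y) - r, 0), min(int(y) + r + 1, h)
    x0, x1 = max(int(x) - r, 0), min(int(x) + r + 1, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    raster[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2)
    )


def _add_ring(
    raster: np.ndarray, x: float, y: float, radius: float, half_width: float, value: float
) -> None:
    h, w = raster.shape
    r = int(math.ceil(radius + half_width)) + 1
    y0, y1 = max(int(y) - r, 0), min(int(y) + r + 1, h)
    x0, x1 = max(int(x) - r, 0), min(int(x) + r + 1, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(yy - y, xx - x)
    raster[y0:y1, x0:x1] += value * (np.abs(d - radius) <= half_width)


def simulate_field(
    config: SimConfig, seed: int, *, strain_id: str | None = None
) -> tuple[FieldImage, GroundTruth]:
    """Render one field and its ground truth.

    Identical ``(config, seed)`` pairs produce bit-identical output.  Raises
    :class:`PlacementError` if ``n_cells`` cannot be placed without overlap.
    """
    rng = _as_rng(seed)
    h, w = config.field_size_px
    shape = (h, w)

    geom = _place_cells(config, rng)

    gfp = np.zeros(shape, dtype=np.float64)
    dna = np.zeros(shape, dtype=np.float64)
    cfw = np.zeros(shape, dtype=np.float64)
    cell_labels = np.zeros(shape, dtype=np.int32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)

    age_w = np.array([config.age_group_weights[a] for a in AGE_GROUPS], float)
    age_w = age_w / age_w.sum()
    lo_p, hi_p = config.psg_count_range

    cell_rows = []
    punctum_rows = []
    scar_rows = []
    for i, cell in enumerate(geom):
        cid = i + 1
        age = AGE_GROUPS[rng.choice(len(AGE_GROUPS), p=age_w)]
        slo, shi = config.scar_count_law[age]
        n_scars = int(rng.integers(slo, shi + 1))
        prev = config.phenotype_prevalence[age]
        pvec = np.array([prev[p] for p in PHENOTYPES], float)
        pvec = pvec / pvec.sum()
        phen = PHENOTYPES[rng.choice(len(PHENOTYPES), p=pvec)]
        n_psg = int(rng.integers(lo_p, hi_p + 1)) if phen in PSG_BEARING else 0
        b = config.cell_baseline * (
            1.0
            + float(
                np.clip(
                    rng.normal(0.0, config.baseline_cv),
                    -3 * config.baseline_cv,
                    3 * config.baseline_cv,
                )
            )
        )

        ys, xs, cmask, nmask = _ellipse_masks(shape, cell, config.nucleus_fraction)
        cell_labels[ys, xs][cmask] = cid
        nucleus_labels[ys, xs][nmask] = cid

        # GFP: flat cell, nucleus boosted for nuclear-enriched phenotypes
        sub = gfp[ys, xs]
        sub[cmask] = b
        if phen in NUCLEAR_ENRICHED:
            sub[nmask] = config.nuclear_enrichment_factor * b

        # DNA: bright nucleus
        dna[ys, xs][nmask] = config.dna_intensity

        # CFW: 2-px cell-wall outline plus one ring per bud scar
        outline = cmask & ~ndi.binary_erosion(cmask, iterations=2)
        cfw[ys, xs][outline] += config.cfw_outline_intensity

        # puncta (rendered after the flat fill so tails add on top)
        for px, py in _punctum_positions(
            cell, n_psg, config.nucleus_fraction, config.psg_sigma_px, rng
        ):
            _add_gaussian_spot(
                gfp, px, py, (config.psg_amplitude_factor - 1.0) * b, config.psg_sigma_px
            )
            punctum_rows.append((cid, px, py))

        circumference = math.pi * (
            3 * (cell["rx"] + cell["ry"])
            - math.sqrt((3 * cell["rx"] + cell["ry"]) * (cell["rx"] + 3 * cell["ry"]))
        )
        for phi in _scar_angles(n_scars, circumference, rng):
            sx, sy = _boundary_point(cell, phi)
            _add_ring(
                cfw, sx, sy, config.scar_ring_radius_px, 1.2, config.cfw_scar_intensity
            )
            scar_rows.append((cid, sx, sy))

        cell_rows.append(
            (
                cid,
                cell["x"],
                cell["y"],
                0.5 * (cell["rx"] + cell["ry"]),
                cell["rx"],
                cell["ry"],
                cell["theta"],
                b,
                age,
                n_scars,
                phen,
                n_psg,
            )
        )

    channels: dict[str, np.ndarray] = {"gfp": gfp, "dna": dna, "cfw": cfw}
    if config.rfp_enabled:
        channels["rfp"] = np.full(shape, config.rfp_baseline, dtype=np.float64)

    if config.psf_sigma_px > 0:
        for name in channels:
            channels[name] = ndi.gaussian_filter(channels[name], config.psf_sigma_px)

    if config.noise is not None:
        poisson_scale, read_sd = config.noise
        for name in list(channels):
            img = channels[name]
            if poisson_scale > 0:
                img = rng.poisson(np.maximum(img, 0.0) * poisson_scale) / poisson_scale
            if read_sd > 0:
                img = img + rng.normal(0.0, read_sd, size=img.shape)
            channels[name] = np.maximum(img, 0.0)

    channels = {k: v.astype(np.float32) for k, v in channels.items()}

    field_img = FieldImage(
        channels=channels,
        pixel_size_um=config.pixel_size_um,
        metadata={"seed": int(seed), "strain_id": strain_id, "generator": "psgquant"},
    )
    truth = GroundTruth(
        cells=pd.DataFrame(
            cell_rows,
            columns=[
                "cell_id",
                "x",
                "y",
                "radius_px",
                "rx",
                "ry",
                "theta",
                "baseline",
                "age_group",
                "scar_count",
                "phenotype",
                "psg_count",
            ],
        ),
        cell_labels=cell_labels,
        nucleus_labels=nucleus_labels,
        puncta=pd.DataFrame(punctum_rows, columns=["cell_id", "x", "y"]),
        scars=pd.DataFrame(scar_rows, columns=["cell_id", "x", "y"]),
    )
    return field_img, truth


def field_seed(master_seed: int, strain_id: str, round_idx: int) -> int:
    """Deterministic per-(strain, round) seed derived from a master seed.

    Stable across processes and platforms, so any single library field can be
    regenerated without generating the whole library.
    """
    digest = hashlib.sha256(
        f"{int(master_seed)}|{strain_id}|{int(round_idx)}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def default_strain_ids(n_strains: int) -> list[str]:
    return [f"s{i:03d}" for i in range(n_strains)]


def simulate_strain_library(
    base: SimConfig,
    n_strains: int,
    hit_strains: set[str] | Sequence[str],
    rounds: int,
    seed: int,
    *,
    strain_ids: Sequence[str] | None = None,
    hit_config: SimConfig | None = None,
) -> Iterator[tuple[str, int, FieldImage, GroundTruth]]:
    """Yield ``(strain_id, round, field, truth)`` for a screening library.

    Hit strains are rendered with a nuclear-retention configuration, all
    others with ``base``.  Each (strain, round) field has its own seed derived
    from ``seed`` via :func:`field_seed`.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    ids = list(strain_ids) if strain_ids is not None else default_strain_ids(n_strains)
    if len(ids) != n_strains:
        raise ValueError("strain_ids length must equal n_strains")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strain ids")
    hits = set(hit_strains)
    unknown = hits - set(ids)
    if unknown:
        raise ValueError(f"hit strains not in library: {sorted(unknown)}")
    hit_cfg = hit_config if hit_config is not None else nuclear_retention_config(base)
    for strain in ids:
        cfg = hit_cfg if strain in hits else base
        for rnd in range(1, rounds + 1):
            fld, truth = simulate_field(
                cfg, field_seed(seed, strain, rnd), strain_id=strain
            )
            yield strain, rnd, fld, truth
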