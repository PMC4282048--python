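"""Population-level statistics: prevalence tables, paired tests, CFW gating
and screen scoring with multi-round hit calling.

Prevalence of each localization phenotype is computed per replicate and age
group as (cells with that phenotype in the age group) / (cells in the age
group).  Replicate-level fractions are compared with a paired two-tailed
Student's t-test.  Screen scoring summarizes each strain and round by its
median per-cell N:C ratio and expresses the shift from wild-type controls in
robust z units (1.4826 x the control MAD); a strain is a hit when its z
reaches the threshold in every analyzed round.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import AGE_GROUPS, PHENOTYPES


@dataclass(frozen=True)
class TestResult:
    """Paired t-test outcome; ``degenerate`` marks a zero-variance difference
    with nonzero mean, where ``p_two_tailed`` is the limiting value 0."""

    t_statistic: float
    degrees_of_freedom: int
    p_two_tailed: float
    n_pairs: int
    degenerate: bool = False

    @property
    def stars(self) -> str:
        """Significance annotation: * for P<0.05, ** for P<0.01."""
        if self.p_two_tailed < 0.01:
            return "**"
        if self.p_two_tailed < 0.05:
            return "*"
        return ""


def prevalence_table(records: pd.DataFrame) -> pd.DataFrame:
    """Phenotype fractions per (replicate, age group).

    ``records`` must contain only QC-passing cells with ``replicate_id``,
    ``age_group`` and ``phenotype`` columns.  Returns a long-format frame with
    one row per (replicate_id, age_group, phenotype) — all four phenotypes
    reported, zero fractions included — plus the stratum cell count ``n``.
    Strata with no cells are omitted.
    """
    req = {"replicate_id", "age_group", "phenotype"}
    if not req.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    if records["phenotype"].isna().any() or records["age_group"].isna().any():
        raise ValueError("records contain QC-failing cells (missing calls)")
    rows = []
    for (rep, age), grp in records.groupby(["replicate_id", "age_group"], sort=True):
        n = len(grp)
        counts = grp["phenotype"].value_counts()
        for phen in PHENOTYPES:
            rows.append((rep, age, phen, counts.get(phen, 0) / n, n))
    out = pd.DataFrame(
        rows, columns=["replicate_id", "age_group", "phenotype", "fraction", "n"]
    )
    out["age_group"] = pd.Categorical(out["age_group"], categories=AGE_GROUPS)
    out["phenotype"] = pd.Categorical(out["phenotype"], categories=PHENOTYPES)
    return out.sort_values(["replicate_id", "age_group", "phenotype"]).reset_index(
        drop=True
    )


def paired_t_test(x, y) -> TestResult:
    """Paired two-tailed Student's t-test on matched replicate fractions.

    t = mean(d) / (sd(d)/sqrt(n)) with d = x - y and the n-1 sample standard
    deviation; p from the t distribution with n-1 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("paired t-test requires at least 2 pairs")
    d = x - y
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return TestResult(0.0, n - 1, 1.0, n)
        return TestResult(
            float(np.sign(mean)) * float("inf"), n - 1, 0.0, n, degenerate=True
        )
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 1))
    return TestResult(float(t), n - 1, min(p, 1.0), n)


def robust_z(strain_values, control_values) -> float:
    """Median shift of ``strain_values`` from controls in robust z units."""
    strain_values = np.asarray(strain_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    mad = sps.median_abs_deviation(control_values, scale=1.0)
    denom = 1.4826 * mad
    if denom == 0:
        return float("inf") if np.median(strain_values) != np.median(control_values) else 0.0
    return float((np.median(strain_values) - np.median(control_values)) / denom)


def screen_score_strain(
    strain_records: pd.DataFrame,
    control_records: pd.DataFrame,
    *,
    min_cells: int = 20,
    summary: str = "median",
) -> pd.DataFrame:
    """Per-round robust z of one strain's N:C ratios against controls.

    Both inputs need ``round`` and ``nc_ratio`` columns (QC-passing cells).
    Rounds with fewer than ``min_cells`` cells on either side are flagged and
    not scored (z = NaN).  ``summary='mean'`` swaps the strain/control
    location estimate for the mean; the denominator stays the control MAD.
    """
    if summary not in ("median", "mean"):
        raise ValueError("summary must be 'median' or 'mean'")
    loc = np.median if summary == "median" else np.mean
    rounds = sorted(set(strain_records["round"]) | set(control_records["round"]))
    rows = []
    for rnd in rounds:
        sv = strain_records.loc[strain_records["round"] == rnd, "nc_ratio"].to_numpy(float)
        cv = control_records.loc[control_records["round"] == rnd, "nc_ratio"].to_numpy(float)
        if len(sv) < min_cells or len(cv) < min_cells:
            rows.append((rnd, np.nan, len(sv), len(cv), "low_cell_count"))
            continue
        mad = sps.median_abs_deviation(cv, scale=1.0)
        denom = 1.4826 * mad
        z = (loc(sv) - loc(cv)) / denom if denom > 0 else np.nan
        rows.append((rnd, float(z), len(sv), len(cv), ""))
    return pd.DataFrame(rows, columns=["round", "z", "n_strain", "n_control", "flag"])


def score_screen(
    records: pd.DataFrame,
    control_records: pd.DataFrame,
    *,
    min_cells: int = 20,
    summary: str = "median",
) -> pd.DataFrame:
    """Score every strain in ``records`` against the shared controls.

    ``records`` needs ``strain_id``, ``round`` and ``nc_ratio`` columns.
    Returns one row per (strain, round) with the strain summary ratio and z.
    """
    loc = np.median if summary == "median" else np.mean
    out = []
    for strain, grp in records.groupby("strain_id", sort=True):
        scores = screen_score_strain(
            grp, control_records, min_cells=min_cells, summary=summary
        )
        for _, r in scores.iterrows():
            sv = grp.loc[grp["round"] == r["round"], "nc_ratio"]
            out.append(
                (
                    strain,
                    int(r["round"]),
                    float(loc(sv)) if len(sv) else np.nan,
                    r["z"],
                    int(r["n_strain"]),
                    r["flag"],
                )
            )
    return pd.DataFrame(
        out, columns=["strain_id", "round", "summary_ratio", "z", "n_cells", "flag"]
    )


def call_hits(
    scores: pd.DataFrame,
    z_threshold: float = 2.5,
    rounds_required: list[int] | None = None,
) -> list[str]:
    """Strains whose z reaches ``z_threshold`` in every required round.

    ``scores`` is a :func:`score_screen` frame.  ``rounds_required`` defaults
    to all rounds present.  Unscored (strain, round) pairs among the required
    rounds are an error.
    """
    rounds = (
        sorted(set(scores["round"])) if rounds_required is None else list(rounds_required)
    )
    hits = []
    for strain, grp in scores.groupby("strain_id", sort=True):
        zs = {}
        for rnd in rounds:
            sel = grp[grp["round"] == rnd]
            if len(sel) != 1 or not np.isfinite(sel["z"].iloc[0]):
                raise ValueError(f"strain {strain!r} not scored in round {rnd}")
            zs[rnd] = float(sel["z"].iloc[0])
        if all(zs[rnd] >= z_threshold for rnd in rounds):
            hits.append(strain)
    return hits


def gate_cfw_extremes(
    records: pd.DataFrame, fraction: float = 0.025
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sort-like gate on total CFW: lowest-fraction tail (young) and highest
    (old).

    Mirrors flow sorting of a stained culture where the 2.5% of cells with the
    lowest and highest CFW signal are collected as virgin and old-mother
    enriched pools.  Ties are broken by stable record order; each tail holds
    exactly ``floor(fraction * n)`` cells.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    if "cfw_total" not in records.columns:
        raise ValueError("records must have a cfw_total column")
    n = len(records)
    if n < 1.0 / fraction:
        raise ValueError(f"need at least {int(np.ceil(1 / fraction))} records")
    k = int(np.floor(fraction * n))
    order = records["cfw_total"].to_numpy(float).argsort(kind="stable")
    young = records.iloc[order[:k]]
    old = records.iloc[order[n - k :]]
    return young, old
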