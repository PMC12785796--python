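"""Spatial classification, per-cell aggregation and group statistics.

Every measured particle is assigned exactly one of four spatial classes
from its nuclear ratio ``NR`` and normalized nucleus distance ``x``
(both unit-free):

========== =================== =====================
class       NR                  x (AU)
========== =================== =====================
inside      NR = 1              x = 0
boundary    0 < NR < 1          x = 0
perinuclear NR = 0              0 <= x <= 0.01
cytoplasmic NR = 0              0.01 < x <= 1
========== =================== =====================

"Nuclear" particles in distribution tables and nuclear fractions are
inside + boundary particles; a config switch restricts per-nucleus
counts to strictly-inside particles instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import log

SPATIAL_CLASSES = ("inside_nucleus", "nuclear_boundary", "perinuclear", "cytoplasmic")
PERINUCLEAR_MAX_AU = 0.01

EXPRESSION_CATEGORIES = ("non", "low", "high")


def classify_particle(nuclear_ratio: float, x_norm: float) -> str:
    """Assign the four-way spatial class from (NR, x)."""
    if not 0 <= nuclear_ratio <= 1 or not 0 <= x_norm <= 1:
        raise ValueError(f"NR={nuclear_ratio}, x={x_norm} outside [0, 1]")
    if nuclear_ratio > 0 and x_norm > 0:
        raise ValueError(
            f"inconsistent inputs: NR={nuclear_ratio} > 0 requires x = 0, got {x_norm}"
        )
    if nuclear_ratio == 1:
        return "inside_nucleus"
    if nuclear_ratio > 0:
        return "nuclear_boundary"
    if x_norm <= PERINUCLEAR_MAX_AU:
        return "perinuclear"
    return "cytoplasmic"


def add_spatial_classes(particles: pd.DataFrame) -> pd.DataFrame:
    """Append a ``spatial_class`` column to a particle measurement table."""
    out = particles.copy()
    out["spatial_class"] = [
        classify_particle(nr, x)
        for nr, x in zip(out["nuclear_ratio"], out["x_norm"])
    ]
    return out


# ---------------------------------------------------------- per-cell records


def nuclear_fraction(class_counts: dict[str, int]) -> float:
    """(inside + boundary) / total; 0 (flagged upstream) when no particles."""
    total = sum(class_counts.get(c, 0) for c in SPATIAL_CLASSES)
    if total == 0:
        return 0.0
    nuclear = class_counts.get("inside_nucleus", 0) + class_counts.get(
        "nuclear_boundary", 0
    )
    return nuclear / total


def aggregate_cells(
    particles: pd.DataFrame,
    cell_info: pd.DataFrame,
    nuclear_counts_boundary_inclusive: bool = True,
) -> pd.DataFrame:
    """Per-cell per-timepoint aggregate table.

    ``particles`` must carry ``spatial_class``; ``cell_info`` has one row
    per (timepoint, cell_label) with track id, cell/nucleus volumes and
    mean eGFP intensity. Cells with zero particles get zero counts and a
    flagged nuclear fraction of 0.
    """
    key = ["timepoint", "cell_label"]
    counts = (
        particles.groupby(key + ["spatial_class"]).size().unstack(fill_value=0)
        if len(particles)
        else pd.DataFrame()
    )
    for cls in SPATIAL_CLASSES:
        if cls not in counts.columns:
            counts[cls] = 0
    counts = counts.reindex(columns=list(SPATIAL_CLASSES))

    out = cell_info.set_index(key).copy()
    out = out.join(counts, how="left").fillna({c: 0 for c in SPATIAL_CLASSES})
    for cls in SPATIAL_CLASSES:
        out[cls] = out[cls].astype(int)
    out["total_particles"] = out[list(SPATIAL_CLASSES)].sum(axis=1)
    nuclear = out["inside_nucleus"] + (
        out["nuclear_boundary"] if nuclear_counts_boundary_inclusive else 0
    )
    out["particles_in_nucleus"] = nuclear
    totals = out["total_particles"]
    frac_nuclear = out["inside_nucleus"] + out["nuclear_boundary"]
    out["nuclear_fraction"] = np.where(totals > 0, frac_nuclear / totals.where(totals > 0, 1), 0.0)
    out["zero_particle_flag"] = totals == 0
    return out.reset_index()


# ------------------------------------------------------------------- curves


@dataclass
class CumulativeCurve:
    """Empirical CDF of normalized particle distances (<= semantics)."""

    x: np.ndarray  # sorted x_norm values
    fraction: np.ndarray  # cumulative fraction at each value

    @classmethod
    def from_values(cls, values) -> "CumulativeCurve":
        v = np.sort(np.asarray(values, dtype=float))
        if v.size == 0:
            return cls(x=np.empty(0), fraction=np.empty(0))
        return cls(x=v, fraction=np.arange(1, v.size + 1) / v.size)

    def __call__(self, x: float | np.ndarray) -> np.ndarray | float:
        """Fraction of particles with x_norm <= x."""
        if self.x.size == 0:
            raise ValueError("empty curve cannot be evaluated")
        out = np.searchsorted(self.x, np.asarray(x, dtype=float), side="right") / self.x.size
        return float(out) if np.isscalar(x) else out


def cumulative_curve(x_norm_values) -> CumulativeCurve:
    """Cumulative fraction of particles within distance x AU or less."""
    return CumulativeCurve.from_values(x_norm_values)


# ------------------------------------------------------- expression classes


@dataclass
class ExpressionThresholds:
    """50th/75th percentiles of pooled per-cell mean eGFP intensity."""

    p50: float
    p75: float

    def __post_init__(self) -> None:
        if self.p50 > self.p75:
            raise ValueError("p50 must not exceed p75")

    def category(self, intensity: float) -> str:
        if intensity <= self.p50:
            return "non"
        if intensity <= self.p75:
            return "low"
        return "high"


def categorize_expression(
    cells: pd.DataFrame,
    final_timepoint: int | None = None,
    intensity_col: str = "mean_egfp",
) -> tuple[pd.DataFrame, ExpressionThresholds]:
    """Non/low/high eGFP categories from pooled percentile thresholds.

    Thresholds are the 50th and 75th percentiles (linear interpolation)
    of ``intensity_col`` pooled over **all** cells and timepoints of the
    given table (one experimental condition). Each cell-timepoint row
    gets its own ``egfp_category``; additionally ``egfp_category_final``
    propagates the category observed at the final timepoint to all of a
    track's rows, which is the grouping used longitudinally.
    """
    values = cells[intensity_col].to_numpy(dtype=float)
    if values.size < 4:
        raise ValueError(f"need >= 4 intensity values, got {values.size}")
    thresholds = ExpressionThresholds(
        p50=float(np.percentile(values, 50)), p75=float(np.percentile(values, 75))
    )
    out = cells.copy()
    out["egfp_category"] = [thresholds.category(v) for v in values]

    if final_timepoint is None:
        final_timepoint = int(out["timepoint"].max())
    final = out[out["timepoint"] == final_timepoint]
    track_col = "track_id" if "track_id" in out.columns else "cell_label"
    final_map = dict(zip(final[track_col], final["egfp_category"]))
    out["egfp_category_final"] = out[track_col].map(final_map)
    return out, thresholds


# --------------------------------------------------------------- statistics


@dataclass
class StatResult:
    """Two-sample Mann-Whitney comparison with five-number summaries."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    method: str
    summary_a: dict
    summary_b: dict


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a from midrank sums."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[: a.size].sum()
    return float(r_a - a.size * (a.size + 1) / 2.0)


def mann_whitney_u(
    a, b, label_a: str = "a", label_b: str = "b", method: str = "auto"
) -> StatResult:
    """Two-tailed Mann-Whitney U test.

    With ``method="auto"``: exact two-sided p by complete enumeration of
    rank allocations when ``n_a + n_b <= 16`` and the pooled sample is
    tie-free; otherwise the normal approximation with tie and continuity
    corrections. ``method="exact"``/``"asymptotic"`` force a branch
    (exact requires a tie-free pooled sample).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    u = _u_statistic(a, b)
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size

    if method == "exact" and not tie_free:
        raise ValueError("exact enumeration requires a tie-free pooled sample")
    use_exact = (
        method == "exact" if method != "auto" else (n1 + n2 <= 16 and tie_free)
    )
    if use_exact:
        method = "exact"
        mid = n1 * n2 / 2.0
        observed_dev = abs(u - mid)
        ranks = np.arange(1, n1 + n2 + 1)
        count = 0
        total = 0
        for combo in itertools.combinations(ranks, n1):
            u_star = sum(combo) - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u_star - mid) >= observed_dev - 1e-12:
                count += 1
        p = count / total
    else:
        method = "asymptotic"
        mean_u = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var_u == 0:
            p = 1.0
        else:
            z = max((abs(u - mean_u) - 0.5) / math.sqrt(var_u), 0.0)
            # one-term Edgeworth refinement: the null U distribution is
            # symmetric with excess kurtosis g2 (tie-free closed form)
            g2 = -1.2 * (n1 * n1 + n2 * n2 + n1 * n2 + n1 + n2) / (n1 * n2 * (n + 1))
            tail = sps.norm.sf(z) + sps.norm.pdf(z) * (g2 / 24.0) * (z**3 - 3 * z)
            p = 2.0 * max(tail, 0.0)
    p = min(p, 1.0)
    return StatResult(
        group_a=label_a,
        group_b=label_b,
        n_a=n1,
        n_b=n2,
        u_statistic=u,
        p_value=p,
        method=method,
        summary_a=boxplot_summary(a),
        summary_b=boxplot_summary(b),
    )


def boxplot_summary(values) -> dict:
    """Median, quartiles and 10/90-percentile whiskers (linear interp)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    return {"p10": p10, "p25": p25, "median": p50, "p75": p75, "p90": p90}


# ------------------------------------------------------- distribution table


def distribution_table(
    particles: pd.DataFrame, reference_condition: str
) -> pd.DataFrame:
    """Per condition x timepoint percentages of cytoplasmic / perinuclear /
    nuclear particles, with absolute-percentage deltas vs the reference.

    ``particles`` must carry ``condition``, ``timepoint`` and
    ``spatial_class`` columns. Rows sum to 100%.
    """
    if reference_condition not in set(particles["condition"]):
        raise ValueError(f"reference condition {reference_condition!r} absent")
    df = particles.copy()
    df["group3"] = df["spatial_class"].map(
        {
            "cytoplasmic": "cytoplasmic",
            "perinuclear": "perinuclear",
            "inside_nucleus": "nuclear",
            "nuclear_boundary": "nuclear",
        }
    )
    counts = (
        df.groupby(["condition", "timepoint", "group3"]).size().unstack(fill_value=0)
    )
    for col in ("cytoplasmic", "perinuclear", "nuclear"):
        if col not in counts.columns:
            counts[col] = 0
    counts = counts[["cytoplasmic", "perinuclear", "nuclear"]]
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct.columns = [f"{c}_pct" for c in pct.columns]
    ref = pct.xs(reference_condition, level="condition")
    out = pct.reset_index()
    for col in ("cytoplasmic_pct", "perinuclear_pct", "nuclear_pct"):
        out[col.replace("_pct", "_delta")] = out.apply(
            lambda r, c=col: r[c] - ref.loc[r["timepoint"], c]
            if r["timepoint"] in ref.index
            else np.nan,
            axis=1,
        )
    return out
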