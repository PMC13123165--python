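"""Equity benchmarks: concentration index, proportional allocation, scorecard.

The Concentration Index (CI) measures how programme dosage is distributed
across areas ranked by ascending need: ``CI = 2 cov(d, r) / mean(d)`` with
``r`` the fractional rank (mid-ranks for ties), ranging from -1 to +1.
Positive values mean dosage is concentrated among high-need areas
(pro-poor).  The CI equals ``1 - 2 * AUC`` of the concentration curve
(cumulative population share vs cumulative dosage share in rank order,
trapezoid rule) exactly under this rank convention; the weighted analogue
uses population-weighted fractional ranks.

The proportional allocation benchmark assigns each area the dosage its
relative need would warrant under strict proportionality,

    benchmark_i = (relative_cni_i / mean(relative_cni)) * mean(dosage),

so benchmark residuals (actual - benchmark) total zero algebraically but —
unlike least-squares residuals — the *share* of areas below benchmark is
unconstrained and reflects genuine under-coverage in zero-heavy
allocations.  The scorecard assembles the proportionality ratio, high-need
coverage at need thresholds, the Q4/Q1 equity gap ratio and the CI.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import UndefinedCIError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ConcentrationResult",
    "BenchmarkClassification",
    "ScorecardReport",
    "concentration_index",
    "proportional_benchmark",
    "classify_benchmark",
    "proportionality_ratio",
    "high_need_coverage",
    "equity_gap_ratio",
    "build_scorecard",
]

#: Category labels of the benchmark performance matrix.
HIGH_ABOVE = "equitable_success"
HIGH_BELOW = "targeting_gap"
LOW_ABOVE = "low_need_above_benchmark"
LOW_BELOW = "low_need_below_benchmark"


@dataclass
class ConcentrationResult:
    """Concentration index plus the concentration-curve points."""

    ci_value: float
    curve: pd.DataFrame  # columns: population_share, dosage_share
    ranking_variable: str = "relative_cni"
    weighted: bool = False

    def plot(self, ax=None):
        """Concentration curve against the line of equality."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        ax.plot([0, 1], [0, 1], "--", color="grey", label="equality")
        ax.plot(
            self.curve["population_share"],
            self.curve["dosage_share"],
            color="C0",
            label=f"CI = {self.ci_value:.3f}",
        )
        ax.set_xlabel(f"cumulative population share (ranked by {self.ranking_variable})")
        ax.set_ylabel("cumulative dosage share")
        ax.legend()
        return ax


@dataclass
class BenchmarkClassification:
    """Four-way partition by need level and benchmark performance."""

    categories: pd.Series  # per-row category label
    shares: dict  # category -> fraction of all rows
    high_need_shares: dict  # above/below shares within the high-need stratum
    need_threshold: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": list(self.shares), "share": list(self.shares.values())}
        )


@dataclass
class ScorecardReport:
    """Explicit targeting success benchmarks for one analysis sample."""

    proportionality_ratio: float
    high_need_coverage: dict  # threshold -> fraction (NaN when undefined)
    equity_gap_ratio: float
    concentration_index: float
    n_obs: int
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "proportionality_ratio": self.proportionality_ratio,
            "high_need_coverage": {str(k): v for k, v in self.high_need_coverage.items()},
            "equity_gap_ratio": self.equity_gap_ratio,
            "concentration_index": self.concentration_index,
            "n_obs": self.n_obs,
            "notes": self.notes,
        }

    def to_json(self, path=None, **kwargs) -> str | None:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text + "\n")
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [("proportionality_ratio", self.proportionality_ratio)]
        rows += [
            (f"high_need_coverage_{t}", v) for t, v in self.high_need_coverage.items()
        ]
        rows += [
            ("equity_gap_ratio", self.equity_gap_ratio),
            ("concentration_index", self.concentration_index),
            ("n_obs", self.n_obs),
        ]
        return pd.DataFrame(rows, columns=["benchmark", "value"])


def _fractional_ranks(need: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Population-weighted fractional mid-ranks in ascending need order.

    Each tie group receives (cumulative weight before the group + half the
    group's weight) / total weight; unweighted this reduces to
    (rank - 0.5) / n with mid-ranks for ties.
    """
    order = np.argsort(need, kind="stable")
    w_sorted = weights[order]
    n_sorted = need[order]
    cum = np.cumsum(w_sorted)
    total = cum[-1]
    # group ties: same need -> same mid-rank
    ranks_sorted = np.empty(len(need))
    i = 0
    while i < len(need):
        j = i
        while j + 1 < len(need) and n_sorted[j + 1] == n_sorted[i]:
            j += 1
        before = cum[i - 1] if i > 0 else 0.0
        group_w = cum[j] - before
        ranks_sorted[i : j + 1] = (before + 0.5 * group_w) / total
        i = j + 1
    ranks = np.empty(len(need))
    ranks[order] = ranks_sorted
    return ranks


def concentration_index(
    dosage,
    need,
    weights=None,
    ranking_variable: str = "relative_cni",
) -> ConcentrationResult:
    """Concentration index of ``dosage`` with respect to the need ranking.

    ``CI = 2 cov_w(dosage, rank) / mean_w(dosage)`` with population-weighted
    fractional mid-ranks; positive values indicate concentration among
    high-need rows.  The concentration curve (cumulative population share vs
    cumulative dosage share, tie groups merged) starts at (0, 0) and ends at
    (1, 1).
    """
    d = np.asarray(dosage, dtype=float)
    x = np.asarray(need, dtype=float)
    if d.shape != x.shape or d.ndim != 1:
        raise ValidationError("dosage and need must be aligned 1-d arrays")
    if len(d) < 2:
        raise ValidationError("concentration index needs >= 2 rows")
    if np.any(d < 0):
        raise ValidationError("dosage must be nonnegative")
    if weights is None:
        w = np.ones(len(d))
        weighted = False
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != d.shape or np.any(w <= 0):
            raise ValidationError("weights must be positive and aligned")
        weighted = True
    mu = float(np.average(d, weights=w))
    if mu == 0:
        raise UndefinedCIError("all-zero dosage: concentration index undefined")

    ranks = _fractional_ranks(x, w)
    wn = w / w.sum()
    rbar = float(np.sum(wn * ranks))
    ci = 2.0 * float(np.sum(wn * (d - mu) * (ranks - rbar))) / mu

    # curve: merge tie groups so the points are order-invariant
    order = np.argsort(x, kind="stable")
    df = pd.DataFrame({"need": x[order], "w": w[order], "dw": (d * w)[order]})
    grouped = df.groupby("need", sort=True).sum()
    pop = np.concatenate([[0.0], np.cumsum(grouped["w"].to_numpy())])
    dose = np.concatenate([[0.0], np.cumsum(grouped["dw"].to_numpy())])
    curve = pd.DataFrame(
        {"population_share": pop / pop[-1], "dosage_share": dose / dose[-1]}
    )
    return ConcentrationResult(
        ci_value=float(ci), curve=curve, ranking_variable=ranking_variable, weighted=weighted
    )


def concentration_curve_ci(result: ConcentrationResult) -> float:
    """CI recomputed from the curve as 1 - 2 * trapezoid area (oracle route)."""
    p = result.curve["population_share"].to_numpy()
    L = result.curve["dosage_share"].to_numpy()
    auc = float(np.trapezoid(L, p))
    return 1.0 - 2.0 * auc


def proportional_benchmark(dosage, relative_cni) -> pd.DataFrame:
    """Benchmark dosage proportional to relative need, and residuals.

    ``benchmark_i = (relative_cni_i / mean(relative_cni)) * mean(dosage)``;
    ``residual = actual - benchmark``.  Residuals are not recentred; their
    total is zero by the algebra of the formula, but the share below
    benchmark is unconstrained.
    """
    d = np.asarray(dosage, dtype=float)
    x = np.asarray(relative_cni, dtype=float)
    if d.size == 0:
        raise ValidationError("empty input")
    if d.shape != x.shape:
        raise ValidationError("dosage and relative_cni must align")
    mean_cni = x.mean()
    if mean_cni <= 0:
        raise ValidationError("mean relative CNI must be positive")
    benchmark = (x / mean_cni) * d.mean()
    return pd.DataFrame({"benchmark": benchmark, "residual": d - benchmark})


def classify_benchmark(
    residuals, relative_cni, need_threshold: float = 1.0
) -> BenchmarkClassification:
    """Four-way classification by (need >= threshold) x (residual > 0).

    A residual of exactly zero counts as below-or-at benchmark (the
    conservative tie rule).
    """
    r = np.asarray(residuals, dtype=float)
    x = np.asarray(relative_cni, dtype=float)
    if r.shape != x.shape:
        raise ValidationError("residuals and relative_cni must align")
    high = x >= need_threshold
    above = r > 0
    labels = np.where(
        high,
        np.where(above, HIGH_ABOVE, HIGH_BELOW),
        np.where(above, LOW_ABOVE, LOW_BELOW),
    )
    cats = pd.Series(labels)
    n = len(cats)
    shares = {
        c: float((cats == c).sum()) / n
        for c in (HIGH_ABOVE, HIGH_BELOW, LOW_ABOVE, LOW_BELOW)
    }
    n_high = int(high.sum())
    if n_high:
        high_shares = {
            "above_benchmark": float((high & above).sum()) / n_high,
            "below_benchmark": float((high & ~above).sum()) / n_high,
        }
    else:
        high_shares = {"above_benchmark": float("nan"), "below_benchmark": float("nan")}
    return BenchmarkClassification(
        categories=cats,
        shares=shares,
        high_need_shares=high_shares,
        need_threshold=need_threshold,
    )


def proportionality_ratio(
    fitted_slope: float, mean_dosage: float, mean_relative_cni: float
) -> float:
    """Fitted need-dosage slope over the slope implied by exact proportionality.

    Perfectly proportional allocation has slope mean(dosage)/mean(need), so
    the ratio is 1.0 under proportionality, above 1.0 when targeting is
    steeper than proportional.
    """
    if mean_dosage <= 0:
        raise ValidationError("mean dosage must be positive")
    if mean_relative_cni <= 0:
        raise ValidationError("mean relative CNI must be positive")
    return float(fitted_slope) / (float(mean_dosage) / float(mean_relative_cni))


def high_need_coverage(
    dosage,
    relative_cni,
    thresholds: Sequence[float] = (1.0, 1.5, 2.0),
    area_ids=None,
) -> dict:
    """Share of high-need units with any programme presence, per threshold.

    With ``area_ids`` given, rows are collapsed to areas first (an area
    counts as covered if it has any dosage in any year; its need is its mean
    over rows), matching the convention of counting areas once per period.
    Without ids, rows are the unit.  Thresholds nobody meets are reported as
    NaN with a warning rather than raising.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValidationError("thresholds must be non-empty")
    if sorted(thresholds) != thresholds:
        raise ValidationError("thresholds must be strictly increasing")
    d = np.asarray(dosage, dtype=float)
    x = np.asarray(relative_cni, dtype=float)
    if area_ids is not None:
        df = pd.DataFrame({"area": np.asarray(area_ids), "d": d, "x": x})
        agg = df.groupby("area").agg(any_dose=("d", lambda s: bool((s > 0).any())), need=("x", "mean"))
        covered = agg["any_dose"].to_numpy()
        need = agg["need"].to_numpy()
    else:
        covered = d > 0
        need = x
    out = {}
    for t in thresholds:
        mask = need >= t
        if not mask.any():
            warnings.warn(f"no unit meets need threshold {t}; coverage undefined", stacklevel=2)
            out[t] = float("nan")
        else:
            out[t] = float(covered[mask].mean())
    return out


def equity_gap_ratio(dosage, relative_cni) -> float:
    """Ratio of mean dosage in the top need quartile (Q4) to the bottom (Q1).

    Quartiles are cut at the sample 25/50/75% quantiles (linear
    interpolation), lower-closed.  A zero Q1 mean returns ``inf`` rather
    than raising.
    """
    d = np.asarray(dosage, dtype=float)
    x = np.asarray(relative_cni, dtype=float)
    if len(d) < 4:
        raise ValidationError("equity gap ratio needs >= 4 rows")
    cuts = np.quantile(x, [0.25, 0.5, 0.75])
    q = np.digitize(x, cuts)  # 0..3, value equal to a cut goes up
    q1 = float(d[q == 0].mean())
    q4 = float(d[q == 3].mean())
    if q1 == 0:
        logger.warning("Q1 mean dosage is zero; equity gap ratio is infinite")
        return float("inf")
    return q4 / q1


def build_scorecard(
    panel: pd.DataFrame,
    fit=None,
    need_col: str = "relative_cni",
    dosage_col: str = "dosage",
    need_thresholds: Sequence[float] = (1.0, 1.5, 2.0),
    weights=None,
    area_col: str | None = "area_id",
) -> ScorecardReport:
    """Assemble the targeting scorecard for one analysis sample.

    ``fit`` is a fitted :class:`~equitarget.panel.TargetingResults` whose
    need slope feeds the proportionality ratio; when omitted, the standard
    year-fixed-effects targeting model is fitted on ``panel``.
    """
    from .panel import ModelSpec, fit_ols_fe  # local import to avoid a cycle

    if fit is None:
        fe = ("year",) if "year" in panel.columns and panel["year"].nunique() > 1 else ()
        cluster = area_col if area_col and area_col in panel.columns else need_col
        fit = fit_ols_fe(
            panel,
            ModelSpec(
                outcome=dosage_col,
                predictors=(need_col,),
                fixed_effects=fe,
                cluster_by=cluster,
            ),
        )
    d = panel[dosage_col].to_numpy(dtype=float)
    x = panel[need_col].to_numpy(dtype=float)
    ratio = proportionality_ratio(fit.params[need_col], d.mean(), x.mean())
    area_ids = panel[area_col] if area_col and area_col in panel.columns else None
    coverage = high_need_coverage(d, x, thresholds=need_thresholds, area_ids=area_ids)
    gap = equity_gap_ratio(d, x)
    ci = concentration_index(d, x, weights=weights, ranking_variable=need_col)
    return ScorecardReport(
        proportionality_ratio=ratio,
        high_need_coverage=coverage,
        equity_gap_ratio=gap,
        concentration_index=ci.ci_value,
        n_obs=len(panel),
        notes={
            "slope_term": need_col,
            "mean_dosage": float(d.mean()),
            "mean_relative_cni": float(x.mean()),
            "coverage_unit": "area" if area_ids is not None else "row",
            "ci_weighted": weights is not None,
        },
    )
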