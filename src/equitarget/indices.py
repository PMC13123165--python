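"""Measurement constructs for small-area targeting analysis.

Three quantities are computed from register-like micro-data:

* **Relative CNI** — a Care Need Index composite for each small area,
  expressed relative to the (population-weighted) national mean, so 1.0
  marks average need and values above 1.0 mark above-average need.  The
  composite here uses the four components relevant to families with young
  children: single parenthood, low maternal education, foreign-born status
  and unemployment.  Component weights are an explicit input
  (:class:`CniWeights`); the packaged default is equal weights, since no
  published weighting applies to the four-component adaptation.
* **Household Vulnerability Index (HVI)** — a per-family count (0–5) of
  binary risk indicators, aggregated per area to a mean, a within-area
  standard deviation (neighbourhood heterogeneity) and the share of
  households with HVI >= 2.
* **Dosage** — the probability-weighted share of an area's children aged
  0–5 registered at a child health centre funded to deliver the extended
  programme: 0 means no access, 1 complete coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AggregationError,
    NormalizationError,
    ReferentialIntegrityError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Order of the five household risk indicators.
INDICATOR_NAMES = (
    "low_education",
    "foreign_born",
    "unemployed",
    "single_parent",
    "mental_disorder",
)

#: Order of the four CNI components (area-level proportions).
CNI_COMPONENTS = ("single_parent", "low_education", "foreign_born", "unemployed")

#: Column schema of one area-year row of the analysis panel.
PANEL_COLUMNS = (
    "area_id",
    "region",
    "year",
    "relative_cni",
    "dosage",
    "hvi_mean",
    "hvi_sd",
    "pct_high_hvi",
    "prop_low_education",
    "prop_foreign_born",
    "prop_unemployed",
    "prop_single_parent",
    "n_households",
    "n_children",
)


@dataclass(frozen=True)
class CniWeights:
    """Weights of the four-component Care Need Index composite.

    Parameters
    ----------
    weights
        Nonnegative weights for (single parenthood, low maternal education,
        foreign-born status, unemployment).  At least one must be positive.
    normalization_mean
        Optional fixed national mean composite used as the denominator of
        the relative index.  When ``None`` the denominator is computed from
        the reference population passed to :func:`compute_relative_cni`.
    """

    weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    normalization_mean: float | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (4,):
            raise ValidationError("CniWeights.weights must have exactly 4 entries")
        if np.any(w < 0):
            raise ValidationError("CniWeights.weights must be nonnegative")
        if not np.any(w > 0):
            raise ValidationError("CniWeights.weights must have at least one positive entry")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "CniWeights":
        """Build from a config block keyed by component name (YAML-friendly)."""
        w = tuple(float(mapping[c]) for c in CNI_COMPONENTS)
        return cls(weights=w, normalization_mean=mapping.get("normalization_mean"))


def compute_relative_cni(
    area_components,
    weights: CniWeights | None = None,
    national_reference=None,
) -> np.ndarray:
    """Relative Care Need Index per area.

    Parameters
    ----------
    area_components
        Array-like of shape ``(n_areas, 4)`` with component proportions in
        ``[0, 1]`` ordered as :data:`CNI_COMPONENTS`, or a DataFrame whose
        columns include the component names.
    weights
        Component weights; equal weights by default.
    national_reference
        Per-area population weights (e.g. household counts) used to form the
        national mean composite.  Ignored when ``weights.normalization_mean``
        is given; equal weights when ``None``.

    Returns
    -------
    numpy.ndarray
        Raw weighted composite divided by the population-weighted national
        mean composite; the reference-weighted mean of the result is 1.
    """
    weights = weights or CniWeights()
    if isinstance(area_components, pd.DataFrame):
        area_components = area_components[list(CNI_COMPONENTS)].to_numpy()
    comp = np.asarray(area_components, dtype=float)
    if comp.ndim != 2 or comp.shape[1] != 4:
        raise ValidationError("area_components must be of shape (n_areas, 4)")
    if comp.size == 0:
        raise ValidationError("area_components is empty")
    if np.any((comp < 0) | (comp > 1)):
        raise ValidationError("component proportions must lie in [0, 1]")

    raw = comp @ weights.array
    if weights.normalization_mean is not None:
        mean = float(weights.normalization_mean)
    else:
        if national_reference is None:
            ref = np.ones(len(raw))
        else:
            ref = np.asarray(national_reference, dtype=float)
            if ref.shape != raw.shape:
                raise ValidationError("national_reference must align with area_components")
        mean = float(np.average(raw, weights=ref))
    if mean == 0:
        raise NormalizationError("national mean composite is zero; cannot normalise")
    return raw / mean


def compute_hvi(indicators) -> np.ndarray | int:
    """Household Vulnerability Index: the sum of five binary risk indicators.

    Accepts a single 5-vector (returns ``int``) or an ``(n, 5)`` array
    (returns an integer array).
    """
    ind = np.asarray(indicators)
    single = ind.ndim == 1
    ind = np.atleast_2d(ind)
    if ind.shape[1] != 5:
        raise ValidationError("indicators must have exactly 5 entries per household")
    if not np.isin(ind, (0, 1)).all():
        raise ValidationError("indicators must be 0 or 1")
    total = ind.sum(axis=1).astype(int)
    return int(total[0]) if single else total


def aggregate_hvi(
    hvi_values,
    high_threshold: int = 2,
    divisor: str = "population",
    area_id: str | None = None,
) -> tuple[float, float, float]:
    """Area-year HVI aggregates: (mean, within-area SD, share with HVI >= 2).

    The standard deviation uses the population divisor ``n`` by default
    (descriptive within-area dispersion; a single household has SD 0).
    ``divisor='sample'`` switches to ``n - 1``.
    """
    h = np.asarray(hvi_values, dtype=float)
    if h.size == 0:
        raise AggregationError(f"no households to aggregate in area {area_id!r}")
    if divisor not in ("population", "sample"):
        raise ValidationError("divisor must be 'population' or 'sample'")
    mean = float(h.mean())
    if divisor == "sample" and h.size > 1:
        sd = float(h.std(ddof=1))
    else:
        sd = float(h.std(ddof=0))
    pct_high = float((h >= high_threshold).mean())
    return mean, sd, pct_high


def compute_dosage(
    chc_ids: Sequence,
    n_children: Sequence[int],
    funded: Mapping,
    area_id: str | None = None,
) -> float:
    """Probability-weighted programme dosage of one area-year.

    Child-weighted share of the area's registered children 0–5 attending a
    funded CHC.  ``funded`` maps ``chc_id`` to a boolean funding status for
    the year in question.

    Returns NaN (with a logged warning) when the area has no registered
    children; such rows are flagged and excluded from panels upstream.
    """
    chc_ids = np.asarray(chc_ids)
    kids = np.asarray(n_children, dtype=float)
    if chc_ids.shape != kids.shape:
        raise ValidationError("chc_ids and n_children must align")
    if np.any(kids < 0):
        raise ValidationError("n_children must be nonnegative")
    unresolved = [c for c in np.unique(chc_ids) if c not in funded]
    if unresolved:
        raise ReferentialIntegrityError(
            f"chc_id(s) {unresolved!r} not resolvable in the CHC table"
        )
    total = kids.sum()
    if total == 0:
        logger.warning("area %r has zero registered children; dosage undefined", area_id)
        return float("nan")
    is_funded = np.array([bool(funded[c]) for c in chc_ids])
    return float(kids[is_funded].sum() / total)
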