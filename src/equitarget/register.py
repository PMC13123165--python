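"""Synthetic register-like micro-data with known targeting strength.

The generator emulates the structure of small-area register data behind an
area-based early-childhood programme: small statistical areas grouped into
implementing regions, families with young children carrying binary risk
indicators, child health centres (CHCs) chosen by families with proximity
as the dominant determinant, and a staged, need-targeted programme rollout
that funds CHCs over time.

Everything downstream is testable because the data-generating process is
explicit and self-calibrating:

* a single latent Gaussian area-deprivation factor drives both the CNI
  component proportions and the household indicator probabilities (logistic
  links), with link intercepts root-solved so realised marginals match the
  configured prevalences, and the coupling noise root-solved so the area
  CNI / area-mean-HVI correlation matches its target;
* programme funding probabilities are linear in CHC catchment need
  (clipped to [0, 1]) with the tilt solved by bisection so the population
  projection of expected dosage on relative CNI — year fixed effects,
  post-rollout sample, the Stage A estimand — equals ``beta_true`` exactly;
* one uniform draw per CHC realises funding monotonically over years, so a
  funded CHC stays funded (staged rollout).

All randomness flows from named substreams of a single seed; identical
configurations produce identical tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .exceptions import GenerationError, PanelConstructionError
from .indices import CNI_COMPONENTS, CniWeights, INDICATOR_NAMES, compute_relative_cni

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationOutput",
    "generate_population",
    "assign_chc_registration",
    "assign_program_funding",
    "build_panel",
    "simulate_panel",
]

# Logistic link slopes on the latent deprivation factor.  The relative sizes
# reflect how strongly each marker concentrates in deprived areas (foreign-born
# status is by far the most spatially concentrated); the overall scale is
# calibrated so the relative CNI matches the emulated dispersion (SD ~0.8 at
# mean ~1.1) under the default spread.
_AREA_SLOPES = {  # CNI components, per unit latent factor
    "single_parent": 0.72,
    "low_education": 0.90,
    "foreign_born": 1.30,
    "unemployed": 0.95,
}
_HH_SLOPES = {  # household indicators
    "low_education": 0.90,
    "foreign_born": 1.30,
    "unemployed": 0.95,
    "single_parent": 0.72,
    "mental_disorder": 0.60,
}
#: Area-level idiosyncratic noise (in latent-factor units) added per CNI
#: component, decoupling the composite from any single marker.
_COMPONENT_NOISE = 0.40
#: Deprivation is spatially clustered: share of latent-need variance carried
#: by a smooth Gaussian field over the region's geography, and the field's
#: squared-exponential length scale (unit-square coordinates).  Spatial
#: clustering is what lets need-targeted funding of whole neighbourhoods
#: produce steep area-level dosage gradients, as observed around segregated
#: high-need districts.
_NEED_SPATIAL_SHARE = 0.6
_NEED_LENGTH_SCALE = 0.30
#: Distribution of children aged 0-5 per family (1, 2 or 3).
_CHILD_COUNTS = np.array([1, 2, 3])
_CHILD_PROBS = np.array([0.55, 0.35, 0.10])


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _solve_intercept(lin: np.ndarray, target: float, weights: np.ndarray) -> float:
    """Solve a in  weighted_mean(sigmoid(a + lin)) = target  by bisection."""
    lo, hi = -20.0, 20.0
    wn = weights / weights.sum()
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if float(np.sum(wn * _sigmoid(mid + lin))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class SimulationOutput:
    """All tables produced by one simulation run."""

    households: pd.DataFrame
    chcs: pd.DataFrame
    areas: pd.DataFrame
    panel: pd.DataFrame
    config: SimulationConfig
    meta: dict

    def write(self, out_dir, fmt: str = "csv") -> None:
        """Write households/chcs/panel (+areas) tables as CSV or Parquet."""
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("households", "chcs", "areas", "panel"):
            df = getattr(self, name)
            if fmt == "parquet":
                df.to_parquet(out / f"{name}.parquet", index=False)
            elif fmt == "csv":
                df.to_csv(out / f"{name}.csv", index=False)
            else:
                raise ValueError(f"unknown format {fmt!r}")


def _hh_link_inputs(z, eps_hvi, sigma, config, n_households):
    """Per-area indicator probabilities for coupling noise ``sigma``."""
    probs = np.empty((len(z), 5))
    for j, name in enumerate(INDICATOR_NAMES):
        lin = _HH_SLOPES[name] * (z + sigma * eps_hvi[:, j])
        a = _solve_intercept(lin, config.indicator_prevalence[j], n_households)
        probs[:, j] = _sigmoid(a + lin)
    return probs


def _solve_hvi_noise(z, eps_hvi, relative_cni, config, n_households) -> float:
    """Coupling-noise scale making corr(area CNI, area-mean HVI) hit target.

    The predicted correlation accounts for binomial sampling of indicators
    within areas; if even noise-free coupling falls short of the target the
    scale is clamped at zero with a warning.
    """
    target = config.need_hvi_corr
    sd_cni = relative_cni.std()
    if sd_cni == 0:
        return 0.0

    def predicted(sigma):
        probs = _hh_link_inputs(z, eps_hvi, sigma, config, n_households)
        hbar = probs.sum(axis=1)
        samp_var = float(np.mean((probs * (1 - probs)).sum(axis=1) / n_households))
        cov = float(np.cov(relative_cni, hbar, bias=True)[0, 1])
        denom = sd_cni * np.sqrt(hbar.var() + samp_var)
        return cov / denom if denom > 0 else 0.0

    if predicted(0.0) <= target:
        if predicted(0.0) < target - 0.05:
            warnings.warn(
                f"need_hvi_corr={target} not attainable even without coupling "
                f"noise (max {predicted(0.0):.3f}); using zero noise",
                stacklevel=2,
            )
        return 0.0
    lo, hi = 0.0, 8.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if predicted(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_population(config: SimulationConfig):
    """Generate areas, households and CHCs (registration/funding unassigned).

    Returns ``(households, chcs, areas, meta)``.  Household indicator
    draws are correlated through the latent area deprivation factor so that
    the area CNI and the area-mean HVI correlate at the configured target;
    realised indicator prevalences match the configured marginals.
    Deterministic given the configured seed.
    """
    ss = np.random.SeedSequence(config.seed)
    area_rng, hh_rng, choice_rng, _ = [np.random.default_rng(s) for s in ss.spawn(4)]

    n_areas = config.n_regions * config.n_areas_per_region
    region_idx = np.repeat(np.arange(config.n_regions), config.n_areas_per_region)
    regions = np.array(config.regions)[region_idx]
    area_ids = np.array(
        [f"A{r}_{k:04d}" for r, k in zip(regions, np.arange(n_areas) % config.n_areas_per_region)]
    )
    pos = area_rng.random((n_areas, 2))
    # latent deprivation: smooth spatial field + idiosyncratic part.  The
    # field is standardised within region: deprivation clusters into
    # neighbourhoods, while regions share comparable need profiles (as the
    # emulated regions do).
    field = np.empty(n_areas)
    for r in range(config.n_regions):
        sel = region_idx == r
        xy = pos[sel]
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
        cov = np.exp(-d2 / (2 * _NEED_LENGTH_SCALE**2)) + 1e-8 * np.eye(sel.sum())
        f = np.linalg.cholesky(cov) @ area_rng.standard_normal(sel.sum())
        sd = f.std()
        field[sel] = (f - f.mean()) / (sd if sd > 0 else 1.0)
    z = config.area_need_spread * (
        np.sqrt(_NEED_SPATIAL_SHARE) * field
        + np.sqrt(1 - _NEED_SPATIAL_SHARE) * area_rng.standard_normal(n_areas)
    )
    eps_comp = area_rng.standard_normal((n_areas, 4))
    eps_hvi = area_rng.standard_normal((n_areas, 5))
    lo, hi = config.households_per_area
    n_households = area_rng.integers(lo, hi + 1, n_areas)

    # CNI component proportions: logistic in the latent factor plus
    # component-specific area noise; intercepts calibrated to the configured
    # marginals (the four overlapping household prevalences).
    comp_targets = {
        "single_parent": config.indicator_prevalence[3],
        "low_education": config.indicator_prevalence[0],
        "foreign_born": config.indicator_prevalence[1],
        "unemployed": config.indicator_prevalence[2],
    }
    components = np.empty((n_areas, 4))
    for j, name in enumerate(CNI_COMPONENTS):
        slope = _AREA_SLOPES[name]
        lin = slope * (z + _COMPONENT_NOISE * eps_comp[:, j])
        a = _solve_intercept(lin, comp_targets[name], n_households.astype(float))
        components[:, j] = _sigmoid(a + lin)

    weights = CniWeights(weights=config.cni_weights)
    raw = components @ weights.array
    national_mean = float(np.average(raw, weights=n_households))
    # The analysed regions sit above the national average need, so the
    # normalising "national mean" is the sample mean deflated accordingly.
    norm = national_mean / config.relative_need_mean
    relative_cni = compute_relative_cni(
        components, CniWeights(weights=config.cni_weights, normalization_mean=norm)
    )

    areas = pd.DataFrame(
        {
            "area_id": area_ids,
            "region": regions,
            "x": pos[:, 0],
            "y": pos[:, 1],
            "latent_need": z,
            **{name: components[:, j] for j, name in enumerate(CNI_COMPONENTS)},
            "n_households": n_households,
            "cni_raw": raw,
            "relative_cni": relative_cni,
        }
    )

    # Households: per-year indicator draws around area-level probabilities.
    sigma = _solve_hvi_noise(z, eps_hvi, relative_cni, config, n_households.astype(float))
    probs = _hh_link_inputs(z, eps_hvi, sigma, config, n_households.astype(float))

    hh_area = np.repeat(np.arange(n_areas), n_households)
    n_hh = len(hh_area)
    hh_ids = np.array(
        [f"H{a}_{k}" for a, k in zip(area_ids[hh_area], _within_counter(hh_area))]
    )
    n_children = hh_rng.choice(_CHILD_COUNTS, size=n_hh, p=_CHILD_PROBS)

    years = np.asarray(config.years)
    u = hh_rng.random((len(years), n_hh, 5))
    draws = (u < probs[hh_area][None, :, :]).astype(np.int8)

    frames = []
    for t, year in enumerate(years):
        frames.append(
            pd.DataFrame(
                {
                    "household_id": hh_ids,
                    "area_id": area_ids[hh_area],
                    "region": regions[hh_area],
                    "year": year,
                    **{name: draws[t, :, j] for j, name in enumerate(INDICATOR_NAMES)},
                    "n_children_0_5": n_children,
                    "chc_id": pd.NA,
                }
            )
        )
    households = pd.concat(frames, ignore_index=True)
    households["hvi"] = households[list(INDICATOR_NAMES)].sum(axis=1)

    # CHCs sit where families live: placed at (jittered) area locations.
    chc_frames = []
    for r, region in enumerate(config.regions):
        n_areas_r = config.n_areas_per_region
        n_chc = max(1, round(config.chc_per_area * n_areas_r))
        sel = np.flatnonzero(region_idx == r)
        if n_chc <= n_areas_r:
            host = sel[choice_rng.permutation(n_areas_r)[:n_chc]]
        else:
            host = sel[choice_rng.integers(0, n_areas_r, n_chc)]
        p = pos[host] + 0.02 * choice_rng.standard_normal((n_chc, 2))
        chc_frames.append(
            pd.DataFrame(
                {
                    "chc_id": [f"C{region}_{k:04d}" for k in range(n_chc)],
                    "region": region,
                    "x": p[:, 0],
                    "y": p[:, 1],
                }
            )
        )
    chcs = pd.concat(chc_frames, ignore_index=True)

    meta = {"hvi_noise": sigma, "national_mean_norm": norm, "choice_rng": choice_rng}
    return households, chcs, areas, meta


def _within_counter(group_idx: np.ndarray) -> np.ndarray:
    """0,1,2,... restarting at each change of (sorted) group index."""
    starts = np.flatnonzero(np.diff(group_idx, prepend=group_idx[0] - 1))
    out = np.arange(len(group_idx))
    return out - np.repeat(out[starts], np.diff(np.append(starts, len(group_idx))))


def assign_chc_registration(
    households: pd.DataFrame,
    chcs: pd.DataFrame,
    areas: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assign each household to exactly one CHC in its region.

    The nearest CHC (Euclidean distance) receives probability
    ``choice_concentration``; the remainder is spread over the next-nearest
    CHCs (up to ``choice_set_size`` in total) with exponential distance
    decay of scale ``choice_decay``.  Registration is drawn once per
    household and held fixed over years.
    """
    chc_choice = {}
    for region, chc_r in chcs.groupby("region", sort=True):
        areas_r = areas[areas["region"] == region]
        if chc_r.empty:
            raise GenerationError(f"region {region!r} has no CHCs")
        cxy = chc_r[["x", "y"]].to_numpy()
        axy = areas_r[["x", "y"]].to_numpy()
        d = np.hypot(axy[:, None, 0] - cxy[None, :, 0], axy[:, None, 1] - cxy[None, :, 1])
        k = min(config.choice_set_size, len(chc_r))
        order = np.argsort(d, axis=1)[:, :k]
        ids = chc_r["chc_id"].to_numpy()
        for i, area_id in enumerate(areas_r["area_id"]):
            nearest = order[i]
            if k == 1:
                probs = np.array([1.0])
            else:
                q = config.choice_concentration
                drest = d[i, nearest[1:]] - d[i, nearest[0]]
                wrest = np.exp(-drest / config.choice_decay)
                wrest = (1.0 - q) * wrest / wrest.sum()
                probs = np.concatenate([[q], wrest])
            chc_choice[area_id] = (ids[nearest], np.cumsum(probs))

    out = households.copy()
    first_year = households["year"].min()
    base = households[households["year"] == first_year]
    u = rng.random(len(base))
    assigned = np.empty(len(base), dtype=object)
    area_vals = base["area_id"].to_numpy()
    # vectorised per area: one cumulative-probability lookup per block
    order = np.argsort(area_vals, kind="stable")
    sorted_areas = area_vals[order]
    boundaries = np.flatnonzero(np.r_[True, sorted_areas[1:] != sorted_areas[:-1]])
    for b, e in zip(boundaries, np.append(boundaries[1:], len(base))):
        ids, cum = chc_choice[sorted_areas[b]]
        assigned[order[b:e]] = ids[np.searchsorted(cum, u[order[b:e]], side="right").clip(max=len(ids) - 1)]
    mapping = dict(zip(base["household_id"], assigned))
    out["chc_id"] = out["household_id"].map(mapping)
    return out


def _coverage_matrix(config: SimulationConfig, region: str) -> np.ndarray:
    path = config.coverage()
    return np.array([path[(region, y)] for y in config.years])


def _probs_for_tilt(g, dev, cov_targets):
    """Funding probabilities clip(s_y + g*dev, 0, 1) with per-year intercept
    s_y solved so the mean funded share equals the coverage target."""
    n_chc = len(dev)
    p = np.zeros((n_chc, len(cov_targets)))
    for t, c in enumerate(cov_targets):
        if c <= 0:
            continue
        lo, hi = -1.0 - abs(g) * np.abs(dev).max(), 2.0 + abs(g) * np.abs(dev).max()
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            if np.clip(mid + g * dev, 0, 1).mean() < c:
                lo = mid
            else:
                hi = mid
        p[:, t] = np.clip(0.5 * (lo + hi) + g * dev, 0, 1)
    return p


def assign_program_funding(
    chcs: pd.DataFrame,
    areas: pd.DataFrame,
    households: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
):
    """Decide CHC funding per year with calibrated need targeting.

    Funding probability is linear (clipped) in CHC catchment mean need; per
    region-year an intercept is solved so the expected funded share matches
    the coverage path, and the common tilt ``g`` is solved so the projection
    of expected dosage on relative CNI over the post-rollout sample (year
    fixed effects) equals ``beta_true``.  One uniform per CHC realises the
    staged rollout monotonically.

    Returns ``(chcs_with_funding, meta)`` where the chcs table gains one
    boolean ``funded_<year>`` column per year.
    """
    years = np.asarray(config.years)
    first_year = households["year"].min()
    base = households[households["year"] == first_year]

    per_region = {}
    for region in config.regions:
        chc_r = chcs[chcs["region"] == region].reset_index(drop=True)
        areas_r = areas[areas["region"] == region].reset_index(drop=True)
        if chc_r.empty:
            raise GenerationError(f"region {region!r} has no CHCs")
        hh = base[base["region"] == region]
        aidx = pd.Index(areas_r["area_id"])
        cidx = pd.Index(chc_r["chc_id"])
        K = np.zeros((len(areas_r), len(chc_r)))
        np.add.at(
            K,
            (aidx.get_indexer(hh["area_id"]), cidx.get_indexer(hh["chc_id"])),
            hh["n_children_0_5"].to_numpy(dtype=float),
        )
        cni = areas_r["relative_cni"].to_numpy()
        colsum = K.sum(axis=0)
        catchment = np.where(colsum > 0, (K.T @ cni) / np.where(colsum > 0, colsum, 1), cni.mean())
        dev = catchment - catchment.mean()
        cov_targets = _coverage_matrix(config, region)
        rollout = config.rollout_years[region]
        per_region[region] = {
            "K": K,
            "rowkids": K.sum(axis=1),
            "cni": cni,
            "dev": dev,
            "cov": cov_targets,
            "post": years >= rollout,
            "chc_ids": cidx,
        }

    def pooled_slope(g_by_region):
        """Projection slope of expected dosage on need, year FE, post-rollout,
        pooled over the regions present in ``g_by_region``."""
        num = den = 0.0
        for t, _year in enumerate(years):
            cnis, eds = [], []
            for region, d in per_region.items():
                if region not in g_by_region or not d["post"][t]:
                    continue
                p = _probs_for_tilt(g_by_region[region], d["dev"], d["cov"][t : t + 1])
                ed = (d["K"] @ p[:, 0]) / np.where(d["rowkids"] > 0, d["rowkids"], 1)
                cnis.append(d["cni"])
                eds.append(ed)
            if not cnis:
                continue
            cni = np.concatenate(cnis)
            ed = np.concatenate(eds)
            cni = cni - cni.mean()
            num += float(cni @ ed)
            den += float(cni @ cni)
        return num / den if den > 0 else 0.0

    def solve_tilt(target, region_subset):
        if target == 0:
            return 0.0

        def slope_at(g):
            return pooled_slope(
                {r: (g if r in region_subset else 0.0) for r in region_subset}
            )

        sign = 1.0 if target > 0 else -1.0
        hi = 4.0
        while sign * slope_at(sign * hi) < sign * target and hi < 128:
            hi *= 2
        if sign * slope_at(sign * hi) < sign * target:
            warnings.warn(
                f"beta_true={target} exceeds the steepest attainable targeting "
                f"slope ({slope_at(sign * hi):.4f}) under the configured coverage; "
                "funding uses the maximal tilt",
                stacklevel=3,
            )
            return sign * hi
        lo = 0.0
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            if sign * slope_at(sign * mid) < sign * target:
                lo = mid
            else:
                hi = mid
        return sign * 0.5 * (lo + hi)

    if isinstance(config.beta_true, Mapping):
        g_by_region = {
            r: solve_tilt(config.beta_for(r), {r}) for r in config.regions
        }
    else:
        g = solve_tilt(float(config.beta_true), set(config.regions))
        g_by_region = {r: g for r in config.regions}

    chcs_out = chcs.copy()
    for y in years:
        chcs_out[f"funded_{y}"] = False
    meta = {"tilt_by_region": g_by_region}
    for region, d in per_region.items():
        p = _probs_for_tilt(g_by_region[region], d["dev"], d["cov"])
        p = np.maximum.accumulate(p, axis=1)  # staged rollout: never de-fund
        funded = _realise_funding(p, rng)
        loc = chcs_out["region"] == region
        for t, y in enumerate(years):
            chcs_out.loc[loc, f"funded_{y}"] = funded[
                d["chc_ids"].get_indexer(chcs_out.loc[loc, "chc_id"]), t
            ]
        meta[f"p_{region}"] = p
    return chcs_out, meta


def _systematic_draw(q: np.ndarray, u: float) -> np.ndarray:
    """Fixed-size-in-expectation PPS draw: systematic sampling with
    inclusion probabilities ``q`` (each < or = 1) and random start ``u``."""
    cum = np.concatenate([[0.0], np.cumsum(q)])
    sel = np.zeros(len(q), dtype=bool)
    pts = np.arange(u, cum[-1], 1.0)
    if len(pts):
        sel[np.searchsorted(cum, pts, side="right") - 1] = True
    return sel


def _realise_funding(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Monotone funding paths with exact marginals and balanced totals.

    Each year the not-yet-funded CHCs are sampled with the conditional
    probabilities that restore the target marginal ``p[:, t]``, using
    systematic PPS sampling in a random CHC order.  The funded count per
    region-year therefore matches its expectation to within one CHC (the
    funding body spends its budget), and a funded CHC stays funded.
    """
    n_chc, n_years = p.shape
    order = rng.permutation(n_chc)
    funded = np.zeros((n_chc, n_years), dtype=bool)
    prev_p = np.zeros(n_chc)
    prev_f = np.zeros(n_chc, dtype=bool)
    for t in range(n_years):
        q = np.where(prev_f, 0.0, (p[:, t] - prev_p) / np.maximum(1.0 - prev_p, 1e-12))
        q = np.clip(q, 0.0, 1.0)
        new = np.zeros(n_chc, dtype=bool)
        new[order] = _systematic_draw(q[order], rng.random())
        prev_f = prev_f | new
        funded[:, t] = prev_f
        prev_p = np.maximum(prev_p, p[:, t])
    return funded


def build_panel(
    households: pd.DataFrame,
    chcs: pd.DataFrame,
    areas: pd.DataFrame,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Aggregate micro-data to the area-year analysis panel.

    One row per (area, year) with dosage, relative CNI, HVI aggregates and
    the covariate proportions; the arithmetic matches the reference
    implementations in :mod:`equitarget.indices` (child-weighted funded
    share, population-SD HVI dispersion, HVI >= 2 share).
    """
    if households["chc_id"].isna().any():
        raise PanelConstructionError("households carry unassigned chc_id")
    years = sorted(households["year"].unique())
    funded_cols = [f"funded_{y}" for y in years]
    missing = [c for c in funded_cols if c not in chcs.columns]
    if missing:
        raise PanelConstructionError(f"chcs table lacks funding columns {missing}")

    hh = households.copy()
    funded_lookup = chcs.set_index("chc_id")[funded_cols]
    flags = funded_lookup.reindex(hh.loc[hh["year"] == years[0], "chc_id"]).to_numpy()
    # per-year funded flag for each household row (registration is constant)
    hh_year_idx = pd.Index(years).get_indexer(hh["year"])
    base_n = (hh["year"] == years[0]).sum()
    if flags.shape[0] * len(years) != len(hh):
        raise PanelConstructionError("household table is not balanced over years")
    hh["funded"] = flags[np.tile(np.arange(base_n), len(years)), hh_year_idx]
    hh["children_funded"] = hh["n_children_0_5"] * hh["funded"].astype(float)
    hh["hvi_sq"] = hh["hvi"].astype(float) ** 2
    hh["high_hvi"] = (hh["hvi"] >= 2).astype(float)

    g = hh.groupby(["area_id", "year"], sort=True)
    panel = g.agg(
        n_households=("household_id", "size"),
        n_children=("n_children_0_5", "sum"),
        children_funded=("children_funded", "sum"),
        hvi_mean=("hvi", "mean"),
        hvi_m2=("hvi_sq", "mean"),
        pct_high_hvi=("high_hvi", "mean"),
        **{f"prop_{n}": (n, "mean") for n in INDICATOR_NAMES if n != "mental_disorder"},
    ).reset_index()
    # population-SD identity: Var = E[x^2] - mean^2 (clipped against roundoff)
    panel["hvi_sd"] = np.sqrt(
        np.maximum(panel.pop("hvi_m2") - panel["hvi_mean"] ** 2, 0.0)
    )
    panel["dosage"] = panel.pop("children_funded") / panel["n_children"]

    area_cols = areas.set_index("area_id")[["region", "relative_cni"]]
    panel = panel.join(area_cols, on="area_id")

    expected = areas["area_id"].nunique() * len(years)
    if len(panel) != expected:
        missing_pairs = expected - len(panel)
        raise PanelConstructionError(
            f"panel has {len(panel)} rows, expected {expected} "
            f"({missing_pairs} missing area-years)"
        )
    cols = [
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
    ]
    return panel[cols].sort_values(["area_id", "year"]).reset_index(drop=True)


def simulate_panel(config: SimulationConfig) -> SimulationOutput:
    """Run the full generator: population, registration, funding, panel."""
    households, chcs, areas, meta = generate_population(config)
    choice_rng = meta.pop("choice_rng")
    households = assign_chc_registration(households, chcs, areas, config, choice_rng)
    funding_rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    chcs, fund_meta = assign_program_funding(chcs, areas, households, config, funding_rng)
    meta.update(fund_meta)
    panel = build_panel(households, chcs, areas, config)
    return SimulationOutput(
        households=households, chcs=chcs, areas=areas, panel=panel, config=config, meta=meta
    )
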