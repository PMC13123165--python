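"""Configuration objects for the synthetic register and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping

import yaml

from .exceptions import ConfigurationError


def _check_prob(name: str, value: float) -> None:
    if not 0 <= value <= 1:
        raise ConfigurationError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic register generator.

    The defaults are the study conditions the generator emulates: four
    implementing regions with a staged rollout (one region one year ahead of
    the other three), roughly 3,000 area-year rows, a right-skewed relative
    CNI (mean ~1.10, SD ~0.8), about 73% of post-rollout area-years with
    zero dosage, and household risk indicators coupled to area need so the
    area CNI and area-mean HVI correlate at ~0.86.

    ``beta_true`` is the targeting slope the funding placement encodes: the
    population projection of expected dosage on relative CNI (year fixed
    effects, post-rollout sample) is calibrated to equal it exactly, so the
    Stage A estimator is unbiased for ``beta_true`` by construction.  It may
    be a scalar (national calibration) or a ``{region: slope}`` map
    (per-region calibration for heterogeneity experiments).
    """

    seed: int = 0
    n_regions: int = 4
    n_areas_per_region: int = 125
    households_per_area: tuple[int, int] = (40, 100)
    years: tuple[int, ...] = (2017, 2018, 2019, 2020, 2021, 2022)
    rollout_year_by_region: Mapping[str, int] | None = None
    coverage_path: Mapping | None = None
    beta_true: float | Mapping[str, float] = 0.10
    indicator_prevalence: tuple[float, ...] = (0.058, 0.315, 0.119, 0.072, 0.15)
    area_need_spread: float = 1.0
    choice_concentration: float = 0.25
    choice_set_size: int = 5
    choice_decay: float = 0.20
    zero_share_target: float = 0.73
    relative_need_mean: float = 1.10
    need_hvi_corr: float = 0.86
    chc_per_area: float = 1.0
    cni_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if self.n_regions < 1:
            raise ConfigurationError(f"n_regions must be >= 1, got {self.n_regions}")
        if self.n_areas_per_region < 1:
            raise ConfigurationError("n_areas_per_region must be >= 1")
        lo, hi = self.households_per_area
        if lo < 1 or lo > hi:
            raise ConfigurationError(
                f"households_per_area must satisfy 1 <= low <= high, got {(lo, hi)}"
            )
        years = tuple(self.years)
        if not years:
            raise ConfigurationError("years must be non-empty")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ConfigurationError(f"years must be strictly increasing, got {years}")
        object.__setattr__(self, "years", years)
        if len(self.indicator_prevalence) != 5:
            raise ConfigurationError("indicator_prevalence must have 5 entries")
        for i, p in enumerate(self.indicator_prevalence):
            _check_prob(f"indicator_prevalence[{i}]", p)
        _check_prob("choice_concentration", self.choice_concentration)
        _check_prob("zero_share_target", self.zero_share_target)
        if self.choice_set_size < 1:
            raise ConfigurationError("choice_set_size must be >= 1")
        if self.choice_decay <= 0:
            raise ConfigurationError("choice_decay must be positive")
        if self.area_need_spread <= 0:
            raise ConfigurationError("area_need_spread must be positive")
        if self.chc_per_area <= 0:
            raise ConfigurationError("chc_per_area must be positive")
        if not -1 <= self.need_hvi_corr <= 1:
            raise ConfigurationError("need_hvi_corr must be in [-1, 1]")
        for r, y in self.rollout_years.items():
            if y not in self.years:
                raise ConfigurationError(
                    f"rollout_year_by_region[{r!r}] = {y} is not in years"
                )
        # coverage must be a valid, non-decreasing path within each region
        path = self.coverage(validate=True)
        for region in self.regions:
            prev = 0.0
            for year in self.years:
                c = path[(region, year)]
                _check_prob(f"coverage_path[({region!r}, {year})]", c)
                if c < prev:
                    raise ConfigurationError(
                        f"coverage_path must be non-decreasing in year within "
                        f"region {region!r} (year {year})"
                    )
                prev = c

    # -- derived structure --------------------------------------------------------
    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(f"R{i + 1}" for i in range(self.n_regions))

    @property
    def rollout_years(self) -> dict:
        """Rollout year per region; default: first region starts one year
        after the panel begins, the others one year after that."""
        if self.rollout_year_by_region is not None:
            return dict(self.rollout_year_by_region)
        years = self.years
        first = years[min(1, len(years) - 1)]
        later = years[min(2, len(years) - 1)]
        return {r: (first if i == 0 else later) for i, r in enumerate(self.regions)}

    def beta_for(self, region: str) -> float:
        if isinstance(self.beta_true, Mapping):
            try:
                return float(self.beta_true[region])
            except KeyError:
                raise ConfigurationError(f"beta_true has no entry for region {region!r}")
        return float(self.beta_true)

    def coverage(self, validate: bool = False) -> dict:
        """Coverage path {(region, year): target funded share of CHCs}.

        When not supplied, a linear ramp per region is derived from
        ``zero_share_target``: with households spread over roughly
        ``choice_set_size`` local CHCs, an area-year is zero-dosage when its
        local CHCs are all unfunded, so the mean post-rollout funded share
        is set to ``1 - zero_share_target ** (1 / k_eff)`` and ramped from
        60% to 140% of that mean across the rollout period.
        """
        if self.coverage_path is not None:
            path = {}
            for key, v in self.coverage_path.items():
                region, year = key
                path[(region, int(year))] = float(v)
            for region in self.regions:
                for year in self.years:
                    if (region, year) not in path:
                        path[(region, year)] = 0.0
            return path
        k_eff = _EFFECTIVE_LOCAL_CHCS if self.choice_set_size > 1 else 1.0
        cbar = 1.0 - self.zero_share_target ** (1.0 / k_eff)
        path = {}
        for region in self.regions:
            r0 = self.rollout_years[region]
            post = [y for y in self.years if y >= r0]
            K = len(post)
            for year in self.years:
                if year < r0:
                    path[(region, year)] = 0.0
                else:
                    k = post.index(year)
                    ramp = 1.0 if K == 1 else 0.85 + 0.3 * k / (K - 1)
                    path[(region, year)] = min(1.0, cbar * ramp)
        return path

    # -- serialisation ------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["coverage_path"], dict):
            d["coverage_path"] = {f"{r},{y}": v for (r, y), v in d["coverage_path"].items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if d.get("coverage_path"):
            cp = {}
            for key, v in d["coverage_path"].items():
                if isinstance(key, str):
                    r, y = key.split(",")
                    cp[(r, int(y))] = float(v)
                else:
                    cp[tuple(key)] = float(v)
            d["coverage_path"] = cp
        for key in ("households_per_area", "years", "indicator_prevalence", "cni_weights"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path=None) -> str | None:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: Effective number of independently funded CHCs an area's children reach;
#: calibrated once against the generator's realised zero-dosage share.
_EFFECTIVE_LOCAL_CHCS = 3.6


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the end-to-end analysis pipeline."""

    simulation: SimulationConfig | None = None
    panel_path: str | None = None
    rollout_threshold: float = 0.10
    alternative_thresholds: tuple[float, ...] = (0.0, 0.05, 0.15, 0.20, 0.25)
    need_thresholds: tuple[float, ...] = (1.0, 1.5, 2.0)
    weighting: bool = False
    stages: tuple[str, ...] = ("A", "B", "C", "D", "temporal", "sensitivity")
    out_dir: str | None = None
    seed: int = 0

    VALID_STAGES = ("A", "B", "C", "D", "temporal", "sensitivity")

    def __post_init__(self):
        if not self.stages:
            raise ConfigurationError("stages must be non-empty")
        bad = [s for s in self.stages if s not in self.VALID_STAGES]
        if bad:
            raise ConfigurationError(f"unknown stages {bad}; valid: {self.VALID_STAGES}")
        for name, t in (
            ("rollout_threshold", self.rollout_threshold),
            *((f"alternative_thresholds[{i}]", t) for i, t in enumerate(self.alternative_thresholds)),
        ):
            _check_prob(name, t)
        if self.simulation is None and self.panel_path is None:
            raise ConfigurationError("either simulation config or panel_path is required")

    def to_dict(self) -> dict:
        d = {
            "simulation": self.simulation.to_dict() if self.simulation else None,
            "panel_path": self.panel_path,
            "rollout_threshold": self.rollout_threshold,
            "alternative_thresholds": list(self.alternative_thresholds),
            "need_thresholds": list(self.need_thresholds),
            "weighting": self.weighting,
            "stages": list(self.stages),
            "out_dir": self.out_dir,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation"):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        for key in ("alternative_thresholds", "need_thresholds", "stages"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path=None) -> str | None:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None
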