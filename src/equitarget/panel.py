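"""Fixed-effects targeting regressions with cluster-robust inference.

The central object pair is :class:`TargetingModel` / :class:`TargetingResults`,
in the spirit of statsmodels: a model is built from an area-year panel and a
:class:`ModelSpec`, ``fit()`` returns results carrying coefficients,
cluster-robust (CR1) standard errors, t(G-1) confidence intervals and fit
diagnostics, with ``summary()`` and tidy export.

The regression of interest is the targeting association

    dosage_it = b0 + b1 * relative_cni_it + gamma_t + eps_it

estimated by least squares with year fixed effects (dummy-encoded, first
level as reference) and standard errors clustered at the area level with the
CR1 small-sample factor G/(G-1) * (N-1)/(N-K); coefficient tests use a t
distribution with G-1 degrees of freedom.  Convenience drivers cover the
stratified-by-region fits, the pooled interaction Wald test of slope
equality, quadratic specifications with a turning point, year-by-year
cross-sections, a two-part (hurdle) decomposition for the zero-heavy dosage
outcome, empirical rollout-year detection and VIF collinearity diagnostics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

from .exceptions import (
    ClusteringError,
    DegenerateMarginError,
    NoTurningPointError,
    SeparationError,
    SingularDesignError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "TargetingModel",
    "TargetingResults",
    "WaldTestResult",
    "TurningPoint",
    "RegionFits",
    "TwoPartResults",
    "ExtensiveResults",
    "fit_ols_fe",
    "fit_quadratic",
    "turning_point",
    "fit_by_region",
    "wald_equality_test",
    "fit_two_part",
    "year_by_year",
    "detect_rollout_year",
    "vif",
]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative regression specification.

    ``predictors`` entries are column names; an interaction is written as a
    2-tuple ``("a", "b")`` or the string ``"a:b"``.  ``subset`` is a pandas
    query string or a boolean-mask callable applied before fitting.
    """

    outcome: str
    predictors: tuple = ("relative_cni",)
    fixed_effects: tuple = ("year",)
    cluster_by: str = "area_id"
    weights_by: str | None = None
    subset: str | Callable | None = None

    def __post_init__(self):
        object.__setattr__(self, "predictors", tuple(self.predictors))
        object.__setattr__(self, "fixed_effects", tuple(self.fixed_effects))
        for p in self._predictor_names():
            if p == self.outcome:
                raise ValidationError(f"outcome {self.outcome!r} cannot be a predictor")

    def _predictor_names(self):
        names = []
        for p in self.predictors:
            if isinstance(p, str) and ":" in p:
                names.extend(p.split(":"))
            elif isinstance(p, (tuple, list)):
                names.extend(p)
            else:
                names.append(p)
        return names

    def to_dict(self) -> dict:
        preds = [":".join(p) if isinstance(p, (tuple, list)) else p for p in self.predictors]
        return {
            "outcome": self.outcome,
            "predictors": preds,
            "fixed_effects": list(self.fixed_effects),
            "cluster_by": self.cluster_by,
            "weights_by": self.weights_by,
            "subset": self.subset if isinstance(self.subset, str) else None,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            outcome=d["outcome"],
            predictors=tuple(d.get("predictors", ("relative_cni",))),
            fixed_effects=tuple(d.get("fixed_effects", ("year",))),
            cluster_by=d.get("cluster_by", "area_id"),
            weights_by=d.get("weights_by"),
            subset=d.get("subset"),
        )

    def to_yaml(self, path=None) -> str | None:
        import yaml

        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _interaction_name(p) -> str:
    return ":".join(p) if isinstance(p, (tuple, list)) else p


def _apply_subset(data: pd.DataFrame, subset) -> pd.DataFrame:
    if subset is None:
        return data
    if isinstance(subset, str):
        return data.query(subset)
    return data[np.asarray(subset(data), dtype=bool)]


def _build_design(data: pd.DataFrame, spec: ModelSpec):
    """Return (y, X DataFrame with intercept, cluster codes, weights)."""
    df = _apply_subset(data, spec.subset)
    needed = set(spec._predictor_names()) | {spec.outcome, spec.cluster_by}
    needed |= set(spec.fixed_effects)
    if spec.weights_by:
        needed.add(spec.weights_by)
    missing = sorted(c for c in needed if c not in df.columns)
    if missing:
        raise ValidationError(f"columns missing from data: {missing}")
    df = df.dropna(subset=sorted(needed))
    if df.empty:
        raise ValidationError("no rows left after subsetting/NA removal")

    cols = {"const": np.ones(len(df))}
    for p in spec.predictors:
        name = _interaction_name(p)
        parts = name.split(":") if ":" in name else [name]
        v = np.ones(len(df))
        for part in parts:
            v = v * df[part].to_numpy(dtype=float)
        cols[name] = v
    X = pd.DataFrame(cols, index=df.index)
    for fe in spec.fixed_effects:
        dummies = pd.get_dummies(
            df[fe].astype("category"), prefix=fe, drop_first=True, dtype=float
        )
        X = pd.concat([X, dummies], axis=1)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # pivoted QR: columns with negligible R diagonal are the collinear ones
        _, r, piv = scipy.linalg.qr(X.to_numpy(), pivoting=True, mode="economic")
        diag = np.abs(np.diag(r))
        bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] < 1e-10 * diag[0]]
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear terms: {bad}"
        )

    y = df[spec.outcome].to_numpy(dtype=float)
    clusters, _ = pd.factorize(df[spec.cluster_by])
    w = df[spec.weights_by].to_numpy(dtype=float) if spec.weights_by else None
    return y, X, clusters, w, df


class TargetingResults:
    """Estimates, cluster-robust uncertainty and diagnostics of one fit.

    Attributes mirror statsmodels results (``params``, ``bse``, ``pvalues``,
    ``conf_int()``) plus the panel-analysis extras the reporting needs
    (``n_clusters``, ``adj_rsquared``, the echoed :class:`ModelSpec`).
    """

    def __init__(self, sm_results, spec: ModelSpec, n_clusters: int):
        self._sm = sm_results
        self.spec = spec
        self.n_clusters = int(n_clusters)

    # -- statsmodels-like surface -------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return self._sm.params

    @property
    def bse(self) -> pd.Series:
        return self._sm.bse

    @property
    def pvalues(self) -> pd.Series:
        return self._sm.pvalues

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self._sm.conf_int(alpha)
        ci.columns = ["low", "high"]
        return ci

    def cov_params(self) -> pd.DataFrame:
        return self._sm.cov_params()

    @property
    def resid(self) -> np.ndarray:
        return np.asarray(self._sm.resid)

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self._sm.fittedvalues)

    @property
    def nobs(self) -> int:
        return int(self._sm.nobs)

    @property
    def adj_rsquared(self) -> float:
        return float(self._sm.rsquared_adj)

    @property
    def df_inference(self) -> float:
        return float(self._sm.df_resid_inference)

    # -- spec-schema maps ---------------------------------------------------------
    @property
    def coefficients(self) -> dict:
        return self.params.to_dict()

    @property
    def clustered_se(self) -> dict:
        return self.bse.to_dict()

    @property
    def conf_int_95(self) -> dict:
        ci = self.conf_int()
        return {t: (ci.loc[t, "low"], ci.loc[t, "high"]) for t in ci.index}

    @property
    def p_values(self) -> dict:
        return self.pvalues.to_dict()

    def wald_test(self, r_matrix) -> "WaldTestResult":
        """Chi-squared Wald test of ``R beta = 0`` on the clustered covariance."""
        R = np.atleast_2d(np.asarray(r_matrix, dtype=float))
        beta = self.params.to_numpy()
        V = self.cov_params().to_numpy()
        RVR = R @ V @ R.T
        eigvals = np.linalg.eigvalsh(RVR)
        if eigvals.min() <= 0:
            cond = np.inf if eigvals.min() <= 0 else eigvals.max() / eigvals.min()
            raise ValidationError(
                "restricted covariance is not positive definite "
                f"(condition number {cond:.3g}); Wald test unavailable"
            )
        rb = R @ beta
        stat = float(rb @ np.linalg.solve(RVR, rb))
        df = R.shape[0]
        p = float(scipy.stats.chi2.sf(stat, df))
        return WaldTestResult(statistic=stat, df=df, pvalue=p)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (term, estimate, se, ci_low, ci_high, p) table."""
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "ci_low": ci["low"].to_numpy(),
                "ci_high": ci["high"].to_numpy(),
                "p": self.pvalues.to_numpy(),
            }
        ).reset_index(drop=True)

    def to_json(self, path=None, **kwargs) -> str | None:
        """Tidy results as JSON records (term, estimate, se, ci, p)."""
        text = self.to_frame().to_json(orient="records", **kwargs)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    def summary(self) -> str:
        lines = [
            f"Targeting regression: {self.spec.outcome} ~ "
            + " + ".join(_interaction_name(p) for p in self.spec.predictors)
            + (
                " + FE(" + ", ".join(self.spec.fixed_effects) + ")"
                if self.spec.fixed_effects
                else ""
            ),
            f"N = {self.nobs}, clusters({self.spec.cluster_by}) = {self.n_clusters}, "
            f"adj. R2 = {self.adj_rsquared:.3f}",
            "Cluster-robust (CR1) standard errors; t with G-1 df.",
            "",
            f"{'term':<24}{'estimate':>12}{'se':>10}{'ci95_low':>12}{'ci95_high':>12}{'p':>10}",
        ]
        ci = self.conf_int()
        for t in self.params.index:
            lines.append(
                f"{t:<24}{self.params[t]:>12.4f}{self.bse[t]:>10.4f}"
                f"{ci.loc[t, 'low']:>12.4f}{ci.loc[t, 'high']:>12.4f}"
                f"{self.pvalues[t]:>10.2g}"
            )
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<TargetingResults n={self.nobs} clusters={self.n_clusters} "
            f"outcome={self.spec.outcome!r}>"
        )


@dataclass(frozen=True)
class WaldTestResult:
    statistic: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class TurningPoint:
    """Turning point of a quadratic need-dosage profile."""

    value: float
    share_above: float | None = None


class TargetingModel:
    """Least-squares targeting model on an area-year panel.

    Parameters
    ----------
    data
        Area-year panel (one row per area and year).
    spec
        The regression specification.

    Examples
    --------
    >>> model = TargetingModel.from_dataframe(panel, outcome="dosage",
    ...                                       predictors=["relative_cni"])
    >>> res = model.fit()
    >>> res.params["relative_cni"]  # doctest: +SKIP
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.data = data
        self.spec = spec

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str = "dosage",
        predictors: Sequence = ("relative_cni",),
        fixed_effects: Sequence = ("year",),
        cluster_by: str = "area_id",
        weights_by: str | None = None,
        subset=None,
    ) -> "TargetingModel":
        spec = ModelSpec(
            outcome=outcome,
            predictors=tuple(predictors),
            fixed_effects=tuple(fixed_effects),
            cluster_by=cluster_by,
            weights_by=weights_by,
            subset=subset,
        )
        return cls(data, spec)

    def fit(self) -> TargetingResults:
        y, X, clusters, w, _ = _build_design(self.data, self.spec)
        n_clusters = int(len(np.unique(clusters)))
        if n_clusters < 2:
            raise ClusteringError(
                f"cluster-robust errors need >= 2 clusters, got {n_clusters}"
            )
        model = sm.WLS(y, X, weights=w) if w is not None else sm.OLS(y, X)
        res = model.fit(
            cov_type="cluster",
            cov_kwds={"groups": clusters, "use_correction": True},
            use_t=True,
        )
        return TargetingResults(res, self.spec, n_clusters)


def fit_ols_fe(data: pd.DataFrame, spec: ModelSpec) -> TargetingResults:
    """Fixed-effects least squares with CR1 area-clustered standard errors."""
    return TargetingModel(data, spec).fit()


def fit_quadratic(
    data: pd.DataFrame, spec: ModelSpec, need: str | None = None
) -> TargetingResults:
    """Fit with an added squared need term and a Wald test of non-linearity.

    The returned results carry ``linear_term``, ``quadratic_term`` and
    ``nonlinearity_wald`` attributes.
    """
    if need is None:
        need = next(p for p in spec.predictors if isinstance(p, str) and ":" not in p)
    sq = f"{need}_sq"
    df = data.copy()
    df[sq] = df[need].astype(float) ** 2
    preds = list(spec.predictors)
    preds.insert(preds.index(need) + 1, sq)
    res = fit_ols_fe(df, replace(spec, predictors=tuple(preds)))
    r = np.zeros(len(res.params))
    r[list(res.params.index).index(sq)] = 1.0
    res.linear_term = need
    res.quadratic_term = sq
    res.nonlinearity_wald = res.wald_test(r)
    return res


def turning_point(
    fit: TargetingResults,
    linear_term: str | None = None,
    quadratic_term: str | None = None,
    need_values=None,
    tol: float = 1e-12,
) -> TurningPoint:
    """Turning point -b1/(2 b2) of a fitted quadratic need profile.

    ``need_values`` (optional) yields the share of observations above the
    turning point.  Raises :class:`NoTurningPointError` when the quadratic
    coefficient is numerically zero.
    """
    linear_term = linear_term or getattr(fit, "linear_term", None)
    quadratic_term = quadratic_term or getattr(fit, "quadratic_term", None)
    if linear_term is None or quadratic_term is None:
        raise ValidationError("linear and quadratic term names are required")
    b1 = float(fit.params[linear_term])
    b2 = float(fit.params[quadratic_term])
    if abs(b2) < tol:
        raise NoTurningPointError(f"quadratic coefficient {b2!r} is numerically zero")
    tp = -b1 / (2.0 * b2)
    share = None
    if need_values is not None:
        share = float(np.mean(np.asarray(need_values, dtype=float) > tp))
    return TurningPoint(value=tp, share_above=share)


@dataclass
class RegionFits:
    """Per-region stratified fits; regions with too few clusters are skipped."""

    fits: dict
    skipped: list = field(default_factory=list)

    @property
    def n_obs(self) -> dict:
        return {r: f.nobs for r, f in self.fits.items()}

    def slopes(self, term: str) -> dict:
        return {r: f.params[term] for r, f in self.fits.items()}


def fit_by_region(
    data: pd.DataFrame,
    spec: ModelSpec,
    region_col: str = "region",
    min_clusters: int = 2,
) -> RegionFits:
    """Stratified regressions, one fit per region on its own subset."""
    fits, skipped = {}, []
    for region, sub in data.groupby(region_col, sort=True):
        n_cl = sub[spec.cluster_by].nunique()
        if n_cl < min_clusters:
            warnings.warn(
                f"region {region!r} skipped: {n_cl} cluster(s) < {min_clusters}",
                stacklevel=2,
            )
            skipped.append(region)
            continue
        fits[region] = fit_ols_fe(sub, spec)
    return RegionFits(fits=fits, skipped=skipped)


def wald_equality_test(
    data: pd.DataFrame,
    spec: ModelSpec,
    region_col: str = "region",
    need: str | None = None,
) -> WaldTestResult:
    """Wald test of slope equality across regions.

    Fits a pooled model with region main effects and region-by-need
    interactions (first region as reference) on the clustered covariance and
    tests all interaction terms jointly zero; df = n_regions - 1.
    """
    if need is None:
        need = next(p for p in spec.predictors if isinstance(p, str) and ":" not in p)
    regions = sorted(data[region_col].unique())
    if len(regions) < 2:
        raise ValidationError("wald_equality_test needs >= 2 regions")
    df = data.copy()
    inter_terms = []
    for r in regions[1:]:
        dummy = f"{region_col}_{r}"
        inter = f"{need}:{dummy}"
        df[dummy] = (df[region_col] == r).astype(float)
        df[inter] = df[dummy] * df[need].astype(float)
        inter_terms.append(inter)
    preds = list(spec.predictors) + [f"{region_col}_{r}" for r in regions[1:]] + inter_terms
    res = fit_ols_fe(df, replace(spec, predictors=tuple(preds)))
    R = np.zeros((len(inter_terms), len(res.params)))
    idx = list(res.params.index)
    for i, t in enumerate(inter_terms):
        R[i, idx.index(t)] = 1.0
    return res.wald_test(R)


class ExtensiveResults:
    """Cluster-robust logistic fit of any-programme-presence, as odds ratios."""

    def __init__(self, sm_results, spec: ModelSpec, n_clusters: int):
        self._sm = sm_results
        self.spec = spec
        self.n_clusters = int(n_clusters)

    @property
    def params(self) -> pd.Series:
        """Log-odds coefficients."""
        return self._sm.params

    @property
    def bse(self) -> pd.Series:
        return self._sm.bse

    @property
    def pvalues(self) -> pd.Series:
        return self._sm.pvalues

    @property
    def nobs(self) -> int:
        return int(self._sm.nobs)

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self._sm.params)

    def conf_int(self, alpha: float = 0.05, odds: bool = True) -> pd.DataFrame:
        ci = self._sm.conf_int(alpha)
        ci.columns = ["low", "high"]
        return np.exp(ci) if odds else ci

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "term": self.params.index,
                "odds_ratio": self.odds_ratios.to_numpy(),
                "log_odds": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "or_ci_low": ci["low"].to_numpy(),
                "or_ci_high": ci["high"].to_numpy(),
                "p": self.pvalues.to_numpy(),
            }
        )


@dataclass
class TwoPartResults:
    """Hurdle decomposition: extensive (any presence) and intensive margins."""

    extensive: ExtensiveResults
    intensive: TargetingResults


def fit_two_part(
    data: pd.DataFrame, spec: ModelSpec, logit_fixed_effects: bool = True
) -> TwoPartResults:
    """Two-part model for a zero-heavy outcome.

    Extensive margin: maximum-likelihood logit of 1{outcome > 0} with
    cluster-robust standard errors, reported as odds ratios.  Intensive
    margin: the fixed-effects least-squares fit on the strictly positive
    subset.  Perfect separation raises :class:`SeparationError` rather than
    silently diverging.
    """
    df = _apply_subset(data, spec.subset).dropna(subset=[spec.outcome])
    positive = df[spec.outcome] > 0
    if positive.all() or (~positive).all():
        raise DegenerateMarginError(
            "two-part model needs both zero and positive outcomes; "
            f"{int(positive.sum())}/{len(df)} rows positive"
        )
    ext_spec = replace(
        spec,
        subset=None,
        weights_by=None,
        fixed_effects=spec.fixed_effects if logit_fixed_effects else (),
    )
    df_ext = df.copy()
    df_ext["_any"] = positive.astype(float)
    _, X, clusters, _, _ = _build_design(df_ext, replace(ext_spec, outcome="_any"))
    n_clusters = int(len(np.unique(clusters)))
    if n_clusters < 2:
        raise ClusteringError("cluster-robust errors need >= 2 clusters")
    y = df_ext.loc[X.index, "_any"].to_numpy()
    try:
        res = sm.Logit(y, X).fit(
            disp=0,
            maxiter=100,
            tol=1e-10,
            cov_type="cluster",
            cov_kwds={"groups": clusters},
            use_t=True,
        )
    except Exception as exc:  # statsmodels PerfectSeparationError and kin
        if "separat" in str(exc).lower() or "Singular" in str(exc):
            raise SeparationError(f"extensive margin failed to fit: {exc}") from exc
        raise
    if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 25:
        raise SeparationError(
            "extensive-margin logit diverged (perfect or quasi-separation suspected); "
            f"max |coef| = {np.abs(res.params).max():.3g}"
        )
    extensive = ExtensiveResults(res, ext_spec, n_clusters)

    intensive_spec = replace(spec, subset=None)
    intensive = fit_ols_fe(df[positive], intensive_spec)
    return TwoPartResults(extensive=extensive, intensive=intensive)


def year_by_year(
    data: pd.DataFrame,
    spec: ModelSpec,
    year_col: str = "year",
    min_clusters: int = 2,
) -> dict:
    """Per-year cross-sectional fits (no year fixed effects), clustered SEs."""
    fe = tuple(f for f in spec.fixed_effects if f != year_col)
    out = {}
    for year, sub in data.groupby(year_col, sort=True):
        n_cl = sub[spec.cluster_by].nunique()
        if n_cl < min_clusters:
            warnings.warn(
                f"year {year!r} skipped: {n_cl} cluster(s) < {min_clusters}",
                stacklevel=2,
            )
            continue
        out[year] = fit_ols_fe(sub, replace(spec, fixed_effects=fe))
    return out


def detect_rollout_year(
    panel: pd.DataFrame,
    threshold: float = 0.10,
    region_col: str = "region",
    year_col: str = "year",
    dosage_col: str = "dosage",
) -> dict:
    """Earliest year per region in which the share of areas with any dosage
    reaches ``threshold`` (strictly positive share when ``threshold`` is 0).

    Returns ``{region: year}`` with ``None`` for regions that never reach it.
    """
    if not 0 <= threshold <= 1:
        raise ValidationError(f"threshold must be in [0, 1], got {threshold}")
    share = (
        panel.assign(_any=panel[dosage_col] > 0)
        .groupby([region_col, year_col], sort=True)["_any"]
        .mean()
    )
    out = {}
    for region in panel[region_col].unique():
        s = share.loc[region]
        hit = s[s > 0] if threshold == 0 else s[s >= threshold]
        out[region] = int(hit.index.min()) if len(hit) else None
    return out


def vif(data: pd.DataFrame, predictors: Sequence[str]) -> dict:
    """Variance inflation factors: VIF_j = 1 / (1 - R2_j) from regressing
    predictor j on the remaining predictors (with intercept).

    A single predictor returns 1.0; perfect collinearity yields ``inf``
    rather than an exception.
    """
    predictors = list(predictors)
    if len(predictors) == 0:
        raise ValidationError("vif needs at least one predictor")
    if len(predictors) == 1:
        return {predictors[0]: 1.0}
    X = data[predictors].dropna().to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(predictors):
        yj = X[:, j]
        Xo = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ beta
        tss = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 1.0
        out[name] = float("inf") if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return out
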