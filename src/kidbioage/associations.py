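"""Covariate-adjusted association testing for biological-age markers.

Markers (Δ age per clock; sign-flipped, SD-scaled telomere length) are
tested against developmental outcomes (outcome as the dependent variable;
logistic for puberty onset) and against health risk factors (marker as the
dependent variable), always adjusting for chronological age, sex,
ethnicity and study centre. Benjamini–Hochberg FDR is computed across the
whole family of primary associations; sensitivity variants (sex and centre
stratification, cell-fraction and risk-factor adjustment) are run outside
the FDR family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age_years", "sex", "ethnicity", "centre")


class AssociationError(ValueError):
    pass


@dataclass(frozen=True)
class AssociationSpec:
    """One regression model: exposure, outcome, direction, covariates."""

    exposure: str
    outcome: str
    direction: str = "outcome_as_dependent"  # or "marker_as_dependent"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    family: str = "linear"  # or "logistic"
    stratum: tuple[str, str] | None = None  # (column, level)
    extra_covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.exposure in self.covariates or self.exposure in self.extra_covariates:
            raise AssociationError(f"exposure {self.exposure!r} also appears among the covariates")
        if self.direction not in ("outcome_as_dependent", "marker_as_dependent"):
            raise AssociationError(f"unknown direction {self.direction!r}")
        if self.family not in ("linear", "logistic"):
            raise AssociationError(f"unknown family {self.family!r}")

    @property
    def dependent(self) -> str:
        return self.outcome if self.direction == "outcome_as_dependent" else self.exposure

    @property
    def independent(self) -> str:
        return self.exposure if self.direction == "outcome_as_dependent" else self.outcome


@dataclass
class AssociationResult:
    spec: AssociationSpec
    estimate: float  # SD of outcome per unit exposure; OR for logistic
    ci_low: float
    ci_high: float
    p: float
    n: int
    q: float | None = None
    flagged: str | None = None
    variant: str = "primary"

    def to_row(self) -> dict:
        return {
            "exposure": self.spec.exposure,
            "outcome": self.spec.outcome,
            "direction": self.spec.direction,
            "family": self.spec.family,
            "stratum": "" if self.spec.stratum is None else f"{self.spec.stratum[0]}={self.spec.stratum[1]}",
            "variant": self.variant,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "q": self.q,
            "n": self.n,
            "flagged": self.flagged or "",
        }


def results_table(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def prepare_markers(
    telomere: pd.DataFrame | None,
    deltas: dict[str, pd.DataFrame],
    epigenetic: pd.Series | None = None,
    chronological: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the per-child marker table on the analysis scale.

    Telomere length is multiplied by −1 (so effects point the same way as
    the age clocks) and scaled to unit SD — a "telomere shortening" scale.
    Clock Δ-age columns pass through in years. An optional precomputed
    epigenetic-age column is converted to Δ age against chronological age.
    """
    pieces = []
    if telomere is not None:
        col = telomere["relative_ts"]
        sd = float(col.std(ddof=1))
        if sd == 0.0:
            raise AssociationError("telomere column has zero SD")
        pieces.append(((-1.0 * col) / sd).rename("telomere_shortening"))
    for name, preds in deltas.items():
        pieces.append(preds["delta_age"].rename(f"{name}_delta_age"))
    if epigenetic is not None:
        if chronological is None:
            raise AssociationError("chronological ages required to convert epigenetic age to delta age")
        pieces.append((epigenetic - chronological.reindex(epigenetic.index)).rename("epigenetic_delta_age"))
    if not pieces:
        raise AssociationError("no markers supplied")
    return pd.concat(pieces, axis=1)


def transform_outcomes(
    cohort: pd.DataFrame,
    continuous: list[str],
    passthrough: tuple[str, ...] = ("zbmi", "height_z"),
    log_plus_one: tuple[str, ...] = ("cbcl_internalizing", "cbcl_externalizing"),
) -> pd.DataFrame:
    """Outcome columns on the analysis scale: continuous outcomes are
    mean-centred and unit-SD scaled except the BMI/height z-scores, which
    pass through; CBCL scores are log(x+1)-transformed before scaling."""
    out = cohort.copy()
    for col in continuous:
        if col in log_plus_one:
            out[col] = np.log(out[col] + 1.0)
        if col not in passthrough:
            sd = out[col].std(ddof=1)
            if sd == 0:
                raise AssociationError(f"outcome {col!r} has zero SD")
            out[col] = (out[col] - out[col].mean()) / sd
    return out


def _term(col: str, data: pd.DataFrame) -> str:
    if data[col].dtype == object or isinstance(data[col].dtype, pd.CategoricalDtype):
        return f"C(Q('{col}'))"
    return f"Q('{col}')"


def _check_collinear(data: pd.DataFrame, columns: list[str]) -> None:
    numeric = [c for c in columns if np.issubdtype(data[c].dtype, np.number)]
    if len(numeric) < 2:
        return
    sub = data[numeric].dropna()
    if len(sub) < 3:
        return
    corr = sub.corr().to_numpy()
    for i in range(len(numeric)):
        for j in range(i + 1, len(numeric)):
            if abs(corr[i, j]) > 1.0 - 1e-10:
                raise AssociationError(f"collinear covariates: {numeric[i]!r} and {numeric[j]!r}")


def run_association(spec: AssociationSpec, data: pd.DataFrame) -> AssociationResult:
    """Fit one adjusted regression and return the exposure effect.

    Linear models use OLS; logistic models maximum-likelihood with the
    estimate exponentiated to an odds ratio. 95% CIs are Wald intervals.
    Complete cases only (listwise deletion on the model's variables).
    """
    columns = [spec.dependent, spec.independent, *spec.covariates, *spec.extra_covariates]
    missing = [c for c in columns if c not in data.columns]
    if missing:
        raise AssociationError(f"data lacks columns: {missing}")
    frame = data[list(dict.fromkeys(columns))]
    if spec.stratum is not None:
        col, level = spec.stratum
        frame = frame[data[col].astype(str) == str(level)]
    frame = frame.dropna()
    _check_collinear(frame, [spec.independent, *spec.covariates, *spec.extra_covariates])

    rhs_cols = [spec.independent, *spec.covariates, *spec.extra_covariates]
    formula = f"Q('{spec.dependent}') ~ " + " + ".join(_term(c, frame) for c in rhs_cols)
    key = f"Q('{spec.independent}')"
    try:
        if spec.family == "linear":
            fit = smf.ols(formula, data=frame).fit()
        else:
            fit = smf.glm(formula, data=frame, family=sm.families.Binomial()).fit()
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        return AssociationResult(
            spec=spec, estimate=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            p=float("nan"), n=len(frame), flagged=f"fit_failed:{type(exc).__name__}",
        )
    n = int(fit.nobs)
    if n <= len(fit.params):
        raise AssociationError(f"n={n} does not exceed the parameter count ({len(fit.params)})")
    est = float(fit.params[key])
    ci = fit.conf_int().loc[key]
    p = float(fit.pvalues[key])
    flagged = None
    if spec.family == "logistic":
        se = float(fit.bse[key])
        if not np.isfinite(se) or se > 1e3:  # quasi-separation
            flagged = "possible_separation"
        est, ci = float(np.exp(est)), np.exp(ci)
    return AssociationResult(
        spec=spec, estimate=est, ci_low=float(ci.iloc[0]), ci_high=float(ci.iloc[1]), p=p, n=n, flagged=flagged
    )


def fdr_adjust(results: list[AssociationResult]) -> list[AssociationResult]:
    """Fill Benjamini–Hochberg q-values across the whole result family."""
    if not results:
        raise AssociationError("empty association family")
    ps = np.array([r.p for r in results])
    ok = np.isfinite(ps)
    qs = np.full(len(ps), np.nan)
    if ok.any():
        qs[ok] = multipletests(ps[ok], method="fdr_bh")[1]
    for r, q in zip(results, qs):
        r.q = float(q) if np.isfinite(q) else None
    return results


def partial_correlation(x, y, covariates: pd.DataFrame | None = None) -> tuple[float, float]:
    """Pearson correlation of x and y after residualizing both on covariates.

    Categorical covariates are indicator-coded. p comes from the t
    distribution with df = n − 2 − k, k the number of covariate columns
    after coding.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None or covariates.shape[1] == 0:
        design = np.ones((n, 1))
        k = 0
    else:
        dummies = pd.get_dummies(covariates, drop_first=True, dtype=float)
        design = np.column_stack([np.ones(n), dummies.to_numpy()])
        k = design.shape[1] - 1
    if n <= k + 2:
        raise AssociationError(f"n={n} too small for {k} covariate columns")
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if np.std(rx) <= 1e-10 * (1.0 + np.std(x)) or np.std(ry) <= 1e-10 * (1.0 + np.std(y)):
        raise AssociationError("zero residual variance in partial correlation")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_clamped = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clamped * np.sqrt(df / (1.0 - r_clamped**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


SENSITIVITY_VARIANTS = ("sex_stratified", "cell_adjusted", "risk_adjusted", "centre_stratified")


def sensitivity_suite(
    base_specs: list[AssociationSpec],
    data: pd.DataFrame,
    cell_columns: tuple[str, ...] = (),
    risk_columns: tuple[str, ...] = (),
    variants: tuple[str, ...] = SENSITIVITY_VARIANTS,
) -> list[AssociationResult]:
    """Re-run every base spec under each sensitivity variant.

    Stratified fits retain the remaining covariates (the stratifying
    variable is removed); extended variants append covariate columns.
    Strata too small for the model are skipped with a log entry.
    """
    out: list[AssociationResult] = []
    for variant in variants:
        for spec in base_specs:
            if variant == "sex_stratified":
                new_specs = [
                    replace(spec, covariates=tuple(c for c in spec.covariates if c != "sex"), stratum=("sex", lv))
                    for lv in data["sex"].dropna().unique()
                ]
            elif variant == "centre_stratified":
                new_specs = [
                    replace(spec, covariates=tuple(c for c in spec.covariates if c != "centre"), stratum=("centre", lv))
                    for lv in data["centre"].dropna().unique()
                ]
            elif variant == "cell_adjusted":
                extra = tuple(c for c in cell_columns if c not in (spec.exposure, spec.outcome))
                new_specs = [replace(spec, extra_covariates=spec.extra_covariates + extra)]
            elif variant == "risk_adjusted":
                extra = tuple(c for c in risk_columns if c not in (spec.exposure, spec.outcome))
                new_specs = [replace(spec, extra_covariates=spec.extra_covariates + extra)]
            else:
                raise AssociationError(f"unknown sensitivity variant {variant!r}")
            for s in new_specs:
                try:
                    res = run_association(s, data)
                except AssociationError as exc:
                    logger.info("skipping %s under %s: %s", s, variant, exc)
                    continue
                res.variant = variant
                out.append(res)
    return out
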