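"""Inferential layer: demographics tests, GLMs, diagnostics, Bonferroni.

Three model families drive the analysis, always with age, sex and
education as covariates:

* group differences in a dynamic state (or diffusion) measure:
  ``Y ~ 1 + group + age + sex + education``;
* personality-by-dynamics interaction on long-term outcome:
  ``Y ~ 1 + emotional_instability * state_metric + age + sex + education``;
* dynamics versus microstructure:
  ``Y ~ 1 + dti_pc1 + age + sex + education``.

The response distribution (Gaussian with identity, square-root or log
transform; Poisson; Gamma; inverse Gaussian; Binomial for dichotomous
outcomes) is selected by AIC over the admissible candidates.  AICs of
transformed-Gaussian fits include the change-of-variables Jacobian so
they are comparable on the original response scale.  Fitted models
carry variance-inflation factors (accepted when all are below 5),
Shapiro-Wilk residual normality, an overall model test against the
intercept-only model, and Bonferroni-corrected overall p-values with
the family size determined by the metric class (k for state-specific
measures, k*k for specific transition probabilities, 1 otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "GlmResult",
    "demographics_tests",
    "bonferroni_threshold",
    "correct_p",
    "vif",
    "fit_glm",
    "select_family_and_transform",
    "interaction_scan",
]

COVARIATES = ("age", "sex", "education")

_FAMILIES = {
    "gaussian": lambda: sm.families.Gaussian(),
    "poisson": lambda: sm.families.Poisson(),
    "gamma": lambda: sm.families.Gamma(link=sm.families.links.Log()),
    "inverse_gaussian": lambda: sm.families.InverseGaussian(
        link=sm.families.links.Log()
    ),
    "binomial": lambda: sm.families.Binomial(),
}

_TRANSFORMS = {
    "identity": (lambda y: y, lambda y: np.zeros_like(y, dtype=float)),
    "sqrt": (np.sqrt, lambda y: np.log(0.5) - 0.5 * np.log(y)),
    "log": (np.log, lambda y: -np.log(y)),
}


@dataclass
class ModelSpec:
    """Declarative description of one GLM."""

    response: str
    predictors: list[str]
    covariates: tuple[str, ...] = COVARIATES
    families: tuple[str, ...] = (
        "gaussian",
        "poisson",
        "gamma",
        "inverse_gaussian",
        "binomial",
    )
    transforms: tuple[str, ...] = ("identity", "sqrt", "log")
    bonferroni_m: int = 1

    def __post_init__(self) -> None:
        if self.bonferroni_m < 1:
            raise ValueError("bonferroni family size must be >= 1")
        unknown = set(self.families) - set(_FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")

    @property
    def formula(self) -> str:
        terms = " + ".join(["1", *self.predictors, *self.covariates])
        return f"{self.response} ~ {terms}"


@dataclass
class GlmResult:
    """A fitted GLM with its diagnostics."""

    spec: ModelSpec
    family: str
    transform: str
    coefficients: pd.DataFrame  # term, estimate, se, stat, p
    overall_stat: float
    overall_df: tuple[int, int]
    overall_p: float
    overall_p_corrected: float
    aic: float
    vif: pd.Series
    shapiro_p: float
    accepted: bool
    n_obs: int


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold ``alpha / m``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("family size must be >= 1")
    return alpha / m


def correct_p(p: float, m: int) -> float:
    """Bonferroni-corrected p-value ``min(1, p * m)``."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return float(min(1.0, p * m))


def demographics_tests(
    cohort: pd.DataFrame,
    group_col: str = "group",
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
    alpha: float = 0.05,
    alpha_overrides: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Group comparisons of demographic and questionnaire variables.

    Continuous variables are tested with an independent two-sample
    t-test when Shapiro-Wilk accepts normality in both groups, and with
    a Mann-Whitney U test otherwise; categorical variables with a
    chi-square test (no continuity correction).  ``alpha_overrides``
    lets multi-scale questionnaires use a Bonferroni-corrected
    threshold (for the five Big Five dimension totals, alpha / 5).
    """
    groups = cohort[group_col].dropna().unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {len(groups)}")
    a = cohort[cohort[group_col] == groups[0]]
    b = cohort[cohort[group_col] == groups[1]]
    alpha_overrides = alpha_overrides or {}
    rows = []
    for var in continuous or []:
        xa = a[var].dropna().to_numpy(dtype=float)
        xb = b[var].dropna().to_numpy(dtype=float)
        normal = (
            scipy.stats.shapiro(xa).pvalue > 0.05
            and scipy.stats.shapiro(xb).pvalue > 0.05
        )
        if normal:
            stat, p = scipy.stats.ttest_ind(xa, xb)
            test = "t"
        else:
            stat, p = scipy.stats.mannwhitneyu(xa, xb, alternative="two-sided")
            test = "mann-whitney-u"
        rows.append((var, test, float(stat), float(p)))
    for var in categorical or []:
        table = pd.crosstab(cohort[group_col], cohort[var])
        stat, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
        rows.append((var, "chi-square", float(stat), float(p)))
    out = pd.DataFrame(rows, columns=["variable", "test", "statistic", "p"])
    out["alpha"] = [alpha_overrides.get(v, alpha) for v in out["variable"]]
    out["significant"] = out["p"] < out["alpha"]
    return out


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor.

    ``VIF_j = 1 / (1 - R^2_j)`` with ``R^2_j`` from regressing
    predictor j on the remaining predictors (plus intercept).  Perfect
    collinearity is reported as ``inf``.
    """
    x = design.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    out = {}
    for j, name in enumerate(design.columns):
        others = np.column_stack(
            [np.ones(x.shape[0]), np.delete(x, j, axis=1)]
        )
        beta, _, _, _ = np.linalg.lstsq(others, x[:, j], rcond=None)
        resid = x[:, j] - others @ beta
        ss_tot = np.sum((x[:, j] - x[:, j].mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def _admissible(y: np.ndarray, spec: ModelSpec) -> list[tuple[str, str]]:
    """Candidate (family, transform) pairs admissible for this response,
    in tie-breaking preference order (gaussian/identity first)."""
    values = np.unique(y)
    if set(values).issubset({0.0, 1.0}):
        return [("binomial", "identity")]
    positive = bool(np.all(y > 0))
    counts = bool(np.all(y >= 0) and np.allclose(y, np.round(y)))
    cands: list[tuple[str, str]] = []
    if "gaussian" in spec.families:
        for t in spec.transforms:
            if t == "identity" or positive:
                cands.append(("gaussian", t))
    if "poisson" in spec.families and counts:
        cands.append(("poisson", "identity"))
    for fam in ("gamma", "inverse_gaussian"):
        if fam in spec.families and positive:
            cands.append((fam, "identity"))
    return cands


def fit_glm(
    spec: ModelSpec,
    data: pd.DataFrame,
    family: str | None = None,
    transform: str = "identity",
) -> GlmResult:
    """Maximum-likelihood GLM fit with diagnostics.

    When ``family`` is None the AIC-best admissible (family, transform)
    pair is selected first.  The overall model test compares the fitted
    model with the intercept-only model: an F-test for Gaussian
    responses, a likelihood-ratio chi-square otherwise.
    """
    work = data.dropna(subset=_columns_used(spec)).copy()
    if family is None:
        family, transform, _ = select_family_and_transform(work, spec)
    y = work[spec.response].to_numpy(dtype=float)
    fwd, log_jac = _TRANSFORMS[transform]
    if transform != "identity" and np.any(y <= 0):
        raise ValueError(f"{transform} transform requires positive response")
    work["_y"] = fwd(y)
    formula = spec.formula.replace(f"{spec.response} ~", "_y ~", 1)
    fam = _FAMILIES[family]()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.glm(formula, data=work, family=fam)
        _check_full_rank(model)
        res = model.fit()
        null = smf.glm("_y ~ 1", data=work, family=fam).fit()
    df_model = int(res.df_model)
    df_resid = int(res.df_resid)
    if family == "gaussian":
        num = (null.deviance - res.deviance) / df_model
        den = res.deviance / df_resid
        overall = float(num / den) if den > 0 else np.inf
        overall_p = float(scipy.stats.f.sf(overall, df_model, df_resid))
    else:
        overall = float(2.0 * (res.llf - null.llf))
        overall_p = float(scipy.stats.chi2.sf(overall, df_model))
    coef = pd.DataFrame(
        {
            "term": res.params.index,
            "estimate": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "stat": res.tvalues.to_numpy(),
            "p": res.pvalues.to_numpy(),
        }
    )
    exog = pd.DataFrame(
        model.exog, columns=model.exog_names, index=work.index
    ).drop(columns="Intercept", errors="ignore")
    vifs = vif(exog) if exog.shape[1] >= 2 else pd.Series(1.0, index=exog.columns)
    resid = np.asarray(res.resid_deviance, dtype=float)
    shapiro_p = float(scipy.stats.shapiro(resid).pvalue) if len(resid) >= 3 else np.nan
    aic = float(res.aic)
    if family == "gaussian" and transform != "identity":
        aic -= 2.0 * float(np.sum(log_jac(y)))
    return GlmResult(
        spec=spec,
        family=family,
        transform=transform,
        coefficients=coef,
        overall_stat=overall,
        overall_df=(df_model, df_resid),
        overall_p=overall_p,
        overall_p_corrected=correct_p(overall_p, spec.bonferroni_m),
        aic=aic,
        vif=vifs,
        shapiro_p=shapiro_p,
        accepted=bool(np.all(np.isfinite(vifs)) and np.all(vifs < 5)),
        n_obs=int(res.nobs),
    )


def _columns_used(spec: ModelSpec) -> list[str]:
    cols = {spec.response, *spec.covariates}
    for term in spec.predictors:
        for part in term.replace("*", ":").split(":"):
            cols.add(part.strip())
    return list(cols)


def _check_full_rank(model) -> None:
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        _, r = np.linalg.qr(exog)
        aliased = [
            model.exog_names[i]
            for i in range(exog.shape[1])
            if abs(r[i, i]) < 1e-10 * abs(r[0, 0])
        ]
        raise ValueError(f"design is rank deficient; aliased terms: {aliased}")


def select_family_and_transform(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[str, str, pd.DataFrame]:
    """AIC-minimising (family, transform) among admissible candidates.

    Every candidate is fitted on the full model; dichotomous responses
    force the binomial family.  Ties (within 1e-9) are broken toward
    the earlier candidate in preference order, i.e. gaussian/identity.
    Raises if every candidate fails, listing the per-candidate reasons.
    """
    work = data.dropna(subset=_columns_used(spec))
    if len(work) < 10:
        raise ValueError("need at least 10 complete observations")
    y = work[spec.response].to_numpy(dtype=float)
    candidates = _admissible(y, spec)
    rows, errors = [], {}
    best: tuple[str, str] | None = None
    best_aic = np.inf
    for fam, transform in candidates:
        try:
            res = fit_glm(spec, work, family=fam, transform=transform)
        except Exception as exc:  # noqa: BLE001 - reported to the caller
            errors[(fam, transform)] = str(exc)
            continue
        rows.append(
            {"family": fam, "transform": transform, "aic": res.aic}
        )
        if res.aic < best_aic - 1e-9:
            best_aic = res.aic
            best = (fam, transform)
    if best is None:
        raise ValueError(f"all candidate fits failed: {errors}")
    return best[0], best[1], pd.DataFrame(rows)


STATE_METRIC_CLASSES = ("mean_dwell_seconds", "fraction_of_time", "n_visits")


def interaction_scan(
    cohort: pd.DataFrame,
    metrics: pd.DataFrame,
    k: int,
    transitions: pd.DataFrame | None = None,
    response: str = "severity_6mo",
    ei_col: str = "emotional_instability",
    covariates: tuple[str, ...] = COVARIATES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One EI-by-metric GLM per dynamic measure, Bonferroni per class.

    ``metrics`` is the tidy per-subject-per-state table from
    :func:`dynstates.state_metrics.cohort_state_summary`;
    ``transitions`` the long-format per-subject transition table.
    State-specific measures form families of size ``k``, specific
    transition probabilities of size ``k * k``, and the total number of
    transitions a family of 1.  Returns one row per fitted model with
    the overall test, corrected p, and the EI, metric and interaction
    coefficients.
    """
    unmatched = sorted(
        set(metrics["subject_id"]) - set(cohort["subject_id"])
    )
    if unmatched:
        raise ValueError(f"metrics subjects missing from cohort: {unmatched}")
    base = cohort.set_index("subject_id")
    rows = []

    def run(metric_values: pd.Series, label: dict, m: int) -> None:
        data = base.loc[
            metric_values.index, [response, ei_col, *covariates]
        ].copy()
        data["ei"] = data[ei_col]
        data["metric"] = metric_values.to_numpy(dtype=float)
        data = data.dropna()
        spec = ModelSpec(
            response=response,
            predictors=["ei * metric"],
            covariates=covariates,
            bonferroni_m=m,
        )
        try:
            res = fit_glm(spec, data)
        except ValueError as exc:
            rows.append({**label, "error": str(exc)})
            return
        coef = res.coefficients.set_index("term")

        def grab(term: str, what: str) -> float:
            match = [t for t in coef.index if t.replace(" ", "") == term]
            return float(coef.loc[match[0], what]) if match else np.nan

        rows.append(
            {
                **label,
                "family": res.family,
                "transform": res.transform,
                "bonferroni_m": m,
                "n_obs": res.n_obs,
                "overall_stat": res.overall_stat,
                "overall_p": res.overall_p,
                "overall_p_corrected": res.overall_p_corrected,
                "significant": res.overall_p < bonferroni_threshold(alpha, m),
                "ei_estimate": grab("ei", "estimate"),
                "ei_p": grab("ei", "p"),
                "metric_estimate": grab("metric", "estimate"),
                "metric_p": grab("metric", "p"),
                "interaction_estimate": grab("ei:metric", "estimate"),
                "interaction_stat": grab("ei:metric", "stat"),
                "interaction_p": grab("ei:metric", "p"),
                "vif_max": float(res.vif.max()),
                "accepted": res.accepted,
            }
        )

    for metric_class in STATE_METRIC_CLASSES:
        for state in range(1, k + 1):
            sub = metrics[metrics["state"] == state].set_index("subject_id")
            run(
                sub[metric_class],
                {"metric_class": metric_class, "metric": f"state{state}"},
                m=k,
            )
    totals = metrics.drop_duplicates("subject_id").set_index("subject_id")
    run(
        totals["n_transitions"],
        {"metric_class": "n_transitions", "metric": "total"},
        m=1,
    )
    if transitions is not None:
        for i in range(1, k + 1):
            for j in range(1, k + 1):
                sub = transitions[
                    (transitions["from_state"] == i)
                    & (transitions["to_state"] == j)
                ].set_index("subject_id")
                run(
                    sub["probability"].dropna(),
                    {
                        "metric_class": "transition_probability",
                        "metric": f"p{i}to{j}",
                    },
                    m=k * k,
                )
    return pd.DataFrame(rows)
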