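"""Gamma log-link regression of habitual MVPA on individual and
built-environment covariates, with stratified basic models and the
measure × distance pattern tables.

The outcome (habitual MVPA, min/day) is positive and right-skewed, so it
is modeled as Gamma(shape ν, mean μ) with log μ = Xβ. Effects are
reported as exp(β̂), i.e. multiplicative changes in expected MVPA. The
shape ν is estimated by full maximum likelihood (not the Pearson moment
estimator) so the AIC is a true likelihood quantity; β̂ itself does not
depend on ν for this family/link, so the IRLS solution is the MLE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

__all__ = ["ModelSpec", "FitResult", "build_design", "fit_gamma_log",
           "fit_basic_models", "run_pattern_analysis", "descriptive_table",
           "pattern_plot", "BASIC_COVARIATES", "STRATA"]

#: basic-model covariate set; reference levels: medium ISCED, no safety
#: concerns, autumn/winter season
BASIC_COVARIATES = ["age_years", "bmi_z", "valid_weartime_h",
                    "season_spring_summer", "safety_concerns",
                    "isced_low", "isced_high"]

#: the six analysis strata: age group × (all, boys, girls)
STRATA = [("school", "all"), ("school", "boy"), ("school", "girl"),
          ("pre_school", "all"), ("pre_school", "boy"), ("pre_school", "girl")]


@dataclass
class ModelSpec:
    outcome: str = "mvpa_min_per_day"
    covariates: list = field(default_factory=lambda: list(BASIC_COVARIATES))
    exposure: str | None = None          # one exposure column, entered alone
    stratum: tuple = ("school", "all")   # (age_group, sex or "all")


@dataclass
class FitResult:
    terms: pd.DataFrame        # index: term; columns: beta, exp_beta, se, p
    shape: float
    loglik: float
    aic: float                 # counts the shape parameter: -2ℓ + 2(k+1)
    aic_excl_shape: float      # alternative convention: -2ℓ + 2k
    n: int
    converged: bool

    def exp_beta(self, term: str) -> float:
        return float(self.terms.loc[term, "exp_beta"])

    def p_value(self, term: str) -> float:
        return float(self.terms.loc[term, "p"])

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        """Wald CI for exp(β) of a term."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        b = self.terms.loc[term, "beta"]
        se = self.terms.loc[term, "se"]
        return (float(np.exp(b - z * se)), float(np.exp(b + z * se)))


def encode_covariates(data: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code the cohort categoricals with the study reference levels."""
    out = data.copy()
    if "season" in out and "season_spring_summer" not in out:
        out["season_spring_summer"] = (out["season"] == "spring_summer").astype(float)
    if "isced" in out and "isced_low" not in out:
        out["isced_low"] = (out["isced"] == "low").astype(float)
        out["isced_high"] = (out["isced"] == "high").astype(float)
    if "safety_concerns" in out:
        out["safety_concerns"] = pd.to_numeric(out["safety_concerns"])
    return out


def build_design(data: pd.DataFrame, spec: ModelSpec
                 ) -> tuple[np.ndarray, np.ndarray, list]:
    """Design matrix, outcome vector, and term names for one model."""
    df = encode_covariates(data)
    grp, sex = spec.stratum
    if grp != "all":
        df = df[df["age_group"] == grp]
    if sex != "all":
        df = df[df["sex"] == sex]
    terms = list(spec.covariates)
    if spec.exposure is not None:
        terms = terms + [spec.exposure]
    y = df[spec.outcome].to_numpy(dtype=float)
    keep = y > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} records with non-positive MVPA "
                      "(gamma likelihood requires positivity)", stacklevel=2)
    X = np.column_stack([np.ones(len(df))] +
                        [df[t].to_numpy(dtype=float) for t in terms])
    return X[keep], y[keep], ["intercept"] + terms


def gamma_loglik(y: np.ndarray, mu: np.ndarray, nu: float) -> float:
    """Gamma log-likelihood with shape ν and mean μ."""
    return float(np.sum(nu * np.log(nu / mu) - special.gammaln(nu)
                        + (nu - 1.0) * np.log(y) - nu * y / mu))


def _ml_shape(y: np.ndarray, mu: np.ndarray) -> float:
    """ML estimate of the gamma shape given fitted means.

    Solves log ν + 1 − ψ(ν) = D with D = mean(log μ − log y + y/μ); the
    left side decreases from ∞ to 1, and D ≥ 1 with equality only for a
    perfect fit, where the shape is unbounded.
    """
    D = float(np.mean(np.log(mu) - np.log(y) + y / mu))
    g = lambda lognu: lognu + 1.0 - special.digamma(np.exp(lognu)) - D
    lo, hi = -10.0, 20.0
    if g(hi) >= 0:   # D at (or below) its degenerate lower bound of 1
        return float(np.exp(hi))
    return float(np.exp(optimize.brentq(g, lo, hi)))


def fit_gamma_log(spec: ModelSpec, data: pd.DataFrame,
                  maxiter: int = 100) -> FitResult:
    """Maximum-likelihood gamma log-link fit with Wald inference.

    β̂ comes from IRLS (statsmodels GLM); ν̂ by 1-D ML given μ̂; Wald
    standard errors use the ML dispersion, cov(β̂) = (XᵀX)⁻¹ / ν̂ for this
    family/link. AIC is reported under both shape-counting conventions.
    """
    X, y, terms = build_design(data, spec)
    if len(y) < 10 * len(terms):
        warnings.warn(f"n = {len(y)} is small for {len(terms)} terms",
                      stacklevel=2)
    model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=maxiter, tol=1e-12)
    converged = bool(getattr(res, "converged", True))
    beta = np.asarray(res.params)
    mu = np.exp(X @ beta)
    nu = _ml_shape(y, mu)
    ll = gamma_loglik(y, mu, nu)
    cov = np.asarray(res.normalized_cov_params) / nu
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    k = len(beta)
    tbl = pd.DataFrame({"beta": beta, "exp_beta": np.exp(beta),
                        "se": se, "p": p}, index=terms)
    return FitResult(terms=tbl, shape=nu, loglik=ll,
                     aic=-2.0 * ll + 2.0 * (k + 1),
                     aic_excl_shape=-2.0 * ll + 2.0 * k,
                     n=len(y), converged=converged)


def fit_basic_models(cohort: pd.DataFrame,
                     strata: list | None = None) -> dict:
    """The six stratified basic models (age group × all/boys/girls)."""
    out = {}
    for stratum in (strata or STRATA):
        spec = ModelSpec(stratum=stratum)
        out[stratum] = fit_gamma_log(spec, cohort)
    return out


def basic_models_table(fits: dict) -> pd.DataFrame:
    """Long-format report of the basic-model fits (one row per term)."""
    rows = []
    for (grp, sex), fit in fits.items():
        for term, r in fit.terms.iterrows():
            rows.append({"age_group": grp, "sex": sex, "term": term,
                         "exp_beta": r["exp_beta"], "p": r["p"],
                         "aic": fit.aic, "n": fit.n})
    return pd.DataFrame(rows)


def run_pattern_analysis(cohort: pd.DataFrame, exposures: pd.DataFrame,
                         strata: list | None = None,
                         measures: list | None = None,
                         distances: list | None = None,
                         layers: list | None = None) -> pd.DataFrame:
    """Fit one exposure-augmented model per (layer, measure, distance,
    stratum) cell and assemble the pattern table.

    ``exposures`` is the tidy exposure matrix (child_id, kind, measure,
    distance_m, value). Non-converged cells are recorded with NaN entries,
    never silently dropped.
    """
    measures = measures or sorted(exposures["measure"].unique())
    distances = distances or sorted(exposures["distance_m"].unique())
    layers = layers or sorted(exposures["kind"].unique())
    strata = strata or STRATA
    rows = []
    for kind in layers:
        for measure in measures:
            for dist in distances:
                sub = exposures[(exposures["kind"] == kind)
                                & (exposures["measure"] == measure)
                                & (exposures["distance_m"] == dist)]
                merged = cohort.merge(
                    sub[["child_id", "value"]].rename(
                        columns={"value": "exposure_value"}),
                    on="child_id", how="inner")
                for stratum in strata:
                    spec = ModelSpec(exposure="exposure_value",
                                     stratum=stratum)
                    row = {"kind": kind, "measure": measure,
                           "distance_m": dist, "age_group": stratum[0],
                           "sex": stratum[1]}
                    try:
                        fit = fit_gamma_log(spec, merged)
                        if not fit.converged:
                            raise RuntimeError("IRLS did not converge")
                        row.update(exp_beta=fit.exp_beta("exposure_value"),
                                   p=fit.p_value("exposure_value"),
                                   aic=fit.aic, n=fit.n, converged=True)
                    except Exception as exc:  # recorded, not dropped
                        row.update(exp_beta=np.nan, p=np.nan, aic=np.nan,
                                   n=len(merged), converged=False,
                                   error=str(exc))
                    rows.append(row)
    return pd.DataFrame(rows)


def descriptive_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) for continuous and n (%) for categorical variables, by the
    six strata; percentages are within-stratum."""
    cont = ["mvpa_min_per_day", "age_years", "bmi_z", "valid_weartime_h"]
    cat = {"isced": ["low", "medium", "high"],
           "safety_concerns": [0, 1],
           "season": ["autumn_winter", "spring_summer"]}
    rows = []
    for grp, sex in STRATA:
        sub = cohort[cohort["age_group"] == grp]
        if sex != "all":
            sub = sub[sub["sex"] == sex]
        n = len(sub)
        for v in cont:
            rows.append({"age_group": grp, "sex": sex, "variable": v,
                         "level": "", "mean": sub[v].mean(),
                         "sd": sub[v].std(ddof=1), "n": n, "pct": np.nan})
        for v, levels in cat.items():
            for lv in levels:
                cnt = int((sub[v] == lv).sum())
                rows.append({"age_group": grp, "sex": sex, "variable": v,
                             "level": str(lv), "mean": np.nan, "sd": np.nan,
                             "n": cnt, "pct": 100.0 * cnt / n if n else np.nan})
    return pd.DataFrame(rows)


def pattern_plot(pattern: pd.DataFrame, kind: str, stratum: tuple,
                 out_path=None):
    """Three-panel pattern figure (exp(β̂), p, AIC vs network-distance, one
    line per intensity measure) for one layer and stratum."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = pattern[(pattern["kind"] == kind)
                  & (pattern["age_group"] == stratum[0])
                  & (pattern["sex"] == stratum[1])]
    fig, axes = plt.subplots(3, 1, figsize=(6, 9), sharex=True)
    for measure, g in sub.groupby("measure"):
        g = g.sort_values("distance_m")
        axes[0].plot(g["distance_m"], g["exp_beta"], marker="o", label=measure)
        axes[1].plot(g["distance_m"], g["p"], marker="o", label=measure)
        axes[2].plot(g["distance_m"], g["aic"], marker="o", label=measure)
    axes[0].axhline(1.0, color="grey", lw=0.5)
    axes[0].set_ylabel(r"$\exp(\hat\beta)$")
    axes[1].axhline(0.05, color="grey", lw=0.5)
    axes[1].set_ylabel("p value")
    axes[1].set_yscale("log")
    axes[2].set_ylabel("AIC")
    axes[2].set_xlabel("network distance (m)")
    axes[0].set_title(f"{kind} — {stratum[0]} / {stratum[1]}")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
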