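"""Mixed-effects models for log acceleration and log migration speed.

Acceleration, per zone stratum: ``log(accel) ~ circadian * tidal + sex``
in the tidal zone (tidal phase is unavailable elsewhere, so transition
and non-tidal strata use ``log(accel) ~ circadian + sex``), with random
intercepts for receiver nested within tag. Migration speed:
``log(speed) ~ sex * tidal_class`` with crossed random intercepts for
tag and receiver. Fixed terms are pruned by stepwise backward selection
on AIC (interactions before their main effects), followed by Wald
omnibus tests, pairwise contrasts (Tukey-adjusted for the 3-level tidal
class in the speed model) and back-transformed geometric group means.

Residuals are fitted as independent: the numerical stack has no exact
AR1-within-group residual correlation for this random structure. This is
reported in every FitResult (``residual_correlation = "independent"``).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import build_design_matrices
from scipy import stats
import statsmodels.formula.api as smf

from ebbtrack.core_data import AnalysisConfig
from ebbtrack.tides import UNAVAILABLE

logger = logging.getLogger(__name__)

Z975 = stats.norm.ppf(0.975)


@dataclass
class FitResult:
    stratum: str
    response: str
    formula: str
    retained_terms: list[str]
    selection_path: list[dict]
    aic: float
    n_obs: int
    n_groups: int
    coef: pd.DataFrame
    omnibus: pd.DataFrame
    contrasts: pd.DataFrame
    group_means: pd.DataFrame
    residual_correlation: str = "independent"
    notes: list[str] = field(default_factory=list)


def _aic(res) -> float:
    # scale (residual variance) is profiled out of params; +1 restores it
    return float(-2.0 * res.llf + 2.0 * (len(res.params) + 1))


def _fit_lmm(data: pd.DataFrame, response: str, fe_terms: list[str], random: str):
    rhs = " + ".join(fe_terms) if fe_terms else "1"
    formula = f"{response} ~ {rhs}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if random == "nested":
            model = smf.mixedlm(
                formula, data, groups=data["tag_id"], re_formula="1",
                vc_formula={"receiver": "0 + C(receiver_id)"},
            )
        elif random == "crossed":
            model = smf.mixedlm(
                formula, data.assign(_one=1), groups="_one", re_formula="0",
                vc_formula={"tag": "0 + C(tag_id)", "receiver": "0 + C(receiver_id)"},
            )
        elif random == "tag_only":
            model = smf.mixedlm(formula, data, groups=data["tag_id"], re_formula="1")
        else:
            raise ValueError(random)
        res = model.fit(reml=False, method="lbfgs", maxiter=500, disp=False)
    return res


def _fit_with_fallback(data, response, fe_terms, random):
    try:
        res = _fit_lmm(data, response, fe_terms, random)
        if np.all(np.isfinite(res.fe_params)) and np.isfinite(res.llf):
            return res, random
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("mixed fit failed (%s); simplifying random structure", exc)
    res = _fit_lmm(data, response, fe_terms, "tag_only")
    logger.warning("refit with tag-only random intercept (singular full structure)")
    return res, "tag_only"


def _is_droppable(term: str, current: list[str]) -> bool:
    """A main effect cannot leave while one of its interactions remains."""
    if ":" in term:
        return True
    return not any(":" in t and term in t.split(":") for t in current)


def backward_select(
    data: pd.DataFrame, response: str, terms: list[str], random: str
) -> tuple[list[str], object, list[dict], str]:
    """Stepwise backward selection on AIC over fixed terms."""
    current = list(terms)
    best, random_used = _fit_with_fallback(data, response, current, random)
    path = [{"terms": " + ".join(current) or "1", "aic": _aic(best), "action": "start"}]
    while True:
        trials = []
        for term in [t for t in current if _is_droppable(t, current)]:
            reduced = [t for t in current if t != term]
            try:
                res, _ = _fit_with_fallback(data, response, reduced, random_used)
            except (np.linalg.LinAlgError, ValueError):
                continue
            trials.append((_aic(res), term, res))
        if not trials:
            break
        trials.sort(key=lambda x: x[0])
        if trials[0][0] < _aic(best) - 1e-9:
            aic_new, dropped, best = trials[0]
            current.remove(dropped)
            path.append(
                {"terms": " + ".join(current) or "1", "aic": aic_new, "action": f"drop {dropped}"}
            )
        else:
            break
    return current, best, path, random_used


def _fe_cov(res) -> pd.DataFrame:
    cov = res.cov_params()
    names = list(res.fe_params.index)
    return cov.loc[names, names]


def _coef_table(res) -> pd.DataFrame:
    cov = _fe_cov(res)
    se = np.sqrt(np.diag(cov))
    est = res.fe_params.to_numpy()
    return pd.DataFrame(
        {
            "term": list(res.fe_params.index),
            "estimate": est,
            "se": se,
            "ci_lo": est - Z975 * se,
            "ci_hi": est + Z975 * se,
        }
    )


def _omnibus(res, terms: list[str]) -> pd.DataFrame:
    """Wald chi-squared test per retained fixed term."""
    di = res.model.data.design_info
    cov = _fe_cov(res).to_numpy()
    fe = res.fe_params.to_numpy()
    names = list(res.fe_params.index)
    rows = []
    for term in terms:
        cols = [i for i, nm in enumerate(names) if _belongs_to_term(nm, term, di)]
        if not cols:
            continue
        b = fe[cols]
        V = cov[np.ix_(cols, cols)]
        chi2 = float(b @ np.linalg.solve(V, b))
        df = len(cols)
        rows.append(
            {"term": term, "chi2": chi2, "df": df, "p": float(stats.chi2.sf(chi2, df))}
        )
    return pd.DataFrame(rows, columns=["term", "chi2", "df", "p"])


def _belongs_to_term(column_name: str, term: str, design_info) -> bool:
    for t, sl in design_info.term_name_slices.items():
        if t == term:
            return column_name in design_info.column_names[sl]
    return False


def _reference_grid(data: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    levels = {f: sorted(data[f].dropna().unique()) for f in factors}
    rows = list(itertools.product(*levels.values()))
    return pd.DataFrame(rows, columns=factors)


def emmeans(res, factor: str, data: pd.DataFrame, factors: list[str]):
    """Estimated marginal means of ``factor`` on the model (log) scale.

    Averages model predictions over a balanced grid of the other factors,
    ignoring random effects (population-level means).
    """
    grid = _reference_grid(data, factors)
    di = res.model.data.design_info
    X = np.asarray(build_design_matrices([di], grid)[0])
    fe = res.fe_params.to_numpy()
    cov = _fe_cov(res).to_numpy()
    lev = sorted(grid[factor].unique())
    L = np.vstack([X[(grid[factor] == lv).to_numpy()].mean(axis=0) for lv in lev])
    means = L @ fe
    V = L @ cov @ L.T
    return lev, means, V


def pairwise_contrasts(
    levels, means, V, df_resid: float, adjust: str = "none"
) -> pd.DataFrame:
    """All pairwise differences of marginal means, optionally Tukey-adjusted."""
    k = len(levels)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        d = means[i] - means[j]
        se = float(np.sqrt(max(V[i, i] + V[j, j] - 2 * V[i, j], 1e-300)))
        z = d / se
        if adjust == "tukey":
            q = abs(z) * np.sqrt(2.0)
            p = float(stats.studentized_range.sf(q, k, df_resid))
        else:
            p = float(2 * stats.norm.sf(abs(z)))
        rows.append(
            {
                "contrast": f"{levels[i]} - {levels[j]}",
                "estimate": float(d),
                "se": se,
                "stat": float(z),
                "p": p,
                "adjust": adjust,
            }
        )
    return pd.DataFrame(rows)


def _group_means_table(levels, means, V, factor: str) -> pd.DataFrame:
    se = np.sqrt(np.maximum(np.diag(V), 0.0))  # clip tiny negative numerical noise
    with np.errstate(over="ignore"):  # degenerate fits may give inf CI bounds
        return pd.DataFrame(
            {
                "factor": factor,
                "level": levels,
                "mean_log": means,
                "mean_backtransformed": np.exp(means),
                "ci_lo": np.exp(means - Z975 * se),
                "ci_hi": np.exp(means + Z975 * se),
            }
        )


def _factor_cols(terms: list[str]) -> list[str]:
    cols = set()
    for t in terms:
        for part in t.split(":"):
            cols.add(part.replace("C(", "").rstrip(")"))
    return sorted(cols)


def _build_fit_result(
    stratum, response, data, terms, random, alpha, tukey_factor=None
) -> FitResult:
    retained, res, path, random_used = backward_select(data, response, terms, random)
    omni = _omnibus(res, retained)
    factors = _factor_cols(retained)
    contrasts = []
    means_tables = []
    df_resid = max(float(len(data) - len(res.fe_params)), 2.0)
    sig_terms = set(omni.loc[omni["p"] < alpha, "term"]) if len(omni) else set()
    for f in factors:
        term = f"C({f})"
        lev, means, V = emmeans(res, f, data, factors)
        means_tables.append(_group_means_table(lev, means, V, f))
        significant = term in sig_terms or any(
            ":" in t and term in t.split(":") for t in sig_terms
        )
        adjust = "tukey" if (tukey_factor == f) else "none"
        if significant or tukey_factor == f:
            ct = pairwise_contrasts(lev, means, V, df_resid, adjust=adjust)
            ct.insert(0, "factor", f)
            contrasts.append(ct)
    notes = []
    if random_used != random:
        notes.append(f"random structure simplified to {random_used}")
    return FitResult(
        stratum=stratum,
        response=response,
        formula=f"{response} ~ {' + '.join(retained) or '1'}",
        retained_terms=retained,
        selection_path=path,
        aic=_aic(res),
        n_obs=int(len(data)),
        n_groups=int(data["tag_id"].nunique()),
        coef=_coef_table(res),
        omnibus=omni,
        contrasts=(
            pd.concat(contrasts, ignore_index=True)
            if contrasts
            else pd.DataFrame(columns=["factor", "contrast", "estimate", "se", "stat", "p", "adjust"])
        ),
        group_means=(
            pd.concat(means_tables, ignore_index=True)
            if means_tables
            else pd.DataFrame(columns=["factor", "level", "mean_log", "mean_backtransformed", "ci_lo", "ci_hi"])
        ),
        notes=notes,
    )


def fit_acceleration_models(
    sensor_obs: pd.DataFrame,
    crabs: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> dict[str, FitResult]:
    """Per-zone mixed models of log acceleration.

    Tidal zone: circadian x tidal interaction + sex; transition and
    non-tidal zones: circadian + sex (no usable tidal annotation there).
    Strata with fewer than two sensor crabs are skipped with a warning.
    """
    config = config or AnalysisConfig()
    obs = sensor_obs.dropna(subset=["accel_ms2"]).copy()
    obs = obs[obs["accel_ms2"] > 0]
    if "sex" not in obs.columns:
        obs = obs.merge(crabs[["tag_id", "sex"]], on="tag_id", how="left")
    obs["log_accel"] = np.log(obs["accel_ms2"])
    results: dict[str, FitResult] = {}
    for zone in ("non_tidal", "transition", "tidal"):
        sub = obs[obs["zone"] == zone].copy()
        if zone == "tidal":
            sub = sub[sub["tidal"] != UNAVAILABLE]
        if sub["tag_id"].nunique() < 2:
            logger.warning("zone %s: <2 sensor crabs, acceleration model skipped", zone)
            continue
        terms = ["C(circadian)"]
        if zone == "tidal":
            terms = ["C(circadian)", "C(tidal)", "C(circadian):C(tidal)"]
        if sub["sex"].nunique() > 1:
            terms.append("C(sex)")
        terms = [
            t for t in terms
            if all(sub[c].nunique() > 1 for c in _factor_cols([t]))
        ]
        results[zone] = _build_fit_result(
            zone, "log_accel", sub, terms, "nested", config.alpha
        )
    return results


def fit_speed_model(
    speeds: pd.DataFrame,
    crabs: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> FitResult:
    """Mixed model of log migration speed: sex x tidal class.

    Crossed random intercepts for tag and receiver (receivers are shared
    across tags); Tukey-adjusted pairwise contrasts between tidal classes.
    """
    config = config or AnalysisConfig()
    data = speeds.copy()
    if not config.include_upstream_speeds:
        data = data[data["direction"] == "downstream"]
    if "sex" not in data.columns:
        data = data.merge(crabs[["tag_id", "sex"]], on="tag_id", how="left")
    data = data[data["speed_km_day"] > 0].copy()
    if data["zone"].nunique() < 2:
        raise ValueError("speed records span a single zone; model not identifiable")
    data["log_speed"] = np.log(data["speed_km_day"])
    data["receiver_id"] = data["to_receiver"]
    terms = ["C(zone)"]
    if data["sex"].nunique() > 1:
        terms = ["C(sex)", "C(zone)", "C(sex):C(zone)"]
    return _build_fit_result(
        "all", "log_speed", data, terms, "crossed", config.alpha, tukey_factor="zone"
    )
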