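"""Treatment-effect inference with random-intercept linear mixed models.

The experimental unit is a bottle nested in a lake; each lake contributes
both a control and a plastic-leachate treatment, so lake identity enters
as a random intercept.  Responses (bacterial protein production or growth
efficiency) are strictly positive and right-skewed, and are natural-log
transformed before fitting; treatment effects therefore back-transform to
fold changes.

Workflow mirrors standard practice for this kind of field experiment:

1. z-score the candidate covariates and screen them for collinearity
   (|Pearson r| > 0.90 drops the less biologically relevant member);
2. fit the full model (treatment, covariate main effects and
   treatment x covariate interactions) by maximum likelihood;
3. backwards stepwise elimination: a term is dropped when keeping it
   would not lower the AIC by more than 2, respecting marginality and
   never dropping the treatment main effect;
4. refit the selected model by REML and report estimated marginal means,
   fold changes, and interaction probes at the moderator mean and +-1 SD,
   with Wald t confidence intervals on the log scale (between-within
   residual degrees of freedom, n - p - (g - 1)).

Fitting uses the profiled (RE)ML likelihood of the single-random-intercept
model: for a fixed variance ratio the fixed effects and residual variance
are closed-form GLS quantities, so only a scalar profile is optimised —
deterministic, fast, and well behaved at the zero-variance boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "LakeObservation",
    "ModelFit",
    "EffectSummary",
    "EliminationResult",
    "DEFAULT_PRIORITY",
    "observations_to_frame",
    "fit_lmm",
    "collinearity_screen",
    "backward_eliminate",
    "marginal_effects",
]

#: "Most biologically relevant first" ordering used to resolve collinear pairs.
DEFAULT_PRIORITY = ("fd", "doc", "tn", "temperature", "ph", "latitude", "shannon")

TREATMENT_TERM = "treatment"



@dataclass(frozen=True)
class LakeObservation:
    """One bottle: lake, treatment arm, positive response, lake covariates."""

    lake_id: str
    treatment: str  # 'control' or 'plastic'
    response: float
    replicate: int = 0
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.treatment not in ("control", "plastic"):
            raise ValueError(f"treatment must be 'control' or 'plastic', got {self.treatment!r}")
        if not self.response > 0:
            raise ValueError("response must be positive (log transform required)")


def observations_to_frame(observations: Sequence[LakeObservation]) -> pd.DataFrame:
    rows = []
    for obs in observations:
        row = {"lake_id": obs.lake_id, "treatment": obs.treatment,
               "replicate": obs.replicate, "response": obs.response}
        row.update(obs.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def _interaction_parts(term: str) -> tuple[str, ...]:
    return tuple(term.split(":"))


def _covariates_in(terms: Sequence[str]) -> list[str]:
    out = []
    for t in terms:
        for part in _interaction_parts(t):
            if part != TREATMENT_TERM and part not in out:
                out.append(part)
    return out


@dataclass(frozen=True)
class ModelFit:
    """A fitted random-intercept LMM on the log response scale."""

    terms: tuple[str, ...]
    params: pd.Series              # fixed effects, index = ['Intercept', *terms]
    cov_params: pd.DataFrame       # covariance of the fixed effects
    group_var: float               # random-intercept variance
    resid_var: float
    llf: float
    aic: float                     # -2 llf + 2 k, k = n fixed + 2 variance params
    objective: str                 # 'ML' or 'REML'
    n_obs: int
    n_groups: int
    covariate_stats: dict          # {name: (mean, sd)} used for z-scoring
    boundary: bool = False         # random-intercept variance at/near zero

    @property
    def k_params(self) -> int:
        return len(self.params) + 2

    @property
    def df_resid(self) -> int:
        """Between-within residual df for Wald t intervals."""
        return max(1, self.n_obs - len(self.params) - (self.n_groups - 1))


def _design_matrix(
    df: pd.DataFrame, terms: Sequence[str], covariate_stats: dict
) -> pd.DataFrame:
    cols = {"Intercept": np.ones(len(df))}
    treat = (df[TREATMENT_TERM].astype(str) == "plastic").astype(float).to_numpy()
    z = {}
    for cov, (mean, sd) in covariate_stats.items():
        z[cov] = (df[cov].to_numpy(dtype=float) - mean) / sd
    for term in terms:
        parts = _interaction_parts(term)
        col = np.ones(len(df))
        for part in parts:
            col = col * (treat if part == TREATMENT_TERM else z[part])
        cols[term] = col
    return pd.DataFrame(cols, index=df.index)


def _check_full_rank(exog: pd.DataFrame) -> None:
    x = exog.to_numpy()
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify offending columns by incremental rank growth
        bad = []
        kept: list[int] = []
        for j in range(x.shape[1]):
            if np.linalg.matrix_rank(x[:, kept + [j]]) == len(kept):
                bad.append(exog.columns[j])
            else:
                kept.append(j)
        raise ValueError(f"singular fixed-effect design; collinear columns: {bad}")


def _gls_pieces(y: np.ndarray, x: np.ndarray, groups: list[np.ndarray], lam: float):
    """Closed-form GLS quantities for V0 = I + lam * Z Z' (random intercept).

    Per group, (I + lam J)^-1 = I - c J with c = lam / (1 + lam n_i), so all
    sums are computed without forming V.  Returns (beta, rss_gls, logdet_V0,
    xtwx) where rss_gls = (y - X beta)' V0^-1 (y - X beta).
    """
    p = x.shape[1]
    xtwx = np.zeros((p, p))
    xtwy = np.zeros(p)
    ytwy = 0.0
    logdet = 0.0
    for idx in groups:
        xi, yi = x[idx], y[idx]
        ni = len(idx)
        c = lam / (1.0 + lam * ni)
        sx, sy = xi.sum(axis=0), yi.sum()
        xtwx += xi.T @ xi - c * np.outer(sx, sx)
        xtwy += xi.T @ yi - c * sx * sy
        ytwy += yi @ yi - c * sy * sy
        logdet += np.log1p(lam * ni)
    beta = np.linalg.solve(xtwx, xtwy)
    rss = float(ytwy - beta @ xtwy)
    return beta, max(rss, 1e-300), logdet, xtwx


def _profile_fit(y: np.ndarray, x: np.ndarray, group_labels: np.ndarray, reml: bool):
    """Random-intercept LMM via the profiled (RE)ML likelihood in lam.

    For fixed lam = sigma_u^2 / sigma_e^2 the fixed effects and residual
    variance have closed forms; the scalar profile is maximised over
    log(lam) by bounded minimisation, with the lam = 0 boundary checked
    explicitly.  Deterministic, and well behaved where free optimisation of
    the full likelihood becomes singular (variance at the boundary, near-
    saturated fixed designs).
    """
    n, p = x.shape
    codes, _ = pd.factorize(group_labels)
    groups = [np.nonzero(codes == g)[0] for g in range(codes.max() + 1)]
    dof = n - p if reml else n

    def neg_profile(log_lam: float) -> float:
        lam = np.exp(log_lam)
        _, rss, logdet, xtwx = _gls_pieces(y, x, groups, lam)
        sigma2 = rss / dof
        ll = -0.5 * (dof * np.log(2.0 * np.pi * sigma2) + logdet + dof)
        if reml:
            sign, logdet_x = np.linalg.slogdet(xtwx)
            ll -= 0.5 * logdet_x
        return -ll

    res = optimize.minimize_scalar(
        neg_profile, bounds=(-15.0, 10.0), method="bounded",
        options={"xatol": 1e-8},
    )
    candidates = [(neg_profile(-40.0), -40.0), (res.fun, float(res.x))]  # -40 ~ lam = 0
    fun, log_lam = min(candidates)
    lam = np.exp(log_lam)
    if log_lam <= -39.0:
        lam = 0.0
    beta, rss, logdet, xtwx = _gls_pieces(y, x, groups, lam)
    sigma2 = rss / dof
    cov_beta = sigma2 * np.linalg.inv(xtwx)
    return beta, cov_beta, lam, sigma2, -fun


def fit_lmm(
    data: pd.DataFrame | Sequence[LakeObservation],
    terms: Sequence[str] | None = None,
    response_col: str = "response",
    objective: str = "ML",
    covariate_stats: dict | None = None,
) -> ModelFit:
    """Fit log(response) ~ fixed terms + (1 | lake_id).

    ``terms`` are fixed-effect term names: 'treatment', covariate column
    names, and 'treatment:cov' interactions; the intercept is implicit.
    Covariates are z-scored (statistics estimated from the data unless
    supplied, so that refits during elimination reuse one standardisation).
    The likelihood is maximised numerically; the fit is deterministic for
    given data and objective.
    """
    if objective not in ("ML", "REML"):
        raise ValueError("objective must be 'ML' or 'REML'")
    if not isinstance(data, pd.DataFrame):
        data = observations_to_frame(data)
    if terms is None:
        terms = [TREATMENT_TERM]
    terms = list(terms)
    if data["lake_id"].nunique() < 2:
        raise ValueError("need observations from at least 2 lakes")

    covs = _covariates_in(terms)
    if covariate_stats is None:
        covariate_stats = {}
        for cov in covs:
            vals = data[cov].to_numpy(dtype=float)
            sd = float(np.std(vals, ddof=1))
            if sd == 0:
                raise ValueError(f"covariate {cov!r} is constant")
            covariate_stats[cov] = (float(np.mean(vals)), sd)

    exog = _design_matrix(data, terms, covariate_stats)
    _check_full_rank(exog)
    endog = np.log(data[response_col].to_numpy(dtype=float))

    beta, cov_beta, lam, sigma2, llf = _profile_fit(
        endog, exog.to_numpy(), data["lake_id"].to_numpy(), reml=(objective == "REML")
    )

    names = list(exog.columns)
    params = pd.Series(beta, index=names)
    cov_fe = pd.DataFrame(cov_beta, index=names, columns=names)
    group_var = float(lam * sigma2)
    resid_var = float(sigma2)
    k = len(names) + 2
    return ModelFit(
        terms=tuple(terms),
        params=params,
        cov_params=cov_fe,
        group_var=group_var,
        resid_var=resid_var,
        llf=llf,
        aic=-2.0 * llf + 2.0 * k,
        objective=objective,
        n_obs=len(data),
        n_groups=int(data["lake_id"].nunique()),
        covariate_stats=dict(covariate_stats),
        boundary=group_var <= 1e-8 * max(resid_var, 1e-12),
    )


def collinearity_screen(
    data: pd.DataFrame,
    covariates: Sequence[str],
    priority: Sequence[str] = DEFAULT_PRIORITY,
    threshold: float = 0.90,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Drop one member of each covariate pair with |Pearson r| strictly > threshold.

    The member appearing later in ``priority`` (less biologically relevant)
    is dropped; covariates absent from the priority list rank after it in
    their given order.  Returns (retained, dropped) where each dropped entry
    is (kept, dropped, r).  A pair at exactly r = 0.90 is kept whole.
    """
    if len(data) < 3:
        raise ValueError("need at least 3 observations to screen correlations")
    rank = {name: i for i, name in enumerate(priority)}
    order = sorted(covariates, key=lambda c: (rank.get(c, len(priority)), list(covariates).index(c)))
    retained: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for cov in order:
        clash = None
        for kept in retained:
            r = float(np.corrcoef(data[kept].astype(float), data[cov].astype(float))[0, 1])
            if abs(r) > threshold:
                clash = (kept, cov, r)
                break
        if clash is None:
            retained.append(cov)
        else:
            dropped.append(clash)
    # restore the caller's covariate ordering for the retained set
    retained.sort(key=lambda c: list(covariates).index(c))
    return retained, dropped


@dataclass(frozen=True)
class EliminationResult:
    """Outcome of backwards stepwise elimination."""

    final: ModelFit        # selected model, refit by REML
    ml_fit: ModelFit       # selected model under ML (the AIC-comparable fit)
    trace: tuple[dict, ...]  # one entry per elimination step


def _droppable(terms: Sequence[str]) -> list[str]:
    droppable = []
    interactions = [t for t in terms if ":" in t]
    for t in terms:
        if t == TREATMENT_TERM:
            continue  # the design variable is never eliminable
        if ":" in t:
            droppable.append(t)
        else:
            in_interaction = any(t in _interaction_parts(i) for i in interactions)
            if not in_interaction:
                droppable.append(t)
    return droppable


def backward_eliminate(
    data: pd.DataFrame,
    terms: Sequence[str],
    response_col: str = "response",
    aic_threshold: float = 2.0,
    tie_tol: float = 1e-6,
) -> EliminationResult:
    """AIC backwards elimination under ML, then a REML refit of the winner.

    At each step every droppable term (marginality respected: a main effect
    is only droppable once no retained interaction contains it; the
    treatment main effect never drops) is removed in turn and the model
    refitted.  The drop with the lowest AIC is taken provided removal does
    not raise the AIC by more than ``aic_threshold``; ties within
    ``tie_tol`` resolve to the lexicographically first term name.
    """
    current = fit_lmm(data, terms, response_col=response_col, objective="ML")
    stats = current.covariate_stats
    trace: list[dict] = []
    while True:
        candidates = []
        for term in _droppable(current.terms):
            reduced_terms = [t for t in current.terms if t != term]
            reduced = fit_lmm(data, reduced_terms, response_col=response_col,
                              objective="ML", covariate_stats=stats)
            candidates.append((term, reduced))
        if not candidates:
            break
        candidates.sort(key=lambda tr: (round(tr[1].aic / tie_tol) * tie_tol, tr[0]))
        term, best = candidates[0]
        trace.append({
            "dropped": term,
            "aic_with": current.aic,
            "aic_without": best.aic,
            "delta_aic": best.aic - current.aic,
            "candidates": {t: r.aic for t, r in candidates},
        })
        if best.aic - current.aic <= aic_threshold:
            current = best
        else:
            trace[-1]["dropped"] = None  # no drop improved enough; stop
            break
    final = fit_lmm(data, list(current.terms), response_col=response_col,
                    objective="REML", covariate_stats=stats)
    return EliminationResult(final=final, ml_fit=current, trace=tuple(trace))


@dataclass(frozen=True)
class EffectSummary:
    """Treatment means, CIs and fold change, optionally at a moderator level."""

    moderator: str | None
    level_sd: float | None          # moderator level in SD units (-1, 0, +1)
    control_mean: float
    control_ci: tuple[float, float]
    plastic_mean: float
    plastic_ci: tuple[float, float]
    fold_change: float
    fold_ci: tuple[float, float]


def _row(fit: ModelFit, treat: float, moderator: str | None, level: float) -> np.ndarray:
    x = np.zeros(len(fit.params))
    names = list(fit.params.index)
    for j, name in enumerate(names):
        if name == "Intercept":
            x[j] = 1.0
            continue
        val = 1.0
        for part in _interaction_parts(name):
            if part == TREATMENT_TERM:
                val *= treat
            elif part == moderator:
                val *= level
            else:
                val *= 0.0  # other covariates held at their (z-scored) mean
        x[j] = val
    return x


def _point_ci(fit: ModelFit, x: np.ndarray) -> tuple[float, tuple[float, float]]:
    beta = fit.params.to_numpy()
    cov = fit.cov_params.to_numpy()
    m = float(x @ beta)
    se = float(np.sqrt(x @ cov @ x))
    tcrit = float(sps.t.ppf(0.975, fit.df_resid))
    return np.exp(m), (np.exp(m - tcrit * se), np.exp(m + tcrit * se))


def marginal_effects(fit: ModelFit, moderator: str | None = None) -> list[EffectSummary]:
    """Estimated marginal means per treatment, back-transformed to the response scale.

    Covariates are held at their means (z = 0).  With a ``moderator`` the
    treatment contrast is probed at the moderator's mean and +-1 SD.  Fold
    change is exp(log-scale treatment contrast) with a Wald t 95% CI
    (between-within residual df); it equals the ratio of the
    back-transformed marginal means exactly.
    """
    if moderator is not None and moderator not in fit.covariate_stats:
        raise ValueError(f"moderator {moderator!r} is not a covariate of the fitted model")
    levels = (-1.0, 0.0, 1.0) if moderator is not None else (0.0,)
    summaries = []
    for level in levels:
        x_c = _row(fit, 0.0, moderator, level)
        x_p = _row(fit, 1.0, moderator, level)
        c_mean, c_ci = _point_ci(fit, x_c)
        p_mean, p_ci = _point_ci(fit, x_p)
        fold, fold_ci = _point_ci(fit, x_p - x_c)
        summaries.append(
            EffectSummary(
                moderator=moderator,
                level_sd=level if moderator is not None else None,
                control_mean=c_mean,
                control_ci=c_ci,
                plastic_mean=p_mean,
                plastic_ci=p_ci,
                fold_change=fold,
                fold_ci=fold_ci,
            )
        )
    return summaries
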