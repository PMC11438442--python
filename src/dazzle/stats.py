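"""Inferential layer: mixed models, likelihood-ratio tests, AIC selection and
Tukey-adjusted pairwise contrasts.

Three model families mirror the analysis design:

* **Motion strength** — linear mixed model on square-root-transformed motion
  strength with direction bin, grating size and orientation as interacting
  fixed effects and a random intercept per fish-within-trial cell.
* **Distance from the grating** — beta mixed regression (logit link, constant
  precision) on distances normalised to (0, 1), with nested random
  intercepts for fish and round-within-fish.  No Python library provides a
  beta-likelihood GLMM, so the marginal likelihood is maximised here directly
  with a Laplace approximation over the intercepts (validated against
  glmmTMB in the test suite).
* **Distance moved** — linear mixed model on ``log(moved + offset)`` with the
  same fixed/random structure; the offset is half the smallest positive
  observation when zeros are present.

Pairwise comparisons are computed from the fitted fixed effects; families of
all-pairwise comparisons among ``k`` cell means use the studentized-range
("Tukey") p-value, while one-comparison families (e.g. horizontal vs vertical
within a direction bin) need no adjustment.  Sidak adjustment is available
for arbitrary families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special, stats as sps
from scipy.special import expit, gammaln
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.numdiff import approx_fprime, approx_hess

__all__ = [
    "fit_motion_model",
    "fit_distance_model",
    "fit_movement_model",
    "BetaMixedRegression",
    "BetaMixedResult",
    "adjust_pvalues",
    "load_supplementary_motion",
    "load_supplementary_behaviour",
]


# ---------------------------------------------------------------------------
# p-value adjustment
# ---------------------------------------------------------------------------


def adjust_pvalues(
    p: np.ndarray,
    method: str = "none",
    stats: np.ndarray | None = None,
    k: int | None = None,
    df: float = 1e6,
) -> np.ndarray:
    """Familywise adjustment of contrast p-values.

    ``"tukey"`` converts the contrast t/z statistics into studentized-range
    p-values for all-pairwise comparison families among ``k`` means (the
    Tukey HSD test); ``"sidak"`` applies the Sidak step for a family of
    ``len(p)`` (or ``k``) independent comparisons; ``"none"`` passes raw
    p-values through.
    """
    p = np.asarray(p, dtype=float)
    if method == "none":
        return p.copy()
    if method == "sidak":
        m = k if k is not None else p.size
        return 1.0 - (1.0 - p) ** m
    if method == "bonferroni":
        m = k if k is not None else p.size
        return np.minimum(p * m, 1.0)
    if method == "tukey":
        if stats is None or k is None:
            raise ValueError("tukey adjustment needs the contrast statistics and k")
        if k < 2:
            raise ValueError("tukey adjustment needs k >= 2 means")
        if k == 2:
            return p.copy()  # one comparison: studentized range == two-sided t
        df = min(df, 1e6)  # scipy's studentized_range is numeric in df
        return sps.studentized_range.sf(np.sqrt(2.0) * np.abs(stats), k, df)
    raise ValueError(f"unknown adjustment method {method!r}")


def _pairs(levels):
    levels = list(levels)
    return [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------


def _factor_formula(df: pd.DataFrame, terms: list[tuple[str, bool]]) -> str:
    """Interaction formula over the terms with >= 2 levels.

    ``terms`` is a list of ``(column, categorical)``; single-level columns are
    dropped (they would make the design singular).
    """
    keep = []
    for col, cat in terms:
        if cat and df[col].nunique() < 2:
            continue
        keep.append(f"C(Q('{col}'))" if cat else f"Q('{col}')")
    if not keep:
        return "1"
    return " * ".join(keep)


def _cell_row(design_info, **values) -> np.ndarray:
    frame = pd.DataFrame({k: [v] for k, v in values.items()})
    (mat,) = patsy.build_design_matrices([design_info], frame)
    return np.asarray(mat)[0]


# ---------------------------------------------------------------------------
# linear mixed models (motion strength, distance moved)
# ---------------------------------------------------------------------------


@dataclass
class LmmContrastResult:
    """Fitted LMM plus its likelihood-ratio test and contrast tables."""

    result: object
    lrt: dict
    contrasts: pd.DataFrame
    converged: bool
    aic_table: pd.DataFrame | None = None
    offset: float = 0.0

    def n_significant(self, alpha: float = 0.05, family: str | None = None) -> pd.Series:
        """Count significant contrasts per grating size (optionally one family)."""
        tab = self.contrasts
        if family is not None:
            tab = tab[tab["family"] == family]
        return tab.groupby("grating_size", dropna=False).apply(
            lambda g: int((g["p_adj"] < alpha).sum()), include_groups=False
        )


def _fit_mixedlm(formula: str, df: pd.DataFrame, group_col: str, reml: bool,
                 inner_col: str | None = None):
    vc = None
    if inner_col is not None and df.groupby(group_col)[inner_col].nunique().max() > 1:
        vc = {"inner": f"0 + C({inner_col})"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            formula, groups=df[group_col], vc_formula=vc, re_formula="1", data=df
        )
        try:
            res = model.fit(reml=reml, method="lbfgs", maxiter=500)
            if not res.converged:
                res = model.fit(reml=reml, maxiter=500)
        except Exception:
            res = model.fit(reml=reml, maxiter=500)
    return res


def _lmm_machinery(
    df: pd.DataFrame,
    response: str,
    group_col: str,
    factors: list[tuple[str, bool]],
    contrast_plan: list[dict],
    alpha: float,
    with_time_model: bool = False,
    time_col: str = "bin_index",
    inner_col: str | None = None,
):
    """Shared LMM fit + LRT + contrasts used by the motion and movement models."""
    fixed = _factor_formula(df, factors)
    formula = f"{response} ~ {fixed}"
    res = _fit_mixedlm(formula, df, group_col, reml=True, inner_col=inner_col)

    # LRT for the highest-order interaction: full vs additive-only, by ML.
    aic_table = None
    if "*" in fixed:
        reduced = fixed.replace("*", "+")
        full_ml = _fit_mixedlm(formula, df, group_col, reml=False, inner_col=inner_col)
        red_ml = _fit_mixedlm(f"{response} ~ {reduced}", df, group_col, reml=False, inner_col=inner_col)
        lr = 2.0 * (full_ml.llf - red_ml.llf)
        ddf = full_ml.params.size - red_ml.params.size
        lrt = {"statistic": float(lr), "df": int(ddf), "p": float(sps.chi2.sf(lr, ddf))}
        aic_table = pd.DataFrame(
            {
                "model": [fixed, reduced],
                "aic": [float(full_ml.aic), float(red_ml.aic)],
                "llf": [float(full_ml.llf), float(red_ml.llf)],
                "k": [int(full_ml.params.size), int(red_ml.params.size)],
            }
        )
    else:
        lrt = {"statistic": np.nan, "df": 0, "p": np.nan}
    if with_time_model:
        fixed_t = f"({fixed}) * {time_col}" if fixed != "1" else time_col
        full_t = _fit_mixedlm(f"{response} ~ {fixed_t}", df, group_col, reml=False, inner_col=inner_col)
        base_ml = _fit_mixedlm(formula, df, group_col, reml=False, inner_col=inner_col)
        lr = 2.0 * (full_t.llf - base_ml.llf)
        ddf = full_t.params.size - base_ml.params.size
        aic_table = pd.DataFrame(
            {
                "model": [f"{fixed_t}", fixed],
                "aic": [float(full_t.aic), float(base_ml.aic)],
                "llf": [float(full_t.llf), float(base_ml.llf)],
                "k": [int(full_t.params.size), int(base_ml.params.size)],
            }
        )
        lrt = {
            "statistic": float(lr), "df": int(ddf), "p": float(sps.chi2.sf(lr, ddf)),
            "comparison": "time interaction",
        }

    design_info = res.model.data.design_info
    k_fe = len(design_info.column_names)
    beta = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
    df_resid = max(len(df) - k_fe, 1)

    rows = []
    for plan in contrast_plan:
        rows.extend(
            _planned_contrasts(design_info, beta, cov, df_resid, plan, alpha)
        )
    contrasts = pd.DataFrame(rows)
    return LmmContrastResult(
        result=res, lrt=lrt, contrasts=contrasts, converged=bool(res.converged),
        aic_table=aic_table,
    )


def _planned_contrasts(design_info, beta, cov, df_resid, plan, alpha):
    """Evaluate one family plan: pairwise over `across` within each `within` cell."""
    across = plan["across"]          # column name varied within the family
    within = plan["within"]          # dict column -> list of fixed values
    levels = plan["levels"]
    fill = plan.get("fill", {})      # remaining columns pinned to a reference
    adjust = plan.get("adjust", "tukey" if len(levels) > 2 else "none")
    family = plan["family"]

    rows = []
    within_cols = list(within)
    for cell in _grid(within):
        ests, ses, tstats, praw, names = [], [], [], [], []
        for a, b in _pairs(levels):
            va = {**fill, **dict(zip(within_cols, cell)), across: a}
            vb = {**fill, **dict(zip(within_cols, cell)), across: b}
            c = _cell_row(design_info, **va) - _cell_row(design_info, **vb)
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            t = est / se if se > 0 else np.nan
            ests.append(est)
            ses.append(se)
            tstats.append(t)
            praw.append(2.0 * sps.t.sf(abs(t), df_resid) if np.isfinite(t) else np.nan)
            names.append(f"{a} - {b}")
        padj = adjust_pvalues(
            np.array(praw), adjust, stats=np.array(tstats), k=len(levels), df=df_resid
        )
        for name, est, se, t, pr, pa in zip(names, ests, ses, tstats, praw, padj):
            row = {
                "family": family,
                "contrast": name,
                "estimate": est,
                "se": se,
                "statistic": t,
                "p_raw": pr,
                "p_adj": float(pa),
            }
            row.update(dict(zip(within_cols, cell)))
            rows.append(row)
    return rows


def _grid(within: dict) -> list[tuple]:
    cells = [()]
    for col, values in within.items():
        cells = [c + (v,) for c in cells for v in values]
    return cells


def fit_motion_model(
    data: pd.DataFrame,
    alpha: float = 0.05,
    adjust_by_direction: str = "none",
) -> LmmContrastResult:
    """Linear mixed model for directional motion strength.

    ``data`` must carry ``strength, direction_bin, grating_size, orientation,
    fish_id, trial_id``.  The response is ``sqrt(strength)``; fixed effects
    are the full interaction of direction bin, grating size and orientation
    (factors with a single level are dropped automatically); the random
    intercept is per fish-within-trial cell.  Returns the REML fit, the ML
    likelihood-ratio test of the highest-order interaction, and the
    per-direction horizontal-vs-vertical contrast table within each grating
    size (``adjust_by_direction`` sets the familywise correction across the
    direction bins; the default ``"none"`` matches per-direction pairwise
    comparison semantics).
    """
    required = {"strength", "direction_bin", "grating_size", "orientation", "fish_id", "trial_id"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"motion table is missing columns: {sorted(missing)}")
    if data["orientation"].nunique() < 2:
        raise ValueError("need both grating orientations to contrast them")
    if data["fish_id"].nunique() < 2:
        raise ValueError("need at least 2 fish")
    if np.any(data["strength"] < 0):
        raise ValueError("motion strength must be non-negative")

    df = data.copy()
    df["sqrt_strength"] = np.sqrt(df["strength"])
    df["_group"] = df["trial_id"].astype(str) + ":" + df["fish_id"].astype(str)

    sizes = sorted(df["grating_size"].unique())
    directions = sorted(df["direction_bin"].unique())
    orientations = sorted(df["orientation"].unique())
    plan = [
        {
            "family": "orientation_within_direction",
            "across": "orientation",
            "levels": orientations,
            "within": {"direction_bin": directions, "grating_size": sizes},
            "adjust": adjust_by_direction if adjust_by_direction != "none" else "none",
        }
    ]
    out = _lmm_machinery(
        df,
        "sqrt_strength",
        "_group",
        [("direction_bin", True), ("grating_size", True), ("orientation", True)],
        plan,
        alpha,
    )
    if not out.converged:
        warnings.warn("motion mixed model did not fully converge; inspect result", UserWarning)
    return out


def fit_movement_model(
    data: pd.DataFrame,
    alpha: float = 0.05,
    time_col: str = "bin_index",
) -> LmmContrastResult:
    """Linear mixed model for distance moved per time bin.

    The response is ``log(moved + offset)`` where the offset is half the
    smallest positive observation when zeros are present (0 otherwise).
    Candidate fixed structures ``orientation x size x time`` and
    ``orientation x size`` are compared by ML likelihood ratio and AIC; the
    contrast table (on the reported ``orientation x size`` model) holds both
    orientation-within-size comparisons and Tukey-adjusted size-within-
    orientation comparisons.  An approximate eta-squared effect size
    (``t^2 / (t^2 + df)``) accompanies each contrast.
    """
    required = {"moved_cm", "grating_size_cm", "orientation", "fish_id", "round_id"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"behaviour table is missing columns: {sorted(missing)}")
    if np.any(data["moved_cm"] < 0):
        raise ValueError("distance moved must be >= 0")

    df = data.copy()
    moved = df["moved_cm"].to_numpy(dtype=float)
    offset = 0.0
    if np.any(moved == 0):
        positive = moved[moved > 0]
        if positive.size == 0:
            raise ValueError("all distances moved are zero; nothing to model")
        offset = float(positive.min() / 2.0)
    df["log_moved"] = np.log(moved + offset)
    df["_group"] = df["fish_id"].astype(str)
    df["_inner"] = df["round_id"].astype(str)

    sizes = sorted(df["grating_size_cm"].unique())
    orientations = sorted(df["orientation"].unique())
    plan = []
    if len(orientations) >= 2:
        plan.append(
            {
                "family": "orientation_within_size",
                "across": "orientation",
                "levels": orientations,
                "within": {"grating_size_cm": sizes},
            }
        )
    if len(sizes) >= 2:
        plan.append(
            {
                "family": "size_within_orientation",
                "across": "grating_size_cm",
                "levels": sizes,
                "within": {"orientation": orientations},
                "adjust": "tukey",
            }
        )
    out = _lmm_machinery(
        df,
        "log_moved",
        "_group",
        [("orientation", True), ("grating_size_cm", True)],
        plan,
        alpha,
        with_time_model=time_col in df.columns and df[time_col].nunique() > 1,
        time_col=time_col,
        inner_col="_inner",
    )
    out.offset = offset
    k_fe = len(out.result.model.data.design_info.column_names)
    dfr = max(len(df) - k_fe, 1)
    t2 = out.contrasts["statistic"] ** 2
    out.contrasts["eta_squared"] = t2 / (t2 + dfr)
    return out


# ---------------------------------------------------------------------------
# beta mixed regression
# ---------------------------------------------------------------------------


@dataclass
class BetaMixedResult:
    """Maximum-likelihood fit of the beta mixed regression.

    ``params`` stacks the fixed-effect coefficients, ``log(phi)`` (precision)
    and ``log(sigma)`` (random-intercept SD); ``cov`` is the inverse observed
    information at the optimum.
    """

    model: "BetaMixedRegression"
    params: np.ndarray
    cov: np.ndarray
    loglike: float
    converged: bool

    @property
    def k_fe(self) -> int:
        return self.model.exog.shape[1]

    @property
    def beta(self) -> np.ndarray:
        return self.params[: self.k_fe]

    @property
    def phi(self) -> float:
        return float(np.exp(self.params[self.k_fe]))

    @property
    def sigma_outer(self) -> float:
        return float(np.exp(self.params[self.k_fe + 1]))

    @property
    def sigma_inner(self) -> float:
        if not self.model.nested:
            return 0.0
        return float(np.exp(self.params[self.k_fe + 2]))

    @property
    def sigma(self) -> float:
        """Total random-intercept SD (outer and inner combined)."""
        return float(np.hypot(self.sigma_outer, self.sigma_inner))

    @property
    def aic(self) -> float:
        return 2.0 * self.params.size - 2.0 * self.loglike

    def population_mean(self, x_row: np.ndarray, with_se: bool = False):
        """Population-average response mean for one fixed-effect cell.

        Integrates the inverse-logit over the combined random-intercept
        distribution with Gauss-Hermite quadrature; the delta-method SE
        propagates the full parameter covariance.
        """
        x_row = np.asarray(x_row, dtype=float)

        def mean_of(params):
            eta = float(x_row @ params[: self.k_fe])
            sigma = np.exp(params[self.k_fe + 1])
            if self.model.nested:
                sigma = np.hypot(sigma, np.exp(params[self.k_fe + 2]))
            b = np.sqrt(2.0) * sigma * self.model._nodes
            return float(self.model._weights @ expit(eta + b) / np.sqrt(np.pi))

        mu = mean_of(self.params)
        if not with_se:
            return mu
        grad = approx_fprime(self.params, lambda p: np.array([mean_of(p)]), centered=True).ravel()
        se = float(np.sqrt(max(grad @ self.cov @ grad, 0.0)))
        return mu, se

    def quantile_residuals(self) -> np.ndarray:
        """Normal quantile (PIT) residuals conditional on the intercept modes.

        Under a well-specified model these are approximately standard normal;
        plot them against theoretical quantiles as a generic residual check.
        """
        self.model.loglike(self.params)  # refresh the posterior-mode cache
        offsets = np.zeros(self.model.endog.size)
        for g, mode in enumerate(self.model._mode_cache):
            rows = self.model._group_obs[g]
            offsets[rows] += mode[0]
            if self.model.nested:
                for r, cell in enumerate(self.model._group_cells[g]):
                    offsets[self.model.inner_codes == cell] += mode[1 + r]
        eta = self.model.exog @ self.beta + offsets
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        u = sps.beta.cdf(self.model.endog, mu * self.phi, (1.0 - mu) * self.phi)
        return sps.norm.ppf(np.clip(u, 1e-10, 1 - 1e-10))

    def overdispersion(self) -> float:
        """Pearson-style dispersion ratio at the posterior-mode-free plug-in
        (random intercept at 0): sum of squared Pearson residuals / residual df."""
        mu = np.clip(expit(self.model.exog @ self.beta), 1e-10, 1 - 1e-10)
        var = mu * (1.0 - mu) / (1.0 + self.phi)
        pearson = (self.model.endog - mu) ** 2 / var
        dfr = max(self.model.endog.size - self.params.size, 1)
        return float(pearson.sum() / dfr)


class BetaMixedRegression:
    """Beta regression with nested Gaussian random intercepts.

    The response ``y`` must lie strictly in (0, 1).  Conditional on an outer
    intercept ``u_g ~ N(0, sigma_outer^2)`` (e.g. fish) and an inner one
    ``w_c ~ N(0, sigma_inner^2)`` per nested cell (e.g. fish-within-round),
    ``y ~ Beta(mu * phi, (1 - mu) * phi)`` with
    ``logit(mu) = X beta + u_g + w_c``.  The intercepts are integrated out
    with a joint Laplace approximation around the per-group posterior mode
    (found by damped Newton iteration), the standard approach for GLMMs with
    non-conjugate likelihoods; parameters are then estimated by maximum
    likelihood.  When ``inner_groups`` is omitted the model collapses to a
    single intercept per group.
    """

    def __init__(self, endog, exog, groups, inner_groups=None, n_quad: int = 21):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.endog.ndim != 1 or self.exog.ndim != 2:
            raise ValueError("endog must be 1-D and exog 2-D")
        if self.endog.size != self.exog.shape[0]:
            raise ValueError("endog and exog lengths differ")
        if np.any(self.endog <= 0.0) or np.any(self.endog >= 1.0):
            raise ValueError(
                "responses must lie strictly inside (0, 1); apply the boundary squeeze first"
            )
        codes, self.group_names = pd.factorize(np.asarray(groups))
        if codes.size != self.endog.size:
            raise ValueError("groups length differs from endog")
        self.group_codes = codes
        self.n_groups = len(self.group_names)

        if inner_groups is None:
            inner = codes.copy()
        else:
            inner, _ = pd.factorize(
                pd.Series(np.asarray(groups)).astype(str)
                + ":"
                + pd.Series(np.asarray(inner_groups)).astype(str)
            )
        self.inner_codes = inner
        self.n_inner = int(inner.max()) + 1
        # outer group of each inner cell (nesting map)
        cell_outer = np.full(self.n_inner, -1, dtype=int)
        cell_outer[inner] = codes
        self._cell_outer = cell_outer
        self.nested = self.n_inner > self.n_groups
        # per-group observation and cell indices (fixed; precompute once)
        self._group_obs = [np.nonzero(codes == g)[0] for g in range(self.n_groups)]
        self._group_cells = [np.nonzero(cell_outer == g)[0] for g in range(self.n_groups)]
        # warm-start cache for the per-group posterior modes
        self._mode_cache = [np.zeros(1 + len(c)) for c in self._group_cells]

        # quadrature rule used for population-mean integration
        self._nodes, self._weights = np.polynomial.hermite.hermgauss(n_quad)
        self._log_y = np.log(self.endog)
        self._log_1my = np.log1p(-self.endog)

    @property
    def k_params(self) -> int:
        return self.exog.shape[1] + (3 if self.nested else 2)

    def _obs_loglik(self, eta: np.ndarray, idx: np.ndarray, phi: float) -> np.ndarray:
        mu = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
        a = mu * phi
        c = (1.0 - mu) * phi
        return (
            gammaln(phi) - gammaln(a) - gammaln(c)
            + (a - 1.0) * self._log_y[idx]
            + (c - 1.0) * self._log_1my[idx]
        )

    def _obs_derivs(self, eta: np.ndarray, idx: np.ndarray, phi: float):
        """First and second derivatives of the beta log-density wrt eta."""
        mu = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
        dmu = mu * (1.0 - mu)
        g = phi * (
            self._log_y[idx] - self._log_1my[idx]
            - special.digamma(mu * phi) + special.digamma((1.0 - mu) * phi)
        )
        gprime = -(phi**2) * (
            special.polygamma(1, mu * phi) + special.polygamma(1, (1.0 - mu) * phi)
        )
        d1 = g * dmu
        d2 = (gprime * dmu + g * (1.0 - 2.0 * mu)) * dmu
        return d1, d2

    def _group_laplace(self, g: int, eta: np.ndarray, phi: float,
                       var_u: float, var_w: float) -> float:
        """Laplace-approximated marginal log-likelihood of one outer group."""
        cells = self._group_cells[g]
        if self.nested:
            blocks = [np.nonzero(self.inner_codes == c)[0] for c in cells]
        else:
            blocks = [self._group_obs[g]]
        R = len(blocks) if self.nested else 0
        d = 1 + R
        v = np.resize(self._mode_cache[g], d).astype(float)

        def h_and_derivs(v):
            u = v[0]
            h = -0.5 * u * u / var_u - 0.5 * np.log(2.0 * np.pi * var_u)
            grad = np.zeros(d)
            grad[0] = -u / var_u
            hess = np.zeros((d, d))
            hess[0, 0] = -1.0 / var_u
            for r, idx in enumerate(blocks):
                w = v[1 + r] if self.nested else 0.0
                shift = eta[idx] + u + w
                h += self._obs_loglik(shift, idx, phi).sum()
                d1, d2 = self._obs_derivs(shift, idx, phi)
                s1, s2 = d1.sum(), d2.sum()
                grad[0] += s1
                hess[0, 0] += s2
                if self.nested:
                    h += -0.5 * w * w / var_w - 0.5 * np.log(2.0 * np.pi * var_w)
                    grad[1 + r] = s1 - w / var_w
                    hess[1 + r, 1 + r] = s2 - 1.0 / var_w
                    hess[0, 1 + r] = hess[1 + r, 0] = s2
            return h, grad, hess

        h, grad, hess = h_and_derivs(v)
        for _ in range(50):
            # damped Newton with ridge fallback for non-concave regions
            H = hess.copy()
            try:
                step = np.linalg.solve(H, -grad)
            except np.linalg.LinAlgError:
                step = -grad
            if not np.all(np.isfinite(step)):
                step = -grad
            lam = 1.0
            for _ in range(20):
                v_new = v + lam * step
                h_new, g_new, hess_new = h_and_derivs(v_new)
                if np.isfinite(h_new) and h_new >= h - 1e-12:
                    break
                lam *= 0.5
            else:
                break
            converged = abs(h_new - h) < 1e-10 and np.max(np.abs(g_new)) < 1e-7
            v, h, grad, hess = v_new, h_new, g_new, hess_new
            if converged:
                break
        self._mode_cache[g] = v.copy()

        neg_hess = -hess
        sign, logdet = np.linalg.slogdet(neg_hess)
        if sign <= 0:  # fall back: treat as diagonal-dominant
            logdet = float(np.log(np.abs(np.diag(neg_hess))).sum())
        return h + 0.5 * d * np.log(2.0 * np.pi) - 0.5 * logdet

    def loglike(self, params: np.ndarray) -> float:
        k = self.exog.shape[1]
        beta = params[:k]
        phi = float(np.exp(params[k]))
        sigma_u = float(np.exp(params[k + 1]))
        var_u = max(sigma_u**2, 1e-12)
        if self.nested:
            sigma_w = float(np.exp(params[k + 2]))
            var_w = max(sigma_w**2, 1e-12)
        else:
            var_w = 1e-12
        eta = self.exog @ beta
        total = 0.0
        for g in range(self.n_groups):
            total += self._group_laplace(g, eta, phi, var_u, var_w)
        return float(total)

    def _start(self) -> np.ndarray:
        z = special.logit(np.clip(self.endog, 1e-4, 1 - 1e-4))
        beta0, *_ = np.linalg.lstsq(self.exog, z, rcond=None)
        resid = z - self.exog @ beta0
        s0 = np.log(max(resid.std() / 2.0, 1e-2))
        tail = [np.log(10.0), s0] + ([s0 - 1.0] if self.nested else [])
        return np.concatenate([beta0, tail])

    def fit(self, start: np.ndarray | None = None) -> BetaMixedResult:
        x0 = self._start() if start is None else np.asarray(start, dtype=float)
        neg = lambda p: -self.loglike(p)
        k = self.exog.shape[1]
        bounds = [(None, None)] * k + [(-2.0, 12.0), (-6.0, 3.0)]
        if self.nested:
            bounds.append((-6.0, 3.0))
        opt = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 500})
        if not opt.success:  # one Nelder-Mead polish attempt
            opt2 = optimize.minimize(neg, opt.x, method="Nelder-Mead",
                                     options={"maxiter": 2000, "fatol": 1e-8})
            if opt2.fun <= opt.fun:
                opt = opt2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = approx_hess(opt.x, neg)
        try:
            cov = np.linalg.inv(hess)
            if np.any(np.diag(cov) <= 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess + 1e-8 * np.eye(hess.shape[0]))
        return BetaMixedResult(
            model=self, params=opt.x, cov=cov, loglike=-float(opt.fun),
            converged=bool(opt.success or np.isfinite(opt.fun)),
        )


@dataclass
class DistanceModelResult:
    """Beta-GLMM analysis bundle for distance-from-grating."""

    final: BetaMixedResult
    final_formula: str
    aic_table: pd.DataFrame
    lrt: dict
    contrasts: pd.DataFrame
    marginal_means: pd.DataFrame
    overdispersion: float
    design_info: object = field(repr=False, default=None)


def fit_distance_model(
    data: pd.DataFrame,
    alpha: float = 0.05,
    arena_length: float = 35.0,
    time_col: str = "bin_index",
    squeeze_n: int | None = None,
    n_quad: int = 21,
    candidate_time_model: bool = True,
) -> DistanceModelResult:
    """Beta mixed regression for normalised distance from the grating.

    ``data`` needs ``normalised_distance`` strictly inside (0, 1) plus
    ``grating_size_cm, orientation, fish_id, round_id`` (and ``bin_index``
    for the time-interaction candidate).  Two candidate fixed structures —
    ``orientation x size x time`` and ``orientation x size`` — are compared by
    AIC and likelihood ratio; contrasts and marginal means are reported from
    the ``orientation x size`` model (the smaller candidate is preferred when
    its AIC is within 2 of the larger, mirroring standard parsimony practice).

    Marginal means are population-averaged over the random intercept and
    back-transformed to cm by inverting the boundary squeeze (``squeeze_n``
    defaults to the table length) and rescaling by ``arena_length``.
    """
    required = {"normalised_distance", "grating_size_cm", "orientation", "fish_id", "round_id"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"behaviour table is missing columns: {sorted(missing)}")
    y = data["normalised_distance"].to_numpy(dtype=float)
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("normalised_distance must lie strictly in (0, 1) (squeeze first)")

    df = data.copy()
    groups = df["fish_id"].astype(str)
    inner = df["round_id"].astype(str)
    fixed = _factor_formula(df, [("orientation", True), ("grating_size_cm", True)])
    X2 = patsy.dmatrix(fixed, df, return_type="dataframe")
    design_info = X2.design_info
    m2 = BetaMixedRegression(y, X2.to_numpy(), groups, inner_groups=inner, n_quad=n_quad).fit()

    have_time = candidate_time_model and time_col in df.columns and df[time_col].nunique() > 1
    if have_time:
        df["_time"] = (df[time_col] - df[time_col].mean()) / max(df[time_col].std(), 1.0)
        fixed_t = f"({fixed}) * _time"
        X1 = patsy.dmatrix(fixed_t, df, return_type="dataframe")
        m1 = BetaMixedRegression(y, X1.to_numpy(), groups, inner_groups=inner, n_quad=n_quad).fit(
            start=np.concatenate([
                m2.params[: len(X2.columns)],
                np.zeros(len(X1.columns) - len(X2.columns)),
                m2.params[len(X2.columns):],
            ])
        )
        lr = 2.0 * (m1.loglike - m2.loglike)
        ddf = m1.params.size - m2.params.size
        lrt = {"statistic": float(lr), "df": int(ddf), "p": float(sps.chi2.sf(max(lr, 0.0), ddf)),
               "comparison": "time interaction"}
        aic_table = pd.DataFrame(
            {"model": [fixed_t, fixed], "aic": [m1.aic, m2.aic],
             "llf": [m1.loglike, m2.loglike], "k": [m1.params.size, m2.params.size]}
        )
    else:
        lrt = {"statistic": np.nan, "df": 0, "p": np.nan, "comparison": "time interaction"}
        aic_table = pd.DataFrame(
            {"model": [fixed], "aic": [m2.aic], "llf": [m2.loglike], "k": [m2.params.size]}
        )

    n_sq = squeeze_n if squeeze_n is not None else len(df)

    def to_cm(mu):
        # invert the (linear) boundary squeeze, then rescale to cm
        return (mu * n_sq - 0.5) / (n_sq - 1) * arena_length

    k_fe = len(X2.columns)
    cov_fe = m2.cov[:k_fe, :k_fe]
    sizes = sorted(df["grating_size_cm"].unique())
    orientations = sorted(df["orientation"].unique())

    # small-sample interval: t quantile on the number of independent fish
    df_fish = max(df["fish_id"].nunique() - 1, 1)
    tq = float(sps.t.ppf(0.975, df_fish))

    mm_rows = []
    for s in sizes:
        for o in orientations:
            x = _cell_row(design_info, orientation=o, grating_size_cm=s)
            mu, se = m2.population_mean(x, with_se=True)
            mm_rows.append(
                {
                    "grating_size_cm": s,
                    "orientation": o,
                    "mean_normalised": mu,
                    "mean_cm": to_cm(mu),
                    "se_cm": se * arena_length * n_sq / (n_sq - 1),
                    "ci_low_cm": to_cm(mu - tq * se),
                    "ci_high_cm": to_cm(mu + tq * se),
                }
            )
    marginal_means = pd.DataFrame(mm_rows)

    rows = []
    dfr = max(len(df) - k_fe, 1)
    if len(orientations) >= 2:
        rows += _planned_contrasts(
            design_info, m2.beta, cov_fe, dfr,
            {"family": "orientation_within_size", "across": "orientation",
             "levels": orientations, "within": {"grating_size_cm": sizes}},
            alpha,
        )
    if len(sizes) >= 2:
        rows += _planned_contrasts(
            design_info, m2.beta, cov_fe, dfr,
            {"family": "size_within_orientation", "across": "grating_size_cm",
             "levels": sizes, "within": {"orientation": orientations}, "adjust": "tukey"},
            alpha,
        )
    contrasts = pd.DataFrame(rows)

    return DistanceModelResult(
        final=m2,
        final_formula=fixed,
        aic_table=aic_table,
        lrt=lrt,
        contrasts=contrasts,
        marginal_means=marginal_means,
        overdispersion=m2.overdispersion(),
        design_info=design_info,
    )


# ---------------------------------------------------------------------------
# supplementary-data loaders (header-sniffing)
# ---------------------------------------------------------------------------

_MOTION_SYNONYMS = {
    "strength": ("strength", "motion", "magnitude", "value"),
    "direction_bin": ("direction", "angle", "vector", "bin"),
    "grating_size": ("size", "grating", "width", "spatial"),
    "orientation": ("orientation", "orient"),
    "fish_id": ("fish", "individual", "id"),
    "trial_id": ("trial", "rep", "video"),
}

_BEHAVIOUR_SYNONYMS = {
    "normalised_distance": ("norm", "scaled"),
    "distance_cm": ("distance", "dist"),
    "moved_cm": ("moved", "movement", "travel"),
    "grating_size_cm": ("size", "grating", "width"),
    "orientation": ("orientation", "orient"),
    "fish_id": ("fish", "individual", "id"),
    "round_id": ("round",),
    "bin_index": ("time", "bin", "interval"),
}


def _sniff(table: pd.DataFrame, synonyms: dict) -> pd.DataFrame:
    mapping = {}
    used = set()
    lowered = {c: str(c).strip().lower() for c in table.columns}
    for target, keys in synonyms.items():
        for col, low in lowered.items():
            if col in used:
                continue
            if any(k in low for k in keys):
                mapping[col] = target
                used.add(col)
                break
    out = table.rename(columns=mapping)
    return out


def _read_any(path) -> pd.DataFrame:
    from pathlib import Path as _P

    p = _P(path)
    if not p.exists():
        raise FileNotFoundError(
            f"supplementary data file not found: {p} (the deposited raw-data files must be "
            "downloaded separately and placed there)"
        )
    if p.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(p)
    return pd.read_csv(p)


def load_supplementary_motion(path) -> pd.DataFrame:
    """Best-effort loader for the deposited raw motion-analysis table.

    The exact column layout of the deposited file is not standardised, so the
    header is sniffed against common synonyms and mapped onto the package's
    tidy motion schema (``strength, direction_bin, grating_size, orientation,
    fish_id, trial_id``).  Raises when required columns cannot be identified.
    """
    table = _sniff(_read_any(path), _MOTION_SYNONYMS)
    required = {"strength", "direction_bin", "grating_size", "orientation", "fish_id", "trial_id"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(
            f"could not identify columns {sorted(missing)} in {path}; "
            f"found {list(table.columns)} — rename them explicitly and retry"
        )
    return table[sorted(required)].copy()


def load_supplementary_behaviour(path) -> pd.DataFrame:
    """Best-effort loader for the deposited fish-behaviour table (see
    :func:`load_supplementary_motion` for the sniffing approach)."""
    table = _sniff(_read_any(path), _BEHAVIOUR_SYNONYMS)
    required = {"grating_size_cm", "orientation", "fish_id", "round_id"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(
            f"could not identify columns {sorted(missing)} in {path}; "
            f"found {list(table.columns)} — rename them explicitly and retry"
        )
    return table.copy()
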