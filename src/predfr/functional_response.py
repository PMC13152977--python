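"""Functional-response analysis for non-replacement predation trials.

Implements three stages of the standard workflow for a depleting-prey
(non-replacement) design:

1. *Type determination* — binomial logistic regression of the proportion of
   prey consumed on initial density ``N0`` with linear and quadratic terms
   (``determine_type``). A significantly negative linear coefficient with a
   non-significant quadratic term indicates a Type II response; a
   significantly positive linear followed by a significantly negative
   quadratic term indicates Type III.

2. *Rogers random-predator fit* — maximum-likelihood estimation of attack
   rate ``a`` and handling time ``h`` under the implicit Rogers equation

       Ne = N0 * (1 - exp(a * (h * Ne - T)))

   solved explicitly via the principal branch of the Lambert W function.
   The observation model is ``consumed ~ Binomial(N0, Ne/N0)``.

3. *Flexible-exponent generalisation* — the attack rate becomes density
   dependent, ``a(N0) = b * N0**q``; ``q = 0`` recovers the pure Type II
   model exactly. Nested fits are compared by AIC, with
   ``delta_AIC = AIC(q free) - AIC(q = 0)``.

The model classes follow the Model/Results convention: build a model from
data, call :meth:`fit`, and read estimates, standard errors, log-likelihood
and AIC off the returned results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

from .io import TrialDataset

__all__ = [
    "rogers_expected",
    "RogersTypeII",
    "FlexibleTypeII",
    "FunctionalResponseResults",
    "TypeDetermination",
    "ModelComparison",
    "fit_rogers",
    "fit_flex",
    "compare_models",
    "determine_type",
    "predict_curve",
    "bootstrap_ci",
]

_PCLIP = 1e-12


def _lambertw_exp(y):
    """W(exp(y)) on the principal branch, stable for large ``y``.

    For moderate ``y`` this is scipy's ``lambertw(exp(y))``; once ``exp(y)``
    would overflow, solve ``w + log(w) = y`` by Newton iteration from the
    asymptotic start ``w0 = y - log(y)``.
    """
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    small = y <= 500.0
    if np.any(small):
        out[small] = special.lambertw(np.exp(y[small])).real
    if np.any(~small):
        yl = y[~small]
        w = yl - np.log(yl)
        for _ in range(6):  # quadratic convergence; 6 steps are plenty
            w = w - (w + np.log(w) - yl) / (1.0 + 1.0 / w)
        out[~small] = w
    return out


def rogers_expected(N0, a, h, T=1.0):
    """Expected number of prey consumed under the Rogers random-predator model.

    Solves ``Ne = N0 * (1 - exp(a * (h * Ne - T)))`` — the non-replacement
    analogue of the Holling disc equation — for the unique root
    ``Ne in [0, min(N0, T/h)]`` via the Lambert W function:

        Ne = N0 - W(a h N0 exp(a h N0 - a T)) / (a h)

    ``h = 0`` uses the closed form ``Ne = N0 * (1 - exp(-a T))`` (pure death
    process). Vectorised over ``N0``.

    Parameters
    ----------
    N0 : array_like
        Initial prey count(s), >= 0.
    a : float
        Attack rate per unit time (>= 0).
    h : float
        Handling time, same time unit as ``T`` (>= 0).
    T : float
        Trial duration (> 0), default one day.
    """
    if not np.all(np.isfinite([a, h, T])):
        raise ValueError("a, h and T must be finite")
    if a < 0 or h < 0 or T <= 0:
        raise ValueError("require a >= 0, h >= 0, T > 0")
    N0 = np.asarray(N0, dtype=float)
    if np.any(N0 < 0):
        raise ValueError("N0 must be >= 0")
    scalar = N0.ndim == 0
    N0 = np.atleast_1d(N0)
    Ne = np.zeros_like(N0)
    pos = N0 > 0
    if a == 0 or not np.any(pos):
        return float(Ne[0]) if scalar else Ne
    if h == 0:
        Ne[pos] = N0[pos] * (1.0 - np.exp(-a * T))
    else:
        n = N0[pos]
        y = np.log(a * h * n) + a * h * n - a * T
        Ne[pos] = n - _lambertw_exp(y) / (a * h)
        np.clip(Ne, 0.0, np.minimum(N0, T / h), out=Ne)
    return float(Ne[0]) if scalar else Ne


def _extract_fr_arrays(dataset: TrialDataset | pd.DataFrame):
    """(N0, consumed, T) arrays from single-stage trials or a frame."""
    if isinstance(dataset, pd.DataFrame):
        return (
            dataset["N0"].to_numpy(dtype=float),
            dataset["consumed"].to_numpy(dtype=float),
            None,
        )
    n0, con, durations = [], [], []
    for t in dataset:
        if len(t.stages) != 1:
            raise ValueError("functional-response trials must be single-stage")
        (s,) = t.stages
        n0.append(t.offered[s])
        con.append(t.consumed[s])
        durations.append(t.duration_T)
    return np.asarray(n0, float), np.asarray(con, float), np.asarray(durations, float)


@dataclass
class TypeDetermination:
    """Logistic-polynomial classification of functional-response shape.

    ``response_type`` is ``"II"``, ``"III"`` or ``"indeterminate"`` based on
    the signs/significance of the linear (``b1``) and quadratic (``b2``)
    density coefficients at the chosen alpha level.
    """

    b1: float
    b1_se: float
    b1_z: float
    b1_p: float
    b2: float
    b2_se: float
    b2_z: float
    b2_p: float
    response_type: str
    alpha: float = 0.05
    converged: bool = True
    linear_only: dict | None = None

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": [self.b1, self.b2],
                "se": [self.b1_se, self.b2_se],
                "z": [self.b1_z, self.b2_z],
                "p": [self.b1_p, self.b2_p],
            },
            index=["density", "density^2"],
        )

    def summary(self) -> str:
        lines = ["Functional-response type determination (binomial GLM, logit link)"]
        lines.append(self.coefficient_table().to_string(float_format="%.4g"))
        lines.append(f"classified type: {self.response_type} (alpha = {self.alpha})")
        if self.linear_only is not None:
            lo = self.linear_only
            lines.append(
                "linear-only model: b = %.4g +/- %.3g (z = %.3g, p = %.3g)"
                % (lo["b1"], lo["b1_se"], lo["b1_z"], lo["b1_p"])
            )
        return "\n".join(lines)


def determine_type(dataset, T: float = 1.0, alpha: float = 0.05) -> TypeDetermination:
    """Classify the functional response from proportion-consumed data.

    Fits ``logit(p) = b0 + b1*N0 + b2*N0**2`` by binomial maximum likelihood
    with the consumed/remaining pair as the response. Requires at least three
    distinct densities so the quadratic is identifiable. Non-convergence or
    complete separation yields ``response_type = "indeterminate"`` with
    ``converged = False``.

    When the quadratic term is non-significant, a reduced linear-only model
    is additionally fitted and reported in ``linear_only`` (some authors
    quote the linear coefficient from the reduced model).
    """
    n0, consumed, _ = _extract_fr_arrays(dataset)
    if len(np.unique(n0)) < 3:
        raise ValueError("need >= 3 distinct initial densities for the quadratic model")
    endog = np.column_stack([consumed, n0 - consumed])
    exog = sm.add_constant(np.column_stack([n0, n0**2]))
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        converged = bool(res.converged)
    except Exception:
        return TypeDetermination(
            b1=np.nan, b1_se=np.nan, b1_z=np.nan, b1_p=np.nan,
            b2=np.nan, b2_se=np.nan, b2_z=np.nan, b2_p=np.nan,
            response_type="indeterminate", alpha=alpha, converged=False,
        )
    b1, b2 = res.params[1], res.params[2]
    se1, se2 = res.bse[1], res.bse[2]
    z1, z2 = res.tvalues[1], res.tvalues[2]
    p1, p2 = res.pvalues[1], res.pvalues[2]

    # Type II: proportion consumed declines monotonically in density — a
    # significantly negative linear term without the sigmoidal signature.
    # A significantly *positive* quadratic only flattens the decline (the
    # exact Rogers logit has mild positive curvature, which large samples
    # resolve), so it does not overturn a Type II reading; only a
    # significantly negative quadratic does. Type III: significantly
    # positive linear followed by significantly negative quadratic.
    if not converged:
        rtype = "indeterminate"
    elif p1 < alpha and b1 < 0 and not (p2 < alpha and b2 < 0):
        rtype = "II"
    elif p1 < alpha and b1 > 0 and p2 < alpha and b2 < 0:
        rtype = "III"
    else:
        rtype = "indeterminate"

    linear_only = None
    if p2 >= alpha:
        res_lin = sm.GLM(
            endog, sm.add_constant(n0), family=sm.families.Binomial()
        ).fit()
        linear_only = {
            "b1": float(res_lin.params[1]),
            "b1_se": float(res_lin.bse[1]),
            "b1_z": float(res_lin.tvalues[1]),
            "b1_p": float(res_lin.pvalues[1]),
        }

    return TypeDetermination(
        b1=float(b1), b1_se=float(se1), b1_z=float(z1), b1_p=float(p1),
        b2=float(b2), b2_se=float(se2), b2_z=float(z2), b2_p=float(p2),
        response_type=rtype, alpha=alpha, converged=converged,
        linear_only=linear_only,
    )


@dataclass
class FunctionalResponseResults:
    """MLE results for a Rogers-family functional-response fit.

    ``params``/``bse`` are pandas Series indexed by parameter name
    (``a``, ``h`` for the Type II model; ``b``, ``q``, ``h`` for the
    flexible model). Standard errors come from the inverse numerical
    Hessian of the negative log-likelihood in the internal (log)
    parameterisation, mapped back by the delta method.
    """

    model: "RogersTypeII"
    params: pd.Series
    bse: pd.Series
    llf: float
    converged: bool
    n_restarts: int
    k_params: int
    fixed: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.llf

    @property
    def nobs(self) -> int:
        return len(self.model.N0)

    def attack_rate(self, N0) -> np.ndarray:
        """Attack rate as a function of initial density (constant for Type II)."""
        if "q" in self.params.index or "q" in self.fixed:
            b = self.params["b"]
            q = self.params.get("q", self.fixed.get("q", 0.0))
            return b * np.asarray(N0, float) ** q
        return np.full_like(np.asarray(N0, float), self.params["a"])

    def predict(self, densities) -> np.ndarray:
        """Expected prey consumed at each initial density."""
        densities = np.asarray(densities, dtype=float)
        h = self.params["h"]
        rates = self.attack_rate(densities)
        return np.array(
            [
                rogers_expected(n, a_n, h, self.model.T)
                for n, a_n in zip(densities, rates)
            ]
        )

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Wald intervals; positive parameters on the log scale, exponentiated."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        lo, hi = {}, {}
        for name in self.params.index:
            est, se = self.params[name], self.bse[name]
            if name in ("a", "b", "h") and est > 0 and np.isfinite(se):
                se_log = se / est
                lo[name] = est * np.exp(-z * se_log)
                hi[name] = est * np.exp(z * se_log)
            else:
                lo[name] = est - z * se
                hi[name] = est + z * se
        return pd.DataFrame({"lower": lo, "upper": hi})

    def summary(self) -> str:
        name = type(self.model).__name__
        tab = pd.DataFrame({"estimate": self.params, "se": self.bse})
        lines = [
            f"{name} maximum-likelihood fit (T = {self.model.T} days, "
            f"n = {self.nobs})",
            tab.to_string(float_format="%.4g"),
            f"logL = {self.llf:.4f}   AIC = {self.aic:.4f}   "
            f"converged = {self.converged}   restarts = {self.n_restarts}",
        ]
        if self.fixed:
            lines.append(f"fixed: {self.fixed}")
        return "\n".join(lines)


class RogersTypeII:
    """Type II functional-response model for a non-replacement design.

    The likelihood treats each replicate's consumed count as
    ``Binomial(N0, Ne(N0; a, h, T) / N0)`` with ``Ne`` the Rogers
    expectation. Optimisation runs on ``(ln a, ln h)`` (positivity without
    constraints; robust to the flat likelihood at low consumption) with
    multi-start from a coarse grid.
    """

    #: coarse-grid multi-start points in (a, h)
    _STARTS = [(0.5, 0.05), (2.0, 0.05), (2.0, 0.3), (8.0, 0.1), (0.5, 0.3)]

    param_names = ("a", "h")

    def __init__(self, N0, consumed, T: float = 1.0):
        self.N0 = np.asarray(N0, dtype=float)
        self.consumed = np.asarray(consumed, dtype=float)
        if self.N0.shape != self.consumed.shape:
            raise ValueError("N0 and consumed must have the same length")
        if np.any(self.consumed > self.N0) or np.any(self.consumed < 0):
            raise ValueError("require 0 <= consumed <= N0")
        if len(np.unique(self.N0)) < 2:
            raise ValueError("need >= 2 distinct initial densities")
        if not T > 0:
            raise ValueError("T must be > 0")
        self.T = float(T)
        # likelihood terms only depend on N0 through its (few) unique values
        self._uniq, self._inv = np.unique(self.N0, return_inverse=True)

    @classmethod
    def from_dataset(cls, dataset: TrialDataset, T: float | None = None):
        n0, consumed, durations = _extract_fr_arrays(dataset)
        if T is None:
            T = durations[0] if durations is not None and len(durations) else 1.0
        return cls(n0, consumed, T=T)

    # -- likelihood ---------------------------------------------------

    def _expected(self, theta) -> np.ndarray:
        a, h = np.exp(theta)
        return rogers_expected(self._uniq, a, h, self.T)[self._inv]

    def nloglik(self, theta) -> float:
        """Negative binomial log-likelihood at internal (log) parameters."""
        if not np.all(np.isfinite(theta)):
            return np.inf
        p = np.clip(self._expected(theta) / self.N0, _PCLIP, 1.0 - _PCLIP)
        r = self.consumed
        return -float(np.sum(r * np.log(p) + (self.N0 - r) * np.log1p(-p)))

    def _start_points(self):
        return [np.log(s) for s in self._STARTS]

    # -- fitting ------------------------------------------------------

    def fit(self, **kwargs) -> FunctionalResponseResults:
        """Maximise the likelihood with multi-start Nelder-Mead.

        All-zero consumption is reported as non-convergence (the attack rate
        runs to the a -> 0 boundary), never as a silent estimate.
        """
        if np.all(self.consumed == 0):
            return self._boundary_result()
        best = None
        starts = self._start_points()
        for theta0 in starts:
            res = optimize.minimize(
                self.nloglik,
                theta0,
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
            )
            if best is None or res.fun < best.fun:
                best = res
        params = pd.Series(np.exp(best.x), index=list(self.param_names))
        bse = self._standard_errors(best.x, params)
        converged = bool(best.success) and params.iloc[0] > 1e-8
        return FunctionalResponseResults(
            model=self,
            params=params,
            bse=bse,
            llf=-best.fun,
            converged=converged,
            n_restarts=len(starts),
            k_params=len(self.param_names),
        )

    def _boundary_result(self) -> FunctionalResponseResults:
        params = pd.Series(
            [0.0] * len(self.param_names), index=list(self.param_names)
        )
        bse = pd.Series(np.nan, index=list(self.param_names))
        # logL of the all-zero data at a = 0 is exactly 0 (p = 0 for every trial)
        return FunctionalResponseResults(
            model=self, params=params, bse=bse, llf=0.0,
            converged=False, n_restarts=0, k_params=len(self.param_names),
        )

    def _standard_errors(self, theta_hat, params: pd.Series) -> pd.Series:
        """Delta-method SEs from the numerical Hessian in log coordinates."""
        hess = _numerical_hessian(self.nloglik, theta_hat)
        names = list(params.index)
        try:
            cov = np.linalg.inv(hess)
            var = np.diag(cov)
            if np.any(var <= 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            return pd.Series(np.nan, index=names)
        se = np.sqrt(var)
        # d(exp x)/dx = exp x for log-scale parameters; q is already natural
        scale = np.array(
            [params[n] if n in ("a", "b", "h") else 1.0 for n in names]
        )
        return pd.Series(se * scale, index=names)


class FlexibleTypeII(RogersTypeII):
    """Flexible-exponent generalisation: ``a(N0) = b * N0**q``.

    ``q = 0`` reduces exactly to :class:`RogersTypeII` with ``a = b``, which
    makes the two models nested and AIC-comparable. ``fix_q`` pins the
    exponent (``fit(fix_q=0)`` reproduces the Type II fit).
    """

    param_names = ("b", "q", "h")

    def __init__(self, N0, consumed, T: float = 1.0):
        super().__init__(N0, consumed, T)

    def _expected_flex(self, b, q, h) -> np.ndarray:
        per_density = np.array(
            [rogers_expected(n, b * n**q, h, self.T) for n in self._uniq]
        )
        return per_density[self._inv]

    def _nloglik_flex(self, x, fix_q=None) -> float:
        if not np.all(np.isfinite(x)):
            return np.inf
        if fix_q is None:
            ln_b, q, ln_h = x
        else:
            ln_b, ln_h = x
            q = fix_q
        if abs(q) > 10:
            return np.inf
        p = np.clip(
            self._expected_flex(np.exp(ln_b), q, np.exp(ln_h)) / self.N0,
            _PCLIP,
            1.0 - _PCLIP,
        )
        r = self.consumed
        return -float(np.sum(r * np.log(p) + (self.N0 - r) * np.log1p(-p)))

    def fit(self, fix_q: float | None = None, **kwargs) -> FunctionalResponseResults:
        if np.all(self.consumed == 0):
            res = self._boundary_result()
            if fix_q is not None:
                res.k_params = 2
                res.fixed = {"q": fix_q}
                res.params = res.params.drop("q")
                res.bse = res.bse.drop("q")
            return res

        # seed the search from the nested Type II optimum
        base = RogersTypeII(self.N0, self.consumed, self.T).fit()
        a0 = max(base.params["a"], 1e-3)
        h0 = max(base.params["h"], 1e-4)

        if fix_q is not None:
            starts = [np.log([a0, h0])] + [
                np.log([a, h]) for a, h in self._STARTS
            ]
            objective = lambda x: self._nloglik_flex(x, fix_q=fix_q)
            names = ["b", "h"]
        else:
            starts = [
                np.array([np.log(a0), q0, np.log(h0)])
                for q0 in (-0.5, 0.0, 0.5)
            ] + [
                np.array([np.log(a), q0, np.log(h)])
                for (a, h), q0 in zip(self._STARTS[:2], (0.0, 1.0))
            ]
            objective = self._nloglik_flex
            names = ["b", "q", "h"]

        best = None
        for x0 in starts:
            res = optimize.minimize(
                objective,
                x0,
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 6000},
            )
            if best is None or res.fun < best.fun:
                best = res

        if fix_q is not None:
            values = [np.exp(best.x[0]), np.exp(best.x[1])]
        else:
            values = [np.exp(best.x[0]), best.x[1], np.exp(best.x[2])]
        params = pd.Series(values, index=names)
        bse = self._se_flex(best.x, params, fix_q)
        converged = bool(best.success) and params["b"] > 1e-8
        out = FunctionalResponseResults(
            model=self,
            params=params,
            bse=bse,
            llf=-best.fun,
            converged=converged,
            n_restarts=len(starts),
            k_params=len(names),
            fixed={} if fix_q is None else {"q": fix_q},
        )
        return out

    def _se_flex(self, x_hat, params, fix_q) -> pd.Series:
        objective = (
            self._nloglik_flex
            if fix_q is None
            else (lambda x: self._nloglik_flex(x, fix_q=fix_q))
        )
        hess = _numerical_hessian(objective, x_hat)
        names = list(params.index)
        try:
            cov = np.linalg.inv(hess)
            var = np.diag(cov)
            if np.any(var <= 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            return pd.Series(np.nan, index=names)
        scale = np.array([params[n] if n != "q" else 1.0 for n in names])
        return pd.Series(np.sqrt(var) * scale, index=names)


def _numerical_hessian(fun, x, step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    hess = np.empty((n, n))
    hs = step * np.maximum(1.0, np.abs(x))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = hs[i]
            ej = np.zeros(n); ej[j] = hs[j]
            if i == j:
                val = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / hs[i] ** 2
            else:
                val = (
                    fun(x + ei + ej) - fun(x + ei - ej)
                    - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4.0 * hs[i] * hs[j])
            hess[i, j] = hess[j, i] = val
    return hess


@dataclass
class ModelComparison:
    """AIC comparison of the free-exponent fit against the nested q = 0 fit.

    With exact optimisation the nesting bound ``delta_aic <= 2`` always
    holds (the free fit cannot have lower likelihood; the penalty for its
    extra parameter is 2 AIC points). The decision rule concludes deviation
    from Type II only when the free model beats the penalty:
    ``delta_aic < -2``.
    """

    delta_aic: float
    aic_free: float
    aic_fixed: float
    conclusion: str

    def summary(self) -> str:
        return (
            f"AIC(q free) = {self.aic_free:.4f}, AIC(q = 0) = {self.aic_fixed:.4f}, "
            f"delta AIC = {self.delta_aic:.4f} -> {self.conclusion}"
        )


def compare_models(
    free: FunctionalResponseResults, fixed: FunctionalResponseResults
) -> ModelComparison:
    """``delta_AIC = AIC(q free) - AIC(q = 0)`` and the type conclusion."""
    same = (
        len(free.model.N0) == len(fixed.model.N0)
        and np.array_equal(free.model.N0, fixed.model.N0)
        and np.array_equal(free.model.consumed, fixed.model.consumed)
    )
    if not same:
        raise ValueError("fits must come from the same dataset")
    delta = free.aic - fixed.aic
    conclusion = "retain Type II" if delta >= -2.0 else "deviation from Type II"
    return ModelComparison(
        delta_aic=float(delta),
        aic_free=float(free.aic),
        aic_fixed=float(fixed.aic),
        conclusion=conclusion,
    )


# -- thin functional wrappers over the model classes -------------------


def fit_rogers(dataset, T: float = 1.0) -> FunctionalResponseResults:
    """Fit the Rogers Type II model to a functional-response dataset."""
    if isinstance(dataset, TrialDataset):
        model = RogersTypeII.from_dataset(dataset, T=T)
    else:
        n0, consumed, _ = _extract_fr_arrays(dataset)
        model = RogersTypeII(n0, consumed, T=T)
    return model.fit()


def fit_flex(dataset, T: float = 1.0, fix_q: float | None = None):
    """Fit the flexible-exponent model (optionally with ``q`` pinned)."""
    n0, consumed, _ = _extract_fr_arrays(dataset)
    return FlexibleTypeII(n0, consumed, T=T).fit(fix_q=fix_q)


def bootstrap_ci(
    fit: FunctionalResponseResults,
    n_boot: int = 200,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Percentile bootstrap intervals for a Rogers-family fit.

    Resamples replicates *within* each initial density (the stratification
    of the design) and refits; returns per-parameter lower/upper bounds.
    Non-converged resamples are dropped. Complements, not replaces, the
    asymptotic delta-method SEs.
    """
    model = fit.model
    rng = np.random.default_rng(seed)
    strata = {n0: np.flatnonzero(model.N0 == n0) for n0 in np.unique(model.N0)}
    draws: list[np.ndarray] = []
    for _ in range(n_boot):
        idx = np.concatenate(
            [rng.choice(ix, size=len(ix), replace=True) for ix in strata.values()]
        )
        boot = type(model)(model.N0[idx], model.consumed[idx], T=model.T)
        res = boot.fit(**({"fix_q": fit.fixed["q"]} if "q" in fit.fixed else {}))
        if res.converged:
            draws.append(res.params.reindex(fit.params.index).to_numpy())
    if not draws:
        raise RuntimeError("no converged bootstrap resamples")
    arr = np.vstack(draws)
    lo = np.percentile(arr, 100 * (0.5 - level / 2), axis=0)
    hi = np.percentile(arr, 100 * (0.5 + level / 2), axis=0)
    return pd.DataFrame(
        {"lower": lo, "upper": hi, "n_converged": len(draws)},
        index=fit.params.index,
    )


def predict_curve(fit: FunctionalResponseResults, densities) -> pd.DataFrame:
    """Expected consumption at each density for a converged fit."""
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    densities = np.asarray(densities, dtype=float)
    return pd.DataFrame({"N0": densities, "expected_consumed": fit.predict(densities)})
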