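"""Linear mixed model with AR(1) within-participant residual correlation.

Effect-detection model for two-arm longitudinal trials:

    y_ij = b0 + b1*t_ij + b2*arm_i + b3*(t_ij*arm_i) + a_i + e_ij

with a random participant intercept a_i ~ N(0, sigma_b^2) and residuals e_ij
that are correlated within participant via a first-order autoregressive
process: corr(e_ij, e_ik) = phi^|j-k| over the participant's assessment order
(optionally phi^|t_j - t_k| on the time scale).  Equivalently the marginal
covariance of participant i's observations is

    V_i = sigma_b^2 * J + sigma^2 * R_i(phi)

block-diagonal across participants.  Fitting is by maximum likelihood (REML
optional) with the residual variance profiled out analytically, so the
optimizer works on only (log gamma, atanh phi) where gamma = sigma_b^2/sigma^2.

Participants sharing the same assessment schedule and arm share a covariance
block and a fixed-effect design block; the likelihood is evaluated once per
unique pattern, which makes balanced trial designs (the common case in power
simulation) cheap regardless of the number of participants.

The treatment-effect test is the two-sided t-test on b3 (time-by-arm
interaction) with between-within denominator degrees of freedom
N_obs - N_participants - 2, the convention used for within-participant fixed
effects by nlme-style mixed-model software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy import stats as sps

__all__ = [
    "LmmFit",
    "LmmError",
    "SingularDesignError",
    "ConvergenceError",
    "DegenerateFitError",
    "fit_lmm",
    "test_interaction",
    "compare_aic",
]

_FIXED_EFFECT_NAMES = ("intercept", "time", "arm", "time_arm")
_PHI_MAX = 0.999


class LmmError(ValueError):
    """Base class for mixed-model fitting errors."""


class SingularDesignError(LmmError):
    """Design matrix is rank deficient (e.g. all times equal, one arm empty)."""


class ConvergenceError(LmmError):
    """Likelihood optimization failed; carries optimizer diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateFitError(LmmError):
    """Fit is degenerate for the requested quantity (e.g. zero standard error)."""


@dataclass
class LmmFit:
    """Result of fitting the interaction LMM.

    ``beta`` is ordered (intercept, time, arm, time*arm); time is in years,
    arm coded 0 = placebo, 1 = treatment, so ``beta[3]`` is the between-arm
    difference in annual progression rate.
    """

    beta: np.ndarray
    se_beta: np.ndarray
    var_intercept: float
    var_resid: float
    phi: float
    loglik: float
    aic: float
    df_denominator: int
    p_interaction: float
    t_interaction: float
    n_obs: int
    n_participants: int
    correlation: str
    method: str
    converged: bool
    fingerprint: float = 0.0
    optimizer_diagnostics: dict = field(default_factory=dict, repr=False)

    @property
    def fixed_effect_names(self) -> tuple[str, ...]:
        return _FIXED_EFFECT_NAMES

    def to_dict(self) -> dict:
        return {
            "beta": dict(zip(_FIXED_EFFECT_NAMES, (float(b) for b in self.beta))),
            "se_beta": dict(zip(_FIXED_EFFECT_NAMES, (float(s) for s in self.se_beta))),
            "var_intercept": float(self.var_intercept),
            "var_resid": float(self.var_resid),
            "phi": float(self.phi),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "df_denominator": int(self.df_denominator),
            "t_interaction": float(self.t_interaction),
            "p_interaction": float(self.p_interaction),
            "n_obs": int(self.n_obs),
            "n_participants": int(self.n_participants),
            "correlation": self.correlation,
            "method": self.method,
            "converged": bool(self.converged),
        }


# ---------------------------------------------------------------------------
# data preparation: group observations into per-pattern blocks
# ---------------------------------------------------------------------------

_ARM_CODES = {"placebo": 0.0, "treatment": 1.0}


def _coerce_arm(arm: np.ndarray) -> np.ndarray:
    if arm.dtype.kind in "OUS":
        try:
            return np.array([_ARM_CODES[str(a)] for a in arm], dtype=float)
        except KeyError as exc:  # pragma: no cover - defensive
            raise LmmError(f"unrecognized arm label {exc.args[0]!r}") from None
    return arm.astype(float)


class _Pattern:
    """Participants sharing an assessment-time vector and an arm code."""

    __slots__ = ("times", "X", "Y", "n_subj", "m")

    def __init__(self, times: np.ndarray, arm_code: float, Y: np.ndarray):
        self.times = times
        self.m = times.size
        self.n_subj = Y.shape[0]
        self.Y = Y
        X = np.empty((self.m, 4))
        X[:, 0] = 1.0
        X[:, 1] = times
        X[:, 2] = arm_code
        X[:, 3] = times * arm_code
        self.X = X


class _Workspace:
    """Pattern-blocked profiled likelihood for the interaction LMM."""

    def __init__(
        self,
        participant: np.ndarray,
        time: np.ndarray,
        arm: np.ndarray,
        y: np.ndarray,
        *,
        time_scaled_phi: bool = False,
    ):
        arm = _coerce_arm(np.asarray(arm))
        time = np.asarray(time, dtype=float)
        y = np.asarray(y, dtype=float)
        participant = np.asarray(participant)
        if not (participant.shape == time.shape == arm.shape == y.shape):
            raise LmmError("participant, time, arm and value columns must align")
        if y.size == 0:
            raise LmmError("empty dataset")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(time)):
            raise LmmError("non-finite values in data")

        self.time_scaled_phi = time_scaled_phi

        # stable sort by participant then time
        order = np.lexsort((time, participant))
        participant, time, arm, y = (
            participant[order],
            time[order],
            arm[order],
            y[order],
        )
        uniq, starts = np.unique(participant, return_index=True)
        starts = np.sort(starts)
        bounds = np.append(starts, y.size)
        self.n_subj = uniq.size
        self.n_obs = y.size

        groups: dict[tuple, list[np.ndarray]] = {}
        keys_meta: dict[tuple, tuple[np.ndarray, float]] = {}
        arms_seen = set()
        for s, e in zip(bounds[:-1], bounds[1:]):
            t_i = time[s:e]
            a_i = arm[s:e]
            if e - s < 2:
                raise LmmError("every participant needs at least 2 observations")
            if not np.all(a_i == a_i[0]):
                raise LmmError("arm must be constant within participant")
            arms_seen.add(float(a_i[0]))
            key = (t_i.tobytes(), float(a_i[0]))
            groups.setdefault(key, []).append(y[s:e])
            keys_meta[key] = (t_i, float(a_i[0]))
        if len(arms_seen) < 2:
            raise SingularDesignError("both arms must be present")
        if np.ptp(time) == 0:
            raise SingularDesignError("all assessment times are equal")

        self.patterns = [
            _Pattern(keys_meta[k][0], keys_meta[k][1], np.vstack(ys))
            for k, ys in groups.items()
        ]

        # rank check on the pooled fixed-effect design
        Xall = np.vstack(
            [np.repeat(p.X[None, :, :], p.n_subj, axis=0).reshape(-1, 4) for p in self.patterns]
        )
        if np.linalg.matrix_rank(Xall) < 4:
            raise SingularDesignError("fixed-effect design is rank deficient")
        self._Xall = Xall
        self._yall = np.concatenate([p.Y.ravel() for p in self.patterns])

        self.fingerprint = float(
            self.n_obs
            + 1e-3 * float(np.sum(y))
            + 1e-6 * float(np.sum(y * y))
            + 1e-9 * float(np.sum(time))
        )

    # -- correlation structure ------------------------------------------------

    def _corr(self, pattern: _Pattern, phi: float) -> np.ndarray:
        if phi == 0.0:
            return np.eye(pattern.m)
        if self.time_scaled_phi:
            lag = np.abs(pattern.times[:, None] - pattern.times[None, :])
        else:
            idx = np.arange(pattern.m, dtype=float)
            lag = np.abs(idx[:, None] - idx[None, :])
        with np.errstate(invalid="ignore"):
            return np.power(phi, lag)

    # -- profiled likelihood --------------------------------------------------

    def profile(self, gamma: float, phi: float, *, reml: bool = False):
        """GLS at scaled covariance C = gamma*J + R(phi); returns
        (nll, beta, sigma2, XtCiX) with sigma^2 profiled out."""
        N, p = self.n_obs, 4
        logdet = 0.0
        XtCiX = np.zeros((p, p))
        XtCiy = np.zeros(p)
        yCiy = 0.0
        per_pattern = []
        for pat in self.patterns:
            C = self._corr(pat, phi)
            if gamma > 0:
                C = C + gamma
            try:
                cho = linalg.cho_factor(C, lower=True, check_finite=False)
            except linalg.LinAlgError:
                return math.inf, None, None, None
            logdet += pat.n_subj * 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
            CiX = linalg.cho_solve(cho, pat.X, check_finite=False)
            XtCiX += pat.n_subj * (pat.X.T @ CiX)
            ysum = pat.Y.sum(axis=0)
            XtCiy += CiX.T @ ysum
            CiYt = linalg.cho_solve(cho, pat.Y.T, check_finite=False)
            yCiy += float(np.sum(pat.Y.T * CiYt))
            per_pattern.append((pat, CiX))
        try:
            beta = np.linalg.solve(XtCiX, XtCiy)
        except np.linalg.LinAlgError:
            return math.inf, None, None, None
        rss = yCiy - 2.0 * float(beta @ XtCiy) + float(beta @ XtCiX @ beta)
        rss = max(rss, 0.0)
        denom = N - p if reml else N
        if rss <= 0.0:
            return -math.inf, beta, 0.0, XtCiX
        sigma2 = rss / denom
        nll = 0.5 * (denom * math.log(2.0 * math.pi * sigma2) + logdet + denom)
        if reml:
            sign, ld_xx = np.linalg.slogdet(XtCiX)
            if sign <= 0:
                return math.inf, None, None, None
            nll += 0.5 * ld_xx
        return nll, beta, sigma2, XtCiX

    def ols_residual_scale(self) -> tuple[np.ndarray, float]:
        beta, *_ = np.linalg.lstsq(self._Xall, self._yall, rcond=None)
        resid = self._yall - self._Xall @ beta
        return beta, float(np.max(np.abs(resid)))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _extract_columns(data) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        cols = {c.lower(): c for c in data.columns}
        def col(*names):
            for n in names:
                if n in cols:
                    return data[cols[n]].to_numpy()
            raise LmmError(f"missing required column (one of {names})")
        return (
            col("participant_id", "participant", "id"),
            col("time_years", "time"),
            col("arm"),
            col("value", "y"),
        )
    raise LmmError("data must be a pandas DataFrame in long format")


def fit_lmm(
    data,
    correlation: str = "ar1",
    *,
    method: str = "ml",
    time_scaled_phi: bool = False,
    xtol: float = 1e-6,
    ftol: float = 1e-9,
    start: tuple[float, float] | None = None,
) -> LmmFit:
    """Fit the time-by-arm interaction LMM by (RE)ML.

    Parameters
    ----------
    data : pandas.DataFrame
        Long format with columns participant_id, arm (0/1 or
        placebo/treatment), time_years (or time) and value.
    correlation : {"ar1", "independent"}
        Residual correlation structure within participant.
    method : {"ml", "reml"}
        ML is the default so that AIC comparisons across correlation
        structures are valid.
    time_scaled_phi : bool
        If True the AR(1) correlation decays as phi**|t_j - t_k| with time in
        years rather than phi**|j - k| over assessment order.
    """
    if correlation not in ("ar1", "independent"):
        raise LmmError(f"unknown correlation structure {correlation!r}")
    if method not in ("ml", "reml"):
        raise LmmError(f"unknown method {method!r}")
    reml = method == "reml"

    participant, time, arm, y = _extract_columns(data)
    ws = _Workspace(participant, time, arm, y, time_scaled_phi=time_scaled_phi)

    # interpolating (noise-free) data: all variance at the zero boundary
    beta_ols, max_resid = ws.ols_residual_scale()
    scale = max(1.0, float(np.max(np.abs(ws._yall))))
    if max_resid <= 1e-10 * scale:
        return _degenerate_fit(ws, beta_ols, correlation, method)

    def pack_nll(x: np.ndarray) -> float:
        gamma = math.exp(min(x[0], 40.0))
        phi = _PHI_MAX * math.tanh(x[1]) if correlation == "ar1" else 0.0
        nll, *_ = ws.profile(gamma, phi, reml=reml)
        return nll if math.isfinite(nll) else 1e300

    # coarse start grid, then a local Nelder-Mead polish from the best start;
    # an explicit (gamma, phi) start (e.g. the previous replicate's optimum in
    # a Monte-Carlo loop) replaces the grid scan
    if start is not None:
        g0, p0 = start
        starts = [
            np.array(
                [
                    math.log(max(g0, 1e-8)),
                    math.atanh(np.clip(p0 / _PHI_MAX, -0.999, 0.999)),
                ]
            )
        ]
        start_vals = [pack_nll(starts[0])]
    else:
        log_gammas = [-2.0, 0.0, 2.0, 4.0]
        phis = [0.0, 0.3, 0.7] if correlation == "ar1" else [0.0]
        starts = [
            np.array([lg, math.atanh(min(ph / _PHI_MAX, 0.999))])
            for lg in log_gammas
            for ph in phis
        ]
        start_vals = [pack_nll(x) for x in starts]
    x0 = starts[int(np.argmin(start_vals))]

    res = optimize.minimize(
        pack_nll,
        x0,
        method="Nelder-Mead",
        options={"xatol": xtol, "fatol": ftol, "maxiter": 400, "maxfev": 600},
    )
    if not res.success:
        # one restart from the runner-up start before giving up
        alt = starts[int(np.argsort(start_vals)[1])] if len(starts) > 1 else x0
        res2 = optimize.minimize(
            pack_nll,
            alt,
            method="Nelder-Mead",
            options={"xatol": xtol, "fatol": ftol, "maxiter": 800, "maxfev": 1200},
        )
        if res2.fun <= res.fun:
            res = res2
    if not math.isfinite(res.fun) or res.fun >= 1e299:
        raise ConvergenceError(
            "likelihood optimization failed",
            {"message": str(res.message), "nfev": int(res.nfev), "fun": float(res.fun)},
        )

    gamma = math.exp(min(res.x[0], 40.0))
    phi = _PHI_MAX * math.tanh(res.x[1]) if correlation == "ar1" else 0.0
    nll, beta, sigma2, XtCiX = ws.profile(gamma, phi, reml=reml)
    if beta is None or sigma2 is None or sigma2 <= 0:
        raise ConvergenceError(
            "profiled likelihood degenerate at optimum",
            {"gamma": gamma, "phi": phi},
        )

    cov_beta = sigma2 * np.linalg.inv(XtCiX)
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    loglik = -nll
    n_cov_params = 3 if correlation == "ar1" else 2  # sigma_b^2, sigma^2 (+ phi)
    k = 4 + n_cov_params
    aic = 2.0 * k - 2.0 * loglik

    df = ws.n_obs - ws.n_subj - 2
    t3, p3 = _interaction_test(beta, se, df)

    return LmmFit(
        beta=beta,
        se_beta=se,
        var_intercept=gamma * sigma2,
        var_resid=sigma2,
        phi=phi,
        loglik=loglik,
        aic=aic,
        df_denominator=df,
        p_interaction=p3,
        t_interaction=t3,
        n_obs=ws.n_obs,
        n_participants=ws.n_subj,
        correlation=correlation,
        method=method,
        converged=bool(res.success or math.isfinite(res.fun)),
        fingerprint=ws.fingerprint,
        optimizer_diagnostics={"nfev": int(res.nfev), "message": str(res.message)},
    )


def _interaction_test(beta, se, df) -> tuple[float, float]:
    if se[3] <= 0 or df <= 0:
        return math.nan, math.nan
    t3 = float(beta[3] / se[3])
    return t3, float(2.0 * sps.t.sf(abs(t3), df))


def _degenerate_fit(ws: _Workspace, beta: np.ndarray, correlation: str, method: str) -> LmmFit:
    """Noise-free data: fixed effects interpolate, variances at the boundary."""
    df = ws.n_obs - ws.n_subj - 2
    return LmmFit(
        beta=beta,
        se_beta=np.zeros(4),
        var_intercept=0.0,
        var_resid=0.0,
        phi=0.0,
        loglik=math.inf,
        aic=-math.inf,
        df_denominator=df,
        p_interaction=math.nan,
        t_interaction=math.nan,
        n_obs=ws.n_obs,
        n_participants=ws.n_subj,
        correlation=correlation,
        method=method,
        converged=True,
    )


def test_interaction(fit: LmmFit) -> tuple[float, int, float]:
    """t-statistic, denominator df and two-sided p for the time-by-arm term.

    Degrees of freedom follow the between-within rule for within-participant
    fixed effects: N_obs - N_participants - 2.
    """
    if not fit.converged:
        raise ConvergenceError("fit did not converge", fit.optimizer_diagnostics)
    if fit.se_beta[3] <= 0 or not math.isfinite(fit.se_beta[3]):
        raise DegenerateFitError("interaction standard error is zero; t-test undefined")
    t3 = float(fit.beta[3] / fit.se_beta[3])
    p3 = float(2.0 * sps.t.sf(abs(t3), fit.df_denominator))
    return t3, fit.df_denominator, p3


def compare_aic(fit_ar1: LmmFit, fit_indep: LmmFit) -> LmmFit:
    """Return the AIC-preferred fit; exact ties go to the AR(1) model."""
    if fit_ar1.correlation != "ar1" or fit_indep.correlation != "independent":
        raise LmmError("expected an (ar1, independent) pair of fits")
    if abs(fit_ar1.fingerprint - fit_indep.fingerprint) > 1e-6 * max(
        1.0, abs(fit_ar1.fingerprint)
    ):
        raise LmmError("fits were not computed on the same data")
    if fit_ar1.aic <= fit_indep.aic:
        return fit_ar1
    return fit_indep
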