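"""Least-squares fitting of duration-response families to WSRI data.

The central objects follow the model/results convention: build a
:class:`DurationResponseModel` from (duration, index) data and a family,
call :meth:`~DurationResponseModel.fit`, and read estimates, standard
errors, residuals and R² off the returned :class:`DurationResponseResults`.

Linear and quadratic families are solved in closed form by the normal
equations; the exponential decay y = a·exp(b·x) is solved by iterative
nonlinear least squares started from a log-linear regression on the
positive indices. Fits are unweighted by default (inverse-variance weights
are accepted) and permutation-invariant in point order.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .curves import CurveRegistry, ResponseCurve, ResponseFamily, load_registry
from .errors import (
    InitializationError,
    RankError,
    UndefinedRSquaredError,
)
from .wsri import WsriTable

#: Parsimony margin on R² under which a family with fewer coefficients is
#: preferred during model selection.
SELECTION_MARGIN = 0.01

_MAX_ITER = 200
_COEF_TOL = 1e-10


class DurationResponseModel:
    """One parameter's stress index as a function of waterlogging duration.

    Parameters
    ----------
    durations : array-like of days, >= 0
    indices : array-like of dimensionless stress indices, same length
    family : ResponseFamily or its string tag
    weights : optional array-like of positive weights (e.g. inverse
        replicate variance); default unweighted
    parameter_code : label carried through to the fitted curve
    """

    def __init__(
        self,
        durations: Sequence[float],
        indices: Sequence[float],
        family: ResponseFamily | str,
        weights: Sequence[float] | None = None,
        parameter_code: str = "FIT",
        description: str = "",
    ):
        self.durations = np.asarray(durations, dtype=float)
        self.indices = np.asarray(indices, dtype=float)
        if self.durations.shape != self.indices.shape or self.durations.ndim != 1:
            raise ValueError("durations and indices must be equal-length 1-D arrays")
        self.family = ResponseFamily(family)
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        if self.weights is not None and self.weights.shape != self.durations.shape:
            raise ValueError("weights must match the number of points")
        self.parameter_code = parameter_code
        self.description = description

        n_distinct = np.unique(self.durations).size
        if n_distinct < self.family.arity:
            raise RankError(
                f"{self.family.value} fit needs >= {self.family.arity} distinct "
                f"durations, got {n_distinct}"
            )

    @classmethod
    def from_dataframe(
        cls,
        df,
        family: ResponseFamily | str,
        duration_col: str = "duration",
        index_col: str = "index",
        **kwargs,
    ) -> "DurationResponseModel":
        return cls(df[duration_col].to_numpy(), df[index_col].to_numpy(), family, **kwargs)

    # -- fitting ---------------------------------------------------------

    def _design(self) -> np.ndarray:
        x = self.durations
        if self.family is ResponseFamily.LINEAR:
            return np.column_stack([x, np.ones_like(x)])
        return np.column_stack([x**2, x, np.ones_like(x)])

    def _fit_polynomial(self) -> tuple[np.ndarray, np.ndarray, bool, int]:
        X = self._design()
        y = self.indices
        if self.weights is not None:
            sw = np.sqrt(self.weights)
            X, y = X * sw[:, None], y * sw
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return coef, X, True, 0

    def _exp_start(self) -> np.ndarray:
        pos = self.indices > 1e-9
        if not np.any(pos):
            raise InitializationError(
                "exp_decay initialization requires at least one positive index"
            )
        if np.count_nonzero(pos) >= 2:
            # log-linear regression on the positive points
            X = np.column_stack([self.durations[pos], np.ones(np.count_nonzero(pos))])
            b, log_a = np.linalg.lstsq(X, np.log(self.indices[pos]), rcond=None)[0]
            return np.array([np.exp(log_a), b])
        # fallback: amplitude from the max, rate from first/last positive pair
        a0 = float(self.indices.max())
        order = np.argsort(self.durations)
        xp, yp = self.durations[order][pos[order]], self.indices[order][pos[order]]
        if len(xp) >= 2 and xp[-1] > xp[0]:
            b0 = (np.log(yp[-1]) - np.log(yp[0])) / (xp[-1] - xp[0])
        else:
            b0 = -0.1
        return np.array([a0, b0])

    def _fit_exp(self, start) -> tuple[np.ndarray, np.ndarray, bool, int]:
        x, y = self.durations, self.indices
        sw = np.ones_like(x) if self.weights is None else np.sqrt(self.weights)

        def resid(theta):
            return sw * (theta[0] * np.exp(theta[1] * x) - y)

        def jac(theta):
            e = np.exp(theta[1] * x)
            return np.column_stack([sw * e, sw * theta[0] * x * e])

        x0 = np.asarray(start, dtype=float) if start is not None else self._exp_start()
        sol = least_squares(
            resid,
            x0,
            jac=jac,
            method="lm",
            xtol=_COEF_TOL,
            ftol=_COEF_TOL,
            gtol=_COEF_TOL,
            max_nfev=_MAX_ITER * 2,
        )
        converged = bool(sol.status > 0)
        return sol.x, jac(sol.x), converged, int(sol.nfev)

    def fit(self, start: Sequence[float] | None = None) -> "DurationResponseResults":
        """Estimate the family's coefficients by (weighted) least squares."""
        if self.family is ResponseFamily.EXP_DECAY:
            params, J, converged, iterations = self._fit_exp(start)
        else:
            params, J, converged, iterations = self._fit_polynomial()
        return DurationResponseResults(self, params, J, converged, iterations)

    @classmethod
    def select(
        cls,
        durations: Sequence[float],
        indices: Sequence[float],
        margin: float = SELECTION_MARGIN,
        **kwargs,
    ) -> "DurationResponseResults":
        """Fit all three families and return the preferred one.

        The highest-R² fit wins, except that a family with fewer
        coefficients is preferred when its R² is within ``margin`` of the
        best. Selection metadata (R² per family) is attached to the result.
        """
        durations = np.asarray(durations, float)
        if np.unique(durations).size < 4:
            raise RankError("model selection needs >= 4 distinct durations")
        candidates: dict[ResponseFamily, DurationResponseResults] = {}
        for family in ResponseFamily:
            try:
                candidates[family] = cls(durations, indices, family, **kwargs).fit()
            except InitializationError:
                continue
        scores = {fam: res.rsquared for fam, res in candidates.items()}
        best_r2 = max(scores.values())
        # among families within the parsimony margin, fewest coefficients
        # wins; linear outranks exp_decay at equal arity
        order = [ResponseFamily.LINEAR, ResponseFamily.EXP_DECAY, ResponseFamily.QUADRATIC]
        eligible = [f for f in order if f in scores and scores[f] >= best_r2 - margin]
        chosen = candidates[eligible[0]]
        chosen.selection = {f.value: s for f, s in scores.items()}
        return chosen


class DurationResponseResults:
    """Fitted coefficients, uncertainties and diagnostics for one curve."""

    def __init__(self, model, params, jacobian, converged, iterations):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.converged = converged
        self.iterations = iterations
        self.selection: dict | None = None
        self._jacobian = jacobian

    # -- core quantities -------------------------------------------------

    @property
    def family(self) -> ResponseFamily:
        return self.model.family

    @property
    def nobs(self) -> int:
        return self.model.durations.size

    n_points = nobs

    @property
    def curve(self) -> ResponseCurve:
        return ResponseCurve(
            parameter_code=self.model.parameter_code,
            description=self.model.description,
            family=self.family,
            coefficients=tuple(float(p) for p in self.params),
            r_squared=self._rsquared_or_none(),
        )

    def predict(self, durations) -> np.ndarray:
        x = np.asarray(durations, dtype=float)
        p = self.params
        if self.family is ResponseFamily.LINEAR:
            return p[0] * x + p[1]
        if self.family is ResponseFamily.QUADRATIC:
            return p[0] * x**2 + p[1] * x + p[2]
        return p[0] * np.exp(p[1] * x)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.durations)

    @property
    def resid(self) -> np.ndarray:
        return self.model.indices - self.fittedvalues

    residuals = resid

    @property
    def ssr(self) -> float:
        return float(np.sum(self.resid**2))

    def _rsquared_or_none(self) -> float | None:
        ss_tot = float(np.sum((self.model.indices - self.model.indices.mean()) ** 2))
        if ss_tot == 0.0:
            return None
        return 1.0 - self.ssr / ss_tot

    @property
    def rsquared(self) -> float:
        r2 = self._rsquared_or_none()
        if r2 is None:
            raise UndefinedRSquaredError("indices have zero variance")
        return r2

    @property
    def df_resid(self) -> int:
        return self.nobs - self.params.size

    @property
    def scale(self) -> float:
        """Residual variance estimate (ssr / df_resid)."""
        if self.df_resid <= 0:
            return float("nan")
        return self.ssr / self.df_resid

    @property
    def cov_params(self) -> np.ndarray:
        JtJ = self._jacobian.T @ self._jacobian
        try:
            return self.scale * np.linalg.inv(JtJ)
        except np.linalg.LinAlgError:
            return np.full((self.params.size,) * 2, np.nan)

    @property
    def bse(self) -> np.ndarray:
        """Asymptotic standard errors of the coefficients."""
        return np.sqrt(np.diag(self.cov_params))

    # -- presentation ----------------------------------------------------

    _COEF_NAMES = {
        ResponseFamily.LINEAR: ("slope", "intercept"),
        ResponseFamily.QUADRATIC: ("a (x^2)", "b (x)", "c (const)"),
        ResponseFamily.EXP_DECAY: ("amplitude", "rate (1/d)"),
    }

    def summary(self) -> str:
        lines = [
            "Duration-response fit",
            "=" * 54,
            f"parameter:  {self.model.parameter_code}",
            f"family:     {self.family.value}",
            f"n points:   {self.nobs}",
            f"converged:  {self.converged} (iterations: {self.iterations})",
        ]
        r2 = self._rsquared_or_none()
        if r2 is not None:
            lines.append(f"R-squared:  {r2:.4f}")
        lines.append("-" * 54)
        lines.append(f"{'coefficient':<12}{'estimate':>14}{'std err':>14}")
        bse = self.bse
        for name, est, se in zip(self._COEF_NAMES[self.family], self.params, bse):
            lines.append(f"{name:<12}{est:>14.6g}{se:>14.4g}")
        if self.selection:
            lines.append("-" * 54)
            scored = ", ".join(f"{k}: {v:.4f}" for k, v in self.selection.items())
            lines.append(f"selection R² by family — {scored}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def __repr__(self) -> str:
        coefs = ", ".join(f"{p:.6g}" for p in self.params)
        return (
            f"<DurationResponseResults {self.model.parameter_code} "
            f"{self.family.value} [{coefs}]>"
        )


# -- functional wrappers (operation surface) ------------------------------


def fit_family(
    points: Iterable[tuple[float, float]],
    family: ResponseFamily | str,
    weights: Sequence[float] | None = None,
    **kwargs,
) -> DurationResponseResults:
    """Fit one family to ordered (duration, index) pairs."""
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (duration, index) pairs")
    return DurationResponseModel(pts[:, 0], pts[:, 1], family, weights=weights, **kwargs).fit()


def r_squared(points: Iterable[tuple[float, float]], curve: ResponseCurve) -> float:
    """Coefficient of determination of a fixed curve against data.

    1 − SS_res/SS_tot with SS_tot about the mean index; may be negative for
    a poor nonlinear fit.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("r_squared needs at least 2 points")
    y = pts[:, 1]
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedRSquaredError("indices have zero variance")
    yhat = np.asarray(curve(pts[:, 0]))
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def select_model(
    points: Iterable[tuple[float, float]], margin: float = SELECTION_MARGIN
) -> DurationResponseResults:
    """Fit all three families and return the parsimony-adjusted best."""
    pts = np.asarray(list(points), dtype=float)
    return DurationResponseModel.select(pts[:, 0], pts[:, 1], margin=margin)


def fit_wsri_table(
    wsri: WsriTable,
    mode: str = "registry_families",
    registry: CurveRegistry | None = None,
) -> dict[str, DurationResponseResults]:
    """Fit every parameter in a WSRI table; a batch registry-schema product.

    ``registry_families`` takes each parameter's family from the registry
    (packaged registry by default); ``auto_select`` chooses per parameter by
    R² with the parsimony margin.
    """
    if mode not in ("registry_families", "auto_select"):
        raise ValueError(f"unknown mode {mode!r}")
    if registry is None and mode == "registry_families":
        registry = load_registry()

    out: dict[str, DurationResponseResults] = {}
    for code in wsri.parameters:
        x, y = wsri.points(code)
        if np.unique(x).size < 4:
            raise RankError(f"parameter {code!r} has fewer than 4 distinct durations")
        if mode == "registry_families":
            if code not in registry:
                raise KeyError(f"parameter {code!r} not in registry {registry.version!r}")
            entry = registry[code]
            model = DurationResponseModel(
                x, y, entry.family, parameter_code=code, description=entry.description
            )
            out[code] = model.fit()
        else:
            out[code] = DurationResponseModel.select(x, y, parameter_code=code)
    return out


def results_to_frame(results: Mapping[str, DurationResponseResults]):
    """Serialise a batch of fits to the registry schema."""
    import pandas as pd

    rows = []
    for code, res in results.items():
        coef = list(res.params) + [np.nan] * (3 - res.params.size)
        rows.append(
            {
                "parameter_code": code,
                "description": res.model.description,
                "family": res.family.value,
                "a": coef[0],
                "b": coef[1],
                "c": coef[2],
                "r_squared": res._rsquared_or_none(),
            }
        )
    return pd.DataFrame(rows)
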