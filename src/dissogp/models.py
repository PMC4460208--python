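"""Closed-form drug-release equations and per-profile Weibull fitting.

The registry holds four equation families over (d, t) — extrudate diameter
in mm and dissolution time in min — each returning cumulative release Q in
percent:

``weibull``
    The empirical Weibull release model Q = 100*(1 - exp(-(t/A)^K)) with
    time-scale A (min) and shape K; parametrised directly by (A, K), no
    diameter dependence.
``eq_indirect``
    Weibull with its constants replaced by diameter maps discovered by
    symbolic regression: A = c3^d and K = c1*d/(d + c2*d) by default.
    Alternative parses of the flattened source typography are selectable:
    ``a_form`` in {"pow": c3**d, "linear": c3*d} and ``k_form`` in
    {"shared_d": c1*d/(d + c2*d), "saturating": c1*d/(d + c2)}.  The
    "shared_d" form collapses to the constant c1/(1 + c2) — kept as the
    literal default reading, but note (c1, c2) are then not separately
    identifiable; "saturating" varies with d and is identifiable.
``eq7_direct``
    The compact three-parameter rational form found by direct symbolic
    regression, read here as Q = (ln d + d + c1*t + c2) / (t + c3*d^2 + d^2)
    — a saturating curve with asymptote c1 (~ the maximal release in %).
``eq_previous``
    The earlier six-parameter mechanistically-derived Weibull variant,
    Q = 100*(1 - exp(-(t/(c5*d + c6))^(exp(c1*d + c2*d*ln(c3*d + c4))))),
    registered for comparison fits only.

The flattened typography of the two discovered forms is ambiguous; the
parses above are documented choices validated for finiteness over the study
domain (d in [0.6, 3.5] mm, t in [0, 1100] min) rather than against point
values.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
from scipy.optimize import least_squares

from .metrics import rmse

__all__ = [
    "WeibullParams",
    "EquationModel",
    "EQUATION_ARITY",
    "weibull_Q",
    "indirect_weibull_maps",
    "eval_equation",
    "fit_weibull_profile",
    "ParameterError",
    "EvaluationError",
    "DegenerateProfileError",
]


class ParameterError(ValueError):
    """Invalid or wrong-arity parameter vector."""


class EvaluationError(ValueError):
    """Equation undefined at the requested point."""


class DegenerateProfileError(ValueError):
    """Profile carries no kinetic information (e.g. constant Q)."""


@dataclass(frozen=True)
class WeibullParams:
    """Weibull release constants: time scale A (min) and shape K."""

    A: float
    K: float

    def __post_init__(self):
        if not (self.A > 0 and self.K > 0):
            raise ParameterError(f"Weibull constants must be positive, got A={self.A}, K={self.K}")


def weibull_Q(t, p: WeibullParams):
    """Cumulative release Q(t) = 100*(1 - exp(-(t/A)^K)), percent.

    Monotone nondecreasing in t, zero at t=0, asymptote 100; Q(A) is the
    63.2% landmark for any shape.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise EvaluationError("negative time")
    return 100.0 * (1.0 - np.exp(-((t / p.A) ** p.K)))


EQUATION_ARITY = {
    "weibull": 2,
    "eq7_direct": 3,
    "eq_indirect": 3,
    "eq_previous": 6,
}


@dataclass(frozen=True)
class EquationModel:
    """A registry equation bound to a concrete parameter vector."""

    equation_id: str
    params: tuple
    options: tuple = ()  # sorted (key, value) pairs, e.g. (("k_form", "saturating"),)

    def __post_init__(self):
        if self.equation_id not in EQUATION_ARITY:
            raise ParameterError(f"unknown equation {self.equation_id!r}")
        arity = EQUATION_ARITY[self.equation_id]
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if len(self.params) != arity:
            raise ParameterError(
                f"{self.equation_id} takes {arity} parameters, got {len(self.params)}"
            )
        object.__setattr__(self, "options", tuple(sorted(dict(self.options).items())))

    @property
    def opts(self) -> dict:
        return dict(self.options)

    def to_json(self) -> str:
        return json.dumps({"equation_id": self.equation_id,
                           "params": list(self.params),
                           "options": dict(self.options)}, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EquationModel":
        raw = json.loads(text)
        return cls(raw["equation_id"], tuple(raw["params"]),
                   tuple(raw.get("options", {}).items()))


def indirect_weibull_maps(d, params, a_form: str = "pow", k_form: str = "shared_d"):
    """Diameter maps (A(d), K(d)) behind the indirect model.

    a_form: "pow" -> A = c3**d ; "linear" -> A = c3*d.
    k_form: "shared_d" -> K = c1*d/(d + c2*d) ; "saturating" -> K = c1*d/(d + c2).
    """
    c1, c2, c3 = params
    d = np.asarray(d, dtype=float)
    if a_form == "pow":
        A = np.power(c3, d) if c3 > 0 else np.full_like(d, np.nan)
    elif a_form == "linear":
        A = c3 * d
    else:
        raise ParameterError(f"unknown a_form {a_form!r}")
    if k_form == "shared_d":
        denom = d + c2 * d
        K = np.where(denom != 0, c1 * d / np.where(denom == 0, 1.0, denom), np.nan)
    elif k_form == "saturating":
        denom = d + c2
        K = np.where(denom != 0, c1 * d / np.where(denom == 0, 1.0, denom), np.nan)
    else:
        raise ParameterError(f"unknown k_form {k_form!r}")
    return A, K


def _weibull_guarded(t, A, K):
    """Weibull evaluated leniently for optimizer sweeps: invalid (A, K)
    regions return NaN instead of raising, so objectives can penalise them."""
    t = np.asarray(t, dtype=float)
    A = np.asarray(A, dtype=float)
    K = np.asarray(K, dtype=float)
    with np.errstate(all="ignore"):
        bad = ~np.isfinite(A) | ~np.isfinite(K) | (A <= 0) | (K <= 0)
        ratio = np.where(bad, 1.0, t / np.where(A <= 0, 1.0, A))
        q = 100.0 * (1.0 - np.exp(-np.power(ratio, np.where(bad, 1.0, K))))
    return np.where(bad, np.nan, q)


def eval_equation(m: EquationModel, d, t):
    """Evaluate a registry equation at (d, t); vectorized.

    Out-of-family parameter regions (e.g. a nonpositive Weibull shape from
    an optimizer's trial point) yield NaN rather than an exception, so
    fitting objectives can penalise them; a fully-NaN result for in-domain
    (d, t) raises EvaluationError.
    """
    d = np.asarray(d, dtype=float)
    t = np.asarray(t, dtype=float)
    c = m.params
    with np.errstate(all="ignore"):
        if m.equation_id == "weibull":
            A, K = c
            q = _weibull_guarded(t, A, K)
        elif m.equation_id == "eq_indirect":
            A, K = indirect_weibull_maps(d, c,
                                         a_form=m.opts.get("a_form", "pow"),
                                         k_form=m.opts.get("k_form", "shared_d"))
            q = _weibull_guarded(t, A, K)
        elif m.equation_id == "eq7_direct":
            c1, c2, c3 = c
            denom = t + c3 * d ** 2 + d ** 2
            num = np.log(np.where(d > 0, d, np.nan)) + d + c1 * t + c2
            q = np.where(denom != 0, num / np.where(denom == 0, 1.0, denom), np.nan)
        elif m.equation_id == "eq_previous":
            c1, c2, c3, c4, c5, c6 = c
            A = c5 * d + c6
            inner = c3 * d + c4
            K = np.exp(np.clip(c1 * d + c2 * d * np.log(np.where(inner > 0, inner, np.nan)),
                               -50.0, 50.0))
            q = _weibull_guarded(t, A, K)
        else:  # pragma: no cover - guarded in EquationModel
            raise ParameterError(m.equation_id)
    if np.all(~np.isfinite(np.atleast_1d(q))):
        raise EvaluationError(
            f"{m.equation_id} undefined everywhere on the requested grid "
            f"(params {c})"
        )
    return q


def fit_weibull_profile(t, Q) -> tuple[WeibullParams, float]:
    """Least-squares Weibull fit of one formulation's release profile.

    Optimizes in (ln A, ln K) so positivity is structural.  The starting
    point reads A off the 63.2%-release landmark by interpolation and sets
    K = 1.  Returns the fitted constants and the achieved RMSE (%).

    Raises DegenerateProfileError for a flat profile and ValueError for
    fewer than three distinct time points.
    """
    t = np.asarray(t, dtype=float)
    Q = np.asarray(Q, dtype=float)
    order = np.argsort(t)
    t, Q = t[order], Q[order]
    if len(np.unique(t)) < 3:
        raise ValueError("need at least three distinct time points")
    if np.ptp(Q) == 0.0:
        raise DegenerateProfileError("profile is flat; Weibull constants undefined")
    mask = t > 0  # t=0 contributes no information to (t/A)^K on the log grid
    A0 = float(np.interp(63.212, np.maximum.accumulate(Q[mask]), t[mask]))
    A0 = min(max(A0, float(t[mask].min())), float(t[mask].max()) * 10)
    x0 = np.array([np.log(A0), 0.0])

    def resid(x):
        p = WeibullParams(float(np.exp(x[0])), float(np.exp(x[1])))
        return weibull_Q(t, p) - Q

    sol = least_squares(resid, x0, method="lm", max_nfev=2000)
    p = WeibullParams(float(np.exp(sol.x[0])), float(np.exp(sol.x[1])))
    return p, rmse(Q, weibull_Q(t, p))
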