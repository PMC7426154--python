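"""Fitting the 5'-end hydrogen-bond ramp and selecting among candidate models.

Three models are fitted to the positional mean bond count y as a function
of the re-indexed codon position x (x = 0 at original position 2, the
first codon after the start):

- uniform        y(x) = A
- linear         y(x) = B x + C
- bounded exponential (logistic-growth form)

      y(x) = A C e^{Bx} / (A + C (e^{Bx} - 1))

  with carrying capacity A (bonds/codon, the plateau), rate B (per codon
  position), and initial content C = y(0) (bonds/codon at the first codon
  after the start).  For B > 0 and A > C the curve rises monotonically
  from C and saturates at A.

Fits are weighted least squares; by default each position is weighted by
the inverse bootstrap variance of its mean.  Model choice uses AIC and
BIC.  A more complex model supplants a simpler one only when it wins under
*both* criteria: unguarded AIC alone prefers a spuriously complex nested
Gaussian model with probability P(chi2_k > 2k) (~14% for one extra
parameter), which would mislabel genuinely flat profiles far too often.
An ``guard="aic"`` mode returns the plain AIC winner instead, flagging
AIC/BIC disagreement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize, stats

from .profiles import PositionalProfile

__all__ = [
    "RampFit",
    "bounded_exponential",
    "fit_models",
    "select_model",
    "fallback_parameters",
]

_MODEL_K = {"uniform": 1, "linear": 2, "bounded_exponential": 3}


def bounded_exponential(x, A, B, C):
    """Bounded-exponential ramp y = ACe^{Bx} / (A + C(e^{Bx} - 1)).

    Evaluated in the overflow-safe logistic form
    y = AC / (C + (A - C) e^{-Bx}).
    """
    x = np.asarray(x, dtype=float)
    if A <= 0 or C <= 0:
        raise ValueError("A and C must be positive")
    return A * C / (C + (A - C) * np.exp(-B * x))


def _bexp_jacobian(x, A, B, C):
    e = np.exp(-B * x)
    D = C + (A - C) * e
    return np.column_stack(
        [
            C * C * (1.0 - e) / D**2,  # d/dA
            A * C * x * (A - C) * e / D**2,  # d/dB
            A * A * e / D**2,  # d/dC
        ]
    )


@dataclass
class RampFit:
    """One fitted positional model with uncertainty and information criteria."""

    model: str
    params: dict[str, float]
    std_errors: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    aic: float = np.inf
    bic: float = np.inf
    rss: float = np.inf  # weighted residual sum of squares
    n: int = 0
    converged: bool = False
    success: bool = False
    flags: list[str] = field(default_factory=list)

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.model == "uniform":
            return np.full_like(x, p["A"])
        if self.model == "linear":
            return p["B"] * x + p["C"]
        return bounded_exponential(x, p["A"], p["B"], p["C"])

    def to_json(self) -> str:
        d = asdict(self)
        d["aic"] = None if not np.isfinite(self.aic) else self.aic
        d["bic"] = None if not np.isfinite(self.bic) else self.bic
        d["rss"] = None if not np.isfinite(self.rss) else self.rss
        return json.dumps(d, indent=2, sort_keys=True)


def _information_criteria(rss_w, n, k):
    # Gaussian likelihood with estimated scale; +1 counts the scale parameter.
    # Terms constant across models (2*pi, the fixed weights) are dropped.
    rss_w = max(rss_w, 1e-300)
    aic = n * np.log(rss_w / n) + 2 * (k + 1)
    bic = n * np.log(rss_w / n) + (k + 1) * np.log(n)
    return aic, bic


def _wald(params, cov, dof):
    se, pv = {}, {}
    for i, (name, val) in enumerate(params.items()):
        s = float(np.sqrt(cov[i, i])) if np.isfinite(cov[i, i]) and cov[i, i] >= 0 else np.nan
        se[name] = s
        pv[name] = float(2 * stats.t.sf(abs(val / s), dof)) if s and np.isfinite(s) and s > 0 else np.nan
    return se, pv


def _self_start(x, y):
    """Logistic-style starting values (A0, B0, C0) for the bounded exponential."""
    A0 = float(np.max(y))
    C0 = float(max(y[0], 1e-3))
    if A0 <= C0:
        A0 = C0 * 1.001
    # slope at the origin of the logistic ODE: y' = B y (1 - y/A)
    head = min(10, len(x) - 1)
    slope = (y[head] - y[0]) / (x[head] - x[0]) if head else 0.0
    denom = C0 * max(1.0 - C0 / A0, 1e-6)
    B0 = float(np.clip(slope / denom, 1e-3, 2.0))
    return A0, B0, C0


def fit_models(
    profile: PositionalProfile,
    weights: str | np.ndarray = "bootstrap",
    max_iter: int = 1000,
) -> dict[str, RampFit]:
    """Fit uniform, linear, and bounded-exponential models to a profile.

    ``weights`` is ``"bootstrap"`` (inverse bootstrap variance of the
    positional means, the default), ``"uniform"``, or an explicit
    per-position weight vector.  x is re-indexed so the first analyzed
    position (original position 2) is x = 0.
    """
    y = np.asarray(profile.mean, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("profile must cover at least 10 positions")
    x = np.asarray(profile.positions, dtype=float) - profile.positions[0]

    if isinstance(weights, str):
        if weights == "uniform":
            w = np.ones(n)
        elif weights == "bootstrap":
            se = np.asarray(profile.se, dtype=float)
            floor = max(np.nanmax(se) * 1e-6, 1e-12)
            w = 1.0 / np.maximum(se, floor) ** 2
            if not np.all(np.isfinite(w)):
                w = np.ones(n)
        else:
            raise ValueError(f"unknown weights mode {weights!r}")
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape:
            raise ValueError("weight vector shape mismatch")
    sw = np.sqrt(w)

    fits: dict[str, RampFit] = {}

    # uniform: weighted mean
    A_hat = float(np.sum(w * y) / np.sum(w))
    r = sw * (y - A_hat)
    rss = float(r @ r)
    cov = np.array([[rss / (n - 1) / np.sum(w)]])
    se, pv = _wald({"A": A_hat}, cov, n - 1)
    aic, bic = _information_criteria(rss, n, 1)
    fits["uniform"] = RampFit("uniform", {"A": A_hat}, se, pv, aic, bic, rss, n, True)

    # linear: weighted least squares
    X = np.column_stack([x, np.ones(n)])
    beta, *_ = np.linalg.lstsq(sw[:, None] * X, sw * y, rcond=None)
    r = sw * (y - X @ beta)
    rss = float(r @ r)
    s2 = rss / (n - 2)
    cov = s2 * np.linalg.inv((sw[:, None] * X).T @ (sw[:, None] * X))
    params = {"B": float(beta[0]), "C": float(beta[1])}
    se, pv = _wald(params, cov, n - 2)
    aic, bic = _information_criteria(rss, n, 2)
    fits["linear"] = RampFit("linear", params, se, pv, aic, bic, rss, n, True)

    # bounded exponential: trust-region least squares, analytic Jacobian
    A0, B0, C0 = _self_start(x, y)

    def resid(theta):
        return sw * (bounded_exponential(x, *theta) - y)

    def jac(theta):
        return sw[:, None] * _bexp_jacobian(x, *theta)

    try:
        sol = optimize.least_squares(
            resid,
            x0=[A0, B0, C0],
            jac=jac,
            bounds=([1e-6, -10.0, 1e-6], [np.inf, 10.0, np.inf]),
            method="trf",
            xtol=1e-10,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=max_iter,
        )
        ok = bool(sol.success) and np.all(np.isfinite(sol.x))
    except Exception:
        sol, ok = None, False

    if ok:
        A, B, C = (float(v) for v in sol.x)
        r = resid([A, B, C])
        rss = float(r @ r)
        dof = max(n - 3, 1)
        J = jac([A, B, C])
        try:
            cov = rss / dof * np.linalg.inv(J.T @ J)
        except np.linalg.LinAlgError:
            cov = np.full((3, 3), np.nan)
        params = {"A": A, "B": B, "C": C}
        se, pv = _wald(params, cov, dof)
        aic, bic = _information_criteria(rss, n, 3)
        fits["bounded_exponential"] = RampFit(
            "bounded_exponential", params, se, pv, aic, bic, rss, n, True
        )
    else:
        C_fb, A_fb = fallback_parameters(profile)
        fits["bounded_exponential"] = RampFit(
            "bounded_exponential",
            {"A": A_fb, "B": np.nan, "C": C_fb},
            converged=False,
            n=n,
            flags=["fallback_parameters"],
        )
    return fits


def select_model(
    fits: dict[str, RampFit],
    p_threshold: float = 0.001,
    guard: str = "parsimony",
) -> RampFit:
    """Choose the best-fitting model among converged fits.

    ``guard="parsimony"`` (default): walking from simple to complex, a
    model is adopted only if it improves both AIC and BIC over the current
    choice.  ``guard="aic"``: plain AIC winner, with AIC/BIC disagreement
    flagged.

    The bounded exponential's ``success`` flag is set only when it
    converged, is best under both AIC and BIC, and its rate parameter B
    has Wald p below ``p_threshold``.  (This operational definition of a
    "successful" ramp fit is this package's own.)
    """
    conv = {m: f for m, f in fits.items() if f.converged}
    if not conv:
        raise ValueError("no converged fit")
    order = sorted(conv, key=_MODEL_K.get)
    best = conv[order[0]]
    disagreement = False
    for name in order[1:]:
        f = conv[name]
        if f.aic < best.aic and f.bic < best.bic:
            best = f
        elif f.aic < best.aic:
            disagreement = True
    if guard == "aic":
        aic_best = min(conv.values(), key=lambda f: f.aic)
        bic_best = min(conv.values(), key=lambda f: f.bic)
        if aic_best.model != bic_best.model and "aic_bic_disagreement" not in aic_best.flags:
            aic_best.flags.append("aic_bic_disagreement")
        best = aic_best
    elif guard == "parsimony":
        if disagreement and "aic_bic_disagreement" not in best.flags:
            best.flags.append("aic_bic_disagreement")
    else:
        raise ValueError(f"unknown guard {guard!r}")

    bexp = fits.get("bounded_exponential")
    if bexp is not None and bexp.converged:
        best_both = all(
            bexp.aic <= f.aic and bexp.bic <= f.bic for f in conv.values()
        )
        p_b = bexp.p_values.get("B", np.nan)
        bexp.success = bool(best_both and np.isfinite(p_b) and p_b < p_threshold)
    return best


def fallback_parameters(profile: PositionalProfile, trim: float = 0.10) -> tuple[float, float]:
    """(initial content, carrying capacity) when the exponential fit fails.

    Initial content = minimum positional mean; carrying capacity = mean of
    positional means after trimming ``trim`` of the positions from each
    end (10 + 10 positions for the standard 100-position window).
    """
    y = np.asarray(profile.mean, dtype=float)
    m = y.size
    k = int(round(trim * m))
    if m - 2 * k < 1 or m < 21:
        raise ValueError("profile too short to trim")
    return float(y.min()), float(y[k : m - k].mean())
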