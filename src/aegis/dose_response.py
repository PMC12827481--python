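"""Log-logistic (Hill) dose-response fitting of DILI scores.

The model is the four-parameter log-logistic

    f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))

with Hill slope ``b``, midpoint ``e`` (EC50, in dose-multiple units) and
lower/upper asymptotes ``c``/``d``.  With this sign convention a NEGATIVE
``b`` describes a response that increases with dose (the convention used
for rising DILI scores).  Two- (c=0, d=1 fixed) and three-parameter (c=0)
reductions are available.  Parameters are estimated by least squares with
``e`` parameterised on the log scale, a heuristic initialisation plus
jittered multi-starts, and asymptotic t-based standard errors/p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


@dataclass
class DoseResponseFit:
    """Fitted log-logistic parameters with SEs, p-values and diagnostics."""

    b: float
    e: float
    c: float
    d: float
    se: dict
    p_values: dict
    sse: float
    converged: bool
    n_params: int
    n_obs: int
    identifiable: bool = True

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.c + (self.d - self.c) / (1.0 + np.exp(self.b * (np.log(x) - np.log(self.e))))

    def summary(self) -> str:
        lines = [
            f"log-logistic dose-response fit ({self.n_params} parameters, "
            f"{self.n_obs} observations)",
            f"  converged: {self.converged}   identifiable: {self.identifiable}",
            f"  SSE: {self.sse:.6g}",
        ]
        for name, val in (("b (Hill slope)", self.b), ("e (EC50)", self.e),
                          ("c (lower)", self.c), ("d (upper)", self.d)):
            key = name.split()[0]
            if key in self.se:
                lines.append(
                    f"  {name:<16} {val:>10.4g}   se {self.se[key]:.3g}   "
                    f"p {self.p_values[key]:.3g}"
                )
            else:
                lines.append(f"  {name:<16} {val:>10.4g}   (fixed)")
        return "\n".join(lines)


def _loglogistic(logx: np.ndarray, b: float, loge: float, c: float, d: float) -> np.ndarray:
    return c + (d - c) / (1.0 + np.exp(np.clip(b * (logx - loge), -700, 700)))


def _initial_guess(logx: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    d_hat = float(y.max())
    c_hat = float(y.min())
    rng_y = d_hat - c_hat
    if rng_y <= 0:
        return -1.0, float(np.median(logx)), c_hat, d_hat
    # midpoint: dose at half-range crossing by linear interpolation in log-dose
    order = np.argsort(logx)
    xs, ys = logx[order], y[order]
    half = c_hat + rng_y / 2.0
    loge = float(np.interp(0.0, ys - half, xs)) if np.any(np.diff(np.sign(ys - half))) else float(np.median(xs))
    # slope: logit-linear regression on interior points
    frac = np.clip((y - c_hat) / rng_y, 1e-3, 1 - 1e-3)
    logit = np.log(frac / (1.0 - frac))
    A = np.column_stack([logx - loge, np.ones_like(logx)])
    slope = float(np.linalg.lstsq(A, logit, rcond=None)[0][0])
    b_hat = -slope if slope != 0 else -1.0
    return b_hat, loge, c_hat, d_hat


def fit_loglogistic(doses, responses, n_params: int = 4, seed: int = 0,
                    n_restarts: int = 5) -> DoseResponseFit:
    """Least-squares log-logistic fit of response vs dose.

    ``n_params`` selects the family: 2 (b, e with c=0, d=1), 3 (b, e, d
    with c=0) or 4 (b, e, c, d with asymptotes bounded to [0, 1], the
    range of normalised scores).  Requires at least n_params + 1 distinct
    positive doses.  Non-convergence is reported, never silent; a flat
    response is flagged non-identifiable.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("doses and responses must be equal-length 1-D arrays")
    if (x <= 0).any():
        raise ValueError("doses must be > 0")
    if n_params not in (2, 3, 4):
        raise ValueError("n_params must be 2, 3 or 4")
    if len(np.unique(x)) < n_params + 1:
        raise ValueError(f"need >= {n_params + 1} distinct doses for a {n_params}-parameter fit")
    logx = np.log(x)
    b0, loge0, c0, d0 = _initial_guess(logx, y)

    if n_params == 2:
        pack = lambda th: (th[0], th[1], 0.0, 1.0)
        theta0 = np.array([b0, loge0])
        lower = np.array([-np.inf, -np.inf])
        upper = np.array([np.inf, np.inf])
        names = ["b", "e"]
    elif n_params == 3:
        pack = lambda th: (th[0], th[1], 0.0, th[2])
        theta0 = np.array([b0, loge0, min(max(d0, 1e-6), 1.0)])
        lower = np.array([-np.inf, -np.inf, 0.0])
        upper = np.array([np.inf, np.inf, 1.0])
        names = ["b", "e", "d"]
    else:
        pack = lambda th: (th[0], th[1], th[2], th[3])
        theta0 = np.array([b0, loge0, min(max(c0, 0.0), 1.0), min(max(d0, 1e-6), 1.0)])
        lower = np.array([-np.inf, -np.inf, 0.0, 0.0])
        upper = np.array([np.inf, np.inf, 1.0, 1.0])
        names = ["b", "e", "c", "d"]

    def resid(th):
        b, loge, c, d = pack(th)
        return _loglogistic(logx, b, loge, c, d) - y

    rng = np.random.default_rng(seed)
    best = None
    starts = [theta0]
    for _ in range(n_restarts):
        jitter = rng.normal(0.0, [0.5, 0.7] + [0.1] * (len(theta0) - 2))
        starts.append(np.clip(theta0 + jitter, lower, upper))
    for th_start in starts:
        try:
            sol = optimize.least_squares(
                resid, th_start, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return DoseResponseFit(
            b=float("nan"), e=float("nan"), c=float("nan"), d=float("nan"),
            se={}, p_values={}, sse=float("nan"), converged=False,
            n_params=n_params, n_obs=len(x), identifiable=False,
        )
    b, loge, c, d = pack(best.x)
    loge = float(np.clip(loge, -700.0, 700.0))
    sse = float(2.0 * best.cost)
    n, p = len(x), len(best.x)
    dof = max(n - p, 1)
    sigma2 = sse / dof
    J = best.jac
    try:
        cov = sigma2 * np.linalg.pinv(J.T @ J)
        se_theta = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se_theta = np.full(p, np.nan)
    se: dict[str, float] = {}
    p_values: dict[str, float] = {}
    for i, name in enumerate(names):
        if name == "e":
            # delta method from log e
            se_val = float(np.exp(loge) * se_theta[i])
            est = float(np.exp(loge))
        else:
            se_val = float(se_theta[i])
            est = float(best.x[i])
        se[name] = se_val
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = est / se_val if se_val > 0 else np.inf * np.sign(est) if est else 0.0
        p_values[name] = float(2.0 * stats.t.sf(abs(tstat), dof)) if np.isfinite(tstat) else 0.0
    identifiable = np.ptp(y) > 1e-12 and np.isfinite(se.get("b", np.nan)) and se["b"] > 0
    if np.ptp(y) <= 1e-12:
        p_values["b"] = 1.0
    return DoseResponseFit(
        b=float(b), e=float(np.exp(loge)), c=float(c), d=float(d),
        se=se, p_values=p_values, sse=sse, converged=bool(best.success),
        n_params=n_params, n_obs=n, identifiable=bool(identifiable),
    )
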