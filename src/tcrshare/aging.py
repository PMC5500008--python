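"""Exponential decay of fetal zero-insertion clonotypes with age.

The fraction Z of zero-insertion clonotypes among the top-K most abundant
clones decays with donor age T as

    Z ≈ c + a exp(-b T)

where c is the adult baseline of zero-insertion production, a the fetal
excess at birth and b the per-year decay rate of fetal clones (1/b is the
characteristic persistence time).  The attrition of the naive compartment
is fit analogously as

    N ≈ a' exp(-b' T)

and the *naive-confound curve* c + a exp(-b' T) shows what the Z decay
would look like if it were driven solely by naive-pool attrition: both
curves share the value c + a at birth and the long-time limit c.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import curve_fit

_B_STARTS = (0.005, 0.02, 0.08)


@dataclass(frozen=True)
class AgingObservation:
    """One donor's zero-insertion fraction (and optional naive fraction)."""

    donor_id: str
    age: float
    z: float
    n: float | None = None
    k: int = 2000

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if not 0.0 <= self.z <= 1.0:
            raise ValueError("Z must be a fraction in [0, 1]")
        if self.n is not None and not 0.0 <= self.n <= 1.0:
            raise ValueError("N must be a fraction in [0, 1]")


@dataclass
class DecayFit:
    """Fitted decay parameters with Jacobian-based standard errors."""

    c: float
    a: float
    b: float
    c_se: float
    a_se: float
    b_se: float
    a_naive: float | None = None
    b_naive: float | None = None
    a_naive_se: float | None = None
    b_naive_se: float | None = None
    ssr_z: float = np.nan
    ssr_n: float = np.nan
    residuals_z: np.ndarray | None = None
    k: int = 2000
    b_identifiable: bool = True


def _z_curve(t, c, a, b):
    return c + a * np.exp(-b * t)


def _n_curve(t, a, b):
    return a * np.exp(-b * t)


def _multi_start_fit(
    func, t: np.ndarray, y: np.ndarray, p0s: list[list[float]], bounds
) -> tuple[np.ndarray, np.ndarray, float]:
    best = None
    last_err: Exception | None = None
    for p0 in p0s:
        try:
            popt, pcov = curve_fit(func, t, y, p0=p0, bounds=bounds, maxfev=20_000)
        except RuntimeError as err:  # no convergence from this start
            last_err = err
            continue
        ssr = float(np.sum((y - func(t, *popt)) ** 2))
        if best is None or ssr < best[2]:
            best = (popt, pcov, ssr)
    if best is None:
        raise RuntimeError(f"decay fit failed to converge from all starts: {last_err}")
    return best


def fit_decay_models(obs: Sequence[AgingObservation]) -> DecayFit:
    """Nonlinear least squares for the Z and (when present) N decay models.

    Unweighted, bounded to c, a, a' in [0, 1] and b, b' in [0, 1] per year,
    with multi-start initialization over decay rates; the lowest final SSR
    is retained.  Standard errors come from the Jacobian-based covariance.
    A near-constant Z series leaves b unidentifiable; the fit is then
    flagged via ``b_identifiable``.
    """
    obs = list(obs)
    t = np.array([o.age for o in obs], dtype=float)
    z = np.array([o.z for o in obs], dtype=float)
    if len(set(t)) < 4:
        raise ValueError("need >= 4 observations with distinct ages for the Z fit")
    ks = {o.k for o in obs}
    k = ks.pop() if len(ks) == 1 else 0

    p0s = [[max(z.min(), 1e-4), max(z.max() - z.min(), 1e-4), b0] for b0 in _B_STARTS]
    popt, pcov, ssr = _multi_start_fit(
        _z_curve, t, z, p0s, bounds=([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
    )
    se = np.sqrt(np.diag(pcov))
    c_hat, a_hat, b_hat = map(float, popt)
    resid = z - _z_curve(t, *popt)
    # b is unidentifiable when the amplitude vanishes or its error explodes
    identifiable = a_hat > max(10.0 * se[1], 1e-6) and np.isfinite(se[2])

    fit = DecayFit(
        c_hat, a_hat, b_hat, *map(float, se),
        ssr_z=ssr, residuals_z=resid, k=k, b_identifiable=bool(identifiable),
    )

    n_obs = [(o.age, o.n) for o in obs if o.n is not None]
    if len({a for a, _ in n_obs}) >= 3:
        tn = np.array([a for a, _ in n_obs])
        yn = np.array([v for _, v in n_obs])
        p0s_n = [[max(yn.max(), 1e-3), b0] for b0 in _B_STARTS]
        popt_n, pcov_n, ssr_n = _multi_start_fit(
            _n_curve, tn, yn, p0s_n, bounds=([0.0, 0.0], [1.0, 1.0])
        )
        se_n = np.sqrt(np.diag(pcov_n))
        fit.a_naive, fit.b_naive = map(float, popt_n)
        fit.a_naive_se, fit.b_naive_se = map(float, se_n)
        fit.ssr_n = ssr_n
    return fit


def naive_confound_curve(fit: DecayFit) -> Callable[[np.ndarray], np.ndarray]:
    """Z decay expected if driven solely by naive-pool attrition.

    Anchored to the Z curve at age 0 (value c + a) and at long times
    (value c), but decaying at the naive rate b'.
    """
    if fit.b_naive is None:
        raise ValueError("naive decay fit missing; provide N observations")
    c, a, bp = fit.c, fit.a, fit.b_naive

    def curve(t):
        return c + a * np.exp(-bp * np.asarray(t, dtype=float))

    return curve


def characteristic_time(rate: float) -> float:
    """Characteristic decay time 1/rate, in years for a per-year rate."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return 1.0 / rate
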