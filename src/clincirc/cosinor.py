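"""Single-component cosinor rhythmometry.

Model: y(t) = M + A*cos(2*pi*(t - phi)/tau) with mesor M, amplitude A >= 0,
acrophase phi (time of model maximum, hours, reduced mod tau) and period tau.
For fixed tau the fit is exact linear least squares on {1, cos, sin}; the
free-period fit profiles the linear solution over tau.

Free-period search. SSE(tau) is evaluated on a frequency grid with spacing
1/(oversample * span) — the natural resolution of a span-T record — between
1/tau_max and an anti-aliasing floor of twice the median sampling interval,
then the best grid point is polished by bounded scalar minimization. The
floor matters: with regular 4-h sampling, periods near the sampling interval
alias slowly drifting long-period segments (tau = 4.8 h reproduces a 24-h
rhythm exactly on a 4-h grid), so sub-Nyquist periods are excluded rather
than reported. Natural harmonics and the 24-h nominal period are always
included as candidate starts.

The zero-amplitude test is the classical cosinor F-test of the 3-parameter
harmonic model (at the fitted period) against the mesor-only model, on
(2, n-3) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .series import SampledSeries

__all__ = [
    "CosinorFit",
    "fit_fixed_period",
    "fit_free_period",
    "zero_amplitude_test",
    "diagnostics",
    "cosinor_call",
    "predict",
]

_DEFAULT_BOUNDS = (18.0, 30.0)


@dataclass(frozen=True)
class CosinorFit:
    """Fitted cosinor parameters plus diagnostics."""

    mesor: float
    amplitude: float  # >= 0, expression units
    acrophase: float  # hours in [0, period)
    period: float  # hours
    r2: float
    adj_r2: float
    leverage_distance: float  # max_i |y_i - yhat(t_i)|
    zero_amp_pvalue: float
    converged: bool
    n: int
    n_params: int  # 3 with fixed period, 4 with free period
    sse: float
    sst: float

    @property
    def relative_amplitude(self) -> float:
        """Amplitude / mesor; defined only for positive mesor."""
        return self.amplitude / self.mesor if self.mesor > 0 else float("nan")


def predict(fit: CosinorFit, t: np.ndarray) -> np.ndarray:
    """Evaluate the fitted sinusoid at times t (hours)."""
    t = np.asarray(t, float)
    return fit.mesor + fit.amplitude * np.cos(
        2 * np.pi * (t - fit.acrophase) / fit.period
    )


def _design(t: np.ndarray, tau: float) -> np.ndarray:
    w = 2 * np.pi / tau
    return np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])


def _linear_fit(t: np.ndarray, y: np.ndarray, tau: float):
    """Exact LS of {1, cos, sin} at period tau -> (sse, mesor, A, phi)."""
    X = _design(t, tau)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise np.linalg.LinAlgError("rank-deficient cosinor design")
    r = y - X @ beta
    sse = float(r @ r)
    M, a, b = beta
    A = float(np.hypot(a, b))
    phi = (np.arctan2(b, a) / (2 * np.pi)) * tau % tau
    return sse, float(M), A, float(phi)


def _sse_only(t: np.ndarray, y: np.ndarray, tau: float) -> float:
    try:
        return _linear_fit(t, y, tau)[0]
    except np.linalg.LinAlgError:
        return float("inf")


def _finalize(
    t: np.ndarray,
    y: np.ndarray,
    M: float,
    A: float,
    phi: float,
    tau: float,
    n_params: int,
    sse: float,
    converged: bool,
) -> CosinorFit:
    n = t.size
    sst = float(np.sum((y - y.mean()) ** 2))
    yhat = M + A * np.cos(2 * np.pi * (t - phi) / tau)
    leverage = float(np.max(np.abs(y - yhat)))
    if sst > 0:
        r2 = 1.0 - sse / sst
        adj = (
            1.0 - (1.0 - r2) * (n - 1) / (n - n_params)
            if n > n_params
            else float("nan")
        )
    else:
        r2 = float("nan")
        adj = float("nan")
    p = _ftest_pvalue(sse, sst, n)
    return CosinorFit(
        mesor=float(M),
        amplitude=float(A),
        acrophase=float(phi % tau),
        period=float(tau),
        r2=r2,
        adj_r2=adj,
        leverage_distance=leverage,
        zero_amp_pvalue=p,
        converged=converged,
        n=int(n),
        n_params=n_params,
        sse=float(sse),
        sst=sst,
    )


def _ftest_pvalue(sse: float, sst: float, n: int) -> float:
    if n - 3 < 1:
        raise ValueError("zero-amplitude test needs at least 1 residual df")
    if sst <= 0:  # constant data: nothing to explain
        return 1.0
    sse = max(sse, 0.0)
    if sse == 0.0:
        return 0.0
    F = ((sst - sse) / 2.0) / (sse / (n - 3))
    return float(stats.f.sf(max(F, 0.0), 2, n - 3))


def fit_fixed_period(s: SampledSeries, tau: float) -> CosinorFit:
    """Cosinor fit at a known period (exact linear least squares)."""
    s.require_usable()
    if tau <= 0:
        raise ValueError("period must be positive")
    try:
        sse, M, A, phi = _linear_fit(s.times, s.values, tau)
    except np.linalg.LinAlgError as e:
        raise ValueError(
            f"cosinor design matrix is rank-deficient at tau={tau:g} h "
            f"(times may be congruent modulo tau/2)"
        ) from e
    return _finalize(s.times, s.values, M, A, phi, tau, 3, sse, True)


def fit_free_period(
    s: SampledSeries,
    bounds: tuple[float, float] | None = None,
    *,
    amplitude_cap: float | None = None,
    oversample: int = 5,
    nominal_period: float = 24.0,
) -> CosinorFit:
    """Cosinor fit with the period estimated by profile least squares.

    Parameters
    ----------
    bounds
        (low, high) period bounds in hours; when absent the period is
        searched over [4 h, 4*span] above the anti-aliasing floor.
    amplitude_cap
        Optional upper bound on the fitted amplitude (expression units).
    """
    s.require_usable()
    t, y = s.times, s.values
    span = s.span
    dt = float(np.median(np.diff(t)))
    alias_floor = 2.0 * dt
    if bounds is None:
        lo, hi = 4.0, 4.0 * span
    else:
        lo, hi = float(bounds[0]), float(bounds[1])
        if not lo < hi:
            raise ValueError("period bounds must satisfy low < high")
    lo = max(lo, alias_floor)
    if lo >= hi:
        raise ValueError("period search range collapsed below the aliasing floor")

    # frequency grid at the record's natural resolution, plus harmonic starts
    df = 1.0 / (oversample * span)
    freqs = np.arange(1.0 / hi, 1.0 / lo + df, df)
    taus = 1.0 / freqs
    harmonics = span / np.arange(1, t.size // 2 + 1)
    extra = [p for p in np.r_[harmonics, nominal_period] if lo <= p <= hi]
    taus = np.unique(np.clip(np.r_[taus, extra, lo, hi], lo, hi))

    sses = np.array([_sse_only(t, y, tau) for tau in taus])
    i = int(np.argmin(sses))
    bracket_lo = taus[max(i - 1, 0)]
    bracket_hi = taus[min(i + 1, taus.size - 1)]
    converged = True
    if bracket_hi > bracket_lo:
        res = optimize.minimize_scalar(
            lambda tau: _sse_only(t, y, tau),
            bounds=(bracket_lo, bracket_hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        tau_hat = float(res.x) if res.fun <= sses[i] else float(taus[i])
        converged = bool(res.success)
    else:
        tau_hat = float(taus[i])

    sse, M, A, phi = _linear_fit(t, y, tau_hat)

    if amplitude_cap is not None and A > amplitude_cap:
        sse, M, A, phi = _capped_fit(t, y, tau_hat, amplitude_cap, phi)
    return _finalize(t, y, M, A, phi, tau_hat, 4, sse, converged)


def _capped_fit(t, y, tau, cap, phi0):
    """LS fit with amplitude fixed at the cap: optimize acrophase (1-D),
    mesor solved in closed form."""

    def sse_phi(phi):
        h = cap * np.cos(2 * np.pi * (t - phi) / tau)
        M = float(np.mean(y - h))
        r = y - M - h
        return float(r @ r), M

    res = optimize.minimize_scalar(
        lambda p: sse_phi(p)[0], bounds=(phi0 - tau / 2, phi0 + tau / 2),
        method="bounded", options={"xatol": 1e-8},
    )
    phi = float(res.x) % tau
    sse, M = sse_phi(phi)
    return sse, M, float(cap), phi


def zero_amplitude_test(fit: CosinorFit, s: SampledSeries) -> float:
    """F-test of the harmonic model at the fitted period against mesor-only.

    Returns the p-value; small values indicate a rhythm.
    """
    if s.n - 3 < 1:
        raise ValueError("zero-amplitude test needs at least 1 residual df")
    return _ftest_pvalue(fit.sse, fit.sst, s.n)


def diagnostics(fit: CosinorFit, s: SampledSeries) -> tuple[float, float, float]:
    """(r2, adjusted r2, leverage distance) of a fit on its own series.

    Leverage distance is the maximum absolute deviation between an
    observation and the fitted oscillation — the overfitting diagnostic used
    to compare detection methods.
    """
    if fit.sst <= 0:
        raise ValueError("r2 undefined for a constant series (SST = 0)")
    return fit.r2, fit.adj_r2, fit.leverage_distance


def cosinor_call(
    s: SampledSeries,
    bounds: tuple[float, float] = _DEFAULT_BOUNDS,
    alpha: float = 0.05,
    *,
    period_mode: str = "free_inband",
) -> bool:
    """Standalone cosinor detector (no periodogram gate, no loose filter).

    ``period_mode`` selects how the classical single-step cosinor decides:

    - ``"free_inband"`` (default): fit with an unconstrained period; call a
      rhythm when the fitted period lands inside ``bounds`` and the full
      4-parameter sinusoid beats the mesor-only model in an F-test on
      (3, n-4) degrees of freedom — the honest df count when the period is
      estimated rather than assumed.
    - ``"bounded"``: fit with the period constrained to ``bounds``, then the
      classical zero-amplitude test on (2, n-3) df.
    - ``"fixed24"``: fit at exactly 24 h, then the zero-amplitude test.
    """
    if period_mode == "free_inband":
        fit = fit_free_period(s)
        if not (bounds[0] <= fit.period <= bounds[1]):
            return False
        if fit.sst <= 0 or s.n <= 4:
            return False
        F = ((fit.sst - fit.sse) / 3.0) / (fit.sse / (s.n - 4)) if fit.sse > 0 else np.inf
        p = float(stats.f.sf(max(F, 0.0), 3, s.n - 4))
        return bool(p < alpha)
    if period_mode == "bounded":
        fit = fit_free_period(s, bounds=bounds)
    elif period_mode == "fixed24":
        fit = fit_fixed_period(s, 24.0)
    else:
        raise ValueError(f"unknown period_mode {period_mode!r}")
    return bool(fit.zero_amp_pvalue < alpha)
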