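"""Gamma-Gaussian pulse wave decomposition and morphological features.

A single PPG beat is modelled as the sum of two kernels,

.. math::

    y(t) = s_1 \\frac{\\beta_1^{\\alpha_1}}{\\Gamma(\\alpha_1)}
           t^{\\alpha_1 - 1} e^{-\\beta_1 t}
         + a_2 \\exp\\!\\left(-\\frac{(t - \\mu_2)^2}{2\\sigma_2^2}\\right),

a scaled Gamma probability density capturing the systolic upstroke and peak,
and a Gaussian capturing the diastolic wave.  The Gamma kernel peaks at its
mode ``mu1 = (alpha1 - 1) / beta1`` with peak value ``a1``; the fit enforces
that the systolic kernel comes first (``mu1 < mu2``) and dominates
(``a1 > a2``).  Fitting the model to a beat template and re-evaluating it
("recomposition") denoises the beat before the four morphological features —
amplitude, slope, area and pulse width at half amplitude (PWHA) — are read
off the recomposed waveform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal as sps
from scipy.special import digamma, gammaln

__all__ = [
    "KernelParams",
    "MorphFeatures",
    "FitResult",
    "gamma_kernel",
    "gaussian_kernel",
    "recompose",
    "fit",
    "extract_features",
    "template_to_features",
]


class FitError(RuntimeError):
    """Raised when the decomposition cannot be fitted to a template."""


class _SkipPolish(Exception):
    """Internal control flow: refinement not worthwhile for this fit."""


@dataclass(frozen=True)
class KernelParams:
    """Parameter vector of the two-kernel beat model.

    Attributes
    ----------
    s1 : float
        Area scale of the Gamma kernel (signal units * s); the kernel
        integrates to ``s1`` over ``[0, inf)``.
    alpha1 : float
        Gamma shape, dimensionless; must exceed 1 so the kernel vanishes
        at t = 0.
    beta1 : float
        Gamma rate in 1/s; positive.
    a2 : float
        Gaussian amplitude in signal units.
    mu2 : float
        Gaussian centre in seconds.
    sigma2 : float
        Gaussian width in seconds; positive.
    """

    s1: float
    alpha1: float
    beta1: float
    a2: float
    mu2: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.alpha1 <= 1:
            raise ValueError(f"Gamma shape alpha1 must exceed 1, got {self.alpha1}")
        if self.beta1 <= 0:
            raise ValueError(f"Gamma rate beta1 must be positive, got {self.beta1}")
        if self.sigma2 <= 0:
            raise ValueError(f"Gaussian width sigma2 must be positive, got {self.sigma2}")

    @property
    def mu1(self) -> float:
        """Mode of the Gamma kernel (time of the systolic peak), s."""
        return (self.alpha1 - 1.0) / self.beta1

    @property
    def a1(self) -> float:
        """Peak value of the Gamma kernel, signal units."""
        mu1 = self.mu1
        log_peak = (self.alpha1 * np.log(self.beta1) - gammaln(self.alpha1)
                    + (self.alpha1 - 1.0) * np.log(mu1) - self.beta1 * mu1)
        return self.s1 * float(np.exp(log_peak))

    def as_array(self) -> np.ndarray:
        return np.array([self.s1, self.alpha1, self.beta1,
                         self.a2, self.mu2, self.sigma2])

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "KernelParams":
        return cls(*(float(v) for v in theta))

    def scaled(self, factors: dict[str, float]) -> "KernelParams":
        """Return a copy with named parameters multiplied by factors."""
        values = {f: getattr(self, f) for f in
                  ("s1", "alpha1", "beta1", "a2", "mu2", "sigma2")}
        for name, factor in factors.items():
            if name not in values:
                raise KeyError(f"unknown kernel parameter {name!r}")
            values[name] *= factor
        return KernelParams(**values)


@dataclass(frozen=True)
class MorphFeatures:
    """The four morphological beat features.

    amplitude : peak height above the beat minimum (signal units)
    slope     : maximum of the first derivative (signal units / s)
    area      : trapezoidal area above the beat minimum (signal units * s)
    pwha      : pulse width at half amplitude (s)
    """

    amplitude: float
    slope: float
    area: float
    pwha: float

    def as_dict(self) -> dict[str, float]:
        return {"amplitude": self.amplitude, "slope": self.slope,
                "area": self.area, "pwha": self.pwha}

    @staticmethod
    def names() -> tuple[str, ...]:
        return ("amplitude", "slope", "area", "pwha")


def gamma_kernel(t: np.ndarray, s1: float, alpha1: float, beta1: float) -> np.ndarray:
    """Scaled Gamma density, evaluated in log space for numerical range."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    log_k = (alpha1 * np.log(beta1) - gammaln(alpha1)
             + (alpha1 - 1.0) * np.log(tp) - beta1 * tp)
    out[pos] = s1 * np.exp(log_k)
    return out


def gaussian_kernel(t: np.ndarray, a2: float, mu2: float, sigma2: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return a2 * np.exp(-((t - mu2) ** 2) / (2.0 * sigma2**2))


def recompose(params: KernelParams, t: np.ndarray) -> np.ndarray:
    """Evaluate the two-kernel beat model on a time grid (seconds)."""
    t = np.asarray(t, dtype=float)
    if t.size == 0:
        return np.empty(0)
    return (gamma_kernel(t, params.s1, params.alpha1, params.beta1)
            + gaussian_kernel(t, params.a2, params.mu2, params.sigma2))


def random_admissible_params(rng: np.random.Generator,
                             beat_duration: float = 1.0) -> KernelParams:
    """Draw a physiologically shaped parameter set satisfying the fit
    constraints: systolic Gamma peak before and above the diastolic
    Gaussian, both kernels well inside the beat."""
    alpha1 = float(rng.uniform(2.0, 5.0))
    mu1 = float(rng.uniform(0.08, 0.22)) * beat_duration
    beta1 = (alpha1 - 1.0) / mu1
    a1 = float(rng.uniform(0.8, 2.0))
    ref = KernelParams(1.0, alpha1, beta1, 0.0, 0.5, 0.05)
    s1 = a1 / ref.a1
    a2 = float(rng.uniform(0.15, 0.6)) * a1
    mu2 = float(rng.uniform(mu1 + 0.12 * beat_duration, 0.55 * beat_duration))
    sigma2 = float(rng.uniform(0.04, 0.12)) * beat_duration
    return KernelParams(s1, alpha1, beta1, a2, mu2, sigma2)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    params: KernelParams
    residual_rms: float
    n_starts: int


def _initial_guesses(t: np.ndarray, y_raw: np.ndarray,
                     rng: np.random.Generator,
                     n_starts: int) -> list[np.ndarray]:
    """Heuristic starts: systolic kernel at the template argmax, diastolic
    Gaussian behind it, then jittered copies.  The landmark search runs on
    a lightly smoothed copy so template noise cannot plant the diastolic
    guess on a spike."""
    from scipy.ndimage import uniform_filter1d

    y = uniform_filter1d(y_raw, size=max(3, y_raw.size // 40),
                         mode="nearest")
    i_max = int(np.argmax(y))
    mu1_0 = max(t[i_max], t[-1] * 0.05)
    a1_0 = max(y[i_max], 1e-6)
    # secondary hump: most prominent local max after the global max, else
    # fall back to 1.5x the systolic peak time
    mu2_0 = min(1.5 * mu1_0, t[-1] * 0.9)
    a2_0 = 0.4 * a1_0
    tail = y[i_max + 1:]
    if tail.size > 2:
        peaks, props = sps.find_peaks(tail, prominence=0.02 * a1_0)
        if peaks.size:
            j = peaks[int(np.argmax(props["prominences"]))] + i_max + 1
            mu2_0 = t[j]
            a2_0 = max(0.8 * y[j], 0.05 * a1_0)
    sigma2_0 = 0.1 * (t[-1] - t[0])
    alpha1_0 = 3.0
    beta1_0 = (alpha1_0 - 1.0) / mu1_0
    # s1 so that the Gamma peak value matches the template max
    ref = KernelParams(1.0, alpha1_0, beta1_0, 0.0, mu2_0, sigma2_0)
    s1_0 = a1_0 / ref.a1
    base = np.array([s1_0, alpha1_0, beta1_0, a2_0, mu2_0, sigma2_0])
    guesses = [base]
    # deterministic sweep of the diastolic-kernel position: the Gaussian
    # location is the least identifiable landmark, so cover its admissible
    # range before falling back on random jitter
    duration = t[-1] - t[0]
    for frac in (1.25, 1.8, 2.5):
        mu2_c = min(frac * mu1_0, 0.75 * duration)
        j = min(len(y) - 1, int(np.searchsorted(t, mu2_c)))
        g = base.copy()
        g[4] = mu2_c
        g[3] = np.clip(y[j], 0.05 * a1_0, 0.9 * a1_0)
        guesses.append(g)
    while len(guesses) < n_starts:
        jitter = rng.uniform(0.6, 1.5, size=6)
        g = base * jitter
        g[1] = max(g[1], 1.2)
        guesses.append(g)
    return guesses[:n_starts]


def fit(template, *, n_starts: int = 10, rms_tol: float = 5e-4,
        seed: int = 0, max_grid: int = 400) -> FitResult:
    """Fit the two-kernel model to a beat template by constrained least
    squares.

    The template's time axis is shifted so its first sample maps to t = 0,
    and its minimum is subtracted so the non-negative kernel model sees a
    zero-anchored beat.  Constraints ``a1 > a2`` (systolic kernel dominates)
    and ``mu1 < mu2`` (systolic kernel first) are enforced as inequality
    constraints with a small margin.  Up to ``n_starts`` jittered starts are
    tried; the search stops early when a start fits essentially exactly
    (residual RMS below ``rms_tol`` times the beat amplitude) or when two
    starts agree on the residual, indicating a shared basin; otherwise the
    best residual wins.

    Parameters
    ----------
    template
        Object with ``values`` (1-D array) and ``fs`` attributes; a
        :class:`~coldwave.beats.BeatTemplate` or a bare sampled beat.
    max_grid : int
        Templates longer than this are fitted on a decimated grid (the
        objective is evaluated on every k-th sample); the model is smooth at
        the beat time scale so this loses no information.

    Raises
    ------
    FitError
        if no start converges to a feasible solution.
    """
    y_full = np.asarray(template.values, dtype=float)
    fs = float(template.fs)
    if y_full.size < 8:
        raise FitError("template too short to fit")
    if not np.isfinite(y_full).all():
        raise FitError("template contains non-finite values")
    # detrended templates sit around zero and need re-anchoring at their
    # minimum; a non-negative beat already lives on the model's baseline.
    # The minimum is taken on a lightly smoothed copy so sample noise does
    # not push the anchor below the true floor.
    from scipy.ndimage import uniform_filter1d

    y_smooth = uniform_filter1d(y_full, size=max(3, y_full.size // 40),
                                mode="nearest")
    baseline = min(float(y_smooth.min()), 0.0)
    y0 = y_full - baseline
    # white-noise floor of the template, from the high-frequency residual
    # (the beat itself is smooth at the few-millisecond scale)
    hf = y_full - uniform_filter1d(y_full, size=9, mode="nearest")
    noise_rms = float(np.std(hf)) * np.sqrt(9.0 / 8.0)
    amp = y0.max()
    if amp <= 0:
        raise FitError("template has no positive excursion")

    step = max(1, int(np.ceil(y0.size / max_grid)))
    y = y0[::step]
    t = np.arange(y_full.size)[::step] / fs

    duration = t[-1]
    eps_a = 1e-3 * amp     # margin for a1 > a2
    eps_mu = 1e-3 * duration  # margin for mu1 < mu2

    pos = t > 0
    tp = t[pos]
    log_tp = np.log(tp)
    _cache: dict = {"x": None, "parts": None}

    def _model_parts_impl(x):
        """Model values and analytic partials w.r.t. the six parameters."""
        s1, alpha1, beta1, a2, mu2, sigma2 = x
        k = np.zeros_like(t)   # unit-scale Gamma kernel
        k[pos] = np.exp(alpha1 * np.log(beta1) - gammaln(alpha1)
                        + (alpha1 - 1.0) * log_tp - beta1 * tp)
        gam = s1 * k
        z = (t - mu2) / sigma2
        e = np.exp(-0.5 * z * z)
        gau = a2 * e
        jac = np.empty((6, t.size))
        jac[0] = k
        dk = np.zeros_like(t)
        dk[pos] = np.log(beta1) - digamma(alpha1) + log_tp
        jac[1] = gam * dk
        jac[2] = gam * (alpha1 / beta1 - t)
        jac[3] = e
        jac[4] = gau * z / sigma2
        jac[5] = gau * z * z / sigma2
        return gam + gau, jac

    def _model_parts(x):
        # objective and gradient are evaluated at the same point in turn
        if _cache["x"] is None or not np.array_equal(_cache["x"], x):
            _cache["x"] = np.array(x, copy=True)
            _cache["parts"] = _model_parts_impl(x)
        return _cache["parts"]

    def objective(x):
        m, _ = _model_parts(x)
        r = m - y
        return float(r @ r)

    def objective_grad(x):
        m, jac = _model_parts(x)
        r = m - y
        return 2.0 * (jac @ r)

    def gamma_peak(x):
        s1, alpha1, beta1 = x[0], x[1], x[2]
        mu1 = (alpha1 - 1.0) / beta1
        log_peak = (alpha1 * np.log(beta1) - gammaln(alpha1)
                    + (alpha1 - 1.0) * np.log(mu1) - beta1 * mu1)
        return s1 * np.exp(log_peak)

    def gamma_peak_grad(x):
        s1, alpha1, beta1 = x[0], x[1], x[2]
        mu1 = (alpha1 - 1.0) / beta1
        log_peak = (alpha1 * np.log(beta1) - gammaln(alpha1)
                    + (alpha1 - 1.0) * np.log(mu1) - beta1 * mu1)
        a1 = s1 * np.exp(log_peak)
        g = np.zeros(6)
        g[0] = np.exp(log_peak)
        # total derivatives through mu1(alpha1, beta1) collapse because
        # beta1 * mu1 = alpha1 - 1 at the mode
        g[1] = a1 * (np.log(beta1) - digamma(alpha1) + np.log(mu1))
        g[2] = a1 * (alpha1 / beta1 - mu1)
        return g

    def c1_grad(x):
        g = gamma_peak_grad(x)
        g[3] -= 1.0
        return g

    def c2_grad(x):
        return np.array([0.0, -1.0 / x[2], (x[1] - 1.0) / x[2] ** 2,
                         0.0, 1.0, 0.0])

    constraints = [
        {"type": "ineq", "fun": lambda x: gamma_peak(x) - x[3] - eps_a,
         "jac": c1_grad},
        {"type": "ineq",
         "fun": lambda x: x[4] - (x[1] - 1.0) / x[2] - eps_mu,
         "jac": c2_grad},
    ]
    bounds = [
        (0.0, None),            # s1
        (1.0 + 1e-6, 50.0),     # alpha1
        (1e-3, None),           # beta1
        (0.0, None),            # a2
        (0.0, 2.0 * duration),  # mu2
        (1e-4, duration),       # sigma2
    ]

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray] | None = None
    tried = 0
    # stop once the residual cannot be distinguished from an exact fit:
    # either essentially zero, or at the template's own noise floor
    stop_rms = max(rms_tol * amp, 1.15 * noise_rms)
    stop_sse = stop_rms**2 * y.size
    for x0 in _initial_guesses(t, y, rng, n_starts):
        tried += 1
        try:
            res = optimize.minimize(
                objective, x0, jac=objective_grad, method="SLSQP",
                bounds=bounds, constraints=constraints,
                options={"maxiter": 500, "ftol": 1e-14})
        except (ValueError, FloatingPointError):
            continue
        if not np.isfinite(res.fun):
            continue
        x = res.x
        # feasibility within a tolerance of the margin
        if gamma_peak(x) - x[3] < 0 or x[4] < (x[1] - 1.0) / x[2]:
            continue
        if best is None or res.fun < best[0]:
            best = (res.fun, x)
        if res.fun < stop_sse:
            break
    if best is None:
        raise FitError("decomposition did not converge from any start")
    sse, x = best

    # Levenberg-Marquardt-style polish: the SLSQP valley around the optimum
    # is nearly flat along correlated parameter directions; a bounded
    # least-squares refinement tightens the last digits.  Only worthwhile
    # when the residual is already close to exact — templates dominated by
    # shape mismatch gain nothing from it.
    def residuals(x):
        return _model_parts(x)[0] - y

    def res_jac(x):
        return _model_parts(x)[1].T

    polish_worthwhile = sse <= (0.05 * amp) ** 2 * y.size
    try:
        if not polish_worthwhile:
            raise _SkipPolish
        lb = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])
        ub = np.array([b[1] if b[1] is not None else np.inf for b in bounds])
        polish = optimize.least_squares(
            residuals, np.clip(x, lb + 1e-12, ub - 1e-12), jac=res_jac,
            bounds=(lb, ub), method="trf", xtol=1e-15, ftol=1e-15,
            gtol=1e-15, max_nfev=3000)
        xp = polish.x
        feasible = (gamma_peak(xp) - xp[3] >= 0
                    and xp[4] >= (xp[1] - 1.0) / xp[2])
        if feasible and 2 * polish.cost < sse:
            sse, x = 2 * polish.cost, xp
    except (_SkipPolish, ValueError, FloatingPointError):
        pass
    params = KernelParams.from_array(x)
    rms = float(np.sqrt(sse / y.size))
    return FitResult(params=params, residual_rms=rms, n_starts=tried)


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def _half_crossing(t: np.ndarray, y: np.ndarray, level: float,
                   i_peak: int, direction: int) -> float:
    """Linear-interpolated crossing of ``level`` nearest the peak.

    direction -1: first crossing before the global max (rising edge);
    direction +1: first crossing after it (falling edge).
    """
    if direction < 0:
        idx = range(i_peak, 0, -1)
        for i in idx:
            if y[i - 1] <= level <= y[i]:
                f = (level - y[i - 1]) / (y[i] - y[i - 1])
                return t[i - 1] + f * (t[i] - t[i - 1])
    else:
        idx = range(i_peak, len(y) - 1)
        for i in idx:
            if y[i] >= level >= y[i + 1]:
                f = (y[i] - level) / (y[i] - y[i + 1])
                return t[i] + f * (t[i + 1] - t[i])
    raise ValueError("no half-amplitude crossing found (flat beat?)")


def extract_features(values: np.ndarray, fs: float) -> MorphFeatures:
    """Morphological features of a (recomposed) beat.

    The beat minimum serves as the baseline: amplitude and area are measured
    above it.  The slope is the maximum of the central-difference first
    derivative.  PWHA spans from the last half-amplitude crossing before the
    global maximum to the first one after it, so a pronounced diastolic wave
    re-crossing half amplitude does not inflate the width.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 3:
        raise ValueError("beat must have at least 3 samples")
    t = np.arange(y.size) / fs
    base = y.min()
    yb = y - base
    i_peak = int(np.argmax(yb))
    amplitude = float(yb[i_peak])
    if amplitude <= 0:
        raise ValueError("beat has no positive excursion above its minimum")
    slope = float(np.max(np.gradient(y, 1.0 / fs)))
    area = float(np.trapezoid(yb, t))
    half = amplitude / 2.0
    t_rise = _half_crossing(t, yb, half, i_peak, -1)
    t_fall = _half_crossing(t, yb, half, i_peak, +1)
    return MorphFeatures(amplitude=amplitude, slope=slope, area=area,
                         pwha=float(t_fall - t_rise))


def template_to_features(template, *, seed: int = 0,
                         n_starts: int = 6) -> tuple[KernelParams, MorphFeatures, dict]:
    """Fit, recompose and measure one template.

    Returns the fitted kernel parameters, the features of the recomposed
    (denoised) beat, and a QC record with the fit residual and the
    template's provenance counters when present.
    """
    result = fit(template, n_starts=n_starts, seed=seed)
    fs = float(template.fs)
    t = np.arange(np.asarray(template.values).size) / fs
    denoised = recompose(result.params, t)
    features = extract_features(denoised, fs)
    qc = {
        "residual_rms": result.residual_rms,
        "n_starts": result.n_starts,
        "n_beats_used": getattr(template, "n_beats_used", None),
        "mean_pairwise_corr": getattr(template, "mean_pairwise_corr", None),
    }
    return result.params, features, qc
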