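"""Validation-assay numerics: SPR 1:1 kinetics and thermal-shift T_M.

SPR
---
The 1:1 Langmuir interaction A + B <-> AB gives, for analyte concentration
C injected at t = 0 over a surface with capacity Rmax:

    association:  R(t) = Req + (R0 - Req) exp(-(ka C + kd) t),
                  Req  = ka C Rmax / (ka C + kd)
    dissociation: R(t) = R(t_a) exp(-kd (t - t_a))

with ka in 1/(M s), kd in 1/s, and K_D = kd/ka.  Fitting is a global
nonlinear least-squares over all concentrations sharing (ka, kd, Rmax) —
standard Biacore practice — with multi-start initialisation (log-spaced
over ka in [1e3, 1e7], kd in [1e-5, 1e-1]) and best-chi-square selection.

Thermal shift
-------------
The melting temperature is the extremum of the first derivative of the
smoothed fluorescence-vs-temperature curve.  Dye-binding (SYPRO Orange
style) unfolding curves rise through the transition, so the peak is in
+dF/dT; instruments that report -dF/dT flip the sign.  The sign is
auto-detected from the overall trend by default and can be forced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize
from scipy.signal import savgol_filter

__all__ = [
    "Trace",
    "Sensorgram",
    "KineticFit",
    "MeltCurve",
    "TmResult",
    "simulate_sensorgram",
    "fit_langmuir",
    "simulate_melt_curve",
    "tm_from_melt",
    "delta_tm",
]


# ---------------------------------------------------------------------------
# Sensorgrams
# ---------------------------------------------------------------------------

@dataclass
class Trace:
    """One analyte concentration's time course (association + dissociation)."""

    concentration_nM: float
    time: np.ndarray  # s, strictly increasing, starts at injection
    response: np.ndarray  # RU
    t_assoc_end: float  # s; association phase is time <= t_assoc_end

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape:
            raise ValueError("time and response shapes differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("non-finite responses")
        if self.t_assoc_end <= self.time[0]:
            raise ValueError("association must precede dissociation")


@dataclass
class Sensorgram:
    traces: list[Trace]
    metadata: dict = field(default_factory=dict)


@dataclass
class KineticFit:
    ka: float  # 1/(M s)
    kd: float  # 1/s
    rmax: float  # RU
    chi2: float  # sum(residual^2) / (N - p)
    residuals: np.ndarray
    n_points: int

    def __post_init__(self):
        if min(self.ka, self.kd, self.rmax) <= 0:
            raise ValueError("fitted parameters must be positive")

    @property
    def kd_nM(self) -> float:
        """Equilibrium K_D = kd/ka, in nM."""
        return self.kd / self.ka * 1e9


def _langmuir_trace(time, t_assoc_end, conc_M, ka, kd, rmax):
    t = np.asarray(time, dtype=float)
    kobs = ka * conc_M + kd
    req = ka * conc_M * rmax / kobs if kobs > 0 else 0.0
    r = np.where(t <= t_assoc_end,
                 req * (1.0 - np.exp(-kobs * t)),
                 0.0)
    r_at_end = req * (1.0 - math.exp(-kobs * t_assoc_end))
    dissoc = t > t_assoc_end
    r[dissoc] = r_at_end * np.exp(-kd * (t[dissoc] - t_assoc_end))
    return r


def simulate_sensorgram(
    ka: float,
    kd: float,
    rmax: float,
    concentrations_nM,
    t_assoc_end: float = 120.0,
    t_end: float = 300.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Sensorgram:
    """Noisy 1:1 Langmuir sensorgram set, bit-reproducible under ``seed``."""
    if min(ka, kd, rmax) <= 0:
        raise ValueError("kinetic parameters must be positive")
    rng = np.random.default_rng(seed)
    traces = []
    time = np.arange(0.0, t_end + dt / 2, dt)
    for c in concentrations_nM:
        r = _langmuir_trace(time, t_assoc_end, c * 1e-9, ka, kd, rmax)
        if noise_sd > 0:
            r = r + rng.normal(0.0, noise_sd, size=r.shape)
        traces.append(Trace(concentration_nM=c, time=time.copy(), response=r,
                            t_assoc_end=t_assoc_end))
    return Sensorgram(traces=traces,
                      metadata={"ka": ka, "kd": kd, "rmax": rmax,
                                "noise_sd": noise_sd, "seed": seed})


_START_GRID = [(1e3, 1e-5), (1e5, 1e-3), (1e7, 1e-1)]


def fit_langmuir(sg: Sensorgram, starts=None) -> KineticFit:
    """Global 1:1 fit sharing (ka, kd, Rmax) across all concentrations.

    Parameters vary on a log10 scale (positivity by construction); three
    log-spaced starts are tried and the best reduced chi-square wins, which
    makes the result deterministic for given data.  A single-concentration
    sensorgram is allowed but ka and Rmax are then strongly correlated.
    """
    import warnings

    if not sg.traces:
        raise ValueError("empty sensorgram")
    if len(sg.traces) < 2:
        warnings.warn("single-concentration fit: ka and Rmax may be poorly "
                      "determined", stacklevel=2)
    for tr in sg.traces:
        n_assoc = int(np.sum(tr.time <= tr.t_assoc_end))
        if n_assoc < 10 or tr.time.size - n_assoc < 10:
            raise ValueError("need >= 10 points per phase in every trace")

    r_scale = max(float(np.max(np.abs(tr.response))) for tr in sg.traces)
    if r_scale == 0:
        raise ValueError("all-zero responses")

    def residual(params):
        ka = 10.0 ** params["log_ka"].value
        kd = 10.0 ** params["log_kd"].value
        rmax = 10.0 ** params["log_rmax"].value
        res = [tr.response - _langmuir_trace(tr.time, tr.t_assoc_end,
                                             tr.concentration_nM * 1e-9,
                                             ka, kd, rmax)
               for tr in sg.traces]
        return np.concatenate(res)

    best = None
    diagnostics = []
    for ka0, kd0 in (starts or _START_GRID):
        params = Parameters()
        params.add("log_ka", value=math.log10(ka0), min=0.0, max=10.0)
        params.add("log_kd", value=math.log10(kd0), min=-8.0, max=2.0)
        params.add("log_rmax", value=math.log10(r_scale), min=math.log10(r_scale) - 3,
                   max=math.log10(r_scale) + 3)
        try:
            out = minimize(residual, params, method="least_squares")
        except Exception as exc:  # pragma: no cover - lmfit internal failure
            diagnostics.append(f"start ({ka0:g}, {kd0:g}): {exc}")
            continue
        if not out.success:
            diagnostics.append(f"start ({ka0:g}, {kd0:g}): no convergence")
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        raise RuntimeError("Langmuir fit failed from all starts: "
                           + "; ".join(diagnostics))
    ka = 10.0 ** best.params["log_ka"].value
    kd = 10.0 ** best.params["log_kd"].value
    rmax = 10.0 ** best.params["log_rmax"].value
    resid = residual(best.params)
    n, p = resid.size, 3
    return KineticFit(ka=ka, kd=kd, rmax=rmax,
                      chi2=float(np.sum(resid ** 2)) / (n - p),
                      residuals=resid, n_points=n)


# ---------------------------------------------------------------------------
# Melt curves
# ---------------------------------------------------------------------------

@dataclass
class MeltCurve:
    temperature: np.ndarray  # deg C, strictly increasing
    fluorescence: np.ndarray  # a.u.

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperature.size < 5:
            raise ValueError("melt curve needs >= 5 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature must be strictly increasing")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("non-finite fluorescence")


@dataclass
class TmResult:
    tm: float  # deg C
    derivative_peak: float  # dF/dT at the extremum, in the chosen sign
    sign: str  # "+" (peak in dF/dT) or "-" (peak in -dF/dT)
    window: int


def simulate_melt_curve(
    tm: float,
    temp_range=(25.0, 95.0),
    step: float = 1.0,
    width: float = 2.0,
    f_folded: float = 100.0,
    f_unfolded: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> MeltCurve:
    """Two-state unfolding curve with logistic transition at ``tm``.

    ``width`` (deg C) sets the transition steepness; flat pre/post baselines
    by default so the derivative extremum sits exactly at the midpoint.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(temp_range[0], temp_range[1] + step / 2, step)
    frac_unfolded = 1.0 / (1.0 + np.exp(-(t - tm) / width))
    f = f_folded + (f_unfolded - f_folded) * frac_unfolded
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    return MeltCurve(temperature=t, fluorescence=f)


def tm_from_melt(mc: MeltCurve, window: int = 5, sign: str = "auto",
                 min_peak_z: float = 6.0) -> TmResult:
    """T_M from the derivative of the smoothed melt curve.

    The fluorescence is smoothed with a centred Savitzky-Golay window
    (``window`` points, quadratic), dF/dT is taken from the same filter,
    and the extremum (excluding the first/last window, where the filter is
    one-sided) is refined by quadratic interpolation on the grid.

    ``sign``: "+" looks for a maximum of dF/dT, "-" for a minimum, "auto"
    picks whichever trend dominates the curve.  A curve whose derivative
    peak does not stand out from the bulk of the derivative (robust z below
    ``min_peak_z``, median/MAD scale) has no transition and raises
    ValueError.  Both checks are invariant under positive affine transforms
    of the fluorescence.
    """
    t, f = mc.temperature, mc.fluorescence
    if window < 3:
        raise ValueError("window must be >= 3 points")
    window = min(window if window % 2 == 1 else window + 1, t.size - (t.size + 1) % 2)
    dt = float(np.median(np.diff(t)))
    deriv = savgol_filter(f, window_length=window, polyorder=2, deriv=1, delta=dt)
    if sign == "auto":
        sign = "+" if f[-1] >= f[0] else "-"
    if sign not in ("+", "-"):
        raise ValueError("sign must be '+', '-' or 'auto'")
    d = deriv if sign == "+" else -deriv
    lo, hi = window // 2, d.size - window // 2
    interior = d[lo:hi]
    if interior.size < 3:
        raise ValueError("melt curve too short for the chosen window")
    i = int(np.argmax(interior)) + lo
    peak = d[i]
    med = float(np.median(d))
    scale = 1.4826 * float(np.median(np.abs(d - med)))
    if scale == 0:
        scale = float(np.std(d)) or 1e-30
    if peak <= 0 or (peak - med) / scale < min_peak_z:
        raise ValueError("no transition detected")
    # quadratic refinement around the discrete extremum
    tm = t[i]
    if 0 < i < d.size - 1:
        denom = d[i - 1] - 2 * d[i] + d[i + 1]
        if denom != 0:
            shift = 0.5 * (d[i - 1] - d[i + 1]) / denom
            tm = t[i] + np.clip(shift, -1, 1) * dt
    return TmResult(tm=float(tm), derivative_peak=float(peak if sign == "+" else -peak),
                    sign=sign, window=window)


def delta_tm(tm_mut: float, tm_wt: float) -> float:
    """Thermal-stability shift, deg C (positive = stabilised)."""
    if not (math.isfinite(tm_mut) and math.isfinite(tm_wt)):
        raise ValueError("T_M values must be finite")
    return tm_mut - tm_wt
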