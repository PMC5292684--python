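"""Transport-limited 1:1 (Langmuir) SPR binding kinetics.

The working model is the standard two-compartment, steady-state
mass-transport-limited form of the 1:1 interaction::

    dR/dt = [k_on * C * (R_max - R) - k_off * R] / [1 + k_on * (R_max - R) / k_t]

with ``C`` the bulk analyte concentration during association and ``C = 0``
during dissociation.  ``k_t`` (RU M^-1 s^-1) is the transport coefficient;
``k_t -> inf`` recovers the ideal Langmuir kinetics, while finite ``k_t``
slows both the apparent association and — through rebinding of freshly
released ligand — the apparent dissociation.  Transport changes kinetics
only: the equilibrium response is ``R_max * C / (C + K_D)`` for every
``k_t``, with ``K_D = k_off / k_on``.

The ODE is separable, and its solution is obtained in closed form through
the Lambert W function; this exact path is the default.  ``method="ode"``
integrates the same equation with a stiff-capable adaptive integrator and
is used as an internal cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit, least_squares
from scipy.special import lambertw

__all__ = [
    "PhaseSchedule",
    "KineticParams",
    "Sensorgram",
    "SensorgramSet",
    "KineticFit",
    "TransportLimitedBindingModel",
    "simulate_sensorgram",
    "double_reference",
    "correct_capture_drift",
    "fit_dissociation_koff",
    "fit_global",
    "compute_kd",
    "expected_mass_fraction",
]

BASELINE = "baseline"
ASSOCIATION = "association"
DISSOCIATION = "dissociation"


@dataclass(frozen=True)
class PhaseSchedule:
    """Durations (s) of the baseline, association and dissociation phases."""

    baseline_duration: float = 60.0
    association_duration: float = 200.0
    dissociation_duration: float = 600.0

    def __post_init__(self) -> None:
        for name in ("baseline_duration", "association_duration", "dissociation_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.association_duration <= 0:
            raise ValueError("association_duration must be > 0 for a binding experiment")

    @property
    def total_duration(self) -> float:
        return self.baseline_duration + self.association_duration + self.dissociation_duration


@dataclass(frozen=True)
class KineticParams:
    """1:1 transport-limited binding parameters.

    k_on in M^-1 s^-1, k_off in s^-1, r_max in RU and k_t (transport
    coefficient) in RU M^-1 s^-1; ``k_t = inf`` means no transport
    limitation.
    """

    k_on: float
    k_off: float
    r_max: float
    k_t: float = math.inf

    def __post_init__(self) -> None:
        if not self.k_on > 0:
            raise ValueError(f"k_on must be > 0, got {self.k_on}")
        if self.k_off < 0:
            raise ValueError(f"k_off must be >= 0, got {self.k_off}")
        if not self.r_max > 0:
            raise ValueError(f"r_max must be > 0, got {self.r_max}")
        if not self.k_t > 0:
            raise ValueError(f"k_t must be > 0 (inf allowed), got {self.k_t}")

    @property
    def kd(self) -> float:
        return self.k_off / self.k_on


@dataclass
class Sensorgram:
    """A single SPR trace: time (s), response (RU), analyte concentration (M)."""

    time: np.ndarray
    response: np.ndarray
    analyte_conc: float
    phase: np.ndarray  # per-point label: baseline / association / dissociation

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if self.time.shape != self.response.shape or self.time.shape != self.phase.shape:
            raise ValueError("time, response and phase must have identical shapes")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.analyte_conc < 0:
            raise ValueError(f"analyte concentration must be >= 0, got {self.analyte_conc}")

    def mask(self, phase: str) -> np.ndarray:
        return self.phase == phase

    @property
    def dissociation_start(self) -> float:
        m = self.mask(DISSOCIATION)
        if not m.any():
            raise ValueError("sensorgram has no dissociation phase")
        return float(self.time[m][0])

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        label = kwargs.pop("label", f"{self.analyte_conc * 1e9:g} nM")
        ax.plot(self.time, self.response, label=label, **kwargs)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("response (RU)")
        return ax


@dataclass
class SensorgramSet:
    """A family of sensorgrams sharing one surface (one experiment)."""

    sensorgrams: list
    kin_true: KineticParams | None = None  # set by the synthetic generator

    def __iter__(self):
        return iter(self.sensorgrams)

    def __len__(self) -> int:
        return len(self.sensorgrams)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([sg.analyte_conc for sg in self.sensorgrams])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for sg in self.sensorgrams:
            sg.plot(ax=ax)
        ax.legend(title="[analyte]")
        return ax


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def _association_response(kin: KineticParams, conc: float, t: np.ndarray) -> np.ndarray:
    """Exact R(t) during association, R(0) = 0."""
    t = np.asarray(t, dtype=float)
    if conc == 0.0:
        # no analyte: R stays at 0 (k_off * 0 = 0)
        return np.zeros_like(t)
    a = kin.k_on * conc + kin.k_off
    r_eq = kin.k_on * conc * kin.r_max / a
    if not math.isfinite(kin.k_t):
        return r_eq * (1.0 - np.exp(-a * t))
    kappa = kin.k_on / kin.k_t
    c1 = 1.0 + kappa * (kin.r_max - r_eq)
    beta = kappa / c1
    # c1*ln u + kappa*u = c1*ln r_eq + kappa*r_eq - a*t, with u = r_eq - R
    m = np.log(beta * r_eq) + beta * r_eq - a * t / c1
    u = np.empty_like(t)
    small = m < -18.0
    large = m > 600.0
    mid = ~(small | large)
    # W(x) ~ x for small x; avoids 0/0 when beta*u underflows
    u[small] = r_eq * np.exp(beta * r_eq - a * t[small] / c1)
    u[mid] = np.real(lambertw(np.exp(m[mid]))) / beta
    if large.any():
        # asymptotic W(e^m) from the fixed point w = m - ln w
        w = np.maximum(m[large], 1.0)
        for _ in range(5):
            w = m[large] - np.log(w)
        u[large] = w / beta
    return r_eq - u


def _dissociation_response(kin: KineticParams, r0: float, t: np.ndarray) -> np.ndarray:
    """Exact R(t) during dissociation (C = 0) from R(0) = r0."""
    t = np.asarray(t, dtype=float)
    if r0 <= 0.0 or kin.k_off == 0.0:
        return np.full_like(t, r0)
    if not math.isfinite(kin.k_t):
        return r0 * np.exp(-kin.k_off * t)
    kappa = kin.k_on / kin.k_t
    c2 = 1.0 + kappa * kin.r_max
    gamma = kappa / c2
    # c2*ln R - kappa*R = c2*ln r0 - kappa*r0 - k_off*t
    m = np.log(gamma * r0) - gamma * r0 - kin.k_off * t / c2
    x = np.exp(m)
    r = np.empty_like(t)
    small = x < 1e-8
    r[small] = r0 * np.exp(-gamma * r0 - kin.k_off * t[small] / c2)
    r[~small] = -np.real(lambertw(-x[~small])) / gamma
    return r


def _rhs(kin: KineticParams, conc: float):
    kappa = 0.0 if not math.isfinite(kin.k_t) else kin.k_on / kin.k_t

    def f(_t, r):
        free = kin.r_max - r
        return (kin.k_on * conc * free - kin.k_off * r) / (1.0 + kappa * free)

    return f


def _ode_response(kin: KineticParams, conc: float, r0: float, t: np.ndarray) -> np.ndarray:
    if t.size == 0:
        return np.zeros(0)
    t_end = float(t[-1])
    if t_end == 0.0:
        return np.full_like(t, r0)
    sol = solve_ivp(
        _rhs(kin, conc),
        (0.0, t_end),
        [r0],
        t_eval=t,
        method="LSODA",
        rtol=1e-8,
        atol=1e-6,
    )
    if not sol.success:
        raise RuntimeError(f"sensorgram integration failed: {sol.message}")
    return sol.y[0]


def simulate_sensorgram(
    kin: KineticParams,
    conc: float,
    schedule: PhaseSchedule | None = None,
    sampling_hz: float = 1.0,
    method: Literal["analytic", "ode"] = "analytic",
) -> Sensorgram:
    """Noise-free sensorgram of the transport-limited 1:1 model.

    ``method="analytic"`` evaluates the exact Lambert-W solution of the
    model ODE; ``method="ode"`` integrates the ODE itself (LSODA,
    rtol 1e-8 / atol 1e-6).  Both describe the same trajectory.
    """
    if schedule is None:
        schedule = PhaseSchedule()
    if conc < 0:
        raise ValueError(f"analyte concentration must be >= 0, got {conc}")
    dt = 1.0 / sampling_hz
    n_total = int(round(schedule.total_duration / dt)) + 1
    time = np.arange(n_total) * dt
    t_assoc0 = schedule.baseline_duration
    t_diss0 = schedule.baseline_duration + schedule.association_duration
    phase = np.empty(n_total, dtype=object)
    phase[:] = BASELINE
    phase[(time >= t_assoc0) & (time < t_diss0)] = ASSOCIATION
    phase[time >= t_diss0] = DISSOCIATION
    if schedule.baseline_duration == 0:
        phase[time < t_diss0] = ASSOCIATION

    response = np.zeros(n_total)
    am = phase == ASSOCIATION
    dm = phase == DISSOCIATION
    if method == "analytic":
        response[am] = _association_response(kin, conc, time[am] - t_assoc0)
        r_end = float(_association_response(kin, conc, np.array([schedule.association_duration]))[0])
        response[dm] = _dissociation_response(kin, r_end, time[dm] - t_diss0)
    elif method == "ode":
        response[am] = _ode_response(kin, conc, 0.0, time[am] - t_assoc0)
        r_end = float(
            _ode_response(kin, conc, 0.0, np.array([0.0, schedule.association_duration]))[-1]
        )
        response[dm] = _ode_response(kin, 0.0, r_end, time[dm] - t_diss0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return Sensorgram(time=time, response=response, analyte_conc=conc, phase=phase)


# ---------------------------------------------------------------------------
# referencing / drift corrections
# ---------------------------------------------------------------------------


def _interp_onto(target_time: np.ndarray, sg: Sensorgram) -> np.ndarray:
    if sg.time[0] > target_time[0] + 1e-9 or sg.time[-1] < target_time[-1] - 1e-9:
        raise ValueError(
            "reference trace does not cover the time range of the raw trace "
            f"([{sg.time[0]}, {sg.time[-1]}] vs [{target_time[0]}, {target_time[-1]}])"
        )
    return np.interp(target_time, sg.time, sg.response)


def double_reference(
    raw: Sensorgram, surface_ref: Sensorgram, buffer_ref: Sensorgram
) -> Sensorgram:
    """Subtract the reference-surface and buffer-blank responses.

    Output is ``raw - surface_ref - buffer_ref`` re-zeroed to the mean of
    the baseline phase, the standard double-referencing correction.
    """
    corrected = (
        raw.response
        - _interp_onto(raw.time, surface_ref)
        - _interp_onto(raw.time, buffer_ref)
    )
    bl = raw.mask(BASELINE)
    if not bl.any():
        raise ValueError("raw sensorgram has no baseline phase to re-zero against")
    corrected = corrected - corrected[bl].mean()
    return Sensorgram(raw.time.copy(), corrected, raw.analyte_conc, raw.phase.copy())


def correct_capture_drift(sg: Sensorgram, capture_koff: float) -> Sensorgram:
    """Deconvolute slow release of the captured surface from the dissociation phase.

    The dissociation-phase response is divided by ``exp(-capture_koff * t)``
    (t measured from the start of dissociation), leaving only the ligand
    release.  A correction amplifying the signal more than 10x at the end of
    the trace is flagged as noise-amplifying.
    """
    if capture_koff < 0:
        raise ValueError(f"capture_koff must be >= 0, got {capture_koff}")
    if capture_koff == 0.0:
        return Sensorgram(sg.time.copy(), sg.response.copy(), sg.analyte_conc, sg.phase.copy())
    dm = sg.mask(DISSOCIATION)
    td = sg.time[dm] - sg.dissociation_start
    gain = np.exp(capture_koff * td)
    if gain.size and gain[-1] > 10.0:
        warnings.warn(
            f"capture-drift correction amplifies the late dissociation signal "
            f"{gain[-1]:.1f}x (> 10x); fitted k_off will be noise-dominated",
            stacklevel=2,
        )
    response = sg.response.copy()
    response[dm] = response[dm] * gain
    return Sensorgram(sg.time.copy(), response, sg.analyte_conc, sg.phase.copy())


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class KoffEstimate:
    value: float
    stderr: float
    per_curve: np.ndarray

    def __float__(self) -> float:
        return self.value


def fit_dissociation_koff(sgs: SensorgramSet | Sequence[Sensorgram]) -> KoffEstimate:
    """Single-exponential k_off from the dissociation phases, averaged over curves.

    Each curve's dissociation phase (> 100 points required) is fitted to
    ``A * exp(-k t)``; the estimate is the mean over curves and the error the
    scatter (sd) across curves.  A non-decaying phase triggers a warning and
    contributes the lower bound 0.
    """
    rates = []
    for sg in sgs:
        dm = sg.mask(DISSOCIATION)
        if dm.sum() <= 100:
            raise ValueError(
                f"dissociation phase needs > 100 points, got {int(dm.sum())} "
                f"(conc {sg.analyte_conc})"
            )
        t = sg.time[dm] - sg.dissociation_start
        r = sg.response[dm]
        # initial guess from a log-linear fit on the positive part
        pos = r > 0
        if pos.sum() >= 2:
            slope = np.polyfit(t[pos], np.log(r[pos]), 1)[0]
        else:
            slope = 0.0
        k0 = max(-slope, 1e-6)
        try:
            popt, _ = curve_fit(
                lambda tt, amp, k: amp * np.exp(-k * tt),
                t,
                r,
                p0=[max(r[0], 1e-6), k0],
                maxfev=10000,
            )
            k_fit = popt[1]
        except RuntimeError:
            k_fit = -1.0
        if k_fit <= 0 or r[-1] >= r[0]:
            warnings.warn(
                f"non-decaying dissociation phase at conc {sg.analyte_conc}; "
                "reporting lower bound k_off = 0",
                stacklevel=2,
            )
            k_fit = 0.0
        rates.append(k_fit)
    rates = np.asarray(rates)
    stderr = float(rates.std(ddof=1)) if rates.size > 1 else 0.0
    return KoffEstimate(value=float(rates.mean()), stderr=stderr, per_curve=rates)


@dataclass
class KineticFit:
    """Results of the global transport-limited fit.

    ``kd = k_off / k_on`` holds exactly.  ``k_t = inf`` with
    ``k_t_unbounded=True`` means the data carry no transport information
    (all curves kinetics-limited).  When k_off was fixed the K_D carries no
    error, mirroring standard practice for forced parameters.
    """

    k_on: float
    k_on_stderr: float
    r_max: float
    r_max_stderr: float
    k_t: float
    k_t_stderr: float
    k_off: float
    k_off_stderr: float
    k_off_fixed: bool
    resid_sd: float
    n_points: int
    n_starts: int
    cost: float
    k_t_unbounded: bool = False
    per_curve_resid_sd: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def kd(self) -> float:
        return self.k_off / self.k_on

    @property
    def kd_stderr(self) -> float | None:
        if self.k_off_fixed:
            return None  # no error: k_off was forced
        return self.kd * math.sqrt(
            (self.k_on_stderr / self.k_on) ** 2 + (self.k_off_stderr / self.k_off) ** 2
        )

    @property
    def params(self) -> KineticParams:
        return KineticParams(self.k_on, self.k_off, self.r_max, self.k_t)

    def summary(self) -> str:
        kt_txt = (
            "unbounded above (kinetics-limited)"
            if self.k_t_unbounded
            else f"{self.k_t:.4g} +/- {self.k_t_stderr:.2g} RU/(M s)"
        )
        koff_txt = f"{self.k_off:.4g} s^-1" + (" (fixed)" if self.k_off_fixed else f" +/- {self.k_off_stderr:.2g}")
        kd_err = "" if self.kd_stderr is None else f" +/- {self.kd_stderr * 1e12:.3g}"
        lines = [
            "Global 1:1 transport-limited kinetic fit",
            "----------------------------------------",
            f"k_on   = {self.k_on:.4g} +/- {self.k_on_stderr:.2g} M^-1 s^-1",
            f"k_off  = {koff_txt}",
            f"R_max  = {self.r_max:.4g} +/- {self.r_max_stderr:.2g} RU",
            f"k_t    = {kt_txt}",
            f"K_D    = {self.kd * 1e12:.3g}{kd_err} pM",
            f"resid. sd = {self.resid_sd:.3g} RU over {self.n_points} points "
            f"({self.n_starts} starts)",
        ]
        return "\n".join(lines)


class TransportLimitedBindingModel:
    """Global 1:1 transport-limited model over a multi-concentration series.

    One shared (k_on, R_max, k_t) — and k_off, fixed or free — is fitted by
    unweighted least squares over all phases of all curves simultaneously,
    with seeded multi-start to guard against local minima.
    """

    #: transport influence below this relative size is non-identifiable
    _KT_NEGLIGIBLE = 1e-3

    def __init__(self, sgs: SensorgramSet | Sequence[Sensorgram]):
        self.sensorgrams = list(sgs)
        concs = {sg.analyte_conc for sg in self.sensorgrams if sg.analyte_conc > 0}
        if len(concs) < 2:
            raise ValueError(
                "global fit is unidentifiable: need >= 2 distinct positive "
                f"analyte concentrations, got {sorted(concs)}"
            )

    # -- model evaluation ---------------------------------------------------
    @staticmethod
    def _predict(kin: KineticParams, sg: Sensorgram) -> np.ndarray:
        pred = np.zeros_like(sg.response)
        am = sg.mask(ASSOCIATION)
        dm = sg.mask(DISSOCIATION)
        if am.any():
            t0 = sg.time[am][0]
            pred[am] = _association_response(kin, sg.analyte_conc, sg.time[am] - t0)
            if dm.any():
                t_assoc_end = sg.time[dm][0] - t0
                r_end = float(
                    _association_response(kin, sg.analyte_conc, np.array([t_assoc_end]))[0]
                )
                pred[dm] = _dissociation_response(kin, r_end, sg.time[dm] - sg.time[dm][0])
        return pred

    def _residuals(self, theta: np.ndarray, koff: float | None) -> np.ndarray:
        k_on = 10.0 ** theta[0]
        r_max = 10.0 ** theta[1]
        k_t = 10.0 ** theta[2]
        k_off = koff if koff is not None else 10.0 ** theta[3]
        kin = KineticParams(k_on, k_off, r_max, k_t)
        res = [self._predict(kin, sg) - sg.response for sg in self.sensorgrams]
        return np.concatenate(res)

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        koff_fixed: float | Literal["free"] = 2e-4,
        n_starts: int = 10,
        seed: int = 0,
    ) -> KineticFit:
        koff = None if koff_fixed == "free" else float(koff_fixed)
        rng = np.random.default_rng(seed)
        r_obs_max = max(float(sg.response.max()) for sg in self.sensorgrams)
        r_obs_max = max(r_obs_max, 1e-3)
        # heuristic start + randomized log-uniform starts
        starts = [np.array([8.0, math.log10(1.2 * r_obs_max), 12.0, -3.7])]
        for _ in range(max(0, n_starts - 1)):
            starts.append(
                np.array(
                    [
                        rng.uniform(6.0, 10.0),
                        math.log10(r_obs_max) + rng.uniform(-0.2, 0.6),
                        rng.uniform(8.0, 14.0),
                        rng.uniform(-5.0, -2.5),
                    ]
                )
            )
        lb = np.array([3.0, math.log10(0.3 * r_obs_max), 6.0, -8.0])
        ub = np.array([12.0, math.log10(30.0 * r_obs_max), 16.0, -1.0])
        nfree = 3 if koff is not None else 4
        best = None
        for x0 in starts:
            try:
                sol = least_squares(
                    self._residuals,
                    x0[:nfree],
                    args=(koff,),
                    bounds=(lb[:nfree], ub[:nfree]),
                    method="trf",
                    xtol=1e-12,
                    ftol=1e-12,
                )
            except Exception:  # pragma: no cover - defensive
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("global fit failed from every start")

        theta = best.x
        k_on = 10.0 ** theta[0]
        r_max = 10.0 ** theta[1]
        k_t = 10.0 ** theta[2]
        k_off = koff if koff is not None else 10.0 ** theta[3]
        n_pts = best.fun.size
        dof = max(n_pts - nfree, 1)
        resid_var = 2.0 * best.cost / dof
        # covariance in log10 space via the Gauss-Newton approximation
        jtj = best.jac.T @ best.jac
        try:
            cov = resid_var * np.linalg.inv(jtj)
            log_err = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            log_err = np.full(nfree, np.nan)
        ln10 = math.log(10.0)
        k_on_err = k_on * ln10 * log_err[0]
        r_max_err = r_max * ln10 * log_err[1]
        k_t_err = k_t * ln10 * log_err[2]
        k_off_err = 0.0 if koff is not None else k_off * ln10 * log_err[3]

        # transport identifiability: is the fitted k_t distinguishable from inf?
        unbounded = k_on * r_max / k_t < self._KT_NEGLIGIBLE
        if unbounded:
            k_t, k_t_err = math.inf, math.nan

        per_curve = np.array(
            [
                float(np.std(self._predict(KineticParams(k_on, k_off, r_max, k_t), sg) - sg.response))
                for sg in self.sensorgrams
            ]
        )
        return KineticFit(
            k_on=k_on,
            k_on_stderr=k_on_err,
            r_max=r_max,
            r_max_stderr=r_max_err,
            k_t=k_t,
            k_t_stderr=k_t_err,
            k_off=k_off,
            k_off_stderr=k_off_err,
            k_off_fixed=koff is not None,
            resid_sd=math.sqrt(resid_var),
            n_points=n_pts,
            n_starts=len(starts),
            cost=float(best.cost),
            k_t_unbounded=unbounded,
            per_curve_resid_sd=per_curve,
        )


def fit_global(
    sgs: SensorgramSet | Sequence[Sensorgram],
    koff_fixed: float | Literal["free"] = 2e-4,
    n_starts: int = 10,
    seed: int = 0,
) -> KineticFit:
    """Globally fit one shared (k_on, R_max, k_t) across all curves."""
    return TransportLimitedBindingModel(sgs).fit(koff_fixed, n_starts=n_starts, seed=seed)


def compute_kd(k_on: float, k_off: float) -> float:
    """Equilibrium dissociation constant K_D = k_off / k_on (M)."""
    if k_on <= 0:
        raise ValueError(f"k_on must be > 0, got {k_on}")
    if k_off < 0:
        raise ValueError(f"k_off must be >= 0, got {k_off}")
    return k_off / k_on


def expected_mass_fraction(n_copies: float, ligand_mass: float, particle_mass: float) -> float:
    """Mass increase (%) of a particle fully decorated by n_copies of the ligand."""
    if ligand_mass <= 0 or particle_mass <= 0:
        raise ValueError("masses must be > 0")
    if n_copies < 0:
        raise ValueError(f"n_copies must be >= 0, got {n_copies}")
    return 100.0 * n_copies * ligand_mass / particle_mass
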