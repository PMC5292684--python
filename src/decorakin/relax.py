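"""Lipari–Szabo model-free analysis of backbone ¹⁵N relaxation.

Amide ¹⁵N R1, R2 and the {¹H-¹⁵N} heteronuclear NOE are driven by the
N-H dipolar interaction and the ¹⁵N chemical-shift anisotropy, sampled at
five canonical frequencies of the spectral density J(ω).  In the
model-free picture each residue's internal motion is summarised by an
order parameter S² (amplitude), an internal correlation time τe, and an
optional exchange-broadening term Rex added to R2, all riding on an
isotropic overall tumbling time τm (here one τm per structural domain —
the two domains of a flexibly linked protein tumble with distinct τm,
which is what the per-domain T1/T2 ≈ R2/R1 diagnostic reports).

Candidate models (classic model-free ladder):

====  ===========================  =========
id    parameters                   count
====  ===========================  =========
M1    S²                           1
M2    S², τe                       2
M3    S², Rex                      2
M4    S², τe, Rex                  3
M5    Sf², Ss², τs  (S²=Sf²·Ss²)   3
====  ===========================  =========

Selection is by AICc on the χ² of the observables (falling back to plain
AIC when the sample size makes the AICc correction undefined), and
parameter uncertainties come from Monte-Carlo resampling of the
observables within their measured errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

__all__ = [
    "NMRConstants",
    "MotionParams",
    "GlobalTumbling",
    "RelaxationDataset",
    "MotionFit",
    "spectral_density",
    "predict_rates",
    "estimate_tm_from_ratio",
    "tm_for_t1t2_ratio",
    "fit_residue",
    "mc_errors",
    "domain_average_t1t2",
    "flag_exchange",
    "ModelFreeModel",
    "ModelFreeResults",
]


@dataclass(frozen=True)
class NMRConstants:
    """Spin-interaction constants for the amide ¹⁵N-¹H pair.

    Defaults are the conventional model-free values: N-H bond length
    1.02 Å and a ¹⁵N CSA of -160 ppm.
    """

    r_nh: float = 1.02e-10  # m
    csa: float = -160e-6  # unitless (ppm * 1e-6)
    gamma_h: float = 2.6752218744e8  # rad s^-1 T^-1
    gamma_n: float = -2.7126e7  # rad s^-1 T^-1
    h_bar: float = 1.054571817e-34  # J s
    mu_0: float = 4e-7 * math.pi

    @property
    def dipolar(self) -> float:
        """Dipolar coupling constant d = (mu0/4pi) * hbar * gH * gN / r^3 (rad/s)."""
        return self.mu_0 / (4 * math.pi) * self.h_bar * self.gamma_h * self.gamma_n / self.r_nh**3


CONSTANTS = NMRConstants()

MODELS = {
    "M1": ("s2",),
    "M2": ("s2", "tau_e"),
    "M3": ("s2", "rex"),
    "M4": ("s2", "tau_e", "rex"),
    "M5": ("s2_f", "s2_s", "tau_s"),
}


@dataclass(frozen=True)
class GlobalTumbling:
    """Isotropic rotational correlation time (s) for a molecule or domain."""

    tau_m: float
    scope: str = "molecule"

    def __post_init__(self) -> None:
        if not self.tau_m > 0:
            raise ValueError(f"tau_m must be > 0, got {self.tau_m}")


@dataclass(frozen=True)
class MotionParams:
    """Per-residue model-free motional parameters.

    S² in [0,1]; τe in seconds (internal motion); Rex in s⁻¹ (exchange
    contribution to R2, quoted at ``rex_field`` MHz and scaled with B²
    across fields).  For the two-timescale model M5, S² = Sf²·Ss² and τs
    is the slow internal correlation time.
    """

    s2: float = 1.0
    tau_e: float = 0.0
    rex: float = 0.0
    s2_f: float | None = None
    s2_s: float | None = None
    tau_s: float | None = None
    model: str = "M1"
    rex_field: float = 600.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.s2 <= 1.0:
            raise ValueError(f"S^2 must be in [0, 1], got {self.s2}")
        if self.tau_e < 0:
            raise ValueError(f"tau_e must be >= 0, got {self.tau_e}")
        if self.rex < 0:
            raise ValueError(f"Rex must be >= 0, got {self.rex}")
        if self.model == "M5":
            if self.s2_f is None or self.s2_s is None or self.tau_s is None:
                raise ValueError("M5 requires s2_f, s2_s and tau_s")
            if abs(self.s2 - self.s2_f * self.s2_s) > 1e-9:
                raise ValueError("M5 requires S^2 = Sf^2 * Ss^2")


@dataclass(frozen=True)
class ResidueMotion:
    """A residue's identity, domain assignment and true motional parameters."""

    residue: int
    domain: str
    params: MotionParams


class RelaxationDataset:
    """Per-residue ¹⁵N relaxation observables, one row per (residue, field).

    Backed by a DataFrame with columns residue, domain, field_MHz,
    R1, R1_err, R2, R2_err, NOE, NOE_err.
    """

    COLUMNS = ["residue", "domain", "field_MHz", "R1", "R1_err", "R2", "R2_err", "NOE", "NOE_err"]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"relaxation table is missing columns {sorted(missing)}")
        if (frame[["R1", "R2"]] <= 0).any().any():
            raise ValueError("R1 and R2 must be > 0")
        if (frame[["R1_err", "R2_err", "NOE_err"]] < 0).any().any():
            raise ValueError("errors must be >= 0")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def residues(self) -> np.ndarray:
        return np.unique(self.frame["residue"].to_numpy())

    @property
    def fields(self) -> np.ndarray:
        return np.unique(self.frame["field_MHz"].to_numpy())

    def for_residue(self, residue: int) -> pd.DataFrame:
        return self.frame[self.frame["residue"] == residue]

    def for_domain(self, domain: str) -> pd.DataFrame:
        return self.frame[self.frame["domain"] == domain]


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def spectral_density(
    m: MotionParams, tumbling: GlobalTumbling, omega: float | np.ndarray
) -> float | np.ndarray:
    """Lipari–Szabo spectral density J(ω) in s/rad.

    J(ω) = (2/5)[S²τm/(1+(ωτm)²) + (1−S²)τ/(1+(ωτ)²)], 1/τ = 1/τm + 1/τe;
    the extended two-timescale form replaces the second term for M5.
    """
    tm = tumbling.tau_m
    w2 = np.square(omega)
    j = (2.0 / 5.0) * m.s2 * tm / (1.0 + w2 * tm * tm)
    if m.model == "M5":
        tau = tm * m.tau_s / (tm + m.tau_s) if m.tau_s > 0 else 0.0
        if tau > 0:
            j = j + (2.0 / 5.0) * (m.s2_f - m.s2) * tau / (1.0 + w2 * tau * tau)
    elif m.tau_e > 0 and m.s2 < 1.0:
        tau = tm * m.tau_e / (tm + m.tau_e)
        j = j + (2.0 / 5.0) * (1.0 - m.s2) * tau / (1.0 + w2 * tau * tau)
    return j


def predict_rates(
    m: MotionParams,
    tumbling: GlobalTumbling,
    field: float,
    constants: NMRConstants = CONSTANTS,
) -> tuple[float, float, float]:
    """(R1, R2, NOE) at a ¹H frequency ``field`` in MHz.

    Standard ¹⁵N dipolar + CSA expressions evaluated from J at the five
    canonical frequencies; Rex (scaled by (B/B_ref)²) is added to R2 only.
    """
    if field <= 0:
        raise ValueError(f"field must be > 0 MHz, got {field}")
    w_h = 2.0 * math.pi * field * 1e6
    w_n = w_h * constants.gamma_n / constants.gamma_h
    d2_4 = constants.dipolar**2 / 4.0
    c = w_n * constants.csa / math.sqrt(3.0)
    c2 = c * c

    j = lambda w: spectral_density(m, tumbling, abs(w))
    j0 = j(0.0)
    jwn = j(w_n)
    jwh = j(w_h)
    jdiff = j(w_h - w_n)
    jsum = j(w_h + w_n)

    r1 = d2_4 * (jdiff + 3.0 * jwn + 6.0 * jsum) + c2 * jwn
    r2 = (d2_4 / 2.0) * (4.0 * j0 + jdiff + 3.0 * jwn + 6.0 * jwh + 6.0 * jsum) + (
        c2 / 6.0
    ) * (4.0 * j0 + 3.0 * jwn)
    rex = m.rex * (field / m.rex_field) ** 2
    r2 = r2 + rex
    noe = 1.0 + (constants.gamma_h / constants.gamma_n) * d2_4 * (6.0 * jsum - jdiff) / r1
    return float(r1), float(r2), float(noe)


def _rigid_ratio(tau_m: float, field: float) -> float:
    r1, r2, _ = predict_rates(MotionParams(s2=1.0), GlobalTumbling(tau_m), field)
    return r2 / r1


def tm_for_t1t2_ratio(
    ratio: float, field: float = 600.0, s2: float = 1.0, tau_e: float = 0.0
) -> float:
    """Invert the (rigid-limit) R2/R1 relation: the τm giving T1/T2 = ratio."""

    params = MotionParams(s2=s2, tau_e=tau_e, model="M1" if tau_e == 0 else "M2")

    def f(tm: float) -> float:
        r1, r2, _ = predict_rates(params, GlobalTumbling(tm), field)
        return r2 / r1 - ratio

    lo, hi = 0.5e-9, 60e-9
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"T1/T2 ratio {ratio} not invertible in [{lo}, {hi}] s at {field} MHz")
    return brentq(f, lo, hi, xtol=1e-14)


def estimate_tm_from_ratio(
    records: RelaxationDataset,
    trim: float = 0.1,
    noe_cutoff: float = 0.6,
    min_residues: int = 5,
) -> dict[str, GlobalTumbling]:
    """Per-domain τm from trimmed mean T1/T2 = R2/R1 of rigid residues.

    Residues with NOE < ``noe_cutoff`` at any field are excluded
    (flexibility criterion), the top and bottom ``trim`` fraction of the
    ratios are discarded (exchange / residual-flexibility outliers), and
    the rigid-limit R2/R1(τm) relation is inverted per field; the reported
    τm is the mean over fields.
    """
    if not 0.0 <= trim < 0.5:
        raise ValueError(f"trim must be in [0, 0.5), got {trim}")
    out: dict[str, GlobalTumbling] = {}
    for domain, dom_df in records.frame.groupby("domain"):
        flexible = set(dom_df.loc[dom_df["NOE"] < noe_cutoff, "residue"])
        usable = dom_df[~dom_df["residue"].isin(flexible)]
        tms = []
        for fld, fdf in usable.groupby("field_MHz"):
            ratios = np.sort((fdf["R2"] / fdf["R1"]).to_numpy())
            k = int(math.floor(trim * ratios.size))
            trimmed = ratios[k : ratios.size - k] if k > 0 else ratios
            if trimmed.size < min_residues:
                raise ValueError(
                    f"domain {domain!r}: only {trimmed.size} usable residues at "
                    f"{fld} MHz after NOE/trim filtering (need >= {min_residues})"
                )
            tms.append(tm_for_t1t2_ratio(float(trimmed.mean()), field=float(fld)))
        out[str(domain)] = GlobalTumbling(float(np.mean(tms)), scope=str(domain))
    return out


def domain_average_t1t2(
    records: RelaxationDataset,
    domains: Mapping[str, Iterable[int]],
    field: float | None = None,
) -> dict[str, float]:
    """Arithmetic mean of per-residue T1/T2 = R2/R1 over each residue range.

    Ranges must be disjoint; only residues with complete data contribute.
    ``field`` restricts to one spectrometer field (T1/T2 is
    field-dependent); default uses all records.
    """
    seen: set[int] = set()
    for name, rng in domains.items():
        s = set(rng)
        if not s:
            raise ValueError(f"domain range {name!r} is empty")
        if seen & s:
            raise ValueError(f"domain range {name!r} overlaps a previous range")
        seen |= s
    df = records.frame
    if field is not None:
        df = df[df["field_MHz"] == field]
    out: dict[str, float] = {}
    for name, rng in domains.items():
        sub = df[df["residue"].isin(set(rng))].dropna(subset=["R1", "R2"])
        if sub.empty:
            raise ValueError(f"no complete records in domain range {name!r}")
        out[name] = float((sub["R2"] / sub["R1"]).mean())
    return out


# ---------------------------------------------------------------------------
# per-residue model fitting
# ---------------------------------------------------------------------------


@dataclass
class MotionFit:
    """A residue's selected model-free fit."""

    residue: int
    params: MotionParams
    chi2: float
    n_obs: int
    aicc: float
    per_model: dict[str, float] = field(default_factory=dict)  # model -> AICc
    flags: list[str] = field(default_factory=list)
    intervals: dict[str, tuple[float, float]] | None = None  # 68% percentile CIs

    @property
    def model(self) -> str:
        return self.params.model

    def rex_significant(self) -> bool:
        """Rex present in the model and, when intervals exist, excluding 0."""
        if self.params.rex == 0.0 and "rex" not in MODELS[self.model]:
            return False
        if self.intervals is not None and "rex" in self.intervals:
            return self.intervals["rex"][0] > 0.0
        return self.params.rex > 0.0


_BOUNDS = {
    "s2": (0.0, 1.0),
    "tau_e": (0.0, 5e-9),
    "rex": (0.0, 100.0),
    "s2_f": (0.0, 1.0),
    "s2_s": (0.0, 1.0),
    "tau_s": (1e-12, 10e-9),
}
_STARTS = {
    "s2": (0.85, 0.5, 0.97),
    "tau_e": (50e-12, 500e-12, 5e-12),
    "rex": (2.0, 8.0, 0.5),
    "s2_f": (0.9, 0.75, 0.99),
    "s2_s": (0.9, 0.6, 0.99),
    "tau_s": (1e-9, 3e-9, 0.2e-9),
}


def _params_from_vector(model: str, x: np.ndarray, rex_field: float) -> MotionParams:
    names = MODELS[model]
    kw = dict(zip(names, x))
    if model == "M5":
        s2f, s2s, taus = kw["s2_f"], kw["s2_s"], kw["tau_s"]
        return MotionParams(
            s2=s2f * s2s, s2_f=s2f, s2_s=s2s, tau_s=taus, model="M5", rex_field=rex_field
        )
    return MotionParams(model=model, rex_field=rex_field, **kw)


def _residual_vector(
    params: MotionParams, rows: pd.DataFrame, tumbling: GlobalTumbling
) -> np.ndarray:
    res = []
    for _, row in rows.iterrows():
        r1, r2, noe = predict_rates(params, tumbling, float(row["field_MHz"]))
        for obs, pred, err in (
            (row["R1"], r1, row["R1_err"]),
            (row["R2"], r2, row["R2_err"]),
            (row["NOE"], noe, row["NOE_err"]),
        ):
            w = err if err > 0 else 1.0  # unit weights for exact/noise-free data
            res.append((pred - obs) / w)
    return np.asarray(res)


def _fit_one_model(
    model: str, rows: pd.DataFrame, tumbling: GlobalTumbling, rex_field: float
) -> tuple[MotionParams, float]:
    names = MODELS[model]
    lb = np.array([_BOUNDS[n][0] for n in names])
    ub = np.array([_BOUNDS[n][1] for n in names])
    best: tuple[MotionParams, float] | None = None
    for i in range(3):
        x0 = np.array([_STARTS[n][i] for n in names])
        sol = least_squares(
            lambda x: _residual_vector(_params_from_vector(model, x, rex_field), rows, tumbling),
            x0,
            bounds=(lb, ub),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        chi2 = float(2.0 * sol.cost)
        if best is None or chi2 < best[1]:
            best = (_params_from_vector(model, sol.x, rex_field), chi2)
    return best


def _aicc(chi2: float, k: int, n: int) -> float:
    aic = chi2 + 2.0 * k
    if n - k - 1 <= 0:
        return aic  # AICc correction undefined at this sample size
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def fit_residue(
    records: RelaxationDataset | pd.DataFrame,
    tumbling: GlobalTumbling,
    residue: int | None = None,
    models: Sequence[str] = ("M1", "M2", "M3", "M4", "M5"),
    rex_field: float | None = None,
    gof_quantile: float = 0.995,
) -> MotionFit:
    """Fit the model-free ladder to one residue and select by AICc.

    ``records`` may be the full dataset plus ``residue``, or a pre-sliced
    per-residue table.  Requires at least (R1, R2, NOE) at one field.  If
    even the best model fails a χ² goodness-of-fit cut the best-effort fit
    is returned flagged ``"unmodelled"``.
    """
    from scipy.stats import chi2 as chi2_dist

    if isinstance(records, RelaxationDataset):
        if residue is None:
            raise ValueError("residue id required when passing a full dataset")
        rows = records.for_residue(residue)
    else:
        rows = records
        if residue is None:
            residue = int(rows["residue"].iloc[0])
    rows = rows.dropna(subset=["R1", "R2", "NOE"])
    if rows.empty:
        raise ValueError(f"no complete relaxation records for residue {residue}")
    if rex_field is None:
        rex_field = float(rows["field_MHz"].min())
    n_obs = 3 * len(rows)

    flags: list[str] = []
    if (rows["NOE_err"] >= 1.0).any():
        flags.append("uninformative")  # NOE error spans the physical range

    fits: dict[str, tuple[MotionParams, float]] = {}
    scores: dict[str, float] = {}
    for model in models:
        k = len(MODELS[model])
        if k >= n_obs:
            continue  # saturated model: not selectable
        fits[model] = _fit_one_model(model, rows, tumbling, rex_field)
        scores[model] = _aicc(fits[model][1], k, n_obs)
    if not fits:
        raise ValueError(f"residue {residue}: too few observables to fit any model")
    winner = min(scores, key=scores.get)
    params, chi2_val = fits[winner]
    dof = max(n_obs - len(MODELS[winner]), 1)
    if chi2_val > chi2_dist.ppf(gof_quantile, dof):
        flags.append("unmodelled")
    return MotionFit(
        residue=int(residue),
        params=params,
        chi2=chi2_val,
        n_obs=n_obs,
        aicc=scores[winner],
        per_model=scores,
        flags=flags,
    )


def mc_errors(
    fit: MotionFit,
    records: RelaxationDataset | pd.DataFrame,
    tumbling: GlobalTumbling,
    n_mc: int = 200,
    seed: int = 0,
    ci: float = 0.68,
) -> dict[str, tuple[float, float]]:
    """Monte-Carlo percentile confidence intervals for the selected model.

    Observables are resampled from Gaussians centred on the measurements
    with the measured sd, the selected model refitted, and the central
    ``ci`` percentile interval reported per parameter.
    """
    if n_mc < 100:
        raise ValueError(f"n_mc must be >= 100, got {n_mc}")
    rows = (
        records.for_residue(fit.residue) if isinstance(records, RelaxationDataset) else records
    ).dropna(subset=["R1", "R2", "NOE"])
    errs = rows[["R1_err", "R2_err", "NOE_err"]].to_numpy()
    if np.all(errs == 0):
        warnings.warn(
            "all measurement errors are zero: Monte-Carlo intervals collapse to points",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    names = MODELS[fit.model]
    samples = {n: [] for n in names}
    base = rows[["R1", "R2", "NOE"]].to_numpy()
    for _ in range(n_mc):
        resampled = rows.copy()
        resampled[["R1", "R2", "NOE"]] = base + rng.normal(size=base.shape) * errs
        p, _ = _fit_one_model(fit.model, resampled, tumbling, fit.params.rex_field)
        for n in names:
            samples[n].append(getattr(p, n))
    lo_q, hi_q = 50 * (1 - ci), 50 * (1 + ci)
    intervals = {
        n: (float(np.percentile(v, lo_q)), float(np.percentile(v, hi_q)))
        for n, v in samples.items()
    }
    fit.intervals = intervals
    return intervals


def flag_exchange(
    fits: Sequence[MotionFit], min_rex: float = 0.0, require_significance: bool = False
) -> list[int]:
    """Residues whose selected model carries Rex >= min_rex (closed threshold).

    With ``require_significance`` the Monte-Carlo Rex interval must also
    exclude zero (intervals must have been computed).
    """
    out = []
    for f in fits:
        if "rex" not in MODELS[f.model]:
            continue
        if f.params.rex < min_rex:
            continue
        if require_significance:
            if f.intervals is None:
                raise ValueError(
                    f"residue {f.residue}: significance requested but no Monte-Carlo intervals"
                )
            if not f.rex_significant():
                continue
        out.append(f.residue)
    return out


# ---------------------------------------------------------------------------
# model / results wrappers
# ---------------------------------------------------------------------------


class ModelFreeModel:
    """Model-free analysis of a relaxation dataset.

    Tumbling may be supplied per domain or estimated from the trimmed
    T1/T2 ratios (``tm_mode="per-domain"``).
    """

    def __init__(
        self,
        dataset: RelaxationDataset,
        tumbling: Mapping[str, GlobalTumbling] | None = None,
        tm_mode: str = "per-domain",
    ):
        self.dataset = dataset
        if tumbling is None:
            if tm_mode != "per-domain":
                raise ValueError(f"unknown tm_mode {tm_mode!r}")
            tumbling = estimate_tm_from_ratio(dataset)
        self.tumbling = dict(tumbling)

    def fit(self, n_mc: int = 0, seed: int = 0, **kwargs) -> "ModelFreeResults":
        fits = []
        for res in self.dataset.residues:
            rows = self.dataset.for_residue(int(res))
            domain = str(rows["domain"].iloc[0])
            tumb = self.tumbling[domain]
            f = fit_residue(rows, tumb, residue=int(res), **kwargs)
            if n_mc:
                mc_errors(f, rows, tumb, n_mc=n_mc, seed=seed + int(res))
            fits.append(f)
        return ModelFreeResults(self, fits)


class ModelFreeResults:
    """Per-residue motional parameters with model ids and diagnostics."""

    def __init__(self, model: ModelFreeModel, fits: list[MotionFit]):
        self.model = model
        self.fits = fits

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            iv = f.intervals or {}
            rows.append(
                {
                    "residue": f.residue,
                    "model": f.model,
                    "S2": f.params.s2,
                    "tau_e_ps": f.params.tau_e * 1e12,
                    "Rex": f.params.rex,
                    "chi2": f.chi2,
                    "flags": ";".join(f.flags),
                    "S2_lo": iv.get("s2", (np.nan, np.nan))[0],
                    "S2_hi": iv.get("s2", (np.nan, np.nan))[1],
                    "Rex_lo": iv.get("rex", (np.nan, np.nan))[0],
                    "Rex_hi": iv.get("rex", (np.nan, np.nan))[1],
                }
            )
        return pd.DataFrame(rows)

    def exchange_residues(self, min_rex: float = 0.0, require_significance: bool = False):
        return flag_exchange(self.fits, min_rex, require_significance)

    def summary(self) -> str:
        df = self.to_frame()
        counts = df["model"].value_counts().to_dict()
        tumb = ", ".join(
            f"{d}: tau_m = {t.tau_m * 1e9:.2f} ns" for d, t in self.model.tumbling.items()
        )
        lines = [
            "Model-free analysis",
            "-------------------",
            f"residues fitted : {len(df)}",
            f"tumbling        : {tumb}",
            f"model counts    : {counts}",
            f"exchange (Rex>0): {len(self.exchange_residues())} residues",
            f"median S^2      : {df['S2'].median():.3f}",
        ]
        return "\n".join(lines)
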