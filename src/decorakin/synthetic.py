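"""Seeded synthetic inputs for every analysis stage, plus sample quantitation.

Each generator is a pure function of its parameters and an explicit
integer seed — identical inputs give bit-identical outputs, and the
noise-free output of a generator is exactly the corresponding forward
model of the analysis modules.  Defaults emulate the study conditions of
the T5 capsid / pb10 decoration system:

* multi-concentration sensorgrams of a transport-limited picomolar
  binder (k_on 1.8e8 M^-1 s^-1, k_off 2e-4 s^-1, ~7% signal loss over a
  700-s dissociation),
* ¹⁵N relaxation data of a two-domain protein whose domains tumble with
  distinct correlation times (T1/T2 ≈ 12 and ≈ 17 at 600 MHz) and carry
  a sparse set of exchange-broadened residues,
* a two-lobe 150-bead scattering model with Rg ≈ 30 Å and Dmax ≈ 107 Å,
* 4–99 °C DNA-release melting curves with a declining probe baseline,
* capsid/site bookkeeping (120 sites per capsid; 3.4e11 particles per mL
  per OD260 unit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .melt import MeltCurve
from .relax import (
    GlobalTumbling,
    MotionParams,
    RelaxationDataset,
    ResidueMotion,
    predict_rates,
    tm_for_t1t2_ratio,
)
from .saxs import BeadModel
from .spr import KineticParams, PhaseSchedule, Sensorgram, SensorgramSet, simulate_sensorgram

import pandas as pd

__all__ = [
    "NoiseSpec",
    "DEFAULT_KINETICS",
    "FIG5B_CONCENTRATIONS",
    "gen_sensorgram_series",
    "gen_relaxation_dataset",
    "two_domain_calibration_protein",
    "pb10_like_protein",
    "gen_two_domain_beads",
    "gen_melt_curve",
    "particles_from_od",
    "site_concentration",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive-noise magnitude (observable units) and the RNG seed."""

    sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"noise sd must be >= 0, got {self.sd}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


#: the study's kinetic regime: picomolar affinity, strong transport limitation
#: (k_t chosen so a 700-s dissociation from saturation loses ~7% of signal)
DEFAULT_KINETICS = KineticParams(k_on=1.8e8, k_off=2e-4, r_max=100.0, k_t=6.5e8)

#: the seven-concentration association/dissociation series design (nM -> M)
FIG5B_CONCENTRATIONS = tuple(c * 1e-9 for c in (0.312, 0.625, 1.25, 2.5, 5.0, 10.0, 20.0))


# ---------------------------------------------------------------------------
# SPR
# ---------------------------------------------------------------------------


def gen_sensorgram_series(
    kin: KineticParams = DEFAULT_KINETICS,
    concentrations=FIG5B_CONCENTRATIONS,
    schedule: PhaseSchedule | None = None,
    noise: NoiseSpec = NoiseSpec(),
    sampling_hz: float = 1.0,
) -> SensorgramSet:
    """One noisy sensorgram per analyte concentration (shared noise stream).

    Ideal traces come from :func:`decorakin.spr.simulate_sensorgram`; noise
    is additive i.i.d. Gaussian in RU.
    """
    if schedule is None:
        schedule = PhaseSchedule()
    for i, c in enumerate(concentrations):
        if c < 0:
            raise ValueError(f"concentration #{i} is negative ({c} M)")
    rng = noise.rng()
    sgs = []
    for c in concentrations:
        sg = simulate_sensorgram(kin, c, schedule, sampling_hz=sampling_hz)
        if noise.sd > 0:
            sg.response = sg.response + rng.normal(0.0, noise.sd, sg.response.size)
        sgs.append(sg)
    return SensorgramSet(sensorgrams=sgs, kin_true=kin)


# ---------------------------------------------------------------------------
# NMR relaxation
# ---------------------------------------------------------------------------


def gen_relaxation_dataset(
    residues,
    tumbling_by_domain,
    fields=(600.0, 700.0),
    noise: NoiseSpec = NoiseSpec(sd=0.02),
    replicates: int = 2,
) -> RelaxationDataset:
    """Noisy per-residue (R1, R2, NOE) tables at each field.

    ``residues`` is a sequence of :class:`ResidueMotion` (each residue is
    thereby assigned to exactly one domain); ``tumbling_by_domain`` maps the
    domain label to its :class:`GlobalTumbling`.  ``noise.sd`` is a
    fractional error on R1/R2 and an absolute error on the NOE.  Reported
    values are replicate means, reported errors the standard error of the
    mean across replicates (hence shrinking as 1/sqrt(replicates)).
    """
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    for f in fields:
        if f <= 0:
            raise ValueError(f"fields must be > 0 MHz, got {f}")
    missing = {r.domain for r in residues} - set(tumbling_by_domain)
    if missing:
        raise ValueError(f"residues assigned to domains with no tumbling entry: {sorted(missing)}")
    rng = noise.rng()
    rows = []
    for r in residues:
        tumb = tumbling_by_domain[r.domain]
        for fld in fields:
            r1, r2, noe = predict_rates(r.params, tumb, fld)
            reps = np.empty((replicates, 3))
            for k in range(replicates):
                reps[k, 0] = r1 * (1.0 + noise.sd * rng.standard_normal())
                reps[k, 1] = r2 * (1.0 + noise.sd * rng.standard_normal())
                reps[k, 2] = noe + noise.sd * rng.standard_normal()
            mean = reps.mean(axis=0)
            if replicates > 1:
                err = reps.std(axis=0, ddof=1) / math.sqrt(replicates)
            else:
                err = np.array([noise.sd * r1, noise.sd * r2, noise.sd])
            rows.append(
                {
                    "residue": r.residue,
                    "domain": r.domain,
                    "field_MHz": fld,
                    "R1": mean[0],
                    "R1_err": err[0],
                    "R2": mean[1],
                    "R2_err": err[1],
                    "NOE": mean[2],
                    "NOE_err": err[2],
                }
            )
    return RelaxationDataset(pd.DataFrame(rows))


def two_domain_calibration_protein(
    ratios=(12.0, 17.2),
    field: float = 600.0,
    n_per_domain: int = 30,
    s2: float = 0.85,
    tau_e: float = 20e-12,
):
    """All-rigid two-domain protein whose mean T1/T2 hits ``ratios`` at ``field``.

    Returns (residues, tumbling_by_domain, domain_ranges).  Used for
    tumbling-diagnostic calibration: every residue shares (S², τe), no
    exchange, so the domain-average R2/R1 equals the configured target.
    """
    tm_a = tm_for_t1t2_ratio(ratios[0], field=field, s2=s2, tau_e=tau_e)
    tm_b = tm_for_t1t2_ratio(ratios[1], field=field, s2=s2, tau_e=tau_e)
    params = MotionParams(s2=s2, tau_e=tau_e, model="M2" if tau_e > 0 else "M1")
    residues = [ResidueMotion(i + 1, "NTD", params) for i in range(n_per_domain)]
    residues += [ResidueMotion(100 + i + 1, "CTD", params) for i in range(n_per_domain)]
    tumbling = {
        "NTD": GlobalTumbling(tm_a, scope="NTD"),
        "CTD": GlobalTumbling(tm_b, scope="CTD"),
    }
    ranges = {
        "NTD": range(1, n_per_domain + 1),
        "CTD": range(101, 100 + n_per_domain + 1),
    }
    return residues, tumbling, ranges


#: residues carrying microsecond-millisecond exchange in the pb10-like protein:
#: NTD helix alpha5 (49-60) plus two CTD loops — 16 residues in all
PB10_REX_RESIDUES = tuple(range(49, 61)) + (111, 112, 126, 127)


def pb10_like_protein(rex: float = 4.0, field: float = 600.0):
    """A pb10-like 164-residue protein: rigid NTD/CTD cores with distinct
    tumbling, a flexible low-NOE linker, and exactly 16 exchange-broadened
    residues (helix α5 and two CTD loops).

    Returns (residues, tumbling_by_domain, core_ranges).
    """
    tm_ntd = tm_for_t1t2_ratio(12.0, field=field, s2=0.85, tau_e=20e-12)
    tm_ctd = tm_for_t1t2_ratio(17.2, field=field, s2=0.85, tau_e=20e-12)
    tumbling = {
        "NTD": GlobalTumbling(tm_ntd, scope="NTD"),
        "CTD": GlobalTumbling(tm_ctd, scope="CTD"),
        "linker": GlobalTumbling(tm_ntd, scope="linker"),
    }
    rigid = dict(s2=0.85, tau_e=20e-12)
    residues = []
    for i in range(2, 165):
        if 63 <= i <= 71:  # poly-proline linker region: fast large-amplitude motion
            p = MotionParams(s2=0.4, tau_e=1.2e-9, model="M2")
            dom = "linker"
        else:
            dom = "NTD" if i <= 62 else "CTD"
            if i in PB10_REX_RESIDUES:
                p = MotionParams(rex=rex, model="M3", rex_field=field, **rigid)
            else:
                p = MotionParams(model="M2", **rigid)
        residues.append(ResidueMotion(i, dom, p))
    core_ranges = {
        "NTD": [i for i in range(2, 63) if i not in PB10_REX_RESIDUES],
        "CTD": [i for i in range(72, 165) if i not in PB10_REX_RESIDUES],
    }
    return residues, tumbling, core_ranges


# ---------------------------------------------------------------------------
# SAXS bead model
# ---------------------------------------------------------------------------

_SPHERE_RADIUS = 14.5  # Å, globular lobe
_ELLIPSOID_AXES = (39.0, 10.0, 10.0)  # Å, elongated (Ig-like) lobe semi-axes


def _sample_ellipsoid(rng: np.random.Generator, n: int, semi_axes) -> np.ndarray:
    """Uniform interior sampling of an axis-aligned ellipsoid (rejection).

    The sampled cloud is standardized per axis to the exact first and
    second moments of the continuous uniform ellipsoid (mean 0, E[x²] =
    a²/5), so lobe mass distributions — and hence the model Rg — do not
    drift with the seed.
    """
    a = np.asarray(semi_axes, dtype=float)
    out = np.empty((n, 3))
    k = 0
    while k < n:
        cand = rng.uniform(-1.0, 1.0, size=(2 * (n - k) + 8, 3))
        keep = (cand**2).sum(axis=1) <= 1.0
        take = cand[keep][: n - k]
        out[k : k + take.shape[0]] = take
        k += take.shape[0]
    if n >= 4:
        out = out - out.mean(axis=0)
        sd = out.std(axis=0)
        sd[sd == 0] = 1.0
        out = out * (1.0 / math.sqrt(5.0)) / sd
    return out * a


def gen_two_domain_beads(
    n_per_domain: int = 75,
    separation: float = 52.0,
    linker_beads: int = 3,
    seed: int = 0,
) -> BeadModel:
    """Two-lobe pseudo-residue model: a globular sphere and an elongated
    ellipsoid joined along x by a short straight linker.

    The first bead of each lobe sits at the lobe centre and (for
    n_per_domain >= 2) the second at the outer pole — the chain termini —
    so the model's maximum extension is deterministic.  Default geometry
    is calibrated to Rg = 30 ± 1 Å and Dmax = 110 ± 5 Å.
    """
    if n_per_domain < 1:
        raise ValueError(f"n_per_domain must be >= 1, got {n_per_domain}")
    if linker_beads < 0:
        raise ValueError(f"linker_beads must be >= 0, got {linker_beads}")
    rng = np.random.default_rng(seed)
    r_sph = _SPHERE_RADIUS
    ax = _ELLIPSOID_AXES

    def lobe(n, center, pole, sampler):
        pts = [np.asarray(center, dtype=float)]
        if n >= 2:
            pts.append(np.asarray(pole, dtype=float))
        if n > 2:
            pts.append(sampler(n - 2) + center)
        return np.vstack([p.reshape(-1, 3) for p in pts])

    sphere = lobe(
        n_per_domain,
        (0.0, 0.0, 0.0),
        (-r_sph, 0.0, 0.0),
        lambda n: _sample_ellipsoid(rng, n, (r_sph,) * 3),
    )
    ellip = lobe(
        n_per_domain,
        (separation, 0.0, 0.0),
        (separation + ax[0], 0.0, 0.0),
        lambda n: _sample_ellipsoid(rng, n, ax),
    )
    parts = [sphere, ellip]
    if linker_beads > 0:
        xs = np.linspace(r_sph, separation - ax[0], linker_beads + 2)[1:-1]
        parts.append(np.column_stack([xs, np.zeros_like(xs), np.zeros_like(xs)]))
    coords = np.vstack(parts)
    return BeadModel(coords=coords)


# ---------------------------------------------------------------------------
# melting curves
# ---------------------------------------------------------------------------


def gen_melt_curve(
    tex_true: float,
    release_width: float = 6.0,
    probe_slope: float = 0.004,
    amplitude: float = 1000.0,
    grid: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(sd=20.0),
    baseline: float = 200.0,
    metadata: dict | None = None,
) -> MeltCurve:
    """Temperature-ramp fluorescence of DNA release from a phage particle.

    fluorescence = baseline(T) * (closed fraction) + amplitude * (released
    fraction), where the released fraction is a logistic centred at
    ``tex_true`` whose 10-90% rise spans ``release_width`` °C, and the
    probe baseline declines linearly by ``probe_slope`` (fraction per °C).
    The analytic maximum of the release derivative sits at ``tex_true``.
    """
    if not 4.0 <= tex_true <= 99.0:
        raise ValueError(f"tex_true must be within the 4-99 °C ramp, got {tex_true}")
    if release_width <= 0:
        raise ValueError(f"release_width must be > 0, got {release_width}")
    if grid is None:
        grid = np.arange(4.0, 99.0 + 1e-9, 0.5)
    grid = np.asarray(grid, dtype=float)
    if tex_true < grid[0] or tex_true > grid[-1]:
        raise ValueError(
            f"tex_true = {tex_true} °C lies outside the temperature grid "
            f"[{grid[0]}, {grid[-1]}]"
        )
    scale = release_width / (2.0 * math.log(9.0))  # logistic 10-90% width
    released = 1.0 / (1.0 + np.exp(-(grid - tex_true) / scale))
    base = baseline * (1.0 - probe_slope * (grid - grid[0]))
    fluo = base * (1.0 - released) + amplitude * released
    if noise.sd > 0:
        fluo = fluo + noise.rng().normal(0.0, noise.sd, fluo.size)
    return MeltCurve(temperature=grid, fluorescence=fluo, metadata=metadata or {})


# ---------------------------------------------------------------------------
# sample quantitation
# ---------------------------------------------------------------------------


def particles_from_od(od260: float) -> float:
    """Phage particle concentration (particles/mL) from OD260: 3.4e11 x OD260."""
    if od260 < 0:
        raise ValueError(f"absorbance must be >= 0, got {od260}")
    return 3.4e11 * od260


def site_concentration(capsid_conc: float) -> float:
    """Decoration-site molarity: 120 hexameric sites per capsid."""
    if capsid_conc < 0:
        raise ValueError(f"capsid concentration must be >= 0, got {capsid_conc}")
    return 120.0 * capsid_conc
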