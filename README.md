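# decorakin

Quantitative biophysics of bacteriophage **capsid decoration**: a Python
toolkit for the measurements that characterise how a decoration protein
binds the 120 hexamer centres of an icosahedral phage capsid and what
that binding does for the particle.

The package grew around one model system — the two-domain decoration
protein of a T5-like siphophage, which binds its capsid with picomolar
affinity, near-irreversibly and with striking all-or-none cooperativity —
but every stage is generic:

| module | what it does |
|---|---|
| `decorakin.spr` | simulate and globally fit **transport-limited 1:1 SPR kinetics** (fixed-k_off fitting, double referencing, capture-drift deconvolution, K_D and mass accounting) |
| `decorakin.relax` | **Lipari–Szabo model-free analysis** of backbone ¹⁵N R1/R2/NOE with per-domain tumbling, AICc model selection and Monte-Carlo errors |
| `decorakin.saxs` | **Debye forward scattering** from bead models, P(r)/Rg/Dmax, χ scoring and Guinier analysis |
| `decorakin.melt` | **DNA-exit temperature (T_ex)** extraction from thermal-ramp fluorescence, condition-wise ΔT_ex tables |
| `decorakin.lattice` | **cooperative lattice-gas Monte Carlo** of decoration populations on the 120-site capsid |
| `decorakin.synthetic` | seeded generators producing inputs with the statistical structure each stage assumes, plus sample quantitation (120 sites/capsid, 3.4 × 10¹¹ particles · mL⁻¹ · OD₂₆₀⁻¹) |

## The models

**SPR kinetics.** Binding of an analyte at concentration `C` to surface
sites follows the two-compartment mass-transport-limited 1:1 model

```
dR/dt = [k_on C (R_max − R) − k_off R] / [1 + k_on (R_max − R)/k_t]
```

which reduces to ideal Langmuir kinetics as the transport coefficient
`k_t → ∞` and produces rebinding-slowed dissociation at finite `k_t`.
The ODE is solved exactly through the Lambert W function, so global
multi-concentration fits (shared `k_on`, `R_max`, `k_t`; `k_off` fixed or
free; `K_D = k_off/k_on`) are fast and robust.

**Model-free relaxation.** ¹⁵N R1, R2 and the heteronuclear NOE are
computed from the Lipari–Szabo spectral density
`J(ω) = (2/5)[S²τm/(1+(ωτm)²) + (1−S²)τ/(1+(ωτ)²)]` with dipolar (N–H,
1.02 Å) and CSA (−160 ppm) interactions; per-residue fits select among
models M1–M5 (S², τe, Rex, two-timescale) by AICc. The R2/R1 ratio gives
per-domain tumbling times — two domains on a flexible linker tumble
separately, which the diagnostics resolve.

**SAXS.** `I(q) = Σᵢⱼ wᵢwⱼ sin(q dᵢⱼ)/(q dᵢⱼ)` on pseudo-residue bead
models; `χ = sqrt(1/N Σ((I_exp − I_calc)/σ)²)` with optional scale
fitting.

**Melting.** T_ex is the temperature of the maximum of the first
derivative of the (Savitzky–Golay smoothed) dye-fluorescence ramp,
restricted to the release region.

**Cooperativity.** A lattice gas on the 120-site capsid graph:
`E = ΔG_bind·N_bound + ε_coop·(occupied neighbour pairs)` in kT, sampled
by Metropolis exchange with a shared finite ligand pool. Attractive
coupling reproduces the all-or-none population split seen on native gels.

## Worked example

```python
from decorakin import synthetic, spr, melt, lattice

# a seven-concentration SPR series (0.312-20 nM) in the picomolar,
# transport-limited regime, 0.5 RU of instrument noise
sgs = synthetic.gen_sensorgram_series(noise=synthetic.NoiseSpec(sd=0.5, seed=42))
print(spr.fit_global(sgs, koff_fixed=2e-4, seed=0).summary())
```

```
Global 1:1 transport-limited kinetic fit
----------------------------------------
k_on   = 1.784e+08 +/- 1.7e+06 M^-1 s^-1
k_off  = 0.0002 s^-1 (fixed)
R_max  = 100 +/- 0.012 RU
k_t    = 6.5e+08 +/- 4.5e+05 RU/(M s)
K_D    = 1.12 pM
resid. sd = 0.502 RU over 6027 points (10 starts)
```

The fit recovers the generating `k_on = 1.8e8 M⁻¹s⁻¹` to 0.9% and, with
the dissociation rate fixed at 2 × 10⁻⁴ s⁻¹, reports the picomolar
affinity `K_D = k_off/k_on`. No error is quoted on K_D when k_off is
forced.

```python
wt = melt.extract_tex(synthetic.gen_melt_curve(53.8, noise=synthetic.NoiseSpec(20.0, 1)))
dd = melt.extract_tex(synthetic.gen_melt_curve(47.5, noise=synthetic.NoiseSpec(20.0, 2)))
print(f"delta T_ex = {wt.tex - dd.tex:.2f} C")
# delta T_ex = 6.36 C       (wild-type phage retains its DNA 6 C further)

lat = lattice.build_capsid_graph("k-regular", seed=1)
dist = lattice.simulate_population(lat, lattice.DecorationModel(ratio=0.4),
                                   n_capsids=150, sweeps=8000, seed=3)
print(lattice.gel_pattern(dist))
# (0.60, 0.00, 0.40)        (all-or-none: no partially decorated band)
```

At a sub-stoichiometric ligand:site ratio of 0.4 the cooperative model
leaves 60% of capsids bare and saturates 40%, with essentially no
intermediates — the signature gel pattern of cooperative decoration.

A CLI mirrors the library: `decorakin simulate {spr,relax,saxs,melt}`,
`decorakin spr fit`, `decorakin relax fit`, `decorakin saxs chi|pr`,
`decorakin melt tex`, `decorakin coop simulate` (see `--help`).

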