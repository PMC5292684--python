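"""Independent oracle implementations, deliberately written as literal
transcriptions of the textbook formulas with no code shared with the
package.  Used to cross-check the package's optimized paths.
"""

import math

import numpy as np


def debye_double_loop(coords, weights, q_values):
    """Literal O(N^2) Debye sum: I(q) = sum_i sum_j w_i w_j sin(q d_ij)/(q d_ij)."""
    coords = np.asarray(coords, float)
    weights = np.asarray(weights, float)
    n = coords.shape[0]
    out = np.zeros(len(q_values))
    for iq, q in enumerate(q_values):
        total = 0.0
        for i in range(n):
            for j in range(n):
                d = math.dist(coords[i], coords[j])
                x = q * d
                total += weights[i] * weights[j] * (1.0 if x == 0.0 else math.sin(x) / x)
        out[iq] = total
    return out


def lipari_szabo_j(s2, tau_e, tau_m, omega):
    """Model-free spectral density, written out directly."""
    term1 = s2 * tau_m / (1.0 + (omega * tau_m) ** 2)
    if tau_e > 0.0 and s2 < 1.0:
        tau = 1.0 / (1.0 / tau_m + 1.0 / tau_e)
        term2 = (1.0 - s2) * tau / (1.0 + (omega * tau) ** 2)
    else:
        term2 = 0.0
    return 0.4 * (term1 + term2)


def nitrogen15_rates(s2, tau_e, rex, tau_m, field_mhz, rex_field_mhz=None):
    """Textbook 15N R1/R2/NOE from dipolar (N-H) + CSA relaxation.

    Constants written out numerically and independently of the package:
    gamma_H = 2.6752218744e8, gamma_N = -2.7126e7 rad/s/T, r_NH = 1.02 A,
    delta_sigma = -160 ppm, hbar = 1.054571817e-34, mu0 = 4pi e-7.
    """
    gamma_h = 2.6752218744e8
    gamma_n = -2.7126e7
    r_nh = 1.02e-10
    delta_sigma = -160.0e-6
    hbar = 1.054571817e-34
    mu0 = 4.0e-7 * math.pi

    omega_h = 2.0 * math.pi * field_mhz * 1.0e6
    omega_n = omega_h * gamma_n / gamma_h

    d = (mu0 / (4.0 * math.pi)) * hbar * gamma_h * gamma_n / r_nh**3
    d2_over_4 = d * d / 4.0
    c = omega_n * delta_sigma / math.sqrt(3.0)
    c2 = c * c

    def j(w):
        return lipari_szabo_j(s2, tau_e, tau_m, abs(w))

    r1 = d2_over_4 * (j(omega_h - omega_n) + 3.0 * j(omega_n) + 6.0 * j(omega_h + omega_n))
    r1 += c2 * j(omega_n)

    r2 = (d2_over_4 / 2.0) * (
        4.0 * j(0.0)
        + j(omega_h - omega_n)
        + 3.0 * j(omega_n)
        + 6.0 * j(omega_h)
        + 6.0 * j(omega_h + omega_n)
    )
    r2 += (c2 / 6.0) * (4.0 * j(0.0) + 3.0 * j(omega_n))
    if rex_field_mhz is None:
        rex_field_mhz = field_mhz
    r2 += rex * (field_mhz / rex_field_mhz) ** 2

    sigma_noe = d2_over_4 * (6.0 * j(omega_h + omega_n) - j(omega_h - omega_n))
    noe = 1.0 + (gamma_h / gamma_n) * sigma_noe / r1
    return r1, r2, noe


def langmuir_association(k_on, k_off, r_max, conc, t):
    """Closed-form ideal (no transport) 1:1 association from R(0)=0."""
    a = k_on * conc + k_off
    r_eq = r_max * k_on * conc / a
    return r_eq * (1.0 - np.exp(-a * np.asarray(t)))
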