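"""Independent numerical oracles used by the tests.

These deliberately avoid the closed forms and sampling tricks used by the
package: transmittance comes from direct integration of the two-flux
linear boundary-value system (matrix exponential), Henyey-Greenstein
moments from numerical quadrature of the phase-function density, and
Gaussian overlap widths from the analytic convolution identity.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm


def ode_transmittance(S: float, K: float, d: float) -> float:
    """Transmittance by solving dI/dx = -(S+K)I + SJ, dJ/dx = (S+K)J - SI
    with I(0) = 1, J(d) = 0, via the matrix exponential of the linear
    system (exact up to round-off)."""
    A = np.array([[-(S + K), S], [-S, (S + K)]])
    M = expm(A * d)
    # [I(d), J(d)] = M @ [1, J(0)];  J(d) = 0 fixes J(0)
    J0 = -M[1, 0] / M[1, 1]
    return float(M[0, 0] + M[0, 1] * J0)


def ode_flux(S: float, K: float, d: float, x: np.ndarray):
    """Forward/backward flux at depths x by the same matrix-exponential
    propagation."""
    A = np.array([[-(S + K), S], [-S, (S + K)]])
    Md = expm(A * d)
    J0 = -Md[1, 0] / Md[1, 1]
    v0 = np.array([1.0, J0])
    out = np.array([expm(A * xi) @ v0 for xi in np.atleast_1d(x)])
    return out[:, 0], out[:, 1]


def hg_pdf(ct: float, g: float) -> float:
    """Henyey-Greenstein density in cos(theta) on [-1, 1]."""
    return 0.5 * (1 - g * g) / (1 + g * g - 2 * g * ct) ** 1.5


def hg_moment(g: float, k: int) -> float:
    """E[cos^k theta] under the HG phase function, by quadrature."""
    val, _ = quad(lambda ct: ct**k * hg_pdf(ct, g), -1.0, 1.0,
                  epsabs=1e-12, epsrel=1e-12)
    return val


def gaussian_overlap_fwhm(fwhm_pump: float, fwhm_probe: float) -> float:
    """FWHM of the cross-correlation of two Gaussians."""
    return float(np.hypot(fwhm_pump, fwhm_probe))


def gaussian_overlap_curve(dx, fwhm_pump: float, fwhm_probe: float):
    """Closed-form probe-weighted pump overlap for unit-peak Gaussian
    beams: a Gaussian in dx of quadrature-summed width whose amplitude
    follows from the product-of-Gaussians integral."""
    dx = np.asarray(dx, dtype=float)
    s2f = 2.0 * np.sqrt(2.0 * np.log(2.0))
    sp = fwhm_pump / s2f
    sr = fwhm_probe / s2f
    s = np.hypot(sp, sr)
    # int G_p(x-dx) G_r(x) dx = sqrt(2 pi) sp sr / s * exp(-dx^2 / 2 s^2);
    # dividing by int G_r = sqrt(2 pi) sr leaves amplitude sp / s
    return (sp / s) * np.exp(-0.5 * (dx / s) ** 2)
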