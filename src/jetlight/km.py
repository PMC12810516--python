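"""Kubelka-Munk two-flux model for light transport in scattering slabs.

The two-flux (Kubelka-Munk) approximation describes diffuse light inside a
plane-parallel slab by a forward flux I(x) and a backward flux J(x) coupled
through

    dI/dx = -(S + K) I + S J
    dJ/dx = +(S + K) J - S I

where S (mm^-1) is the backward-scattering coefficient for diffuse light --
the probability per unit path that a scattering event reverses the
propagation direction -- and K (mm^-1) is the diffuse absorption
coefficient.  With boundary conditions I(0) = 1 (unit incident flux) and
J(d) = 0 (nothing returns from behind the slab) the system has the
classical closed-form solution in terms of

    a = (S + K) / S,      b = sqrt(a^2 - 1)

and the slab transmittance

    T(d) = b / (a sinh(b S d) + b cosh(b S d)).

The pure-absorption (S -> 0) and conservative (K = 0) limits are handled by
their analytic limit expressions rather than the general form, which
degenerates to 0/0 there.

Coefficients are in mm^-1 and thicknesses in mm throughout this module;
file I/O elsewhere accepts micrometres and converts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "KMCoefficients",
    "SlabSample",
    "FluxProfile",
    "TransmittanceDataset",
    "KMFitResult",
    "km_transmittance",
    "km_flux_profile",
    "mean_internal_intensity",
    "km_fit",
]


@dataclass(frozen=True)
class KMCoefficients:
    """Scattering/absorption coefficients of a turbid medium (mm^-1).

    The derived constants ``a`` and ``b`` of the closed-form solution are
    computed on construction.  For S = 0 they are not defined (the model is
    pure Beer-Lambert absorption); they are stored as NaN and never used by
    the limit expressions.
    """

    S: float
    K: float
    a: float = field(init=False)
    b: float = field(init=False)

    def __post_init__(self) -> None:
        if self.S < 0 or self.K < 0:
            raise ValueError(
                f"coefficients must be non-negative (got S={self.S}, K={self.K})"
            )
        if self.S > 0:
            a = (self.S + self.K) / self.S
            b = math.sqrt(max(a * a - 1.0, 0.0))
        else:
            a = math.nan
            b = math.nan
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)


@dataclass(frozen=True)
class SlabSample:
    """A slab of a given medium: optics plus thickness d (mm)."""

    optics: KMCoefficients
    d: float
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError(f"slab thickness must be positive (got d={self.d})")


@dataclass
class FluxProfile:
    """Forward/backward flux vs depth, relative to unit incident flux.

    Invariants: I[0] == 1, J[-1] == 0, total == I + J elementwise.
    """

    x: np.ndarray  # depth grid, mm, from 0 (front) to d (back)
    I: np.ndarray  # forward flux
    J: np.ndarray  # backward flux

    @property
    def total(self) -> np.ndarray:
        return self.I + self.J

    @property
    def d(self) -> float:
        return float(self.x[-1])


@dataclass
class TransmittanceDataset:
    """Multi-path-length transmittance records for one sample.

    ``pathlengths_mm`` and ``transmittance`` are parallel arrays;
    transmittances are fractions in (0, 1] measured relative to a
    non-scattering reference, so T = 1 means an optically empty slab.
    """

    sample: str
    wavelength_nm: float
    pathlengths_mm: np.ndarray
    transmittance: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pathlengths_mm = np.asarray(self.pathlengths_mm, dtype=float)
        self.transmittance = np.asarray(self.transmittance, dtype=float)
        if self.pathlengths_mm.shape != self.transmittance.shape:
            raise ValueError("pathlengths and transmittances must align")
        if np.any(self.pathlengths_mm <= 0):
            raise ValueError("path lengths must be positive")
        if np.any((self.transmittance <= 0) | (self.transmittance > 1)):
            raise ValueError("transmittances must lie in (0, 1]")

    def __len__(self) -> int:
        return self.pathlengths_mm.size


@dataclass
class KMFitResult:
    """Result of fitting KM coefficients to a TransmittanceDataset."""

    optics: KMCoefficients
    residuals: np.ndarray  # model - observed, per record
    converged: bool
    stderr_S: float | None
    stderr_K: float | None  # None when K was fixed
    K_fixed: bool
    n_records: int

    def report(self) -> dict:
        """JSON-compatible fit report with coefficients in mm^-1."""
        return {
            "S_mm^-1": self.optics.S,
            "K_mm^-1": self.optics.K,
            "stderr_S_mm^-1": self.stderr_S,
            "stderr_K_mm^-1": "n/a (fixed)" if self.K_fixed else self.stderr_K,
            "K_fixed": self.K_fixed,
            "converged": self.converged,
            "n_records": self.n_records,
            "rms_residual": float(np.sqrt(np.mean(self.residuals**2))),
        }


def _check_domain(S: float, K: float, d: float) -> None:
    if S < 0 or K < 0:
        raise ValueError(f"coefficients must be non-negative (S={S}, K={K})")
    if d < 0:
        raise ValueError(f"thickness must be non-negative (d={d})")


def km_transmittance(optics: KMCoefficients, d: float) -> float:
    """Slab transmittance of the two-flux model.

    Parameters
    ----------
    optics : KMCoefficients
        S and K in mm^-1.
    d : float
        Slab thickness in mm (d = 0 returns 1).
    """
    S, K = optics.S, optics.K
    _check_domain(S, K, d)
    if d == 0.0 or (S == 0.0 and K == 0.0):
        return 1.0
    if S == 0.0:  # pure absorption
        return math.exp(-K * d)
    if K == 0.0 or optics.b == 0.0:  # conservative scattering (or K/S below
        return 1.0 / (1.0 + S * d)   # round-off, where a==1 collapses b to 0)
    a, b = optics.a, optics.b
    bsd = b * S * d
    return b / (a * math.sinh(bsd) + b * math.cosh(bsd))


def km_flux_profile(optics: KMCoefficients, d: float, n_points: int = 501) -> FluxProfile:
    """Forward and backward flux versus depth inside a slab.

    General case (S > 0, K > 0), with D = a sinh(bSd) + b cosh(bSd):

        I(x) = [a sinh(bS(d-x)) + b cosh(bS(d-x))] / D
        J(x) = sinh(bS(d-x)) / D

    so I(0) = 1, J(d) = 0 and I(d) = T.  The K = 0 and S = 0 limits use
    their analytic forms.  Because back-scattered light adds to the
    not-yet-depleted forward flux near the entrance face, the total I + J
    can exceed 1 at the front of a strongly scattering slab.
    """
    S, K = optics.S, optics.K
    _check_domain(S, K, d)
    if d <= 0:
        raise ValueError("flux profile requires d > 0")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    x = np.linspace(0.0, d, n_points)
    if S == 0.0:
        I = np.exp(-K * x)
        J = np.zeros_like(x)
    elif K == 0.0 or optics.b == 0.0:
        # limit of the general form: I = (1 + S(d-x)) / (1 + Sd), J = S(d-x)/(1+Sd)
        denom = 1.0 + S * d
        I = (1.0 + S * (d - x)) / denom
        J = S * (d - x) / denom
    else:
        a, b = optics.a, optics.b
        arg = b * S * (d - x)
        D = a * math.sinh(b * S * d) + b * math.cosh(b * S * d)
        I = (a * np.sinh(arg) + b * np.cosh(arg)) / D
        J = np.sinh(arg) / D
    return FluxProfile(x=x, I=I, J=J)


def mean_internal_intensity(profile: FluxProfile) -> float:
    """Depth-average of the total internal intensity (I + J) over [0, d].

    For a non-absorbing slab this equals 1 for any scattering strength:
    scattering redistributes light between the forward and backward fluxes
    without changing the mean photon flux density (I - J is constant when
    K = 0, and I + J is then linear in depth from 2 - T to T).
    """
    return float(np.trapezoid(profile.total, profile.x) / profile.d)


def _initial_S(dataset: TransmittanceDataset) -> float:
    # algebraic inversion of the K=0 form at the mean record
    Tbar = float(np.mean(dataset.transmittance))
    dbar = float(np.mean(dataset.pathlengths_mm))
    Tbar = min(Tbar, 0.999999)
    return max((1.0 / Tbar - 1.0) / dbar, 1e-6)


def km_fit(
    dataset: TransmittanceDataset,
    fix_K_to_zero: bool = True,
    initial_guess: KMCoefficients | None = None,
) -> KMFitResult:
    """Fit S (and optionally K) to multi-path-length transmittance data.

    Unweighted least squares on transmittance with both coefficients
    constrained non-negative.  With K fixed at zero (the default, suitable
    for media with no absorber at the probe wavelength) a single record
    suffices; fitting S and K jointly requires at least two distinct path
    lengths and three are recommended.
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("empty dataset")
    if np.unique(dataset.pathlengths_mm).size < 2:
        if not (fix_K_to_zero and n >= 1):
            raise ValueError(
                "degenerate design: need >= 2 distinct path lengths to fit S and K"
            )
        if n == 1 and fix_K_to_zero:
            # exact inversion of T = 1/(1 + S d)
            T = float(dataset.transmittance[0])
            d = float(dataset.pathlengths_mm[0])
            S = (1.0 / T - 1.0) / d
            opt = KMCoefficients(S=S, K=0.0)
            res = np.array([km_transmittance(opt, d) - T])
            return KMFitResult(opt, res, True, None, None, True, 1)
        if n > 1:
            raise ValueError(
                "degenerate design: all path lengths identical"
            )

    if initial_guess is not None:
        S0, K0 = initial_guess.S, initial_guess.K
    else:
        S0, K0 = _initial_S(dataset), 0.01

    params = lmfit.Parameters()
    params.add("S", value=max(S0, 1e-8), min=0.0)
    params.add("K", value=0.0 if fix_K_to_zero else max(K0, 1e-8),
               min=0.0, vary=not fix_K_to_zero)

    d_arr = dataset.pathlengths_mm
    T_obs = dataset.transmittance

    def residual(p: lmfit.Parameters) -> np.ndarray:
        opt = KMCoefficients(S=p["S"].value, K=p["K"].value)
        return np.array([km_transmittance(opt, d) for d in d_arr]) - T_obs

    out = lmfit.minimize(residual, params, method="least_squares")
    opt = KMCoefficients(S=out.params["S"].value, K=out.params["K"].value)
    return KMFitResult(
        optics=opt,
        residuals=np.asarray(out.residual),
        converged=bool(out.success),
        stderr_S=out.params["S"].stderr,
        stderr_K=None if fix_K_to_zero else out.params["K"].stderr,
        K_fixed=fix_K_to_zero,
        n_records=n,
    )
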