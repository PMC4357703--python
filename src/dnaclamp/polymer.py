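"""Elastic polymer models for dsDNA and ssDNA.

The worm-like chain (WLC) describes double-stranded DNA through the
Marko-Siggia interpolation with the seven-term polynomial correction,

    F(l) = (kBT/Lp) * [ 1/(4(1-l)^2) - 1/4 + l + sum_{i=2..7} a_i l^i ],

where ``l`` is the relative extension.  In the *inextensible* variant
``l = x/l0``; in the *extensible* variant enthalpic stretching enters
through ``l = x/l0 - F/S`` and the force solves the implicit relation.

Single-stranded DNA is described by the extensible freely-jointed chain
(FJC),

    x(F) = n * b * [coth(F lk / kBT) - kBT/(F lk)] * (1 + F/S_ss).

Fitting of force-extension curves uses Levenberg-Marquardt least squares
(via :mod:`lmfit`) over any subset of (l0, Lp, S).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np
from scipy.optimize import brentq

from .constants import (
    DSDNA_LP,
    DSDNA_S,
    KBT_298,
    SSDNA_CONTOUR_PER_BASE,
    SSDNA_KUHN,
    SSDNA_STRETCH,
    WLC_ALPHA,
)

__all__ = [
    "WlcParams",
    "FjcParams",
    "ForceExtensionCurve",
    "WlcFitResult",
    "wlc_force",
    "wlc_extension",
    "fjc_extension",
    "fit_wlc",
]


@dataclass(frozen=True)
class WlcParams:
    """Worm-like-chain parameters.

    Attributes
    ----------
    l0 : contour length, nm.
    Lp : persistence length, nm.
    S : stretch modulus, pN (ignored by the inextensible variant).
    kBT : thermal energy, pN*nm.
    alpha : the six polynomial correction coefficients a_2..a_7.
    """

    l0: float
    Lp: float = DSDNA_LP
    S: float = DSDNA_S
    kBT: float = KBT_298
    alpha: tuple = field(default=WLC_ALPHA)

    def __post_init__(self):
        if self.l0 <= 0 or self.Lp <= 0 or self.S <= 0 or self.kBT <= 0:
            raise ValueError("WLC parameters must be positive")
        if len(self.alpha) != 6:
            raise ValueError("exactly six correction coefficients (a_2..a_7) required")


@dataclass(frozen=True)
class FjcParams:
    """Extensible freely-jointed-chain parameters for ssDNA."""

    kuhn_length: float = SSDNA_KUHN
    contour_per_base: float = SSDNA_CONTOUR_PER_BASE
    stretch_modulus: float = SSDNA_STRETCH
    kBT: float = KBT_298

    def __post_init__(self):
        if min(self.kuhn_length, self.contour_per_base, self.stretch_modulus, self.kBT) <= 0:
            raise ValueError("FJC parameters must be positive")


@dataclass
class ForceExtensionCurve:
    """Ordered (force, extension) samples from a pulling experiment."""

    force: np.ndarray  # pN
    extension: np.ndarray  # nm
    direction: str = "stretch"  # stretch | release
    pulling_speed: float = float("nan")  # nm/s
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.force = np.asarray(self.force, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.force.shape != self.extension.shape:
            raise ValueError("force and extension must have equal length")
        if np.any(self.force < 0):
            raise ValueError("forces must be non-negative")
        if self.direction not in ("stretch", "release"):
            raise ValueError("direction must be 'stretch' or 'release'")

    def __len__(self):
        return self.force.size


def _ms_force_rel(l, params: WlcParams):
    """Marko-Siggia force at relative extension ``l`` (vectorized)."""
    l = np.asarray(l, dtype=float)
    poly = np.zeros_like(l)
    for i, a in enumerate(params.alpha, start=2):
        poly = poly + a * l**i
    return (params.kBT / params.Lp) * (0.25 / (1.0 - l) ** 2 - 0.25 + l + poly)


def _ms_inverse(force, params: WlcParams, tol=1e-12):
    """Relative extension solving the Marko-Siggia relation (vectorized).

    Newton iteration with a bracketing bisection fallback; the force law is
    strictly increasing on [0, 1) so the root is unique.
    """
    F = np.atleast_1d(np.asarray(force, dtype=float))
    lo = np.zeros_like(F)
    hi = np.full_like(F, 1.0 - 1e-12)
    # bisection: robust, ~45 iterations reach 1e-14 in l
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_low = _ms_force_rel(mid, params) < F
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
        if np.max(hi - lo) < tol:
            break
    out = 0.5 * (lo + hi)
    out[F <= 0] = 0.0
    return out if np.ndim(force) else float(out[0])


def wlc_force(x, params: WlcParams, variant="inextensible"):
    """Force of the worm-like chain.

    For the inextensible variant ``x`` is the relative extension
    ``l = x_abs/l0`` and must lie in [0, 1).  For the extensible variant
    ``x`` is the absolute extension in nm and the returned force solves
    the implicit relation ``l = x/l0 - F/S``.
    """
    if variant == "inextensible":
        l = np.asarray(x, dtype=float)
        if np.any(l < 0) or np.any(l >= 1):
            raise ValueError("relative extension must satisfy 0 <= l < 1")
        return _ms_force_rel(l, params)
    if variant != "extensible":
        raise ValueError(f"unknown WLC variant {variant!r}")

    def solve_one(xi):
        if xi <= 0:
            return 0.0

        def resid(F):
            return _ms_force_rel(xi / params.l0 - F / params.S, params) - F

        f_lo = max(0.0, params.S * (xi / params.l0 - 1.0) + 1e-9)
        f_hi = max(1.0, 2.0 * f_lo)
        for _ in range(200):
            if resid(f_hi) < 0:
                break
            f_hi = 2.0 * f_hi + 1.0
        else:
            raise RuntimeError("extensible WLC force solve did not bracket")
        if resid(f_lo + 1e-12) < 0:
            return f_lo
        return brentq(resid, f_lo + 1e-12, f_hi, xtol=1e-12, rtol=1e-14)

    if np.ndim(x) == 0:
        return solve_one(float(x))
    return np.array([solve_one(float(xi)) for xi in np.asarray(x, dtype=float)])


def wlc_extension(force, params: WlcParams, variant="inextensible"):
    """Extension (nm) of the worm-like chain at the given force (pN)."""
    F = np.asarray(force, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be non-negative")
    l = _ms_inverse(F, params)
    if variant == "inextensible":
        return params.l0 * l
    if variant == "extensible":
        return params.l0 * (l + F / params.S)
    raise ValueError(f"unknown WLC variant {variant!r}")


def fjc_extension(force, params: FjcParams, n_bases):
    """Extension (nm) of an extensible FJC of ``n_bases`` bases.

    Returns 0 at F = 0 by continuity (the Langevin bracket vanishes).
    """
    if n_bases < 0:
        raise ValueError("n_bases must be non-negative")
    F = np.asarray(force, dtype=float)
    u = F * params.kuhn_length / params.kBT
    with np.errstate(divide="ignore", invalid="ignore"):
        bracket = np.where(u > 1e-8, 1.0 / np.tanh(np.maximum(u, 1e-300)) - 1.0 / np.maximum(u, 1e-300), u / 3.0)
    x = n_bases * params.contour_per_base * bracket * (1.0 + F / params.stretch_modulus)
    return x if np.ndim(force) else float(x)


@dataclass
class WlcFitResult:
    """Outcome of a WLC least-squares fit."""

    params: WlcParams
    stderr: dict
    residual_rms: float
    n_points: int
    success: bool
    report: str


def fit_wlc(
    curve: ForceExtensionCurve,
    variant="extensible",
    force_range=(0.0, 40.0),
    free_params=("l0", "Lp", "S"),
    initial: WlcParams | None = None,
) -> WlcFitResult:
    """Fit a force-extension curve to the WLC model.

    Residuals are taken in extension (model extension at the measured
    force), which keeps the extensible variant explicit.  ``free_params``
    selects the subset of (l0, Lp, S) to optimize; the rest are held at
    the values in ``initial`` (or package defaults).
    """
    mask = (curve.force >= force_range[0]) & (curve.force <= force_range[1])
    F = curve.force[mask]
    x = curve.extension[mask]
    free_params = tuple(free_params)
    for p in free_params:
        if p not in ("l0", "Lp", "S"):
            raise ValueError(f"unknown free parameter {p!r}")
    if F.size < 3 * len(free_params) or F.size < 10:
        raise ValueError(
            f"insufficient data: {F.size} samples in force range for "
            f"{len(free_params)} free parameters"
        )
    if initial is None:
        l0_guess = float(np.max(x) / 0.95)
        initial = WlcParams(l0=l0_guess)

    pars = lmfit.Parameters()
    pars.add("l0", value=initial.l0, min=1e-3, vary="l0" in free_params)
    pars.add("Lp", value=initial.Lp, min=1e-3, vary="Lp" in free_params)
    pars.add("S", value=initial.S, min=1.0, vary="S" in free_params)

    def residual(p):
        wp = replace(initial, l0=p["l0"].value, Lp=p["Lp"].value, S=p["S"].value)
        return wlc_extension(F, wp, variant) - x

    result = lmfit.minimize(residual, pars, method="leastsq")
    if not result.success:
        raise RuntimeError(f"WLC fit did not converge: {result.message}")
    best = replace(
        initial,
        l0=result.params["l0"].value,
        Lp=result.params["Lp"].value,
        S=result.params["S"].value,
    )
    stderr = {
        name: (result.params[name].stderr if result.params[name].vary else None)
        for name in ("l0", "Lp", "S")
    }
    return WlcFitResult(
        params=best,
        stderr=stderr,
        residual_rms=float(np.sqrt(np.mean(result.residual**2))),
        n_points=int(F.size),
        success=bool(result.success),
        report=lmfit.fit_report(result),
    )
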