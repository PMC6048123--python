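"""Worm-like-chain (WLC) polymer elasticity.

The entropic elasticity of an unfolded polypeptide chain is modelled with the
Marko-Siggia interpolation formula

    F(x) = (kBT / p) * [ 1/4 (1 - x/Lc)^-2 - 1/4 + x/Lc ]

where ``p`` is the persistence length, ``Lc`` the contour length and ``kBT``
the thermal energy.  This single form is used both to synthesise
force-extension behaviour in the simulator and to fit rupture peaks for
contour-length increments in the analysis pipeline, so that the closed loop
(simulate -> analyse) is internally consistent.

Default parameters: ``p = 0.4 nm`` (the conventional polypeptide value) and
``kBT = 4.114 pN nm`` (298 K).  Both are overridable everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KBT_ROOM",
    "DEFAULT_PERSISTENCE_NM",
    "WLCParams",
    "ContourIncrement",
    "wlc_force",
    "wlc_extension",
    "theoretical_delta_lc",
    "series_extension",
]

#: thermal energy at 298 K, pN nm
KBT_ROOM = 4.114

#: conventional polypeptide persistence length, nm
DEFAULT_PERSISTENCE_NM = 0.4

# relative distance from the contour length at which the chain is treated as
# fully extended (the WLC force diverges there)
_EDGE = 1e-9


@dataclass(frozen=True)
class WLCParams:
    """Parameter bundle for one worm-like chain.

    Attributes
    ----------
    persistence_length : float
        Persistence length ``p`` in nm (> 0).
    contour_length : float
        Contour length ``Lc`` in nm (> 0).
    thermal_energy : float
        ``kBT`` in pN nm (> 0).
    """

    persistence_length: float = DEFAULT_PERSISTENCE_NM
    contour_length: float = 28.0
    thermal_energy: float = KBT_ROOM

    def __post_init__(self) -> None:
        if not (self.persistence_length > 0):
            raise ValueError("persistence_length must be > 0")
        if not (self.contour_length > 0):
            raise ValueError("contour_length must be > 0")
        if not (self.thermal_energy > 0):
            raise ValueError("thermal_energy must be > 0")


@dataclass(frozen=True)
class ContourIncrement:
    """A contour-length increment released by one unfolding event (nm)."""

    delta_lc: float
    uncertainty: float = 0.0

    def __post_init__(self) -> None:
        if not (self.delta_lc > 0):
            raise ValueError("delta_lc must be > 0")


def _ms_force(x, p: float, lc: float, kbt: float):
    s = np.asarray(x, dtype=float) / lc
    return (kbt / p) * (0.25 / (1.0 - s) ** 2 - 0.25 + s)


def wlc_force(extension, params: WLCParams):
    """Marko-Siggia force (pN) at the given extension (nm).

    ``extension`` may be a scalar or array; it must satisfy
    ``0 <= extension < contour_length``.
    """
    x = np.asarray(extension, dtype=float)
    if np.any(x < 0):
        raise ValueError("extension must be non-negative")
    if np.any(x >= params.contour_length):
        raise ValueError("extension must be smaller than the contour length")
    out = _ms_force(
        x, params.persistence_length, params.contour_length, params.thermal_energy
    )
    if np.ndim(extension) == 0:
        return float(out)
    return out


def wlc_extension(force, params: WLCParams, rtol: float = 1e-9):
    """Numerical inverse of :func:`wlc_force` by bracketed bisection.

    Returns the extension (nm) in ``[0, Lc)`` at which the chain exerts the
    requested force.  ``force`` may be a scalar or array of non-negative,
    finite values.
    """
    f = np.asarray(force, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("force must be finite")
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    scalar = np.ndim(force) == 0
    f = np.atleast_1d(f)
    lc = params.contour_length
    p = params.persistence_length
    kbt = params.thermal_energy

    lo = np.zeros_like(f)
    hi = np.full_like(f, lc * (1.0 - _EDGE))
    # ~60 bisection steps: resolution 2^-60 * Lc, far below rtol * Lc
    n_iter = max(60, int(np.ceil(-np.log2(rtol))) + 10)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        too_low = _ms_force(mid, p, lc, kbt) < f
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    out = 0.5 * (lo + hi)
    out[f == 0] = 0.0
    if scalar:
        return float(out[0])
    return out


def theoretical_delta_lc(
    n_residues: int,
    length_per_residue: float = 0.4,
    folded_length: float = 5.0,
) -> float:
    """Theoretical contour-length increment for a domain of ``n_residues``.

    The released contour is estimated as 0.4 nm per residue minus the size of
    the folded domain (default 5 nm), i.e. the length already spanned before
    unfolding.
    """
    if n_residues <= 0:
        raise ValueError("n_residues must be > 0")
    if folded_length < 0:
        raise ValueError("folded_length must be >= 0")
    value = length_per_residue * n_residues - folded_length
    if value <= 0:
        raise ValueError(
            "domain smaller than its folded size: "
            f"{length_per_residue} * {n_residues} <= {folded_length}"
        )
    return value


def series_extension(base_position, params: WLCParams, stiffness: float):
    """Quasi-static equilibrium of a WLC in series with a Hookean cantilever.

    In force-extension mode the cantilever base sits at ``z``; the molecule
    extends by ``x`` and the cantilever deflects by ``z - x``, so the
    equilibrium satisfies ``F_wlc(x) = k_c (z - x)``.  The left side is
    strictly increasing and the right side strictly decreasing in ``x``, so
    the root is unique; it is found by vectorised bisection.

    Returns ``(x, F)`` arrays for an array of base positions (nm).
    """
    if stiffness <= 0:
        raise ValueError("stiffness must be > 0")
    z = np.atleast_1d(np.asarray(base_position, dtype=float))
    lc = params.contour_length
    p = params.persistence_length
    kbt = params.thermal_energy

    lo = np.zeros_like(z)
    hi = np.minimum(np.clip(z, 0.0, None), lc * (1.0 - _EDGE))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_low = _ms_force(mid, p, lc, kbt) < stiffness * (z - mid)
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    x = 0.5 * (lo + hi)
    x[z <= 0] = 0.0
    force = stiffness * np.clip(z - x, 0.0, None)
    return x, force
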