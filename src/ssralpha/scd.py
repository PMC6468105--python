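"""Reference-free scalp current density (SCD) via spherical splines.

The scalp potential map at each time sample is interpolated with a
spherical spline (Perrin-style Legendre-series kernel) and the surface
Laplacian of that spline is evaluated at the electrode sites.  The result
is a current source density: positive where current flows out of the
scalp (potential maxima), in input-units per square radian on the unit
sphere.  The transform is linear, so it is precomputed once as a
channels x channels matrix and applied to all trials and samples.

Because the Laplacian annihilates constants, SCD is independent of the
recording reference — the property that motivates its use ahead of any
spectral decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import legval

from .data import Epochs, Montage

__all__ = ["SCDParams", "scd_transform_matrix", "spherical_spline_scd"]


@dataclass
class SCDParams:
    """Spline settings: ridge regularizer ``lam``, spline order ``m`` and
    Legendre-series truncation ``n_legendre`` (terms below ``term_tol``
    are dropped early)."""

    lam: float = 1e-4
    m: int = 4
    n_legendre: int = 20
    term_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.m < 2:
            raise ValueError("spline order m must be >= 2")
        if self.n_legendre < 7:
            raise ValueError("n_legendre must be >= 7")


def _kernel_coeffs(params: SCDParams) -> tuple[np.ndarray, np.ndarray]:
    """Legendre coefficients of the interpolation kernel g and the
    (negated-)Laplacian kernel h: term n of g is
    (2n+1) / (n (n+1))**m / (4 pi) and h drops one power of n(n+1)."""
    cg = [0.0]
    ch = [0.0]
    for n in range(1, params.n_legendre + 1):
        base = (2 * n + 1) / (4 * np.pi)
        g_n = base / (n * (n + 1)) ** params.m
        cg.append(g_n)
        ch.append(base / (n * (n + 1)) ** (params.m - 1))
        if g_n < params.term_tol and n >= 7:
            break
    return np.array(cg), np.array(ch)


def scd_transform_matrix(montage: Montage, params: SCDParams | None = None) -> np.ndarray:
    """Channels x channels matrix mapping a potential map to its SCD map.

    Solves the constrained spline system (kernel Gram matrix with ridge
    ``lam`` on the diagonal, zero-sum constraint on the spline weights)
    and composes it with the Laplacian kernel evaluated between all
    electrode pairs.
    """
    if params is None:
        params = SCDParams()
    pos = montage.positions
    n = pos.shape[0]
    if n < 8:
        raise ValueError("SCD needs at least 8 channels")
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    off = ~np.eye(n, dtype=bool)
    if np.any(cosang[off] > 1.0 - 1e-12):
        raise ValueError("coincident electrode positions make the spline system singular")
    cg, ch = _kernel_coeffs(params)
    G = legval(cosang, cg)
    H = legval(cosang, ch)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G + params.lam * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise ValueError("singular spline system (coincident electrodes?)") from exc
    # spline weights c = Ainv[:n, :n] @ v (the constraint row absorbs the
    # constant offset), SCD = H @ c
    return H @ Ainv[:n, :n]


def spherical_spline_scd(epochs: Epochs, montage: Montage,
                         params: SCDParams | None = None) -> Epochs:
    """Apply the spherical-spline surface Laplacian to every sample."""
    if epochs.n_channels != montage.n_channels:
        raise ValueError("epochs/montage channel mismatch")
    M = scd_transform_matrix(montage, params)
    out = np.einsum("ij,tjs->tis", M, epochs.data)
    return epochs.copy_with(data=out, units=f"{epochs.units}/sr")
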