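"""Classical Ewald summation for the explicit-ion electrostatics mode.

Intended for small cross-check systems (a few hundred charges), so the
reciprocal sum is evaluated with dense numpy arrays over a cubic k-grid.
Splitting parameter alpha and the k-space extent are chosen from the
requested ``accuracy`` a:  with s = sqrt(-ln a), alpha = s/rcut and
kmax = ceil(s * alpha * L / pi), the standard heuristic that balances the
real- and reciprocal-space truncation errors.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erfc


def _params(L: float, accuracy: float, rcut: float | None):
    if rcut is None:
        rcut = 0.499 * L
    s = math.sqrt(-math.log(accuracy))
    alpha = s / rcut
    kmax = int(math.ceil(s * alpha * L / math.pi))
    return rcut, alpha, max(kmax, 1)


def _kvectors(L: float, kmax: int) -> np.ndarray:
    rng = np.arange(-kmax, kmax + 1)
    kx, ky, kz = np.meshgrid(rng, rng, rng, indexing="ij")
    k = np.stack([kx.ravel(), ky.ravel(), kz.ravel()], axis=1)
    k = k[np.any(k != 0, axis=1)]
    return (2.0 * np.pi / L) * k.astype(float)


def _real_space(pos: np.ndarray, q: np.ndarray, L: float, lb: float, alpha: float, rcut: float):
    d = pos[:, None, :] - pos[None, :, :]
    d -= L * np.rint(d / L)
    r = np.sqrt((d * d).sum(axis=2))
    np.fill_diagonal(r, np.inf)
    mask = r < rcut
    qq = q[:, None] * q[None, :]
    u = 0.5 * lb * (qq * erfc(alpha * r) / r * mask).sum()
    return u, d, r, qq, mask


def ewald_energy(pos: np.ndarray, q: np.ndarray, L: float, lb: float,
                 accuracy: float = 1e-5, rcut: float | None = None) -> float:
    """Periodic Coulomb energy (in k_BT) of a neutral set of point charges."""
    rcut, alpha, kmax = _params(L, accuracy, rcut)
    u_real, _, _, _, _ = _real_space(pos, q, L, lb, alpha, rcut)
    kvec = _kvectors(L, kmax)
    k2 = (kvec * kvec).sum(axis=1)
    phase = kvec @ pos.T                       # (K, N)
    S_re = (np.cos(phase) * q).sum(axis=1)
    S_im = (np.sin(phase) * q).sum(axis=1)
    A = np.exp(-k2 / (4.0 * alpha * alpha)) / k2
    u_recip = (2.0 * np.pi * lb / L ** 3) * (A * (S_re ** 2 + S_im ** 2)).sum()
    u_self = -lb * alpha / math.sqrt(math.pi) * (q * q).sum()
    return float(u_real + u_recip + u_self)


def ewald_forces(pos: np.ndarray, q: np.ndarray, L: float, lb: float,
                 accuracy: float = 1e-5, rcut: float | None = None) -> np.ndarray:
    """Forces conjugate to :func:`ewald_energy`."""
    rcut, alpha, kmax = _params(L, accuracy, rcut)
    _, d, r, qq, mask = _real_space(pos, q, L, lb, alpha, rcut)
    with np.errstate(invalid="ignore"):
        coef = lb * qq * (
            erfc(alpha * r) / r + 2.0 * alpha / math.sqrt(math.pi) * np.exp(-(alpha * r) ** 2)
        ) / (r * r)
    coef = np.where(mask, coef, 0.0)
    F = (coef[:, :, None] * d).sum(axis=1)

    kvec = _kvectors(L, kmax)
    k2 = (kvec * kvec).sum(axis=1)
    phase = kvec @ pos.T                       # (K, N)
    cos_p = np.cos(phase)
    sin_p = np.sin(phase)
    S_re = (cos_p * q).sum(axis=1)
    S_im = (sin_p * q).sum(axis=1)
    A = np.exp(-k2 / (4.0 * alpha * alpha)) / k2
    # F_i = (4 pi lb q_i / V) sum_k A(k) k [sin(k.r_i) Re S - cos(k.r_i) Im S]
    w = A[:, None] * (sin_p * S_re[:, None] - cos_p * S_im[:, None])   # (K, N)
    F += (4.0 * np.pi * lb / L ** 3) * q[:, None] * (kvec.T @ w).T
    return F
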