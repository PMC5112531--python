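"""Multiplicative growth kinematics and neo-Hookean constitutive law.

Kinematics: the total deformation gradient decomposes as F = A G, where the
growth tensor G = g I changes volume stress-free and the elastic tensor A
carries the stress.  The material is neo-Hookean with strain energy
quadratic in the elastic principal stretches,

    W(A) = mu/2 (lam1^2 + lam2^2 + lam3^2 - 3) - mu ln J + K/2 (J - 1)^2,

with J = det A.  The logarithmic term makes the undeformed state
stress-free; the volumetric penalty pressure p = K (J - 1) stands in for
the incompressibility Lagrange multiplier (K >> mu keeps |J - 1| small).
The resulting Cauchy stress is

    sigma = (mu / J) (A A^T - I) + p I.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_MU = 330.0            # Pa, shear modulus of cortex and core
DEFAULT_BULK_FACTOR = 100.0   # bulk_penalty = factor * mu


@dataclass
class Material:
    """Near-incompressible neo-Hookean material.

    ``stiffness_schedule`` optionally maps baseline cortex growth g to the
    shear-modulus multiplier of the special area; it must start at 1 and be
    non-decreasing (checked where it is sampled).
    """

    mu: float = DEFAULT_MU
    bulk_penalty: float | None = None
    stiffness_schedule: object = None  # callable g -> multiplier, or None

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.bulk_penalty is None:
            self.bulk_penalty = DEFAULT_BULK_FACTOR * self.mu
        if self.bulk_penalty < 50.0 * self.mu:
            raise ValueError("bulk_penalty must be >= 50*mu for "
                             "near-incompressibility")


def growth_tensor(g: float, dim: int = 3) -> np.ndarray:
    """Isotropic growth tensor G = g I (g >= 1; resorption not modelled)."""
    if g < 1.0:
        raise ValueError("growth multiplier must be >= 1 (no resorption)")
    return g * np.eye(dim)


def elastic_tensor(F: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Elastic part A = F G^{-1} of the multiplicative split F = A G."""
    F = np.asarray(F, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    if np.linalg.det(G) <= 0:
        raise ValueError("growth tensor must have positive determinant")
    if np.linalg.det(F) <= 0:
        raise ValueError("deformation gradient must have positive determinant")
    return F @ np.linalg.inv(G)


def strain_energy_density(A: np.ndarray, mat: Material) -> float:
    """Energy per unit intermediate (grown) volume.

    In 2D (plane strain) the out-of-plane elastic stretch is 1 and drops
    out of the stretch sum.
    """
    A = np.asarray(A, dtype=np.float64)
    d = A.shape[0]
    J = np.linalg.det(A)
    if J <= 0:
        raise ValueError("element inversion: det A <= 0")
    I1 = float(np.sum(A * A))  # lam1^2 + ... in d dimensions
    K = mat.bulk_penalty
    return 0.5 * mat.mu * (I1 - d) - mat.mu * np.log(J) + 0.5 * K * (J - 1.0) ** 2


def cauchy_stress(A: np.ndarray, mat: Material) -> tuple[np.ndarray, float]:
    """Cauchy stress and penalty pressure for an elastic tensor A.

    Returns ``(sigma, p)`` with sigma symmetric, sigma(I) = 0, and
    sigma(R) = 0 for any rotation R (frame indifference).
    """
    A = np.asarray(A, dtype=np.float64)
    d = A.shape[0]
    J = float(np.linalg.det(A))
    if J <= 0:
        raise ValueError("element inversion: det A <= 0")
    B = A @ A.T
    p = mat.bulk_penalty * (J - 1.0)
    sigma = (mat.mu / J) * (B - np.eye(d)) + p * np.eye(d)
    return 0.5 * (sigma + sigma.T), p


def principal_stretches(A: np.ndarray) -> np.ndarray:
    """Elastic principal stretches (singular values of A), padded with the
    unit out-of-plane stretch in 2D plane strain."""
    s = np.linalg.svd(np.asarray(A, dtype=np.float64), compute_uv=False)
    if len(s) == 2:
        s = np.append(s, 1.0)
    return s
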