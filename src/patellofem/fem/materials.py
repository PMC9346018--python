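"""Cartilage constitutive parameters.

Cartilage is modeled as a homogeneous, isotropic, linear-elastic solid
(small strain), rigidly bonded to rigid bone at the osteochondral
interface.  Defaults follow the patellofemoral FE literature: E = 5.0 MPa,
nu = 0.47 (nearly incompressible), cartilage-on-cartilage friction 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MaterialParams:
    E: float = 5.0     # Young's modulus, MPa
    nu: float = 0.47   # Poisson's ratio
    mu: float = 0.02   # friction coefficient

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError("Poisson's ratio must be in [0, 0.5)")
        if self.mu < 0:
            raise ValueError("friction coefficient must be non-negative")

    @property
    def constrained_modulus(self) -> float:
        """Uniaxial-strain (confined compression) modulus
        E(1-nu) / ((1+nu)(1-2nu))."""
        E, nu = self.E, self.nu
        return E * (1 - nu) / ((1 + nu) * (1 - 2 * nu))

    def stiffness_matrix(self) -> np.ndarray:
        """6x6 isotropic elasticity matrix, Voigt order
        [xx, yy, zz, xy, yz, zx] with engineering shear strains."""
        E, nu = self.E, self.nu
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        g = E / (2 * (1 + nu))
        C = np.zeros((6, 6))
        C[:3, :3] = lam
        C[np.arange(3), np.arange(3)] = lam + 2 * g
        C[np.arange(3, 6), np.arange(3, 6)] = g
        return C
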