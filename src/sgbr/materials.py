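"""Isotropic linear-elastic material models with brittle-failure parameters.

Shipped defaults are the moduli used throughout the mandible reconstruction
analyses: mandibular bone 12 000 MPa, laser-sintered PEK 2 400 MPa, and the
beta-TCP ceramic 15 000 MPa, all with Poisson ratio 0.3; tensile strengths
(maximum allowable principal stress) 150 MPa for bone and 80 MPa for
LS-PEK, with fracture toughness 1.46 and 1.05 MPa*m^0.5 respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MaterialModel:
    """Isotropic elasticity plus optional failure parameters.

    E : Young's modulus, MPa. nu : Poisson ratio in [0, 0.5).
    sigma_max : allowable principal (tensile) stress, MPa (None disables
    fracture for this material). K_Ic : mode-I fracture toughness,
    MPa*m^0.5. rho : density, g/cm^3.
    """

    name: str
    E: float
    nu: float = 0.3
    sigma_max: float | None = None
    K_Ic: float | None = None
    rho: float | None = None

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError(f"material {self.name!r}: E must be positive")
        if not 0 <= self.nu < 0.5:
            raise ValueError(f"material {self.name!r}: nu must be in [0, 0.5)")
        if self.sigma_max is not None and self.sigma_max <= 0:
            raise ValueError(f"material {self.name!r}: sigma_max must be positive")

    def stiffness_matrix(self) -> np.ndarray:
        """6x6 isotropic elasticity tensor in Voigt order (xx,yy,zz,yz,xz,xy)."""
        return isotropic_stiffness(self.E, self.nu)


def isotropic_stiffness(E: float, nu: float) -> np.ndarray:
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.diag_indices(3)] = lam + 2 * mu
    C[3, 3] = C[4, 4] = C[5, 5] = mu
    return C


BONE = MaterialModel("bone", E=12000.0, nu=0.3, sigma_max=150.0, K_Ic=1.46,
                     rho=1.62)
LS_PEK = MaterialModel("ls_pek", E=2400.0, nu=0.3, sigma_max=80.0, K_Ic=1.05)
BTCP = MaterialModel("btcp", E=15000.0, nu=0.3)
NEW_BONE = MaterialModel("new_bone", E=12000.0, nu=0.3, sigma_max=150.0,
                         K_Ic=1.46, rho=1.62)
TITANIUM_SCREW = MaterialModel("screw", E=110000.0, nu=0.3)

DEFAULT_MATERIALS = {
    "bone": BONE,
    "ls_pek": LS_PEK,
    "btcp": BTCP,
    "new_bone": NEW_BONE,
    "screw": TITANIUM_SCREW,
}

# Shipped interface friction coefficients: bone-scaffold contact without
# osseointegration mu = 0.1; bone-screw grip mu = 0.3. With
# osseointegration the bone-scaffold interface is tied (bonded).
MU_BONE_SCAFFOLD = 0.1
MU_BONE_SCREW = 0.3
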