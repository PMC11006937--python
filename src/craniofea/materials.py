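"""Isotropic linear-elastic materials and the constitutive matrix.

Moduli are stored in MPa so that with mm/N geometry and loads the stress
field is in MPa directly.  The study defaults follow experimentally derived
properties for archosaur cranial tissue: bone E = 20.49 GPa, nu = 0.40 and
tooth enamel/dentine E = 60.40 GPa, nu = 0.31, both treated as isotropic
and homogeneous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Material", "elasticity_matrix", "BONE", "TEETH"]


@dataclass(frozen=True)
class Material:
    """Isotropic elastic material: name, Young's modulus (MPa), Poisson ratio."""

    name: str
    E: float  # MPa
    nu: float

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"Young's modulus must be positive, got {self.E}")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError(
                f"Poisson ratio must lie in [0, 0.5), got {self.nu} "
                "(the incompressible limit is unsupported)"
            )

    @classmethod
    def from_gpa(cls, name: str, E_GPa: float, nu: float) -> "Material":
        """Construct from a modulus quoted in GPa (converted x1000 to MPa)."""
        return cls(name=name, E=E_GPa * 1e3, nu=nu)


#: Cranial bone default (alligator-mandible derived): E = 20.49 GPa, nu = 0.40.
BONE = Material.from_gpa("bone", 20.49, 0.40)
#: Tooth default (crocodile-tooth derived): E = 60.40 GPa, nu = 0.31.
TEETH = Material.from_gpa("teeth", 60.40, 0.31)


def elasticity_matrix(material: Material) -> np.ndarray:
    """6x6 isotropic constitutive matrix D in Voigt order (xx,yy,zz,xy,yz,zx).

    Engineering shear strains are used, so the shear diagonal carries the
    shear modulus G = E/(2(1+nu)).  The matrix is symmetric positive
    definite for 0 <= nu < 0.5.
    """
    E, nu = material.E, material.nu
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    G = E / (2.0 * (1.0 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] = lam + 2.0 * G
    D[np.arange(3, 6), np.arange(3, 6)] = G
    return D
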