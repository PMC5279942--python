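"""Spring-constant and force calibration for cylindrical elastomer pili.

Each pilus in a PDMS pillar array behaves as a cantilevered cylinder: a
lateral deflection ``d`` of the pilus top produces a restoring force
``F = k·d`` with spring constant

    k = (3/4) · π · E · r⁴ / L³

where ``E`` is the elastic modulus of the elastomer and ``r``, ``L`` the
cylinder radius and length.  With ``E`` in MPa, ``r`` and ``L`` in µm and
``d`` in nm the natural output units are pN/nm for ``k`` and nN for ``F``,
using the exact identity 1 MPa ≡ 1 pN/nm².

Forces are reported as positive magnitudes; the restoring force opposes
the deflection, but the sign carries no information once the deflection
magnitude is the quantity of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PillarGeometry",
    "SpringModel",
    "DEFAULT_GEOMETRY",
    "spring_constant",
    "deflection_to_force",
    "MPA_PER_PN_NM2",
    "NM_PER_UM",
]

#: 1 MPa = 1 pN/nm², exactly (1e6 N/m² · 1e12 pN/N / 1e18 nm²/m²).
MPA_PER_PN_NM2 = 1.0
#: nanometres per micrometre.
NM_PER_UM = 1000.0


@dataclass(frozen=True)
class PillarGeometry:
    """Elastomer modulus and cylinder dimensions of one pilus.

    Parameters
    ----------
    E_MPa : float
        Elastic modulus of the cured elastomer, MPa.
    r_um : float
        Pilus radius, µm.
    L_um : float
        Pilus length, µm.
    """

    E_MPa: float
    r_um: float
    L_um: float

    def __post_init__(self) -> None:
        for name in ("E_MPa", "r_um", "L_um"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be positive and finite, got {value!r}")


#: Calibration of the arrays used for chondrocyte stimulation
#: (PDMS cured to 2.1 MPa; pili of radius 1.79 µm and length 5.87 µm).
DEFAULT_GEOMETRY = PillarGeometry(E_MPa=2.1, r_um=1.79, L_um=5.87)


@dataclass(frozen=True)
class SpringModel:
    """Linear spring model of one pilus: restoring force = k · deflection."""

    k_pn_per_nm: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k_pn_per_nm) and self.k_pn_per_nm > 0):
            raise ValueError(f"spring constant must be positive, got {self.k_pn_per_nm!r}")


def spring_constant(geom: PillarGeometry) -> SpringModel:
    """Spring constant of a cantilevered cylindrical pilus, in pN/nm.

    Evaluates k = (3/4)·π·E·r⁴/L³ with all lengths converted to nm and the
    modulus converted via the exact identity 1 MPa = 1 pN/nm².

    Examples
    --------
    >>> round(spring_constant(PillarGeometry(2.1, 1.79, 5.87)).k_pn_per_nm)
    251
    """
    e_pn_nm2 = geom.E_MPa * MPA_PER_PN_NM2
    r_nm = geom.r_um * NM_PER_UM
    l_nm = geom.L_um * NM_PER_UM
    k = 0.75 * math.pi * e_pn_nm2 * r_nm**4 / l_nm**3
    return SpringModel(k_pn_per_nm=k)


def deflection_to_force(d_magnitude_nm, spring: SpringModel):
    """Restoring-force magnitude for a deflection, in nN.

    Accepts a scalar deflection magnitude or an array of magnitudes (nm)
    and returns |k·d| in nN (1 nN = 1000 pN).  Deflections must be
    non-negative: the magnitude of the deflection vector, not a signed
    component.
    """
    d = np.asarray(d_magnitude_nm, dtype=float)
    if np.any(d < 0):
        raise ValueError("deflection magnitude must be non-negative")
    force_nn = np.abs(spring.k_pn_per_nm * d) / 1000.0
    if np.isscalar(d_magnitude_nm) or d.ndim == 0:
        return float(force_nn)
    return force_nn
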