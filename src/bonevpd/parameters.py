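"""Material parameter bundles for the bone visco-plasto-damage model.

All stresses are carried internally in MPa and times in seconds.  A full
material description is a :class:`MaterialParameters` aggregate of five
blocks: orthotropic elasticity, scalar damage, isotropic hardening (with an
optional softening branch), Perzyna viscosity, and the Tsai-Wu-type yield
parameters.  Two calibrated presets, ``cortical`` and ``trabecular``, ship
with the package as YAML files and are loaded via :func:`load_preset`.

Voigt convention: component order (11, 22, 33, 12, 23, 31); strain vectors
use engineering shear (gamma_ij = 2 eps_ij).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from functools import cached_property
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ElasticParameters",
    "DamageParameters",
    "HardeningParameters",
    "ViscosityParameters",
    "YieldParameters",
    "MaterialParameters",
    "MaterialState",
    "load_preset",
    "load_parameters",
    "save_parameters",
    "PRESET_NAMES",
]

PRESET_NAMES = ("cortical", "trabecular")


class ParameterError(ValueError):
    """Raised for thermodynamically or structurally inadmissible parameters."""


@dataclass(frozen=True)
class ElasticParameters:
    """Orthotropic engineering constants (moduli in MPa).

    Poisson ratios follow the convention nu_ij / E_i = nu_ji / E_j; the three
    given ratios are nu12, nu23, nu31 and the compliance is assembled with
    -nu_ij/E_i off-diagonals and symmetrized.
    """

    E1: float
    E2: float
    E3: float
    nu12: float
    nu23: float
    nu31: float
    G12: float
    G23: float
    G31: float

    def __post_init__(self) -> None:
        for name in ("E1", "E2", "E3", "G12", "G23", "G31"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"modulus {name} must be positive")
        # Admissibility (positive-definite stiffness) is verified on assembly
        # in constitutive.build_stiffness; do a cheap eager check here so that
        # invalid bundles fail at construction.
        from . import constitutive  # local import avoids a cycle

        constitutive.build_stiffness(self)

    @property
    def is_transverse_isotropic(self) -> bool:
        return (
            np.isclose(self.E2, self.E3)
            and np.isclose(self.G12, self.G31)
            and np.isclose(self.nu12, self.nu31)
        )


@dataclass(frozen=True)
class DamageParameters:
    """Scalar damage law D(kappa) = 1 - exp(-kp (kappa - k0)) for kappa >= k0.

    ``k0`` delays damage onset relative to plastic-strain onset; ``kp`` sets
    the accumulation rate.  D stays in [0, 1) for every kappa >= 0.
    """

    k0: float
    kp: float

    def __post_init__(self) -> None:
        if self.k0 < 0:
            raise ParameterError("damage threshold k0 must be >= 0")
        if self.kp <= 0:
            raise ParameterError("damage rate kp must be > 0")


@dataclass(frozen=True)
class HardeningParameters:
    """Isotropic hardening r(kappa), optionally with a softening branch.

    ``mode='original'`` is the saturating exponential 1 + (yr-1)(1-e^{-sh k});
    ``mode='softening'`` switches to r(ks) e^{-ss (kappa-ks)} beyond the
    softening-onset threshold ks, continuous at ks.
    """

    yr: float
    sh: float
    ks: float
    ss: float
    mode: str = "softening"

    def __post_init__(self) -> None:
        if self.yr <= 1:
            raise ParameterError("saturation ratio yr must exceed 1")
        if self.sh <= 0 or self.ks <= 0 or self.ss <= 0:
            raise ParameterError("sh, ks, ss must be positive")
        if self.mode not in ("original", "softening"):
            raise ParameterError(f"unknown hardening mode {self.mode!r}")


@dataclass(frozen=True)
class ViscosityParameters:
    """Perzyna overstress parameters: gamma = (Y^2 + m Y) / eta."""

    m: float
    eta: float

    def __post_init__(self) -> None:
        if self.m <= 0 or self.eta <= 0:
            raise ParameterError("m and eta must be positive")


@dataclass(frozen=True)
class YieldParameters:
    """Yield strains and fabric directions of the Tsai-Wu-type surface.

    ``eps0p``/``eps0m`` are the uniaxial tensile/compressive yield strains
    (both stored positive), ``xi0`` the strain interaction coefficient, and
    m1, m2, m3 the (mutually orthogonal, unit) fabric direction vectors that
    define the material frame.
    """

    eps0p: float
    eps0m: float
    xi0: float
    m1: tuple[float, float, float] = (1.0, 0.0, 0.0)
    m2: tuple[float, float, float] = (0.0, 1.0, 0.0)
    m3: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.eps0p <= 0 or self.eps0m <= 0:
            raise ParameterError("yield strains eps0p, eps0m must be positive")
        M = self.fabric_matrix
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-8):
            raise ParameterError("fabric vectors must be orthonormal")

    @property
    def fabric_matrix(self) -> np.ndarray:
        """3x3 matrix with rows m1, m2, m3 (material axes in global frame)."""
        return np.array([self.m1, self.m2, self.m3], dtype=float)


@dataclass(frozen=True)
class MaterialParameters:
    """Full parameter bundle for one tissue type.

    The derived stiffness, compliance and yield tensors are assembled once
    per instance and cached; `replace()`-derived copies rebuild them.
    """

    elastic: ElasticParameters
    damage: DamageParameters
    hardening: HardeningParameters
    viscosity: ViscosityParameters
    yield_: YieldParameters
    name: str = ""

    def with_yield(self, yp: YieldParameters) -> "MaterialParameters":
        return replace(self, yield_=yp)

    @cached_property
    def stiffness(self) -> np.ndarray:
        from . import constitutive

        return constitutive.build_stiffness(self.elastic)

    @cached_property
    def compliance(self) -> np.ndarray:
        from . import constitutive

        return constitutive.build_compliance(self.elastic)

    @cached_property
    def yield_tensors(self):
        from . import constitutive

        return constitutive.build_yield_tensors(self.yield_, self.elastic)


@dataclass
class MaterialState:
    """State of a material point: stress, plastic strain, kappa, damage.

    ``sigma`` is the Voigt stress (MPa), ``eps_p`` the Voigt plastic strain
    with engineering shear, ``kappa`` the accumulated plastic strain (norm of
    the plastic strain-rate tensor integrated in time, non-decreasing) and
    ``D`` the scalar damage, always equal to D(kappa).
    """

    sigma: np.ndarray = field(default_factory=lambda: np.zeros(6))
    eps_p: np.ndarray = field(default_factory=lambda: np.zeros(6))
    kappa: float = 0.0
    D: float = 0.0

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(6)
        self.eps_p = np.asarray(self.eps_p, dtype=float).reshape(6)
        if self.kappa < 0:
            raise ParameterError("kappa must be >= 0")
        if not 0.0 <= self.D < 1.0:
            raise ParameterError("damage must lie in [0, 1)")

    def copy(self) -> "MaterialState":
        return MaterialState(self.sigma.copy(), self.eps_p.copy(), self.kappa, self.D)


# ---------------------------------------------------------------------------
# Serialization

def _params_to_dict(params: MaterialParameters) -> dict:
    d = {
        "elastic": asdict(params.elastic),
        "damage": asdict(params.damage),
        "hardening": asdict(params.hardening),
        "viscosity": asdict(params.viscosity),
        "yield": asdict(params.yield_),
    }
    for key in ("m1", "m2", "m3"):
        d["yield"][key] = list(d["yield"][key])
    if params.name:
        d["name"] = params.name
    return d


def _params_from_dict(d: dict) -> MaterialParameters:
    yd = dict(d["yield"])
    for key in ("m1", "m2", "m3"):
        if key in yd:
            yd[key] = tuple(float(v) for v in yd[key])
    return MaterialParameters(
        elastic=ElasticParameters(**d["elastic"]),
        damage=DamageParameters(**d["damage"]),
        hardening=HardeningParameters(**d["hardening"]),
        viscosity=ViscosityParameters(**d["viscosity"]),
        yield_=YieldParameters(**yd),
        name=d.get("name", ""),
    )


def save_parameters(params: MaterialParameters, path: str | Path) -> None:
    """Write a parameter bundle to YAML (``.yaml``/``.yml``) or JSON."""
    path = Path(path)
    d = _params_to_dict(params)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_parameters(path: str | Path) -> MaterialParameters:
    """Read a parameter bundle from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _params_from_dict(d)


def load_preset(name: str) -> MaterialParameters:
    """Load one of the packaged tissue presets (``cortical``/``trabecular``)."""
    if name not in PRESET_NAMES:
        raise ParameterError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    ref = resources.files("bonevpd").joinpath(f"data/{name}.yaml")
    return _params_from_dict(yaml.safe_load(ref.read_text()))
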