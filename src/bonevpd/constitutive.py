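"""Constitutive functions of the orthotropic visco-plasto-damage model.

The model combines four ingredients, each exposed here as a pure function so
it can be tested in isolation:

* damaged orthotropic elasticity,   sigma = (1 - D(kappa)) S (eps - eps_p);
* a scalar damage law D(kappa) driven by accumulated plastic strain;
* isotropic hardening r(kappa) with an optional softening branch;
* a Tsai-Wu-type yield surface with tension-compression asymmetry
  (kinematic term r(kappa) A) and Perzyna-type viscous overstress.

Voigt convention throughout: component order (11, 22, 33, 12, 23, 31),
single shear entries in stress vectors, engineering shear (gamma = 2 eps)
in strain vectors.  With this pairing, the derivative of a scalar with
respect to the Voigt stress vector is directly the engineering-shear strain
conjugate, so the associated flow rule eps_p_dot = gamma * dY/dsigma can be
written componentwise on the 6-vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import (
    DamageParameters,
    ElasticParameters,
    HardeningParameters,
    MaterialParameters,
    ParameterError,
    ViscosityParameters,
    YieldParameters,
)

__all__ = [
    "build_stiffness",
    "build_compliance",
    "damage_value",
    "damage_derivative",
    "hardening_value",
    "hardening_derivative",
    "YieldTensors",
    "build_yield_tensors",
    "yield_value",
    "yield_gradient",
    "perzyna_rate",
    "overstress_phi",
    "generalized_yield",
    "flow_norm",
    "voigt_stress_rotation",
    "FLOW_NORM_WEIGHTS",
]

# Tensor-consistent norm weights for engineering-shear Voigt vectors:
# |e|^2 = e11^2+e22^2+e33^2 + 2(e12^2+e23^2+e31^2) with gamma_ij = 2 e_ij.
FLOW_NORM_WEIGHTS = np.array([1.0, 1.0, 1.0, 0.5, 0.5, 0.5])


def flow_norm(v: np.ndarray) -> float:
    """Tensor norm of an engineering-shear Voigt strain-rate direction."""
    return float(np.sqrt(np.sum(FLOW_NORM_WEIGHTS * np.asarray(v) ** 2)))


# ---------------------------------------------------------------------------
# Elasticity


def build_compliance(ep: ElasticParameters) -> np.ndarray:
    """Assemble the 6x6 orthotropic compliance matrix (1/MPa).

    Off-diagonals follow the engineering convention in which each listed
    ratio is referenced to the modulus of its plane's distinguished axis:
    -nu12/E1 for the 12 pair, -nu23/E2 for the 23 pair and -nu31/E1 for the
    31 pair (``nu31`` plays the role of nu13; the cyclic label follows the
    calibration tables).  With E2 = E3, G12 = G31 and nu12 = nu31 the
    matrix is then exactly transversely isotropic about axis 1.  The
    assembled matrix must be symmetric; a violation beyond 1e-8 relative
    is rejected as a Poisson-convention error.
    """
    C = np.zeros((6, 6))
    C[0, 0] = 1.0 / ep.E1
    C[1, 1] = 1.0 / ep.E2
    C[2, 2] = 1.0 / ep.E3
    C[0, 1] = C[1, 0] = -ep.nu12 / ep.E1
    C[1, 2] = C[2, 1] = -ep.nu23 / ep.E2
    C[2, 0] = C[0, 2] = -ep.nu31 / ep.E1
    C[3, 3] = 1.0 / ep.G12
    C[4, 4] = 1.0 / ep.G23
    C[5, 5] = 1.0 / ep.G31
    asym = np.abs(C - C.T).max()
    if asym > 1e-8 * np.abs(C).max():
        raise ParameterError(f"compliance asymmetry {asym:.3e} violates Poisson convention")
    return C


def build_stiffness(ep: ElasticParameters) -> np.ndarray:
    """Invert the orthotropic compliance into the 6x6 stiffness (MPa).

    The result must be symmetric positive definite; an indefinite stiffness
    (thermodynamically inadmissible constants) is rejected with the offending
    eigenvalue in the diagnostic.
    """
    C = build_compliance(ep)
    S = np.linalg.inv(C)
    S = 0.5 * (S + S.T)
    w = np.linalg.eigvalsh(S)
    if w[0] <= 0:
        raise ParameterError(
            f"stiffness not positive definite: smallest eigenvalue {w[0]:.6g} MPa"
        )
    return S


def voigt_stress_rotation(R: np.ndarray) -> np.ndarray:
    """6x6 matrix T with voigt(R s R^T) = T voigt(s) for stress-like tensors.

    R rows are the target-frame axes expressed in the source frame (so T maps
    source-frame Voigt components to target-frame components).
    """
    R = np.asarray(R, dtype=float)
    T = np.empty((6, 6))
    idx = [(0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (2, 0)]
    for k in range(6):
        s = np.zeros((3, 3))
        i, j = idx[k]
        s[i, j] = s[j, i] = 1.0
        sr = R @ s @ R.T
        T[:, k] = [sr[0, 0], sr[1, 1], sr[2, 2], sr[0, 1], sr[1, 2], sr[2, 0]]
    return T


# ---------------------------------------------------------------------------
# Damage


def _damage(kappa: float, dp: DamageParameters) -> float:
    # Analytic continuation used inside the return map: defined for any real
    # kappa (zero below k0) so Newton iterates may cross zero smoothly.
    if kappa < dp.k0:
        return 0.0
    return 1.0 - math.exp(-dp.kp * (kappa - dp.k0))


def _damage_prime(kappa: float, dp: DamageParameters) -> float:
    if kappa < dp.k0:
        return 0.0
    return dp.kp * math.exp(-dp.kp * (kappa - dp.k0))


def damage_value(kappa: float, dp: DamageParameters) -> float:
    """Scalar damage D(kappa): zero below k0, saturating exponential above."""
    if kappa < 0:
        raise ParameterError("kappa must be >= 0")
    return _damage(kappa, dp)


def damage_derivative(kappa: float, dp: DamageParameters) -> float:
    """dD/dkappa (right derivative at the activation threshold k0)."""
    if kappa < 0:
        raise ParameterError("kappa must be >= 0")
    return _damage_prime(kappa, dp)


# ---------------------------------------------------------------------------
# Hardening / softening


def _hardening(kappa: float, hp: HardeningParameters, mode: str | None = None) -> float:
    mode = mode or hp.mode
    if mode not in ("original", "softening"):
        raise ParameterError(f"unknown hardening mode {mode!r}")
    if mode == "original" or kappa <= hp.ks:
        return 1.0 + (hp.yr - 1.0) * (1.0 - math.exp(-hp.sh * kappa))
    r_ks = 1.0 + (hp.yr - 1.0) * (1.0 - math.exp(-hp.sh * hp.ks))
    return r_ks * math.exp(-hp.ss * (kappa - hp.ks))


def _hardening_prime(kappa: float, hp: HardeningParameters, mode: str | None = None) -> float:
    mode = mode or hp.mode
    if mode == "original" or kappa < hp.ks:
        return (hp.yr - 1.0) * hp.sh * math.exp(-hp.sh * kappa)
    r_ks = 1.0 + (hp.yr - 1.0) * (1.0 - math.exp(-hp.sh * hp.ks))
    return -hp.ss * r_ks * math.exp(-hp.ss * (kappa - hp.ks))


def hardening_value(kappa: float, hp: HardeningParameters, mode: str | None = None) -> float:
    """Isotropic hardening function r(kappa), with r(0) = 1.

    ``mode='original'``: monotone saturation towards yr.
    ``mode='softening'``: same up to ks, then exponential decay, continuous
    at ks.  ``mode=None`` uses the mode stored on the parameter bundle.
    """
    if kappa < 0:
        raise ParameterError("kappa must be >= 0")
    return _hardening(kappa, hp, mode)


def hardening_derivative(kappa: float, hp: HardeningParameters, mode: str | None = None) -> float:
    """dr/dkappa (right derivative at the softening onset ks)."""
    if kappa < 0:
        raise ParameterError("kappa must be >= 0")
    return _hardening_prime(kappa, hp, mode)


# ---------------------------------------------------------------------------
# Yield surface


@dataclass(frozen=True)
class YieldTensors:
    """Centre direction A (Voigt, MPa) and metric Afour (6x6, 1/MPa^2).

    The yield function is Y = sqrt((s - r A) . Afour (s - r A)) - r; the
    surface Y = 0 passes through the six uniaxial calibration stress states
    at kappa = 0 by construction.
    """

    A: np.ndarray
    Afour: np.ndarray


def build_yield_tensors(yp: YieldParameters, ep: ElasticParameters) -> YieldTensors:
    """Assemble the Tsai-Wu-type tensors from yield strains and elasticity.

    Uniaxial yield stresses follow from the yield strains via
    sigma0i+ = Ei eps0p and sigma0i- = Ei eps0m; shear yield stresses use the
    geometric mean tau0ij = Gij sqrt(eps0p eps0m).  The classical Tsai-Wu
    coefficients (linear vector F_i, quadratic F_ii, normal-normal
    interaction F_ij = -xi0 sqrt(F_ii F_jj)) are then converted to the
    centred form: centre c = -1/2 F^-1 f on the normal-stress subspace,
    A = c and Afour = F / (1 + c . F c).  The six uniaxial calibration
    states are verified at construction to lie on Y = 0 within 1e-8.
    """
    E = np.array([ep.E1, ep.E2, ep.E3])
    G = np.array([ep.G12, ep.G23, ep.G31])
    sig_t = E * yp.eps0p
    sig_c = E * yp.eps0m  # stored positive (magnitude of compressive yield)
    tau0 = G * math.sqrt(yp.eps0p * yp.eps0m)

    F = np.zeros((6, 6))
    Fii = 1.0 / (sig_t * sig_c)
    for i in range(3):
        F[i, i] = Fii[i]
    for i in range(3):
        for j in range(i + 1, 3):
            F[i, j] = F[j, i] = -yp.xi0 * math.sqrt(Fii[i] * Fii[j])
    for k in range(3):
        F[3 + k, 3 + k] = 1.0 / tau0[k] ** 2
    fvec = np.zeros(6)
    fvec[:3] = 1.0 / sig_t - 1.0 / sig_c

    w = np.linalg.eigvalsh(F)
    if w[0] <= 0:
        raise ParameterError(
            f"interaction coefficient xi0={yp.xi0} yields a non-convex quadric "
            f"(eigenvalue {w[0]:.6g})"
        )

    c = np.zeros(6)
    c[:3] = -0.5 * np.linalg.solve(F[:3, :3], fvec[:3])
    denom = 1.0 + c @ F @ c
    A = c
    Afour = F / denom

    R = yp.fabric_matrix
    if not np.allclose(R, np.eye(3), atol=1e-12):
        # Tensors were assembled in the material frame; express them in the
        # global frame.  With T mapping global to material Voigt components,
        # the quadratic form pulls back as T^T Q T and the centre as T^-1 c.
        T = voigt_stress_rotation(R)
        Tinv = voigt_stress_rotation(R.T)
        A = Tinv @ A
        Afour = T.T @ Afour @ T
        Afour = 0.5 * (Afour + Afour.T)

    yt = YieldTensors(A=A, Afour=Afour)

    # Construction constraint: all six uniaxial calibration states at r = 1.
    for i in range(3):
        m = R[i]
        dyad = np.outer(m, m)
        v = np.array([dyad[0, 0], dyad[1, 1], dyad[2, 2], dyad[0, 1], dyad[1, 2], dyad[2, 0]])
        for s in (sig_t[i] * v, -sig_c[i] * v):
            q = s - A
            y = math.sqrt(q @ Afour @ q) - 1.0
            if abs(y) > 1e-8:
                raise ParameterError(
                    f"yield surface misses calibration state on axis {i + 1}: Y={y:.3e}"
                )
    return yt


def yield_value(
    sigma: np.ndarray,
    kappa: float,
    yt: YieldTensors,
    hp: HardeningParameters,
    mode: str | None = None,
) -> float:
    """Yield function Y = sqrt((s - r A) . Afour (s - r A)) - r (dimensionless).

    Negative inside the elastic domain; degree-1 homogeneous about the
    centre r A.
    """
    r = hardening_value(kappa, hp, mode)
    q = np.asarray(sigma, dtype=float) - r * yt.A
    return math.sqrt(max(q @ yt.Afour @ q, 0.0)) - r


def yield_gradient(
    sigma: np.ndarray,
    kappa: float,
    yt: YieldTensors,
    hp: HardeningParameters,
    mode: str | None = None,
) -> np.ndarray:
    """dY/dsigma = Afour (s - r A) / sqrt((s - r A) . Afour (s - r A)).

    Undefined (rejected) at the surface centre sigma = r A.
    """
    r = hardening_value(kappa, hp, mode)
    q = np.asarray(sigma, dtype=float) - r * yt.A
    w = yt.Afour @ q
    n2 = q @ w
    if n2 <= 0.0:
        raise ParameterError("yield gradient undefined at the surface centre")
    return w / math.sqrt(n2)


# ---------------------------------------------------------------------------
# Perzyna viscosity


def perzyna_rate(Y: float, vp: ViscosityParameters) -> float:
    """Viscoplastic consistency parameter gamma = (Y^2 + m Y) / eta (1/s)."""
    if Y < 0:
        raise ParameterError("perzyna_rate requires Y >= 0 (gate on the yield check)")
    return (Y * Y + vp.m * Y) / vp.eta


def overstress_phi(gamma: float, vp: ViscosityParameters) -> float:
    """Inverse of the Perzyna relation: phi(gamma) = -m/2 + sqrt(m^2/4 + eta gamma)."""
    if gamma < 0:
        raise ParameterError("overstress_phi requires gamma >= 0")
    return _phi(gamma, vp)


def _phi(gamma: float, vp: ViscosityParameters) -> float:
    # Internal variant tolerating the small negative gamma excursions a
    # Newton iterate may take; the radicand stays positive for
    # gamma > -m^2/(4 eta).
    return -0.5 * vp.m + math.sqrt(0.25 * vp.m * vp.m + vp.eta * gamma)


def _phi_prime(gamma: float, vp: ViscosityParameters) -> float:
    return 0.5 * vp.eta / math.sqrt(0.25 * vp.m * vp.m + vp.eta * gamma)


def generalized_yield(
    sigma: np.ndarray,
    kappa: float,
    gamma: float,
    params: MaterialParameters,
    mode: str | None = None,
) -> float:
    """Generalized yield Ybar = Y(sigma, kappa) - phi(gamma).

    Vanishes at a converged viscoplastic state; together with gamma >= 0 and
    gamma * Ybar = 0 it expresses the generalized Kuhn-Tucker conditions.
    """
    if gamma < 0:
        raise ParameterError("gamma must be >= 0")
    y = yield_value(sigma, kappa, params.yield_tensors, params.hardening, mode)
    return y - overstress_phi(gamma, params.viscosity)
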