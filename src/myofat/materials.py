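"""Constitutive models: muscle, intramuscular fat, their mixture, aponeurosis.

Muscle is a transversely isotropic, nearly incompressible hyperelastic
solid with active and passive fiber behaviour; intramuscular fat is an
isochoric neo-Hookean solid; an element's strain energy is the fat-fraction
weighted mixture

    W = (1 - X/100) W_muscle_iso + (X/100) W_fat_iso + U(J),

with a single volumetric penalty U(J) = K/2 (ln J)^2 shared by both
constituents (fat carries no bulk term of its own).  The aponeurosis is a
Mooney-Rivlin matrix plus tension-only exponential-power-law fibers.

Deviatoric terms are evaluated on isochoric kinematics (Fbar = J^(-1/3) F),
so the pressure comes only from U.  Units: stresses/moduli in MPa, forces
in N when lengths are mm.

Muscle deviatoric energy: W_lambda(lambda, a) + G_phi phi^2 + G_beta beta^2,
with lambda = sqrt(I4) the (isochoric) along-fiber stretch, the shear
measures the transversely isotropic invariant forms

    phi^2  = I5/I4^2 - 1,
    beta   = acosh( (I1 I4 - I5) / (2 sqrt(I4)) ),

both vanishing at the reference state and linearising to engineering shear
in the corresponding simple-shear modes.  W_lambda is defined through the
fiber Cauchy stress

    sigma(lambda, a) = sigma_max f_total(lambda/lambda_ofl, a) lambda/lambda_ofl,
    lambda dW/dlambda = sigma,

where f_total = a f_active + f_passive is the normalised force-length
curve: a piecewise-quadratic active curve supported on [0.4, 1.6] with peak
1 at the optimal stretch, and an exponential passive curve that continues
linearly (C^1) beyond the stretch lambda_star.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "MuscleFatParams",
    "AponeurosisParams",
    "LocalState",
    "force_length_active",
    "force_length_passive",
    "force_length_total",
    "fiber_cauchy_stress",
    "fiber_energy",
    "muscle_energy",
    "muscle_stress",
    "fat_energy",
    "fat_stress",
    "mixture_energy",
    "mixture_stress",
    "aponeurosis_energy",
    "aponeurosis_stress",
    "load_material_params",
    "save_material_params",
]

_I3 = np.eye(3)


def _det3(A: np.ndarray) -> np.ndarray:
    """Determinant of (..., 3, 3) arrays (cofactor form, faster than
    np.linalg.det for large batches of small matrices)."""
    return (
        A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
        - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
        + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0])
    )


def _inv3(A: np.ndarray, det: np.ndarray | None = None) -> np.ndarray:
    """Inverse of (..., 3, 3) arrays via the adjugate."""
    if det is None:
        det = _det3(A)
    out = np.empty_like(A)
    out[..., 0, 0] = A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1]
    out[..., 0, 1] = A[..., 0, 2] * A[..., 2, 1] - A[..., 0, 1] * A[..., 2, 2]
    out[..., 0, 2] = A[..., 0, 1] * A[..., 1, 2] - A[..., 0, 2] * A[..., 1, 1]
    out[..., 1, 0] = A[..., 1, 2] * A[..., 2, 0] - A[..., 1, 0] * A[..., 2, 2]
    out[..., 1, 1] = A[..., 0, 0] * A[..., 2, 2] - A[..., 0, 2] * A[..., 2, 0]
    out[..., 1, 2] = A[..., 0, 2] * A[..., 1, 0] - A[..., 0, 0] * A[..., 1, 2]
    out[..., 2, 0] = A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]
    out[..., 2, 1] = A[..., 0, 1] * A[..., 2, 0] - A[..., 0, 0] * A[..., 2, 1]
    out[..., 2, 2] = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    return out / det[..., None, None]


@dataclass
class MuscleFatParams:
    """Muscle + fat material constants (MPa where dimensional)."""

    K: float = 75.0  # bulk modulus
    G_phi: float = 3.87e-3  # along-fiber shear modulus
    G_beta: float = 2.24e-2  # cross-fiber shear modulus
    P1: float = 0.04  # passive exponential stress coefficient
    P2: float = 6.6  # passive fiber uncrimping factor
    lambda_ofl: float = 1.0  # optimal fiber stretch
    lambda_star: float = 1.4  # passive curve becomes linear here
    sigma_max: float = 0.3  # specific tension
    G_f: float = 4.19e-3  # fat shear modulus
    # "half": conventional neo-Hookean (G_f/2)(I1-3); "printed": 2 G_f (I1-3)
    fat_energy_convention: str = "half"

    def __post_init__(self) -> None:
        for name in ("K", "G_phi", "G_beta", "sigma_max", "G_f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.lambda_star > self.lambda_ofl > 0:
            raise ValueError("need lambda_star > lambda_ofl > 0")
        if self.fat_energy_convention not in ("half", "printed"):
            raise ValueError("fat_energy_convention must be 'half' or 'printed'")

    @property
    def fat_coeff(self) -> float:
        """Coefficient c in W_fat = c (I1bar - 3)."""
        return 0.5 * self.G_f if self.fat_energy_convention == "half" else 2.0 * self.G_f


@dataclass
class AponeurosisParams:
    """Aponeurosis material constants (MPa where dimensional)."""

    K: float = 500.0
    C1: float = 5.0
    C2: float = 0.0
    alpha_apo: float = 0.0  # exponential-argument coefficient
    beta_apo: float = 2.5  # power of the fiber strain argument
    ksi: float = 1.5  # fiber modulus

    def __post_init__(self) -> None:
        if self.K <= 0 or self.ksi <= 0:
            raise ValueError("K and ksi must be > 0")
        if self.beta_apo <= 1:
            raise ValueError("beta_apo must be > 1")
        if self.alpha_apo < 0:
            raise ValueError("alpha_apo must be >= 0")


@dataclass
class LocalState:
    """Deformation state at a material point."""

    F: np.ndarray  # (..., 3, 3) deformation gradient
    fiber: np.ndarray  # (..., 3) unit fiber direction, reference frame
    activation: float | np.ndarray = 0.0  # in [0, 1]
    fat_percent: float | np.ndarray = 0.0  # X_fat in [0, 100]


# ----------------------------------------------------------------------
# normalised force-length curves (argument x = lambda / lambda_ofl)


def force_length_active(x):
    """Piecewise-quadratic active curve: 0 outside [0.4, 1.6], peak 1 at 1."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    m = (x >= 0.4) & (x < 0.6)
    out = np.where(m, 9.0 * (x - 0.4) ** 2, out)
    m = (x >= 0.6) & (x <= 1.4)
    out = np.where(m, 1.0 - 4.0 * (1.0 - x) ** 2, out)
    m = (x > 1.4) & (x <= 1.6)
    out = np.where(m, 9.0 * (x - 1.6) ** 2, out)
    return out


def _active_integral(x):
    """A(x) = integral_1^x f_active dt (piecewise closed form)."""
    x = np.asarray(x, dtype=float)
    A06 = -0.4 + (4.0 / 3.0) * 0.4**3  # A at x=0.6
    A04 = A06 - 0.024  # A at x=0.4
    A14 = 0.4 - (4.0 / 3.0) * 0.4**3
    A16 = A14 + 0.024
    out = np.where(x <= 0.4, A04, 0.0)
    m = (x > 0.4) & (x < 0.6)
    out = np.where(m, A06 - 0.024 + 3.0 * (x - 0.4) ** 3, out)
    m = (x >= 0.6) & (x <= 1.4)
    out = np.where(m, (x - 1.0) + (4.0 / 3.0) * (1.0 - x) ** 3, out)
    m = (x > 1.4) & (x < 1.6)
    out = np.where(m, A14 + 0.024 + 3.0 * (x - 1.6) ** 3, out)
    out = np.where(x >= 1.6, A16, out)
    return out


def force_length_passive(x, p: MuscleFatParams):
    """Exponential passive curve, zero below optimum, linear (C^1) beyond
    x_star = lambda_star / lambda_ofl."""
    x = np.asarray(x, dtype=float)
    xs = p.lambda_star / p.lambda_ofl
    f_star = p.P1 * (np.exp(p.P2 * (xs - 1.0)) - 1.0)
    s_star = p.P1 * p.P2 * np.exp(p.P2 * (xs - 1.0))
    out = np.zeros_like(x)
    m = (x > 1.0) & (x < xs)
    with np.errstate(over="ignore"):
        out = np.where(m, p.P1 * (np.exp(p.P2 * (np.minimum(x, xs) - 1.0)) - 1.0), out)
    out = np.where(x >= xs, f_star + s_star * (x - xs), out)
    return out


def _passive_integral(x, p: MuscleFatParams):
    """Pp(x) = integral_1^x f_passive dt."""
    x = np.asarray(x, dtype=float)
    xs = p.lambda_star / p.lambda_ofl
    f_star = p.P1 * (np.exp(p.P2 * (xs - 1.0)) - 1.0)
    s_star = p.P1 * p.P2 * np.exp(p.P2 * (xs - 1.0))

    def exp_part(t):
        return p.P1 * ((np.exp(p.P2 * (t - 1.0)) - 1.0) / p.P2 - (t - 1.0))

    out = np.zeros_like(x)
    m = (x > 1.0) & (x < xs)
    out = np.where(m, exp_part(np.clip(x, 1.0, xs)), out)
    m = x >= xs
    out = np.where(m, exp_part(xs) + f_star * (x - xs) + 0.5 * s_star * (x - xs) ** 2, out)
    return out


def force_length_total(lam, a, p: MuscleFatParams):
    """f_total = a f_active + f_passive at fiber stretch ``lam``."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("fiber stretch must be > 0")
    x = lam / p.lambda_ofl
    return np.asarray(a) * force_length_active(x) + force_length_passive(x, p)


def fiber_cauchy_stress(lam, a, p: MuscleFatParams):
    """Along-fiber Cauchy stress sigma_max f_total(lambda, a) lambda/lambda_ofl (MPa)."""
    lam = np.asarray(lam, dtype=float)
    return p.sigma_max * force_length_total(lam, a, p) * lam / p.lambda_ofl


def fiber_energy(lam, a, p: MuscleFatParams):
    """Fiber strain energy density W_lambda with W(lambda_ofl) = 0,
    satisfying lambda dW/dlambda = fiber_cauchy_stress."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("fiber stretch must be > 0")
    x = lam / p.lambda_ofl
    return p.sigma_max * (np.asarray(a) * _active_integral(x) + _passive_integral(x, p))


# ----------------------------------------------------------------------
# kinematics helpers (vectorised over leading axes)


def _kinematics(F: np.ndarray, fiber: np.ndarray):
    F = np.asarray(F, dtype=float)
    J = _det3(F)
    if np.any(J <= 0):
        raise ValueError("det(F) must be > 0 (element inversion)")
    Fb = F * J[..., None, None] ** (-1.0 / 3.0)
    Bb = Fb @ np.swapaxes(Fb, -1, -2)
    I1 = np.trace(Bb, axis1=-2, axis2=-1)
    a0 = np.asarray(fiber, dtype=float)
    m = np.einsum("...ij,...j->...i", Fb, a0)
    I4 = np.einsum("...i,...i->...", m, m)
    Ca = np.einsum("...ji,...j->...i", Fb, m)  # Cbar a0 = Fbar^T m
    I5 = np.einsum("...i,...i->...", Ca, Ca)
    return J, Fb, Bb, I1, m, I4, I5


def _dev(t: np.ndarray) -> np.ndarray:
    tr = np.trace(t, axis1=-2, axis2=-1)
    return t - (tr / 3.0)[..., None, None] * _I3


def _acosh_ratio(y):
    """g(y) = acosh(y)/sqrt(y^2-1), stable near y=1 (limit 1)."""
    y = np.maximum(np.asarray(y, dtype=float), 1.0)
    eps = y - 1.0
    small = eps < 1e-8
    ys = np.where(small, 2.0, y)
    g = np.arccosh(ys) / np.sqrt(ys**2 - 1.0)
    return np.where(small, 1.0 - eps / 3.0, g)


def _vol_stress(J, K):
    return (K * np.log(J) / J)[..., None, None] * _I3


# ----------------------------------------------------------------------
# muscle


def muscle_energy(F, fiber, a, p: MuscleFatParams, include_vol: bool = True):
    """Strain energy density (MPa) of the pure muscle material."""
    J, Fb, Bb, I1, m, I4, I5 = _kinematics(F, fiber)
    lam = np.sqrt(I4)
    W = fiber_energy(lam, a, p)
    W = W + p.G_phi * (I5 / I4**2 - 1.0)
    y = (I1 * I4 - I5) / (2.0 * np.sqrt(I4))
    beta = np.arccosh(np.maximum(y, 1.0))
    W = W + p.G_beta * beta**2
    if include_vol:
        W = W + 0.5 * p.K * np.log(J) ** 2
    return W


def _muscle_iso_kirchhoff(Fb, Bb, I1, m, I4, I5, a, p: MuscleFatParams):
    """Isochoric Kirchhoff stress tau_bar of the muscle material."""
    lam = np.sqrt(I4)
    sig_f = fiber_cauchy_stress(lam, a, p)  # = lam * dW/dlam
    mm = np.einsum("...i,...j->...ij", m, m)
    Bm = np.einsum("...ij,...j->...i", Bb, m)
    mBm = np.einsum("...i,...j->...ij", m, Bm) + np.einsum("...i,...j->...ij", Bm, m)

    tau = (sig_f / I4)[..., None, None] * mm  # lam W' a^ x a^ ; mm = I4 a^ x a^

    c_phi = 2.0 * p.G_phi
    tau = tau + c_phi * (
        mBm / I4[..., None, None] ** 2 - (2.0 * I5 / I4**3)[..., None, None] * mm
    )

    sqI4 = np.sqrt(I4)
    y = (I1 * I4 - I5) / (2.0 * sqI4)
    c_b = 2.0 * p.G_beta * _acosh_ratio(y)  # dW/dy = 2 G_b acosh(y)/sqrt(y^2-1)
    dy = (
        (I4[..., None, None] * Bb + I1[..., None, None] * mm - mBm)
        / (2.0 * sqI4)[..., None, None]
        - (y / (2.0 * I4))[..., None, None] * mm
    )
    tau = tau + 2.0 * c_b[..., None, None] * dy
    return tau


def muscle_stress(F, fiber, a, p: MuscleFatParams, include_vol: bool = True):
    """Cauchy stress (MPa) of the pure muscle material."""
    J, Fb, Bb, I1, m, I4, I5 = _kinematics(F, fiber)
    tau = _muscle_iso_kirchhoff(Fb, Bb, I1, m, I4, I5, a, p)
    sig = _dev(tau) / J[..., None, None]
    if include_vol:
        sig = sig + _vol_stress(J, p.K)
    return sig


# ----------------------------------------------------------------------
# fat


def fat_energy(F, p: MuscleFatParams, include_vol: bool = True):
    J, Fb, Bb, I1, *_ = _kinematics(F, _dummy_fiber(F))
    W = p.fat_coeff * (I1 - 3.0)
    if include_vol:
        W = W + 0.5 * p.K * np.log(J) ** 2
    return W


def fat_stress(F, p: MuscleFatParams, include_vol: bool = True):
    """Isochoric neo-Hookean Cauchy stress; activation independent."""
    J, Fb, Bb, I1, *_ = _kinematics(F, _dummy_fiber(F))
    sig = 2.0 * p.fat_coeff * _dev(Bb) / J[..., None, None]
    if include_vol:
        sig = sig + _vol_stress(J, p.K)
    return sig


def _dummy_fiber(F):
    shp = np.asarray(F).shape[:-2] + (3,)
    f = np.zeros(shp)
    f[..., 0] = 1.0
    return f


# ----------------------------------------------------------------------
# mixture


def mixture_energy(F, fiber, a, fat_percent, p: MuscleFatParams):
    x = np.asarray(fat_percent, dtype=float) / 100.0
    W = (1.0 - x) * muscle_energy(F, fiber, a, p, include_vol=False)
    W = W + x * fat_energy(F, p, include_vol=False)
    J = _det3(np.asarray(F, dtype=float))
    return W + 0.5 * p.K * np.log(J) ** 2


def mixture_stress(F, fiber, a, fat_percent, p: MuscleFatParams):
    """Fat-fraction weighted Cauchy stress, linear mixture of the muscle and
    fat isochoric stresses with a single volumetric penalty (muscle K).

    Kinematics are evaluated once and shared between the constituents; a
    constituent with weight identically zero is skipped."""
    x = np.asarray(fat_percent, dtype=float) / 100.0
    J, Fb, Bb, I1, m, I4, I5 = _kinematics(F, fiber)
    tau = None
    if np.any(x < 1.0):
        tau_m = _muscle_iso_kirchhoff(Fb, Bb, I1, m, I4, I5, a, p)
        tau = (1.0 - x)[..., None, None] * tau_m
    if np.any(x > 0.0):
        tau_f = 2.0 * p.fat_coeff * Bb
        tau = x[..., None, None] * tau_f if tau is None else tau + x[..., None, None] * tau_f
    return _dev(tau) / J[..., None, None] + _vol_stress(J, p.K)


# ----------------------------------------------------------------------
# aponeurosis


def _apo_fiber_energy(I4, p: AponeurosisParams):
    """Tension-only exponential power-law fiber energy in I4 = lambda_apo^2.

    ksi/(alpha beta) (exp[alpha (I4-1)^beta] - 1); the alpha -> 0 limit is
    (ksi/beta)(I4-1)^beta (the Table default alpha = 0)."""
    e = np.maximum(np.asarray(I4, dtype=float) - 1.0, 0.0)
    if p.alpha_apo == 0.0:
        return (p.ksi / p.beta_apo) * e**p.beta_apo
    return (p.ksi / (p.alpha_apo * p.beta_apo)) * (np.exp(p.alpha_apo * e**p.beta_apo) - 1.0)


def _apo_fiber_dW_dI4(I4, p: AponeurosisParams):
    e = np.maximum(np.asarray(I4, dtype=float) - 1.0, 0.0)
    if p.alpha_apo == 0.0:
        return p.ksi * e ** (p.beta_apo - 1.0)
    return p.ksi * e ** (p.beta_apo - 1.0) * np.exp(p.alpha_apo * e**p.beta_apo)


def aponeurosis_energy(F, fiber, p: AponeurosisParams, include_vol: bool = True):
    J, Fb, Bb, I1, m, I4, I5 = _kinematics(F, fiber)
    B2 = Bb @ Bb
    I2 = 0.5 * (I1**2 - np.trace(B2, axis1=-2, axis2=-1))
    W = p.C1 * (I1 - 3.0) + p.C2 * (I2 - 3.0) + _apo_fiber_energy(I4, p)
    if include_vol:
        W = W + 0.5 * p.K * np.log(J) ** 2
    return W


def aponeurosis_stress(F, fiber, p: AponeurosisParams, include_vol: bool = True):
    """Mooney-Rivlin matrix + tension-only fiber Cauchy stress (MPa)."""
    J, Fb, Bb, I1, m, I4, I5 = _kinematics(F, fiber)
    tau = 2.0 * p.C1 * Bb
    if p.C2 != 0.0:
        tau = tau + 2.0 * p.C2 * (I1[..., None, None] * Bb - Bb @ Bb)
    mm = np.einsum("...i,...j->...ij", m, m)
    tau = tau + 2.0 * _apo_fiber_dW_dI4(I4, p)[..., None, None] * mm
    sig = _dev(tau) / J[..., None, None]
    if include_vol:
        sig = sig + _vol_stress(J, p.K)
    return sig


# ----------------------------------------------------------------------
# parameter file I/O (YAML or JSON, by extension)


def save_material_params(
    path: str | Path, muscle: MuscleFatParams, aponeurosis: AponeurosisParams
) -> None:
    data = {"muscle_fat": asdict(muscle), "aponeurosis": asdict(aponeurosis)}
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        import yaml

        path.write_text(yaml.safe_dump(data))
    else:
        path.write_text(json.dumps(data, indent=2))


def load_material_params(path: str | Path) -> tuple[MuscleFatParams, AponeurosisParams]:
    """Read material constants from YAML/JSON; missing keys keep defaults."""
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        import yaml

        data = yaml.safe_load(path.read_text())
    else:
        data = json.loads(path.read_text())
    return (
        MuscleFatParams(**data.get("muscle_fat", {})),
        AponeurosisParams(**data.get("aponeurosis", {})),
    )
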