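"""Physical interpretation of the discovered active-nematic relations.

Implements the active and anisotropic viscous stresses appearing in the
discovered stress balance, the generic Leslie viscous stress it specializes,
strong-form residual maps (divergence, director angular velocity, stress
components), the two-layer Rayleigh friction of the confining fluids, and
the buckling length scale that balances bundle elasticity against the
viscous forces of extension.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .field_data import (
    FieldSequence,
    Mask,
    derived_fields,
    director_diff,
)

__all__ = [
    "ModelCoefficients",
    "StressParams",
    "LeslieParams",
    "LayerGeometry",
    "BucklingParams",
    "active_stress",
    "viscous_stress",
    "leslie_viscous_stress",
    "stress_balance_residual",
    "angular_velocity_map",
    "friction_coefficient",
    "layer_flow_profiles",
    "interfacial_stress",
    "buckling_length",
    "check_relations_strong_form",
]


@dataclass
class ModelCoefficients:
    """Discovered coefficients of the director equation and stress balance.

    c1: advection, c2: co-rotation, c3: alignment (director equation);
    c5: active/viscous ratio in the tensor stress balance; c5_prime: its
    scalar form.  Uncertainties are one-sigma absolute values.
    """

    c1: float = 1.0
    c2: float = -1.0
    c3: float = -1.0
    c5: float = -0.56
    c5_prime: float = -0.55
    sd: Optional[dict] = None

    def __post_init__(self):
        for v in (self.c1, self.c2, self.c3, self.c5, self.c5_prime):
            if not np.isfinite(v):
                raise ValueError("coefficients must be finite")
        if self.sd:
            if any(s < 0 for s in self.sd.values()):
                raise ValueError("uncertainties must be non-negative")


@dataclass
class StressParams:
    """Activity alpha and anisotropic viscosity mu_a; c5 is proportional to
    -alpha/mu_a (extensile systems have alpha > 0, hence c5 < 0)."""

    alpha: float
    mu_a: float

    @property
    def c5_ratio(self) -> float:
        return -self.alpha / self.mu_a


@dataclass
class LeslieParams:
    """Parameters of the generic uniaxial viscous stress
    nu4 A + beta1 (n.A.n) nn + beta2 (A nn + nn A)."""

    nu4: float = 0.0
    beta1: float = 1.0
    beta2: float = 0.0
    lam: float = 1.0


@dataclass
class LayerGeometry:
    """Thicknesses and viscosities of the two confining fluid layers."""

    h_t: float
    h_b: float
    mu_t: float
    mu_b: float

    def __post_init__(self):
        if min(self.h_t, self.h_b, self.mu_t, self.mu_b) <= 0:
            raise ValueError("layer geometry entries must be positive")


@dataclass
class BucklingParams:
    """Inputs of the buckling length estimate.

    ``youngs_modulus`` (E_Y, Pa) and ``extension_rate`` (1/s) are distinct
    quantities even though the field often writes both as E.
    """

    radius: float            # bundle radius r [m]
    youngs_modulus: float    # E_Y [Pa]
    viscosity: float         # ambient fluid viscosity mu [Pa s]
    layer_thickness: float   # h [m]
    extension_rate: float    # Edot [1/s]

    def __post_init__(self):
        vals = (
            self.radius, self.youngs_modulus, self.viscosity,
            self.layer_thickness, self.extension_rate,
        )
        if min(vals) <= 0:
            raise ValueError("buckling parameters must be positive")


# ---------------------------------------------------------------------------
# stresses


def active_stress(Qbar: np.ndarray, alpha: float) -> np.ndarray:
    """sigma^a = alpha Qbar (symmetric traceless by construction)."""

    return alpha * Qbar


def viscous_stress(Qbar: np.ndarray, Abar: np.ndarray, mu_a: float) -> np.ndarray:
    """sigma^v = mu_a (Abar : Qbar) Qbar, the single anisotropic viscous
    stress surviving in the discovered balance."""

    contraction = np.einsum("...ij,...ij->...", Abar, Qbar)
    return mu_a * contraction[..., None, None] * Qbar


def leslie_viscous_stress(
    A: np.ndarray, n: np.ndarray, params: LeslieParams
) -> np.ndarray:
    """Generic uniaxial viscous stress
    nu4 A_ij + beta1 (A_kl n_k n_l) n_i n_j + beta2 (A_ik n_k n_j + A_jk n_k n_i).

    With nu4 = beta2 = 0 its deviatoric part equals ``viscous_stress`` with
    mu_a = beta1 (the nn outer product differs from Qbar by an isotropic,
    pressure-like term only).
    """

    nn = n[..., :, None] * n[..., None, :]
    nAn = np.einsum("...kl,...k,...l->...", A, n, n)
    An = np.einsum("...ik,...k->...i", A, n)
    sym = An[..., :, None] * n[..., None, :] + An[..., None, :] * n[..., :, None]
    return params.nu4 * A + params.beta1 * nAn[..., None, None] * nn + params.beta2 * sym


def deviatoric(T: np.ndarray) -> np.ndarray:
    tr = np.trace(T, axis1=-2, axis2=-1)
    return T - 0.5 * tr[..., None, None] * np.eye(2)


# ---------------------------------------------------------------------------
# strong-form maps


def stress_balance_residual(
    fields: FieldSequence,
    c5: float,
    mask: Optional[Mask] = None,
):
    """Pointwise residuals of the stress balance and its scalar form.

    Returns a dict with the rank-2 map (Abar:Qbar) Qbar + c5 Qbar, the scalar
    map Abar:Qbar + c5 (the scalar form's coefficient equals c5 for data
    satisfying the tensor balance), and mask-weighted RMS summaries.
    """

    d = derived_fields(fields)
    contraction = np.einsum("...ij,...ij->...", d.Abar, d.Qbar)
    tensor_map = (contraction[..., None, None] + c5) * d.Qbar
    scalar_map = contraction + c5
    w = mask.psi if mask is not None else np.ones(fields.grid.shape)
    wsum = w.sum()
    if wsum == 0:
        return {
            "tensor": tensor_map, "scalar": scalar_map,
            "rms_tensor": np.nan, "rms_scalar": np.nan, "empty_mask": True,
        }
    rms_t = float(np.sqrt((w * np.sum(tensor_map ** 2, axis=(-2, -1))).sum() / wsum))
    rms_s = float(np.sqrt((w * scalar_map ** 2).sum() / wsum))
    return {
        "tensor": tensor_map, "scalar": scalar_map,
        "rms_tensor": rms_t, "rms_scalar": rms_s, "empty_mask": False,
    }


def angular_velocity_map(fields: FieldSequence, coeffs: ModelCoefficients):
    """Observed vs reconstructed director angular velocity.

    Observed: dtheta/dt = eps_ij n_i dt n_j from sign-aligned time
    differences.  Reconstructed: -(c1 u.grad n + c2 Omega n + c3 Pperp Abar n)
    contracted the same way.  Both maps are even in n (gauge invariant).
    """

    g = fields.grid
    if g.nt < 3:
        raise ValueError("need at least 3 time slices")
    n = fields.n
    dtn = director_diff(n, "t", g.dt)
    observed = n[..., 0] * dtn[..., 1] - n[..., 1] * dtn[..., 0]
    d = derived_fields(fields)
    gradn = np.stack(
        [director_diff(n, i, g.spacing(i)) for i in range(2)], axis=-2
    )  # (..., i, comp)
    adv = np.einsum("...a,...ac->...c", fields.u, gradn)
    Omn = np.einsum("...ij,...j->...i", d.Omega, n)
    Abn = np.einsum("...ij,...j->...i", d.Abar, n)
    nAbn = np.einsum("...i,...i->...", n, Abn)
    PAbn = Abn - nAbn[..., None] * n
    rhs = -(coeffs.c1 * adv + coeffs.c2 * Omn + coeffs.c3 * PAbn)
    reconstructed = n[..., 0] * rhs[..., 1] - n[..., 1] * rhs[..., 0]
    return observed, reconstructed


def check_relations_strong_form(
    fields: FieldSequence,
    coeffs: ModelCoefficients,
    mask: Optional[Mask] = None,
):
    """Pointwise (finite-difference) residual maps of the three relations.

    Returns maps and mask-weighted RMS residuals normalized by the RMS of
    each relation's largest term.
    """

    d = derived_fields(fields)
    w = mask.psi if mask is not None else np.ones(fields.grid.shape)
    wsum = w.sum()
    out = {"empty_mask": wsum == 0}
    if wsum == 0:
        return out

    def _rms(x):
        return float(np.sqrt((w * x ** 2).sum() / wsum))

    # incompressibility
    gradu_scale = _rms(np.sqrt(np.sum(d.gradu ** 2, axis=(-2, -1))))
    out["divergence_map"] = d.div
    out["divergence_rms"] = _rms(d.div) / max(gradu_scale, 1e-300)
    # director evolution
    observed, reconstructed = angular_velocity_map(fields, coeffs)
    out["angular_velocity_observed"] = observed
    out["angular_velocity_reconstructed"] = reconstructed
    out["angular_velocity_rms"] = _rms(observed - reconstructed) / max(
        _rms(observed), 1e-300
    )
    # stress balance
    sb = stress_balance_residual(fields, coeffs.c5, mask)
    qa_scale = _rms(np.sqrt(np.sum((coeffs.c5 * d.Qbar) ** 2, axis=(-2, -1))))
    out["stress_map"] = sb["tensor"]
    out["stress_rms"] = sb["rms_tensor"] / max(qa_scale, 1e-300)
    return out


def render_residual_maps(maps: dict, path: str, frame: int = 0) -> None:
    """Write a PNG panel of the strong-form residual maps (one frame)."""

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [
        ("divergence_map", "div u"),
        ("angular_velocity_observed", "observed dtheta/dt"),
        ("angular_velocity_reconstructed", "reconstructed dtheta/dt"),
    ]
    fig, axes = plt.subplots(1, len(panels), figsize=(4 * len(panels), 3.5))
    for ax, (key, title) in zip(np.atleast_1d(axes), panels):
        if key not in maps:
            ax.axis("off")
            continue
        im = ax.imshow(maps[key][frame], origin="lower", cmap="RdBu_r")
        ax.set_title(title)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# confinement physics


def friction_coefficient(geom: LayerGeometry) -> float:
    """Rayleigh friction eta_f = mu_t / h_t + mu_b / h_b [Pa s / m]."""

    return geom.mu_t / geom.h_t + geom.mu_b / geom.h_b


def layer_flow_profiles(
    u_interface: np.ndarray, z: float, geom: LayerGeometry
) -> np.ndarray:
    """Linear shear profiles in the confining layers.

    z = 0 is the interface; the bottom layer occupies -h_b <= z <= 0 with
    u^b = (1 + z/h_b) u_i, the top layer 0 <= z <= h_t with
    u^t = (1 - z/h_t) u_i; both satisfy no slip at the rigid walls.
    """

    u_interface = np.asarray(u_interface, dtype=float)
    if z < -geom.h_b or z > geom.h_t:
        raise ValueError("z outside the fluid layers")
    factor = 1.0 + z / geom.h_b if z <= 0 else 1.0 - z / geom.h_t
    return factor * u_interface


def interfacial_stress(u_interface: np.ndarray, geom: LayerGeometry) -> np.ndarray:
    """sigma_z = mu_t dz(u^t) - mu_b dz(u^b) = -eta_f u_i (Rayleigh drag)."""

    return -friction_coefficient(geom) * np.asarray(u_interface, dtype=float)


def buckling_length(p: BucklingParams) -> float:
    """Buckling wavelength L = r [ (h/r) E_Y / (mu Edot) ]^(1/4).

    Balances the elastic restoring force of a bundle of radius r and Young's
    modulus E_Y against the viscous force exerted through a fluid layer of
    thickness h and viscosity mu by the motor-driven extension at rate Edot.
    The scaling relation is evaluated with unit prefactor.
    """

    ratio = (p.layer_thickness / p.radius) * p.youngs_modulus / (
        p.viscosity * p.extension_rate
    )
    return p.radius * ratio ** 0.25
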