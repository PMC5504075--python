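"""Specular neutron reflectivity of a slab stack.

The forward model is the standard optical transfer-matrix (Abelès/Parratt)
recursion.  In medium j the normal wavevector is

    k_j = sqrt((q/2)^2 - 4 pi (rho_j - rho_0)),

with rho_0 the fronting SLD; interfacial r.m.s. roughness sigma enters
through Nevot–Croce damping of each Fresnel coefficient,

    r_j -> r_j * exp(-2 k_j k_{j+1} sigma_j^2).

Instrumental q-resolution is applied as a point-wise Gaussian convolution
(fixed-node quadrature over +/-3.5 sigma), matching the per-point dq column
of reduced reflectivity files.  No absorption terms are included: imaginary
SLDs are negligible for the H/D/C/N/O/Si isotopes involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .materials import SolventContrast
from .slabs import SlabStack

# fixed-node Gaussian quadrature for resolution smearing
_N_GAUSS = 17
_GAUSS_X = np.linspace(-3.5, 3.5, _N_GAUSS)
_GAUSS_W = np.exp(-0.5 * _GAUSS_X**2)
_GAUSS_W /= _GAUSS_W.sum()


class InvalidStackError(ValueError):
    pass


def _abeles_kernel_numpy(q, slds, thick, rough):
    """Parratt recursion, vectorised over q (reference implementation)."""
    kz0_sq = (q / 2.0) ** 2
    k = np.sqrt(kz0_sq[None, :] - 4.0 * np.pi * (slds[:, None] - slds[0]) + 0j)
    n_interfaces = len(slds) - 1
    r_amp = np.zeros_like(q, dtype=complex)
    for j in range(n_interfaces - 1, -1, -1):
        kj, kj1 = k[j], k[j + 1]
        rj = (kj - kj1) / (kj + kj1)
        rj = rj * np.exp(-2.0 * kj * kj1 * rough[j] ** 2)
        if j == n_interfaces - 1:
            r_amp = rj
        else:
            beta = np.exp(2j * kj1 * thick[j])
            r_amp = (rj + r_amp * beta) / (1.0 + rj * r_amp * beta)
    return np.abs(r_amp) ** 2


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _abeles_kernel_jit(q, slds, thick, rough):  # pragma: no cover
        nq = q.shape[0]
        nmedia = slds.shape[0]
        out = np.empty(nq)
        for iq in range(nq):
            kz0_sq = (q[iq] / 2.0) ** 2
            r_amp = 0.0 + 0.0j
            k_below = np.sqrt(
                kz0_sq - 4.0 * np.pi * (slds[nmedia - 1] - slds[0]) + 0j
            )
            for j in range(nmedia - 2, -1, -1):
                kj = np.sqrt(kz0_sq - 4.0 * np.pi * (slds[j] - slds[0]) + 0j)
                kj1 = k_below
                rj = (kj - kj1) / (kj + kj1) * np.exp(
                    -2.0 * kj * kj1 * rough[j] ** 2
                )
                if j == nmedia - 2:
                    r_amp = rj
                else:
                    beta = np.exp(2j * kj1 * thick[j])
                    r_amp = (rj + r_amp * beta) / (1.0 + rj * r_amp * beta)
                k_below = kj
            out[iq] = np.abs(r_amp) ** 2
        return out

    _abeles_kernel = _abeles_kernel_jit
except ImportError:  # pragma: no cover
    _abeles_kernel = _abeles_kernel_numpy


@dataclass
class NRDataset:
    """One contrast's reduced reflectivity curve.

    Columns follow the conventional 4-column reduced format:
    q (Å⁻¹), R, sigma_R (1-sigma uncertainty), sigma_q (1-sigma Gaussian
    resolution width).
    """

    q: np.ndarray
    R: np.ndarray
    sigma_R: np.ndarray
    sigma_q: np.ndarray
    contrast: SolventContrast
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.sigma_R = np.asarray(self.sigma_R, dtype=float)
        self.sigma_q = np.asarray(self.sigma_q, dtype=float)
        n = self.q.size
        if not (self.R.size == self.sigma_R.size == self.sigma_q.size == n):
            raise ValueError("q, R, sigma_R, sigma_q must share one length")
        if not (np.all(np.diff(self.q) > 0) and np.all(self.q > 0)):
            raise ValueError("q must be strictly increasing and positive")
        if np.any(self.R < 0):
            raise ValueError("R must be >= 0")
        if np.any(self.sigma_R <= 0):
            raise ValueError("sigma_R must be > 0")

    def __len__(self) -> int:
        return self.q.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"q": self.q, "R": self.R, "dR": self.sigma_R, "dq": self.sigma_q}
        )


def abeles_reflectivity(q, stack: SlabStack) -> np.ndarray:
    """Specular reflectivity R(q) of a slab stack.

    Parameters
    ----------
    q : array-like
        Momentum transfer, Å⁻¹ (positive).
    stack : SlabStack
        Layer model including fronting/backing media and roughnesses.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q <= 0):
        raise ValueError("q must be > 0")
    thick = stack.thicknesses()
    if np.any(thick < 0):
        raise InvalidStackError("negative slab thickness")

    slds = stack.slds()
    rough = stack.roughnesses()
    return _abeles_kernel(
        np.ascontiguousarray(q),
        np.ascontiguousarray(slds),
        np.ascontiguousarray(thick),
        np.ascontiguousarray(rough),
    )


def fresnel_reflectivity(q, sld_front: float, sld_back: float) -> np.ndarray:
    """Closed-form Fresnel reflectivity of one sharp interface."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    k0 = q / 2.0
    k1 = np.sqrt(k0**2 - 4 * np.pi * (sld_back - sld_front) + 0j)
    return np.abs((k0 - k1) / (k0 + k1)) ** 2


def critical_edge(sld_front: float, sld_back: float) -> float:
    """q below which total external reflection occurs (requires
    ``sld_back > sld_front``)."""
    drho = sld_back - sld_front
    if drho <= 0:
        raise ValueError("no critical edge unless backing SLD exceeds fronting")
    return float(np.sqrt(16 * np.pi * drho))


def smear(q, sigma_q, reflectivity_fn) -> np.ndarray:
    """Point-wise Gaussian q-resolution convolution.

    ``reflectivity_fn`` maps a q array to R; ``sigma_q`` is the 1-sigma
    width per point (scalar or array).  ``sigma_q = 0`` returns the
    unsmeared curve.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    sigma_q = np.broadcast_to(np.asarray(sigma_q, dtype=float), q.shape)
    if np.any(sigma_q < 0):
        raise ValueError("sigma_q must be >= 0")
    if np.all(sigma_q == 0):
        return reflectivity_fn(q)
    q_nodes = q[:, None] + _GAUSS_X[None, :] * sigma_q[:, None]
    q_nodes = np.clip(q_nodes, 1e-8, None)
    R_nodes = reflectivity_fn(q_nodes.ravel()).reshape(q_nodes.shape)
    return R_nodes @ _GAUSS_W


def smeared_reflectivity(q, stack: SlabStack, sigma_q=None) -> np.ndarray:
    """Abelès reflectivity, optionally resolution-smeared."""
    if sigma_q is None:
        return abeles_reflectivity(q, stack)
    return smear(q, sigma_q, lambda qq: abeles_reflectivity(qq, stack))


def chi_squared(dataset: NRDataset, stack: SlabStack) -> float:
    """Sum of squared sigma-normalised residuals of the smeared model."""
    if np.any(dataset.sigma_R <= 0):
        raise ValueError("sigma_R must be > 0")
    model = smeared_reflectivity(dataset.q, stack, dataset.sigma_q)
    return float(np.sum(((model - dataset.R) / dataset.sigma_R) ** 2))


def microslice_reflectivity(
    q, stack: SlabStack, dz: float = 0.5, pad_sigmas: float = 5.0
) -> np.ndarray:
    """Reflectivity via fine micro-slicing of the roughness-broadened
    profile, with no analytic roughness factors.

    The error-function SLD profile is discretised into ``dz``-thick sharp
    slabs, independently cross-checking the Nevot–Croce treatment.  Slow;
    intended for validation, not fitting.
    """
    from .slabs import sld_profile, Slab

    pad = pad_sigmas * max(float(np.max(stack.roughnesses())), 1.0)
    z = np.arange(-pad, stack.total_thickness + pad + dz, dz)
    centers = 0.5 * (z[:-1] + z[1:])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = sld_profile(stack, centers)
    slabs = tuple(
        Slab(thickness=dz, sld=float(r), roughness=0.0) for r in rho
    )
    fine = SlabStack(
        slabs=slabs,
        fronting_sld=stack.fronting_sld,
        backing_sld=stack.backing_sld,
        backing_roughness=0.0,
    )
    return abeles_reflectivity(q, fine)
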