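"""Normal-incidence plane-wave solution through a layered tissue stack.

A plane wave in air impinges normally on the stack surface (z = 0, depth
increasing into tissue). Within layer i, with local depth zeta = z - z_i,
the electric field phasor (unit incident amplitude, e^{+j w t} convention)
is

    e_i(zeta) = tau_i e^{-gamma_i zeta} + upsilon_i e^{+gamma_i zeta},

with tau_i / upsilon_i the forward / backward complex amplitudes. The
deepest layer is treated as semi-infinite (upsilon_N = 0). Amplitudes are
obtained by the impedance-transformation recursion: input impedances are
propagated bottom-up, then local reflection ratios Gamma are carried
top-down. Backward waves are stored through the bottom-interface ratio
Gamma_bot so the growing exponential is always evaluated as
e^{-gamma (2 d - zeta)} — a scaled representation that cannot overflow in
thick lossy layers.

Power bookkeeping uses unit-field amplitudes; the physical scaling
|E_inc|^2 = 2 p eta0 (incident power density p) enters only in SAR and
Poynting-flux evaluations, giving SAR = sigma p eta0 |e|^2 / rho.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dielectrics import (
    ETA0,
    PropagationTriple,
    complex_permittivity,
    effective_conductivity,
    load_tissue_database,
    propagation_constants,
)
from .layer_models import LayerStack

__all__ = ["LayerWave", "EMSolution", "solve_stack_em", "sar_at", "apd_surface", "depth_profile"]

_F_MIN, _F_MAX = 1e9, 300e9  # nominal validity band of the stack solve


@dataclass(frozen=True)
class LayerWave:
    """Wave amplitudes and constants of one layer (unit incident field).

    X = 2 Re(tau conj(upsilon)) and Y = 2 Im(tau conj(upsilon)) are the
    standing-wave cosine/sine coefficients appearing in |e(zeta)|^2.
    ``gamma_bot`` is the backward/forward ratio at the layer's bottom
    interface; it is zero in the terminal (semi-infinite) layer.
    """

    tau: complex
    upsilon: complex
    prop: PropagationTriple
    sigma: float
    z_top: float
    thickness: float
    gamma_bot: complex  # reflection ratio at the bottom interface

    @property
    def X(self) -> float:
        return 2.0 * (self.tau * self.upsilon.conjugate()).real

    @property
    def Y(self) -> float:
        return 2.0 * (self.tau * self.upsilon.conjugate()).imag

    def efield(self, zeta: float | np.ndarray) -> complex | np.ndarray:
        """Unit-normalised E at local depth zeta in [0, thickness]."""
        g = self.prop.gamma
        return self.tau * (
            np.exp(-g * zeta) + self.gamma_bot * np.exp(-g * (2.0 * self.thickness - zeta))
        )

    def hfield(self, zeta: float | np.ndarray) -> complex | np.ndarray:
        """Unit-normalised H at local depth zeta."""
        g = self.prop.gamma
        return (
            self.tau
            * (np.exp(-g * zeta) - self.gamma_bot * np.exp(-g * (2.0 * self.thickness - zeta)))
            / self.prop.eta
        )


@dataclass(frozen=True)
class EMSolution:
    """Solved plane-wave problem for one stack at one frequency.

    frequency : Hz;  p : incident power density, W/m^2;
    reflection : overall complex reflection coefficient at the surface;
    apd : absorbed power density at the surface, W/m^2.
    """

    frequency: float
    p: float
    waves: tuple[LayerWave, ...]
    reflection: complex
    eta0: float = ETA0

    @property
    def apd(self) -> float:
        """Absorbed power density p (1 - |r|^2), W/m^2."""
        return self.p * (1.0 - abs(self.reflection) ** 2)

    @property
    def transmittance(self) -> float:
        """APD / IPD at the surface."""
        return 1.0 - abs(self.reflection) ** 2


def solve_stack_em(
    stack: LayerStack,
    f: float,
    p: float,
    tissues: Mapping | None = None,
) -> EMSolution:
    """Solve the normal-incidence multilayer problem at frequency ``f`` (Hz).

    ``p`` is the incident power density (W/m^2). ``tissues`` optionally
    supplies a dielectric database mapping each layer's ``dielectric_ref``
    to a dispersion model; by default the packaged table is used.
    """
    if not _F_MIN < f <= _F_MAX:
        raise ValueError(
            f"frequency {f:.4g} Hz outside the supported band ({_F_MIN:.0e}, {_F_MAX:.0e}] Hz"
        )
    if not p >= 0:
        raise ValueError(f"incident power density p = {p} must be >= 0")
    if tissues is None:
        tissues = load_tissue_database()

    props: list[PropagationTriple] = []
    sigmas: list[float] = []
    for layer in stack.layers:
        try:
            model = tissues[layer.dielectric_ref]
        except KeyError:
            raise ValueError(
                f"layer {layer.name!r}: dielectric_ref {layer.dielectric_ref!r} "
                "not in the tissue database"
            ) from None
        eps = complex_permittivity(model, f)
        props.append(propagation_constants(eps, f))
        sigmas.append(effective_conductivity(eps, f))

    n = len(stack.layers)
    ds = [la.thickness for la in stack.layers]

    # Bottom-up: input impedance looking into layer i's top, via the local
    # bottom-interface reflection ratio (terminal layer is semi-infinite).
    gamma_bot = [0j] * n
    z_in = props[-1].eta
    for i in range(n - 2, -1, -1):
        g = (z_in - props[i].eta) / (z_in + props[i].eta)
        gamma_bot[i] = g
        ge = g * cmath.exp(-2.0 * props[i].gamma * ds[i])
        z_in = props[i].eta * (1.0 + ge) / (1.0 - ge)

    r = (z_in - ETA0) / (z_in + ETA0)

    # Top-down: amplitudes from field continuity at each interface.
    waves: list[LayerWave] = []
    e_top = 1.0 + r  # total E at the surface, unit incident field
    z_top = 0.0
    for i in range(n):
        g_top = gamma_bot[i] * cmath.exp(-2.0 * props[i].gamma * ds[i])
        tau = e_top / (1.0 + g_top)
        ups = tau * g_top
        waves.append(
            LayerWave(
                tau=tau,
                upsilon=ups,
                prop=props[i],
                sigma=sigmas[i],
                z_top=z_top,
                thickness=ds[i],
                gamma_bot=gamma_bot[i],
            )
        )
        # E at the bottom of layer i == E at the top of layer i+1
        e_top = tau * cmath.exp(-props[i].gamma * ds[i]) * (1.0 + gamma_bot[i])
        z_top += ds[i]

    return EMSolution(frequency=f, p=p, waves=tuple(waves), reflection=r)


def apd_surface(sol: EMSolution) -> float:
    """Absorbed power density: net Poynting flux 1/2 Re(E x H*) at z = 0.

    Evaluated from the reconstructed fields just inside the first layer;
    equals p (1 - |r|^2) by energy conservation.
    """
    w = sol.waves[0]
    e = w.efield(0.0)
    h = w.hfield(0.0)
    return sol.p * sol.eta0 * (e * np.conjugate(h)).real


def poynting_at(sol: EMSolution, stack: LayerStack, z: float) -> float:
    """Net downward power flux 1/2 Re(E x H*) at depth ``z``, W/m^2."""
    i = stack.layer_index_at(z)
    w = sol.waves[i]
    zeta = z - w.z_top
    return sol.p * sol.eta0 * (w.efield(zeta) * np.conjugate(w.hfield(zeta))).real


def sar_at(sol: EMSolution, stack: LayerStack, z: float | np.ndarray) -> float | np.ndarray:
    """Specific absorption rate sigma |E|^2 / (2 rho) at depth ``z``, W/kg.

    Piecewise smooth; discontinuous only at layer interfaces (a depth that
    falls exactly on an interface reports the deeper layer's side).
    """
    if np.ndim(z) > 0:
        return np.array([sar_at(sol, stack, float(zz)) for zz in np.asarray(z).ravel()])
    i = stack.layer_index_at(float(z))
    w = sol.waves[i]
    layer = stack.layers[i]
    e2 = abs(w.efield(float(z) - w.z_top)) ** 2
    return w.sigma * sol.p * sol.eta0 * e2 / layer.rho


def depth_profile(
    sol: EMSolution, stack: LayerStack, z: Sequence[float] | np.ndarray
) -> pd.DataFrame:
    """SAR and cumulative absorbed power versus depth, as a table.

    Columns: z [m], tissue, SAR [W/kg], cumulative absorbed power [W/m^2]
    (the power deposited between the surface and depth z).
    """
    z = np.asarray(z, float)
    rows = []
    for zz in z:
        i = stack.layer_index_at(float(zz))
        rows.append(
            {
                "z_m": float(zz),
                "tissue": stack.layers[i].name,
                "sar_W_per_kg": float(sar_at(sol, stack, float(zz))),
                "cumulative_absorbed_W_per_m2": sol.apd - poynting_at(sol, stack, float(zz)),
            }
        )
    return pd.DataFrame(rows)
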