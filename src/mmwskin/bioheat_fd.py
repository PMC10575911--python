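"""Independent finite-difference verification solver for the steady Pennes
equation.

Conservative node-centred discretisation on a 1-D grid that places every
layer interface exactly on a node: within each interval the conductivity is
single-valued, and interface flux continuity is enforced by the shared-node
half-cell balance (the harmonic-mean construction for discontinuous
coefficients, which the interface-aligned grid renders exact). Volumetric
sources (rho SAR, metabolic A, perfusion sink B (T - T_blood)) are
evaluated pointwise at the nodes from the correct side of each interface
and weighted by the adjoining half-cells.

Boundary conditions mirror the analytic solver: Robin h (T_0 - T_air) =
kappa T'(0) at the surface, Dirichlet T_body at the last node. The scheme
is second-order accurate on smooth-per-layer problems and is used purely
as a cross-check oracle for the closed-form solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .em_solver import EMSolution, sar_at
from .layer_models import LayerStack

__all__ = ["Grid1D", "build_grid", "solve_fd", "delta_T_fd"]

_MIN_INTERIOR_NODES = 4  # required resolution of the thinnest layer


@dataclass(frozen=True)
class Grid1D:
    """Strictly increasing node depths honouring every layer interface.

    ``layer_of_interval[k]`` is the layer index of interval (z_k, z_{k+1}).
    """

    z: np.ndarray
    layer_of_interval: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z, float)
        if z.ndim != 1 or z.size < 3:
            raise ValueError("grid needs at least 3 nodes")
        if z[0] != 0.0:
            raise ValueError("first grid node must sit at z = 0")
        if np.any(np.diff(z) <= 0):
            raise ValueError("grid nodes must be strictly increasing")
        if len(self.layer_of_interval) != z.size - 1:
            raise ValueError("layer_of_interval must have one entry per interval")


def build_grid(stack: LayerStack, max_step: float = 1e-6, max_nodes_per_layer: int = 4000) -> Grid1D:
    """Interface-aligned grid with spacing <= ``max_step`` where affordable.

    Each layer gets ``ceil(d / max_step)`` intervals capped at
    ``max_nodes_per_layer`` (thick deep layers need no micrometre
    resolution for the targeted accuracy), and never fewer than the
    minimum interior-node count.
    """
    zs = [0.0]
    owner = []
    z0 = 0.0
    for i, layer in enumerate(stack.layers):
        n = int(np.ceil(layer.thickness / max_step))
        n = min(max(n, _MIN_INTERIOR_NODES + 1), max_nodes_per_layer)
        pts = z0 + np.linspace(0.0, layer.thickness, n + 1)[1:]
        zs.extend(pts.tolist())
        owner.extend([i] * n)
        z0 += layer.thickness
    return Grid1D(z=np.asarray(zs), layer_of_interval=np.asarray(owner, int))


def _check_resolution(stack: LayerStack, grid: Grid1D) -> None:
    counts = np.bincount(grid.layer_of_interval, minlength=len(stack.layers))
    for i, layer in enumerate(stack.layers):
        if counts[i] - 1 < _MIN_INTERIOR_NODES:
            raise ValueError(
                f"grid under-resolves layer {layer.name!r}: "
                f"{max(counts[i] - 1, 0)} interior nodes < {_MIN_INTERIOR_NODES}"
            )


def solve_fd(stack: LayerStack, sar=None, grid: Grid1D | None = None) -> np.ndarray:
    """Nodal steady-state temperatures on ``grid`` (°C).

    ``sar`` is either ``None`` (baseline), a callable ``SAR(z, layer_index)``
    in W/kg, or an :class:`~mmwskin.em_solver.EMSolution` whose SAR profile
    is evaluated pointwise. Interfaces are sampled from the side of the
    half-cell being integrated.
    """
    if grid is None:
        grid = build_grid(stack)
    _check_resolution(stack, grid)
    z = grid.z
    n = z.size
    hs = np.diff(z)
    owner = grid.layer_of_interval
    kappa_iv = np.array([stack.layers[i].kappa for i in owner])

    def q_coeffs(node: int, interval: int):
        """Source (const, linear-in-T) of the half-cell of ``interval`` at ``node``:
        q = c0 - B*T with pointwise SAR from that interval's layer side."""
        layer = stack.layers[owner[interval]]
        if sar is None:
            s = 0.0
        elif isinstance(sar, EMSolution):
            # nudge strictly inside the interval so the correct layer is sampled
            lo, hi = z[interval], z[interval + 1]
            zz = min(max(z[node], lo + 1e-15 * (1 + hi)), hi - 1e-15 * (1 + hi))
            s = float(sar_at(sar, stack, zz))
        else:
            s = float(sar(z[node], owner[interval]))
        c0 = layer.rho * s + layer.metabolic_rate + layer.perfusion_term * stack.T_blood
        return c0, layer.perfusion_term

    # banded tridiagonal system: rows = flux balance per control volume
    ab = np.zeros((3, n))
    rhs = np.zeros(n)

    # surface node: kappa (T_1 - T_0)/h_1 - h_surf (T_0 - T_air) + (h_1/2) q_0 = 0
    c0, bb = q_coeffs(0, 0)
    w = hs[0] / 2.0
    ab[1, 0] = -kappa_iv[0] / hs[0] - stack.h - w * bb
    ab[0, 1] = kappa_iv[0] / hs[0]
    rhs[0] = -stack.h * stack.T_air - w * c0

    for j in range(1, n - 1):
        cl, bl = q_coeffs(j, j - 1)
        cr, br = q_coeffs(j, j)
        wl, wr = hs[j - 1] / 2.0, hs[j] / 2.0
        ab[2, j - 1] = kappa_iv[j - 1] / hs[j - 1]
        ab[0, j + 1] = kappa_iv[j] / hs[j]
        ab[1, j] = -kappa_iv[j - 1] / hs[j - 1] - kappa_iv[j] / hs[j] - wl * bl - wr * br
        rhs[j] = -wl * cl - wr * cr

    ab[1, n - 1] = 1.0
    rhs[n - 1] = stack.T_body

    return solve_banded((1, 1), ab, rhs)


def delta_T_fd(stack: LayerStack, em: EMSolution, grid: Grid1D | None = None):
    """FD temperature elevation: (grid nodes, Delta T at nodes).

    Baseline and exposed problems share the identical grid and assembly.
    """
    if grid is None:
        grid = build_grid(stack)
    t_exp = solve_fd(stack, sar=em, grid=grid)
    t_base = solve_fd(stack, sar=None, grid=grid)
    return grid.z, t_exp - t_base
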