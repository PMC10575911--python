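"""Closed-form steady-state solution of the 1-D Pennes bioheat equation.

Within layer i the steady Pennes balance is

    kappa_i T'' + rho_i SAR_i(z) + A_i - B_i (T_i - T_blood) = 0,

with convective (Robin) exchange against air at the surface,
h (T(0) - T_air) = kappa_1 T'(0), temperature and conductive-flux
continuity at every interior interface, and the core temperature T_body
clamped at the stack bottom.

Per layer the solution splits into a homogeneous part parameterised by the
layer-top temperature T(z_i) and slope T'(z_i) — linear in (z - z_i) for
B = 0, cosh/sinh in sqrt(B/kappa)(z - z_i) for B > 0, the latter carrying
the metabolic/perfusion offset T_blood + A/B — plus particular terms
anchored with zero value and slope at the layer top. The electromagnetic
particular term S_i solves

    kappa_i S'' - B_i S + rho_i SAR_i = 0,   S(z_i) = S'(z_i) = 0,

and is evaluated in closed form: rho SAR is a sum of e^{-2 alpha zeta},
e^{+2 alpha zeta} and e^{2j beta zeta} basis terms, each convolved exactly
with the zero-state kernel of the operator d^2/dz^2 - B/kappa. Near the
degenerate denominator 4 alpha^2 kappa = B the evaluation switches to the
analytic limit form (relative distance 1e-6) to avoid catastrophic
cancellation; the 4 beta^2 kappa + B denominator of the oscillatory terms
can never vanish. For B = 0 layers the metabolic heat contributes the
quadratic particular term -A (z - z_i)^2 / (2 kappa).

The 2N layer-top unknowns are solved from the surface Robin equation,
2(N-1) interface-continuity equations and the core Dirichlet equation.
The unexposed baseline reuses the identical assembly with S = 0, so the
reported temperature elevation Delta T = T_exposed - T_baseline inherits
no discretisation mismatch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .dielectrics import ETA0
from .em_solver import EMSolution, LayerWave, solve_stack_em
from .layer_models import LayerStack, TissueLayer

__all__ = [
    "SourceTerm",
    "LayerThermalState",
    "ThermalSolution",
    "DeltaTProfile",
    "particular_term",
    "assemble_and_solve",
    "delta_T",
    "boundary_residuals",
]

_DEGENERATE_RTOL = 1e-6  # switch to the limit form of the resonant kernel


def _kernel(lam: complex, m: float, zeta):
    """Zero-state response of y'' - m^2 y = e^{lam zeta}: returns (y, y').

    For m > 0 this is the convolution with sinh(m u)/m, for m = 0 with u,
    so y(0) = y'(0) = 0 exactly. ``lam`` may be complex (oscillatory basis
    terms enter with lam = 2j beta). Vectorised over ``zeta``.
    """
    zeta = np.asarray(zeta, dtype=float)
    if m == 0.0:
        if lam == 0:
            return zeta**2 / 2.0 + 0j, zeta.astype(complex)
        e = np.exp(lam * zeta)
        return (e - 1.0 - lam * zeta) / lam**2, (e - 1.0) / lam
    den = lam * lam - m * m
    scale = max(abs(lam) ** 2, m * m)
    if abs(den) < _DEGENERATE_RTOL * scale:
        # resonant limit lam -> +-m (L'Hopital on the regular form)
        e = np.exp(lam * zeta)
        y = (zeta * e - np.sinh(m * zeta) / m) / (2.0 * lam)
        dy = (e + lam * zeta * e - np.cosh(m * zeta)) / (2.0 * lam)
        return y, dy
    e = np.exp(lam * zeta)
    ch = np.cosh(m * zeta)
    sh = np.sinh(m * zeta)
    return (e - ch - (lam / m) * sh) / den, (lam * e - m * sh - lam * ch) / den


@dataclass(frozen=True)
class SourceTerm:
    """Particular solution S(zeta), S'(zeta) of one layer, zero state at the top.

    ``terms`` lists (coefficient, lam) pairs of the basis decomposition
    rho SAR(zeta) = Re[ sum_k c_k e^{lam_k zeta} ]; then
    S(zeta) = -(1/kappa) Re[ sum_k c_k K_k(zeta) ] with K_k the zero-state
    kernel response, so kappa S'' - B S + rho SAR = 0 holds exactly.
    """

    kappa: float
    B: float
    terms: tuple[tuple[complex, complex], ...]

    def _eval(self, zeta):
        m = math.sqrt(self.B / self.kappa) if self.B > 0 else 0.0
        val = np.zeros(np.shape(zeta), dtype=complex)
        slope = np.zeros(np.shape(zeta), dtype=complex)
        for coeff, lam in self.terms:
            y, dy = _kernel(lam, m, zeta)
            val = val + coeff * y
            slope = slope + coeff * dy
        return -val.real / self.kappa, -slope.real / self.kappa

    def value(self, zeta):
        """S at local depth zeta (m); S(0) = 0."""
        return self._eval(zeta)[0]

    def slope(self, zeta):
        """dS/dz at local depth zeta; S'(0) = 0."""
        return self._eval(zeta)[1]

    def rho_sar(self, zeta):
        """The driving volumetric heating rho SAR(zeta), W/m^3."""
        zeta = np.asarray(zeta, dtype=float)
        out = np.zeros(np.shape(zeta), dtype=complex)
        for coeff, lam in self.terms:
            out = out + coeff * np.exp(lam * zeta)
        return out.real


ZERO_SOURCE = SourceTerm(kappa=1.0, B=0.0, terms=())


def particular_term(layer: TissueLayer, wave: LayerWave, p: float) -> SourceTerm:
    """Electromagnetic particular term of one layer.

    ``wave`` supplies the unit-field amplitudes, ``p`` (W/m^2) the incident
    power density; rho SAR = sigma p eta0 |e(zeta)|^2 expands into the
    forward/backward exponentials plus the standing-wave oscillation
    (X - jY) e^{2j beta zeta}. A lossless layer (sigma = 0) yields S = 0.
    """
    c = wave.sigma * p * ETA0
    if c == 0.0:
        return SourceTerm(kappa=layer.kappa, B=layer.perfusion_term, terms=())
    a2 = 2.0 * wave.prop.alpha
    terms: list[tuple[complex, complex]] = [
        (c * abs(wave.tau) ** 2 + 0j, complex(-a2))
    ]
    if wave.upsilon != 0:
        terms.append((c * abs(wave.upsilon) ** 2 + 0j, complex(+a2)))
        terms.append((c * complex(wave.X, -wave.Y), 2j * wave.prop.beta))
    return SourceTerm(kappa=layer.kappa, B=layer.perfusion_term, terms=tuple(terms))


@dataclass(frozen=True)
class LayerThermalState:
    """Solved layer-top state: temperature T(z_i), slope T'(z_i), sources."""

    layer: TissueLayer
    T_top: float
    dT_top: float
    source: SourceTerm
    T_blood: float

    def temperature(self, zeta):
        """T at local depth zeta in [0, thickness], °C."""
        zeta = np.asarray(zeta, dtype=float)
        la = self.layer
        s = self.source.value(zeta) if self.source.terms else 0.0
        if la.perfusion_term == 0.0:
            return (
                self.T_top
                + self.dT_top * zeta
                - la.metabolic_rate * zeta**2 / (2.0 * la.kappa)
                + s
            )
        m = math.sqrt(la.perfusion_term / la.kappa)
        theta = self.T_blood + la.metabolic_rate / la.perfusion_term
        return (
            (self.T_top - theta) * np.cosh(m * zeta)
            + self.dT_top * np.sinh(m * zeta) / m
            + theta
            + s
        )

    def gradient(self, zeta):
        """dT/dz at local depth zeta, °C/m."""
        zeta = np.asarray(zeta, dtype=float)
        la = self.layer
        ds = self.source.slope(zeta) if self.source.terms else 0.0
        if la.perfusion_term == 0.0:
            return self.dT_top - la.metabolic_rate * zeta / la.kappa + ds
        m = math.sqrt(la.perfusion_term / la.kappa)
        theta = self.T_blood + la.metabolic_rate / la.perfusion_term
        return (
            (self.T_top - theta) * m * np.sinh(m * zeta)
            + self.dT_top * np.cosh(m * zeta)
            + ds
        )


@dataclass(frozen=True)
class ThermalSolution:
    """Piecewise steady-state temperature field over a stack.

    ``exposed`` flags whether the electromagnetic source was included.
    ``condition_number`` is the 2-norm conditioning of the interface system.
    """

    stack: LayerStack
    states: tuple[LayerThermalState, ...]
    exposed: bool
    condition_number: float

    @cached_property
    def _edges(self) -> np.ndarray:
        return self.stack.interfaces

    def temperature(self, z):
        """T(z) over the full depth, °C; vectorised."""
        z = np.asarray(z, dtype=float)
        scalar = z.ndim == 0
        zf = np.atleast_1d(z).astype(float)
        if np.any(zf < -1e-15) or np.any(zf > self._edges[-1] * (1 + 1e-12) + 1e-15):
            raise ValueError("z outside the stack depth range")
        out = np.empty_like(zf)
        idx = np.clip(
            np.searchsorted(self._edges, zf, side="right") - 1, 0, len(self.states) - 1
        )
        for i, st in enumerate(self.states):
            mask = idx == i
            if np.any(mask):
                out[mask] = st.temperature(zf[mask] - self._edges[i])
        return out[0] if scalar else out

    def gradient(self, z):
        """dT/dz at depth z, °C/m (deeper layer's side on interfaces)."""
        z = np.asarray(z, dtype=float)
        scalar = z.ndim == 0
        zf = np.atleast_1d(z).astype(float)
        out = np.empty_like(zf)
        idx = np.clip(
            np.searchsorted(self._edges, zf, side="right") - 1, 0, len(self.states) - 1
        )
        for i, st in enumerate(self.states):
            mask = idx == i
            if np.any(mask):
                out[mask] = st.gradient(zf[mask] - self._edges[i])
        return out[0] if scalar else out

    @property
    def surface_temperature(self) -> float:
        return float(self.states[0].T_top)


def assemble_and_solve(stack: LayerStack, em: EMSolution | None = None) -> ThermalSolution:
    """Solve the interface linear system for the stack's steady temperature.

    With ``em`` given the electromagnetic particular terms are included
    (frequency/power are those of the EM solution); with ``em=None`` the
    unexposed baseline is solved from the identical assembly with S = 0.
    """
    n = len(stack.layers)
    if em is not None and len(em.waves) != n:
        raise ValueError("EM solution does not match the stack layer count")

    sources: list[SourceTerm] = []
    for i, layer in enumerate(stack.layers):
        if em is None:
            sources.append(
                SourceTerm(kappa=layer.kappa, B=layer.perfusion_term, terms=())
            )
        else:
            sources.append(particular_term(layer, em.waves[i], em.p))

    # unknowns x = [T_top_1, dT_top_1, ..., T_top_N, dT_top_N]
    mat = np.zeros((2 * n, 2 * n))
    rhs = np.zeros(2 * n)

    # surface Robin: h (T_1(0) - T_air) = kappa_1 T'(0)
    mat[0, 0] = stack.h
    mat[0, 1] = -stack.layers[0].kappa
    rhs[0] = stack.h * stack.T_air

    def homogeneous_bottom(i: int):
        """(aT, ag, const, daT, dag, dconst): T and T' at the bottom of layer i
        as affine forms in (T_top_i, dT_top_i)."""
        la = stack.layers[i]
        d = la.thickness
        s_val = float(sources[i].value(d))
        s_slp = float(sources[i].slope(d))
        if la.perfusion_term == 0.0:
            quad = la.metabolic_rate * d * d / (2.0 * la.kappa)
            return (
                1.0, d, -quad + s_val,
                0.0, 1.0, -la.metabolic_rate * d / la.kappa + s_slp,
            )
        m = math.sqrt(la.perfusion_term / la.kappa)
        theta = stack.T_blood + la.metabolic_rate / la.perfusion_term
        ch, sh = math.cosh(m * d), math.sinh(m * d)
        return (
            ch, sh / m, theta * (1.0 - ch) + s_val,
            m * sh, ch, -theta * m * sh + s_slp,
        )

    row = 1
    for i in range(n - 1):
        aT, ag, c0, daT, dag, dc0 = homogeneous_bottom(i)
        # temperature continuity: T_i(d_i) = T_top_{i+1}
        mat[row, 2 * i] = aT
        mat[row, 2 * i + 1] = ag
        mat[row, 2 * (i + 1)] = -1.0
        rhs[row] = -c0
        row += 1
        # flux continuity: kappa_i T_i'(d_i) = kappa_{i+1} dT_top_{i+1}
        ki, kn = stack.layers[i].kappa, stack.layers[i + 1].kappa
        mat[row, 2 * i] = ki * daT
        mat[row, 2 * i + 1] = ki * dag
        mat[row, 2 * (i + 1) + 1] = -kn
        rhs[row] = -ki * dc0
        row += 1

    # core Dirichlet: T_N(d_N) = T_body
    aT, ag, c0, *_ = homogeneous_bottom(n - 1)
    mat[row, 2 * (n - 1)] = aT
    mat[row, 2 * (n - 1) + 1] = ag
    rhs[row] = stack.T_body - c0

    cond = float(np.linalg.cond(mat))
    try:
        x = np.linalg.solve(mat, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"singular thermal interface system (condition number {cond:.3g})"
        ) from exc

    states = tuple(
        LayerThermalState(
            layer=stack.layers[i],
            T_top=float(x[2 * i]),
            dT_top=float(x[2 * i + 1]),
            source=sources[i],
            T_blood=stack.T_blood,
        )
        for i in range(n)
    )
    return ThermalSolution(
        stack=stack, states=states, exposed=em is not None, condition_number=cond
    )


@dataclass(frozen=True)
class DeltaTProfile:
    """Exposure-minus-baseline temperature elevation over a stack's depth."""

    stack: LayerStack
    exposed: ThermalSolution
    baseline: ThermalSolution
    em: EMSolution

    def __call__(self, z):
        """Delta T(z) = T_exposed(z) - T_baseline(z), °C."""
        return self.exposed.temperature(z) - self.baseline.temperature(z)

    @property
    def surface(self) -> float:
        """Delta T at the skin surface (z = 0), °C."""
        return float(
            self.exposed.surface_temperature - self.baseline.surface_temperature
        )


def delta_T(
    stack: LayerStack, f: float, p: float, tissues=None, em: EMSolution | None = None
) -> DeltaTProfile:
    """Steady-state temperature-elevation profile for one exposure.

    Solves the plane-wave problem at frequency ``f`` (Hz) and incident power
    density ``p`` (W/m^2), then the bioheat system with and without the
    electromagnetic source. A pre-computed ``em`` solution may be supplied
    (its frequency/power must match).
    """
    if em is None:
        em = solve_stack_em(stack, f, p, tissues=tissues)
    elif not (em.frequency == f and em.p == p):
        raise ValueError("supplied EM solution does not match f, p")
    return DeltaTProfile(
        stack=stack,
        exposed=assemble_and_solve(stack, em),
        baseline=assemble_and_solve(stack, None),
        em=em,
    )


def boundary_residuals(sol: ThermalSolution) -> dict[str, np.ndarray | float]:
    """Residuals of all boundary/interface conditions (diagnostics).

    Returns the Robin surface residual (°C), the core Dirichlet residual
    (°C) and arrays of interface temperature (°C) and flux (W/m^2)
    mismatches; all are at machine-precision scale for a valid solve.
    """
    stack = sol.stack
    robin = stack.h * (
        sol.states[0].temperature(0.0) - stack.T_air
    ) - stack.layers[0].kappa * sol.states[0].gradient(0.0)
    t_jump, q_jump = [], []
    for i in range(len(stack.layers) - 1):
        d = stack.layers[i].thickness
        t_jump.append(float(sol.states[i].temperature(d) - sol.states[i + 1].temperature(0.0)))
        q_jump.append(
            float(
                stack.layers[i].kappa * sol.states[i].gradient(d)
                - stack.layers[i + 1].kappa * sol.states[i + 1].gradient(0.0)
            )
        )
    dirichlet = float(
        sol.states[-1].temperature(stack.layers[-1].thickness) - stack.T_body
    )
    return {
        "robin": float(robin),
        "dirichlet": dirichlet,
        "temperature_jumps": np.asarray(t_jump),
        "flux_jumps": np.asarray(q_jump),
    }
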