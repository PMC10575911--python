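"""Scalar dosimetric summaries and parametric sweeps.

The two headline metrics of millimeter-wave skin dosimetry:

transmittance
    APD / IPD at the skin surface — the fraction of the incident plane-wave
    power density entering the tissue, one minus the stack's power
    reflectance.
heating factor
    Steady-state surface temperature elevation divided by the surface APD,
    °C·m²/W — multiplying an exposure-limit APD by this factor bounds the
    worst-case steady surface heating.

Both are invariant to the incident power density (the EM and bioheat
problems are linear), which :func:`metrics_at` asserts by computing at two
power levels. Sweeps cover frequency (6–100 GHz band) and per-layer blood
perfusion, and :func:`layer_report` regenerates the per-layer table of
thickness, layer-top temperature elevation and absorbed power flux, and
conduction-slab thermal resistance R_i = d_i / kappa_i.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bioheat_analytic import delta_T
from .em_solver import poynting_at, solve_stack_em
from .layer_models import LayerStack, TissueLayer

__all__ = [
    "DoseMetrics",
    "SweepResult",
    "thermal_resistance",
    "metrics_at",
    "sweep_frequency",
    "sweep_perfusion",
    "model_dispersion",
    "layer_report",
    "with_layer_perfusion",
]

_LINEARITY_RTOL = 1e-9  # power-invariance guard inside metrics_at


def thermal_resistance(layer: TissueLayer) -> float:
    """Conduction-slab thermal resistance R = d / kappa, °C·m²/W."""
    return layer.thickness / layer.kappa


@dataclass(frozen=True)
class DoseMetrics:
    """Scalar dosimetric summary of one stack at one frequency."""

    frequency: float
    transmittance: float
    heating_factor: float
    surface_delta_T_per_kW: float  # °C at IPD = 1000 W/m^2
    thermal_resistances: tuple[float, ...]  # per layer, °C·m²/W


@dataclass(frozen=True)
class SweepResult:
    """One swept axis (strictly increasing) with metric values per point."""

    axis_name: str
    axis: np.ndarray
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, float)
        if np.any(np.diff(axis) <= 0):
            raise ValueError("sweep axis must be strictly increasing")
        for key, v in self.values.items():
            if len(np.asarray(v)) != axis.size:
                raise ValueError(f"metric {key!r} length does not match the axis")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(
            self, "values", {k: np.asarray(v, float) for k, v in self.values.items()}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.axis_name: self.axis, **self.values})


def metrics_at(stack: LayerStack, f: float, p: float = 1000.0, tissues=None) -> DoseMetrics:
    """Transmittance and heating factor of ``stack`` at frequency ``f`` (Hz).

    Computed from the coupled EM + bioheat solves at ``p`` and cross-checked
    at a second power level: both metrics must be power-invariant.
    """
    if not p > 0:
        raise ValueError(f"incident power density p = {p} must be > 0")
    prof = delta_T(stack, f, p, tissues=tissues)
    apd = prof.em.apd
    trans = prof.em.transmittance
    hf = prof.surface / apd

    prof2 = delta_T(stack, f, 2.0 * p, tissues=tissues)
    hf2 = prof2.surface / prof2.em.apd
    if abs(hf2 - hf) > _LINEARITY_RTOL * abs(hf):
        raise AssertionError(
            f"heating factor not power-invariant: {hf!r} vs {hf2!r}"
        )

    return DoseMetrics(
        frequency=f,
        transmittance=trans,
        heating_factor=hf,
        surface_delta_T_per_kW=hf * trans * 1000.0,
        thermal_resistances=tuple(thermal_resistance(la) for la in stack.layers),
    )


def sweep_frequency(
    stack: LayerStack, frequencies, p: float = 1000.0, tissues=None
) -> SweepResult:
    """APD, surface Delta T, transmittance and heating factor vs frequency (Hz)."""
    frequencies = np.asarray(sorted(float(f) for f in np.atleast_1d(frequencies)))
    apd, dts, trans, hf = [], [], [], []
    for f in frequencies:
        prof = delta_T(stack, f, p, tissues=tissues)
        apd.append(prof.em.apd)
        dts.append(prof.surface)
        trans.append(prof.em.transmittance)
        hf.append(prof.surface / prof.em.apd)
    return SweepResult(
        axis_name="frequency_Hz",
        axis=frequencies,
        values={
            "apd_W_per_m2": apd,
            "surface_delta_T_degC": dts,
            "transmittance": trans,
            "heating_factor_degC_m2_per_W": hf,
        },
    )


def with_layer_perfusion(stack: LayerStack, layer_name: str, B: float) -> LayerStack:
    """Copy of ``stack`` with the named layer's perfusion term set to ``B``."""
    names = [la.name for la in stack.layers]
    if layer_name not in names:
        raise ValueError(
            f"unknown layer {layer_name!r}; stack layers: {', '.join(names)}"
        )
    layers = tuple(
        replace(la, perfusion_term=float(B)) if la.name == layer_name else la
        for la in stack.layers
    )
    return LayerStack(
        name=stack.name, layers=layers, h=stack.h,
        T_air=stack.T_air, T_blood=stack.T_blood, T_body=stack.T_body,
    )


def sweep_perfusion(
    stack: LayerStack,
    layer_name: str,
    B_values=None,
    f: float = 30e9,
    p: float = 1000.0,
    tissues=None,
) -> SweepResult:
    """Surface Delta T vs the named layer's blood-perfusion term B.

    All other layers keep their stack values; the requested B is applied
    verbatim (including to layers whose nominal B is zero). The default
    grid is 13 log-spaced points over 300–36300 W/(m³·°C), the reported
    rat perfusion range.
    """
    if B_values is None:
        B_values = np.geomspace(300.0, 36300.0, 13)
    B_values = np.asarray(sorted(float(b) for b in np.atleast_1d(B_values)))
    if np.any(B_values < 0):
        raise ValueError("perfusion values must be >= 0")
    em = solve_stack_em(stack, f, p, tissues=tissues)  # B does not affect the EM side
    dts = []
    for b in B_values:
        st = with_layer_perfusion(stack, layer_name, b)
        dts.append(delta_T(st, f, p, tissues=tissues, em=em).surface)
    return SweepResult(
        axis_name="perfusion_W_per_m3_degC",
        axis=B_values,
        values={"surface_delta_T_degC": dts},
    )


def model_dispersion(stacks, f: float, p: float = 1000.0, tissues=None) -> dict[str, float]:
    """Relative standard deviation (population SD / mean, %) of the surface
    APD and surface Delta T across >= 2 stacks."""
    stacks = list(stacks)
    if len(stacks) < 2:
        raise ValueError("model_dispersion needs at least 2 stacks")
    apds, dts = [], []
    for st in stacks:
        prof = delta_T(st, f, p, tissues=tissues)
        apds.append(prof.em.apd)
        dts.append(prof.surface)
    apds, dts = np.asarray(apds), np.asarray(dts)
    return {
        "apd_rsd_percent": float(100.0 * apds.std() / apds.mean()),
        "delta_T_rsd_percent": float(100.0 * dts.std() / dts.mean()),
    }


def layer_report(
    stack: LayerStack, f: float = 30e9, p: float = 1000.0, tissues=None
) -> pd.DataFrame:
    """Per-layer table: thickness, layer-top Delta T and absorbed power flux,
    and thermal resistance, at one frequency and incident power density.

    Columns mirror the standard thermal-resistance summary: the power flux
    at a layer top is the net Poynting flux crossing that depth (the APD at
    the surface for the first layer).
    """
    prof = delta_T(stack, f, p, tissues=tissues)
    tops = stack.interfaces[:-1]
    rows = []
    for la, z_top in zip(stack.layers, tops):
        rows.append(
            {
                "tissue": la.name,
                "thickness_um": la.thickness * 1e6,
                "delta_T_top_degC": float(prof(z_top)),
                "power_flux_top_W_per_m2": float(poynting_at(prof.em, stack, z_top)),
                "thermal_resistance_degC_m2_per_W": thermal_resistance(la),
            }
        )
    return pd.DataFrame(rows)
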