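"""Layered skin-stack data model, packaged body-part fixtures and a
stochastic thickness sampler.

A :class:`LayerStack` is an ordered list of tissue slabs, exposure side
first, plus the thermal boundary settings: convective surface coefficient
``h`` against air at ``T_air``, arterial blood temperature ``T_blood`` and
a core Dirichlet temperature ``T_body`` clamped at the bottom of the stack.

Packaged fixtures
-----------------
``rat_head`` and ``rat_dorsal`` are six-layer stacks built from histological
skin-layer thickness measurements (epidermis, dermis, dermal white adipose
tissue, panniculus carnosus) over X-ray-CT deep layers (bone/brain for the
head, muscle/bone for the dorsum). ``human_forearm`` is the four-layer
epidermis/dermis/subcutaneous-fat/muscle comparison stack. Skin-layer
thicknesses carry measurement scatter (mean ± SD over animals), which the
:func:`sample_stack` generator propagates by truncated-normal draws.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .dielectrics import load_tissue_database

__all__ = [
    "TissueLayer",
    "LayerStack",
    "ThicknessDistribution",
    "fixture_stack",
    "fixture_checksum",
    "sample_stack",
    "thickness_distributions",
    "read_stack",
    "write_stack",
    "BODY_PARTS",
]


@dataclass(frozen=True)
class TissueLayer:
    """One tissue slab.

    thickness : m
    kappa     : thermal conductivity, W/(m·°C)
    rho       : mass density, kg/m³
    metabolic_rate : basal metabolic heat A, W/m³
    perfusion_term : blood-perfusion coefficient B, W/(m³·°C)
    dielectric_ref : tissue label resolving in the dielectric database
    """

    name: str
    thickness: float
    kappa: float
    rho: float
    metabolic_rate: float
    perfusion_term: float
    dielectric_ref: str

    def __post_init__(self) -> None:
        for fld, val, cond in (
            ("thickness", self.thickness, self.thickness > 0),
            ("kappa", self.kappa, self.kappa > 0),
            ("rho", self.rho, self.rho > 0),
            ("metabolic_rate", self.metabolic_rate, self.metabolic_rate >= 0),
            ("perfusion_term", self.perfusion_term, self.perfusion_term >= 0),
        ):
            if not cond:
                raise ValueError(f"layer {self.name!r}: {fld} = {val} is out of range")


@dataclass(frozen=True)
class LayerStack:
    """Ordered tissue layers (exposure side first) with boundary settings.

    h       : surface heat-transfer coefficient, W/(m²·°C)
    T_air   : ambient air temperature, °C
    T_blood : arterial blood temperature, °C
    T_body  : body-core temperature clamped at the stack bottom, °C
    """

    name: str
    layers: tuple[TissueLayer, ...]
    h: float = 0.5
    T_air: float = 23.0
    T_blood: float = 37.0
    T_body: float = 37.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if len(self.layers) < 2:
            raise ValueError("a LayerStack needs at least 2 layers")
        if not self.h > 0:
            raise ValueError(f"h = {self.h} must be > 0")
        for fld in ("T_air", "T_blood", "T_body"):
            if not np.isfinite(getattr(self, fld)):
                raise ValueError(f"{fld} must be finite")

    @property
    def total_thickness(self) -> float:
        """Total stack depth, m."""
        return float(sum(layer.thickness for layer in self.layers))

    @property
    def interfaces(self) -> np.ndarray:
        """Depths of layer tops plus the bottom: z_1=0 … z_{N+1}=total, m."""
        return np.concatenate([[0.0], np.cumsum([la.thickness for la in self.layers])])

    def layer_index_at(self, z: float) -> int:
        """Index of the layer containing depth ``z`` (ties go to the deeper layer)."""
        edges = self.interfaces
        if not 0.0 <= z <= edges[-1]:
            raise ValueError(f"z = {z} m outside stack [0, {edges[-1]}] m")
        idx = int(np.searchsorted(edges, z, side="right") - 1)
        return min(idx, len(self.layers) - 1)

    def to_frame(self) -> pd.DataFrame:
        """Layer table (one row per layer) for reports and CSV export."""
        return pd.DataFrame(
            {
                "tissue": [la.name for la in self.layers],
                "thickness_m": [la.thickness for la in self.layers],
                "kappa_W_per_m_degC": [la.kappa for la in self.layers],
                "rho_kg_per_m3": [la.rho for la in self.layers],
                "metabolic_rate_W_per_m3": [la.metabolic_rate for la in self.layers],
                "perfusion_term_W_per_m3_degC": [la.perfusion_term for la in self.layers],
                "dielectric_ref": [la.dielectric_ref for la in self.layers],
            }
        )


@dataclass(frozen=True)
class ThicknessDistribution:
    """Per-layer thickness measurement statistics: mean and SD, metres."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.mean > 0:
            raise ValueError(f"mean thickness must be > 0, got {self.mean}")
        if self.sd < 0:
            raise ValueError(f"thickness sd must be >= 0, got {self.sd}")


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------
# (name, thickness um, kappa, rho, A, B, dielectric_ref)

_RAT_HEAD = (
    ("epidermis", 22.8, 0.42, 1109.0, 7486.0, 0.0, "skin"),
    ("dermis", 563.4, 0.42, 1109.0, 7486.0, 1160.0, "skin"),
    ("dWAT", 191.5, 0.25, 911.0, 4063.0, 5629.0, "fat"),
    ("panniculus_carnosus", 230.1, 0.50, 1090.0, 1858.0, 9380.0, "muscle"),
    ("bone", 1000.0, 0.37, 1990.0, 7945.0, 12317.0, "bone"),
    ("brain", 9500.0, 0.57, 1038.0, 10837.0, 6800.0, "brain"),
)

_RAT_DORSAL = (
    ("epidermis", 26.1, 0.42, 1109.0, 7486.0, 0.0, "skin"),
    ("dermis", 908.0, 0.42, 1109.0, 7486.0, 1160.0, "skin"),
    ("dWAT", 577.3, 0.25, 911.0, 4063.0, 5629.0, "fat"),
    ("panniculus_carnosus", 567.5, 0.50, 1090.0, 1858.0, 9380.0, "muscle"),
    ("muscle", 4750.0, 0.50, 1090.0, 1858.0, 3801.0, "muscle"),
    ("bone", 4750.0, 0.37, 1990.0, 7945.0, 12317.0, "bone"),
)

# Human forearm comparison stack: thicknesses and kappa follow the four-layer
# forearm model used in mmWave dosimetry; rho and A reuse the rat analogue
# tissues, B defaults likewise (all three overridable via config files).
_HUMAN_FOREARM = (
    ("epidermis", 102.0, 0.42, 1109.0, 7486.0, 0.0, "skin"),
    ("dermis", 1080.0, 0.42, 1109.0, 7486.0, 1160.0, "skin"),
    ("subcutaneous_fat", 3890.0, 0.25, 911.0, 4063.0, 5629.0, "fat"),
    ("muscle", 23250.0, 0.50, 1090.0, 1858.0, 3801.0, "muscle"),
)

_FIXTURES = {
    "rat_head": _RAT_HEAD,
    "rat_dorsal": _RAT_DORSAL,
    "human_forearm": _HUMAN_FOREARM,
}

#: Recognised fixture labels.
BODY_PARTS = tuple(_FIXTURES)

# Histological skin-layer thickness statistics, mean ± SD in um.
_THICKNESS_STATS = {
    "rat_head": {
        "epidermis": (22.8, 2.4),
        "dermis": (563.4, 62.8),
        "dWAT": (191.5, 28.0),
        "panniculus_carnosus": (230.1, 25.3),
    },
    "rat_dorsal": {
        "epidermis": (26.1, 2.6),
        "dermis": (908.0, 22.4),
        "dWAT": (577.3, 45.0),
        "panniculus_carnosus": (567.5, 60.7),
    },
}


def fixture_stack(body_part: str) -> LayerStack:
    """Packaged layer stack for ``rat_head``, ``rat_dorsal`` or ``human_forearm``."""
    try:
        rows = _FIXTURES[body_part]
    except KeyError:
        raise ValueError(
            f"unknown body part {body_part!r}; valid labels: {', '.join(BODY_PARTS)}"
        ) from None
    layers = tuple(
        TissueLayer(
            name=name,
            thickness=um * 1e-6,
            kappa=kappa,
            rho=rho,
            metabolic_rate=a,
            perfusion_term=b,
            dielectric_ref=ref,
        )
        for name, um, kappa, rho, a, b, ref in rows
    )
    return LayerStack(name=body_part, layers=layers)


def fixture_checksum() -> str:
    """SHA-256 over the canonical fixture tables (guards silent edits)."""
    payload = repr((_FIXTURES, _THICKNESS_STATS)).encode()
    return hashlib.sha256(payload).hexdigest()


def thickness_distributions(body_part: str) -> dict[str, ThicknessDistribution]:
    """Measured skin-layer thickness statistics for a rat body part."""
    try:
        stats_ = _THICKNESS_STATS[body_part]
    except KeyError:
        raise ValueError(
            f"no thickness statistics for {body_part!r}; valid labels: "
            f"{', '.join(_THICKNESS_STATS)}"
        ) from None
    return {
        name: ThicknessDistribution(mean=m * 1e-6, sd=s * 1e-6)
        for name, (m, s) in stats_.items()
    }


_MIN_THICKNESS = 1e-6  # 1 um floor for sampled layers


def sample_stack(
    body_part: str,
    distributions: Mapping[str, ThicknessDistribution] | None = None,
    *,
    seed: int,
) -> LayerStack:
    """Draw one stack with skin-layer thicknesses sampled from measurement scatter.

    Thicknesses are drawn per skin layer from a normal(mean, sd) truncated
    below at mean − 3·sd and floored at 1 µm; deep (CT-derived) layers keep
    their fixture values. Deterministic for a fixed ``seed``.
    """
    base = fixture_stack(body_part)
    if distributions is None:
        distributions = thickness_distributions(body_part)
    rng = np.random.default_rng(seed)
    layers = []
    for layer in base.layers:
        dist = distributions.get(layer.name)
        if dist is None:
            layers.append(layer)
            continue
        if dist.sd == 0.0:
            d = dist.mean
        else:
            d = float(
                stats.truncnorm.rvs(
                    -3.0, np.inf, loc=dist.mean, scale=dist.sd, random_state=rng
                )
            )
        layers.append(replace(layer, thickness=max(d, _MIN_THICKNESS)))
    return LayerStack(
        name=f"{body_part}_sampled",
        layers=tuple(layers),
        h=base.h,
        T_air=base.T_air,
        T_blood=base.T_blood,
        T_body=base.T_body,
    )


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

_LENGTH_UNITS = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6}

_LAYER_FIELDS = (
    "thickness",
    "kappa",
    "rho",
    "metabolic_rate",
    "perfusion_term",
    "dielectric_ref",
)


def _parse_thickness(value, where: str) -> float:
    """Parse a thickness entry: a number (metres) or a '563.4 um' string."""
    if isinstance(value, (int, float)):
        d = float(value)
    elif isinstance(value, str):
        parts = value.split()
        if len(parts) != 2 or parts[1] not in _LENGTH_UNITS:
            raise ValueError(
                f"{where}: thickness {value!r} must be '<number> <m|mm|um>'"
            )
        d = float(parts[0]) * _LENGTH_UNITS[parts[1]]
    else:
        raise ValueError(f"{where}: thickness has invalid type {type(value).__name__}")
    if d <= 0:
        raise ValueError(f"{where}: thickness {value!r} must be positive")
    return d


def read_stack(source: str | Path | io.TextIOBase) -> LayerStack:
    """Read a stack from YAML text/config, validating every field.

    The config must declare ``layers`` (each with thickness, kappa, rho,
    metabolic_rate, perfusion_term, dielectric_ref) and the boundary settings
    ``h``, ``T_air``, ``T_blood``, ``T_body``. Thickness accepts a plain
    number in metres or a ``"<value> <m|mm|um>"`` string.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    elif isinstance(source, str):
        raw = yaml.safe_load(source)
    else:
        raw = yaml.safe_load(source)
    if not isinstance(raw, Mapping):
        raise ValueError("stack config must be a mapping")

    for fld in ("h", "T_air", "T_blood", "T_body"):
        if fld not in raw:
            raise ValueError(f"stack config: missing required field {fld!r}")
    if "layers" not in raw or not isinstance(raw["layers"], Sequence):
        raise ValueError("stack config: missing required field 'layers'")

    known = set(load_tissue_database())
    layers = []
    for k, rec in enumerate(raw["layers"]):
        where = f"layers[{k}] ({rec.get('name', '?')})" if isinstance(rec, Mapping) else f"layers[{k}]"
        if not isinstance(rec, Mapping):
            raise ValueError(f"{where}: layer record must be a mapping")
        missing = [fld for fld in _LAYER_FIELDS if fld not in rec]
        if missing:
            raise ValueError(f"{where}: missing field(s) {', '.join(missing)}")
        ref = rec["dielectric_ref"]
        if ref not in known:
            raise ValueError(
                f"{where}: unknown dielectric_ref {ref!r}; known tissues: "
                f"{', '.join(sorted(known))}"
            )
        layers.append(
            TissueLayer(
                name=str(rec.get("name", f"layer{k + 1}")),
                thickness=_parse_thickness(rec["thickness"], where),
                kappa=float(rec["kappa"]),
                rho=float(rec["rho"]),
                metabolic_rate=float(rec["metabolic_rate"]),
                perfusion_term=float(rec["perfusion_term"]),
                dielectric_ref=str(ref),
            )
        )
    return LayerStack(
        name=str(raw.get("name", "custom")),
        layers=tuple(layers),
        h=float(raw["h"]),
        T_air=float(raw["T_air"]),
        T_blood=float(raw["T_blood"]),
        T_body=float(raw["T_body"]),
    )


def write_stack(stack: LayerStack, path: str | Path | None = None) -> str:
    """Serialise a stack to YAML config text (round-trips through read_stack)."""
    doc = {
        "name": stack.name,
        "h": stack.h,
        "T_air": stack.T_air,
        "T_blood": stack.T_blood,
        "T_body": stack.T_body,
        "layers": [
            {
                "name": la.name,
                "thickness": la.thickness,  # metres
                "kappa": la.kappa,
                "rho": la.rho,
                "metabolic_rate": la.metabolic_rate,
                "perfusion_term": la.perfusion_term,
                "dielectric_ref": la.dielectric_ref,
            }
            for la in stack.layers
        ],
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
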