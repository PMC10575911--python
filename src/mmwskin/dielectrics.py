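"""Tissue dielectric dispersion and plane-wave propagation constants.

Complex relative permittivity of biological tissues in the 6–100 GHz band is
modelled with the multi-term Cole-Cole relaxation

    eps(w) = eps_inf + sum_k d_eps_k / (1 + (j w tau_k)^(1 - alpha_k))
             + sigma_s / (j w eps0)

under the e^{+j w t} engineering time convention, so a passive (lossy) tissue
has eps = eps' - j eps'' with eps'' >= 0 and fields decay as e^{-gamma z}
into the tissue.

The packaged database (``data/tissues.yaml``) carries the literature 4-term
Cole-Cole fits for dry skin, infiltrated fat, muscle, cortical bone and grey
matter; users may merge an override table in the same format, including
direct tabulated (eps', sigma) pairs per frequency for tissues with measured
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.constants import c as C_LIGHT
from scipy.constants import epsilon_0 as EPS0
from scipy.constants import mu_0 as MU0

#: Free-space wave impedance, ohms (CODATA-derived, not rounded).
ETA0 = math.sqrt(MU0 / EPS0)

__all__ = [
    "ColeColeModel",
    "TabulatedDielectric",
    "PropagationTriple",
    "ETA0",
    "complex_permittivity",
    "effective_conductivity",
    "propagation_constants",
    "load_tissue_database",
    "VACUUM",
]


@dataclass(frozen=True)
class ColeColeModel:
    """Multi-term Cole-Cole dispersion parameters for one tissue.

    Parameters
    ----------
    eps_inf
        Optical-limit relative permittivity, dimensionless, >= 1.
    terms
        Sequence of ``(delta_eps, tau, alpha)`` relaxation terms with
        ``delta_eps >= 0`` (dimensionless), ``tau > 0`` (s) and broadening
        exponent ``0 <= alpha < 1``.
    sigma_static
        Static ionic conductivity, S/m, >= 0.
    """

    eps_inf: float
    terms: tuple[tuple[float, float, float], ...] = ()
    sigma_static: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_inf < 1.0:
            raise ValueError(f"eps_inf must be >= 1, got {self.eps_inf}")
        if self.sigma_static < 0.0:
            raise ValueError(f"sigma_static must be >= 0, got {self.sigma_static}")
        norm = []
        for k, (de, tau, alpha) in enumerate(self.terms):
            if de < 0.0:
                raise ValueError(f"terms[{k}]: delta_eps must be >= 0, got {de}")
            if tau <= 0.0:
                raise ValueError(f"terms[{k}]: tau must be > 0, got {tau}")
            if not 0.0 <= alpha < 1.0:
                raise ValueError(f"terms[{k}]: alpha must be in [0, 1), got {alpha}")
            norm.append((float(de), float(tau), float(alpha)))
        object.__setattr__(self, "terms", tuple(norm))


@dataclass(frozen=True)
class TabulatedDielectric:
    """Measured dielectric data: (eps', sigma) pairs on a frequency grid.

    Linear interpolation in frequency between tabulated points; evaluation
    outside the tabulated range is rejected. This is the override path for
    tissues whose measured values should replace the Cole-Cole fit.
    """

    frequencies_hz: tuple[float, ...]
    eps_real: tuple[float, ...]
    sigma: tuple[float, ...]

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, float)
        if f.size < 1 or np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies_hz must be positive and strictly increasing")
        if len(self.eps_real) != f.size or len(self.sigma) != f.size:
            raise ValueError("eps_real and sigma must match frequencies_hz in length")
        if min(self.sigma) < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class PropagationTriple:
    """Plane-wave constants of one medium at one frequency.

    alpha : attenuation constant, Np/m (>= 0 in passive media)
    beta  : phase constant, rad/m (> 0 for f > 0)
    eta   : complex intrinsic wave impedance, ohms (Re(eta) > 0)
    """

    alpha: float
    beta: float
    eta: complex

    @property
    def gamma(self) -> complex:
        """Propagation constant gamma = alpha + j beta."""
        return complex(self.alpha, self.beta)


#: Free space / vacuum dielectric model (identity case).
VACUUM = ColeColeModel(eps_inf=1.0, terms=(), sigma_static=0.0)


def _check_frequency(f: float) -> float:
    f = float(f)
    if not f > 0.0:
        raise ValueError(f"frequency must be > 0 Hz, got f={f}")
    return f


def complex_permittivity(model: ColeColeModel | TabulatedDielectric, f: float) -> complex:
    """Complex relative permittivity eps' - j eps'' at frequency ``f`` (Hz)."""
    f = _check_frequency(f)
    w = 2.0 * math.pi * f
    if isinstance(model, TabulatedDielectric):
        fs = np.asarray(model.frequencies_hz)
        if not fs[0] <= f <= fs[-1]:
            raise ValueError(
                f"frequency {f:.4g} Hz outside tabulated range "
                f"[{fs[0]:.4g}, {fs[-1]:.4g}] Hz"
            )
        er = float(np.interp(f, fs, np.asarray(model.eps_real)))
        sig = float(np.interp(f, fs, np.asarray(model.sigma)))
        return complex(er, -sig / (w * EPS0))
    eps = complex(model.eps_inf, 0.0)
    for de, tau, alpha in model.terms:
        eps += de / (1.0 + (1j * w * tau) ** (1.0 - alpha))
    eps += model.sigma_static / (1j * w * EPS0)
    return eps


def effective_conductivity(eps: complex, f: float) -> float:
    """Effective conductivity sigma = w eps0 eps'' (S/m), all loss channels."""
    f = _check_frequency(f)
    return 2.0 * math.pi * f * EPS0 * (-eps.imag)


def propagation_constants(eps: complex, f: float) -> PropagationTriple:
    """Propagation constants of a nonmagnetic medium with permittivity ``eps``.

    gamma = j w sqrt(mu0 eps0 eps) on the branch with Re(gamma) = alpha >= 0,
    eta = sqrt(mu0 / (eps0 eps)) on the branch with Re(eta) > 0. For eps = 1
    the free-space constants are recovered.
    """
    f = _check_frequency(f)
    if eps.imag > 1e-15 * abs(eps):
        raise ValueError(
            f"active medium (eps'' = {-eps.imag:.3g} < 0) not supported"
        )
    w = 2.0 * math.pi * f
    root = np.sqrt(complex(eps))  # principal branch: Re >= 0
    if root.real < 0:
        root = -root
    gamma = 1j * (w / C_LIGHT) * root
    eta = ETA0 / root if root != 0 else complex("inf")
    alpha = gamma.real
    if -1e-12 * abs(gamma) < alpha < 0.0:
        alpha = 0.0  # clip branch-rounding noise for lossless media
    return PropagationTriple(alpha=alpha, beta=gamma.imag, eta=eta)


# ---------------------------------------------------------------------------
# Packaged tissue database
# ---------------------------------------------------------------------------

def _parse_tissue(name: str, rec: Mapping) -> ColeColeModel | TabulatedDielectric:
    kind = rec.get("model", "cole-cole")
    try:
        if kind == "cole-cole":
            return ColeColeModel(
                eps_inf=float(rec["eps_inf"]),
                terms=tuple((float(d), float(t), float(a)) for d, t, a in rec.get("terms", ())),
                sigma_static=float(rec.get("sigma_static", 0.0)),
            )
        if kind == "tabulated":
            return TabulatedDielectric(
                frequencies_hz=tuple(float(x) for x in rec["frequencies_hz"]),
                eps_real=tuple(float(x) for x in rec["eps_real"]),
                sigma=tuple(float(x) for x in rec["sigma"]),
            )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"tissue {name!r}: invalid record ({exc})") from exc
    raise ValueError(f"tissue {name!r}: unknown model type {kind!r}")


def load_tissue_database(
    override: str | Path | Mapping | None = None,
) -> dict[str, ColeColeModel | TabulatedDielectric]:
    """Load the packaged tissue dielectric table, optionally merged with overrides.

    ``override`` may be a mapping or a path to a YAML file in the same format;
    override records replace packaged records of the same tissue name.
    """
    text = resources.files("mmwskin").joinpath("data/tissues.yaml").read_text()
    raw: dict = yaml.safe_load(text)
    if override is not None:
        if isinstance(override, (str, Path)):
            with open(override) as fh:
                extra = yaml.safe_load(fh)
        else:
            extra = dict(override)
        if not isinstance(extra, Mapping):
            raise ValueError("override must be a mapping of tissue records")
        raw.update(extra)
    return {name: _parse_tissue(name, rec) for name, rec in raw.items()}
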