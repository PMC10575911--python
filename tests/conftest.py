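"""Shared fixtures and independent oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mmwskin.dielectrics import (
    ETA0,
    ColeColeModel,
    complex_permittivity,
    propagation_constants,
)
from mmwskin.layer_models import LayerStack, TissueLayer, fixture_stack


@pytest.fixture(scope="session")
def rat_head() -> LayerStack:
    return fixture_stack("rat_head")


@pytest.fixture(scope="session")
def rat_dorsal() -> LayerStack:
    return fixture_stack("rat_dorsal")


@pytest.fixture(scope="session")
def human_forearm() -> LayerStack:
    return fixture_stack("human_forearm")


# ---------------------------------------------------------------------------
# Synthetic dielectric media for contrived stacks
# ---------------------------------------------------------------------------

#: Lossless and lossy synthetic media keyed by dielectric_ref labels.
TEST_TISSUES = {
    "vac": ColeColeModel(eps_inf=1.0),
    "eps4": ColeColeModel(eps_inf=4.0),
    "lossy10": ColeColeModel(eps_inf=10.0, sigma_static=5.0),
    "lossy30": ColeColeModel(eps_inf=30.0, sigma_static=15.0),
    "mild": ColeColeModel(eps_inf=6.0, sigma_static=1.0),
}


def make_stack(specs, *, h=0.5, T_air=23.0, T_blood=37.0, T_body=37.0, name="synthetic"):
    """Build a stack from (thickness_m, kappa, rho, A, B, dielectric_ref) tuples."""
    layers = tuple(
        TissueLayer(
            name=f"L{i + 1}",
            thickness=d,
            kappa=k,
            rho=r,
            metabolic_rate=a,
            perfusion_term=b,
            dielectric_ref=ref,
        )
        for i, (d, k, r, a, b, ref) in enumerate(specs)
    )
    return LayerStack(name=name, layers=layers, h=h, T_air=T_air, T_blood=T_blood, T_body=T_body)


def random_stack(rng: np.random.Generator, n_layers: int | None = None) -> LayerStack:
    """Random 3-5 layer stack over the synthetic media (physically plausible)."""
    n = int(n_layers or rng.integers(3, 6))
    refs = list(TEST_TISSUES)
    specs = []
    for i in range(n):
        specs.append(
            (
                float(rng.uniform(5e-5, 2e-3)),  # 50 um - 2 mm
                float(rng.uniform(0.2, 0.6)),
                float(rng.uniform(900.0, 2000.0)),
                float(rng.uniform(0.0, 12000.0)),
                float(rng.uniform(0.0, 15000.0)) if (i > 0 or rng.random() < 0.3) else 0.0,
                refs[int(rng.integers(1, len(refs)))],  # skip pure vacuum inside tissue
            )
        )
    return make_stack(specs, name="random")


# ---------------------------------------------------------------------------
# Brute-force EM oracle: directly assembled boundary-condition linear system
# ---------------------------------------------------------------------------

def em_brute_force(stack: LayerStack, f: float, tissues):
    """Solve the full interface continuity system for (r, [tau_i], [ups_i]).

    Unknowns: surface reflection r, per-layer forward/backward amplitudes
    (backward amplitude of the terminal semi-infinite layer fixed at 0).
    Independent of the impedance-recursion implementation.
    """
    n = len(stack.layers)
    props = [
        propagation_constants(complex_permittivity(tissues[la.dielectric_ref], f), f)
        for la in stack.layers
    ]
    ds = [la.thickness for la in stack.layers]
    # unknown vector: [r, tau_1, ups_1, ..., tau_{n-1}, ups_{n-1}, tau_n]
    m = 2 * n
    A = np.zeros((m, m), complex)
    b = np.zeros(m, complex)

    def col_tau(i):
        return 1 + 2 * i

    def col_ups(i):
        return 2 + 2 * i  # valid for i < n-1

    # surface: 1 + r = tau_1 + ups_1 ; (1 - r)/eta0 = (tau_1 - ups_1)/eta_1
    A[0, 0] = -1.0
    A[0, col_tau(0)] = 1.0
    b[0] = 1.0
    A[1, 0] = 1.0 / ETA0
    A[1, col_tau(0)] = 1.0 / props[0].eta
    b[1] = 1.0 / ETA0
    if n > 1:
        A[0, col_ups(0)] = 1.0
        A[1, col_ups(0)] = -1.0 / props[0].eta
    row = 2
    for i in range(n - 1):
        gi, gn = props[i].gamma, props[i + 1].eta
        em_, ep = np.exp(-gi * ds[i]), np.exp(gi * ds[i])
        # E continuity
        A[row, col_tau(i)] = em_
        if i < n - 1:
            A[row, col_ups(i)] = ep
        A[row, col_tau(i + 1)] = -1.0
        if i + 1 < n - 1:
            A[row, col_ups(i + 1)] = -1.0
        row += 1
        # H continuity
        A[row, col_tau(i)] = em_ / props[i].eta
        A[row, col_ups(i)] = -ep / props[i].eta
        A[row, col_tau(i + 1)] = -1.0 / props[i + 1].eta
        if i + 1 < n - 1:
            A[row, col_ups(i + 1)] = 1.0 / props[i + 1].eta
        row += 1
    x = np.linalg.solve(A, b)
    r = x[0]
    taus = [x[col_tau(i)] for i in range(n)]
    upss = [x[col_ups(i)] for i in range(n - 1)] + [0j]
    return r, taus, upss
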