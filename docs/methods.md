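# Methods

## Model overview

`mmwskin` treats the exposed body part as a one-dimensional stack of
homogeneous tissue slabs, exposure side first, with depth `z` increasing
into the body from the air/skin interface at `z = 0`. Two coupled problems
are solved on this geometry:

1. **Electromagnetic**: a normal-incidence plane wave from air, solved by
   impedance-transformation recursion through the layers (equivalent to
   the transfer-matrix method), yielding per-layer forward/backward
   complex amplitudes, the SAR depth profile, the surface absorbed power
   density (APD) and the transmittance `1 − |r|²`.
2. **Thermal**: the steady-state Pennes bioheat equation per layer,

   `κᵢ T″ + ρᵢ SARᵢ(z) + Aᵢ − Bᵢ (Tᵢ − T_blood) = 0`,

   with a Robin (convective) surface condition against air and a Dirichlet
   core-temperature clamp at the stack bottom, solved in closed form. The
   reported temperature elevation ΔT is the difference between the exposed
   and unexposed solutions of the identical assembly, so baseline
   metabolic heating cancels exactly.

## Electromagnetic formulation

- Time convention `e^{+jωt}`; fields decay as `e^{−γz}` into tissue with
  `γ = α + jβ`, `Re(γ) ≥ 0`, `Re(η) > 0`. Nonmagnetic media, normal
  incidence only.
- Tissue permittivity follows multi-term Cole-Cole dispersion
  `ε̂(ω) = ε∞ + Σ Δεₖ/(1 + (jωτₖ)^{1−αₖ}) + σₛ/(jωε₀)`; the effective
  conductivity `σ = ωε₀ε″` collects all loss channels. The packaged
  database holds the literature 4-term fits (Gabriel-family) for dry skin,
  infiltrated fat, muscle, cortical bone and grey matter. dWAT uses the
  fat dispersion and panniculus carnosus the muscle dispersion, matching
  their anatomical identity (their thermal parameters already follow fat
  and muscle respectively). Users may override any tissue with their own
  Cole-Cole parameters or tabulated (ε′, σ) measurements; all downstream
  solvers accept the override database.
- The deepest layer is treated as **semi-infinite** (no reflection from
  the model bottom). At ≥30 GHz this choice is immaterial (penetration
  never reaches the stack bottom); at 6 GHz it is material at the few
  percent level. A numerical comparison of semi-infinite, air-backed and
  conductor-backed terminations moves the rat-head 6 GHz transmittance
  only within 0.62–0.67 — the choice of skin dielectric data dominates
  (see Limitations).
- Amplitudes are stored for a unit incident field; the power scaling
  `|E_inc|² = 2pη₀` enters only in SAR and Poynting evaluations. Backward
  waves are represented through the bottom-interface reflection ratio so
  growing exponentials are always evaluated as `e^{−γ(2d−ζ)}`; thick lossy
  layers therefore cannot overflow.
- Energy bookkeeping is verified three ways: surface Poynting flux versus
  `p(1 − |r|²)` (≤1e−9 relative), adaptive quadrature of ρ·SAR versus the
  APD minus the flux leaking past the stack bottom (≤1e−6), and the
  recursion versus a directly assembled full boundary-condition linear
  system on random stacks (≤1e−10).

## Analytic bioheat solution

Per layer, with local depth ζ = z − zᵢ and layer-top unknowns T(zᵢ),
T′(zᵢ):

- homogeneous part: linear in ζ for B = 0; for B > 0,
  cosh/sinh in `m ζ` with `m = √(B/κ)` around the perfusion equilibrium
  `T_blood + A/B` (which also carries the metabolic heat); for B = 0 the
  metabolic term contributes the quadratic particular `−Aζ²/(2κ)`.
- electromagnetic particular term: `S` solves
  `κS″ − B·S + ρ·SAR = 0` with `S(zᵢ) = S′(zᵢ) = 0`. Since
  `ρ·SAR(ζ) = σpη₀(|τ|²e^{−2αζ} + |υ|²e^{+2αζ} + X cos 2βζ + Y sin 2βζ)`
  with `X = 2Re(τῡ)`, `Y = 2Im(τῡ)`, each basis term is convolved exactly
  with the zero-state kernel of `d²/dζ² − m²`. Near the degenerate
  denominator `4α²κ = B` the evaluation switches to the analytic
  L'Hôpital limit at relative distance 1e−6 (the oscillatory denominator
  `4β²κ + B` can never vanish). Correctness is enforced by a
  finite-difference residual test: `κS″ − BS + ρSAR` stays below 1e−6 of
  each layer's peak volumetric heating.

The 2N layer-top unknowns satisfy one Robin equation, 2(N−1) interface
temperature/flux continuity equations and one core Dirichlet equation; the
dense 2N×2N system is solved directly (condition numbers are ~10²–10³ for
the packaged stacks and are reported at INFO logging). Interface and
boundary residuals of the solved field are at machine precision (≤1e−9).

## Finite-difference verification solver

An independent conservative node-centred scheme on an interface-aligned
grid: every layer interface is a shared node, half-cell flux balances use
the interval conductivities (the harmonic-mean construction made exact by
interface alignment), and sources are sampled pointwise from the correct
side of each interface. Second-order convergence is confirmed by a
Richardson study; on 1 µm-resolved grids the closed-form and FD ΔT
profiles agree to ~1e−6 of the peak for the packaged stacks — far inside
the 0.5% verification band used in the tests — and the same agreement
holds across randomised 3–5 layer stacks spanning the 6–100 GHz band.

## Parameters and defaults

| Parameter | Default | Units | Notes |
|---|---|---|---|
| h (surface heat transfer) | 0.5 | W/(m²·°C) | still-air convective exchange used in rodent analyses; nearly adiabatic, so almost all absorbed power flows core-ward |
| T_air | 23 | °C | ambient |
| T_blood, T_body | 37, 37 | °C | arterial and core clamp |
| IPD p | 1000 | W/m² | normalisation only: ΔT and APD are exactly linear in p, so transmittance and heating factor are p-invariant (asserted at every metrics call) |
| Frequency band | 6–100 | GHz | fixture-validated; the solver accepts (1, 300] GHz, the CLI requires `--allow-extrapolation` outside 6–100 |
| Perfusion sweep grid | 13 log-spaced points over 300–36300 | W/(m³·°C) | typical rat perfusion range; sensitivity spans are reported as (max−min)/max over the sweep |

Layer tables (thickness; κ; ρ; A; B) are packaged for the rat head,
rat dorsal and human forearm stacks, with a frozen checksum test guarding
silent edits. The rat six-column thermal-parameter table resolves the
perfusion row as B = (0, 1160, 5629, 9380, 12317/3801, 6800/12317) for
head/dorsal deep layers — the unique segmentation consistent with the
slash convention of the κ, ρ, A rows. The human forearm stack fixes
thicknesses (102, 1080, 3890, 23250 µm) and conductivities
(0.42, 0.42, 0.25, 0.50); its ρ, A and B reuse the corresponding rat
tissue analogues and are configurable — absolute human ΔT values should
therefore be treated as indicative only.

"Surface ΔT" always means ΔT at z = 0 exactly (not an epidermal average),
matching the depth at which the APD is defined, so the heating-factor
quotient compares like with like.

## Synthetic thickness sampling

The four histological skin layers carry measurement scatter (mean ± SD
over animals). `sample_stack` draws per-layer thicknesses from a normal
distribution truncated below at mean − 3·SD and floored at 1 µm,
deterministic per seed; CT-derived deep layers stay fixed. This emulates
between-animal thickness variability only — it does not model within-section
correlation between layers, thickness-dependent dielectric changes, or
animal-to-animal variation in thermal parameters. Passing sampler tests
therefore demonstrate correct uncertainty propagation through the solvers,
not a validated population model of rat skin.

## Numerical choices

- Degenerate-kernel switch at relative distance 1e−6 (above); continuity
  across the switch is tested to 1e−5.
- EM fields guarded against overflow by the scaled backward-wave
  representation; validated with a 50 cm lossy-layer stress test.
- FD grids require ≥4 interior nodes in the thinnest layer and cap nodes
  per layer at 4000 (micrometre resolution in skin, coarser in thick deep
  layers, which the convergence study shows is ample).
- Temperatures are handled in °C throughout; the equations are affine in
  T so no Kelvin conversion is needed.
- Tie-breaks: a depth falling exactly on an interface belongs to the
  deeper layer (relevant for SAR, which is discontinuous there).

## Design decisions taken where the design was open

- **Skin dielectric source.** Measured rodent-skin permittivity data are
  not redistributable here, so the packaged default is the literature
  dry-skin Cole-Cole fit, with a first-class override path for measured
  (ε′, σ) tables. This choice dominates the quantities that depend on
  6 GHz penetration depth and on the exact air/skin contrast: with the
  packaged fits the rat-head 6 GHz transmittance is 0.64 and analyses
  using measured (wetter, lossier) skin data report substantially lower
  values; at ≥30 GHz the effect shrinks to a few percent. The package
  therefore separates solver fidelity (pinned by the FD, Fresnel,
  conservation and brute-force oracles) from input fidelity (delegated to
  the dielectric database the user selects).
- **EM termination** semi-infinite (above).
- **Standing-wave coefficients** X, Y derived by expanding
  `|τe^{−γζ} + υe^{+γζ}|²` under the chosen conventions and verified
  structurally by the SAR-integral conservation property.

## Known limitations

- One-dimensional plane-wave model: no oblique incidence, polarisation,
  near-field antenna sources or 3-D heat spreading; no transient heating
  or thermoregulatory feedback (B is temperature-independent).
- Results at 6 GHz are sensitive to the skin dielectric database and, to a
  lesser degree, the termination convention; transmittance versus
  frequency under the packaged fits is smooth but not monotone (a shallow
  minimum near 30 GHz), and the multilayer-to-Fresnel collapse at 100 GHz
  is complete to ~1% only.
- Increasing any single layer's perfusion term monotonically decreases the
  surface ΔT in this model, for every layer of both rat stacks — deep
  perfusion always acts as a heat sink here; no parameter range was found
  in which a deep layer's perfusion raises the surface elevation.
- The metabolic rates and perfusion terms packaged for the rat stacks put
  the brain perfusion equilibrium `T_blood + A/B ≈ 38.6 °C` above the
  core clamp, so the unexposed baseline surface sits slightly above 37 °C;
  the classical air/core maximum principle applies only with metabolism
  switched off (both solvers agree on this behaviour).
- Human-stack thermal parameters beyond thickness and conductivity are rat
  analogues by default; human heating factors computed from the packaged
  forearm stack are indicative, not validated.
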