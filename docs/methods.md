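# Methods

This note documents the models implemented in `mnph`, the assumptions
behind them, the defaults and why they were chosen, and what the
synthetic-data studies do and do not demonstrate.

## Dipolar coupling and attraction zones

Particles are uniformly magnetized spheres of diameter `d0` carrying the
saturation moment `μs = M_s,m·ρ_p·(π/6)d0³`, treated as point dipoles
pinned along the applied-field axis (moments are assumed saturated; the
40 mT alignment-field magnitude therefore does not enter the dynamics).
The strength of dipolar interactions relative to thermal motion is the
coupling parameter

    Γ = μ0·μs² / (2π·d0³·kB·T),

i.e. the magnitude of the head-to-tail contact pair energy over `kB·T`.
With the default populations: Γ ≈ 192 for 40 nm magnetite
(ρ = 5180 kg/m³, M_s = 92 A·m²/kg) and Γ ≈ 0.32 for 10 nm. The 10 nm
mass magnetization (30 A·m²/kg) is an assumption — no measured value is
available for the small co-precipitated particles — chosen to encode the
qualitative weak-coupling regime `E_mag/kBT ≪ 1`.

A chain of `s` particles attracts a co-aligned test particle on its axis
at distance `r` beyond the tip with

    E(s, r) = −(μ0 μs²/2π) Σ_{n=0}^{s−1} (r + n·d0)^{−3},

and the attraction-zone radius `r_a(s)` is the root of `E(s, r) = −kB·T`
(Brent's method on the bracket `[Γ^{1/3}d0, (sΓ)^{1/3}d0]`; the s = 1
closed form is `r_a = Γ^{1/3}d0`). `r_a(s)` grows with `s` and saturates
(≈ 5.8·d0 at s = 1 up to ≈ 10·d0 for long chains with the 40 nm
defaults). For Γ ≤ 1 no zone exists and the simulator treats the
population as non-aggregating.

## Brownian dynamics with on-the-fly coarse-graining

Simulation objects are rigid segments of `s ≥ 1` particles pinned to the
field (z) axis; rotational diffusion and torque-driven rotation are not
modelled. Translational diffusion uses Stokes–Einstein for singletons,
`D = kB·T/(3πη·d0)`, and slender-body rod forms for chains,

    D_par  = kB·T (ln s − 0.207) / (2π η s d0),
    D_perp = kB·T (ln s + 0.839) / (4π η s d0),

whose ratio approaches the free-draining limit of 2. The constant end
corrections make `D_par` dip at `s = 2` before its asymptotic `ln s / s`
decay (the form's small-aspect-ratio artifact); the effect on the
kinetics is negligible and no ad-hoc smoothing is applied.

Each step draws independent Gaussian displacements with per-axis
variance `2DΔt` (axial/lateral `D` for chains), in stable object-id
order from a single seeded generator, making trajectories bit-identical
under a fixed (config, seed) pair. The step is clamped so the RMS
singleton displacement stays below `0.1·d0`, which resolves the
attraction zones (`r_a ≥ d0`) without tunnelling. A move that would
create a hard-core overlap between two objects whose zones are *not* met
is rejected for the later-id object that step; zone-satisfying contacts
are left for the merge pass. Boundaries are periodic by default
(minimum-image distances), with a reflecting option.

After each diffusion step, every pair whose nearest tip-to-tip distance
falls below `r_a` of the longer partner merges: the new object has
length `s1 + s2`, sits at the length-weighted centre of mass, and the
pass repeats (closest pairs first) until no pair qualifies. Lateral
bundling is not modelled — laterally captured material lengthens a chain
rather than thickening it — and chains never fragment, so the mean
length `⟨s⟩ = N/objects` is nondecreasing by construction.

## Time scale and study durations

The aggregation kinetics scale linearly with the medium viscosity
through `D`. The viscosity of the hot agarose solution during alignment
is not known, so presets default to water at 300 K (1.0 mPa·s, with a
0.355 mPa·s 80 °C variant available). At water viscosity the
strong-coupling population at 1–4 mg/mL passes through its fast growth
stage within ~10 μs of simulated time and plateaus within a few
milliseconds; the same dimensionless kinetics at gel-like viscosities
would stretch over the hundreds of seconds that alignment protocols
use. Preset duration is 5 ms.

Two simulation studies are built on this:

* **Regime dichotomy** — 200 particles at the 4 mg/mL number density
  (box shrunk to 40.7·d0 to preserve density), 1 ms, 10 seeds: the
  40 nm population reaches `⟨s⟩ ≫ 3`; the 10 nm population stays at
  `⟨s⟩ = 1` exactly (no zones exist).
* **Concentration ordering** — 1 vs 4 mg/mL number densities at half
  linear scale (190 vs 760 particles in a 63.5·d0 box), compared at
  10 μs over 10 seeds: the denser system grows longer chains and its
  chains sit laterally closer. The comparison time is the end of the
  fast growth stage — the structure a gelling matrix would freeze in.
  This model has no gelation arrest and no chain width: if left to run,
  end-to-end capture keeps consuming chains at a rate set by the zone
  radius rather than by particle count, the surviving chain number
  becomes concentration-independent, and the lateral-spacing contrast
  fades. The spacing trend is therefore a statement about the growth
  stage, not the infinite-time limit of this model.

## Hysteresis losses and SLP prediction

Heating is attributed to hysteresis losses of thermally activated
single-domain particles (linear-response/susceptibility heating and
Brownian rotation losses are out of scope). The coercivity law is

    Hc(T, f) = κ·H_K·max(0, 1 − [kB·T·ln(f0/f) / (K·V)]^{3/4}),

with `H_K = 2K/(μ0·M_s,v)`, attempt frequency `f0 = 1e10 Hz`
(configurable), and `κ = 0.48` for randomly oriented easy axes or `1.0`
for aligned ones. The 3/4 exponent and κ values are the standard
finite-temperature sweep-rate treatment of randomly-oriented
Stoner–Wohlfarth particles; they are stated assumptions, not fitted
values. With `K = 11 kJ/m³` (bulk magnetite) the 40 nm population gives
`μ0·Hc ≈ 18 mT` at 765 kHz and 300 K — hysteretic but switchable by the
30 mT drive — while the 10 nm population is superparamagnetic
(`Hc = 0`) at both drive frequencies.

Loop area per cycle uses the rectangular-loop estimate
`A_v = 4·α·μ0·Hc·M_v`, zero when the drive amplitude cannot reach `Hc`
(minor-loop rule). The magnetization entering the area is, by default,
the 30 mT minor-loop value of the sample (18 A·m²/kg chain, 8 A·m²/kg
random) rather than the intrinsic saturation value, since the operating
loop at the hyperthermia amplitude is a minor loop. The chain/random
comparison applies one shared coercivity to both configurations (the
random-orientation κ by default): the configurations are distinguished
through α and the minor-loop magnetization, giving the enhancement
(0.75·18)/(0.5·8) = 3.375. Applying the aligned κ = 1.0 to the chain
row instead would push its coercivity above the 30 mT drive with these
defaults and zero the loop by the minor-loop rule — one more reason the
shared-Hc convention is the appropriate reading of the comparison.

The model SLP is `A_m·f` (W/g with `A_m = A_v/ρ_p` in J/kg), and the
volumetric source for the thermal models is `Q = A_v·f·ω` with
`ω = c/ρ_p` the particle volume fraction (≈ 7.7e-4 at 4 mg/mL).

A dipolar shape-anisotropy field for chains,
`ΔH_dip = μs/(2π(g·d0)³)·Σ(s−n)/(s·n³)` (saturating at the ζ(3) lattice
sum), is provided for sensitivity studies only; it never feeds the
coercivity law unless wired in explicitly.

## Thermal models

The vial-scale 3D heat-transfer problem is replaced by two analytically
checkable reductions:

* **Lumped energy balance** `m_f·c·dT/dt = Q·V_s − λ(T − T_amb)`,
  integrated adaptively (rtol 1e-10) and matching its closed-form
  exponential to below a microkelvin. Defaults describe a 1 mL aqueous
  sample (m_f = 1 g, c = 4186 J/(kg·K)) with λ = 8.372e-3 W/K, i.e. a
  time constant τ = m_f·c/λ = 500 s typical of a loosely insulated
  vial; λ can also be fitted from a recorded cooling phase (log-linear
  fit).
* **1D spherical conduction** `ρC_p ∂T/∂t = k∇²T + Q·1(r ≤ R)`, explicit
  finite volumes on node-centred shells, with either a convective
  boundary whose film coefficient derives from the same λ
  (`h = λ/4πR²`) or a fixed-temperature boundary. A user step above the
  explicit stability limit is refused with the required Δt. The steady
  Dirichlet profile matches the parabola `T_b + Q(R²−r²)/6k` to better
  than 0.1% at 60 shells, and the volume-averaged trace converges to
  the lumped curve as k grows.

Temperature traces are sampled at 0.4 s, like the fibre-optic probe of
a calorimetry rig, and labelled with contiguous heating/cooling phases.

## SLP extraction

The initial-slope method fits an ordinary least-squares line to the
first seconds of the heating phase; `SLP = c·(m_f/m_MNPs)·dT/dt`. The
default window is 30 s (the protocol only specifies "initial"); a
window `w` on a lumped trace biases the slope by a factor
`≈ 1 − w/(2τ)`, so recovery studies against known ground truth use a
10 s window (≈ 1% bias at τ = 500 s). Box–Lucas-style exponential
fitting is deliberately not the default: the quantity defined by the
measurement protocol is a fitted initial gradient. Batch processing
carries per-row errors (a bad trace fails its row, not the batch) and
reports chain/random SLP ratios per (concentration, frequency)
condition.

## What the synthetic studies show — and what they do not

The generators emulate: the two coupling regimes, the published box
geometry and particle counts (380/760/1520 in an 80·d0 box for
1/2/4 mg/mL), the field parameters (40 mT static; 30 mT AC at 210/765
kHz), and probe noise (Gaussian, σ = 0.05 K) on lumped-model traces.
They do not emulate: polydispersity, chain width/bundling, gelation
arrest and gel elasticity, field inhomogeneity, probe-position effects,
or non-hysteretic heating channels. Passing tests therefore demonstrate
internal consistency of the model chain — formation kinetics in the
right coupling regimes, loss-model arithmetic, thermal solutions
against closed forms, and unbiased SLP recovery from noisy traces — not
agreement with any particular measured SLP magnitude, which depends on
sample-specific quantities (true Hc, loop shape, losses to the
environment) that only calorimetry can fix.

## Numerical choices

* Attraction-radius roots: Brent, rtol 1e-14, residuals verified to
  1e-6 relative for s = 1..50.
* Merge tie-break: qualifying pairs processed in ascending tip-distance
  order with re-scan after each merge (incremental pair-matrix update).
* Degenerate inputs: zero magnetization gives Γ = 0 and zero losses;
  `Γ ≤ 1` raises a typed no-aggregation signal; drive below coercivity
  gives zero loop area; packing fractions above 0.3 are refused.
* Problem sizes in the shipped studies (scaled-down replicates at
  preserved number density): 200 particles / 1 ms for the regime
  dichotomy, 190 vs 760 particles / 10 μs for the concentration
  comparison, 10⁴ steps for the diffusion oracles, 100 replicates for
  SLP recovery.
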