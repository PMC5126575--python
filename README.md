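# mnph — nanoparticle chain assembly and magnetic hyperthermia heating

`mnph` models how magnetite nanoparticles (MNPs) dispersed in a gel
matrix assemble into linear chains under a static magnetic field, and
how that arrangement changes their heating efficiency under an AC
hyperthermia drive. It is aimed at people working on magnetic particle
hyperthermia (MPH) who want a desk-scale, mechanistic account of the
observation that field-aligned chain samples heat roughly twice as
efficiently as randomly dispersed ones.

The package covers four connected stages:

1. **Chain formation** (`mnph.chain_sim`) — an on-the-fly coarse-grained
   Brownian dynamics simulation. Each diffusing object is a single
   particle or a field-aligned chain of `s` particles with slender-body
   anisotropic diffusion (`D_par/D_perp → 2`). Dipole–dipole attraction
   is coarse-grained into polar *attraction zones* of radius `r_a(s)`,
   defined by `E_mag(s, r_a) = −k_B·T`; any object entering a zone
   aggregates instantly, and the merged chain replaces its parents.
   Whether chains form at all is governed by the coupling parameter

   `Γ = μ0·μs² / (2π·d0³·k_B·T)`,

   the head-to-tail contact dipole energy over the thermal energy:
   `Γ ≈ 190` for 40 nm magnetite (chains form), `Γ < 1` for 10 nm
   (no chains).

2. **Hysteresis losses** (`mnph.magnetics`) — a finite-temperature
   Stoner–Wohlfarth model. The coercivity follows the thermally
   activated sweep-rate law
   `Hc(T,f) = κ·H_K·(1 − [k_B·T·ln(f0/f)/(K·V)]^{3/4})`, and the loop
   area per cycle is the rectangular-loop estimate
   `A = 4·α·μ0·Hc·M`, with squareness `α = 0.5` for random easy axes
   and `0.75` for aligned chains, and `M` the 30 mT minor-loop
   magnetization (18 vs 8 A·m²/kg for chain vs random samples).

3. **Heat generation and transfer** (`mnph.heating`) — the volumetric
   source `Q = A·f·ω` (ω the particle volume fraction) drives either a
   lumped energy balance `m_f·c·dT/dt = Q·V_s − λ(T − T_amb)` or a 1D
   spherical conduction model, producing heating/cooling `T(t)` cycles
   sampled like a fibre-optic probe.

4. **Calorimetry** (`mnph.calorimetry`) — specific loss power from the
   initial-slope method, `SLP = c·(m_f/m_MNPs)·dT/dt` in W per gram of
   magnetic material, with batch processing and chain/random ratio
   tables.

`mnph.synthetic_data` bundles the study conditions as named presets
(40 nm and 10 nm populations, 1–4 mg/mL in a cubic box of side 80
diameters, 40 mT alignment field, 30 mT AC drive at 210/765 kHz) and
generates noisy ground-truth calorimetry traces.

## Worked example

```python
from mnph import loss_comparison, make_preset, run_simulation, scale_particle_count
from dataclasses import replace

pre = make_preset("paper_40nm_4mgml")          # 1520 particles, box 80·d0

# predicted heating efficiency, chains vs random dispersion
report = loss_comparison(pre.particle, pre.environment, pre.field)
print(report[["label", "alpha", "A_v_Jm3", "SLP_Wg"]].to_string(index=False))

# scaled-down chain-formation run (200 particles at the same density)
small = scale_particle_count(pre, 200)
sim = replace(small.simulation, total_time_s=1e-3, seed=1)
res = run_simulation(sim, small.particle, small.environment)
print(f"final mean chain length: {res.final_state.mean_length:.1f}")
```

prints

```
 label  alpha     A_v_Jm3     SLP_Wg
 chain   0.75 5042.707855 744.724229
random   0.50 1494.135661 220.659031
final mean chain length: 33.3
```

The loss model predicts an SLP of 745 W/g for the aligned chain sample
against 221 W/g for the random one at 30 mT / 765 kHz — an enhancement
of 3.375 = (0.75·18)/(0.5·8), consistent with the roughly twofold
heating-efficiency gain observed calorimetrically for aligned samples.
The simulation shows the strong-coupling 40 nm population condensing
into field-aligned chains (mean length ≈ 33 particles here), while the
same run with the `paper_10nm` preset stays fully dispersed.

The same pipeline is available from the shell:

```bash
mnph simulate-chains --preset paper_40nm_4mgml --n-particles 200 --duration 1e-3 --seed 1 --out run/
mnph predict-slp --out slp/
mnph simulate-heating --out cycles/
mnph fit-slp --metadata cycles/metadata.csv --out fits/
```

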