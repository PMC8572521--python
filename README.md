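# phagestrat

Chemostat simulations of bacterial coexistence under three bacteriophage
infection strategies — purely lytic, **Piggyback-the-Winner** (PtW) and
**Piggyback-the-Loser** (PtL) — with viral-shunt nutrient recycling and
sinusoidally fluctuating resource supply, plus the analysis layer
(bifurcation scans, persistence classification, 2-D fluctuation sweeps) that
turns trajectories into coexistence maps.

The package is aimed at microbial ecologists and theoreticians studying how
phage life-cycle strategies shape bacterial diversity: why can a fast- and a
slow-growing bacterium share a single limiting nutrient at all, and which
phage strategies keep that coexistence alive when the resource supply
fluctuates?

## Model

Two bacterial species (k = 1 fast, k = 2 slow), their infected counterparts,
free phages and one nutrient pool, all as normalized biovolume densities:

```
G_k(N) = x y_k N / (N + N_H)                    (Type-2 growth)

dB_k/dt = G_k(N) B_k − x B_k − i B_k P_k
dI_k/dt = (1+c) i B_k P_k + [g_k] G_k(N) I_k − x I_k − s_k I_k
dP_k/dt = n s_k I_k − c i B_k P_k − d P_k
dN/dt   = D_F(t) (N_0 − N) − Σ_k G_k(N) B_k − Σ_k [g_k] G_k(N) I_k
          + Σ_k (1−n) s_k I_k                   (viral shunt)

D_F(t)  = a D sin(2π t / T) + D                 (resource forcing, a < 1)
```

The phage strategy enters through the lysis rate `s_k` of infected cells:

| strategy | lysis rate | behaviour |
|---|---|---|
| lytic | `s`                                  | constant |
| PtL   | `s (B_k+I_k)² / ((B_k+I_k)² + SH)`   | lysogeny when hosts are **rare** |
| PtW   | `s / (((B_k+I_k) r)² + H)`           | lysogeny when hosts **abound** |

Infected cells grow (and consume nutrient) only while their current lysis
rate is at or below the switching point `s_switch = 0.0033 h⁻¹` — the
lysogenic regime (`[g_k]` above).  Inverting the lysis laws at the switching
point gives the switch densities 0.2010076 (PtL) and 19.89975 (PtW)
normalized, i.e. 2.01·10⁶ and 1.99·10⁸ particles mL⁻¹.

Trajectories are integrated with an adaptive Cash–Karp 5(4) embedded
Runge–Kutta stepper (numba-compiled), and classified on the post-transient
window into a 0–4 persistence code (each bacterium, and each phage +
infected-host pair, counts as one community state).

## Worked example

```python
from phagestrat import (ModelParams, SimulationSpec, StrategyKind,
                        classify_persistence, final_window, run_simulation)

params = ModelParams()                      # tabulated defaults, N0 = 2
spec = SimulationSpec(strategy=StrategyKind.PTL, params=params,
                      output_step=2.0)      # 5 years, last 20% analyzed
traj = run_simulation(spec)

state = classify_persistence(traj)
print("persistence code:", state.code)
print("survived:", state.survived)
win = final_window(traj)
for name in ("B1", "B2", "I1", "P1", "N"):
    print(f"{name}: window mean {win.series(name).mean():.4f}")
```

prints

```
persistence code: 4
survived: {'B1': True, 'infection1': True, 'B2': True, 'infection2': True}
B1: window mean 1.0094
B2: window mean 1.0472
I1: window mean 0.3542
P1: window mean 0.0084
N: window mean 0.7177
```

— under PtL at a supply concentration of 2 both bacteria, the infected
compartments and both phages settle on a steady four-state coexistence
(code 4), with the slow grower slightly *above* the fast grower because the
phage load falls more heavily on the better competitor.  Running the same
scenario with `StrategyKind.NONE` instead gives code 1: without phages the
slow grower is competitively excluded.

The same pipelines are scriptable from the shell via bundled presets named
after the study's scenarios:

```bash
phagestrat presets                          # list the 31 bundled scenarios
phagestrat run fig3_ptl --out out/          # time series CSV at N0 = 2
phagestrat run fig4_ptw_fluct --out out/    # bifurcation scan, a=0.5, T=7 d
phagestrat run fig5_lytic_amplitude --out out/   # 2-D persistence sweep
```

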