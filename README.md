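# mitoclock

Clocks and switches of the eukaryotic cell-cycle engine: a toolkit for
simulating and analysing ODE models of mitotic control, from the classic
negative-feedback MPF oscillator of the early frog embryo to a
size-controlled division cycle of fission yeast.

## Who this is for

Systems biologists and dynamical-systems modellers who want runnable,
inspectable versions of the canonical cell-cycle control circuits —
complete with the analysis machinery (limit cycles, pseudo-nullclines,
bifurcation diagrams) used to reason about them — without driving an
external continuation tool.

## The models

Four nested models, each a mechanistic refinement of the previous:

1. **Negative-feedback oscillator** — MPF (CycB:Cdk1) activates an
   intermediary kinase, which activates the APC/C ubiquitin ligase, which
   degrades cyclin B and thereby MPF:

   d[MPF]/dt = k_sy − (k_de1 + k_de2·[APC_P])·[MPF]

   with zero-order-ultrasensitive (Michaelis–Menten) activation terms for
   the kinase and the APC/C. The delay through the intermediary kinase makes
   this a limit-cycle oscillator (period ≈ 46 min).

2. **Greatwall–ENSA–B55 pathway** — the delay is resolved mechanistically:
   MPF activates Greatwall kinase, Greatwall phosphorylates ENSA, and
   phospho-ENSA sequesters the phosphatase PP2A:B55, which opposes APC/C
   phosphorylation (a coherent feed-forward loop). The sequestered complex
   is closed algebraically by the total quasi-steady-state approximation

   [ENSA_P:B55] = 2·E·B / (Σ + √(Σ² − 4·E·B)),  Σ = E + B + K_m,

   and cyclin degradation is driven by the polyubiquitinated fraction of the
   CycB pool, f(r) = r⁴(1−r)/(1−r⁵), the top-state occupancy of an
   ordered-distributive ubiquitination chain (r = [APC_P:C20]/[deUb]).

3. **Bistable APC/C switch** — PP2A:B55 also dephosphorylates Greatwall,
   closing a double-negative feedback loop; APC/C activity becomes a
   bistable (S-shaped) function of MPF and the oscillations turn into
   relaxation oscillations.

4. **Dual bistability** — Wee1 kinase and Cdc25 phosphatase control
   inhibitory tyrosine phosphorylation of Cdk1, and both are nine-state
   multisite substrates of MPF with geometric state occupancies
   (Wee1 active fraction (1−s⁵)/(1−s⁹), Cdc25 active fraction
   s⁵(1−s⁴)/(1−s⁹), s = [MPF]/[CAP]). Total cyclin CycB_T and active MPF
   separate, and MPF becomes a hysteretic function of CycB_T.

Checkpoints are parameter changes of model 4 that replace the limit cycle by
a stable steady state: G2 arrest (Cdc25_tot ↓), spindle-assembly-checkpoint
arrest (Cdc20_tot ↓) and G1 arrest (Cdh1-mediated degradation, k_de3 ↑).
The size-control model couples model 4 to cell growth via
[Cdc25_tot] = V(t), dV/dt = μV, with V → V/2 when MPF falls through the
mitotic-exit threshold.

The analysis layer provides stiff integration, limit-cycle measurement,
arrest detection, steady-state search, native pseudo-arclength continuation
with fold and Hopf detection, SNIC classification by period divergence, and
pseudo-nullclines (steady-state branches of a reduced system with one
variable clamped).

## Worked example

Measure the limit cycle of the negative-feedback oscillator and the size
homeostasis of the growth-coupled cycle:

```python
import numpy as np
from mitoclock import (find_limit_cycle, get_model, interdivision_stats,
                       simulate_size_control, table1_parameters)

m1 = get_model("model1")
lc = find_limit_cycle(m1, table1_parameters(1), np.zeros(3))
print(f"period = {lc.period:.2f} min, MPF in "
      f"[{lc.minima['MPF']:.3f}, {lc.maxima['MPF']:.3f}]")

m4 = get_model("model4")
trace, traj = simulate_size_control(m4, table1_parameters(4),
                                    mu=0.005, v0=1.0, n_cycles=12)
st = interdivision_stats(trace, discard=5)
print(f"interdivision time = {st.mean_cycle_min:.1f} min, "
      f"division size = {st.mean_division_size:.3f}")
```

prints

```
period = 45.75 min, MPF in [0.180, 0.603]
interdivision time = 138.5 min, division size = 0.639
```

The period is the mean spacing of successive MPF maxima after transient
removal; the interdivision time equals the mass doubling time ln 2/μ
(139 min at μ = 0.005 min⁻¹) — the signature of size control: cycle
duration is set by growth, not by the oscillator's free-running period.
Division size and birth size converge to fixed points regardless of the
initial size.

The same analyses are available from the shell:

```sh
mitoclock list-scenarios
mitoclock cycle --scenario fig2 --out out/
mitoclock nullcline --scenario fig5d --out out/
mitoclock sizecycle --scenario size_cycle --out out/
```

Each command writes a tidy CSV plus a JSON metadata sidecar (parameter
provenance, tolerances, version); outputs are seed-free deterministic.

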