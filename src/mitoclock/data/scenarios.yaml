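# Named figure-level scenarios: model, parameter overrides, analysis to run
# and the projection plane of the corresponding phase-plane plot.  Initial
# states default to the all-low state (everything zero); limit-cycle results
# are initial-condition independent after transient removal.
fig2:
  model: model1
  analysis: cycle
  plane: [MPF, APCP]
  description: >
    Negative-feedback mitotic oscillator of the early frog embryo; limit
    cycle of MPF, intermediary kinase and APC/C (period about 46 min).
  anchor: fig2 / text on model 1

fig3:
  model: model2
  analysis: cycle
  plane: [MPF, APCPC20]
  nullclines:
    - {clamp: APCPC20, response: MPF}
    - {clamp: MPF, response: APCPC20}
  description: >
    Greatwall-ENSA-B55 feed-forward loop; soft, nearly sinusoidal
    oscillations; both pseudo-nullclines monotone (no bistability).
  anchor: fig3 caption (Km = 0.0008, deUb = 0.75)

fig4:
  model: model3
  analysis: cycle
  plane: [MPF, APCPC20]
  nullclines:
    - {clamp: APCPC20, response: MPF}
    - {clamp: MPF, response: APCPC20}
  description: >
    B55 dephosphorylates Greatwall: APC/C activity becomes a bistable
    function of MPF (S-shaped pseudo-nullcline) and the oscillations turn
    into relaxation (hard) oscillations.
  anchor: fig4 caption (Km = 0.0026, deUb = 0.5)

fig5:
  model: model4
  analysis: cycle
  plane: [MPF, CycBT]
  description: >
    Wee1/Cdc25 tyrosine-phosphorylation switch added: total cyclin and
    active MPF separate, and MPF is a bistable function of total cyclin.
  anchor: fig5 caption (Km = 0.0026, deUb = 0.5, CAP = 0.3)

fig5d:
  model: model4
  analysis: nullclines
  plane: [MPF, CycBT]
  nullclines:
    - {clamp: CycBT, response: MPF, range: [0.02, 2.0]}
    - {clamp: MPF, response: CycBT, range: [0.02, 1.8]}
  description: >
    Pseudo-phase plane of model 4 in the (MPF, CycBT) projection: the MPF
    nullcline has hysteresis folds near CycBT 1.2 (activation) and 0.5
    (inactivation); the region MPF > CycBT is unreachable.
  anchor: fig5d and the hysteresis thresholds in the model-4 text

g2_arrest:
  model: model4
  analysis: arrest
  checkpoint: {kind: G2, overrides: {Cdc25_tot: 0.4}}
  plane: [MPF, CycBT]
  description: >
    G2 checkpoint: unreplicated DNA sequesters ~60% of Cdc25; the limit
    cycle is replaced by a stable steady state of high total cyclin and low
    MPF (mitotic entry blocked).
  anchor: fig6b caption (Cdc25_tot = 0.4)

sac_arrest:
  model: model4
  analysis: arrest
  checkpoint: {kind: SAC, overrides: {Cdc20_tot: 0.1}}
  plane: [MPF, CycBT]
  description: >
    Spindle-assembly checkpoint: mitotic checkpoint complexes sequester
    Cdc20; stable arrest at high total cyclin and high MPF (metaphase).
  anchor: fig6c caption (Cdc20_tot = 0.1)

sac_arrest_alt:
  model: model4
  analysis: arrest
  checkpoint: {kind: SAC, overrides: {Cdc20_tot: 0.2}}
  plane: [MPF, CycBT]
  description: >
    Spindle-assembly checkpoint, alternate strength quoted in the body
    text (Cdc20_tot lowered from 1 to 0.2); also arrests.
  anchor: body text on the spindle checkpoint (Cdc20_tot = 0.2)

g1_arrest:
  model: model4
  analysis: arrest
  checkpoint: {kind: G1, overrides: {kde3_cycb: 0.2}}
  plane: [MPF, CycBT]
  description: >
    G1 checkpoint: DNA damage stabilises Cdh1, which targets cyclin B via
    unphosphorylated APC/C; cyclin cannot accumulate and the cell arrests
    at low total cyclin and low MPF.
  anchor: fig6d caption (kde3_cycb = 0.2)

size_cycle:
  model: model4
  analysis: sizecycle
  mu: 0.005
  v0: 1.0
  entry_threshold: 0.5
  exit_threshold: 0.2
  n_cycles: 10
  description: >
    Size-controlled division cycle of fission yeast: Cdc25_tot = V(t), V
    grows exponentially (mu = 0.005 per min, mass doubling time 139 min)
    and halves when MPF drops below 0.2 after mitotic entry.
  anchor: fig7a caption (mu = 0.005 per min, exit threshold 0.2)

fig7b:
  model: model4
  analysis: branch
  free_param: Cdc25_tot
  range: [0.02, 1.3]
  envelope_values: [0.3, 0.45, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3]
  plane: [Cdc25_tot, MPF]
  description: >
    One-parameter bifurcation diagram of the size-control system with cell
    size V (= Cdc25_tot) clamped: steady-state branches with stability,
    fold detection and SNIC classification, plus the stable limit-cycle
    envelope of MPF extrema.
  anchor: fig7b caption
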