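# flash-esd

Equilibrium-state-dynamics (ESD) modeling of how the *temporal structure* of
radiotherapy dose delivery changes normal-tissue toxicity at ultra-high dose
rates (the FLASH effect).

## Who this is for

Radiobiology modelers and medical physicists who want to (a) predict
FLASH-modifying factors (FMF) for arbitrary delivery time structures —
continuous beams, pulsed linac beams, scanned pencil-beam spot sequences,
split schedules with pauses — under a family of latent-state radiosensitivity
models, (b) derive experimental FMF values from per-animal dose-response
data, and (c) fit and rank the model variants against FMF datasets.

## The model

A latent resource pool Q(t) starts at equilibrium Q0 (fixed to 1), is
depleted by irradiation at instantaneous dose rate Ḋ(t), and recovers toward
equilibrium:

    dQ/dt = Δ(Q)·Ḋ(t) + Ṙ(Q),      Q0 ≥ Q(t) ≥ 0,  Q(0) = Q0

with three depletion/recovery combinations (Θ is the Heaviside step,
Θ(x>0)=1, Θ(x≤0)=0):

| ODE  | Δ(Q)       | Ṙ(Q)        |
|------|------------|-------------|
| ESD1 | −g·Θ(Q)    | r·Θ(Q0−Q)   |
| ESD2 | −g·Q       | r·(Q0−Q)    |
| ESD3 | −g·Θ(Q)    | r·(Q0−Q)    |

While perturbed, Q scales the instantaneous relative radiosensitivity
S_rel(Q) between 1 and a floor S_min through a step (RRS1), power (RRS2), or
Michaelis–Menten-type (RRS3) response. The RRS-weighted dose

    D_RRS = ∫ S_rel(Q(t))·Ḋ(t) dt,      RRS = D_RRS / D

measures effective damage, and the predicted FLASH-modifying factor of a
test delivery against a constant-rate reference is the isoeffective dose
ratio FMF = D_ref/D_test with D_ref solving D_ref·RRS_ref(D_ref) = D_test·RRS_test.
ESD2 with RRS1 is degenerate (Q never reaches 0, FMF ≡ 1), leaving eight
variants with 3–4 free parameters. Experimental FMFs come from logistic
NTCP fits to reference cohorts inverted at each test group's responder
fraction (only fractions in the open 1–99% band define an isoeffect).
Variants are fitted to FMF data by Nelder–Mead on the mean-squared-error
objective and ranked by BIC = n·ln(χ²) + k·ln(n).

## Worked example

```python
from flash_esd import (ESDParameters, ModelVariant, make_pulsed,
                       solve_state, rrs_weighted_dose, rrs, fmf_pred)

variant = ModelVariant("ESD1", "RRS1")
params = ESDParameters(g=0.22, r=0.29, smin=0.65)   # best-fit murine skin set

# 37 Gy in 37 rectangular 1.8-us pulses at 100 Hz (UHDR electron beam)
prof = make_pulsed(37.0, 37, 1.8e-6, 100.0, label="uhdr-pulsed")
print(prof.total_dose, prof.exposure_time, prof.tadr)
# 37.0 0.36000180000000015 102.77726389145828

traj = solve_state(prof, variant, params)
print(rrs_weighted_dose(traj), rrs(prof, variant, params))
# 25.806974272457147 0.6974857911474904

print(fmf_pred(prof, 0.11, variant, params))
# 0.6974857911474904
```

Reading: the 37 Gy delivered in 0.36 s acts like 25.8 Gy delivered at a
conventional 0.11 Gy/s — the pool empties early in the delivery and the
remaining dose is weighted by S_min = 0.65. The FMF of 0.697 means an
isoeffective conventional irradiation needs only 69.7% of the test dose
(the reference rate is too slow to deplete the pool, so RRS_ref = 1 and
FMF equals the test delivery's RRS).

The same pipeline is scriptable from the shell via the `flash-esd` CLI
(`profile`, `simulate`, `fmf`, `derive-fmf`, `fit`, `rank`, `synth`).

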