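# Ketoprofen / plasma cortisol system: one-compartment plasma PK, first-order
# effect compartment (unit partition), sigmoidal inhibitory indirect-response
# model driven by the effect-compartment concentration.

[model]
name = "ketoprofen_cortisol"
drug = "S-(+)-ketoprofen"
label_dose = 3.0 # mg/kg IM

[pk]
Ka = 5.63
Ke = 0.20
V = 302.11

[link]
Ke0 = 15.35 # 1/h equilibration rate

[idr]
Kin = 65.46  # %/h
Kout = 0.72  # 1/h
Imax = 0.73  # fraction (printed 73.00%)
IC50 = 2.56  # ug/ml, plasma scale
gamma = 1.90

[iiv_percent]
Ke = 23.31
V = 12.92
Kin = 30.28
IC50 = 124.08
gamma = 78.87

[residual]
plasma = { type = "multiplicative", sigma = 0.1 }
pd = { type = "multiplicative", sigma = 0.1 }

[design]
n_per_group = 8
castration_time = 2.0

[design.schedule]
plasma = [0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0]
pd = [0.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0]

[design.loq]
plasma = 0.05
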