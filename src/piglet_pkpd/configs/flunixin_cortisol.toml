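# Flunixin / plasma cortisol system: two-compartment plasma PK in
# micro-constant parameterisation; the plasma concentration directly drives an
# Imax (Hill exponent fixed to 1) inhibitory indirect-response model.  The
# biomarker residual error is Poisson-type (variance proportional to the
# prediction).

[model]
name = "flunixin_cortisol"
drug = "flunixin"
label_dose = 2.2 # mg/kg IM

[pk]
Ka = 6.68    # 1/h
Ke = 0.16    # 1/h
K12 = 0.11   # 1/h
K21 = 0.16   # 1/h
V = 636.17   # Vd/F, ml/kg

[idr]
Kin = 44.93   # %/h
Kout = 0.46   # 1/h
Imax = 0.7202 # fraction (printed 72.02%)
IC50 = 0.059  # ug/ml, plasma scale
gamma = 1.0   # fixed

[iiv_percent]
Ke = 31.44
K12 = 71.98
K21 = 94.78
V = 41.07
Kin = 38.58
Imax = 13.26
IC50 = 10.62

[residual]
plasma = { type = "multiplicative", sigma = 0.1 }
# sqrt-prediction scaling: sd = sigma * sqrt(E), ~10% of a baseline near 100
pd = { type = "poisson", sigma = 1.0 }

[design]
n_per_group = 8
castration_time = 2.0

[design.schedule]
plasma = [0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0]
pd = [0.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0]

[design.loq]
plasma = 0.0005
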