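# Ketoprofen / ISF PGE2 system: one-compartment plasma PK, interstitial-fluid
# link compartment, sigmoidal inhibitory indirect-response model driven by the
# ISF concentration.  Typical values, IIV% and study design for the 3.0 mg/kg
# intramuscular piglet study.

[model]
name = "ketoprofen_pge2"
drug = "S-(+)-ketoprofen"
label_dose = 3.0 # mg/kg IM

[pk] # one-compartment, micro-constant parameterisation
Ka = 5.63    # 1/h
Ke = 0.20    # 1/h
V = 302.11   # Vd/F, ml/kg

[link] # central -> ISF
Ke0in = 0.012  # 1/h
Ke0out = 0.17  # 1/h

[idr] # inhibition of PGE2 production, Hill exponent free
Kin = 207.20   # %/h
Kout = 2.34    # 1/h
Imax = 0.9733  # fraction (printed 97.33%)
IC50 = 0.08    # ug/ml, ISF scale
gamma = 2.07

[iiv_percent] # lognormal CV%, parameters not listed carry no IIV
Ke = 23.31
V = 12.92
Ke0in = 8.63
Ke0out = 9.22
IC50 = 6.39

[residual]
plasma = { type = "multiplicative", sigma = 0.1 }
isf = { type = "multiplicative", sigma = 0.1 }
pd = { type = "multiplicative", sigma = 0.1 }

[design]
n_per_group = 8
castration_time = 2.0 # h post-dose; metadata only

[design.schedule] # h post-dose
plasma = [0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0]
isf = [2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0]
pd = [0.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0]

[design.loq] # ug/ml
plasma = 0.05
isf = 0.001
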