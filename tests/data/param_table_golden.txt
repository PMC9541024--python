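     Parameter          Estimate (CI) Units   CV%  IIV% Bootstrap median estimate (CI)
            Ka       5.63 (4.09–7.16)   1/h 13.65     -                              -
            Ke       0.20 (0.17–0.23)   1/h  8.43 23.31                              -
             V 302.11 (270.43–333.79) ml/kg  5.25 12.90                              -
sigma (plasma)                   0.10           -     -                              -
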