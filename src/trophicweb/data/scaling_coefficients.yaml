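# Allometric scaling coefficients for consumer search rate and resource
# density, by interaction dimensionality, from the Pawar, Dell & Savage
# (2012) cross-ecosystem regressions.  Power laws are on the natural
# scale: value = intercept * mass_g ** exponent; `se` is the standard
# error of the regression exponent, propagated by Monte-Carlo sampling.
search_rate:
  "2D":
    intercept: 8.3176e-4     # 10^-3.08, area searched per unit time
    exponent: 0.68
    se: 0.12
  "3D":
    intercept: 1.6982e-2     # 10^-1.77, volume searched per unit time
    exponent: 1.05
    se: 0.08
density:
  "2D":
    intercept: 2.1380e-3     # 10^-2.67, individuals per unit area
    exponent: -0.79
    se: 0.09
  "3D":
    intercept: 3.3113e-3     # 10^-2.48, individuals per unit volume
    exponent: -0.86
    se: 0.06
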