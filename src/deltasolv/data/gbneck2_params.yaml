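# deltasolv GB parameter table, version 1
#
# radius: intrinsic Born / van der Waals radius in Å (mbondi2-style set).
# screen: HCT descreening scale factor.
# alpha/beta/gamma: per-element tanh-rescaling coefficients of the
#   neck-corrected GB model (R_i^-1 = rho~_i^-1 - rho_i^-1 tanh(aP - bP^2 + cP^3)).
# H/C/N/O/S carry the neck-model refit coefficients of the Amber igb=8
# parameterization; halogens fall back to generic OBC-II style values and a
# 0.8 screen (documented package choice -- no refit exists for them here).
# Sulfur's refit screen factor is negative in the published set; it is kept
# as published but flagged: descreening by S atoms is outside the physical
# HCT regime and package fixtures avoid S.
offset: 0.195141
neck_scale: 0.826836
elements:
  H: {radius: 1.20, screen: 1.425952, alpha: 0.788440, beta: 0.798699, gamma: 0.437334}
  C: {radius: 1.70, screen: 1.058554, alpha: 0.733756, beta: 0.506378, gamma: 0.205844}
  N: {radius: 1.55, screen: 0.733599, alpha: 0.503364, beta: 0.316828, gamma: 0.192915}
  O: {radius: 1.50, screen: 1.061039, alpha: 0.867814, beta: 0.876635, gamma: 0.387882}
  S: {radius: 1.80, screen: -0.703469, alpha: 0.867814, beta: 0.876635, gamma: 0.387882}
  F: {radius: 1.50, screen: 0.80, alpha: 1.0, beta: 0.80, gamma: 4.85}
  Cl: {radius: 1.70, screen: 0.80, alpha: 1.0, beta: 0.80, gamma: 4.85}
  Br: {radius: 1.85, screen: 0.80, alpha: 1.0, beta: 0.80, gamma: 4.85}
  I: {radius: 1.98, screen: 0.80, alpha: 1.0, beta: 0.80, gamma: 4.85}
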