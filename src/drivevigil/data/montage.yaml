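cap:
  Fp1:
  - -0.31
  - 0.95
  Fp2:
  - 0.31
  - 0.95
  F7:
  - -0.81
  - 0.59
  Fz:
  - 0.0
  - 0.5
  F8:
  - 0.81
  - 0.59
  FC1:
  - -0.31
  - 0.27
  FC2:
  - 0.31
  - 0.27
  T7:
  - -1.0
  - 0.0
  C3:
  - -0.5
  - 0.0
  Cz:
  - 0.0
  - 0.0
  C4:
  - 0.5
  - 0.0
  T8:
  - 1.0
  - 0.0
  CP5:
  - -0.73
  - -0.29
  CP1:
  - -0.27
  - -0.27
  CPz:
  - 0.0
  - -0.25
  CP2:
  - 0.27
  - -0.27
  CP6:
  - 0.73
  - -0.29
  P3:
  - -0.5
  - -0.52
  Pz:
  - 0.0
  - -0.5
  P4:
  - 0.5
  - -0.52
  O1:
  - -0.31
  - -0.95
  O2:
  - 0.31
  - -0.95
  M1:
  - -1.05
  - -0.35
  M2:
  - 1.05
  - -0.35
grid:
  G_FP:
  - 0.45
  - 0.92
  G_C:
  - 0.78
  - 0.05
  G_P:
  - 0.9
  - -0.4
  G_O:
  - 0.55
  - -0.85
  G_EOG_L:
  - 0.2
  - 0.88
  G_EOG_R:
  - 0.62
  - 0.8
  G_EOG_U:
  - 0.42
  - 0.98
  G_EOG_D:
  - 0.45
  - 0.7
  G_M2:
  - 1.05
  - -0.35
  G_DRL:
  - 1.1
  - -0.15
virtual:
  reference: G_M2
  combos:
    FPz_M2:
    - - G_FP
      - 1.0
    - - G_M2
      - -1.0
    C4_M2:
    - - G_C
      - 1.0
    - - G_M2
      - -1.0
    P4_M2:
    - - G_P
      - 1.0
    - - G_M2
      - -1.0
    O2_M2:
    - - G_O
      - 1.0
    - - G_M2
      - -1.0
    EOGh:
    - - G_EOG_L
      - 1.0
    - - G_EOG_R
      - -1.0
    EOGv:
    - - G_EOG_U
      - 1.0
    - - G_EOG_D
      - -1.0
    EOGd:
    - - G_EOG_U
      - 1.0
    - - G_EOG_R
      - -1.0
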