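# Published correction-factor constants for Gamma Knife Perfexion fields.
#
# kvol:  literature volume-averaging correction factors (kvol)_{Q0}^{f}
#        per detector for the 16 mm (msr), 8 mm and 4 mm collimators.
# ratio: the corresponding published clin/msr ratios
#        (kvol)_{Q0,Q0}^{fmsr,fclin}, printed to 3 decimals.
# kq:    field output correction factors k_{Q0,Q0}^{fmsr,fclin} from the
#        IAEA TRS-483 Code of Practice, where tabulated (null = N.A.).
# k:     published volume-averaging contribution to the field output
#        correction (ratio / kq), where tabulated (null = N.A.).
#
# A few published ratio/k cells were evidently chained from unrounded
# intermediates and do not reproduce from the printed 3-decimal inputs;
# they are listed under inconsistent_cells and excluded from arithmetic
# cross-checks.
fields_mm: [16, 8, 4]
msr_field_mm: 16
kvol:
  Semiflex T31010:      [1.006, 1.042, 1.627]
  Semiflex 3D T31021:   [1.005, 1.019, 1.304]
  PinPoint T31014:      [1.005, 1.011, 1.181]
  PinPoint 3D T31022:   [1.003, 1.010, 1.101]
  Diode P T60016:       [1.001, 1.000, 1.008]
  Diode E T60017:       [1.001, 1.000, 1.008]
  microDiamond T60019:  [1.000, 1.002, 1.021]
  RAZOR diode:          [1.001, 1.000, 1.004]
  EFD 3G-pSi:           [1.001, 1.001, 1.018]
  EDGE detector:        [1.004, 1.003, 1.007]
  RAZOR chamber:        [1.003, 1.006, 1.074]
  IBA CC04:             [1.007, 1.014, 1.156]
  Exradin W2 1x1:       [1.003, 1.002, 1.010]
  Exradin W2 1x3:       [1.005, 1.005, 1.042]
ratio:
  Semiflex T31010:      [1.000, 1.036, 1.617]
  Semiflex 3D T31021:   [1.000, 1.014, 1.298]
  PinPoint T31014:      [1.000, 1.006, 1.175]
  PinPoint 3D T31022:   [1.000, 1.001, 1.091]
  Diode P T60016:       [1.000, 0.999, 1.007]
  Diode E T60017:       [1.000, 0.999, 1.007]
  microDiamond T60019:  [1.000, 1.001, 1.020]
  RAZOR diode:          [1.000, 0.999, 1.003]
  EFD 3G-pSi:           [1.000, 1.000, 1.017]
  EDGE detector:        [1.000, 0.999, 1.004]
  RAZOR chamber:        [1.000, 1.003, 1.071]
  IBA CC04:             [1.000, 1.007, 1.147]
  Exradin W2 1x1:       [1.000, 0.999, 1.007]
  Exradin W2 1x3:       [1.000, 1.000, 1.037]
kq:
  Semiflex T31010:      [1.004, null, null]
  PinPoint T31014:      [1.000, 1.030, null]
  Diode P T60016:       [1.000, 0.981, 0.965]
  Diode E T60017:       [1.000, 0.996, 0.985]
  microDiamond T60019:  [1.000, 1.005, 0.993]
  IBA CC04:             [1.021, null, null]
k:
  Semiflex T31010:      [0.996, null, null]
  PinPoint T31014:      [1.000, 0.984, null]
  Diode P T60016:       [1.000, 1.018, 1.044]
  Diode E T60017:       [1.000, 1.003, 1.022]
  microDiamond T60019:  [1.001, 0.996, 1.029]
  IBA CC04:             [0.979, null, null]
inconsistent_cells:
  ratio:
    - [PinPoint 3D T31022, 8]
    - [PinPoint 3D T31022, 4]
    - [microDiamond T60019, 4]
    - [IBA CC04, 4]
    - [EDGE detector, 4]
  k:
    - [PinPoint T31014, 8]
    - [microDiamond T60019, 16]
    - [microDiamond T60019, 4]
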