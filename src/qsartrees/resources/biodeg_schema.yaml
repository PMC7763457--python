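# Canonical 41-descriptor schema for the UCI QSAR biodegradation table.
# Each entry: descriptor name and measurement kind (continuous | ordinal | flag).
# Order matches the deposited data file's column order is not guaranteed by UCI;
# this is the alphabetical-by-table listing used throughout the package.
features:
  - {name: "B01[C-Br]", kind: flag}
  - {name: "B03[C-Cl]", kind: flag}
  - {name: "B04[C-Br]", kind: flag}
  - {name: "C%", kind: continuous}
  - {name: "C-026", kind: ordinal}
  - {name: "F01[N-N]", kind: ordinal}
  - {name: "F02[C-N]", kind: ordinal}
  - {name: "F03[C-N]", kind: ordinal}
  - {name: "F03[C-O]", kind: ordinal}
  - {name: "F04[C-N]", kind: ordinal}
  - {name: "HyWi_B(m)", kind: continuous}
  - {name: "J_Dz(e)", kind: continuous}
  - {name: "LOC", kind: continuous}
  - {name: "Me", kind: continuous}
  - {name: "Mi", kind: continuous}
  - {name: "N-073", kind: ordinal}
  - {name: "nArCOOR", kind: ordinal}
  - {name: "nArNO2", kind: ordinal}
  - {name: "nCb-", kind: ordinal}
  - {name: "nCIR", kind: ordinal}
  - {name: "nCp", kind: ordinal}
  - {name: "nCrt", kind: ordinal}
  - {name: "nCRX3", kind: ordinal}
  - {name: "nHDon", kind: ordinal}
  - {name: "nHM", kind: ordinal}
  - {name: "nN", kind: ordinal}
  - {name: "nN-N", kind: ordinal}
  - {name: "nO", kind: ordinal}
  - {name: "NssssC", kind: ordinal}
  - {name: "nX", kind: ordinal}
  - {name: "Psi_i_1d", kind: continuous}
  - {name: "Psi_i_A", kind: continuous}
  - {name: "SdO", kind: continuous}
  - {name: "SdssC", kind: continuous}
  - {name: "SM6_B(m)", kind: continuous}
  - {name: "SM6_L", kind: continuous}
  - {name: "SpMax_A", kind: continuous}
  - {name: "SpMax_B(m)", kind: continuous}
  - {name: "SpMax_L", kind: continuous}
  - {name: "SpPosA_B(p)", kind: continuous}
  - {name: "TI2_L", kind: continuous}
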