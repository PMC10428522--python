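# Shipped TCB/LVM method configuration: divisor concentrations, plateau
# windows and measurement wavelengths for the nine resolution routes.
analytes:
  extended: TCB
  less_extended: LVM

methods:
  RS_SS:
    divisor_conc: 5.0          # ug/mL pure TCB divisor
    plateau_region: [290, 306]
    responses: {TCB: "D0@304", LVM: "D0@214"}
    alt_responses: {TCB: ["D0@220"]}
  CM_SS:
    divisor_conc: 5.0
    plateau_region: [290, 306]
    responses: {TCB: "D0@220", LVM: "D0@214"}
  FC_SS:
    factorization_ref: 304.0
    responses: {TCB: "D0@220", LVM: "D0@214"}
  DS_SS:
    divisor_conc: 5.0
    plateau_region: [280, 315]  # wider interference-free window on D1
    responses: {TCB: "D1@310", LVM: "D1@221"}
    alt_responses: {TCB: ["D1@228-216"]}
  D1CM_SS:
    divisor_conc: 5.0
    plateau_region: [280, 315]
    responses: {TCB: "D1@228-216", LVM: "D1@221"}
  D1FC_SS:
    factorization_ref: 310.0
    responses: {TCB: "D1@228-216", LVM: "D1@221"}
  DD1:
    dd1_divisors:
      TCB: {analyte: LVM, conc: 4.0}
      LVM: {analyte: TCB, conc: 3.0}
    responses: {TCB: "D1@230-220", LVM: "D1@219"}
  CV:
    plateau_region: [290, 306]
    responses: {LVM: "D0@214"}
  CNV:
    plateau_region: [290, 306]
    responses: {LVM: "D0@214"}
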