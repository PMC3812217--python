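kind: network
name: tca_classical
metabolites:
- id: Pyr
  name: pyruvate
- id: AcCoA
  name: acetyl-CoA
- id: OAA
  name: oxaloacetate
- id: Cit
  name: citrate
- id: ICit
  name: isocitrate
- id: AKG
  name: alpha-ketoglutarate
- id: SucCoA
  name: succinyl-CoA
- id: Suc
  name: succinate
- id: Fum
  name: fumarate
- id: Mal
  name: malate
- id: CoA
  name: coenzyme A
- id: Glc
  name: glycolytic carbon source
  external: true
- id: AcP
  name: acetyl-phosphate
  external: true
- id: CO2
  external: true
- id: NAD
  external: true
- id: NADH
  external: true
- id: FAD
  external: true
- id: FADH2
  external: true
- id: ATP
  external: true
- id: ADP
  external: true
reactions:
- id: pdh
  stoich:
    Pyr: -1
    CoA: -1
    NAD: -1
    AcCoA: 1
    CO2: 1
    NADH: 1
- id: citA
  stoich:
    AcCoA: -1
    OAA: -1
    Cit: 1
    CoA: 1
- id: citB
  stoich:
    Cit: -1
    ICit: 1
- id: icd
  stoich:
    ICit: -1
    NAD: -1
    AKG: 1
    CO2: 1
    NADH: 1
- id: odh
  stoich:
    AKG: -1
    CoA: -1
    NAD: -1
    SucCoA: 1
    CO2: 1
    NADH: 1
- id: SucCD
  stoich:
    Suc: -1
    CoA: -1
    ATP: -1
    SucCoA: 1
    ADP: 1
  reversible: true
- id: SucABC
  stoich:
    Suc: -1
    FAD: -1
    Fum: 1
    FADH2: 1
- id: fumC
  stoich:
    Fum: -1
    Mal: 1
- id: mdh
  stoich:
    Mal: -1
    NAD: -1
    OAA: 1
    NADH: 1
  reversible: true
- id: ywka
  stoich:
    Mal: -1
    NAD: -1
    Pyr: 1
    CO2: 1
    NADH: 1
- id: pyc
  stoich:
    Pyr: -1
    CO2: -1
    ATP: -1
    OAA: 1
    ADP: 1
- id: Pta
  stoich:
    AcCoA: -1
    AcP: 1
    CoA: 1
  reversible: true
- id: Glyco
  stoich:
    Glc: -1
    Pyr: 1
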