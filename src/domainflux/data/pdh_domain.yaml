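kind: domain_network
name: pdh_domain
domains:
- label: PdhA
  gene: pdhA
  scop_fold: c.36.1
  function: Binding TPP and active site (first reaction)
  role: catalytic
- label: PdhB1
  gene: pdhB
  scop_fold: c.36.1
  function: Binding TPP and active site (second reaction)
  role: catalytic
- label: PdhB2
  gene: pdhB
  scop_fold: c.48.1
  function: regulatory binding site
  role: regulatory
- label: PdhC1
  gene: pdhC
  scop_fold: b.84.1
  function: Lipoyl binding
  role: binding
- label: PdhC2
  gene: pdhC
  scop_fold: a.9.1
  function: E1/E3 binding
  role: binding
- label: PdhC3
  gene: pdhC
  scop_fold: c.43.1
  function: Active site
  role: catalytic
- label: PdhD1
  gene: pdhD
  scop_fold: c.3.1
  function: Binding FAD
  role: binding
- label: PdhD2
  gene: pdhD
  scop_fold: c.4.1
  function: Binding NAD/FAD
  role: binding
- label: PdhD3
  gene: pdhD
  scop_fold: d.87.1
  function: Active site
  role: catalytic
species:
- id: Pyr
  name: pyruvate
  external: true
- id: CoA
  name: coenzyme A
  external: true
- id: NAD
  external: true
- id: CO2
  external: true
- id: AcCoA
  name: acetyl-CoA
  external: true
- id: NADH
  external: true
- id: TPP
  name: enzyme-bound thiamine diphosphate
- id: HE_TPP
  name: 2-hydroxyethyl-TPP
- id: LA_E
  name: lipoamide (enzyme-bound)
- id: AcDHL_E
  name: acetyl-dihydrolipoamide (enzyme-bound)
- id: DHA_E
  name: dihydrolipoamide (enzyme-bound)
- id: AcCoA_E
  name: enzyme-bound acetyl-CoA
- id: FAD_E
  name: lipoamide-dehydrogenase-bound FAD
  contains:
  - PdhD1
- id: FADH2_E
  name: lipoamide-dehydrogenase-bound FADH2
  contains:
  - PdhD1
- id: NAD_E
  name: lipoamide-dehydrogenase-bound NAD
  contains:
  - PdhD2
- id: NADH_E
  name: lipoamide-dehydrogenase-bound NADH
  contains:
  - PdhD2
steps:
- id: R1
  stoich:
    Pyr: -1
    TPP: -1
    HE_TPP: 1
    CO2: 1
  catalysts:
  - PdhA
- id: R2
  stoich:
    HE_TPP: -1
    LA_E: -1
    AcDHL_E: 1
    TPP: 1
  catalysts:
  - PdhB1
  - PdhC1
- id: R3
  stoich:
    AcDHL_E: -1
    CoA: -1
    AcCoA_E: 1
    DHA_E: 1
  catalysts:
  - PdhC3
  - PdhC1
- id: R4
  stoich:
    AcCoA_E: -1
    AcCoA: 1
  catalysts:
  - PdhC1
- id: R5
  stoich:
    DHA_E: -1
    FAD_E: -1
    LA_E: 1
    FADH2_E: 1
  catalysts:
  - PdhD3
  - PdhD2
  - PdhD1
- id: R6
  stoich:
    FADH2_E: -1
    NAD_E: -1
    FAD_E: 1
    NADH_E: 1
  catalysts:
  - PdhD2
  - PdhD1
- id: R7
  stoich:
    NADH_E: -1
    NAD: -1
    NAD_E: 1
    NADH: 1
  catalysts:
  - PdhD2
enzyme_map:
  pdh:
  - R1
  - R2
  - R3
  - R4
  - R5
  - R6
  - R7
notes: 'Pyruvate dehydrogenase complex of B. subtilis resolved into the seven elementary
  steps of its functional domains: E1 decarboxylation (R1, PdhA), reductive acetyl
  transfer to the lipoyl arm (R2, PdhB1), transacetylation to CoA on E2 (R3-R4, PdhC),
  and reoxidation of dihydrolipoamide by the E3 lipoamide dehydrogenase through its
  bound FAD and NAD (R5-R7, PdhD). The flavin and nicotinamide cofactors of E3 stay
  enzyme-bound and cycle internally; free NAD/NADH exchange only through R7.'
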