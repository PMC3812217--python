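-ENZREV
R18 R21 R25 R28 R29 R31

-ENZIRREV
R1 R2 R3 R4 R5 R6 R7 R8 R9 R10 R11 R12 R13 R14 R15 R16 R17 R19 R20 R22 R23 R24 R26 R27 R30 R32 R33

-METINT
Pyr AcCoA OAA Cit ICit AKG SucCoA Suc Fum Mal CoA TPP HE_TPP LA_E AcDHL_E DHA_E AcCoA_E FAD_E FADH2_E NAD_E NADH_E SHE_TPP SucDHL_E SucCoA_E SucC1 SucC1_ADP SucC1_ATP SucD1_CoA sdhA1 sdhA1_FAD sdhA1_FADH2 mdh1 mdh1_NAD mdh1_NADH ywkA2 ywkA2_NAD ywkA2_NADH pyc2 pyc2_ATP pyc2_ADP

-METEXT
Glc AcP CO2 NAD NADH FAD FADH2 ATP ADP SucD1

-CAT
R1 : Pyr + TPP = HE_TPP + CO2 .
R2 : HE_TPP + LA_E = AcDHL_E + TPP .
R3 : AcDHL_E + CoA = AcCoA_E + DHA_E .
R4 : AcCoA_E = AcCoA .
R5 : DHA_E + FAD_E = LA_E + FADH2_E .
R6 : FADH2_E + NAD_E = FAD_E + NADH_E .
R7 : NADH_E + NAD = NAD_E + NADH .
R8 : AcCoA + OAA = Cit + CoA .
R9 : Cit = ICit .
R10 : ICit + NAD = AKG + CO2 + NADH .
R11 : AKG + TPP = SHE_TPP + CO2 .
R12 : SHE_TPP + LA_E = SucDHL_E + TPP .
R13 : SucDHL_E + CoA = SucCoA_E + DHA_E .
R14 : SucCoA_E = SucCoA .
R15 : SucCoA + SucC1_ADP + SucD1 = Suc + SucC1_ATP + SucD1_CoA .
R16 : Suc + sdhA1_FAD = Fum + sdhA1_FADH2 .
R17 : Fum = Mal .
R18 : Mal + mdh1_NAD = OAA + mdh1_NADH .
R19 : Mal + ywkA2_NAD = Pyr + CO2 + ywkA2_NADH .
R20 : Pyr + CO2 + pyc2_ATP = OAA + pyc2_ADP .
R21 : AcCoA = AcP + CoA .
R22 : Glc = Pyr .
R23 : ADP + SucC1 = SucC1_ADP .
R24 : SucC1_ATP = ATP + SucC1 .
R25 : CoA + SucD1 = SucD1_CoA .
R26 : FAD + sdhA1 = sdhA1_FAD .
R27 : sdhA1_FADH2 = FADH2 + sdhA1 .
R28 : NAD + mdh1 = mdh1_NAD .
R29 : mdh1_NADH = NADH + mdh1 .
R30 : NAD + ywkA2 = ywkA2_NAD .
R31 : NADH + ywkA2 = ywkA2_NADH .
R32 : ATP + pyc2 = pyc2_ATP .
R33 : pyc2_ADP = ADP + pyc2 .
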