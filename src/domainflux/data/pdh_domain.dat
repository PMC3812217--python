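-ENZREV


-ENZIRREV
R1 R2 R3 R4 R5 R6 R7

-METINT
TPP HE_TPP LA_E AcDHL_E DHA_E AcCoA_E FAD_E FADH2_E NAD_E NADH_E

-METEXT
Pyr CoA NAD CO2 AcCoA NADH

-CAT
R1 : Pyr + TPP = HE_TPP + CO2 .
R2 : HE_TPP + LA_E = AcDHL_E + TPP .
R3 : AcDHL_E + CoA = AcCoA_E + DHA_E .
R4 : AcCoA_E = AcCoA .
R5 : DHA_E + FAD_E = LA_E + FADH2_E .
R6 : FADH2_E + NAD_E = FAD_E + NADH_E .
R7 : NADH_E + NAD = NAD_E + NADH .
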