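-ENZREV
SucCD mdh Pta

-ENZIRREV
pdh citA citB icd odh SucABC fumC ywka pyc Glyco

-METINT
Pyr AcCoA OAA Cit ICit AKG SucCoA Suc Fum Mal CoA

-METEXT
Glc AcP CO2 NAD NADH FAD FADH2 ATP ADP

-CAT
pdh : Pyr + CoA + NAD = AcCoA + CO2 + NADH .
citA : AcCoA + OAA = Cit + CoA .
citB : Cit = ICit .
icd : ICit + NAD = AKG + CO2 + NADH .
odh : AKG + CoA + NAD = SucCoA + CO2 + NADH .
SucCD : Suc + CoA + ATP = SucCoA + ADP .
SucABC : Suc + FAD = Fum + FADH2 .
fumC : Fum = Mal .
mdh : Mal + NAD = OAA + NADH .
ywka : Mal + NAD = Pyr + CO2 + NADH .
pyc : Pyr + CO2 + ATP = OAA + ADP .
Pta : AcCoA = AcP + CoA .
Glyco : Glc = Pyr .
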