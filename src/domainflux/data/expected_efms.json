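{
 "tca_classical": {
  "aliases": {},
  "labels": {
   "EFM 1": [
    "pyc",
    "-mdh",
    "ywka"
   ],
   "EFM 2": [
    "citA",
    "odh",
    "citB",
    "icd",
    "-SucCD",
    "SucABC",
    "fumC",
    "mdh",
    "-Pta"
   ],
   "EFM 3": [
    "citA",
    "pyc",
    "odh",
    "citB",
    "icd",
    "-SucCD",
    "SucABC",
    "fumC",
    "ywka",
    "-Pta"
   ],
   "EFM 4": [
    "pdh",
    "Glyco",
    "Pta"
   ],
   "EFM 5": [
    "pdh",
    "citA",
    "odh",
    "Glyco",
    "citB",
    "icd",
    "-SucCD",
    "SucABC",
    "fumC",
    "mdh"
   ],
   "EFM 6": [
    "pdh",
    "citA",
    "pyc",
    "odh",
    "Glyco",
    "citB",
    "icd",
    "-SucCD",
    "SucABC",
    "fumC",
    "ywka"
   ]
  },
  "coefficients": {}
 },
 "tca_domain": {
  "aliases": {},
  "labels": {
   "EFM 1": [
    "R20",
    "-R18",
    "R19",
    "-R28",
    "-R29",
    "R30",
    "-R31",
    "R32",
    "R33"
   ],
   "EFM 2": [
    "R5",
    "R6",
    "R7",
    "R8",
    "R11",
    "R12",
    "R13",
    "R14",
    "R9",
    "R10",
    "R15",
    "R16",
    "R17",
    "R18",
    "-R21",
    "R23",
    "R24",
    "-R25",
    "R26",
    "R27",
    "R28",
    "R29"
   ],
   "EFM 3": [
    "R5",
    "R6",
    "R7",
    "R8",
    "R11",
    "R12",
    "R13",
    "R14",
    "R20",
    "R9",
    "R10",
    "R15",
    "R16",
    "R17",
    "R19",
    "-R21",
    "R23",
    "R24",
    "-R25",
    "R26",
    "R27",
    "R30",
    "-R31",
    "R32",
    "R33"
   ],
   "EFM 4": [
    "R1",
    "R2",
    "R3",
    "R4",
    "R5",
    "R6",
    "R7",
    "R22",
    "R21"
   ],
   "EFM 5": [
    "R1",
    "R2",
    "R3",
    "R4",
    "R5",
    "R6",
    "R7",
    "R8",
    "R11",
    "R12",
    "R13",
    "R14",
    "R22",
    "R9",
    "R10",
    "R15",
    "R16",
    "R17",
    "R18",
    "R23",
    "R24",
    "-R25",
    "R26",
    "R27",
    "R28",
    "R29"
   ],
   "EFM 6": [
    "R1",
    "R2",
    "R3",
    "R4",
    "R5",
    "R6",
    "R7",
    "R8",
    "R11",
    "R12",
    "R13",
    "R14",
    "R20",
    "R22",
    "R9",
    "R10",
    "R15",
    "R16",
    "R17",
    "R19",
    "R23",
    "R24",
    "-R25",
    "R26",
    "R27",
    "R30",
    "-R31",
    "R32",
    "R33"
   ]
  },
  "coefficients": {
   "EFM 5": {
    "R1": 1,
    "R5": 2,
    "R6": 2,
    "R7": 2
   },
   "EFM 6": {
    "R1": 1,
    "R5": 2,
    "R6": 2,
    "R7": 2
   }
  }
 },
 "pdh_domain": {
  "aliases": {},
  "labels": {
   "EFM 1": [
    "R1",
    "R2",
    "R3",
    "R4",
    "R5",
    "R6",
    "R7"
   ]
  },
  "coefficients": {
   "EFM 1": {
    "R1": 1,
    "R7": 1
   }
  }
 }
}
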