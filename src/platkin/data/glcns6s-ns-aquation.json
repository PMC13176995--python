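{
 "name": "glcns6s-ns-aquation",
 "reference_label": "Cl-PtN3",
 "temperature": 298.15,
 "points": [
  {
   "label": "Cl-PtN3",
   "kind": "separated_species",
   "g_rel_kcal": 0.0,
   "explicit_waters": 0
  },
  {
   "label": "MS1",
   "kind": "minimum",
   "g_rel_kcal": 4.5,
   "explicit_waters": 0
  },
  {
   "label": "TS1",
   "kind": "transition_state",
   "g_rel_kcal": 29.3,
   "explicit_waters": 0
  },
  {
   "label": "MS2",
   "kind": "minimum",
   "g_rel_kcal": 11.2,
   "explicit_waters": 0
  },
  {
   "label": "H2O-PtN3",
   "kind": "separated_species",
   "g_rel_kcal": 20.9,
   "explicit_waters": 0,
   "meta": {
    "note": "printed as 20.9 'compared with the starting material MS1'; stored relative to the global Cl-PtN3 reference (reference ambiguity recorded)"
   }
  },
  {
   "label": "MS5",
   "kind": "minimum",
   "g_rel_kcal": 0.0,
   "explicit_waters": 0
  },
  {
   "label": "TS3",
   "kind": "transition_state",
   "g_rel_kcal": 29.2,
   "explicit_waters": 0
  },
  {
   "label": "MS6",
   "kind": "minimum",
   "g_rel_kcal": 11.6,
   "explicit_waters": 0
  },
  {
   "label": "GlcNS(6S)-NS-PtN3",
   "kind": "separated_species",
   "g_rel_kcal": 6.6,
   "explicit_waters": 0
  }
 ],
 "steps": [
  {
   "from": "Cl-PtN3",
   "ts": null,
   "to": "MS1",
   "dg_forward_kcal": null,
   "consumed": "H2O:1",
   "released": ""
  },
  {
   "from": "MS1",
   "ts": "TS1",
   "to": "MS2",
   "dg_forward_kcal": 24.8,
   "consumed": "",
   "released": ""
  },
  {
   "from": "MS2",
   "ts": null,
   "to": "H2O-PtN3",
   "dg_forward_kcal": null,
   "consumed": "",
   "released": "Cl-:1"
  },
  {
   "from": "H2O-PtN3",
   "ts": null,
   "to": "MS5",
   "dg_forward_kcal": null,
   "consumed": "GlcNS(6S):1",
   "released": ""
  },
  {
   "from": "MS5",
   "ts": "TS3",
   "to": "MS6",
   "dg_forward_kcal": 29.2,
   "consumed": "",
   "released": ""
  },
  {
   "from": "MS6",
   "ts": null,
   "to": "GlcNS(6S)-NS-PtN3",
   "dg_forward_kcal": null,
   "consumed": "",
   "released": "H2O:1"
  }
 ],
 "species_tags": {
  "Cl-PtN3": {
   "Pt": 1,
   "Cl": 1
  },
  "MS1": {
   "Pt": 1,
   "Cl": 1
  },
  "MS2": {
   "Pt": 1,
   "Cl": 1
  },
  "H2O-PtN3": {
   "Pt": 1
  },
  "Cl-": {
   "Cl": 1
  },
  "GlcNS(6S)": {
   "sugar": 1
  },
  "MS5": {
   "Pt": 1,
   "sugar": 1
  },
  "MS6": {
   "Pt": 1,
   "sugar": 1
  },
  "GlcNS(6S)-NS-PtN3": {
   "Pt": 1,
   "sugar": 1
  }
 },
 "meta": {
  "printed_reverse_barriers": {
   "MS1->MS2": 18.0,
   "MS5->MS6": 17.6
  }
 }
}
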