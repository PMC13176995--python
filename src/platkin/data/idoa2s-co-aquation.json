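{
 "name": "idoa2s-co-aquation",
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
   "label": "MS3",
   "kind": "minimum",
   "g_rel_kcal": 10.5,
   "explicit_waters": 0
  },
  {
   "label": "TS2",
   "kind": "transition_state",
   "g_rel_kcal": 28.4,
   "explicit_waters": 0
  },
  {
   "label": "MS4",
   "kind": "minimum",
   "g_rel_kcal": 4.4,
   "explicit_waters": 0
  },
  {
   "label": "IdoA(2S)-CO-PtN3",
   "kind": "separated_species",
   "g_rel_kcal": 0.9,
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
   "to": "MS3",
   "dg_forward_kcal": null,
   "consumed": "IdoA(2S):1",
   "released": ""
  },
  {
   "from": "MS3",
   "ts": "TS2",
   "to": "MS4",
   "dg_forward_kcal": 17.9,
   "consumed": "",
   "released": ""
  },
  {
   "from": "MS4",
   "ts": null,
   "to": "IdoA(2S)-CO-PtN3",
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
  "IdoA(2S)": {
   "sugar": 1
  },
  "MS3": {
   "Pt": 1,
   "sugar": 1
  },
  "MS4": {
   "Pt": 1,
   "sugar": 1
  },
  "IdoA(2S)-CO-PtN3": {
   "Pt": 1,
   "sugar": 1
  }
 },
 "meta": {
  "printed_reverse_barriers": {
   "MS1->MS2": 18.0,
   "MS3->MS4": 24.0
  }
 }
}
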