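{
 "name": "idoa2s-co-direct",
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
   "label": "MSa",
   "kind": "minimum",
   "g_rel_kcal": -4.92,
   "explicit_waters": 0
  },
  {
   "label": "TSa",
   "kind": "transition_state",
   "g_rel_kcal": 23.4,
   "explicit_waters": 0
  },
  {
   "label": "MSb",
   "kind": "minimum",
   "g_rel_kcal": 0.8,
   "explicit_waters": 0
  },
  {
   "label": "IdoA(2S)-CO-PtN3",
   "kind": "separated_species",
   "g_rel_kcal": 0.85,
   "explicit_waters": 0
  }
 ],
 "steps": [
  {
   "from": "Cl-PtN3",
   "ts": null,
   "to": "MSa",
   "dg_forward_kcal": null,
   "consumed": "IdoA(2S):1",
   "released": ""
  },
  {
   "from": "MSa",
   "ts": "TSa",
   "to": "MSb",
   "dg_forward_kcal": 28.32,
   "consumed": "",
   "released": ""
  },
  {
   "from": "MSb",
   "ts": null,
   "to": "IdoA(2S)-CO-PtN3",
   "dg_forward_kcal": null,
   "consumed": "",
   "released": "Cl-:1"
  }
 ],
 "species_tags": {
  "Cl-PtN3": {
   "Pt": 1,
   "Cl": 1
  },
  "IdoA(2S)": {
   "sugar": 1
  },
  "MSa": {
   "Pt": 1,
   "Cl": 1,
   "sugar": 1
  },
  "MSb": {
   "Pt": 1,
   "Cl": 1,
   "sugar": 1
  },
  "Cl-": {
   "Cl": 1
  },
  "IdoA(2S)-CO-PtN3": {
   "Pt": 1,
   "sugar": 1
  }
 },
 "meta": {
  "printed_reverse_barriers": {
   "MSa->MSb": 22.6
  }
 }
}
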