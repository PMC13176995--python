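{
 "name": "glcns6s-ns-direct",
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
   "label": "MSc",
   "kind": "minimum",
   "g_rel_kcal": -2.6,
   "explicit_waters": 0
  },
  {
   "label": "TSb",
   "kind": "transition_state",
   "g_rel_kcal": 23.6,
   "explicit_waters": 0
  },
  {
   "label": "MSd",
   "kind": "minimum",
   "g_rel_kcal": 9.7,
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
   "to": "MSc",
   "dg_forward_kcal": null,
   "consumed": "GlcNS(6S):1",
   "released": ""
  },
  {
   "from": "MSc",
   "ts": "TSb",
   "to": "MSd",
   "dg_forward_kcal": 26.2,
   "consumed": "",
   "released": ""
  },
  {
   "from": "MSd",
   "ts": null,
   "to": "GlcNS(6S)-NS-PtN3",
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
  "GlcNS(6S)": {
   "sugar": 1
  },
  "MSc": {
   "Pt": 1,
   "Cl": 1,
   "sugar": 1
  },
  "MSd": {
   "Pt": 1,
   "Cl": 1,
   "sugar": 1
  },
  "Cl-": {
   "Cl": 1
  },
  "GlcNS(6S)-NS-PtN3": {
   "Pt": 1,
   "sugar": 1
  }
 },
 "meta": {
  "printed_reverse_barriers": {
   "MSc->MSd": 13.9
  }
 }
}
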