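{
 "name": "glcns6s-os-direct",
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
   "label": "MSc'",
   "kind": "minimum",
   "g_rel_kcal": 6.1,
   "explicit_waters": 0
  },
  {
   "label": "TSb'",
   "kind": "transition_state",
   "g_rel_kcal": 25.4,
   "explicit_waters": 0
  },
  {
   "label": "MSd'",
   "kind": "minimum",
   "g_rel_kcal": 5.9,
   "explicit_waters": 0
  }
 ],
 "steps": [
  {
   "from": "Cl-PtN3",
   "ts": null,
   "to": "MSc'",
   "dg_forward_kcal": null,
   "consumed": "GlcNS(6S):1",
   "released": ""
  },
  {
   "from": "MSc'",
   "ts": "TSb'",
   "to": "MSd'",
   "dg_forward_kcal": 19.3,
   "consumed": "",
   "released": ""
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
  "MSc'": {
   "Pt": 1,
   "Cl": 1,
   "sugar": 1
  },
  "MSd'": {
   "Pt": 1,
   "Cl": 1,
   "sugar": 1
  },
  "Cl-": {
   "Cl": 1
  }
 },
 "meta": {
  "printed_reverse_barriers": {
   "MSc'->MSd'": 19.5
  },
  "flags": [
   "isolated GlcNS(6S)-OS-PtN3 energy not printed; profile ends at MSd'"
  ]
 }
}
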