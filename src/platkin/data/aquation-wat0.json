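{
 "name": "aquation-wat0",
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
   "g_rel_kcal": 4.46,
   "explicit_waters": 0
  },
  {
   "label": "TS1",
   "kind": "transition_state",
   "g_rel_kcal": 29.25,
   "explicit_waters": 0
  },
  {
   "label": "MS2",
   "kind": "minimum",
   "g_rel_kcal": 11.22,
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
   "dg_forward_kcal": 24.79,
   "consumed": "",
   "released": ""
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
  }
 },
 "meta": {
  "printed_reverse_barriers": {
   "MS1->MS2": 18.03
  },
  "explicit_waters": 0
 }
}
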