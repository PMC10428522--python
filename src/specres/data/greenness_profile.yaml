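# Greenness profile of the shipped spectrophotometric procedure:
# methanolic-HCl solvent, double-beam spectrophotometer, recycled waste.
eco_scale:
  reagents:
    - {name: methanol, pictogram_count: 3, signal_word: danger, amount_class: "<10"}
    - {name: HCl, pictogram_count: 1, signal_word: danger, amount_class: "<10"}
  instrument_energy_class: "<=0.1 kWh"
  occupational_hazard: false
  waste: {amount_class: "1-10", treatment: recycling}

# Twelve per-principle scores (0-1). Most principles score at or near 1 for a
# direct spectrophotometric assay; sample-preparation position, bio-based
# reagent share and solvent flammability pull their principles down.
agree:
  scores: [0.75, 0.9, 0.5, 0.75, 0.25, 1.0, 1.0, 0.9, 1.0, 0.5, 1.0, 0.6]
  weights: null

# NEMI quadrants: methanol is RCRA-listed (hazardous) but not PBT; the
# methanolic-HCl working solution is non-corrosive and waste is a few grams.
nemi:
  pbt_listed: false
  hazardous_listed: true
  ph: 4.0
  waste_g_per_sample: 5.0
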