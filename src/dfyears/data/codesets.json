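{
  "alcohol_hospitalisation": {
    "description": "Hospitalisation for alcohol abuse or poisoning",
    "codes": ["F100", "F101", "T510", "Y15", "X45"],
    "ranges": []
  },
  "alcohol_related_death": {
    "description": "Death from alcohol-related causes",
    "codes": ["C09", "C10", "C22", "C32", "F10", "K70"],
    "ranges": [["C01", "C06"], ["C12", "C15"], ["S00", "Y91"]]
  },
  "alcohol_attributable": {
    "description": "Wholly alcohol-attributable conditions",
    "codes": ["E244", "F10", "G312", "G621", "G721", "I426", "K292", "K70",
              "K852", "K860", "O354", "P043", "Q860", "R780", "T51", "X45",
              "X65", "Y15", "Y90", "Y91", "Z040", "Z502", "Z714", "Z721", "Z811"],
    "ranges": []
  },
  "chronic_disease_endpoint": {
    "description": "First of six chronic diseases: type 2 diabetes, coronary heart disease, stroke, cancer, asthma, COPD",
    "codes": ["E11", "I60", "I61", "I63", "I64", "J45", "J46", "J41", "J42", "J43", "J44"],
    "ranges": [["I20", "I25"], ["C00", "C97"]]
  }
}
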