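{
  "name": "lehninger",
  "description": "Side-chain and terminal pKa values from the Lehninger biochemistry textbook scale. Basic groups: K, R, H and the amino terminus; acidic groups: D, E, C, Y and the carboxyl terminus.",
  "side_chain": {
    "R": 12.48,
    "H": 6.0,
    "K": 10.53,
    "D": 3.65,
    "E": 4.25,
    "C": 8.18,
    "Y": 10.07
  },
  "amino_terminus": 9.69,
  "carboxyl_terminus": 2.34,
  "basic": ["R", "H", "K"],
  "acidic": ["D", "E", "C", "Y"]
}
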