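{
  "default": {
    "A": "apolar", "C": "polar", "D": "charged", "E": "charged",
    "F": "apolar", "G": "apolar", "H": "polar", "I": "apolar",
    "K": "charged", "L": "apolar", "M": "apolar", "N": "polar",
    "P": "apolar", "Q": "polar", "R": "charged", "S": "polar",
    "T": "polar", "V": "apolar", "W": "polar", "Y": "polar"
  },
  "consensus_model": {
    "A": "apolar", "C": "apolar", "D": "charged", "E": "charged",
    "F": "apolar", "G": "apolar", "H": "charged", "I": "apolar",
    "K": "charged", "L": "apolar", "M": "apolar", "N": "polar",
    "P": "apolar", "Q": "polar", "R": "charged", "S": "polar",
    "T": "polar", "V": "apolar", "W": "apolar", "Y": "polar"
  }
}
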