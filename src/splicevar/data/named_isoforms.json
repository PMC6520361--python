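[
  {
    "label": "p53ψ",
    "event_type": "cryptic_acceptor",
    "index": 6,
    "offset": -49,
    "note": "Truncated TP53 isoform from a cryptic splice acceptor 49 bp upstream of the canonical intron 6 acceptor; carries a premature termination codon in intron 6."
  }
]
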