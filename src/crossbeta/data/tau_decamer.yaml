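# Default assembly description for the tau decamer builder output.
# chain_order: first five chains form protofilament a (stack 1a..5a by
# position along the fibril axis), the rest protofilament b.
chain_order: [A, B, C, D, E, F, G, H, I, J]
first_residue_number: 304
segments:
  PHF6: [306, 311]
  PAM4: [350, 362]
  turn: [340, 350]
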