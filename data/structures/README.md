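# Structure files (not bundled)

Acceptance targets t3/t4/t5 and the criterion-2 acceptance tests need the
public atomic structures:

- `6KAD.cif` — PSII-LHCII (C2S2M2L2) supercomplex
- `1Q90.pdb` — cytochrome b6f dimer

Download them from the PDB into this directory (or point
`--structures-dir` / `$MCART_STRUCTURES_DIR` at a directory containing
them). They are not redistributed with this repository.
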