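"""Unit conversions. Geometry files are in angstrom; all internals are atomic units."""

BOHR_PER_ANGSTROM = 1.8897261254578281
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM
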