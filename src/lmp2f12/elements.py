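"""Minimal periodic-table data for the supported elements."""

ATOMIC_NUMBER = {"H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7,
                 "O": 8, "F": 9, "Ne": 10}
SYMBOL = {z: s for s, z in ATOMIC_NUMBER.items()}


def n_core_orbitals(z: int) -> int:
    """Chemical-core orbital count (frozen in the correlation treatment).

    H and He have none; first-row atoms freeze the 1s shell.
    """
    if z <= 2:
        return 0
    if z <= 10:
        return 1
    raise ValueError(f"element Z={z} not supported")
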