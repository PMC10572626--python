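"""Random-coil chemical-shift reference tables.

Secondary chemical shifts are observed shifts minus a tabulated random-coil
baseline; the choice of baseline set shifts absolute delta values slightly but
not the helix/coil contrast this package classifies on.  One published set is
built in (Wishart et al., J. Biomol. NMR 5, 1995: Calpha/Cbeta shifts of
Ac-GGXGG-NH2 peptides); user-supplied tables are accepted anywhere a
:class:`RandomCoilTable` is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AA1 = "ACDEFGHIKLMNPQRSTVWY"
AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
AA1_FROM_3 = {three: one for one, three in AA3.items()}

# (CA, CB) ppm; glycine has no CB.
_WISHART_1995_CACB: dict[str, tuple[float, float | None]] = {
    "A": (52.5, 19.1),
    "C": (58.2, 28.0),
    "D": (54.2, 41.1),
    "E": (56.6, 29.9),
    "F": (57.7, 39.6),
    "G": (45.1, None),
    "H": (55.0, 29.0),
    "I": (61.1, 38.8),
    "K": (56.2, 33.1),
    "L": (55.1, 42.4),
    "M": (55.4, 32.9),
    "N": (53.1, 38.9),
    "P": (63.3, 31.7),
    "Q": (55.7, 29.4),
    "R": (56.0, 30.9),
    "S": (58.3, 63.8),
    "T": (61.8, 69.8),
    "V": (62.2, 32.9),
    "W": (57.5, 29.6),
    "Y": (57.9, 38.8),
}

# Additive corrections for a residue immediately preceding a proline (offset +1
# means the neighbor sits C-terminal of the corrected residue).  Applied only
# when neighbor corrections are switched on.
_PRE_PROLINE_CORRECTIONS: dict[tuple[str, str, int], float] = {
    ("CA", "P", +1): -2.0,
    ("CB", "P", +1): 0.0,
}


@dataclass
class RandomCoilTable:
    """Per-residue-type random-coil CA/CB reference shifts in ppm.

    Parameters
    ----------
    ca, cb
        Mapping one-letter residue type -> reference shift.  ``cb`` has no
        glycine entry.
    corrections
        Additive neighbor corrections keyed ``(nucleus, neighbor_type,
        offset)`` with offset in {-1, +1}; missing keys mean zero.
    label
        Provenance of the values.
    """

    ca: dict[str, float]
    cb: dict[str, float]
    corrections: dict[tuple[str, str, int], float] = field(default_factory=dict)
    label: str = "user"

    def __post_init__(self) -> None:
        missing = sorted(set(AA1) - set(self.ca))
        if missing:
            raise ValueError(f"random-coil table lacks CA entries for {missing}")
        missing_cb = sorted(set(AA1) - {"G"} - set(self.cb))
        if missing_cb:
            raise ValueError(f"random-coil table lacks CB entries for {missing_cb}")

    def reference(
        self,
        residue_type: str,
        nucleus: str,
        neighbors: dict[int, str] | None = None,
    ) -> float:
        """Reference shift for one nucleus, with optional neighbor corrections.

        ``neighbors`` maps offset (-1 or +1) to the one-letter type of the
        sequence neighbor at that offset, when known.
        """
        if nucleus == "CA":
            base = self.ca[residue_type]
        elif nucleus == "CB":
            if residue_type == "G":
                raise KeyError("glycine has no CB reference shift")
            base = self.cb[residue_type]
        else:
            raise KeyError(f"no reference values for nucleus {nucleus!r}")
        if neighbors:
            for offset, ntype in neighbors.items():
                base += self.corrections.get((nucleus, ntype, offset), 0.0)
        return base


def wishart_1995() -> RandomCoilTable:
    """The built-in random-coil reference set (Wishart et al. 1995 values)."""
    ca = {aa: vals[0] for aa, vals in _WISHART_1995_CACB.items()}
    cb = {aa: vals[1] for aa, vals in _WISHART_1995_CACB.items() if vals[1] is not None}
    return RandomCoilTable(
        ca=ca, cb=cb, corrections=dict(_PRE_PROLINE_CORRECTIONS), label="wishart1995"
    )
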