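"""Secondary-structure region definitions used for interface typing.

The head-to-tail and zipper interfaces are argued in terms of seven regions
of the ubiquitin-like DIX fold: strands beta1..beta5 and the two loops
loop12 (beta1-beta2) and loop34 (beta3-beta4).  Rather than re-deriving a
secondary-structure assignment, the pipeline takes these residue ranges from
a small per-protein table (YAML-overridable), keyed by author residue
numbers.

The mouse and zebrafish Ccd1 ranges below are transcribed from the fold's
annotated topology and bracket every residue the interface analysis names
(e.g. Lys393 on beta1, Asn408 on beta2, Val445/Lys446/Glu447 on beta4,
Lys462/Trp466 on beta5, Asp399/Arg400/Leu402 on loop12).  They are defaults,
not measurements; supply your own YAML for other DIX proteins.
"""

from __future__ import annotations

import yaml

__all__ = ["DEFAULT_STRAND_DEFS", "load_strand_defs", "regions_for"]

DEFAULT_STRAND_DEFS: dict[str, dict[str, tuple[int, int]]] = {
    # mouse Ccd1 DIX, author numbering 388-470
    "mccd1": {
        "beta1": (391, 397),
        "loop12": (398, 404),
        "beta2": (405, 410),
        "beta3": (429, 438),
        "loop34": (439, 443),
        "beta4": (444, 448),
        "beta5": (460, 468),
    },
    # zebrafish Ccd1 DIX, author numbering 356-438 (mouse ranges shifted by -32)
    "zccd1": {
        "beta1": (359, 365),
        "loop12": (366, 372),
        "beta2": (373, 378),
        "beta3": (397, 406),
        "loop34": (407, 411),
        "beta4": (412, 416),
        "beta5": (428, 436),
    },
    # synthetic toy subunit written by dixpol.synthetic
    "toy": {
        "beta2": (1, 3),
        "beta4": (4, 6),
        "loop12": (7, 9),
        "beta1": (20, 22),
        "beta3": (23, 25),
        "loop34": (26, 28),
        "beta5": (29, 31),
    },
}


def load_strand_defs(path: str) -> dict[str, dict[str, tuple[int, int]]]:
    """Read per-protein region ranges from YAML: {protein: {region: [lo, hi]}}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out: dict[str, dict[str, tuple[int, int]]] = {}
    for protein, regions in raw.items():
        out[protein] = {k: (int(v[0]), int(v[1])) for k, v in regions.items()}
    return out


def regions_for(protein: str, defs=None) -> dict[str, tuple[int, int]]:
    table = defs or DEFAULT_STRAND_DEFS
    key = protein.lower()
    if key not in table:
        raise KeyError(
            f"no strand definitions for protein {protein!r}; "
            f"known: {sorted(table)}"
        )
    return table[key]
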