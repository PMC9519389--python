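"""The motif registry: the 17 motif classes of plant NLR receptors.

One coiled-coil motif (the extended EDVID of the CC alpha3 helix), six TIR
structural elements, the nine conserved NBS (NB-ARC) motifs that form or flank
the ADP/ATP pocket, and the LxxLxL repeat-start motif of the LRR domain.

Consensus strings use three symbol classes:

* an upper-case amino acid letter — that exact residue (an "anchor"),
* ``b`` — any hydrophobic residue ({A,V,L,I,M,F,W,Y,C}),
* ``x`` — any residue.

Consensi printed in the literature (EDVID, P-loop, Walker-B, RNBS-B/C/D, VG
frame, LxxLxL) are used verbatim; the TIR elements and RNBS-A have no
published consensus string, so the defaults below are synthetic patterns
anchored on the conserved positions that are described for them (e.g. the
catalytic Glu and neighbouring Cys at alphaC positions 1 and 4, Phe/Pro at
betaD-alphaD1 positions 4 and 9, Phe@0 and Trp@5 of RNBS-A). All lengths and
consensi are overridable through :func:`default_registry`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

from .alphabet import HYDROPHOBIC, VALID_RESIDUES
from .errors import InputError

DOMAINS = ("CC", "TIR", "NBS", "LRR")

#: Canonical NBS motif order (strictly increasing along the sequence).
NBS_ORDER = (
    "VG", "P-loop", "RNBS-A", "Walker-B", "RNBS-B",
    "RNBS-C", "GLPL", "RNBS-D", "MHD",
)

#: Canonical TIR element order.
TIR_ORDER = ("betaA", "alphaA", "betaC", "alphaC", "betaD-alphaD1", "alphaD3")


@dataclass(frozen=True)
class MotifDefinition:
    """One of the 17 motif classes.

    Attributes
    ----------
    name : str
        Motif name (registry key).
    domain : str
        One of CC, TIR, NBS, LRR.
    length : int
        Motif window length L.
    consensus : str or None
        Consensus pattern of length L over {residue letters, 'b', 'x'}.
    order_index : int or None
        Rank within the canonical NBS or TIR order; None for CC/LRR.
    """

    name: str
    domain: str
    length: int
    consensus: Optional[str] = None
    order_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise InputError(f"unknown domain {self.domain!r} for motif {self.name!r}")
        if self.length <= 0:
            raise InputError(f"motif {self.name!r}: length must be positive")
        if self.consensus is not None:
            if len(self.consensus) != self.length:
                raise InputError(
                    f"motif {self.name!r}: consensus length {len(self.consensus)} "
                    f"!= declared length {self.length}"
                )
            bad = set(self.consensus) - VALID_RESIDUES - {"b", "x"}
            if bad:
                raise InputError(
                    f"motif {self.name!r}: illegal consensus symbols {sorted(bad)}"
                )


# (name, domain, length, consensus). Order: CC, TIR, NBS, LRR.
_DEFAULTS = (
    ("EDVID", "CC", 12, "RDbbbDbEDbbD"),
    # TIR structural elements (synthetic default consensi, see module docstring).
    ("betaA", "TIR", 8, "bYDVFLSF"),
    ("alphaA", "TIR", 10, "KRDbFbSFRG"),
    ("betaC", "TIR", 8, "bbRbVIPb"),
    ("alphaC", "TIR", 10, "AEbxCbxAbx"),
    ("betaD-alphaD1", "TIR", 12, "bxWbFGxbxPbE"),
    ("alphaD3", "TIR", 15, "WbxxbAbbELxxxbx"),
    # NBS (NB-ARC) motifs in canonical order.
    ("VG", "NBS", 6, "bbVGxx"),
    ("P-loop", "NBS", 9, "GbGGbGKTT"),
    ("RNBS-A", "NBS", 7, "FxbbxWb"),
    ("Walker-B", "NBS", 11, "KRFbbbbDDbW"),
    ("RNBS-B", "NBS", 7, "KbbbTTR"),
    ("RNBS-C", "NBS", 10, "LxxxExWxLF"),
    ("GLPL", "NBS", 4, "GLPL"),
    ("RNBS-D", "NBS", 9, "CFbYCxLFP"),
    ("MHD", "NBS", 3, "MHD"),
    ("LxxLxL", "LRR", 6, "bxxbxb"),
)


def default_registry(
    overrides: Optional[Mapping[str, Mapping[str, object]]] = None,
) -> tuple[MotifDefinition, ...]:
    """Return the 17 motif definitions (a fresh immutable tuple).

    Parameters
    ----------
    overrides : mapping, optional
        Per-motif field overrides, e.g. ``{"alphaD3": {"length": 16,
        "consensus": None}}``. Overriding creates a new registry; the default
        one is never mutated.
    """
    defs = []
    for name, domain, length, consensus in _DEFAULTS:
        order = None
        if domain == "NBS":
            order = NBS_ORDER.index(name)
        elif domain == "TIR":
            order = TIR_ORDER.index(name)
        d = MotifDefinition(name, domain, length, consensus, order)
        if overrides and name in overrides:
            d = replace(d, **dict(overrides[name]))
        defs.append(d)
    return tuple(defs)


def registry_by_name(
    registry: Iterable[MotifDefinition],
) -> dict[str, MotifDefinition]:
    return {d.name: d for d in registry}


def get_definition(name: str, registry: Optional[Iterable[MotifDefinition]] = None) -> MotifDefinition:
    table = registry_by_name(registry if registry is not None else default_registry())
    try:
        return table[name]
    except KeyError:
        raise InputError(f"unknown motif {name!r}") from None


def matches_consensus(window: str, definition: MotifDefinition) -> bool:
    """True iff `window` matches `definition.consensus` position by position.

    'b' matches any hydrophobic residue, 'x' matches anything; a residue
    letter matches only itself. Raises on length mismatch or when the
    definition has no consensus.
    """
    if definition.consensus is None:
        raise InputError(f"motif {definition.name!r} has no consensus pattern")
    if len(window) != definition.length:
        raise InputError(
            f"window length {len(window)} != motif {definition.name!r} "
            f"length {definition.length}"
        )
    for ch, pat in zip(window, definition.consensus):
        if pat == "x":
            continue
        if pat == "b":
            if ch not in HYDROPHOBIC:
                return False
        elif ch != pat:
            return False
    return True


def save_registry(registry: Iterable[MotifDefinition], path) -> None:
    """Serialize a registry to JSON (name, domain, length, consensus, order)."""
    payload = [
        {
            "name": d.name,
            "domain": d.domain,
            "length": d.length,
            "consensus": d.consensus,
            "order_index": d.order_index,
        }
        for d in registry
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_registry(path) -> tuple[MotifDefinition, ...]:
    with open(path) as fh:
        payload = json.load(fh)
    return tuple(
        MotifDefinition(
            e["name"], e["domain"], e["length"], e.get("consensus"),
            e.get("order_index"),
        )
        for e in payload
    )
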