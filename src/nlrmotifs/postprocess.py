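"""From per-residue probabilities to motif calls, domain layouts and classes.

The rules implemented here mirror how integral NLRs are recognized from raw
per-residue predictions:

* a motif is called at every local probability maximum strictly above 80%;
* nearby competing "satellite" calls (< 15 aa apart) are resolved when their
  probabilities differ by more than 20 percentage points, otherwise both are
  kept and flagged ambiguous;
* a valid NBS layout requires all nine NBS motifs exactly once, in canonical
  order (VG < P-loop < RNBS-A < Walker-B < RNBS-B < RNBS-C < GLPL < RNBS-D
  < MHD);
* an LRR ladder is accepted when it starts within a < 50 aa linker downstream
  of the NBS, spaces consecutive LxxLxL starts by 15-50 aa and counts at
  least 9 repeats (5 for CNL-oriented analyses);
* sequences are classified CNL / TNL / NL / other from which modules fired
  and in which order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import InputError
from .registry import (
    NBS_ORDER,
    TIR_ORDER,
    default_registry,
    registry_by_name,
)

CALL_THRESHOLD = 0.80
SATELLITE_WINDOW = 15
SATELLITE_MARGIN = 0.20


@dataclass(frozen=True)
class MotifCall:
    """A predicted motif start."""

    seqid: str
    motif: str
    start: int  # 0-based
    probability: float
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise InputError("call probability must be in [0, 1]")
        if self.start < 0:
            raise InputError("call start must be non-negative")


@dataclass
class DomainAnnotation:
    """Per-sequence motif calls grouped by domain, with layout validity."""

    seqid: str
    calls_by_domain: dict[str, list[MotifCall]]
    nbs_valid: bool = False
    reasons: list[str] = field(default_factory=list)
    linker_lengths: dict[str, int] = field(default_factory=dict)

    def all_calls(self) -> list[MotifCall]:
        out: list[MotifCall] = []
        for calls in self.calls_by_domain.values():
            out.extend(calls)
        return sorted(out, key=lambda c: c.start)


@dataclass
class LRRLadder:
    """Accepted LxxLxL starts with repeat lengths and ladder indices."""

    seqid: str
    starts: list[int]
    repeat_lengths: list[Optional[int]]  # last repeat open-ended (None)
    ladder_indices: list[int]

    def __len__(self) -> int:
        return len(self.starts)


@dataclass
class NLRClass:
    """Architecture classification with the evidence that produced it."""

    label: str  # CNL | TNL | NL | other
    evidence: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def call_motifs(
    probs: np.ndarray,
    seqid: str,
    motif: str,
    threshold: float = CALL_THRESHOLD,
) -> list[MotifCall]:
    """One call per local maximum with probability strictly above `threshold`.

    A local maximum is a position whose probability is >= both neighbours;
    on a plateau of equal values only the leftmost position is called.
    """
    p = np.asarray(probs, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise InputError("probability vector outside [0, 1]")
    calls: list[MotifCall] = []
    n = len(p)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and p[j + 1] == p[i]:
            j += 1
        left = p[i - 1] if i > 0 else -np.inf
        right = p[j + 1] if j + 1 < n else -np.inf
        if p[i] > threshold and p[i] >= left and p[i] >= right:
            calls.append(MotifCall(seqid, motif, i, float(p[i])))
        i = j + 1
    return calls


def resolve_satellites(
    calls: Sequence[MotifCall],
    window: int = SATELLITE_WINDOW,
    margin: float = SATELLITE_MARGIN,
) -> list[MotifCall]:
    """Resolve competing same-motif calls closer than `window` residues.

    Within any conflicting pair, a probability difference above `margin`
    keeps only the stronger call; otherwise both survive but are flagged
    ambiguous. The operation is idempotent.
    """
    motifs = {c.motif for c in calls}
    if len(motifs) > 1:
        raise InputError("resolve_satellites expects calls of a single motif class")
    live = sorted(calls, key=lambda c: (c.start, -c.probability))
    changed = True
    while changed:
        changed = False
        for a_idx in range(len(live) - 1):
            b_idx = a_idx + 1
            a, b = live[a_idx], live[b_idx]
            if b.start - a.start < window and abs(a.probability - b.probability) > margin:
                weaker = a_idx if a.probability < b.probability else b_idx
                del live[weaker]
                changed = True
                break
    out: list[MotifCall] = []
    for idx, c in enumerate(live):
        near = (
            (idx > 0 and c.start - live[idx - 1].start < window)
            or (idx + 1 < len(live) and live[idx + 1].start - c.start < window)
        )
        out.append(replace(c, ambiguous=bool(near or c.ambiguous)))
    return out


def validate_nbs_layout(calls: Sequence[MotifCall]) -> DomainAnnotation:
    """Check the nine-NBS-motif layout: each exactly once, strictly in order.

    Invalid layouts come back with machine-readable reasons:
    ``missing:X``, ``duplicated:X``, ``disordered:X|Y``.
    """
    registry = registry_by_name(default_registry())
    by_domain: dict[str, list[MotifCall]] = {}
    seqid = calls[0].seqid if calls else ""
    for c in calls:
        dom = registry[c.motif].domain if c.motif in registry else None
        if dom is None:
            raise InputError(f"call references unknown motif {c.motif!r}")
        by_domain.setdefault(dom, []).append(c)
    nbs = sorted(by_domain.get("NBS", []), key=lambda c: c.start)
    reasons: list[str] = []
    seen: dict[str, int] = {}
    for c in nbs:
        seen[c.motif] = seen.get(c.motif, 0) + 1
    for name in NBS_ORDER:
        k = seen.get(name, 0)
        if k == 0:
            reasons.append(f"missing:{name}")
        elif k > 1:
            reasons.append(f"duplicated:{name}")
    if not reasons:
        starts = {c.motif: c.start for c in nbs}
        for i, a in enumerate(NBS_ORDER):
            for b in NBS_ORDER[i + 1:]:
                if not starts[a] < starts[b]:
                    reasons.append(f"disordered:{a}|{b}")
    return DomainAnnotation(
        seqid=seqid,
        calls_by_domain=by_domain,
        nbs_valid=not reasons,
        reasons=reasons,
    )


def delineate_lrr_ladder(
    calls: Sequence[MotifCall],
    nbs_annotation: Optional[DomainAnnotation] = None,
    min_repeats: int = 9,
    max_linker: int = 50,
    min_len: int = 15,
    max_len: int = 50,
    registry=None,
) -> tuple[Optional[LRRLadder], Optional[str]]:
    """Accept or reject an LRR repeat ladder from satellite-resolved calls.

    Returns ``(ladder, None)`` on acceptance or ``(None, reason)`` with
    reasons ``linker``, ``too-few:<n>``, ``short-repeat:<i>``,
    ``long-repeat:<i>`` (i = 1-based repeat index of the offending spacing).
    """
    table = registry_by_name(registry if registry is not None else default_registry())
    lrr = sorted((c for c in calls if c.motif == "LxxLxL"), key=lambda c: c.start)
    if not lrr:
        return None, "too-few:0"
    seqid = lrr[0].seqid
    if nbs_annotation is not None:
        if not nbs_annotation.nbs_valid:
            raise InputError("linker rule requires a valid NBS annotation")
        mhd = next(
            c for c in nbs_annotation.calls_by_domain["NBS"] if c.motif == "MHD"
        )
        mhd_end = mhd.start + table["MHD"].length
        linker = lrr[0].start - mhd_end
        if linker >= max_linker:
            return None, "linker"
    starts = [c.start for c in lrr]
    for i, (a, b) in enumerate(zip(starts, starts[1:]), start=1):
        d = b - a
        if d < min_len:
            return None, f"short-repeat:{i}"
        if d > max_len:
            return None, f"long-repeat:{i}"
    if len(starts) < min_repeats:
        return None, f"too-few:{len(starts)}"
    lengths: list[Optional[int]] = [b - a for a, b in zip(starts, starts[1:])]
    lengths.append(None)  # the last repeat is open-ended
    return (
        LRRLadder(
            seqid=seqid,
            starts=starts,
            repeat_lengths=lengths,
            ladder_indices=list(range(1, len(starts) + 1)),
        ),
        None,
    )


def classify_nlr(
    annotation: DomainAnnotation,
    ladder: Optional[LRRLadder] = None,
) -> NLRClass:
    """CNL / TNL / NL / other from the per-domain evidence.

    TNL requires all six TIR motifs in order upstream of a valid NBS; CNL an
    extended-EDVID call upstream of a valid NBS; NL a valid NBS without
    either. TIR takes precedence when both fire (flagged). An EDVID call
    downstream of the NBS flags a shuffled layout.
    """
    evidence: list[str] = []
    flags: list[str] = []
    if not annotation.nbs_valid:
        return NLRClass("other", evidence=["nbs-invalid"] + annotation.reasons)
    nbs_calls = sorted(annotation.calls_by_domain["NBS"], key=lambda c: c.start)
    nbs_start = nbs_calls[0].start
    evidence.append("nbs-valid")
    if ladder is not None:
        evidence.append(f"lrr-ladder:{len(ladder)}")

    cc = [c for c in annotation.calls_by_domain.get("CC", []) if c.motif == "EDVID"]
    cc_upstream = any(c.start < nbs_start for c in cc)
    if cc and not cc_upstream:
        flags.append("shuffled")

    tir = annotation.calls_by_domain.get("TIR", [])
    tir_names = {c.motif for c in tir}
    tir_complete = all(name in tir_names for name in TIR_ORDER)
    tir_ok = False
    if tir_complete:
        starts = {c.motif: c.start for c in sorted(tir, key=lambda c: c.start)}
        ordered = all(
            starts[a] < starts[b] for a, b in zip(TIR_ORDER, TIR_ORDER[1:])
        )
        tir_ok = ordered and max(starts.values()) < nbs_start

    if tir_ok:
        evidence.append("tir-complete")
        if cc_upstream:
            flags.append("cc-and-tir")
        return NLRClass("TNL", evidence=evidence, flags=flags)
    if cc_upstream:
        evidence.append("edvid-upstream")
        return NLRClass("CNL", evidence=evidence, flags=flags)
    if flags and "shuffled" in flags:
        return NLRClass("other", evidence=evidence, flags=flags)
    return NLRClass("NL", evidence=evidence, flags=flags)
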