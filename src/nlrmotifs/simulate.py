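"""Synthetic sequence generators with ground truth.

Everything the test-bed needs is generated here: labeled motif training sets,
full synthetic NLR proteins (CNL/TNL/NL layouts with planted motifs, linkers
and LRR ladders), focused profile databases with family structure, planted
physico-chemical LRR motif classes, and covarying alignments.

Design notes
------------
* Background residues are drawn from the BLOSUM62 marginal frequencies,
  matching the background model of the profiles module.
* Motifs are planted as consensus-conforming windows; hydrophobic 'b'
  positions are sampled from {L,I,V,M,F} (LRR repeats: leucine-dominant),
  'x' positions from the background. Noise mu then perturbs each non-anchor
  position independently with probability mu — class-preservingly: a 'b'
  position is redrawn uniformly from the full hydrophobic class (eroding the
  sampling bias while keeping the motif a motif, as in curated motif sets,
  which only contain delineated conforming motifs), an 'x' position is
  redrawn from the background. Fixed anchor residues are never touched, so
  every planted window matches its consensus at any mu.
* LRR repeats carry the canonical extended repeat context beyond the 6-mer
  (LxxLxLxx[N/T/S]xL), which is what makes repeat-start prediction from
  sequence well-posed.
* All randomness flows through one seeded numpy Generator per call; no
  global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alphabet import AMINO_ACIDS, BACKGROUND, HYDROPHOBIC
from .errors import InputError
from .profiles import FocusedDB
from .registry import (
    MotifDefinition,
    NBS_ORDER,
    TIR_ORDER,
    default_registry,
    registry_by_name,
)
from .seqio import SequenceRecord

_AA = np.array(list(AMINO_ACIDS))
_B_DEFAULT = "LIVMF"


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions of the synthetic NLR generator."""

    seed: int = 0
    n: int = 100
    layout: str = "CNL"
    mu: float = 0.1
    nter_pad_range: tuple[int, int] = (20, 60)
    cc_pad_range: tuple[int, int] = (30, 80)
    tir_spacer_range: tuple[int, int] = (10, 25)
    nbs_spacer_range: tuple[int, int] = (15, 35)
    linker_range: tuple[int, int] = (10, 49)
    repeat_range: tuple[int, int] = (15, 50)
    n_repeats_range: tuple[int, int] = (9, 14)
    satellite_rate: float = 0.0
    cter_pad_range: tuple[int, int] = (5, 30)
    lrr_leucine_prob: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise InputError("mu must be in [0, 1]")
        for name in (
            "nter_pad_range", "cc_pad_range", "tir_spacer_range",
            "nbs_spacer_range", "linker_range", "repeat_range",
            "n_repeats_range", "cter_pad_range",
        ):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise InputError(f"invalid range {name}={lo, hi}")


@dataclass
class GroundTruth:
    """Planted annotation of one synthetic sequence."""

    seqid: str
    motif_starts: dict[str, list[int]] = field(default_factory=dict)
    ladder_starts: list[int] = field(default_factory=list)
    ladder_indices: list[int] = field(default_factory=list)
    satellites: list[int] = field(default_factory=list)
    nlr_class: str = "other"


def _bg(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(_AA[rng.choice(20, size=n, p=BACKGROUND)])


def sample_consensus(
    definition: MotifDefinition,
    rng: np.random.Generator,
    b_choices: str = _B_DEFAULT,
    leucine_prob: Optional[float] = None,
) -> str:
    """A consensus-conforming window ('b' from b_choices, 'x' background)."""
    if definition.consensus is None:
        raise InputError(f"motif {definition.name!r} has no consensus to sample")
    out = []
    for pat in definition.consensus:
        if pat == "x":
            out.append(_bg(rng, 1))
        elif pat == "b":
            if leucine_prob is not None and rng.random() < leucine_prob:
                out.append("L")
            else:
                out.append(b_choices[rng.integers(len(b_choices))])
        else:
            out.append(pat)
    return "".join(out)


_HYDROPHOBIC_STR = "".join(sorted(HYDROPHOBIC))


def _apply_noise(
    window: str, definition: MotifDefinition, mu: float, rng: np.random.Generator
) -> str:
    """Class-preserving per-position noise at the non-anchor positions.

    Each 'b' position is redrawn uniformly within the hydrophobic class with
    probability mu, each 'x' position is redrawn from the background; fixed
    anchor residues are never perturbed, so the window keeps matching its
    consensus.
    """
    if mu <= 0:
        return window
    chars = list(window)
    for i, pat in enumerate(definition.consensus):
        if rng.random() >= mu:
            continue
        if pat == "b":
            chars[i] = _HYDROPHOBIC_STR[rng.integers(len(_HYDROPHOBIC_STR))]
        elif pat == "x":
            chars[i] = _bg(rng, 1)
    return "".join(chars)


def _plant(definition, rng, mu, b_choices=_B_DEFAULT, leucine_prob=None) -> str:
    w = sample_consensus(definition, rng, b_choices, leucine_prob)
    return _apply_noise(w, definition, mu, rng)


def generate_motif_dataset(
    definition: MotifDefinition,
    n: int,
    mu: float,
    seed: int,
    length: int = 300,
    b_choices: str = _B_DEFAULT,
) -> tuple[list[SequenceRecord], dict[str, list[int]]]:
    """Background sequences with one planted motif each, plus true starts.

    Each sequence has one consensus-conforming window planted at a uniform
    random position, then per-position noise ``mu`` applied to its non-anchor
    positions. Deterministic for a fixed seed.
    """
    if n < 10:
        raise InputError("need at least 10 sequences for a motif dataset")
    if length <= definition.length:
        raise InputError("sequence length must exceed the motif length")
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    truth: dict[str, list[int]] = {}
    for i in range(n):
        seqid = f"{definition.name}_{i:05d}"
        start = int(rng.integers(0, length - definition.length + 1))
        seq = list(_bg(rng, length))
        seq[start: start + definition.length] = _plant(definition, rng, mu, b_choices)
        records.append(SequenceRecord(seqid, "".join(seq)))
        truth[seqid] = [start]
    return records, truth


_LRR_CONTEXT_POLAR = "NTS"


def _emit_repeat(
    lrr_def: MotifDefinition,
    rep_len: int,
    spec: GeneratorSpec,
    rng: np.random.Generator,
) -> str:
    """One LRR repeat: LxxLxLxx[NTS]xL + background tail, length rep_len."""
    motif = _plant(lrr_def, rng, spec.mu, leucine_prob=spec.lrr_leucine_prob)
    chars = list(motif + _bg(rng, rep_len - len(motif)))
    if rep_len > 8:
        chars[8] = _LRR_CONTEXT_POLAR[rng.integers(3)]
    if rep_len > 10:
        chars[10] = (
            "L" if rng.random() < spec.lrr_leucine_prob
            else _B_DEFAULT[rng.integers(len(_B_DEFAULT))]
        )
    return "".join(chars)


def generate_nlr(
    layout: str,
    spec: Optional[GeneratorSpec] = None,
    rng: Optional[np.random.Generator] = None,
    seqid: str = "nlr",
    registry=None,
) -> tuple[SequenceRecord, GroundTruth]:
    """One synthetic NLR protein with planted motifs and ground truth.

    ``layout`` is CNL (EDVID + NBS + ladder), TNL (6 TIR + NBS + ladder) or
    NL (NBS + ladder).
    """
    if layout not in ("CNL", "TNL", "NL"):
        raise InputError(f"unknown layout {layout!r}")
    spec = spec or GeneratorSpec(layout=layout)
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    table = registry_by_name(registry if registry is not None else default_registry())
    truth = GroundTruth(seqid=seqid, nlr_class=layout)
    parts: list[str] = []
    pos = 0

    def emit(s: str) -> None:
        nonlocal pos
        parts.append(s)
        pos += len(s)

    def emit_motif(name: str, leucine_prob=None) -> None:
        d = table[name]
        truth.motif_starts.setdefault(name, []).append(pos)
        emit(_plant(d, rng, spec.mu, leucine_prob=leucine_prob))

    def rint(rg: tuple[int, int]) -> int:
        return int(rng.integers(rg[0], rg[1] + 1))

    emit(_bg(rng, rint(spec.nter_pad_range)))
    if layout == "CNL":
        emit_motif("EDVID")
        emit(_bg(rng, rint(spec.cc_pad_range)))
    elif layout == "TNL":
        for name in TIR_ORDER:
            emit_motif(name)
            emit(_bg(rng, rint(spec.tir_spacer_range)))
    for name in NBS_ORDER:
        emit_motif(name)
        if name != "MHD":
            emit(_bg(rng, rint(spec.nbs_spacer_range)))
    emit(_bg(rng, rint(spec.linker_range)))

    lrr_def = table["LxxLxL"]
    k = rint(spec.n_repeats_range)
    for r in range(k):
        rep_len = rint(spec.repeat_range)
        start = pos
        truth.motif_starts.setdefault("LxxLxL", []).append(start)
        truth.ladder_starts.append(start)
        truth.ladder_indices.append(r + 1)
        repeat = _emit_repeat(lrr_def, rep_len, spec, rng)
        if spec.satellite_rate > 0 and rng.random() < spec.satellite_rate:
            hi = min(14, rep_len - lrr_def.length)
            if hi >= 6:
                delta = int(rng.integers(6, hi + 1))
                decoy = sample_consensus(
                    lrr_def, rng, b_choices="".join(sorted(HYDROPHOBIC))
                )
                repeat = (
                    repeat[:delta] + decoy + repeat[delta + lrr_def.length:]
                )
                truth.satellites.append(start + delta)
        emit(repeat)
    emit(_bg(rng, rint(spec.cter_pad_range)))
    return SequenceRecord(seqid, "".join(parts)), truth


def generate_nlr_set(
    layout: str,
    n: int,
    seed: int,
    spec: Optional[GeneratorSpec] = None,
) -> tuple[list[SequenceRecord], list[GroundTruth]]:
    """n synthetic NLRs of one layout, driven by a single seeded generator."""
    spec = spec or GeneratorSpec(layout=layout, seed=seed)
    rng = np.random.default_rng(seed)
    records, truths = [], []
    for i in range(n):
        rec, truth = generate_nlr(layout, spec, rng, seqid=f"{layout}_{i:05d}")
        records.append(rec)
        truths.append(truth)
    return records, truths


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < rate
    n_hit = int(hit.sum())
    if n_hit:
        chars[hit] = _AA[rng.choice(20, size=n_hit, p=BACKGROUND)]
    return "".join(chars)


def generate_focused_db(
    n_nlr: int = 150,
    n_lrr: int = 100,
    seed: int = 0,
    mutation_rate: float = 0.2,
) -> FocusedDB:
    """A focused profile database with family structure.

    ``n_nlr`` NLR-like entries of >= 500 aa and ``n_lrr`` LRR-domain entries
    of >= 200 aa, generated as noisy copies of a small number of archetypes
    so that profile searches can find homolog families.
    """
    rng = np.random.default_rng(seed)
    n_arch_nlr = max(1, n_nlr // 10)
    n_arch_lrr = max(1, n_lrr // 10)
    spec = GeneratorSpec(mu=0.05, n_repeats_range=(9, 14))
    layouts = ("CNL", "TNL", "NL")
    nlr_arch: list[str] = []
    for i in range(n_arch_nlr):
        rec, _ = generate_nlr(layouts[i % 3], spec, rng, seqid=f"arch{i}")
        seq = rec.residues
        if len(seq) < 500:
            seq += _bg(rng, 500 - len(seq))
        nlr_arch.append(seq)
    lrr_def = registry_by_name(default_registry())["LxxLxL"]
    lrr_arch: list[str] = []
    for i in range(n_arch_lrr):
        k = int(rng.integers(9, 15))
        seq = _bg(rng, int(rng.integers(10, 30)))
        for _ in range(k):
            seq += _emit_repeat(lrr_def, int(rng.integers(18, 30)), spec, rng)
        if len(seq) < 200:
            seq += _bg(rng, 200 - len(seq))
        lrr_arch.append(seq)
    records = []
    for i in range(n_nlr):
        base = nlr_arch[i % n_arch_nlr]
        records.append(
            SequenceRecord(f"nlrdb{i:04d}", _mutate(base, mutation_rate, rng))
        )
    for i in range(n_lrr):
        base = lrr_arch[i % n_arch_lrr]
        records.append(
            SequenceRecord(f"lrrdb{i:04d}", _mutate(base, mutation_rate, rng))
        )
    return FocusedDB(
        records,
        metadata={"n_nlr": n_nlr, "n_lrr": n_lrr, "seed": seed,
                  "synthetic": True},
    )


#: Charge placements defining the planted LRR motif classes (position in the
#: LxxLxL frame, class residue). Mirrors the observed class structure: Lys or
#: Arg in position 1, Asp/Lys in position 4, Glu/Arg in position 2.
_LRR_CLASS_TEMPLATES = (
    (1, "K"),
    (4, "D"),
    (2, "E"),
    (1, "R"),
    (4, "K"),
    (2, "R"),
)


def generate_planted_lrr_classes(
    k_classes: int,
    n_per_class: int = 200,
    sigma: float = 0.05,
    seed: int = 0,
) -> tuple[list[str], np.ndarray]:
    """LxxLxL 6-mers with planted charge classes at exposed positions 1/2/4.

    Each class is a tight cloud around one template (leucines at the
    structural positions 0/3/5, serine at unmarked exposed positions, the
    class-defining charged residue at its position). ``sigma`` is the
    per-window residue-jitter probability: with probability sigma one random
    position is replaced (structural positions by a random hydrophobic
    residue, exposed ones by a random residue).
    """
    if not 1 <= k_classes <= len(_LRR_CLASS_TEMPLATES):
        raise InputError(f"k_classes must be in [1, {len(_LRR_CLASS_TEMPLATES)}]")
    rng = np.random.default_rng(seed)
    windows: list[str] = []
    labels: list[int] = []
    for cls in range(k_classes):
        pos, residue = _LRR_CLASS_TEMPLATES[cls]
        for _ in range(n_per_class):
            chars = []
            for p in range(6):
                if p in (0, 3, 5):
                    chars.append("L")
                elif p == pos:
                    chars.append(residue)
                else:
                    chars.append("S")
            if rng.random() < sigma:
                p = int(rng.integers(6))
                if p in (0, 3, 5):
                    chars[p] = _B_DEFAULT[rng.integers(len(_B_DEFAULT))]
                else:
                    chars[p] = str(_bg(rng, 1))
            windows.append("".join(chars))
            labels.append(cls)
    return windows, np.array(labels)


def generate_covarying_alignment(
    n_rows: int,
    n_cols: int,
    pair: tuple[int, int],
    coupling: float,
    seed: int,
) -> list[str]:
    """Background alignment with one planted 2-state covarying column pair.

    The planted columns are binary (A/C and D/K); per row a hidden state
    picks the coupled letters, and the second column follows the state with
    probability ``coupling`` (1 = perfect covariation, 0 = independence).
    """
    i, j = pair
    if not (0 <= i < n_cols and 0 <= j < n_cols) or i == j:
        raise InputError("planted pair must be two distinct columns in range")
    if not 0.0 <= coupling <= 1.0:
        raise InputError("coupling must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_rows):
        chars = list(_bg(rng, n_cols))
        state = rng.random() < 0.5
        chars[i] = "A" if state else "C"
        if rng.random() < coupling:
            chars[j] = "D" if state else "K"
        else:
            chars[j] = "D" if rng.random() < 0.5 else "K"
        rows.append("".join(chars))
    return rows
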