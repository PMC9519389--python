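"""Fixed-length per-candidate feature vectors from profile features.

A candidate window for a motif of length L at position ``pos`` spans
``[pos - flank, pos + L + flank)``; with the default 5-residue flanks and two
profile iterations this yields 20 x 2 x (5 + L + 5) = 40*(L+10) features.
Positions outside the sequence are padded with the background block, so every
residue of a sequence is a scoreable candidate. Feature ordering is fixed:
position-major, then iteration (1, 2), then alphabetical amino acid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .profiles import ProfileFeatures, background_block
from .registry import MotifDefinition

DEFAULT_FLANK = 5


def window_dim(definition: MotifDefinition, flank: int = DEFAULT_FLANK,
               iterations: int = 2) -> int:
    """Flat feature dimensionality: 20 * iterations * (flank + L + flank)."""
    return 20 * iterations * (definition.length + 2 * flank)


@dataclass(frozen=True)
class WindowVector:
    """One candidate: sequence id, 0-based start position, motif, features."""

    seqid: str
    pos: int
    motif: str
    vector: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vector)):
            raise InputError("window vector contains non-finite entries")


def _padded_matrix(features: ProfileFeatures, definition: MotifDefinition,
                   flank: int) -> np.ndarray:
    """Feature matrix padded with background blocks on both borders."""
    n_it = features.matrix.shape[1]
    bg = background_block(n_it)[None, :, :]
    front = np.repeat(bg, flank, axis=0)
    back = np.repeat(bg, definition.length + flank - 1, axis=0)
    return np.concatenate([front, features.matrix, back], axis=0)


def window_matrix(features: ProfileFeatures, definition: MotifDefinition,
                  flank: int = DEFAULT_FLANK) -> np.ndarray:
    """All candidate windows at once: shape (sequence length, 40*(L+10)).

    Row ``i`` is the flat window vector anchored at position ``i``.
    """
    width = definition.length + 2 * flank
    padded = _padded_matrix(features, definition, flank)
    flat = padded.reshape(padded.shape[0], -1)  # (Lpad, it*20), position-major
    view = np.lib.stride_tricks.sliding_window_view(flat, (width, flat.shape[1]))
    return view[:, 0].reshape(features.length, -1).astype(np.float32, copy=False)


def extract_window(features: ProfileFeatures, pos: int,
                   definition: MotifDefinition,
                   flank: int = DEFAULT_FLANK) -> WindowVector:
    """The feature vector of the candidate at `pos` (border-padded)."""
    if not 0 <= pos < features.length:
        raise InputError(
            f"candidate position {pos} outside sequence of length {features.length}"
        )
    width = definition.length + 2 * flank
    padded = _padded_matrix(features, definition, flank)
    block = padded[pos : pos + width]
    return WindowVector(features.seqid, pos, definition.name, block.reshape(-1))


def enumerate_candidates(features: ProfileFeatures,
                         definition: MotifDefinition,
                         flank: int = DEFAULT_FLANK) -> list[WindowVector]:
    """One WindowVector per residue position (every position is a candidate)."""
    mat = window_matrix(features, definition, flank)
    return [
        WindowVector(features.seqid, i, definition.name, mat[i])
        for i in range(features.length)
    ]
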