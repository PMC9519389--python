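"""Downstream motif analytics: chimeras, clustering, logos, LRR embeddings.

* Motif chimeras: the regions conveying each motif plus 5 flanking positions
  on both sides, excised and concatenated in canonical order; used for
  sequence-identity clustering of NBS / TIR+NBS / CNL motif complements.
* Identity clustering: pairwise ungapped identity between fixed-layout
  chimeras, edges at or above the threshold, clusters = connected components.
* Column conservation: per-column relative entropy (bits) against the
  BLOSUM62 background, and the derived logo matrix.
* LRR physico-chemical embedding: hydropathy (Kyte-Doolittle), formal charge
  (K/R +1, D/E -1, H +0.1) and residue volume (Zamyatnin) for each of the six
  LxxLxL positions — an 18-dimensional space, z-scored across the dataset and
  clustered with OPTICS (Xi extraction, Minkowski-2 metric).
* Ladder-position distributions: percentage of each motif cluster per
  position of the LRR repeat ladder, columns normalized to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import OPTICS

from .alphabet import AMINO_ACIDS, AA_INDEX, BACKGROUND
from .errors import InputError
from .postprocess import DomainAnnotation, MotifCall
from .registry import default_registry, registry_by_name
from .seqio import SequenceRecord

# Kyte-Doolittle hydropathy.
HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# Formal side-chain charge at neutral pH (His partially protonated).
CHARGE = {a: 0.0 for a in AMINO_ACIDS}
CHARGE.update({"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0, "H": 0.1})

# Zamyatnin residue volumes (A^3).
VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}

_SCALE_MEANS = {
    "hydropathy": float(np.mean([HYDROPATHY[a] for a in AMINO_ACIDS])),
    "charge": float(np.mean([CHARGE[a] for a in AMINO_ACIDS])),
    "volume": float(np.mean([VOLUME[a] for a in AMINO_ACIDS])),
}


@dataclass
class Chimera:
    """Concatenation of (5-flank + motif + 5-flank) segments in canonical order."""

    seqid: str
    sequence: str
    boundaries: list[int]  # segment boundary indices, length = n_segments + 1
    motifs: list[str]

    def __post_init__(self) -> None:
        if self.boundaries[0] != 0 or self.boundaries[-1] != len(self.sequence):
            raise InputError("chimera boundaries inconsistent with sequence length")
        if len(self.boundaries) != len(self.motifs) + 1:
            raise InputError("chimera boundary list must have n_segments + 1 entries")


@dataclass
class ClusterAssignment:
    """Item -> cluster label (-1 = noise); labels are dense non-negative ints."""

    ids: list[str]
    labels: np.ndarray
    method: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.labels):
            raise InputError("cluster assignment ids/labels length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "cluster": self.labels})


def excise_chimera(
    record: SequenceRecord,
    annotation: DomainAnnotation,
    motifs: Sequence[str],
    flank: int = 5,
    registry=None,
) -> Chimera:
    """Excise (flank + motif + flank) segments and concatenate them in order.

    ``motifs`` lists the motif complement of the analysis (e.g. the 9 NBS
    motifs, 6 TIR + 9 NBS, or EDVID + 9 NBS + first five LxxLxL). Flanks
    reaching outside the sequence are padded with 'X'. For motifs with
    multiple calls the calls are consumed in positional order.
    """
    table = registry_by_name(registry if registry is not None else default_registry())
    calls = sorted(annotation.all_calls(), key=lambda c: c.start)
    pool: dict[str, list[MotifCall]] = {}
    for c in calls:
        pool.setdefault(c.motif, []).append(c)
    segments: list[str] = []
    boundaries = [0]
    names: list[str] = []
    seq = record.residues
    for name in motifs:
        if name not in table:
            raise InputError(f"unknown motif {name!r} in chimera layout")
        if not pool.get(name):
            raise InputError(
                f"sequence {record.id!r} has no remaining call for motif {name!r}"
            )
        call = pool[name].pop(0)
        length = table[name].length
        lo = call.start - flank
        hi = call.start + length + flank
        left_pad = "X" * max(0, -lo)
        right_pad = "X" * max(0, hi - len(seq))
        segment = left_pad + seq[max(0, lo): min(len(seq), hi)] + right_pad
        segments.append(segment)
        names.append(name)
        boundaries.append(boundaries[-1] + len(segment))
    return Chimera(record.id, "".join(segments), boundaries, names)


def pairwise_identity(a: str, b: str) -> float:
    """Ungapped identity = matches / aligned length for equal-length strings."""
    if len(a) != len(b):
        raise InputError("identity requires equal-length sequences")
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "X")
    return matches / len(a)


def cluster_by_identity(
    chimeras: Sequence[Chimera],
    identity_threshold: float,
) -> ClusterAssignment:
    """Connected-component clustering of fixed-layout chimeras.

    Edges connect pairs with ungapped identity >= threshold; clusters are the
    connected components, labelled densely in order of first occurrence.
    """
    if len(chimeras) < 2:
        raise InputError("need at least 2 chimeras to cluster")
    layouts = {tuple(c.motifs) for c in chimeras}
    if len(layouts) > 1:
        raise InputError("chimeras have mixed motif layouts")
    lengths = {len(c.sequence) for c in chimeras}
    if len(lengths) > 1:
        raise InputError("chimeras have unequal lengths")
    n = len(chimeras)
    seqs = [np.frombuffer(c.sequence.encode(), dtype=np.uint8) for c in chimeras]
    mat = np.stack(seqs)
    x_code = ord("X")
    rows, cols = [], []
    for i in range(n):
        eq = (mat[i + 1:] == mat[i]) & (mat[i] != x_code)
        ident = eq.mean(axis=1)
        hits = np.nonzero(ident >= identity_threshold)[0]
        for j in hits:
            rows.append(i)
            cols.append(i + 1 + j)
    graph = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    _, raw = connected_components(graph, directed=False)
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        labels[i] = relabel.setdefault(int(r), len(relabel))
    return ClusterAssignment(
        [c.seqid for c in chimeras],
        labels,
        method={"algorithm": "connected-components", "identity": identity_threshold},
    )


def column_relative_entropy(
    sequences: Sequence[str],
    weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-column relative entropy (bits) against the background frequencies.

    Gaps and 'X' are excluded from the counts; a column without any standard
    residue scores 0.
    """
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise InputError("relative entropy requires equal-length sequences")
    (length,) = lengths
    if weights is None:
        weights = np.ones(len(sequences))
    weights = np.asarray(weights, dtype=float)
    out = np.zeros(length)
    for c in range(length):
        freq = np.zeros(20)
        for s, w in zip(sequences, weights):
            idx = AA_INDEX.get(s[c])
            if idx is not None:
                freq[idx] += w
        total = freq.sum()
        if total <= 0:
            continue
        f = freq / total
        nz = f > 0
        out[c] = float(np.sum(f[nz] * np.log2(f[nz] / BACKGROUND[nz])))
    return out


def logo_matrix(
    sequences: Sequence[str],
    weights: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Relative-entropy-scaled letter heights (position x amino acid, bits).

    The resulting frame is directly consumable by logo plotting tools.
    """
    re_bits = column_relative_entropy(sequences, weights)
    if weights is None:
        weights = np.ones(len(sequences))
    length = len(sequences[0])
    heights = np.zeros((length, 20))
    for c in range(length):
        freq = np.zeros(20)
        for s, w in zip(sequences, weights):
            idx = AA_INDEX.get(s[c])
            if idx is not None:
                freq[idx] += w
        total = freq.sum()
        if total > 0:
            heights[c] = freq / total * re_bits[c]
    return pd.DataFrame(heights, columns=list(AMINO_ACIDS))


def lrr_embedding(window: str) -> np.ndarray:
    """18-dim raw physico-chemical descriptor of one LxxLxL window.

    Per position: (hydropathy, charge, volume); 'X' gets the scale means.
    """
    if len(window) != 6:
        raise InputError(f"LxxLxL window must have 6 residues, got {len(window)}")
    out = np.empty(18)
    for i, ch in enumerate(window):
        if ch == "X":
            h, q, v = (_SCALE_MEANS["hydropathy"], _SCALE_MEANS["charge"],
                       _SCALE_MEANS["volume"])
        else:
            try:
                h, q, v = HYDROPATHY[ch], CHARGE[ch], VOLUME[ch]
            except KeyError:
                raise InputError(f"illegal residue {ch!r} in LxxLxL window") from None
        out[3 * i: 3 * i + 3] = (h, q, v)
    return out


class LrrEmbedding(TransformerMixin, BaseEstimator):
    """Transformer: LxxLxL 6-mers -> z-scored 18-dim embedding vectors.

    ``fit`` learns the per-feature mean and standard deviation across the
    dataset; ``transform`` embeds and standardizes. Constant features keep
    unit scale.
    """

    def fit(self, X, y=None):
        raw = np.stack([lrr_embedding(w) for w in X])
        self.mean_ = raw.mean(axis=0)
        scale = raw.std(axis=0)
        scale[scale <= 1e-8] = 1.0  # constant features keep unit scale
        self.scale_ = scale
        self.n_features_in_ = 18
        return self

    def transform(self, X):
        raw = np.stack([lrr_embedding(w) for w in X])
        return (raw - self.mean_) / self.scale_


def cluster_lrr_motifs(
    embeddings: np.ndarray,
    min_samples: int = 20,
    xi: float = 0.05,
    ids: Optional[Sequence[str]] = None,
) -> ClusterAssignment:
    """OPTICS clustering (Xi extraction, Minkowski-2) of embedding vectors."""
    embeddings = np.asarray(embeddings)
    if len(embeddings) < min_samples:
        raise InputError(
            f"need at least min_samples={min_samples} points, got {len(embeddings)}"
        )
    optics = OPTICS(
        min_samples=min_samples,
        xi=xi,
        cluster_method="xi",
        metric="minkowski",
        p=2,
    )
    with np.errstate(divide="ignore"):  # duplicate points yield 0 reachability
        raw = optics.fit_predict(embeddings)
    relabel: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=int)
    for i, r in enumerate(raw):
        if r < 0:
            labels[i] = -1
        else:
            labels[i] = relabel.setdefault(int(r), len(relabel))
    if ids is None:
        ids = [str(i) for i in range(len(labels))]
    return ClusterAssignment(
        list(ids), labels,
        method={"algorithm": "OPTICS/xi", "min_samples": min_samples, "xi": xi},
    )


def ladder_distribution(
    labels: Sequence[int],
    ladder_positions: Sequence[int],
    max_position: Optional[int] = None,
) -> pd.DataFrame:
    """Cluster x ladder-position matrix of percentages (columns sum to 100).

    ``ladder_positions`` gives each motif's 1-based index in its repeat
    ladder; positions beyond ``max_position`` are pooled into an ``"N+"``
    column.
    """
    labels = np.asarray(labels)
    pos = np.asarray(ladder_positions)
    if len(labels) != len(pos):
        raise InputError("labels and ladder positions length mismatch")
    if max_position is None:
        max_position = int(pos.max()) if len(pos) else 1
    col_names = [str(i) for i in range(1, max_position + 1)] + [f"{max_position}+"]
    clusters = sorted(set(labels.tolist()))
    out = pd.DataFrame(0.0, index=clusters, columns=col_names)
    for lab, p in zip(labels, pos):
        col = str(p) if p <= max_position else f"{max_position}+"
        out.loc[lab, col] += 1
    sums = out.sum(axis=0)
    nonzero = sums > 0
    out.loc[:, nonzero] = out.loc[:, nonzero] / sums[nonzero] * 100.0
    return out.drop(columns=[c for c, nz in zip(col_names, nonzero) if not nz])
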