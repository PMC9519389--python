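"""Per-residue evolutionary features from iterative profile search.

For every query position the feature block is the vector of negative natural
log match-emission probabilities to each of the 20 amino acids, for two
successive iterations of a profile search of the query against a small
"focused" database of homologs.

Two engines implement the same contract:

* :func:`internal_pssm_search` — the reference engine, dependency-free.
  Iteration 1 finds gapless, k-mer-anchored local alignments of the query
  against each database sequence under BLOSUM62 scoring; aligned residues are
  collected into query-anchored columns, and emissions are Henikoff-weighted
  frequencies mixed with substitution-profile pseudocounts (pseudocount mass
  1 relative to the observed count mass). Iteration 2 repeats the search with
  the iteration-1 position-specific scoring matrix and rebuilds the emissions
  from the new hit set.
* a profile-HMM engine backed by pyhmmer (``engine="pyhmmer"``): iteration 1
  uses phmmer, iteration 2 builds a query-anchored HMM from the iteration-1
  alignment and searches with it. Alignment rows are featurized by the same
  emission machinery, so both engines are exchangeable.

The query sequence is always a row of its own profile (as in iterative HMM
search, where the first model is seeded from the query); pass
``include_query=False`` to build emissions from database hits only, in which
case positions without any hit fall back to the background distribution.
Alignment-score thresholds are derived from the requested E-value cutoff via
ungapped Karlin–Altschul statistics for BLOSUM62.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alphabet import BACKGROUND, BLOSUM62, COND, encode
from .errors import InputError, ModelError
from .seqio import SequenceRecord, read_fasta

logger = logging.getLogger(__name__)

#: Probability floor applied before taking logs (no infinite features).
EPS = 1e-9

#: Anchor k-mer length of the internal search engine.
KMER = 4

# Ungapped Karlin-Altschul parameters for BLOSUM62 in native score units.
_KA_LAMBDA = 0.3176
_KA_K = 0.13

#: Pseudocount mass mixed into each column (relative to observed count mass).
PSEUDOCOUNT_MASS = 1.0

_X_SCORE = -4.0  # score against 'X' / unknown residues


@dataclass
class FocusedDB:
    """A small curated homolog collection used for profile construction."""

    records: list[SequenceRecord]
    metadata: dict = field(default_factory=dict)
    _encoded: Optional[list[np.ndarray]] = field(default=None, repr=False)
    _kmer_index: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError("focused database is empty")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"focused database contains duplicate id(s) {dup}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def encoded(self) -> list[np.ndarray]:
        if self._encoded is None:
            self._encoded = [encode(r.residues) for r in self.records]
        return self._encoded

    @property
    def kmer_index(self) -> dict:
        """Exact k-mer -> list of (sequence index, position) over the db."""
        if self._kmer_index is None:
            index: dict[bytes, list[tuple[int, int]]] = {}
            for si, enc in enumerate(self.encoded):
                data = enc.tobytes()
                for p in range(len(enc) - KMER + 1):
                    kmer = data[p : p + KMER]
                    if b"\xff" in kmer:  # contains X
                        continue
                    index.setdefault(kmer, []).append((si, p))
            self._kmer_index = index
        return self._kmer_index

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.records)


def build_focused_db_from_fasta(path) -> FocusedDB:
    """Load a focused database from FASTA; logs its composition."""
    records = read_fasta(path)
    n_long = sum(1 for r in records if len(r) >= 500)
    n_mid = sum(1 for r in records if len(r) >= 200)
    logger.info(
        "focused db: %d sequences (%d of >=500 aa, %d of >=200 aa)",
        len(records), n_long, n_mid,
    )
    return FocusedDB(records, metadata={"n": len(records), "source": str(path)})


@dataclass
class ProfileFeatures:
    """Per-residue feature matrix for one sequence.

    ``matrix[i, it, a]`` is -ln p(amino acid a at position i) for iteration
    ``it`` (0 = first, 1 = second). ``mask[i]`` is True when position ``i``
    was covered by at least one database hit; False positions carry either
    the query's own substitution profile (``include_query=True``) or the
    background distribution.
    """

    seqid: str
    matrix: np.ndarray  # (L, n_iterations, 20), float32, -ln probabilities
    mask: np.ndarray  # (L,), bool

    def __post_init__(self) -> None:
        if self.matrix.ndim != 3 or self.matrix.shape[2] != 20:
            raise InputError("ProfileFeatures matrix must have shape (L, it, 20)")
        if self.matrix.shape[0] != self.mask.shape[0]:
            raise InputError("ProfileFeatures mask/matrix length mismatch")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


def _min_segment_score(query_len: int, db_len: int, evalue: float) -> float:
    return math.log(_KA_K * query_len * db_len / evalue) / _KA_LAMBDA


def _best_segment(scores: np.ndarray) -> tuple[float, int, int]:
    """Maximum-sum contiguous segment (Kadane, vectorized).

    Returns (score, start, end) with end exclusive; score may be <= 0.
    """
    cs = np.cumsum(scores)
    prefix = np.concatenate(([0.0], cs[:-1]))
    rmin = np.minimum.accumulate(prefix)
    gains = cs - rmin
    e = int(np.argmax(gains))
    s = int(np.argmax(prefix[: e + 1] == rmin[e]))
    return float(gains[e]), s, e + 1


def _collect_rows_blosum(q_enc, db, min_score):
    """Iteration-1 hit rows: gapless BLOSUM62 segments via k-mer anchors."""
    sm = np.full((21, 21), _X_SCORE)
    sm[:20, :20] = BLOSUM62
    return _collect_rows(q_enc, db, min_score, lambda qs, ts: sm[q_enc[qs], ts])


def _collect_rows_pssm(q_enc, db, min_score, pssm_scores):
    """Iteration-2 hit rows: gapless segments scored by the iteration-1 PSSM."""
    padded = np.concatenate(
        [pssm_scores, np.full((len(q_enc), 1), _X_SCORE)], axis=1
    )
    return _collect_rows(
        q_enc, db, min_score, lambda qs, ts: padded[qs, ts]
    )


def _collect_rows(q_enc, db, min_score, score_fn):
    m = len(q_enc)
    qdata = q_enc.tobytes()
    index = db.kmer_index
    encoded = db.encoded
    seen: set[tuple[int, int]] = set()
    rows: list[np.ndarray] = []
    for p in range(m - KMER + 1):
        kmer = qdata[p : p + KMER]
        if b"\xff" in kmer:
            continue
        for si, tp in index.get(kmer, ()):
            diag = p - tp
            if (si, diag) in seen:
                continue
            seen.add((si, diag))
            t_enc = encoded[si]
            qs = max(0, diag)
            ts = max(0, -diag)
            n = min(m - qs, len(t_enc) - ts)
            if n < KMER:
                continue
            q_idx = np.arange(qs, qs + n)
            t_seg = t_enc[ts : ts + n].astype(np.intp)
            scores = score_fn(q_idx, t_seg)
            best, s, e = _best_segment(scores)
            if best < min_score:
                continue
            row = np.full(m, -1, dtype=np.int8)
            row[qs + s : qs + e] = t_enc[ts + s : ts + e]
            rows.append(row)
    return rows


def _henikoff_row_weights(rows: list[np.ndarray]) -> np.ndarray:
    """Position-based sequence weights over query-anchored rows.

    Rows are full-length int8 arrays with -1 at uncovered positions. Weights
    are normalized so that their sum equals the number of rows (an identical
    stack of rows therefore contributes one count per row).
    """
    stack = np.stack(rows)  # (R, L)
    n_rows, length = stack.shape
    weights = np.zeros(n_rows)
    for i in range(length):
        col = stack[:, i]
        present = col >= 0
        if not present.any():
            continue
        vals, inv, counts = np.unique(col[present], return_inverse=True, return_counts=True)
        r = len(vals)
        weights[present] += 1.0 / (r * counts[inv])
    total = weights.sum()
    if total <= 0:
        return np.ones(n_rows)
    return weights * (n_rows / total)


def _emissions_from_rows(
    length: int, rows: list[np.ndarray], pseudocount_mass: float
) -> np.ndarray:
    """Column emissions from weighted counts + substitution-profile pseudocounts."""
    emissions = np.tile(BACKGROUND, (length, 1))
    if not rows:
        return emissions
    weights = _henikoff_row_weights(rows)
    stack = np.stack(rows)
    counts = np.zeros((length, 20))
    for r, w in zip(stack, weights):
        present = r >= 0
        np.add.at(counts, (np.nonzero(present)[0], r[present].astype(np.intp)), w)
    totals = counts.sum(axis=1)
    covered = totals > 0
    f = counts[covered] / totals[covered, None]
    pc = f @ COND
    emissions[covered] = (counts[covered] + pseudocount_mass * pc) / (
        totals[covered, None] + pseudocount_mass
    )
    return emissions


def internal_pssm_search(
    query: SequenceRecord,
    db: FocusedDB,
    iterations: int = 2,
    evalue_cutoff: float = 1e-5,
    include_query: bool = True,
    pseudocount_mass: float = PSEUDOCOUNT_MASS,
) -> ProfileFeatures:
    """Reference profile-search engine (see module docstring)."""
    if iterations < 1:
        raise InputError("iterations must be >= 1")
    q_enc = encode(query.residues)
    m = len(q_enc)
    min_score = _min_segment_score(m, db.total_length, evalue_cutoff)

    matrix = np.empty((m, iterations, 20), dtype=np.float32)
    mask = np.zeros(m, dtype=bool)
    query_row = q_enc.copy()
    emissions = None
    any_hits = False
    for it in range(iterations):
        if it == 0:
            hit_rows = _collect_rows_blosum(q_enc, db, min_score)
        else:
            pssm_scores = 2.0 * np.log2(
                np.clip(emissions, EPS, None) / BACKGROUND[None, :]
            )
            hit_rows = _collect_rows_pssm(q_enc, db, min_score, pssm_scores)
        if hit_rows:
            any_hits = True
            for row in hit_rows:
                mask |= row >= 0
        rows = ([query_row] if include_query else []) + hit_rows
        emissions = _emissions_from_rows(m, rows, pseudocount_mass)
        matrix[:, it, :] = -np.log(np.clip(emissions, EPS, None))
    if not any_hits:
        warnings.warn(
            f"no database hits for {query.id!r}; features fall back to "
            + ("the query's own substitution profile" if include_query else "background"),
            stacklevel=2,
        )
    return ProfileFeatures(query.id, matrix, mask)


def build_profile_features(
    query: SequenceRecord,
    db: FocusedDB,
    iterations: int = 2,
    evalue_cutoff: float = 1e-5,
    engine: str = "internal",
    include_query: bool = True,
) -> ProfileFeatures:
    """Build per-residue -ln match-emission features for `query` against `db`.

    ``engine`` selects the search backend: ``"internal"`` (reference PSSM
    engine) or ``"pyhmmer"`` (profile-HMM engine; requires the optional
    pyhmmer dependency).
    """
    if engine == "internal":
        return internal_pssm_search(query, db, iterations, evalue_cutoff, include_query)
    if engine == "pyhmmer":
        from . import _hmmengine

        if not _hmmengine.available():
            raise ModelError(
                "the pyhmmer search engine is not installed; use the internal "
                "PSSM engine (engine='internal') instead"
            )
        return _hmmengine.search(query, db, iterations, evalue_cutoff, include_query)
    raise ModelError(f"unknown profile engine {engine!r}")


def save_features(features: ProfileFeatures, path) -> None:
    """Cache features as an NPZ file keyed by sequence id."""
    np.savez_compressed(
        path, seqid=features.seqid, matrix=features.matrix, mask=features.mask
    )


def load_features(path) -> ProfileFeatures:
    data = np.load(path, allow_pickle=False)
    return ProfileFeatures(str(data["seqid"]), data["matrix"], data["mask"])


#: Background feature block (-ln background), shape (iterations, 20).
def background_block(iterations: int = 2) -> np.ndarray:
    return np.tile(-np.log(BACKGROUND).astype(np.float32), (iterations, 1))
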