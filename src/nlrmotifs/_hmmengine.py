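"""Optional profile-HMM search backend built on pyhmmer.

Iteration 1 searches the query against the focused database with phmmer;
iteration 2 builds a query-anchored profile HMM (hand architecture, one match
state per query position) from the iteration-1 alignment and searches the
database with it. Domain alignments are converted to query-anchored rows and
featurized by the same Henikoff-weighted emission machinery as the internal
engine, which keeps the two engines exchangeable.
"""

from __future__ import annotations

import warnings

import numpy as np

from .alphabet import encode
from .errors import ModelError

try:  # pragma: no cover - import guard
    import pyhmmer
    from pyhmmer import easel, hmmer, plan7

    _AVAILABLE = True
except ImportError:  # pragma: no cover
    _AVAILABLE = False


def available() -> bool:
    return _AVAILABLE


def _alignment_row(ali, length: int) -> np.ndarray:
    """Convert a pyhmmer domain alignment to a query-anchored int8 row."""
    row = np.full(length, -1, dtype=np.int8)
    qpos = ali.hmm_from - 1
    for qc, tc in zip(ali.hmm_sequence, ali.target_sequence):
        if qc == ".":  # insertion relative to the query: no query advance
            continue
        if tc != "-":
            row[qpos] = encode(tc.upper())[0]
        qpos += 1
    return row


def _rows_from_hits(top_hits, length: int, evalue_cutoff: float) -> list[np.ndarray]:
    rows = []
    for hit in top_hits:
        for dom in hit.domains:
            if dom.i_evalue > evalue_cutoff:
                continue
            rows.append(_alignment_row(dom.alignment, length))
    return rows


def search(query, db, iterations=2, evalue_cutoff=1e-5, include_query=True):
    """Same contract as :func:`nlrmotifs.profiles.internal_pssm_search`."""
    from .profiles import (
        EPS,
        PSEUDOCOUNT_MASS,
        ProfileFeatures,
        _emissions_from_rows,
    )

    if not _AVAILABLE:  # pragma: no cover
        raise ModelError(
            "pyhmmer is not installed; use the internal PSSM engine instead"
        )
    alph = easel.Alphabet.amino()
    length = len(query.residues)
    q_enc = encode(query.residues)
    dseqs = [
        easel.TextSequence(name=r.id.encode(), sequence=r.residues).digitize(alph)
        for r in db.records
    ]
    qseq = easel.TextSequence(name=b"query", sequence=query.residues).digitize(alph)

    matrix = np.empty((length, iterations, 20), dtype=np.float32)
    mask = np.zeros(length, dtype=bool)
    any_hits = False
    hit_rows: list[np.ndarray] = []
    for it in range(iterations):
        if it == 0:
            top = next(iter(hmmer.phmmer([qseq], dseqs, E=evalue_cutoff)))
        else:
            hmm = _build_anchored_hmm(query, hit_rows, alph)
            top = next(iter(hmmer.hmmsearch([hmm], dseqs, E=evalue_cutoff)))
        hit_rows = _rows_from_hits(top, length, evalue_cutoff)
        if hit_rows:
            any_hits = True
            for row in hit_rows:
                mask |= row >= 0
        rows = ([q_enc.copy()] if include_query else []) + hit_rows
        emissions = _emissions_from_rows(length, rows, PSEUDOCOUNT_MASS)
        matrix[:, it, :] = -np.log(np.clip(emissions, EPS, None))
    if not any_hits:
        warnings.warn(
            f"no database hits for {query.id!r}; features fall back to "
            + ("the query's own substitution profile" if include_query else "background"),
            stacklevel=2,
        )
    return ProfileFeatures(query.id, matrix, mask)


def _build_anchored_hmm(query, hit_rows, alph):
    """Build a profile HMM whose match states are exactly the query positions."""
    from .alphabet import AMINO_ACIDS

    length = len(query.residues)
    texts = [easel.TextSequence(name=b"query", sequence=query.residues)]
    for i, row in enumerate(hit_rows):
        chars = ["-" if v < 0 else AMINO_ACIDS[v] for v in row]
        texts.append(
            easel.TextSequence(name=f"hit{i}".encode(), sequence="".join(chars))
        )
    msa = easel.TextMSA(name=b"iter1", sequences=texts)
    msa.reference = "x" * length
    dmsa = msa.digitize(alph)
    builder = plan7.Builder(alph, architecture="hand")
    hmm, _, _ = builder.build_msa(dmsa, plan7.Background(alph))
    return hmm
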