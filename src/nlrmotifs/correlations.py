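"""Column-pair coevolution analysis over concatenated motif alignments.

Mutual information between alignment columns is computed from
Henikoff-weighted joint counts with profile-based pseudocounts (pseudocount
mass distributed proportionally to the substitution profile of the observed
column), gaps and 'X' excluded. Pair significance is a Z-score against the
empirical off-diagonal MI distribution, cut at Z >= 3.5. Per-column summary
metrics: cumulative MI (sum of significant MI of a column) and proximity MI
(mean cumulative MI over its 3D-contact neighbours, when a contact map is
supplied).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .alphabet import AA_INDEX, COND
from .errors import InputError

Z_CUTOFF = 3.5


@dataclass
class MIResult:
    """Symmetric MI matrix with Z-scores and derived summaries."""

    mi: np.ndarray
    zero_columns: list[int] = field(default_factory=list)
    z: Optional[np.ndarray] = None
    significant: Optional[list[tuple[int, int]]] = None
    cumulative: Optional[np.ndarray] = None
    proximity: Optional[np.ndarray] = None
    degenerate: bool = False

    @property
    def n_columns(self) -> int:
        return self.mi.shape[0]


@dataclass(frozen=True)
class ContactMap:
    """Symmetric set of in-contact position pairs (no self-pairs)."""

    pairs: frozenset
    source: str = ""

    def __contains__(self, pair) -> bool:
        i, j = pair
        return (i, j) in self.pairs or (j, i) in self.pairs

    def neighbours(self, i: int) -> list[int]:
        out = set()
        for a, b in self.pairs:
            if a == i:
                out.add(b)
            elif b == i:
                out.add(a)
        return sorted(out)


def contact_map_from_pairs(pairs, source: str = "") -> ContactMap:
    clean = set()
    for i, j in pairs:
        if i == j:
            raise InputError("contact map must not contain self-pairs")
        clean.add((min(i, j), max(i, j)))
    return ContactMap(frozenset(clean), source)


def read_contact_table(path, cutoff: float = 5.0) -> ContactMap:
    """Read a plain TSV of (i, j, distance) rows; keep pairs at <= cutoff.

    Positions are 1-based in the file (converted to 0-based here).
    """
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i, j, dist = line.split("\t")[:3]
            if float(dist) <= cutoff:
                pairs.append((int(i) - 1, int(j) - 1))
    return contact_map_from_pairs(pairs, source=str(path))


def _column_codes(alignment: Sequence[str]) -> np.ndarray:
    lengths = {len(r) for r in alignment}
    if len(lengths) != 1:
        raise InputError("alignment rows must have equal length")
    codes = np.full((len(alignment), len(alignment[0])), -1, dtype=np.int8)
    for r, row in enumerate(alignment):
        for c, ch in enumerate(row):
            codes[r, c] = AA_INDEX.get(ch, -1)
    return codes


def henikoff_weights(alignment: Sequence[str]) -> np.ndarray:
    """Position-based Henikoff-Henikoff sequence weights, normalized to sum 1.

    At each column, a residue of type a observed n_a times in a column with r
    distinct types contributes 1/(r * n_a) to its row's weight. Gap/'X'
    positions contribute nothing.
    """
    if len(alignment) < 2:
        raise InputError("need at least 2 rows for Henikoff weights")
    codes = _column_codes(alignment)
    n_rows, n_cols = codes.shape
    weights = np.zeros(n_rows)
    for c in range(n_cols):
        col = codes[:, c]
        present = col >= 0
        if not present.any():
            continue
        vals, inv, counts = np.unique(
            col[present], return_inverse=True, return_counts=True
        )
        weights[present] += 1.0 / (len(vals) * counts[inv])
    total = weights.sum()
    if total <= 0:
        return np.full(n_rows, 1.0 / n_rows)
    return weights / total


def weighted_mutual_information(
    alignment: Sequence[str],
    weights: Optional[np.ndarray] = None,
    pseudocount_mass: float = 0.0,
) -> MIResult:
    """Pairwise column MI (nats) from weighted counts + profile pseudocounts.

    ``pseudocount_mass`` sets the strength of the profile pseudocounts in
    observation units *per observed state pair*: the joint distribution of
    columns (i, j) receives a pseudo-observation mass of
    ``pseudocount_mass * Ki * Kj`` (Ki, Kj = number of distinct residues
    observed in each column), distributed as the product of the two columns'
    substitution profiles. Scaling with the observed cardinalities suppresses
    the finite-sample MI inflation of high-cardinality column pairs (whose
    joint counts are sparse) while leaving concentrated, low-cardinality
    columns essentially untouched. Weights are rescaled so one alignment row
    carries one unit of count mass. Columns with zero effective counts get an
    all-zero MI row and are flagged.
    """
    codes = _column_codes(alignment)
    n_rows, n_cols = codes.shape
    if weights is None:
        weights = np.full(n_rows, 1.0 / n_rows)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != n_rows:
        raise InputError("one weight per alignment row required")
    if np.any(weights <= 0):
        raise InputError("weights must be positive")
    weights = weights * (n_rows / weights.sum())  # one row = one count

    mi = np.zeros((n_cols, n_cols))
    zero_columns = [
        c for c in range(n_cols) if not (codes[:, c] >= 0).any()
    ]
    # Single-column pseudocount profiles and observed cardinalities.
    profiles = []
    cardinalities = np.ones(n_cols)
    for c in range(n_cols):
        col = codes[:, c]
        present = col >= 0
        counts = np.zeros(20)
        if present.any():
            np.add.at(counts, col[present].astype(np.intp), weights[present])
            cardinalities[c] = int((counts > 0).sum())
        total = counts.sum()
        if total > 0:
            pc = (counts / total) @ COND
        else:
            pc = np.full(20, 1 / 20)
        profiles.append(pc)

    for i in range(n_cols):
        if i in zero_columns:
            continue
        for j in range(i + 1, n_cols):
            if j in zero_columns:
                continue
            ci, cj = codes[:, i], codes[:, j]
            both = (ci >= 0) & (cj >= 0)
            if not both.any():
                continue
            joint = np.zeros((20, 20))
            np.add.at(
                joint,
                (ci[both].astype(np.intp), cj[both].astype(np.intp)),
                weights[both],
            )
            total = joint.sum()
            joint /= total
            if pseudocount_mass > 0:
                mass = pseudocount_mass * cardinalities[i] * cardinalities[j]
                lam = mass / (total + mass)
                joint = (1 - lam) * joint + lam * np.outer(profiles[i], profiles[j])
            pi = joint.sum(axis=1)
            pj = joint.sum(axis=0)
            nz = joint > 0
            denom = np.outer(pi, pj)
            val = float(np.sum(joint[nz] * np.log(joint[nz] / denom[nz])))
            mi[i, j] = mi[j, i] = max(0.0, val)
    return MIResult(mi=mi, zero_columns=zero_columns)


def mi_zscores(result: MIResult, cutoff: float = Z_CUTOFF) -> MIResult:
    """Z-scores against the empirical off-diagonal MI distribution.

    A pair is significant iff Z >= cutoff (boundary included). A degenerate
    (zero-variance) MI matrix yields no significant pairs.
    """
    mi = result.mi
    n = mi.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = mi[iu]
    mean = vals.mean() if len(vals) else 0.0
    sd = vals.std() if len(vals) else 0.0
    z = np.zeros_like(mi)
    significant: list[tuple[int, int]] = []
    if sd <= 1e-12 * max(1.0, abs(mean)):
        result.degenerate = True
    else:
        z = (mi - mean) / sd
        np.fill_diagonal(z, 0.0)
        for i, j in zip(*iu):
            if z[i, j] >= cutoff:
                significant.append((int(i), int(j)))
    result.z = z
    result.significant = significant
    return result


def cumulative_and_proximity_mi(
    result: MIResult,
    contacts: Optional[ContactMap] = None,
) -> MIResult:
    """Per-column cumulative MI and (with contacts) proximity MI.

    cumulative(i) = sum of MI[i, j] over significant pairs touching i;
    proximity(i) = mean cumulative over the contact neighbours of i.
    """
    if result.significant is None:
        raise InputError("run mi_zscores before the cumulative/proximity summaries")
    n = result.n_columns
    cumulative = np.zeros(n)
    for i, j in result.significant:
        cumulative[i] += result.mi[i, j]
        cumulative[j] += result.mi[i, j]
    result.cumulative = cumulative
    if contacts is not None:
        for a, b in contacts.pairs:
            if not (0 <= a < n and 0 <= b < n):
                raise InputError(
                    f"contact pair ({a}, {b}) outside alignment of {n} columns"
                )
        proximity = np.zeros(n)
        for i in range(n):
            nb = contacts.neighbours(i)
            if nb:
                proximity[i] = float(np.mean(cumulative[nb]))
        result.proximity = proximity
    return result


def map_pairs_to_contacts(
    pairs: Sequence[tuple[int, int]],
    contacts: ContactMap,
    offsets: Optional[Mapping[int, int]] = None,
) -> dict[tuple[int, int], str]:
    """Label each pair 'supported', 'unsupported' or 'unmapped'.

    ``offsets`` maps alignment (chimera) positions to reference coordinates;
    pairs with an endpoint missing from the mapping are 'unmapped'. Without
    an offset table positions are used as-is.
    """
    out: dict[tuple[int, int], str] = {}
    for i, j in pairs:
        if offsets is not None:
            if i not in offsets or j not in offsets:
                out[(i, j)] = "unmapped"
                continue
            a, b = offsets[i], offsets[j]
        else:
            a, b = i, j
        out[(i, j)] = "supported" if (a, b) in contacts else "unsupported"
    return out
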