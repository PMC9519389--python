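"""Motif calling, satellite resolution, layout rules, classification."""

import itertools

import numpy as np
import pytest

from nlrmotifs.errors import InputError
from nlrmotifs.postprocess import (
    MotifCall,
    call_motifs,
    classify_nlr,
    delineate_lrr_ladder,
    resolve_satellites,
    validate_nbs_layout,
)
from nlrmotifs.registry import NBS_ORDER


def _oracle_plateau_calls(p, thr):
    """Independent re-statement of the local-maximum/plateau rule."""
    calls = []
    n = len(p)
    for i in range(n):
        if p[i] <= thr:
            continue
        if i > 0 and p[i - 1] == p[i]:
            continue  # not the leftmost point of its plateau
        j = i
        while j + 1 < n and p[j + 1] == p[i]:
            j += 1
        left_ok = i == 0 or p[i - 1] <= p[i]
        right_ok = j == n - 1 or p[j + 1] <= p[i]
        if left_ok and right_ok:
            calls.append(i)
    return calls


def test_single_peak_and_threshold_strictness():
    p = np.zeros(20)
    p[7] = 0.95
    calls = call_motifs(p, "s", "MHD")
    assert [(c.start, c.probability) for c in calls] == [(7, 0.95)]
    p[7] = 0.80  # exactly at the threshold: "higher than 80%" excludes it
    assert call_motifs(p, "s", "MHD") == []


def test_plateaus_call_leftmost_position_exhaustively():
    """All length-5 vectors over {0.5, 0.9} match the rule oracle."""
    for vals in itertools.product([0.5, 0.9], repeat=5):
        p = np.array(vals)
        got = [c.start for c in call_motifs(p, "s", "MHD")]
        assert got == _oracle_plateau_calls(p, 0.80), vals


def _c(start, prob, motif="LxxLxL"):
    return MotifCall("s", motif, start, prob)


def test_satellite_rule_truth_table():
    # clear conflict: delta p = 0.25 > 0.20 -> keep the stronger only
    kept = resolve_satellites([_c(100, 0.95), _c(108, 0.70)])
    assert [(c.start, c.ambiguous) for c in kept] == [(100, False)]
    # delta p <= 0.20 -> both kept, flagged ambiguous
    kept = resolve_satellites([_c(100, 0.90), _c(108, 0.85)])
    assert [(c.start, c.ambiguous) for c in kept] == [(100, True), (108, True)]
    # 20 aa apart: outside the window, untouched
    kept = resolve_satellites([_c(100, 0.95), _c(120, 0.70)])
    assert [(c.start, c.ambiguous) for c in kept] == [(100, False), (120, False)]
    # boundary: exactly 15 aa apart is not a conflict
    kept = resolve_satellites([_c(100, 0.95), _c(115, 0.70)])
    assert [(c.start, c.ambiguous) for c in kept] == [(100, False), (115, False)]


def test_satellite_resolution_is_idempotent(rng):
    for _ in range(50):
        n = rng.integers(2, 8)
        starts = np.sort(rng.choice(200, n, replace=False))
        calls = [_c(int(s), float(rng.integers(81, 100)) / 100) for s in starts]
        once = resolve_satellites(calls)
        twice = resolve_satellites(once)
        assert [(c.start, c.probability, c.ambiguous) for c in once] == [
            (c.start, c.probability, c.ambiguous) for c in twice
        ]


def test_satellite_chain_keeps_single_winner():
    calls = [_c(100, 0.99), _c(108, 0.70), _c(112, 0.45)]
    with pytest.raises(InputError):
        resolve_satellites(calls + [_c(1, 0.9, motif="MHD")])
    kept = resolve_satellites(calls)
    assert [c.start for c in kept] == [100]


def _nbs_calls(order=NBS_ORDER, step=40):
    return [
        MotifCall("s", name, 10 + i * step, 0.9) for i, name in enumerate(order)
    ]


def test_nbs_layout_validation_reason_codes():
    assert validate_nbs_layout(_nbs_calls()).nbs_valid

    swapped = list(NBS_ORDER)
    g, m = swapped.index("GLPL"), swapped.index("MHD")
    swapped[g], swapped[m] = swapped[m], swapped[g]
    ann = validate_nbs_layout(_nbs_calls(tuple(swapped)))
    assert not ann.nbs_valid
    assert "disordered:GLPL|MHD" in ann.reasons

    doubled = _nbs_calls() + [MotifCall("s", "P-loop", 500, 0.9)]
    ann = validate_nbs_layout(doubled)
    assert ann.reasons == ["duplicated:P-loop"]

    missing = [c for c in _nbs_calls() if c.motif != "RNBS-C"]
    ann = validate_nbs_layout(missing)
    assert ann.reasons == ["missing:RNBS-C"]


def test_nbs_order_permutations_valid_iff_sorted(rng):
    """Random position permutations validate exactly when in registry order."""
    base = np.array([10 + i * 40 for i in range(9)])
    perms = [np.arange(9)] + [rng.permutation(9) for _ in range(300)]
    for perm in perms:
        calls = [
            MotifCall("s", name, int(base[perm[i]]), 0.9)
            for i, name in enumerate(NBS_ORDER)
        ]
        ann = validate_nbs_layout(calls)
        assert ann.nbs_valid == bool((perm == np.arange(9)).all())


def _ladder_calls(starts):
    return [MotifCall("s", "LxxLxL", s, 0.9) for s in starts]


def test_lrr_ladder_acceptance_and_rejections():
    nbs = validate_nbs_layout(_nbs_calls())
    mhd_end = 10 + 8 * 40 + 3
    starts = [mhd_end + 30 + 24 * i for i in range(10)]
    ladder, reason = delineate_lrr_ladder(_ladder_calls(starts), nbs)
    assert reason is None
    assert len(ladder) == 10
    assert ladder.repeat_lengths[:-1] == [24] * 9
    assert ladder.repeat_lengths[-1] is None
    assert ladder.ladder_indices == list(range(1, 11))

    bad = starts.copy()
    bad[3] = bad[2] + 12  # 12 aa spacing between repeats 3 and 4
    bad[4] = bad[3] + 24
    ladder, reason = delineate_lrr_ladder(_ladder_calls(sorted(bad)), nbs)
    assert ladder is None and reason == "short-repeat:3"

    far = [mhd_end + 60 + 24 * i for i in range(10)]
    ladder, reason = delineate_lrr_ladder(_ladder_calls(far), nbs)
    assert ladder is None and reason == "linker"

    few = [mhd_end + 30 + 24 * i for i in range(5)]
    ladder, reason = delineate_lrr_ladder(_ladder_calls(few), nbs)
    assert ladder is None and reason == "too-few:5"
    ladder, reason = delineate_lrr_ladder(_ladder_calls(few), nbs, min_repeats=5)
    assert reason is None and len(ladder) == 5


def test_ladder_never_accepts_out_of_range_spacing(rng):
    for _ in range(100):
        n = int(rng.integers(9, 14))
        gaps = rng.integers(5, 70, size=n - 1)
        starts = np.concatenate([[100], 100 + np.cumsum(gaps)])
        ladder, reason = delineate_lrr_ladder(_ladder_calls(starts.tolist()))
        ok = bool(np.all((gaps >= 15) & (gaps <= 50)))
        assert (ladder is not None) == ok
        if ladder is not None:
            assert all(15 <= g <= 50 for g in ladder.repeat_lengths[:-1])


def test_classification_rules():
    nbs = validate_nbs_layout(_nbs_calls())
    assert classify_nlr(nbs).label == "NL"

    with_cc = validate_nbs_layout(
        [MotifCall("s", "EDVID", 2, 0.95)] + _nbs_calls()
    )
    assert classify_nlr(with_cc).label == "CNL"

    shuffled = validate_nbs_layout(
        _nbs_calls() + [MotifCall("s", "EDVID", 900, 0.95)]
    )
    cls = classify_nlr(shuffled)
    assert cls.label == "other"
    assert "shuffled" in cls.flags

    from nlrmotifs.registry import TIR_ORDER

    tir_calls = [
        MotifCall("s", name, 2 + 15 * i, 0.95) for i, name in enumerate(TIR_ORDER)
    ]
    tnl = validate_nbs_layout(tir_calls + [
        MotifCall("s", name, 200 + i * 40, 0.9) for i, name in enumerate(NBS_ORDER)
    ])
    assert classify_nlr(tnl).label == "TNL"
    both = validate_nbs_layout(
        tir_calls
        + [MotifCall("s", "EDVID", 5, 0.95)]
        + [MotifCall("s", name, 200 + i * 40, 0.9) for i, name in enumerate(NBS_ORDER)]
    )
    cls = classify_nlr(both)
    assert cls.label == "TNL"  # TIR precedence
    assert "cc-and-tir" in cls.flags
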