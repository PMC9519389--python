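"""Chimeras, identity clustering, conservation profiles, LRR embeddings."""

import numpy as np
import pytest

from nlrmotifs.alphabet import AA_INDEX, BACKGROUND
from nlrmotifs.analysis import (
    Chimera,
    LrrEmbedding,
    cluster_by_identity,
    cluster_lrr_motifs,
    column_relative_entropy,
    excise_chimera,
    ladder_distribution,
    logo_matrix,
    lrr_embedding,
    pairwise_identity,
)
from nlrmotifs.errors import InputError
from nlrmotifs.postprocess import MotifCall, validate_nbs_layout
from nlrmotifs.registry import NBS_ORDER
from nlrmotifs.seqio import SequenceRecord
from nlrmotifs.simulate import GeneratorSpec, generate_nlr, generate_planted_lrr_classes


def _truth_calls(gt):
    return [
        MotifCall(gt.seqid, m, s, 1.0)
        for m, starts in gt.motif_starts.items()
        for s in starts
    ]


@pytest.fixture(scope="module")
def cnl_with_truth():
    rec, gt = generate_nlr(
        "CNL", GeneratorSpec(mu=0.0), np.random.default_rng(11), seqid="cnl"
    )
    return rec, validate_nbs_layout(_truth_calls(gt))


def test_nbs_chimera_length_is_sum_of_motifs_plus_flanks(by_name, cnl_with_truth):
    rec, ann = cnl_with_truth
    chimera = excise_chimera(rec, ann, NBS_ORDER)
    total = sum(by_name[n].length for n in NBS_ORDER) + 10 * len(NBS_ORDER)
    assert len(chimera.sequence) == total
    assert chimera.boundaries[-1] == total
    assert len(chimera.boundaries) == 10


def test_cnl_fifteen_motif_chimera(by_name, cnl_with_truth):
    rec, ann = cnl_with_truth
    layout = ["EDVID"] + list(NBS_ORDER) + ["LxxLxL"] * 5
    chimera = excise_chimera(rec, ann, layout)
    assert len(chimera.motifs) == 15
    assert len(chimera.boundaries) == 16


def test_motif_at_sequence_start_gets_x_flank(by_name):
    rec = SequenceRecord("s", "MHD" + "A" * 30)
    ann = validate_nbs_layout([MotifCall("s", "MHD", 0, 1.0)])
    chimera = excise_chimera(rec, ann, ["MHD"])
    assert chimera.sequence.startswith("XXXXX")
    assert chimera.sequence[5:8] == "MHD"


def _chim(seqid, seq):
    return Chimera(seqid, seq, [0, len(seq)], ["seg"])


def test_identity_clustering_transitive_components():
    a = _chim("a", "A" * 100)
    b = _chim("b", "C" * 40 + "A" * 60)  # 60% to a
    c = _chim("c", "C" * 40 + "G" * 40 + "A" * 20)  # 60% to b, 20% to a
    assert pairwise_identity(a.sequence, b.sequence) == pytest.approx(0.60)
    assert pairwise_identity(b.sequence, c.sequence) == pytest.approx(0.60)
    assert pairwise_identity(a.sequence, c.sequence) == pytest.approx(0.20)
    labels = cluster_by_identity([a, b, c], 0.55).labels
    assert len(set(labels)) == 1  # one connected component via b

    labels = cluster_by_identity([a, b, c], 0.65).labels
    assert len(set(labels)) == 3


def test_identity_clustering_exact_group_oracle(rng):
    """At threshold 1.0 clusters must equal the exact-string groups."""
    from nlrmotifs.alphabet import AMINO_ACIDS

    uniques = ["".join(rng.choice(list(AMINO_ACIDS), 30)) for _ in range(6)]
    seqs = [uniques[i % 6] for i in range(18)]
    chims = [_chim(f"s{i}", s) for i, s in enumerate(seqs)]
    labels = cluster_by_identity(chims, 1.0).labels
    groups = {}
    for lab, s in zip(labels, seqs):
        groups.setdefault(s, set()).add(lab)
    assert all(len(v) == 1 for v in groups.values())
    assert len({next(iter(v)) for v in groups.values()}) == 6


def test_identity_clustering_input_validation():
    with pytest.raises(InputError, match="at least 2"):
        cluster_by_identity([_chim("a", "AAA")], 0.5)
    with pytest.raises(InputError, match="unequal"):
        cluster_by_identity([_chim("a", "AAA"), _chim("b", "AAAA")], 0.5)


def test_relative_entropy_closed_forms():
    # a fully conserved glycine column carries -log2(q_G) bits
    re_bits = column_relative_entropy(["G", "G", "G", "G"])
    expected = -np.log2(BACKGROUND[AA_INDEX["G"]])
    assert re_bits[0] == pytest.approx(expected, abs=1e-9)
    # a column distributed exactly as the background carries 0 bits
    from nlrmotifs.alphabet import AMINO_ACIDS

    rows = list(AMINO_ACIDS)
    re_bg = column_relative_entropy(rows, weights=BACKGROUND)
    assert re_bg[0] == pytest.approx(0.0, abs=1e-12)


def test_relative_entropy_never_negative(rng):
    from nlrmotifs.alphabet import AMINO_ACIDS

    rows = ["".join(rng.choice(list(AMINO_ACIDS), 15)) for _ in range(30)]
    assert np.all(column_relative_entropy(rows) >= 0)


def test_shuffled_column_entropy_shrinks_with_sample_size(rng):
    """Background-sampled columns drift to 0 bits as n grows (Monte Carlo)."""
    from nlrmotifs.alphabet import AMINO_ACIDS

    aa = list(AMINO_ACIDS)
    small = ["".join(rng.choice(aa, 1, p=BACKGROUND)) for _ in range(20)]
    large = ["".join(rng.choice(aa, 1, p=BACKGROUND)) for _ in range(4000)]
    assert column_relative_entropy(large)[0] < column_relative_entropy(small)[0]
    assert column_relative_entropy(large)[0] < 0.05


def test_logo_matrix_heights_sum_to_column_entropy():
    rows = ["GA", "GA", "GC", "GD"]
    logo = logo_matrix(rows)
    re_bits = column_relative_entropy(rows)
    assert np.allclose(logo.sum(axis=1).values, re_bits)


def test_lrr_embedding_lookup_and_validation():
    emb = lrr_embedding("LADLSL")
    assert np.allclose(emb[1::3], [0, 0, -1, 0, 0, 0])  # charge: D at position 2
    k = lrr_embedding("KADLSL")
    r = lrr_embedding("RADLSL")
    assert k[1] == r[1] == 1.0  # same charge class at position 0
    assert np.array_equal(lrr_embedding("LADLSL"), lrr_embedding("LADLSL"))
    with pytest.raises(InputError):
        lrr_embedding("LADLS")
    x = lrr_embedding("XADLSL")
    assert np.isfinite(x).all()


def test_embedding_transformer_standardizes():
    windows, _ = generate_planted_lrr_classes(3, 50, 0.05, seed=1)
    emb = LrrEmbedding().fit(windows)
    Z = emb.transform(windows)
    assert Z.shape == (150, 18)
    assert np.allclose(Z.mean(axis=0), 0, atol=1e-9)


def test_optics_recovers_planted_charge_classes():
    from sklearn.metrics import adjusted_rand_score

    windows, labels = generate_planted_lrr_classes(3, 200, 0.05, seed=7)
    Z = LrrEmbedding().fit_transform(windows)
    assignment = cluster_lrr_motifs(Z, min_samples=20, xi=0.05)
    assert adjusted_rand_score(labels, assignment.labels) >= 0.9


def test_optics_single_blob_and_determinism(rng):
    blob = rng.normal(size=(120, 18))
    a = cluster_lrr_motifs(blob, min_samples=20)
    assert len(set(a.labels) - {-1}) <= 1
    b = cluster_lrr_motifs(blob, min_samples=20)
    assert np.array_equal(a.labels, b.labels)
    with pytest.raises(InputError, match="min_samples"):
        cluster_lrr_motifs(blob[:10], min_samples=20)


def test_ladder_distribution_normalization():
    labels = [0, 0, 1, 1, 0, 1]
    positions = [1, 1, 1, 1, 2, 3]
    dist = ladder_distribution(labels, positions, max_position=2)
    assert np.allclose(dist.sum(axis=0).values, 100.0)
    assert dist.loc[0, "1"] == pytest.approx(50.0)
    assert dist.loc[1, "1"] == pytest.approx(50.0)
    assert dist.loc[0, "2"] == pytest.approx(100.0)
    assert dist.loc[1, "2+"] == pytest.approx(100.0)

    single = ladder_distribution([0, 0, 0], [1, 2, 3], max_position=3)
    assert np.allclose(single.loc[0].values, 100.0)
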