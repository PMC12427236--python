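"""Query-adaptive matching: kernel banks, responses, similarity head, ranking."""

import numpy as np
import pytest

from moo_reid import nn, qaconv
from moo_reid.qaconv import (
    SimilarityHead,
    build_class_memory,
    extract_local_kernels,
    global_mean_pool_scores,
    match,
    response,
    similarity,
    similarity_matrix,
    train_head,
)


def brute_force_response(query_fm, gallery_fm):
    """Exhaustive double loop over all position pairs (p=1 oracle)."""
    C, Hg, Wg = gallery_fm.shape
    _, Hq, Wq = query_fm.shape
    g = gallery_fm.reshape(C, -1).T
    q = query_fm.reshape(C, -1).T

    def unit(v):
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    scores = np.empty(Hg * Wg)
    for s, gv in enumerate(g):
        best = -np.inf
        for qv in q:
            best = max(best, float(unit(gv) @ unit(qv)))
        scores[s] = best
    return scores


def test_p1_bank_is_the_normalized_pixels(rng):
    fm = rng.normal(size=(4, 3, 3))
    bank = extract_local_kernels(fm, patch_size=1)
    assert bank.shape == (9, 4, 1, 1)
    flat = bank.reshape(9, 4)
    assert np.allclose(np.linalg.norm(flat, axis=1), 1.0, atol=1e-6)
    # orthonormal pixel vectors are preserved exactly
    eye = np.zeros((4, 2, 2))
    eye[0, 0, 0] = eye[1, 0, 1] = eye[2, 1, 0] = eye[3, 1, 1] = 1.0
    bank2 = extract_local_kernels(eye, patch_size=1).reshape(4, 4)
    assert np.allclose(bank2, np.eye(4))


def test_zero_feature_map_yields_zero_kernels_not_nan():
    bank = extract_local_kernels(np.zeros((3, 2, 2)), patch_size=1)
    assert np.isfinite(bank).all()
    assert np.allclose(bank, 0.0)


def test_even_patch_size_rejected(rng):
    with pytest.raises(ValueError, match="odd"):
        extract_local_kernels(rng.normal(size=(2, 3, 3)), patch_size=2)


def test_self_match_gives_all_ones(rng):
    fm = rng.normal(size=(5, 3, 4))
    bank = extract_local_kernels(fm, patch_size=1)
    scores = response(fm, bank)
    assert np.allclose(scores, 1.0, atol=1e-6)


def test_orthogonal_query_scores_zero():
    g = np.zeros((2, 2, 2))
    g[0] = 1.0  # gallery lives on channel 0
    q = np.zeros((2, 2, 2))
    q[1] = 1.0  # query lives on channel 1
    scores = response(q, extract_local_kernels(g, patch_size=1))
    assert np.allclose(scores, 0.0, atol=1e-7)


@pytest.mark.parametrize("shape_g,shape_q", [((3, 2, 2), (3, 2, 2)), ((2, 4, 4), (2, 3, 4))])
def test_response_matches_exhaustive_oracle(rng, shape_g, shape_q):
    for _ in range(25):
        g = rng.normal(size=shape_g)
        q = rng.normal(size=shape_q)
        got = response(q, extract_local_kernels(g, patch_size=1))
        assert np.allclose(got, brute_force_response(q, g), atol=1e-5)
        assert (got >= -1 - 1e-9).all() and (got <= 1 + 1e-9).all()


def test_response_rejects_channel_mismatch(rng):
    bank = extract_local_kernels(rng.normal(size=(3, 2, 2)), 1)
    with pytest.raises(ValueError, match="channel mismatch"):
        response(rng.normal(size=(4, 2, 2)), bank)


def test_global_mean_pooling():
    assert np.allclose(global_mean_pool_scores([1, 0, 1, 0]), 0.5)
    assert np.allclose(global_mean_pool_scores([0.3] * 6), 0.3)
    grouped = global_mean_pool_scores([1, 0, 1, 0], groups=1)
    assert np.allclose(grouped, 0.5)
    with pytest.raises(ValueError):
        global_mean_pool_scores([])


def test_head_initially_monotone_in_mean_score(rng):
    head = SimilarityHead(6)
    head.eval()
    lo = np.full((1, 6), 0.1, dtype=np.float32)
    hi = np.full((1, 6), 0.9, dtype=np.float32)
    with nn.no_grad():
        assert float(head(hi).data[0]) > float(head(lo).data[0])
    # identical score vectors -> identical similarity
    with nn.no_grad():
        assert float(head(lo).data[0]) == float(head(lo.copy()).data[0])
    with pytest.raises(ValueError):
        head(np.zeros((1, 5), dtype=np.float32))


def test_trained_head_ranks_self_match_first(rng):
    """On separable features, a briefly fitted head puts the matching gallery
    image at rank 1 for every query (20 random query/gallery sets)."""
    S, C = 9, 6
    failures = 0
    for trial in range(20):
        trng = np.random.default_rng(trial)
        gallery = [trng.normal(size=(C, 3, 3)) for _ in range(4)]
        memory = build_class_memory(gallery, range(4), patch_size=1)
        queries = [fm + 0.05 * trng.normal(size=fm.shape) for fm in gallery]
        vecs, labels = [], []
        for q in queries:
            for _, bank in memory.entries:
                vecs.append(response(q, bank))
        for qi in range(4):
            labels.extend([1.0 if gi == qi else 0.0 for gi in range(4)])
        head = SimilarityHead(S)
        train_head(head, np.array(vecs), np.array(labels), epochs=60, lr=0.05)
        ranks = match(queries, memory, head)
        if not all(ranks[i, 0] == i for i in range(4)):
            failures += 1
    assert failures == 0


def test_match_agrees_with_brute_force_sort(rng):
    gallery = [rng.normal(size=(3, 2, 2)) for _ in range(5)]
    queries = [rng.normal(size=(3, 2, 2)) for _ in range(3)]
    memory = build_class_memory(gallery, range(5), patch_size=1)
    head = SimilarityHead(4)
    head.eval()
    sims = similarity_matrix(queries, memory, head)
    ranks = match(queries, memory, head)
    for qi in range(3):
        expect = sorted(range(5), key=lambda g: (-sims[qi, g], g))
        assert ranks[qi].tolist() == expect
    # scalar path agrees with the matrix path
    got = similarity(queries[0], memory.entries[2][1], head)
    assert np.isclose(got, sims[0, 2], atol=1e-6)


def test_single_entry_gallery_and_empty_gallery(rng):
    fm = rng.normal(size=(2, 2, 2))
    memory = build_class_memory([fm], [0], patch_size=1)
    head = SimilarityHead(4)
    head.eval()
    assert match([fm], memory, head)[0, 0] == 0
    from moo_reid.qaconv import ClassMemory

    with pytest.raises(ValueError, match="empty"):
        similarity_matrix([fm], ClassMemory(1, []), head)
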