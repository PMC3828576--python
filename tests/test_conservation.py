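"""Paralogue disorder-conservation scoring and chromosomal location classes."""

import numpy as np
import pytest

from idrmap import (DisorderMask, GeneLocus, ParalogPair, classify_location,
                    conservation_by_location, pair_is_conserved,
                    summarize_conservation)


def mask_with_segments(pid, n_segments, length=400):
    calls = np.zeros(length, dtype=bool)
    for i in range(n_segments):
        start = i * 70
        calls[start:start + 35] = True
    return DisorderMask(pid, calls)


@pytest.mark.parametrize("na,nb,expected", [
    (2, 2, True),
    (0, 1, False),  # gain/loss of a segment
    (0, 0, True),   # equality of zeros
])
def test_pair_conservation_is_count_equality(na, nb, expected):
    assert pair_is_conserved(mask_with_segments("a", na),
                             mask_with_segments("b", nb)) is expected


def test_pair_conservation_symmetric_and_tolerance():
    a, b = mask_with_segments("a", 3), mask_with_segments("b", 2)
    assert pair_is_conserved(a, b) == pair_is_conserved(b, a) is False
    assert pair_is_conserved(a, b, count_tolerance=1) is True


def test_summary_percentages():
    masks = {"a": mask_with_segments("a", 1), "b": mask_with_segments("b", 1),
             "c": mask_with_segments("c", 2), "d": mask_with_segments("d", 2),
             "e": mask_with_segments("e", 0), "f": mask_with_segments("f", 3)}
    pairs = [ParalogPair("a", "b"), ParalogPair("c", "d"), ParalogPair("e", "f")]
    s = summarize_conservation(pairs, masks)
    assert (s.n_pairs, s.n_conserved) == (3, 2)
    assert s.pct_conserved == pytest.approx(200 / 3)
    assert s.pct_nonconserved == pytest.approx(100 / 3)
    assert s.pct_conserved + s.pct_nonconserved == pytest.approx(100.0)


def test_identical_masks_fully_conserved():
    masks = {f"p{i}": mask_with_segments(f"p{i}", 2) for i in range(10)}
    pairs = [ParalogPair(f"p{i}", f"p{(i + 1) % 10}") for i in range(10)]
    assert summarize_conservation(pairs, masks).pct_conserved == 100.0


def test_missing_mask_skipped_with_warning():
    masks = {"a": mask_with_segments("a", 1), "b": mask_with_segments("b", 1)}
    pairs = [ParalogPair("a", "b"), ParalogPair("a", "zz")]
    with pytest.warns(UserWarning, match="zz"):
        s = summarize_conservation(pairs, masks)
    assert (s.n_pairs, s.n_skipped) == (1, 1)


def test_all_pairs_skipped_is_error():
    with pytest.raises(ValueError):
        with pytest.warns(UserWarning):
            summarize_conservation([ParalogPair("x", "y")], {})


def test_conservation_estimate_converges_binomially(rng):
    # segment-count-equality recovery of a known conservation probability
    p_true, n = 0.65, 5000
    masks, pairs = {}, []
    for i in range(n):
        k = int(rng.integers(0, 4))
        masks[f"a{i}"] = mask_with_segments(f"a{i}", k)
        kb = k if rng.random() < p_true else k + 1
        masks[f"b{i}"] = mask_with_segments(f"b{i}", kb)
        pairs.append(ParalogPair(f"a{i}", f"b{i}"))
    s = summarize_conservation(pairs, masks)
    assert s.pct_conserved / 100 == pytest.approx(p_true, abs=0.02)


# ---------------------------------------------------------------------------
# location classes

def locus_at(mid, gene_id="g", chrom="chr1"):
    return GeneLocus(gene_id, chrom, mid - 50, mid + 50, "+", gene_id)


def test_location_classes_geometry():
    cen, clen = 5_000_000, 10_000_000
    assert classify_location(locus_at(cen - 100_000), cen, clen) == "A_centromeric"
    assert classify_location(locus_at(1000), cen, clen) == "C_arm_distal"
    # just outside the centromeric window, well within proximal fraction
    assert classify_location(locus_at(cen + 260_000), cen, clen) == "B_arm_proximal"


def test_location_class_frequencies_match_direct_binning(rng):
    cen, clen, radius, frac = 5_000_000, 10_000_000, 250_000, 0.25
    counts = {"A_centromeric": 0, "B_arm_proximal": 0, "C_arm_distal": 0}
    expected = {"A_centromeric": 0, "B_arm_proximal": 0, "C_arm_distal": 0}
    for i in range(2000):
        mid = int(rng.integers(100, clen - 100))
        counts[classify_location(locus_at(mid), cen, clen, radius, frac)] += 1
        # direct geometric computation
        if abs(mid - cen) <= radius:
            expected["A_centromeric"] += 1
        elif mid < cen and (cen - radius) - mid <= frac * (cen - radius):
            expected["B_arm_proximal"] += 1
        elif mid > cen and mid - (cen + radius) <= frac * (clen - cen - radius):
            expected["B_arm_proximal"] += 1
        else:
            expected["C_arm_distal"] += 1
    assert counts == expected


def test_location_outside_chromosome_is_error():
    with pytest.raises(ValueError, match="midpoint"):
        classify_location(locus_at(11_000_000), 5_000_000, 10_000_000)


def test_per_class_summary_toy_centromeric_fraction():
    # 8 centromeric pairs, exactly 1 non-conserved -> 12.5% non-conserved
    cen, clen = 5_000_000, 10_000_000
    masks, pairs, loci = {}, {}, {}
    loci = {}
    pair_list = []
    for i in range(8):
        a, b = f"a{i}", f"b{i}"
        masks[a] = mask_with_segments(a, 1)
        masks[b] = mask_with_segments(b, 1 if i else 2)  # pair 0 non-conserved
        loci[a] = locus_at(cen + 1000 * i, a)
        pair_list.append(ParalogPair(a, b))
    per = conservation_by_location(pair_list, masks, loci, {"chr1": cen},
                                   {"chr1": clen})
    a_class = per["A_centromeric"]
    assert a_class.n_pairs == 8
    assert a_class.pct_nonconserved == pytest.approx(12.5)
    assert per["B_arm_proximal"] is None and per["C_arm_distal"] is None


def test_conservation_permutation_invariance(small_bundle):
    masks = small_bundle.mask_dict()
    pairs = list(small_bundle.pairs)
    s1 = summarize_conservation(pairs, masks)
    s2 = summarize_conservation(pairs[::-1], masks)
    s3 = summarize_conservation(
        [ParalogPair(p.id_b, p.id_a) for p in pairs], masks)
    assert s1.n_conserved == s2.n_conserved == s3.n_conserved
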