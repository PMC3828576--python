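"""Segment extraction against a brute-force oracle, and the Table-style
residue classification arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idrmap import (DisorderBreakdown, DisorderMask, DomainAnnotation,
                    classify_disordered_residues, extract_segments,
                    summarize_breakdowns)


def brute_force_segments(calls, min_len):
    """Independent O(L) left-to-right scan for maximal runs."""
    runs, start = [], None
    for i, c in enumerate(list(calls) + [False]):
        if c and start is None:
            start = i
        elif not c and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    return runs


def test_single_long_run():
    calls = np.zeros(100, dtype=bool)
    calls[10:45] = True
    (seg,) = extract_segments(DisorderMask("p", calls))
    assert (seg.start, seg.end, seg.length) == (10, 45, 35)


def test_length_threshold_boundary():
    calls = np.zeros(100, dtype=bool)
    calls[0:29] = True   # below threshold
    calls[40:70] = True  # exactly 30
    segs = extract_segments(DisorderMask("p", calls))
    assert [(s.start, s.end) for s in segs] == [(40, 70)]


def test_empty_mask_gives_no_segments():
    assert extract_segments(DisorderMask("p", np.zeros(0, dtype=bool))) == []


@pytest.mark.parametrize("min_len", [1, 5, 30])
def test_extraction_matches_oracle_on_random_masks(rng, min_len):
    for _ in range(200):
        n = int(rng.integers(1, 400))
        calls = rng.random(n) < rng.uniform(0.1, 0.9)
        segs = extract_segments(DisorderMask("p", calls), min_len)
        assert [(s.start, s.end) for s in segs] == brute_force_segments(calls, min_len)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.booleans(), max_size=200), st.integers(1, 40))
def test_extraction_matches_oracle_property(calls, min_len):
    mask = DisorderMask("p", np.array(calls, dtype=bool))
    segs = extract_segments(mask, min_len)
    assert [(s.start, s.end) for s in segs] == brute_force_segments(calls, min_len)
    # maximality: flanking residues are ordered
    for s in segs:
        assert s.start == 0 or not calls[s.start - 1]
        assert s.end == len(calls) or not calls[s.end]


# ---------------------------------------------------------------------------
# classification

def brute_force_breakdown(calls, domains, L):
    """Per-residue labelling oracle: independent re-derivation."""
    merged = []
    for s, e in sorted((d.start, d.end) for d in domains):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    counts = {"in": 0, "link": 0, "nt": 0, "ct": 0}
    for i in range(L):
        if not calls[i]:
            continue
        if any(s <= i < e for s, e in merged):
            counts["in"] += 1
        elif i < merged[0][0]:
            counts["nt"] += 1
        elif i >= merged[-1][1]:
            counts["ct"] += 1
        else:
            counts["link"] += 1
    return counts


def test_classification_single_domain_all_disordered():
    mask = DisorderMask("p", np.ones(10, dtype=bool))
    b = classify_disordered_residues(mask, [DomainAnnotation("p", "d", 3, 7)], 10)
    assert (b.n_in_domain, b.n_nterm, b.n_cterm, b.n_linker) == (4, 3, 3, 0)


def test_classification_linker_between_domains():
    calls = np.zeros(10, dtype=bool)
    calls[4:6] = True
    domains = [DomainAnnotation("p", "d1", 2, 4), DomainAnnotation("p", "d2", 6, 8)]
    b = classify_disordered_residues(DisorderMask("p", calls), domains, 10)
    assert b.n_linker == 2 and b.n_disordered == 2


def test_classification_requires_domains_and_valid_intervals():
    mask = DisorderMask("p", np.ones(10, dtype=bool))
    with pytest.raises(ValueError):
        classify_disordered_residues(mask, [], 10)
    with pytest.raises(ValueError, match="outside"):
        classify_disordered_residues(mask, [DomainAnnotation("p", "d", 5, 12)], 10)


def test_classification_matches_per_residue_oracle(rng):
    for _ in range(300):
        L = int(rng.integers(10, 300))
        calls = rng.random(L) < 0.4
        k = int(rng.integers(1, 5))
        domains = []
        for j in range(k):
            s = int(rng.integers(0, L - 1))
            e = int(rng.integers(s + 1, L + 1))
            domains.append(DomainAnnotation("p", f"d{j}", s, e))
        b = classify_disordered_residues(DisorderMask("p", calls), domains, L)
        oracle = brute_force_breakdown(calls, domains, L)
        assert (b.n_in_domain, b.n_linker, b.n_nterm, b.n_cterm) == (
            oracle["in"], oracle["link"], oracle["nt"], oracle["ct"])
        # exact partition identity
        assert (b.n_in_domain + b.n_linker + b.n_nterm + b.n_cterm
                == b.n_disordered == int(calls.sum()))


# ---------------------------------------------------------------------------
# summary double-normalization

def test_summary_double_normalization_arithmetic():
    b = DisorderBreakdown("p", 10, 1, 1, 4, 4)
    s = summarize_breakdowns([b], total_residues=50)
    assert s.pct_total_disorder == pytest.approx(20.0)
    assert s.pct_in_domain == pytest.approx(10.0)
    assert s.pct_outside == pytest.approx(90.0)
    assert s.pct_linker == pytest.approx(100 / 9)
    assert s.pct_nterm == pytest.approx(400 / 9)
    assert s.pct_cterm == pytest.approx(400 / 9)
    assert s.pct_in_domain + s.pct_outside == pytest.approx(100.0)
    assert s.pct_linker + s.pct_nterm + s.pct_cterm == pytest.approx(100.0)


def test_summary_all_disorder_in_domains_flags_termini_undefined():
    b = DisorderBreakdown("p", 5, 5, 0, 0, 0)
    s = summarize_breakdowns([b], total_residues=20)
    assert s.pct_outside == 0.0
    assert not s.defined and math.isnan(s.pct_nterm)


def test_summary_equals_direct_recomputation(rng):
    # aggregate over a cohort == recomputation from pooled raw counts
    breakdowns, total = [], 0
    pooled = np.zeros(4, dtype=int)
    for i in range(50):
        L = int(rng.integers(40, 200))
        parts = rng.multinomial(int(rng.integers(0, L // 2)), [0.25] * 4)
        breakdowns.append(DisorderBreakdown(f"p{i}", int(parts.sum()), *map(int, parts)))
        pooled += parts
        total += L
    s = summarize_breakdowns(breakdowns, total)
    n_dis, n_out = pooled.sum(), pooled[1:].sum()
    assert s.pct_in_domain == pytest.approx(100 * pooled[0] / n_dis)
    assert s.pct_nterm == pytest.approx(100 * pooled[2] / n_out)
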