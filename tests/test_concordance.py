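"""Set-comparison statistics: percent overlap, enrichment with exact
hypergeometric oracles, identification/accuracy, Venn partitions, and
identifier harmonization."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pooldeg import (GeneSet, accuracy_fraction, fold_enrichment,
                     harmonize_ids, identification_fraction, multiway_overlap,
                     pairwise_overlap, read_gene_list, read_id_mapping,
                     round_half_up, write_gene_list)


def _ids(prefix, n):
    return frozenset(f"{prefix}{i}" for i in range(n))


def _pair_with(intersection, only_a, only_b, namespace="WormBase"):
    shared = _ids("s", intersection)
    a = GeneSet("a", shared | _ids("a", only_a), namespace)
    b = GeneSet("b", shared | _ids("b", only_b), namespace)
    return a, b


# ---------------------------------------------------------------------------
# pairwise overlap
# ---------------------------------------------------------------------------

def test_percent_overlap_smallest_set_denominator():
    """Two DEG sets sharing 735 genes with 685 and 776 unique: the overlap
    relative to the smaller set is 51.8%, printed as 52%."""
    a, b = _pair_with(735, 685, 776)
    res = pairwise_overlap(a, b)
    assert (res.n_intersection, res.n_only_a, res.n_only_b) == (735, 685, 776)
    assert res.percent_overlap == pytest.approx(100 * 735 / 1420, abs=1e-9)
    assert round(res.percent_overlap, 1) == 51.8
    assert res.percent_overlap_rounded == 52


def test_overlap_identity_and_disjoint():
    a = GeneSet("a", _ids("x", 10))
    same = pairwise_overlap(a, GeneSet("b", a.ids))
    assert same.percent_overlap == 100.0
    assert same.n_only_a == same.n_only_b == 0
    disjoint = pairwise_overlap(a, GeneSet("b", _ids("y", 7)))
    assert disjoint.percent_overlap == 0.0


def test_overlap_rejects_namespace_mismatch_and_empty():
    a = GeneSet("a", _ids("x", 3), "WormBase")
    b = GeneSet("b", _ids("x", 3), "Ensembl")
    with pytest.raises(ValueError, match="namespace"):
        pairwise_overlap(a, b)
    with pytest.raises(ValueError, match="empty identifiers"):
        GeneSet("bad", frozenset({""}))
    with pytest.raises(ValueError, match="empty"):
        pairwise_overlap(a, GeneSet("b", frozenset(), "WormBase"))


def test_overlap_symmetry_on_random_sets():
    rng = np.random.default_rng(4)
    universe = [f"g{i}" for i in range(100)]
    for _ in range(10):
        a = GeneSet("a", frozenset(rng.choice(universe, 30, replace=False)))
        b = GeneSet("b", frozenset(rng.choice(universe, 45, replace=False)))
        ab, ba = pairwise_overlap(a, b), pairwise_overlap(b, a)
        assert ab.n_intersection == ba.n_intersection
        assert ab.percent_overlap == ba.percent_overlap
        fab = fold_enrichment(a, b, 100)
        fba = fold_enrichment(b, a, 100)
        assert fab.fold_enrichment == pytest.approx(fba.fold_enrichment)
        assert fab.hypergeometric_p == pytest.approx(fba.hypergeometric_p)


@settings(max_examples=60, derandomize=True)
@given(a=st.frozensets(st.integers(0, 30), min_size=1, max_size=20),
       b=st.frozensets(st.integers(0, 30), min_size=1, max_size=20))
def test_percent_overlap_100_iff_smaller_is_subset(a, b):
    sa = GeneSet("a", frozenset(map(str, a)))
    sb = GeneSet("b", frozenset(map(str, b)))
    res = pairwise_overlap(sa, sb)
    small, big = (a, b) if len(a) <= len(b) else (b, a)
    assert (res.percent_overlap == 100.0) == small.issubset(big)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def test_fold_enrichment_closed_forms():
    a, b = _pair_with(5, 5, 5)
    res = fold_enrichment(a, b, 100)
    assert res.fold_enrichment == pytest.approx(5 / (10 * 10 / 100))  # 5.0
    # intersection exactly at the independence expectation -> 1.0
    a2, b2 = _pair_with(4, 16, 16)  # |a|=|b|=20, N=100 -> expect 4
    res2 = fold_enrichment(a2, b2, 100)
    assert res2.fold_enrichment == pytest.approx(1.0)


def test_hypergeometric_matches_exhaustive_draw_enumeration():
    """Upper-tail p for (N=20, |a|=5, |b|=8, k=4) equals a literal
    enumeration of all C(20,5) possible draws."""
    a, b = _pair_with(4, 1, 4)  # |a|=5, |b|=8
    res = fold_enrichment(a, b, 20)
    hits = sum(1 for draw in itertools.combinations(range(20), 5)
               if sum(1 for x in draw if x < 8) >= 4)
    assert res.hypergeometric_p == pytest.approx(hits / comb(20, 5), rel=1e-12)


def test_log_tail_reported_for_underflowing_p():
    a, b = _pair_with(735, 685, 776)
    res = fold_enrichment(a, b, 20_000)
    assert res.hypergeometric_p == 0.0  # underflows double precision
    # but the log-scale tail survives as a finite number
    assert np.isfinite(res.log_hypergeometric_p)
    assert res.log_hypergeometric_p < -700


def test_background_smaller_than_union_rejected():
    a, b = _pair_with(5, 5, 5)
    with pytest.raises(ValueError, match="smaller than the union"):
        fold_enrichment(a, b, 14)


# ---------------------------------------------------------------------------
# identification / accuracy
# ---------------------------------------------------------------------------

def test_identification_of_reference_recovery():
    """701 recovered of a 735-gene reference is 95.4%, printed as 95%."""
    reference = GeneSet("ref", _ids("r", 735))
    candidate = GeneSet("cand",
                        frozenset(list(sorted(reference.ids))[:701])
                        | _ids("extra", 2000))
    pct = identification_fraction(candidate, reference)
    assert pct == pytest.approx(100 * 701 / 735, abs=1e-9)
    assert round_half_up(pct) == 95


def test_identification_saturation_and_null():
    ref = GeneSet("ref", _ids("r", 10))
    superset = GeneSet("c", ref.ids | _ids("x", 5))
    assert identification_fraction(superset, ref) == 100.0
    assert identification_fraction(GeneSet("c", _ids("y", 3)), ref) == 0.0
    with pytest.raises(ValueError, match="empty"):
        identification_fraction(superset, GeneSet("ref", frozenset()))


def test_accuracy_fraction_examples():
    ref = GeneSet("ref", _ids("r", 50))
    inside = GeneSet("c", frozenset(list(sorted(ref.ids))[:8]))
    assert accuracy_fraction(inside, ref) == 100.0
    mixed = GeneSet("c", frozenset(list(sorted(ref.ids))[:7]) | _ids("x", 13))
    assert accuracy_fraction(mixed, ref) == pytest.approx(35.0)
    with pytest.raises(ValueError, match="empty"):
        accuracy_fraction(GeneSet("c", frozenset()), ref)


def test_identification_and_accuracy_share_the_intersection():
    rng = np.random.default_rng(11)
    universe = [f"g{i}" for i in range(60)]
    for _ in range(10):
        x = GeneSet("x", frozenset(rng.choice(universe, 20, replace=False)))
        r = GeneSet("r", frozenset(rng.choice(universe, 25, replace=False)))
        inter = len(x.ids & r.ids)
        # brute-force per-element membership count
        assert inter == sum(1 for g in x.ids if g in r.ids)
        assert identification_fraction(x, r) == pytest.approx(
            100 * inter / len(r))
        assert accuracy_fraction(x, r) == pytest.approx(100 * inter / len(x))
        # complement identity: recovered + missed = 100% of the reference
        missed = 100 * len(r.ids - x.ids) / len(r)
        assert identification_fraction(x, r) + missed == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# multiway partitions
# ---------------------------------------------------------------------------

def test_multiway_disjoint_and_identical():
    disjoint = [GeneSet(l, _ids(l, 4)) for l in ("a", "b", "c")]
    m = multiway_overlap(disjoint)
    assert all(m.counts[(l,)] == 4 for l in ("a", "b", "c"))
    assert sum(c for pat, c in m.counts.items() if len(pat) > 1) == 0

    ids = _ids("z", 6)
    identical = [GeneSet(l, ids) for l in ("a", "b", "c")]
    m2 = multiway_overlap(identical)
    assert m2.counts[("a", "b", "c")] == 6
    assert sum(c for pat, c in m2.counts.items() if len(pat) < 3) == 0


def test_multiway_matches_per_element_enumeration():
    rng = np.random.default_rng(21)
    universe = [f"g{i}" for i in range(200)]
    sets = [GeneSet(f"s{i}",
                    frozenset(rng.choice(universe, 50, replace=False)))
            for i in range(4)]
    m = multiway_overlap(sets)
    m.validate()
    for r in range(1, 5):
        for combo in itertools.combinations(sets, r):
            members = set(combo)
            expect = sum(
                1 for g in universe
                if all(g in s.ids for s in combo)
                and all(g not in s.ids for s in sets if s not in members))
            assert m.count_exactly([s.label for s in combo]) == expect
    for s in sets:
        assert m.margin(s.label) == 50


def test_multiway_rejects_bad_inputs():
    a = GeneSet("a", _ids("x", 3))
    with pytest.raises(ValueError, match="2-4"):
        multiway_overlap([a])
    b = GeneSet("b", _ids("x", 3), "other")
    with pytest.raises(ValueError, match="namespace"):
        multiway_overlap([a, b])


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def test_harmonize_identity_and_many_to_one():
    s = GeneSet("s", frozenset({"o1", "o2", "o3"}), "old")
    out, unmapped = harmonize_ids(s, {"o1": "o1", "o2": "o2", "o3": "o3"})
    assert out.ids == s.ids and unmapped == []
    out2, _ = harmonize_ids(s, {"o1": "n1", "o2": "n1", "o3": "n2"})
    assert out2.ids == frozenset({"n1", "n2"})  # deduplicated


def test_harmonize_drops_and_reports_unmapped():
    s = GeneSet("s", frozenset({"o1", "o2", "o3", "o4", "o5"}), "old")
    out, unmapped = harmonize_ids(s, {"o1": "n1", "o2": "n2", "o4": "n4"})
    assert out.ids == frozenset({"n1", "n2", "n4"})
    assert unmapped == ["o3", "o5"]


def test_mapping_conflicts_rejected(tmp_path):
    path = tmp_path / "map.tsv"
    path.write_text("o1\tn1\no1\tn2\n")
    with pytest.raises(ValueError, match="conflicting"):
        read_id_mapping(path)
    path.write_text("o1\tn1\no1\tn1\no2\tn2\n")  # agreeing duplicate is fine
    assert read_id_mapping(path) == {"o1": "n1", "o2": "n2"}


def test_gene_list_roundtrip(tmp_path):
    s = GeneSet("genes", _ids("WBGene", 5), "WormBase")
    write_gene_list(s, tmp_path / "genes.txt")
    back = read_gene_list(tmp_path / "genes.txt", namespace="WormBase")
    assert back.ids == s.ids
    assert back.label == "genes"
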