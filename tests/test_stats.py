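"""Column classification, SV%/PIS%, ranking, class summaries and the NJ
sanity tree."""

import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastovar.io import AlignmentMatrix
from plastovar.stats import (ColumnStats, class_summary, classify_columns,
                             concatenate_alignments, count_indel_events,
                             nj_tree, p_distance_matrix, pis_percent,
                             rank_regions, sv_percent, variability_stats)


def _aln(rows, name="r", cls="IGS"):
    return AlignmentMatrix(name, cls, [f"t{i}" for i in range(len(rows))],
                           rows)


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------

def _oracle(rows):
    """Pure-python column scanner implementing the documented counting
    rules from scratch (no shared code with the implementation)."""
    ncol = len(rows[0])
    inv = subs = pis = 0
    for k in range(ncol):
        col = [r[k] for r in rows]
        if "-" in col:
            continue
        states = {}
        for c in col:
            if c in "ACGT":
                states[c] = states.get(c, 0) + 1
        if not states:
            continue
        if len(states) == 1:
            inv += 1
        else:
            subs += len(states) - 1
            if sum(1 for v in states.values() if v >= 2) >= 2:
                pis += 1
    events = set()
    for r in rows:
        start = None
        for k, c in enumerate(r + "$"):
            if c == "-":
                if start is None:
                    start = k
            elif start is not None:
                events.add((start, k))
                start = None
    return inv, subs, pis, len(events)


def test_classification_matches_bruteforce_oracle_on_random_alignments():
    rng = np.random.default_rng(99)
    alphabet = np.array(list("ACGT-N"))
    for _ in range(1000):
        nrow = int(rng.integers(2, 9))
        ncol = int(rng.integers(1, 51))
        rows = ["".join(rng.choice(alphabet, size=ncol,
                                   p=[.22, .22, .22, .22, .08, .04]))
                for _ in range(nrow)]
        # avoid gap-only rows producing empty post-strip regions is not
        # needed: classify_columns works on the matrix as-is
        got = classify_columns(_aln(rows))
        inv, subs, pis, events = _oracle(rows)
        assert (got.n_invariable, got.n_subs, got.n_pis,
                got.n_indel_events) == (inv, subs, pis, events)


# ---------------------------------------------------------------------------
# documented examples
# ---------------------------------------------------------------------------

def test_identical_rows_all_invariable():
    c = classify_columns(_aln(["ACGT", "ACGT", "ACGT"]))
    assert c == ColumnStats(n_sites=4, n_invariable=4, n_pis=0, n_subs=0,
                            n_indel_events=0)


def test_three_rows_cannot_be_parsimony_informative():
    """{AAAA, AAAT, AATT}: two variable columns, each with a singleton
    state, so substitutions are counted but no column is PIS (PIS needs
    two states each in >= 2 rows, impossible to satisfy twice with 3
    rows and 2 states unless a state repeats)."""
    c = classify_columns(_aln(["AAAA", "AAAT", "AATT"]))
    assert c.n_invariable == 2
    assert c.n_subs == 2
    assert c.n_pis == 0


def test_pis_needs_two_states_twice():
    c = classify_columns(_aln(["AAAA", "AAAT", "AATT", "AATT"]))
    # col2: A,A,T,T -> PIS; col3: A,T,T,T -> variable, not PIS
    assert c.n_pis == 1
    assert c.n_subs == 2


def test_gap_columns_count_as_indel_events_only():
    c = classify_columns(_aln(["AC--T", "ACGGT", "ACGGT"]))
    assert c.n_indel_events == 1
    assert c.n_invariable == 3
    assert c.n_subs == 0


def test_shared_gap_interval_is_one_event():
    assert count_indel_events(_aln(["A--T", "A--T", "ACGT"])) == 1


def test_distinct_gap_intervals_are_distinct_events():
    assert count_indel_events(_aln(["A--T", "A-GT", "ACGT"])) == 2


def test_terminal_gap_is_an_event():
    assert count_indel_events(_aln(["ACG-", "ACGT"])) == 1


def test_gapfree_column_with_k_states_contributes_k_minus_1():
    c = classify_columns(_aln(["A", "C", "G", "T"]))
    assert c.n_subs == 3


# ---------------------------------------------------------------------------
# percentages
# ---------------------------------------------------------------------------

def test_sv_and_pis_formulas():
    c = ColumnStats(n_sites=100, n_invariable=96, n_pis=2, n_subs=3,
                    n_indel_events=1)
    assert sv_percent(c) == pytest.approx(4.0)
    assert pis_percent(c) == pytest.approx(2.0)


def test_zero_denominator_reports_zero():
    c = ColumnStats(n_sites=4, n_invariable=0, n_pis=0, n_subs=0,
                    n_indel_events=0)
    assert sv_percent(c) == 0.0
    assert pis_percent(c) == 0.0


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.lists(st.text(alphabet="ACGT-", min_size=12, max_size=12),
                min_size=2, max_size=6))
def test_subs_bound_pis_and_partition_invariant(rows):
    c = classify_columns(_aln(rows))
    # every PIS column has >= 2 states, contributing >= 1 substitution
    assert c.n_pis <= c.n_subs
    # invariable + variable-column count never exceeds gap-free columns
    ncol = len(rows[0])
    gapfree = sum(1 for k in range(ncol)
                  if all(r[k] != "-" for r in rows))
    assert c.n_invariable <= gapfree


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def _vs(name, cls, sv, pis, length):
    denom = 1000
    subs = round(sv * denom / 100)
    c = ColumnStats(n_sites=length, n_invariable=denom - subs,
                    n_pis=round(pis * denom / 100), n_subs=subs,
                    n_indel_events=0)
    from plastovar.stats import VariabilityStats
    return VariabilityStats(region_name=name, region_class=cls, n_taxa=4,
                            length=length, columns=c,
                            sv_pct=sv_percent(c), pis_pct=pis_percent(c))


def test_rank_ties_prefer_longer_region_then_name():
    a = _vs("short", "IGS", 5.0, 1.0, 300)
    b = _vs("long", "IGS", 5.0, 1.0, 500)
    c = _vs("top", "IGS", 9.0, 1.0, 100)
    ranked = rank_regions([a, b, c], metric="sv", top_n=10)
    assert [s.region_name for s in ranked] == ["top", "long", "short"]


def test_rank_is_input_order_invariant():
    stats = [_vs(f"r{i}", "IGS", float(i), 0.5, 200 + i) for i in range(8)]
    fwd = rank_regions(list(stats), metric="sv", top_n=3)
    rev = rank_regions(stats[::-1], metric="sv", top_n=3)
    assert [s.region_name for s in fwd] == [s.region_name for s in rev]


def test_rank_topn_larger_than_list_returns_all():
    stats = [_vs("a", "IGS", 1.0, 0.0, 100)]
    assert len(rank_regions(stats, top_n=10)) == 1


def test_rank_empty_rejected():
    with pytest.raises(ValueError):
        rank_regions([])


# ---------------------------------------------------------------------------
# class summary
# ---------------------------------------------------------------------------

def test_class_summary_hand_arithmetic():
    """153 substitutions + 30 indel events + 9817 invariable: mutation
    1.53%, indel 0.30%, ratio 5.10."""
    c = ColumnStats(n_sites=10000, n_invariable=9817, n_pis=0, n_subs=153,
                    n_indel_events=30)
    from plastovar.stats import VariabilityStats
    s = VariabilityStats("all", "IGS", 8, 10000, c, sv_percent(c),
                         pis_percent(c))
    summary = {cs.scope: cs for cs in class_summary([s])}
    assert summary["plastome"].mutation_pct == pytest.approx(1.53)
    assert summary["plastome"].indel_pct == pytest.approx(0.30)
    assert summary["plastome"].ratio == pytest.approx(5.1)
    assert summary["IGS"].ratio == pytest.approx(5.1)
    assert summary["CDS"].mutation_pct == 0.0


def test_zero_indels_report_infinite_ratio():
    c = ColumnStats(n_sites=100, n_invariable=95, n_pis=0, n_subs=5,
                    n_indel_events=0)
    from plastovar.stats import VariabilityStats
    s = VariabilityStats("x", "CDS", 4, 100, c, sv_percent(c),
                         pis_percent(c))
    summary = {cs.scope: cs for cs in class_summary([s])}
    assert math.isinf(summary["CDS"].ratio)


# ---------------------------------------------------------------------------
# distances and NJ
# ---------------------------------------------------------------------------

def test_p_distance_excludes_gap_columns():
    aln = _aln(["ACGT-A", "ACGAGA"])
    d = p_distance_matrix(aln)
    # column 4 has a gap and is excluded: 5 comparable columns, one
    # mismatch (T vs A at column 3)
    assert d[0, 1] == pytest.approx(1 / 5)


def test_concatenation_requires_shared_taxa():
    a = AlignmentMatrix("r1", "IGS", ["x", "y"], ["AC", "AC"])
    b = AlignmentMatrix("r2", "IGS", ["x", "z"], ["GG", "GG"])
    with pytest.raises(ValueError):
        concatenate_alignments([a, b])


def test_nj_recovers_two_pairs_topology():
    """Taxa a,b differ by 1 site and c,d by 1 site, with 20 differences
    across the pairs: NJ must return ((a,b),(c,d))."""
    rng = np.random.default_rng(11)
    base = "".join(rng.choice(list("ACGT"), size=60))
    far = list(base)
    for pos in rng.choice(60, size=20, replace=False):
        far[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[far[pos]]
    far = "".join(far)

    def tweak(s, pos):
        l = list(s)
        l[pos] = {"A": "G", "C": "T", "G": "A", "T": "C"}[l[pos]]
        return "".join(l)

    aln = AlignmentMatrix("x", "IGS", ["a", "b", "c", "d"],
                          [base, tweak(base, 3), far, tweak(far, 7)])
    newick = nj_tree([aln])
    tns = dendropy.TaxonNamespace()
    got = dendropy.Tree.get(data=newick, schema="newick",
                            taxon_namespace=tns)
    want = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick",
                             taxon_namespace=tns)
    got.encode_bipartitions()
    want.encode_bipartitions()
    assert dendropy.calculate.treecompare.symmetric_difference(
        got, want) == 0


def test_nj_needs_three_taxa():
    aln = AlignmentMatrix("x", "IGS", ["a", "b"], ["ACGT", "ACGA"])
    with pytest.raises(ValueError):
        nj_tree([aln])


def test_variability_stats_round_trip():
    aln = _aln(["ACGT", "ACGA", "ACGA", "TCGA"], name="demo", cls="intron")
    s = variability_stats(aln)
    assert s.region_name == "demo"
    assert s.region_class == "intron"
    assert s.columns == classify_columns(aln)
    assert s.sv_pct == sv_percent(s.columns)
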