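"""Quadripartite detection, GC partitioning, junction geometry, censuses
and gene-order inversion blocks."""

import numpy as np
import pytest

from plastovar.io import GeneFeature, Plastome
from plastovar.structure import (QuadripartiteStructure,
                                 StructureNotFound,
                                 detect_gene_order_inversions,
                                 detect_quadripartite,
                                 flag_alternative_start_codons, gc_report,
                                 gene_census, intron_census, junction_report)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _planted_genome(rng, L, I, S):
    """LSC + IRb + SSC + IRa with IRa = revcomp(IRb), and the partition
    boundary bases fixed so no chance base-pairing blurs the junctions."""
    lsc = list(_random_seq(rng, L))
    irb = list(_random_seq(rng, I))
    ssc = list(_random_seq(rng, S))
    ira = [_COMP[c] for c in reversed(irb)]
    # anti-diagonal D = 2L + 2I + S - 1; the first extension step past
    # each junction pairs seq[L+I] with seq[L+I+S-1] — break that pair
    ssc[0] = "A"
    ssc[-1] = "A"
    return "".join(lsc + irb + ssc + ira)


def test_planted_structure_recovered_exactly():
    rng = np.random.default_rng(5)
    L, I, S = 50_000, 8_000, 10_000
    p = Plastome(id="planted", sequence=_planted_genome(rng, L, I, S))
    q = detect_quadripartite(p)
    assert (q.lsc_length, q.ir_length, q.ssc_length) == (L, I, S)
    assert q.lsc == (0, L)
    assert q.irb == (L, L + I)
    assert q.ssc == (L + I, L + I + S)
    assert q.ira == (L + I + S, L + 2 * I + S)
    assert q.ir_mismatches == 0
    assert q.junctions == {"JLB": L, "JSB": L + I, "JSA": L + I + S,
                           "JLA": 0}


def test_isolated_ir_mismatches_do_not_move_boundaries():
    """Five point mutations scattered inside one IR arm are crossed by
    the extension and counted, not used to trim the arm."""
    rng = np.random.default_rng(5)
    L, I, S = 50_000, 8_000, 10_000
    seq = list(_planted_genome(rng, L, I, S))
    for pos in (L + 700, L + 2100, L + 3900, L + 5500, L + 7300):
        seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
    q = detect_quadripartite(Plastome(id="mut", sequence="".join(seq)))
    assert (q.lsc_length, q.ir_length, q.ssc_length) == (L, I, S)
    assert q.ir_mismatches == 5


def _longest_inverted_repeat(seq):
    """Brute-force O(n^2): longest exact inverted repeat with disjoint
    arms (arm length, in bp)."""
    n = len(seq)
    best = 0
    for D in range(2 * n - 1):
        run = 0
        x0 = max(0, D - n + 1)
        for x in range(x0, (D - 1) // 2 + 1):
            if _COMP.get(seq[x]) == seq[D - x]:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


def test_detected_ir_length_matches_bruteforce_oracle():
    rng = np.random.default_rng(19)
    seq = _planted_genome(rng, 600, 150, 300)
    p = Plastome(id="small", sequence=seq)
    q = detect_quadripartite(p, min_ir=100)
    assert q.ir_mismatches == 0
    assert q.ir_length == _longest_inverted_repeat(seq) == 150


def test_partitions_tile_the_genome(toy_run):
    q = detect_quadripartite(toy_run["ancestor"])
    n = q.genome_length
    assert q.lsc_length + q.ssc_length + 2 * q.ir_length == n
    # every position belongs to exactly one partition
    for pos in range(0, n, 997):
        assert q.partition_of(pos) in ("LSC", "IRB", "SSC", "IRA")
    # mirror is an involution between the arms
    for pos in range(q.irb[0], q.irb[1], 251):
        m = q.mirror(pos)
        assert q.partition_of(m) == "IRA"
        assert q.mirror(m) == pos


def test_structure_not_found_on_plain_sequence():
    rng = np.random.default_rng(3)
    p = Plastome(id="norepeat", sequence=_random_seq(rng, 30_000))
    with pytest.raises(StructureNotFound):
        detect_quadripartite(p)


def test_genome_too_short_for_requested_ir():
    p = Plastome(id="short", sequence="ACGT" * 100)
    with pytest.raises(StructureNotFound):
        detect_quadripartite(p, min_ir=1000)


# ---------------------------------------------------------------------------
# GC partitioning
# ---------------------------------------------------------------------------

def _no_ir_structure(n):
    return QuadripartiteStructure(lsc=(0, n), irb=(n, n), ssc=(n, n),
                                  ira=(n, n), genome_length=n,
                                  ir_mismatches=0, mirror_diag=0)


def test_gc_report_hand_counts():
    """'ACGTACGTAA' with a CDS over [1,5): overall 4/10, CDS 'CGTA' 2/4,
    IGS 'A'+'CGTAA' 2/6."""
    p = Plastome(id="hand", sequence="ACGTACGTAA",
                 features=[GeneFeature("x", "CDS", 1, ((1, 5),))])
    rep = gc_report(p, _no_ir_structure(10))
    assert rep.overall_pct == 40.0
    assert rep.lsc_pct == 40.0
    assert rep.ir_pct == 0.0  # empty partition
    assert rep.by_class["CDS"] == 50.0
    assert rep.by_class["IGS"] == 33.3


def test_gc_report_all_gc_sequence():
    p = Plastome(id="gc", sequence="GC" * 20)
    rep = gc_report(p, _no_ir_structure(40))
    assert rep.overall_pct == 100.0


def test_gc_ir_elevated_ssc_depressed(toy_run):
    """The simulator's default GC skew (IR > LSC > SSC) survives into the
    assembled genome."""
    q = detect_quadripartite(toy_run["ancestor"])
    rep = gc_report(toy_run["ancestor"], q)
    assert rep.ir_pct > rep.lsc_pct > rep.ssc_pct


# ---------------------------------------------------------------------------
# junction geometry
# ---------------------------------------------------------------------------

def test_junction_spanning_genes_on_toy_ancestor(toy_run):
    anc = toy_run["ancestor"]
    q = detect_quadripartite(anc)
    rep = junction_report(anc, q)
    spanning = {(e.gene, e.junction): e for e in rep.entries if e.spans}
    # ndhF reaches 56 bp across JSB into IRb
    ndhf = spanning[("ndhF", "JSB")]
    assert ndhf.bp_upstream == 56
    # ycf1 reaches 200 bp across JSA into IRa
    ycf1 = spanning[("ycf1", "JSA")]
    assert ycf1.bp_downstream == 200
    # bp on each side of the junction always add up to the gene's span
    by_name = {f.name: f for f in anc.features}
    for e in rep.entries:
        if e.spans:
            f = by_name[e.gene]
            assert e.bp_upstream + e.bp_downstream <= f.end - f.start \
                or e.bp_upstream + e.bp_downstream == f.end - f.start


def test_pseudo_ycf1_overlaps_ndhf(toy_run):
    """The IR-mirror projection of ycf1's IRa overhang lands at JSB and
    overlaps ndhF by exactly ndhF's own 56 bp IR overhang."""
    anc = toy_run["ancestor"]
    q = detect_quadripartite(anc)
    rep = junction_report(anc, q)
    ycf1_proj = [ps for ps in rep.pseudo if ps.gene == "ycf1"]
    assert len(ycf1_proj) == 1
    ps = ycf1_proj[0]
    assert ps.length == 200
    assert dict(ps.overlaps).get("ndhF") == 56


def test_gene_ending_exactly_at_junction_does_not_span():
    q = QuadripartiteStructure(lsc=(0, 200), irb=(200, 250), ssc=(250, 350),
                               ira=(350, 400), genome_length=400,
                               ir_mismatches=0, mirror_diag=799)
    p = Plastome(id="edge", sequence="A" * 400,
                 features=[GeneFeature("x", "CDS", 1, ((150, 200),))])
    rep = junction_report(p, q)
    jlb = [e for e in rep.entries if e.junction == "JLB" and e.gene == "x"]
    assert jlb and jlb[0].distance == 0 and not jlb[0].spans


def test_junction_distances_recomputable(toy_run):
    """Non-spanning distances equal the modular gap between the gene end
    nearest the junction and the junction coordinate."""
    anc = toy_run["ancestor"]
    q = detect_quadripartite(anc)
    n = len(anc)
    rep = junction_report(anc, q)
    by_name = {}
    for f in anc.features:
        by_name.setdefault(f.name, []).append(f)
    for e in rep.entries:
        if e.spans:
            continue
        jpos = rep.junctions[e.junction]
        gaps = []
        for f in by_name[e.gene]:
            gaps.append((jpos - f.end) % n)    # gene upstream of junction
            gaps.append((f.start - jpos) % n)  # gene downstream
        assert e.distance == min(gaps)


# ---------------------------------------------------------------------------
# censuses
# ---------------------------------------------------------------------------

def test_toy_ancestor_census(toy_run):
    anc = toy_run["ancestor"]
    q = detect_quadripartite(anc)
    census = gene_census(anc, q)
    assert census["unique_genes"] == 12
    assert census["protein_coding"] == 8
    assert census["trna"] == 3
    assert census["rrna"] == 1
    assert census["duplicated_in_ir"] == ["rps19", "rrn16", "trnH-GUG"]
    introns = intron_census(anc, q)
    assert introns["one_intron"] == ["trnK-UUU"]
    assert introns["two_intron"] == []


def test_census_of_unannotated_plastome_is_zero():
    p = Plastome(id="bare", sequence="ACGT" * 10)
    census = gene_census(p)
    assert census["unique_genes"] == 0
    assert census["duplicated_in_ir"] == []
    assert intron_census(p) == {"one_intron": [], "two_intron": []}


def test_minus_strand_atg_not_flagged(toy_run):
    """Genes encoded on the minus strand read ATG after strand
    correction; only the planted GTG start (rps19) is reported."""
    flags = flag_alternative_start_codons(toy_run["ancestor"])
    assert flags == [{"gene": "rps19", "codon": "GTG"}]


# ---------------------------------------------------------------------------
# gene-order inversions
# ---------------------------------------------------------------------------

def _linear_plastome(pid, signed_order):
    """5-gene annotated genome without IRs; signed entries give gene
    identity (g<k>) and strand."""
    feats = []
    for i, v in enumerate(signed_order):
        s = 100 + i * 300
        feats.append(GeneFeature(f"g{abs(v)}", "CDS", 1 if v > 0 else -1,
                                 ((s, s + 100),)))
    return Plastome(id=pid, sequence="A" * (100 + len(signed_order) * 300),
                    features=feats)


REF_ORDER = [1, 2, 3, 4, 5]


@pytest.mark.parametrize("i,j", [(1, 4), (2, 4), (1, 3), (2, 5), (3, 4)])
def test_interior_reversal_recovered_exactly(i, j):
    """Reversing genes i..j-1 (0-based, interior) yields one inversion
    block containing exactly those genes."""
    order = REF_ORDER[:i] + [-v for v in REF_ORDER[i:j]][::-1] + REF_ORDER[j:]
    a = _linear_plastome("ref", REF_ORDER)
    b = _linear_plastome("qry", order)
    blocks = detect_gene_order_inversions(a, b)
    assert len(blocks) == 1
    assert set(blocks[0].genes) == {f"g{k}" for k in REF_ORDER[i:j]}


def test_identical_order_yields_no_blocks():
    a = _linear_plastome("ref", REF_ORDER)
    b = _linear_plastome("qry", REF_ORDER)
    assert detect_gene_order_inversions(a, b) == []


def test_whole_genome_reversal_is_orientation_not_inversion():
    """Reading the same circle from the other strand is not a
    rearrangement."""
    a = _linear_plastome("ref", REF_ORDER)
    b = _linear_plastome("qry", [-v for v in REF_ORDER[::-1]])
    assert detect_gene_order_inversions(a, b) == []


def test_block_spans_cover_the_inverted_genes():
    order = [1, -4, -3, -2, 5]
    a = _linear_plastome("ref", REF_ORDER)
    b = _linear_plastome("qry", order)
    (blk,) = detect_gene_order_inversions(a, b)
    assert set(blk.genes) == {"g2", "g3", "g4"}
    assert blk.span_a == blk.span_b == 700  # 3 genes x 100 + 2 gaps x 200
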