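"""Quadripartite structure detection and plastome structural reports.

A plastid genome is canonically LSC + IRb + SSC + IRa, where IRa is the
reverse complement of IRb.  The finder here is a seed-and-extend scan of
the sequence against its own reverse complement: exact k-mer seeds vote
for an anti-diagonal, the winning diagonal is extended outwards with a
bounded mismatch budget, and the ends are trimmed back to the outermost
matching base.  At plastome scale (~160 kb) this is effectively instant
and recovers identical IRs exactly.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .io import GeneFeature, Plastome, revcomp

log = logging.getLogger("plastovar")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class StructureNotFound(ValueError):
    """No inverted repeat of the requested minimum length exists."""


# ---------------------------------------------------------------------------
# intervals that may wrap the circular origin: (start, end) half-open,
# wrap encoded as start > end meaning [start, n) + [0, end)
# ---------------------------------------------------------------------------

def interval_length(iv: tuple[int, int], n: int) -> int:
    s, e = iv
    return e - s if s <= e else (n - s) + e


def in_interval(pos: int, iv: tuple[int, int], n: int) -> bool:
    s, e = iv
    if s <= e:
        return s <= pos < e
    return pos >= s or pos < e


def interval_slice(seq: str, iv: tuple[int, int]) -> str:
    s, e = iv
    return seq[s:e] if s <= e else seq[s:] + seq[:e]


@dataclass(frozen=True)
class QuadripartiteStructure:
    """The four partition intervals on the canonical linearization."""

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genome_length: int
    ir_mismatches: int
    mirror_diag: int  # position x in one IR pairs with (mirror_diag - x) % n

    @property
    def lsc_length(self) -> int:
        return interval_length(self.lsc, self.genome_length)

    @property
    def ssc_length(self) -> int:
        return interval_length(self.ssc, self.genome_length)

    @property
    def ir_length(self) -> int:
        return interval_length(self.irb, self.genome_length)

    def partition_of(self, pos: int) -> str:
        for name in ("lsc", "irb", "ssc", "ira"):
            if in_interval(pos % self.genome_length, getattr(self, name),
                           self.genome_length):
                return name.upper() if name != "lsc" else "LSC"
        raise ValueError(f"position {pos} outside genome")  # pragma: no cover

    def mirror(self, pos: int) -> int:
        """IR mirror symmetry: maps IRb positions onto IRa and back."""
        return (self.mirror_diag - pos) % self.genome_length

    @property
    def junctions(self) -> dict[str, int]:
        """JLB (LSC|IRb), JSB (IRb|SSC), JSA (SSC|IRa), JLA (IRa|LSC)."""
        return {"JLB": self.irb[0], "JSB": self.ssc[0],
                "JSA": self.ira[0], "JLA": self.lsc[0]}


def detect_quadripartite(p: Plastome, min_ir: int = 1000,
                         max_mismatch_frac: float = 0.01,
                         k: int = 25) -> QuadripartiteStructure:
    """Locate the inverted-repeat pair and derive the four partitions.

    Parameters
    ----------
    min_ir : minimum acceptable IR arm length in bp.
    max_mismatch_frac : mismatch budget during extension, as a fraction
        of the current IR length (the two arms of real plastomes are
        identical or nearly so).
    """
    seq, n = p.sequence, len(p.sequence)
    if n <= 2 * min_ir:
        raise StructureNotFound(
            f"{p.id}: genome ({n} bp) too short for IRs of {min_ir} bp")

    index: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        index[seq[i:i + k]].append(i)

    rcs = revcomp(seq)
    diag_pos: dict[int, list[int]] = defaultdict(list)
    for q in range(0, n - k + 1):
        for i in index.get(rcs[q:q + k], ()):
            j = n - q - k
            if i + k <= j:  # keep the two arms disjoint
                diag_pos[i + j].append(i)

    best = None
    ranked = sorted(diag_pos.items(), key=lambda kv: -len(kv[1]))[:10]
    for d, hits in ranked:
        # largest contiguous seed cluster on this anti-diagonal; distant
        # stray hits come from repeated k-mers, not the IR itself
        hits = sorted(set(hits))
        clusters: list[list[int]] = [[hits[0]]]
        for h in hits[1:]:
            if h - clusters[-1][-1] <= 1000:
                clusters[-1].append(h)
            else:
                clusters.append([h])
        cl = max(clusters, key=lambda c: c[-1] - c[0])
        cand = _extend_ir(seq, d + k - 1, cl[0], cl[-1] + k,
                          max_mismatch_frac)
        if cand is None:
            continue
        length, mism = cand[1] - cand[0], cand[3]
        if mism > max(2.0, max_mismatch_frac * length):
            continue
        if best is None or length > (best[1] - best[0]):
            best = cand
    if best is None or best[1] - best[0] < min_ir:
        raise StructureNotFound(
            f"{p.id}: no inverted repeat of >= {min_ir} bp found")

    s1, e1, D, mism = best
    s2, e2 = D - e1 + 1, D - s1 + 1
    arm1, arm2 = (s1, e1), (s2, e2)
    gap_mid = (e1, s2)                       # between the arms
    gap_wrap = (e2 % n, s1)                  # through the origin
    len_mid = interval_length(gap_mid, n)
    len_wrap = interval_length(gap_wrap, n)

    if len_wrap >= len_mid:                  # LSC wraps (or starts at) origin
        lsc, irb, ssc, ira = gap_wrap, arm1, gap_mid, (s2, e2)
    else:
        lsc, irb, ssc, ira = gap_mid, arm2, gap_wrap, arm1
    q = QuadripartiteStructure(lsc=lsc, irb=irb, ssc=ssc, ira=ira,
                               genome_length=n, ir_mismatches=mism,
                               mirror_diag=D)
    assert (q.lsc_length + q.ssc_length + 2 * q.ir_length) == n
    return q


def _extend_ir(seq: str, D: int, s1: int, e1: int,
               max_mismatch_frac: float, xdrop: int = 20):
    """Extend a seeded arm [s1,e1) outwards along anti-diagonal D.

    Pairing: seq[x] must complement seq[D-x].  Each direction extends
    under an X-drop rule (match +1, mismatch -3; stop once the running
    score falls ``xdrop`` below its maximum) and the boundary is the
    last scoring maximum, i.e. the outermost matching base, so isolated
    interior mismatches are crossed but random flanking sequence never
    drags the boundary outward.  Returns (s1, e1, D, mismatches) or None.
    """
    n = len(seq)

    def pairs(x: int) -> bool:
        y = D - x
        if y < 0 or y >= n:
            return False
        return _COMP.get(seq[x]) == seq[y]

    # leftward from s1 (mirrored rightward on the partner arm)
    score = best = 0.0
    best_x = s1
    x = s1 - 1
    while x >= 0 and D - x < n:
        score += 1.0 if pairs(x) else -3.0
        if score > best:
            best, best_x = score, x
        if best - score > xdrop:
            break
        x -= 1
    s1 = best_x
    # rightward from e1, keeping the two arms disjoint (e1 <= (D+1)/2)
    score = best = 0.0
    best_x = e1
    x = e1
    while 2 * (x + 1) <= D + 1 and D - x >= 0:
        score += 1.0 if pairs(x) else -3.0
        if score > best:
            best, best_x = score, x + 1
        if best - score > xdrop:
            break
        x += 1
    e1 = best_x
    # trim ends to the outermost matching base
    while e1 > s1 and not pairs(s1):
        s1 += 1
    while e1 > s1 and not pairs(e1 - 1):
        e1 -= 1
    if e1 - s1 <= 0:
        return None
    mism = sum(1 for x in range(s1, e1) if not pairs(x))
    return (s1, e1, D, mism)


# ---------------------------------------------------------------------------
# GC partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GCReport:
    overall_pct: float
    lsc_pct: float
    ssc_pct: float
    ir_pct: float
    by_class: dict[str, float]  # CDS / tRNA / rRNA / IGS / intron


def _gc_pct(chunks) -> float:
    gc = at = 0
    for chunk in chunks:
        for b in chunk:
            if b in "GC":
                gc += 1
            elif b in "AT":
                at += 1
    total = gc + at
    return round(100.0 * gc / total, 1) if total else 0.0


def dedupe_ir_features(p: Plastome,
                       q: QuadripartiteStructure | None) -> list[GeneFeature]:
    """One feature per gene copy-class: IRb duplicates of a name that
    also occurs in IRa are dropped (census convention: count the IRa
    copy).  Without a structure, exact same-name same-length duplicates
    collapse to one."""
    by_name: dict[str, list[GeneFeature]] = defaultdict(list)
    for f in p.features:
        by_name[f.name].append(f)
    kept: list[GeneFeature] = []
    for name, feats in by_name.items():
        if len(feats) == 1:
            kept.extend(feats)
            continue
        if q is not None:
            in_irb = [f for f in feats if in_interval(
                int(f.midpoint) % len(p), q.irb, len(p))]
            others = [f for f in feats if f not in in_irb]
            kept.extend(others if others else in_irb[:1])
        else:
            seen = set()
            for f in feats:
                sig = (f.length, len(f.parts), f.kind)
                if sig not in seen:
                    seen.add(sig)
                    kept.append(f)
    return kept


def gc_report(p: Plastome, q: QuadripartiteStructure) -> GCReport:
    """GC percentages overall, per partition and per feature class.

    Ambiguity codes and N are excluded from both numerator and
    denominator.  Feature classes pool IR-duplicated genes once (the
    IRa copy); IGS is the genome minus all feature parts with the IRb
    partition excluded; introns are the inter-part gaps of multi-part
    features.
    """
    seq, n = p.sequence, len(p)
    overall = _gc_pct([seq])
    lsc = _gc_pct([interval_slice(seq, q.lsc)])
    ssc = _gc_pct([interval_slice(seq, q.ssc)])
    ir = _gc_pct([interval_slice(seq, q.irb), interval_slice(seq, q.ira)])

    feats = dedupe_ir_features(p, q)
    class_chunks: dict[str, list[str]] = {"CDS": [], "tRNA": [], "rRNA": [],
                                          "intron": []}
    for f in feats:
        chunks = [seq[s:e] for s, e in f.parts]
        class_chunks.setdefault(f.kind, []).append("".join(chunks))
        for (s1, e1), (s2, _) in zip(f.parts, f.parts[1:]):
            class_chunks["intron"].append(seq[e1:s2])

    covered = bytearray(n)
    for f in p.features:
        for s, e in f.parts:
            for x in range(s, min(e, n)):
                covered[x] = 1
    igs_chunks = []
    run = []
    for x in range(n):
        if not covered[x] and not in_interval(x, q.irb, n):
            run.append(seq[x])
        elif run:
            igs_chunks.append("".join(run))
            run = []
    if run:
        igs_chunks.append("".join(run))

    by_class = {k: _gc_pct(v) for k, v in class_chunks.items()}
    by_class["IGS"] = _gc_pct(igs_chunks)
    return GCReport(overall_pct=overall, lsc_pct=lsc, ssc_pct=ssc,
                    ir_pct=ir, by_class=by_class)


# ---------------------------------------------------------------------------
# junction geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionGene:
    junction: str
    gene: str
    strand: int
    side: str          # partition the gene (or its bulk) lies in
    distance: int      # bp from gene end to junction; negative = spans
    spans: bool
    bp_upstream: int   # bases of the gene on each side when spanning
    bp_downstream: int


@dataclass(frozen=True)
class PseudoProjection:
    """IR-mirrored, boundary-truncated copy of a junction-spanning gene."""
    gene: str
    junction: str
    interval: tuple[int, int]
    length: int
    overlaps: tuple[tuple[str, int], ...]  # (gene, overlap bp)


@dataclass
class JunctionReport:
    junctions: dict[str, int]
    entries: list[JunctionGene]
    pseudo: list[PseudoProjection]


def _recenter(x: int, j: int, n: int) -> int:
    r = (x - j) % n
    return r - n if r > n // 2 else r


def junction_report(p: Plastome, q: QuadripartiteStructure) -> JunctionReport:
    """Genes nearest to / spanning each of the four IR junctions, plus
    the truncated mirror ('pseudo') projections of IR-spanning genes."""
    if not p.features:
        raise ValueError(f"{p.id}: junction report needs annotations")
    n = len(p)
    sides = {"JLB": ("LSC", "IRb"), "JSB": ("IRb", "SSC"),
             "JSA": ("SSC", "IRa"), "JLA": ("IRa", "LSC")}
    entries: list[JunctionGene] = []
    for jname, jpos in q.junctions.items():
        up_side, down_side = sides[jname]
        best_up = best_down = None
        for f in p.features:
            s = _recenter(f.start, jpos, n)
            e = s + (f.end - f.start)
            if s < 0 < e:
                entries.append(JunctionGene(
                    junction=jname, gene=f.name, strand=f.strand,
                    side=up_side if -s >= e else down_side,
                    distance=-min(-s, e), spans=True,
                    bp_upstream=-s, bp_downstream=e))
            elif e <= 0 and (best_up is None or e > best_up[0]):
                best_up = (e, f)
            elif s >= 0 and (best_down is None or s < best_down[0]):
                best_down = (s, f)
        if best_up:
            e, f = best_up
            entries.append(JunctionGene(jname, f.name, f.strand, up_side,
                                        -e, False, 0, 0))
        if best_down:
            s, f = best_down
            entries.append(JunctionGene(jname, f.name, f.strand, down_side,
                                        s, False, 0, 0))

    pseudo: list[PseudoProjection] = []
    for f in p.features:
        for arm, other_junction in (("irb", "JSA"), ("ira", "JSB")):
            arm_iv = getattr(q, arm)
            inside = [x for x in (f.start, f.end - 1)
                      if in_interval(x % n, arm_iv, n)]
            if len(inside) != 1:
                continue  # fully inside or fully outside the arm
            # clip the feature's span to the arm, then mirror it
            lo, hi = f.start, f.end
            a_s, a_e = arm_iv
            cs, ce = max(lo, a_s), min(hi, a_e if a_e > a_s else a_e + n)
            if ce <= cs:
                continue
            m1, m2 = q.mirror(cs), q.mirror(ce - 1)
            proj = (min(m1, m2), max(m1, m2) + 1)
            # which junction the truncated copy sits at: mirror of the
            # boundary the gene crosses
            jname = ("JSB" if arm == "ira" else "JSA") \
                if f.start < a_s or f.end > (a_e if a_e > a_s else a_e + n) \
                else other_junction
            ovl = []
            for g in p.features:
                if g.name == f.name:
                    continue
                o = min(proj[1], g.end) - max(proj[0], g.start)
                if o > 0:
                    ovl.append((g.name, o))
            pseudo.append(PseudoProjection(
                gene=f.name, junction=jname, interval=proj,
                length=proj[1] - proj[0], overlaps=tuple(sorted(ovl))))
    return JunctionReport(junctions=dict(q.junctions), entries=entries,
                          pseudo=pseudo)


# ---------------------------------------------------------------------------
# censuses
# ---------------------------------------------------------------------------

def gene_census(p: Plastome,
                q: QuadripartiteStructure | None = None) -> dict:
    """Distinct canonical gene names per kind, plus the names duplicated
    across the two IR copies (pseudo annotations excluded from counts)."""
    names_by_kind: dict[str, set[str]] = defaultdict(set)
    for f in p.features:
        if not f.is_pseudo:
            names_by_kind[f.kind].add(f.name)
    unique = set().union(*names_by_kind.values()) if names_by_kind else set()

    duplicated: set[str] = set()
    by_name: dict[str, list[GeneFeature]] = defaultdict(list)
    for f in p.features:
        by_name[f.name].append(f)
    for name, feats in by_name.items():
        if len(feats) < 2:
            continue
        if q is not None:
            n = len(p)
            in_b = any(in_interval(int(f.midpoint) % n, q.irb, n)
                       for f in feats)
            in_a = any(in_interval(int(f.midpoint) % n, q.ira, n)
                       for f in feats)
            if in_b and in_a:
                duplicated.add(name)
        else:
            duplicated.add(name)
    return {
        "unique_genes": len(unique),
        "protein_coding": len(names_by_kind.get("CDS", ())),
        "trna": len(names_by_kind.get("tRNA", ())),
        "rrna": len(names_by_kind.get("rRNA", ())),
        "duplicated_in_ir": sorted(duplicated),
    }


def intron_census(p: Plastome,
                  q: QuadripartiteStructure | None = None) -> dict:
    """Names of one- and two-intron genes.

    IR-duplicated copies are collapsed first; the trans-spliced rps12
    (separate exon-1 and exons-2/3 features) is merged by name, so its
    three exons count as two introns.
    """
    feats = [f for f in dedupe_ir_features(p, q) if not f.is_pseudo]
    parts_by_name: Counter[str] = Counter()
    for f in feats:
        parts_by_name[f.name] += len(f.parts)
    one = sorted(n for n, c in parts_by_name.items() if c == 2)
    two = sorted(n for n, c in parts_by_name.items() if c == 3)
    return {"one_intron": one, "two_intron": two}


def flag_alternative_start_codons(p: Plastome) -> list[dict]:
    """CDS whose strand-aware first codon is not ATG.

    A gene name duplicated across features (IR copies, the trans-spliced
    rps12) is unflagged if any copy starts with ATG — the copy carrying
    the true initiation codon wins.
    """
    codons: dict[str, set[str]] = defaultdict(set)
    for f in p.features:
        if f.kind != "CDS" or f.is_pseudo:
            continue
        s = p.feature_sequence(f)
        if len(s) < 3:
            continue
        if f.length % 3:
            log.warning("%s: CDS %s length %d not divisible by 3",
                        p.id, f.name, f.length)
        codons[f.name].add(s[:3])
    out = []
    for name in sorted(codons):
        if "ATG" not in codons[name]:
            for codon in sorted(codons[name]):
                out.append({"gene": name, "codon": codon})
    return out


# ---------------------------------------------------------------------------
# gene-order inversions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InversionBlock:
    genes: tuple[str, ...]      # in reference block order
    orientation: str            # "inverted"
    span_a: int                 # approx bp span on each genome
    span_b: int


def _masked_gene_order(p: Plastome) -> list[GeneFeature]:
    try:
        q = detect_quadripartite(p)
        n = len(p)
        feats = [f for f in p.features if not f.is_pseudo and
                 not in_interval(int(f.midpoint) % n, q.irb, n)]
    except StructureNotFound:
        feats = [f for f in p.features if not f.is_pseudo]
    seen: set[str] = set()
    out = []
    for f in sorted(feats, key=lambda f: f.midpoint):
        if f.name in seen:
            log.warning("%s: duplicate gene %s outside IR; keeping first",
                        p.id, f.name)
            continue
        seen.add(f.name)
        out.append(f)
    return out


def detect_gene_order_inversions(a: Plastome,
                                 b: Plastome) -> list[InversionBlock]:
    """Inversion blocks between two annotated plastomes.

    Shared genes become a signed permutation (order = midpoint order
    with one IR masked, sign = relative strand); maximal runs that are
    reversed and sign-flipped in ``b`` are reported, largest first.
    """
    order_a = _masked_gene_order(a)
    order_b = _masked_gene_order(b)
    shared = {f.name for f in order_a} & {f.name for f in order_b}
    if len(shared) < 2:
        log.warning("fewer than 2 shared genes between %s and %s", a.id, b.id)
        return []
    fa = [f for f in order_a if f.name in shared]
    fb = [f for f in order_b if f.name in shared]
    rank = {f.name: i + 1 for i, f in enumerate(fa)}
    strand_a = {f.name: f.strand for f in fa}
    perm = [(rank[f.name] * (1 if f.strand == strand_a[f.name] else -1))
            for f in fb]

    def find_runs(p: list[int]) -> list[tuple[int, int]]:
        """(lo, hi) rank ranges of maximal inverted runs, after rotating
        so rank 1 leads."""
        pivot = next((i for i, v in enumerate(p) if abs(v) == 1), 0)
        p = p[pivot:] + p[:pivot]
        runs = []
        i, m = 0, len(p)
        while i < m:
            if p[i] < 0:
                j = i
                while j + 1 < m and p[j + 1] == p[j] + 1 and p[j + 1] < 0:
                    j += 1
                runs.append((-p[j], -p[i]))
                i = j + 1
            else:
                i += 1
        return runs

    # the genome is circular and unoriented: try both global orientations
    # and keep the more parsimonious reading (fewer blocks, then fewer
    # inverted genes)
    candidates = [find_runs(perm), find_runs([-v for v in perm[::-1]])]
    runs = min(candidates,
               key=lambda rs: (len(rs), sum(hi - lo + 1 for lo, hi in rs)))

    blocks: list[InversionBlock] = []
    for lo, hi in runs:
        genes = tuple(f.name for f in fa[lo - 1:hi])
        ga = fa[lo - 1:hi]
        names = set(genes)
        gb = [f for f in fb if f.name in names]
        blocks.append(InversionBlock(
            genes=genes, orientation="inverted",
            span_a=max(f.end for f in ga) - min(f.start for f in ga),
            span_b=max(f.end for f in gb) - min(f.start for f in gb)))
    blocks.sort(key=lambda blk: -len(blk.genes))
    return blocks
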