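"""Synthetic quadripartite plastomes evolved along a known tree, with a
complete ground-truth event log.

The ancestor is generated from a gene map (default: the bundled
Cocoseae-like 113-gene map) laid out over LSC + IRb + SSC + IRa with
partition-specific GC content; IRa is the exact reverse complement of
IRb.  Internally the genome is a list of *segments* — CDS exons,
introns, IGS gaps and tRNA/rRNA bodies tiling the IR-masked circle —
and evolution (per-branch Poisson substitutions and short indels at
region-class-specific rates, optional planted inversions and IR
boundary shifts) acts segment-wise, so every tip stays correctly
annotated and IRb is rebuilt as the mirror of the evolved IRa (IR
copies co-mutate, keeping the repeats identical).  Every event is
logged; replaying the log on the ancestor reproduces each tip exactly.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .genemap import GeneSpec, default_cocoseae_map
from .io import GeneFeature, Plastome, base_symbol, revcomp
from .structure import QuadripartiteStructure

log = logging.getLogger("plastovar")

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SimulationConfigError(ValueError):
    pass


DEFAULT_TREE = (
    "((((Bactris_gasipaes:0.02,(Astrocaryum_aculeatum:0.01,"
    "Astrocaryum_murumuru:0.01):0.01):0.01,Acrocomia_aculeata:0.03):0.01,"
    "Elaeis_guineensis:0.04):0.01,((Cocos_nucifera:0.02,"
    "Syagrus_coronata:0.02):0.01,Butia_eriospatha:0.03):0.02);"
)

# per-class substitution / indel rates (events per site per unit branch
# length); defaults chosen so an 8-taxon run at the default tree depth
# lands near the observed plastome regime: substitutions ~5x more
# frequent than indels overall and ~80x in CDS
DEFAULT_SUB_RATES = {"CDS": 0.032, "IGS": 0.092, "intron": 0.0448,
                     "other": 0.012}
DEFAULT_INDEL_RATES = {"CDS": 0.0004, "IGS": 0.023, "intron": 0.01375,
                       "other": 0.0006}


@dataclass
class SimulationConfig:
    seed: int = 0
    lsc_len: int = 85000
    ir_len: int = 27000
    ssc_len: int = 17000
    gene_map: object = "default-cocoseae"
    tree: str = DEFAULT_TREE
    sub_rates: dict = field(default_factory=lambda: dict(DEFAULT_SUB_RATES))
    indel_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_INDEL_RATES))
    indel_mean_len: float = 3.0
    indel_max_len: int = 50
    gc: dict = field(default_factory=lambda: {"LSC": 0.355, "SSC": 0.313,
                                              "IRA": 0.426})
    inversions: list = field(default_factory=list)  # (branch, [genes])
    ir_boundary_shift: dict = field(default_factory=dict)  # branch -> bp
    region_rate_multipliers: dict = field(default_factory=dict)
    min_igs: int = 120

    def resolved_map(self) -> dict[str, list[GeneSpec]]:
        if self.gene_map == "default-cocoseae":
            return default_cocoseae_map()
        if isinstance(self.gene_map, dict):
            return self.gene_map
        raise SimulationConfigError(f"unknown gene map {self.gene_map!r}")

    def validate(self):
        for d in (self.sub_rates, self.indel_rates):
            if any(v < 0 for v in d.values()):
                raise SimulationConfigError("rates must be >= 0")
        for v in (self.lsc_len, self.ir_len, self.ssc_len):
            if v <= 0:
                raise SimulationConfigError("partition lengths must be > 0")


@dataclass
class Segment:
    """One tile of the IR-masked circle."""
    region: str       # region name (shared by multi-segment regions)
    cls: str          # CDS | intron | IGS | other
    gene: str | None  # owning gene occurrence id, e.g. "ycf1" / "rps12/IRA"
    gene_name: str | None
    kind: str | None  # feature kind for gene segments
    strand: int
    partition: str    # LSC | SSC | IRA
    seq: list[str]
    anc: list[int]    # ancestral position ids; -1 for inserted bases

    def clone(self) -> "Segment":
        return Segment(self.region, self.cls, self.gene, self.gene_name,
                       self.kind, self.strand, self.partition,
                       list(self.seq), list(self.anc))


# ---------------------------------------------------------------------------
# ancestor construction
# ---------------------------------------------------------------------------

def _distribute_gaps(rng, free: int, slots: int, min_gap: int) -> list[int]:
    if slots == 0:
        return []
    if free < slots * min_gap:
        raise SimulationConfigError(
            f"gene map too dense: {free} bp free for {slots} spacers")
    w = rng.random(slots) + 0.25
    extra = np.floor(w / w.sum() * (free - slots * min_gap)).astype(int)
    gaps = (min_gap + extra).tolist()
    gaps[0] += free - sum(gaps)
    return gaps


def _random_seq(rng, length: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(_BASES, size=length, p=p))


def _build_segments(cfg: SimulationConfig, rng) -> list[Segment]:
    gm = cfg.resolved_map()
    lsc_genes, ssc_genes, ira_genes = gm["LSC"], gm["SSC"], gm["IRA"]

    # --- lay out gene coordinates within each partition -----------------
    def layout(genes, start, length, first_fixed=False, last_fixed=0):
        """Positions for a partition; returns [(GeneSpec, gene_start)] and
        leading/trailing gap sizes."""
        foot = sum(g.footprint for g in genes)
        foot -= sum(g.ir_overhang + g.ira_overhang for g in genes)
        free = length - foot
        n = len(genes)
        if first_fixed and last_fixed:
            gaps = [0] + _distribute_gaps(rng, free, n - 1, cfg.min_igs)
            gaps += [0]
        elif first_fixed:
            gaps = [0] + _distribute_gaps(rng, free, n, cfg.min_igs)
        else:
            gaps = _distribute_gaps(rng, free, n + 1, cfg.min_igs)
        placed = []
        pos = start
        for g, gap in zip(genes, gaps[:-1]):
            pos += gap
            placed.append((g, pos))
            pos += g.footprint - g.ir_overhang - g.ira_overhang
        return placed, gaps

    L, I, S = cfg.lsc_len, cfg.ir_len, cfg.ssc_len
    n = L + 2 * I + S
    lsc_placed, _ = layout(lsc_genes, 0, L)
    ssc_placed, _ = layout(ssc_genes, L + I, S, first_fixed=True,
                           last_fixed=1)
    ycf_over = ssc_genes[-1].ira_overhang
    ira_start = L + I + S
    ira_placed, _ = layout(ira_genes, ira_start + ycf_over, I - ycf_over,
                           first_fixed=False)

    # pin the trailing SSC gene so its last exon ends ira_overhang into IRa
    if ycf_over:
        g = ssc_genes[-1]
        want_end = ira_start + ycf_over
        ssc_placed[-1] = (g, want_end - g.footprint)

    # --- raw sequence (IRb filled later as the mirror of IRa) -----------
    seq = (_random_seq(rng, L, cfg.gc["LSC"])
           + ["N"] * I
           + _random_seq(rng, S, cfg.gc["SSC"])
           + _random_seq(rng, I, cfg.gc["IRA"]))
    D = 2 * L + 2 * I + S - 1  # base-level IR mirror anti-diagonal

    def write(pos, base):
        seq[pos] = base
        if L <= pos < L + I or ira_start <= pos < n:
            seq[D - pos] = _COMP[base]

    # exon intervals per placed gene, genome-forward; a gene with an
    # ir_overhang actually begins that many bp earlier (inside IRb)
    def exon_intervals(g: GeneSpec, gstart: int):
        ivs = []
        pos = gstart - g.ir_overhang
        for i, ex in enumerate(g.exons):
            ivs.append((pos, pos + ex))
            pos += ex
            if i < len(g.introns):
                pos += g.introns[i]
        return ivs

    all_placed = [("LSC", g, s) for g, s in lsc_placed] \
        + [("SSC", g, s) for g, s in ssc_placed] \
        + [("IRA", g, s) for g, s in ira_placed]

    for part, g, gstart in all_placed:
        if g.kind != "CDS":
            continue
        ivs = exon_intervals(g, gstart)
        order = ivs if g.strand >= 0 else ivs[::-1]
        splice_pos = []
        for s, e in order:
            rng_pos = range(s, e) if g.strand >= 0 else range(e - 1, s - 1, -1)
            splice_pos.extend(rng_pos)
        for k, b in enumerate(g.start_codon):
            pos = splice_pos[k]
            write(pos, b if g.strand >= 0 else _COMP[b])
        for k, b in enumerate("TAA"):
            pos = splice_pos[len(splice_pos) - 3 + k]
            write(pos, b if g.strand >= 0 else _COMP[b])

    # break chance base-pairing across the SSC junctions so the planted
    # IR is exactly the maximal inverted repeat: the only pair a
    # boundary extension can test is (first SSC base, last SSC base)
    first_ssc, last_ssc = L + I, ira_start - 1
    if _COMP.get(seq[first_ssc]) == seq[last_ssc]:
        bad = _COMP[seq[first_ssc]]
        choices = [b for b in "ACGT" if b != bad]
        seq[last_ssc] = choices[int(rng.integers(0, len(choices)))]

    # --- cut the masked circle into segments ----------------------------
    segments: list[Segment] = []

    def occurrence(part, g):
        return f"{g.name}/{part}"

    def region_name(part, g):
        if g.name == "rps12":
            return "rps12-5p" if len(g.exons) == 1 else "rps12-3p"
        return g.name

    def gene_segments(part, g, gstart):
        ivs = exon_intervals(g, gstart)
        rname = region_name(part, g)
        cls = "CDS" if g.kind == "CDS" else "other"
        out = []
        n_int = len(g.introns)
        for i, (s, e) in enumerate(ivs):
            pieces = [(s, e)]
            if g.ira_overhang and e > ira_start >= s:
                pieces = [(s, ira_start), (ira_start, e)]
            for ps, pe in pieces:
                ps = max(ps, L + I) if ps < L + I <= pe else ps  # clip IRb
                if pe <= ps:
                    continue
                p_part = "IRA" if ps >= ira_start else part
                out.append(Segment(rname, cls, occurrence(part, g), g.name,
                                   g.kind, g.strand, p_part,
                                   seq[ps:pe], []))
            if i < n_int:
                idx = (i + 1) if g.strand >= 0 else (n_int - i)
                suffix = "-intron" if n_int == 1 else f"-intron{idx}"
                gs, ge = e, e + g.introns[i]
                out.append(Segment(rname + suffix, "intron",
                                   occurrence(part, g), g.name, g.kind,
                                   g.strand, part, seq[gs:ge], []))
        return out

    def igs(a_name, b_name, s, e, part):
        if e <= s:
            return []
        name = f"{base_symbol(a_name)}-{base_symbol(b_name)}"
        return [Segment(name, "IGS", None, None, None, 1, part,
                        seq[s:e], [])]

    # LSC: leading gap belongs to the wrap IGS (last IRa gene -> psbA)
    wrap_left = ira_genes[-1].name
    first = lsc_placed[0]
    segments += igs(wrap_left, first[0].name, 0, first[1], "LSC")
    for (g1, s1), (g2, s2) in zip(lsc_placed, lsc_placed[1:]):
        segments += gene_segments("LSC", g1, s1)
        segments += igs(g1.name, g2.name,
                        s1 + g1.footprint - g1.ir_overhang - g1.ira_overhang,
                        s2, "LSC")
    g_last, s_last = lsc_placed[-1]
    segments += gene_segments("LSC", g_last, s_last)
    # IGS across the masked IRb: LSC tail joined to the first SSC gene
    segments += igs(g_last.name, ssc_genes[0].name,
                    s_last + g_last.footprint, L, "LSC")

    for (g1, s1), (g2, s2) in zip(ssc_placed, ssc_placed[1:]):
        segments += gene_segments("SSC", g1, s1)
        segments += igs(g1.name, g2.name, s1 + g1.footprint, s2, "SSC")
    segments += gene_segments("SSC", ssc_placed[-1][0], ssc_placed[-1][1])

    prev_name = ssc_genes[-1].name
    prev_end = ssc_placed[-1][1] + ssc_placed[-1][0].footprint
    for g, s in ira_placed:
        segments += igs(prev_name, g.name, prev_end, s, "IRA")
        segments += gene_segments("IRA", g, s)
        prev_name, prev_end = g.name, s + g.footprint
    # trailing IRa gap: the IRa-side half of the wrap IGS
    segments += igs(wrap_left, lsc_placed[0][0].name, prev_end, n, "IRA")

    # assign ancestral position ids over the masked circle
    next_id = 0
    for seg in segments:
        seg.anc = list(range(next_id, next_id + len(seg.seq)))
        next_id += len(seg.seq)
    return segments


def assemble(segments: list[Segment], taxon: str,
             ir_overhangs: dict[str, int] | None = None
             ) -> tuple[Plastome, QuadripartiteStructure]:
    """Genome + annotations + planted structure from a segment list."""
    ir_overhangs = ir_overhangs or {}
    lsc = [s for s in segments if s.partition == "LSC"]
    ssc = [s for s in segments if s.partition == "SSC"]
    ira = [s for s in segments if s.partition == "IRA"]
    L = sum(len(s.seq) for s in lsc)
    S = sum(len(s.seq) for s in ssc)
    I = sum(len(s.seq) for s in ira)
    n = L + 2 * I + S
    D = 2 * L + 2 * I + S - 1

    offsets: dict[int, int] = {}
    pos = 0
    for s in lsc:
        offsets[id(s)] = pos
        pos += len(s.seq)
    pos = L + I
    for s in ssc:
        offsets[id(s)] = pos
        pos += len(s.seq)
    for s in ira:
        offsets[id(s)] = pos
        pos += len(s.seq)

    ira_seq = "".join("".join(s.seq) for s in ira)
    sequence = ("".join("".join(s.seq) for s in lsc) + revcomp(ira_seq)
                + "".join("".join(s.seq) for s in ssc) + ira_seq)

    # gene features from exon segments, in segment order
    by_gene: dict[str, list[Segment]] = {}
    for s in segments:
        if s.gene and s.cls in ("CDS", "other"):
            by_gene.setdefault(s.gene, []).append(s)
    features: list[GeneFeature] = []
    for gene, segs in by_gene.items():
        parts: list[tuple[int, int]] = []
        for s in segs:
            st = offsets[id(s)]
            iv = (st, st + len(s.seq))
            if parts and iv[0] == parts[-1][1]:
                parts[-1] = (parts[-1][0], iv[1])
            else:
                parts.append(iv)
        over = ir_overhangs.get(segs[0].gene_name, 0)
        if over:
            parts[0] = (parts[0][0] - min(over, I), parts[0][1])
        feat = GeneFeature(name=segs[0].gene_name, kind=segs[0].kind,
                           strand=segs[0].strand,
                           parts=tuple(sorted(parts)))
        features.append(feat)
        if all(s.partition == "IRA" for s in segs):  # mirror copy in IRb
            mparts = tuple(sorted((D - e + 1, D - s + 1)
                                  for s, e in feat.parts))
            features.append(replace(feat, strand=-feat.strand, parts=mparts))
    features.sort(key=lambda f: f.start)
    p = Plastome(id=taxon, sequence=sequence, features=features,
                 source="synthetic")
    q = QuadripartiteStructure(
        lsc=(0, L), irb=(L, L + I), ssc=(L + I, L + I + S),
        ira=(L + I + S, n), genome_length=n, ir_mismatches=0, mirror_diag=D)
    return p, q


def simulate_ancestor(cfg: SimulationConfig
                      ) -> tuple[Plastome, list[Segment]]:
    """Random quadripartite ancestor with planted gene features; IRa is
    the exact reverse complement of IRb."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    segments = _build_segments(cfg, rng)
    overhangs = {g.name: g.ir_overhang
                 for part in cfg.resolved_map().values()
                 for g in part if g.ir_overhang}
    plastome, _ = assemble(segments, "ancestor", overhangs)
    return plastome, segments


# ---------------------------------------------------------------------------
# evolution along a tree
# ---------------------------------------------------------------------------

@dataclass
class MutationTruth:
    tree: str
    taxa: list[str]
    events: dict[str, list[tuple]]        # branch id -> ordered events
    tips_below: dict[str, frozenset]
    region_anc: dict[str, tuple[str, int]]  # region -> (class, anc length)
    anc_segments: list[Segment]
    structures: dict[str, QuadripartiteStructure]
    seed: int


def _apply_events(segments: list[Segment], events: list[tuple]) -> None:
    """Apply one branch's logged events, in order, to a segment list."""
    for ev in events:
        kind = ev[0]
        if kind == "sub":
            _, si, pos, _old, new = ev
            segments[si].seq[pos] = new
        elif kind == "del":
            _, si, pos, ln, _deleted = ev
            seg = segments[si]
            del seg.seq[pos:pos + ln]
            del seg.anc[pos:pos + ln]
        elif kind == "ins":
            _, si, pos, bases = ev
            seg = segments[si]
            seg.seq[pos:pos] = list(bases)
            seg.anc[pos:pos] = [-1] * len(bases)
        elif kind == "inv":
            _, lo, hi = ev
            block = segments[lo:hi]
            for s in block:
                s.seq = [_COMP[c] if c in _COMP else c
                         for c in reversed(s.seq)]
                s.anc = list(reversed(s.anc))
                s.strand = -s.strand
            segments[lo:hi] = block[::-1]
        elif kind == "ren":
            _, si, new_name = ev
            segments[si].region = new_name
        elif kind == "shift":
            _, s_bp = ev
            last_lsc = max(i for i, s in enumerate(segments)
                           if s.partition == "LSC")
            last_ira = max(i for i, s in enumerate(segments)
                           if s.partition == "IRA")
            src, dst = segments[last_lsc], segments[last_ira]
            if src.gene is not None or len(src.seq) <= s_bp:
                raise SimulationConfigError(
                    f"ir_boundary_shift of {s_bp} bp must fit inside the "
                    f"terminal LSC spacer ({len(src.seq)} bp of "
                    f"{src.region!r} available)")
            moved = src.seq[-s_bp:]
            moved_anc = src.anc[-s_bp:]
            del src.seq[-s_bp:]
            del src.anc[-s_bp:]
            if dst.gene is not None:
                # never splice spacer bases into a gene segment: grow a
                # dedicated spacer at the IRA end (start of IRb's mirror)
                dst = Segment("jla-shift", "other", None, None, None, 1,
                              "IRA", [], [])
                segments.insert(last_ira + 1, dst)
            dst.seq.extend(_COMP.get(c, c) for c in reversed(moved))
            dst.anc.extend(reversed(moved_anc))
        else:  # pragma: no cover
            raise ValueError(f"unknown event {kind}")


def _sample_branch_events(segments, blen, cfg, rng) -> list[tuple]:
    events: list[tuple] = []
    for si, seg in enumerate(segments):
        ln = len(seg.seq)
        if ln == 0:
            continue
        mult = cfg.region_rate_multipliers.get(seg.region, 1.0)
        sub_rate = cfg.sub_rates.get(seg.cls, 0.0) * mult
        ind_rate = cfg.indel_rates.get(seg.cls, 0.0) * mult

        fresh: list[tuple[int, int]] = []  # inserted ranges, current coords
        n_ind = rng.poisson(ind_rate * blen * ln) if ind_rate > 0 else 0
        for _ in range(int(n_ind)):
            length = min(int(rng.geometric(1.0 / cfg.indel_mean_len)),
                         cfg.indel_max_len)
            if rng.random() < 0.5 and len(seg.seq) > length:
                pos = int(rng.integers(0, len(seg.seq) - length + 1))
                deleted = "".join(seg.seq[pos:pos + length])
                ev = ("del", si, pos, length, deleted)
                _apply_events(segments, [ev])
                events.append(ev)
                fresh = [(max(s - length, pos) if s >= pos else s,
                          max(e - length, pos) if e >= pos else e)
                         for s, e in fresh]
            else:
                if len(seg.seq) <= length:
                    raise SimulationConfigError(
                        f"indel rate too high: region {seg.region} "
                        "about to vanish")
                pos = int(rng.integers(0, len(seg.seq) + 1))
                bases = "".join(rng.choice(_BASES, size=length))
                ev = ("ins", si, pos, bases)
                _apply_events(segments, [ev])
                events.append(ev)
                fresh = [(s + length if s >= pos else s,
                          e + length if e >= pos else e) for s, e in fresh]
                fresh.append((pos, pos + length))

        ln_now = len(seg.seq)
        n_sub = rng.poisson(sub_rate * blen * ln_now) if sub_rate > 0 else 0
        if n_sub:
            allowed = [x for x in range(ln_now)
                       if not any(s <= x < e for s, e in fresh)
                       and seg.seq[x] in _COMP]
            n_sub = min(int(n_sub), len(allowed))
            picks = rng.choice(len(allowed), size=n_sub, replace=False)
            for x in sorted(int(allowed[i]) for i in picks):
                old = seg.seq[x]
                choices = [b for b in "ACGT" if b != old]
                new = choices[int(rng.integers(0, 3))]
                ev = ("sub", si, x, old, new)
                _apply_events(segments, [ev])
                events.append(ev)
    return events


def _plan_inversion(segments, genes: list[str]) -> list[tuple]:
    idx = [i for i, s in enumerate(segments) if s.gene_name in genes]
    if not idx:
        raise SimulationConfigError(f"inversion genes not found: {genes}")
    lo, hi = min(idx), max(idx) + 1
    evs: list[tuple] = [("inv", lo, hi)]
    # the two edge IGS change one flank each: rename to the new adjacency
    if lo > 0 and segments[lo - 1].cls == "IGS":
        left = segments[lo - 1].region.split("-")[0]
        new_right = base_symbol(segments[hi - 1].gene_name or "")
        evs.append(("ren", lo - 1, f"{left}-{new_right}"))
    if hi < len(segments) and segments[hi].cls == "IGS":
        right = segments[hi].region.split("-")[-1]
        new_left = base_symbol(segments[lo].gene_name or "")
        evs.append(("ren", hi, f"{new_left}-{right}"))
    return evs


def evolve_on_tree(ancestor_segments: list[Segment], cfg: SimulationConfig
                   ) -> tuple[dict[str, Plastome], MutationTruth]:
    """Evolve the ancestor along ``cfg.tree``; returns annotated tip
    plastomes and the ground-truth event log."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    tree = dendropy.Tree.get(data=cfg.tree, schema="newick",
                             preserve_underscores=True)
    taxa = [lf.taxon.label.replace(" ", "_") for lf in tree.leaf_node_iter()]
    if len(taxa) < 2:
        raise SimulationConfigError("tree needs >= 2 tips")

    # stable branch ids: tip label, or n<k> in preorder for internals
    k = 0
    for node in tree.preorder_node_iter():
        if node.taxon is not None:
            node.branch_id = node.taxon.label.replace(" ", "_")
        else:
            node.branch_id = f"n{k}"
            k += 1

    def branch_of(spec):
        if isinstance(spec, str):
            for node in tree.preorder_node_iter():
                if node.branch_id == spec:
                    return spec
            raise SimulationConfigError(f"no branch {spec!r}")
        mrca = tree.mrca(taxon_labels=list(spec))
        return mrca.branch_id

    inversions: dict[str, list[list[str]]] = {}
    for branch, genes in cfg.inversions:
        inversions.setdefault(branch_of(branch), []).append(list(genes))

    overhangs = {g.name: g.ir_overhang
                 for part in cfg.resolved_map().values()
                 for g in part if g.ir_overhang}

    events: dict[str, list[tuple]] = {}
    tips_below: dict[str, frozenset] = {}
    tips: dict[str, Plastome] = {}
    structures: dict[str, QuadripartiteStructure] = {}

    def recurse(node, segments):
        bid = node.branch_id
        tips_below[bid] = frozenset(
            lf.taxon.label.replace(" ", "_")
            for lf in node.leaf_iter())
        blen = node.edge.length or 0.0
        evs: list[tuple] = []
        shift = cfg.ir_boundary_shift.get(bid, 0)
        if shift:
            evs.append(("shift", int(shift)))
        for genes in inversions.get(bid, []):
            evs.extend(_plan_inversion(segments, genes))
        _apply_events(segments, evs)
        evs += _sample_branch_events(segments, blen, cfg, rng)
        events[bid] = evs
        if node.is_leaf():
            label = node.taxon.label.replace(" ", "_")
            p, q = assemble(segments, label, overhangs)
            tips[label] = p
            structures[label] = q
        else:
            for child in node.child_nodes():
                recurse(child, [s.clone() for s in segments])

    root = tree.seed_node
    root.branch_id = "root"
    events["root"] = []
    tips_below["root"] = frozenset(taxa)
    for child in root.child_nodes():
        recurse(child, [s.clone() for s in ancestor_segments])

    region_anc: dict[str, tuple[str, int]] = {}
    for s in ancestor_segments:
        cls, ln = region_anc.get(s.region, (s.cls, 0))
        region_anc[s.region] = (s.cls, ln + len(s.seq))

    truth = MutationTruth(
        tree=cfg.tree, taxa=taxa, events=events, tips_below=tips_below,
        region_anc=region_anc,
        anc_segments=[s.clone() for s in ancestor_segments],
        structures=structures, seed=cfg.seed)
    return tips, truth


def replay(truth: MutationTruth, cfg: SimulationConfig, tip: str) -> str:
    """Re-derive one tip's genome purely from the ancestor segments and
    the event log (replay invariant check)."""
    tree = dendropy.Tree.get(data=truth.tree, schema="newick",
                             preserve_underscores=True)
    k = 0
    target = None
    for node in tree.preorder_node_iter():
        if node.taxon is not None:
            node.branch_id = node.taxon.label.replace(" ", "_")
            if node.branch_id == tip:
                target = node
        else:
            node.branch_id = f"n{k}"
            k += 1
    if target is None:
        raise ValueError(f"no tip {tip!r}")
    path = []
    node = target
    while node.parent_node is not None:
        path.append(node.branch_id)
        node = node.parent_node
    segments = [s.clone() for s in truth.anc_segments]
    for bid in reversed(path):
        _apply_events(segments, truth.events.get(bid, []))
    overhangs = {g.name: g.ir_overhang
                 for part in cfg.resolved_map().values()
                 for g in part if g.ir_overhang}
    p, _ = assemble(segments, tip, overhangs)
    return p.sequence


# ---------------------------------------------------------------------------
# truth-log expectations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpectedStats:
    region: str
    n_sites: int
    n_invariable: int
    n_pis: int
    n_subs: int
    n_indel_events: int
    exact: bool


def truth_expected_stats(truth: MutationTruth, region: str,
                         taxa: list[str] | None = None) -> ExpectedStats:
    """Event-level expectation for one region's column statistics.

    Exact when no two events touch the same ancestral position (and no
    inversion or boundary shift involves the region); otherwise the
    counts are reported with ``exact=False`` and should be treated as
    bounds.
    """
    taxa = taxa or truth.taxa
    ntip = len(taxa)
    if region not in truth.region_anc:
        raise KeyError(f"unknown region {region!r}")
    _cls, anc_len = truth.region_anc[region]

    # map: segment identity evolves, so walk events per branch tracking
    # which segment indices belong to the region at that moment
    subs: list[tuple[int, str]] = []     # (anc id, branch)
    dels: list[tuple[tuple[int, ...], str]] = []
    inss: list[tuple[int, str]] = []     # (length, branch)
    ins_anchors: list = []               # anc id left of each insertion
    exact = True

    # reconstruct per-branch segment states to resolve anc ids
    tree = dendropy.Tree.get(data=truth.tree, schema="newick",
                             preserve_underscores=True)
    k = 0
    for node in tree.preorder_node_iter():
        if node.taxon is not None:
            node.branch_id = node.taxon.label.replace(" ", "_")
        else:
            node.branch_id = f"n{k}"
            k += 1

    def walk(node, segments):
        nonlocal exact
        bid = node.branch_id
        evs = truth.events.get(bid, [])
        for ev in evs:
            kind = ev[0]
            if kind in ("inv", "shift", "ren"):
                exact = False  # rearrangements void exact expectations
            elif kind == "sub":
                _, si, pos, _old, _new = ev
                if segments[si].region == region:
                    aid = segments[si].anc[pos]
                    if aid < 0:
                        exact = False
                    subs.append((aid, bid))
            elif kind == "del":
                _, si, pos, ln, _d = ev
                if segments[si].region == region:
                    ids = tuple(segments[si].anc[pos:pos + ln])
                    if any(i < 0 for i in ids):
                        exact = False
                    dels.append((ids, bid))
            elif kind == "ins":
                _, si, pos, bases = ev
                if segments[si].region == region:
                    anchor = (si, segments[si].anc[pos - 1] if pos else -2)
                    inss.append((len(bases), bid))
                    ins_anchors.append(anchor)
            _apply_events(segments, [ev])
        for child in node.child_nodes():
            walk(child, [s.clone() for s in segments])

    for child in tree.seed_node.child_nodes():
        walk(child, [s.clone() for s in truth.anc_segments])

    # collision checks on ancestral ids
    sub_ids = [a for a, _ in subs]
    del_ids = [i for ids, _ in dels for i in ids]
    if len(set(sub_ids)) != len(sub_ids):
        exact = False
    if len(set(del_ids)) != len(del_ids):
        exact = False
    if set(sub_ids) & set(del_ids):
        exact = False
    if len(set(ins_anchors)) != len(ins_anchors) or any(
            a[1] == -1 for a in ins_anchors):
        exact = False
    if {a[1] for a in ins_anchors} & set(del_ids):
        exact = False

    n_subs = len(subs)
    n_indel = len(dels) + len(inss)
    n_ins_cols = sum(ln for ln, _ in inss)
    n_del_cols = len(set(del_ids))
    n_pis = 0
    for aid, bid in subs:
        nb = len(truth.tips_below.get(bid, ()) & set(taxa))
        if 2 <= nb <= ntip - 2:
            n_pis += 1
    invariable = anc_len - len(set(sub_ids)) - n_del_cols
    return ExpectedStats(region=region, n_sites=anc_len + n_ins_cols,
                         n_invariable=invariable, n_pis=n_pis,
                         n_subs=n_subs, n_indel_events=n_indel, exact=exact)


def truth_to_json(truth: MutationTruth) -> dict:
    return {
        "tree": truth.tree,
        "taxa": truth.taxa,
        "seed": truth.seed,
        "events": {b: [list(e) for e in evs]
                   for b, evs in truth.events.items()},
        "region_anc": {r: list(v) for r, v in truth.region_anc.items()},
    }
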