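"""Slicing plastomes into named CDS / intron / IGS regions and grouping
homologous regions across taxa.

One IR copy (IRb by default) is masked before slicing, so every locus
appears once.  CDS regions are spliced, strand-corrected exon
concatenations; introns are the inter-exon gaps; IGS are the maximal
gaps between consecutive gene spans on the masked circular genome,
named ``<left>-<right>`` in genome order with tRNA anticodons stripped
(the field's ``trnC-petN`` style).  tRNA/rRNA gene bodies are carried as
class ``other`` so that the masked genome is fully tiled.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from .io import Plastome, base_symbol, revcomp
from .structure import QuadripartiteStructure, in_interval, interval_length

log = logging.getLogger("plastovar")


@dataclass(frozen=True)
class Region:
    name: str
    region_class: str  # CDS | IGS | intron | other
    taxon: str
    sequence: str
    intervals: tuple[tuple[int, int], ...]  # genome-forward, on the taxon
    strand: int = 1

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty region {self.name} ({self.taxon})")


@dataclass
class RegionGroup:
    name: str
    region_class: str
    members: dict[str, Region]
    complete: bool


def _rotated_span(parts, rot, n) -> tuple[int, int] | None:
    """Bounding span of a feature in walk coordinates (origin = mask end)."""
    pts = []
    for s, e in parts:
        pts.append(rot(s))
        pts.append(rot(e - 1))
    lo, hi = min(pts), max(pts)
    if hi - lo > n // 2:  # crosses the walk origin; clip there
        log.warning("feature span crosses the IR-mask joint; truncating")
        hi = max(x for x in pts if x <= n // 2)
        lo = min(x for x in pts if x <= n // 2)
    return lo, hi + 1


def extract_regions(p: Plastome, q: QuadripartiteStructure,
                    drop_ir: str = "IRb") -> list[Region]:
    """One Region per CDS, intron, IGS (and tRNA/rRNA body) with one IR
    masked.  Features overlapping the mask edge are truncated with a
    warning; zero-length IGS between abutting or overlapping genes are
    omitted."""
    if not p.features:
        raise ValueError(
            f"{p.id}: no annotations — supply an annotated GenBank record")
    n = len(p)
    mask = q.irb if drop_ir.upper() == "IRB" else q.ira
    mask_len = interval_length(mask, n)
    walk_start = mask[1] % n  # first base after the masked arm

    def rot(x: int) -> int:
        return (x - walk_start) % n

    def unrot(x: int) -> int:
        return (x + walk_start) % n

    # --- keep / truncate features against the mask ---------------------
    kept: list[tuple[object, tuple[tuple[int, int], ...]]] = []
    for f in p.features:
        if f.is_pseudo:
            continue
        parts = []
        for s, e in f.parts:
            inside_s = in_interval(s % n, mask, n)
            inside_e = in_interval((e - 1) % n, mask, n)
            if inside_s and inside_e:
                continue
            if inside_s or inside_e:
                log.warning("%s: %s truncated at the %s mask edge",
                            p.id, f.name, drop_ir)
                ms, me = mask
                me = me if me > ms else me + n
                if inside_s:         # starts inside mask, ends after it
                    parts.append((me % n, e))
                else:                # starts before mask, ends inside
                    parts.append((s, ms))
            else:
                parts.append((s, e))
        parts = tuple(pp for pp in parts if pp[1] > pp[0])
        if parts:
            kept.append((f, parts))

    regions: list[Region] = []
    name_counts: dict[tuple[str, str], int] = defaultdict(int)

    def add(name, cls, seq, intervals, strand=1):
        name_counts[(cls, name)] += 1
        k = name_counts[(cls, name)]
        if k > 1:
            name = f"{name}@{k}"
        regions.append(Region(name=name, region_class=cls, taxon=p.id,
                              sequence=seq, intervals=tuple(intervals),
                              strand=strand))

    # --- gene-body and intron regions ----------------------------------
    rps12_seen = False
    for f, parts in kept:
        fwd = sorted(parts)
        spliced_parts = fwd if f.strand >= 0 else fwd[::-1]
        chunks = [p.sequence[s:e] for s, e in spliced_parts]
        if f.strand < 0:
            chunks = [revcomp(c) for c in chunks]
        body = "".join(chunks)
        if f.name == "rps12":
            # trans-spliced: the LSC exon and the IR exons are not
            # collinear, so they are kept as two separate CDS regions
            name = "rps12-5p" if len(fwd) == 1 else "rps12-3p"
            rps12_seen = True
        else:
            name = f.name
        cls = "CDS" if f.kind == "CDS" else "other"
        if body:
            add(name, cls, body, fwd, f.strand)
        gaps = [(e1, s2) for (s1, e1), (s2, e2) in zip(fwd, fwd[1:])
                if s2 > e1]
        if f.name == "rps12" and len(fwd) == 1:
            gaps = []
        order = gaps if f.strand >= 0 else gaps[::-1]
        for idx, (gs, ge) in enumerate(order, start=1):
            seq = p.sequence[gs:ge]
            if f.strand < 0:
                seq = revcomp(seq)
            suffix = "-intron" if len(order) == 1 else f"-intron{idx}"
            base = "rps12-3p" if f.name == "rps12" else f.name
            add(base + suffix, "intron", seq, [(gs, ge)], f.strand)

    # --- IGS: gaps between gene spans on the masked circle --------------
    spans = []
    for f, parts in kept:
        sp = _rotated_span(parts, rot, n)
        if sp:
            spans.append((sp[0], sp[1], f.name))
    spans.sort()
    circ_len = n - mask_len
    igs = []
    if spans:
        run_end, run_name = spans[0][1], spans[0][2]
        for s, e, name in spans[1:]:
            if s > run_end:
                igs.append((run_end, s, run_name, name))
            if e > run_end:
                run_end, run_name = e, name
        # wrap gap: from the last span back to the first
        first = spans[0]
        if first[0] + circ_len > run_end:
            igs.append((run_end, first[0] + circ_len, run_name, first[2]))
    for gs, ge, left, right in igs:
        a, b = unrot(gs), unrot(ge % n if ge >= n else ge)
        if a < b:
            seq = p.sequence[a:b]
            ivs = [(a, b)]
        else:  # wraps the genome origin
            seq = p.sequence[a:] + p.sequence[:b]
            ivs = [(a, n), (0, b)]
        if not seq:
            continue
        add(f"{base_symbol(left)}-{base_symbol(right)}", "IGS", seq, ivs)

    log.info("%s: %d regions (%srps12 trans-spliced split)", p.id,
             len(regions), "" if rps12_seen else "no ")
    return regions


def group_homologous(regions_by_taxon: dict[str, list[Region]],
                     reference: str | None = None) -> list[RegionGroup]:
    """Group same-named regions across taxa.

    IGS flank order follows each taxon's own genome order, so a pair
    living inside an inverted block appears flipped (``B-A``); such
    regions are reverse-complemented and renamed into the reference
    orientation before grouping.  Groups missing from one or more taxa
    are kept but flagged incomplete.
    """
    if len(regions_by_taxon) < 2:
        raise ValueError("need regions from at least 2 taxa")
    taxa = list(regions_by_taxon)
    ref = reference or taxa[0]
    ref_names = {(r.region_class, r.name) for r in regions_by_taxon[ref]}

    grouped: dict[tuple[str, str], dict[str, Region]] = defaultdict(dict)
    for taxon in taxa:
        for r in regions_by_taxon[taxon]:
            key = (r.region_class, r.name)
            if r.region_class == "IGS" and key not in ref_names:
                parts = r.name.split("-")
                flipped = "-".join(parts[::-1])
                if ("IGS", flipped) in ref_names:
                    r = Region(name=flipped, region_class="IGS",
                               taxon=r.taxon, sequence=revcomp(r.sequence),
                               intervals=r.intervals, strand=-r.strand)
                    key = ("IGS", flipped)
            if r.taxon in grouped[key] or taxon in grouped[key]:
                continue
            grouped[key][taxon] = r
    out = []
    for (cls, name), members in sorted(grouped.items()):
        out.append(RegionGroup(name=name, region_class=cls, members=members,
                               complete=len(members) == len(taxa)))
    return out
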