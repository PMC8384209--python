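"""Column classification and the SV% / PIS% variability statistics.

The counting follows the DnaSP convention used for plastome marker
screens: columns containing a gap are excluded from the substitution /
invariable / parsimony-informative tallies and contribute only through
InDel events; ambiguity codes are treated as missing row-wise.  A
gap-free column with k distinct states contributes k-1 substitutions
(the site-wise minimum number of changes).  An InDel event is a distinct
maximal gap interval — identical (start, end) runs shared by several
rows collapse to one event.

    SV%  = (subs + indel events) / (subs + indel events + invariable) * 100
    PIS% =  PIS                  / (subs + indel events + invariable) * 100
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io import AlignmentMatrix

log = logging.getLogger("plastovar")

_GAP = ord("-")
_BASES = tuple(ord(c) for c in "ACGT")


@dataclass(frozen=True)
class ColumnStats:
    n_sites: int
    n_invariable: int
    n_pis: int
    n_subs: int
    n_indel_events: int

    def __add__(self, other: "ColumnStats") -> "ColumnStats":
        return ColumnStats(*(a + b for a, b in zip(
            (self.n_sites, self.n_invariable, self.n_pis, self.n_subs,
             self.n_indel_events),
            (other.n_sites, other.n_invariable, other.n_pis, other.n_subs,
             other.n_indel_events))))


@dataclass(frozen=True)
class VariabilityStats:
    region_name: str
    region_class: str
    n_taxa: int
    length: int           # alignment columns
    columns: ColumnStats
    sv_pct: float
    pis_pct: float


def count_indel_events(aln: AlignmentMatrix) -> int:
    """Distinct maximal gap intervals across all rows."""
    if aln.n_rows < 2:
        raise ValueError("indel events need >= 2 rows")
    events: set[tuple[int, int]] = set()
    for row in aln.rows:
        start = None
        for k, c in enumerate(row):
            if c == "-" and start is None:
                start = k
            elif c != "-" and start is not None:
                events.add((start, k))
                start = None
        if start is not None:
            events.add((start, len(row)))
    return len(events)


def classify_columns(aln: AlignmentMatrix) -> ColumnStats:
    """Invariable / substitution / PIS column tallies plus InDel events."""
    if aln.n_rows < 2:
        raise ValueError("column classification needs >= 2 rows")
    mat = np.stack([np.frombuffer(r.encode(), dtype=np.uint8)
                    for r in aln.rows])
    has_gap = (mat == _GAP).any(axis=0)
    counts = np.stack([(mat == b).sum(axis=0) for b in _BASES])  # 4 x ncol
    k_states = (counts > 0).sum(axis=0)
    informative = (counts >= 2).sum(axis=0) >= 2

    gapfree = ~has_gap
    scored = gapfree & (k_states > 0)
    invariable = int((scored & (k_states == 1)).sum())
    subs = int(np.clip(k_states[scored] - 1, 0, None).sum())
    pis = int((scored & informative & (k_states >= 2)).sum())
    return ColumnStats(
        n_sites=aln.n_cols, n_invariable=invariable, n_pis=pis,
        n_subs=subs, n_indel_events=count_indel_events(aln))


def sv_percent(c: ColumnStats) -> float:
    denom = c.n_subs + c.n_indel_events + c.n_invariable
    if denom == 0:
        log.warning("SV%% undefined (all-zero counts); reporting 0.0")
        return 0.0
    return 100.0 * (c.n_subs + c.n_indel_events) / denom


def pis_percent(c: ColumnStats) -> float:
    denom = c.n_subs + c.n_indel_events + c.n_invariable
    if denom == 0:
        log.warning("PIS%% undefined (all-zero counts); reporting 0.0")
        return 0.0
    return 100.0 * c.n_pis / denom


def variability_stats(aln: AlignmentMatrix) -> VariabilityStats:
    c = classify_columns(aln)
    return VariabilityStats(
        region_name=aln.region_name, region_class=aln.region_class,
        n_taxa=aln.n_rows, length=aln.n_cols, columns=c,
        sv_pct=sv_percent(c), pis_pct=pis_percent(c))


def rank_regions(stats: list[VariabilityStats], metric: str = "sv",
                 top_n: int = 10) -> list[VariabilityStats]:
    """Regions ordered by descending SV% or PIS%; ties broken by longer
    region, then name."""
    if not stats:
        raise ValueError("rank_regions needs at least one region")
    key = (lambda s: (-s.sv_pct, -s.length, s.region_name)) if metric == "sv" \
        else (lambda s: (-s.pis_pct, -s.length, s.region_name))
    return sorted(stats, key=key)[:top_n]


INF_RATIO = math.inf


@dataclass(frozen=True)
class ClassSummary:
    scope: str            # plastome | CDS | IGS | intron
    mutation_pct: float
    indel_pct: float
    ratio: float          # raw substitution count / raw indel count


def class_summary(stats: list[VariabilityStats]) -> list[ClassSummary]:
    """Per-scope substitution and InDel frequencies (the genome-wide
    scope pools every region).  The ratio uses raw counts, never the
    rounded percentages."""
    scopes = {"plastome": [s for s in stats],
              "CDS": [s for s in stats if s.region_class == "CDS"],
              "IGS": [s for s in stats if s.region_class == "IGS"],
              "intron": [s for s in stats if s.region_class == "intron"]}
    out = []
    for scope, members in scopes.items():
        tot = ColumnStats(0, 0, 0, 0, 0)
        for s in members:
            tot = tot + s.columns
        denom = tot.n_subs + tot.n_indel_events + tot.n_invariable
        mut = 100.0 * tot.n_subs / denom if denom else 0.0
        ind = 100.0 * tot.n_indel_events / denom if denom else 0.0
        ratio = (tot.n_subs / tot.n_indel_events
                 if tot.n_indel_events else INF_RATIO)
        out.append(ClassSummary(scope=scope, mutation_pct=mut,
                                indel_pct=ind, ratio=ratio))
    return out


# ---------------------------------------------------------------------------
# distance/NJ sanity-check utility
# ---------------------------------------------------------------------------

def concatenate_alignments(groups: list[AlignmentMatrix]) -> AlignmentMatrix:
    taxa = None
    for g in groups:
        s = sorted(g.taxa)
        if taxa is None:
            taxa = s
        elif s != taxa:
            raise ValueError("groups do not share a common taxon set")
    rows = {t: [] for t in taxa}
    for g in groups:
        for t, r in zip(g.taxa, g.rows):
            rows[t].append(r)
    return AlignmentMatrix("concatenated", "other", taxa,
                           ["".join(rows[t]) for t in taxa])


def p_distance_matrix(aln: AlignmentMatrix) -> np.ndarray:
    """Pairwise p-distances (mismatches / comparable non-gap columns)."""
    mat = np.stack([np.frombuffer(r.encode(), dtype=np.uint8)
                    for r in aln.rows])
    nongap = mat != _GAP
    k = aln.n_rows
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            both = nongap[i] & nongap[j]
            comp = int(both.sum())
            if comp == 0:
                raise ValueError(
                    f"no comparable columns between {aln.taxa[i]} and "
                    f"{aln.taxa[j]}")
            d[i, j] = d[j, i] = ((mat[i] != mat[j]) & both).sum() / comp
    return d


def nj_tree(groups: list[AlignmentMatrix]) -> str:
    """Neighbor-joining newick from the p-distance matrix of the
    concatenated groups (sanity-check utility, not an inference tool)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    aln = concatenate_alignments(groups)
    if aln.n_rows < 3:
        raise ValueError("NJ needs at least 3 taxa")
    dm = DistanceMatrix(p_distance_matrix(aln), ids=aln.taxa)
    tree = nj(dm)
    return str(tree).strip()
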