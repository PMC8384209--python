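"""The bundled ``default-cocoseae`` gene map for the plastome simulator.

A realistic palm-like plastome complement: 113 unique genes (79
protein-coding, 30 tRNA, 4 rRNA), 15 one-intron and 3 two-intron genes,
a trans-spliced rps12 (exon 1 in the LSC, exons 2-3 in the IR), rps19
fully inside the IR (so two complete copies), ycf1 spanning the SSC/IRa
junction (its truncated mirror is the classic pseudo-ycf1 at IRb) and
ndhF poking 56 bp into IRb where it overlaps that pseudo-copy.  Gene
lengths are typical magnitudes, not any particular accession's.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GeneSpec:
    name: str
    kind: str                      # CDS | tRNA | rRNA
    strand: int
    exons: tuple[int, ...]
    introns: tuple[int, ...] = ()
    start_codon: str = "ATG"       # CDS only
    ir_overhang: int = 0           # bp extending into IRb (ndhF)
    ira_overhang: int = 0          # bp of the last exon inside IRa (ycf1)

    def __post_init__(self):
        if len(self.introns) != max(0, len(self.exons) - 1):
            raise ValueError(f"{self.name}: intron/exon count mismatch")

    @property
    def footprint(self) -> int:
        return sum(self.exons) + sum(self.introns)


def _cds(name, length, strand=1, introns=(), exon_split=None,
         start="ATG", **kw):
    if exon_split is None:
        exons = (length,)
    else:
        exons = tuple(exon_split)
    return GeneSpec(name, "CDS", strand, exons, tuple(introns),
                    start_codon=start, **kw)


def _trna(name, strand=1, intron=None):
    if intron:
        return GeneSpec(name, "tRNA", strand, (38, 37), (intron,))
    return GeneSpec(name, "tRNA", strand, (75,))


def _rrna(name, length, strand=1):
    return GeneSpec(name, "rRNA", strand, (length,))


def toy_map() -> dict[str, list[GeneSpec]]:
    """A minimal desk-scale map (11 genes) with the same structural
    motifs as the full map: an intron gene, a minus-strand gene, an
    IR-duplicated pair, ycf1 across the SSC/IRa junction and ndhF
    reaching into IRb."""
    lsc = [
        _cds("psbA", 300, -1),
        _trna("trnK-UUU", -1, intron=200),
        _cds("matK", 600, -1),
        _cds("ndhJ", 300, -1),
        _trna("trnF-GAA"),
        _cds("rbcL", 450),
    ]
    ssc = [
        _cds("ndhF", 600, -1, ir_overhang=56),
        _cds("ccsA", 300),
        _cds("ycf1", 900, 1, ira_overhang=200),
    ]
    ira = [
        _rrna("rrn16", 400),
        _cds("rps19", 279, -1, start="GTG"),
        _trna("trnH-GUG", -1),
    ]
    return {"LSC": lsc, "SSC": ssc, "IRA": ira}


def medium_map() -> dict[str, list[GeneSpec]]:
    """A mid-scale map (~55 kb genome, ~55 regions): the first 18 LSC
    genes and first 6 IRa genes of the full map plus the complete SSC.
    Large enough for rank-correlation and rate-recovery experiments,
    small enough to align in seconds."""
    gm = default_cocoseae_map()
    return {"LSC": gm["LSC"][:18], "SSC": gm["SSC"], "IRA": gm["IRA"][:6]}


def default_cocoseae_map() -> dict[str, list[GeneSpec]]:
    """Gene lists per partition; the IRA list is in IRa genome order
    (its mirror in IRb runs the other way)."""
    lsc = [
        _cds("psbA", 1062, -1),
        _trna("trnK-UUU", -1, intron=700),
        _cds("matK", 1530, -1),
        _cds("rps16", 267, -1, introns=(840,), exon_split=(40, 227)),
        _trna("trnQ-UUG", -1),
        _cds("psbK", 186),
        _cds("psbI", 111),
        _trna("trnS-GCU", -1),
        _trna("trnG-UCC", 1, intron=690),
        _trna("trnR-UCU"),
        _cds("atpA", 1524, -1),
        _cds("atpF", 555, -1, introns=(720,), exon_split=(145, 410)),
        _cds("atpH", 246, -1),
        _cds("atpI", 744, -1),
        _cds("rps2", 711, -1),
        _cds("rpoC2", 4101, -1),
        _cds("rpoC1", 2043, -1, introns=(750,), exon_split=(432, 1611)),
        _cds("rpoB", 3213, -1),
        _trna("trnC-GCA"),
        _cds("petN", 90),
        _cds("psbM", 105, -1),
        _trna("trnD-GUC", -1),
        _trna("trnY-GUA", -1),
        _trna("trnE-UUC", -1),
        _trna("trnT-GGU"),
        _cds("psbD", 1062),
        _cds("psbC", 1386),
        _trna("trnS-UGA", -1),
        _cds("psbZ", 189),
        _trna("trnG-GCC"),
        _trna("trnfM-CAU", -1),
        _cds("rps14", 303, -1),
        _cds("psaB", 2205, -1),
        _cds("psaA", 2253, -1),
        _cds("ycf3", 507, -1, introns=(730, 740), exon_split=(124, 230, 153)),
        _trna("trnS-GGA", -1),
        _cds("rps4", 606, -1),
        _trna("trnT-UGU", -1),
        _trna("trnL-UAA", 1, intron=520),
        _trna("trnF-GAA"),
        _cds("ndhJ", 477, -1),
        _cds("ndhK", 678, -1),
        _cds("ndhC", 363, -1),
        _trna("trnV-UAC", -1, intron=600),
        _trna("trnM-CAU"),
        _cds("atpE", 411, -1),
        _cds("atpB", 1497, -1),
        _cds("rbcL", 1434),
        _cds("accD", 1467),
        _cds("psaI", 111),
        _cds("ycf4", 555),
        _cds("cemA", 690, start="ACG"),
        _cds("petA", 963),
        _cds("psbJ", 123, -1),
        _cds("psbL", 117, -1),
        _cds("psbF", 120, -1),
        _cds("psbE", 252, -1),
        _cds("petL", 96),
        _cds("petG", 114),
        _trna("trnW-CCA", -1),
        _trna("trnP-UGG", -1),
        _cds("psaJ", 129),
        _cds("rpl33", 201),
        _cds("rps18", 306),
        _cds("rpl20", 354, -1),
        _cds("rps12", 114, -1),  # trans-spliced 5' exon
        _cds("clpP", 591, -1, introns=(810, 620), exon_split=(71, 292, 228)),
        _cds("psbB", 1527),
        _cds("psbT", 108),
        _cds("psbN", 132, -1),
        _cds("psbH", 222),
        _cds("petB", 648, 1, introns=(770,), exon_split=(6, 642)),
        _cds("petD", 483, 1, introns=(740,), exon_split=(8, 475)),
        _cds("rpoA", 1014, -1),
        _cds("rps11", 417, -1),
        _cds("rpl36", 114, -1),
        _cds("infA", 234, -1),
        _cds("rps8", 405, -1),
        _cds("rpl14", 369, -1),
        _cds("rpl16", 408, -1, introns=(960,), exon_split=(9, 399)),
        _cds("rps3", 657, -1),
        _cds("rpl22", 480, -1),
    ]
    ssc = [
        # ndhF reaches 56 bp into IRb, overlapping the pseudo-ycf1 there
        _cds("ndhF", 2241, -1, ir_overhang=56),
        _cds("rpl32", 174),
        _trna("trnL-UAG"),
        _cds("ccsA", 960),
        _cds("ndhD", 1503, -1, start="ATC"),
        _cds("psaC", 246, -1),
        _cds("ndhE", 306, -1),
        _cds("ndhG", 531, -1),
        _cds("ndhI", 504, -1),
        _cds("ndhA", 1092, -1, introns=(1100,), exon_split=(553, 539)),
        _cds("ndhH", 1182, -1),
        _cds("rps15", 273, -1),
        # ycf1's last 1100 bp sit inside IRa (complete copy at JSA,
        # truncated pseudo projection at IRb)
        _cds("ycf1", 5001, 1, ira_overhang=1100),
    ]
    ira = [
        _trna("trnN-GUU", -1),
        _trna("trnR-ACG"),
        _rrna("rrn5", 121),
        _rrna("rrn4.5", 103),
        _rrna("rrn23", 2810),
        _trna("trnA-UGC", 1, intron=800),
        _trna("trnI-GAU", 1, intron=940),
        _rrna("rrn16", 1491),
        _trna("trnV-GAC", -1),
        _cds("rps12", 258, -1, introns=(540,), exon_split=(232, 26)),
        _cds("rps7", 468, -1),
        _cds("ndhB", 1533, -1, introns=(680,), exon_split=(777, 756)),
        _trna("trnL-CAA", -1),
        _cds("ycf2", 6801),
        _trna("trnI-CAU"),
        _cds("rpl23", 282),
        _cds("rpl2", 1485, 1, introns=(660,), exon_split=(391, 1094),
             start="ACG"),
        _cds("rps19", 279, -1, start="GTG"),
        _trna("trnH-GUG", -1),
    ]
    return {"LSC": lsc, "SSC": ssc, "IRA": ira}
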