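"""Reading and writing annotated plastomes and per-region alignments.

The in-memory model is deliberately small: a :class:`Plastome` is a
nucleotide string plus a list of :class:`GeneFeature` records, and an
:class:`AlignmentMatrix` is a rectangular block of gapped rows.  All
coordinates are 0-based half-open on the record's own linearization;
the GenBank dialect (1-based inclusive, ``join``/``complement``) exists
only at the I/O boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("plastovar")

IUPAC = set("ACGTRYSWKMBDHVN")
COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")

FEATURE_KINDS = ("CDS", "tRNA", "rRNA")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class CoordinateError(ValueError):
    """Raised when feature coordinates fall outside the sequence."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene with its exon structure.

    ``parts`` are 0-based half-open intervals in genome-forward order;
    a multi-part feature is intron-containing (or trans-spliced for
    rps12).  Features duplicated by the inverted repeat appear twice,
    once per copy.
    """

    name: str
    kind: str  # CDS | tRNA | rRNA
    strand: int  # +1 / -1
    parts: tuple[tuple[int, int], ...]
    is_pseudo: bool = False

    def __post_init__(self):
        if not self.parts:
            raise ValueError("feature needs at least one part")
        for s, e in self.parts:
            if e <= s:
                raise ValueError(f"empty interval in {self.name}: [{s},{e})")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.parts)

    @property
    def end(self) -> int:
        return max(e for _, e in self.parts)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.parts)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    @property
    def n_introns(self) -> int:
        return len(self.parts) - 1


@dataclass
class Plastome:
    """A circular annotated plastid genome."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    is_circular: bool = True
    source: str = "synthetic"

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - IUPAC
        if bad:
            raise FormatError(f"{self.id}: non-IUPAC characters {sorted(bad)}")
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.parts:
                if s < 0 or e > n:
                    raise CoordinateError(
                        f"{self.id}: feature {f.name} part [{s},{e}) outside [0,{n})"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_sequence(self, f: GeneFeature) -> str:
        """Spliced, strand-corrected nucleotide sequence of a feature."""
        parts = f.parts if f.strand >= 0 else f.parts[::-1]
        chunks = [self.sequence[s:e] for s, e in parts]
        if f.strand < 0:
            chunks = [revcomp(c) for c in chunks]
        return "".join(chunks)


@dataclass
class AlignmentMatrix:
    """One homologous region aligned across taxa (rows of equal length)."""

    region_name: str
    region_class: str  # CDS | IGS | intron | other
    taxa: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise FormatError("taxa/rows length mismatch")
        if self.rows:
            ncol = len(self.rows[0])
            if any(len(r) != ncol for r in self.rows):
                raise FormatError(
                    f"{self.region_name}: unequal row lengths "
                    f"{sorted({len(r) for r in self.rows})}"
                )
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def drop_gap_only_columns(self) -> "AlignmentMatrix":
        keep = [
            j for j in range(self.n_cols)
            if any(r[j] != "-" for r in self.rows)
        ]
        dropped = self.n_cols - len(keep)
        if dropped:
            log.info("%s: dropped %d gap-only columns", self.region_name, dropped)
            rows = ["".join(r[j] for j in keep) for r in self.rows]
            return AlignmentMatrix(self.region_name, self.region_class,
                                   list(self.taxa), rows)
        return self


# ---------------------------------------------------------------------------
# gene-name normalization
# ---------------------------------------------------------------------------

_EXON_RE = re.compile(r"\s*\(\s*exons?\s+([\d\s,and]+?)\s*\)\s*$", re.IGNORECASE)
_TRNA_RE = re.compile(r"^trn(\w+?)[-_ ]([acgut]{3})$", re.IGNORECASE)

KNOWN_GENES: set[str] = set()  # populated lazily from the bundled gene map


def normalize_gene_label(raw: str) -> tuple[str, tuple[int, ...]]:
    """Canonical gene name plus any exon indices split off the label.

    ``"rps12 (exons 2 and 3)"`` -> ``("rps12", (2, 3))``.
    """
    if not raw:
        raise ValueError("empty gene label")
    s = raw.strip()
    exons: tuple[int, ...] = ()
    m = _EXON_RE.search(s)
    if m:
        exons = tuple(int(x) for x in re.findall(r"\d+", m.group(1)))
        s = s[: m.start()].strip()
    s = s.replace("*", "").strip()
    m = _TRNA_RE.match(s)
    if m:
        return f"trn{m.group(1)}-{m.group(2).upper().replace('T', 'U')}", exons
    if s.isupper() and not s.startswith("RRN"):
        s = s.lower()
    if s.lower().startswith("rrn"):
        s = s.lower()
    return s, exons


def normalize_gene_name(raw: str) -> str:
    """Case/separator-normalized community gene symbol (``trnL_UAA`` ->
    ``trnL-UAA``, ``RPS19`` -> ``rps19``); unknown names pass through."""
    name, _ = normalize_gene_label(raw)
    return name


def base_symbol(name: str) -> str:
    """Gene symbol without the tRNA anticodon (``trnL-UAA`` -> ``trnL``)."""
    if name.startswith("trn") and "-" in name:
        return name.split("-", 1)[0]
    return name


# ---------------------------------------------------------------------------
# GenBank / FASTA reading
# ---------------------------------------------------------------------------

def _feature_name(feat: SeqFeature) -> str | None:
    for key in ("gene", "locus_tag", "product"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return None


def _location_parts(feat: SeqFeature) -> tuple[tuple[int, int], ...]:
    loc = feat.location
    locs = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    parts = sorted((int(p.start), int(p.end)) for p in locs)
    # merge book-keeping splits that actually abut (origin-crossing joins
    # arrive as two simple locations; keep them as separate wrap parts)
    merged: list[tuple[int, int]] = []
    for s, e in parts:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return tuple(merged)


def read_genbank(path: str | Path) -> Plastome:
    """Parse a GenBank flat file into the internal plastome model.

    Gene/CDS/tRNA/rRNA annotations are captured with their exon structure;
    1-based inclusive spans become 0-based half-open, ``complement``
    becomes strand −1 and ``join`` a multi-part feature.
    """
    path = Path(path)
    try:
        record: SeqRecord = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise FormatError(f"{path}: no GenBank record found") from None
    seq = str(record.seq).upper()
    if not seq or set(seq) == {"N"} and len(seq) < 2:
        raise FormatError(f"{path}: record has no sequence")

    circular = record.annotations.get("topology", "circular") == "circular"
    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type not in FEATURE_KINDS:
            continue
        raw = _feature_name(feat)
        if raw is None:
            continue
        name, _ = normalize_gene_label(raw)
        parts = _location_parts(feat)
        if not parts:
            continue
        if any(e > len(seq) for _, e in parts) and not circular:
            raise CoordinateError(f"{path}: {name} beyond sequence end")
        pseudo = "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers
        features.append(GeneFeature(
            name=name, kind=feat.type,
            strand=-1 if feat.location.strand == -1 else 1,
            parts=parts, is_pseudo=pseudo,
        ))
    return Plastome(id=record.id or record.name or path.stem, sequence=seq,
                    features=features, is_circular=circular, source=str(path))


def write_genbank(p: Plastome, path: str | Path) -> None:
    """Write the plastome back out as an annotated GenBank flat file."""
    record = SeqRecord(Seq(p.sequence), id=p.id[:16] or "plastome",
                       name=(p.id[:16] or "plastome").replace(" ", "_"),
                       description=f"{p.id} plastome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if p.is_circular else "linear"
    for f in p.features:
        locs = [SimpleLocation(s, e, strand=f.strand) for s, e in f.parts]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [f.name]}
        if f.is_pseudo:
            quals["pseudo"] = [""]
        record.features.append(SeqFeature(loc, type=f.kind, qualifiers=quals))
    SeqIO.write([record], str(path), "genbank")


def read_fasta(path: str | Path, record_id: str | None = None) -> Plastome:
    """Read a single-record nucleotide FASTA as an unannotated plastome."""
    records = list(SeqIO.parse(str(Path(path)), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    if len(records) > 1:
        if record_id is None:
            raise FormatError(
                f"{path}: {len(records)} records; pass record_id to pick one")
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise FormatError(f"{path}: no record named {record_id!r}")
        records = matches
    rec = records[0]
    return Plastome(id=rec.id, sequence=str(rec.seq).upper(),
                    features=[], source=str(path))


# ---------------------------------------------------------------------------
# aligned FASTA
# ---------------------------------------------------------------------------

def write_alignment_fasta(aln: AlignmentMatrix, path: str | Path) -> None:
    """Aligned FASTA with region metadata in the headers (lossless)."""
    with open(path, "w", encoding="utf-8") as fh:
        for taxon, row in zip(aln.taxa, aln.rows):
            fh.write(f">{taxon} region={aln.region_name} "
                     f"class={aln.region_class}\n")
            for i in range(0, len(row), 70):
                fh.write(row[i:i + 70] + "\n")


def read_alignment_fasta(path: str | Path,
                         region_name: str | None = None,
                         region_class: str = "other") -> AlignmentMatrix:
    """Read an aligned FASTA; gap-only columns are dropped with a log line."""
    taxa: list[str] = []
    rows: list[str] = []
    name, cls = region_name, region_class
    for rec in SeqIO.parse(str(Path(path)), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq).upper())
        meta = dict(tok.split("=", 1) for tok in rec.description.split()
                    if "=" in tok)
        name = name or meta.get("region")
        if "class" in meta:
            cls = meta["class"]
    if not rows:
        raise FormatError(f"{path}: empty alignment")
    aln = AlignmentMatrix(name or Path(path).stem, cls, taxa, rows)
    return aln.drop_gap_only_columns()


# ---------------------------------------------------------------------------
# coordinate dialect helpers (GenBank <-> internal)
# ---------------------------------------------------------------------------

def to_half_open(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    return start_1based - 1, end_inclusive


def to_one_based(start: int, end: int) -> tuple[int, int]:
    return start + 1, end
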