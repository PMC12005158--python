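"""Reference data model for circular organellar genomes.

Plant mitochondrial and plastid genomes are (conceptually) circular molecules
a few hundred kilobases long, carrying protein-coding genes (CDS), introns,
rRNAs, and tRNAs, plus dispersed repeat pairs that mediate non-allelic
recombination.  This module holds the genome/feature/repeat containers and the
coordinate conventions every downstream analysis relies on:

* coordinates are 1-based inclusive throughout (a repeat printed as
  19,682-20,237 has length 20,237 - 19,682 + 1 = 556);
* inverted repeat copies are printed with descending coordinates and are
  stored internally as ascending intervals with an ``inverted`` flag;
* trinucleotide contexts are extracted with circular wraparound, and the
  minus-strand context is the reverse complement of the plus-strand context;
* overlapping features are resolved with precedence tRNA > rRNA > CDS >
  intron (structural RNA genes are short; burying them inside CDS would bias
  small-region frequencies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("orgmut")

VALID_BASES = set("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

REGION_CLASSES = ("intergenic", "CDS", "intron", "rRNA", "tRNA")
#: precedence used to resolve overlapping features (higher wins)
_PRECEDENCE = {"tRNA": 4, "rRNA": 3, "CDS": 2, "intron": 1}

REGION_CODE = {name: i for i, name in enumerate(REGION_CLASSES)}
STRAND_NONE, STRAND_PLUS, STRAND_MINUS, STRAND_BOTH = 0, 1, 2, 3


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(COMPLEMENT)[::-1]


class MalformedRecordError(ValueError):
    """A catalog or annotation record violates the coordinate conventions."""


@dataclass(frozen=True)
class OrganelleGenome:
    """A circular (by default) organellar reference sequence."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("empty genome sequence")
        if not set(seq) <= VALID_BASES:
            bad = sorted(set(seq) - VALID_BASES)
            raise ValueError(f"genome {self.id}: invalid bases {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos`` (modular if circular)."""
        if self.circular:
            return self.sequence[(pos - 1) % self.length]
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside linear genome")
        return self.sequence[pos - 1]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature interval (1-based inclusive).

    ``strand`` is the strand carrying the sense (non-template) sequence of the
    gene; the template strand read by RNA polymerase is the opposite one.
    Features spanning the circular origin are represented as two intervals
    sharing a name.
    """

    name: str
    region_class: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.region_class not in _PRECEDENCE:
            raise MalformedRecordError(
                f"feature {self.name}: region_class {self.region_class!r} "
                f"not one of {sorted(_PRECEDENCE)}"
            )
        if not 1 <= self.start <= self.end:
            raise MalformedRecordError(
                f"feature {self.name}: bad interval {self.start}-{self.end}"
            )
        if self.strand not in "+-":
            raise MalformedRecordError(f"feature {self.name}: bad strand")


@dataclass(frozen=True)
class RepeatPair:
    """A pair of dispersed repeat copies.

    Copies are stored as ascending 1-based inclusive intervals; ``inverted``
    records whether copy2 was printed with descending coordinates (i.e. the
    copies lie on opposite strands).
    """

    name: str
    copy1: tuple[int, int]
    copy2: tuple[int, int]
    inverted: bool
    percent_identity: float
    length: int

    def __post_init__(self):
        if self.copy1[0] > self.copy1[1]:
            raise MalformedRecordError(
                f"repeat {self.name}: copy1 interval inverted {self.copy1}"
            )
        if self.copy2[0] > self.copy2[1]:
            raise MalformedRecordError(
                f"repeat {self.name}: copy2 must be stored ascending"
            )
        if not 0 < self.percent_identity <= 100:
            raise MalformedRecordError(
                f"repeat {self.name}: percent identity {self.percent_identity}"
            )


@dataclass(frozen=True)
class TrinucleotideContext:
    """The 5'-X, center, 3'-Y context of one genome position on one strand."""

    fivep: str
    center: str
    threep: str
    strand_of_report: str

    @property
    def usable(self) -> bool:
        """Contexts touching an N are excluded from frequency denominators."""
        return "N" not in (self.fivep, self.center, self.threep)

    def __str__(self) -> str:
        return self.fivep + self.center + self.threep


def repeat_length(rp: RepeatPair) -> int:
    """Length of a repeat copy under the 1-based inclusive convention."""
    return rp.copy1[1] - rp.copy1[0] + 1


def trinucleotide_context(
    g: OrganelleGenome, pos: int, strand: str = "+"
) -> TrinucleotideContext:
    """Extract the trinucleotide context at ``pos`` (1-based).

    On the plus strand the context is (pos-1, pos, pos+1) with circular
    wraparound; on the minus strand it is the reverse complement of that
    triple.  On a linear genome, positions at the ends get an ``N`` neighbor
    and are flagged unusable via :attr:`TrinucleotideContext.usable`.
    """
    if not 1 <= pos <= g.length:
        raise IndexError(f"position {pos} outside genome of length {g.length}")
    if strand not in "+-":
        raise ValueError(f"bad strand {strand!r}")
    triple = []
    for p in (pos - 1, pos, pos + 1):
        if g.circular:
            triple.append(g.sequence[(p - 1) % g.length])
        elif 1 <= p <= g.length:
            triple.append(g.sequence[p - 1])
        else:
            triple.append("N")
    ctx = "".join(triple)
    if strand == "-":
        ctx = revcomp(ctx)
    return TrinucleotideContext(ctx[0], ctx[1], ctx[2], strand)


class RegionIndex:
    """Per-position region/strand lookup for one genome.

    Precomputes two arrays of length ``genome.length``:

    * ``region``: code into :data:`REGION_CLASSES` after precedence
      resolution (tRNA > rRNA > CDS > intron, intergenic elsewhere);
    * ``strand``: 0 none, 1 plus, 2 minus, 3 both.  A site covered by
      winning-class features on both strands is "both" and is excluded from
      strand-asymmetry denominators.
    """

    def __init__(self, genome: OrganelleGenome, features: list[GeneFeature]):
        self.genome = genome
        L = genome.length
        prec = np.zeros(L, dtype=np.int8)  # best precedence seen
        self.region = np.zeros(L, dtype=np.int8)  # intergenic
        self.strand = np.zeros(L, dtype=np.int8)
        order = sorted(features, key=lambda f: _PRECEDENCE[f.region_class])
        for f in order:
            if f.end > L:
                raise MalformedRecordError(
                    f"feature {f.name} end {f.end} beyond genome length {L}"
                )
            sl = slice(f.start - 1, f.end)
            p = _PRECEDENCE[f.region_class]
            code = REGION_CODE[f.region_class]
            scode = STRAND_PLUS if f.strand == "+" else STRAND_MINUS
            higher = prec[sl] < p
            same = prec[sl] == p
            # new winner: take region and strand
            self.region[sl] = np.where(higher, code, self.region[sl])
            new_strand = np.where(higher, scode, self.strand[sl])
            # equal precedence on the other strand -> both
            conflict = same & (self.strand[sl] != scode) & (self.strand[sl] != 0)
            new_strand = np.where(conflict, STRAND_BOTH, new_strand)
            self.strand[sl] = new_strand
            prec[sl] = np.maximum(prec[sl], p)

    def region_of(self, pos: int) -> str:
        return REGION_CLASSES[self.region[pos - 1]]

    def strand_of(self, pos: int) -> str | None:
        code = self.strand[pos - 1]
        return {0: None, 1: "+", 2: "-", 3: "both"}[int(code)]


def site_region(
    features: list[GeneFeature] | RegionIndex,
    pos: int,
    genome: OrganelleGenome | None = None,
) -> tuple[str, str | None]:
    """Region class and feature strand at one 1-based position.

    Accepts a prebuilt :class:`RegionIndex` or a feature list (in which case
    ``genome`` is required to size the index).  Sites in no feature are
    intergenic with no strand.
    """
    if isinstance(features, RegionIndex):
        idx = features
    else:
        if genome is None:
            raise ValueError("genome required when passing a raw feature list")
        idx = RegionIndex(genome, features)
    return idx.region_of(pos), idx.strand_of(pos)


# ---------------------------------------------------------------------------
# File formats


def read_fasta(path) -> list[OrganelleGenome]:
    return [
        OrganelleGenome(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(genomes: list[OrganelleGenome], path) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


_GFF_TYPES = {"CDS": "CDS", "intron": "intron", "rRNA": "rRNA", "tRNA": "tRNA"}


def read_gff_features(path) -> list[GeneFeature]:
    """Read the consumed subset of a GFF3 file.

    Only rows of type CDS/intron/rRNA/tRNA are kept; other types are counted
    and logged.  The feature name is taken from the ``Name=`` or ``ID=``
    attribute, falling back to ``<type>_<start>``.
    """
    feats: list[GeneFeature] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                continue
            ftype = parts[2]
            if ftype not in _GFF_TYPES:
                skipped += 1
                continue
            attrs = {}
            if len(parts) > 8:
                for kv in parts[8].split(";"):
                    if "=" in kv:
                        k, v = kv.split("=", 1)
                        attrs[k.strip()] = v.strip()
            name = attrs.get("Name") or attrs.get("ID") or f"{ftype}_{parts[3]}"
            feats.append(
                GeneFeature(
                    name=name,
                    region_class=_GFF_TYPES[ftype],
                    start=int(parts[3]),
                    end=int(parts[4]),
                    strand=parts[6],
                )
            )
    if skipped:
        logger.info("read_gff_features: ignored %d rows of other types", skipped)
    return feats


def write_gff_features(features: list[GeneFeature], path, source="orgmut") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"chr\t{source}\t{f.region_class}\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t.\tName={f.name}\n"
            )


def _parse_coord_pair(text: str) -> tuple[int, int]:
    text = text.strip().replace(",", "").replace("–", "-")
    a, b = text.split("-")
    return int(a), int(b)


def parse_repeat_row(
    name: str, copy1: str, copy2: str, percent_id: float, length: int
) -> RepeatPair:
    """Build a RepeatPair from printed-style coordinate strings.

    Descending copy2 coordinates mark an inverted repeat; both copies are
    stored ascending.  The printed length must match the coordinate span.
    """
    c1 = _parse_coord_pair(copy1)
    c2 = _parse_coord_pair(copy2)
    if c1[0] > c1[1]:
        raise MalformedRecordError(f"repeat {name}: copy1 printed descending")
    inverted = c2[0] > c2[1]
    if inverted:
        c2 = (c2[1], c2[0])
    rp = RepeatPair(name, c1, c2, inverted, float(percent_id), int(length))
    # printed lengths are alignment lengths: indels let the two copies differ
    # by a base or two, so the length must match at least one copy's span
    span1 = repeat_length(rp)
    span2 = c2[1] - c2[0] + 1
    if int(length) not in (span1, span2):
        raise MalformedRecordError(
            f"repeat {name}: printed length {length} matches neither copy span "
            f"({span1}, {span2})"
        )
    return rp


def read_repeat_table(path) -> list[RepeatPair]:
    """Read a tab-separated repeat catalog.

    Columns: name, copy1 (``start-end``), copy2 (``start-end``; descending
    means inverted), percent identity, length.  An empty file yields an empty
    list.
    """
    out: list[RepeatPair] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "name":
                continue
            if len(parts) < 5:
                raise MalformedRecordError(f"{path} row {i}: expected 5 columns")
            try:
                out.append(
                    parse_repeat_row(
                        parts[0], parts[1], parts[2], float(parts[3]), int(parts[4])
                    )
                )
            except MalformedRecordError as e:
                raise MalformedRecordError(f"{path} row {i}: {e}") from e
    return out


def write_repeat_table(repeats: list[RepeatPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tcopy1\tcopy2\tpercent_id\tlength\n")
        for rp in repeats:
            c2 = rp.copy2 if not rp.inverted else (rp.copy2[1], rp.copy2[0])
            fh.write(
                f"{rp.name}\t{rp.copy1[0]}-{rp.copy1[1]}\t{c2[0]}-{c2[1]}\t"
                f"{rp.percent_identity}\t{rp.length}\n"
            )
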