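"""Synthetic genomes, duplex read families, and long reads with planted truth.

Every generator records the events it plants (:class:`TruthRecord`), so each
downstream stage — duplex consensus calling, NUMT filtering, spectrum
analysis, split-read classification — can be checked against known answers.

The duplex generator works in the sparse-difference representation used by
:mod:`orgmut.duplexcall`: a read is its mapped interval plus the list of
positions where it differs from the reference.  This is exact for the error
rates of interest (mutation and sequencing-error rates far below one event
per molecule) and lets simulations cover 10^8 duplex bases in seconds.

Mutation rates are pyrimidine-keyed: each substitution is one of the six
classes C>A, C>G, C>T, T>A, T>C, T>G read on the strand carrying the
pyrimidine, so a planted G>A on the reference plus strand is a C>T event
whose pyrimidine sits on the minus strand.  Context multipliers modify the
rate per (class, 5' base, 3' base) on the pyrimidine strand, and the
template-strand bias ``b`` multiplies the rate at genic sites whose
pyrimidine lies on the template (RNA-polymerase-read) strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .orgmodel import (
    COMPLEMENT,
    GeneFeature,
    OrganelleGenome,
    RegionIndex,
    RepeatPair,
    revcomp,
)

logger = logging.getLogger("orgmut")

#: the six pyrimidine-keyed substitution classes
CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate("ACGTN")}
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G


def encode_seq(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    lut = np.full(256, 4, dtype=np.uint8)
    for b, i in _CODE.items():
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


_DECODE_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)


def decode_seq(codes: np.ndarray) -> str:
    return _DECODE_LUT[codes].tobytes().decode()


class PlacementError(RuntimeError):
    """Could not place genes/repeats without overlap within bounded retries."""


class ParameterError(ValueError):
    """A generator parameter is outside its valid range."""


@dataclass
class TruthEvent:
    """One planted event on one molecule/read."""

    position: int  # 1-based genome position (anchor for indels)
    etype: str  # SNV | insertion | deletion | dinucleotide | recombination
    ref: str
    alt: str
    strand_of_placement: str = "+"
    repeat: str | None = None


@dataclass
class TruthRecord:
    molecule_id: str
    events: list[TruthEvent] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Genome simulation


def _random_seq(rng, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def simulate_genome(
    length: int,
    n_genes: dict[str, int] | None = None,
    repeat_specs: list[tuple[int, float, str]] | None = None,
    seed: int | np.random.Generator = 0,
    gene_length: dict[str, tuple[int, int]] | None = None,
    max_tries: int = 200,
) -> tuple[OrganelleGenome, list[GeneFeature], list[RepeatPair]]:
    """Simulate a circular genome with annotated genes and planted repeats.

    ``n_genes`` maps region class (CDS/intron/rRNA/tRNA) to a count;
    ``repeat_specs`` is a list of (length, percent identity, orientation)
    tuples with orientation ``"direct"`` or ``"inverted"``, optionally
    extended to (length, identity, orientation, start1, start2) to pin the
    1-based start of each copy (useful to keep repeat pairs in disjoint
    territories so recombination products of one pair cannot overlap
    another).  The second repeat copy differs from the first at exactly
    ``round((1 - id/100) * length)`` positions.  All placements are
    non-overlapping; identical seeds give byte-identical output.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_genes is None:
        n_genes = {"CDS": 4, "intron": 1, "rRNA": 1, "tRNA": 2}
    n_genes = dict(n_genes)
    repeat_specs = list(repeat_specs or [])
    gene_length = gene_length or {
        "CDS": (600, 1500),
        "intron": (300, 800),
        "rRNA": (900, 1800),
        "tRNA": (70, 90),
    }
    footprint = sum(2 * int(spec[0]) for spec in repeat_specs)
    footprint += sum(gene_length[c][1] * n for c, n in n_genes.items())
    if footprint >= length:
        raise PlacementError(
            f"feature+repeat footprint {footprint} exceeds genome length {length}"
        )

    seq = _random_seq(rng, length)
    occupied = np.zeros(length, dtype=bool)

    def _place(span: int) -> int:
        # linear placement (avoids origin-spanning features); 1-bp spacer
        for _ in range(max_tries):
            s = int(rng.integers(0, length - span))
            if not occupied[max(0, s - 1) : s + span + 1].any():
                occupied[s : s + span] = True
                return s
        raise PlacementError(f"cannot place a {span}-bp element without overlap")

    def _place_at(start0: int, span: int) -> int:
        if start0 < 0 or start0 + span > length:
            raise PlacementError(f"fixed placement {start0} outside genome")
        if occupied[max(0, start0 - 1) : start0 + span + 1].any():
            raise PlacementError(f"fixed placement at {start0 + 1} overlaps")
        occupied[start0 : start0 + span] = True
        return start0

    # reserve fixed repeat placements before anything random lands on them
    fixed_at: dict[int, tuple[int, int]] = {}
    for idx, spec in enumerate(repeat_specs):
        if len(spec) >= 5:
            fixed_at[idx] = (
                _place_at(int(spec[3]) - 1, int(spec[0])),
                _place_at(int(spec[4]) - 1, int(spec[0])),
            )

    features: list[GeneFeature] = []
    for cls in ("rRNA", "CDS", "intron", "tRNA"):
        lo, hi = gene_length[cls]
        for i in range(n_genes.get(cls, 0)):
            span = int(rng.integers(lo, hi + 1))
            s = _place(span)
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(
                GeneFeature(f"{cls}_{i + 1}", cls, s + 1, s + span, strand)
            )

    repeats: list[RepeatPair] = []
    for idx, spec in enumerate(repeat_specs):
        rlen, identity, orientation = int(spec[0]), spec[1], spec[2]
        if orientation not in ("direct", "inverted"):
            raise ParameterError(f"repeat orientation {orientation!r}")
        if idx in fixed_at:
            s1, s2 = fixed_at[idx]
        else:
            s1 = _place(rlen)
            s2 = _place(rlen)
        if s2 < s1:
            s1, s2 = s2, s1
        unit = _random_seq(rng, rlen)
        seq[s1 : s1 + rlen] = unit
        n_diff = int(round((1.0 - identity / 100.0) * rlen))
        copy2 = unit.copy()
        if n_diff > 0:
            pos = rng.choice(rlen, size=n_diff, replace=False)
            copy2[pos] = (copy2[pos] + rng.integers(1, 4, size=n_diff)) % 4
        inverted = orientation == "inverted"
        if inverted:
            copy2 = _COMP_CODE[copy2][::-1]
        seq[s2 : s2 + rlen] = copy2
        repeats.append(
            RepeatPair(
                name=f"R{idx + 1}",
                copy1=(s1 + 1, s1 + rlen),
                copy2=(s2 + 1, s2 + rlen),
                inverted=inverted,
                percent_identity=float(identity),
                length=rlen,
            )
        )

    genome = OrganelleGenome("synth", decode_seq(seq), circular=True)
    return genome, features, repeats


# ---------------------------------------------------------------------------
# Duplex family simulation


@dataclass
class MutationModel:
    """Per-site, per-molecule mutation probabilities.

    Defaults sit in the regime of wild-type plant organellar genomes
    (overall SNV frequency of order 1e-7 per molecule-base, transition
    dominated); every field is a dial for planting stronger effects.
    """

    base_rate_per_class: dict[str, float] = field(
        default_factory=lambda: {
            "C>A": 1e-8,
            "C>G": 1e-8,
            "C>T": 1e-7,
            "T>A": 1e-8,
            "T>C": 3e-8,
            "T>G": 1e-8,
        }
    )
    context_multiplier: dict[tuple[str, str, str], float] = field(default_factory=dict)
    template_strand_bias: float = 1.0
    indel_rate: float = 2e-8
    dinucleotide_rate: float = 1e-9

    def validate(self, molecule_length: int) -> None:
        for cls, r in self.base_rate_per_class.items():
            if cls not in CLASSES or not 0 <= r <= 1:
                raise ParameterError(f"bad rate for class {cls}: {r}")
        if self.template_strand_bias < 0:
            raise ParameterError("template_strand_bias must be >= 0")
        for p in (self.indel_rate, self.dinucleotide_rate):
            if not 0 <= p <= 1:
                raise ParameterError("indel/dinucleotide rate outside [0, 1]")
        expected = molecule_length * (
            max(self.base_rate_per_class.values(), default=0.0)
            * max(1.0, self.template_strand_bias)
            * max([1.0, *self.context_multiplier.values()])
            + self.indel_rate
            + self.dinucleotide_rate
        )
        if expected >= 0.1 * molecule_length:
            raise ParameterError("model outside the sparse-mutation regime")


def site_rate_table(
    genome: OrganelleGenome,
    region_index: RegionIndex | None,
    model: MutationModel,
) -> np.ndarray:
    """Per-position, per-alternative mutation rates, shape (L, 3).

    Column j is the rate of the j-th alternative of the site's pyrimidine
    class triplet (C sites: C>A, C>G, C>T; T sites: T>A, T>C, T>G), after
    applying context multipliers and the template-strand bias.  N-context
    sites get rate 0.
    """
    L = genome.length
    codes = encode_seq(genome.sequence)
    pyr_minus = (codes == 0) | (codes == 2)  # A or G: pyrimidine on minus strand
    pyr_base_is_c = (codes == 1) | (codes == 2)  # C or G sites
    five = np.empty(L, dtype=np.uint8)
    three = np.empty(L, dtype=np.uint8)
    left = np.roll(codes, 1)
    right = np.roll(codes, -1)
    # pyrimidine-strand flanks: plus strand reads (left, right); minus strand
    # reads (comp(right), comp(left))
    five[~pyr_minus] = left[~pyr_minus]
    three[~pyr_minus] = right[~pyr_minus]
    five[pyr_minus] = _COMP_CODE[right[pyr_minus]]
    three[pyr_minus] = _COMP_CODE[left[pyr_minus]]

    # context multiplier lookup M[class, five, three]
    M = np.ones((6, 5, 5), dtype=float)
    for (cls, f5, t3), mult in model.context_multiplier.items():
        if mult < 0:
            raise ParameterError("context multiplier must be >= 0")
        M[CLASSES.index(cls), _CODE[f5], _CODE[t3]] = mult

    rates = np.zeros((L, 3), dtype=float)
    cls_base = np.where(pyr_base_is_c, 0, 3)  # offset into CLASSES
    base_rates = np.array([model.base_rate_per_class.get(c, 0.0) for c in CLASSES])
    for j in range(3):
        cls_idx = cls_base + j
        rates[:, j] = base_rates[cls_idx] * M[cls_idx, five, three]
    rates[codes == 4] = 0.0
    usable = (left != 4) & (right != 4)
    rates[~usable] = 0.0

    b = model.template_strand_bias
    if region_index is not None and b != 1.0:
        sc = region_index.strand
        # template strand is the opposite of the feature (sense) strand
        on_template = ((sc == 1) & pyr_minus) | ((sc == 2) & ~pyr_minus)
        rates[on_template] *= b
    return rates


def _pyr_event(codes: np.ndarray, pos: int, j: int) -> tuple[str, str, str]:
    """(ref, alt, pyrimidine strand) for alternative j at genome position pos."""
    ref_code = int(codes[pos])
    ref = _BASES[ref_code]
    pyr_minus = ref in "AG"
    pyr = "C" if ref in "CG" else "T"
    alts = {"C": "AGT", "T": "ACG"}[pyr]
    alt_pyr = alts[j]
    alt = revcomp(alt_pyr) if pyr_minus else alt_pyr
    return ref, alt, "-" if pyr_minus else "+"


@dataclass
class DuplexReadSet:
    """A set of simulated duplex families in sparse representation.

    ``starts`` are 0-based molecule start positions (modular on the circular
    genome), all molecules share ``insert_length``; ``diffs`` holds one row
    per (read, differing position) with columns mol, strand (0=A, 1=B),
    read, pos (0-based genome), vtype, ref, alt.
    """

    genome: OrganelleGenome
    starts: np.ndarray
    insert_length: int
    reads_per_strand: int
    diffs: pd.DataFrame

    @property
    def n_molecules(self) -> int:
        return len(self.starts)

    @property
    def duplex_bases(self) -> int:
        return self.n_molecules * self.insert_length

    def tag(self, mol: int) -> str:
        return f"M{mol:07d}"

    def to_tagged_reads(self):
        """Materialize per-read objects for the family-level API."""
        from .duplexcall import TaggedRead

        per_read: dict[tuple[int, int, int], list] = {}
        for row in self.diffs.itertuples(index=False):
            per_read.setdefault((row.mol, row.strand, row.read), []).append(
                (int(row.pos), row.vtype, row.ref, row.alt)
            )
        reads = []
        for mol in range(self.n_molecules):
            for strand in (0, 1):
                for r in range(self.reads_per_strand):
                    diffs = tuple(sorted(per_read.get((mol, strand, r), [])))
                    reads.append(
                        TaggedRead(
                            tag=self.tag(mol),
                            strand_family="AB"[strand],
                            start=int(self.starts[mol]),
                            length=self.insert_length,
                            diffs=diffs,
                        )
                    )
        return reads

    def read_sequence(self, mol: int, strand: int, read: int) -> str:
        """Reconstruct the full base string of one read (small runs only)."""
        L = self.genome.length
        s = int(self.starts[mol])
        idx = (np.arange(self.insert_length) + s) % L
        seq = list(self.genome.sequence[i] for i in idx)
        sel = self.diffs[
            (self.diffs.mol == mol)
            & (self.diffs.strand == strand)
            & (self.diffs.read == read)
        ]
        # apply substitutions first, then indels right-to-left
        offsets = ((sel.pos.to_numpy() - s) % L).astype(int)
        order = np.argsort(-offsets)
        for k in order:
            row = sel.iloc[int(k)]
            o = int(offsets[int(k)])
            if row.vtype == "SNV":
                seq[o] = row.alt
            elif row.vtype == "deletion":
                del seq[o]
            elif row.vtype == "insertion":
                seq.insert(o + 1, row.alt)
        return "".join(seq)

    def write_fastq(self, path_a, path_b) -> None:
        """Emit the two strand-family read files (tag embedded in names)."""
        with open(path_a, "w") as fa, open(path_b, "w") as fb:
            for mol in range(self.n_molecules):
                for strand, fh in ((0, fa), (1, fb)):
                    for r in range(self.reads_per_strand):
                        seq = self.read_sequence(mol, strand, r)
                        name = (
                            f"@{self.tag(mol)}:{'AB'[strand]}:{r} "
                            f"start={int(self.starts[mol]) + 1}"
                        )
                        fh.write(f"{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_duplex_families(
    genome: OrganelleGenome,
    features: list[GeneFeature] | None,
    model: MutationModel,
    n_molecules: int,
    reads_per_strand: int = 3,
    insert_length: int = 300,
    seq_error: float = 0.0,
    seed: int | np.random.Generator = 0,
    region_index: RegionIndex | None = None,
) -> tuple[DuplexReadSet, list[TruthRecord]]:
    """Simulate tagged duplex families with planted mutations.

    Each molecule yields two strand-families sharing a tag; planted mutations
    appear on all reads of both families, sequencing errors are i.i.d. per
    read.  Returns the read set and one exhaustive truth record per molecule.
    """
    if reads_per_strand < 1:
        raise ParameterError("reads_per_strand must be >= 1")
    if insert_length >= genome.length:
        raise ParameterError("insert_length must be below genome length")
    if not 0 <= seq_error <= 1:
        raise ParameterError("seq_error outside [0, 1]")
    model.validate(insert_length)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if region_index is None and features:
        region_index = RegionIndex(genome, features)

    L = genome.length
    codes = encode_seq(genome.sequence)
    rates = site_rate_table(genome, region_index, model)
    total = rates.sum(axis=1)
    cum2 = np.concatenate([[0.0], np.cumsum(np.tile(total, 2))])

    starts = rng.integers(0, L, size=n_molecules, dtype=np.int64)
    lam = cum2[starts + insert_length] - cum2[starts]
    n_events = rng.poisson(lam)

    truths = [TruthRecord(f"M{m:07d}") for m in range(n_molecules)]
    rows: list[tuple] = []  # (mol, strand, read, pos, vtype, ref, alt)
    n_reads = reads_per_strand
    used_positions: dict[int, set[int]] = {}  # one planted event per site/molecule

    def plant(mol: int, pos: int, vtype: str, ref: str, alt: str):
        for strand in (0, 1):
            for r in range(n_reads):
                rows.append((mol, strand, r, pos, vtype, ref, alt))

    # --- substitutions, rate-weighted positions within each molecule
    for mol in np.nonzero(n_events)[0]:
        s = int(starts[mol])
        lo, hi = cum2[s], cum2[s + insert_length]
        used = used_positions.setdefault(int(mol), set())
        for _ in range(int(n_events[mol])):
            u = rng.uniform(lo, hi)
            q = int(np.searchsorted(cum2, u, side="right") - 1)
            pos = q % L
            if pos in used:
                continue
            used.add(pos)
            w = rates[pos]
            j = int(rng.choice(3, p=w / w.sum()))
            ref, alt, pyr_strand = _pyr_event(codes, pos, j)
            plant(int(mol), pos, "SNV", ref, alt)
            truths[mol].events.append(
                TruthEvent(pos + 1, "SNV", ref, alt, pyr_strand)
            )

    # --- indels and dinucleotides (uniform placement)
    for vkind, rate in (("indel", model.indel_rate), ("dinuc", model.dinucleotide_rate)):
        if rate <= 0:
            continue
        counts = rng.binomial(insert_length - 1, rate, size=n_molecules)
        for mol in np.nonzero(counts)[0]:
            s = int(starts[mol])
            used = used_positions.setdefault(int(mol), set())
            for _ in range(int(counts[mol])):
                off = int(rng.integers(1, insert_length - 1))
                pos = (s + off) % L
                pos_next = (pos + 1) % L
                if pos in used or (vkind == "dinuc" and pos_next in used):
                    continue
                used.add(pos)
                if vkind == "dinuc":
                    used.add(pos_next)
                ref = _BASES[codes[pos]] if codes[pos] < 4 else "N"
                if vkind == "indel":
                    if rng.random() < 0.5:
                        ins = _BASES[int(rng.integers(0, 4))]
                        plant(int(mol), pos, "insertion", "", ins)
                        truths[mol].events.append(
                            TruthEvent(pos + 1, "insertion", "", ins)
                        )
                    else:
                        plant(int(mol), pos, "deletion", ref, "")
                        truths[mol].events.append(
                            TruthEvent(pos + 1, "deletion", ref, "")
                        )
                else:
                    pos2 = (pos + 1) % L
                    ref2 = _BASES[codes[pos2]] if codes[pos2] < 4 else "N"
                    alt1 = _BASES[(codes[pos] + int(rng.integers(1, 4))) % 4]
                    alt2 = _BASES[(codes[pos2] + int(rng.integers(1, 4))) % 4]
                    plant(int(mol), pos, "SNV", ref, alt1)
                    plant(int(mol), pos2, "SNV", ref2, alt2)
                    truths[mol].events.append(
                        TruthEvent(pos + 1, "dinucleotide", ref + ref2, alt1 + alt2)
                    )

    # --- i.i.d. sequencing errors, per read
    if seq_error > 0:
        n_total_reads = n_molecules * 2 * n_reads
        err_counts = rng.binomial(insert_length, seq_error, size=n_total_reads)
        for ridx in np.nonzero(err_counts)[0]:
            mol, rem = divmod(int(ridx), 2 * n_reads)
            strand, r = divmod(rem, n_reads)
            s = int(starts[mol])
            for _ in range(int(err_counts[ridx])):
                off = int(rng.integers(0, insert_length))
                pos = (s + off) % L
                ref = _BASES[codes[pos]] if codes[pos] < 4 else "N"
                alt = _BASES[(codes[pos] + int(rng.integers(1, 4))) % 4]
                rows.append((mol, strand, r, pos, "SNV", ref, alt))

    diffs = pd.DataFrame(
        rows, columns=["mol", "strand", "read", "pos", "vtype", "ref", "alt"]
    )
    if len(diffs):
        # a planted diff takes precedence over an error at the same read/pos
        diffs = diffs.drop_duplicates(
            subset=["mol", "strand", "read", "pos"], keep="first"
        ).reset_index(drop=True)
    readset = DuplexReadSet(genome, starts, insert_length, n_reads, diffs)
    return readset, truths


def make_numt_fixture(
    genome: OrganelleGenome,
    numt_interval: tuple[int, int],
    n_paralog_variants: int = 10,
    nuclear_pad: int = 5_000,
    seed: int | np.random.Generator = 0,
) -> tuple[str, list[TruthEvent]]:
    """Build a synthetic nuclear sequence containing a diverged organellar copy.

    Returns the nuclear sequence (random DNA with an embedded copy of the
    organellar interval carrying ``n_paralog_variants`` substitutions) and the
    paralogous variants in organellar coordinates.  Reads derived from this
    insertion mimic NUMT/NUPT contamination: they carry the paralog alleles
    and their local haplotype matches the nuclear genome exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a, b = numt_interval
    segment = encode_seq(genome.sequence[a - 1 : b])
    span = len(segment)
    if n_paralog_variants > span:
        raise ParameterError("more paralog variants than segment positions")
    pos = np.sort(rng.choice(span, size=n_paralog_variants, replace=False))
    variants = []
    for p in pos:
        ref = _BASES[segment[p]]
        segment[p] = (segment[p] + int(rng.integers(1, 4))) % 4
        variants.append(TruthEvent(a + int(p), "SNV", ref, _BASES[segment[p]]))
    left = decode_seq(_random_seq(rng, nuclear_pad))
    right = decode_seq(_random_seq(rng, nuclear_pad))
    nuclear = left + decode_seq(segment) + right
    return nuclear, variants


def simulate_numt_families(
    genome: OrganelleGenome,
    numt_interval: tuple[int, int],
    paralog_variants: list[TruthEvent],
    n_molecules: int,
    reads_per_strand: int = 3,
    insert_length: int = 300,
    seed: int | np.random.Generator = 0,
) -> DuplexReadSet:
    """Simulate duplex families from the nuclear paralog, mapped onto the
    organellar reference (so they carry all overlapping paralog alleles)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a, b = numt_interval
    if b - a + 1 <= insert_length:
        raise ParameterError("NUMT interval shorter than insert length")
    starts = rng.integers(a - 1, b - insert_length, size=n_molecules, dtype=np.int64)
    rows = []
    for mol, s in enumerate(starts):
        for ev in paralog_variants:
            if s < ev.position - 1 < s + insert_length:
                for strand in (0, 1):
                    for r in range(reads_per_strand):
                        rows.append(
                            (mol, strand, r, ev.position - 1, "SNV", ev.ref, ev.alt)
                        )
    diffs = pd.DataFrame(
        rows, columns=["mol", "strand", "read", "pos", "vtype", "ref", "alt"]
    )
    return DuplexReadSet(genome, starts, insert_length, reads_per_strand, diffs)


# ---------------------------------------------------------------------------
# Long-read simulation


@dataclass
class LongReadModel:
    """Nanopore-like long reads over a genome with recombining repeats.

    Read lengths are lognormal (``mu``/``sigma`` on the log scale) truncated
    at ``min_length``; a read whose source molecule spans a repeat copy is
    recombinant with the per-repeat probability; errors are i.i.d.
    substitutions/indels (no homopolymer bias — downstream classification
    depends on alignment geometry, not base accuracy).
    """

    n_reads: int = 1000
    mu: float = np.log(2500.0)
    sigma: float = 0.45
    min_length: int = 200
    per_repeat_recomb_freq: dict[str, float] = field(default_factory=dict)
    error_rate: float = 0.0
    circular_fraction: float = 0.5  # direct-repeat products: circular vs deletion
    span_margin: int = 100  # flank a molecule must cover to "span" a copy
    seed: int = 0

    def validate(self, repeats: list[RepeatPair]) -> None:
        if not 0 <= self.error_rate <= 0.3:
            raise ParameterError("error_rate outside [0, 0.3]")
        by_name = {rp.name: rp for rp in repeats}
        for name, f in self.per_repeat_recomb_freq.items():
            if name not in by_name:
                raise ParameterError(f"unknown repeat {name!r}")
            if not 0 <= f <= 1:
                raise ParameterError(f"recombination frequency {f} outside [0, 1]")
            if f > 0 and by_name[name].length < 2:
                raise ParameterError(f"repeat {name} too short to recombine")


@dataclass
class LongRead:
    name: str
    sequence: str


def _apply_long_read_errors(codes: np.ndarray, rate: float, rng) -> np.ndarray:
    """i.i.d. substitution (50%), insertion (25%), deletion (25%) errors."""
    if rate <= 0:
        return codes
    n = len(codes)
    n_err = rng.binomial(n, rate)
    if n_err == 0:
        return codes
    pos = np.sort(rng.choice(n, size=n_err, replace=False))
    kinds = rng.random(n_err)
    out = []
    prev = 0
    for p, k in zip(pos, kinds):
        out.append(codes[prev:p])
        if k < 0.5:  # substitution
            out.append(np.array([(codes[p] + rng.integers(1, 4)) % 4], dtype=np.uint8))
            prev = p + 1
        elif k < 0.75:  # insertion before p
            out.append(np.array([rng.integers(0, 4)], dtype=np.uint8))
            prev = p
        else:  # deletion of p
            prev = p + 1
    out.append(codes[prev:])
    return np.concatenate(out)


def simulate_long_reads(
    genome: OrganelleGenome,
    repeats: list[RepeatPair],
    model: LongReadModel,
) -> tuple[list[LongRead], list[TruthRecord]]:
    """Simulate long reads whose molecules recombined at planted repeats.

    Inverted-repeat recombinants switch strand at a crossover point uniform
    within the repeat; direct-repeat recombinants are deletion-type or
    circular/tandem-type per ``circular_fraction``.  Read start positions are
    drawn so reads do not cross the circular origin (the classifier treats
    the genome linearly).  Every read has a truth record.
    """
    model.validate(repeats)
    rng = np.random.default_rng(model.seed)
    L = genome.length
    codes = encode_seq(genome.sequence)
    active = [
        (rp, model.per_repeat_recomb_freq[rp.name])
        for rp in repeats
        if model.per_repeat_recomb_freq.get(rp.name, 0.0) > 0.0
    ]

    reads: list[LongRead] = []
    truths: list[TruthRecord] = []
    lengths = np.exp(rng.normal(model.mu, model.sigma, size=model.n_reads))
    lengths = np.maximum(lengths.astype(int), model.min_length)
    lengths = np.minimum(lengths, L - 1)
    for i in range(model.n_reads):
        ell = int(lengths[i])
        s = int(rng.integers(0, L - ell))
        truth = TruthRecord(f"LR{i:06d}")
        seq = None
        # every repeat whose copy the molecule spans gets one Bernoulli(f)
        # trial, in genomic order; the first success sets the read geometry
        candidates = []
        m = model.span_margin
        for rp, f in active:
            for copy in (rp.copy1, rp.copy2):
                a, b = copy[0] - 1, copy[1]  # 0-based half-open
                if s <= a - m and b + m <= s + ell:
                    candidates.append((a, b, rp, f, copy))
        candidates.sort(key=lambda t: t[0])
        tried: set[str] = set()
        for a, b, rp, f, copy in candidates:
            if rp.name in tried:
                continue  # one trial per repeat even if both copies are spanned
            tried.add(rp.name)
            if rng.random() < f:
                seq = _recombinant_read(codes, s, ell, rp, copy, rng, model)
                geometry = (
                    "inverted"
                    if rp.inverted
                    else ("circular" if seq[1] else "deletion")
                )
                ev = TruthEvent(a + 1, "recombination", "", geometry, "+", rp.name)
                truth.events.append(ev)
                seq = seq[0]
                break
        if seq is None:
            seq = codes[s : s + ell]
        seq = _apply_long_read_errors(seq, model.error_rate, rng)
        reads.append(LongRead(truth.molecule_id, decode_seq(seq)))
        truths.append(truth)
    return reads, truths


def _recombinant_read(
    codes: np.ndarray,
    s: int,
    ell: int,
    rp: RepeatPair,
    copy: tuple[int, int],
    rng,
    model: LongReadModel,
) -> tuple[np.ndarray, bool]:
    """Build one recombinant read; returns (sequence, is_circular_type)."""
    rlen = rp.length
    a1, a2 = rp.copy1[0] - 1, rp.copy2[0] - 1
    ca = copy[0] - 1  # encountered copy start (0-based)
    o = int(rng.integers(1, rlen))  # crossover offset within the repeat
    x = ca + o  # first base after the crossover switches template
    if rp.inverted:
        # continue on the opposite strand: pair copy offset o with the
        # mirrored position in the other copy
        other = a2 if ca == a1 else a1
        y = other + (rlen - o)  # exclusive end of the revcomp segment
        left = codes[s:x]
        rem = ell - len(left)
        lo = max(0, y - rem)
        right = _COMP_CODE[codes[lo:y]][::-1]
        return np.concatenate([left, right]), False
    # direct repeat
    d = abs(a2 - a1)
    m = model.span_margin
    want_circular = rng.random() < model.circular_fraction
    ell_c = min(ell, d)
    # the junction of the excised circle is seamless while inside the hybrid
    # repeat copy, so a detectable read must clear both repeat edges at the
    # junction by the span margin; molecules too short for that fall back to
    # the deletion-type product
    seg_lo, seg_hi = o + m, ell_c - (rlen - o) - m
    if want_circular and d >= rlen + 2 * m + 2 and seg_hi >= seg_lo and seg_lo < d:
        lo = min(a1, a2) + o
        circle = np.take(codes, (lo + np.arange(d)) % len(codes), mode="wrap")
        seg1 = int(rng.integers(seg_lo, min(seg_hi, d - 1) + 1))
        phi = d - seg1
        idx = (phi + np.arange(ell_c)) % d
        return circle[idx], True
    # deletion-type: skip from the crossover in the left copy to the
    # equivalent point in the right copy
    lo_copy = min(a1, a2)
    x = lo_copy + o
    left = codes[s:x] if s < x else codes[max(0, x - ell // 2) : x]
    rem = ell - len(left)
    right = codes[x + d : x + d + rem]
    return np.concatenate([left, right]), False


def write_long_reads_fastq(reads: list[LongRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_long_reads_fasta(reads: list[LongRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.name}\n{r.sequence}\n")


def write_truth_tsv(truths: list[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("molecule\tposition\ttype\tref\talt\tstrand\trepeat\n")
        for t in truths:
            for e in t.events:
                fh.write(
                    f"{t.molecule_id}\t{e.position}\t{e.etype}\t{e.ref}\t{e.alt}\t"
                    f"{e.strand_of_placement}\t{e.repeat or '.'}\n"
                )
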