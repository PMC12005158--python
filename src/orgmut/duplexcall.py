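"""Duplex consensus building, variant calling, NUMT filtering, coverage.

Duplex sequencing tags both strands of each source molecule, so reads group
into two strand-families per molecule.  A base is accepted into the duplex
consensus only when both strand-family consensuses agree; everything else is
an ``N``, never a guessed base.  This double-strand requirement is what
suppresses sequencing errors and single-strand damage, and the module
enforces it in two equivalent code paths:

* a per-family object API (:func:`group_families`, :func:`build_consensus`,
  :func:`call_variants`) mirroring how one thinks about a single molecule;
* a vectorized bulk path (:func:`duplex_pipeline`) over a
  :class:`~orgmut.synth.DuplexReadSet`, used for simulations covering 1e8+
  duplex bases.

Reads are carried in a sparse representation: mapped interval plus the list
of differences from the reference.  Positions without a recorded difference
are reference-equal by construction.

Variant calls are annotated with region class, gene strand, and the
trinucleotide context on the strand of the pyrimidine, and pass through two
filters: an end-trim (consensus termini are conventionally distrusted) and a
NUMT/NUPT filter that discards calls whose local alternate haplotype occurs
in the nuclear genome.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

import edlib
import numpy as np
import pandas as pd

from .orgmodel import OrganelleGenome, RegionIndex, revcomp
from .synth import DuplexReadSet, encode_seq

logger = logging.getLogger("orgmut")

PASS, NUMT, END_TRIMMED = "pass", "numt", "end_trimmed"


@dataclass(frozen=True)
class TaggedRead:
    """One aligned read in sparse-difference form.

    ``diffs`` is a tuple of (pos0, vtype, ref, alt) with 0-based genome
    positions; vtype in {SNV, insertion, deletion}.
    """

    tag: str
    strand_family: str  # "A" or "B"
    start: int  # 0-based mapped start
    length: int
    diffs: tuple = ()


@dataclass
class DuplexFamily:
    tag: str
    strand_a_reads: list[TaggedRead] = field(default_factory=list)
    strand_b_reads: list[TaggedRead] = field(default_factory=list)

    @property
    def duplex_eligible(self) -> bool:
        return bool(self.strand_a_reads) and bool(self.strand_b_reads)


@dataclass
class DuplexConsensus:
    """Double-strand consensus of one molecule.

    ``variants`` maps 0-based genome position -> (vtype, ref, alt) for duplex-
    confirmed differences; ``n_positions`` lists positions that failed
    consensus (reported as N, never a guessed base).
    """

    molecule_id: str
    start: int
    length: int
    variants: dict[int, tuple[str, str, str]]
    n_positions: set[int]
    n_reads_a: int
    n_reads_b: int


@dataclass
class VariantCall:
    position: int  # 1-based reference position
    vtype: str  # SNV | insertion | deletion | dinucleotide
    ref: str
    alt: str
    molecule_id: str
    region: str = "intergenic"
    gene_strand: str | None = None
    context: str | None = None  # trinucleotide on the pyrimidine strand
    pyr_strand: str | None = None
    status: str = PASS


def group_families(
    reads: list[TaggedRead], locus_slop: int = 1000
) -> tuple[list[DuplexFamily], int]:
    """Partition reads into duplex families by tag, splitting multi-locus tags.

    Reads sharing a tag but mapped more than ``locus_slop`` apart form
    separate families (tag collisions / translocated fragments).  Untagged
    reads are rejected and counted.
    """
    by_tag: dict[str, list[TaggedRead]] = defaultdict(list)
    n_rejected = 0
    for r in reads:
        if not r.tag:
            n_rejected += 1
            continue
        by_tag[r.tag].append(r)
    families: list[DuplexFamily] = []
    for tag, group in by_tag.items():
        group.sort(key=lambda r: r.start)
        clusters: list[list[TaggedRead]] = [[group[0]]]
        for r in group[1:]:
            if r.start - clusters[-1][-1].start > locus_slop:
                clusters.append([r])
            else:
                clusters[-1].append(r)
        for i, cluster in enumerate(clusters):
            name = tag if len(clusters) == 1 else f"{tag}.{i + 1}"
            fam = DuplexFamily(name)
            for r in cluster:
                (fam.strand_a_reads if r.strand_family == "A" else fam.strand_b_reads).append(r)
            families.append(fam)
    if n_rejected:
        logger.info("group_families: rejected %d untagged reads", n_rejected)
    return families, n_rejected


def _strand_consensus(
    reads: list[TaggedRead], threshold: float
) -> tuple[dict[int, tuple[str, str, str]], set[int]]:
    """Sparse single-strand consensus: position -> variant, plus N positions."""
    n = len(reads)
    votes: Counter = Counter()
    tot_at_pos: Counter = Counter()
    for r in reads:
        for pos, vtype, ref, alt in r.diffs:
            votes[(pos, vtype, ref, alt)] += 1
            tot_at_pos[pos] += 1
    called: dict[int, tuple[str, str, str]] = {}
    n_pos: set[int] = set()
    need = math.ceil(threshold * n)
    for pos in tot_at_pos:
        best_key, best_votes = None, 0
        for key, v in votes.items():
            if key[0] == pos and v > best_votes:
                best_key, best_votes = key, v
        if best_votes >= need:
            called[pos] = best_key[1:]
        elif n - tot_at_pos[pos] >= need:
            pass  # reference wins
        else:
            n_pos.add(pos)
    return called, n_pos


def build_consensus(
    family: DuplexFamily,
    min_reads_per_strand: int = 3,
    strand_consensus_threshold: float = 0.9,
    genome_length: int | None = None,
) -> DuplexConsensus | None:
    """Collapse a duplex family into its double-strand consensus.

    Per strand, a base is called when at least ``strand_consensus_threshold``
    of reads agree; the duplex base requires both strand consensuses to agree
    and be non-N.  Families with fewer than ``min_reads_per_strand`` reads on
    either strand are rejected (``None``) — a counted outcome, not an error.
    """
    if (
        len(family.strand_a_reads) < min_reads_per_strand
        or len(family.strand_b_reads) < min_reads_per_strand
    ):
        return None
    all_reads = family.strand_a_reads + family.strand_b_reads
    start = max(r.start for r in all_reads)
    end = min(r.start + r.length for r in all_reads)
    if end <= start:
        return None
    cons_a, n_a = _strand_consensus(family.strand_a_reads, strand_consensus_threshold)
    cons_b, n_b = _strand_consensus(family.strand_b_reads, strand_consensus_threshold)
    variants: dict[int, tuple[str, str, str]] = {}
    n_positions = set(n_a) | set(n_b)
    for pos in set(cons_a) | set(cons_b):
        if pos in n_positions:
            continue
        va, vb = cons_a.get(pos), cons_b.get(pos)
        if va is not None and va == vb:
            variants[pos] = va
        else:
            n_positions.add(pos)  # strand disagreement (incl. one-sided)
    if genome_length is not None:
        # diff positions are modular on a circular genome; molecules may wrap
        in_span = lambda p: ((p - start) % genome_length) < (end - start)
    else:
        in_span = lambda p: start <= p < end
    return DuplexConsensus(
        molecule_id=family.tag,
        start=start,
        length=end - start,
        variants={p: v for p, v in variants.items() if in_span(p)},
        n_positions={p for p in n_positions if in_span(p)},
        n_reads_a=len(family.strand_a_reads),
        n_reads_b=len(family.strand_b_reads),
    )


# ---------------------------------------------------------------------------
# Variant calling


def _left_align(genome: OrganelleGenome, pos0: int, vtype: str, allele: str) -> int:
    """Left-align a 1-bp indel on the reference (VCF convention)."""
    if vtype not in ("insertion", "deletion") or not allele:
        return pos0
    L = genome.length
    shifts = 0
    p = pos0
    while shifts < 200 and genome.sequence[(p - 1) % L] == allele:
        p = (p - 1) % L
        shifts += 1
    return p


def _pyrimidine_context(
    genome: OrganelleGenome, pos0: int
) -> tuple[str | None, str | None]:
    """Trinucleotide context on the pyrimidine strand of a site, + strand."""
    L = genome.length
    ref = genome.sequence[pos0]
    if ref == "N":
        return None, None
    left = genome.sequence[(pos0 - 1) % L]
    right = genome.sequence[(pos0 + 1) % L]
    if "N" in (left, right):
        return None, None
    if ref in "CT":
        return left + ref + right, "+"
    return revcomp(left + ref + right), "-"


def finalize_calls(
    rows: list[tuple[str, int, int, int, str, str, str]],
    genome: OrganelleGenome,
    region_index: RegionIndex | None,
    end_trim: int = 10,
) -> list[VariantCall]:
    """Turn raw duplex-consensus differences into annotated variant calls.

    ``rows`` holds (molecule_id, mol_start0, mol_length, pos0, vtype, ref,
    alt).  Applies: end-trim status, adjacent-SNV merging into dinucleotide
    calls, indel left-alignment, and region/strand/context annotation.
    Shared by the per-family and the bulk calling paths.
    """
    L = genome.length
    by_mol: dict[tuple[str, int, int], list] = defaultdict(list)
    for mol, start, length, pos0, vtype, ref, alt in rows:
        by_mol[(mol, start, length)].append((pos0, vtype, ref, alt))
    calls: list[VariantCall] = []
    for (mol, start, length), events in by_mol.items():
        events.sort(key=lambda e: (e[0] - start) % L)
        merged: list[tuple[int, str, str, str]] = []
        i = 0
        while i < len(events):
            pos0, vtype, ref, alt = events[i]
            if (
                vtype == "SNV"
                and i + 1 < len(events)
                and events[i + 1][1] == "SNV"
                and ((events[i + 1][0] - pos0) % L) == 1
            ):
                p2, _, r2, a2 = events[i + 1]
                merged.append((pos0, "dinucleotide", ref + r2, alt + a2))
                i += 2
                continue
            merged.append((pos0, vtype, ref, alt))
            i += 1
        for pos0, vtype, ref, alt in merged:
            off = (pos0 - start) % L
            status = PASS
            if off < end_trim or off >= length - end_trim:
                status = END_TRIMMED
            if vtype == "deletion":
                pos0 = _left_align(genome, pos0, vtype, ref)
            elif vtype == "insertion":
                pos0 = _left_align(genome, pos0, vtype, alt)
            region, gstrand = "intergenic", None
            if region_index is not None:
                region = region_index.region_of(pos0 + 1)
                gstrand = region_index.strand_of(pos0 + 1)
            ctx = pyr = None
            if vtype == "SNV":
                ctx, pyr = _pyrimidine_context(genome, pos0)
            calls.append(
                VariantCall(
                    position=pos0 + 1,
                    vtype=vtype,
                    ref=ref,
                    alt=alt,
                    molecule_id=mol,
                    region=region,
                    gene_strand=gstrand,
                    context=ctx,
                    pyr_strand=pyr,
                    status=status,
                )
            )
    calls.sort(key=lambda c: (c.position, c.molecule_id))
    return calls


def call_variants(
    consensus: DuplexConsensus,
    genome: OrganelleGenome,
    region_index: RegionIndex | None = None,
    end_trim: int = 10,
) -> list[VariantCall]:
    """Call SNVs/indels/dinucleotides from one duplex consensus."""
    rows = [
        (consensus.molecule_id, consensus.start, consensus.length, pos0, vtype, ref, alt)
        for pos0, (vtype, ref, alt) in consensus.variants.items()
    ]
    return finalize_calls(rows, genome, region_index, end_trim)


# ---------------------------------------------------------------------------
# NUMT / NUPT filter


def _consensus_haplotype(
    genome: OrganelleGenome,
    mol_variants: list[tuple[int, str, str, str]],
    pos0: int,
    k_flank: int,
    mol_start: int,
    mol_length: int,
) -> tuple[str, int]:
    """Alternate-allele haplotype window around a call.

    Returns (window sequence with all of the molecule's duplex variants
    applied, full untruncated window length).  The window is clipped to the
    molecule's extent, so edge calls yield shorter windows.
    """
    L = genome.length
    off = (pos0 - mol_start) % L
    lo_off = max(0, off - k_flank)
    hi_off = min(mol_length, off + k_flank + 1)
    idx = [(mol_start + o) % L for o in range(lo_off, hi_off)]
    seq = [genome.sequence[i] for i in idx]
    pos_to_i = {p: i for i, p in enumerate(idx)}
    for vpos, vtype, ref, alt in sorted(
        mol_variants, key=lambda v: -((v[0] - mol_start) % L)
    ):
        i = pos_to_i.get(vpos % L)
        if i is None:
            continue
        if vtype == "SNV":
            seq[i] = alt
        elif vtype == "deletion":
            del seq[i]
        elif vtype == "insertion":
            seq.insert(i + 1, alt)
    return "".join(seq), 2 * k_flank + 1


def numt_filter(
    call: VariantCall,
    mol_variants: list[tuple[int, str, str, str]],
    genome: OrganelleGenome,
    nuclear_seqs: list[str],
    k_flank: int = 20,
    max_mismatch: int = 0,
    mol_start: int = 0,
    mol_length: int | None = None,
) -> str:
    """Return ``numt`` if the call's alternate haplotype occurs in the nuclear
    genome (either strand) within ``max_mismatch`` edits, else ``pass``.

    The haplotype window spans ``k_flank`` bases each side of the variant and
    includes the alternate allele plus any other duplex-confirmed variants of
    the same molecule.  Windows truncated by the molecule end scale the edit
    allowance proportionally.
    """
    if mol_length is None:
        mol_length = genome.length
    window, full_len = _consensus_haplotype(
        genome, mol_variants, call.position - 1, k_flank, mol_start, mol_length
    )
    if not window:
        return PASS
    allowed = int(math.floor(max_mismatch * len(window) / full_len))
    for nuc in nuclear_seqs:
        for target in (nuc, revcomp(nuc)):
            if allowed == 0:
                if window in target:
                    return NUMT
            else:
                res = edlib.align(window, target, mode="HW", task="distance", k=allowed)
                if res["editDistance"] != -1:
                    return NUMT
    return PASS


# ---------------------------------------------------------------------------
# Coverage


class CoverageProfile:
    """Per-position duplex depth with region/strand/context stratification.

    Depth counts pass-filter consensus molecules overlapping each position,
    with ``end_trim`` bases removed from each molecule end so the denominator
    covers exactly the bases on which variants could have been called.
    Context and strand stratifications are derived lazily from the genome:
    the trinucleotide context of a position is a property of the reference,
    so context-stratified coverage is a masked sum over the depth vector.
    """

    def __init__(
        self,
        genome: OrganelleGenome,
        depth: np.ndarray,
        region_index: RegionIndex | None = None,
    ):
        if len(depth) != genome.length:
            raise ValueError("depth vector length != genome length")
        if (depth < 0).any():
            raise ValueError("negative depth")
        self.genome = genome
        self.depth = depth.astype(np.int64)
        self.region_index = region_index
        self._ctx_cache: dict[str, np.ndarray] = {}

    @classmethod
    def from_molecules(
        cls,
        genome: OrganelleGenome,
        starts: np.ndarray,
        lengths: np.ndarray | int,
        end_trim: int = 0,
        region_index: RegionIndex | None = None,
    ) -> "CoverageProfile":
        L = genome.length
        starts = np.asarray(starts, dtype=np.int64)
        lengths = np.broadcast_to(np.asarray(lengths, dtype=np.int64), starts.shape)
        eff = lengths - 2 * end_trim
        keep = eff > 0
        s = (starts[keep] + end_trim) % L
        e = s + eff[keep]
        delta = np.zeros(2 * L + 1, dtype=np.int64)
        np.add.at(delta, s, 1)
        np.add.at(delta, np.minimum(e, 2 * L), -1)
        unrolled = np.cumsum(delta[:-1])
        depth = unrolled[:L] + unrolled[L:]
        return cls(genome, depth, region_index)

    def total(self) -> int:
        return int(self.depth.sum())

    def region_coverage(self) -> dict[str, int]:
        from .orgmodel import REGION_CLASSES

        if self.region_index is None:
            raise ValueError("CoverageProfile built without a region index")
        return {
            name: int(self.depth[self.region_index.region == code].sum())
            for code, name in enumerate(REGION_CLASSES)
        }

    def _context_codes(self) -> np.ndarray:
        """Per-position pyrimidine-strand context id (0..31) or -1 for N."""
        if "ctx" in self._ctx_cache:
            return self._ctx_cache["ctx"]
        codes = encode_seq(self.genome.sequence)
        L = len(codes)
        left, right = np.roll(codes, 1), np.roll(codes, -1)
        comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
        pyr_minus = (codes == 0) | (codes == 2)
        center_is_c = (codes == 1) | (codes == 2)
        five = np.where(pyr_minus, comp[right], left)
        three = np.where(pyr_minus, comp[left], right)
        ctx = np.where(
            (codes == 4) | (five == 4) | (three == 4),
            -1,
            five.astype(np.int64) * 8 + center_is_c.astype(np.int64) * 4 + three,
        )
        self._ctx_cache["ctx"] = ctx
        return ctx

    @staticmethod
    def context_id(context: str) -> int:
        """Context string on the pyrimidine strand -> id used internally."""
        f, c, t = context
        return "ACGT".index(f) * 8 + (4 if c == "C" else 0) + "ACGT".index(t)

    def context_coverage(self, center: str) -> dict[str, int]:
        """Duplex depth per trinucleotide context with the given pyrimidine
        center (16 contexts), measured on the strand of the pyrimidine."""
        if center not in "CT":
            raise ValueError("center must be the pyrimidine C or T")
        ctx = self._context_codes()
        out = {}
        for f in "ACGT":
            for t in "ACGT":
                name = f + center + t
                out[name] = int(self.depth[ctx == self.context_id(name)].sum())
        return out

    def strand_base_coverage(self) -> pd.DataFrame:
        """Genic coverage of each pyrimidine, split by template placement.

        One row per (region, pyrimidine base, on_template); ``on_template``
        is True where the strand carrying the pyrimidine is the template
        (RNA-polymerase-read) strand of the containing gene.  Dual-strand
        sites are excluded.
        """
        from .orgmodel import REGION_CLASSES

        if self.region_index is None:
            raise ValueError("CoverageProfile built without a region index")
        codes = encode_seq(self.genome.sequence)
        pyr_minus = (codes == 0) | (codes == 2)
        base_c = (codes == 1) | (codes == 2)
        sc = self.region_index.strand
        rows = []
        for rc, region in enumerate(REGION_CLASSES):
            if region == "intergenic":
                continue
            in_region = self.region_index.region == rc
            for strand_code in (1, 2):
                sense_plus = strand_code == 1
                sel = in_region & (sc == strand_code)
                # template strand is opposite the sense strand
                on_template = pyr_minus if sense_plus else ~pyr_minus
                for pyr, base_mask in (("C", base_c), ("T", ~base_c)):
                    for tmpl in (True, False):
                        mask = sel & base_mask & (on_template == tmpl)
                        rows.append(
                            {
                                "region": region,
                                "pyrimidine": pyr,
                                "on_template": tmpl,
                                "coverage": int(self.depth[mask & (codes != 4)].sum()),
                            }
                        )
        df = pd.DataFrame(rows)
        return df.groupby(["region", "pyrimidine", "on_template"], as_index=False)[
            "coverage"
        ].sum()


def variant_frequency(
    calls: list[VariantCall],
    cov: CoverageProfile,
    vtype: str = "SNV",
    include_dinucleotide: bool = False,
) -> float:
    """Pass-filter variant frequency per duplex molecule-base.

    ``frequency = count(pass calls of vtype) / total duplex coverage``.
    Dinucleotide calls are excluded from the SNV numerator by default (they
    are reported separately).
    """
    total = cov.total()
    if total <= 0:
        raise ZeroDivisionError("zero total duplex coverage: frequency undefined")
    n = sum(
        1
        for c in calls
        if c.status == PASS
        and (
            c.vtype == vtype
            or (include_dinucleotide and vtype == "SNV" and c.vtype == "dinucleotide")
        )
    )
    return n / total


# ---------------------------------------------------------------------------
# Bulk pipeline over a DuplexReadSet


@dataclass
class DuplexCallParams:
    min_reads_per_strand: int = 3
    strand_consensus_threshold: float = 0.9
    end_trim: int = 10
    numt_k_flank: int = 20
    numt_max_mismatch: int = 0


@dataclass
class DuplexCallResult:
    calls: list[VariantCall]
    coverage: CoverageProfile
    n_molecules_pass: int
    n_molecules_rejected: int


def duplex_pipeline(
    readset: DuplexReadSet,
    region_index: RegionIndex | None = None,
    params: DuplexCallParams | None = None,
    nuclear_seqs: list[str] | None = None,
) -> DuplexCallResult:
    """Vectorized duplex calling over a simulated read set.

    Produces exactly the calls the per-family path would (consensus votes per
    strand, duplex agreement, end-trim, dinucleotide merge, left-alignment,
    NUMT filter), but with the voting done in pandas group-bys.
    """
    params = params or DuplexCallParams()
    genome = readset.genome
    n = readset.reads_per_strand
    if n < params.min_reads_per_strand:
        cov = CoverageProfile(genome, np.zeros(genome.length, dtype=np.int64), region_index)
        return DuplexCallResult([], cov, 0, readset.n_molecules)

    need = math.ceil(params.strand_consensus_threshold * n)
    diffs = readset.diffs
    raw_rows: list[tuple] = []
    if len(diffs):
        votes = (
            diffs.groupby(["mol", "strand", "pos", "vtype", "ref", "alt"])
            .size()
            .rename("votes")
            .reset_index()
        )
        tot = (
            votes.groupby(["mol", "strand", "pos"])["votes"]
            .sum()
            .rename("tot")
            .reset_index()
        )
        votes = votes.merge(tot, on=["mol", "strand", "pos"])
        # strand state per candidate position: alt key, REF, or N
        best = votes.sort_values("votes", ascending=False).drop_duplicates(
            ["mol", "strand", "pos"]
        )
        alt_ok = best.votes >= need
        ref_ok = (n - best.tot) >= need
        best = best.assign(
            state=np.where(alt_ok, "ALT", np.where(ref_ok, "REF", "N"))
        )
        a = best[best.strand == 0]
        b = best[best.strand == 1]
        m = a.merge(
            b,
            on=["mol", "pos"],
            how="outer",
            suffixes=("_a", "_b"),
        )
        # absent strand entry means that strand is unanimously reference
        m["state_a"] = m["state_a"].fillna("REF")
        m["state_b"] = m["state_b"].fillna("REF")
        dup = m[
            (m.state_a == "ALT")
            & (m.state_b == "ALT")
            & (m.vtype_a == m.vtype_b)
            & (m.alt_a == m.alt_b)
            & (m.ref_a == m.ref_b)
        ]
        insert_length = readset.insert_length
        for row in dup.itertuples(index=False):
            mol = int(row.mol)
            raw_rows.append(
                (
                    readset.tag(mol),
                    int(readset.starts[mol]),
                    insert_length,
                    int(row.pos),
                    row.vtype_a,
                    row.ref_a,
                    row.alt_a,
                )
            )
    calls = finalize_calls(raw_rows, genome, region_index, params.end_trim)

    if nuclear_seqs:
        per_mol: dict[str, list] = defaultdict(list)
        mol_start = {}
        for mol, start, length, pos0, vtype, ref, alt in raw_rows:
            per_mol[mol].append((pos0, vtype, ref, alt))
            mol_start[mol] = start
        filtered = []
        for c in calls:
            if c.status == PASS:
                status = numt_filter(
                    c,
                    per_mol[c.molecule_id],
                    genome,
                    nuclear_seqs,
                    params.numt_k_flank,
                    params.numt_max_mismatch,
                    mol_start=mol_start[c.molecule_id],
                    mol_length=readset.insert_length,
                )
                c = replace(c, status=status)
            filtered.append(c)
        calls = filtered

    cov = CoverageProfile.from_molecules(
        genome,
        readset.starts,
        readset.insert_length,
        end_trim=params.end_trim,
        region_index=region_index,
    )
    return DuplexCallResult(calls, cov, readset.n_molecules, 0)


def family_pipeline(
    reads: list[TaggedRead],
    genome: OrganelleGenome,
    region_index: RegionIndex | None = None,
    params: DuplexCallParams | None = None,
    nuclear_seqs: list[str] | None = None,
) -> DuplexCallResult:
    """Per-family reference path: group, consensus, call, filter, coverage."""
    params = params or DuplexCallParams()
    families, _ = group_families(reads)
    calls: list[VariantCall] = []
    starts, lengths = [], []
    n_pass = n_rej = 0
    for fam in families:
        cons = build_consensus(
            fam,
            params.min_reads_per_strand,
            params.strand_consensus_threshold,
            genome_length=genome.length,
        )
        if cons is None:
            n_rej += 1
            continue
        n_pass += 1
        starts.append(cons.start)
        lengths.append(cons.length)
        mol_calls = call_variants(cons, genome, region_index, params.end_trim)
        if nuclear_seqs:
            mol_vars = [(p, v[0], v[1], v[2]) for p, v in cons.variants.items()]
            mol_calls = [
                replace(
                    c,
                    status=numt_filter(
                        c,
                        mol_vars,
                        genome,
                        nuclear_seqs,
                        params.numt_k_flank,
                        params.numt_max_mismatch,
                        mol_start=cons.start,
                        mol_length=cons.length,
                    ),
                )
                if c.status == PASS
                else c
                for c in mol_calls
            ]
        calls.extend(mol_calls)
    calls.sort(key=lambda c: (c.position, c.molecule_id))
    cov = CoverageProfile.from_molecules(
        genome,
        np.array(starts, dtype=np.int64) if starts else np.zeros(0, dtype=np.int64),
        np.array(lengths, dtype=np.int64) if lengths else 0,
        end_trim=params.end_trim,
        region_index=region_index,
    )
    return DuplexCallResult(calls, cov, n_pass, n_rej)


def calls_to_frame(calls: list[VariantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "position": c.position,
                "type": c.vtype,
                "ref": c.ref,
                "alt": c.alt,
                "molecule": c.molecule_id,
                "region": c.region,
                "gene_strand": c.gene_strand or ".",
                "context": c.context or ".",
                "pyr_strand": c.pyr_strand or ".",
                "status": c.status,
            }
            for c in calls
        ],
        columns=[
            "position",
            "type",
            "ref",
            "alt",
            "molecule",
            "region",
            "gene_strand",
            "context",
            "pyr_strand",
            "status",
        ],
    )
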