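"""Split-alignment classification and repeat-mediated recombination analysis.

Long reads from a recombining organellar genome fall into a small set of
alignment geometries:

* one local hit covering (nearly) the whole read — no structural event;
* one hit with a large unexplained remainder — candidate indel;
* two hits in opposite orientations — recombination between an *inverted*
  repeat pair (the read switches strand at the crossover);
* two hits in the same orientation whose genome order matches the read order
  with a genomic gap — *deletion-type* recombination between direct repeats;
* two hits in the same orientation whose genome order is reversed relative
  to the read order — a read walking around the small *circular* molecule
  excised by direct-repeat recombination ("the end of the read maps in front
  of the end of the read");
* three or more hits — excluded from analysis (such reads span multiple
  recombined repeats and are not reconstructed).

Recombination breakpoints are matched against a repeat catalog; per-repeat
recombination frequency is recombined reads / repeat-spanning reads, and
genome-wide frequencies pool repeats passing a minimum summed recombining-
read threshold (default 10 for mtDNA, 3 for cpDNA).  Indel calls require a
configurable number of independent supporting reads with the exact same
position and length (default 2).  Coverage-ratio profiles average depth in
1,000-bp windows and report a mutant:WT ratio normalized to mean 1.

Hits may come from BLAST tabular output, SAM records with supplementary
alignments, or the built-in k-mer seed-and-chain aligner (sufficient for
synthetic reads, including nanopore-like error rates).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .orgmodel import OrganelleGenome, RepeatPair
from .synth import LongRead, encode_seq

logger = logging.getLogger("orgmut")

SINGLE_CLEAN = "single_hit_clean"
SINGLE_INDEL = "single_hit_indel"
TWO_INVERTED = "two_hit_inverted"
TWO_DELETION = "two_hit_direct_deletion"
TWO_CIRCULAR = "two_hit_direct_circular"
MULTI_EXCLUDED = "multi_hit_excluded"
UNMAPPED = "unmapped"

GEOM_INVERTED = "inverted"
GEOM_DELETION = "direct_deletion"
GEOM_CIRCULAR = "direct_circular"


@dataclass(frozen=True)
class LocalHit:
    """One local alignment of a read segment to the genome.

    All coordinates 1-based inclusive; ``g_start <= g_end`` always, with
    ``strand`` recording orientation; read coordinates are in original read
    orientation.
    """

    read_start: int
    read_end: int
    g_start: int
    g_end: int
    strand: str  # "+" or "-"
    identity: float = 1.0

    def __post_init__(self):
        if self.read_start > self.read_end or self.g_start > self.g_end:
            raise ValueError("empty hit interval")

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start + 1


@dataclass
class RecombEvent:
    read_id: str
    junction: tuple[int, int]  # genome coordinates at the read junction
    geometry: str
    repeat: str | None = None


@dataclass
class ReadStructure:
    read_id: str
    read_length: int
    hits: list[LocalHit]
    cls: str
    event: RecombEvent | None = None
    indel_candidate: tuple[str, int, int] | None = None  # (type, position, length)


@dataclass
class RepeatRecombStats:
    repeat: str
    recombined: int
    spanning: int

    def __post_init__(self):
        if not 0 <= self.recombined <= self.spanning:
            raise ValueError("recombined count must be within [0, spanning]")

    @property
    def frequency(self) -> float | None:
        """recombined / spanning, or None when no read spans the repeat."""
        if self.spanning == 0:
            return None
        return self.recombined / self.spanning


# ---------------------------------------------------------------------------
# Read classification


def _dedupe_hits(hits: list[LocalHit]) -> list[LocalHit]:
    """Drop hits mostly contained (on the read) in a longer kept hit.

    Repeat copies generate a short extra hit covering the same read interval
    as the main alignment; keeping it would push junction reads into the
    excluded >=3-hit class for the wrong reason.
    """
    kept: list[LocalHit] = []
    for h in sorted(hits, key=lambda h: -h.read_span):
        contained = False
        for k in kept:
            ov = min(h.read_end, k.read_end) - max(h.read_start, k.read_start) + 1
            if ov >= 0.95 * h.read_span:
                contained = True
                break
        if not contained:
            kept.append(h)
    kept.sort(key=lambda h: h.read_start)
    return kept


def _trim_overlap(h1: LocalHit, h2: LocalHit) -> tuple[LocalHit, LocalHit]:
    """Split the shared read interval of two junction hits at its midpoint.

    Hits flanking a recombination junction both extend through the (near-)
    identical repeat sequence, so their read intervals overlap by up to the
    repeat length; trimming at the midpoint leaves each junction coordinate
    inside its repeat copy.
    """
    overlap = min(h1.read_end, h2.read_end) - max(h1.read_start, h2.read_start) + 1
    if overlap <= 0:
        return h1, h2
    mid = (max(h1.read_start, h2.read_start) + min(h1.read_end, h2.read_end)) // 2
    s1 = h1.read_end - mid
    if s1 > 0 and h1.read_span - s1 >= 1:
        if h1.strand == "+":
            h1 = LocalHit(h1.read_start, mid, h1.g_start, h1.g_end - s1, "+", h1.identity)
        else:
            h1 = LocalHit(h1.read_start, mid, h1.g_start + s1, h1.g_end, "-", h1.identity)
    s2 = (mid + 1) - h2.read_start
    if s2 > 0 and h2.read_span - s2 >= 1:
        if h2.strand == "+":
            h2 = LocalHit(mid + 1, h2.read_end, h2.g_start + s2, h2.g_end, "+", h2.identity)
        else:
            h2 = LocalHit(mid + 1, h2.read_end, h2.g_start, h2.g_end - s2, "-", h2.identity)
    return h1, h2


def _junction_coords(h1: LocalHit, h2: LocalHit) -> tuple[int, int]:
    """Genome coordinates flanking the read junction between two hits."""
    j1 = h1.g_end if h1.strand == "+" else h1.g_start
    j2 = h2.g_start if h2.strand == "+" else h2.g_end
    return j1, j2


def classify_read(
    hits: list[LocalHit],
    read_id: str,
    read_length: int,
    min_hit_len: int = 100,
    max_unexplained: int | None = None,
    gap_slop: int = 50,
) -> ReadStructure:
    """Assign one read to its structural class from its local hits.

    ``max_unexplained`` defaults to 50 bp + 5% of the read length.  Two hits
    whose read intervals overlap beyond 80% of the shorter hit are ambiguous
    and classified by the longer hit alone (logged).
    """
    if max_unexplained is None:
        max_unexplained = int(50 + 0.05 * read_length)
    hits = [h for h in hits if h.read_span >= min_hit_len]
    hits = _dedupe_hits(hits)

    def _single(h: LocalHit) -> ReadStructure:
        unexplained = read_length - h.read_span
        if unexplained <= max_unexplained:
            return ReadStructure(read_id, read_length, [h], SINGLE_CLEAN)
        return ReadStructure(read_id, read_length, [h], SINGLE_INDEL)

    if not hits:
        return ReadStructure(read_id, read_length, [], UNMAPPED)
    if len(hits) == 1:
        return _single(hits[0])
    if len(hits) >= 3:
        return ReadStructure(read_id, read_length, hits, MULTI_EXCLUDED)

    h1, h2 = hits
    overlap = min(h1.read_end, h2.read_end) - max(h1.read_start, h2.read_start) + 1
    if overlap >= 0.95 * min(h1.read_span, h2.read_span):
        logger.warning("read %s: ambiguous overlapping hits; using longer hit", read_id)
        return _single(max(h1, h2, key=lambda h: h.read_span))
    h1, h2 = _trim_overlap(h1, h2)
    hits = [h1, h2]

    j1, j2 = _junction_coords(h1, h2)
    if h1.strand != h2.strand:
        ev = RecombEvent(read_id, (j1, j2), GEOM_INVERTED)
        return ReadStructure(read_id, read_length, hits, TWO_INVERTED, event=ev)

    read_gap = h2.read_start - h1.read_end - 1
    # orient the genome axis along the molecule: forward hits read the genome
    # ascending, reverse hits descending
    signed = (j2 - j1) if h1.strand == "+" else (j1 - j2)
    net = signed - read_gap
    if signed < -gap_slop:
        # genome order reversed relative to read order: the end of the read
        # maps in front of the start — circular/tandem product
        ev = RecombEvent(read_id, (j1, j2), GEOM_CIRCULAR)
        return ReadStructure(read_id, read_length, hits, TWO_CIRCULAR, event=ev)
    if net > gap_slop:
        a, b = sorted((j1, j2))
        ev = RecombEvent(read_id, (a, b), GEOM_DELETION)
        return ReadStructure(
            read_id,
            read_length,
            hits,
            TWO_DELETION,
            event=ev,
            indel_candidate=("deletion", a, b - a),
        )
    if net < -gap_slop:
        # more read than genome between the hits: insertion candidate
        return ReadStructure(
            read_id,
            read_length,
            hits,
            SINGLE_INDEL,
            indel_candidate=("insertion", min(j1, j2), -net),
        )
    return ReadStructure(read_id, read_length, hits, SINGLE_CLEAN)


# ---------------------------------------------------------------------------
# Breakpoint matching


def _interval_distance(pos: int, interval: tuple[int, int]) -> int:
    a, b = interval
    if pos < a:
        return a - pos
    if pos > b:
        return pos - b
    return 0


def match_breakpoint(
    event: RecombEvent,
    repeats: list[RepeatPair],
    tolerance: int = 100,
) -> str | None:
    """Match a recombination junction to a catalogued repeat pair.

    Each junction end must lie within one repeat copy's interval extended by
    ``tolerance``, one junction per copy, and the repeat orientation must
    match the event geometry (inverted geometry <=> inverted repeat).  Ties
    between equally distant repeats are ambiguous (None, logged).
    """
    want_inverted = event.geometry == GEOM_INVERTED
    j1, j2 = event.junction
    best: tuple[int, str] | None = None
    tie = False
    for rp in repeats:
        if rp.inverted != want_inverted:
            continue
        for ja, jb in ((j1, j2), (j2, j1)):
            d1 = _interval_distance(ja, rp.copy1)
            d2 = _interval_distance(jb, rp.copy2)
            if d1 <= tolerance and d2 <= tolerance:
                total = d1 + d2
                if best is None or total < best[0]:
                    best = (total, rp.name)
                    tie = False
                elif total == best[0] and rp.name != best[1]:
                    tie = True
    if best is None:
        return None
    if tie:
        logger.warning(
            "read %s: junction %s matches two repeats equally well; ambiguous",
            event.read_id,
            event.junction,
        )
        return None
    return best[1]


def count_spanning(
    structures: list[ReadStructure],
    rp: RepeatPair,
    flank: int = 100,
) -> int:
    """Number of reads informative about recombination at one repeat pair.

    A read spans the repeat if one of its hits fully covers either copy plus
    ``flank`` bases on both sides, or if it is a recombined read matched to
    this repeat; both copies are pooled and each read counts once.
    """
    n = 0
    for s in structures:
        if s.event is not None and s.event.repeat == rp.name:
            n += 1
            continue
        spanning = False
        for h in s.hits:
            for a, b in (rp.copy1, rp.copy2):
                if h.g_start <= a - flank and h.g_end >= b + flank:
                    spanning = True
                    break
            if spanning:
                break
        if spanning:
            n += 1
    return n


def repeat_frequency(recombined: int, spanning: int, repeat: str) -> RepeatRecombStats:
    return RepeatRecombStats(repeat, recombined, spanning)


def analyze_reads(
    structures: list[ReadStructure],
    repeats: list[RepeatPair],
    tolerance: int = 100,
    flank: int = 100,
) -> list[RepeatRecombStats]:
    """Match events to repeats, then tally per-repeat recombination stats."""
    for s in structures:
        if s.event is not None and s.cls in (TWO_INVERTED, TWO_DELETION, TWO_CIRCULAR):
            s.event.repeat = match_breakpoint(s.event, repeats, tolerance)
    stats = []
    for rp in repeats:
        rec = sum(
            1
            for s in structures
            if s.event is not None and s.event.repeat == rp.name
        )
        span = count_spanning(structures, rp, flank)
        stats.append(RepeatRecombStats(rp.name, rec, span))
    return stats


def genome_frequency(
    stats_by_replicate: list[list[RepeatRecombStats]],
    min_recombined: int = 10,
) -> tuple[list[float], list[str]]:
    """Genome-wide recombination frequency per replicate.

    Repeats are included when their recombining-read totals *summed across
    replicates* reach ``min_recombined`` (default 10, the mtDNA threshold;
    use 3 for cpDNA).  Each replicate's frequency pools counts over the
    included repeats.  Returns ([] , []) when no repeat passes.
    """
    totals: dict[str, int] = defaultdict(int)
    for rep in stats_by_replicate:
        for s in rep:
            totals[s.repeat] += s.recombined
    included = sorted(r for r, t in totals.items() if t >= min_recombined)
    if not included:
        logger.warning("genome_frequency: no repeat passes threshold %d", min_recombined)
        return [], []
    out = []
    for rep in stats_by_replicate:
        by_name = {s.repeat: s for s in rep}
        rec = sum(by_name[r].recombined for r in included if r in by_name)
        span = sum(by_name[r].spanning for r in included if r in by_name)
        out.append(rec / span if span else float("nan"))
    return out, included


def call_supported_indels(
    structures: list[ReadStructure], min_support: int = 2
) -> list[dict]:
    """Indel calls supported by >= ``min_support`` independent reads.

    Candidates are grouped by exact (type, position, length); reads
    supporting nearly-but-not-exactly the same indel do not pool (this is
    deliberately strict, matching the high artifactual-indel rate of long
    reads).
    """
    groups: dict[tuple[str, int, int], list[str]] = defaultdict(list)
    for s in structures:
        if s.indel_candidate is not None:
            groups[s.indel_candidate].append(s.read_id)
    calls = []
    for (itype, pos, length), readers in sorted(groups.items()):
        if len(readers) >= min_support:
            calls.append(
                {
                    "type": itype,
                    "position": pos,
                    "length": length,
                    "support": len(readers),
                    "reads": sorted(readers),
                }
            )
    return calls


# ---------------------------------------------------------------------------
# Coverage windows


@dataclass
class CoverageWindows:
    window: int
    starts: np.ndarray  # 1-based window start positions
    mutant_depth: np.ndarray
    wt_depth: np.ndarray
    ratio: np.ndarray  # normalized mutant:WT ratio, mean 1 over finite windows
    flagged_zero_wt: np.ndarray


def coverage_ratio_windows(
    mutant_depth: np.ndarray,
    wt_depth: np.ndarray,
    window: int = 1000,
) -> CoverageWindows:
    """Mean depth in tiling windows and the normalized mutant:WT ratio.

    The per-window ratio vector is rescaled so its mean over finite windows
    is exactly 1; windows with zero WT depth are flagged and excluded from
    the rescaling.  A genome shorter than one window yields a single
    whole-genome window.
    """
    mutant_depth = np.asarray(mutant_depth, dtype=float)
    wt_depth = np.asarray(wt_depth, dtype=float)
    L = len(mutant_depth)
    if len(wt_depth) != L:
        raise ValueError("depth vectors differ in length")
    window = min(window, L)
    edges = list(range(0, L, window))
    starts = np.array([e + 1 for e in edges])
    mut = np.array([mutant_depth[e : e + window].mean() for e in edges])
    wt = np.array([wt_depth[e : e + window].mean() for e in edges])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mut / wt
    flagged = ~np.isfinite(ratio)
    finite_mean = ratio[~flagged].mean() if (~flagged).any() else np.nan
    ratio = ratio / finite_mean
    return CoverageWindows(window, starts, mut, wt, ratio, flagged)


def depth_from_structures(structures: list[ReadStructure], genome_length: int) -> np.ndarray:
    """Per-base depth from the genome intervals of all local hits."""
    delta = np.zeros(genome_length + 1, dtype=np.int64)
    for s in structures:
        for h in s.hits:
            delta[h.g_start - 1] += 1
            delta[min(h.g_end, genome_length)] -= 1
    return np.cumsum(delta[:-1])


# ---------------------------------------------------------------------------
# Hit providers: internal chainer, BLAST tabular, SAM


class GenomeKmerIndex:
    """Exact k-mer index of one genome for the seed-and-chain aligner."""

    def __init__(self, genome: OrganelleGenome, k: int = 13):
        self.genome = genome
        self.k = k
        codes = encode_seq(genome.sequence).astype(np.int64)
        L = len(codes)
        if L < k:
            raise ValueError("genome shorter than k")
        mult = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        valid = codes < 4
        kmers = np.zeros(L - k + 1, dtype=np.int64)
        ok = np.ones(L - k + 1, dtype=bool)
        for j in range(k):
            kmers = kmers * 4 + codes[j : L - k + 1 + j]
            ok &= valid[j : L - k + 1 + j]
        self.index: dict[int, np.ndarray] = {}
        order = np.argsort(kmers, kind="stable")
        sk = kmers[order]
        bounds = np.flatnonzero(np.diff(sk)) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [len(sk)]])
        for s, e in zip(starts, ends):
            positions = order[s:e]
            positions = positions[ok[positions]]
            if len(positions):
                self.index[int(sk[s])] = np.sort(positions)
        self._mult = mult

    def read_kmers(self, codes: np.ndarray, stride: int) -> tuple[np.ndarray, np.ndarray]:
        k = self.k
        n = len(codes) - k + 1
        if n <= 0:
            return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
        offs = np.arange(0, n, stride)
        vals = np.zeros(len(offs), dtype=np.int64)
        ok = np.ones(len(offs), dtype=bool)
        for j in range(k):
            c = codes[offs + j]
            vals = vals * 4 + c
            ok &= c < 4
        return offs[ok], vals[ok]


_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def find_hits(
    index: GenomeKmerIndex,
    read_seq: str,
    stride: int = 5,
    band: int = 120,
    max_seed_gap: int = 400,
    min_seeds: int = 4,
    min_hit_len: int = 100,
) -> list[LocalHit]:
    """Locate local alignments of a read by exact-seed chaining.

    Seeds are exact k-mer matches; colinear seeds (consistent diagonal within
    ``band``, read gaps below ``max_seed_gap``) chain into one hit.  Handles
    nanopore-like error rates (a 13-mer survives 5% per-base error with
    probability ~0.5, so seeds at stride 5 land every few bases).
    """
    k = index.k
    codes = encode_seq(read_seq)
    rc = _COMP[codes][::-1]
    n = len(codes)
    chains: list[dict] = []

    def _feed(offs, vals, strand):
        open_chains: list[dict] = []
        for i, v in zip(offs, vals):
            positions = index.index.get(int(v))
            if positions is None or len(positions) > 50:
                continue
            for p in positions:
                diag = int(p) - int(i)
                placed = False
                for ch in open_chains:
                    if (
                        abs(diag - ch["diag"]) <= band
                        and i - ch["last_i"] <= max_seed_gap
                        and i > ch["last_i"]
                    ):
                        ch["last_i"] = int(i)
                        ch["last_p"] = int(p)
                        ch["diag"] = 0.8 * ch["diag"] + 0.2 * diag
                        ch["n"] += 1
                        placed = True
                        break
                if not placed:
                    open_chains.append(
                        {
                            "diag": float(diag),
                            "first_i": int(i),
                            "first_p": int(p),
                            "last_i": int(i),
                            "last_p": int(p),
                            "n": 1,
                            "strand": strand,
                        }
                    )
        chains.extend(open_chains)

    offs_f, vals_f = index.read_kmers(codes, stride)
    _feed(offs_f, vals_f, "+")
    offs_r, vals_r = index.read_kmers(rc, stride)
    _feed(offs_r, vals_r, "-")

    hits = []
    for ch in chains:
        if ch["n"] < min_seeds:
            continue
        span = ch["last_i"] - ch["first_i"] + k
        if span < min_hit_len:
            continue
        if ch["strand"] == "+":
            read_start = ch["first_i"] + 1
            read_end = ch["last_i"] + k
            g_start = ch["first_p"] + 1
            g_end = ch["last_p"] + k
        else:
            # seed offsets are on the reverse-complemented read
            read_start = n - (ch["last_i"] + k) + 1
            read_end = n - ch["first_i"]
            g_start = ch["first_p"] + 1
            g_end = ch["last_p"] + k
        if g_end < g_start:
            continue
        identity = min(1.0, ch["n"] * stride / span)
        hits.append(
            LocalHit(read_start, read_end, g_start, g_end, ch["strand"], identity)
        )
    return hits


def classify_long_reads(
    genome: OrganelleGenome,
    reads: list[LongRead],
    min_hit_len: int = 100,
    k: int = 13,
    stride: int = 5,
) -> list[ReadStructure]:
    """Run the internal aligner + classifier over a set of long reads."""
    index = GenomeKmerIndex(genome, k=k)
    out = []
    for r in reads:
        hits = find_hits(index, r.sequence, stride=stride, min_hit_len=min_hit_len)
        out.append(classify_read(hits, r.name, len(r.sequence), min_hit_len=min_hit_len))
    return out


def read_blast_tab(path) -> dict[str, list[LocalHit]]:
    """Parse BLAST outfmt-6 (qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore) into per-read hit lists."""
    hits: dict[str, list[LocalHit]] = defaultdict(list)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qstart, qend = int(f[6]), int(f[7])
            sstart, send = int(f[8]), int(f[9])
            strand = "+" if sstart <= send else "-"
            if strand == "-":
                sstart, send = send, sstart
            hits[f[0]].append(
                LocalHit(qstart, qend, sstart, send, strand, float(f[2]) / 100.0)
            )
    for v in hits.values():
        v.sort(key=lambda h: h.read_start)
    return dict(hits)


def read_sam_hits(path) -> dict[str, tuple[int, list[LocalHit]]]:
    """Collect primary + supplementary alignments per read from a SAM file.

    Returns read -> (read length, hits) with read coordinates expressed in
    original-read orientation.
    """
    import pysam

    out: dict[str, tuple[int, list[LocalHit]]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary:
                continue
            rl = aln.infer_read_length()
            qs = aln.query_alignment_start
            qe = aln.query_alignment_end  # exclusive
            if aln.is_reverse:
                read_start = rl - qe + 1
                read_end = rl - qs
            else:
                read_start = qs + 1
                read_end = qe
            hit = LocalHit(
                read_start,
                read_end,
                aln.reference_start + 1,
                aln.reference_end,
                "-" if aln.is_reverse else "+",
            )
            length, hits = out.get(aln.query_name, (rl, []))
            hits.append(hit)
            out[aln.query_name] = (max(length or 0, rl or 0), hits)
    for name, (length, hits) in out.items():
        hits.sort(key=lambda h: h.read_start)
    return out
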