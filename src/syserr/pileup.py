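"""Per-site pileups, overlapping mate-pair detection and pair classification.

Coordinates are 0-based, half-open everywhere inside the package; 1-based
coordinates appear only in user-facing reports written by the CLI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

import pysam

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")
ALPHABET = frozenset("ACGTN")

FORWARD = "forward"
REVERSE = "reverse"

#: SAM flags excluded by default: unmapped, secondary, QC-fail, duplicate,
#: supplementary.
DEFAULT_EXCLUDE_FLAGS = 0x4 | 0x100 | 0x200 | 0x400 | 0x800


class PairCategory(str, Enum):
    """Classification of the two base calls of one overlapping mate pair."""

    REFERENCE_PAIR = "reference_pair"
    SNP_PAIR = "snp_pair"
    ERROR_PAIR = "error_pair"
    DISCORDANT = "discordant"


@dataclass(frozen=True, slots=True)
class BaseCall:
    """One read's base call at one reference position."""

    base: str
    quality: int
    strand: str  # FORWARD or REVERSE — alignment orientation of the read
    read_id: str
    mate_index: int | None = None  # 1, 2 or None for single-end

    def __post_init__(self) -> None:
        if self.base not in ALPHABET:
            raise ValueError(f"invalid base {self.base!r}")
        if self.quality < 0:
            raise ValueError(f"negative quality {self.quality}")


@dataclass(slots=True)
class SitePileup:
    """All base calls overlapping one genomic position.

    Calls are stored columnar (parallel lists) to keep large pileups cheap;
    :attr:`calls` materializes :class:`BaseCall` objects on demand.
    """

    chrom: str
    pos: int  # 0-based
    ref_base: str
    bases: list[str] = field(default_factory=list)
    quals: list[int] = field(default_factory=list)
    strands: list[str] = field(default_factory=list)
    read_ids: list[str] = field(default_factory=list)
    mates: list[int | None] = field(default_factory=list)

    def add(
        self,
        base: str,
        quality: int,
        strand: str,
        read_id: str,
        mate_index: int | None = None,
    ) -> None:
        self.bases.append(base)
        self.quals.append(quality)
        self.strands.append(strand)
        self.read_ids.append(read_id)
        self.mates.append(mate_index)

    @property
    def calls(self) -> list[BaseCall]:
        return [
            BaseCall(b, q, s, r, m)
            for b, q, s, r, m in zip(
                self.bases, self.quals, self.strands, self.read_ids, self.mates
            )
        ]

    @property
    def coverage(self) -> int:
        return len(self.bases)

    def strand_counts(self) -> tuple[int, int]:
        """(forward, reverse) call counts."""
        n_fwd = sum(1 for s in self.strands if s == FORWARD)
        return n_fwd, len(self.strands) - n_fwd

    def mismatch_counts(self) -> tuple[int, int]:
        """(forward, reverse) counts of calls differing from the reference."""
        fwd = rev = 0
        for b, s in zip(self.bases, self.strands):
            if b != self.ref_base and b != "N":
                if s == FORWARD:
                    fwd += 1
                else:
                    rev += 1
        return fwd, rev

    @property
    def n_mismatches(self) -> int:
        fwd, rev = self.mismatch_counts()
        return fwd + rev


@dataclass(frozen=True, slots=True)
class PairCall:
    """The two base calls one overlapping mate pair makes at one position."""

    chrom: str
    pos: int
    call_fwd: BaseCall
    call_rev: BaseCall
    category: PairCategory


class MissingReferenceError(RuntimeError):
    """A SAM record refers to a sequence absent from the FASTA."""


def classify_pair(ref_base: str, fwd: str, rev: str) -> PairCategory:
    """Classify a pair of overlapping-mate base calls against the reference.

    Both calls matching the reference is a reference pair; both calls equal
    to each other but differing from the reference is a SNP pair; exactly one
    call matching the reference is an error pair; and two distinct
    non-reference calls are discordant (excluded from all rate estimates).

    Raises ``ValueError`` for any base outside {A,C,G,T}.
    """
    for b in (ref_base, fwd, rev):
        if b not in NUCLEOTIDES:
            raise ValueError(f"base {b!r} not in {{A,C,G,T}}")
    if fwd == ref_base and rev == ref_base:
        return PairCategory.REFERENCE_PAIR
    if fwd == rev:
        return PairCategory.SNP_PAIR
    if fwd == ref_base or rev == ref_base:
        return PairCategory.ERROR_PAIR
    return PairCategory.DISCORDANT


def _parse_region(region: str) -> tuple[str, int | None, int | None]:
    """Parse ``chrom`` or ``chrom:start-end`` (1-based inclusive) strings."""
    if ":" not in region:
        return region, None, None
    chrom, _, span = region.partition(":")
    start_s, _, end_s = span.partition("-")
    start = int(start_s.replace(",", "")) - 1
    end = int(end_s.replace(",", "")) if end_s else None
    return chrom, start, end


def read_alignments(
    sam_path: str,
    fasta_path: str,
    region: str | None = None,
    exclude_flags: int = DEFAULT_EXCLUDE_FLAGS,
) -> Iterator[SitePileup]:
    """Build per-site pileups from a SAM/BAM file, sorted by (chrom, pos).

    One :class:`SitePileup` is yielded per covered reference position.
    Deletions and reference skips contribute no call; positions whose
    reference base is N are skipped.  Records matching ``exclude_flags``
    (default: unmapped/secondary/supplementary/QC-fail/duplicate) are
    ignored.
    """
    with pysam.FastaFile(fasta_path) as fasta:
        refs = {name: fasta.fetch(name).upper() for name in fasta.references}

    want_chrom, want_start, want_end = (None, None, None)
    if region is not None:
        want_chrom, want_start, want_end = _parse_region(region)
        if want_chrom not in refs:
            raise MissingReferenceError(
                f"region sequence {want_chrom!r} not in {fasta_path}"
            )

    piles: dict[tuple[str, int], SitePileup] = {}
    mode = "rb" if sam_path.endswith(".bam") else "r"
    with pysam.AlignmentFile(sam_path, mode, check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.flag & exclude_flags:
                continue
            chrom = rec.reference_name
            if chrom is None:
                continue
            if want_chrom is not None and chrom != want_chrom:
                continue
            if chrom not in refs:
                raise MissingReferenceError(
                    f"alignment references {chrom!r}, absent from {fasta_path}"
                )
            ref_seq = refs[chrom]
            seq = rec.query_sequence
            quals = rec.query_qualities
            if seq is None or quals is None:
                continue
            strand = REVERSE if rec.is_reverse else FORWARD
            if rec.is_paired:
                mate: int | None = 1 if rec.is_read1 else 2
            else:
                mate = None
            name = rec.query_name
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                if want_start is not None and rpos < want_start:
                    continue
                if want_end is not None and rpos >= want_end:
                    continue
                ref_base = ref_seq[rpos]
                if ref_base == "N":
                    continue
                key = (chrom, rpos)
                pile = piles.get(key)
                if pile is None:
                    pile = piles[key] = SitePileup(chrom, rpos, ref_base)
                pile.add(seq[qpos], quals[qpos], strand, name, mate)

    for key in sorted(piles):
        yield piles[key]


def pair_overlaps(
    pileups: Iterable[SitePileup],
    counters: dict[str, int] | None = None,
) -> Iterator[PairCall]:
    """Emit one :class:`PairCall` per (fragment, position) covered by both mates.

    A fragment contributes a pair at a position when exactly one forward and
    one reverse call from the same read name overlap it.  Fragments with
    inconsistent mate structure at a position (e.g. two same-orientation
    calls) and pairs involving an N call are skipped; counts are accumulated
    in ``counters`` when provided (keys ``inconsistent`` and ``n_call``).
    """
    if counters is None:
        counters = {}
    counters.setdefault("inconsistent", 0)
    counters.setdefault("n_call", 0)
    for pile in pileups:
        by_fragment: dict[str, list[int]] = {}
        for idx, rid in enumerate(pile.read_ids):
            by_fragment.setdefault(rid, []).append(idx)
        for rid, idxs in by_fragment.items():
            if len(idxs) != 2:
                if len(idxs) > 2:
                    counters["inconsistent"] += 1
                continue
            i, j = idxs
            if pile.strands[i] == pile.strands[j]:
                counters["inconsistent"] += 1
                continue
            if pile.strands[i] == REVERSE:
                i, j = j, i
            fwd = BaseCall(
                pile.bases[i], pile.quals[i], FORWARD, rid, pile.mates[i]
            )
            rev = BaseCall(
                pile.bases[j], pile.quals[j], REVERSE, rid, pile.mates[j]
            )
            if fwd.base == "N" or rev.base == "N" or pile.ref_base == "N":
                counters["n_call"] += 1
                continue
            category = classify_pair(pile.ref_base, fwd.base, rev.base)
            yield PairCall(pile.chrom, pile.pos, fwd, rev, category)


@dataclass(slots=True)
class SitePairCounts:
    """Per-site tally of pair categories."""

    chrom: str
    pos: int
    ref_base: str
    n_ref: int = 0
    n_snp: int = 0
    n_err: int = 0
    n_discordant: int = 0

    @property
    def n_pairs(self) -> int:
        return self.n_ref + self.n_snp + self.n_err + self.n_discordant

    @property
    def n_concordant(self) -> int:
        return self.n_ref + self.n_snp + self.n_err


def tally_pairs(
    paircalls: Iterable[PairCall],
    ref_bases: Mapping[tuple[str, int], str] | None = None,
) -> dict[tuple[str, int], SitePairCounts]:
    """Aggregate a stream of pair calls into per-site category counts."""
    sites: dict[tuple[str, int], SitePairCounts] = {}
    for pc in paircalls:
        key = (pc.chrom, pc.pos)
        site = sites.get(key)
        if site is None:
            ref = ref_bases[key] if ref_bases else (
                pc.call_fwd.base
                if pc.category
                in (PairCategory.REFERENCE_PAIR, PairCategory.ERROR_PAIR)
                else "N"
            )
            site = sites[key] = SitePairCounts(pc.chrom, pc.pos, ref)
        if pc.category is PairCategory.REFERENCE_PAIR:
            site.n_ref += 1
            site.ref_base = pc.call_fwd.base
        elif pc.category is PairCategory.SNP_PAIR:
            site.n_snp += 1
        elif pc.category is PairCategory.ERROR_PAIR:
            site.n_err += 1
        else:
            site.n_discordant += 1
    return sites


def error_rate(
    paircalls: Iterable[PairCall] | Mapping[tuple[str, int], SitePairCounts],
    min_coverage: int = 10,
) -> float:
    """Background per-pair error probability.

    The ratio of error pairs to all concordant-with-taxonomy pairs
    (reference + SNP + error; discordant pairs excluded) over sites covered
    by at least ``min_coverage`` pairs.

    Raises ``ValueError`` when no site meets the coverage threshold.
    """
    if isinstance(paircalls, Mapping):
        sites = paircalls
    else:
        sites = tally_pairs(paircalls)
    n_err = 0
    n_all = 0
    for site in sites.values():
        if site.n_pairs < min_coverage:
            continue
        n_err += site.n_err
        n_all += site.n_concordant
    if n_all == 0:
        raise ValueError(
            f"no sites with pair coverage >= {min_coverage}; cannot estimate error rate"
        )
    return n_err / n_all
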