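"""Read simulator with planted heterozygous and systematic-error sites.

Emits a random reference (FASTA), aligned reads (SAM; alignment is by
construction, no aligner involved) and a truth table, emulating a deeply
covered library with overlapping mate pairs: a configurable background
per-pair error rate, heterozygous sites at a chosen variant-allele
fraction, and systematic-error sites whose errors concentrate on one read
orientation, favor a GGT sequence context and a T>G substitution, and carry
locally depressed quality scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pileup import FORWARD, REVERSE

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = np.array(["A", "C", "G", "T"])
_COMP = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G

#: Substitution preference of systematic errors: strongly toward G, weakly
#: toward A/T, mirroring the observed spectrum concentration on T>G.
SYSERR_SUBST_WEIGHTS = {"A": 0.05, "C": 0.15, "G": 0.70, "T": 0.10}


def base_error_for_pair_rate(pair_rate: float) -> float:
    """Per-base error rate epsilon such that P(exactly one of 2 calls errs) = pair_rate.

    Solves 2*eps*(1-eps) = pair_rate, the error-pair probability for one
    overlapping mate pair at a clean site.
    """
    if not 0.0 <= pair_rate < 0.5:
        raise ValueError("pair_rate must lie in [0, 0.5)")
    return 0.5 * (1.0 - math.sqrt(1.0 - 2.0 * pair_rate))


@dataclass(slots=True)
class SimConfig:
    """Simulation parameters; ``seed`` is mandatory for full determinism."""

    seed: int
    genome_length: int = 100_000
    gc: float = 0.5
    ggt_enrichment: float = 1.0
    n_het_sites: int = 0
    variant_allele_fraction: float = 0.5
    n_syserr_sites: int = 0
    syserr_ggt_fraction: float = 0.5
    pair_error_rate: float = 0.0026
    base_error_rate: float | None = None  # overrides pair_error_rate calibration
    syserr_strand_rate: float = 0.4
    qual_mean: float = 32.0
    qual_sd: float = 3.0
    qual_depression: int = 10
    read_length: int = 76
    frag_min: int = 50
    frag_max: int = 300
    coverage: float = 30.0
    paired: bool = True
    chrom: str = "sim1"

    def __post_init__(self) -> None:
        for name in (
            "gc",
            "variant_allele_fraction",
            "syserr_ggt_fraction",
            "pair_error_rate",
            "syserr_strand_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frag_min > self.frag_max:
            raise ValueError("frag_min > frag_max")
        if self.read_length > self.frag_max:
            raise ValueError("read_length exceeds max fragment length")

    @property
    def epsilon(self) -> float:
        if self.base_error_rate is not None:
            return self.base_error_rate
        return base_error_for_pair_rate(self.pair_error_rate)


@dataclass(frozen=True, slots=True)
class TruthRecord:
    """Ground truth for one planted site."""

    chrom: str
    pos: int
    site_type: str  # "het" | "syserr"
    alt_base: str  # het alternate allele or syserr erroneous call
    affected_strand: str | None = None  # syserr only
    param: float = 0.0  # variant-allele fraction or strand error rate


@dataclass(slots=True)
class SimResult:
    """Bookkeeping returned by :func:`simulate_reads`."""

    config: SimConfig
    truth: list[TruthRecord]
    read_depth: np.ndarray  # calls per position
    pair_depth: np.ndarray  # overlapping-pair calls per position
    n_fragments: int = 0
    n_reads: int = 0


def simulate_genome(
    config: SimConfig, rng: np.random.Generator
) -> tuple[str, list[tuple[int, str]]]:
    """Random reference sequence plus an index of GGT sites on both strands.

    Bases are i.i.d. at the configured GC fraction; with
    ``ggt_enrichment > 1`` additional GGT (forward) / ACC (reverse-strand
    GGT) trinucleotides are planted at random positions to inflate the motif
    frequency by roughly that factor.  The returned index lists
    (position-of-the-T, strand) for every motif occurrence in the final
    sequence.
    """
    L = config.genome_length
    p = np.array(
        [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    )
    codes = rng.choice(4, size=L, p=p).astype(np.int8)
    if config.ggt_enrichment > 1.0:
        base_rate = p[2] * p[2] * p[3]  # per-position per-strand GGT chance
        n_extra = int(round((config.ggt_enrichment - 1.0) * base_rate * L))
        for motif in ("GGT", "ACC"):
            starts = rng.choice(L - 3, size=n_extra, replace=False)
            for s in starts:
                for off, b in enumerate(motif):
                    codes[s + off] = _CODE[b]
    seq = "".join(_BASES[codes])
    index: list[tuple[int, str]] = []
    for i in range(L - 2):
        tri = seq[i : i + 3]
        if tri == "GGT":
            index.append((i + 2, FORWARD))
        if tri == "ACC":
            index.append((i, REVERSE))
    return seq, index


def _syserr_alt(ref: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != ref]
    w = np.array([SYSERR_SUBST_WEIGHTS[b] for b in choices])
    return rng.choice(choices, p=w / w.sum())


def plant_sites(
    genome: str,
    ggt_index: Sequence[tuple[int, str]],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[TruthRecord]:
    """Choose planted het and systematic-error sites (no collisions).

    A ``syserr_ggt_fraction`` share of systematic-error sites is placed at
    GGT-context positions (the T, on the motif strand); the rest, and all
    het sites, are placed uniformly away from contig edges with a uniformly
    chosen affected strand.  Sites are kept >= 5 bp apart so planted
    contexts stay clean.
    """
    L = len(genome)
    margin = 6
    used: set[int] = set()

    def free(pos: int) -> bool:
        return all(pos + d not in used for d in range(-4, 5))

    truth: list[TruthRecord] = []
    n_ggt = int(round(config.syserr_ggt_fraction * config.n_syserr_sites))
    ggt_pool = [
        (pos, strand)
        for pos, strand in ggt_index
        if margin <= pos < L - margin and genome[pos] in "ACGT"
    ]
    order = rng.permutation(len(ggt_pool))
    taken = 0
    for idx in order:
        if taken == n_ggt:
            break
        pos, strand = ggt_pool[idx]
        if not free(pos):
            continue
        ref = genome[pos]
        # on the motif strand the reference base is T (fwd) / its complement A (rev)
        alt = "G" if strand == FORWARD else "C"
        truth.append(
            TruthRecord(
                config.chrom, pos, "syserr", alt, strand, config.syserr_strand_rate
            )
        )
        used.add(pos)
        taken += 1
    if taken < n_ggt:
        raise ValueError(
            f"only {taken} of {n_ggt} requested GGT systematic-error sites placeable"
        )

    def draw_positions(n: int) -> list[int]:
        out = []
        attempts = 0
        while len(out) < n:
            attempts += 1
            if attempts > 100 * n + 1000:
                raise ValueError("demand exceeds eligible positions")
            pos = int(rng.integers(margin, L - margin))
            if free(pos) and genome[pos] in "ACGT":
                used.add(pos)
                out.append(pos)
        return out

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for pos in draw_positions(config.n_syserr_sites - taken):
        strand = FORWARD if rng.random() < 0.5 else REVERSE
        if strand == FORWARD:
            alt = str(_syserr_alt(genome[pos], rng))
        else:
            # substitution bias acts in read space; store forward-strand base
            alt = comp[str(_syserr_alt(comp[genome[pos]], rng))]
        truth.append(
            TruthRecord(
                config.chrom,
                pos,
                "syserr",
                alt,
                strand,
                config.syserr_strand_rate,
            )
        )
    for pos in draw_positions(config.n_het_sites):
        ref = genome[pos]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        truth.append(
            TruthRecord(
                config.chrom,
                pos,
                "het",
                str(alt),
                None,
                config.variant_allele_fraction,
            )
        )
    truth.sort(key=lambda t: t.pos)
    return truth


def _phred_string(quals: np.ndarray) -> str:
    return "".join(chr(q + 33) for q in quals)


def simulate_reads(
    genome: str,
    truth: Sequence[TruthRecord],
    config: SimConfig,
    rng: np.random.Generator,
    sam_path: str,
    fastq_path: str | None = None,
) -> SimResult:
    """Simulate fragments and write coordinate-sorted aligned SAM records.

    Fragments are placed uniformly with lengths uniform on
    [frag_min, frag_max]; paired mode emits a forward read from the left end
    and a reverse read from the right end (reads truncate to the fragment
    when it is shorter than the read length), so mates overlap whenever the
    fragment is shorter than twice the read length.  Het-site alleles are
    drawn once per fragment; systematic-error sites corrupt calls on their
    affected strand with probability ``syserr_strand_rate`` and depress
    those calls' qualities by ``qual_depression``; all other calls err at
    the baseline per-base rate with a uniform substitution.
    """
    L = len(genome)
    codes = np.frombuffer(
        genome.encode().translate(bytes.maketrans(b"ACGT", bytes([0, 1, 2, 3]))),
        dtype=np.int8,
    ).copy()

    het = [t for t in truth if t.site_type == "het"]
    het_pos = np.array([t.pos for t in het], dtype=np.int64)
    het_alt = np.array([_CODE[t.alt_base] for t in het], dtype=np.int8)
    syserr_fwd = {t.pos: t for t in truth if t.site_type == "syserr" and t.affected_strand == FORWARD}
    syserr_rev = {t.pos: t for t in truth if t.site_type == "syserr" and t.affected_strand == REVERSE}

    reads_per_frag = 2 if config.paired else 1
    mean_read = min(
        config.read_length, (config.frag_min + config.frag_max) / 2
    )
    n_frags = max(
        1, int(round(config.coverage * L / (reads_per_frag * mean_read)))
    )

    eps = config.epsilon
    read_depth = np.zeros(L, dtype=np.int64)
    pair_depth = np.zeros(L, dtype=np.int64)
    records: list[tuple[int, str]] = []
    fastq_lines: list[str] = []
    n_reads = 0

    for fi in range(n_frags):
        frag_len = int(rng.integers(config.frag_min, config.frag_max + 1))
        frag_len = min(frag_len, L)
        start = int(rng.integers(0, L - frag_len + 1))
        end = start + frag_len
        name = f"frag{fi:07d}"

        # fragment-level het alleles, consistent across both mates
        overrides: dict[int, int] = {}
        if len(het_pos):
            lo = np.searchsorted(het_pos, start)
            hi = np.searchsorted(het_pos, end)
            for hidx in range(lo, hi):
                if rng.random() < het[hidx].param:
                    overrides[int(het_pos[hidx])] = int(het_alt[hidx])

        rlen = min(config.read_length, frag_len)
        if config.paired:
            mates = [(start, FORWARD, 1), (end - rlen, REVERSE, 2)]
            ov_lo, ov_hi = max(start, end - rlen), min(start + rlen, end)
            if ov_hi > ov_lo:
                pair_depth[ov_lo:ov_hi] += 1
        else:
            if rng.random() < 0.5:
                mates = [(start, FORWARD, None)]
            else:
                mates = [(end - rlen, REVERSE, None)]

        mate_fields = []
        for rstart, strand, mate_idx in mates:
            pos_arr = np.arange(rstart, rstart + rlen)
            seq_codes = codes[rstart : rstart + rlen].copy()
            quals = np.clip(
                np.rint(rng.normal(config.qual_mean, config.qual_sd, rlen)),
                2,
                41,
            ).astype(np.int64)
            for p, alt in overrides.items():
                if rstart <= p < rstart + rlen:
                    seq_codes[p - rstart] = alt
            # baseline errors, uniform substitution to one of the other bases
            err_mask = rng.random(rlen) < eps
            syserr_here = syserr_fwd if strand == FORWARD else syserr_rev
            for p, rec in syserr_here.items():
                if rstart <= p < rstart + rlen:
                    i = p - rstart
                    err_mask[i] = False  # site governed by the planted process
                    quals[i] = max(2, quals[i] - config.qual_depression)
                    if rng.random() < rec.param:
                        seq_codes[i] = _CODE[rec.alt_base]
            idx = np.nonzero(err_mask)[0]
            if len(idx):
                shifts = rng.integers(1, 4, size=len(idx)).astype(np.int8)
                seq_codes[idx] = (seq_codes[idx] + shifts) % 4
            read_depth[rstart : rstart + rlen] += 1
            seq = "".join(_BASES[seq_codes])
            mate_fields.append((rstart, strand, mate_idx, seq, quals))
            n_reads += 1

        if config.paired:
            (s1, _, _, seq1, q1), (s2, _, _, seq2, q2) = mate_fields
            flag1 = 0x1 | 0x2 | 0x20 | 0x40  # paired, proper, mate reverse, first
            flag2 = 0x1 | 0x2 | 0x10 | 0x80  # paired, proper, reverse, second
            tlen = frag_len
            records.append(
                (
                    s1,
                    "\t".join(
                        [
                            name,
                            str(flag1),
                            config.chrom,
                            str(s1 + 1),
                            "60",
                            f"{len(seq1)}M",
                            "=",
                            str(s2 + 1),
                            str(tlen),
                            seq1,
                            _phred_string(q1),
                        ]
                    ),
                )
            )
            records.append(
                (
                    s2,
                    "\t".join(
                        [
                            name,
                            str(flag2),
                            config.chrom,
                            str(s2 + 1),
                            "60",
                            f"{len(seq2)}M",
                            "=",
                            str(s1 + 1),
                            str(-tlen),
                            seq2,
                            _phred_string(q2),
                        ]
                    ),
                )
            )
            if fastq_path is not None:
                fastq_lines.extend(_fastq_entry(name + "/1", seq1, q1, False))
                fastq_lines.extend(_fastq_entry(name + "/2", seq2, q2, True))
        else:
            rstart, strand, _, seq, q = mate_fields[0]
            flag = 0x10 if strand == REVERSE else 0
            records.append(
                (
                    rstart,
                    "\t".join(
                        [
                            name,
                            str(flag),
                            config.chrom,
                            str(rstart + 1),
                            "60",
                            f"{len(seq)}M",
                            "*",
                            "0",
                            "0",
                            seq,
                            _phred_string(q),
                        ]
                    ),
                )
            )
            if fastq_path is not None:
                fastq_lines.extend(
                    _fastq_entry(name, seq, q, strand == REVERSE)
                )

    records.sort(key=lambda r: r[0])
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{config.chrom}\tLN:{L}\n")
        fh.write("@PG\tID:syserr-sim\tPN:syserr-sim\n")
        for _, line in records:
            fh.write(line + "\n")
    if fastq_path is not None:
        with open(fastq_path, "w") as fh:
            fh.write("\n".join(fastq_lines) + "\n")

    return SimResult(
        config=config,
        truth=list(truth),
        read_depth=read_depth,
        pair_depth=pair_depth,
        n_fragments=n_frags,
        n_reads=n_reads,
    )


def _fastq_entry(
    name: str, seq: str, quals: np.ndarray, is_reverse: bool
) -> list[str]:
    if is_reverse:
        codes = np.array([_CODE[b] for b in seq], dtype=np.int8)
        seq = "".join(_BASES[_COMP[codes]][::-1])
        quals = quals[::-1]
    return [f"@{name}", seq, "+", _phred_string(quals)]


def write_fasta(seq: str, path: str, chrom: str = "sim1", width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def write_truth(truth: Sequence[TruthRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tsite_type\talt_base\taffected_strand\tparam\n")
        for t in truth:
            fh.write(
                f"{t.chrom}\t{t.pos + 1}\t{t.site_type}\t{t.alt_base}\t"
                f"{t.affected_strand or '.'}\t{t.param}\n"
            )


def simulate_dataset(
    config: SimConfig,
    outdir: str,
    fastq: bool = False,
) -> tuple[dict[str, str], SimResult]:
    """Full pipeline: genome, planted sites, reads; writes FASTA/SAM/truth TSV.

    Returns (paths, result) with paths keyed ``fasta``, ``sam``, ``truth``
    and optionally ``fastq``.  Byte-identical outputs for a fixed config.
    """
    import os

    rng = np.random.default_rng(config.seed)
    genome, ggt_index = simulate_genome(config, rng)
    truth = plant_sites(genome, ggt_index, config, rng)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "ref.fa"),
        "sam": os.path.join(outdir, "reads.sam"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    if fastq:
        paths["fastq"] = os.path.join(outdir, "reads.fastq")
    write_fasta(genome, paths["fasta"], chrom=config.chrom)
    result = simulate_reads(
        genome, truth, config, rng, paths["sam"], paths.get("fastq")
    )
    write_truth(truth, paths["truth"])
    return paths, result
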