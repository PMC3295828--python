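import numpy as np
import pytest

from syserr import pileup, simdata, syscall


@pytest.fixture(scope="session")
def planted_dataset(tmp_path_factory):
    """Paired dataset with planted het and systematic-error sites."""
    cfg = simdata.SimConfig(
        seed=11,
        genome_length=20_000,
        coverage=45,
        n_het_sites=25,
        n_syserr_sites=25,
        frag_min=90,
        frag_max=130,
        syserr_strand_rate=0.4,
    )
    outdir = tmp_path_factory.mktemp("planted")
    paths, result = simdata.simulate_dataset(cfg, str(outdir))
    piles = {
        (p.chrom, p.pos): p
        for p in pileup.read_alignments(paths["sam"], paths["fasta"])
    }
    return {
        "config": cfg,
        "paths": paths,
        "result": result,
        "pileups": piles,
        "reference": syscall._reference_map(paths["fasta"]),
        "truth": {(t.chrom, t.pos): t for t in result.truth},
    }


@pytest.fixture(scope="session")
def clean_dataset(tmp_path_factory):
    """Dataset with no planted sites; ~2e5 overlapping pairs."""
    cfg = simdata.SimConfig(
        seed=13,
        genome_length=40_000,
        coverage=45,
        frag_min=80,
        frag_max=120,
    )
    outdir = tmp_path_factory.mktemp("clean")
    paths, result = simdata.simulate_dataset(cfg, str(outdir))
    piles = {
        (p.chrom, p.pos): p
        for p in pileup.read_alignments(paths["sam"], paths["fasta"])
    }
    return {
        "config": cfg,
        "paths": paths,
        "result": result,
        "pileups": piles,
    }


def write_fasta(path, seqs):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def write_sam(path, seqs, records):
    """records: list of 11-field SAM tuples (already formatted)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, seq in seqs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for rec in records:
            fh.write("\t".join(str(f) for f in rec) + "\n")


def make_pileup(chrom, pos, ref_base, calls):
    """calls: list of (base, qual, strand, read_id[, mate])."""
    p = pileup.SitePileup(chrom, pos, ref_base)
    for c in calls:
        mate = c[4] if len(c) > 4 else None
        p.add(c[0], c[1], c[2], c[3], mate)
    return p
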