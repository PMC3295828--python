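"""Site-level detection statistics and characterization summaries.

Implements the expected error-proportion model, exact binomial and
quality-conditioned Poisson-binomial p-values with Bonferroni annotation,
a strand-directionality chi-square screen, and motif / substitution-spectrum
characterization of annotated systematic-error sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pileup import FORWARD, NUCLEOTIDES, REVERSE, PairCategory

logger = logging.getLogger(__name__)

# Reported p-values are clipped into this range; the binomial tail is
# evaluated via the survival function, which is exact to double precision.
P_FLOOR = 1e-320

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class CoverageSpectrum:
    """Number of analyzed sites at each pair-coverage depth."""

    counts: dict[int, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative site count in coverage spectrum")

    @property
    def total_sites(self) -> int:
        return sum(self.counts.values())


@dataclass(slots=True)
class ProportionHistogram:
    """Observed vs expected site counts per error-proportion bin on [0, 1]."""

    edges: np.ndarray  # length n_bins + 1
    observed: np.ndarray
    expected: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.edges[:-1],
                "bin_high": self.edges[1:],
                "observed": self.observed,
                "expected": self.expected,
            }
        )


@dataclass(frozen=True, slots=True)
class AnnotatedSite:
    """A site with its error count, p-value and Bonferroni significance call."""

    chrom: str
    pos: int
    coverage: int
    errors: int
    p_value: float
    significant: bool
    alpha_corrected: float


@dataclass(frozen=True, slots=True)
class StrandMismatchTable:
    """2x2 table of (forward, reverse) x (mismatch, match) call counts."""

    fwd_mismatch: int
    fwd_match: int
    rev_mismatch: int
    rev_match: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                [self.fwd_mismatch, self.fwd_match],
                [self.rev_mismatch, self.rev_match],
            ],
            dtype=float,
        )

    @property
    def fwd_coverage(self) -> int:
        return self.fwd_mismatch + self.fwd_match

    @property
    def rev_coverage(self) -> int:
        return self.rev_mismatch + self.rev_match


# ---------------------------------------------------------------------------
# expected-proportion model
# ---------------------------------------------------------------------------


def proportion_bin_index(k: int, n: int, bin_width: float, n_bins: int) -> int:
    """Bin index for error proportion k/n; proportion 1.0 lands in the last bin."""
    idx = int(np.floor((k / n) / bin_width))
    return min(idx, n_bins - 1)


def expected_proportion_histogram(
    spectrum: CoverageSpectrum,
    p: float,
    bin_width: float = 0.02,
    observed: Iterable[tuple[int, int]] = (),
) -> ProportionHistogram:
    """Expected number of sites per error-proportion bin under binomial error.

    For each coverage ``j`` holding ``c_j`` sites, the full Binomial(j, p)
    pmf over error counts k = 0..j is evaluated and mass ``c_j * pmf(k)`` is
    added to the bin containing k/j.  The expected counts therefore sum to
    the total number of sites.  ``observed`` is an optional iterable of
    (errors, coverage) pairs used to fill the observed counts.
    """
    if not spectrum.counts:
        raise ValueError("empty coverage spectrum")
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide 1")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    expected = np.zeros(n_bins)
    for j, c_j in spectrum.counts.items():
        if c_j == 0:
            continue
        k = np.arange(j + 1)
        pmf = sps.binom.pmf(k, j, p)
        idx = np.minimum((k / j / bin_width).astype(int), n_bins - 1)
        np.add.at(expected, idx, c_j * pmf)
    obs = np.zeros(n_bins)
    for k_i, n_i in observed:
        obs[proportion_bin_index(k_i, n_i, bin_width, n_bins)] += 1
    return ProportionHistogram(edges=edges, observed=obs, expected=expected)


# ---------------------------------------------------------------------------
# p-values
# ---------------------------------------------------------------------------


def binomial_site_pvalue(k: int, n: int, p: float) -> float:
    """Exact upper-tail binomial probability P(K >= k | n, p), k inclusive."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if k == 0:
        return 1.0
    pv = float(sps.binom.sf(k - 1, n, p))
    return float(np.clip(pv, P_FLOOR, 1.0))


def binomial_site_pvalues(
    k: np.ndarray, n: np.ndarray, p: float
) -> np.ndarray:
    """Vectorized :func:`binomial_site_pvalue`."""
    k = np.asarray(k)
    n = np.asarray(n)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("need 0 <= k <= n elementwise")
    pv = sps.binom.sf(k - 1, n, p)
    pv = np.where(k == 0, 1.0, pv)
    return np.clip(pv, P_FLOOR, 1.0)


def annotate_systematic(
    sites: Iterable[tuple[str, int, int, int]],
    p: float,
    alpha: float = 0.05,
    family_size: int | None = None,
) -> list[AnnotatedSite]:
    """Bonferroni-corrected binomial annotation of systematic-error sites.

    ``sites`` is an iterable of (chrom, pos, errors, coverage) tuples.  A
    site is significant when its exact binomial p-value is at most
    ``alpha / family_size``; ``family_size`` defaults to the number of sites
    supplied (all tested sites).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    site_list = list(sites)
    if family_size is None:
        family_size = len(site_list)
    if family_size <= 0:
        raise ValueError("family_size must be positive")
    if family_size < len(site_list):
        raise ValueError(
            f"family_size {family_size} smaller than number of sites {len(site_list)}"
        )
    threshold = alpha / family_size
    if not site_list:
        return []
    ks = np.array([s[2] for s in site_list])
    ns = np.array([s[3] for s in site_list])
    pvs = binomial_site_pvalues(ks, ns, p)
    return [
        AnnotatedSite(
            chrom=chrom,
            pos=pos,
            coverage=n,
            errors=k,
            p_value=float(pv),
            significant=bool(pv <= threshold),
            alpha_corrected=threshold,
        )
        for (chrom, pos, k, n), pv in zip(site_list, pvs)
    ]


def quality_dp_pvalue(error_probs: Sequence[float], k_obs: int) -> float:
    """Upper-tail Poisson-binomial p-value from per-call error probabilities.

    ``error_probs`` are the per-call error probabilities e_i (from Phred
    quality q via e = 10^(-q/10)).  The distribution of the total error
    count K is built by the dynamic-programming recurrence

        P(K_n = k) = e_n * P(K_{n-1} = k-1) + (1 - e_n) * P(K_{n-1} = k)

    in O(n^2) time and O(n) space, and P(K >= k_obs) is returned.
    """
    e = np.asarray(error_probs, dtype=float)
    n = len(e)
    if np.any((e < 0) | (e > 1)):
        raise ValueError("error probabilities must lie in [0, 1]")
    if not 0 <= k_obs <= n:
        raise ValueError(f"need 0 <= k_obs <= n, got k_obs={k_obs}, n={n}")
    dist = np.zeros(n + 1)
    dist[0] = 1.0
    for i, e_i in enumerate(e):
        # dist[: i + 2] holds P(K_i = 0..i+1) after this update
        dist[1 : i + 2] = e_i * dist[: i + 1] + (1.0 - e_i) * dist[1 : i + 2]
        dist[0] *= 1.0 - e_i
    pv = float(dist[k_obs:].sum())
    return float(np.clip(pv, P_FLOOR, 1.0))


def phred_to_error_prob(quality: int | np.ndarray) -> float | np.ndarray:
    """Phred quality q -> error probability 10^(-q/10)."""
    return 10.0 ** (-np.asarray(quality, dtype=float) / 10.0)


def directionality_chisq(
    table: StrandMismatchTable,
    correction: bool = False,
    min_per_strand: int = 10,
) -> tuple[float, float]:
    """Pearson chi-square for association of mismatches with read direction.

    1 degree of freedom, no continuity correction by default.  Requires both
    strand coverages to reach ``min_per_strand``; raises ``ValueError`` when
    a row or column margin is zero (test undefined) or coverage too low.
    """
    arr = table.as_array()
    if table.fwd_coverage < min_per_strand or table.rev_coverage < min_per_strand:
        raise ValueError(
            f"strand coverages ({table.fwd_coverage}, {table.rev_coverage}) "
            f"below minimum {min_per_strand}"
        )
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero margin: chi-square test undefined")
    expected = sps.contingency.expected_freq(arr)
    if np.any(expected < 5):
        logger.warning("chi-square expected cell count below 5; test may be unreliable")
    stat, pv, _, _ = sps.chi2_contingency(arr, correction=correction)
    return float(stat), float(pv)


# ---------------------------------------------------------------------------
# characterization
# ---------------------------------------------------------------------------


def motif_counts(
    sites: Iterable[tuple[str, int, str]],
    reference: Mapping[str, str],
    window: Sequence[int] = tuple(range(-6, 7)),
    stratify: bool = False,
) -> pd.DataFrame | dict[str, pd.DataFrame]:
    """Reference-base counts at each offset around annotated error sites.

    ``sites`` yields (chrom, pos, direction) with direction the
    error-enriched read orientation.  For reverse-direction sites the window
    walks the reverse complement, so offset -1 is one base downstream on the
    forward reference, complemented.  Sites whose window leaves the contig
    are dropped (and logged).  With ``stratify=True`` a dict keyed by the
    site's (direction-oriented) reference base is returned.
    """
    offsets = list(window)

    def empty() -> pd.DataFrame:
        return pd.DataFrame(
            0, index=list(NUCLEOTIDES), columns=offsets, dtype=int
        )

    total = empty()
    strata: dict[str, pd.DataFrame] = {}
    n_dropped = 0
    for chrom, pos, direction in sites:
        seq = reference[chrom]
        row_bases = {}
        ok = True
        for off in offsets:
            gpos = pos + off if direction == FORWARD else pos - off
            if not 0 <= gpos < len(seq):
                ok = False
                break
            base = seq[gpos]
            if direction == REVERSE:
                base = COMPLEMENT[base]
            if base not in NUCLEOTIDES:
                ok = False
                break
            row_bases[off] = base
        if not ok:
            n_dropped += 1
            continue
        for off, base in row_bases.items():
            total.loc[base, off] += 1
        if stratify:
            b0 = row_bases[0]
            if b0 not in strata:
                strata[b0] = empty()
            for off, base in row_bases.items():
                strata[b0].loc[base, off] += 1
    if n_dropped:
        logger.info("motif_counts: dropped %d sites at contig edges", n_dropped)
    return strata if stratify else total


def substitution_spectrum(
    substitutions: Iterable[tuple[str, str]],
) -> pd.DataFrame:
    """4x4 reference-base x called-base count matrix (diagonal zero).

    ``substitutions`` yields (ref_base, called_base) pairs for identified
    error calls.  Same-base pairs are rejected.
    """
    mat = pd.DataFrame(
        0, index=list(NUCLEOTIDES), columns=list(NUCLEOTIDES), dtype=int
    )
    for ref, called in substitutions:
        if ref not in NUCLEOTIDES or called not in NUCLEOTIDES:
            raise ValueError(f"invalid substitution {ref!r}>{called!r}")
        if ref == called:
            raise ValueError(f"substitution {ref}>{called} is not a mismatch")
        mat.loc[ref, called] += 1
    return mat


def pair_substitutions(
    paircalls, ref_bases: Mapping[tuple[str, int], str]
) -> list[tuple[str, str]]:
    """(ref, erroneous call) for the mismatching side of each error pair."""
    subs = []
    for pc in paircalls:
        if pc.category is not PairCategory.ERROR_PAIR:
            continue
        ref = ref_bases[(pc.chrom, pc.pos)]
        bad = pc.call_fwd.base if pc.call_fwd.base != ref else pc.call_rev.base
        subs.append((ref, bad))
    return subs


def motif_site_index(
    reference: Mapping[str, str], motif: str = "GGT"
) -> list[tuple[str, int, str]]:
    """All motif occurrences on both strands; site = last motif base.

    Returns (chrom, pos, direction) where pos is the genomic position of the
    motif's final base on its strand (for GGT, the T at which errors
    concentrate) and direction the strand carrying the motif.
    """
    rc = revcomp(motif)
    w = len(motif)
    out = []
    for chrom, seq in reference.items():
        for i in range(len(seq) - w + 1):
            tri = seq[i : i + w]
            if tri == motif:
                out.append((chrom, i + w - 1, FORWARD))
            if tri == rc:
                out.append((chrom, i, REVERSE))
    return out


def restricted_motif_annotation(
    sites: Iterable[tuple[str, int, int, int]],
    p_motif: float,
    alpha: float = 0.05,
    family_size: int | None = None,
) -> list[AnnotatedSite]:
    """Binomial/Bonferroni annotation restricted to motif sites.

    Identical machinery to :func:`annotate_systematic` but with a
    motif-specific background error rate; the Bonferroni family defaults to
    the number of motif sites tested.
    """
    return annotate_systematic(sites, p_motif, alpha=alpha, family_size=family_size)


# ---------------------------------------------------------------------------
# worked closed forms
# ---------------------------------------------------------------------------


def expected_replication_overlap(n1: int, n2: int, N: int) -> float:
    """Expected overlap of two independent random subsets of sizes n1, n2 of N."""
    if N <= 0:
        raise ValueError("N must be positive")
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise ValueError("need 0 <= n1, n2 <= N")
    return n1 * n2 / N


def same_strand_probability(k: int) -> float:
    """Probability that k independent fair strand assignments all coincide.

    Each of the two specific strands has probability (1/2)^k, hence
    2 * (1/2)^k overall; for k = 1 this is 1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return 2.0 * 0.5**k
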