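"""Logistic-regression classifier separating heterozygous sites from systematic errors.

The classifier works on per-site feature vectors built from any aligned
dataset (single- or paired-end): the two upstream reference bases and the
base at the site in the error-enriched read direction, the difference and
magnitude of per-direction mismatch proportions, and a paired t statistic
contrasting quality scores at the site against the neighboring position.
Training requires overlapping mate pairs (to label sites with certainty);
classification does not.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pileup import (
    FORWARD,
    NUCLEOTIDES,
    REVERSE,
    PairCategory,
    SitePairCounts,
    SitePileup,
)
from .stats import COMPLEMENT

logger = logging.getLogger(__name__)

LABEL_SYSTEMATIC = 0
LABEL_HETEROZYGOUS = 1

#: Sentinel for a paired-t with zero-variance, nonzero-mean differences.
PT_CAP = 100.0

#: Encoded design column names: intercept, one-hot nucleotide indicators with
#: reference level A for the three context bases, then the numeric features.
FEATURE_NAMES = (
    ["intercept"]
    + [f"b_minus2_{b}" for b in "CGT"]
    + [f"b_minus1_{b}" for b in "CGT"]
    + [f"b0_{b}" for b in "CGT"]
    + ["delta_q", "q1", "pt"]
)


class SiteRejected(ValueError):
    """A site cannot be made into a feature vector; carries the reason."""


@dataclass(frozen=True, slots=True)
class FeatureVector:
    """Per-site classifier features.

    ``b_minus2``, ``b_minus1``, ``b_0`` are reference bases at offsets
    -2, -1, 0 walking in the chosen read direction (reverse-complemented for
    the reverse direction); ``q1``/``delta_q`` are the larger per-direction
    mismatch proportion and its excess over the other direction; ``pt`` is
    the paired t statistic of site vs next-position quality scores.
    """

    chrom: str
    pos: int
    direction: str
    b_minus2: str
    b_minus1: str
    b_0: str
    delta_q: float
    q1: float
    pt: float


@dataclass(slots=True)
class LogisticModel:
    """Fitted coefficients over the encoded design, keyed by training coverage."""

    beta: np.ndarray
    feature_names: tuple[str, ...] = tuple(FEATURE_NAMES)
    training_coverage: float = float("nan")
    ridge_used: bool = False
    dropped_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.beta) != len(self.feature_names):
            raise ValueError("coefficient count does not match design width")

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """P(heterozygous) = logistic(X @ beta)."""
        eta = np.asarray(X, dtype=float) @ self.beta
        return 1.0 / (1.0 + np.exp(-eta))

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "beta": [float(b) for b in self.beta],
            "training_coverage": self.training_coverage,
            "ridge_used": self.ridge_used,
            "dropped_columns": list(self.dropped_columns),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticModel":
        return cls(
            beta=np.array(d["beta"], dtype=float),
            feature_names=tuple(d["feature_names"]),
            training_coverage=float(d["training_coverage"]),
            ridge_used=bool(d.get("ridge_used", False)),
            dropped_columns=tuple(d.get("dropped_columns", ())),
        )


@dataclass(slots=True)
class ModelBank:
    """Models trained at increasing coverage depths; selection by nearest depth."""

    models: list[LogisticModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.models.sort(key=lambda m: m.training_coverage)

    def add(self, model: LogisticModel) -> None:
        self.models.append(model)
        self.models.sort(key=lambda m: m.training_coverage)

    def select(self, coverage: float) -> LogisticModel:
        """Model with training coverage closest to ``coverage``; ties -> deeper."""
        if not self.models:
            raise ValueError("empty model bank")
        best = None
        best_key = None
        for m in self.models:
            key = (abs(m.training_coverage - coverage), -m.training_coverage)
            if best_key is None or key < best_key:
                best, best_key = m, key
        return best

    def to_json(self, path: str, meta: dict | None = None) -> None:
        payload = {
            "format": "syserr-model-bank",
            "version": 1,
            "encoding": "one-hot nucleotide contexts, reference level A",
            "models": [m.to_dict() for m in self.models],
        }
        if meta:
            payload["meta"] = meta
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "ModelBank":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "syserr-model-bank":
            raise ValueError(f"{path} is not a model-bank file")
        return cls(models=[LogisticModel.from_dict(d) for d in payload["models"]])


@dataclass(frozen=True, slots=True)
class Classification:
    """Posterior probability of a true heterozygous site, with 0.5-threshold label."""

    chrom: str
    pos: int
    posterior: float
    label: str  # "heterozygous" | "systematic_error"


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------


def choose_direction(site: SitePileup) -> tuple[str, float, float]:
    """Pick the read direction with the larger mismatch proportion.

    Returns (direction, q1, q2) with q1 the mismatch proportion in the
    chosen direction and q2 in the other.  A direction with no calls has
    proportion 0.  Ties choose forward.  Sites without any mismatching call
    are rejected.
    """
    n_fwd, n_rev = site.strand_counts()
    mm_fwd, mm_rev = site.mismatch_counts()
    if mm_fwd + mm_rev == 0:
        raise SiteRejected(
            f"{site.chrom}:{site.pos}: no base-call differs from the reference"
        )
    q_fwd = mm_fwd / n_fwd if n_fwd else 0.0
    q_rev = mm_rev / n_rev if n_rev else 0.0
    if q_fwd >= q_rev:
        return FORWARD, q_fwd, q_rev
    return REVERSE, q_rev, q_fwd


def paired_t(w0: Sequence[float], w1: Sequence[float]) -> float:
    """Paired t statistic on two equal-length quality vectors.

    t = mean(d) / (sd(d) / sqrt(n)) with d = w0 - w1 paired by read.
    Degenerate cases: fewer than 2 pairs -> 0; zero-variance differences
    with nonzero mean -> +/-100 (sign of the mean).
    """
    w0 = np.asarray(w0, dtype=float)
    w1 = np.asarray(w1, dtype=float)
    if w0.shape != w1.shape:
        raise ValueError("paired vectors must have equal length")
    n = len(w0)
    if n < 2:
        return 0.0
    d = w0 - w1
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return 0.0
        return math.copysign(PT_CAP, mean)
    return float(mean / (sd / math.sqrt(n)))


def _paired_quality_vectors(
    site: SitePileup, neighbor: SitePileup | None
) -> tuple[list[int], list[int]]:
    """Quality scores paired by read between the site and its neighbor."""
    if neighbor is None:
        return [], []
    w0, w1 = [], []
    nb = {
        (rid, strand, mate): q
        for rid, strand, mate, q in zip(
            neighbor.read_ids, neighbor.strands, neighbor.mates, neighbor.quals
        )
    }
    for rid, strand, mate, q in zip(
        site.read_ids, site.strands, site.mates, site.quals
    ):
        key = (rid, strand, mate)
        if key in nb:
            w0.append(q)
            w1.append(nb[key])
    return w0, w1


def extract_features(
    site: SitePileup,
    reference: Mapping[str, str],
    pileups: Mapping[tuple[str, int], SitePileup],
) -> FeatureVector:
    """Assemble the feature vector for one candidate site.

    ``pileups`` must allow lookup of the neighboring position (one step
    onward in the chosen direction) so the paired-t feature can be computed;
    quality vectors pair all reads covering both positions, regardless of
    direction.  Sites too close to a contig edge are rejected.
    """
    direction, q1, q2 = choose_direction(site)
    seq = reference[site.chrom]
    if direction == FORWARD:
        offsets = {(-2): site.pos - 2, (-1): site.pos - 1, 0: site.pos}
        next_pos = site.pos + 1
    else:
        offsets = {(-2): site.pos + 2, (-1): site.pos + 1, 0: site.pos}
        next_pos = site.pos - 1
    if not all(0 <= g < len(seq) for g in offsets.values()) or not (
        0 <= next_pos < len(seq)
    ):
        raise SiteRejected(f"{site.chrom}:{site.pos}: window leaves contig")
    bases = {}
    for off, gpos in offsets.items():
        b = seq[gpos]
        if direction == REVERSE:
            b = COMPLEMENT[b]
        if b not in NUCLEOTIDES:
            raise SiteRejected(
                f"{site.chrom}:{site.pos}: ambiguous reference base in context"
            )
        bases[off] = b
    neighbor = pileups.get((site.chrom, next_pos))
    w0, w1 = _paired_quality_vectors(site, neighbor)
    pt = paired_t(w0, w1)
    return FeatureVector(
        chrom=site.chrom,
        pos=site.pos,
        direction=direction,
        b_minus2=bases[-2],
        b_minus1=bases[-1],
        b_0=bases[0],
        delta_q=q1 - q2,
        q1=q1,
        pt=pt,
    )


def encode_features(
    features: Sequence[FeatureVector], delta_q_only: bool = False
) -> np.ndarray:
    """Encode feature vectors into the numeric design matrix (with intercept).

    Context bases are one-hot encoded with reference level A (three
    indicator columns each).  ``delta_q_only=True`` yields the two-column
    directionality-bias-only design (intercept, delta_q) used for ablation.
    """
    if delta_q_only:
        X = np.ones((len(features), 2))
        X[:, 1] = [f.delta_q for f in features]
        return X
    X = np.zeros((len(features), len(FEATURE_NAMES)))
    X[:, 0] = 1.0
    for i, f in enumerate(features):
        col = 1
        for b in (f.b_minus2, f.b_minus1, f.b_0):
            for j, nt in enumerate("CGT"):
                X[i, col + j] = 1.0 if b == nt else 0.0
            col += 3
        X[i, 10] = f.delta_q
        X[i, 11] = f.q1
        X[i, 12] = f.pt
    return X


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, bool]:
    """Newton/IRLS maximization of the (optionally ridge-penalized) log-likelihood."""
    n, d = X.shape
    beta = np.zeros(d)
    ll_prev = -np.inf
    penalty = np.eye(d) * ridge
    penalty[0, 0] = 0.0  # intercept unpenalized
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -500, 500)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        grad = X.T @ (y - mu) - penalty @ beta
        hess = (X * w[:, None]).T @ X + penalty
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + step
        eta = np.clip(X @ beta, -500, 500)
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-300, 1 - 1e-16)
        ll = float(y @ np.log(mu) + (1 - y) @ np.log1p(-mu))
        ll -= 0.5 * float(beta @ penalty @ beta)
        if abs(ll - ll_prev) < tol * (abs(ll_prev) + 1e-12):
            if not np.all(np.isfinite(beta)):
                return beta, False
            if ridge == 0.0 and np.max(np.abs(beta)) > 30.0:
                return beta, False  # likely separation: coefficients diverging
            return beta, True
        ll_prev = ll
    return beta, False


def train(
    X: np.ndarray,
    y: Sequence[int],
    seed: int | None = None,
    feature_names: Sequence[str] | None = None,
    training_coverage: float = float("nan"),
    ridge: float = 1e-4,
) -> LogisticModel:
    """Maximum-likelihood logistic fit of P(heterozygous | features).

    Convergence: relative log-likelihood change < 1e-8 within 100 Newton
    iterations.  Constant non-intercept columns are dropped with a warning
    (their coefficients reported as 0).  On perfect separation or other
    non-convergence the fit is repeated with a small ridge penalty
    (lambda = 1e-4) and flagged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if feature_names is None:
        feature_names = (
            FEATURE_NAMES if X.shape[1] == len(FEATURE_NAMES) else
            ["intercept"] + [f"x{i}" for i in range(1, X.shape[1])]
        )
    if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 examples of each class")
    keep = [0] + [
        j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0
    ]
    dropped = tuple(
        feature_names[j] for j in range(1, X.shape[1]) if j not in keep
    )
    if dropped:
        warnings.warn(f"dropping constant feature columns: {dropped}")
    Xk = X[:, keep]
    beta_k, ok = _irls(Xk, y)
    ridge_used = False
    if not ok:
        beta_k, ok = _irls(Xk, y, ridge=ridge)
        ridge_used = True
        if not ok:
            raise RuntimeError(
                "logistic fit failed to converge even with ridge fallback "
                f"(n={len(y)}, d={Xk.shape[1]}, ridge={ridge})"
            )
    beta = np.zeros(X.shape[1])
    beta[keep] = beta_k
    return LogisticModel(
        beta=beta,
        feature_names=tuple(feature_names),
        training_coverage=training_coverage,
        ridge_used=ridge_used,
        dropped_columns=dropped,
    )


def build_training_sets(
    pileups: Mapping[tuple[str, int], SitePileup],
    pair_counts: Mapping[tuple[str, int], SitePairCounts],
    coverage_min: int = 40,
    band: tuple[float, float] = (0.10, 0.90),
    rng: np.random.Generator | None = None,
    balance: bool = True,
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """High-certainty (SNP sites, systematic-error sites) from pair evidence.

    Candidate sites have pair coverage >= ``coverage_min`` and a
    forward-strand mismatch fraction inside ``band``.  Sites where every
    difference from the reference is a SNP pair go to the SNP set; sites
    where every difference is an error pair go to the systematic-error set;
    mixed-evidence sites are excluded.  With ``balance=True`` the larger set
    is randomly downsampled to the size of the smaller.
    """
    if rng is None:
        rng = np.random.default_rng()
    snp_sites: list[tuple[str, int]] = []
    err_sites: list[tuple[str, int]] = []
    for key, pc in pair_counts.items():
        if pc.n_pairs < coverage_min:
            continue
        pile = pileups.get(key)
        if pile is None:
            continue
        n_fwd, _ = pile.strand_counts()
        mm_fwd, _ = pile.mismatch_counts()
        if n_fwd == 0:
            continue
        frac = mm_fwd / n_fwd
        if not band[0] <= frac <= band[1]:
            continue
        n_diff = pc.n_snp + pc.n_err + pc.n_discordant
        if n_diff == 0:
            continue
        if pc.n_snp == n_diff:
            snp_sites.append(key)
        elif pc.n_err == n_diff:
            err_sites.append(key)
    if not snp_sites or not err_sites:
        raise ValueError(
            f"training aborted: {len(snp_sites)} SNP and {len(err_sites)} "
            "systematic-error sites found; both classes required"
        )
    if balance:
        m = min(len(snp_sites), len(err_sites))
        if len(snp_sites) > m:
            idx = rng.choice(len(snp_sites), size=m, replace=False)
            snp_sites = [snp_sites[i] for i in sorted(idx)]
        elif len(err_sites) > m:
            idx = rng.choice(len(err_sites), size=m, replace=False)
            err_sites = [err_sites[i] for i in sorted(idx)]
    return snp_sites, err_sites


def candidate_sites(
    pileups: Iterable[SitePileup],
    min_frac: float = 0.10,
    min_diff: int = 5,
) -> list[tuple[str, int]]:
    """Sites with >= ``min_frac`` of calls and >= ``min_diff`` calls mismatching."""
    out = []
    for pile in pileups:
        mm = pile.n_mismatches
        if mm >= min_diff and mm / pile.coverage >= min_frac:
            out.append((pile.chrom, pile.pos))
    return out


def mean_coverage(pileups: Iterable[SitePileup]) -> float:
    """Mean call depth over covered positions."""
    total = n = 0
    for pile in pileups:
        total += pile.coverage
        n += 1
    if n == 0:
        raise ValueError("no covered positions")
    return total / n


def features_for_sites(
    sites: Iterable[tuple[str, int]],
    pileups: Mapping[tuple[str, int], SitePileup],
    reference: Mapping[str, str],
) -> tuple[list[FeatureVector], list[tuple[str, int, str]]]:
    """Extract features for each site; returns (features, rejects-with-reason)."""
    feats: list[FeatureVector] = []
    rejects: list[tuple[str, int, str]] = []
    for key in sites:
        pile = pileups.get(tuple(key))
        if pile is None:
            rejects.append((key[0], key[1], "no coverage"))
            continue
        try:
            feats.append(extract_features(pile, reference, pileups))
        except SiteRejected as exc:
            rejects.append((key[0], key[1], str(exc)))
    return feats, rejects


def train_bank(
    sam_path: str,
    fasta_path: str,
    fractions: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0),
    seed: int = 0,
    coverage_min: int = 40,
    single_end: bool = True,
    min_pair_coverage: int = 10,
) -> ModelBank:
    """Train a coverage-stratified model bank from overlapping paired reads.

    High-certainty training labels are derived once from the full-coverage
    pair evidence.  For each fraction the reads are subsampled without
    replacement, labeled sites are refined to those retaining at least one
    mismatching call, features are rebuilt on the subsampled pileups and a
    model is fitted; the bank is keyed by the realized mean coverage.  With
    ``single_end=True`` one read of each mate pair is dropped at random
    before feature building, emulating a non-paired dataset.  Fractions
    whose refined data lose a class are skipped with a warning.
    """
    from .pileup import pair_overlaps, read_alignments, tally_pairs

    rng = np.random.default_rng(seed)
    pileups = {(p.chrom, p.pos): p for p in read_alignments(sam_path, fasta_path)}
    pair_counts = tally_pairs(pair_overlaps(pileups.values()))
    snp_sites, err_sites = build_training_sets(
        pileups, pair_counts, coverage_min=coverage_min, rng=rng
    )
    reference = _reference_map(fasta_path)

    fragment_ids = sorted(
        {rid for p in pileups.values() for rid in p.read_ids}
    )
    drop_mate = (
        {rid: int(rng.integers(1, 3)) for rid in fragment_ids}
        if single_end
        else {}
    )

    bank = ModelBank()
    for frac in fractions:
        if not 0.0 < frac <= 1.0:
            raise ValueError(f"fraction {frac} outside (0, 1]")
        n_keep = int(round(frac * len(fragment_ids)))
        keep_idx = rng.choice(len(fragment_ids), size=n_keep, replace=False)
        keep = {fragment_ids[i] for i in keep_idx}
        sub = _subsample_pileups(pileups, keep, drop_mate)
        labeled = [(s, LABEL_HETEROZYGOUS) for s in snp_sites] + [
            (s, LABEL_SYSTEMATIC) for s in err_sites
        ]
        feats, labels = [], []
        for key, lab in labeled:
            pile = sub.get(key)
            if pile is None or pile.n_mismatches == 0:
                continue
            try:
                feats.append(extract_features(pile, reference, sub))
                labels.append(lab)
            except SiteRejected:
                continue
        labels_arr = np.array(labels)
        if (
            len(labels_arr) == 0
            or min((labels_arr == 0).sum(), (labels_arr == 1).sum()) < 2
        ):
            warnings.warn(
                f"fraction {frac}: a training class is empty after refinement; skipped"
            )
            continue
        X = encode_features(feats)
        cov = mean_coverage(sub.values())
        model = train(X, labels_arr, training_coverage=cov)
        bank.add(model)
    if not bank.models:
        raise RuntimeError("no model could be trained at any fraction")
    return bank


def _reference_map(fasta_path: str) -> dict[str, str]:
    import pysam

    with pysam.FastaFile(fasta_path) as fa:
        return {name: fa.fetch(name).upper() for name in fa.references}


def _subsample_pileups(
    pileups: Mapping[tuple[str, int], SitePileup],
    keep_fragments: set[str],
    drop_mate: Mapping[str, int],
) -> dict[tuple[str, int], SitePileup]:
    sub: dict[tuple[str, int], SitePileup] = {}
    for key, pile in pileups.items():
        new = SitePileup(pile.chrom, pile.pos, pile.ref_base)
        for b, q, s, rid, m in zip(
            pile.bases, pile.quals, pile.strands, pile.read_ids, pile.mates
        ):
            if rid not in keep_fragments:
                continue
            if rid in drop_mate and m == drop_mate[rid]:
                continue
            new.add(b, q, s, rid, m)
        if new.coverage:
            sub[key] = new
    return sub


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict(
    bank: ModelBank,
    sites: Sequence[tuple[str, int]],
    pileups: Mapping[tuple[str, int], SitePileup],
    reference: Mapping[str, str],
    delta_q_only: bool = False,
) -> tuple[list[Classification], list[tuple[str, int, str]]]:
    """Classify candidate sites with the model nearest the dataset's coverage.

    Returns (classifications, rejects); the union of classified and rejected
    sites equals the input candidate list.  Posterior >= 0.5 labels a site
    heterozygous, < 0.5 a systematic error.
    """
    cov = mean_coverage(pileups.values())
    model = bank.select(cov)
    feats, rejects = features_for_sites(sites, pileups, reference)
    out: list[Classification] = []
    if feats:
        X = encode_features(feats, delta_q_only=delta_q_only)
        post = model.posterior(X)
        for f, pi in zip(feats, post):
            label = "heterozygous" if pi >= 0.5 else "systematic_error"
            out.append(Classification(f.chrom, f.pos, float(pi), label))
    return out, rejects
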