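import math
import warnings

import numpy as np
import pytest
import scipy.stats

from syserr import pileup, syscall
from syserr.pileup import FORWARD, REVERSE, SitePairCounts
from syserr.syscall import (
    FEATURE_NAMES,
    Classification,
    FeatureVector,
    LogisticModel,
    ModelBank,
    SiteRejected,
    build_training_sets,
    candidate_sites,
    choose_direction,
    encode_features,
    extract_features,
    paired_t,
    predict,
    train,
)

from conftest import make_pileup


# ---------------------------------------------------------------------------
# choose_direction
# ---------------------------------------------------------------------------


def test_choose_direction_all_forward_mismatch():
    # every forward call differs from the reference, no reverse mismatch
    calls = [("G", 30, FORWARD, f"r{i}") for i in range(5)] + [
        ("T", 30, REVERSE, f"s{i}") for i in range(5)
    ]
    site = make_pileup("c", 10, "T", calls)
    assert choose_direction(site) == (FORWARD, 1.0, 0.0)


def test_choose_direction_tie_prefers_forward():
    calls = [
        ("G", 30, FORWARD, "a"),
        ("T", 30, FORWARD, "b"),
        ("G", 30, REVERSE, "c"),
        ("T", 30, REVERSE, "d"),
    ]
    d, q1, q2 = choose_direction(make_pileup("c", 10, "T", calls))
    assert d == FORWARD
    assert q1 == q2 == 0.5


def test_choose_direction_reverse_only_mismatch():
    calls = [("T", 30, FORWARD, "a"), ("G", 30, REVERSE, "b"), ("G", 30, REVERSE, "c")]
    d, q1, q2 = choose_direction(make_pileup("c", 10, "T", calls))
    assert d == REVERSE
    assert q1 == 1.0
    assert q2 == 0.0


def test_choose_direction_uncovered_direction_proportion_zero():
    calls = [("G", 30, FORWARD, "a"), ("T", 30, FORWARD, "b")]
    d, q1, q2 = choose_direction(make_pileup("c", 10, "T", calls))
    assert (d, q1, q2) == (FORWARD, 0.5, 0.0)


def test_choose_direction_rejects_clean_site():
    calls = [("T", 30, FORWARD, "a"), ("T", 30, REVERSE, "b")]
    with pytest.raises(SiteRejected):
        choose_direction(make_pileup("c", 10, "T", calls))


# ---------------------------------------------------------------------------
# paired t
# ---------------------------------------------------------------------------


def test_paired_t_equal_vectors():
    assert paired_t([30, 31, 32], [30, 31, 32]) == 0.0


def test_paired_t_constant_shift_capped():
    assert paired_t([30, 28, 32, 30], [31, 29, 33, 31]) == -100.0
    assert paired_t([31, 29, 33, 31], [30, 28, 32, 30]) == 100.0


def test_paired_t_too_few_pairs():
    assert paired_t([30], [31]) == 0.0
    assert paired_t([], []) == 0.0


def test_paired_t_matches_scipy_oracle():
    rng = np.random.default_rng(3)
    for _ in range(10):
        w0 = rng.normal(30, 4, 20)
        w1 = rng.normal(31, 4, 20)
        expected = scipy.stats.ttest_rel(w0, w1).statistic
        assert paired_t(w0, w1) == pytest.approx(expected, rel=1e-10)


def test_paired_t_length_mismatch():
    with pytest.raises(ValueError):
        paired_t([1, 2], [1])


# ---------------------------------------------------------------------------
# extract_features
# ---------------------------------------------------------------------------


def _site_with_neighbors(ref_seq, pos, site_calls, neighbor_calls, neighbor_pos):
    piles = {
        ("c", pos): make_pileup("c", pos, ref_seq[pos], site_calls),
        ("c", neighbor_pos): make_pileup(
            "c", neighbor_pos, ref_seq[neighbor_pos], neighbor_calls
        ),
    }
    return piles


def test_extract_features_forward_context():
    ref = {"c": "AAGGTAAAA"}
    # site at the T (pos 4), all forward calls mismatching
    site_calls = [("G", 20, FORWARD, f"r{i}") for i in range(4)]
    nbr_calls = [("A", 30, FORWARD, f"r{i}") for i in range(4)]
    piles = _site_with_neighbors(ref["c"], 4, site_calls, nbr_calls, 5)
    fv = extract_features(piles[("c", 4)], ref, piles)
    assert (fv.b_minus2, fv.b_minus1, fv.b_0) == ("G", "G", "T")
    assert fv.q1 == 1.0
    assert fv.delta_q == 1.0
    assert fv.pt < -5  # site qualities uniformly 10 below neighbor


def test_extract_features_reverse_context_revcomp():
    # forward sequence ...ACC...: reverse-strand motif GGT with site at the A
    ref = {"c": "TTTTACCTT"}
    site_calls = [("C", 20, REVERSE, f"r{i}") for i in range(3)] + [
        ("A", 30, FORWARD, "f0")
    ]
    nbr_calls = [("T", 30, REVERSE, f"r{i}") for i in range(3)]
    piles = _site_with_neighbors(ref["c"], 4, site_calls, nbr_calls, 3)
    fv = extract_features(piles[("c", 4)], ref, piles)
    assert fv.direction == REVERSE
    assert (fv.b_minus2, fv.b_minus1, fv.b_0) == ("G", "G", "T")
    assert fv.q1 == 1.0
    assert fv.delta_q == 1.0


def test_extract_features_edge_rejected():
    ref = {"c": "ACGT"}
    calls = [("T", 20, FORWARD, "r0")]
    piles = {("c", 1): make_pileup("c", 1, "C", calls)}
    with pytest.raises(SiteRejected):
        extract_features(piles[("c", 1)], ref, piles)


def test_extract_features_planted_context_simulation(planted_dataset):
    # GGT-planted systematic sites must expose the G,G,T context when the
    # affected direction is chosen
    ref = planted_dataset["reference"]
    piles = planted_dataset["pileups"]
    checked = 0
    for key, t in planted_dataset["truth"].items():
        if t.site_type != "syserr":
            continue
        ctx = ref[t.chrom][t.pos - 2 : t.pos + 1]
        rc_ctx = ref[t.chrom][t.pos : t.pos + 3]
        is_ggt = (t.affected_strand == FORWARD and ctx == "GGT") or (
            t.affected_strand == REVERSE and rc_ctx == "ACC"
        )
        if not is_ggt or key not in piles:
            continue
        pile = piles[key]
        try:
            fv = extract_features(pile, ref, piles)
        except SiteRejected:
            continue
        if fv.direction == t.affected_strand:
            assert (fv.b_minus2, fv.b_minus1, fv.b_0) == ("G", "G", "T")
            checked += 1
    assert checked >= 3


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


def _fv(b2="A", b1="A", b0="A", dq=0.0, q1=0.0, pt=0.0):
    return FeatureVector("c", 0, FORWARD, b2, b1, b0, dq, q1, pt)


def test_encode_one_hot_reference_level_A():
    X = encode_features([_fv()])
    assert X.shape == (1, 13)
    assert X[0, 0] == 1.0
    assert X[0, 1:10].sum() == 0.0  # A is the reference level everywhere


def test_encode_one_hot_positions():
    X = encode_features([_fv(b2="C", b1="G", b0="T", dq=0.2, q1=0.5, pt=-3.0)])
    names = dict(zip(FEATURE_NAMES, X[0]))
    assert names["b_minus2_C"] == 1.0
    assert names["b_minus1_G"] == 1.0
    assert names["b0_T"] == 1.0
    assert names["delta_q"] == 0.2
    assert names["q1"] == 0.5
    assert names["pt"] == -3.0
    assert X[0, 1:10].sum() == 3.0


def test_encode_delta_q_only():
    X = encode_features([_fv(dq=0.7)], delta_q_only=True)
    assert X.shape == (1, 2)
    assert X[0].tolist() == [1.0, 0.7]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _random_design(rng, n, d=13):
    X = np.ones((n, d))
    X[:, 1:10] = rng.integers(0, 2, size=(n, 9))
    X[:, 10] = rng.random(n)
    X[:, 11] = rng.random(n)
    X[:, 12] = rng.normal(0, 3, n)
    return X


def test_train_null_model_coefficients_near_zero():
    rng = np.random.default_rng(42)
    X = _random_design(rng, 4000)
    y = rng.integers(0, 2, 4000)
    model = train(X, y)
    # labels independent of features: each coefficient within 3 SE of 0
    mu = model.posterior(X)
    W = mu * (1 - mu)
    cov = np.linalg.inv((X * W[:, None]).T @ X)
    se = np.sqrt(np.diag(cov))
    assert np.all(np.abs(model.beta[1:]) < 3 * se[1:])


def test_train_perfect_separation_ridge_fallback():
    rng = np.random.default_rng(1)
    X = np.ones((200, 3))
    X[:, 1] = rng.normal(0, 1, 200)
    X[:, 2] = np.r_[np.full(100, -1.0), np.full(100, 1.0)]
    y = np.r_[np.zeros(100), np.ones(100)]
    model = train(X, y, feature_names=["intercept", "noise", "sep"])
    assert model.ridge_used
    assert model.beta[2] > 0  # sign of the separating feature preserved


def test_train_parameter_recovery():
    rng = np.random.default_rng(7)
    beta_true = np.array(
        [0.5, -1.0, 0.8, 0.0, 1.2, -0.5, 0.3, 0.0, -0.7, 0.9, 2.0, -1.5, 0.4]
    )
    X = _random_design(rng, 5000)
    p = 1 / (1 + np.exp(-X @ beta_true))
    y = rng.random(5000) < p
    model = train(X, y.astype(int))
    assert not model.ridge_used
    mu = model.posterior(X)
    W = mu * (1 - mu)
    se = np.sqrt(np.diag(np.linalg.inv((X * W[:, None]).T @ X)))
    assert np.all(np.abs(model.beta - beta_true) < 3 * se)


def test_train_matches_statsmodels_oracle():
    import statsmodels.api as sm

    rng = np.random.default_rng(9)
    X = _random_design(rng, 1500)
    beta_true = rng.normal(0, 0.5, 13)
    y = (rng.random(1500) < 1 / (1 + np.exp(-X @ beta_true))).astype(int)
    model = train(X, y)
    ref = sm.Logit(y, X).fit(disp=0)
    assert np.allclose(model.beta, ref.params, atol=1e-5)


def test_train_drops_constant_column():
    rng = np.random.default_rng(3)
    X = _random_design(rng, 500)
    X[:, 4] = 1.0  # constant non-intercept column
    y = rng.integers(0, 2, 500)
    with pytest.warns(UserWarning, match="constant"):
        model = train(X, y)
    assert model.beta[4] == 0.0
    assert FEATURE_NAMES[4] in model.dropped_columns


def test_train_requires_both_classes():
    X = np.ones((10, 2))
    with pytest.raises(ValueError):
        train(X, np.ones(10))


# ---------------------------------------------------------------------------
# training-set construction
# ---------------------------------------------------------------------------


def _pair_counts(key, n_ref=0, n_snp=0, n_err=0):
    c = SitePairCounts(key[0], key[1], "A")
    c.n_ref, c.n_snp, c.n_err = n_ref, n_snp, n_err
    return c


def test_build_training_sets_definitions():
    # snp site: all 20 differences are SNP pairs, 44% fwd mismatch, cov 45
    # err site: all 12 differences are error pairs, cov 41
    piles = {}
    counts = {}
    k1 = ("c", 100)
    piles[k1] = make_pileup(
        "c", 100, "A",
        [("G" if i < 4 else "A", 30, FORWARD, f"r{i}") for i in range(9)],
    )
    counts[k1] = _pair_counts(k1, n_ref=25, n_snp=20)
    k2 = ("c", 200)
    piles[k2] = make_pileup(
        "c", 200, "A",
        [("G" if i < 3 else "A", 30, FORWARD, f"r{i}") for i in range(10)],
    )
    counts[k2] = _pair_counts(k2, n_ref=29, n_err=12)
    # mixed-evidence site: excluded
    k3 = ("c", 300)
    piles[k3] = make_pileup(
        "c", 300, "A",
        [("G" if i < 3 else "A", 30, FORWARD, f"r{i}") for i in range(10)],
    )
    counts[k3] = _pair_counts(k3, n_ref=30, n_snp=5, n_err=5)
    snp, err = build_training_sets(
        piles, counts, rng=np.random.default_rng(0), balance=False
    )
    assert snp == [k1]
    assert err == [k2]


def test_build_training_sets_coverage_and_band_filters():
    piles = {
        ("c", 1): make_pileup(
            "c", 1, "A",
            [("G" if i < 5 else "A", 30, FORWARD, f"r{i}") for i in range(10)],
        )
    }
    counts = {("c", 1): _pair_counts(("c", 1), n_ref=10, n_snp=10)}  # cov 20 < 40
    with pytest.raises(ValueError):
        build_training_sets(piles, counts, rng=np.random.default_rng(0))


def test_build_training_sets_balance():
    piles, counts = {}, {}
    for i in range(10):
        key = ("c", i)
        piles[key] = make_pileup(
            "c", i, "A",
            [("G" if j < 4 else "A", 30, FORWARD, f"r{j}") for j in range(10)],
        )
        counts[key] = _pair_counts(key, n_ref=30, n_snp=15)
    key = ("c", 99)
    piles[key] = make_pileup(
        "c", 99, "A",
        [("G" if j < 4 else "A", 30, FORWARD, f"r{j}") for j in range(10)],
    )
    counts[key] = _pair_counts(key, n_ref=30, n_err=15)
    snp, err = build_training_sets(piles, counts, rng=np.random.default_rng(1))
    assert len(snp) == len(err) == 1


def test_build_training_sets_simulation_label_agreement(planted_dataset):
    piles = planted_dataset["pileups"]
    counts = pileup.tally_pairs(pileup.pair_overlaps(piles.values()))
    truth = planted_dataset["truth"]
    snp, err = build_training_sets(
        piles, counts, coverage_min=10, rng=np.random.default_rng(2),
        balance=False,
    )
    labels = [truth[k].site_type == "het" for k in snp if k in truth] + [
        truth[k].site_type == "syserr" for k in err if k in truth
    ]
    assert len(labels) >= 8
    assert np.mean(labels) >= 0.99


# ---------------------------------------------------------------------------
# candidate sites
# ---------------------------------------------------------------------------


def _mismatch_pileup(pos, n_calls, n_mismatch):
    calls = [
        ("G" if i < n_mismatch else "A", 30, FORWARD, f"r{i}")
        for i in range(n_calls)
    ]
    return make_pileup("c", pos, "A", calls)


def test_candidate_sites_thresholds():
    piles = [
        _mismatch_pileup(1, 100, 4),   # fails min_diff
        _mismatch_pileup(2, 20, 5),    # 25%, included
        _mismatch_pileup(3, 100, 9),   # 9%, fails min_frac
        _mismatch_pileup(4, 100, 10),  # boundary: included
    ]
    assert candidate_sites(piles) == [("c", 2), ("c", 4)]


# ---------------------------------------------------------------------------
# model bank & prediction
# ---------------------------------------------------------------------------


def _model(cov, beta=None):
    b = np.zeros(13) if beta is None else beta
    return LogisticModel(beta=b, training_coverage=cov)


def test_bank_select_nearest_and_tie():
    bank = ModelBank([_model(7), _model(14), _model(21)])
    assert bank.select(8).training_coverage == 7
    assert bank.select(13).training_coverage == 14
    assert bank.select(10.5).training_coverage == 14  # tie -> deeper
    assert bank.select(100).training_coverage == 21


def test_bank_json_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    bank = ModelBank([_model(7, rng.normal(size=13)), _model(28, rng.normal(size=13))])
    path = tmp_path / "bank.json"
    bank.to_json(str(path), meta={"seed": 1})
    loaded = ModelBank.from_json(str(path))
    assert len(loaded.models) == 2
    for a, b in zip(bank.models, loaded.models):
        assert np.allclose(a.beta, b.beta)
        assert a.training_coverage == b.training_coverage


def test_predict_zero_beta_posterior_half(planted_dataset):
    piles = planted_dataset["pileups"]
    ref = planted_dataset["reference"]
    cands = candidate_sites(piles.values())[:20]
    bank = ModelBank([_model(10)])
    cls, rejects = predict(bank, cands, piles, ref)
    assert len(cls) + len(rejects) == len(cands)
    for c in cls:
        assert c.posterior == pytest.approx(0.5)
        assert c.label == "heterozygous"  # tie at 0.5 -> heterozygous


def test_predict_partition_and_permutation_invariance(planted_dataset):
    piles = planted_dataset["pileups"]
    ref = planted_dataset["reference"]
    cands = candidate_sites(piles.values())
    rng = np.random.default_rng(4)
    beta = rng.normal(0, 0.5, 13)
    bank = ModelBank([_model(10, beta)])
    cls1, rej1 = predict(bank, cands, piles, ref)
    assert {(c.chrom, c.pos) for c in cls1} | {
        (c, p) for c, p, _ in rej1
    } == set(cands)
    perm = [cands[i] for i in rng.permutation(len(cands))]
    cls2, _ = predict(bank, perm, piles, ref)
    assert {(c.chrom, c.pos, round(c.posterior, 12)) for c in cls1} == {
        (c.chrom, c.pos, round(c.posterior, 12)) for c in cls2
    }
    for c in cls1:
        assert 0.0 < c.posterior < 1.0
        assert (c.label == "heterozygous") == (c.posterior >= 0.5)


def test_posterior_monotone_in_linear_predictor():
    model = _model(10, np.r_[0.0, np.zeros(9), 2.0, 0.0, 0.0])
    grid = [_fv(dq=v) for v in np.linspace(0, 1, 11)]
    post = model.posterior(encode_features(grid))
    assert np.all(np.diff(post) > 0)
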