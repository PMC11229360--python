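import math
from functools import lru_cache

import numpy as np
import pytest

from crispr3census.profile_engine import (
    CalibrationError,
    ProfileConstructionError,
    build_profile,
    calibrate,
    evalue,
    greedy_cluster,
    gumbel_moments_fit,
    pairwise_identity,
    scan,
    uniform_background,
    window_scores,
)

AAS = "ACDEFGHIKLMNPQRSTVWY"


def _rand_seq(rng, n):
    return "".join(AAS[i] for i in rng.integers(0, 20, size=n))


# ---------------------------------------------------------------- profiles


def test_build_profile_identical_seed_symmetry():
    prof = build_profile(["ACDE"] * 3, pseudocount=1.0)
    idx = {a: i for i, a in enumerate(AAS)}
    scores = [prof.log_odds[i, idx[c]] for i, c in enumerate("ACDE")]
    assert all(s > 0 for s in scores)
    assert np.allclose(scores, scores[0])


def test_build_profile_monotone_in_counts():
    strong = build_profile(["A", "A", "A"], pseudocount=1.0)
    weak = build_profile(["A", "C", "D"], pseudocount=1.0)
    assert strong.log_odds[0, 0] > weak.log_odds[0, 0]


def test_build_profile_two_seed_hand_computed():
    # seeds AC / AD, pseudocount 1, uniform background 1/20:
    # consensus A: log2((2 + 0.05) / 3 / 0.05) = log2(41/3)
    # observed C or D: log2((1 + 0.05) / 3 / 0.05) = log2(7)
    # unobserved:     log2((0 + 0.05) / 3 / 0.05) = log2(1/3)
    prof = build_profile(["AC", "AD"], pseudocount=1.0)
    idx = {a: i for i, a in enumerate(AAS)}
    assert prof.log_odds[0, idx["A"]] == pytest.approx(math.log2(41 / 3))
    assert prof.log_odds[1, idx["C"]] == pytest.approx(math.log2(7))
    assert prof.log_odds[1, idx["D"]] == pytest.approx(math.log2(7))
    assert prof.log_odds[0, idx["W"]] == pytest.approx(math.log2(1 / 3))
    assert prof.log_odds[1, 20] == 0.0  # X always scores zero


def test_build_profile_gap_columns_dropped():
    prof = build_profile(["A-C", "A-D", "AEC"], pseudocount=1.0)
    assert prof.length == 2  # middle column is 2/3 gaps


def test_build_profile_errors():
    with pytest.raises(ProfileConstructionError):
        build_profile(["ACDE"])
    with pytest.raises(ProfileConstructionError):
        build_profile(["--", "--"])


# ---------------------------------------------------------------- scanning


def _brute_force_best(profile, seq):
    """Independent oracle: explicit per-window scoring."""
    idx = {a: i for i, a in enumerate(AAS + "X")}
    best = None
    for start in range(len(seq) - profile.length + 1):
        s = sum(
            profile.log_odds[k, idx[seq[start + k]]] for k in range(profile.length)
        )
        if best is None or s > best[1]:
            best = (start, s)
    return best


def test_scan_consensus_at_origin():
    prof = build_profile(["MKVLW", "MKVLW", "MKVLW"])
    hit = scan(prof, "MKVLW")
    assert hit.window_start == 0
    assert hit.bitscore == pytest.approx(prof.log_odds.max(axis=1).sum())


def test_scan_embedded_consensus(rng):
    prof = build_profile(["MKVLWAQ"] * 3)
    seq = _rand_seq(rng, 17) + "MKVLWAQ" + _rand_seq(rng, 30)
    hit = scan(prof, seq)
    start, score = _brute_force_best(prof, seq)
    assert hit.window_start == start == 17
    assert hit.bitscore == pytest.approx(score)


def test_scan_too_short_returns_none():
    prof = build_profile(["MKVLW"] * 2)
    assert scan(prof, "MKV") is None


def test_scan_matches_brute_force_on_random_sequences(rng):
    prof = build_profile([_rand_seq(rng, 12) for _ in range(4)])
    idx = {a: i for i, a in enumerate(AAS + "X")}
    for _ in range(25):
        seq = _rand_seq(rng, int(rng.integers(12, 200)))
        hit = scan(prof, seq)
        start, score = _brute_force_best(prof, seq)
        assert hit.bitscore == pytest.approx(score)
        # the reported window attains the brute-force maximum (fp-tolerant)
        at_hit = sum(
            prof.log_odds[k, idx[seq[hit.window_start + k]]] for k in range(prof.length)
        )
        assert at_hit == pytest.approx(score)


# ---------------------------------------------------------------- calibration


def test_calibrate_deterministic():
    a = calibrate(build_profile(["MKVLWAQRST"] * 3), seed=5)
    b = calibrate(build_profile(["MKVLWAQRST"] * 3), seed=5)
    assert (a.gumbel_mu, a.gumbel_lambda) == (b.gumbel_mu, b.gumbel_lambda)


def test_calibrate_requires_enough_shuffles():
    prof = build_profile(["MKVLW"] * 3)
    with pytest.raises(ValueError, match="n_shuffles"):
        calibrate(prof, n_shuffles=10)


def test_gumbel_moment_estimator_recovers_truth(rng):
    # Gumbel(mu=0, lambda=1) sample of 10k: estimates within 5% / 0.05
    u = rng.random(10_000)
    sample = -np.log(-np.log(u))
    mu, lam = gumbel_moments_fit(sample)
    assert abs(mu) < 0.05
    assert abs(lam - 1.0) < 0.05


def test_evalue_properties():
    prof = build_profile(["MKVLWAQRST"] * 3)
    prof.gumbel_mu, prof.gumbel_lambda = 10.0, 0.5
    e1 = evalue(20.0, prof, db_size=100)
    e2 = evalue(30.0, prof, db_size=100)
    assert e2 < e1
    assert evalue(10.0, prof, db_size=1) == pytest.approx(1 - math.exp(-1))
    assert evalue(20.0, prof, db_size=200) == pytest.approx(2 * e1)


def test_evalue_requires_calibration():
    prof = build_profile(["MKVLW"] * 3)
    with pytest.raises(CalibrationError):
        evalue(10.0, prof, db_size=10)


# ---------------------------------------------------------------- identity


def _identity_oracle(a, b):
    """Exhaustive top-down alignment oracle maximizing (score, matches, -len)."""

    @lru_cache(maxsize=None)
    def best(i, j):
        if i == 0 and j == 0:
            return (0, 0, 0)
        cands = []
        if i > 0 and j > 0:
            inc = 1 if a[i - 1] == b[j - 1] else 0
            s, m, L = best(i - 1, j - 1)
            cands.append((s + inc, m + inc, L - 1))
        if i > 0:
            s, m, L = best(i - 1, j)
            cands.append((s - 1, m, L - 1))
        if j > 0:
            s, m, L = best(i, j - 1)
            cands.append((s - 1, m, L - 1))
        return max(cands)

    s, m, L = best(len(a), len(b))
    return m / (-L)


def test_identity_examples():
    assert pairwise_identity("MKVLW", "MKVLW") == 1.0
    assert pairwise_identity("AAAA", "AAAT") == 0.75
    with pytest.raises(ValueError):
        pairwise_identity("", "A")


def test_identity_matches_dp_oracle(rng):
    for _ in range(10):
        a = _rand_seq(rng, 20)
        b = _rand_seq(rng, 20)
        assert pairwise_identity(a, b) == pytest.approx(_identity_oracle(a, b))


def test_identity_symmetric_under_swap(rng):
    for _ in range(5):
        a, b = _rand_seq(rng, 15), _rand_seq(rng, 25)
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))


# ---------------------------------------------------------------- clustering


def _brute_force_cluster(seqs, threshold):
    """Greedy assignment oracle without the word prefilter."""
    ordered = sorted(seqs, key=lambda kv: (-len(kv[1]), kv[0]))
    clusters = []
    for sid, seq in ordered:
        for cl in clusters:
            if pairwise_identity(seq, cl["rep_seq"]) >= threshold:
                cl["members"].append(sid)
                break
        else:
            clusters.append({"representative": sid, "rep_seq": seq, "members": [sid]})
    return [(c["representative"], sorted(c["members"])) for c in clusters]


def test_cluster_all_identical():
    out = greedy_cluster([("a", "MKVLW"), ("b", "MKVLW"), ("c", "MKVLW")], 0.9, 2)
    assert len(out) == 1 and len(out[0]["members"]) == 3


def test_cluster_word_prefilter_blocks_merge():
    # identical length, zero shared 3-mers: prefilter forces two clusters
    out = greedy_cluster([("a", "AAAAAA"), ("b", "CCCCCC")], 0.1, 3)
    assert len(out) == 2


def test_cluster_matches_brute_force_oracle(rng):
    # family bases mutated lightly: true pairs share plenty of words, so the
    # prefilter never rejects a >= 0.9 pair and the oracle applies
    base1, base2 = _rand_seq(rng, 40), _rand_seq(rng, 46)
    def mut(s, k):
        chars = list(s)
        for i in rng.choice(len(chars), size=k, replace=False):
            chars[i] = AAS[rng.integers(0, 20)]
        return "".join(chars)
    seqs = [(f"a{i}", mut(base1, 2)) for i in range(4)] + [
        (f"b{i}", mut(base2, 2)) for i in range(4)
    ]
    got = [(c["representative"], sorted(c["members"])) for c in greedy_cluster(seqs, 0.9, 4)]
    assert got == _brute_force_cluster(seqs, 0.9)


def test_cluster_members_reach_threshold_to_representative(rng):
    seqs = [(f"s{i}", _rand_seq(rng, int(rng.integers(20, 40)))) for i in range(12)]
    base = _rand_seq(rng, 30)
    seqs += [(f"h{i}", base[:i] + base[i:]) for i in range(3)]
    by_id = dict(seqs)
    for cl in greedy_cluster(seqs, 0.6, 2):
        rep = by_id[cl["representative"]]
        for m in cl["members"]:
            assert pairwise_identity(by_id[m], rep) >= 0.6
        # representative is a longest member
        assert len(rep) == max(len(by_id[m]) for m in cl["members"])


def test_cluster_deterministic(rng):
    seqs = [(f"s{i}", _rand_seq(rng, 25)) for i in range(10)]
    assert greedy_cluster(seqs, 0.4, 2) == greedy_cluster(list(reversed(seqs)), 0.4, 2)


def test_evalues_conservative_on_null_sequences(rng):
    """Per-sequence P(best-window E/db below p) stays near or under p on
    background-generated sequences (the Gumbel calibration is not
    anti-conservative)."""
    prof = calibrate(build_profile([_rand_seq(rng, 15) for _ in range(5)]), seed=17)
    n_null = 1000
    pvals = []
    for _ in range(n_null):
        seq = _rand_seq(rng, 400)
        hit = scan(prof, seq, db_size=1)
        pvals.append(hit.evalue)  # db_size 1: E is the per-sequence p-value
    pvals = np.array(pvals)
    for p in (0.01, 0.05):
        assert (pvals < p).mean() <= 1.5 * p
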