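"""Position-specific scoring profiles with Gumbel E-values, plus identity
clustering.

This module is the package's internal stand-in for a profile-HMM scanner and
for greedy incremental clustering. A profile is an ungapped log-odds matrix
(bits) built from an equal-length seed alignment; scanning slides it over
every window of a query and keeps the best window; significance comes from
an empirical Gumbel fit to best-window scores on i.i.d. background
sequences, so downstream E-value cutoffs keep their usual semantics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from crispr3census.sequence_io import ALPHABET, AMINO_ACIDS

_EULER_GAMMA = 0.5772156649015329
_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}  # X is index 20
N_SYMBOLS = len(ALPHABET)  # 21


class CalibrationError(RuntimeError):
    pass


class ProfileConstructionError(ValueError):
    pass


def uniform_background() -> np.ndarray:
    """Uniform frequencies over the 20 standard residues; X carries none."""
    bg = np.zeros(N_SYMBOLS)
    bg[:20] = 1.0 / 20.0
    return bg


@dataclass
class Profile:
    """Ungapped log-odds profile over the 21-letter alphabet (bits).

    The 21st column (X) always scores 0. ``gumbel_mu``/``gumbel_lambda`` are
    set by :func:`calibrate` and define the best-window score null.
    """

    name: str
    log_odds: np.ndarray  # (length, 21)
    family: str
    gumbel_mu: float | None = None
    gumbel_lambda: float | None = None

    @property
    def length(self) -> int:
        return int(self.log_odds.shape[0])

    @property
    def calibrated(self) -> bool:
        return self.gumbel_mu is not None and self.gumbel_lambda is not None

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "family": self.family,
                "log_odds": self.log_odds.tolist(),
                "gumbel_mu": self.gumbel_mu,
                "gumbel_lambda": self.gumbel_lambda,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, payload: str) -> "Profile":
        d = json.loads(payload)
        return cls(
            name=d["name"],
            log_odds=np.asarray(d["log_odds"], dtype=float),
            family=d["family"],
            gumbel_mu=d["gumbel_mu"],
            gumbel_lambda=d["gumbel_lambda"],
        )


@dataclass
class ProfileHit:
    """Best-window match of one profile on one protein."""

    profile_name: str
    protein_id: str
    bitscore: float
    evalue: float
    window_start: int
    window_end: int
    family: str = ""


def encode(seq: str) -> np.ndarray:
    return np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))


def build_profile(
    seed_alignment: Sequence[str],
    name: str = "profile",
    family: str = "",
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    max_gap_fraction: float = 0.5,
) -> Profile:
    """Build a log-odds profile from an equal-length gapped seed alignment.

    Columns with more than ``max_gap_fraction`` gaps are dropped. For a
    retained column i with residue counts c[i][a] over n_i non-gap rows,

        log_odds[i][a] = log2( (c[i][a] + pseudocount*bg[a]) / (n_i + pseudocount) / bg[a] )

    X scores 0 at every position.
    """
    if len(seed_alignment) < 2:
        raise ProfileConstructionError("need at least 2 seed sequences")
    L = len(seed_alignment[0])
    if any(len(s) != L for s in seed_alignment):
        raise ProfileConstructionError("seed sequences must be equal length (aligned)")
    if background is None:
        background = uniform_background()
    seqs = [s.upper() for s in seed_alignment]
    n_rows = len(seqs)
    keep_cols = []
    for j in range(L):
        gaps = sum(1 for s in seqs if s[j] in "-.")
        if gaps / n_rows <= max_gap_fraction:
            keep_cols.append(j)
    if not keep_cols:
        raise ProfileConstructionError("all columns dropped by the gap filter")
    lo = np.zeros((len(keep_cols), N_SYMBOLS))
    for i, j in enumerate(keep_cols):
        counts = np.zeros(N_SYMBOLS)
        n_i = 0
        for s in seqs:
            c = s[j]
            if c in "-.":
                continue
            counts[_AA_INDEX.get(c, 20)] += 1
            n_i += 1
        for a in range(20):
            lo[i, a] = math.log2(
                (counts[a] + pseudocount * background[a]) / (n_i + pseudocount) / background[a]
            )
        lo[i, 20] = 0.0
    return Profile(name=name, log_odds=lo, family=family)


def window_scores(profile: Profile, seq: str) -> np.ndarray:
    """Scores of every ungapped window; empty array if seq shorter than profile."""
    m = profile.length
    s = encode(seq)
    n = len(s) - m + 1
    if n <= 0:
        return np.empty(0)
    # sum log-odds along the diagonal of each window
    idx = np.arange(n)[:, None] + np.arange(m)[None, :]
    return profile.log_odds[np.arange(m)[None, :], s[idx]].sum(axis=1)


def scan(
    profile: Profile,
    seq: str,
    protein_id: str = "?",
    db_size: int | None = None,
) -> ProfileHit | None:
    """Best-window match of ``profile`` on ``seq``; None if seq is too short.

    Ties on score go to the leftmost window. E-value is computed when the
    profile is calibrated and ``db_size`` given, else reported as inf.
    """
    scores = window_scores(profile, seq)
    if scores.size == 0:
        return None
    best = int(np.argmax(scores))
    bits = float(scores[best])
    ev = evalue(bits, profile, db_size) if (profile.calibrated and db_size) else math.inf
    return ProfileHit(
        profile_name=profile.name,
        protein_id=protein_id,
        bitscore=bits,
        evalue=ev,
        window_start=best,
        window_end=best + profile.length,
        family=profile.family,
    )


def calibrate(
    profile: Profile,
    n_shuffles: int = 200,
    length: int = 400,
    background: np.ndarray | None = None,
    seed: int = 0,
) -> Profile:
    """Fit Gumbel (mu, lambda) to best-window scores on background sequences.

    Method-of-moments fit: lambda = pi / (sigma * sqrt(6)),
    mu = mean - gamma / lambda (gamma the Euler-Mascheroni constant).
    Deterministic given ``seed``. Requires n_shuffles >= 100.
    """
    if n_shuffles < 100:
        raise ValueError(f"n_shuffles must be >= 100 (got {n_shuffles})")
    if background is None:
        background = uniform_background()
    rng = np.random.default_rng(seed)
    p = background / background.sum()
    draws = rng.choice(N_SYMBOLS, size=(n_shuffles, max(length, profile.length)), p=p)
    best = np.empty(n_shuffles)
    for i in range(n_shuffles):
        seq = "".join(ALPHABET[a] for a in draws[i])
        best[i] = window_scores(profile, seq).max()
    sigma = best.std(ddof=1)
    if sigma == 0:
        raise CalibrationError(f"{profile.name}: zero score variance across shuffles")
    lam = math.pi / (sigma * math.sqrt(6.0))
    mu = best.mean() - _EULER_GAMMA / lam
    profile.gumbel_mu = float(mu)
    profile.gumbel_lambda = float(lam)
    return profile


def gumbel_moments_fit(sample: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Gumbel fit; returns (mu, lambda)."""
    sample = np.asarray(sample, dtype=float)
    sigma = sample.std(ddof=1)
    if sigma == 0:
        raise CalibrationError("zero variance sample")
    lam = math.pi / (sigma * math.sqrt(6.0))
    return float(sample.mean() - _EULER_GAMMA / lam), float(lam)


def evalue(bitscore: float, profile: Profile, db_size: int) -> float:
    """Expected number of best-window scores >= bitscore over db_size proteins.

    E = db_size * (1 - exp(-exp(-lambda * (bitscore - mu)))).
    """
    if not profile.calibrated:
        raise CalibrationError(f"profile {profile.name} is not calibrated")
    if db_size < 1:
        raise ValueError("db_size must be >= 1")
    lam = profile.gumbel_lambda
    mu = profile.gumbel_mu
    p = -math.expm1(-math.exp(-lam * (bitscore - mu)))
    return db_size * p


def _identity_dp_py(a: str, b: str) -> tuple[int, int]:
    """Reference DP: returns (matches, alignment_length) of the alignment
    maximizing (score, matches, -length) lexicographically."""
    n, m = len(a), len(b)
    prev = [(0, 0, 0)] + [(-j, 0, -j) for j in range(1, m + 1)]
    for i in range(1, n + 1):
        cur = [(0, 0, 0)] * (m + 1)
        cur[0] = (-i, 0, -i)
        ai = a[i - 1]
        prev_jm1 = prev[0]
        for j in range(1, m + 1):
            inc = 1 if ai == b[j - 1] else 0
            p = prev_jm1
            diag = (p[0] + inc, p[1] + inc, p[2] - 1)
            p = prev[j]
            up = (p[0] - 1, p[1], p[2] - 1)
            p = cur[j - 1]
            left = (p[0] - 1, p[1], p[2] - 1)
            cur[j] = max(diag, up, left)
            prev_jm1 = prev[j]
        prev = cur
    _, matches, neg_len = prev[m]
    return matches, -neg_len


# Fast path: pack (score, matches, -length) into one int64 so lexicographic
# max becomes plain integer max. Fields are 13 bits; with score offset 4096
# and alignment length stored as 8191 - length, no field under/overflows as
# long as len(a) + len(b) < 4000.
_FIELD = 8192
_SCORE_OFF = 4096
_LEN_OFF = 8191

try:  # numba accelerates the DP; the pure-Python version is the fallback
    from numba import njit

    @njit(cache=True)
    def _identity_dp_packed(a: np.ndarray, b: np.ndarray) -> np.int64:  # pragma: no cover
        n = a.shape[0]
        m = b.shape[0]
        F = 8192
        prev = np.empty(m + 1, dtype=np.int64)
        cur = np.empty(m + 1, dtype=np.int64)
        for j in range(m + 1):
            prev[j] = (4096 - j) * F * F + 0 * F + (8191 - j)
        for i in range(1, n + 1):
            cur[0] = (4096 - i) * F * F + 0 * F + (8191 - i)
            ai = a[i - 1]
            for j in range(1, m + 1):
                inc = 1 if ai == b[j - 1] else 0
                diag = prev[j - 1] + inc * F * F + inc * F - 1
                up = prev[j] - F * F - 1
                left = cur[j - 1] - F * F - 1
                best = diag
                if up > best:
                    best = up
                if left > best:
                    best = left
                cur[j] = best
            tmp = prev
            prev = cur
            cur = tmp
        return prev[m]

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity in [0, 1].

    Needleman-Wunsch with match +1, mismatch 0, linear gap -1 (the score is
    used for alignment only); identity = matches / alignment length. Among
    co-optimal alignments the one maximizing (score, matches, -length)
    lexicographically is used, which makes the result deterministic.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if _HAVE_NUMBA and len(a) + len(b) < 4000:
        packed = int(_identity_dp_packed(encode(a), encode(b)))
        matches = (packed // _FIELD) % _FIELD
        alen = _LEN_OFF - (packed % _FIELD)
        return matches / alen
    matches, alen = _identity_dp_py(a, b)
    return matches / alen


def _words(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def greedy_cluster(
    seqs: Sequence[tuple[str, str]],
    identity_threshold: float,
    word_size: int,
) -> list[dict]:
    """Greedy incremental identity clustering (CD-HIT-style).

    Sequences are sorted by descending length (ties broken by id); each in
    turn joins the first existing cluster whose representative shares at
    least one ``word_size``-mer (prefilter) and has identity >=
    ``identity_threshold``; otherwise it founds a new cluster. The founder —
    the longest member — is the representative.

    Returns ``[{"representative": id, "members": [ids...]}, ...]`` in
    founding order; members include the representative.
    """
    if not (0 < identity_threshold <= 1):
        raise ValueError("identity_threshold must be in (0, 1]")
    ordered = sorted(seqs, key=lambda kv: (-len(kv[1]), kv[0]))
    clusters: list[dict] = []
    rep_words: list[set[str]] = []
    rep_seq: list[str] = []
    for sid, seq in ordered:
        w = _words(seq, word_size)
        placed = False
        for ci, cluster in enumerate(clusters):
            if not (w & rep_words[ci]):
                continue
            if pairwise_identity(seq, rep_seq[ci]) >= identity_threshold:
                cluster["members"].append(sid)
                placed = True
                break
        if not placed:
            clusters.append({"representative": sid, "members": [sid]})
            rep_words.append(w)
            rep_seq.append(seq)
    return clusters


def read_aligned_fasta(path: str | Path) -> list[str]:
    """Read a seed alignment (aligned FASTA); returns the gapped rows."""
    from crispr3census.sequence_io import _iter_fasta

    rows = []
    with Path(path).open() as fh:
        for _, (rid, seq) in _iter_fasta(fh):
            rows.append(seq.upper())
    return rows
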