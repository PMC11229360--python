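"""Census statistics: family counts, co-occurrence, UpSet configurations,
activator fractions and the inter-locus signalling GLM.

The census table has one row per locus with its effector family set and the
number of type III loci in the same genome. The association test is a
binomial GLM (logistic regression) at the locus level: response = locus has
at least one known effector, covariate = genome carries >= 2 type III loci.
Genome-level clustering of loci is ignored, so p-values assume independent
loci — outputs flag this caveat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from crispr3census.effector_typing import ACTIVATOR_MAP, KNOWN_FAMILIES

CENSUS_COLUMNS = [
    "locus_id",
    "genome_id",
    "subtype",
    "has_cyclase",
    "has_hd",
    "families",
    "activators",
    "n_type3_loci_in_genome",
]

NONINDEPENDENCE_NOTE = (
    "loci from one genome are treated as independent observations; "
    "genome-level clustering is not modelled"
)


class SeparationError(RuntimeError):
    """Degenerate 2x2 margin: perfect separation or a constant column."""


@dataclass
class GlmResult:
    coefficient: float
    std_error: float
    z: float
    p_value: float
    odds_ratio: float
    n: int
    note: str = NONINDEPENDENCE_NOTE


def make_census_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Normalize census rows into the canonical DataFrame (one row per locus)."""
    df = pd.DataFrame(list(rows))
    for col in CENSUS_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"census table missing column {col!r}")
    df["families"] = df["families"].map(frozenset)
    df["activators"] = df["activators"].map(frozenset)
    return df


def count_families(table: pd.DataFrame) -> tuple[dict[str, int], int]:
    """Per-family locus counts and the total number of effector instances.

    A locus contributes one instance to each distinct family it contains;
    the total is the sum over families.
    """
    counts: dict[str, int] = {}
    for fams in table["families"]:
        for f in fams:
            counts[f] = counts.get(f, 0) + 1
    return counts, sum(counts.values())


def cooccurrence_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Symmetric family x family co-occurrence counts and per-family
    co-occurrence proportions.

    M[f][g] = number of loci containing both f and g (zero diagonal);
    proportion(f) = loci with f and >= 1 other family, over loci with f.
    """
    fams = sorted({f for s in table["families"] for f in s})
    M = pd.DataFrame(0, index=fams, columns=fams, dtype=int)
    with_f = {f: 0 for f in fams}
    co_f = {f: 0 for f in fams}
    for s in table["families"]:
        ss = sorted(s)
        for f in ss:
            with_f[f] += 1
            if len(ss) > 1:
                co_f[f] += 1
        for i, f in enumerate(ss):
            for g in ss[i + 1 :]:
                M.loc[f, g] += 1
                M.loc[g, f] += 1
    proportion = {f: (co_f[f] / with_f[f]) if with_f[f] else 0.0 for f in fams}
    return M, proportion


def upset_configurations(table: pd.DataFrame) -> dict[frozenset, dict]:
    """Group loci by exact family set (the UpSet configuration).

    Returns {family_set: {"count": n, "by_subtype": {subtype: n}}}; the
    empty set collects effector-less loci, and counts partition the table.
    """
    out: dict[frozenset, dict] = {}
    for _, row in table.iterrows():
        key = frozenset(row["families"])
        entry = out.setdefault(key, {"count": 0, "by_subtype": {}})
        entry["count"] += 1
        st = row["subtype"]
        entry["by_subtype"][st] = entry["by_subtype"].get(st, 0) + 1
    return out


def activator_fraction(
    counts: Mapping[str, int],
    activator: str,
    activator_map: Mapping[str, str] = ACTIVATOR_MAP,
) -> float:
    """Fraction of effector instances whose family uses ``activator``."""
    valid = set(activator_map.values()) | {"unknown"}
    if activator not in valid:
        raise ValueError(f"unknown activator {activator!r}; known: {sorted(valid)}")
    total = sum(counts.values())
    if total == 0:
        return 0.0
    hit = sum(c for fam, c in counts.items() if activator_map.get(fam, "unknown") == activator)
    return hit / total


def round_half_up_pct(fraction: float) -> int:
    """Percentage rounded half-up to an integer (report presentation)."""
    return int(math.floor(fraction * 100 + 0.5))


def fit_logistic(y: Sequence[int], x: Sequence[int]) -> GlmResult:
    """Logistic regression of binary y on a single binary covariate x.

    Fitted by IRLS (binomial GLM, logit link). Reports the covariate's
    log-odds coefficient, Wald z and two-sided normal p. For binary x the
    MLE equals the closed-form 2x2 cross-product odds ratio.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) != len(x) or len(y) < 4:
        raise ValueError("need equal-length y and x with n >= 4")
    for name, v in (("y", y), ("x", x)):
        if len(np.unique(v)) < 2:
            raise SeparationError(f"covariate/response {name} is constant")
    # a 2x2 zero cell implies infinite MLE (perfect separation on that margin)
    a = int(((y == 1) & (x == 1)).sum())
    b = int(((y == 1) & (x == 0)).sum())
    c = int(((y == 0) & (x == 1)).sum())
    d = int(((y == 0) & (x == 0)).sum())
    if min(a, b, c, d) == 0:
        zero = [n for n, v in zip("abcd", (a, b, c, d)) if v == 0]
        raise SeparationError(f"degenerate 2x2 margin: zero cell(s) {zero} in (a,b,c,d)=({a},{b},{c},{d})")
    X = sm.add_constant(x)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-10)
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    z = coef / se
    from scipy.stats import norm

    p = float(2 * norm.sf(abs(z)))
    return GlmResult(
        coefficient=coef,
        std_error=se,
        z=z,
        p_value=max(p, np.finfo(float).tiny),
        odds_ratio=math.exp(coef),
        n=len(y),
    )


def interlocus_association(table: pd.DataFrame) -> dict:
    """Locus-level test: does effector absence associate with multi-locus genomes?

    Fits effector presence (>= 1 known family) on the multi-locus indicator
    (n_type3_loci_in_genome >= 2) and reports, alongside the fitted result,
    the inverted odds ratio: how much more likely the genome of an
    effector-lacking locus is to carry multiple type III loci.
    """
    known = set(KNOWN_FAMILIES)
    y = [1 if (set(f) & known) else 0 for f in table["families"]]
    x = [1 if n >= 2 else 0 for n in table["n_type3_loci_in_genome"]]
    res = fit_logistic(y, x)
    return {
        "glm": res,
        "multi_locus_odds_ratio_when_effectorless": 1.0 / res.odds_ratio,
    }


def cooccurrence_edge_list(M: pd.DataFrame) -> pd.DataFrame:
    """Upper-triangle non-zero co-occurrence counts as an edge list."""
    rows = []
    fams = list(M.index)
    for i, f in enumerate(fams):
        for g in fams[i + 1 :]:
            c = int(M.loc[f, g])
            if c > 0:
                rows.append({"family1": f, "family2": g, "count": c})
    return pd.DataFrame(rows, columns=["family1", "family2", "count"])
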