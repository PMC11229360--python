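"""Known-effector typing in locus neighbourhoods.

Each protein within the operon boundaries ±4 kb is scanned against every
family's profile library; families with any hit below the E-value cutoff
compete, and multi-family proteins are resolved by best bitscore — except
the Csx1/Cam1 cross-annotation (both carry CARF sensor domains), which is
resolved by transmembrane-helix presence: Cam1 requires a TM segment, Csx1
requires its absence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from crispr3census.sequence_io import LocusRecord, ProteinRecord
from crispr3census.profile_engine import Profile, ProfileHit, scan

KNOWN_FAMILIES: tuple[str, ...] = (
    "Csx1", "Csm6", "Can1-2", "Cami1", "CalpL",
    "SAVED-CHAT", "NucC", "Cam1", "Csx23", "CorA",
)

CANDIDATE_FAMILIES: tuple[str, ...] = ("TIR-SAVED", "Cam2", "Cam3", "Csm6-2")

# Family -> activating second messenger. Candidate assignments are tentative
# (Cam2 predicted from NucC/SAVED-CHAT adjacency; TIR-SAVED from its CBASS role).
ACTIVATOR_MAP: dict[str, str] = {
    "Csx1": "cA4",
    "Csm6": "cA6",
    "Can1-2": "cA4",
    "Cami1": "cA4",
    "CalpL": "cA4",
    "SAVED-CHAT": "cA3",
    "NucC": "cA3",
    "Cam1": "cA4",
    "Csx23": "cA4",
    "CorA": "SAM-AMP",
    "TIR-SAVED": "cA4",
    "Cam2": "cA3",
    "Cam3": "unknown",
    "Csm6-2": "cA6",
}

TENTATIVE_ACTIVATORS: frozenset[str] = frozenset({"TIR-SAVED", "Cam2", "Cam3", "Csm6-2"})

# Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}


@dataclass
class EffectorHit:
    """Final family assignment for one neighbourhood protein."""

    protein_id: str
    locus_id: str
    family: str
    bitscore: float
    evalue: float
    tm_count: int = 0
    resolution: str = "unique"  # unique | best_bitscore | tm_rule
    activator: str = "unknown"
    qc_warnings: list[str] = field(default_factory=list)


def locus_neighborhood(
    locus: LocusRecord,
    proteins: Sequence[ProteinRecord],
    flank: int = 4000,
) -> list[ProteinRecord]:
    """Proteins on the locus contig whose gene intersects the operon ±flank.

    Intersection semantics: a gene counts if its [start, end) interval
    overlaps [operon_start - flank, operon_end + flank) by at least 1 nt.
    """
    lo = locus.operon_start - flank
    hi = locus.operon_end + flank
    return [
        p
        for p in proteins
        if p.contig_id == locus.contig_id and p.start < hi and p.end > lo
    ]


def predict_tm(sequence: str, window: int = 19, threshold: float = 1.6) -> int:
    """Count putative transmembrane segments by Kyte-Doolittle hydropathy.

    Windows of ``window`` residues with mean hydropathy >= ``threshold``
    mark TM candidates; maximal non-overlapping qualifying windows are
    counted greedily from the N-terminus. Sequences shorter than the window
    yield 0.
    """
    n = len(sequence)
    if n < window:
        return 0
    vals = [KYTE_DOOLITTLE.get(c, 0.0) for c in sequence]
    # prefix sums for O(n) window means
    pref = [0.0]
    for v in vals:
        pref.append(pref[-1] + v)
    count = 0
    i = 0
    while i + window <= n:
        mean = (pref[i + window] - pref[i]) / window
        if mean >= threshold:
            count += 1
            i += window  # skip past this segment: non-overlapping
        else:
            i += 1
    return count


def _family_best_hits(
    protein: ProteinRecord,
    libraries: Mapping[str, Sequence[Profile]],
    cutoff: float,
    db_size: int,
) -> dict[str, ProfileHit]:
    """Best significant hit per family for one protein."""
    out: dict[str, ProfileHit] = {}
    for family, profiles in libraries.items():
        best: ProfileHit | None = None
        for prof in profiles:
            hit = scan(prof, protein.sequence, protein.protein_id, db_size=db_size)
            if hit is not None and (best is None or hit.bitscore > best.bitscore):
                best = hit
        if best is not None and best.evalue <= cutoff:
            out[family] = best
    return out


def resolve_cam1_csx1(tm_count: int) -> str:
    """TM rule for the Csx1/Cam1 CARF cross-annotation."""
    return "Cam1" if tm_count >= 1 else "Csx1"


def type_effectors(
    neighborhood: Sequence[ProteinRecord],
    locus_id: str,
    libraries: Mapping[str, Sequence[Profile]],
    cutoff: float = 1e-3,
    db_size: int | None = None,
    activator_map: Mapping[str, str] = ACTIVATOR_MAP,
) -> list[EffectorHit]:
    """Assign at most one effector family per neighbourhood protein.

    Multiple significant families resolve to the best bitscore, except the
    Csx1/Cam1 pair which uses the TM rule. Exact bitscore ties between other
    families go to the lexicographically smaller family name. A Cam1-only
    hit with no TM segment is retained but flagged with a QC warning.
    """
    unknown = set(libraries) - set(activator_map)
    if unknown:
        raise ValueError(f"families without activator mapping: {sorted(unknown)}")
    if db_size is None:
        db_size = max(len(neighborhood), 1)
    hits: list[EffectorHit] = []
    for prot in neighborhood:
        fam_hits = _family_best_hits(prot, libraries, cutoff, db_size)
        if not fam_hits:
            continue
        qc: list[str] = []
        if len(fam_hits) == 1:
            family = next(iter(fam_hits))
            resolution = "unique"
        elif set(fam_hits) >= {"Cam1", "Csx1"} and len(fam_hits) == 2:
            family = resolve_cam1_csx1(predict_tm(prot.sequence))
            resolution = "tm_rule"
        else:
            family = min(fam_hits, key=lambda f: (-fam_hits[f].bitscore, f))
            resolution = "best_bitscore"
        tm = predict_tm(prot.sequence)
        if family == "Cam1" and resolution != "tm_rule" and tm == 0:
            qc.append("Cam1 call without predicted TM segment")
        best = fam_hits[family]
        hits.append(
            EffectorHit(
                protein_id=prot.protein_id,
                locus_id=locus_id,
                family=family,
                bitscore=best.bitscore,
                evalue=best.evalue,
                tm_count=tm,
                resolution=resolution,
                activator=activator_map[family],
                qc_warnings=qc,
            )
        )
    return hits


def detect_cross_hits(
    neighborhood: Sequence[ProteinRecord],
    libraries: Mapping[str, Sequence[Profile]],
    cutoff: float = 1e-3,
    db_size: int | None = None,
) -> list[dict]:
    """QC report of proteins significant in >= 2 family libraries.

    Each row lists the protein, the families and their bitscores, and
    whether the Csx1/Cam1 TM rule auto-resolves it. Drives seed-alignment
    trimming and the shipped libraries' zero-cross-hit regression tests.
    """
    if db_size is None:
        db_size = max(len(neighborhood), 1)
    rows = []
    for prot in neighborhood:
        fam_hits = _family_best_hits(prot, libraries, cutoff, db_size)
        if len(fam_hits) >= 2:
            rows.append(
                {
                    "protein_id": prot.protein_id,
                    "families": sorted(fam_hits),
                    "bitscores": {f: h.bitscore for f, h in fam_hits.items()},
                    "auto_resolved": set(fam_hits) == {"Cam1", "Csx1"},
                }
            )
    return rows
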