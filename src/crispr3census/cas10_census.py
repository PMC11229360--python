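"""Cas10 identification, domain calls (cyclase / HD), hybrid-locus filtering
and the Cas10 tree.

The cyclase (PALM) call is a two-stage rule: a calibrated cyclase-profile
hit below the E-value cutoff AND a literal occurrence of one of the ten
observed active-site motif variants (GGDD and relatives). The HD nuclease
call requires the literal 'HD' 2-mer within the first 50 residues AND an
HD-profile hit on residues 10-40 below its (lenient) cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from crispr3census.sequence_io import LocusRecord, ProteinRecord
from crispr3census.profile_engine import (
    Profile,
    ProfileHit,
    greedy_cluster,
    pairwise_identity,
    scan,
)

# Active-site 4-mer variants, canonical motif first; order is reporting order only.
CYCLASE_MOTIFS: tuple[str, ...] = (
    "GGDD", "AGDD", "GGED", "GGDE", "SGDD",
    "DGDD", "AGDE", "EGDD", "KGDD", "GEDD",
)


class TreeError(ValueError):
    pass


@dataclass
class Cas10Record:
    """Per-Cas10 census entry: identity hit plus domain calls."""

    protein_id: str
    locus_id: str | None
    best_cas10_profile: str
    cas10_evalue: float
    bitscore: float = 0.0
    has_cyclase: bool = False
    cyclase_motif: str | None = None
    cyclase_motif_pos: int | None = None
    has_hd: bool = False
    hd_window: str | None = None
    cluster_rep: bool = True


def find_cas10(
    proteins: Sequence[ProteinRecord],
    cas10_profiles: Sequence[Profile],
    locus_of: Mapping[str, str | None] | None = None,
    min_len: int = 500,
    cutoff: float = 1e-20,
    db_size: int | None = None,
) -> list[Cas10Record]:
    """Identify Cas10 proteins: length >= min_len, then any profile E <= cutoff.

    Proteins shorter than ``min_len`` are excluded before scanning (short
    Cas10 fragments are assumed non-functional). The best profile by
    bitscore is recorded. ``db_size`` defaults to the number of proteins
    actually scanned.
    """
    if not cas10_profiles:
        raise ValueError("empty Cas10 profile library")
    candidates = [p for p in proteins if p.length >= min_len]
    if db_size is None:
        db_size = max(len(candidates), 1)
    out = []
    for prot in candidates:
        best: ProfileHit | None = None
        for prof in cas10_profiles:
            hit = scan(prof, prot.sequence, prot.protein_id, db_size=db_size)
            if hit is not None and (best is None or hit.bitscore > best.bitscore):
                best = hit
        if best is not None and best.evalue <= cutoff:
            out.append(
                Cas10Record(
                    protein_id=prot.protein_id,
                    locus_id=locus_of.get(prot.protein_id) if locus_of else None,
                    best_cas10_profile=best.profile_name,
                    cas10_evalue=best.evalue,
                    bitscore=best.bitscore,
                )
            )
    return out


def dereplicate(
    cas10s: Sequence[Cas10Record],
    sequences: Mapping[str, str],
    identity_threshold: float = 0.9,
    word_size: int = 5,
) -> list[Cas10Record]:
    """Collapse near-identical Cas10s; flags exactly one representative per cluster.

    Removes assembly redundancy (e.g. GCA/GCF duplicates of one genome).
    Downstream census counts use representatives only.
    """
    clusters = greedy_cluster(
        [(r.protein_id, sequences[r.protein_id]) for r in cas10s],
        identity_threshold,
        word_size,
    )
    reps = {c["representative"] for c in clusters}
    for rec in cas10s:
        rec.cluster_rep = rec.protein_id in reps
    return list(cas10s)


def detect_cyclase(
    cas10: Cas10Record,
    sequence: str,
    cyclase_profiles: Sequence[Profile],
    motif_table: Sequence[str] = CYCLASE_MOTIFS,
    cutoff: float = 1e-3,
    db_size: int = 1,
) -> Cas10Record:
    """Two-stage cyclase call: profile hit at E <= cutoff AND a literal motif.

    A strong profile hit without any literal active-site variant is called
    cyclase-negative (degenerate PALM domain); a literal motif without a
    profile hit is treated as a chance 4-mer and also rejected. When several
    variants occur, the first occurrence in N->C order is recorded.
    """
    profile_ok = False
    for prof in cyclase_profiles:
        hit = scan(prof, sequence, cas10.protein_id, db_size=db_size)
        if hit is not None and hit.evalue <= cutoff:
            profile_ok = True
            break
    motif, pos = _first_motif(sequence, motif_table)
    cas10.has_cyclase = profile_ok and motif is not None
    cas10.cyclase_motif = motif if cas10.has_cyclase else None
    cas10.cyclase_motif_pos = pos if cas10.has_cyclase else None
    return cas10


def _first_motif(sequence: str, motif_table: Sequence[str]) -> tuple[str | None, int | None]:
    best_pos, best_motif = None, None
    for m in motif_table:
        p = sequence.find(m)
        if p != -1 and (best_pos is None or p < best_pos):
            best_pos, best_motif = p, m
    return best_motif, best_pos


def extract_motif_window(sequence: str, motif_pos: int, upstream: int = 50, downstream: int = 100) -> str:
    """Sequence window from 50 aa N-terminal to 100 aa C-terminal of a 4-mer motif.

    Clamped at the sequence ends; used to build cyclase seed alignments.
    """
    start = max(0, motif_pos - upstream)
    end = min(len(sequence), motif_pos + 4 + downstream)
    return sequence[start:end]


def detect_hd(
    cas10: Cas10Record,
    sequence: str,
    hd_profile: Profile,
    cutoff: float = 1e-1,
    first_n: int = 50,
    extract_start: int = 10,
    extract_end: int = 40,
    db_size: int = 1,
) -> Cas10Record:
    """HD nuclease call: literal 'HD' in the first 50 residues AND a profile
    hit on residues 10-40 (1-based inclusive) at E <= cutoff.

    The complete 2-mer must lie within the first ``first_n`` residues
    (0-based start <= first_n - 2). Sequences shorter than ``extract_end``
    are HD-negative with a warning.
    """
    cas10.has_hd = False
    cas10.hd_window = None
    if len(sequence) < extract_end:
        warnings.warn(f"{cas10.protein_id}: shorter than {extract_end} aa, HD call skipped")
        return cas10
    head = sequence[:first_n]
    hd_pos = head.find("HD")
    if hd_pos == -1 or hd_pos > first_n - 2:
        return cas10
    window = sequence[extract_start - 1 : extract_end]  # 1-based inclusive 10..40
    hit = scan(hd_profile, window, cas10.protein_id, db_size=db_size)
    if hit is not None and hit.evalue <= cutoff:
        cas10.has_hd = True
        cas10.hd_window = window
    return cas10


def filter_hybrid_loci(
    loci: Sequence[LocusRecord], cas10_count: Mapping[str, int]
) -> list[LocusRecord]:
    """Drop loci with >= 2 cas10 genes and non-type-III loci; rename hybrids.

    A hybrid combining a type III subtype with a non-III CRISPR type keeps
    the type III subtype as its name. ``cas10_count`` maps locus_id to the
    number of Cas10 genes called in that locus.
    """
    out = []
    for locus in loci:
        if cas10_count.get(locus.locus_id, 0) >= 2:
            continue
        parts = [p.strip() for p in locus.subtype.split("/")]
        iii = [p for p in parts if p.startswith("III")]
        if not iii:
            continue
        if len(parts) > 1:
            locus.subtype = iii[0]
        out.append(locus)
    return out


def nj_newick(ids: Sequence[str], distances: np.ndarray, midpoint_root: bool = True) -> str:
    """Neighbour joining on a distance matrix, exported as Newick.

    Negative NJ branch lengths are clamped to zero; the unrooted tree is
    midpoint-rooted for display by default.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(ids) < 3:
        raise TreeError("need at least 3 sequences to build a tree")
    if len(set(ids)) != len(ids):
        raise TreeError("duplicate sequence ids")
    tree = nj(DistanceMatrix(distances, list(ids)), neg_as_zero=True)
    if midpoint_root:
        tree = tree.root_at_midpoint()
    return str(tree).strip()


def build_tree(representatives: Sequence[tuple[str, str]], midpoint_root: bool = True) -> str:
    """Neighbour-joining tree over 1 - identity distances, exported as Newick.

    Requires >= 3 sequences; see :func:`nj_newick` for the NJ conventions.
    """
    if len(representatives) < 3:
        raise TreeError("need at least 3 sequences to build a tree")
    ids = [rid for rid, _ in representatives]
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - pairwise_identity(representatives[i][1], representatives[j][1])
            dm[i, j] = dm[j, i] = d
    return nj_newick(ids, dm, midpoint_root=midpoint_root)
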