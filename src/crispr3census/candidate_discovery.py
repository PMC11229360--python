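"""Novel effector-candidate discovery, CorA ancillary genes and fusions.

Candidates come from loci with no known effector: genes the upstream caller
left "Unknown" or annotated only at poor E-value are flagged, clustered at
low identity, and each cluster representative is searched across all loci
to count recurrence. Recurrent unannotated neighbours of matched candidates
are added as guilt-by-association candidates. Similarity screening uses
global pairwise identity at an explicit minimum, standing in for a
BLAST/Diamond search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from crispr3census.sequence_io import LocusRecord, ProteinRecord, GeneAnnotation
from crispr3census.profile_engine import Profile, greedy_cluster, pairwise_identity, scan
from crispr3census.effector_typing import EffectorHit
from crispr3census.cas10_census import build_tree

CORA_ANCILLARY_FAMILIES: tuple[str, ...] = ("NrN", "DEDD", "SAM-lyase")


@dataclass
class CandidateRecord:
    protein_id: str
    locus_id: str
    flag_reason: str  # unknown_annotation | poor_evalue | guilt_by_association
    cluster_id: int | None = None
    is_representative: bool = False
    occurrence_count: int = 1


@dataclass
class FusionCall:
    """Multi-domain protein: >= 2 family hits with non-overlapping windows."""

    protein_id: str
    domains: list[tuple[str, int, int]]  # (family, window_start, window_end), N->C
    overlap_free: bool = True


def flag_candidates(
    loci: Sequence[LocusRecord],
    annotations: Mapping[str, GeneAnnotation],
    effector_hits: Sequence[EffectorHit],
    evalue_floor: float = 1e-7,
    exclusion_list: Iterable[str] = (),
) -> list[CandidateRecord]:
    """Flag potentially novel effector genes in effector-less loci.

    A gene is flagged iff its annotation is "Unknown" or its annotation
    E-value exceeds ``evalue_floor``, AND its locus has zero known-effector
    hits. ``exclusion_list`` holds manually curated protein or family names
    to drop (the reproducible stand-in for manual curation).
    """
    loci_with_effectors = {h.locus_id for h in effector_hits}
    effector_proteins = {h.protein_id for h in effector_hits}
    excluded = set(exclusion_list)
    out = []
    for locus in loci:
        if locus.locus_id in loci_with_effectors:
            continue
        for pid in locus.member_proteins:
            if pid in effector_proteins or pid in excluded:
                continue
            ann = annotations.get(pid)
            if ann is None:
                continue
            if ann.annotation_label == "Cas10":
                continue
            if ann.annotation_label == "Unknown":
                reason = "unknown_annotation"
            elif ann.annotation_evalue is not None and ann.annotation_evalue > evalue_floor:
                reason = "poor_evalue"
            else:
                continue
            out.append(CandidateRecord(protein_id=pid, locus_id=locus.locus_id, flag_reason=reason))
    return out


def cluster_candidates(
    flagged: Sequence[CandidateRecord],
    sequences: Mapping[str, str],
    identity_threshold: float = 0.4,
    word_size: int = 2,
) -> list[CandidateRecord]:
    """Cluster flagged candidates at low identity; mark representatives."""
    clusters = greedy_cluster(
        [(c.protein_id, sequences[c.protein_id]) for c in flagged],
        identity_threshold,
        word_size,
    )
    assignment: dict[str, tuple[int, bool]] = {}
    for ci, cluster in enumerate(clusters):
        for pid in cluster["members"]:
            assignment[pid] = (ci, pid == cluster["representative"])
    for rec in flagged:
        rec.cluster_id, rec.is_representative = assignment[rec.protein_id]
    return list(flagged)


def _word_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def cross_locus_search(
    representatives: Sequence[CandidateRecord],
    loci: Sequence[LocusRecord],
    sequences: Mapping[str, str],
    annotations: Mapping[str, GeneAnnotation],
    identity_min: float = 0.3,
    min_recurrence: int = 2,
    word_size: int = 5,
) -> tuple[dict[str, int], list[CandidateRecord]]:
    """Count, per representative, the loci containing a homolog; add
    guilt-by-association candidates.

    A locus counts when any member protein has pairwise identity >=
    ``identity_min`` to the representative. Pairs sharing no ``word_size``-mer
    are skipped before alignment — the seeded-search heuristic of the
    BLAST-style step this stands in for. Unannotated ("Unknown") neighbours
    that co-occur with the representative's homologs in >= ``min_recurrence``
    matched loci are emitted as guilt_by_association candidates (they escaped
    the primary flagging, e.g. because their locus carried a known effector
    or a confident annotation such as CasR).
    """
    words = {pid: _word_set(seq, word_size) for pid, seq in sequences.items()}
    occurrence: dict[str, int] = {}
    gba: dict[str, CandidateRecord] = {}
    rep_ids = {r.protein_id for r in representatives}

    def homologous(pid_a: str, pid_b: str) -> bool:
        if pid_a == pid_b:
            return True
        if not (words[pid_a] & words[pid_b]):
            return False
        return pairwise_identity(sequences[pid_a], sequences[pid_b]) >= identity_min

    for rep in representatives:
        rid = rep.protein_id
        matched_loci = [
            locus
            for locus in loci
            if any(homologous(pid, rid) for pid in locus.member_proteins)
        ]
        occurrence[rid] = len(matched_loci)
        rep.occurrence_count = len(matched_loci)
        # recurrent unannotated neighbours across the matched loci
        neighbour_groups: dict[str, list[str]] = {}
        for locus in matched_loci:
            for pid in locus.member_proteins:
                if pid in rep_ids:
                    continue
                ann = annotations.get(pid)
                if ann is None or ann.annotation_label != "Unknown":
                    continue
                if homologous(pid, rid):
                    continue  # a homolog of the candidate itself
                key = None
                for gid in neighbour_groups:
                    if homologous(pid, gid):
                        key = gid
                        break
                if key is None:
                    neighbour_groups[pid] = [pid]
                else:
                    neighbour_groups[key].append(pid)
        for gid, members in neighbour_groups.items():
            if len(members) >= min_recurrence and gid not in gba:
                locus_id = next(l.locus_id for l in matched_loci if gid in l.member_proteins)
                gba[gid] = CandidateRecord(
                    protein_id=gid,
                    locus_id=locus_id,
                    flag_reason="guilt_by_association",
                    occurrence_count=len(members),
                )
    return occurrence, list(gba.values())


def detect_cora_ancillary(
    locus: LocusRecord,
    sequences: Mapping[str, str],
    ancillary_refs: Mapping[str, Sequence[str]],
    cora_protein_ids: set[str],
    identity_min: float = 0.3,
) -> dict[str, bool] | None:
    """Presence/absence of NrN / DEDD / SAM-lyase homologs in a CorA locus.

    Returns None (locus skipped) when the locus carries no CorA hit. Each
    ancillary family is present when any member protein reaches
    ``identity_min`` identity to any reference sequence of that family; a
    protein is assigned to its best-identity family only.
    """
    if not any(pid in cora_protein_ids for pid in locus.member_proteins):
        return None
    presence = {fam: False for fam in ancillary_refs}
    for pid in locus.member_proteins:
        if pid in cora_protein_ids:
            continue
        best_fam, best_ident = None, 0.0
        for fam, refs in ancillary_refs.items():
            for ref in refs:
                ident = pairwise_identity(sequences[pid], ref)
                if ident > best_ident:
                    best_fam, best_ident = fam, ident
        if best_fam is not None and best_ident >= identity_min:
            presence[best_fam] = True
    return presence


def detect_fusions(
    protein: ProteinRecord,
    libraries: Mapping[str, Sequence[Profile]],
    cutoff: float = 1e-3,
    db_size: int = 1,
) -> FusionCall | None:
    """Call a domain fusion when >= 2 families hit non-overlapping windows.

    Domains are reported N->C. Two significant families whose best windows
    overlap yield None (ambiguous cross-hit, not a fusion).
    """
    best_per_family = {}
    for fam, profiles in libraries.items():
        best = None
        for prof in profiles:
            hit = scan(prof, protein.sequence, protein.protein_id, db_size=db_size)
            if hit is not None and (best is None or hit.bitscore > best.bitscore):
                best = hit
        if best is not None and best.evalue <= cutoff:
            best_per_family[fam] = best
    if len(best_per_family) < 2:
        return None
    domains = sorted(
        ((fam, h.window_start, h.window_end) for fam, h in best_per_family.items()),
        key=lambda d: d[1],
    )
    for (_, _, end_a), (_, start_b, _) in zip(domains, domains[1:]):
        if start_b < end_a:
            return None
    return FusionCall(protein_id=protein.protein_id, domains=domains, overlap_free=True)


def build_cora_tree(
    cora_seqs: Sequence[tuple[str, str]],
    metadata: Mapping[str, Mapping[str, object]],
) -> tuple[str, list[dict]]:
    """NJ tree of CorA effectors plus a per-leaf metadata table.

    ``metadata`` maps protein_id to a dict of per-leaf annotations (ancillary
    presence, Csm6-2 association, subtype). Returns (newick, rows); rows are
    one per leaf, in leaf id order.
    """
    newick = build_tree(cora_seqs)
    rows = []
    for pid, _ in sorted(cora_seqs):
        row = {"protein_id": pid}
        row.update(metadata.get(pid, {}))
        rows.append(row)
    return newick, rows
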