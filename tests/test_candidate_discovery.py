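import numpy as np
import pytest
from io import StringIO
from skbio import TreeNode

from crispr3census.candidate_discovery import (
    CORA_ANCILLARY_FAMILIES,
    build_cora_tree,
    cluster_candidates,
    cross_locus_search,
    detect_cora_ancillary,
    detect_fusions,
    flag_candidates,
)
from crispr3census.effector_typing import EffectorHit
from crispr3census.profile_engine import build_profile, calibrate, pairwise_identity
from crispr3census.sequence_io import GeneAnnotation, LocusRecord, ProteinRecord

AAS = "ACDEFGHIKLMNPQRSTVWY"


def _rand_seq(rng, n):
    return "".join(AAS[i] for i in rng.integers(0, 20, size=n))


def _mut(rng, seq, k):
    chars = list(seq)
    for i in rng.choice(len(chars), size=k, replace=False):
        chars[i] = AAS[rng.integers(0, 20)]
    return "".join(chars)


def _locus(lid, members):
    return LocusRecord(lid, "g", "III-A", "c", 0, 1000, member_proteins=members)


def _hit(pid, lid, family="Csx1"):
    return EffectorHit(pid, lid, family, 100.0, 1e-10, activator="cA4")


def _ann(pid, label, ev):
    return GeneAnnotation(pid, "L", label, ev, "III-A")


def test_flag_candidates_rules():
    loci = [_locus("L1", ["u1", "good1", "poor1"]), _locus("L2", ["u2"])]
    annotations = {
        "u1": _ann("u1", "Unknown", None),
        "good1": _ann("good1", "Cas6", 1e-9),  # confident annotation: passes
        "poor1": _ann("poor1", "CasR", 1e-5),  # poor E-value: flagged
        "u2": _ann("u2", "Unknown", None),
    }
    hits = [_hit("x", "L2")]  # L2 carries a known effector
    out = flag_candidates(loci, annotations, hits)
    by_id = {c.protein_id: c for c in out}
    assert set(by_id) == {"u1", "poor1"}
    assert by_id["u1"].flag_reason == "unknown_annotation"
    assert by_id["poor1"].flag_reason == "poor_evalue"


def test_flag_candidates_never_from_effector_loci(small_dataset):
    # property over the synthetic corpus: loci with planted effectors yield none
    ds = small_dataset
    annotations = {a.protein_id: a for a in ds.annotations}
    hits = [
        _hit(pid, v["locus_id"])
        for pid, v in ds.truth["proteins"].items()
        if v["role"] == "effector"
    ]
    effector_loci = {h.locus_id for h in hits}
    out = flag_candidates(ds.loci, annotations, hits)
    assert all(c.locus_id not in effector_loci for c in out)


def test_flag_candidates_exclusion_list():
    loci = [_locus("L1", ["u1", "u2"])]
    annotations = {"u1": _ann("u1", "Unknown", None), "u2": _ann("u2", "Unknown", None)}
    out = flag_candidates(loci, annotations, [], exclusion_list=["u2"])
    assert [c.protein_id for c in out] == ["u1"]


def test_cluster_candidates_matches_identity_semantics(rng):
    base = _rand_seq(rng, 60)
    seqs = {
        "a1": base,
        "a2": _mut(rng, base, 6),  # ~90% identical to base
        "b1": _rand_seq(rng, 60),
    }
    from crispr3census.candidate_discovery import CandidateRecord

    flagged = [CandidateRecord(pid, "L1", "unknown_annotation") for pid in seqs]
    out = cluster_candidates(flagged, seqs, identity_threshold=0.4, word_size=2)
    clusters = {}
    for c in out:
        clusters.setdefault(c.cluster_id, set()).add(c.protein_id)
    assert {frozenset(v) for v in clusters.values()} == {
        frozenset({"a1", "a2"}),
        frozenset({"b1"}),
    }
    reps = [c for c in out if c.is_representative]
    assert len(reps) == len(clusters)


def test_cross_locus_search_counts_planted_occurrences(rng):
    from crispr3census.candidate_discovery import CandidateRecord

    fam = _rand_seq(rng, 80)
    seqs, loci = {}, []
    for i in range(5):
        hom = _mut(rng, fam, 8)
        seqs[f"c{i}"] = hom
        seqs[f"bg{i}"] = _rand_seq(rng, 80)
        loci.append(_locus(f"L{i}", [f"c{i}", f"bg{i}"]))
    seqs["solo"] = _rand_seq(rng, 90)
    loci.append(_locus("Lsolo", ["solo"]))
    annotations = {pid: _ann(pid, "Unknown", None) for pid in seqs}
    reps = [CandidateRecord("c0", "L0", "unknown_annotation", is_representative=True),
            CandidateRecord("solo", "Lsolo", "unknown_annotation", is_representative=True)]
    occurrence, gba = cross_locus_search(reps, loci, seqs, annotations)
    assert occurrence["c0"] == 5
    assert occurrence["solo"] == 1


def test_cross_locus_search_emits_guilt_by_association(rng):
    from crispr3census.candidate_discovery import CandidateRecord

    fam = _rand_seq(rng, 80)
    neigh = _rand_seq(rng, 70)
    seqs, loci = {}, []
    for i in range(3):
        seqs[f"c{i}"] = _mut(rng, fam, 8)
        seqs[f"n{i}"] = _mut(rng, neigh, 7)  # recurrent colocalized neighbour
        loci.append(_locus(f"L{i}", [f"c{i}", f"n{i}"]))
    annotations = {pid: _ann(pid, "Unknown", None) for pid in seqs}
    reps = [CandidateRecord("c0", "L0", "unknown_annotation", is_representative=True)]
    _, gba = cross_locus_search(reps, loci, seqs, annotations)
    assert len(gba) == 1
    assert gba[0].flag_reason == "guilt_by_association"
    assert gba[0].protein_id.startswith("n")
    assert gba[0].occurrence_count == 3


def test_detect_cora_ancillary(rng):
    refs = {fam: [_rand_seq(rng, 100)] for fam in CORA_ANCILLARY_FAMILIES}
    seqs = {
        "cora": _rand_seq(rng, 120),
        "nrn_like": _mut(rng, refs["NrN"][0], 10),
        "bg": _rand_seq(rng, 100),
    }
    locus = _locus("L1", ["cora", "nrn_like", "bg"])
    presence = detect_cora_ancillary(locus, seqs, refs, cora_protein_ids={"cora"})
    assert presence == {"NrN": True, "DEDD": False, "SAM-lyase": False}
    empty = detect_cora_ancillary(_locus("L2", ["bg"]), seqs, refs, cora_protein_ids={"cora"})
    assert empty is None  # non-CorA locus skipped
    bare = detect_cora_ancillary(_locus("L3", ["cora", "bg"]), seqs, refs, cora_protein_ids={"cora"})
    assert bare == {"NrN": False, "DEDD": False, "SAM-lyase": False}


@pytest.fixture(scope="module")
def fusion_libraries():
    rng = np.random.default_rng(31)
    sig_a = "".join(AAS[i] for i in rng.integers(0, 20, size=30))
    sig_b = "".join(AAS[i] for i in rng.integers(0, 20, size=30))
    libs = {}
    for fam, sig in (("CorA", sig_a), ("Csm6-2", sig_b)):
        seeds = []
        for _ in range(5):
            chars = list(sig)
            for i in rng.choice(30, size=2, replace=False):
                chars[i] = AAS[rng.integers(0, 20)]
            seeds.append("".join(chars))
        libs[fam] = [calibrate(build_profile(seeds, name=fam, family=fam), seed=8)]
    return libs, sig_a, sig_b


def test_detect_fusions_concatemer(fusion_libraries, rng):
    libs, sig_a, sig_b = fusion_libraries
    seq = _rand_seq(rng, 40) + sig_a + _rand_seq(rng, 60) + sig_b + _rand_seq(rng, 40)
    prot = ProteinRecord("fusion", "g", "c", 0, 3 * len(seq), "+", seq)
    call = detect_fusions(prot, libs)
    assert call is not None and call.overlap_free
    assert [d[0] for d in call.domains] == ["CorA", "Csm6-2"]  # N->C order

    single_seq = _rand_seq(rng, 40) + sig_a + _rand_seq(rng, 40)
    single = ProteinRecord("single", "g", "c", 0, 3 * len(single_seq), "+", single_seq)
    assert detect_fusions(single, libs) is None


def test_detect_fusions_order_reported_not_presence(fusion_libraries, rng):
    libs, sig_a, sig_b = fusion_libraries
    seq = _rand_seq(rng, 40) + sig_b + _rand_seq(rng, 60) + sig_a + _rand_seq(rng, 40)
    prot = ProteinRecord("rev", "g", "c", 0, 3 * len(seq), "+", seq)
    call = detect_fusions(prot, libs)
    assert call is not None
    assert [d[0] for d in call.domains] == ["Csm6-2", "CorA"]


def test_detect_fusions_overlap_rejected(fusion_libraries):
    libs, sig_a, sig_b = fusion_libraries
    # same 30-aa window cannot host both domains without overlap
    interleaved = "".join(a + b for a, b in zip(sig_a, sig_b))[:60]
    # craft a sequence where both best windows coincide: a 50/50 chimera
    chimera = sig_a[:15] + sig_b[15:]
    seq = "D" * 40 + chimera + "D" * 40
    prot = ProteinRecord("chimera", "g", "c", 0, 3 * len(seq), "+", seq)
    call = detect_fusions(prot, libs)
    assert call is None  # either below cutoff or overlapping windows


def test_build_cora_tree_clades_and_metadata(rng):
    fam1, fam2 = _rand_seq(rng, 80), _rand_seq(rng, 80)
    seqs = [(f"x{i}", _mut(rng, fam1, 6)) for i in range(3)] + [
        (f"y{i}", _mut(rng, fam2, 6)) for i in range(3)
    ]
    meta = {pid: {"Csm6-2": pid.startswith("x"), "subtype": "III-B"} for pid, _ in seqs}
    newick, rows = build_cora_tree(seqs, meta)
    assert len(rows) == 6
    tree = TreeNode.read(StringIO(newick))
    clades = {frozenset(t.name for t in n.tips()) for n in tree.non_tips(include_self=True)}
    assert frozenset({"x0", "x1", "x2"}) in clades or frozenset({"y0", "y1", "y2"}) in clades
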