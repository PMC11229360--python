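import numpy as np
import pytest
from skbio import TreeNode
from io import StringIO

from crispr3census.cas10_census import (
    CYCLASE_MOTIFS,
    Cas10Record,
    TreeError,
    build_tree,
    dereplicate,
    detect_cyclase,
    detect_hd,
    extract_motif_window,
    filter_hybrid_loci,
    find_cas10,
    nj_newick,
)
from crispr3census.sequence_io import LocusRecord, ProteinRecord
from crispr3census.profile_engine import build_profile, calibrate

AAS = "ACDEFGHIKLMNPQRSTVWY"


def _rand_seq(rng, n):
    return "".join(AAS[i] for i in rng.integers(0, 20, size=n))


def _protein(pid, seq):
    return ProteinRecord(pid, "g", "c", 0, 3 * len(seq), "+", seq)


@pytest.fixture(scope="module")
def cas10_profile():
    rng = np.random.default_rng(9)
    sig = "".join(AAS[i] for i in rng.integers(0, 20, size=120))
    seeds = []
    for _ in range(5):
        chars = list(sig)
        for i in rng.choice(len(chars), size=6, replace=False):
            chars[i] = AAS[rng.integers(0, 20)]
        seeds.append("".join(chars))
    prof = calibrate(build_profile(seeds, name="Cas10", family="Cas10"), seed=1)
    return prof, sig


def test_find_cas10_length_filter_and_planted_positive(cas10_profile, rng):
    prof, sig = cas10_profile
    planted = _rand_seq(rng, 200) + sig + _rand_seq(rng, 280)  # 600 aa
    short = planted[:499]
    background = _rand_seq(rng, 600)
    out = find_cas10(
        [_protein("hit", planted), _protein("short", short), _protein("bg", background)],
        [prof],
    )
    assert [r.protein_id for r in out] == ["hit"]


def test_find_cas10_empty_library(rng):
    with pytest.raises(ValueError, match="empty"):
        find_cas10([_protein("p", _rand_seq(rng, 600))], [])


def test_dereplicate_flags_single_representative(rng):
    seq = _rand_seq(rng, 520)
    other = _rand_seq(rng, 520)
    recs = [
        Cas10Record("a", "L1", "Cas10", 1e-30),
        Cas10Record("b", "L2", "Cas10", 1e-30),
        Cas10Record("c", "L3", "Cas10", 1e-30),
    ]
    out = dereplicate(recs, {"a": seq, "b": seq, "c": other})
    reps = {r.protein_id for r in out if r.cluster_rep}
    assert len(reps) == 2 and "c" in reps
    assert len(reps & {"a", "b"}) == 1


@pytest.fixture(scope="module")
def cyclase_setup():
    rng = np.random.default_rng(11)
    ctx = "".join(AAS[i] for i in rng.integers(0, 20, size=154))
    block = ctx[:50] + "GGDD" + ctx[54:]
    seeds = []
    for _ in range(5):
        chars = list(block)
        for i in rng.choice(len(chars), size=7, replace=False):
            if i not in (50, 51, 52, 53):
                chars[i] = AAS[rng.integers(0, 20)]
        seeds.append("".join(chars))
    prof = calibrate(build_profile(seeds, name="cyclase", family="cyclase"), seed=2)
    return prof, block


def _fresh_record():
    return Cas10Record("p", "L1", "Cas10", 1e-30)


def test_cyclase_requires_profile_and_literal_motif(cyclase_setup, rng):
    prof, block = cyclase_setup
    flank = _rand_seq(rng, 150)
    tail = _rand_seq(rng, 250).replace("GGDD", "GGDA")

    # profile hit + literal motif -> positive, first motif in N->C order
    rec = detect_cyclase(_fresh_record(), flank + block + tail, [prof])
    assert rec.has_cyclase and rec.cyclase_motif == "GGDD"
    assert rec.cyclase_motif_pos == 200

    # profile hit but motif ablated -> negative despite the hit
    ablated = block[:50] + "AAAA" + block[54:]
    rec = detect_cyclase(_fresh_record(), flank + ablated + tail, [prof])
    assert not rec.has_cyclase and rec.cyclase_motif is None

    # literal motif without any profile hit -> negative (chance 4-mer)
    rec = detect_cyclase(_fresh_record(), flank + "GGDD" + tail, [prof])
    assert not rec.has_cyclase


def test_cyclase_variant_motifs_accepted(cyclase_setup, rng):
    prof, block = cyclase_setup
    for variant in CYCLASE_MOTIFS:
        seq = _rand_seq(rng, 30) + block[:50] + variant + block[54:] + _rand_seq(rng, 50)
        rec = detect_cyclase(_fresh_record(), seq, [prof])
        assert rec.has_cyclase and rec.cyclase_motif == variant


def test_cyclase_invariant_to_cterminal_extension(cyclase_setup, rng):
    prof, block = cyclase_setup
    core = _rand_seq(rng, 100) + block
    extended = core + _rand_seq(rng, 300).replace("GGDD", "GGDA")
    assert detect_cyclase(_fresh_record(), core, [prof]).has_cyclase
    assert detect_cyclase(_fresh_record(), extended, [prof]).has_cyclase


def test_extract_motif_window_clamping():
    seq = "M" * 500
    assert len(extract_motif_window(seq, 200)) == 154  # 50 + 4 + 100
    assert len(extract_motif_window(seq, 10)) == 114  # clamped at N-terminus
    assert len(extract_motif_window(seq, 480)) == 50 + 20  # clamped at C-terminus


@pytest.fixture(scope="module")
def hd_setup():
    rng = np.random.default_rng(13)
    block = "".join(AAS[i] for i in rng.integers(0, 20, size=31))
    block = block[:5] + "HD" + block[7:]
    seeds = []
    for _ in range(5):
        chars = list(block)
        for i in rng.choice(len(chars), size=2, replace=False):
            if i not in (5, 6):
                chars[i] = AAS[rng.integers(0, 20)]
        seeds.append("".join(chars))
    prof = calibrate(build_profile(seeds, name="HD", family="HD"), seed=3)
    return prof, block


def test_hd_positive_with_block_and_motif(hd_setup, rng):
    prof, block = hd_setup
    seq = _rand_seq(rng, 9).replace("HD", "HA") + block + _rand_seq(rng, 400)
    rec = detect_hd(_fresh_record(), seq, prof)
    assert rec.has_hd
    assert rec.hd_window == seq[9:40]


def test_hd_positional_rule(hd_setup, rng):
    prof, block = hd_setup
    # HD first occurs at residue 80: negative regardless of profile score
    head = _rand_seq(rng, 80).replace("HD", "HA")
    seq = head + "HD" + block + _rand_seq(rng, 300)
    assert not detect_hd(_fresh_record(), seq, prof).has_hd


def test_hd_absent_motif_and_short_sequence(hd_setup, rng):
    prof, _ = hd_setup
    seq = (_rand_seq(rng, 200) + "X").replace("HD", "HA")
    assert not detect_hd(_fresh_record(), seq, prof).has_hd
    with pytest.warns(UserWarning):
        assert not detect_hd(_fresh_record(), "MHD", prof).has_hd


def _locus(lid, subtype):
    return LocusRecord(lid, "g", subtype, "c", 0, 1000)


def test_filter_hybrid_loci():
    loci = [
        _locus("two_cas10", "III-B"),
        _locus("hybrid", "III-B/I-C"),
        _locus("type1", "I-E"),
        _locus("plain", "III-A"),
    ]
    out = filter_hybrid_loci(loci, {"two_cas10": 2, "hybrid": 1, "type1": 0, "plain": 1})
    ids = {l.locus_id: l for l in out}
    assert set(ids) == {"hybrid", "plain"}
    assert ids["hybrid"].subtype == "III-B"  # renamed after the type III subtype


def test_tree_sister_pairs_and_leaf_set(rng):
    a = _rand_seq(rng, 60)
    b = _rand_seq(rng, 60)
    seqs = [("a1", a), ("a2", a[:58] + "WW"), ("b1", b), ("b2", b[:58] + "WW")]
    newick = build_tree(seqs)
    tree = TreeNode.read(StringIO(newick))
    assert {t.name for t in tree.tips()} == {"a1", "a2", "b1", "b2"}
    sisters = {frozenset(t.name for t in n.tips()) for n in tree.non_tips(include_self=True)}
    assert frozenset({"a1", "a2"}) in sisters or frozenset({"b1", "b2"}) in sisters
    for node in tree.traverse():
        assert node.length is None or node.length >= 0


def test_nj_reconstructs_additive_topology():
    # additive distances from ((a:1,b:2):1,(c:3,d:4):1)
    dm = np.array(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        dtype=float,
    )
    tree = TreeNode.read(StringIO(nj_newick(["a", "b", "c", "d"], dm, midpoint_root=False)))
    clades = {frozenset(t.name for t in n.tips()) for n in tree.non_tips(include_self=True)}
    assert frozenset({"a", "b"}) in clades or frozenset({"c", "d"}) in clades


def test_tree_requires_three_sequences(rng):
    with pytest.raises(TreeError):
        build_tree([("a", _rand_seq(rng, 10)), ("b", _rand_seq(rng, 10))])
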