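"""Synthetic genomes with planted ground truth for the census pipeline.

The generator emulates the shape of a real census input: genomes carrying
1-3 type III CRISPR loci, each with a Cas10 gene (>= 520 aa) that may carry
a planted cyclase motif variant inside a conserved PALM context block and/or
an N-terminal HD nuclease block, effector genes with per-family signature
blocks placed within +-4 kb of the operon, candidate-family genes in
effector-less loci, CorA ancillary genes, and background genes. Whether a
locus carries any known effector is drawn from a logistic model with a
planted log-odds ratio against the genome's multi-locus indicator, so the
inter-locus association test has a known truth.

Family signatures are synthetic conserved blocks unique per family (30 aa
for effectors and candidates, 120 aa for Cas10, matching the relative
profile coverage of the families they stand in for; the
artifact tests the census logic, not real family biology; real seed
alignments are a drop-in replacement). Default rates mirror the observed
census: 92% cyclase-positive and 39% HD-positive Cas10s, 88% of loci with
at least one effector, family weights proportional to the observed family
counts, and a planted log-OR of -log(2.57) for effector presence against
the multi-locus indicator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from crispr3census.sequence_io import AMINO_ACIDS, ProteinRecord, GeneAnnotation, LocusRecord
from crispr3census.cas10_census import CYCLASE_MOTIFS
from crispr3census.effector_typing import KNOWN_FAMILIES, CANDIDATE_FAMILIES
from crispr3census.candidate_discovery import CORA_ANCILLARY_FAMILIES

# Family weights proportional to observed locus counts in the census this
# generator emulates (Csx1 411 ... SAVED-CHAT 3).
_FAMILY_WEIGHTS = {
    "Csx1": 411, "Can1-2": 143, "Cami1": 135, "Csm6": 55, "CorA": 53,
    "Cam1": 52, "NucC": 35, "CalpL": 17, "Csx23": 4, "SAVED-CHAT": 3,
}

_FAMILY_LENGTHS = {
    "Csx1": 380, "Csm6": 420, "Can1-2": 340, "Cami1": 300, "CalpL": 520,
    "SAVED-CHAT": 460, "NucC": 260, "Cam1": 240, "Csx23": 180, "CorA": 350,
    "TIR-SAVED": 400, "Cam2": 220, "Cam3": 260, "Csm6-2": 795,
}

_SUBTYPE_WEIGHTS = {"III-A": 0.38, "III-B": 0.30, "III-D": 0.17, "III-C": 0.06, "III-E": 0.03, "III-F": 0.06}

# GGDD predominates; the nine variants share the remainder.
_MOTIF_WEIGHTS = {m: (0.82 if m == "GGDD" else 0.02) for m in CYCLASE_MOTIFS}


@dataclass
class SynthConfig:
    n_genomes: int = 200
    p_multi_locus: float = 0.30
    subtype_weights: dict = field(default_factory=lambda: dict(_SUBTYPE_WEIGHTS))
    p_cyclase: float = 0.92
    motif_variant_weights: dict = field(default_factory=lambda: dict(_MOTIF_WEIGHTS))
    p_hd: float = 0.39
    family_weights: dict = field(default_factory=lambda: dict(_FAMILY_WEIGHTS))
    baseline_effector_logodds: float = math.log(0.88 / 0.12)
    planted_log_or: float = -math.log(2.57)
    n_candidate_families: int = 4
    p_candidate: float = 0.6
    p_second_family: float = 0.25
    p_cora_ancillary: float = 0.7
    p_hybrid: float = 0.04
    noise: float = 0.01
    protect_planted: bool = True
    seed: int = 0

    def validate(self) -> None:
        probs = [self.p_multi_locus, self.p_cyclase, self.p_hd, self.p_candidate,
                 self.p_second_family, self.p_cora_ancillary, self.p_hybrid, self.noise]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("probabilities must be in [0, 1]")
        if self.p_multi_locus == 0 and self.planted_log_or != 0:
            raise ValueError(
                "infeasible config: planted_log_or != 0 requires p_multi_locus > 0"
            )
        if not (1 <= self.n_candidate_families <= len(CANDIDATE_FAMILIES)):
            raise ValueError("n_candidate_families must be in 1..4")


@dataclass
class SyntheticDataset:
    """In-memory synthetic census input plus its ground truth."""

    proteins: list[ProteinRecord]
    annotations: list[GeneAnnotation]
    loci: list[LocusRecord]
    truth: dict
    config: SynthConfig

    def fasta_records(self) -> list[tuple[str, str]]:
        return [(p.protein_id, p.sequence) for p in self.proteins]

    def annotation_frame(self) -> pd.DataFrame:
        prot = {p.protein_id: p for p in self.proteins}
        rows = []
        for ann in self.annotations:
            p = prot[ann.protein_id]
            rows.append(
                {
                    "protein_id": ann.protein_id,
                    "genome_id": p.genome_id,
                    "contig_id": p.contig_id,
                    "start": p.start,
                    "end": p.end,
                    "strand": p.strand,
                    "locus_id": ann.locus_id or "",
                    "annotation_label": ann.annotation_label,
                    "annotation_evalue": "" if ann.annotation_evalue is None else repr(ann.annotation_evalue),
                    "subtype": ann.subtype or "",
                }
            )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        from crispr3census.sequence_io import write_fasta

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "proteins.faa",
            "annotations": out / "annotations.tsv",
            "truth": out / "truth.json",
            "seeds": out / "seed_alignments",
        }
        write_fasta(self.fasta_records(), paths["fasta"])
        self.annotation_frame().to_csv(paths["annotations"], sep="\t", index=False)
        paths["truth"].write_text(json.dumps(self.truth, indent=1, sort_keys=True) + "\n")
        seeds = make_seed_alignments(self.config)
        paths["seeds"].mkdir(exist_ok=True)
        for name, rows in sorted(seeds.items()):
            with (paths["seeds"] / f"{name}.afa").open("w") as fh:
                for i, row in enumerate(rows):
                    fh.write(f">{name}_{i}\n{row}\n")
        return paths


# ---------------------------------------------------------------------------
# signature construction (deterministic in config.seed)

_SIG_STREAM = 101
_SEED_STREAM = 202
_GENOME_STREAM = 303


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float, protected: set[int] = frozenset()) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if i in protected:
            continue
        if rng.random() < rate:
            chars[i] = AMINO_ACIDS[rng.integers(0, 20)]
    return "".join(chars)


def family_signatures(config: SynthConfig) -> dict[str, str]:
    """Per-family synthetic signature blocks, plus the cyclase PALM context
    block (154 aa, active-site slot at offset 50) and the HD block (31 aa,
    'HD' at offset 5). Deterministic in config.seed."""
    rng = np.random.default_rng([config.seed, _SIG_STREAM])
    sigs: dict[str, str] = {"Cas10": _rand_seq(rng, 120)}
    for fam in KNOWN_FAMILIES:
        sigs[fam] = _rand_seq(rng, 30)
    # candidate families are full-length bases: their discovery path relies
    # on global identity (clustering, cross-locus search), not profile hits
    for fam in CANDIDATE_FAMILIES[: config.n_candidate_families]:
        sigs[fam] = _rand_seq(rng, _FAMILY_LENGTHS[fam])
    for fam in CORA_ANCILLARY_FAMILIES:
        sigs[fam] = _rand_seq(rng, 200)
    cyc = _rand_seq(rng, 154)
    sigs["cyclase"] = cyc[:50] + "GGDD" + cyc[54:]
    hd = _rand_seq(rng, 31)
    sigs["HD"] = hd[:5] + "HD" + hd[7:]
    return sigs


def make_seed_alignments(config: SynthConfig, n_rows: int = 6, mutation_rate: float = 0.05) -> dict[str, list[str]]:
    """Trivially aligned (equal-length, gap-free) seed families for profiles.

    One alignment per profile family: Cas10, the known effectors, the
    candidate families, the CorA ancillaries, the cyclase PALM context and
    the HD block. Rows are independently mutated copies of the signature;
    active-site positions (the cyclase 4-mer slot and the HD 2-mer) are kept
    intact so literal-motif semantics survive.
    """
    config.validate()
    sigs = family_signatures(config)
    rng = np.random.default_rng([config.seed, _SEED_STREAM])
    out: dict[str, list[str]] = {}
    for name in sorted(sigs):
        base = sigs[name]
        protected: set[int] = set()
        if name == "cyclase":
            protected = {50, 51, 52, 53}
        elif name == "HD":
            protected = {5, 6}
        out[name] = [_mutate(rng, base, mutation_rate, protected) for _ in range(n_rows)]
    return out


# ---------------------------------------------------------------------------
# genome generation


def _weighted_choice(rng: np.random.Generator, weights: Mapping[str, float]) -> str:
    keys = sorted(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


class _GeneEmitter:
    """Lays genes on one contig with 200-2000 nt intergenic gaps."""

    def __init__(self, rng: np.random.Generator, genome_id: str, contig_id: str):
        self.rng = rng
        self.genome_id = genome_id
        self.contig_id = contig_id
        self.pos = int(rng.integers(500, 2000))
        self.n = 0
        self.proteins: list[ProteinRecord] = []
        self.annotations: list[GeneAnnotation] = []

    def gap(self, lo: int = 200, hi: int = 2000) -> None:
        self.pos += int(self.rng.integers(lo, hi))

    def emit(self, sequence: str, label: str, evalue: float | None,
             locus_id: str | None, subtype: str | None) -> ProteinRecord:
        self.n += 1
        pid = f"{self.genome_id}_p{self.n:03d}"
        start = self.pos
        end = start + 3 * len(sequence)
        self.pos = end
        strand = "+" if self.rng.random() < 0.5 else "-"
        prot = ProteinRecord(pid, self.genome_id, self.contig_id, start, end, strand, sequence)
        self.proteins.append(prot)
        self.annotations.append(GeneAnnotation(pid, locus_id, label, evalue, subtype))
        return prot


def generate(config: SynthConfig) -> SyntheticDataset:
    """Generate the synthetic census input with full truth labels.

    Deterministic in config.seed: the same config yields byte-identical
    outputs. Substitution noise at config.noise is applied everywhere except
    planted signature blocks and motifs when ``protect_planted`` is set.
    """
    config.validate()
    sigs = family_signatures(config)
    rng = np.random.default_rng([config.seed, _GENOME_STREAM])
    candidate_menu = list(CANDIDATE_FAMILIES[: config.n_candidate_families])

    proteins: list[ProteinRecord] = []
    annotations: list[GeneAnnotation] = []
    loci: list[LocusRecord] = []
    truth_proteins: dict[str, dict] = {}
    truth_cas10: dict[str, dict] = {}
    truth_loci: dict[str, dict] = {}
    truth_genomes: dict[str, dict] = {}

    def noisy(seq: str, protected: set[int]) -> str:
        prot = protected if config.protect_planted else set()
        return _mutate(rng, seq, config.noise, prot)

    def plant(base_len: int, blocks: list[tuple[int, str]]) -> tuple[str, set[int]]:
        """Random sequence of base_len with blocks planted at given offsets."""
        chars = list(_rand_seq(rng, base_len))
        protected: set[int] = set()
        for off, block in blocks:
            chars[off : off + len(block)] = list(block)
            protected.update(range(off, off + len(block)))
        return "".join(chars), protected

    for g in range(config.n_genomes):
        genome_id = f"G{g:04d}"
        contig_id = f"{genome_id}_c1"
        multi = rng.random() < config.p_multi_locus
        n_loci = int(rng.integers(2, 4)) if multi else 1
        truth_genomes[genome_id] = {"n_loci": n_loci, "multi_locus": multi}
        em = _GeneEmitter(rng, genome_id, contig_id)

        for li in range(n_loci):
            locus_id = f"{genome_id}_L{li + 1}"
            subtype = _weighted_choice(rng, config.subtype_weights)
            reported_subtype = subtype
            if rng.random() < config.p_hybrid:
                reported_subtype = f"{subtype}/I-C"

            if li > 0:
                em.gap(12000, 20000)  # keep loci well apart on the contig

            member_ids: list[str] = []

            # a couple of leading interference-complex genes
            for label in ("Cas7", "Cas5")[: int(rng.integers(1, 3))]:
                seq = noisy(_rand_seq(rng, int(rng.integers(150, 300))), set())
                p = em.emit(seq, label, 1e-30, locus_id, reported_subtype)
                member_ids.append(p.protein_id)
                truth_proteins[p.protein_id] = {"role": "background", "family": None, "locus_id": locus_id}
                em.gap()

            # the Cas10 gene
            has_cyclase = rng.random() < config.p_cyclase
            has_hd = rng.random() < config.p_hd
            motif = _weighted_choice(rng, config.motif_variant_weights) if has_cyclase else None
            base_len = 520 + int(rng.integers(0, 120))
            blocks = [(60, sigs["Cas10"])]
            if has_hd:
                blocks.append((9, sigs["HD"]))
            if has_cyclase:
                cyc = sigs["cyclase"]
                blocks.append((200, cyc[:50] + motif + cyc[54:]))
            seq, protected = plant(base_len, blocks)
            seq = noisy(seq, protected)
            cas10 = em.emit(seq, "Cas10", 1e-50, locus_id, reported_subtype)
            member_ids.append(cas10.protein_id)
            operon_start = em.proteins[len(em.proteins) - len(member_ids)].start
            truth_proteins[cas10.protein_id] = {"role": "cas10", "family": "Cas10", "locus_id": locus_id}
            truth_cas10[cas10.protein_id] = {
                "has_cyclase": has_cyclase,
                "cyclase_motif": motif,
                "cyclase_motif_pos": 250 if has_cyclase else None,
                "has_hd": has_hd,
            }
            operon_end = cas10.end

            # effector presence from the planted logistic model
            logit = config.baseline_effector_logodds + config.planted_log_or * (1 if multi else 0)
            has_effector = rng.random() < 1.0 / (1.0 + math.exp(-logit))
            families: list[str] = []
            if has_effector:
                families.append(_weighted_choice(rng, config.family_weights))
                if rng.random() < config.p_second_family:
                    rest = {f: w for f, w in config.family_weights.items() if f not in families}
                    families.append(_weighted_choice(rng, rest))

            for fam in families:
                em.gap(100, 600)
                L = _FAMILY_LENGTHS[fam]
                seq, protected = plant(L, [(20, sigs[fam])])
                seq = noisy(seq, protected)
                p = em.emit(seq, "Unknown", None, locus_id, reported_subtype)
                member_ids.append(p.protein_id)
                truth_proteins[p.protein_id] = {"role": "effector", "family": fam, "locus_id": locus_id}

            # CorA ancillary enzymes near CorA loci
            ancillaries: list[str] = []
            if "CorA" in families:
                for anc in CORA_ANCILLARY_FAMILIES:
                    if rng.random() < config.p_cora_ancillary:
                        em.gap(100, 600)
                        seq = _mutate(rng, sigs[anc], 0.1)
                        p = em.emit(seq, "Unknown", None, locus_id, reported_subtype)
                        member_ids.append(p.protein_id)
                        truth_proteins[p.protein_id] = {"role": "ancillary", "family": anc, "locus_id": locus_id}
                        ancillaries.append(anc)

            # candidate-family genes only in effector-less loci
            candidate_fam = None
            if not families and rng.random() < config.p_candidate:
                candidate_fam = candidate_menu[int(rng.integers(0, len(candidate_menu)))]
                em.gap(100, 600)
                seq = _mutate(rng, sigs[candidate_fam], 0.1)
                if rng.random() < 0.5:
                    label, ev = "Unknown", None
                else:
                    label, ev = "CasR", 1e-5  # confident-looking but poor E-value
                p = em.emit(seq, label, ev, locus_id, reported_subtype)
                member_ids.append(p.protein_id)
                truth_proteins[p.protein_id] = {"role": "candidate", "family": candidate_fam, "locus_id": locus_id}

            loci.append(
                LocusRecord(
                    locus_id=locus_id,
                    genome_id=genome_id,
                    subtype=reported_subtype,
                    contig_id=contig_id,
                    operon_start=operon_start,
                    operon_end=operon_end,
                    member_proteins=member_ids,
                    cas10_id=cas10.protein_id,
                )
            )
            truth_loci[locus_id] = {
                "genome_id": genome_id,
                "subtype": subtype,
                "families": sorted(families),
                "candidate_family": candidate_fam,
                "ancillaries": sorted(ancillaries),
                "multi_locus": multi,
            }

            # distant background gene, > 4 kb past the cassette
            em.gap(6000, 9000)
            seq = noisy(_rand_seq(rng, int(rng.integers(150, 400))), set())
            p = em.emit(seq, "Unknown", None, None, None)
            truth_proteins[p.protein_id] = {"role": "background", "family": None, "locus_id": None}

        proteins.extend(em.proteins)
        annotations.extend(em.annotations)

    truth = {
        "proteins": truth_proteins,
        "cas10": truth_cas10,
        "loci": truth_loci,
        "genomes": truth_genomes,
        "config": {k: (dict(v) if isinstance(v, dict) else v) for k, v in asdict(config).items()},
    }
    return SyntheticDataset(proteins, annotations, loci, truth, config)


def simulate_census(
    n_loci: int,
    log_or: float,
    seed: int,
    baseline_logodds: float = math.log(0.88 / 0.12),
    p_multi: float = 0.4,
) -> pd.DataFrame:
    """Lightweight locus-level census table for association-test simulations.

    Draws, per locus, a multi-locus indicator x ~ Bernoulli(p_multi) and
    effector presence y from the logistic model logit(p) = baseline +
    log_or * x. Generates census rows directly (no sequences), which keeps
    large replicate studies of the GLM cheap. Each locus is given its own
    genome (the GLM treats loci as independent anyway).
    """
    rng = np.random.default_rng(seed)
    x = rng.random(n_loci) < p_multi
    p = 1.0 / (1.0 + np.exp(-(baseline_logodds + log_or * x.astype(float))))
    y = rng.random(n_loci) < p
    rows = []
    for i in range(n_loci):
        rows.append(
            {
                "locus_id": f"L{i:05d}",
                "genome_id": f"G{i:05d}",
                "subtype": "III-A",
                "has_cyclase": True,
                "has_hd": False,
                "families": frozenset({"Csx1"}) if y[i] else frozenset(),
                "activators": frozenset({"cA4"}) if y[i] else frozenset(),
                "n_type3_loci_in_genome": 2 if x[i] else 1,
            }
        )
    return pd.DataFrame(rows)
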