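"""End-to-end orchestration: ingest -> profiles -> Cas10 census -> hybrid
filter -> effector typing -> candidate discovery -> CorA analysis ->
statistics -> reports.

Every stage writes its TSV/JSON artifact; an effective-config YAML, a
line-oriented run log with per-stage record counts, and a MANIFEST
(path, sha256, rows) are always written. Reruns with identical inputs,
config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from crispr3census import sequence_io as sio
from crispr3census import profile_engine as pe
from crispr3census import cas10_census as cc
from crispr3census import effector_typing as et
from crispr3census import candidate_discovery as cd
from crispr3census import cooccurrence_stats as cs


@dataclass
class PipelineConfig:
    """Every numeric threshold the pipeline consumes, with its default.

    Defaults are the census workflow's operating points: Cas10 length >= 500
    aa at E <= 1e-20, dereplication at 0.9 identity / word 5, cyclase call at
    E <= 1e-3, HD call at E <= 1e-1 on residues 10-40 with the literal 'HD'
    in the first 50, effector search in operon +-4 kb, candidate flagging
    above E-value 1e-7 with clustering at 0.4 identity / word 2.
    """

    min_cas10_len: int = 500
    cas10_evalue: float = 1e-20
    derep_identity: float = 0.9
    derep_word_size: int = 5
    cyclase_evalue: float = 1e-3
    hd_evalue: float = 1e-1
    hd_scan_first: int = 50
    hd_extract_start: int = 10
    hd_extract_end: int = 40
    cyclase_window_upstream: int = 50
    cyclase_window_downstream: int = 100
    neighborhood_flank: int = 4000
    effector_evalue: float = 1e-3
    candidate_evalue_floor: float = 1e-7
    candidate_cluster_identity: float = 0.4
    candidate_cluster_word_size: int = 2
    cross_locus_identity_min: float = 0.3
    ancillary_identity_min: float = 0.3
    gba_min_recurrence: int = 2
    calibration_n_shuffles: int = 200
    calibration_length: int = 400
    calibration_seed: int = 0
    profile_pseudocount: float = 1.0
    build_trees: bool = True

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _rows(path: Path) -> int:
    if path.suffix in (".tsv", ".csv"):
        with path.open() as fh:
            return max(sum(1 for _ in fh) - 1, 0)
    return 1


class _Run:
    """Artifact bookkeeping for one pipeline run."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        out_dir.mkdir(parents=True, exist_ok=True)
        self.manifest: list[dict] = []
        self.log_lines: list[str] = []
        self.t0 = time.time()

    def log(self, stage: str, message: str) -> None:
        self.log_lines.append(f"[{stage}] {message}")

    def register(self, path: Path) -> None:
        self.manifest.append(
            {"path": path.name, "sha256": _sha256(path), "rows": _rows(path)}
        )

    def finalize(self, complete: bool, failed_stage: str | None = None) -> None:
        (self.out_dir / "run.log").write_text("\n".join(self.log_lines) + "\n")
        manifest = {
            "complete": complete,
            "failed_stage": failed_stage,
            "artifacts": sorted(self.manifest, key=lambda a: a["path"]),
        }
        (self.out_dir / "MANIFEST.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )


def load_seed_alignments(seeds_dir: str | Path) -> dict[str, list[str]]:
    """Read one aligned FASTA per profile family from a directory."""
    out = {}
    for path in sorted(Path(seeds_dir).glob("*.afa")):
        out[path.stem] = pe.read_aligned_fasta(path)
    return out


def build_profile_library(
    seed_alignments: Mapping[str, Sequence[str]], config: PipelineConfig
) -> dict[str, pe.Profile]:
    """Build and calibrate one profile per seed family."""
    profiles = {}
    for name in sorted(seed_alignments):
        prof = pe.build_profile(
            seed_alignments[name], name=name, family=name,
            pseudocount=config.profile_pseudocount,
        )
        pe.calibrate(
            prof,
            n_shuffles=config.calibration_n_shuffles,
            length=config.calibration_length,
            seed=config.calibration_seed,
        )
        profiles[name] = prof
    return profiles


def loci_from_annotations(
    joined: Sequence[tuple[sio.ProteinRecord, sio.GeneAnnotation]]
) -> list[sio.LocusRecord]:
    """Assemble locus records from the annotation table.

    Operon boundaries are taken verbatim from the input table as the span of
    the genes sharing a locus_id (the upstream caller's contract).
    """
    by_locus: dict[str, list[tuple[sio.ProteinRecord, sio.GeneAnnotation]]] = {}
    for prot, ann in joined:
        if ann.locus_id:
            by_locus.setdefault(ann.locus_id, []).append((prot, ann))
    loci = []
    for locus_id in sorted(by_locus):
        rows = sorted(by_locus[locus_id], key=lambda pa: pa[0].start)
        subtype = next((a.subtype for _, a in rows if a.subtype), "unknown")
        loci.append(
            sio.LocusRecord(
                locus_id=locus_id,
                genome_id=rows[0][0].genome_id,
                subtype=subtype,
                contig_id=rows[0][0].contig_id,
                operon_start=min(p.start for p, _ in rows),
                operon_end=max(p.end for p, _ in rows),
                member_proteins=[p.protein_id for p, _ in rows],
            )
        )
    return loci


def run_pipeline(
    fasta_path: str | Path,
    annotations_path: str | Path,
    seeds_dir: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full census. Returns a result dict; artifacts land in out_dir.

    On stage failure raises :class:`StageFailure` after writing a MANIFEST
    marking the run incomplete and naming the failed stage; artifacts of
    completed stages are retained.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    run = _Run(out)
    (out / "effective_config.yaml").write_text(config.to_yaml())
    run.register(out / "effective_config.yaml")
    results: dict = {}
    stage = "ingest"
    try:
        # ---------------- ingest ----------------
        fasta = sio.read_fasta(fasta_path)
        joined = sio.read_annotation_table(annotations_path, fasta)
        proteins = [p for p, _ in joined]
        annotations = {a.protein_id: a for _, a in joined}
        sequences = {p.protein_id: p.sequence for p in proteins}
        locus_of = {a.protein_id: a.locus_id for _, a in joined}
        loci = loci_from_annotations(joined)
        run.log(stage, f"proteins={len(proteins)} loci={len(loci)}")

        # ---------------- profiles ----------------
        stage = "profiles"
        seeds = load_seed_alignments(seeds_dir)
        if not seeds:
            raise ValueError(f"no seed alignments (*.afa) found in {seeds_dir}")
        profiles = build_profile_library(seeds, config)
        profile_rows = [
            {"name": p.name, "length": p.length, "gumbel_mu": round(p.gumbel_mu, 6),
             "gumbel_lambda": round(p.gumbel_lambda, 6)}
            for p in profiles.values()
        ]
        pd.DataFrame(profile_rows).to_csv(out / "profiles.tsv", sep="\t", index=False)
        run.register(out / "profiles.tsv")
        run.log(stage, f"profiles={len(profiles)}")

        # ---------------- cas10 census ----------------
        stage = "cas10_census"
        cas10_profiles = [profiles[n] for n in profiles if n == "Cas10"]
        cas10s = cc.find_cas10(
            proteins, cas10_profiles, locus_of=locus_of,
            min_len=config.min_cas10_len, cutoff=config.cas10_evalue,
        )
        cas10s = cc.dereplicate(
            cas10s, sequences,
            identity_threshold=config.derep_identity, word_size=config.derep_word_size,
        )
        cyclase_profiles = [profiles[n] for n in profiles if n == "cyclase"]
        hd_profile = profiles.get("HD")
        n_cas10 = len(cas10s)
        for rec in cas10s:
            cc.detect_cyclase(
                rec, sequences[rec.protein_id], cyclase_profiles,
                cutoff=config.cyclase_evalue, db_size=n_cas10,
            )
            if hd_profile is not None:
                cc.detect_hd(
                    rec, sequences[rec.protein_id], hd_profile,
                    cutoff=config.hd_evalue, first_n=config.hd_scan_first,
                    extract_start=config.hd_extract_start,
                    extract_end=config.hd_extract_end, db_size=n_cas10,
                )
        run.log(stage, f"cas10={n_cas10} reps={sum(r.cluster_rep for r in cas10s)}")

        # ---------------- hybrid filter ----------------
        stage = "hybrid_filter"
        cas10_count: dict[str, int] = {}
        for rec in cas10s:
            if rec.locus_id:
                cas10_count[rec.locus_id] = cas10_count.get(rec.locus_id, 0) + 1
        loci = cc.filter_hybrid_loci(loci, cas10_count)
        cas10_by_locus = {r.locus_id: r for r in cas10s if r.locus_id}
        loci = [l for l in loci if l.locus_id in cas10_by_locus]
        for locus in loci:
            locus.cas10_id = cas10_by_locus[locus.locus_id].protein_id
        cas10_tsv = pd.DataFrame(
            [
                {
                    "protein_id": r.protein_id,
                    "locus_id": r.locus_id or "",
                    "best_profile": r.best_cas10_profile,
                    "has_cyclase": r.has_cyclase,
                    "cyclase_motif": r.cyclase_motif or "",
                    "cyclase_motif_pos": "" if r.cyclase_motif_pos is None else r.cyclase_motif_pos,
                    "has_hd": r.has_hd,
                    "cluster_rep": r.cluster_rep,
                }
                for r in sorted(cas10s, key=lambda r: r.protein_id)
            ]
        )
        cas10_tsv.to_csv(out / "cas10_census.tsv", sep="\t", index=False)
        run.register(out / "cas10_census.tsv")
        run.log(stage, f"loci_after_filter={len(loci)}")

        # ---------------- effector typing ----------------
        stage = "effector_typing"
        effector_libs = {
            fam: [profiles[fam]] for fam in et.KNOWN_FAMILIES if fam in profiles
        }
        by_contig: dict[str, list[sio.ProteinRecord]] = {}
        for p in proteins:
            by_contig.setdefault(p.contig_id, []).append(p)
        all_hits: list[et.EffectorHit] = []
        cross_rows: list[dict] = []
        neighborhood_ids = set()
        neighborhoods = {}
        for locus in loci:
            nb = et.locus_neighborhood(
                locus, by_contig.get(locus.contig_id, []), flank=config.neighborhood_flank
            )
            nb = [p for p in nb if p.protein_id != locus.cas10_id]
            neighborhoods[locus.locus_id] = nb
            neighborhood_ids.update(p.protein_id for p in nb)
        db_size = max(len(neighborhood_ids), 1)
        for locus in loci:
            nb = neighborhoods[locus.locus_id]
            all_hits.extend(
                et.type_effectors(
                    nb, locus.locus_id, effector_libs,
                    cutoff=config.effector_evalue, db_size=db_size,
                )
            )
            cross_rows.extend(
                et.detect_cross_hits(nb, effector_libs, cutoff=config.effector_evalue, db_size=db_size)
            )
        pd.DataFrame(
            [
                {
                    "protein_id": h.protein_id, "locus_id": h.locus_id, "family": h.family,
                    "bitscore": round(h.bitscore, 4), "evalue": f"{h.evalue:.6g}",
                    "tm_count": h.tm_count, "resolution": h.resolution, "activator": h.activator,
                }
                for h in sorted(all_hits, key=lambda h: h.protein_id)
            ]
        ).to_csv(out / "effector_hits.tsv", sep="\t", index=False)
        run.register(out / "effector_hits.tsv")
        pd.DataFrame(
            [
                {"protein_id": r["protein_id"], "families": ",".join(r["families"]),
                 "auto_resolved": r["auto_resolved"]}
                for r in sorted(cross_rows, key=lambda r: r["protein_id"])
            ],
            columns=["protein_id", "families", "auto_resolved"],
        ).to_csv(out / "cross_hits.tsv", sep="\t", index=False)
        run.register(out / "cross_hits.tsv")
        run.log(stage, f"effector_hits={len(all_hits)} cross_hits={len(cross_rows)}")

        # ---------------- candidate discovery ----------------
        stage = "candidate_discovery"
        flagged = cd.flag_candidates(
            loci, annotations, all_hits, evalue_floor=config.candidate_evalue_floor
        )
        flagged = cd.cluster_candidates(
            flagged, sequences,
            identity_threshold=config.candidate_cluster_identity,
            word_size=config.candidate_cluster_word_size,
        )
        reps = [c for c in flagged if c.is_representative]
        occurrence, gba = cd.cross_locus_search(
            reps, loci, sequences, annotations,
            identity_min=config.cross_locus_identity_min,
            min_recurrence=config.gba_min_recurrence,
        )
        candidate_rows = flagged + gba
        pd.DataFrame(
            [
                {
                    "protein_id": c.protein_id, "locus_id": c.locus_id,
                    "flag_reason": c.flag_reason,
                    "cluster_id": "" if c.cluster_id is None else c.cluster_id,
                    "is_representative": c.is_representative,
                    "occurrence_count": c.occurrence_count,
                }
                for c in sorted(candidate_rows, key=lambda c: c.protein_id)
            ]
        ).to_csv(out / "candidates.tsv", sep="\t", index=False)
        run.register(out / "candidates.tsv")
        run.log(stage, f"flagged={len(flagged)} reps={len(reps)} gba={len(gba)}")

        # ---------------- CorA analysis ----------------
        stage = "cora_analysis"
        cora_ids = {h.protein_id for h in all_hits if h.family == "CorA"}
        ancillary_seeds = {
            fam: seeds[fam] for fam in cd.CORA_ANCILLARY_FAMILIES if fam in seeds
        }
        cora_rows = []
        for locus in loci:
            presence = cd.detect_cora_ancillary(
                locus, sequences, ancillary_seeds, cora_ids,
                identity_min=config.ancillary_identity_min,
            )
            if presence is not None:
                row = {"locus_id": locus.locus_id}
                row.update({fam: presence.get(fam, False) for fam in cd.CORA_ANCILLARY_FAMILIES})
                cora_rows.append(row)
        pd.DataFrame(
            cora_rows, columns=["locus_id", *cd.CORA_ANCILLARY_FAMILIES]
        ).to_csv(out / "cora_ancillary.tsv", sep="\t", index=False)
        run.register(out / "cora_ancillary.tsv")
        if config.build_trees and len(cora_ids) >= 3:
            cora_seqs = sorted((pid, sequences[pid]) for pid in cora_ids)
            (out / "cora_tree.nwk").write_text(cc.build_tree(cora_seqs) + "\n")
            run.register(out / "cora_tree.nwk")
        run.log(stage, f"cora_loci={len(cora_rows)}")

        # ---------------- census + statistics ----------------
        stage = "statistics"
        hits_by_locus: dict[str, set[str]] = {}
        for h in all_hits:
            hits_by_locus.setdefault(h.locus_id, set()).add(h.family)
        loci_per_genome: dict[str, int] = {}
        for locus in loci:
            loci_per_genome[locus.genome_id] = loci_per_genome.get(locus.genome_id, 0) + 1
        census_rows = []
        for locus in loci:
            rec = cas10_by_locus[locus.locus_id]
            fams = frozenset(hits_by_locus.get(locus.locus_id, set()))
            census_rows.append(
                {
                    "locus_id": locus.locus_id,
                    "genome_id": locus.genome_id,
                    "subtype": locus.subtype,
                    "has_cyclase": rec.has_cyclase,
                    "has_hd": rec.has_hd,
                    "families": fams,
                    "activators": frozenset(et.ACTIVATOR_MAP[f] for f in fams),
                    "n_type3_loci_in_genome": loci_per_genome[locus.genome_id],
                }
            )
        census = cs.make_census_table(census_rows)
        sio.write_census(census, out / "census.tsv", out / "census.json")
        run.register(out / "census.tsv")
        run.register(out / "census.json")

        counts, total = cs.count_families(census)
        M, proportions = cs.cooccurrence_matrix(census)
        configs = cs.upset_configurations(census)
        stats = {
            "n_loci": len(census),
            "total_effector_instances": total,
            "family_counts": dict(sorted(counts.items())),
            "cooccurrence_proportion": {f: round(p, 4) for f, p in sorted(proportions.items())},
            "activator_fractions": {
                act: round(cs.activator_fraction(counts, act), 4)
                for act in sorted(set(et.ACTIVATOR_MAP.values()))
            },
            "pct_has_cyclase": cs.round_half_up_pct(census["has_cyclase"].mean()),
            "pct_has_hd": cs.round_half_up_pct(census["has_hd"].mean()),
        }
        try:
            assoc = cs.interlocus_association(census)
            stats["interlocus_glm"] = {
                "coefficient": assoc["glm"].coefficient,
                "std_error": assoc["glm"].std_error,
                "z": assoc["glm"].z,
                "p_value": assoc["glm"].p_value,
                "odds_ratio": assoc["glm"].odds_ratio,
                "multi_locus_odds_ratio_when_effectorless": assoc["multi_locus_odds_ratio_when_effectorless"],
                "n": assoc["glm"].n,
                "note": assoc["glm"].note,
            }
        except cs.SeparationError as exc:
            stats["interlocus_glm"] = {"error": str(exc)}
        (out / "statistics.json").write_text(json.dumps(stats, indent=1, sort_keys=True) + "\n")
        run.register(out / "statistics.json")
        cs.cooccurrence_edge_list(M).to_csv(out / "cooccurrence_edges.tsv", sep="\t", index=False)
        run.register(out / "cooccurrence_edges.tsv")
        upset_df = pd.DataFrame(
            [
                {"families": ",".join(sorted(k)), "count": v["count"],
                 "by_subtype": json.dumps(v["by_subtype"], sort_keys=True)}
                for k, v in sorted(configs.items(), key=lambda kv: (",".join(sorted(kv[0]))))
            ]
        )
        upset_df.to_csv(out / "upset_configurations.tsv", sep="\t", index=False)
        run.register(out / "upset_configurations.tsv")
        run.log(stage, f"census_rows={len(census)} effector_instances={total}")

        # ---------------- Cas10 tree ----------------
        stage = "cas10_tree"
        surviving = {l.locus_id for l in loci}
        reps_seqs = sorted(
            (r.protein_id, sequences[r.protein_id])
            for r in cas10s
            if r.cluster_rep and r.locus_id in surviving
        )
        if config.build_trees and len(reps_seqs) >= 3:
            (out / "cas10_tree.nwk").write_text(cc.build_tree(reps_seqs) + "\n")
            run.register(out / "cas10_tree.nwk")
            leaf_meta = cas10_tsv[cas10_tsv["protein_id"].isin({p for p, _ in reps_seqs})]
            leaf_meta.to_csv(out / "cas10_tree_leaves.tsv", sep="\t", index=False)
            run.register(out / "cas10_tree_leaves.tsv")
            run.log(stage, f"leaves={len(reps_seqs)}")

        results = {
            "census": census,
            "cas10s": cas10s,
            "loci": loci,
            "effector_hits": all_hits,
            "candidates": candidate_rows,
            "stats": stats,
        }
    except Exception as exc:
        run.log(stage, f"FAILED: {exc}")
        run.finalize(complete=False, failed_stage=stage)
        raise StageFailure(stage, exc) from exc
    run.finalize(complete=True)
    return results


def stats_only(census_tsv: str | Path, out_path: str | Path) -> dict:
    """Recompute the statistics stage from a prior census TSV (no rescanning)."""
    df = pd.read_csv(census_tsv, sep="\t", keep_default_na=False)
    df["families"] = df["families"].map(
        lambda s: frozenset(x for x in str(s).split(",") if x)
    )
    df["activators"] = df["activators"].map(
        lambda s: frozenset(x for x in str(s).split(",") if x)
    )
    census = cs.make_census_table(df.to_dict(orient="records"))
    counts, total = cs.count_families(census)
    stats = {
        "n_loci": len(census),
        "total_effector_instances": total,
        "family_counts": dict(sorted(counts.items())),
    }
    try:
        assoc = cs.interlocus_association(census)
        stats["interlocus_glm"] = {
            "coefficient": assoc["glm"].coefficient,
            "odds_ratio": assoc["glm"].odds_ratio,
            "multi_locus_odds_ratio_when_effectorless": assoc["multi_locus_odds_ratio_when_effectorless"],
            "z": assoc["glm"].z,
            "p_value": assoc["glm"].p_value,
        }
    except cs.SeparationError as exc:
        stats["interlocus_glm"] = {"error": str(exc)}
    Path(out_path).write_text(json.dumps(stats, indent=1, sort_keys=True) + "\n")
    return stats
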