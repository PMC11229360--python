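"""Identify Cas10 proteins and call their cyclase and HD nuclease domains.

Cas10 identification: length >= 500 aa, then a calibrated profile hit at
E <= 1e-20. The cyclase call is two-stage — a profile hit at E <= 1e-3 AND a
literal active-site motif (GGDD or one of nine observed variants). The HD
call needs the literal 'HD' in the first 50 residues AND a profile hit on
residues 10-40 at E <= 0.1.
"""

from crispr3census import SynthConfig, find_cas10, detect_cyclase, detect_hd
from crispr3census.pipeline import PipelineConfig, build_profile_library
from crispr3census.synthetic_data import generate, make_seed_alignments

config = SynthConfig(n_genomes=10, seed=7, noise=0.0)
dataset = generate(config)
profiles = build_profile_library(make_seed_alignments(config), PipelineConfig())

sequences = {p.protein_id: p.sequence for p in dataset.proteins}
locus_of = {a.protein_id: a.locus_id for a in dataset.annotations}

cas10s = find_cas10(dataset.proteins, [profiles["Cas10"]], locus_of=locus_of)
for rec in cas10s:
    detect_cyclase(rec, sequences[rec.protein_id], [profiles["cyclase"]], db_size=len(cas10s))
    detect_hd(rec, sequences[rec.protein_id], profiles["HD"], db_size=len(cas10s))

n_cyc = sum(r.has_cyclase for r in cas10s)
n_hd = sum(r.has_hd for r in cas10s)
print(f"Cas10 proteins identified: {len(cas10s)}")
print(f"cyclase-positive: {n_cyc}; HD-positive: {n_hd}")
print()
print("protein        cyclase  motif  pos   HD")
for rec in cas10s[:8]:
    motif = rec.cyclase_motif or "-"
    pos = rec.cyclase_motif_pos if rec.cyclase_motif_pos is not None else "-"
    print(f"{rec.protein_id:14s} {str(rec.has_cyclase):7s}  {motif:5s}  {str(pos):4s}  {rec.has_hd}")
print()
print("A cyclase-positive call means the locus can synthesize cyclic")
print("oligoadenylate second messengers; HD marks the ssDNA nuclease domain.")
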