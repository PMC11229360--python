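# crispr3census

A tested, reusable pipeline for the bioinformatic census of **type III
CRISPR-Cas loci**: from per-genome protein sequences and a locus annotation
table to Cas10 domain calls, known-effector typing, novel-effector candidate
discovery, co-occurrence statistics and the inter-locus signalling
association test.

## The scientific problem

Type III CRISPR systems recognise invader RNA and respond through the Cas10
subunit, which can carry two catalytic modules: an **HD nuclease** domain
(single-stranded DNA cleavage) and a **PALM cyclase** domain that synthesises
cyclic oligoadenylate (cOA) second messengers — cA₃, cA₄, cA₆ — or SAM-AMP.
These messengers switch on *ancillary effector* proteins encoded near the
locus (Csx1, Csm6, Can1-2, Cami1, CalpL, SAVED-CHAT, NucC, Cam1, Csx23,
CorA), which degrade nucleic acids or depolarise the membrane to abort
infection. Mapping which loci carry which domains and effectors, how
effectors co-occur, and whether effector-lacking loci rely on effectors
encoded by *other* loci in the same genome, requires a census over many
genomes. This package implements that census as a library with a thin CLI.

The core calls are:

- **Cas10 identification** — proteins ≥ 500 aa with a calibrated profile hit
  at E ≤ 10⁻²⁰, dereplicated by greedy clustering at 0.9 identity (word
  size 5).
- **Cyclase call (two-stage)** — a cyclase-profile hit at E ≤ 10⁻³ **and** a
  literal active-site motif, one of
  GGDD, AGDD, GGED, GGDE, SGDD, DGDD, AGDE, EGDD, KGDD, GEDD.
  A profile hit without the literal motif is a degenerate PALM domain, not
  an active cyclase.
- **HD call** — the literal `HD` within the first 50 residues **and** a
  profile hit on residues 10–40 at E ≤ 0.1.
- **Effector typing** — every protein whose gene intersects the locus operon
  ± 4 kb is scanned against all family libraries; multi-family hits resolve
  by best bitscore, except Csx1/Cam1 cross-hits (shared CARF sensors), which
  resolve by predicted transmembrane helices (Cam1 requires one, Csx1 its
  absence).
- **Candidate discovery** — genes annotated `Unknown` or only at E > 10⁻⁷,
  in loci with *no* known effector, clustered at 0.4 identity (word size 2),
  with cross-locus recurrence counts and guilt-by-association neighbours.
- **Inter-locus association** — a locus-level binomial GLM (logistic
  regression, IRLS) of effector presence on the multi-locus-genome
  indicator:

  logit P(effector) = β₀ + β·𝟙[n_loci ≥ 2],  OR = e^β.

Profile searches use position-specific log-odds matrices with empirical
Gumbel E-value calibration — an internal, dependency-free stand-in for a
profile-HMM scanner that preserves E-value threshold semantics. Clustering,
identity and TM prediction are likewise self-contained stand-ins for
CD-HIT, BLAST-style search and hydropathy-based TM prediction
(Kyte–Doolittle windows).

Because the original genome collection is far beyond desk scale, the package
ships a first-class **synthetic data generator** that plants Cas10s with
known cyclase/HD status, effector genes with family signatures, candidate
families and a controllable effector/multi-locus log-odds ratio, so every
stage is tested against known truth.

## Worked example

```bash
python examples/06_full_pipeline.py
```

```
loci in census: 60
effector instances: 64
family counts: {'CalpL': 1, 'Cam1': 6, 'Cami1': 13, 'Can1-2': 5, 'CorA': 5,
                'Csm6': 6, 'Csx1': 25, 'Csx23': 1, 'NucC': 2}
% cyclase-positive Cas10: 88
% HD-positive Cas10: 35
MANIFEST complete: True; artifacts: 15
```

Sixty synthetic loci pass the census: each row of `census.tsv` records a
locus, its Cas10 domain calls and its effector family set. The association
test on a larger simulated census (`examples/05_cooccurrence_and_glm.py`,
2 000 loci, planted inverted odds ratio 2.57):

```
binomial GLM (effector presence ~ multi-locus genome), n = 2000
coefficient -1.054 (SE 0.123), Z = -8.565, P = 1.08e-17
odds ratio 0.349; inverted direction: a locus lacking effectors is
2.87x more likely to sit in a multi-locus genome
```

The negative coefficient means effector-lacking loci concentrate in genomes
carrying several type III loci — the signature of effectors being activated
*in trans* by another locus.

Other examples: `01_generate_synthetic_census.py` (the generator and its
truth labels), `02_cas10_domain_calls.py`, `03_effector_typing.py`,
`04_candidate_discovery.py`.

The CLI wraps the same library:

```bash
crispr3census simulate --out data/ --n-genomes 50 --seed 1
crispr3census run --fasta data/proteins.faa --annotations data/annotations.tsv \
                  --seeds data/seed_alignments --out out/
crispr3census stats --census out/census.tsv --out out/stats.json
```

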