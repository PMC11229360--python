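# Methods

This note documents the models and procedures implemented in
`crispr3census`, the parameters that matter, the numerical choices, and what
the synthetic benchmark does and does not establish.

## Scope and data model

The pipeline starts downstream of a locus caller: its inputs are (a) protein
sequences per genome (FASTA, amino acids), (b) a per-gene annotation table
(TSV) carrying genome/contig/coordinates/strand, a locus id, the caller's
product annotation with its E-value, and a CRISPR subtype call, and (c) seed
alignments (aligned FASTA) for each profile family. Coordinates are 0-based
half-open throughout; strand enters only through gene extent (sequences are
already translated). Operon boundaries are taken verbatim from the input
table as the span of the genes sharing a locus id — how the upstream caller
delimits operons is its contract, not re-derived here. Amino acids outside
the 20-letter alphabet are mapped to X (with a warning) to keep the scoring
alphabet closed.

## Profile scanning and E-values

Family detection uses ungapped position-specific scoring matrices rather
than profile HMMs. A profile is built from a seed alignment after dropping
columns with more than 50% gaps; for retained column *i* with residue counts
c\[i]\[a] over n\_i non-gap rows,

    log_odds[i][a] = log2( (c[i][a] + τ·bg[a]) / (n_i + τ) / bg[a] ),

with pseudocount τ = 1 and a uniform background over the 20 standard
residues (X scores 0 everywhere). Scanning slides the profile over every
window of the query and keeps the best window; ties go to the leftmost
window.

Significance comes from an empirical Gumbel null: the best-window scores of
200 i.i.d. background sequences of length 400 are fitted by the method of
moments (λ = π/(σ√6), μ = mean − γ/λ with γ the Euler–Mascheroni constant),
and

    E(S) = db_size · (1 − exp(−exp(−λ(S − μ)))),

where `db_size` is the number of proteins in the current search set,
mirroring search-set-dependent E-values in profile-HMM practice. Calibration
is deterministic given its seed; 200 shuffles give μ and λ stable enough
that the thresholds below sit orders of magnitude away from both planted
and null scores. Fixed-length null sequences make the E-value conservative
for queries shorter than the calibration length (e.g. the 31-residue HD
window), which only strengthens rejection of chance hits. This PSSM/Gumbel
engine deliberately omits insert/delete states; it preserves the E-value
threshold semantics the census logic relies on, and a real HMM scanner can
be swapped in behind the same interface without touching downstream
contracts.

## Census rules and thresholds

All thresholds live in `PipelineConfig` and are dumped with every run:

| parameter | default | role |
|---|---|---|
| `min_cas10_len` | 500 aa | discard non-functional Cas10 fragments before scanning |
| `cas10_evalue` | 1e-20 | Cas10 identification cutoff |
| `derep_identity` / word | 0.9 / 5 | dereplication of assembly duplicates |
| `cyclase_evalue` | 1e-3 | cyclase profile stage |
| `hd_evalue` | 1e-1 | HD profile stage (lenient: one diverse profile) |
| `hd_scan_first` | 50 | literal `HD` must start within the first 50 residues |
| `hd_extract_start/end` | 10–40 | 1-based inclusive window scanned against the HD profile |
| `cyclase_window` | −50/+100 | seed window around the motif for profile construction |
| `neighborhood_flank` | 4000 nt | effector search span beyond the operon |
| `effector_evalue` | 1e-3 | effector search cutoff (assumed, configurable — not a published value) |
| `candidate_evalue_floor` | 1e-7 | “poor annotation” threshold for candidate flagging |
| `candidate_cluster` | 0.4 / 2 | candidate clustering identity / word size |
| `cross_locus_identity_min` | 0.3 | homolog threshold for cross-locus search (explicit config, not an inferred value) |

Interpretation choices where the rules are ambiguous, fixed here and
flippable by config:

- “first 50 aa” means the complete `HD` 2-mer lies within residues 1–50
  (0-based start ≤ 48), avoiding a boundary-straddle ambiguity;
- “residues 10–40” is 1-based inclusive (31 residues, slice `[9:40]`);
- any literal motif occurrence satisfies the cyclase literal check, not just
  the first; the first occurrence in N→C order is the one reported;
- cyclase profiles are scanned against the full Cas10 sequence, not a
  sub-region;
- neighbourhood membership is by ≥ 1 nt interval intersection with the
  operon ± flank.

The cyclase call is the conjunction *profile hit AND literal motif*: the
profile alone flags degenerate PALM domains, the motif alone is a chance
4-mer (a random 500-aa sequence contains one of the ten variants with
probability ≈ 3%). Hybrid loci with ≥ 2 Cas10 genes are removed; hybrids of
a type III subtype with another CRISPR type keep the type III subtype;
non-III loci are dropped.

Effector typing resolves multi-family proteins by best bitscore; exact ties
between families other than Csx1/Cam1 go to the lexicographically smaller
family name (a pure determinism device). The Csx1/Cam1 cross-hit is resolved
by transmembrane prediction: Kyte–Doolittle hydropathy averaged over
19-residue windows, counting maximal non-overlapping windows with mean
≥ 1.6. A Cam1-only call with no predicted TM segment is retained but carries
a QC warning — the TM rule applies only to cross-hits.

Candidate discovery replaces BLAST/Diamond searches with global pairwise
identity at an explicit minimum (0.3), with a shared-5-mer prefilter playing
the role of the seeded-search heuristic. Guilt-by-association neighbours
must recur in ≥ 2 matched loci — the weakest recurrence that is recurrence
at all. The manual-curation step of the workflow this emulates is replaced
by an explicit exclusion-list file read at run time. Domain fusions (e.g.
CorA with a C-terminal Csm6-2) are called when two families hit
non-overlapping best windows; overlapping windows are an ambiguous
cross-hit, not a fusion.

## Alignment, clustering, trees

Pairwise identity is Needleman–Wunsch with match +1, mismatch 0, linear gap
−1 (scores are used for alignment only); identity = matches / alignment
length. Among co-optimal alignments the one maximising
(score, matches, −length) lexicographically is used — lexicographic
maximisation of additive tuples has optimal substructure, so the DP is
exact and deterministic. The hot path packs the three fields into one int64
(13-bit fields, compiled with numba); a pure-Python DP with identical
semantics is the fallback and the tests' reference.

Greedy clustering sorts sequences by descending length (ties by id); each
joins the first cluster whose representative shares a word of the given
size and reaches the identity threshold, else founds a cluster. The founder
(longest member) is the representative.

Trees are neighbour joining on 1 − identity distances (scikit-bio's NJ),
with negative branch lengths clamped to zero and midpoint rooting for
display — the rooting is presentational, so the cheapest defensible choice
is used. NJ recovers the true topology exactly on additive matrices, which
is what the test suite checks; it is a stand-in for the likelihood trees a
production census would build, adequate here because only topology-level
groupings (clades sharing ancillary enzymes) are consumed downstream.

## The association test

The inter-locus signalling question — do effector-lacking loci sit in
genomes with additional type III loci? — is answered by a binomial GLM at
the locus level: response = locus has ≥ 1 known effector, covariate =
genome carries ≥ 2 type III loci, fitted by IRLS (statsmodels, logit link),
with Wald z and two-sided normal p. For a single binary covariate the MLE
equals the closed-form 2×2 cross-product odds ratio, which the tests verify
to 1e-8 relative error. Zero cells in the 2×2 table mean an infinite MLE;
these raise a separation error naming the degenerate margin rather than
returning a divergent fit. The model treats loci as independent even when
they share a genome — the same simplification the census question is posed
under — and every GLM output carries a note flagging this
non-independence. Candidate families are excluded from “effector presence”
by default. Reported percentages are rounded half-up to integers.

## The synthetic benchmark

The generator (`synthetic_data`) emulates the *shape* of a real census
input, not protein biology. Per genome it draws a locus count (1, or 2–3
with probability `p_multi_locus` = 0.30); per locus it emits one or two
leading interference-complex genes, a Cas10 of 520–640 aa, effector genes,
and background genes on one contig with 200–2000 nt intergenic gaps
(12–20 kb between loci; a distant background gene 6–9 kb past each cassette
exercises the ± 4 kb boundary from outside, intra-cassette gaps of
100–600 nt keep planted effectors inside it).

Planted structure, all deterministic in the config seed:

- **family signatures** — unique random blocks: 120 aa for Cas10 (matching
  the broad profile coverage of the real family), 30 aa for the ten
  effector families; candidate families and CorA ancillaries are full-length
  bases whose instances are 10%-mutated copies, because their discovery
  path runs on global identity rather than profiles;
- **cyclase** — with probability `p_cyclase` = 0.92, a conserved 154-aa PALM
  context block at position 200 with a motif variant (GGDD-weighted 0.82)
  at offset 50;
- **HD** — with probability `p_hd` = 0.39, a conserved 31-aa block at
  residues 10–40 with `HD` at residue 15;
- **effectors** — presence drawn from
  logit P = β₀ + β·𝟙\[multi-locus], β₀ = logit(0.88), β = −log 2.57; family
  identity sampled with weights proportional to the observed census counts
  (Csx1 411 … SAVED-CHAT 3); a second family with probability 0.25;
- **candidates** — in effector-less loci only (probability 0.6), labelled
  `Unknown` or with a poor-E-value annotation, exercising both flag paths;
- substitution noise (default 0.01/residue) everywhere except planted
  blocks; `noise=0` is the noiseless condition under which recovery is
  required to be perfect.

Seed alignments for profile construction are six independently mutated
copies (rate 0.05) of each signature, active-site positions kept intact.

What passing tests show: the census *logic* — thresholds, conjunction rules,
boundary semantics, resolution and exclusion rules, statistics — is correct
against planted truth, and the whole pipeline is byte-deterministic. What
they do not show: performance on real sequence diversity (indels, domain
shuffling, compositional bias, profile curation quality), which enters
through the seed alignments and is exactly what the drop-in path for real
seeds is for.

## Problem sizes and verification

The shipped studies use 200 genomes (~290 loci, ~1400 proteins) for
planted-signal recovery and determinism, 200 replicates of 2000-locus
censuses for odds-ratio recovery (3-SE coverage ≥ 95%), and 1000 replicates
of 1000-locus null censuses for the Wald test's empirical size (within
[0.03, 0.07] at α = 0.05). `scripts/acceptance.py --seed 1` reproduces all
of these plus the printed-count arithmetic in a few minutes on one CPU.

## Known limitations

- Ungapped PSSM scanning cannot model indels inside a domain; real seed
  alignments with internal gaps lose the gapped columns.
- Identity-based candidate search is a global-alignment criterion; remote
  homology below ~30% identity is invisible, as it would be to the
  BLAST-style step it stands in for.
- The GLM ignores genome-level clustering of loci (flagged in output).
- The hydropathy TM counter is a coarse stand-in: it finds strongly
  hydrophobic helices but has no topology model.
- Trees are distance-based NJ, not maximum likelihood; branch lengths are
  not interpretable as substitution rates.
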