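# Methods

This note documents the models and procedures implemented in `streamscan`,
the parameter choices that matter, what the synthetic-data generators do and
do not emulate, and the numerical decisions taken where the underlying
protocol left the design open.

## Bin decontamination and streamlining statistics

Each predicted gene carries zero or more database hits
(e-value, percent similarity, percent query coverage, bitscore). A hit is
admissible when e-value < 1e-3, similarity > 10, coverage > 10 and
bitscore > 50 — all strict inequalities, mirroring the protocol wording —
and the gene takes the taxon of the best admissible hit (highest bitscore;
ties by lowest e-value, then lexicographic subject id, so the assignment is
deterministic). The bin's dominant taxon is the mode over assigned genes;
a tie is broken lexicographically and flagged in the report.

A contig is discarded as a contaminant when strictly fewer than 30% of its
*taxonomically assigned* genes match the dominant taxon. Two conventions
here were genuinely open and are configurable:

- **Denominator.** Unassigned genes are excluded from the fraction. A contig
  with no assigned genes carries no evidence either way; it is kept and
  flagged `no taxonomic evidence` rather than silently removed.
- **Rank.** Taxon strings are compared verbatim at whatever rank the caller
  supplies; no taxonomy tree is maintained.

Viral filtering removes contigs with strictly more than 25% viral-flagged
genes (viral labels are inputs from upstream predictors). The contaminant
filter runs before the viral filter; both report independently and the
kept/removed sets always partition the input contigs.

Statistics: GC is computed over unambiguous A/C/G/T only; coding density is
the union of gene intervals (overlaps counted once) over assembly length;
estimated genome size applies the standard completeness correction
`assembly_length / (completeness/100)`, making
`size x completeness = assembly_length` an exact identity; N50 is the
largest-first cumulative definition. The MAG selection gate is strict:
completeness > 70 and contamination < 5. The whole-genome HGT screen flags a
bin whose self-taxon gene fraction is not strictly above 0.90.

## Fragment recruitment and the replication index

Alignment records are filtered at identity >= 95%, aligned-fraction-of-read
>= 0.90, and >= 0.50 (the alignment-length rule; mathematically subsumed by
the 0.90 rule but applied separately for auditability). "Minimum" thresholds
are inclusive, unlike the strict textual inequalities in bin QC. One best hit
per read is kept: highest identity, then longest alignment, then lexicographic
genome id. The 50%-alignment-length rule is read as a fraction of the read
(not 50 bases); both interpretations are reachable through the threshold
arguments.

Coverage per Gb = (sum of aligned bases / genome length) divided by
(metagenome size / 1e9). Aligned-base coverage is the default because only it
yields a dimensionless depth; a hit-count mode (`mode="counts"`, hit count x
read length) is provided for comparison with count-based normalisations.
A metagenome is included when its mean coverage per Gb across genomes is
strictly above 0.1. rRNA (or any) intervals can be masked to N before mapping
to avoid conserved-region bias; masking preserves length and merges
overlapping intervals.

**Replication index.** The profile is the per-window mean depth with window
size `max(1 kb, genome_length/100)`. Windows deviating more than 8x from the
median are discarded first (mobile-element-like spikes). The default
estimator (`method="fit"`) searches every window as a candidate replication
origin, regresses depth against the folded circular distance from that
candidate (0 at the candidate, 1 at the opposite window), keeps the
candidate with the lowest residual sum of squares, and reports the
peak-to-trough ratio of the fitted line, floored at 1.0. Because the folded
distance from the origin is exactly one minus the distance from the
terminus, the best candidate may sit at either extreme; taking
max(fitted ends)/min(fitted ends) makes the estimate orientation-free.

A simpler estimator — mean of the top depth decile over the mean of the
bottom decile (`method="decile"`) — is also provided but is not the default:
on a linear ori→ter gradient the decile means sit strictly inside the
peak/trough (underestimating a true ratio of 2.0 by ≈ 0.14), and under
Poisson window noise order-statistic selection inflates a true ratio of 1.0
by ≈ 0.1–0.2. The regression estimator is unbiased in both regimes; at
depth 50 on a 100 kb genome its mean absolute error over ratios 1.0–2.0 is
≈ 0.03 (measured by `scripts/acceptance.py`).

## Comparative genomics

Protein comparisons use Smith–Waterman local alignment with BLOSUM62 and
BLAST-style affine gaps (gap of length k costs 11 + k); these are the
standard protein-search defaults, adopted because the original BLASTP runs
specify no parameters. `X` is scored 0 against everything. Identity is
identical columns over all alignment columns (gap columns included);
coverage is the fraction of a sequence's residues consumed by the alignment.
All-vs-all comparison aligns each unordered cross-genome pair once and
reports both directions; a shared 4-mer seed prefilter (>= 3 shared k-mers)
skips hopeless pairs, exactly as seed-based search tools do, and can be
disabled when exact behaviour on arbitrary low-identity pairs is required.

- **POCP** = (C1 + C2)/(T1 + T2) x 100, where C_i counts proteins with at
  least one hit at identity and query coverage strictly over 50%. The strict
  reading follows the protocol's "over 50%" wording; an `inclusive=True`
  switch gives the >= variant used by some POCP definitions.
- **AAI** averages identity over reciprocal best hits (mutual best by score,
  ties by subject id) after requiring query coverage >= 50% and identity
  >= 30% — the conventional definition, since none was printed. AAI is
  undefined (returned as None) without a reciprocal pair. ~65% marks a genus
  boundary.
- **Gene ANI** globally aligns reciprocal-best gene pairs (match +1,
  mismatch -2, gap of length k costing 4 + 2k) and averages identity. It is
  a gene-level stand-in for whole-genome fragment ANI, adequate for the
  dereplication and species-boundary (~95%) reports at desk scale; it is not
  a substitute for fragment-based ANI on full assemblies.
- **Orthologue clusters** are connected components (single linkage) over
  hits with identity >= 50% and query coverage >= 50% ("at least", hence
  inclusive). Coverage is evaluated on the query side of each directed hit
  and an edge exists if either direction qualifies; the protocol does not
  say whose length the 50% refers to, and single linkage makes the graph
  undirected anyway. Unhit proteins become singletons.
- **Core/pan curves** average over seeded permutations of genome order:
  pan(k) = clusters present in >= 1 of the first k genomes, core(k) =
  clusters present in all k. Pan is non-decreasing and core non-increasing
  for every permutation by construction.
- **Dereplication** single-links genomes at ANI strictly > 99 and keeps the
  highest `completeness - 5 x contamination` (the dRep-style quality score),
  ties to the longest assembly, then lexicographic id.
- **SCG selection** returns marker families with copy count exactly 1 in
  every genome — the common single-copy set used for concatenated
  phylogenomics. Tree inference itself is out of scope.

## Rhodopsin classification

Candidates shorter than 150 aa are discarded, as are candidates whose screen
p-value is strictly above 1e-2; a missing p-value passes because candidates
may enter without an external HMM score.

Transmembrane topology comes from a Kyte–Doolittle hydropathy scan: window
19, threshold 1.6, runs of passing window centres merged when separated by
fewer than 5 residues, each run expanded by half a window, helices shorter
than 15 aa dropped and longer than 25 aa capped around their hydropathy
peak, and residual overlaps between consecutive helices split at the
midpoint. These parameters are exposed as arguments. This scanner replaces a
dedicated topology predictor; its claims are validated only on synthetic
constructs, where the planted helix count is recovered exactly.

A canonical call requires exactly 7 helices. Helix 7 plus a ±5-residue flank
(absorbing helix-boundary error) is scanned for D-x-x-x-K (Type I) or
S-x-x-x-K (heliorhodopsin); the motif lysine is the retinal-binding residue,
so a Type I call always carries it. For Type I calls, the helix-C (third
helix) region ±10 residues is globally aligned (BLOSUM62, free end gaps) to
a packaged reference segment, and the residues at the reference's
proton-transfer offsets (acceptor/stabiliser/donor; "DTE" = proton-pumping
proteorhodopsin) and the spectral-tuning offset (position-105 homolog;
L = green-absorbing, Q = blue-shifted, otherwise unknown) are read off. The
reference segment is a synthetic construct produced by this package's own
generator (seed 0) and shipped as data
(`data/rhodopsin_reference.synthetic.json`); alignment-based offset mapping
was chosen over query-local numbering because residue numbering is only
meaningful relative to a homologous frame.

## Pathway completeness and auxotrophy

A hit is accepted when the protein covers >= 65% of the HMM model and the
e-value is <= 1e-3 (inclusive, "minimum"/"threshold" wording); per
(genome, gene, model) only the lowest e-value survives. Multiple annotation
namespaces are collapsed through an alias map *after* acceptance, so the
coverage rule applies per source hit. Pathways are flat ordered step lists,
each step a set of alternative model ids; completeness = satisfied steps /
total steps. Block logic (AND/OR trees) is not modelled; the packaged
definitions avoid it by construction. A genome is prototrophic for a
compound only at completeness exactly 1.0 — partial pathways count as
auxotrophic — while the presence/absence export distinguishes
complete / partial / absent with configurable cut points.

The packaged definition file curates the pathway inventory relevant to
streamlined freshwater heterotrophs (central carbon, amino-acid and
cofactor/vitamin biosynthesis, sulfur/nitrogen marker sets, key transporters,
the cbb3 oxidase ccoN/ccoO/ccoP minimal unit, photorepair) as KO-like step
lists following standard KEGG module composition. It is data, not code, and
editable; model ids are unique to one pathway within the packaged file so
that planted-truth recovery is exact.

## Synthetic data: what it emulates, and what it does not

Every generator draws from a single `numpy.random.default_rng(seed)`, so
identical seeds give byte-identical outputs.

- **Genomes/bins**: contig sequences at a target GC (default 0.46) with
  non-overlapping genes tiled at a target coding density (default 0.93,
  mean gene 900 bp) — mid-range of the 44–49% GC / 92–95% coding-density
  envelope of streamlined freshwater MAGs. Contamination is planted by
  relabelling `round(fraction x n_genes)` genes on chosen contigs to a
  foreign taxon; viral flags analogously.
- **Reads**: sampled with replacement, read count Poisson at the target
  depth; positions uniform or with a linear density falling from `ratio` at
  the origin (coordinate 0) to 1 at the terminus (genome midpoint) and back.
  Substitutions are i.i.d. to one of the three other bases. No indels, no
  quality strings, forward strand only — recruitment filters operate on
  alignment records, not on qualities or strands.
- **Proteome families**: each family descends from a random ancestor;
  members are mutated i.i.d. at rate `1 - sqrt(target_identity)` so expected
  pairwise identity equals the target (no indels by default, which keeps the
  identity oracle exact — per-site agreement *is* the global-alignment
  identity). Core families appear everywhere; accessory families in a random
  proper non-empty subset.
- **Rhodopsin constructs**: 19-aa helices drawn from {L,I,V,F,M}
  (motif-bearing helices from {L,I,V}) separated by >= 7-aa linkers drawn
  from {N,Q,E,R}. With these alphabets, any scan window centred >= 7
  residues from a helix centre has at most 12 hydrophobic residues and a
  window mean provably below 1.6 (max helix KD 4.5, max linker KD -3.5), so
  the planted helix count is a worst-case construction invariant rather
  than a probabilistic outcome. Alanine (KD 1.8) stays out of the sampled
  set — a window mixing planted polar motif residues with many alanines
  could dip below threshold — but remains recognised by the scanner.
  Excluding D/S/K from linkers prevents accidental retinal-motif matches in
  the scanned flanks. Consequence: 7 helices need >= 176 aa, so the
  generator rejects shorter requests; the default construct is 220 aa.
  Real rhodopsins are not this clean — helices vary in length and
  hydrophobicity, and loops contain hydrophobic residues — so perfect
  classification on these constructs validates the decision logic, not
  real-data performance of the hydropathy scanner.
- **Annotation tables**: for each genome and pathway, exactly
  `round(fraction x n_steps)` randomly chosen steps receive one
  accepted-quality hit (e-value 1e-10, coverage 90%).

## Problem sizes and numerical choices

The test and acceptance workloads use 60–100 kb genomes, depth 10–50, 100 bp
reads, 4–8 genomes with 50 core + 30 accessory protein families of 150 aa at
within-family identity 0.9, 100 rhodopsin constructs per class, and 20 seeds
per stochastic check — small enough to run the full suite in well under a
minute per suite while keeping every statistical bound comfortably away from
its tolerance (binomial GC bound ±0.01 at 200 kb; Poisson read-count bound
±3σ; replication-index MAE ≈ 0.03 against a 0.1 tolerance).

Tie-breaks are lexicographic everywhere a score ties, which makes every
result order-independent and reruns byte-identical. Degenerate inputs raise
typed errors rather than returning sentinel values: empty hit lists return
None assignments, zero-completeness bins and empty marker matrices raise
`ValueError`, and coverage profiles with fewer than 20 usable windows or
zero median depth raise `InsufficientCoverageError`.

## Known limitations

- Completeness/contamination estimation, viral prediction, gene calling,
  read mapping, HMM searching and tree inference are consumed as inputs,
  not reimplemented.
- Gene-wise ANI approximates fragment-based whole-genome ANI.
- The hydropathy scanner is a deterministic stand-in for dedicated topology
  predictors and is validated on synthetic constructs only.
- Helix-C and tuning-site numbering is defined relative to the packaged
  synthetic reference segment, not to any natural rhodopsin's numbering.
- Pathway definitions use flat step lists with alternatives; spontaneous
  steps and nested boolean module logic are not modelled.
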