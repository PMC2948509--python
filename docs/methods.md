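# Methods

`its2eval` evaluates the internal transcribed spacer 2 (ITS2) of the
nuclear rRNA cistron as a DNA barcode. The workflow mirrors how barcode
loci are judged in practice: delimit the spacer from its conserved
flanking genes, curate a taxon-labelled reference collection, quantify
the "barcoding gap" between intra- and inter-specific K2P divergence, and
score how often a nearest-neighbor search assigns a query to the right
species. Because the published evaluations of this kind rest on large
public-database snapshots, the package ships a seeded simulator that
generates structurally equivalent datasets with known ground truth, so
every stage is testable at desk scale.

## Synthetic data model

Per genus, an ancestral core sequence is drawn i.i.d. at a target GC
composition (`gc_target`, default 0.55, inside the observed 48–65% band
for ITS2). Species and individual sequences then evolve under a
continuous-time Kimura two-parameter (K2P/K80) substitution process with
transition/transversion rate ratio `kappa` (default 2), applied via the
closed-form transition matrix normalized to one expected substitution per
site per unit branch length.

The within-genus tree is a star phylogeny and ultrametric: species tips
sit at depth `inter_branch` (default 0.2 substitutions/site) and
conspecific sequences coalesce at depth `intra_branch` (default 0.01).
Concretely, a species core evolves from the genus ancestor along a branch
of `max(inter_branch − intra_branch, 0)` and each sequence evolves a
further `intra_branch`, so the expected pairwise K2P distance is exactly
`2·inter_branch` between congeneric species and `2·intra_branch` within a
species. This makes the simulated truth directly commensurable with the
distance statistics the package estimates; an additive parameterization
(full `inter_branch` per species plus `intra_branch` per sequence) would
instead put the congeneric expectation at `2(inter+intra)` and decouple
the dial from the quantity being recovered.

Each record is the core flanked by a conserved 5.8S-gene tail and
28S-gene head (defaults 60 nt each), shared dataset-wide with 2%
per-record point noise and no indels — emulating the strong conservation
that makes these segments usable as delimitation anchors. Ground truth
records each core as a 0-based half-open interval on the raw sequence.

Degenerate records are injected at seeded rates from an RNG stream
separate from sequence simulation (so the draw is replayable): cores
truncated below 100 nt, cores given 3–5 ambiguous Ns, species labels
rewritten with "sp."/"aff." tokens, and fungal decoys — cores replaced
from an unrelated high-divergence pool at neutral GC that doubles as the
fungal reference set for contamination screening.

What the generator deliberately does not model: indel evolution inside
the core (alignment is therefore easy on synthetic data; real ITS2 is
length-variable), rRNA secondary structure, rate heterogeneity across
sites, nested coalescent genealogies, and ITS paralogy/intragenomic
variation. Passing tests therefore demonstrate correctness of the
statistics and decision rules under a clean substitution-only regime, not
robustness to alignment ambiguity or paralogous copies in real data.

## Spacer delimitation

Each anchor is a position-specific log-odds profile built from a
user-supplied alignment: columns with gap fraction > 0.5 are dropped,
and emissions are `(count + p·background) / (n_residues + p)` with
pseudocount weight `p` (default 1) over a uniform background. Scoring is
Viterbi dynamic programming in bits, "glocal": the whole model must
align, anywhere on the target, with affine gap penalties (defaults 4
bits open, 1 bit extend). Viterbi (a single best interval) was chosen
over forward-posterior decoding because only the boundary location is
needed and a unique deterministic interval simplifies downstream
trimming; end-position ties resolve leftmost, and traceback prefers
match over delete over insert.

Significance is a Gumbel E-value, `E = K·m·n·exp(−λS)`, with λ and the
location fitted by the method of moments on ≥200 seeded shuffles of a
target and K anchored so that `E = 1` falls at the null's 99th
percentile for the calibration length. Accepting anchors at `E ≤ 1.0`
thus admits about 1% of unrelated targets per scan; true anchor hits sit
tens of bits above the null and receive E-values near zero. The anchor
choice is deliberate: tying `E = 1` to the null's extreme-value location
itself would leave ~63% of random targets below the threshold, which is
useless as a gate. Batch annotation calibrates each model once (on
shuffles of the first record) and rescales other targets through the
`m·n` term; single-record calls calibrate on their own target.

The ITS2 core is the interval between the end of the accepted 5.8S hit
and the start of the accepted 28S hit. A missing anchor or an inverted
arrangement yields a status (`no_5_8S`, `no_28S`, `inverted`) rather than
a guessed one-sided boundary.

## Curation

Records are excluded with the first failing rule in a fixed order —
trimmed length < 100 nt, more than 2 ambiguous Ns, unnamed species
("sp.", "spp.", "aff." tokens, case-insensitive), then membership in a
genus left with fewer than 2 species by the preceding rules. Both
boundaries are inclusive (exactly 100 nt and exactly 2 Ns survive), and
genus occupancy is recounted on the post-filter survivor set, making the
outcome independent of input order. The length filter applies to the
trimmed core, since trimming precedes curation in the workflow.

Suspected fungal contamination is flagged by two separate routes — a
fungal profile scan gated at `E ≤ fungal_max_evalue`, and a best-hit
local-alignment identity against a fungal reference pool, where identity
is coverage-weighted (identical columns over the shorter sequence's
length) so short chance local alignments cannot saturate it. Flags are
advisory and reported separately; dropping flagged records is an explicit
configuration choice (`drop_fungal`).

Per-species reference barcodes are majority-rule consensus sequences over
a center-star multiple alignment (star centered on the longest record,
"once a gap, always a gap" merging). Residue ties become the IUPAC code
of the tied set and majority-gap columns are dropped; a deterministic
consensus was preferred over assembly tooling because conspecific ITS2
clusters are short and highly similar.

## Divergence statistics

Pairs are aligned globally (Needleman–Wunsch, affine gaps; defaults
match +1, mismatch −1, gap open −5, extend −1, where a gap of length g
costs `open + (g−1)·extend`). K2P distance uses only comparable columns
(both residues in {A,C,G,T}); saturated pairs (`1−2P−Q ≤ 0` or
`1−2Q ≤ 0`) are flagged invalid and excluded from every mean with a
logged count rather than clamped. Per-pair optimal alignment replaces a
per-group multiple alignment: the distance is defined pairwise, and the
pairwise optimum is deterministic.

Six statistics summarize the barcoding gap, all within genera only:

- **all intra** — pooled mean over conspecific pairs;
- **theta (θ)** — per-species mean conspecific distance, averaged
  unweighted over species with ≥2 records;
- **coalescent depth** — per-species maximum conspecific distance,
  averaged over the same species;
- **all inter** — pooled mean over congeneric heterospecific pairs;
- **theta prime (θ′)** — per-genus mean heterospecific distance,
  averaged unweighted over genera;
- **minimum inter-specific distance** — per species, the nearest
  congeneric heterospecific sequence, averaged over species.

The pooled variants weight taxa by pair count; the primed/θ variants
weight taxa equally — both are reported since they answer different
questions. Standard deviations are population-style (divide by n) over
the respective pooled or per-taxon samples. When judging recovery of the
simulated regime, the standard error is taken over per-genus means:
genera are the independent replicates, while pairs within a genus share
branch realizations and are correlated.

Composition summaries report mean/median/quartiles of length and GC per
taxon set, with GC counted over unambiguous positions only.

## Identification

Every reference record is scored against the query by local affine-gap
alignment with the same scoring configuration as the distance module, so
similarity and distance rankings agree. The top-hit rule is rank-based:
all hits tied at the exactly-best score form the top tier; a single-
species tier assigns the query (judged correct/incorrect), a multi-
species tier is ambiguous — but a tie confined to one genus still counts
as a genus-level assignment. A score window around the top was rejected
in favor of exact ties to keep the trichotomy deterministic.

Evaluation is leave-one-out by record id (not species): with the query's
own record present every search self-matches and success is trivially
100%, so published-style rates are only meaningful with the exact record
excluded. The self-inclusive protocol remains available via a flag.
Queries whose species is absent from the searched set are flagged
(`species_in_db`) and scored as incorrect-or-ambiguous; no novel-species
detection is attempted. "Incorrect" is tracked as a third outcome;
`fold_incorrect_into_ambiguous` reproduces two-column correct/ambiguous
reporting. Success reports aggregate per taxon set, family, or genus at
the species or genus level.

## Pipeline and reproducibility

`run_pipeline` executes simulate → annotate → curate → divergence →
identify → report in fixed order under one config; a disabled stage is
skipped and the next stage consumes the most recent upstream output.
Every stochastic step (simulation streams, shuffle calibration) derives
from the single global seed, and a rerun with the same config is
byte-identical; the manifest lists every output with a SHA-256 hash and
per-stage record counts. The report assembles the stage TSVs into one
document without recomputing anything.

## Default problem sizes

The standard synthetic regime used by the test suite and by
`scripts/acceptance.py` is 50 genera × 2 species × 3 sequences (300
records, 360 nt cores, 60 nt anchors) at `intra_branch = 0.01`,
`inter_branch = 0.2` — small enough to rerun freely while leaving ~450
congeneric pairs and 100 species for stable estimates. Consistency
properties are checked across 20 additional smaller seeded datasets.

## Known limitations

- The simulator's substitution-only model makes alignment nearly trivial;
  length-variable real ITS2 will stress the alignment choices more.
- Gumbel calibration assumes the shuffle null is approximately
  extreme-value distributed; for very short targets (< ~3 model lengths)
  the fit is coarse, and the per-batch calibration assumes records share
  the composition of the calibration record.
- The E ≤ 1.0 anchor-acceptance gate admits ~1% of unrelated segments by
  construction; downstream curation is expected to absorb rare false
  anchors.
- Secondary-structure information, multi-copy ITS variation, and
  novel-species detection are out of scope.
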