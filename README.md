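# its2eval

Evaluation toolkit for the **internal transcribed spacer 2 (ITS2)** of the
nuclear rRNA cistron as a DNA barcode, for molecular systematists and
barcoding-database curators. It implements the complete desk workflow for
judging a barcode locus:

1. **simulate** — seeded generation of taxonomically structured,
   flanked ITS2-like datasets with known ground truth;
2. **annotate** — delimitation of the ITS2 core between conserved
   5.8S-tail and 28S-head anchors, using position-specific log-odds
   profiles scanned by glocal Viterbi with Gumbel-calibrated E-values;
3. **curate** — exclusion filters (length < 100 nt, > 2 Ns, unnamed
   "sp."/"aff." species, monotypic genera), a two-route fungal
   contamination screen, and per-species majority-rule consensus barcodes;
4. **divergence** — pairwise Kimura 2-parameter distances and the six
   barcoding-gap statistics;
5. **identify** — top-hit (BLAST1-style) species assignment with
   leave-one-out success-rate evaluation.

## The statistics at the core

For an alignment of two sequences with transition proportion *P* and
transversion proportion *Q* over comparable columns, the K2P distance is

    d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q).

Intra-specific variation is summarized by the pooled conspecific mean,
**θ** (per-species mean, averaged over species) and the **coalescent
depth** (per-species maximum, averaged over species); inter-specific
divergence by the pooled congeneric heterospecific mean, **θ′**
(per-genus mean, averaged over genera) and the **minimum inter-specific
distance** (per-species nearest heterospecific congener, averaged over
species). A usable barcode shows the inter-specific statistics well
above the intra-specific ones — the *barcoding gap*.

Identification follows the top-hit rule: a query is assigned to the
species of its highest-scoring database hit; a tie across several
species renders the query *ambiguous* (a tie within one genus still
assigns the genus). Evaluation excludes the query's own record
(leave-one-out), so success reflects informative matching.

## Worked example

```python
from its2eval import (SimulationParams, simulate_dataset, build_profile,
                      annotate_batch, build_reference_db, divergence_summary,
                      evaluate_success)

params = SimulationParams(seed=42, n_families=2, genera_per_family=5,
                          species_per_genus=2, seqs_per_species=3)
dataset = simulate_dataset(params)

m58 = build_profile(dataset.alignment_5_8S)
m28 = build_profile(dataset.alignment_28S)
results, trimmed = annotate_batch(dataset.records, m58, m28, calib_seed=42)
print(f"annotated {sum(r.annotated for r in results)}/{len(results)} records")

db = build_reference_db(trimmed, dataset.taxonomy_table,
                        fungal_refs=dataset.fungal_refs,
                        fungal_profile=build_profile(dataset.fungal_refs))
print(f"reference database: {len(db.records)} records, "
      f"{len(db.consensus)} species consensus barcodes")

summary = divergence_summary(db.records, db.taxonomy_table)
print(f"all inter-specific: {summary.all_inter.mean:.4f} +/- {summary.all_inter.sd:.4f}")
print(f"all intra-specific: {summary.all_intra.mean:.4f} +/- {summary.all_intra.sd:.4f}")
print(f"theta: {summary.theta.mean:.4f}   theta': {summary.theta_prime.mean:.4f}")
print(f"coalescent depth: {summary.coalescent_depth.mean:.4f}")

_, report = evaluate_success(db.records, db.taxonomy_table, db)
row = report.iloc[0]
print(f"species-level: {row.pct_correct:.1f}% correct, "
      f"{row.pct_ambiguous:.1f}% ambiguous ({row.n_queries} queries)")
```

Output:

```
annotated 60/60 records
reference database: 60 records, 20 species consensus barcodes
all inter-specific: 0.4097 +/- 0.0413
all intra-specific: 0.0218 +/- 0.0064
theta: 0.0218   theta': 0.4097
coalescent depth: 0.0255
species-level: 100.0% correct, 0.0% ambiguous (60 queries)
```

Reading it: all 60 raw records were delimited between their anchors; the
mean congeneric inter-specific distance (0.41) estimates twice the
simulated species branch length (2 × 0.2), the conspecific mean (0.022)
twice the within-species depth (2 × 0.01), and with that ~20-fold gap
every leave-one-out query finds a conspecific nearest neighbor, giving
100% species-level success. On data without a gap the correct rate
drops and the ambiguous rate rises, which is precisely what the toolkit
is built to measure.

The same flow is available from the shell:

```sh
its2eval run --seed 42 --out demo_run     # full pipeline + report.md
its2eval simulate --seed 1 --out data/    # or stage by stage
its2eval annotate --in data/raw.fasta --model58 data/aln_5_8S.fasta \
                  --model28 data/aln_28S.fasta --out trimmed/
```

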