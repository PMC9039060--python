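# sagpop

Population genomics for untargeted single-cell genome surveys.

Single amplified genomes (SAGs) sample a microbial community one cell at a
time: each assembly is an incomplete, MDA-biased snapshot of one organism,
but a few dozen SAGs from the same species-level population carry
information that no metagenome-assembled genome (MAG) consensus retains —
within-population SNPs and their linkage, strain-private mobile elements
(MGEs), CRISPR spacer repertoires, and rRNA loci invisible to common PCR
primers. `sagpop` implements that analysis stack as a reusable pipeline:

* **ANI species clustering** — fragment-mapping average nucleotide
  identity, single-linkage 95% species groups (99% for MGE grouping).
* **SNP matrices with explicit missingness** — assembly-based allele
  calls for each species group against its best SAG (most complete,
  contamination < 5%), biallelic site filters.
* **LD decay and LD50** — pairwise r² from haplotype counts,
  r² = D²/(p_A(1−p_A)p_B(1−p_B)) with D = p_AB − p_A p_B, distance-binned
  decay curves, and the 50%-unlinked distance (first crossing of r² = 0.5,
  log-interpolated), with a cell bootstrap. Small LD50 ⇒ frequent
  recombination (quasi-sexual population); no crossing ⇒ clonal.
* **Population structure** — SNP distances, Saitou–Nei neighbor-joining
  trees, silhouette-selected sub-population labels, and a PERMANOVA
  concordance test (Anderson pseudo-F, exhaustive enumeration when
  feasible).
* **SAG-vs-MAG gene content** — greedy nucleotide gene-family clustering,
  the "seen in ≥ 2 SAGs" singleton filter, closed-form rarefaction
  E[k] = Σ_f (1 − C(n−m_f,k)/C(n,k)), and the families a MAG misses.
* **MGE and CRISPR analysis** — canonical tetranucleotide profiles, the
  >10 kb carriage rule, circularity screening, lineage-specificity
  PERMANOVA, a CRT-style repeat-spacer array finder, protospacer matching
  with self / within-lineage / cross-lineage classification, and spacer
  rarefaction.
* **16S primer screening** — IUPAC-degenerate in-silico PCR with
  mismatch, 3'-mismatch and oversized-amplicon (intron) failure criteria
  and per-lineage blind-spot flags.
* **Synthetic community generator** — Wright–Fisher populations with
  homologous-recombination tract import, lineage-private MGE pools,
  CRISPR arrays whose spacers trace to those pools, planted 16S edits,
  MDA-style block dropout, and a composition-filtered mock MAG — with
  truth tables for every downstream stage.

See `docs/methods.md` for the models, defaults, and design decisions.

## Worked example

Run the whole pipeline on the default synthetic community (3 species,
16 SAGs each plus a mock MAG per species):

```
sagpop all --out report --seed 1
```

or equivalently from Python:

```python
from sagpop import PipelineConfig, run_pipeline
run_pipeline(PipelineConfig(rng_seed=1), "report")
```

The report directory then contains, among others
(`species_groups.tsv`, `snp_matrix_*.tsv`, `ld_curve_*.tsv`, `tree_*.nwk`,
`families.tsv`, `carriage.tsv`, `arrays.tsv`, `spacer_hits.tsv`,
`amplifiability.tsv`) the JSON stage summaries. With seed 1:

* `ani_summary.json` — `"n_groups": 3`, each of size 17 (16 SAGs + 1
  MAG): the 95% ANI clustering recovers the three simulated species
  exactly.
* `snp_summary.json` — e.g. group `g_sp1_MAG`: reference `sp1_cell04`,
  312 filtered biallelic SNP sites across 17 genomes.
* `ld50.json` — at the default intermediate recombination rate
  (ρ = 10⁻²) two populations never cross r² = 0.5
  (`"ld50": "not_reached"` — near-clonal) while the third crosses at
  `"ld50": 14826` bp with a bootstrap interval of roughly 3.8–24.9 kb:
  recombination strong enough to unlink distant sites but not nearby
  ones.
* `genefam_summary.json` — for species 1, 46 of 90 retained families are
  SAG-only (absent from the mock MAG) and 83% of those are flagged
  mobile: the MAG's composition filter discarded exactly the MGE cargo
  the SAGs still carry.
* `tnf_permanova.json` — MGE composition is lineage-specific
  (pseudo-F = 5.9, p = 0.001, prophages excluded).
* `crispr_summary.json` — 32/48 SAGs retain a detectable CRISPR array
  after dropout (95 spacers total).
* `primers_summary.json` — 37.5% of 16S sequences fail the primer
  criteria, matching the planted mismatch+intron fraction.

Individual stages re-run independently
(`sagpop ld --out report`), reusing the tables earlier stages wrote;
per-stage RNG substreams keep reruns byte-identical.

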