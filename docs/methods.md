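# Methods

`sagpop` analyses communities of single amplified genomes (SAGs): it
clusters assemblies into species groups by average nucleotide identity
(ANI), calls SNPs within each group against a selected reference SAG,
profiles linkage-disequilibrium (LD) decay to rank populations by
recombination, builds SNP trees and sub-population labels, compares the
collective SAG gene content against a metagenome-assembled genome (MAG),
and screens mobile elements (MGEs), CRISPR spacers, and 16S primer sites.
A synthetic community generator provides ground truth for every stage.
This note records the models, the defaults that matter, and the design
choices made where the design was genuinely open.

## Population model

Populations evolve under a forward-time haploid Wright–Fisher model with
constant size *N*. Each generation every offspring copies a uniformly
chosen parent; with probability ρ (per genome per generation) it imports
one homologous tract from a second uniformly chosen donor of the parental
generation — start uniform, length geometric with mean λ, truncated at the
chromosome end — and point mutations arrive at rate μ per site per
generation, each to a uniformly chosen different base. There is no
selection, no demography, and no crossover: the tract-import model matches
the unidirectional, gene-conversion-like character of bacterial homologous
recombination that LD analysis assumes.

Defaults: *N* = 100, *L* = 50 kb, μ = 2.5×10⁻⁵, λ = 5000 bp, *G* = 10·*N*
generations of burn-in from a monomorphic ancestor before sampling
(*G* ≫ expected coalescence depth ≈ 2*N*, so samples are at
drift–mutation equilibrium; a shorter run warns). The sanity anchor is
Watterson's estimator: mean segregating sites over replicates match
2*N*μ*L*·a₍ₙ₋₁₎ within Monte-Carlo tolerance.

λ = 5000 bp deserves a note. The per-site chance that a lineage's ancestry
is rerouted by recombination over the genealogy scales as ρ·(λ/L)·T_total.
With λ in the hundreds of base pairs, no value of ρ ≤ 0.1 makes
recombination dynamically visible at these population sizes — every
population behaves clonally and the clonal-vs-panmictic contrast the
package is built to detect cannot exist. Multi-kilobase imports are within
the range reported for transformation and ICE-mediated transfer in
bacteria, and make ρ = 10⁻³ vs 10⁻¹ span near-clonal to highly recombined.

Every simulation event (parent choice, tract, mutation) is logged;
replaying the log against the ancestral sequence reproduces the sampled
genomes byte-for-byte, which is the test that the truth tables are a
complete account.

## What the generator emulates — and what it does not

* **MDA dropout** — per cell, genome breadth is drawn from a Beta
  distribution matched to (mean, sd); contiguous blocks (exponential
  lengths) are retained until the drawn breadth is covered, with the final
  block trimmed so realized recovery tracks the draw. Retained runs become
  contigs; contigs under a minimum size are dropped; whole extra replicons
  survive with probability equal to the breadth draw. Uniform (per-site)
  dropout is available for ablations. Not modeled: chimeras beyond a
  simple foreign-contig contamination flag, read errors, assembly breaks
  at repeats.
* **Mobile elements** — each lineage carries a private pool (phage,
  plasmid, prophage) of low-GC random sequence; phage/plasmid ride as
  separate replicons, prophages insert at a fixed chromosomal site per
  element. Within-pool sequences are identical across carriers (no MGE
  evolution).
* **CRISPR arrays** — one array per chromosome: identical repeats
  (28 bp default) separated by spacers (33 bp) copied verbatim from
  carried MGEs, from the lineage pool when the cell carries none
  (flagged), or from the cell's own chromosome for the self-targeting
  fraction. Spacer sets are redrawn until the bases flanking the repeats
  are mutually distinct across spacers; without that constraint the true
  repeat boundary is formally ambiguous (a unanimous flanking column *is*
  repeat sequence) and exact recovery would be ill-posed.
* **16S genes** — one per chromosome from a population template with
  concrete primer sites planted at a fixed amplicon spacing; per-cell
  edit classes (clean / 2 primer mismatches / 500-bp intron) are assigned
  to exact cell counts.
* **Mock MAG** — majority-rule consensus of the sampled core chromosomes,
  fragmented (exponential, mean 5 kb), pooled with one representative
  contig per circulating MGE (emulating co-assembly), then filtered like a
  composition binner: contigs under 2500 bp go first, then contigs whose
  tetranucleotide profile sits more than `tnf_z_cutoff` robust z-units
  (median/MAD) from the median contig. The robust scale matters: with a
  handful of strong outliers among ~10 contigs, a plain z-score lets the
  outliers mask themselves. CRISPR/16S loci are absent from the MAG, as
  repetitive loci often are.

Passing tests on this generator show the analysis stack recovers planted
structure under MDA-like missingness; they do not show robustness to
assembly chimerism, strain mixtures within a cell sort, read-level error,
or MGE sequence evolution — none of which are generated.

## SNP calling

Allele calling is assembly-based: collinear alignment segments place each
cell's contigs on the reference (simulator truth coordinates, or an
external PAF assumed gap-free without a cigar). The reference is the most
complete SAG with contamination < 5% (ties to the smaller id). Synthetic
truth segments are expressed on a per-species core frame and composed onto
the chosen reference's contigs, so calls exist only where the reference
has sequence — as with real mapping. A position covered once yields that
cell's base; uncovered positions are missing; conflicting overlaps become
missing (logged), which is conservative under chimerism. Sites are kept
when called in ≥ max(10 cells, 50% of cells), exactly two alleles
segregate, and the minor allele is seen ≥ 2 times; frequency ties make the
alphabetically first base the major allele. All thresholds are config.

## LD decay and LD50

For haploid data every genome is a phased haplotype, so r² for a site pair
comes directly from the 2×2 haplotype counts over cells called at both
sites: D = p_AB − p_A·p_B, r² = D²/(p_A(1−p_A)p_B(1−p_B)). Pairs with
fewer than 5 co-called cells, or monomorphic within the co-called subset,
are excluded (undefined denominator), never scored zero. Pairs are binned
by distance (20 log-spaced edges, 10 bp – 50 kb, within-contig only) and
LD50 is the first crossing of the binned curve below r² = 0.5,
interpolated linearly in log₁₀ distance between geometric bin midpoints,
with `below_min` / `not_reached` sentinels. A secondary statistic (the
smallest distance at which more than half of the pairs so far have
r² < 0.5) is exposed for comparison, since "50% of pairs unlinked" admits
both readings.

Two numerical guards, both configurable:

* **MAF floor (`ld.min_maf` = 0.25 of the full sample).** Rare variants
  carry almost no linkage information: a doubleton's r̂² against anything
  is near zero regardless of linkage, and with sample size 40 the
  doubleton-dominated mean r² of a *fully clonal* population is ≈ 0.25 —
  below the 0.5 threshold, making "LD50" meaningless. Intermediate-
  frequency variants sit on deep branches, where clonal curves plateau
  near 0.8–1.0 and recombining ones decay to ≈ 0.2, which is the regime
  the crossing statistic was designed for. The denominator is the full
  sample, so sparsely called sites (whose frequency is poorly estimated)
  are excluded too.
* **Pair floor per bin (`ld.min_pairs_per_bin` = 10).** Bins with a
  handful of pairs are noise and otherwise anchor spurious crossings; the
  crossing walk treats them as empty.

The packaged recombination study (`sagpop.study`) simulates three
replicate populations per condition and pools their site pairs into one
curve before locating the crossing: a single genealogy's plateau level is
itself a random variable that can straddle the threshold, and pooling
estimates the expected curve. Under the study conditions (N=100, L=50 kb,
μ=2.5×10⁻⁵, G=1000, 40 SAGs at 70% breadth), ρ=0 and ρ=10⁻³ leave the
crossing unreached while ρ=10⁻¹ yields LD50 of roughly 1.5–6 kb — the
qualitative structured-vs-panmictic contrast, at synthetic scale; the
real-data LD50 magnitudes are not reproduced and not targeted.

The cell bootstrap resamples cells with replacement and reports percentile
95% intervals over non-sentinel replicates; with more than half sentinels
the interval is undefined (warned), not fabricated.

## Population structure

SNP distance is mismatches over co-called sites per pair; pairs sharing
fewer than 20 sites are an error listing the pairs (the pipeline drops the
worst-connected cells greedily and warns). Trees are Saitou–Nei neighbor
joining with a deterministic tie-break (lowest index pair) and negative
branch lengths clamped to zero with the deficit moved to the sibling; NJ
is exact on additive matrices, which is the test oracle. Sub-population
labels come from average-linkage hierarchical clustering with k chosen by
mean silhouette over k ∈ [2, 10] — a stand-in for Bayesian population
structure, chosen because the downstream concordance test needs only
labels; real labels can be supplied via TSV.

PERMANOVA uses Anderson's pseudo-F on squared distances with label
permutation, the (b+1)/(m+1) p-value estimator, and exhaustive enumeration
whenever the number of distinct assignments is ≤ 10,000 (the balanced 4+4
design gives p = 2/70 exactly). The tree-vs-cluster concordance test runs
PERMANOVA of cophenetic (default) or SNP distances against the cluster
labels. One caveat is documented rather than hidden: because the
silhouette labels are themselves derived from the distances, the
concordance test is essentially always significant whenever it is
applicable; with model-based external labels (as in real analyses)
non-significance is informative. What does distinguish panmictic from
structured synthetic populations here is cluster separation itself
(silhouette ≈ 0.6–0.85 vs ≈ 0.95+ for true clades) and the frequency of
degenerate singleton clusterings.

## Gene families and rarefaction

Genes (ORF-like fixed windows emitted by the simulator with truth family
ids; externally called genes via FASTA+TSV for real data) are clustered
greedily, longest first: a gene joins the first family whose
representative it matches at ≥ 80% identity — the full gene is aligned as
an infix of the representative, so coverage of the shorter sequence is
complete — else founds a family. The longest-first rule makes the result
order-canonical when lengths are distinct. The two-SAG rule removes
families observed in fewer than two SAGs (MAG presence does not rescue).
Rarefaction uses the closed form E[k] = Σ_f (1 − C(n−m_f, k)/C(n, k)),
cross-checked against the permutation estimator. The SAG-vs-MAG comparison
applies the two-SAG rule to the SAG side internally, so MAG-only families
remain reportable.

## MGEs, CRISPR, primers, ANI

Tetranucleotide frequencies use canonical (strand-merged) 4-mers — 136
dimensions; windows containing N are skipped; raw 256-dim mode is a flag.
Contigs count as MGE hits only above 10 kb (strict), circularity is a
terminal prefix/suffix overlap screen, and lineage specificity of MGE
composition is PERMANOVA of Euclidean TNF distances with prophages
excluded (host background inseparable). MGEs group at 99% ANI by single
linkage.

The CRISPR finder seeds on exact 8-mers recurring at one repeat+spacer
period, extends while the seeded pair agrees, locates all copies within a
one-mismatch budget, chains them under the spacer-length bounds, then
*trims* boundary columns where more than one chain copy disagrees with the
column majority (the pairwise extension overruns boundaries when just two
copies agree by chance) and extends only under unanimity. Candidates are
deduplicated and resolved preferring more repeat copies, then longer
spans; arrays need ≥ 3 copies and mutually distinct spacers (tandem-repeat
guard). Spacer–protospacer matching is full-length, both strands, ≤ 1
mismatch (pigeonhole-seeded exact search), hits within the source array
± 500 bp discarded, and classes assigned against the 95% ANI grouping:
self / within-lineage / cross-lineage. Spacer uniqueness for rarefaction
is strand-canonical. Note that self-derived (chromosomal) spacers can
legitimately match conserved regions of sister species; the zero-cross-
lineage expectation applies to the MGE-derived pool.

The primer screen matches IUPAC-degenerate primers exhaustively and
ungapped on both strands (N in the subject matches nothing), counting
3'-terminal (last 4 bases) mismatches separately. Verdicts: no usable site
(> 5 mismatches, or an amplicon shorter than expected), mismatch failure
(total > 1 or any 3' mismatch), intron failure (inter-primer span
exceeding the expected amplicon by > 150 bp), else pass; a lineage is
flagged as an amplicon blind spot when strictly more than 80% of its
genomes fail. Primer sequences are configuration, defaulting to the
926wF/1392R pair.

ANI chops the query into 1-kb fragments, places each by shared unique
16-mers (modal diagonal, both strands), scores it by infix alignment
against the placed window (±32 bp band), keeps fragments at ≥ 0.7
identity, and averages both directions; below 20% mapped fragments the
value is undefined — an absent edge, never zero. Species groups are
single-linkage components at 95%. This is a desk-scale reimplementation of
the fragment-mapping idea, not a performance claim, and exact agreement
with fastANI values is not claimed.

## Determinism

One root seed; each pipeline stage draws from an independent substream
keyed by the stage name, so re-running one stage never shifts another's
randomness, and a full rerun with the same config is byte-identical. All
interchange is TSV (tab, no quoting) with JSON run summaries.

## Problem sizes

Default synthetic community: 3 species at ~22% mutual divergence, N=100,
L=50 kb, 16 SAGs per species at 70% mean breadth plus one mock MAG each.
The recombination study uses 40 SAGs per population and three pooled
replicates per condition. These sizes were chosen so a full pipeline run
and the whole verification suite complete in minutes on a single core
while every statistic rests on hundreds of SNPs and tens of thousands of
site pairs.

## Known limitations

No selection or demography; no MGE sequence evolution (identical pool
copies make 99%-ANI grouping easier than real data); no read-level error;
assembly-based allele calls cannot see within-cell heterogeneity; the
hierBAPS stand-in is distance-based, so its concordance test against the
tree is not an independent comparison; primer-failure criteria are an
operationalization, and no equivalence with the real survey's failure
percentages is claimed.
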