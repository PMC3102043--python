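# Methods

This note documents the models and procedures implemented in `popvar`,
the conventions and defaults chosen where several were defensible, and
what the synthetic data used for testing does and does not establish.

## Variant detection from alignments

The input model is a Sanger-style diploid consensus alignment: one row per
accession, equal lengths, with a two-fold IUPAC code standing for a
heterozygous base call.  Detection is a per-column parse:

* **SNPs.** Each character resolves to an unordered diploid pair
  (A→A/A, R→A/G, …); `N` and the three-fold codes B, D, H, V resolve to
  missing (a warning is logged for the latter, which carry no usable
  diploid information).  A column is a SNP when the multiset of resolved
  allele copies holds ≥ 2 distinct bases.  Gapped rows contribute no base
  call at that column and are recorded as missing for the SNP.
* **Indels.** A single FASTA row cannot encode a heterozygous gap, so a
  gap run is a homozygous `absent` call.  Events are delimited by
  *extents*: every distinct maximal per-accession gap run (start, end)
  yields one event, so two accessions sharing the same run share an event
  while overlapping-but-different runs stay separate events.  An accession
  entirely gapped over the extent is `absent/absent`, entirely base-called
  is `present/present`, anything else (partial gap, missing base) is
  missing.  The event records the run length and the majority sequence
  among `present` accessions (ties: lexicographically smallest).  Indels
  are binary coded (`present`/`absent`) in the genotype matrix so phasing
  and LD treat them as ordinary biallelic sites; in haplotype networks an
  indel is one mutational step regardless of length.
* **Site statistics** are computed over allele *copies* (two per readable
  accession), not over accessions: `freq_major`/`freq_minor` are fractions
  of non-missing copies, and `n_hom + n_het = n_readable` always.
* **Consensus.** Per column, bases weigh 1, each base of a het code weighs
  0.5, `N` weighs 0.  The column renders as a gap only when gaps outnumber
  total base weight; base ties break in the fixed order A < C < G < T;
  all-missing columns render as `N`.
* **Missing-data column filter.** Columns whose fraction of `N` strictly
  exceeds the user threshold are removed before detection (the usual
  treatment of low-quality sequence ends); removed/kept original indices
  are reported for coordinate back-mapping.  Only `N` counts as missing
  here — `-` is structural.
* **Accession subsetting** re-detects variation on the subset; a site
  monomorphic within the subset disappears and all frequencies downstream
  refer to the subset.

Multiallelic SNPs (≥ 3 observed bases) are retained in detection and site
statistics but excluded from phasing, LD and chip-design export, whose
formulas are biallelic.

## Mapping and annotation

Amplicon placement uses precomputed 12-column tabular hits.  The best hit
is the highest bitscore; ties break by lexicographic chromosome name, then
by the lower subject coordinate.  The hit count is reported to flag
duplicated genes or pseudo-genes.  Variant columns are projected by offset
arithmetic — `s_start ± (pos − q_start)` according to strand — which
assumes the best hit is co-linear (gap-free) across the variant's
neighbourhood; positions outside the aligned query interval are
`unplaced`.

Region classification against GFF3 gene models assigns exactly one label
per position with priority CDS > UTR > intron across overlapping genes;
positions inside a gene span but outside annotated sub-features are
introns, everything else is intergenic.

Synonymy is decided by rebuilding the spliced CDS from the genome
(segments reverse-complemented and re-ordered for `-` strand genes),
shifting the frame by the first transcribed segment's phase, substituting
each allele into its codon and translating with the standard genetic code.
Alleles are taken to be reported on the `+` genomic strand and are
complemented for `-` strand genes.  A reference base matching neither
allele is logged and annotation proceeds with the alignment alleles.
Stop gains translate to `*` and are non-synonymous.  CDS indels are
labelled `frameshift` (length not divisible by 3) or `in-frame`, never
translated.  The invariant `synonymous ⇔ aa_ref == aa_alt` is asserted on
construction.

## EM phasing

Haplotype reconstruction is classical gene-counting EM on population
haplotype frequencies.  For each accession the set of compatible ordered
haplotype pairs is enumerated (heterozygous site → two assignments,
missing site → four); the E-step distributes each accession's unit mass
over its pairs proportional to p_a·p_b, the M-step re-estimates p from
expected counts.  Convergence is `max |Δp| < 1e-8` (up to 1000
iterations); five random Dirichlet(1) initialisations are run and the best
final log-likelihood kept.  The log-likelihood is asserted non-decreasing
at every iteration.  Each accession receives its maximum-posterior
unordered pair (ties broken deterministically), which simultaneously
imputes its missing alleles; the chosen pair is hard-asserted
genotype-consistent.  Accessions with more than 25 heterozygous-plus-
missing sites would require enumerating > 2²⁵ pairs and are left unphased
with a warning.  The whole region is treated as a single block — no
recombination-aware or block-partitioned model is attempted; export
writers retain interoperability with external phasing tools for users who
need those models.

Completed sequences substitute each accession's phased alleles into the
consensus; an `absent` indel allele deletes the event's columns
(right-to-left application keeps coordinates stable), so completed
sequences may differ in length.

## Diversity statistics

Given n completed sequences, sites containing any character outside
{A, C, G, T} in any sequence are removed (complete-site deletion, the
convention of the standard sequence-diversity libraries), reducing the
surveyed length L.  Then:

* π (pi_total) is the mean number of pairwise differences, computed from
  per-site allele counts — at a site with counts c_a the number of
  differing pairs is (n² − Σc_a²)/2 — which is algebraically identical to
  the explicit pairwise loop the test suite uses as oracle;
* θ_W = S/a₁ with a₁ = Σ_{k<n} 1/k;
* Tajima's D uses the standard coefficient chain (a₁, a₂, b₁, b₂, c₁, c₂,
  e₁, e₂) and is undefined (reported as n/a) when S = 0.  For n ≤ 3 the
  variance term vanishes identically (π ≡ θ_W); the implementation reports
  D = 0 in that degenerate case;
* H is the number of distinct sequences over included sites and
  Hd = n(1 − Σf_h²)/(n − 1).

The diversity map classifies each gene's D against the two-sided
standard-normal critical value (|D| > 1.96 at α = 0.05) — the usual
large-sample approximation; the beta-distribution refinement is not
implemented.  An empirical quantile (rank among all genes with defined D)
supports "most extreme 5 %" selection scans.  A gene's map position is the
midpoint of its mapped amplicon.

## Linkage disequilibrium

From phased haplotypes, with p_AB the frequency of the A–B haplotype:
D = p_AB − p_A·p_B; D_max = min(p_A p_b, p_a p_B) for D > 0 and
min(p_A p_B, p_a p_b) otherwise; D′ = |D|/D_max; r² = D²/(p_A p_a p_B p_b).
Significance uses χ² = n·r² on 1 df, replaced by Fisher's exact test on
the 2×2 haplotype table whenever an expected cell count is below 5.
Haplotypes missing at either site are dropped pairwise; a site monomorphic
after dropping yields an undefined, flagged result.

For unphased genotypes the composite (Rogers–Huff) r² is the squared
Pearson correlation of per-accession allele dosages (0/1/2), which
converges to the phased r² under random mating.

The all-pairs table reports raw p-values plus Benjamini–Hochberg q-values
per region — BH being the least-surprising default where no correction is
prescribed — and reserves empty columns (`r2S`, `r2K`, `r2SK`) for
structure/kinship-corrected measures so an extension can slot in without a
schema change; those corrected measures are out of scope here.

## Median-joining networks

Nodes are haplotype strings (indels binary recoded); distance is Hamming;
observed nodes carry their multiplicity as frequency, inferred median
vectors have frequency 0.  Construction:

1. Greedy median adoption: each round, the per-site majority consensus of
   every node triple is evaluated and the vector that most lowers the
   network cost (MST weight over the node set) is adopted; ties break on
   the lexicographically smallest vector; rounds repeat until no single
   median lowers the cost.  Considering all triples (rather than only
   triples linked in the current minimum-spanning network) costs little at
   these problem sizes and removes a known failure mode of the restricted
   heuristic.
2. Small-instance refinement: greedy adoption can stall above the optimum
   when two medians only help jointly.  For ≤ 12 observed haplotypes all
   subsets of up to three triple-medians are searched exhaustively and the
   cheaper solution kept.  Beyond that size the greedy result stands
   (documented heuristic, not exact Steiner).
3. Pruning: any median whose removal does not raise the network cost
   (cost-neutral vectors included) is deleted, greedily in lexicographic
   order.
4. The final graph is the minimum-spanning network over the surviving
   nodes under the relaxation parameter ε: edge (u, v) is kept iff u and v
   are not connected using only strictly shorter edges, relaxed by ε.
   ε defaults to 0 (pure minimum-cost behaviour, the union of all MSTs)
   and is configurable.

All tie-breaks are lexicographic on haplotype strings, so the network is
invariant to input order.  Subgroup composition attaches one count per
haplotype copy; unlabelled accessions pool into `unassigned`.  DOT export
scales node *area* proportionally to frequency (width ∝ √freq) and renders
median vectors as points.

## Group comparison and merging

A site belongs to a group's polymorphism set iff it segregates within that
group's accessions alone; groups with < 2 accessions cannot segregate and
are excluded with a warning.  Venn regions follow inclusion–exclusion
exactly.  Because a site fixed for different alleles in two groups is in
neither group's set but segregates in the pooled accessions, the
"cumulative" count per group union re-detects polymorphism on the pooled
accession set (and the plain set-union count is reported alongside); the
cumulative count can therefore exceed the union.

The between-group diversity comparison reports, per gene, the difference
in Tajima's D between the first two groups.  No distributional form is
assumed for ΔD: significance comes from label permutation (group labels
shuffled over accessions, default B = 1000 in the library function, with
the (hits+1)/(B+1) small-sample correction; B = 0 disables the test).  The
pipeline's `compare` step uses B = 100 as its default, a problem size that
keeps multi-gene runs responsive while the library default remains
available through configuration.

Multi-experiment merging is keyed by (genomic position, accession,
experiment); heterozygote comparison is unordered.  Agreeing non-missing
calls merge to that call; any disagreement merges to missing data.
Position status: `white` when a single experiment covers it, `green` when
several experiments contributed without conflict, `yellow` when any
accession conflicted.  Merging is idempotent and commutative in experiment
order.  The experiment-level merging mode restricts to one experiment and
bypasses merging entirely; the sample/sequence hierarchy of provenance is
modelled as plain experiment tags.

Variant queries are conjunctive filters (position interval, missing
fraction, kind, MAF range, synonymy, indel length) over the per-site
table; frequencies must be recomputed on the selected accession subset
before filtering, which `subset_accessions` performs.

## Synthetic data

The generators emulate Sanger-style amplicon resequencing of a diploid
panel: a monomorphic random background with planted SNPs (genotypes drawn
at the specified allele frequency, Hardy–Weinberg by default, heterozygotes
encoded as IUPAC codes), planted deletions (a fraction of accessions gap
the extent), and missing data applied at planted SNP sites at the
specified rate.  The generator returns the exact truth table detection
must recover, making planted-truth tests exact rather than statistical.
Not emulated: sequencing error, alignment error, heterozygous indels,
recombination, demography and selection — so passing tests establish
correctness of the computation, not robustness to upstream artefacts in
real data.

The neutral simulator is a single-genealogy Hudson-style coalescent:
exponential coalescence times at rate k(k−1)/2, Poisson mutations at rate
θ/2 per unit total branch length, each mutation mapped to a distinct
position on an L-site grid (ancestral `A`, derived `T`).  If more
mutations arise than grid sites the surplus is placed with replacement and
flagged — a finite-grid approximation of infinite sites that is negligible
at the sizes used (θ = 5, L = 500).  Calibration checks E[S] ≈ a₁θ and
E[π/L] ≈ θ/L over 500 replicates at n = 20.

The synthetic multi-gene project embeds each amplicon's consensus in a toy
chromosome with a single-mRNA gene model (UTRs flanking a phase-0 CDS) and
identity mapping hits, exercising the full seven-step pipeline without any
external input.

## Pipeline, sizes and determinism

Steps run in dependency order (detect → map → annotate → phase → LD →
diversity → network, plus compare when metadata is present); a failed step
marks its dependents skipped and the run manifest `ok=false` (nonzero exit
from the CLI).  PED input disables mapping, annotation and diversity,
which need sequence information.  Input caps (4000 alignments/run, 200
sequences per alignment, 500 SNPs, 500 accessions) are soft: they were
sized for a shared service rather than by the algorithms, and a flag
overrides them with a warning.

All randomness flows from the configured seed (EM restarts, permutation
tests, generators), dictionaries are written in sorted order and no
timestamps enter outputs, so two runs with identical configuration and
seed produce byte-identical files.

## Known limitations

* Heterozygous indels are not representable in the input encoding.
* The projection is alignment-free; hits with internal indels would
  misplace variants near the gap (split hits are not reconstructed from
  12-column tabular input, which carries no alignment detail).
* One gene model per mRNA; no cross-isoform consequence ranking.
* The MJN is exact only on small instances (see above); ε > 0 behaviour
  follows the relaxed-MSN definition but is not tested against an
  external reference implementation.
* Tajima's D significance uses the normal approximation only.
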