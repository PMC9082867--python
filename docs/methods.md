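# Methods

This note documents the models and procedures implemented in `itscan`,
the defaults and why they were chosen, what the synthetic data generator
does and does not emulate, and the numerical conventions that make runs
reproducible.

## Coordinate and sequence conventions

Internal coordinates are 0-based half-open everywhere; GFF3 output is
the single conversion point to 1-based inclusive (and is round-trip
tested).  RNA `U` is normalised to DNA `T` on input; the folding engine
treats `T` as `U` again, so rDNA and rRNA views of one molecule
coexist.  IUPAC ambiguity codes other than `N` are rejected rather than
remapped — the assemblies in scope are unambiguous consensus sequences,
and a silent remap would corrupt identity statistics.

## Operon finding

**Homology search.**  An internal seed-and-extend local search: exact
`seed_k = 12`-mer matches on both strands are clustered by diagonal
(tolerance 50, so distinct repeat copies stay distinct) into candidate
subject windows, padded generously, and each window is aligned to the
query by Smith–Waterman (match +1, mismatch −2; a gap of length L costs
5 + 2L).  Every exact shared ≥12-mer seeds a window, giving seed-level
completeness.  Hits carry ungapped Karlin–Altschul E-values
`E = K·m·n·e^(−λS)`: λ is the positive root of
`¼e^{λ·match} + ¾e^{λ·mismatch} = 1` (uniform base composition) solved
numerically, and K is evaluated from the Karlin–Altschul random-walk
series by convolving the aligned-pair score distribution.  Both are
recomputed whenever the scores change; for +1/−3 the implementation
reproduces the classical λ = 1.374, K = 0.711.  Gapped-statistics
corrections are deliberately not applied: the filter operates at
E < 10⁻⁵ on near-identical multi-copy rDNA hits, far from the regime
where the ungapped/gapped distinction matters.

**Coverage filter.**  A contig is retained iff it has a hit with
E < 10⁻⁵ *and* depth above 5× the genome-average depth.  "Genome
average" defaults to the **length-weighted median** of per-contig depth:
on compact assemblies the rDNA contigs' own enrichment would inflate a
mean and make the 5× rule partially self-defeating; length-weighted and
unweighted means are selectable for parity with mean-based pipelines.
The weighted median reproduces `numpy.median` over the
contig-length-expanded depth vector (property-tested).  Coverage comes
from SPAdes-style headers (`NODE_i_length_L_cov_c`) or a TSV override —
the header dialect does not distinguish k-mer coverage from read depth,
so the TSV exists for pipelines that computed depth differently.
Mitochondrial/contaminant rRNA exclusion relies on these two gates
alone; no composition heuristics are added.

**Annotation.**  Each reference rRNA (SSU, 5.8S, LSU) is searched
independently; the strand is chosen by total hit score, collinear hits
of one segment are chained to their spanning interval (so an insertion
inside a segment lengthens it instead of truncating it), and ITS1/ITS2
are the gaps between mapped rRNAs.  A minus-strand contig is annotated
via its reverse complement and flipped, which makes strand involution
exact by construction.  Segments mapping in an order inconsistent with
one strand raise a structured "inconsistent layout" error — the
automated counterpart of manual misassembly screening.

## Helix anchors and expansion detection

Helix anchors are conserved paired elements used as coordinate
landmarks.  An anchor's extent (5′ strand through 3′ strand) is
projected from template coordinates to alignment columns via the
template row's gap pattern, then to each row's unaligned coordinates via
per-row non-gap prefix counts.  An anchor fully gapped in a row is
ABSENT and bridged (recorded, not an error): real lineages do lose
helices.  Template self-projection is the identity, and per row, anchor
lengths plus inter-anchor region lengths sum exactly to the unaligned
sequence length — both property-tested invariants.

A focal species is flagged in a region iff its length exceeds
`factor = 4` times the background statistic **and** the absolute excess
is ≥ `min_abs = 30` nt.  The background statistic is the **median**
(robust when another lineage carries an insertion at the same site;
`max` gives the strictest reading of "longer than in the other
species"); the rule is scale-free above the absolute guard, which exists
because a 4× rule alone is vacuous on near-zero regions.  Focal and
background sets are explicit parameters, since "other species" can
reasonably mean all other taxa or only taxa outside the focal lineage;
the pipeline default tests each taxon against all others.  Spacer-domain
regions (ITS1/ITS2) are excluded from detection — they are spacers
already, and the classification rules are defined only over rRNA-gene
domains.

**Folding.**  The internal engine is base-pair maximisation
(Watson–Crick + GU wobble, minimum hairpin loop 3) with a deterministic
traceback (prefer unpaired, then the smallest partner).  It is a
sanity/annotation aid — structural element boundaries come from the
helix map, and no free-energy model is implemented.  The cubic DP is
JIT-compiled; call evidence folds at most a centred 400-nt window of
long inserts, since the reported quantity is pair density, not the exact
structure.

## ITS classification

Rules apply in fixed order, making classification total and
deterministic: (1) a region matching the site registry → known ITS
citing that site (when a shared region carries sites of two lineages,
the species' lineage selects the cited site); (2) otherwise SSU domain →
SSU expansion segment, never an ITS (18S expansions are retained in the
mature rRNA); (3) otherwise (5.8S/28S domain) → novel candidate.

ORFs are ATG…stop in all six frames under the standard code, reported
iff **strictly** longer than 20 aa (a 20-aa ORF is not reported); an
ORF running off the end is flagged partial.  A stop-to-stop mode exists
because the initiator convention is not universal.  Cross-ITS homology
is all-vs-all best local alignment; a pair is *reported* homologous at
identity ≥ 0.7 over ≥ 50 nt — a report threshold only, never an input to
classification, since no numeric criterion is canonical.  Fragment
arithmetic: N ITS calls (known or novel) in the 28S domain imply N+1
mature fragments.

The shipped registry (`src/itscan/data/its_registry.tsv`) encodes the
curated euglenozoan site numbering: 13 euglenid (eITS) and 7
kinetoplastid (kITS) numbered sites, of which 12 and 5 respectively lie
inside the 28S gene — consistent with 13 and 6 mature fragments — and
three shared positions (eITS10/kITS5, eITS11/kITS6, eITS13/kITS7).  The
flanking-helix names in the fixture are synthetic placeholders (the
per-site helices are figure-level curation with no machine-readable
source); the file header documents exactly which fields are curated and
which inferred.  External screening tools (rRNA gene models, public
database searches) are integration points via an adapter that ingests
their tabular output; they are not reimplemented.

## Cross-lineage parsimony

Shared positions are exact region-id identity (same flanking anchor
pair), matching how homologous sites are equated on a structure-based
alignment; a column-window tolerance mode exists for registry-free
comparisons.  `min_state_changes` is Fitch small parsimony implemented
as a symmetric-cost Sankoff DP, so polytomies are scored exactly and the
count is invariant under re-rooting (property-tested against exhaustive
internal-labeling enumeration).  `gain_scenarios` additionally reports
the minimum gains with loss forbidden (the number of maximal all-present
clades) and Dollo losses under a single gain at the MRCA of present
taxa.  Characters are analysed per site and as the single "any 28S ITS
present" character; the headline independent-origins claim concerns the
latter, and `gains_no_loss ≥ 2` on every candidate backbone topology is
its machine-checkable form.  The backbone of Euglenozoa is not resolved,
so trees are inputs, never assumptions.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

* a template operon (defaults SSU 2000, ITS1 300, 5.8S 160, ITS2 400,
  LSU 3500 nt) whose core anchors are engineered hairpins (stem 10,
  loop 4) spread evenly through the rRNA genes, so the folding engine
  recovers them;
* evolution on a user tree under a single-parameter substitution
  process (equal exchangeabilities, uniform frequencies) with per-class
  rate multipliers core 0.1, divergent (ES) 2.0, spacer 3.0 — the
  analysis detects *length* irregularities, so substitution-model
  richness is deliberately minimal; indels (rate 0.02 events per
  eligible site per unit branch length, geometric mean length 4) occur
  only outside the conserved core, and insertions open gap columns in
  all rows, so the emitted alignment is the true one (no external
  aligner needed; a re-alignment hook exists for integration runs);
* planted ITSs: one uniform-random insert per site spec (planted ITSs
  have no conserved composition or structure), placed at the region
  midpoint in the same new columns for every carrier taxon
  (within-lineage homology), with exact truth intervals recorded;
* an assembly with one contig per operon at 20× baseline depth among
  random decoy contigs at jittered baseline, decoys dominating assembly
  length as the single-copy genome fraction does.

The default taxon structure mirrors the euglenozoan study design: an
outgroup, a diplonemid-like clade without ITSs, a euglenid-like clade
with 12 LSU sites plus one large shared SSU expansion and two novel
unregistered sites in one taxon, a prokinetoplastid-like lineage
without ITSs, and a metakinetoplastid-like clade with 5 LSU sites,
three of them at euglenid site regions.  Planted insert lengths
(800–1200 nt; SSU expansion 900–1300 nt) are chosen so each planted
site exceeds the 4× rule relative to its region's background width —
the generator plants detectable signal by construction, because its
purpose is to verify the machinery, not to measure a detection limit.
The compact configuration used in tests and the acceptance script
shrinks the operon (LSU 1000 nt, regions ≈ 45–70 nt, inserts
250–400 nt, 5 sites, 8 taxa) to keep full-suite runtimes in minutes;
these are the problem sizes the reported recovery statistics refer to.

What the generator does **not** emulate: sequencing reads and their
error profiles (coverage is asserted, not simulated), tandem rDNA
repeats and intragenomic copy variation, introns, alignment error (the
true alignment is emitted), and base-compositional heterogeneity.
Perfect recovery on synthetic bundles therefore demonstrates the
correctness of the detection logic under the stated statistical
structure, not robustness to assembler or aligner artefacts in real
data.

## Determinism and degenerate inputs

Every random choice flows from a single integer seed through one
generator; bundles are byte-identical per seed, and pipeline reports are
byte-identical per input.  Tie-breaks are fixed: hits sort by (E-value,
−score, subject id, query id); folding traceback prefers unpaired;
shared-site pairs order by (region, lineage).  Degenerate inputs have
defined behaviour: empty query/subject sets return empty hit lists; a
background of fewer than two species skips the region with a recorded
warning; a character absent from all leaves yields (0, 0, 0) gain
scenarios; empty sequences fold to nothing and scan to no ORFs.

## Known limitations

* E-values use ungapped statistics; absolute values for heavily gapped
  alignments are approximate (the 10⁻⁵ gate is insensitive to this at
  rDNA identity levels).
* The expansion rule compares one region at a time; coordinated
  multi-region elongation below 4× per region is invisible by design.
* The folding engine maximises pair count, not stability; it must not
  be read as a structure prediction.
* Registry helix names are placeholders until a curated helix map for
  the target lineage is supplied.
* The annotation chaining assumes one operon copy per contig; tandem
  multi-copy contigs raise the inconsistent-layout error rather than
  being split.
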