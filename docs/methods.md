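# Methods

## Scope and data model

`gatascan` annotates GATA-family transcription factors from genome
scaffolds plus gene models (GFF3 CDS features grouped by `Parent`), or
from a pre-translated proteome. Internal coordinates are 0-based
half-open; GFF3's 1-based inclusive convention is converted at the I/O
boundary and round-trips exactly. Minus-strand products (spliced CDS,
flanks, intron order) are always reported in transcription orientation.
When a gene has several transcripts the default policy keeps the one with
the longest total CDS (ties by transcript id); `first-id` and `all` are
available. This is deliberately independent of naming schemes — selecting
"the lowest-numbered transcript" is not deterministic across annotation
pipelines. The GFF3 phase column is never used for splicing (phases are
derived from coordinates) but is validated when present, with mismatches
logged as model-quality warnings; automated re-splicing of broken models
is out of scope, as is homology-based candidate retrieval — the pipeline
scans the sequences it is given.

## Domain detection

Finger scanning enumerates all cysteine quadruples matching
C-X(f)-C-X(L)-C-X₂-C and resolves overlaps deterministically (leftmost
match wins, then longest). Defaults: f ∈ {2..4}, L ∈ {16..19}. The
`gata_canonical` label is reserved for exactly (f, L) = (2, 17); other
accepted geometries are `gata_variant` (this keeps a strict canonical
label while tolerating real variants such as the CSNSNC spacer). The
degenerate-finger search uses f = 2 and L ∈ {9..20} and requires the
candidate to sit upstream of a GATA finger with at most 200 residues
between its C4 and the GATA finger's C1 — a permissive bound around the
observed 34–152 range; free-standing degenerate motifs are reported
separately as orphans rather than silently mixed in. The basic domain is
the up-to-30-residue window after C4 (shorter windows are flagged
truncated), with the K/R fraction reported over observed residues. The
hexapeptide is the first T-X-[LA]-W-R-R match within finger-through-basic
span. Poly-serine segments are the union of all length-10 windows with
≥ 6 serines, reported untrimmed (the merged span can include up to four
non-serine residues on each side — this is what "the union of qualifying
windows" means and is asserted as such in the tests). All residue
comparisons are case-insensitive and `X` never matches a specific residue.

## Intron coordinates and landmarks

An intron is (codon_index, phase) where codon_index counts complete
codons 5′ of the intron over the spliced CDS and phase is the number of
nucleotides of the interrupted codon lying 5′ of it. Landmark descriptors
express introns relative to C3 or C4 of a finger: for phase 0 the offset
counts complete codons between the landmark codon and the intron; for
phase 1/2 the interrupted codon itself counts as the offset-th codon
after the landmark. Under this single convention the family's three
conserved marker introns are (C4 of the amino finger, +20, phase 0),
(C4 of the carboxyl finger, +8, phase 0) and (C3, +1, phase 1) — the last
being "1 bp after the C3 codon". Introns 5′ of their landmark get
non-positive offsets and a `non_canonical` flag rather than being
discarded, so same-intron/different-landmark hypotheses remain testable.
Matching is exact by default; a slop option (in codons) exists for
indel-shifted orthologues. For proteins with more than two fingers,
descriptors are reported against every finger; the signature flags match
the amino-basic intron against the first finger and the carboxyl-basic
intron against the last (these coincide for single-finger factors).

## Classification

The decision sequence is: (1) ≥ 2 GATA DBDs with a C4-to-next-C1 gap
≤ `tandem_gap` → ELT1; (2) one DBD plus ≥ 1 degenerate upstream finger →
ELT2; (3) one DBD → anchored-identity argmax over the ELT3/ELT5 consensus
templates if ≥ `min_identity`, ties broken by hexapeptide (TTAWRR → ELT5)
then intron flags (zinc-finger intron → ELT3, carboxyl-basic intron →
ELT5), otherwise ELTX; (4) ≥ 2 widely spaced DBDs → per-DBD rule-3 votes,
unanimous or ELTX. Every factor receives exactly one label and a list of
rule firings as evidence; ELT1/ELT2 calls are purely structural (their
identity scores are informational and never part of the decision).

Parameter choices: `tandem_gap` = 50 residues separates the ~29-residue
tandem arrangement of two-finger factors from the 100–311-residue
spacings seen in duplicated single-finger factors. `min_identity` = 0.60
sits between the family's reported within-class conservation extremes for
the two single-finger classes (ELT5 high, ELT3 low), so that genuinely
divergent fingers fall into the ELTX catch-all instead of being forced
into a named class. Both are configurable, and the tests include a
sensitivity check at the extremes (0.0 assigns the argmax; an unreachable
threshold sends all single-finger factors to ELTX). Identity is computed
over the fixed 55-column anchored layout only — there is little reliable
conservation outside the DBD to formalise on — with gaps never matching
and 55 always the denominator.

Derived single-finger subfamilies of particular lineages (e.g. the
MED/END/ELT-7 expansions) are not modelled as separate labels; with the
default library they resolve to ELT3 or ELTX.

## Anchored alignment and conservation

DBD windows are aligned by structural landmarks into a fixed 55-column
layout (C1, 2-spacer, C2, 17-loop, C3, 2-spacer, C4, 30 basic columns) —
no progressive MSA is involved, so the alignment is a pure function of
the detected domains. Shorter-than-canonical spacers/loops are
centre-padded (the extra gap goes right of centre); longer ones are
centre-trimmed with the excised residues kept as an insertion
side-record; the basic domain is left-aligned and gap-padded. Consensus
strings follow the family's case convention: uppercase = absolute
conservation (one residue, no gaps), lowercase = strict majority (> 50%
of rows), `.` otherwise (ties included). Conservation counts are
reported in both `absolute` and `majority` modes since the convention a
given "/55" figure uses is not always stated; absolute ≤ majority always
holds. DNA-contact variability counts the configured contact columns at
which the per-class consensi are not all the same uppercase residue.

The shipped class-consensus library and the 18-column contact set are
constructed synthetic stand-ins (filenames carry `.synthetic`): they
satisfy every structural constraint the classes impose (cysteine layout,
class-diagnostic hexapeptides, K/R-rich basic domains, pairwise
identities that separate the classes) but are not transcriptions of any
published alignment figure. Users with curated consensus rows can swap
the FASTA in place. The same file is the single source of truth for the
synthetic generator's templates, so classifier and generator can never
drift apart.

## Synteny and flank motifs

Gene spans are min/max over CDS segments (UTRs are unavailable in most
models). All within-species, within-class pairs are emitted once in
lexicographic id order; separation is the gap between facing span ends
(0 when overlapping), and orientation is same_direction / convergent
(3′ ends facing) / divergent (5′ ends facing), `n/a` across scaffolds.
The "nearby" summary threshold is 50 kbp, covering the observed
2.6–35 kbp linked-pair band with margin.

Flank scanning is targeted, not de novo: single HGATAR sites on both
strands (minus-strand hits at forward coordinates), double-GATA
(a plus-strand site 5′ of a minus-strand site, spacer ≤ 20 bp, all
overlapping pairs reported so the scan stays a pure function of the
sequence), and polypyrimidine tracts (merged length-12 windows with
≥ 90% C/T — the real motif is unquantified in the literature, so these
are stated defaults, not reproductions).

## Synthetic data generator

The generator is the package's study-condition definition: five classes ×
ten genes by default, each built from the class templates with
class-typical architecture — ELT1 with two tandem DBDs 29 residues apart
and a 10-serine segment 25 residues upstream of the amino DBD; ELT2 with
a CX₂C-X₁₂-CX₂C degenerate finger 60 residues upstream of its DBD; ELT3
with an 8-residue tail; ELT5 with an 80-residue tail; ELTX divergent,
intronless, the first copy carrying the CSNSNC variant spacer. Landmark
introns follow the class plan (ELT1: both basic-domain introns; ELT2/
ELT3: the zinc-finger intron; ELT5: the carboxyl-basic intron). Non-ELT1
classes receive a poly-serine segment with probability 0.2. Seven paralog
pairs mirror the observed linked-duplicate band (six at 2.6–35 kbp plus
one at 893 kbp; five same-direction, two convergent). Flank motifs are
planted per class (polypyrimidine for ELT1/ELT5 promoters, double-GATA
for ELT2, a single HGATAR for ELT3) at 42% GC background.

Mutation is i.i.d. per-residue substitution, uniform over the 19 other
residues. With `protect_landmarks` on, the GATA-finger cysteines and the
hexapeptides are immune — but the degenerate-finger cysteines are not,
by design: the degenerate finger is the class's least-conserved feature,
and leaving it mutable is what makes classification accuracy degrade
realistically with rate (ELT2 factors lose the finger and fall to ELTX).
Reverse translation draws synonymous codons uniformly (codon usage is
irrelevant downstream); intron interiors are random with GT..AG ends.

Planted flank motifs must be unambiguously scorable, so each flank is
scrubbed of chance matches: spurious HGATAR/pyrimidine-tract hits are
destroyed by targeted base edits outside the planted span until only the
planted hits remain. One subtlety: a planted 14-bp pyrimidine tract
always merges with one or two neighbouring bases under the ≥ 90%-of-12
window rule, so its expected hit is re-read from the scrubbed flank
rather than pre-declared. The double-GATA spacer alternates C/G so the
planted span itself can never contain a chance site. Everything planted
is recorded in a JSON truth manifest; recovery scoring matches domains at
≥ 80% reciprocal span overlap, introns and motifs exactly, classes by
label. Identical seed and configuration give byte-identical outputs.

What the generator does **not** emulate: indels (so landmark offsets
never shift), realistic codon usage or splice-site variation, gene
prediction errors, pseudogenes, tree-structured divergence between
species, or background sequence with genic composition. Passing recovery
tests therefore demonstrate the correctness of the measurement machinery
under the stated conditions, not robustness to annotation noise in real
assemblies — on real data, gene-model quality is the dominant error
source and is surfaced through the QC table, not corrected.

## Problem sizes and numerical choices

The default corpus (50 genes, ~1.3 Mbp over 43 scaffolds) generates in
about a second and annotates in well under one. The
accuracy-versus-mutation study runs at the protein level (mutated
templates plus their planned intron signatures, 10 replicates × rates
{0.05, 0.10, 0.20}, 50 factors each) so that the whole sweep takes
seconds; the genome→GFF3→annotation path is exercised at rate 0 by the
recovery scoring, which demands precision = recall = 1.0 for every
planted feature type and an identity confusion matrix. Determinism is
part of the contract: scans are pure functions of sequence and
configuration, table orderings are fixed, and rerunning the pipeline on
identical inputs produces byte-identical bundles.

Known limitations: classification of genuinely intermediate factors
(e.g. a factor sharing ELT-1 and ELT-2 features) follows the rule order,
not curator judgement, and class counts on real assemblies will deviate
where curators made calls the rules cannot reproduce; the consensus
library is synthetic (see above) and should be replaced with curated
rows for benchmark use; conservation statistics depend on which rows
enter each class alignment, which here is determined by the classifier
itself.
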