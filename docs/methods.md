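# Methods

## Problem and model

A recombinant phage genome derived from two parents is modelled as an
alternating sequence of parental segments separated by crossovers.  Because
the parents are nearly identical (>99% nucleotide identity in the system
this package was built around), ancestry is only observable at *informative
sites*: alignment columns where the parents differ and the recombinant
matches exactly one of them.  Between informative sites the two parents are
indistinguishable, so:

* every inferred crossover count is a **lower bound** — two crossovers with
  no informative site between them cancel and are invisible, and crossovers
  outside the informative-site span are undetectable;
* a crossover can only be **localised to an interval** between the last
  informative site exclusive to the outgoing parent and the first exclusive
  to the incoming parent.  The reported point coordinate (the last base
  matching the outgoing parent, scanning left to right) is a convention,
  which is why every breakpoint record carries the full interval.

The greedy left-to-right rule (switch ancestry at every informative site
that contradicts the current parent) yields the minimal number of switches
consistent with the sites.  This is verified in the test suite against an
independent dynamic-programming parsimony oracle over (site, parent)
states, with ties broken toward the latest possible switch.

## Trio alignment

Internal mode chains 21-mers that occur exactly once in each of the three
genomes (greedy co-linear selection, adequate at near-identity), aligns the
inter-anchor gaps with exact global edit distance (edlib), pairwise against
the recombinant, and merges the two pairwise alignments column-wise on the
recombinant.  Parent insertions meeting at the same recombinant locus are
co-aligned against each other, so an indel shared by both parents (i.e. a
deletion in the recombinant) appears as matched parental columns rather
than two staggered single-parent events.  A prealigned mode ingests a
3-row aligned FASTA produced by any external aligner and only validates it.
For inputs under ~50 kb with no usable anchors the aligner falls back to a
single whole-sequence edit-distance alignment; longer anchor-free inputs
are rejected with a pointer to prealigned mode.

Column classification:

* a contiguous run of columns gapped in the same subset of rows is
  **collapsed into one gap event** — a contiguous indel has a single
  mutational origin and is one piece of evidence, not one per base;
* a gap event is *informative* for the parent whose gap pattern and bases
  the recombinant reproduces (matching a parent-specific deletion is
  evidence just like matching a base);
* columns containing N are uninformative by fiat, so ambiguous bases never
  create breakpoints;
* sites matching neither parent never vote on ancestry; they are candidate
  variants.  They do displace the reported crossover coordinate, which must
  be a base that actually matches the outgoing parent.

Events gapped in the recombinant sit between two recombinant bases; their
evidence is anchored as a (flank, flank+1) straddle so that breakpoint
intervals remain well-formed when an indel event and a substitution site
are adjacent.

## Variant adjudication

A neither-parent site is either a genuine de-novo mutation or a sequencing
artifact.  Pyrosequencing miscounts homopolymer run lengths, so the
adjudication rule is: **indels** whose context includes a parental
homopolymer run of `min_run` (default 4) or more bases, overlapping or
within 1 bp, are `suspected_error`; everything else — including every
substitution, regardless of context — is `accepted_mutation`.  The default
of 4 is the shortest run length at which pyrosequencing indel errors are
classically frequent; it is a configuration knob, not a fitted value.
Substitutions are never auto-suspected because a real mosaic analysis must
be able to accept a lone point mutation even when homopolymer errors are
present elsewhere.

Coding effects use the bacterial genetic code (translation table 11), with
reverse-strand ORFs (encoded start > stop, as in the source tables)
reverse-complemented before codon comparison.  A substitution is
synonymous when the recombinant residue equals either parent's residue at
that codon, nonsense when it creates a stop, missense otherwise.  Indels
inside an ORF are frameshift candidates unless their length change is a
multiple of 3.  Amino-acid difference counts per ORF compare the
recombinant's codons with the codons spelled by the chosen parent's aligned
bases; codons touching a parental gap or insertion count as differences and
raise a frameshift warning.

## Per-ORF accounting

Each crossover's reported position is assigned to the ORF whose
(strand-agnostic) interval contains it; positions in no ORF go to a named
intergenic bucket between the flanking ORFs; zero-count ORFs are always
reported.  Overlapping ORFs both receive the event, with a warning making
the double count explicit — event totals equal input size only without
overlaps.  The bundled fixture reproduces the study's printed accounting:
48 events, 63 of 92 ORFs untouched, maxima of 5 and 6 events in the two
rII-like/tailspike genes, one intergenic event.  (The printed source also
states "22 of 29" single-crossover ORFs while its own table lists 21 plus
the intergenic event; the fixture follows the table.  One printed ORF size,
1167 bp, conflicts with its own printed coordinates, 16,639–17,976; the
fixture keeps the coordinates and omits that size cell.)

## Host-range statistics

Breadth is lysed/tested strains from a spot matrix ("+" cells).  EOP is
the titer ratio against the isolation host; titers below the detection
limit (10 pfu/mL by default) produce *censored* records carrying the bound
`detection_limit / titer_isolation` — never zero, because "no plaques" is
an inequality, not a measurement.  The serial-dilution endpoint rule is
read strictly: endpoint reached only when *more than* the threshold
fraction (default 0.8) of strains lyse at a dilution at least as deep as
10^-7.  Phages with any measured (non-censored) EOP > 1 on a non-isolation
strain are flagged; the isolation host is taken as given and the ratios are
not renormalised to the best host.

The amplification estimate is the plain exponential `burst_size **
replication_rounds` (defaults 50 pfu/cell and 5 rounds per protocol round,
≈3×10^8 from a single phage).

## Synthetic data generator

The generator emulates the study conditions and is the ground truth for
every pipeline test:

| parameter | default | meaning |
|---|---|---|
| `genome_length` | 73,050 bp | full-size genome of the real recombinant |
| `snp_rate` | 0.005 /bp | parent divergence, inside the >99% identity regime |
| `indel_rate` | 0.0005 /bp | short indels, max length `indel_max_len`=4 |
| `homopolymer_seed_count` | 50 | planted runs of length 4–8 in parent A |
| `n_crossovers` | 48 | study-scale crossover count |
| `n_mutations` | 1 | de-novo substitutions |
| `n_error_indels` | 0 | planted 1-bp deletions inside shared runs |
| `rng_seed` | — | mandatory; identical seeds give identical bytes |

Parent A is uniform random with planted homopolymer runs; parent B applies
SNPs and indels at the configured rates.  The recombinant copies parent A
up to the first crossover and alternates thereafter; truth coordinates are
recombinant-frame, and each crossover coordinate is the last base taken
from the outgoing parent.

Two placement rules keep the ground truth identifiable, by construction
rather than by luck:

* **Crossover boundaries stay clear of indels.**  With
  `guarantee_separation` (default), each boundary falls strictly between
  two parental-difference columns, inside the agreement region, and at
  least `max(10, indel_max_len + 2)` columns from any indel column.  Indel
  placement within a repeat is alignment-ambiguous; a junction planted
  inside that ambiguity region cannot be recovered exactly by any aligner,
  so planting one would test alignment tie-breaking, not inference.
  Without `guarantee_separation`, boundaries are uniform over the interior
  of the parental-difference span (so undetectable crossovers always cancel
  pairwise and the detectable count preserves parity), and the truth object
  records the parity-reduced `expected_detectable_crossovers`.
* **Planted mutations are clean substitutions.**  De-novo substitutions
  avoid parental-difference columns, homopolymer runs (±1 bp) and indel
  neighbourhoods, mirroring the real case where the single accepted
  mutation was a substitution away from any run.  A substitution planted
  inside a long run that also carries parental indels is not recoverable
  *as* a substitution — the optimal alignment can absorb it into indel
  rearrangements — so such placements are excluded rather than papered
  over.  Homopolymer-error indels (`n_error_indels`) delete one base from a
  run shared by both parents; their truth coordinate is the run's left
  flank, and comparisons tolerate placement anywhere within the run.

What the generator does **not** emulate: read-level sequencing error
processes and coverage (errors are planted directly in the assembled
sequence), structural rearrangements, repeat families longer than the
planted homopolymers, and real phage base composition.  Passing tests
therefore demonstrate correctness of the inference given near-identical
parents with point differences and short indels — the regime of the real
trio — not robustness to diverged or repeat-rich genomes.

## Problem sizes and numerical choices

The test suite runs the full pipeline on a 73,050 bp trio (seconds) and on
100 seeded 2 kb instances for the recovery property; property tests over
informative-site patterns use 1,000 random patterns against the exact
oracle.  The acceptance script runs one full-size trio with 48 crossovers,
1 mutation and 4 planted homopolymer errors, deliberately mirroring the
real recombinant's five neither-parent sites (1 accepted + 4 suspected).
All randomness flows from explicit seeds; the aligner and classifiers are
fully deterministic (greedy anchor selection, leftmost-gap edit paths from
edlib, no randomized initialisation).

## Known limitations

* The crossover count and positions inherit alignment conventions near
  indels; positions can shift by a few bases between equally optimal
  alignments.  Intervals, not point estimates, are the robust output.
* Heritage fractions assign whole ambiguity intervals to the outgoing
  parent (the point-estimate convention); with ~1.5 kb average segment
  length and ~180 bp mean intervals the induced bias is at the percent
  level, which is why the headline figure is "about two thirds".
* Greedy parsimony reports one minimal explanation; regions with dense
  crossovers between few informative sites (e.g. 3–7 nt template switches)
  are systematically undercounted — as any sequence-based method must.
* The ORF table is consumed as given; ORF calling is out of scope.
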