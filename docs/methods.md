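# Methods

## The annotation-transfer model

Paralogue annotation assumes that paralogous proteins retain functionally
equivalent residues at aligned positions, and that a residue observed to
cause Mendelian disease when substituted in one family member is likely
intolerant of substitution in the others. The unit of transfer is an
alignment column: residue *i* of paralogue *P* corresponds to residue *j*
of query *Q* iff they occupy the same column of the family multiple
alignment, with gap-opposite residues explicitly unmapped (never nearest-
neighbour interpolated). Residue maps built this way are partial,
injective, and symmetric (the *Q*→*P* map is the inverse of the *P*→*Q*
map), which is what makes reciprocal annotation — re-using the same bundle
to annotate any other family member — a pure role swap.

Every transfer is graded before it is believed:

| tier | rule |
|------|------|
| HIGH | reference residue identical in query and paralogue AND consensus > 3 |
| MEDIUM | conserved OR consensus > 3 OR ≥ 2 paralogue variants at the residue |
| LOW | none of the above — excluded from all outputs |

"Conserved" is pairwise identity of the two reference residues (taken from
the alignment rows), not column-wide conservation. The multiplicity
criterion counts distinct paralogue variants across *all* paralogues
mapping to the query residue, after gap filtering and before tier
filtering, and is shared by all transfers at that residue. The threshold
is strictly greater than 3, so a consensus of exactly 3 never satisfies
the score criterion on its own.

## Consensus score

The 0–9 consensus score measures agreement between alignment algorithms at
a residue. When a per-residue score file accompanies the alignment it is
authoritative. Otherwise the package computes its own *partner-
reproduction* score: let *P(r)* be the set of (member, residue) partners
aligned to residue *r* in the primary alignment; each alternative
alignment contributes the fraction of *P(r)* it reproduces; the score is
`round_half_up(9 × mean fraction)`, and 0 when *r* aligns only to gaps.
This is a package-defined stand-in on the same 0–9 scale with the same
downstream threshold, not a re-implementation of any specific aligner's
formula; reports flag when it was used. All rounding of reported values
is half-up (`0.5 → 1`), matching how the printed tables round.

## Residue status

Query residues are classified from collated evidence in a strict decision
order: no records → **unannotated**; both pathogenic and benign support
(same or different variants at the residue) → **uncertain**; pathogenic
support only → **pathogenic**; benign support only → **benign**; only weak
records (database entries without usable frequency, or frequency records
failing the benign rule) → **uncertain**. Benign support means a benign
report, or the population rule: MAF ≥ 0.01 in *any* population and more
than one observation *in total* across datasets (the observation clause
attaches to the variant, the MAF clause to the population). Conflict
dominates regardless of report counts. The PPV of annotation is computed
over annotated residues with a known pathogenic-or-benign status only;
uncertain and unannotated residues carry no truth label.

## Statistics

With *n* annotated residues on a protein of length *L*, the expected count
in a status class of size *k* under uniform random placement is *n·k/L*;
the unrounded expectations sum exactly to *n*. Two enrichment conventions
are emitted: the default *paper-compat* ratio divides observed by the
half-up-rounded expectation (reproducing the printed 35/8 = 4.4 rather
than 35/7.695 = 4.5), the other by the exact expectation. Region
enrichment compares the fraction of annotations falling in a region group
with the group's residue-span fraction of the protein; groups are named
(hotspots, transmembrane, ...) and residues outside all regions form an
implicit "outside" group, so observed fractions always sum to 1. Fisher's
exact test is the conventional two-sided rule (sum of hypergeometric
probabilities ≤ the observed table's), delegated to scipy and cross-
checked in the tests against a full margin-enumeration oracle for small
tables. The package does not claim a specific 2×2 construction for the
published pooled test, because pooling and class inclusion admit several
readings; `fisher_exact` is exposed generically.

## Packaged fixtures

The RYR fixture (query RYR2, length 4967; paralogues RYR1, RYR3) and SCN
fixture (query SCN5A, length 2016; 19 sodium/calcium-channel paralogues)
package the printed per-variant annotation rows, family composition,
hotspot/transmembrane coordinates (RYR2 hotspots 77–466, 2246–2534,
3778–4959; SCN5A TM 127–415, 712–939, 1201–1470, 1524–1772, with the
non-TM domains defined as their complements), and recorded full-protein
summary vectors.

Two fixture components are synthetic, clearly labelled as such in file
names and docstrings, because the underlying data are not published:

* **Anchored scaffold alignments.** Full-length family alignments are not
  available, so the fixture builds filler sequences in which every printed
  (query position, paralogue position, reference residue) pair is anchored
  into a shared column; surplus paralogue residues between anchors go into
  member-specific insertion columns. The score track carries the printed
  consensus at anchored query residues and a neutral 5 elsewhere. The
  scaffold reproduces exactly the printed mappings, conservation states
  and consensus scores — and nothing else; query-sequence validation is
  disabled for fixtures since inter-anchor residues are filler.
* **Status evidence.** The full pathogenic/benign evidence set is
  proprietary, so deterministic synthetic records are planted to reproduce
  the recorded per-class residue counts exactly (SCN5A 368/28/60/1560,
  RYR2 139/20/71/4737); positions are arbitrary under a fixed internal
  seed. Consequently residue-level *observed* annotation overlaps cannot
  be recomputed and are carried as recorded vectors (SCN5A 113/1/6/321 of
  441; RYR2 35/1/1/238 of 275), which the statistics layer consumes
  directly and marks `from_recorded` in its reports.

Where the source text and its summary table disagree on in-region
annotation counts (172 vs 157 for RYR2 hotspots; 227 vs 355 for SCN5A TM),
the table values are used: only they reproduce the printed enrichment
factors 1.52 and 1.57. Two printed paralogue rows are not missense
(a nonsense and a synonymous substitution) and are rejected at parse time
with distinct error kinds and logged, consistent with the missense-only
evidence rule.

## Simulator

`simulate_family` emulates the one signal the method exploits: a set of
variation-intolerant residues shared family-wide. An ancestor sequence
(uniform over the 20 amino acids, default length 200) spawns each of the
`n_members` (default 4) by independent point substitution at
`substitution_rate` (default 0.1 per residue), never at the
`n_intolerant_residues` (default 12). Pathogenic variants (default 3 per
member) are planted on intolerant residues, benign ones (default 3)
elsewhere; `mislabel_fraction` relabels planted benign variants as
pathogenic to model corrupted evidence. Alternative alignments (default 3)
perturb the identity alignment at tolerant columns with probability
`alignment_noise` (default 0.05) by locally shifting one member's residues
one column, which lowers the partner-reproduction consensus there.
All randomness flows from one `numpy` Generator seeded by `seed`.

What the simulator does *not* model: indels (sequences stay equal length,
so the true alignment is the identity), phylogenetic tree structure,
realistic substitution matrices, and evidence-ascertainment bias. Passing
recovery tests therefore demonstrate that the mapping, tier filtering and
bookkeeping are correct — not that the method performs at any particular
level on real proteins. With `alignment_noise=0` and uncorrupted evidence
the recovery PPV is 100% by construction for any seed; sensitivity is
bounded by how many intolerant residues the planted variants cover.
The monotone-degradation property (mean PPV falls as `mislabel_fraction`
rises) is evaluated over 40–60 seeds at protein length 120 in the tests —
sizes chosen to make the trend decisive while keeping the suite quick.

## Numerical and degenerate-input choices

* Protein coordinates are 1-based; region ranges inclusive on both ends.
* Gap character is `-`; `.` normalised on read; residues uppercased.
* Half-up rounding everywhere a report prints a rounded number
  (`decimal`-based, so 80.5 → 81 rather than banker's 80).
* Enrichment against a zero expectation, PPV with no classified residues,
  and region enrichment of an empty annotation set report N/A (`None`)
  rather than raising.
* Annotation tables are sorted (tier desc, consensus desc, paralogue,
  position, variant) so outputs are byte-stable; duplicate (paralogue,
  variant, query residue) triples — e.g. one protein change printed under
  two cDNA changes — collapse to one annotation.
* A query gene's own known variants are never annotations of itself; they
  enter residue status, and annotate other members after a role swap.

## Limitations

Fixture-based numbers inherit the recorded-vector caveat above. The
consensus stand-in is not T-Coffee's formula; supplied score files always
take precedence. cDNA coordinates are provenance only (no codon
arithmetic). Paralogue discovery, alignment computation, and live database
retrieval are out of scope: the family composition, alignments and
evidence tables are user inputs.
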