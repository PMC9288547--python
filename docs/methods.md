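# Methods

This note records the models behind each module, the defaults and why they
were chosen, the numerical and design decisions made where the design was
genuinely open, and what the synthetic data can and cannot show.

## Signature discovery

A *signature site* is an alignment column where the target group shares one
unambiguous base that no background record can carry. The scan
(`signature.find_signature_sites`) is deterministic, column-independent and
parameterized by:

- `min_target_fraction` (default 1.0) — fraction of target records that must
  carry the same unambiguous base. Gaps and IUPAC ambiguity codes count as
  *non-agreeing*: a diagnostic assay must not rest on uncertain bases, so an
  ambiguous target base never supports a site even when its expansion
  contains the candidate allele.
- `min_background_fraction` (default 0.9) — fraction of background records
  that must be informative (unambiguous, non-gap) at the column before it is
  judged at all. Real barcode alignments mix full-length and partial
  records, so demanding full background coverage would discard most columns;
  0.9 tolerates a small minority of short records while still requiring the
  uniqueness claim to rest on essentially the whole panel.
- `treat_ambiguity_as_match` (default on) — a background Y defeats a T
  signature, because the ambiguity may hide the target allele.

Coordinates: alignment columns are reported 1-based; an ungapped
gene coordinate is additionally reported when a reference record is named
(`map_to_reference` counts non-gap reference bases up to the column). On the
default fixture the two coincide because the reference is gapless.

**A monotonicity caveat.** With fully informative backgrounds
(`min_background_fraction = 1.0`) the scan is monotone: adding a background
record can only remove sites. The fraction generalization deliberately
sacrifices strict monotonicity — a newly added informative record can lift
a column's informative fraction over the threshold (8/9 < 0.9 ≤ 9/10) and
thereby *create* a site. The property tests assert monotonicity in the
strict setting only.

Footprint screening (`screen_against_background`) replaces a remote
database search with an exhaustive both-strand, every-offset scan of a
primer against background records, reporting the minimum-mismatch binding
and whether the 3′-terminal base pairs. This is what certifies the
"shared allele, divergent footprint" case: a taxon that carries the
signature allele but differs elsewhere under the primer (the Thottea-like
fixture record) is still discriminated by footprint mismatches even though
the column itself is no longer a valid signature.

## Melting temperature

`primer_design.tm` evaluates the unified nearest-neighbor parameter set
(SantaLucia & Hicks 2004; Biopython's `DNA_NN3` table, version-pinned by
dependency) at `TmConditions` defaults of 50 mM monovalent cation, 3 mM
Mg²⁺ and 250 nM primer — the composition of a standard hot-start Taq mix,
which is the solution the panel actually anneals in. Salt correction is
Owczarzy et al. 2008 when Mg²⁺ is present and the SantaLucia 1998 entropy
correction (0.368·(N−1)·ln[Mon⁺]) otherwise. Under these conditions the
reference panel computes to 62.1 °C (A397F), 52.4 °C (C357F) and 61.0 °C
(R502). The test suite re-derives the no-Mg²⁺ path by hand summation over
an independently transcribed copy of the parameter table (agreement within
0.5 °C).

The familiar rule that extending an oligo by G or C raises T_m holds for
primer-like composition but is *not* a theorem of the NN model: seeded
sweeps found rare reversals, all above ~0.55 GC fraction. The property test
is therefore scoped to GC ≤ 0.55.

## Dimer scoring

`dimer_score` scans every ungapped antiparallel offset of two oligos and
scores the longest contiguous Watson–Crick run, doubled when the run
reaches either oligo's 3′ terminus (an extendable dimer is what produces
spurious dual-labeled product and hence a false strip line). The score is
symmetric and exact, and the reference panel's pairwise scores are 8
(A397F–C357F: the control's 3′-terminal TTTG pairs the specific primer's
internal CAAA), 4 (A397F–R502) and 6 (C357F–R502). The default screening
cutoff `max_dimer_score = 8` is set at the reference panel's realized
maximum — the published primers are taken as the boundary of acceptable
cross-complementarity; anything worse than the worst published pair is
rejected. Stricter cutoffs can be passed explicitly.

## Panel design

Design is exhaustive enumeration plus deterministic ranking — no
randomness, no heuristics:

- **Specific forward**: every admissible length (default 18–27 nt) ending
  exactly on the signature column, residues taken from the target-group
  majority consensus; any footprint column below
  `target_footprint_identity` (default 1.0) disqualifies the footprint
  rather than introducing degenerate bases, because the realized panel must
  be a plain oligo. No deliberate destabilizing penultimate mismatch is
  added: the modeled assay uses a perfect-match allele-specific primer.
- **Control forward / shared reverse**: all windows conserved across
  *every* record (targets and backgrounds) upstream resp. downstream of the
  specific primer, filtered on both product lengths (default 80–300 bp),
  the between-product size gap (default ≥ 10 bp, so a strip-free gel can
  still tell the products apart in principle), and cross-dimer scores.
  Reverse-primer residues are the reverse complement of the plus-strand
  consensus; coordinates are always reported on the plus strand.
- **Ranking**: weighted sum of |T_m − midpoint of the allowed range|,
  footprint non-identity and dimer score; ties break to shorter length,
  then smaller start column. Identical inputs give identical ranked lists.
- `tm_range_celsius` defaults to (50, 65) — a window bracketing the
  reference panel's computed T_m values under the assay-salt model, centered
  near standard multiplex practice of annealing-compatible primers.
- Rejected searches return an empty candidate list plus machine-readable
  rejection tallies (`DesignResult.rejections`), so a caller can tell *why*
  a design space is empty.

`assemble_panel` attaches the labels (specific→DIG, control→FAM,
reverse→biotin by default), verifies label distinctness, footprint order,
the 3′ anchor, and the product-size identity
`control − specific = specific_start − control_start`.

### The 124 vs 125 bp off-by-one

The reference panel's printed footprint coordinates (378–397 and 478–502)
span 125 columns inclusive, yet the products are reported as 124 bp and
145 bp. The package does not silently resolve this: the reference panel and
the template generator realize the *printed sizes* (124/145), while the
coordinate metadata keeps the printed spans; panels assembled from scratch
default to inclusive-span arithmetic with an explicit
`expected_specific_len` override available.

## In-silico PCR

The binding model is categorical, matching how the assay is read:

- a site exists where the primer's 3′-terminal window (default 1 nt — the
  single discriminating base; wider windows would be an undocumented
  strengthening) matches the template exactly under IUPAC set-intersection,
  and at most `max_internal_mismatches` (default 2) positions mismatch
  elsewhere;
- both strands are searched; sites and products are reported in plus-strand
  coordinates;
- every convergent forward/reverse site pair on one template with product
  length ≤ `max_product_len` (default 2000) yields an amplicon carrying the
  unordered pair of 5′ labels. Pairs whose two labels are identical are
  suppressed (such a product cannot form a sandwich on the strip);
  divergent (fwd/fwd, rev/rev) pairings are never products; templates are
  linear.
- no efficiency or quantity model: an amplicon supported only by
  mismatched binding is tagged *faint*, mirroring the categorical
  ++ / + / − read of strip lines. Ambiguity codes in templates match softly
  and are counted per site, since sequences from degraded herbal material
  are often ambiguous.

`electrophoresis_table` groups amplicons into bands and flags pairs closer
than 25 bp (default) as poorly resolved — on a standard agarose gel the
124/145 bp duo appears as one band, which is precisely why the strip
readout exists.

## Strip readout

Line logic: T1 captures {FAM, biotin} amplicons, T2 captures {DIG, biotin},
C captures unbound conjugate and is therefore always on in prediction
(invalid strips arise only when classifying externally recorded patterns).
A line is strong if any clean amplicon supports it, faint if only
mismatch-flagged amplicons do, absent otherwise; amplicons without biotin
are excluded with a warning flag (the gold conjugate cannot pick them up).

The call rule is total over all 27 line-state triples and frozen by a
golden test: no C → `invalid_strip`; neither T line → `no_amplification`;
T1 and T2 → `target_detected`; T1 only → `target_not_detected`. Faint
counts as present — the recorded panel calls faint-line crude drugs
positive, and the model follows it. The never-observed pattern "T2 without
T1" is called positive but flagged anomalous rather than invented a rule
for.

## Synthetic fixtures

`generate_fixture_alignment` plants one diagnostic column in an otherwise
neutral alignment: three disjoint conserved windows carry the primer
footprints (defaults: the published 357–376 / 378–397 / 478–502 geometry
and footprint sequences), all records are identical inside the windows
except at the diagnostic column (9 targets carry T; each of 13 backgrounds
draws C or A with equal probability — the observed background alleles, with
no reported proportions), and every other column mutates independently at
2% per record. Substitutions never touch the windows or the diagnostic
column, keeping class labels exact. Record counts default to the physical
validation panel (9 target, 13 background) rather than the much larger
accession bookkeeping, which is internally inconsistent in the source
material.

Templates reuse the alignment's ancestral sequence for flanks and the
control→specific spacer — so designed footprints that extend slightly past
a designated window still bind — and splice in a filler segment between the
specific and reverse footprints sized to realize the configured specific
product length (124 bp by default; when the configured size equals the
alignment span the ancestral segment is used unchanged). The optional
Thottea-like record shares the target allele but carries two planted
mismatches at 3 and 6 nt from the primer's 3′ end.

All generators are pure functions of `FixtureConfig.seed`; identical seeds
give byte-identical FASTA.

What the fixture does **not** emulate: phylogenetic correlation between
records, indels and alignment gaps (tests inject those separately),
sequencing error, length heterogeneity of real accessions, template
quantity and PCR efficiency, and the chemistry of strips (antibody
affinities, flow kinetics, band intensity gradients). Passing tests
therefore demonstrate the correctness of the discovery/design/readout
logic under the assay's idealized premises, not wet-lab performance on
herbal extracts — analytical sensitivity in nanograms is out of scope by
construction.

The recorded 26-row strip-pattern panel (9 authentic targets, 4 authentic
substitutes, 8 crude drugs, the target-free laboratory formula F0 and 4
commercial formulae) ships as a packaged TSV; replaying it through the call
rule reproduces every reported species call (9/9, 0/4, 7/8, and F0 + F3
negative among formulae).

## Problem sizes

Default analyses run on 22 records × 600 columns and 44 templates of
~225 nt; the property suites use 200 random alignments (≤ 20 records ×
≤ 80 columns) for oracle equivalence and 50 random fixture geometries for
full-pipeline parameter recovery. The whole test suite completes in well
under a minute on one CPU.
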