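# taxsig

Desk-side design and interpretation toolkit for **PCR–lateral-flow (PCR-LFA)
species authentication assays** built on taxon-diagnostic nucleotide
signatures.

The motivating use case is detecting *Aristolochia* — the aristolochic-acid
plants behind aristolochic acid nephropathy — in herbal crude drugs and
polyherbal formulae via the plastid *rbc*L barcode: a single alignment column
(position 397, allele T) separates the genus from every co-occurring
ingredient plant, and an allele-specific primer anchored on it turns that
column into a visual strip readout. The toolkit generalizes each step so any
target/background partition of an alignment can be worked the same way.

## What it does

Given an aligned FASTA plus a two-column taxon partition
(`record_id<TAB>target|background`), `taxsig` will:

1. **Discover signatures** (`signature`): scan every column for an
   unambiguous base carried by all targets and absent — even under IUPAC
   ambiguity expansion — from every background record.
2. **Design a labeled triplex panel** (`primer_design`): an allele-specific
   forward primer whose 3′-terminal base sits exactly on the signature
   (ARMS principle — a 3′ mismatch blocks extension), a conserved control
   forward upstream, and a shared conserved reverse downstream, labeled
   DIG / FAM / biotin. Candidates are screened on length, nearest-neighbor
   T_m (unified parameter set, Mg²⁺-corrected), GC, footprint conservation,
   product sizes and cross-dimer scores, and ranked deterministically.
3. **Predict multiplex PCR** (`insilico_pcr`): 3′-mismatch-sensitive
   binding on both strands of ungapped templates, propagating the 5′ labels
   onto each predicted amplicon; includes a gel-band report that flags
   poorly resolved near-equal sizes.
4. **Read the strip** (`lfa_readout`): label pairs → T1 (anti-FAM, internal
   control) / T2 (anti-DIG, taxon) / C (strip control) line states → a call:
   `target_detected`, `target_not_detected`, `no_amplification` or
   `invalid_strip`. Recorded ++ / + / − pattern tables are parsed and
   classified the same way.
5. **Generate synthetic study data** (`fixtures`): a seeded alignment /
   template / sample-panel generator that plants a diagnostic column inside
   conserved primer footprints (by default the published *rbc*L geometry and
   the published A397F / C357F / R502 primer sequences), plus a packaged
   26-sample recorded strip-pattern panel.

Because both forward primers share one reverse primer, the two products
differ in length by exactly the offset between the forward starts
(145 − 124 = 378 − 357 = 21 in the reference panel) — an invariant the
package enforces.

## Worked example

The five CLI subcommands chain into a full in-silico study:

```bash
taxsig simulate --outdir demo --seed 1
taxsig find-signatures --alignment demo/alignment.fasta \
    --partition demo/partition.tsv --reference tgt_01 --out demo/sites.tsv
taxsig design --alignment demo/alignment.fasta --partition demo/partition.tsv \
    --site 397 --out demo/panel.yaml
taxsig amplify --panel demo/panel.yaml --templates demo/templates.fasta \
    --out demo/amplicons.tsv
taxsig readout --amplicons demo/amplicons.tsv --out demo/calls.tsv
```

which prints (stderr log, abridged):

```text
[taxsig] simulate: wrote 22 aligned records (reference tgt_01), 44 templates, patterns.tsv -> demo
[taxsig] find-signatures: 1 site(s) -> demo/sites.tsv
[taxsig] design: panel sfwd_380_397/cfwd_356_378/rev_479_500, expected products 121/145 bp -> demo/panel.yaml
[taxsig] amplify: 63 amplicon(s) -> demo/amplicons.tsv
[taxsig] readout: calls -> demo/calls.tsv
```

`sites.tsv` holds the one diagnostic column — column 397, target allele T,
background alleles {A, C}, informative in 9/9 targets and 13/13
backgrounds. The designed panel here is an 18-mer specific forward
(3′-anchored on 397), a 23-mer control forward and a 22-mer reverse, giving
121 bp and 145 bp products; the calls table reproduces the sample-panel
truth, e.g.:

```text
sample          t1   t2   c    call
A_acuminata     ++   ++   ++   target_detected
C5              ++   -    ++   target_not_detected
F0_YMVT         ++   -    ++   target_not_detected
```

The same thing in Python, using the published primer panel instead of a
freshly designed one:

```python
from taxsig import (FixtureConfig, SampleClass, generate_templates,
                    reference_panel, simulate_multiplex, predict_strip)

cfg = FixtureConfig(seed=1)
panel = reference_panel()            # A397F / C357F / R502, DIG / FAM / biotin
t = generate_templates(cfg, [SampleClass("sample", ("target",))])
amps = simulate_multiplex(panel, t)
# -> 124 bp {DIG, biotin} and 145 bp {FAM, biotin}
print(predict_strip(amps).call)      # Call.TARGET_DETECTED
```

## Layout

```
src/taxsig/        seqio, signature, primer_design, insilico_pcr,
                   lfa_readout, fixtures, cli (+ packaged pattern TSV)
tests/             unit, property and end-to-end acceptance tests
docs/methods.md    models, defaults, numerical choices, limitations
scripts/           acceptance.py
```

See `docs/methods.md` for the modeling assumptions (binding model, T_m
conditions, dimer scoring, the 124 vs 125 bp coordinate off-by-one) and the
limits of what the synthetic fixtures can show about real herbal samples.
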