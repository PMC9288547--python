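"""Diagnostic-column (nucleotide signature) discovery and background screening.

A signature site is an alignment column where the whole target group shares
one unambiguous base that is absent — even under IUPAC ambiguity expansion —
from every background sequence. Such a column can anchor the 3' terminus of
an allele-specific (ARMS) primer: extension from a 3'-terminal mismatch is
blocked, so amplification succeeds only on templates of the target taxon.

The scan is deterministic: no randomness, output sorted by column.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import ValidationError
from .seqio import (
    GAP,
    UNAMBIGUOUS,
    Alignment,
    SequenceRecord,
    TaxonPartition,
    bases_compatible,
    expand,
    reverse_complement,
)


@dataclass(frozen=True)
class SignatureParams:
    """Thresholds generalizing exact target/background uniqueness.

    min_target_fraction
        Fraction of target records that must carry the same unambiguous
        base at the column (gaps and ambiguity codes count against it).
    min_background_fraction
        Fraction of background records that must be informative
        (unambiguous, non-gap) for the column to be judged at all.
    treat_ambiguity_as_match
        If true, an ambiguous background symbol whose expansion contains
        the candidate target allele disqualifies the column (a background
        Y defeats a T signature).
    """

    min_target_fraction: float = 1.0
    min_background_fraction: float = 0.9
    treat_ambiguity_as_match: bool = True

    def __post_init__(self) -> None:
        for name in ("min_target_fraction", "min_background_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class SignatureSite:
    """A diagnostic alignment column.

    ``background_alleles`` records every non-gap symbol observed in the
    background group at the column (ambiguity codes included).
    ``reference_position`` is the 1-based ungapped coordinate on a named
    reference record, when one was requested.
    """

    column: int
    target_allele: str
    background_alleles: frozenset[str]
    n_target_informative: int
    n_background_informative: int
    n_target_missing: int
    reference_position: int | None = None

    def __post_init__(self) -> None:
        if self.target_allele not in UNAMBIGUOUS:
            raise ValidationError(
                f"target allele must be unambiguous, got {self.target_allele!r}"
            )
        if self.n_target_informative < 1 or self.n_background_informative < 1:
            raise ValidationError("a signature site needs informative records on both sides")


def find_signature_sites(
    aln: Alignment,
    part: TaxonPartition,
    params: SignatureParams | None = None,
    *,
    reference_id: str | None = None,
) -> list[SignatureSite]:
    """Scan every column for a target-unique unambiguous allele.

    A column qualifies when at least ``min_target_fraction`` of the target
    records carry the same unambiguous base, at least
    ``min_background_fraction`` of the background records are informative
    there, and no background symbol is compatible with that base (exact
    equality only, if ``treat_ambiguity_as_match`` is off).
    """
    params = params or SignatureParams()
    part.validate_against(aln)
    target_seqs = [aln.get(i).residues for i in sorted(part.target_ids)]
    background_seqs = [aln.get(i).residues for i in sorted(part.background_ids)]
    n_targets, n_background = len(target_seqs), len(background_seqs)

    sites: list[SignatureSite] = []
    for col0 in range(aln.n_columns):
        t_syms = [s[col0] for s in target_seqs]
        t_informative = [b for b in t_syms if b in UNAMBIGUOUS]
        if not t_informative:
            continue
        counts = Counter(t_informative)
        # deterministic tie-break: highest count, then alphabetical
        allele, agree = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if agree / n_targets < params.min_target_fraction:
            continue

        b_syms = [s[col0] for s in background_seqs if s[col0] != GAP]
        b_informative = [b for b in b_syms if b in UNAMBIGUOUS]
        if not b_informative:
            continue
        if len(b_informative) / n_background < params.min_background_fraction:
            continue

        if any(b == allele for b in b_informative):
            continue
        if params.treat_ambiguity_as_match and any(
            b not in UNAMBIGUOUS and allele in expand(b) for b in b_syms
        ):
            continue

        column = col0 + 1
        ref_pos = (
            map_to_reference(aln, column, reference_id) if reference_id is not None else None
        )
        sites.append(
            SignatureSite(
                column=column,
                target_allele=allele,
                background_alleles=frozenset(b_syms),
                n_target_informative=len(t_informative),
                n_background_informative=len(b_informative),
                n_target_missing=n_targets - len(t_informative),
                reference_position=ref_pos,
            )
        )
    return sites


def map_to_reference(aln: Alignment, column: int, reference_id: str) -> int:
    """Map an alignment column to the 1-based ungapped coordinate on a reference.

    The mapping counts non-gap reference bases from column 1 through the
    given column; the reference must not be gapped at the column itself.
    """
    ref = aln.get(reference_id)
    if not 1 <= column <= aln.n_columns:
        raise ValidationError(f"column {column} outside [1, {aln.n_columns}]")
    prefix = ref.residues[:column]
    if prefix[-1] == GAP:
        raise ValidationError(
            f"reference {reference_id!r} is gapped at alignment column {column}"
        )
    return len(prefix) - prefix.count(GAP)


@dataclass(frozen=True)
class FootprintMatch:
    """Best (minimum-mismatch) binding of a primer on one background record.

    ``start``/``end`` are 1-based inclusive on the degapped plus strand of
    the record; ``strand`` is the orientation in which the primer anneals.
    ``three_prime_match`` reports whether the primer's 3'-terminal base is
    IUPAC-compatible with the template at that binding.
    """

    record_id: str
    strand: str  # "forward" | "reverse"
    start: int | None
    end: int | None
    mismatch_count: int
    three_prime_match: bool


def screen_against_background(primer, background: list[SequenceRecord]) -> list[FootprintMatch]:
    """Exhaustively scan a primer against every background record.

    For each record the minimum-mismatch ungapped binding over both strands
    is reported, together with whether the 3'-terminal base pairs. This
    certifies that taxa sharing the signature allele but carrying variation
    elsewhere in the primer footprint (near-signature variants) are still
    discriminated by footprint mismatches.

    ``primer`` may be a :class:`~taxsig.primer_design.PrimerSpec` or a plain
    residue string.
    """
    if not background:
        raise ValidationError("background screen requires at least one record")
    residues = getattr(primer, "residues", primer)
    name_len = len(residues)
    rc = reverse_complement(residues)

    reports: list[FootprintMatch] = []
    for rec in background:
        template = rec.degapped()
        best: FootprintMatch | None = None
        if len(template) >= name_len:
            for start0 in range(len(template) - name_len + 1):
                window = template[start0 : start0 + name_len]
                for strand, probe in (("forward", residues), ("reverse", rc)):
                    mism = sum(
                        not bases_compatible(p, w) for p, w in zip(probe, window)
                    )
                    # primer 3' terminus sits at the window end on the plus
                    # strand, at the window start when bound on the minus strand
                    if strand == "forward":
                        three = bases_compatible(residues[-1], window[-1])
                    else:
                        three = bases_compatible(residues[-1], reverse_complement(window[0]))
                    cand = FootprintMatch(
                        record_id=rec.id,
                        strand=strand,
                        start=start0 + 1,
                        end=start0 + name_len,
                        mismatch_count=mism,
                        three_prime_match=three,
                    )
                    if best is None or _match_order(cand) < _match_order(best):
                        best = cand
        if best is None:
            best = FootprintMatch(
                record_id=rec.id,
                strand="forward",
                start=None,
                end=None,
                mismatch_count=name_len,
                three_prime_match=False,
            )
        reports.append(best)
    return reports


def _match_order(m: FootprintMatch) -> tuple:
    return (m.mismatch_count, not m.three_prime_match, m.start or 0, m.strand)
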