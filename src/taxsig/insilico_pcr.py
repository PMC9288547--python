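"""In-silico multiplex PCR with a 3'-mismatch-sensitive binding model.

Primer annealing is modeled as ungapped IUPAC-compatible matching: the
3'-terminal window (default one base — the ARMS discriminator) must match
exactly, and at most ``max_internal_mismatches`` are tolerated elsewhere.
Products are enumerated from every convergent forward/reverse site pair on
the same template, carrying the unordered pair of 5' labels of the two
primers onto the amplicon. No efficiency or quantity model: presence or
absence only, with a categorical ``faint`` tag when a supporting binding
carries internal mismatches.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .errors import ValidationError
from .primer_design import Label, PrimerSpec, TriplexPanel
from .seqio import GAP, UNAMBIGUOUS, bases_compatible, reverse_complement


@dataclass(frozen=True)
class Template:
    """An ungapped DNA template (one extracted molecule class of a sample)."""

    id: str
    residues: str
    origin_tag: str = ""

    def __post_init__(self) -> None:
        if GAP in self.residues or "." in self.residues:
            raise ValidationError(f"template {self.id}: must be ungapped")
        if len(self.residues) < 1:
            raise ValidationError(f"template {self.id}: empty sequence")
        object.__setattr__(self, "residues", self.residues.upper().replace("U", "T"))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class BindingModel:
    """Annealing stringency parameters."""

    three_prime_window: int = 1
    max_internal_mismatches: int = 2
    max_product_len: int = 2000

    def __post_init__(self) -> None:
        if self.three_prime_window < 1:
            raise ValidationError("three_prime_window must be >= 1")
        if self.max_internal_mismatches < 0 or self.max_product_len < 1:
            raise ValidationError("binding model thresholds out of range")


@dataclass(frozen=True)
class BindingSite:
    """One annealing position, reported in plus-strand coordinates."""

    primer_name: str
    template_id: str
    start: int  # 1-based inclusive, plus strand
    end: int
    strand: str  # "forward": primer == plus-strand window; "reverse": primer == revcomp
    mismatch_count: int
    three_prime_exact: bool
    ambiguous_pairings: int = 0


@dataclass(frozen=True)
class Amplicon:
    """A predicted product delimited by a forward and a reverse binding site."""

    template_id: str
    start: int
    end: int
    fwd_primer: str
    rev_primer: str
    label_pair: frozenset
    mismatches: int = 0
    origin_tag: str = ""

    def __post_init__(self) -> None:
        if len(self.label_pair) != 2:
            raise ValidationError("label_pair must contain exactly two distinct labels")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def faint(self) -> bool:
        return self.mismatches > 0


def find_binding_sites(primer: PrimerSpec, t: Template, m: BindingModel | None = None) -> list[BindingSite]:
    """All annealing positions of a primer on both strands of a template.

    A window qualifies when every base of the 3'-terminal window is
    IUPAC-compatible with the template and the remaining positions carry at
    most ``max_internal_mismatches`` incompatibilities. Ambiguity codes in
    the template match by set intersection; the count of such soft pairings
    is reported per site.
    """
    m = m or BindingModel()
    res = primer.residues
    L = len(res)
    seq = t.residues
    if len(seq) < L:
        return []
    rc = reverse_complement(res)
    k = min(m.three_prime_window, L)
    sites: list[BindingSite] = []
    for start0 in range(len(seq) - L + 1):
        window = seq[start0 : start0 + L]
        # forward orientation: primer 3' end at the window end
        if _window_matches(res, window, terminal_at_end=True, k=k, max_mm=m.max_internal_mismatches):
            mm, amb = _mismatch_stats(res, window)
            sites.append(
                BindingSite(
                    primer_name=primer.name, template_id=t.id,
                    start=start0 + 1, end=start0 + L, strand="forward",
                    mismatch_count=mm, three_prime_exact=True, ambiguous_pairings=amb,
                )
            )
        # reverse orientation: primer anneals to the plus strand's complement,
        # its 3' end sits at the window *start* in plus-strand coordinates
        if _window_matches(rc, window, terminal_at_end=False, k=k, max_mm=m.max_internal_mismatches):
            mm, amb = _mismatch_stats(rc, window)
            sites.append(
                BindingSite(
                    primer_name=primer.name, template_id=t.id,
                    start=start0 + 1, end=start0 + L, strand="reverse",
                    mismatch_count=mm, three_prime_exact=True, ambiguous_pairings=amb,
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand, s.primer_name))
    return sites


def _window_matches(probe: str, window: str, *, terminal_at_end: bool, k: int, max_mm: int) -> bool:
    L = len(probe)
    if terminal_at_end:
        terminal = range(L - k, L)
    else:
        terminal = range(0, k)
    mm = 0
    for i in range(L):
        ok = bases_compatible(probe[i], window[i])
        if i in terminal:
            if not ok:
                return False
        elif not ok:
            mm += 1
            if mm > max_mm:
                return False
    return True


def _mismatch_stats(probe: str, window: str) -> tuple[int, int]:
    mm = sum(not bases_compatible(p, w) for p, w in zip(probe, window))
    amb = sum(
        1
        for p, w in zip(probe, window)
        if w not in UNAMBIGUOUS and bases_compatible(p, w)
    )
    return mm, amb


def simulate_multiplex(
    panel: TriplexPanel, templates: list[Template], m: BindingModel | None = None
) -> list[Amplicon]:
    """Predict all products of the triplex reaction over a template list.

    Every forward-oriented site pairs with every reverse-oriented site
    downstream of it on the same template (product length capped by the
    model); the amplicon carries the unordered pair of the two primers'
    5' labels. Results are deterministic and per-template independent, so
    a mixture is simply the union of its members' products.
    """
    m = m or BindingModel()
    amplicons: list[Amplicon] = []
    for t in templates:
        fwd_sites: list[tuple[BindingSite, PrimerSpec]] = []
        rev_sites: list[tuple[BindingSite, PrimerSpec]] = []
        for primer in panel.primers:
            for site in find_binding_sites(primer, t, m):
                if site.strand == "forward":
                    fwd_sites.append((site, primer))
                else:
                    rev_sites.append((site, primer))
        for fsite, fprimer in fwd_sites:
            for rsite, rprimer in rev_sites:
                if fsite.start > rsite.start:
                    continue
                length = rsite.end - fsite.start + 1
                if length > m.max_product_len:
                    continue
                if fprimer.label == rprimer.label:
                    continue  # indistinct label pair is undetectable and unreported
                amplicons.append(
                    Amplicon(
                        template_id=t.id,
                        start=fsite.start,
                        end=rsite.end,
                        fwd_primer=fprimer.name,
                        rev_primer=rprimer.name,
                        label_pair=frozenset({fprimer.label, rprimer.label}),
                        mismatches=fsite.mismatch_count + rsite.mismatch_count,
                        origin_tag=t.origin_tag,
                    )
                )
    amplicons.sort(key=lambda a: (a.template_id, a.start, a.end, a.fwd_primer, a.rev_primer))
    return amplicons


@dataclass(frozen=True)
class Band:
    """One gel band: amplicons of equal length from one template."""

    template_id: str
    length: int
    count: int
    comigrates_with: tuple[int, ...] = ()

    @property
    def poorly_resolved(self) -> bool:
        return bool(self.comigrates_with)


def electrophoresis_table(amplicons: list[Amplicon], *, comigration_threshold: int = 25) -> list[Band]:
    """Group amplicons into size-sorted bands, flagging near-equal sizes.

    Two bands from the same template closer than ``comigration_threshold``
    base pairs are flagged as a poorly resolved pair (they would appear as
    one band on a standard agarose gel).
    """
    by_template: dict[str, dict[int, int]] = defaultdict(lambda: defaultdict(int))
    for a in amplicons:
        by_template[a.template_id][a.length] += 1
    bands: list[Band] = []
    for template_id in sorted(by_template):
        lengths = sorted(by_template[template_id])
        for ln in lengths:
            near = tuple(
                other for other in lengths if other != ln and abs(other - ln) < comigration_threshold
            )
            bands.append(
                Band(
                    template_id=template_id,
                    length=ln,
                    count=by_template[template_id][ln],
                    comigrates_with=near,
                )
            )
    return bands
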