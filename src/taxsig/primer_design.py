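"""Design of the labeled triplex panel for allele-specific duplex PCR.

The panel holds three 5'-labeled oligos:

* a *specific forward* primer whose 3'-terminal base sits exactly on the
  diagnostic signature allele (ARMS principle: a 3' mismatch blocks
  extension, so only the target taxon amplifies),
* a *control forward* primer on a footprint conserved across every record
  (target and background), upstream of the specific primer, and
* a *shared reverse* primer on a conserved footprint downstream.

Because both forwards pair with the same reverse, the two products differ
in length by exactly the offset between the forward starts — the property
that lets one strip distinguish "PCR worked" from "target present".

Melting temperatures use the unified nearest-neighbor parameter set
(SantaLucia & Hicks 2004, as distributed with Biopython's
``MeltingTemp.DNA_NN3`` table) with monovalent + magnesium salt correction.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from Bio.SeqUtils import MeltingTemp as _mt
from Bio.SeqUtils import gc_fraction as _gc_fraction

from .errors import PanelAssemblyError, ValidationError
from .seqio import UNAMBIGUOUS, Alignment, TaxonPartition, reverse_complement
from .signature import SignatureSite


class Label(str, Enum):
    """5' hapten/label attached to a primer."""

    FAM = "FAM"
    DIG = "DIG"
    BIOTIN = "biotin"
    NONE = "none"


@dataclass(frozen=True)
class TmConditions:
    """Solution conditions for the nearest-neighbor Tm model.

    Defaults mirror a standard hot-start Taq mix: ~50 mM monovalent
    cation, 3 mM Mg2+ and 250 nM of each primer.
    """

    na_mM: float = 50.0
    mg_mM: float = 3.0
    primer_nM: float = 250.0


DEFAULT_TM_CONDITIONS = TmConditions()


def tm(residues: str, conditions: TmConditions | None = None) -> float:
    """Nearest-neighbor melting temperature in degrees Celsius.

    Uses the unified NN table (DNA_NN3); salt correction is
    Owczarzy et al. 2008 when Mg2+ is present, SantaLucia 1998
    (0.368·(N−1)·ln[Mon+] on the entropy) otherwise.
    """
    c = conditions or DEFAULT_TM_CONDITIONS
    residues = residues.upper()
    if len(residues) < 8:
        raise ValidationError(f"Tm model needs length >= 8, got {len(residues)}")
    if any(b not in UNAMBIGUOUS for b in residues):
        raise ValidationError("Tm model accepts unambiguous DNA only")
    return float(
        _mt.Tm_NN(
            residues,
            nn_table=_mt.DNA_NN3,
            Na=c.na_mM,
            Mg=c.mg_mM,
            dnac1=c.primer_nM,
            dnac2=0,
            saltcorr=7 if c.mg_mM > 0 else 5,
        )
    )


@dataclass(frozen=True)
class PrimerSpec:
    """A labeled oligo with its alignment footprint.

    Coordinates are 1-based inclusive alignment columns of the footprint on
    the plus strand; for ``strand == "reverse"`` the residues are the
    reverse complement of the plus-strand footprint (so ``aln_start <
    aln_end`` always holds).
    """

    name: str
    residues: str
    strand: str
    aln_start: int
    aln_end: int
    label: Label = Label.NONE
    tm_celsius: float | None = None
    gc_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("forward", "reverse"):
            raise ValidationError(f"strand must be forward/reverse, got {self.strand!r}")
        n = len(self.residues)
        if not 15 <= n <= 35:
            raise ValidationError(f"primer {self.name}: length {n} outside [15, 35]")
        if any(b not in UNAMBIGUOUS for b in self.residues):
            raise ValidationError(
                f"primer {self.name}: residues must be unambiguous, gap-free DNA"
            )
        if self.aln_end - self.aln_start + 1 != n:
            raise ValidationError(
                f"primer {self.name}: footprint span {self.aln_start}-{self.aln_end} "
                f"does not match length {n}"
            )
        if self.gc_fraction is None:
            object.__setattr__(self, "gc_fraction", float(_gc_fraction(self.residues)))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def three_prime_base(self) -> str:
        return self.residues[-1]


@dataclass(frozen=True)
class DesignConstraints:
    """Tunable screening thresholds for panel design."""

    length_range: tuple[int, int] = (18, 27)
    tm_range_celsius: tuple[float, float] = (50.0, 65.0)
    gc_range: tuple[float, float] = (0.30, 0.60)
    target_footprint_identity: float = 1.0
    max_dimer_score: int = 8
    product_len_range: tuple[int, int] = (80, 300)
    min_product_len_gap: int = 10

    def __post_init__(self) -> None:
        for name in ("length_range", "tm_range_celsius", "gc_range", "product_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name} is not well-ordered: {lo} > {hi}")
        if not 0 < self.target_footprint_identity <= 1:
            raise ValidationError("target_footprint_identity must be in (0, 1]")
        if self.max_dimer_score < 0 or self.min_product_len_gap < 0:
            raise ValidationError("thresholds must be non-negative")


@dataclass(frozen=True)
class DimerHit:
    """Best cross-hybridization found between two primers.

    ``score`` is the length of the best contiguous complementary run over
    all ungapped antiparallel offsets, doubled when the run reaches either
    primer's 3' terminus (extendable dimers are the dangerous kind).
    """

    score: int
    illustration: str = ""


@dataclass
class DesignResult:
    """Ranked primer candidates plus machine-readable rejection tallies."""

    candidates: list
    rejections: Counter = field(default_factory=Counter)

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)

    def __getitem__(self, i):
        return self.candidates[i]


_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def dimer_score(p, q) -> DimerHit:
    """Exhaustive ungapped antiparallel duplex scan between two primers.

    Accepts :class:`PrimerSpec` or plain residue strings; symmetric in its
    arguments.
    """
    s = getattr(p, "residues", p).upper()
    t = getattr(q, "residues", q).upper()
    n, m = len(s), len(t)
    best = DimerHit(score=0)
    for shift in range(-(m - 1), n):
        lo = max(0, shift)
        hi = min(n, shift + m)
        if hi <= lo:
            continue
        i = lo
        while i < hi:
            # antiparallel pairing: s[i] against t[m - 1 - (i - shift)]
            if _COMP[s[i]] == t[m - 1 - (i - shift)]:
                start = i
                while i < hi and _COMP[s[i]] == t[m - 1 - (i - shift)]:
                    i += 1
                run = i - start
                # t index m-1 (its 3' end) is paired at s-position `shift`
                touches_3p = (i - 1 == n - 1) or (start <= shift <= i - 1)
                score = run * 2 if touches_3p else run
                if score > best.score:
                    best = DimerHit(
                        score=score,
                        illustration=_dimer_illustration(s, t, shift, start, i - 1),
                    )
            else:
                i += 1
    return best


def _dimer_illustration(s: str, t: str, shift: int, run_start: int, run_end: int) -> str:
    rt = t[::-1]  # t written 3'->5' under s
    pad_s = max(0, -shift)
    pad_t = max(0, shift)
    bars = []
    for i in range(len(s)):
        j = i - shift
        paired = 0 <= j < len(t) and _COMP[s[i]] == t[len(t) - 1 - j]
        bars.append("|" if paired and run_start <= i <= run_end else " ")
    line1 = " " * pad_s + f"5'-{s}-3'"
    line2 = " " * (pad_s + 3) + "".join(bars)
    line3 = " " * pad_t + f"3'-{rt}-5'"
    return "\n".join((line1, line2, line3))


def _group_consensus(aln: Alignment, ids: frozenset[str]) -> tuple[list[str | None], list[float]]:
    """Per-column majority unambiguous base and agreement fraction for a group.

    Gaps and ambiguity codes count against agreement; a column with no
    informative base gets consensus ``None`` and identity 0.
    """
    seqs = [aln.get(i).residues for i in sorted(ids)]
    n = len(seqs)
    consensus: list[str | None] = []
    identity: list[float] = []
    for col0 in range(aln.n_columns):
        counts = Counter(s[col0] for s in seqs if s[col0] in UNAMBIGUOUS)
        if not counts:
            consensus.append(None)
            identity.append(0.0)
            continue
        base, cnt = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        consensus.append(base)
        identity.append(cnt / n)
    return consensus, identity


def design_allele_specific_forward(
    aln: Alignment,
    part: TaxonPartition,
    site: SignatureSite,
    c: DesignConstraints | None = None,
    *,
    tm_conditions: TmConditions | None = None,
) -> DesignResult:
    """Enumerate forward primers 3'-anchored on the signature column.

    Every candidate ends exactly at ``site.column`` with the target allele
    as its 3' base; residues are the target-group majority consensus over
    the footprint, and any footprint column whose target identity falls
    below ``target_footprint_identity`` disqualifies that footprint.
    Candidates are ranked deterministically (see module docs).
    """
    c = c or DesignConstraints()
    part.validate_against(aln)
    consensus, identity = _group_consensus(aln, part.target_ids)
    mid_tm = sum(c.tm_range_celsius) / 2

    scored: list[tuple[tuple, PrimerSpec]] = []
    rejections: Counter = Counter()
    for length in range(c.length_range[0], c.length_range[1] + 1):
        aln_start = site.column - length + 1
        if aln_start < 1:
            rejections["outside_alignment"] += 1
            continue
        cols = range(aln_start - 1, site.column)
        if any(consensus[j] is None for j in cols):
            rejections["no_consensus_base"] += 1
            continue
        if any(identity[j] < c.target_footprint_identity for j in cols):
            rejections["footprint_identity"] += 1
            continue
        residues = "".join(consensus[j] for j in cols)  # type: ignore[misc]
        if residues[-1] != site.target_allele:
            rejections["terminal_allele"] += 1
            continue
        t = tm(residues, tm_conditions)
        if not c.tm_range_celsius[0] <= t <= c.tm_range_celsius[1]:
            rejections["tm_range"] += 1
            continue
        gc = _gc_fraction(residues)
        if not c.gc_range[0] <= gc <= c.gc_range[1]:
            rejections["gc_range"] += 1
            continue
        spec = PrimerSpec(
            name=f"sfwd_{aln_start}_{site.column}",
            residues=residues,
            strand="forward",
            aln_start=aln_start,
            aln_end=site.column,
            tm_celsius=round(t, 2),
        )
        mean_ident = sum(identity[j] for j in cols) / length
        score = abs(t - mid_tm) + 50.0 * (1.0 - mean_ident) + dimer_score(spec, spec).score
        scored.append(((score, length, aln_start), spec))

    scored.sort(key=lambda kv: kv[0])
    return DesignResult(candidates=[s for _, s in scored], rejections=rejections)


def design_conserved_pair(
    aln: Alignment,
    part: TaxonPartition,
    specific: PrimerSpec,
    c: DesignConstraints | None = None,
    *,
    tm_conditions: TmConditions | None = None,
) -> DesignResult:
    """Enumerate (control forward, shared reverse) pairs on conserved footprints.

    Both footprints must be conserved across *all* records (target and
    background) at the identity threshold; the control forward lies
    strictly upstream of the specific primer, the reverse strictly
    downstream. Returned reverse primers carry the reverse complement of
    the plus-strand consensus. Pairs are filtered on both product lengths
    and the between-product size gap, then on cross-dimer scores with the
    chosen specific primer.
    """
    c = c or DesignConstraints()
    part.validate_against(aln)
    all_ids = part.target_ids | part.background_ids
    consensus, identity = _group_consensus(aln, all_ids)
    mid_tm = sum(c.tm_range_celsius) / 2

    def window_candidates(start_lo: int, start_hi_of_end: int, forward: bool) -> list[PrimerSpec]:
        out = []
        for length in range(c.length_range[0], c.length_range[1] + 1):
            for aln_start in range(start_lo, start_hi_of_end - length + 2):
                aln_end = aln_start + length - 1
                cols = range(aln_start - 1, aln_end)
                if any(consensus[j] is None for j in cols):
                    continue
                if any(identity[j] < c.target_footprint_identity for j in cols):
                    continue
                plus = "".join(consensus[j] for j in cols)  # type: ignore[misc]
                residues = plus if forward else reverse_complement(plus)
                t = tm(residues, tm_conditions)
                if not c.tm_range_celsius[0] <= t <= c.tm_range_celsius[1]:
                    continue
                gc = _gc_fraction(residues)
                if not c.gc_range[0] <= gc <= c.gc_range[1]:
                    continue
                prefix = "cfwd" if forward else "rev"
                out.append(
                    PrimerSpec(
                        name=f"{prefix}_{aln_start}_{aln_end}",
                        residues=residues,
                        strand="forward" if forward else "reverse",
                        aln_start=aln_start,
                        aln_end=aln_end,
                        tm_celsius=round(t, 2),
                    )
                )
        return out

    controls = window_candidates(1, specific.aln_start - 1, forward=True)
    reverses = window_candidates(specific.aln_end + 1, aln.n_columns, forward=False)
    rejections: Counter = Counter()
    if not controls:
        rejections["no_conserved_control_window"] += 1
    if not reverses:
        rejections["no_conserved_reverse_window"] += 1

    scored: list[tuple[tuple, tuple[PrimerSpec, PrimerSpec]]] = []
    for ctrl in controls:
        for rev in reverses:
            specific_product = rev.aln_end - specific.aln_start + 1
            control_product = rev.aln_end - ctrl.aln_start + 1
            lo, hi = c.product_len_range
            if not (lo <= specific_product <= hi and lo <= control_product <= hi):
                rejections["product_len_range"] += 1
                continue
            if control_product - specific_product < c.min_product_len_gap:
                rejections["product_len_gap"] += 1
                continue
            cross = max(
                dimer_score(ctrl, rev).score,
                dimer_score(ctrl, specific).score,
                dimer_score(rev, specific).score,
            )
            if cross > c.max_dimer_score:
                rejections["dimer_score"] += 1
                continue
            score = (
                abs((ctrl.tm_celsius or 0) - mid_tm)
                + abs((rev.tm_celsius or 0) - mid_tm)
                + cross
            )
            key = (score, len(ctrl) + len(rev), ctrl.aln_start, rev.aln_start)
            scored.append((key, (ctrl, rev)))

    scored.sort(key=lambda kv: kv[0])
    return DesignResult(candidates=[pair for _, pair in scored], rejections=rejections)


@dataclass(frozen=True)
class TriplexPanel:
    """The assembled three-primer panel with its product-size expectations."""

    specific_fwd: PrimerSpec
    control_fwd: PrimerSpec
    shared_rev: PrimerSpec
    signature: SignatureSite
    expected_specific_len: int
    expected_control_len: int

    def __post_init__(self) -> None:
        sp, ct, rv = self.specific_fwd, self.control_fwd, self.shared_rev
        if sp.three_prime_base != self.signature.target_allele:
            raise PanelAssemblyError(
                "specific forward 3' base must equal the signature target allele"
            )
        if sp.aln_end != self.signature.column:
            raise PanelAssemblyError(
                "specific forward must end exactly on the signature column"
            )
        labels = [sp.label, ct.label, rv.label]
        if len(set(labels)) != 3:
            raise PanelAssemblyError("the three primer labels must be pairwise distinct")
        if rv.label != Label.BIOTIN:
            raise PanelAssemblyError("shared reverse primer must carry the biotin label")
        if not (ct.aln_start < sp.aln_start < rv.aln_start):
            raise PanelAssemblyError(
                "footprint order must be control < specific < reverse"
            )
        if self.expected_control_len - self.expected_specific_len != sp.aln_start - ct.aln_start:
            raise PanelAssemblyError(
                "product size difference must equal the forward-start offset"
            )

    @property
    def forward_start_offset(self) -> int:
        return self.specific_fwd.aln_start - self.control_fwd.aln_start

    @property
    def primers(self) -> tuple[PrimerSpec, PrimerSpec, PrimerSpec]:
        return (self.specific_fwd, self.control_fwd, self.shared_rev)


DEFAULT_LABELS = {"specific": Label.DIG, "control": Label.FAM, "reverse": Label.BIOTIN}


def assemble_panel(
    specific: PrimerSpec,
    control: PrimerSpec,
    rev: PrimerSpec,
    site: SignatureSite,
    *,
    labels: dict[str, Label] | None = None,
    expected_specific_len: int | None = None,
    max_dimer_score: int | None = None,
) -> TriplexPanel:
    """Label the three primers and build a validated :class:`TriplexPanel`.

    ``expected_specific_len`` defaults to the inclusive alignment span from
    the specific forward start to the reverse footprint end; pass an
    explicit value when the realized template spacing differs from the
    alignment span. Cross-dimer screening is applied when
    ``max_dimer_score`` is given.
    """
    lab = dict(DEFAULT_LABELS)
    if labels:
        lab.update(labels)
    specific = dataclasses.replace(specific, label=lab["specific"])
    control = dataclasses.replace(control, label=lab["control"])
    rev = dataclasses.replace(rev, label=lab["reverse"])

    if max_dimer_score is not None:
        for a, b in ((specific, control), (specific, rev), (control, rev)):
            hit = dimer_score(a, b)
            if hit.score > max_dimer_score:
                raise PanelAssemblyError(
                    f"cross-dimer score {hit.score} between {a.name} and {b.name} "
                    f"exceeds limit {max_dimer_score}"
                )

    if expected_specific_len is None:
        expected_specific_len = rev.aln_end - specific.aln_start + 1
    expected_control_len = expected_specific_len + (specific.aln_start - control.aln_start)
    return TriplexPanel(
        specific_fwd=specific,
        control_fwd=control,
        shared_rev=rev,
        signature=site,
        expected_specific_len=expected_specific_len,
        expected_control_len=expected_control_len,
    )


# --- the published rbcL panel -------------------------------------------------

#: Sequences and footprints of the published Aristolochia rbcL triplex:
#: A397F is the allele-specific forward (3' T on the diagnostic column 397),
#: C357F the conserved control forward, R502 the shared biotinylated reverse.
A397F_SEQ = "GTTCAAAGCCTTACGAGCTT"
C357F_SEQ = "CATTGTAGGTAATGTATTTG"
R502_SEQ = "GACGACCATACTTGTTCAATTTATC"


def reference_panel(tm_conditions: TmConditions | None = None) -> TriplexPanel:
    """The published rbcL triplex panel (A397F/C357F/R502).

    Product-size expectations are the published 124 bp (specific) and
    145 bp (control); note the printed inclusive coordinate spans imply
    one extra base — see the methods note for the off-by-one discussion.
    """
    site = SignatureSite(
        column=397,
        target_allele="T",
        background_alleles=frozenset({"C", "A"}),
        n_target_informative=9,
        n_background_informative=13,
        n_target_missing=0,
        reference_position=397,
    )
    specific = PrimerSpec(
        name="A397F", residues=A397F_SEQ, strand="forward",
        aln_start=378, aln_end=397, label=Label.DIG,
        tm_celsius=round(tm(A397F_SEQ, tm_conditions), 2),
    )
    control = PrimerSpec(
        name="C357F", residues=C357F_SEQ, strand="forward",
        aln_start=357, aln_end=376, label=Label.FAM,
        tm_celsius=round(tm(C357F_SEQ, tm_conditions), 2),
    )
    rev = PrimerSpec(
        name="R502", residues=R502_SEQ, strand="reverse",
        aln_start=478, aln_end=502, label=Label.BIOTIN,
        tm_celsius=round(tm(R502_SEQ, tm_conditions), 2),
    )
    return TriplexPanel(
        specific_fwd=specific,
        control_fwd=control,
        shared_rev=rev,
        signature=site,
        expected_specific_len=124,
        expected_control_len=145,
    )


# --- serialization -----------------------------------------------------------


def primer_to_dict(p: PrimerSpec) -> dict:
    return {
        "name": p.name,
        "residues": p.residues,
        "strand": p.strand,
        "aln_start": p.aln_start,
        "aln_end": p.aln_end,
        "label": p.label.value,
        "tm_celsius": p.tm_celsius,
        "gc_fraction": round(p.gc_fraction, 4) if p.gc_fraction is not None else None,
    }


def primer_from_dict(d: dict) -> PrimerSpec:
    return PrimerSpec(
        name=d["name"],
        residues=d["residues"],
        strand=d["strand"],
        aln_start=int(d["aln_start"]),
        aln_end=int(d["aln_end"]),
        label=Label(d.get("label", "none")),
        tm_celsius=d.get("tm_celsius"),
        gc_fraction=d.get("gc_fraction"),
    )


def panel_to_dict(panel: TriplexPanel) -> dict:
    s = panel.signature
    return {
        "signature": {
            "column": s.column,
            "target_allele": s.target_allele,
            "background_alleles": sorted(s.background_alleles),
            "n_target_informative": s.n_target_informative,
            "n_background_informative": s.n_background_informative,
            "n_target_missing": s.n_target_missing,
            "reference_position": s.reference_position,
        },
        "specific_fwd": primer_to_dict(panel.specific_fwd),
        "control_fwd": primer_to_dict(panel.control_fwd),
        "shared_rev": primer_to_dict(panel.shared_rev),
        "expected_specific_len": panel.expected_specific_len,
        "expected_control_len": panel.expected_control_len,
    }


def panel_from_dict(d: dict) -> TriplexPanel:
    s = d["signature"]
    site = SignatureSite(
        column=int(s["column"]),
        target_allele=s["target_allele"],
        background_alleles=frozenset(s["background_alleles"]),
        n_target_informative=int(s["n_target_informative"]),
        n_background_informative=int(s["n_background_informative"]),
        n_target_missing=int(s.get("n_target_missing", 0)),
        reference_position=s.get("reference_position"),
    )
    return TriplexPanel(
        specific_fwd=primer_from_dict(d["specific_fwd"]),
        control_fwd=primer_from_dict(d["control_fwd"]),
        shared_rev=primer_from_dict(d["shared_rev"]),
        signature=site,
        expected_specific_len=int(d["expected_specific_len"]),
        expected_control_len=int(d["expected_control_len"]),
    )
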