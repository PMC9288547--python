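"""Lateral-flow strip logic: amplicon label pairs -> line states -> taxon call.

The strip carries three antibody lines read in flow order: T1 (anti-FAM,
internal PCR control), T2 (anti-DIG, taxon line) and C (anti-mouse IgG,
strip control). Dual-labeled amplicons are detectable only when one label
is biotin (captured by the gold-nanoparticle anti-biotin conjugate); the
second label decides which line traps the complex. Calls follow the
rule: all three lines present -> target detected; T1 + C only -> target
absent but PCR worked; C only -> no amplification; no C -> invalid strip.
A faint line counts as present.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .errors import ParseError
from .insilico_pcr import Amplicon
from .primer_design import Label


class LineSignal(str, Enum):
    """Categorical band intensity as read by eye."""

    STRONG = "++"
    FAINT = "+"
    ABSENT = "-"

    @property
    def present(self) -> bool:
        return self is not LineSignal.ABSENT


#: symbols accepted when parsing recorded patterns (unicode dashes included)
_SIGNAL_ALIASES = {
    "++": LineSignal.STRONG,
    "+": LineSignal.FAINT,
    "-": LineSignal.ABSENT,
    "−": LineSignal.ABSENT,  # minus sign
    "–": LineSignal.ABSENT,  # en dash
}


def parse_signal(symbol: str) -> LineSignal:
    try:
        return _SIGNAL_ALIASES[symbol.strip()]
    except KeyError:
        raise ParseError(f"unknown line symbol {symbol!r} (expected ++, + or -)") from None


class Call(str, Enum):
    TARGET_DETECTED = "target_detected"
    TARGET_NOT_DETECTED = "target_not_detected"
    NO_AMPLIFICATION = "no_amplification"
    INVALID_STRIP = "invalid_strip"


@dataclass(frozen=True)
class StripResult:
    """Line states plus the derived call and any anomaly/warning flags."""

    t1: LineSignal
    t2: LineSignal
    c: LineSignal
    call: Call
    flags: tuple[str, ...] = ()


def classify(t1: LineSignal, t2: LineSignal, c: LineSignal) -> StripResult:
    """Total decision rule over the 27 possible line-state triples.

    The T2-without-T1 pattern (taxon line without the internal control)
    is still called positive but flagged as anomalous, since a missing
    internal control with a successful taxon amplicon has no documented
    interpretation.
    """
    flags: tuple[str, ...] = ()
    if not c.present:
        call = Call.INVALID_STRIP
    elif not t1.present and not t2.present:
        call = Call.NO_AMPLIFICATION
    elif t2.present and t1.present:
        call = Call.TARGET_DETECTED
    elif t1.present:
        call = Call.TARGET_NOT_DETECTED
    else:
        call = Call.TARGET_DETECTED
        flags = ("anomalous: taxon line without internal control line",)
    return StripResult(t1=t1, t2=t2, c=c, call=call, flags=flags)


_T1_PAIR = frozenset({Label.FAM, Label.BIOTIN})
_T2_PAIR = frozenset({Label.DIG, Label.BIOTIN})


def predict_strip(amplicons: list[Amplicon]) -> StripResult:
    """Predict the strip read-out for one sample's pooled reaction products.

    A line is strong when supported by a clean amplicon, faint when its
    only support carries binding mismatches, absent otherwise. The strip
    control line is always strong in prediction (it captures unbound
    conjugate regardless of amplification). Amplicons without a biotin
    label cannot be picked up by the conjugate; they are excluded and
    flagged.
    """
    flags: list[str] = []

    def line_state(pair: frozenset) -> LineSignal:
        supporting = [a for a in amplicons if a.label_pair == pair]
        if not supporting:
            return LineSignal.ABSENT
        if all(a.faint for a in supporting):
            return LineSignal.FAINT
        return LineSignal.STRONG

    for a in amplicons:
        if Label.BIOTIN not in a.label_pair:
            flags.append(
                f"amplicon {a.fwd_primer}/{a.rev_primer} on {a.template_id} lacks biotin; "
                "undetectable by the conjugate and excluded"
            )
    t1 = line_state(_T1_PAIR)
    t2 = line_state(_T2_PAIR)
    c = LineSignal.STRONG
    base = classify(t1, t2, c)
    return StripResult(t1=t1, t2=t2, c=c, call=base.call, flags=base.flags + tuple(flags))


@dataclass(frozen=True)
class PatternRow:
    """One recorded strip pattern from a delimited table."""

    sample: str
    t1: LineSignal
    t2: LineSignal
    c: LineSignal
    extra: dict = field(default_factory=dict)


def read_pattern_table(path: str | Path) -> list[PatternRow]:
    """Parse a TSV of recorded line patterns (columns: sample, t1, t2, c).

    Extra columns are preserved in ``extra``; an unknown symbol raises a
    parse error naming the row. An empty file yields an empty list.
    """
    rows: list[PatternRow] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            return rows
        missing = {"sample", "t1", "t2", "c"} - set(reader.fieldnames)
        if missing:
            raise ParseError(f"{path}: missing column(s): {', '.join(sorted(missing))}")
        for lineno, rec in enumerate(reader, start=2):
            try:
                t1, t2, c = (parse_signal(rec[k]) for k in ("t1", "t2", "c"))
            except ParseError as exc:
                raise ParseError(f"{path}: row {lineno} ({rec.get('sample', '?')}): {exc}") from None
            extra = {
                k: v for k, v in rec.items() if k not in ("sample", "t1", "t2", "c") and v is not None
            }
            rows.append(PatternRow(sample=rec["sample"], t1=t1, t2=t2, c=c, extra=extra))
    return rows
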