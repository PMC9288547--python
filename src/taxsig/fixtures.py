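"""Seeded synthetic data emulating the published assay's study materials.

The generator plants a single diagnostic column inside an otherwise
neutral alignment: three protected windows hold the control-forward,
specific-forward and reverse primer footprints (by default the published
rbcL footprints at columns 357-376, 378-397 and 478-502), every record is
identical inside those windows except at the diagnostic column (targets
carry the signature allele, each background record draws C or A), and
independent substitutions at a fixed per-base rate fall everywhere else.
Templates for in-silico PCR are rebuilt from the same footprints with a
spacing that realizes the published product sizes (124 bp specific,
145 bp control).

This emulates the real alignment's structure, not its evolution: no
phylogeny, no indels, no sequencing error, and missing data only where a
test injects it. The recorded 26-sample strip-pattern panel ships as a
packaged TSV.

All generators are pure functions of their seed: the same seed yields
byte-identical FASTA output.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .insilico_pcr import Template
from .lfa_readout import Call, PatternRow, read_pattern_table
from .primer_design import A397F_SEQ, C357F_SEQ, R502_SEQ
from .seqio import Alignment, SequenceRecord, TaxonPartition, reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the synthetic alignment/template generator.

    Defaults reproduce the published assay's geometry: a ~600-column
    alignment with 9 target and 13 background records, diagnostic allele T
    at column 397 (backgrounds carry C or A, drawn evenly), the three
    published primer footprints as conserved windows, a 124 bp specific
    product, and 2% background substitution outside protected columns.
    """

    aln_length: int = 600
    n_target: int = 9
    n_background: int = 13
    diagnostic_column: int = 397
    target_allele: str = "T"
    background_allele_set: tuple[str, ...] = ("C", "A")
    control_window: tuple[int, int] = (357, 376)
    specific_window: tuple[int, int] = (378, 397)
    reverse_window: tuple[int, int] = (478, 502)
    specific_product_len: int = 124
    substitution_rate: float = 0.02
    include_thottea_like: bool = False
    thottea_footprint_mismatches: int = 2
    template_flank: int = 40
    seed: int = 1

    def __post_init__(self) -> None:
        windows = [self.control_window, self.specific_window, self.reverse_window]
        for lo, hi in windows:
            if not (1 <= lo <= hi <= self.aln_length):
                raise ConfigError(f"window {lo}-{hi} outside alignment of {self.aln_length} columns")
        spans = sorted(windows)
        for (_, hi1), (lo2, _) in zip(spans, spans[1:]):
            if hi1 >= lo2:
                raise ConfigError("conserved windows must be disjoint")
        if self.diagnostic_column != self.specific_window[1]:
            raise ConfigError("diagnostic column must be the specific-forward window end")
        if self.target_allele not in "ACGT":
            raise ConfigError("target allele must be one of A/C/G/T")
        if not self.background_allele_set or self.target_allele in self.background_allele_set:
            raise ConfigError("background alleles must be non-empty and exclude the target allele")
        min_len = self._window_len(self.specific_window) + self._window_len(self.reverse_window)
        if self.specific_product_len < min_len:
            raise ConfigError(
                f"specific product ({self.specific_product_len}) shorter than the two "
                f"footprints combined ({min_len})"
            )
        if not 0 <= self.substitution_rate < 1:
            raise ConfigError("substitution rate must be in [0, 1)")
        if self.n_target < 1 or self.n_background < 1:
            raise ConfigError("need at least one target and one background record")
        offset = self.specific_window[0] - self.control_window[0]
        if offset < self._window_len(self.control_window):
            raise ConfigError("control and specific footprints overlap on the template")

    @staticmethod
    def _window_len(w: tuple[int, int]) -> int:
        return w[1] - w[0] + 1

    @property
    def forward_start_offset(self) -> int:
        return self.specific_window[0] - self.control_window[0]

    @property
    def control_product_len(self) -> int:
        return self.specific_product_len + self.forward_start_offset


_DEFAULT_WINDOWS = ((357, 376), (378, 397), (478, 502))


def window_sequences(cfg: FixtureConfig) -> dict[str, str]:
    """Footprint sequences pasted into the conserved windows.

    With the default window geometry and allele these are the published
    primer footprints (the specific window ends with the signature allele;
    the reverse window carries the plus-strand complement of the reverse
    primer). Non-default geometries get seeded random footprints.
    """
    default_geometry = (
        (cfg.control_window, cfg.specific_window, cfg.reverse_window) == _DEFAULT_WINDOWS
        and cfg.target_allele == "T"
    )
    if default_geometry:
        return {
            "control": C357F_SEQ,
            "specific": A397F_SEQ,
            "reverse_plus": reverse_complement(R502_SEQ),
        }
    rng = np.random.default_rng([cfg.seed, 7])
    out = {}
    for key, window in (
        ("control", cfg.control_window),
        ("specific", cfg.specific_window),
        ("reverse_plus", cfg.reverse_window),
    ):
        n = cfg._window_len(window)
        out[key] = "".join(rng.choice(_BASES, size=n))
    out["specific"] = out["specific"][:-1] + cfg.target_allele
    return out


def _thottea_footprint(specific_seq: str, n_mismatches: int) -> str:
    """Plant mismatches near (but not at) the 3' end of the specific footprint."""
    seq = list(specific_seq)
    order = "ACGT"
    # positions 3, 6, 9, ... bases upstream of the 3' terminus
    for k in range(n_mismatches):
        idx = len(seq) - 3 - 3 * k
        if idx < 0:
            raise ConfigError("footprint too short for requested planted mismatches")
        seq[idx] = order[(order.index(seq[idx]) + 1) % 4]
    return "".join(seq)


def _base_and_rng(cfg: FixtureConfig) -> tuple[np.ndarray, np.random.Generator]:
    """Seeded ancestral sequence with footprints pasted into the windows."""
    rng = np.random.default_rng(cfg.seed)
    seqs = window_sequences(cfg)
    base = rng.choice(_BASES, size=cfg.aln_length)
    for key, window in (
        ("control", cfg.control_window),
        ("specific", cfg.specific_window),
        ("reverse_plus", cfg.reverse_window),
    ):
        base[window[0] - 1 : window[1]] = list(seqs[key])
    return base, rng


def generate_fixture_alignment(
    cfg: FixtureConfig | None = None,
) -> tuple[Alignment, TaxonPartition, str]:
    """Build the synthetic alignment, its partition and a gapless reference id.

    All records agree inside the conserved windows except at the
    diagnostic column; substitutions elsewhere are independent draws at
    ``substitution_rate`` per base. The optional Thottea-like background
    record shares the target allele at the diagnostic column but carries
    planted mismatches inside the specific-forward footprint.
    """
    cfg = cfg or FixtureConfig()
    seqs = window_sequences(cfg)
    base, rng = _base_and_rng(cfg)

    protected = np.zeros(cfg.aln_length, dtype=bool)
    for lo, hi in (cfg.control_window, cfg.specific_window, cfg.reverse_window):
        protected[lo - 1 : hi] = True
    diag0 = cfg.diagnostic_column - 1

    def mutate(seq: np.ndarray) -> np.ndarray:
        hit = (rng.random(cfg.aln_length) < cfg.substitution_rate) & ~protected
        for i in np.flatnonzero(hit):
            choices = [b for b in "ACGT" if b != seq[i]]
            seq[i] = choices[rng.integers(0, 3)]
        return seq

    records: list[SequenceRecord] = []
    target_ids, background_ids = [], []
    for i in range(cfg.n_target):
        seq = base.copy()
        seq[diag0] = cfg.target_allele
        rec_id = f"tgt_{i + 1:02d}"
        records.append(SequenceRecord(id=rec_id, residues="".join(mutate(seq)), description="target taxon"))
        target_ids.append(rec_id)
    for i in range(cfg.n_background):
        seq = base.copy()
        seq[diag0] = rng.choice(np.array(cfg.background_allele_set))
        rec_id = f"bg_{i + 1:02d}"
        records.append(SequenceRecord(id=rec_id, residues="".join(mutate(seq)), description="background taxon"))
        background_ids.append(rec_id)
    if cfg.include_thottea_like:
        seq = base.copy()
        fp = _thottea_footprint(seqs["specific"], cfg.thottea_footprint_mismatches)
        seq[cfg.specific_window[0] - 1 : cfg.specific_window[1]] = list(fp)
        seq[diag0] = cfg.target_allele
        records.append(
            SequenceRecord(
                id="thottea_like",
                residues="".join(mutate(seq)),
                description="background taxon sharing the signature allele",
            )
        )
        background_ids.append("thottea_like")

    aln = Alignment(records=tuple(records))
    part = TaxonPartition(target_ids=frozenset(target_ids), background_ids=frozenset(background_ids))
    return aln, part, target_ids[0]


@dataclass(frozen=True)
class SampleClass:
    """One simulated reaction: a named mixture of template kinds.

    ``members`` entries are ``"target"``, ``"background"`` or
    ``"thottea"``; a mixture emits one template per member, all sharing
    the class name as origin tag.
    """

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ConfigError(f"sample class {self.name!r} has no members")
        bad = set(self.members) - {"target", "background", "thottea"}
        if bad:
            raise ConfigError(f"unknown member kind(s) {sorted(bad)} in class {self.name!r}")

    @property
    def contains_target(self) -> bool:
        return "target" in self.members

    @property
    def expected_call(self) -> Call:
        return Call.TARGET_DETECTED if self.contains_target else Call.TARGET_NOT_DETECTED


def default_sample_classes() -> list[SampleClass]:
    """The physical validation panel: authentic singles, crude drugs, formulae.

    Nine authentic target plants, four authentic substitutes, eight
    single-ingredient crude drugs of which the fifth contains no target
    taxon, one target-free six-herb laboratory formula (F0) and four
    commercial formulae of which F3 is target-free.
    """
    classes: list[SampleClass] = []
    targets = [
        "A_pierrei", "A_pothieri", "A_acuminata", "A_gigantea", "A_grandiflora",
        "A_cambodiana", "A_littoralis", "A_ringens", "A_tentaculata",
    ]
    classes += [SampleClass(name, ("target",)) for name in targets]
    nontargets = ["C_pulchellum", "T_scabra", "J_sambac", "J_adenophyllum"]
    classes += [SampleClass(name, ("background",)) for name in nontargets]
    for i in range(1, 9):
        kind = "background" if i == 5 else "target"
        classes.append(SampleClass(f"C{i}", (kind,)))
    classes.append(SampleClass("F0_YMVT", ("background",) * 6))
    classes.append(SampleClass("F1", ("target",) + ("background",) * 5))
    classes.append(SampleClass("F2", ("target", "background", "background")))
    classes.append(SampleClass("F3", ("background",) * 4))
    classes.append(SampleClass("F4", ("target", "background", "background", "background")))
    return classes


def generate_templates(
    cfg: FixtureConfig | None = None, classes: list[SampleClass] | None = None
) -> list[Template]:
    """Build ungapped PCR templates realizing the configured product sizes.

    Each template carries the control footprint, the specific footprint
    (3'-terminal base set by the member kind) and the reverse footprint,
    spaced so the specific product is exactly ``specific_product_len`` and
    the control product exceeds it by the forward-start offset. Flanks and
    the control-to-specific spacer copy the fixture's ancestral sequence,
    so footprints that extend slightly past a designated window still
    match; the specific-to-reverse segment is the ancestral segment when
    the configured product size equals the alignment span, and seeded
    random filler of the required length otherwise (the published sizes
    are one base short of the printed coordinate span).
    """
    cfg = cfg or FixtureConfig()
    classes = classes if classes is not None else default_sample_classes()
    seqs = window_sequences(cfg)
    base, _ = _base_and_rng(cfg)
    basestr = "".join(base)
    rng = np.random.default_rng([cfg.seed, 101])

    ctrl_lo, ctrl_hi = cfg.control_window
    spec_lo, spec_hi = cfg.specific_window
    rev_lo, rev_hi = cfg.reverse_window
    spacer = basestr[ctrl_hi : spec_lo - 1]  # ancestral control->specific gap
    gap_len = (
        cfg.specific_product_len
        - cfg._window_len(cfg.specific_window)
        - cfg._window_len(cfg.reverse_window)
    )
    natural_gap = basestr[spec_hi : rev_lo - 1]
    flank5 = basestr[max(0, ctrl_lo - 1 - cfg.template_flank) : ctrl_lo - 1]
    flank3 = basestr[rev_hi : rev_hi + cfg.template_flank]

    templates: list[Template] = []
    for cls in classes:
        for i, kind in enumerate(cls.members, start=1):
            if kind == "target":
                footprint = seqs["specific"]
            elif kind == "background":
                allele = str(rng.choice(np.array(cfg.background_allele_set)))
                footprint = seqs["specific"][:-1] + allele
            else:  # thottea-like: signature allele present, footprint degenerate
                footprint = _thottea_footprint(seqs["specific"], cfg.thottea_footprint_mismatches)
            if gap_len == len(natural_gap):
                gap = natural_gap
            else:
                gap = "".join(rng.choice(_BASES, size=gap_len)) if gap_len else ""
            parts = [
                flank5,
                seqs["control"],
                spacer,
                footprint,
                gap,
                seqs["reverse_plus"],
                flank3,
            ]
            templates.append(
                Template(
                    id=f"{cls.name}.{i}.{kind}",
                    residues="".join(parts),
                    origin_tag=cls.name,
                )
            )
    return templates


def reference_pattern_path() -> Path:
    """Path of the packaged 26-row recorded strip-pattern panel."""
    return Path(str(files("taxsig").joinpath("data/reference_strip_patterns.tsv")))


def reference_pattern_rows() -> list[PatternRow]:
    """The packaged recorded patterns, parsed (26 rows; ``extra`` holds
    the sample group and the reported call)."""
    return read_pattern_table(reference_pattern_path())


def fixture_config_to_dict(cfg: FixtureConfig) -> dict:
    return {
        "aln_length": cfg.aln_length,
        "n_target": cfg.n_target,
        "n_background": cfg.n_background,
        "diagnostic_column": cfg.diagnostic_column,
        "target_allele": cfg.target_allele,
        "background_allele_set": list(cfg.background_allele_set),
        "control_window": list(cfg.control_window),
        "specific_window": list(cfg.specific_window),
        "reverse_window": list(cfg.reverse_window),
        "specific_product_len": cfg.specific_product_len,
        "substitution_rate": cfg.substitution_rate,
        "include_thottea_like": cfg.include_thottea_like,
        "thottea_footprint_mismatches": cfg.thottea_footprint_mismatches,
        "template_flank": cfg.template_flank,
        "seed": cfg.seed,
    }


def fixture_config_from_dict(d: dict) -> FixtureConfig:
    kwargs = dict(d)
    for key in ("background_allele_set", "control_window", "specific_window", "reverse_window"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return FixtureConfig(**kwargs)
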