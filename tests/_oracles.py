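"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from the problem statement, not
from the package internals: a per-column set-comparison scan for signature
sites, a hand summation over the unified nearest-neighbor table for Tm,
a padded-string duplex scan for dimer scores, and a direct re-verification
of predicted amplicons against their template.
"""

from __future__ import annotations

import math

import numpy as np

from taxsig import Alignment, SequenceRecord, TaxonPartition
from taxsig.seqio import IUPAC_EXPANSION

UNAMB = "ACGT"


def naive_signature_scan(aln, part, params):
    """Per-column set comparison: returns [(column, allele), ...]."""
    t_seqs = [aln.get(i).residues for i in sorted(part.target_ids)]
    b_seqs = [aln.get(i).residues for i in sorted(part.background_ids)]
    hits = []
    for col in range(1, aln.n_columns + 1):
        tsyms = [s[col - 1] for s in t_seqs]
        bsyms = [s[col - 1] for s in b_seqs]
        b_nongap = [x for x in bsyms if x != "-"]
        b_unamb = [x for x in b_nongap if x in UNAMB]
        if len(b_unamb) < 1 or len(b_unamb) / len(b_seqs) < params.min_background_fraction:
            continue
        for allele in UNAMB:
            agree = sum(1 for x in tsyms if x == allele)
            if agree == 0 or agree / len(t_seqs) < params.min_target_fraction:
                continue
            if params.treat_ambiguity_as_match:
                conflict = any(allele in IUPAC_EXPANSION[x] for x in b_nongap)
            else:
                conflict = any(x == allele for x in b_unamb)
            if not conflict:
                hits.append((col, allele))
    return hits


# unified nearest-neighbor parameters (kcal/mol, cal/mol/K), duplicated over
# both reading directions so lookup is by plain dinucleotide
_NN = {
    "AA": (-7.6, -21.3), "TT": (-7.6, -21.3),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT = (0.2, -5.7)
_TERMINAL_AT = (2.2, 6.9)


def nn_tm_oracle(seq: str, *, na_mM: float = 50.0, primer_nM: float = 250.0) -> float:
    """Hand summation of the unified NN table with monovalent salt correction."""
    dh, ds = _INIT
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    for end in (seq[0], seq[-1]):
        if end in "AT":
            dh += _TERMINAL_AT[0]
            ds += _TERMINAL_AT[1]
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    r = 1.987
    k = primer_nM * 1e-9
    return 1000.0 * dh / (ds + r * math.log(k)) - 273.15


_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


def brute_force_dimer(s: str, t: str) -> int:
    """Best weighted complementary run over all antiparallel offsets."""
    n, m = len(s), len(t)
    best = 0
    for shift in range(-(m - 1), n):
        cells = [
            (i, m - 1 - (i - shift))
            for i in range(n)
            if 0 <= m - 1 - (i - shift) < m
        ]
        current: list[tuple[int, int]] = []
        for pos, (i, j) in enumerate(cells):
            if _WC[s[i]] == t[j]:
                current.append((i, j))
            if current and (pos == len(cells) - 1 or _WC[s[i]] != t[j]):
                touches = any(ci == n - 1 or cj == m - 1 for ci, cj in current)
                best = max(best, len(current) * (2 if touches else 1))
                current = []
    return best


def amplicon_reverifies(amp, panel, template, model) -> bool:
    """Directly re-check an amplicon's two primers against the template."""
    from taxsig.seqio import bases_compatible, reverse_complement

    primers = {p.name: p for p in panel.primers}
    fwd = primers[amp.fwd_primer]
    rev = primers[amp.rev_primer]
    seq = template.residues

    fseg = seq[amp.start - 1 : amp.start - 1 + len(fwd.residues)]
    rseg = seq[amp.end - len(rev.residues) : amp.end]
    if len(fseg) != len(fwd.residues) or len(rseg) != len(rev.residues):
        return False

    def check(probe: str, seg: str, terminal_at_end: bool) -> bool:
        k = model.three_prime_window
        idx = range(len(probe) - k, len(probe)) if terminal_at_end else range(k)
        mm = 0
        for i, (p, w) in enumerate(zip(probe, seg)):
            ok = bases_compatible(p, w)
            if i in idx and not ok:
                return False
            if i not in idx and not ok:
                mm += 1
        return mm <= model.max_internal_mismatches

    return check(fwd.residues, fseg, True) and check(
        reverse_complement(rev.residues), rseg, False
    )


def random_alignment(rng: np.random.Generator, *, max_records: int = 30, max_columns: int = 200):
    """Seeded random gapped IUPAC alignment plus a partition."""
    n_target = int(rng.integers(1, max(2, max_records // 2)))
    n_background = int(rng.integers(1, max_records - n_target + 1))
    n_cols = int(rng.integers(5, max_columns + 1))
    symbols = np.array(list("ACGTACGTACGTNRY-"))
    records = []
    for idx in range(n_target + n_background):
        residues = "".join(rng.choice(symbols, size=n_cols))
        records.append(SequenceRecord(id=f"r{idx:02d}", residues=residues))
    aln = Alignment(records=tuple(records))
    part = TaxonPartition(
        target_ids=frozenset(r.id for r in records[:n_target]),
        background_ids=frozenset(r.id for r in records[n_target:]),
    )
    return aln, part
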