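"""IUPAC-aware degenerate-primer matching and amplicon extraction.

Degenerate primers are compared to template windows position by position
under set-intersection semantics: a primer letter matches a template letter
when their IUPAC nucleotide sets share at least one base (so a template
``N`` matches anything, and primer ``Y`` matches template ``C``, ``T`` or
``Y``).  Primer-site search scans both strands and reports coordinates on
the stored (sense) sequence, 0-based half-open.  An amplicon spans from the
start of a forward site to the end of a downstream reverse-complemented
reverse-primer site, primer regions included — the span a PCR product would
cover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import TYPE_CHECKING, Iterable

import numpy as np
from Bio.Seq import Seq

if TYPE_CHECKING:  # pragma: no cover
    from .reference_db import ReferenceRecord

__all__ = [
    "IUPAC_SETS",
    "PrimerSet",
    "PrimerSite",
    "Amplicon",
    "iupac_sets",
    "is_valid_iupac",
    "revcomp",
    "expand_degenerate",
    "mismatch_count",
    "find_primer_sites",
    "extract_amplicons",
    "TABLE1_18SV4",
    "TABLE1_18SV1V2",
    "TABLE1_BLOCKING_18SV4",
]

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# 4-bit encoding (A=1, C=2, G=4, T=8); two codes are compatible iff the
# bitwise AND of their masks is non-zero.  Used for the vectorised scan.
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_BITS = {
    code: sum(_BASE_BITS[b] for b in bases) for code, bases in IUPAC_SETS.items()
}
_BITS_LUT = np.zeros(256, dtype=np.uint8)
for _c, _b in _CODE_BITS.items():
    _BITS_LUT[ord(_c)] = _b

# Primer sequences for the oyster 18S system: the eukaryote-universal V4
# pair with its Crassostrea-targeted blocking primer, and the non-metazoan
# V1V2 excluding pair.
TABLE1_18SV4_FORWARD = "CCAGCASCYGCGGTAATTCC"
TABLE1_18SV4_REVERSE = "ACTTTCGTTCTTGATYRA"
TABLE1_BLOCKING_18SV4 = "TCTTGACTAATGAAAACATGCTTGG"
TABLE1_18SV1V2_FORWARD = "ACCTGGTTGATCCTGCCAGT"
TABLE1_18SV1V2_REVERSE = "ARKCCWMTAYMYTACC"


def iupac_sets(code: str) -> frozenset[str]:
    """Return the set of concrete bases denoted by one IUPAC code.

    >>> sorted(iupac_sets("Y"))
    ['C', 'T']
    """
    try:
        return IUPAC_SETS[code.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC nucleotide code: {code!r}") from None


def is_valid_iupac(seq: str) -> bool:
    """True if every character of *seq* is an IUPAC nucleotide code."""
    return all(c in IUPAC_SETS for c in seq.upper())


def _validate(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    for c in seq:
        if c not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC character {c!r} in {what}")
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC string (Y<->R, S<->S, W<->W, K<->M)."""
    seq = _validate(seq)
    return str(Seq(seq).reverse_complement())


def expand_degenerate(seq: str, limit: int = 512) -> list[str]:
    """All concrete ACGT expansions of a degenerate sequence.

    Raises :class:`ValueError` when the expansion would exceed *limit*
    sequences (guards against pathological all-N inputs).
    """
    seq = _validate(seq)
    n = 1
    for c in seq:
        n *= len(IUPAC_SETS[c])
    if n > limit:
        raise ValueError(f"{n} expansions exceed limit {limit}")
    return ["".join(p) for p in product(*(sorted(IUPAC_SETS[c]) for c in seq))]


def mismatch_count(primer: str, window: str) -> int:
    """Number of positions where the primer and window IUPAC sets are disjoint.

    >>> mismatch_count("ACYT", "ACTT")
    0
    >>> mismatch_count("TCTTGATYRA", "TCTTGACTAA")
    1
    """
    if len(primer) != len(window):
        raise ValueError(
            f"length mismatch: primer {len(primer)} vs window {len(window)}"
        )
    p = _validate(primer, "primer")
    w = _validate(window, "window")
    return sum(
        1 for a, b in zip(p, w) if not (IUPAC_SETS[a] & IUPAC_SETS[b])
    )


@dataclass(frozen=True)
class PrimerSet:
    """A named forward/reverse degenerate primer pair.

    ``max_mismatch`` is the default per-primer mismatch allowance used when
    a search does not specify one; the host system's universal V4 pair uses
    1 because known oyster sequences differ from the reverse primer at a
    single position.
    """

    name: str
    forward: str
    reverse: str
    max_mismatch: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward", _validate(self.forward, "forward primer"))
        object.__setattr__(self, "reverse", _validate(self.reverse, "reverse primer"))
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 10:
                raise ValueError(f"{label} primer shorter than 10 nt: {p!r}")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be non-negative")
        shortest = min(len(self.forward), len(self.reverse))
        if self.max_mismatch > shortest // 4:
            raise ValueError(
                f"max_mismatch {self.max_mismatch} exceeds primer length / 4"
            )


TABLE1_18SV4 = PrimerSet(
    "18SV4", TABLE1_18SV4_FORWARD, TABLE1_18SV4_REVERSE, max_mismatch=1
)
TABLE1_18SV1V2 = PrimerSet(
    "18SV1V2", TABLE1_18SV1V2_FORWARD, TABLE1_18SV1V2_REVERSE, max_mismatch=1
)


@dataclass(frozen=True)
class PrimerSite:
    """One primer match on a stored sequence.

    Coordinates are 0-based half-open on the sense strand; ``strand`` is
    '+' when the primer matches the stored sequence as written and '-' when
    it matches the reverse complement.
    """

    record_id: str
    strand: str
    start: int
    end: int
    mismatches: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product, primer regions included.

    ``sense_sequence`` is always the stored-strand substring
    ``record.sequence[start:end]``; ``antisense`` is True when the entry is
    deposited in the opposite orientation (forward primer on '-'), in which
    case the biological product reads as the reverse complement.
    """

    record_id: str
    start: int
    end: int
    sense_sequence: str
    forward_site: PrimerSite
    reverse_site: PrimerSite
    primary: bool = True
    antisense: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def _bits(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    bits = _BITS_LUT[arr]
    if (bits == 0).any():
        bad = seq[int(np.argmax(bits == 0))]
        raise ValueError(f"invalid IUPAC character {bad!r}")
    return bits


def _scan_one_strand(seq_bits: np.ndarray, primer_bits: np.ndarray, max_mm: int):
    """Yield (start, mismatches) for windows matching with <= max_mm."""
    k = len(primer_bits)
    n = len(seq_bits)
    if k > n:
        return
    windows = np.lib.stride_tricks.sliding_window_view(seq_bits, k)
    mm = np.count_nonzero((windows & primer_bits) == 0, axis=1)
    for i in np.flatnonzero(mm <= max_mm):
        yield int(i), int(mm[i])


def find_primer_sites(
    record: "ReferenceRecord | str",
    primer: str,
    max_mismatch: int = 0,
    record_id: str | None = None,
) -> list[PrimerSite]:
    """Locate every match of *primer* on either strand of a sequence.

    Accepts a :class:`~hostblock.reference_db.ReferenceRecord` or a plain
    string.  A '-' site means the primer matches the reverse complement
    there; coordinates always refer to the stored sequence.  Results are
    sorted by start, '+' before '-' at equal start.
    """
    if isinstance(record, str):
        seq = record.upper()
        rid = record_id or ""
    else:
        seq = record.sequence
        rid = record.id
    primer = _validate(primer, "primer")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be non-negative")
    seq_bits = _bits(seq)
    k = len(primer)
    sites: list[PrimerSite] = []
    for strand, p in (("+", primer), ("-", revcomp(primer))):
        pb = _bits(p)
        for start, mm in _scan_one_strand(seq_bits, pb, max_mismatch):
            sites.append(PrimerSite(rid, strand, start, start + k, mm))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def extract_amplicons(
    record: "ReferenceRecord",
    primer_set: PrimerSet,
    max_mismatch: int | None = None,
) -> list[Amplicon]:
    """Predicted products of *primer_set* on one record.

    Pairs every forward '+' site with every downstream reverse '-' site
    (the reverse primer annealing to the sense strand), and symmetrically
    every reverse '+' site with a downstream forward '-' site for entries
    deposited antisense.  All pairings are emitted; the shortest product is
    flagged ``primary`` so multi-site records are never silently collapsed.
    """
    if max_mismatch is None:
        max_mismatch = primer_set.max_mismatch
    fwd_sites = find_primer_sites(record, primer_set.forward, max_mismatch)
    rev_sites = find_primer_sites(record, primer_set.reverse, max_mismatch)
    pairs: list[tuple[PrimerSite, PrimerSite, bool]] = [
        (f, r, False)
        for f in fwd_sites
        if f.strand == "+"
        for r in rev_sites
        if r.strand == "-" and f.start < r.start
    ]
    pairs += [
        (f, r, True)
        for f in fwd_sites
        if f.strand == "-"
        for r in rev_sites
        if r.strand == "+" and r.start < f.start
    ]
    if not pairs:
        return []
    shortest = min(max(f.end, r.end) - min(f.start, r.start) for f, r, _ in pairs)
    out = []
    for f, r, anti in sorted(pairs, key=lambda fr: (min(fr[0].start, fr[1].start), max(fr[0].end, fr[1].end))):
        start = min(f.start, r.start)
        end = max(f.end, r.end)
        out.append(
            Amplicon(
                record_id=record.id,
                start=start,
                end=end,
                sense_sequence=record.sequence[start:end],
                forward_site=f,
                reverse_site=r,
                primary=(end - start == shortest),
                antisense=anti,
            )
        )
    return out
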