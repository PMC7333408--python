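"""Design of annealing-inhibiting blocking primers from host amplicons.

A blocking primer is a 3'-non-extendable oligo (Spacer C3) that anneals
over a host-specific region at the 3' end of the host amplicon, overlapping
the universal reverse primer's binding site, so that host templates are not
elongated while non-host templates amplify normally.

The design procedure mirrors the published strategy for the oyster 18S-V4
system: take the 3'-terminal window (default 40 nt) of every host amplicon,
stack the windows right-anchored at the reverse-primer site into an IUPAC
consensus, enumerate reverse-complement candidates whose 5' ends sit a
fixed number of bases (default 10) inside the reverse-primer site, keep
those shorter than 30 nt with a melting temperature close to the primer
pair, and rank them by in-silico specificity against the amplifiable
target and off-target pools.
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from .insilico_pcr import (
    IUPAC_SETS,
    Amplicon,
    PrimerSet,
    expand_degenerate,
    extract_amplicons,
    find_primer_sites,
    mismatch_count,
    revcomp,
)
from .reference_db import ReferenceRecord

__all__ = [
    "DesignConstraints",
    "BlockingPrimer",
    "CandidateScore",
    "DesignResult",
    "extract_host_window",
    "window_consensus",
    "melting_temperature",
    "primer_pair_mean_tm",
    "enumerate_candidates",
    "overlap_length",
    "score_candidate",
    "select_best",
    "run_design",
]

# Nearest-neighbor Tm conditions (documented, fixed): SantaLucia & Hicks
# (2004) unified parameter set, 50 mM monovalent salt, 250 nM oligo in
# excess, entropic salt correction.
TM_CONDITIONS = {
    "nn_table": _mt.DNA_NN4,
    "Na": 50.0,
    "dnac1": 250.0,
    "dnac2": 0.0,
    "saltcorr": 5,
}

_SET_TO_CODE = {bases: code for code, bases in IUPAC_SETS.items()}


@dataclass(frozen=True)
class DesignConstraints:
    """Tunable design thresholds.

    window_len
        3'-terminal amplicon window stacked into the host consensus (nt).
    min_len, max_len
        candidate length bounds; max_len 29 keeps candidates under 30 nt.
    overlap_len
        bases of the reverse-primer binding site covered by the candidate's
        5' end (exactly, by default).
    tm_tolerance
        allowed |Tm(candidate) - mean Tm(primer pair)| in deg C.
    block_max_mismatch
        mismatches tolerated when deciding that a candidate blocks a record
        (0 = exact IUPAC-compatible site required).
    """

    window_len: int = 40
    min_len: int = 18
    max_len: int = 29
    overlap_len: int = 10
    tm_tolerance: float = 3.0
    block_max_mismatch: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("require 0 < min_len <= max_len")
        if self.window_len < self.max_len:
            raise ValueError("window_len must be >= max_len")
        if not 0 < self.overlap_len < self.min_len:
            raise ValueError("require 0 < overlap_len < min_len")
        if self.tm_tolerance < 0 or self.block_max_mismatch < 0:
            raise ValueError("tolerances must be non-negative")


@dataclass(frozen=True)
class BlockingPrimer:
    """A candidate or final blocking oligo.

    Oriented like the reverse primer (anneals to the amplicon sense
    strand); ``spacer_3prime`` records the chemical 3' modification, which
    has no computational effect here.
    """

    sequence: str
    overlap_len: int
    tm: float
    tm_delta: float = 0.0
    within_tm_tolerance: bool = True
    spacer_3prime: bool = True

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CandidateScore:
    target_blocked_fraction: float
    offtarget_blocked_fraction: float
    tm_delta: float

    def __post_init__(self) -> None:
        for f in (self.target_blocked_fraction, self.offtarget_blocked_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("blocked fractions must lie in [0, 1]")


def extract_host_window(
    amplicon: Amplicon, reverse_primer: str, window_len: int = 40
) -> str:
    """The 3'-terminal *window_len* bases of the amplicon sense sequence.

    The extreme 3' end of this window is the reverse-primer binding region;
    the remainder is amplicon-interior (host-specific) sequence.
    """
    if window_len < len(reverse_primer):
        raise ValueError("window_len shorter than the reverse primer")
    seq = amplicon.sense_sequence
    if len(seq) < window_len:
        raise ValueError(
            f"amplicon {amplicon.record_id!r} length {len(seq)} < window {window_len}"
        )
    return seq[-window_len:]


def window_consensus(windows: Sequence[str]) -> str:
    """Per-column IUPAC consensus covering every base observed.

    Windows must be equal length and right-anchored at the reverse-primer
    site so homologous columns line up.
    """
    if not windows:
        raise ValueError("need at least one window")
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ValueError(
            "windows have unequal lengths; right-anchor them at the "
            "reverse-primer site before stacking"
        )
    cols = []
    for i in range(lengths.pop()):
        bases: set[str] = set()
        for w in windows:
            bases |= IUPAC_SETS[w[i].upper()]
        cols.append(_SET_TO_CODE[frozenset(bases)])
    return "".join(cols)


def modal_window(windows: Sequence[str]) -> str:
    """Per-column most frequent concrete base (ambiguity codes split their
    weight; ties broken alphabetically).  Used to give degenerate candidate
    positions a concrete base for Tm evaluation."""
    if not windows:
        raise ValueError("need at least one window")
    out = []
    for i in range(len(windows[0])):
        votes: Counter[str] = Counter()
        for w in windows:
            s = IUPAC_SETS[w[i].upper()]
            for b in s:
                votes[b] += 1.0 / len(s)
        best = max(sorted(votes), key=lambda b: votes[b])
        out.append(best)
    return "".join(out)


def melting_temperature(seq: str) -> float:
    """Nearest-neighbor duplex melting temperature in deg C.

    Requires a concrete (non-degenerate) sequence of at least 8 nt; the
    two-state NN model is unreliable below that.
    """
    seq = seq.upper()
    if len(seq) < 8:
        raise ValueError("sequence shorter than 8 nt: NN Tm unreliable")
    if any(c not in "ACGT" for c in seq):
        raise ValueError(
            "degenerate sequence: evaluate Tm on a concrete expansion "
            "(e.g. the modal host expansion)"
        )
    return float(_mt.Tm_NN(seq, **TM_CONDITIONS))


def primer_pair_mean_tm(primer_set: PrimerSet, limit: int = 64) -> float:
    """Mean Tm of the pair, averaging each primer over its degenerate
    expansions (sampled pairs of a metabarcoding primer expand to only a
    handful of concrete oligos)."""

    def one(p: str) -> float:
        return statistics.fmean(
            melting_temperature(e) for e in expand_degenerate(p, limit=limit)
        )

    return (one(primer_set.forward) + one(primer_set.reverse)) / 2.0


def enumerate_candidates(
    host_window: str,
    reverse_primer: str,
    constraints: DesignConstraints = DesignConstraints(),
    pair_tm: float | None = None,
    windows: Sequence[str] | None = None,
) -> list[BlockingPrimer]:
    """Enumerate blocking-primer candidates from a host 3' window.

    The window's 3' end is the reverse-primer binding region.  Each
    candidate is the reverse complement of a window substring whose 3'
    (rightmost, sense coordinates) end lies exactly ``overlap_len`` bases
    inside the reverse-primer site, so the candidate's 5' end covers
    ``overlap_len`` bases of the primer site and the rest extends into
    host-specific sequence.  One candidate per length in
    [min_len, max_len] that fits in the window.

    Candidates whose Tm is outside ``tm_tolerance`` of *pair_tm* are
    reported with ``within_tm_tolerance=False`` rather than dropped.
    Degenerate consensus positions keep their IUPAC code in the candidate
    sequence; Tm is evaluated on the modal concrete expansion (from
    *windows* when given, else the alphabetically first base per code).
    """
    host_window = host_window.upper()
    rev_len = len(reverse_primer)
    if len(host_window) < rev_len:
        raise ValueError("host window shorter than the reverse primer")
    # sense coordinate one past the candidate's annealing region
    anchor = len(host_window) - rev_len + constraints.overlap_len
    concrete = (
        modal_window(windows)
        if windows
        else modal_window([host_window])
    )
    out: list[BlockingPrimer] = []
    for length in range(constraints.min_len, constraints.max_len + 1):
        start = anchor - length
        if start < 0:
            continue
        cand = revcomp(host_window[start:anchor])
        tm = melting_temperature(revcomp(concrete[start:anchor]))
        delta = 0.0 if pair_tm is None else tm - pair_tm
        out.append(
            BlockingPrimer(
                sequence=cand,
                overlap_len=constraints.overlap_len,
                tm=tm,
                tm_delta=delta,
                within_tm_tolerance=(
                    pair_tm is None or abs(delta) <= constraints.tm_tolerance
                ),
            )
        )
    return out


def overlap_length(blocking: str, reverse_primer: str, max_mismatch: int = 1) -> int:
    """Largest k such that the blocking primer's first k bases match the
    reverse primer's k-base 3' suffix with at most *max_mismatch* IUPAC
    mismatches; 0 when no prefix/suffix pair qualifies."""
    if not blocking or not reverse_primer:
        raise ValueError("both sequences must be non-empty")
    for k in range(min(len(blocking), len(reverse_primer)), 0, -1):
        if mismatch_count(blocking[:k], reverse_primer[-k:]) <= max_mismatch:
            return k
    return 0


def _blocks(candidate: str, record: ReferenceRecord, max_mismatch: int) -> bool:
    return bool(find_primer_sites(record, candidate, max_mismatch))


def score_candidate(
    candidate: BlockingPrimer | str,
    target_db: Sequence[ReferenceRecord],
    offtarget_db: Sequence[ReferenceRecord],
    block_max_mismatch: int = 0,
    tm_delta: float | None = None,
) -> CandidateScore:
    """In-silico specificity of one candidate.

    A record is "blocked" when the candidate has an IUPAC-compatible site
    (either strand, <= block_max_mismatch mismatches) anywhere in it; pass
    databases already restricted to records the primer set amplifies so the
    fractions read as "share of otherwise-amplified sequences suppressed".
    """
    if not target_db:
        raise ValueError("empty target pool: specificity undefined")
    seq = candidate.sequence if isinstance(candidate, BlockingPrimer) else candidate
    if tm_delta is None:
        tm_delta = candidate.tm_delta if isinstance(candidate, BlockingPrimer) else 0.0
    hit_t = sum(_blocks(seq, r, block_max_mismatch) for r in target_db)
    hit_o = sum(_blocks(seq, r, block_max_mismatch) for r in offtarget_db)
    return CandidateScore(
        target_blocked_fraction=hit_t / len(target_db),
        offtarget_blocked_fraction=hit_o / len(offtarget_db) if offtarget_db else 0.0,
        tm_delta=tm_delta,
    )


def select_best(
    scored_candidates: Sequence[tuple[BlockingPrimer, CandidateScore]],
) -> BlockingPrimer:
    """Deterministic lexicographic ranking of scored candidates.

    Maximise target blocking, then minimise off-target blocking, then
    minimise |Tm delta|, then prefer the shorter, then alphabetical
    sequence order — a total order, so permuting the input never changes
    the winner.
    """
    if not scored_candidates:
        raise ValueError("no candidates to select from")

    def key(item: tuple[BlockingPrimer, CandidateScore]):
        cand, score = item
        return (
            -score.target_blocked_fraction,
            score.offtarget_blocked_fraction,
            abs(score.tm_delta),
            len(cand.sequence),
            cand.sequence,
        )

    return min(scored_candidates, key=key)[0]


@dataclass(frozen=True)
class DesignResult:
    """Everything the design pipeline produced, selected primer included."""

    selected: BlockingPrimer
    selected_score: CandidateScore
    candidates: tuple[tuple[BlockingPrimer, CandidateScore], ...]
    consensus_window: str
    n_target_amplified: int
    n_offtarget_amplified: int
    pair_tm: float


def run_design(
    records: Sequence[ReferenceRecord],
    primer_set: PrimerSet,
    target_label: str,
    constraints: DesignConstraints = DesignConstraints(),
    max_mismatch: int | None = None,
) -> DesignResult:
    """Full blocking-primer design against an annotated database.

    Splits the database on *target_label* (e.g. the host genus), restricts
    both pools to records the primer set amplifies, stacks the target
    amplicons' 3' windows into an IUPAC consensus, enumerates candidates,
    scores each within-tolerance candidate against both pools and applies
    the deterministic ranking.

    Raises :class:`ValueError` when no target record yields a full-length
    amplicon or no candidate survives the Tm filter.
    """
    from .reference_db import partition_by_label

    if max_mismatch is None:
        max_mismatch = primer_set.max_mismatch
    target_recs, offtarget_recs = partition_by_label(records, target_label)
    if not target_recs:
        raise ValueError(f"no records annotated with {target_label!r}")

    def amplified(pool):
        out = []
        for rec in pool:
            amps = extract_amplicons(rec, primer_set, max_mismatch)
            primary = next((a for a in amps if a.primary), None)
            if primary is not None:
                out.append((rec, primary))
        return out

    target_amp = amplified(target_recs)
    offtarget_amp = amplified(offtarget_recs)
    if not target_amp:
        raise ValueError(
            f"no {target_label!r} record carries a complete amplicon; "
            "cannot extract host windows"
        )
    windows = [
        extract_host_window(a, primer_set.reverse, constraints.window_len)
        for _, a in target_amp
        if a.length >= constraints.window_len
    ]
    if not windows:
        raise ValueError("all target amplicons shorter than the design window")
    consensus = window_consensus(windows)
    pair_tm = primer_pair_mean_tm(primer_set)
    candidates = enumerate_candidates(
        consensus, primer_set.reverse, constraints, pair_tm=pair_tm, windows=windows
    )
    if not candidates:
        raise ValueError("design window admits no candidate in the length range")
    target_db = [rec for rec, _ in target_amp]
    offtarget_db = [rec for rec, _ in offtarget_amp]
    scored = tuple(
        (c, score_candidate(c, target_db, offtarget_db, constraints.block_max_mismatch))
        for c in candidates
    )
    eligible = [cs for cs in scored if cs[0].within_tm_tolerance]
    if not eligible:
        raise ValueError("no candidate within the Tm tolerance of the primer pair")
    selected = select_best(eligible)
    sel_score = next(s for c, s in scored if c == selected)
    return DesignResult(
        selected=selected,
        selected_score=sel_score,
        candidates=scored,
        consensus_window=consensus,
        n_target_amplified=len(target_db),
        n_offtarget_amplified=len(offtarget_db),
        pair_tm=pair_tm,
    )
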