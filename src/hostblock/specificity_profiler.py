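"""Per-record amplification status and per-taxon coverage profiles.

Every reference record is classified against a primer configuration
(primer pair, optional blocking primer, mismatch allowances) into exactly
one status:

AMPLIFIED    both primer sites present in amplifiable orientation
BLOCKED      would amplify, but the blocking primer has a compatible site
             inside the amplicon (host template suppressed)
INCOMPLETE   only one primer site, or sites mis-ordered — typically a
             truncated database entry
NO_SITE      neither primer site

Aggregating statuses per taxonomic group gives the coverage/blocking
profile used to compare primer strategies (which groups a universal pair
plus blocking primer retains versus an excluding pair).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .insilico_pcr import PrimerSet, extract_amplicons, find_primer_sites
from .reference_db import ReferenceRecord, TaxonomyPath

__all__ = [
    "Status",
    "RecordStatus",
    "PrimerConfig",
    "GroupProfile",
    "classify_record",
    "completeness_filter",
    "profile_groups",
    "compare_primer_sets",
    "profiles_to_frame",
    "write_profile_tsv",
    "write_profile_json",
]

UNRESOLVED = "unresolved"


class Status(str, enum.Enum):
    AMPLIFIED = "AMPLIFIED"
    BLOCKED = "BLOCKED"
    NO_SITE = "NO_SITE"
    INCOMPLETE = "INCOMPLETE"


@dataclass(frozen=True)
class RecordStatus:
    record_id: str
    status: Status
    amplicon_length: int | None = None
    reoriented: bool = False


@dataclass(frozen=True)
class PrimerConfig:
    """One profiling configuration: a primer set, an optional blocking
    primer, and the mismatch allowances used for each."""

    name: str
    primer_set: PrimerSet
    blocking: str | None = None
    max_mismatch: int | None = None
    block_max_mismatch: int = 0

    @property
    def effective_max_mismatch(self) -> int:
        return (
            self.primer_set.max_mismatch
            if self.max_mismatch is None
            else self.max_mismatch
        )


@dataclass(frozen=True)
class GroupProfile:
    group: str
    rank: int
    n: int
    n_amplified: int
    n_blocked: int
    n_no_site: int
    n_incomplete: int

    def __post_init__(self) -> None:
        total = self.n_amplified + self.n_blocked + self.n_no_site + self.n_incomplete
        if total != self.n:
            raise ValueError(f"group {self.group!r}: status counts {total} != n {self.n}")

    @property
    def fraction_amplified(self) -> float:
        return self.n_amplified / self.n if self.n else 0.0

    @property
    def fraction_blocked(self) -> float:
        return self.n_blocked / self.n if self.n else 0.0


def classify_record(
    record: ReferenceRecord,
    primer_set: PrimerSet,
    blocking: str | None = None,
    max_mismatch: int | None = None,
    block_max_mismatch: int = 0,
) -> RecordStatus:
    """Classify one record; BLOCKED requires a blocking-primer site inside
    the (otherwise amplified) primary amplicon.  Antisense-deposited
    entries are recognised through the amplicon search's own strand
    symmetry and flagged ``reoriented``."""
    mm = primer_set.max_mismatch if max_mismatch is None else max_mismatch
    amps = extract_amplicons(record, primer_set, mm)
    if amps:
        primary = next(a for a in amps if a.primary)
        status = Status.AMPLIFIED
        if blocking is not None:
            for amp in amps:
                if find_primer_sites(amp.sense_sequence, blocking, block_max_mismatch):
                    status = Status.BLOCKED
                    break
        return RecordStatus(record.id, status, primary.length, primary.antisense)
    n_sites = len(find_primer_sites(record, primer_set.forward, mm)) + len(
        find_primer_sites(record, primer_set.reverse, mm)
    )
    if n_sites:
        return RecordStatus(record.id, Status.INCOMPLETE)
    return RecordStatus(record.id, Status.NO_SITE)


def completeness_filter(
    records: Sequence[ReferenceRecord],
    primer_set: PrimerSet,
    max_mismatch: int | None = None,
    length_bounds: tuple[int, int] = (1, 10_000),
) -> list[ReferenceRecord]:
    """Keep records carrying the complete amplicon region.

    A record passes when both primer sites are found in amplifiable
    orientation and the primary amplicon length falls inside
    *length_bounds* (inclusive) — a direct criterion standing in for
    similarity-search-based completeness screening of partial SSU entries.
    """
    lo, hi = length_bounds
    if lo > hi:
        raise ValueError("length_bounds must satisfy lo <= hi")
    kept = []
    for rec in records:
        rs = classify_record(rec, primer_set, max_mismatch=max_mismatch)
        if rs.status is Status.AMPLIFIED and lo <= (rs.amplicon_length or 0) <= hi:
            kept.append(rec)
    return kept


def _group_label(taxonomy: TaxonomyPath, rank: int) -> str:
    return taxonomy.at_rank(rank) or UNRESOLVED


def profile_groups(
    records: Sequence[ReferenceRecord],
    primer_configs: Sequence[PrimerConfig],
    rank: int,
) -> dict[str, list[GroupProfile]]:
    """Status tallies per taxonomic group for each primer configuration.

    *rank* is a 0-based taxonomy depth; records annotated more shallowly
    fall in an "unresolved" bin so counts always conserve.  Groups are
    ordered by descending size (ties alphabetical).  Returns
    {config name: [GroupProfile, ...]}.
    """
    if rank < 0:
        raise ValueError("rank must be non-negative")
    groups: dict[str, list[ReferenceRecord]] = {}
    for rec in records:
        groups.setdefault(_group_label(rec.taxonomy, rank), []).append(rec)
    ordered = sorted(groups, key=lambda g: (-len(groups[g]), g))
    out: dict[str, list[GroupProfile]] = {}
    for cfg in primer_configs:
        profiles = []
        for g in ordered:
            tally = {s: 0 for s in Status}
            for rec in groups[g]:
                rs = classify_record(
                    rec,
                    cfg.primer_set,
                    blocking=cfg.blocking,
                    max_mismatch=cfg.effective_max_mismatch,
                    block_max_mismatch=cfg.block_max_mismatch,
                )
                tally[rs.status] += 1
            profiles.append(
                GroupProfile(
                    group=g,
                    rank=rank,
                    n=len(groups[g]),
                    n_amplified=tally[Status.AMPLIFIED],
                    n_blocked=tally[Status.BLOCKED],
                    n_no_site=tally[Status.NO_SITE],
                    n_incomplete=tally[Status.INCOMPLETE],
                )
            )
        out[cfg.name] = profiles
    return out


def compare_primer_sets(
    profiles_a: Sequence[GroupProfile], profiles_b: Sequence[GroupProfile]
) -> pd.DataFrame:
    """Per-group difference in amplified fraction between two configs.

    Requires identical group universes (same records, same rank).  The
    ``exclusive`` flag marks groups amplified by exactly one of the two
    configurations.
    """
    by_a = {p.group: p for p in profiles_a}
    by_b = {p.group: p for p in profiles_b}
    if set(by_a) != set(by_b):
        only_a = sorted(set(by_a) - set(by_b))
        only_b = sorted(set(by_b) - set(by_a))
        raise ValueError(
            f"mismatched group universes (only in A: {only_a}, only in B: {only_b})"
        )
    rows = []
    for g in [p.group for p in profiles_a]:
        fa, fb = by_a[g].fraction_amplified, by_b[g].fraction_amplified
        rows.append(
            {
                "group": g,
                "n": by_a[g].n,
                "fraction_amplified_a": fa,
                "fraction_amplified_b": fb,
                "delta": fa - fb,
                "exclusive": (by_a[g].n_amplified > 0) != (by_b[g].n_amplified > 0),
            }
        )
    return pd.DataFrame(rows)


def profiles_to_frame(profiles: dict[str, list[GroupProfile]]) -> pd.DataFrame:
    rows = []
    for cfg_name, plist in profiles.items():
        for p in plist:
            rows.append(
                {
                    "config": cfg_name,
                    "group": p.group,
                    "rank": p.rank,
                    "n": p.n,
                    "n_amplified": p.n_amplified,
                    "n_blocked": p.n_blocked,
                    "n_no_site": p.n_no_site,
                    "n_incomplete": p.n_incomplete,
                    "fraction_amplified": p.fraction_amplified,
                    "fraction_blocked": p.fraction_blocked,
                }
            )
    return pd.DataFrame(rows)


def write_profile_tsv(
    profiles: dict[str, list[GroupProfile]], path: str | Path, metadata: dict | None = None
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        profiles_to_frame(profiles).to_csv(fh, sep="\t", index=False)


def write_profile_json(profiles: dict[str, list[GroupProfile]], path: str | Path) -> None:
    payload = {
        cfg: [
            {
                "group": p.group,
                "rank": p.rank,
                "n": p.n,
                "n_amplified": p.n_amplified,
                "n_blocked": p.n_blocked,
                "n_no_site": p.n_no_site,
                "n_incomplete": p.n_incomplete,
                "fraction_amplified": p.fraction_amplified,
                "fraction_blocked": p.fraction_blocked,
            }
            for p in plist
        ]
        for cfg, plist in profiles.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
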