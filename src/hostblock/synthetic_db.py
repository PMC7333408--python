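"""Seeded generator of Silva-style reference databases with planted truth.

The generator emulates the structure the blocking-primer design procedure
assumes in a real SSU database: a host clade whose reverse-primer binding
site differs from the universal primer at exactly one position and which
carries a fully conserved blocking motif overlapping that site; sister
clades conserving the motif with some probability; protist clades lacking
it entirely; and a fraction of truncated (partial) entries.

Every record is assembled as

    5' pad | forward-primer site | insert | 3' host region | reverse site | 3' pad

where the 3' host region plus the first bases of the reverse site either
spell the reverse complement of the blocking primer (motif planted) or are
random background (motif absent).  Per-record ground truth (site presence,
truncation, planted amplicon coordinates) is returned alongside, so every
downstream classifier can be checked against what was actually planted.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .insilico_pcr import (
    IUPAC_SETS,
    PrimerSet,
    TABLE1_18SV4,
    TABLE1_BLOCKING_18SV4,
    expand_degenerate,
    mismatch_count,
    revcomp,
)
from .reference_db import ReferenceRecord, TaxonomyPath

__all__ = [
    "CladeSpec",
    "SyntheticDbSpec",
    "RecordTruth",
    "simulate_reference_db",
    "planted_truth_profile",
    "write_truth_tsv",
    "default_oyster_spec",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CladeSpec:
    """One simulated clade.

    fwd_mismatches / rev_mismatches: true (IUPAC-incompatible) substitutions
    planted in each primer site.  block_p: per-record probability that the
    blocking motif is conserved (records carrying it inherit the motif's
    overlap-induced reverse-site variant instead of rev_mismatches).
    trunc_q: per-record probability the entry is truncated before the
    reverse site, as partial database sequences are.
    """

    name: str
    taxonomy: str
    n: int
    fwd_mismatches: int = 0
    rev_mismatches: int = 0
    block_p: float = 0.0
    trunc_q: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for p, lab in ((self.block_p, "block_p"), (self.trunc_q, "trunc_q")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{lab} must lie in [0, 1]")
        if min(self.fwd_mismatches, self.rev_mismatches) < 0:
            raise ValueError("mismatch counts must be >= 0")


@dataclass(frozen=True)
class SyntheticDbSpec:
    seed: int
    clades: tuple[CladeSpec, ...]
    primer_set: PrimerSet = TABLE1_18SV4
    blocking: str = TABLE1_BLOCKING_18SV4
    block_overlap: int = 10
    insert_mean: float = 150.0
    insert_sd: float = 20.0
    pad_range: tuple[int, int] = (30, 60)
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background_rate must lie in [0, 1]")
        if not 0 < self.block_overlap < len(self.blocking):
            raise ValueError("block_overlap must lie inside the blocking primer")
        if self.block_overlap >= len(self.primer_set.reverse):
            raise ValueError("block_overlap must be shorter than the reverse primer")
        for c in self.clades:
            if c.fwd_mismatches > len(self.primer_set.forward):
                raise ValueError(f"clade {c.name}: fwd_mismatches exceeds primer length")
            if c.rev_mismatches > len(self.primer_set.reverse):
                raise ValueError(f"clade {c.name}: rev_mismatches exceeds primer length")


@dataclass(frozen=True)
class RecordTruth:
    record_id: str
    clade: str
    has_fwd_site: bool
    has_rev_site: bool
    has_block_site: bool
    truncated: bool
    amplicon_start: int | None
    amplicon_end: int | None


def _clade_rng(seed: int, clade_name: str) -> np.random.Generator:
    # stable per-clade stream: independent of clade order in the spec
    digest = hashlib.sha256(clade_name.encode()).digest()
    child = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, child]))


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _concrete_instance(rng: np.random.Generator, primer: str) -> str:
    """One concrete expansion of a degenerate primer, uniformly drawn."""
    return "".join(
        sorted(IUPAC_SETS[c])[rng.integers(0, len(IUPAC_SETS[c]))] for c in primer
    )


def _plant_mismatches(rng: np.random.Generator, primer: str, instance: str, k: int) -> str:
    """Substitute *k* positions of *instance* with bases incompatible with
    the primer's IUPAC set there, producing exactly k true mismatches."""
    if k == 0:
        return instance
    positions = [i for i in range(len(primer)) if len(IUPAC_SETS[primer[i]]) < 4]
    if len(positions) < k:
        raise ValueError("primer too degenerate to plant that many mismatches")
    chosen = rng.choice(len(positions), size=k, replace=False)
    seq = list(instance)
    for idx in sorted(int(i) for i in chosen):
        pos = positions[idx]
        options = sorted(set("ACGT") - IUPAC_SETS[primer[pos]])
        seq[pos] = options[rng.integers(0, len(options))]
    return "".join(seq)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_reference_db(
    spec: SyntheticDbSpec,
) -> tuple[list[ReferenceRecord], list[RecordTruth]]:
    """Generate a deterministic annotated database plus per-record truth.

    For a fixed spec (seed included) two runs produce identical records.
    """
    ps = spec.primer_set
    host_specific_len = len(spec.blocking) - spec.block_overlap
    records: list[ReferenceRecord] = []
    truths: list[RecordTruth] = []
    for clade in spec.clades:
        rng = _clade_rng(spec.seed, clade.name)
        taxonomy = TaxonomyPath.from_string(clade.taxonomy)
        for i in range(clade.n):
            rid = f"{clade.name}_{i:04d}"
            pad5 = _random_bases(rng, int(rng.integers(*spec.pad_range)))
            pad3 = _random_bases(rng, int(rng.integers(*spec.pad_range)))
            insert_len = max(10, int(round(rng.normal(spec.insert_mean, spec.insert_sd))))
            insert = _random_bases(rng, insert_len)
            fwd_site = _plant_mismatches(
                rng, ps.forward, _concrete_instance(rng, ps.forward), clade.fwd_mismatches
            )
            has_block = bool(rng.random() < clade.block_p)
            if has_block:
                # motif conserved: the sense strand spells revcomp(blocking),
                # its 3' end reaching block_overlap bases into the reverse
                # site — the overlap dictates the host reverse-site variant
                rev_variant = (
                    _concrete_instance(rng, ps.reverse)[: -spec.block_overlap]
                    + spec.blocking[: spec.block_overlap]
                )
                host_region = revcomp(spec.blocking)[:host_specific_len]
            else:
                rev_variant = _plant_mismatches(
                    rng,
                    ps.reverse,
                    _concrete_instance(rng, ps.reverse),
                    clade.rev_mismatches,
                )
                host_region = _random_bases(rng, host_specific_len)
            rev_site = revcomp(rev_variant)
            body = pad5 + fwd_site + insert + host_region + rev_site + pad3
            amp_start = len(pad5)
            amp_end = len(pad5) + len(fwd_site) + insert_len + host_specific_len + len(rev_site)
            truncated = bool(rng.random() < clade.trunc_q)
            if truncated:
                cut = amp_start + len(fwd_site) + insert_len // 2
                body = body[:cut]
                truth = RecordTruth(rid, clade.name, True, False, False, True, None, None)
            else:
                truth = RecordTruth(
                    rid, clade.name, True, True, has_block, False, amp_start, amp_end
                )
            body = _mutate(rng, body, spec.background_rate)
            records.append(ReferenceRecord(id=rid, taxonomy=taxonomy, sequence=body))
            truths.append(truth)
    return records, truths


@dataclass(frozen=True)
class ExpectedCladeProfile:
    clade: str
    fraction_amplified: float
    fraction_blocked: float
    fraction_incomplete: float


def planted_truth_profile(
    spec: SyntheticDbSpec,
    max_mismatch: int | None = None,
    block_max_mismatch: int = 0,
    with_blocking: bool = True,
) -> dict[str, ExpectedCladeProfile]:
    """Analytic expectations for observed per-clade profile fractions.

    With conservation probability p and truncation probability q, an
    amplifiable clade expects fraction_blocked = p*(1-q) and
    fraction_amplified = (1-q) minus whatever is blocked.  Clades whose
    planted primer-site mismatches exceed the search allowance amplify
    nothing.  Valid for background_rate = 0, where planted truth and
    classification agree exactly.
    """
    mm = spec.primer_set.max_mismatch if max_mismatch is None else max_mismatch
    # reverse-site mismatch burden carried by motif-bearing records
    overlap_mm = mismatch_count(
        spec.blocking[: spec.block_overlap],
        spec.primer_set.reverse[-spec.block_overlap :],
    )
    out = {}
    for clade in spec.clades:
        p, q = clade.block_p, clade.trunc_q
        fwd_ok = clade.fwd_mismatches <= mm
        amp_with_block = fwd_ok and overlap_mm <= mm
        amp_without = fwd_ok and clade.rev_mismatches <= mm
        f_blocked = p * (1 - q) * amp_with_block if with_blocking else 0.0
        f_amplified = (1 - q) * (
            p * amp_with_block + (1 - p) * amp_without
        ) - f_blocked
        out[clade.name] = ExpectedCladeProfile(
            clade=clade.name,
            fraction_amplified=f_amplified,
            fraction_blocked=f_blocked,
            fraction_incomplete=q,
        )
    return out


def write_truth_tsv(truths: Sequence[RecordTruth], path: str | Path) -> None:
    lines = ["record_id\tclade\thas_fwd_site\thas_rev_site\thas_block_site\ttruncated\tamplicon_start\tamplicon_end"]
    for t in truths:
        lines.append(
            "\t".join(
                [
                    t.record_id,
                    t.clade,
                    str(int(t.has_fwd_site)),
                    str(int(t.has_rev_site)),
                    str(int(t.has_block_site)),
                    str(int(t.truncated)),
                    "" if t.amplicon_start is None else str(t.amplicon_start),
                    "" if t.amplicon_end is None else str(t.amplicon_end),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def default_oyster_spec(seed: int = 1, host_n: int = 20, protist_n: int = 50) -> SyntheticDbSpec:
    """The canonical design fixture: one host (oyster-like) clade carrying
    the conserved blocking motif — hence one reverse-primer-site mismatch —
    and three motif-free protist clades."""
    return SyntheticDbSpec(
        seed=seed,
        clades=(
            CladeSpec(
                "Crassostrea",
                "Eukaryota;Opisthokonta;Metazoa;Mollusca;Ostreoida;Crassostrea",
                n=host_n,
                block_p=1.0,
            ),
            CladeSpec(
                "Dinophyceae",
                "Eukaryota;Alveolata;Dinophyceae",
                n=protist_n,
            ),
            CladeSpec(
                "Bacillariophyta",
                "Eukaryota;Stramenopiles;Bacillariophyta",
                n=protist_n,
            ),
            CladeSpec(
                "Chlorophyta",
                "Eukaryota;Archaeplastida;Chlorophyta",
                n=protist_n,
            ),
        ),
    )
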