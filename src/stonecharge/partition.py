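"""Matrix-preferring vs urine-preferring group construction and truncation.

Two rules turn abundance inputs into the analysis groups:

1. ``build_groups`` — a protein from the stone-matrix list whose mean urine
   abundance exceeds its mean matrix abundance actually prefers the urine
   phase and is reassigned; the urine group is those reassigned proteins
   plus every urine-list protein above the abundance cutoff (default 0.5 %
   relative abundance) that is not already in the matrix group. A
   configurable exclusion list (default: ubiquitin, whose identity is
   ambiguous across database releases) is dropped from both sides.

2. ``truncate_by_net_charge`` — strongly charged matrix proteins (net
   charge percent strictly beyond +/-5 %) are set aside as the putative
   aggregation triggers, leaving the weakly charged remainder for the
   total-charge comparison. Boundary values exactly at the cutoff are
   retained. Truncation is only ever applied to the matrix group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .charge_metrics import ChargeProfile
from .sequence_io import Group, ProteinRecord, ProteinSet

__all__ = [
    "PartitionConfig",
    "PartitionResult",
    "TruncationResult",
    "build_groups",
    "truncate_by_net_charge",
]

ProfilePair = tuple[ProteinRecord, ChargeProfile]


@dataclass(frozen=True)
class PartitionConfig:
    """Cutoffs and exclusions for group construction and truncation.

    net_charge_pct_cutoff : percent; proteins strictly beyond +/-cutoff are
        removed by truncation (default 5.0).
    abundance_cutoff : percent relative abundance a urine-list protein must
        exceed to enter the urine-preferring group (default 0.5).
    exclusions : identifiers/accessions/names removed from both groups,
        matched case-insensitively.
    """

    net_charge_pct_cutoff: float = 5.0
    abundance_cutoff: float = 0.5
    exclusions: tuple[str, ...] = ("ubiquitin",)

    def __post_init__(self) -> None:
        if self.net_charge_pct_cutoff <= 0 or self.abundance_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass
class PartitionResult:
    mpp: ProteinSet
    upp: ProteinSet
    reassigned: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)


@dataclass
class TruncationResult:
    retained: list[ProfilePair]
    removed_anionic: list[ProfilePair]
    removed_cationic: list[ProfilePair]

    @property
    def tally(self) -> dict[str, int]:
        return {
            "retained": len(self.retained),
            "removed_anionic": len(self.removed_anionic),
            "removed_cationic": len(self.removed_cationic),
        }


def _is_excluded(rec: ProteinRecord, exclusions: Sequence[str]) -> bool:
    keys = {rec.identifier.lower(), rec.accession.lower(), rec.name.lower()}
    return any(e.lower() in keys for e in exclusions)


def build_groups(
    matrix_list: ProteinSet,
    urine_list: ProteinSet,
    config: PartitionConfig | None = None,
) -> PartitionResult:
    """Assign each protein to the matrix-preferring or urine-preferring group.

    Matrix-list records must carry both matrix and urine mean abundances;
    urine-list records need a relative (urine) abundance. Output sets are
    disjoint by construction.
    """
    config = config or PartitionConfig()
    excluded: list[str] = []
    reassigned: list[str] = []
    mpp: list[ProteinRecord] = []
    upp: list[ProteinRecord] = []

    for rec in matrix_list:
        if _is_excluded(rec, config.exclusions):
            excluded.append(rec.identifier)
            continue
        if rec.matrix_abundance is None or rec.urine_abundance is None:
            raise ValueError(
                f"record {rec.identifier!r}: matrix and urine abundances "
                "are both required to assign phase preference"
            )
        if rec.urine_abundance > rec.matrix_abundance:
            reassigned.append(rec.identifier)
            upp.append(rec.with_group(Group.UPP))
        else:
            mpp.append(rec.with_group(Group.MPP))

    mpp_ids = {r.identifier for r in mpp}
    upp_ids = {r.identifier for r in upp}
    for rec in urine_list:
        if _is_excluded(rec, config.exclusions):
            excluded.append(rec.identifier)
            continue
        abundance = rec.relative_abundance
        if abundance is None:
            abundance = rec.urine_abundance
        if abundance is None:
            raise ValueError(
                f"record {rec.identifier!r}: missing relative abundance"
            )
        if (abundance > config.abundance_cutoff
                and rec.identifier not in mpp_ids
                and rec.identifier not in upp_ids):
            upp.append(rec.with_group(Group.UPP))
            upp_ids.add(rec.identifier)

    return PartitionResult(
        mpp=ProteinSet(records=mpp, label="MPP"),
        upp=ProteinSet(records=upp, label="UPP"),
        reassigned=reassigned,
        excluded=excluded,
    )


def truncate_by_net_charge(
    profiles: Sequence[ProfilePair],
    config: PartitionConfig | None = None,
) -> TruncationResult:
    """Split profiles into retained / removed-anionic / removed-cationic.

    Strict inequalities: net charge percent < -cutoff is removed as anionic,
    > +cutoff as cationic, values exactly at +/-cutoff are retained. The
    three outputs partition the input exactly, so the operation is
    idempotent on its own retained set.
    """
    if not profiles:
        raise ValueError("no profiles to truncate")
    config = config or PartitionConfig()
    cut = config.net_charge_pct_cutoff
    result = TruncationResult(retained=[], removed_anionic=[], removed_cationic=[])
    for rec, prof in profiles:
        if prof.net_charge_pct < -cut:
            result.removed_anionic.append((rec, prof))
        elif prof.net_charge_pct > cut:
            result.removed_cationic.append((rec, prof))
        else:
            result.retained.append((rec, prof))
    return result
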