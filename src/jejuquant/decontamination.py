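"""Negative-control-based removal of reagent contaminant background.

Low-biomass samples are dominated by reagent/environmental DNA, so every
identification also seen in any pooled negative/weak-positive control is
suspect. The canonical contaminant taxa (consistent across all controls)
define a sample-specific relative-abundance cutoff: a control-overlapping
species survives only if it out-ranks every canonical contaminant in that
sample. Species cultured from the same patient are always accepted. Finally,
species seen in only one sample cohort-wide and a user-supplied
"biologically unexpected" blocklist are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .taxonomy_annotation import labels_overlap

__all__ = [
    "SpeciesProfile",
    "DecontaminationConfig",
    "RemovalRecord",
    "pool_controls",
    "sample_cutoff",
    "filter_contaminants",
    "remove_rare_cross_sample",
]

#: the consistently most abundant control taxa, as reported labels
DEFAULT_CANONICAL_CONTAMINANTS = (
    "Cutibacterium acnes",
    "Ralstonia pickettii",
    "Staphylococcus capitis/caprae/epidermidis",
    "Aquabacterium",
    "Hydrotalea flava",
)


@dataclass
class SpeciesProfile:
    """Per-sample read counts keyed by identification label (species or
    slash-group)."""

    sample_id: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("read counts must be non-negative")

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def species(self) -> set[str]:
        return {s for s, c in self.counts.items() if c > 0}

    def relative_abundance(self, label: str) -> float:
        total = self.total_reads
        if total == 0:
            return 0.0
        return self.counts.get(label, 0) / total


@dataclass(frozen=True)
class DecontaminationConfig:
    canonical_contaminants: tuple[str, ...] = DEFAULT_CANONICAL_CONTAMINANTS
    blocklist: tuple[str, ...] = ()
    min_cross_sample_occurrence: int = 2
    #: 'sample' = cutoff from canonical contaminant abundances within the
    #: sample being filtered; 'controls' = from the pooled control profiles
    cutoff_source: str = "sample"

    def __post_init__(self) -> None:
        if self.min_cross_sample_occurrence < 1:
            raise ValueError("min_cross_sample_occurrence must be >= 1")
        if self.cutoff_source not in ("sample", "controls"):
            raise ValueError("cutoff_source must be 'sample' or 'controls'")


@dataclass(frozen=True)
class RemovalRecord:
    sample_id: str
    species: str
    reads: int
    reason: str  # control_overlap | blocklist | singleton


def _matches_any(label: str, reference_labels: Iterable[str]) -> bool:
    return any(labels_overlap(label, ref) for ref in reference_labels)


def pool_controls(
    control_profiles: Sequence[SpeciesProfile],
    spike_species: Iterable[str] = (),
) -> set[str]:
    """Union of labels observed in any control, excluding designated spike
    organisms."""
    if not control_profiles:
        raise ValueError("need at least one control profile")
    spike = tuple(spike_species)
    pooled: set[str] = set()
    for prof in control_profiles:
        for label in prof.species:
            if spike and _matches_any(label, spike):
                continue
            pooled.add(label)
    return pooled


def sample_cutoff(profile: SpeciesProfile, config: DecontaminationConfig | None = None) -> float:
    """Sample-specific validity cutoff: the largest relative abundance among
    canonical contaminant labels present in this sample (0 if none)."""
    config = config or DecontaminationConfig()
    total = profile.total_reads
    if total == 0:
        return 0.0
    best = 0.0
    for label, count in profile.counts.items():
        if count > 0 and _matches_any(label, config.canonical_contaminants):
            best = max(best, count / total)
    return best


def filter_contaminants(
    profile: SpeciesProfile,
    contaminant_set: Iterable[str],
    cutoff: float,
    cultured_species: Iterable[str] = (),
    config: DecontaminationConfig | None = None,
    removal_log: list[RemovalRecord] | None = None,
) -> SpeciesProfile:
    """Apply the control-overlap removal rule to one sample.

    A label is removed iff it overlaps the pooled contaminant set AND its
    relative abundance does not exceed the cutoff AND no member of it was
    cultured from this patient. Blocklisted labels are removed
    unconditionally. Every removal is logged with its reason.
    """
    config = config or DecontaminationConfig()
    contaminants = tuple(contaminant_set)
    cultured = tuple(cultured_species)
    kept: dict[str, int] = {}
    for label, count in profile.counts.items():
        if count == 0:
            continue
        if _matches_any(label, config.blocklist):
            if removal_log is not None:
                removal_log.append(RemovalRecord(profile.sample_id, label, count, "blocklist"))
            continue
        if (
            _matches_any(label, contaminants)
            and profile.relative_abundance(label) <= cutoff
            and not _matches_any(label, cultured)
        ):
            if removal_log is not None:
                removal_log.append(
                    RemovalRecord(profile.sample_id, label, count, "control_overlap")
                )
            continue
        kept[label] = count
    return SpeciesProfile(profile.sample_id, kept)


def remove_rare_cross_sample(
    all_profiles: Sequence[SpeciesProfile],
    config: DecontaminationConfig | None = None,
    removal_log: list[RemovalRecord] | None = None,
) -> list[SpeciesProfile]:
    """Remove labels present in fewer samples than the occurrence floor.

    With the default floor of 2, a species appearing in only one of the
    cohort's samples is removed everywhere. Blocklisted labels are removed
    as well.
    """
    config = config or DecontaminationConfig()
    occurrence: dict[str, int] = {}
    for prof in all_profiles:
        for label in prof.species:
            occurrence[label] = occurrence.get(label, 0) + 1
    out: list[SpeciesProfile] = []
    for prof in all_profiles:
        kept: dict[str, int] = {}
        for label, count in prof.counts.items():
            if count == 0:
                continue
            if _matches_any(label, config.blocklist):
                if removal_log is not None:
                    removal_log.append(RemovalRecord(prof.sample_id, label, count, "blocklist"))
                continue
            if occurrence[label] < config.min_cross_sample_occurrence:
                if removal_log is not None:
                    removal_log.append(RemovalRecord(prof.sample_id, label, count, "singleton"))
                continue
            kept[label] = count
        out.append(SpeciesProfile(prof.sample_id, kept))
    return out
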