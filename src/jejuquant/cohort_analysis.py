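"""Patient-level merging, prevalence/core-microbiota analysis, quantity
binning, rank aggregation, and culture-vs-sequencing concordance.

Results from a patient's two jejunal segments are merged as a presence union
(per-segment counts are retained); prevalence is the fraction of patients in
which an identification appears; the core microbiota at threshold t is every
identification present in strictly more than a fraction t of patients.
Quantities are binned per patient by the most microbe-rich segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .decontamination import SpeciesProfile
from .quantification import (
    CULTURE_CATEGORIES,
    CensoredValue,
    GENOME_BINS,
    QuantResult,
    culture_category,
    genome_bin,
)
from .taxonomy_annotation import labels_overlap

__all__ = [
    "PatientProfile",
    "CoreConfig",
    "merge_segments",
    "species_frequency",
    "core_microbiota",
    "patient_quant_category",
    "aggregate_rank",
    "compare_culture_sequencing",
    "compare_frequency_tables",
    "fraction_below",
]


@dataclass(frozen=True)
class CoreConfig:
    """Prevalence threshold for core membership; 0.30 and 0.50 are the
    conventional presets."""

    prevalence_threshold: float = 0.30

    def __post_init__(self) -> None:
        if not 0 < self.prevalence_threshold <= 1:
            raise ValueError("prevalence threshold must lie in (0, 1]")


@dataclass
class PatientProfile:
    patient_id: str
    segment_profiles: dict[str, SpeciesProfile]
    quant: dict[str, QuantResult] = field(default_factory=dict)

    @property
    def species_present(self) -> set[str]:
        present: set[str] = set()
        for prof in self.segment_profiles.values():
            present |= prof.species
        return present


def merge_segments(
    patient_id: str, profiles: Mapping[str, SpeciesProfile], quant: Mapping[str, QuantResult] | None = None
) -> PatientProfile:
    """Merge a patient's segment profiles; presence is the union, counts stay
    per segment."""
    ids = {p.sample_id.split("-", 1)[0] for p in profiles.values()}
    if len(ids) > 1:
        raise ValueError(f"segment profiles belong to different patients: {sorted(ids)}")
    return PatientProfile(patient_id, dict(profiles), dict(quant or {}))


def species_frequency(patients: Sequence[PatientProfile]) -> dict[str, float]:
    """Fraction of patients in which each identification is present."""
    if not patients:
        raise ValueError("cohort must contain at least one patient")
    n = len(patients)
    counts: dict[str, int] = {}
    for pat in patients:
        for sp in pat.species_present:
            counts[sp] = counts.get(sp, 0) + 1
    return {sp: c / n for sp, c in sorted(counts.items())}


def core_microbiota(freq: Mapping[str, float], config: CoreConfig | None = None) -> list[str]:
    """Identifications present in strictly more than the threshold fraction of
    patients, sorted by descending frequency then name."""
    config = config or CoreConfig()
    hits = [(sp, f) for sp, f in freq.items() if f > config.prevalence_threshold]
    hits.sort(key=lambda h: (-h[1], h[0]))
    return [sp for sp, _ in hits]


def patient_quant_category(quant: Mapping[str, QuantResult]) -> dict[str, str | None]:
    """Patient-level culture and molecular categories from the richest segment.

    Returns {'culture': category or None, 'molecular': bin or None}; each
    modality uses the maximum (by knowable magnitude) across segments of the
    values available for it.
    """
    if not quant:
        raise ValueError("need at least one quantified segment")
    cfu = [q.cfu_per_ml for q in quant.values() if q.cfu_per_ml is not None]
    gen = [q.genomes_per_ml for q in quant.values() if q.genomes_per_ml is not None]
    out: dict[str, str | None] = {"culture": None, "molecular": None}
    if cfu:
        out["culture"] = culture_category(max(cfu, key=CensoredValue.sort_key))
    if gen:
        out["molecular"] = genome_bin(max(gen, key=CensoredValue.sort_key))
    return out


def aggregate_rank(
    profiles: Sequence[SpeciesProfile],
    lineage: Mapping[str, Sequence[str]],
    rank: str = "genus",
) -> pd.DataFrame:
    """Per-sample relative abundance at genus or phylum level.

    Slash-group labels resolve through any member found in the lineage table
    provided all members agree at the requested rank; labels that cannot be
    resolved fall into an 'unresolved' column. Rows (samples) sum to 1 where
    the sample has any reads.
    """
    from .taxonomy_annotation import split_slash_label

    rank_index = {"phylum": 0, "class": 1, "order": 2, "family": 3, "genus": 4}
    if rank not in rank_index:
        raise ValueError(f"rank must be one of {sorted(rank_index)}")
    idx = rank_index[rank]

    def taxon_of(label: str) -> str:
        members = split_slash_label(label)
        taxa = {tuple(lineage[m])[idx] for m in members if m in lineage}
        if not taxa:
            # bare genus labels resolve directly at genus rank
            if rank == "genus" and len(members) == 1 and " " not in members[0]:
                return members[0]
            return "unresolved"
        if len(taxa) == 1:
            return taxa.pop()
        return "unresolved"

    rows: dict[str, dict[str, float]] = {}
    unresolved_seen = False
    for prof in profiles:
        total = prof.total_reads
        row: dict[str, float] = {}
        for label, count in prof.counts.items():
            if count == 0:
                continue
            taxon = taxon_of(label)
            if taxon == "unresolved":
                unresolved_seen = True
            row[taxon] = row.get(taxon, 0.0) + count / total
        rows[prof.sample_id] = row
    if unresolved_seen:
        import warnings

        warnings.warn("some labels could not be resolved at the requested rank", stacklevel=2)
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    return df.reindex(sorted(df.columns), axis=1)


def compare_culture_sequencing(
    patients: Sequence[PatientProfile],
    culture_ids: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Concordance of culture and sequencing identifications per sample.

    culture_ids maps sample_id -> cultured species labels. Matching is
    slash-group aware: a cultured species agrees with a sequencing slash
    group that contains it. Returns one row per sample with counts of
    identifications found by both, culture only, and sequencing only, plus an
    'overall' row.
    """
    rows = []
    tot_both = tot_culture = tot_seq = 0
    for pat in patients:
        for seg, prof in sorted(pat.segment_profiles.items()):
            cultured = list(culture_ids.get(prof.sample_id, []))
            seq_labels = sorted(prof.species)
            matched_seq: set[str] = set()
            both = culture_only = 0
            for c in cultured:
                hit = next((s for s in seq_labels if labels_overlap(c, s)), None)
                if hit is None:
                    culture_only += 1
                else:
                    both += 1
                    matched_seq.add(hit)
            seq_only = len([s for s in seq_labels if s not in matched_seq])
            rows.append(
                {
                    "sample_id": prof.sample_id,
                    "both": both,
                    "culture_only": culture_only,
                    "sequencing_only": seq_only,
                }
            )
            tot_both += both
            tot_culture += culture_only
            tot_seq += seq_only
    rows.append(
        {"sample_id": "overall", "both": tot_both, "culture_only": tot_culture, "sequencing_only": tot_seq}
    )
    return pd.DataFrame(rows).set_index("sample_id")


def compare_frequency_tables(
    freq_a: Mapping[str, float], freq_b: Mapping[str, float]
) -> pd.DataFrame:
    """Outer-join two prevalence tables; absent species get frequency 0.

    Rows are sorted by descending freq_a then name (the layout used to set a
    reference cohort against the study cohort).
    """
    species = sorted(set(freq_a) | set(freq_b))
    df = pd.DataFrame(
        {
            "species": species,
            "freq_a": [freq_a.get(s, 0.0) for s in species],
            "freq_b": [freq_b.get(s, 0.0) for s in species],
        }
    )
    return df.sort_values(["freq_a", "species"], ascending=[False, True]).reset_index(drop=True)


def fraction_below(category_counts: Mapping[str, int], below: Sequence[str]) -> float:
    """Fraction of patients whose category falls in the given low bins.

    Operates on a category -> patient-count table (e.g. the patient-level
    column of a quantification summary); returns sum(below) / total.
    """
    total = sum(category_counts.values())
    if total == 0:
        raise ValueError("empty category table")
    return sum(category_counts.get(b, 0) for b in below) / total
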