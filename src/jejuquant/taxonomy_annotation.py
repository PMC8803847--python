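"""Species/genus assignment of OTU centroids by percent-identity thresholds.

The decision ladder mirrors clinical 16S practice: an unambiguous species
call requires >= 99.0% identity to a reference with a margin of > 0.8% to the
best other species; a near runner-up is reported as a parenthetical
alternative; references tied at the exact same top score produce a
slash-group label; 97-99% identity supports only a genus-level call; anything
lower is unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ._alignment import identity
from .synthetic_data import ReferenceDB

__all__ = [
    "AnnotationThresholds",
    "TaxonomyCall",
    "align_to_reference",
    "call_taxonomy",
    "annotate_centroid",
    "slash_label",
    "split_slash_label",
    "labels_overlap",
]

#: decimal places at which two identities count as "identical scores"
SCORE_DECIMALS = 4


@dataclass(frozen=True)
class AnnotationThresholds:
    species_min_identity: float = 0.990
    species_min_gap: float = 0.008  # exclusive margin to the next species
    genus_min_identity: float = 0.97

    def __post_init__(self) -> None:
        if not 0 < self.genus_min_identity <= self.species_min_identity <= 1:
            raise ValueError("need 0 < genus_min_identity <= species_min_identity <= 1")
        if self.species_min_gap < 0:
            raise ValueError("species_min_gap must be >= 0")


@dataclass(frozen=True)
class TaxonomyCall:
    """Rank-qualified identification of one OTU centroid.

    rank 'species_with_alternative' carries the runner-up in alternatives;
    rank 'slash_group' lists every tied species (primary = first
    alphabetically); 'genus' carries the genus of the top hit; identity is
    absent (None) only for empty hit lists.
    """

    rank: str
    primary: str
    alternatives: tuple[str, ...] = ()
    identity: float | None = None
    runner_up_identity: float | None = None

    def __post_init__(self) -> None:
        if self.rank not in ("species", "species_with_alternative", "slash_group", "genus", "unclassified"):
            raise ValueError(f"unknown rank {self.rank!r}")
        needs_alts = self.rank in ("species_with_alternative", "slash_group")
        if needs_alts != bool(self.alternatives):
            raise ValueError("alternatives must be non-empty exactly for alternative/slash calls")
        if (
            self.identity is not None
            and self.runner_up_identity is not None
            and self.identity < self.runner_up_identity
        ):
            raise ValueError("top identity below runner-up identity")

    @property
    def label(self) -> str:
        """Reporting label: 'A', 'A (B)', 'A/B', genus name, or 'unclassified'."""
        if self.rank == "species_with_alternative":
            return f"{self.primary} ({', '.join(self.alternatives)})"
        if self.rank == "slash_group":
            return slash_label((self.primary,) + self.alternatives)
        if self.rank == "unclassified":
            return "unclassified"
        return self.primary


def slash_label(species: Sequence[str]) -> str:
    """Compact slash-group label; same-genus epithets after the first are bare.

    ('Staphylococcus capitis', 'Staphylococcus epidermidis') ->
    'Staphylococcus capitis/epidermidis'.
    """
    names = sorted(set(species))
    if not names:
        return ""
    parts = [names[0]]
    first_genus = names[0].split()[0]
    for sp in names[1:]:
        genus, _, epithet = sp.partition(" ")
        parts.append(epithet if genus == first_genus and epithet else sp)
    return "/".join(parts)


def split_slash_label(label: str) -> list[str]:
    """Expand a slash-group label into full binomials.

    'Staphylococcus capitis/caprae/epidermidis' -> the three binomials;
    parenthetical alternatives are included as members.
    """
    label = label.strip()
    alts: list[str] = []
    if label.endswith(")") and "(" in label:
        base, _, inner = label.rpartition("(")
        alts = [a.strip() for a in inner[:-1].split(",") if a.strip()]
        label = base.strip()
    parts = [p.strip() for p in label.split("/") if p.strip()]
    if not parts:
        return alts
    out = [parts[0]]
    genus = parts[0].split()[0]
    for p in parts[1:]:
        out.append(p if " " in p else f"{genus} {p}")
    return out + alts


def labels_overlap(label_a: str, label_b: str) -> bool:
    """Whether two identification labels share any species member.

    Slash-aware: a single species matches a slash group containing it. A
    bare genus name (single word) matches any member of that genus.
    """
    mem_a = split_slash_label(label_a)
    mem_b = split_slash_label(label_b)
    for a in mem_a:
        for b in mem_b:
            if a == b:
                return True
            if " " not in a and b.split()[0] == a:
                return True
            if " " not in b and a.split()[0] == b:
                return True
    return False


def align_to_reference(centroid: str, db: ReferenceDB) -> list[tuple[str, float]]:
    """Identity of the centroid against every reference sequence.

    Returns (species, identity) sorted by descending identity, ties broken
    by species name.
    """
    if not centroid:
        raise ValueError("centroid must be non-empty")
    if len(db) == 0:
        raise ValueError("reference database is empty")
    hits = [(e.species, identity(centroid, e.sequence)) for e in db.entries]
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits


def call_taxonomy(
    hits: Sequence[tuple[str, float]],
    thresholds: AnnotationThresholds | None = None,
    db: ReferenceDB | None = None,
) -> TaxonomyCall:
    """Apply the identification decision ladder to a ranked hit list.

    Scores are compared at 4-decimal precision to decide ties. The margin is
    measured to the best hit of any *other* species (extra references of the
    top species are skipped). A genus-band call uses the top hit's genus from
    the reference lineage when a database is supplied, else the first word of
    the species name.
    """
    th = thresholds or AnnotationThresholds()
    if not hits:
        return TaxonomyCall(rank="unclassified", primary="unclassified")
    top_species, top_id = hits[0]
    top_score = round(top_id, SCORE_DECIMALS)

    runner_species: str | None = None
    runner_id: float | None = None
    tied: list[str] = [top_species]
    for sp, ident in hits[1:]:
        if sp == top_species:
            continue
        score = round(ident, SCORE_DECIMALS)
        if score == top_score and runner_id is None:
            if sp not in tied:
                tied.append(sp)
        elif runner_id is None:
            runner_species, runner_id = sp, ident
            break

    if top_score >= round(th.species_min_identity, SCORE_DECIMALS):
        if len(tied) > 1:
            names = sorted(tied)
            return TaxonomyCall(
                rank="slash_group",
                primary=names[0],
                alternatives=tuple(names[1:]),
                identity=top_id,
                runner_up_identity=top_id,
            )
        # gap compared at the same 4-decimal precision as tie detection
        if runner_id is None or round(top_id - runner_id, SCORE_DECIMALS) > th.species_min_gap:
            return TaxonomyCall(
                rank="species",
                primary=top_species,
                identity=top_id,
                runner_up_identity=runner_id,
            )
        return TaxonomyCall(
            rank="species_with_alternative",
            primary=top_species,
            alternatives=(runner_species,),
            identity=top_id,
            runner_up_identity=runner_id,
        )
    if top_score >= round(th.genus_min_identity, SCORE_DECIMALS):
        genus = db[top_species].genus if db is not None and top_species in db else top_species.split()[0]
        return TaxonomyCall(rank="genus", primary=genus, identity=top_id, runner_up_identity=runner_id)
    return TaxonomyCall(
        rank="unclassified", primary="unclassified", identity=top_id, runner_up_identity=runner_id
    )


def annotate_centroid(
    centroid: str, db: ReferenceDB, thresholds: AnnotationThresholds | None = None
) -> TaxonomyCall:
    """Convenience: align then call."""
    return call_taxonomy(align_to_reference(centroid, db), thresholds, db)
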