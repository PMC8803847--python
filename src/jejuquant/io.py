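"""Readers and writers for the pipeline's standard formats.

FASTA/FASTQ go through Biopython's SeqIO; tabular sidecars (lineages, truth
concentrations, colony counts, Ct values, metadata, species-by-sample
matrices) are plain TSV via pandas. All writers round-trip losslessly with
their readers.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .decontamination import SpeciesProfile
from .quantification import NO_AMPLIFICATION
from .synthetic_data import RANKS, CommunityTruth, RefEntry, ReferenceDB

__all__ = [
    "read_fastq",
    "write_fastq",
    "write_fasta",
    "read_fasta",
    "write_reference_db",
    "read_reference_db",
    "write_truths",
    "read_truths",
    "write_profiles",
    "read_profiles",
    "read_table",
]


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Parse a Phred+33 FASTQ file; malformed records raise with position."""
    path = Path(path)
    records: list[SeqRecord] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            records.append(rec)
    except ValueError as exc:
        raise ValueError(
            f"{path}: malformed FASTQ after record {len(records)} "
            f"(approx. line {len(records) * 4 + 1}): {exc}"
        ) from exc
    return records


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    SeqIO.write(records, str(path), "fastq")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA."""
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def _species_key(species: str) -> str:
    return species.replace(" ", "_")


def write_reference_db(db: ReferenceDB, fasta_path: str | Path, lineage_path: str | Path) -> None:
    """Write the reference collection as FASTA plus a lineage/cultivability TSV."""
    write_fasta([(_species_key(e.species), e.sequence) for e in db.entries], fasta_path)
    rows = [
        {"species": e.species, **dict(zip(RANKS, e.lineage)), "cultivable": int(e.cultivable)}
        for e in db.entries
    ]
    pd.DataFrame(rows).to_csv(lineage_path, sep="\t", index=False)


def read_reference_db(fasta_path: str | Path, lineage_path: str | Path) -> ReferenceDB:
    seqs = {rid.replace("_", " "): seq for rid, seq in read_fasta(fasta_path)}
    table = read_table(lineage_path, required=("species",) + RANKS + ("cultivable",))
    entries = []
    for _, row in table.iterrows():
        sp = row["species"]
        if sp not in seqs:
            raise ValueError(f"{lineage_path}: species {sp!r} missing from {fasta_path}")
        lineage = tuple(str(row[r]) for r in RANKS)
        entries.append(RefEntry(sp, lineage, seqs[sp], bool(row["cultivable"])))
    return ReferenceDB(entries)


def write_truths(truths: Sequence[CommunityTruth], path: str | Path) -> None:
    rows = [
        {"sample_id": t.sample_id, "species": sp, "genomes_per_ml": conc}
        for t in truths
        for sp, conc in sorted(t.species_conc.items())
    ]
    # keep empty samples visible
    rows += [
        {"sample_id": t.sample_id, "species": "", "genomes_per_ml": 0.0}
        for t in truths
        if not t.species_conc
    ]
    pd.DataFrame(rows, columns=["sample_id", "species", "genomes_per_ml"]).to_csv(
        path, sep="\t", index=False
    )


def read_truths(path: str | Path) -> list[CommunityTruth]:
    table = read_table(path, required=("sample_id", "species", "genomes_per_ml"))
    truths: dict[str, dict[str, float]] = {}
    for row in table.itertuples(index=False):
        truths.setdefault(row.sample_id, {})
        if isinstance(row.species, str) and row.species:
            truths[row.sample_id][row.species] = float(row.genomes_per_ml)
    return [CommunityTruth(sid, conc) for sid, conc in truths.items()]


def write_profiles(profiles: Sequence[SpeciesProfile], path: str | Path) -> None:
    """Species-by-sample count matrix (rows = species labels, columns = samples)."""
    df = pd.DataFrame(
        {p.sample_id: pd.Series(p.counts, dtype="int64") for p in profiles}
    ).fillna(0).astype(int)
    df.index.name = "species"
    df.sort_index().to_csv(path, sep="\t")


def read_profiles(path: str | Path) -> list[SpeciesProfile]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [
        SpeciesProfile(str(col), {sp: int(c) for sp, c in df[col].items() if c > 0})
        for col in df.columns
    ]


def read_table(path: str | Path, required: Sequence[str] = ()) -> pd.DataFrame:
    """Read a TSV, requiring the named columns; unknown columns are kept but
    flagged with a warning."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if required:
        extra = [c for c in df.columns if c not in required]
        if extra:
            warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=2)
    return df


def format_ct(ct: float) -> str:
    return "NA" if ct == NO_AMPLIFICATION or ct != ct else f"{ct:.4f}"


def parse_ct(text: str) -> float:
    return NO_AMPLIFICATION if text in ("NA", "", "inf") else float(text)
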