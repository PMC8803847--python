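"""Synthetic low-biomass jejunal cohort generator.

Emulates a 60-patient, two-segment surgical cohort in which most samples carry
very few bacteria: sparse log-normal communities, a reagent contaminant
background shared with negative extraction controls, weak positive (spiked)
controls, paired V3-V4 amplicon reads with substitution errors and PCR
chimeras, plate culture colony counts, and universal 16S qPCR Ct values -- all
derived from the same per-sample ground-truth concentrations so that every
downstream stage can be validated against truth.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .quantification import (
    CultureProtocolParams,
    MolecularProtocolParams,
    NO_AMPLIFICATION,
    StandardCurve,
)

__all__ = [
    "RANKS",
    "CANONICAL_CONTAMINANTS",
    "SPIKE_SPECIES",
    "SPIKE_CELLS",
    "RefEntry",
    "ReferenceDB",
    "CohortDesign",
    "CommunityTruth",
    "generate_reference_db",
    "simulate_cohort_truth",
    "simulate_reads",
    "simulate_controls",
    "simulate_culture",
    "simulate_qpcr",
]

RANKS = ("phylum", "class", "order", "family", "genus")

#: reagent/environmental background taxa consistently seen in extraction controls
CANONICAL_CONTAMINANTS = (
    "Cutibacterium acnes",
    "Ralstonia pickettii",
    "Staphylococcus capitis",
    "Staphylococcus epidermidis",
    "Aquabacterium parvum",
    "Hydrotalea flava",
)

#: marker organism for weak positive extraction controls
SPIKE_SPECIES = "Legionella pneumophila"
#: cells spiked per control (0.5 McFarland, 1 ul)
SPIKE_CELLS = 1.5e5
#: collection volume the spike is suspended in (swab uptake + transport medium), ml
COLLECTION_VOLUME_ML = 1.2

# species that must exist in any generated reference database
_REQUIRED_SPECIES = CANONICAL_CONTAMINANTS + (
    SPIKE_SPECIES,
    "Streptococcus mitis",
    "Streptococcus oralis",
)

# curated lineages: species -> (phylum, class, order, family, genus)
_CURATED: dict[str, tuple[str, str, str, str, str]] = {
    "Cutibacterium acnes": ("Actinobacteria", "Actinomycetia", "Propionibacteriales", "Propionibacteriaceae", "Cutibacterium"),
    "Ralstonia pickettii": ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Burkholderiaceae", "Ralstonia"),
    "Staphylococcus capitis": ("Firmicutes", "Bacilli", "Bacillales", "Staphylococcaceae", "Staphylococcus"),
    "Staphylococcus epidermidis": ("Firmicutes", "Bacilli", "Bacillales", "Staphylococcaceae", "Staphylococcus"),
    "Aquabacterium parvum": ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Aquabacteriaceae", "Aquabacterium"),
    "Hydrotalea flava": ("Bacteroidetes", "Sphingobacteriia", "Sphingobacteriales", "Chitinophagaceae", "Hydrotalea"),
    "Legionella pneumophila": ("Proteobacteria", "Gammaproteobacteria", "Legionellales", "Legionellaceae", "Legionella"),
    "Streptococcus mitis": ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
    "Streptococcus oralis": ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
    "Streptococcus salivarius": ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
    "Streptococcus parasanguinis": ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
    "Streptococcus sanguinis": ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
    "Granulicatella adiacens": ("Firmicutes", "Bacilli", "Lactobacillales", "Carnobacteriaceae", "Granulicatella"),
    "Granulicatella elegans": ("Firmicutes", "Bacilli", "Lactobacillales", "Carnobacteriaceae", "Granulicatella"),
    "Gemella haemolysans": ("Firmicutes", "Bacilli", "Bacillales", "Gemellaceae", "Gemella"),
    "Gemella taiwanensis": ("Firmicutes", "Bacilli", "Bacillales", "Gemellaceae", "Gemella"),
    "Veillonella parvula": ("Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae", "Veillonella"),
    "Veillonella atypica": ("Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae", "Veillonella"),
    "Rothia mucilaginosa": ("Actinobacteria", "Actinomycetia", "Micrococcales", "Micrococcaceae", "Rothia"),
    "Rothia dentocariosa": ("Actinobacteria", "Actinomycetia", "Micrococcales", "Micrococcaceae", "Rothia"),
    "Schaalia odontolytica": ("Actinobacteria", "Actinomycetia", "Actinomycetales", "Actinomycetaceae", "Schaalia"),
    "Actinomyces oris": ("Actinobacteria", "Actinomycetia", "Actinomycetales", "Actinomycetaceae", "Actinomyces"),
    "Corynebacterium durum": ("Actinobacteria", "Actinomycetia", "Corynebacteriales", "Corynebacteriaceae", "Corynebacterium"),
    "Corynebacterium kroppenstedtii": ("Actinobacteria", "Actinomycetia", "Corynebacteriales", "Corynebacteriaceae", "Corynebacterium"),
    "Corynebacterium aurimucosum": ("Actinobacteria", "Actinomycetia", "Corynebacteriales", "Corynebacteriaceae", "Corynebacterium"),
    "Micrococcus luteus": ("Actinobacteria", "Actinomycetia", "Micrococcales", "Micrococcaceae", "Micrococcus"),
    "Haemophilus parainfluenzae": ("Proteobacteria", "Gammaproteobacteria", "Pasteurellales", "Pasteurellaceae", "Haemophilus"),
    "Neisseria flavescens": ("Proteobacteria", "Betaproteobacteria", "Neisseriales", "Neisseriaceae", "Neisseria"),
    "Neisseria subflava": ("Proteobacteria", "Betaproteobacteria", "Neisseriales", "Neisseriaceae", "Neisseria"),
    "Escherichia coli": ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia"),
    "Klebsiella pneumoniae": ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Klebsiella"),
    "Prevotella melaninogenica": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella"),
    "Fusobacterium nucleatum": ("Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae", "Fusobacterium"),
    "Lactobacillus gasseri": ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus"),
    "Limosilactobacillus fermentum": ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Limosilactobacillus"),
}


@dataclass(frozen=True)
class RefEntry:
    """One reference amplicon: species, five-rank lineage, sequence, cultivability."""

    species: str
    lineage: tuple[str, str, str, str, str]  # phylum..genus
    sequence: str
    cultivable: bool

    def __post_init__(self) -> None:
        if len(self.lineage) != len(RANKS):
            raise ValueError("lineage must carry exactly phylum..genus")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("sequence must be plain A/C/G/T")

    @property
    def genus(self) -> str:
        return self.lineage[-1]


@dataclass
class ReferenceDB:
    """In-silico stand-in for a curated 16S reference collection."""

    entries: list[RefEntry]

    def __post_init__(self) -> None:
        names = [e.species for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        self._by_species = {e.species: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, species: str) -> bool:
        return species in self._by_species

    def __getitem__(self, species: str) -> RefEntry:
        return self._by_species[species]

    @property
    def species(self) -> list[str]:
        return [e.species for e in self.entries]

    @property
    def contaminant_species(self) -> tuple[str, ...]:
        return tuple(s for s in CANONICAL_CONTAMINANTS if s in self._by_species)

    def lineage_table(self) -> dict[str, tuple[str, str, str, str, str]]:
        return {e.species: e.lineage for e in self.entries}


@dataclass(frozen=True)
class CommunityTruth:
    """Ground-truth species concentrations (genomes/ml) for one sample."""

    sample_id: str
    species_conc: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.species_conc.values()):
            raise ValueError("concentrations must be non-negative")

    @property
    def total_conc(self) -> float:
        return float(sum(self.species_conc.values()))


@dataclass(frozen=True)
class CohortDesign:
    """Study design and statistical structure of the simulated cohort.

    abundance_mu/abundance_sigma parameterize the log-normal (natural log)
    per-species concentration in genomes/ml; patient_effect_sd is the shared
    patient-level component of abundance_sigma (both jejunal segments of a
    patient tend to carry similar loads); sparsity is the expected species
    richness per sample (Poisson); background_pressure is the contaminant
    background expressed as an equivalent concentration C0 so that a sample
    with total concentration T receives contaminant reads with weight
    C0 / (C0 + T). Defaults are tuned so roughly 40% of patient-level maxima
    (and ~60% of individual segments) fall below the 2.9e3 genomes/ml
    molecular LoQ, with a heavy right tail reaching 1e5-1e6 genomes/ml.
    """

    n_patients: int = 60
    segments_per_patient: int = 2
    n_negative_controls: int = 10
    n_spiked_controls: int = 10
    contaminant_profile: Mapping[str, float] = field(
        default_factory=lambda: {
            "Cutibacterium acnes": 0.35,
            "Ralstonia pickettii": 0.20,
            "Staphylococcus capitis": 0.10,
            "Staphylococcus epidermidis": 0.10,
            "Aquabacterium parvum": 0.15,
            "Hydrotalea flava": 0.10,
        }
    )
    abundance_mu: float = 5.0
    abundance_sigma: float = 3.0
    patient_effect_sd: float = 1.0
    sparsity: float = 3.0
    background_pressure: float = 2.0e3
    read_pairs_per_sample: int = 3000
    error_rate: float = 0.002
    chimera_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_patients,
            self.segments_per_patient,
            self.n_negative_controls,
            self.n_spiked_controls,
            self.read_pairs_per_sample,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all design counts must be >= 0")
        if any(not 0 <= f <= 1 for f in self.contaminant_profile.values()):
            raise ValueError("contaminant fractions must lie in [0, 1]")
        if not 0 <= self.patient_effect_sd <= self.abundance_sigma:
            raise ValueError("patient_effect_sd must lie in [0, abundance_sigma]")

    @property
    def segment_names(self) -> tuple[str, ...]:
        return ("proximal", "mid")[: self.segments_per_patient]


def _random_amplicon(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute n_subs distinct positions, never with the original base."""
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def _synth_species(i: int) -> tuple[str, tuple[str, str, str, str, str]]:
    name = f"Simulibacter synthetus{i}"
    return name, ("Firmicutes", "Clostridia", "Eubacteriales", "Simulibacteraceae", "Simulibacter")


def generate_reference_db(n_species: int = 50, seed: int = 0) -> ReferenceDB:
    """Build a deterministic reference database of ~420 nt amplicons.

    Includes by construction: the canonical contaminant taxa, the spike
    organism, one near-identical species pair (Streptococcus mitis/oralis,
    2 substitutions apart, <0.8% divergence, exercising parenthetical
    alternative calls) and one fully identical pair (Staphylococcus
    capitis/epidermidis, exercising slash-group calls). Cultivability is a
    per-species flag (~50% cultivable; the spike organism is fastidious and
    flagged non-cultivable).
    """
    if n_species < len(_REQUIRED_SPECIES) + 1:
        raise ValueError(
            f"n_species must be at least {len(_REQUIRED_SPECIES) + 1} to host the designed species pairs"
        )
    rng = np.random.default_rng(seed)
    names: list[str] = list(_REQUIRED_SPECIES)
    for sp in _CURATED:
        if len(names) >= n_species:
            break
        if sp not in names:
            names.append(sp)
    i = 0
    lineages = dict(_CURATED)
    while len(names) < n_species:
        name, lin = _synth_species(i)
        lineages[name] = lin
        names.append(name)
        i += 1

    entries: list[RefEntry] = []
    sequences: dict[str, str] = {}
    for sp in names:
        length = int(rng.integers(410, 431))
        sequences[sp] = _random_amplicon(rng, length)
    # designed identical pair: indistinguishable by the amplicon
    sequences["Staphylococcus epidermidis"] = sequences["Staphylococcus capitis"]
    # designed near-identical pair: 2 substitutions, divergence < 0.8%
    sequences["Streptococcus oralis"] = _mutate(rng, sequences["Streptococcus mitis"], 2)

    for sp in names:
        cultivable = bool(rng.random() < 0.5)
        if sp == SPIKE_SPECIES:
            cultivable = False
        entries.append(RefEntry(sp, lineages[sp], sequences[sp], cultivable))
    return ReferenceDB(entries)


def simulate_cohort_truth(design: CohortDesign, db: ReferenceDB) -> list[CommunityTruth]:
    """Draw sparse log-normal ground-truth communities for every patient sample.

    Community species are drawn from the non-contaminant, non-spike part of
    the reference database; the contaminant background enters only at the
    read-simulation stage, mirroring reagent-borne DNA.
    """
    if len(db) == 0:
        raise ValueError("reference database is empty")
    rng = np.random.default_rng(design.seed)
    pool = [
        s
        for s in db.species
        if s not in CANONICAL_CONTAMINANTS and s != SPIKE_SPECIES
    ]
    within_sd = math.sqrt(design.abundance_sigma**2 - design.patient_effect_sd**2)
    truths: list[CommunityTruth] = []
    for p in range(1, design.n_patients + 1):
        patient_effect = (
            float(rng.normal(0.0, design.patient_effect_sd)) if design.patient_effect_sd > 0 else 0.0
        )
        for seg in design.segment_names:
            sample_id = f"P{p:03d}-{seg}"
            richness = int(rng.poisson(design.sparsity)) if design.sparsity > 0 else 0
            richness = min(richness, len(pool))
            conc: dict[str, float] = {}
            if richness > 0:
                chosen = rng.choice(pool, size=richness, replace=False)
                for sp in chosen:
                    conc[str(sp)] = float(
                        math.exp(design.abundance_mu + patient_effect + rng.normal(0.0, within_sd))
                    )
            truths.append(CommunityTruth(sample_id, conc))
    return truths


def _phred_string(qualities: Iterable[int]) -> list[int]:
    return [int(q) for q in qualities]


def _make_pair(
    sample_id: str,
    idx: int,
    amplicon: str,
    read_len: int,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[SeqRecord, SeqRecord]:
    r1 = amplicon[:read_len]
    r2 = str(Seq(amplicon[-read_len:]).reverse_complement())
    reads = []
    for seq in (r1, r2):
        if error_rate > 0:
            n_err = rng.binomial(len(seq), error_rate)
            if n_err:
                seq = _mutate(rng, seq, int(n_err))
        reads.append(seq)
    quals1 = np.clip(rng.normal(37, 2, size=len(reads[0])).round(), 2, 40)
    quals2 = np.clip(rng.normal(35, 3, size=len(reads[1])).round(), 2, 40)
    rid = f"{sample_id}:read{idx:06d}"
    rec1 = SeqRecord(Seq(reads[0]), id=rid, description="")
    rec1.letter_annotations["phred_quality"] = _phred_string(quals1)
    rec2 = SeqRecord(Seq(reads[1]), id=rid, description="")
    rec2.letter_annotations["phred_quality"] = _phred_string(quals2)
    return rec1, rec2


def simulate_reads(
    truth: CommunityTruth,
    db: ReferenceDB,
    n_read_pairs: int,
    error_rate: float = 0.002,
    chimera_rate: float = 0.01,
    contaminant_profile: Mapping[str, float] | None = None,
    background_pressure: float = 2.0e3,
    read_len: int = 300,
    seed: int = 0,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Simulate paired 2x300 reads for one sample.

    Reads are drawn multinomially from the truth composition mixed with the
    contaminant profile; the contaminant mixing weight is
    w = C0 / (C0 + total_conc) with C0 = background_pressure, so low-biomass
    samples are contaminant-dominated and a zero-concentration sample yields
    pure background. Substitution errors are i.i.d. per base; with probability
    chimera_rate a read pair derives from a two-parent splice of distinct
    source amplicons. Headers carry the sample id only, never the source
    species.
    """
    if not 0 <= error_rate <= 1 or not 0 <= chimera_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    if n_read_pairs < 0:
        raise ValueError("n_read_pairs must be >= 0")
    contaminant_profile = contaminant_profile or {}
    total = truth.total_conc
    if n_read_pairs > 0 and total == 0 and not contaminant_profile:
        raise ValueError(
            f"sample {truth.sample_id}: nothing to sequence (empty truth, no contaminant profile)"
        )

    species: list[str] = []
    probs: list[float] = []
    w = background_pressure / (background_pressure + total) if contaminant_profile else 0.0
    if total == 0 and contaminant_profile:
        w = 1.0
    if total > 0:
        for sp, c in sorted(truth.species_conc.items()):
            if c > 0:
                species.append(sp)
                probs.append((1 - w) * c / total)
    if contaminant_profile:
        frac_total = sum(contaminant_profile.values())
        for sp, f in sorted(contaminant_profile.items()):
            if f > 0:
                species.append(sp)
                probs.append(w * f / frac_total)
    probs_arr = np.asarray(probs)
    probs_arr = probs_arr / probs_arr.sum()

    rng = np.random.default_rng(seed)
    r1s: list[SeqRecord] = []
    r2s: list[SeqRecord] = []
    for i in range(n_read_pairs):
        chimeric = len(species) >= 2 and rng.random() < chimera_rate
        if chimeric:
            a, b = rng.choice(len(species), size=2, replace=False, p=probs_arr)
            seq_a = db[species[int(a)]].sequence
            seq_b = db[species[int(b)]].sequence
            L = min(len(seq_a), len(seq_b))
            cut = int(rng.integers(int(0.2 * L), int(0.8 * L) + 1))
            amplicon = seq_a[:cut] + seq_b[cut:]
        else:
            s = int(rng.choice(len(species), p=probs_arr))
            amplicon = db[species[s]].sequence
        rec1, rec2 = _make_pair(truth.sample_id, i, amplicon, read_len, error_rate, rng)
        r1s.append(rec1)
        r2s.append(rec2)
    return r1s, r2s


def control_truths(design: CohortDesign) -> list[CommunityTruth]:
    """Ground truth for negative and weak positive (spiked) controls.

    Negative controls contain no organisms; spiked controls carry the spike
    organism at 1.5e5 cells suspended in the 1.2 ml collection volume.
    """
    spike_conc = SPIKE_CELLS / COLLECTION_VOLUME_ML
    truths = [
        CommunityTruth(f"NC{i:02d}", {}) for i in range(1, design.n_negative_controls + 1)
    ]
    truths += [
        CommunityTruth(f"SC{i:02d}", {SPIKE_SPECIES: spike_conc})
        for i in range(1, design.n_spiked_controls + 1)
    ]
    return truths


def simulate_controls(
    design: CohortDesign, db: ReferenceDB, seed: int = 0
) -> dict[str, tuple[list[SeqRecord], list[SeqRecord]]]:
    """Simulate read pairs for every extraction control.

    Negative controls receive pure contaminant-background reads; spiked
    controls mix the spike amplicon with background at the design's
    background pressure (the spike dominates at default settings).
    """
    if design.n_spiked_controls > 0 and SPIKE_SPECIES not in db:
        raise ValueError(f"spike species {SPIKE_SPECIES!r} missing from reference database")
    rng = np.random.default_rng(seed)
    out: dict[str, tuple[list[SeqRecord], list[SeqRecord]]] = {}
    for truth in control_truths(design):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        out[truth.sample_id] = simulate_reads(
            truth,
            db,
            design.read_pairs_per_sample,
            error_rate=design.error_rate,
            chimera_rate=design.chimera_rate,
            contaminant_profile=design.contaminant_profile,
            background_pressure=design.background_pressure,
            seed=sub_seed,
        )
    return out


def simulate_culture(
    truth: CommunityTruth,
    db: ReferenceDB,
    protocol: CultureProtocolParams | None = None,
    seed: int = 0,
) -> dict[str, int | str]:
    """Simulate per-species plate colony counts for one sample.

    Each cultivable species yields Poisson(concentration / cfu-per-colony)
    colonies (160 cfu/ml per colony at default volumes); plates beyond 100
    colonies are reported ">100". Non-cultivable species never grow.
    """
    protocol = protocol or CultureProtocolParams()
    rng = np.random.default_rng(seed)
    counts: dict[str, int | str] = {}
    for sp, conc in sorted(truth.species_conc.items()):
        if sp in db and not db[sp].cultivable:
            continue
        if conc <= 0:
            continue
        n = int(rng.poisson(conc / protocol.cfu_per_colony))
        if n > 0:
            counts[sp] = ">100" if n > 100 else n
    return counts


def simulate_qpcr(
    truth: CommunityTruth,
    curve: StandardCurve,
    protocol: MolecularProtocolParams | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> float:
    """Simulate the universal 16S qPCR Ct for one sample.

    Target copies per reaction = total_conc / sample_dilution x 16S copies
    per genome; Ct follows the standard curve plus Gaussian noise. Zero
    concentration returns the no-amplification sentinel; copy numbers below
    the linear-range floor never report below the LoQ Ct.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    protocol = protocol or MolecularProtocolParams()
    genomes_per_rxn = truth.total_conc / protocol.sample_dilution
    copies = genomes_per_rxn * protocol.rrn_copies_per_genome
    if copies <= 0:
        return NO_AMPLIFICATION
    ct = curve.predict_ct(copies)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ct += float(rng.normal(0.0, noise_sd))
    if copies < curve.linear_range[0]:
        ct = max(ct, math.nextafter(curve.loq_ct + curve.run_offset, math.inf))
    return float(ct)
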