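"""Absolute bacterial load estimation from culture plates and universal 16S qPCR.

Culture side: colony counts from a fixed-volume plating protocol are converted
to cfu/ml of the original sample and binned into the reporting categories used
for swab-collected mucosal samples (no growth, single colonies/broth only,
sparse, moderate, abundant).

Molecular side: a genome-equivalent standard curve (Ct vs log10 target copies
per reaction) is fitted from a dilution series, optionally re-anchored per run
with a calibration standard, and inverted to genomes/ml with explicit
left-censoring below the limit of quantification (LoQ).

Censored results are typed (`CensoredValue`), never encoded as magic numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence, Union

import numpy as np

__all__ = [
    "CensoredValue",
    "CultureProtocolParams",
    "MolecularProtocolParams",
    "StandardCurve",
    "QuantResult",
    "NO_AMPLIFICATION",
    "cfu_per_ml",
    "culture_category",
    "genomes_per_ul_from_mass",
    "calibration_curve",
    "calibration_dilution_series",
    "loq_genomes_per_ml",
    "fit_standard_curve",
    "run_adjustment",
    "genomes_per_ml",
    "genome_bin",
    "GENOME_BINS",
    "CULTURE_CATEGORIES",
]

#: average mass of one double-stranded base pair, g/mol
DSDNA_BP_MASS_G_PER_MOL = 650.0
AVOGADRO = 6.02214076e23

#: sentinel Ct for reactions that never crossed threshold
NO_AMPLIFICATION = math.inf


@dataclass(frozen=True)
class CensoredValue:
    """A point value or a one-sided censored bound ("<x" / ">x")."""

    value: float
    censor: str = "="  # one of "=", "<", ">"

    def __post_init__(self) -> None:
        if self.censor not in ("=", "<", ">"):
            raise ValueError(f"invalid censor {self.censor!r}")
        if self.value < 0:
            raise ValueError("censored quantities are non-negative")

    @property
    def is_point(self) -> bool:
        return self.censor == "="

    def __str__(self) -> str:
        if self.is_point:
            return f"{self.value:g}"
        return f"{self.censor}{self.value:g}"

    @classmethod
    def parse(cls, text: str) -> "CensoredValue":
        text = text.strip()
        if text and text[0] in "<>":
            return cls(float(text[1:]), text[0])
        return cls(float(text))

    def sort_key(self) -> float:
        """Order censored values by their knowable magnitude.

        "<x" sorts just below x, ">x" just above x; used when picking the
        most microbe-rich segment of a patient.
        """
        if self.censor == "<":
            return math.nextafter(self.value, -math.inf)
        if self.censor == ">":
            return math.nextafter(self.value, math.inf)
        return self.value


@dataclass(frozen=True)
class CultureProtocolParams:
    """Swab-kit volumes governing the colony-count -> cfu/ml conversion.

    Defaults: swab absorbs 150 ul of sample into 1050 ul of transport medium
    (1:8 dilution) and 50 ul are plated, so one colony represents
    1 x 8 x 20 = 160 cfu/ml of the original sample.
    """

    swab_uptake_ul: float = 150.0
    medium_volume_ul: float = 1050.0
    plated_volume_ul: float = 50.0

    def __post_init__(self) -> None:
        if min(self.swab_uptake_ul, self.medium_volume_ul, self.plated_volume_ul) <= 0:
            raise ValueError("all protocol volumes must be positive")

    @property
    def dilution_factor(self) -> float:
        return (self.swab_uptake_ul + self.medium_volume_ul) / self.swab_uptake_ul

    @property
    def plating_factor(self) -> float:
        return 1000.0 / self.plated_volume_ul

    @property
    def cfu_per_colony(self) -> float:
        return self.dilution_factor * self.plating_factor


@dataclass(frozen=True)
class MolecularProtocolParams:
    """Constants linking qPCR target copies per reaction to genomes/ml.

    sample_dilution is the overall 1:833 dilution of the clinical sample
    through collection and DNA extraction; it already folds in the
    template volume, so genomes/ml = genomes/reaction x sample_dilution.
    rrn_copies_per_genome converts 16S target copies to genome equivalents.
    """

    sample_dilution: float = 833.0
    rrn_copies_per_genome: float = 4.0
    template_volume_ul: float = 2.0

    def __post_init__(self) -> None:
        if min(self.sample_dilution, self.rrn_copies_per_genome, self.template_volume_ul) <= 0:
            raise ValueError("all molecular protocol parameters must be positive")


@dataclass(frozen=True)
class StandardCurve:
    """Fitted Ct = slope * log10(copies/reaction) + intercept, with linear range.

    loq_ct is the mean Ct at the lowest dilution step still inside the linear
    range; run_offset is the per-run shift from the calibration standard and
    is added to every prediction.
    """

    slope: float
    intercept: float
    linear_range: tuple[float, float]  # (min_copies, max_copies) per reaction
    loq_ct: float
    run_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")
        if not self.linear_range[0] < self.linear_range[1]:
            raise ValueError("linear range must have min < max")

    @property
    def efficiency(self) -> float:
        """Amplification efficiency implied by the slope (1.0 = 100%)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def predict_ct(self, copies_per_reaction: float) -> float:
        if copies_per_reaction <= 0:
            return NO_AMPLIFICATION
        return self.slope * math.log10(copies_per_reaction) + self.intercept + self.run_offset

    def invert_ct(self, ct: float) -> float:
        """Copies per reaction implied by an observed Ct."""
        return 10.0 ** ((ct - self.intercept - self.run_offset) / self.slope)


@dataclass(frozen=True)
class QuantResult:
    """Per-sample absolute load by culture and by qPCR."""

    sample_id: str
    cfu_per_ml: CensoredValue | None = None
    culture_category: str | None = None
    genomes_per_ml: CensoredValue | None = None
    genome_category: str | None = None


def cfu_per_ml(
    colony_count: Union[int, str],
    protocol: CultureProtocolParams | None = None,
) -> CensoredValue:
    """Convert a plate colony count (or ">100") to cfu/ml of original sample.

    0 colonies is below the detection limit and reported "<160"; plates too
    dense to count (">100") exceed the upper quantification limit (">1.6e4").
    """
    protocol = protocol or CultureProtocolParams()
    per_colony = protocol.cfu_per_colony
    if isinstance(colony_count, str):
        text = colony_count.strip()
        if not text.startswith(">"):
            raise ValueError(f"unrecognized colony count {colony_count!r}")
        bound = float(text[1:])
        return CensoredValue(bound * per_colony, ">")
    if colony_count < 0:
        raise ValueError("colony count must be non-negative")
    if colony_count == 0:
        return CensoredValue(per_colony, "<")
    return CensoredValue(colony_count * per_colony)


#: category labels in increasing load order; edges at 160 / 1600 / 8000 / 16000 cfu/ml
CULTURE_CATEGORIES: tuple[str, ...] = (
    "no growth",
    "single colonies/broth only",
    "sparse growth",
    "moderate growth",
    "abundant growth",
)


def culture_category(cfu_value: CensoredValue) -> str:
    """Map a (possibly censored) cfu/ml value to its reporting category.

    Bins: <160 / 160-<1600 / 1600-<8000 / 8000-16000 (100 colonies lands
    exactly on 1.6e4, still countable) / >16000.
    """
    if cfu_value.censor == "<":
        return "no growth"
    if cfu_value.censor == ">":
        return "abundant growth"
    v = cfu_value.value
    if v < 160:
        return "no growth"
    if v < 1600:
        return "single colonies/broth only"
    if v < 8000:
        return "sparse growth"
    if v <= 16000:
        return "moderate growth"
    return "abundant growth"


def genomes_per_ul_from_mass(dna_ng_per_ul: float, genome_size_bp: float) -> float:
    """Genome equivalents per microliter from a DNA mass concentration.

    Uses 650 g/mol as the average dsDNA base-pair mass.
    """
    if dna_ng_per_ul <= 0 or genome_size_bp <= 0:
        raise ValueError("mass concentration and genome size must be positive")
    grams_per_genome = genome_size_bp * DSDNA_BP_MASS_G_PER_MOL / AVOGADRO
    ng_per_genome = grams_per_genome * 1e9
    return dna_ng_per_ul / ng_per_genome


def fit_standard_curve(
    dilution_series: Sequence[tuple[float, Sequence[float]]],
    residual_tolerance_ct: float = 0.5,
) -> StandardCurve:
    """Fit the standard curve over the maximal linear stretch of a dilution series.

    dilution_series: (copies_per_reaction, replicate Cts) per step; Cts that
    are the no-amplification sentinel are ignored within a step, and steps
    with no finite Ct are treated as plateaued (outside the linear range).

    The line is least squares of mean Ct on log10(copies) over the longest
    run of steps, starting from the most concentrated, whose per-step
    residuals all stay within residual_tolerance_ct. The lowest retained step
    defines the LoQ Ct. At least 3 linear steps are required.
    """
    steps = []
    for copies, cts in dilution_series:
        if copies <= 0:
            raise ValueError("copies per reaction must be positive")
        finite = [c for c in cts if math.isfinite(c)]
        steps.append((copies, float(np.mean(finite)) if finite else math.nan))
    steps.sort(key=lambda s: -s[0])  # most concentrated first
    if len(steps) < 3:
        raise ValueError("need at least 3 dilution steps")

    best: tuple[int, float, float] | None = None  # (k, slope, intercept)
    for k in range(len(steps), 2, -1):
        sub = steps[:k]
        if any(math.isnan(ct) for _, ct in sub):
            continue
        x = np.log10([c for c, _ in sub])
        y = np.array([ct for _, ct in sub])
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        if np.max(np.abs(resid)) <= residual_tolerance_ct:
            best = (k, float(slope), float(intercept))
            break
    if best is None:
        raise ValueError("fewer than 3 dilution steps fall on a common line")
    k, slope, intercept = best
    low_copies, low_ct = steps[k - 1]
    return StandardCurve(
        slope=slope,
        intercept=intercept,
        linear_range=(low_copies, steps[0][0]),
        loq_ct=low_ct,
    )


def run_adjustment(
    standard_replicate_cts: Sequence[float],
    curve: StandardCurve,
    standard_copies: float,
) -> StandardCurve:
    """Re-anchor the curve to this run's calibration standard.

    run_offset = mean(observed Ct) - curve prediction at the standard's known
    copy number; the offset shifts every subsequent prediction/inversion.
    """
    if len(standard_replicate_cts) == 0:
        raise ValueError("need at least one standard replicate")
    base = replace(curve, run_offset=0.0)
    offset = float(np.mean(standard_replicate_cts)) - base.predict_ct(standard_copies)
    return replace(curve, run_offset=offset)


def loq_genomes_per_ml(curve: StandardCurve, protocol: MolecularProtocolParams) -> float:
    """Genomes/ml of original sample at the lowest linear dilution step."""
    genomes_per_rxn = curve.linear_range[0] / protocol.rrn_copies_per_genome
    return genomes_per_rxn * protocol.sample_dilution


def genomes_per_ml(
    ct: float,
    curve: StandardCurve,
    protocol: MolecularProtocolParams | None = None,
) -> CensoredValue:
    """Invert an observed Ct to genomes/ml; censor below the LoQ.

    Ct values beyond the LoQ Ct (after the run offset), and no-amplification
    reactions, are reported "<LoQ" where LoQ is the lowest linear step
    expressed in genomes/ml.
    """
    protocol = protocol or MolecularProtocolParams()
    loq = loq_genomes_per_ml(curve, protocol)
    if not math.isfinite(ct) or ct > curve.loq_ct + curve.run_offset:
        return CensoredValue(loq, "<")
    copies = curve.invert_ct(ct)
    genomes_per_rxn = copies / protocol.rrn_copies_per_genome
    return CensoredValue(genomes_per_rxn * protocol.sample_dilution)


#: slope of an ideal 100%-efficiency standard curve, Ct per log10(copies)
IDEAL_SLOPE = -1.0 / math.log10(2.0)

#: the assay's calibration standard (S. pneumoniae genomic DNA): genome
#: equivalents per reaction at the run standard, and the stock concentration
#: implied by fluorometry (reported to 3 significant figures)
STANDARD_GENOMES_PER_RXN = 33.8
CALIBRATION_STOCK_GENOMES_PER_UL = 1.69e7
CALIBRATION_LOQ_CT = 34.17


def calibration_curve(
    protocol: MolecularProtocolParams | None = None,
    slope: float = IDEAL_SLOPE,
) -> StandardCurve:
    """The assay's reference standard curve from its genomic-DNA calibration.

    A ten-fold dilution series of quantified S. pneumoniae DNA (stock 1.69e7
    genomes/ul) is linear down to 1.69 genomes/ul, i.e. with 2 ul of template
    and 4 rRNA operons per genome about 14 target copies per reaction, at
    Ct 34.17. The curve is anchored there with the ideal -3.3219 slope.
    """
    protocol = protocol or MolecularProtocolParams()
    copies_per_genome_ul = protocol.template_volume_ul * protocol.rrn_copies_per_genome
    floor_copies = 1.69 * copies_per_genome_ul  # lowest linear step
    top_copies = CALIBRATION_STOCK_GENOMES_PER_UL / 10.0 * copies_per_genome_ul
    intercept = CALIBRATION_LOQ_CT - slope * math.log10(floor_copies)
    return StandardCurve(
        slope=slope,
        intercept=intercept,
        linear_range=(floor_copies, top_copies),
        loq_ct=CALIBRATION_LOQ_CT,
    )


def calibration_dilution_series(
    curve: StandardCurve | None = None,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    plateau_ct: float = 36.0,
    seed: int = 0,
) -> list[tuple[float, list[float]]]:
    """Synthesize the nine-step ten-fold dilution series used for curve fitting.

    Steps 1-7 (1.69e6 down to 1.69 genomes/ul) lie on the curve; the two most
    dilute steps plateau near plateau_ct, reproducing loss of linearity below
    ~14 copies per reaction.
    """
    curve = curve or calibration_curve()
    rng = np.random.default_rng(seed)
    series = []
    for step in range(1, 10):
        genomes_per_ul = CALIBRATION_STOCK_GENOMES_PER_UL / 10.0**step
        copies = genomes_per_ul * 8.0  # 2 ul template x 4 operons
        base = curve.predict_ct(copies) if step <= 7 else plateau_ct
        cts = [base + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0) for _ in range(n_replicates)]
        series.append((copies, cts))
    return series


#: (label, lower edge inclusive, upper edge exclusive) in genomes/ml
GENOME_BINS: tuple[tuple[str, float, float], ...] = (
    ("<2.9e3", 0.0, 2.9e3),
    ("2.9e3-<1e4", 2.9e3, 1e4),
    ("1e4-<1e5", 1e4, 1e5),
    ("1e5-<1e6", 1e5, 1e6),
)


def genome_bin(value: CensoredValue) -> str:
    """Bin a genomes/ml estimate into the molecular reporting categories.

    Values at or above 1e6 (not observed in practice for these samples) fall
    into the highest bin with a warning.
    """
    if value.censor == "<":
        return GENOME_BINS[0][0]
    v = value.sort_key()
    for label, lo, hi in GENOME_BINS:
        if lo <= v < hi:
            return label
    import warnings

    warnings.warn(f"genomes/ml {v:g} above the highest reporting bin", stacklevel=2)
    return GENOME_BINS[-1][0]
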