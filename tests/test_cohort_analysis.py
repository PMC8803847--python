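"""Patient-level merging, prevalence and core-microbiota sets, quantity
binning by the richest segment, rank aggregation, and concordance."""

import itertools

import pytest

from jejuquant.cohort_analysis import (
    CoreConfig,
    PatientProfile,
    compare_culture_sequencing,
    compare_frequency_tables,
    core_microbiota,
    fraction_below,
    merge_segments,
    patient_quant_category,
    species_frequency,
)
from jejuquant.decontamination import SpeciesProfile
from jejuquant.quantification import (
    CensoredValue,
    GENOME_BINS,
    QuantResult,
    genome_bin,
)


def _patient(pid, prox=None, mid=None):
    profiles = {}
    if prox is not None:
        profiles["proximal"] = SpeciesProfile(f"{pid}-proximal", prox)
    if mid is not None:
        profiles["mid"] = SpeciesProfile(f"{pid}-mid", mid)
    return merge_segments(pid, profiles)


class TestMergeSegments:
    def test_presence_is_union(self):
        pat = _patient("P1", {"A sp": 5}, {"B sp": 3})
        assert pat.species_present == {"A sp", "B sp"}

    def test_species_in_one_segment_is_present(self):
        pat = _patient("P1", {"A sp": 5}, {})
        assert "A sp" in pat.species_present

    def test_empty_segments_empty_patient(self):
        assert _patient("P1", {}, {}).species_present == set()

    def test_identical_segments_idempotent(self):
        pat = _patient("P1", {"A sp": 5}, {"A sp": 9})
        assert pat.species_present == {"A sp"}

    def test_mismatched_patient_ids_rejected(self):
        profiles = {
            "proximal": SpeciesProfile("P1-proximal", {}),
            "mid": SpeciesProfile("P2-mid", {}),
        }
        with pytest.raises(ValueError):
            merge_segments("P1", profiles)


class TestSpeciesFrequency:
    def test_fraction_of_patients(self):
        patients = [
            _patient(f"P{i}", {"A sp": 1} if i < 29 else {}, {}) for i in range(60)
        ]
        freq = species_frequency(patients)
        assert freq["A sp"] == pytest.approx(29 / 60)

    def test_ubiquitous_species_at_one(self):
        patients = [_patient(f"P{i}", {"A sp": 1}, None) for i in range(5)]
        assert species_frequency(patients)["A sp"] == 1.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            species_frequency([])


class TestCoreMicrobiota:
    FREQ = {"A sp": 0.48, "B sp": 0.47, "C sp": 0.45, "D sp": 0.42, "E sp": 0.40,
            "F sp": 0.30, "G sp": 0.10}

    def test_no_core_above_50pct_when_max_is_48(self):
        assert core_microbiota(self.FREQ, CoreConfig(0.50)) == []

    def test_exactly_five_species_above_30pct(self):
        core = core_microbiota(self.FREQ, CoreConfig(0.30))
        assert core == ["A sp", "B sp", "C sp", "D sp", "E sp"]

    def test_threshold_is_strict(self):
        # F sp sits exactly at 0.30 and is excluded
        assert "F sp" not in core_microbiota(self.FREQ, CoreConfig(0.30))

    def test_core_size_weakly_decreasing_in_threshold(self):
        sizes = [len(core_microbiota(self.FREQ, CoreConfig(t))) for t in (0.05, 0.3, 0.45, 0.5)]
        assert sizes == sorted(sizes, reverse=True)


class TestPatientQuantCategory:
    def test_max_segment_wins(self):
        quant = {
            "proximal": QuantResult("P1-proximal", genomes_per_ml=CensoredValue(9e3)),
            "mid": QuantResult("P1-mid", genomes_per_ml=CensoredValue(2e5)),
        }
        assert patient_quant_category(quant)["molecular"] == "1e5-<1e6"

    def test_both_below_loq(self):
        quant = {
            "proximal": QuantResult("P1-proximal", genomes_per_ml=CensoredValue(2816, "<")),
            "mid": QuantResult("P1-mid", genomes_per_ml=CensoredValue(2816, "<")),
        }
        assert patient_quant_category(quant)["molecular"] == "<2.9e3"

    def test_culture_no_growth_plus_single_colony(self):
        quant = {
            "proximal": QuantResult("P1-proximal", cfu_per_ml=CensoredValue(160, "<")),
            "mid": QuantResult("P1-mid", cfu_per_ml=CensoredValue(160)),
        }
        assert patient_quant_category(quant)["culture"] == "single colonies/broth only"

    def test_matches_bin_of_max_over_all_bin_pairs(self):
        """Brute force: for every ordered pair of molecular bins, the patient
        category equals the bin of the larger representative value."""
        reps = [CensoredValue(2816, "<"), CensoredValue(5e3), CensoredValue(5e4), CensoredValue(5e5)]
        for a, b in itertools.product(reps, repeat=2):
            quant = {
                "proximal": QuantResult("P1-proximal", genomes_per_ml=a),
                "mid": QuantResult("P1-mid", genomes_per_ml=b),
            }
            expected = genome_bin(max([a, b], key=CensoredValue.sort_key))
            assert patient_quant_category(quant)["molecular"] == expected

    def test_no_segments_rejected(self):
        with pytest.raises(ValueError):
            patient_quant_category({})


class TestAggregateRank:
    LINEAGE = {
        "Streptococcus mitis": ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
        "Streptococcus oralis": ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
        "Rothia mucilaginosa": ("Actinobacteria", "Actinomycetia", "Micrococcales", "Micrococcaceae", "Rothia"),
    }

    def test_single_species_sample(self):
        from jejuquant.cohort_analysis import aggregate_rank

        df = aggregate_rank([SpeciesProfile("S1", {"Rothia mucilaginosa": 50})], self.LINEAGE)
        assert df.loc["S1", "Rothia"] == 1.0

    def test_genus_additivity(self):
        from jejuquant.cohort_analysis import aggregate_rank

        prof = SpeciesProfile(
            "S1",
            {"Streptococcus mitis": 30, "Streptococcus oralis": 20, "Rothia mucilaginosa": 50},
        )
        df = aggregate_rank([prof], self.LINEAGE)
        assert df.loc["S1", "Streptococcus"] == pytest.approx(0.5)
        assert df.loc["S1", "Rothia"] == pytest.approx(0.5)

    def test_rows_sum_to_one_with_slash_groups_and_phylum(self):
        from jejuquant.cohort_analysis import aggregate_rank

        prof = SpeciesProfile("S1", {"Streptococcus mitis/oralis": 40, "Rothia mucilaginosa": 60})
        df = aggregate_rank([prof], self.LINEAGE, rank="phylum")
        assert df.loc["S1"].sum() == pytest.approx(1.0)
        assert df.loc["S1", "Firmicutes"] == pytest.approx(0.4)

    def test_unknown_species_goes_to_unresolved_with_warning(self):
        from jejuquant.cohort_analysis import aggregate_rank

        with pytest.warns(UserWarning):
            df = aggregate_rank([SpeciesProfile("S1", {"Mystery sp": 10})], self.LINEAGE, "phylum")
        assert df.loc["S1", "unresolved"] == 1.0


class TestConcordance:
    def test_slash_group_membership_counts_as_agreement(self):
        pat = _patient("P1", {"Streptococcus mitis/oralis": 100}, None)
        table = compare_culture_sequencing([pat], {"P1-proximal": ["Streptococcus mitis"]})
        row = table.loc["P1-proximal"]
        assert (row["both"], row["culture_only"], row["sequencing_only"]) == (1, 0, 0)

    def test_culture_negative_sample_all_sequencing_only(self):
        pat = _patient("P1", {"A sp": 10, "B sp": 5}, None)
        table = compare_culture_sequencing([pat], {})
        assert table.loc["P1-proximal", "sequencing_only"] == 2

    def test_empty_inputs_zero_counts(self):
        table = compare_culture_sequencing([], {})
        assert table.loc["overall"].sum() == 0


class TestCompareFrequencyTables:
    def test_outer_join_fills_zero(self):
        df = compare_frequency_tables({"A sp": 0.5}, {"B sp": 0.2})
        assert set(df["species"]) == {"A sp", "B sp"}
        assert df.set_index("species").loc["A sp", "freq_b"] == 0.0

    def test_identical_maps_identical_columns(self):
        f = {"A sp": 0.5, "B sp": 0.1}
        df = compare_frequency_tables(f, f)
        assert (df["freq_a"] == df["freq_b"]).all()

    def test_sorted_by_first_table_descending(self):
        df = compare_frequency_tables({"A sp": 0.1, "B sp": 0.9}, {})
        assert list(df["species"]) == ["B sp", "A sp"]


def test_fraction_below_patient_counts():
    counts = {"a": 31, "b": 22, "c": 2, "d": 2, "e": 3}
    assert fraction_below(counts, ["a", "b"]) == pytest.approx(53 / 60)
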