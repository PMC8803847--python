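"""The synthetic cohort generator: determinism, designed reference structure,
load-distribution calibration, read/chimera statistics, controls, culture and
qPCR observation models."""

import math

import numpy as np
import pytest

from jejuquant._alignment import identity
from jejuquant.quantification import NO_AMPLIFICATION, calibration_curve
from jejuquant.read_processing import merge_pairs
from jejuquant.synthetic_data import (
    CANONICAL_CONTAMINANTS,
    RANKS,
    SPIKE_SPECIES,
    CohortDesign,
    CommunityTruth,
    control_truths,
    generate_reference_db,
    simulate_cohort_truth,
    simulate_controls,
    simulate_culture,
    simulate_qpcr,
    simulate_reads,
)


class TestReferenceDB:
    def test_seeded_determinism(self):
        a = generate_reference_db(50, seed=1)
        b = generate_reference_db(50, seed=1)
        assert [e.sequence for e in a.entries] == [e.sequence for e in b.entries]
        assert [e.cultivable for e in a.entries] == [e.cultivable for e in b.entries]

    def test_near_identical_pair_divergence_below_0p8pct(self, db):
        a = db["Streptococcus mitis"].sequence
        b = db["Streptococcus oralis"].sequence
        mism = sum(x != y for x, y in zip(a, b))
        assert len(a) == len(b)
        assert 0 < mism / len(a) < 0.008

    def test_identical_pair(self, db):
        assert db["Staphylococcus capitis"].sequence == db["Staphylococcus epidermidis"].sequence

    def test_canonical_contaminants_and_spike_present(self, db):
        for sp in CANONICAL_CONTAMINANTS + (SPIKE_SPECIES,):
            assert sp in db

    def test_lineages_have_exactly_the_five_ranks(self, db):
        assert all(len(e.lineage) == len(RANKS) for e in db.entries)

    def test_sequences_are_plain_dna(self, db):
        assert all(set(e.sequence) <= set("ACGT") for e in db.entries)

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            generate_reference_db(5, seed=0)

    def test_unrelated_species_well_separated(self, db):
        # random amplicons sit far below the 97% genus threshold
        a = db["Escherichia coli"].sequence
        b = db["Fusobacterium nucleatum"].sequence
        assert identity(a, b) < 0.9


class TestCohortTruth:
    def test_zero_sparsity_gives_sterile_cohort(self, db):
        d = CohortDesign(n_patients=5, sparsity=0.0, seed=2)
        truths = simulate_cohort_truth(d, db)
        assert len(truths) == 10
        assert all(t.total_conc == 0 for t in truths)

    def test_seeded_determinism(self, db):
        d = CohortDesign(n_patients=4, seed=11)
        a = simulate_cohort_truth(d, db)
        b = simulate_cohort_truth(d, db)
        assert [(t.sample_id, t.species_conc) for t in a] == [
            (t.sample_id, t.species_conc) for t in b
        ]

    def test_contaminants_and_spike_never_in_truth(self, db):
        d = CohortDesign(n_patients=30, seed=3)
        excluded = set(CANONICAL_CONTAMINANTS) | {SPIKE_SPECIES}
        for t in simulate_cohort_truth(d, db):
            assert not (set(t.species_conc) & excluded)

    def test_patient_maxima_below_loq_near_40pct(self, db):
        """Monte-Carlo calibration check: ~40% of patient-level maxima fall
        below the 2.9e3 genomes/ml quantification limit (200 patients)."""
        d = CohortDesign(n_patients=200, seed=42)
        truths = simulate_cohort_truth(d, db)
        totals = np.array([t.total_conc for t in truths]).reshape(-1, 2)
        frac = (totals.max(axis=1) < 2.9e3).mean()
        target = 0.40
        tol = 3 * math.sqrt(target * (1 - target) / 200)
        assert abs(frac - target) < tol


class TestSimulateReads:
    def test_noiseless_single_species_reads_reconstruct_amplicon(self, db):
        truth = CommunityTruth("S1", {"Escherichia coli": 1e5})
        r1, r2 = simulate_reads(truth, db, 50, error_rate=0, chimera_rate=0,
                                contaminant_profile={}, seed=4)
        merged = merge_pairs(r1, r2)
        amp = db["Escherichia coli"].sequence
        assert len(merged) == 50
        assert all(m.sequence == amp for m in merged)

    def test_zero_concentration_draws_only_contaminants(self, db):
        truth = CommunityTruth("S0", {})
        profile = {"Cutibacterium acnes": 1.0}
        r1, _ = simulate_reads(truth, db, 30, error_rate=0, chimera_rate=0,
                               contaminant_profile=profile, seed=5)
        amp = db["Cutibacterium acnes"].sequence
        assert all(str(rec.seq) == amp[:300] for rec in r1)

    def test_empty_truth_without_background_rejected(self, db):
        with pytest.raises(ValueError):
            simulate_reads(CommunityTruth("S0", {}), db, 10, contaminant_profile={}, seed=0)

    def test_headers_carry_sample_id_not_species(self, db):
        truth = CommunityTruth("P001-mid", {"Escherichia coli": 1e4})
        r1, r2 = simulate_reads(truth, db, 5, contaminant_profile={}, seed=6)
        for rec in r1 + r2:
            assert rec.id.startswith("P001-mid:")
            assert "coli" not in rec.id and "coli" not in rec.description

    def test_pairs_are_index_matched(self, db):
        truth = CommunityTruth("S1", {"Escherichia coli": 1e4})
        r1, r2 = simulate_reads(truth, db, 20, contaminant_profile={}, seed=7)
        assert [a.id for a in r1] == [b.id for b in r2]

    def test_chimera_fraction_within_3_binomial_sd(self, db):
        """At chimera_rate 0.05 the fraction of spliced (non-parental) merged
        reads over 10,000 pairs stays within 3 binomial SDs of 0.05."""
        truth = CommunityTruth("S1", {"Escherichia coli": 5e4, "Veillonella parvula": 5e4})
        r1, r2 = simulate_reads(truth, db, 10_000, error_rate=0, chimera_rate=0.05,
                                contaminant_profile={}, seed=8)
        merged = merge_pairs(r1, r2)
        parents = {db["Escherichia coli"].sequence, db["Veillonella parvula"].sequence}
        frac = sum(m.sequence not in parents for m in merged) / len(merged)
        sd = math.sqrt(0.05 * 0.95 / 10_000)
        assert abs(frac - 0.05) < 3 * sd


class TestControls:
    def test_negative_controls_contain_only_background_species(self, db):
        d = CohortDesign(n_patients=0, n_negative_controls=2, n_spiked_controls=0,
                         read_pairs_per_sample=200, error_rate=0.0, chimera_rate=0.0, seed=9)
        out = simulate_controls(d, db)
        background = {db[sp].sequence[:300] for sp in d.contaminant_profile}
        for r1, _ in out.values():
            assert {str(rec.seq) for rec in r1} <= background

    def test_spike_is_majority_of_spiked_control_reads(self, db):
        d = CohortDesign(n_patients=0, n_negative_controls=0, n_spiked_controls=2,
                         read_pairs_per_sample=500, error_rate=0.0, chimera_rate=0.0, seed=10)
        out = simulate_controls(d, db)
        spike_prefix = db[SPIKE_SPECIES].sequence[:300]
        for r1, _ in out.values():
            frac = sum(str(rec.seq) == spike_prefix for rec in r1) / len(r1)
            assert frac > 0.5

    def test_no_controls_requested_gives_empty_output(self, db):
        d = CohortDesign(n_patients=0, n_negative_controls=0, n_spiked_controls=0, seed=0)
        assert simulate_controls(d, db) == {}
        assert control_truths(d) == []


class TestCulture:
    def test_mean_colonies_one_at_160_cfu_per_ml(self, db):
        sp = next(e.species for e in db.entries if e.cultivable)
        truth = CommunityTruth("S1", {sp: 160.0})
        counts = [simulate_culture(truth, db, seed=s).get(sp, 0) for s in range(2000)]
        mean = np.mean(counts)
        assert abs(mean - 1.0) < 3 * math.sqrt(1.0 / 2000)

    def test_zero_concentration_never_grows(self, db):
        truth = CommunityTruth("S1", {})
        assert simulate_culture(truth, db, seed=1) == {}

    def test_dense_plate_reported_uncountable(self, db):
        sp = next(e.species for e in db.entries if e.cultivable)
        truth = CommunityTruth("S1", {sp: 1.6e5})  # Poisson mean 1000
        assert simulate_culture(truth, db, seed=2)[sp] == ">100"

    def test_noncultivable_species_never_grow(self, db):
        sp = next(e.species for e in db.entries if not e.cultivable)
        truth = CommunityTruth("S1", {sp: 1.6e5})
        assert sp not in simulate_culture(truth, db, seed=3)


class TestQpcr:
    def test_loq_concentration_reads_ct_34_17(self):
        truth = CommunityTruth("S1", {"X": 2816.0})
        ct = simulate_qpcr(truth, calibration_curve(), noise_sd=0.0)
        assert ct == pytest.approx(34.17, abs=0.005)

    def test_tenfold_increase_drops_ct_by_one_log_slope(self):
        curve = calibration_curve()
        a = simulate_qpcr(CommunityTruth("S", {"X": 1e4}), curve, noise_sd=0.0)
        b = simulate_qpcr(CommunityTruth("S", {"X": 1e5}), curve, noise_sd=0.0)
        assert a - b == pytest.approx(abs(curve.slope), abs=1e-9)

    def test_sterile_sample_never_amplifies(self):
        assert simulate_qpcr(CommunityTruth("S", {}), calibration_curve()) == NO_AMPLIFICATION

    def test_below_linear_range_reports_at_or_beyond_loq_ct(self):
        curve = calibration_curve()
        ct = simulate_qpcr(CommunityTruth("S", {"X": 100.0}), curve, noise_sd=0.2, seed=1)
        assert ct > curve.loq_ct
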