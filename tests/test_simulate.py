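"""Synthetic-panel generator: distributional, determinism and planting checks."""

import numpy as np
import pytest

from kaspanel.io import MISSING, write_vcf, read_vcf
from kaspanel.simulate import (AnnotationModel, ParameterError, PopulationModel,
                               plant_duplicates, simulate_flank_template,
                               simulate_panel, simulate_vcf)
from kaspanel.screening import hard_filter, flank_isolation
from kaspanel.core_markers import duplicate_groups


class TestSimulatePanel:
    def test_hardy_weinberg_dosage_mean(self):
        # single population with allele frequency pinned at 0.5: mean alt
        # dosage must match the expectation 2p = 1 within 3 standard errors
        model = PopulationModel(n_pops=1, n_loci=1, n_samples=10_000,
                                freq_prior=(1, 1), freq_bounds=(0.499, 0.501),
                                admix_alpha=1.0, seed=42)
        panel = simulate_panel(model)
        mean = panel.genotypes.dosage.astype(float).mean()
        se = np.sqrt(0.5 / 10_000)  # var(dosage) = 2pq = 0.5
        assert abs(mean - 1.0) < 3 * se + 0.004  # 0.004 = 2×freq_bounds width

    def test_zero_missing_rate_gives_no_missing(self):
        panel = simulate_panel(PopulationModel(2, 50, 40, missing_rate=0.0, seed=1))
        assert not (panel.genotypes.dosage == MISSING).any()

    def test_missing_fraction_near_rate(self):
        rate = 0.05
        panel = simulate_panel(PopulationModel(2, 100, 200, missing_rate=rate, seed=3))
        frac = (panel.genotypes.dosage == MISSING).mean()
        se = np.sqrt(rate * (1 - rate) / (100 * 200))
        assert abs(frac - rate) < 3 * se

    def test_seed_determinism(self):
        model = PopulationModel(n_pops=8, n_loci=32, n_samples=280,
                                freq_prior=(0.2, 0.2), admix_alpha=0.05, seed=5)
        a, b = simulate_panel(model), simulate_panel(model)
        assert np.array_equal(a.genotypes.dosage, b.genotypes.dosage)
        assert np.array_equal(a.true_Q, b.true_Q)

    def test_q_rows_sum_to_one_and_p_in_open_interval(self):
        panel = simulate_panel(PopulationModel(4, 30, 50, seed=2))
        assert np.allclose(panel.true_Q.sum(axis=1), 1.0, atol=1e-9)
        assert ((panel.true_P > 0) & (panel.true_P < 1)).all()

    @pytest.mark.parametrize("kwargs", [
        dict(n_pops=0, n_loci=1, n_samples=1),
        dict(n_pops=1, n_loci=1, n_samples=1, missing_rate=1.0),
        dict(n_pops=1, n_loci=1, n_samples=1, admix_alpha=0.0),
    ])
    def test_invalid_model_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            PopulationModel(**kwargs)


class TestPlantDuplicates:
    def test_planted_quadruple_has_identical_rows(self):
        panel = simulate_panel(PopulationModel(2, 30, 50, seed=9))
        planted = plant_duplicates(panel, [{0, 1, 2, 3}])
        d = planted.genotypes.dosage
        for i in (1, 2, 3):
            assert np.array_equal(d[0], d[i])

    def test_empty_groups_is_identity(self):
        panel = simulate_panel(PopulationModel(2, 30, 50, seed=9))
        planted = plant_duplicates(panel, [])
        assert np.array_equal(panel.genotypes.dosage, planted.genotypes.dosage)

    def test_two_planted_pairs_recovered_by_duplicate_detection(self):
        panel = simulate_panel(PopulationModel(2, 40, 50, missing_rate=0.0, seed=13))
        planted = plant_duplicates(panel, [{5, 6}, {7, 8}])
        groups = duplicate_groups(planted.genotypes)
        names = {frozenset(g) for g in map(tuple, groups)}
        s = planted.genotypes.samples
        assert frozenset((s[5], s[6])) in names
        assert frozenset((s[7], s[8])) in names
        assert len(groups) == 2

    def test_overlapping_groups_rejected(self):
        panel = simulate_panel(PopulationModel(2, 10, 20, seed=1))
        with pytest.raises(ParameterError, match="overlap"):
            plant_duplicates(panel, [{0, 1}, {1, 2}])


class TestSimulateVcf:
    CHROMS = {f"chr{c:02d}": 2_000_000 for c in range(1, 13)}

    def test_all_passing_unclustered_survive_flank_filter(self):
        sim = simulate_vcf(200, 10, self.CHROMS, AnnotationModel(),
                           clustered_fraction=0.0, seed=4)
        kept = flank_isolation(sorted(sim.records, key=lambda r: (r.chrom, r.pos)),
                               flank_bp=100)
        assert len(kept) == len(sim.records)
        assert all(hard_filter(r)[0] for r in sim.records)

    def test_planted_hard_filter_violations_counted_exactly(self):
        sim = simulate_vcf(300, 10, self.CHROMS,
                           AnnotationModel(violate_fraction={"QD": 0.1}),
                           clustered_fraction=0.0, seed=8)
        failing = [i for i, r in enumerate(sim.records) if not hard_filter(r)[0]]
        assert failing == sim.planted_violations["QD"]
        assert len(failing) == 30

    def test_clustered_sites_flagged_non_isolated(self):
        sim = simulate_vcf(100, 5, self.CHROMS, AnnotationModel(),
                           clustered_fraction=0.2, seed=6)
        recs = sorted(sim.records, key=lambda r: (r.chrom, r.pos))
        kept = {(r.chrom, r.pos) for r in flank_isolation(recs, 100)}
        for i in sim.clustered_indices:
            r = sim.records[i]
            assert (r.chrom, r.pos) not in kept

    def test_round_trip_through_vcf_file(self, tmp_path):
        sim = simulate_vcf(50, 8, self.CHROMS, AnnotationModel(),
                           clustered_fraction=0.1, seed=2)
        path = tmp_path / "sim.vcf"
        write_vcf(sim.records, path, [f"S{i}" for i in range(8)])
        back = read_vcf(path)
        assert len(back) == len(sim.records)
        for a, b in zip(sim.records, back):
            assert (a.chrom, a.pos, a.ref, a.alts) == (b.chrom, b.pos, b.ref, b.alts)
            assert a.sample_calls == b.sample_calls
            assert a.sample_depths == b.sample_depths
            for key in ("QD", "MQ", "MQRankSum", "ReadPosRankSum"):
                assert b.info[key] == pytest.approx(a.info[key], abs=5e-3)


class TestFlankTemplate:
    def test_length_and_center(self):
        t = simulate_flank_template(0, flank_len=100, seed=1)
        assert len(t.seq) == 201
        assert t.seq[100] == t.ref

    def test_gc_zero_gives_at_only(self):
        t = simulate_flank_template(0, flank_len=50, gc_target=0.0, seed=2)
        assert set(t.seq) <= {"A", "T"}
        assert {t.ref, t.alt} <= {"A", "T"}

    def test_seed_determinism(self):
        a = simulate_flank_template(0, 60, 0.4, seed=77)
        b = simulate_flank_template(0, 60, 0.4, seed=77)
        assert a.seq == b.seq and (a.ref, a.alt) == (b.ref, b.alt)

    def test_short_flank_rejected(self):
        with pytest.raises(ParameterError):
            simulate_flank_template(0, flank_len=10, seed=1)
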