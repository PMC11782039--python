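"""Generator contracts: determinism, effect injection, missingness, PSMs."""

import numpy as np
import pandas as pd
import pytest

from plasmapipe.interface import PeptideQuery, k_sasa, map_peptide
from plasmapipe.io_formats import apply_two_peptide_rule
from plasmapipe.synthetic import (
    CohortDesign,
    EffectSpec,
    MissingnessSpec,
    ToyComplexSpec,
    apply_missingness,
    generate_cohort,
    generate_psm_table,
    generate_toy_complex,
)


class TestGenerateCohort:
    def test_same_seed_bit_identical(self):
        design = CohortDesign(group_sizes={"A": 4, "B": 4}, n_proteins=10,
                              seed=42)
        m1, man1 = generate_cohort(design, [])
        m2, man2 = generate_cohort(design, [])
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_series_equal(man1.assignments, man2.assignments)

    def test_no_effects_group_medians_agree(self):
        design = CohortDesign(group_sizes={"A": 50, "B": 50}, n_proteins=30,
                              seed=1)
        m, man = generate_cohort(design, [])
        med = np.log10(m.values).T.groupby(man.assignments).median().T
        # within sampling error of the per-cell scatter
        tol = 4 * design.sample_log_sd / np.sqrt(50)
        assert (np.abs(med["A"] - med["B"]) < tol).all()

    def test_noiseless_limit_exact_fold_change(self):
        design = CohortDesign(group_sizes={"A": 50, "B": 50}, n_proteins=5,
                              sample_log_sd=1e-12, seed=2)
        m, man = generate_cohort(design, [EffectSpec("P0001", "B", 2.0)])
        med = m.values.loc["P0001"].groupby(man.assignments).median()
        assert med["B"] / med["A"] == pytest.approx(2.0, rel=1e-9)

    def test_seeded_fold_change_recovery(self):
        design = CohortDesign(group_sizes={"A": 25, "B": 25}, n_proteins=50,
                              sample_log_sd=0.05, seed=7)
        m, man = generate_cohort(design, [EffectSpec("P0003", "B", 1.7)])
        med = m.values.loc["P0003"].groupby(man.assignments).median()
        assert med["B"] / med["A"] == pytest.approx(1.7, abs=0.15)

    def test_negative_fold_change_divides(self):
        design = CohortDesign(group_sizes={"A": 30, "B": 30}, n_proteins=5,
                              sample_log_sd=1e-12, seed=3)
        m, man = generate_cohort(design, [EffectSpec("P0002", "B", -4.0)])
        med = m.values.loc["P0002"].groupby(man.assignments).median()
        assert med["A"] / med["B"] == pytest.approx(4.0, rel=1e-9)

    def test_unknown_group_rejected_by_name(self):
        design = CohortDesign(group_sizes={"A": 3}, n_proteins=5, seed=0)
        with pytest.raises(ValueError, match="NOPE"):
            generate_cohort(design, [EffectSpec("P0001", "NOPE", 2.0)])

    def test_manifest_covers_every_sample_once(self):
        design = CohortDesign.default_study(seed=0, n_proteins=5)
        m, man = generate_cohort(design, [])
        assert list(man.assignments.index) == m.sample_ids
        assert man.assignments.index.is_unique


class TestApplyMissingness:
    def test_zero_rates_leave_all_cells(self, small_cohort):
        m, _ = small_cohort
        res = apply_missingness(
            m, MissingnessSpec(mcar_rate=0.0, mnar_logistic_slope=0.0),
            seed=1)
        assert not res.matrix.values.isna().any().any()

    def test_mcar_rate_matches_binomial_expectation(self):
        design = CohortDesign(group_sizes={"A": 50}, n_proteins=200, seed=4)
        m, _ = generate_cohort(design, [])
        res = apply_missingness(
            m, MissingnessSpec(mcar_rate=0.1, mnar_logistic_slope=0.0),
            seed=5)
        frac = res.matrix.values.isna().to_numpy().mean()
        assert frac == pytest.approx(0.10, abs=0.01)

    def test_mnar_removes_lower_intensities(self, small_cohort):
        m, _ = small_cohort
        res = apply_missingness(
            m, MissingnessSpec(mcar_rate=0.0, mnar_logistic_midpoint=6.0,
                               mnar_logistic_slope=2.0), seed=6)
        logs = np.log10(res.truth.values.to_numpy())
        mask = res.mask.to_numpy()
        assert mask.any() and (~mask).any()
        assert logs[mask].mean() < logs[~mask].mean()

    def test_rejects_prior_missingness(self, tiny_matrix):
        with pytest.raises(ValueError, match="already"):
            apply_missingness(tiny_matrix, MissingnessSpec(), seed=0)


class TestGeneratePSMTable:
    def test_zero_phospho_fraction_unmodified(self, small_cohort):
        m, _ = small_cohort
        psm = generate_psm_table(m, phospho_fraction=0.0, seed=1)
        assert (psm.rows["mod_type"] == "none").all()

    def test_every_protein_has_two_unique_peptides(self, small_cohort):
        m, _ = small_cohort
        psm = generate_psm_table(m, phospho_fraction=0.1, seed=2)
        assert apply_two_peptide_rule(psm) == set(m.protein_ids)

    def test_phospho_count_binomial(self, small_cohort):
        m, _ = small_cohort
        psm = generate_psm_table(m, phospho_fraction=0.2, seed=3)
        n = len(psm.rows)
        k = (psm.rows["mod_type"] != "none").sum()
        assert abs(k - 0.2 * n) < 2.5 * np.sqrt(n * 0.2 * 0.8)

    def test_modified_rows_carry_matching_site(self, small_cohort):
        m, _ = small_cohort
        psm = generate_psm_table(m, phospho_fraction=0.3, seed=4)
        mod = psm.rows[psm.rows["mod_type"] != "none"]
        by_type = {"SEP": "S", "TPO": "T", "PTR": "Y"}
        residues = [row.peptide[int(row.mod_site) - 1]
                    for row in mod.itertuples()]
        assert all(r == by_type[t] for r, t in zip(residues, mod["mod_type"]))

    def test_psm_intensities_sum_to_protein(self, small_cohort):
        m, _ = small_cohort
        psm = generate_psm_table(m, phospho_fraction=0.1, seed=5)
        sums = psm.rows.groupby(["protein_id", "sample_id"])["intensity"].sum()
        for (pid, sid), total in sums.items():
            assert total == pytest.approx(m.values.loc[pid, sid], rel=1e-9)


class TestToyComplex:
    def test_no_burial_gives_unit_k(self, toy_free):
        mapping = [m for m in map_peptide(PeptideQuery(toy_free.peptide),
                                          toy_free.structure)
                   if m.chain == "A"][0]
        assert k_sasa(mapping, toy_free.structure) == pytest.approx(
            1.0, abs=0.02)

    def test_half_burial_gives_half_k(self, toy_half):
        mapping = [m for m in map_peptide(PeptideQuery(toy_half.peptide),
                                          toy_half.structure)
                   if m.chain == "A"][0]
        assert k_sasa(mapping, toy_half.structure) == pytest.approx(
            0.5, abs=0.1)

    def test_near_total_burial_small_k(self):
        toy = generate_toy_complex(ToyComplexSpec(
            peptide_length=8, burial_fraction=0.95, seed=9))
        mapping = [m for m in map_peptide(PeptideQuery(toy.peptide),
                                          toy.structure) if m.chain == "A"][0]
        assert k_sasa(mapping, toy.structure) < 0.15

    def test_same_seed_identical_structures(self):
        spec = ToyComplexSpec(peptide_length=6, burial_fraction=0.3, seed=12)
        t1 = generate_toy_complex(spec)
        t2 = generate_toy_complex(spec)
        assert t1.peptide == t2.peptide
        pd.testing.assert_frame_equal(t1.structure.atoms, t2.structure.atoms)

    def test_k_monotone_as_partner_approaches(self):
        ks = []
        for offset in (12.0, 6.0, 3.0, 1.0, 0.0):
            toy = generate_toy_complex(ToyComplexSpec(
                peptide_length=6, burial_fraction=0.6, seed=2,
                partner_offset=offset))
            mapping = [m for m in map_peptide(PeptideQuery(toy.peptide),
                                              toy.structure)
                       if m.chain == "A"][0]
            ks.append(k_sasa(mapping, toy.structure))
        assert all(ks[i] >= ks[i + 1] - 1e-9 for i in range(len(ks) - 1))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ToyComplexSpec(peptide_length=2)
        with pytest.raises(ValueError):
            ToyComplexSpec(burial_fraction=1.5)
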