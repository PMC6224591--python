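import numpy as np
import pandas as pd
import pytest

from immunopep.constants import AMINO_ACIDS
from immunopep.motif import (
    PositionFrequencyMatrix,
    background_frequencies,
    enrichment_profile,
    length_distribution,
    motif_summary,
    omega_position,
    position_frequency_matrix,
)


class TestLengthDistribution:
    def test_single_nonamer(self):
        df = length_distribution(["LSSPVTKSF"])
        assert df.loc["9", "proportion"] == 1.0
        assert df["proportion"].sum() == pytest.approx(1.0)

    def test_lengths_outside_range_pool_into_other(self):
        df = length_distribution(["AAAA", "A" * 25, "A" * 9])
        assert df.loc["other", "count"] == 2

    def test_sampled_proportions_match_weights(self):
        # binomial CI oracle: with n=5000 each weight is recovered within
        # ~3*sqrt(p(1-p)/n) < 0.02
        from immunopep.simulate import RepertoireSpec, simulate_repertoire

        weights = {9: 0.6, 10: 0.25, 11: 0.15}
        spec = RepertoireSpec(
            n=5000, seed=9, length_weights=weights,
            contaminant_fraction=0.0, low_confidence_fraction=0.0,
        )
        df = length_distribution(simulate_repertoire(spec).sequence.tolist())
        for L, w in weights.items():
            assert df.loc[str(L), "proportion"] == pytest.approx(w, abs=0.02)

    def test_synthetic_cohort_mode_is_nonamer(self, b57_cohort):
        for rep in b57_cohort.values():
            df = length_distribution(rep)
            assert df["count"].idxmax() == "9"


class TestPositionFrequencyMatrix:
    def test_single_peptide_counts(self):
        pfm = position_frequency_matrix(["LSSPVTKSF"], 9)
        assert pfm.counts.loc[1, "L"] == 1
        assert pfm.counts.loc[1].sum() == 1

    def test_two_peptide_symmetry(self):
        pfm = position_frequency_matrix(["AAAAAAAAA", "CCCCCCCCC"], 9)
        assert (pfm.freqs["A"] == 0.5).all() and (pfm.freqs["C"] == 0.5).all()

    def test_no_peptides_of_length_raises(self):
        with pytest.raises(ValueError, match="length"):
            position_frequency_matrix(["AAAA"], 9)

    def test_frequencies_within_sampling_error_of_profile(self, nonamers_fixed_profile):
        seqs, prof = nonamers_fixed_profile
        pfm = position_frequency_matrix(seqs, 9)
        n = pfm.n
        f = pfm.freqs.to_numpy()
        tol = 3.0 * np.sqrt(prof * (1 - prof) / n) + 1e-12
        assert (np.abs(f - prof) <= tol).mean() > 0.99

    def test_rows_sum_to_n_and_freqs_to_one(self, b57_cohort):
        rep = next(iter(b57_cohort.values()))
        pfm = position_frequency_matrix(rep, 9)
        assert (pfm.counts.sum(axis=1) == pfm.n).all()
        assert np.allclose(pfm.freqs.sum(axis=1), 1.0, atol=1e-9)


class TestMotifSummary:
    def test_uniform_position_is_empty(self):
        counts = pd.DataFrame(1, index=[1], columns=list(AMINO_ACIDS))
        pfm = PositionFrequencyMatrix(1, counts, 20)
        assert motif_summary(pfm)[1] == []

    def test_threshold_and_ordering(self):
        row = {aa: 0 for aa in AMINO_ACIDS}
        row.update({"S": 45, "T": 30, "A": 15, "G": 6, "V": 4})
        counts = pd.DataFrame([row], index=[1])[list(AMINO_ACIDS)]
        pfm = PositionFrequencyMatrix(1, counts, 100)
        assert [aa for aa, _ in motif_summary(pfm)[1]] == ["S", "T", "A"]

    def test_anchor_bias_in_synthetic_cohort(self, b57_cohort):
        # all three allotype-like sets share the Ser/Thr/Ala bias at P2
        for rep in b57_cohort.values():
            pfm = position_frequency_matrix(rep, 9)
            p2 = [aa for aa, _ in motif_summary(pfm)[2]]
            assert set(p2) >= {"S", "T"}


class TestBackgroundFrequencies:
    def test_embedded_table_sums_to_one(self):
        ref = background_frequencies()
        assert ref.freqs.sum() == pytest.approx(1.0, abs=1e-9)
        assert (ref.freqs > 0).all()
        # tryptophan is the rarest residue in the human proteome (~1.2%)
        assert ref.freqs.idxmin() == "W"

    def test_fasta_derived_hand_count(self, tmp_path):
        fasta = tmp_path / "bg.fasta"
        fasta.write_text(">a\nACD\n>b\nACD\n")
        ref = background_frequencies(fasta)
        for aa in "ACD":
            assert ref[aa] == pytest.approx(1 / 3, abs=1e-4)
        assert ref.source == "fasta_derived"

    def test_single_letter_fasta_floor_keeps_all_positive(self, tmp_path):
        fasta = tmp_path / "bg.fasta"
        fasta.write_text(">a\nAAAA\n")
        ref = background_frequencies(fasta)
        assert ref["A"] == pytest.approx(1.0, abs=1e-4)
        assert (ref.freqs > 0).all()

    def test_nonstandard_letters_skipped_and_reported(self, tmp_path):
        fasta = tmp_path / "bg.fasta"
        fasta.write_text(">a\nACDX\n")
        ref = background_frequencies(fasta)
        assert ref.skipped_letters == {"X": 1}

    def test_empty_fasta_raises(self, tmp_path):
        fasta = tmp_path / "bg.fasta"
        fasta.write_text("")
        with pytest.raises(ValueError):
            background_frequencies(fasta)


class TestEnrichmentProfile:
    def _pfm_from_counts(self, count_a: int, n: int, aa: str = "R"):
        row = {a: 0 for a in AMINO_ACIDS}
        row[aa] = count_a
        row["A"] = n - count_a
        counts = pd.DataFrame([row], index=[1])[list(AMINO_ACIDS)]
        return PositionFrequencyMatrix(1, counts, n)

    def test_hand_evaluated_z_and_fc(self):
        # n=100, count=20, p_ref=0.05: FC=4, z=(0.2-0.05)/sqrt(0.05*0.95/100)
        ref = background_frequencies()
        p_ref = 0.05
        ref.freqs[:] = (1 - p_ref) / 19
        ref.freqs["R"] = p_ref
        pfm = self._pfm_from_counts(20, 100)
        res = enrichment_profile(pfm, ref)
        cell = res.cell(1, "R")
        assert cell["value"] == pytest.approx(4.0)
        assert cell["z"] == pytest.approx(6.882, abs=0.01)
        assert cell["status"] == "enriched"

    def test_observed_equal_reference_is_not_significant(self):
        ref = background_frequencies()
        ref.freqs[:] = 0.05
        pfm = self._pfm_from_counts(5, 100)
        # every residue present at exactly p_ref... build uniform counts
        counts = pd.DataFrame([{a: 5 for a in AMINO_ACIDS}], index=[1])
        pfm = PositionFrequencyMatrix(1, counts[list(AMINO_ACIDS)], 100)
        res = enrichment_profile(pfm, ref)
        assert (res.table.status == "not_significant").all()
        assert np.allclose(res.table.z, 0.0)

    def test_absent_residue_gets_sentinel(self):
        ref = background_frequencies()
        pfm = self._pfm_from_counts(0, 50, "W")
        res = enrichment_profile(pfm, ref)
        assert res.status(1, "W") == "absent"
        assert res.value(1, "W") == -100.0

    def test_each_cell_has_exactly_one_status_with_value_ranges(self, b57_cohort):
        ref = background_frequencies()
        rep = next(iter(b57_cohort.values()))
        res = enrichment_profile(position_frequency_matrix(rep, 9), ref)
        t = res.table
        assert t.status.isin(["enriched", "depleted", "absent", "not_significant"]).all()
        assert (t.loc[t.status == "enriched", "value"] >= 1).all()
        assert (t.loc[t.status == "depleted", "value"] <= -1).all()
        assert (t.loc[t.status == "absent", "value"] == -100).all()
        # FC_con = -1/FC
        dep = t[t.status == "depleted"]
        assert np.allclose(dep.value, -dep.p_ref / dep.p_obs.where(dep.p_obs > 0))

    def test_swap_antisymmetry_inverts_fc_and_flips_z_sign(self):
        p_ref, n, count = 0.05, 400, 60
        ref = background_frequencies()
        ref.freqs[:] = (1 - p_ref) / 19
        ref.freqs["R"] = p_ref
        res = enrichment_profile(self._pfm_from_counts(count, n), ref)
        fc = res.cell(1, "R")["p_obs"] / p_ref
        z = res.cell(1, "R")["z"]
        # swapped: observe p_ref*n counts against a reference of count/n
        swapped_ref = background_frequencies()
        swapped_ref.freqs[:] = (1 - count / n) / 19
        swapped_ref.freqs["R"] = count / n
        res2 = enrichment_profile(self._pfm_from_counts(int(p_ref * n), n), swapped_ref)
        fc2 = res2.cell(1, "R")["p_obs"] / (count / n)
        assert fc2 == pytest.approx(1 / fc, rel=1e-9)
        assert np.sign(res2.cell(1, "R")["z"]) == -np.sign(z)

    def test_omega2_arg_contrast_across_synthetic_allotypes(self, b57_cohort):
        # the Arg-enriched spec is the only one with Arg enriched at PΩ-2
        ref = background_frequencies()
        statuses = {}
        for name, rep in b57_cohort.items():
            res = enrichment_profile(position_frequency_matrix(rep, 9), ref)
            statuses[name] = res.status(omega_position(9, 2), "R")
        assert statuses["W-RposE"] == "enriched"
        assert statuses["F-RnegP"] in ("depleted", "absent")
        assert statuses["W-EposR"] in ("depleted", "absent")


def test_omega_position_indexing():
    assert omega_position(9) == 9
    assert omega_position(9, 2) == 7
    assert omega_position(10, 2) == 8
    assert omega_position(11, 2) == 9
    with pytest.raises(ValueError):
        omega_position(9, 9)
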