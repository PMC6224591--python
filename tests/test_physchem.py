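import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from immunopep.constants import default_property_table
from immunopep.physchem import encode_peptides, pca_cluster
from immunopep.simulate import RepertoireSpec, profile_with_anchors, simulate_repertoire


def draw_nonamers(profile, n, seed):
    spec = RepertoireSpec(
        n=n, seed=seed, length_weights={9: 1.0}, profiles={9: profile},
        contaminant_fraction=0.0, low_confidence_fraction=0.0,
    )
    return simulate_repertoire(spec).sequence.tolist()


@pytest.fixture(scope="module")
def two_cluster_set():
    """Trp-enders vs Phe-enders with a shared P2 bias; labels are the truth."""
    profW = profile_with_anchors(9, {2: {"S": 0.4, "T": 0.2, "A": 0.15}, 9: {"W": 1.0}})
    profF = profile_with_anchors(9, {2: {"S": 0.4, "T": 0.2, "A": 0.15}, 9: {"F": 1.0}})
    w = draw_nonamers(profW, 500, 3)
    f = draw_nonamers(profF, 500, 4)
    return w + f, [0] * 500 + [1] * 500


class TestEncodePeptides:
    def test_identity_block_sums_to_length_before_standardisation(self):
        seqs = ["LSSPVTKSF", "LTVQVARVY", "AAAAAAAAW"]
        fm = encode_peptides(seqs, 9)
        means = fm.column_means
        identity_cols = [c for c in means.index if "_is_" in c]
        # per-row sums equal L, so the column means of the identity block sum to L
        assert means[identity_cols].sum() == pytest.approx(9.0)

    def test_all_identical_peptides_degenerate(self):
        fm = encode_peptides(["LSSPVTKSF"] * 5, 9)
        assert fm.is_degenerate
        assert len(fm.dropped_columns) == 24 * 9

    def test_two_peptides_differing_only_at_omega(self):
        fm = encode_peptides(["LSSPVTKSW", "LSSPVTKSF"], 9)
        assert all(c.startswith("P9_") for c in fm.data.columns)
        # W and F share no property value, so 4 properties + 2 indicators survive
        assert set(fm.data.columns) == {
            "P9_mol_weight", "P9_hydropathy", "P9_surface_area",
            "P9_isoelectric_point", "P9_is_W", "P9_is_F",
        }

    def test_row_count_and_standardisation(self, two_cluster_set):
        seqs, _ = two_cluster_set
        fm = encode_peptides(seqs, 9)
        assert fm.n == len(seqs)
        X = fm.data.to_numpy()
        assert np.allclose(X.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(X.std(axis=0), 1.0, atol=1e-9)


class TestPcaCluster:
    def test_reconstruction_with_all_components(self, two_cluster_set):
        seqs, _ = two_cluster_set
        fm = encode_peptides(seqs[:200], 9)
        res = pca_cluster(fm, k_candidates=(2,), seed=0)
        X = fm.data.to_numpy()
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, X, atol=1e-8)

    def test_variance_fractions_non_increasing(self, two_cluster_set):
        seqs, _ = two_cluster_set
        res = pca_cluster(encode_peptides(seqs, 9), seed=0)
        vf = res.variance_fractions
        assert (np.diff(vf) <= 1e-12).all() and vf.sum() <= 1.0 + 1e-9

    def test_sign_convention_largest_loading_positive(self, two_cluster_set):
        seqs, _ = two_cluster_set
        res = pca_cluster(encode_peptides(seqs, 9), seed=0)
        for col in res.loadings.columns[:5]:
            j = res.loadings[col].abs().idxmax()
            assert res.loadings.loc[j, col] > 0

    def test_silhouette_peaks_at_two_and_labels_recover_truth(self, two_cluster_set):
        seqs, truth = two_cluster_set
        res = pca_cluster(encode_peptides(seqs, 9), seed=0)
        assert res.chosen_k == 2
        assert adjusted_rand_score(truth, res.labels) > 0.9
        assert sum(res.cluster_percentages.values()) == pytest.approx(100.0)

    def test_duplicated_dataset_gives_identical_scores_and_labels(self, two_cluster_set):
        seqs, _ = two_cluster_set
        sub = seqs[:150]
        r1 = pca_cluster(encode_peptides(sub, 9), k_candidates=(2,), seed=0)
        r2 = pca_cluster(encode_peptides(sub * 2, 9), k_candidates=(2,), seed=0)
        s1 = r1.scores.to_numpy()[:, :2]
        s2 = r2.scores.to_numpy()[:150, :2]
        assert np.allclose(np.abs(s1), np.abs(s2), atol=1e-8)
        assert (r1.labels == r2.labels[:150]).all() or (r1.labels == 1 - r2.labels[:150]).all()

    def test_omega_surface_area_among_top_pc1_drivers(self, b57_cohort):
        rep = next(iter(b57_cohort.values()))
        fm = encode_peptides(rep, 9)
        res = pca_cluster(fm, seed=0)
        top = set(res.top_loading_features(1, 8).index)
        assert "P9_surface_area" in top

    def test_cluster_bias_inversion_between_trp_and_phe_majors(self):
        # pooled basis over one Trp-major and one Phe-major repertoire: the
        # two sets fall majority-wise into opposite clusters, and swapping
        # the PΩ mixes swaps the majority clusters while the basis persists
        profW = profile_with_anchors(9, {2: {"S": 0.4}, 9: {"W": 0.7, "F": 0.2}})
        profF = profile_with_anchors(9, {2: {"S": 0.4}, 9: {"F": 0.7, "W": 0.2}})
        a = draw_nonamers(profW, 400, 21)
        b = draw_nonamers(profF, 400, 22)
        fm = encode_peptides(a + b, 9)
        res = pca_cluster(fm, k_candidates=(2,), seed=0)
        maj_a = np.bincount(res.labels[:400]).argmax()
        maj_b = np.bincount(res.labels[400:]).argmax()
        assert maj_a != maj_b

        flipped_a = draw_nonamers(profF, 400, 23)  # Trp-major set flipped to Phe-major
        fm2 = encode_peptides(flipped_a + b, 9)
        res2 = pca_cluster(fm2, k_candidates=(2,), seed=0)
        # basis unchanged: PC1 is still driven by the same PΩ features
        top1 = set(res.top_loading_features(1, 5).index)
        top2 = set(res2.top_loading_features(1, 5).index)
        assert len(top1 & top2) >= 3
        # the flipped repertoire now sits in the same cluster as the Phe-major one
        maj_fa = np.bincount(res2.labels[:400]).argmax()
        maj_b2 = np.bincount(res2.labels[400:]).argmax()
        assert maj_fa == maj_b2

    def test_degenerate_matrix_raises(self):
        fm = encode_peptides(["LSSPVTKSF"] * 5, 9)
        with pytest.raises(ValueError, match="degenerate"):
            pca_cluster(fm, seed=0)


def test_property_table_complete_and_finite():
    t = default_property_table()
    assert t.shape == (20, 4)
    assert np.isfinite(t.to_numpy()).all()
    # tryptophan is the largest residue; arginine the most basic
    assert t["surface_area"].idxmax() == "W"
    assert t["isoelectric_point"].idxmax() == "R"
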