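import numpy as np
import pytest
from scipy import sparse

import spatialcite as sc
from spatialcite.cluster import ClusterAssignment
from spatialcite.demux import PixelMatrix
from spatialcite.integrate import (
    ReferenceAtlas,
    SignatureDefinition,
    cluster_majority_smooth,
)
from spatialcite.simulate import make_reference_atlas, make_tissue, simulate_counts


def _matrix(counts, genes, modality="rna"):
    counts = np.asarray(counts)
    return PixelMatrix(
        sparse.csr_matrix(counts.astype(np.int64)),
        [sc.PixelAddress(i + 1, 1) for i in range(counts.shape[0])],
        list(genes),
        modality,
    )


class TestSignatureScore:
    def test_identical_pixels_score_zero(self):
        mat = _matrix(np.full((10, 4), 3), ["LAG3", "PDCD1", "CXCR6", "OTHER"])
        scores = sc.signature_score(
            sc.log_normalize(mat), SignatureDefinition("Tph", ["LAG3", "PDCD1", "CXCR6"])
        )
        assert np.allclose(scores, 0.0)

    def test_matches_zscore_mean_recomputation(self, rng):
        genes = [f"g{j}" for j in range(5)]
        x = rng.poisson(6, size=(20, 5))
        norm = sc.log_normalize(_matrix(x, genes))
        sig_genes = genes[:3]
        scores = sc.signature_score(norm, SignatureDefinition("s", sig_genes))
        sub = norm.values[:, :3]
        z = (sub - sub.mean(axis=0)) / sub.std(axis=0)
        np.testing.assert_allclose(scores, z.mean(axis=1), atol=1e-9)

    def test_maximal_marker_pixel_is_argmax(self, rng):
        genes = ["LAG3", "PDCD1", "CXCR6", "BG1", "BG2"]
        x = rng.poisson(3, size=(30, 5))
        x[17, :3] = 100  # one pixel maximal in every signature gene
        norm = sc.log_normalize(_matrix(x, genes))
        scores = sc.signature_score(
            norm, SignatureDefinition("Tph", ["LAG3", "PDCD1", "CXCR6"])
        )
        assert int(np.argmax(scores)) == 17

    def test_protein_aliases_resolve(self, rng):
        genes = ["LAG3", "PDCD1", "CXCR6", "BG"]
        norm = sc.log_normalize(_matrix(rng.poisson(4, (15, 4)), genes))
        a = sc.signature_score(norm, SignatureDefinition("Tph", ["LAG3", "PDCD1", "CXCR6"]))
        b = sc.signature_score(norm, SignatureDefinition("Tph", ["CD223", "PD-1", "CXCR6"]))
        np.testing.assert_allclose(a, b)

    def test_missing_feature_error_names_it(self, rng):
        norm = sc.log_normalize(_matrix(rng.poisson(4, (10, 2)), ["LAG3", "PDCD1"]))
        with pytest.raises(KeyError, match="CXCR6"):
            sc.signature_score(norm, SignatureDefinition("Tph", ["LAG3", "PDCD1", "CXCR6"]))

    def test_invariant_to_shift_of_non_signature_feature(self, rng):
        genes = ["a", "b", "c", "d"]
        x = rng.poisson(4, size=(12, 4))
        sig = SignatureDefinition("s", ["a", "b"])
        base = sc.signature_score(sc.log_normalize(_matrix(x, genes)), sig)
        # shifting a non-signature feature's z-scores cannot change the score,
        # which only reads the signature columns of the normalized matrix
        norm = sc.log_normalize(_matrix(x, genes))
        norm.values[:, 3] += 5.0
        shifted = sc.signature_score(norm, sig)
        np.testing.assert_allclose(base, shifted, atol=1e-12)

    def test_monotone_in_signature_expression(self, rng):
        genes = ["a", "b", "c"]
        x = rng.poisson(4, size=(10, 3)).astype(float)
        sig = SignatureDefinition("s", ["a"])
        norm = sc.log_normalize(_matrix(x, genes))
        base = sc.signature_score(norm, sig)[4]
        norm.values[4, 0] += 1.0  # raise pixel 4's signature expression
        assert sc.signature_score(norm, sig)[4] > base


class TestTransferLabels:
    def test_self_transfer_is_perfect(self, rng):
        genes = [f"g{j}" for j in range(60)]
        x = rng.poisson(3, size=(80, 60))
        x[:40, :10] += 20
        x[40:, 10:20] += 20
        types = ["alpha"] * 40 + ["beta"] * 40
        ref = ReferenceAtlas(sparse.csr_matrix(x.astype(np.int64)), genes, types)
        norm = sc.log_normalize(_matrix(x, genes))
        table = sc.transfer_labels(norm, ref, n_dims=10)
        assert (table.predicted_type.to_numpy() == np.asarray(types)).all()

    def test_two_type_recovery_from_simulated_tissue(self):
        truth = make_tissue(2, (12, 12), 8.0, seed=9, markers_per_domain_rna=8)
        _, rna = simulate_counts(truth, 9)
        ref = make_reference_atlas(truth, 60, seed=10)
        table = sc.transfer_labels(sc.log_normalize(rna), ref, n_dims=20)
        truth_types = np.array([f"type{truth.domain_of(p)}" for p in rna.pixel_index])
        assert (table.predicted_type.to_numpy() == truth_types).mean() >= 0.9

    def test_cluster_majority_rule_applied_exactly(self):
        predicted = np.array(["a", "a", "b", "b", "b", "c"], dtype=object)
        labels = np.array([0, 0, 0, 1, 1, 1])
        smoothed = cluster_majority_smooth(predicted, labels)
        assert smoothed.tolist() == ["a", "a", "a", "b", "b", "b"]

    def test_majority_tie_breaks_deterministically(self):
        predicted = np.array(["b", "a"], dtype=object)
        smoothed = cluster_majority_smooth(predicted, np.array([0, 0]))
        assert smoothed.tolist() == ["a", "a"]

    def test_too_few_shared_genes_rejected(self, rng):
        genes = [f"g{j}" for j in range(10)]
        ref = ReferenceAtlas(
            sparse.csr_matrix(rng.poisson(3, (20, 10)).astype(np.int64)), genes, ["t"] * 20
        )
        norm = sc.log_normalize(_matrix(rng.poisson(3, (15, 10)), genes))
        with pytest.raises(ValueError, match="shared"):
            sc.transfer_labels(norm, ref, min_shared_genes=50)

    def test_smoothing_column_respects_cluster_modal_type(self):
        truth = make_tissue(2, (12, 12), 8.0, seed=9, markers_per_domain_rna=8)
        _, rna = simulate_counts(truth, 9)
        norm = sc.log_normalize(rna)
        ref = make_reference_atlas(truth, 60, seed=10)
        clusters = ClusterAssignment(
            np.array([p.row % 2 for p in rna.pixel_index]), {}, "rna"
        )
        table = sc.transfer_labels(norm, ref, n_dims=20, clusters=clusters)
        for c in (0, 1):
            sub = table[table.cluster == c]
            vals, counts = np.unique(sub.predicted_type, return_counts=True)
            modal = sorted(vals[counts == counts.max()])[0]
            assert (sub.smoothed_type == modal).all()
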