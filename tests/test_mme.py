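import numpy as np
import pytest
import scipy.sparse as sp

from ssrel.genomic import GenotypeSet, MarkerMatrix, build_G, build_G_omega, center_scale
from ssrel.mme import (
    ModelError,
    VarianceComponents,
    assemble_gblup,
    assemble_snpblup,
    assemble_snpblup_direct,
    assemble_ssgblup_exact,
    assemble_weighted_pblup,
    build_H_inverse,
    reliability_from_factor,
)
from ssrel.pedigree import (
    RelationshipMatrix,
    build_A,
    build_A_inverse,
    extract_A22,
    pedigree_from_records,
)


def toy_markers(n, m, seed=0):
    """A nonsingular toy marker matrix (external frequencies, n < m)."""
    rng = np.random.default_rng(seed)
    p_true = rng.uniform(0.2, 0.8, size=m)
    dos = rng.binomial(2, p_true, size=(n, m)).astype(float)
    geno = GenotypeSet([f"g{i}" for i in range(n)], dos, allele_freq=p_true)
    return center_scale(geno)


class TestVarianceComponents:
    def test_lambda(self):
        assert VarianceComponents(2.0, 5.0).lambda_ == pytest.approx(2.5)

    @pytest.mark.parametrize(
        "kwargs", [dict(sigma2_u=0.0, sigma2_e=1.0), dict(sigma2_u=1.0, sigma2_e=-1.0),
                   dict(sigma2_u=1.0, sigma2_e=1.0, omega=1.2)]
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VarianceComponents(**kwargs)


class TestWeightedPblup:
    def test_scalar_closed_form(self):
        ped = pedigree_from_records([("1", "0", "0")])
        Ainv = build_A_inverse(ped)
        vc = VarianceComponents(1.0, 2.0)  # lambda = 2
        d = 3.0
        f = assemble_weighted_pblup(Ainv, np.array([d]), vc, include_mean=False)
        r2 = reliability_from_factor(f, np.array([1.0]), vc)
        assert r2[0] == pytest.approx(d / (d + 2.0), abs=1e-14)

    def test_trio_matches_dense_inversion(self, trio, vc):
        Ainv = build_A_inverse(trio)
        w = np.array([1.0, 1.0, 1.0])
        f = assemble_weighted_pblup(Ainv, w, vc)
        # independent dense assembly of [[1'D1, 1'D],[D1, D + lam*Ainv]]
        lam = vc.lambda_
        lhs = np.zeros((4, 4))
        lhs[0, 0] = w.sum()
        lhs[0, 1:] = w
        lhs[1:, 0] = w
        lhs[1:, 1:] = np.diag(w) + lam * Ainv.toarray()
        C = np.linalg.inv(lhs)[1:, 1:]
        np.testing.assert_allclose(f.inverse_diag(), np.diag(C), atol=1e-10)
        r2 = reliability_from_factor(f, np.ones(3), vc)
        np.testing.assert_allclose(r2, 1 - lam * np.diag(C), atol=1e-10)

    def test_floor_weights_give_near_zero_reliability(self, small_pop, vc):
        ped = small_pop.ped
        A = build_A(ped)
        Ainv = build_A_inverse(ped, A.inbreeding)
        w = np.full(ped.n_animals, 0.01)
        f = assemble_weighted_pblup(Ainv, w, vc)
        r2 = reliability_from_factor(f, 1 + A.inbreeding, vc)
        # individual floor weights carry ~d/(d+lambda) ~ 0.007 of own
        # information; relatives' floors accumulate a little more
        assert r2.max() < 0.1
        assert np.median(r2) < 0.05

    def test_all_zero_weights_singular(self, trio, vc):
        Ainv = build_A_inverse(trio)
        with pytest.raises(ModelError, match="zero"):
            assemble_weighted_pblup(Ainv, np.zeros(3), vc)


class TestSnpblup:
    def test_scalar_no_mean(self):
        vc = VarianceComponents(1.0, 1.5)
        z, d = 0.7, 2.0
        Zm = MarkerMatrix(Z=np.array([[z]]), scale_constant=1.0)
        f = assemble_snpblup(Zm, np.array([d]), vc, include_mean=False)
        cgg = f.inverse_diag()[0]
        assert cgg == pytest.approx(1.0 / (d * z * z + vc.lambda_), abs=1e-14)

    def test_hand_assembled_lhs(self):
        vc = VarianceComponents(0.5, 1.0)
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(5, 8))
        w = rng.uniform(0.5, 2.0, 5)
        Zm = MarkerMatrix(Z=Z, scale_constant=1.0)
        f = assemble_snpblup(Zm, w, vc)
        D = np.diag(w)
        top = np.block(
            [[np.array([[w.sum()]]), (D @ Z).sum(axis=0, keepdims=True)],
             [(D @ Z).sum(axis=0, keepdims=True).T, Z.T @ D @ Z + vc.lambda_ * np.eye(8)]]
        )
        np.testing.assert_allclose(f.lhs, top, atol=1e-12)

    def test_direct_hand_assembled_lhs(self):
        vc = VarianceComponents(0.5, 1.0, omega=0.4)
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(2, 3))
        w = np.array([1.5, 0.5])
        A22v = np.array([[1.0, 0.25], [0.25, 1.0]])
        A22 = RelationshipMatrix(values=A22v, inbreeding=np.zeros(2))
        Zm = MarkerMatrix(Z=Z, scale_constant=1.0)
        f = assemble_snpblup_direct(Zm, A22, w, vc)
        W = np.hstack([np.sqrt(0.6) * Z, np.sqrt(0.4) * np.eye(2)])
        D = np.diag(w)
        omega_inv = np.block(
            [[np.eye(3), np.zeros((3, 2))], [np.zeros((2, 3)), np.linalg.inv(A22v)]]
        )
        lhs = np.zeros((6, 6))
        lhs[0, 0] = w.sum()
        lhs[0, 1:] = (D @ W).sum(axis=0)
        lhs[1:, 0] = lhs[0, 1:]
        lhs[1:, 1:] = W.T @ D @ W + vc.lambda_ * omega_inv
        np.testing.assert_allclose(f.lhs, lhs, atol=1e-12)

    def test_weights_to_zero_kills_reliability(self):
        vc = VarianceComponents(1.0, 1.0)
        Zm = toy_markers(6, 20)
        G = build_G(Zm)
        w = np.full(6, 1e-10)
        f = assemble_snpblup(Zm, w, vc)
        r2 = reliability_from_factor(f, np.diag(G), vc)
        assert r2.max() < 1e-8


class TestGblup:
    def test_identity_relationship_closed_form(self):
        vc = VarianceComponents(1.0, 1.0)
        f = assemble_gblup(np.eye(4), np.ones(4), vc, include_mean=False)
        r2 = reliability_from_factor(f, np.ones(4), vc)
        np.testing.assert_allclose(r2, 0.5, atol=1e-12)

    def test_singular_without_ridge_raises(self):
        vc = VarianceComponents(1.0, 1.0)
        K = np.ones((3, 3))  # rank 1
        with pytest.raises(ModelError, match="singular"):
            assemble_gblup(K, np.ones(3), vc, allow_ridge=False)


class TestModelEquivalences:
    """SNP-effect and animal-effect formulations give identical reliabilities."""

    def test_snpblup_equals_gblup_on_G(self, vc):
        Zm = toy_markers(20, 100, seed=3)
        rng = np.random.default_rng(4)
        w = rng.uniform(0.2, 4.0, 20)
        G = build_G(Zm)
        r_snp = reliability_from_factor(
            assemble_snpblup(Zm, w, vc), np.diag(G), vc
        )
        r_gbl = reliability_from_factor(
            assemble_gblup(G, w, vc), np.diag(G), vc
        )
        np.testing.assert_allclose(r_snp, r_gbl, atol=1e-8)

    def test_direct_snpblup_equals_gblup_on_G_omega(self, small_pop, vc):
        ped = small_pop.ped
        A = build_A(ped)
        A22 = extract_A22(A, small_pop.genotyped)
        Zm = center_scale(small_pop.geno.drop_monomorphic())
        rng = np.random.default_rng(5)
        w = rng.uniform(0.2, 4.0, Zm.n_animals)
        Gw = build_G_omega(build_G(Zm), A22, vc.omega)
        r_snp = reliability_from_factor(
            assemble_snpblup_direct(Zm, A22, w, vc), np.diag(Gw), vc
        )
        r_gbl = reliability_from_factor(
            assemble_gblup(Gw, w, vc), np.diag(Gw), vc
        )
        np.testing.assert_allclose(r_snp, r_gbl, atol=1e-8)

    def test_direct_omega_one_degenerates_to_animal_model_on_A22(self, small_pop):
        vc1 = VarianceComponents(0.4, 0.6, omega=1.0)
        ped = small_pop.ped
        A = build_A(ped)
        A22 = extract_A22(A, small_pop.genotyped)
        Zm = center_scale(small_pop.geno.drop_monomorphic())
        rng = np.random.default_rng(6)
        w = rng.uniform(0.2, 4.0, Zm.n_animals)
        r_dir = reliability_from_factor(
            assemble_snpblup_direct(Zm, A22, w, vc1), np.diag(A22.values), vc1
        )
        r_a = reliability_from_factor(
            assemble_gblup(A22.values, w, vc1), np.diag(A22.values), vc1
        )
        np.testing.assert_allclose(r_dir, r_a, atol=1e-8)


class TestSsgblupExact:
    def test_no_genotyped_reduces_to_weighted_pblup(self, small_pop, vc):
        ped = small_pop.ped
        A = build_A(ped)
        Ainv = build_A_inverse(ped, A.inbreeding)
        Hinv = build_H_inverse(
            Ainv, extract_A22(A, np.array([0])), np.eye(1), np.array([], dtype=int)
        )
        np.testing.assert_allclose(Hinv, Ainv.toarray(), atol=1e-14)

    def test_all_genotyped_equals_gblup_on_G_omega(self, vc):
        sc_ids = [("1", "0", "0"), ("2", "0", "0"), ("3", "1", "2"), ("4", "1", "2"),
                  ("5", "3", "4"), ("6", "3", "4")]
        ped = pedigree_from_records(sc_ids)
        A = build_A(ped)
        Ainv = build_A_inverse(ped, A.inbreeding)
        Zm = toy_markers(6, 40, seed=7)
        Gw = build_G_omega(build_G(Zm), A, vc.omega)
        rng = np.random.default_rng(8)
        w = rng.uniform(0.2, 3.0, 6)
        f_ss = assemble_ssgblup_exact(Ainv, A, Gw, np.arange(6), w, vc)
        r_ss = reliability_from_factor(f_ss, np.diag(Gw), vc)
        r_gb = reliability_from_factor(
            assemble_gblup(Gw, w, vc), np.diag(Gw), vc
        )
        np.testing.assert_allclose(r_ss, r_gb, atol=1e-8)

    def test_mixed_pedigree_matches_dense_hand_assembly(self, vc):
        rng = np.random.default_rng(9)
        recs = [(f"f{i}", "0", "0") for i in range(8)]
        for i in range(32):
            s, d = rng.choice(8, 2, replace=False)
            recs.append((f"o{i}", f"f{s}", f"f{d}"))
        ped = pedigree_from_records(recs)
        p = ped.n_animals
        A = build_A(ped)
        Ainv = build_A_inverse(ped, A.inbreeding)
        genotyped = np.sort(rng.choice(p, 12, replace=False))
        A22 = extract_A22(A, genotyped)
        Zm = toy_markers(12, 60, seed=10)
        Gw = build_G_omega(build_G(Zm), A22, vc.omega)
        w = rng.uniform(0.1, 2.0, p)
        f = assemble_ssgblup_exact(Ainv, A22, Gw, genotyped, w, vc)
        # independent dense H^-1 and bordered LHS
        Hinv = Ainv.toarray().copy()
        Hinv[np.ix_(genotyped, genotyped)] += np.linalg.inv(Gw) - np.linalg.inv(
            A22.values
        )
        lhs = np.zeros((p + 1, p + 1))
        lhs[0, 0] = w.sum()
        lhs[0, 1:] = w
        lhs[1:, 0] = w
        lhs[1:, 1:] = np.diag(w) + vc.lambda_ * Hinv
        C = np.linalg.inv(lhs)[1:, 1:]
        np.testing.assert_allclose(f.inverse_diag(), np.diag(C), atol=1e-9)


class TestReliability:
    def test_zero_information_unrelated_animal(self, vc):
        ped = pedigree_from_records([("1", "0", "0"), ("2", "0", "0")])
        Ainv = build_A_inverse(ped)
        f = assemble_weighted_pblup(
            Ainv, np.array([2.0, 0.0]), vc, include_mean=False
        )
        r2 = reliability_from_factor(f, np.ones(2), vc)
        assert r2[1] == pytest.approx(0.0, abs=1e-12)
        assert r2[0] == pytest.approx(2.0 / (2.0 + vc.lambda_), abs=1e-12)

    def test_quadratic_form_route_equals_animal_route(self, vc):
        """SNPBLUP W C^uu W' quadratic forms equal the GBLUP C^aa route."""
        Zm = toy_markers(10, 50, seed=11)
        rng = np.random.default_rng(12)
        w = rng.uniform(0.5, 2.0, 10)
        G = build_G(Zm)
        f_snp = assemble_snpblup(Zm, w, vc)
        quad = f_snp.quadratic_forms(Zm.Z)
        C_aa = assemble_gblup(G, w, vc).inverse_diag()
        np.testing.assert_allclose(quad, C_aa, atol=1e-9)

    def test_monotone_in_weights(self, trio, vc):
        Ainv = build_A_inverse(trio)
        base = np.array([1.0, 1.0, 1.0])
        f0 = assemble_weighted_pblup(Ainv, base, vc)
        r0 = reliability_from_factor(f0, np.ones(3), vc)
        for i in range(3):
            w = base.copy()
            w[i] += 1.0
            f1 = assemble_weighted_pblup(Ainv, w, vc)
            r1 = reliability_from_factor(f1, np.ones(3), vc)
            assert (r1 >= r0 - 1e-12).all()

    def test_all_outputs_in_unit_interval(self, small_pop, vc):
        ped = small_pop.ped
        A = build_A(ped)
        Ainv = build_A_inverse(ped, A.inbreeding)
        rng = np.random.default_rng(13)
        w = rng.uniform(0.0, 50.0, ped.n_animals)
        f = assemble_weighted_pblup(Ainv, w, vc)
        r2 = reliability_from_factor(f, 1 + A.inbreeding, vc)
        assert (r2 >= 0).all() and (r2 < 1).all()


class TestSparseDenseAgreement:
    def test_same_results_beyond_dense_limit(self, small_pop, vc):
        ped = small_pop.ped
        A = build_A(ped)
        Ainv = build_A_inverse(ped, A.inbreeding)
        w = np.random.default_rng(14).uniform(0.1, 5.0, ped.n_animals)
        f_dense = assemble_weighted_pblup(Ainv, w, vc)
        f_sparse = assemble_weighted_pblup(Ainv, w, vc, dense_limit=10)
        assert sp.issparse(f_sparse.lhs) and not sp.issparse(f_dense.lhs)
        idx = np.arange(0, ped.n_animals, 17)
        np.testing.assert_allclose(
            f_dense.inverse_diag(idx), f_sparse.inverse_diag(idx), atol=1e-8
        )
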