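import numpy as np
import pytest
import scipy.sparse as sp

from themeclust import (
    EPS,
    ClusterThemeModel,
    DegenerateClusterError,
    IncidenceRelation,
    TermVocabulary,
    ThemePrior,
    assign_clusters,
    best_of_restarts,
    compute_alpha,
    compute_membership,
    estimate_background,
    estimate_cluster_params,
    reassign_lowest,
    run_theme_clustering,
    select_subject_terms,
    theme_score,
)
from themeclust.em import _clamp


def rel_from_matrix(mat):
    """Incidence relation from a dense 0/1 terms-by-docs array."""
    mat = np.asarray(mat, dtype=np.int8)
    vocab = TermVocabulary([f"t{i:03d}" for i in range(mat.shape[0])])
    docs = [f"d{j}" for j in range(mat.shape[1])]
    return IncidenceRelation(vocab, docs, sp.csr_matrix(mat))


def make_model(p, q, subject=None, alpha=None):
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    u = np.arange(len(p)) if subject is None else np.asarray(subject)
    return ClusterThemeModel(
        subject_terms=u,
        p_in=p,
        p_out=q,
        alpha=np.zeros(len(p)) if alpha is None else np.asarray(alpha, float),
        constant=float(np.sum(np.log((1 - p[u]) / (1 - q[u])))),
        soft_size=0.0,
        soft_cooccurrence=np.zeros(len(p)),
    )


# ---------------------------------------------------------------------------
# Independent oracles


def bayes_posterior(delta, p, q, prior):
    """Brute-force Bayes posterior for one document over the subject terms."""
    like1 = prior * np.prod(np.where(delta, p, 1 - p))
    like0 = (1 - prior) * np.prod(np.where(delta, q, 1 - q))
    return like1 / (like1 + like0)


def alpha_direct(delta_t, pz, p, q, r):
    """Expected log-likelihood contribution difference for one term:
    theme-specific rates (p inside, q outside) versus background rate r."""
    d = delta_t.astype(float)
    with_theme = np.sum(pz * (d * np.log(p) + (1 - d) * np.log(1 - p))) + np.sum(
        (1 - pz) * (d * np.log(q) + (1 - d) * np.log(1 - q))
    )
    background_only = np.sum(d * np.log(r) + (1 - d) * np.log(1 - r))
    return with_theme - background_only


# ---------------------------------------------------------------------------
# Parameter estimation


class TestEstimateClusterParams:
    def test_binary_membership_reduces_to_frequencies(self):
        rel = rel_from_matrix([[1, 1, 0, 0]])
        p, q, n_s, n_st = estimate_cluster_params(rel, np.array([1.0, 1, 0, 0]))
        assert p[0] == pytest.approx(1 - EPS)
        assert q[0] == pytest.approx(EPS)
        assert n_s == 2.0
        assert n_st[0] == 2.0

    def test_uniform_weights_cancel(self, rng):
        mat = rng.integers(0, 2, size=(6, 8))
        rel = rel_from_matrix(mat)
        p, q, _, _ = estimate_cluster_params(rel, np.full(8, 0.5))
        expected = _clamp(rel.term_doc_freq / rel.n_docs)
        np.testing.assert_allclose(p, expected)
        np.testing.assert_allclose(q, expected)

    @pytest.mark.parametrize("pz", [np.zeros(4), np.ones(4)])
    def test_degenerate_mass(self, pz):
        rel = rel_from_matrix([[1, 1, 0, 0]])
        with pytest.raises(DegenerateClusterError):
            estimate_cluster_params(rel, pz)


def test_background_rates():
    rel = rel_from_matrix([[1, 0, 1, 0], [1, 1, 1, 1], [0, 0, 0, 0]])
    r = estimate_background(rel).background
    assert r[0] == 0.5
    assert r[1] == pytest.approx(1 - EPS)
    assert r[2] == pytest.approx(EPS)


# ---------------------------------------------------------------------------
# Alpha scoring and subject-term selection


class TestAlpha:
    def test_no_contrast_means_zero_gain(self):
        a = compute_alpha(
            p_in=np.array([0.3]), p_out=np.array([0.3]),
            background=np.array([0.3]), soft_size=5.0,
            soft_cooccurrence=np.array([2.0]),
            term_doc_freq=np.array([4]), n_docs=10,
        )
        assert a[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_likelihood_difference(self, rng):
        # alpha equals the expected-log-likelihood gain computed from scratch
        for _ in range(200):
            n = int(rng.integers(3, 9))
            t = int(rng.integers(1, 5))
            mat = rng.integers(0, 2, size=(t, n))
            rel = rel_from_matrix(mat)
            pz = rng.uniform(0.05, 0.95, size=n)
            p, q, n_s, n_st = estimate_cluster_params(rel, pz)
            r = estimate_background(rel).background
            alpha = compute_alpha(p, q, r, n_s, n_st, rel.term_doc_freq, n)
            for ti in range(t):
                expected = alpha_direct(mat[ti], pz, p[ti], q[ti], r[ti])
                assert alpha[ti] == pytest.approx(expected, abs=1e-9)


class TestSelectSubjectTerms:
    def test_top_k_descending(self):
        sel = select_subject_terms(np.array([5.0, 1.0, 3.0]), 2)
        assert sel.tolist() == [0, 2]

    def test_saturation(self):
        sel = select_subject_terms(np.array([1.0, 2.0]), 10)
        assert sorted(sel.tolist()) == [0, 1]

    def test_tie_goes_to_lower_index(self):
        sel = select_subject_terms(np.array([2.0, 7.0, 2.0]), 2)
        assert sel.tolist() == [1, 0]


# ---------------------------------------------------------------------------
# Posterior membership


class TestComputeMembership:
    def test_no_evidence_returns_prior(self):
        rel = rel_from_matrix([[1, 0]])
        model = make_model([0.4], [0.4])
        mm = compute_membership(rel, model, 0.5)
        np.testing.assert_allclose(mm.posterior, [0.5, 0.5])

    def test_single_term_worked_example(self):
        rel = rel_from_matrix([[1, 0]])
        model = make_model([0.8], [0.2])
        mm = compute_membership(rel, model, 0.5)
        assert mm.posterior[0] == pytest.approx(0.8, abs=1e-12)
        assert mm.posterior[1] == pytest.approx(0.2, abs=1e-12)

    def test_matches_bayes_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 7))
            t = int(rng.integers(1, 6))
            mat = rng.integers(0, 2, size=(t, n))
            rel = rel_from_matrix(mat)
            n_u = int(rng.integers(1, t + 1))
            subject = rng.choice(t, size=n_u, replace=False)
            p = rng.uniform(0.05, 0.95, size=t)
            q = rng.uniform(0.05, 0.95, size=t)
            prior = float(rng.uniform(0.05, 0.95))
            model = make_model(p, q, subject=np.sort(subject))
            mm = compute_membership(rel, model, ThemePrior(prior))
            for d in range(n):
                delta = mat[np.sort(subject), d].astype(bool)
                expected = bayes_posterior(
                    delta, p[np.sort(subject)], q[np.sort(subject)], prior
                )
                assert mm.posterior[d] == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# Assignment and perturbation


class TestAssignment:
    def test_argmax(self):
        a, surv = assign_clusters(np.array([[0.9, 0.1], [0.2, 0.8]]))
        assert a.tolist() == [0, 1]
        assert surv.tolist() == [0, 1]

    def test_tie_lowest_index(self):
        a, _ = assign_clusters(np.array([[0.5], [0.5]]))
        assert a.tolist() == [0]

    def test_loser_cluster_removed(self):
        a, surv = assign_clusters(np.array([[0.9, 0.8], [0.1, 0.2]]))
        assert surv.tolist() == [0]


class TestReassignLowest:
    def test_floor_zero_moves_nothing(self, rng):
        pz = rng.uniform(size=(2, 50))
        assignments = np.zeros(50, dtype=int)
        out = reassign_lowest(pz, assignments, 0.01)
        assert np.array_equal(out, assignments)

    def test_moves_weakest_two_of_200(self):
        pz = np.vstack([np.linspace(0.4, 0.99, 200), np.full(200, 0.3)])
        assignments = np.zeros(200, dtype=int)
        out = reassign_lowest(pz, assignments, 0.01)
        assert np.flatnonzero(out != assignments).tolist() == [0, 1]
        assert out[0] == out[1] == 1

    def test_single_cluster_noop(self):
        pz = np.array([[0.9, 0.1, 0.5]])
        assignments = np.zeros(3, dtype=int)
        out = reassign_lowest(pz, assignments, 0.5)
        assert np.array_equal(out, assignments)


# ---------------------------------------------------------------------------
# Full clustering loop


class TestRunThemeClustering:
    def test_single_cluster(self, planted_relation):
        res = run_theme_clustering(planted_relation, 1, 10, seed=0)
        assert res.final_k == 1
        assert res.converged
        assert np.all(res.assignments == 0)

    def test_deterministic(self, planted_relation):
        a = run_theme_clustering(planted_relation, 5, 50, seed=7)
        b = run_theme_clustering(planted_relation, 5, 50, seed=7)
        assert np.array_equal(a.assignments, b.assignments)
        assert a.theme_quality == b.theme_quality
        assert a.n_iterations == b.n_iterations

    def test_partition_invariants(self, planted_relation):
        res = run_theme_clustering(planted_relation, 8, 50, seed=3)
        assert res.final_k <= res.initial_k
        assert res.assignments.shape == (planted_relation.n_docs,)
        present = np.unique(res.assignments)
        assert present.tolist() == list(range(res.final_k))
        sizes = np.bincount(res.assignments, minlength=res.final_k)
        assert np.all(sizes > 0)

    def test_recovers_two_planted_themes(self):
        from themeclust import build_incidence, nmi
        from themeclust.synthetic import PlantedCorpusSpec, generate

        corpus = generate(PlantedCorpusSpec(n_themes=2, seed=11))
        rel = build_incidence(corpus.documents, min_doc_freq=2,
                              use_bigrams=False)
        best, _ = best_of_restarts(rel, 2, 100, n_runs=20, base_seed=0)
        assert best.final_k == 2
        assert nmi(best.assignments, corpus.labels) >= 0.9


class TestThemeScore:
    def test_direct_arithmetic(self):
        m1 = make_model([0.5, 0.5], [0.4, 0.4], subject=[0, 1],
                        alpha=[1.0, 2.0])
        m2 = make_model([0.5], [0.4], subject=[0], alpha=[3.0])
        res = run_result_stub([m1, m2])
        assert theme_score(res) == pytest.approx(14.0)

    def test_relabel_invariance(self):
        m1 = make_model([0.5], [0.4], subject=[0], alpha=[2.0])
        m2 = make_model([0.5], [0.4], subject=[0], alpha=[5.0])
        assert theme_score(run_result_stub([m1, m2])) == theme_score(
            run_result_stub([m2, m1])
        )

    def test_all_zero(self):
        m = make_model([0.5, 0.5], [0.5, 0.5], subject=[0, 1])
        assert theme_score(run_result_stub([m])) == 0.0


def run_result_stub(models):
    from themeclust import ClusteringResult

    return ClusteringResult(
        assignments=np.zeros(1, dtype=int), clusters=models,
        theme_quality=0.0, n_iterations=1, converged=True, seed=0,
        initial_k=len(models),
    )


class TestBestOfRestarts:
    def test_single_run_degenerate(self, planted_relation):
        best, qs = best_of_restarts(planted_relation, 3, 50, n_runs=1,
                                    base_seed=5)
        solo = run_theme_clustering(planted_relation, 3, 50, seed=5)
        assert qs.shape == (1,)
        assert best.theme_quality == solo.theme_quality
        assert np.array_equal(best.assignments, solo.assignments)

    def test_best_q_monotone_in_n(self, planted_relation):
        _, qs = best_of_restarts(planted_relation, 3, 50, n_runs=6,
                                 base_seed=0)
        running = np.maximum.accumulate(qs)
        assert np.all(np.diff(running) >= 0)
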