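"""EM-based thematic clustering with cluster-dependent subject-term selection.

The model: a theme is a pair (U, V) of a subject-term set U and a document
set V.  Term occurrences are independent Bernoulli events; a term t in U
occurs with probability p_t inside V and q_t outside, while every other term
occurs with its background rate r_t = n_t / N everywhere.  The score

    alpha_t = n_st ln(p_t/q_t) + (n_s - n_st) ln((1-p_t)/(1-q_t))
            + (n_t - n_st) ln(q_t/r_t) + (N - n_t - n_s + n_st) ln((1-q_t)/(1-r_t))

is the gain in expected complete-data log-likelihood from modelling t with
theme-specific probabilities instead of the background rate, where
n_s = sum_d pz_d and n_st = sum_d delta_td pz_d are the soft cluster size
and soft term/cluster co-occurrence.  Maximization selects the n_U terms
with largest alpha as U.

The clustering loop alternates, per cluster: parameter estimation from the
current membership weights (the initial random partition's indicators, then
the evolving posteriors), alpha-based subject-term selection, posterior
membership pz_d for every document, and a global hard argmax re-assignment.
Clusters that win no document vanish, so the final cluster count is
data-driven.  A small perturbation step re-seats each cluster's weakest
members (lowest pz_d) into their runner-up cluster every iteration, escaping
shallow local optima.  Model selection across random restarts maximizes the
theme score Q = sum over clusters of the squared selected alphas.

Posterior note: with pr_d the prior membership probability, the exact Bayes
posterior under the Bernoulli model restricted to U is

    pz_d = 1 / (1 + exp(-(score_d + C')))
    score_d = ln(pr_d/(1-pr_d)) + sum_{t in U} delta_td ln(p_t(1-q_t)/(q_t(1-p_t)))
    C'      = sum_{t in U} ln((1-p_t)/(1-q_t))

which is what this module computes (verified against a brute-force Bayes
oracle in the test suite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .corpus import IncidenceRelation

__all__ = [
    "EPS",
    "DegenerateClusterError",
    "ThemePrior",
    "GlobalTermModel",
    "ClusterThemeModel",
    "MembershipMatrix",
    "ClusteringResult",
    "estimate_cluster_params",
    "estimate_background",
    "compute_alpha",
    "select_subject_terms",
    "compute_membership",
    "assign_clusters",
    "reassign_lowest",
    "run_theme_clustering",
    "theme_score",
    "best_of_restarts",
]

logger = logging.getLogger(__name__)

# Probability floor/ceiling keeping every logarithm finite.  Hard assignments
# routinely produce empirical probabilities of exactly 0 or 1, so clamping is
# a structural necessity, not a numerical nicety.
EPS = 1e-6


class DegenerateClusterError(ValueError):
    """A cluster whose soft membership mass (or its complement) is zero."""


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS, 1.0 - EPS)


@dataclass
class ThemePrior:
    """Per-document prior membership probability pr_d, strictly in (0, 1).

    A scalar prior is broadcast to all documents.  The default 0.5 makes the
    prior term of score_d vanish, i.e. the data alone decide membership.
    """

    prior: float | np.ndarray = 0.5

    def as_array(self, n_docs: int) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(self.prior, dtype=float), (n_docs,))
        if np.any(arr <= 0.0) or np.any(arr >= 1.0):
            raise ValueError("prior probabilities must lie strictly in (0, 1)")
        return np.array(arr)


@dataclass
class GlobalTermModel:
    """Corpus-wide background occurrence rate r_t per term (clamped)."""

    background: np.ndarray


@dataclass
class ClusterThemeModel:
    """One cluster's fitted theme parameters.

    ``subject_terms`` holds the n_U selected term indices in descending
    alpha order; ``constant`` is C' = sum_{t in U} ln((1-p_t)/(1-q_t)), the
    additive constant completing the posterior log-odds.
    """

    subject_terms: np.ndarray
    p_in: np.ndarray
    p_out: np.ndarray
    alpha: np.ndarray
    constant: float
    soft_size: float
    soft_cooccurrence: np.ndarray

    @property
    def selected_alpha(self) -> np.ndarray:
        return self.alpha[self.subject_terms]


@dataclass
class MembershipMatrix:
    """Posterior pz_d and log-odds score_d, clusters by documents."""

    posterior: np.ndarray
    score: np.ndarray


@dataclass
class ClusteringResult:
    """Final hard assignments plus per-cluster theme models and metadata."""

    assignments: np.ndarray
    clusters: list[ClusterThemeModel]
    theme_quality: float
    n_iterations: int
    converged: bool
    seed: int
    initial_k: int
    doc_ids: list[str] = field(default_factory=list)

    @property
    def final_k(self) -> int:
        return len(self.clusters)


# ---------------------------------------------------------------------------
# M-step


def estimate_cluster_params(
    relation: IncidenceRelation, posterior: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Maximum-likelihood p_t, q_t for one cluster from membership weights.

    p_t = sum_d delta_td pz_d / sum_d pz_d and
    q_t = sum_d delta_td (1-pz_d) / sum_d (1-pz_d), both clamped to
    [EPS, 1-EPS].  Also returns the soft size n_s = sum_d pz_d and the soft
    co-occurrence n_st = sum_d delta_td pz_d needed by the alpha score.

    Raises :class:`DegenerateClusterError` when either membership mass is
    zero (an empty cluster, or a cluster that owns the whole corpus).
    """
    pz = np.asarray(posterior, dtype=float)
    if pz.shape != (relation.n_docs,):
        raise ValueError("posterior length must equal the number of documents")
    if np.any(pz < 0.0) or np.any(pz > 1.0):
        raise ValueError("posterior weights must lie in [0, 1]")
    n_s = float(pz.sum())
    comp = float(relation.n_docs - n_s)
    if n_s <= 0.0 or comp <= 0.0:
        raise DegenerateClusterError("zero membership mass on one side")
    n_st = relation.incidence @ pz
    p_in = _clamp(n_st / n_s)
    p_out = _clamp((relation.term_doc_freq - n_st) / comp)
    return p_in, p_out, n_s, n_st


def estimate_background(relation: IncidenceRelation) -> GlobalTermModel:
    """Background rate r_t = n_t / N, clamped to [EPS, 1-EPS]."""
    if relation.n_docs < 1:
        raise ValueError("empty relation")
    return GlobalTermModel(_clamp(relation.term_doc_freq / relation.n_docs))


def compute_alpha(
    p_in: np.ndarray,
    p_out: np.ndarray,
    background: GlobalTermModel | np.ndarray,
    soft_size: float,
    soft_cooccurrence: np.ndarray,
    term_doc_freq: np.ndarray,
    n_docs: int,
) -> np.ndarray:
    """Per-term likelihood gain alpha_t from theme-specific modelling.

    alpha_t is the difference in the expected complete-data log-likelihood
    between modelling term t with theme-specific rates (p_t inside, q_t
    outside) and modelling it with the single background rate r_t:

        alpha_t = n_st ln(p_t/r_t) + (n_s - n_st) ln((1-p_t)/(1-r_t))
                + (n_t - n_st) ln(q_t/r_t)
                + (N - n_t - n_s + n_st) ln((1-q_t)/(1-r_t))

    All probabilities must already be clamped into (0, 1).
    """
    r = background.background if isinstance(background, GlobalTermModel) else background
    n_s, n_st, n_t, n = soft_size, soft_cooccurrence, term_doc_freq, n_docs
    return (
        n_st * np.log(p_in / r)
        + (n_s - n_st) * np.log((1.0 - p_in) / (1.0 - r))
        + (n_t - n_st) * np.log(p_out / r)
        + (n - n_t - n_s + n_st) * np.log((1.0 - p_out) / (1.0 - r))
    )


def select_subject_terms(alpha: np.ndarray, n_subject: int) -> np.ndarray:
    """Indices of the n_U largest alphas, descending; ties -> lower index.

    Term indices follow lexicographic term order by construction of the
    vocabulary, so the tie rule is "lexicographically smaller term wins".
    Returns all terms when n_subject >= len(alpha).
    """
    if n_subject < 1:
        raise ValueError("n_subject must be >= 1")
    order = np.lexsort((np.arange(len(alpha)), -alpha))
    return order[: min(n_subject, len(alpha))]


# ---------------------------------------------------------------------------
# E-step


def compute_membership(
    relation: IncidenceRelation,
    model: ClusterThemeModel,
    prior: ThemePrior | float = 0.5,
) -> MembershipMatrix:
    """Exact posterior pz_d and log-odds score_d for one cluster.

    Only the subject terms U enter the evidence; all other terms carry the
    background rate under both hypotheses and cancel.
    """
    if isinstance(prior, (int, float)):
        prior = ThemePrior(float(prior))
    pr = prior.as_array(relation.n_docs)
    u = model.subject_terms
    p, q = model.p_in[u], model.p_out[u]
    weight = np.log(p * (1.0 - q) / (q * (1.0 - p)))
    # delta restricted to U: (|U| x N) slice of the incidence
    evidence = relation.incidence[u, :].T @ weight
    score = np.log(pr / (1.0 - pr)) + evidence
    with np.errstate(over="ignore"):
        pz = 1.0 / (1.0 + np.exp(-(score + model.constant)))
    return MembershipMatrix(posterior=pz, score=score)


def assign_clusters(posterior: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hard argmax assignment from a (clusters x documents) posterior.

    Ties go to the lowest cluster index.  Returns (assignments, surviving
    cluster row indices); clusters winning no document are dropped.
    """
    pz = np.atleast_2d(np.asarray(posterior, dtype=float))
    if pz.shape[0] < 1:
        raise ValueError("at least one cluster required")
    assignments = np.argmax(pz, axis=0)
    surviving = np.unique(assignments)
    return assignments, surviving


def reassign_lowest(
    posterior: np.ndarray, assignments: np.ndarray, fraction: float
) -> np.ndarray:
    """Move each cluster's weakest members to their runner-up cluster.

    Per cluster V_i, the floor(fraction * |V_i|) members with lowest pz_d in
    V_i are re-assigned to the cluster with the second-highest pz_d for that
    document.  With fewer than two clusters present this is a no-op.  Ties
    on pz_d are broken by document order.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    pz = np.atleast_2d(np.asarray(posterior, dtype=float))
    out = np.array(assignments, copy=True)
    if pz.shape[0] < 2 or fraction == 0.0:
        return out
    for ci in np.unique(assignments):
        members = np.flatnonzero(assignments == ci)
        k = int(np.floor(fraction * len(members)))
        if k == 0:
            continue
        weakest = members[np.argsort(pz[ci, members], kind="stable")[:k]]
        for d in weakest:
            col = pz[:, d].copy()
            col[assignments[d]] = -np.inf
            out[d] = int(np.argmax(col))
    return out


# ---------------------------------------------------------------------------
# Driver


def _fit_cluster(
    relation: IncidenceRelation,
    membership: np.ndarray,
    background: GlobalTermModel,
    n_subject: int,
    allow_full_coverage: bool,
) -> ClusterThemeModel:
    """Steps 2-4 for one cluster: parameters, alphas, subject terms.

    When the cluster covers every document there is no outside evidence for
    q_t; if ``allow_full_coverage`` the outside rate is clamped at the floor
    EPS instead of raising, which keeps a sole surviving cluster alive.
    """
    try:
        p_in, p_out, n_s, n_st = estimate_cluster_params(relation, membership)
    except DegenerateClusterError:
        n_s = float(membership.sum())
        if not allow_full_coverage or n_s <= 0.0:
            raise
        n_st = relation.incidence @ membership.astype(float)
        p_in = _clamp(n_st / n_s)
        p_out = np.full(relation.n_terms, EPS)
    alpha = compute_alpha(
        p_in, p_out, background, n_s, n_st, relation.term_doc_freq, relation.n_docs
    )
    subject = select_subject_terms(alpha, n_subject)
    constant = float(
        np.sum(np.log((1.0 - p_in[subject]) / (1.0 - p_out[subject])))
    )
    return ClusterThemeModel(
        subject_terms=subject,
        p_in=p_in,
        p_out=p_out,
        alpha=alpha,
        constant=constant,
        soft_size=n_s,
        soft_cooccurrence=n_st,
    )


def run_theme_clustering(
    relation: IncidenceRelation,
    n_clusters: int,
    n_subject: int,
    prior: ThemePrior | float = 0.5,
    seed: int = 0,
    max_iter: int = 100,
    reassign_fraction: float = 0.01,
) -> ClusteringResult:
    """One seeded run of the thematic clustering loop.

    Starts from a uniform random partition into ``n_clusters`` clusters and
    iterates estimation / subject-term selection / posterior assignment
    until the hard assignment repeats, removing clusters that win no
    document.  Deterministic given ``seed``.

    Parameters
    ----------
    n_clusters : initial cluster count K (the final count may be smaller).
    n_subject : number n_U of subject terms kept per cluster.
    prior : membership prior pr_d; scalar or per-document.
    reassign_fraction : per-iteration fraction of each cluster's weakest
        members moved to their runner-up cluster (0 disables).
    """
    if n_clusters < 1 or n_subject < 1 or max_iter < 1:
        raise ValueError("n_clusters, n_subject and max_iter must be >= 1")
    if isinstance(prior, (int, float)):
        prior = ThemePrior(float(prior))
    rng = np.random.default_rng(seed)
    n = relation.n_docs
    labels = rng.integers(0, n_clusters, size=n)  # step 1: random partition
    background = estimate_background(relation)
    active = [int(c) for c in np.unique(labels)]
    # Estimation weights: binary indicators of the initial random partition,
    # thereafter each cluster's posterior pz_d over ALL documents — the
    # membership probabilities the estimation formulas are written in.
    weights: dict[int, np.ndarray] = {
        cid: (labels == cid).astype(float) for cid in active
    }
    prev_hard: np.ndarray | None = None
    converged = False
    iteration = 0
    models: dict[int, ClusterThemeModel] = {}

    for iteration in range(1, max_iter + 1):
        # steps 2-4: per-cluster parameter fits and subject-term selection
        models = {}
        for cid in list(active):
            try:
                models[cid] = _fit_cluster(
                    relation,
                    weights[cid],
                    background,
                    n_subject,
                    allow_full_coverage=len(active) == 1,
                )
            except DegenerateClusterError:
                active.remove(cid)
        if not models:
            raise DegenerateClusterError("all clusters degenerate")

        # step 5: posterior membership for every cluster
        pz = np.vstack(
            [compute_membership(relation, models[cid], prior).posterior
             for cid in active]
        )

        # step 6: hard argmax assignment; empty clusters vanish
        rows, surviving_rows = assign_clusters(pz)
        hard = np.asarray(active)[rows]
        pz = pz[surviving_rows, :]
        active = [active[r] for r in surviving_rows]

        # step 7: convergence when the step-6 assignment repeats
        if prev_hard is not None and np.array_equal(hard, prev_hard):
            labels = hard
            converged = True
            break
        prev_hard = hard
        labels = hard

        n_moved = 0
        if len(active) >= 2 and reassign_fraction > 0.0:
            # step 8: re-seat each cluster's weakest members into their
            # runner-up cluster, swapping the two posterior masses so the
            # perturbation feeds the next iteration's estimation
            keep = np.searchsorted(np.asarray(active), hard)
            moved = reassign_lowest(pz, keep, reassign_fraction)
            for d in np.flatnonzero(moved != keep):
                a, b = keep[d], moved[d]
                pz[a, d], pz[b, d] = pz[b, d], pz[a, d]
            n_moved = int(np.sum(moved != keep))
            labels = np.asarray(active)[moved]
        weights = {cid: pz[i, :] for i, cid in enumerate(active)}
        if logger.isEnabledFor(logging.INFO):
            q_now = sum(
                float(np.sum(models[c].selected_alpha ** 2)) for c in models
            )
            logger.info(
                "iter %d: k=%d reassigned=%d Q=%.4f",
                iteration, len(active), n_moved, q_now,
            )

    if not converged and prev_hard is not None:
        # report the last argmax assignment, not the step-8 perturbation
        labels = prev_hard

    # Theme extraction: refit every surviving cluster from its final
    # document set, so the reported subject terms, alphas and theme score
    # describe the clusters actually returned.
    models = {}
    for cid in active:
        models[cid] = _fit_cluster(
            relation,
            (labels == cid).astype(float),
            background,
            n_subject,
            allow_full_coverage=len(active) == 1,
        )

    # relabel surviving clusters 0..final_k-1 in stable (original id) order
    remap = {cid: i for i, cid in enumerate(sorted(models))}
    assignments = np.array([remap[c] for c in labels], dtype=np.int64)
    clusters = [models[cid] for cid in sorted(models)]
    result = ClusteringResult(
        assignments=assignments,
        clusters=clusters,
        theme_quality=0.0,
        n_iterations=iteration,
        converged=converged,
        seed=seed,
        initial_k=n_clusters,
        doc_ids=list(relation.doc_ids),
    )
    result.theme_quality = theme_score(result)
    return result


def theme_score(result: ClusteringResult) -> float:
    """Theme score Q: sum over clusters of the squared selected alphas."""
    if not result.clusters:
        raise ValueError("result has no surviving cluster")
    return float(sum(np.sum(m.selected_alpha ** 2) for m in result.clusters))


def best_of_restarts(
    relation: IncidenceRelation,
    n_clusters: int,
    n_subject: int,
    prior: ThemePrior | float = 0.5,
    n_runs: int = 100,
    base_seed: int = 0,
    max_iter: int = 100,
    reassign_fraction: float = 0.01,
) -> tuple[ClusteringResult, np.ndarray]:
    """Best-of-n model selection by theme score Q.

    Runs :func:`run_theme_clustering` with seeds base_seed .. base_seed +
    n_runs - 1 and returns the maximal-Q result (ties -> lowest seed)
    together with the full Q trace.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    best: ClusteringResult | None = None
    qs = np.empty(n_runs)
    for i in range(n_runs):
        res = run_theme_clustering(
            relation, n_clusters, n_subject, prior,
            seed=base_seed + i, max_iter=max_iter,
            reassign_fraction=reassign_fraction,
        )
        qs[i] = res.theme_quality
        if best is None or res.theme_quality > best.theme_quality:
            best = res
    assert best is not None
    return best, qs
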