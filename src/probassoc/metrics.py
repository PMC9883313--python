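"""Social-structure evaluation: CV permutation tests, Mantel test,
leading-eigenvector modularity clustering, and social differentiation.

These are the standard performance checks for an association matrix built
from identification data:

* the coefficient of variation (CV) of half-weight indices quantifies how
  mixed strong and weak relationships are, tested against a within-day
  degree-preserving permutation null (sequential checkerboard swaps of the
  per-day association structure, after Bejder-style matrix inversions);
* a Mantel test asks whether associations are stronger within known social
  units (e.g. matrilines) than between them;
* Newman's leading-eigenvector method partitions the weighted association
  network by recursively bisecting along the dominant eigenvector of the
  modularity matrix, accepting only splits that increase modularity Q;
* social differentiation S estimates the CV of the *latent* association
  probabilities by maximum likelihood, treating each dyad's associated-day
  count as a Beta-Binomial draw and so correcting for binomial sampling
  noise in the observed indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, gammaln

from .associations import AssociationData, HWIMatrix, hwi_matrix

__all__ = [
    "CVResult",
    "MantelResult",
    "CommunityPartition",
    "SocialDifferentiation",
    "association_cv",
    "permute_within_days",
    "mantel_test",
    "newman_clusters",
    "modularity",
    "social_differentiation",
    "beta_binomial_fit",
]


def _cv(values: np.ndarray) -> float:
    """Population (n-denominator) coefficient of variation, sd/mean."""
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined: mean association is zero")
    return float(values.std(ddof=0) / mean)


def association_cv(matrix: HWIMatrix, nonzero_only: bool = False) -> float:
    """CV of the off-diagonal half-weight indices.

    With ``nonzero_only`` the zeros are dropped first; large numbers of
    never-associated dyads otherwise inflate the CV.
    """
    vals = matrix.offdiag(nonzero_only=nonzero_only)
    if len(vals) < 2:
        raise ValueError("need at least two dyads to compute a CV")
    return _cv(vals)


# --------------------------------------------------------------------------
# Within-day permutation null
# --------------------------------------------------------------------------

@dataclass
class CVResult:
    """Observed CVs with their one-sided permutation P values.

    P = (1 + #{permuted >= observed}) / (1 + n_permutations); high observed
    CV relative to the null indicates preferred/avoided companionship.
    """

    cv_all: float
    cv_nonzero: float
    p_all: float
    p_nonzero: float
    n_permutations: int
    n_trials: int
    null_cv_all: np.ndarray = field(repr=False, default=None)
    null_cv_nonzero: np.ndarray = field(repr=False, default=None)
    flip_success_rate: float = float("nan")


def _day_arrays(assoc: AssociationData, idx: Mapping[str, int], n: int):
    """Per-day seen masks and adjacency edge sets (as index pairs)."""
    day_edges, day_seen = [], []
    for day in assoc.days:
        seen = np.zeros(n, dtype=bool)
        for ind in assoc.seen[day]:
            if ind in idx:
                seen[idx[ind]] = True
        edges = {tuple(sorted((idx[a], idx[b])))
                 for a, b in assoc.associated[day]
                 if a in idx and b in idx}
        day_seen.append(seen)
        day_edges.append(edges)
    return day_seen, day_edges


def permute_within_days(assoc: AssociationData,
                        n_permutations: int = 1000,
                        n_trials: int = 1000,
                        ids: Sequence[str] | None = None,
                        seed: int | None = None,
                        check_degrees: bool = False) -> CVResult:
    """Test observed HWI CVs against a within-day degree-preserving null.

    Each permutation applies ``n_trials`` attempted checkerboard swaps to
    randomly chosen days: a swap picks two associated dyads (i~j) and (k~l)
    on one day, with i, j, k, l distinct and (i~l), (k~j) absent, and rewires
    them to (i~l), (k~j) — inverting a 2x2 sub-block of the day's association
    matrix while preserving every individual's per-day association degree.
    Permutations are sequential: each continues from the previous state, and
    both CV statistics are recomputed from the accumulated HWI matrix after
    every permutation.

    ``check_degrees`` asserts per-day degree conservation after every
    accepted swap (used by the test suite).
    """
    individuals = sorted(set(ids)) if ids is not None else assoc.individuals
    idx = {ind: k for k, ind in enumerate(individuals)}
    n = len(individuals)
    if n < 4:
        raise ValueError("need at least 4 individuals for checkerboard swaps")
    day_seen, day_edges = _day_arrays(assoc, idx, n)
    n_days = len(assoc.days)

    # denominator of the HWI is invariant under within-day swaps: seen sets
    # never change, so x + yAB, yA and yB are all fixed per dyad
    x = np.zeros((n, n))
    denom = np.zeros((n, n))
    seen_days = np.zeros(n)
    for seen, edges in zip(day_seen, day_edges):
        seen_days += seen
        both = np.outer(seen, seen)
        denom += both
        for i, j in edges:
            x[i, j] += 1
            x[j, i] += 1
    only = (seen_days[:, None] - denom) + (seen_days[None, :] - denom)
    denom = denom + 0.5 * only
    np.fill_diagonal(denom, 1.0)  # diagonal never read

    iu, ju = np.triu_indices(n, k=1)

    def stats(xmat: np.ndarray) -> tuple[float, float]:
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(denom[iu, ju] > 0, xmat[iu, ju] / denom[iu, ju], 0.0)
        nz = vals[vals > 0]
        cv_all = _cv(vals)
        cv_nz = _cv(nz) if len(nz) >= 2 else float("nan")
        return cv_all, cv_nz

    if check_degrees:
        base_degrees = [
            {v: sum(1 for e in edges if v in e) for v in range(n)}
            for edges in day_edges
        ]

    obs_all, obs_nz = stats(x)
    rng = np.random.default_rng(seed)
    edge_lists = [sorted(edges) for edges in day_edges]
    edge_sets = [set(edges) for edges in day_edges]

    null_all = np.empty(n_permutations)
    null_nz = np.empty(n_permutations)
    attempted = succeeded = 0
    for p in range(n_permutations):
        for _ in range(n_trials):
            attempted += 1
            d = int(rng.integers(n_days))
            edges = edge_lists[d]
            if len(edges) < 2:
                continue
            e1, e2 = rng.integers(len(edges), size=2)
            if e1 == e2:
                continue
            i, j = edges[e1]
            k, l = edges[e2]
            if rng.integers(2):
                i, j = j, i
            if rng.integers(2):
                k, l = l, k
            if len({i, j, k, l}) < 4:
                continue
            new1 = tuple(sorted((i, l)))
            new2 = tuple(sorted((k, j)))
            es = edge_sets[d]
            if new1 in es or new2 in es:
                continue
            # accept the swap
            old1, old2 = tuple(sorted((i, j))), tuple(sorted((k, l)))
            es.discard(old1); es.discard(old2)
            es.add(new1); es.add(new2)
            edges[e1] = new1
            edges[e2] = new2
            for (a, b) in (old1, old2):
                x[a, b] -= 1; x[b, a] -= 1
            for (a, b) in (new1, new2):
                x[a, b] += 1; x[b, a] += 1
            succeeded += 1
            if check_degrees:
                deg = {v: sum(1 for e in es if v in e) for v in range(n)}
                assert deg == base_degrees[d], "degree sequence not conserved"
        null_all[p], null_nz[p] = stats(x)

    p_all = (1 + int(np.sum(null_all >= obs_all))) / (1 + n_permutations)
    nz_valid = ~np.isnan(null_nz)
    if np.isnan(obs_nz):
        p_nz = float("nan")
    else:
        p_nz = (1 + int(np.sum(null_nz[nz_valid] >= obs_nz))) / (1 + n_permutations)
    return CVResult(cv_all=obs_all, cv_nonzero=obs_nz, p_all=p_all,
                    p_nonzero=p_nz, n_permutations=n_permutations,
                    n_trials=n_trials, null_cv_all=null_all,
                    null_cv_nonzero=null_nz,
                    flip_success_rate=succeeded / max(attempted, 1))


# --------------------------------------------------------------------------
# Mantel test
# --------------------------------------------------------------------------

@dataclass
class MantelResult:
    matrix_correlation: float
    p_value: float
    n_permutations: int


def mantel_test(matrix: HWIMatrix, membership: Mapping[str, object],
                n_permutations: int = 1000,
                seed: int | None = None) -> MantelResult:
    """Matrix correlation between HWI and same-group membership.

    Pearson correlation between the vectorized off-diagonal HWI and a binary
    same-group indicator; the null distribution permutes group labels across
    individuals (simultaneous row/column permutation).  One-sided P for
    positive correlation, with add-one correction.
    """
    ids = matrix.individuals
    missing = [i for i in ids if i not in membership]
    if missing:
        raise ValueError(f"membership missing for {missing[:5]}...")
    labels = np.asarray([membership[i] for i in ids], dtype=object)
    uniq = set(labels.tolist())
    if len(uniq) < 2 or len(uniq) == len(ids):
        raise ValueError("membership must define >= 2 groups, each not all "
                         "singletons (degenerate indicator matrix)")
    iu, ju = np.triu_indices(len(ids), k=1)
    vals = matrix.values[iu, ju]
    if np.std(vals) == 0:
        raise ValueError("constant association matrix: correlation undefined")

    def corr(lab: np.ndarray) -> float:
        same = (lab[iu] == lab[ju]).astype(float)
        if same.std() == 0:
            return float("nan")
        return float(np.corrcoef(vals, same)[0, 1])

    observed = corr(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        r = corr(rng.permutation(labels))
        if r >= observed:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return MantelResult(matrix_correlation=observed, p_value=p,
                        n_permutations=n_permutations)


# --------------------------------------------------------------------------
# Leading-eigenvector modularity clustering
# --------------------------------------------------------------------------

@dataclass
class CommunityPartition:
    assignment: Mapping[str, int]
    q: float
    n_clusters: int
    cluster_sizes: list

    def labels(self, ids: Sequence[str]) -> np.ndarray:
        return np.asarray([self.assignment[i] for i in ids])


def modularity(weights: np.ndarray, labels: np.ndarray) -> float:
    """Weighted modularity Q of a partition.

    Q = (1/2W) * sum_ij (w_ij - s_i s_j / 2W) * [c_i == c_j], with s the
    weighted degrees and 2W the total weight.
    """
    w = np.asarray(weights, dtype=float)
    s = w.sum(axis=1)
    two_w = s.sum()
    if two_w == 0:
        return 0.0
    same = labels[:, None] == labels[None, :]
    b = w - np.outer(s, s) / two_w
    return float(b[same].sum() / two_w)


def _split(b_sub: np.ndarray, fine_tune: bool, two_w: float
           ) -> np.ndarray | None:
    """One leading-eigenvector bisection of a (generalized) modularity
    sub-matrix; returns a +/-1 sign vector or None if indivisible."""
    evals, evecs = np.linalg.eigh(b_sub)
    lead = evecs[:, -1]
    if evals[-1] <= 1e-12:
        return None
    s = np.where(lead >= 0, 1.0, -1.0)
    if np.all(s == s[0]):
        return None

    def dq(sv: np.ndarray) -> float:
        return float(sv @ b_sub @ sv) / (4.0 * (two_w / 2.0))

    if fine_tune:
        # Kernighan-Lin style sweep: move each vertex once, greedily, keep
        # the best intermediate state; repeat while it improves
        improved = True
        while improved:
            improved = False
            s_work = s.copy()
            moved = np.zeros(len(s), dtype=bool)
            best_s, best_val = s.copy(), dq(s)
            for _ in range(len(s)):
                gains = -4.0 * s_work * (b_sub @ s_work) + 4.0 * np.diag(b_sub)
                gains[moved] = -np.inf
                v = int(np.argmax(gains))
                s_work[v] = -s_work[v]
                moved[v] = True
                val = dq(s_work)
                if val > best_val and not (np.all(s_work == s_work[0])):
                    best_val, best_s = val, s_work.copy()
            if best_val > dq(s) + 1e-12:
                s = best_s
                improved = True
    if dq(s) <= 1e-12:
        return None
    return s


def newman_clusters(matrix: HWIMatrix, fine_tune: bool = False
                    ) -> CommunityPartition:
    """Partition the weighted association network by recursive
    leading-eigenvector bisection of the modularity matrix.

    A bisection is accepted only when it increases Q; an indivisible
    sub-network (non-positive leading eigenvalue, or no Q-increasing sign
    split) stays whole.  All-zero weights give a single cluster with Q = 0.
    """
    ids = matrix.individuals
    if not ids:
        raise ValueError("empty association matrix")
    w = matrix.values
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    s = w.sum(axis=1)
    two_w = s.sum()
    if two_w == 0:
        return CommunityPartition({i: 0 for i in ids}, 0.0, 1, [len(ids)])
    b = w - np.outer(s, s) / two_w

    labels = np.zeros(len(ids), dtype=int)
    next_label = 1
    stack = [np.arange(len(ids))]
    while stack:
        g = stack.pop()
        if len(g) < 2:
            continue
        b_g = b[np.ix_(g, g)]
        b_g = b_g - np.diag(b_g.sum(axis=1))
        sign = _split(b_g, fine_tune, two_w)
        if sign is None:
            continue
        right = g[sign > 0]
        left = g[sign < 0]
        labels[right] = next_label
        next_label += 1
        stack.append(left)
        stack.append(right)

    # relabel densely
    uniq, dense = np.unique(labels, return_inverse=True)
    assignment = {ids[k]: int(dense[k]) for k in range(len(ids))}
    q = modularity(w, dense)
    sizes = np.bincount(dense).tolist()
    return CommunityPartition(assignment=assignment, q=q,
                              n_clusters=len(uniq), cluster_sizes=sizes)


# --------------------------------------------------------------------------
# Social differentiation (Beta-Binomial likelihood)
# --------------------------------------------------------------------------

@dataclass
class SocialDifferentiation:
    """Estimated CV of the latent association probabilities.

    S near 0 means homogeneous associations; S > 1 means highly diverse
    relationships across dyads.
    """

    s: float
    alpha: float
    beta: float
    loglik: float
    n_dyads: int
    boundary: bool = False
    converged: bool = True


def _bb_loglik(log_ab: np.ndarray, x: np.ndarray, d: np.ndarray) -> float:
    a, b = np.exp(log_ab)
    if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
        return -np.inf
    ll = (gammaln(d + 1) - gammaln(x + 1) - gammaln(d - x + 1)
          + betaln(x + a, d - x + b) - betaln(a, b))
    return float(ll.sum())


def beta_binomial_fit(x: np.ndarray, d: np.ndarray,
                      n_grid_starts: int = 16) -> SocialDifferentiation:
    """ML fit of x ~ BetaBinomial(d, alpha, beta) over dyads.

    The latent dyadic association probability is Beta(alpha, beta); S is the
    CV of that Beta, sqrt(beta / (alpha * (alpha + beta + 1))).  Multi-start
    Nelder-Mead on (log alpha, log beta) from a log-grid of starts.
    """
    x = np.asarray(x, dtype=float)
    d = np.asarray(d, dtype=float)
    keep = d > 0
    if not np.any(keep):
        raise ValueError("no dyads with a positive number of joint sampling days")
    x, d = x[keep], d[keep]
    if np.any(x > d) or np.any(x < 0):
        raise ValueError("require 0 <= x <= d per dyad")

    side = int(np.round(np.sqrt(n_grid_starts)))
    grid = np.linspace(-2.0, 2.5, side)
    starts = [np.array([la, lb]) for la in grid for lb in grid]

    best = None
    for th0 in starts:
        res = minimize(lambda th: -_bb_loglik(th, x, d), th0,
                       method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        return SocialDifferentiation(s=float("nan"), alpha=float("nan"),
                                     beta=float("nan"), loglik=-np.inf,
                                     n_dyads=len(x), converged=False)
    a, b = np.exp(best.x)
    s = float(np.sqrt(b / (a * (a + b + 1))))
    boundary = bool(a > 1e6 or b > 1e6 or s < 1e-4)
    if boundary and s < 1e-4:
        s = 0.0
    return SocialDifferentiation(s=s, alpha=float(a), beta=float(b),
                                 loglik=-float(best.fun), n_dyads=len(x),
                                 boundary=boundary, converged=True)


def social_differentiation(assoc: AssociationData,
                           ids: Sequence[str] | None = None
                           ) -> SocialDifferentiation:
    """Social differentiation S from per-day associations.

    For each dyad, x = days both were identified and associated and d = days
    both were identified; the Beta-Binomial likelihood over all dyads with
    d > 0 is maximized to estimate the latent CV.
    """
    matrix = hwi_matrix(assoc, ids=ids)
    xs, ds = [], []
    for (a, b), (x, yab, _, _) in matrix.counts.items():
        xs.append(x)
        ds.append(x + yab)
    return beta_binomial_fit(np.asarray(xs), np.asarray(ds))
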