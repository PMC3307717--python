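"""Independent brute-force oracles used to validate the dynamic programming.

Everything here sums or maximizes over *all* ``2 * 8**S`` explanations
(orientation x hidden path) explicitly, reusing only the elementary
single-site quantities (per-process transition matrices, per-state emission
distributions), never the forward/backward/Viterbi code under test.
"""

from __future__ import annotations

import itertools

import numpy as np

from hairpinhmm import hmm_core as hc
from hairpinhmm.patterns_io import MISSING, CpGLocus, DoubleStrandPattern


def random_params(rng: np.random.Generator, n_sites: int,
                  max_error: float = 0.1) -> hc.ModelParams:
    return hc.ModelParams(
        hc.EnzymeProcessParams(*rng.uniform(0.01, 0.99, 2)),
        hc.EnzymeProcessParams(*rng.uniform(0.01, 0.99, 2)),
        hc.EnzymeProcessParams(*rng.uniform(0.01, 0.99, 2)),
        hc.ActivityParams(*rng.uniform(0.0, 1.0, 4)),
        hc.ErrorParams(*rng.uniform(0.0, max_error, 2)),
        hc.SiteDensities(tuple(rng.uniform(0.0, 1.0, n_sites))),
    )


def random_locus(rng: np.random.Generator, n_sites: int) -> CpGLocus:
    gaps = rng.integers(1, 12, size=n_sites - 1)
    pos = 100 + np.concatenate(([0], np.cumsum(gaps)))
    return CpGLocus("toy", "chrT", tuple(int(x) for x in pos),
                    int(pos[0]) - 1, int(pos[-1]) + 1)


def random_pattern(rng: np.random.Generator, n_sites: int,
                   p_missing: float = 0.1) -> DoubleStrandPattern:
    probs = [(1 - p_missing) / 2, (1 - p_missing) / 2, p_missing]
    sa = rng.choice([0, 1, MISSING], size=n_sites, p=probs).astype(np.int8)
    sb = rng.choice([0, 1, MISSING], size=n_sites, p=probs).astype(np.int8)
    return DoubleStrandPattern("toy", sa, sb)


def _per_strand_emission(state: int, m_i: float, params: hc.ModelParams,
                         obs_parent: int, obs_daughter: int) -> float:
    """P(observed pair | state) from emission_observed, marginalizing missing."""
    dist = hc.emission_observed(state, m_i, params.activity, params.errors)
    total = 0.0
    for p in range(2):
        if obs_parent != MISSING and obs_parent != p:
            continue
        for d in range(2):
            if obs_daughter != MISSING and obs_daughter != d:
                continue
            total += dist[2 * p + d]
    return total


def _explanations(pattern: DoubleStrandPattern, locus: CpGLocus,
                  params: hc.ModelParams):
    """Yield (orientation, path, joint probability) over every explanation."""
    params = params.constrained()
    S = locus.n_sites
    m = params.densities.as_array()
    pis = [np.array([1 - hc.stationary_association_frequency(p),
                     hc.stationary_association_frequency(p)])
           for p in params.processes]
    mats = [[hc.transition_over_distance(p, int(L)) for p in params.processes]
            for L in locus.gaps]
    for orient in (0, 1):
        if orient == 0:
            obs_p, obs_d = pattern.strand_a, pattern.strand_b
        else:
            obs_p, obs_d = pattern.strand_b, pattern.strand_a
        for path in itertools.product(range(8), repeat=S):
            bits = [hc.state_bits(s) for s in path]
            prob = 0.5
            for k in range(3):
                prob *= pis[k][bits[0][k]]
            prob *= _per_strand_emission(path[0], m[0], params,
                                         int(obs_p[0]), int(obs_d[0]))
            for i in range(1, S):
                for k in range(3):
                    prob *= mats[i - 1][k][bits[i - 1][k], bits[i][k]]
                prob *= _per_strand_emission(path[i], m[i], params,
                                             int(obs_p[i]), int(obs_d[i]))
            yield orient, path, prob


def brute_loglik(pattern, locus, params) -> float:
    return float(np.log(sum(p for _, _, p in _explanations(pattern, locus, params))))


def brute_loglik_fast(pattern, locus, params) -> float:
    """Vectorized enumeration over all 2 * 8**S explanations.

    Same quantity as :func:`brute_loglik` but with the path sum done by
    array gathers, so hundreds of draws at S = 5 stay cheap.  Joint
    transition matrices are assembled from the three per-process 2x2
    matrices by explicit products (independently of the forward code path).
    """
    params = params.constrained()
    S = locus.n_sites
    m = params.densities.as_array()
    pis = [np.array([1 - hc.stationary_association_frequency(p),
                     hc.stationary_association_frequency(p)])
           for p in params.processes]
    pi0 = np.array([pis[0][b[0]] * pis[1][b[1]] * pis[2][b[2]]
                    for b in map(hc.state_bits, range(8))])
    joint_mats = []
    for L in locus.gaps:
        per = [hc.transition_over_distance(p, int(L)) for p in params.processes]
        J = np.empty((8, 8))
        for a in range(8):
            for b in range(8):
                ba, bb = hc.state_bits(a), hc.state_bits(b)
                J[a, b] = per[0][ba[0], bb[0]] * per[1][ba[1], bb[1]] \
                    * per[2][ba[2], bb[2]]
        joint_mats.append(J)

    paths = np.array(list(itertools.product(range(8), repeat=S)))  # (8^S, S)
    total = 0.0
    for orient in (0, 1):
        if orient == 0:
            obs_p, obs_d = pattern.strand_a, pattern.strand_b
        else:
            obs_p, obs_d = pattern.strand_b, pattern.strand_a
        e = np.array([[_per_strand_emission(s, m[i], params,
                                            int(obs_p[i]), int(obs_d[i]))
                       for s in range(8)] for i in range(S)])  # (S, 8)
        prob = 0.5 * pi0[paths[:, 0]] * e[0][paths[:, 0]]
        for i in range(1, S):
            prob = prob * joint_mats[i - 1][paths[:, i - 1], paths[:, i]] \
                * e[i][paths[:, i]]
        total += prob.sum()
    return float(np.log(total))


def brute_orientation_posterior(pattern, locus, params) -> float:
    w = [0.0, 0.0]
    for orient, _, p in _explanations(pattern, locus, params):
        w[orient] += p
    return w[0] / (w[0] + w[1])


def brute_state_marginals(pattern, locus, params) -> np.ndarray:
    """Orientation-averaged per-site state marginals, shape (S, 8)."""
    S = locus.n_sites
    acc = np.zeros((S, 8))
    total = 0.0
    for _, path, p in _explanations(pattern, locus, params):
        total += p
        for i, s in enumerate(path):
            acc[i, s] += p
    return acc / total


def brute_best_explanation(pattern, locus, params):
    """(orientation, path, normalized posterior) of the single best explanation."""
    total = 0.0
    best = None
    for orient, path, p in _explanations(pattern, locus, params):
        total += p
        key = (-p, orient, path)
        if best is None or key < best:
            best = key
    return best[1], best[2], -best[0] / total
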