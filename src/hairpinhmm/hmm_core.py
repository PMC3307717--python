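"""The probabilistic model: transitions, emissions, likelihood, decoding.

The observed double-stranded methylation pattern of a molecule is modelled
as the output of three independent two-state Markov chains along the DNA,
tracking whether each of three enzymatic processes is *associated* with the
molecule at each CpG site:

* ``1``  — DNMT1 acting on the daughter strand (maintenance methylation),
* ``3p`` — the de novo enzymes (DNMT3A/B) acting on the parent strand,
* ``3d`` — the de novo enzymes acting on the daughter strand.

Each chain is parameterised by a per-bp reassociating probability ``r``
(an unassociated enzyme binds over 1 bp) and a per-bp dissociating
probability ``d`` (an associated enzyme lets go over 1 bp; it may rebind
within the same bp with probability ``r``).  Small ``d`` means processive
behaviour; the mean association tract length is ``1/d`` bp and the mean
non-association tract (gap) length is ``1/r`` bp.  The stationary fraction
of sites with the enzyme associated is ``f = r / (r + d(1 - r))``.

The joint hidden state at a site is the triple ``(s1, s3p, s3d)`` of
association indicators, packed into an index 0..7 with ``s1`` the most
significant bit: ``index = 4*s1 + 2*s3p + s3d``.

Emissions describe how hidden association states generate the methylation
states of the (parent, daughter) CpG pair at a site, given the probability
``m_i`` that the site was methylated before replication, the enzymes'
maintenance/de novo activity probabilities, and a per-strand bisulfite
conversion error channel.  Because parent/daughter identity is not observed,
the likelihood of a pattern is an equal-weight mixture over the two possible
strand-role assignments (orientations).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

try:  # optional acceleration of the inner forward recursion
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is present in supported envs
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(fn):
            return fn
        return deco if not (args and callable(args[0])) else args[0]

from .patterns_io import MISSING, CpGLocus, DoubleStrandPattern

__all__ = [
    "EnzymeProcessParams",
    "ActivityParams",
    "ErrorParams",
    "SiteDensities",
    "VariantKind",
    "ModelVariant",
    "ModelParams",
    "state_index",
    "state_bits",
    "per_bp_transition",
    "transition_over_distance",
    "stationary_association_frequency",
    "mean_tract_lengths",
    "joint_transition",
    "joint_initial_distribution",
    "emission_true",
    "emission_observed",
    "encode_patterns",
    "dataset_loglik",
    "pattern_loglik",
    "orientation_posterior",
    "posterior_state_marginals",
    "kbest_explanations",
]


# ---------------------------------------------------------------------------
# parameter containers

def _check_prob(value: float, name: str) -> None:
    if not np.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")


@dataclass(frozen=True)
class EnzymeProcessParams:
    """Per-bp reassociating and dissociating probabilities of one association chain."""

    reassoc_per_bp: float
    dissoc_per_bp: float

    def __post_init__(self) -> None:
        _check_prob(self.reassoc_per_bp, "reassoc_per_bp")
        _check_prob(self.dissoc_per_bp, "dissoc_per_bp")


@dataclass(frozen=True)
class ActivityParams:
    """Methylation probabilities of associated enzymes on the daughter strand.

    ``mu1``/``mu3``: probability of methylating the daughter CpG when the
    pre-replication parent CpG was methylated (maintenance).  ``delta1``/
    ``delta3``: the same when it was unmethylated (de novo).  The ratios
    ``mu/delta`` are the hemi-preference ratios.
    """

    mu1: float
    delta1: float
    mu3: float = 1.0
    delta3: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mu1", "delta1", "mu3", "delta3"):
            _check_prob(getattr(self, name), name)


@dataclass(frozen=True)
class ErrorParams:
    """Per-CpG, per-strand bisulfite conversion error probabilities.

    ``p_fail_conversion``: an unmethylated cytosine escapes conversion and is
    read as methylated.  ``p_inappropriate``: a methylated cytosine is
    converted and read as unmethylated.  Errors are independent across CpGs
    and strands.
    """

    p_fail_conversion: float = 0.0
    p_inappropriate: float = 0.0

    def __post_init__(self) -> None:
        _check_prob(self.p_fail_conversion, "p_fail_conversion")
        _check_prob(self.p_inappropriate, "p_inappropriate")


@dataclass(frozen=True)
class SiteDensities:
    """Per-site probabilities that the CpG was methylated before replication."""

    m: tuple[float, ...]

    def __post_init__(self) -> None:
        m = tuple(float(v) for v in self.m)
        object.__setattr__(self, "m", m)
        for v in m:
            _check_prob(v, "site density")

    @classmethod
    def uniform(cls, value: float, n_sites: int) -> "SiteDensities":
        return cls((float(value),) * n_sites)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.m, dtype=float)


class VariantKind(enum.Enum):
    """Identifiability constraints selecting a model variant."""

    #: DNMT3s methylate an associated daughter CpG with probability 1
    #: (mu3 = delta3 = 1); DNMT1 activities free.
    IN_VIVO_DEFAULT = "in_vivo_default"
    #: DNMT1 is purely maintenance (mu1 = 1, delta1 = 0); DNMT3 daughter
    #: activities mu3, delta3 free, so their hemi-preference is estimable.
    DNMT3_HEMI = "dnmt3_hemi"
    #: in vitro single-enzyme setting: both DNMT3 chains disabled
    #: (reassoc = 0, dissoc = 1); only the DNMT1 process is active.
    IN_VITRO_DNMT1 = "in_vitro_dnmt1"


@dataclass(frozen=True)
class ModelVariant:
    kind: VariantKind = VariantKind.IN_VIVO_DEFAULT
    errors_off: bool = False
    fix_site_densities: bool = False


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector of the model, with variant constraints applied."""

    process_dnmt1: EnzymeProcessParams
    process_dnmt3_parent: EnzymeProcessParams
    process_dnmt3_daughter: EnzymeProcessParams
    activity: ActivityParams
    errors: ErrorParams
    densities: SiteDensities
    variant: ModelVariant = field(default_factory=ModelVariant)

    def constrained(self) -> "ModelParams":
        """Return a copy with the variant's constraints substituted in."""
        act, errs = self.activity, self.errors
        p3p, p3d = self.process_dnmt3_parent, self.process_dnmt3_daughter
        if self.variant.kind is VariantKind.IN_VIVO_DEFAULT:
            act = replace(act, mu3=1.0, delta3=1.0)
        elif self.variant.kind is VariantKind.DNMT3_HEMI:
            act = replace(act, mu1=1.0, delta1=0.0)
        elif self.variant.kind is VariantKind.IN_VITRO_DNMT1:
            off = EnzymeProcessParams(reassoc_per_bp=0.0, dissoc_per_bp=1.0)
            p3p = p3d = off
        if self.variant.errors_off:
            errs = ErrorParams(0.0, 0.0)
        return replace(self, activity=act, errors=errs,
                       process_dnmt3_parent=p3p, process_dnmt3_daughter=p3d)

    @property
    def processes(self) -> tuple[EnzymeProcessParams, ...]:
        return (self.process_dnmt1, self.process_dnmt3_parent,
                self.process_dnmt3_daughter)


# ---------------------------------------------------------------------------
# hidden-state indexing: index = 4*s1 + 2*s3p + s3d  (s1 most significant)

_STATE_BITS = np.array(list(itertools.product((0, 1), repeat=3)), dtype=np.int8)


def state_index(s1: int, s3p: int, s3d: int) -> int:
    return 4 * s1 + 2 * s3p + s3d


def state_bits(index: int) -> tuple[int, int, int]:
    return tuple(int(b) for b in _STATE_BITS[index])  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# transitions

def per_bp_transition(p: EnzymeProcessParams) -> np.ndarray:
    """2x2 single-bp transition matrix; rows = current state (0 unassoc, 1 assoc).

    Over one bp an associated enzyme first dissociates with probability ``d``
    and any unassociated enzyme then (re)binds with probability ``r``, so an
    associated enzyme stays associated either by never letting go (``1 - d``,
    processivity) or by falling off and immediately rebinding (``d * r``).
    With ``d = 1`` both rows equal ``(1 - r, r)``: association is independent
    from site to site, the no-processivity limit.
    """
    r, d = p.reassoc_per_bp, p.dissoc_per_bp
    return np.array([[1.0 - r, r],
                     [d * (1.0 - r), 1.0 - d + d * r]], dtype=float)


def transition_over_distance(p: EnzymeProcessParams, L: int) -> np.ndarray:
    """The per-bp matrix raised to the L-th power (L >= 1 bp between sites).

    Computed in closed form from the chain's eigenstructure (see
    ``_transition_batch``); identical to repeated matrix multiplication.
    """
    if L < 1:
        raise ValueError("inter-site distance L must be >= 1 bp")
    return _transition_batch(p, np.array([int(L)]))[0]


def stationary_association_frequency(p: EnzymeProcessParams) -> float:
    """Average fraction of sites at which the enzyme is associated.

    The stationary law of the per-bp chain: ``f = r / (r + d(1 - r))``.  For
    the small dissociation probabilities typical of processive enzymes this
    is numerically indistinguishable from ``r / (r + d)``.
    """
    r, d = p.reassoc_per_bp, p.dissoc_per_bp
    denom = r + d * (1.0 - r)
    if denom == 0.0:
        raise ValueError("stationary frequency undefined for r = d = 0")
    return r / denom


def mean_tract_lengths(p: EnzymeProcessParams) -> tuple[float, float]:
    """(mean association tract, mean non-association tract) in bp: (1/d, 1/r).

    Dwell times of a two-state chain are geometric; a zero rate yields an
    infinite mean tract, returned as ``inf``.
    """
    assoc = np.inf if p.dissoc_per_bp == 0.0 else 1.0 / p.dissoc_per_bp
    non_assoc = np.inf if p.reassoc_per_bp == 0.0 else 1.0 / p.reassoc_per_bp
    return float(assoc), float(non_assoc)


def _transition_batch(p: EnzymeProcessParams, gaps: np.ndarray) -> np.ndarray:
    """(G, 2, 2) closed-form L-step matrices for a vector of gaps (bp).

    The chain's second eigenvalue is ``(1 - r)(1 - d)``; the L-step matrix is
    the stationary projector plus that eigenvalue to the L-th power times the
    complementary projector — identical to repeated matrix multiplication.
    """
    r, d = p.reassoc_per_bp, p.dissoc_per_bp
    denom = r + d * (1.0 - r)
    G = gaps.size
    if denom == 0.0:  # r = d = 0: frozen chain
        return np.broadcast_to(np.eye(2), (G, 2, 2)).copy()
    lam = ((1.0 - r) * (1.0 - d)) ** gaps.astype(float)
    f = r / denom
    out = np.empty((G, 2, 2))
    out[:, 0, 0] = 1.0 - f + f * lam
    out[:, 0, 1] = f - f * lam
    out[:, 1, 0] = (1.0 - f) * (1.0 - lam)
    out[:, 1, 1] = f + (1.0 - f) * lam
    return out


def _joint_transition_batch(params: ModelParams, gaps: np.ndarray) -> np.ndarray:
    """(G, 8, 8) joint matrices: Kronecker product over the 3 chains per gap."""
    t1, t3p, t3d = (_transition_batch(p, gaps) for p in params.processes)
    joint = np.einsum("gij,gkl,gmn->gikmjln", t1, t3p, t3d)
    return joint.reshape(gaps.size, 8, 8)


def joint_transition(params: ModelParams, L: int) -> np.ndarray:
    """8x8 joint L-bp transition matrix, Kronecker product over the 3 chains."""
    if L < 1:
        raise ValueError("inter-site distance L must be >= 1 bp")
    return _joint_transition_batch(params, np.array([int(L)]))[0]


def _stationary_vector(p: EnzymeProcessParams) -> np.ndarray:
    f = stationary_association_frequency(p)
    return np.array([1.0 - f, f])


def joint_initial_distribution(params: ModelParams) -> np.ndarray:
    """Initial distribution at the first CpG: product of per-chain stationary laws."""
    v1, v3p, v3d = (_stationary_vector(p) for p in params.processes)
    return (v1[:, None, None] * v3p[None, :, None] * v3d[None, None, :]).reshape(8)


# ---------------------------------------------------------------------------
# emissions

# true/observed dyad ordering: index = 2*parent + daughter, i.e.
# 0:(P=0,D=0)  1:(P=0,D=1)  2:(P=1,D=0)  3:(P=1,D=1)

def emission_true(state: tuple[int, int, int] | int, m_i: float,
                  a: ActivityParams) -> np.ndarray:
    """Distribution over the true (parent, daughter) methylation pair at a site.

    Generative order: draw the pre-replication parent state
    ``z ~ Bernoulli(m_i)``.  The post-replication parent is methylated if
    ``z = 1`` (methyl groups are not actively removed) or, when ``z = 0``, if
    the parent-strand DNMT3 process is associated (it methylates with
    probability 1).  The daughter is methylated by DNMT1 and/or the
    daughter-strand DNMT3s as independent attempts (noisy-OR), with
    maintenance probabilities used when ``z = 1`` and de novo probabilities
    when ``z = 0`` — the substrate (hemi vs unmethylated) is judged on the
    *pre-replication* state ``z``, not on the concurrently methylated parent.
    """
    if isinstance(state, (int, np.integer)):
        s1, s3p, s3d = state_bits(int(state))
    else:
        s1, s3p, s3d = state
    _check_prob(m_i, "m_i")
    out = np.zeros(4)
    for z, pz in ((1, m_i), (0, 1.0 - m_i)):
        if pz == 0.0:
            continue
        parent = 1 if z == 1 else s3p
        q1 = s1 * (a.mu1 if z == 1 else a.delta1)
        q3 = s3d * (a.mu3 if z == 1 else a.delta3)
        p_daughter = 1.0 - (1.0 - q1) * (1.0 - q3)
        out[2 * parent + 1] += pz * p_daughter
        out[2 * parent + 0] += pz * (1.0 - p_daughter)
    return out


def _strand_error_channel(e: ErrorParams) -> np.ndarray:
    """2x3 channel: rows true state {0,1}, cols observed {0, 1, missing}.

    A missing read contributes a factor 1 (the strand is marginalized), so
    the channel is not row-stochastic over the missing column by design.
    """
    pf, pi_ = e.p_fail_conversion, e.p_inappropriate
    return np.array([[1.0 - pf, pf, 1.0], [pi_, 1.0 - pi_, 1.0]])


def emission_observed(state: tuple[int, int, int] | int, m_i: float,
                      a: ActivityParams, e: ErrorParams) -> np.ndarray:
    """True-dyad distribution pushed through the per-strand error channel.

    Returns the 4-vector over observed (parent-read, daughter-read) pairs in
    the ``2*P + D`` order; with both error probabilities 0 this equals
    :func:`emission_true`.
    """
    true4 = emission_true(state, m_i, a).reshape(2, 2)
    chan = _strand_error_channel(e)[:, :2]
    obs = chan.T @ true4 @ chan
    return obs.reshape(4)


def _emission_tensor(params: ModelParams, n_sites: int) -> np.ndarray:
    """(n_sites, 8, 9) emission table over observed symbol pairs.

    Observed symbol per strand is 0, 1 or 2 (missing); the pair code is
    ``3 * parent_sym + daughter_sym``.  Missing strands contribute a factor
    1, i.e. they are marginalized out.
    """
    a = params.activity
    m = params.densities.as_array()
    if m.size != n_sites:
        raise ValueError("site densities length does not match locus")
    bits = _STATE_BITS  # (8, 3)
    s1 = bits[:, 0][None, :]
    s3p = bits[:, 1][None, :]
    s3d = bits[:, 2][None, :]
    mi = m[:, None]  # (S, 1)

    # z = 1 branch
    p_d1 = 1.0 - (1.0 - s1 * a.mu1) * (1.0 - s3d * a.mu3)
    # z = 0 branch
    p_d0 = 1.0 - (1.0 - s1 * a.delta1) * (1.0 - s3d * a.delta3)

    true4 = np.zeros((n_sites, 8, 2, 2))  # (..., P, D)
    true4[:, :, 1, 1] += mi * p_d1
    true4[:, :, 1, 0] += mi * (1.0 - p_d1)
    # z = 0: parent state equals s3p
    w0 = 1.0 - mi
    for pv in (0, 1):
        mask = (s3p == pv).astype(float)
        true4[:, :, pv, 1] += w0 * mask * p_d0
        true4[:, :, pv, 0] += w0 * mask * (1.0 - p_d0)

    chan = _strand_error_channel(params.errors)  # (2, 3)
    obs = np.einsum("ispd,pa,db->isab", true4, chan, chan)
    return obs.reshape(n_sites, 8, 9)


# ---------------------------------------------------------------------------
# likelihood machinery

_SYM = {0: 0, 1: 1, MISSING: 2}


@dataclass
class EncodedPatterns:
    """Dataset pre-encoded for the vectorized forward pass."""

    sym_a: np.ndarray        # (N, S) strand symbols 0/1/2
    sym_b: np.ndarray
    multiplicity: np.ndarray  # (N,)
    gaps: np.ndarray          # (S-1,) bp distances between consecutive sites
    n_sites: int

    @property
    def n_patterns(self) -> int:
        return int(self.sym_a.shape[0])

    @property
    def orientation_codes(self) -> np.ndarray:
        """(2N, S) observed symbol-pair codes, orientation 0 rows first."""
        if not hasattr(self, "_codes"):
            codes = np.empty((2, self.n_patterns, self.n_sites), dtype=np.int64)
            codes[0] = 3 * self.sym_a + self.sym_b  # strand A as parent
            codes[1] = 3 * self.sym_b + self.sym_a
            self._codes = np.ascontiguousarray(
                codes.reshape(2 * self.n_patterns, self.n_sites))
        return self._codes


def encode_patterns(patterns: Sequence[DoubleStrandPattern],
                    locus: CpGLocus) -> EncodedPatterns:
    S = locus.n_sites
    gaps = locus.gaps
    if np.any(gaps < 1):
        raise ValueError("locus has coincident CpG positions")
    sym = np.vectorize(_SYM.get, otypes=[np.int64])
    sa = np.stack([sym(p.strand_a) for p in patterns])
    sb = np.stack([sym(p.strand_b) for p in patterns])
    if sa.shape[1] != S:
        raise ValueError("pattern length does not match locus")
    mult = np.array([p.multiplicity for p in patterns], dtype=float)
    return EncodedPatterns(sa, sb, mult, np.asarray(gaps, dtype=int), S)


@_njit(cache=False)
def _forward_kernel(E: np.ndarray, codes: np.ndarray, mats: np.ndarray,
                    pi0: np.ndarray) -> np.ndarray:  # pragma: no cover - jitted
    S, K, _ = E.shape
    M = codes.shape[0]
    loglik = np.zeros(M)
    alpha = np.empty(K)
    nxt = np.empty(K)
    for m in range(M):
        norm = 0.0
        c0 = codes[m, 0]
        for a in range(K):
            alpha[a] = pi0[a] * E[0, a, c0]
            norm += alpha[a]
        if norm <= 0.0:
            loglik[m] = -np.inf
            continue
        ll = np.log(norm)
        inv = 1.0 / norm
        for a in range(K):
            alpha[a] *= inv
        dead = False
        for i in range(1, S):
            ci = codes[m, i]
            for b in range(K):
                acc = 0.0
                for a in range(K):
                    acc += alpha[a] * mats[i - 1, a, b]
                nxt[b] = acc * E[i, b, ci]
            norm = 0.0
            for b in range(K):
                norm += nxt[b]
            if norm <= 0.0:
                dead = True
                break
            ll += np.log(norm)
            inv = 1.0 / norm
            for b in range(K):
                alpha[b] = nxt[b] * inv
        loglik[m] = -np.inf if dead else ll
    return loglik


def _forward_numpy(E: np.ndarray, codes: np.ndarray, mats: np.ndarray,
                   pi0: np.ndarray) -> np.ndarray:
    S = E.shape[0]
    M = codes.shape[0]
    # Eobs[i, j, :] = E[i, :, codes[j, i]]
    Eobs = E.transpose(0, 2, 1)[np.arange(S)[:, None], codes.T]  # (S, M, 8)
    alpha = pi0[None, :] * Eobs[0]
    scales = np.empty((S, M))
    scales[0] = alpha.sum(axis=1)
    alpha /= np.where(scales[0] > 0.0, scales[0], 1.0)[:, None]
    for i in range(1, S):
        alpha = (alpha @ mats[i - 1]) * Eobs[i]
        norm = alpha.sum(axis=1)
        scales[i] = norm
        alpha /= np.where(norm > 0.0, norm, 1.0)[:, None]
    with np.errstate(divide="ignore"):
        return np.log(scales).sum(axis=0)  # zero scale -> -inf, as intended


def _forward_logliks(enc: EncodedPatterns, params: ModelParams) -> np.ndarray:
    """Per-pattern, per-orientation log-likelihoods, shape (N, 2).

    Orientation 0 treats strand A as the parent; orientation 1 treats
    strand B as the parent.  Scaled forward recursion (per-site
    normalization), so patterns of any length stay in range.
    """
    params = params.constrained()
    S, N = enc.n_sites, enc.n_patterns
    E = _emission_tensor(params, S)  # (S, 8, 9)
    pi0 = joint_initial_distribution(params)  # (8,)
    mats = _joint_transition_batch(params, enc.gaps) if S > 1 \
        else np.zeros((0, 8, 8))
    fwd = _forward_kernel if _HAVE_NUMBA else _forward_numpy
    loglik = fwd(np.ascontiguousarray(E), enc.orientation_codes,
                 np.ascontiguousarray(mats), pi0)
    return loglik.reshape(2, N).T


def dataset_loglik(enc: EncodedPatterns, params: ModelParams) -> float:
    """Total log-likelihood: multiplicity-weighted sum of orientation mixtures."""
    ll = _forward_logliks(enc, params)  # (N, 2)
    mx = ll.max(axis=1)
    mix = mx + np.log(0.5 * (np.exp(ll[:, 0] - mx) + np.exp(ll[:, 1] - mx)))
    mix = np.where(np.isfinite(mx), mix, -np.inf)
    return float(np.sum(enc.multiplicity * mix))


def pattern_loglik(pattern: DoubleStrandPattern, locus: CpGLocus,
                   params: ModelParams) -> float:
    """log( 1/2 L(A is parent) + 1/2 L(B is parent) ) for one molecule."""
    enc = encode_patterns([pattern], locus)
    ll = _forward_logliks(enc, params)[0]
    mx = ll.max()
    if not np.isfinite(mx):
        return -np.inf
    return float(mx + np.log(0.5 * np.exp(ll[0] - mx) + 0.5 * np.exp(ll[1] - mx)))


def orientation_posterior(pattern: DoubleStrandPattern, locus: CpGLocus,
                          params: ModelParams) -> float:
    """Posterior probability that strand A is the parent (prior 1/2 each)."""
    enc = encode_patterns([pattern], locus)
    ll = _forward_logliks(enc, params)[0]
    mx = ll.max()
    wa, wb = np.exp(ll - mx)
    return float(wa / (wa + wb))


# ---------------------------------------------------------------------------
# smoothing and decoding (single-pattern, per orientation)

def _pattern_codes(pattern: DoubleStrandPattern, orientation: int) -> np.ndarray:
    sym = np.vectorize(_SYM.get, otypes=[np.int64])
    a, b = sym(pattern.strand_a), sym(pattern.strand_b)
    return 3 * a + b if orientation == 0 else 3 * b + a


def posterior_state_marginals(pattern: DoubleStrandPattern, locus: CpGLocus,
                              params: ModelParams) -> dict[str, np.ndarray]:
    """Forward–backward smoothed per-site distributions over the 8 joint states.

    Returns per-orientation marginals (keys ``"A_is_parent"``,
    ``"B_is_parent"``, each (S, 8)) and the orientation-averaged marginal
    (key ``"mixed"``), weighted by the orientation posterior.
    """
    params = params.constrained()
    S = locus.n_sites
    E = _emission_tensor(params, S)
    pi0 = joint_initial_distribution(params)
    mats = [joint_transition(params, int(L)) for L in locus.gaps]

    per_orient = []
    logliks = []
    for orient in (0, 1):
        codes = _pattern_codes(pattern, orient)
        e = np.stack([E[i][:, codes[i]] for i in range(S)])  # (S, 8)
        alpha = np.zeros((S, 8))
        scale = np.zeros(S)
        alpha[0] = pi0 * e[0]
        scale[0] = alpha[0].sum()
        alpha[0] /= scale[0]
        for i in range(1, S):
            alpha[i] = (alpha[i - 1] @ mats[i - 1]) * e[i]
            scale[i] = alpha[i].sum()
            alpha[i] /= scale[i]
        beta = np.zeros((S, 8))
        beta[-1] = 1.0
        for i in range(S - 2, -1, -1):
            beta[i] = (mats[i] @ (e[i + 1] * beta[i + 1])) / scale[i + 1]
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        per_orient.append(gamma)
        logliks.append(float(np.sum(np.log(scale))))

    mx = max(logliks)
    w = np.exp(np.asarray(logliks) - mx)
    w /= w.sum()
    mixed = w[0] * per_orient[0] + w[1] * per_orient[1]
    return {"A_is_parent": per_orient[0], "B_is_parent": per_orient[1],
            "mixed": mixed, "orientation_weights": w}


@dataclass(frozen=True)
class Explanation:
    """One (orientation, hidden path) configuration with its posterior probability."""

    orientation: str           # "A_is_parent" or "B_is_parent"
    path: tuple[int, ...]      # joint state index per site
    posterior: float


def kbest_explanations(pattern: DoubleStrandPattern, locus: CpGLocus,
                       params: ModelParams, k: int = 2) -> list[Explanation]:
    """Top-k joint (orientation, hidden path) explanations of one molecule.

    k-best Viterbi within each orientation, merged across orientations;
    posterior of a configuration = (1/2 x path x emission product) divided by
    the pattern likelihood, so over all ``2 * 8**S`` configurations the
    probabilities sum to 1.  Sorted descending; ties broken by orientation
    then lexicographic path order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    params = params.constrained()
    S = locus.n_sites
    E = _emission_tensor(params, S)
    with np.errstate(divide="ignore"):
        log_pi = np.log(joint_initial_distribution(params))
        log_mats = [np.log(joint_transition(params, int(L))) for L in locus.gaps]

    candidates: list[tuple[float, int, tuple[int, ...]]] = []
    for orient in (0, 1):
        codes = _pattern_codes(pattern, orient)
        with np.errstate(divide="ignore"):
            log_e = np.stack([np.log(E[i][:, codes[i]]) for i in range(S)])
        # lists[state] = up to k (logp, path) entries, best first
        lists: list[list[tuple[float, tuple[int, ...]]]] = [
            [(log_pi[s] + log_e[0][s], (s,))] for s in range(8)
        ]
        for i in range(1, S):
            new_lists: list[list[tuple[float, tuple[int, ...]]]] = []
            for s in range(8):
                merged: list[tuple[float, tuple[int, ...]]] = []
                for prev in range(8):
                    step = log_mats[i - 1][prev, s] + log_e[i][s]
                    if step == -np.inf:
                        continue
                    merged.extend((lp + step, path + (s,)) for lp, path in lists[prev])
                merged.sort(key=lambda t: (-t[0], t[1]))
                new_lists.append(merged[:k])
            lists = new_lists
        for s in range(8):
            candidates.extend((lp, orient, path) for lp, path in lists[s])

    total = pattern_loglik(pattern, locus, params)
    log_half = np.log(0.5)
    scored = [
        (lp + log_half - total, orient, path) for lp, orient, path in candidates
    ]
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    names = ("A_is_parent", "B_is_parent")
    return [
        Explanation(orientation=names[orient], path=path,
                    posterior=float(np.exp(logpost)))
        for logpost, orient, path in scored[:k]
    ]
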