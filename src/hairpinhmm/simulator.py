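"""Generative dual of the HMM: synthetic hairpin-bisulfite datasets.

Simulates, molecule by molecule, the same generative story the likelihood
integrates over: three independent association chains along the CpG sites,
pre-replication methylation states drawn from the per-site densities,
enzymatic methylation of the post-replication strands, the two bisulfite
conversion error types, random strand labelling (so parentage is unknown, as
in real hairpin data), and optionally PCR-crossover chimeras.  Ground truth
(orientation, hidden paths, pre-replication states) is retained alongside
the patterns for evaluating inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hmm_core import (
    ActivityParams,
    EnzymeProcessParams,
    ErrorParams,
    ModelParams,
    ModelVariant,
    SiteDensities,
    transition_over_distance,
    stationary_association_frequency,
)
from .patterns_io import CpGLocus, DoubleStrandPattern

__all__ = [
    "SimulationSpec",
    "SimulationTruth",
    "auto_locus",
    "fmr1_like_locus",
    "fmr1_regime_params",
    "simulate_dataset",
    "empirical_association_frequency",
]


def auto_locus(n_sites: int, seed: int = 0, spacing_low: int = 4,
               spacing_high: int = 10, name: str = "sim_locus",
               chromosome: str = "chrS", start: int = 1000) -> CpGLocus:
    """A synthetic locus with inter-CpG spacings uniform on {low..high} bp.

    The default 4–10 bp range gives a median spacing around 7 bp, typical of
    the dense CpG spacing seen in promoter-region hairpin data.
    """
    rng = np.random.default_rng(seed)
    gaps = rng.integers(spacing_low, spacing_high + 1, size=n_sites - 1)
    positions = start + np.concatenate(([0], np.cumsum(gaps)))
    return CpGLocus(name=name, chromosome=chromosome,
                    cpg_positions=tuple(int(p) for p in positions),
                    region_start=int(positions[0]) - 5,
                    region_end=int(positions[-1]) + 5)


def fmr1_like_locus(seed: int = 7) -> CpGLocus:
    """A 22-site locus mimicking a dense Xi-linked promoter region (~140 bp)."""
    return auto_locus(n_sites=22, seed=seed, spacing_low=4, spacing_high=10,
                      name="fmr1_like", chromosome="chrX")


def _heterogeneous_densities(n_sites: int, mean: float = 0.88,
                             seed: int = 2012) -> SiteDensities:
    """Per-site pre-replication densities with realistic site-to-site spread.

    Drawn once from a Beta(17.6, 2.4) law (mean 0.88) and rescaled to the
    requested mean; densely methylated promoter regions always show this
    kind of heterogeneity, and spatially constant densities would make the
    de novo and conversion-error parameters nearly interchangeable.
    """
    rng = np.random.default_rng(seed)
    m = rng.beta(17.6, 2.4, size=n_sites)
    m = np.clip(m * (mean / m.mean()), 0.30, 0.99)
    return SiteDensities(tuple(m))


def fmr1_regime_params(n_sites: int = 22,
                       variant: ModelVariant | None = None) -> ModelParams:
    """Parameters of the densely methylated Xi-linked regime used throughout.

    DNMT1 is highly processive and nearly always associated (r = 0.12,
    d = 0.002, so mean association tracts of 500 bp and association level
    0.98), with near-perfect maintenance (mu1 = 0.99) and weak de novo
    activity (delta1 = 0.02, hemi-preference ratio ~50).  The DNMT3 chains
    are nearly off (r = 0.01; d = 0.65 parent / 0.28 daughter).  Bisulfite
    errors: inappropriate conversion 0.02, failed conversion 0.003 per CpG
    per strand.  Pre-replication site densities vary across sites around a
    mean of 0.88; with these activities and errors the implied observed
    dyad mix is close to 82% methylated / 6% hemimethylated / 12%
    unmethylated.
    """
    return ModelParams(
        process_dnmt1=EnzymeProcessParams(reassoc_per_bp=0.12, dissoc_per_bp=0.002),
        process_dnmt3_parent=EnzymeProcessParams(reassoc_per_bp=0.01, dissoc_per_bp=0.65),
        process_dnmt3_daughter=EnzymeProcessParams(reassoc_per_bp=0.01, dissoc_per_bp=0.28),
        activity=ActivityParams(mu1=0.99, delta1=0.02, mu3=1.0, delta3=1.0),
        errors=ErrorParams(p_fail_conversion=0.003, p_inappropriate=0.02),
        densities=_heterogeneous_densities(n_sites),
        variant=variant or ModelVariant(),
    )


@dataclass
class SimulationSpec:
    locus: CpGLocus
    true_params: ModelParams
    n_patterns: int
    seed: int = 0
    crossover_rate: float = 0.0
    orientation_randomized: bool = True

    def __post_init__(self) -> None:
        if self.n_patterns < 1:
            raise ValueError("n_patterns must be >= 1")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must be in [0, 1]")
        if len(self.true_params.densities.m) != self.locus.n_sites:
            raise ValueError("site densities length must match locus")


@dataclass
class SimulationTruth:
    """Per-molecule ground truth emitted alongside the observable patterns."""

    a_is_parent: np.ndarray      # (N,) bool: True if strand A got the parent reads
    hidden: np.ndarray           # (N, S, 3) association indicators (s1, s3p, s3d)
    pre_replication: np.ndarray  # (N, S) pre-replication parent state z
    true_parent: np.ndarray      # (N, S) post-replication parent, pre-error
    true_daughter: np.ndarray    # (N, S)
    crossover: np.ndarray        # (N,) bool: molecule replaced by a chimera
    field_order: tuple[str, ...] = ("s1", "s3p", "s3d")


def _sample_chain(p: EnzymeProcessParams, gaps: np.ndarray, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Sample n trajectories of one association chain over the locus's sites."""
    S = gaps.size + 1
    out = np.zeros((n, S), dtype=np.int8)
    f = stationary_association_frequency(p)
    out[:, 0] = rng.random(n) < f
    for i, L in enumerate(gaps, start=1):
        T = transition_over_distance(p, int(L))
        p_assoc = np.where(out[:, i - 1] == 1, T[1, 1], T[0, 1])
        out[:, i] = rng.random(n) < p_assoc
    return out


def simulate_dataset(spec: SimulationSpec
                     ) -> tuple[list[DoubleStrandPattern], SimulationTruth]:
    """Draw a synthetic dataset and its ground truth from the generative model."""
    params = spec.true_params.constrained()
    locus = spec.locus
    rng = np.random.default_rng(spec.seed)
    N, S = spec.n_patterns, locus.n_sites
    gaps = locus.gaps
    a = params.activity
    m = params.densities.as_array()

    s1 = _sample_chain(params.process_dnmt1, gaps, N, rng)
    s3p = _sample_chain(params.process_dnmt3_parent, gaps, N, rng)
    s3d = _sample_chain(params.process_dnmt3_daughter, gaps, N, rng)

    z = (rng.random((N, S)) < m[None, :]).astype(np.int8)
    # post-replication parent: methyl persists; else parent-strand DNMT3s (prob 1)
    parent = np.where(z == 1, 1, s3p).astype(np.int8)
    # daughter: independent attempts by DNMT1 and daughter-strand DNMT3s
    q1 = np.where(z == 1, a.mu1, a.delta1) * s1
    q3 = np.where(z == 1, a.mu3, a.delta3) * s3d
    p_daughter = 1.0 - (1.0 - q1) * (1.0 - q3)
    daughter = (rng.random((N, S)) < p_daughter).astype(np.int8)

    # PCR crossover: replace a molecule by a single-breakpoint hybrid of itself
    # and an independently drawn partner molecule
    crossover = rng.random(N) < spec.crossover_rate
    if crossover.any():
        partners = rng.integers(0, N, size=N)
        breaks = rng.integers(1, S, size=N)  # breakpoint after site `break`-1
        for i in np.flatnonzero(crossover):
            j, b = partners[i], breaks[i]
            parent[i, b:] = parent[j, b:]
            daughter[i, b:] = daughter[j, b:]

    chan_fail = params.errors.p_fail_conversion
    chan_inap = params.errors.p_inappropriate
    def observe(true_mat: np.ndarray) -> np.ndarray:
        u = rng.random(true_mat.shape)
        flip = np.where(true_mat == 1, u < chan_inap, u < chan_fail)
        return np.where(flip, 1 - true_mat, true_mat).astype(np.int8)

    obs_parent = observe(parent)
    obs_daughter = observe(daughter)

    if spec.orientation_randomized:
        a_is_parent = rng.random(N) < 0.5
    else:
        a_is_parent = np.ones(N, dtype=bool)
    strand_a = np.where(a_is_parent[:, None], obs_parent, obs_daughter)
    strand_b = np.where(a_is_parent[:, None], obs_daughter, obs_parent)

    width = len(str(N - 1))
    patterns = [
        DoubleStrandPattern(pattern_id=f"sim_{i:0{width}d}",
                            strand_a=strand_a[i], strand_b=strand_b[i])
        for i in range(N)
    ]
    truth = SimulationTruth(
        a_is_parent=a_is_parent,
        hidden=np.stack([s1, s3p, s3d], axis=-1),
        pre_replication=z,
        true_parent=parent,
        true_daughter=daughter,
        crossover=crossover,
    )
    return patterns, truth


def empirical_association_frequency(truth: SimulationTruth) -> dict[str, float]:
    """Fraction of (molecule, site) pairs with each process associated.

    Converges to the stationary frequency r/(r+d) of each chain as the
    number of molecules grows.
    """
    h = truth.hidden
    return {name: float(h[:, :, k].mean())
            for k, name in enumerate(truth.field_order)}


def write_truth(truth: SimulationTruth, path) -> None:
    """Write the ground-truth sidecar as a TSV (one row per molecule)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("molecule\ta_is_parent\tcrossover\ts1\ts3p\ts3d\tz\n")
        N = truth.a_is_parent.size
        for i in range(N):
            cols = ["".join(str(int(v)) for v in truth.hidden[i, :, k])
                    for k in range(3)]
            zrow = "".join(str(int(v)) for v in truth.pre_replication[i])
            fh.write(f"{i}\t{int(truth.a_is_parent[i])}\t"
                     f"{int(truth.crossover[i])}\t"
                     f"{cols[0]}\t{cols[1]}\t{cols[2]}\t{zrow}\n")
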