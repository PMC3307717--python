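"""Bayesian estimation of the model parameters by MCMC.

The posterior targeted is

    p(theta | data)  ∝  L(data | theta) * prior(theta)

where ``L`` is the orientation-mixture HMM likelihood over all molecules
(multiplicities included) and the prior is, by default, independent
uniform(0,1) on every free probability.  Sampling is component-wise
random-walk Metropolis on the logit scale (so proposals respect the [0,1]
supports), with the per-site pre-replication densities optionally updated as
one block and proposal scales adapted during burn-in only.  Posterior
summaries follow the convention of reporting the median with an 80% credible
interval (10- and 90-percentiles); hemi-preference ratios additionally get a
one-sided 80% lower bound (the 20-percentile), because the data can never
exclude arbitrarily large ratios when the de novo probability is near 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import beta as beta_dist

from . import hmm_core
from .hmm_core import (
    ActivityParams,
    EncodedPatterns,
    EnzymeProcessParams,
    ErrorParams,
    ModelParams,
    ModelVariant,
    SiteDensities,
    VariantKind,
)
from .patterns_io import MISSING, CpGLocus, DoubleStrandPattern

__all__ = [
    "Uniform",
    "Beta",
    "Fixed",
    "PriorSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "free_parameter_names",
    "run_mcmc",
    "summarize_posterior",
    "derived_quantities",
    "convergence_diagnostics",
]


# ---------------------------------------------------------------------------
# priors

@dataclass(frozen=True)
class Uniform:
    """Uniform(0, 1) prior."""

    def logpdf(self, p: float) -> float:
        return 0.0

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.random())


@dataclass(frozen=True)
class Beta:
    alpha: float
    beta: float

    def logpdf(self, p: float) -> float:
        return float(beta_dist.logpdf(p, self.alpha, self.beta))

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.beta(self.alpha, self.beta))


@dataclass(frozen=True)
class Fixed:
    value: float


Prior = Uniform | Beta | Fixed

#: default fixed value for the failure-of-conversion probability; this error
#: type is weakly identified from dense data and is conventionally plugged in
#: from independent calibration rather than estimated.
DEFAULT_P_FAIL = 0.003


@dataclass
class PriorSpec:
    """Per-parameter priors; anything not listed defaults to uniform(0, 1).

    ``p_fail`` defaults to ``Fixed(0.003)``; set it to a non-fixed prior to
    estimate it.  Site densities share the prior under key ``"m"``.
    """

    priors: dict[str, Prior] = field(default_factory=dict)

    def get(self, name: str) -> Prior:
        if name in self.priors:
            return self.priors[name]
        if name.startswith("m_") and "m" in self.priors:
            return self.priors["m"]
        if name == "p_fail":
            return Fixed(DEFAULT_P_FAIL)
        return Uniform()


# ---------------------------------------------------------------------------
# free-parameter bookkeeping

_BASE_NAMES = {
    VariantKind.IN_VIVO_DEFAULT: ["r1", "d1", "r3p", "d3p", "r3d", "d3d",
                                  "mu1", "delta1", "p_inapp"],
    VariantKind.DNMT3_HEMI: ["r1", "d1", "r3p", "d3p", "r3d", "d3d",
                             "mu3", "delta3", "p_inapp"],
    VariantKind.IN_VITRO_DNMT1: ["r1", "d1", "mu1", "delta1", "p_inapp"],
}


def free_parameter_names(variant: ModelVariant, n_sites: int,
                         priors: PriorSpec | None = None) -> list[str]:
    """Names of the parameters sampled under a given model variant."""
    priors = priors or PriorSpec()
    names = [n for n in _BASE_NAMES[variant.kind]
             if not isinstance(priors.get(n), Fixed)]
    if variant.errors_off and "p_inapp" in names:
        names.remove("p_inapp")
    if not isinstance(priors.get("p_fail"), Fixed) and not variant.errors_off:
        names.append("p_fail")
    if not variant.fix_site_densities:
        names.extend(f"m_{i:02d}" for i in range(n_sites))
    return names


def _empirical_site_densities(patterns: Sequence[DoubleStrandPattern],
                              n_sites: int) -> np.ndarray:
    """Plug-in per-site methylation frequency over both strands (scored entries)."""
    meth = np.zeros(n_sites)
    tot = np.zeros(n_sites)
    for p in patterns:
        for strand in (p.strand_a, p.strand_b):
            ok = strand != MISSING
            meth[ok] += p.multiplicity * (strand[ok] == 1)
            tot[ok] += p.multiplicity
    with np.errstate(invalid="ignore"):
        dens = np.where(tot > 0, meth / np.maximum(tot, 1), 0.5)
    return np.clip(dens, 0.01, 0.99)


def _build_params(values: dict[str, float], variant: ModelVariant,
                  densities: np.ndarray) -> ModelParams:
    act = ActivityParams(
        mu1=values.get("mu1", 1.0), delta1=values.get("delta1", 0.0),
        mu3=values.get("mu3", 1.0), delta3=values.get("delta3", 1.0),
    )
    return ModelParams(
        process_dnmt1=EnzymeProcessParams(values["r1"], values["d1"]),
        process_dnmt3_parent=EnzymeProcessParams(
            values.get("r3p", 0.0), values.get("d3p", 1.0)),
        process_dnmt3_daughter=EnzymeProcessParams(
            values.get("r3d", 0.0), values.get("d3d", 1.0)),
        activity=act,
        errors=ErrorParams(p_fail_conversion=values.get("p_fail", DEFAULT_P_FAIL),
                           p_inappropriate=values.get("p_inapp", 0.0)),
        densities=SiteDensities(tuple(densities)),
        variant=variant,
    ).constrained()


# ---------------------------------------------------------------------------
# MCMC

@dataclass
class MCMCConfig:
    n_iterations: int = 6000
    n_burnin: int = 2000
    thin: int = 5
    n_chains: int = 1
    proposal_scale: float = 1.0
    seed: int = 0
    density_block_update: bool = True
    adapt_interval: int = 50
    prior_only: bool = False
    progress_every: int = 0  # 0 disables progress logging

    def __post_init__(self) -> None:
        if self.n_iterations <= self.n_burnin:
            raise ValueError("n_iterations must exceed n_burnin")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws plus metadata.

    ``draws`` has one row per retained draw with the free parameters,
    the log-likelihood and a ``chain`` label.  ``fixed`` records plugged-in
    values (including per-site densities when they were fixed).
    """

    draws: pd.DataFrame
    param_names: list[str]
    variant: ModelVariant
    config: MCMCConfig
    fixed: dict[str, float]
    acceptance_rates: dict[str, float]

    @property
    def n_chains(self) -> int:
        return int(self.draws["chain"].nunique())


class _Target:
    def __init__(self, enc: EncodedPatterns, variant: ModelVariant,
                 priors: PriorSpec, names: list[str],
                 fixed: dict[str, float], fixed_densities: np.ndarray | None,
                 n_sites: int, prior_only: bool,
                 density_init: np.ndarray | None = None):
        self.enc = enc
        self.variant = variant
        self.priors = priors
        self.names = names
        self.fixed = fixed
        self.fixed_densities = fixed_densities
        self.n_sites = n_sites
        self.prior_only = prior_only
        self.density_init = density_init
        self.density_idx = [i for i, n in enumerate(names) if n.startswith("m_")]
        self.scalar_idx = [i for i, n in enumerate(names) if not n.startswith("m_")]

    def params(self, x: np.ndarray) -> ModelParams:
        values = dict(self.fixed)
        for i in self.scalar_idx:
            values[self.names[i]] = float(x[i])
        if self.density_idx:
            densities = x[self.density_idx]
        else:
            densities = self.fixed_densities
        return _build_params(values, self.variant, densities)

    def loglik(self, x: np.ndarray) -> float:
        if self.prior_only:
            return 0.0
        return hmm_core.dataset_loglik(self.enc, self.params(x))

    def log_prior(self, x: np.ndarray) -> float:
        return float(sum(self.priors.get(self.names[i]).logpdf(float(x[i]))
                         for i in range(len(self.names))))


def _run_single_chain(target: _Target, config: MCMCConfig, seed: int,
                      chain_label: int) -> tuple[pd.DataFrame, dict[str, float]]:
    rng = np.random.default_rng(seed)
    names = target.names
    n_par = len(names)

    # initialize from the priors, but start inside the intended labeling:
    # site densities begin at the data's empirical per-site frequencies and
    # maintenance starts >= de novo (the model has a mirror mode that swaps
    # the roles of pre-replication states and strand orientations; like
    # label switching in mixtures, it is excluded by starting — and hence
    # exploring — the basin where DNMT1 is the maintenance enzyme).
    # Zero-likelihood starts are re-drawn a bounded number of times.
    idx_of = {n: i for i, n in enumerate(names)}
    for attempt in range(20):
        x = np.array([target.priors.get(n).sample(rng) for n in names])
        if not target.prior_only:
            if target.density_init is not None and target.density_idx:
                x[target.density_idx] = target.density_init
            for hi, lo in (("mu1", "delta1"), ("mu3", "delta3")):
                if hi in idx_of and lo in idx_of and x[idx_of[hi]] < x[idx_of[lo]]:
                    x[idx_of[hi]], x[idx_of[lo]] = x[idx_of[lo]], x[idx_of[hi]]
        x = np.clip(x, 1e-6, 1.0 - 1e-6)
        ll = target.loglik(x)
        if np.isfinite(ll):
            break
    else:
        raise RuntimeError("could not find a finite-likelihood starting point")

    eta = logit(x)
    lp = target.log_prior(x) + float(np.sum(np.log(x) + np.log1p(-x)))

    # update blocks: each scalar separately; densities as one block (optional)
    blocks: list[list[int]] = [[i] for i in target.scalar_idx]
    if target.density_idx:
        if config.density_block_update:
            blocks.append(list(target.density_idx))
        else:
            blocks.extend([[i] for i in target.density_idx])

    # mode-jumping moves: the association chains have well-separated
    # processive (small d) and dissociation-reassociation (large r, large d)
    # modes that random-walk steps rarely cross.  For each (r, d) pair an
    # independence proposal redraws both coordinates: r from its prior and d
    # log-uniformly on [1e-4, 1], so the thin small-d mode is visited often;
    # the Hastings ratio corrects for the non-uniform d proposal.
    name_to_idx = {n: i for i, n in enumerate(names)}
    jump_blocks: list[tuple[int, int]] = []
    for r_name, d_name in (("r1", "d1"), ("r3p", "d3p"), ("r3d", "d3d")):
        if r_name in name_to_idx and d_name in name_to_idx:
            jump_blocks.append((name_to_idx[r_name], name_to_idx[d_name]))
    # similar prior-independence jumps for parameter groups with swap-type
    # local modes (e.g. a mirror mode exchanging maintenance and de novo
    # roles); proposing from the prior makes the ratio the likelihoods'
    prior_jump_blocks: list[list[int]] = []
    for group in (("mu1", "delta1"), ("mu3", "delta3"), ("p_inapp",)):
        idx = [name_to_idx[n] for n in group if n in name_to_idx]
        if idx:
            prior_jump_blocks.append(idx)
    _D_LO = 1e-4
    _log_range = np.log(1.0 / _D_LO)

    def _log_q_d(d: float) -> float:
        # log-uniform density on [_D_LO, 1]
        return -np.log(d) - np.log(_log_range)
    scales = np.full(len(blocks), config.proposal_scale)
    acc = np.zeros(len(blocks))
    tries = np.zeros(len(blocks))
    acc_total = np.zeros(len(blocks))
    tries_total = np.zeros(len(blocks))

    rows = []
    for it in range(config.n_iterations):
        for b, idx in enumerate(blocks):
            eta_prop = eta.copy()
            step = rng.normal(0.0, scales[b], size=len(idx))
            if len(idx) > 1:
                step /= np.sqrt(len(idx))
            eta_prop[idx] += step
            x_prop = expit(eta_prop)
            x_prop = np.clip(x_prop, 1e-12, 1.0 - 1e-12)
            ll_prop = target.loglik(x_prop)
            lp_prop = (target.log_prior(x_prop)
                       + float(np.sum(np.log(x_prop) + np.log1p(-x_prop))))
            tries[b] += 1
            tries_total[b] += 1
            if np.isfinite(ll_prop) and \
                    np.log(rng.random()) < (ll_prop + lp_prop) - (ll + lp):
                eta, x, ll, lp = eta_prop, x_prop, ll_prop, lp_prop
                acc[b] += 1
                acc_total[b] += 1
        for ri, di in jump_blocks:
            if x[di] < _D_LO:
                # the jump kernel cannot reach states below its support, so
                # the reverse density is zero and the correct move is a
                # rejection; the random-walk moves handle this region
                continue
            x_prop = x.copy()
            x_prop[ri] = target.priors.get(names[ri]).sample(rng)
            x_prop[di] = _D_LO * np.exp(rng.random() * _log_range)
            x_prop = np.clip(x_prop, 1e-12, 1.0 - 1e-12)
            ll_prop = target.loglik(x_prop)
            # r is proposed from its prior (cancels); d needs the Hastings
            # correction for the log-uniform proposal plus its prior ratio
            log_acc = ((ll_prop + target.priors.get(names[di]).logpdf(float(x_prop[di]))
                        - _log_q_d(float(x_prop[di])))
                       - (ll + target.priors.get(names[di]).logpdf(float(x[di]))
                          - _log_q_d(float(x[di]))))
            if np.isfinite(ll_prop) and np.log(rng.random()) < log_acc:
                x, ll = x_prop, ll_prop
                eta = logit(x)
                lp = (target.log_prior(x)
                      + float(np.sum(np.log(x) + np.log1p(-x))))
        for idx in prior_jump_blocks:
            x_prop = x.copy()
            for i in idx:
                x_prop[i] = target.priors.get(names[i]).sample(rng)
            x_prop = np.clip(x_prop, 1e-12, 1.0 - 1e-12)
            ll_prop = target.loglik(x_prop)
            if np.isfinite(ll_prop) and np.log(rng.random()) < ll_prop - ll:
                x, ll = x_prop, ll_prop
                eta = logit(x)
                lp = (target.log_prior(x)
                      + float(np.sum(np.log(x) + np.log1p(-x))))
        if it < config.n_burnin and (it + 1) % config.adapt_interval == 0:
            target_rate = np.where(
                np.array([len(i) for i in blocks]) > 1, 0.234, 0.44)
            rate = acc / np.maximum(tries, 1)
            scales *= np.exp(np.clip(rate - target_rate, -0.5, 0.5))
            scales = np.clip(scales, 1e-3, 20.0)
            acc[:] = 0
            tries[:] = 0
        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
            rows.append(np.concatenate([x, [ll, chain_label]]))
        if config.progress_every and (it + 1) % config.progress_every == 0:
            print(f"chain {chain_label}: iteration {it + 1}/{config.n_iterations}")

    df = pd.DataFrame(rows, columns=names + ["loglik", "chain"])
    df["chain"] = df["chain"].astype(int)
    block_names = ["+".join(names[i] for i in idx) if len(idx) <= 2
                   else "densities" for idx in blocks]
    rates = {bn: float(a / max(t, 1))
             for bn, a, t in zip(block_names, acc_total, tries_total)}
    return df, rates


def run_mcmc(patterns: Sequence[DoubleStrandPattern], locus: CpGLocus,
             variant: ModelVariant | None = None,
             priors: PriorSpec | None = None,
             config: MCMCConfig | None = None) -> PosteriorSamples:
    """Sample the posterior of the free parameters given a dataset.

    Runs ``config.n_chains`` independent chains (seeds derived from
    ``config.seed``), discards burn-in and thins.  Under
    ``variant.fix_site_densities`` the per-site densities are plugged in as
    the empirical per-site methylation frequency of the data; otherwise they
    are sampled with the ``"m"`` prior (uniform by default).
    """
    if not patterns:
        raise ValueError("cannot fit an empty dataset")
    variant = variant or ModelVariant()
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    enc = hmm_core.encode_patterns(patterns, locus)
    names = free_parameter_names(variant, locus.n_sites, priors)

    fixed: dict[str, float] = {}
    for n in _BASE_NAMES[variant.kind] + ["p_fail"]:
        pr = priors.get(n)
        if isinstance(pr, Fixed):
            fixed[n] = pr.value
    if variant.errors_off:
        fixed["p_inapp"] = 0.0
        fixed["p_fail"] = 0.0
    empirical = _empirical_site_densities(patterns, locus.n_sites)
    fixed_densities = None
    if variant.fix_site_densities:
        fixed_densities = empirical
        for i, v in enumerate(fixed_densities):
            fixed[f"m_{i:02d}"] = float(v)

    target = _Target(enc, variant, priors, names, fixed, fixed_densities,
                     locus.n_sites, config.prior_only,
                     density_init=np.clip(empirical, 1e-3, 1 - 1e-3))
    chain_dfs = []
    rates: dict[str, float] = {}
    ss = np.random.SeedSequence(config.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                   ss.spawn(config.n_chains)]
    for c, seed in enumerate(child_seeds):
        df, r = _run_single_chain(target, config, seed, c)
        chain_dfs.append(df)
        rates.update({f"chain{c}:{k}": v for k, v in r.items()})
    draws = pd.concat(chain_dfs, ignore_index=True)
    return PosteriorSamples(draws=draws, param_names=names, variant=variant,
                            config=config, fixed=fixed, acceptance_rates=rates)


# ---------------------------------------------------------------------------
# summaries and derived quantities

def derived_quantities(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-draw scientific quantities: tract lengths, association levels, ratios.

    Tract lengths are 1/d (association) and 1/r (non-association) in bp;
    association level is r/(r+d); hemi-preference ratios are mu/delta with
    draws at delta = 0 giving ``inf`` (quantiles remain well defined on the
    extended line, matching one-sided reporting).
    """
    df = samples.draws
    full = {n: (df[n].to_numpy() if n in df.columns
                else np.full(len(df), samples.fixed.get(n, np.nan)))
            for n in ("r1", "d1", "r3p", "d3p", "r3d", "d3d",
                      "mu1", "delta1", "mu3", "delta3")}
    if samples.variant.kind is VariantKind.IN_VIVO_DEFAULT:
        full["mu3"] = np.ones(len(df))
        full["delta3"] = np.ones(len(df))
    if samples.variant.kind is VariantKind.DNMT3_HEMI:
        full["mu1"] = np.ones(len(df))
        full["delta1"] = np.zeros(len(df))
    if samples.variant.kind is VariantKind.IN_VITRO_DNMT1:
        full["r3p"] = full["r3d"] = np.zeros(len(df))
        full["d3p"] = full["d3d"] = np.ones(len(df))

    out = pd.DataFrame(index=df.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        for tag, r, d in (("dnmt1", "r1", "d1"), ("dnmt3_parent", "r3p", "d3p"),
                          ("dnmt3_daughter", "r3d", "d3d")):
            rv, dv = full[r], full[d]
            out[f"assoc_len_{tag}"] = np.where(dv > 0, 1.0 / np.maximum(dv, 1e-300), np.inf)
            out[f"nonassoc_len_{tag}"] = np.where(rv > 0, 1.0 / np.maximum(rv, 1e-300), np.inf)
            denom = rv + dv * (1.0 - rv)  # stationary law of the per-bp chain
            out[f"assoc_freq_{tag}"] = np.where(denom > 0, rv / np.maximum(denom, 1e-300), np.nan)
        out["hemi_ratio_dnmt1"] = np.where(
            full["delta1"] > 0, full["mu1"] / np.maximum(full["delta1"], 1e-300), np.inf)
        if samples.variant.kind is VariantKind.DNMT3_HEMI:
            out["hemi_ratio_dnmt3"] = np.where(
                full["delta3"] > 0, full["mu3"] / np.maximum(full["delta3"], 1e-300), np.inf)
    out["chain"] = df["chain"].to_numpy()
    return out


def summarize_posterior(draws: pd.DataFrame | PosteriorSamples,
                        min_draws: int = 100) -> pd.DataFrame:
    """Median and 80% CI (10-/90-percentiles) per column; type-7 quantiles.

    Columns whose name starts with ``hemi_ratio`` are summarized one-sided:
    the 20-percentile is reported as the lower bound (column ``q20``) and the
    upper bound is left as NaN, since such ratios are unbounded above when
    the de novo probability can be near 0.
    """
    df = draws.draws if isinstance(draws, PosteriorSamples) else draws
    df = df.drop(columns=[c for c in ("chain",) if c in df.columns])
    if len(df) == 0:
        raise ValueError("no draws to summarize")
    if len(df) < min_draws:
        raise ValueError(f"need at least {min_draws} retained draws, have {len(df)}")
    rows = []
    for col in df.columns:
        v = df[col].to_numpy(dtype=float)
        one_sided = col.startswith("hemi_ratio")
        # interpolation between infinite draws (delta -> 0 ridge) warns; the
        # resulting inf/nan quantiles are meaningful on the extended line
        rows.append(_quiet_quantiles(v, col, one_sided))
    return pd.DataFrame(rows).set_index("quantity")


def _quiet_quantiles(v: np.ndarray, col: str, one_sided: bool) -> dict:
    with np.errstate(invalid="ignore"):
        return {
            "quantity": col,
            "median": float(np.quantile(v, 0.5)),
            "q10": np.nan if one_sided else float(np.quantile(v, 0.1)),
            "q90": np.nan if one_sided else float(np.quantile(v, 0.9)),
            "q20": float(np.quantile(v, 0.2)) if one_sided else np.nan,
        }


def convergence_diagnostics(samples: PosteriorSamples,
                            rhat_threshold: float = 1.05,
                            ess_threshold: float = 100.0) -> pd.DataFrame:
    """Split-chain potential scale reduction (R-hat) and effective sample size.

    Uses ArviZ's rank-normalized split R-hat and bulk ESS.  With a single
    chain only the ESS is reported (R-hat is NaN) and a warning flag is set.
    """
    import arviz as az

    df = samples.draws
    chains = sorted(df["chain"].unique())
    per_chain = [df[df["chain"] == c][samples.param_names].to_numpy()
                 for c in chains]
    n = min(len(a) for a in per_chain)
    stacked = np.stack([a[:n] for a in per_chain])  # (chain, draw, param)
    data = {name: stacked[:, :, j]
            for j, name in enumerate(samples.param_names)}
    idata = az.from_dict(posterior=data)
    ess = az.ess(idata)
    rows = []
    single = len(chains) < 2
    rhat = None if single else az.rhat(idata)
    for name in samples.param_names:
        r = np.nan if single else float(rhat[name].values)
        e = float(ess[name].values)
        rows.append({
            "parameter": name,
            "rhat": r,
            "ess_bulk": e,
            "flag": bool(single or (np.isfinite(r) and r > rhat_threshold)
                         or e < ess_threshold),
        })
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# serialization

def write_samples(samples: PosteriorSamples, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# variant={samples.variant.kind.value}"
                 f" errors_off={samples.variant.errors_off}"
                 f" fix_site_densities={samples.variant.fix_site_densities}\n")
        fh.write(f"# seed={samples.config.seed}"
                 f" n_iterations={samples.config.n_iterations}"
                 f" n_burnin={samples.config.n_burnin}"
                 f" thin={samples.config.thin}"
                 f" n_chains={samples.config.n_chains}\n")
        for k, v in samples.fixed.items():
            fh.write(f"# fixed {k}={v}\n")
        samples.draws.to_csv(fh, sep="\t", index=False)
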