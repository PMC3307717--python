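# Methods

## The model

`hairpinhmm` infers in vivo properties of the mammalian DNA
methyltransferases — the maintenance enzyme DNMT1 and the de novo enzymes
DNMT3A/B — from double-stranded CpG methylation patterns measured by
hairpin-bisulfite PCR. Each sequenced molecule reports the methylation
state of **both** strands at every CpG of one locus; which strand is the
replication parent and which is the newly synthesized daughter is not
observable.

The data are modelled by a hidden Markov model over the CpG sites of the
locus. The hidden state at a site is the triple of association indicators

    (s1, s3p, s3d) ∈ {0,1}³   →   8 joint states, index 4·s1 + 2·s3p + s3d

for three independent two-state Markov chains along the DNA: DNMT1 on the
daughter strand, the DNMT3s on the parent strand, and the DNMT3s on the
daughter strand.

### Association chains (processivity)

Each chain has a per-bp reassociating probability `r` and a per-bp
dissociating probability `d`. Over one bp an associated enzyme first
dissociates with probability `d`, and any unassociated enzyme binds with
probability `r`; an associated enzyme therefore stays associated either
processively (`1 − d`) or by falling off and immediately rebinding (`d·r`):

    T = [ 1 − r        r        ]
        [ d(1 − r)     1 − d + d·r ]

`d = 1` is the no-processivity limit: both rows collapse to `(1 − r, r)` and
association becomes independent from site to site. The transition matrix
between CpGs `L` bp apart is `T^L`, computed in closed form from the chain's
eigenstructure (second eigenvalue `(1 − r)(1 − d)`); this equals repeated
matrix multiplication exactly and vectorizes over the locus's gaps. The
stationary association frequency is `f = r / (r + d(1 − r))`; for the small
`d` of processive enzymes this is indistinguishable from `r/(r+d)`.
Interpretable summaries: mean association tract `1/d` bp (dissociation
events end a tract, even when followed by instant rebinding, so
dissociation–reassociation cannot masquerade as processivity), mean
non-association gap `1/r` bp.

The chain is assumed at stationarity when it enters the region, so the
hidden distribution at the first CpG is the product of the three stationary
laws. Inter-site distances are differences of the 1-based genomic
coordinates of the CpG cytosines on the top strand; coincident sites are
rejected.

### Emissions (substrate preference)

At site `i`, the pre-replication parent state is `z ~ Bernoulli(m_i)`, where
`m_i` is the site's methylation density. Generatively:

* parent strand: methyl groups are never actively removed, so `z = 1` keeps
  the parent methylated; when `z = 0` the parent-strand DNMT3s methylate
  with probability 1 if associated (`s3p`).
* daughter strand: DNMT1 (if `s1 = 1`) methylates with probability `mu1`
  when `z = 1` (maintenance) and `delta1` when `z = 0` (de novo); the
  daughter-strand DNMT3s analogously with `mu3`, `delta3`. Simultaneous
  association combines as independent attempts (noisy-OR). The substrate
  type (hemi vs unmethylated) is judged on the *pre-replication* state `z`,
  not on the concurrently methylated parent — this is what makes the fully
  methylated dyad under `(s1=1, s3p=1)` a sum of a maintenance term `m·mu1`
  and a double-de-novo term `(1−m)·delta1`.

`mu/delta` is the **hemi-preference ratio**, the enzyme's preference for
hemimethylated over unmethylated substrate.

Bisulfite conversion errors act as an independent per-strand channel on the
true states: an unmethylated cytosine reads methylated with probability
`p_fail_conversion` (failed conversion) and a methylated cytosine reads
unmethylated with probability `p_inappropriate` (inappropriate conversion).
A missing read (`?`) marginalizes its strand. Because parentage is unknown,
a molecule's likelihood is the equal-weight mixture of the two strand-role
assignments; the forward pass runs both orientations and mixes at the end.

### Model variants

* `in_vivo_default` — `mu3 = delta3 = 1` (association of daughter-strand
  DNMT3s is synonymous with methylation). Used for most analyses.
* `dnmt3_hemi` — DNMT1 purely maintenance (`mu1 = 1, delta1 = 0`), freeing
  `mu3`, `delta3` so the DNMT3 hemi-preference becomes estimable. The
  constraint values follow the reading that DNMT1 is the primary
  maintenance enzyme.
* `in_vitro_dnmt1` — both DNMT3 chains disabled (`r = 0, d = 1`) for
  single-enzyme in vitro data.
* flags: `errors_off` (both error probabilities pinned to 0) and
  `fix_site_densities` (plug in the empirical per-site methylation
  frequency instead of sampling the `m_i`).

## Inference

Bayesian, by Markov chain Monte Carlo. Free parameters (depending on the
variant): the three `(r, d)` pairs, the activity probabilities, the
inappropriate-conversion probability, and one density `m_i` per site.
`p_fail_conversion` is fixed by default at 0.003 — this error type is weakly
identified from dense data and is conventionally plugged in from
independent calibration; it is configurable and can be given a prior
instead. Priors default to uniform(0,1); Beta priors and point-fixing are
supported per parameter.

The sampler is component-wise random-walk Metropolis on the logit scale
(proposals respect the [0,1] supports; the Jacobian `p(1−p)` is included).
Site densities are updated as one joint block by default (individually on
request); proposal scales adapt toward 44% acceptance (23% for the block)
during burn-in only, so the post-burn-in chain is a valid fixed kernel.
Random-walk moves alone mix poorly across this posterior's structure, so
two kinds of independence "jump" moves are mixed in every iteration:
for each association chain, a joint `(r, d)` redraw with `r` from its
prior and `d` log-uniform on [1e-4, 1] (exact Hastings correction) — this
crosses between the thin processive mode and the broad
dissociation–reassociation arm — and prior redraws of `(mu1, delta1)`,
`(mu3, delta3)` and the error rate. Prior-only runs (likelihood switched
off) reproduce the priors exactly, which validates every acceptance
ratio. Chains initialize from the priors but start inside the intended
labeling: site densities begin at the data's empirical per-site
frequencies and maintenance ≥ de novo at the start — the model has a
mirror mode (pre-replication states relabeled, orientations swapped,
maintenance and de novo roles exchanged) that is handled like label
switching in mixture models. Zero-likelihood starts are re-drawn up to 20
times. Multiple chains derive their seeds from one seed via
`SeedSequence`; runs are bit-reproducible.

Summaries follow the convention: posterior median with an 80% credible
interval (10- and 90-percentiles, type-7 linear interpolation), chosen over
95% intervals because several posteriors are heavy-tailed. Hemi-preference
ratios are reported one-sided (20-percentile lower bound only): when the
de novo probability can approach 0 the ratio is unbounded above, and draws
with `delta = 0` to machine precision are kept as `+inf` on the extended
line, where quantiles remain well defined. Convergence diagnostics
(rank-normalized split R-hat, bulk ESS) come from ArviZ; default warning
thresholds are R-hat > 1.05 and ESS < 100.

The forward pass is linear in molecules and sites (8 states; 8×8 gap
matrices built in closed form). The inner recursion is a numba-jitted
kernel with a numpy fallback; both are tested for agreement, and the
likelihood is validated against exhaustive enumeration over all
`2·8^S` explanations on small loci.

## The simulator

`simulator.simulate_dataset` is the exact generative dual of the
likelihood: stationary starts, `T^L` steps between sites, `z ~ Bern(m_i)`,
the emission law above, the two error flips, then random A/B strand
labelling so parentage is unknown, exactly like real hairpin data.
Ground truth (orientation, hidden paths, pre-replication states, crossover
flags) goes to a sidecar, never into the pattern file. PCR-crossover
artifacts can be injected as single-breakpoint hybrids of two simulated
molecules (uniform breakpoint), matching how one template switch produces a
chimeric pattern; double crossovers are not injected by default.

The default study regime (`fmr1_regime_params`) mimics a densely methylated
Xi-linked promoter: `r1 = 0.12`, `d1 = 0.002` (500 bp mean association
tracts, association level 0.99), `mu1 = 0.99`, `delta1 = 0.02`
(hemi-preference ≈ 50), DNMT3 chains nearly off (`r = 0.01`;
`d3p = 0.65`, `d3d = 0.28`), `p_inappropriate = 0.02`,
`p_fail_conversion = 0.003`. Site densities are heterogeneous — one frozen
Beta(17.6, 2.4) draw rescaled to mean 0.88 — because real promoter loci
always vary site to site, and spatially constant densities would leave the
de novo and conversion-error parameters nearly interchangeable. The
implied observed dyad mix is ≈ 82.5% fully methylated / 6.2% hemi /
11.2% unmethylated, matching the composition reported for such loci.
Synthetic loci draw inter-CpG spacings uniformly from 4–10 bp (median ≈ 7,
typical of these promoter regions).

What the simulator does **not** emulate: read-level artifacts (PCR bias,
sequencing error beyond the two conversion error types), cell-population
heterogeneity in the parameters themselves, multiple enzymatic passes per
replication round (inferred processivity is therefore cumulative), and
active demethylation. Passing recovery tests show the inference is
self-consistent under the model's own assumptions at realistic sizes; they
cannot certify those assumptions for real molecules.

## Numerical and design choices

* Scaled (per-site normalized) forward recursion; log-space mixing of the
  two orientations. A pattern with all sites missing has likelihood 1.
* k-best decoding: k-best Viterbi per orientation, merged, normalized by
  the pattern likelihood so all `2·8^S` explanation posteriors sum to 1;
  ties break by orientation then lexicographic path order.
* Degenerate inputs: `r = d = 0` leaves the stationary frequency undefined
  and is rejected in likelihood contexts; `L = 0` (coincident CpGs) is
  rejected; zero-probability observations drive the likelihood to `−inf`
  rather than raising.
* The adjacent-hemi permutation test is a reconstruction (the statistic and
  null were chosen here): observed statistic = number of adjacent site
  pairs whose dyads are both hemimethylated with the methyl on the same
  strand, summed over molecules; null = independent within-molecule
  permutation of each dyad sequence, which keeps composition and breaks
  adjacency; p-values use the add-one convention, so p ∈ (0, 1].
* Hemi runs are maximal runs of ≥ 2 same-orientation hemi dyads; missing or
  opposite-orientation dyads break runs; lengths ≥ 6 share one bin.

## Known limitations

* **Error-rate identifiability at desk scale.** At 200 molecules × 22 CpGs,
  the inappropriate-conversion probability is partially confounded with
  `(mu1, delta1, r3d)`: a conversion error on one strand of a fully
  methylated dyad is observationally close to a maintenance failure or a
  de novo event. Well-mixed chains (R-hat ≤ 1.01) place the posterior
  median near 0.01 when the generating value is 0.02, so frequentist 80%
  CI coverage for this parameter sits well below nominal at this design
  size. Larger datasets (the effect vanishes by a few thousand molecules)
  or external calibration of the error rates resolve this.
* **Ridge geometry of the association parameters.** The likelihood is
  nearly flat along a ridge of constant association level `f` connecting
  the processive corner (small `d`, small `r`) to a broad
  dissociation–reassociation arm, and the posterior consequently has a
  mild volume-driven pull away from the corner. The reassociation and
  activity parameters (`r1`, `mu1`, `delta1`) remain calibrated at the
  default study size, but credible intervals for the dissociation
  probability `d1` under-cover a fixed corner truth (several simulated
  datasets genuinely resemble a slightly less processive enzyme); longer
  chains do not change this — it is posterior geometry, not a sampling
  artifact. Real analyses should read `d1` together with its full
  posterior and the prior-sensitivity behavior, as is standard for
  flagged, weakly informed parameters.
* MCMC chain lengths used in the test-suite studies (3000 iterations, 1000
  burn-in, thin 2, 200 molecules per replicate, 20 replicates) are sized
  for desk-scale reproducibility; production analyses should run the
  packaged defaults (≥ 6000 iterations, multiple chains) and check the
  diagnostics report.
* The DNMT3 dissociation probabilities are unidentifiable whenever DNMT3
  association is rare — their posteriors then simply return the prior, as
  expected, and the package's uninformative-data check asserts exactly
  that.
* No model-comparison machinery (marginal likelihoods) is provided, and the
  tetrameric DNMT3A binding mode is out of scope.
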