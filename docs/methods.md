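# Methods

`chronnect` implements a complete analysis chain for *time-varying
connector networks with preserved negative links* in parcel-level
functional time series, together with a synthetic-data generator that
plants the structure the chain is designed to detect.

## Analysis model

**Band limitation.** Parcel series are reduced to a low-frequency band
(default 0.03–0.07 Hz) by a shift-invariant wavelet multiresolution
analysis: the detail component at level *j* has theoretical passband
[f_nyq/2^j, f_nyq/2^(j−1)], and the output sums the components whose
passband overlaps the requested band by at least half of the narrower
interval. At a 2 s sampling interval this selects exactly level 3
(0.031–0.0625 Hz); dyadic passbands cannot match an arbitrary band, and
levels that merely graze a band edge are excluded. The default filter
is the least-asymmetric 16-tap wavelet (`sym8`): with the 8-tap
`sym4` the level-3 component retains only ~64 % of a mid-band
0.05 Hz tone (FFT band-power oracle), versus ~72–80 % for `sym8`,
whose sharper rolloff also keeps out-of-band leakage below 1 %.
Series are reflection-padded to a multiple of 2^level and cropped, so
the components still sum to the input exactly. Filtering operates on
the trial-concatenated run of each subject × condition; a single
9-sample trial cannot support the decomposition depth.

**Dynamic correlations.** Each parcel pair's time-varying correlation
is estimated with the two-stage DCC(1,1) model: per-parcel GARCH(1,1)
by Gaussian quasi-ML with variance targeting
(ω = s²(1 − α − β)), then the correlation recursion
Q_t = (1 − a − b)·Q̄ + a·ε_{t−1}ε′_{t−1} + b·Q_{t−1} with
r_t = Q_t normalized to unit diagonal, parameters by quasi-ML with
correlation targeting (Q̄ = sample second-moment matrix of the
standardized residuals). Estimation is pairwise-bivariate — tractable
at hundreds of parcels and faithful to common neuroimaging usage — and
runs on the concatenated run per subject × condition, then is epoched
back to trials; nine samples are far too few to fit a GARCH model
per trial. Both recursions are linear IIR filters in their driving
terms and are evaluated through `scipy.signal.lfilter`; the optimizer
seeds one bounded L-BFGS-B polish from the best cell of a coarse 6 × 6
grid over (a, b), which is markedly more robust than multistart on the
often-flat quasi-likelihood surface of short series. Non-convergence
falls back to the constant-correlation model (a = b = 0), flagged and
counted in the run manifest. Parameter recovery on simulated data
(n = 4000, 20 replicates) gives median absolute errors ≈ 0.01 for both
a and b.

**Group matrices.** For each condition and within-trial time index k,
correlations at the k-th sample of every trial are averaged over
subjects and trials on the r scale and then Fisher z-transformed
(z after averaging; averaging on the z scale first is available as a
switch, default off). A 3-condition × 9-sample design yields 27
group matrices.

**Signed graphs.** Correlations map to weights by the power
soft-threshold w = ((r + 1)/2)^12 — strictly increasing, sending
r = −1 to 0 and r = 1 to 1 — which suppresses rather than removes
weak and negative links and keeps the graph fully connected. Because
the mapping needs r ∈ [−1, 1], Fisher-z matrices are back-transformed
(tanh) before thresholding. Communities come from Louvain modularity
(resolution 1, best of 20 seeded runs). Participation coefficient is
PC_i = 1 − Σ_s (κ_is/k_i)². Nodal and edge betweenness use shortest
paths under the length transform length = 1/w (strong links are
short), unnormalized, unordered pairs, endpoints excluded for nodal
and included for edge betweenness; normalization is irrelevant to the
"≠ 0" hub rule and to binarization.

**Connector hubs and sparsification.** A connector hub has PC > 0.5
and nonzero nodal and edge betweenness at every time index of its
condition. Classified hubs are pruned to a fixed point: a hub is
retained only if it has a nonzero-edge-betweenness link to another
retained hub in a different community at some time index. Support is
aggregated over time because the retention rule describes the
condition's hub roster, and a hub's intermodular edges can rotate
across time points while the hub itself remains a stable connector.
The connector network at (condition, k) then keeps exactly the
hub–hub edges whose edge betweenness is nonzero — the union of
shortest paths — carrying the *signed* group-z value unchanged, so
negative intermodular links survive sparsification by construction.

**Backbone and small-worldness.** The functional backbone is the hub
set shared by all conditions plus, per condition, the edges present at
every time index (exact binary equality; Jaccard similarity is
reported as a diagnostic only). Small-worldness σ = γ/λ is computed
on the binarized connector network (clustering and path length are
undefined for signed weights) against 50 degree-preserving
Maslov–Sneppen rewired nulls (10·|E| swap attempts each, seeded);
γ = 0 for triangle-free networks, and a network needs ≥ 4 nodes to be
evaluated. Union-of-shortest-paths networks are triangle-poor, so σ
lands well below 1.

## Synthetic data generator

The generator emulates a multi-subject, multi-condition, trial-
structured task fMRI experiment at parcel level: 3 conditions,
9 trials per condition, 9 samples per trial at a 2 s sampling
interval, 24 subjects, 30 parcels in 6 modules. Innovations at each
sample carry a planted instantaneous correlation matrix and per-parcel
GARCH(1,1) conditional variances (ω, α, β = 0.05, 0.10, 0.85); trials
are contiguous segments of one long stationary-parameter run, epoched
afterwards.

The planted correlation structure, chosen once by a
positive-definiteness and detection-margin analysis:

* six modules (intra-module r = 0.75, weak allied coupling 0.18
  between modules of the same system) grouped into two mutually
  anticorrelated *systems* (member-level cross-system r = −0.20),
  mirroring task-positive/task-negative organisation — mutual
  anticorrelation among K independent modules is infeasible below
  −1/(K−1), so the planted negativity lives between two supersystems;
* one designated *connector parcel* per module acting as a
  system-wide gateway: uniform moderate coupling (0.40) to every
  member of its own system, weak coupling to its fellow connectors
  (0.20, so connector–connector links within a system never lie on
  shortest paths), and cross-system couplings milder than the member
  level (−0.17 to members, −0.13 to the opposite system's
  connectors — the *bridges*);
* a smooth periodic attenuation of all off-diagonal correlations
  (amplitude 0.2, period = one 18 s trial, per-condition phase).
  The factor multiplies the off-diagonal block and never exceeds 1,
  so the modulated matrix shrinks toward the identity and stays
  positive definite whenever the base matrix is.

This geometry makes the planted connectors exactly what the hub rule
detects. Their participation spreads over several communities
(PC ≈ 0.67 versus ≤ 0.4 for members). Because direct member–member
links between modules are much weaker than the two-hop route through
a connector, essentially all inter-module traffic passes through some
connector — betweenness is guaranteed by the planted topology rather
than won in a noise lottery, so every connector keeps nonzero nodal
betweenness at (almost) every time point. And all cross-system
shortest paths traverse connector-to-connector *bridge* edges whose
correlation values are negative, so the sparsified connector networks
consist of negatively linked hubs across communities with a
bipartite-like, triangle-poor structure (σ < 1).

Two design constants deserve justification. Bridges are planted
several noise standard deviations below zero because shortest-path
retention *selects* the least-negative crossing (an extreme-value
bias toward zero would otherwise flip retained values positive). And
the β = 12 soft-threshold amplifies estimation noise on edge lengths
multiplicatively (≈ e^(12σ/(1+r))), which funnels cross-system
traffic through one or two winning bridges at any one time point — a
scale effect, not an estimator defect; the winning bridge rotates
across time points, which is why hub pruning aggregates intermodular
support over time.

**What the generator does not emulate:** hemodynamic response
convolution, scanner noise spectra and drift, head motion, spatial
autocorrelation between parcels, heterogeneous per-edge coupling
strengths, and anatomically realistic module sizes. Passing tests
demonstrate that the pipeline recovers the planted structure under the
model's own assumptions — not that the same settings are optimal for
real fMRI data.

## Problem sizes and scale compensation

The default network is 30 parcels (the full-scale study this emulates
used 278); at this reduced size, node-level graph metrics average
noise over communities of ~5 nodes instead of ~40, so group-matrix
entry noise (σ ≈ 0.05 at 24 subjects × 9 trials) leaves hub
classification lottery-dominated. The shared study-scale test run and
the acceptance script therefore generate 96 trials per condition,
bringing entry noise to σ ≈ 0.015 — the level at which a Monte-Carlo
analysis of the planted design shows hub recovery is reliable — and
per-node metrics to a signal-to-noise ratio comparable to the
full-resolution setting. Generator defaults keep the 9-trial design.

## Numerical choices and degenerate inputs

* GARCH/DCC stationarity is enforced as a + b ≤ 0.999 with a penalty
  outside the box; |r_t| ≤ 1 holds by construction (each Q_t is a PSD
  combination) and is clipped only inside the likelihood.
* Constant (zero-variance) series are rejected by the estimators and
  mapped to zero by the band filter.
* The Fisher transform refuses |r| ≥ 1; diagonals are excluded
  upstream and stored as z = 0.
* Louvain ties are resolved by best-of-n modularity with seeds derived
  deterministically from the run configuration; identical config and
  seed reproduce byte-identical outputs, digest-verified in the run
  manifest.
* Small-worldness guards 0/0: a triangle-free network has γ = 0 (and
  σ = 0); a clustered network whose nulls are all triangle-free is
  flagged undefined rather than divided.
* An empty hub set or empty connector network is a declared result,
  not an error; the intermodular sign summary returns fraction `None`
  when no intermodular edge exists.

## Known limitations

* Pairwise-bivariate DCC ignores cross-pair information; a joint
  p-dimensional model would share the correlation driver but is not
  tractable at this pair count.
* On 81-sample band-limited runs the GARCH stage is weakly identified
  (the band filter leaves ~n/8 effective degrees of freedom);
  estimates are usable only after group averaging, which is exactly
  how the pipeline consumes them.
* Hub classification at 30 parcels is sensitive to the shortest-path
  winner-take-all effect described above; conclusions about marginal
  hubs should rest on the full-scale (hundreds of parcels) setting.
* The backbone's "stable edge" criterion (exact presence at all nine
  time indices) is strict; under strong noise the stable edge set can
  be empty even when hubs are stable.
* Because the group-matrix noise is dominated by a *static*
  per-condition component (the dynamic-correlation fits are shared
  across within-trial time points), shortest-path retention selects
  one or two statically determined bridge edges per condition, and
  they often share an endpoint. The pruned hub roster of a synthetic
  condition is therefore typically two to three connectors — below
  the four-node minimum for a small-worldness evaluation — in a
  substantial fraction of runs. The σ < 1 property of
  union-of-shortest-paths networks is exercised by unit tests on
  constructed networks regardless; at full (hundreds-of-parcels)
  scale the connector networks are large enough to evaluate directly.
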