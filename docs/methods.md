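# Methods

## Study design being emulated

A single-subject dense-sampling design: 40 resting-state fMRI sessions over
30 consecutive days (TR = 0.72 s, 1,250 frames ≈ 15 min per session), 20
sessions at ~7 a.m. (one hour after waking) and 20 at ~8 p.m. (~14 h after
waking). Saliva is collected at every session (salivary testosterone and
cortisol); serum is drawn on 30 of the 40 sessions (serum testosterone,
free testosterone, estradiol, serum cortisol), split 15 morning / 15
evening by alternating the draw on two-session days. Mood/state scales are
completed each session.

## Synthetic signal model

Each node's session timeseries is a unit-variance mixture of band-limited
latent signals plus white measurement noise:

    x_i(t) = a·g(t) + b_i·m_{net(i)}(t) + Σ_e w_e(s)·u_e(t) + c_i·v_i(t) + ε_i(t)

where `g` is a global latent shared by all nodes, `m_k` a per-network block
latent, `u_e` a pair latent shared only by the two endpoints of a coupled
edge `e`, `v_i` a node-private latent, and ε white noise with SD
`noise_sd`. All latents are white noise band-limited to the analysis band
by the same MODWT filter used in estimation, then re-standardized, so the
intended coherence algebra holds inside the band.

For two nodes mixing a shared unit-variance latent with weights w and all
sources independent, the band magnitude-squared coherence is (w·w')² of the
total shared cross-spectral fraction. The weights therefore solve:

- global floor: a² = sqrt(global_coherence) so every pair has MSC ≈
  global_coherence (default 0.12);
- within-network baseline: a² + b² = sqrt(baseline_block_coherence)
  (default 0.4);
- coupled edge at session s: a² + w(s)² = sqrt(ρ(s)) with target
  ρ(s) = clip(baseline + β·z_s, 0, 0.97), where z_s is the session's
  z-scored coupling analyte (salivary testosterone by default) and β is in
  coherence units per hormone SD.

Coupled-edge endpoints carry **no block latent**, and only their private
weight c_i shrinks/grows to keep unit variance as w(s) changes. This is
essential: if the hormone-dependent pair weight displaced a *shared*
component (block or global), every edge incident to a coupled node would
inherit a session-varying cross-spectral fraction and thus spurious hormone
coupling. With the private-only trade-off, the global and block weights are
constant across sessions and exactly the listed edges track the hormone.

Feasibility requires a² + Σ_e w_e(s)² ≤ 1 per node; at the defaults the
worst case is a² + sqrt(0.97) ≈ 0.985. Configurations that violate it
(e.g. two high-baseline coupled edges sharing a node) raise `ConfigError`
rather than being silently renormalized. Measurement noise (white, SD 0.5 by
default) attenuates the realized in-band coherence modestly — on the order
of 10 % at the defaults, since only the noise power falling inside the
0.01–0.17 Hz band competes with the band-limited latents — so realized
coherence is an emergent quantity the estimator sees, not a value the
generator writes down.

Limits of realism: latents are stationary Gaussian within a session; there
is no hemodynamic model, scanner drift beyond a linear trend, or spatial
autocorrelation beyond the network blocks; motion influences the data only
through the nuisance pathway (it is generated, regressed, and summarized,
but not convolved into the BOLD signal).

## Estimation pipeline

**Nuisance regression.** FWD is the sum of absolute frame-to-frame
differences of the six rigid-body parameters with rotations (radians)
scaled by a 50 mm head radius. The design is the Friston-24 expansion
(6 params, their one-frame lags, and both squared) plus one indicator per
frame with FWD > 0.5 mm. Timeseries are median-1000 scaled (skipped when
the median is ~0 relative to the spread, as for already-centered data),
and residualized against the design plus a linear trend by least squares;
rank-deficient design columns are dropped.

**Connectomes.** Each regional timeseries is band-limited by an MODWT MRA
(sym8, `pywt.mra(..., transform="swt")`, reflect padding to a multiple of
2⁶) keeping detail levels 3–6, nominal band [1/(2⁷·TR), 1/(2³·TR)] =
[0.0109, 0.1736] Hz at TR = 0.72 s. The level-6 filter support (15·63 + 1 =
946 taps) sets the minimum usable session length. Magnitude-squared
coherence is Welch's estimate (Hann window 128, 50 % overlap → L = 18
segments at 1,250 frames) averaged over in-band frequencies; it matches
`scipy.signal.coherence` exactly. Per-session matrices are thresholded by
BH FDR (q = 0.05) against the independence null p = (1 − C)^(L−1).

**Edgewise regression.** Hormone and edge values are z-scored per edge;
the statistic is the regression t (equal to r·sqrt((n−2)/(1−r²)) without
covariates; computed via pseudoinverse with covariates). The null permutes
session order: exhaustively when B ≥ n! (p then exact), otherwise B Monte
Carlo draws with p = #{b : |t_b| ≥ |t_obs|} / B, floored at 1/B. Serum-only hormones use only the serum sessions (df =
n_serum − 2). Two masks are kept: BH FDR q = 0.05 (used for strengths) and
p < 0.001 (display). **Permutation resolution:** BH at q over m edges with
k true effects needs the p floor ≈ 1/B below k·q/m; B = 2,000 suffices for
the 40-node validation studies (m = 780) and is also the smallest round B
at which that BH floor argument holds there, while the 100-node analysis
profile (m = 4,950, k ≈ 5) needs B ≈ 20,000.

**Strengths and networks.** A node's positive (negative) strength is the
sum of suprathreshold positive t values (magnitudes of negative t) over its
masked edges — so summed nodal strengths equal exactly twice the summed
masked edge statistics (handshake identity, used as an invariant test).
Network means get t-based 95 % CIs; hormone × network (3 × 9) and sex ×
network (2 × 9) fixed-effects ANOVAs with interaction use nodes as
observations (residual df 3·415 − 27 = 1,218 and 2·415 − 18 = 812 at full
scale) with Tukey HSD on both margins.

**Graph topology.** On FDR-thresholded matrices: weighted global efficiency
(mean inverse shortest-path length with edge length 1/coherence) and mean
participation coefficient over the nine networks, compared AM vs PM by
Welch's t test with Cohen's d. Under block-diagonal synthetic truth,
between-network edges rarely survive per-session FDR, so participation can
be identically zero; such comparisons are flagged degenerate rather than
inventing a t statistic.

## Validation with known ground truth

`diurnalconn.validation` (shared by the test suite and
`scripts/acceptance.py`):

- **Null calibration** — a 46-node, 40-session study with no coupled edges;
  the 1,035 edgewise permutation p-values must pass a KS test against
  uniformity.
- **Recovery** — 20 replicate 40-node, 40-session studies, each with 10
  disjoint coupled edges at |β| = 0.15; mean sensitivity of BH-FDR
  detections ≥ 0.80 with mean empirical false-discovery proportion ≤ 0.10.
- **Exactness** — at n = 5 sessions the engine's exhaustive p-values match
  an independent brute-force enumeration to 0.
- **Estimator bias** — Welch MSC of independent noise with L = 8 segments
  averages ≈ 1/L.
- **Handshake identity** — summed nodal strengths equal exactly twice the
  summed masked edge statistics.

## Reproducibility

`derive_seeds(master, n)` spawns independent child seeds (all < 2³¹) for
the hormone, BOLD, motion, and permutation stages, so any stage can be
re-run in isolation and full runs are bit-reproducible from
`(config, seed)`. Every written artifact carries the seed and a 16-hex
SHA-256 hash of the canonical config JSON.
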