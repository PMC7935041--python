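# Methods

## Model

A temporal functional-connectivity experiment is represented as a
multilayer network: `L` daily layers of symmetric, nonnegative,
zero-diagonal `N×N` weight matrices `A_ijl`, with every node coupled to
itself in adjacent layers (and only adjacent layers) with weight `ω`.
Community structure is scored by multislice modularity

    Q = (1/2μ) Σ_{ijlr} [ (A_ijl − γ k_il k_jl / 2m_l) δ_lr + δ_ij ω_jlr ] δ(g_il, g_jr)

with `k_il = Σ_j A_ijl`, `2m_l = Σ_ij A_ijl`, and the normalizer
convention `2μ = Σ_l 2m_l + 2ωN(L−1)` (interlayer coupling counts
toward total weight — this convention is fixed by requiring the
coupling-only network with a persistent single community to score
exactly Q = 1). Sums run over ordered pairs including `i = j`, so
diagonal null-model terms are included; they are partition-independent
and do not affect the argmax. A layer with zero total strength
contributes a zero null-model term (all its strengths vanish), so
all-zero networks are evaluable; with `ω = 0` every partition of such a
network scores 0 and the optimizer returns singletons.

## Optimizer

Maximization is a Louvain-type greedy on the `NL×NL` supra-modularity
matrix, alternating (a) single-slot local moving — randomized sweep
order per pass, candidate communities scored by grouped row sums, ties
broken toward the lowest label, moves accepted only for `ΔQ > 1e−10` —
with (b) an aggregation phase that moves whole communities as units,
until neither improves Q. Every returned partition is therefore
single-move locally optimal. Runs are deterministic given their seed;
labels are canonicalized by first appearance in (layer, node) order so
identical partitions compare equal elementwise. A numba-compiled sweep
kernel and a pure-NumPy fallback implement identical semantics
(parity-asserted in the test suite). Memory scales as `(NL)²` doubles
for the dense supra matrix — ~60 MB for the 90-node/30-day scenarios
used here, ~1.2 GB at 415 nodes.

The optimizer's quality is validated two ways: closed-form values
(dyad network Q = 1/2; one community at γ = 1 gives Q = 0; pure
coupling gives Q = 1), and exhaustive enumeration — on random instances
with at most 10 node-layer slots, the best of 20 seeded restarts equals
the global maximum over all set partitions (restricted-growth
enumeration with incremental scoring) to 1e−9. Ten slots is the
practical enumeration ceiling (Bell(10) ≈ 1.2·10⁵ partitions).

## Ensembles and consensus

Because the optimizer is stochastic, partitions are estimated `R` times
with consecutive seeds. `R = 150` is the default, matching standard
practice for this analysis; the test suite and acceptance script use
`R = 15–20`, which the calibration experiments showed saturates
recovery on these problem sizes. The consensus is the ensemble medoid:
the member with maximal mean adjusted Rand index (on flattened
node-by-layer labels) to the other members, ties toward the lowest run
index. Medoid consensus always returns an actually-observed partition
and avoids a second clustering stage; iterated consensus reclustering
is deliberately out of scope. A standardized pair-count z-score
("z-Rand") is available as an alternative similarity.

Community significance compares each community's pooled mean intralayer
within-community weight with `n_draws` uniformly random node sets of
matched per-layer sizes; `p = (1 + #{null ≥ obs}) / (1 + n_draws)`
(add-one smoothing, so p is never 0). Null draws are seeded by the
community's size profile, making p-values invariant to relabeling.
Communities that never reach size two report p = 1.

High-flexibility nodes are flagged against a pooled cutoff: node-by-run
flexibilities are pooled, the cutoff is their 95th percentile (strict
exceedance of the across-run mean), and each a priori network's
exceedance count is tested against the overall exceedance rate with a
one-sided binomial test.

## Connectivity front end

Regional series are linearly detrended, reflection-padded to a multiple
of `2^max_level`, decomposed with an undecimated (maximal-overlap)
discrete wavelet transform using the least-asymmetric Daubechies
length-8 filter (`sym4`), and reconstructed from detail levels 3–6,
which at a 0.72 s sampling interval cover ≈0.0109–0.174 Hz. Association
is the mean over in-band FFT bins of Welch magnitude-squared coherence
(Hann, 128-sample segments, 50% overlap); band filtering is applied
before coherence rather than averaging per-level coherences — with the
band limits passed to the estimator, both select the same spectral
support. Per-edge p-values use the analytic `(1−C)^{K−1}` null for `K`
segments. With 50% overlap this `K` is conservative, and averaging over
band bins shrinks the null's spread, so the p-values under-reject on
null data (measured false-positive rate ≈ 0 at α = 0.05); since their
only use is edge screening before Benjamini–Hochberg FDR control, the
conservatism costs edge density, not validity. Edges failing FDR at
`q` are zeroed; surviving weights are untouched.

## Synthetic study conditions

The generator plants the structure every downstream stage is validated
against. Defaults describe one 30-day "cycle" over 60 nodes:

- **Cores.** Four cores sized 20/40/20/20% of N, each mapped to a named
  functional network (visual, default mode, control, somatomotor). The
  default-mode core is largest on purpose: during a split, whichever
  side of the cut is larger keeps the old label under temporal
  coupling, and the scenario this emulates has the split block smaller
  than the core remainder.
- **Weights.** Beta-distributed per edge (support (0,1), the natural
  range of coherence values), parameterized by mean and concentration:
  within-core mean 0.45, between-core 0.25, concentration 40 (per-edge
  SD ≈ 0.08). Layers are independent draws, so day-to-day edge
  autocorrelation is zero outside events — real coherence matrices are
  temporally autocorrelated; the edge-autocorrelation statistic is
  validated on separate AR(1) fixtures.
- **Events.** The primary event spans days 22–24 (resolved as ~3 days
  at 0.72·L for other L): the split block (leading 40% of the
  default-mode core, or explicit `split_members`) gains `split_boost`
  = 0.3 on within-block means and loses `split_detach` = 0.2 on its
  links to the rest of its core. The detach term is essential, not
  cosmetic: within-block terms count identically whether or not the
  block is its own community, so only shedding negative cross terms can
  make separation modularity-favorable; it also mirrors what coherence
  does when a sub-block locks onto its own latent signal. A secondary
  event on days 8–10 reuses 90% of the block; it is three days long
  because a one-day deviation cannot repay the adjacent-layer coupling
  cost (gain ≈ 2·P·margin per day vs 4ωn at the boundaries) and the
  emulated phenomenon shows multi-day elevated flexibility at the
  secondary hormone peak. `suppressed=True` removes both events.
- **Hormones.** Baseline plus Gaussian bumps with multiplicative
  log-normal noise (σ = 0.08): estradiol (pg/mL) peaks at the primary
  event center with a smaller bump at the secondary event; LH/FSH
  (IU/L) spike only at the primary peak; progesterone (ng/mL) rises in
  the late luteal days; testosterone is flat. The suppressed variant
  keeps estradiol at comparable levels but moves its peak away from any
  event, flattens LH/FSH, and cuts progesterone by 97%. No endocrine
  pharmacokinetics beyond peak timing is modeled. Phases default to
  follicular days 11–22, ovulatory 23–25, luteal 1–10 and 26–30.
- **Time series.** Optionally, per-day node-by-time series: each
  community in each layer gets an independent band-limited (0.01–0.17
  Hz) latent; node series are latent plus white noise at a given SNR.
  No hemodynamics, scanner noise, or motion is simulated — passing
  end-to-end tests shows the pipeline recovers planted mesoscale
  structure from coherence, not that it is robust to fMRI artifacts.

Calibration of the event effect sizes (the one genuinely free design
area) was run once and frozen: `split_detach` 0.15 detects the 15-node
split in 8/20 seeds, 0.2 in 20/20 with the suppressed arm event-free in
20/20, at fine-scale parameters γ = 1.2, ω = 0.9 and R = 15. Those
fine-scale parameters are likewise frozen: γ = 1.2 sits above the range
where only the four cores appear (the large core subdivides from γ ≈
1.3 on these sizes), and ω = 0.9 lies inside the standard temporal
sweep range.

## Dynamics and endocrine coupling

- **Flexibility** is `#{label changes}/(L−1)` per node; persistence is
  the complementary fraction over all node-transitions, so
  `mean flexibility + persistence = 1` exactly.
- **Sliding windows** are centered by default: the value at day `d`
  averages the `window−1` transitions inside the window centered on
  `d`, so an event's flexibility peak lands on the days it spans. (A
  trailing variant exists; it shifts the bump half a window late, which
  decouples it from covariates aligned to the event itself.)
  Incomplete windows are NaN and dropped pairwise downstream.
- **Events.** A split at day `l` is a ≥ `min_size` set sharing a label
  at `l−1` that carries a common, previously absent label at `l`; a
  merge is a disappearing label whose members land in one pre-existing
  community. Duration counts the consecutive days the moved set remains
  separated from its source residual (majority rule) rather than the
  lifetime of the label, because after reunification the optimizer may
  let either side's label survive. The default `min_size` = 10 reflects
  that only large coordinated reorganizations are of interest; smaller
  moves show up in flexibility but are not events.
- **Edge-change attribution** ranks upper-triangle weight changes into
  a day by signed increase (ties toward larger baseline weight), keeps
  the top fraction (default 5%), and tabulates unordered network-pair
  and subnetwork-pair counts; an all-zero-change day is flagged
  degenerate rather than erroring.
- **Phase comparison** computes per-node flexibility within each cycle
  phase using only that phase's transitions (a transition into day `d`
  belongs to the phase of day `d`, so boundary changes are counted
  once) and compares phases across nodes with two-sided Wilcoxon
  rank-sum tests (exact for small tie-free samples, tie-corrected
  normal approximation otherwise).
- **Hormone coupling** takes Spearman rank correlations between each
  network's windowed flexibility series and each hormone series,
  Bonferroni-corrected over the full network×hormone family (the
  conservative default; the family can be overridden), and reports
  which pairs exceed ρ = 0.6 and survive correction. P-values default
  to a seeded permutation null (2000 permutations, add-one smoothing):
  the usual asymptotic t approximation is anti-conservative exactly in
  the far tail where Bonferroni thresholds land (measured family-wise
  error 0.069 instead of ≤ 0.05 on null data), while permutation
  p-values are valid under exchangeability by construction. The t
  approximation remains available via ``method="asymptotic"``.
- **Cross-covariance** is mean-removed with 1/n normalization, so lag
  0 equals the (biased) sample covariance.

## Numerical and interface choices

Node identifiers, not positions, key all on-disk formats; layers are
keyed by 1-based study day. Edge lists are long-format TSV (`i < j`),
written with 17-significant-digit floats and read back with round-trip
float parsing, so write→read is bit-exact. Gaps in the day sequence are
an error unless explicitly allowed (layers are then relabeled
contiguously, original days retained). Weights must be nonnegative;
matrices are symmetrized (max of triangles) with diagonals zeroed.
Every CLI stage writes a provenance JSON (full configuration, SHA-256
config hash, seed, package version) sufficient to regenerate its
stochastic outputs bit-identically, and removes partial outputs on
failure.

## Known limitations

- Negative-weight modularity variants, non-adjacent or all-to-all
  interlayer coupling, and GPU execution are out of scope; γ is a
  single scalar across layers.
- The dense supra matrix bounds practical size to a few hundred nodes
  at 30 layers on an 8 GB machine.
- The medoid consensus cannot produce a partition absent from the
  ensemble; with very small R on ambiguous data, the consensus inherits
  that run's idiosyncrasies (observed as occasional ±1-day event-onset
  shifts).
- Which side of a bipartition receives the new community label is an
  optimizer choice; analyses that need the identity of the moved set
  should inspect both the split's `node_set` and its complement.
- The generator's layers are conditionally independent given the
  planted structure; statistics that depend on temporal smoothness of
  edge weights are exercised on dedicated fixtures instead.
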