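# dyncomm

Dynamic community detection for temporal brain networks, with tools to
relate network reorganization to endocrine time series.

Dense-sampling neuroimaging studies scan the same person every day for
weeks, yielding one functional-connectivity matrix per session. The
question this package addresses: which groups of brain regions form
stable functional communities across days, when do they transiently
reorganize, and do those reorganizations track physiological covariates
such as cycling sex hormones?

## The method

Daily ROI time series are band-limited with a maximal overlap discrete
wavelet transform (details 3–6, ≈0.01–0.17 Hz at TR = 0.72 s), turned
into weighted association matrices by band-averaged magnitude-squared
coherence, FDR-thresholded (Benjamini–Hochberg, q < 0.05), and stacked
into an N×N×L multilayer network with each node coupled to itself in
adjacent layers. Communities maximize multislice modularity

    Q = (1/2μ) Σ_{ijlr} [ (A_ijl − γ k_il k_jl / 2m_l) δ_lr + δ_ij ω_jlr ] δ(g_il, g_jr)

where γ is the structural resolution, ω the temporal coupling between
adjacent layers, k_il node strengths, 2m_l layer totals, and
2μ = Σ 2m_l + 2ωN(L−1). Maximization uses a seeded Louvain-type
optimizer (randomized sweeps, aggregation phases, deterministic per
seed); repeated runs form an ensemble whose medoid (highest mean
adjusted Rand index to the others) is the consensus partition.
Downstream analyses quantify node flexibility (fraction of adjacent-day
label changes), persistence, community composition against an a priori
network atlas, split/merge reorganization events, and Spearman
correlations between sliding-window network flexibility and daily
hormone panels (estradiol, progesterone, testosterone, LH, FSH) with
Bonferroni control.

A synthetic-data module generates the full study design with known
ground truth: 30 daily layers, four planted community cores with
Beta-distributed coherence-like weights, a transient 3-day split of a
prefrontal-like sub-block of the default-mode core around the ovulatory
estradiol/LH/FSH peak, a smaller earlier event at the secondary
estradiol peak, and a "suppressed" variant (hormonal-regimen analogue)
with no events.

## Worked example

```python
import dyncomm as dc
from dyncomm.consensus import consensus_partition

cfg = dc.ScenarioConfig(seed=11)                      # 60 nodes, 30 days
net, truth, meta = dc.generate_multilayer(cfg)

# standard resolution: the four stable cores
ens = dc.run_ensemble(net, dc.ModularityParams(1.0, 1.0), n_runs=20, base_seed=0)
cons = consensus_partition(ens).partition
print(cons.n_communities(), round(dc.persistence(cons), 3))

# fine resolution: the transient split and its hormonal coupling
fine = consensus_partition(
    dc.run_ensemble(net, dc.ModularityParams(1.2, 0.9), n_runs=15, base_seed=0)
).partition
for e in dc.detect_events(fine, min_size=10):
    print(e.kind, "day", e.day, "size", e.size, "duration", e.duration)

wf = dc.sliding_window_flexibility(fine, meta, net.node_ids, window=5)
corr = dc.hormone_flexibility_correlation(wf, dc.generate_hormones(cfg))
best = corr.dropna(subset=["rho"]).sort_values("rho").iloc[-1]
print(best["network"], best["hormone"], round(best["rho"], 3), bool(best["passes"]))
```

Output:

```
4 1.0
split day 8 size 15 duration 3
split day 22 size 14 duration 3
merge day 25 size 14 duration 1
default_mode estradiol 0.768 True
```

At standard resolution the four planted cores are recovered and fully
persistent. At elevated γ both planted bipartitions of the default-mode
core are detected with their exact 3-day windows (days 8–10 and 22–24).
Which side of a split carries the new community label is the
optimizer's choice — here the core remainder (14–15 nodes) took the new
label while the boosted sub-block kept the core's — but the detected
separation is the same either way. The default-mode network's windowed
flexibility correlates most strongly, and Bonferroni-significantly,
with estradiol, whose peaks coincide with the two events.

The same workflow is available from the shell:

```bash
dyncomm simulate --seed 11 --out sim/
dyncomm communities --edges sim/edges.tsv --gamma 1.2 --omega 0.9 \
        --runs 15 --seed 0 --out work/
dyncomm events --partition work/consensus.tsv --out work/
dyncomm hormones --partition work/consensus.tsv --metadata sim/metadata.tsv \
        --hormones sim/hormones.csv --out work/
```

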