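# brainsongs

Whole-brain dynamic mean-field modelling and spacetime-motif repertoire
analysis across timescales.

fMRI sees the brain once every 1–3 seconds, but the interactions that
route information between brain regions play out in milliseconds. This
package implements a two-part framework that bridges the gap:

1. **Regenerate millisecond activity from slow recordings.** A dynamic
   mean-field (reduced Wong–Wang) model — coupled excitatory/inhibitory
   populations per region, wired by a structural connectome C_ij and
   scaled by a single global coupling G — is fitted to empirical BOLD
   through a Balloon–Windkessel hemodynamic forward model. The working
   point is the G minimising the quadratic error between empirical and
   simulated Kuramoto order parameters
   R(t) = |Σ_k e^{iφ_k(t)}|/n of the band-passed (0.01–0.1 Hz) signals,
   with Feedback Inhibition Control clamping every region's excitatory
   rate near 3 Hz. At that working point the model emits neuronal rate
   time series at 1 ms resolution.

2. **Extract the dynamical repertoire at any timescale.** The ms-scale
   signals are averaged in bins of width Δ, binarised into events
   (upward crossings of a z-score threshold — a Poincaré section),
   z-scored, and decomposed: the number of significant co-activation
   patterns K is the count of eigenvalues of the event covariance above
   the Marchenko–Pastur bound λ_max = (1+√(N/N_B))², and the patterns
   ("spacetime motifs") are extracted by FastICA on the significant
   subspace. Motif probabilities give the repertoire's entropy
   H = −Σ_c p(c) log p(c); per-region cohesiveness
   Coh(i) = Σ_c w_ic p(c) Σ_j w_jc and its spread (hierarchy), plus a
   motif transition-probability matrix, complete the summary. Sweeping
   Δ locates the timescale that maximises the repertoire.

It is aimed at computational neuroscientists who want to run
timescale analyses on their own connectomes and recordings, or to probe
the method itself on fully synthetic ground truth (planted assemblies
with known membership, activation probability and duration — all
generators ship with the package).

## Worked example

Generate a raster of 30 regions with five planted assemblies of
characteristic duration 200 ms, then sweep binning timescales:

```bash
brainsongs synth raster --n-regions 30 --duration-s 120 \
    --n-assemblies 5 --assembly-ms 200 --seed 7 --out data
brainsongs sweep --input data/raster.tsv \
    --bins 25,50,100,200,400,800,1600 --theta 1.0 --seed 7 --out sweep
```

which prints

```
entropy optimum at 200 ms, hierarchy optimum at 1600 ms -> sweep/
```

and writes `sweep/curves.tsv`:

```
bin_ms  K  entropy  hierarchy  mean_fc
25.0    2  0.693    0.126      0.223
50.0    3  1.087    0.127      0.288
100.0   5  1.586    0.094      0.350
200.0   6  1.773    0.078      0.415
400.0   4  1.298    0.160      0.504
800.0   5  1.503    0.131      0.625
1600.0  1  0.000    0.285      0.742
```

Reading it: at 200 ms bins all five planted assemblies plus the shared
global mode are significant (K = 6) and the motif probabilities are
nearly even, so the entropy peaks (1.773 ≈ ln 6 = 1.792) exactly at the
planted timescale; at finer bins member jitter destroys co-binning and
at coarser bins activations merge, so K and entropy fall away on both
sides. The mean binned-signal FC rises monotonically with bin size, as
averaging strengthens shared slow structure. (The hierarchy column
tracks probability concentration rather than repertoire richness on
planted data — see `docs/methods.md` for why its optimum sits at coarse
bins here.) `brainsongs motifs --input data/raster.tsv --bin-ms 200`
reports the same decomposition at one timescale
(`K = 6 significant motifs`, λ_max = 1.497, leading eigenvalue 3.16).

The model side is one call each:

```python
import brainsongs as bs

sc = bs.make_connectome(20, family="community", seed=42)
params = bs.DmfParameters()                      # printed constants
fic = bs.fic_tune(sc, params, G=1.0, seed=0)     # balance inhibition
traj = bs.simulate_dmf(sc, params.with_(G=1.0), fic,
                       duration=120_000, dt=0.1, seed=0)
bold = bs.bold_from_rates(traj.rates_E, bs.HemodynamicParameters(),
                          out_interval=2.0)      # TR = 2 s
fit = bs.sweep_G(sc, params, bold, [0.2, 0.6, 1.0, 1.4, 1.8], seed=1)
```

`fit.G_opt` recovers the generating coupling within one grid step, and
`bs.timescale_sweep(traj.rates_E, ...)` runs part 2 on the simulated
millisecond rates. The motif side also composes with scikit-learn:
`bs.MotifExtractor(bin_ms=200).fit(X)` is a standard transformer with
`weights_`, `probabilities_` and `transform`.

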