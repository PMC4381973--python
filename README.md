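# tfmap

Quantitative analysis of clustered transcription-factor binding sites in the
nucleus, from single-molecule localization data down to genomic footprints —
with synthetic-data generators for every input, so each estimator can be
validated against known ground truth.

Stably bound transcription-factor molecules imaged one at a time trace out a
3D map of binding sites.  This package quantifies how those sites are
organised and what that organisation does to function:

- **Localization** — 3D Gaussian PSF fitting of voxel stacks,
  `I(x,y,z) = A₀ exp(−Δx²/2σ²ₓᵧ) exp(−Δy²/2σ²ₓᵧ) exp(−Δz²/2σ²_z) + B`,
  the photon-limited precision estimator
  `Δ² = (σ² + a²/12)/N · (16/9 + 4τ)`, and block-centroid drift correction.
- **Tracking** — greedy nearest-neighbour linking under a diffusion-limited
  gate `r_max = √(2·d·D_max·dt)` and extraction of *stable sites*: tracks
  whose every step and end-to-end displacement stay below 50 nm for at least
  a dwell cutoff.
- **Cluster statistics** — the random-catalog pair-correlation estimator
  `g(r) = [N_R(N_R−1)/N(N−1)] · DD(r)/RR(r)` (g = 1 for complete spatial
  randomness) and a fluctuation-model fit
  `g(r) = (A·e^{−r/ε} + 1) ⊗ g_PSF(r)` separating true clustering
  (amplitude A, range ε) from localization blur.
- **Field maps** — kernel-density intensity maps, nucleus masks, and the
  masked FFT cross-correlation
  `c(r⃗) = Re{FFT⁻¹(FFT(I₁)·conj FFT(I₂))} / (ρ₁ρ₂N(r⃗))` with
  `N(r⃗) = FFT⁻¹(|FFT(mask)|²)`, angularly averaged; plus pixel-wise Pearson
  statistics and relative fluorescence intensity (RFI).
- **Diffusion** — mask-partitioned tracks, MSD fits (`⟨r²⟩ = 2dDt`), and
  Gaussian mixtures on log₁₀D resolving bound/slow/fast populations.
- **Target-search simulation** — Brownian dynamics in a reflecting spherical
  nucleus with absorbing targets; first-passage times τ₃D, the Fold of Delay
  (mean τ₃D clustered / uniform), exponential decompositions, and the
  Smoluchowski reference `τ₃D = 1/(4πRDρ)`.
- **ChIP-exo** — 5′-end reduction of stranded reads, per-strand peak calling,
  pairing of forward/reverse peaks within 20 bp into bound regions,
  chromosome-bin densities, and distance-to-TSS CDFs.

## Worked example

`examples/target_search.py` simulates the search of a transcription factor
(D = 10 µm²/s) for 700 non-overlapping 40 nm targets in a 2 µm nucleus and
asks how target clustering changes the first-passage time:

```
uniform targets: mean tau3D = 12.3 ms (Smoluchowski estimate 9.5 ms)
clustered (sigma = 800 nm): Fold of Delay = 1.5 [1.3, 1.7]
clustered (sigma = 400 nm): Fold of Delay = 2.9 [2.4, 3.5]
clustered (sigma = 200 nm): Fold of Delay = 7.2 [6.1, 8.3]
tau3D decomposition (3 tight clusters): one-component t = 277.8 ms;
two-component t1 = 21.52 ms, t2 = 347.1 ms, fast fraction = 0.21
likelihood ratio = 111
```

With uniform targets the mean first-passage time sits near the
diffusion-limited Smoluchowski estimate and a single exponential describes
its distribution.  Packing the same 700 targets into Gaussian clusters slows
the global search — 7-fold at σ = 200 nm — and splits τ₃D into a fast local
component (injection lands near a cluster) and a slow long-range component,
so a two-exponential model is strongly preferred.

The other scripts in `examples/` follow the same pattern, one per capability:
pair correlation and the fluctuation fit, PSF fitting precision, stable-site
extraction, masked map cross-correlation, regional diffusion mixtures, and
the ChIP-exo pairing pipeline.

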