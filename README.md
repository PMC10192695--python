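# ictalnet

Whole-brain characterization of epileptic scalp EEG, combining a
time–frequency view and a spatial (network) view of the same 10 s,
23-channel, 256 Hz segments:

1. **Time–frequency arm.** Each channel is decomposed by empirical mode
   decomposition (EMD) into intrinsic mode functions; the Hilbert transform
   of each IMF gives the analytic signal *z(t) = a(t) e^{jθ(t)}*, and the
   squared envelope accumulated at instantaneous frequency
   *ω(t) = dθ/dt* forms the Hilbert spectrum *H(ω, t)* (0–40 Hz).  Its time
   integral, the Hilbert marginal spectrum, yields the energy fractions in
   the conventional δ (0.5–3 Hz), θ (4–7), α (8–13) and β (14–30) bands.
   Per-segment stacks of 23 Hilbert-spectrum images are classified
   ictal/interictal by a small convolutional network
   (conv 32·3×3 → pool 2×2 → conv 64·3×3 → pool 2×2 → dropout → dense →
   softmax, Adam optimizer, 80/20 split).
2. **Spatial arm.** Every channel is reduced to ordinal symbols
   (permutation patterns of length *m* = 3) and the symbolic transfer
   entropy STE(J→I) = Σ p(s_I^{n+1}, s_I^n, s_J^n)
   log[p(s_I^{n+1}|s_I^n, s_J^n)/p(s_I^{n+1}|s_I^n)] is estimated for every
   ordered channel pair, giving a 23×23 directed coupling matrix.  Edges
   with STE ≥ 0.02 bits form a weighted directed brain network, summarized
   by mean shortest path, clustering coefficient, global efficiency and
   synchronizability (Laplacian eigenratio λ₂/λ_max).  The same matrices
   drive a Kuramoto model,
   dθᵢ/dt = ωᵢ + (K/N) Σⱼ G_ij sin(θⱼ − θᵢ), with N = 23, K = 3.5 and
   intrinsic frequencies evenly spread over [0, 1], to compare how quickly
   seizure and non-seizure networks reach phase synchrony (order parameter
   r(t) ≥ 0.9).

Real recordings enter as EDF files; a synthetic-data module generates
23-channel segments with *known* band-energy profiles and *known* directed
coupling (a strongly coupled six-channel focus block during seizures), so
every stage of the pipeline can be validated against ground truth.  The
package is aimed at researchers studying seizure signatures in scalp EEG
and at anyone needing a tested, self-contained reference implementation of
the EMD → Hilbert-spectrum → STE-network → Kuramoto chain.

## Worked example

```python
import numpy as np
from ictalnet import (default_ictal_spec, default_interictal_spec,
                      generate_segment, emd, hilbert_spectrum,
                      marginal_spectrum, band_energy_fractions,
                      ste_matrix, threshold_network, metrics_report)

seg_i, truth = generate_segment(default_ictal_spec(seed=42))
seg_n, _     = generate_segment(default_interictal_spec(seed=42))

for name, seg in [("ictal", seg_i), ("interictal", seg_n)]:
    hs = hilbert_spectrum(emd(seg.data[0]), seg.rate)
    be = band_energy_fractions(marginal_spectrum(hs))
    net = threshold_network(ste_matrix(seg), threshold=0.02)
    rep = metrics_report(net, label=name)
    print(f"{name:11s} delta={be.fractions['delta']:.2f} "
          f"edges={net.n_edges} sync={rep.synchronizability:.3f}")
```

prints

```
ictal       delta=0.14 edges=142 sync=0.313
interictal  delta=0.51 edges=112 sync=0.188
```

Between seizures most energy sits in the δ band (0.51 of the first
channel's Hilbert-spectrum energy here) and the directed network is sparser;
during a seizure the energy shifts to higher bands (δ falls to 0.14), more
channel pairs exceed the 0.02-bit STE threshold (142 vs 112 edges) and the
network's Laplacian eigenratio — its ease of synchronization — rises.

The same analysis runs from the shell:

```bash
ictalnet run-all --n-per-class 10 --seed 0 --out results/run0
ictalnet print-defaults
```

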