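# eegtopo

Global network topology of multichannel EEG: from resting-state time
series to band-specific functional-connectivity graphs and
pre/post-intervention statistics.

`eegtopo` is aimed at researchers analyzing pre/post intervention
resting-state EEG studies (active vs. sham arms) with a 19-channel
10–20 montage. It implements the full chain:

1. **Preprocessing** — 1–55 Hz zero-phase Butterworth bandpass,
   spike/flat transient repair (50/50 blend of flanking windows),
   neighbor-based bad-channel interpolation, common-average
   re-referencing, and ICA-based removal of eye/muscle artifact
   components, with an auditable cleaning report.
2. **Connectivity** — the recording is cut into 10-s epochs; multitaper
   (DPSS/Slepian) cross-spectral densities give the complex coherency

   $$C_{xy}(\omega) = \frac{S_{xy}(\omega)}{\sqrt{S_{xx}(\omega)\,S_{yy}(\omega)}},$$

   whose magnitude is the ordinary coherence in [0, 1]. Edge weights are
   the magnitude of the **imaginary part** of the coherency, which is
   insensitive to zero-lag (volume-conducted) coupling; pairs with a
   cross-spectral phase of 0 (or equivalently 2π) are set to zero.
   Per-frequency values are averaged into five bands (delta 1–4, theta
   4–8, alpha 8–13, beta 13–30, gamma 30–55 Hz), producing one symmetric
   19×19 adjacency matrix (171 unique pairs) per band.
3. **Graph theory** — each weighted matrix is thresholded over a
   sparsity grid (5%–95% in 5% steps, 19 levels, keeping the largest
   edges) and, per binary graph, seven global metrics are computed:
   clustering coefficient Cp, characteristic path length Lp, global and
   local efficiency Eg/Eloc, and the null-normalized indices
   γ = Cp/⟨Cp_null⟩, λ = Lp/⟨Lp_null⟩ and the small-world index
   σ = γ/λ, where the nulls are degree-preserving double-edge-swap
   randomizations.
4. **Statistics** — every metric is normalized within subject and arm to
   its pre-stimulation value, M_nor = (M_post − M_pre)/M_pre, and the
   active and sham arms are compared with paired two-sided t-tests per
   (metric, band, sparsity) cell at p < 0.05 (no multiple-comparison
   correction; raw p values are reported).

Because subject-level EEG from such studies is rarely shareable, the
package ships a first-class **synthetic-data generator**: band-limited
oscillatory sources with controllable phase-lagged coupling, 1/f
background noise, instantaneous volume-conduction mixing, and full
pre/post × active/sham study designs with a configurable band-specific
coupling increase in active post segments. All generation is seeded and
bit-reproducible.

## Worked example

```python
from eegtopo import (Effect, analyze_study, generate_study)
from eegtopo.synth import reduced_design
from eegtopo.pipeline import reduced_analysis_params
from eegtopo.stats import summary_to_markdown

# a desk-scale study: 26 subjects, left active + sham arms, an injected
# alpha-band coupling increase in active post segments
design = reduced_design(n_subjects=26, effect=Effect(band="alpha"),
                        seed=77000, duration=60.0)
result = analyze_study(generate_study(design),
                       reduced_analysis_params(seed=0, n_null=4))
print(summary_to_markdown(result.summary))
```

prints (abridged to the alpha-band rows):

```
| Side | Band | Metric | Direction | Significant sparsity |
|------|------|--------|-----------|----------------------|
| left | alpha | Cp | ↑ | 0.10-0.35, 0.70-0.85 |
| left | alpha | gamma | ↑ | 0.10-0.35, 0.95 |
| left | alpha | sigma | ↑ | 0.10-0.35, 0.95 |
| left | alpha | Eloc | ↑ | 0.10-0.35, 0.70-0.85 |
```

The injected alpha-band coupling raises clustering (Cp), its
null-normalized version (γ), small-worldness (σ) and local efficiency
(Eloc) in the active arm relative to sham over contiguous sparsity
ranges. Bands without an injected effect show only scattered flags at
roughly the chance rate (plus some spectral leakage into theta at this
desk-scale frequency resolution; see `docs/methods.md`).

A command-line interface mirrors the stages
(`eegtopo simulate | preprocess | connectivity | metrics | compare | run`);
recordings interchange as EDF or delimited text with a JSON metadata
sidecar.

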