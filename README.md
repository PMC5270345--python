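# plumavis

Comparative analysis of avian plumage conspicuousness: receptor-noise
visual modelling of plumage contrast against natural backgrounds, a
vegetation principal-component habitat axis, and a Bayesian phylogenetic
mixed model marginalized over a posterior sample of candidate
phylogenies.

The package is aimed at evolutionary biologists asking whether habitat
structure shapes plumage colour — for example, whether females of
open-habitat species are less conspicuous to avian predators than those
of closed-habitat species — in clades of roughly 15–30 species and
subspecies measured with a reflectance spectrometer.

## The model

**Vision.** A tetrachromatic observer with cones (VS, S, M, L) sees a
plumage patch with reflectance R(λ) under illuminant I(λ) through cone
sensitivities S_i(λ) (Govardovskii A1 pigment templates, violet-sensitive
defaults λmax = 405/480/535/565 nm).  Quantum catches

    q_i = ∫ R(λ) S_i(λ) I(λ) dλ / ∫ S_i(λ) I(λ) dλ      (von Kries)

enter the Vorobyev–Osorio receptor-noise model on log catches
f_i = ln q_i, with noise-to-signal ratios ω_i = ν √(η_L/η_i) from the L-cone
Weber fraction ν = 0.05 and relative cone proportions
η = 0.38 : 0.69 : 1.14 : 1 (VS:S:M:L), giving
ω = (0.08, 0.06, 0.046, 0.05).  The chromatic distance ΔS (in
just-noticeable differences, JND) is a rank-3 quadratic form in Δf; its
eigen-factorization embeds every spectrum at xyz coordinates whose
Euclidean metric equals ΔS exactly.  Luminance contrast uses the double
cone: ΔL = |Δf_D| / ω_D.

**Contrast.** Coordinates are averaged replicates → individual →
(taxon, sex, patch); contrast is the distance from each patch mean to
green-foliage and brown-bark background coordinates, and conspicuousness
is their mean.  Patches with UV chroma (share of reflectance below
400 nm) above 0.30 count as structurally coloured; per-taxon percentages
use equal 1/7 body-region weights.

**Comparative model.** Contrast y per taxon × patch is modelled as

    y = Xβ + u_phylo + u_species + e,
    u_phylo ~ N(0, σ²_p C(tree)),  u_species ~ N(0, σ²_s I),  e ~ N(0, σ²_e I)

with fixed effects for the vegetation PC (covariance PCA of three
environmental variables), patch, PC × patch, and latitude.  Phylogenetic
uncertainty is marginalized by drawing a tree from the candidate set at
each outer MCMC step (Gibbs sampler, warm-started; default 1300 outer ×
1000 inner sweeps, first 300 stored states discarded).  Effects are
summarized with shortest 95% HPD intervals; phylogenetic signal is
λ = σ²_p / (σ²_p + σ²_s + σ²_e).

## Worked example

`examples/` holds one short script per capability.  A condensed session:

```python
>>> from plumavis import build_visual_system, quantum_catch, chromatic_distance
>>> from plumavis.spectra import GRID_5NM, ReflectanceSpectrum
>>> from plumavis.synthetic import structural_template, green_background_template
>>> vs = build_visual_system()
>>> vs.omega.round(4)
array([0.0811, 0.0602, 0.0468, 0.05  ])
>>> blue = ReflectanceSpectrum(GRID_5NM, structural_template(GRID_5NM, peak=380))
>>> leaf = ReflectanceSpectrum(GRID_5NM, green_background_template(GRID_5NM))
>>> chromatic_distance(quantum_catch(blue, vs), quantum_catch(leaf, vs))
32.92...
```

32.9 JND means a UV-blue patch is trivially discriminable from foliage
by a violet-sensitive predator (1 JND is the discrimination threshold).
Running `python examples/04_tree_resampled_mixed_model.py` simulates a
24-taxon study with a planted habitat slope of 0.15 JND per PC unit and
prints

```
habitat slope: +0.295 (95% HPD +0.087 to +0.513, excludes zero)
phylogenetic signal lambda: 0.431 (95% HPD 0.003 to 0.832)
```

— the HPD covers the planted value and excludes zero, and λ reports how
much residual variance tracks the phylogeny.

The same pipeline is scriptable from the shell:

```bash
plumavis simulate --seed 1 --out run/sim
plumavis contrast --spectra run/sim/spectra.csv --metadata run/sim/metadata.csv --out run/contrast
plumavis habitat-pca --habitat run/sim/habitat.csv --out run/pca
plumavis fit --responses run/sim/responses.csv --habitat run/sim/habitat.csv \
    --trees run/sim/trees.nwk --grafting run/sim/grafting.csv --seed 2 --out run/fit
plumavis report --run-dir run/fit
```

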