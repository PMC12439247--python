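# nanocolloid

Colloidal-interaction analysis for nanoparticle dispersions: potentials of
mean force from 3D particle centroids, aggregation-state censuses, and
hard-core two-Yukawa pair-potential inference from SAXS structure factors —
plus a seeded Monte Carlo / forward-scattering generator that produces
synthetic versions of both kinds of input from a known potential.

## Who this is for

Soft-matter and biophysics groups studying how additives (amino acids and
other small molecules) stabilize dispersions of nanoscale objects —
ligand-coated gold nanoparticles, proteins — by modulating their attractive
interactions.  The package covers the analysis chain between raw
observables and interaction physics:

* **Centroids → g(r) → W(r)**.  From cryo-electron-tomography particle
  positions (or any 3D centroid list), an edge-corrected radial
  distribution function and the potential of mean force
  `W(r) = −kT ln g(r)`, with well/barrier feature extraction.
* **Centroids → aggregation census**.  Single-linkage contact clusters
  ("touching" particles) and the dual histograms used in dispersion work:
  particle-weighted percentages and entity-weighted mole fractions, with
  the monomer percentage as the headline stability statistic.
* **SAXS → pair interaction potential**.  `I(q) = scale·⟨P(q)⟩·S(q) + bg`
  with a fixed log-normal sphere form factor and S(q) from a numerical
  Ornstein–Zernike solver (Percus–Yevick or HNC closure) for a hard-core
  two-Yukawa fluid:

      βV(x) = +∞ (x<1);  −[K₁e^(−Z₁(x−1)) + K₂e^(−Z₂(x−1))]/x  (x = r/σ ≥ 1)

  Weighted least-squares fitting recovers {K₁, Z₁, K₂, Z₂, φ, scale, bg},
  and fitted potentials decompose exactly into attractive (K>0) and
  repulsive (K<0) components for paired-condition comparisons.
* **Synthetic dispersions**.  A Metropolis Monte Carlo sampler (periodic
  box or vitrified-film slab) and a forward SAXS synthesizer, both driven
  by one seed, stand in for the instrument data so every stage is testable
  against known ground truth.

See `docs/methods.md` for the model, numerical choices, and limitations.

## Worked example

Simulate a "stabilizer" contrast — the same dispersion with full and
reduced hydrophobic attraction at matched number concentration — and
compare PMF features and censuses:

```python
import numpy as np
from nanocolloid import (Box, SimulationConfig, TwoYukawaPotential, YukawaTerm,
                         run_mc, average_rdf, rdf_to_pmf, pmf_features,
                         find_clusters, pooled_census, monomer_fraction)

sigma, conc = 7.0, 5e22            # nm, particles per m^3
n = 200
L = (n / conc * 1e27) ** (1 / 3)   # 158.7 nm box

for label, K_att in (("plain", 3.5), ("stabilized", 1.5)):
    pot = TwoYukawaPotential(sigma, YukawaTerm(K_att, 2.0), YukawaTerm(-2.0, 0.5))
    frames, _ = run_mc(SimulationConfig(
        n_particles=n, box=Box.cube(L), potential=pot,
        n_sweeps_equilibration=400, n_sweeps_production=1000,
        sample_interval=10, max_displacement=3.0, seed=5))
    rdf = average_rdf(frames, sigma / 20, L / 2 * 0.999)
    f = pmf_features(rdf_to_pmf(rdf))
    cens = pooled_census([find_clusters(fr, 1.2 * sigma) for fr in frames])
    print(f"{label}: well {f.well_depth:+.2f} kT @ {f.well_position:.1f} nm, "
          f"barrier {f.barrier_height:+.2f} kT @ {f.barrier_position:.1f} nm, "
          f"monomers {monomer_fraction(cens):.1f}%")
```

Output:

```
plain: well -1.25 kT @ 7.2 nm, barrier +0.31 kT @ 13.8 nm, monomers 86.9%
stabilized: well +0.29 kT @ 7.2 nm, barrier +0.55 kT @ 9.6 nm, monomers 96.5%
```

Cutting the attractive strength raises the aggregation barrier (+0.31 →
+0.55 kT), lifts the contact well above zero, and shifts the census toward
monomers (86.9 → 96.5%) — the stabilization signature this pipeline is
built to quantify.

The same workflow runs end-to-end from a YAML config on the command line:

```bash
nanocolloid replay --config replay.yaml --out results/
nanocolloid simulate mc --config mc.yaml --out frames/
nanocolloid structure rdf --input frames/frame_0000.csv --bin-width 0.35 --r-max 60 --out rdf.csv
nanocolloid structure pmf --input rdf.csv --out pmf.csv
nanocolloid aggregation census --input frames/frame_0000.csv --cutoff 8.4 --out census.csv
nanocolloid saxs fit --data curve.dat --ff ff.yaml --init init.yaml --out fit.json
nanocolloid saxs decompose --fit fit.json --compare other.json --out decomp.csv
```

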