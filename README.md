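# lols — low-energy latent-space conformer search

Flexible organic molecules adopt many energetically accessible
conformers, and finding the low-energy ones with quantum-mechanical
accuracy is a core problem in computational chemistry and drug design.
`lols` searches torsion space with an active-learning loop built from two
machine-learning models:

1. an **energy-weighted variational auto-encoder (VAE)** trained on
   normalized dihedral vectors `x ∈ [-1, 1]^D` and scaled energies `E*`,
   with loss

   ```
   δ_total = δ_rec + λ·δ_kld
   δ_rec   = (1/N) Σᵢ exp(β·E*ᵢ) · meanⱼ |x_ij^in − x_ij^out|
   δ_kld   = (1/N) Σᵢ ½ Σⱼ (μ_ij² + σ_ij² − 1 − ln σ_ij²)
   ```

   A negative energy weight `β` biases the 2-D latent space toward
   low-energy conformations; new candidates are drawn uniformly from the
   encoded data's bounding rectangle expanded by 20% and decoded back to
   torsions, then scored by a pluggable energy backend;

2. a **Gaussian-process energy model** with a standard periodic
   (exp-sine-squared) kernel per torsion, fixed 0.001 eV noise and an
   uninformative mean prior, refitted every `k` iterations on the whole
   data pool. Its local minima (conjugate-gradient descent from every
   training point, duplicates merged under a 15° mean circular-distance
   rule) are banked across all refits, refined by local optimization on
   the true energy, and ranked relative to the global minimum.

Energies are preprocessed as `E* = E − E0` below a threshold `E0` and
`E* = ln(1 + E − E0)` above it, and points with
`E* > mean(E*) + α·std(E*)` are held out of VAE training (they still
inform the energy model).

No quantum-chemistry engine is bundled: backends are pluggable (a Python
callable, a templated external command, or the built-in **synthetic
periodic multi-well landscape** whose minima are enumerable exactly by
brute force — the test and benchmark oracle). A real-space baseline that
replaces the VAE with uniform torsion sampling is included for
sample-efficiency comparisons.

## Worked example

```python
import numpy as np
from lols import RunConfig, make_synthetic_pes, oracle_targets, run_lols

pes = make_synthetic_pes(dim=2, n_wells=4, seed=3)      # test landscape
targets = oracle_targets(pes, window=0.25)              # brute-force oracle

config = RunConfig(initdata=50, max_iterations=4, energy_model_interval=2,
                   batch_size=20, beta=-1.0, layersize=32,
                   vae_epochs=1500, vae_patience=500, seed=0)
result = run_lols(pes, pes.ranges, config, targets=targets)
for c in result.conformers:
    print(np.round(c.angles, 1), f"{c.relative_energy:+.3f} eV")
print({k: result.report[k] for k in
       ("achieved", "n_targets", "global_min_found", "single", "new")})
```

prints

```
[306.  164.8] +0.000 eV
[125.2 345.7] +0.018 eV
[125.2 164.4] +0.092 eV
[306.6 345.3] +0.099 eV
{'achieved': 4, 'n_targets': 4, 'global_min_found': True, 'single': 90, 'new': 0}
```

i.e. after 90 single-point evaluations the search refined four conformers
— all four reference minima of the landscape, including the global
minimum (`+0.000 eV` is the energy relative to it), with no extra ("new")
structures. The loop stopped early because the global minimum and at
least 70% of the targets were found.

The same pipeline runs from the shell:

```bash
lols make-pes --dim 2 --n-wells 4 --seed 3 --out pes.yaml
lols run --config run.yaml --outdir out/       # pool CSVs, conformers, report.json
lols baseline --config run.yaml --outdir base/
lols refine --pes pes.yaml --candidates cands.csv
lols match --results out/conformers.csv --targets targets.csv --pes pes.yaml
lols analyze-latent --pool out/pool_run0.csv --pes pes.yaml --beta -1
```

For real molecules, provide a reference XYZ structure plus a YAML list of
rotatable dihedrals (see `lols.molecule.load_molecule_spec`) and a
backend (`MolecularBackend` around a callable, or `ExternalBackend`
around an engine command); steric-clash structures are detected from
covalent radii and excluded automatically.

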