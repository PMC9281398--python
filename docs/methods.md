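# Methods

`lols` implements a low-energy latent-space conformer search: an
active-learning loop that trains an energy-weighted variational
auto-encoder (VAE) on torsion-angle data, samples candidate conformations
from its latent space, and periodically distills the accumulated data into
a periodic-kernel Gaussian-process (GP) energy model whose local minima
are refined and ranked. This note records the model, its assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Search space and geometry

A molecule is a rigid skeleton plus `D` free dihedral angles; all bond
lengths, bond angles, ring torsions and explicitly fixed dihedrals keep
their reference values. Torsion driving rotates, for a dihedral
`(a, b, c, d)`, the subtree on the `d`-side of bond `b–c`. Because the
rotation axis passes through both `b` and `c`, every other internal
coordinate — including previously set and fixed torsions — is invariant,
so torsions can be applied in any order on an acyclic rotor tree. A bond
inside a ring is rejected as an unsupported topology. The dihedral sign
convention is the atan2 form mapped to `[0, 360)`; only round-trip
consistency matters, and the test suite cross-checks against an external
geometry library (which uses the mirrored convention, so the relation is
`ours = (−theirs) mod 360`).

Steric clashes stand in for failed quantum-chemistry single points, which
have no algorithmic definition: a structure is invalid when any non-bonded
pair is closer than `0.7 ×` the sum of the two covalent radii (Cordero
values). The bond graph is inferred from the reference geometry at
`1.2 ×` the radius sum and can be overridden in the molecule file.

## Preprocessing

Angles are mapped linearly from their declared ranges onto `[-1, 1]`.
Raw energies `E` (eV) are shifted by a per-molecule threshold `E0` and
compressed above it:

    E* = E − E0                 E ≤ E0
    E* = ln(1 + (E − E0))       E > E0

This transform is continuous, strictly increasing, near zero around `E0`,
and never expands raw increments above `E0`, so high-energy structure
cannot dominate the fit while every energy ordering — hence every minimum
location — is preserved. `E0` is a configuration constant; for synthetic
backends it defaults to the minimum energy in the initial data, and raw
energies remain the source of truth when `E0` changes.

Records with `E* > mean(E*) + α·std(E*)` (population standard deviation,
strict inequality, default `α = 2`) are excluded from VAE training but
stay in the pool for the energy model.

## The energy-weighted VAE

Two fully connected ReLU layers of equal width (`layersize`) on each side
of a `d = 2` dimensional Gaussian latent space. The encoder input is the
concatenation of the normalized dihedrals and `E*`; the decoder outputs
dihedrals only. A log-variance head guarantees positive `σ²`. The loss is

    δ_total = δ_rec + λ·δ_kld
    δ_rec   = (1/N) Σ_i exp(β·E*_i) · mean_j |x_ij^in − x_ij^out|
    δ_kld   = (1/N) Σ_i ½ Σ_j (μ_ij² + σ_ij² − 1 − ln σ_ij²)

with `β ≤ 0` down-weighting high-energy samples and `λ = 0.01` by
default. The reconstruction difference is taken on the normalized values
without circular wrap; periodicity is honored in the distance metric and
the GP kernel instead. During training `z = μ + σ·ε`; after training the
latent data are simply `z = μ`.

The networks are small (≤ 128 units) and training sets are at most a few
thousand records, so the VAE is implemented directly in numpy with
hand-written backpropagation and full-batch Adam (learning rate `1e-3`).
The default budget is 100,000 epochs with plateau early stopping
(relative improvement of the running-minimum loss below `1e-5` over 1000
epochs); inside the active loop each retraining re-initializes the
network from a seed derived from `(run seed, iteration)`. The benchmark
configurations in the tests and the acceptance script cap retraining at a
few thousand epochs — on pools of a few hundred records the loss plateau
is reached well within that budget.

## Latent sampling

The encoded training data define a minimal axis-aligned rectangle,
expanded symmetrically about its center by 20% per side (collapsed sides
are widened to an absolute floor of 0.1); candidates are drawn i.i.d.
uniformly from the expanded rectangle. Decoded values may fall slightly
outside `[-1, 1]` and are clipped before denormalization. Invalid decoded
samples are logged and dropped without replacement draws. The
latent-space scale `L` — the RMS distance of the latent points from their
centroid — summarizes the spread of the latent cloud; it is zero at zero
dispersion, homogeneous of degree one under dilation about the centroid,
and for a standard-normal 2-D latent equals `√2 ≈ 1.41`. `L` is the
diagnostic for choosing `λ`: in the production region
`λ ∈ [0.001, 0.03]` it is stable to within a factor of about 1.3.

## GP energy model

All pool records (including α-excluded ones) enter a GP over normalized
dihedrals with the standard periodic (exp-sine-squared) kernel, one
period and one lengthscale per dimension; aperiodic dimensions fall back
to a squared-exponential factor. Observation noise is fixed at 0.001 eV.
The constant mean is profiled out by generalized least squares
(an uninformative mean prior); signal variance and lengthscales are MAP
estimates under weak inverse-gamma priors chosen to keep lengthscales
roughly in the 5–120° band (shape 3, scale 1.2 in normalized units, mode
≈ 54° on a full circle), with two seeded optimizer restarts. By default
the GP fits `E*`; fitting raw `E` is supported and yields the same minima
locations to within a couple of degrees, since the scaling is monotone.

Local minima are extracted by conjugate-gradient descent of the posterior
mean from every training input (subsampled to 5000 starts on very large
pools), with periodic coordinate wrapping instead of box constraints;
endpoints with gradient norm above tolerance are skipped. Duplicates are
merged by single linkage under mean circular dihedral distance < 15°,
keeping the lowest-energy member (ties broken lexicographically).

## The loop, banking and refinement

Each iteration: α-cutoff → retrain VAE → encode pool → expanded-rectangle
batch (50 by default) → decode, validate, score with the backend → append
to the pool. Every `k` iterations (and at the final iteration) the GP is
fitted and its merged minima are banked with their model tag; candidates
from *all* intermediate models are kept because GP refits fluctuate and
minima can disappear between fits. Banked candidates are refined at the
end by local minimization on the true backend energy (analytic gradients
for the synthetic landscape; finite differences or the engine's own
optimizer otherwise), with convergence at gradient norm ≤ `1e-4` eV/°
(the torsional analog of a 0.01 eV/Å Cartesian force criterion) within
200 steps; non-converged candidates are excluded and counted. Survivors
are merged and ranked relative to the global minimum.

In benchmark mode a target is *achieved* when some result is within 15°
of it in every dihedral (max circular difference); results matching no
target but lying below the highest target energy count as *new*. The loop
stops early once the global-minimum target and ≥ 70% of all targets are
achieved. Parallel runs use independent seeds and are merged after
refinement by union + duplicate purge. Initial data are seeded uniform
random draws (resampled until valid); an externally produced pool can be
loaded from the data-pool CSV instead.

The real-space baseline replaces the VAE sampling with uniform draws in
dihedral space and keeps everything else identical, fitting the GP every
`k` iterations (i.e. every `k × batch` samples), so samples-vs-targets
curves are directly comparable.

## Synthetic benchmark landscape

The built-in test oracle is a smooth, exactly periodic multi-well energy
function over `D` torsions, with `u_d = 2π(θ_d − low_d)/span_d`:

    E(θ) = base + Σ_d [ A_d cos(c_d u_d + φ_d) + ε_d cos(u_d + ψ_d) ]
         + cs Σ_{d<e} B_de cos(u_d − u_e + χ_de)

The per-dimension well counts `c_d` multiply to roughly the requested
total; amplitudes `A_d` are drawn in 0.12–0.25 eV (typical torsional
barriers), the symmetry-breaking tilt `ε_d` at 4–8% of `A_d` (so the
global minimum is unique, generically separated by ≥ 5 meV), and every
torsion pair is weakly coupled (`cs = 0.05` eV by default). The base
energy defaults to −20,000 eV so the absolute-energy shift pathway is
exercised the way a real total-energy engine would. Its minima are
enumerated exactly: a full periodic grid scan (24 points per dimension by
default) keeps nodes minimal in their wrap-around neighbourhood, polishes
them by gradient descent and merges duplicates.

What the generator emulates: multi-well periodicity, correlated torsion
pairs, a narrow low-energy window holding a handful of reference minima,
absolute-energy offsets, and (via the molecular backends) steric-clash
invalidity. What it does not: rugged high-frequency landscapes, cis/trans
isomerization barriers, bond-length/angle relaxation coupling, and
quantum-chemistry noise — so passing benchmarks demonstrate the machinery
and its statistics, not chemical accuracy on real peptides.

## Benchmark problem sizes

The standard desk-scale benchmark is the seeded 5-D landscape
(~10 requested wells; the brute-force oracle finds 10 minima, 7 of them
within 0.25 eV of the global minimum): 100 initial samples, 10
iterations of batches of 30, energy model every 5 iterations, `β = −1`,
three merged seeds, VAE retraining capped at 3000 epochs. The
surrogate-equivalence check uses a 2-D landscape with 500 training
points; the β-bias comparison trains paired `β = 0 / −3` models on a
fixed 400-record 5-D pool and compares the mean `E*` of 500 decoded
random-latent draws.

## Known limitations

- Latent dimensions other than 2 are plumbed through but unexercised;
  the island analysis assumes a 2-D latent space.
- Exact GP inference is `O(n³)`: pools beyond ~5000 records get slow and
  only minimization starts (not the fit itself) are thinned.
- Cartesian refinement of real molecules is delegated to the external
  engine; the package optimizes torsions only.
- Acquisition functions or GP modelling *in* latent space are
  deliberately out of scope: the latent landscape is neither smooth nor
  continuous enough to support them, which is why rectangle random
  sampling is used.
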