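"""End-to-end low-energy latent-space (LOLS) conformer search.

The generation loop alternates between (1) retraining the energy-weighted
VAE on the current data pool, (2) drawing a batch of latent-rectangle
samples, decoding them to dihedral vectors and scoring them with the
energy backend, and (3) every ``k`` iterations fitting the periodic-kernel
GP energy model and banking its local minima.  Minima candidates from
*every* intermediate energy model are kept, not only the final one —
GP refits fluctuate and a minimum found early can vanish later.  After the
loop every banked candidate is refined by local minimization on the true
backend energy, non-converged candidates are dropped, duplicates are
merged and the survivors are ranked relative to the global minimum.

A real-space baseline replaces the VAE sampling with uniform random draws
in dihedral space while keeping the rest of the pipeline identical, for
like-for-like sample-efficiency comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize

from .energy_backend import bruteforce_minima
from .latent_sampler import draw_batch, latent_scale, make_rectangle
from .preprocessing import DataPool, denormalize_angles, vae_cutoff
from .surrogate import (
    extract_local_minima,
    fit_energy_model,
    merge_similar,
    predict_energy,
)
from .molecule import circular_diff, dihedral_distance
from .vae import VAEConfig, VAEModel, train_vae

__all__ = [
    "RunConfig",
    "ConformerRecord",
    "RunResult",
    "generate_initial_data",
    "run_lols",
    "run_parallel",
    "run_real_space_baseline",
    "refine_candidates",
    "match_targets",
    "stop_check",
    "map_latent_islands",
    "oracle_targets",
]

logger = logging.getLogger(__name__)

MATCH_THRESHOLD = 15.0  # deg, max circular difference for an achieved target


@dataclass
class RunConfig:
    """All knobs of one search run.

    Defaults follow the production settings for a 5-torsion molecule:
    100 initial samples, batches of 50, energy model every 5 iterations,
    alpha = 2 cutoff, loss ratio 0.01, 20% rectangle expansion, 0.001 eV
    GP noise, refinement capped at 200 steps.
    """

    initdata: int = 100
    max_iterations: int = 40  # M
    energy_model_interval: int = 5  # k
    batch_size: int = 50
    alpha: float = 2.0
    beta: float = 0.0
    lambda_: float = 0.01
    layersize: int = 80
    latent_dim: int = 2
    expansion_rate: float = 0.2
    E0: float | None = None
    noise: float = 0.001
    seed: int = 0
    vae_epochs: int = 100_000
    vae_patience: int = 1000
    refine_max_steps: int = 200
    refine_force_tol: float = 1e-4  # eV/deg, torsional analog of 0.01 eV/A
    fit_scaled: bool = True

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.energy_model_interval < 1:
            raise ValueError("energy_model_interval must be >= 1")


@dataclass
class ConformerRecord:
    """One refined conformer: location, energy, provenance."""

    angles: np.ndarray
    energy: float
    relative_energy: float
    source: str = ""
    converged: bool = True


@dataclass
class RunResult:
    pool: DataPool
    candidates: list  # banked (angles, predicted E*, model tag)
    conformers: list[ConformerRecord]
    report: dict
    curve: list  # per energy-model snapshots
    counters: dict
    latent_snapshots: list = field(default_factory=list)


def _derived_seed(*parts) -> int:
    """Stable child seed from a run seed plus string/int context labels."""
    ints = tuple(
        int.from_bytes(p.encode(), "big") if isinstance(p, str) else int(p)
        for p in parts
    )
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % (2**31))


def generate_initial_data(
    backend, ranges, n: int, seed: int, E0: float | None = None,
    run_id: str = "run0",
) -> DataPool:
    """Uniform random valid conformations as the initial pool (seeded).

    Invalid draws (clashes / backend failures) are resampled until ``n``
    valid records exist.
    """
    rng = np.random.default_rng(seed)
    lows = np.array([r[0] for r in ranges])
    highs = np.array([r[1] for r in ranges])
    angles, energies = [], []
    attempts = 0
    while len(angles) < n:
        a = lows + rng.random(len(ranges)) * (highs - lows)
        e = backend.evaluate(a)
        attempts += 1
        if e is not None:
            angles.append(a)
            energies.append(e)
        if attempts > 100 * n:
            raise RuntimeError("backend rejects nearly every random draw")
    pool = DataPool(ranges, E0=E0)
    pool.add(np.array(angles), np.array(energies), iteration=0, run_id=run_id)
    return pool


def _score_batch(backend, angles: np.ndarray):
    """Evaluate a batch; returns (valid angles, energies, n_invalid)."""
    kept, energies = [], []
    for a in angles:
        e = backend.evaluate(a)
        if e is None:
            continue
        kept.append(a)
        energies.append(e)
    n_invalid = len(angles) - len(kept)
    return np.array(kept), np.array(energies), n_invalid


def _fit_and_bank(pool, config, ranges, tag, seed):
    gp = fit_energy_model(
        pool, noise=config.noise, use_scaled=config.fit_scaled, seed=seed
    )
    minima = merge_similar(extract_local_minima(gp, seed=seed), ranges)
    return gp, [(ang, e, tag) for ang, e in minima]


def run_lols(
    backend,
    ranges,
    config: RunConfig,
    targets=None,
    initial_pool: DataPool | None = None,
    run_id: str = "run0",
) -> RunResult:
    """One seeded LOLS run: generation loop, candidate banking, refinement.

    ``targets`` (optional benchmark mode) is a list of (angles, energy)
    reference conformers; when given, the loop may stop early once the
    global-minimum target and at least 70% of all targets are achieved.
    """
    D = len(ranges)
    seed = config.seed
    pool = initial_pool if initial_pool is not None else generate_initial_data(
        backend, ranges, config.initdata, _derived_seed(seed, "init"),
        E0=config.E0, run_id=run_id,
    )
    if config.E0 is not None:
        pool.set_E0(config.E0)
    banked: list = []
    counters = {"single": len(pool), "invalid": 0, "relax": 0, "converged": 0}
    curve, snapshots = [], []
    stopped_early = False

    for t in range(1, config.max_iterations + 1):
        vae_cutoff(pool, config.alpha)
        Xv, Ev = pool.vae_subset()
        vcfg = VAEConfig(
            input_dim=D,
            layersize=config.layersize,
            latent_dim=config.latent_dim,
            lambda_=config.lambda_,
            beta=config.beta,
            epochs=config.vae_epochs,
            early_stop_patience=config.vae_patience,
            seed=_derived_seed(seed, "vae", t),
        )
        model, _ = train_vae(vcfg, Xv, Ev)
        Z = model.latent_points(Xv, Ev)
        snapshots.append(
            {"iteration": t, "L": latent_scale(Z), "n_train": len(Z)}
        )
        rect = make_rectangle(Z, config.expansion_rate)
        zs = draw_batch(
            rect, config.batch_size,
            np.random.default_rng(_derived_seed(seed, "draw", t)),
        )
        decoded = np.clip(model.decode(zs), -1.0, 1.0)
        angles = denormalize_angles(decoded, ranges)
        kept, energies, n_invalid = _score_batch(backend, angles)
        counters["single"] += len(kept)
        counters["invalid"] += n_invalid
        if n_invalid > 0.5 * config.batch_size:
            raise RuntimeError(
                f"iteration {t}: backend rejected {n_invalid}/"
                f"{config.batch_size} samples — check the molecule spec "
                "or clash scale"
            )
        if len(kept):
            pool.add(kept, energies, iteration=t, run_id=run_id)

        at_interval = (t % config.energy_model_interval == 0)
        if at_interval or t == config.max_iterations:
            _, new_candidates = _fit_and_bank(
                pool, config, ranges, f"{run_id}/model_t{t}",
                _derived_seed(seed, "gp", t),
            )
            banked.extend(new_candidates)
            snap = {"iteration": t, "n_samples": counters["single"]}
            if targets:
                rep = match_targets(
                    [(a, e) for a, e, _ in banked], targets, ranges
                )
                snap.update(
                    achieved=rep["achieved"], n_targets=rep["n_targets"]
                )
                if stop_check(rep):
                    curve.append(snap)
                    stopped_early = True
                    break
            curve.append(snap)
    conformers, refine_stats = refine_candidates(
        banked, backend, ranges,
        max_steps=config.refine_max_steps,
        force_tol=config.refine_force_tol,
        return_stats=True,
    )
    counters["relax"] = refine_stats["relaxed"]
    counters["converged"] = refine_stats["converged"]
    report = _final_report(conformers, targets, ranges, counters)
    report["stopped_early"] = stopped_early
    return RunResult(
        pool=pool,
        candidates=banked,
        conformers=conformers,
        report=report,
        curve=curve,
        counters=counters,
        latent_snapshots=snapshots,
    )


def run_real_space_baseline(
    backend, ranges, config: RunConfig, targets=None, run_id: str = "base0"
) -> RunResult:
    """Uniform real-space sampling through the identical downstream pipeline.

    Candidates are drawn uniformly in dihedral space each iteration (no
    VAE); the GP fit / minima extraction / banking / refinement steps and
    all bookkeeping match :func:`run_lols`, so sample-efficiency curves are
    directly comparable.
    """
    seed = config.seed
    pool = generate_initial_data(
        backend, ranges, config.initdata, _derived_seed(seed, "init"),
        E0=config.E0, run_id=run_id,
    )
    lows = np.array([r[0] for r in ranges])
    highs = np.array([r[1] for r in ranges])
    banked: list = []
    counters = {"single": len(pool), "invalid": 0, "relax": 0, "converged": 0}
    curve = []
    for t in range(1, config.max_iterations + 1):
        rng = np.random.default_rng(_derived_seed(seed, "real", t))
        angles = lows + rng.random((config.batch_size, len(ranges))) * (
            highs - lows
        )
        kept, energies, n_invalid = _score_batch(backend, angles)
        counters["single"] += len(kept)
        counters["invalid"] += n_invalid
        if len(kept):
            pool.add(kept, energies, iteration=t, run_id=run_id)
        if t % config.energy_model_interval == 0 or t == config.max_iterations:
            _, new_candidates = _fit_and_bank(
                pool, config, ranges, f"{run_id}/model_t{t}",
                _derived_seed(seed, "gp", t),
            )
            banked.extend(new_candidates)
            snap = {"iteration": t, "n_samples": counters["single"]}
            if targets:
                rep = match_targets(
                    [(a, e) for a, e, _ in banked], targets, ranges
                )
                snap.update(
                    achieved=rep["achieved"], n_targets=rep["n_targets"]
                )
            curve.append(snap)
    conformers, refine_stats = refine_candidates(
        banked, backend, ranges,
        max_steps=config.refine_max_steps,
        force_tol=config.refine_force_tol,
        return_stats=True,
    )
    counters["relax"] = refine_stats["relaxed"]
    counters["converged"] = refine_stats["converged"]
    report = _final_report(conformers, targets, ranges, counters)
    return RunResult(
        pool=pool,
        candidates=banked,
        conformers=conformers,
        report=report,
        curve=curve,
        counters=counters,
    )


def refine_candidates(
    candidates,
    backend,
    ranges,
    max_steps: int = 200,
    force_tol: float = 1e-4,
    return_stats: bool = False,
):
    """Locally minimize each banked candidate on the true backend energy.

    Convergence requires the gradient-norm analog of the residual force to
    drop below ``force_tol`` (eV/deg) within ``max_steps`` optimizer
    steps; anything else is excluded.  Survivors are merged (15 deg rule)
    and re-referenced to the new global minimum.  Backends without an
    analytic ``gradient`` are differentiated by finite differences.
    """
    lows = np.array([r[0] for r in ranges])
    spans = np.array([r[1] - r[0] for r in ranges])
    periodic = np.array([bool(r[2]) for r in ranges])
    has_grad = hasattr(backend, "gradient")
    refined = []
    for cand in candidates:
        angles = np.asarray(cand[0], dtype=float)
        source = cand[2] if len(cand) > 2 else ""

        def objective(a):
            e = backend.evaluate(a)
            return np.inf if e is None else e

        res = optimize.minimize(
            objective,
            angles,
            jac=(backend.gradient if has_grad else None),
            method="CG",
            options={"gtol": force_tol, "maxiter": max_steps},
        )
        if has_grad:
            gnorm = float(np.linalg.norm(backend.gradient(res.x)))
        else:
            gnorm = float(np.linalg.norm(res.jac)) if res.jac is not None else np.inf
        converged = gnorm <= force_tol and res.nit <= max_steps
        if not converged:
            logger.debug("candidate %s not converged (|g|=%.2e)", source, gnorm)
            continue
        wrapped = res.x.copy()
        wrapped[periodic] = lows[periodic] + np.mod(
            res.x[periodic] - lows[periodic], spans[periodic]
        )
        refined.append((wrapped, float(res.fun), source))
    merged = merge_similar([(a, e) for a, e, _ in refined], ranges)
    source_of = {tuple(np.round(a, 6)): s for a, e, s in refined}
    records = []
    if merged:
        e_min = merged[0][1]
        records = [
            ConformerRecord(
                angles=a,
                energy=e,
                relative_energy=e - e_min,
                source=source_of.get(tuple(np.round(a, 6)), ""),
                converged=True,
            )
            for a, e in merged
        ]
    if return_stats:
        return records, {"relaxed": len(candidates), "converged": len(refined)}
    return records


def match_targets(results, targets, ranges) -> dict:
    """Compare found conformers against reference targets (15 deg rule).

    A target is *achieved* when some result differs from it by less than
    15 deg in every dihedral (max circular difference).  Results matching
    no target but lying below the highest target energy are *new*.
    """
    res_list = [
        (np.asarray(r.angles if isinstance(r, ConformerRecord) else r[0],
                    dtype=float),
         float(r.energy if isinstance(r, ConformerRecord) else r[1]))
        for r in results
    ]
    tgt_list = [
        (np.asarray(a, dtype=float), float(e)) for a, e in targets
    ]
    achieved_mask = []
    for t_ang, _ in tgt_list:
        hit = any(
            circular_diff(r_ang, t_ang, ranges).max() < MATCH_THRESHOLD
            for r_ang, _ in res_list
        )
        achieved_mask.append(bool(hit))
    e_cap = max((e for _, e in tgt_list), default=np.inf)
    new = 0
    for r_ang, r_e in res_list:
        matches_some = any(
            circular_diff(r_ang, t_ang, ranges).max() < MATCH_THRESHOLD
            for t_ang, _ in tgt_list
        )
        if not matches_some and r_e < e_cap:
            new += 1
    n_targets = len(tgt_list)
    global_min_found = bool(achieved_mask[int(np.argmin([e for _, e in tgt_list]))]) if tgt_list else False
    return {
        "n_targets": n_targets,
        "achieved": int(sum(achieved_mask)),
        "achieved_mask": achieved_mask,
        "achieved_fraction": (
            sum(achieved_mask) / n_targets if n_targets else float("nan")
        ),
        "global_min_found": global_min_found,
        "new": new,
    }


def stop_check(report: dict) -> bool:
    """Stop once the global-minimum target and >= 70% of targets are found."""
    if not report.get("n_targets"):
        return False
    return report["global_min_found"] and report["achieved_fraction"] >= 0.7


def _final_report(conformers, targets, ranges, counters) -> dict:
    report = {
        "n_conformers": len(conformers),
        **{k: int(v) for k, v in counters.items()},
    }
    if targets:
        report.update(match_targets(conformers, targets, ranges))
    return report


def run_parallel(
    backend, ranges, config: RunConfig, seeds, targets=None,
    baseline: bool = False,
) -> tuple[list[ConformerRecord], dict, list[RunResult]]:
    """Independent seeded runs merged into one conformer list.

    Each run uses its own seed; the refined conformers are pooled, merged
    under the 15 deg rule and re-referenced to the overall global minimum
    (merging happens after refinement).  Returns (merged records, merged
    report, per-run results).
    """
    runner = run_real_space_baseline if baseline else run_lols
    results = []
    for i, s in enumerate(seeds):
        cfg = RunConfig(**{**asdict(config), "seed": int(s)})
        results.append(
            runner(backend, ranges, cfg, targets=targets, run_id=f"run{i}")
        )
    pooled = [
        (c.angles, c.energy, c.source)
        for r in results
        for c in r.conformers
    ]
    merged = merge_similar([(a, e) for a, e, _ in pooled], ranges)
    records = []
    if merged:
        e_min = merged[0][1]
        records = [
            ConformerRecord(a, e, e - e_min) for a, e in merged
        ]
    counters = {
        k: int(sum(r.counters[k] for r in results))
        for k in ("single", "invalid", "relax", "converged")
    }
    report = _final_report(records, targets, ranges, counters)
    return records, report, results


def oracle_targets(pes, window: float = 0.25, grid_points_per_dim: int = 24):
    """Benchmark targets: brute-force minima within ``window`` eV of the
    global minimum of a synthetic PES."""
    minima = bruteforce_minima(pes, grid_points_per_dim)
    e0 = minima[0][1]
    return [(a, e) for a, e in minima if e - e0 <= window]


def map_latent_islands(
    vae_model: VAEModel,
    rect,
    ranges,
    targets,
    grid_n: int = 400,
    energy_window: float = 0.5,
    assign_threshold: float = 30.0,
) -> dict:
    """Decode a latent grid and map it onto reference conformers.

    The latent rectangle is discretized on a ``grid_n`` x ``grid_n`` grid;
    every node is decoded to dihedrals and assigned to its nearest target
    (mean circular dihedral difference < 30 deg) among the targets within
    ``energy_window`` eV of the lowest target.  Reports the per-target
    island area fractions and their total.
    """
    tgt = [(np.asarray(a, float), float(e)) for a, e in targets]
    if tgt:
        e0 = min(e for _, e in tgt)
        tgt = [(a, e) for a, e in tgt if e - e0 <= energy_window]
    g1 = np.linspace(rect.lower[0], rect.upper[0], grid_n)
    g2 = np.linspace(rect.lower[1], rect.upper[1], grid_n)
    zz = np.stack(np.meshgrid(g1, g2, indexing="ij"), -1).reshape(-1, 2)
    decoded = np.clip(vae_model.decode(zz), -1.0, 1.0)
    angles = denormalize_angles(decoded, ranges)
    counts = np.zeros(len(tgt), dtype=int)
    if tgt:
        # mean circular distance of every grid point to every target
        dists = np.stack(
            [
                circular_diff(angles, np.broadcast_to(a, angles.shape), ranges)
                .mean(axis=1)
                for a, _ in tgt
            ],
            axis=1,
        )  # (grid^2, n_targets)
        nearest = dists.argmin(axis=1)
        assigned = dists[np.arange(len(nearest)), nearest] < assign_threshold
        for k in range(len(tgt)):
            counts[k] = int(np.sum(assigned & (nearest == k)))
    total = grid_n * grid_n
    fractions = counts / total
    return {
        "per_target_fraction": fractions.tolist(),
        "total_fraction": float(fractions.sum()),
        "grid_n": grid_n,
        "n_targets": len(tgt),
    }
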