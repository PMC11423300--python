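"""Self-contained synthetic fixtures: everything the test-bench needs
without downloads.

``desk_config`` scales the engine down to interactive sizes (order 10^2
particles, shortened blocks, block-averaged checkpoint energies -- see
docs/methods.md for why instantaneous checkpoints are too noisy at small
N).  ``make_fixtures`` writes a small corpus, analytic-limit curves and a
"pseudo-experimental" measurement: a fresh MC curve at a held-out
parameter pair with 2% multiplicative noise and a sigma column, standing
in for a real dilute-gold-nanoparticle measurement.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .dataset import DEFAULT_BASE_PARAMS, build_dataset, generate_curve, save_dataset
from .mc import SimulationConfig
from .potentials import InteractionParams
from .io import write_saxs_curve

__all__ = ["desk_config", "hard_sphere_config", "make_fixtures",
           "PSEUDO_EXPERIMENT_TRUTH"]

#: Held-out ground truth of the pseudo-experimental fixture.
PSEUDO_EXPERIMENT_TRUTH = (32.0, 5.5)


def desk_config(n_particles: int = 128, seed: int = 0,
                **overrides) -> SimulationConfig:
    """Desk-scale engine settings (see docs/methods.md for the numbers)."""
    defaults = dict(
        n_particles=n_particles,
        seed=seed,
        equil_block=20_000,
        equil_rel_tol=0.05,
        block_average=True,
        equil_energy_floor=0.05 * n_particles,
        post_equil_steps=75_000,
        n_snapshots=500,
        max_equil_blocks=40,
        rdf_bins=256,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def hard_sphere_config(phi: float = 0.05, radius: float = 1.985,
                       seed: int = 0, **overrides) -> SimulationConfig:
    """Engine settings for the dilute hard-sphere reference fluid.

    At phi = 0.05 a near-teleport trial move is still accepted ~2/3 of the
    time, which decorrelates snapshots in about one sweep and removes the
    slow long-wavelength density modes that otherwise dominate the S(0)
    error budget; g(r) is truncated at ~2.5 diameters, beyond which the
    dilute-fluid correlations have decayed (docs/methods.md).
    """
    density = phi / (4.0 / 3.0 * np.pi * radius ** 3)
    defaults = dict(
        n_particles=256,
        number_density=density,
        max_displacement=20.0,
        n_snapshots=2000,
        post_equil_steps=500_000,
        rdf_r_max=10.0,
        rdf_bins=200,
        seed=seed,
    )
    defaults.update(overrides)
    return desk_config(**defaults)


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Generate the fixture bundle; returns {name: path}.

    * ``corpus.h5``     -- ~60-curve MC dataset (box corners, center and
      random interior pairs) at 128 particles;
    * ``pseudo_experiment.dat`` -- noisy MC curve at the held-out pair
      with its truth recorded in the header;
    * ``ideal_gas.dat`` / ``hard_sphere.dat`` -- analytic-limit curves.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    cfg = desk_config(seed=seed)
    corpus = build_dataset(60, cfg, seed=seed)
    # overwrite the first five sampled pairs with the box corners + center
    anchors = np.array([[10.0, 3.0], [10.0, 7.0], [70.0, 3.0],
                        [70.0, 7.0], [40.0, 5.0]])
    from dataclasses import replace as _rep
    for i, (z, k) in enumerate(anchors):
        p = InteractionParams(**{**DEFAULT_BASE_PARAMS,
                                 "z_eff": z, "kappa_inv": k})
        c = generate_curve(p, _rep(cfg, seed=int(seed + 1000 + i)))
        corpus.curves[i] = c.intensity
        corpus.labels[i] = (z, k)
    paths["corpus"] = out / "corpus.h5"
    save_dataset(corpus, paths["corpus"])

    z_true, k_true = PSEUDO_EXPERIMENT_TRUTH
    pseudo = generate_curve(
        InteractionParams(**{**DEFAULT_BASE_PARAMS, "z_eff": z_true,
                             "kappa_inv": k_true}),
        desk_config(seed=seed + 9001),
        noise_fraction=0.02,
        rng=np.random.default_rng(seed + 7))
    pseudo.metadata["role"] = "pseudo-experimental stand-in (synthetic)"
    paths["pseudo_experiment"] = out / "pseudo_experiment.dat"
    write_saxs_curve(pseudo, paths["pseudo_experiment"])

    # non-interacting system: box-scale trial moves are exact decorrelation,
    # so snapshots spaced ~N steps apart are statistically independent
    ideal = generate_curve(
        InteractionParams(z_eff=0.0, kappa_inv=5.0, hamaker=0.0),
        desk_config(seed=seed + 11, n_snapshots=4000,
                    post_equil_steps=600_000, rdf_r_max=32.0,
                    max_displacement=30.0))
    ideal.metadata["role"] = "ideal-gas analytic limit"
    paths["ideal_gas"] = out / "ideal_gas.dat"
    write_saxs_curve(ideal, paths["ideal_gas"])

    hard_sphere = generate_curve(
        InteractionParams(z_eff=0.0, kappa_inv=5.0, hamaker=0.0),
        hard_sphere_config(seed=seed + 13))
    hard_sphere.metadata["role"] = "dilute hard-sphere limit (phi=0.05)"
    paths["hard_sphere"] = out / "hard_sphere.dat"
    write_saxs_curve(hard_sphere, paths["hard_sphere"])
    return paths
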