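"""Labelled (curve, parameter) corpora for training the networks.

Parameters are drawn uniformly over the study box Z_eff in [10, 70],
kappa^-1 in [3, 7] nm; each curve runs the full engine pipeline
(init -> equilibrate -> snapshots -> RDF -> S -> P -> I) with a per-curve
seed derived from the master seed, so any single curve is reproducible in
isolation.  Corpora are split 8:1:1 into train/validation/test by a
seeded shuffle, and model-input normalization (log10 then per-feature
standardization) uses training-split statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mc import SimulationConfig, simulate_rdf
from .potentials import InteractionParams
from .scattering import SAXSCurve, intensity, make_q_grid, sphere_form_factor, structure_factor

__all__ = [
    "PARAM_BOUNDS",
    "SPLIT_NAMES",
    "TrainingDataset",
    "NormalizationStats",
    "sample_parameters",
    "generate_curve",
    "build_dataset",
    "apply_q_cutoff",
    "normalize_features",
    "save_dataset",
    "load_dataset",
]

#: The sampled parameter box: (Z_eff, kappa_inv/nm).
PARAM_BOUNDS = ((10.0, 70.0), (3.0, 7.0))

#: Fixed physics shared by all generated curves: 3.97 nm gold core with a
#: 1.2 nm impenetrable ligand shell.  The shell keeps the cores outside
#: the singular contact attraction (where the weakly charged corner of
#: the parameter box would otherwise aggregate irreversibly) and reflects
#: the sterically stabilized particles the simulations emulate.
DEFAULT_BASE_PARAMS = dict(z_eff=10.0, kappa_inv=3.0, shell_thickness=1.2)

SPLIT_NAMES = ("train", "val", "test")
#: Fraction of intensities clipped away from zero before taking logs;
#: simulated S(q) can graze zero through counting noise.
_INTENSITY_FLOOR = 1e-12


@dataclass
class NormalizationStats:
    """Per-feature location/scale of log10 intensities (training split)."""

    mean: np.ndarray
    std: np.ndarray

    def forward(self, curves: np.ndarray) -> np.ndarray:
        x = np.log10(np.maximum(curves, _INTENSITY_FLOOR))
        return (x - self.mean) / self.std

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return 10.0 ** (x * self.std + self.mean)


@dataclass
class TrainingDataset:
    """A labelled corpus of simulated SAXS curves.

    ``curves`` holds raw (physical) intensities, one row per sample on the
    shared grid ``q``; ``labels`` the generating (z_eff, kappa_inv) pairs;
    ``split_assignment`` integer codes indexing :data:`SPLIT_NAMES`.
    """

    curves: np.ndarray            # (n_samples, n_q)
    labels: np.ndarray            # (n_samples, 2)
    q: np.ndarray                 # (n_q,)
    split_assignment: np.ndarray  # (n_samples,), int8 codes
    normalization_stats: NormalizationStats | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.curves.shape[0]

    def mask(self, split: str) -> np.ndarray:
        return self.split_assignment == SPLIT_NAMES.index(split)

    def split(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.mask(name)
        return self.curves[m], self.labels[m]

    def curve(self, index: int) -> SAXSCurve:
        return SAXSCurve(self.q, self.curves[index],
                         labels=tuple(self.labels[index]))


def sample_parameters(n: int, seed: int,
                      bounds=PARAM_BOUNDS) -> np.ndarray:
    """n independent uniform (z_eff, kappa_inv) draws over the box."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    (z_lo, z_hi), (k_lo, k_hi) = bounds
    out = np.empty((n, 2))
    out[:, 0] = rng.uniform(z_lo, z_hi, n)
    out[:, 1] = rng.uniform(k_lo, k_hi, n)
    return out


def generate_curve(params: InteractionParams, sim_config: SimulationConfig,
                   q: np.ndarray | None = None,
                   noise_fraction: float = 0.0,
                   rng: np.random.Generator | None = None) -> SAXSCurve:
    """One labelled synthetic SAXS curve from the full MC pipeline.

    ``noise_fraction`` > 0 adds multiplicative Gaussian noise of that
    relative amplitude and populates the sigma column accordingly (off by
    default: training uses raw simulated curves).
    """
    if q is None:
        q = make_q_grid()
    rdf, _ = simulate_rdf(params, sim_config)
    s_of_q = structure_factor(rdf, q)
    # counting noise can push a deeply suppressed S(q) below zero; clip at
    # a tiny positive floor so the curve stays a valid intensity
    s_of_q = np.maximum(s_of_q, 1e-6)
    p_of_q = sphere_form_factor(q, 2.0 * params.radius)
    sigma = None
    i_of_q = p_of_q * s_of_q
    if noise_fraction > 0.0:
        if rng is None:
            rng = np.random.default_rng(sim_config.seed + 1)
        i_of_q = i_of_q * (1.0 + noise_fraction * rng.standard_normal(q.size))
        i_of_q = np.maximum(i_of_q, _INTENSITY_FLOOR)
        sigma = noise_fraction * i_of_q
    return SAXSCurve(q, i_of_q, sigma=sigma,
                     labels=(params.z_eff, params.kappa_inv),
                     metadata={"seed": sim_config.seed,
                               "n_particles": sim_config.n_particles,
                               "number_density": sim_config.number_density,
                               "noise_fraction": noise_fraction})


def _curve_seeds(master_seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence([master_seed, 17]).generate_state(n) % (2 ** 31)


def assign_splits(n: int, seed: int) -> np.ndarray:
    """8:1:1 split codes by seeded shuffle (disjoint, exhaustive)."""
    n_val = int(round(n * 0.1))
    n_test = int(round(n * 0.1))
    codes = np.zeros(n, dtype=np.int8)
    codes[-(n_val + n_test):-n_test or None] = 1
    if n_test:
        codes[-n_test:] = 2
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    rng.shuffle(codes)
    return codes


def build_dataset(n: int, sim_config: SimulationConfig, seed: int,
                  parallel_workers: int = 1,
                  base_params: InteractionParams | None = None,
                  q: np.ndarray | None = None) -> TrainingDataset:
    """Simulate n labelled curves and split them 8:1:1.

    Per-curve seeds derive from ``seed``; ``base_params`` carries the
    fixed physics (radius, Hamaker constant, temperature) shared by all
    curves.  ``parallel_workers`` > 1 distributes curve generation with
    joblib (the result is identical to the serial one).
    """
    if n < 10:
        raise ValueError("need n >= 10 for an 8:1:1 split")
    if base_params is None:
        base_params = InteractionParams(**DEFAULT_BASE_PARAMS)
    if q is None:
        q = make_q_grid()
    pairs = sample_parameters(n, seed)
    seeds = _curve_seeds(seed, n)

    def one(i: int) -> np.ndarray:
        p = replace(base_params, z_eff=pairs[i, 0], kappa_inv=pairs[i, 1])
        cfg = replace(sim_config, seed=int(seeds[i]))
        try:
            return generate_curve(p, cfg, q=q).intensity
        except Exception as exc:  # pragma: no cover - worker diagnostics
            raise RuntimeError(
                f"curve {i} failed at (z_eff={pairs[i, 0]:.3f}, "
                f"kappa_inv={pairs[i, 1]:.3f}, seed={seeds[i]})") from exc

    if parallel_workers > 1:
        from joblib import Parallel, delayed
        rows = Parallel(n_jobs=parallel_workers)(
            delayed(one)(i) for i in range(n))
    else:
        rows = [one(i) for i in range(n)]
    curves = np.vstack(rows)
    return TrainingDataset(
        curves=curves, labels=pairs, q=np.asarray(q, dtype=float),
        split_assignment=assign_splits(n, seed),
        metadata={"master_seed": seed, "curve_seeds": seeds,
                  "n_particles": sim_config.n_particles,
                  "number_density": sim_config.number_density})


def apply_q_cutoff(dataset: TrainingDataset, q_cutoff: float) -> TrainingDataset:
    """Retain only grid points with q <= q_cutoff (the low-q signal region)."""
    q = dataset.q
    if q_cutoff < q[0]:
        raise ValueError(
            f"q_cutoff {q_cutoff} lies below the first grid point {q[0]}: "
            "no features would survive")
    if q_cutoff > q[-1]:
        raise ValueError(f"q_cutoff {q_cutoff} beyond the grid maximum {q[-1]}")
    keep = q <= q_cutoff
    return TrainingDataset(
        curves=dataset.curves[:, keep], labels=dataset.labels,
        q=q[keep], split_assignment=dataset.split_assignment,
        normalization_stats=None,
        metadata={**dataset.metadata, "q_cutoff": q_cutoff,
                  "n_features": int(keep.sum())})


def normalize_features(dataset: TrainingDataset,
                       ) -> tuple[np.ndarray, NormalizationStats]:
    """Model-ready features: log10 intensity, standardized per column.

    Statistics come from the training split only (no leakage); the stats
    object provides the exact inverse transform.  The computed stats are
    stored on ``dataset.normalization_stats``.
    """
    if np.any(dataset.curves <= 0):
        raise ValueError("intensities must be positive to take logs")
    train = dataset.curves[dataset.mask("train")]
    if train.shape[0] == 0:
        raise ValueError("empty training split")
    logs = np.log10(train)
    std = logs.std(axis=0)
    stats = NormalizationStats(mean=logs.mean(axis=0),
                               std=np.where(std > 0, std, 1.0))
    dataset.normalization_stats = stats
    return stats.forward(dataset.curves), stats


# ---------------------------------------------------------------------------
# persistence: HDF5 container + plain-text manifest
# ---------------------------------------------------------------------------

def save_dataset(dataset: TrainingDataset, path) -> None:
    """Write the corpus to one HDF5 file plus a ``<path>.manifest`` text file."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("curves", data=dataset.curves)
        fh.create_dataset("labels", data=dataset.labels)
        fh.create_dataset("q", data=dataset.q)
        fh.create_dataset("split_assignment", data=dataset.split_assignment)
        if dataset.normalization_stats is not None:
            fh.create_dataset("norm_mean", data=dataset.normalization_stats.mean)
            fh.create_dataset("norm_std", data=dataset.normalization_stats.std)
        meta = fh.create_group("metadata")
        for key, value in dataset.metadata.items():
            meta.attrs[key] = value
    counts = {name: int(dataset.mask(name).sum()) for name in SPLIT_NAMES}
    with open(f"{path}.manifest", "w") as fh:
        fh.write(f"samples: {dataset.n_samples}\n")
        fh.write(f"q_points: {dataset.q.size}\n")
        fh.write(f"q_range: {dataset.q[0]:.6g} {dataset.q[-1]:.6g}\n")
        for name, count in counts.items():
            fh.write(f"{name}: {count}\n")
        for key, value in dataset.metadata.items():
            if np.isscalar(value):
                fh.write(f"{key}: {value}\n")


def load_dataset(path) -> TrainingDataset:
    import h5py

    with h5py.File(path, "r") as fh:
        stats = None
        if "norm_mean" in fh:
            stats = NormalizationStats(fh["norm_mean"][...], fh["norm_std"][...])
        return TrainingDataset(
            curves=fh["curves"][...], labels=fh["labels"][...],
            q=fh["q"][...], split_assignment=fh["split_assignment"][...],
            normalization_stats=stats,
            metadata=dict(fh["metadata"].attrs))
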