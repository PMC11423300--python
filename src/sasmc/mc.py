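"""Metropolis Monte Carlo of DLVO spheres in a periodic cubic box.

The engine follows the classic single-particle-move recipe: random initial
placement with overlap rejection, Metropolis acceptance on the total DLVO
energy, an equilibration rule that compares checkpoint energies every
``equil_block`` steps, a production window from which snapshots are drawn
at random step indices, and a snapshot-averaged radial distribution
function g(r).

All stochastic operations are exactly reproducible from (seed, config):
sub-seeds for initialization, equilibration blocks and production are
derived from the master seed with :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _kernels
from .constants import DEFAULT_NUMBER_DENSITY
from .potentials import InteractionParams

__all__ = [
    "SimulationConfig",
    "ParticleConfiguration",
    "RDF",
    "EquilibrationResult",
    "interaction_cutoff",
    "initialize_configuration",
    "total_energy",
    "mc_sweep",
    "run_to_equilibrium",
    "sample_snapshots",
    "compute_rdf",
    "simulate_rdf",
]


@dataclass
class SimulationConfig:
    """Knobs of one Monte Carlo run.

    Defaults are the full-scale study conditions: 5000 particles at the
    number density of a 40 mg/mL gold-nanoparticle solution, checkpoint
    energies compared every 100,000 steps with a 1% relative tolerance,
    50,000 production steps and 1000 snapshots at T = 297 K.  Desk-scale
    work shrinks ``n_particles`` and the step counts (see
    ``docs/methods.md``), it does not touch the physics.
    """

    n_particles: int = 5000
    number_density: float = DEFAULT_NUMBER_DENSITY  # nm^-3
    max_displacement: float = 2.0  # nm, trial-move amplitude
    temperature: float = 297.0
    seed: int = 0
    equil_block: int = 100_000
    equil_rel_tol: float = 0.01
    post_equil_steps: int = 50_000
    n_snapshots: int = 1000
    #: hard budget: at most this many equilibration blocks before erroring
    max_equil_blocks: int = 100
    #: compare block-averaged energies at checkpoints instead of
    #: instantaneous ones (optional variant; the literal rule is default)
    block_average: bool = False
    #: floor for the relative-change denominator (the zero-energy guard)
    equil_energy_floor: float = 1e-8
    #: adapt max_displacement toward 30-50% acceptance during
    #: equilibration; frozen during production (detailed balance)
    adapt_displacement: bool = True
    rdf_bins: int = 256
    rdf_r_max: float | None = None  # default box_length/2

    def __post_init__(self):
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.number_density <= 0:
            raise ValueError("number_density must be positive")
        if not 0 < self.equil_rel_tol:
            raise ValueError("equil_rel_tol must be positive")

    @property
    def box_length(self) -> float:
        """Cubic edge L = (N / n_p)^(1/3), nm."""
        return (self.n_particles / self.number_density) ** (1.0 / 3.0)

    def packing_fraction(self, radius: float) -> float:
        return self.number_density * 4.0 / 3.0 * np.pi * radius ** 3


@dataclass
class ParticleConfiguration:
    """N sphere centers in a periodic cubic box (lengths in nm)."""

    positions: np.ndarray  # (N, 3), coordinates in [0, box_length)
    box_length: float
    radius: float

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def validate(self) -> None:
        """Check both invariants (O(N^2); meant for tests and debugging)."""
        pos = self.positions
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if np.any(pos < 0) or np.any(pos >= self.box_length):
            raise ValueError("coordinates outside [0, box_length)")
        if self.min_pair_distance() <= 2.0 * self.radius:
            raise ValueError("hard-core overlap between particles")

    def min_pair_distance(self) -> float:
        """Smallest minimum-image pair distance (brute force)."""
        delta = self.positions[:, None, :] - self.positions[None, :, :]
        delta -= self.box_length * np.round(delta / self.box_length)
        d2 = np.einsum("ijk,ijk->ij", delta, delta)
        np.fill_diagonal(d2, np.inf)
        return float(np.sqrt(d2.min()))

    def copy(self) -> "ParticleConfiguration":
        return ParticleConfiguration(self.positions.copy(),
                                     self.box_length, self.radius)


@dataclass
class RDF:
    """Binned radial distribution function of a snapshot ensemble."""

    r_centers: np.ndarray  # bin midpoints, nm
    g_values: np.ndarray   # dimensionless g(r)
    n_p: float             # number density used downstream (N/V, nm^-3)

    def __post_init__(self):
        if np.any(self.g_values < 0):
            raise ValueError("g(r) must be nonnegative")


@dataclass
class EquilibrationResult:
    configuration: ParticleConfiguration
    steps: int
    energy_trace: list[float] = field(default_factory=list)
    max_displacement: float = 0.0
    energy: float = 0.0


def interaction_cutoff(params: InteractionParams, box_length: float) -> float:
    """Pair-potential truncation radius min(L/2, 2r + 8 kappa^-1), nm."""
    return min(box_length / 2.0, 2.0 * params.radius + 8.0 * params.kappa_inv)


def _kernel_constants(params: InteractionParams, box_length: float,
                      cutoff: float | None = None):
    rc = interaction_cutoff(params, box_length) if cutoff is None else cutoff
    return (box_length,
            params.contact_distance ** 2,  # steric hard core
            4.0 * params.radius ** 2,      # 4 r^2 of the potential forms
            params.hamaker_beta,
            params.yukawa_prefactor,
            params.kappa,
            rc * rc)


def _sub_seed(seed: int, *tags: int) -> int:
    """31-bit sub-seed derived from the master seed and a stage tag."""
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def initialize_configuration(config: SimulationConfig,
                             params: InteractionParams,
                             rng: np.random.Generator | None = None,
                             ) -> ParticleConfiguration:
    """Place N spheres by sequential random insertion with overlap rejection.

    Deterministic given ``config.seed``.  Refuses packing fractions above
    0.3, where naive insertion stalls; raises if the per-particle attempt
    budget is exhausted.
    """
    phi = config.packing_fraction(params.radius + params.shell_thickness)
    if phi >= 0.3:
        raise ValueError(
            f"steric packing fraction {phi:.3f} >= 0.3: random insertion "
            "is unreliable; lower the density")
    if rng is None:
        rng = np.random.default_rng(_sub_seed(config.seed, 0))
    box = config.box_length
    n = config.n_particles
    hc2 = params.contact_distance ** 2
    positions = np.empty((n, 3))
    max_attempts = 1000
    for i in range(n):
        for _ in range(max_attempts):
            candidate = rng.random(3) * box
            if i == 0:
                positions[0] = candidate
                break
            delta = positions[:i] - candidate
            delta -= box * np.round(delta / box)
            if np.min(np.einsum("ij,ij->i", delta, delta)) > hc2:
                positions[i] = candidate
                break
        else:
            raise RuntimeError(
                f"failed to insert particle {i} after {max_attempts} "
                "attempts; lower the density")
    return ParticleConfiguration(positions, box, params.radius)


def total_energy(conf: ParticleConfiguration, params: InteractionParams,
                 cutoff: float | None = None) -> float:
    """Total DLVO energy (k_B*T): unique minimum-image pairs within cutoff."""
    if cutoff is not None and cutoff > conf.box_length / 2.0:
        raise ValueError("cutoff exceeds box_length/2: minimum image violated")
    box, hc2, four_r2, a_vdw, c_el, kappa, rc2 = _kernel_constants(
        params, conf.box_length, cutoff)
    energy, overlap = _kernels.total_energy_kernel(
        conf.positions, box, hc2, four_r2, a_vdw, c_el, kappa, rc2)
    if overlap:
        return np.inf
    return float(energy)


def mc_sweep(conf: ParticleConfiguration, params: InteractionParams,
             config: SimulationConfig,
             rng: np.random.Generator | None = None,
             ) -> tuple[ParticleConfiguration, dict]:
    """One attempted Metropolis move (a "step"), in pure numpy.

    Mirrors the compiled kernel move-for-move and exists for tests and
    single-step introspection; bulk stepping goes through the kernel.
    Returns the (mutated) configuration and diagnostics.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    box = conf.box_length
    pos = conf.positions
    _, hc2, four_r2, a_vdw, c_el, kappa, rc2 = _kernel_constants(params, box)
    i = int(rng.integers(conf.n_particles))
    old = pos[i].copy()
    e_old, _ = _kernels.particle_energy(pos, i, box, hc2, four_r2,
                                        a_vdw, c_el, kappa, rc2)
    trial = old + (2.0 * rng.random(3) - 1.0) * config.max_displacement
    pos[i] = trial - box * np.floor(trial / box)
    e_new, overlap = _kernels.particle_energy(pos, i, box, hc2, four_r2,
                                              a_vdw, c_el, kappa, rc2)
    accepted = False
    delta_e = np.inf if overlap else e_new - e_old
    if not overlap and (delta_e <= 0.0 or rng.random() < np.exp(-delta_e)):
        accepted = True
    else:
        pos[i] = old
    return conf, {"accepted": accepted, "particle": i,
                  "delta_energy": delta_e if accepted else 0.0}


def _run_block(conf, kc, max_disp, n_steps, seed,
               snap_steps=None, snaps=None):
    if snap_steps is None:
        snap_steps = np.empty(0, dtype=np.int64)
        snaps = np.empty((0, conf.n_particles, 3))
    box, hc2, four_r2, a_vdw, c_el, kappa, rc2 = kc
    delta_e, n_accept = _kernels.run_mc_kernel(
        conf.positions, box, hc2, four_r2, a_vdw, c_el, kappa, rc2,
        max_disp, n_steps, seed, snap_steps, snaps)
    return float(delta_e), int(n_accept)


def run_to_equilibrium(conf: ParticleConfiguration,
                       params: InteractionParams,
                       config: SimulationConfig) -> EquilibrationResult:
    """Iterate MC steps until the checkpoint-energy rule declares equilibrium.

    Every ``equil_block`` steps the current total energy E_i is compared
    with the previous checkpoint's E_{i-1}; equilibrium is declared when
    |E_i - E_{i-1}| / max(|E_{i-1}|, floor) < equil_rel_tol.  With
    ``block_average=True`` the checkpoints carry block-averaged instead of
    instantaneous energies.  The trial-move amplitude adapts toward 30-50%
    acceptance between blocks (and is frozen afterwards).

    Raises RuntimeError carrying the energy trace if the block budget is
    exhausted.
    """
    kc = _kernel_constants(params, conf.box_length)
    max_disp = config.max_displacement
    energy = total_energy(conf, params)
    prev_checkpoint = energy
    trace = [energy]
    steps = 0
    for block in range(config.max_equil_blocks):
        seed = _sub_seed(config.seed, 1, block)
        if config.block_average:
            # accumulate a within-block average from sub-block checkpoints
            n_sub = 20
            sub = max(1, config.equil_block // n_sub)
            acc_e, acc_moves = 0.0, 0
            for s in range(n_sub):
                d_e, n_acc = _run_block(conf, kc, max_disp, sub,
                                        _sub_seed(seed, s))
                energy += d_e
                acc_e += energy
                acc_moves += n_acc
            checkpoint = acc_e / n_sub
            n_accept, block_steps = acc_moves, n_sub * sub
        else:
            d_e, n_accept = _run_block(conf, kc, max_disp,
                                       config.equil_block, seed)
            energy += d_e
            checkpoint = energy
            block_steps = config.equil_block
        steps += block_steps
        trace.append(checkpoint)
        rel = abs(checkpoint - prev_checkpoint) / max(
            abs(prev_checkpoint), config.equil_energy_floor)
        if rel < config.equil_rel_tol:
            return EquilibrationResult(conf, steps, trace, max_disp, energy)
        prev_checkpoint = checkpoint
        if config.adapt_displacement:
            rate = n_accept / block_steps
            if rate < 0.3:
                max_disp *= 0.8
            elif rate > 0.5:
                max_disp = min(max_disp * 1.25, conf.box_length / 4.0)
    raise RuntimeError(
        f"equilibration budget of {config.max_equil_blocks} blocks "
        f"exhausted; energy trace: {trace}")


def sample_snapshots(conf: ParticleConfiguration,
                     params: InteractionParams,
                     config: SimulationConfig,
                     max_displacement: float | None = None) -> np.ndarray:
    """Run the production window and return snapshots, shape (S, N, 3).

    ``n_snapshots`` step indices are drawn uniformly without replacement
    from the ``post_equil_steps`` production steps (deterministic given
    the seed); the configuration is recorded after each selected step.
    """
    if config.n_snapshots > config.post_equil_steps:
        raise ValueError("n_snapshots cannot exceed post_equil_steps")
    rng = np.random.default_rng(_sub_seed(config.seed, 2))
    snap_steps = np.sort(rng.choice(config.post_equil_steps,
                                    size=config.n_snapshots,
                                    replace=False)).astype(np.int64)
    snaps = np.empty((config.n_snapshots, conf.n_particles, 3))
    kc = _kernel_constants(params, conf.box_length)
    max_disp = (config.max_displacement if max_displacement is None
                else max_displacement)
    _run_block(conf, kc, max_disp, config.post_equil_steps,
               _sub_seed(config.seed, 3), snap_steps, snaps)
    return snaps


def compute_rdf(snapshots: np.ndarray | Sequence[ParticleConfiguration],
                box_length: float | None = None,
                radius: float | None = None,
                n_bins: int = 256,
                r_max: float | None = None) -> RDF:
    """Snapshot-averaged g(r) from minimum-image pair distances.

    Counts are normalized per snapshot by the ideal-gas shell expectation
    (N/2) * n'_p * (4/3) pi (r_{k+1}^3 - r_k^3) with the *pair* density
    n'_p = (N-1)/V, which makes g(r) = 1 exactly for an uncorrelated
    fixed-N system (see docs/methods.md).  The returned ``n_p`` is N/V,
    the density entering the structure-factor transform.
    """
    if not isinstance(snapshots, np.ndarray):
        confs = list(snapshots)
        if not confs:
            raise ValueError("need at least one snapshot")
        box_length = confs[0].box_length
        radius = confs[0].radius
        snapshots = np.stack([c.positions for c in confs])
    if snapshots.ndim != 3 or snapshots.shape[0] < 1:
        raise ValueError("need at least one snapshot of shape (N, 3)")
    if box_length is None:
        raise ValueError("box_length required with array snapshots")
    if r_max is None:
        r_max = box_length / 2.0
    if r_max > box_length / 2.0 + 1e-12:
        raise ValueError("r_max beyond box_length/2: minimum image violated")
    n_snap, n, _ = snapshots.shape
    counts = _kernels.rdf_counts_kernel(snapshots, box_length, r_max, n_bins)
    edges = np.linspace(0.0, r_max, n_bins + 1)
    volume = box_length ** 3
    shell = 4.0 / 3.0 * np.pi * np.diff(edges ** 3)
    ideal = 0.5 * n * (n - 1) / volume * shell * n_snap
    g = counts / ideal
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDF(centers, g, n / volume)


def simulate_rdf(params: InteractionParams, config: SimulationConfig,
                 ) -> tuple[RDF, EquilibrationResult]:
    """Full engine pass: init -> equilibrate -> snapshots -> g(r)."""
    conf = initialize_configuration(config, params)
    equil = run_to_equilibrium(conf, params, config)
    snaps = sample_snapshots(equil.configuration, params, config,
                             equil.max_displacement)
    rdf = compute_rdf(snaps, conf.box_length, params.radius,
                      n_bins=config.rdf_bins, r_max=config.rdf_r_max)
    return rdf, equil


def write_xyz(path, snapshots: np.ndarray, box_length: float,
              comment: str = "") -> None:
    """Dump snapshots as a plain-text XYZ-style trajectory."""
    with open(path, "w") as fh:
        for k, snap in enumerate(snapshots):
            fh.write(f"{snap.shape[0]}\n")
            fh.write(f"box_length={box_length:.6f} snapshot={k} {comment}\n")
            for x, y, z in snap:
                fh.write(f"P {x:.6f} {y:.6f} {z:.6f}\n")
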