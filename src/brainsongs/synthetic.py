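"""Synthetic inputs: connectomes, planted-assembly rasters, surrogate BOLD.

These generators stand in for diffusion-MRI connectomes and empirical
recordings so the whole framework can be exercised and validated without
any acquired data.  Rasters carry machine-readable ground truth (planted
memberships, activation intervals) so recovery can be asserted
automatically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .connectome import StructuralConnectome
from .hemodynamics import BoldTimeseries, bold_from_rates
from .params import DmfParameters, HemodynamicParameters

__all__ = ["AssemblySpec", "make_connectome", "damage_connectome",
           "make_planted_raster", "make_surrogate_bold"]


@dataclass
class AssemblySpec:
    """A planted assembly: members, stationary activation probability and
    mean active-duration (ms)."""

    members: list[int]
    p_active: float = 0.15
    duration_ms: float = 200.0
    p_member: float = 0.75
    jitter_frac: float = 1.0
    regularity: float = 6.0
    on_regularity: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.p_active < 1:
            raise ValueError("p_active must lie in (0, 1)")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if not 0 < self.p_member <= 1:
            raise ValueError("p_member must lie in (0, 1]")
        if self.jitter_frac < 0:
            raise ValueError("jitter_frac must be nonnegative")
        if self.regularity < 1 or self.on_regularity < 1:
            raise ValueError("regularity shape parameters must be >= 1")


def make_connectome(n_regions: int, family: str = "community",
                    density: float = 0.3, weight_scale: float = 1.0,
                    n_communities: int = 3, shortcut_prob: float = 0.05,
                    seed: int = 0) -> StructuralConnectome:
    """Generate a symmetric, zero-diagonal, nonnegative coupling matrix.

    Families
    --------
    ``community``
        Stochastic block structure: dense strong within-community edges,
        sparse weak between-community edges.
    ``distance``
        Regions on a ring; connection weights decay exponentially with
        ring distance, thresholded to the requested density.
    ``ring``
        Ring lattice (each region linked to its nearest neighbours) plus
        random shortcuts.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    W = np.zeros((n_regions, n_regions))
    iu = np.triu_indices(n_regions, k=1)

    if family == "community":
        comm = np.sort(np.arange(n_regions) % n_communities)
        same = comm[iu[0]] == comm[iu[1]]
        p_edge = np.where(same, min(1.0, 2.5 * density), 0.5 * density)
        present = rng.random(iu[0].size) < p_edge
        w = rng.gamma(2.0, weight_scale / 2.0, iu[0].size)
        w = np.where(same, w, 0.3 * w)
        W[iu] = present * w
    elif family == "distance":
        d = np.abs(iu[0] - iu[1])
        d = np.minimum(d, n_regions - d).astype(float)
        scale = max(n_regions / 6.0, 1.0)
        w = weight_scale * np.exp(-d / scale)
        n_keep = max(1, int(round(density * iu[0].size)))
        thresh = np.sort(w)[-n_keep]
        W[iu] = np.where(w >= thresh, w, 0.0)
    elif family == "ring":
        k = max(1, int(round(density * (n_regions - 1) / 2)))
        d = np.abs(iu[0] - iu[1])
        d = np.minimum(d, n_regions - d)
        lattice = d <= k
        shortcuts = rng.random(iu[0].size) < shortcut_prob
        w = rng.gamma(2.0, weight_scale / 2.0, iu[0].size)
        W[iu] = (lattice | shortcuts) * w
    else:
        raise ValueError(f"unknown connectome family {family!r}")

    W = W + W.T
    np.fill_diagonal(W, 0.0)
    # normalise so the strongest total input equals weight_scale; keeps the
    # useful range of the global coupling G comparable across families
    rowmax = W.sum(axis=1).max()
    if rowmax > 0:
        W *= weight_scale / rowmax
    return StructuralConnectome(W)


def damage_connectome(sc: StructuralConnectome, percent: float
                      ) -> StructuralConnectome:
    """Zero the top ``percent`` % strongest edges (ceil of the edge count).

    Emulates targeted damage to the strongest couplings of the network;
    ``percent=0`` returns an identical copy.
    """
    if not 0 <= percent <= 100:
        raise ValueError("percent must lie in [0, 100]")
    W = sc.weights.copy()
    iu = np.triu_indices_from(W, k=1)
    vals = W[iu]
    edges = np.flatnonzero(vals > 0)
    n_cut = int(np.ceil(percent / 100.0 * edges.size))
    if n_cut > 0:
        order = edges[np.argsort(-vals[edges], kind="stable")][:n_cut]
        vals = vals.copy()
        vals[order] = 0.0
        W[iu] = vals
        W = np.triu(W, 1)
        W = W + W.T
    return StructuralConnectome(W, list(sc.region_labels))


def make_planted_raster(n_regions: int, duration_ms: float,
                        assemblies: list[AssemblySpec],
                        amplitude: float = 1.0, background_sd: float = 1.0,
                        global_amplitude: float = 0.15,
                        global_timescale_ms: float = 1000.0,
                        dt: float = 1.0, seed: int = 0
                        ) -> tuple[np.ndarray, dict]:
    """Generate an activity raster with planted assemblies of known timescale.

    Background is independent Gaussian noise per region and sample.  Each
    assembly is a two-state renewal process: Erlang-distributed dwell
    times (shape ``on_regularity`` with mean ``duration_ms`` in the
    active state, shape ``regularity`` in the inactive state) with the
    inactive mean chosen so the stationary active probability equals
    ``p_active``.  The Erlang shapes make the recurrence quasi-regular,
    which is what gives the assembly a well-defined characteristic
    timescale (shape 1 recovers the memoryless/geometric limit).  Per
    activation, each member participates with
    probability ``p_member`` and its active interval is shifted by a
    uniform onset jitter of up to ``jitter_frac * duration_ms`` in either
    direction: the assembly is coherent only at its own timescale, which
    is what gives "characteristic duration" its meaning for recovery
    experiments (at much finer binning the members no longer co-occupy
    bins).  While participating, a member's signal is raised by
    ``amplitude`` (in units of the background SD); overlapping assemblies
    add (a warning is emitted when memberships are shared).

    On top of the independent noise, every region shares a slow global
    co-fluctuation (an Ornstein-Uhlenbeck process with correlation time
    ``global_timescale_ms`` and stationary SD ``global_amplitude``),
    mimicking the global signal of real whole-brain recordings.

    Returns
    -------
    activity : ndarray of shape (n_regions, n_samples)
    truth : dict
        ``membership`` (n_assemblies x n_regions 0/1), ``active`` (the
        realised assembly on/off rasters), per-assembly realised active
        fraction and activation counts, and the generator arguments.
    """
    if duration_ms <= 10 * max((a.duration_ms for a in assemblies),
                               default=0.0):
        raise ValueError("duration must exceed 10x the longest assembly "
                         "duration")
    rng = np.random.default_rng(seed)
    T = int(round(duration_ms / dt))
    activity = rng.standard_normal((n_regions, T)) * background_sd
    if global_amplitude > 0:
        # shared OU process with unit stationary SD
        from scipy.signal import lfilter

        a = np.exp(-dt / global_timescale_ms)
        innov = rng.standard_normal(T) * np.sqrt(1.0 - a * a)
        innov[0] = rng.standard_normal()
        g = lfilter([1.0], [1.0, -a], innov)
        activity += global_amplitude * background_sd * g[None, :]

    seen: set[int] = set()
    membership = np.zeros((len(assemblies), n_regions))
    active = np.zeros((len(assemblies), T), dtype=bool)
    for a_idx, a in enumerate(assemblies):
        if any(m >= n_regions or m < 0 for m in a.members):
            raise ValueError("assembly member outside region range")
        overlap = seen.intersection(a.members)
        if overlap:
            warnings.warn(f"assemblies share members {sorted(overlap)}; "
                          "their signals add")
        seen.update(a.members)
        membership[a_idx, a.members] = 1.0
        # alternating Erlang renewal on the dt grid
        mean_off = a.duration_ms * (1.0 - a.p_active) / a.p_active
        jitter = a.jitter_frac * a.duration_ms / dt
        boost = amplitude * background_sd
        t = -rng.random() * mean_off / dt   # random phase at t = 0
        while t < T:
            t += rng.gamma(a.regularity, mean_off / a.regularity / dt)
            dur = rng.gamma(a.on_regularity, a.duration_ms /
                            a.on_regularity / dt)
            if t >= T:
                break
            lo0 = max(0, int(t))
            hi0 = max(lo0, min(T, int(t + dur)))
            active[a_idx, lo0:hi0] = True
            for m in a.members:
                if rng.random() > a.p_member:
                    continue
                shift = rng.uniform(-jitter, jitter)
                lo = max(0, int(t + shift))
                hi = max(lo, min(T, int(t + dur + shift)))
                if hi > lo:
                    activity[m, lo:hi] += boost
            t += dur

    starts = np.diff(active.astype(int), axis=1, prepend=0) == 1
    truth = {
        "membership": membership,
        "active": active,
        "active_fraction": active.mean(axis=1).tolist(),
        "n_activations": starts.sum(axis=1).tolist(),
        "assemblies": [asdict(a) for a in assemblies],
        "amplitude": amplitude,
        "background_sd": background_sd,
        "dt": dt,
        "seed": seed,
    }
    return activity, truth


def save_truth(truth: dict, path) -> None:
    """Write the ground-truth sidecar as JSON (arrays as lists)."""
    out = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
           for k, v in truth.items()}
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)


def make_surrogate_bold(sc: StructuralConnectome, params: DmfParameters,
                        G: float, tr: float = 2.0,
                        duration_ms: float = 360_000.0, seed: int = 0,
                        hemo: HemodynamicParameters | None = None,
                        dt: float = 0.1, transient_ms: float = 2_000.0,
                        bold_discard_s: float = 20.0,
                        ) -> tuple[BoldTimeseries, dict]:
    """Run the full forward model and relabel the output as "empirical".

    The generating coupling G is recorded in the returned truth sidecar so
    parameter-recovery experiments can assert against it.
    """
    from .fic import fic_tune
    from .dmf import simulate_dmf

    ss = np.random.SeedSequence([int(seed), 77])
    fic_seed, sim_seed = (int(s.generate_state(1)[0] & 0x7FFFFFFF)
                          for s in ss.spawn(2))
    fic = fic_tune(sc, params, G=G, seed=fic_seed, dt=dt)
    traj = simulate_dmf(sc, params.with_(G=float(G)), fic, duration_ms,
                        dt=dt, seed=sim_seed).discard(transient_ms)
    bold = bold_from_rates(traj.rates_E, hemo or HemodynamicParameters(),
                           dt=traj.record_dt, out_interval=tr,
                           region_labels=traj.region_labels)
    bold = bold.discard(bold_discard_s)
    truth = {"G": float(G), "seed": int(seed), "tr": tr,
             "duration_ms": duration_ms}
    return bold, truth
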