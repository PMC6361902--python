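"""Dynamic mean-field simulation of coupled excitatory-inhibitory regions.

Each brain region is a reduced Wong-Wang node: an excitatory pool with
NMDA-mediated recurrence and an inhibitory pool with GABA-A feedback,
coupled between regions through the structural connectome scaled by the
global coupling G.  Integration is Euler-Maruyama with additive Gaussian
noise on both gating variables; gating is clipped to [0, 1] after every
step (the noise can otherwise eject it), which is part of the simulator's
contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import dmf_euler
from .connectome import StructuralConnectome
from .params import DmfParameters

__all__ = ["NeuralTrajectory", "transfer_rate", "simulate_dmf"]


@dataclass
class NeuralTrajectory:
    """Sampled state of a dynamic mean-field simulation.

    Rates, currents and gating variables are recorded as averages over
    consecutive windows of ``record_dt`` ms (default 1 ms, i.e. the rate
    of spiking activity in 1 ms windows); ``dt`` is the integration step.
    """

    time_axis: np.ndarray          # ms, centre-independent window index * record_dt
    rates_E: np.ndarray            # N x T, Hz
    rates_I: np.ndarray            # N x T, Hz
    gating_E: np.ndarray           # N x T, dimensionless in [0, 1]
    gating_I: np.ndarray
    currents_E: np.ndarray         # N x T, nA
    currents_I: np.ndarray
    dt: float                      # integration step, ms
    record_dt: float               # recording window, ms
    seed: int
    region_labels: list[str] = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return self.rates_E.shape[0]

    @property
    def n_samples(self) -> int:
        return self.rates_E.shape[1]

    def discard(self, transient_ms: float) -> "NeuralTrajectory":
        """Return a view with the first ``transient_ms`` dropped."""
        k = int(round(transient_ms / self.record_dt))
        return NeuralTrajectory(
            self.time_axis[k:], self.rates_E[:, k:], self.rates_I[:, k:],
            self.gating_E[:, k:], self.gating_I[:, k:],
            self.currents_E[:, k:], self.currents_I[:, k:],
            self.dt, self.record_dt, self.seed, self.region_labels,
        )

    def to_file(self, path, decimate: int = 1, delimiter: str = "\t") -> None:
        """Write time + excitatory rates as delimited text."""
        sl = slice(None, None, int(decimate))
        data = np.column_stack([self.time_axis[sl], self.rates_E[:, sl].T])
        header = delimiter.join(["time_ms"] + self.region_labels)
        np.savetxt(path, data, delimiter=delimiter, header=header, comments="")


def transfer_rate(current, pop: str, params: DmfParameters):
    """Population input-output transfer function H(I) = (aI-b)/(1-exp(-d(aI-b))).

    Vectorised over ``current`` (nA); ``pop`` selects the excitatory or
    inhibitory constant set.  The removable singularity at aI - b = 0
    evaluates to 1/d.
    """
    current = np.asarray(current, dtype=float)
    if not np.all(np.isfinite(current)):
        raise ValueError("transfer_rate: non-finite input current")
    if pop.startswith("e"):
        a, b, d = params.a_E, params.b_E, params.d_E
    elif pop.startswith("i"):
        a, b, d = params.a_I, params.b_I, params.d_I
    else:
        raise ValueError(f"unknown population {pop!r}")
    x = a * current - b
    u = d * x
    small = np.abs(u) < 1e-6
    safe = np.where(small, 1.0, u)
    out = np.where(
        small,
        1.0 / d + x / 2.0 + d * x * x / 12.0,
        x / (1.0 - np.exp(-safe)),
    )
    return out if out.ndim else float(out)


def simulate_dmf(sc: StructuralConnectome, params: DmfParameters,
                 fic, duration: float, dt: float = 0.1,
                 seed: int = 0, record_dt: float = 1.0,
                 initial_gating: tuple[float, float] = (0.1, 0.1),
                 ) -> NeuralTrajectory:
    """Simulate the whole-brain dynamic mean-field model.

    Parameters
    ----------
    sc : StructuralConnectome
        Anatomical coupling matrix C_ij.
    params : DmfParameters
        Model constants; ``params.G`` is the global coupling.
    fic : FicWeights or array-like
        Per-region inhibitory feedback weights J_i (nA).
    duration : float
        Simulated time in ms; must be at least 10 * dt.
    dt : float
        Euler-Maruyama step in ms, at most 1 ms.
    seed : int
        Seeds the whole noise stream; identical arguments give a
        bit-identical trajectory.
    record_dt : float
        Width of the averaging window used for recording (ms); must be an
        integer multiple of dt.

    Raises
    ------
    FloatingPointError
        If the state becomes non-finite, naming the first offending region
        and integration step.
    """
    J = np.asarray(getattr(fic, "J", fic), dtype=float)
    if dt <= 0 or dt > 1.0:
        raise ValueError("dt must lie in (0, 1] ms")
    if duration < 10 * dt:
        raise ValueError("duration must be at least 10 * dt")
    N = sc.n_regions
    if J.shape != (N,):
        raise ValueError(f"FIC weights length {J.shape} does not match N={N}")
    rec_every = int(round(record_dt / dt))
    if abs(rec_every * dt - record_dt) > 1e-9:
        raise ValueError("record_dt must be an integer multiple of dt")
    n_steps = int(round(duration / dt))
    n_steps = (n_steps // rec_every) * rec_every

    S0_E = np.full(N, float(initial_gating[0]))
    S0_I = np.full(N, float(initial_gating[1]))
    status, bad_region, bad_step, rE, rI, IE, II, SE, SI, _, _ = dmf_euler(
        np.ascontiguousarray(sc.weights), J, params.G,
        params.a_E, params.b_E, params.d_E,
        params.a_I, params.b_I, params.d_I,
        params.gamma_kinetic, params.tau_E, params.tau_I,
        params.I0, params.W_E, params.W_I, params.w_plus, params.J_NMDA,
        params.sigma_noise, dt, n_steps, rec_every, int(seed) & 0x7FFFFFFF,
        S0_E, S0_I,
    )
    if status != 0:
        raise FloatingPointError(
            f"DMF integration produced a non-finite state in region "
            f"{bad_region} at step {bad_step} (t = {bad_step * dt:.3f} ms)"
        )
    time_axis = (np.arange(rE.shape[1]) + 1) * record_dt
    return NeuralTrajectory(time_axis, rE, rI, SE, SI, IE, II,
                            dt, record_dt, int(seed), list(sc.region_labels))
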