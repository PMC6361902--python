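"""Richness of the motif repertoire: entropy, cohesiveness, hierarchy,
motif transitions, and the timescale sweep.

The entropy of the motif activation probabilities measures how rich the
switching between spacetime motifs is at a given timescale; the
cohesiveness of a region aggregates, over motifs, its participation
(w_ic) times the motif's probability p(c) times the motif's broadness
(sum_j w_jc), and the hierarchy is the spread (population SD) of
cohesiveness across regions.  Sweeping the bin size yields
entropy/hierarchy-versus-timescale curves whose peak locates the
timescale that maximises the dynamical repertoire.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .motifs import (MotifExtractor, bin_timeseries)

logger = logging.getLogger(__name__)

__all__ = ["RepertoireSummary", "SweepResult", "entropy", "cohesiveness",
           "hierarchy", "transition_matrix", "analyse_at_bin",
           "timescale_sweep", "TimescaleSweep"]


def entropy(p, base: float | None = None) -> float:
    """Shannon entropy H = -sum_c p(c) log p(c) of a probability vector.

    ``base=None`` uses the natural log (nats); pass 2 for bits.  The
    convention 0 * log 0 = 0 applies.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return 0.0
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("p must be a probability vector summing to 1")
    p = np.clip(p, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    H = -float(terms.sum())
    if base is not None:
        H /= np.log(base)
    return max(H, 0.0)


def cohesiveness(weights: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Per-region cohesiveness Coh(i) = sum_c w_ic p(c) (sum_j w_jc)."""
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    p = np.asarray(p, dtype=float)
    if weights.shape[1] != p.size:
        raise ValueError(
            f"weights columns {weights.shape[1]} != len(p) {p.size}")
    if p.size and (np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9):
        raise ValueError("p must be a probability vector summing to 1")
    broadness = weights.sum(axis=0)
    return weights @ (p * broadness)


def hierarchy(coh: np.ndarray) -> float:
    """Population SD of the cohesiveness across regions."""
    coh = np.asarray(coh, dtype=float)
    if coh.size < 2:
        raise ValueError("need at least 2 regions")
    return float(coh.std())


def transition_matrix(A: np.ndarray) -> np.ndarray:
    """Row-stochastic transition matrix between dominant motifs.

    Each time bin is assigned to the motif with the largest activity
    (ties resolved to the lowest index); consecutive-bin transitions are
    counted and rows normalised.  Motifs that are never dominant get a
    uniform row with a warning.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    K, n_bins = A.shape
    if K < 1 or n_bins < 2:
        raise ValueError("need K >= 1 motifs and at least 2 bins")
    assign = np.argmax(A, axis=0)
    counts = np.zeros((K, K))
    np.add.at(counts, (assign[:-1], assign[1:]), 1.0)
    sums = counts.sum(axis=1)
    empty = np.flatnonzero(sums == 0)
    if empty.size:
        warnings.warn(f"motifs never dominant: {empty.tolist()}; "
                      "uniform rows substituted")
        counts[empty] = 1.0
        sums = counts.sum(axis=1)
    return counts / sums[:, None]


def _mean_fc(binned: np.ndarray) -> float:
    """Mean absolute off-diagonal correlation of the binned signals."""
    sd = binned.std(axis=1)
    keep = binned[sd > 0]
    if keep.shape[0] < 2:
        return float("nan")
    fc = np.corrcoef(keep)
    iu = np.triu_indices_from(fc, k=1)
    return float(np.abs(fc[iu]).mean())


@dataclass
class RepertoireSummary:
    """Repertoire statistics at one timescale (bin size)."""

    bin_ms: float
    K: int
    entropy: float
    cohesiveness: np.ndarray
    hierarchy: float
    tpm: np.ndarray | None
    mean_fc: float
    probabilities: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_row(self) -> dict:
        return {"bin_ms": self.bin_ms, "K": self.K, "entropy": self.entropy,
                "hierarchy": self.hierarchy, "mean_fc": self.mean_fc}


@dataclass
class SweepResult:
    """Entropy/hierarchy curves over bin sizes plus located optima."""

    summaries: list[RepertoireSummary]
    entropy_opt_bin: float
    hierarchy_opt_bin: float
    entropy_opt_refined: float
    hierarchy_opt_refined: float
    skipped_bins: list[float] = field(default_factory=list)

    def curves(self):
        import pandas as pd

        return pd.DataFrame([s.to_row() for s in self.summaries])


def analyse_at_bin(activity: np.ndarray, bin_ms: float, theta: float = 1.0,
                   seed: int = 0, dt: float = 1.0,
                   event_rule: str = "crossing") -> RepertoireSummary:
    """Full motif extraction + repertoire metrics at one bin size."""
    ext = MotifExtractor(bin_ms=bin_ms, dt_ms=dt, theta=theta,
                         event_rule=event_rule, random_state=seed)
    ext.fit(np.asarray(activity, dtype=float).T)
    binned = bin_timeseries(activity, bin_ms, dt)
    if ext.n_motifs_ == 0:
        return RepertoireSummary(bin_ms, 0, 0.0,
                                 np.zeros(ext.weights_.shape[0]), 0.0, None,
                                 _mean_fc(binned))
    coh = cohesiveness(ext.weights_, ext.probabilities_)
    tpm = (transition_matrix(ext.activities_)
           if ext.activities_.shape[1] >= 2 else None)
    return RepertoireSummary(
        bin_ms, ext.n_motifs_, entropy(ext.probabilities_), coh,
        hierarchy(coh), tpm, _mean_fc(binned), ext.probabilities_)


def _parabolic_refine(bins: np.ndarray, values: np.ndarray, k: int) -> float:
    """Refine an argmax with a parabola through its grid neighbours (log bins)."""
    if k == 0 or k == len(bins) - 1:
        return float(bins[k])
    x = np.log(bins[k - 1:k + 2])
    y = values[k - 1:k + 2]
    denom = (y[0] - 2 * y[1] + y[2])
    if denom >= 0:  # not locally concave; keep the grid point
        return float(bins[k])
    shift = 0.5 * (y[0] - y[2]) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    xm = x[1] + shift * (x[2] - x[1] if shift > 0 else x[1] - x[0])
    return float(np.exp(xm))


def timescale_sweep(activity: np.ndarray, bin_grid, theta: float = 1.0,
                    seed: int = 0, dt: float = 1.0,
                    event_rule: str = "crossing") -> SweepResult:
    """Run the repertoire analysis across bin sizes and locate the optimum.

    ``bin_grid`` must be sorted (ms) and each entry a multiple of ``dt``;
    bin sizes leaving fewer bins than regions (q < 1) are skipped with a
    warning.  The optimum is the argmax of the entropy curve; the
    hierarchy optimum is located and reported independently, and both
    optima are additionally refined by a parabola through the three
    neighbouring grid points (on a log-bin axis).
    """
    activity = np.atleast_2d(np.asarray(activity, dtype=float))
    bin_grid = list(bin_grid)
    if sorted(bin_grid) != bin_grid:
        raise ValueError("bin_grid must be sorted ascending")
    N, T = activity.shape
    seeds = np.random.SeedSequence(seed).spawn(len(bin_grid))
    summaries, skipped = [], []
    for b, s in zip(bin_grid, seeds):
        n_bins = int(T * dt / b)
        if n_bins < N:
            skipped.append(float(b))
            warnings.warn(f"bin {b} ms leaves {n_bins} bins < {N} regions "
                          "(q < 1); skipped")
            continue
        summaries.append(analyse_at_bin(
            activity, b, theta=theta,
            seed=int(s.generate_state(1)[0] & 0x7FFFFFFF), dt=dt,
            event_rule=event_rule))
    if not summaries:
        raise ValueError("no usable bin sizes in the grid")
    bins = np.array([s.bin_ms for s in summaries])
    ent = np.array([s.entropy for s in summaries])
    hie = np.array([s.hierarchy for s in summaries])
    ke = int(np.argmax(ent))
    kh = int(np.argmax(hie))
    return SweepResult(
        summaries, float(bins[ke]), float(bins[kh]),
        _parabolic_refine(bins, ent, ke), _parabolic_refine(bins, hie, kh),
        skipped)


class TimescaleSweep(BaseEstimator):
    """Estimator wrapper: fit(X) sweeps timescales on (n_samples, n_regions) data.

    Attributes after fitting: ``summaries_``, ``entropy_opt_bin_``,
    ``hierarchy_opt_bin_``, ``result_``.
    """

    def __init__(self, bin_grid=(10, 20, 50, 100, 200, 500, 1000, 2000, 3000),
                 theta: float = 1.0, dt_ms: float = 1.0,
                 event_rule: str = "crossing", random_state=None):
        self.bin_grid = bin_grid
        self.theta = theta
        self.dt_ms = dt_ms
        self.event_rule = event_rule
        self.random_state = random_state

    def fit(self, X, y=None):
        from sklearn.utils.validation import check_array, check_random_state

        X = check_array(X, dtype=float)
        seed = check_random_state(self.random_state).randint(2 ** 31)
        res = timescale_sweep(X.T, list(self.bin_grid), theta=self.theta,
                              seed=seed, dt=self.dt_ms,
                              event_rule=self.event_rule)
        self.result_ = res
        self.summaries_ = res.summaries
        self.entropy_opt_bin_ = res.entropy_opt_bin
        self.hierarchy_opt_bin_ = res.hierarchy_opt_bin
        self.n_features_in_ = X.shape[1]
        return self
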