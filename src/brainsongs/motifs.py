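"""Spacetime-motif extraction from millisecond-scale activity.

The pipeline reduces a region x time activity matrix to a repertoire of
whole-brain co-activation patterns at a chosen timescale:

1. average the signals in non-overlapping windows of ``bin_ms`` (the
   timescale under study);
2. binarise each region's binned series into events by z-scoring and
   marking upward crossings of a threshold theta (a Poincare-section
   reduction, which is what makes the procedure threshold-insensitive);
3. z-score the event matrix row-wise (zero mean, unit variance per
   region);
4. count significant co-activation patterns as eigenvalues of the event
   covariance e e^T / N_B exceeding the Marchenko-Pastur upper bound
   lambda_max = rho^2 (1 + sqrt(1/q))^2 with q = N_B / N (rho^2 = 1 after
   z-scoring);
5. extract the patterns with FastICA on the projection onto the
   significant principal subspace, and track each pattern's activity as
   the squared projection of every time-bin column onto it.

`MotifExtractor` wraps the pipeline as a scikit-learn estimator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.validation import check_array, check_is_fitted, check_random_state

logger = logging.getLogger(__name__)

__all__ = ["EventMatrix", "MotifSet", "bin_timeseries", "threshold_crossings",
           "detect_events", "zscore_events", "mp_bounds", "count_significant",
           "extract_motifs", "motif_activity", "motif_probabilities",
           "extract_motif_set", "MotifExtractor"]


@dataclass
class EventMatrix:
    """Binary events per region per bin, plus the z-scored form."""

    binary: np.ndarray                     # N x N_B, 0/1 upward crossings
    bin_ms: float
    threshold_theta: float
    excluded_regions: list[int] = field(default_factory=list)
    zscored: np.ndarray | None = None      # rows: mean 0, population SD 1

    @property
    def n_regions(self) -> int:
        return self.binary.shape[0]

    @property
    def n_bins(self) -> int:
        return self.binary.shape[1]


@dataclass
class MotifSet:
    """Significant co-activation patterns and their temporal statistics."""

    K: int
    weights: np.ndarray            # N x K, unit-norm sign-fixed columns
    activities: np.ndarray         # K x N_B, squared projections (>= 0)
    probabilities: np.ndarray      # K, sums to 1
    eigenvalues: np.ndarray        # spectrum of e e^T / N_B, descending
    lambda_min: float
    lambda_max: float
    bin_ms: float | None = None


def bin_timeseries(x: np.ndarray, bin_ms: float, dt: float = 1.0
                   ) -> np.ndarray:
    """Average an (n_regions, n_samples) matrix in windows of ``bin_ms``.

    Windows are non-overlapping and half-open; a trailing partial window
    is dropped.  ``bin_ms`` must be an integer multiple of the sampling
    step ``dt`` (ms).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    ratio = bin_ms / dt
    per_bin = int(round(ratio))
    if per_bin < 1 or abs(ratio - per_bin) > 1e-9:
        raise ValueError(
            f"bin_ms={bin_ms} must be an integer multiple of dt={dt}")
    n_bins = x.shape[1] // per_bin
    if n_bins < 1:
        raise ValueError("signal shorter than one bin")
    return x[:, :n_bins * per_bin].reshape(x.shape[0], n_bins,
                                           per_bin).mean(axis=2)


def threshold_crossings(z: np.ndarray, theta: float) -> np.ndarray:
    """Mark upward crossings: 1 where z > theta and the previous sample <= theta.

    The state before the first sample is taken as sub-threshold, so a
    super-threshold first sample counts as a crossing.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    above = z > theta
    prev_below = np.concatenate(
        [np.ones((z.shape[0], 1), dtype=bool), ~above[:, :-1]], axis=1)
    return (above & prev_below).astype(float)


def detect_events(binned: np.ndarray, theta: float = 1.0,
                  bin_ms: float = float("nan"), rule: str = "crossing"
                  ) -> EventMatrix:
    """Binarise binned activity into point-process events.

    Each region's series is z-scored (population SD) and events are the
    upward crossings of ``theta`` (``rule="crossing"``, the default) or
    every super-threshold bin (``rule="threshold"``).  Constant regions
    cannot be z-scored and are excluded with a warning.
    """
    binned = np.atleast_2d(np.asarray(binned, dtype=float))
    sd = binned.std(axis=1)
    excluded = np.flatnonzero(sd == 0).tolist()
    if len(excluded) == binned.shape[0]:
        raise ValueError("all regions are constant; nothing to binarise")
    if excluded:
        warnings.warn(f"excluding constant regions {excluded}")
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (binned - binned.mean(axis=1, keepdims=True)) / sd_safe[:, None]
    if rule == "crossing":
        binary = threshold_crossings(z, theta)
    elif rule == "threshold":
        binary = (z > theta).astype(float)
    else:
        raise ValueError(f"unknown event rule {rule!r}")
    binary[excluded, :] = 0.0
    return EventMatrix(binary, bin_ms, theta, excluded)


def zscore_events(em: EventMatrix) -> np.ndarray:
    """Row-wise z-scoring of the event matrix (population SD).

    Rows with no events (or events everywhere) have zero variance and are
    added to ``excluded_regions``; the returned matrix keeps only the
    usable rows.  The result is stored on ``em.zscored``.
    """
    binary = em.binary
    sd = binary.std(axis=1)
    newly = [i for i in np.flatnonzero(sd == 0).tolist()
             if i not in em.excluded_regions]
    if newly:
        warnings.warn(f"excluding event-free/saturated regions {newly}")
        em.excluded_regions = sorted(em.excluded_regions + newly)
    keep = [i for i in range(em.n_regions) if i not in em.excluded_regions]
    if len(keep) < 2:
        raise ValueError("fewer than 2 regions with usable event series")
    rows = binary[keep]
    z = (rows - rows.mean(axis=1, keepdims=True)) / rows.std(
        axis=1, keepdims=True)
    em.zscored = z
    return z


def mp_bounds(q: float, rho2: float = 1.0) -> tuple[float, float]:
    """Marchenko-Pastur eigenvalue bounds rho^2 (1 +/- sqrt(1/q))^2.

    ``q`` is the bins-to-regions aspect ratio N_B / N and must be >= 1.
    """
    if q < 1:
        raise ValueError(
            f"q = {q:.3f} < 1: use more time bins or fewer regions so that "
            "N_B >= N")
    root = np.sqrt(1.0 / q)
    return rho2 * (1.0 - root) ** 2, rho2 * (1.0 + root) ** 2


def count_significant(e: np.ndarray) -> tuple[int, np.ndarray, tuple[float, float]]:
    """Number of eigenvalues of e e^T / N_B above the Marchenko-Pastur bound.

    Rows of e must be z-scored (rho^2 = 1).  The count uses a strict
    inequality at lambda_max; exact ties are not counted.  Returns
    ``(K, eigenvalues_descending, (lambda_min, lambda_max))``.
    """
    e = np.atleast_2d(np.asarray(e, dtype=float))
    N, N_B = e.shape
    bounds = mp_bounds(N_B / N)
    cov = e @ e.T / N_B
    ev = np.linalg.eigvalsh(cov)[::-1]
    K = int(np.sum(ev > bounds[1]))
    return K, ev, bounds


def extract_motifs(e: np.ndarray, K: int, seed: int = 0,
                   max_retries: int = 5, max_iter: int = 1000) -> np.ndarray:
    """Extract K motif weight vectors with ICA on the significant subspace.

    The z-scored event matrix is projected onto its top-K principal
    components; FastICA unmixes the projection, and each component is
    mapped back to region space.  Columns are unit-norm, sign-fixed so the
    largest-magnitude weight is positive, and ordered by decreasing
    activity variance.  Deterministic given ``seed``.
    """
    e = np.atleast_2d(np.asarray(e, dtype=float))
    N, N_B = e.shape
    if not 1 <= K <= N:
        raise ValueError(f"K={K} out of range for N={N}")
    cov = e @ e.T / N_B
    evals, evecs = np.linalg.eigh(cov)
    V = evecs[:, ::-1][:, :K]                      # N x K principal axes
    if K == 1:
        # a one-dimensional subspace has nothing to unmix; the motif is
        # the principal axis itself
        w = V.copy()
    else:
        proj = V.T @ e                             # K x N_B
        rng = check_random_state(seed)
        last_exc: Exception | None = None
        for attempt in range(max_retries):
            # relax tolerance progressively on restarts
            ica = FastICA(n_components=K,
                          random_state=rng.randint(2 ** 31),
                          max_iter=max_iter * (1 + attempt),
                          tol=1e-4 * 10 ** min(attempt, 2),
                          whiten="unit-variance")
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                try:
                    ica.fit(proj.T)
                except ConvergenceWarning as exc:
                    last_exc = exc
                    continue
            break
        else:
            raise RuntimeError(
                f"FastICA failed to converge after {max_retries} restarts: "
                f"{last_exc}")
        w = V @ ica.mixing_                        # back to region space
    w /= np.linalg.norm(w, axis=0, keepdims=True)
    # sign convention: dominant weight positive
    idx = np.argmax(np.abs(w), axis=0)
    signs = np.sign(w[idx, np.arange(w.shape[1])])
    signs[signs == 0] = 1.0
    w = w * signs
    order = np.argsort(-((w.T @ e) ** 2).sum(axis=1))
    return w[:, order]


def motif_activity(e: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Squared projection of each time-bin column onto each motif.

    A_cb = (w_c . e_b)^2 = e_b^T (w_c w_c^T) e_b; nonnegative by
    construction.  ``weights`` columns must be unit-norm.
    """
    e = np.atleast_2d(np.asarray(e, dtype=float))
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    if weights.shape[0] != e.shape[0]:
        raise ValueError(
            f"weights rows {weights.shape[0]} != regions {e.shape[0]}")
    norms = np.linalg.norm(weights, axis=0)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("weight columns must be unit-norm")
    return (weights.T @ e) ** 2


def motif_probabilities(A: np.ndarray) -> np.ndarray:
    """Activation probability of each motif: p(c) = sum_b A_cb / sum_cb A_cb."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if np.any(A < 0):
        raise ValueError("activities must be nonnegative")
    total = A.sum()
    if total <= 0:
        raise ValueError("all-zero activity matrix")
    return A.sum(axis=1) / total


def extract_motif_set(e: np.ndarray, seed: int = 0,
                      bin_ms: float | None = None) -> MotifSet:
    """Full significance + extraction pass on a z-scored event matrix."""
    K, ev, (lo, hi) = count_significant(e)
    N, N_B = np.atleast_2d(e).shape
    if K == 0:
        return MotifSet(0, np.empty((N, 0)), np.empty((0, N_B)),
                        np.empty(0), ev, lo, hi, bin_ms)
    w = extract_motifs(e, K, seed=seed)
    A = motif_activity(e, w)
    p = motif_probabilities(A)
    return MotifSet(K, w, A, p, ev, lo, hi, bin_ms)


class MotifExtractor(BaseEstimator, TransformerMixin):
    """Scikit-learn estimator for spacetime-motif extraction.

    Parameters
    ----------
    bin_ms : float
        Timescale: width of the averaging window in ms.
    dt_ms : float
        Sampling step of the input activity in ms.
    theta : float
        Event threshold in SD units of the binned series.
    event_rule : {"crossing", "threshold"}
        Upward-crossing events (default) or plain super-threshold bins.
    random_state : int, RandomState or None
        Seeds the ICA step.

    Attributes
    ----------
    n_motifs_ : int
        Number of significant components K.
    weights_ : ndarray of shape (n_kept_regions, K)
    activities_ : ndarray of shape (K, n_bins)
    probabilities_ : ndarray of shape (K,)
    eigenvalues_ : ndarray
        Spectrum of the event covariance, descending.
    mp_bounds_ : (float, float)
        Marchenko-Pastur (lambda_min, lambda_max).
    event_matrix_ : EventMatrix
    excluded_regions_ : list of int

    Notes
    -----
    ``fit`` follows the scikit-learn orientation: X has shape
    (n_samples, n_regions) with time along the first axis.
    """

    def __init__(self, bin_ms: float = 200.0, dt_ms: float = 1.0,
                 theta: float = 1.0, event_rule: str = "crossing",
                 random_state=None):
        self.bin_ms = bin_ms
        self.dt_ms = dt_ms
        self.theta = theta
        self.event_rule = event_rule
        self.random_state = random_state

    def _pipeline(self, X):
        activity = check_array(X, dtype=float).T  # regions x time
        binned = bin_timeseries(activity, self.bin_ms, self.dt_ms)
        em = detect_events(binned, self.theta, self.bin_ms, self.event_rule)
        e = zscore_events(em)
        return em, e

    def fit(self, X, y=None):
        em, e = self._pipeline(X)
        seed = check_random_state(self.random_state).randint(2 ** 31)
        ms = extract_motif_set(e, seed=seed, bin_ms=self.bin_ms)
        self.event_matrix_ = em
        self.excluded_regions_ = em.excluded_regions
        self.n_motifs_ = ms.K
        self.weights_ = ms.weights
        self.activities_ = ms.activities
        self.probabilities_ = ms.probabilities
        self.eigenvalues_ = ms.eigenvalues
        self.mp_bounds_ = (ms.lambda_min, ms.lambda_max)
        self.motif_set_ = ms
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Motif activities of (possibly new) activity data, shape (n_bins, K)."""
        check_is_fitted(self, "weights_")
        _, e = self._pipeline(X)
        if e.shape[0] != self.weights_.shape[0]:
            raise ValueError("region count differs from the fitted data")
        if self.n_motifs_ == 0:
            return np.empty((e.shape[1], 0))
        return motif_activity(e, self.weights_).T

    def fit_transform(self, X, y=None, **fit_params):
        self.fit(X)
        return self.activities_.T
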