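"""Structural connectome container and delimited-text I/O."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_SYMMETRY_TOL = 1e-9


@dataclass
class StructuralConnectome:
    """Symmetric nonnegative coupling matrix C_ij between brain regions.

    The entries represent the density of anatomical fibres connecting
    regions i and j; the diagonal is zero (no self-coupling) and the
    matrix is symmetric within 1e-9.
    """

    weights: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not self.region_labels:
            self.region_labels = [f"R{i}" for i in range(self.weights.shape[0])]
        self.validate()

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def validate(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"connectome must be square, got shape {w.shape}")
        if w.shape[0] < 2:
            raise ValueError("connectome needs at least 2 regions")
        if not np.all(np.isfinite(w)):
            raise ValueError("connectome contains non-finite weights")
        if np.any(w < 0):
            raise ValueError("connectome weights must be nonnegative")
        if np.max(np.abs(w - w.T)) > _SYMMETRY_TOL:
            raise ValueError(
                "connectome is asymmetric beyond tolerance; "
                "load with symmetrise=True to average C and C.T"
            )
        if np.any(np.abs(np.diag(w)) > 0):
            raise ValueError("connectome diagonal must be zero")
        if len(self.region_labels) != w.shape[0]:
            raise ValueError("region_labels length does not match matrix size")

    def permuted(self, order: np.ndarray) -> "StructuralConnectome":
        order = np.asarray(order)
        return StructuralConnectome(
            self.weights[np.ix_(order, order)],
            [self.region_labels[i] for i in order],
        )

    def to_file(self, path, delimiter: str = "\t") -> None:
        header = delimiter.join(self.region_labels)
        np.savetxt(path, self.weights, delimiter=delimiter, header=header, comments="")

    @classmethod
    def from_file(cls, path, delimiter: str = "\t", symmetrise: bool = False
                  ) -> "StructuralConnectome":
        """Load a connectome from delimited text (header of labels, N x N body).

        With ``symmetrise=True`` an asymmetric matrix is replaced by
        (C + C.T)/2 with a logged warning, mirroring the usual averaging of
        the two tract directions.
        """
        with open(path) as fh:
            labels = fh.readline().strip().split(delimiter)
        w = np.loadtxt(path, delimiter=delimiter, skiprows=1, ndmin=2)
        if symmetrise and np.max(np.abs(w - w.T)) > _SYMMETRY_TOL:
            logger.warning("symmetrising asymmetric connectome from %s", path)
            w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        return cls(w, labels)
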