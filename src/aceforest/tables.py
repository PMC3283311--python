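"""2x2 edge weight tables: construction, lookup, and green/red classification.

A weight table assigns a non-negative cost to each ordered label pair
(0,0), (0,1), (1,0), (1,1) at the two ends of an edge.  Tree-edge tables
are indexed (parent label, child label); co-evolution tables are indexed
(lower tree index, higher tree index).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, DegenerateTableError

__all__ = [
    "WeightTable",
    "GREEN_TABLE",
    "RED_TABLE",
    "classify_edge",
    "table_from_joint",
]

_EPS = 1e-9


@dataclass(frozen=True)
class WeightTable:
    """Costs for the four ordered label pairs at an edge's ends.

    Parameters
    ----------
    w00, w01, w10, w11 : float
        Non-negative, finite costs for label pairs (0,0), (0,1), (1,0), (1,1).
    """

    w00: float
    w01: float
    w10: float
    w11: float

    def __post_init__(self) -> None:
        for name in ("w00", "w01", "w10", "w11"):
            v = getattr(self, name)
            if not (v >= 0.0 and math.isfinite(v)):
                raise ContractError(f"weight {name}={v!r} must be finite and >= 0")

    def lookup(self, x: int, y: int) -> float:
        """Cost of the ordered label pair ``(x, y)``, x, y in {0, 1}."""
        if x not in (0, 1) or y not in (0, 1):
            raise ContractError(f"labels must be 0/1, got ({x}, {y})")
        return self.as_array()[x, y]

    def as_array(self) -> np.ndarray:
        """The table as a 2x2 float array indexed ``[first, second]``."""
        return np.array([[self.w00, self.w01], [self.w10, self.w11]], dtype=float)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.w00, self.w01, self.w10, self.w11)

    @property
    def is_green_form(self) -> bool:
        """True for tables exactly of the form (0, a, a, 0)."""
        return self.w00 == 0.0 and self.w11 == 0.0 and self.w01 == self.w10

    @property
    def is_red_form(self) -> bool:
        """True for tables exactly of the form (a, 0, 0, a)."""
        return self.w01 == 0.0 and self.w10 == 0.0 and self.w00 == self.w11


#: Unit cost for a label change, zero for agreement (Fitch-style).
GREEN_TABLE = WeightTable(0.0, 1.0, 1.0, 0.0)
#: Unit cost for label agreement, zero for a change (anti-correlated).
RED_TABLE = WeightTable(1.0, 0.0, 0.0, 1.0)


def _to_distribution(table: WeightTable, eps: float = _EPS) -> np.ndarray:
    # p propto exp(-w): inverts the -log joint construction of table_from_joint.
    p = np.exp(-table.as_array().ravel())
    total = p.sum()
    if total <= 0.0 or not np.isfinite(total):
        raise DegenerateTableError(f"table {table.as_tuple()} has no probability mass")
    p = p / total
    p = np.maximum(p, eps)
    return p / p.sum()


def classify_edge(table: WeightTable) -> str:
    """Classify a table as ``'green'`` (correlated) or ``'red'`` (anti-correlated).

    The table and the canonical green (0,1,1,0) / red (1,0,0,1) tables are
    converted to distributions via p ∝ exp(-w); the class whose canonical
    distribution is nearer in KL divergence wins.  Ties go to green.
    """
    p = _to_distribution(table)
    kl_green = _kl(p, _to_distribution(GREEN_TABLE))
    kl_red = _kl(p, _to_distribution(RED_TABLE))
    return "green" if kl_green <= kl_red else "red"


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.sum(p * np.log(p / q)))


def table_from_joint(joint_counts, eps: float = _EPS) -> WeightTable:
    """Build a weight table as -log of the smoothed empirical joint distribution.

    Parameters
    ----------
    joint_counts : array-like of shape (2, 2)
        Non-negative counts; ``joint_counts[x][y]`` counts co-occurrences of
        label x (first variable) with label y (second variable).
    eps : float
        Additive smoothing applied to every cell before normalization, so
        zero cells map to a large finite cost.
    """
    counts = np.asarray(joint_counts, dtype=float)
    if counts.shape != (2, 2):
        raise ContractError(f"joint counts must be 2x2, got shape {counts.shape}")
    if (counts < 0).any():
        raise ContractError("joint counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise DegenerateTableError("all-zero joint counts")
    p = (counts + eps) / (total + 4 * eps)
    w = -np.log(p)
    return WeightTable(w[0, 0], w[0, 1], w[1, 0], w[1, 1])
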