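"""Solver result container shared by exact solvers, reductions, and heuristics."""

from __future__ import annotations

from dataclasses import dataclass, field

from .forest import FullLabeling


@dataclass
class SolveResult:
    """Outcome of a labeling solver.

    Attributes
    ----------
    labeling : FullLabeling or None
        The returned assignment; ``None`` only for fractional LP relaxations.
    cost : float
        Achieved total weight; equals ``ace_score(forest, labeling)`` when a
        labeling is present.
    optimal : bool
        Whether the solver proves global optimality.
    lower_bound : float or None
        A certified lower bound on the optimum, when available.
    method : str
        Identifier of the producing algorithm.
    info : dict
        Solver-specific metadata (iteration counts, warnings, sub-costs).
    """

    labeling: FullLabeling | None
    cost: float
    optimal: bool
    method: str
    lower_bound: float | None = None
    info: dict = field(default_factory=dict)
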