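"""Per-population secretion deconvolution by median over replicate triples.

Cultures contain three cell populations — DN (CD11b-CD14-), SP
(CD11b-CD14+) and DP (CD11b+CD14+, the in-vitro-differentiated TEM) — whose
bulk secretion is measured together.  For one (cytokine, treatment) pair,
each biological replicate i contributes one linear equation

    Ca * Na_i + Cb * Nb_i + Cc * Nc_i = K_i

with Na/Nb/Nc the population fractions (from cytofluorimetry, summing to 1)
and K the bulk percent-of-untreated secretion change.  The three per-
population contributions Ca/Cb/Cc are recovered by solving the exact 3x3
system of every replicate triple (C(n,3) systems, 4 at n=4 up to 84 at
n=9), and taking the per-coefficient median across the solved triples.
Ill-conditioned triples are skipped; the median over the remaining triples
supplies robustness to outlying replicates.  A contribution that comes out
below the 1% floor is clamped to it (a secretion cannot be negative).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "POPULATIONS",
    "DeconvolutionConfig",
    "PopulationContribution",
    "DegenerateDataError",
    "enumerate_replicate_triples",
    "solve_triple",
    "deconvolve_contributions",
    "TripleMedianDeconvolver",
]

POPULATIONS = ("DN", "SP", "DP")

_TRIPLE_SIZE = 3


class DegenerateDataError(ValueError):
    """All replicate triples were singular: no contribution can be inferred."""


class InsufficientDataError(ValueError):
    """Fewer than three replicates with both composition and measurement."""


@dataclass(frozen=True)
class DeconvolutionConfig:
    """Numerical policy for the triple solver.

    clamp_floor:
        Minimal reported contribution in percent units (default 1, i.e. the
        1% floor applied to inferred amounts below zero).
    condition_limit:
        Triples whose composition matrix condition number exceeds this are
        flagged singular and skipped.
    """

    clamp_floor: float = 1.0
    condition_limit: float = 1e8
    triple_size: int = _TRIPLE_SIZE

    def __post_init__(self) -> None:
        if self.clamp_floor <= 0:
            raise ValueError("clamp_floor must be positive")
        if self.triple_size != _TRIPLE_SIZE:
            raise ValueError("the replicate-triple design is fixed at 3")


@dataclass(frozen=True)
class PopulationContribution:
    """Inferred per-population contributions for one (cytokine, treatment)."""

    ca: float
    cb: float
    cc: float
    n_systems_solved: int
    clamped: frozenset[str] = field(default_factory=frozenset)
    spread: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.ca, self.cb, self.cc], dtype=float)


def enumerate_replicate_triples(n_replicates: int) -> list[tuple[int, int, int]]:
    """All C(n, 3) unordered index triples, in lexicographic order."""
    if n_replicates < _TRIPLE_SIZE:
        raise InsufficientDataError(
            f"need at least 3 replicates to solve a triple; got {n_replicates}"
        )
    return list(itertools.combinations(range(n_replicates), _TRIPLE_SIZE))


def solve_triple(
    compositions: np.ndarray,
    measurements: np.ndarray,
    config: DeconvolutionConfig | None = None,
) -> np.ndarray | None:
    """Solve one 3x3 system exactly; ``None`` flags a singular triple."""
    config = config or DeconvolutionConfig()
    matrix = np.asarray(compositions, dtype=float)
    rhs = np.asarray(measurements, dtype=float)
    if matrix.shape != (3, 3) or rhs.shape != (3,):
        raise ValueError("solve_triple expects a 3x3 composition matrix and 3 measurements")
    if np.linalg.cond(matrix) > config.condition_limit:
        return None
    return np.linalg.solve(matrix, rhs)


class TripleMedianDeconvolver(BaseEstimator):
    """Median-of-replicate-triples estimator of per-population contributions.

    Parameters
    ----------
    clamp_floor:
        Minimal reported contribution (percent), default 1.
    condition_limit:
        Condition-number bound above which a triple is skipped as singular.
    validate_fractions:
        Require composition rows to be non-negative and sum to 1 (1e-6
        tolerance).

    Attributes (after ``fit``)
    --------------------------
    contributions_:
        Array (3,) of clamped median contributions, ordered DN, SP, DP.
    raw_contributions_:
        Medians before the floor clamp.
    solutions_:
        Array (n_solved, 3) of all non-singular triple solutions.
    n_systems_solved_:
        Number of non-singular triples.
    clamped_:
        Frozenset of population labels whose contribution hit the floor.
    spread_:
        Per-population interquartile range of the triple solutions (the raw
        dispersion; exported, not modelled).
    """

    def __init__(
        self,
        clamp_floor: float = 1.0,
        condition_limit: float = 1e8,
        validate_fractions: bool = True,
    ):
        self.clamp_floor = clamp_floor
        self.condition_limit = condition_limit
        self.validate_fractions = validate_fractions

    def _config(self) -> DeconvolutionConfig:
        return DeconvolutionConfig(clamp_floor=self.clamp_floor, condition_limit=self.condition_limit)

    def fit(self, X, y):
        """Infer contributions from compositions ``X`` (n, 3) and bulk ``y`` (n,)."""
        config = self._config()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (n_replicates, 3) population fractions (DN, SP, DP)")
        if y.shape != (X.shape[0],):
            raise ValueError("y must hold one bulk measurement per replicate")
        if self.validate_fractions:
            if (X < 0).any():
                raise ValueError("population fractions must be non-negative")
            sums = X.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError("population fractions must sum to 1 (tolerance 1e-6)")
        triples = enumerate_replicate_triples(X.shape[0])

        solutions = []
        for triple in triples:
            solution = solve_triple(X[list(triple)], y[list(triple)], config)
            if solution is not None:
                solutions.append(solution)
        if not solutions:
            raise DegenerateDataError("every replicate triple was singular")
        self.solutions_ = np.array(solutions, dtype=float)
        self.n_systems_solved_ = len(solutions)
        self.raw_contributions_ = np.median(self.solutions_, axis=0)
        clamped_mask = self.raw_contributions_ < config.clamp_floor
        self.contributions_ = np.where(clamped_mask, config.clamp_floor, self.raw_contributions_)
        self.clamped_ = frozenset(
            label for label, flag in zip(POPULATIONS, clamped_mask) if flag
        )
        q75, q25 = np.percentile(self.solutions_, [75, 25], axis=0)
        self.spread_ = q75 - q25
        return self

    def predict(self, X):
        """Reconstructed bulk measurements for compositions ``X``."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "contributions_")
        return np.asarray(X, dtype=float) @ self.contributions_

    def result_(self) -> PopulationContribution:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "contributions_")
        return PopulationContribution(
            ca=float(self.contributions_[0]),
            cb=float(self.contributions_[1]),
            cc=float(self.contributions_[2]),
            n_systems_solved=self.n_systems_solved_,
            clamped=self.clamped_,
            spread=tuple(float(v) for v in self.spread_),
        )


def deconvolve_contributions(
    measurements: Sequence[float],
    compositions: np.ndarray,
    config: DeconvolutionConfig | None = None,
) -> PopulationContribution:
    """Functional wrapper around :class:`TripleMedianDeconvolver`."""
    config = config or DeconvolutionConfig()
    estimator = TripleMedianDeconvolver(
        clamp_floor=config.clamp_floor, condition_limit=config.condition_limit
    )
    estimator.fit(np.asarray(compositions, dtype=float), np.asarray(measurements, dtype=float))
    return estimator.result_()
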