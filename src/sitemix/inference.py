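"""Naive Markov re-inference of the generator, and substitution flux fractions.

If pairwise data generated by the ensemble dynamics are analyzed as if they
were Markovian, the apparent generator is

    Qtilde = log(Ptilde(t_true)) / t_assumed

where ``t_assumed`` is the (shorter) time a Markov observer would infer —
by convention the time at which the Markov dynamics reaches the same
expected identity as the ensemble one.  The resulting ``Qtilde`` acquires
spurious rate between states several nucleotide changes apart.  The flux
fractions

    f_k = sum_{(i,j) in class k} pi_i |Q_ij|  /  sum_{j != i} pi_i |Q_ij|

measure that: a mechanistic single-nucleotide-change model has
``f2 = f3 = 0`` exactly, while the re-inferred ``Qtilde`` does not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import scipy.linalg

from .models import RateMatrix
from .propagate import TransitionMatrix
from .statespace import DiffClassPartition, StateSpace

__all__ = [
    "InferredRateMatrix",
    "FractionReport",
    "InferenceError",
    "infer_q_markov",
    "substitution_fractions",
]


class InferenceError(ValueError):
    pass


@dataclass(frozen=True)
class InferredRateMatrix:
    """Apparent generator recovered under the (false) Markov assumption.

    Unlike a true generator, ``Qtilde`` may carry small negative
    off-diagonal entries — an artifact of taking the logarithm of a
    non-Markovian transition matrix.  They are retained as-is;
    ``max_imag_residue`` records the largest imaginary component discarded
    from the principal matrix logarithm.
    """

    space: StateSpace
    Qtilde: np.ndarray
    t_true: float
    t_assumed: float
    max_imag_residue: float

    def __post_init__(self):
        Qt = np.asarray(self.Qtilde, dtype=float)
        rs = np.abs(Qt.sum(axis=1)).max()
        if rs > 1e-8 * max(1.0, np.abs(Qt).max()):
            raise InferenceError(f"rows of Qtilde do not sum to zero (max {rs:g})")
        if self.max_imag_residue > 1e-9:
            raise InferenceError(
                f"imaginary residue {self.max_imag_residue:g} of the matrix "
                "logarithm exceeds 1e-9"
            )
        object.__setattr__(self, "Qtilde", Qt)

    @property
    def min_off_diagonal(self) -> float:
        n = self.space.N
        return float(self.Qtilde[~np.eye(n, dtype=bool)].min())


def infer_q_markov(Pe: TransitionMatrix, t_assumed: float) -> InferredRateMatrix:
    """Recover the apparent generator ``log(Pe) / t_assumed``.

    ``Pe`` is typically an ensemble average ``Ptilde(t_true)``; passing a
    genuine Markov ``P(t)`` with ``t_assumed = t`` recovers the original
    generator exactly (up to round-off).  The principal logarithm requires
    the spectrum of ``Pe`` to avoid the closed negative real axis.
    """
    if t_assumed <= 0:
        raise InferenceError("t_assumed must be positive")
    w = np.linalg.eigvals(Pe.P)
    real_axis = np.abs(w.imag) < 1e-12
    if np.any(w.real[real_axis] <= 0):
        raise InferenceError(
            "principal matrix logarithm undefined: transition matrix has a "
            f"non-positive real eigenvalue (spectrum: {np.sort(w.real)[:3]} ...)"
        )
    L = scipy.linalg.logm(Pe.P)
    resid = float(np.abs(L.imag).max()) if np.iscomplexobj(L) else 0.0
    return InferredRateMatrix(
        space=Pe.space,
        Qtilde=L.real / t_assumed,
        t_true=Pe.time,
        t_assumed=float(t_assumed),
        max_imag_residue=resid,
    )


@dataclass(frozen=True)
class FractionReport:
    """Share of stationary substitution flux by nucleotide-difference class.

    ``f1 + f2 + f3 == 1``: the off-diagonal flux partitions into single,
    double and triple classes.  Computed on absolute flux so it stays
    well-defined for re-inferred matrices with small negative entries.
    """

    f1: float
    f2: float
    f3: float
    matrix_id: str = ""

    def __post_init__(self):
        if min(self.f1, self.f2, self.f3) < 0:
            raise InferenceError("fractions must be non-negative")
        if abs(self.f1 + self.f2 + self.f3 - 1) > 1e-9:
            raise InferenceError("fractions must sum to 1")

    def as_dict(self) -> dict:
        return {"f1": self.f1, "f2": self.f2, "f3": self.f3, "matrix_id": self.matrix_id}


def substitution_fractions(
    Q: Union[RateMatrix, InferredRateMatrix],
    partition: Optional[DiffClassPartition] = None,
    pi: Optional[np.ndarray] = None,
    matrix_id: Optional[str] = None,
) -> FractionReport:
    """Flux fractions ``f1, f2, f3`` of a (possibly re-inferred) rate matrix.

    ``pi`` defaults to the generator's own stationary distribution for a
    :class:`RateMatrix` and must be supplied for an
    :class:`InferredRateMatrix`.  Normalization of ``Q`` cancels in the
    ratios.
    """
    if isinstance(Q, RateMatrix):
        M, space = Q.Q, Q.space
        if pi is None:
            pi = Q.pi
        mid = matrix_id if matrix_id is not None else Q.name
    else:
        M, space = Q.Qtilde, Q.space
        if pi is None:
            raise InferenceError("pi must be supplied for an inferred matrix")
        mid = matrix_id if matrix_id is not None else "Qtilde"
    if partition is None:
        partition = DiffClassPartition.for_space(space)
    if partition.space.labels != space.labels:
        raise InferenceError("partition does not match the matrix state space")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (space.N,):
        raise InferenceError("pi does not match the state space")
    flux = np.abs(pi[:, None] * M)
    off = ~np.eye(space.N, dtype=bool)
    total = flux[off].sum()
    if total <= 0:
        raise InferenceError("matrix has zero off-diagonal flux")
    f = {k: float(flux[off & partition.mask(k)].sum() / total) for k in (1, 2, 3)}
    return FractionReport(f1=f[1], f2=f[2], f3=f[3], matrix_id=mid)
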