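"""Diagnostics of the Markov assumption under among-site rate variability.

Four probes, all operating on the propagators from :mod:`sitemix.propagate`:

* expected sequence identity ``sum_i pi_i P_ii(t)`` and its inverse (the
  time at which a model reaches a target identity) — the ensemble dynamics
  keeps a higher identity than the Markov one at equal time, i.e. the
  Markov assumption underestimates evolutionary distances;
* entry-by-entry comparison of a Markov and an ensemble transition matrix,
  stratified by the nucleotide-difference class of each state pair — at
  matched identity the ensemble dynamics enhances double and triple
  substitutions;
* a Chapman-Kolmogorov test: a genuine Markov propagator satisfies
  ``P(t) = [P(t0)]^(t/t0)``, an ensemble average does not;
* the Kemeny-Snell lumpability criterion on the rate-expanded chain
  (rate class x state), whose violation is the structural reason for the
  above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.optimize import brentq

from .models import RateMatrix
from .propagate import (
    DiscreteRateMixture,
    PropagateError,
    RateLaw,
    TransitionMatrix,
    propagate,
)
from .statespace import DiffClassPartition

__all__ = [
    "ComparisonTable",
    "CKReport",
    "DiagnosticsError",
    "expected_identity",
    "expected_identity_aa",
    "time_for_identity",
    "compare_matrices",
    "ck_deviation",
    "lumpability_deviation",
]


class DiagnosticsError(ValueError):
    pass


def expected_identity(P: TransitionMatrix, pi: Optional[np.ndarray] = None) -> float:
    """Expected fraction of unchanged sites at stationarity, ``sum_i pi_i P_ii``."""
    if pi is None:
        if P.model_ref is None:
            raise DiagnosticsError("pi not given and P carries no model reference")
        pi = P.model_ref[0].pi
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (P.space.N,):
        raise DiagnosticsError("pi does not match the state space of P")
    return float(pi @ np.diag(P.P))


def expected_identity_aa(P: TransitionMatrix, pi: Optional[np.ndarray] = None) -> float:
    """Amino-acid-level identity induced by a codon transition matrix.

    Counts a site as unchanged when ancestral and descendant codons code for
    the same amino acid: ``sum_i pi_i sum_{j: aa(j)=aa(i)} P_ij``.
    """
    sp = P.space
    if sp.kind != "codon":
        raise DiagnosticsError("amino-acid identity requires a codon-space matrix")
    if pi is None:
        pi = P.model_ref[0].pi
    aa = np.array([sp.code[c] for c in sp.labels])
    same = aa[:, None] == aa[None, :]
    return float(np.asarray(pi) @ (P.P * same).sum(axis=1))


def time_for_identity(
    Q: RateMatrix,
    target: float,
    rate_law: RateLaw = None,
    t_max: float = 50.0,
    tol: float = 1e-10,
) -> float:
    """Time at which the (Markov or ensemble) dynamics reaches a target identity.

    The expected identity decreases monotonically from 1 at t=0 towards
    ``sum_i pi_i^2`` for reversible models, so the root is unique; it is
    found by bracketed root search to ``|identity - target| < tol``.
    """
    floor = float((Q.pi ** 2).sum())
    if not (floor < target < 1.0):
        raise DiagnosticsError(
            f"target identity {target} outside the attainable range ({floor:.6g}, 1)"
        )

    def f(t: float) -> float:
        return expected_identity(propagate(Q, t, rate_law), Q.pi) - target

    hi = 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > t_max:
            raise DiagnosticsError(
                f"identity {target} not reached by t={t_max} "
                f"(asymptotic identity is {floor:.6g})"
            )
    t = brentq(f, 0.0, hi, xtol=1e-14, rtol=8.9e-16)
    if abs(f(t)) > tol:
        raise DiagnosticsError(f"root search residual {abs(f(t)):g} exceeds {tol:g}")
    return float(t)


@dataclass(frozen=True)
class ComparisonTable:
    """Per-pair comparison of a Markov and an ensemble transition matrix.

    ``table`` has one row per ordered state pair with columns
    ``state_i, state_j, diff_class, p_markov, p_ensemble, ratio``
    (``ratio = p_markov / p_ensemble``); ``per_class`` summarizes each
    class with its pair count and the geometric mean ratio (structural
    zeros excluded).
    """

    table: pd.DataFrame
    per_class: pd.DataFrame
    times: tuple

    def ratio(self, i: str, j: str) -> float:
        sel = (self.table["state_i"] == i) & (self.table["state_j"] == j)
        return float(self.table.loc[sel, "ratio"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def compare_matrices(
    Pm: TransitionMatrix,
    Pe: TransitionMatrix,
    partition: Optional[DiffClassPartition] = None,
) -> ComparisonTable:
    """Entry-by-entry comparison of Markov vs ensemble probabilities by class."""
    if Pm.space is not Pe.space and Pm.space.labels != Pe.space.labels:
        raise DiagnosticsError("transition matrices live on different state spaces")
    if partition is None:
        partition = DiffClassPartition.for_space(Pm.space)
    labels = Pm.space.labels
    n = len(labels)
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    pm = Pm.P.ravel()
    pe = Pe.P.ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pe > 0, pm / pe, np.nan)
    table = pd.DataFrame({
        "state_i": np.array(labels)[ii.ravel()],
        "state_j": np.array(labels)[jj.ravel()],
        "diff_class": partition.classes.ravel(),
        "p_markov": pm,
        "p_ensemble": pe,
        "ratio": ratio,
    })
    rows = []
    for k, grp in table.groupby("diff_class"):
        ok = (grp["p_markov"] > 0) & (grp["p_ensemble"] > 0)
        gm = float(np.exp(np.log(grp.loc[ok, "ratio"]).mean())) if ok.any() else np.nan
        rows.append({"diff_class": k, "n_pairs": len(grp), "geom_mean_ratio": gm})
    per_class = pd.DataFrame(rows).set_index("diff_class")
    return ComparisonTable(table=table, per_class=per_class, times=(Pm.time, Pe.time))


@dataclass(frozen=True)
class CKReport:
    """Chapman-Kolmogorov test summary.

    Compares the propagator at time ``t`` with the matrix power
    ``[P(t0)]^(t/t0)``; for a Markov propagator the two coincide.
    ``frob_to_markov``/``frob_to_ensemble`` are the Frobenius distances of
    the power to the pure-Markov ``P(t)`` and to the ensemble ``Ptilde(t)``
    — for small ``t0`` the power behaves like a Markov propagator for a
    slightly perturbed generator, so it lands much closer to the former.
    """

    t: float
    t0: float
    max_abs_dev: float
    frob_to_markov: float
    frob_to_ensemble: float
    per_class_mean_log_ratio: pd.Series
    power: np.ndarray

    @property
    def markovian(self) -> bool:
        return self.max_abs_dev < 1e-9


def _principal_power(P: np.ndarray, exponent: float) -> np.ndarray:
    """``P^exponent`` through the principal matrix logarithm."""
    w = np.linalg.eigvals(P)
    if np.any(w.real <= 0) and np.any(np.abs(w.imag) < 1e-12):
        bad = w[(w.real <= 0) & (np.abs(w.imag) < 1e-12)]
        raise DiagnosticsError(
            f"principal matrix logarithm undefined: eigenvalue(s) {bad} on the "
            "closed negative real axis"
        )
    L = scipy.linalg.logm(P)
    resid = float(np.abs(L.imag).max()) if np.iscomplexobj(L) else 0.0
    if resid > 1e-9:
        raise DiagnosticsError(f"matrix logarithm has imaginary residue {resid:g} > 1e-9")
    return scipy.linalg.expm(exponent * L.real)


def ck_deviation(
    Q: RateMatrix,
    rate_law: RateLaw,
    t: float,
    t0: float,
    partition: Optional[DiffClassPartition] = None,
) -> CKReport:
    """Quantify the Chapman-Kolmogorov violation of an ensemble propagator.

    Builds ``Ptilde(t0)``, raises it to the power ``t/t0`` via the principal
    logarithm, and reports the maximal absolute deviation from ``Ptilde(t)``
    together with Frobenius distances of the power to the Markov ``P(t)``
    and to ``Ptilde(t)``.  With a point-mass rate law the deviation vanishes
    to numerical tolerance.
    """
    if t0 <= 0 or t <= 0:
        raise DiagnosticsError("t and t0 must be positive")
    Pe_t0 = propagate(Q, t0, rate_law)
    Pe_t = propagate(Q, t, rate_law)
    Pm_t = propagate(Q, t, None)
    power = _principal_power(Pe_t0.P, t / t0)
    dev = np.abs(power - Pe_t.P)
    if partition is None:
        partition = DiffClassPartition.for_space(Q.space)
    with np.errstate(divide="ignore", invalid="ignore"):
        logratio = np.log(power / Pe_t.P)
    rows = {}
    for k in np.unique(partition.classes):
        m = (partition.classes == k) & np.isfinite(logratio)
        rows[int(k)] = float(logratio[m].mean()) if m.any() else np.nan
    return CKReport(
        t=float(t),
        t0=float(t0),
        max_abs_dev=float(dev.max()),
        frob_to_markov=float(np.linalg.norm(power - Pm_t.P)),
        frob_to_ensemble=float(np.linalg.norm(power - Pe_t.P)),
        per_class_mean_log_ratio=pd.Series(rows, name="mean_log_ratio"),
        power=power,
    )


def lumpability_deviation(Q: RateMatrix, mix: DiscreteRateMixture, dt: float) -> float:
    """Kemeny-Snell lumpability deviation of the rate-expanded chain.

    The full chain lives on pairs (rate class, state); one step of duration
    ``dt`` is block-diagonal in the rate class with blocks ``exp(r_c dt Q)``.
    Lumping states across rate classes is admissible only if, for every
    target state, the transition probability is the same from every source
    rate class.  Returns the maximal spread
    ``max_{i,j} (max_c - min_c) [exp(r_c dt Q)]_ij``, which is 0 exactly
    when all rate classes coincide and O(dt) otherwise.
    """
    if dt <= 0:
        raise DiagnosticsError("dt must be positive")
    blocks = np.stack([scipy.linalg.expm(r * dt * Q.Q) for r in mix.rates])
    spread = blocks.max(axis=0) - blocks.min(axis=0)
    return float(spread.max())
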