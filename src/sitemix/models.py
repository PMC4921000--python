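"""Instantaneous substitution matrices (generators).

Builds, normalizes and round-trips the rate matrices the rest of the package
propagates: the mechanistic M0 codon model (kappa/omega/codon frequencies,
single-nucleotide changes only), empirical matrices read from PAML-style
exchangeability files (WAG and relatives) or dense labeled TSV, and a small
3-state toy generator used in worked examples.

Time units: every normalized generator has unit stationary substitution flux,
sum_i sum_{j!=i} pi_i Q_ij = 1, so time is measured in expected substitutions
per site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .statespace import (
    AA_ORDER,
    PAML_AA_ORDER,
    StateSpace,
    StateSpaceError,
    amino_acid_space,
    codon_space,
    generic_space,
    is_transition,
)

__all__ = [
    "RateMatrix",
    "M0Params",
    "ModelError",
    "build_m0",
    "stationary",
    "normalize",
    "toy_three_state",
    "load_empirical",
    "load_dense",
    "write_dense",
    "load_freqs",
    "write_freqs",
    "uniform_codon_freqs",
    "wag_path",
]

_GEN_TOL = 1e-10
_FLOAT_FMT = "%.12g"


class ModelError(ValueError):
    """Raised for invalid generators or malformed matrix files."""


@dataclass(frozen=True)
class RateMatrix:
    """A continuous-time Markov generator with its stationary distribution.

    Invariants (checked on construction): off-diagonal entries non-negative,
    rows sum to zero, ``pi`` is a probability vector in the left null space
    of ``Q``, and — when ``normalized`` — the stationary flux
    ``-sum_i pi_i Q_ii`` equals 1 (time in expected substitutions per site).
    """

    space: StateSpace
    Q: np.ndarray
    pi: np.ndarray
    normalized: bool = False
    name: str = ""

    def __post_init__(self):
        Q = np.asarray(self.Q, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        n = self.space.N
        if Q.shape != (n, n):
            raise ModelError(f"Q has shape {Q.shape}, expected ({n}, {n})")
        off = Q[~np.eye(n, dtype=bool)]
        if off.size and off.min() < -_GEN_TOL:
            raise ModelError(f"negative off-diagonal rate: {off.min():g}")
        rs = np.abs(Q.sum(axis=1)).max()
        if rs > 1e-8 * max(1.0, np.abs(Q).max()):
            raise ModelError(f"rows do not sum to zero (max |row sum| = {rs:g})")
        if pi.shape != (n,) or pi.min() < -_GEN_TOL or abs(pi.sum() - 1) > 1e-8:
            raise ModelError("pi must be a probability vector over the state space")
        bal = np.abs(pi @ Q).max()
        if bal > 1e-7 * max(1.0, np.abs(Q).max()):
            raise ModelError(f"pi is not stationary for Q (max |pi Q| = {bal:g})")
        if self.normalized and abs(self.flux - 1) > 1e-8:
            raise ModelError(f"normalized flag set but stationary flux is {self.flux:g}")
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "pi", pi)

    @property
    def flux(self) -> float:
        """Total stationary substitution flux, ``sum_{i, j!=i} pi_i Q_ij``."""
        return float(-(self.pi * np.diag(self.Q)).sum())

    def is_reversible(self, tol: float = 1e-8) -> bool:
        """Detailed balance check ``pi_i Q_ij == pi_j Q_ji``."""
        F = self.pi[:, None] * self.Q
        scale = max(1.0, np.abs(F).max())
        return bool(np.abs(F - F.T).max() <= tol * scale)


@dataclass(frozen=True)
class M0Params:
    """Parameters of the M0 codon model.

    kappa : transition/transversion rate ratio (dimensionless, > 0)
    omega : nonsynonymous/synonymous rate ratio (dimensionless, > 0)
    codon_freqs : equilibrium probabilities of the 61 sense codons
    """

    kappa: float
    omega: float
    codon_freqs: np.ndarray

    def __post_init__(self):
        if not self.kappa > 0:
            raise ModelError("kappa must be positive")
        if not self.omega > 0:
            raise ModelError("omega must be positive")
        f = np.asarray(self.codon_freqs, dtype=float)
        if f.shape != (61,):
            raise ModelError(f"codon_freqs must have 61 entries, got {f.shape}")
        if f.min() < 0 or abs(f.sum() - 1) > 1e-8:
            raise ModelError("codon_freqs must be non-negative and sum to 1")
        object.__setattr__(self, "codon_freqs", f)


def uniform_codon_freqs() -> np.ndarray:
    """The uniform distribution over the 61 sense codons."""
    return np.full(61, 1.0 / 61.0)


def build_m0(params: M0Params) -> RateMatrix:
    """Build the M0 codon generator.

    Off-diagonal rates: zero unless the codons differ at exactly one
    nucleotide position (and neither is a stop codon, which are excluded
    from the state space altogether); otherwise proportional to the target
    codon frequency, times ``kappa`` for a transition (A<->G, C<->T) and
    ``omega`` for a nonsynonymous change.  The overall scale is fixed by
    normalizing the stationary flux to one substitution per site.  The
    construction is reversible with stationary distribution
    ``codon_freqs``.
    """
    sp = codon_space()
    pi = params.codon_freqs
    n = sp.N
    Q = np.zeros((n, n))
    for a in range(n):
        ca = sp.labels[a]
        for b in range(n):
            if a == b:
                continue
            cb = sp.labels[b]
            diff = [(x, y) for x, y in zip(ca, cb) if x != y]
            if len(diff) != 1:
                continue
            rate = pi[b]
            if is_transition(*diff[0]):
                rate *= params.kappa
            if sp.code[ca] != sp.code[cb]:
                rate *= params.omega
            Q[a, b] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rm = RateMatrix(space=sp, Q=Q, pi=pi, normalized=False,
                    name=f"M0(kappa={params.kappa:g}, omega={params.omega:g})")
    return normalize(rm)


def stationary(Q: np.ndarray, *, space: Optional[StateSpace] = None) -> np.ndarray:
    """Stationary distribution of a generator: the probability vector with ``pi Q = 0``.

    Solved as the null space of ``Q^T``; a reducible or defective generator
    (null space not one-dimensional) raises :class:`ModelError`.
    """
    Q = np.asarray(Q, dtype=float)
    ns = scipy.linalg.null_space(Q.T, rcond=1e-10)
    if ns.shape[1] != 1:
        raise ModelError(
            f"generator has a {ns.shape[1]}-dimensional left null space; "
            "expected exactly one stationary distribution (is Q irreducible?)"
        )
    v = ns[:, 0].real
    if v.sum() < 0:
        v = -v
    if v.min() < -1e-10:
        raise ModelError("left null vector has mixed signs; Q is not a proper generator")
    v = np.clip(v, 0, None)
    return v / v.sum()


def normalize(rm: RateMatrix) -> RateMatrix:
    """Rescale a generator to unit stationary flux (idempotent; ``pi`` unchanged)."""
    f = rm.flux
    if f <= 0:
        raise ModelError("cannot normalize a generator with zero stationary flux")
    return replace(rm, Q=rm.Q / f, normalized=True)


def toy_three_state() -> RateMatrix:
    """The symmetric 3-state toy generator with uniform stationary distribution.

    Returned un-normalized: its stationary flux is 0.8, not 1.
    """
    sp = generic_space(("A", "B", "C"))
    Q = np.array([
        [-1.0, 0.9, 0.1],
        [0.9, -1.1, 0.2],
        [0.1, 0.2, -0.3],
    ])
    return RateMatrix(space=sp, Q=Q, pi=np.full(3, 1 / 3), normalized=False, name="toy3")


# ---------------------------------------------------------------------------
# file I/O


def wag_path() -> Path:
    """Path of the bundled published WAG parameter file (PAML .dat format)."""
    return Path(__file__).parent / "data" / "wag.dat"


def _paml_space(n: int) -> tuple[StateSpace, Sequence[str]]:
    """Canonical space and file-order labels for an n-state PAML file."""
    if n == 20:
        return amino_acid_space(), tuple(PAML_AA_ORDER)
    if n == 61:
        sp = codon_space()
        return sp, sp.labels
    raise ModelError(f"unsupported PAML state count: {n}")


def load_empirical(
    path,
    format: str = "paml_exchangeability",
    freq_override: Optional[np.ndarray] = None,
    n_states: int = 20,
) -> RateMatrix:
    """Load an empirical rate matrix and return it normalized.

    ``format="paml_exchangeability"``: PAML .dat dialect — N-1 lines of
    lower-triangular symmetric exchangeabilities ``s_ij`` followed by the
    equilibrium frequencies; the generator is ``Q_ij = s_ij pi_j`` (hence
    reversible).  Amino-acid files are given in PAML order and permuted to
    the package's canonical alphabetical order.  ``format="dense_rate_matrix"``
    delegates to :func:`load_dense`.

    ``freq_override`` replaces the file's frequency vector (in canonical
    order).  Frequencies off by more than 1e-4 from sum 1 trigger a warning;
    they are always renormalized.
    """
    if format == "dense_rate_matrix":
        return load_dense(path)
    if format != "paml_exchangeability":
        raise ModelError(f"unknown matrix format: {format!r}")
    tokens_by_line = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    flat = [float(tok) for ln in tokens_by_line for tok in ln]
    n = n_states
    need = n * (n - 1) // 2 + n
    if len(flat) < need:
        raise ModelError(f"PAML file {path}: expected at least {need} numbers, found {len(flat)}")
    S = np.zeros((n, n))
    k = 0
    for i in range(1, n):
        S[i, :i] = flat[k:k + i]
        k += i
    S = S + S.T
    if S.min() < 0:
        raise ModelError(f"PAML file {path}: negative exchangeability")
    freqs = np.asarray(flat[k:k + n])
    sp, file_order = _paml_space(n)
    perm = np.array([file_order.index(lab) for lab in sp.labels])
    S = S[np.ix_(perm, perm)]
    freqs = freqs[perm]
    if freq_override is not None:
        freqs = np.asarray(freq_override, dtype=float)
        if freqs.shape != (n,):
            raise ModelError(f"freq_override must have {n} entries")
    if freqs.min() < 0:
        raise ModelError(f"PAML file {path}: negative frequency")
    if abs(freqs.sum() - 1) > 1e-4:
        warnings.warn(
            f"frequencies in {path} sum to {freqs.sum():g}; renormalizing", stacklevel=2
        )
    freqs = freqs / freqs.sum()
    Q = S * freqs[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rm = RateMatrix(space=sp, Q=Q, pi=freqs, normalized=False, name=str(path))
    return normalize(rm)


def load_dense(path) -> RateMatrix:
    """Read a dense labeled rate matrix (TSV: header row + label column).

    The stationary distribution is recomputed from the matrix; the result is
    returned with its normalization status detected from the flux.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split("\t")
    labels = tuple(header[1:])
    n = len(labels)
    Q = np.zeros((n, n))
    for i, ln in enumerate(lines[1:n + 1]):
        parts = ln.split("\t")
        if parts[0] != labels[i]:
            raise ModelError(f"{path}: row label {parts[0]!r} does not match header order")
        Q[i] = [float(x) for x in parts[1:n + 1]]
    sp = _space_for_labels(labels)
    pi = stationary(Q)
    rm = RateMatrix(space=sp, Q=Q, pi=pi, normalized=False, name=str(path))
    if abs(rm.flux - 1) <= 1e-8:
        rm = replace(rm, normalized=True)
    return rm


def _space_for_labels(labels: Sequence[str]) -> StateSpace:
    labels = tuple(labels)
    if labels == codon_space().labels:
        return codon_space()
    if labels == amino_acid_space().labels:
        return amino_acid_space()
    if len(labels) == 61 and all(len(l) == 3 and set(l) <= set("ACGT") for l in labels):
        sp = codon_space()
        if set(labels) == set(sp.labels):
            raise ModelError(
                "codon labels are in a non-canonical order; re-order to lexicographic A<C<G<T"
            )
    return generic_space(labels)


def write_dense(rm_or_matrix, path, labels: Optional[Sequence[str]] = None) -> None:
    """Write a matrix as labeled TSV at 12 significant digits."""
    if isinstance(rm_or_matrix, RateMatrix):
        M, labels = rm_or_matrix.Q, rm_or_matrix.space.labels
    else:
        M = np.asarray(rm_or_matrix)
        if labels is None:
            raise ModelError("labels required when writing a bare matrix")
    with open(path, "w") as fh:
        fh.write("\t".join(("state",) + tuple(labels)) + "\n")
        for lab, row in zip(labels, M):
            fh.write(lab + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")


def load_freqs(path, n: Optional[int] = None) -> np.ndarray:
    """Read a frequency vector, one value per line (``#`` comments allowed)."""
    vals = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.split("#", 1)[0].strip()
        if ln:
            vals.append(float(ln))
    f = np.asarray(vals, dtype=float)
    if n is not None and f.shape != (n,):
        raise ModelError(f"{path}: expected {n} frequencies, found {f.size}")
    if f.min() < 0:
        raise ModelError(f"{path}: negative frequency")
    if abs(f.sum() - 1) > 1e-4:
        warnings.warn(f"frequencies in {path} sum to {f.sum():g}; renormalizing", stacklevel=2)
    return f / f.sum()


def write_freqs(freqs: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        for v in np.asarray(freqs, dtype=float):
            fh.write(_FLOAT_FMT % v + "\n")
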