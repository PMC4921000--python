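"""Discrete state spaces for substitution models.

The package works on three kinds of state space: the 61 sense codons of the
standard genetic code, the 20 amino acids, and arbitrary "generic" toy
alphabets.  Alongside the spaces themselves this module defines the
nucleotide-difference classification used throughout the diagnostics and
inference machinery: every ordered pair of states is assigned a class in
{0, 1, 2, 3} — for codons the number of nucleotide positions at which they
differ, for amino acids the minimum of that count over all pairs of coding
codons, and 0 exactly on the diagonal.

Codons are ordered lexicographically over the DNA alphabet A < C < G < T.
Amino acids are ordered alphabetically by one-letter code; the PAML file
order (``ARNDCQEGHILKMFPSTWYV``) is handled at the I/O layer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Optional

import numpy as np
from Bio.Data import CodonTable
from Bio.SeqUtils import seq1

__all__ = [
    "StateSpace",
    "DiffClassPartition",
    "StateSpaceError",
    "codon_space",
    "amino_acid_space",
    "generic_space",
    "standard_code",
    "nuc_diff_class",
    "aa_diff_class",
    "canonical_aa",
    "is_transition",
    "NUCLEOTIDES",
    "AA_ORDER",
    "PAML_AA_ORDER",
    "STOP_CODONS",
]

NUCLEOTIDES = "ACGT"
#: canonical amino-acid order: alphabetical one-letter codes
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
#: the order used by PAML-style .dat matrix files
PAML_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)


class StateSpaceError(ValueError):
    """Raised for unknown labels or malformed state spaces."""


def is_transition(x: str, y: str) -> bool:
    """True if the nucleotide change ``x`` -> ``y`` is a transition (A<->G, C<->T)."""
    pair = {x, y}
    return pair == set("AG") or pair == set("CT")


def canonical_aa(label: str) -> str:
    """Canonicalize an amino-acid label (1- or 3-letter) to its one-letter code."""
    s = label.strip()
    if len(s) == 1:
        one = s.upper()
    elif len(s) == 3:
        one = seq1(s)
    else:
        raise StateSpaceError(f"not an amino-acid label: {label!r}")
    if one not in AA_ORDER:
        raise StateSpaceError(f"unknown amino acid: {label!r}")
    return one


@dataclass(frozen=True)
class StateSpace:
    """An ordered, labeled set of discrete states.

    Parameters
    ----------
    labels
        Ordered state names; must be unique.
    kind
        ``"codon"`` (61 sense codons), ``"amino_acid"`` (20 states) or
        ``"generic"``.
    code
        For ``kind="codon"``: mapping codon -> one-letter amino acid.
    """

    labels: tuple[str, ...]
    kind: str = "generic"
    code: Optional[Mapping[str, str]] = None
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise StateSpaceError("state labels must be unique")
        if self.kind == "codon":
            if len(self.labels) != 61:
                raise StateSpaceError("codon space must have 61 states")
            bad = STOP_CODONS.intersection(self.labels)
            if bad:
                raise StateSpaceError(f"stop codons not allowed in the state set: {sorted(bad)}")
            if self.code is None or set(self.code) != set(self.labels):
                raise StateSpaceError("codon space requires a genetic-code mapping for all 61 codons")
        elif self.kind == "amino_acid":
            if len(self.labels) != 20:
                raise StateSpaceError("amino-acid space must have 20 states")
        elif self.kind != "generic":
            raise StateSpaceError(f"unknown state-space kind: {self.kind!r}")
        object.__setattr__(self, "_index", {lab: i for i, lab in enumerate(self.labels)})

    @property
    def N(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise StateSpaceError(f"unknown state label {label!r} for {self.kind} space") from None

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __len__(self) -> int:
        return len(self.labels)


@lru_cache(maxsize=None)
def codon_space() -> StateSpace:
    """The 61 sense codons of the standard genetic code, lexicographic in A<C<G<T."""
    codons = tuple(
        "".join(p)
        for p in itertools.product(NUCLEOTIDES, repeat=3)
        if "".join(p) not in STOP_CODONS
    )
    code = {c: _STANDARD_TABLE.forward_table[c] for c in codons}
    return StateSpace(labels=codons, kind="codon", code=code)


def standard_code() -> tuple[StateSpace, dict[str, str]]:
    """The standard-genetic-code codon space together with its codon->amino-acid map."""
    sp = codon_space()
    return sp, dict(sp.code)


@lru_cache(maxsize=None)
def amino_acid_space() -> StateSpace:
    """The 20 standard amino acids, alphabetical by one-letter code."""
    return StateSpace(labels=tuple(AA_ORDER), kind="amino_acid")


def generic_space(labels: Iterable[str]) -> StateSpace:
    """An arbitrary toy state space with the given labels."""
    return StateSpace(labels=tuple(labels), kind="generic")


def nuc_diff_class(i: str, j: str) -> int:
    """Number of nucleotide positions (0-3) at which two sense codons differ.

    Both labels must be sense codons of the standard code; stop codons and
    unknown strings are rejected.
    """
    sp = codon_space()
    if i not in sp:
        raise StateSpaceError(f"not a sense codon: {i!r}")
    if j not in sp:
        raise StateSpaceError(f"not a sense codon: {j!r}")
    return sum(a != b for a, b in zip(i, j))


@lru_cache(maxsize=None)
def _aa_class_table() -> dict[tuple[str, str], int]:
    sp = codon_space()
    by_aa: dict[str, list[str]] = {}
    for c in sp.labels:
        by_aa.setdefault(sp.code[c], []).append(c)
    table: dict[tuple[str, str], int] = {}
    for a, ca in by_aa.items():
        for b, cb in by_aa.items():
            if a == b:
                table[(a, b)] = 0
            else:
                table[(a, b)] = min(
                    sum(x != y for x, y in zip(u, v)) for u in ca for v in cb
                )
    return table


def aa_diff_class(a: str, b: str) -> int:
    """Minimal nucleotide-difference class between two amino acids.

    0 iff the amino acids are identical; otherwise the minimum, over all
    pairs of standard-code codons coding for ``a`` and ``b`` respectively,
    of the number of differing nucleotide positions.  Accepts one- and
    three-letter labels.
    """
    return _aa_class_table()[(canonical_aa(a), canonical_aa(b))]


@dataclass(frozen=True)
class DiffClassPartition:
    """Classification of every ordered state pair into classes 0-3.

    ``classes[i, j]`` is 0 on the diagonal and, off the diagonal, the
    (minimal) number of nucleotide changes separating states ``i`` and
    ``j``.  For a generic space every off-diagonal pair is class 1.
    """

    space: StateSpace
    classes: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.classes)
        n = self.space.N
        if c.shape != (n, n):
            raise StateSpaceError("class table shape does not match the state space")
        if np.any(np.diag(c) != 0):
            raise StateSpaceError("diagonal pairs must be class 0")
        if not np.array_equal(c, c.T):
            raise StateSpaceError("class table must be symmetric")
        object.__setattr__(self, "classes", c.astype(np.int64))

    @classmethod
    def for_space(cls, space: StateSpace) -> "DiffClassPartition":
        n = space.N
        table = np.zeros((n, n), dtype=np.int64)
        if space.kind == "codon":
            for i, ci in enumerate(space.labels):
                for j, cj in enumerate(space.labels):
                    table[i, j] = sum(a != b for a, b in zip(ci, cj))
        elif space.kind == "amino_acid":
            t = _aa_class_table()
            for i, a in enumerate(space.labels):
                for j, b in enumerate(space.labels):
                    table[i, j] = t[(canonical_aa(a), canonical_aa(b))]
        else:
            table = np.ones((n, n), dtype=np.int64)
            np.fill_diagonal(table, 0)
        return cls(space=space, classes=table)

    def class_of(self, i: str, j: str) -> int:
        return int(self.classes[self.space.index(i), self.space.index(j)])

    def mask(self, k: int) -> np.ndarray:
        """Boolean matrix selecting the ordered pairs of class ``k``."""
        return self.classes == k

    def counts(self) -> dict[int, int]:
        """Number of ordered pairs per class."""
        vals, cnt = np.unique(self.classes, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, cnt)}
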