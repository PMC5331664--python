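"""The k-mer convolution string kernel and its induced distance.

Given the residue kernel ``K1`` (see :mod:`seqkernel.matrices`), two
sequences S (length n) and T (length m) are compared gap-free through all
their contiguous k-mers:

    K2_k(u, v) = prod_{i=1..k} K1(u_i, v_i)            (k-mer kernel)
    K3_k(S,T)  = sum over all k-mer pairs of K2_k      (fixed-k kernel)
    K3(S, T)   = sum_{k=1..p} K3_k(S, T)               (sequence kernel)

with p = min(k_max, n, m): the sum naturally stops at the shorter sequence
and is truncated at ``k_max`` for cost.  The correlation kernel

    Khat3(S, T) = K3(S, T) / sqrt(K3(S, S) * K3(T, T))

is 1 on the diagonal and induces the metric D = sqrt(2 - 2*Khat3), bounded
by sqrt(2).

Two evaluation routes are provided: :func:`k3_naive` enumerates every k-mer
pair (O(n*m*k_max^2), the reference oracle), and :func:`k3_recursive`
exploits K2_k(u,v) = K2_{k-1} * K1(u_k, v_k) as a dynamic programme over
k-mer start positions (O(n*m*k_max), the production route).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .matrices import (
    STANDARD_ALPHABET,
    AminoAlphabet,
    NONSTANDARD_MAP,
    RatioMatrix,
    hadamard_power,
)

SQRT2 = math.sqrt(2.0)

_KHAT_CLAMP = 1e-9  # round-off excess above 1 that is clamped, not raised


class SequenceError(ValueError):
    """Raised for invalid protein-sequence input."""


class KernelOverflowError(OverflowError):
    """Raised when kernel accumulation leaves double-precision range."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence stored as alphabet indices.

    ``residues`` is an integer array indexing into ``alphabet.letters``;
    :meth:`from_string` handles uppercasing and the nonstandard-residue
    policy ("strict" rejects B/Z/J/U/O/X with the offending position, "map"
    substitutes the common fallbacks B->D, Z->E, J->L, U->C, O->K; X always
    errors).
    """

    id: str
    residues: np.ndarray
    alphabet: AminoAlphabet = STANDARD_ALPHABET

    def __post_init__(self) -> None:
        residues = np.asarray(self.residues, dtype=np.intp)
        if residues.ndim != 1 or residues.size < 1:
            raise SequenceError(f"sequence {self.id!r} must have length >= 1")
        if residues.min() < 0 or residues.max() >= len(self.alphabet):
            raise SequenceError(f"sequence {self.id!r} has out-of-alphabet indices")
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return self.residues.size

    def __str__(self) -> str:
        return "".join(self.alphabet.letters[i] for i in self.residues)

    @classmethod
    def from_string(
        cls,
        id: str,
        sequence: str,
        alphabet: AminoAlphabet = STANDARD_ALPHABET,
        residue_policy: str = "strict",
    ) -> "ProteinSequence":
        if residue_policy not in ("strict", "map"):
            raise ValueError(f"unknown residue policy {residue_policy!r}")
        seq = sequence.upper()
        if not seq:
            raise SequenceError(f"sequence {id!r} is empty")
        indices = np.empty(len(seq), dtype=np.intp)
        for pos, letter in enumerate(seq):
            if letter in alphabet:
                indices[pos] = alphabet.index[letter]
                continue
            if residue_policy == "map" and letter in NONSTANDARD_MAP:
                mapped = NONSTANDARD_MAP[letter]
                indices[pos] = alphabet.index[mapped]
                continue
            raise SequenceError(
                f"sequence {id!r}: disallowed residue {letter!r} at position "
                f"{pos + 1} (policy {residue_policy!r})"
            )
        return cls(id, indices, alphabet)


@dataclass(frozen=True)
class KernelParams:
    """Kernel configuration: the residue matrix, beta and the k-mer cap.

    ``matrix`` may be a plain odds-ratio matrix (beta is applied here) or a
    matrix that already carries a Hadamard power, in which case ``beta``
    must agree with it.  The recommended setting is beta=0.2, k_max=10.
    """

    matrix: RatioMatrix
    beta: float = 0.2
    k_max: int = 10
    k1: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if not np.isfinite(self.beta) or self.beta <= 0:
            raise ValueError("beta must be strictly positive")
        if self.matrix.beta_applied is None:
            k1 = hadamard_power(self.matrix, self.beta).values
        elif math.isclose(self.matrix.beta_applied, self.beta):
            k1 = self.matrix.values
        else:
            raise ValueError(
                f"matrix carries beta={self.matrix.beta_applied}, "
                f"params request beta={self.beta}"
            )
        object.__setattr__(self, "k1", k1)

    @property
    def alphabet(self) -> AminoAlphabet:
        return self.matrix.alphabet

    def effective_p(self, n: int, m: int) -> int:
        """Largest k-mer length used for a pair of lengths (n, m)."""
        return min(self.k_max, n, m)


@dataclass(frozen=True)
class KernelValue:
    """K3 value with its per-k breakdown (k3_by_k[k-1] = K3_k)."""

    k3: float
    k3_by_k: np.ndarray


def _check_pair(s: ProteinSequence, t: ProteinSequence, params: KernelParams) -> None:
    if s.alphabet != params.alphabet or t.alphabet != params.alphabet:
        raise SequenceError("sequence alphabet does not match the kernel matrix")


def k2(u: np.ndarray, v: np.ndarray, params: KernelParams) -> float:
    """k-mer kernel: product of K1 over aligned positions (no gaps)."""
    u = np.asarray(u, dtype=np.intp)
    v = np.asarray(v, dtype=np.intp)
    if u.size != v.size:
        raise SequenceError(f"k-mer length mismatch: {u.size} vs {v.size}")
    if u.size < 1:
        raise SequenceError("k-mers must have length >= 1")
    return float(np.prod(params.k1[u, v]))


def k3_naive(
    s: ProteinSequence, t: ProteinSequence, params: KernelParams
) -> KernelValue:
    """Brute-force K3: enumerate every contiguous k-mer pair.

    O(n*m*k_max^2); kept as the independent reference implementation that
    :func:`k3_recursive` is validated against.
    """
    _check_pair(s, t, params)
    n, m = len(s), len(t)
    p = params.effective_p(n, m)
    by_k = np.zeros(p)
    for k in range(1, p + 1):
        total = 0.0
        for i in range(n - k + 1):
            for j in range(m - k + 1):
                total += k2(s.residues[i : i + k], t.residues[j : j + k], params)
        by_k[k - 1] = total
    return KernelValue(float(by_k.sum()), by_k)


def k3_recursive(
    s: ProteinSequence, t: ProteinSequence, params: KernelParams
) -> KernelValue:
    """Dynamic-programming K3 in O(n*m*k_max).

    Layer k holds M_k(i, j) = K2_k of the k-mers starting at (i, j);
    M_k = M_{k-1}[:-1, :-1] * K1(s_{i+k-1}, t_{j+k-1}), and K3_k is the
    layer sum.  Only the current layer is retained.
    """
    _check_pair(s, t, params)
    n, m = len(s), len(t)
    p = params.effective_p(n, m)
    base = params.k1[np.ix_(s.residues, t.residues)]
    layer = base
    by_k = np.zeros(p)
    by_k[0] = layer.sum()
    with np.errstate(over="ignore"):  # overflow is detected and raised below
        for k in range(2, p + 1):
            layer = layer[: n - k + 1, : m - k + 1] * base[k - 1 :, k - 1 :]
            by_k[k - 1] = layer.sum()
    if not np.all(np.isfinite(by_k)):
        raise KernelOverflowError(
            "kernel accumulation overflowed double precision; "
            "reduce beta or k_max"
        )
    return KernelValue(float(by_k.sum()), by_k)


def correlation_kernel(
    s: ProteinSequence,
    t: ProteinSequence,
    params: KernelParams,
    *,
    k3_func=k3_recursive,
) -> float:
    """Correlation kernel Khat3 = K3(S,T) / sqrt(K3(S,S) * K3(T,T)).

    Exactly 1 for S == T; values in (1, 1 + 1e-9] from round-off are clamped
    to 1.  With the identity residue matrix and sequences sharing no k-mer
    the numerator can vanish; 0 is returned in that degenerate case.
    """
    kss = k3_func(s, s, params).k3
    ktt = k3_func(t, t, params).k3
    if kss <= 0 or ktt <= 0:
        bad = s.id if kss <= 0 else t.id
        raise SequenceError(
            f"zero self-kernel for sequence {bad!r}; the residue matrix gives "
            "this sequence no similarity with itself"
        )
    kst = k3_func(s, t, params).k3
    return _normalize(kst, kss, ktt)


def _normalize(kst: float, kss: float, ktt: float) -> float:
    khat = kst / math.sqrt(kss * ktt)
    if khat > 1.0 + _KHAT_CLAMP:
        raise ValueError(
            f"correlation kernel {khat} exceeds 1 beyond round-off; "
            "the upstream kernel matrix is not a valid kernel"
        )
    if khat >= 1.0 - 1e-12:  # self-pairs land here up to sqrt round-off
        return 1.0
    return khat


def kernel_distance(khat: float) -> float:
    """Metric induced by the correlation kernel: D = sqrt(2 - 2*Khat3).

    D(S, S) = 0 and D <= sqrt(2) for non-negative Khat3.
    """
    if khat > 1.0 + _KHAT_CLAMP:
        raise ValueError(f"correlation kernel value {khat} > 1: broken kernel upstream")
    return math.sqrt(max(2.0 - 2.0 * min(khat, 1.0), 0.0))


def limit_semikernel(n: int, m: int, k_max: int) -> float:
    """Closed form of K3 in the beta -> 0 (all-ones matrix) limit.

    K3 = sum_{k=1..min(k_max,n,m)} (n-k+1)(m-k+1): a function of the two
    lengths only.  The matching correlation value is 1 for equal-length
    pairs, which is why tiny beta turns the kernel into a length detector.
    """
    if n < 1 or m < 1:
        raise ValueError("sequence lengths must be >= 1")
    p = min(k_max, n, m)
    ks = np.arange(1, p + 1)
    return float(np.sum((n - ks + 1) * (m - ks + 1)))


@dataclass(frozen=True)
class PairMatrix:
    """Symmetric all-vs-all similarity (Khat3) or distance (D) matrix."""

    ids: tuple[str, ...]
    values: np.ndarray
    kind: str  # "similarity" | "distance"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("sequence ids must be unique")
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} ids")
        if self.kind not in ("similarity", "distance"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "values", values)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_distance(self) -> "PairMatrix":
        if self.kind == "distance":
            return self
        d = np.sqrt(np.maximum(2.0 - 2.0 * np.minimum(self.values, 1.0), 0.0))
        np.fill_diagonal(d, 0.0)
        return PairMatrix(self.ids, d, "distance")


def pairwise_matrix(
    seqs: list[ProteinSequence],
    params: KernelParams,
    output: str = "similarity",
) -> PairMatrix:
    """All-vs-all correlation-kernel (or distance) matrix.

    Self-kernels are computed once per sequence and reused; the diagonal is
    exactly 1 (similarity) or 0 (distance).
    """
    if output not in ("similarity", "distance"):
        raise ValueError(f"output must be 'similarity' or 'distance', got {output!r}")
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence ids: {', '.join(dup)}")
    n = len(seqs)
    self_k3 = np.array([k3_recursive(s, s, params).k3 for s in seqs])
    for s, v in zip(seqs, self_k3):
        if v <= 0:
            raise SequenceError(f"zero self-kernel for sequence {s.id!r}")
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            kst = k3_recursive(seqs[i], seqs[j], params).k3
            sim[i, j] = sim[j, i] = _normalize(kst, self_k3[i], self_k3[j])
    matrix = PairMatrix(tuple(ids), sim, "similarity")
    return matrix.to_distance() if output == "distance" else matrix
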