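"""Amino-acid substitution kernels.

The sequence kernel is built on top of a similarity function between single
residues.  That function starts from a symmetric table of raw substitution
counts ``SM`` (how often residue *i* is seen replaced by residue *j* in
trusted alignments), which is normalized by its row sums into an odds-ratio
matrix::

    P(i)     = sum_j SM(i, j)
    SM2(i,j) = SM(i, j) / (P(i) * P(j))

and then sharpened or flattened by an entrywise (Hadamard) power with a
strictly positive exponent ``beta``::

    K1(i,j) = SM2(i, j) ** beta

``K1`` is a valid kernel on the residue alphabet whenever ``SM2`` is
symmetric positive definite and ``beta > 0``.  BLOSUM-style integer
log-odds matrices are related to ``SM2`` by ``BL = round(log2(SM2))`` and
can be back-transformed (approximately, because of the rounding) with
:func:`from_log_odds`.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical one-letter codes of the 20 standard amino acids, alphabetical.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Replacement policy for ambiguous / nonstandard residue codes under the
#: "map" policy.  X is never mapped: any numeric stand-in would bias the
#: kernel silently.
NONSTANDARD_MAP = {"B": "D", "Z": "E", "J": "L", "U": "C", "O": "K"}

_SYMMETRY_TOL = 1e-8


class MatrixError(ValueError):
    """Raised for invalid substitution-matrix input."""


@dataclass(frozen=True)
class AminoAlphabet:
    """An ordered residue alphabet with letter -> index lookup.

    The canonical instance is :data:`STANDARD_ALPHABET` (the 20 standard
    amino acids in alphabetical one-letter order); smaller alphabets are
    allowed for toy matrices and tests.
    """

    letters: tuple[str, ...]
    index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        letters = tuple(self.letters)
        if len(letters) == 0:
            raise MatrixError("alphabet must not be empty")
        if any(len(c) != 1 or not c.isupper() for c in letters):
            raise MatrixError("alphabet letters must be single uppercase characters")
        if len(set(letters)) != len(letters):
            raise MatrixError("alphabet letters must be unique")
        object.__setattr__(self, "letters", letters)
        object.__setattr__(self, "index", {c: i for i, c in enumerate(letters)})

    def __len__(self) -> int:
        return len(self.letters)

    def __contains__(self, letter: str) -> bool:
        return letter in self.index


STANDARD_ALPHABET = AminoAlphabet(tuple(STANDARD_AA))


def _check_square(values: np.ndarray, alphabet: AminoAlphabet, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    n = len(alphabet)
    if values.shape != (n, n):
        raise MatrixError(
            f"{what} must be {n}x{n} for a {n}-letter alphabet, got {values.shape}"
        )
    asym = np.max(np.abs(values - values.T)) if values.size else 0.0
    scale = max(np.max(np.abs(values)), 1.0)
    if asym > _SYMMETRY_TOL * scale:
        raise MatrixError(f"{what} is not symmetric (max asymmetry {asym:.3g})")
    return values


@dataclass(frozen=True)
class CountMatrix:
    """Raw substitution counts SM(i, j) with strictly positive row sums."""

    counts: np.ndarray
    alphabet: AminoAlphabet = STANDARD_ALPHABET

    def __post_init__(self) -> None:
        counts = _check_square(self.counts, self.alphabet, "count matrix")
        if np.any(counts < 0):
            raise MatrixError("substitution counts must be non-negative")
        row_sums = counts.sum(axis=1)
        for i, s in enumerate(row_sums):
            if s <= 0:
                raise MatrixError(
                    f"row sum P({self.alphabet.letters[i]}) is zero; every residue "
                    "needs at least one observed substitution"
                )
        object.__setattr__(self, "counts", counts)

    @property
    def row_sums(self) -> np.ndarray:
        """P(i) = sum_j SM(i, j)."""
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class RatioMatrix:
    """An odds-ratio matrix SM2, or its Hadamard power K1 = SM2**beta.

    ``beta_applied`` is ``None`` for a plain odds-ratio matrix and records
    the exponent once :func:`hadamard_power` has been applied.  Entries must
    be non-negative with a strictly positive diagonal; the identity matrix
    (off-diagonal zeros) is the only sanctioned source of zeros.
    """

    values: np.ndarray
    alphabet: AminoAlphabet = STANDARD_ALPHABET
    beta_applied: float | None = None

    def __post_init__(self) -> None:
        values = _check_square(self.values, self.alphabet, "ratio matrix")
        if np.any(values < 0):
            raise MatrixError("ratio-matrix entries must be non-negative")
        if np.any(np.diag(values) <= 0):
            raise MatrixError("ratio-matrix diagonal must be strictly positive")
        if self.beta_applied is not None and self.beta_applied <= 0:
            raise MatrixError("beta must be strictly positive")
        object.__setattr__(self, "values", values)


class PDReport(NamedTuple):
    """Result of a positive-definiteness check on a symmetric matrix.

    Truthiness equals ``is_pd``, so the report can be used directly in
    assertions while still carrying the extreme eigenvalues.
    """

    is_pd: bool
    smallest_eigenvalue: float
    largest_eigenvalue: float

    def __bool__(self) -> bool:  # pragma: no cover - trivial
        return self.is_pd


def normalize_counts(counts: CountMatrix) -> RatioMatrix:
    """Normalize raw counts into the odds-ratio matrix SM2.

    SM2(i, j) = SM(i, j) / (P(i) * P(j)) with P the row sums.  Symmetry of
    the counts makes SM2 symmetric, and whenever the raw counts come from a
    BLOSUM-style tally SM2 is also positive definite.
    """
    p = counts.row_sums
    values = counts.counts / np.outer(p, p)
    return RatioMatrix(values, counts.alphabet, beta_applied=None)


def hadamard_power(ratio: RatioMatrix, beta: float) -> RatioMatrix:
    """Entrywise power SM2**beta, producing the residue kernel K1.

    Large ``beta`` sharpens the matrix around its diagonal; as ``beta`` goes
    to zero every positive entry flattens toward 1 and the kernel degenerates
    into a pure sequence-length signal (see :func:`seqkernel.kernel.limit_semikernel`).
    """
    if not np.isfinite(beta) or beta <= 0:
        raise MatrixError("beta must be strictly positive")
    if ratio.beta_applied is not None:
        raise MatrixError(
            f"matrix already has beta={ratio.beta_applied} applied; "
            "start from the un-powered odds-ratio matrix"
        )
    return RatioMatrix(ratio.values**beta, ratio.alphabet, beta_applied=beta)


def check_positive_definite(ratio: RatioMatrix, tol: float = 1e-8) -> PDReport:
    """Check whether the matrix is positive definite.

    Passes iff the smallest eigenvalue exceeds ``tol`` relative to the
    largest one.  The strictly positive threshold matters: a rank-deficient
    matrix (such as the all-ones beta -> 0 limit) has eigenvalue 0 up to the
    eigensolver's backward error and must *not* be reported as definite,
    while a genuinely definite matrix clears the relative threshold easily.
    """
    eigenvalues = np.linalg.eigvalsh(ratio.values)
    smallest, largest = float(eigenvalues[0]), float(eigenvalues[-1])
    threshold = tol * max(abs(largest), 1e-300)
    return PDReport(smallest > threshold, smallest, largest)


def from_log_odds(
    int_matrix: np.ndarray,
    alphabet: AminoAlphabet = STANDARD_ALPHABET,
    base: float = 2.0,
) -> RatioMatrix:
    """Back-transform an integer log-odds matrix into a ratio matrix.

    BLOSUM matrices are published as ``BL = round(log2(SM2))``; this inverts
    the log, ``values = base**BL``.  The rounding is lossy, so the result is
    only an approximation of the original odds-ratio matrix — a warning is
    emitted, and the positive-definiteness of the reconstruction is checked
    and logged (rounding can break it).
    """
    int_matrix = np.asarray(int_matrix)
    values = _check_square(int_matrix.astype(float), alphabet, "log-odds matrix")
    ratio = RatioMatrix(np.power(float(base), values), alphabet, beta_applied=None)
    warnings.warn(
        "log-odds entries are rounded to integers; the back-transformed matrix "
        "is only an approximation of the underlying odds-ratio matrix",
        UserWarning,
        stacklevel=2,
    )
    report = check_positive_definite(ratio)
    logger.info(
        "back-transformed log-odds matrix: positive definite=%s "
        "(smallest eigenvalue %.3g)",
        report.is_pd,
        report.smallest_eigenvalue,
    )
    return ratio


def identity_matrix(alphabet: AminoAlphabet = STANDARD_ALPHABET) -> RatioMatrix:
    """Exact-match residue kernel: 1 on the diagonal, 0 elsewhere.

    With this matrix the k-mer kernel simply counts identical k-mer pairs.
    It is invariant under any Hadamard power.
    """
    return RatioMatrix(np.eye(len(alphabet)), alphabet, beta_applied=None)


def ones_matrix(alphabet: AminoAlphabet = STANDARD_ALPHABET) -> RatioMatrix:
    """All-ones residue matrix — the analytic beta -> 0 limit.

    This is *not* a kernel (rank one, hence not positive definite) but is
    useful as a diagnostic: with it the sequence kernel depends on sequence
    lengths only.
    """
    n = len(alphabet)
    return RatioMatrix(np.ones((n, n)), alphabet, beta_applied=None)


# ---------------------------------------------------------------------------
# File I/O


def read_ncbi_matrix(
    path, alphabet: AminoAlphabet = STANDARD_ALPHABET
) -> np.ndarray:
    """Read an NCBI-style substitution matrix file (e.g. a BLOSUM file).

    Whitespace-separated table with a header row of letters and '#' comment
    lines.  Columns for ambiguity codes (B, Z, X, *) and anything else
    outside ``alphabet`` are dropped with a logged notice.  Returns the
    integer log-odds submatrix in alphabet order; feed it to
    :func:`from_log_odds` to obtain a ratio matrix.
    """
    from Bio.Align import substitution_matrices

    full = substitution_matrices.read(str(path))
    file_letters = list(full.alphabet)
    extra = [c for c in file_letters if c not in alphabet]
    if extra:
        logger.info("ignoring non-alphabet columns in %s: %s", path, " ".join(extra))
    missing = [c for c in alphabet.letters if c not in file_letters]
    if missing:
        raise MatrixError(f"matrix file {path} lacks residues: {' '.join(missing)}")
    idx = [file_letters.index(c) for c in alphabet.letters]
    sub = np.asarray(full)[np.ix_(idx, idx)]
    return np.rint(sub).astype(int)


def write_ratio_matrix(ratio: RatioMatrix, path) -> None:
    """Write a ratio matrix as a plain table with a one-line alphabet header."""
    with open(path, "w") as fh:
        fh.write(" ".join(ratio.alphabet.letters) + "\n")
        for row in ratio.values:
            fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")


def read_ratio_matrix(path) -> RatioMatrix:
    """Read a ratio matrix written by :func:`write_ratio_matrix`."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise MatrixError(f"empty matrix file: {path}")
    alphabet = AminoAlphabet(tuple(lines[0].split()))
    values = np.array([[float(v) for v in ln.split()] for ln in lines[1:]])
    return RatioMatrix(values, alphabet, beta_applied=None)


def _read_count_table(text: str) -> CountMatrix:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    alphabet = AminoAlphabet(tuple(lines[0].split()))
    counts = np.array([[float(v) for v in ln.split()] for ln in lines[1:]])
    return CountMatrix(counts, alphabet)


def read_count_matrix(path) -> CountMatrix:
    """Read a raw-count table (alphabet header line, then the square table)."""
    with open(path) as fh:
        return _read_count_table(fh.read())


def load_default_counts() -> CountMatrix:
    """Load the packaged synthetic substitution-count matrix.

    A BLOSUM-like 20x20 integer count table generated once with a strongly
    dominant diagonal, so that the normalized odds-ratio matrix is provably
    positive definite.  It is synthetic: convenient, self-contained and valid
    as a kernel, but not derived from real alignment data — substitute a real
    count or log-odds matrix for production comparisons.
    """
    text = (
        importlib.resources.files("seqkernel.data")
        .joinpath("synthetic_counts.txt")
        .read_text()
    )
    return _read_count_table(text)
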