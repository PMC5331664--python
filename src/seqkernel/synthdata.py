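"""Synthetic protein families for testing and calibration.

Real benchmark sets for fold recognition are built from structural
classifications and are not shipped here.  Instead, this module generates
"fold families" by mutating random ancestors: each family is one uniform
random ancestor sequence plus members derived from it by point
substitutions (a fixed fraction of positions redrawn) and single-residue
indels.  The families share no ancestry with each other, so group structure
is real but entirely controlled: higher substitution rates push
within-family identity toward the ~5% background of unrelated sequences.

The residue background is uniform over the 20 standard amino acids — the
simplest defensible null; substitute empirical frequencies if composition
effects matter for your use.  Indels are single-residue events: the kernel
is gap-free, so realistic affine indel blocks would add nothing the tests
could detect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernel import ProteinSequence
from .matrices import STANDARD_ALPHABET, AminoAlphabet
from .seqio import LabeledDataset


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a synthetic family set.

    Defaults give four 10-member families at 50% substitution and 5% indel
    rate, lengths 60-180 — families that are clearly divergent yet still
    separable by a k-mer kernel, with a length spread comparable to single
    protein domains.
    """

    n_families: int = 4
    members_per_family: int = 10
    ancestor_length_range: tuple[int, int] = (60, 180)
    substitution_rate: float = 0.5
    indel_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.members_per_family < 1:
            raise ValueError("need at least one family and one member")
        lo, hi = self.ancestor_length_range
        if lo < 20 or hi < lo:
            raise ValueError("ancestor lengths must satisfy 20 <= min <= max")
        for name in ("substitution_rate", "indel_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")


def random_sequence(
    length: int,
    seed: int | np.random.Generator = 0,
    id: str = "random",
    alphabet: AminoAlphabet = STANDARD_ALPHABET,
) -> ProteinSequence:
    """Uniform iid random sequence of the given length."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    residues = rng.integers(0, len(alphabet), size=length)
    return ProteinSequence(id, residues, alphabet)


def _mutate(
    ancestor: np.ndarray,
    substitution_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
    n_letters: int,
) -> np.ndarray:
    residues = ancestor.copy()
    # point substitutions: redraw to a *different* residue at selected sites
    hit = rng.random(residues.size) < substitution_rate
    if hit.any():
        shift = rng.integers(1, n_letters, size=int(hit.sum()))
        residues[hit] = (residues[hit] + shift) % n_letters
    # single-residue indels, deletions and insertions equally likely
    if indel_rate > 0:
        keep = rng.random(residues.size) >= indel_rate / 2.0
        residues = residues[keep]
        n_insert = int(rng.binomial(residues.size + 1, indel_rate / 2.0))
        if n_insert:
            positions = np.sort(rng.integers(0, residues.size + 1, size=n_insert))
            residues = np.insert(
                residues, positions, rng.integers(0, n_letters, size=n_insert)
            )
    if residues.size == 0:  # pathological high-indel draw; keep one residue
        residues = ancestor[:1].copy()
    return residues


def make_families(
    spec: FamilySpec, alphabet: AminoAlphabet = STANDARD_ALPHABET
) -> LabeledDataset:
    """Generate labelled synthetic families.

    One random ancestor per family; members are independent mutants of it.
    Group label = ``fam<N>``; member ids are ``fam<N>_m<M>``.  Output is a
    deterministic function of the spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    n_letters = len(alphabet)
    sequences: list[ProteinSequence] = []
    groups: dict[str, str] = {}
    lo, hi = spec.ancestor_length_range
    for fam in range(spec.n_families):
        label = f"fam{fam}"
        length = int(rng.integers(lo, hi + 1))
        ancestor = rng.integers(0, n_letters, size=length)
        for member in range(spec.members_per_family):
            residues = _mutate(
                ancestor, spec.substitution_rate, spec.indel_rate, rng, n_letters
            )
            sid = f"{label}_m{member}"
            sequences.append(ProteinSequence(sid, residues, alphabet))
            groups[sid] = label
    return LabeledDataset(
        sequences,
        groups,
        provenance=f"synthetic families {spec!r}",
    )
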