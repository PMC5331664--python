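"""Sequence and matrix I/O: FASTA in, pairwise tables and PHYLIP out.

The PHYLIP writer emits the classic square distance format (count line,
then one row per sequence with the name padded to 10 characters) consumed
by distance-based tree programs such as Fitch; distances are printed with
6 decimals, the PHYLIP convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .kernel import PairMatrix, ProteinSequence
from .matrices import STANDARD_ALPHABET, AminoAlphabet

_PHYLIP_NAME_WIDTH = 10


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class LabeledDataset:
    """Sequences plus an optional id -> group-label map.

    When groups are present they must cover every sequence id exactly once.
    """

    sequences: list[ProteinSequence]
    groups: dict[str, str] | None = None
    provenance: str = ""
    _ids: set = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate sequence ids in dataset")
        self._ids = set(ids)
        if self.groups is not None and set(self.groups) != self._ids:
            raise FormatError("group map must cover every sequence id exactly once")


def read_fasta(
    path,
    residue_policy: str = "strict",
    alphabet: AminoAlphabet = STANDARD_ALPHABET,
) -> list[ProteinSequence]:
    """Read protein sequences from FASTA.

    Ids are the header up to the first whitespace; sequences are uppercased
    and the nonstandard-residue policy applied (see
    :meth:`ProteinSequence.from_string`).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    seqs = [
        ProteinSequence.from_string(r.id, str(r.seq), alphabet, residue_policy)
        for r in records
    ]
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"duplicate ids in {path}: {', '.join(dup)}")
    return seqs


def write_fasta(seqs: list[ProteinSequence], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            text = str(s)
            for i in range(0, len(text), width):
                fh.write(text[i : i + width] + "\n")


def read_groups(path) -> dict[str, str]:
    """Read a two-column TSV of (sequence id, group label)."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
            if parts[0] in groups:
                raise FormatError(f"{path}:{lineno}: duplicate id {parts[0]!r}")
            groups[parts[0]] = parts[1]
    if not groups:
        raise FormatError(f"no group labels in {path}")
    return groups


def write_groups(groups: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid, label in groups.items():
            fh.write(f"{sid}\t{label}\n")


def write_pair_matrix(matrix: PairMatrix, path) -> None:
    """Write a pair matrix as a TSV square table with an id header row."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(matrix.ids) + "\n")
        for sid, row in zip(matrix.ids, matrix.values):
            fh.write(sid + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_pair_matrix(path, kind: str) -> PairMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "id":
            raise FormatError(f"{path}: expected 'id' header")
        ids = header[1:]
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append([float(v) for v in parts[1:]])
    return PairMatrix(tuple(ids), np.array(rows), kind)


def write_phylip_distance(matrix: PairMatrix, path) -> None:
    """Write a distance matrix in square PHYLIP format.

    Names are padded/truncated to 10 characters; truncation collisions are
    an error because PHYLIP identifies taxa by that field alone.
    """
    if matrix.kind != "distance":
        raise ValueError("PHYLIP export requires a distance matrix")
    short = [sid[:_PHYLIP_NAME_WIDTH] for sid in matrix.ids]
    if len(set(short)) != len(short):
        dup = sorted({s for s in short if short.count(s) > 1})
        raise FormatError(
            "ids collide after truncation to 10 characters: " + ", ".join(dup)
        )
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.ids)}\n")
        for name, row in zip(short, matrix.values):
            fh.write(name.ljust(_PHYLIP_NAME_WIDTH))
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_phylip_distance(path) -> PairMatrix:
    """Read a square PHYLIP distance matrix (round-trip check of the writer)."""
    with open(path) as fh:
        first = fh.readline().strip()
        try:
            n = int(first)
        except ValueError as exc:
            raise FormatError(f"{path}: bad taxon count line {first!r}") from exc
        ids, rows = [], []
        for _ in range(n):
            line = fh.readline()
            if not line:
                raise FormatError(f"{path}: expected {n} rows")
            ids.append(line[:_PHYLIP_NAME_WIDTH].strip())
            rows.append([float(v) for v in line[_PHYLIP_NAME_WIDTH:].split()])
    return PairMatrix(tuple(ids), np.array(rows), "distance")


def rescale_distances(matrix: PairMatrix) -> PairMatrix:
    """Scale a distance matrix so the largest distance is exactly 1.

    Used before tree building so that matrices from different measures are
    comparable; idempotent, and the diagonal stays 0.
    """
    if matrix.kind != "distance":
        raise ValueError("rescaling applies to distance matrices")
    peak = float(matrix.values.max())
    if peak <= 0:
        raise ValueError("all distances are zero; nothing to rescale")
    return PairMatrix(matrix.ids, matrix.values / peak, "distance")


def read_score_table(path) -> dict[frozenset, float]:
    """Read a three-column table (idA, idB, score) keyed by unordered pair.

    Used to ingest externally computed per-pair scores (e.g. structural
    alignment SAS values) for correlation against kernel similarities.
    Conflicting duplicate pairs are an error.
    """
    scores: dict[frozenset, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected three tab-separated columns"
                )
            a, b, raw = parts
            try:
                value = float(raw)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad score {raw!r}") from exc
            key = frozenset((a, b))
            if key in scores and scores[key] != value:
                raise FormatError(
                    f"{path}:{lineno}: conflicting scores for pair ({a}, {b})"
                )
            scores[key] = value
    return scores
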