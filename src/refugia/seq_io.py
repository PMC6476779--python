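"""Sequence alignment I/O, validation, and partitioning.

Alignments are held as integer-coded numpy matrices (one row per sequence)
so that downstream column-wise statistics vectorize cleanly.  FASTA is the
only sequence format; sample metadata (population assignment, coordinates)
travels as CSV with a header row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, DataError, FormatError

# Integer residue codes.  A,C,G,T are 0..3; N and '-' are treated as missing
# by the statistics layer.
CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
DECODE = np.array(list("ACGTN-"))
N_CODE = CODES["N"]
GAP_CODE = CODES["-"]

MITOCHONDRIAL = "mitochondrial_haploid"
NUCLEAR = "nuclear_diploid"
INHERITANCE_MODES = (MITOCHONDRIAL, NUCLEAR)

_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _ch, _code in CODES.items():
    _ENCODE_LUT[ord(_ch)] = _code
    _ENCODE_LUT[ord(_ch.lower())] = _code


def encode(seq: str) -> np.ndarray:
    """Encode a residue string to integer codes; reject illegal characters."""
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    out = _ENCODE_LUT[raw]
    if (out == 255).any():
        bad = sorted({seq[i] for i in np.nonzero(out == 255)[0]})
        raise FormatError(f"illegal residue character(s): {bad}")
    return out


def decode(row: np.ndarray) -> str:
    return "".join(DECODE[row])


@dataclass(frozen=True)
class Alignment:
    """An equal-length set of DNA sequences from one locus.

    ``matrix`` has shape (n_sequences, length) with the integer codes above.
    ``inheritance`` fixes the coalescent copy-number scaling downstream:
    mitochondrial loci carry Ne/2 gene copies per Ne diploid individuals,
    nuclear autosomal loci carry 2Ne.
    """

    sample_ids: tuple[str, ...]
    matrix: np.ndarray
    locus_name: str = "locus"
    inheritance: str = MITOCHONDRIAL

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.uint8)
        if m.ndim != 2:
            raise AlignmentError("sequence matrix must be 2-D")
        if m.shape[0] < 1:
            raise DataError("alignment must contain at least one sequence")
        if len(self.sample_ids) != m.shape[0]:
            raise AlignmentError(
                f"{len(self.sample_ids)} sample ids for {m.shape[0]} sequences"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample ids")
        if m.size and m.max() > GAP_CODE:
            raise FormatError("matrix contains codes outside {A,C,G,T,N,-}")
        if self.inheritance not in INHERITANCE_MODES:
            raise DataError(f"unknown inheritance mode {self.inheritance!r}")
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, i: int) -> str:
        return decode(self.matrix[i])

    def take(self, idx, locus_name: str | None = None) -> "Alignment":
        idx = np.asarray(idx)
        return Alignment(
            tuple(self.sample_ids[i] for i in idx),
            self.matrix[idx],
            locus_name or self.locus_name,
            self.inheritance,
        )

    @classmethod
    def from_strings(
        cls,
        sequences,
        sample_ids=None,
        locus_name: str = "locus",
        inheritance: str = MITOCHONDRIAL,
    ) -> "Alignment":
        seqs = list(sequences)
        if not seqs:
            raise DataError("empty sequence list")
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        if sample_ids is None:
            sample_ids = [f"s{i + 1}" for i in range(len(seqs))]
        matrix = np.vstack([encode(s) for s in seqs]) if seqs[0] else np.zeros(
            (len(seqs), 0), dtype=np.uint8
        )
        return cls(tuple(sample_ids), matrix, locus_name, inheritance)


@dataclass(frozen=True)
class PopulationAssignment:
    """Maps sample ids to population labels, optionally with coordinates."""

    mapping: dict[str, str]
    coordinates: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def labels(self) -> tuple[str, ...]:
        # stable order: first appearance
        seen: dict[str, None] = {}
        for lab in self.mapping.values():
            seen.setdefault(lab)
        return tuple(seen)

    def samples_for(self, label: str) -> list[str]:
        return [s for s, lab in self.mapping.items() if lab == label]


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct sequences with their multiplicities and member samples."""

    haplotypes: tuple[str, ...]
    counts: tuple[int, ...]
    members: tuple[tuple[str, ...], ...]

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


def read_alignment(
    path, locus_name: str = "locus", inheritance: str = MITOCHONDRIAL
) -> Alignment:
    """Read a FASTA alignment; residues are uppercased and validated."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataError(f"no FASTA records in {path}")
    return Alignment.from_strings(
        [str(r.seq) for r in records],
        [r.id for r in records],
        locus_name,
        inheritance,
    )


def write_alignment(alignment: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(alignment.sequence(i)), id=alignment.sample_ids[i], description="")
        for i in range(alignment.n)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_assignment(path) -> PopulationAssignment:
    """Read a sample_id,population[,lat,lon] CSV."""
    df = pd.read_csv(path, dtype={"sample_id": str, "population": str})
    for col in ("sample_id", "population"):
        if col not in df.columns:
            raise FormatError(f"assignment CSV lacks required column {col!r}")
    mapping = dict(zip(df["sample_id"], df["population"]))
    coords: dict[str, tuple[float, float]] = {}
    if {"lat", "lon"}.issubset(df.columns):
        coords = {
            s: (float(la), float(lo))
            for s, la, lo in zip(df["sample_id"], df["lat"], df["lon"])
            if np.isfinite(la) and np.isfinite(lo)
        }
    return PopulationAssignment(mapping, coords)


def write_assignment(pa: PopulationAssignment, path) -> None:
    rows = []
    for s, lab in pa.mapping.items():
        row = {"sample_id": s, "population": lab}
        if s in pa.coordinates:
            row["lat"], row["lon"] = pa.coordinates[s]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def concatenate(a: Alignment, b: Alignment) -> Alignment:
    """Join two loci sampled from the same individuals (a's sites then b's)."""
    if set(a.sample_ids) != set(b.sample_ids):
        only_a = set(a.sample_ids) - set(b.sample_ids)
        only_b = set(b.sample_ids) - set(a.sample_ids)
        raise KeyError(f"sample sets differ (only in a: {sorted(only_a)}, only in b: {sorted(only_b)})")
    if a.inheritance != b.inheritance:
        raise DataError("cannot concatenate loci with different inheritance modes")
    order = {s: i for i, s in enumerate(b.sample_ids)}
    b_rows = b.matrix[[order[s] for s in a.sample_ids]]
    return Alignment(
        a.sample_ids,
        np.hstack([a.matrix, b_rows]),
        f"{a.locus_name}+{b.locus_name}",
        a.inheritance,
    )


def collapse_haplotypes(a: Alignment) -> HaplotypeTable:
    """Group identical sequences.

    Comparison is literal: 'N' and '-' are ordinary states and never
    wildcard-match, so two sequences differing only by an N are distinct
    haplotypes.  Order follows first occurrence.
    """
    groups: dict[bytes, list[int]] = {}
    for i in range(a.n):
        groups.setdefault(a.matrix[i].tobytes(), []).append(i)
    haps, counts, members = [], [], []
    for key, idx in groups.items():
        haps.append(a.sequence(idx[0]))
        counts.append(len(idx))
        members.append(tuple(a.sample_ids[i] for i in idx))
    return HaplotypeTable(tuple(haps), tuple(counts), tuple(members))


def partition_by_population(
    a: Alignment, pa: PopulationAssignment
) -> dict[str, Alignment]:
    """Split an alignment into per-population sub-alignments."""
    missing = [s for s in a.sample_ids if s not in pa.mapping]
    if missing:
        raise KeyError(f"samples without population assignment: {missing[:5]}")
    out: dict[str, Alignment] = {}
    for label in pa.labels:
        idx = [i for i, s in enumerate(a.sample_ids) if pa.mapping[s] == label]
        if idx:
            out[label] = a.take(idx)
    return out


__all__ = [
    "Alignment",
    "PopulationAssignment",
    "HaplotypeTable",
    "read_alignment",
    "write_alignment",
    "read_assignment",
    "write_assignment",
    "concatenate",
    "collapse_haplotypes",
    "partition_by_population",
    "encode",
    "decode",
    "CODES",
    "MITOCHONDRIAL",
    "NUCLEAR",
]
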