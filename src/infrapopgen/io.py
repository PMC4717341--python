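"""Reading and validating aligned sequences, sample metadata and load tables.

The analysis operates on a single multiple-sequence alignment of COI
haplotypes (pre-aligned, pre-trimmed upstream — typically 507 bp), a
per-sample metadata table mapping each sequence to its mite species, host
bird individual and sampling locality, and a per-species table of median
infrapopulation sizes (mites per host individual).

Sites are indexed 0-based internally and 1-based in all reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import (
    AlignmentError,
    ConfigurationError,
    DuplicateIdError,
    SchemaError,
)

# A, C, G, T -> 0..3; every other symbol (N, -, IUPAC ambiguity) -> 255,
# treated as missing by all downstream statistics (pairwise deletion).
MISSING = np.uint8(255)
_CODE_TABLE = np.full(256, MISSING, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i

REQUIRED_METADATA_COLUMNS = ("sample_id", "species", "bird_id", "locality")


def _encode(seq: str) -> np.ndarray:
    return _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class Alignment:
    """Equal-length aligned nucleotide sequences keyed by sample id.

    Sequences are stored upper-case with ``U`` mapped to ``T``; gaps and
    IUPAC ambiguity codes are retained in the strings but encoded as
    missing in the numeric code matrix used by the statistics.
    """

    ids: list[str]
    seqs: list[str]
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.ids:
            raise AlignmentError("alignment is empty")
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and sequences differ in number")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        if lengths == {0}:
            raise AlignmentError("alignment has zero sites")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise DuplicateIdError(f"duplicate sequence ids: {dupes}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def codes(self) -> np.ndarray:
        """(n, L) uint8 matrix; A,C,G,T -> 0..3, anything else -> 255."""
        if self._codes is None:
            self._codes = np.vstack([_encode(s) for s in self.seqs])
        return self._codes

    def subset(self, ids: Sequence[str]) -> "Alignment":
        index = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        rows = [index[s] for s in ids]
        codes = self.codes[rows] if self._codes is not None else None
        return Alignment(
            [self.ids[i] for i in rows], [self.seqs[i] for i in rows], codes
        )

    def window(self, start: int, end: int) -> "Alignment":
        """Slice sites [start, end) using 0-based coordinates."""
        if not (0 <= start < end <= self.length):
            raise AlignmentError(f"bad window {start}:{end} for L={self.length}")
        return Alignment(list(self.ids), [s[start:end] for s in self.seqs])


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA; upper-cases and maps U->T.

    Raises :class:`AlignmentError` on ragged or empty input and
    :class:`DuplicateIdError` on repeated ids.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper().replace("U", "T") for r in records]
    return Alignment(ids, seqs)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="")
        for i, s in zip(alignment.ids, alignment.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class SampleMetadata:
    """Provenance of one sequenced mite."""

    sample_id: str
    species: str
    bird_id: str
    locality: str
    source: str = "multi_per_bird"  # or "one_per_bird"


def read_metadata(path: str | Path, sep: str = "\t") -> list[SampleMetadata]:
    """Read the per-sample metadata table (TSV/CSV with header).

    Required columns: sample_id, species, bird_id, locality. Unknown
    columns are preserved in the file but ignored here; an optional
    ``source`` column is honoured.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    return metadata_from_frame(df)


def metadata_from_frame(df: pd.DataFrame) -> list[SampleMetadata]:
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata table missing required columns: {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise DuplicateIdError(f"duplicate sample_id values: {dupes}")
    if (df["bird_id"].astype(str).str.len() == 0).any() or df["bird_id"].isna().any():
        raise SchemaError("bird_id must be non-empty for every sample")
    has_source = "source" in df.columns
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SampleMetadata(
                sample_id=str(row.sample_id),
                species=str(row.species),
                bird_id=str(row.bird_id),
                locality=str(row.locality),
                source=str(row.source) if has_source else "multi_per_bird",
            )
        )
    return out


def read_loads(path: str | Path, sep: str = "\t") -> dict[str, float]:
    """Read per-species median infrapopulation sizes (columns species, median_load)."""
    df = pd.read_csv(path, sep=sep)
    for col in ("species", "median_load"):
        if col not in df.columns:
            raise SchemaError(f"loads table missing required column: {col}")
    loads = dict(zip(df["species"].astype(str), df["median_load"].astype(float)))
    bad = {s: m for s, m in loads.items() if not m > 0}
    if bad:
        raise ConfigurationError(f"non-positive median loads: {bad}")
    return loads


@dataclass
class SpeciesDataset:
    """One mite species: its alignment, per-sample metadata, and median load."""

    species: str
    alignment: Alignment
    metadata: list[SampleMetadata]
    median_load: float

    def __post_init__(self) -> None:
        if self.median_load <= 0:
            raise ConfigurationError(
                f"{self.species}: median load must be positive, got {self.median_load}"
            )
        if self.alignment.n < 2:
            raise ConfigurationError(
                f"{self.species}: needs >= 2 sequences, got {self.alignment.n}"
            )
        meta_ids = {m.sample_id for m in self.metadata}
        missing = [i for i in self.alignment.ids if i not in meta_ids]
        if missing:
            raise SchemaError(f"{self.species}: no metadata for {missing}")

    @property
    def n(self) -> int:
        return self.alignment.n

    def birds(self) -> dict[str, list[str]]:
        """bird_id -> sample ids, in alignment order."""
        by_bird: dict[str, list[str]] = {}
        meta = {m.sample_id: m for m in self.metadata}
        for sid in self.alignment.ids:
            by_bird.setdefault(meta[sid].bird_id, []).append(sid)
        return by_bird

    @property
    def n_birds(self) -> int:
        return len(self.birds())


def build_species_datasets(
    alignment: Alignment,
    metadata: Iterable[SampleMetadata],
    loads: Mapping[str, float],
) -> list[SpeciesDataset]:
    """Assemble one dataset per species from the joined inputs.

    Metadata rows whose sample is absent from the alignment (and vice
    versa) are reported with a warning; species with fewer than two
    matched sequences are excluded with a warning. Every species present
    among the matched samples must have an entry in ``loads``.
    """
    meta = {m.sample_id: m for m in metadata}
    aligned = set(alignment.ids)
    orphan_meta = sorted(set(meta) - aligned)
    orphan_seqs = sorted(aligned - set(meta))
    if orphan_meta:
        warnings.warn(f"metadata rows without sequence: {orphan_meta}")
    if orphan_seqs:
        warnings.warn(f"sequences without metadata: {orphan_seqs}")

    by_species: dict[str, list[str]] = {}
    for sid in alignment.ids:
        if sid in meta:
            by_species.setdefault(meta[sid].species, []).append(sid)

    missing_loads = sorted(s for s in by_species if s not in loads)
    if missing_loads:
        raise ConfigurationError(f"species missing from loads table: {missing_loads}")

    datasets = []
    for species in sorted(by_species):
        ids = by_species[species]
        if len(ids) < 2:
            warnings.warn(f"{species}: only {len(ids)} sequence(s); excluded")
            continue
        datasets.append(
            SpeciesDataset(
                species=species,
                alignment=alignment.subset(ids),
                metadata=[meta[i] for i in ids],
                median_load=float(loads[species]),
            )
        )
    return datasets
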