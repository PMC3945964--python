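"""Aligned marker datasets: reading, length filtering, trimming, evaluation sets.

A reference library for barcode-based species identification is a set of
aligned sequences of one marker (COI, 16S rDNA, ITS2 or 12S rDNA), each tied
to a species name, a reliability status and a life stage.  Three evaluation
sets are derived from it:

* **set 1** — the full curated library (published, locally amplified, and
  unpublished records that survived tree-based screening);
* **set 2** — every record of a species represented by at least two records
  in set 1; these serve as queries, identified against set 1;
* **set 3** — set 1 without subadult-derived amplified records and without
  screened-in unpublished records, used to check whether distance overlaps
  are artifacts of those two record classes.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

MARKERS = ("COI", "16S", "ITS2", "12S")
STATUSES = ("published", "amplified", "unpublished", "screened-in", "screened-out")
RELIABLE_STATUSES = ("published", "amplified")
STAGES = ("adult", "subadult", "unknown")

#: IUPAC nucleotide codes plus the alignment gap character.
ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

#: Minimum ungapped length per marker (ITS2 uses a fraction of full length).
MIN_UNGAPPED = {"COI": 450, "16S": 350, "12S": 240}
ITS2_FULL_LENGTH_FRACTION = 0.70

METADATA_COLUMNS = ("id", "species", "genus", "marker", "status", "stage")


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned marker sequence with taxonomy and reliability status."""

    id: str
    species: str
    marker: str
    status: str
    stage: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty residue string")
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        for pos, ch in enumerate(residues):
            if ch not in ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos}"
                )
        if self.marker not in MARKERS:
            raise ValueError(f"record {self.id!r}: unknown marker {self.marker!r}")
        if self.status not in STATUSES:
            raise ValueError(f"record {self.id!r}: unknown status {self.status!r}")
        if self.stage not in STAGES:
            raise ValueError(f"record {self.id!r}: unknown stage {self.stage!r}")
        if not self.species.strip():
            raise ValueError(f"record {self.id!r}: empty species name")

    @property
    def genus(self) -> str:
        return self.species.split()[0]

    @property
    def ungapped_length(self) -> int:
        return len(self.residues) - self.residues.count("-")

    @property
    def reliable(self) -> bool:
        return self.status in RELIABLE_STATUSES

    def with_status(self, status: str) -> "SequenceRecord":
        if self.status not in ("unpublished",) and status != self.status:
            raise ValueError(
                f"record {self.id!r}: status may only change from 'unpublished' "
                f"(is {self.status!r})"
            )
        if status not in ("screened-in", "screened-out"):
            raise ValueError(f"invalid screening status {status!r}")
        return dataclasses.replace(self, status=status)


@dataclass(frozen=True)
class MarkerDataset:
    """An ordered set of records of one marker, optionally tagged with a role."""

    marker: str
    records: tuple[SequenceRecord, ...]
    role: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        for rec in self.records:
            if rec.marker != self.marker:
                raise ValueError(
                    f"record {rec.id!r} has marker {rec.marker!r}, dataset is {self.marker!r}"
                )
        ids = [r.id for r in self.records]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def is_aligned(self) -> bool:
        lengths = {len(r.residues) for r in self.records}
        return len(lengths) <= 1

    @property
    def alignment_length(self) -> int:
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) > 1:
            raise ValueError("records are not aligned (unequal lengths)")
        if not lengths:
            raise ValueError("empty dataset has no alignment length")
        return lengths.pop()

    def get(self, record_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(record_id)

    def subset(self, ids: Iterable[str], role: str = "custom") -> "MarkerDataset":
        wanted = set(ids)
        return MarkerDataset(
            self.marker, tuple(r for r in self.records if r.id in wanted), role
        )

    def species_counts(self) -> Counter:
        return Counter(r.species for r in self.records)

    def species_of(self) -> dict[str, str]:
        """Map record id -> species binomial."""
        return {r.id: r.species for r in self.records}

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "species": [r.species for r in self.records],
                "genus": [r.genus for r in self.records],
                "marker": [r.marker for r in self.records],
                "status": [r.status for r in self.records],
                "stage": [r.stage for r in self.records],
            }
        )

    def write_fasta(self, path: str | Path) -> None:
        bio = [
            _BioSeqRecord(Seq(r.residues), id=r.id, description="")
            for r in self.records
        ]
        SeqIO.write(bio, str(path), "fasta")

    def write_metadata(self, path: str | Path) -> None:
        self.metadata_frame().to_csv(path, sep="\t", index=False)


def read_marker_dataset(
    fasta_path: str | Path,
    metadata_path: str | Path,
    marker: str,
    role: str = "custom",
) -> MarkerDataset:
    """Read an aligned FASTA plus a tab-separated metadata table.

    The metadata table must carry columns ``id``, ``species``, ``status`` and
    ``stage`` (``genus`` and ``marker`` columns are accepted and checked for
    consistency; unknown extra columns are ignored).  Every FASTA id must have
    exactly one metadata row.
    """
    if marker not in MARKERS:
        raise ValueError(f"unknown marker {marker!r}")
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    required = {"id", "species", "status", "stage"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    if meta["id"].duplicated().any():
        dupes = meta.loc[meta["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate metadata ids: {dupes}")
    rows = meta.set_index("id")

    records = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(fasta_path), "fasta"):
        if bio.id in seen:
            raise ValueError(f"duplicate FASTA id {bio.id!r}")
        seen.add(bio.id)
        if bio.id not in rows.index:
            raise ValueError(f"FASTA id {bio.id!r} has no metadata row")
        row = rows.loc[bio.id]
        if "marker" in rows.columns and row["marker"] and row["marker"] != marker:
            raise ValueError(
                f"record {bio.id!r}: metadata marker {row['marker']!r} != {marker!r}"
            )
        records.append(
            SequenceRecord(
                id=bio.id,
                species=row["species"],
                marker=marker,
                status=row["status"] or "published",
                stage=row["stage"] or "unknown",
                residues=str(bio.seq),
            )
        )
    return MarkerDataset(marker, tuple(records), role)


def default_its2_full_length(dataset: MarkerDataset) -> int:
    """Default ITS2 full length: the longest ungapped record in the dataset."""
    if not len(dataset):
        raise ValueError("empty dataset has no default full length")
    return max(r.ungapped_length for r in dataset)


def filter_by_length(
    dataset: MarkerDataset, full_length: int | None = None
) -> MarkerDataset:
    """Drop records below the per-marker minimum ungapped length.

    COI < 450, 16S < 350 and 12S < 240 ungapped bases are removed; ITS2
    records covering less than 70% of ``full_length`` are removed
    (``full_length`` is required for ITS2).  Lengths are ungapped residue
    counts: gaps are alignment artifacts, not sequence.
    """
    if dataset.marker == "ITS2":
        if full_length is None:
            raise ValueError("filtering ITS2 requires full_length")
        cutoff = ITS2_FULL_LENGTH_FRACTION * full_length
    else:
        cutoff = MIN_UNGAPPED[dataset.marker]
    kept = tuple(r for r in dataset if r.ungapped_length >= cutoff)
    removed = len(dataset) - len(kept)
    if removed:
        logger.info(
            "filter_by_length(%s): removed %d of %d records below %.1f ungapped bases",
            dataset.marker, removed, len(dataset), cutoff,
        )
    return MarkerDataset(dataset.marker, kept, dataset.role)


def trim_to_common_region(dataset: MarkerDataset, min_columns: int = 50) -> MarkerDataset:
    """Trim leading/trailing columns so every record spans the full region.

    The shared region runs from the latest first non-gap column to the
    earliest last non-gap column over all records; internal gaps are left
    untouched.  Fails if fewer than ``min_columns`` columns would remain,
    which guards against alignments of disjoint fragments.
    """
    if not len(dataset):
        return dataset
    length = dataset.alignment_length  # raises if unaligned
    start = 0
    stop = length
    for rec in dataset:
        res = rec.residues
        first = len(res) - len(res.lstrip("-"))
        last = len(res.rstrip("-"))
        if first >= last:
            raise ValueError(f"record {rec.id!r} is all gaps")
        start = max(start, first)
        stop = min(stop, last)
    if stop - start < min_columns:
        raise ValueError(
            f"common region has {max(stop - start, 0)} columns "
            f"(< {min_columns}); records look like disjoint fragments"
        )
    if start == 0 and stop == length:
        return dataset
    trimmed = tuple(
        dataclasses.replace(r, residues=r.residues[start:stop]) for r in dataset
    )
    return MarkerDataset(dataset.marker, trimmed, dataset.role)


def build_evaluation_sets(
    dataset: MarkerDataset,
) -> tuple[MarkerDataset, MarkerDataset, MarkerDataset]:
    """Assemble evaluation sets 1, 2 and 3 from a screened dataset.

    Records still carrying status ``unpublished`` (i.e. never screened) are
    excluded from all three sets, as are ``screened-out`` records.
    """
    set1_records = tuple(
        r for r in dataset if r.status in ("published", "amplified", "screened-in")
    )
    counts = Counter(r.species for r in set1_records)
    set2_records = tuple(r for r in set1_records if counts[r.species] >= 2)
    set3_records = tuple(
        r
        for r in set1_records
        if r.status != "screened-in"
        and not (r.status == "amplified" and r.stage == "subadult")
    )
    return (
        MarkerDataset(dataset.marker, set1_records, "set1"),
        MarkerDataset(dataset.marker, set2_records, "set2"),
        MarkerDataset(dataset.marker, set3_records, "set3"),
    )
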