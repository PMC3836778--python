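"""FASTA / label-file I/O and dataset curation filters.

The training table pairs curated protein sequences (signal peptides already
removed upstream with dedicated tools, redundancy-reduced, membrane proteins
excluded — all external preprocessing recorded only as provenance) with a
binary label: secreted into the culture supernatant (1) or not (0). The one
in-scope curation filter is the minimum-length rule: proteins shorter than
50 residues are excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import DatasetError

MIN_LENGTH_DEFAULT = 50


@dataclass
class LabeledRecord:
    id: str
    sequence: str
    label: int  # 1 = secreted, 0 = not secreted


@dataclass
class LabeledDataset:
    """Curated two-class sequence set ready for encoding and training."""

    records: list[LabeledRecord]
    provenance: str = ""
    filter_log: dict[str, int] = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[int]:
        return [r.label for r in self.records]

    def class_counts(self) -> tuple[int, int]:
        """(n_positive, n_negative)."""
        pos = sum(r.label == 1 for r in self.records)
        return pos, len(self.records) - pos

    def __len__(self) -> int:
        return len(self.records)

    def dump_filter_log(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.filter_log, indent=2) + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercased sequence) pairs.

    The id is the first whitespace-delimited header token; wrapped sequence
    lines are joined. Duplicate ids and empty records are errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DatasetError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise DatasetError(f"empty sequence for FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, seq))
    if not records:
        raise DatasetError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    seq_records = [
        SeqRecord(Seq(seq), id=seq_id, description="") for seq_id, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_label_table(path: str | Path) -> dict[str, int]:
    """Two-column tab-separated (id, 0/1) label file; '#' comments allowed."""
    labels: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise DatasetError(f"{path}:{lineno}: expected two tab-separated columns")
        seq_id, value = parts
        if value not in ("0", "1"):
            raise DatasetError(f"{path}:{lineno}: label must be 0 or 1, got {value!r}")
        if seq_id in labels:
            raise DatasetError(f"{path}:{lineno}: duplicate label for id {seq_id!r}")
        labels[seq_id] = int(value)
    if not labels:
        raise DatasetError(f"no labels found in {path}")
    return labels


def write_label_table(labels: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, label in labels.items():
            fh.write(f"{seq_id}\t{int(label)}\n")


def apply_filters(
    records: list[tuple[str, str]], min_length: int = MIN_LENGTH_DEFAULT
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Apply the in-scope curation filters.

    Retains records of length >= ``min_length`` (the default mirrors the
    exclusion of proteins shorter than 50 residues). Returns the retained
    records and a filter log counting removals per reason; retained +
    removed always equals the input count.
    """
    kept = [(i, s) for i, s in records if len(s) >= min_length]
    log = {"input": len(records), "short": len(records) - len(kept), "retained": len(kept)}
    if not kept:
        raise DatasetError(
            f"all {len(records)} records shorter than min_length={min_length}"
        )
    return kept, log


def attach_labels(
    records: list[tuple[str, str]],
    label_table: Mapping[str, int],
    provenance: str = "",
    filter_log: dict[str, int] | None = None,
) -> LabeledDataset:
    """Join sequences with their labels into a :class:`LabeledDataset`.

    Every record id must be present in the label table; no resampling or
    rebalancing is applied, so imbalanced sets load as-is.
    """
    missing = [i for i, _ in records if i not in label_table]
    if missing:
        raise DatasetError(f"no label for id(s): {', '.join(missing[:10])}")
    ds = LabeledDataset(
        records=[LabeledRecord(i, s, int(label_table[i])) for i, s in records],
        provenance=provenance,
        filter_log=dict(filter_log or {}),
    )
    return ds


def load_dataset(
    fasta_path: str | Path,
    label_path: str | Path,
    min_length: int = MIN_LENGTH_DEFAULT,
    provenance: str = "",
) -> LabeledDataset:
    """read_fasta -> apply_filters -> attach_labels, in one call."""
    records = read_fasta(fasta_path)
    kept, log = apply_filters(records, min_length=min_length)
    return attach_labels(kept, read_label_table(label_path), provenance=provenance, filter_log=log)
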