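"""Dataset and results I/O.

Canonical dataset format is a UTF-8 TSV with header
``mirna_id  mirna_seq  site_id  site_seq  label``.  A FASTA_PAIR variant
reads/writes ``<prefix>.mirna.fa`` + ``<prefix>.sites.fa`` (matched record
order) plus ``<prefix>.labels.tsv``.  All numeric results are serialised
with 6 significant digits for diff-stable golden files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequence_encoding import InvalidSequenceError, normalize_sequence
from .synthetic_data import DuplexRecord

__all__ = [
    "DatasetTable",
    "DatasetFormatError",
    "read_dataset",
    "write_dataset",
    "write_results",
    "write_predictions",
    "write_training_log",
]

DATASET_COLUMNS = ("mirna_id", "mirna_seq", "site_id", "site_seq", "label")


class DatasetFormatError(ValueError):
    """Malformed dataset file (bad header, row, label, sequence or key)."""


@dataclass
class DatasetTable:
    """Ordered duplex records with optional per-record split tags."""

    records: list[DuplexRecord]
    splits: list[str] | None = field(default=None)

    def __post_init__(self):
        seen = set()
        for r in self.records:
            key = (r.mirna_id, r.site_id)
            if key in seen:
                raise DatasetFormatError(f"duplicate record key {key}")
            seen.add(key)
        if self.splits is not None and len(self.splits) != len(self.records):
            raise DatasetFormatError("split tags and records differ in length")

    def __len__(self) -> int:
        return len(self.records)

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])


def _parse_label(raw: str, line_no: int) -> int:
    if raw not in ("0", "1"):
        raise DatasetFormatError(f"line {line_no}: label must be 0 or 1, got {raw!r}")
    return int(raw)


def _validated_record(fields: list[str], line_no: int) -> DuplexRecord:
    mirna_id, mirna_seq, site_id, site_seq, label = fields
    try:
        mirna_seq = normalize_sequence(mirna_seq)
        site_seq = normalize_sequence(site_seq)
    except InvalidSequenceError as exc:
        raise DatasetFormatError(
            f"line {line_no} (record {mirna_id!r}/{site_id!r}): {exc}") from exc
    return DuplexRecord(mirna_id=mirna_id, mirna_seq=mirna_seq,
                        site_id=site_id, site_seq=site_seq,
                        label=_parse_label(label, line_no))


def _read_tsv(path: Path) -> DatasetTable:
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise DatasetFormatError(f"{path}: empty file")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != DATASET_COLUMNS:
        raise DatasetFormatError(
            f"{path}: bad header {header}, expected {DATASET_COLUMNS}")
    records = []
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise DatasetFormatError(
                f"line {line_no}: expected 5 tab-separated fields, got {len(fields)}")
        records.append(_validated_record(fields, line_no))
    return DatasetTable(records=records)


def _read_fasta_pair(prefix: Path) -> DatasetTable:
    mirna_path = Path(f"{prefix}.mirna.fa")
    site_path = Path(f"{prefix}.sites.fa")
    label_path = Path(f"{prefix}.labels.tsv")
    for p in (mirna_path, site_path, label_path):
        if not p.exists():
            raise FileNotFoundError(p)
    mirnas = list(SeqIO.parse(str(mirna_path), "fasta"))
    sites = list(SeqIO.parse(str(site_path), "fasta"))
    labels = [ln for ln in label_path.read_text().splitlines() if ln.strip()]
    if not (len(mirnas) == len(sites) == len(labels)):
        raise DatasetFormatError(
            f"FASTA_PAIR record counts differ: {len(mirnas)} miRNA, "
            f"{len(sites)} sites, {len(labels)} labels")
    records = []
    for i, (mr, sr, raw) in enumerate(zip(mirnas, sites, labels), start=1):
        records.append(_validated_record(
            [mr.id, str(mr.seq), sr.id, str(sr.seq), raw.strip()], i))
    return DatasetTable(records=records)


def read_dataset(path: str | Path, format: str = "TSV") -> DatasetTable:
    """Load a dataset; raises DatasetFormatError with the offending line."""
    path = Path(path)
    if format == "TSV":
        if not path.exists():
            raise FileNotFoundError(path)
        return _read_tsv(path)
    if format == "FASTA_PAIR":
        return _read_fasta_pair(path)
    raise ValueError(f"unknown dataset format {format!r}")


def write_dataset(table: DatasetTable | Sequence[DuplexRecord],
                  path: str | Path, format: str = "TSV") -> None:
    records = table.records if isinstance(table, DatasetTable) else list(table)
    path = Path(path)
    if format == "TSV":
        with path.open("w", encoding="utf-8") as fh:
            fh.write("\t".join(DATASET_COLUMNS) + "\n")
            for r in records:
                fh.write(f"{r.mirna_id}\t{r.mirna_seq}\t{r.site_id}\t{r.site_seq}\t{r.label}\n")
        return
    if format == "FASTA_PAIR":
        SeqIO.write([SeqRecord(Seq(r.mirna_seq), id=r.mirna_id, description="")
                     for r in records], f"{path}.mirna.fa", "fasta")
        SeqIO.write([SeqRecord(Seq(r.site_seq), id=r.site_id, description="")
                     for r in records], f"{path}.sites.fa", "fasta")
        Path(f"{path}.labels.tsv").write_text(
            "".join(f"{r.label}\n" for r in records))
        return
    raise ValueError(f"unknown dataset format {format!r}")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if isinstance(x, (float, np.floating)):
        return f"{x:.6g}"
    return str(x)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_results(out_dir: str | Path, replicate_table: pd.DataFrame,
                  summary: pd.DataFrame,
                  predictions: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write replicates.tsv, summary.tsv and optionally predictions.tsv."""
    if len(replicate_table) == 0:
        raise ValueError("empty replicate table: nothing to summarize or write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"replicates": out_dir / "replicates.tsv",
             "summary": out_dir / "summary.tsv"}
    _write_tsv(replicate_table, paths["replicates"])
    _write_tsv(summary, paths["summary"])
    if predictions is not None:
        paths["predictions"] = out_dir / "predictions.tsv"
        _write_tsv(predictions, paths["predictions"])
    return paths


def write_predictions(records: Sequence[DuplexRecord], probabilities: np.ndarray,
                      path: str | Path) -> pd.DataFrame:
    """Predictions TSV: record key, probability_positive, predicted_label."""
    prob_pos = np.asarray(probabilities)[:, 1]
    df = pd.DataFrame({
        "mirna_id": [r.mirna_id for r in records],
        "site_id": [r.site_id for r in records],
        "probability_positive": prob_pos,
        "predicted_label": (prob_pos >= 0.5).astype(int),
    })
    _write_tsv(df, Path(path))
    return df


def write_training_log(log_df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(log_df, Path(path))
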