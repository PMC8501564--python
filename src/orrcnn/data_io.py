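"""Readers, writers and dataset-preparation rules for sequences and scored pairs.

Inputs are plain FASTA files and tab-separated pair tables
(``id1<TAB>id2<TAB>score``, score strictly inside (0, 1)); the preparation
pipeline is length filtering, per-label balanced subsampling and a stratified
train/test split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by one-letter code.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Symbols tolerated in input sequences but embedded as zero vectors.
UNKNOWN_RESIDUES = frozenset("XBZU")

#: Sequence-length bounds applied when preparing a dataset.
MIN_LENGTH = 50
MAX_LENGTH = 2000


class FastaParseError(ValueError):
    """Raised for structurally invalid FASTA input, with a line reference."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus its residue string.

    Residues must come from the 20-letter amino-acid alphabet; the symbols
    X, B, Z, U are tolerated (flagged via :attr:`has_unknown`) and embed to
    zero vectors downstream.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise FastaParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - set(ALPHABET) - UNKNOWN_RESIDUES
        if bad:
            raise FastaParseError(
                f"record {self.id!r}: invalid residue symbol(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def has_unknown(self) -> bool:
        return any(c in UNKNOWN_RESIDUES for c in self.residues)


@dataclass(frozen=True)
class ScoredPair:
    """Two protein identifiers with a confidence score in the open (0, 1).

    ``label`` is the 1-based sub-interval index assigned once a partition is
    chosen; it stays ``None`` until then.
    """

    id1: str
    id2: str
    score: float
    label: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.score < 1.0:
            raise ValueError(f"score {self.score} outside the open interval (0, 1)")

    def with_label(self, label: int) -> "ScoredPair":
        return replace(self, label=label)


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    The id is the header token before the first whitespace; sequences are
    uppercased. Multi-line sequences are supported. Raises
    :class:`FastaParseError` on sequence data before the first header or on
    residues outside the alphabet.
    """
    records: list[ProteinRecord] = []
    # Detect sequence-before-header explicitly so the error names a line.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: sequence data before first header"
                    )
                break
    for entry in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(id=entry.id, residues=str(entry.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_pair_table(path, header: bool = False) -> list[ScoredPair]:
    """Read a scored-pair TSV (``id1  id2  score``; extra columns ignored).

    Rows whose score falls outside the open interval (0, 1) are rejected and
    counted in a log message; a non-numeric score raises a row-level error.
    """
    df = pd.read_csv(
        path, sep="\t", header=0 if header else None, dtype=str, comment=None
    )
    if df.shape[1] < 3:
        raise ValueError(f"{path}: pair table needs >=3 columns, found {df.shape[1]}")
    pairs: list[ScoredPair] = []
    rejected = 0
    offset = 2 if header else 1  # 1-based line number of the first data row
    for i, row in enumerate(df.itertuples(index=False)):
        id1, id2, raw = str(row[0]), str(row[1]), row[2]
        try:
            score = float(raw)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: line {i + offset}: non-numeric score {raw!r}"
            ) from None
        if not 0.0 < score < 1.0:
            rejected += 1
            continue
        pairs.append(ScoredPair(id1=id1, id2=id2, score=score))
    if rejected:
        logger.warning("%s: rejected %d rows with score outside (0, 1)", path, rejected)
    return pairs


def write_pair_table(pairs: Iterable[ScoredPair], path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.id1}\t{p.id2}\t{p.score:.6f}\n")


def filter_by_length(
    records: Sequence[ProteinRecord],
    min_len: int = MIN_LENGTH,
    max_len: int = MAX_LENGTH,
) -> list[ProteinRecord]:
    """Keep records with min_len <= length <= max_len, preserving order."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in records if min_len <= len(r) <= max_len]


def balance_subsample(
    pairs: Sequence[ScoredPair], cap: int, seed: int
) -> list[ScoredPair]:
    """Cap each ordinal label at ``cap`` pairs by uniform sampling without
    replacement; labels at or under the cap are kept whole. Deterministic
    given ``seed``; output preserves the input order of the kept pairs.
    """
    if cap <= 0:
        raise ValueError(f"cap must be positive, got {cap}")
    _require_labels(pairs)
    rng = np.random.default_rng(seed)
    by_label: dict[int, list[int]] = {}
    for i, p in enumerate(pairs):
        by_label.setdefault(p.label, []).append(i)
    keep: set[int] = set()
    for label in sorted(by_label):
        idx = by_label[label]
        if len(idx) > cap:
            keep.update(rng.choice(idx, size=cap, replace=False).tolist())
        else:
            keep.update(idx)
    return [p for i, p in enumerate(pairs) if i in keep]


def split_train_test(
    pairs: Sequence[ScoredPair], train_fraction: float, seed: int
) -> tuple[list[ScoredPair], list[ScoredPair]]:
    """Stratified train/test split: per label, round(fraction * n) pairs go to
    the training set, rounding half-counts up so ties land in training; the
    rest go to test. The two outputs partition the input. A label with fewer
    than two members goes wholly to train with a warning.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    _require_labels(pairs)
    rng = np.random.default_rng(seed)
    by_label: dict[int, list[int]] = {}
    for i, p in enumerate(pairs):
        by_label.setdefault(p.label, []).append(i)
    train_idx: set[int] = set()
    for label in sorted(by_label):
        idx = np.array(by_label[label])
        if len(idx) < 2:
            logger.warning("label %d has <2 members; all assigned to train", label)
            train_idx.update(idx.tolist())
            continue
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))  # ties to train
        perm = rng.permutation(len(idx))
        train_idx.update(idx[perm[:n_train]].tolist())
    train = [p for i, p in enumerate(pairs) if i in train_idx]
    test = [p for i, p in enumerate(pairs) if i not in train_idx]
    return train, test


def write_predictions(preds, path) -> None:
    """Write predictions as TSV with a header line.

    Columns: id1, id2, rank, confidence_score (>=4 decimals so K=20 interval
    mid-points stay distinguishable), ppi_call.
    """
    with open(path, "w") as fh:
        fh.write("id1\tid2\trank\tconfidence_score\tppi_call\n")
        for p in preds:
            call = "" if p.call is None else str(int(p.call))
            fh.write(f"{p.id1}\t{p.id2}\t{p.rank}\t{p.score:.6f}\t{call}\n")


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"id1", "id2", "rank", "confidence_score", "ppi_call"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing prediction columns {sorted(missing)}")
    return df


def _require_labels(pairs: Iterable[ScoredPair]) -> None:
    for p in pairs:
        if p.label is None:
            raise ValueError(f"pair ({p.id1}, {p.id2}) has no ordinal label")
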