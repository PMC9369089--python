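"""Reading, validating and writing labeled 41-bp DNA sequence datasets.

Datasets arrive as a pair of FASTA files — one per class, positives first —
following the packaging convention of the 6mA benchmark collections
(rice-Lv, F. vesca, R. chinensis, A. thaliana).  Every window is a fixed
length (41 bp by default) over the strict {A,C,G,T} alphabet; the candidate
adenine sits at the central position.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger("sixmanet")

#: Default window length in base pairs.  All downstream shapes (41x8 encoded
#: matrix, 328-long flattened vector) derive from this constant.
WINDOW_LENGTH = 41

#: Strict nucleotide alphabet; IUPAC ambiguity codes (including N) are
#: rejected because the encoders define values for exactly these four bases.
ALPHABET = frozenset("ACGT")


class SequenceValidationError(ValueError):
    """A record failed length or alphabet validation; names the record."""


class FastaParseError(ValueError):
    """The file is not parseable FASTA."""


@dataclass(frozen=True)
class DnaSequence:
    """A validated fixed-length DNA window."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """Sequences paired with binary labels (1 = 6mA, 0 = non-6mA)."""

    sequences: list[DnaSequence]
    labels: list[int]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise ValueError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def positive_count(self) -> int:
        return sum(self.labels)

    @property
    def negative_count(self) -> int:
        return len(self.labels) - self.positive_count


def validate_sequence(
    record_id: str, residues: str, length: int = WINDOW_LENGTH
) -> DnaSequence:
    """Uppercase and validate one record; raise naming the record on failure."""
    residues = residues.upper()
    if len(residues) != length:
        raise SequenceValidationError(
            f"record '{record_id}': length {len(residues)} != required {length}"
        )
    bad = set(residues) - ALPHABET
    if bad:
        raise SequenceValidationError(
            f"record '{record_id}': invalid characters {sorted(bad)}"
        )
    # The 6mA benchmarks center the candidate adenine; a non-A center is
    # legal input (the negatives' construction is not documented) but worth
    # flagging.
    center = length // 2
    if residues[center] != "A":
        logger.warning(
            "record '%s' has %s (not A) at central position %d",
            record_id,
            residues[center],
            center + 1,
        )
    return DnaSequence(id=record_id, residues=residues)


def read_fasta(
    path: str | Path,
    length: int = WINDOW_LENGTH,
    skip_invalid: bool = False,
) -> list[DnaSequence]:
    """Read and validate all records of a FASTA file, preserving order.

    With ``skip_invalid`` records failing validation are dropped and counted
    (logged) instead of raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[DnaSequence] = []
    dropped = 0
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython signals malformed FASTA this way
        raise FastaParseError(f"{path}: {exc}") from exc
    for rec in records:
        try:
            out.append(validate_sequence(rec.id, str(rec.seq), length=length))
        except SequenceValidationError:
            if not skip_invalid:
                raise
            dropped += 1
    if dropped:
        logger.warning("%s: dropped %d invalid record(s)", path, dropped)
    return out


def load_dataset(
    pos_path: str | Path,
    neg_path: str | Path,
    length: int = WINDOW_LENGTH,
    skip_invalid: bool = False,
    name: str = "",
) -> LabeledDataset:
    """Load a positive/negative FASTA pair into one dataset.

    Positives come first with label 1, then negatives with label 0.  Labels
    are tied to file identity, not to header parsing.
    """
    try:
        pos = read_fasta(pos_path, length=length, skip_invalid=skip_invalid)
    except (ValueError, FileNotFoundError) as exc:
        raise type(exc)(f"positive file: {exc}") from exc
    try:
        neg = read_fasta(neg_path, length=length, skip_invalid=skip_invalid)
    except (ValueError, FileNotFoundError) as exc:
        raise type(exc)(f"negative file: {exc}") from exc
    if not pos:
        logger.warning("positive file %s contains no records", pos_path)
    if not neg:
        logger.warning("negative file %s contains no records", neg_path)
    return LabeledDataset(
        sequences=pos + neg,
        labels=[1] * len(pos) + [0] * len(neg),
        name=name or Path(pos_path).stem,
    )


def write_fasta(sequences: Iterable[DnaSequence], path: str | Path) -> None:
    """Write sequences as plain single-line FASTA."""
    path = Path(path)
    with path.open("w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n{seq.residues}\n")


def write_predictions(
    records: Sequence[tuple[str, float, str]], path: str | Path
) -> None:
    """Write (id, score, call) rows as CSV with a header, input order kept.

    Scores must lie in [0,1]; calls are the class names '6mA' / 'non-6mA'.
    """
    for rid, score, call in records:
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"record '{rid}': score {score} outside [0,1]")
        if call not in ("6mA", "non-6mA"):
            raise ValueError(f"record '{rid}': unknown call '{call}'")
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "score", "call"])
        for rid, score, call in records:
            writer.writerow([rid, f"{score:.6f}", call])


def read_predictions(path: str | Path) -> list[tuple[str, float, str]]:
    """Read back a predictions CSV written by :func:`write_predictions`."""
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["id", "score", "call"]:
            raise ValueError(f"{path}: unexpected header {header}")
        return [(rid, float(score), call) for rid, score, call in reader]
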