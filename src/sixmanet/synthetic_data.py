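"""Motif-planted synthetic 41-bp datasets for exercising the pipeline.

Real 6mA benchmark windows are genomic; this generator instead plants a
short motif (GAGG by default, the context enriched around rice 6mA sites)
at a fixed offset in class-dependent proportions on an i.i.d. background,
which gives a dataset whose separability is known by construction:

* ``signal_strength = 1`` — every positive carries the motif at the
  offset and no negative does: fully separable;
* ``signal_strength = 0.5`` — both classes carry it with probability 1/2:
  the classes are exchangeable, a clean chance-level null fixture.

The central position is forced to adenine by default, mimicking the
candidate-site convention of the benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import DnaSequence, LabeledDataset, WINDOW_LENGTH, write_fasta

BASES = np.array(list("ACGT"))


class SpecError(ValueError):
    """The synthetic specification is internally inconsistent."""


@dataclass
class SyntheticSpec:
    n_pos: int = 1000
    n_neg: int = 1000
    motif: str = "GAGG"
    motif_offset: int = 10
    signal_strength: float = 1.0
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    central_adenine: bool = True
    length: int = WINDOW_LENGTH
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if abs(sum(self.background) - 1.0) > 1e-12:
            raise SpecError("background composition must sum to 1")
        if not 0 <= self.motif_offset <= self.length - len(self.motif):
            raise SpecError(
                f"motif offset {self.motif_offset} out of range for "
                f"{len(self.motif)}-mer in {self.length}-bp window"
            )
        if not 0.0 <= self.signal_strength <= 1.0:
            raise SpecError("signal_strength must lie in [0,1]")
        if set(self.motif) - set("ACGT"):
            raise SpecError("motif must be over ACGT")
        center = self.length // 2
        if (self.central_adenine
                and self.motif_offset <= center < self.motif_offset + len(self.motif)
                and self.motif[center - self.motif_offset] != "A"):
            raise SpecError(
                "motif would overwrite the forced central adenine with "
                f"'{self.motif[center - self.motif_offset]}'"
            )


def _one_sequence(spec: SyntheticSpec, rng: np.random.Generator,
                  plant: bool) -> str:
    center = spec.length // 2
    chars = rng.choice(BASES, size=spec.length, p=spec.background)
    if spec.central_adenine:
        chars[center] = "A"
    lo, hi = spec.motif_offset, spec.motif_offset + len(spec.motif)
    if plant:
        chars[lo:hi] = list(spec.motif)
        if spec.central_adenine:
            chars[center] = "A"  # guaranteed compatible by spec validation
    else:
        # guarantee absence of the motif at the planting offset
        free = [i for i in range(lo, hi)
                if not (spec.central_adenine and i == center)]
        if not free and "".join(chars[lo:hi]) == spec.motif:
            raise SpecError("cannot avoid a motif fixed entirely by the central A")
        for _ in range(1000):
            if "".join(chars[lo:hi]) != spec.motif:
                break
            j = free[int(rng.integers(len(free)))]
            chars[j] = rng.choice(BASES, p=spec.background)
        else:  # pragma: no cover - probability ~0 with any non-degenerate background
            raise SpecError("failed to avoid the motif at the planting offset")
    return "".join(chars)


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Generate n_pos + n_neg windows, reproducible under the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    sequences: list[DnaSequence] = []
    labels: list[int] = []
    for label, count, tag in ((1, spec.n_pos, "pos"), (0, spec.n_neg, "neg")):
        p_motif = spec.signal_strength if label == 1 else 1.0 - spec.signal_strength
        for i in range(count):
            plant = bool(rng.random() < p_motif)
            residues = _one_sequence(spec, rng, plant)
            sequences.append(DnaSequence(id=f"{spec.name}_{tag}_{i}", residues=residues))
            labels.append(label)
    return LabeledDataset(sequences=sequences, labels=labels, name=spec.name)


def write_fixture(dataset: LabeledDataset, directory: str | Path) -> tuple[Path, Path]:
    """Write the dataset as a positive/negative FASTA pair.

    File names derive deterministically from the dataset name; the pair is
    directly consumable by :func:`sixmanet.sequence_io.load_dataset`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pos_path = directory / f"{dataset.name}_pos.fasta"
    neg_path = directory / f"{dataset.name}_neg.fasta"
    pos = [s for s, l in zip(dataset.sequences, dataset.labels) if l == 1]
    neg = [s for s, l in zip(dataset.sequences, dataset.labels) if l == 0]
    write_fasta(pos, pos_path)
    write_fasta(neg, neg_path)
    return pos_path, neg_path
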