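"""Label-preserving data augmentation by local-mean downsampling.

Each original feature matrix spawns a level-1 variant (column-wise means of
non-overlapping row pairs, floor(n/2) rows) and a level-2 variant (the same
pairwise averaging applied to the level-1 rows, floor(floor(n/2)/2) rows).
Averaging sorted columns keeps them sorted and means never escape the
parent's column hull, so the variants are lower-resolution views of the same
motion — new training samples with the parent's labels.  A seeded per-class
shuffle then randomizes sample order before splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .exceptions import ConfigurationError, DegenerateInputError
from .features import (
    PROVENANCE_LEVEL1,
    PROVENANCE_LEVEL2,
    PROVENANCE_ORIGINAL,
    SpectralFeatureMatrix,
)


@dataclass
class AugmentedDataset:
    """An ordered pool of labeled feature matrices with provenance tags."""

    samples: list = field(default_factory=list)
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, i):
        return self.samples[i]

    @property
    def class_labels(self) -> list:
        return [s.class_label for s in self.samples]

    @property
    def subjects(self) -> list:
        return sorted({s.subject_id for s in self.samples})

    def by_provenance(self, provenance: str) -> list:
        return [s for s in self.samples if s.provenance == provenance]


def _pairwise_row_means(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    k = n // 2
    return (values[0 : 2 * k : 2] + values[1 : 2 * k : 2]) / 2.0


def downsample_level1(
    m: SpectralFeatureMatrix, sliding: bool = False
) -> SpectralFeatureMatrix:
    """Level-1 variant: column-wise mean of consecutive row pairs.

    Non-overlapping pairs (stride 2) by default; ``sliding=True`` averages
    every adjacent pair instead (n-1 rows).
    """
    if m.provenance != PROVENANCE_ORIGINAL:
        raise ConfigurationError(
            f"level-1 downsampling expects an original sample, got {m.provenance}"
        )
    if m.n_rows < 2:
        raise DegenerateInputError("level-1 downsampling needs at least 2 rows")
    if sliding:
        values = (m.values[:-1] + m.values[1:]) / 2.0
    else:
        values = _pairwise_row_means(m.values)
    return m.with_values(values, PROVENANCE_LEVEL1)


def downsample_level2(m1: SpectralFeatureMatrix) -> SpectralFeatureMatrix:
    """Level-2 variant: pairwise row averaging applied to a level-1 sample.

    Columns 1-2 of the result are the acceleration-derived MC pair and
    columns 3-4 the gyroscope-derived MD pair.
    """
    if m1.provenance != PROVENANCE_LEVEL1:
        raise ConfigurationError(
            f"level-2 downsampling expects a level-1 sample, got {m1.provenance}"
        )
    if m1.n_rows < 2:
        raise DegenerateInputError("level-2 downsampling needs at least 2 rows")
    return m1.with_values(_pairwise_row_means(m1.values), PROVENANCE_LEVEL2)


def augment(
    samples: Iterable[SpectralFeatureMatrix],
    levels: Sequence[int] = (1, 2),
    sliding: bool = False,
) -> AugmentedDataset:
    """Originals plus the requested downsampling levels, in stable order.

    With both levels and n >= 4 rows per original, the dataset size exactly
    triples.
    """
    levels = tuple(levels)
    if any(lv not in (1, 2) for lv in levels):
        raise ConfigurationError(f"levels must be drawn from (1, 2), got {levels}")
    if 2 in levels and 1 not in levels:
        raise ConfigurationError("level 2 requires level 1")
    out: list = []
    for m in samples:
        out.append(m)
        if 1 in levels:
            m1 = downsample_level1(m, sliding=sliding)
            out.append(m1)
            if 2 in levels:
                out.append(downsample_level2(m1))
    return AugmentedDataset(samples=out)


def randomize_within_class(ds: AugmentedDataset, seed: int) -> AugmentedDataset:
    """Seeded interline randomization: permute sample order within each class.

    Positions occupied by each class are preserved; which sample of that
    class sits at each position is shuffled.  The per-class multiset of
    samples is unchanged and the permutation is reproducible from the seed.
    """
    rng = np.random.default_rng(seed)
    samples = list(ds.samples)
    order = {}
    for i, s in enumerate(samples):
        order.setdefault(s.class_label, []).append(i)
    # iterate classes in first-appearance order for a stable seed contract
    out = list(samples)
    for label, idxs in order.items():
        perm = rng.permutation(len(idxs))
        for slot, j in zip(idxs, perm):
            out[slot] = samples[idxs[j]]
    return AugmentedDataset(samples=out, seed=seed)
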