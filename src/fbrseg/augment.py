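"""Train/validation splitting and the eightfold dihedral augmentation.

Augmentation happens strictly after splitting so that the eight variants of
one source image never straddle the train/validation boundary.  The eight
variants are the full D4 orbit of a square image: four 90-degree rotations
of the original and of its left-right mirror.  No elastic deformation,
rescaling or noise injection is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

Sample = tuple  # (image, mask[, weight_map]) of aligned 2D arrays


@dataclass
class SplitDataset:
    train: list
    val: list
    seed: int


def split_dataset(samples: list, train_count: int, seed: int = 0) -> SplitDataset:
    """Random, reproducible partition into exactly ``train_count`` training samples."""
    n = len(samples)
    if not 0 < train_count < n:
        raise ValueError(f"train_count must be in (0, {n}), got {train_count}")
    order = np.random.default_rng(seed).permutation(n)
    train = [samples[i] for i in order[:train_count]]
    val = [samples[i] for i in order[train_count:]]
    return SplitDataset(train=train, val=val, seed=seed)


def _d4_variants(arr: np.ndarray) -> list[np.ndarray]:
    """The 8 dihedral-group variants: rotations of arr and of its LR mirror."""
    out = []
    for base in (arr, np.fliplr(arr)):
        for k in range(4):
            out.append(np.rot90(base, k))
    return out


def augment_eightfold(sample: Sample) -> list[Sample]:
    """Expand one (image, mask[, weight_map]) sample into its 8 D4 variants.

    Every array in the sample is transformed identically; rotations are exact
    index permutations, so labels and weights are never interpolated.
    """
    arrays = [np.asarray(a) for a in sample]
    for a in arrays:
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("eightfold augmentation requires square 2D arrays")
    variant_lists = [_d4_variants(a) for a in arrays]
    return [tuple(v[i] for v in variant_lists) for i in range(8)]


def augment_dataset(samples: list[Sample]) -> list[Sample]:
    """Apply the eightfold augmentation to every sample (size grows 8x)."""
    out: list[Sample] = []
    for s in samples:
        out.extend(augment_eightfold(s))
    return out
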