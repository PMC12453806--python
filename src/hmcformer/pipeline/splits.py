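"""Five-fold cross-validation plan with rotating validation/test folds.

Each of the k folds serves as the test set exactly once; the next fold in
rotation is the validation set, and the remaining k-2 folds train the
model.  Folds are an even split of a seeded permutation (sizes differ by
at most one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SplitPlan:
    folds: list            # list of k index arrays
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def iteration(self, i: int):
        """(train_idx, val_idx, test_idx) for rotation ``i``."""
        k = self.k
        test = self.folds[i % k]
        val = self.folds[(i + 1) % k]
        train = np.concatenate(
            [self.folds[j] for j in range(k) if j not in (i % k, (i + 1) % k)])
        return np.sort(train), np.sort(val), np.sort(test)

    def iterations(self):
        for i in range(self.k):
            yield self.iteration(i)


def make_splits(n_samples: int, seed: int, k: int = 5,
                labels: np.ndarray | None = None) -> SplitPlan:
    """Deterministic k-fold assignment; stratified when labels are given."""
    if n_samples < k:
        raise ValueError(f"need at least {k} samples, got {n_samples}")
    rng = np.random.default_rng(seed)
    if labels is None:
        perm = rng.permutation(n_samples)
        folds = [np.sort(perm[i::k]) for i in range(k)]
    else:
        labels = np.asarray(labels)
        buckets: list[list[int]] = [[] for _ in range(k)]
        pos = 0
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            idx = idx[rng.permutation(idx.size)]
            for j, sample in enumerate(idx):
                buckets[(pos + j) % k].append(int(sample))
            pos += idx.size
        folds = [np.sort(np.asarray(b, dtype=np.int64)) for b in buckets]
    return SplitPlan(folds, seed)
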