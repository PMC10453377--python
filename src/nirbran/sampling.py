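"""Kennard-Stone calibration/validation partitioning.

The Kennard-Stone algorithm picks a representative calibration subset by
max-min Euclidean distance in spectral space: it seeds with the two most
distant samples, then repeatedly adds the sample farthest from the
selected set.  The first 70 % of samples selected this way form the
calibration set (99 of 141 at the study size); the remainder validate.
Because the most extreme spectra are selected first, the calibration set
tends to span the validation set's reference range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io import Role, SpectraSet

__all__ = ["SplitResult", "kennard_stone", "assign_roles"]


@dataclass(frozen=True)
class SplitResult:
    """Outcome of a Kennard-Stone split."""

    calibration_ids: list[str]
    validation_ids: list[str]
    calibration_indices: list[int]
    validation_indices: list[int]
    #: selection_order[i] = rank (0-based) at which calibration sample i was chosen
    selection_order: list[int]

    @property
    def n_calibration(self) -> int:
        return len(self.calibration_ids)

    @property
    def n_validation(self) -> int:
        return len(self.validation_ids)


def kennard_stone(spectra: SpectraSet, fraction: float = 0.7) -> SplitResult:
    """Partition a set by the Kennard-Stone max-min algorithm.

    ``ceil(fraction * n)`` samples are selected into the calibration set;
    distances are Euclidean on the absorbance matrix as given (pretreat
    the set first to run the algorithm in a pretreated space).  The
    procedure is deterministic; ties break toward the lowest input index.
    """
    n = spectra.n_samples
    if n < 4:
        raise ValueError("Kennard-Stone needs at least 4 samples")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    n_cal = math.ceil(fraction * n)

    dist = squareform(pdist(spectra.absorbance, metric="euclidean"))
    if dist.max() == 0.0:
        raise ValueError("all spectra identical; Kennard-Stone distances are zero")

    # seed: farthest pair; np.argmax scans row-major, i.e. lowest (i, j) first
    i, j = np.unravel_index(int(np.argmax(dist)), dist.shape)
    selected = [int(min(i, j)), int(max(i, j))]
    min_dist = np.minimum(dist[selected[0]], dist[selected[1]])
    min_dist[selected] = -np.inf
    while len(selected) < n_cal:
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, dist[nxt])
        min_dist[nxt] = -np.inf

    remaining = [k for k in range(n) if k not in set(selected)]
    return SplitResult(
        calibration_ids=[spectra.sample_ids[k] for k in selected],
        validation_ids=[spectra.sample_ids[k] for k in remaining],
        calibration_indices=selected,
        validation_indices=remaining,
        selection_order=list(range(len(selected))),
    )


def assign_roles(spectra: SpectraSet, split: SplitResult) -> SpectraSet:
    """Return a copy of the set with calibration/validation role tags."""
    roles = [Role.VALIDATION] * spectra.n_samples
    for k in split.calibration_indices:
        roles[k] = Role.CALIBRATION
    out = spectra.subset(range(spectra.n_samples))
    out.roles = roles
    return out
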