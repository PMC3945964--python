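"""Species-boundary threshold optimization from FP/FN error curves.

For a candidate threshold t, a *false positive* is a conspecific sequence
pair whose distance exceeds t (the threshold would split a species) and a
*false negative* is a heterospecific pair whose distance is at or below t
(the threshold would lump two species).  Scanning t from 0 to 15% yields two
cumulative error curves; the optimal boundary minimizes their sum.  Counting
is over sequence pairs with defined distances; undefined pairs are excluded
and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import MarkerDataset
from .distances import DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdScan:
    thresholds: np.ndarray
    fp_counts: np.ndarray
    fn_counts: np.ndarray
    optimal: float
    tie_thresholds: tuple[float, ...] = ()
    tie_policy: str = "smallest"
    n_conspecific: int = 0
    n_heterospecific: int = 0
    n_undefined: int = 0

    @property
    def error_sums(self) -> np.ndarray:
        return self.fp_counts + self.fn_counts

    @property
    def min_error_sum(self) -> int:
        return int(self.error_sums.min())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "false_positives": self.fp_counts,
                "false_negatives": self.fn_counts,
                "error_sum": self.error_sums,
            }
        )


def _optimal_from_arrays(thresholds: np.ndarray, sums: np.ndarray) -> tuple[float, tuple[float, ...]]:
    best = sums.min()
    ties = thresholds[sums == best]
    return float(ties[0]), tuple(float(t) for t in ties)


def error_curves(
    matrix: DistanceMatrix,
    dataset: "MarkerDataset | dict[str, str]",
    grid_step: float = 0.0001,
    max_threshold: float = 0.15,
    merge_at_threshold: bool = True,
) -> ThresholdScan:
    """Scan thresholds over [0, max_threshold] and count FP/FN per threshold.

    ``dataset`` may be a MarkerDataset or a plain id -> species mapping.

    ``merge_at_threshold`` controls the inequality at t: when True (default)
    a heterospecific pair at exactly d == t counts as lumped (FN uses
    d <= t); when False the comparison is strict.
    """
    if grid_step <= 0 or max_threshold <= 0:
        raise ValueError("grid_step and max_threshold must be positive")
    n_steps = int(round(max_threshold / grid_step))
    thresholds = np.round(np.arange(n_steps + 1) * grid_step, 10)
    if thresholds.size == 0:
        raise ValueError("empty threshold grid")

    lookup = dataset.species_of() if hasattr(dataset, "species_of") else dict(dataset)
    species = np.array([lookup[i] for i in matrix.ids])
    same = species[:, None] == species[None, :]
    iu = np.triu_indices(len(matrix), k=1)
    d = matrix.values[iu]
    conspecific = same[iu]
    defined = ~matrix.undefined[iu]
    n_undef = int((~defined).sum())
    if n_undef:
        logger.info("error_curves: excluding %d undefined pairs", n_undef)

    intra = np.sort(d[conspecific & defined])
    inter = np.sort(d[~conspecific & defined])
    if intra.size == 0 or inter.size == 0:
        raise ValueError("need at least one conspecific and one heterospecific pair")

    # FP(t) = #conspecific pairs with d > t; FN(t) = #heterospecific d <= t
    side = "right" if merge_at_threshold else "left"
    fp = intra.size - np.searchsorted(intra, thresholds, side=side)
    fn = np.searchsorted(inter, thresholds, side=side)
    optimal, ties = _optimal_from_arrays(thresholds, fp + fn)
    return ThresholdScan(
        thresholds=thresholds,
        fp_counts=fp.astype(int),
        fn_counts=fn.astype(int),
        optimal=optimal,
        tie_thresholds=ties,
        n_conspecific=int(intra.size),
        n_heterospecific=int(inter.size),
        n_undefined=n_undef,
    )


def optimal_threshold(scan: ThresholdScan) -> float:
    """Threshold minimizing FP + FN; ties resolve to the smallest threshold."""
    optimal, _ = _optimal_from_arrays(scan.thresholds, scan.error_sums)
    return optimal
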