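"""Kimura two-parameter (K2P) distances with pairwise deletion.

The K2P model corrects observed divergence separately for transitions
(A<->G, C<->T, proportion ``P``) and transversions (proportion ``Q``):

    d = -1/2 * ln( (1 - 2P - Q) * sqrt(1 - 2Q) )

Alignment columns where either sequence carries a gap or an IUPAC ambiguity
code are skipped pair by pair (pairwise deletion), so each pair has its own
comparable-site count.  When divergence saturates — ``1 - 2P - Q <= 0`` or
``1 - 2Q <= 0`` — the logarithm is undefined and the distance is flagged
rather than raised: downstream statistics skip flagged pairs and
identification treats them as infinitely far.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import MarkerDataset

# A, G even; C, T odd -> a substitution is a transition iff parities match.
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class PairwiseComparison:
    """Site counts and distance for one sequence pair."""

    n_sites: int
    P: float
    Q: float
    d: float | None  #: None when the K2P logarithm is undefined
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.d is not None


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric K2P distance matrix with per-pair site counts.

    ``values[i, j]`` is NaN exactly where ``undefined[i, j]`` is True.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    site_counts: np.ndarray
    undefined: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("values", "site_counts", "undefined"):
            arr = getattr(self, name)
            if arr.shape != (n, n):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(n, n)}")

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, record_id: str) -> int:
        try:
            return self.ids.index(record_id)
        except ValueError:
            raise KeyError(record_id) from None

    def distance(self, a: str, b: str) -> float:
        """Distance between two records by id (NaN if undefined)."""
        return float(self.values[self.index_of(a), self.index_of(b)])

    def max_defined(self) -> float:
        defined = self.values[~self.undefined]
        return float(np.nanmax(defined)) if defined.size else 0.0

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.index_of(i) for i in ids]
        ix = np.ix_(idx, idx)
        return DistanceMatrix(
            tuple(ids), self.values[ix], self.site_counts[ix], self.undefined[ix]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DistanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        values = frame.to_numpy(dtype=float)
        undefined = np.isnan(values)
        np.fill_diagonal(undefined, False)
        counts = np.zeros_like(values, dtype=int)  # site counts not round-tripped
        return cls(tuple(str(c) for c in frame.columns), values, counts, undefined)

    def write_phylip(self, path: str | Path) -> None:
        """Lower-format square PHYLIP distance matrix (NaN for undefined)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{name:<10s} {row}\n")


def k2p_formula(P: float, Q: float) -> float | None:
    """Closed-form K2P distance; None outside the defined region."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return None
    return -0.5 * math.log(w1 * math.sqrt(w2))


def encode(residues: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3 and gaps/ambiguity codes as -1."""
    return np.array([_CODE.get(ch, -1) for ch in residues], dtype=np.int8)


def _compare_encoded(a: np.ndarray, b: np.ndarray) -> PairwiseComparison:
    valid = (a >= 0) & (b >= 0)
    n = int(valid.sum())
    if n == 0:
        return PairwiseComparison(0, 0.0, 0.0, None, "no comparable sites")
    av, bv = a[valid], b[valid]
    diff = av != bv
    transitions = int((diff & ((av & 1) == (bv & 1))).sum())
    transversions = int(diff.sum()) - transitions
    P = transitions / n
    Q = transversions / n
    d = k2p_formula(P, Q)
    if d is None:
        return PairwiseComparison(n, P, Q, None, "saturated (log argument <= 0)")
    return PairwiseComparison(n, P, Q, d)


def k2p_distance(a: str, b: str) -> PairwiseComparison:
    """K2P distance between two equal-length aligned sequences."""
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    return _compare_encoded(encode(a.upper()), encode(b.upper()))


def distance_matrix(dataset: MarkerDataset) -> DistanceMatrix:
    """All-pairs K2P distances for an aligned dataset.

    Undefined (saturated or zero-overlap) pairs are flagged in
    ``undefined`` and stored as NaN, never silently zeroed.
    """
    n = len(dataset)
    ids = tuple(dataset.ids)
    values = np.zeros((n, n), dtype=float)
    counts = np.zeros((n, n), dtype=int)
    undefined = np.zeros((n, n), dtype=bool)
    if n == 0:
        return DistanceMatrix(ids, values, counts, undefined)
    length = dataset.alignment_length
    encoded = np.empty((n, length), dtype=np.int8)
    for i, rec in enumerate(dataset):
        encoded[i] = encode(rec.residues)
        counts[i, i] = int((encoded[i] >= 0).sum())
    for i in range(n):
        for j in range(i + 1, n):
            cmp = _compare_encoded(encoded[i], encoded[j])
            counts[i, j] = counts[j, i] = cmp.n_sites
            if cmp.defined:
                values[i, j] = values[j, i] = cmp.d
            else:
                values[i, j] = values[j, i] = np.nan
                undefined[i, j] = undefined[j, i] = True
    return DistanceMatrix(ids, values, counts, undefined)
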