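"""Inter- and intra-specific divergence parameters and barcoding-gap histograms.

Six headline parameters summarize how well a marker separates species:

* average inter-specific distance — the pooled mean over all heterospecific
  congeneric sequence pairs (genera with >= 2 species); mean +/- sd over
  those pairs;
* theta prime — the mean heterospecific congeneric pairwise distance per
  genus, averaged over genera, which removes bias from unequal species and
  record counts among genera; mean +/- sd over genera;
* minimum inter-specific distance — the smallest heterospecific congeneric
  pairwise distance per genus; mean +/- sd over genera;
* average intra-specific distance — the pooled mean over all conspecific
  sequence pairs (species with >= 2 records); mean +/- sd over those pairs;
* theta — the mean conspecific pairwise distance per species, averaged over
  species, removing unequal-sampling bias; mean +/- sd over species;
* coalescent depth — the maximum conspecific pairwise distance per species;
  mean +/- sd over species.

The "barcoding gap" is the separation between the distribution of coalescent
depths and the distribution of each species' distance to its nearest
heterospecific congener; overlap between the two is what ultimately limits
threshold-based identification.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import MarkerDataset
from .distances import DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GapHistogram:
    bin_edges: np.ndarray
    min_interspecific_counts: np.ndarray
    coalescent_depth_counts: np.ndarray

    @property
    def overlap(self) -> bool:
        """True when any bin holds counts from both distributions."""
        return bool(
            np.any((self.min_interspecific_counts > 0) & (self.coalescent_depth_counts > 0))
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "min_interspecific": self.min_interspecific_counts,
                "coalescent_depth": self.coalescent_depth_counts,
            }
        )


@dataclass(frozen=True)
class DivergenceSummary:
    marker: str
    avg_interspecific: tuple[float, float]
    theta_prime: tuple[float, float]
    min_interspecific: tuple[float, float]
    avg_intraspecific: tuple[float, float]
    theta: tuple[float, float]
    coalescent_depth: tuple[float, float]
    per_species: pd.DataFrame
    per_genus: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("avg_interspecific", *self.avg_interspecific),
            ("theta_prime", *self.theta_prime),
            ("min_interspecific", *self.min_interspecific),
            ("avg_intraspecific", *self.avg_intraspecific),
            ("theta", *self.theta),
            ("coalescent_depth", *self.coalescent_depth),
        ]
        return pd.DataFrame(rows, columns=["parameter", "mean", "sd"])


def _pair_distances(matrix: DistanceMatrix, ids_a: list[str], ids_b: list[str] | None = None):
    """Defined distances over all pairs within ids_a (or between a and b)."""
    out = []
    skipped = 0
    if ids_b is None:
        pairs = itertools.combinations(ids_a, 2)
    else:
        pairs = itertools.product(ids_a, ids_b)
    for a, b in pairs:
        d = matrix.distance(a, b)
        if math.isnan(d):
            skipped += 1
        else:
            out.append(d)
    return out, skipped


def intraspecific_stats(matrix: DistanceMatrix, dataset: MarkerDataset) -> pd.DataFrame:
    """Per-species conspecific distance summaries.

    One row per species with >= 2 records: ``theta`` (mean pairwise
    conspecific distance), ``depth`` (maximum), record and pair counts.
    Undefined pairs are skipped and counted.
    """
    by_species: dict[str, list[str]] = {}
    for rec in dataset:
        by_species.setdefault(rec.species, []).append(rec.id)
    rows = []
    for species in sorted(by_species):
        ids = by_species[species]
        if len(ids) < 2:
            continue
        dists, skipped = _pair_distances(matrix, ids)
        if not dists:
            logger.warning("species %s: all %d pairs undefined", species, skipped)
            continue
        rows.append(
            {
                "species": species,
                "genus": species.split()[0],
                "n_records": len(ids),
                "n_pairs": len(dists),
                "n_undefined": skipped,
                "theta": float(np.mean(dists)),
                "depth": float(np.max(dists)),
            }
        )
    if not rows:
        logger.warning("no species with >= 2 records and defined distances")
        return pd.DataFrame(
            columns=["species", "genus", "n_records", "n_pairs", "n_undefined", "theta", "depth"]
        )
    return pd.DataFrame(rows)


def interspecific_stats(matrix: DistanceMatrix, dataset: MarkerDataset) -> pd.DataFrame:
    """Per-genus congeneric divergence summaries.

    One row per genus with >= 2 species: ``theta_prime`` (mean over all
    heterospecific congeneric sequence pairs) and ``min_inter`` (smallest
    heterospecific congeneric pairwise distance).
    """
    by_genus: dict[str, dict[str, list[str]]] = {}
    for rec in dataset:
        by_genus.setdefault(rec.genus, {}).setdefault(rec.species, []).append(rec.id)
    rows = []
    for genus in sorted(by_genus):
        species_ids = by_genus[genus]
        if len(species_ids) < 2:
            continue
        pooled: list[float] = []
        skipped = 0
        for sp_a, sp_b in itertools.combinations(sorted(species_ids), 2):
            dists, sk = _pair_distances(matrix, species_ids[sp_a], species_ids[sp_b])
            skipped += sk
            pooled.extend(dists)
        if not pooled:
            logger.warning("genus %s: all congeneric pairs undefined", genus)
            continue
        rows.append(
            {
                "genus": genus,
                "n_species": len(species_ids),
                "n_pairs": len(pooled),
                "n_undefined": skipped,
                "theta_prime": float(np.mean(pooled)),
                "min_inter": float(np.min(pooled)),
            }
        )
    if not rows:
        logger.warning("no genus with >= 2 species and defined distances")
        return pd.DataFrame(
            columns=[
                "genus", "n_species", "n_pairs", "n_undefined",
                "theta_prime", "min_inter",
            ]
        )
    return pd.DataFrame(rows)


def nearest_congener_distances(matrix: DistanceMatrix, dataset: MarkerDataset) -> pd.Series:
    """Per species: smallest distance to any heterospecific congener.

    This is the species-level view behind the barcoding-gap histograms; it is
    NaN for species with no congener with defined distances.
    """
    by_genus: dict[str, dict[str, list[str]]] = {}
    for rec in dataset:
        by_genus.setdefault(rec.genus, {}).setdefault(rec.species, []).append(rec.id)
    values: dict[str, float] = {}
    for genus, species_ids in by_genus.items():
        for species in species_ids:
            best = math.nan
            for other, other_ids in species_ids.items():
                if other == species:
                    continue
                dists, _ = _pair_distances(matrix, species_ids[species], other_ids)
                if dists:
                    m = float(np.min(dists))
                    if math.isnan(best) or m < best:
                        best = m
            values[species] = best
    return pd.Series(values, name="nearest_congener").sort_index()


def _mean_sd(values) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return (math.nan, math.nan)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return (float(np.mean(arr)), sd)


def summarize_divergence(matrix: DistanceMatrix, dataset: MarkerDataset) -> DivergenceSummary:
    """Compute all six divergence parameters plus the component tables."""
    per_species = intraspecific_stats(matrix, dataset)
    per_genus = interspecific_stats(matrix, dataset)
    nearest = nearest_congener_distances(matrix, dataset)
    if not per_species.empty:
        per_species = per_species.merge(
            nearest.rename("nearest_congener"),
            left_on="species", right_index=True, how="left",
        )

    # pooled means weight each sequence pair equally (conspecific pairs for
    # the intra side, heterospecific congeneric pairs for the inter side)
    pooled: list[float] = []
    by_species: dict[str, list[str]] = {}
    by_genus: dict[str, dict[str, list[str]]] = {}
    for rec in dataset:
        by_species.setdefault(rec.species, []).append(rec.id)
        by_genus.setdefault(rec.genus, {}).setdefault(rec.species, []).append(rec.id)
    for ids in by_species.values():
        if len(ids) >= 2:
            dists, _ = _pair_distances(matrix, ids)
            pooled.extend(dists)
    pooled_inter: list[float] = []
    for species_ids in by_genus.values():
        if len(species_ids) < 2:
            continue
        for sp_a, sp_b in itertools.combinations(sorted(species_ids), 2):
            dists, _ = _pair_distances(matrix, species_ids[sp_a], species_ids[sp_b])
            pooled_inter.extend(dists)

    return DivergenceSummary(
        marker=dataset.marker,
        avg_interspecific=_mean_sd(pooled_inter),
        theta_prime=_mean_sd(per_genus["theta_prime"]) if not per_genus.empty else (math.nan, math.nan),
        min_interspecific=_mean_sd(per_genus["min_inter"]) if not per_genus.empty else (math.nan, math.nan),
        avg_intraspecific=_mean_sd(pooled),
        theta=_mean_sd(per_species["theta"]) if not per_species.empty else (math.nan, math.nan),
        coalescent_depth=_mean_sd(per_species["depth"]) if not per_species.empty else (math.nan, math.nan),
        per_species=per_species,
        per_genus=per_genus,
    )


def gap_histograms(
    per_species: pd.DataFrame,
    per_genus: pd.DataFrame,
    bin_width: float = 0.01,
    max_distance: float | None = None,
) -> GapHistogram:
    """Histogram the barcoding gap: nearest-congener distances vs depths.

    Uses the species-level ``nearest_congener`` column when present, falling
    back to the per-genus minima otherwise.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if per_species.empty and per_genus.empty:
        raise ValueError("both component tables are empty")
    if "nearest_congener" in per_species.columns:
        inter = per_species["nearest_congener"].dropna().to_numpy()
    else:
        inter = per_genus["min_inter"].dropna().to_numpy() if not per_genus.empty else np.array([])
    depth = per_species["depth"].dropna().to_numpy() if not per_species.empty else np.array([])
    top = max(
        [max_distance or 0.0]
        + ([float(inter.max())] if inter.size else [])
        + ([float(depth.max())] if depth.size else [])
        + [bin_width]
    )
    n_bins = int(math.ceil(top / bin_width + 1e-9)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    inter_counts, _ = np.histogram(inter, bins=edges)
    depth_counts, _ = np.histogram(depth, bins=edges)
    return GapHistogram(edges, inter_counts, depth_counts)


def ratio_gap_index(summary: DivergenceSummary) -> float:
    """Mean minimum inter-specific distance over mean coalescent depth.

    A large ratio indicates a wide barcoding gap.  NaN when the mean depth is
    zero or either component is unavailable.
    """
    num = summary.min_interspecific[0]
    den = summary.coalescent_depth[0]
    if math.isnan(num) or math.isnan(den) or den == 0.0:
        return math.nan
    return num / den
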