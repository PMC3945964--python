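"""Synthetic aligned marker datasets with controlled divergence structure.

Sequences evolve under the Kimura two-parameter substitution process on a
star-within-star genealogy: a root sequence spawns genus ancestors, each
genus ancestor spawns species centroids at half the target inter-specific
divergence, and each centroid spawns individual records at half the target
intra-specific divergence.  Because expected K2P distance is additive in
branch length under the generating model, conspecific pairs land near the
intra target and congeneric heterospecific pairs near the inter target.

Three complications of real barcode libraries can be switched on:

* *overlap pairs* — species pairs whose centroids sit 0.5% apart, below
  typical intra-specific divergence (the scenario where two nominal species
  are genetically inseparable);
* *deep splits* — species drawing half their records from a second centroid
  a long branch away, producing rare large intra-specific distances;
* *mislabels* — records emitted under the name of a different congeneric
  species with status "unpublished", which screening should reject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import MarkerDataset, SequenceRecord

_BASES = "ACGT"

#: centroid separation for overlap species pairs (K2P scale)
OVERLAP_SEPARATION = 0.005
#: deep-split second centroid sits this many intra-divergences away
DEEP_SPLIT_FACTOR = 4.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for one simulated marker dataset.

    Divergence targets are on the K2P distance scale.  Defaults mirror a
    typical tick barcode library: ~1.5% conspecific divergence against
    ~20% congeneric divergence across 4 genera of 5 species with 4 records
    each.
    """

    seed: int = 1
    n_genera: int = 4
    species_per_genus: int = 5
    records_per_species: int = 4
    seq_length: int = 600
    kappa: float = 4.0
    intra_divergence: float = 0.015
    inter_divergence: float = 0.20
    genus_divergence: float = 0.40
    overlap_pairs: int = 0
    deep_split_species: int = 0
    mislabel_fraction: float = 0.0
    marker: str = "COI"

    def __post_init__(self) -> None:
        if self.intra_divergence >= self.inter_divergence:
            raise ValueError("intra_divergence must be below inter_divergence")
        if min(self.n_genera, self.species_per_genus, self.records_per_species) < 1:
            raise ValueError("counts must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0.0 <= self.mislabel_fraction < 1.0:
            raise ValueError("mislabel_fraction must be in [0, 1)")
        available = self.n_genera * (self.species_per_genus // 2)
        if self.overlap_pairs > available:
            raise ValueError(
                f"overlap_pairs={self.overlap_pairs} exceeds the "
                f"{available} disjoint congeneric pairs available"
            )
        if self.deep_split_species > self.n_genera * self.species_per_genus:
            raise ValueError("deep_split_species exceeds the species count")


def evolve_sequence(
    parent: str, branch_length: float, kappa: float, rng: np.random.Generator
) -> str:
    """Evolve a sequence along one branch of the K2P process.

    ``branch_length`` is the expected number of substitutions per site, so
    the expected K2P distance estimate between parent and child equals the
    branch length.  Site fates are drawn from the exact K2P transition
    probabilities (multiple hits included): with transition rate alpha and
    per-target transversion rate beta normalized to alpha + 2 beta = 1,

        P(transition)        = 1/4 + 1/4 e^(-4 beta t) - 1/2 e^(-2(alpha+beta) t)
        P(each transversion) = 1/4 - 1/4 e^(-4 beta t)
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    if branch_length == 0:
        return parent
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    t = branch_length
    e_tv = math.exp(-4.0 * beta * t)
    e_ts = math.exp(-2.0 * (alpha + beta) * t)
    p_transition = 0.25 + 0.25 * e_tv - 0.5 * e_ts
    p_transversion = 0.5 - 0.5 * e_tv  # both transversion targets together

    codes = np.frombuffer(parent.encode(), dtype=np.uint8)
    base = np.empty(len(parent), dtype=np.int8)
    for i, ch in enumerate(_BASES):
        base[codes == ord(ch)] = i
    u = rng.random(len(parent))
    pick = rng.integers(0, 2, size=len(parent))  # which transversion target
    out = base.copy()
    is_ts = u < p_transition
    is_tv = (~is_ts) & (u < p_transition + p_transversion)
    out[is_ts] = base[is_ts] ^ 2  # A<->G, C<->T
    out[is_tv] = (base[is_tv] + 1 + 2 * pick[is_tv]) % 4  # parity flip
    return "".join(_BASES[c] for c in out)


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[c] for c in rng.integers(0, 4, size=length))


def simulate_dataset(config: SimulationConfig) -> tuple[MarkerDataset, pd.DataFrame]:
    """Generate one aligned dataset plus a truth table.

    The truth table has one row per record: ``id``, ``true_species``,
    ``labeled_species``, ``mislabeled``, ``subpopulation``.  Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    root = _random_sequence(config.seq_length, rng)

    species_names: list[str] = []
    centroids: dict[str, str] = {}
    deep_centroids: dict[str, str] = {}
    genus_of: dict[str, str] = {}

    for g in range(config.n_genera):
        genus = f"Genus{g + 1}"
        ancestor = evolve_sequence(root, config.genus_divergence / 2.0, config.kappa, rng)
        # centroid separation discounts the two individual branches so that
        # heterospecific *individuals* land at the inter_divergence target
        centroid_branch = max(config.inter_divergence - config.intra_divergence, 0.0) / 2.0
        for s in range(config.species_per_genus):
            species = f"{genus} sp{s + 1}"
            species_names.append(species)
            genus_of[species] = genus
            centroids[species] = evolve_sequence(
                ancestor, centroid_branch, config.kappa, rng
            )

    # overlap pairs: successive disjoint congeneric pairs get near-identical
    # centroids (the R. microplus / R. annulatus scenario)
    remaining = config.overlap_pairs
    overlap_species: set[str] = set()
    for g in range(config.n_genera):
        if remaining == 0:
            break
        genus_species = [s for s in species_names if genus_of[s] == f"Genus{g + 1}"]
        for a, b in zip(genus_species[::2], genus_species[1::2]):
            if remaining == 0:
                break
            centroids[b] = evolve_sequence(
                centroids[a], OVERLAP_SEPARATION, config.kappa, rng
            )
            overlap_species.update((a, b))
            remaining -= 1

    # deep splits: prefer species untouched by overlap scenarios
    candidates = [s for s in species_names if s not in overlap_species]
    candidates += [s for s in species_names if s in overlap_species]
    for species in candidates[: config.deep_split_species]:
        deep_centroids[species] = evolve_sequence(
            centroids[species],
            DEEP_SPLIT_FACTOR * config.intra_divergence,
            config.kappa,
            rng,
        )

    records: list[dict] = []
    for species in species_names:
        n_deep = (
            config.records_per_species // 2 if species in deep_centroids else 0
        )
        for r in range(config.records_per_species):
            use_deep = r >= config.records_per_species - n_deep
            source = deep_centroids[species] if use_deep else centroids[species]
            residues = evolve_sequence(
                source, config.intra_divergence / 2.0, config.kappa, rng
            )
            g_idx = species_names.index(species) // config.species_per_genus + 1
            s_idx = species_names.index(species) % config.species_per_genus + 1
            records.append(
                {
                    "id": f"G{g_idx}S{s_idx}R{r + 1}",
                    "true_species": species,
                    "residues": residues,
                    "subpopulation": "deep" if use_deep else "main",
                }
            )

    # mislabels: wrong congeneric name, status unpublished
    n_mislabeled = int(round(config.mislabel_fraction * len(records)))
    mislabel_idx = set(
        rng.choice(len(records), size=n_mislabeled, replace=False).tolist()
    )
    rows = []
    out_records = []
    for i, rec in enumerate(records):
        label = rec["true_species"]
        status = "published"
        if i in mislabel_idx:
            genus = genus_of[label]
            congeners = [
                s for s in species_names if genus_of[s] == genus and s != label
            ]
            pool = congeners or [s for s in species_names if s != label]
            label = pool[int(rng.integers(0, len(pool)))]
            status = "unpublished"
        out_records.append(
            SequenceRecord(
                id=rec["id"],
                species=label,
                marker=config.marker,
                status=status,
                stage="adult",
                residues=rec["residues"],
            )
        )
        rows.append(
            {
                "id": rec["id"],
                "true_species": rec["true_species"],
                "labeled_species": label,
                "mislabeled": i in mislabel_idx,
                "subpopulation": rec["subpopulation"],
            }
        )
    dataset = MarkerDataset(config.marker, tuple(out_records), "custom")
    return dataset, pd.DataFrame(rows)
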