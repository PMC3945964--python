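"""Species-identification decision rules and reference-library screening.

Four rules assign a query sequence to a species against a reference library:

* **nearest neighbour (NN)** — the species of the minimum-K2P-distance
  reference; exact ties across species make the call uncertain;
* **best hit** — Smith-Waterman local alignment of the query against every
  reference, hits filtered by identity and E-value and ranked by bit score;
  the top hit's species is assigned unless the top score is shared across
  species;
* **liberal tree-based** — on a neighbour-joining tree, the query is
  assigned species X when it is sister to a monospecific clade of X
  (((X,X),Q)) or nested inside one (((X,Q),X)); anything else is uncertain;
* **liberal tree-based + threshold** — the tree rule, additionally vetoed
  (uncertain) when the query's nearest reference lies at or beyond a
  distance threshold.

Screening admits an unverified ("unpublished") reference record only when
its smallest clade containing any reliable record (published or locally
amplified) holds exclusively reliable records of its own nominal species,
plus possibly other unpublished records of that species.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignmentHit, ScoringScheme, local_align
from .datasets import MarkerDataset, SequenceRecord
from .distances import DistanceMatrix
from .tree import PhyloTree, neighbor_joining

logger = logging.getLogger(__name__)

#: decimal places used when testing for exact distance ties
TIE_DECIMALS = 10

METHODS = ("nn", "best-hit", "tree", "tree+threshold")


@dataclass(frozen=True)
class IdentificationCall:
    query_id: str
    method: str
    assigned_species: str | None
    state: str  # assigned | uncertain | no-hit
    support: object = None
    tied_species: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ok = self.state == "assigned"
        if ok != (self.assigned_species is not None and not self.tied_species):
            raise ValueError(
                f"inconsistent call for {self.query_id!r}: state={self.state!r}, "
                f"species={self.assigned_species!r}, ties={self.tied_species!r}"
            )


def calls_to_frame(calls: list[IdentificationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "query": [c.query_id for c in calls],
            "method": [c.method for c in calls],
            "state": [c.state for c in calls],
            "species": [c.assigned_species or "" for c in calls],
            "support": [c.support for c in calls],
            "tied_species": [";".join(c.tied_species) for c in calls],
        }
    )


# ---------------------------------------------------------------------------
# nearest neighbour

def nn_identify(
    query_id: str, matrix: DistanceMatrix, reference: MarkerDataset
) -> IdentificationCall:
    """Assign the species of the minimum-distance reference record.

    The query itself is never compared against (self-match removal).  Ties
    are exact after rounding to 10 decimals, so duplicated sequences from
    different species reliably produce an uncertain call.
    """
    qi = matrix.index_of(query_id)
    ref_ids = [i for i in reference.ids if i != query_id]
    if not ref_ids:
        raise ValueError("reference is empty after self-match removal")
    species_map = reference.species_of()
    dists = []
    for rid in ref_ids:
        d = matrix.values[qi, matrix.index_of(rid)]
        if not math.isnan(d):
            dists.append((round(float(d), TIE_DECIMALS), rid))
    if not dists:
        return IdentificationCall(query_id, "nn", None, "no-hit", "all distances undefined")
    best = min(d for d, _ in dists)
    tied = sorted({species_map[rid] for d, rid in dists if d == best})
    if len(tied) == 1:
        return IdentificationCall(query_id, "nn", tied[0], "assigned", best)
    return IdentificationCall(
        query_id, "nn", None, "uncertain", best, tied_species=tuple(tied)
    )


# ---------------------------------------------------------------------------
# best hit

def best_hit_identify(
    query: SequenceRecord,
    reference: MarkerDataset,
    scoring: ScoringScheme | None = None,
    evalue_cutoff: float = 1e-6,
    identity_floor: float = 0.80,
    max_hits: int = 100,
) -> IdentificationCall:
    """Rank references by local-alignment bit score; assign the top species.

    Hits must reach ``identity_floor`` over their aligned columns and an
    E-value at or below ``evalue_cutoff``; at most ``max_hits`` are kept.
    A shared top bit score across >= 2 species is uncertain; no qualifying
    hit is a no-hit.
    """
    scoring = scoring or ScoringScheme()
    species_map = reference.species_of()
    hits: list[tuple[float, str, AlignmentHit]] = []
    for ref in reference:
        if ref.id == query.id:
            continue
        hit = local_align(query.residues, ref.residues, scoring)
        if hit.identity >= identity_floor and hit.evalue <= evalue_cutoff:
            hits.append((hit.bit_score, ref.id, hit))
    hits.sort(key=lambda h: (-h[0], h[1]))
    hits = hits[:max_hits]
    if not hits:
        return IdentificationCall(query.id, "best-hit", None, "no-hit", None)
    top_bits = hits[0][0]
    top_species = sorted(
        {species_map[rid] for bits, rid, _ in hits if bits == top_bits}
    )
    support = {"bit_score": top_bits, "evalue": hits[0][2].evalue}
    if len(top_species) == 1:
        return IdentificationCall(query.id, "best-hit", top_species[0], "assigned", support)
    return IdentificationCall(
        query.id, "best-hit", None, "uncertain", support, tied_species=tuple(top_species)
    )


# ---------------------------------------------------------------------------
# trees

def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Neighbour-joining tree; undefined distances imputed as the matrix max.

    Saturated pairs carry no usable signal, so they are placed as far apart
    as anything observed; the imputation count is logged.
    """
    if len(matrix) < 3:
        raise ValueError("need at least 3 records to build a tree")
    values = matrix.values.copy()
    n_undef = int(matrix.undefined[np.triu_indices(len(matrix), 1)].sum())
    if n_undef:
        values[matrix.undefined] = matrix.max_defined()
        logger.info("nj_tree: imputed %d undefined distances as matrix max", n_undef)
    np.fill_diagonal(values, 0.0)
    return neighbor_joining(list(matrix.ids), values)


def _monospecific(direction: frozenset[str], species_map: dict[str, str], query_id: str):
    """Species name if all mapped leaves in a direction agree, else None."""
    species = {species_map[l] for l in direction if l in species_map and l != query_id}
    if len(species) == 1:
        return species.pop()
    return None


def liberal_tree_identify(
    tree: PhyloTree, query_id: str, species_map: dict[str, str]
) -> IdentificationCall:
    """Assign a species when the query neighbours a monospecific clade.

    The attachment node of the query leaf has two other directions in the
    unrooted tree; if at least one direction's reference leaves are all one
    species (the ((X,X),Q) and ((X,Q),X) patterns), that species is
    assigned.  Two monospecific directions of different species, or none,
    leave the query uncertain.
    """
    if query_id not in tree.leaf_names:
        raise KeyError(f"query {query_id!r} not in tree")
    n_refs = sum(1 for l in tree.leaf_names if l in species_map and l != query_id)
    if n_refs < 2:
        raise ValueError("need at least 2 reference leaves")
    candidates = []
    for direction in tree.sibling_directions(query_id):
        sp = _monospecific(direction, species_map, query_id)
        if sp is not None:
            candidates.append(sp)
    unique = sorted(set(candidates))
    if len(unique) == 1:
        return IdentificationCall(query_id, "tree", unique[0], "assigned", "monospecific sibling")
    if len(unique) > 1:
        return IdentificationCall(
            query_id, "tree", None, "uncertain", "conflicting siblings",
            tied_species=tuple(unique),
        )
    return IdentificationCall(query_id, "tree", None, "uncertain", "sibling not monospecific")


def liberal_tree_threshold_identify(
    tree: PhyloTree,
    query_id: str,
    species_map: dict[str, str],
    matrix: DistanceMatrix,
    threshold: float,
) -> IdentificationCall:
    """The liberal tree rule, vetoed when no reference is within threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    call = liberal_tree_identify(tree, query_id, species_map)
    qi = matrix.index_of(query_id)
    nearest = math.inf
    for rid in species_map:
        if rid == query_id or rid not in matrix.ids:
            continue
        d = matrix.values[qi, matrix.index_of(rid)]
        if not math.isnan(d):
            nearest = min(nearest, float(d))
    if call.state == "assigned" and nearest >= threshold:
        return IdentificationCall(
            query_id, "tree+threshold", None, "uncertain",
            {"nearest": nearest, "threshold": threshold},
        )
    return IdentificationCall(
        query_id, "tree+threshold", call.assigned_species, call.state,
        {"nearest": nearest, "threshold": threshold},
        tied_species=call.tied_species,
    )


# ---------------------------------------------------------------------------
# screening

def screen_unpublished(
    tree: PhyloTree, dataset: MarkerDataset
) -> tuple[MarkerDataset, pd.DataFrame]:
    """Screen unpublished records by tree clustering with reliable records.

    On the midpoint-rooted tree, each unpublished record's smallest ancestral
    clade containing any reliable (published or amplified) record must hold
    only reliable records of the record's nominal species — other unpublished
    records in the clade must also carry that species name.  Statuses of
    reliable records never change.
    """
    missing = {r.id for r in dataset} - set(tree.leaf_names)
    if missing:
        raise ValueError(f"records absent from tree: {sorted(missing)}")
    rooted = tree.midpoint_rooted()
    by_id = {r.id: r for r in dataset}
    reliable_species = {r.species for r in dataset if r.reliable}

    new_records = []
    report_rows = []
    for rec in dataset:
        if rec.status != "unpublished":
            new_records.append(rec)
            continue
        if rec.species not in reliable_species:
            status, reason = "screened-out", "no reliable conspecific"
        else:
            status, reason = "screened-out", "no clade with reliable records"
            for clade in rooted.ancestor_leaf_sets(rec.id):
                members = [by_id[l] for l in clade if l in by_id and l != rec.id]
                reliables = [m for m in members if m.reliable]
                if not reliables:
                    continue
                ok_reliable = all(m.species == rec.species for m in reliables)
                ok_unpub = all(
                    m.species == rec.species
                    for m in members
                    if m.status == "unpublished"
                )
                if ok_reliable and ok_unpub:
                    status, reason = "screened-in", "clusters with reliable conspecifics"
                else:
                    status, reason = "screened-out", "clusters with other species"
                break
        new_records.append(rec.with_status(status))
        report_rows.append(
            {"id": rec.id, "species": rec.species, "status": status, "reason": reason}
        )
    report = pd.DataFrame(report_rows, columns=["id", "species", "status", "reason"])
    return MarkerDataset(dataset.marker, tuple(new_records), dataset.role), report
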