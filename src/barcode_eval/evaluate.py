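"""Identification success rates and multiple-range comparison of groups.

A query is *correctly identified* when a decision rule assigns it exactly
its true species; uncertain calls and no-hits count as failures.  The
sequence identification success rate of a marker x method combination is
correct calls over total queries.  Groups of replicate rates (by default the
per-genus rates) are compared with Duncan's multiple range test, which sorts
group means and tests each span of p consecutive means against a least
significant range built from the studentized range at protection level
1 - (1-alpha)**(p-1); groups not separated share a letter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

from .align import ScoringScheme
from .classify import (
    IdentificationCall,
    best_hit_identify,
    liberal_tree_identify,
    liberal_tree_threshold_identify,
    nj_tree,
    nn_identify,
)
from .datasets import MarkerDataset
from .distances import DistanceMatrix, distance_matrix
from .tree import PhyloTree

METHOD_ALIASES = {
    "nn": "nn",
    "best-hit": "best-hit",
    "blast": "best-hit",
    "tree": "tree",
    "tree+threshold": "tree+threshold",
    "tree-thresh": "tree+threshold",
}


@dataclass(frozen=True)
class EvaluationReport:
    marker: str
    method: str
    n_queries: int
    n_correct: int
    n_wrong: int
    n_uncertain: int
    n_nohit: int
    per_genus: pd.DataFrame
    calls: tuple[IdentificationCall, ...]

    def __post_init__(self) -> None:
        total = self.n_correct + self.n_wrong + self.n_uncertain + self.n_nohit
        if total != self.n_queries:
            raise ValueError("call counts do not sum to n_queries")

    @property
    def success_rate(self) -> float:
        return self.n_correct / self.n_queries if self.n_queries else math.nan


def _normalize(species: str) -> str:
    return " ".join(species.lower().split())


def _union_dataset(query_set: MarkerDataset, reference_set: MarkerDataset) -> MarkerDataset:
    ref_ids = set(reference_set.ids)
    extra = tuple(r for r in query_set if r.id not in ref_ids)
    return MarkerDataset(
        reference_set.marker, reference_set.records + extra, "custom"
    )


def run_evaluation(
    query_set: MarkerDataset,
    reference_set: MarkerDataset,
    method: str,
    threshold: float | None = None,
    scoring: ScoringScheme | None = None,
    evalue_cutoff: float = 1e-6,
    identity_floor: float = 0.80,
    max_hits: int = 100,
    matrix: DistanceMatrix | None = None,
    tree: PhyloTree | None = None,
) -> EvaluationReport:
    """Identify every query against the reference and score correctness.

    A query also present in the reference is removed from the reference for
    its own identification (self-match exclusion).  The tree methods build
    one neighbour-joining tree over references and queries together; a
    precomputed ``matrix`` / ``tree`` over the union may be supplied.
    """
    method = METHOD_ALIASES.get(method, method)
    if not len(query_set):
        raise ValueError("empty query set")
    ref_species = {_normalize(r.species) for r in reference_set}
    missing = {r.species for r in query_set if _normalize(r.species) not in ref_species}
    if missing:
        raise ValueError(f"query species absent from reference: {sorted(missing)}")

    union = _union_dataset(query_set, reference_set)
    if method in ("nn", "tree", "tree+threshold") and matrix is None:
        matrix = distance_matrix(union)
    if method in ("tree", "tree+threshold") and tree is None:
        tree = nj_tree(matrix)
    species_map = reference_set.species_of()

    calls = []
    for query in query_set:
        if method == "nn":
            call = nn_identify(query.id, matrix, reference_set)
        elif method == "best-hit":
            call = best_hit_identify(
                query, reference_set, scoring, evalue_cutoff, identity_floor, max_hits
            )
        elif method == "tree":
            smap = {k: v for k, v in species_map.items() if k != query.id}
            call = liberal_tree_identify(tree, query.id, smap)
        elif method == "tree+threshold":
            if threshold is None:
                raise ValueError("tree+threshold requires a threshold")
            smap = {k: v for k, v in species_map.items() if k != query.id}
            call = liberal_tree_threshold_identify(tree, query.id, smap, matrix, threshold)
        else:
            raise ValueError(f"unknown method {method!r}")
        calls.append(call)

    truth = {r.id: r.species for r in query_set}
    genus = {r.id: r.genus for r in query_set}
    tallies = {"correct": 0, "wrong": 0, "uncertain": 0, "no-hit": 0}
    genus_rows: dict[str, list[int]] = {}
    for call in calls:
        g = genus[call.query_id]
        counts = genus_rows.setdefault(g, [0, 0])
        counts[1] += 1
        if call.state == "assigned":
            if _normalize(call.assigned_species) == _normalize(truth[call.query_id]):
                tallies["correct"] += 1
                counts[0] += 1
            else:
                tallies["wrong"] += 1
        elif call.state == "uncertain":
            tallies["uncertain"] += 1
        else:
            tallies["no-hit"] += 1
    per_genus = pd.DataFrame(
        [
            {"genus": g, "n_queries": n, "n_correct": c, "success_rate": c / n}
            for g, (c, n) in sorted(genus_rows.items())
        ]
    )
    return EvaluationReport(
        marker=query_set.marker,
        method=method,
        n_queries=len(query_set),
        n_correct=tallies["correct"],
        n_wrong=tallies["wrong"],
        n_uncertain=tallies["uncertain"],
        n_nohit=tallies["no-hit"],
        per_genus=per_genus,
        calls=tuple(calls),
    )


def genus_restricted_rate(
    query_set: MarkerDataset,
    reference_set: MarkerDataset,
    method: str,
    genus: str,
    **kwargs,
) -> EvaluationReport:
    """Evaluation restricted to queries of one genus; reference unrestricted."""
    genus_ids = [r.id for r in query_set if r.genus == genus]
    if not genus_ids:
        raise ValueError(f"genus {genus!r} not present in query set")
    restricted = query_set.subset(genus_ids, role=query_set.role)
    return run_evaluation(restricted, reference_set, method, **kwargs)


# ---------------------------------------------------------------------------
# Duncan's multiple range test

def duncan_multiple_range(
    groups: dict[str, "list[float] | np.ndarray"], alpha: float = 0.05
) -> pd.DataFrame:
    """Duncan's multiple range test with letter display.

    ``groups`` maps labels to replicate observations (>= 2 each).  Returns a
    table sorted by descending mean with columns ``group``, ``n``, ``mean``,
    ``se`` and ``letters``; groups sharing any letter are not significantly
    different at level ``alpha``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = list(groups)
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 replicates")
    n_total = sum(v.size for v in data.values())
    k = len(labels)
    df_error = n_total - k
    sse = sum(float(((v - v.mean()) ** 2).sum()) for v in data.values())
    mse = sse / df_error
    if mse == 0.0:
        raise ValueError("zero within-group variance in every group; test undefined")

    order = sorted(labels, key=lambda l: (-data[l].mean(), l))
    means = np.array([data[l].mean() for l in order])
    sizes = np.array([data[l].size for l in order])

    def critical_range(i: int, j: int) -> float:
        p = j - i + 1
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        q = studentized_range.ppf(1.0 - alpha_p, p, df_error)
        nh = 2.0 / (1.0 / sizes[i] + 1.0 / sizes[j])
        return float(q) * math.sqrt(mse / nh)

    # direct span tests, then Duncan's protection: a span inside a
    # non-significant span is itself non-significant
    ns = np.zeros((k, k), dtype=bool)
    for span in range(k - 1, 0, -1):
        for i in range(k - span):
            j = i + span
            direct = (means[i] - means[j]) <= critical_range(i, j)
            inherited = (i > 0 and ns[i - 1, j]) or (j < k - 1 and ns[i, j + 1])
            ns[i, j] = ns[j, i] = direct or inherited
    np.fill_diagonal(ns, True)

    # maximal non-significant intervals -> letters
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and ns[i, j + 1]:
            j += 1
        intervals.append((i, j))
    maximal = [
        (a, b)
        for a, b in dict.fromkeys(intervals)
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in intervals)
    ]
    letters = {label: "" for label in order}
    for idx, (a, b) in enumerate(sorted(maximal)):
        letter = chr(ord("a") + idx)
        for pos in range(a, b + 1):
            letters[order[pos]] += letter

    return pd.DataFrame(
        {
            "group": order,
            "n": sizes,
            "mean": means,
            "se": [data[l].std(ddof=1) / math.sqrt(data[l].size) for l in order],
            "letters": [letters[l] for l in order],
        }
    )
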