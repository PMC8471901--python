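"""Per-day Ward clustering of seeds and consensus assignment across days.

Each monitored day is clustered independently (Ward linkage, Euclidean
distances, tree cut at k = 3).  Dendrogram labels are arbitrary per day,
so before counting appearances each day's labels are permuted to maximize
seed overlap with a reference day (optimal assignment over the k!
permutations, ties broken toward the lexicographically smallest
permutation).  The consensus label of a seed is the one it carries most
frequently across days; ties go to the lowest label and are flagged.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .preprocess import second_derivative
from .spectra import SpectraTable

__all__ = ["ClusterAssignment", "ward_cluster_day", "align_labels",
           "consensus_assign", "cluster_profiles", "cluster_seeds"]


@dataclass
class ClusterAssignment:
    per_day_labels: pd.DataFrame       # index seed_id, columns days
    consensus: pd.Series               # seed_id -> label
    appearance_counts: pd.DataFrame    # index seed_id, columns labels
    tie_flags: tuple

    def label_of(self, seed_id) -> int:
        return int(self.consensus.loc[seed_id])


def ward_cluster_day(table_day: SpectraTable, k: int = 3) -> tuple[pd.Series, np.ndarray]:
    """Ward/Euclidean clustering of one day's seeds into exactly k clusters.

    Requires one row per seed (average positions first).  Returns labels
    (seed_id -> 1..k) and the scipy linkage matrix.
    """
    seeds = table_day.meta["seed_id"]
    if seeds.duplicated().any():
        raise ValueError("one row per seed required; average positions first")
    if table_day.n_rows < k:
        raise ValueError(f"fewer seeds ({table_day.n_rows}) than clusters ({k})")
    Z = linkage(table_day.values, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=list(seeds), name="cluster"), Z


def align_labels(partitions: pd.DataFrame, reference_day=None) -> pd.DataFrame:
    """Permute each day's labels to best match the reference day's partition.

    ``partitions``: DataFrame indexed by seed_id with one column per day
    (NaN marks a seed missing on that day).  The permutation maximizing
    the number of seeds with matching labels is applied per day; among
    equally good permutations the lexicographically smallest is chosen,
    so aligning a day with itself is the identity.
    """
    days = list(partitions.columns)
    if reference_day is None:
        reference_day = days[0]
    ref = partitions[reference_day]
    labels = sorted({int(v) for col in days
                     for v in partitions[col].dropna().unique()})
    aligned = partitions.copy()
    for day in days:
        col = partitions[day]
        shared = col.notna() & ref.notna()
        best_perm, best_score = None, -1
        for perm in itertools.permutations(labels):
            mapping = dict(zip(labels, perm))
            score = int((col[shared].map(mapping) == ref[shared]).sum())
            if score > best_score:
                best_perm, best_score = mapping, score
        aligned[day] = col.map(lambda v, m=best_perm: m[int(v)] if pd.notna(v) else v)
    return aligned


def consensus_assign(aligned: pd.DataFrame) -> ClusterAssignment:
    """Most-frequent-appearance consensus over aligned per-day labels."""
    if aligned.shape[1] < 1:
        raise ValueError("need at least one day of labels")
    labels = sorted({int(v) for col in aligned.columns
                     for v in aligned[col].dropna().unique()})
    counts = pd.DataFrame(0, index=aligned.index, columns=labels)
    for col in aligned.columns:
        for seed, v in aligned[col].dropna().items():
            counts.loc[seed, int(v)] += 1
    consensus = {}
    ties = []
    for seed, row in counts.iterrows():
        top = row.max()
        winners = [l for l in labels if row[l] == top]
        consensus[seed] = winners[0]
        if len(winners) > 1:
            ties.append(seed)
    return ClusterAssignment(aligned, pd.Series(consensus, name="consensus"),
                             counts, tuple(ties))


def cluster_seeds(table: SpectraTable, k: int = 3, reference_day=None) -> ClusterAssignment:
    """Full chain: per-day Ward clustering -> label alignment -> consensus.

    ``table`` must hold one row per (seed, day): average positions first.
    """
    days = sorted(pd.unique(table.meta["day"]))
    cols = {}
    for day in days:
        sub = table.select_rows((table.meta["day"] == day).to_numpy())
        labels, _ = ward_cluster_day(sub, k=k)
        cols[day] = labels
    partitions = pd.DataFrame(cols)
    aligned = align_labels(partitions, reference_day)
    return consensus_assign(aligned)


def cluster_profiles(table: SpectraTable, assignment: ClusterAssignment,
                     d2_window: int = 31, d2_polyorder: int = 2
                     ) -> tuple[SpectraTable, SpectraTable]:
    """Per-cluster (and per sample type) average spectra and their 2nd
    derivatives.  Empty clusters are omitted with a warning."""
    seeds = table.meta["seed_id"]
    unknown = set(seeds) - set(assignment.consensus.index)
    if unknown:
        raise ValueError(f"assignment does not cover seeds {sorted(unknown)}")
    cluster = seeds.map(assignment.consensus)
    types = pd.unique(table.meta["sample_type"]) if "sample_type" in table.meta.columns \
        else np.array(["all"])
    rows, metas = [], []
    for t in types:
        in_type = (table.meta["sample_type"] == t).to_numpy() \
            if "sample_type" in table.meta.columns else np.ones(table.n_rows, bool)
        for c in sorted(assignment.consensus.unique()):
            sel = in_type & (cluster == c).to_numpy()
            if not sel.any():
                warnings.warn(f"cluster {c} of {t!r} is empty; omitted", stacklevel=2)
                continue
            rows.append(table.values[sel].mean(axis=0))
            metas.append({"sample_type": t, "cluster": int(c)})
    profiles = SpectraTable(table.wavelengths, np.array(rows), pd.DataFrame(metas),
                            table.provenance + ("cluster_profiles",))
    d2 = second_derivative(profiles, d2_window, d2_polyorder)
    return profiles, d2
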