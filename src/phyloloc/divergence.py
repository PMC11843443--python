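"""Greedy identity clustering and per-compartment sequence divergence.

Clustering is a simplified greedy incremental scheme in the style of CD-HIT
(threshold 0.5, word length 3): sequences are taken longest first, each
joining the first existing cluster whose representative it matches at or
above the identity threshold (identity = identical alignment positions /
shorter sequence length), else founding its own cluster; a shared-3-mer
prefilter can skip alignments that cannot pass.

Divergence of a cluster is the average pairwise divergence D: for each
unordered member pair the two sequences are globally aligned and divergence
is the fraction of differing columns among columns where both sequences have
residues (indel columns excluded); D is the mean over pairs.  Compartments
retain only clusters with >= 2 members, all single-localized to the same
compartment, and only compartments with more than 40 surviving clusters
enter the cross-compartment comparison.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import global_align

log = logging.getLogger(__name__)


@dataclass
class Cluster:
    cluster_id: int
    representative: str
    members: list[str] = field(default_factory=list)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def pair_identity(seq_a: str, seq_b: str) -> float:
    """Identity over the shorter sequence (the CD-HIT convention)."""
    aln = global_align(seq_a, seq_b)
    return aln.n_identical / min(len(seq_a), len(seq_b))


def greedy_cluster(
    sequences: Mapping[str, str],
    threshold: float = 0.5,
    word_length: int = 3,
) -> list[Cluster]:
    """Greedy incremental clustering at an identity threshold.

    Sequences are processed by decreasing length (ties by ID); each joins the
    first cluster (in creation order) whose representative it matches at
    >= *threshold* identity, else founds a new cluster.
    """
    order = sorted(sequences, key=lambda s: (-len(sequences[s]), s))
    clusters: list[Cluster] = []
    rep_kmers: list[set[str]] = []
    for name in order:
        seq = sequences[name]
        words = _kmers(seq, word_length)
        placed = False
        for cluster, kset in zip(clusters, rep_kmers):
            if words and kset and not (words & kset):
                continue  # no shared word: identity cannot reach the threshold
            if pair_identity(sequences[cluster.representative], seq) >= threshold:
                cluster.members.append(name)
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(cluster_id=len(clusters), representative=name, members=[name])
            )
            rep_kmers.append(words)
    return clusters


def average_pairwise_divergence(member_sequences: Sequence[str]) -> float:
    """Mean over unordered pairs of (differing columns / mutually resolved
    columns) from global pairwise alignments."""
    if len(member_sequences) < 2:
        raise ValueError("divergence requires >= 2 member sequences")
    divergences = []
    for a, b in itertools.combinations(member_sequences, 2):
        aln = global_align(a, b)
        both = [
            (x, y)
            for x, y in zip(aln.aligned_a, aln.aligned_b)
            if x != "-" and y != "-"
        ]
        if not both:
            divergences.append(1.0)
            continue
        diff = sum(1 for x, y in both if x != y)
        divergences.append(diff / len(both))
    return float(np.mean(divergences))


@dataclass(frozen=True)
class ClusterDivergence:
    """A retained protein cluster with its compartment and D value."""

    cluster_id: int
    members: tuple[str, ...]
    compartment: str
    d_value: float
    age_composition: dict[str, float]


def filter_clusters(
    clusters: Sequence[Cluster],
    called_sets: Mapping[str, frozenset[str]],
    min_members: int = 2,
    min_clusters_per_compartment: int = 40,
    require_shared_compartment: bool = True,
) -> list[tuple[Cluster, str]]:
    """Apply the cluster retention rules and return (cluster, compartment).

    Drops clusters with fewer than *min_members* members, clusters containing
    any multi-localized member and (by default) clusters whose members do not
    all share one compartment; compartments with <= *min_clusters_per_compartment*
    surviving clusters are then dropped entirely.
    """
    survivors: list[tuple[Cluster, str]] = []
    n_small = n_multi = n_mixed = 0
    for cluster in clusters:
        if len(cluster.members) < min_members:
            n_small += 1
            continue
        sets = [called_sets.get(m, frozenset()) for m in cluster.members]
        if any(len(s) != 1 for s in sets):
            n_multi += 1
            continue
        comps = {next(iter(s)) for s in sets}
        if require_shared_compartment and len(comps) != 1:
            n_mixed += 1
            continue
        survivors.append((cluster, next(iter(comps))))
    by_comp: dict[str, int] = {}
    for _, comp in survivors:
        by_comp[comp] = by_comp.get(comp, 0) + 1
    kept = [
        (cluster, comp)
        for cluster, comp in survivors
        if by_comp[comp] > min_clusters_per_compartment
    ]
    log.info(
        "filter_clusters: %d small, %d multi-localized, %d mixed-compartment "
        "dropped; %d clusters in %d compartments retained",
        n_small, n_multi, n_mixed, len(kept),
        len({c for _, c in kept}),
    )
    return kept


def compute_cluster_divergences(
    filtered: Sequence[tuple[Cluster, str]],
    sequences: Mapping[str, str],
    age_class_of: Mapping[str, str] | None = None,
) -> list[ClusterDivergence]:
    results = []
    for cluster, comp in filtered:
        seqs = [sequences[m] for m in cluster.members]
        d = average_pairwise_divergence(seqs)
        composition: dict[str, float] = {}
        if age_class_of is not None:
            for member in cluster.members:
                cls = age_class_of.get(member, "unknown")
                composition[cls] = composition.get(cls, 0.0) + 1
            composition = {
                k: v / len(cluster.members) for k, v in composition.items()
            }
        results.append(
            ClusterDivergence(
                cluster.cluster_id, tuple(cluster.members), comp, d, composition
            )
        )
    return results


def age_constrained_subset(
    cluster_divergences: Sequence[ClusterDivergence],
    allowed_classes: frozenset[str] | set[str] = frozenset({"oldest", "older"}),
) -> list[ClusterDivergence]:
    """Clusters whose age composition lies 100% within *allowed_classes*."""
    return [
        cd
        for cd in cluster_divergences
        if cd.age_composition
        and all(cls in allowed_classes for cls in cd.age_composition)
    ]


def compare_compartment_divergence(
    cluster_divergences: Sequence[ClusterDivergence],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-compartment D summaries and all-pairs two-sided rank-sum p-values.

    Compartments with fewer than two clusters are excluded from testing.
    """
    by_comp: dict[str, list[float]] = {}
    for cd in cluster_divergences:
        by_comp.setdefault(cd.compartment, []).append(cd.d_value)
    summary = pd.DataFrame(
        [
            {
                "compartment": comp,
                "n_clusters": len(ds),
                "mean_d": float(np.mean(ds)),
                "median_d": float(np.median(ds)),
            }
            for comp, ds in sorted(by_comp.items())
        ]
    )
    testable = sorted(c for c, ds in by_comp.items() if len(ds) >= 2)
    pvals = pd.DataFrame(np.nan, index=testable, columns=testable)
    for a, b in itertools.combinations(testable, 2):
        _, p = stats.mannwhitneyu(by_comp[a], by_comp[b], alternative="two-sided")
        pvals.loc[a, b] = p
        pvals.loc[b, a] = p
    if not testable:
        log.info("compare_compartment_divergence: <2 testable compartments")
    return summary, pvals
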