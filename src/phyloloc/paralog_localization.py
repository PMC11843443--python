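"""Paralog duplication-age and localization-change classification.

Paralog pairs are oriented so the parent gene originated on a strictly older
branch than the offspring.  Duplication age is ancient for the deep-branch
pairs (parent br-2 with offspring br-1/br0, or parent br-1 with offspring
br0) and recent otherwise.  The localization-change pattern of offspring
set O relative to parent set P is:

    K   O = P            (kept identical)
    KE  P proper subset of O   (kept and extended)
    S   O proper subset of P   (shrunk)
    E   O and P disjoint       (entirely exchanged)
    SE  partial overlap with both gain and loss

which is a partition of all non-empty (P, O) pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import global_align, mutation_position_bins
from .vocab import is_older

log = logging.getLogger(__name__)

PATTERNS = ("K", "SE", "S", "E", "KE")

ANCIENT_RULES = frozenset({("br-2", "br-1"), ("br-2", "br0"), ("br-1", "br0")})


def classify_duplication(parent_branch: str, offspring_branch: str) -> str:
    """'ancient' for the deep-branch rule set, 'recent' for everything else."""
    if not is_older(parent_branch, offspring_branch):
        raise ValueError(
            f"parent branch {parent_branch!r} must be strictly older than "
            f"offspring branch {offspring_branch!r}"
        )
    if (parent_branch, offspring_branch) in ANCIENT_RULES:
        return "ancient"
    return "recent"


def classify_change(parent_set: frozenset[str], offspring_set: frozenset[str]) -> str:
    """Localization-change pattern of the offspring relative to the parent."""
    if not parent_set or not offspring_set:
        raise ValueError("parent and offspring localization sets must be non-empty")
    if offspring_set == parent_set:
        return "K"
    if parent_set < offspring_set:
        return "KE"
    if offspring_set < parent_set:
        return "S"
    if not (offspring_set & parent_set):
        return "E"
    return "SE"


@dataclass(frozen=True)
class ParalogPair:
    parent: str
    offspring: str
    parent_branch: str
    offspring_branch: str
    parent_set: frozenset[str]
    offspring_set: frozenset[str]
    duplication_age: str
    change_pattern: str


def classify_pairs(
    pairs: pd.DataFrame,
    branch_of: Mapping[str, str],
    called_sets: Mapping[str, frozenset[str]],
) -> tuple[list[ParalogPair], dict[str, int]]:
    """Orient, filter and classify raw paralog pairs.

    Filters, in order: pairs with an undated gene; equal-branch pairs (the
    parent must be strictly older); genes participating in more than one pair
    (the one-to-one filter); pairs with an empty localization set on either
    side.  Returns the classified pairs and the per-filter attrition counts.
    """
    attrition = {
        "input_pairs": len(pairs),
        "undated": 0,
        "equal_branch": 0,
        "not_one_to_one": 0,
        "unlocalized": 0,
        "classified": 0,
    }
    oriented: list[tuple[str, str]] = []
    for g1, g2 in pairs.itertuples(index=False):
        if g1 not in branch_of or g2 not in branch_of:
            attrition["undated"] += 1
            continue
        b1, b2 = branch_of[g1], branch_of[g2]
        if b1 == b2:
            attrition["equal_branch"] += 1
            continue
        parent, offspring = (g1, g2) if is_older(b1, b2) else (g2, g1)
        oriented.append((parent, offspring))

    usage: dict[str, int] = {}
    for parent, offspring in oriented:
        usage[parent] = usage.get(parent, 0) + 1
        usage[offspring] = usage.get(offspring, 0) + 1

    classified: list[ParalogPair] = []
    for parent, offspring in oriented:
        if usage[parent] > 1 or usage[offspring] > 1:
            attrition["not_one_to_one"] += 1
            continue
        p_set = called_sets.get(parent, frozenset())
        o_set = called_sets.get(offspring, frozenset())
        if not p_set or not o_set:
            attrition["unlocalized"] += 1
            continue
        pb, ob = branch_of[parent], branch_of[offspring]
        classified.append(
            ParalogPair(
                parent, offspring, pb, ob,
                p_set, o_set,
                classify_duplication(pb, ob),
                classify_change(p_set, o_set),
            )
        )
    attrition["classified"] = len(classified)
    log.info("classify_pairs attrition: %s", attrition)
    return classified, attrition


def pattern_spectrum(pairs: Sequence[ParalogPair]) -> pd.DataFrame:
    """Percentage of pairs per change pattern, overall and per duplication age."""
    rows = []
    strata = [("all", list(pairs))]
    for age in ("recent", "ancient"):
        strata.append((age, [p for p in pairs if p.duplication_age == age]))
    for stratum, members in strata:
        n = len(members)
        for pattern in PATTERNS:
            count = sum(1 for p in members if p.change_pattern == pattern)
            rows.append(
                {
                    "stratum": stratum,
                    "pattern": pattern,
                    "count": count,
                    "percent": 100.0 * count / n if n else np.nan,
                    "flagged": n == 0,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class KvsNonKResult:
    k_similarity: list[float]
    nonk_similarity: list[float]
    similarity_p: float  # one-sided: K greater
    k_positions: list[float]
    nonk_positions: list[float]
    position_p: float  # two-sided
    k_bins: tuple[int, int, int]
    nonk_bins: tuple[int, int, int]
    n_dropped: int


def k_vs_nonk_comparison(
    pairs: Sequence[ParalogPair],
    sequences: Mapping[str, str],
) -> KvsNonKResult:
    """Compare sequence similarity and mutation positions between K pairs
    and non-K pairs (alignment identity; one-sided rank-sum for similarity,
    two-sided for pooled relative mutation positions)."""
    k_sim: list[float] = []
    nonk_sim: list[float] = []
    k_pos: list[float] = []
    nonk_pos: list[float] = []
    n_dropped = 0
    for pair in pairs:
        if pair.parent not in sequences or pair.offspring not in sequences:
            n_dropped += 1
            continue
        aln = global_align(sequences[pair.parent], sequences[pair.offspring])
        positions = aln.mutation_positions()
        if pair.change_pattern == "K":
            k_sim.append(aln.identity)
            k_pos.extend(positions)
        else:
            nonk_sim.append(aln.identity)
            nonk_pos.extend(positions)
    if n_dropped:
        log.info("k_vs_nonk: %d pair(s) dropped for missing sequences", n_dropped)

    def _test(a: list[float], b: list[float], alternative: str) -> float:
        if not a or not b:
            return float("nan")
        if np.var(a + b) == 0:
            return 1.0
        return float(stats.mannwhitneyu(a, b, alternative=alternative).pvalue)

    return KvsNonKResult(
        k_similarity=k_sim,
        nonk_similarity=nonk_sim,
        similarity_p=_test(k_sim, nonk_sim, "greater"),
        k_positions=k_pos,
        nonk_positions=nonk_pos,
        position_p=_test(k_pos, nonk_pos, "two-sided"),
        k_bins=mutation_position_bins(k_pos),
        nonk_bins=mutation_position_bins(nonk_pos),
        n_dropped=n_dropped,
    )


def pairs_table(pairs: Sequence[ParalogPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parent": p.parent,
                "offspring": p.offspring,
                "parent_branch": p.parent_branch,
                "offspring_branch": p.offspring_branch,
                "parent_set": ";".join(sorted(p.parent_set)),
                "offspring_set": ";".join(sorted(p.offspring_set)),
                "duplication_age": p.duplication_age,
                "change_pattern": p.change_pattern,
            }
            for p in pairs
        ]
    )
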