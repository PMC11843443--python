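"""Co-localization resampling and co-function expectation statistics.

Co-localization: within a target branch, count protein pairs sharing their
(single) subcellular compartment; compare against an equal-size random
sample of comparison pairs, either target-vs-other-branch pairs (strategy A)
or all pairs in the dataset (strategy B).  The per-iteration excess percent
is (intra co-localization - sampled comparison co-localization) /
sampled comparison co-localization x 100, summarized as mean +/- sd over
(by default) 100 iterations.

Co-function: a protein pair is co-functional when their pathway sets
intersect.  The random expectation that a pair shares a pathway is
p_co = sum_i P(K_i)^2 with P(K_i) the fraction of all annotated proteins on
pathway K_i; the expected number of co-functional pairs in a group of m
proteins is C(m, 2) x p_co, compared with the observed count O via the
excess (O - E) / E.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .vocab import BRANCH_LABELS

log = logging.getLogger(__name__)


@dataclass
class ColocalizationResult:
    """Resampled co-localization excess for one target branch."""

    branch: str
    strategy: str
    intra_num: int
    inter_num: int
    co_intra: int
    sample_size: int
    excess_per_iteration: list[float] = field(default_factory=list)
    n_zero_denominator: int = 0
    capped: bool = False
    skipped: bool = False

    @property
    def mean_excess(self) -> float:
        if not self.excess_per_iteration:
            return math.nan
        return float(np.mean(self.excess_per_iteration))

    @property
    def sd_excess(self) -> float:
        if not self.excess_per_iteration:
            return math.nan
        return float(np.std(self.excess_per_iteration, ddof=1))


def _count_copairs(codes: np.ndarray) -> int:
    """Number of unordered pairs with equal compartment code."""
    counts = np.bincount(codes)
    return int((counts * (counts - 1) // 2).sum())


def _triangular_decode(linear: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map linear indices in [0, C(n,2)) to unordered pairs (i < j)."""
    linear = linear.astype(np.int64)
    b = 2 * n - 1
    i = np.floor((b - np.sqrt(b * b - 8.0 * linear)) / 2.0).astype(np.int64)
    # guard against float rounding at stratum boundaries
    start = i * (2 * n - i - 1) // 2
    too_big = start > linear
    i[too_big] -= 1
    start = i * (2 * n - i - 1) // 2
    too_small = linear - start >= (n - 1 - i)
    i[too_small] += 1
    start = i * (2 * n - i - 1) // 2
    j = i + 1 + (linear - start)
    return i, j


def colocalization_excess(
    branch_of: Mapping[str, str],
    compartment_of: Mapping[str, str],
    strategy: str = "A",
    n_iter: int = 100,
    seed: int = 0,
) -> list[ColocalizationResult]:
    """Per-branch co-localization excess over *n_iter* resampling iterations.

    Only proteins present in both mappings participate; callers are expected
    to have restricted *compartment_of* to single-compartment proteins
    (longest-transcript representatives).  Iterations whose comparison sample
    contains no co-localized pair are excluded from the mean and counted.
    """
    if strategy not in ("A", "B"):
        raise ValueError(f"strategy must be 'A' or 'B', got {strategy!r}")
    proteins = sorted(p for p in compartment_of if p in branch_of)
    n = len(proteins)
    branches = np.array([branch_of[p] for p in proteins])
    comp_names = sorted(set(compartment_of[p] for p in proteins))
    comp_code = {c: i for i, c in enumerate(comp_names)}
    comps = np.array([comp_code[compartment_of[p]] for p in proteins])

    rng = np.random.default_rng(seed)
    results: list[ColocalizationResult] = []
    for branch in BRANCH_LABELS:
        t_mask = branches == branch
        m = int(t_mask.sum())
        if m < 2:
            if m > 0:
                results.append(
                    ColocalizationResult(branch, strategy, 0, 0, 0, 0, skipped=True)
                )
            continue
        t_comps = comps[t_mask]
        o_comps = comps[~t_mask]
        intra_num = m * (m - 1) // 2
        co_intra = _count_copairs(t_comps)
        if strategy == "A":
            pool_size = m * (n - m)
        else:
            pool_size = n * (n - 1) // 2
        k = min(intra_num, pool_size)
        res = ColocalizationResult(
            branch, strategy, intra_num, pool_size, co_intra, k,
            capped=k < intra_num,
        )
        if pool_size == 0:
            res.skipped = True
            results.append(res)
            continue
        rate_intra = co_intra / intra_num
        for _ in range(n_iter):
            linear = rng.choice(pool_size, size=k, replace=False)
            if strategy == "A":
                ii = linear // (n - m)
                jj = linear % (n - m)
                co = int((t_comps[ii] == o_comps[jj]).sum())
            else:
                ii, jj = _triangular_decode(linear, n)
                co = int((comps[ii] == comps[jj]).sum())
            if co == 0:
                res.n_zero_denominator += 1
                continue
            rate_inter = co / k
            res.excess_per_iteration.append(
                (rate_intra - rate_inter) / rate_inter * 100.0
            )
        if res.n_zero_denominator:
            log.info(
                "colocalization %s: %d/%d iterations had zero co-localized "
                "comparison pairs and were excluded",
                branch, res.n_zero_denominator, n_iter,
            )
        results.append(res)
    return results


@dataclass(frozen=True)
class RegressionResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    flagged: bool


def excess_vs_branch_regression(
    mean_excess: Sequence[float],
    branch_order: Sequence[str] | None = None,
) -> RegressionResult:
    """Pearson correlation of mean co-localization excess against branch
    index (oldest to youngest), with fitted-line parameters."""
    y = np.asarray(mean_excess, dtype=float)
    keep = ~np.isnan(y)
    y = y[keep]
    if branch_order is not None and len(branch_order) != len(keep):
        raise ValueError("branch_order length does not match mean_excess")
    x = np.arange(len(keep), dtype=float)[keep]
    if len(y) < 3:
        raise ValueError(f"need >= 3 branches with defined means, got {len(y)}")
    if np.allclose(y, y[0]):
        return RegressionResult(math.nan, math.nan, 0.0, float(y[0]), flagged=True)
    fit = stats.linregress(x, y)
    return RegressionResult(
        float(fit.rvalue), float(fit.pvalue), float(fit.slope),
        float(fit.intercept), flagged=False,
    )


@dataclass(frozen=True)
class CofunctionResult:
    """Observed vs expected co-functional pair counts for one age group."""

    group: str
    n_proteins: int
    p_co: float
    expected: float
    observed: int

    @property
    def excess(self) -> float:
        if self.expected == 0:
            return math.nan
        return (self.observed - self.expected) / self.expected


def cofunction_probability(pathways: Mapping[str, set[str]]) -> float:
    """p_co = sum over pathways of (fraction of annotated proteins on it)^2.

    Single-membership arithmetic as defined for the expectation; with
    multi-pathway proteins the sum can exceed the true pair probability,
    which is kept as the normative (documented) simplification.
    """
    annotated = [p for p, s in pathways.items() if s]
    if not annotated:
        raise ValueError("pathway universe is empty")
    n = len(annotated)
    counts: dict[str, int] = {}
    for protein in annotated:
        for pw in pathways[protein]:
            counts[pw] = counts.get(pw, 0) + 1
    return float(sum((c / n) ** 2 for c in counts.values()))


def _observed_cofunction_pairs(members: list[str], pathways: Mapping[str, set[str]]) -> int:
    """Pairs with intersecting pathway sets, via a sparse incidence product."""
    universe = sorted({pw for m in members for pw in pathways[m]})
    if not universe:
        return 0
    col = {pw: i for i, pw in enumerate(universe)}
    rows, cols = [], []
    for r, m in enumerate(members):
        for pw in pathways[m]:
            rows.append(r)
            cols.append(col[pw])
    inc = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(members), len(universe)),
    )
    gram = (inc @ inc.T).tocoo()
    return int(np.count_nonzero(gram.row < gram.col))


def cofunction_expectation(
    pathways: Mapping[str, set[str]],
    group_of: Mapping[str, str],
) -> list[CofunctionResult]:
    """Per-group observed vs expected co-functional pair counts.

    P(K_i) is computed over all annotated proteins; groups with fewer than
    two annotated members are skipped with a log line.
    """
    p_co = cofunction_probability(pathways)
    members_by_group: dict[str, list[str]] = {}
    for protein, group in group_of.items():
        if pathways.get(protein):
            members_by_group.setdefault(group, []).append(protein)
    results = []
    for group in sorted(members_by_group):
        members = sorted(members_by_group[group])
        m = len(members)
        if m < 2:
            log.info("cofunction: group %s has <2 annotated proteins, skipped", group)
            continue
        expected = m * (m - 1) / 2 * p_co
        observed = _observed_cofunction_pairs(members, pathways)
        results.append(CofunctionResult(group, m, p_co, expected, observed))
    return results


def colocalization_table(results: list[ColocalizationResult]) -> pd.DataFrame:
    rows = [
        {
            "branch": r.branch,
            "strategy": r.strategy,
            "intra_num": r.intra_num,
            "inter_num": r.inter_num,
            "co_intra": r.co_intra,
            "sample_size": r.sample_size,
            "mean_excess_pct": r.mean_excess,
            "sd_excess_pct": r.sd_excess,
            "n_iterations_used": len(r.excess_per_iteration),
            "n_zero_denominator": r.n_zero_denominator,
            "capped": r.capped,
            "skipped": r.skipped,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def cofunction_table(results: list[CofunctionResult]) -> pd.DataFrame:
    rows = [
        {
            "group": r.group,
            "n_proteins": r.n_proteins,
            "p_co": r.p_co,
            "expected": r.expected,
            "observed": r.observed,
            "excess": r.excess,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
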