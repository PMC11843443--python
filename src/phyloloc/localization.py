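"""Compartment calling and branch-wise localization enrichment.

A protein is called to every compartment whose predicted probability is
strictly greater than 0.5, so multi-compartment membership is allowed.
Enrichment compares, per (age group, compartment) cell, the observed count of
localized proteins with the count expected if localization were independent
of gene age: expected = total_in_compartment x group_size / N.  Excess is
reported as (observed - expected) / expected x 100 with a per-cell Fisher
exact test and Benjamini-Hochberg adjusted q-values.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .vocab import COMPARTMENTS, LEVEL3, age_class, level3_of

log = logging.getLogger(__name__)


def call_compartments(
    probabilities: Mapping[str, float], threshold: float = 0.5
) -> frozenset[str]:
    """Compartments with probability strictly greater than *threshold*."""
    called = set()
    for comp in COMPARTMENTS:
        p = probabilities[comp]
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} for {comp} outside [0, 1]")
        if p > threshold:
            called.add(comp)
    return frozenset(called)


def called_sets_from_table(
    table: pd.DataFrame, threshold: float = 0.5
) -> dict[str, frozenset[str]]:
    """Vectorized compartment calling over a localization probability table."""
    mask = table[list(COMPARTMENTS)].to_numpy() > threshold
    comps = np.array(COMPARTMENTS)
    return {
        protein: frozenset(comps[row])
        for protein, row in zip(table.index, mask)
    }


def level3_set(called: frozenset[str]) -> frozenset[str]:
    """Collapse a nine-compartment call set to the three-level grouping."""
    return frozenset(level3_of(c) for c in called)


def enrichment(
    branch_of: Mapping[str, str],
    called: Mapping[str, frozenset[str]],
    level: str = "compartment9",
    group_by_age_class: bool = False,
) -> pd.DataFrame:
    """Observed-vs-expected localization counts per (group, compartment).

    Proteins with an empty call set are excluded from all denominators and
    reported via the table's ``n_unlocalized`` attribute.  Groups are either
    branches or (with *group_by_age_class*) the four-class collapse; *level*
    selects the nine compartments or the three-level grouping.
    """
    if level == "compartment9":
        categories: tuple[str, ...] = COMPARTMENTS
        setter = lambda s: s  # noqa: E731
    elif level == "level3":
        categories = LEVEL3
        setter = level3_set
    else:
        raise ValueError(f"unknown level {level!r}")

    proteins = [p for p in called if p in branch_of]
    localized = [p for p in proteins if called[p]]
    n_unlocalized = len(proteins) - len(localized)
    if n_unlocalized:
        log.info("enrichment: %d unlocalized proteins excluded", n_unlocalized)

    group_of = {
        p: (age_class(branch_of[p]) if group_by_age_class else branch_of[p])
        for p in localized
    }
    groups = sorted(set(group_of.values()))
    n_total = len(localized)

    in_group = {g: {p for p in localized if group_of[p] == g} for g in groups}
    in_comp = {
        c: {p for p in localized if c in setter(called[p])} for c in categories
    }

    rows = []
    for g in groups:
        n_g = len(in_group[g])
        for c in categories:
            total_c = len(in_comp[c])
            observed = len(in_group[g] & in_comp[c])
            expected = total_c * n_g / n_total if n_total else 0.0
            if expected > 0:
                excess = (observed - expected) / expected * 100.0
                flagged = False
            else:
                excess = np.nan
                flagged = True
            a = observed
            b = n_g - observed
            c_out = total_c - observed
            d = n_total - n_g - c_out
            _, p_value = stats.fisher_exact([[a, b], [c_out, d]])
            rows.append(
                {
                    "group": g,
                    "compartment": c,
                    "n_group": n_g,
                    "observed": observed,
                    "expected": expected,
                    "excess_pct": excess,
                    "fisher_p": p_value,
                    "flagged": flagged,
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["fisher_q"] = multipletests(table["fisher_p"], method="fdr_bh")[1]
    table.attrs["n_unlocalized"] = n_unlocalized
    table.attrs["n_localized"] = n_total
    return table


def breadth_by_age(
    called: Mapping[str, frozenset[str]],
    branch_of: Mapping[str, str],
    k: int,
) -> pd.DataFrame:
    """Per age class, the proportion of proteins localized to more than *k*
    subcellular compartments."""
    if k not in (2, 3, 4):
        raise ValueError(f"k must be 2, 3 or 4, got {k}")
    rows = []
    by_class: dict[str, list[int]] = {}
    for protein, branch in branch_of.items():
        if protein not in called:
            continue
        by_class.setdefault(age_class(branch), []).append(len(called[protein]))
    for cls in ("oldest", "older", "old", "young"):
        sizes = by_class.get(cls, [])
        if not sizes:
            rows.append(
                {"age_class": cls, "k": k, "n": 0, "proportion": np.nan, "flagged": True}
            )
            continue
        prop = sum(1 for s in sizes if s > k) / len(sizes)
        rows.append(
            {"age_class": cls, "k": k, "n": len(sizes), "proportion": prop, "flagged": False}
        )
    return pd.DataFrame(rows)
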