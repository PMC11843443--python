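"""Parsimony gene-age dating from syntenic-ortholog presence.

A gene's origination branch is the stratum implied by the oldest-diverging
outgroup clade that still carries a syntenic ortholog of the gene; a gene
absent from every outgroup is species-specific.  The module also implements
the gene-loss correction via a secondary deep outgroup, the masked-exon
retention filter, fixation-rate arithmetic and the sex-vs-autosome
young-gene comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .tables_io import GeneAgeRecord
from .vocab import (
    BRANCH_LABELS,
    YOUNG_BRANCHES,
    branch_index,
    is_older,
    validate_branch,
)


@dataclass(frozen=True)
class Clade:
    """An outgroup clade and the branch implied when it is the most distant
    clade retaining an ortholog."""

    clade_id: str
    species: tuple[str, ...]
    implied_branch: str


@dataclass(frozen=True)
class CladeMap:
    """Ordered outgroup clades, oldest divergence first.

    ``implied_branch`` must strictly increase (get younger) along the list;
    the deepest clade implies br-2 because ages are capped at that stratum.
    """

    clades: tuple[Clade, ...]

    def __post_init__(self) -> None:
        if not self.clades:
            raise ValueError("clade map must contain at least one clade")
        indices = [branch_index(c.implied_branch) for c in self.clades]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("implied branches must strictly increase (get younger)")
        ids = [c.clade_id for c in self.clades]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate clade_id in clade map")

    @property
    def clade_ids(self) -> tuple[str, ...]:
        return tuple(c.clade_id for c in self.clades)


def default_clade_map() -> CladeMap:
    """Eight outgroup clades, one per stratum br-2..br5; genes absent from
    all of them are assigned the species-specific stratum br6."""
    spec = [
        ("bdor", ("B_dorsalis",), "br-2"),
        ("sleb", ("S_lebanonensis",), "br-1"),
        ("dvir_grp", ("D_virilis", "D_novamexicana", "D_hydei"), "br0"),
        ("dwil", ("D_willistoni",), "br1"),
        ("dana", ("D_ananassae",), "br2"),
        ("dpse_grp", ("D_persimilis", "D_azteca"), "br3"),
        ("dere_grp", ("D_erecta", "D_orena"), "br4"),
        ("dsim_grp", ("D_simulans", "D_sechellia"), "br5"),
    ]
    return CladeMap(tuple(Clade(cid, sp, br) for cid, sp, br in spec))


def assign_age(presence_row: Mapping[str, bool], clade_map: CladeMap) -> str:
    """Parsimony assignment: the implied branch of the oldest-diverging clade
    with a present ortholog; br6 (species-specific) when all are absent."""
    unknown = set(presence_row) - set(clade_map.clade_ids)
    if unknown:
        raise KeyError(f"unknown clade key(s) {sorted(unknown)}")
    for clade in clade_map.clades:
        if clade.clade_id not in presence_row:
            raise KeyError(f"presence row missing clade {clade.clade_id!r}")
        if presence_row[clade.clade_id]:
            return clade.implied_branch
    return BRANCH_LABELS[-1]


def assign_ages(presence: pd.DataFrame, clade_map: CladeMap) -> pd.Series:
    """Vectorized :func:`assign_age` over a gene x clade boolean matrix."""
    missing = [c for c in clade_map.clade_ids if c not in presence.columns]
    if missing:
        raise KeyError(f"presence matrix missing clade column(s) {missing}")
    ordered = presence[list(clade_map.clade_ids)].astype(bool)
    labels = pd.Series(BRANCH_LABELS[-1], index=presence.index, name="branch")
    assigned = pd.Series(False, index=presence.index)
    for clade in clade_map.clades:
        hit = ordered[clade.clade_id] & ~assigned
        labels[hit] = clade.implied_branch
        assigned |= hit
    return labels


def apply_loss_correction(
    ages: Mapping[str, str],
    secondary_presence: Mapping[str, bool],
    from_branch: str,
    to_branch: str,
) -> tuple[dict[str, str], int]:
    """Reassign genes dated *from_branch* but present in a secondary deep
    outgroup to the older *to_branch*; such genes were mis-dated because the
    primary outgroup lost them.  Returns (corrected ages, count moved)."""
    validate_branch(from_branch)
    validate_branch(to_branch)
    if not is_older(to_branch, from_branch):
        raise ValueError(f"to_branch {to_branch!r} must be older than from_branch {from_branch!r}")
    corrected = dict(ages)
    moved = 0
    for gene, branch in ages.items():
        if branch == from_branch and secondary_presence.get(gene, False):
            corrected[gene] = to_branch
            moved += 1
    return corrected, moved


def masked_exon_filter(
    masked_fraction: Mapping[str, float], max_fraction: float = 0.70
) -> set[str]:
    """Retain genes whose masked-exon fraction does not exceed the cutoff
    (strictly greater than 70% is excluded)."""
    retained = set()
    for gene, frac in masked_fraction.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"gene {gene!r}: masked fraction {frac} outside [0, 1]")
        if frac <= max_fraction:
            retained.add(gene)
    return retained


@dataclass(frozen=True)
class FixationRateResult:
    """Net gene fixations per million years on a branch: (births - deaths)/span."""

    births: int
    deaths: int
    span_my: float

    @property
    def rate(self) -> float:
        return (self.births - self.deaths) / self.span_my

    def rounded(self, ndigits: int = 0) -> float:
        """Rate rounded half-up to the requested precision (the convention
        used when quoting rates); the raw float stays available as .rate."""
        q = Decimal(1).scaleb(-ndigits)
        value = Decimal(repr(self.rate)).quantize(q, rounding=ROUND_HALF_UP)
        return float(value)


def fixation_rate(births: int, deaths: int, span_my: float) -> FixationRateResult:
    if span_my <= 0:
        raise ValueError(f"span must be positive, got {span_my}")
    if not births >= deaths >= 0:
        raise ValueError(f"need births >= deaths >= 0, got {births}, {deaths}")
    return FixationRateResult(births, deaths, span_my)


def percentage(part: int, whole: int, ndigits: int = 1) -> float:
    """part/whole as a percent, rounded half-up to *ndigits* decimals."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    q = Decimal(1).scaleb(-ndigits)
    value = Decimal(repr(100.0 * part / whole)).quantize(q, rounding=ROUND_HALF_UP)
    return float(value)


def branch_counts(
    records: Iterable[GeneAgeRecord], biotype: str | None = None
) -> dict[str, int]:
    """Gene counts per branch, optionally restricted to one biotype."""
    counts = {b: 0 for b in BRANCH_LABELS}
    for rec in records:
        if biotype is not None and rec.biotype != biotype:
            continue
        counts[rec.branch] += 1
    return counts


def young_count(counts: Mapping[str, int]) -> int:
    return sum(counts[b] for b in YOUNG_BRANCHES)


@dataclass(frozen=True)
class ChromosomeClassResult:
    young_proportion: dict[str, float]
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: classes; cols: young, not-young
    statistic: float
    p_value: float


def chromosome_class_test(
    records: Iterable[GeneAgeRecord],
    class_of: Mapping[str, str],
) -> ChromosomeClassResult:
    """Young-gene proportion per chromosome class (sex vs autosome) and a
    2x2 chi-squared test (young vs not-young x sex vs autosome)."""
    classes = ("sex", "autosome")
    young = {c: 0 for c in classes}
    old = {c: 0 for c in classes}
    for rec in records:
        try:
            cls = class_of[rec.chromosome]
        except KeyError as exc:
            raise KeyError(f"gene {rec.gene_id}: chromosome {rec.chromosome!r} unmapped") from exc
        if cls not in classes:
            raise ValueError(f"unknown chromosome class {cls!r}")
        if rec.branch in YOUNG_BRANCHES:
            young[cls] += 1
        else:
            old[cls] += 1
    for cls in classes:
        if young[cls] + old[cls] == 0:
            raise ValueError(f"chromosome class {cls!r} has zero genes")
    table = tuple((young[c], old[c]) for c in classes)
    proportions = {
        c: 100.0 * young[c] / (young[c] + old[c]) for c in classes
    }
    # plain (uncorrected) chi-squared so the statistic matches the textbook formula
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ChromosomeClassResult(proportions, table, float(stat), float(p))


def records_from_ages(
    ages: Mapping[str, str],
    biotype_of: Mapping[str, str] | None = None,
    chromosome_of: Mapping[str, str] | None = None,
) -> list[GeneAgeRecord]:
    """Assemble GeneAgeRecords from an age mapping plus optional metadata."""
    return [
        GeneAgeRecord(
            gene,
            branch,
            (biotype_of or {}).get(gene, "protein_coding"),
            (chromosome_of or {}).get(gene, "NA"),
        )
        for gene, branch in ages.items()
    ]
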