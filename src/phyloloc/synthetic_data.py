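"""Synthetic input generator with retained ground truth.

Emulates the six input classes the pipeline consumes — syntenic-ortholog
presence matrices, localization probability tables, STRING-style physical
links, pathway annotations, paralog pair tables with protein FASTA, and a
GTF annotation — with the statistical structure the analysis assumes:
branch-dependent compartment preferences (young genes skewed extracellular),
a within-compartment edge preference in the interaction network, a
same-branch pathway co-membership boost, and compartment-dependent
substitution rates (extracellular fastest).

Every generator draws from its own pseudo-random stream derived from the
master seed by a fixed offset (``default_rng([seed, offset])``), so changing
one generator's draw count never perturbs another's output.  A fixed seed
makes every table bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import tables_io
from .age_dating import CladeMap, default_clade_map
from .vocab import BRANCH_LABELS, COMPARTMENTS, age_class, branch_index

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# substream offsets (see module docstring)
_STREAMS = {
    "history": 0,
    "localization": 1,
    "ppi": 2,
    "pathways": 3,
    "paralogs": 4,
    "sequences": 5,
    "annotation": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


def _default_birth_weights() -> dict[str, float]:
    # proportions follow the observed dated protein-coding distribution:
    # a br-2-heavy background with young branches at their reported ratios
    return {
        "br-2": 11000.0,
        "br-1": 1107.0,
        "br0": 714.0,
        "br1": 198.0,
        "br2": 275.0,
        "br3": 241.0,
        "br4": 326.0,
        "br5": 47.0,
        "br6": 47.0,
    }


def _default_compartment_preference() -> dict[str, np.ndarray]:
    """Per-age-class probability vector over the nine compartments.

    Emulates the study conditions: young (and old/br0) proteins skewed to
    the extracellular space, the oldest proteins intracellular
    (nucleus/cytoplasm/mitochondrion-heavy).
    """
    # The oldest class is spread broadly over the intracellular compartments
    # (broad localization, weak within-class co-localization); preference
    # sharpens toward the young class, which concentrates on the
    # extracellular space.
    base = {
        # Cyt,  Nuc,  Ext,  Mem,  Mit,  ER,   Lys,  Gol,  Per
        "oldest": [0.18, 0.20, 0.02, 0.12, 0.14, 0.10, 0.09, 0.09, 0.06],
        "older":  [0.20, 0.22, 0.08, 0.12, 0.13, 0.08, 0.06, 0.07, 0.04],
        "old":    [0.16, 0.16, 0.30, 0.12, 0.10, 0.06, 0.04, 0.04, 0.02],
        "young":  [0.12, 0.12, 0.45, 0.10, 0.06, 0.05, 0.04, 0.04, 0.02],
    }
    return {cls: np.asarray(v, dtype=float) for cls, v in base.items()}


def uniform_compartment_preference() -> dict[str, np.ndarray]:
    """Age-independent localization (the null condition for enrichment)."""
    v = np.full(len(COMPARTMENTS), 1.0 / len(COMPARTMENTS))
    return {cls: v.copy() for cls in ("oldest", "older", "old", "young")}


def _default_substitution_rates() -> dict[str, float]:
    # extracellular proteins diverge 3x faster than the baseline; the
    # baseline keeps within-family identity well above the 0.5 clustering
    # threshold so families remain recoverable as clusters
    rates = {c: 0.05 for c in COMPARTMENTS}
    rates["Extracellular"] = 0.15
    return rates


def _default_pattern_fractions() -> dict[str, float]:
    # K-dominated mix; non-K mass split across the four change patterns
    return {"K": 0.667, "KE": 0.12, "S": 0.12, "E": 0.05, "SE": 0.043}


@dataclass
class SimulationParams:
    """All dials of the generator; defaults are the emulated study conditions."""

    n_genes: int = 2000
    branch_birth_weights: dict[str, float] = field(default_factory=_default_birth_weights)
    outgroup_loss_prob: float | dict[str, float] = 0.0
    secondary_loss_prob: float = 0.0
    compartment_preference: dict[str, np.ndarray] = field(
        default_factory=_default_compartment_preference
    )
    multi_label_rate: float = 0.2
    n_edges: int = 10_000
    within_edge_preference: float = 5.0
    n_pathways: int = 50
    cofunction_boost: float = 2.0
    substitution_rate_by_compartment: dict[str, float] = field(
        default_factory=_default_substitution_rates
    )
    n_paralog_pairs: int = 300
    pattern_fractions: dict[str, float] = field(default_factory=_default_pattern_fractions)
    paralog_substitution_rate_k: float = 0.05
    paralog_substitution_rate_nonk: float = 0.15
    nonk_nterm_concentration: float = 0.8
    sequence_length: int = 90
    family_size: int = 3
    alt_transcript_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        weights = [self.branch_birth_weights.get(b, 0.0) for b in BRANCH_LABELS]
        if any(w < 0 for w in weights) or sum(weights) <= 0:
            raise ValueError("branch_birth_weights must be non-negative with positive sum")
        probs = (
            list(self.outgroup_loss_prob.values())
            if isinstance(self.outgroup_loss_prob, dict)
            else [self.outgroup_loss_prob]
        )
        for p in probs + [self.secondary_loss_prob, self.multi_label_rate]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for cls, vec in self.compartment_preference.items():
            vec = np.asarray(vec, dtype=float)
            if len(vec) != len(COMPARTMENTS) or (vec < 0).any():
                raise ValueError(f"bad preference vector for {cls}")
            if not math.isclose(float(vec.sum()), 1.0, rel_tol=1e-9):
                raise ValueError(f"preference vector for {cls} must sum to 1")
        if self.n_pathways <= 0:
            raise ValueError("n_pathways must be positive")
        if not math.isclose(sum(self.pattern_fractions.values()), 1.0, rel_tol=1e-6):
            raise ValueError("pattern_fractions must sum to 1")
        if self.within_edge_preference < 0:
            raise ValueError("within_edge_preference must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually drew, for recovery tests."""

    true_branch: dict[str, str] = field(default_factory=dict)
    compartments: dict[str, frozenset[str]] = field(default_factory=dict)
    loss_events: set[tuple[str, str]] = field(default_factory=set)
    pattern_of_pair: dict[tuple[str, str], str] = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    params: SimulationParams
    clade_map: CladeMap
    truth: GroundTruth
    presence: pd.DataFrame
    secondary_presence: pd.Series
    localization: pd.DataFrame
    links: pd.DataFrame
    pathways: dict[str, set[str]]
    paralog_pairs: pd.DataFrame
    sequences: dict[str, str]
    transcripts: list[tables_io.TranscriptModel]
    chromosome_of: dict[str, str]

    @property
    def representative_protein(self) -> dict[str, str]:
        """gene -> protein ID of the longest-transcript representative."""
        longest = tables_io.select_longest_transcript(self.transcripts)
        return {gene: tid for gene, tid in longest.items()}

    def write_all(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "presence": outdir / "presence.tsv",
            "secondary_presence": outdir / "secondary_presence.tsv",
            "localization": outdir / "localization.csv",
            "links": outdir / "physical_links.txt",
            "pathways": outdir / "pathways.tsv",
            "paralogs": outdir / "paralogs.tsv",
            "fasta": outdir / "proteins.fa",
            "gtf": outdir / "annotation.gtf",
            "ground_truth": outdir / "ground_truth.tsv",
        }
        tables_io.write_presence_matrix(self.presence, paths["presence"])
        self.secondary_presence.astype(int).to_csv(
            paths["secondary_presence"], sep="\t", header=["present"]
        )
        tables_io.write_localization_table(self.localization, paths["localization"])
        with open(paths["links"], "w") as fh:
            fh.write("protein1 protein2 combined_score\n")
            for a, b, s in self.links.itertuples(index=False):
                fh.write(f"{a} {b} {s}\n")
                fh.write(f"{b} {a} {s}\n")
        tables_io.write_pathways(self.pathways, paths["pathways"])
        tables_io.write_paralog_table(self.paralog_pairs, paths["paralogs"])
        tables_io.write_fasta(self.sequences, paths["fasta"])
        _write_gtf(self.transcripts, self.chromosome_of, paths["gtf"])
        truth_rows = [
            {
                "gene_id": g,
                "true_branch": b,
                "compartments": ";".join(sorted(self.truth.compartments.get(g, ()))),
                "chromosome": self.chromosome_of.get(g, "NA"),
            }
            for g, b in self.truth.true_branch.items()
        ]
        pd.DataFrame(truth_rows).to_csv(paths["ground_truth"], sep="\t", index=False)
        return paths


def _write_gtf(
    transcripts: list[tables_io.TranscriptModel],
    chromosome_of: Mapping[str, str],
    path: Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("#!genome-build synthetic\n")
        for model in transcripts:
            for chrom, start, end, strand in model.exon_intervals:
                attrs = (
                    f'gene_id "{model.gene_id}"; '
                    f'transcript_id "{model.transcript_id}";'
                )
                fh.write(
                    f"{chrom}\tsynthetic\texon\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"
                )


def gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(n)]


def gen_gene_history(
    params: SimulationParams, clade_map: CladeMap | None = None
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Draw true branches and build the (post-loss) presence matrix.

    A gene born on branch b is present, pre-loss, in exactly the clades whose
    implied branch is b or younger (those lineages diverged after the birth);
    each presence is flipped to absent independently with the clade's loss
    probability.  The secondary presence series emulates a second deep
    outgroup at the br-1 level (present for genes truly born at br-1 or
    older, with its own loss probability).
    """
    params.validate()
    if clade_map is None:
        clade_map = default_clade_map()
    rng = _rng(params.seed, "history")
    genes = gene_ids(params.n_genes)
    weights = np.array(
        [params.branch_birth_weights.get(b, 0.0) for b in BRANCH_LABELS], dtype=float
    )
    weights /= weights.sum()
    branch_draw = rng.choice(len(BRANCH_LABELS), size=params.n_genes, p=weights)
    truth = GroundTruth()
    for g, bi in zip(genes, branch_draw):
        truth.true_branch[g] = BRANCH_LABELS[bi]

    presence = pd.DataFrame(False, index=genes, columns=list(clade_map.clade_ids))
    presence.index.name = "gene_id"
    loss = params.outgroup_loss_prob
    for clade in clade_map.clades:
        clade_idx = branch_index(clade.implied_branch)
        pre = branch_draw <= clade_idx
        p_loss = loss.get(clade.clade_id, 0.0) if isinstance(loss, dict) else loss
        lost = rng.random(params.n_genes) < p_loss
        presence[clade.clade_id] = pre & ~lost
        for g in np.array(genes)[pre & lost]:
            truth.loss_events.add((g, clade.clade_id))

    br1_idx = branch_index("br-1")
    sec_pre = branch_draw <= br1_idx
    sec_lost = rng.random(params.n_genes) < params.secondary_loss_prob
    secondary = pd.Series(sec_pre & ~sec_lost, index=genes, name="present")
    return presence, secondary, truth


def gen_localizations(
    truth: GroundTruth, params: SimulationParams
) -> pd.DataFrame:
    """Draw per-gene compartment sets and emit a probability table.

    The primary compartment follows the gene's age-class preference vector;
    a second compartment is added with probability ``multi_label_rate``.
    Called compartments get probabilities strictly above 0.5, all others
    strictly below, so threshold calling is unambiguous on synthetic data.
    """
    params.validate()
    rng = _rng(params.seed, "localization")
    genes = sorted(truth.true_branch)
    rows = np.empty((len(genes), len(COMPARTMENTS)))
    for r, gene in enumerate(genes):
        cls = age_class(truth.true_branch[gene])
        pref = np.asarray(params.compartment_preference[cls], dtype=float)
        primary = rng.choice(len(COMPARTMENTS), p=pref)
        comps = {primary}
        if rng.random() < params.multi_label_rate:
            others = [i for i in range(len(COMPARTMENTS)) if i != primary]
            comps.add(int(rng.choice(others)))
        truth.compartments[gene] = frozenset(COMPARTMENTS[i] for i in comps)
        for c in range(len(COMPARTMENTS)):
            if c in comps:
                rows[r, c] = 0.5 + rng.uniform(1e-6, 0.5)
            else:
                rows[r, c] = rng.uniform(0.0, 0.5 - 1e-9)
    table = pd.DataFrame(rows, index=pd.Index(genes, name="protein_id"),
                         columns=list(COMPARTMENTS))
    return table


def gen_ppi(truth: GroundTruth, params: SimulationParams) -> pd.DataFrame:
    """Sample unordered protein pairs with within-compartment pairs
    upweighted by ``within_edge_preference``; scores are uniform on
    [701, 999] so every generated edge survives the score filter."""
    params.validate()
    rng = _rng(params.seed, "ppi")
    genes = sorted(truth.compartments)
    n = len(genes)
    max_pairs = n * (n - 1) // 2
    if params.n_edges > max_pairs:
        raise ValueError(f"n_edges {params.n_edges} exceeds {max_pairs} distinct pairs")
    if params.n_edges == 0:
        return pd.DataFrame(columns=["protein_a", "protein_b", "score"])

    w = params.within_edge_preference
    chosen: set[tuple[int, int]] = set()
    sets = [truth.compartments[g] for g in genes]
    while len(chosen) < params.n_edges:
        need = params.n_edges - len(chosen)
        batch = max(4 * need, 1024)
        ii = rng.integers(0, n, size=batch)
        jj = rng.integers(0, n, size=batch)
        ok = ii != jj
        ii, jj = ii[ok], jj[ok]
        lo = np.minimum(ii, jj)
        hi = np.maximum(ii, jj)
        wc = np.array([bool(sets[a] & sets[b]) for a, b in zip(lo, hi)])
        if math.isinf(w):
            accept = wc
        elif w >= 1:
            accept = wc | (rng.random(len(lo)) < 1.0 / w)
        else:
            accept = ~wc | (rng.random(len(lo)) < w)
        for a, b in zip(lo[accept], hi[accept]):
            chosen.add((int(a), int(b)))
            if len(chosen) >= params.n_edges:
                break
    pairs = sorted(chosen)
    scores = rng.integers(701, 1000, size=len(pairs))
    return pd.DataFrame(
        {
            "protein_a": [genes[a] for a, _ in pairs],
            "protein_b": [genes[b] for _, b in pairs],
            "score": scores,
        }
    )


def gen_pathways(truth: GroundTruth, params: SimulationParams) -> dict[str, set[str]]:
    """Assign one pathway per gene; each branch has a favoured pathway whose
    weight is multiplied by ``cofunction_boost`` (boost 1 = exactly uniform),
    so same-branch pairs share pathways more often than random pairs."""
    params.validate()
    rng = _rng(params.seed, "pathways")
    pathway_names = [f"pw{i:03d}" for i in range(params.n_pathways)]
    mapping: dict[str, set[str]] = {}
    for gene in sorted(truth.true_branch):
        favored = branch_index(truth.true_branch[gene]) % params.n_pathways
        weights = np.ones(params.n_pathways)
        weights[favored] *= params.cofunction_boost
        weights /= weights.sum()
        mapping[gene] = {pathway_names[rng.choice(params.n_pathways, p=weights)]}
    return mapping


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _mutate(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    nterm_concentration: float | None = None,
) -> str:
    """Per-site substitution at *rate*; with *nterm_concentration*, that
    fraction of the substitutions is forced into the first third."""
    arr = np.array(list(seq))
    n = len(arr)
    n_mut = rng.binomial(n, rate)
    if n_mut == 0:
        return seq
    if nterm_concentration is None:
        sites = rng.choice(n, size=min(n_mut, n), replace=False)
    else:
        third = max(1, n // 3)
        n_front = min(third, int(round(n_mut * nterm_concentration)))
        n_rest = min(n - third, n_mut - n_front)
        front = rng.choice(third, size=n_front, replace=False)
        rest = third + rng.choice(n - third, size=n_rest, replace=False)
        sites = np.concatenate([front, rest])
    for s in sites:
        current = arr[s]
        choices = AMINO_ACIDS[AMINO_ACIDS != current]
        arr[s] = rng.choice(choices)
    return "".join(arr)


def _set_localization_row(
    table: pd.DataFrame, rng: np.random.Generator, protein: str, comps: frozenset[str]
) -> None:
    for c in COMPARTMENTS:
        if c in comps:
            table.loc[protein, c] = 0.5 + rng.uniform(1e-6, 0.5)
        else:
            table.loc[protein, c] = rng.uniform(0.0, 0.5 - 1e-9)


def gen_paralogs_and_sequences(
    truth: GroundTruth,
    params: SimulationParams,
    localization: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Generate protein sequences for every gene and a paralog pair table.

    Sequences: single-compartment genes are grouped per compartment into
    families of ``family_size``; each family evolves from a random ancestor
    by per-site substitution at the compartment's rate, so within-cluster
    divergence mirrors the compartment's substitution rate.  Multi-localized
    genes get independent random sequences.

    Paralogs: parent/offspring pairs with the parent on a strictly older
    branch; offspring sequences derive from the parent at the K or non-K
    substitution rate (non-K substitutions concentrated in the N-terminal
    third), and offspring localization sets (and the probability table) are
    rewritten to realise the configured K/SE/S/E/KE mix.
    """
    params.validate()
    rng = _rng(params.seed, "sequences")
    prng = _rng(params.seed, "paralogs")
    genes = sorted(truth.true_branch)

    # --- family-structured sequences ---------------------------------------
    sequences: dict[str, str] = {}
    single = [g for g in genes if len(truth.compartments.get(g, ())) == 1]
    multi = [g for g in genes if g not in set(single)]
    by_comp: dict[str, list[str]] = {}
    for g in single:
        by_comp.setdefault(next(iter(truth.compartments[g])), []).append(g)
    for comp in sorted(by_comp):
        members = by_comp[comp]
        perm = rng.permutation(len(members))
        members = [members[i] for i in perm]
        rate = params.substitution_rate_by_compartment.get(comp, 0.1)
        for start in range(0, len(members), params.family_size):
            family = members[start : start + params.family_size]
            ancestor = _random_sequence(rng, params.sequence_length)
            for g in family:
                sequences[g] = _mutate(rng, ancestor, rate)
    for g in multi:
        sequences[g] = _random_sequence(rng, params.sequence_length)

    # --- paralog pairs ------------------------------------------------------
    patterns = list(params.pattern_fractions)
    frac = np.array([params.pattern_fractions[p] for p in patterns])
    candidates = [g for g in genes if truth.compartments.get(g)]
    prng.shuffle(candidates)
    used: set[str] = set()
    pairs: list[tuple[str, str]] = []
    pair_patterns: list[str] = []
    n_comp = len(COMPARTMENTS)
    by_branch_idx: dict[int, list[str]] = {}
    for g in candidates:
        by_branch_idx.setdefault(branch_index(truth.true_branch[g]), []).append(g)
    n_branches = len(BRANCH_LABELS)
    older_pool = {0: []}
    for k in range(1, n_branches):
        older_pool[k] = older_pool[k - 1] + by_branch_idx.get(k - 1, [])
    for offspring in candidates:
        if len(pairs) >= params.n_paralog_pairs:
            break
        if offspring in used:
            continue
        ob_idx = branch_index(truth.true_branch[offspring])
        pool = older_pool[ob_idx]
        parent = None
        if pool:
            for _ in range(20):  # rejection-sample an unused strictly-older parent
                cand = pool[int(prng.integers(len(pool)))]
                if cand not in used and cand != offspring:
                    parent = cand
                    break
        if parent is None:
            continue
        pattern = patterns[int(prng.choice(len(patterns), p=frac))]

        # The offspring keeps the compartment set its age class drew (so the
        # branch-level preference structure survives); the parent's set is
        # rewritten relative to it to realise the requested pattern.  Parents
        # sit overwhelmingly in the large deep branches, where the rewrite is
        # negligible dilution.
        o_set = set(truth.compartments[offspring])
        if pattern in ("KE", "SE") and len(o_set) < 2:
            extra = [c for c in COMPARTMENTS if c not in o_set]
            o_set.add(extra[int(prng.integers(len(extra)))])
            truth.compartments[offspring] = frozenset(o_set)
            _set_localization_row(localization, prng, offspring, frozenset(o_set))
        if pattern == "S" and len(o_set) == n_comp:
            pattern = "K"

        if pattern == "K":
            p_set = set(o_set)
        elif pattern == "KE":  # parent is a proper subset of offspring
            drop = sorted(o_set)[int(prng.integers(len(o_set)))]
            p_set = o_set - {drop}
        elif pattern == "S":  # offspring is a proper subset of parent
            pool = [c for c in COMPARTMENTS if c not in o_set]
            p_set = o_set | {pool[int(prng.integers(len(pool)))]}
        elif pattern == "E":  # disjoint sets
            pool = [c for c in COMPARTMENTS if c not in o_set]
            p_set = {pool[int(prng.integers(len(pool)))]}
        else:  # SE: partial overlap with both gain and loss
            drop = sorted(o_set)[int(prng.integers(len(o_set)))]
            pool = [c for c in COMPARTMENTS if c not in o_set]
            p_set = (o_set - {drop}) | {pool[int(prng.integers(len(pool)))]}

        truth.compartments[parent] = frozenset(p_set)
        _set_localization_row(localization, prng, parent, frozenset(p_set))
        if pattern == "K":
            sequences[offspring] = _mutate(
                prng, sequences[parent], params.paralog_substitution_rate_k
            )
        else:
            sequences[offspring] = _mutate(
                prng,
                sequences[parent],
                params.paralog_substitution_rate_nonk,
                nterm_concentration=params.nonk_nterm_concentration,
            )
        used.update((parent, offspring))
        pairs.append((parent, offspring))
        pair_patterns.append(pattern)
        truth.pattern_of_pair[(parent, offspring)] = pattern

    pair_table = pd.DataFrame(pairs, columns=list(tables_io.PARALOG_TABLE_COLUMNS))
    return pair_table, sequences


def gen_annotation(
    truth: GroundTruth, params: SimulationParams
) -> tuple[list[tables_io.TranscriptModel], dict[str, str]]:
    """Emit exon-level transcript models and per-gene chromosomes.

    Each gene gets one transcript named after the gene (its protein ID in the
    other tables); a fraction get a second, shorter transcript so the
    longest-transcript rule has work to do.
    """
    rng = _rng(params.seed, "annotation")
    chroms = ["X", "Y", "2L", "2R", "3L", "3R", "4"]
    chrom_p = [0.14, 0.01, 0.21, 0.21, 0.21, 0.20, 0.02]
    transcripts: list[tables_io.TranscriptModel] = []
    chromosome_of: dict[str, str] = {}
    cursor = {c: 1000 for c in chroms}
    for gene in sorted(truth.true_branch):
        chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
        chromosome_of[gene] = chrom
        start = cursor[chrom]
        n_exons = int(rng.integers(1, 4))
        intervals = []
        pos = start
        for _ in range(n_exons):
            length = int(rng.integers(150, 600))
            intervals.append((chrom, pos, pos + length - 1, "+"))
            pos += length + int(rng.integers(50, 200))
        transcripts.append(
            tables_io.TranscriptModel(gene, gene, tuple(intervals))
        )
        if rng.random() < params.alt_transcript_rate and n_exons > 1:
            # shorter isoform: drop the last exon
            transcripts.append(
                tables_io.TranscriptModel(f"{gene}.alt", gene, tuple(intervals[:-1]))
            )
        cursor[chrom] = pos + 1000
    return transcripts, chromosome_of


def simulate(
    params: SimulationParams | None = None,
    clade_map: CladeMap | None = None,
) -> SyntheticDataset:
    """Run every generator in its fixed order and return the full dataset."""
    if params is None:
        params = SimulationParams()
    params.validate()
    if clade_map is None:
        clade_map = default_clade_map()
    presence, secondary, truth = gen_gene_history(params, clade_map)
    localization = gen_localizations(truth, params)
    paralog_pairs, sequences = gen_paralogs_and_sequences(truth, params, localization)
    pathways = gen_pathways(truth, params)
    links = gen_ppi(truth, params)
    transcripts, chromosome_of = gen_annotation(truth, params)
    return SyntheticDataset(
        params=params,
        clade_map=clade_map,
        truth=truth,
        presence=presence,
        secondary_presence=secondary,
        localization=localization,
        links=links,
        pathways=pathways,
        paralog_pairs=paralog_pairs,
        sequences=sequences,
        transcripts=transcripts,
        chromosome_of=chromosome_of,
    )
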