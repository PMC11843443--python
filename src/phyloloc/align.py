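"""Global pairwise protein alignment, identity and mutation positions.

Alignment is Needleman-Wunsch with affine gaps (BLOSUM62, gap open -10,
gap extend -1 by default) via Bio.Align.PairwiseAligner.  Identity is the
fraction of identical columns over the whole alignment length, so gap
columns count against identity.  Mutation positions are the relative
positions (1-based column / alignment length) of substituted columns;
indel columns are excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

#: twenty standard residues plus the ambiguity code X
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

GAP = "-"


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two protein sequences."""

    seq_a: str
    seq_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")
        if self.aligned_a.replace(GAP, "") != self.seq_a:
            raise ValueError("aligned_a does not recover seq_a")
        if self.aligned_b.replace(GAP, "") != self.seq_b:
            raise ValueError("aligned_b does not recover seq_b")

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    @property
    def n_identical(self) -> int:
        return sum(
            1
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x != GAP
        )

    @property
    def identity(self) -> float:
        """Identical columns / alignment length (gaps count against identity)."""
        return self.n_identical / self.length

    def mutation_positions(self, include_indels: bool = False) -> list[float]:
        """Relative positions in (0, 1] of mutated columns.

        A mutated column is a substitution (both residues present, unequal);
        with *include_indels* gap columns are counted too.
        """
        positions = []
        for i, (x, y) in enumerate(zip(self.aligned_a, self.aligned_b)):
            if x == y:
                continue
            if GAP in (x, y) and not include_indels:
                continue
            positions.append((i + 1) / self.length)
        return positions


@lru_cache(maxsize=8)
def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Optimal global alignment under affine gap costs.

    Among co-optimal alignments the aligner's first traceback is taken,
    which is deterministic; score and identity do not depend on the choice.
    """
    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValueError(f"{name} is empty")
        illegal = set(seq) - AA_ALPHABET
        if illegal:
            raise ValueError(f"{name} contains illegal character(s) {sorted(illegal)}")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(seq_a, seq_b)[0]
    return PairwiseAlignment(seq_a, seq_b, str(aln[0]), str(aln[1]), float(aln.score))


def align_score(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> float:
    """Optimal global alignment score only (cheaper than a full traceback)."""
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    return float(aligner.score(seq_a, seq_b))


def mutation_position_bins(
    positions: list[float] | PairwiseAlignment,
) -> tuple[int, int, int]:
    """Bin relative mutation positions into protein thirds.

    N-terminal = [0, 1/3] (closed upper bound), middle = (1/3, 2/3],
    C-terminal = (2/3, 1].
    """
    if isinstance(positions, PairwiseAlignment):
        positions = positions.mutation_positions()
    n_term = middle = c_term = 0
    for p in positions:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"relative position {p} outside (0, 1]")
        if p <= 1 / 3:
            n_term += 1
        elif p <= 2 / 3:
            middle += 1
        else:
            c_term += 1
    return (n_term, middle, c_term)
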