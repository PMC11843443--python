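"""Shared vocabularies: phylostratum branch labels, age classes, compartments.

The focal-species phylogeny is cut into nine ordered origination strata
("branches") from the oldest detectable stratum ``br-2`` down to the
species-specific stratum ``br6``.  The nine strata collapse into four age
classes: oldest (br-2), older (br-1), old (br0, the genus MRCA) and young
(br1..br6).

Protein subcellular localization uses the nine-compartment vocabulary of
DeepLoc-2.0-style predictors (the plant-specific Plastid class is excluded),
optionally collapsed to three levels: intracellular, cell membrane and
extracellular.
"""

from __future__ import annotations

BRANCH_LABELS: tuple[str, ...] = (
    "br-2", "br-1", "br0", "br1", "br2", "br3", "br4", "br5", "br6",
)

BRANCH_INDEX: dict[str, int] = {b: i for i, b in enumerate(BRANCH_LABELS)}

AGE_CLASSES: tuple[str, ...] = ("oldest", "older", "old", "young")

_AGE_CLASS_OF = {
    "br-2": "oldest",
    "br-1": "older",
    "br0": "old",
}

YOUNG_BRANCHES: tuple[str, ...] = ("br1", "br2", "br3", "br4", "br5", "br6")

BIOTYPES: tuple[str, ...] = ("protein_coding", "ncRNA")


def validate_branch(label: str) -> str:
    if label not in BRANCH_INDEX:
        raise ValueError(
            f"unknown branch label {label!r}; expected one of {BRANCH_LABELS}"
        )
    return label


def branch_index(label: str) -> int:
    """Position of *label* on the oldest-to-youngest branch scale."""
    validate_branch(label)
    return BRANCH_INDEX[label]


def is_older(a: str, b: str) -> bool:
    """True if branch *a* is strictly older than branch *b*."""
    return branch_index(a) < branch_index(b)


def age_class(branch: str) -> str:
    """Collapse a branch label to its four-class age category."""
    validate_branch(branch)
    return _AGE_CLASS_OF.get(branch, "young")


# Default branch durations in million years.  br0 spans ~7 MY (69 to 62 MY
# before present) and the young branches br1..br6 total 62 MY with br6 (the
# species-specific branch) spanning 5 MY; the split of the remaining 57 MY
# across br1..br5 is configuration, not a measured quantity.
DEFAULT_BRANCH_SPANS_MY: dict[str, float] = {
    "br-2": 30.0,
    "br-1": 31.0,
    "br0": 7.0,
    "br1": 20.0,
    "br2": 12.0,
    "br3": 10.0,
    "br4": 10.0,
    "br5": 5.0,
    "br6": 5.0,
}

YOUNG_SPAN_MY: float = 62.0


COMPARTMENTS: tuple[str, ...] = (
    "Cytoplasm",
    "Nucleus",
    "Extracellular",
    "Cell_membrane",
    "Mitochondrion",
    "Endoplasmic_reticulum",
    "Lysosome_Vacuole",
    "Golgi_apparatus",
    "Peroxisome",
)

#: Plant-specific compartment dropped on ingestion.
PLASTID = "Plastid"

LEVEL3: tuple[str, ...] = ("intracellular", "cell_membrane", "extracellular")

_LEVEL3_OF = {
    "Extracellular": "extracellular",
    "Cell_membrane": "cell_membrane",
}


def level3_of(compartment: str) -> str:
    """Map one of the nine compartments to the three-level grouping."""
    if compartment not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}")
    return _LEVEL3_OF.get(compartment, "intracellular")


def _normalize_header(name: str) -> str:
    return (
        name.strip()
        .replace("/", "_")
        .replace("-", "_")
        .replace(" ", "_")
        .lower()
    )


_CANONICAL_BY_NORM = {_normalize_header(c): c for c in COMPARTMENTS}
_CANONICAL_BY_NORM[_normalize_header(PLASTID)] = PLASTID
# common predictor-output spellings
_CANONICAL_BY_NORM["lysosome_vacuole"] = "Lysosome_Vacuole"
_CANONICAL_BY_NORM["endoplasmic_reticulum"] = "Endoplasmic_reticulum"


def canonical_compartment(name: str) -> str | None:
    """Resolve a header synonym to its canonical compartment name.

    Returns None for unrecognized headers (e.g. the protein-ID column).
    """
    return _CANONICAL_BY_NORM.get(_normalize_header(name))
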