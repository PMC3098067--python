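"""Marker-based assignment of cell-type labels to estimated signatures.

The factorization itself is label-symmetric: nothing distinguishes
"column 1" from "column 2".  Biological identity is recovered from
marker genes with a priori known behaviour — positive markers are
expressed exclusively in the target cell type, negative markers
exclusively outside it.  Each marker casts a vote by strict pairwise
comparison of its estimated expression across the two candidate
columns; the column winning the majority of votes receives the marker
set's label, the other is labelled "Other".  An exact tie is an error:
without a trustworthy assignment the downstream analysis is void, so
the user is asked for more markers rather than given a coin flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .matrices import DeconfoundError, SignatureMatrix, ValidationError

__all__ = [
    "MarkerSet",
    "AssignmentReport",
    "MarkerNotFoundError",
    "MarkerTieError",
    "assign_cell_types",
    "CD3_MARKERS",
    "OTHER_LABEL",
]

OTHER_LABEL = "Other"


class MarkerNotFoundError(DeconfoundError, KeyError):
    """A marker gene is missing from the signature matrix."""


class MarkerTieError(DeconfoundError):
    """Positive and negative evidence balanced exactly; assignment refused."""


@dataclass
class MarkerSet:
    """Positive/negative marker gene lists for one cell type."""

    cell_type: str
    positive_markers: list = field(default_factory=list)
    negative_markers: list = field(default_factory=list)

    def __post_init__(self):
        self.positive_markers = [str(g) for g in self.positive_markers]
        self.negative_markers = [str(g) for g in self.negative_markers]
        if not self.positive_markers or not self.negative_markers:
            raise ValidationError("positive and negative marker lists must be non-empty")
        if set(self.positive_markers) & set(self.negative_markers):
            raise ValidationError("positive and negative marker lists must be disjoint")

    @property
    def n_markers(self) -> int:
        return len(self.positive_markers) + len(self.negative_markers)

    @property
    def all_markers(self) -> list:
        return self.positive_markers + self.negative_markers


#: T-lymphocyte marker panel used for whole-blood CD3+ deconvolution:
#: five genes expressed exclusively in T cells, four exclusively outside.
CD3_MARKERS = MarkerSet(
    cell_type="CD3",
    positive_markers=["CD3D", "CD3E", "CD3G", "CD2", "CD7"],
    negative_markers=["CD19", "FCGR1A", "CD14", "MARCO"],
)


@dataclass
class AssignmentReport:
    """Per-marker votes and the resulting label assignment."""

    cell_type: str
    assigned_column: int  # index of the column labelled with the cell type
    votes: dict = field(default_factory=dict)  # marker id -> voted column index or None
    tally: tuple = (0, 0)  # votes for (column 0, column 1)


def assign_cell_types(S_hat: SignatureMatrix, markers: MarkerSet):
    """Label the two estimated signature columns by marker majority vote.

    A positive marker votes for the column where its estimated
    expression is strictly higher; a negative marker votes for the
    column where it is strictly lower.  Markers with exactly equal
    values in both columns vote for neither column.

    Returns
    -------
    (relabelled SignatureMatrix, AssignmentReport) — column order is
    preserved, only the labels change.

    Raises
    ------
    MarkerNotFoundError : a marker gene is absent from ``S_hat``.
    MarkerTieError : both columns receive equally many votes.
    ValidationError : ``S_hat`` does not have exactly two columns.
    """
    if S_hat.n_cell_types != 2:
        raise ValidationError(
            "marker-based assignment is defined for exactly 2 cell types, "
            f"got {S_hat.n_cell_types}"
        )
    index = {g: i for i, g in enumerate(S_hat.gene_ids)}
    for g in markers.all_markers:
        if g not in index:
            raise MarkerNotFoundError(f"marker gene {g!r} not found in signature matrix")

    votes: dict = {}
    tally = [0, 0]
    for g in markers.positive_markers:
        a, b = S_hat.values[index[g], 0], S_hat.values[index[g], 1]
        voted = 0 if a > b else 1 if b > a else None
        votes[g] = voted
        if voted is not None:
            tally[voted] += 1
    for g in markers.negative_markers:
        a, b = S_hat.values[index[g], 0], S_hat.values[index[g], 1]
        voted = 0 if a < b else 1 if b < a else None
        votes[g] = voted
        if voted is not None:
            tally[voted] += 1

    if tally[0] == tally[1]:
        raise MarkerTieError(
            f"marker vote tied {tally[0]}:{tally[1]} between the two columns; "
            "add more (or more specific) marker genes to resolve the assignment"
        )
    winner = 0 if tally[0] > tally[1] else 1
    labels = [OTHER_LABEL, OTHER_LABEL]
    labels[winner] = markers.cell_type
    relabelled = SignatureMatrix(S_hat.values.copy(), list(S_hat.gene_ids), labels)
    report = AssignmentReport(
        cell_type=markers.cell_type,
        assigned_column=winner,
        votes=votes,
        tally=(tally[0], tally[1]),
    )
    return relabelled, report
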