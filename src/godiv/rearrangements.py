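"""Attribution of lost gene neighborhoods to rearrangement types.

Each neighborhood that is not conserved in the other genome is assigned a
single cause, with precedence DELETION > TRANSLOCATION > OTHERS:

* ``DELETION`` — one or both genes have no ortholog in the other genome
  (imbalanced rearrangement: the gene content changed);
* ``TRANSLOCATION`` — both orthologs exist but sit on different
  chromosomes (inter-chromosomal, balanced);
* ``OTHERS`` — both orthologs share a chromosome but are no longer
  adjacent, i.e. inversions and intra-chromosomal transpositions, which
  are pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .divergence import DEFAULT_THRESHOLD, conserved_flags, neighborhood_status
from .genome import Genome, Neighborhood, OrthologMap

__all__ = [
    "DELETION",
    "TRANSLOCATION",
    "OTHERS",
    "LossRecord",
    "Composition",
    "classify_loss",
    "loss_records",
    "composition",
    "gene_loss_rate",
]

DELETION = "DELETION"
TRANSLOCATION = "TRANSLOCATION"
OTHERS = "OTHERS"


@dataclass(frozen=True)
class LossRecord:
    """One lost neighborhood with its classified cause."""

    neighborhood: Neighborhood
    direction: str
    cause: str
    missing_count: int  # orthologs absent from the other genome, 0-2


@dataclass
class Composition:
    """Fractions of lost neighborhoods per rearrangement type."""

    f_deletion: float
    f_translocation: float
    f_others: float
    lost_total: int

    @property
    def defined(self) -> bool:
        return self.lost_total > 0


def classify_loss(
    nb: Neighborhood,
    map: OrthologMap,
    other: Genome,
    threshold: int = DEFAULT_THRESHOLD,
    direction: str = "A->B",
) -> LossRecord:
    """Classify one non-conserved neighborhood."""
    status = neighborhood_status(nb, map, other, threshold, direction)
    if status.conserved:
        raise ValueError(
            f"neighborhood ({nb.left}, {nb.right}) is conserved; nothing to classify"
        )
    table = map.a_to_b if direction == "A->B" else map.b_to_a
    orthologs = []
    missing = 0
    for g in (nb.left, nb.right):
        o = table.get(g)
        if o is None or o not in other:
            missing += 1
        else:
            orthologs.append(o)
    if missing:
        cause = DELETION
    elif other.chromosome_of(orthologs[0]) != other.chromosome_of(orthologs[1]):
        cause = TRANSLOCATION
    else:
        cause = OTHERS
    return LossRecord(nb, direction, cause, missing)


def loss_records(
    a: Genome,
    b: Genome,
    map: OrthologMap,
    threshold: int = DEFAULT_THRESHOLD,
) -> list[LossRecord]:
    """Classified loss records pooled over both directions."""
    out: list[LossRecord] = []
    for source, other, direction in ((a, b, "A->B"), (b, a, "B->A")):
        flags = conserved_flags(source, other, map, threshold, direction)
        for nb, ok in zip(source.neighborhoods(), flags):
            if not ok:
                out.append(classify_loss(nb, map, other, threshold, direction))
    return out


def composition(
    a: Genome,
    b: Genome,
    map: OrthologMap,
    threshold: int = DEFAULT_THRESHOLD,
) -> Composition:
    """Fraction of lost neighborhoods per cause, pooled over directions.

    With no lost neighborhood the composition is undefined: fractions are
    NaN and ``.defined`` is False.
    """
    records = loss_records(a, b, map, threshold)
    total = len(records)
    if total == 0:
        return Composition(np.nan, np.nan, np.nan, 0)
    counts = {DELETION: 0, TRANSLOCATION: 0, OTHERS: 0}
    for r in records:
        counts[r.cause] += 1
    return Composition(
        counts[DELETION] / total,
        counts[TRANSLOCATION] / total,
        counts[OTHERS] / total,
        total,
    )


def gene_loss_rate(
    a: Genome, b: Genome, map: OrthologMap, seq_distance: float
) -> float:
    """Unshared-gene fraction per unit sequence distance.

    ``((N1 - |map|) + (N2 - |map|)) / (N1 + N2) / seq_distance`` — the
    symmetric fraction of genes without an ortholog in the other species,
    normalised by divergence.
    """
    if seq_distance <= 0:
        raise ValueError(f"sequence distance must be positive, got {seq_distance}")
    m = len(map)
    return ((a.N - m) + (b.N - m)) / (a.N + b.N) / seq_distance
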