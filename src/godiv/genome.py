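"""Gene-order representation of annotated genomes.

A genome is reduced to the order of its genes along each chromosome.  Every
gene receives a 1-based ``rank`` on its chromosome (5'->3' by start
coordinate) and a genome-wide ``coordination`` number ``L`` built from the
rank plus a large per-chromosome offset, so that two genes are neighbours
iff ``|L_i - L_j| == 1``.  The first gene of the first chromosome gets
``L = 10001``, the second ``L = 10002``, and the first gene of the second
chromosome ``L = 110001`` with the default offset of 100000 — genes on
different chromosomes can therefore never look adjacent.

Strand is deliberately ignored: the divergence statistics downstream depend
only on gene order, and strand-flipping events surface as rearrangements
when the order changes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "Gene",
    "Genome",
    "Neighborhood",
    "OrthologMap",
    "read_gene_positions",
    "assign_coordination",
    "read_ortholog_map",
]

#: rank of the first gene on a chromosome maps to offset + RANK_BASE + 1
RANK_BASE = 10_000
DEFAULT_CHROMOSOME_OFFSET = 100_000

TSV_COLUMNS = ["gene_id", "chromosome", "start", "end"]


@dataclass(frozen=True)
class Gene:
    """One gene placed on a chromosome, with order bookkeeping."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    rank: int
    coordination: int | None = None


@dataclass(frozen=True)
class Neighborhood:
    """A pair of rank-adjacent genes on one chromosome."""

    left: str
    right: str
    chromosome: str


class Genome:
    """Ordered gene list of one species, grouped by chromosome.

    Parameters
    ----------
    species_id:
        Label used in outputs and error messages.
    frame:
        DataFrame with columns ``gene_id, chromosome, start, end`` (and
        optionally ``rank`` / ``coordination``).  Rows are re-sorted per
        chromosome by (start, end, gene_id); chromosome order follows first
        appearance in the input.
    """

    def __init__(self, species_id: str, frame: pd.DataFrame):
        missing = [c for c in TSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"gene table is missing column(s): {', '.join(missing)}")
        if len(frame) == 0:
            raise ValueError("no gene records")
        dup = frame["gene_id"][frame["gene_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene_id: {dup.iloc[0]!r}")

        frame = frame.copy()
        frame["chromosome"] = frame["chromosome"].astype(str)
        frame["gene_id"] = frame["gene_id"].astype(str)
        # chromosome order = order of first appearance in the file
        self.chromosomes: list[str] = list(dict.fromkeys(frame["chromosome"]))
        chrom_index = {c: i for i, c in enumerate(self.chromosomes)}
        frame["_ci"] = frame["chromosome"].map(chrom_index)
        frame = frame.sort_values(
            ["_ci", "start", "end", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)
        frame["rank"] = frame.groupby("_ci").cumcount() + 1
        if "coordination" not in frame.columns:
            frame["coordination"] = pd.array([pd.NA] * len(frame), dtype="Int64")
        self.species_id = species_id
        self._frame = frame
        self._chrom_index = chrom_index
        self._refresh_lookups()

    # -- basic counts -------------------------------------------------
    @property
    def N(self) -> int:
        """Total number of genes."""
        return len(self._frame)

    @property
    def n(self) -> int:
        """Number of chromosomes carrying at least one gene."""
        return len(self.chromosomes)

    @property
    def neighborhood_count(self) -> int:
        """Number of gene neighborhoods, ``N - n``."""
        return self.N - self.n

    @property
    def coordinated(self) -> bool:
        return not self._frame["coordination"].isna().any()

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying gene table (copy)."""
        return self._frame[TSV_COLUMNS + ["rank", "coordination"]].copy()

    def _refresh_lookups(self) -> None:
        f = self._frame
        self._chrom_of = dict(zip(f["gene_id"], f["chromosome"]))
        if f["coordination"].isna().any():
            self._coord_of: dict[str, int] = {}
        else:
            self._coord_of = dict(zip(f["gene_id"], f["coordination"].astype(int)))

    # -- lookups ------------------------------------------------------
    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._chrom_of

    def chromosome_of(self, gene_id: str) -> str:
        return self._chrom_of[gene_id]

    def coordination_of(self, gene_id: str) -> int:
        return self._coord_of[gene_id]

    def genes(self, chromosome: str | None = None) -> list[Gene]:
        f = self._frame
        if chromosome is not None:
            f = f[f["chromosome"] == chromosome]
        return [
            Gene(
                r.gene_id,
                r.chromosome,
                int(r.start),
                int(r.end),
                int(r.rank),
                None if pd.isna(r.coordination) else int(r.coordination),
            )
            for r in f.itertuples(index=False)
        ]

    def gene_ids(self, chromosome: str) -> list[str]:
        f = self._frame
        return list(f.loc[f["chromosome"] == chromosome, "gene_id"])

    def neighborhoods(self, chromosome: str | None = None) -> Iterator[Neighborhood]:
        """Yield every rank-adjacent gene pair, per chromosome in order."""
        chroms = [chromosome] if chromosome is not None else self.chromosomes
        for c in chroms:
            ids = self.gene_ids(c)
            for left, right in zip(ids, ids[1:]):
                yield Neighborhood(left, right, c)

    # -- I/O ----------------------------------------------------------
    def to_tsv(self, path: str | os.PathLike) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Genome({self.species_id!r}, N={self.N}, n={self.n})"


def _read_gff3(path: str | os.PathLike, feature_types: tuple[str, ...]) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    records = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype, order_by=None):
            records.append((feat.id, feat.seqid, feat.start, feat.end))
    if not records:
        raise ValueError("no gene records")
    frame = pd.DataFrame(records, columns=TSV_COLUMNS)
    return frame


def read_gene_positions(
    path: str | os.PathLike,
    format: str = "tsv",
    species_id: str | None = None,
    feature_types: tuple[str, ...] = ("gene",),
) -> Genome:
    """Read gene positions from a GFF3 or 4-column TSV file.

    The TSV must carry a header line with columns
    ``gene_id  chromosome  start  end``.  Genes are sorted per chromosome
    by start (ties broken by end, then gene_id) and ranked 1..k.

    Parameters
    ----------
    format:
        ``"tsv"`` or ``"gff3"``.
    feature_types:
        GFF3 feature types to keep (``gene`` by default).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    sid = species_id or os.path.splitext(os.path.basename(str(path)))[0]
    if format == "tsv":
        try:
            frame = pd.read_csv(path, sep="\t")
        except pd.errors.EmptyDataError:
            raise ValueError("no gene records") from None
        frame.columns = [str(c).strip() for c in frame.columns]
    elif format == "gff3":
        frame = _read_gff3(path, feature_types)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'gff3'")
    return Genome(sid, frame)


def assign_coordination(
    genome: Genome, chromosome_offset: int = DEFAULT_CHROMOSOME_OFFSET
) -> Genome:
    """Assign genome coordination numbers ``L`` to every gene in place.

    ``L = chromosome_index * chromosome_offset + 10000 + rank`` with
    chromosomes indexed 0, 1, 2, ... in file order, so the first chromosome
    runs 10001, 10002, ... and the second starts at ``offset + 10001``.
    Idempotent; returns the same genome for chaining.
    """
    per_chrom = genome._frame.groupby("_ci")["rank"].max()
    limit = chromosome_offset - RANK_BASE - 1
    too_big = per_chrom[per_chrom > limit]
    if len(too_big):
        raise ValueError(
            f"chromosome {genome.chromosomes[int(too_big.index[0])]!r} has "
            f"{int(too_big.iloc[0])} genes; more than {limit} would alias "
            f"adjacency across chromosomes (raise chromosome_offset)"
        )
    f = genome._frame
    f["coordination"] = (f["_ci"] * chromosome_offset + RANK_BASE + f["rank"]).astype(
        "Int64"
    )
    genome._refresh_lookups()
    return genome


class OrthologMap:
    """One-to-one map between gene ids of two species."""

    def __init__(self, pairs: Iterable[tuple[str, str]], dropped: int = 0):
        self.pairs: set[tuple[str, str]] = set(pairs)
        self.a_to_b = {a: b for a, b in self.pairs}
        self.b_to_a = {b: a for a, b in self.pairs}
        if len(self.a_to_b) != len(self.pairs) or len(self.b_to_a) != len(self.pairs):
            raise ValueError("ortholog map is not one-to-one")
        self.dropped = dropped

    def __len__(self) -> int:
        return len(self.pairs)

    def get(self, gene_id: str, direction: str = "a_to_b") -> str | None:
        table = self.a_to_b if direction == "a_to_b" else self.b_to_a
        return table.get(gene_id)

    def reversed(self) -> "OrthologMap":
        return OrthologMap({(b, a) for a, b in self.pairs}, dropped=self.dropped)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], policy: str = "drop_ambiguous"
    ) -> "OrthologMap":
        """Normalize raw ortholog pairs to a one-to-one map.

        ``drop_ambiguous`` removes every pair touching a gene id that occurs
        more than once on its side (the count removed is kept in
        ``.dropped``); ``strict_one_to_one`` raises on the first such id.
        """
        pairs = list(dict.fromkeys((str(a), str(b)) for a, b in pairs))
        if not pairs:
            raise ValueError("empty ortholog map")
        from collections import Counter

        ca = Counter(a for a, _ in pairs)
        cb = Counter(b for _, b in pairs)
        if policy == "strict_one_to_one":
            for a, k in ca.items():
                if k > 1:
                    raise ValueError(f"gene {a!r} maps to {k} orthologs")
            for b, k in cb.items():
                if k > 1:
                    raise ValueError(f"gene {b!r} maps to {k} orthologs")
            return cls(pairs)
        if policy != "drop_ambiguous":
            raise ValueError(f"unknown policy {policy!r}")
        kept = [(a, b) for a, b in pairs if ca[a] == 1 and cb[b] == 1]
        return cls(kept, dropped=len(pairs) - len(kept))


def read_ortholog_map(
    path: str | os.PathLike, policy: str = "drop_ambiguous"
) -> OrthologMap:
    """Read a two-column TSV of ortholog gene-id pairs.

    A header line ``gene_id_a<TAB>gene_id_b`` (any capitalisation) is
    skipped if present.
    """
    try:
        frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError("empty ortholog map") from None
    if frame.shape[1] != 2:
        raise ValueError(
            f"ortholog map must have exactly 2 columns, found {frame.shape[1]}"
        )
    first = [str(v).lower() for v in frame.iloc[0]]
    if first in (["gene_id_a", "gene_id_b"], ["gene_a", "gene_b"]):
        frame = frame.iloc[1:]
    return OrthologMap.from_pairs(
        zip(frame.iloc[:, 0], frame.iloc[:, 1]), policy=policy
    )
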