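import numpy as np
import pandas as pd
import pytest

from godiv import Genome, OrthologMap, assign_coordination


def make_genome(species_id: str, chrom_genes: dict[str, list[str]]) -> Genome:
    """Build a coordinated genome from {chromosome: ordered gene ids}."""
    rows = [
        (g, c, (i + 1) * 100, (i + 1) * 100 + 50)
        for c, ids in chrom_genes.items()
        for i, g in enumerate(ids)
    ]
    frame = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])
    return assign_coordination(Genome(species_id, frame))


def identity_map(ids: list[str]) -> OrthologMap:
    return OrthologMap([(g, g) for g in ids])


def brute_force_pgod(a: Genome, b: Genome, omap: OrthologMap, threshold: int = 1) -> float:
    """Independent pGOD oracle: enumerate every adjacent gene pair by
    scanning the raw gene tables, check conservation by position lookup
    in the full table of the other genome.  No coordination numbers."""

    def order(genome):
        out = {}
        for chrom in genome.frame["chromosome"].unique():
            sub = genome.frame[genome.frame["chromosome"] == chrom]
            sub = sub.sort_values(["start", "end", "gene_id"])
            for pos, gid in enumerate(sub["gene_id"]):
                out[gid] = (chrom, pos)
        return out

    def conserved_count(src, other, table):
        pos_other = order(other)
        count = 0
        for chrom in src.frame["chromosome"].unique():
            sub = src.frame[src.frame["chromosome"] == chrom]
            ids = list(sub.sort_values(["start", "end", "gene_id"])["gene_id"])
            for left, right in zip(ids, ids[1:]):
                ol, orr = table.get(left), table.get(right)
                if ol in pos_other and orr in pos_other:
                    (c1, p1), (c2, p2) = pos_other[ol], pos_other[orr]
                    if c1 == c2 and abs(p1 - p2) <= threshold:
                        count += 1
        return count

    nb_a = a.N - a.n
    nb_b = b.N - b.n
    c = conserved_count(a, b, omap.a_to_b) + conserved_count(b, a, omap.b_to_a)
    return 1.0 - c / (nb_a + nb_b)


@pytest.fixture
def five_gene_pair():
    """Worked example: B carries one adjacent swap relative to A."""
    a = make_genome("A", {"chr1": ["a1", "a2", "a3", "a4", "a5"]})
    b = make_genome("B", {"chr1": ["b1", "b2", "b4", "b3", "b5"]})
    omap = OrthologMap([(f"a{i}", f"b{i}") for i in range(1, 6)])
    return a, b, omap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
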