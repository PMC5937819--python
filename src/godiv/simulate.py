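"""Ground-truthed genome-evolution and SV-fixture simulators.

``simulate_pair`` evolves one (or both) lineages of a species pair away
from a common ancestor by applying inversions, reciprocal translocations,
transpositions, deletions and tandem duplications to ordered gene lists,
and returns the two genomes together with the true ortholog map and event
log.  Rearrangement breakpoints can be drawn with regionally heterogeneous
rates: consecutive blocks of ``regional_block`` genes carry i.i.d.
Gamma(shape, 1/shape) rate multipliers (mean 1), emulating fragile and
stable chromosomal regions; ``regional_shape=None`` gives homogeneous
rates.  Rate multipliers attach to the genes of a block, so fragility
travels with the sequence when segments move.

Event-to-neighborhood bookkeeping (threshold 1, interior events; an
"A-loss" is an ancestral neighborhood no longer adjacent in the derived
genome, a "B-loss" a derived-genome neighborhood that is novel or carries
an unmapped gene):

======================  ========  ========  ==============
event                   A-losses  B-losses  gene-count
======================  ========  ========  ==============
inversion (>= 2 genes)  2         2         0
reciprocal transloc.    2         2         0
transposition           3         3         0
deletion of L genes     L + 1     1         -L
tandem dup of L genes   1         L + 1     +L
======================  ========  ========  ==============

A transposition breaks two junctions at the excision site and one at the
insertion site (the healed excision junction and the two insertion-side
junctions are novel on the derived side).  Chromosome-end events break
fewer neighborhoods; the simulator only places events in chromosome
interiors so the table is exact.

``simulate_sv_fixture`` builds SV calls paired with split alignments of
known validity: every true call satisfies its validation rule and every
decoy violates exactly one rule, so validator precision and recall are
1.0 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import Genome, OrthologMap
from .sv import Segment, SplitAlignment, SVCall

import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_pair",
    "simulate_clade",
    "expected_pgod",
    "simulate_sv_fixture",
]

EVENT_TYPES = (
    "inversion",
    "reciprocal_translocation",
    "transposition",
    "deletion",
    "tandem_duplication",
)


def _default_events() -> dict[str, int]:
    # deletion-heavy mix echoing the dominant role of imbalanced
    # rearrangements in fungal gene-order evolution
    return {
        "deletion": 100,
        "inversion": 40,
        "transposition": 20,
        "reciprocal_translocation": 10,
        "tandem_duplication": 10,
    }


@dataclass
class SimConfig:
    """Study conditions of one simulated species pair.

    Defaults emulate a typical ascomycete genome: ~5000 genes on 8
    chromosomes, gamma-distributed regional rate heterogeneity of shape
    2.8 over 50-gene blocks, geometric rearrangement tracts of 4 genes on
    average.
    """

    n_genes: int = 5000
    n_chromosomes: int = 8
    events: dict[str, int] = field(default_factory=_default_events)
    regional_shape: float | None = 2.8
    regional_block: int = 50
    segment_length_mean: float = 4.0
    events_split: str = "one"  # apply events to "one" lineage or "both"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= self.n_chromosomes:
            raise ValueError("n_genes must exceed n_chromosomes")
        unknown = set(self.events) - set(EVENT_TYPES)
        if unknown:
            raise ValueError(f"unknown event type(s): {sorted(unknown)}")
        if any(v < 0 for v in self.events.values()):
            raise ValueError("event counts must be non-negative")
        if self.events.get("deletion", 0) * self.segment_length_mean >= self.n_genes:
            raise ValueError("deletions would exhaust the genome")
        if self.events_split not in ("one", "both"):
            raise ValueError("events_split must be 'one' or 'both'")

    @property
    def total_events(self) -> int:
        return sum(self.events.values())


@dataclass
class SimTruth:
    """Ground truth of a simulated pair."""

    event_log: list[tuple[str, str, tuple[int, ...]]]
    ortholog_map: OrthologMap
    proxy_distance: float


def _gene_id(g: int) -> str:
    return f"g{g:06d}" if g >= 0 else f"d{-g:06d}"


class _Evolver:
    """Applies rearrangement events to ordered per-chromosome gene lists.

    Genes are ancestral integer ids 0..N-1; tandem-duplicate copies get
    negative ids and are never event anchors nor orthologs.
    """

    _BATCH = 8192

    def __init__(
        self,
        chroms: list[list[int]],
        weights: np.ndarray,
        segment_mean: float,
        rng: np.random.Generator,
    ):
        self.chroms = [list(c) for c in chroms]
        self.n_genes = int(weights.size)
        self._p = weights / weights.sum()
        self.segment_mean = segment_mean
        self.rng = rng
        self.alive = np.ones(self.n_genes, dtype=bool)
        self.loc: dict[int, tuple[int, int]] = {}
        for ci in range(len(self.chroms)):
            self._rebuild(ci)
        self._next_dup = 1
        self.log: list[tuple[str, str, tuple[int, ...]]] = []
        self._buf = np.empty(0, dtype=np.int64)
        self._buf_i = 0

    # -- plumbing -----------------------------------------------------
    def _rebuild(self, ci: int) -> None:
        for idx, g in enumerate(self.chroms[ci]):
            self.loc[g] = (ci, idx)

    def _draw_gene(self) -> int:
        while True:
            if self._buf_i >= len(self._buf):
                self._buf = self.rng.choice(
                    self.n_genes, size=self._BATCH, p=self._p
                )
                self._buf_i = 0
            g = int(self._buf[self._buf_i])
            self._buf_i += 1
            if self.alive[g]:
                return g

    def _seg_len(self, minimum: int = 1) -> int:
        return max(minimum, int(self.rng.geometric(1.0 / self.segment_mean)))

    def _chrom_name(self, ci: int) -> str:
        return f"chr{ci + 1:02d}"

    # -- events -------------------------------------------------------
    def apply(self, event_type: str) -> None:
        for _ in range(1000):
            if getattr(self, "_" + event_type)():
                return
        raise RuntimeError(f"could not place a {event_type} event")

    def _inversion(self) -> bool:
        g = self._draw_gene()
        ci, i = self.loc[g]
        chrom = self.chroms[ci]
        s = i + 1
        L = self._seg_len(minimum=2)
        e = s + L
        if e > len(chrom) - 1:  # keep the event interior
            return False
        seg = chrom[s:e]
        chrom[s:e] = seg[::-1]
        for idx in range(s, e):
            self.loc[chrom[idx]] = (ci, idx)
        self.log.append(("inversion", self._chrom_name(ci), tuple(seg)))
        return True

    def _deletion(self) -> bool:
        g = self._draw_gene()
        ci, i = self.loc[g]
        chrom = self.chroms[ci]
        L = self._seg_len()
        if i < 1 or i + L > len(chrom) - 1:
            return False
        seg = chrom[i : i + L]
        if any(s < 0 for s in seg):  # only delete ancestral genes
            return False
        del chrom[i : i + L]
        for s in seg:
            self.alive[s] = False
            del self.loc[s]
        self._rebuild(ci)
        self.log.append(("deletion", self._chrom_name(ci), tuple(seg)))
        return True

    def _transposition(self) -> bool:
        g = self._draw_gene()
        ci, i = self.loc[g]
        chrom = self.chroms[ci]
        L = self._seg_len()
        if i < 1 or i + L > len(chrom) - 1:
            return False
        seg = chrom[i : i + L]
        h = self._draw_gene()
        if h in seg:
            return False
        del chrom[i : i + L]
        for s in seg:
            del self.loc[s]
        self._rebuild(ci)
        cj, j = self.loc[h]
        if j >= len(self.chroms[cj]) - 1:  # insertion must be interior
            self.chroms[ci][i:i] = seg  # roll back
            self._rebuild(ci)
            return False
        self.chroms[cj][j + 1 : j + 1] = seg
        self._rebuild(cj)
        self.log.append(("transposition", self._chrom_name(cj), tuple(seg)))
        return True

    def _reciprocal_translocation(self) -> bool:
        if len(self.chroms) < 2:
            return False
        g1 = self._draw_gene()
        g2 = self._draw_gene()
        c1, i1 = self.loc[g1]
        c2, i2 = self.loc[g2]
        if c1 == c2:
            return False
        if i1 >= len(self.chroms[c1]) - 1 or i2 >= len(self.chroms[c2]) - 1:
            return False  # breakpoint must split the chromosome
        tail1 = self.chroms[c1][i1 + 1 :]
        tail2 = self.chroms[c2][i2 + 1 :]
        self.chroms[c1] = self.chroms[c1][: i1 + 1] + tail2
        self.chroms[c2] = self.chroms[c2][: i2 + 1] + tail1
        self._rebuild(c1)
        self._rebuild(c2)
        self.log.append(
            (
                "reciprocal_translocation",
                f"{self._chrom_name(c1)}|{self._chrom_name(c2)}",
                (g1, g2),
            )
        )
        return True

    def _tandem_duplication(self) -> bool:
        g = self._draw_gene()
        ci, i = self.loc[g]
        chrom = self.chroms[ci]
        L = self._seg_len()
        if i + L > len(chrom) - 1:
            return False
        seg = chrom[i : i + L]
        copies = [-(self._next_dup + k) for k in range(L)]
        self._next_dup += L
        chrom[i + L : i + L] = copies
        self._rebuild(ci)
        self.log.append(("tandem_duplication", self._chrom_name(ci), tuple(seg)))
        return True

    # -- export -------------------------------------------------------
    def to_genome(self, species_id: str) -> Genome:
        rows = []
        for ci, chrom in enumerate(self.chroms):
            name = self._chrom_name(ci)
            for idx, g in enumerate(chrom):
                start = (idx + 1) * 1000
                rows.append((_gene_id(g), name, start, start + 500))
        frame = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])
        from .genome import DEFAULT_CHROMOSOME_OFFSET, RANK_BASE, assign_coordination

        # large simulated chromosomes need a wider coordination offset
        longest = max(len(c) for c in self.chroms)
        offset = DEFAULT_CHROMOSOME_OFFSET
        while offset - RANK_BASE - 1 < longest:
            offset *= 10
        return assign_coordination(Genome(species_id, frame), offset)


def _ancestor_chroms(n_genes: int, n_chromosomes: int) -> list[list[int]]:
    bounds = np.linspace(0, n_genes, n_chromosomes + 1).astype(int)
    return [list(range(bounds[i], bounds[i + 1])) for i in range(n_chromosomes)]


def _weights(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.regional_shape is None:
        return np.ones(config.n_genes)
    n_blocks = -(-config.n_genes // config.regional_block)
    mult = rng.gamma(config.regional_shape, 1.0 / config.regional_shape, n_blocks)
    return np.repeat(mult, config.regional_block)[: config.n_genes]


def _event_sequence(events: dict[str, int], rng: np.random.Generator) -> list[str]:
    seq = [t for t in EVENT_TYPES for _ in range(events.get(t, 0))]
    return [seq[i] for i in rng.permutation(len(seq))]


def simulate_pair(config: SimConfig) -> tuple[Genome, Genome, SimTruth]:
    """Evolve a species pair from a shared ancestor.

    With ``events_split="one"`` genome A stays ancestral and all events
    hit lineage B; ``"both"`` splits each event count evenly (A gets the
    floor half).  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    weights = _weights(config, rng)
    ancestor = _ancestor_chroms(config.n_genes, config.n_chromosomes)

    if config.events_split == "both":
        ev_a = {t: k // 2 for t, k in config.events.items()}
        ev_b = {t: k - k // 2 for t, k in config.events.items()}
    else:
        ev_a = {}
        ev_b = dict(config.events)

    lineages = []
    for sid, ev in (("A", ev_a), ("B", ev_b)):
        evolver = _Evolver(ancestor, weights, config.segment_length_mean, rng)
        for event_type in _event_sequence(ev, rng):
            evolver.apply(event_type)
        lineages.append(evolver)
    ev_a_obj, ev_b_obj = lineages

    shared = np.flatnonzero(ev_a_obj.alive & ev_b_obj.alive)
    pairs = [(_gene_id(int(g)), _gene_id(int(g))) for g in shared]
    truth = SimTruth(
        event_log=ev_a_obj.log + ev_b_obj.log,
        ortholog_map=OrthologMap(pairs),
        proxy_distance=config.total_events / config.n_genes,
    )
    return ev_a_obj.to_genome("A"), ev_b_obj.to_genome("B"), truth


def simulate_clade(
    branch_distances: dict[str, float],
    events_per_distance: float,
    mix: dict[str, float] | None = None,
    config: SimConfig | None = None,
    seed: int = 0,
) -> tuple[dict[str, Genome], dict[tuple[str, str], OrthologMap], dict[tuple[str, str], float]]:
    """Evolve several species independently from one common ancestor.

    Each species ``s`` receives ``round(events_per_distance *
    branch_distances[s])`` events split over ``mix`` (fractions per event
    type; default all inversions).  For a pair (i, j) the pairwise
    sequence distance is ``d_i + d_j`` and the event count is additive,
    so dGOD grows linearly in distance with slope set by
    ``events_per_distance``.

    Returns per-species genomes, pairwise ortholog maps and pairwise
    distances.
    """
    base = config or SimConfig()
    mix = mix or {"inversion": 1.0}
    rng = np.random.default_rng(seed)
    weights = _weights(base, rng)
    ancestor = _ancestor_chroms(base.n_genes, base.n_chromosomes)

    evolvers: dict[str, _Evolver] = {}
    for sid, dist in branch_distances.items():
        total = round(events_per_distance * dist)
        ev = {t: int(round(total * f)) for t, f in mix.items()}
        evo = _Evolver(ancestor, weights, base.segment_length_mean, rng)
        for event_type in _event_sequence(ev, rng):
            evo.apply(event_type)
        evolvers[sid] = evo

    genomes = {sid: evo.to_genome(sid) for sid, evo in evolvers.items()}
    maps: dict[tuple[str, str], OrthologMap] = {}
    dists: dict[tuple[str, str], float] = {}
    species = sorted(branch_distances)
    for i, si in enumerate(species):
        for sj in species[i + 1 :]:
            shared = np.flatnonzero(evolvers[si].alive & evolvers[sj].alive)
            maps[(si, sj)] = OrthologMap(
                [(_gene_id(int(g)), _gene_id(int(g))) for g in shared]
            )
            dists[(si, sj)] = branch_distances[si] + branch_distances[sj]
    return genomes, maps, dists


def expected_pgod(config: SimConfig) -> float:
    """Analytic expectation of pGOD for homogeneous rates.

    Uses the per-event neighborhood bookkeeping tabulated in the module
    docstring, with a multiple-hit correction for repeated breakage of
    the same neighborhood: an event hitting ``b`` distinct junctions
    leaves a given junction intact with probability ``1 - b/nb``, so
    over independent events the expected number hit at least once is
    ``nb * (1 - prod_e (1 - b_e/nb))``.  Segment lengths enter through
    their mean ``m``.  Only supported for ``regional_shape=None`` and
    ``events_split="one"``; accurate while events rarely collide.
    """
    if config.regional_shape is not None:
        raise ValueError("analytic expectation requires homogeneous rates "
                         "(regional_shape=None)")
    if config.events_split != "one":
        raise ValueError("analytic expectation requires events on one lineage")
    N, n, m = config.n_genes, config.n_chromosomes, config.segment_length_mean
    ev = config.events
    # A-side breaks / B-side novel-or-unmapped junctions per event
    per_event = {
        "inversion": (2.0, 2.0, 0.0),
        "reciprocal_translocation": (2.0, 2.0, 0.0),
        "transposition": (3.0, 3.0, 0.0),
        "deletion": (m + 1.0, 1.0, -m),
        "tandem_duplication": (1.0, m + 1.0, m),
    }
    dN = sum(k * per_event[t][2] for t, k in ev.items())
    nbA = N - n
    nbB = N + dN - n
    survA = survB = 1.0
    for t, k in ev.items():
        bA, bB, _ = per_event[t]
        survA *= (1.0 - bA / nbA) ** k
        survB *= (1.0 - bB / nbB) ** k
    lostA = nbA * (1.0 - survA)
    lostB = nbB * (1.0 - survB)
    return float((lostA + lostB) / (nbA + nbB))


# ---------------------------------------------------------------------------
# SV fixtures
# ---------------------------------------------------------------------------

#: decoy labels name the single validation rule each decoy violates
DECOY_RULES = {
    "DEL": "ref_gap_deficit",
    "INS": "contig_gap_deficit",
    "INV": "reverse_segment_too_short",
    "DUP": "ref_overlap_deficit",
    "TRA": "single_chromosome",
}

_SEG = 500  # anchor alignment block size used for fixture contigs


def _fixture_alignment(sv_type: str, chrom: str, pos: int, size: int,
                       valid: bool, alt_chrom: str) -> SplitAlignment:
    """Split alignment supporting (or just failing to support) one call.

    Invalid geometries miss the 100 bp requirement by exactly 1 bp (gap
    difference 99, reverse segment 99 bp) or, for TRA, keep both segments
    on one chromosome.
    """
    x = pos
    if sv_type == "DEL":
        gap = size if valid else GAP_DEFICIT
        segs = [
            Segment(0, _SEG, chrom, x - _SEG, x, "+"),
            Segment(_SEG, 2 * _SEG, chrom, x + gap, x + gap + _SEG, "+"),
        ]
    elif sv_type == "INS":
        gap = size if valid else GAP_DEFICIT
        segs = [
            Segment(0, _SEG, chrom, x - _SEG, x, "+"),
            Segment(_SEG + gap, 2 * _SEG + gap, chrom, x, x + _SEG, "+"),
        ]
    elif sv_type == "INV":
        L = size if valid else GAP_DEFICIT
        segs = [
            Segment(0, _SEG, chrom, x - _SEG, x, "+"),
            Segment(_SEG, _SEG + L, chrom, x, x + L, "-"),
            Segment(_SEG + L, 2 * _SEG + L, chrom, x + L, x + L + _SEG, "+"),
        ]
    elif sv_type == "DUP":
        ov = min(size, int(0.7 * _SEG)) if valid else GAP_DEFICIT
        segs = [
            Segment(0, _SEG, chrom, x, x + _SEG, "+"),
            Segment(_SEG, 2 * _SEG, chrom, x + _SEG - ov, x + 2 * _SEG - ov, "+"),
        ]
    elif sv_type == "TRA":
        other = alt_chrom if valid else chrom
        segs = [
            Segment(0, _SEG, chrom, x - _SEG, x, "+"),
            Segment(_SEG, 2 * _SEG, other, x + 5000, x + 5000 + _SEG, "+"),
        ]
    else:  # pragma: no cover
        raise ValueError(sv_type)
    return SplitAlignment(f"{sv_type}_{x}", segs)


GAP_DEFICIT = 99  # one bp short of the 100 bp validation requirement


def simulate_sv_fixture(
    n_true: int,
    n_decoy: int,
    genome_size: int = 12_000_000,
    seed: int = 0,
) -> tuple[dict[str, int], list[SVCall], dict[str, SplitAlignment], list[tuple[str, bool, str | None]]]:
    """Build SV calls with split alignments of known validity.

    Returns (reference chromosome sizes, calls, split alignments keyed by
    call id, labels).  Each label is ``(call_id, is_true, violated_rule)``
    with ``violated_rule`` naming the single rule a decoy breaks.  True
    calls additionally pass every hard filter (size >= 100 bp, quality
    above threshold, both ends assembled, away from chromosome ends).
    """
    rng = np.random.default_rng(seed)
    n_chrom = 3
    size = genome_size // n_chrom
    ref = {f"chr{i + 1}": size for i in range(n_chrom)}
    chrom_names = list(ref)

    calls: list[SVCall] = []
    alignments: dict[str, SplitAlignment] = {}
    labels: list[tuple[str, bool, str | None]] = []

    def build(idx: int, valid: bool) -> None:
        sv_type = SV_CYCLE[idx % len(SV_CYCLE)]
        chrom = chrom_names[idx % n_chrom]
        alt = chrom_names[(idx + 1) % n_chrom]
        pos = int(rng.integers(100_000, size - 100_000))
        sv_size = int(rng.integers(100, 5000))
        pos2 = pos + 5000 if sv_type == "TRA" else pos + sv_size
        call = SVCall(
            sv_type, chrom, pos, alt if sv_type == "TRA" else chrom, pos2,
            sv_size, 5000.0, True, True,
            id=f"{'sv' if valid else 'decoy'}{idx:04d}",
        )
        calls.append(call)
        alignments[call.id] = SplitAlignment(
            call.id, _fixture_alignment(sv_type, chrom, pos, sv_size, valid, alt).segments
        )
        labels.append((call.id, valid, None if valid else DECOY_RULES[sv_type]))

    for i in range(n_true):
        build(i, True)
    for i in range(n_true, n_true + n_decoy):
        build(i, False)
    return ref, calls, alignments, labels


SV_CYCLE = ("DEL", "INS", "INV", "DUP", "TRA")
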