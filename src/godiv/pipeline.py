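"""End-to-end orchestration: all-pairs divergence tables and reports.

``run_all_pairs`` computes one row per within-group species pair (pGOD,
fitted gamma shape, dGOD, sequence distance, dGOD rate, rearrangement
composition and gene-loss rate); ``run_report`` fits the
divergence-versus-distance models per group, derives half-lives and slope
ratios, compares group rates (ANOVA + Tukey HSD) and, when described
species counts are supplied, the richness correlation.  ``run`` ties both
together with deterministic file outputs and a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .divergence import SUBPHYLUM_ALPHA, pair_divergence
from .genome import Genome, OrthologMap, assign_coordination, read_gene_positions, read_ortholog_map
from .rearrangements import composition, gene_loss_rate
from .stats import (
    LINEAR,
    LOGARITHMIC,
    GroupRates,
    compare_groups,
    fit_divergence_model,
    half_life,
    rate_ratio,
    richness_correlation,
)

__all__ = ["RunConfig", "run_all_pairs", "run_report", "run"]

log = logging.getLogger("godiv")

PAIR_COLUMNS = [
    "species_a", "species_b", "group", "pGOD", "alpha", "dGOD",
    "seq_distance", "dGOD_rate", "f_deletion", "f_translocation",
    "f_others", "gene_loss_rate",
]


@dataclass
class RunConfig:
    """Configuration of an end-to-end run (loadable from YAML)."""

    genomes: dict[str, str]  # species_id -> gene table path
    orthologs_dir: str  # holds <a>__<b>.tsv per pair
    distances: str  # square TSV, species x species
    membership: str  # TSV: species_id <TAB> group
    outdir: str = "godiv_out"
    genome_format: str = "tsv"
    threshold: int = 1
    window: int = 50
    step: int = 25
    alpha: float | str = "auto"  # "auto" | "table" | float
    alpha_table: dict[str, float] = field(default_factory=lambda: dict(SUBPHYLUM_ALPHA))
    max_distance: float = 0.6
    cross_groups: bool = False
    species_counts: dict[str, int] | None = None  # group -> described species
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        missing = [p for p in [*self.genomes.values(), self.orthologs_dir,
                               self.distances, self.membership]
                   if not os.path.exists(p)]
        if missing:
            raise FileNotFoundError(f"missing input path(s): {missing}")


def _ortholog_path(orthologs_dir: str, a: str, b: str) -> tuple[str, bool]:
    forward = os.path.join(orthologs_dir, f"{a}__{b}.tsv")
    if os.path.exists(forward):
        return forward, False
    backward = os.path.join(orthologs_dir, f"{b}__{a}.tsv")
    if os.path.exists(backward):
        return backward, True
    raise FileNotFoundError(f"no ortholog map for pair ({a}, {b}) in {orthologs_dir}")


def _read_membership(path: str) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in frame.columns}
    sid = cols.get("species_id", frame.columns[0])
    grp = cols.get("subphylum") or cols.get("group") or frame.columns[1]
    return dict(zip(frame[sid].astype(str), frame[grp].astype(str)))


def run_all_pairs(
    config: RunConfig,
    genomes: dict[str, Genome] | None = None,
    ortholog_maps: dict[tuple[str, str], OrthologMap] | None = None,
    distances: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Divergence table over all unordered within-group species pairs.

    Inputs are read from the paths in ``config`` unless pre-built objects
    are passed (as the simulator does).  Pairs at sequence distance >=
    ``max_distance`` keep their pGOD and composition but carry a null
    dGOD rate.  Rows are ordered by (group, species_a, species_b).
    """
    membership = _read_membership(config.membership)
    missing = sorted(s for s in config.genomes if s not in membership)
    if genomes is not None:
        missing = sorted(s for s in genomes if s not in membership)
    if missing:
        raise ValueError(f"species missing from membership file: {missing}")

    if genomes is None:
        genomes = {
            s: assign_coordination(
                read_gene_positions(p, format=config.genome_format, species_id=s)
            )
            for s, p in config.genomes.items()
        }
    if distances is None:
        distances = pd.read_csv(config.distances, sep="\t", index_col=0)
        distances.index = distances.index.astype(str)

    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")

    groups: dict[str, list[str]] = {}
    for s in sorted(genomes):
        groups.setdefault(membership[s], []).append(s)

    pairs: list[tuple[str, str, str]] = []
    if config.cross_groups:
        species = sorted(genomes)
        pairs = [
            (a, b, f"{membership[a]}|{membership[b]}" if membership[a] != membership[b]
             else membership[a])
            for i, a in enumerate(species) for b in species[i + 1 :]
        ]
    else:
        for g in sorted(groups):
            sp = groups[g]
            pairs.extend((a, b, g) for i, a in enumerate(sp) for b in sp[i + 1 :])

    rows = []
    for a, b, g in pairs:
        if ortholog_maps is not None:
            omap = ortholog_maps.get((a, b)) or ortholog_maps[(b, a)].reversed()
        else:
            path, rev = _ortholog_path(config.orthologs_dir, a, b)
            omap = read_ortholog_map(path)
            if rev:
                omap = omap.reversed()
        dist = float(distances.loc[a, b])
        alpha = config.alpha
        if alpha == "table":
            alpha = config.alpha_table[g.split("|")[0]]
        res = pair_divergence(
            genomes[a], genomes[b], omap,
            threshold=config.threshold, alpha=alpha, seq_distance=dist,
            window=config.window, step=config.step,
            max_distance=config.max_distance,
        )
        comp = composition(genomes[a], genomes[b], omap, config.threshold)
        rows.append({
            "species_a": a, "species_b": b, "group": g,
            "pGOD": res.pGOD, "alpha": res.alpha, "dGOD": res.dGOD,
            "seq_distance": dist, "dGOD_rate": res.dGOD_rate,
            "f_deletion": comp.f_deletion,
            "f_translocation": comp.f_translocation,
            "f_others": comp.f_others,
            "gene_loss_rate": gene_loss_rate(genomes[a], genomes[b], omap, dist),
        })
        log.info("pair %s-%s (%s): pGOD=%.4f dGOD=%s", a, b, g, res.pGOD, res.dGOD)
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def _fit_pgod_models(pts: np.ndarray) -> dict:
    out = {}
    for kind in (LOGARITHMIC, LINEAR):
        try:
            m = fit_divergence_model(pts, kind)
            out[kind] = {"a": m.a, "b": m.b, "r2": m.r2}
        except ValueError as exc:
            out[kind] = {"error": str(exc)}
    return out


def run_report(
    table: pd.DataFrame,
    species_counts: dict[str, int] | None = None,
    outdir: str | None = None,
) -> dict:
    """Models, half-lives, ratios, group tests and optional figures.

    The half-life of each group comes from its best-fitting pGOD model
    (logarithmic versus linear by r-squared); dGOD rates use the linear
    model.  Groups with fewer than 3 pairs are excluded with a warning.
    """
    report: dict = {"groups": {}, "warnings": []}
    dgod_models: dict[str, object] = {}
    for g, sub in table.groupby("group", sort=True):
        if len(sub) < 3:
            report["warnings"].append(f"group {g!r} has {len(sub)} pairs; excluded")
            continue
        entry: dict = {"n_pairs": int(len(sub))}
        pgod_pts = sub[["seq_distance", "pGOD"]].to_numpy(float)
        entry["pgod_models"] = _fit_pgod_models(pgod_pts)
        fits = {
            k: v for k, v in entry["pgod_models"].items() if "error" not in v
        }
        if fits:
            best = max(fits, key=lambda k: fits[k]["r2"])
            model = fit_divergence_model(pgod_pts, best)
            entry["half_life_model"] = best
            try:
                entry["half_life"] = half_life(model)
            except ValueError as exc:
                entry["half_life"] = None
                report["warnings"].append(f"group {g!r}: {exc}")
        dsub = sub.dropna(subset=["dGOD", "dGOD_rate"])
        if len(dsub) >= 3:
            m = fit_divergence_model(
                dsub[["seq_distance", "dGOD"]].to_numpy(float), LINEAR
            )
            dgod_models[g] = m
            entry["dgod_model"] = {"a": m.a, "b": m.b, "r2": m.r2}
            rates = dsub["dGOD_rate"].tolist()
            entry["dgod_rate"] = {
                "mean": float(np.mean(rates)),
                "median": float(np.median(rates)),
                "sd": float(np.std(rates, ddof=1)) if len(rates) > 1 else 0.0,
            }
        entry["composition"] = {
            c: float(sub[c].mean())
            for c in ("f_deletion", "f_translocation", "f_others")
        }
        entry["gene_loss_rate_mean"] = float(sub["gene_loss_rate"].mean())
        report["groups"][g] = entry

    names = sorted(dgod_models)
    report["slope_ratios"] = {
        f"{a}/{b}": rate_ratio(dgod_models[a], dgod_models[b])
        for i, a in enumerate(names) for b in names[i + 1 :]
    }

    rate_groups = [
        GroupRates(g, table.loc[table["group"] == g, "dGOD_rate"].dropna().tolist())
        for g in sorted(table["group"].unique())
    ]
    rate_groups = [g for g in rate_groups if len(g.rates) >= 2]
    if len(rate_groups) >= 2:
        cmp_res = compare_groups(rate_groups)
        report["anova"] = {
            "F": cmp_res["anova_F"], "p": cmp_res["anova_p"],
            "tukey": {f"{a}|{b}": p for (a, b), p in cmp_res["tukey"].items()},
        }
    else:
        report["warnings"].append("fewer than 2 groups with rates; ANOVA skipped")

    if species_counts:
        classes = [
            (species_counts[g], report["groups"][g]["dgod_rate"]["median"])
            for g in report["groups"]
            if g in species_counts and "dgod_rate" in report["groups"][g]
        ]
        if len(classes) >= 3:
            report["richness_pearson_r"] = richness_correlation(classes)

    if outdir is not None:
        _figures(table, dgod_models, outdir)
        report["figures"] = ["pgod_vs_distance.svg", "dgod_vs_distance.svg",
                            "rate_boxplot.svg"]
    return report


def _figures(table: pd.DataFrame, dgod_models: dict, outdir: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = os.path.join(outdir, "figures")
    os.makedirs(figdir, exist_ok=True)
    groups = sorted(table["group"].unique())

    for col, fname in (("pGOD", "pgod_vs_distance.svg"), ("dGOD", "dgod_vs_distance.svg")):
        fig, ax = plt.subplots(figsize=(5, 4))
        for g in groups:
            sub = table[table["group"] == g].dropna(subset=[col])
            ax.scatter(sub["seq_distance"], sub[col], s=12, label=g)
            if col == "dGOD" and g in dgod_models:
                m = dgod_models[g]
                xs = np.linspace(sub["seq_distance"].min(), sub["seq_distance"].max(), 50)
                ax.plot(xs, m.predict(xs), lw=1)
        ax.set_xlabel("sequence distance (subst./site)")
        ax.set_ylabel(col)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(os.path.join(figdir, fname))
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    data = [table.loc[table["group"] == g, "dGOD_rate"].dropna() for g in groups]
    ax.boxplot([d for d in data if len(d)], tick_labels=[g for g, d in zip(groups, data) if len(d)])
    ax.set_ylabel("dGOD per unit sequence distance")
    fig.tight_layout()
    fig.savefig(os.path.join(figdir, "rate_boxplot.svg"))
    plt.close(fig)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and write pairs.tsv, report.json and a
    run manifest under ``config.outdir``."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    table = run_all_pairs(config)
    pairs_path = os.path.join(config.outdir, "pairs.tsv")
    table.to_csv(pairs_path, sep="\t", index=False, float_format="%.6g")
    report = run_report(table, config.species_counts, outdir=config.outdir)
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    cfg = asdict(config)
    manifest = {
        "tool": "godiv",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "config": cfg,
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("wrote %s", pairs_path)
    return report
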