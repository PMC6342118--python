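"""End-to-end analysis pipeline: dedup -> popgen -> spatial regression ->
landscape models -> MU comparison, with deterministic, re-runnable outputs.

The pipeline is configured by a plain dict (read from YAML by the CLI);
every permutation stage derives its seed from the single top-level seed, so
a rerun with the same config is bit-reproducible.  Outputs are delimited
tables shaped like the classical reporting layout (diversity/F_ST, IBD,
landscape fractions, MU fractions) plus a machine-readable JSON summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from . import __version__
from .genotypes import match_duplicates, read_genotype_table
from .landscape import GridSpec, load_features, model_search
from .mem import dps_distance, mgquick
from .mu import MUScenario, compare_scenarios, mu_varpart
from .popgen import diversity_stats, mantel_test, weir_cockerham_fst

DEFAULTS = {
    "alpha": 0.05,
    "n_perm": 999,
    "min_matching_loci": 8,
    "stages": ["dedup", "stats", "ibd", "memgene", "landscape", "mu"],
}


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the configured stages; returns the JSON-able summary dict."""
    cfg = {**DEFAULTS, **config}
    if "seed" not in cfg:
        raise ValueError("config must set a seed (permutation stages need it)")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(
        json.dumps(cfg, sort_keys=True, default=str), encoding="utf-8"
    )
    seed = int(cfg["seed"])
    alpha = cfg["alpha"]
    n_perm = int(cfg["n_perm"])
    stages = cfg["stages"]
    summary: dict = {"version": __version__, "seed": seed, "stages": {}}

    table = read_genotype_table(cfg["genotypes"])
    summary["n_input"] = table.n

    if "dedup" in stages:
        table, report = match_duplicates(table, cfg["min_matching_loci"])
        summary["stages"]["dedup"] = {
            "n_input": report.n_input,
            "n_unique": report.n_unique,
            "mismatch_histogram": report.mismatch_histogram,
        }
    summary["n"] = table.n

    group = table.group
    if cfg.get("groups"):            # user-supplied cluster labels
        gdf = pd.read_csv(cfg["groups"], sep="\t", dtype=str, comment="#")
        gmap = dict(zip(gdf["id"], gdf["group"]))
        group = np.array([gmap.get(i, "NA") for i in table.individual_id], object)
        table.group = group

    if "stats" in stages and group is not None and len(set(group)) >= 2:
        div = diversity_stats(table, group, n_perm=n_perm, random_state=seed + 1)
        div.per_locus.to_csv(outdir / "diversity_per_locus.tsv", sep="\t", index=False)
        div.per_group.to_csv(outdir / "diversity_per_group.tsv", sep="\t", index=False)
        fst = weir_cockerham_fst(table, group, n_perm=n_perm, random_state=seed + 2)
        pd.DataFrame(fst.theta, index=fst.labels, columns=fst.labels).to_csv(
            outdir / "fst.tsv", sep="\t"
        )
        summary["stages"]["stats"] = {
            "groups": [str(g) for g in fst.labels],
            "max_theta": float(np.nanmax(fst.theta)),
        }

    D_gen = dps_distance(table).matrix
    D_geo = squareform(pdist(table.xy))

    if "ibd" in stages:
        rows = []
        res = mantel_test(D_geo, D_gen, n_perm=n_perm, random_state=seed + 3)
        rows.append(("all", res.r, res.p, res.n))
        for sx in ("F", "M"):
            sel = table.sex == sx
            if sel.sum() >= 10:
                r = mantel_test(
                    D_geo[np.ix_(sel, sel)], D_gen[np.ix_(sel, sel)],
                    n_perm=n_perm, random_state=seed + 4,
                )
                rows.append((sx, r.r, r.p, r.n))
        ibd = pd.DataFrame(rows, columns=["subset", "mantel_r", "p", "n"])
        ibd.to_csv(outdir / "ibd.tsv", sep="\t", index=False)
        summary["stages"]["ibd"] = {
            "mantel_r": round(res.r, 6), "p": res.p, "n": res.n
        }

    memgene = None
    if "memgene" in stages:
        memgene = mgquick(
            table, alpha=alpha, n_perm=n_perm, random_state=seed + 5
        )
        axes_df = pd.DataFrame(
            {
                "id": table.individual_id,
                "x": table.xy[:, 0],
                "y": table.xy[:, 1],
                **{
                    f"axis{k + 1}": memgene.axes[:, k]
                    for k in range(memgene.n_axes)
                },
            }
        )
        axes_df.to_csv(outdir / "memgene_axes.tsv", sep="\t", index=False)
        summary["stages"]["memgene"] = {
            "n_axes": memgene.n_axes,
            "adj_r2": round(memgene.adj_r2, 6),
            "r2": round(memgene.r2, 6),
            "p": memgene.p_value,
            "axis_proportions": [round(float(v), 6) for v in memgene.axis_proportions],
        }

    if "landscape" in stages and cfg.get("features"):
        features = load_features(cfg["features"])
        grid = GridSpec.from_points(table.xy, cell_size=cfg.get("cell_size"))
        res = model_search(
            table, table.xy, features, grid=grid,
            alpha=alpha, n_perm=n_perm,
            n_perm_part=int(cfg.get("n_perm_part", n_perm)),
            random_state=seed + 6,
        )
        res.to_csv(outdir / "landscape_models.tsv", sep="\t", index=False)
        best = res.sort_values("a", ascending=False).iloc[0]
        summary["stages"]["landscape"] = {
            "best_model": best["model"],
            "best_a": round(float(best["a"]), 6),
        }

    if "mu" in stages and cfg.get("mu_scenarios") and memgene is not None:
        if memgene.n_axes == 0:
            summary["stages"]["mu"] = {"skipped": "no spatial axes"}
        else:
            results = []
            for name, path in cfg["mu_scenarios"].items():
                feats = load_features(path)
                polys = [g for g, _ in sorted(
                    feats, key=lambda t: t[1].get("unit_id", 0)
                )]
                scen = MUScenario(name=name, polygons=polys)
                results.append(
                    mu_varpart(
                        memgene, table.xy, scen, n_perm=n_perm,
                        random_state=seed + 7,
                    )
                )
            ranked = compare_scenarios(results, force=cfg.get("force", False))
            ranked.to_csv(outdir / "mu_comparison.tsv", sep="\t", index=False)
            summary["stages"]["mu"] = {
                "best_scenario": ranked.iloc[0]["scenario"],
                "best_a": round(float(ranked.iloc[0]["a"]), 6),
            }

    (outdir / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=1), encoding="utf-8"
    )
    return summary
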