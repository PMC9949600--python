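"""End-to-end orchestration: simulation or measured inputs through the
comparative statistics, with report tables and a reproducibility manifest.

The full chain is

    simulate (optional) -> VOI -> TBA metrics -> morphometry
        -> allometry -> phylogenetic statistics -> discriminant analyses

Imaging stages run on the synthetic vertebra when no stacks are
supplied, demonstrating the VOI/metric path at desk scale; the
comparative stages run on the simulated (or supplied) specimen table.
Every random stage draws a named seed from one master seed recorded in
the manifest, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allometry import (
    BUILTIN_METRICS,
    classify_allometry,
    fit_loglog,
    sma_common_slope_test,
    species_means,
)
from .discriminant import METRIC_SUBSETS, ClassificationTask, fda, pfda
from .metrics import DirectionSet, compute_tba
from .morphometry import gc_csa
from .phylo import Phylogeny, average_over_positions, blomberg_k, pgls
from .synthetic import (
    METRICS,
    CladeSimSpec,
    make_synthetic_vertebra,
    simulate_clade,
)
from .volume_io import extract_prism_voi, inscribed_sphere, load_stack

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run", "report"]


@dataclass
class PipelineConfig:
    """Declarative configuration; all defaults land in the run manifest."""

    output_dir: str = "trabecula_out"
    seed: int = 0
    simulate: bool = True
    specimen_csv: str | None = None  # used when simulate is False
    newick_path: str | None = None
    stacks_dir: str | None = None  # optional imaging inputs
    imaging_demo: bool = True  # run the synthetic vertebra through VOI/metrics
    n_directions: int = 128  # direction count for the imaging demo
    n_sld_points: int = 300
    binarize_threshold: int = 127
    ci_level: float = 0.95
    n_permutations: int = 199
    size_subset: str = "size"
    ecology_subset: str = "least_size"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _seed_for(master: int, stage: str) -> int:
    # stable per-stage substreams, kept below 2**31
    h = int(master) & 0xFFFFFFFF
    for ch in stage:
        h = (h * 31 + ord(ch)) & 0xFFFFFFFF
    return h % (2**31 - 1)


def _log_columns(df: pd.DataFrame, cols) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        out[f"log_{c}"] = np.log10(out[c])
    return out


def run(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the result bundle and
    writes CSV/JSON tables plus the manifest under ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    # --- data ------------------------------------------------------------
    if config.simulate:
        spec = CladeSimSpec(seed=_seed_for(config.seed, "simulate"))
        table, newick = simulate_clade(spec)
    else:
        if config.specimen_csv is None:
            raise ValueError("stage 'load': specimen_csv is required when simulate=false")
        table = pd.read_csv(config.specimen_csv)
        if config.newick_path is None:
            raise ValueError("stage 'load': newick_path is required for the phylogenetic stages")
        newick = Path(config.newick_path).read_text()
    tree = Phylogeny.from_newick(newick)
    missing = set(table["taxon"]) - set(tree.tip_labels)
    if missing:
        raise ValueError(f"stage 'phylo-validate': taxa missing from tree: {sorted(missing)}")
    bundle["table"] = table
    table.to_csv(out / "specimens.csv", index=False)
    (out / "tree.nwk").write_text(newick)

    # --- imaging demo -----------------------------------------------------
    if config.imaging_demo:
        volume, info = make_synthetic_vertebra()
        voi = extract_prism_voi(volume)
        roi = inscribed_sphere(voi)
        dirs = DirectionSet(n_directions=config.n_directions)
        tba = compute_tba(
            volume,
            roi,
            dirs=dirs,
            n_sld_points=config.n_sld_points,
            seed=_seed_for(config.seed, "sld"),
        )
        morpho = gc_csa(volume)
        imaging = {
            "waist_index_truth": info["waist_index"],
            "voi": asdict(voi),
            "roi": {"center": list(roi.center), "radius": roi.radius},
            "tba": {
                k: (v if not isinstance(v, tuple) else list(v))
                for k, v in asdict(tba).items()
            },
            "morphometry": asdict(morpho),
        }
        bundle["imaging"] = imaging
        (out / "imaging_demo.json").write_text(json.dumps(imaging, indent=2, default=float))

    # --- allometry --------------------------------------------------------
    gls = {}
    for m in list(METRICS) + ["mass"]:
        y = table["mass_g"] if m == "mass" else table[m]
        r = fit_loglog(table["izl_mm"], y, ci_level=config.ci_level)
        gls[m] = {
            "result": r,
            "call": classify_allometry(r, BUILTIN_METRICS[m]),
        }
    bundle["gls"] = gls

    sp_means = species_means(table, value_columns=list(METRICS) + ["izl_mm", "mass_g"])
    bundle["species_means"] = sp_means
    sp_means.to_csv(out / "species_means.csv", index=False)

    equality = {"clade": {}, "ecology": {}}
    for group_col, key in (("clade", "clade"), ("ecology", "ecology")):
        for m in METRICS:
            groups = {}
            for label, grp in table.groupby(group_col):
                if len(grp) >= 3:
                    groups[label] = (grp["izl_mm"].to_numpy(), grp[m].to_numpy())
                else:
                    logger.warning("group %s omitted for %s (too few rows)", label, m)
            per_group = {
                lab: fit_loglog(x, y, ci_level=config.ci_level)
                for lab, (x, y) in groups.items()
            }
            equality[key][m] = {
                "per_group": per_group,
                "calls": {
                    lab: classify_allometry(r, BUILTIN_METRICS[m])
                    for lab, r in per_group.items()
                },
                "sma": sma_common_slope_test(groups),
            }
    bundle["equality"] = equality

    # --- phylogenetic stats ------------------------------------------------
    taxa = sorted(sp_means["taxon"].unique())
    C = tree.prune_to(taxa).brownian_covariance(taxa)
    positions = sorted(sp_means["position"].unique())
    pgls_by_metric = {}
    k_by_metric = {}
    for m in METRICS:
        per_pos = {}
        per_pos_k = {}
        for pos in positions:
            sub = sp_means[sp_means["position"] == pos].set_index("taxon").loc[taxa]
            x = np.log10(sub["izl_mm"].to_numpy())
            y = np.log10(sub[m].to_numpy())
            per_pos[pos] = pgls(x, y, C, ci_level=config.ci_level)
            per_pos_k[pos] = blomberg_k(
                y,
                C,
                n_perm=config.n_permutations,
                seed=_seed_for(config.seed, f"k-{m}-{pos}"),
            )
        avg = average_over_positions(per_pos)
        avg["call"] = classify_allometry(
            (avg["slope"], avg["ci_low"], avg["ci_high"]),
            BUILTIN_METRICS[m],
        )
        pgls_by_metric[m] = {"per_position": per_pos, "average": avg}
        k_by_metric[m] = per_pos_k
    bundle["pgls"] = pgls_by_metric
    bundle["blomberg_k"] = k_by_metric

    # --- discriminant -------------------------------------------------------
    tasks = {
        "size_class": ClassificationTask(
            METRIC_SUBSETS[config.size_subset], "size_class"
        ),
        "ecology": ClassificationTask(
            METRIC_SUBSETS[config.ecology_subset], "ecology"
        ),
    }
    dfa = {}
    for name, task in tasks.items():
        per_pos_fda = {}
        per_pos_pfda = {}
        for pos in positions:
            sub = sp_means[sp_means["position"] == pos].set_index("taxon").loc[taxa]
            data = _log_columns(sub.reset_index(), task.predictors)
            data = data.drop(columns=list(task.predictors)).rename(
                columns={f"log_{p}": p for p in task.predictors}
            )
            per_pos_fda[pos] = fda(task, data)
            per_pos_pfda[pos] = pfda(task, data, C)
        dfa[name] = {"fda": per_pos_fda, "pfda": per_pos_pfda}
    bundle["discriminant"] = dfa

    # --- reports and manifest ------------------------------------------------
    tables = report(bundle)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    bundle["tables"] = tables
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "master_seed": config.seed,
        "stage_seeds": {
            s: _seed_for(config.seed, s) for s in ("simulate", "sld")
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    summary = _summarize(tables)
    (out / "summary.txt").write_text(summary)
    bundle["summary"] = summary
    return bundle


def report(bundle: dict) -> dict[str, pd.DataFrame]:
    """Render the report tables (whole-group regressions, per-clade and
    per-ecology slope comparisons, phylogenetic signal, and the
    discriminant accuracies per vertebral position)."""
    tables = {}

    rows = []
    for m, entry in bundle["gls"].items():
        r = entry["result"]
        row = {
            "metric": m,
            "isometric_slope": BUILTIN_METRICS[m].isometric_slope,
            "gls_slope": round(r.slope, 3),
            "gls_ci": f"{r.ci_low:.2f} to {r.ci_high:.2f}",
            "gls_allometry": entry["call"],
            "gls_p": r.p_value,
            "gls_r_squared": round(r.r_squared, 3),
        }
        if m in bundle.get("pgls", {}):
            avg = bundle["pgls"][m]["average"]
            row["pgls_slope"] = avg["formatted"]
            row["pgls_ci"] = f"{avg['ci_low']:.2f} to {avg['ci_high']:.2f}"
            row["pgls_allometry"] = avg["call"]
            row["pgls_p"] = round(avg["p_value"], 4)
        rows.append(row)
    tables["table2_regressions"] = pd.DataFrame(rows)

    for key, name in (("clade", "table3_equality_clade"), ("ecology", "table4_equality_ecology")):
        rows = []
        for m, entry in bundle["equality"][key].items():
            sma = entry["sma"]
            for lab, r in entry["per_group"].items():
                rows.append(
                    {
                        "metric": m,
                        "group": lab,
                        "slope": round(r.slope, 3),
                        "r_squared": round(r.r_squared, 3),
                        "p_value": r.p_value,
                        "allometry": entry["calls"][lab],
                        "equality": f"Slopes are {sma.verdict}.",
                        "equality_p": sma.p_value,
                    }
                )
        tables[name] = pd.DataFrame(rows)

    rows = []
    for m, per_pos in bundle["blomberg_k"].items():
        ks = [r.K for r in per_pos.values()]
        ps = [r.p_value for r in per_pos.values()]
        rows.append(
            {
                "metric": m,
                "mean_K": round(float(np.mean(ks)), 3),
                "K_range": f"{min(ks):.2f}–{max(ks):.2f}",
                "mean_p": round(float(np.mean(ps)), 3),
                "p_range": f"{min(ps):.2f}–{max(ps):.2f}",
            }
        )
    tables["table5_blomberg_k"] = pd.DataFrame(rows)

    rows = []
    for name, entry in bundle["discriminant"].items():
        for flavor, per_pos in (("", entry["fda"]), ("phylogenetic ", entry["pfda"])):
            accs = []
            for pos in sorted(per_pos):
                accs.append(per_pos[pos].accuracy)
                rows.append(
                    {
                        "group": f"{flavor}{name}",
                        "position": pos,
                        "accuracy": round(per_pos[pos].accuracy, 2),
                    }
                )
            rows.append(
                {
                    "group": f"{flavor}{name}",
                    "position": "All positions",
                    "accuracy": round(float(np.mean(accs)), 2),
                }
            )
    tables["table6_discriminant"] = pd.DataFrame(rows)
    return tables


def _summarize(tables: dict[str, pd.DataFrame]) -> str:
    lines = []
    for name, df in tables.items():
        lines.append(f"== {name} ==")
        lines.append(df.to_string(index=False))
        lines.append("")
    return "\n".join(lines)


def load_measured_stack(path, threshold: int | None = None):
    """Convenience loader for one measured stack (binary TIFF + sidecar)."""
    return load_stack(path)
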