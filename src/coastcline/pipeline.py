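"""End-to-end orchestration: generate-or-load inputs, QC, statistics, model fit.

A single YAML config drives the run.  Every stage draws its randomness
from a seed derived deterministically from one master seed and the stage
name, so a full run is byte-reproducible and any stage can be rerun in
isolation.  Artifacts are plain CSV/TSV/FASTA/JSON files in the output
directory, plus ``summary.json`` (machine-readable key results) and
``run_log.txt``.
"""

from __future__ import annotations

import json
import platform
import zlib
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO

from . import __version__
from .core import CoastGrid, FitnessScenario, LineageCline
from .fit import scan_breaks
from .gio import (apply_qc, read_connectivity, read_genotypes, read_observed_cline,
                  write_connectivity, write_genotypes, write_observed_cline)
from .mitotype import classify_mitotypes, cline_from_calls, write_calls
from .model import run_to_steady_state
from .popgen import cnd_to_frame, cytonuclear, mantel_ibd, pairwise_gst, region_mean_gst
from .synthetic import (make_advective_kernel, sigmoid_cline, simulate_coi,
                        simulate_genotypes)


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending key."""


DEFAULT_CONFIG = {
    "seed": 0,
    "grid": {"n_sites": 60, "spacing_km": 10.0, "lat_south": -45.0, "lon": -73.0},
    "connectivity": {"path": None, "mean_displacement_km": 15.0,
                     "spread_km": 25.0, "loss": 0.3},
    "cline": {"path": None, "center_site": 36, "width_km": 50.0,
              "coi_per_site": 30, "site_stride": 2},
    "genotypes": {"path": None, "dialect": "csv", "n_loci": 60, "divergence": 0.4,
                  "missing_rate": 0.05, "ascertain_north": True,
                  "sample_sites": [0, 18, 36, 54],
                  "compose_from_cline": True, "n_parental_per_site": 24,
                  "n_per_class": {"N": 12, "S": 12, "F1": 2, "F2": 2, "BxN": 2, "BxS": 2}},
    "coi": {"length_bp": 600, "divergence": 0.034, "spei_in": "southern"},
    "qc": {"locus_missing_max": 0.5, "indiv_missing_max": 0.25},
    "gst": {"n_permutations": 199, "estimator": "nei_chesser"},
    "mantel": {"n_permutations": 999, "partition": None},
    "cnd": {"alpha": 0.05, "outlier_flags_path": None},
    "fit": {"break_min_site": 10, "break_max_site": 55, "break_step": 3,
            "dw_max": 0.95, "tol": 1.0e-8, "max_generations": 5000},
    "stages": ["connectivity", "cline", "genotypes", "qc", "gst",
               "mantel", "cnd", "fit"],
}

STAGE_ORDER = ("connectivity", "cline", "genotypes", "qc", "gst", "mantel",
               "cnd", "fit")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (int(master_seed) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid with a YAML file and explicit overrides (per section)."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    layers = []
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        layers.append(loaded)
    if overrides:
        layers.append(overrides)
    for layer in layers:
        for key, val in layer.items():
            if key not in cfg:
                raise ConfigError(f"unknown config key {key!r}")
            if isinstance(cfg[key], dict):
                if not isinstance(val, dict):
                    raise ConfigError(f"config section {key!r} must be a mapping")
                for k2, v2 in val.items():
                    if k2 not in cfg[key]:
                        raise ConfigError(f"unknown config key {key!r}.{k2!r}")
                    cfg[key][k2] = v2
            else:
                cfg[key] = val
    unknown = set(cfg["stages"]) - set(STAGE_ORDER)
    if unknown:
        raise ConfigError(f"stages: unknown stage(s) {sorted(unknown)}")
    return cfg


def _validate(cfg: dict) -> None:
    stages = cfg["stages"]
    if "qc" in stages and "genotypes" not in stages and not cfg["genotypes"]["path"]:
        raise ConfigError("qc: needs 'genotypes' stage enabled or genotypes.path set")
    for dep in ("gst", "mantel", "cnd"):
        if dep in stages and "qc" not in stages:
            raise ConfigError(f"{dep}: needs the 'qc' stage enabled")
    if "fit" in stages:
        if "connectivity" not in stages and not cfg["connectivity"]["path"]:
            raise ConfigError("fit: needs 'connectivity' stage enabled or connectivity.path set")
        if "cline" not in stages and not cfg["cline"]["path"]:
            raise ConfigError("fit: needs 'cline' stage enabled or cline.path set")


def run(config=None, out_dir="artifacts", config_path=None) -> dict:
    """Execute the enabled stages in dependency order; returns the summary dict."""
    cfg = config if isinstance(config, dict) else load_config(config_path or config)
    _validate(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])
    log: list[str] = [f"coastcline {__version__} (python {platform.python_version()})",
                      f"master seed: {master}"]
    summary: dict = {"seed": master, "stages": list(cfg["stages"])}
    stages = cfg["stages"]

    g = cfg["grid"]
    grid = CoastGrid.regular(int(g["n_sites"]), float(g["spacing_km"]),
                             float(g["lat_south"]), float(g["lon"]))

    conn = None
    if "connectivity" in stages or cfg["connectivity"]["path"]:
        c = cfg["connectivity"]
        if c["path"]:
            conn = read_connectivity(c["path"])
            grid = conn.grid
            log.append(f"connectivity: loaded {c['path']}")
        else:
            conn = make_advective_kernel(grid, float(c["mean_displacement_km"]),
                                         float(c["spread_km"]), float(c["loss"]))
            log.append(f"connectivity: kernel mu={c['mean_displacement_km']} "
                       f"sigma={c['spread_km']} loss={c['loss']}")
        write_connectivity(conn, out / "connectivity.tsv")

    observed = None
    if "cline" in stages or cfg["cline"]["path"]:
        ccl = cfg["cline"]
        if ccl["path"]:
            observed = read_observed_cline(ccl["path"])
            log.append(f"cline: loaded {ccl['path']}")
        else:
            observed = _synthesize_cline_via_coi(grid, cfg, out, log, master)
        write_observed_cline(observed, out / "observed_cline.csv")
        summary["cline"] = {
            "n_sites": observed.grid.n_sites,
            "f_north": {s: round(float(f), 4)
                        for s, f in zip(observed.grid.site_ids, observed.f)},
        }

    table = None
    if "genotypes" in stages or cfg["genotypes"]["path"]:
        gcfg = cfg["genotypes"]
        if gcfg["path"]:
            table = read_genotypes(gcfg["path"], dialect=gcfg["dialect"])
            log.append(f"genotypes: loaded {gcfg['path']}")
        else:
            sub_idx = [int(i) for i in gcfg["sample_sites"]]
            sub = CoastGrid(tuple(grid.site_ids[i] for i in sub_idx),
                            grid.latitudes[sub_idx], grid.longitudes[sub_idx])
            if gcfg["compose_from_cline"] and observed is not None:
                # parental mix per site tracks the cline, as in field samples
                n_par = int(gcfg["n_parental_per_site"])
                hybrids = {k: v for k, v in gcfg["n_per_class"].items()
                           if k not in ("N", "S")}
                ccl = cfg["cline"]
                center_lat = float(grid.latitudes[int(ccl["center_site"])])
                ftrue = sigmoid_cline(sub, center_lat, float(ccl["width_km"])).f
                counts = {}
                for k, s in enumerate(sub.site_ids):
                    n_north = int(round(n_par * float(ftrue[k])))
                    counts[s] = {"N": n_north, "S": n_par - n_north, **hybrids}
            else:
                counts = dict(gcfg["n_per_class"])
            table = simulate_genotypes(
                sub, counts, int(gcfg["n_loci"]),
                float(gcfg["divergence"]), float(gcfg["missing_rate"]),
                bool(gcfg["ascertain_north"]), seed=stage_seed(master, "genotypes"))
            log.append(f"genotypes: simulated {table.n_individuals} ind x "
                       f"{table.n_loci} loci at sites {list(sub.site_ids)}")
        write_genotypes(table, out / "genotypes.csv")

    if "qc" in stages:
        qcfg = cfg["qc"]
        table, report = apply_qc(table, float(qcfg["locus_missing_max"]),
                                 float(qcfg["indiv_missing_max"]))
        write_genotypes(table, out / "genotypes_qc.csv")
        summary["qc"] = {
            "n_loci_removed": len(report.loci_removed),
            "n_individuals_removed": len(report.individuals_removed),
            "n_retained_individuals": report.n_retained_individuals,
            "n_retained_loci": report.n_retained_loci,
            "n_variable_loci": report.n_variable_loci,
        }
        (out / "qc_report.json").write_text(json.dumps({
            "loci_removed": report.loci_removed,
            "individuals_removed": report.individuals_removed,
            **summary["qc"]}, indent=2, sort_keys=True))
        log.append(f"qc: retained {report.n_retained_individuals} individuals, "
                   f"{report.n_retained_loci} loci ({report.n_variable_loci} variable)")

    if "gst" in stages:
        scfg = cfg["gst"]
        pg = pairwise_gst(table, int(scfg["n_permutations"]),
                          seed=stage_seed(master, "gst"),
                          estimator=scfg["estimator"])
        pg.gst.to_csv(out / "gst_matrix.csv")
        pg.p_value.to_csv(out / "gst_pvalues.csv")
        lats = {s: table.site_coords[s][0] for s in pg.gst.index}
        regions = region_mean_gst(pg.gst, lats)
        summary["gst"] = {
            "max_pairwise": float(np.nanmax(pg.gst.to_numpy())),
            "region_means": {k: (None if np.isnan(v) else round(v, 4))
                             for k, v in regions.items()},
        }
        log.append(f"gst: {len(pg.results)} pairs, max {summary['gst']['max_pairwise']:.3f}")

    if "mantel" in stages:
        mcfg = cfg["mantel"]
        res = mantel_ibd(table, partition=mcfg["partition"],
                         n_permutations=int(mcfg["n_permutations"]),
                         seed=stage_seed(master, "mantel"))
        summary["mantel"] = {"r": round(res.r, 4), "p": round(res.p, 5),
                             "n_permutations": res.n_permutations,
                             "partition": mcfg["partition"]}
        (out / "mantel.txt").write_text(
            f"Mantel isolation-by-distance (partition={mcfg['partition']})\n"
            f"r = {res.r:.4f}\np = {res.p:.5f} ({res.n_permutations} permutations"
            f"{', exhaustive' if res.exhaustive else ''})\n")
        log.append(f"mantel: r={res.r:.3f} p={res.p:.4f}")

    if "cnd" in stages:
        ncfg = cfg["cnd"]
        results = cytonuclear(table, alpha=float(ncfg["alpha"]),
                              seed=stage_seed(master, "cnd"))
        df = cnd_to_frame(results)
        df.to_csv(out / "cnd.csv", index=False)
        n_sig = int((df["significant_allelic"] | df["significant_genotypic"]).sum())
        summary["cnd"] = {"n_tested": int(df["testable"].sum()),
                          "n_significant": n_sig}
        if ncfg["outlier_flags_path"]:
            from .popgen import overlap_report
            flags = json.loads(Path(ncfg["outlier_flags_path"]).read_text())
            overlap, odf = overlap_report(results, flags)
            odf.to_csv(out / "overlap.csv", index=False)
            summary["cnd"]["overlap_loci"] = overlap
        log.append(f"cnd: {n_sig} of {summary['cnd']['n_tested']} loci significant")

    if "fit" in stages:
        fcfg = cfg["fit"]
        lo, hi, step = (int(fcfg["break_min_site"]), int(fcfg["break_max_site"]),
                        int(fcfg["break_step"]))
        breaks = grid.latitudes[lo:hi + 1:step]
        scan = scan_breaks(breaks, conn, observed,
                           dw_bounds=(0.0, float(fcfg["dw_max"])),
                           tol=float(fcfg["tol"]),
                           max_generations=int(fcfg["max_generations"]))
        scan.to_frame().to_csv(out / "breakscan.csv", index=False)
        best = scan.best
        final = run_to_steady_state(
            0.5, conn, FitnessScenario(best.break_latitude, best.dw_opt),
            tol=float(fcfg["tol"]), max_generations=int(fcfg["max_generations"]))
        write_observed_cline(final.final_cline, out / "fitted_cline.csv")
        summary["fit"] = {"best_break_lat": round(best.break_latitude, 4),
                          "dw_opt": round(best.dw_opt, 4),
                          "misfit_opt": round(best.misfit_opt, 6),
                          "misfit_at_zero": round(best.misfit_at_zero, 6),
                          "improved": best.improved}
        log.append(f"fit: best break {best.break_latitude:.2f} deg, "
                   f"dw_opt={best.dw_opt:.3f}, misfit={best.misfit_opt:.4f}")

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    (out / "config_used.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return summary


def _synthesize_cline_via_coi(grid, cfg, out, log, master) -> LineageCline:
    """True sigmoid cline -> per-site COI individuals -> SpeI calls -> cline."""
    ccl, kcfg = cfg["cline"], cfg["coi"]
    center_lat = float(grid.latitudes[int(ccl["center_site"])])
    true = sigmoid_cline(grid, center_lat, float(ccl["width_km"]))
    rng = np.random.default_rng(stage_seed(master, "cline"))
    stride = int(ccl["site_stride"])
    n_per_site = int(ccl["coi_per_site"])
    idx = list(range(0, grid.n_sites, stride))
    n_north = rng.binomial(n_per_site, true.f[idx])
    records = simulate_coi(
        {"northern": int(n_north.sum()),
         "southern": int(n_per_site * len(idx) - n_north.sum())},
        length_bp=int(kcfg["length_bp"]),
        pairwise_divergence=float(kcfg["divergence"]),
        spei_in=kcfg["spei_in"], seed=stage_seed(master, "coi"))
    SeqIO.write(records, str(out / "coi.fasta"), "fasta")
    north_ids = [r.id for r in records if r.id.startswith("northern")]
    south_ids = [r.id for r in records if r.id.startswith("southern")]
    site_of, ni, si = {}, 0, 0
    for k, i in enumerate(idx):
        for _ in range(int(n_north[k])):
            site_of[north_ids[ni]] = grid.site_ids[i]
            ni += 1
        for _ in range(n_per_site - int(n_north[k])):
            site_of[south_ids[si]] = grid.site_ids[i]
            si += 1
    cut_lineage = "S" if kcfg["spei_in"] == "southern" else "N"
    calls = classify_mitotypes(records, cut_lineage=cut_lineage)
    write_calls(calls, site_of, out / "mitotype_calls.csv")
    log.append(f"cline: {len(records)} COI records typed by SpeI digest at "
               f"{len(idx)} sites (cut lineage {cut_lineage})")
    return cline_from_calls(calls, site_of, grid)


def report(artifact_dir) -> str:
    """One-page human-readable summary of a run's artifact directory."""
    out = Path(artifact_dir)
    lines = [f"coastcline run report: {out}"]
    summary_path = out / "summary.json"
    if not summary_path.exists():
        return "\n".join(lines + ["MISSING: summary.json (directory not produced by run?)"])
    s = json.loads(summary_path.read_text())
    lines.append(f"master seed: {s.get('seed')}; stages: {', '.join(s.get('stages', []))}")
    if "qc" in s:
        q = s["qc"]
        lines.append(f"QC: retained {q['n_retained_individuals']} individuals, "
                     f"{q['n_retained_loci']} loci ({q['n_variable_loci']} variable); "
                     f"removed {q['n_loci_removed']} loci, "
                     f"{q['n_individuals_removed']} individuals")
    if "cline" in s:
        f = s["cline"]["f_north"]
        ends = list(f.items())
        lines.append(f"cline: {s['cline']['n_sites']} sites; southernmost "
                     f"{ends[0][0]} f_N={ends[0][1]}, northernmost {ends[-1][0]} f_N={ends[-1][1]}")
    if "gst" in s:
        lines.append(f"Gst: max pairwise {s['gst']['max_pairwise']:.3f}; "
                     f"region means {s['gst']['region_means']}")
    if "mantel" in s:
        m = s["mantel"]
        lines.append(f"Mantel IBD: r={m['r']} p={m['p']} ({m['n_permutations']} perms)")
    if "cnd" in s:
        lines.append(f"CND: {s['cnd']['n_significant']} of {s['cnd']['n_tested']} "
                     "testable loci significant after Bonferroni")
    if "fit" in s:
        ft = s["fit"]
        lines.append(f"fit: best break {ft['best_break_lat']} deg, "
                     f"dw_opt={ft['dw_opt']}, misfit={ft['misfit_opt']} "
                     f"(neutral misfit {ft['misfit_at_zero']})")
    expected = {"connectivity": "connectivity.tsv", "cline": "observed_cline.csv",
                "genotypes": "genotypes.csv", "qc": "qc_report.json",
                "gst": "gst_matrix.csv", "mantel": "mantel.txt",
                "cnd": "cnd.csv", "fit": "breakscan.csv"}
    missing = [fn for st, fn in expected.items()
               if st in s.get("stages", []) and not (out / fn).exists()]
    if missing:
        lines.append("WARNING missing artifacts: " + ", ".join(missing))
    return "\n".join(lines)
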