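"""Configuration-driven orchestration of the full analysis.

Stage order mirrors the analysis workflow: simulate (optional, synthetic
inputs) -> egv (resource-unit table and screening) -> homerange (MCPs,
availability, use) -> ratios (Manly design III) -> kselect (marginality
eigenanalysis and randomization tests) -> thin (Clark-Evans thinning of the
settled points) -> suitability (Mahalanobis D2 maps) -> evaluate (Fi curve,
Boyce index, reclassification).  Every stage reads its declared inputs from
and writes its declared outputs to the run directory; a manifest records the
config hash, seeds and a checksum per output so that reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .resource_units import (
    RasterGrid, RUStack, aggregate_to_ru, pearson_screen, pca_egv,
    read_ascii_grid, write_ascii_grid,
)
from .home_range import availability, mcp, used_units, write_geojson
from .selection_ratios import DesignIIIInput, global_ratios, group_ratios
from .kselect import (
    first_eigenvalue_test, kselect_eigen, marginality,
    marginality_randomization, standardize,
)
from .thinning import clark_evans, dedupe, thin_to_random
from .suitability import (
    boyce_index, fi_curve, fit_niche, reclassify_and_summarize,
    select_niche_columns, suitability_map,
)

logger = logging.getLogger("habselect")

STAGES = ["simulate", "egv", "homerange", "ratios", "kselect", "thin",
          "suitability", "evaluate"]

FLOAT_FORMAT = "%.10g"  # 10 significant digits in every CSV


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' needs {path.name}, produced by stage "
            f"'{stage}'; run that stage first"
        )
    return path


def load_ru_stack(outdir: Path) -> RUStack:
    table = pd.read_csv(_require(outdir / "ru_table.csv", "egv", "load"))
    classes = sorted(
        int(c.split("_", 1)[1]) for c in table.columns if c.startswith("prop_")
    )
    grids = {}
    for p in sorted(outdir.glob("ru_*.asc")):
        grids[p.stem[3:]] = read_ascii_grid(p)
    return RUStack(table=table, grids=grids, cover_classes=classes)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, outdir: Path, seed: int | None) -> list[Path]:
    from .synthetic import SyntheticConfig, generate_landscape, build_ru_stack, \
        generate_telemetry

    syn = dict(cfg.get("synthetic", {}))
    if seed is not None:
        syn["seed"] = seed
    for key in ("selection_coefficients", "exploratory_coefficients",
                "home_range_centres", "home_range_radii"):
        if syn.get(key) is not None:
            syn[key] = np.asarray(syn[key], dtype=float)
    sc = SyntheticConfig(**syn)
    cover, continuous = generate_landscape(sc)
    stack = build_ru_stack(sc, cover, continuous)
    telemetry, truth = generate_telemetry(sc, stack)

    outputs = []
    for name, grid in {"cover": cover, **continuous}.items():
        p = outdir / f"fine_{name}.asc"
        write_ascii_grid(grid, p)
        outputs.append(p)
    p = outdir / "telemetry.csv"
    _write_csv(telemetry, p)
    outputs.append(p)
    p = outdir / "truth_points.csv"
    _write_csv(truth.point_ru, p)
    outputs.append(p)
    p = outdir / "truth_beta.csv"
    _write_csv(
        pd.DataFrame(truth.beta_settled, columns=truth.egv_names), p
    )
    outputs.append(p)

    # core/buffer zone raster at RU scale: core = central 40% of the extent
    any_grid = next(iter(stack.grids.values()))
    xc, yc = any_grid.cell_centres()
    cx = any_grid.x_min + any_grid.n_cols * any_grid.cell_size / 2
    cy = any_grid.y_max - any_grid.n_rows * any_grid.cell_size / 2
    r_core = 0.4 * min(any_grid.n_cols, any_grid.n_rows) * any_grid.cell_size
    zones = (np.hypot(xc - cx, yc - cy) <= r_core).astype(float)
    p = outdir / "zones.asc"
    write_ascii_grid(
        RasterGrid(zones, any_grid.cell_size, any_grid.origin), p
    )
    outputs.append(p)
    return outputs


def stage_egv(cfg: dict, outdir: Path, seed: int | None) -> list[Path]:
    cover = read_ascii_grid(_require(outdir / "fine_cover.asc", "simulate",
                                     "egv"))
    continuous = {
        p.stem[5:]: read_ascii_grid(p)
        for p in sorted(outdir.glob("fine_*.asc")) if p.stem != "fine_cover"
    }
    factor = int(cfg.get("aggregation_factor", 3))
    stack = aggregate_to_ru(cover, continuous, factor=factor)

    outputs = []
    p = outdir / "ru_table.csv"
    _write_csv(stack.table, p)
    outputs.append(p)
    for name, grid in stack.grids.items():
        gp = outdir / f"ru_{name}.asc"
        write_ascii_grid(grid, gp)
        outputs.append(gp)

    corr, flagged = pearson_screen(
        stack.table, threshold=float(cfg.get("correlation_threshold", 0.7))
    )
    p = outdir / "correlation.csv"
    corr.to_csv(p, float_format=FLOAT_FORMAT)
    outputs.append(p)
    if flagged:
        logger.warning("strongly correlated EGV pairs: %s", flagged)

    res = pca_egv(stack.table)
    p = outdir / "pca.csv"
    out = res.loadings.copy()
    out.loc["__eigenvalue__"] = res.eigenvalues
    out.loc["__percent_variance__"] = res.percent_variance
    out.to_csv(p, float_format=FLOAT_FORMAT)
    outputs.append(p)
    return outputs


def _load_telemetry(outdir: Path, needed_by: str) -> pd.DataFrame:
    return pd.read_csv(_require(outdir / "telemetry.csv", "simulate",
                                needed_by))


def stage_homerange(cfg: dict, outdir: Path, seed: int | None) -> list[Path]:
    tele = _load_telemetry(outdir, "homerange")
    stack = load_ru_stack(outdir)
    polys, avail_rows, used_rows = [], [], []
    for (animal, period), grp in tele.groupby(["animal_id", "period"]):
        pts = grp[["x", "y"]].to_numpy()
        poly = mcp(pts, animal_id=animal, period=period)
        polys.append(poly)
        ru_ids, counts = used_units(pts, stack)
        av = availability(stack, poly, include_ru_ids=ru_ids)
        for cat, pi in av.proportions.items():
            avail_rows.append(dict(animal_id=animal, period=period,
                                   category=cat, available=pi))
        for cat, u in counts.items():
            used_rows.append(dict(animal_id=animal, period=period,
                                  category=cat, used=int(u)))
    outputs = []
    p = outdir / "mcp.geojson"
    write_geojson(polys, p)
    outputs.append(p)
    p = outdir / "availability.csv"
    _write_csv(pd.DataFrame(avail_rows), p)
    outputs.append(p)
    p = outdir / "used_counts.csv"
    _write_csv(pd.DataFrame(used_rows), p)
    outputs.append(p)
    return outputs


def _design_inputs(outdir: Path, period: str, needed_by: str
                   ) -> list[DesignIIIInput]:
    avail = pd.read_csv(_require(outdir / "availability.csv", "homerange",
                                 needed_by))
    used = pd.read_csv(_require(outdir / "used_counts.csv", "homerange",
                                needed_by))
    inputs = []
    for animal in sorted(avail["animal_id"].unique()):
        a = avail[(avail.animal_id == animal) & (avail.period == period)]
        u = used[(used.animal_id == animal) & (used.period == period)]
        if a.empty:
            continue
        inputs.append(DesignIIIInput(
            animal_id=str(animal),
            used=u.set_index("category")["used"],
            available=a.set_index("category")["available"],
        ))
    return inputs


def stage_ratios(cfg: dict, outdir: Path, seed: int | None) -> list[Path]:
    tele = _load_telemetry(outdir, "ratios")
    outputs = []
    for period in sorted(tele["period"].unique()):
        inputs = _design_inputs(outdir, period, "ratios")
        table = global_ratios(inputs, alpha=float(cfg.get("alpha", 0.05)))
        p = outdir / f"selection_ratios_{period}.csv"
        _write_csv(table, p)
        outputs.append(p)
    # sex-specific selection during the settled period
    sexes = tele.drop_duplicates("animal_id").set_index("animal_id")["sex"]
    inputs = _design_inputs(outdir, "settled", "ratios")
    if inputs and sexes.notna().all():
        groups = {i.animal_id: str(sexes[i.animal_id]) for i in inputs}
        for g, table in group_ratios(inputs, groups).items():
            p = outdir / f"selection_ratios_settled_sex_{g}.csv"
            _write_csv(table, p)
            outputs.append(p)
    return outputs


def _used_available_ids(tele: pd.DataFrame, stack: RUStack, period: str):
    """Per-animal (used RU multiset, available RU set) for one period."""
    out = {}
    for animal, grp in tele[tele.period == period].groupby("animal_id"):
        pts = grp[["x", "y"]].to_numpy()
        poly = mcp(pts, animal_id=animal, period=period)
        ru_ids, _ = used_units(pts, stack)
        av = availability(stack, poly, include_ru_ids=ru_ids)
        # the RU is the analysis unit: marginality and its randomization
        # null operate on the set of distinct used RUs
        out[str(animal)] = (np.unique(ru_ids), av.ru_ids)
    return out


def stage_kselect(cfg: dict, outdir: Path, seed: int | None) -> list[Path]:
    tele = _load_telemetry(outdir, "kselect")
    stack = load_ru_stack(outdir)
    ztab, _ = standardize(stack.table)
    n_rand = int(cfg.get("randomization_n", 10_000))
    root = np.random.SeedSequence(
        seed if seed is not None else int(cfg.get("seed", 0))
    )
    outputs = []
    for period in sorted(tele["period"].unique()):
        ua = _used_available_ids(tele, stack, period)
        vectors, prows = [], []
        ss = root.spawn(len(ua) + 1)
        for i, (animal, (used_ids, avail_ids)) in enumerate(sorted(ua.items())):
            v = marginality(used_ids, avail_ids, ztab, animal, period)
            pval, _ = marginality_randomization(
                used_ids, avail_ids, ztab, n_rand,
                rng=np.random.default_rng(ss[i]), animal_id=animal,
            )
            v.p_value = pval
            vectors.append(v)
            prows.append(dict(animal_id=animal, period=period,
                              marginality=v.squared_norm, p_value=pval,
                              n_used=v.n_used, n_available=v.n_available))
        res = kselect_eigen(vectors)
        lam1_p, lam1, _ = first_eigenvalue_test(
            [ua[a] for a in sorted(ua)], ztab,
            n_randomizations=min(n_rand, 1000),
            rng=np.random.default_rng(ss[len(ua)]),
        )
        p = outdir / f"kselect_marginality_{period}.csv"
        _write_csv(pd.DataFrame(prows), p)
        outputs.append(p)
        p = outdir / f"kselect_eigen_{period}.csv"
        eig = res.loadings.copy()
        eig.loc["__eigenvalue__"] = res.eigenvalues
        eig.loc["__percent__"] = res.percent_marginality
        eig.to_csv(p, float_format=FLOAT_FORMAT)
        outputs.append(p)
        p = outdir / f"kselect_lambda1_{period}.json"
        p.write_text(json.dumps(
            {"lambda1": lam1, "p_value": lam1_p, "n_randomizations":
             min(n_rand, 1000)}, indent=1))
        outputs.append(p)
    return outputs


def stage_thin(cfg: dict, outdir: Path, seed: int | None) -> list[Path]:
    tele = _load_telemetry(outdir, "thin")
    settled = tele[tele.period == "settled"]
    tol = float(cfg.get("thinning_tolerance", 0.05))
    min_pts = int(cfg.get("thinning_min_points", 10))
    reports, retained_frames = [], []
    for animal, grp in settled.groupby("animal_id"):
        pts = dedupe(grp[["x", "y"]].to_numpy())
        area = mcp(pts, animal_id=animal).area
        res = thin_to_random(pts, area, tolerance=tol,
                             min_points=min(min_pts, max(3, len(pts) - 1)),
                             animal_id=str(animal))
        reports.append(res.to_dict())
        kept = pd.DataFrame(pts[res.retained], columns=["x", "y"])
        kept.insert(0, "animal_id", animal)
        retained_frames.append(kept)
    outputs = []
    p = outdir / "telemetry_thinned.csv"
    _write_csv(pd.concat(retained_frames, ignore_index=True), p)
    outputs.append(p)
    p = outdir / "thinning_report.json"
    p.write_text(json.dumps(reports, indent=1))
    outputs.append(p)
    return outputs


def stage_suitability(cfg: dict, outdir: Path, seed: int | None) -> list[Path]:
    stack = load_ru_stack(outdir)
    thinned = pd.read_csv(_require(outdir / "telemetry_thinned.csv", "thin",
                                   "suitability"))
    ru_ids, _ = used_units(thinned[["x", "y"]].to_numpy(), stack)
    used_vals = stack.table.set_index("ru_id").loc[ru_ids].reset_index()
    egv_cols = select_niche_columns(used_vals, stack.cover_classes)
    model = fit_niche(used_vals, columns=egv_cols,
                      ridge=float(cfg.get("ridge", 0.0)))
    d2, suit = suitability_map(stack, model)
    outputs = []
    for name, grid in (("d2", d2), ("suitability", suit)):
        p = outdir / f"map_{name}.asc"
        write_ascii_grid(grid, p)
        outputs.append(p)
    p = outdir / "niche_model.json"
    p.write_text(json.dumps({
        "mean": model.mean.tolist(), "cov": model.cov.tolist(),
        "columns": model.columns, "n": model.n,
        "condition_number": model.condition_number}, indent=1))
    outputs.append(p)
    return outputs


def stage_evaluate(cfg: dict, outdir: Path, seed: int | None) -> list[Path]:
    suit = read_ascii_grid(_require(outdir / "map_suitability.asc",
                                    "suitability", "evaluate"))
    thinned = pd.read_csv(_require(outdir / "telemetry_thinned.csv", "thin",
                                   "evaluate"))
    pts = thinned[["x", "y"]].to_numpy()
    holdout = float(cfg.get("holdout", 0.0))
    if holdout > 0:
        rng = np.random.default_rng(
            seed if seed is not None else int(cfg.get("seed", 0))
        )
        n_hold = int(round(holdout * len(pts)))
        idx = rng.permutation(len(pts))
        pts = pts[idx[:n_hold]] if n_hold else pts
    curve = fi_curve(suit, pts, n_classes=int(cfg.get("fi_classes", 20)))
    curve = boyce_index(curve)
    outputs = []
    p = outdir / "fi_curve.csv"
    _write_csv(curve.table, p)
    outputs.append(p)

    report = {"boyce_spearman_r": curve.boyce_r,
              "adjusted_r2": curve.adjusted_r2,
              "threshold": curve.threshold,
              "n_evaluation_points": int(len(pts))}
    if curve.threshold is not None:
        zones_path = outdir / "zones.asc"
        zones = read_ascii_grid(zones_path) if zones_path.exists() else None
        binary, summary = reclassify_and_summarize(suit, curve, zones)
        p = outdir / "map_suitable_binary.asc"
        write_ascii_grid(binary, p)
        outputs.append(p)
        p = outdir / "zone_summary.csv"
        _write_csv(summary, p)
        outputs.append(p)
        report["percent_suitable"] = {
            str(r.zone): r.percent_suitable for r in summary.itertuples()
        }
    p = outdir / "evaluation.json"
    p.write_text(json.dumps(report, indent=1))
    outputs.append(p)
    return outputs


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "egv": stage_egv,
    "homerange": stage_homerange,
    "ratios": stage_ratios,
    "kselect": stage_kselect,
    "thin": stage_thin,
    "suitability": stage_suitability,
    "evaluate": stage_evaluate,
}


def run(config: dict | str | Path, outdir: str | Path,
        stages: list[str] | None = None, seed: int | None = None) -> dict:
    """Run the pipeline and return the manifest.

    ``config`` is a dict or a YAML path.  ``stages`` defaults to all stages
    in order; ``seed`` overrides any seed in the config.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = stages or STAGES
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    stages = [s for s in STAGES if s in stages]

    cfg_text = yaml.safe_dump(config, sort_keys=True)
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": seed if seed is not None else config.get("seed"),
        "stages": {},
    }
    for s in stages:
        logger.info("running stage %s", s)
        try:
            outputs = _STAGE_FUNCS[s](config, outdir, seed)
        except Exception:
            logger.error("stage %s failed", s)
            raise
        manifest["stages"][s] = {
            p.name: _sha256(p) for p in outputs
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
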