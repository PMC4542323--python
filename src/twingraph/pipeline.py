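"""End-to-end orchestration: simulate -> fit -> matrix -> cluster -> network.

A single :class:`RunConfig` drives all stages.  Every stochastic stage
consumes a named sub-seed derived deterministically from the master seed, so
the manifest written at the end suffices to reproduce any single stage in
isolation.  Stage outputs are plain CSV/JSON files in the output directory;
with ``resume=True`` stages whose outputs already exist are skipped, making
an aborted run restartable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import twingraph
from twingraph.biometric_models import compare_models, fit_univariate, fits_to_frame
from twingraph.cluster_ordering import bilateral_homologue_check, cluster_matrix
from twingraph.correlation_matrix import residualize_panel, run_all_fits
from twingraph.network_analysis import (
    build_network,
    graph_metrics,
    hub_nodes,
    rich_club,
    sigma_ratio,
    simulate_null,
    small_world_estimability,
    sparsity_sweep,
)
from twingraph.synthetic_twins import (
    COVARIATE_COLUMNS,
    SimulationSpec,
    TwinCohort,
    demo_spec,
    generate_cohort,
)

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic named sub-seed below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Either ``spec`` (a simulation specification) or ``input_csv`` (a
    long-format cohort file) must be provided.  ``subsets`` selects which
    node subsets get network metrics; ``null_reps`` sizes the matched null
    distribution; ``alpha_grid`` drives the sparsity sweep.
    """

    output_dir: str | Path = "twingraph_run"
    spec: SimulationSpec | None = None
    input_csv: str | Path | None = None
    seed: int = 0
    alpha: float = 0.05
    null_reps: int = 1000
    null_mode: str = "edge_sampling"
    degree_convention: str = "paper"
    linkage_method: str = "complete"
    subsets: tuple[str, ...] = ("all", "CT", "SA")
    alpha_grid: tuple[float, ...] = (0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0)
    residualize: bool = True
    compute_ci: bool = False
    n_restarts: int = 5
    resume: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.null_reps < 1:
            raise ValueError("null_reps must be >= 1")
        if self.spec is None and self.input_csv is None:
            raise ValueError("provide either a simulation spec or an input CSV")


def default_demo_config(output_dir: str | Path = "twingraph_demo",
                        seed: int = 0) -> RunConfig:
    """Demo configuration: 6-measure bilateral panel, 300 pairs/zygosity."""
    spec = demo_spec(n_mz_pairs=300, n_dz_pairs=300, n_singletons=30,
                     seed=stage_seed(seed, "simulate"))
    return RunConfig(output_dir=output_dir, spec=spec, seed=seed,
                     null_reps=200)


@dataclass
class ValidationReport:
    path: str
    n_rows: int
    violations: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_input(path: str | Path) -> ValidationReport:
    """Schema check for a long-format cohort CSV.

    Verifies required columns, MZ/DZ zygosity codes, at most two members
    per family, and numeric parsing of covariate and phenotype columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path)
    report = ValidationReport(str(path), len(df))
    required = ["family_id", "member_index", "zygosity"]
    for col in required:
        if col not in df.columns:
            report.violations.append(
                {"row": None, "message": f"missing required column {col!r}"})
    if report.violations:
        return report
    bad_zyg = df[~df["zygosity"].isin(["MZ", "DZ"])]
    for r, row in bad_zyg.iterrows():
        report.violations.append(
            {"row": int(r) + 2,  # 1-based with header line
             "message": f"unsupported zygosity code {row['zygosity']!r} "
                        "(only MZ/DZ supported)"})
    sizes = df.groupby("family_id").size()
    for fam, n in sizes[sizes > 2].items():
        report.violations.append(
            {"row": None,
             "message": f"family {fam!r} has {n} members (max 2)"})
    dup = df.duplicated(subset=["family_id", "member_index"], keep=False)
    for fam in df.loc[dup, "family_id"].unique():
        report.violations.append(
            {"row": None,
             "message": f"family {fam!r} has duplicated member_index"})
    value_cols = [c for c in df.columns if c not in ("family_id", "zygosity")]
    for col in value_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for r in bad:
            report.violations.append(
                {"row": int(r) + 2,
                 "message": f"non-numeric value in column {col!r}"})
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _metrics_to_dict(met) -> dict:
    return {
        "n_nodes": met.n_nodes, "n_edges": met.n_edges,
        "mean_degree_paper": met.mean_degree_paper,
        "mean_degree_standard": met.mean_degree_standard,
        "ln_n_nodes": met.ln_n_nodes, "sparsity": met.sparsity,
        "C": met.C, "L": met.L, "sigma": met.sigma,
        "local_efficiency": met.local_efficiency,
        "global_efficiency": met.global_efficiency,
        "n_unreachable_pairs": met.n_unreachable_pairs,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": twingraph.__version__,
        "seed": config.seed,
        "stage_seeds": {},
        "timings_s": {},
        "outputs": {},
        "counts": {},
    }
    manifest_path = out / "manifest.json"

    def finish_stage(stage: str, t0: float, files: list[Path]) -> None:
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
        for f in files:
            manifest["outputs"][f.name] = _sha256(f)
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    # ---- stage 1: cohort -------------------------------------------------
    t0 = time.perf_counter()
    cohort_path = out / "cohort.csv"
    if config.spec is not None:
        manifest["stage_seeds"]["simulate"] = int(config.spec.seed)
        if config.resume and cohort_path.exists():
            cohort = TwinCohort.from_csv(cohort_path,
                                         config.spec.phenotype_labels)
        else:
            cohort = generate_cohort(config.spec)
            cohort.to_csv(cohort_path)
            (out / "simulation_spec.json").write_text(config.spec.to_json())
        files = [cohort_path, out / "simulation_spec.json"]
    else:
        report = validate_input(config.input_csv)
        if not report.ok:
            msgs = "; ".join(
                f"line {v['row']}: {v['message']}" if v["row"] else v["message"]
                for v in report.violations)
            raise ValueError(f"input schema violations: {msgs}")
        cohort = TwinCohort.from_csv(config.input_csv)
        cohort.to_csv(cohort_path)
        files = [cohort_path]
    labels = list(cohort.phenotype_labels)
    manifest["counts"]["n_families"] = cohort.n_families
    manifest["counts"]["n_phenotypes"] = len(labels)
    finish_stage("cohort", t0, files)

    # ---- stage 2: residualization ---------------------------------------
    t0 = time.perf_counter()
    if config.residualize and all(c in cohort.data.columns
                                  for c in COVARIATE_COLUMNS):
        cohort = residualize_panel(cohort)
    resid_path = out / "cohort_residualized.csv"
    cohort.to_csv(resid_path)
    finish_stage("residualize", t0, [resid_path])

    # ---- stage 3: univariate fits + shared-environment screen ------------
    t0 = time.perf_counter()
    uni_fits = []
    comparisons: dict[str, dict] = {}
    significant_c = []
    for ph in labels:
        ace = fit_univariate(cohort, ph, "ACE", n_restarts=config.n_restarts,
                             compute_ci=config.compute_ci)
        ae = fit_univariate(cohort, ph, "AE", n_restarts=config.n_restarts)
        ce = fit_univariate(cohort, ph, "CE", n_restarts=config.n_restarts)
        e = fit_univariate(cohort, ph, "E", n_restarts=config.n_restarts)
        comparisons[ph] = {
            "A": compare_models(ace, ce, n_boundary_components=1),
            "C": compare_models(ace, ae, n_boundary_components=1),
            "AC": compare_models(ace, e, n_boundary_components=2),
        }
        if comparisons[ph]["C"].p_value < config.alpha:
            significant_c.append(ph)
        uni_fits.append(ace)
    uni_path = out / "univariate_fits.csv"
    fits_to_frame(uni_fits, comparisons).to_csv(uni_path, index=False)
    screen = {"significant": significant_c,
              "ae_approved": not significant_c, "alpha": config.alpha}
    screen_path = out / "shared_environment_screen.json"
    screen_path.write_text(json.dumps(screen, indent=2))
    manifest["counts"]["n_univariate_fits"] = len(uni_fits)
    finish_stage("univariate", t0, [uni_path, screen_path])

    # ---- stage 4: bivariate fits, rg matrix ------------------------------
    t0 = time.perf_counter()
    matrix = run_all_fits(cohort, labels, n_restarts=config.n_restarts)
    rg_path = out / "rg_matrix.csv"
    p_path = out / "p_matrix.csv"
    edges_path = out / "edge_table.csv"
    matrix.rg.to_csv(rg_path)
    matrix.p.to_csv(p_path)
    matrix.edge_table().to_csv(edges_path, index=False)
    manifest["counts"]["n_bivariate_fits"] = matrix.n_pairs
    manifest["counts"]["n_missing_pairs"] = matrix.n_missing_pairs
    finish_stage("matrix", t0, [rg_path, p_path, edges_path])

    # ---- stage 5: cluster ordering ---------------------------------------
    t0 = time.perf_counter()
    clus = cluster_matrix(matrix.rg, linkage_method=config.linkage_method)
    order_path = out / "leaf_order.csv"
    merge_path = out / "merge_table.csv"
    pd.Series(clus.leaf_order, name="label").to_csv(order_path, index=False)
    clus.merge_table().to_csv(merge_path, index=False)
    cluster_files = [order_path, merge_path]
    try:
        hom = bilateral_homologue_check(matrix.rg)
        hom_path = out / "homologue_pairs.csv"
        hom["pairs"].to_csv(hom_path, index=False)
        cluster_files.append(hom_path)
        manifest["counts"]["fraction_positive_homologue"] = \
            hom["fraction_positive_homologue"]
    except ValueError:
        logger.info("labels lack matched homologues; skipping bilateral check")
    finish_stage("cluster", t0, cluster_files)

    # ---- stage 6: network analysis ---------------------------------------
    t0 = time.perf_counter()
    edge_table = matrix.edge_table()
    net_report: dict = {}
    net_files: list[Path] = []
    null_seed = stage_seed(config.seed, "null_networks")
    manifest["stage_seeds"]["null_networks"] = null_seed
    for subset in config.subsets:
        net = build_network(edge_table, alpha=config.alpha, subset=subset)
        met = graph_metrics(net)
        entry = _metrics_to_dict(met)
        entry["small_world_estimable"] = small_world_estimability(
            met, config.degree_convention).estimable
        if net.n_edges > 0 and net.n_nodes > 1:
            null = simulate_null(net.n_nodes, net.n_edges,
                                 reps=config.null_reps,
                                 seed=stage_seed(null_seed, subset),
                                 mode=config.null_mode,
                                 observed_C=met.C, observed_L=met.L)
            entry["null_quantile_C"] = null.observed_quantile_C
            entry["null_quantile_L"] = null.observed_quantile_L
            entry["sigma_null_quantiles"] = sigma_ratio(
                null.observed_quantile_C, null.observed_quantile_L)
            nd_path = out / f"null_distribution_{subset}.csv"
            null.to_frame().to_csv(nd_path, index=False)
            net_files.append(nd_path)

            rc = rich_club(net)
            rc_path = out / f"rich_club_{subset}.csv"
            rc.table.to_csv(rc_path, index=False)
            net_files.append(rc_path)

            hubs = hub_nodes(met)
            hub_path = out / f"hubs_{subset}.csv"
            hubs.to_csv(hub_path)
            net_files.append(hub_path)
            entry["hubs"] = list(hubs.index[hubs["hub"]])

            edge_list_path = out / f"edge_list_{subset}.csv"
            sub_edges = edge_table[
                (edge_table["p"] < config.alpha) & edge_table["rg"].notna()]
            if subset != "all":
                keep = set(net.labels)
                sub_edges = sub_edges[sub_edges["label_i"].isin(keep)
                                      & sub_edges["label_j"].isin(keep)]
            signed = sub_edges.rename(
                columns={"label_i": "source", "label_j": "target"}).copy()
            signed["sign"] = np.where(signed["rg"] >= 0, 1, -1)
            signed[["source", "target", "sign", "rg", "p"]].to_csv(
                edge_list_path, index=False)
            net_files.append(edge_list_path)

        sweep = sparsity_sweep(edge_table, list(config.alpha_grid),
                               subset=subset)
        sweep_path = out / f"sparsity_sweep_{subset}.csv"
        sweep.to_csv(sweep_path, index=False)
        net_files.append(sweep_path)
        net_report[subset] = entry
    metrics_path = out / "network_metrics.json"
    metrics_path.write_text(json.dumps(net_report, indent=2, sort_keys=True))
    net_files.append(metrics_path)
    finish_stage("network", t0, net_files)

    manifest["screen"] = screen
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# plain key-value config files
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "output_dir": str, "input_csv": str, "seed": int, "alpha": float,
    "null_reps": int, "null_mode": str, "degree_convention": str,
    "linkage_method": str, "residualize": bool, "compute_ci": bool,
    "n_restarts": int, "resume": bool,
}


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Parse a ``key = value`` config file into a RunConfig.

    Unknown keys raise; ``spec_json`` points at a serialized simulation
    spec.  Keyword overrides (e.g. from CLI flags) win over file values.
    """
    kwargs: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key == "spec_json":
            kwargs["spec"] = SimulationSpec.from_json(Path(value).read_text())
        elif key in _CONFIG_KEYS:
            typ = _CONFIG_KEYS[key]
            kwargs[key] = (value.lower() in ("1", "true", "yes")
                           if typ is bool else typ(value))
        elif key == "subsets":
            kwargs["subsets"] = tuple(s.strip() for s in value.split(","))
        elif key == "alpha_grid":
            kwargs["alpha_grid"] = tuple(float(s) for s in value.split(","))
        else:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**kwargs)
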