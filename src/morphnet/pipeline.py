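"""End-to-end orchestration: simulate -> build -> metrics -> compare -> nbs -> clinical.

A single RunConfig (YAML or dict) drives all stages; every stochastic stage
derives its RNG stream from the global seed plus a stage tag, so a saved
config replays to identical outputs. Each stage reads only files written by
earlier stages (no hidden in-memory state), and a JSON run report records
per-stage record counts, seeds, and output paths.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import roi_io
from .clinical_analysis import correlation_grid
from .graph_metrics import (GLOBAL_METRICS, NODAL_METRICS, MetricPanel,
                            ThresholdSpec, auc_to_tidy, panel_to_tidy,
                            sweep_metrics)
from .group_inference import (PermutationConfig, fdr_correct,
                              permutation_anova, permutation_pairwise)
from .kls_network import GridSpec, build_network
from .nbs_stats import NbsConfig, nbs_permutation_test
from .synthetic_cohort import (ClinicalModel, CohortSpec, generate_cohort,
                               plant_degree_trs_correlation)

log = logging.getLogger("morphnet")

ALL_STAGES = ("simulate", "build", "metrics", "compare", "nbs", "clinical")

_KNOWN_KEYS = {
    "": {"out_dir", "seed", "stages", "log_level", "cohort", "grid",
         "thresholds", "metrics", "inference", "nbs", "clinical"},
    "cohort": {"group_sizes", "n_rois", "voxels_per_roi", "latent_dim",
               "planted_edges", "planted_global_effect",
               "planted_global_group", "plant_trs"},
    "grid": {"n_points"},
    "thresholds": {"s_min", "s_max", "s_step"},
    "metrics": {"n_nulls"},
    "inference": {"n_perm", "fdr_q", "alpha"},
    "nbs": {"f_threshold", "t_threshold", "n_perm", "use_node_subset"},
    "clinical": {"group", "metric", "nodes", "variables", "covariates"},
}


@dataclass
class RunConfig:
    out_dir: str = "morphnet_run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    log_level: str = "INFO"
    cohort: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    inference: dict = field(default_factory=dict)
    nbs: dict = field(default_factory=dict)
    clinical: dict = field(default_factory=dict)

    def __post_init__(self):
        for stage in self.stages:
            if stage not in ALL_STAGES:
                raise ValueError(f"unknown stage: {stage}")
        for section, keys in _KNOWN_KEYS.items():
            if not section:
                continue
            payload = getattr(self, section)
            unknown = set(payload) - keys
            if unknown:
                raise ValueError(f"unknown key(s) in [{section}]: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        unknown = set(payload) - _KNOWN_KEYS[""]
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)


def _stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence(
        [seed, zlib.crc32(stage.encode())]).generate_state(1)[0])


def _cohort_spec(config: RunConfig) -> CohortSpec:
    payload = {k: v for k, v in config.cohort.items() if k != "plant_trs"}
    if "group_sizes" in payload:
        payload["group_sizes"] = {k: int(v) for k, v in payload["group_sizes"].items()}
    if "voxels_per_roi" in payload:
        payload["voxels_per_roi"] = tuple(payload["voxels_per_roi"])
    if "planted_edges" in payload:
        payload["planted_edges"] = [tuple(e) for e in payload["planted_edges"]]
    return CohortSpec(seed=_stage_seed(config.seed, "simulate"),
                      clinical_model=ClinicalModel(), **payload)


def _grid_spec(config: RunConfig) -> GridSpec:
    return GridSpec(**config.grid)


def _threshold_spec(config: RunConfig) -> ThresholdSpec:
    return ThresholdSpec(**config.thresholds)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, out: Path) -> dict:
    spec = _cohort_spec(config)
    cohort = generate_cohort(spec)
    plant = config.cohort.get("plant_trs")
    if plant:
        cohort = plant_degree_trs_correlation(
            cohort, int(plant["target_roi"]), float(plant["rho"]))
    cohort_dir = out / "cohort"
    cohort_dir.mkdir(parents=True, exist_ok=True)
    for ss in cohort.sample_sets:
        roi_io.write_roi_table(ss, cohort_dir / f"{ss.subject_id}_samples.tsv")
    roi_io.write_cohort_table(cohort.table, out / "cohort.tsv")
    return {"n_subjects": len(cohort.sample_sets), "n_rois": spec.n_rois,
            "seed": spec.seed, "outputs": [str(out / "cohort.tsv"),
                                           str(cohort_dir)]}


def stage_build(config: RunConfig, out: Path) -> dict:
    grid = _grid_spec(config)
    cohort_dir = out / "cohort"
    net_dir = out / "networks"
    net_dir.mkdir(parents=True, exist_ok=True)
    paths = sorted(cohort_dir.glob("*_samples.tsv"))
    if not paths:
        raise FileNotFoundError(f"no sample tables under {cohort_dir}")
    for path in paths:
        ss = roi_io.read_roi_table(path)
        net = build_network(ss, grid)
        roi_io.write_network(net, net_dir / f"{net.subject_id}_network.tsv")
    return {"n_networks": len(paths), "grid_points": grid.n_points,
            "outputs": [str(net_dir)]}


def _sweep_all(config: RunConfig, out: Path) -> list[MetricPanel]:
    tspec = _threshold_spec(config)
    n_nulls = int(config.metrics.get("n_nulls", 100))
    seed = _stage_seed(config.seed, "metrics")
    panels = []
    for path in sorted((out / "networks").glob("*_network.tsv")):
        net = roi_io.read_network(path)
        panels.append(sweep_metrics(net, tspec, n_nulls=n_nulls, seed=seed))
    if not panels:
        raise FileNotFoundError(f"no networks under {out / 'networks'}")
    return panels


def stage_metrics(config: RunConfig, out: Path) -> dict:
    panels = _sweep_all(config, out)
    tidy = pd.concat([panel_to_tidy(p) for p in panels], ignore_index=True)
    tidy.to_csv(out / "panels.tsv", sep="\t", index=False, float_format="%.17g")
    auc = auc_to_tidy(panels)
    auc.to_csv(out / "auc.tsv", sep="\t", index=False, float_format="%.17g")
    return {"n_subjects": len(panels),
            "n_thresholds": int(panels[0].thresholds.size),
            "outputs": [str(out / "panels.tsv"), str(out / "auc.tsv")]}


def _read_auc(path) -> pd.DataFrame:
    auc = pd.read_csv(path, sep="\t", float_precision="round_trip")
    auc["node"] = auc["node"].fillna("")
    return auc


def _auc_by_group(auc: pd.DataFrame, cohort: pd.DataFrame):
    groups = list(dict.fromkeys(cohort["group"]))
    sid_to_group = dict(zip(cohort["subject_id"], cohort["group"]))
    auc = auc.assign(group=auc["subject"].map(sid_to_group))
    return auc, groups


def stage_compare(config: RunConfig, out: Path) -> dict:
    auc = _read_auc(out / "auc.tsv")
    cohort = roi_io.read_cohort_table(out / "cohort.tsv")
    auc, groups = _auc_by_group(auc, cohort)
    pconf = PermutationConfig(n_perm=int(config.inference.get("n_perm", 10_000)),
                              seed=_stage_seed(config.seed, "compare"),
                              fdr_q=float(config.inference.get("fdr_q", 0.05)))

    def by_group(frame):
        return [frame[frame["group"] == g]["auc"].to_numpy() for g in groups]

    global_rows = []
    gl = auc[auc["node"] == ""]
    for metric in GLOBAL_METRICS:
        frame = gl[gl["metric"] == metric]
        if not np.isfinite(frame["auc"]).all():
            # e.g. gamma undefined on degenerate nulls of tiny sparse graphs
            log.warning("metric %s has non-finite AUC values; skipped", metric)
            global_rows.append({"metric": metric, "F": np.nan, "p": np.nan})
            continue
        res = permutation_anova(by_group(frame), pconf, metric=metric)
        row = {"metric": metric, "F": res.statistic, "p": res.p_value}
        for (ga, gb) in [(a, b) for i, a in enumerate(groups)
                         for b in groups[i + 1:]]:
            pair = permutation_pairwise(
                frame[frame["group"] == ga]["auc"].to_numpy(),
                frame[frame["group"] == gb]["auc"].to_numpy(), pconf)
            row[f"t_{ga}_vs_{gb}"] = pair.statistic
            row[f"p_{ga}_vs_{gb}"] = pair.p_value
        global_rows.append(row)
    global_df = pd.DataFrame(global_rows)
    finite = np.isfinite(global_df["p"].to_numpy())
    global_df["p_fdr"] = np.nan
    global_df["significant"] = False
    if finite.any():
        mask, adj = fdr_correct(global_df.loc[finite, "p"].to_numpy(),
                                pconf.fdr_q)
        global_df.loc[finite, "p_fdr"] = adj
        global_df.loc[finite, "significant"] = mask
    global_df.to_csv(out / "stats_global.tsv", sep="\t", index=False,
                     float_format="%.17g")

    nodal_rows = []
    nd = auc[auc["node"] != ""]
    for metric in NODAL_METRICS:
        frame = nd[nd["metric"] == metric]
        nodes = list(dict.fromkeys(frame["node"]))
        pvals, stats_ = [], []
        for node in nodes:
            nf = frame[frame["node"] == node]
            res = permutation_anova(by_group(nf), pconf, metric=f"{metric}:{node}")
            pvals.append(res.p_value)
            stats_.append(res.statistic)
        # FDR within each nodal metric family across the nodes
        mask, adj = fdr_correct(np.asarray(pvals), pconf.fdr_q)
        for node, f, p, pf, sig in zip(nodes, stats_, pvals, adj, mask):
            nodal_rows.append({"metric": metric, "node": node, "F": f,
                               "p": p, "p_fdr": pf, "significant": sig})
    nodal_df = pd.DataFrame(nodal_rows)
    nodal_df.to_csv(out / "stats_nodal.tsv", sep="\t", index=False,
                    float_format="%.17g")
    n_sig = int(nodal_df["significant"].sum()) if len(nodal_df) else 0
    return {"n_global_metrics": len(global_df), "n_nodal_tests": len(nodal_df),
            "n_nodal_significant": n_sig, "seed": pconf.seed,
            "outputs": [str(out / "stats_global.tsv"),
                        str(out / "stats_nodal.tsv")]}


def _load_network_stack(out: Path, cohort: pd.DataFrame):
    nets = {}
    labels = None
    for path in sorted((out / "networks").glob("*_network.tsv")):
        net = roi_io.read_network(path)
        nets[net.subject_id] = net
        labels = net.roi_labels
    order = [s for s in cohort["subject_id"] if s in nets]
    stack = np.stack([nets[s].matrix for s in order])
    groups = cohort.set_index("subject_id").loc[order, "group"].to_numpy()
    return stack, groups, labels


def stage_nbs(config: RunConfig, out: Path) -> dict:
    cohort = roi_io.read_cohort_table(out / "cohort.tsv")
    stack, labels, roi_labels = _load_network_stack(out, cohort)
    node_subset = None
    if config.nbs.get("use_node_subset", True):
        stats_path = out / "stats_nodal.tsv"
        if stats_path.exists():
            nodal = pd.read_csv(stats_path, sep="\t")
            sig_nodes = set(nodal.loc[nodal["significant"], "node"])
            if sig_nodes:
                node_subset = [i for i, lab in enumerate(roi_labels)
                               if lab in sig_nodes]
    conf = NbsConfig(f_threshold=float(config.nbs.get("f_threshold", 4.64)),
                     t_threshold=float(config.nbs.get("t_threshold", 2.64)),
                     n_perm=int(config.nbs.get("n_perm", 10_000)),
                     seed=_stage_seed(config.seed, "nbs"),
                     node_subset=node_subset)
    rows = []
    results = {"anova": nbs_permutation_test(stack, labels, "anova", conf)}
    group_names = list(dict.fromkeys(labels))
    for i, ga in enumerate(group_names):
        for gb in group_names[i + 1:]:
            for tail in ("greater", "less"):
                key = f"{ga}_vs_{gb}_{tail}"
                results[key] = nbs_permutation_test(stack, labels, (ga, gb),
                                                    conf, tail=tail)
    for name, res in results.items():
        for ci, comp in enumerate(res.components):
            for (i, j) in comp.edges:
                rows.append({"contrast": name, "component": ci,
                             "roi_a": roi_labels[i], "roi_b": roi_labels[j],
                             "statistic": res.stat_matrix[i, j],
                             "n_edges": comp.n_edges, "p": comp.p_value})
    comp_df = pd.DataFrame(rows, columns=["contrast", "component", "roi_a",
                                          "roi_b", "statistic", "n_edges",
                                          "p"])
    comp_df.to_csv(out / "nbs_components.tsv", sep="\t", index=False,
                   float_format="%.17g")
    return {"n_contrasts": len(results),
            "n_components": int(sum(len(r.components) for r in results.values())),
            "seed": conf.seed, "outputs": [str(out / "nbs_components.tsv")]}


def stage_clinical(config: RunConfig, out: Path) -> dict:
    auc = _read_auc(out / "auc.tsv")
    cohort = roi_io.read_cohort_table(out / "cohort.tsv")
    group = config.clinical.get("group", "SleET")
    metric = config.clinical.get("metric", "degree")
    variables = list(config.clinical.get("variables",
                                         ["TRS", "PSQI", "onset_age", "duration"]))
    covariates = list(config.clinical.get("covariates",
                                          ["age", "sex", "education", "HAMA",
                                           "HAMD"]))
    sub = cohort[cohort["group"] == group].reset_index(drop=True)
    nd = auc[(auc["node"] != "") & (auc["metric"] == metric)]
    nodes = config.clinical.get("nodes")
    if nodes is None:
        nodes = list(dict.fromkeys(nd["node"]))
    pivot = nd.pivot_table(index="subject", columns="node", values="auc")
    metric_values = {}
    for node in nodes:
        metric_values[f"{metric}:{node}"] = pivot.reindex(
            sub["subject_id"])[node].to_numpy()
    grid = correlation_grid(sub, metric_values, variables, covariates)
    if len(grid):
        split = grid["metric"].str.split(":", n=1, expand=True)
        grid["metric"] = split[0]
        grid.insert(1, "node", split[1])
    else:
        grid.insert(1, "node", pd.Series(dtype=str))
    grid.insert(0, "group", group)
    grid.to_csv(out / "clinical_correlations.tsv", sep="\t", index=False,
                float_format="%.17g")
    return {"n_correlations": len(grid), "group": group,
            "outputs": [str(out / "clinical_correlations.tsv")]}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "build": stage_build,
    "metrics": stage_metrics,
    "compare": stage_compare,
    "nbs": stage_nbs,
    "clinical": stage_clinical,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write a JSON run report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"version": __version__, "seed": config.seed,
              "config": asdict(config), "stages": {}}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        log.info("stage %s starting", stage)
        try:
            report["stages"][stage] = _STAGE_FUNCS[stage](config, out)
        except Exception as exc:
            report["stages"][stage] = {"error": str(exc)}
            roi_io.write_report(report, out / "run_report.json")
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        log.info("stage %s done", stage)
    roi_io.write_report(report, out / "run_report.json")
    return report
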