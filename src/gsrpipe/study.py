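"""End-to-end factorial study runner.

Executes the full design — two drug groups x two states x two
global-signal conditions — from a single seeded configuration:
simulate -> preprocess both GS branches -> fluctuation indices ->
functional connectivity and state contrasts -> cost-thresholded graph
metrics -> paired Bayesian tests, writing every intermediate and summary
table as TSV so any stage can be reproduced from stored artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .parcellation import ParcellationScheme, make_parcellation, GROUP_NAMES
from .simulate import SimulationConfig, simulate_cohort, write_cohort, GROUPS, STATES
from .preprocess import preprocess, GS_CONDITIONS, PreprocessedRecording
from .fluctuation import summarize
from .connectivity import (FCMatrix, network_timeseries, fc_matrix, mean_fc,
                           state_contrast)
from .graphmetrics import (feasible_cost_range, metrics_over_costs,
                           GraphMetricsResult)
from .bayes import jzs_bf_paired

log = logging.getLogger("gsrpipe")

NODAL_METRICS = ("path_length", "clustering", "local_efficiency")
GLOBAL_METRICS = ("global_efficiency", "small_worldness")


@dataclass(frozen=True)
class StudyConfig:
    """All knobs of a study run; serializes losslessly to JSON."""

    simulation: SimulationConfig
    band: tuple[float, float] = (0.01, 0.1)
    n_discard: int = 5
    gs_conditions: tuple[str, ...] = GS_CONDITIONS
    cost_mode: str = "auc"              # "auc" (feasible-range scan) or "fixed"
    costs: tuple[float, ...] = (0.15,)  # used when cost_mode == "fixed"
    cost_step: float = 0.005
    n_rand: int = 100
    swaps_per_edge: int = 10
    cauchy_scale: float = 0.707
    bf_threshold: float = 3.0
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        d = json.loads(Path(path).read_text())
        sim = d.pop("simulation")
        for key in ("n_subjects_per_group", "band"):
            if key in sim:
                sim[key] = tuple(sim[key])
        for key in ("band", "gs_conditions", "costs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(simulation=SimulationConfig(**sim), **d)


@dataclass
class ReportBundle:
    fluctuation: pd.DataFrame
    fluctuation_bf: pd.DataFrame
    fc_contrasts: dict            # (group, gs) -> edge contrast table
    graph_global: pd.DataFrame
    graph_network: pd.DataFrame
    graph_global_bf: pd.DataFrame
    graph_network_bf: pd.DataFrame
    cost_ranges: dict
    out_dir: Path | None


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _paired_bf_table(df: pd.DataFrame, value_col: str, by: list[str],
                     cauchy_scale: float, bf_threshold: float) -> pd.DataFrame:
    """Baseline-vs-unconscious paired JZS tests within each stratum."""
    rows = []
    for keys, sub in df.groupby(by, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        wide = sub.pivot_table(index="subject_id", columns="state",
                               values=value_col)
        if set(STATES) - set(wide.columns) or len(wide) < 3:
            continue
        wide = wide.dropna()
        try:
            res = jzs_bf_paired(wide["baseline"].to_numpy(),
                                wide["unconscious"].to_numpy(),
                                r=cauchy_scale, bf_threshold=bf_threshold)
        except ValueError:
            continue
        rows.append(dict(zip(by, keys)) | {
            "n": res.n, "t": res.t_stat, "bf10": res.bf10,
            "delta_median": res.delta_median,
            "ci_lo": res.ci95[0], "ci_hi": res.ci95[1],
            "significant": res.significant})
    return pd.DataFrame(rows)


def run_study(cfg: StudyConfig, out_dir: str | Path | None = None,
              scheme: ParcellationScheme | None = None) -> ReportBundle:
    """Run every stage for all 8 cells of the design. Fully seeded."""
    t0 = time.time()
    scheme = scheme or make_parcellation()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_json(out / "study_config.json")
        scheme.to_tsv(out / "parcellation.tsv")

    log.info("simulating cohort (seed=%d)", cfg.simulation.seed)
    cohort = simulate_cohort(cfg.simulation, scheme)
    if out is not None:
        write_cohort(cohort, cfg.simulation, out / "cohort")

    # deterministic RNG stream for the graph stage, independent of sim seed
    graph_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))

    pre: dict[tuple, PreprocessedRecording] = {}
    for rec in cohort:
        for gs in cfg.gs_conditions:
            pre[(rec.subject_id, rec.state, gs)] = preprocess(
                rec, gs, f_lo=cfg.band[0], f_hi=cfg.band[1],
                n_discard=cfg.n_discard)
    log.info("preprocessed %d recording x GS cells", len(pre))

    # --- fluctuation indices -------------------------------------------
    fl_rows = []
    for (sid, state, gs), p in pre.items():
        s = summarize(p, *cfg.band)
        for metric, value in (("sd_gm_average", s.sd_gm_average),
                              ("mean_voxel_sd", s.mean_voxel_sd),
                              ("mean_norm_alff", s.mean_norm_alff)):
            fl_rows.append({"subject_id": sid, "group": p.group,
                            "state": state, "gs_condition": gs,
                            "metric": metric, "value": value})
    fluct = pd.DataFrame(fl_rows)
    fluct_bf = _paired_bf_table(fluct, "value",
                                ["group", "gs_condition", "metric"],
                                cfg.cauchy_scale, cfg.bf_threshold)

    # --- functional connectivity ---------------------------------------
    fc_net: dict[tuple, FCMatrix] = {}
    fc_roi: dict[tuple, FCMatrix] = {}
    for key, p in pre.items():
        ts, labels = network_timeseries(p, scheme, "network17")
        fc_net[key] = fc_matrix(ts, labels, "network17")
        ts_r, labels_r = network_timeseries(p, scheme, "roi114")
        fc_roi[key] = fc_matrix(ts_r, labels_r, "roi114")

    contrasts = {}
    for group in GROUPS:
        sids = sorted({r.subject_id for r in cohort if r.group == group})
        for gs in cfg.gs_conditions:
            base = [fc_net[(s, "baseline", gs)] for s in sids]
            unco = [fc_net[(s, "unconscious", gs)] for s in sids]
            contrasts[(group, gs)] = state_contrast(
                base, unco, bf_threshold=cfg.bf_threshold,
                cauchy_scale=cfg.cauchy_scale)
            if out is not None:
                _write(contrasts[(group, gs)],
                       out / f"fc_contrast_{group}_{gs}.tsv")
                mean_fc(base).to_tsv(out / f"fc_mean_{group}_baseline_{gs}.tsv")
                mean_fc(unco).to_tsv(out / f"fc_mean_{group}_unconscious_{gs}.tsv")
    log.info("FC contrasts done (%.1fs)", time.time() - t0)

    # --- graph metrics --------------------------------------------------
    cost_ranges: dict[tuple, tuple[float, float] | None] = {}
    costs_for: dict[tuple, list[float]] = {}
    for group in GROUPS:
        for gs in cfg.gs_conditions:
            if cfg.cost_mode == "fixed":
                costs_for[(group, gs)] = list(cfg.costs)
                cost_ranges[(group, gs)] = (min(cfg.costs), max(cfg.costs))
            else:
                mats = [fc for (sid, st, g), fc in fc_roi.items()
                        if g == gs and sid.startswith(group)]
                rng_scan = np.random.default_rng(
                    np.random.SeedSequence([cfg.seed, 11, GROUPS.index(group),
                                            GS_CONDITIONS.index(gs)]))
                rang = feasible_cost_range(
                    mats, step=cfg.cost_step, n_rand=min(cfg.n_rand, 10),
                    rng=rng_scan, swaps_per_edge=cfg.swaps_per_edge)
                cost_ranges[(group, gs)] = rang
                if rang is None:
                    log.warning("empty feasible cost range for %s/%s; "
                                "falling back to %s", group, gs, cfg.costs)
                    costs_for[(group, gs)] = list(cfg.costs)
                else:
                    costs_for[(group, gs)] = list(
                        np.arange(rang[0], rang[1] + cfg.cost_step / 2,
                                  cfg.cost_step))

    roi_nets = scheme.network_of_roi()
    group_of = scheme.group_of_network()
    roi_group = np.asarray([group_of[n] for n in roi_nets])
    g_rows, n_rows = [], []
    for (sid, state, gs), fc in sorted(fc_roi.items()):
        grp = "drugA" if sid.startswith("drugA") else "drugB"
        res: GraphMetricsResult = metrics_over_costs(
            fc, costs_for[(grp, gs)], n_rand=cfg.n_rand, rng=graph_rng,
            swaps_per_edge=cfg.swaps_per_edge)
        g_rows.append({"subject_id": sid, "group": grp, "state": state,
                       "gs_condition": gs, "L": res.L, "lambda": res.lam,
                       "C": res.C, "gamma": res.gamma, "e_loc": res.e_loc,
                       "global_efficiency": res.e_glob,
                       "small_worldness": res.sw,
                       "disconnected_pair_fraction":
                           res.disconnected_pair_fraction})
        nodal = {"path_length": res.per_node_L,
                 "clustering": res.per_node_C,
                 "local_efficiency": res.per_node_eloc}
        for metric, vec in nodal.items():
            for net_group in GROUP_NAMES:
                vals = np.asarray(vec)[roi_group == net_group]
                n_rows.append({"subject_id": sid, "group": grp,
                               "state": state, "gs_condition": gs,
                               "network": net_group, "metric": metric,
                               "value": float(np.nanmean(vals))})
    graph_global = pd.DataFrame(g_rows)
    graph_network = pd.DataFrame(n_rows)
    log.info("graph metrics done (%.1fs)", time.time() - t0)

    glob_long = graph_global.melt(
        id_vars=["subject_id", "group", "state", "gs_condition"],
        value_vars=["L", "lambda", "C", "gamma", "e_loc",
                    "global_efficiency", "small_worldness"],
        var_name="metric", value_name="value")
    graph_global_bf = _paired_bf_table(
        glob_long, "value", ["group", "gs_condition", "metric"],
        cfg.cauchy_scale, cfg.bf_threshold)
    graph_network_bf = _paired_bf_table(
        graph_network, "value",
        ["group", "gs_condition", "network", "metric"],
        cfg.cauchy_scale, cfg.bf_threshold)

    if out is not None:
        _write(fluct, out / "fluctuation.tsv")
        _write(fluct_bf, out / "fluctuation_bf.tsv")
        _write(graph_global, out / "graph_global.tsv")
        _write(graph_network, out / "graph_network.tsv")
        _write(graph_global_bf, out / "graph_global_bf.tsv")
        _write(graph_network_bf, out / "graph_network_bf.tsv")
        ranges_json = {f"{g}_{gs}": cost_ranges[(g, gs)]
                       for g in GROUPS for gs in cfg.gs_conditions}
        (out / "cost_ranges.json").write_text(json.dumps(ranges_json, indent=2))
    log.info("study complete in %.1fs", time.time() - t0)
    return ReportBundle(
        fluctuation=fluct, fluctuation_bf=fluct_bf, fc_contrasts=contrasts,
        graph_global=graph_global, graph_network=graph_network,
        graph_global_bf=graph_global_bf, graph_network_bf=graph_network_bf,
        cost_ranges=cost_ranges, out_dir=out)
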