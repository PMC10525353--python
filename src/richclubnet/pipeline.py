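"""Full-analysis orchestration: metrics → rich-club → edge classes → stats.

``run_full_analysis`` takes a validated :class:`RunConfig`, runs every stage
on a cohort of connectomes and writes tidy CSV tables plus a JSON run
manifest (config, seeds, library versions).  All randomness is derived from
the master seed via a per-stage/per-subject counter scheme, so results do
not depend on execution order and identical manifests imply identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import edges as edges_mod
from . import metrics as metrics_mod
from . import richclub as rc_mod
from . import stats as stats_mod
from .io import CohortTable, NodeAtlas, load_atlas, read_cohort
from .synthetic import make_synthetic_atlas

logger = logging.getLogger("richclubnet")

__all__ = ["RunConfig", "run_full_analysis", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage (and subject) that failed."""


@dataclasses.dataclass
class RunConfig:
    cohort_csv: str | Path | None = None
    matrix_dir: str | Path | None = None
    atlas: str = "aal90"
    reference_group: str = "CU"
    m: int = 1000
    n_perm: int = 10000
    master_seed: int = 0
    covariates: tuple[str, ...] = ("age", "education")
    family_wise: bool = True
    existence_on: str = "group_mean"  # or "per_subject"
    swap_factor: int = 10
    output_dir: str | Path | None = None
    # stages to run; "stats" needs "edges" (strengths) and, for the global
    # metric comparisons, "metrics"
    stages: tuple[str, ...] = ("metrics", "richclub", "edges", "stats")

    def validate(self, cohort: CohortTable | None = None) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if cohort is not None and (
            self.reference_group not in set(cohort.table["group"])
        ):
            raise ValueError(
                f"reference group {self.reference_group!r} absent from cohort"
            )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # annotate with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("metrics")
def _stage_metrics(cohort: CohortTable) -> pd.DataFrame:
    rows = []
    for sid in cohort.subject_ids:
        g = metrics_mod.compute_global_metrics(cohort.connectomes[sid])
        rows.append({
            "subject_id": sid,
            "strength": g.connectivity_strength,
            "clustering": g.clustering_coefficient,
            "eglob": g.global_efficiency,
            "eloc": g.local_efficiency,
        })
    return pd.DataFrame(rows)


@_stage("richclub")
def _stage_richclub(cohort: CohortTable, cfg: RunConfig, seed: int):
    if cfg.existence_on == "group_mean":
        targets = [rc_mod.average_connectome(
            list(cohort.connectomes.values()), subject_id="cohort_mean")]
    else:
        targets = list(cohort.connectomes.values())
    curve_rows = []
    test_results = {}
    for k, c in enumerate(targets):
        res = rc_mod.rich_club_existence_test(
            c, m=cfg.m, n_perm=cfg.n_perm, seed=seed + k,
            swap_factor=cfg.swap_factor,
        )
        cv = res.curve
        for i, kappa in enumerate(cv.kappa_grid):
            curve_rows.append({
                "subject_id": c.subject_id, "kappa": int(kappa),
                "phi": cv.phi[i], "phi_rand_mean": cv.phi_rand_mean[i],
                "phi_rand_sd": cv.phi_rand_sd[i], "phi_norm": cv.phi_norm[i],
            })
        test_results[c.subject_id] = {
            "observed_auc": res.observed_auc,
            "p_value": res.p_value,
            "p_ttest": res.p_ttest,
            "n_permutations": res.n_permutations,
            "decision": res.decision,
        }
    return pd.DataFrame(curve_rows), test_results


@_stage("edge_classes")
def _stage_edges(cohort: CohortTable, atlas, reference_group: str):
    strength_rows = []
    for sid in cohort.subject_ids:
        c = cohort.connectomes[sid]
        cls = edges_mod.classify_edges(c, atlas)
        s = edges_mod.class_strengths(c, cls, atlas=atlas)
        for lab, val in s.as_dict().items():
            strength_rows.append({
                "subject_id": sid, "region": "whole_brain",
                "class": lab, "strength": val,
            })
        for (region, lab), val in s.region_strengths.items():
            strength_rows.append({
                "subject_id": sid, "region": region,
                "class": lab, "strength": val,
            })
    strengths = pd.DataFrame(strength_rows)

    z_rows = []
    for (region, lab), sub in strengths.groupby(["region", "class"]):
        vals = sub.set_index("subject_id")["strength"]
        zres = edges_mod.zscore_vs_reference(
            vals, cohort, reference_group=reference_group,
            variable=f"{region}:{lab}",
        )
        for sid, z in zres.z.items():
            z_rows.append({
                "subject_id": sid, "region": region, "class": lab,
                "zscore": z, "reference_mean": zres.reference_mean,
                "reference_sd": zres.reference_sd,
            })
    return strengths, pd.DataFrame(z_rows)


@_stage("stats")
def _stage_stats(strengths: pd.DataFrame, metrics: pd.DataFrame | None,
                 cohort: CohortTable, cfg: RunConfig, seed: int):
    table = cohort.table.set_index("subject_id")
    wb = strengths[strengths["region"] == "whole_brain"]
    wide = wb.pivot(index="subject_id", columns="class", values="strength")
    if metrics is not None:
        wide = wide.join(metrics.set_index("subject_id"))
    data_all = table.join(wide).reset_index()
    covs = tuple(cfg.covariates)
    rows, adj_rows = [], []

    def record(res: stats_mod.StatResult, subset: str):
        rows.append({
            "outcome": res.outcome, "term": res.term, "subset": subset,
            "F": res.F_statistic, "eta_p2": res.partial_eta_sq,
            "p_param": res.p_parametric, "p_perm": res.p_permutation,
            "n_perm": res.n_perm,
        })

    class_family = ["rich", "feeder", "local"]
    global_family = ["strength", "clustering", "eglob"]

    # per-group sex effects on class strengths: one figure-panel family of
    # all group × class tests, max-statistic adjusted under stratified
    # (within-group) label permutation
    class_outs = {name: data_all[name] for name in class_family}
    if cfg.family_wise:
        res = stats_mod.groupwise_sex_family(
            class_outs, data_all, covariates=covs,
            n_perm=cfg.n_perm, seed=seed)
        for (group, _name), r in res.items():
            record(r, subset=group)
    else:
        for group, sub in data_all.groupby("group"):
            sub = sub.reset_index(drop=True)
            for name in class_family:
                r = stats_mod.permutation_adjusted_p(
                    sub[name], sub, "sex", covariates=covs,
                    n_perm=cfg.n_perm, seed=seed, outcome_name=name)
                record(r, subset=group)

    # per-group sex effects on global metrics: one family per group
    if metrics is not None:
        for group, sub in data_all.groupby("group"):
            sub = sub.reset_index(drop=True)
            outs = {name: sub[name] for name in global_family}
            if cfg.family_wise:
                res_g = stats_mod.family_maxstat_pvalues(
                    outs, sub, "sex", covariates=covs,
                    n_perm=cfg.n_perm, seed=seed)
            else:
                res_g = {
                    name: stats_mod.permutation_adjusted_p(
                        y, sub, "sex", covariates=covs,
                        n_perm=cfg.n_perm, seed=seed, outcome_name=name)
                    for name, y in outs.items()
                }
            for r in res_g.values():
                record(r, subset=group)

    # whole-cohort: group, sex and group-by-sex per class outcome
    for name in class_family:
        y = data_all[name]
        for term in ("group", "sex"):
            r = stats_mod.permutation_adjusted_p(
                y, data_all, term, covariates=covs,
                factors=("group", "sex"), n_perm=cfg.n_perm, seed=seed,
                outcome_name=name)
            record(r, subset="all")
        r = stats_mod.interaction_test(
            y, data_all, covariates=covs, n_perm=cfg.n_perm, seed=seed,
            outcome_name=name)
        record(r, subset="all")
        adj = stats_mod.glm_term_test(
            y, data_all, "group:sex", covariates=covs,
            outcome_name=name).adjusted_means
        adj.insert(0, "outcome", name)
        adj_rows.append(adj)

    return pd.DataFrame(rows), pd.concat(adj_rows, ignore_index=True)


def _resolve_atlas(spec) -> NodeAtlas:
    """Atlas from a NodeAtlas, a builtin/user spec, or ``synthetic:<n>:<k>``
    (the generator's generic bilateral atlas with n nodes, k rich)."""
    if isinstance(spec, NodeAtlas):
        return spec
    if isinstance(spec, str) and spec.startswith("synthetic:"):
        _, n, k = spec.split(":")
        return make_synthetic_atlas(int(n), int(k))
    return load_atlas(spec)


def run_full_analysis(
    cfg: RunConfig,
    cohort: CohortTable | None = None,
) -> dict:
    """Run every stage and return (and optionally write) the result bundle.

    Either pass an in-memory ``cohort`` or set ``cfg.cohort_csv`` /
    ``cfg.matrix_dir``.  Returns a dict with metrics, curves, rich-club test
    results, strengths, z-scores, stats, adjusted means and the manifest.
    """
    atlas = _resolve_atlas(cfg.atlas)
    if cohort is None:
        if cfg.cohort_csv is None:
            raise ValueError("need a cohort (in memory or via cohort_csv)")
        cohort = read_cohort(cfg.cohort_csv, cfg.matrix_dir, atlas=atlas)
    cfg.validate(cohort)
    ss = np.random.SeedSequence(cfg.master_seed)
    stage_seeds = ss.generate_state(4) % (2**31 - 1)

    metrics = (_stage_metrics(cohort) if "metrics" in cfg.stages else None)
    if "richclub" in cfg.stages:
        curves, rc_tests = _stage_richclub(cohort, cfg, int(stage_seeds[0]))
    else:
        curves, rc_tests = pd.DataFrame(), {}
    if "edges" in cfg.stages:
        strengths, zscores = _stage_edges(cohort, atlas, cfg.reference_group)
    else:
        strengths = zscores = pd.DataFrame()
    if "stats" in cfg.stages:
        if strengths.empty:
            raise PipelineError("stage 'stats' requires stage 'edges'")
        stats_table, adjusted_means = _stage_stats(
            strengths, metrics, cohort, cfg, int(stage_seeds[1]))
    else:
        stats_table = adjusted_means = pd.DataFrame()

    import networkx
    import scipy
    manifest = {
        # output_dir is a location, not an analysis parameter: identical
        # manifests must imply identical result tables
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(cfg).items()
            if k != "output_dir"
        },
        "stage_seeds": [int(s) for s in stage_seeds],
        "n_subjects": len(cohort),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "networkx": networkx.__version__,
        },
    }
    bundle = {
        "metrics": metrics if metrics is not None else pd.DataFrame(),
        "curves": curves,
        "richclub_tests": rc_tests,
        "strengths": strengths,
        "zscores": zscores,
        "stats": stats_table,
        "adjusted_means": adjusted_means,
        "manifest": manifest,
    }
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("metrics", "curves", "strengths", "zscores", "stats",
                     "adjusted_means"):
            bundle[name].to_csv(out / f"{name}.csv", index=False)
        (out / "richclub_tests.json").write_text(
            json.dumps(rc_tests, indent=2))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle
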