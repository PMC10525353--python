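"""Synthetic cohorts of weighted connectomes with planted effects.

The generator emulates the statistical structure of a clinical structural
connectome cohort so every pipeline stage is testable without imaging data:

* a core–periphery **template** network over the atlas: edges between
  rich-club nodes are dense and strong, feeder edges intermediate, local
  edges sparse and weak — so the template genuinely exhibits rich-club
  organization;
* **subjects** as the template with multiplicative (mean-1 log-normal) edge
  noise — weights stay positive and the sparsity pattern is preserved — and
  multiplicative (group, sex, edge-class) effect factors, the level at
  which the clinical findings live (e.g. a women-only deficit in rich-club
  and feeder strength in the dementia cell);
* **covariates** correlated with the design: age ~ Normal(μ_group, σ) and
  education ~ Normal(μ_sex, σ) with a male–female education gap;
* **cognition** linearly coupled to total connectivity plus group base
  levels and noise, clamped to valid ranges (K-MMSE to [0, 30], CDR sum of
  boxes to ≥ 0).

Default cell sizes, noise level and planted-effect magnitudes are the study
conditions used throughout the test-suite calibrations.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .edges import classify_edges
from .io import (
    GROUPS,
    SEXES,
    CohortTable,
    NodeAtlas,
    WeightedConnectome,
    load_atlas,
    make_atlas,
    make_connectome,
    write_connectome,
)

__all__ = [
    "SyntheticConfig",
    "fig_pattern_effects",
    "make_synthetic_atlas",
    "build_template",
    "simulate_subject",
    "simulate_cohort",
]

EdgeClassEffects = dict[tuple[str, str, str], float]  # (group, sex, class) -> x


def fig_pattern_effects() -> EdgeClassEffects:
    """The planted sex-by-group pattern used in recovery tests: a women-only
    0.8× deficit on rich and feeder strengths in the AD-dementia cell and a
    0.85× deficit on local strength in both sexes of that cell."""
    return {
        ("ADdementia", "F", "rich"): 0.8,
        ("ADdementia", "F", "feeder"): 0.8,
        ("ADdementia", "F", "local"): 0.85,
        ("ADdementia", "M", "local"): 0.85,
    }


@dataclasses.dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort generator (defaults = the study
    conditions used by the calibration and recovery suites)."""

    n_per_cell: int = 60
    n_nodes: int = 90
    n_rich: int = 12
    # template edge probabilities and weight scales per class
    p_rich: float = 0.9
    p_feeder: float = 0.4
    p_local: float = 0.15
    w_rich: float = 0.6
    w_feeder: float = 0.3
    w_local: float = 0.15
    template_weight_cv: float = 0.25  # log-SD of template weight dispersion
    noise_sd: float = 0.2  # log-SD of subject-level multiplicative noise
    effects: EdgeClassEffects = dataclasses.field(default_factory=dict)
    # covariates: age by group, education by sex (years)
    age_mean: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"CU": 69.4, "prodromalAD": 71.7,
                                 "ADdementia": 69.6})
    age_sd: float = 8.0
    education_mean: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"F": 10.3, "M": 13.7})
    education_sd: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"F": 4.7, "M": 4.0})
    # cognition: score = base(group) + coupling*(total/template_total) +
    #            beta_age*(age-70) + Normal(0, noise); clamped to range
    kmmse_base: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"CU": 25.0, "prodromalAD": 21.5,
                                 "ADdementia": 15.0})
    kmmse_coupling: float = 3.5
    kmmse_beta_age: float = -0.05
    kmmse_noise: float = 1.8
    cdr_base: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"CU": 2.1, "prodromalAD": 3.6,
                                 "ADdementia": 8.0})
    cdr_coupling: float = -1.5
    cdr_beta_age: float = 0.0
    cdr_noise: float = 1.2
    master_seed: int = 0

    def validate(self) -> None:
        for p in (self.p_rich, self.p_feeder, self.p_local):
            if not 0 <= p <= 1:
                raise ValueError("edge probabilities must lie in [0, 1]")
        for s in (self.w_rich, self.w_feeder, self.w_local):
            if s <= 0:
                raise ValueError("weight scales must be positive")
        if any(f <= 0 for f in self.effects.values()):
            raise ValueError("effect factors must be positive")
        if self.n_rich < 1 or self.n_rich >= self.n_nodes:
            raise ValueError("need 1 <= n_rich < n_nodes")

    def atlas(self) -> NodeAtlas:
        if self.n_nodes == 90 and self.n_rich == 12:
            return load_atlas("aal90")
        return make_synthetic_atlas(self.n_nodes, self.n_rich)


def make_synthetic_atlas(n_nodes: int, n_rich: int) -> NodeAtlas:
    """Generic bilateral atlas for non-default sizes: regions R00, R01, ...
    each with a left and right node; the first ``n_rich`` nodes flagged."""
    if n_nodes % 2:
        raise ValueError("synthetic atlas needs an even node count")
    node_ids, regions, hemis = [], [], []
    for r in range(n_nodes // 2):
        for hemi, suf in (("left", "L"), ("right", "R")):
            node_ids.append(f"R{r:02d}_{suf}")
            regions.append(f"R{r:02d}")
            hemis.append(hemi)
    flags = [i < n_rich for i in range(n_nodes)]
    return make_atlas(node_ids, regions, hemis, flags)


def _expected_degree(cfg: SyntheticConfig) -> float:
    nr, nl = cfg.n_rich, cfg.n_nodes - cfg.n_rich
    # periphery node: feeder edges to the core + local edges
    return nr * cfg.p_feeder + (nl - 1) * cfg.p_local


def build_template(cfg: SyntheticConfig, seed: int | None = None,
                   atlas: NodeAtlas | None = None) -> WeightedConnectome:
    """Core–periphery weighted template network.

    Edge presence is Bernoulli per class probability; weights are the class
    scale times a log-normal dispersion factor.  Regenerated (up to 100
    attempts) until connected.
    """
    cfg.validate()
    if _expected_degree(cfg) < 1.0:
        raise ValueError("infeasible config: expected periphery degree < 1")
    if atlas is None:
        atlas = cfg.atlas()
    rng = np.random.default_rng(
        cfg.master_seed if seed is None else seed)
    flags = atlas.rich_club_flags
    n = cfg.n_nodes
    n_ends = flags[:, None].astype(int) + flags[None, :].astype(int)
    p = np.choose(n_ends, [cfg.p_local, cfg.p_feeder, cfg.p_rich])
    scale = np.choose(n_ends, [cfg.w_local, cfg.w_feeder, cfg.w_rich])
    triu = np.triu(np.ones((n, n), dtype=bool), 1)
    for _ in range(100):
        present = (rng.random((n, n)) < p) & triu
        disp = rng.lognormal(
            -cfg.template_weight_cv**2 / 2, cfg.template_weight_cv, (n, n))
        w = np.where(present, scale * disp, 0.0)
        w = w + w.T
        ncomp, _ = connected_components(csr_matrix(w > 0), directed=False)
        if ncomp == 1:
            return make_connectome(w, node_ids=atlas.node_ids,
                                   subject_id="template")
    raise RuntimeError("could not generate a connected template in 100 tries")


def _edge_class_factor_matrix(
    template: WeightedConnectome, atlas: NodeAtlas,
    group: str, sex: str, effects: EdgeClassEffects,
) -> np.ndarray:
    cls = classify_edges(template, atlas)
    fac = np.ones(template.weights.shape)
    for lab in ("rich", "feeder", "local"):
        f = effects.get((group, sex, lab), 1.0)
        if f != 1.0:
            sel = cls.labels == lab
            i, j = cls.edge_i[sel], cls.edge_j[sel]
            fac[i, j] = f
            fac[j, i] = f
    return fac


def simulate_subject(
    template: WeightedConnectome,
    group: str,
    sex: str,
    cfg: SyntheticConfig,
    seed: int,
    atlas: NodeAtlas | None = None,
    subject_id: str | None = None,
) -> WeightedConnectome:
    """One subject: template × class effect factor × mean-1 log-normal noise.

    The noise factor is exp(Normal(−σ²/2, σ)), so E[weight] is exactly the
    effect factor times the template weight; the sparsity pattern is
    preserved.
    """
    if atlas is None:
        atlas = cfg.atlas()
    rng = np.random.default_rng(seed)
    fac = _edge_class_factor_matrix(template, atlas, group, sex, cfg.effects)
    n = template.n_nodes
    noise = rng.lognormal(-cfg.noise_sd**2 / 2, cfg.noise_sd, (n, n))
    noise = np.triu(noise, 1)
    noise = noise + noise.T
    if cfg.noise_sd == 0:
        noise = np.ones((n, n))
    w = template.weights * fac * noise
    return make_connectome(
        w, node_ids=template.node_ids,
        subject_id=subject_id or f"{group}_{sex}_{seed}",
    )


def _clamp(x: float, lo: float, hi: float) -> float:
    return float(min(max(x, lo), hi))


def simulate_cohort(
    cfg: SyntheticConfig,
    out_dir: str | Path | None = None,
) -> CohortTable:
    """Full synthetic cohort: ``n_per_cell`` subjects per group×sex cell.

    Returns an in-memory :class:`CohortTable`; if ``out_dir`` is given the
    matrices, metadata CSV and a ``truth.json`` sidecar (planted effects,
    config, seeds) are also written in exactly the formats the readers
    ingest.  Per-subject seeds are spawned from ``cfg.master_seed`` so
    results are independent of generation order.
    """
    cfg.validate()
    atlas = cfg.atlas()
    ss = np.random.SeedSequence(cfg.master_seed)
    n_cells = len(GROUPS) * len(SEXES)
    n_subj = n_cells * cfg.n_per_cell
    seeds = ss.generate_state(2 + 2 * n_subj) % (2**31 - 1)
    template = build_template(cfg, seed=int(seeds[0]), atlas=atlas)
    template_total = template.total_weight()

    rows = []
    connectomes: dict[str, WeightedConnectome] = {}
    k = 0
    for group in GROUPS:
        for sex in SEXES:
            for i in range(cfg.n_per_cell):
                sid = f"sub-{group}-{sex}-{i:03d}"
                c = simulate_subject(
                    template, group, sex, cfg, int(seeds[2 + k]),
                    atlas=atlas, subject_id=sid,
                )
                rng = np.random.default_rng(int(seeds[2 + n_subj + k]))
                age = float(rng.normal(cfg.age_mean[group], cfg.age_sd))
                edu = max(
                    0.0,
                    float(rng.normal(cfg.education_mean[sex],
                                     cfg.education_sd[sex])),
                )
                rel = c.total_weight() / template_total
                kmmse = _clamp(
                    cfg.kmmse_base[group] + cfg.kmmse_coupling * rel
                    + cfg.kmmse_beta_age * (age - 70.0)
                    + rng.normal(0, cfg.kmmse_noise), 0, 30)
                cdr = max(
                    0.0,
                    cfg.cdr_base[group] + cfg.cdr_coupling * rel
                    + cfg.cdr_beta_age * (age - 70.0)
                    + rng.normal(0, cfg.cdr_noise))
                rows.append({
                    "subject_id": sid, "group": group, "sex": sex,
                    "age": age, "education": edu,
                    "kmmse": int(round(kmmse)), "cdr_sob": cdr,
                    "connectome_path": f"{sid}.csv",
                })
                connectomes[sid] = c
                k += 1
    table = pd.DataFrame(rows)
    cohort = CohortTable(table=table, connectomes=connectomes)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sid, c in connectomes.items():
            write_connectome(c, out_dir / f"{sid}.csv")
        table.to_csv(out_dir / "cohort.csv", index=False)
        truth = {
            "effects": {"|".join(key): val
                        for key, val in cfg.effects.items()},
            "config": {
                f.name: getattr(cfg, f.name)
                for f in dataclasses.fields(cfg)
                if f.name != "effects"
            },
            "template_seed": int(seeds[0]),
        }
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    return cohort
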