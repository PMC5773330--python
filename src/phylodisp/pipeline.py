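"""Run the full design grid: scales x size classes x metrics x bases.

`run_all` drives one complete study from a :class:`RunConfig`: generate or
load the inputs, prepare traits and dendrograms, compute per-cell SES of
phylogenetic and trait dispersion at every requested scale and size class,
test phylogenetic signal at pool and community level, build the dbMEM and
polynomial-environment predictor matrices, and partition the variance of
trait dispersion against phylogenetic dispersion with and without the
environment/space control.  All randomness derives from one master seed via
fixed per-stage streams, so a config run twice writes byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dispersion import (CommunityTable, build_communities, classify_pattern,
                         ses_table)
from .signal import community_signal, compare_signal_by_pattern, k_test
from .spatial_env import dbmem, env_expand
from .synthetic import ScenarioConfig, generate_scenario
from .trait_space import build_dendrogram, pca_reduce, prepare_traits
from .tree_ops import read_tree
from .varpart import forward_select, global_test, partition

log = logging.getLogger("phylodisp")

__all__ = ["RunConfig", "RunResult", "run_all", "scale_comparison"]

_STAGE_DISPERSION = 10
_STAGE_SIGNAL_POOL = 20
_STAGE_SIGNAL_COMM = 21
_STAGE_VARPART = 30


def _stage_seed(master: int, *codes: int) -> int:
    ss = np.random.SeedSequence([int(master), *codes])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either `scenario` (a synthetic study) or the four input paths must be
    given.  `scales` must divide the plot side exactly.  `n_null` is the
    number of taxa-shuffle null communities per cell; `n_perm` the number of
    permutations for signal and variation-partitioning tests (9999 is the
    faithful default for publication-grade runs; smaller values keep
    exploratory runs fast).
    """

    scenario: ScenarioConfig | None = None
    tree_path: str | None = None
    stems_path: str | None = None
    traits_path: str | None = None
    env_path: str | None = None
    plot_size: float = 300.0
    env_cell: float = 20.0
    scales: tuple[float, ...] = (10.0, 20.0, 30.0, 50.0)
    size_classes: tuple[str, ...] = ("small", "medium", "large", "all")
    metrics: tuple[str, ...] = ("mpd", "mntd")
    per_trait_bases: bool = False
    log_traits: object = None          # None | "all" | list of columns
    variance_target: float = 0.90
    n_components: int | None = None
    n_null: int = 999
    n_perm: int = 999
    alpha: float = 0.05
    signal_scale: float = 20.0
    signal_traits: tuple[str, ...] | None = None
    min_taxa: int = 4
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        for s in self.scales:
            k = self.plot_size / s
            if abs(k - round(k)) > 1e-9:
                raise ValueError(f"scale {s} does not divide plot side "
                                 f"{self.plot_size}")
        if self.scenario is None and not all(
                (self.tree_path, self.stems_path, self.traits_path)):
            raise ValueError("give either a scenario or input paths")


@dataclass
class RunResult:
    """All tables produced by one run (also written as CSVs when
    `cfg.outdir` is set)."""

    config: RunConfig
    dispersion: pd.DataFrame
    signal_pool: pd.DataFrame
    signal_community: pd.DataFrame
    signal_comparison: pd.DataFrame
    varpart: pd.DataFrame
    manifest: dict = field(repr=False)


def _load_inputs(cfg: RunConfig):
    if cfg.scenario is not None:
        sc = generate_scenario(cfg.scenario)
        return sc.tree, sc.stems, sc.traits, sc.env, cfg.scenario.plot_size, \
            cfg.scenario.env_cell
    tree = read_tree(cfg.tree_path)
    stems = pd.read_csv(cfg.stems_path)
    traits = pd.read_csv(cfg.traits_path, index_col=0)
    env = pd.read_csv(cfg.env_path, index_col=0) if cfg.env_path else None
    return tree, stems, traits, env, cfg.plot_size, cfg.env_cell


def aggregate_env(env: pd.DataFrame, env_cell: float, scale: float,
                  plot_size: float) -> pd.DataFrame:
    """Environmental values on the `scale` grid.

    For scales at or above the native environmental grid, each target cell
    averages the fine cells whose centres fall inside it; for finer scales
    every target cell inherits the value of the containing native cell.
    Aspect is averaged as a circular quantity via its sine and cosine.
    """
    n = int(round(plot_size / scale))
    ids = [f"{i}_{j}" for i in range(n) for j in range(n)]
    ci = (np.floor(env["y"].to_numpy() / scale).astype(int) * n
          + np.floor(env["x"].to_numpy() / scale).astype(int))
    vals = env.drop(columns=["x", "y"])
    if scale >= env_cell:
        work = vals.copy()
        if "aspect" in work.columns:
            rad = np.deg2rad(work.pop("aspect").to_numpy(float))
            work["_asp_sin"] = np.sin(rad)
            work["_asp_cos"] = np.cos(rad)
        agg = work.groupby(ci).mean()
        agg = agg.reindex(np.arange(n * n))
        if "_asp_sin" in agg.columns:
            asp = np.rad2deg(np.arctan2(agg.pop("_asp_sin"),
                                        agg.pop("_asp_cos")))
            agg["aspect"] = np.mod(asp, 360.0)
    else:
        fine_n = int(round(plot_size / env_cell))
        rows = []
        for i in range(n):
            for j in range(n):
                cx, cy = (j + 0.5) * scale, (i + 0.5) * scale
                fi = int(cy // env_cell) * fine_n + int(cx // env_cell)
                rows.append(vals.iloc[fi])
        agg = pd.DataFrame(rows).reset_index(drop=True)
    agg.index = pd.Index(ids, name="cell_id")
    centers = [( (j + 0.5) * scale, (i + 0.5) * scale)
               for i in range(n) for j in range(n)]
    agg.insert(0, "x", [c[0] for c in centers])
    agg.insert(1, "y", [c[1] for c in centers])
    return agg


def run_all(cfg: RunConfig) -> RunResult:
    """Execute the full pipeline; see module docstring."""
    tree, stems, traits, env, plot_size, env_cell = _load_inputs(cfg)
    prepared = prepare_traits(traits, log_columns=cfg.log_traits)
    red = pca_reduce(prepared, variance_target=cfg.variance_target,
                     n_components=cfg.n_components)
    log.info("PCA retained %d components (%.1f%% of variance)",
             red.n_components, 100 * red.cumulative_variance)
    phylo_dist = tree.cophenetic()
    bases = {"phylogeny": phylo_dist,
             "trait_all": build_dendrogram(red.scores).cophenetic}
    if cfg.per_trait_bases:
        for t in prepared.columns:
            bases[f"trait_{t}"] = build_dendrogram(prepared[t]).cophenetic

    # --- dispersion over the design grid -----------------------------------
    disp_rows = []
    communities: dict[tuple[float, str], CommunityTable] = {}
    for si, scale in enumerate(cfg.scales):
        for ci, size_class in enumerate(cfg.size_classes):
            comm = build_communities(stems, scale, size_class, plot_size)
            communities[(scale, size_class)] = comm
            for basis, dist in bases.items():
                for metric in cfg.metrics:
                    seed = _stage_seed(cfg.seed, _STAGE_DISPERSION, si, ci)
                    tab = ses_table(comm, dist, metric, cfg.n_null,
                                    seed=seed, basis=basis)
                    tab = tab.reset_index()
                    tab.insert(0, "scale", scale)
                    tab.insert(1, "size_class", size_class)
                    disp_rows.append(tab)
    dispersion = pd.concat(disp_rows, ignore_index=True)

    # --- phylogenetic signal ----------------------------------------------
    signal_traits = cfg.signal_traits or tuple(prepared.columns)
    pool_rows = []
    for ti, t in enumerate(signal_traits):
        r = k_test(tree, prepared[t], n_perm=cfg.n_perm,
                   seed=_stage_seed(cfg.seed, _STAGE_SIGNAL_POOL, ti), trait=t)
        pool_rows.append((t, "pool", r.n_taxa, r.K, r.p, r.n_perm))
    signal_pool = pd.DataFrame(pool_rows, columns=[
        "trait", "level", "n_taxa", "K", "p", "n_perm"])

    comm_rows, cmp_rows = [], []
    for ci, size_class in enumerate(cfg.size_classes):
        comm = communities.get((cfg.signal_scale, size_class))
        if comm is None:
            comm = build_communities(stems, cfg.signal_scale, size_class,
                                     plot_size)
        pat_src = dispersion[(dispersion["scale"] == cfg.signal_scale)
                             & (dispersion["size_class"] == size_class)
                             & (dispersion["metric"] == "mpd")
                             & (dispersion["basis"] == "phylogeny")]
        patterns = pat_src.set_index("cell_id")["ses"].map(classify_pattern)
        for ti, t in enumerate(signal_traits):
            sig = community_signal(
                tree, prepared[t], comm, min_taxa=cfg.min_taxa,
                n_perm=cfg.n_perm,
                seed=_stage_seed(cfg.seed, _STAGE_SIGNAL_COMM, ci, ti),
                trait=t)
            sig = sig.reset_index()
            sig.insert(0, "scale", cfg.signal_scale)
            sig.insert(1, "size_class", size_class)
            comm_rows.append(sig)
            try:
                c = compare_signal_by_pattern(sig.set_index("cell_id"),
                                              patterns)
                cmp_rows.append((cfg.signal_scale, size_class, t,
                                 c.mean_clustered, c.mean_overdispersed,
                                 c.n_clustered, c.n_overdispersed, c.t, c.p))
            except ValueError:
                cmp_rows.append((cfg.signal_scale, size_class, t,
                                 np.nan, np.nan, 0, 0, np.nan, np.nan))
    signal_community = pd.concat(comm_rows, ignore_index=True) if comm_rows \
        else pd.DataFrame()
    signal_comparison = pd.DataFrame(cmp_rows, columns=[
        "scale", "size_class", "trait", "mean_K_clustered",
        "mean_K_overdispersed", "n_clustered", "n_overdispersed", "t", "p"])

    # --- spatial / environmental control and variation partitioning --------
    vp_rows = []
    for si, scale in enumerate(cfg.scales):
        n_side = int(round(plot_size / scale))
        mem = dbmem(communities[(scale, cfg.size_classes[0])]
                    .grid.cell_centers(),
                    cell_ids=[f"{i}_{j}" for i in range(n_side)
                              for j in range(n_side)])
        mem_df = mem.to_dataframe()
        env_df = None
        if env is not None:
            env_scale = aggregate_env(env, env_cell, scale, plot_size)
            env_df = env_expand(env_scale)
        for ci, size_class in enumerate(cfg.size_classes):
            sub = dispersion[(dispersion["scale"] == scale)
                             & (dispersion["size_class"] == size_class)]
            for mi, metric in enumerate(cfg.metrics):
                phylo = sub[(sub["metric"] == metric)
                            & (sub["basis"] == "phylogeny")] \
                    .set_index("cell_id")["ses"]
                trait_ses = sub[(sub["metric"] == metric)
                                & (sub["basis"] == "trait_all")] \
                    .set_index("cell_id")["ses"]
                ok = phylo.notna() & trait_ses.notna()
                n_ok = int(ok.sum())
                dropped = len(ok) - n_ok
                if dropped:
                    log.info("%gm/%s/%s: dropping %d cells with undefined SES",
                             scale, size_class, metric, dropped)
                seed = _stage_seed(cfg.seed, _STAGE_VARPART, si, ci, mi)
                rows = _varpart_rows(trait_ses[ok], phylo[ok],
                                     mem_df.loc[ok[ok].index],
                                     env_df.loc[ok[ok].index]
                                     if env_df is not None else None,
                                     cfg, seed)
                for adj_label, vals in rows:
                    vp_rows.append((scale, size_class, metric, adj_label,
                                    *vals, n_ok))
    varpart_df = pd.DataFrame(vp_rows, columns=[
        "scale", "size_class", "metric", "adjustment", "adj_r2", "p",
        "n_selected", "n_cells"])

    cfg_json = _jsonable(cfg)
    cfg_json.pop("outdir", None)   # manifests of identical analyses match
    manifest = {
        "package": "phylodisp",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg_json,
    }
    result = RunResult(cfg, dispersion, signal_pool, signal_community,
                       signal_comparison, varpart_df, manifest)
    if cfg.outdir:
        _write(result, Path(cfg.outdir))
    return result


def _varpart_rows(y: pd.Series, phylo: pd.Series, mem: pd.DataFrame,
                  envp: pd.DataFrame | None, cfg: RunConfig, seed: int):
    """The three reported adjustments for one (scale, size class, metric).

    * Phylo — marginal adjusted R2 of trait SES on phylogenetic SES alone.
    * -S    — pure phylogenetic fraction after forward-selected space.
    * -ES   — pure fraction after jointly forward-selected environment+space.
    When the marginal relationship is nonsignificant the partition cannot be
    interpreted and all values are reported as NaN (the "NA" rule).
    """
    yv = y.to_numpy(float)
    x2 = phylo.to_numpy(float)[:, None]
    out = []
    if len(yv) < 10 or np.var(yv) == 0 or np.var(x2) == 0:
        return [(lbl, (np.nan, np.nan, 0)) for lbl in ("Phylo", "-S", "-ES")]
    from .varpart import adj_r2
    _, p_marg = global_test(yv, x2, n_perm=cfg.n_perm, seed=seed)
    if p_marg > cfg.alpha:
        return [(lbl, (np.nan, np.nan, 0)) for lbl in ("Phylo", "-S", "-ES")]
    out.append(("Phylo", (adj_r2(yv, x2), p_marg, 0)))
    for lbl, cand in (("-S", mem),
                      ("-ES", pd.concat([envp, mem], axis=1)
                       if envp is not None else None)):
        if cand is None:
            out.append((lbl, (np.nan, np.nan, 0)))
            continue
        fs = forward_select(yv, cand, alpha=cfg.alpha, n_perm=cfg.n_perm,
                            seed=seed + 1)
        x1 = cand[fs.selected] if fs.selected else None
        vp = partition(yv, x1, x2, n_perm=cfg.n_perm, seed=seed + 2,
                       x1_label=lbl)
        out.append((lbl, (vp.c, vp.p_pure_x2, len(fs.selected))))
    return out


def scale_comparison(varpart_df: pd.DataFrame) -> pd.DataFrame:
    """Pivot partition results into a size-class x adjustment by
    scale x metric table (the layout used to read scale effects)."""
    return varpart_df.pivot_table(
        index=["size_class", "adjustment"], columns=["scale", "metric"],
        values="adj_r2", sort=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _write(res: RunResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    res.dispersion.to_csv(out / "dispersion.csv", index=False)
    res.signal_pool.to_csv(out / "signal_pool.csv", index=False)
    res.signal_community.to_csv(out / "signal_community.csv", index=False)
    res.signal_comparison.to_csv(out / "signal_comparison.csv", index=False)
    res.varpart.to_csv(out / "varpart.csv", index=False)
    scale_comparison(res.varpart).to_csv(out / "varpart_by_scale.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(res.manifest, fh, indent=2, sort_keys=True)
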