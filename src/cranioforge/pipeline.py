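"""End-to-end orchestration of the craniodental ecomorphology analysis.

``run_all`` executes the full analysis sequence on a conforming dataset:

1. bite force — Zi, calibrated log10 force, BFQ residuals; ANCOVA with sex;
   post-hoc pairwise contrasts; admixture regression over hybrids;
2. sutures — length ratios, per-suture ANCOVA, PCA of the five LRs with
   ANCOVAs on PC1/PC2 scores, admixture regressions;
3. geometric morphometrics — GPA with bending-energy sliding, PCA with the
   Monte Carlo axis test, Procrustes ANOVA (group, sex, size and the size
   interactions), centroid-size ANOVA, pairwise shape contrasts;
4. morphospace overlap — posterior overlap of (PC1, PC2, log10 centroid
   size) for all ordered group pairs.

One global seed is expanded into fixed per-stage substreams so that toggling
a stage off does not shift any other stage's draws.  Every output file is
listed in a JSON manifest with the parameters and seeds that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .biteforce import calibrate_bite_force, compute_bfq, compute_zi
from .datatypes import CalibrationParams, Group
from .gpa import GeneralizedProcrustes
from .group_stats import (
    AncovaSpec,
    ancova,
    hybrid_q_summary,
    posthoc_pairs,
    regress_on_admixture,
)
from .io import incisor_measurements, read_specimen_table, read_suture_traces, read_tps
from .overlap import overlap_matrix
from .shape_stats import (
    ShapePCA,
    pairwise_groups,
    pairwise_to_frame,
    procrustes_anova,
)
from .suture import assemble_lr_matrix

logger = logging.getLogger(__name__)

# fixed substream indices: disabling one stage must not shift another
_STAGE_STREAMS = {"gmm": 0, "overlap": 1, "pairwise": 2, "axis": 3}


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    specimen_csv: Path
    suture_csv: Optional[Path] = None
    landmarks_tps: Optional[Path] = None
    out_dir: Path = Path("cranioforge_out")
    seed: int = 0
    n_perm: int = 999
    n_posterior: int = 3000
    n_mc: int = 10_000
    alpha: float = 0.95
    n_slide_cycles: int = 3
    posthoc_adjust: str = "holm"
    run_biteforce: bool = True
    run_suture: bool = True
    run_gmm: bool = True
    run_overlap: bool = True


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(seed).spawn(len(_STAGE_STREAMS))
    return int(ss[_STAGE_STREAMS[stage]].generate_state(1)[0] % (2**31))


def run_all(cfg: RunConfig) -> dict:
    """Run the configured stages; returns the manifest dict (also written)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in dataclasses.asdict(cfg).items()},
        "outputs": {},
    }

    records, spec_df = read_specimen_table(cfg.specimen_csv)
    table = spec_df.copy()
    results: dict = {"specimens": table}

    if cfg.run_biteforce:
        _stage_biteforce(cfg, table, out, manifest, results)
    if cfg.run_suture and cfg.suture_csv:
        _stage_suture(cfg, table, out, manifest, results)
    if cfg.run_gmm and cfg.landmarks_tps:
        _stage_gmm(cfg, table, out, manifest, results)
    if cfg.run_overlap and "shape_pca_scores" in results:
        _stage_overlap(cfg, out, manifest, results)

    # admixture summary over hybrids
    hyb = table[table["group"] == Group.HYBRID.value]
    if len(hyb) > 1 and hyb["admixture_q"].notna().any():
        manifest["hybrid_q"] = hybrid_q_summary(hyb["admixture_q"].to_numpy())

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    results["manifest"] = manifest
    return results


def _record(manifest: dict, out: Path, name: str, params: dict) -> Path:
    path = out / name
    manifest["outputs"][name] = {"params": params}
    return path


def _finish(manifest: dict, name: str, path: Path) -> None:
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest["outputs"][name]["sha256"] = digest


def _save_csv(df: pd.DataFrame, manifest: dict, out: Path, name: str, params: dict) -> None:
    path = _record(manifest, out, name, params)
    df.to_csv(path, index=False)
    _finish(manifest, name, path)


_ANOVA_COLS = ["term", "Df", "SS", "MS", "Rsq", "F", "Z", "P"]


def _anova_csv(tbl: pd.DataFrame) -> pd.DataFrame:
    for c in _ANOVA_COLS:
        if c not in tbl.columns:
            tbl[c] = np.nan
    return tbl[_ANOVA_COLS]


def _stage_biteforce(cfg, table, out, manifest, results) -> None:
    cal = CalibrationParams()
    meas = {m.specimen_id: m for m in incisor_measurements(table)}
    zi, lbf = {}, {}
    for sid, m in meas.items():
        zi[sid] = compute_zi(m)
        lbf[sid] = calibrate_bite_force(zi[sid], cal)
    table["zi_mm3"] = table["specimen_id"].map(zi)
    table["log10_bite_force"] = table["specimen_id"].map(lbf)

    ok = table["log10_bite_force"].notna() & table["body_mass_g"].notna()
    n_skip = int((table["log10_bite_force"].notna() & ~ok).sum())
    if n_skip:
        logger.warning("BFQ: excluding %d specimens missing body mass", n_skip)
    bfq, fit = compute_bfq(table.loc[ok, "log10_bite_force"], table.loc[ok, "body_mass_g"])
    table.loc[ok, "bfq"] = bfq
    manifest["bfq_fit"] = dataclasses.asdict(fit)

    fit_anc = ancova(table, AncovaSpec(response="bfq", factors=("group", "sex"),
                                       posthoc_adjust=cfg.posthoc_adjust))
    _save_csv(_anova_csv(fit_anc.table), manifest, out, "bfq_ancova.csv", {"model": "bfq ~ group + sex"})
    _save_csv(pairwise_to_frame(posthoc_pairs(fit_anc)), manifest, out, "bfq_pairwise.csv",
              {"adjust": cfg.posthoc_adjust})
    _save_csv(table[["specimen_id", "group", "sex", "zi_mm3", "log10_bite_force", "bfq"]],
              manifest, out, "biteforce.csv", {"calibration": dataclasses.asdict(cal)})
    results["bfq_ancova"] = fit_anc
    results["bfq_table"] = table

    hyb = table[(table["group"] == Group.HYBRID.value) & table["bfq"].notna()
                & table["admixture_q"].notna()]
    if len(hyb) >= 3:
        reg = regress_on_admixture(hyb["bfq"], hyb["admixture_q"])
        manifest["bfq_admixture_regression"] = dataclasses.asdict(reg)
        results["bfq_admixture"] = reg


def _stage_suture(cfg, table, out, manifest, results) -> None:
    traces = read_suture_traces(cfg.suture_csv, format="csv")
    lr = assemble_lr_matrix(traces)
    merged = table.merge(lr, on="specimen_id", how="left")
    lr_cols = [c for c in lr.columns if c.startswith("lr_")]
    _save_csv(lr, manifest, out, "suture_lr.csv", {"n_traces": len(traces)})

    suture_tables = {}
    for col in lr_cols:
        fit = ancova(merged, AncovaSpec(response=col, factors=("group", "sex"),
                                        posthoc_adjust=cfg.posthoc_adjust))
        suture_tables[col] = fit
        _save_csv(_anova_csv(fit.table), manifest, out, f"{col}_ancova.csv",
                  {"model": f"{col} ~ group + sex"})
    results["suture_ancovas"] = suture_tables

    complete = merged.dropna(subset=lr_cols)
    if len(complete) >= 3:
        est = ShapePCA().fit(complete[lr_cols].to_numpy(), ids=list(complete["specimen_id"]))
        scores = est.scores_
        pc_df = complete[["specimen_id", "group", "sex"]].copy()
        pc_df["pc1"] = scores[:, 0]
        pc_df["pc2"] = scores[:, 1]
        _save_csv(pc_df, manifest, out, "suture_pca_scores.csv",
                  {"proportion": est.proportion_[:2].tolist()})
        results["suture_pca"] = est
        for pc in ("pc1", "pc2"):
            fit = ancova(pc_df, AncovaSpec(response=pc, factors=("group", "sex"),
                                           posthoc_adjust=cfg.posthoc_adjust))
            _save_csv(_anova_csv(fit.table), manifest, out, f"suture_{pc}_ancova.csv",
                      {"model": f"{pc} ~ group + sex"})
            results[f"suture_{pc}_ancova"] = fit

    hyb = merged[merged["group"] == Group.HYBRID.value]
    regs = {}
    for col in lr_cols:
        sub = hyb.dropna(subset=[col, "admixture_q"])
        if len(sub) >= 3:
            regs[col] = dataclasses.asdict(regress_on_admixture(sub[col], sub["admixture_q"]))
    if regs:
        manifest["suture_admixture_regressions"] = regs


def _stage_gmm(cfg, table, out, manifest, results) -> None:
    configs = read_tps(cfg.landmarks_tps)
    seed = _stage_seed(cfg.seed, "gmm")
    est = GeneralizedProcrustes(n_slide_cycles=cfg.n_slide_cycles).fit(configs)
    ds = est.dataset()
    results["shape_dataset"] = ds

    flat = ds.flat()
    aligned_df = pd.DataFrame(flat, columns=[f"{ax}{i}" for i in range(ds.aligned.shape[1])
                                             for ax in ("x", "y")])
    aligned_df.insert(0, "specimen_id", ds.specimen_ids)
    _save_csv(aligned_df, manifest, out, "aligned_coords.csv",
              {"n_slide_cycles": cfg.n_slide_cycles, "max_slide": est.max_slide_})
    size_df = pd.DataFrame({"specimen_id": ds.specimen_ids,
                            "centroid_size": ds.centroid_size,
                            "log10_centroid_size": ds.log10_centroid_size})
    _save_csv(size_df, manifest, out, "centroid_size.csv", {})

    pca_est = ShapePCA().fit(flat, ids=ds.specimen_ids)
    axis_p = pca_est.axis_significance(n_perm=cfg.n_perm, random_state=_stage_seed(cfg.seed, "axis"))
    scores = pca_est.scores_
    meta = table.set_index("specimen_id").loc[ds.specimen_ids].reset_index()
    shape_df = meta[["specimen_id", "group", "sex"]].copy()
    shape_df["pc1"] = scores[:, 0]
    shape_df["pc2"] = scores[:, 1]
    shape_df["size"] = ds.log10_centroid_size
    _save_csv(shape_df, manifest, out, "shape_pca_scores.csv",
              {"proportion": pca_est.proportion_[:2].tolist(),
               "axis_p": axis_p[: min(5, axis_p.size)].tolist(), "n_perm": cfg.n_perm})
    results["shape_pca"] = pca_est
    results["shape_pca_scores"] = shape_df

    # Procrustes ANOVA on PC1+PC2 with sex excluded when unknown
    model_df = shape_df[shape_df["sex"] != "UNKNOWN"].reset_index(drop=True)
    Y = model_df[["pc1", "pc2"]].to_numpy()
    tbl = procrustes_anova(Y, model_df,
                           model_terms=("group", "sex", "size", "group:size", "sex:size"),
                           n_perm=cfg.n_perm, random_state=seed)
    _save_csv(_anova_csv(tbl), manifest, out, "procrustes_anova.csv",
              {"n_perm": cfg.n_perm, "seed": seed, "response": "pc1+pc2"})
    results["procrustes_anova"] = tbl

    pw = pairwise_groups(Y, model_df["group"], adjust=cfg.posthoc_adjust,
                         n_perm=cfg.n_perm, random_state=_stage_seed(cfg.seed, "pairwise"))
    _save_csv(pairwise_to_frame(pw), manifest, out, "shape_pairwise.csv",
              {"adjust": cfg.posthoc_adjust, "n_perm": cfg.n_perm})

    size_tbl = ancova(shape_df.assign(size=ds.log10_centroid_size),
                      AncovaSpec(response="size", factors=("group", "sex"),
                                 posthoc_adjust=cfg.posthoc_adjust))
    _save_csv(_anova_csv(size_tbl.table), manifest, out, "centroid_size_ancova.csv",
              {"model": "log10_centroid_size ~ group + sex"})
    results["centroid_size_ancova"] = size_tbl

    hyb_mask = (meta["group"] == Group.HYBRID.value) & meta["admixture_q"].notna()
    if hyb_mask.sum() >= 3:
        reg_pc1 = regress_on_admixture(scores[hyb_mask.to_numpy(), 0],
                                       meta.loc[hyb_mask, "admixture_q"])
        reg_size = regress_on_admixture(ds.log10_centroid_size[hyb_mask.to_numpy()],
                                        meta.loc[hyb_mask, "admixture_q"])
        manifest["shape_admixture_regressions"] = {
            "pc1": dataclasses.asdict(reg_pc1), "log10_centroid_size": dataclasses.asdict(reg_size),
        }


def _stage_overlap(cfg, out, manifest, results) -> None:
    shape_df = results["shape_pca_scores"]
    traits = shape_df[["pc1", "pc2", "size"]].to_numpy()
    per_group = {g: traits[(shape_df["group"] == g).to_numpy()]
                 for g in shape_df["group"].unique()}
    seed = _stage_seed(cfg.seed, "overlap")
    posts = overlap_matrix(per_group, alpha=cfg.alpha, n_posterior=cfg.n_posterior,
                           n_mc=cfg.n_mc, random_state=seed)
    rows = []
    for (a, b), post in posts.items():
        lo, hi = post.ci
        rows.append(dict(group_a=a, group_b=b, mean=post.mean, lo=lo, hi=hi))
    _save_csv(pd.DataFrame(rows), manifest, out, "overlap.csv",
              {"alpha": cfg.alpha, "n_posterior": cfg.n_posterior, "n_mc": cfg.n_mc, "seed": seed})
    results["overlap"] = posts
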