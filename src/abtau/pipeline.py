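"""End-to-end orchestration: generate -> (pvc) -> quantify -> categorize ->
atlas/correlogram -> associations -> resonance -> summary.

The stage functions are pure library calls over in-memory objects;
:func:`run_pipeline` wires them together through a run directory whose
stages communicate only via files (re-entrant and debuggable).  All
randomness flows from one root seed, split per stage.

Default analysis choices (each overridable in :class:`PipelineConfig`):

* composites, atlases, regional tables and resonance are computed on *raw*
  SUVR maps; partial-volume correction runs as its own stage and its
  corrected maps are written alongside, with ``analyze_on_pvc=True``
  switching the downstream analyses onto them;
* cut-points are derived from the young cohorts at the configured
  percentile (default 96th);
* vertex-wise models use Benjamini-Hochberg FDR at ``q``; regional models
  use permutation family-wise thresholds from ``n_perm`` shuffles at the
  5th/95th percentiles of the fitted null.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as abio
from .association import (build_design, residualize, regional_association,
                          vertexwise_association, StatMap)
from .atlas import binarize_overlay, cross_correlogram, probabilistic_atlas
from .categorize import (GROUPS, CutPoints, assign_groups, derive_cutpoints,
                         fit_reference, group_share_report)
from .cohort import SurfaceGeometry, VertexOverlay
from .pvc import PSFModel, SpillinOperator, apply_pvc, fit_spillin_model
from .quantify import build_panel, build_region_table, default_definitions
from .resonance import resonance_association, resonance_scores
from .synthetic import GeneratorConfig, SyntheticCohort, generate_cohort

logger = logging.getLogger("abtau")

MIN_SIG_FRACTION = 0.005  # fraction of gray vertices needed to call a direction


class PipelineError(Exception):
    pass


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    pvc_modalities: tuple[str, ...] = ("abeta", "tau")
    analyze_on_pvc: bool = False
    percentile: float = 96.0
    q: float = 0.05
    n_perm: int = 10000
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["pvc_modalities"] = list(self.pvc_modalities)
        yaml.safe_dump(d, open(path, "w"), sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(open(path))
        gen = d.pop("generator", {})
        # YAML has no tuple type; restore the tuple-typed generator fields
        for key in ("grid_shape", "young_abeta", "young_tau"):
            if key in gen:
                gen[key] = tuple(gen[key])
        for key in ("group_abeta", "group_tau"):
            if key in gen:
                gen[key] = {g: tuple(v) for g, v in gen[key].items()}
        d["pvc_modalities"] = tuple(d.get("pvc_modalities", ("abeta", "tau")))
        return cls(generator=GeneratorConfig(**gen), **d)


# ------------------------------------------------------------ stage helpers

def split_young_old(subject_frame: pd.DataFrame):
    young = subject_frame.index[subject_frame["cohort"] == "young"]
    old = subject_frame.index[subject_frame["cohort"] == "old"]
    return list(young), list(old)


def pvc_stage(subject_frame: pd.DataFrame, overlays: dict,
              geometry: SurfaceGeometry, psf: PSFModel,
              modalities=("abeta", "tau")):
    """Fit spill-in models on the young cohorts and correct every overlay.

    Returns (corrected overlays mapping, models per modality).
    """
    op = SpillinOperator(geometry, psf)
    models = {}
    corrected: dict[str, dict[str, VertexOverlay]] = {
        sid: dict(m) for sid, m in overlays.items()}
    young, _ = split_young_old(subject_frame)
    for modality in modalities:
        train = [overlays[sid][modality] for sid in young
                 if modality in overlays[sid]]
        models[modality] = fit_spillin_model(train, geometry, psf, operator=op)
        for sid, mods in overlays.items():
            if modality in mods:
                corrected[sid][modality] = apply_pvc(
                    mods[modality], models[modality], geometry, operator=op)
    return corrected, models


def quantify_stage(subject_frame: pd.DataFrame, overlays: dict,
                   geometry: SurfaceGeometry):
    """Region tables per modality and the composite panel."""
    by_mod = {m: {} for m in ("abeta", "tau", "thickness")}
    for sid, mods in overlays.items():
        for m, ov in mods.items():
            by_mod[m][sid] = ov
    tables = {m: build_region_table(ovs, geometry) for m, ovs in by_mod.items()}
    panel = build_panel(subject_frame, tables["abeta"], tables["tau"], geometry)
    return tables, panel


def categorize_stage(panel: pd.DataFrame, percentile: float = 96.0):
    """Young reference fits, cut-points, and old-subject group labels."""
    young = panel[panel["cohort"] == "young"]
    refs = {}
    for marker in ("global_abeta", "global_tau", "mtl_tau"):
        vals = young[marker].dropna().to_numpy()
        refs[marker] = fit_reference(vals, marker=marker)
    cuts = derive_cutpoints(refs["global_abeta"], refs["global_tau"],
                            refs["mtl_tau"], percentile=percentile)
    old = panel[panel["cohort"] == "old"]
    groups = assign_groups(old, cuts)
    return refs, cuts, groups


def atlas_stage(overlays: dict, geometry: SurfaceGeometry, groups: pd.Series,
                tables: dict, cuts: CutPoints):
    """Per-group probabilistic atlases (global cut-points only) and
    amyloid x tau cross-correlograms."""
    gray = geometry.gray_mask
    atlases = {}
    correlograms = {}
    for g in GROUPS:
        members = list(groups.index[groups == g])
        if not members:
            continue
        atlases[g] = {}
        for modality, cut in (("abeta", cuts.abeta_global),
                              ("tau", cuts.tau_global)):
            maps = [binarize_overlay(overlays[sid][modality].values[gray], cut)
                    for sid in members]
            atlases[g][modality] = probabilistic_atlas(maps, group=g,
                                                       modality=modality)
        if len(members) >= 3:
            correlograms[g] = cross_correlogram(
                tables["abeta"], tables["tau"], members, group=g)
    return atlases, correlograms


def thickness_matrix(overlays: dict, geometry: SurfaceGeometry,
                     subject_ids: list[str]) -> np.ndarray:
    gray = geometry.gray_mask
    return np.vstack([overlays[sid]["thickness"].values[gray]
                      for sid in subject_ids])


def vertexwise_stage(overlays: dict, geometry: SurfaceGeometry,
                     panel: pd.DataFrame, groups: pd.Series,
                     q: float = 0.05) -> dict[str, dict[str, StatMap]]:
    """Model 1 per group: thickness ~ global amyloid + global tau + covariates."""
    out = {}
    for g in GROUPS:
        members = list(groups.index[groups == g])
        if len(members) < 10:
            continue
        th = thickness_matrix(overlays, geometry, members)
        out[g] = vertexwise_association(
            th, panel.loc[members], ["global_abeta", "global_tau"], q=q)
    return out


def regional_stage(tables: dict, panel: pd.DataFrame, groups: pd.Series,
                   geometry: SurfaceGeometry, n_perm: int = 10000,
                   seed: int = 0) -> pd.DataFrame:
    """Model 2 per group, modality, and region: two-step residualized
    regression with permutation family-wise thresholds."""
    labels = geometry.region_label_strings()
    ids = list(geometry.region_table.index)
    rows = []
    other = {"abeta": "tau", "tau": "abeta"}
    for gi, g in enumerate(GROUPS):
        members = list(groups.index[groups == g])
        if len(members) < 10:
            continue
        sub = panel.loc[members]
        for mi, modality in enumerate(("abeta", "tau")):
            for ri, rid in enumerate(ids):
                y = tables["thickness"].loc[members, rid].to_numpy(float)
                x = tables[modality].loc[members, rid].to_numpy(float)
                xo = tables[other[modality]].loc[members, rid].to_numpy(float)
                nuis = pd.DataFrame({"other": xo, "age": sub["age"],
                                     "sex": sub["sex"], "icv": sub["icv"]},
                                    index=sub.index)
                X, names = build_design(nuis, ["other", "age", "sex", "icv"])
                resid = residualize(y, X, names)
                stat = regional_association(
                    resid, x, n_perm=n_perm,
                    seed=seed + 7919 * gi + 911 * mi + ri,
                    region=labels[ri])
                rows.append({"group": g, "modality": modality,
                             "region": labels[ri], "t": stat.t, "p": stat.p,
                             "t_low": stat.t_low, "t_high": stat.t_high,
                             "survived": stat.survived, "flagged": stat.flagged})
    return pd.DataFrame(rows)


def resonance_stage(overlays: dict, geometry: SurfaceGeometry,
                    panel: pd.DataFrame, groups: pd.Series, tables: dict,
                    q: float = 0.05, n_perm: int = 10000, seed: int = 0):
    """Resonance scores, model-3 vertex maps per group, and the regional
    resonance association."""
    scores = resonance_scores(overlays, geometry)
    panel = panel.join(scores["resonance"], how="left")
    maps = {}
    rows = []
    labels = geometry.region_label_strings()
    ids = list(geometry.region_table.index)
    for gi, g in enumerate(GROUPS):
        members = list(groups.index[groups == g])
        if len(members) < 10:
            continue
        sub = panel.loc[members]
        th = thickness_matrix(overlays, geometry, members)
        maps[g] = resonance_association(th, sub, q=q)
        X, names = build_design(
            sub, ["global_abeta", "global_tau", "age", "sex", "icv"])
        res_x = sub["resonance"].to_numpy(float)
        for ri, rid in enumerate(ids):
            y = tables["thickness"].loc[members, rid].to_numpy(float)
            resid = residualize(y, X, names)
            stat = regional_association(
                resid, res_x, n_perm=n_perm,
                seed=seed + 104729 * gi + ri, region=labels[ri])
            rows.append({"group": g, "region": labels[ri], "t": stat.t,
                         "p": stat.p, "t_low": stat.t_low,
                         "t_high": stat.t_high, "survived": stat.survived,
                         "flagged": stat.flagged})
    return scores, maps, pd.DataFrame(rows), panel


def direction_of(stat_map: StatMap, n_gray: int) -> dict:
    """Dominant FDR-surviving direction of a vertex map ('+', '-', or '0')."""
    min_n = max(1, int(round(MIN_SIG_FRACTION * n_gray)))
    np_, nn = stat_map.n_sig_pos, stat_map.n_sig_neg
    if np_ >= min_n and np_ > nn:
        d = "+"
    elif nn >= min_n and nn > np_:
        d = "-"
    else:
        d = "0"
    return {"n_pos": np_, "n_neg": nn, "direction": d}


# ------------------------------------------------------------ full analysis

@dataclass
class AnalysisResults:
    tables: dict
    panel: pd.DataFrame
    references: dict
    cutpoints: CutPoints
    groups: pd.Series
    atlases: dict
    correlograms: dict
    vertex_maps: dict
    regional: pd.DataFrame
    resonance_scores: pd.DataFrame
    resonance_maps: dict
    resonance_regional: pd.DataFrame
    pvc_models: dict
    summary: dict


def analyze_cohort(subject_frame: pd.DataFrame, overlays: dict,
                   geometry: SurfaceGeometry,
                   config: PipelineConfig) -> AnalysisResults:
    """Run every analysis stage on an in-memory cohort."""
    t0 = time.time()
    pvc_models = {}
    analysis_overlays = overlays
    if config.pvc_modalities:
        corrected, pvc_models = pvc_stage(
            subject_frame, overlays, geometry,
            PSFModel(fwhm_mm=config.generator.psf_fwhm_mm),
            modalities=config.pvc_modalities)
        if config.analyze_on_pvc:
            analysis_overlays = corrected
    tables, panel = quantify_stage(subject_frame, analysis_overlays, geometry)
    refs, cuts, groups = categorize_stage(panel, percentile=config.percentile)
    atlases, correlograms = atlas_stage(analysis_overlays, geometry, groups,
                                        tables, cuts)
    vertex_maps = vertexwise_stage(analysis_overlays, geometry, panel, groups,
                                   q=config.q)
    regional = regional_stage(tables, panel, groups, geometry,
                              n_perm=config.n_perm, seed=config.seed)
    scores, res_maps, res_regional, panel = resonance_stage(
        analysis_overlays, geometry, panel, groups, tables,
        q=config.q, n_perm=config.n_perm, seed=config.seed + 1)
    summary = summarize(subject_frame, panel, refs, cuts, groups, atlases,
                        correlograms, vertex_maps, regional, res_maps,
                        res_regional, geometry, config)
    summary["wall_time_s"] = round(time.time() - t0, 2)
    return AnalysisResults(tables=tables, panel=panel, references=refs,
                           cutpoints=cuts, groups=groups, atlases=atlases,
                           correlograms=correlograms, vertex_maps=vertex_maps,
                           regional=regional, resonance_scores=scores,
                           resonance_maps=res_maps,
                           resonance_regional=res_regional,
                           pvc_models=pvc_models, summary=summary)


def summarize(subject_frame, panel, refs, cuts, groups, atlases, correlograms,
              vertex_maps, regional, res_maps, res_regional, geometry,
              config) -> dict:
    n_gray = int(geometry.gray_mask.sum())
    old = subject_frame[subject_frame["cohort"] == "old"]
    counts = pd.DataFrame(0, index=list(GROUPS), columns=["HC", "MCI"])
    for g in GROUPS:
        members = groups.index[groups == g]
        dx = old.loc[members, "diagnosis"]
        counts.loc[g, "HC"] = int((dx == "HC").sum())
        counts.loc[g, "MCI"] = int((dx == "MCI").sum())
    shares = group_share_report(counts) if counts.to_numpy().sum() else None

    summary: dict = {
        "parameters": {
            "percentile": config.percentile, "q": config.q,
            "n_perm": config.n_perm, "seed": config.seed,
            "pvc_modalities": list(config.pvc_modalities),
            "analyze_on_pvc": config.analyze_on_pvc,
        },
        "n_subjects": {
            "young": int((subject_frame["cohort"] == "young").sum()),
            "old": int(len(old)),
        },
        "cutpoints": {
            "global_abeta": cuts.abeta_global, "global_tau": cuts.tau_global,
            "mtl_tau": cuts.tau_mtl, "percentile": cuts.percentile,
        },
        "reference_fits": {m: {"mu": r.mu, "sigma": r.sigma,
                               "n_young": r.n_young,
                               "normality_p": r.normality_p}
                           for m, r in refs.items()},
        "group_counts": {g: {"HC": int(counts.loc[g, "HC"]),
                             "MCI": int(counts.loc[g, "MCI"]),
                             "n": int(counts.loc[g].sum())} for g in GROUPS},
    }
    if shares is not None:
        summary["group_percentages"] = {
            g: {"pct_of_all": float(shares.loc[g, "pct_of_all"]),
                "pct_of_hc": float(shares.loc[g, "pct_of_hc"]),
                "pct_of_mci": float(shares.loc[g, "pct_of_mci"])}
            for g in GROUPS}
    summary["atlas_mean_probability"] = {
        g: {m: float(a.probability.mean()) for m, a in mods.items()}
        for g, mods in atlases.items()}
    summary["correlogram_mean"] = {
        g: float(np.nanmean(c.matrix.to_numpy())) for g, c in correlograms.items()}
    signs = {}
    for g, maps in vertex_maps.items():
        signs[g] = {name: direction_of(sm, n_gray) for name, sm in maps.items()}
    for g, sm in res_maps.items():
        signs.setdefault(g, {})["resonance"] = direction_of(sm, n_gray)
    summary["vertexwise_signs"] = signs
    summary["resonance_mean"] = {
        g: float(panel.loc[groups.index[groups == g], "resonance"].mean())
        for g in GROUPS if (groups == g).any()}
    surv = {}
    for g in GROUPS:
        gsel = regional[regional["group"] == g]
        if gsel.empty:
            continue
        surv[g] = {}
        for modality in ("abeta", "tau"):
            msel = gsel[gsel["modality"] == modality]
            surv[g][modality] = {
                "n_pos": int(((msel["t"] > 0) & msel["survived"]).sum()),
                "n_neg": int(((msel["t"] < 0) & msel["survived"]).sum())}
        rsel = res_regional[res_regional["group"] == g]
        surv[g]["resonance"] = {
            "n_pos": int(((rsel["t"] > 0) & rsel["survived"]).sum()),
            "n_neg": int(((rsel["t"] < 0) & rsel["survived"]).sum())}
    summary["regional_survivors"] = surv
    return summary


# ------------------------------------------------------------ run directory

def _write_statmap_csv(sm: StatMap, path: Path) -> None:
    pd.DataFrame({"beta": sm.beta, "t": sm.t, "p": sm.p,
                  "significant": sm.sig_mask.astype(int),
                  "valid": sm.valid_mask.astype(int)}).to_csv(
        path, index_label="gray_index", float_format="%.10g")


def _safe(name: str) -> str:
    return name.replace("/", "_")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Generate a cohort, round-trip it through the canonical file formats,
    run every stage, and write all artifacts plus ``summary.json``.

    Returns the summary dict.  Deterministic given ``config`` (the generator
    and analysis seeds both derive from the config seeds).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    logger.addHandler(fh)
    try:
        config.to_yaml(out / "config.yaml")
        logger.info("stage=generate seed=%s", config.generator.seed)
        cohort = generate_cohort(config.generator)
        cohort.save(out / "cohort")
        logger.info("stage=load")
        subjects, overlays, geometry = abio.load_cohort(
            out / "cohort" / "subjects.csv", out / "cohort" / "overlays",
            out / "cohort" / "geometry")
        from .cohort import subjects_to_frame
        frame = subjects_to_frame(subjects)
        logger.info("stage=analyze")
        results = analyze_cohort(frame, overlays, geometry, config)
        logger.info("stage=write")
        _write_outputs(results, geometry, out)
        (out / "summary.json").write_text(
            json.dumps(results.summary, indent=2, sort_keys=True))
        return results.summary
    except Exception as exc:  # surface the failing stage to the caller
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(fh)
        fh.close()


def _write_outputs(results: AnalysisResults, geometry: SurfaceGeometry,
                   out: Path) -> None:
    qdir = out / "quantify"; qdir.mkdir(exist_ok=True)
    for m, tab in results.tables.items():
        tab.to_csv(qdir / f"regions_{m}.csv", float_format="%.10g")
    results.panel.to_csv(qdir / "panel.csv", float_format="%.10g")
    cdir = out / "categorize"; cdir.mkdir(exist_ok=True)
    results.cutpoints.to_json(cdir / "cutpoints.json")
    results.groups.to_frame().to_csv(cdir / "groups.csv")
    adir = out / "atlas"; adir.mkdir(exist_ok=True)
    for g, mods in results.atlases.items():
        for m, a in mods.items():
            np.savetxt(adir / f"atlas_{_safe(g)}_{m}.txt", a.probability,
                       fmt="%.10g")
    for g, c in results.correlograms.items():
        c.matrix.to_csv(adir / f"correlogram_{_safe(g)}.csv",
                        float_format="%.10g")
    sdir = out / "assoc"; sdir.mkdir(exist_ok=True)
    for g, maps in results.vertex_maps.items():
        for name, sm in maps.items():
            _write_statmap_csv(sm, sdir / f"statmap_{_safe(g)}_{name}.csv")
    results.regional.to_csv(sdir / "regional.csv", index=False,
                            float_format="%.10g")
    rdir = out / "resonance"; rdir.mkdir(exist_ok=True)
    results.resonance_scores.to_csv(rdir / "scores.csv", float_format="%.10g")
    for g, sm in results.resonance_maps.items():
        _write_statmap_csv(sm, rdir / f"statmap_{_safe(g)}_resonance.csv")
    results.resonance_regional.to_csv(rdir / "regional.csv", index=False,
                                      float_format="%.10g")
    for m, model in results.pvc_models.items():
        model.save(out / "pvc" / m)
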