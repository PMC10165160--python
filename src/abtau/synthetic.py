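"""Synthetic cohort generator with the statistical structure the analysis assumes.

The generator emulates a surface-based amyloid/tau PET study:

* a rectangular gray-matter patch (default 64 x 64 vertices, 1.5 mm
  spacing) carrying a Desikan-Killiany-style parcellation laid out in row
  bands, sandwiched between a white-matter sheet beneath and a meningeal
  sheet above; both sheets extend beyond the patch rim by more than the
  point-spread-function reach, so every gray vertex — interior or edge —
  receives (near-)uniform spill-in from non-specific binding sources;
* young normative subjects whose gray uptake is *pure spill-in* (the
  PSF-blurred white/meninges field) plus measurement noise, calibrated so
  the young composite SUVRs follow the configured normal distributions
  (global amyloid ~ N(1.11, 0.06), global tau ~ N(0.90, 0.10));
* four old groups whose composite SUVRs follow the configured group
  means/SDs, truncated at the configured cut-points so that each subject's
  composites are consistent with its generating group (this mirrors how
  observed group statistics arise: groups are *defined* by categorization);
* spatial patterns: amyloid signal seeded in neocortical (amyloid-composite)
  parcels, tau signal in temporal/medial-temporal parcels, overlapping over
  the whole cortex only in the doubly abnormal group — which makes the
  amyloid-tau spatial correlation (resonance) discriminative by
  construction; subject-wise amyloid/tau amplitudes are correlated only in
  that group, so group cross-correlograms are strongly positive there and
  weak elsewhere;
* thickness = base + covariate effects + regime-dependent pathology effects
  (thickening with deposition at normal levels, thinning at abnormal tau,
  extra thinning with resonance in the doubly abnormal group) + noise.  The
  regime switch is keyed to the subject's *generating* group, never to an
  estimated label.

A :class:`GroundTruth` record (true group, true composites, true spill-in
and specific-binding fields, the effect sizes used) is produced alongside
the data and is never consumed by the analysis path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

from .categorize import GROUPS
from .cohort import Subject, SurfaceGeometry, VertexOverlay, subjects_to_frame
from .pvc import PSFModel, SpillinOperator
from .quantify import CompositeDefinition, default_definitions
from . import io as abio

Z96 = float(stats.norm.ppf(0.96))


class GeneratorError(Exception):
    pass


#: Row-band order of the 34 cortical parcels from "superior" rows down to the
#: temporal pole, keeping the temporal / medial-temporal block contiguous so
#: that amyloid- and tau-seeded territories are spatially coherent.
REGION_ROW_ORDER = (
    "superiorfrontal", "rostralmiddlefrontal", "caudalmiddlefrontal",
    "parsopercularis", "parsorbitalis", "parstriangularis",
    "lateralorbitofrontal", "medialorbitofrontal", "frontalpole",
    "precentral", "paracentral", "postcentral", "superiorparietal",
    "inferiorparietal", "supramarginal", "precuneus", "cuneus",
    "pericalcarine", "lateraloccipital", "lingual", "isthmuscingulate",
    "posteriorcingulate", "caudalanteriorcingulate", "rostralanteriorcingulate",
    "insula", "transversetemporal", "superiortemporal", "bankssts",
    "middletemporal", "inferiortemporal", "fusiform", "parahippocampal",
    "entorhinal", "temporalpole",
)

#: Per-group demographics used by default: (age mean, age sd, fraction female,
#: fraction MCI).
GROUP_DEMOGRAPHICS = {
    "nAb/nTau": (64.79, 3.55, 138 / 232, 3 / 232),
    "aAb/nTau": (66.84, 5.17, 30 / 46, 7 / 46),
    "nAb/aTau": (67.20, 5.90, 64 / 96, 3 / 96),
    "aAb/aTau": (69.69, 7.11, 47 / 72, 39 / 72),
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Composite means/SDs parameterize the parent normal of each group's
    composite SUVR; draws are truncated at the configured cut-points
    (``young mean + z(percentile) * young sd``) to the side the group label
    requires.  Effect sizes are in mm of cortical thickness per unit of the
    (group-centered) predictor.
    """

    seed: int = 0
    grid_shape: tuple[int, int] = (64, 64)
    spacing_mm: float = 1.5
    sheet_offset_mm: float = 2.0
    sheet_padding_cells: int = 6
    n_young_abeta: int = 97
    n_young_tau: int = 47
    n_per_group: dict = field(default_factory=lambda: {g: 200 for g in GROUPS})
    young_abeta: tuple[float, float] = (1.11, 0.06)
    young_tau: tuple[float, float] = (0.90, 0.10)
    group_abeta: dict = field(default_factory=lambda: {
        "nAb/nTau": (1.14, 0.07), "aAb/nTau": (1.37, 0.13),
        "nAb/aTau": (1.15, 0.06), "aAb/aTau": (1.71, 0.29)})
    group_tau: dict = field(default_factory=lambda: {
        "nAb/nTau": (0.94, 0.09), "aAb/nTau": (0.95, 0.09),
        "nAb/aTau": (1.20, 0.34), "aAb/aTau": (2.23, 1.11)})
    percentile: float = 96.0
    psf_fwhm_mm: float = 6.0
    spillin_slope: float = 0.85
    uptake_noise_sd: float = 0.10
    white_field_jitter_sd: float = 0.12
    thickness_base_mm: float = 2.5
    thickness_noise_sd: float = 0.15
    beta_abeta_pos: float = 1.0
    beta_tau_pos: float = 1.0
    beta_tau_neg: float = -0.6
    beta_resonance: float = -1.5
    beta_age: float = -0.01
    beta_sex: float = -0.05
    beta_icv: float = 2.0e-7
    tau_mix_max_angle_deg: float = 60.0
    #: Gaussian-copula correlation between the amyloid and tau composite
    #: targets in the doubly abnormal group (independent in all others).
    group_amplitude_corr: float = 0.7
    #: Exclusion zone around each truncation cut-point.  The analysis derives
    #: its cut-points from the young sample, so they differ from the
    #: generator's by estimation error (a few hundredths of SUVR); keeping
    #: generated composites at least this far from the boundary makes group
    #: membership robust to that drift plus composite observation noise.
    boundary_margin: float = 0.05

    def cutpoints(self) -> dict[str, float]:
        """Configured (analytic) cut-points used for truncated group draws."""
        z = float(stats.norm.ppf(self.percentile / 100.0))
        cut_ab = self.young_abeta[0] + z * self.young_abeta[1]
        cut_tau = self.young_tau[0] + z * self.young_tau[1]
        return {"abeta": cut_ab, "tau": cut_tau, "mtl": cut_tau}


@dataclass
class GroundTruth:
    """Generator-side record for recovery tests; never read by the analysis."""

    frame: pd.DataFrame
    effects: dict
    true_signal: dict          # modality -> subject id -> gray vector (float32)
    true_spillin: dict         # modality -> subject id -> gray vector (float32)
    configured_cutpoints: dict

    def save(self, path: str | Path) -> None:
        import json
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(path / "truth.csv", float_format="%.17g")
        (path / "effects.json").write_text(json.dumps(
            {"effects": self.effects, "cutpoints": self.configured_cutpoints},
            indent=2, sort_keys=True))


@dataclass
class SyntheticCohort:
    subjects: list[Subject]
    overlays: dict[str, dict[str, VertexOverlay]]
    geometry: SurfaceGeometry
    ground_truth: GroundTruth

    @property
    def subject_frame(self) -> pd.DataFrame:
        return subjects_to_frame(self.subjects)

    def save(self, path: str | Path) -> None:
        abio.save_cohort(self.subjects, self.overlays, self.geometry, path)
        self.ground_truth.save(Path(path) / "ground_truth")


# ------------------------------------------------------------------ geometry

def grid_layout(grid_shape: tuple[int, int], padding: int = 6) -> dict:
    """Vertex-index layout of the grid geometry, in construction order:
    gray sheet, white sheet (padded), meningeal sheet (padded)."""
    nr, nc = grid_shape
    g = nr * nc
    sheet = (nr + 2 * padding) * (nc + 2 * padding)
    out = {}
    pos = 0
    for name, size in (("gray", g), ("white_sheet", sheet),
                       ("men_sheet", sheet)):
        out[name] = slice(pos, pos + size)
        pos += size
    out["n_total"] = pos
    out["sheet_shape"] = (nr + 2 * padding, nc + 2 * padding)
    return out


def build_grid_geometry(grid_shape: tuple[int, int] = (64, 64),
                        spacing_mm: float = 1.5,
                        sheet_offset_mm: float = 2.0,
                        padding: int = 6) -> SurfaceGeometry:
    """Grid surface: gray patch with a padded white-matter sheet below and a
    padded meningeal sheet above (cortex sandwiched between its two
    non-specific-binding sources).  The sheets extend ``padding`` cells
    beyond the patch rim — surrounding it in-plane as well — so interior and
    edge gray vertices receive comparable spill-in."""
    nr, nc = grid_shape
    if nr * nc <= 0:
        raise GeneratorError("grid must contain gray vertices")
    if nr < len(REGION_ROW_ORDER) or nc < 2:
        raise GeneratorError(
            f"grid needs >= {len(REGION_ROW_ORDER)} rows (one per row-band "
            "parcel) and >= 2 columns (two hemispheres)")
    sp = spacing_mm
    ii, jj = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    gray_xy = np.column_stack([ii.ravel() * sp, jj.ravel() * sp])
    pi, pj = np.meshgrid(np.arange(-padding, nr + padding),
                         np.arange(-padding, nc + padding), indexing="ij")
    sheet_xy = np.column_stack([pi.ravel() * sp, pj.ravel() * sp])

    n_sheet = sheet_xy.shape[0]
    coords, tissue, hemi = [], [], []
    # gray sheet
    coords.append(np.column_stack([gray_xy, np.zeros(nr * nc)]))
    tissue += ["gray"] * (nr * nc)
    hemi += ["L" if j < nc // 2 else "R" for j in jj.ravel()]
    # white sheet below
    coords.append(np.column_stack([sheet_xy, np.full(n_sheet, -sheet_offset_mm)]))
    tissue += ["white"] * n_sheet
    hemi += ["-"] * n_sheet
    # meninges sheet above
    coords.append(np.column_stack([sheet_xy, np.full(n_sheet, sheet_offset_mm)]))
    tissue += ["meninges"] * n_sheet
    hemi += ["-"] * n_sheet

    coordinates = np.vstack(coords)
    tissue_arr = np.asarray(tissue, dtype="U8")
    hemi_arr = np.asarray(hemi, dtype="U1")

    n_reg = len(REGION_ROW_ORDER)
    band = (ii.ravel() * n_reg) // nr  # 0..33 by row band
    left = jj.ravel() < nc // 2
    region_gray = np.where(left, band, band + n_reg)
    region = np.full(coordinates.shape[0], -1, dtype=int)
    region[:nr * nc] = region_gray
    table = pd.DataFrame({
        "name": list(REGION_ROW_ORDER) * 2,
        "hemisphere": ["L"] * n_reg + ["R"] * n_reg,
    }, index=pd.Index(range(2 * n_reg), name="region_id"))
    return SurfaceGeometry(coordinates=coordinates, tissue=tissue_arr,
                           region=region, hemisphere=hemi_arr,
                           region_table=table)


# ------------------------------------------------------------------ helpers

def _region_mean_map(gray_field: np.ndarray, labels: np.ndarray,
                     n_regions: int) -> np.ndarray:
    cnt = np.bincount(labels, minlength=n_regions).astype(float)
    tot = np.bincount(labels, weights=gray_field, minlength=n_regions)
    with np.errstate(invalid="ignore"):
        return tot / cnt


def _composite_of(gray_field: np.ndarray, labels: np.ndarray, n_regions: int,
                  ids: list[int]) -> float:
    means = _region_mean_map(gray_field, labels, n_regions)
    return float(np.mean(means[ids]))


def _smooth_indicator(ids: list[int], labels: np.ndarray, grid_shape, sigma=2.0,
                      ripple: np.ndarray | None = None) -> np.ndarray:
    ind = np.isin(labels, ids).astype(float).reshape(grid_shape)
    sm = gaussian_filter(ind, sigma, mode="nearest").ravel()
    if ripple is not None:
        sm = sm * ripple
    return sm


def _truncnorm_draw(rng, mean, sd, lower=-np.inf, upper=np.inf, size=None):
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


# ------------------------------------------------------------------ generator

def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort (in memory) with ground truth."""
    nr, nc = config.grid_shape
    if nr * nc <= 0:
        raise GeneratorError("config yields zero gray vertices")
    rng = np.random.default_rng(config.seed)
    geom = build_grid_geometry(config.grid_shape, config.spacing_mm,
                               config.sheet_offset_mm,
                               padding=config.sheet_padding_cells)
    layout = grid_layout(config.grid_shape, config.sheet_padding_cells)
    psf = PSFModel(fwhm_mm=config.psf_fwhm_mm)
    op = SpillinOperator(geom, psf)
    gray = geom.gray_mask
    n_gray = int(gray.sum())
    labels = geom.region[gray]
    n_regions = len(geom.region_table)
    src_mask = geom.source_mask
    n_src = int(src_mask.sum())
    defs = default_definitions()

    def ids_of(d: CompositeDefinition) -> list[int]:
        return d.resolve_ids(geom, strict=False)

    ids_ab = ids_of(defs["global_abeta"])
    ids_tau = ids_of(defs["global_tau"])
    ids_mtl = ids_of(defs["mtl_tau"])
    cuts = config.cutpoints()

    # fixed spatial patterns
    grid = (nr, nc)
    ii, jj = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    ripple = (1.0 + 0.3 * np.sin(2 * np.pi * ii / max(nr / 4, 1))
              * np.cos(2 * np.pi * jj / max(nc / 4, 1))).ravel()
    P_ab = _smooth_indicator(ids_ab, labels, grid, ripple=ripple)
    P_tau = _smooth_indicator(ids_tau, labels, grid, ripple=ripple)
    P_mtl = _smooth_indicator(ids_mtl, labels, grid, ripple=ripple)
    P_full = _smooth_indicator(list(range(n_regions)), labels, grid, ripple=ripple)
    base_thick_var = gaussian_filter(
        rng.standard_normal(grid), 4.0, mode="nearest").ravel()
    sdv = base_thick_var.std()
    base_field = config.thickness_base_mm + 0.1 * (base_thick_var / (sdv or 1.0))

    theta_max = np.deg2rad(config.tau_mix_max_angle_deg)

    # Deterministic spill geometry (unit sources): divided out below so that
    # the expected spill field is flat over gray.  Otherwise every subject in
    # every modality would share this one anatomical pattern, which would
    # dominate the amyloid-tau spatial correlation in the normal groups.  The
    # per-vertex rescaling is exactly what the per-vertex spill-in regression
    # absorbs at correction time.
    ones_src = np.zeros(geom.n_vertices)
    ones_src[src_mask] = 1.0
    spill_shape_bar = config.spillin_slope * op.synthesize(ones_src)
    spill_shape_mean = float(spill_shape_bar.mean())

    def unit_spill(shape_src_full: np.ndarray) -> np.ndarray:
        return (config.spillin_slope * op.synthesize(shape_src_full)
                / spill_shape_bar * spill_shape_mean)

    sheet_shape = layout["sheet_shape"]

    def make_source_field(rngl) -> np.ndarray:
        """Unit non-specific-binding field: 1 + a smooth random modulation on
        each sheet (spatial correlation length wider than the PSF, so the
        modulation survives convolution), rings at exactly 1."""
        f = np.zeros(geom.n_vertices)
        f[src_mask] = 1.0
        for key in ("white_sheet", "men_sheet"):
            j = gaussian_filter(rngl.standard_normal(sheet_shape), 3.0,
                                mode="nearest")
            j = (j - j.mean()) / (j.std() or 1.0)
            f[layout[key]] = 1.0 + config.white_field_jitter_sd * j.ravel()
        return f

    subjects: list[Subject] = []
    overlays: dict[str, dict[str, VertexOverlay]] = {}
    truth_rows: list[dict] = []
    true_signal = {"abeta": {}, "tau": {}}
    true_spillin = {"abeta": {}, "tau": {}}

    def pet_overlay(sid, modality, source_field, u, gray_clean) -> VertexOverlay:
        full = np.zeros(geom.n_vertices)
        full[src_mask] = u * source_field[src_mask]
        noise = rng.normal(0.0, config.uptake_noise_sd, geom.n_vertices)
        full[gray] = gray_clean
        full = full + noise * (geom.tissue != "excluded")
        return VertexOverlay(subject_id=sid, modality=modality, values=full)

    def add_subject(s: Subject) -> None:
        subjects.append(s)
        overlays[s.id] = {}

    def make_covariates(rngl, age_mean, age_sd, f_frac, lo, hi):
        age = float(np.clip(rngl.normal(age_mean, age_sd), lo, hi))
        sex = "F" if rngl.random() < f_frac else "M"
        icv = float(rngl.normal(1.40e6 if sex == "F" else 1.55e6,
                                1.3e5))
        icv = max(icv, 9.0e5)
        return age, sex, icv

    def thickness_overlay(sid, age, sex, icv, extra_gray) -> VertexOverlay:
        th = (base_field
              + config.beta_age * (age - 65.0)
              + config.beta_sex * (1.0 if sex == "F" else 0.0)
              + config.beta_icv * (icv - 1.5e6)
              + extra_gray
              + rng.normal(0.0, config.thickness_noise_sd, n_gray))
        full = np.zeros(geom.n_vertices)
        full[gray] = np.maximum(th, 0.0)
        return VertexOverlay(subject_id=sid, modality="thickness", values=full)

    # -------------------------------------------------- young cohorts
    young_vals = {"abeta": [], "tau": [], "mtl": []}
    young_specs = [("ya", config.n_young_abeta, "abeta",
                    config.young_abeta, ids_ab),
                   ("yt", config.n_young_tau, "tau",
                    config.young_tau, ids_tau)]
    for prefix, n, modality, (mu, sd), comp_ids in young_specs:
        for i in range(n):
            sid = f"{prefix}{i:03d}"
            age, sex, icv = make_covariates(rng, 29.0, 4.5, 0.57, 20.0, 40.0)
            s = Subject(id=sid, age=age, sex=sex, icv=icv, diagnosis="HC",
                        cohort="young", modalities=(modality, "thickness"))
            add_subject(s)
            shape = make_source_field(rng)
            spill_unit = unit_spill(shape)
            base_unit = _composite_of(spill_unit, labels, n_regions, comp_ids)
            target = float(_truncnorm_draw(rng, mu, sd, lower=0.3))
            u = target / base_unit
            gray_clean = u * spill_unit
            young_vals[modality].append(target)
            if modality == "tau":
                young_vals["mtl"].append(
                    _composite_of(gray_clean, labels, n_regions, ids_mtl))
            overlays[sid][modality] = pet_overlay(sid, modality, shape, u, gray_clean)
            overlays[sid]["thickness"] = thickness_overlay(sid, age, sex, icv, 0.0)
            true_signal[modality][sid] = np.zeros(n_gray, dtype=np.float32)
            true_spillin[modality][sid] = gray_clean.astype(np.float32)
            truth_rows.append({"id": sid, "cohort": "young", "group": "",
                               "abeta_target": target if modality == "abeta" else np.nan,
                               "tau_target": target if modality == "tau" else np.nan,
                               "mtl_target": np.nan, "r_true": np.nan,
                               "theta": np.nan})

    # Truncation cut-points for the old groups come from the generated young
    # sample itself (its mean + z * sd), not from the parent parameters, so
    # that group membership by construction agrees with the normative
    # cut-points the analysis will later derive from the same young cohort.
    z96 = float(stats.norm.ppf(config.percentile / 100.0))

    def _empirical_cut(vals: list[float], fallback: float) -> float:
        if len(vals) >= 10:
            arr = np.asarray(vals)
            return float(arr.mean() + z96 * arr.std(ddof=1))
        return fallback

    trunc_cuts = {"abeta": _empirical_cut(young_vals["abeta"], cuts["abeta"]),
                  "tau": _empirical_cut(young_vals["tau"], cuts["tau"]),
                  "mtl": _empirical_cut(young_vals["mtl"], cuts["mtl"])}

    # -------------------------------------------------- old cohort
    # draw all targets first so effects can be centered at group sample means
    old_draws: dict[str, list[dict]] = {g: [] for g in GROUPS}
    for g in GROUPS:
        mu_a, sd_a = config.group_abeta[g]
        mu_t, sd_t = config.group_tau[g]
        ab_abn = g.startswith("aAb")
        tau_abn = g.endswith("aTau")
        is_aa = g == "aAb/aTau"
        rho = config.group_amplitude_corr if is_aa else 0.0
        dm = config.boundary_margin
        ab_lo = trunc_cuts["abeta"] + dm
        ab_hi = trunc_cuts["abeta"] - dm
        tau_hi = trunc_cuts["tau"] - dm
        mtl_hi = trunc_cuts["mtl"] - dm
        for _ in range(int(config.n_per_group.get(g, 0))):
            if rho != 0.0:
                # Gaussian copula: correlated amyloid/tau severity, with the
                # amyloid margin truncated above its cut as the group requires.
                z1 = rng.standard_normal()
                z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal()
                q1 = float(np.clip(stats.norm.cdf(z1), 1e-12, 1.0 - 1e-12))
                a_lo = (ab_lo - mu_a) / sd_a
                T_a = float(stats.truncnorm.ppf(q1, a_lo, np.inf,
                                                loc=mu_a, scale=sd_a))
                T_t = float(max(mu_t + sd_t * z2, 0.3))
            else:
                if ab_abn:
                    T_a = float(_truncnorm_draw(rng, mu_a, sd_a, lower=ab_lo))
                else:
                    T_a = float(_truncnorm_draw(rng, mu_a, sd_a, lower=0.3,
                                                upper=ab_hi))
                if tau_abn:
                    T_t = float(max(rng.normal(mu_t, sd_t), 0.3))
            if tau_abn:
                if T_t > trunc_cuts["tau"] + dm:
                    T_m = float(max(T_t + rng.normal(0.0, 0.05), 0.3))
                else:
                    # global tau too close to its cut to carry abnormality:
                    # medial-temporal tau does, clear of the boundary
                    T_m = float(trunc_cuts["mtl"] + dm
                                + abs(rng.normal(0.03, 0.02)))
            else:
                T_t = float(_truncnorm_draw(rng, mu_t, sd_t, lower=0.3,
                                            upper=tau_hi))
                T_m = float(_truncnorm_draw(rng, T_t, 0.02, lower=0.3,
                                            upper=mtl_hi))
            old_draws[g].append({"T_a": T_a, "T_t": T_t, "T_m": T_m})

    idx = 0
    for g in GROUPS:
        draws = old_draws[g]
        if not draws:
            continue
        mean_Ta = float(np.mean([d["T_a"] for d in draws]))
        mean_Tt = float(np.mean([d["T_t"] for d in draws]))
        age_mu, age_sd, f_frac, mci_frac = GROUP_DEMOGRAPHICS[g]
        is_aa = g == "aAb/aTau"
        tau_abn = g.endswith("aTau")
        ab_norm = g.startswith("nAb")
        r_list = []
        sub_cache = []
        for d in draws:
            sid = f"old{idx:04d}"
            idx += 1
            age, sex, icv = make_covariates(rng, age_mu, age_sd, f_frac,
                                            55.0, 95.0)
            dx = "MCI" if rng.random() < mci_frac else "HC"
            s = Subject(id=sid, age=age, sex=sex, icv=icv, diagnosis=dx,
                        cohort="old", modalities=("abeta", "tau", "thickness"))
            add_subject(s)

            # amyloid field
            shape_a = make_source_field(rng)
            spill_a = unit_spill(shape_a)
            base_a = float(_truncnorm_draw(rng, *config.young_abeta, lower=0.3))
            u_a = base_a / _composite_of(spill_a, labels, n_regions, ids_ab)
            M_a = P_full if is_aa else P_ab
            a_amp = (d["T_a"] - base_a) / _composite_of(M_a, labels, n_regions, ids_ab)
            sig_a = a_amp * M_a
            clean_a = u_a * spill_a + sig_a

            # tau field: mixed pattern in the doubly abnormal group
            shape_t = make_source_field(rng)
            spill_t = unit_spill(shape_t)
            base_t = float(_truncnorm_draw(rng, *config.young_tau, lower=0.3))
            u_t = base_t / _composite_of(spill_t, labels, n_regions, ids_tau)
            base_t_mtl = u_t * _composite_of(spill_t, labels, n_regions, ids_mtl)
            theta = float(rng.uniform(0.0, theta_max)) if is_aa else 0.0
            if is_aa:
                q = gaussian_filter(rng.standard_normal(grid), 4.0,
                                    mode="nearest").ravel()
                q = (q - q.mean()) / (q.std() or 1.0) * P_full.std()
                M_t = np.cos(theta) * P_full + np.sin(theta) * q
            else:
                M_t = P_tau
            A = np.array([
                [_composite_of(M_t, labels, n_regions, ids_tau),
                 _composite_of(P_mtl, labels, n_regions, ids_tau)],
                [_composite_of(M_t, labels, n_regions, ids_mtl),
                 _composite_of(P_mtl, labels, n_regions, ids_mtl)]])
            rhs = np.array([d["T_t"] - base_t, d["T_m"] - base_t_mtl])
            b_amp, c_amp = np.linalg.solve(A, rhs)
            sig_t = b_amp * M_t + c_amp * P_mtl
            clean_t = u_t * spill_t + sig_t

            r_true = float(np.corrcoef(clean_a, clean_t)[0, 1])
            r_list.append(r_true)

            overlays[sid]["abeta"] = pet_overlay(sid, "abeta", shape_a, u_a, clean_a)
            overlays[sid]["tau"] = pet_overlay(sid, "tau", shape_t, u_t, clean_t)
            true_signal["abeta"][sid] = sig_a.astype(np.float32)
            true_signal["tau"][sid] = sig_t.astype(np.float32)
            true_spillin["abeta"][sid] = (u_a * spill_a).astype(np.float32)
            true_spillin["tau"][sid] = (u_t * spill_t).astype(np.float32)
            sub_cache.append((s, d, r_true))
            truth_rows.append({"id": sid, "cohort": "old", "group": g,
                               "abeta_target": d["T_a"], "tau_target": d["T_t"],
                               "mtl_target": d["T_m"], "r_true": r_true,
                               "theta": theta})

        mean_r = float(np.mean(r_list))
        mask_ab = np.isin(labels, ids_ab)
        mask_tau = np.isin(labels, ids_tau)
        for s, d, r_true in sub_cache:
            extra = np.zeros(n_gray)
            if ab_norm and config.beta_abeta_pos != 0.0:
                extra += config.beta_abeta_pos * (d["T_a"] - mean_Ta) * mask_ab
            beta_tau = config.beta_tau_neg if tau_abn else config.beta_tau_pos
            if beta_tau != 0.0:
                extra += beta_tau * (d["T_t"] - mean_Tt) * mask_tau
            if is_aa and config.beta_resonance != 0.0:
                extra += config.beta_resonance * (r_true - mean_r)
            overlays[s.id]["thickness"] = thickness_overlay(
                s.id, s.age, s.sex, s.icv, extra)

    frame = pd.DataFrame(truth_rows).set_index("id")
    effects = {k: getattr(config, k) for k in
               ("beta_abeta_pos", "beta_tau_pos", "beta_tau_neg",
                "beta_resonance", "beta_age", "beta_sex", "beta_icv",
                "spillin_slope")}
    truth = GroundTruth(frame=frame, effects=effects,
                        true_signal=true_signal, true_spillin=true_spillin,
                        configured_cutpoints={"analytic": cuts,
                                              "truncation": trunc_cuts})
    return SyntheticCohort(subjects=subjects, overlays=overlays,
                           geometry=geom, ground_truth=truth)
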