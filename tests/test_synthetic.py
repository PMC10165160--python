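import numpy as np
import pytest

from abtau.categorize import GROUPS
from abtau.synthetic import (GeneratorConfig, GeneratorError,
                             REGION_ROW_ORDER, build_grid_geometry,
                             generate_cohort, grid_layout)


def test_grid_geometry_guards():
    with pytest.raises(GeneratorError, match="34"):
        build_grid_geometry(grid_shape=(33, 4))
    with pytest.raises(GeneratorError):
        build_grid_geometry(grid_shape=(34, 1))


def test_grid_geometry_structure(grid_geometry):
    nr, nc, pad = 34, 4, 6
    layout = grid_layout((nr, nc), padding=pad)
    assert layout["n_total"] == grid_geometry.n_vertices
    assert (grid_geometry.tissue == "gray").sum() == nr * nc
    sheet = (nr + 2 * pad) * (nc + 2 * pad)
    assert (grid_geometry.tissue == "white").sum() == sheet
    assert (grid_geometry.tissue == "meninges").sum() == sheet
    # 34 parcels per hemisphere, every gray vertex labeled
    assert len(grid_geometry.region_table) == 2 * len(REGION_ROW_ORDER)
    gray_regions = grid_geometry.region[grid_geometry.gray_mask]
    assert set(gray_regions) == set(range(68))
    # hemispheres split at the column midline
    gray_hemi = grid_geometry.hemisphere[grid_geometry.gray_mask]
    assert (gray_hemi == "L").sum() == (gray_hemi == "R").sum() == nr * nc // 2


def test_sheets_extend_beyond_psf_reach():
    """Padding must cover the truncated-kernel radius so edge gray vertices
    see the same source neighborhood as interior ones."""
    cfg = GeneratorConfig()
    sigma = cfg.psf_fwhm_mm / 2.3548200450309493
    assert cfg.sheet_padding_cells * cfg.spacing_mm >= 3.5 * sigma


def test_generator_is_deterministic(small_cohort):
    cfg, cohort = small_cohort
    again = generate_cohort(GeneratorConfig(**{**cfg.__dict__}))
    assert [s.id for s in again.subjects] == [s.id for s in cohort.subjects]
    for sid in ("ya000", "yt005", "old0000", "old0119"):
        for m, ov in cohort.overlays[sid].items():
            np.testing.assert_array_equal(again.overlays[sid][m].values,
                                          ov.values)
    assert again.ground_truth.frame.equals(cohort.ground_truth.frame)


def test_cohort_bookkeeping(small_cohort):
    cfg, cohort = small_cohort
    frame = cohort.subject_frame
    assert len(frame) == 30 + 20 + 4 * 30
    assert (frame.loc[frame.cohort == "young", "age"].between(20, 40)).all()
    assert (frame.loc[frame.cohort == "old", "age"].between(55, 95)).all()
    assert (frame["icv"] >= 9.0e5).all()
    truth = cohort.ground_truth.frame
    assert (truth.loc[truth.cohort == "old", "group"]
            .value_counts() == 30).all()
    # every overlay validates against the geometry; thickness non-negative
    for sid, mods in cohort.overlays.items():
        for ov in mods.values():
            ov.validate(cohort.geometry)
        th = mods["thickness"].values[cohort.geometry.gray_mask]
        assert (th >= 0).all()


def test_young_gray_signal_is_pure_spillin(small_cohort):
    _, cohort = small_cohort
    truth = cohort.ground_truth
    for modality in ("abeta", "tau"):
        for sid, sig in truth.true_signal[modality].items():
            if sid.startswith(("ya", "yt")):
                assert not sig.any()
    # young composite targets follow the configured parent distributions
    ya = truth.frame.query("cohort == 'young'")["abeta_target"].dropna()
    yt = truth.frame.query("cohort == 'young'")["tau_target"].dropna()
    assert ya.mean() == pytest.approx(1.11, abs=4 * 0.06 / np.sqrt(len(ya)))
    assert yt.mean() == pytest.approx(0.90, abs=4 * 0.10 / np.sqrt(len(yt)))


def test_group_targets_respect_truncation_and_margin(small_cohort):
    cfg, cohort = small_cohort
    truth = cohort.ground_truth
    cuts = truth.configured_cutpoints["truncation"]
    assert set(cuts) == {"abeta", "tau", "mtl"}
    dm = cfg.boundary_margin
    old = truth.frame.query("cohort == 'old'")
    for g in GROUPS:
        sub = old[old.group == g]
        if g.startswith("aAb"):
            assert (sub["abeta_target"] >= cuts["abeta"] + dm - 1e-12).all()
        else:
            assert (sub["abeta_target"] <= cuts["abeta"] - dm + 1e-12).all()
        tau_abn = (np.maximum(sub["tau_target"] - cuts["tau"],
                              sub["mtl_target"] - cuts["mtl"]))
        if g.endswith("aTau"):
            assert (tau_abn >= dm - 1e-12).all()
        else:
            assert (sub["tau_target"] <= cuts["tau"] - dm + 1e-12).all()
            assert (sub["mtl_target"] <= cuts["mtl"] - dm + 1e-12).all()


def test_group_severity_ordering(small_cohort):
    _, cohort = small_cohort
    old = cohort.ground_truth.frame.query("cohort == 'old'")
    mean_ab = old.groupby("group")["abeta_target"].mean()
    mean_tau = old.groupby("group")["tau_target"].mean()
    assert mean_ab["aAb/aTau"] > mean_ab["aAb/nTau"] > mean_ab["nAb/nTau"]
    assert mean_tau["aAb/aTau"] > mean_tau["nAb/aTau"] > mean_tau["nAb/nTau"]


def test_resonance_is_discriminative_by_construction(small_cohort):
    _, cohort = small_cohort
    old = cohort.ground_truth.frame.query("cohort == 'old'")
    r = old.groupby("group")["r_true"].mean()
    assert r["aAb/aTau"] > 0.3
    for g in ("nAb/nTau", "aAb/nTau", "nAb/aTau"):
        assert abs(r[g]) < 0.2
        assert r["aAb/aTau"] > r[g] + 0.25


def test_true_composites_match_targets(small_cohort):
    """Noiseless gray fields reproduce the drawn composite targets exactly."""
    from abtau.quantify import default_definitions
    _, cohort = small_cohort
    geom = cohort.geometry
    labels = geom.region[geom.gray_mask]
    defs = default_definitions()
    ids_ab = defs["global_abeta"].resolve_ids(geom, strict=False)
    ids_tau = defs["global_tau"].resolve_ids(geom, strict=False)
    truth = cohort.ground_truth
    old = truth.frame.query("cohort == 'old'")
    for sid in old.index[::17]:
        clean_ab = (truth.true_spillin["abeta"][sid]
                    + truth.true_signal["abeta"][sid]).astype(float)
        clean_tau = (truth.true_spillin["tau"][sid]
                     + truth.true_signal["tau"][sid]).astype(float)
        import pandas as pd
        means_ab = pd.Series(clean_ab).groupby(labels).mean()
        means_tau = pd.Series(clean_tau).groupby(labels).mean()
        assert means_ab[ids_ab].mean() == pytest.approx(
            old.loc[sid, "abeta_target"], abs=1e-4)
        assert means_tau[ids_tau].mean() == pytest.approx(
            old.loc[sid, "tau_target"], abs=1e-4)


def test_cohort_save_writes_truth(tmp_path, small_cohort):
    _, cohort = small_cohort
    out = tmp_path / "cohort"
    cohort.save(out)
    assert (out / "ground_truth" / "truth.csv").exists()
    assert (out / "ground_truth" / "effects.json").exists()
    assert (out / "subjects.csv").exists() or any(out.iterdir())
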