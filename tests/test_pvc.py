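import numpy as np
import pytest

from abtau.pvc import (PSFModel, PVCError, SpillInModel, SpillinOperator,
                       apply_pvc, fit_spillin_model, synthesize_spillin)

from conftest import overlay_on


def test_psf_sigma_from_fwhm():
    psf = PSFModel(fwhm_mm=6.0)
    assert psf.sigma_mm == pytest.approx(6.0 / 2.3548200450309493, rel=1e-12)
    with pytest.raises(PVCError):
        PSFModel(fwhm_mm=0.0)
    with pytest.raises(PVCError):
        PSFModel(kind="boxcar")


def test_kernel_closed_form(tiny_geometry):
    """Single-source spill weights follow the truncated, per-source-normalized
    Gaussian computed by hand."""
    psf = PSFModel(fwhm_mm=6.0, cutoff_sigmas=3.5)
    sigma = psf.sigma_mm
    op = SpillinOperator(tiny_geometry, psf)
    vals = np.zeros(8)
    vals[0] = 2.0  # white source at the origin only
    got = op.synthesize(vals)

    coords = tiny_geometry.coordinates
    live = tiny_geometry.tissue != "excluded"
    radius = psf.cutoff_sigmas * sigma
    d = np.linalg.norm(coords - coords[0], axis=1)
    w = np.where((d <= radius) & live, np.exp(-d ** 2 / (2 * sigma ** 2)), 0.0)
    w = w / w.sum()  # per-source activity conservation over live support
    expected = 2.0 * w[tiny_geometry.gray_mask]
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_kernel_conserves_source_activity(grid_geometry):
    """Column sums of the kernel over *all* live vertices equal 1; the
    gray-row synthesis therefore never exceeds the source total."""
    psf = PSFModel(fwhm_mm=6.0)
    op = SpillinOperator(grid_geometry, psf)
    vals = np.zeros(grid_geometry.n_vertices)
    vals[grid_geometry.source_mask] = 1.0
    total_spill_to_gray = op.synthesize(vals).sum()
    assert total_spill_to_gray <= grid_geometry.source_mask.sum() + 1e-9


def test_synthesize_spillin_is_linear(tiny_geometry):
    psf = PSFModel(fwhm_mm=6.0)
    op = SpillinOperator(tiny_geometry, psf)
    rng = np.random.default_rng(0)
    a = np.abs(rng.normal(1, 0.2, 8))
    b = np.abs(rng.normal(1, 0.2, 8))
    sa = synthesize_spillin(overlay_on(tiny_geometry, a), tiny_geometry, psf,
                            operator=op)
    sb = synthesize_spillin(overlay_on(tiny_geometry, b), tiny_geometry, psf,
                            operator=op)
    sab = synthesize_spillin(overlay_on(tiny_geometry, 2 * a + 3 * b),
                             tiny_geometry, psf, operator=op)
    np.testing.assert_allclose(sab, 2 * sa + 3 * sb, atol=1e-12)


def _noise_free_young(geometry, op, intercept, slope, amplitudes):
    """Young overlays whose gray uptake is exactly intercept + slope*spill."""
    out = []
    for i, amp in enumerate(amplitudes):
        vals = np.zeros(geometry.n_vertices)
        vals[geometry.source_mask] = amp
        spill = op.synthesize(vals)
        vals[geometry.gray_mask] = intercept + slope * spill
        out.append(overlay_on(geometry, vals, subject_id=f"y{i}"))
    return out


def test_fit_recovers_exact_linear_model(tiny_geometry):
    psf = PSFModel(fwhm_mm=6.0)
    op = SpillinOperator(tiny_geometry, psf)
    young = _noise_free_young(tiny_geometry, op, 0.1, 0.5,
                              [0.8, 1.0, 1.2, 1.5])
    model = fit_spillin_model(young, tiny_geometry, psf, operator=op)
    np.testing.assert_allclose(model.intercept, 0.1, atol=1e-9)
    np.testing.assert_allclose(model.slope, 0.5, atol=1e-9)
    assert not model.degenerate.any()

    # applying the model to a noise-free subject removes all gray signal
    test = _noise_free_young(tiny_geometry, op, 0.1, 0.5, [1.1])[0]
    corrected = apply_pvc(test, model, tiny_geometry, operator=op)
    np.testing.assert_allclose(corrected.values[tiny_geometry.gray_mask],
                               0.0, atol=1e-9)
    # non-gray vertices pass through unchanged
    src = tiny_geometry.source_mask
    np.testing.assert_array_equal(corrected.values[src], test.values[src])


def test_fit_requires_three_subjects(tiny_geometry):
    psf = PSFModel(fwhm_mm=6.0)
    op = SpillinOperator(tiny_geometry, psf)
    young = _noise_free_young(tiny_geometry, op, 0.0, 0.5, [1.0, 1.1])
    with pytest.raises(PVCError):
        fit_spillin_model(young, tiny_geometry, psf, operator=op)


def test_degenerate_regressor_falls_back_to_intercept(tiny_geometry):
    """Identical source fields across subjects leave the regressor constant;
    the model must flag that and use the mean observed uptake."""
    psf = PSFModel(fwhm_mm=6.0)
    op = SpillinOperator(tiny_geometry, psf)
    overlays = []
    for i, g in enumerate([0.9, 1.0, 1.1]):
        vals = np.zeros(8)
        vals[tiny_geometry.source_mask] = 1.0  # same every subject
        vals[tiny_geometry.gray_mask] = g
        overlays.append(overlay_on(tiny_geometry, vals, subject_id=f"y{i}"))
    model = fit_spillin_model(overlays, tiny_geometry, psf, operator=op)
    assert model.degenerate.all()
    np.testing.assert_allclose(model.slope, 0.0)
    np.testing.assert_allclose(model.intercept, 1.0, atol=1e-12)


def test_clamp_at_zero_option(tiny_geometry):
    psf = PSFModel(fwhm_mm=6.0)
    op = SpillinOperator(tiny_geometry, psf)
    young = _noise_free_young(tiny_geometry, op, 0.2, 0.5, [0.8, 1.0, 1.2])
    model = fit_spillin_model(young, tiny_geometry, psf, operator=op)
    vals = np.zeros(8)
    vals[tiny_geometry.source_mask] = 1.0
    vals[tiny_geometry.gray_mask] = 0.01  # below the modelled spill-in
    ov = overlay_on(tiny_geometry, vals)
    raw = apply_pvc(ov, model, tiny_geometry, operator=op)
    assert (raw.values[tiny_geometry.gray_mask] < 0).all()  # retained
    clamped = apply_pvc(ov, model, tiny_geometry, operator=op,
                        clamp_at_zero=True)
    assert (clamped.values[tiny_geometry.gray_mask] == 0).all()


def test_model_save_load_roundtrip(tmp_path, tiny_geometry):
    psf = PSFModel(fwhm_mm=5.0, cutoff_sigmas=3.0)
    op = SpillinOperator(tiny_geometry, psf)
    young = _noise_free_young(tiny_geometry, op, 0.1, 0.7, [0.8, 1.0, 1.3])
    model = fit_spillin_model(young, tiny_geometry, psf, operator=op)
    model.save(tmp_path / "m")
    back = SpillInModel.load(tmp_path / "m")
    np.testing.assert_array_equal(back.intercept, model.intercept)
    np.testing.assert_array_equal(back.slope, model.slope)
    assert back.psf == psf
    assert back.n_train == 3
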