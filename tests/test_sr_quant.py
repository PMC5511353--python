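"""Rendering, segmentation, classification rules and ROI metrics."""

import numpy as np
import pytest

from ccsquant import (
    CellOutline,
    ClassifierParams,
    LocalizationTable,
    RenderedImage,
    analyze_scene,
    ccs_metrics,
    classify_object,
    peripheral_roi,
    render,
    segment,
)
from ccsquant.errors import ComputationError, ParameterError
from ccsquant.sr_quant import (
    RoiBand,
    SegmentedObject,
    detect_embedded_pits,
    display_filter,
    estimate_background_brightness,
    object_mask,
    objects_from_labels,
)


def make_obj(
    d_nm=150.0,
    circularity=0.85,
    holes=0,
    ratio=3.0,
    feret_min=None,
    feret_max=None,
) -> SegmentedObject:
    """Craft a SegmentedObject with explicit morphometrics."""
    area_px = np.pi * (d_nm / 2) ** 2 / 400.0
    return SegmentedObject(
        label=1,
        pixels=np.zeros((max(int(area_px), 2), 2), dtype=int),
        pixel_size_nm=20.0,
        origin_nm=(0.0, 0.0),
        centroid_nm=(0.0, 0.0),
        area_um2=area_px * 4e-4,
        perimeter_um=0.1,
        circularity=circularity,
        equivalent_diameter_nm=d_nm,
        feret_max_nm=feret_max if feret_max is not None else d_nm,
        feret_min_nm=feret_min if feret_min is not None else d_nm,
        hole_count=holes,
        mean_brightness=ratio,
        brightness_ratio=ratio,
    )


# ---------------------------------------------------------------- rendering
def test_histogram_single_localization_lands_in_pixel():
    table = LocalizationTable.from_arrays([1010.0], [1010.0])
    img = render(table, 20.0, "histogram", bounds_nm=(0, 0, 2000, 2000))
    assert img.pixels[50, 50] == 1.0
    assert img.total_mass == 1.0


def test_default_pixel_size_is_20nm():
    import inspect

    assert inspect.signature(render).parameters["pixel_size_nm"].default == 20.0


def test_gaussian_render_conserves_mass(rng):
    n = 500
    table = LocalizationTable.from_arrays(
        rng.uniform(500, 1500, n), rng.uniform(500, 1500, n), uncertainty_nm=15.0
    )
    img = render(table, 20.0, "normalized_gaussian")
    assert img.total_mass == pytest.approx(n, rel=1e-3)


def test_render_empty_and_bad_pixel():
    img = render(LocalizationTable.empty(), 20.0, "histogram")
    assert img.total_mass == 0.0
    with pytest.raises(ParameterError):
        render(LocalizationTable.empty(), -1.0)


# ---------------------------------------------------------------- display filter
def test_display_filter_constant_unchanged():
    img = RenderedImage(np.full((10, 10), 3.0))
    out = display_filter(img)
    assert np.allclose(out.pixels, 3.0)
    assert out.display_only


def test_display_filter_impulse_and_mass():
    px = np.zeros((9, 9))
    px[4, 4] = 9.0
    out = display_filter(RenderedImage(px))
    assert np.allclose(out.pixels[3:6, 3:6], 1.0)
    assert out.pixels.sum() == pytest.approx(9.0)  # interior mass conserved


def test_display_filtered_image_refuses_quantification():
    out = display_filter(RenderedImage(np.ones((5, 5))))
    with pytest.raises(ParameterError):
        segment(out)


# ---------------------------------------------------------------- background
def test_background_uniform_value():
    img = RenderedImage(np.full((50, 50), 0.5))
    assert estimate_background_brightness(img) == pytest.approx(0.5)


def test_background_empty_image_is_zero():
    assert estimate_background_brightness(RenderedImage(np.zeros((10, 10)))) == 0.0


def test_background_poisson_conditional_mean_oracle(rng):
    mu = 0.2
    img = RenderedImage(rng.poisson(mu, (400, 400)).astype(float))
    est = estimate_background_brightness(img)
    oracle = mu / (1 - np.exp(-mu))
    # 3 sd of the conditional mean estimate (Monte-Carlo calibrated scale)
    sims = [
        np.mean(v[v > 0])
        for v in (rng.poisson(mu, (400 * 400,)) for _ in range(60))
    ]
    assert abs(est - oracle) <= 3 * np.std(sims)


# ---------------------------------------------------------------- segmentation
def _disk_image(radius_px, value=10.0, shape=(64, 64), centre=None):
    h, w = shape
    cy, cx = centre or (h // 2, w // 2)
    yy, xx = np.mgrid[0:h, 0:w]
    px = np.where((yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2, value, 0.0)
    return RenderedImage(px, 20.0)


def test_two_disks_two_objects():
    img = _disk_image(5, centre=(15, 15))
    img.pixels += _disk_image(5, centre=(48, 48)).pixels
    objs = segment(img, ClassifierParams(threshold=1.0))
    assert len(objs) == 2


def test_disk_circularity_matches_boundary_walk_oracle():
    img = _disk_image(10)
    obj = segment(img, ClassifierParams(threshold=1.0))[0]
    # oracle: marching-squares boundary walk on the same rasterization
    from skimage import measure

    mask = img.pixels > 1.0
    contour = measure.find_contours(mask.astype(float), 0.5)[0]
    per = np.sum(np.hypot(*np.diff(contour, axis=0).T))
    oracle = 4 * np.pi * mask.sum() / per**2
    assert obj.circularity == pytest.approx(oracle, abs=0.1)


def test_equivalent_diameter_closed_form():
    px = np.zeros((30, 30))
    px[10:20, 10:20] = 5.0  # 100 pixels
    obj = segment(RenderedImage(px, 20.0), ClassifierParams(threshold=1.0))[0]
    assert obj.equivalent_diameter_nm == pytest.approx(2 * np.sqrt(100 / np.pi) * 20)


def test_blank_image_gives_empty_list():
    assert segment(RenderedImage(np.zeros((20, 20))), ClassifierParams(threshold=0.5)) == []


def test_sub_2px_objects_discarded():
    px = np.zeros((10, 10))
    px[3, 3] = 5.0
    assert segment(RenderedImage(px, 20.0), ClassifierParams(threshold=1.0)) == []


def test_donut_object_has_hole():
    img = _disk_image(8)
    yy, xx = np.mgrid[0:64, 0:64]
    img.pixels[(yy - 32) ** 2 + (xx - 32) ** 2 <= 3**2] = 0.0
    obj = segment(img, ClassifierParams(threshold=1.0))[0]
    assert obj.hole_count == 1


# ---------------------------------------------------------------- classification
@pytest.mark.parametrize(
    "obj,expected",
    [
        (make_obj(150, circularity=0.85, ratio=3.0), "pit"),
        (make_obj(500, circularity=0.3, ratio=1.2, feret_min=600), "plaque"),
        (make_obj(150, circularity=0.9, ratio=1.0), "unclassified"),
        (make_obj(150, circularity=0.4, holes=1, ratio=3.0), "pit"),  # donut rescue
        (make_obj(150, circularity=0.4, holes=0, ratio=3.0, feret_min=150), "unclassified"),
        (make_obj(250, circularity=0.9, ratio=3.0, feret_min=250), "unclassified"),
    ],
)
def test_rule_table(obj, expected):
    assert classify_object(obj, ClassifierParams()) == expected


def test_rule_boundaries_closed_and_open():
    params = ClassifierParams()
    # diameter bounds are a closed interval
    assert classify_object(make_obj(100.0), params) == "pit"
    assert classify_object(make_obj(200.0), params) == "pit"
    assert classify_object(make_obj(99.999), params) == "unclassified"
    # brightness 2.0 exactly: pit rule passes (>=), plaque rule fails (<)
    assert classify_object(make_obj(150, ratio=2.0), params) == "pit"
    assert (
        classify_object(make_obj(500, circularity=0.3, ratio=2.0, feret_min=600), params)
        == "unclassified"
    )
    # min Feret exactly at 200 nm fails the strict plaque bound
    assert (
        classify_object(make_obj(300, circularity=0.3, ratio=1.0, feret_min=200), params)
        == "unclassified"
    )
    # circularity boundary
    assert classify_object(make_obj(150, circularity=0.7), params) == "pit"


def test_classify_requires_background():
    obj = make_obj()
    obj.brightness_ratio = None
    with pytest.raises(ComputationError):
        classify_object(obj, ClassifierParams())


# ---------------------------------------------------------------- embedded pits
def test_plaque_without_bright_subregion_unchanged():
    px = np.full((40, 40), 1.3)
    img = RenderedImage(px, 20.0)
    plaque = segment(img, ClassifierParams(threshold=1.0))[0]
    plaque.brightness_ratio = 1.3
    plaque.cls = "plaque"
    pits, residual = detect_embedded_pits(plaque, img, ClassifierParams(), 1.0)
    assert pits == []
    assert residual is plaque


def test_embedded_pit_recovered_and_disjoint():
    px = np.zeros((60, 60))
    px[10:50, 10:50] = 1.3  # plaque footprint, 800 nm square
    yy, xx = np.mgrid[0:60, 0:60]
    pit_mask = (yy - 30) ** 2 + (xx - 30) ** 2 <= 3.5**2  # ~140 nm disk
    px[pit_mask] += 3.0
    img = RenderedImage(px, 20.0)
    objs = segment(img, ClassifierParams(threshold=1.0))
    plaque = objs[0]
    plaque.brightness_ratio = 1.4
    plaque.cls = "plaque"
    pits, residual = detect_embedded_pits(plaque, img, ClassifierParams(), 1.0)
    assert len(pits) == 1
    assert 100 <= pits[0].equivalent_diameter_nm <= 200
    pit_px = {tuple(p) for p in pits[0].pixels}
    res_px = {tuple(p) for p in residual.pixels}
    assert not pit_px & res_px


# ---------------------------------------------------------------- ROI + metrics
def square_cell(side_um=20.0):
    s = side_um * 1000
    return CellOutline([[0, 0], [s, 0], [s, s], [0, s]])


def test_peripheral_band_area_square_cell():
    roi = peripheral_roi(square_cell(20.0), width_um=3.0, pixel_size_nm=100.0)
    assert roi.area_um2 == pytest.approx(400 - 196, rel=0.02)


def test_band_default_width_is_3um():
    import inspect

    assert inspect.signature(peripheral_roi).parameters["width_um"].default == 3.0


def test_band_wider_than_inradius_falls_back_to_cell():
    with pytest.warns(UserWarning):
        roi = peripheral_roi(square_cell(10.0), width_um=5.0, pixel_size_nm=100.0)
    assert roi.area_um2 == pytest.approx(100.0, rel=0.02)


def _roi_of_area(area_um2, pixel_size_nm=20.0):
    n = int(area_um2 / (pixel_size_nm / 1000.0) ** 2)
    side = int(np.ceil(np.sqrt(n)))
    mask = np.zeros((side, side + 1), dtype=bool)
    mask.ravel()[:n] = True
    return RoiBand(None, 3.0, mask, pixel_size_nm, (0.0, 0.0))


def test_pit_density_formula():
    roi = _roi_of_area(5.0)
    pits = []
    for _ in range(10):
        o = make_obj(150)
        o.cls = "pit"
        o.centroid_nm = (10.0, 10.0)  # inside ROI
        pits.append(o)
    m = ccs_metrics(pits, roi)
    assert m.pit_density_per_um2 == pytest.approx(2.0)
    assert m.n_pits == 10


def test_plaque_area_fraction_formula():
    roi = _roi_of_area(4.0)
    n_px = int(1.0 / 4e-4)  # 1 um^2 of 20-nm pixels
    rows, cols = np.nonzero(roi.mask)
    o = make_obj(800)
    o.cls = "plaque"
    o.pixels = np.column_stack([rows[:n_px], cols[:n_px]])
    m = ccs_metrics([o], roi)
    assert m.plaque_area_fraction == pytest.approx(0.25)


def test_no_objects_zero_metrics():
    m = ccs_metrics([], _roi_of_area(4.0))
    assert m.pit_density_per_um2 == 0.0
    assert m.plaque_area_fraction == 0.0


def test_zero_area_roi_is_error():
    empty = RoiBand(None, 3.0, np.zeros((5, 5), dtype=bool), 20.0, (0.0, 0.0))
    with pytest.raises(ComputationError):
        ccs_metrics([], empty)


# ---------------------------------------------------------------- invariances
def test_metrics_invariant_under_row_permutation(default_config):
    from ccsquant import simulate_scene

    table, _ = simulate_scene(default_config, 10, 1)
    bounds = (0, 0, *default_config.field_size_nm)
    m1 = analyze_scene(table, bounds_nm=bounds)["metrics"]
    shuffled = LocalizationTable(
        table.data.sample(frac=1.0, random_state=0).reset_index(drop=True)
    )
    m2 = analyze_scene(shuffled, bounds_nm=bounds)["metrics"]
    assert m1 == m2


def test_object_mask_covers_object_pixels():
    img = _disk_image(5)
    objs = segment(img, ClassifierParams(threshold=1.0))
    mask = object_mask(objs, img.pixels.shape)
    assert mask.sum() == objs[0].n_pixels
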