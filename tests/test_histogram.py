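"""Quantization, histogram accounting, dominant code, exports, pseudo-color."""

import numpy as np
import pandas as pd
import pytest

from mangocolor import colorspace, histogram, ncs, segmentation
from mangocolor.pipeline import measure_image


def measure(fruit_factory, mixture, **kw):
    img, truth = fruit_factory(mixture, **kw)
    record, qfield, seg = measure_image(img)
    return img, truth, record, qfield, seg


def test_quantize_pixel_idempotent_on_worked_example(chart):
    code = ncs.parse_code("1050-Y40R")
    rgb = np.asarray(ncs.representative_rgb(code)) / 255.0
    hsi = colorspace.rgb_to_hsi(rgb)
    assert histogram.quantize_pixel(float(hsi.hue_deg), float(hsi.saturation),
                                    float(hsi.intensity)) == code


def test_quantize_tie_resolves_to_lower_step(chart):
    # saturation exactly midway between steps 20 and 30 -> 20
    hi, ci, bi = chart.quantize_hsv(60.0, 0.25, 0.95)
    assert chart.chromaticness_steps[int(ci)] == 20
    # blackness midway between 5 and 10 -> 5
    hi, ci, bi = chart.quantize_hsv(60.0, 0.30, 1.0 - 0.075)
    assert chart.blackness_steps[int(bi)] == 5


def test_quantizer_agrees_with_brute_force_search(chart, rng):
    rgb = rng.uniform(0, 1, size=(1000, 3))
    hsi = colorspace.rgb_to_hsi(rgb)
    value = colorspace.brightness_value(rgb)
    hi, ci, bi = chart.quantize_hsv(hsi.hue_deg, hsi.saturation, value)
    # oracle: exhaustive nearest-neighbor over all 512 codes in
    # (hue angle, saturation step, blackness step) space
    angles = chart.hue_angles
    chroma = np.asarray(chart.chromaticness_steps, float)
    black = np.asarray(chart.blackness_steps, float)
    for k in rng.choice(1000, size=80, replace=False):
        best, best_d = None, np.inf
        for a_i, a in enumerate(angles):
            for c_i, c in enumerate(chroma):
                for b_i, b in enumerate(black):
                    d = ((hsi.hue_deg[k] - a) ** 2 + (hsi.saturation[k] * 100 - c) ** 2
                         + ((1 - value[k]) * 100 - b) ** 2)
                    if d < best_d - 1e-12:
                        best, best_d = (a_i, c_i, b_i), d
        assert (int(hi[k]), int(ci[k]), int(bi[k])) == best


def test_single_code_histograms(fruit_factory):
    _, truth, record, _, _ = measure(fruit_factory, {"0560-Y20R": 1.0})
    h = record.histograms
    assert dict(h.code_table) == {"0560-Y20R": 100.0}
    assert h.hue_hist["Y20R"] == 100.0
    assert h.saturation_hist[60] == 100.0
    assert h.blackness_hist[5] == 100.0


def test_two_code_mixture_recovered_exactly(fruit_factory):
    _, truth, record, _, _ = measure(fruit_factory, {"0560-Y20R": 0.7, "0560-Y40R": 0.3})
    table = record.histograms.code_table
    for label, pct in truth.code_fractions_pct.items():
        assert table[label] == pytest.approx(pct, abs=1e-9)


def test_marginals_sum_and_match_joint(fruit_factory):
    _, _, record, _, _ = measure(
        fruit_factory, {"0560-Y20R": 0.4, "1050-Y40R": 0.3, "2010-G40Y": 0.2},
        black=0.06, red=0.04, seed=5)
    h = record.histograms
    for marg in (h.hue_hist, h.saturation_hist, h.blackness_hist):
        assert marg.sum() == pytest.approx(100.0, abs=1e-9)
    assert h.code_table.sum() == pytest.approx(record.pixel_percentages["color"], abs=1e-9)
    # marginal = sum over the joint table (denominators differ by color share)
    scale = h.n_fruit / h.n_color
    hue_from_joint = {}
    for label, share in h.code_table.items():
        tok = str(ncs.parse_code(label).hue)
        hue_from_joint[tok] = hue_from_joint.get(tok, 0.0) + share * scale
    for tok, v in hue_from_joint.items():
        assert h.hue_hist[tok] == pytest.approx(v, abs=1e-9)


def test_dominant_code_rules_differ_on_constructed_mixture(fruit_factory):
    # hue marginal peaks at Y40R (35+25=60 %), but the joint argmax is 0560-Y20R
    _, truth, record, _, _ = measure(
        fruit_factory, {"0560-Y20R": 0.40, "0560-Y40R": 0.35, "1050-Y40R": 0.25})
    dom = record.dominant
    assert str(dom.marginal_code) == "0560-Y40R"
    assert str(dom.joint_code) == "0560-Y20R"
    assert dom.marginal_peaks["hue"] == pytest.approx(60.0, abs=0.1)
    assert dom.joint_share_pct == pytest.approx(40.0, abs=0.1)


def test_dominant_code_without_color_pixels_raises(fruit_factory):
    img, _ = fruit_factory({}, black=1.0)
    seg, _ = segmentation.segment(img)
    unit = colorspace.normalize_rgb(img)
    qf = histogram.quantize_field(unit, seg.color_mask)
    with pytest.warns(UserWarning, match="no COLOR"):
        h = histogram.build_histograms(qf, seg)
    with pytest.raises(ValueError):
        histogram.dominant_code(h)


def test_top_k_codes_rules(chart, rng):
    table = pd.Series({"0510-G": 10.0, "0530-Y": 10.0, "1050-Y40R": 30.0})
    out = histogram.top_k_codes(table, k=6)
    assert [str(c) for c in out] == ["1050-Y40R", "0510-G", "0530-Y"]  # tie by chart number
    labels = [str(chart.entries[i].code) for i in rng.choice(512, 20, replace=False)]
    shares = rng.uniform(0, 10, 20)
    table = pd.Series(dict(zip(labels, shares)))
    out = histogram.top_k_codes(table, k=6)
    oracle = sorted(table.items(),
                    key=lambda kv: (-kv[1], chart.number_of(ncs.parse_code(kv[0]))))
    assert [str(c) for c in out] == [k for k, _ in oracle[:6]]
    with pytest.raises(ValueError):
        histogram.top_k_codes(table, k=0)


def test_pseudo_color_class_counts(fruit_factory):
    img, truth, record, qfield, seg = measure(
        fruit_factory, {"0560-Y20R": 0.6, "2010-G40Y": 0.3}, black=0.06, red=0.04)
    pal = histogram.default_palette()
    out = histogram.pseudo_color(qfield, seg, palette=pal)
    assert np.all(out[seg.background_mask] == pal["background"])
    assert (np.all(out == pal["black"], axis=-1)).sum() == seg.black_mask.sum()
    assert (np.all(out == pal["red"], axis=-1)).sum() == seg.red_mask.sum()
    n_y20r = (np.all(out == pal["Y20R"], axis=-1)).sum()
    assert n_y20r == (seg.color_mask & (qfield.hue_idx == 12)).sum()


def test_pseudo_color_single_code_two_colors(fruit_factory):
    img, truth, record, qfield, seg = measure(fruit_factory, {"0560-Y20R": 1.0})
    out = histogram.pseudo_color(qfield, seg)
    colors = {tuple(c) for c in out.reshape(-1, 3)}
    assert len(colors) == 2


def test_pseudo_color_palette_permutation(fruit_factory):
    img, truth, record, qfield, seg = measure(fruit_factory, {"0560-Y20R": 0.5, "0530-Y": 0.5})
    pal = histogram.default_palette()
    swapped = dict(pal)
    swapped["Y20R"], swapped["Y"] = pal["Y"], pal["Y20R"]
    a = histogram.pseudo_color(qfield, seg, palette=pal)
    b = histogram.pseudo_color(qfield, seg, palette=swapped)
    m_y20r = seg.color_mask & (qfield.hue_idx == 12)
    assert np.all(a[m_y20r] == pal["Y20R"]) and np.all(b[m_y20r] == pal["Y"])


def test_export_reimport_round_trip(tmp_path, fruit_factory):
    _, _, record, _, _ = measure(
        fruit_factory, {"0560-Y20R": 0.5, "1050-Y40R": 0.4}, black=0.1,
        seed=9, noise_sigma=1.5)
    path = tmp_path / "measurement.csv"
    histogram.export_measurement(record, path)
    back = histogram.read_measurement(path)
    assert back.sample_id == record.sample_id
    assert back.pixel_percentages == pytest.approx(record.pixel_percentages)
    pd.testing.assert_series_equal(back.histograms.hue_hist, record.histograms.hue_hist,
                                   check_names=False)
    pd.testing.assert_series_equal(back.histograms.code_table.sort_index(),
                                   record.histograms.code_table.sort_index(),
                                   check_names=False)
    assert back.dominant.marginal_code == record.dominant.marginal_code
    assert back.dominant.joint_share_pct == record.dominant.joint_share_pct


def test_export_section_order_and_display_precision(tmp_path, fruit_factory):
    _, _, record, _, _ = measure(fruit_factory, {"0560-Y20R": 1.0})
    path = tmp_path / "m.csv"
    histogram.export_measurement(record, path)
    df = pd.read_csv(path)
    order = list(dict.fromkeys(df["section"]))
    assert order == list(histogram.SECTION_ORDER)
    pixel = df[df["section"] == "PIXEL"]
    assert list(pixel["key"]) == ["BLACK", "RED", "COLOR"]
    assert all(len(str(d).split(".")[-1]) == 1 for d in pixel["display"])


def test_noisy_mixture_within_two_points(fruit_factory):
    # sigma = 3 digital levels, fruit >= 1e4 pixels
    mixture = {"0560-Y20R": 0.6, "0560-Y40R": 0.4}
    img, truth, record, _, _ = measure(
        fruit_factory, mixture, shape=(140, 180), noise_sigma=3.0, seed=11)
    assert truth.fruit_pixels >= 10_000
    table = record.histograms.code_table
    for label, pct in truth.code_fractions_pct.items():
        assert table[label] == pytest.approx(pct, abs=2.0)
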