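import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from amyquant.config import SegmentationParams
from amyquant.segmentation import (
    CLASS_DARK,
    CLASS_LIGHT,
    CLASS_NONE,
    RULE_DARK_FRACTION,
    RULE_MIN_AREA,
    RULE_MIN_DARK_AREA,
    RULE_NON_ELLIPTICAL,
    RULE_UNIFORM_INTENSITY,
    BrownClassMask,
    CandidateObject,
    block_mean,
    classify_brown,
    detect_tissue,
    elliptic_fit,
    filter_candidates,
    grow_candidates,
    min_channel_brightness,
)
from amyquant.stains import StainMaps


# ---------------------------------------------------------------------------
# tissue detection


def test_min_channel_examples(rng):
    assert min_channel_brightness(np.array([[[200, 150, 250]]], dtype=np.uint8))[0, 0] == 150
    img = rng.integers(0, 256, size=(20, 20, 3), dtype=np.uint8)
    np.testing.assert_array_equal(
        min_channel_brightness(img),
        np.minimum(np.minimum(img[..., 0], img[..., 1]), img[..., 2]),
    )
    achromatic = np.repeat(rng.integers(0, 256, size=(5, 5, 1), dtype=np.uint8), 3, axis=2)
    np.testing.assert_array_equal(min_channel_brightness(achromatic), achromatic[..., 0])


def test_uniform_raster_yields_empty_tissue_mask():
    tm = detect_tissue(np.full((50, 50), 250.0))
    assert tm.threshold_used == 240.0
    assert not tm.mask.any()


def test_bimodal_raster_thresholds_exactly_at_planted_fraction():
    grey = np.full(10000, 250.0)
    grey[:1000] = 100.0
    tm = detect_tissue(grey.reshape(100, 100))
    assert tm.threshold_used == 240.0
    assert tm.mask.sum() == 1000
    assert np.all(grey.reshape(100, 100)[tm.mask] == 100.0)


def test_threshold_clamped_to_grey_range():
    tm = detect_tissue(np.full((10, 10), 5.0),
                       SegmentationParams(tissue_offset=-10.0))
    assert tm.threshold_used == 0.0


def test_block_mean_averages_blocks_exactly():
    arr = np.arange(16, dtype=float).reshape(4, 4)
    out = block_mean(arr, 2)
    np.testing.assert_array_equal(out, [[2.5, 4.5], [10.5, 12.5]])
    # odd trailing row/col trimmed
    assert block_mean(np.ones((5, 5)), 2).shape == (2, 2)


# ---------------------------------------------------------------------------
# brown classification


def _maps(brown, brown_pos=None):
    brown = np.atleast_2d(np.asarray(brown, dtype=np.float32))
    if brown_pos is None:
        brown_pos = brown
    brown_pos = np.atleast_2d(np.asarray(brown_pos, dtype=np.float32))
    return StainMaps(brown_au=brown, blue_au=brown - brown_pos,
                     brown_pos_au=brown_pos, mpp=1.0)


@pytest.mark.parametrize("brown,brown_pos,expected", [
    (0.2, 0.15, CLASS_LIGHT),    # above both entry thresholds, below dark
    (0.6, 0.3, CLASS_DARK),
    (0.5, 0.3, CLASS_DARK),      # dark threshold is inclusive
    (0.2, 0.05, CLASS_NONE),     # brown-positive condition fails
    (0.15, 0.15, CLASS_NONE),    # entry threshold is strict
    (0.3, 0.1, CLASS_NONE),      # brown-positive threshold is strict
    (0.499999, 0.3, CLASS_LIGHT),
])
def test_classification_boundaries(brown, brown_pos, expected):
    classes = classify_brown(_maps([[brown]], [[brown_pos]]))
    assert classes.labels[0, 0] == expected


@given(hnp.arrays(np.float32, (8, 8), elements=st.floats(0, 1, width=32)))
def test_every_pixel_gets_exactly_one_class(brown):
    labels = classify_brown(_maps(brown)).labels
    assert set(np.unique(labels)) <= {CLASS_NONE, CLASS_LIGHT, CLASS_DARK}


# ---------------------------------------------------------------------------
# seed growing


def _classes_from_labels(labels, brown=None):
    labels = np.asarray(labels, dtype=np.uint8)
    if brown is None:
        brown = np.where(labels == CLASS_DARK, 0.8, np.where(labels == CLASS_LIGHT, 0.3, 0.0))
    return BrownClassMask(labels=labels, brown_au=brown.astype(np.float32), mpp=1.0)


def test_dark_blob_grows_into_light_ring():
    labels = np.zeros((7, 7), dtype=np.uint8)
    labels[2:5, 2:5] = CLASS_LIGHT      # 3x3 ring ...
    labels[3, 2:5] = CLASS_DARK         # ... around a 1x3 dark bar
    cands = grow_candidates(_classes_from_labels(labels))
    assert len(cands) == 1
    assert len(cands[0].pixels) == 9
    assert cands[0].dark_area_um2 == 3.0


def test_isolated_dark_blob_is_its_own_candidate():
    labels = np.zeros((5, 5), dtype=np.uint8)
    labels[1:3, 1:3] = CLASS_DARK
    cands = grow_candidates(_classes_from_labels(labels))
    assert len(cands) == 1
    assert cands[0].area_um2 == 4.0
    assert cands[0].dark_area_um2 == 4.0


def test_light_bridge_merges_two_seeds():
    labels = np.zeros((3, 9), dtype=np.uint8)
    labels[1, 0:2] = CLASS_DARK
    labels[1, 2:7] = CLASS_LIGHT
    labels[1, 7:9] = CLASS_DARK
    cands = grow_candidates(_classes_from_labels(labels))
    assert len(cands) == 1
    assert len(cands[0].pixels) == 9


def test_light_without_seed_is_discarded():
    labels = np.zeros((4, 4), dtype=np.uint8)
    labels[1:3, 1:3] = CLASS_LIGHT
    assert grow_candidates(_classes_from_labels(labels)) == []


def _union_find_candidates(labels, connectivity=8):
    """Independent oracle: explicit union-find over dark/light components
    with adjacency scanned pixel by pixel."""
    from scipy import ndimage

    struct = np.ones((3, 3), bool) if connectivity == 8 else \
        ndimage.generate_binary_structure(2, 1)
    dark_lab, nd = ndimage.label(labels == CLASS_DARK, structure=struct)
    light_lab, nl = ndimage.label(labels == CLASS_LIGHT, structure=struct)
    parent = list(range(nd + 1))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    h, w = labels.shape
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)] \
        if connectivity == 8 else [(-1, 0), (0, -1), (0, 1), (1, 0)]
    light_touches = {k: set() for k in range(1, nl + 1)}
    for r in range(h):
        for c in range(w):
            if light_lab[r, c]:
                for dr, dc in offsets:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and dark_lab[rr, cc]:
                        light_touches[light_lab[r, c]].add(dark_lab[rr, cc])
    for seeds in light_touches.values():
        seeds = sorted(seeds)
        for s in seeds[1:]:
            union(s, seeds[0])
    groups = {}
    for r in range(h):
        for c in range(w):
            if dark_lab[r, c]:
                groups.setdefault(find(dark_lab[r, c]), set()).add((r, c))
            elif light_lab[r, c]:
                touch = light_touches[light_lab[r, c]]
                if touch:
                    groups.setdefault(find(next(iter(touch))), set()).add((r, c))
    return sorted(frozenset(px) for px in groups.values())


@given(st.integers(0, 999))
@settings(max_examples=30)
def test_grow_matches_union_find_oracle(seed):
    rng = np.random.default_rng(seed)
    labels = rng.choice([CLASS_NONE, CLASS_LIGHT, CLASS_DARK],
                        size=(12, 12), p=[0.6, 0.25, 0.15]).astype(np.uint8)
    cands = grow_candidates(_classes_from_labels(labels))
    got = sorted(frozenset(map(tuple, c.pixels)) for c in cands)
    assert got == _union_find_candidates(labels)


def test_candidates_are_disjoint_and_stained(clean_section):
    *_, result = clean_section
    seen = set()
    for cand in result.candidates:
        px = set(map(tuple, cand.pixels))
        assert not (px & seen)
        seen |= px
        for r, c in list(px)[:5]:
            assert result.classes.labels[r, c] != CLASS_NONE


# ---------------------------------------------------------------------------
# elliptic fit


def test_disk_scores_high():
    yy, xx = np.mgrid[-12:13, -12:13]
    disk = np.column_stack(np.nonzero(xx ** 2 + yy ** 2 <= 100))
    assert elliptic_fit(disk) >= 0.9


def test_thin_line_scores_well_below_threshold():
    line = np.column_stack([np.zeros(40, int), np.arange(40)])
    assert elliptic_fit(line) < 0.5


def test_single_pixel_is_elliptical_by_convention():
    assert elliptic_fit(np.array([[3, 7]])) == 1.0


def test_rotated_ellipse_scores_high():
    yy, xx = np.mgrid[-20:21, -20:21]
    u = (xx + yy) / np.sqrt(2)
    v = (yy - xx) / np.sqrt(2)
    ell = np.column_stack(np.nonzero((u / 15) ** 2 + (v / 6) ** 2 <= 1))
    assert elliptic_fit(ell) >= 0.85


# ---------------------------------------------------------------------------
# the five removal rules


def _cand(area=25.0, dark=5.0, mean=0.35, sd=0.15, fit=0.9):
    return CandidateObject(
        pixels=np.array([[0, 0]]), area_um2=area, dark_area_um2=dark,
        mean_brown_au=mean, sd_brown_au=sd, elliptic_fit=fit, centroid=(0.0, 0.0),
    )


@pytest.mark.parametrize("cand,expected_flags", [
    (_cand(area=9.0, dark=2.0), (RULE_MIN_AREA,)),
    (_cand(area=25.0, dark=1.0), (RULE_MIN_DARK_AREA,)),
    (_cand(mean=0.6, sd=0.10), (RULE_UNIFORM_INTENSITY,)),
    (_cand(area=25.0, fit=0.5), (RULE_NON_ELLIPTICAL,)),
    (_cand(area=50.0, dark=40.0), (RULE_DARK_FRACTION,)),
    (_cand(), ()),
    (_cand(area=40.0, fit=0.2, dark=35.0), ()),   # exactly 40: neither size rule
    (_cand(area=10.0, dark=1.5), ()),             # thresholds are strict
])
def test_removal_rule_boundaries(cand, expected_flags):
    plaques, rejected = filter_candidates([cand])
    if expected_flags:
        assert not plaques
        assert rejected[0].removal_flags == expected_flags
    else:
        assert not rejected
        assert plaques[0].removal_flags == ()


def _oracle_flags(c, p=SegmentationParams()):
    flags = []
    if c.area_um2 < p.min_area_um2:
        flags.append(RULE_MIN_AREA)
    if c.dark_area_um2 < p.min_dark_area_um2:
        flags.append(RULE_MIN_DARK_AREA)
    if c.mean_brown_au > p.artifact_intensity_min_au and c.sd_brown_au < p.artifact_sd_max_au:
        flags.append(RULE_UNIFORM_INTENSITY)
    if c.area_um2 < p.small_area_um2 and c.elliptic_fit < p.elliptic_fit_min:
        flags.append(RULE_NON_ELLIPTICAL)
    if c.area_um2 > p.small_area_um2 and c.dark_area_um2 / c.area_um2 > p.dark_fraction_max:
        flags.append(RULE_DARK_FRACTION)
    return tuple(flags)


def _random_candidates(rng, n):
    cands = []
    for _ in range(n):
        area = float(rng.uniform(0.5, 120.0))
        cands.append(_cand(
            area=area,
            dark=float(rng.uniform(0.0, area)),
            mean=float(rng.uniform(0.0, 1.2)),
            sd=float(rng.uniform(0.0, 0.6)),
            fit=float(rng.uniform(0.0, 1.0)),
        ))
    return cands


def test_randomized_candidates_match_rule_oracle(rng):
    cands = _random_candidates(rng, 1000)
    plaques, rejected = filter_candidates(cands)
    assert len(plaques) + len(rejected) == 1000
    for cand in plaques:
        assert _oracle_flags(cand) == ()
    for cand in rejected:
        assert _oracle_flags(cand) == cand.removal_flags != ()


def test_filtering_accepted_plaques_again_removes_nothing(rng):
    plaques, _ = filter_candidates(_random_candidates(rng, 500))
    again, rejected = filter_candidates(plaques)
    assert not rejected
    assert len(again) == len(plaques)
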