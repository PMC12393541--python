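import numpy as np
import pytest
from scipy import ndimage
from skimage import morphology

from orgate import fishquant as F
from orgate import synthetic as syn
from tests.oracles import t_ci


def _stack(data):
    return F.ImageStack(np.asarray(data, dtype=float))


def _disk_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


# ---------------------------------------------------------------------------
# Depth correction
# ---------------------------------------------------------------------------


def test_depth_correct_scales_by_dapi_ratio():
    data = np.zeros((2, 2, 4, 4))
    data[0, 0] = 10.0  # DAPI slice 0 (max)
    data[1, 0] = 5.0  # DAPI slice 1 at half
    data[0, 1] = 7.0
    data[1, 1] = 7.0
    out = F.depth_correct(_stack(data))
    np.testing.assert_allclose(out.data[0, 1], 7.0)  # maximal slice unchanged
    np.testing.assert_allclose(out.data[1, 1], 14.0)  # doubled
    np.testing.assert_allclose(out.data[:, 0], data[:, 0])  # DAPI untouched


def test_depth_correct_uniform_dapi_is_identity_and_idempotent():
    rng = np.random.default_rng(0)
    data = rng.uniform(1, 9, size=(3, 2, 8, 8))
    data[:, 0] = 4.0
    out = F.depth_correct(_stack(data))
    np.testing.assert_allclose(out.data, data)
    # recomputed scalars on corrected DAPI are all 1
    means = out.data[:, 0].reshape(3, -1).mean(axis=1)
    np.testing.assert_allclose(means.max() / means, 1.0)


def test_depth_correct_zero_dapi_slice_errors():
    data = np.ones((2, 2, 4, 4))
    data[1, 0] = 0.0
    with pytest.raises(ValueError, match="slice 1"):
        F.depth_correct(_stack(data))


# ---------------------------------------------------------------------------
# Signal segmentation
# ---------------------------------------------------------------------------


def test_segment_signal_blob_retention_and_size_gate():
    img = np.zeros((128, 128))
    big = _disk_mask((128, 128), 40, 40, 2.4)  # ~20 px
    assert big.sum() >= 12
    img[big] = 100.0
    small = np.zeros((128, 128), dtype=bool)
    small[100:102, 100:104] = True  # 8 px
    img[small] = 100.0
    mask = F.segment_signal(img, sigma=30, min_area=12)
    assert mask[big].all()
    assert not mask[small].any()  # below the 12-px object gate
    assert F.segment_signal(np.zeros((64, 64))).sum() == 0  # blank slice
    assert F.segment_signal(np.full((64, 64), 5.0)).sum() == 0  # constant slice


# ---------------------------------------------------------------------------
# Cytoplasm rings
# ---------------------------------------------------------------------------


def test_ring_matches_dilation_oracle_and_avoids_nucleus():
    labels = np.zeros((64, 64), dtype=np.int32)
    nucleus = _disk_mask((64, 64), 32, 32, 10)
    labels[nucleus] = 1
    rings = F.cytoplasm_rings(labels, dilate_px=3)
    ring = rings == 1
    # independent oracle: grey dilation via scipy with an explicit disk footprint
    footprint = morphology.disk(3).astype(bool)
    dilated = ndimage.binary_dilation(nucleus, structure=footprint)
    np.testing.assert_array_equal(ring, dilated & ~nucleus)
    assert not (ring & nucleus).any()


def test_contested_ring_pixels_removed_from_both():
    labels = np.zeros((40, 80), dtype=np.int32)
    labels[_disk_mask((40, 80), 20, 30, 8)] = 1
    labels[_disk_mask((40, 80), 20, 48, 8)] = 2  # 2 px between dilated rings
    rings = F.cytoplasm_rings(labels, dilate_px=3)
    fp = morphology.disk(3).astype(bool)
    d1 = ndimage.binary_dilation(labels == 1, structure=fp) & ~(labels == 1)
    d2 = ndimage.binary_dilation(labels == 2, structure=fp) & ~(labels == 2)
    contested = d1 & d2
    assert contested.any()
    assert not (rings[contested] > 0).any()
    # ring pixels overlapping the neighbour's nucleus are excluded too
    assert not ((rings == 1) & (labels == 2)).any()


def test_rings_disjoint_from_all_nuclei_random(rng):
    labels = np.zeros((96, 96), dtype=np.int32)
    for lab in range(1, 7):
        cy, cx = rng.integers(10, 86, size=2)
        labels[_disk_mask((96, 96), cy, cx, int(rng.integers(4, 9)))] = lab
    rings = F.cytoplasm_rings(labels)
    assert not ((rings > 0) & (labels > 0)).any()
    for lab in range(1, 7):
        others = (rings > 0) & (rings != lab)
        assert not ((rings == lab) & others).any()


# ---------------------------------------------------------------------------
# ROI quantification
# ---------------------------------------------------------------------------


def test_masked_mean_rules():
    residual = np.full((10, 10), 10.0)
    roi = np.zeros((10, 10), dtype=bool)
    roi[2:6, 2:6] = True
    full = np.ones((10, 10), dtype=bool)
    half = np.zeros((10, 10), dtype=bool)
    half[2:4, 2:6] = True  # half the ROI
    assert F._masked_mean(residual, roi, full, "zeroed") == 10.0
    assert F._masked_mean(residual, roi, half, "zeroed") == 5.0
    assert F._masked_mean(residual, roi, half, "masked_only") == 10.0
    assert F._masked_mean(residual, roi, half, "unmasked") == 10.0
    assert F._masked_mean(residual, np.zeros_like(roi), full, "zeroed") is None


def test_quantify_rois_geometry():
    data = np.zeros((1, 2, 64, 64))
    data[0, 0] = 5.0  # DAPI
    nucleus = _disk_mask((64, 64), 32, 32, 8)
    data[0, 1][nucleus] = 50.0
    labels = np.zeros((1, 64, 64), dtype=np.int32)
    labels[0][nucleus] = 1
    recs = F.quantify_rois(_stack(data), labels, sigma=20)
    assert len(recs) == 1
    rec = recs[0]
    assert rec.nuclear_area == int(nucleus.sum())
    assert rec.eccentricity < 0.1  # circular ROI
    assert rec.centroid == pytest.approx((32, 32), abs=0.5)
    assert rec.cytoplasmic_area > 0
    assert rec.raw_nuclear[1] > 0


# ---------------------------------------------------------------------------
# Normalization and classification
# ---------------------------------------------------------------------------


def _rec(nuc, cyto, area=500, cyto_area=150, ecc=0.5):
    r = F.RoiRecord((0, 1), (0, 0), area, ecc, cyto_area)
    r.norm_nuclear[1] = nuc
    r.norm_cytoplasmic[1] = cyto
    return r


def test_normalize_signals_quantile_mapping():
    records = []
    for i, val in enumerate(np.linspace(10, 110, 11)):
        r = F.RoiRecord((0, i), (0, 0), 500, 0.2, 100)
        r.raw_nuclear[1] = val
        r.raw_cytoplasmic[1] = val / 2
        records.append(r)
    F.normalize_signals(records, q_low=0.0, q_high=1.0)
    nucs = [r.norm_nuclear[1] for r in records]
    assert min(nucs) == 0.0 and max(nucs) == 1.0  # Q_low -> 0, Q_high -> 1 exactly
    # cytoplasmic value equal to the nuclear upper quantile maps to 1
    records[0].raw_cytoplasmic[1] = 110.0
    F.normalize_signals(records, q_low=0.0, q_high=1.0)
    assert records[0].norm_cytoplasmic[1] == pytest.approx(1.0)


def test_normalize_signals_degenerate_inputs():
    records = [_rec(0, 0)]
    with pytest.raises(ValueError):
        F.normalize_signals(records)
    two = []
    for i in range(2):
        r = F.RoiRecord((0, i), (0, 0), 500, 0.2, 100)
        r.raw_nuclear[1] = 5.0
        r.raw_cytoplasmic[1] = 5.0
        two.append(r)
    with pytest.raises(ValueError):
        F.normalize_signals(two)  # zero quantile range


@pytest.mark.parametrize(
    "kwargs,expected",
    [
        (dict(nuc=0.8, cyto=0.25), True),
        (dict(nuc=0.8, cyto=0.10), False),  # cytoplasmic export required
        (dict(nuc=0.8, cyto=0.25, area=950), False),  # nuclear size gate
        (dict(nuc=0.8, cyto=0.25, area=300), False),
        (dict(nuc=0.8, cyto=0.25, cyto_area=50), False),
        (dict(nuc=0.8, cyto=0.25, ecc=0.9), False),  # non-circular
        (dict(nuc=0.7, cyto=0.25), False),
    ],
)
def test_classify_chosen_threshold_conjunction(kwargs, expected):
    assert F.classify_chosen(_rec(**kwargs), 1) is expected


@pytest.mark.parametrize(
    "nuc,cyto,expected",
    [
        (0.15, 0.10, "nuclear"),
        (0.5, 0.3, "nuclear+cytoplasmic"),
        (0.05, 0.9, "none"),  # cytoplasmic requires nuclear first
        (0.05, 0.05, "none"),
    ],
)
def test_classify_localization(nuc, cyto, expected):
    assert F.classify_localization(_rec(nuc, cyto), 1) == expected


def test_chosen_implies_nuclear_cytoplasmic(rng):
    for _ in range(200):
        r = _rec(
            nuc=rng.uniform(-0.2, 1.4),
            cyto=rng.uniform(-0.2, 1.4),
            area=int(rng.integers(100, 1200)),
            cyto_area=int(rng.integers(0, 400)),
            ecc=rng.uniform(0, 1),
        )
        if F.classify_chosen(r, 1):
            assert F.classify_localization(r, 1) == "nuclear+cytoplasmic"


# ---------------------------------------------------------------------------
# Subnuclear overlap and replicate summaries
# ---------------------------------------------------------------------------


def test_subnuclear_overlap_fractions():
    nucleus = np.zeros((20, 20), dtype=bool)
    nucleus[2:18, 2:18] = True
    m = np.zeros((20, 20), dtype=bool)
    m[4:12, 4:12] = True
    assert F.subnuclear_overlap(m, m, nucleus)["overlap_fraction"] == 1.0
    disjoint = np.zeros_like(m)
    disjoint[13:17, 13:17] = True
    assert F.subnuclear_overlap(m, disjoint, nucleus)["overlap_fraction"] == 0.0
    half = np.zeros_like(m)
    half[4:8, 4:12] = True
    assert F.subnuclear_overlap(m, half, nucleus)["overlap_fraction"] == 0.5


def test_proportion_summary_t_interval():
    assert F.proportion_summary([1.0, 1.0, 1.0]) == {"mean": 1.0, "ci_low": 1.0, "ci_high": 1.0}
    assert F.proportion_summary([0.0, 1.0])["mean"] == 0.5
    single = F.proportion_summary([0.7])
    assert np.isnan(single["ci_low"])
    vals = [0.2, 0.4, 0.5, 0.65, 0.8]
    got = F.proportion_summary(vals)
    lo, hi = t_ci(vals)
    assert got["ci_low"] == pytest.approx(lo) and got["ci_high"] == pytest.approx(hi)


# ---------------------------------------------------------------------------
# Fallback nuclear segmentation on synthetic stacks
# ---------------------------------------------------------------------------


def test_fallback_segmentation_counts_disjoint_disks():
    stack, labels, truths = syn.gen_stack(seed=3, n_cells=6, shape=(3, 2, 192, 192))
    seg = F.segment_nuclei(stack)
    for t in truths:
        region = seg[t.z][labels[t.z] == t.cell_id]
        vals, counts = np.unique(region[region > 0], return_counts=True)
        assert len(vals) >= 1  # each true nucleus is covered by some label
        # majority of the disk maps to a single label
        assert counts.max() / region.size > 0.5
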