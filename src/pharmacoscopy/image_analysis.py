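"""Synthetic two-channel well imaging and single-cell count extraction.

A simplified, fully specified imaging stage: wells are rendered as
two-channel fluorescence images (DNA stain + lineage marker), then
segmented back into per-cell calls.  Viability follows nuclear
morphology — an intact nucleus is one non-fragmented, solid object of
plausible area, while a dead cell's nucleus appears as a group of small
displaced fragments.  Marker positivity is gated per well on cell-wise
marker intensities (Otsu split, with a conservative fixed-quantile
fallback when the intensity distribution is unimodal).

The extracted counts feed :mod:`pharmacoscopy.screen_core` as
:class:`~pharmacoscopy.screen_core.WellRecord` inputs, so the image path
and the count path can be compared end to end on matched simulations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skimage import filters, measure

from .screen_core import WellRecord


@dataclass
class CellTruth:
    y: float
    x: float
    viable: bool
    marker_positive: bool


@dataclass
class WellImage:
    """Co-registered DNA and marker intensity channels plus optional truth."""

    dna_channel: np.ndarray
    marker_channel: np.ndarray
    pixel_size_um: float = 0.66
    truth: list[CellTruth] | None = None

    def __post_init__(self) -> None:
        if self.dna_channel.shape != self.marker_channel.shape:
            raise ValueError("channels must be co-registered (same shape)")


@dataclass
class SegmentedCell:
    """One detected nucleus group and its morphology/intensity features."""

    label: int
    area: int
    n_fragments: int
    solidity: float
    marker_mean_intensity: float
    centroid: tuple[float, float]
    viable: bool = False
    marker_positive: bool = False


@dataclass
class RenderConfig:
    shape: tuple[int, int] = (256, 256)
    nucleus_sigma_px: float = 3.0
    fragment_sigma_px: float = 1.2
    dna_amplitude: float = 180.0
    marker_pos_amplitude: float = 150.0
    marker_neg_amplitude: float = 8.0
    background: float = 5.0
    read_noise_sd: float = 2.0
    n_fragments_range: tuple[int, int] = (3, 6)
    fragment_displacement_px: float = 9.0


@dataclass
class SegmentationConfig:
    smooth_sigma_px: float = 2.0
    min_area_px: int = 30
    fragment_group_radius_px: float = 15.0
    solidity_min: float = 0.85
    area_window_px: tuple[int, int] = (30, 400)
    otsu_separation_min: float = 0.1
    fallback_quantile: float = 0.99


# ---------------------------------------------------------------------------
# Rendering


def _stamp(img: np.ndarray, y: float, x: float, sigma: float, amplitude: float) -> None:
    """Add a Gaussian blob in place (local patch, 3-sigma support)."""
    r = int(np.ceil(3 * sigma))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    patch = amplitude * np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
    iy, ix = int(round(y)), int(round(x))
    y0, y1 = max(iy - r, 0), min(iy + r + 1, img.shape[0])
    x0, x1 = max(ix - r, 0), min(ix + r + 1, img.shape[1])
    img[y0:y1, x0:x1] += patch[
        y0 - (iy - r) : patch.shape[0] - ((iy + r + 1) - y1),
        x0 - (ix - r) : patch.shape[1] - ((ix + r + 1) - x1),
    ]


def random_cell_layout(
    n_intact: int,
    n_fragmented: int,
    marker_pos_fraction: float,
    seed: int,
    shape: tuple[int, int] = (256, 256),
    min_distance_px: float = 26.0,
    margin_px: float = 12.0,
) -> list[CellTruth]:
    """Random non-overlapping ground-truth cell positions (rejection sampling)."""
    rng = np.random.default_rng(seed)
    n = n_intact + n_fragmented
    pts: list[tuple[float, float]] = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not place cells; lower density or min distance")
        y = rng.uniform(margin_px, shape[0] - margin_px)
        x = rng.uniform(margin_px, shape[1] - margin_px)
        if all((y - py) ** 2 + (x - px) ** 2 >= min_distance_px**2 for py, px in pts):
            pts.append((y, x))
    cells = []
    for i, (y, x) in enumerate(pts):
        cells.append(
            CellTruth(
                y=y,
                x=x,
                viable=i < n_intact,
                marker_positive=bool(rng.random() < marker_pos_fraction),
            )
        )
    return cells


def render_well(
    cells: list[CellTruth],
    config: RenderConfig | None = None,
    seed: int = 0,
) -> WellImage:
    """Render a ground-truth cell layout into a two-channel well image.

    Intact nuclei are single Gaussian blobs; fragmented (dead) nuclei are
    3-6 small displaced blobs of equal total intensity.  Marker-positive
    cells receive elevated marker-channel intensity at the same location.
    Gaussian read noise is added to both channels; same seed, same pixels.
    """
    cfg = config or RenderConfig()
    rng = np.random.default_rng(seed)
    dna = np.full(cfg.shape, cfg.background, dtype=float)
    marker = np.full(cfg.shape, cfg.background, dtype=float)
    # equal total intensity: amplitude * sigma^2 is conserved across fragments
    intact_integral = cfg.dna_amplitude * cfg.nucleus_sigma_px**2
    for cell in cells:
        if cell.viable:
            _stamp(dna, cell.y, cell.x, cfg.nucleus_sigma_px, cfg.dna_amplitude)
        else:
            k = int(rng.integers(cfg.n_fragments_range[0], cfg.n_fragments_range[1] + 1))
            amp = intact_integral / (k * cfg.fragment_sigma_px**2)
            # apoptotic bodies on a ring around the former nucleus: evenly
            # spaced angles keep fragments mutually resolved, the radius cap
            # keeps the whole group inside the fragment-grouping radius
            sep = 2 * np.sin(np.pi / k)  # adjacent separation per unit radius
            r_min = max(5.0, 7.0 / sep)            # fragments stay resolved
            r_max = max(r_min, min(cfg.fragment_displacement_px, 14.0 / sep))
            r_base = rng.uniform(r_min, r_max)
            ang0 = rng.uniform(0, 2 * np.pi)
            for j in range(k):
                ang = ang0 + 2 * np.pi * j / k + rng.normal(0, 0.1)
                rad = r_base + rng.uniform(-0.8, 0.8)
                _stamp(
                    dna,
                    cell.y + rad * np.sin(ang),
                    cell.x + rad * np.cos(ang),
                    cfg.fragment_sigma_px,
                    amp,
                )
        amp_m = cfg.marker_pos_amplitude if cell.marker_positive else cfg.marker_neg_amplitude
        _stamp(marker, cell.y, cell.x, cfg.nucleus_sigma_px, amp_m)
    dna += rng.normal(0.0, cfg.read_noise_sd, cfg.shape)
    marker += rng.normal(0.0, cfg.read_noise_sd, cfg.shape)
    return WellImage(
        dna_channel=np.clip(dna, 0, None),
        marker_channel=np.clip(marker, 0, None),
        truth=list(cells),
    )


# ---------------------------------------------------------------------------
# Segmentation


def segment_nuclei(
    image: WellImage, config: SegmentationConfig | None = None
) -> list[SegmentedCell]:
    """Detect nucleus groups in the DNA channel.

    Otsu threshold on the smoothed DNA channel, connected components,
    min-area filter, then single-linkage grouping of components whose
    centroids lie within the fragment-grouping radius: each group is one
    (possibly fragmented) nucleus.  An all-zero or featureless image
    yields an empty list, not an error.
    """
    cfg = config or SegmentationConfig()
    dna = np.asarray(image.dna_channel, dtype=float)
    if dna.size == 0:
        raise ValueError("empty DNA channel")
    smooth = filters.gaussian(dna, sigma=cfg.smooth_sigma_px, preserve_range=True)
    if np.allclose(smooth, smooth.flat[0]):
        return []
    thr = filters.threshold_otsu(smooth)
    mask = smooth > thr
    # a featureless (noise-only) image splits near half its pixels: no cells
    if not mask.any() or mask.mean() > 0.3:
        return []
    labelled = measure.label(mask)
    props = [
        p
        for p in measure.regionprops(labelled, intensity_image=image.marker_channel)
        if p.area >= cfg.min_area_px / 2  # keep small fragments for grouping
    ]
    if not props:
        return []
    centroids = np.array([p.centroid for p in props])
    # single-linkage grouping by centroid proximity
    n = len(props)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if n > 1:
        d = squareform(pdist(centroids))
        for i in range(n):
            for j in range(i + 1, n):
                if d[i, j] <= cfg.fragment_group_radius_px:
                    parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    cells = []
    for gid, members in enumerate(sorted(groups.values(), key=min), start=1):
        comps = [props[i] for i in members]
        area = int(sum(p.area for p in comps))
        if area < cfg.min_area_px:
            continue
        w = np.array([p.area for p in comps], dtype=float)
        solidity = float(np.average([p.solidity for p in comps], weights=w))
        marker_mean = float(
            np.average([p.intensity_mean for p in comps], weights=w)
        )
        cy = float(np.average([p.centroid[0] for p in comps], weights=w))
        cx = float(np.average([p.centroid[1] for p in comps], weights=w))
        cells.append(
            SegmentedCell(
                label=gid,
                area=area,
                n_fragments=len(comps),
                solidity=solidity,
                marker_mean_intensity=marker_mean,
                centroid=(cy, cx),
            )
        )
    return cells


def call_viability(
    cells: list[SegmentedCell], config: SegmentationConfig | None = None
) -> int:
    """Flag viable cells in place; returns the well's viable count.

    Viable means a single non-fragmented nucleus (n_fragments == 1) that
    is solid (solidity >= s_min) and of plausible area.
    """
    cfg = config or SegmentationConfig()
    lo, hi = cfg.area_window_px
    count = 0
    for c in cells:
        c.viable = (
            c.n_fragments == 1
            and c.solidity >= cfg.solidity_min
            and lo <= c.area <= hi
        )
        count += c.viable
    return count


def _exact_otsu_1d(values: np.ndarray) -> float:
    """Exact Otsu split of a small 1-D sample (no histogram binning).

    Evaluates every cut between consecutive sorted values and returns the
    midpoint of the gap with maximal between-class variance.  Histogram
    Otsu can misplace the gate by up to a bin width, which matters when
    gating a few dozen cell intensities per well.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    csum = np.cumsum(x)
    k = np.arange(1, n)
    m_lo = csum[:-1] / k
    m_hi = (csum[-1] - csum[:-1]) / (n - k)
    var_b = k * (n - k) * (m_lo - m_hi) ** 2
    best = int(np.argmax(var_b))
    return float((x[best] + x[best + 1]) / 2.0)


def otsu_separation(values: np.ndarray, thr: float) -> float:
    """Normalized gap between the two groups an intensity split induces.

    (10th percentile of the upper group - 90th percentile of the lower
    group) / value range: near 0 for a unimodal sample split through its
    bulk, large for well-separated modes; the quantiles make the score
    robust to single values straying across the split.  0 when the split
    or the sample is degenerate.
    """
    rng_ = values.max() - values.min()
    if rng_ == 0:
        return 0.0
    lo, hi = values[values <= thr], values[values > thr]
    if len(lo) == 0 or len(hi) == 0:
        return 0.0
    gap = np.quantile(hi, 0.10) - np.quantile(lo, 0.90)
    return float(max(gap, 0.0) / rng_)


def call_marker(
    cells: list[SegmentedCell], config: SegmentationConfig | None = None
) -> int:
    """Gate marker positivity per well on cell-wise mean marker intensities.

    An Otsu split of the intensities defines the gate; when the split is
    weak (separation score below the configured minimum, i.e. a unimodal
    well), a conservative fallback calls positive only cells above both
    the fixed high quantile and twice the median, so an all-negative well
    yields zero positives.  Flags in place, returns the positive count.
    """
    cfg = config or SegmentationConfig()
    if not cells:
        return 0
    x = np.array([c.marker_mean_intensity for c in cells])
    use_fallback = len(np.unique(x)) < 2
    thr = None
    if not use_fallback:
        thr = _exact_otsu_1d(x)
        use_fallback = otsu_separation(x, thr) < cfg.otsu_separation_min
    if use_fallback:
        thr = max(float(np.quantile(x, cfg.fallback_quantile)), 2.0 * float(np.median(x)))
    else:
        # centre the gate in the inter-mode gap (robust to boundary strays)
        lo, hi = x[x <= thr], x[x > thr]
        thr = float((np.quantile(lo, 0.90) + np.quantile(hi, 0.10)) / 2.0)
    count = 0
    for c in cells:
        c.marker_positive = bool(c.marker_mean_intensity > thr)
        count += c.marker_positive
    return count


def image_to_wellrecord(
    cells: list[SegmentedCell],
    patient_id: str,
    plate_id: str,
    well: str,
    drug: str,
    concentration_um: float,
    replicate: int,
    marker: str,
) -> WellRecord:
    """Collapse per-cell calls into a screen-level well-count record."""
    n_pos = sum(1 for c in cells if c.viable and c.marker_positive)
    n_neg = sum(1 for c in cells if c.viable and not c.marker_positive)
    return WellRecord(
        patient_id=patient_id,
        plate_id=plate_id,
        well=well,
        drug=drug,
        concentration_um=concentration_um,
        replicate=replicate,
        n_viable_marker_pos={marker: n_pos},
        n_viable_marker_neg={marker: n_neg},
        n_total_cells=len(cells),
    )


def analyze_well(
    image: WellImage, config: SegmentationConfig | None = None
) -> list[SegmentedCell]:
    """Segment, call viability and marker positivity in one pass."""
    cells = segment_nuclei(image, config)
    call_viability(cells, config)
    call_marker(cells, config)
    return cells


# ---------------------------------------------------------------------------
# TIFF / JSON I/O


def write_well_image(image: WellImage, path) -> None:
    """Write a two-channel TIFF stack plus a JSON truth sidecar."""
    import tifffile

    stack = np.stack([image.dna_channel, image.marker_channel]).astype(np.float32)
    tifffile.imwrite(path, stack)
    if image.truth is not None:
        sidecar = str(path) + ".truth.json"
        with open(sidecar, "w") as fh:
            json.dump([asdict(c) for c in image.truth], fh)


def read_well_image(path) -> WellImage:
    import tifffile

    stack = tifffile.imread(path)
    truth = None
    sidecar = str(path) + ".truth.json"
    try:
        with open(sidecar) as fh:
            truth = [CellTruth(**c) for c in json.load(fh)]
    except FileNotFoundError:
        pass
    return WellImage(
        dna_channel=np.asarray(stack[0], float),
        marker_channel=np.asarray(stack[1], float),
        truth=truth,
    )
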