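"""Synthetic data with known ground truth.

Four generators mirror the four data tiers of the maturation assay:

* :func:`render_field` — multi-channel immunofluorescence fields (DAPI, MAP2,
  FOS, EGR-1 and optionally SYN1/PSD95) of neurons with controllable nuclear
  morphometry, neurite content, depolarization-dependent IEG state and
  synaptic puncta.  Nuclei are filled ellipses whose axis ratio is solved so
  that the 4πA/P² roundness index of the population matches the requested
  mean; neurites are random trees of 1-px polylines rooted at somata.
* :func:`simulate_screen_features` — a feature-level compound screen
  (2,688 compounds in duplicate by default) with paired stimulated /
  unstimulated plates, DMSO controls, additive row/column plate artifacts,
  planted toxic compounds (depressed nuclei counts) and planted maturation
  hits (all six parameters elevated).
* :func:`simulate_mea` — extracellular recordings on a 64×64-style electrode
  grid: Gaussian noise plus biphasic spike waveforms at planted times, with
  optional synchronized network bursts.
* :func:`simulate_calcium` — ROI fluorescence time series on the 5-s / 20-min
  schedule with planted exponentially decaying transients.

Every generator is deterministic given its spec's seed, and every planted
object (nucleus, spike, burst, transient, hit, toxic compound) appears exactly
once in the returned ground truth.

Well-level technical noise in the feature-level screen tier is uniform
(bounded) rather than Gaussian: it keeps planted effects cleanly separable
from background at the screen's exclusion thresholds.  See docs/methods.md
for what this does and does not emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

__all__ = [
    "FieldSpec",
    "ImageField",
    "LibrarySpec",
    "PlateFeatureSet",
    "MEASimSpec",
    "ArrayRecording",
    "CalciumSimSpec",
    "CalciumTraceSet",
    "preset",
    "PRESET_NAMES",
    "render_field",
    "simulate_screen_features",
    "simulate_mea",
    "simulate_calcium",
    "SCREEN_FEATURES",
    "MORPHOLOGY_FEATURES",
    "IEG_FEATURES",
]

# ---------------------------------------------------------------------------
# Field specification and presets
# ---------------------------------------------------------------------------


@dataclass
class FieldSpec:
    """Parameters of one synthetic microscopy field."""

    preset_name: str = "custom"
    n_neurons: int = 60
    nucleus_area_mean: float = 90.0          # μm²
    nucleus_area_cv: float = 0.12
    roundness_mean: float = 0.82             # 4πA/P², in (0, 1]
    neurite_length_mean: float = 400.0       # μm per neuron
    branches_per_neuron: int = 4
    ieg_pos_fraction_stim: float = 0.25
    ieg_pos_fraction_unstim: float = 0.05
    fos_pos_intensity: float = 2000.0        # AFU, above the 800 threshold
    fos_neg_intensity: float = 200.0
    egr1_pos_intensity: float = 2500.0       # AFU, above the 1,000 threshold
    egr1_neg_intensity: float = 300.0
    puncta_density_syn1: float = 0.0         # puncta per 100 μm neurite
    puncta_density_psd95: float = 0.0
    apposed_fraction: float = 0.0
    pixel_size: float = 0.65                 # μm/px
    field_shape: tuple = (1024, 1024)
    noise_sd: float = 50.0                   # AFU
    stimulated: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ieg_pos_fraction_stim", "ieg_pos_fraction_unstim",
                     "apposed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.nucleus_area_mean <= 0:
            raise ValueError("nucleus_area_mean must be positive")
        if not 0.0 < self.roundness_mean <= 1.0:
            raise ValueError("roundness_mean must lie in (0, 1]")
        if self.n_neurons < 0:
            raise ValueError("n_neurons must be non-negative")
        self.field_shape = tuple(int(s) for s in self.field_shape)


@dataclass
class ImageField:
    """Multi-channel field plus optional generator ground truth.

    ``channels`` maps channel name (DAPI, MAP2, FOS, EGR1, SYN1, PSD95) to a
    2-D float32 raster in AFU; all rasters share one shape.  ``ground_truth``
    (populated by the generator) holds per-neuron records plus puncta
    coordinates and apposition labels.
    """

    channels: dict
    pixel_size: float
    ground_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape


# Preset parameter sets.  rat_day14 is the mature benchmark (large round
# nuclei of 130 μm² at roundness 0.93, ~2,800 μm of neurite per neuron,
# near-complete KCl-induced IEG response); it is rendered sparse (12 neurons
# per 1,024² field) so that 1-px neurite rasters stay traceable at its very
# high per-cell neurite content.  hpsc_day21 is the immature screen-stage
# state; hpsc_treated a maturation-enhanced version of it.
_PRESETS: dict[str, dict] = {
    "rat_day14": dict(
        n_neurons=12, nucleus_area_mean=130.0, nucleus_area_cv=0.12,
        roundness_mean=0.93, neurite_length_mean=2800.0,
        branches_per_neuron=12, ieg_pos_fraction_stim=0.98,
        ieg_pos_fraction_unstim=0.05,
        puncta_density_syn1=0.0, puncta_density_psd95=0.0,
        apposed_fraction=0.0,
    ),
    "hpsc_day21": dict(
        n_neurons=60, nucleus_area_mean=90.0, nucleus_area_cv=0.14,
        roundness_mean=0.82, neurite_length_mean=400.0,
        branches_per_neuron=4, ieg_pos_fraction_stim=0.25,
        ieg_pos_fraction_unstim=0.05,
        puncta_density_syn1=8.0, puncta_density_psd95=6.0,
        apposed_fraction=0.3,
    ),
    "hpsc_treated": dict(
        n_neurons=60, nucleus_area_mean=115.0, nucleus_area_cv=0.13,
        roundness_mean=0.90, neurite_length_mean=900.0,
        branches_per_neuron=7, ieg_pos_fraction_stim=0.60,
        ieg_pos_fraction_unstim=0.06,
        puncta_density_syn1=12.0, puncta_density_psd95=9.0,
        apposed_fraction=0.5,
    ),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str, **overrides) -> FieldSpec:
    """Return the named :class:`FieldSpec` preset.

    ``rat_day14`` encodes the mature reference culture; ``hpsc_day21`` the
    immature screen-stage state (strictly smaller nucleus area, roundness,
    neurite length and stimulated IEG fraction); ``hpsc_treated`` an
    intermediate, maturation-enhanced condition.  Keyword overrides replace
    individual fields.
    """
    if name not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    params = dict(_PRESETS[name])
    params.update(overrides)
    return FieldSpec(preset_name=name, **params)


# ---------------------------------------------------------------------------
# Field rendering
# ---------------------------------------------------------------------------


def _ellipse_axis_ratio(roundness: float) -> float:
    """Axis ratio b/a of an ellipse with circularity 4πA/P² = ``roundness``.

    Uses Ramanujan's perimeter approximation; the same 4πA/P² definition is
    used by the morphometry measurement, so generator and measurement agree.
    """
    if roundness >= 1.0:
        return 1.0

    def circ(r: float) -> float:
        a, b = 1.0, r
        h = ((a - b) / (a + b)) ** 2
        p = math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
        return 4 * math.pi * (math.pi * a * b) / p**2 - roundness

    return brentq(circ, 0.02, 1.0, xtol=1e-10)


def _place_nuclei(rng, spec: FieldSpec):
    """Sample non-overlapping nucleus geometries (center, semi-axes, angle)."""
    h, w = spec.field_shape
    ps = spec.pixel_size
    placed = []  # (r, c, a_px, b_px, theta)
    attempts = 0
    budget = 4000 * max(spec.n_neurons, 1)
    while len(placed) < spec.n_neurons:
        attempts += 1
        if attempts > budget:
            raise RuntimeError(
                f"could not place {spec.n_neurons} non-overlapping nuclei in a "
                f"{h}x{w} field within the retry budget"
            )
        area = rng.normal(spec.nucleus_area_mean,
                          spec.nucleus_area_cv * spec.nucleus_area_mean)
        area = max(area, 0.25 * spec.nucleus_area_mean)
        rnd = float(np.clip(rng.normal(spec.roundness_mean, 0.015), 0.40, 1.0))
        ratio = _ellipse_axis_ratio(rnd)
        area_px = area / ps**2
        a_px = math.sqrt(area_px / (math.pi * ratio))
        b_px = a_px * ratio
        theta = rng.uniform(0, math.pi)
        margin = a_px + 3
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        ok = True
        for (r2, c2, a2, _b2, _t2) in placed:
            if (r - r2) ** 2 + (c - c2) ** 2 < (a_px + a2 + 2) ** 2:
                ok = False
                break
        if ok:
            placed.append((r, c, a_px, b_px, theta))
    return placed


def _grow_neurite_tree(rng, root_rc, root_dir, length_budget_px, n_branches,
                       shape, want_samples=True):
    """Random neurite tree as a list of integer polyline vertices.

    Returns (segments, euclid_len_px, branch_events, samples) where
    ``segments`` is a list of ((r0,c0),(r1,c1)) steps, ``samples`` a dense
    list of float points along the tree used for puncta placement.
    """
    h, w = shape
    step = 10.0
    tips = [(root_rc, root_dir)]
    segments = []
    samples = []
    total = 0.0
    branches = 0
    # branch probability tuned so the expected number of branch events over
    # the whole budget is ~n_branches
    n_steps_expected = max(length_budget_px / step, 1.0)
    p_branch = min(0.5, n_branches / n_steps_expected)
    while total < length_budget_px and tips:
        idx = rng.integers(len(tips))
        (r, c), ang = tips[idx]
        ang = ang + rng.normal(0.0, 0.35)
        r2 = r + step * math.sin(ang)
        c2 = c + step * math.cos(ang)
        # reflect at the field border
        if r2 < 2 or r2 > h - 3:
            ang = -ang
            r2 = r + step * math.sin(ang)
        if c2 < 2 or c2 > w - 3:
            ang = math.pi - ang
            c2 = c + step * math.cos(ang)
        r2 = min(max(r2, 2.0), h - 3.0)
        c2 = min(max(c2, 2.0), w - 3.0)
        seg_len = math.hypot(r2 - r, c2 - c)
        if seg_len < 1.0:
            tips[idx] = ((r, c), rng.uniform(0, 2 * math.pi))
            continue
        segments.append(((int(round(r)), int(round(c))),
                         (int(round(r2)), int(round(c2)))))
        if want_samples:
            nsmp = max(int(seg_len // 3), 1)
            for j in range(1, nsmp + 1):
                t = j / nsmp
                samples.append((r + t * (r2 - r), c + t * (c2 - c)))
        total += seg_len
        tips[idx] = ((r2, c2), ang)
        if branches < n_branches and rng.random() < p_branch:
            branches += 1
            tips.append(((r2, c2), ang + rng.choice([-1.0, 1.0]) *
                         rng.uniform(0.6, 1.4)))
    return segments, total, branches, samples


def _stamp_spot(img, r, c, sigma, amplitude):
    """Add a small Gaussian spot centered at (r, c)."""
    rad = int(math.ceil(3 * sigma))
    h, w = img.shape
    r0, r1 = max(int(r) - rad, 0), min(int(r) + rad + 1, h)
    c0, c1 = max(int(c) - rad, 0), min(int(c) + rad + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += amplitude * np.exp(
        -((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2)
    )


def render_field(spec: FieldSpec) -> ImageField:
    """Render one multi-channel field from a :class:`FieldSpec`.

    Deterministic given ``spec.seed``.  The returned ``ground_truth`` dict has
    a ``neurons`` list (centroid, rasterized nucleus area in μm², target
    roundness, neurite path length in μm, branch count, IEG classes) and,
    when puncta channels are rendered, ``syn1_points`` / ``psd95_points``
    (px coordinates) with per-PSD95 ``psd95_apposed`` labels.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_shape
    ps = spec.pixel_size

    dapi = np.full((h, w), 100.0, dtype=np.float64)
    map2 = np.full((h, w), 50.0, dtype=np.float64)
    fos = np.full((h, w), 50.0, dtype=np.float64)
    egr1 = np.full((h, w), 50.0, dtype=np.float64)
    want_puncta = spec.puncta_density_syn1 > 0 or spec.puncta_density_psd95 > 0
    syn1 = np.full((h, w), 50.0, dtype=np.float64) if want_puncta else None
    psd95 = np.full((h, w), 50.0, dtype=np.float64) if want_puncta else None

    placed = _place_nuclei(rng, spec)

    pos_frac = (spec.ieg_pos_fraction_stim if spec.stimulated
                else spec.ieg_pos_fraction_unstim)
    neurons = []
    all_samples = []
    total_neurite_um = 0.0
    for i, (r, c, a_px, b_px, theta) in enumerate(placed):
        rr, cc = draw_ellipse(r, c, a_px, b_px, shape=(h, w), rotation=theta)
        dapi[rr, cc] = 5000.0
        # soma in the MAP2 channel, slightly larger than the nucleus
        rs, cs = draw_ellipse(r, c, 1.25 * a_px, 1.25 * b_px, shape=(h, w),
                              rotation=theta)
        map2[rs, cs] = np.maximum(map2[rs, cs], 1200.0)

        # coupled IEG classes: one latent responder variable drives both, so
        # double positivity equals the smaller of the two marginal fractions
        u = rng.random()
        fos_pos = u < pos_frac
        egr1_pos = u < pos_frac  # equal marginals within a condition
        fos[rr, cc] = spec.fos_pos_intensity if fos_pos else spec.fos_neg_intensity
        egr1[rr, cc] = (spec.egr1_pos_intensity if egr1_pos
                        else spec.egr1_neg_intensity)

        target_um = max(rng.normal(spec.neurite_length_mean,
                                   0.10 * spec.neurite_length_mean), 0.0)
        length_um = 0.0
        branches = 0
        if target_um > 0:
            root_ang = rng.uniform(0, 2 * math.pi)
            root = (r + (a_px + 2) * math.sin(root_ang),
                    c + (a_px + 2) * math.cos(root_ang))
            segs, tot_px, branches, samples = _grow_neurite_tree(
                rng, root, root_ang, target_um / ps,
                spec.branches_per_neuron, (h, w), want_samples=want_puncta)
            for (p0, p1) in segs:
                lr, lc = draw_line(p0[0], p0[1], p1[0], p1[1])
                map2[lr, lc] = np.maximum(map2[lr, lc], 1500.0)
            length_um = tot_px * ps
            all_samples.extend(samples)
        total_neurite_um += length_um

        neurons.append(dict(
            neuron=i, centroid=(float(r), float(c)),
            area_um2=float(len(rr)) * ps**2,
            roundness=float(4 * math.pi * (math.pi * a_px * b_px)
                            / _ramanujan(a_px, b_px) ** 2),
            neurite_length_um=float(length_um), n_branches=int(branches),
            fos_pos=bool(fos_pos), egr1_pos=bool(egr1_pos),
            double_pos=bool(fos_pos and egr1_pos),
        ))

    truth: dict = dict(neurons=neurons,
                       total_neurite_um=float(total_neurite_um))

    if want_puncta and all_samples:
        samples_arr = np.asarray(all_samples)
        n_syn1 = int(round(spec.puncta_density_syn1 * total_neurite_um / 100.0))
        n_psd = int(round(spec.puncta_density_psd95 * total_neurite_um / 100.0))
        rad_px = 1.0 / ps  # apposition radius of 1 μm, matching the default
        sy_pts = []
        for _ in range(n_syn1):
            p = samples_arr[rng.integers(len(samples_arr))]
            sy_pts.append((p[0] + rng.normal(0, 1.0), p[1] + rng.normal(0, 1.0)))
        sy_pts = np.asarray(sy_pts) if sy_pts else np.empty((0, 2))
        tree = cKDTree(sy_pts) if len(sy_pts) else None
        ps_pts, apposed = [], []
        n_app = int(round(spec.apposed_fraction * n_psd))
        for j in range(n_psd):
            if j < n_app and tree is not None:
                anchor = sy_pts[rng.integers(len(sy_pts))]
                ang = rng.uniform(0, 2 * math.pi)
                d = rng.uniform(0, 0.7 * rad_px)
                ps_pts.append((anchor[0] + d * math.sin(ang),
                               anchor[1] + d * math.cos(ang)))
                apposed.append(True)
            else:
                for _try in range(200):
                    p = samples_arr[rng.integers(len(samples_arr))]
                    cand = (p[0] + rng.normal(0, 1.0), p[1] + rng.normal(0, 1.0))
                    if tree is None or tree.query(cand)[0] > 1.8 * rad_px:
                        ps_pts.append(cand)
                        apposed.append(False)
                        break
        ps_pts = np.asarray(ps_pts) if ps_pts else np.empty((0, 2))
        for (pr, pc) in sy_pts:
            _stamp_spot(syn1, pr, pc, 1.3, 3000.0)
        for (pr, pc) in ps_pts:
            _stamp_spot(psd95, pr, pc, 1.3, 3000.0)
        truth["syn1_points"] = sy_pts
        truth["psd95_points"] = ps_pts
        truth["psd95_apposed"] = np.asarray(apposed, dtype=bool)

    channels = {"DAPI": dapi, "MAP2": map2, "FOS": fos, "EGR1": egr1}
    if want_puncta:
        channels["SYN1"] = syn1
        channels["PSD95"] = psd95
    if spec.noise_sd > 0:
        for name in channels:
            channels[name] = channels[name] + rng.normal(
                0.0, spec.noise_sd, size=(h, w))
    for name in channels:
        channels[name] = np.clip(channels[name], 0.0, 65535.0).astype(np.float32)

    return ImageField(channels=channels, pixel_size=ps, ground_truth=truth)


def _ramanujan(a: float, b: float) -> float:
    hh = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1 + 3 * hh / (10 + math.sqrt(4 - 3 * hh)))


# ---------------------------------------------------------------------------
# Feature-level screen simulation
# ---------------------------------------------------------------------------

MORPHOLOGY_FEATURES = ("nucleus_area", "nucleus_roundness",
                       "neurite_length", "n_segments")
IEG_FEATURES = ("frac_fos", "frac_egr1", "frac_double")
SCREEN_FEATURES = MORPHOLOGY_FEATURES + IEG_FEATURES

# control (DMSO) means per condition and uniform noise half-widths
_BASE = {
    "nucleus_area": 90.0, "nucleus_roundness": 0.82,
    "neurite_length": 400.0, "n_segments": 20.0,
    "frac_fos": {"stim": 0.30, "unstim": 0.05},
    "frac_egr1": {"stim": 0.25, "unstim": 0.05},
    "frac_double": {"stim": 0.20, "unstim": 0.03},
    "nuclei_count": 1200.0,
}
_NOISE_HW = {
    "nucleus_area": 5.0, "nucleus_roundness": 0.02,
    "neurite_length": 25.0, "n_segments": 1.5,
    "frac_fos": 0.02, "frac_egr1": 0.02, "frac_double": 0.015,
    "nuclei_count": 60.0,
}
# robust scale (1.4826 × MAD) of U(−hw, hw) is 1.4826 × hw/2
_ROBUST_OF_UNIFORM = 1.4826 * 0.5

ROW_LABELS = "ABCDEFGHIJKLMNOP"


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> 384-well address like 'A01'."""
    return f"{ROW_LABELS[row]}{col + 1:02d}"


@dataclass
class LibrarySpec:
    """Parameters of a feature-level whole-screen simulation.

    Effect sizes are expressed in robust z units of the well-level noise so
    they translate directly to the screen's normalized scale: a toxic
    compound's unstimulated nuclei count lands near viability z ≈
    −``toxic_effect_sd`` and a hit elevates all six maturity parameters.
    """

    n_compounds: int = 2688
    n_replicates: int = 2
    plate_shape: tuple = (16, 24)
    n_toxic: int = 325
    toxic_effect_sd: float = 6.0
    n_hits: int = 30
    hit_effect_sd: float = 6.0
    row_effect_sd: float = 1.0   # × per-feature noise half-width
    col_effect_sd: float = 1.0
    controls_per_plate: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        self.plate_shape = tuple(int(s) for s in self.plate_shape)
        if self.n_toxic + self.n_hits > self.n_compounds:
            raise ValueError("n_toxic + n_hits must not exceed n_compounds")
        rows, cols = self.plate_shape
        cap = rows * cols - self.controls_per_plate
        if cap <= 0:
            raise ValueError("controls leave no room for compounds")
        self.n_plates = math.ceil(self.n_compounds / cap)
        self.wells_per_plate = cap


@dataclass
class PlateFeatureSet:
    """Per-well feature table plus planted ground truth."""

    features: pd.DataFrame     # one row per well × replicate × condition
    truth: pd.DataFrame        # compound_id, label ∈ {hit, toxic, inert}
    spec: LibrarySpec


def simulate_screen_features(lib: LibrarySpec) -> PlateFeatureSet:
    """Simulate per-well features for a duplicate stimulated/unstimulated screen.

    Every plate carries DMSO controls in the outer columns; compounds fill the
    interior columns row-major across plates.  Toxic compounds depress the
    nuclei count; hit compounds elevate all six maturity parameters (IEG
    fractions in the stimulated condition only, so the planted effect shows up
    as induced response).  Additive row/column artifacts are drawn per plate ×
    replicate × condition.
    """
    rng = np.random.default_rng(lib.seed)
    rows, cols = lib.plate_shape

    # control layout: outer columns first (col 0 then col cols-1, top-down)
    control_wells = []
    for c in (0, cols - 1):
        for r in range(rows):
            control_wells.append((r, c))
    control_wells = control_wells[: lib.controls_per_plate]
    control_set = set(control_wells)
    compound_wells = [(r, c) for c in range(cols) for r in range(rows)
                      if (r, c) not in control_set]

    ids = np.array([f"C{i + 1:04d}" for i in range(lib.n_compounds)])
    labels = np.array(["inert"] * lib.n_compounds, dtype=object)
    special = rng.choice(lib.n_compounds, size=lib.n_toxic + lib.n_hits,
                         replace=False)
    labels[special[: lib.n_toxic]] = "toxic"
    labels[special[lib.n_toxic:]] = "hit"
    truth = pd.DataFrame({"compound_id": ids, "label": labels})
    label_of = dict(zip(ids, labels))

    records = []
    for rep in range(1, lib.n_replicates + 1):
        for cond in ("stim", "unstim"):
            for plate_i in range(lib.n_plates):
                plate = f"P{plate_i + 1:02d}"
                row_eff = rng.normal(0.0, lib.row_effect_sd, size=rows)
                col_eff = rng.normal(0.0, lib.col_effect_sd, size=cols)
                start = plate_i * lib.wells_per_plate
                plate_ids = ids[start: start + lib.wells_per_plate]
                wells = ([(rc, "DMSO") for rc in control_wells]
                         + [(rc, cid) for rc, cid
                            in zip(compound_wells, plate_ids)])
                for (r, c), cid in wells:
                    lab = label_of.get(cid, "control")
                    rec = {"plate": plate, "well": well_name(r, c),
                           "row": r, "col": c, "condition": cond,
                           "compound_id": cid, "replicate": rep}
                    for feat in SCREEN_FEATURES + ("nuclei_count",):
                        base = _BASE[feat]
                        if isinstance(base, dict):
                            base = base[cond]
                        hw = _NOISE_HW[feat]
                        val = base + rng.uniform(-hw, hw)
                        if feat != "nuclei_count":
                            # plate artifacts model staining/illumination
                            # gradients: they perturb the intensity-derived
                            # features, not the detected-nuclei count
                            val += (row_eff[r] + col_eff[c]) * hw
                        if lab == "hit" and feat in MORPHOLOGY_FEATURES:
                            val += lib.hit_effect_sd * _ROBUST_OF_UNIFORM * hw
                        if (lab == "hit" and feat in IEG_FEATURES
                                and cond == "stim"):
                            val += lib.hit_effect_sd * _ROBUST_OF_UNIFORM * hw
                        if lab == "toxic" and feat == "nuclei_count":
                            val -= lib.toxic_effect_sd * _ROBUST_OF_UNIFORM * hw
                        if feat.startswith("frac"):
                            val = float(np.clip(val, 0.0, 1.0))
                        if feat == "nuclei_count":
                            val = max(val, 0.0)
                        rec[feat] = val
                    records.append(rec)
    features = pd.DataFrame.from_records(records)
    return PlateFeatureSet(features=features, truth=truth, spec=lib)


# ---------------------------------------------------------------------------
# MEA simulation
# ---------------------------------------------------------------------------


@dataclass
class MEASimSpec:
    """Parameters of a simulated extracellular array recording."""

    n_channels: int = 4096
    grid_shape: tuple = (64, 64)
    duration: float = 60.0          # s
    sampling_rate: float = 10000.0  # Hz
    noise_sd: float = 10.0          # μV
    baseline_rate: float = 0.1      # spikes/s per channel
    spike_amplitude: float = 12.0   # × noise_sd at the trough
    burst_rate: float = 0.0         # Hz (array-wide)
    burst_participation: float = 0.5
    burst_width: float = 0.15       # s
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if self.burst_rate < 0:
            raise ValueError("burst_rate must be non-negative")
        if not 0.0 <= self.burst_participation <= 1.0:
            raise ValueError("burst_participation must lie in [0, 1]")


@dataclass
class ArrayRecording:
    """Per-channel data from one electrode array.

    Either raw voltage ``traces`` (channel × sample, μV) or precomputed
    ``spike_trains`` (list of sorted time arrays, s) — or both — are present.
    """

    n_channels: int
    grid_shape: tuple
    duration: float
    sampling_rate: float
    traces: Optional[np.ndarray] = None
    spike_trains: Optional[list] = None
    truth: Optional[dict] = None


def _spike_template(fs: float) -> np.ndarray:
    """Biphasic extracellular waveform, trough normalized to −1."""
    t = np.arange(-int(0.001 * fs), int(0.0015 * fs) + 1) / fs
    w = -np.exp(-((t / 2.0e-4) ** 2)) + 0.35 * np.exp(
        -(((t - 4.5e-4) / 3.0e-4) ** 2))
    return w / abs(w.min())  # trough at exactly −1


def simulate_mea(spec: MEASimSpec, traces: Optional[bool] = None
                 ) -> ArrayRecording:
    """Simulate an array recording with planted spikes and network bursts.

    Baseline spikes are a per-channel Poisson process; bursts are windows of
    width ``burst_width`` placed at ``burst_rate`` (near-regular schedule with
    bounded jitter) in which ``burst_participation`` of the channels each fire
    1–2 extra spikes.  With ``traces=True`` (default when the sample count is
    desk-scale) raw voltages are synthesized as Gaussian noise plus biphasic
    waveforms of ``spike_amplitude`` × noise s.d.; otherwise only spike-time
    lists are returned.  Truth tables list every planted spike and burst.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.duration * spec.sampling_rate))
    if traces is None:
        traces = spec.n_channels * n_samples <= 40_000_000

    min_gap = 0.005  # s between spikes on one channel, > 2 ms refractory
    spike_lists: list[np.ndarray] = []
    for _ch in range(spec.n_channels):
        n = rng.poisson(spec.baseline_rate * spec.duration)
        times = np.sort(rng.uniform(0.0, spec.duration, size=n))
        spike_lists.append(times)

    burst_truth = []
    n_bursts = int(np.floor(spec.burst_rate * spec.duration))
    if n_bursts > 0:
        interval = spec.duration / n_bursts
        starts = (np.arange(n_bursts) * interval
                  + 0.2 * interval
                  + rng.uniform(-0.08, 0.08, size=n_bursts) * interval)
        n_part = int(round(spec.burst_participation * spec.n_channels))
        for s in starts:
            chans = rng.choice(spec.n_channels, size=n_part, replace=False)
            for ch in chans:
                k = rng.integers(1, 3)
                tt = s + rng.uniform(0.0, spec.burst_width, size=k)
                spike_lists[ch] = np.concatenate([spike_lists[ch], tt])
            burst_truth.append((float(s), float(s + spec.burst_width),
                                int(n_part)))

    # enforce per-channel minimum spacing; truth is the post-thinning list
    for ch in range(spec.n_channels):
        t = np.sort(spike_lists[ch])
        t = t[(t >= 0.0) & (t <= spec.duration - 0.002)]
        keep = []
        last = -np.inf
        for x in t:
            if x - last >= min_gap:
                keep.append(x)
                last = x
        spike_lists[ch] = np.asarray(keep)

    truth = {
        "spikes": pd.DataFrame(
            [(ch, t) for ch in range(spec.n_channels)
             for t in spike_lists[ch]],
            columns=["channel", "time_s"]),
        "bursts": pd.DataFrame(burst_truth,
                               columns=["start_s", "end_s", "n_channels"]),
    }

    trace_arr = None
    if traces:
        tmpl = _spike_template(spec.sampling_rate)
        half = len(tmpl)
        trace_arr = rng.normal(0.0, spec.noise_sd,
                               size=(spec.n_channels, n_samples))
        amp = spec.spike_amplitude * spec.noise_sd
        for ch in range(spec.n_channels):
            for t in spike_lists[ch]:
                i0 = int(round(t * spec.sampling_rate))
                i1 = min(i0 + half, n_samples)
                trace_arr[ch, i0:i1] += amp * tmpl[: i1 - i0]

    return ArrayRecording(
        n_channels=spec.n_channels, grid_shape=spec.grid_shape,
        duration=spec.duration, sampling_rate=spec.sampling_rate,
        traces=trace_arr, spike_trains=spike_lists, truth=truth)


# ---------------------------------------------------------------------------
# Calcium simulation
# ---------------------------------------------------------------------------


@dataclass
class CalciumSimSpec:
    """Parameters of a simulated ROI fluorescence recording."""

    n_rois: int = 20
    frame_interval: float = 5.0     # s
    duration: float = 1200.0        # s; 20 min → 240 frames
    baseline: float = 1000.0        # AFU
    transient_amplitude: float = 800.0
    transient_decay: float = 3.0    # frames (e-folding; 15 s at 5-s frames)
    events_per_roi: int = 5
    noise_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        nf = self.duration / self.frame_interval
        if abs(nf - round(nf)) > 1e-9:
            raise ValueError(
                "duration must be an integer multiple of frame_interval")
        if self.transient_amplitude <= 0 or self.baseline <= 0:
            raise ValueError("baseline and transient_amplitude must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))


@dataclass
class CalciumTraceSet:
    """ROI × frame fluorescence matrix with the acquisition schedule."""

    traces: np.ndarray            # (n_rois, n_frames), AFU
    frame_interval: float
    truth: Optional[dict] = None  # {"events": {roi: frame indices}}

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]


def simulate_calcium(spec: CalciumSimSpec) -> CalciumTraceSet:
    """Simulate ROI traces with planted exponentially decaying transients."""
    rng = np.random.default_rng(spec.seed)
    nf = spec.n_frames
    frames = np.arange(nf)
    traces = np.empty((spec.n_rois, nf))
    events: dict[int, np.ndarray] = {}
    min_gap = max(int(6 * spec.transient_decay), 4)
    for roi in range(spec.n_rois):
        tr = np.full(nf, spec.baseline, dtype=float)
        ev: list[int] = []
        guard = 0
        while len(ev) < spec.events_per_roi and guard < 10000:
            guard += 1
            f0 = int(rng.integers(2, nf - 3))
            if all(abs(f0 - e) >= min_gap for e in ev):
                ev.append(f0)
        if len(ev) < spec.events_per_roi:
            raise RuntimeError("could not place transients with the required "
                               "separation; reduce events_per_roi")
        ev.sort()
        for f0 in ev:
            amp = spec.transient_amplitude * rng.uniform(0.8, 1.2)
            mask = frames >= f0
            tr[mask] += amp * np.exp(-(frames[mask] - f0) / spec.transient_decay)
        tr += rng.normal(0.0, spec.noise_sd, size=nf)
        traces[roi] = tr
        events[roi] = np.asarray(ev, dtype=int)
    return CalciumTraceSet(traces=traces, frame_interval=spec.frame_interval,
                           truth={"events": events})
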