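"""Ground-truthed synthetic inputs: fiber mosaics, gait traces, force traces.

The mosaic generator emulates a laminin/procion-orange confocal section:
jittered hexagonal (or square) seed points tessellated Voronoi-fashion into
polygonal fibers with bright borders on the green channel and per-fiber dye
fill on the red channel.  Every generator is a pure function of its spec and
seed, and each records exact ground truth (labels, positivity flags, lattice
ring index for layer peeling) so segmentation accuracy can be scored without
manual annotation.

The gait-trace generator emulates the structure of human walking-simulation
muscle traces: a smooth periodic fiber-length excursion that starts below the
optimal length, burst-like excitation in [0, 1], and a non-negative
plausibility force channel.  Defaults reproduce the study conditions: soleus
peak-to-peak excursion 40% of Lo, EDL 20%, cycle period 1.101 s from the
walking cadence of 109 steps/min.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import morphology, segmentation

from .histology import Channel, ChannelImage
from .metrics import ForceTrace
from .protocol import HumanGaitTrace, Muscle

__all__ = [
    "MosaicSpec",
    "MosaicTruth",
    "generate_fiber_mosaic",
    "GAIT_TEMPLATES",
    "generate_gait_trace",
    "generate_force_trace",
]


@dataclass(frozen=True)
class MosaicSpec:
    """Geometry, staining and corruption settings of one synthetic mosaic."""

    grid: tuple[int, int] = (9, 9)
    lattice: str = "hex"                 # "hex" or "square"
    fiber_spacing_px: float = 30.0
    jitter_px: float = 2.0
    border_thickness_px: int = 3
    margin_px: int = 14
    gap_probability: float = 0.0
    gap_width_px: int = 3
    positive_fraction: float = 0.0
    dye_coverage: float = 1.0
    noise_sd: float = 0.0                # fraction of dynamic range
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.positive_fraction <= 1:
            raise ValueError("positive_fraction must lie in [0, 1]")
        if not 0 <= self.dye_coverage <= 1:
            raise ValueError("dye_coverage must lie in [0, 1]")
        if self.lattice not in ("hex", "square"):
            raise ValueError("lattice must be 'hex' or 'square'")
        if self.fiber_spacing_px < 4 * self.border_thickness_px:
            raise ValueError("fiber spacing too small for the border thickness")
        if self.jitter_px > 0.25 * self.fiber_spacing_px:
            raise ValueError("jitter too large: fibers would swap lattice sites")


@dataclass(frozen=True)
class MosaicTruth:
    """Exact ground truth rendered into the mosaic images."""

    labels: np.ndarray                  # fiber interiors, 0 = border/exterior
    positive_ids: tuple[int, ...]
    ring_index: dict[int, int] = field(repr=False)  # lattice ring, 0 = outermost

    @property
    def n_fibers(self) -> int:
        return len(self.ring_index)

    def interior_ids(self, n_layers: int) -> tuple[int, ...]:
        """Fibers remaining after removing ``n_layers`` outer lattice rings.

        Exact for square lattices; on hexagonal lattices the geometric
        peeling order can deviate at offset-row edges, where
        :meth:`peeled_interior_ids` is the reference instead.
        """
        return tuple(i for i, r in self.ring_index.items() if r >= n_layers)

    def peeled_interior_ids(self, n_layers: int) -> tuple[int, ...]:
        """Interior fibers under adjacency peeling of the perfect truth labels.

        This is the perfect-segmentation reference: it applies the layer
        definition to the rendered geometry itself, so comparing a pipeline
        result against it isolates segmentation error from layer-definition
        ambiguity.
        """
        from .histology import FiberLabelMap, peel_outer_layers
        fm = peel_outer_layers(FiberLabelMap.from_labels(self.labels), n_layers)
        return tuple(int(i) for i in fm.included_ids)

    def percent_positive(self, n_layers: int, peeled: bool = True) -> float:
        ids = (self.peeled_interior_ids(n_layers) if peeled
               else self.interior_ids(n_layers))
        if not ids:
            raise ValueError("no interior fibers at this peeling depth")
        pos = sum(1 for i in ids if i in self.positive_ids)
        return 100.0 * pos / len(ids)


def _lattice_seeds(spec: MosaicSpec, rng: np.random.Generator,
                   ) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    rows, cols = spec.grid
    s = spec.fiber_spacing_px
    pts, ring = [], []
    if spec.lattice == "hex":
        dy = s * np.sqrt(3) / 2
        for i in range(rows):
            for j in range(cols):
                x = spec.margin_px + s * (j + 0.5 + 0.25 * (i % 2)) - 0.125 * s
                y = spec.margin_px + dy * (i + 0.5)
                pts.append((y, x))
                ring.append(min(i, j, rows - 1 - i, cols - 1 - j))
        height = int(np.ceil(2 * spec.margin_px + dy * rows))
        width = int(np.ceil(2 * spec.margin_px + s * (cols + 0.5)))
    else:
        for i in range(rows):
            for j in range(cols):
                pts.append((spec.margin_px + s * (i + 0.5),
                            spec.margin_px + s * (j + 0.5)))
                ring.append(min(i, j, rows - 1 - i, cols - 1 - j))
        height = width = None
        height = int(np.ceil(2 * spec.margin_px + s * rows))
        width = int(np.ceil(2 * spec.margin_px + s * cols))
    pts = np.asarray(pts, dtype=float)
    pts += rng.uniform(-spec.jitter_px, spec.jitter_px, size=pts.shape)
    return pts, np.asarray(ring), (height, width)


def generate_fiber_mosaic(spec: MosaicSpec) -> tuple[ChannelImage, ChannelImage,
                                                     MosaicTruth]:
    """Render a two-channel fiber mosaic with exact ground truth.

    Returns (green laminin borders, red dye channel, truth).  Bit-identical
    for a fixed spec (the seed is part of the spec).
    """
    rng = np.random.default_rng(spec.seed)
    seeds, ring, (h, w) = _lattice_seeds(spec, rng)
    if min(h, w) < 64:
        raise ValueError("mosaic too small; increase grid or spacing")
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    _, idx = cKDTree(seeds).query(pix, k=1)
    cell = (idx + 1).astype(np.int32).reshape(h, w)
    # section support: convex hull of the seed lattice plus half a cell of
    # rim; a convex rim keeps outer cells compact (no necked crescents)
    seed_mask = np.zeros((h, w), dtype=bool)
    seed_mask[np.clip(np.round(seeds[:, 0]).astype(int), 0, h - 1),
              np.clip(np.round(seeds[:, 1]).astype(int), 0, w - 1)] = True
    hull = morphology.convex_hull_image(seed_mask)
    section = ndi.distance_transform_edt(~hull) <= 0.45 * spec.fiber_spacing_px
    cell[~section] = 0

    # border network: boundaries between cells and around the section rim
    bounds = segmentation.find_boundaries(cell, mode="thick", background=-1)
    half = max(spec.border_thickness_px // 2, 1)
    border = morphology.dilation(bounds & section, morphology.disk(half))
    border &= section

    n_fibers = len(seeds)
    truth_labels = np.where(border, 0, cell).astype(np.int32)

    # border gaps: per selected fiber, erase a disk on its boundary
    gap_ids = [i + 1 for i in range(n_fibers)
               if rng.random() < spec.gap_probability]
    green_border = border.copy()
    for gid in gap_ids:
        edge = border & morphology.dilation(cell == gid,
                                                   np.ones((3, 3), bool))
        ys, xs = np.nonzero(edge)
        if ys.size == 0:
            continue
        k = rng.integers(ys.size)
        hole = np.zeros_like(border)
        hole[ys[k], xs[k]] = True
        # gap_width_px is the real opening width: a disk of radius (w-1)//2
        r_hole = (spec.gap_width_px - 1) // 2
        if r_hole > 0:
            hole = morphology.dilation(hole, morphology.disk(r_hole))
        green_border &= ~hole

    # dye: exact count of positive fibers, innermost pixels filled first
    n_pos = int(round(spec.positive_fraction * n_fibers))
    positive_ids = tuple(int(i) + 1 for i in
                         rng.choice(n_fibers, size=n_pos, replace=False))
    red = np.full((h, w), 0.05)
    if positive_ids:
        interior_dist = ndi.distance_transform_edt(truth_labels > 0)
        for pid in positive_ids:
            sel = truth_labels == pid
            if spec.dye_coverage >= 1.0:
                red[sel] = 0.85
            elif spec.dye_coverage > 0:
                d = interior_dist[sel]
                cut = np.quantile(d, 1.0 - spec.dye_coverage)
                inner = np.zeros_like(sel)
                inner[sel] = d >= cut
                red[inner] = 0.85
    green = np.where(green_border, 0.9, 0.12)

    if spec.noise_sd > 0:
        green = green + rng.normal(0, spec.noise_sd, green.shape)
        red = red + rng.normal(0, spec.noise_sd, red.shape)
    green = np.clip(green, 0.0, 1.0)
    red = np.clip(red, 0.0, 1.0)

    truth = MosaicTruth(truth_labels, positive_ids,
                        {i + 1: int(r) for i, r in enumerate(ring)})
    return (ChannelImage(green, Channel.LAMININ_GREEN),
            ChannelImage(red, Channel.DYE_RED), truth)


# ---------------------------------------------------------------------------
# Gait traces
# ---------------------------------------------------------------------------

#: Stride period of the walking simulation's subject: cadence 109 steps/min,
#: one gait cycle = two steps -> 2 * 60 / 109 s.
CYCLE_PERIOD_S = 2 * 60.0 / 109.0

#: Representative template settings per muscle.  Optimal fiber lengths and
#: model forces are of the order used in human lower-limb models; the
#: excursion fractions are the study conditions (40% soleus, 20% EDL).
#: Burst windows (fractions of the cycle): soleus fires through stance;
#: EDL (dorsiflexor) fires in swing and again around heel strike, giving its
#: characteristic two-peak force shape.
GAIT_TEMPLATES = {
    Muscle.SOLEUS: dict(excursion_fraction=0.40, lo_human_mm=44.0,
                        fmax_human_n=2800.0,
                        excitation_bursts=((0.10, 0.55, 0.85),)),
    Muscle.EDL: dict(excursion_fraction=0.20, lo_human_mm=69.0,
                     fmax_human_n=350.0,
                     excitation_bursts=((0.00, 0.10, 0.55),
                                        (0.58, 0.78, 0.80))),
}


def _merge_bursts(bursts):
    out = []
    for b in sorted(bursts, key=lambda b: b[0]):
        if out and b[0] < out[-1][1]:
            _warnings.warn("overlapping excitation bursts merged")
            prev = out.pop()
            out.append((prev[0], max(prev[1], b[1]), max(prev[2], b[2])))
        else:
            out.append(tuple(b))
    return out


def generate_gait_trace(muscle: Muscle | str = Muscle.SOLEUS,
                        excursion_fraction: float | None = None,
                        excitation_bursts=None,
                        cycle_T_s: float = CYCLE_PERIOD_S,
                        n_samples: int = 201,
                        lo_human_mm: float | None = None,
                        fmax_human_n: float | None = None) -> HumanGaitTrace:
    """Parametric one-cycle human gait trace emulating a walking simulation.

    The fiber length is a smooth two-harmonic periodic curve with the given
    peak-to-peak excursion (fraction of Lo) that starts just below the optimal
    length, as all gait cycles do.  Excitation is a sum of smoothed boxcar
    bursts ``(onset_frac, offset_frac, level)``; force is a plausibility
    channel (excitation x force-length factor x Fmax), not ground truth.
    """
    muscle = Muscle.coerce(muscle)
    tmpl = GAIT_TEMPLATES[muscle]
    exc_frac = tmpl["excursion_fraction"] if excursion_fraction is None \
        else float(excursion_fraction)
    if exc_frac <= 0:
        raise ValueError("excursion_fraction must be > 0")
    lo = tmpl["lo_human_mm"] if lo_human_mm is None else float(lo_human_mm)
    fmax = tmpl["fmax_human_n"] if fmax_human_n is None else float(fmax_human_n)
    bursts = _merge_bursts(tmpl["excitation_bursts"]
                           if excitation_bursts is None else excitation_bursts)

    tau = np.linspace(0.0, 1.0, n_samples)
    shape = 0.8 * np.sin(2 * np.pi * (tau - 0.15)) \
        + 0.2 * np.sin(4 * np.pi * (tau - 0.05))
    u = (shape - shape.min()) / np.ptp(shape)      # normalized to [0, 1]
    # start the cycle 2% of Lo below optimal length
    norm_length = 1.0 + exc_frac * (u - u[0]) - 0.02
    length = lo * norm_length

    exc = np.zeros_like(tau)
    for on, off, level in bursts:
        exc = np.maximum(exc, np.where((tau >= on) & (tau <= off), level, 0.0))
    exc = ndi.gaussian_filter1d(exc, sigma=0.02 * n_samples, mode="wrap")
    exc = np.clip(exc, 0.0, 1.0)

    fl = np.exp(-(((norm_length - 1.0) / 0.45) ** 2))
    force = np.clip(exc * fl * fmax, 0.0, None)
    return HumanGaitTrace(tau * cycle_T_s, length, exc, force)


def generate_force_trace(n_cycles: int, peak_schedule, n_peaks: int = 1,
                         noise_sd: float = 0.0, seed: int = 0,
                         cycle_T_s: float = 1.0,
                         sample_rate_hz: float = 1000.0,
                         peak_times=(0.3, 0.7)) -> ForceTrace:
    """Multi-cycle force trace with a known per-cycle peak schedule.

    ``peak_schedule`` holds one amplitude (mN) per cycle for ``n_peaks=1`` or
    an (amp1, amp2) pair per cycle for ``n_peaks=2``; each peak is a Gaussian
    bump at a fixed phase of the cycle.  ``noise_sd`` is additive Gaussian
    noise in mN, clipped so force stays non-negative.
    """
    schedule = np.atleast_2d(np.asarray(peak_schedule, dtype=float))
    if schedule.shape[0] == 1 and n_cycles > 1:
        schedule = schedule.reshape(n_cycles, -1)
    if schedule.shape != (n_cycles, n_peaks):
        raise ValueError("peak_schedule must supply n_peaks amplitudes per cycle")
    rng = np.random.default_rng(seed)
    n_per = int(round(cycle_T_s * sample_rate_hz))
    t_cycle = np.arange(n_per) / sample_rate_hz
    centers = [0.5 * cycle_T_s] if n_peaks == 1 else \
        [p * cycle_T_s for p in peak_times]
    sigma = 0.06 * cycle_T_s
    chunks, boundaries = [], []
    for c in range(n_cycles):
        f = np.zeros(n_per)
        for amp, mu in zip(schedule[c], centers):
            f += amp * np.exp(-0.5 * ((t_cycle - mu) / sigma) ** 2)
        chunks.append(f)
        boundaries.append((c * cycle_T_s, (c + 1) * cycle_T_s))
    force = np.concatenate(chunks)
    if noise_sd > 0:
        force = force + rng.normal(0, noise_sd, force.shape)
    force = np.clip(force, 0.0, None)
    time = np.arange(len(force)) / sample_rate_hz
    return ForceTrace(time, force, tuple(boundaries))
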