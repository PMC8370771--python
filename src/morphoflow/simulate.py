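"""Synthetic imaging-flow-cytometry data with known ground truth.

The generator emulates the statistical structure the downstream pipeline
assumes: distinct cell populations parameterized by size, nuclear/cell (N/C)
area ratio, cytoplasmic granularity and fluorescence-marker intensity; 2N/4N
DNA-content bimodality; per-sample multiplicative intensity drift;
fluorescence spillover between channels; and doublet and debris events.
Every event carries its ground-truth population label, ploidy, flags and
masks, so clustering and gating can be scored against the truth.

Images are rendered in float64 on a 64x64 frame by default (a 32x32 crop is
then a true crop for large cells and a pad for small ones); quantization to
16-bit unsigned is available as a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ImageEvent, SpilloverMatrix, is_fluorescence

# Rendering constants (arbitrary-unit intensities, 16-bit friendly).
BF_BACKGROUND = 200.0
BF_CELL_LEVEL = 120.0
BF_NOISE_SD = 2.0
SSC_UNIT = 30.0          # in-cell SSC intensity per unit granularity_level
FLUOR_BACKGROUND = 5.0
FLUOR_NOISE_SD = 0.3
DNA_2N_TOTAL = 5000.0    # total nuclear intensity of a 2N cell before drift


@dataclass
class ImageGeometry:
    """Frame size, channel list and quantization flag for rendering."""

    frame: tuple[int, int] = (64, 64)
    channels: tuple[str, ...] = ("BF", "SSC", "DNA", "FL1")
    quantize: bool = False


@dataclass
class PopulationSpec:
    """One cell population: morphology and marker-intensity parameters.

    ``channel_means`` maps fluorescence channel name (e.g. ``"FL1"``) to the
    (mean, sd) of the natural log of the event's total intensity in that
    channel.  ``granularity_level`` (>= 0) scales the multiplicative
    log-normal speckle texture and the SSC signal.
    """

    name: str
    frequency: float
    cell_diameter: tuple[float, float]          # mean, sd in pixels
    nc_ratio: tuple[float, float]               # mean, sd; mean in (0, 1)
    granularity_level: float
    channel_means: dict[str, tuple[float, float]] = field(default_factory=dict)
    dna_4n_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency must be in [0,1], got {self.frequency}")
        if self.cell_diameter[0] <= 0:
            raise ValueError("cell_diameter mean must be > 0")
        if not 0.0 < self.nc_ratio[0] < 1.0:
            raise ValueError("nc_ratio mean must be in (0,1)")
        if self.granularity_level < 0:
            raise ValueError("granularity_level must be >= 0")
        if not 0.0 <= self.dna_4n_fraction <= 1.0:
            raise ValueError("dna_4n_fraction must be in [0,1]")


@dataclass
class SampleSpec:
    """One simulated sample: populations, event count, drift and artifacts."""

    sample_id: str
    condition: str
    n_events: int
    populations: list[PopulationSpec]
    intensity_drift: dict[str, float] = field(default_factory=dict)
    doublet_rate: float = 0.0
    debris_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        total = sum(p.frequency for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population frequencies sum to {total}, expected 1")
        if self.doublet_rate + self.debris_rate >= 1.0:
            raise ValueError("doublet_rate + debris_rate must be < 1")
        for ch, f in self.intensity_drift.items():
            if f <= 0:
                raise ValueError(f"intensity drift for {ch} must be > 0")


def default_populations() -> list[PopulationSpec]:
    """Four well-separated hematopoietic-like populations.

    Loosely modeled on the composition of a fish kidney-marrow suspension:
    small high-N/C lymphoid cells, medium blast-like progenitors, large
    agranular monocytic cells and large granular cells, with FL1 marker
    intensities about a decade apart.  The mixture is non-cycling
    (dna_4n_fraction = 0): a cycling compartment of any size is a fifth
    population in its own right — all 4N cells share the DNA-high signature
    across morphologies and legitimately cluster together — so benchmarks
    that are defined as four populations exclude it.  Fixtures exercising
    the 2N/4N machinery use populations with a large 4N fraction instead.
    """
    return [
        PopulationSpec("lymphoid", 0.35, (12.0, 0.9), (0.80, 0.03), 0.1,
                       {"FL1": (math.log(20000.0), 0.25)}, dna_4n_fraction=0.0),
        PopulationSpec("progenitor", 0.25, (16.0, 1.1), (0.62, 0.03), 0.4,
                       {"FL1": (math.log(200.0), 0.25)}, dna_4n_fraction=0.0),
        PopulationSpec("monocytic", 0.25, (21.0, 1.3), (0.45, 0.03), 0.9,
                       {"FL1": (math.log(200000.0), 0.25)}, dna_4n_fraction=0.0),
        PopulationSpec("granulocyte", 0.15, (19.0, 1.2), (0.38, 0.03), 2.5,
                       {"FL1": (math.log(2000.0), 0.25)}, dna_4n_fraction=0.0),
    ]


def default_sample_spec(sample_id: str = "s1", condition: str = "ctrl",
                        n_events: int = 4000, seed: int = 0,
                        doublet_rate: float = 0.03,
                        debris_rate: float = 0.03) -> SampleSpec:
    return SampleSpec(sample_id, condition, n_events, default_populations(),
                      doublet_rate=doublet_rate, debris_rate=debris_rate, seed=seed)


# ---------------------------------------------------------------------------
# rendering

def _ellipse_mask(shape, center, a, b, theta, boundary=None) -> np.ndarray:
    """Elliptical mask, optionally with low-order harmonic boundary wobble.

    ``boundary`` is a list of (amplitude, harmonic, phase) triples perturbing
    the radius as r(angle) = 1 + sum a_m cos(m*angle + phi_m): real cell
    outlines are irregular, and the wobble keeps discrete shape features
    (perimeter, solidity, circularity) continuously distributed.
    """
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    dy, dx = yy - center[0], xx - center[1]
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    lim = np.ones_like(r)
    if boundary:
        ang = np.arctan2(v / b, u / a)
        for amp, m, phase in boundary:
            lim = lim + amp * np.cos(m * ang + phase)
    return r <= lim


def _draw_boundary(rng, amplitude: float = 0.03):
    return [(rng.normal(0.0, amplitude), m, rng.uniform(0, 2 * math.pi))
            for m in (2, 3, 4)]


def _speckle(rng, shape, sigma):
    """Unit-mean multiplicative log-normal field with ~1-2 px grain."""
    if sigma <= 0:
        return np.ones(shape)
    z = rng.standard_normal(shape)
    z = 0.7 * z + 0.3 * ndimage.gaussian_filter(rng.standard_normal(shape), 1.2)
    return np.exp(sigma * z - 0.5 * sigma**2)


def _draw_cell(rng, pop: PopulationSpec, geometry: ImageGeometry, center=None):
    """Render one cell's per-channel contributions; returns (channels, cell, nucleus, ploidy).

    Fluorescence channels contain signal only (no background); BF is returned
    as the darkening to subtract from the bright background.
    """
    h, w = geometry.frame
    d = max(4.0, rng.normal(*pop.cell_diameter))
    if min(h, w) < d + 4:
        raise ValueError(f"cell diameter {d:.1f}px does not fit frame {geometry.frame} with 4px margin")
    # minor/major axis ratio: mostly round with a unimodal tail of mildly
    # elongated cells (a flat distribution here would create artificial
    # density modes for the downstream mode-seeking clustering)
    q = float(np.clip(1.0 - abs(rng.normal(0.0, 0.05)), 0.85, 1.0))
    a, b = (d / 2) / math.sqrt(q), (d / 2) * math.sqrt(q)
    theta = rng.uniform(0, math.pi)
    if center is None:
        center = (h / 2 + rng.uniform(-2, 2), w / 2 + rng.uniform(-2, 2))
    cell = _ellipse_mask(geometry.frame, center, a, b, theta,
                         boundary=_draw_boundary(rng))
    nc = float(np.clip(rng.normal(*pop.nc_ratio), 0.02, 0.999))
    s = math.sqrt(nc)
    nucleus = _ellipse_mask(geometry.frame, center, a * s, b * s, theta,
                            boundary=_draw_boundary(rng, 0.04)) & cell

    chans: dict[str, np.ndarray] = {}
    g = pop.granularity_level
    # BF darkening: cell interior sits below the bright background, modulated
    # by granularity speckle.
    bf_tex = BF_CELL_LEVEL * _speckle(rng, geometry.frame, 0.08 * g)
    chans["BF"] = np.where(cell, np.clip(BF_BACKGROUND - bf_tex, 0, None), 0.0)
    # SSC: intensity proportional to granularity_level inside the mask, with
    # speckle log-sd also scaling with the level so the granularity spectrum
    # (a removed-intensity *fraction*, scale-invariant) responds to it.
    if g > 0:
        ssc = SSC_UNIT * g * _speckle(rng, geometry.frame, 0.35 * g)
        chans["SSC"] = np.where(cell, ssc, 0.0)
    else:
        chans["SSC"] = np.zeros(geometry.frame)
    # DNA: total nuclear intensity proportional to ploidy.
    ploidy = 4 if rng.uniform() < pop.dna_4n_fraction else 2
    npx = int(nucleus.sum())
    dna = np.zeros(geometry.frame)
    if npx:
        total = DNA_2N_TOTAL * (ploidy / 2.0) * math.exp(rng.normal(0.0, 0.05))
        tex = _speckle(rng, geometry.frame, 0.1)
        tex = np.where(nucleus, tex, 0.0)
        dna = tex * (total / tex.sum())
    chans["DNA"] = dna
    # Extra fluorescence channels: log-normal total spread over the cell.
    for ch in geometry.channels:
        if ch in ("BF", "SSC", "DNA"):
            continue
        cpx = int(cell.sum())
        img = np.zeros(geometry.frame)
        if ch in pop.channel_means and cpx:
            mu, sd = pop.channel_means[ch]
            total = math.exp(rng.normal(mu, sd))
            tex = np.where(cell, _speckle(rng, geometry.frame, 0.15), 0.0)
            img = tex * (total / tex.sum())
        chans[ch] = img
    return chans, cell, nucleus, ploidy


def _assemble(chans_list, cells, nuclei, geometry: ImageGeometry, rng):
    """Compose cell contributions onto a noisy frame background."""
    h, w = geometry.frame
    out: dict[str, np.ndarray] = {}
    for ch in geometry.channels:
        if ch == "BF":
            img = BF_BACKGROUND + rng.normal(0, BF_NOISE_SD, (h, w))
            for c in chans_list:
                img = np.where(c["BF"] > 0, np.minimum(img, c["BF"]), img)
        elif ch == "SSC":
            img = np.zeros((h, w))
            for c in chans_list:
                img = img + c["SSC"]
        else:
            img = FLUOR_BACKGROUND + rng.normal(0, FLUOR_NOISE_SD, (h, w))
            for c in chans_list:
                img = img + c[ch]
        out[ch] = np.clip(img, 0, None)
    cell = np.zeros((h, w), dtype=bool)
    for m in cells:
        cell |= m
    nuc = np.zeros((h, w), dtype=bool)
    for m in nuclei:
        nuc |= m
    return out, cell, nuc


def render_cell_image(pop: PopulationSpec, rng_seed: int,
                      geometry: ImageGeometry | None = None,
                      event_id: str = "e0", sample_id: str = "s0") -> ImageEvent:
    """Render a single cell of ``pop`` into an :class:`ImageEvent`.

    Same (pop, seed, geometry) gives a pixel-identical stack.  Raises if the
    drawn cell cannot fit the frame with a 4 px margin.
    """
    geometry = geometry or ImageGeometry()
    rng = np.random.default_rng(rng_seed)
    chans, cell, nucleus, ploidy = _draw_cell(rng, pop, geometry)
    out, cellm, nucm = _assemble([chans], [cell], [nucleus], geometry, rng)
    if geometry.quantize:
        out = {c: np.round(np.clip(a, 0, 65535)).astype(np.uint16).astype(float)
               for c, a in out.items()}
    ev = ImageEvent(event_id, sample_id, out,
                    truth_masks={"cell": cellm, "nucleus": nucm})
    ev.flags["ploidy"] = ploidy
    return ev


def _render_doublet(rng, populations, freqs, geometry):
    """Two overlapping same-population cells along a random axis.

    Doublets are modeled as aggregates of like cells (the common case in
    flow), with 30-50% mask overlap: the union has roughly 1.5-1.7x the
    singlet area and a clearly reduced aspect ratio, the signature the
    area-vs-aspect singlet gate keys on.
    """
    h, w = geometry.frame
    i1 = i2 = int(rng.choice(len(populations), p=freqs))
    theta = rng.uniform(0, 2 * math.pi)
    d1 = populations[i1].cell_diameter[0]
    d2 = populations[i2].cell_diameter[0]
    # center distance in (0.42, 0.58) of the summed radii -> 30-50% overlap
    off = (d1 + d2) / 2 * rng.uniform(0.84, 1.16) / 2
    c0 = (h / 2, w / 2)
    c1 = (c0[0] - off / 2 * math.sin(theta), c0[1] - off / 2 * math.cos(theta))
    c2 = (c0[0] + off / 2 * math.sin(theta), c0[1] + off / 2 * math.cos(theta))
    ch1, m1, n1, p1 = _draw_cell(rng, populations[i1], geometry, center=c1)
    ch2, m2, n2, p2 = _draw_cell(rng, populations[i2], geometry, center=c2)
    return [ch1, ch2], [m1, m2], [n1, n2], p1 + p2


def _render_debris(rng, geometry):
    """Sub-threshold fragment: faint BF dent, weak SSC, no nuclear signal."""
    h, w = geometry.frame
    d = rng.uniform(2.0, 5.0)
    center = (h / 2 + rng.uniform(-4, 4), w / 2 + rng.uniform(-4, 4))
    frag = _ellipse_mask(geometry.frame, center, d / 2, d / 2 * rng.uniform(0.5, 1.0),
                         rng.uniform(0, math.pi))
    chans = {ch: np.zeros(geometry.frame) for ch in geometry.channels}
    chans["BF"] = np.where(frag, BF_BACKGROUND - 40.0 * _speckle(rng, geometry.frame, 0.2), 0.0)
    chans["SSC"] = np.where(frag, 5.0 * _speckle(rng, geometry.frame, 0.5), 0.0)
    return chans, frag


def apply_spillover(event: ImageEvent, spill: SpilloverMatrix) -> ImageEvent:
    """Mix fluorescence channels: detected = S.T @ true, per pixel."""
    if spill.is_identity:
        return event
    stack = np.stack([event.channels[c] for c in spill.channels])
    mixed = np.einsum("tc,thw->chw", spill.matrix, stack)
    chans = dict(event.channels)
    for i, c in enumerate(spill.channels):
        chans[c] = mixed[i]
    return replace(event, channels=chans)


def simulate_sample(spec: SampleSpec, spill: SpilloverMatrix | None = None,
                    geometry: ImageGeometry | None = None
                    ) -> tuple[list[ImageEvent], pd.DataFrame]:
    """Simulate one sample: events per population frequencies plus artifacts.

    Returns the rendered events and a ground-truth table with one row per
    event (population, ploidy, doublet/debris flags, true mask areas).
    Output is a pure function of (spec, spill, geometry).
    """
    geometry = geometry or ImageGeometry()
    rng = np.random.default_rng(spec.seed)
    freqs = np.array([p.frequency for p in spec.populations])
    events: list[ImageEvent] = []
    rows = []
    for i in range(spec.n_events):
        u = rng.uniform()
        eid = f"{spec.sample_id}_{i:06d}"
        ploidy = 0
        if u < spec.debris_rate:
            kind, label = "debris", "debris"
            chans, frag = _render_debris(rng, geometry)
            out, cellm, nucm = _assemble([chans], [frag], [], geometry, rng)
        elif u < spec.debris_rate + spec.doublet_rate:
            kind, label = "doublet", "doublet"
            chans_list, cells, nuclei, ploidy = _render_doublet(
                rng, spec.populations, freqs, geometry)
            out, cellm, nucm = _assemble(chans_list, cells, nuclei, geometry, rng)
        else:
            kind = "singlet"
            idx = int(rng.choice(len(freqs), p=freqs))
            pop = spec.populations[idx]
            label = pop.name
            chans, cell, nucleus, ploidy = _draw_cell(rng, pop, geometry)
            out, cellm, nucm = _assemble([chans], [cell], [nucleus], geometry, rng)
        # per-sample multiplicative intensity drift
        for ch, factor in spec.intensity_drift.items():
            out[ch] = out[ch] * factor
        if geometry.quantize:
            out = {c: np.round(np.clip(a, 0, 65535)).astype(np.uint16).astype(float)
                   for c, a in out.items()}
        ev = ImageEvent(eid, spec.sample_id, out,
                        truth_masks={"cell": cellm, "nucleus": nucm})
        ev.flags["ploidy"] = ploidy
        if spill is not None:
            ev = apply_spillover(ev, spill)
        events.append(ev)
        rows.append({
            "event_id": eid, "sample_id": spec.sample_id, "condition": spec.condition,
            "population": label, "ploidy": ploidy,
            "is_doublet": kind == "doublet", "is_debris": kind == "debris",
            "cell_area_true": int(cellm.sum()), "nucleus_area_true": int(nucm.sum()),
        })
    return events, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# count-matrix simulation for the differential-abundance harness

def simulate_count_matrix(n_clusters: int, n_per_condition: tuple[int, int],
                          baseline_proportions: np.ndarray,
                          effect_log2fc: np.ndarray,
                          dispersion: float, seed: int,
                          total_per_sample: int = 10_000):
    """Simulate a clusters x samples count matrix for two conditions.

    Counts are drawn negative-binomially (gamma-Poisson) around
    condition-specific expected proportions of a fixed per-sample total
    (default 10,000 recorded events per sample).  ``effect_log2fc`` is a
    per-cluster log2 fold change applied to the second condition, with
    proportions renormalized to sum to 1 (compositional).  ``dispersion`` is
    the NB dispersion phi (variance = mu + phi*mu^2); phi = 0 reduces to
    Poisson sampling.

    Returns ``(counts DataFrame [clusters x samples], conditions Series)``.
    """
    p = np.asarray(baseline_proportions, dtype=float)
    if p.shape != (n_clusters,):
        raise ValueError("baseline_proportions length must equal n_clusters")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("baseline proportions must sum to 1")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    fc = np.asarray(effect_log2fc, dtype=float)
    if fc.shape != (n_clusters,):
        raise ValueError("effect_log2fc length must equal n_clusters")
    rng = np.random.default_rng(seed)
    p2 = p * np.exp2(fc)
    p2 = p2 / p2.sum()
    n1, n2 = n_per_condition
    cols, conds = [], []
    for j in range(n1 + n2):
        prop = p if j < n1 else p2
        mu = total_per_sample * prop
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
        else:
            lam = mu
        cols.append(rng.poisson(lam))
        conds.append("A" if j < n1 else "B")
    samples = [f"s{j+1}" for j in range(n1 + n2)]
    counts = pd.DataFrame(np.column_stack(cols),
                          index=[f"c{i+1}" for i in range(n_clusters)],
                          columns=samples)
    return counts, pd.Series(conds, index=samples, name="condition")
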