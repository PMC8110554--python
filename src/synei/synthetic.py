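"""Synthetic cohort generator with planted, recoverable ground truth.

Every analysis stage in this package has a matching generator here that
emulates the statistical structure the stage assumes, while recording the
planted truth so parameter recovery can be verified end to end:

* ``gen_fdt_stack``   — two-channel 3D stacks of spherical-Gaussian puncta
  over a noisy background, with co-localized oversized lipofuscin-like
  blobs in both channels.  Per-group punctum intensity models plant the
  leftward intensity shifts and peak-ratio changes of diseased tissue.
* ``gen_ish_image``   — 2D label-dark fields of non-overlapping cell disks
  plus sub-threshold speckle artifacts.
* ``gen_oocyte_traces`` — voltage-clamp traces (baseline, drift,
  mono-exponential activation/deactivation, Gaussian noise) for GABA and
  kainate applied to the same oocyte.
* ``gen_flow_events`` — particle-diameter mixtures over (0.5, 4) µm.
* ``gen_expression``  — log-normal FPKM matrices with named DLG4/GPHN genes,
  per-group multipliers, and a "postsynapse" block co-varying with the
  planted DLG4/GPHN ratio.

All randomness flows from one root seed: a ``numpy.random.SeedSequence``
is spawned once per object/subject in a fixed documented order, so the same
(spec, seed) pair is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ephys import CurrentTrace, OocyteRecording
from .fdt import ImageStack
from .ish import IshImage

__all__ = [
    "IntensityModel",
    "FdtSceneSpec",
    "IshSceneSpec",
    "EphysSpec",
    "FlowSpec",
    "ExprSpec",
    "GroundTruth",
    "gen_fdt_stack",
    "gen_ish_image",
    "gen_oocyte_traces",
    "gen_flow_events",
    "gen_expression",
]


@dataclass(frozen=True)
class GroundTruth:
    """Planted objects (one row each) and per-subject summary truths."""

    objects: pd.DataFrame | None
    summary: dict


@dataclass(frozen=True)
class IntensityModel:
    """Punctum peak-intensity model: a Gaussian mode with an optional
    low-intensity mixture component (the plantable leftward shift).

    The default mode keeps the whole +-3 sigma population above the
    detection floor (puncta dimmer than ~16 counts over background are
    unresolvable) and below the 8-bit ceiling — the synthetic analogue of
    correct acquisition exposure.
    """

    mode: float = 170.0
    spread: float = 16.0
    shift_fraction: float = 0.0
    shift: float = 35.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        low = rng.random(n) < self.shift_fraction
        loc = np.where(low, self.mode - self.shift, self.mode)
        return np.clip(rng.normal(loc, self.spread), 0.0, 255.0)


@dataclass(frozen=True)
class FdtSceneSpec:
    """Scene for one two-channel 3D stack.

    Defaults emulate a 63x/1.4NA-like acquisition: 0.1 x 0.1 µm pixels,
    0.2 µm z-steps, ~2.4 µm depth, and a punctum density of ~0.6/µm³ per
    channel (the density regime of cortical postsynaptic puncta).  Punctum
    radii are chosen so their volumes fall inside the detection size
    window; blob radii fall above it.
    """

    shape: tuple[int, int, int] = (12, 160, 160)      # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (0.2, 0.1, 0.1)  # µm
    n_puncta: int = 120                                # per channel
    punctum_radius_range: tuple[float, float] = (0.40, 0.46)  # µm (2-sigma)
    exc_intensity: IntensityModel = field(default_factory=IntensityModel)
    inh_intensity: IntensityModel = field(default_factory=IntensityModel)
    n_blobs: int = 3
    blob_radius_range: tuple[float, float] = (0.8, 1.1)  # µm
    blob_intensity: float = 210.0
    background_level: float = 100.0
    noise_sd: float = 6.0
    min_separation_factor: float = 1.0  # center distance > factor * sum radii

    def __post_init__(self) -> None:
        r_lo, r_hi = self.punctum_radius_range
        if not 0 < r_lo <= r_hi:
            raise ValueError("invalid punctum radius range")
        vol = lambda r: 4.0 / 3.0 * np.pi * r ** 3  # noqa: E731
        if vol(r_lo) < 0.01 or vol(r_hi) > 1.0:
            raise ValueError("punctum radii must yield synapse-window volumes")
        if self.n_blobs and vol(self.blob_radius_range[0]) <= 1.0:
            raise ValueError("blob radii must yield volumes above the "
                             "detection size window")
        if not 0 <= self.background_level <= 255:
            raise ValueError("background level must be an 8-bit value")


@dataclass(frozen=True)
class IshSceneSpec:
    """Scene for one single-probe ISH field (label-dark)."""

    shape: tuple[int, int] = (1500, 1500)   # pixels
    pixel_size: float = 1.0                 # µm
    n_cells: int = 300
    cell_radius_range: tuple[float, float] = (2.5, 5.0)  # px
    cell_intensity: float = 70.0
    background_level: float = 200.0
    noise_sd: float = 4.0
    n_speckles: int = 40
    speckle_radius: float = 0.8             # px; area stays under 10 px
    min_gap_px: float = 8.0                 # clearance so blur cannot merge cells

    @property
    def area_um2(self) -> float:
        return float(self.shape[0] * self.shape[1] * self.pixel_size ** 2)


@dataclass(frozen=True)
class EphysSpec:
    """Per-subject voltage-clamp recording conditions.

    Amplitudes are response magnitudes in nA (inward currents are written
    negative into the traces).  Each oocyte receives every agonist; a
    shared per-oocyte expression factor scales both so the planted E/I
    ratio holds exactly per oocyte.
    """

    gaba_amplitude: float = 200.0     # nA
    ei_ratio: float = 0.5             # kainate = ei_ratio * GABA
    n_oocytes: int = 3
    n_applications: int = 2           # repeats per agonist per oocyte
    oocyte_cv: float = 0.10           # between-oocyte expression scatter
    tau_act: float = 1.0              # s
    tau_deact: float = 2.0            # s
    sample_rate: float = 50.0         # Hz
    baseline_s: float = 5.0
    application_s: float = 10.0
    tail_s: float = 15.0
    noise_sd: float = 2.0             # nA
    drift: float = 0.0                # nA/s
    holding_current: float = -20.0    # nA

    def __post_init__(self) -> None:
        if self.gaba_amplitude <= 0 or self.ei_ratio <= 0:
            raise ValueError("amplitudes must be positive")
        if self.tau_act <= 0 or self.tau_deact <= 0:
            raise ValueError("time constants must be positive")
        if self.n_oocytes < 3:
            raise ValueError("at least 3 oocytes per subject (triplicate rule)")


@dataclass(frozen=True)
class FlowSpec:
    """Particle-diameter mixture for one subject's flow-cytometry run.

    ``components`` are (weight, mean µm, sd µm) triples over (0.5, 4) µm.
    ``total_particles`` is the planted absolute in-gate particle count the
    acquisition would report (the event table itself holds ``n_events``
    sampled events).
    """

    n_events: int = 8000
    components: tuple[tuple[float, float, float], ...] = (
        (0.45, 1.5, 0.25), (0.10, 2.0, 0.06), (0.45, 2.5, 0.25))
    total_particles: float = 2.5e6

    def __post_init__(self) -> None:
        w = sum(c[0] for c in self.components)
        if self.components and abs(w - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


@dataclass(frozen=True)
class ExprSpec:
    """FPKM matrix shape and planted group effects.

    ``multipliers`` maps group -> gene -> multiplicative expression change;
    the default plants the disease signature of a reduced GPHN (x0.6) with
    DLG4 untouched.  A block of "postsynapse" genes co-varies with each
    subject's realized DLG4/GPHN ratio.
    """

    n_genes: int = 2000
    n_per_group: dict = field(default_factory=lambda: {"CTRL": 8, "AD": 12})
    subject_sd: float = 0.25          # lognormal sigma (natural log)
    dlg4_base: float = 30.0
    gphn_base: float = 30.0
    multipliers: dict = field(default_factory=lambda: {"AD": {"GPHN": 0.6}})
    n_postsynapse: int = 50
    coupling: float = 0.4             # loading of the block on the EI z-score


# ---------------------------------------------------------------------------
# placement helper

def _place_spheres(rng: np.random.Generator, extent: np.ndarray,
                   radii: np.ndarray, existing_pos: np.ndarray | None,
                   existing_rad: np.ndarray | None,
                   sep_factor: float, max_tries_per_obj: int = 400
                   ) -> np.ndarray:
    """Random sequential placement of non-overlapping spheres.

    Overlap rule: center distance must exceed ``sep_factor`` times the sum
    of radii.  Raises when an object cannot be placed within the bounded
    retry budget.
    """
    placed = [] if existing_pos is None else list(existing_pos)
    placed_r = [] if existing_rad is None else list(existing_rad)
    out = []
    for r in radii:
        lo, hi = r, extent - r
        if np.any(hi <= lo):
            raise ValueError("object radius exceeds the field")
        for attempt in range(max_tries_per_obj):
            pos = rng.uniform(lo, hi)
            if placed:
                d = np.linalg.norm(np.asarray(placed) - pos, axis=1)
                min_d = sep_factor * (np.asarray(placed_r) + r)
                if np.any(d <= min_d):
                    continue
            placed.append(pos)
            placed_r.append(r)
            out.append(pos)
            break
        else:
            raise RuntimeError(
                "could not place all objects without overlap; reduce density")
    return np.asarray(out).reshape(len(out), 3)


def _add_gaussian_sphere(field_arr: np.ndarray, pos: np.ndarray, radius: float,
                         amplitude: float, voxel_size: np.ndarray,
                         sigma_fraction: float = 0.5) -> None:
    """Add a truncated isotropic Gaussian (sigma = radius * fraction,
    truncated at the radius) into a 3D array, in place."""
    sigma = radius * sigma_fraction
    lo_v = np.maximum(np.floor((pos - radius) / voxel_size).astype(int), 0)
    hi_v = np.minimum(np.ceil((pos + radius) / voxel_size).astype(int) + 1,
                      np.asarray(field_arr.shape))
    grids = np.meshgrid(*[(np.arange(lo_v[a], hi_v[a]) + 0.5) * voxel_size[a]
                          for a in range(3)], indexing="ij")
    d2 = sum((g - p) ** 2 for g, p in zip(grids, pos))
    prof = amplitude * np.exp(-d2 / (2.0 * sigma ** 2))
    prof[d2 > radius ** 2] = 0.0
    field_arr[lo_v[0]:hi_v[0], lo_v[1]:hi_v[1], lo_v[2]:hi_v[2]] += prof


# ---------------------------------------------------------------------------
# generators

def gen_fdt_stack(spec: FdtSceneSpec, seed: int | np.random.SeedSequence
                  ) -> tuple[ImageStack, GroundTruth]:
    """Generate one two-channel stack plus the planted object table.

    Puncta are isotropic 3D Gaussians truncated at 2 sigma (the nominal
    radius), placed with center distance greater than the sum of radii;
    lipofuscin-like blobs appear co-located in both channels and are larger
    than the synapse size window.  Voxel = background + objects + Gaussian
    noise, clipped to 8 bits.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    vox = np.asarray(spec.voxel_size, dtype=float)
    extent = np.asarray(spec.shape, dtype=float) * vox

    radii = {}
    models = {"PSD95": spec.exc_intensity, "GPHN": spec.inh_intensity}
    blob_r = rng.uniform(*spec.blob_radius_range, size=spec.n_blobs)
    blob_pos = _place_spheres(rng, extent, blob_r, None, None,
                              spec.min_separation_factor)
    all_pos, all_r = list(blob_pos), list(blob_r)
    positions, peaks = {}, {}
    for ch in models:
        radii[ch] = rng.uniform(*spec.punctum_radius_range, size=spec.n_puncta)
        pos = _place_spheres(rng, extent, radii[ch],
                             np.asarray(all_pos).reshape(-1, 3) if all_pos else None,
                             np.asarray(all_r) if all_r else None,
                             spec.min_separation_factor)
        all_pos.extend(pos)
        all_r.extend(radii[ch])
        positions[ch] = pos
        peaks[ch] = models[ch].sample(rng, spec.n_puncta)

    data = np.empty((2, *spec.shape), dtype=np.uint8)
    rows = []
    for ci, ch in enumerate(models):
        fld = np.full(spec.shape, spec.background_level, dtype=float)
        for pos, r, peak in zip(positions[ch], radii[ch], peaks[ch]):
            amp = max(peak - spec.background_level, 1.0)
            _add_gaussian_sphere(fld, pos, r, amp, vox)
            rows.append({"kind": "punctum", "channel": ch,
                         "z_um": pos[0], "y_um": pos[1], "x_um": pos[2],
                         "radius_um": r, "peak_intensity": peak})
        for pos, r in zip(blob_pos, blob_r):
            amp = max(spec.blob_intensity - spec.background_level, 1.0)
            _add_gaussian_sphere(fld, pos, r, amp, vox, sigma_fraction=0.5)
            if ci == 0:
                rows.append({"kind": "lipofuscin", "channel": "both",
                             "z_um": pos[0], "y_um": pos[1], "x_um": pos[2],
                             "radius_um": r,
                             "peak_intensity": spec.blob_intensity})
        if spec.noise_sd > 0:
            fld = fld + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        data[ci] = np.clip(np.rint(fld), 0, 255).astype(np.uint8)

    objects = pd.DataFrame(rows, columns=["kind", "channel", "z_um", "y_um",
                                          "x_um", "radius_um",
                                          "peak_intensity"])
    summary = {
        "n_puncta_per_channel": spec.n_puncta,
        "n_blobs": spec.n_blobs,
        # peak height of a binned unimodal distribution scales as 1/spread,
        # so the planted anatomical peak ratio is the spread ratio
        "true_peak_ratio": spec.inh_intensity.spread / spec.exc_intensity.spread,
    }
    stack = ImageStack(data=data, voxel_size=spec.voxel_size,
                       channels=tuple(models))
    return stack, GroundTruth(objects=objects, summary=summary)


def gen_ish_image(spec: IshSceneSpec, seed: int | np.random.SeedSequence,
                  probe: str = "vGluT1") -> tuple[IshImage, GroundTruth]:
    """Generate one label-dark ISH field of non-overlapping cell disks.

    Speckle artifacts (area under the counting size criterion) and Gaussian
    noise are added on top; the planted count and per-cell rasterized areas
    are recorded in the truth table.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    h, w = spec.shape
    img = np.full((h, w), spec.background_level, dtype=float)

    r_cells = rng.uniform(*spec.cell_radius_range, size=spec.n_cells)
    extent = np.asarray([h, w], dtype=float)
    centers = []
    for r in r_cells:
        lo, hi = r + 1, extent - r - 1
        if np.any(hi <= lo):
            raise ValueError("cell radius exceeds the field")
        for attempt in range(400):
            pos = rng.uniform(lo, hi)
            if centers:
                d = np.linalg.norm(np.asarray([c[:2] for c in centers]) - pos,
                                   axis=1)
                if np.any(d <= np.asarray([c[2] for c in centers]) + r
                          + spec.min_gap_px):
                    continue
            centers.append((pos[0], pos[1], r))
            break
        else:
            raise RuntimeError("cell density too high to place without overlap")

    yy, xx = np.mgrid[0:h, 0:w]
    rows = []
    for (cy, cx, r) in centers:
        y0, y1 = max(0, int(cy - r - 2)), min(h, int(cy + r + 3))
        x0, x1 = max(0, int(cx - r - 2)), min(w, int(cx + r + 3))
        sub_y, sub_x = yy[y0:y1, x0:x1], xx[y0:y1, x0:x1]
        mask = (sub_y - cy) ** 2 + (sub_x - cx) ** 2 <= r ** 2
        img[y0:y1, x0:x1][mask] = spec.cell_intensity
        rows.append({"y_px": cy, "x_px": cx, "radius_px": r,
                     "area_px": int(mask.sum())})

    for _ in range(spec.n_speckles):
        cy, cx = rng.uniform(1, h - 1), rng.uniform(1, w - 1)
        y0, y1 = max(0, int(cy - 2)), min(h, int(cy + 3))
        x0, x1 = max(0, int(cx - 2)), min(w, int(cx + 3))
        sub_y, sub_x = yy[y0:y1, x0:x1], xx[y0:y1, x0:x1]
        mask = (sub_y - cy) ** 2 + (sub_x - cx) ** 2 <= spec.speckle_radius ** 2
        img[y0:y1, x0:x1][mask] = spec.cell_intensity

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    objects = pd.DataFrame(rows, columns=["y_px", "x_px", "radius_px",
                                          "area_px"])
    density = spec.n_cells / (spec.area_um2 / 10_000.0)
    truth = GroundTruth(objects=objects,
                        summary={"n_cells": spec.n_cells,
                                 "density_per_10k_um2": density,
                                 "area_um2": spec.area_um2})
    return IshImage(data=img, pixel_size=spec.pixel_size, probe=probe), truth


def gen_oocyte_traces(spec: EphysSpec, seed: int | np.random.SeedSequence,
                      subject_id: str = "S0"
                      ) -> tuple[list[OocyteRecording], GroundTruth]:
    """Generate voltage-clamp recordings for one subject.

    Each oocyte gets ``n_applications`` GABA and kainate traces; both
    agonist amplitudes share the oocyte's expression factor, so the planted
    kainate/GABA ratio holds exactly per oocyte.  Traces are holding
    current + linear drift + mono-exponential response + Gaussian noise;
    responses are inward (negative).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n_samples = int(round((spec.baseline_s + spec.application_s + spec.tail_s)
                          * spec.sample_rate))
    t = np.arange(n_samples) / spec.sample_rate
    t_on = spec.baseline_s
    t_off = spec.baseline_s + spec.application_s

    shape = np.zeros_like(t)
    during = (t >= t_on) & (t <= t_off)
    after = t > t_off
    shape[during] = 1.0 - np.exp(-(t[during] - t_on) / spec.tau_act)
    level_off = 1.0 - np.exp(-spec.application_s / spec.tau_act)
    shape[after] = level_off * np.exp(-(t[after] - t_off) / spec.tau_deact)

    recordings = []
    oocyte_truth = []
    for o in range(spec.n_oocytes):
        factor = max(float(rng.normal(1.0, spec.oocyte_cv)), 0.1)
        amps = {"GABA": spec.gaba_amplitude * factor,
                "kainate": spec.gaba_amplitude * spec.ei_ratio * factor}
        traces = []
        for agonist, amp in amps.items():
            for _ in range(spec.n_applications):
                cur = (spec.holding_current + spec.drift * t - amp * shape)
                if spec.noise_sd > 0:
                    cur = cur + rng.normal(0.0, spec.noise_sd, size=t.shape)
                traces.append(CurrentTrace(time=t, current=cur,
                                           window=(t_on, t_off),
                                           agonist=agonist))
        recordings.append(OocyteRecording(oocyte_id=f"{subject_id}_oo{o}",
                                          subject_id=subject_id,
                                          traces=traces))
        oocyte_truth.append({"oocyte_id": f"{subject_id}_oo{o}",
                             "gaba_amplitude": amps["GABA"],
                             "kainate_amplitude": amps["kainate"]})
    truth = GroundTruth(objects=pd.DataFrame(oocyte_truth),
                        summary={"true_ei_ratio": spec.ei_ratio,
                                 "gaba_amplitude": spec.gaba_amplitude})
    return recordings, truth


def gen_flow_events(spec: FlowSpec, seed: int | np.random.SeedSequence,
                    subject_id: str = "S0"
                    ) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw particle diameters from the planted mixture over (0.5, 4) µm."""
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    if spec.n_events == 0 or not spec.components:
        events = pd.DataFrame({"event_id": pd.Series(dtype=int),
                               "subject_id": pd.Series(dtype=str),
                               "diameter": pd.Series(dtype=float)})
        return events, GroundTruth(objects=None,
                                   summary={"weights": (),
                                            "total_particles": spec.total_particles})
    weights = np.array([c[0] for c in spec.components])
    comp = rng.choice(len(weights), size=spec.n_events, p=weights)
    means = np.array([c[1] for c in spec.components])[comp]
    sds = np.array([c[2] for c in spec.components])[comp]
    d = rng.normal(means, sds)
    d = np.clip(d, 0.5 + 1e-6, 4.0 - 1e-6)
    events = pd.DataFrame({"event_id": np.arange(spec.n_events),
                           "subject_id": subject_id, "diameter": d})
    truth = GroundTruth(objects=None,
                        summary={"weights": tuple(weights.tolist()),
                                 "total_particles": spec.total_particles})
    return events, truth


def gen_expression(spec: ExprSpec, seed: int | np.random.SeedSequence
                   ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate an FPKM matrix (genes x subjects), metadata, and truth.

    Gene baselines are log-normal; subject values scatter log-normally
    (sigma ``subject_sd``) around baseline x group multiplier.  The
    postsynapse block co-varies with each subject's realized log DLG4/GPHN
    ratio (standardized), emulating coordinated postsynaptic expression.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    groups = [g for g, n in spec.n_per_group.items() for _ in range(n)]
    subjects = [f"{g}{i:02d}" for g in spec.n_per_group
                for i in range(spec.n_per_group[g])]
    n_subj = len(subjects)

    n_psy = min(spec.n_postsynapse, max(spec.n_genes - 2, 0))
    n_other = spec.n_genes - 2 - n_psy
    genes = (["DLG4", "GPHN"]
             + [f"PSY{i:04d}" for i in range(n_psy)]
             + [f"GENE{i:04d}" for i in range(n_other)])

    base = np.empty(len(genes))
    base[0], base[1] = spec.dlg4_base, spec.gphn_base
    base[2:] = np.exp(rng.normal(np.log(20.0), 1.2, size=len(genes) - 2))

    mult = np.ones((len(genes), n_subj))
    for j, g in enumerate(groups):
        for gene, m in spec.multipliers.get(g, {}).items():
            if gene in genes:
                mult[genes.index(gene), j] = m

    noise = rng.normal(0.0, spec.subject_sd, size=(len(genes), n_subj))
    values = base[:, None] * mult * np.exp(noise)

    log_ratio = np.log(values[0] / values[1])
    z = (log_ratio - log_ratio.mean()) / max(log_ratio.std(), 1e-12)
    if n_psy:
        values[2:2 + n_psy] *= np.exp(spec.coupling * z)[None, :]

    matrix = pd.DataFrame(values, index=genes, columns=subjects)
    meta = pd.DataFrame({
        "diagnosis": groups,
        "age": rng.integers(78, 101, size=n_subj),
        "sex": rng.choice(["M", "F"], size=n_subj),
        "pmi_h": np.round(rng.uniform(3.0, 20.0, size=n_subj), 1),
    }, index=subjects)
    true_ratio = {
        g: (spec.dlg4_base * spec.multipliers.get(g, {}).get("DLG4", 1.0))
        / (spec.gphn_base * spec.multipliers.get(g, {}).get("GPHN", 1.0))
        for g in spec.n_per_group
    }
    truth = GroundTruth(objects=None,
                        summary={"true_ratio_per_group": true_ratio,
                                 "postsynapse_genes": genes[2:2 + n_psy]})
    return matrix, meta, truth
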