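"""Synthetic dorsal olfactory-bulb GCaMP movies and NQO1 coronal section stacks
with planted ground truth.

The forward model emulates the imaging arm of the study: awake-anesthetized
mice carrying a genetically encoded calcium indicator in their olfactory
sensory neurons are imaged over the dorsal bulb at 2 frames/s while odors are
delivered in 10-s pulses, at least five trials per odor and at least 60 s
between stimuli. Glomeruli are modelled as 100-um circles; a responsive
glomerulus multiplies its baseline fluorescence by ``1 + dF/F(t)`` where the
response waveform rises linearly to the planted amplitude over 1 s, holds for
the stimulus, and decays exponentially (tau = 4 s by default). All pixels share
a single exponential photobleach factor; Gaussian read noise is added last.

    pixel(t) = baseline * exp(-bleach_rate * t) * (1 + dF/F(t)) + N(0, noise_sd)

Coordinates are 0-based ``(t, row, col)``; rows run anterior -> posterior and
columns medial -> lateral in the dorsal view, 5 um/pixel by default so the
default 512 x 512 field covers ~2.5 mm.

The NQO1 section generator produces serial coronal images (anterior ->
posterior) in the same (x = mediolateral, y = anteroposterior) frame as the
movies: each section shows the glomerular layer in a depth x mediolateral
plane, with a connective-tissue band below the lamina propria serving as the
background region for the 2-SD positivity rule. DI glomeruli are drawn at
``bg_mean + di_contrast_sd_units * bg_sd``; DII glomeruli follow the background
distribution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import tifffile

from .exceptions import LayoutError, ValidationError

FRAME_RATE: float = 2.0  # frames / s
PIXEL_SIZE_UM: float = 5.0
GLOM_DIAMETER_UM: float = 100.0
STIM_DURATION_S: float = 10.0
MIN_ISI_S: float = 60.0  # minimum offset -> next onset gap
RISE_S: float = 1.0
DECAY_TAU_S: float = 4.0
DEFAULT_TRIALS: int = 5
DEFAULT_FIELD: tuple[int, int] = (512, 512)
DEFAULT_Z_SPACING_UM: float = 40.0


class Odor(str, Enum):
    TNT_MIX = "TNT_MIX"  # equal mixture of the five orthonasal test odorants
    IVO = "IVO"  # intravenous prosultiamine


class DomainLabel(str, Enum):
    DI = "DI"  # class I OSN projection domain (NQO1-positive)
    DII = "DII"  # class II OSN projection domain (NQO1-negative)


@dataclass(frozen=True)
class StimulusEvent:
    odor: Odor
    onset_frame: int
    duration_frames: int
    trial_index: int

    @property
    def offset_frame(self) -> int:
        return self.onset_frame + self.duration_frames


@dataclass(frozen=True)
class GlomerulusGT:
    """Planted glomerulus: position, baseline, per-odor response amplitudes, domain."""

    id: str
    center_um: tuple[float, float]  # (x = mediolateral, y = anteroposterior)
    baseline: float = 100.0
    amplitudes: dict = field(default_factory=dict)  # Odor -> dF/F amplitude (> 0)
    domain: DomainLabel = DomainLabel.DII
    diameter_um: float = GLOM_DIAMETER_UM

    @property
    def responsive_odors(self) -> frozenset:
        return frozenset(o for o, a in self.amplitudes.items() if a > 0)


@dataclass
class MovieStack:
    frames: np.ndarray  # (T, H, W), float32, nonnegative
    frame_rate: float
    pixel_size_um: float
    stimuli: list  # of StimulusEvent

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass
class SectionStack:
    """Serial coronal sections, anterior -> posterior.

    ``images[s]`` is a (depth x mediolateral) intensity image; ``label_masks[s]``
    assigns each pixel a 1-based glomerulus index (0 = none); ``background_masks``
    marks the sub-lamina-propria connective tissue used as the staining-intensity
    reference.
    """

    images: np.ndarray  # (S, D, W)
    label_masks: np.ndarray  # (S, D, W) int32, 0 = no glomerulus
    background_masks: np.ndarray  # (S, D, W) bool
    glomeruli: list  # of GlomerulusGT, index i <-> mask value i + 1
    z_spacing_um: float
    pixel_size_um: float


# ---------------------------------------------------------------------------
# Geometry helpers (shared with the analysis pipeline)
# ---------------------------------------------------------------------------

def circle_mask(shape: tuple[int, int], center_px: tuple[float, float],
                radius_px: float) -> np.ndarray:
    """Boolean mask of pixels whose centers lie within ``radius_px`` of the center.

    ``center_px`` is (row, col); membership is center-in-circle (distance <=
    radius), matching the ROI convention of the analysis pipeline.
    """
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center_px[0]) ** 2 + (cc - center_px[1]) ** 2 <= radius_px**2


def um_to_px(value_um: float, pixel_size_um: float) -> float:
    return value_um / pixel_size_um


# ---------------------------------------------------------------------------
# Stimulus schedule
# ---------------------------------------------------------------------------

def make_schedule(
    n_trials: int = DEFAULT_TRIALS,
    odors: Sequence[Odor] = (Odor.TNT_MIX, Odor.IVO),
    pre_s: float = 20.0,
    stim_s: float = STIM_DURATION_S,
    isi_s: float = MIN_ISI_S,
    post_s: float = 20.0,
    frame_rate: float = FRAME_RATE,
) -> tuple[list, int]:
    """Block design: all trials of each odor in sequence, >= 60 s between stimuli.

    Returns the stimulus list and the total frame count (covering the last
    offset plus the post window).
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    if isi_s < MIN_ISI_S:
        raise ValidationError(f"inter-stimulus interval must be >= {MIN_ISI_S} s")
    stim_frames = int(round(stim_s * frame_rate))
    isi_frames = int(round(isi_s * frame_rate))
    onset = int(round(pre_s * frame_rate))
    events: list[StimulusEvent] = []
    for odor in odors:
        for trial in range(n_trials):
            events.append(StimulusEvent(Odor(odor), onset, stim_frames, trial))
            onset += stim_frames + isi_frames
    total = events[-1].offset_frame + int(round(post_s * frame_rate))
    return events, total


def response_waveform(
    amplitude: float,
    n_frames: int,
    duration_frames: int,
    frame_rate: float = FRAME_RATE,
    rise_s: float = RISE_S,
    tau_s: float = DECAY_TAU_S,
) -> np.ndarray:
    """dF/F time course from stimulus onset: linear 1-s rise, plateau for the
    stimulus, exponential decay after offset."""
    t = np.arange(n_frames) / frame_rate
    stim_s = duration_frames / frame_rate
    w = np.where(t < rise_s, t / rise_s, 1.0)
    decay = t >= stim_s
    w = np.where(decay, np.exp(-(t - stim_s) / tau_s), w)
    return amplitude * w


# ---------------------------------------------------------------------------
# Movie generation
# ---------------------------------------------------------------------------

def _validate_layout(layout: Sequence[GlomerulusGT], field_shape: tuple[int, int],
                     pixel_size_um: float, overlap_tol_um: float) -> None:
    h, w = field_shape
    for g in layout:
        r = g.diameter_um / 2.0
        x, y = g.center_um
        if not (r <= x <= w * pixel_size_um - r and r <= y <= h * pixel_size_um - r):
            raise LayoutError(f"glomerulus {g.id} does not fit inside the field")
    for i, gi in enumerate(layout):
        for gj in layout[i + 1:]:
            dist = math.hypot(
                gi.center_um[0] - gj.center_um[0],
                gi.center_um[1] - gj.center_um[1],
            )
            min_dist = (gi.diameter_um + gj.diameter_um) / 2.0 - overlap_tol_um
            if dist < min_dist:
                raise LayoutError(
                    f"glomeruli {gi.id} and {gj.id} overlap (distance {dist:.1f} um)"
                )


def generate_movie(
    layout: Sequence[GlomerulusGT],
    noise_sd: float = 0.0,
    bleach_rate: float = 0.0,
    n_trials: int = DEFAULT_TRIALS,
    seed: int = 0,
    field_shape: tuple[int, int] = DEFAULT_FIELD,
    pixel_size_um: float = PIXEL_SIZE_UM,
    frame_rate: float = FRAME_RATE,
    bg_level: float = 20.0,
    tau_s: float = DECAY_TAU_S,
    odors: Sequence[Odor] = (Odor.TNT_MIX, Odor.IVO),
    overlap_tol_um: float = 0.0,
    schedule: Optional[tuple[list, int]] = None,
) -> MovieStack:
    """Render a synthetic dorsal-bulb movie from a planted glomerulus layout.

    ``bleach_rate`` is the shared exponential decay constant in 1/s; ``noise_sd``
    the additive Gaussian SD in raw intensity units. Deterministic under ``seed``.
    """
    _validate_layout(layout, field_shape, pixel_size_um, overlap_tol_um)
    if schedule is None:
        schedule = make_schedule(n_trials=n_trials, odors=odors,
                                 frame_rate=frame_rate)
    stimuli, n_frames = schedule
    h, w = field_shape

    base = np.full((h, w), bg_level, dtype=np.float64)
    masks = []
    for g in layout:
        m = circle_mask(
            (h, w),
            (um_to_px(g.center_um[1], pixel_size_um),
             um_to_px(g.center_um[0], pixel_size_um)),
            um_to_px(g.diameter_um / 2.0, pixel_size_um),
        )
        base[m] = g.baseline
        masks.append(m)

    # noiseless movies render in float64 so the planted signal is exact;
    # noisy movies use float32 to halve memory (noise dwarfs rounding)
    dtype = np.float64 if noise_sd == 0 else np.float32
    t_s = np.arange(n_frames) / frame_rate
    bleach = np.exp(-bleach_rate * t_s)
    frames = (bleach[:, None, None] * base[None, :, :]).astype(dtype)

    # response window length: stimulus plus 8 decay constants (negligible tail)
    tail = int(math.ceil(8.0 * tau_s * frame_rate))
    for g, m in zip(layout, masks):
        for ev in stimuli:
            amp = float(g.amplitudes.get(ev.odor, 0.0))
            if amp <= 0:
                continue
            n_w = min(ev.duration_frames + tail, n_frames - ev.onset_frame)
            wave = response_waveform(
                amp, n_w, ev.duration_frames, frame_rate=frame_rate, tau_s=tau_s
            )
            seg = frames[ev.onset_frame: ev.onset_frame + n_w]
            seg[:, m] *= (1.0 + wave[:, None]).astype(dtype)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames += rng.standard_normal(frames.shape, dtype=np.float32) * np.float32(
            noise_sd
        )
        np.maximum(frames, 0.0, out=frames)  # fluorescence is nonnegative

    return MovieStack(frames=frames, frame_rate=frame_rate,
                      pixel_size_um=pixel_size_um, stimuli=list(stimuli))


# ---------------------------------------------------------------------------
# NQO1 coronal sections
# ---------------------------------------------------------------------------

def generate_nqo1_sections(
    geometry: Sequence[GlomerulusGT],
    bg_mean: float = 100.0,
    bg_sd: float = 10.0,
    di_contrast_sd_units: float = 5.0,
    seed: int = 0,
    z_spacing_um: float = DEFAULT_Z_SPACING_UM,
    pixel_size_um: float = PIXEL_SIZE_UM,
    section_depth_px: int = 60,
    width_px: Optional[int] = None,
    n_sections: Optional[int] = None,
    glom_layer_depth_um: float = 100.0,
    section_noise_sd_units: float = 0.0,
    pixel_noise_sd: float = 0.0,
    tissue_level: Optional[float] = None,
) -> SectionStack:
    """Render serial coronal NQO1 sections for a glomerulus geometry.

    Each glomerulus is a sphere centered at depth ``glom_layer_depth_um`` below
    the dorsal surface; a section at anteroposterior position z shows the circle
    of radius sqrt(r^2 - dz^2). Per glomerulus and section, the staining
    intensity is drawn once: DI at ``bg_mean + di_contrast_sd_units * bg_sd``
    (plus optional section-to-section noise in bg-SD units), DII from the
    background distribution itself. The bottom quarter of every section is the
    sub-lamina-propria connective-tissue band whose pixels ~ N(bg_mean, bg_sd).
    """
    if di_contrast_sd_units < 0:
        raise ValidationError("di_contrast_sd_units must be >= 0")
    rng = np.random.default_rng(seed)
    if width_px is None:
        extent = max((g.center_um[0] + g.diameter_um for g in geometry), default=500.0)
        width_px = int(math.ceil(extent / pixel_size_um))
    if n_sections is None:
        extent = max((g.center_um[1] + g.diameter_um for g in geometry), default=200.0)
        n_sections = int(math.ceil(extent / z_spacing_um))
    if n_sections < 1 or width_px < 1:
        raise ValidationError("section stack must have positive extent")
    if tissue_level is None:
        tissue_level = 0.5 * bg_mean

    D, W, S = section_depth_px, width_px, n_sections
    bg_rows = slice(3 * D // 4, D)  # connective tissue under the lamina propria

    images = np.full((S, D, W), tissue_level, dtype=np.float64)
    labels = np.zeros((S, D, W), dtype=np.int32)
    bg_masks = np.zeros((S, D, W), dtype=bool)
    bg_masks[:, bg_rows, :] = True
    images[bg_masks] = rng.normal(bg_mean, bg_sd, size=int(bg_masks.sum()))

    layer_row = glom_layer_depth_um / pixel_size_um
    for gi, g in enumerate(geometry):
        r_um = g.diameter_um / 2.0
        x_px = g.center_um[0] / pixel_size_um
        y_um = g.center_um[1]
        offset = bg_mean + di_contrast_sd_units * bg_sd if g.domain is DomainLabel.DI else bg_mean
        for s in range(S):
            dz = s * z_spacing_um - y_um
            if abs(dz) >= r_um:
                continue
            r_sec = math.sqrt(r_um**2 - dz**2) / pixel_size_um
            m = circle_mask((D, W), (layer_row, x_px), r_sec)
            m &= ~bg_masks[s]
            if not m.any():
                continue
            intensity = offset
            if section_noise_sd_units > 0:
                intensity += rng.normal(0.0, section_noise_sd_units * bg_sd)
            images[s][m] = intensity
            if pixel_noise_sd > 0:
                images[s][m] += rng.normal(0.0, pixel_noise_sd, size=int(m.sum()))
            labels[s][m] = gi + 1

    return SectionStack(
        images=images, label_masks=labels, background_masks=bg_masks,
        glomeruli=list(geometry), z_spacing_um=z_spacing_um,
        pixel_size_um=pixel_size_um,
    )


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF + JSON sidecar
# ---------------------------------------------------------------------------

def _stimuli_to_json(stimuli: Sequence[StimulusEvent]) -> list:
    return [
        {"odor": e.odor.value, "onset_frame": e.onset_frame,
         "duration_frames": e.duration_frames, "trial_index": e.trial_index}
        for e in stimuli
    ]


def _stimuli_from_json(doc: list) -> list:
    return [
        StimulusEvent(Odor(e["odor"]), int(e["onset_frame"]),
                      int(e["duration_frames"]), int(e["trial_index"]))
        for e in doc
    ]


def _glomeruli_to_json(gloms: Sequence[GlomerulusGT]) -> list:
    out = []
    for g in gloms:
        d = asdict(g)
        d["center_um"] = list(g.center_um)
        d["amplitudes"] = {Odor(o).value: float(a) for o, a in g.amplitudes.items()}
        d["domain"] = g.domain.value
        out.append(d)
    return out


def _glomeruli_from_json(doc: list) -> list:
    return [
        GlomerulusGT(
            id=d["id"], center_um=tuple(d["center_um"]), baseline=d["baseline"],
            amplitudes={Odor(o): float(a) for o, a in d["amplitudes"].items()},
            domain=DomainLabel(d["domain"]), diameter_um=d["diameter_um"],
        )
        for d in doc
    ]


def write_movie(movie: MovieStack, tiff_path: Union[str, Path],
                layout: Optional[Sequence[GlomerulusGT]] = None) -> None:
    """Multi-page TIFF plus a JSON sidecar (schedule, scale, ground truth)."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, movie.frames)
    sidecar = {
        "frame_rate": movie.frame_rate,
        "pixel_size_um": movie.pixel_size_um,
        "stimuli": _stimuli_to_json(movie.stimuli),
    }
    if layout is not None:
        sidecar["ground_truth"] = _glomeruli_to_json(layout)
    tiff_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_movie(tiff_path: Union[str, Path]) -> tuple[MovieStack, Optional[list]]:
    """Read a movie TIFF and its JSON sidecar; returns (movie, ground truth or None)."""
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path)
    doc = json.loads(tiff_path.with_suffix(".json").read_text())
    movie = MovieStack(
        frames=np.asarray(frames, dtype=np.float32),
        frame_rate=float(doc["frame_rate"]),
        pixel_size_um=float(doc["pixel_size_um"]),
        stimuli=_stimuli_from_json(doc["stimuli"]),
    )
    gt = _glomeruli_from_json(doc["ground_truth"]) if "ground_truth" in doc else None
    return movie, gt


def write_sections(stack: SectionStack, tiff_path: Union[str, Path]) -> None:
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, stack.images.astype(np.float32))
    sidecar = {
        "z_spacing_um": stack.z_spacing_um,
        "pixel_size_um": stack.pixel_size_um,
        "glomeruli": _glomeruli_to_json(stack.glomeruli),
    }
    tiff_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    np.savez(tiff_path.with_suffix(".masks.npz"),
             labels=stack.label_masks, background=stack.background_masks)


def read_sections(tiff_path: Union[str, Path]) -> SectionStack:
    tiff_path = Path(tiff_path)
    images = np.asarray(tifffile.imread(tiff_path), dtype=np.float64)
    doc = json.loads(tiff_path.with_suffix(".json").read_text())
    masks = np.load(tiff_path.with_suffix(".masks.npz"))
    return SectionStack(
        images=images,
        label_masks=masks["labels"],
        background_masks=masks["background"],
        glomeruli=_glomeruli_from_json(doc["glomeruli"]),
        z_spacing_um=float(doc["z_spacing_um"]),
        pixel_size_um=float(doc["pixel_size_um"]),
    )
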