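"""Glomerular response analysis: ROI traces, dF/F0, photobleach correction and
excitatory-response calling.

Pipeline, in running order:

1. **ROI extraction** — each glomerulus is a 100-um-diameter circular ROI; the
   raw trace is the mean intensity over pixels whose centers fall within the
   circle.
2. **dF/F0** — per stimulus, F0 is the mean of the 20 frames (10 s at
   2 frames/s) immediately before odor onset and dF/F = (F - F0) / F0.
3. **Photobleach correction** — two-pass: responses are first called on
   uncorrected dF/F; ROIs nonresponsive to every odor form the reference set,
   whose mean dF/F time course is subtracted from every ROI (bleaching is
   shared across the field, so the reference trace isolates it); responses are
   then re-called on the corrected traces.
4. **Response calling** — per ROI and odor, the mean dF/F over the 10 s after
   onset is compared with the 10 s before across trials (>= 5 per odor in the
   emulated acquisition) with a one-sided paired t-test (increase only);
   responsive iff p < 0.05. The response magnitude is the peak of the
   trial-averaged dF/F in the post window. A Wilcoxon signed-rank alternative
   is available behind a flag. No multiple-testing correction is applied
   across ROIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import ValidationError
from .simulate import (
    GLOM_DIAMETER_UM,
    MovieStack,
    Odor,
    StimulusEvent,
    circle_mask,
    um_to_px,
)

PRE_FRAMES: int = 20  # 10 s at 2 frames/s
POST_FRAMES: int = 20
DEFAULT_ALPHA: float = 0.05


@dataclass(frozen=True)
class GlomerulusROI:
    """Circular region of interest over one glomerulus (dorsal-view um coords)."""

    id: str
    center_um: tuple[float, float]  # (x = mediolateral, y = anteroposterior)
    diameter_um: float = GLOM_DIAMETER_UM


@dataclass
class TraceSet:
    """Per-ROI traces and per-stimulus dF/F segments.

    ``segments[odor]`` has shape (n_rois, n_trials, PRE + POST) and is aligned
    so that index PRE is the stimulus-onset frame; ``f0[odor]`` has shape
    (n_rois, n_trials).
    """

    roi_ids: tuple[str, ...]
    raw: np.ndarray  # (n_rois, T)
    frame_rate: float
    segments: dict = field(default_factory=dict)  # Odor -> (R, trials, PRE+POST)
    f0: dict = field(default_factory=dict)  # Odor -> (R, trials)
    corrected: bool = False
    reference_rois: tuple[str, ...] = ()


@dataclass(frozen=True)
class ResponseCall:
    roi_id: str
    odor: Odor
    pre_mean: float
    post_mean: float
    p_value: float
    responsive: bool
    magnitude: float  # peak trial-averaged dF/F in the post window


def roi_pixel_mask(roi: GlomerulusROI, shape: tuple[int, int],
                   pixel_size_um: float) -> np.ndarray:
    m = circle_mask(
        shape,
        (um_to_px(roi.center_um[1], pixel_size_um),
         um_to_px(roi.center_um[0], pixel_size_um)),
        um_to_px(roi.diameter_um / 2.0, pixel_size_um),
    )
    r_px = roi.diameter_um / 2.0 / pixel_size_um
    row = roi.center_um[1] / pixel_size_um
    col = roi.center_um[0] / pixel_size_um
    if (row - r_px < -0.5 or col - r_px < -0.5
            or row + r_px > shape[0] - 0.5 or col + r_px > shape[1] - 0.5):
        raise ValidationError(f"ROI {roi.id} extends outside the movie frame")
    if not m.any():
        raise ValidationError(f"ROI {roi.id} covers no pixels")
    return m


def extract_traces(movie: MovieStack, rois: Sequence[GlomerulusROI]) -> TraceSet:
    """Mean-intensity trace per ROI; warns when ROI circles intersect."""
    if not rois:
        raise ValidationError("at least one ROI is required")
    h, w = movie.frames.shape[1:]
    masks = [roi_pixel_mask(roi, (h, w), movie.pixel_size_um) for roi in rois]
    for i, ri in enumerate(rois):
        for rj in rois[i + 1:]:
            dist = np.hypot(ri.center_um[0] - rj.center_um[0],
                            ri.center_um[1] - rj.center_um[1])
            if dist < (ri.diameter_um + rj.diameter_um) / 2.0:
                warnings.warn(
                    f"ROIs {ri.id} and {rj.id} overlap; traces are not independent",
                    stacklevel=2,
                )
    traces = np.stack(
        [movie.frames[:, m].mean(axis=1, dtype=np.float64) for m in masks]
    )
    return TraceSet(
        roi_ids=tuple(r.id for r in rois), raw=traces, frame_rate=movie.frame_rate
    )


def compute_dff(
    trace: np.ndarray,
    stimulus: StimulusEvent,
    baseline_frames: int = PRE_FRAMES,
) -> tuple[np.ndarray, float]:
    """dF/F0 for one trace and stimulus.

    F0 is the mean of the ``baseline_frames`` immediately before onset; the
    whole trace is transformed elementwise. Returns (dff, f0).
    """
    trace = np.asarray(trace, dtype=np.float64)
    start = stimulus.onset_frame - baseline_frames
    if start < 0:
        raise ValidationError(
            f"baseline window ({baseline_frames} frames) does not fit before "
            f"onset frame {stimulus.onset_frame}"
        )
    if stimulus.onset_frame + POST_FRAMES > trace.size:
        raise ValidationError("post-stimulus window extends past the trace end")
    f0 = float(trace[start: stimulus.onset_frame].mean())
    if f0 <= 0:
        raise ValidationError(f"nonpositive baseline F0 = {f0}")
    return (trace - f0) / f0, f0


def segment_dff(traces: TraceSet, stimuli: Sequence[StimulusEvent],
                pre: int = PRE_FRAMES, post: int = POST_FRAMES) -> TraceSet:
    """Fill ``traces.segments``/``f0`` with onset-aligned dF/F windows per odor."""
    by_odor: dict = {}
    for ev in stimuli:
        by_odor.setdefault(ev.odor, []).append(ev)
    for odor, events in by_odor.items():
        events = sorted(events, key=lambda e: e.trial_index)
        segs = np.empty((traces.raw.shape[0], len(events), pre + post))
        f0s = np.empty((traces.raw.shape[0], len(events)))
        for r in range(traces.raw.shape[0]):
            for t, ev in enumerate(events):
                dff, f0 = compute_dff(traces.raw[r], ev, baseline_frames=pre)
                segs[r, t] = dff[ev.onset_frame - pre: ev.onset_frame + post]
                f0s[r, t] = f0
        traces.segments[odor] = segs
        traces.f0[odor] = f0s
    return traces


def detect_response(
    trial_dff: np.ndarray,
    roi_id: str = "",
    odor: Odor = Odor.TNT_MIX,
    alpha: float = DEFAULT_ALPHA,
    pre: int = PRE_FRAMES,
    use_wilcoxon: bool = False,
) -> ResponseCall:
    """Call an excitatory response for one ROI x odor from per-trial dF/F segments.

    ``trial_dff`` has shape (n_trials, pre + post) aligned at onset (index
    ``pre``). The per-trial pre- and post-window means are compared with a
    one-sided paired t-test for an increase (Wilcoxon signed-rank behind the
    flag). Zero across-trial variance is resolved by the sign of the common
    difference (no evidence when 0 or negative, certain response when
    positive). The magnitude is the peak trial-averaged dF/F in the post window.
    """
    trial_dff = np.asarray(trial_dff, dtype=np.float64)
    if trial_dff.ndim != 2 or trial_dff.shape[0] < 2:
        raise ValidationError("response detection needs >= 2 trials")
    pre_means = trial_dff[:, :pre].mean(axis=1)
    post_means = trial_dff[:, pre:].mean(axis=1)
    diffs = post_means - pre_means
    # across-trial variance below numerical resolution: the t statistic is
    # undefined, so resolve by the sign of the common difference
    if np.max(np.abs(diffs - diffs.mean())) < 1e-12:
        p = 0.0 if diffs.mean() > 1e-9 else 1.0
    elif use_wilcoxon:
        p = float(sps.wilcoxon(post_means, pre_means, alternative="greater").pvalue)
    else:
        p = float(sps.ttest_rel(post_means, pre_means, alternative="greater").pvalue)
    avg = trial_dff.mean(axis=0)
    return ResponseCall(
        roi_id=roi_id,
        odor=odor,
        pre_mean=float(pre_means.mean()),
        post_mean=float(post_means.mean()),
        p_value=p,
        responsive=p < alpha,
        magnitude=float(avg[pre:].max()),
    )


def _call_all(traces: TraceSet, alpha: float, use_wilcoxon: bool) -> list:
    calls = []
    for odor, segs in traces.segments.items():
        for r, roi_id in enumerate(traces.roi_ids):
            calls.append(
                detect_response(segs[r], roi_id=roi_id, odor=odor, alpha=alpha,
                                use_wilcoxon=use_wilcoxon)
            )
    return calls


def bleach_correct(
    traces: TraceSet,
    alpha: float = DEFAULT_ALPHA,
    use_wilcoxon: bool = False,
) -> tuple[TraceSet, tuple[str, ...]]:
    """Two-pass photobleach correction by reference-ROI subtraction.

    Pass 1 calls responses on the uncorrected segments; ROIs nonresponsive to
    every odor form the reference set. The mean dF/F time course over the
    reference ROIs is subtracted from every ROI, per odor and trial. If every
    ROI responds to some odor, correction is skipped with a warning.
    """
    if not traces.segments:
        raise ValidationError("segment_dff must be run before bleach correction")
    pass1 = _call_all(traces, alpha, use_wilcoxon)
    responsive_rois = {c.roi_id for c in pass1 if c.responsive}
    reference = tuple(r for r in traces.roi_ids if r not in responsive_rois)
    if not reference:
        warnings.warn(
            "every ROI responds to at least one odor: no reference available, "
            "bleach correction skipped",
            stacklevel=2,
        )
        return traces, ()
    ref_idx = [i for i, r in enumerate(traces.roi_ids) if r in reference]
    corrected = TraceSet(
        roi_ids=traces.roi_ids, raw=traces.raw, frame_rate=traces.frame_rate,
        corrected=True, reference_rois=reference,
    )
    for odor, segs in traces.segments.items():
        ref_mean = segs[ref_idx].mean(axis=0)  # (trials, pre+post)
        corrected.segments[odor] = segs - ref_mean[None]
        corrected.f0[odor] = traces.f0[odor]
    return corrected, reference


def analyze_movie(
    movie: MovieStack,
    rois: Sequence[GlomerulusROI],
    alpha: float = DEFAULT_ALPHA,
    bleach_correction: bool = True,
    use_wilcoxon: bool = False,
) -> tuple[list, TraceSet]:
    """Full pipeline: extract -> dF/F -> (optional) bleach-correct -> call responses.

    Returns the final response calls and the TraceSet they were computed from.
    """
    traces = segment_dff(extract_traces(movie, rois), movie.stimuli)
    if bleach_correction:
        traces, _ = bleach_correct(traces, alpha=alpha, use_wilcoxon=use_wilcoxon)
    return _call_all(traces, alpha, use_wilcoxon), traces


def count_responsive(calls: Sequence[ResponseCall]) -> tuple[dict, dict]:
    """Per-odor responsive counts and the magnitude samples of the responders."""
    counts: dict = {}
    magnitudes: dict = {}
    for c in calls:
        counts.setdefault(c.odor, 0)
        magnitudes.setdefault(c.odor, [])
        if c.responsive:
            counts[c.odor] += 1
            magnitudes[c.odor].append(c.magnitude)
    return counts, magnitudes


def calls_to_frame(calls: Sequence[ResponseCall]):
    """Response calls as a tidy DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "roi_id": c.roi_id, "odor": c.odor.value,
                "pre_mean_dff": c.pre_mean, "post_mean_dff": c.post_mean,
                "p_value": c.p_value, "responsive": c.responsive,
                "magnitude": c.magnitude,
            }
            for c in calls
        ]
    )


def plot_traces(traces: TraceSet, path, odor: Optional[Odor] = None) -> None:
    """QC plot: trial-averaged dF/F per ROI (one panel per odor)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    odors = [odor] if odor is not None else list(traces.segments)
    fig, axes = plt.subplots(1, max(len(odors), 1), figsize=(5 * len(odors), 4),
                             squeeze=False)
    for ax, od in zip(axes[0], odors):
        segs = traces.segments[od]
        t = (np.arange(segs.shape[2]) - PRE_FRAMES) / traces.frame_rate
        for r, roi_id in enumerate(traces.roi_ids):
            ax.plot(t, segs[r].mean(axis=0), lw=0.8, label=roi_id)
        ax.axvspan(0, POST_FRAMES / traces.frame_rate, color="0.9")
        ax.set_xlabel("time from onset (s)")
        ax.set_ylabel("dF/F0")
        ax.set_title(Odor(od).value)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
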