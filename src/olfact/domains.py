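"""NQO1-based DI/DII domain mapping: staining threshold, coronal-to-dorsal 3D
reconstruction, ROI-to-domain assignment, and the domain-distribution statistics.

The dorsal olfactory bulb splits into the DI domain (targets of class I
olfactory sensory neurons, marked by NQO1 immunoreactivity) and the DII domain
(class II targets, NQO1-negative). A glomerulus is NQO1-positive when its mean
staining intensity *exceeds* (strict) the mean background intensity of the
sub-lamina-propria connective tissue by two sample standard deviations. Serial
coronal sections labelled this way are reconstructed into a dorsal-view domain
map by taking, in every coronal column, the label of the dorsal-most labelled
voxel — the view an imaging experiment of the dorsal surface sees. Imaging
ROIs are assigned the domain of their center pixel (majority vote over the ROI
footprint behind a flag), and odor x domain responder counts feed a chi-square
test while response magnitudes are compared between domains by Mann-Whitney U.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Optional, Sequence, Union

import numpy as np

from .exceptions import ValidationError
from .responses import GlomerulusROI, ResponseCall
from .simulate import DomainLabel, Odor, SectionStack
from .stats import TestResult, chi_square_test, mann_whitney_u

UNASSIGNED = "UNASSIGNED"


class MapLabel(IntEnum):
    """Pixel labels of the dorsal-view domain map."""

    OUTSIDE = 0
    DI = 1
    DII = 2


_MAP_TO_DOMAIN = {MapLabel.DI: DomainLabel.DI, MapLabel.DII: DomainLabel.DII}
_DOMAIN_TO_MAP = {DomainLabel.DI: MapLabel.DI, DomainLabel.DII: MapLabel.DII}


@dataclass
class DomainMap:
    """Dorsal-view label image: rows = anteroposterior (one per coronal section),
    columns = mediolateral."""

    labels: np.ndarray  # (S, W) int, values from MapLabel
    ap_spacing_um: float  # anteroposterior extent per row (section spacing)
    ml_pixel_um: float  # mediolateral extent per column


def nqo1_positive(
    glomerulus_mean_intensity: float, background_pixels: Sequence[float]
) -> bool:
    """NQO1 positivity: intensity strictly exceeding background mean + 2 sample SD.

    The background is the connective tissue under the lamina propria; SD uses
    the n-1 (sample) convention. Intensity exactly at the threshold is negative
    ("exceeding" is strict).
    """
    bg = np.asarray(background_pixels, dtype=float)
    if bg.size < 2:
        raise ValidationError("need >= 2 background pixels to estimate the SD")
    threshold = bg.mean() + 2.0 * bg.std(ddof=1)
    return float(glomerulus_mean_intensity) > threshold


def label_sections(stack: SectionStack) -> list[dict]:
    """Apply the 2-SD rule per section: glomerulus id -> DI/DII for every section.

    Each section's own connective-tissue pixels are the background reference;
    a glomerulus present in the section is DI if positive, DII otherwise.
    """
    if stack.images.shape[0] == 0:
        raise ValidationError("empty section stack")
    if stack.images.shape != stack.label_masks.shape or stack.images.shape != stack.background_masks.shape:
        raise ValidationError("section images and masks have inconsistent shapes")
    out: list[dict] = []
    for s in range(stack.images.shape[0]):
        img = stack.images[s]
        bg = img[stack.background_masks[s]]
        labels: dict[int, DomainLabel] = {}
        for gid in np.unique(stack.label_masks[s]):
            if gid == 0:
                continue
            mean_int = float(img[stack.label_masks[s] == gid].mean())
            labels[int(gid)] = (
                DomainLabel.DI if nqo1_positive(mean_int, bg) else DomainLabel.DII
            )
        out.append(labels)
    return out


def reconstruct_dorsal_map(
    stack: SectionStack, section_labels: Optional[list[dict]] = None
) -> DomainMap:
    """Project coronal domain labels onto the dorsal view.

    For every dorsal-view pixel (section x mediolateral column), the label is
    that of the dorsal-most (smallest-depth) labelled voxel in the coronal
    column; OUTSIDE where the column holds no glomerulus. ``section_labels``
    defaults to :func:`label_sections` on the stack.
    """
    if stack.images.shape[0] == 0:
        raise ValidationError("empty section stack")
    if section_labels is None:
        section_labels = label_sections(stack)
    if len(section_labels) != stack.images.shape[0]:
        raise ValidationError("one label dict per section is required")
    S, D, W = stack.label_masks.shape
    out = np.zeros((S, W), dtype=np.int8)
    for s in range(S):
        masks = stack.label_masks[s]
        occupied = masks > 0
        has_any = occupied.any(axis=0)
        if not has_any.any():
            continue
        # dorsal-most labelled voxel = first occupied row from the top
        first_row = np.argmax(occupied, axis=0)
        for x in np.nonzero(has_any)[0]:
            gid = int(masks[first_row[x], x])
            domain = section_labels[s].get(gid)
            if domain is not None:
                out[s, x] = int(_DOMAIN_TO_MAP[domain])
    return DomainMap(
        labels=out, ap_spacing_um=stack.z_spacing_um, ml_pixel_um=stack.pixel_size_um
    )


def assign_domains(
    dmap: DomainMap,
    rois: Sequence[GlomerulusROI],
    mode: str = "center",
) -> dict[str, str]:
    """Assign each ROI a domain from the dorsal map.

    ``mode='center'`` (default) uses the label of the ROI's center pixel;
    ``mode='majority'`` votes over the map pixels within the ROI footprint
    (ellipse in map coordinates, which are anisotropic). An ROI over an OUTSIDE
    pixel — or outside the map bounds — is UNASSIGNED.
    """
    if mode not in ("center", "majority"):
        raise ValidationError(f"unknown assignment mode {mode!r}")
    S, W = dmap.labels.shape
    out: dict[str, str] = {}
    for roi in rois:
        x_um, y_um = roi.center_um
        row = int(round(y_um / dmap.ap_spacing_um))
        col = int(round(x_um / dmap.ml_pixel_um))
        if not (0 <= row < S and 0 <= col < W):
            out[roi.id] = UNASSIGNED
            continue
        if mode == "center":
            label = MapLabel(dmap.labels[row, col])
        else:
            rr, cc = np.ogrid[:S, :W]
            dy = (rr - y_um / dmap.ap_spacing_um) * dmap.ap_spacing_um
            dx = (cc - x_um / dmap.ml_pixel_um) * dmap.ml_pixel_um
            inside = dy**2 + dx**2 <= (roi.diameter_um / 2.0) ** 2
            votes = dmap.labels[inside]
            votes = votes[votes != MapLabel.OUTSIDE]
            if votes.size == 0:
                out[roi.id] = UNASSIGNED
                continue
            vals, counts = np.unique(votes, return_counts=True)
            label = MapLabel(int(vals[np.argmax(counts)]))
        out[roi.id] = (
            _MAP_TO_DOMAIN[label].value if label != MapLabel.OUTSIDE else UNASSIGNED
        )
    return out


def domain_counts(
    calls: Sequence[ResponseCall], assignment: dict[str, str]
) -> dict[Odor, dict[str, int]]:
    """Responsive-glomerulus counts per odor x domain (UNASSIGNED excluded)."""
    counts: dict = {}
    for c in calls:
        if not c.responsive:
            continue
        dom = assignment.get(c.roi_id, UNASSIGNED)
        if dom == UNASSIGNED:
            continue
        counts.setdefault(c.odor, {DomainLabel.DI.value: 0, DomainLabel.DII.value: 0})
        counts[c.odor][dom] += 1
    return counts


def domain_distribution_test(
    counts_by_odor: Union[np.ndarray, Sequence[Sequence[int]]],
    yates: bool = False,
) -> tuple[TestResult, dict]:
    """Chi-square test of odor x domain independence plus per-odor DI/DII fractions.

    ``counts_by_odor`` is a 2x2 table, rows = odors (orthonasal mixture first,
    then the intravenous odor), columns = (DI, DII).
    """
    table = np.asarray(counts_by_odor, dtype=float)
    if table.shape != (2, 2):
        raise ValidationError("domain distribution test expects a 2x2 table")
    result = chi_square_test(table, yates=yates)
    fractions = {}
    for i, odor in enumerate((Odor.TNT_MIX, Odor.IVO)):
        total = table[i].sum()
        fractions[odor.value] = {
            "DI": float(table[i, 0] / total) if total else float("nan"),
            "DII": float(table[i, 1] / total) if total else float("nan"),
        }
    return result, fractions


def magnitude_by_domain(
    calls: Sequence[ResponseCall], assignment: dict[str, str]
) -> dict[str, TestResult]:
    """Per-odor two-sided Mann-Whitney U comparing responder magnitudes DI vs DII."""
    out: dict[str, TestResult] = {}
    by_odor: dict = {}
    for c in calls:
        if not c.responsive:
            continue
        dom = assignment.get(c.roi_id, UNASSIGNED)
        if dom == UNASSIGNED:
            continue
        by_odor.setdefault(c.odor, {DomainLabel.DI.value: [],
                                    DomainLabel.DII.value: []})
        by_odor[c.odor][dom].append(c.magnitude)
    for odor, groups in by_odor.items():
        di, dii = groups[DomainLabel.DI.value], groups[DomainLabel.DII.value]
        if not di or not dii:
            continue
        out[odor.value] = mann_whitney_u(di, dii, alternative="two-sided")
    return out
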