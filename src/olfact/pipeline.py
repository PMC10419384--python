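"""Orchestration: one-command reproduction of the clinical and imaging analyses.

:func:`reproduce_clinical` rebuilds the 307-patient fixture from the published
marginals, pushes every record through the scoring pipeline, and recomputes the
headline diagnostics: the four disease x response-combination signatures
(odds ratio, sensitivity, specificity), the response-combination count table,
the univariable logistic screen, and the domain-distribution statistics of the
published responder counts.

:func:`reproduce_imaging` simulates a full imaging experiment at the scale of
the published mouse data — 35 orthonasal-mixture responders (15 DI / 20 DII)
and 44 intravenous-odor responders (40 DI / 4 DII) plus nonresponsive
glomeruli, five trials per odor — renders the movie and the NQO1 section
stack, runs the complete analysis pipeline, and reports recovered counts,
domain fractions, the chi-square and Mann-Whitney results, and recovery
metrics against the planted ground truth.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from . import __version__
from .cohort import COMBO_COUNTS, Disease, build_paper_cohort
from .domains import (
    assign_domains,
    domain_counts,
    domain_distribution_test,
    label_sections,
    magnitude_by_domain,
    reconstruct_dorsal_map,
)
from .exceptions import ValidationError
from .responses import GlomerulusROI, analyze_movie, count_responsive
from .scoring import Combo, classify_combination
from .simulate import (
    DomainLabel,
    GlomerulusGT,
    Odor,
    generate_movie,
    generate_nqo1_sections,
)
from .stats import (
    combo_indicators,
    diagnostics,
    disease_indicator,
    make_table,
    mann_whitney_u,
    univariable_screen,
)

#: Published dorsal-domain responder counts: rows = (orthonasal mixture, IV odor),
#: columns = (DI, DII).
PUBLISHED_DOMAIN_COUNTS: tuple[tuple[int, int], ...] = ((15, 20), (40, 4))

#: The four headline disease x combination signatures.
SIGNATURES: tuple[tuple[Disease, Combo], ...] = (
    (Disease.PVOD, Combo.PN),
    (Disease.CRS_NOPOLYP, Combo.PP),
    (Disease.CRS_POLYP, Combo.NP),
    (Disease.PTOD, Combo.NN),
)


@dataclass
class ImagingSpec:
    """Scale and noise of the simulated imaging experiment."""

    n_tnt_di: int = 15
    n_tnt_dii: int = 20
    n_ivo_di: int = 40
    n_ivo_dii: int = 4
    n_nonresponders: int = 10
    n_trials: int = 5
    noise_sd: float = 2.0  # raw intensity units (baseline 100)
    bleach_rate: float = 0.002  # 1/s shared exponential
    field_px: int = 256
    pixel_size_um: float = 5.0
    pitch_px: int = 25  # glomerulus grid pitch
    tnt_amplitude: tuple[float, float] = (0.30, 0.05)  # mean, sd of dF/F
    ivo_amplitude: tuple[float, float] = (0.55, 0.08)
    baseline: float = 100.0
    di_contrast_sd_units: float = 5.0
    section_z_spacing_um: float = 40.0


@dataclass
class RunConfig:
    """Seed, analysis flags, simulation scale and output location for a run."""

    seed: int = 0
    outdir: Optional[str] = None
    yates: bool = False
    haldane: bool = False
    detection_alpha: float = 0.05
    use_wilcoxon: bool = False
    imaging: ImagingSpec = field(default_factory=ImagingSpec)

    def to_yaml(self, path: Optional[Union[str, Path]] = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: Union[str, Path]) -> "RunConfig":
        p = Path(source)
        doc = yaml.safe_load(p.read_text() if p.exists() else str(source))
        imaging = doc.pop("imaging", {})
        for key in ("tnt_amplitude", "ivo_amplitude"):
            if key in imaging:
                imaging[key] = tuple(imaging[key])
        return cls(imaging=ImagingSpec(**imaging), **doc)


def manifest(config: RunConfig) -> dict:
    """Reproducibility manifest: config hash, seed, versions."""
    text = config.to_yaml()
    return {
        "config_sha256": hashlib.sha256(text.encode()).hexdigest(),
        "seed": config.seed,
        "olfact_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
    }


# ---------------------------------------------------------------------------
# Clinical arm
# ---------------------------------------------------------------------------

def reproduce_clinical(config: Optional[RunConfig] = None) -> dict:
    """Recompute the clinical headline results from the built-in fixture.

    Every number is recomputed: each patient's tests are re-scored from raw
    thresholds/latencies, combinations re-derived, tables re-marginalized and
    diagnostics re-evaluated. The report is a JSON-serializable dict.
    """
    config = config or RunConfig()
    cohort = build_paper_cohort()

    # recompute combinations through the scoring pipeline (not the stored labels)
    combo_table: dict = {}
    for r in cohort:
        combo = classify_combination(r.tnt.response, r.ivo.response)
        combo_table.setdefault(r.disease.value, {c.value: 0 for c in Combo})
        combo_table[r.disease.value][combo.value] += 1

    signatures = {}
    for disease, combo in SIGNATURES:
        table = make_table(cohort, disease, combo)
        stats = diagnostics(table, haldane=config.haldane)
        signatures[f"{disease.value}|{combo.value}"] = {
            "table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
            "odds_ratio": stats.odds_ratio,
            "ci95": [stats.ci95_low, stats.ci95_high],
            "sensitivity": stats.sensitivity,
            "specificity": stats.specificity,
        }

    n_pvod = sum(combo_table[Disease.PVOD.value].values())
    pvod_both_pct = 100.0 * combo_table[Disease.PVOD.value][Combo.PP.value] / n_pvod

    screen = univariable_screen(
        combo_indicators(cohort), disease_indicator(cohort, Disease.PVOD)
    )
    screen_report = {
        name: {
            "coef": float(fit.coef[1]),
            "se": float(fit.se[1]),
            "p": float(fit.p[1]),
            "selected": name in screen.selected,
        }
        for name, fit in screen.fits.items()
    }
    for name, err in screen.errors.items():
        screen_report[name] = {"error": err, "selected": False}

    chi2, fractions = domain_distribution_test(
        PUBLISHED_DOMAIN_COUNTS, yates=config.yates
    )

    return {
        "n_total": len(cohort),
        "combo_counts": combo_table,
        "signatures": signatures,
        "pvod_both_responsive_pct": pvod_both_pct,
        "univariable_screen_pvod": screen_report,
        "published_domain_counts": [list(r) for r in PUBLISHED_DOMAIN_COUNTS],
        "domain_chi_square": {"statistic": chi2.statistic, "df": chi2.df,
                              "p_value": chi2.p_value},
        "domain_fractions": fractions,
        "manifest": manifest(config),
    }


# ---------------------------------------------------------------------------
# Imaging arm
# ---------------------------------------------------------------------------

def build_imaging_layout(spec: ImagingSpec, seed: int) -> list[GlomerulusGT]:
    """Planted glomerulus layout at the published responder scale.

    Glomeruli sit on a square grid (no overlaps by construction); domain truth
    and odor responsiveness follow the spec counts; response amplitudes are
    drawn per glomerulus, the intravenous odor stronger than the orthonasal
    mixture as in the recorded data.
    """
    rng = np.random.default_rng(seed)
    roles = (
        [(Odor.TNT_MIX, DomainLabel.DI)] * spec.n_tnt_di
        + [(Odor.TNT_MIX, DomainLabel.DII)] * spec.n_tnt_dii
        + [(Odor.IVO, DomainLabel.DI)] * spec.n_ivo_di
        + [(Odor.IVO, DomainLabel.DII)] * spec.n_ivo_dii
        + [(None, DomainLabel.DII)] * ((spec.n_nonresponders + 1) // 2)
        + [(None, DomainLabel.DI)] * (spec.n_nonresponders // 2)
    )
    pitch_um = spec.pitch_px * spec.pixel_size_um
    margin_um = 60.0
    per_row = int((spec.field_px * spec.pixel_size_um - 2 * margin_um) // pitch_um) + 1
    if per_row**2 < len(roles):
        raise ValidationError("field too small for the requested glomerulus count")
    order = rng.permutation(len(roles))  # scatter roles over the grid
    layout = []
    for k, idx in enumerate(order):
        odor, domain = roles[idx]
        gx = margin_um + (k % per_row) * pitch_um
        gy = margin_um + (k // per_row) * pitch_um
        amplitudes = {}
        if odor is Odor.TNT_MIX:
            amplitudes[odor] = max(0.1, rng.normal(*spec.tnt_amplitude))
        elif odor is Odor.IVO:
            amplitudes[odor] = max(0.1, rng.normal(*spec.ivo_amplitude))
        layout.append(
            GlomerulusGT(
                id=f"g{idx:03d}", center_um=(gx, gy), baseline=spec.baseline,
                amplitudes=amplitudes, domain=domain,
            )
        )
    return layout


def reproduce_imaging(config: Optional[RunConfig] = None) -> dict:
    """Simulate and analyze a full imaging experiment at the published scale."""
    config = config or RunConfig()
    spec = config.imaging
    seed = config.seed

    layout = build_imaging_layout(spec, seed)
    movie = generate_movie(
        layout, noise_sd=spec.noise_sd, bleach_rate=spec.bleach_rate,
        n_trials=spec.n_trials, seed=seed + 1,
        field_shape=(spec.field_px, spec.field_px),
        pixel_size_um=spec.pixel_size_um,
    )
    rois = [GlomerulusROI(g.id, g.center_um, g.diameter_um) for g in layout]
    calls, traces = analyze_movie(
        movie, rois, alpha=config.detection_alpha,
        use_wilcoxon=config.use_wilcoxon,
    )
    del movie

    sections = generate_nqo1_sections(
        layout, di_contrast_sd_units=spec.di_contrast_sd_units, seed=seed + 2,
        z_spacing_um=spec.section_z_spacing_um, pixel_size_um=spec.pixel_size_um,
        width_px=spec.field_px,
        n_sections=int(np.ceil(spec.field_px * spec.pixel_size_um
                               / spec.section_z_spacing_um)),
    )
    dmap = reconstruct_dorsal_map(sections, label_sections(sections))
    assignment = assign_domains(dmap, rois)

    counts, magnitudes = count_responsive(calls)
    dom_counts = domain_counts(calls, assignment)
    table = [
        [dom_counts.get(o, {}).get("DI", 0), dom_counts.get(o, {}).get("DII", 0)]
        for o in (Odor.TNT_MIX, Odor.IVO)
    ]
    chi2, fractions = domain_distribution_test(table, yates=config.yates)
    mwu_domains = magnitude_by_domain(calls, assignment)
    mwu_odors = mann_whitney_u(
        magnitudes.get(Odor.IVO, [0.0]), magnitudes.get(Odor.TNT_MIX, [0.0]),
        alternative="two-sided",
    )

    # recovery vs planted truth
    planted = {(g.id, o) for g in layout for o in g.responsive_odors}
    detected = {(c.roi_id, c.odor) for c in calls if c.responsive}
    amp_errors = []
    for c in calls:
        if (c.roi_id, c.odor) in planted:
            g = next(g for g in layout if g.id == c.roi_id)
            amp_errors.append(abs(c.magnitude - g.amplitudes[c.odor]))
    domain_truth = {g.id: g.domain.value for g in layout}
    dom_correct = sum(
        1 for rid, dom in assignment.items() if dom == domain_truth[rid]
    )

    return {
        "planted": {
            "TNT_MIX": spec.n_tnt_di + spec.n_tnt_dii,
            "IVO": spec.n_ivo_di + spec.n_ivo_dii,
            "domain_table": [[spec.n_tnt_di, spec.n_tnt_dii],
                             [spec.n_ivo_di, spec.n_ivo_dii]],
        },
        "recovered_counts": {o.value: counts.get(o, 0)
                             for o in (Odor.TNT_MIX, Odor.IVO)},
        "recovered_domain_table": table,
        "domain_chi_square": {"statistic": chi2.statistic, "df": chi2.df,
                              "p_value": chi2.p_value},
        "domain_fractions": fractions,
        "magnitude_mwu_by_domain": {
            odor: {"U": t.statistic, "p_value": t.p_value}
            for odor, t in mwu_domains.items()
        },
        "magnitude_mwu_ivo_vs_tnt": {"U": mwu_odors.statistic,
                                     "p_value": mwu_odors.p_value},
        "recovery": {
            "true_positives": len(planted & detected),
            "false_positives": len(detected - planted),
            "false_negatives": len(planted - detected),
            "max_amplitude_abs_error": max(amp_errors) if amp_errors else None,
            "domain_assignment_accuracy": dom_correct / len(assignment),
            "n_reference_rois": len(traces.reference_rois),
        },
        "manifest": manifest(config),
    }


def write_report(report: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(report, indent=1, default=str))
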