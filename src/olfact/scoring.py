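"""Scoring rules for the two clinical olfactory tests and the response-combination
classifier.

Two tests are scored:

* **T&T olfactometry** (orthonasal): five odorants (A) beta-phenylethyl alcohol,
  (B) methyl cyclopentenolone, (C) isovaleric acid, (D) gamma-undecalactone,
  (E) skatol, each presented over a graded concentration series. Odors A, C, D
  and E span eight intensity degrees (-2..5); odor B spans seven (-2..4). The
  recognition threshold is the lowest degree at which the subject identifies the
  odor; "not recognized" (NR) is encoded as one degree above the odor's maximum
  (6 for A/C/D/E, 5 for B), which makes the all-recognized-at-minimum average -2
  and the nothing-recognized average 5.8. The test is a *response* when the
  five-odor average is below 5.6; an average of 5.6 or more is no response.

* **IVO test** (retronasal): intravenous prosultiamine; the subject reports the
  first perception of a garlic odor. A response is any perception within the
  3-minute window (latency <= 180 s). A latency under 10 s is a normal onset,
  and a perception duration over 60 s is a normal duration.

The combination of the two boolean responses yields one of four categories,
written T&T sign first: PP = T&T(+)IVO(+), PN = T&T(+)IVO(-),
NP = T&T(-)IVO(+), NN = T&T(-)IVO(-).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence, Union

from .exceptions import ValidationError

ODORS: tuple[str, ...] = ("A", "B", "C", "D", "E")

#: Legal threshold range per odor (inclusive); B has one fewer degree.
ODOR_MIN: int = -2
ODOR_MAX: dict[str, int] = {"A": 5, "B": 4, "C": 5, "D": 5, "E": 5}

#: Sentinel accepted in threshold inputs / CSV cells for "not recognized".
NR = "NR"

#: Averaged T&T score at or above this value is classified as no response.
TNT_NO_RESPONSE_CUTOFF: float = 5.6

#: IVO response window: perception within 3 minutes (inclusive).
IVO_WINDOW_S: float = 180.0
#: Latency strictly below this is a normal onset time.
IVO_NORMAL_ONSET_S: float = 10.0
#: Duration strictly above this is a normal duration.
IVO_NORMAL_DURATION_S: float = 60.0


class Combo(str, Enum):
    """Four-way response combination; T&T sign first, then IVO sign."""

    PP = "PP"  # T&T(+) IVO(+)
    PN = "PN"  # T&T(+) IVO(-)
    NP = "NP"  # T&T(-) IVO(+)
    NN = "NN"  # T&T(-) IVO(-)


Threshold = Union[int, float, str, None]  # numeric degree, "NR", or None (= NR)


@dataclass(frozen=True)
class TnTResult:
    """Scored T&T olfactometry result.

    ``thresholds`` keeps the raw per-odor recognition thresholds (``None`` where
    the odor was not recognized), in odor order A..E.
    """

    thresholds: tuple[Optional[int], ...]
    averaged_score: float
    response: bool


@dataclass(frozen=True)
class IvoResult:
    """Scored intravenous-olfaction (prosultiamine) result.

    ``latency`` / ``duration`` are in seconds; ``None`` when the subject never
    perceived the odor (censored at the 180-s window).
    """

    latency: Optional[float]
    duration: Optional[float]
    response: bool
    normal_onset: bool
    normal_duration: bool


def _nr_encoded(odor: str) -> int:
    # NR = one degree above the odor's maximum: 6 for A/C/D/E, 5 for B.
    return ODOR_MAX[odor] + 1


def _normalize_thresholds(
    thresholds: Union[Mapping[str, Threshold], Sequence[Threshold]],
) -> dict[str, Threshold]:
    if isinstance(thresholds, Mapping):
        missing = [o for o in ODORS if o not in thresholds]
        if missing:
            raise ValidationError(f"missing T&T thresholds for odors {missing}")
        return {o: thresholds[o] for o in ODORS}
    values = list(thresholds)
    if len(values) != len(ODORS):
        raise ValidationError(
            f"expected {len(ODORS)} T&T thresholds (odors A-E), got {len(values)}"
        )
    return dict(zip(ODORS, values))


def score_tnt(
    thresholds: Union[Mapping[str, Threshold], Sequence[Threshold]],
) -> TnTResult:
    """Score a T&T olfactometry test from the five per-odor recognition thresholds.

    Parameters
    ----------
    thresholds
        Mapping keyed by odor letter A-E, or a sequence in odor order. Each value
        is an integer degree within the odor's legal range, or ``"NR"``/``None``
        for "not recognized".

    Returns
    -------
    TnTResult
        The averaged score (mean of the five encoded thresholds, NR encoded as
        odor maximum + 1) and the response flag (average < 5.6).

    Raises
    ------
    ValidationError
        If a threshold lies outside its odor's legal range; the message names
        the offending odor.
    """
    values = _normalize_thresholds(thresholds)
    raw: list[Optional[int]] = []
    encoded: list[float] = []
    for odor in ODORS:
        v = values[odor]
        if v is None or (isinstance(v, str) and v.strip().upper() == NR):
            raw.append(None)
            encoded.append(_nr_encoded(odor))
            continue
        if isinstance(v, str):
            try:
                v = float(v)
            except ValueError as exc:
                raise ValidationError(
                    f"odor {odor}: threshold {v!r} is neither numeric nor 'NR'"
                ) from exc
        fv = float(v)
        if not fv.is_integer():
            raise ValidationError(
                f"odor {odor}: threshold {v!r} must be an integer degree"
            )
        iv = int(fv)
        if not (ODOR_MIN <= iv <= ODOR_MAX[odor]):
            raise ValidationError(
                f"odor {odor}: threshold {iv} outside legal range "
                f"[{ODOR_MIN}, {ODOR_MAX[odor]}]"
            )
        raw.append(iv)
        encoded.append(float(iv))
    averaged = sum(encoded) / len(encoded)
    return TnTResult(
        thresholds=tuple(raw),
        averaged_score=averaged,
        response=averaged < TNT_NO_RESPONSE_CUTOFF,
    )


def score_ivo(
    latency: Optional[float], duration: Optional[float]
) -> IvoResult:
    """Score an IVO test from the perception latency and duration (seconds).

    A response is a perceived garlic odor within the 3-minute window
    (``latency`` present and <= 180 s). Latency below 10 s is a normal onset;
    duration above 60 s is a normal duration. Absent latency means no
    perception within the window.
    """
    if latency is not None and latency < 0:
        raise ValidationError(f"IVO latency must be nonnegative, got {latency}")
    if duration is not None and duration < 0:
        raise ValidationError(f"IVO duration must be nonnegative, got {duration}")
    response = latency is not None and latency <= IVO_WINDOW_S
    normal_onset = response and latency < IVO_NORMAL_ONSET_S
    normal_duration = (
        response and duration is not None and duration > IVO_NORMAL_DURATION_S
    )
    return IvoResult(
        latency=latency,
        duration=duration,
        response=response,
        normal_onset=normal_onset,
        normal_duration=normal_duration,
    )


def classify_combination(tnt_response: bool, ivo_response: bool) -> Combo:
    """Map the pair of boolean test responses to the four-way combination."""
    if tnt_response:
        return Combo.PP if ivo_response else Combo.PN
    return Combo.NP if ivo_response else Combo.NN
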