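"""¹⁶O/¹⁸O doublet pairing and classification of MS1 features.

Tryptic digests prepared separately in light and heavy water and mixed 1:1
produce co-eluting feature doublets. A linear peptide carries one new
C-terminus (two ¹⁸O atoms, +4.008 Da at full incorporation); a cross-linked
pair carries two new termini (+8.017 Da). Shifts of one or three ¹⁸O atoms
(+2.004 / +6.013 Da) indicate incomplete incorporation and are flagged
``partial``; anything else is ``unclassified``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .chem import O18_MINUS_O16

#: Admissible neutral-mass shifts (Da) and the call each one implies.
ADMISSIBLE_SHIFTS: dict[float, str] = {
    1 * O18_MINUS_O16: "partial",
    2 * O18_MINUS_O16: "linear",
    3 * O18_MINUS_O16: "partial",
    4 * O18_MINUS_O16: "crosslinked",
}

DEFAULT_SHIFT_TOLERANCE = 0.015  # Da, neutral-mass space


@dataclass(frozen=True)
class Ms1Feature:
    """An observed precursor feature (one charge state, one channel)."""

    feature_id: str
    mz: float
    charge: int
    area: float
    rt_start: float
    rt_end: float
    channel: str = ""  # "16O" | "18O" | "" when unknown (mixed run)
    sample: str = ""
    fraction: str = ""

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.area < 0:
            raise ValueError("area must be >= 0")
        if self.rt_end < self.rt_start:
            raise ValueError("rt_end must be >= rt_start")

    def coelutes(self, other: "Ms1Feature") -> bool:
        return self.rt_start <= other.rt_end and other.rt_start <= self.rt_end


@dataclass(frozen=True)
class DoubletCall:
    light_feature: Ms1Feature
    heavy_feature: Ms1Feature
    neutral_shift: float
    call: str  # linear | crosslinked | partial | unclassified
    charge: int


def classify_shift(neutral_shift: float, tolerance: float = DEFAULT_SHIFT_TOLERANCE) -> str:
    """Call a neutral-mass shift against the admissible ¹⁸O shift ladder.

    The heavy channel must be the heavier one: negative shifts are never
    classified. The nearest admissible shift wins if within ``tolerance``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if neutral_shift <= 0:
        return "unclassified"
    best = min(ADMISSIBLE_SHIFTS, key=lambda s: abs(neutral_shift - s))
    if abs(neutral_shift - best) <= tolerance:
        return ADMISSIBLE_SHIFTS[best]
    return "unclassified"


def pair_doublets(
    features: Sequence[Ms1Feature],
    shift_tolerance: float = DEFAULT_SHIFT_TOLERANCE,
) -> list[DoubletCall]:
    """Pair co-eluting same-charge features into ¹⁶O/¹⁸O doublets.

    For every ordered light/heavy pair with overlapping retention windows
    and identical charge, the neutral shift is charge × (heavy m/z − light
    m/z). Pairs whose shift classifies are accepted greedily by combined
    intensity (ties by smaller shift error); each feature joins at most one
    doublet.
    """
    candidates: list[tuple[float, float, Ms1Feature, Ms1Feature, float, str]] = []
    by_charge: dict[int, list[Ms1Feature]] = {}
    for f in features:
        by_charge.setdefault(f.charge, []).append(f)
    for charge, group in by_charge.items():
        group = sorted(group, key=lambda f: f.mz)
        max_dmz = (4 * O18_MINUS_O16 + shift_tolerance) / charge
        for i, light in enumerate(group):
            for heavy in group[i + 1 :]:
                dmz = heavy.mz - light.mz
                if dmz > max_dmz:
                    break
                if not light.coelutes(heavy):
                    continue
                if light.channel and heavy.channel and light.channel == heavy.channel:
                    continue
                shift = charge * dmz
                call = classify_shift(shift, shift_tolerance)
                if call == "unclassified":
                    continue
                err = min(abs(shift - s) for s in ADMISSIBLE_SHIFTS)
                candidates.append((light.area + heavy.area, err, light, heavy, shift, call))

    candidates.sort(key=lambda c: (-c[0], c[1]))
    used: set[str] = set()
    calls: list[DoubletCall] = []
    for _, _, light, heavy, shift, call in candidates:
        if light.feature_id in used or heavy.feature_id in used:
            continue
        used.update((light.feature_id, heavy.feature_id))
        calls.append(DoubletCall(light, heavy, shift, call, light.charge))
    return calls


def doublets_of_kind(calls: Iterable[DoubletCall], kind: str) -> list[DoubletCall]:
    return [c for c in calls if c.call == kind]
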