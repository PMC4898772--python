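"""Relative-response statistic and recognition-scenario classification.

For each population, the area under the fitted response-probability curve
(AUC, trapezoidal, units kHz * probability) is computed for every stimulus
note variant over the tested frequency range, then expressed as a
proportion of the own-call AUC.  A relative response of 1 is the population
responding to a variant exactly as to its own call; values above 1 mean a
foreign variant is recognized *better* than the own call — a pattern that
does occur and must not be capped.

Scenario classification over the tested variants:

* ``null``          — no significant note effect: the population responds to
                      all note variants alike.
* ``matched``       — significant note effect and every non-own variant's
                      relative response below a small floor: the receiver
                      only recognizes the own signal (perfect sender-receiver
                      coupling).
* ``intermediate``  — significant note effect with graded, non-negligible
                      responses to foreign variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recognition import ResponseCurve

__all__ = [
    "RelativeResponseTable",
    "ScenarioCall",
    "curve_auc",
    "relative_response_table",
    "classify_scenario",
]


@dataclass
class RelativeResponseTable:
    population: str
    own_note: int
    auc: dict[int, float]        # note variant -> area (kHz * probability)
    relative: dict[int, float]   # note variant -> AUC / own-call AUC


@dataclass
class ScenarioCall:
    population: str
    scenario: str                # "null" | "matched" | "intermediate"
    note_effect_pvalue: float
    min_relative: float
    max_relative: float
    alpha: float
    floor: float


def curve_auc(curve: ResponseCurve, note: int) -> float:
    """Trapezoidal area under one note variant's probability curve."""
    if note not in curve.curves:
        raise KeyError(f"no curve for note variant {note}")
    if len(curve.grid) < 2:
        raise ValueError("grid needs >= 2 points for an area")
    return float(np.trapezoid(curve.curves[note], curve.grid))


def relative_response_table(
    curve: ResponseCurve, own_note: int, population: str = ""
) -> RelativeResponseTable:
    """AUC of each variant as a proportion of the own-call AUC."""
    if own_note not in curve.curves:
        raise ValueError(f"own note {own_note} not among fitted variants "
                         f"{sorted(curve.curves)}")
    auc = {k: curve_auc(curve, k) for k in curve.curves}
    if auc[own_note] <= 0:
        raise ValueError("own-call AUC is zero; relative response undefined")
    rel = {k: a / auc[own_note] for k, a in auc.items()}
    return RelativeResponseTable(population=population, own_note=own_note,
                                 auc=auc, relative=rel)


def classify_scenario(
    table: RelativeResponseTable,
    note_pvalue: float,
    alpha: float = 0.05,
    floor: float = 0.05,
) -> ScenarioCall:
    """Assign one of the three recognition scenarios to a population.

    ``null`` when the note effect is not significant at ``alpha``;
    ``matched`` when significant and all non-own relative responses are at
    or below ``floor``; ``intermediate`` otherwise.  ``alpha`` may be the
    Bonferroni-corrected threshold when family-wise control is wanted.
    """
    non_own = [v for k, v in table.relative.items() if k != table.own_note]
    rels = list(table.relative.values())
    if note_pvalue >= alpha:
        scenario = "null"
    elif all(v <= floor for v in non_own):
        scenario = "matched"
    else:
        scenario = "intermediate"
    return ScenarioCall(
        population=table.population, scenario=scenario,
        note_effect_pvalue=float(note_pvalue),
        min_relative=float(min(rels)), max_relative=float(max(rels)),
        alpha=alpha, floor=floor,
    )
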