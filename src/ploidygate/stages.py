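"""Morphology-based life-stage classification.

Combines the DNA-content gate with image-derived organelle counts to
separate mitotic from sexual (meiotic) cells. The biology behind the rules:

* the accumulation body stays single through mitosis, so *two* accumulation
  bodies in a one-nucleus 2C cell mean two merged cytoplasms — a zygote;
* pyrenoids duplicate only late in mitotic division, so a one-nucleus 2C
  cell with two pyrenoids likewise cannot be mitotic;
* DNA content above 2C cannot arise in a mitotic cycle: a one-nucleus
  hyper-gate cell is a replicating zygote (meiotic S), a two-nuclei one a
  dyad (meiosis I product), and three- / four-nuclei objects are triads and
  tetrads of the delayed second meiotic division.

A caveat the labels inherit from the underlying evidence: tetrads are
interpreted here as two-step meiotic products; a two-round asynchronous
mitosis producing four nuclei cannot be fully excluded on DNA content and
morphology alone.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import EmptyGateError, ValidationError
from .events import EventSet
from .gating import GATED_LABELS, GateComposition, GateLabel, gate_composition


class StageLabel(str, enum.Enum):
    """Life-cycle stage of a single event."""

    VEGETATIVE = "VEGETATIVE"
    MITOTIC_S = "MITOTIC_S"
    MITOTIC_DIVIDING = "MITOTIC_DIVIDING"
    ZYGOTE = "ZYGOTE"
    MEIOTIC_S = "MEIOTIC_S"
    DYAD = "DYAD"
    TRIAD = "TRIAD"
    TETRAD = "TETRAD"
    UNCLASSIFIED = "UNCLASSIFIED"


#: Stages counted as sexual (gamete fusion or meiosis).
SEXUAL_STAGES = frozenset(
    {StageLabel.ZYGOTE, StageLabel.MEIOTIC_S, StageLabel.DYAD,
     StageLabel.TRIAD, StageLabel.TETRAD}
)

#: Canonical morphology (nuclei, pyrenoids, accumulation bodies, lobes) per
#: stage, used by the synthetic-population generator.
CANONICAL_MORPHOLOGY: Mapping[StageLabel, tuple[int, int, int, int]] = {
    StageLabel.VEGETATIVE: (1, 1, 1, 1),
    StageLabel.MITOTIC_S: (1, 1, 1, 1),
    StageLabel.MITOTIC_DIVIDING: (2, 2, 1, 2),
    StageLabel.ZYGOTE: (1, 2, 2, 1),
    StageLabel.MEIOTIC_S: (1, 2, 2, 1),
    StageLabel.DYAD: (2, 2, 2, 2),
    StageLabel.TRIAD: (3, 2, 2, 3),
    StageLabel.TETRAD: (4, 2, 2, 3),
}


def classify_stage(
    gate: GateLabel,
    nuclei_count: int | None = None,
    pyrenoid_count: int | None = None,
    accumulation_body_count: int | None = None,
    lobe_count: int | None = None,
) -> StageLabel:
    """Assign a life-cycle stage from gate membership and morphology counts.

    First matching rule wins; any count required by a rule that is absent
    makes the rule inapplicable, and events matching no rule are
    UNCLASSIFIED (missing morphology degrades gracefully rather than
    guessing). Nuclear count outranks gate membership for triads/tetrads:
    three or four nuclei identify those stages at any DNA content.
    ``lobe_count`` is accepted for forward compatibility but used by no
    rule (lobes are descriptive of triad/tetrad geometry, not diagnostic).
    """
    for name, value in (
        ("nuclei_count", nuclei_count),
        ("pyrenoid_count", pyrenoid_count),
        ("accumulation_body_count", accumulation_body_count),
    ):
        if value is not None and value < 0:
            raise ValidationError(f"{name} must be >= 0, got {value}")
    if lobe_count is not None and lobe_count < 1:
        raise ValidationError(f"lobe_count must be >= 1, got {lobe_count}")
    if gate not in GATED_LABELS:
        raise ValidationError(f"classification requires a gated event, got {gate}")

    n, p, a = nuclei_count, pyrenoid_count, accumulation_body_count
    if n == 4:
        return StageLabel.TETRAD
    if n == 3:
        return StageLabel.TRIAD
    if gate == GateLabel.HYPER and n == 2:
        return StageLabel.DYAD
    if gate == GateLabel.HYPER and n == 1:
        return StageLabel.MEIOTIC_S
    if gate == GateLabel.C2 and n == 1 and p == 2 and a == 2:
        return StageLabel.ZYGOTE
    if gate == GateLabel.C2 and n == 2 and a == 1:
        return StageLabel.MITOTIC_DIVIDING
    if (gate in (GateLabel.S, GateLabel.C2) and n == 1
            and p is not None and p <= 1 and a is not None and a <= 1):
        return StageLabel.MITOTIC_S
    if gate == GateLabel.C1 and n == 1:
        return StageLabel.VEGETATIVE
    return StageLabel.UNCLASSIFIED


def classify_events(labeled: EventSet) -> EventSet:
    """Add a ``stage`` column to a gate-labelled event set.

    Vectorised application of the :func:`classify_stage` decision table;
    filtered events (sub-1C, unfocused, aggregates) receive no stage.
    """
    if "gate" not in labeled.table.columns:
        raise ValidationError("events carry no gate labels; run assign_gates")
    out = labeled.copy()
    df = out.table
    for col in ("nuclei_count", "pyrenoid_count", "accumulation_body_count"):
        present = df[col].dropna()
        if (present < 0).any():
            raise ValidationError(f"negative {col} values present")

    gate = df["gate"].to_numpy()
    # missing counts become -1, which matches no equality rule
    n = df["nuclei_count"].fillna(-1).to_numpy(dtype=int)
    p = df["pyrenoid_count"].fillna(-1).to_numpy(dtype=int)
    a = df["accumulation_body_count"].fillna(-1).to_numpy(dtype=int)
    hyper = gate == GateLabel.HYPER.value
    c2 = gate == GateLabel.C2.value
    s_or_c2 = (gate == GateLabel.S.value) | c2
    stage = np.select(
        [
            n == 4,
            n == 3,
            hyper & (n == 2),
            hyper & (n == 1),
            c2 & (n == 1) & (p == 2) & (a == 2),
            c2 & (n == 2) & (a == 1),
            s_or_c2 & (n == 1) & (p >= 0) & (p <= 1) & (a >= 0) & (a <= 1),
            (gate == GateLabel.C1.value) & (n == 1),
        ],
        [
            StageLabel.TETRAD.value,
            StageLabel.TRIAD.value,
            StageLabel.DYAD.value,
            StageLabel.MEIOTIC_S.value,
            StageLabel.ZYGOTE.value,
            StageLabel.MITOTIC_DIVIDING.value,
            StageLabel.MITOTIC_S.value,
            StageLabel.VEGETATIVE.value,
        ],
        default=StageLabel.UNCLASSIFIED.value,
    )
    gated = np.isin(gate, [g.value for g in GATED_LABELS])
    df["stage"] = pd.array(np.where(gated, stage, None), dtype="string")
    return out


@dataclass(frozen=True)
class StageComposition:
    """Per-stage percentages over the gated denominator."""

    stage_pct: Mapping[str, float]
    sexual_fraction: float  # percent of gated events in a sexual stage
    pct_hyper: float  # gate-level hyper percentage, for cross-checking
    n_gated: int


def stage_composition(labeled: EventSet) -> StageComposition:
    """Stage percentages, the sexual fraction, and the hyper-gate percent.

    Denominator as in :func:`ploidygate.gating.gate_composition` (gated
    events only). The sexual fraction counts zygotes, meiotic-S cells,
    dyads, triads and tetrads; the gate-level hyper percentage — the
    DNA-content-only sex metric — is reported alongside it.
    """
    if "stage" not in labeled.table.columns:
        raise ValidationError("events carry no stage labels; run classify_events")
    comp: GateComposition = gate_composition(labeled)  # raises EmptyGateError if needed
    gated = labeled.table["gate"].isin([g.value for g in GATED_LABELS])
    stages = labeled.table.loc[gated, "stage"]
    denom = comp.n_gated
    if denom == 0:
        raise EmptyGateError("no events in the gated denominator")
    pct = {
        s.value: 100.0 * float((stages == s.value).sum()) / denom
        for s in StageLabel
    }
    sexual = sum(pct[s.value] for s in SEXUAL_STAGES)
    return StageComposition(
        stage_pct=pct,
        sexual_fraction=sexual,
        pct_hyper=comp.pct_hyper,
        n_gated=denom,
    )
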