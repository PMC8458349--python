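"""Synthetic cytometry populations with known ground truth.

Emulates a fixed snapshot of a mixed symbiont population under the
two-step-meiosis ploidy model: vegetative haploids at 1C, mitotic S phase
between 1C and 2C, mitotically dividing cells at 2C; on the sexual side,
zygotes at 2C, replicating zygotes (meiotic S) between 2C and 4C, and
dyads/triads/tetrads as single 4C objects (the nuclei divide before the
cytoplasms separate, so the whole meiotic product passes the detector as
one event). Measured DNA fluorescence is the true content times a
multiplicative lognormal noise of configurable CV; projected cell area
scales as content^(2/3) (volume to projected area) with independent noise
of the same CV. Instrument artifacts — sub-1C debris, coincident-event
aggregates (sums of two cells) and out-of-focus events — are injected at
configurable rates.

Every generated event has exactly one truth record (stage, true DNA
content, artifact class), so downstream gating and classification can be
scored exactly. Identical seed and config give bitwise-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, PairingError
from .events import EventSet
from .stages import CANONICAL_MORPHOLOGY, SEXUAL_STAGES, StageLabel

#: Stage fractions emulating the study conditions: ~1.5% of cells in sexual
#: stages (most of them in the >2C-4C gate), a mitotic cycle occupying
#: ~8% at 2C, and the vegetative haploid bulk.
DEFAULT_STAGE_FRACTIONS: Mapping[StageLabel, float] = {
    StageLabel.VEGETATIVE: 0.845,
    StageLabel.MITOTIC_S: 0.060,
    StageLabel.MITOTIC_DIVIDING: 0.080,
    StageLabel.ZYGOTE: 0.0005,
    StageLabel.MEIOTIC_S: 0.0030,
    StageLabel.DYAD: 0.0040,
    StageLabel.TRIAD: 0.0035,
    StageLabel.TETRAD: 0.0040,
}

#: Support of the focus metric for in-focus events; unfocused events are
#: drawn below it (gradient RMS is lower for blurred objects).
_FOCUSED_RANGE = (40.0, 80.0)
_UNFOCUSED_BASE_HIGH = 20.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic population snapshot.

    ``noise_cv`` is the coefficient of variation of the multiplicative
    measurement noise (the default 0.05 is a stand-in for an unreported
    instrument CV and should be adjusted to the instrument at hand).
    ``focus_overlap`` raises the upper edge of the unfocused focus-metric
    distribution into the focused support (0 = perfectly separable).
    """

    n_events: int = 40_000
    stage_fractions: Mapping[StageLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_FRACTIONS)
    )
    c1_fluorescence_mean: float = 100.0
    noise_cv: float = 0.05
    debris_fraction: float = 0.01
    aggregate_fraction: float = 0.01
    unfocused_fraction: float = 0.02
    morphology_error_rate: float = 0.01
    area_scale: float = 50.0
    focus_overlap: float = 0.0
    seed: int = 0

    def __post_init__(self):
        fr = {StageLabel(k): float(v) for k, v in self.stage_fractions.items()}
        object.__setattr__(self, "stage_fractions", fr)
        if self.n_events <= 0:
            raise ConfigError("n_events must be positive")
        if any(v < 0 or v > 1 for v in fr.values()):
            raise ConfigError("stage fractions must lie in [0, 1]")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ConfigError(
                f"stage fractions sum to {sum(fr.values())}, expected 1"
            )
        for name in ("debris_fraction", "aggregate_fraction",
                     "unfocused_fraction", "morphology_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if (self.debris_fraction + self.aggregate_fraction
                + self.unfocused_fraction) > 1.0:
            raise ConfigError("artifact fractions sum above 1")
        if self.c1_fluorescence_mean <= 0 or self.area_scale <= 0:
            raise ConfigError("scales must be positive")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")

    def sexual_fraction(self) -> float:
        """Configured ground-truth fraction of sexual-stage cells."""
        return sum(self.stage_fractions.get(s, 0.0) for s in SEXUAL_STAGES)


def _lognormal_sigma(cv: float) -> float:
    """Lognormal shape parameter giving the requested CV: sqrt(ln(1+CV^2))."""
    return math.sqrt(math.log1p(cv * cv))


def _draw_content(rng: np.random.Generator, stages: np.ndarray) -> np.ndarray:
    """True DNA content (multiples of the haploid amount) per stage."""
    c = np.ones(len(stages))
    for stage, value in (
        (StageLabel.MITOTIC_DIVIDING, 2.0),
        (StageLabel.ZYGOTE, 2.0),
        (StageLabel.DYAD, 4.0),
        (StageLabel.TRIAD, 4.0),
        (StageLabel.TETRAD, 4.0),
    ):
        c[stages == stage.value] = value
    for stage, lo, hi in (
        (StageLabel.MITOTIC_S, 1.0, 2.0),
        (StageLabel.MEIOTIC_S, 2.0, 4.0),
    ):
        mask = stages == stage.value
        c[mask] = rng.uniform(lo, hi, size=int(mask.sum()))
    return c


def generate_population(config: SimulationConfig):
    """Generate one population snapshot.

    Returns ``(EventSet, truth)`` where ``truth`` is a DataFrame with one
    row per event: ``event_id``, ``true_stage`` (missing for debris and
    aggregates), ``true_c`` and ``artifact_class``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_events
    sigma = _lognormal_sigma(config.noise_cv)

    p_art = [config.debris_fraction, config.aggregate_fraction,
             config.unfocused_fraction]
    artifact = rng.choice(
        np.array(["debris", "aggregate", "unfocused", "none"]),
        size=n,
        p=p_art + [1.0 - sum(p_art)],
    )

    stage_names = np.array([s.value for s in config.stage_fractions])
    stage_probs = np.array(list(config.stage_fractions.values()), dtype=float)
    stage_probs = stage_probs / stage_probs.sum()

    stage = np.full(n, None, dtype=object)
    c = np.empty(n)
    fluor = np.empty(n)
    area = np.empty(n)
    morph = {col: np.full(n, -1, dtype=int) for col in
             ("nuclei_count", "pyrenoid_count",
              "accumulation_body_count", "lobe_count")}

    def _noise(size):
        return np.exp(rng.normal(0.0, sigma, size=size)) if sigma > 0 else np.ones(size)

    # cells (in-focus and unfocused alike carry a true stage)
    cellmask = (artifact == "none") | (artifact == "unfocused")
    n_cell = int(cellmask.sum())
    cell_stages = rng.choice(stage_names, size=n_cell, p=stage_probs)
    cell_c = _draw_content(rng, cell_stages)
    stage[cellmask] = cell_stages
    c[cellmask] = cell_c
    fluor[cellmask] = config.c1_fluorescence_mean * cell_c * _noise(n_cell)
    area[cellmask] = config.area_scale * cell_c ** (2.0 / 3.0) * _noise(n_cell)
    canon = {s.value: CANONICAL_MORPHOLOGY[s] for s in CANONICAL_MORPHOLOGY}
    for j, col in enumerate(morph):
        morph[col][cellmask] = [canon[s][j] for s in cell_stages]

    # debris: fragments well below 1C
    dmask = artifact == "debris"
    n_deb = int(dmask.sum())
    deb_c = rng.uniform(0.1, 0.7, size=n_deb)
    c[dmask] = deb_c
    fluor[dmask] = config.c1_fluorescence_mean * deb_c * _noise(n_deb)
    area[dmask] = config.area_scale * deb_c ** (2.0 / 3.0) * _noise(n_deb)

    # aggregates: sums of two independently drawn non-artifact cells
    amask = artifact == "aggregate"
    n_agg = int(amask.sum())
    comp_stages = rng.choice(stage_names, size=2 * n_agg, p=stage_probs)
    comp_c = _draw_content(rng, comp_stages)
    comp_f = config.c1_fluorescence_mean * comp_c * _noise(2 * n_agg)
    comp_a = config.area_scale * comp_c ** (2.0 / 3.0) * _noise(2 * n_agg)
    c[amask] = comp_c[:n_agg] + comp_c[n_agg:]
    fluor[amask] = comp_f[:n_agg] + comp_f[n_agg:]
    area[amask] = comp_a[:n_agg] + comp_a[n_agg:]
    for j, col in enumerate(morph):
        comp_counts = np.array([canon[s][j] for s in comp_stages])
        morph[col][amask] = comp_counts[:n_agg] + comp_counts[n_agg:]

    # morphology miscounts: each observed count perturbed +/-1 independently
    if config.morphology_error_rate > 0:
        observed = cellmask | amask
        for col in morph:
            hit = observed & (rng.random(n) < config.morphology_error_rate)
            delta = rng.choice([-1, 1], size=n)
            floor = 1 if col == "lobe_count" else 0
            morph[col][hit] = np.maximum(floor, morph[col][hit] + delta[hit])
    else:
        # keep the stream position independent of the error rate toggle
        pass

    focus = rng.uniform(*_FOCUSED_RANGE, size=n)
    umask = artifact == "unfocused"
    focus[umask] = rng.uniform(
        0.0, _UNFOCUSED_BASE_HIGH + config.focus_overlap, size=int(umask.sum())
    )

    ids = np.array([f"ev{i:06d}" for i in range(n)])
    table = pd.DataFrame(
        {
            "event_id": ids,
            "dna_fluorescence": fluor,
            "cell_area": area,
            "focus_metric": focus,
            "nuclear_aspect_ratio": np.ones(n),
        }
    )
    for col, vals in morph.items():
        table[col] = pd.array(np.where(vals < 0, None, vals), dtype="Int64")

    truth = pd.DataFrame(
        {
            "event_id": ids,
            "true_stage": pd.array(stage, dtype="string"),
            "true_c": c,
            "artifact_class": artifact,
        }
    )
    meta = {"generator": "ploidygate.simulate", "seed": config.seed,
            "noise_cv": config.noise_cv}
    return EventSet(table, meta), truth


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def confusion_matrix(truth: pd.DataFrame, predicted: pd.DataFrame) -> pd.DataFrame:
    """Counts indexed (true_stage, predicted_stage).

    ``predicted`` needs columns ``event_id`` and ``stage``; the id sets
    must match exactly. Rows with a missing true stage (debris, aggregates)
    are tallied under ``"<artifact>"``; missing predictions under
    ``"<none>"``.
    """
    t_ids, p_ids = set(truth["event_id"]), set(predicted["event_id"])
    if t_ids != p_ids:
        raise PairingError(
            f"event id mismatch: {len(t_ids - p_ids)} truth-only, "
            f"{len(p_ids - t_ids)} prediction-only"
        )
    merged = truth.merge(predicted[["event_id", "stage"]], on="event_id")
    true_lab = merged["true_stage"].astype(object).fillna("<artifact>")
    pred_lab = merged["stage"].astype(object).fillna("<none>")
    return pd.crosstab(true_lab, pred_lab, rownames=["true_stage"],
                       colnames=["predicted_stage"])


def per_stage_recall(matrix: pd.DataFrame) -> dict[str, float]:
    """Diagonal / row-sum recall per true stage present in the matrix."""
    out = {}
    for stage in matrix.index:
        total = int(matrix.loc[stage].sum())
        correct = int(matrix.loc[stage, stage]) if stage in matrix.columns else 0
        out[str(stage)] = correct / total if total else float("nan")
    return out
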