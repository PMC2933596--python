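"""Per-compound activity predictor plug-ins and probability colour coding.

A predictor maps a query compound (SMILES + fingerprint) to a list of
activity probabilities, one per target (e.g. a tumor cell line), each tagged
with a traffic-light colour: red for probability >= 0.7, yellow for >= 0.6
and < 0.7, grey below 0.6 (cutoffs configurable).  Production deployments
attach trained models behind this contract; the package ships a seeded
deterministic reference predictor so the report pipeline is fully testable
on its own.  Confusion metrics (sensitivity/specificity) are pass-through
model metadata, never recomputed here.
"""

from __future__ import annotations

import hashlib
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import pandas as pd

from .chem_core import Fingerprint
from .config import EngineConfig
from .errors import InvalidInputError

logger = logging.getLogger(__name__)

COLOR_RANK = {"grey": 0, "yellow": 1, "red": 2}

# 40 pseudo tumor cell lines spread over the customary panel names.
DEFAULT_TARGETS: tuple[tuple[str, str], ...] = tuple(
    (f"{prefix}-{i}", panel)
    for prefix, panel, count in (
        ("REN", "renal", 5),
        ("NSCLC", "non-small cell lung", 5),
        ("BRE", "breast", 5),
        ("COL", "colon", 5),
        ("MEL", "melanoma", 4),
        ("LEU", "leukemia", 4),
        ("OVA", "ovarian", 4),
        ("PRO", "prostate", 4),
        ("CNS", "central nervous system", 4),
    )
    for i in range(1, count + 1)
)


@dataclass(frozen=True)
class ActivityPrediction:
    """Predicted probability of activity against one target, colour coded."""

    target_name: str
    panel: str
    probability: float
    color: str
    confusion_metrics: Mapping[str, float] | None = None


def color_code(probability: float, config: EngineConfig | None = None) -> str:
    """Traffic-light colour for an activity probability.

    red for p >= red_threshold (default 0.7); yellow for
    yellow_threshold <= p < red_threshold (default 0.6); grey otherwise.
    """
    config = config or EngineConfig()
    if not (0.0 <= probability <= 1.0):
        raise InvalidInputError(f"probability must be in [0, 1], got {probability}")
    if probability >= config.red_threshold:
        return "red"
    if probability >= config.yellow_threshold:
        return "yellow"
    return "grey"


class PredictorContract(Protocol):
    """What any attached predictor must provide."""

    name: str
    metadata: str

    def predict(self, smiles: str, fp: Fingerprint) -> list[ActivityPrediction]:
        """Deterministic for fixed inputs and fixed predictor state."""
        ...


def _target_mask(seed: int, target_name: str, length: int) -> frozenset[int]:
    digest = hashlib.sha256(f"{seed}:{target_name}".encode("utf-8")).digest()
    rng = random.Random(int.from_bytes(digest[:8], "big"))
    size = max(1, length // 8 + rng.randrange(length // 4 or 1))
    return frozenset(rng.sample(range(length), min(size, length)))


@dataclass
class ReferencePredictor:
    """Seeded deterministic predictor for exercising the report pipeline.

    Each target owns a pseudo-random bit mask M_t (|M_t| >= 1) derived from
    the seed and the target name; the predicted probability is the fraction
    of M_t present in the query fingerprint, |fp ∩ M_t| / |M_t|.  A full
    fingerprint scores 1.0 everywhere, an empty one 0.0.
    """

    seed: int = 0
    targets: Sequence[tuple[str, str]] = DEFAULT_TARGETS
    fingerprint_length: int = 166
    config: EngineConfig = field(default_factory=EngineConfig)
    confusion: Mapping[str, Mapping[str, float]] | None = None
    name: str = "reference"
    metadata: str = "seeded mask-overlap reference predictor"

    def predict(self, smiles: str, fp: Fingerprint) -> list[ActivityPrediction]:
        predictions: list[ActivityPrediction] = []
        for target_name, panel in self.targets:
            mask = _target_mask(self.seed, target_name, self.fingerprint_length)
            probability = len(fp.on_bits & mask) / len(mask)
            metrics = self.confusion.get(target_name) if self.confusion else None
            predictions.append(
                ActivityPrediction(
                    target_name, panel, probability,
                    color_code(probability, self.config), metrics,
                )
            )
        return predictions


def reference_predict(
    fp: Fingerprint,
    predictor_seed: int,
    targets: Sequence[str] | Sequence[tuple[str, str]],
    config: EngineConfig | None = None,
) -> list[ActivityPrediction]:
    """Functional form of :class:`ReferencePredictor` for a bare target list."""
    named = [(t, "unassigned") if isinstance(t, str) else tuple(t) for t in targets]
    predictor = ReferencePredictor(
        seed=predictor_seed, targets=named,
        fingerprint_length=fp.length, config=config or EngineConfig(),
    )
    return predictor.predict("", fp)


def load_predictor_metadata(path: str | Path) -> dict[str, dict[str, float]]:
    """Read a ``target_name, panel, sensitivity, specificity`` TSV into
    pass-through confusion metrics keyed by target name."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    metrics: dict[str, dict[str, float]] = {}
    for row in frame.itertuples(index=False):
        metrics[str(row.target_name)] = {
            "sensitivity": float(row.sensitivity),
            "specificity": float(row.specificity),
        }
    return metrics


def get_predictor(config: EngineConfig) -> PredictorContract:
    """Resolve the predictor named in the configuration."""
    if config.predictor == "reference":
        return ReferencePredictor(
            seed=config.seed,
            fingerprint_length=config.fingerprint_length,
            config=config,
        )
    raise InvalidInputError(f"unknown predictor {config.predictor!r}")
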