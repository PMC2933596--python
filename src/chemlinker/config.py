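"""Engine configuration: thresholds, limits and backend selection.

All knobs live in one flat record that can be loaded from a plain
``key = value`` text file.  Defaults follow the published service
configuration: similarity threshold 0.85 on 166-key fingerprints, activity
colour cutoffs 0.7 (red) and 0.6 (yellow), disease reporting floor 0.5.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from .errors import InvalidInputError

_TRUE = {"1", "true", "yes", "on"}
_FALSE = {"0", "false", "no", "off"}


@dataclass(frozen=True)
class EngineConfig:
    """Tunable parameters for one engine instance.

    similarity_threshold:
        Minimum Tanimoto for a compound to count as similar (default 0.85).
    strict_threshold:
        When on, require similarity strictly above the threshold; off by
        default so exact matches (the query itself in the store at 1.0) are
        representable.
    red_threshold / yellow_threshold:
        Activity-probability colour cutoffs: red at p >= red_threshold,
        yellow at yellow_threshold <= p < red_threshold, grey below.
    disease_min_score:
        Minimum gene-disease association score for a disease to be reported.
    """

    similarity_threshold: float = 0.85
    strict_threshold: bool = False
    red_threshold: float = 0.7
    yellow_threshold: float = 0.6
    disease_min_score: float = 0.5
    fingerprint_length: int = 166
    max_hits_per_section: int = 100
    k_3d: int = 10
    predictor: str = "reference"
    fingerprint_backend: str = "fixture-hash"
    empty_similarity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.similarity_threshold <= 1.0):
            raise InvalidInputError(
                f"similarity_threshold must be in (0, 1], got {self.similarity_threshold}"
            )
        if not (0.0 < self.yellow_threshold <= self.red_threshold <= 1.0):
            raise InvalidInputError(
                "colour thresholds must satisfy 0 < yellow <= red <= 1, got "
                f"yellow={self.yellow_threshold}, red={self.red_threshold}"
            )
        if self.fingerprint_length <= 0:
            raise InvalidInputError("fingerprint_length must be positive")
        if self.max_hits_per_section <= 0:
            raise InvalidInputError("max_hits_per_section must be positive")
        if self.k_3d <= 0:
            raise InvalidInputError("k_3d must be positive")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, object]:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path, **overrides: object) -> "EngineConfig":
        """Read a flat ``key = value`` file; later keys win, kwargs win over file."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        values: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise InvalidInputError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise InvalidInputError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = _coerce(fields[key].type, value, f"{path}:{lineno}")
        values.update(overrides)
        return cls(**values)  # type: ignore[arg-type]


def _coerce(annotation: object, value: str, where: str) -> object:
    ann = str(annotation)
    if "bool" in ann:
        low = value.lower()
        if low in _TRUE:
            return True
        if low in _FALSE:
            return False
        raise InvalidInputError(f"{where}: expected a boolean, got {value!r}")
    if "int" in ann:
        try:
            return int(value)
        except ValueError as exc:
            raise InvalidInputError(f"{where}: expected an integer, got {value!r}") from exc
    if "float" in ann:
        try:
            return float(value)
        except ValueError as exc:
            raise InvalidInputError(f"{where}: expected a number, got {value!r}") from exc
    return value
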