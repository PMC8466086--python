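"""Scoring tables and weight profiles for the suitability model.

The model rates every mapped geological unit on an ordinal 1-4 scale
(4 = most favourable) for up to five palaeoenvironmental factors:

* ``L`` — substrate suitability for bioturbation (loose substrates),
* ``H`` — substrate suitability for bioerosion (lithified hardgrounds),
* ``E`` — kinetic energy regime (low energy preserves traces),
* ``S`` — sedimentation rate (slow accumulation gives organisms time),
* ``K`` — surficial cover (4 = uncovered bedrock, 1 = fully concealed).

Bedrock units carry ``L, H, E, S``; surficial units carry only ``K``.
The water-table factor ``W`` is not tabulated per unit: it is derived
from elevation relative to the palaeolake shoreline (see
:class:`WaterScoreRule` and :func:`ichno.factor_layers.water_score_raster`).

Two weight presets are shipped because the published aggregation
formulas and the published weight table disagree for the bioturbation
and bioerosion profiles (0.4/0.2/0.3/0.1 and 0.4/0.1/0.3/0.2 versus
0.5/0.1/0.2/0.2 for both).  The ``equations`` preset is the default;
``table5`` selects the tabulated alternative.  Both agree on the
biostratification profile.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

logger = logging.getLogger(__name__)

#: Ordinal factor symbols; W is elevation-derived, not catalogued per unit.
FACTORS = ("L", "H", "E", "S", "W", "K")

#: The three ichnofossil-type profiles: A bioturbation, B bioerosion,
#: C biostratification.
PROFILES = ("A", "B", "C")

BEDROCK_FACTORS = ("L", "H", "E", "S")

_VALID_SCORES = frozenset({1, 2, 3, 4})


class CatalogueError(ValueError):
    """Malformed catalogue entry or configuration."""


class LookupError_(KeyError):
    """Unknown unit or factor not applicable to the unit's category."""


def _normalize_name(name: str) -> str:
    """Trim and collapse internal whitespace; matching is otherwise exact."""
    return re.sub(r"\s+", " ", name.strip())


@dataclass(frozen=True)
class UnitScores:
    """Ordinal suitability scores for one geological unit.

    Bedrock units must define L, H, E, S and no K; surficial units
    define only K.
    """

    unit_name: str
    category: str  # "bedrock" | "surficial"
    scores: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in ("bedrock", "surficial"):
            raise CatalogueError(
                f"unit {self.unit_name!r}: category must be 'bedrock' or "
                f"'surficial', got {self.category!r}"
            )
        expected = set(BEDROCK_FACTORS) if self.category == "bedrock" else {"K"}
        got = set(self.scores)
        if got != expected:
            raise CatalogueError(
                f"unit {self.unit_name!r} ({self.category}): expected factors "
                f"{sorted(expected)}, got {sorted(got)}"
            )
        for factor, value in self.scores.items():
            if not isinstance(value, int) or value not in _VALID_SCORES:
                raise CatalogueError(
                    f"unit {self.unit_name!r}, factor {factor}: score must be "
                    f"an integer in 1..4, got {value!r}"
                )


@dataclass(frozen=True)
class WaterScoreRule:
    """Elevation threshold scoring for the past water-table factor W.

    Cells strictly below ``shoreline_elevation`` (the most elevated
    position of the palaeolake shoreline, extended to -2,200 m to take
    in the inlet-valley channel) receive ``high_score``; cells at or
    above it receive ``low_score``.
    """

    shoreline_elevation: float = -2200.0
    high_score: int = 4
    low_score: int = 1

    def __post_init__(self) -> None:
        for name in ("high_score", "low_score"):
            v = getattr(self, name)
            if v not in _VALID_SCORES:
                raise CatalogueError(f"water rule {name} must be in 1..4, got {v!r}")
        if not self.high_score > self.low_score:
            raise CatalogueError(
                "water rule requires high_score > low_score, got "
                f"{self.high_score} <= {self.low_score}"
            )


@dataclass(frozen=True)
class WeightProfile:
    """Non-negative factor weights for one ichnofossil type; sum to 1."""

    profile_name: str
    wL: float = 0.0
    wH: float = 0.0
    wE: float = 0.0
    wS: float = 0.0
    wW: float = 0.0

    _SUM_TOL = 1e-9

    def __post_init__(self) -> None:
        if self.profile_name not in PROFILES:
            raise CatalogueError(
                f"profile name must be one of {PROFILES}, got {self.profile_name!r}"
            )
        weights = self.as_dict()
        if any(w < 0 for w in weights.values()):
            raise CatalogueError(f"profile {self.profile_name}: negative weight")
        total = sum(weights.values())
        if abs(total - 1.0) > self._SUM_TOL:
            raise CatalogueError(
                f"profile {self.profile_name}: weights sum to {total!r}, expected 1"
            )

    def as_dict(self) -> dict[str, float]:
        return {
            "L": self.wL,
            "H": self.wH,
            "E": self.wE,
            "S": self.wS,
            "W": self.wW,
        }

    @property
    def required_factors(self) -> tuple[str, ...]:
        """Factors with a strictly positive weight (zero weights are omitted)."""
        return tuple(f for f, w in self.as_dict().items() if w > 0)


# Default catalogue: 15 bedrock + 6 surficial units with their ordinal
# scores (L, H, E, S) / (K).
_BEDROCK_DEFAULTS: dict[str, tuple[int, int, int, int]] = {
    "Crater floor fractured 1": (4, 2, 4, 4),
    "Crater floor fractured 2": (4, 2, 3, 3),
    "Crater floor fractured rough": (4, 2, 4, 4),
    "Margin fractured": (4, 2, 3, 2),
    "Crater rim blocky": (1, 4, 2, 4),
    "Crater rim breccia": (1, 4, 1, 4),
    "Crater rim layered": (1, 4, 2, 4),
    "Crater rim rough": (1, 4, 2, 4),
    "Neretva Vallis layered": (4, 1, 1, 3),
    "Nili Planum fractured": (1, 4, 2, 4),
    "Delta blocky": (4, 1, 2, 1),
    "Delta layered rough": (4, 1, 4, 4),
    "Delta thickly layered": (4, 1, 4, 4),
    "Delta thinly layered": (4, 1, 4, 4),
    "Delta truncated curvilinear layered": (4, 1, 3, 3),
}

_SURFICIAL_DEFAULTS: dict[str, int] = {
    "Aeolian bedforms, large": 1,
    "Aeolian bedforms, small": 2,
    "Minor Cover Units": 2,
    "Moderate Cover Units": 1,
    "Talus": 3,
    "Undifferentiated smooth": 2,
}

# Weight presets (L, H, E, S, W).  "equations" are the operational
# formulas printed with the results; "table5" is the tabulated set.
_WEIGHT_PRESETS: dict[str, dict[str, tuple[float, float, float, float, float]]] = {
    "equations": {
        "A": (0.4, 0.0, 0.2, 0.3, 0.1),
        "B": (0.0, 0.4, 0.1, 0.3, 0.2),
        "C": (0.0, 0.0, 0.1, 0.4, 0.5),
    },
    "table5": {
        "A": (0.5, 0.0, 0.1, 0.2, 0.2),
        "B": (0.0, 0.5, 0.1, 0.2, 0.2),
        "C": (0.0, 0.0, 0.1, 0.4, 0.5),
    },
}


@dataclass(frozen=True)
class ScoreCatalogue:
    """Mapping of unit name to :class:`UnitScores` with validated lookups."""

    entries: Mapping[str, UnitScores]

    def __contains__(self, unit_name: str) -> bool:
        return _normalize_name(unit_name) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def unit(self, unit_name: str) -> UnitScores:
        key = _normalize_name(unit_name)
        try:
            return self.entries[key]
        except KeyError:
            raise LookupError_(f"unknown geological unit {unit_name!r}") from None

    def units(self, category: str | None = None) -> list[str]:
        return [
            name
            for name, entry in self.entries.items()
            if category is None or entry.category == category
        ]

    def to_config(self) -> dict:
        """Serializable form accepted back by :func:`load_catalogue`."""
        return {
            "units": [
                {
                    "name": entry.unit_name,
                    "category": entry.category,
                    "scores": dict(entry.scores),
                }
                for entry in self.entries.values()
            ]
        }


def lookup_score(catalogue: ScoreCatalogue, unit_name: str, factor: str) -> int:
    """Return the ordinal score of ``factor`` for ``unit_name``.

    Raises a lookup error for unknown units and a "factor not
    applicable" error when a bedrock unit is asked for K or a
    surficial unit for L/H/E/S.
    """
    if factor not in ("L", "H", "E", "S", "K"):
        raise LookupError_(
            f"factor must be one of L, H, E, S, K, got {factor!r} "
            "(W is elevation-derived, not catalogued)"
        )
    entry = catalogue.unit(unit_name)
    if factor not in entry.scores:
        raise LookupError_(
            f"factor {factor} not applicable to {entry.category} unit "
            f"{entry.unit_name!r}"
        )
    return entry.scores[factor]


def _default_entries() -> dict[str, UnitScores]:
    entries: dict[str, UnitScores] = {}
    for name, (l, h, e, s) in _BEDROCK_DEFAULTS.items():
        entries[name] = UnitScores(
            name, "bedrock", {"L": l, "H": h, "E": e, "S": s}
        )
    for name, k in _SURFICIAL_DEFAULTS.items():
        entries[name] = UnitScores(name, "surficial", {"K": k})
    return entries


def _entry_from_config(item: Mapping) -> UnitScores:
    try:
        name = _normalize_name(str(item["name"]))
        category = str(item["category"])
        scores = {str(k): v for k, v in dict(item["scores"]).items()}
    except (KeyError, TypeError) as exc:
        raise CatalogueError(f"malformed unit entry {item!r}: {exc}") from exc
    return UnitScores(name, category, scores)


def load_catalogue(config: Mapping | str | Path | None = None) -> ScoreCatalogue:
    """Build the unit-score catalogue, optionally overridden by config.

    Without ``config`` the embedded default table (15 bedrock + 6
    surficial units) is returned.  A config mapping (or path to a
    YAML/JSON document) with a top-level ``units`` list replaces or
    extends default entries by (whitespace-normalized, case-sensitive)
    unit name.
    """
    entries = _default_entries()
    doc = _load_config_document(config)
    if doc:
        for item in doc.get("units", []):
            entry = _entry_from_config(item)
            entries[entry.unit_name] = entry
    return ScoreCatalogue(entries)


def load_weight_profiles(
    config: Mapping | str | Path | None = None,
    source: str = "equations",
) -> dict[str, WeightProfile]:
    """Return the three weight profiles A, B, C.

    ``source`` selects a shipped preset (``equations`` or ``table5``);
    explicit weights in ``config`` (key ``weights`` with per-profile
    ``{L,H,E,S,W}`` mappings) override the preset and must sum to 1.
    """
    doc = _load_config_document(config)
    weights_cfg = doc.get("weights", {}) if doc else {}
    if isinstance(weights_cfg, Mapping) and "preset" in weights_cfg:
        source = str(weights_cfg["preset"])
    if source not in _WEIGHT_PRESETS:
        raise CatalogueError(
            f"unknown weight preset {source!r}; choose from "
            f"{sorted(_WEIGHT_PRESETS)}"
        )
    if source == "equations":
        logger.info(
            "Using 'equations' weight preset; the alternative 'table5' preset "
            "differs for profiles A and B (published formulas and weight "
            "table disagree)."
        )
    profiles: dict[str, WeightProfile] = {}
    for name in PROFILES:
        wl, wh, we, ws, ww = _WEIGHT_PRESETS[source][name]
        override = weights_cfg.get(name) if isinstance(weights_cfg, Mapping) else None
        if override is not None:
            wl = float(override.get("L", 0.0))
            wh = float(override.get("H", 0.0))
            we = float(override.get("E", 0.0))
            ws = float(override.get("S", 0.0))
            ww = float(override.get("W", 0.0))
        profiles[name] = WeightProfile(name, wL=wl, wH=wh, wE=we, wS=ws, wW=ww)
    return profiles


def load_water_rule(config: Mapping | str | Path | None = None) -> WaterScoreRule:
    """Water-table scoring rule, defaulting to the -2,200 m shoreline."""
    doc = _load_config_document(config)
    cfg = doc.get("water_rule", {}) if doc else {}
    return WaterScoreRule(
        shoreline_elevation=float(cfg.get("shoreline_elevation", -2200.0)),
        high_score=int(cfg.get("high_score", 4)),
        low_score=int(cfg.get("low_score", 1)),
    )


def _load_config_document(config: Mapping | str | Path | None) -> Mapping | None:
    if config is None:
        return None
    if isinstance(config, Mapping):
        return config
    path = Path(config)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
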