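"""Core record types flowing through the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .alphabets import WINDOW_WIDTH, validate_primary, validate_secondary

#: Where a sequence came from; used for bookkeeping and filtering.
PROVENANCES = ("expert", "generated", "scramble", "natural", "perturbed", "refined")

TRYPSIN = "trypsin"
CHYMOTRYPSIN = "chymotrypsin"
PROTEASES = (TRYPSIN, CHYMOTRYPSIN)


@dataclass
class ProteinDesign:
    """A designed mini-protein: primary sequence with optional aligned
    secondary-structure string over {L, E, H}."""

    id: str
    primary: str
    secondary: Optional[str] = None
    design_class: str = ""
    provenance: str = "expert"

    def __post_init__(self) -> None:
        validate_primary(self.primary)
        if not 1 <= len(self.primary) <= WINDOW_WIDTH:
            raise ValueError(
                f"{self.id}: length {len(self.primary)} outside [1, {WINDOW_WIDTH}]"
            )
        if self.secondary is not None:
            validate_secondary(self.secondary)
            if len(self.secondary) != len(self.primary):
                raise ValueError(f"{self.id}: primary/secondary length mismatch")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.primary)


@dataclass
class ProteaseAssay:
    """One protease measurement: EC50 (log concentration units) and the
    width of its credible interval."""

    protease: str
    ec50_obs: float
    ci_width: float = 0.0

    def __post_init__(self) -> None:
        if self.protease not in PROTEASES:
            raise ValueError(f"unknown protease {self.protease!r}")
        if self.ci_width < 0:
            raise ValueError("ci_width must be >= 0")


@dataclass
class StabilityRecord:
    """Observed and unfolded-state-predicted EC50s with derived stability
    scores.  ``score_p = ec50_obs - ec50_usm`` per protease; the combined
    score is the minimum of the two."""

    design_id: str
    ec50_obs: dict = field(default_factory=dict)   # protease -> float
    ec50_usm: dict = field(default_factory=dict)   # protease -> float

    @property
    def score_trypsin(self) -> float:
        return self.ec50_obs[TRYPSIN] - self.ec50_usm[TRYPSIN]

    @property
    def score_chymotrypsin(self) -> float:
        return self.ec50_obs[CHYMOTRYPSIN] - self.ec50_usm[CHYMOTRYPSIN]

    @property
    def score(self) -> float:
        return min(self.score_trypsin, self.score_chymotrypsin)
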