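"""Variable catalog: the ordered set of complication indicators plus the
terminal outcome (death).

The default catalog covers the 12 perioperative complications recorded after
heart-valve surgery — prolonged ICU stay, prolonged mechanical ventilation,
increased chest tube drainage, postoperative atrial fibrillation,
postoperative myocardial infarction, sternal wound infection, pericardial
tamponade, reoperation, secondary tracheal intubation, stroke, postoperative
renal failure and multiple organ dysfunction syndrome (MODS) — together with
30-day death. All variables are binary indicators (1 = event occurred).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

__all__ = ["VariableCatalog", "DEFAULT_COMPLICATIONS", "DEFAULT_CATALOG"]


@dataclass(frozen=True)
class VariableCatalog:
    """Ordered, named binary variables with exactly one terminal outcome.

    Parameters
    ----------
    names
        Unique, non-empty variable identifiers, in column order.
    outcome
        The single variable treated as the terminal outcome; must be one of
        ``names``. Downstream stages use it for the arc blacklist (no arcs
        out of the outcome) and for mortality summaries.
    """

    names: tuple[str, ...]
    outcome: str = "death"

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        object.__setattr__(self, "names", names)
        if len(names) == 0:
            raise ValidationError("catalog must contain at least one variable")
        if any(n == "" for n in names):
            raise ValidationError("variable names must be non-empty")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate variable names: {dupes}")
        if self.outcome not in names:
            raise ValidationError(
                f"outcome variable {self.outcome!r} not present in catalog"
            )

    @property
    def size(self) -> int:
        return len(self.names)

    @property
    def complications(self) -> tuple[str, ...]:
        """All non-outcome variables, in catalog order."""
        return tuple(n for n in self.names if n != self.outcome)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValidationError(f"unknown variable {name!r}") from None

    def __contains__(self, name: object) -> bool:
        return name in self.names


#: The 12 complications in registry-table order.
DEFAULT_COMPLICATIONS: tuple[str, ...] = (
    "increased_chest_tube_drainage",
    "prolonged_icu_stays",
    "prolonged_mechanical_ventilation",
    "postoperative_af",
    "postoperative_mi",
    "sternal_wound_infections",
    "pericardial_tamponade",
    "reoperation",
    "secondary_tracheal_intubation",
    "stroke",
    "postoperative_rf",
    "mods",
)

#: 12 complications + death, the standard 13-variable catalog.
DEFAULT_CATALOG = VariableCatalog(
    names=DEFAULT_COMPLICATIONS + ("death",), outcome="death"
)
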