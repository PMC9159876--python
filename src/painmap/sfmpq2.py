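"""Short-Form McGill Pain Questionnaire-2 (SF-MPQ-2) scoring.

The SF-MPQ-2 rates 22 pain-quality descriptors, each on an 11-point
numerical rating scale (0 = none, 10 = worst possible). Items group into
four subclasses — three sensory (continuous, intermittent, neuropathic
pain) and one affective — whose scores are the sums of their member items;
the total score is the sum of all 22 items (range 0–220).

Item names are accepted in a normalized form: matching is case-insensitive
and folds hyphens, slashes and spaces, and common long-form descriptors
("pain caused by light touch", "tingling or pins and needles") map onto
the short canonical identifiers used as table columns throughout the
package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

CONTINUOUS_ITEMS = (
    "throbbing", "cramping", "gnawing", "aching", "heavy", "tenderness",
)
INTERMITTENT_ITEMS = (
    "shooting", "stabbing", "sharp", "splitting", "electric_shock", "piercing",
)
NEUROPATHIC_ITEMS = (
    "hot_burning", "cold_freezing", "light_touch", "itching",
    "tingling_pins_needles", "numbness",
)
AFFECTIVE_ITEMS = (
    "tiring_exhausting", "sickening", "fearful", "punishing_cruel",
)

ITEM_NAMES: tuple[str, ...] = (
    CONTINUOUS_ITEMS + INTERMITTENT_ITEMS + NEUROPATHIC_ITEMS + AFFECTIVE_ITEMS
)

SUBCLASSES: dict[str, tuple[str, ...]] = {
    "continuous_pain": CONTINUOUS_ITEMS,
    "intermittent_pain": INTERMITTENT_ITEMS,
    "neuropathic_pain": NEUROPATHIC_ITEMS,
    "affective": AFFECTIVE_ITEMS,
}

SUBCLASS_NAMES: tuple[str, ...] = tuple(SUBCLASSES)

#: Human-readable names, used in report tables.
DISPLAY_NAMES: dict[str, str] = {
    "throbbing": "Throbbing pain",
    "cramping": "Cramping pain",
    "gnawing": "Gnawing pain",
    "aching": "Aching pain",
    "heavy": "Heavy pain",
    "tenderness": "Tenderness",
    "shooting": "Shooting pain",
    "stabbing": "Stabbing pain",
    "sharp": "Sharp pain",
    "splitting": "Splitting pain",
    "electric_shock": "Electric-shock pain",
    "piercing": "Piercing",
    "hot_burning": "Hot-burning pain",
    "cold_freezing": "Cold-freezing pain",
    "light_touch": "Pain caused by light touch",
    "itching": "Itching",
    "tingling_pins_needles": "Tingling or pins and needles",
    "numbness": "Numbness",
    "tiring_exhausting": "Tiring-exhausting",
    "sickening": "Sickening",
    "fearful": "Fearful",
    "punishing_cruel": "Punishing-cruel",
    "continuous_pain": "Continuous pain",
    "intermittent_pain": "Intermittent pain",
    "neuropathic_pain": "Neuropathic pain",
    "affective": "Affective",
}


def _fold(name: str) -> str:
    out = name.strip().lower()
    for ch in ("-", "/", " ", "–"):
        out = out.replace(ch, "_")
    while "__" in out:
        out = out.replace("__", "_")
    return out.strip("_")


def _build_aliases() -> dict[str, str]:
    aliases: dict[str, str] = {}
    for key in list(ITEM_NAMES) + list(SUBCLASS_NAMES):
        aliases[_fold(key)] = key
        aliases[_fold(DISPLAY_NAMES[key])] = key
    # long/short variants seen in tabular inputs
    extra = {
        "tender": "tenderness",
        "electric_shock_pain": "electric_shock",
        "pins_and_needles": "tingling_pins_needles",
        "tingling": "tingling_pins_needles",
    }
    for k, item in extra.items():
        aliases[_fold(k)] = item
    for item in ITEM_NAMES:
        aliases.setdefault(_fold(item + "_pain"), item)
    return aliases


_ALIASES = _build_aliases()


def canonical_item(name: str) -> str:
    """Resolve an item or subclass name to its canonical identifier.

    Raises ``KeyError`` for names that are not SF-MPQ-2 items/subclasses.
    """
    folded = _fold(str(name))
    if folded in _ALIASES:
        return _ALIASES[folded]
    raise KeyError(f"unknown SF-MPQ-2 item or subclass name: {name!r}")


def _check_score(name: str, value) -> int:
    v = float(value)
    if not v.is_integer():
        raise ValueError(f"item {name!r}: score {value!r} is not an integer")
    iv = int(v)
    if not 0 <= iv <= 10:
        raise ValueError(f"item {name!r}: score {iv} outside [0, 10]")
    return iv


@dataclass(frozen=True)
class SFMPQ2Scores:
    """Scored questionnaire: per-item scores plus subclass and total sums."""

    items: Mapping[str, int]

    def subclass(self, name: str) -> int:
        return sum(self.items[i] for i in SUBCLASSES[name])

    @property
    def continuous_pain(self) -> int:
        return self.subclass("continuous_pain")

    @property
    def intermittent_pain(self) -> int:
        return self.subclass("intermittent_pain")

    @property
    def neuropathic_pain(self) -> int:
        return self.subclass("neuropathic_pain")

    @property
    def affective(self) -> int:
        return self.subclass("affective")

    @property
    def total(self) -> int:
        return sum(self.items.values())


def score_sfmpq2(item_scores: Mapping[str, object]) -> SFMPQ2Scores:
    """Validate and score a complete set of 22 SF-MPQ-2 item ratings.

    ``item_scores`` must contain exactly the 22 canonical items (any accepted
    spelling); each value must be an integer in [0, 10]. Unknown, missing or
    duplicate names raise ``ValueError`` listing the offenders.
    """
    resolved: dict[str, int] = {}
    unknown: list[str] = []
    for name, value in item_scores.items():
        try:
            key = canonical_item(name)
        except KeyError:
            unknown.append(str(name))
            continue
        if key not in ITEM_NAMES:
            raise ValueError(f"{name!r} is a subclass, not an item score")
        if key in resolved:
            raise ValueError(f"duplicate item after name folding: {name!r}")
        resolved[key] = _check_score(key, value)
    if unknown:
        raise ValueError(f"unknown SF-MPQ-2 item names: {sorted(unknown)}")
    missing = [i for i in ITEM_NAMES if i not in resolved]
    if missing:
        raise ValueError(f"missing SF-MPQ-2 items: {missing}")
    return SFMPQ2Scores(items={i: resolved[i] for i in ITEM_NAMES})


@dataclass(frozen=True)
class PainAssessment:
    """Validated pain profile for one patient.

    ``pain_site_cm`` is the cranial–caudal distance from the top of the
    EMG electrode sheet (0 cm) to the patient-indicated most painful site.
    """

    pain_site_cm: float
    nrs: int
    scores: SFMPQ2Scores


def validate_patient(pain_site_cm: float, nrs, items: Mapping[str, object]) -> PainAssessment:
    """Validate one patient record against the study's inclusion rules.

    Accepts iff the pain-intensity NRS is an integer in [1, 10] (patients
    reporting NRS 0 do not meet the chronic-pain inclusion criterion), the
    pain site is a non-negative coordinate, and the 22 item scores are valid.
    """
    nrs_f = float(nrs)
    if not nrs_f.is_integer():
        raise ValueError(f"NRS must be an integer, got {nrs!r}")
    nrs_i = int(nrs_f)
    if nrs_i < 1:
        raise ValueError(
            f"NRS={nrs_i} violates the inclusion criterion (pain intensity >= 1)"
        )
    if nrs_i > 10:
        raise ValueError(f"NRS={nrs_i} outside the 0-10 rating scale")
    site = float(pain_site_cm)
    if not site >= 0:
        raise ValueError(f"pain_site_cm={site} must be >= 0 (cm from sheet top)")
    return PainAssessment(pain_site_cm=site, nrs=nrs_i, scores=score_sfmpq2(items))
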