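"""Exposome-score construction.

The exposome score (ES) is a cumulative measure of environmental risk for
psychopathology.  Ten binary exposures — winter season of birth, obstetric
complications, advanced paternal age, non-right-handedness, four childhood
trauma screens (emotional neglect, emotional abuse, bullying, sexual abuse),
problematic cannabis use and urban upbringing — are each weighted by the
natural-log odds ratio reported in meta-analyses of their association with
psychotic disorders.  A respondent's ES is the sum of the weights of the
exposures they report, divided by the number of exposure components.

This module turns raw survey answers into binary exposure states
(:func:`binarize_exposures`) and computes the weighted score
(:func:`compute_es`).  The weight table ships as a versioned JSON resource
and is validated against the published two-decimal log-odds on load.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping

import pandas as pd

__all__ = [
    "ExposureState",
    "PaternalTier",
    "WeightTable",
    "ExposureProfile",
    "ESResult",
    "COMPONENTS",
    "TRAUMA_COMPONENTS",
    "N_CPQ_ITEMS",
    "log_odds_weight",
    "load_weight_table",
    "binarize_exposures",
    "compute_es",
    "score_cohort",
]

ExposureState = Literal["present", "absent", "missing"]
PaternalTier = Literal["none", "35-54", ">=55", "missing"]
DenominatorPolicy = Literal["fixed_total", "per_respondent_recorded"]

#: The ten scoreable exposure components, in canonical order.
COMPONENTS: tuple[str, ...] = (
    "winter_birth",
    "obstetric_complications",
    "advanced_paternal_age",
    "non_right_handedness",
    "emotional_neglect",
    "emotional_abuse",
    "bullying",
    "sexual_abuse",
    "cannabis_use",
    "urban_upbringing",
)

TRAUMA_COMPONENTS = ("emotional_neglect", "emotional_abuse", "bullying", "sexual_abuse")

#: Number of cannabis-problem screen items; endorsing any one marks the exposure.
N_CPQ_ITEMS = 11

WINTER_MONTHS = frozenset({12, 1, 2})

MONTH_NAMES = {
    name.lower(): i + 1
    for i, name in enumerate(
        ["January", "February", "March", "April", "May", "June",
         "July", "August", "September", "October", "November", "December"]
    )
}

RESIDENCE_LEVELS = ("rural", "city_le_100k", "city_200k_500k", "city_gt_500k")

_YES = frozenset({"yes", "y", "1", "true"})
_NO = frozenset({"no", "n", "0", "false"})
_DONT_KNOW = frozenset({"dont_know", "don't know", "i don't know", "dk", "unknown"})


class ExposomeError(ValueError):
    """Raised on invalid exposure inputs or undefined scores."""


def log_odds_weight(odds_ratio: float) -> float:
    """Natural-log weight of an exposure given its meta-analytic odds ratio.

    Raises :class:`ExposomeError` for non-positive odds ratios.
    """
    if not odds_ratio > 0:
        raise ExposomeError(f"odds ratio must be positive, got {odds_ratio!r}")
    return math.log(odds_ratio)


@dataclass(frozen=True)
class WeightTable:
    """Odds ratios and log-odds weights for the ten exposure components.

    ``log_odds`` are computed as ln(OR) at full precision; on load they are
    checked to round to the published two-decimal values (weight fidelity).
    Advanced paternal age carries two mutually exclusive tier weights
    (father aged 35–54 vs >= 55 at the respondent's birth).
    """

    odds_ratios: Mapping[str, float]
    log_odds: Mapping[str, float]
    paternal_tiers: Mapping[str, float]  # tier -> log-odds

    def __post_init__(self) -> None:
        if set(self.odds_ratios) != set(COMPONENTS):
            raise ExposomeError(
                "weight table must cover exactly the 10 exposome components"
            )

    def weight(self, component: str, paternal_tier: PaternalTier = "none") -> float:
        if component == "advanced_paternal_age":
            if paternal_tier not in self.paternal_tiers:
                raise ExposomeError(
                    f"paternal tier {paternal_tier!r} has no weight entry"
                )
            return self.paternal_tiers[paternal_tier]
        return self.log_odds[component]

    @property
    def max_score_fixed(self) -> dict[str, float]:
        """Maximum fixed-denominator score per paternal tier (all present)."""
        base = sum(v for k, v in self.log_odds.items() if k != "advanced_paternal_age")
        return {
            tier: (base + w) / len(COMPONENTS)
            for tier, w in self.paternal_tiers.items()
        }


def load_weight_table(path: str | None = None, *, check_fidelity: bool = True) -> WeightTable:
    """Load the packaged (or a user-supplied) exposure weight table.

    With ``check_fidelity`` every ln(OR) must agree with the published
    two-decimal log-odds to within 0.005.
    """
    if path is None:
        raw = json.loads(
            resources.files("exponet.data").joinpath("exposure_weights.json").read_text()
        )
    else:
        with open(path) as fh:
            raw = json.load(fh)

    odds: dict[str, float] = {}
    logw: dict[str, float] = {}
    for entry in raw["components"]:
        cid = entry["id"]
        lo = log_odds_weight(entry["odds_ratio"])
        if check_fidelity and abs(lo - entry["printed_log_odds"]) > 0.005:
            raise ExposomeError(
                f"component {cid}: ln({entry['odds_ratio']}) = {lo:.4f} does not "
                f"round to printed log-odds {entry['printed_log_odds']}"
            )
        odds[cid] = entry["odds_ratio"]
        logw[cid] = lo
    tiers: dict[str, float] = {}
    for entry in raw["paternal_age_tiers"]:
        lo = log_odds_weight(entry["odds_ratio"])
        if check_fidelity and abs(lo - entry["printed_log_odds"]) > 0.005:
            raise ExposomeError(
                f"paternal tier {entry['tier']}: log-odds fidelity check failed"
            )
        tiers[entry["tier"]] = lo
    return WeightTable(odds_ratios=odds, log_odds=logw, paternal_tiers=tiers)


@dataclass
class ExposureProfile:
    """Binary present/absent/missing state of the ten components for one respondent."""

    states: dict[str, ExposureState]
    paternal_tier: PaternalTier = "none"

    def __post_init__(self) -> None:
        if set(self.states) != set(COMPONENTS):
            raise ExposomeError("profile must contain exactly the 10 components")
        apa = self.states["advanced_paternal_age"]
        tier_ok = {
            "present": self.paternal_tier in ("35-54", ">=55"),
            "absent": self.paternal_tier == "none",
            "missing": self.paternal_tier == "missing",
        }[apa]
        if not tier_ok:
            raise ExposomeError(
                f"paternal tier {self.paternal_tier!r} inconsistent with "
                f"advanced_paternal_age state {apa!r}"
            )

    @property
    def n_recorded(self) -> int:
        return sum(1 for s in self.states.values() if s != "missing")


@dataclass
class ESResult:
    """Computed exposome score with its per-component decomposition."""

    score: float
    n_recorded: int
    component_contributions: dict[str, float] = field(repr=False)


# --- raw-answer parsing helpers -------------------------------------------


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def _parse_yesno(value, *, allow_dont_know: bool, field_name: str) -> str:
    """Normalize a yes/no(/don't-know) answer; returns 'yes' | 'no' | 'missing'."""
    if _is_missing(value):
        return "missing"
    text = str(value).strip().lower()
    if text in _YES:
        return "yes"
    if text in _NO:
        return "no"
    if allow_dont_know and text in _DONT_KNOW:
        return "missing"
    raise ExposomeError(f"unparseable answer {value!r} for field {field_name!r}")


def _parse_month(value) -> int | None:
    if _is_missing(value):
        return None
    if isinstance(value, str) and value.strip().lower() in MONTH_NAMES:
        return MONTH_NAMES[value.strip().lower()]
    try:
        month = int(float(value))
    except (TypeError, ValueError):
        raise ExposomeError(f"unparseable month {value!r}") from None
    if not 1 <= month <= 12:
        raise ExposomeError(f"month out of range: {value!r}")
    return month


def binarize_exposures(record: Mapping) -> ExposureProfile:
    """Binarize one respondent's raw survey answers into an exposure profile.

    Expected raw fields: ``month`` (1–12 or an English month name),
    ``oc_csection`` / ``oc_low_weight`` / ``oc_preterm`` (yes/no/don't-know),
    ``paternal_age`` (years), ``handedness`` (right/left/mixed),
    the four trauma screens (yes/no), ``cpq_01``..``cpq_11`` (yes/no) and
    ``residence`` (rural or one of three city-size categories).

    Rules: winter birth = December–February; obstetric complications are
    present if any of the three items is "yes", missing if none is "yes"
    and at least one is "don't know"; a trauma component is present when
    its screen item is affirmed; cannabis use is present when at least one
    of the 11 problem items is affirmed; handedness counts left and mixed
    together as non-right; any non-rural residence counts as urban.
    """
    states: dict[str, ExposureState] = {}

    month = _parse_month(record.get("month"))
    if month is None:
        states["winter_birth"] = "missing"
    else:
        states["winter_birth"] = "present" if month in WINTER_MONTHS else "absent"

    oc_items = [
        _parse_yesno(record.get(f), allow_dont_know=True, field_name=f)
        for f in ("oc_csection", "oc_low_weight", "oc_preterm")
    ]
    if "yes" in oc_items:
        states["obstetric_complications"] = "present"
    elif "missing" in oc_items:
        # an unresolved "don't know" leaves the exposure undetermined
        states["obstetric_complications"] = "missing"
    else:
        states["obstetric_complications"] = "absent"

    pat_age = record.get("paternal_age")
    if _is_missing(pat_age):
        states["advanced_paternal_age"] = "missing"
        tier: PaternalTier = "missing"
    else:
        age = float(pat_age)
        if age >= 55:
            states["advanced_paternal_age"], tier = "present", ">=55"
        elif age >= 35:
            states["advanced_paternal_age"], tier = "present", "35-54"
        else:
            states["advanced_paternal_age"], tier = "absent", "none"

    hand = record.get("handedness")
    if _is_missing(hand):
        states["non_right_handedness"] = "missing"
    else:
        hand = str(hand).strip().lower()
        if hand not in ("right", "left", "mixed"):
            raise ExposomeError(f"unparseable handedness {hand!r}")
        states["non_right_handedness"] = "absent" if hand == "right" else "present"

    for comp in TRAUMA_COMPONENTS:
        ans = _parse_yesno(record.get(comp), allow_dont_know=False, field_name=comp)
        states[comp] = {"yes": "present", "no": "absent", "missing": "missing"}[ans]

    cpq = [
        _parse_yesno(record.get(f"cpq_{i:02d}"), allow_dont_know=False,
                     field_name=f"cpq_{i:02d}")
        for i in range(1, N_CPQ_ITEMS + 1)
    ]
    if "yes" in cpq:
        states["cannabis_use"] = "present"
    elif all(a == "missing" for a in cpq):
        states["cannabis_use"] = "missing"
    else:
        states["cannabis_use"] = "absent"

    res = record.get("residence")
    if _is_missing(res):
        states["urban_upbringing"] = "missing"
    else:
        res = str(res).strip().lower()
        if res not in RESIDENCE_LEVELS:
            raise ExposomeError(f"unparseable residence level {res!r}")
        states["urban_upbringing"] = "absent" if res == "rural" else "present"

    return ExposureProfile(states=states, paternal_tier=tier)


def compute_es(
    profile: ExposureProfile,
    weights: WeightTable,
    denominator_policy: DenominatorPolicy = "fixed_total",
) -> ESResult:
    """Weighted exposome score of one respondent.

    Present components contribute their log-odds weight (the paternal-age
    component contributes its tier weight); absent and missing components
    contribute 0.  Under ``fixed_total`` the sum is divided by 10; under
    ``per_respondent_recorded`` it is divided by the number of non-missing
    components (undefined when all ten are missing).
    """
    contributions: dict[str, float] = {}
    for comp in COMPONENTS:
        state = profile.states[comp]
        if state == "present":
            contributions[comp] = weights.weight(comp, profile.paternal_tier)
        else:
            contributions[comp] = 0.0

    if denominator_policy == "fixed_total":
        denom = len(COMPONENTS)
    elif denominator_policy == "per_respondent_recorded":
        denom = profile.n_recorded
        if denom == 0:
            raise ExposomeError(
                "score undefined: all components missing under "
                "per_respondent_recorded policy"
            )
    else:
        raise ExposomeError(f"unknown denominator policy {denominator_policy!r}")

    return ESResult(
        score=sum(contributions.values()) / denom,
        n_recorded=profile.n_recorded,
        component_contributions=contributions,
    )


def score_cohort(
    cohort: pd.DataFrame,
    weights: WeightTable | None = None,
    denominator_policy: DenominatorPolicy = "fixed_total",
) -> pd.DataFrame:
    """Score every respondent of a raw cohort table.

    Returns a frame with ``respondent_id``, ``es`` (the score),
    ``n_recorded`` and one contribution column per component.
    """
    if weights is None:
        weights = load_weight_table()
    rows = []
    for idx, rec in enumerate(cohort.to_dict("records")):
        profile = binarize_exposures(rec)
        result = compute_es(profile, weights, denominator_policy)
        row = {
            "respondent_id": rec.get("respondent_id", idx),
            "es": result.score,
            "n_recorded": result.n_recorded,
        }
        row.update({f"contrib_{c}": v for c, v in result.component_contributions.items()})
        rows.append(row)
    return pd.DataFrame(rows)
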