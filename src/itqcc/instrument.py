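"""ITQ/ITQ-CC instrument model and the ICD-11 PTSD/CPTSD diagnostic algorithm.

The International Trauma Questionnaire (ITQ) is an 18-item self-report measure
of ICD-11 posttraumatic stress disorder (PTSD) and complex PTSD (CPTSD).  Six
items measure the three PTSD symptom clusters (re-experiencing in the here and
now, avoidance, sense of threat; two items per cluster), six measure the three
"disturbances in self-organization" (DSO) clusters (affective dysregulation,
negative self-concept, disturbed relationships), and three functional
impairment items accompany each scale.  Items are rated on a five-point Likert
scale (0 = "Not at all" ... 4 = "Extremely"); a score of 2 ("Moderately") or
higher marks the symptom as present.

The clinical-check extension (ITQ-CC) attaches a yes/no follow-up question to
each item.  The check is presented only when the item is endorsed (score >= 2);
answering "no" removes the endorsement.  Two items — emotional numbing and
feeling cut off from others — trialled two alternative checks; the final
instrument retains, per the pre-set rule, whichever variant produced the
larger decrease in endorsement.

Diagnostic rules implemented here:

* a symptom cluster is met when at least one of its two items is endorsed;
* functional impairment is met when at least one of the scale's three
  impairment items is endorsed;
* PTSD requires all three PTSD clusters plus PTSD impairment, *without* the
  full DSO pattern;
* CPTSD requires all six clusters plus both impairment blocks;
* the two labels are mutually exclusive; a DSO-only presentation is "none"
  (no stand-alone DSO disorder exists in ICD-11).

Check gating can only remove endorsements, so every item-, cluster- and
CPTSD-level predicate is monotone non-increasing under gating.  The PTSD label
is the one exception: a respondent meeting CPTSD without checks whose DSO
endorsements fail their checks migrates CPTSD -> PTSD, so PTSD counts may rise.
"""

from __future__ import annotations

import enum
import numbers
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

__all__ = [
    "Scale",
    "Cluster",
    "ItemId",
    "ITEMS",
    "SYMPTOM_ITEMS",
    "SYMPTOM_CLUSTERS",
    "CheckAnswer",
    "CheckResponse",
    "ItqRecord",
    "ScoringMode",
    "DiagnosisResult",
    "DUAL_VARIANT_ITEMS",
    "DEFAULT_VARIANT_CHOICE",
    "N_EXPOSURE_EVENTS",
    "validate_likert",
    "symptom_present",
    "gated_symptom_present",
    "cluster_met",
    "impairment_met",
    "diagnose",
    "select_check_variant",
]

#: Number of binary lifetime trauma-exposure indicators (ITEM inventory).
N_EXPOSURE_EVENTS = 21


class InvalidInputError(ValueError):
    """Raised for scores, clusters or arguments outside the instrument's domain."""


class InconsistentRecordError(ValueError):
    """Raised when a record violates the check-gating invariant.

    Gated scoring requires a check answer for every endorsed item; an endorsed
    item whose check was never presented cannot be scored in gated mode.
    """


class Scale(str, enum.Enum):
    PTSD = "ptsd"
    DSO = "dso"


class Cluster(str, enum.Enum):
    """Symptom clusters plus the two functional-impairment blocks."""

    RE = "re"    # re-experiencing in the here and now
    AV = "av"    # avoidance
    TH = "th"    # sense of threat
    AD = "ad"    # affective dysregulation
    NSC = "nsc"  # negative self-concept
    DR = "dr"    # disturbed relationships
    PTSD_FI = "ptsd_fi"
    DSO_FI = "dso_fi"

    @property
    def scale(self) -> Scale:
        return Scale.PTSD if self in (Cluster.RE, Cluster.AV, Cluster.TH, Cluster.PTSD_FI) else Scale.DSO

    @property
    def is_impairment(self) -> bool:
        return self in (Cluster.PTSD_FI, Cluster.DSO_FI)


#: The six symptom clusters, in instrument order (PTSD scale then DSO scale).
SYMPTOM_CLUSTERS = (Cluster.RE, Cluster.AV, Cluster.TH, Cluster.AD, Cluster.NSC, Cluster.DR)


@dataclass(frozen=True, order=True)
class ItemId:
    """One of the 18 ITQ items, addressed by cluster and within-cluster index."""

    cluster: Cluster
    index: int  # 1-based

    def __post_init__(self) -> None:
        n = 3 if self.cluster.is_impairment else 2
        if not 1 <= self.index <= n:
            raise InvalidInputError(
                f"cluster {self.cluster.value!r} has {n} items; index {self.index} is out of range"
            )

    @property
    def scale(self) -> Scale:
        return self.cluster.scale

    @property
    def column(self) -> str:
        """Canonical CSV column name, e.g. ``ptsd_re1`` or ``dso_fi3``."""
        if self.cluster.is_impairment:
            return f"{self.cluster.value}{self.index}"
        return f"{self.scale.value}_{self.cluster.value}{self.index}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.column


def _all_items() -> tuple[ItemId, ...]:
    items = []
    for cluster in (Cluster.RE, Cluster.AV, Cluster.TH):
        items += [ItemId(cluster, i) for i in (1, 2)]
    items += [ItemId(Cluster.PTSD_FI, i) for i in (1, 2, 3)]
    for cluster in (Cluster.AD, Cluster.NSC, Cluster.DR):
        items += [ItemId(cluster, i) for i in (1, 2)]
    items += [ItemId(Cluster.DSO_FI, i) for i in (1, 2, 3)]
    return tuple(items)


#: All 18 items in instrument order.
ITEMS: tuple[ItemId, ...] = _all_items()

#: The 12 symptom items (impairment blocks excluded).
SYMPTOM_ITEMS: tuple[ItemId, ...] = tuple(i for i in ITEMS if not i.cluster.is_impairment)

#: Human-readable symptom labels, keyed by column name (reporting only).
ITEM_LABELS: Mapping[str, str] = {
    "ptsd_re1": "Nightmares",
    "ptsd_re2": "Flashbacks",
    "ptsd_av1": "Internal avoidance",
    "ptsd_av2": "External avoidance",
    "ptsd_th1": "Hyperalert",
    "ptsd_th2": "Hyperarousal",
    "dso_ad1": "Difficulty calming down",
    "dso_ad2": "Numbing",
    "dso_nsc1": "Feel like a failure",
    "dso_nsc2": "Feel worthless",
    "dso_dr1": "Feel cut off from others",
    "dso_dr2": "Difficult close to others",
    "ptsd_fi": "Functional impairment (PTSD)",
    "dso_fi": "Functional impairment (DSO)",
}

#: Items for which two clinical-check variants were trialled:
#: emotional numbing (dso_ad2) and feeling cut off from others (dso_dr1).
DUAL_VARIANT_ITEMS: tuple[ItemId, ...] = (ItemId(Cluster.AD, 2), ItemId(Cluster.DR, 1))

#: Final-instrument variant choice under the largest-decrease rule:
#: variant 1 for numbing, variant 2 for feeling cut off.
DEFAULT_VARIANT_CHOICE: Mapping[ItemId, int] = {
    ItemId(Cluster.AD, 2): 1,
    ItemId(Cluster.DR, 1): 2,
}

#: Likert endorsement threshold: scores of 2 ("Moderately") or higher.
ENDORSEMENT_THRESHOLD = 2


def validate_likert(score: object) -> int:
    """Validate a Likert response; return it as ``int`` in 0..4."""
    if isinstance(score, bool) or not isinstance(score, numbers.Integral):
        raise InvalidInputError(f"Likert score must be an integer, got {score!r}")
    if not 0 <= score <= 4:
        raise InvalidInputError(f"Likert score must be in 0..4, got {int(score)}")
    return int(score)


class CheckAnswer(str, enum.Enum):
    YES = "yes"
    NO = "no"
    NOT_PRESENTED = "not_presented"


@dataclass(frozen=True)
class CheckResponse:
    """A yes/no clinical-check response for one item (and variant)."""

    item: ItemId
    answer: CheckAnswer
    variant: int = 1

    def __post_init__(self) -> None:
        if self.variant not in (1, 2):
            raise InvalidInputError(f"check variant must be 1 or 2, got {self.variant}")
        if self.variant == 2 and self.item not in DUAL_VARIANT_ITEMS:
            raise InvalidInputError(f"item {self.item} has no second check variant")


@dataclass(frozen=True)
class ScoringMode:
    """How a record is scored.

    Parameters
    ----------
    gated : bool
        ``False`` scores the plain ITQ; ``True`` applies the clinical checks
        (ITQ-CC), in which an endorsement only stands if its check was
        answered "yes".
    variant_choice : mapping
        Which trialled check variant to consult for the two dual-variant
        items.  The default is the final instrument's choice under the
        largest-decrease rule.
    lenient_missing : bool
        If ``True``, missing item scores are treated as 0 rather than
        invalidating the record.
    require_exposure : bool
        If ``True``, respondents reporting zero traumatic exposures are
        classified "none" regardless of item responses.  Off by default:
        published prevalence denominators include unexposed respondents.
    """

    gated: bool = False
    variant_choice: Mapping[ItemId, int] = field(default_factory=lambda: dict(DEFAULT_VARIANT_CHOICE))
    lenient_missing: bool = False
    require_exposure: bool = False

    def chosen_variant(self, item: ItemId) -> int:
        if item in DUAL_VARIANT_ITEMS:
            return self.variant_choice.get(item, DEFAULT_VARIANT_CHOICE[item])
        return 1


@dataclass
class ItqRecord:
    """One respondent: 18 Likert scores, check responses, trauma exposures.

    ``checks`` maps ``(item, variant)`` to a :class:`CheckAnswer`.  The gating
    invariant requires an answer other than ``NOT_PRESENTED`` exactly for items
    scored >= 2 (for every variant the item carries).
    """

    respondent_id: str
    items: Mapping[ItemId, Optional[int]]
    checks: Mapping[tuple[ItemId, int], CheckAnswer] = field(default_factory=dict)
    exposures: tuple[int, ...] = (0,) * N_EXPOSURE_EVENTS
    worst_event: Optional[int] = None
    time_since_event: Optional[str] = None

    def __post_init__(self) -> None:
        missing = [i for i in ITEMS if i not in self.items]
        if missing:
            raise InvalidInputError(
                f"record {self.respondent_id!r}: missing item columns {[str(i) for i in missing]}"
            )
        unknown = [i for i in self.items if i not in ITEMS]
        if unknown:
            raise InvalidInputError(f"record {self.respondent_id!r}: unknown items {unknown}")
        for item, score in self.items.items():
            if score is not None:
                validate_likert(score)
        if len(self.exposures) != N_EXPOSURE_EVENTS:
            raise InvalidInputError(
                f"record {self.respondent_id!r}: exposure vector must have "
                f"{N_EXPOSURE_EVENTS} entries, got {len(self.exposures)}"
            )
        if any(e not in (0, 1) for e in self.exposures):
            raise InvalidInputError(f"record {self.respondent_id!r}: exposures must be 0/1")
        if self.worst_event is not None and not 1 <= self.worst_event <= N_EXPOSURE_EVENTS:
            raise InvalidInputError(
                f"record {self.respondent_id!r}: worst_event must be in 1..{N_EXPOSURE_EVENTS}"
            )

    @property
    def exposure_count(self) -> int:
        return int(sum(self.exposures))

    def score(self, item: ItemId, mode: ScoringMode) -> int:
        raw = self.items[item]
        if raw is None:
            if mode.lenient_missing:
                return 0
            raise InvalidInputError(
                f"record {self.respondent_id!r}: item {item} is missing (strict mode)"
            )
        return raw

    def check_answer(self, item: ItemId, variant: int) -> CheckAnswer:
        return self.checks.get((item, variant), CheckAnswer.NOT_PRESENTED)

    def validate_gating(self, lenient_missing: bool = False) -> list[str]:
        """Return a list of gating-invariant violations (empty if consistent).

        A violation is an endorsed item (score >= 2) whose check is recorded as
        not presented, or a check answer recorded for an unendorsed item.
        """
        problems: list[str] = []
        for item in ITEMS:
            raw = self.items[item]
            score = 0 if (raw is None and lenient_missing) else raw
            if score is None:
                continue
            variants = (1, 2) if item in DUAL_VARIANT_ITEMS else (1,)
            for v in variants:
                ans = self.check_answer(item, v)
                if score >= ENDORSEMENT_THRESHOLD and ans is CheckAnswer.NOT_PRESENTED:
                    problems.append(f"item {item} scored {score} but check (variant {v}) not presented")
                if score < ENDORSEMENT_THRESHOLD and ans is not CheckAnswer.NOT_PRESENTED:
                    problems.append(f"item {item} scored {score} but has a check answer (variant {v})")
        return problems


@dataclass(frozen=True)
class DiagnosisResult:
    """Trichotomous classification with the per-cluster flags that produced it."""

    label: str  # "none" | "ptsd" | "cptsd"
    cluster_flags: Mapping[Cluster, bool]
    ptsd_impairment: bool
    dso_impairment: bool

    @property
    def ptsd_part(self) -> bool:
        f = self.cluster_flags
        return f[Cluster.RE] and f[Cluster.AV] and f[Cluster.TH] and self.ptsd_impairment

    @property
    def dso_part(self) -> bool:
        f = self.cluster_flags
        return f[Cluster.AD] and f[Cluster.NSC] and f[Cluster.DR] and self.dso_impairment

    @property
    def any_disorder(self) -> bool:
        return self.label in ("ptsd", "cptsd")


def symptom_present(score: object) -> bool:
    """Plain-ITQ endorsement rule: a response of 2 ("Moderately") or higher."""
    return validate_likert(score) >= ENDORSEMENT_THRESHOLD


def gated_symptom_present(record: ItqRecord, item: ItemId, mode: ScoringMode) -> bool:
    """Endorsement of one item under the given scoring mode.

    Ungated: score >= 2.  Gated: score >= 2 *and* the chosen check variant was
    answered "yes".  Gating never adds endorsements.
    """
    score = record.score(item, mode)
    if score < ENDORSEMENT_THRESHOLD:
        return False
    if not mode.gated:
        return True
    answer = record.check_answer(item, mode.chosen_variant(item))
    if answer is CheckAnswer.NOT_PRESENTED:
        raise InconsistentRecordError(
            f"record {record.respondent_id!r}: item {item} endorsed (score {score}) "
            f"but check variant {mode.chosen_variant(item)} was not presented"
        )
    return answer is CheckAnswer.YES


def _cluster_items(cluster: Cluster) -> tuple[ItemId, ...]:
    n = 3 if cluster.is_impairment else 2
    return tuple(ItemId(cluster, i) for i in range(1, n + 1))


def cluster_met(record: ItqRecord, cluster: Cluster, mode: ScoringMode) -> bool:
    """A symptom cluster is met when at least one of its two items is endorsed."""
    if not isinstance(cluster, Cluster) or cluster.is_impairment:
        raise InvalidInputError(f"not a symptom cluster: {cluster!r}")
    return any(gated_symptom_present(record, item, mode) for item in _cluster_items(cluster))


def impairment_met(record: ItqRecord, scale: Scale, mode: ScoringMode) -> bool:
    """Functional impairment: at least one of the scale's three items endorsed."""
    if not isinstance(scale, Scale):
        raise InvalidInputError(f"not a scale: {scale!r}")
    cluster = Cluster.PTSD_FI if scale is Scale.PTSD else Cluster.DSO_FI
    return any(gated_symptom_present(record, item, mode) for item in _cluster_items(cluster))


def diagnose(record: ItqRecord, mode: ScoringMode) -> DiagnosisResult:
    """Apply the ICD-11 diagnostic algorithm to one respondent.

    CPTSD requires the full PTSD pattern (re-experiencing, avoidance, sense of
    threat, PTSD impairment) *and* the full DSO pattern (affective
    dysregulation, negative self-concept, disturbed relationships, DSO
    impairment).  PTSD requires the PTSD pattern without the full DSO pattern.
    A DSO-only presentation is "none".
    """
    flags = {c: cluster_met(record, c, mode) for c in SYMPTOM_CLUSTERS}
    ptsd_fi = impairment_met(record, Scale.PTSD, mode)
    dso_fi = impairment_met(record, Scale.DSO, mode)
    if mode.require_exposure and record.exposure_count == 0:
        return DiagnosisResult("none", flags, ptsd_fi, dso_fi)
    ptsd_part = flags[Cluster.RE] and flags[Cluster.AV] and flags[Cluster.TH] and ptsd_fi
    dso_part = flags[Cluster.AD] and flags[Cluster.NSC] and flags[Cluster.DR] and dso_fi
    if ptsd_part and dso_part:
        label = "cptsd"
    elif ptsd_part:
        label = "ptsd"
    else:
        label = "none"
    return DiagnosisResult(label, flags, ptsd_fi, dso_fi)


def select_check_variant(decrease_by_variant: Mapping[int, float]) -> int:
    """Choose the check variant that produced the largest endorsement decrease.

    Ties break to the lowest variant id (the published rule never needed a
    tie-break; this keeps selection deterministic).
    """
    if not decrease_by_variant:
        raise InvalidInputError("no variants to select among")
    for v, d in decrease_by_variant.items():
        if d < 0:
            raise InvalidInputError(f"variant {v} has negative decrease {d}")
    best = max(decrease_by_variant, key=lambda v: (decrease_by_variant[v], -v))
    return best


def ungated_mode(base: ScoringMode | None = None) -> ScoringMode:
    """The plain-ITQ counterpart of a scoring mode."""
    return replace(base or ScoringMode(), gated=False)


def gated_mode(base: ScoringMode | None = None) -> ScoringMode:
    """The ITQ-CC counterpart of a scoring mode."""
    return replace(base or ScoringMode(), gated=True)
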