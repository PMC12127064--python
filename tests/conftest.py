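import pytest

from itqcc.instrument import (
    DUAL_VARIANT_ITEMS,
    ITEMS,
    CheckAnswer,
    ItemId,
    ItqRecord,
)

COLUMN_TO_ITEM = {item.column: item for item in ITEMS}


def make_record(scores=None, checks=None, exposures=None, rid="r0", autofill_checks="yes"):
    """Build an ItqRecord from sparse column->value dicts.

    ``scores`` maps column names (e.g. ``"ptsd_re1"``) to Likert values;
    unmentioned items default to 0.  ``checks`` maps a column name or a
    ``(column, variant)`` pair to ``"yes"``/``"no"``.  Endorsed items without
    an explicit check answer get ``autofill_checks`` (keeps the gating
    invariant satisfied without spelling out every check).
    """
    scores = dict(scores or {})
    items = {item: scores.get(item.column, 0) for item in ITEMS}
    explicit = {}
    for key, ans in (checks or {}).items():
        col, variant = key if isinstance(key, tuple) else (key, 1)
        explicit[(COLUMN_TO_ITEM[col], variant)] = CheckAnswer(ans)
    for item in ITEMS:
        if autofill_checks is not None and items[item] is not None and items[item] >= 2:
            variants = (1, 2) if item in DUAL_VARIANT_ITEMS else (1,)
            for v in variants:
                explicit.setdefault((item, v), CheckAnswer(autofill_checks))
    if exposures is None:
        exposures = (0,) * 21
    return ItqRecord(respondent_id=rid, items=items, checks=explicit, exposures=tuple(exposures))


def migration_record(rid="mig"):
    """A respondent meeting CPTSD ungated whose DSO checks all fail.

    Under gating the DSO side collapses while the PTSD side survives, so the
    label migrates CPTSD -> PTSD.
    """
    scores = {item.column: 3 for item in ITEMS}
    checks = {}
    for item in ITEMS:
        ans = "no" if item.scale.value == "dso" else "yes"
        checks[item.column] = ans
        if item in DUAL_VARIANT_ITEMS:
            checks[(item.column, 2)] = ans
    return make_record(scores, checks, rid=rid)


@pytest.fixture
def small_cohort_params():
    from itqcc import default_params

    return default_params(n=300, seed=42)
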