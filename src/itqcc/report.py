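"""Study report builders and the printed-table verification harness.

``build_report`` scores a cohort under both modes (plain ITQ and ITQ-CC) and
assembles the analysis tables: per-event trauma exposure, per-symptom and
per-cluster endorsement with and without checks, and the disorder-level
prevalence comparison.  Percentages are displayed to one decimal; relative
decreases are computed from those displayed percentages (a count-basis
variant is available); McNemar's Z is uncorrected at the symptom and cluster
level and continuity-corrected at the disorder level, mirroring the analysis
being reproduced.

``verify_table`` is the inverse tool: given a table of *printed* endorsement
counts and percentages, it recomputes every derived column (decrease counts,
relative decreases, Z statistics) and flags cells that disagree — e.g. a
decrease-count cell inconsistent with its own endorsement counts, or a
percentage that does not match count/total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .instrument import (
    DUAL_VARIANT_ITEMS,
    ITEM_LABELS,
    ITEMS,
    N_EXPOSURE_EVENTS,
    SYMPTOM_CLUSTERS,
    SYMPTOM_ITEMS,
    Cluster,
    ItemId,
    ItqRecord,
    Scale,
    ScoringMode,
    cluster_met,
    diagnose,
    gated_symptom_present,
    impairment_met,
)
from .stats import (
    NoDiscordanceError,
    PairedCounts,
    mcnemar_z,
    paired_discordant_counts,
    percentage_decrease,
    round_half_up,
)

__all__ = [
    "StudyReport",
    "build_report",
    "verify_table",
    "score_cohort",
    "frame_item_endorsed",
    "diagnose_frame",
]

_REPORT_COLUMNS = [
    "level", "label", "variant", "selected", "n_total",
    "n_without", "pct_without", "n_with", "pct_with",
    "decrease_n", "decrease_pct", "z", "p", "corrected",
]


@dataclass(frozen=True)
class StudyReport:
    """All analysis tables for one cohort."""

    n: int
    exposure_table: pd.DataFrame
    symptom_table: pd.DataFrame
    cluster_table: pd.DataFrame
    disorder_table: pd.DataFrame

    def tables(self) -> Mapping[str, pd.DataFrame]:
        return {
            "exposure": self.exposure_table,
            "symptoms": self.symptom_table,
            "clusters": self.cluster_table,
            "disorders": self.disorder_table,
        }


def _pct(count: int, total: int) -> float:
    return round_half_up(100.0 * count / total, 1)


def _row(
    level: str,
    label: str,
    before: np.ndarray,
    after: np.ndarray,
    corrected: bool,
    decrease_from_counts: bool,
    variant: int | None = None,
    selected: bool = True,
) -> dict:
    counts = paired_discordant_counts(before, after)
    n = counts.n
    pct_without = _pct(counts.n_without, n)
    pct_with = _pct(counts.n_with, n)
    decrease_n = counts.n_without - counts.n_with
    if counts.n_without == 0:
        dec = None
    elif decrease_from_counts:
        dec = round_half_up(100.0 * decrease_n / counts.n_without, 1)
    else:
        dec = round_half_up(percentage_decrease(pct_without, pct_with), 1)
    try:
        test = mcnemar_z(counts, corrected=corrected)
        z, p = round_half_up(test.z, 2), test.p
    except NoDiscordanceError:
        z, p = None, None
    return {
        "level": level, "label": label, "variant": variant, "selected": selected,
        "n_total": n, "n_without": counts.n_without, "pct_without": pct_without,
        "n_with": counts.n_with, "pct_with": pct_with,
        "decrease_n": decrease_n, "decrease_pct": dec,
        "z": z, "p": p, "corrected": corrected,
    }


def _item_endorsed(records: Sequence[ItqRecord], item: ItemId, mode: ScoringMode) -> np.ndarray:
    return np.array([gated_symptom_present(r, item, mode) for r in records], dtype=bool)


def score_cohort(records: Sequence[ItqRecord], base_mode: ScoringMode | None = None) -> pd.DataFrame:
    """Per-respondent diagnoses under both modes.

    Returns one row per respondent with the ungated and gated labels and the
    per-cluster flags that produced them.
    """
    base = base_mode or ScoringMode()
    ungated = replace(base, gated=False)
    gated = replace(base, gated=True)
    rows = []
    for rec in records:
        du = diagnose(rec, ungated)
        dg = diagnose(rec, gated)
        row = {
            "respondent_id": rec.respondent_id,
            "label_ungated": du.label,
            "label_gated": dg.label,
            "n_events": rec.exposure_count,
        }
        for c in SYMPTOM_CLUSTERS:
            row[f"{c.value}_ungated"] = du.cluster_flags[c]
            row[f"{c.value}_gated"] = dg.cluster_flags[c]
        row["ptsd_fi_ungated"], row["ptsd_fi_gated"] = du.ptsd_impairment, dg.ptsd_impairment
        row["dso_fi_ungated"], row["dso_fi_gated"] = du.dso_impairment, dg.dso_impairment
        rows.append(row)
    return pd.DataFrame(rows)


def _exposure_table(records: Sequence[ItqRecord]) -> pd.DataFrame:
    n = len(records)
    counts = np.sum([r.exposures for r in records], axis=0)
    rows = [
        {"event": f"item{j + 1:02d}", "n": int(counts[j]), "pct": _pct(int(counts[j]), n)}
        for j in range(N_EXPOSURE_EVENTS)
    ]
    any_count = sum(1 for r in records if r.exposure_count > 0)
    rows.append({"event": "any_event", "n": any_count, "pct": _pct(any_count, n)})
    mean_events = sum(r.exposure_count for r in records) / n
    rows.append({"event": "mean_events", "n": None, "pct": round_half_up(mean_events, 2)})
    return pd.DataFrame(rows)


def build_report(
    records: Sequence[ItqRecord],
    base_mode: ScoringMode | None = None,
    decrease_from_counts: bool = False,
) -> StudyReport:
    """Score a cohort under both modes and assemble all analysis tables.

    ``decrease_from_counts`` switches the relative-decrease column from the
    displayed-percentage basis (the reproduced convention) to raw counts.
    """
    if not records:
        raise ValueError("cannot report on an empty cohort")
    base = base_mode or ScoringMode()
    ungated = replace(base, gated=False)
    gated = replace(base, gated=True)
    n = len(records)

    # --- symptom table: 12 symptoms (dual-variant items once per variant) + 2 impairment blocks
    sym_rows = []
    for item in SYMPTOM_ITEMS:
        before = _item_endorsed(records, item, ungated)
        if item in DUAL_VARIANT_ITEMS:
            for v in (1, 2):
                mode_v = replace(gated, variant_choice={**dict(gated.variant_choice), item: v})
                after = _item_endorsed(records, item, mode_v)
                sym_rows.append(
                    _row("item", ITEM_LABELS[item.column], before, after, False,
                         decrease_from_counts, variant=v,
                         selected=(v == base.chosen_variant(item)))
                )
        else:
            after = _item_endorsed(records, item, gated)
            sym_rows.append(
                _row("item", ITEM_LABELS[item.column], before, after, False, decrease_from_counts)
            )
    for scale in (Scale.PTSD, Scale.DSO):
        key = "ptsd_fi" if scale is Scale.PTSD else "dso_fi"
        before = np.array([impairment_met(r, scale, ungated) for r in records])
        after = np.array([impairment_met(r, scale, gated) for r in records])
        sym_rows.append(_row("item", ITEM_LABELS[key], before, after, False, decrease_from_counts))
    symptom_table = pd.DataFrame(sym_rows, columns=_REPORT_COLUMNS)

    # --- cluster table: 6 clusters + the 2 impairment blocks
    clu_rows = []
    for cluster in SYMPTOM_CLUSTERS:
        before = np.array([cluster_met(r, cluster, ungated) for r in records])
        after = np.array([cluster_met(r, cluster, gated) for r in records])
        clu_rows.append(_row("cluster", cluster.value, before, after, False, decrease_from_counts))
    for scale, key in ((Scale.PTSD, "ptsd_fi"), (Scale.DSO, "dso_fi")):
        before = np.array([impairment_met(r, scale, ungated) for r in records])
        after = np.array([impairment_met(r, scale, gated) for r in records])
        clu_rows.append(_row("cluster", key, before, after, False, decrease_from_counts))
    cluster_table = pd.DataFrame(clu_rows, columns=_REPORT_COLUMNS)

    # --- disorder table (continuity-corrected tests)
    scored = score_cohort(records, base)
    dis_rows = []
    for label in ("ptsd", "cptsd"):
        before = (scored["label_ungated"] == label).to_numpy()
        after = (scored["label_gated"] == label).to_numpy()
        dis_rows.append(_row("disorder", label, before, after, True, decrease_from_counts))
    before = (scored["label_ungated"] != "none").to_numpy()
    after = (scored["label_gated"] != "none").to_numpy()
    dis_rows.append(_row("disorder", "either", before, after, True, decrease_from_counts))
    disorder_table = pd.DataFrame(dis_rows, columns=_REPORT_COLUMNS)

    return StudyReport(
        n=n,
        exposure_table=_exposure_table(records),
        symptom_table=symptom_table,
        cluster_table=cluster_table,
        disorder_table=disorder_table,
    )


# ---------------------------------------------------------------------------
# Vectorised scoring straight from a cohort frame
# ---------------------------------------------------------------------------

def frame_item_endorsed(cohort: pd.DataFrame, item: ItemId, mode: ScoringMode) -> np.ndarray:
    """Vectorised per-respondent endorsement of one item from a cohort frame.

    Equivalent to :func:`itqcc.instrument.gated_symptom_present` applied
    row-wise; used for large simulated cohorts where building record objects
    would dominate the runtime.
    """
    col = item.column
    scores = cohort[col]
    if scores.isna().any():
        if not mode.lenient_missing:
            raise ValueError(f"missing scores in {col} (strict mode)")
        scores = scores.fillna(0)
    endorsed = scores.to_numpy() >= 2
    if not mode.gated:
        return endorsed
    v = mode.chosen_variant(item)
    chk = cohort[f"chk_{col}" + ("" if v == 1 else "_v2")].to_numpy()
    if np.any(endorsed & (chk == "NA")):
        raise ValueError(f"endorsed {col} rows with check not presented")
    return endorsed & (chk == "yes")


def diagnose_frame(cohort: pd.DataFrame, mode: ScoringMode) -> pd.Series:
    """Vectorised diagnostic labels ("none"/"ptsd"/"cptsd") for a cohort frame."""
    def union(cluster: Cluster) -> np.ndarray:
        n_items = 3 if cluster.is_impairment else 2
        u = np.zeros(len(cohort), dtype=bool)
        for i in range(1, n_items + 1):
            u |= frame_item_endorsed(cohort, ItemId(cluster, i), mode)
        return u

    ptsd_part = union(Cluster.RE) & union(Cluster.AV) & union(Cluster.TH) & union(Cluster.PTSD_FI)
    dso_part = union(Cluster.AD) & union(Cluster.NSC) & union(Cluster.DR) & union(Cluster.DSO_FI)
    if mode.require_exposure:
        exposure_cols = [f"item{j:02d}" for j in range(1, N_EXPOSURE_EVENTS + 1)]
        exposed = cohort[exposure_cols].to_numpy().sum(axis=1) > 0
        ptsd_part &= exposed
        dso_part &= exposed
    labels = np.where(ptsd_part & dso_part, "cptsd", np.where(ptsd_part, "ptsd", "none"))
    return pd.Series(labels, index=cohort.index, name="label")


# ---------------------------------------------------------------------------
# Verification of printed tables
# ---------------------------------------------------------------------------

def verify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute the derived columns of a printed with/without-checks table.

    Expects columns ``level`` ("item" | "cluster" | "disorder"), ``label``,
    ``n_total``, ``n_without``, ``pct_without``, ``n_with``, ``pct_with`` and,
    for comparison, the printed ``decrease_n``, ``decrease_pct`` and ``z``.
    An optional boolean ``monotone`` column (default True) marks rows whose
    predicate can only lose cases under gating; for those rows the decrease
    count must equal ``n_without - n_with`` and the Z statistic is fully
    determined by it.  Non-monotone rows (the PTSD label, which can gain
    migrated cases) have an unknown discordant split, so their Z cannot be
    recomputed from the printed marginals.

    Returns the table with ``*_calc`` columns and a ``mismatches`` column
    listing every printed cell that disagrees with recomputation.
    """
    req = {"level", "label", "n_total", "n_without", "pct_without", "n_with", "pct_with"}
    missing = sorted(req - set(table.columns))
    if missing:
        raise ValueError(f"verification table is missing columns: {missing}")
    out = table.copy()
    rows = []
    for _, r in table.iterrows():
        monotone = bool(r.get("monotone", True)) if not pd.isna(r.get("monotone", True)) else True
        calc: dict[str, object] = {}
        flags: list[str] = []
        calc["pct_without_calc"] = _pct(int(r["n_without"]), int(r["n_total"]))
        calc["pct_with_calc"] = _pct(int(r["n_with"]), int(r["n_total"]))
        for col in ("pct_without", "pct_with"):
            if not pd.isna(r.get(col)) and not math.isclose(r[col], calc[col + "_calc"], abs_tol=0.051):
                flags.append(f"{col}: printed {r[col]} vs {calc[col + '_calc']} from counts")

        dec_n = int(r["n_without"]) - int(r["n_with"])
        calc["decrease_n_calc"] = dec_n if monotone else None
        if monotone and not pd.isna(r.get("decrease_n")) and int(r["decrease_n"]) != dec_n:
            flags.append(f"decrease_n: printed {int(r['decrease_n'])} vs {dec_n} from counts")

        if r["pct_without"] > 0:
            dec_pct = round_half_up(percentage_decrease(float(r["pct_without"]), float(r["pct_with"])), 1)
        else:
            dec_pct = None
        calc["decrease_pct_calc"] = dec_pct
        if dec_pct is not None and not pd.isna(r.get("decrease_pct")) and not math.isclose(
            float(r["decrease_pct"]), dec_pct, abs_tol=0.051
        ):
            flags.append(f"decrease_pct: printed {r['decrease_pct']} vs {dec_pct}")

        if monotone and dec_n > 0:
            counts = PairedCounts(b=dec_n, c=0, n11=int(r["n_with"]),
                                  n00=int(r["n_total"]) - int(r["n_without"]))
            corrected = str(r["level"]) == "disorder"
            z = round_half_up(mcnemar_z(counts, corrected=corrected).z, 2)
            calc["z_calc"] = z
            if not pd.isna(r.get("z")) and not math.isclose(float(r["z"]), z, abs_tol=0.0051):
                flags.append(f"z: printed {r['z']} vs {z}")
        else:
            # non-monotone rows (PTSD label) or no decrease: the discordant
            # split is not recoverable from marginals, so z is left blank
            calc["z_calc"] = None
        rows.append({**calc, "mismatches": "; ".join(flags)})
    calc_df = pd.DataFrame(rows, index=out.index)
    return pd.concat([out, calc_df], axis=1)
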