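"""YAML/JSON configuration for scoring modes and simulator parameters."""

from __future__ import annotations

import os
from importlib import resources

import pandas as pd
import yaml

from .instrument import Cluster, ItemId, ScoringMode, DEFAULT_VARIANT_CHOICE
from .simulate import CohortParams

__all__ = ["load_mode", "load_params", "published_rates"]

_VARIANT_KEYS = {"dso_ad2": ItemId(Cluster.AD, 2), "dso_dr1": ItemId(Cluster.DR, 1)}


def load_mode(path: str | os.PathLike | None) -> ScoringMode:
    """Build a :class:`ScoringMode` from a YAML/JSON file (None -> defaults).

    Recognised keys: ``gated`` (bool), ``variant_choice`` (mapping of
    ``dso_ad2`` / ``dso_dr1`` to 1 or 2), ``lenient_missing`` (bool),
    ``require_exposure`` (bool).
    """
    if path is None:
        return ScoringMode()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    variant_choice = dict(DEFAULT_VARIANT_CHOICE)
    for key, v in (raw.get("variant_choice") or {}).items():
        if key not in _VARIANT_KEYS:
            raise ValueError(f"unknown dual-variant item {key!r}; expected one of {sorted(_VARIANT_KEYS)}")
        variant_choice[_VARIANT_KEYS[key]] = int(v)
    return ScoringMode(
        gated=bool(raw.get("gated", False)),
        variant_choice=variant_choice,
        lenient_missing=bool(raw.get("lenient_missing", False)),
        require_exposure=bool(raw.get("require_exposure", False)),
    )


def load_params(path: str | os.PathLike | None, **overrides) -> CohortParams:
    """Build :class:`CohortParams` from a YAML/JSON file plus overrides."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if "pass_false_overrides" in raw:
        raw["pass_false_overrides"] = {
            (col, int(v)): float(p)
            for col, by_variant in raw["pass_false_overrides"].items()
            for v, p in by_variant.items()
        }
    if "item_thresholds" in raw and raw["item_thresholds"] is not None:
        raw["item_thresholds"] = {c: tuple(t) for c, t in raw["item_thresholds"].items()}
    raw.update(overrides)
    return CohortParams(**raw)


def published_rates() -> pd.DataFrame:
    """The bundled published with/without-checks table (N = 975 UK cohort)."""
    with resources.files("itqcc.data").joinpath("published_rates.csv").open() as fh:
        return pd.read_csv(fh)
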