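"""Questionnaire data handling: reading, orientation coding and scoring.

Items have five ordered response categories from "never" to "always".
Items phrased as *negative* experiences are coded 4 ("never") down to 0
("always"); items phrased as *positive* experiences 0 ("never") up to 4
("always"), so that a high coded score always means few problems and a
high quality of life, whatever the item's phrasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources as _resources

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "LABELS", "MISSING", "ScaleDefinition", "RawResponseTable", "ResponseMatrix",
    "CovariateTable", "AnalysisConfig", "ConfigurationError", "EmptyDataError",
    "load_responses", "load_covariates", "load_scales", "packaged_scales",
    "apply_scoring", "complete_case_filter", "subscale_total",
    "discretize_covariates",
]

#: canonical response labels, in increasing order of frequency/intensity
LABELS = ("never", "seldom", "sometimes", "often", "always")
MISSING = -1


class ConfigurationError(ValueError):
    """Input files or configuration do not match expectations."""


class EmptyDataError(ValueError):
    """An operation left no usable rows."""


class DataError(ValueError):
    """A value in the data violates a contract."""


@dataclass(frozen=True)
class ScaleDefinition:
    """One subscale: its items, orientations and category count.

    ``orientation`` maps each item id to ``"positive"`` (coded never=0 …
    always=4) or ``"negative"`` (coded never=4 … always=0).
    """

    name: str
    items: tuple
    orientation: dict
    m: int = 5
    domain: str = ""

    def __post_init__(self):
        object.__setattr__(self, "items", tuple(self.items))
        if len(self.items) < 2:
            raise ConfigurationError(f"scale {self.name!r} needs at least 2 items")
        if len(set(self.items)) != len(self.items):
            raise ConfigurationError(f"scale {self.name!r} has duplicate item ids")
        for it in self.items:
            o = self.orientation.get(it)
            if o not in ("positive", "negative"):
                raise ConfigurationError(
                    f"scale {self.name!r}: item {it!r} lacks a valid orientation")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def max_total(self) -> int:
        return self.n_items * (self.m - 1)

    def reversed(self) -> "ScaleDefinition":
        flipped = {it: ("negative" if o == "positive" else "positive")
                   for it, o in self.orientation.items()}
        return replace(self, orientation=flipped)


@dataclass
class RawResponseTable:
    """Normalized but uncoded responses: one row per (person, occasion)."""

    frame: pd.DataFrame          # columns: person_id, occasion, <item ids>
    items: tuple
    n_warnings: int = 0

    def __len__(self):
        return len(self.frame)


@dataclass
class ResponseMatrix:
    """Persons x items coded scores in ``0..m-1``; ``np.nan`` marks missing."""

    scores: np.ndarray           # float array, nan = missing
    items: tuple
    person_id: np.ndarray
    occasion: np.ndarray
    m: int = 5
    n_dropped: int = 0

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        finite = self.scores[np.isfinite(self.scores)]
        if finite.size and (finite.min() < 0 or finite.max() > self.m - 1):
            raise DataError(f"coded scores outside 0..{self.m - 1}")
        if self.scores.shape[1] != len(self.items):
            raise DataError("column count does not match the scale item count")

    @property
    def n_persons(self) -> int:
        return self.scores.shape[0]

    @property
    def complete_mask(self) -> np.ndarray:
        return np.isfinite(self.scores).all(axis=1)

    def values_int(self) -> np.ndarray:
        if not self.complete_mask.all():
            raise DataError("missing responses present; filter to complete cases")
        return self.scores.astype(int)


@dataclass
class CovariateTable:
    """Person covariates with a discretization map (set at analysis time)."""

    frame: pd.DataFrame          # person_id, occasion, age, sex, hba1c, treatment

    REQUIRED = ("person_id", "occasion", "age", "sex", "hba1c", "treatment")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ConfigurationError(f"covariate table lacks columns {missing}")

    def aligned_to(self, rm: ResponseMatrix) -> pd.DataFrame:
        key = pd.MultiIndex.from_arrays([rm.person_id, rm.occasion])
        idx = self.frame.set_index(["person_id", "occasion"])
        try:
            return idx.loc[key].reset_index()
        except KeyError as exc:
            raise DataError(f"covariate row missing for a respondent: {exc}") from exc


@dataclass
class AnalysisConfig:
    """Analysis-wide settings (significance levels, cut-points, seeds)."""

    alpha: float = 0.05
    strong_alpha: float = 0.01
    bh: bool = True
    n_bootstrap: int = 1000
    mc_persons: int = 10_000
    seed: int = 0
    covariate_cuts: dict = field(default_factory=lambda: {
        "age": "tertiles", "hba1c": "median", "sex": "asis",
        "treatment": "asis", "occasion": "asis",
    })
    missing_policy: str = "complete-case"
    strict_categories: bool = False

    def __post_init__(self):
        if not (0 < self.strong_alpha < self.alpha < 1):
            raise ConfigurationError("need 0 < strong_alpha < alpha < 1")
        if self.n_bootstrap < 100:
            raise ConfigurationError("bootstrap replicate count must be >= 100")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_LABEL_INDEX = {lab: i for i, lab in enumerate(LABELS)}
_OCCASIONS = ("inclusion", "follow-up")


def _normalize_cell(value):
    """Return (normalized value, ok). Values: label string, int, or None."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None, True
    s = str(value).strip()
    if s == "" or s.upper() == "NA":
        return None, True
    low = s.casefold()
    if low in _LABEL_INDEX:
        return low, True
    try:
        return int(s), True
    except ValueError:
        return None, False


def load_responses(path, scale: ScaleDefinition) -> RawResponseTable:
    """Read a response CSV and normalize its cells.

    Expected columns: ``person_id``, ``occasion``, then the scale's item ids.
    Labels are matched case-insensitively after trimming; unparseable cells
    become missing with a logged warning.
    """
    df = pd.read_csv(path, dtype=str)
    required = ["person_id", "occasion", *scale.items]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"response file lacks columns {missing}")
    df = df[required].copy()
    df["occasion"] = df["occasion"].str.strip().str.casefold()
    bad_occ = ~df["occasion"].isin(_OCCASIONS)
    if bad_occ.any():
        raise DataError(f"unknown occasion values: {df.loc[bad_occ, 'occasion'].unique()}")
    dup = df.duplicated(subset=["person_id", "occasion"])
    if dup.any():
        raise DataError(f"duplicate (person_id, occasion) rows: {int(dup.sum())}")
    n_warn = 0
    for it in scale.items:
        normalized = []
        for v in df[it]:
            nv, ok = _normalize_cell(v)
            if not ok:
                n_warn += 1
                logger.warning("unparseable response %r for item %s set to missing", v, it)
            normalized.append(nv)
        df[it] = normalized
    return RawResponseTable(frame=df, items=scale.items, n_warnings=n_warn)


def load_covariates(path) -> CovariateTable:
    df = pd.read_csv(path)
    df["occasion"] = df["occasion"].astype(str).str.strip().str.casefold()
    return CovariateTable(frame=df)


def load_scales(path) -> list:
    """Read a YAML/JSON scale-definition file into ScaleDefinition objects."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _scales_from_doc(doc)


def load_domain_pairs(path) -> list:
    """Unidimensionality pairs declared in a scale-definition file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [tuple(p) for p in doc.get("unidimensionality_pairs", [])]


def _scales_from_doc(doc) -> list:
    out = []
    for entry in doc["scales"]:
        orientation = entry["orientation"]
        if isinstance(orientation, str):
            orientation = {it: orientation for it in entry["items"]}
        out.append(ScaleDefinition(
            name=entry["name"], items=tuple(entry["items"]),
            orientation=dict(orientation), m=int(entry.get("m", 5)),
            domain=entry.get("domain", "")))
    return out


def packaged_scales() -> list:
    """The DISABKIDS DCGM-37 / DSM-10 subscale structure shipped with the
    package (eight subscales over four domains)."""
    ref = _resources.files("gllrasch") / "resources" / "disabkids_scales.yaml"
    doc = yaml.safe_load(ref.read_text())
    return _scales_from_doc(doc)


def packaged_domain_pairs() -> list:
    """Subscale pairs tested for joint unidimensionality, per domain."""
    ref = _resources.files("gllrasch") / "resources" / "disabkids_scales.yaml"
    doc = yaml.safe_load(ref.read_text())
    return [tuple(p) for p in doc.get("unidimensionality_pairs", [])]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def apply_scoring(raw: RawResponseTable, scale: ScaleDefinition,
                  integers_coded: bool = False) -> ResponseMatrix:
    """Map labels to coded scores with the orientation rule.

    Negative-experience items: never -> 4 ... always -> 0; positive items:
    never -> 0 ... always -> 4.  Integer cells are accepted as *already
    coded* only when ``integers_coded`` is set, to avoid silently reversing
    twice.
    """
    n = len(raw.frame)
    out = np.full((n, scale.n_items), np.nan)
    top = scale.m - 1
    for j, it in enumerate(scale.items):
        neg = scale.orientation[it] == "negative"
        col = raw.frame[it].to_numpy(dtype=object)
        for v_ix, v in enumerate(col):
            if v is None:
                continue
            if isinstance(v, int) and not isinstance(v, bool):
                if not integers_coded:
                    raise DataError(
                        f"integer response {v} for item {it}: pass integers_coded=True "
                        "if the file already holds coded scores")
                if not 0 <= v <= top:
                    raise DataError(f"coded score {v} outside 0..{top} for item {it}")
                out[v_ix, j] = v
            else:
                idx = _LABEL_INDEX[v]
                out[v_ix, j] = (top - idx) if neg else idx
    return ResponseMatrix(
        scores=out, items=scale.items,
        person_id=raw.frame["person_id"].to_numpy(),
        occasion=raw.frame["occasion"].to_numpy(), m=scale.m)


def complete_case_filter(rm: ResponseMatrix) -> ResponseMatrix:
    """Keep only rows with a response to every item of the subscale."""
    mask = rm.complete_mask
    kept, dropped = int(mask.sum()), int((~mask).sum())
    if kept == 0:
        raise EmptyDataError("no complete rows remain for this subscale")
    logger.info("complete-case filter: kept %d rows, dropped %d", kept, dropped)
    return ResponseMatrix(
        scores=rm.scores[mask], items=rm.items,
        person_id=rm.person_id[mask], occasion=rm.occasion[mask],
        m=rm.m, n_dropped=dropped)


def subscale_total(rm: ResponseMatrix) -> np.ndarray:
    """Per-person total coded score over the subscale (complete cases)."""
    return rm.values_int().sum(axis=1)


# ---------------------------------------------------------------------------
# covariate discretization
# ---------------------------------------------------------------------------

def discretize_covariates(cov: pd.DataFrame, config: AnalysisConfig) -> dict:
    """Map covariates to ordered integer group codes per person.

    Defaults: age in tertiles, HbA1c split at the median, sex / treatment /
    occasion as given; all overridable through ``config.covariate_cuts``
    (either a keyword or an explicit list of cut-points).
    """
    out = {}
    for name in ("age", "sex", "hba1c", "treatment", "occasion"):
        if name not in cov.columns:
            continue
        col = cov[name]
        rule = config.covariate_cuts.get(name, "asis")
        if rule == "asis":
            vals, codes = np.unique(col.astype(str).to_numpy(), return_inverse=True)
            out[name] = codes.astype(int)
        elif rule in ("median", "tertiles") or isinstance(rule, (list, tuple)):
            x = col.astype(float).to_numpy()
            if rule == "median":
                cuts = [np.median(x)]
            elif rule == "tertiles":
                cuts = list(np.quantile(x, [1 / 3, 2 / 3]))
            else:
                cuts = list(rule)
            out[name] = np.searchsorted(cuts, x, side="left").astype(int)
        else:
            raise ConfigurationError(f"unknown discretization rule {rule!r} for {name}")
        groups, counts = np.unique(out[name], return_counts=True)
        if np.any(counts == 0):  # np.unique cannot return empty groups; guard anyway
            raise ConfigurationError(f"empty group for covariate {name}")
        # re-code to consecutive 0..G-1
        out[name] = np.searchsorted(groups, out[name]).astype(int)
    return out
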