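"""Risk labels, class-distribution tables, complaint cross-tabs and GeoJSON.

The class index produced by the sorter runs from 1 (worst indicator
profile) to n + 1 (best).  Risk labels invert that ordering: the best
municipalities — those with the most protection equipment and the
strongest socioeconomic indicators — carry the lowest propensity of
violence against women, so class 6 maps to "Very Low" risk and class 1
to "Extremely High".  This orientation is fixed here, in one place, so
the sorting engine stays orientation-agnostic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import JoinError

logger = logging.getLogger("vawrisk")

#: six risk categories, ordered from best class (index 6) to worst (index 1)
RISK_LABELS_6 = {
    6: "Very Low",
    5: "Low",
    4: "Medium",
    3: "High",
    2: "Very High",
    1: "Extremely High",
}

NOT_CLASSIFIED = "not classified"


def label_classes(class_index: int, n_profiles: int = 5) -> str:
    """Risk label for a class index in [1, n_profiles + 1].

    Bijective for fixed ``n_profiles``; the named six-category scale
    applies when n_profiles = 5, other profile counts fall back to a
    generic inverse-risk numbering ("Risk level k of m", level 1 = lowest
    risk = best class).
    """
    n_classes = n_profiles + 1
    if not 1 <= class_index <= n_classes:
        raise ValueError(
            f"class index {class_index} outside [1, {n_classes}]")
    if n_profiles == 5:
        return RISK_LABELS_6[class_index]
    level = n_classes - class_index + 1
    return f"Risk level {level} of {n_classes}"


@dataclass(frozen=True)
class ClassDistribution:
    """Per-class municipality counts (keys are class indices)."""

    counts: dict[int, int]
    labels: dict[int, str] = field(default_factory=dict)
    total: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class": k, "label": self.labels.get(k, str(k)),
             "count": self.counts[k]}
            for k in sorted(self.counts, reverse=True)
        ]
        return pd.DataFrame(rows, columns=["class", "label", "count"])


def class_distribution(assignments: Iterable,
                       rule: str = "pessimistic") -> ClassDistribution:
    """Count municipalities per class (default: pessimistic assignment)."""
    attr = f"class_{rule}"
    counts: dict[int, int] = {}
    labels: dict[int, str] = {}
    total = 0
    for a in assignments:
        k = getattr(a, attr)
        counts[k] = counts.get(k, 0) + 1
        labels[k] = a.label if rule == "pessimistic" else labels.get(k, str(k))
        total += 1
    return ClassDistribution(counts=counts, labels=labels, total=total)


def complaints_by_class(assignments: Sequence, records: Sequence,
                        rule: str = "pessimistic") -> pd.DataFrame:
    """Aggregate complaint counts over risk classes.

    Returns one row per class with the number of municipalities, how many
    of them reported complaint data, and the total and mean complaints
    over the reporting ones.  Assignment ids without a matching record
    raise :class:`JoinError`.
    """
    by_id = {r.id: r for r in records}
    orphans = [a.id for a in assignments if a.id not in by_id]
    if orphans:
        raise JoinError(f"assignments without matching record: {orphans}")

    attr = f"class_{rule}"
    rows: dict[int, dict] = {}
    for a in assignments:
        rec = by_id[a.id]
        k = getattr(a, attr)
        row = rows.setdefault(k, {"class": k, "label": a.label,
                                  "n_municipalities": 0, "n_with_complaints": 0,
                                  "total_complaints": 0})
        row["n_municipalities"] += 1
        if rec.complaints is not None:
            row["n_with_complaints"] += 1
            row["total_complaints"] += rec.complaints

    out = []
    for k in sorted(rows, reverse=True):
        row = rows[k]
        reporting = row["n_with_complaints"]
        row["mean_complaints"] = (row["total_complaints"] / reporting
                                  if reporting else float("nan"))
        row["n_skipped"] = row["n_municipalities"] - reporting
        out.append(row)
    return pd.DataFrame(out, columns=["class", "label", "n_municipalities",
                                      "n_with_complaints", "total_complaints",
                                      "mean_complaints", "n_skipped"])


def export_geojson(assignments: Sequence, geometry: str | Path | dict,
                   out_path: str | Path | None = None,
                   key: str = "id") -> dict:
    """Annotate boundary features with ``risk_class`` and ``risk_label``.

    ``geometry`` is a GeoJSON FeatureCollection (path or parsed mapping)
    whose feature properties carry an identifier under ``key`` joinable to
    assignment ids.  Unmatched features are retained with null class and a
    logged warning.  Returns the annotated mapping; writes it to
    ``out_path`` when given.
    """
    if isinstance(geometry, (str, Path)):
        with Path(geometry).open(encoding="utf-8") as fh:
            collection = json.load(fh)
    else:
        collection = json.loads(json.dumps(geometry))  # deep copy

    by_id = {a.id: a for a in assignments}
    for feature in collection.get("features", []):
        props = feature.setdefault("properties", {})
        fid = props.get(key, feature.get("id"))
        match = by_id.get(str(fid)) if fid is not None else None
        if match is None:
            props["risk_class"] = None
            props["risk_label"] = None
            logger.warning("feature %r has no matching assignment", fid)
        else:
            props["risk_class"] = match.class_pessimistic
            props["risk_label"] = match.label

    if out_path is not None:
        with Path(out_path).open("w", encoding="utf-8") as fh:
            json.dump(collection, fh)
    return collection


def assignments_to_frame(assignments: Sequence,
                         excluded: dict[str, str] | None = None,
                         names: dict[str, str] | None = None) -> pd.DataFrame:
    """Tabulate assignments; excluded municipalities keep an explicit marker."""
    names = names or {}
    rows = [
        {"id": a.id, "name": a.name or names.get(a.id, ""),
         "class_pessimistic": a.class_pessimistic,
         "class_optimistic": a.class_optimistic,
         "risk_label": a.label, "excluded_reason": ""}
        for a in assignments
    ]
    for alt_id, reason in (excluded or {}).items():
        rows.append({"id": alt_id, "name": names.get(alt_id, ""),
                     "class_pessimistic": pd.NA, "class_optimistic": pd.NA,
                     "risk_label": NOT_CLASSIFIED, "excluded_reason": reason})
    return pd.DataFrame(rows, columns=["id", "name", "class_pessimistic",
                                       "class_optimistic", "risk_label",
                                       "excluded_reason"])
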