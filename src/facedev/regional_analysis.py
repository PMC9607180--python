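"""Region-atlas aggregation and clinical-threshold classification.

Deviations are binned into four clinical intervals; a region is flagged
"clinically relevant" when its robust summary statistic (default: the
95th percentile of raw per-vertex deviation) is strictly greater than
3 mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from facedev.deviation_map import DeviationField

CLINICAL_THRESHOLD_MM = 3.0


@dataclass(frozen=True)
class ClinicalClass:
    """One row of the clinical-relevance rubric."""

    label: str
    approximation: float
    explanation: str
    index: int  # interval order, for monotonicity checks


CLINICAL_CLASSES: tuple[ClinicalClass, ...] = (
    ClinicalClass("0", 0.0, "clinically irrelevant", 0),
    ClinicalClass("0-1", 0.5, "clinically irrelevant", 1),
    ClinicalClass(
        "1-3",
        2.0,
        "clinically relevant only in extreme detail evaluations for micro-aesthetics",
        2,
    ),
    ClinicalClass(
        "3+", 4.0, "clinically relevant, questioning suitability of this method", 3
    ),
)


def classify_deviation(d: float) -> ClinicalClass:
    """Map a nonnegative deviation (mm) to its clinical interval.

    Boundaries belong to the lower interval: 1.0 mm is "0-1", 3.0 mm is
    "1-3"; only strictly greater than 3 mm counts as relevant.
    """
    d = float(d)
    if not np.isfinite(d) or d < 0:
        raise ValueError(f"deviation must be finite and >= 0, got {d!r}")
    if d == 0.0:
        return CLINICAL_CLASSES[0]
    if d <= 1.0:
        return CLINICAL_CLASSES[1]
    if d <= CLINICAL_THRESHOLD_MM:
        return CLINICAL_CLASSES[2]
    return CLINICAL_CLASSES[3]


class RegionAtlas:
    """Assignment of mesh vertices to named facial locations.

    ``labels`` is a per-vertex array of region names; the empty string
    marks unassigned vertices.
    """

    def __init__(self, labels: Sequence[str]):
        self.labels = np.asarray(labels, dtype=object)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def region_names(self) -> list[str]:
        names = {str(r) for r in self.labels if r}
        return sorted(names)

    def vertices_in(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.labels == region)

    def subset(self, vertex_indices: np.ndarray) -> "RegionAtlas":
        return RegionAtlas(self.labels[vertex_indices])

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            {"vertex_id": np.arange(len(self.labels)), "region": self.labels}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "RegionAtlas":
        df = pd.read_csv(path, keep_default_na=False)
        labels = np.empty(len(df), dtype=object)
        labels[df["vertex_id"].to_numpy()] = df["region"].astype(str).to_numpy()
        return cls(labels)


@dataclass
class RegionSummary:
    """Per-region deviation statistics for one subject."""

    region: str
    n_valid: int
    median_mm: float
    p95_mm: float
    max_mm: float
    clinical_class: Optional[ClinicalClass]
    flag_over_3mm: bool
    assessable: bool


def summarize_regions(
    field: DeviationField,
    atlas: RegionAtlas,
    min_vertices: int = 20,
    percentile: float = 95.0,
    threshold: float = CLINICAL_THRESHOLD_MM,
    regions: Optional[Iterable[str]] = None,
) -> list[RegionSummary]:
    """Aggregate a deviation field over atlas regions.

    A region with fewer than ``min_vertices`` valid vertices (e.g. lost to
    crop artifacts) is marked unassessable and carries no statistics.
    """
    if len(atlas) != len(field.raw):
        raise ValueError(
            f"atlas has {len(atlas)} vertices but field has {len(field.raw)}"
        )
    names = list(regions) if regions is not None else atlas.region_names
    out: list[RegionSummary] = []
    for name in names:
        idx = atlas.vertices_in(name)
        vals = field.raw[idx]
        vals = vals[field.valid[idx]]
        if len(vals) < min_vertices:
            out.append(
                RegionSummary(name, len(vals), np.nan, np.nan, np.nan, None, False, False)
            )
            continue
        p = float(np.percentile(vals, percentile))
        out.append(
            RegionSummary(
                region=name,
                n_valid=len(vals),
                median_mm=float(np.median(vals)),
                p95_mm=p,
                max_mm=float(vals.max()),
                clinical_class=classify_deviation(p),
                flag_over_3mm=p > threshold,
                assessable=True,
            )
        )
    return out


def summaries_to_frame(summaries: list[RegionSummary], subject_id=None) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "subject_id": subject_id,
                "region": s.region,
                "n_valid": s.n_valid,
                "median_mm": s.median_mm,
                "p95_mm": s.p95_mm,
                "max_mm": s.max_mm,
                "class": s.clinical_class.label if s.clinical_class else "",
                "flag": s.flag_over_3mm,
                "assessable": s.assessable,
            }
        )
    return pd.DataFrame(rows)


_REQUIRED_MANIFEST_COLUMNS = ("interval_days", "expression_ok", "artifact_ok")


def filter_cohort(manifest: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cohort inclusion criteria.

    A subject is kept iff the scan interval is under 7 days, the expression
    is neutral and the reference scan is artifact-free.  Returns
    ``(included, exclusion_log)``; the log lists every violated criterion
    per excluded subject.
    """
    for col in _REQUIRED_MANIFEST_COLUMNS:
        if col not in manifest.columns:
            raise KeyError(f"manifest is missing required column {col!r}")
    reasons: list[tuple] = []
    keep = np.ones(len(manifest), dtype=bool)
    for i, row in enumerate(manifest.itertuples(index=False)):
        why = []
        if not row.interval_days < 7:
            why.append("interval")
        if not bool(row.expression_ok):
            why.append("expression")
        if not bool(row.artifact_ok):
            why.append("artifact")
        if why:
            keep[i] = False
            sid = getattr(row, "subject_id", i)
            reasons.append((sid, ";".join(why)))
    included = manifest[keep].reset_index(drop=True)
    log = pd.DataFrame(reasons, columns=["subject_id", "reasons"])
    return included, log
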