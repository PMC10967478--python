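"""Slice-wise elliptical plug annotations: IO, adjudication, burden scores.

Readers mark each mucus plug with one axis-aligned ellipse per axial slice
(center, full width, full height, in 0-based voxel coordinates); all
ellipses of one plug share a ``(reader_id, plug_label)`` pair. Two readers
annotate independently; plugs found by only one reader are *discordant* and
require an accept/reject verdict from a third reader. The three burden
scores are computed from the finalized consensus:

* slice score — total number of elliptical annotations,
* plug score — number of distinct plugs,
* segment score — number of bronchopulmonary segments containing at least
  one plug (classic 0-20 scale).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EllipseAnnotation",
    "AnnotationSet",
    "AdjudicationDecision",
    "BurdenScores",
    "DiscordanceReport",
    "read_annotations",
    "write_annotations",
    "adjudicate",
    "burden_scores",
]

CSV_COLUMNS = [
    "scan_id", "reader_id", "plug_label", "slice_index",
    "center_x", "center_y", "width", "height",
]

N_BRONCHOPULMONARY_SEGMENTS = 20


@dataclass(frozen=True)
class EllipseAnnotation:
    """One elliptical ROI on one axial slice, in voxel coordinates."""

    scan_id: str
    reader_id: str
    plug_label: int
    slice_index: int
    center_x: float
    center_y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"plug {self.plug_label} slice {self.slice_index}: "
                "ellipse extents must be positive"
            )
        if self.slice_index < 0:
            raise ValueError("slice_index must be non-negative")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Inclusive interior test for voxel coordinates (boundary counts)."""
        return ((x - self.center_x) / (self.width / 2.0)) ** 2 + (
            (y - self.center_y) / (self.height / 2.0)
        ) ** 2 <= 1.0

    def pixel_set(self) -> set[tuple[int, int]]:
        """Integer pixel coordinates inside the ellipse (inclusive rule)."""
        x0 = int(np.floor(self.center_x - self.width / 2.0))
        x1 = int(np.ceil(self.center_x + self.width / 2.0))
        y0 = int(np.floor(self.center_y - self.height / 2.0))
        y1 = int(np.ceil(self.center_y + self.height / 2.0))
        xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1), indexing="ij")
        inside = self.contains(xs, ys)
        return {(int(a), int(b)) for a, b in zip(xs[inside], ys[inside])}


@dataclass
class AnnotationSet:
    """All annotations of one scan, groupable into plugs per reader."""

    scan_id: str
    annotations: list[EllipseAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, int]] = set()
        for a in self.annotations:
            key = (a.reader_id, a.plug_label, a.slice_index)
            if key in seen:
                raise ValueError(f"duplicate annotation for (reader, plug, slice) {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.annotations)

    def plugs(self) -> dict[tuple[str, int], list[EllipseAnnotation]]:
        """Group annotations by (reader_id, plug_label), slice-sorted."""
        out: dict[tuple[str, int], list[EllipseAnnotation]] = {}
        for a in self.annotations:
            out.setdefault((a.reader_id, a.plug_label), []).append(a)
        for v in out.values():
            v.sort(key=lambda a: a.slice_index)
        return out

    @property
    def plug_labels(self) -> list[tuple[str, int]]:
        return sorted(self.plugs())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {c: getattr(a, c) for c in CSV_COLUMNS}
                for a in sorted(
                    self.annotations, key=lambda a: (a.reader_id, a.plug_label, a.slice_index)
                )
            ],
            columns=CSV_COLUMNS,
        )


@dataclass(frozen=True)
class AdjudicationDecision:
    """Third-reader verdict on one discordant (single-reader) plug."""

    reader_id: str
    plug_label: int
    verdict: str  # "accept" | "reject"
    adjudicator_id: str = "reader3"

    def __post_init__(self) -> None:
        if self.verdict not in ("accept", "reject"):
            raise ValueError(f"verdict must be accept|reject, got {self.verdict!r}")


@dataclass
class DiscordanceReport:
    concordant: int
    discordant: int
    accepted: int
    rejected: int
    matches: list[tuple[int, int]] = field(default_factory=list)  # (label A, label B)


@dataclass
class BurdenScores:
    """Per-scan mucus burden scores from the finalized annotation."""

    slice_score: int
    plug_score: int
    segment_score: int | None  # absent when segment labels are missing

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "slice_score": self.slice_score,
                "plug_score": self.plug_score,
                "segment_score": self.segment_score,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


# --------------------------------------------------------------------------- IO
def read_annotations(source: str | Path | pd.DataFrame) -> AnnotationSet:
    """Read an annotation table (CSV path or DataFrame) into an AnnotationSet.

    Malformed rows raise with their (0-based) row number; an empty table
    with a valid header yields an empty set.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table is missing columns: {missing}")
    annotations = []
    for i, row in df.iterrows():
        try:
            annotations.append(
                EllipseAnnotation(
                    scan_id=str(row["scan_id"]),
                    reader_id=str(row["reader_id"]),
                    plug_label=int(row["plug_label"]),
                    slice_index=int(row["slice_index"]),
                    center_x=float(row["center_x"]),
                    center_y=float(row["center_y"]),
                    width=float(row["width"]),
                    height=float(row["height"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    scan_ids = {a.scan_id for a in annotations}
    if len(scan_ids) > 1:
        raise ValueError(f"annotation table mixes scans: {sorted(scan_ids)}")
    scan_id = scan_ids.pop() if scan_ids else ""
    return AnnotationSet(scan_id=scan_id, annotations=annotations)


def write_annotations(annotation_set: AnnotationSet, path: str | Path) -> None:
    annotation_set.to_frame().to_csv(path, index=False)


def read_decisions(source: str | Path | pd.DataFrame) -> list[AdjudicationDecision]:
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    return [
        AdjudicationDecision(
            reader_id=str(r["reader_id"]),
            plug_label=int(r["plug_label"]),
            verdict=str(r["verdict"]),
            adjudicator_id=str(r.get("adjudicator_id", "reader3")),
        )
        for _, r in df.iterrows()
    ]


# --------------------------------------------------------------------------- adjudication
def _stack_pixels(plug: Sequence[EllipseAnnotation]) -> dict[int, set[tuple[int, int]]]:
    return {a.slice_index: a.pixel_set() for a in plug}


def _overlap(
    a: Mapping[int, set[tuple[int, int]]], b: Mapping[int, set[tuple[int, int]]]
) -> int:
    return sum(len(a[z] & b[z]) for z in set(a) & set(b))


def adjudicate(
    reader_a: AnnotationSet,
    reader_b: AnnotationSet,
    decisions: Iterable[AdjudicationDecision] = (),
    geometry: str = "a",
) -> tuple[AnnotationSet, DiscordanceReport]:
    """Merge two readers into a consensus set with third-reader adjudication.

    Two plugs from different readers are *concordant* when their stacked
    ellipse interiors share at least one voxel on at least one common slice;
    candidate matches are resolved greedily by descending overlap (ties to
    the lower plug labels). Concordant plugs keep reader A's geometry
    (``geometry="union"`` keeps both readers' ellipses, preferring A on
    shared slices). Single-reader plugs need an accept/reject decision and
    are kept iff accepted. Consensus plugs are relabeled 0..n-1.
    """
    if reader_a.scan_id != reader_b.scan_id:
        raise ValueError("annotation sets belong to different scans")
    if geometry not in ("a", "union"):
        raise ValueError("geometry must be 'a' or 'union'")
    plugs_a = reader_a.plugs()
    plugs_b = reader_b.plugs()
    pix_a = {k: _stack_pixels(v) for k, v in plugs_a.items()}
    pix_b = {k: _stack_pixels(v) for k, v in plugs_b.items()}

    candidates = []
    for ka in sorted(plugs_a):
        for kb in sorted(plugs_b):
            ov = _overlap(pix_a[ka], pix_b[kb])
            if ov > 0:
                candidates.append((-ov, ka[1], kb[1], ka, kb))
    candidates.sort()
    matched_a: dict[tuple[str, int], tuple[str, int]] = {}
    matched_b: set[tuple[str, int]] = set()
    for _, _, _, ka, kb in candidates:
        if ka in matched_a or kb in matched_b:
            continue
        matched_a[ka] = kb
        matched_b.add(kb)

    decision_map = {(d.reader_id, d.plug_label): d.verdict for d in decisions}
    consensus_plugs: list[list[EllipseAnnotation]] = []
    accepted = rejected = 0
    discordant_keys = [k for k in sorted(plugs_a) if k not in matched_a] + [
        k for k in sorted(plugs_b) if k not in matched_b
    ]
    for key in discordant_keys:
        if key not in decision_map:
            raise ValueError(f"missing adjudication decision for discordant plug {key}")

    for ka in sorted(plugs_a):
        if ka in matched_a:
            anns = list(plugs_a[ka])
            if geometry == "union":
                have = {a.slice_index for a in anns}
                anns += [a for a in plugs_b[matched_a[ka]] if a.slice_index not in have]
            consensus_plugs.append(anns)
        elif decision_map[ka] == "accept":
            consensus_plugs.append(list(plugs_a[ka]))
            accepted += 1
        else:
            rejected += 1
    for kb in sorted(plugs_b):
        if kb in matched_b:
            continue
        if decision_map[kb] == "accept":
            consensus_plugs.append(list(plugs_b[kb]))
            accepted += 1
        else:
            rejected += 1

    merged = []
    for new_label, anns in enumerate(consensus_plugs):
        for a in sorted(anns, key=lambda a: a.slice_index):
            merged.append(
                EllipseAnnotation(
                    scan_id=a.scan_id, reader_id="consensus", plug_label=new_label,
                    slice_index=a.slice_index, center_x=a.center_x, center_y=a.center_y,
                    width=a.width, height=a.height,
                )
            )
    report = DiscordanceReport(
        concordant=len(matched_a),
        discordant=len(discordant_keys),
        accepted=accepted,
        rejected=rejected,
        matches=sorted((ka[1], kb[1]) for ka, kb in matched_a.items()),
    )
    return AnnotationSet(scan_id=reader_a.scan_id, annotations=merged), report


# --------------------------------------------------------------------------- scores
def burden_scores(
    consensus: AnnotationSet, segment_labels: Mapping[int, str] | None = None
) -> BurdenScores:
    """Slice, plug and (when segment labels are supplied) segment scores.

    ``segment_labels`` maps consensus plug labels to bronchopulmonary
    segment names; when absent or incomplete, the segment score is reported
    as ``None`` and the other scores are still computed.
    """
    plugs = consensus.plugs()
    slice_score = len(consensus)
    plug_score = len(plugs)
    segment_score: int | None = None
    if segment_labels is not None:
        labels = {label for _, label in plugs}
        if labels <= set(segment_labels):
            segments = {segment_labels[label] for label in labels}
            segment_score = min(len(segments), N_BRONCHOPULMONARY_SEGMENTS)
    return BurdenScores(slice_score=slice_score, plug_score=plug_score, segment_score=segment_score)
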