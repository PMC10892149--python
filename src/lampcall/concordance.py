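"""Scoring of body-fluid marker call panels against expected truth.

A mock forensic study probes each sample for a panel of mRNA markers —
venous blood Vb (HBB), semen Se (SEMG1), saliva Sa (HTN3) and vaginal
fluid Vf (CYP2B7P) — and compares the instrument's calls against the known
sample composition.  A sample counts as correctly identified only when
every probed marker matches its expectation; per-marker false-positive and
false-negative tallies localize where cross-reactivity or low RNA input
degrades the calls.  The bundled mock-study table ships with the package.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from .calling import CallResult
from .plate import WellID

__all__ = [
    "DEFAULT_MARKERS",
    "ConcordanceReport",
    "MarkerPanel",
    "MockSample",
    "bundled_mock_study",
    "load_study",
    "panel_from_calls",
    "sample_correct",
    "save_study",
    "score_study",
]

#: Default marker panel: body fluid tag -> target transcript.
DEFAULT_MARKERS = ("Vb", "Se", "Sa", "Vf")
MARKER_GENES = {"Vb": "HBB", "Se": "SEMG1", "Sa": "HTN3", "Vf": "CYP2B7P"}


@dataclass(frozen=True)
class MarkerPanel:
    """Positive/negative call for each marker of one sample."""

    calls: Mapping[str, str]  # marker -> "positive" | "negative"

    def __post_init__(self) -> None:
        for marker, value in self.calls.items():
            if value not in ("positive", "negative"):
                raise ValueError(f"marker {marker}: call must be positive/negative")

    @classmethod
    def from_signs(cls, signs: Mapping[str, str]) -> "MarkerPanel":
        """Build from +/- notation as printed in study tables."""
        trans = {"+": "positive", "-": "negative"}
        return cls({m: trans[s.strip()] for m, s in signs.items()})

    def markers(self) -> frozenset[str]:
        return frozenset(self.calls)


@dataclass(frozen=True)
class MockSample:
    """One mock specimen: identifier, description, expected and actual panels."""

    sample_id: int
    description: str
    expected: MarkerPanel
    actual: MarkerPanel


@dataclass
class ConcordanceReport:
    """Study-level score: per-sample correctness and per-marker error tallies."""

    n_samples: int
    n_correct: int
    correct_flags: dict[int, bool]
    false_positives: dict[str, int]
    false_negatives: dict[str, int]
    false_positive_samples: dict[str, list[int]] = field(default_factory=dict)
    false_negative_samples: dict[str, list[int]] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"{self.n_correct}/{self.n_samples} samples fully concordant"]
        for marker in sorted(set(self.false_positives) | set(self.false_negatives)):
            fp = self.false_positives.get(marker, 0)
            fn = self.false_negatives.get(marker, 0)
            lines.append(f"  {marker}: {fp} false positive(s), {fn} false negative(s)")
        return "\n".join(lines)


def sample_correct(expected: MarkerPanel, actual: MarkerPanel) -> bool:
    """True iff every probed marker's call matches its expectation."""
    if expected.markers() != actual.markers():
        raise ValueError(
            f"marker sets differ: {sorted(expected.markers())} vs {sorted(actual.markers())}"
        )
    return all(expected.calls[m] == actual.calls[m] for m in expected.calls)


def score_study(samples: Sequence[MockSample]) -> ConcordanceReport:
    """Score a whole study; order of samples does not affect the report."""
    if not samples:
        raise ValueError("no samples to score")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in study")
    flags: dict[int, bool] = {}
    fp: dict[str, int] = {}
    fn: dict[str, int] = {}
    fp_samples: dict[str, list[int]] = {}
    fn_samples: dict[str, list[int]] = {}
    for s in sorted(samples, key=lambda s: s.sample_id):
        flags[s.sample_id] = sample_correct(s.expected, s.actual)
        for m in s.expected.calls:
            e, a = s.expected.calls[m], s.actual.calls[m]
            if e == "negative" and a == "positive":
                fp[m] = fp.get(m, 0) + 1
                fp_samples.setdefault(m, []).append(s.sample_id)
            elif e == "positive" and a == "negative":
                fn[m] = fn.get(m, 0) + 1
                fn_samples.setdefault(m, []).append(s.sample_id)
    return ConcordanceReport(
        n_samples=len(samples),
        n_correct=sum(flags.values()),
        correct_flags=flags,
        false_positives=fp,
        false_negatives=fn,
        false_positive_samples=fp_samples,
        false_negative_samples=fn_samples,
    )


def _read_study_rows(rows, markers: Sequence[str]) -> list[MockSample]:
    samples = []
    for row in rows:
        expected = MarkerPanel.from_signs({m: row[f"{m}_expected"] for m in markers})
        actual = MarkerPanel.from_signs({m: row[f"{m}_actual"] for m in markers})
        samples.append(
            MockSample(
                sample_id=int(row["sample_id"]),
                description=row.get("description", ""),
                expected=expected,
                actual=actual,
            )
        )
    return samples


def load_study(path: Path, markers: Sequence[str] = DEFAULT_MARKERS) -> list[MockSample]:
    """Read a study table CSV: sample_id, description, then
    ``<marker>_expected``/``<marker>_actual`` sign columns per marker."""
    with open(path, newline="") as fh:
        return _read_study_rows(csv.DictReader(fh), markers)


def save_study(path: Path, samples: Sequence[MockSample],
               markers: Sequence[str] = DEFAULT_MARKERS) -> None:
    sign = {"positive": "+", "negative": "-"}
    header = ["sample_id", "description"]
    for m in markers:
        header += [f"{m}_expected", f"{m}_actual"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for s in samples:
            row = [s.sample_id, s.description]
            for m in markers:
                row += [sign[s.expected.calls[m]], sign[s.actual.calls[m]]]
            writer.writerow(row)


def bundled_mock_study() -> list[MockSample]:
    """The package's bundled 12-sample mock-study table."""
    ref = resources.files("lampcall.data").joinpath("mock_study_table.csv")
    with resources.as_file(ref) as path:
        return load_study(path)


def panel_from_calls(
    plate_calls: Mapping[WellID, CallResult],
    well_assignment: Mapping[WellID, tuple[int, str]],
) -> dict[int, MarkerPanel]:
    """Assemble per-sample actual panels from plate calls.

    ``well_assignment`` maps each probed well to ``(sample_id, marker)``;
    wells without an assignment are ignored.  Raises when an assigned well
    has no call.
    """
    by_sample: dict[int, dict[str, str]] = {}
    for well, (sample_id, marker) in well_assignment.items():
        if well not in plate_calls:
            raise KeyError(f"well {well} (sample {sample_id}, {marker}) has no call")
        by_sample.setdefault(sample_id, {})[marker] = plate_calls[well].status
    return {sid: MarkerPanel(calls) for sid, calls in sorted(by_sample.items())}
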