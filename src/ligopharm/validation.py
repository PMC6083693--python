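"""Decoy-set validation: contingency counts and Guner-Henry statistics.

A labeled database of A known actives among D molecules is screened; from
the Ht retrieved hits, of which Ha are active, the classical enrichment
statistics follow:

    % yield of actives  = 100 * Ha / Ht
    % ratio of actives  = 100 * Ha / A
    enrichment factor   = (Ha * D) / (Ht * A)
    false negatives     = A - Ha
    false positives     = Ht - Ha
    GH = [Ha * (3A + Ht) / (4 * Ht * A)] * [1 - (Ht - Ha) / (D - A)]

GH (goodness of hit) lies in [0, 1], equals 1 exactly for perfect retrieval
(Ha = Ht = A), and a value of 0.6-0.8 is conventionally read as a very good
model.  Display rounding: percentages and EF to one decimal; GH is
*truncated* (floored) to two decimals — a conservative convention that never
overstates the score.  Raw full-precision values are always retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .core import GenerationConfig, Hypothesis, Molecule
from .features import FeatureDefs
from .screening import HitList, screen

logger = logging.getLogger(__name__)

__all__ = [
    "DecoyCounts",
    "ValidationReport",
    "compute_counts",
    "compute_metrics",
    "validate",
    "read_labels",
    "write_labels",
]


@dataclass(frozen=True)
class DecoyCounts:
    """Screening contingency: database size D, actives A, hits Ht, active hits Ha."""

    D: int
    A: int
    Ht: int
    Ha: int

    def __post_init__(self) -> None:
        if min(self.D, self.A, self.Ht, self.Ha) < 0:
            raise ValueError("counts must be non-negative")
        if self.A > self.D or self.Ht > self.D:
            raise ValueError("A and Ht cannot exceed D")
        if self.Ha > min(self.A, self.Ht):
            raise ValueError("Ha cannot exceed min(A, Ht)")
        # inactive hits cannot exceed the number of inactives
        if self.Ht - self.Ha > self.D - self.A:
            raise ValueError("Ht - Ha cannot exceed D - A")


def _floor2(x: float) -> float:
    return math.floor(x * 100 + 1e-9) / 100


@dataclass
class ValidationReport:
    """Raw metrics (None = undefined), display rounding and annotations."""

    counts: DecoyCounts
    yield_of_actives: Optional[float]
    ratio_of_actives: Optional[float]
    enrichment_factor: Optional[float]
    false_negatives: int
    false_positives: int
    gh: Optional[float]
    warnings: list[str] = field(default_factory=list)
    annotation: str = ""
    config: Optional[dict] = None

    def display(self) -> dict:
        """Metrics rounded for presentation (GH floored at 2 d.p.)."""
        rnd = lambda x, n: None if x is None else round(x, n)
        return {
            "yield_of_actives": rnd(self.yield_of_actives, 1),
            "ratio_of_actives": rnd(self.ratio_of_actives, 1),
            "enrichment_factor": rnd(self.enrichment_factor, 1),
            "false_negatives": self.false_negatives,
            "false_positives": self.false_positives,
            "gh": None if self.gh is None else _floor2(self.gh),
        }

    def to_dict(self) -> dict:
        return {
            "counts": {"D": self.counts.D, "A": self.counts.A,
                       "Ht": self.counts.Ht, "Ha": self.counts.Ha},
            "raw": {
                "yield_of_actives": self.yield_of_actives,
                "ratio_of_actives": self.ratio_of_actives,
                "enrichment_factor": self.enrichment_factor,
                "false_negatives": self.false_negatives,
                "false_positives": self.false_positives,
                "gh": self.gh,
            },
            "display": self.display(),
            "warnings": list(self.warnings),
            "annotation": self.annotation,
            "config": self.config,
        }


def compute_counts(hits: HitList, labels: dict[str, str]) -> DecoyCounts:
    """Contingency counts from a hit list and an id -> active/inactive map."""
    for r in hits:
        if r.molecule_id not in labels:
            raise KeyError(f"hit {r.molecule_id!r} has no active/inactive label")
    D = len(labels)
    A = sum(1 for v in labels.values() if v == "active")
    Ht = len(hits)
    Ha = sum(1 for r in hits if labels[r.molecule_id] == "active")
    return DecoyCounts(D=D, A=A, Ht=Ht, Ha=Ha)


def compute_metrics(c: DecoyCounts) -> ValidationReport:
    """Derive yield/ratio/EF/FN/FP/GH; degenerate counts yield undefined
    markers (None) with a logged warning rather than an exception."""
    warnings: list[str] = []
    fn = c.A - c.Ha
    fp = c.Ht - c.Ha

    if c.Ht > 0:
        yield_ = 100.0 * c.Ha / c.Ht
    else:
        yield_ = None
        warnings.append("Ht = 0: yield of actives undefined")
    if c.A > 0:
        ratio = 100.0 * c.Ha / c.A
    else:
        ratio = None
        warnings.append("A = 0: ratio of actives undefined")
    if c.Ht > 0 and c.A > 0:
        ef = (c.Ha * c.D) / (c.Ht * c.A)
    else:
        ef = None
        warnings.append("Ht = 0 or A = 0: enrichment factor undefined")
    if c.Ht > 0 and c.A > 0 and c.D > c.A:
        gh = (c.Ha * (3 * c.A + c.Ht)) / (4 * c.Ht * c.A) * (1 - fp / (c.D - c.A))
    else:
        gh = None
        warnings.append("GH undefined (requires Ht > 0, A > 0 and D > A)")

    for w in warnings:
        logger.warning(w)
    annotation = "very good model" if gh is not None and 0.6 <= gh <= 0.8 else ""
    return ValidationReport(
        counts=c,
        yield_of_actives=yield_,
        ratio_of_actives=ratio,
        enrichment_factor=ef,
        false_negatives=fn,
        false_positives=fp,
        gh=gh,
        warnings=warnings,
        annotation=annotation,
    )


def validate(
    h: Hypothesis,
    db: list[Molecule],
    labels: dict[str, str],
    cfg: GenerationConfig | None = None,
    max_omit: int = 0,
    defs: FeatureDefs | None = None,
) -> ValidationReport:
    """Screen a labeled decoy database and report the validation statistics.

    Database screening conventionally allows no omitted features
    (``max_omit=0``); the configuration snapshot is attached to the report.
    """
    hits = screen(h, db, max_omit=max_omit, defs=defs)
    counts = compute_counts(hits, labels)
    report = compute_metrics(counts)
    report.config = cfg.to_dict() if cfg is not None else None
    return report


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a labels TSV: ``id<TAB>active|inactive`` per line."""
    labels: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or parts[1] not in ("active", "inactive"):
            raise ValueError(f"labels file line {lineno + 1}: expected 'id<TAB>active|inactive'")
        labels[parts[0]] = parts[1]
    return labels


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{k}\t{v}\n" for k, v in labels.items()))
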