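"""Ligand-to-pharmacophore mapping, fit values and database screening.

A molecule maps onto a hypothesis when a type-consistent correspondence
places each matched feature inside its tolerance sphere after optimal rigid
superposition, leaving at most ``max_omit`` hypothesis features unmatched.
The fit value uses the classical quadratic falloff

    fit = sum over matched features of  w * max(0, 1 - (d / t)^2)

where d is the residual displacement and t the sphere radius, so a perfect
mapping scores the sum of weights and a feature sitting on its sphere
boundary contributes nothing.  Fit values are on this package's own scale.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._geometry import aligned_displacements
from .core import GenerationConfig, Hypothesis, Molecule
from .features import FeatureDefs, FeaturePoint, get_feature_sets
from .hypogen import Correspondence, enumerate_common_cliques

__all__ = ["MappingResult", "HitList", "fit_value", "map_ligand", "screen", "write_hits_tsv"]


@dataclass(frozen=True)
class MappingResult:
    """Best mapping of one molecule: conformer, correspondence, fit, omissions."""

    molecule_id: str
    conformer: int
    correspondence: Correspondence
    fit: float
    omitted: int


#: A hit list is a list of MappingResult sorted by fit descending,
#: ties broken by molecule id ascending.
HitList = list[MappingResult]


def fit_value(h: Hypothesis, matched: list[tuple]) -> float:
    """Fit of a set of (feature, point, displacement) matches against ``h``.

    Omitted features simply do not appear in ``matched`` and contribute 0.
    """
    total = 0.0
    for feature, _point, d in matched:
        if d < 0:
            raise ValueError("displacement must be >= 0")
        total += feature.weight * max(0.0, 1.0 - (d / feature.tolerance) ** 2)
    return total


def _refine_mapping(
    h: Hypothesis,
    feats: list[FeaturePoint],
    corr: Correspondence,
    max_omit: int,
) -> tuple[float, int, tuple[tuple[int, int], ...]] | None:
    """Align the correspondence, dropping out-of-sphere pairs one at a time.

    Returns (fit, omitted, pairs) for a valid mapping, else None.
    """
    n = len(h.features)
    pairs = list(corr.pairs)
    while pairs and len(pairs) >= n - max_omit:
        P = np.array([feats[j].position for _, j in pairs])
        Q = np.array([h.features[i].position for i, _ in pairs])
        d = aligned_displacements(P, Q)
        tol = np.array([h.features[i].tolerance for i, _ in pairs])
        excess = d - tol
        if (excess <= 0).all():
            omitted = n - len(pairs)
            fit = fit_value(
                h, [(h.features[i], feats[j], dk) for (i, j), dk in zip(pairs, d)]
            )
            return fit, omitted, tuple(pairs)
        pairs.pop(int(np.argmax(excess)))
    return None


def map_ligand(
    h: Hypothesis,
    m: Molecule,
    max_omit: int = 0,
    defs: FeatureDefs | None = None,
) -> MappingResult | None:
    """Highest-fit mapping of ``m`` over all conformers and correspondences.

    Returns ``None`` when no mapping with at most ``max_omit`` omitted
    features exists (including for featureless molecules).  An empty
    hypothesis is rejected: every molecule would vacuously map with fit 0.
    """
    if not h.features:
        raise ValueError("cannot map onto an empty hypothesis")
    if max_omit < 0:
        raise ValueError("max_omit must be >= 0")
    n = len(h.features)
    hpoints = h.feature_points()
    dist_tol = max(f.tolerance for f in h.features)
    best: MappingResult | None = None
    best_key = None
    for ci, feats in enumerate(get_feature_sets(m, defs)):
        if len(feats) < n - max_omit:
            continue
        for corr in enumerate_common_cliques(hpoints, feats, dist_tol):
            if corr.size < n - max_omit:
                break  # correspondences are sorted by size descending
            refined = _refine_mapping(h, feats, corr, max_omit)
            if refined is None:
                continue
            fit, omitted, pairs = refined
            key = (fit, -omitted, -ci)
            if best_key is None or key > best_key:
                matched = {p[0] for p in pairs}
                best = MappingResult(
                    m.id,
                    ci,
                    Correspondence(pairs, tuple(i for i in range(n) if i not in matched)),
                    fit,
                    omitted,
                )
                best_key = key
    return best


def screen(
    h: Hypothesis,
    db: list[Molecule],
    cfg: GenerationConfig | None = None,
    max_omit: int | None = None,
    defs: FeatureDefs | None = None,
) -> HitList:
    """Map every database molecule onto ``h`` and rank the hits by fit.

    Molecules without a valid mapping are absent from the result.  The sort
    is deterministic: fit descending, molecule id ascending on ties.
    """
    if not h.features:
        raise ValueError("cannot screen with an empty hypothesis")
    if not db:
        raise ValueError("database is empty")
    if max_omit is None:
        max_omit = cfg.max_omit_feat if cfg is not None else 0
    hits = []
    for m in db:
        result = map_ligand(h, m, max_omit=max_omit, defs=defs)
        if result is not None:
            hits.append(result)
    hits.sort(key=lambda r: (-r.fit, r.molecule_id))
    return hits


def write_hits_tsv(hits: HitList, path: str | Path) -> None:
    """Write a ranked hit list as TSV: rank, id, fit, omitted, conformer."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["rank", "id", "fit", "omitted", "conformer"])
        for rank, r in enumerate(hits, start=1):
            writer.writerow([rank, r.molecule_id, f"{r.fit:.5f}", r.omitted, r.conformer])
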