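"""Seeded synthetic benchmarks with a planted common pharmacophore.

Synthetic "molecules" here are feature clouds — typed 3D points — rather
than chemical structures.  This isolates the geometric machinery (clique
correspondence search, alignment, fit scoring, enrichment statistics) from
chemistry-specific perception choices, and makes every pipeline stage
testable without external data.

The generator plants a random template arrangement (default composition
"RHDDDAA": one aromatic ring, one hydrophobe, three donors, two acceptors)
and emits:

* a training set of clouds, each the template under a random rigid motion
  with isotropic Gaussian jitter plus random distractor features;
* a labeled decoy database (default 30 actives + 970 inactives) where each
  inactive lacks *all* features of one template type, so it can never match
  the full template;
* a corruption operation that manufactures a prescribed number of false
  negatives (one template feature displaced far beyond tolerance) and false
  positives (inactives given the full template arrangement), reproducing an
  imperfect-retrieval contingency table exactly.

Identifiability margins: template features of the same type are kept at
least ``SAME_TYPE_SEPARATION`` apart and distractors at least
``DISTRACTOR_CLEARANCE`` tolerance radii away from every planted point.
With the default 1.6 Å tolerance these margins guarantee that neither a
jittered same-type feature nor a distractor can stand in for a displaced
feature, so corrupted benchmarks yield their contingency counts exactly for
every seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._geometry import random_rotation
from .core import Conformer, Hypothesis, HypothesisFeature, Molecule
from .features import FeaturePoint, FeatureType, parse_composition

__all__ = [
    "BenchmarkSpec",
    "plant_pharmacophore",
    "make_decoy_benchmark",
    "corrupt_benchmark",
    "write_clouds",
    "read_clouds",
]

#: Minimum separation between any two template features (Å).
MIN_SEPARATION = 2.0
#: Minimum separation between same-type template features (Å).
SAME_TYPE_SEPARATION = 4.5
#: Distractors stay this many tolerance radii from every planted point.
DISTRACTOR_CLEARANCE = 2.5
#: Displacement applied to a corrupted feature (Å) — far beyond any tolerance.
FAR_DISPLACEMENT = 100.0


@dataclass
class BenchmarkSpec:
    """Conditions of a synthetic benchmark.

    Defaults mirror the validation design of the study this package grew out
    of: a 7-feature "RHDDDAA" pharmacophore shared by 8 training compounds,
    and a decoy database of 30 actives among 1000 molecules.  Jitter of
    0.2 Å (an eighth of the 1.6 Å tolerance radius) emulates the residual
    feature scatter of flexible actives; 2 distractor features per cloud
    emulate pharmacophorically irrelevant decoration.
    """

    composition: str = "RHDDDAA"
    n_training: int = 8
    n_actives: int = 30
    n_inactives: int = 970
    jitter_sd: float = 0.2
    extra_features_per_mol: int = 2
    box_size: float = 10.0
    tolerance_radius: float = 1.6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_training, self.n_actives, self.n_inactives,
               self.extra_features_per_mol) < 0:
            raise ValueError("counts must be >= 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.box_size <= 0 or self.tolerance_radius <= 0:
            raise ValueError("box_size and tolerance_radius must be positive")
        parse_composition(self.composition)  # raises on unknown letters

    def to_dict(self) -> dict:
        return {
            "composition": self.composition,
            "n_training": self.n_training,
            "n_actives": self.n_actives,
            "n_inactives": self.n_inactives,
            "jitter_sd": self.jitter_sd,
            "extra_features_per_mol": self.extra_features_per_mol,
            "box_size": self.box_size,
            "tolerance_radius": self.tolerance_radius,
            "seed": self.seed,
        }


def _draw_template(rng: np.random.Generator, types, box: float) -> np.ndarray:
    """Rejection-sample template positions honouring the separation margins."""
    for _restart in range(200):
        positions: list[np.ndarray] = []
        ok = True
        for t in types:
            placed = False
            for _attempt in range(2000):
                p = rng.uniform(0.0, box, size=3)
                if all(
                    np.linalg.norm(p - q)
                    >= (SAME_TYPE_SEPARATION if types[k] == t else MIN_SEPARATION)
                    for k, q in enumerate(positions)
                ):
                    positions.append(p)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(positions)
    raise RuntimeError(
        f"could not place {len(types)} template features in a {box} Å box; "
        "increase box_size"
    )


def _make_cloud(
    rng: np.random.Generator,
    template: Hypothesis,
    mol_id: str,
    jitter_sd: float,
    n_extra: int,
    box: float,
) -> Molecule:
    """One feature cloud: jittered template under a random rigid motion,
    plus distractors kept clear of the planted points."""
    tpos = template.positions()
    local = tpos + (rng.normal(0.0, jitter_sd, tpos.shape) if jitter_sd > 0 else 0.0)
    clearance = DISTRACTOR_CLEARANCE * max(f.tolerance for f in template.features)
    center = tpos.mean(axis=0)
    vocab = list(FeatureType)
    extra_pos, extra_types = [], []
    half = box / 2.0
    for _ in range(n_extra):
        placed = False
        attempts = 0
        while not placed:
            p = center + rng.uniform(-half, half, size=3)
            attempts += 1
            if np.linalg.norm(tpos - p, axis=1).min() >= clearance:
                extra_pos.append(p)
                extra_types.append(vocab[rng.integers(len(vocab))])
                placed = True
            elif attempts % 500 == 0:
                half *= 1.3  # clearance-dominated box: widen the shell
            if attempts > 5000:
                raise RuntimeError("could not place distractor feature; box too small")

    all_local = np.vstack([local] + [p.reshape(1, 3) for p in extra_pos]) if extra_pos else local
    R = random_rotation(rng)
    t = rng.uniform(-20.0, 20.0, size=3)
    coords = all_local @ R.T + t
    types = [f.type for f in template.features] + extra_types
    points = [FeaturePoint(ty, coords[k], (k,)) for k, ty in enumerate(types)]
    return Molecule(
        id=mol_id,
        mol=None,
        conformers=[Conformer(coords, 0.0)],
        feature_sets=[points],
        meta={"synthetic": True, "planted": list(range(len(template.features)))},
    )


def plant_pharmacophore(spec: BenchmarkSpec) -> tuple[Hypothesis, list[Molecule]]:
    """Draw a random template arrangement and a training set containing it.

    Fixed seed gives identical output.  Compositions of fewer than two
    features are rejected as degenerate.
    """
    types = parse_composition(spec.composition)
    if len(types) < 2:
        raise ValueError("template composition must have at least 2 features")
    rng = np.random.default_rng(spec.seed)
    positions = _draw_template(rng, types, spec.box_size)
    template = Hypothesis(
        name=f"template_seed{spec.seed}",
        features=[
            HypothesisFeature(t, p, spec.tolerance_radius, 1.0)
            for t, p in zip(types, positions)
        ],
        config=spec.to_dict(),
    )
    training = [
        _make_cloud(rng, template, f"train_{k:02d}", spec.jitter_sd,
                    spec.extra_features_per_mol, spec.box_size)
        for k in range(spec.n_training)
    ]
    return template, training


def make_decoy_benchmark(
    spec: BenchmarkSpec, template: Hypothesis
) -> tuple[list[Molecule], dict[str, str]]:
    """A labeled decoy database: jittered-template actives plus inactives
    that lack every feature of one (randomly chosen) template type."""
    rng = np.random.default_rng([spec.seed, 1])
    db: list[Molecule] = []
    labels: dict[str, str] = {}
    for k in range(spec.n_actives):
        m = _make_cloud(rng, template, f"active_{k:04d}", spec.jitter_sd,
                        spec.extra_features_per_mol, spec.box_size)
        db.append(m)
        labels[m.id] = "active"

    template_types = sorted({f.type for f in template.features},
                            key=lambda t: t.value)
    vocab = list(FeatureType)
    center = template.positions().mean(axis=0)
    half = spec.box_size / 2.0
    n_points = len(template.features) + spec.extra_features_per_mol
    for k in range(spec.n_inactives):
        missing = template_types[rng.integers(len(template_types))]
        allowed = [t for t in vocab if t != missing]
        pos = center + rng.uniform(-half, half, size=(n_points, 3))
        types = [allowed[i] for i in rng.integers(len(allowed), size=n_points)]
        points = [FeaturePoint(t, pos[i], (i,)) for i, t in enumerate(types)]
        m = Molecule(
            id=f"decoy_{k:04d}",
            mol=None,
            conformers=[Conformer(pos, 0.0)],
            feature_sets=[points],
            meta={"synthetic": True, "missing_type": missing.value},
        )
        db.append(m)
        labels[m.id] = "inactive"
    return db, labels


def corrupt_benchmark(
    db: list[Molecule],
    labels: dict[str, str],
    n_false_neg: int,
    n_false_pos: int,
    seed: int,
    template: Hypothesis,
    jitter_sd: float = 0.0,
) -> list[Molecule]:
    """Manufacture an imperfect-retrieval benchmark.

    ``n_false_neg`` randomly chosen actives get one planted feature displaced
    far beyond tolerance (they can no longer map the full template);
    ``n_false_pos`` randomly chosen inactives are replaced by clouds carrying
    the full template arrangement (they will map).  Labels are unchanged —
    that is the point.  Returns a new database list; untouched molecules are
    shared, modified ones are copies.
    """
    active_idx = [i for i, m in enumerate(db) if labels[m.id] == "active"]
    inactive_idx = [i for i, m in enumerate(db) if labels[m.id] == "inactive"]
    if not 0 <= n_false_neg <= len(active_idx):
        raise ValueError(f"n_false_neg must be in [0, {len(active_idx)}]")
    if not 0 <= n_false_pos <= len(inactive_idx):
        raise ValueError(f"n_false_pos must be in [0, {len(inactive_idx)}]")

    rng = np.random.default_rng(seed)
    new_db = list(db)

    if n_false_neg:
        for sel in sorted(rng.choice(len(active_idx), size=n_false_neg, replace=False)):
            i = active_idx[sel]
            m = db[i].copy()
            planted = m.meta.get("planted", list(range(len(template.features))))
            fi = planted[int(rng.integers(len(planted)))]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            old = m.feature_sets[0][fi]
            new_pos = old.position + direction * FAR_DISPLACEMENT
            m.feature_sets[0][fi] = FeaturePoint(old.type, new_pos, old.atom_indices)
            m.conformers[0].coords[fi] = new_pos
            m.meta["corruption"] = "false_negative"
            new_db[i] = m

    if n_false_pos:
        for sel in sorted(rng.choice(len(inactive_idx), size=n_false_pos, replace=False)):
            i = inactive_idx[sel]
            m = _make_cloud(rng, template, db[i].id, jitter_sd, 0, 1.0)
            m.meta["corruption"] = "false_positive"
            new_db[i] = m
    return new_db


# ---------------------------------------------------------------------------
# feature-cloud JSON IO


def write_clouds(molecules: list[Molecule], path: str | Path) -> None:
    doc = {
        "molecules": [
            {
                "id": m.id,
                "features": [
                    {"type": p.type.value, "position": [float(x) for x in p.position]}
                    for p in m.feature_sets[0]
                ],
                "meta": m.meta,
            }
            for m in molecules
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_clouds(path: str | Path) -> list[Molecule]:
    doc = json.loads(Path(path).read_text())
    molecules = []
    for rec in doc["molecules"]:
        points = [
            FeaturePoint(FeatureType(f["type"]), f["position"], (k,))
            for k, f in enumerate(rec["features"])
        ]
        coords = (
            np.array([p.position for p in points]).reshape(-1, 3)
            if points
            else np.zeros((0, 3))
        )
        molecules.append(
            Molecule(
                id=rec["id"],
                mol=None,
                conformers=[Conformer(coords, 0.0)],
                feature_sets=[points],
                meta=rec.get("meta", {}),
            )
        )
    return molecules
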