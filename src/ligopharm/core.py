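"""Core data model and file IO: molecules, conformers, hypotheses.

Molecules wrap an RDKit ``Mol`` (or ``None`` for synthetic feature clouds)
plus an ordered conformer ensemble with strain energies in kcal/mol relative
to the ensemble minimum.  Hypotheses are ordered sets of typed tolerance
spheres with per-feature weights; they serialize to a small JSON schema.
All coordinates are in Angstrom.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .features import FeaturePoint, FeatureType, composition_string

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # rdkit parse noise is re-reported via logging

__all__ = [
    "Conformer",
    "Molecule",
    "GenerationConfig",
    "HypothesisFeature",
    "Hypothesis",
    "read_molecules",
    "read_hypothesis",
    "write_hypothesis",
]


@dataclass
class Conformer:
    """One 3D geometry: per-atom coordinates (Å) and relative strain energy."""

    coords: np.ndarray
    energy: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.energy < 0:
            raise ValueError("conformer energy must be >= 0 (relative to minimum)")


@dataclass
class Molecule:
    """A structure with identifier, conformer ensemble and optional
    precomputed feature sets (used by synthetic feature clouds)."""

    id: str
    mol: Optional[Chem.Mol] = None
    conformers: list[Conformer] = field(default_factory=list)
    feature_sets: Optional[list[list[FeaturePoint]]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("molecule id must be non-empty")

    def copy(self) -> "Molecule":
        return Molecule(
            id=self.id,
            mol=self.mol,
            conformers=[Conformer(c.coords.copy(), c.energy) for c in self.conformers],
            feature_sets=None
            if self.feature_sets is None
            else [list(fs) for fs in self.feature_sets],
            meta=dict(self.meta),
        )


@dataclass
class GenerationConfig:
    """Parameters governing hypothesis generation and screening.

    Defaults follow common-feature pharmacophore practice: interfeature
    distances of at least 1 Å, up to 300 conformers per molecule inside a
    20 kcal/mol strain window, every training molecule acting as reference
    (principal 2), one feature omittable during generation and none during
    database screening, and 1.6 Å tolerance spheres.
    """

    min_interfeature_distance: float = 1.0
    max_conformers: int = 300
    energy_window: float = 20.0
    principal: int = 2
    max_omit_feat: int = 1
    tolerance_radius: float = 1.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_interfeature_distance", "max_conformers", "energy_window",
                     "principal", "tolerance_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"GenerationConfig.{name} must be positive")
        if self.max_omit_feat < 0:
            raise ValueError("GenerationConfig.max_omit_feat must be >= 0")

    def to_dict(self) -> dict:
        return {
            "min_interfeature_distance": self.min_interfeature_distance,
            "max_conformers": self.max_conformers,
            "energy_window": self.energy_window,
            "principal": self.principal,
            "max_omit_feat": self.max_omit_feat,
            "tolerance_radius": self.tolerance_radius,
            "seed": self.seed,
        }


@dataclass
class HypothesisFeature:
    """A typed tolerance sphere: position (Å), radius (Å) and weight."""

    type: FeatureType
    position: np.ndarray
    tolerance: float = 1.6
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.type = FeatureType(self.type)
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.tolerance <= 0:
            raise ValueError("feature tolerance must be positive")
        if self.weight < 0:
            raise ValueError("feature weight must be >= 0")

    def as_point(self, index: int = 0) -> FeaturePoint:
        return FeaturePoint(self.type, self.position, (index,))


@dataclass
class Hypothesis:
    """A pharmacophore model: ordered typed feature spheres plus bookkeeping.

    ``direct_hit_mask``/``partial_hit_mask`` are per-training-molecule bit
    strings ("11111111" = every molecule maps with no omitted feature).
    ``max_fit`` — the fit value of a perfect mapping — is the sum of weights.
    """

    name: str
    features: list[HypothesisFeature]
    composition: str = ""
    rank: float = 0.0
    direct_hit_mask: str = ""
    partial_hit_mask: str = ""
    config: Optional[dict] = None

    def __post_init__(self) -> None:
        if not self.composition:
            self.composition = composition_string(self.features)

    @property
    def max_fit(self) -> float:
        return float(sum(f.weight for f in self.features))

    def feature_points(self) -> list[FeaturePoint]:
        return [f.as_point(i) for i, f in enumerate(self.features)]

    def positions(self) -> np.ndarray:
        return np.array([f.position for f in self.features]).reshape(-1, 3)


# ---------------------------------------------------------------------------
# molecule readers


def _largest_fragment(mol: Chem.Mol, record: str) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) <= 1:
        return mol
    best = max(frags, key=lambda f: f.GetNumHeavyAtoms())
    logger.warning(
        "record %s: multi-fragment structure, keeping largest fragment (%d heavy atoms)",
        record, best.GetNumHeavyAtoms(),
    )
    return best


def _read_smiles(path: Path) -> list[Molecule]:
    molecules: list[Molecule] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                skipped += 1
                logger.warning("line %d: unparsable SMILES %r, skipped", lineno + 1, smiles)
                continue
            mol = _largest_fragment(mol, f"line {lineno + 1}")
            mol_id = parts[1] if len(parts) > 1 else f"mol_{len(molecules)}"
            molecules.append(Molecule(id=mol_id, mol=mol))
    if skipped:
        logger.warning("%d record(s) skipped while reading %s", skipped, path)
    return molecules


def _read_sdf(path: Path) -> list[Molecule]:
    molecules: list[Molecule] = []
    skipped = 0
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            skipped += 1
            logger.warning("SDF record %d unparsable, skipped", i)
            continue
        mol_id = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        if not mol_id:
            mol_id = f"mol_{len(molecules)}"
        conformers = []
        if mol.GetNumConformers() > 0 and mol.GetConformer().Is3D():
            conformers.append(Conformer(np.array(mol.GetConformer().GetPositions())))
        molecules.append(Molecule(id=mol_id, mol=mol, conformers=conformers))
    if skipped:
        logger.warning("%d record(s) skipped while reading %s", skipped, path)
    return molecules


def read_molecules(path: str | Path, format: str | None = None) -> list[Molecule]:
    """Read a SMILES (.smi: ``SMILES [id]`` per line) or SDF V2000 file.

    Unparsable records are skipped with a logged warning; input order is
    preserved; missing ids become ``mol_<index>``.  SDF 3D coordinates, when
    present, are trusted as conformer 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"molecule file not found: {path}")
    if format is None:
        format = "sdf" if path.suffix.lower() == ".sdf" else "smiles"
    if format == "smiles":
        mols = _read_smiles(path)
    elif format == "sdf":
        mols = _read_sdf(path)
    else:
        raise ValueError(f"unknown molecule format {format!r}")
    seen: set[str] = set()
    for m in mols:
        if m.id in seen:
            logger.warning("duplicate molecule id %r", m.id)
        seen.add(m.id)
    return mols


# ---------------------------------------------------------------------------
# hypothesis JSON IO
#
# {"name": str,
#  "features": [{"type": "A|D|H|PI|R", "position": [x,y,z],
#                "tolerance": float, "weight": float}, ...],
#  "composition": str, "rank": float, "config": {...}}


def write_hypothesis(h: Hypothesis, path: str | Path) -> None:
    doc = {
        "name": h.name,
        "features": [
            {
                "type": f.type.value,
                "position": [float(x) for x in f.position],
                "tolerance": float(f.tolerance),
                "weight": float(f.weight),
            }
            for f in h.features
        ],
        "composition": h.composition,
        "rank": float(h.rank),
        "direct_hit_mask": h.direct_hit_mask,
        "partial_hit_mask": h.partial_hit_mask,
        "config": h.config,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def _require(doc: dict, key: str, context: str):
    if key not in doc:
        raise ValueError(f"hypothesis file invalid: {context} missing {key!r}")
    return doc[key]


def read_hypothesis(path: str | Path) -> Hypothesis:
    """Read a hypothesis JSON file, validating the schema.

    Schema violations raise ``ValueError`` naming the offending field
    (e.g. ``features[3] missing 'tolerance'``).
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"hypothesis file invalid: not JSON ({exc})") from exc
    name = _require(doc, "name", "document")
    raw_features = _require(doc, "features", "document")
    features = []
    for i, rf in enumerate(raw_features):
        ctx = f"features[{i}]"
        ftype = _require(rf, "type", ctx)
        try:
            ftype = FeatureType(ftype)
        except ValueError:
            raise ValueError(f"hypothesis file invalid: {ctx} unknown type {ftype!r}") from None
        position = _require(rf, "position", ctx)
        if not isinstance(position, (list, tuple)) or len(position) != 3:
            raise ValueError(f"hypothesis file invalid: {ctx} position must be [x,y,z]")
        tolerance = _require(rf, "tolerance", ctx)
        weight = _require(rf, "weight", ctx)
        features.append(HypothesisFeature(ftype, position, float(tolerance), float(weight)))
    return Hypothesis(
        name=name,
        features=features,
        composition=doc.get("composition", ""),
        rank=float(doc.get("rank", 0.0)),
        direct_hit_mask=doc.get("direct_hit_mask", ""),
        partial_hit_mask=doc.get("partial_hit_mask", ""),
        config=doc.get("config"),
    )
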