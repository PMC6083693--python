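"""Pharmacophoric feature perception.

A pharmacophore abstracts a ligand into the handful of interaction points
that matter for binding: hydrogen-bond acceptors (A) and donors (D),
hydrophobic groups (H), positive-ionizable centres (PI) and aromatic-ring
centroids (R).  This module maps a 3D conformer to such typed points using
configurable SMARTS substructure definitions in the Catalyst/HipHop
tradition.  The shipped defaults are deliberately conservative:

* D  — any O-H or N-H (including protonated nitrogens and aromatic N-H);
* A  — neutral N/O lone-pair bearers, excluding amide/sulfonamide nitrogens,
       anilines and pyrrole-type aromatic N-H;
* PI — formally positive centres plus readily protonated nitrogens
       (primary aliphatic amines, amidine/guanidine nitrogens);
* H  — connected groups of saturated carbons with no heteroatom neighbour,
       and heavy halogens; one point per connected group, at its centroid;
* R  — 5- and 6-membered aromatic rings, one point at the ring centroid.

Synthetic benchmark molecules carry precomputed feature clouds and bypass
perception entirely (see :mod:`ligopharm.synthetic`).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

__all__ = [
    "FeatureType",
    "FeaturePoint",
    "FeatureDefs",
    "perceive_features",
    "get_feature_sets",
    "composition_string",
    "parse_composition",
    "COMPOSITION_ORDER",
]


class FeatureType(str, enum.Enum):
    """The closed five-type pharmacophoric feature vocabulary."""

    ACCEPTOR = "A"
    DONOR = "D"
    HYDROPHOBE = "H"
    POSITIVE = "PI"
    AROMATIC = "R"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical ordering used when rendering composition strings: "RHDDDAA".
COMPOSITION_ORDER: tuple[FeatureType, ...] = (
    FeatureType.AROMATIC,
    FeatureType.HYDROPHOBE,
    FeatureType.DONOR,
    FeatureType.ACCEPTOR,
    FeatureType.POSITIVE,
)

_ORDER_INDEX = {t: i for i, t in enumerate(COMPOSITION_ORDER)}


@dataclass(frozen=True)
class FeaturePoint:
    """A typed pharmacophoric point at the centroid of its contributing atoms.

    For synthetic feature clouds ``atom_indices`` is a bookkeeping index
    rather than a real atom reference.
    """

    type: FeatureType
    position: np.ndarray
    atom_indices: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )
        if len(self.atom_indices) == 0:
            raise ValueError("FeaturePoint requires at least one contributing atom")


_DEFAULT_PATTERNS: dict[FeatureType, list[str]] = {
    FeatureType.DONOR: [
        "[#7;!H0]",
        "[#8;!H0;+0]",
    ],
    FeatureType.ACCEPTOR: [
        "[OX1;+0]",
        "[OX2;+0]",
        "[NX1;+0]",
        "[NX2;+0;!$([NX2]=O)]",
        "[nX2;+0]",
        "[NX3;+0;!$([NX3][C,S,P]=[O,S,N]);!$([NX3]a);!$([NX4])]",
    ],
    FeatureType.POSITIVE: [
        "[+1;!$([*+1]~[*-1])]",
        "[NX3;H2;+0;$([NX3][CX4])]",
        "[NX3;+0;$([NX3][CX3]=[NX2])]",
    ],
    FeatureType.HYDROPHOBE: [
        "[CX4;+0;!$([CX4]~[#7,#8,#15,#16])]",
        "[Cl,Br,I;X1]",
    ],
    FeatureType.AROMATIC: [
        "a1aaaaa1",
        "a1aaaa1",
    ],
}

#: Feature types whose matched atoms are clustered into connected groups
#: with one point per group (rather than one point per match).
_GROUPED_TYPES = frozenset({FeatureType.HYDROPHOBE})


@dataclass
class FeatureDefs:
    """SMARTS-based feature definitions.

    ``patterns`` maps each :class:`FeatureType` to a list of SMARTS strings.
    Matches of D/A/PI/R patterns each yield one point at the centroid of the
    matched atoms; hydrophobe matches are first merged into bond-connected
    groups.  Same-type points closer than ``merge_radius`` are collapsed to
    their centroid to avoid redundant points inflating the clique search.
    """

    patterns: dict[FeatureType, list[str]] = field(
        default_factory=lambda: {t: list(p) for t, p in _DEFAULT_PATTERNS.items()}
    )
    merge_radius: float = 0.5

    def __post_init__(self) -> None:
        self._compiled: dict[FeatureType, list[Chem.Mol]] = {}
        for ftype, smarts_list in self.patterns.items():
            ftype = FeatureType(ftype)
            compiled = []
            for smarts in smarts_list:
                patt = Chem.MolFromSmarts(smarts)
                if patt is None:
                    raise ValueError(
                        f"invalid SMARTS for feature type {ftype.value!r}: {smarts!r}"
                    )
                compiled.append(patt)
            self._compiled[ftype] = compiled

    @classmethod
    def default(cls) -> "FeatureDefs":
        return cls()

    @classmethod
    def from_file(cls, path: str | Path) -> "FeatureDefs":
        """Load definitions from a JSON or YAML mapping {type: [SMARTS, ...]}."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        patterns = {FeatureType(k): list(v) for k, v in raw.items()}
        return cls(patterns=patterns)

    def compiled(self, ftype: FeatureType) -> list[Chem.Mol]:
        return self._compiled.get(ftype, [])


def _connected_groups(mol: Chem.Mol, atoms: set[int]) -> list[tuple[int, ...]]:
    """Split an atom set into bond-connected components (sorted, deterministic)."""
    remaining = set(atoms)
    groups = []
    while remaining:
        seed = min(remaining)
        comp = {seed}
        frontier = [seed]
        while frontier:
            a = frontier.pop()
            for nbr in mol.GetAtomWithIdx(a).GetNeighbors():
                i = nbr.GetIdx()
                if i in remaining and i not in comp:
                    comp.add(i)
                    frontier.append(i)
        remaining -= comp
        groups.append(tuple(sorted(comp)))
    return sorted(groups)


def _merge_close(points: list[FeaturePoint], radius: float) -> list[FeaturePoint]:
    """Collapse same-type points closer than ``radius`` (single-linkage)."""
    out: list[FeaturePoint] = []
    by_type: dict[FeatureType, list[FeaturePoint]] = {}
    for p in points:
        by_type.setdefault(p.type, []).append(p)
    for ftype in sorted(by_type, key=lambda t: _ORDER_INDEX[t]):
        pts = by_type[ftype]
        n = len(pts)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if np.linalg.norm(pts[i].position - pts[j].position) < radius:
                    parent[find(i)] = find(j)
        clusters: dict[int, list[FeaturePoint]] = {}
        for i in range(n):
            clusters.setdefault(find(i), []).append(pts[i])
        for members in clusters.values():
            if len(members) == 1:
                out.append(members[0])
            else:
                pos = np.mean([m.position for m in members], axis=0)
                atoms = tuple(sorted({a for m in members for a in m.atom_indices}))
                out.append(FeaturePoint(ftype, pos, atoms))
    out.sort(key=lambda p: (_ORDER_INDEX[p.type], p.atom_indices))
    return out


def _perceive(mol: Chem.Mol, coords: np.ndarray, defs: FeatureDefs) -> list[FeaturePoint]:
    points: list[FeaturePoint] = []
    for ftype in COMPOSITION_ORDER:
        matched_atom_sets: list[tuple[int, ...]] = []
        if ftype in _GROUPED_TYPES:
            atoms: set[int] = set()
            for patt in defs.compiled(ftype):
                for match in mol.GetSubstructMatches(patt, uniquify=True):
                    atoms.update(match)
            matched_atom_sets = _connected_groups(mol, atoms)
        else:
            seen: set[tuple[int, ...]] = set()
            for patt in defs.compiled(ftype):
                for match in mol.GetSubstructMatches(patt, uniquify=True):
                    key = tuple(sorted(match))
                    if key not in seen:
                        seen.add(key)
                        matched_atom_sets.append(key)
            matched_atom_sets.sort()
        for atom_set in matched_atom_sets:
            pos = coords[list(atom_set)].mean(axis=0)
            points.append(FeaturePoint(ftype, pos, atom_set))
    return _merge_close(points, defs.merge_radius)


def perceive_features(molecule, conformer: int = 0, defs: FeatureDefs | None = None) -> list[FeaturePoint]:
    """Perceive the typed feature points of one conformer of ``molecule``.

    Synthetic molecules carrying precomputed ``feature_sets`` return those
    directly; chemical molecules are matched against ``defs`` (the shipped
    defaults when ``None``) using the conformer's 3D coordinates.
    """
    if getattr(molecule, "feature_sets", None) is not None:
        return list(molecule.feature_sets[conformer])
    if molecule.mol is None or not molecule.conformers:
        raise ValueError(
            f"molecule {molecule.id!r} has no 3D conformers; "
            "run conformer generation (ligopharm.confgen.generate_conformers) first"
        )
    defs = defs or FeatureDefs.default()
    coords = np.asarray(molecule.conformers[conformer].coords, dtype=float)
    return _perceive(molecule.mol, coords, defs)


def get_feature_sets(molecule, defs: FeatureDefs | None = None) -> list[list[FeaturePoint]]:
    """Feature points for every conformer of ``molecule`` (cached for clouds)."""
    if getattr(molecule, "feature_sets", None) is not None:
        return [list(fs) for fs in molecule.feature_sets]
    return [
        perceive_features(molecule, i, defs) for i in range(len(molecule.conformers))
    ]


def _types_of(obj) -> list[FeatureType]:
    if hasattr(obj, "features"):  # Hypothesis-like
        obj = obj.features
    types = []
    for item in obj:
        if isinstance(item, FeatureType):
            types.append(item)
        else:
            types.append(FeatureType(item.type))
    return types


def composition_string(obj: Iterable | object) -> str:
    """Render a feature multiset in canonical order R, H, D, A, PI.

    E.g. one ring, one hydrophobe, three donors and two acceptors give
    ``"RHDDDAA"``.
    """
    types = _types_of(obj)
    counts = {t: 0 for t in COMPOSITION_ORDER}
    for t in types:
        counts[t] += 1
    return "".join(t.value * counts[t] for t in COMPOSITION_ORDER)


def parse_composition(s: str) -> list[FeatureType]:
    """Inverse of :func:`composition_string` ('PI' is a two-letter token)."""
    out: list[FeatureType] = []
    i = 0
    while i < len(s):
        if s[i] == "P":
            if i + 1 >= len(s) or s[i + 1] != "I":
                raise ValueError(f"invalid composition string {s!r} at position {i}")
            out.append(FeatureType.POSITIVE)
            i += 2
        else:
            try:
                out.append(FeatureType(s[i]))
            except ValueError:
                raise ValueError(
                    f"invalid composition string {s!r}: unknown feature {s[i]!r}"
                ) from None
            i += 1
    return out
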