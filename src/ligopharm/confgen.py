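"""Conformer ensemble generation.

Produces a bounded, energy-windowed conformer ensemble per molecule:
distance-geometry embedding (ETKDG) followed by force-field relaxation
(MMFF94 when parameterized, UFF otherwise).  Energies are stored relative
to the ensemble minimum in kcal/mol; conformers outside the window are
dropped, near-duplicates (RMSD < 0.5 Å) are pruned at embedding time, and
the ensemble is sorted by increasing strain.  Fixed seeds give identical
ensembles.
"""

from __future__ import annotations

import logging

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .core import Conformer, GenerationConfig, Molecule

logger = logging.getLogger(__name__)

__all__ = ["generate_conformers"]

#: RMSD below which two embedded conformers are considered duplicates.
DUPLICATE_RMSD = 0.5


def generate_conformers(molecule: Molecule, cfg: GenerationConfig | None = None) -> Molecule:
    """Populate ``molecule.conformers`` in place (and return the molecule).

    Raises ``RuntimeError`` naming the molecule if embedding fails after a
    randomized retry.  The returned ensemble satisfies
    ``1 <= len <= cfg.max_conformers`` and
    ``max(energy) - min(energy) <= cfg.energy_window``.
    """
    cfg = cfg or GenerationConfig()
    if molecule.mol is None:
        raise ValueError(f"molecule {molecule.id!r} has no chemical structure to embed")
    mol = Chem.AddHs(molecule.mol)

    params = AllChem.ETKDGv3()
    params.randomSeed = int(cfg.seed) & 0x7FFFFFFF
    params.pruneRmsThresh = DUPLICATE_RMSD
    params.numThreads = 1
    cids = list(AllChem.EmbedMultipleConfs(mol, numConfs=cfg.max_conformers, params=params))
    if not cids:
        params.useRandomCoords = True
        params.randomSeed = (int(cfg.seed) + 1) & 0x7FFFFFFF
        cids = list(AllChem.EmbedMultipleConfs(mol, numConfs=cfg.max_conformers, params=params))
    if not cids:
        raise RuntimeError(f"conformer embedding failed for molecule {molecule.id!r}")

    if AllChem.MMFFHasAllMoleculeParams(mol):
        results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=500)
    else:
        logger.warning("molecule %s lacks MMFF parameters; using UFF", molecule.id)
        results = AllChem.UFFOptimizeMoleculeConfs(mol, maxIters=500)
    energies = np.array([e for _, e in results], dtype=float)
    emin = energies.min()
    rel = energies - emin

    keep = [(rel[k], cid) for k, cid in enumerate(cids) if rel[k] <= cfg.energy_window]
    keep.sort(key=lambda t: (t[0], t[1]))
    keep = keep[: cfg.max_conformers]

    conformers = [
        Conformer(np.array(mol.GetConformer(cid).GetPositions()), float(e))
        for e, cid in keep
    ]
    molecule.mol = mol  # keep explicit hydrogens so coords match atom indices
    molecule.conformers = conformers
    return molecule
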