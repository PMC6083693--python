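"""Common-feature pharmacophore hypothesis generation (HipHop-style).

Given a training set of actives, the generator looks for 3D arrangements of
typed features shared by every molecule, without using activity magnitudes.
The search is a classical correspondence-graph formulation: a node pairs a
reference feature with a same-type feature of another molecule, an edge
joins two pairs whose intra-molecular distances agree within a tolerance,
and maximal cliques are exactly the maximal rigid-compatible feature
correspondences.  Each training molecule in turn acts as the reference
(principal value 2); candidate hypotheses are subsets of reference features
supported by every molecule within the allowed number of omitted features,
their positions refined by Kabsch-consensus over the contributing
molecules, and the pooled hypotheses deduplicated and ranked.

The rank rewards breadth and size of matching while penalizing omissions:

    rank(H) = max(0, sum over training molecules of
                     (best_fit(molecule, H) - omega * omitted(molecule, H)))
              + lambda * |features(H)|     (lambda = 1, omega = 2 by default)

The omission penalty omega exceeds the largest possible per-feature fit
contribution plus the size bonus share, so a feature matched by only a
minority of the training set costs more than it earns: hypotheses decorated
with molecule-specific features cannot outrank the truly common arrangement.
This scale is this package's own; it is not comparable to the rank values
printed by commercial common-feature implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._geometry import kabsch_align
from .core import GenerationConfig, Hypothesis, HypothesisFeature, Molecule
from .features import (
    COMPOSITION_ORDER,
    FeatureDefs,
    FeaturePoint,
    get_feature_sets,
)

__all__ = [
    "Correspondence",
    "enumerate_common_cliques",
    "generate_hypotheses",
    "rank_hypothesis",
]

_ORDER_INDEX = {t: i for i, t in enumerate(COMPOSITION_ORDER)}

#: Upper bound on candidate feature subsets examined per reference conformer.
MAX_CANDIDATES = 200

#: Weight of the hypothesis-size bonus in the rank score.
RANK_SIZE_BONUS = 1.0

#: Rank penalty per omitted feature per molecule (fit units).
OMISSION_PENALTY = 2.0


@dataclass(frozen=True)
class Correspondence:
    """A one-to-one, type-consistent pairing of reference feature indices
    with feature indices of another molecule."""

    pairs: tuple[tuple[int, int], ...]
    unmatched_ref: tuple[int, ...] = ()

    @property
    def size(self) -> int:
        return len(self.pairs)

    def ref_indices(self) -> frozenset[int]:
        return frozenset(p[0] for p in self.pairs)


def enumerate_common_cliques(
    ref_feats: list[FeaturePoint],
    other_feats: list[FeaturePoint],
    dist_tol: float,
) -> list[Correspondence]:
    """All maximal type- and distance-compatible feature correspondences.

    Two pairs (i,j) and (k,l) are compatible when i!=k, j!=l and
    ``|dist(ref_i, ref_k) - dist(other_j, other_l)| <= dist_tol``.  Returned
    correspondences are maximal cliques of the compatibility graph, ordered
    by size descending then lexicographically — a deterministic order.
    """
    if dist_tol <= 0:
        raise ValueError("dist_tol must be positive")
    nodes = [
        (i, j)
        for i in range(len(ref_feats))
        for j in range(len(other_feats))
        if ref_feats[i].type == other_feats[j].type
    ]
    if not nodes:
        return []
    rpos = np.array([f.position for f in ref_feats]).reshape(-1, 3)
    opos = np.array([f.position for f in other_feats]).reshape(-1, 3)
    dref = squareform(pdist(rpos)) if len(ref_feats) > 1 else np.zeros((1, 1))
    doth = squareform(pdist(opos)) if len(other_feats) > 1 else np.zeros((1, 1))

    graph = nx.Graph()
    graph.add_nodes_from(range(len(nodes)))
    for a in range(len(nodes)):
        i, j = nodes[a]
        for b in range(a + 1, len(nodes)):
            k, l = nodes[b]
            if i != k and j != l and abs(dref[i, k] - doth[j, l]) <= dist_tol:
                graph.add_edge(a, b)

    n_ref = len(ref_feats)
    corrs = []
    for clique in nx.find_cliques(graph):
        pairs = tuple(sorted(nodes[a] for a in clique))
        matched = {p[0] for p in pairs}
        unmatched = tuple(i for i in range(n_ref) if i not in matched)
        corrs.append(Correspondence(pairs, unmatched))
    corrs.sort(key=lambda c: (-c.size, c.pairs))
    return corrs


def _consensus_positions(
    ref_feats: list[FeaturePoint],
    subset: tuple[int, ...],
    contributions: list[tuple[list[FeaturePoint], Correspondence]],
) -> dict[int, np.ndarray]:
    """Average matched feature positions across molecules after rigid
    alignment of each molecule's matched points onto the reference."""
    sums = {i: [ref_feats[i].position] for i in subset}
    sset = set(subset)
    for feats, corr in contributions:
        pairs = [(i, j) for i, j in corr.pairs if i in sset]
        if len(pairs) < 3:
            continue  # alignment underdetermined; reference positions suffice
        P = np.array([feats[j].position for _, j in pairs])
        Q = np.array([ref_feats[i].position for i, _ in pairs])
        aligned = kabsch_align(P, Q)
        for (i, _), p in zip(pairs, aligned):
            sums[i].append(p)
    return {i: np.mean(v, axis=0) for i, v in sums.items()}


def _duplicate(h1: Hypothesis, h2: Hypothesis, tol: float) -> bool:
    """Same composition and same pairwise-distance multiset within tol."""
    if h1.composition != h2.composition:
        return False
    if len(h1.features) != len(h2.features):
        return False
    if len(h1.features) < 2:
        return True
    d1 = np.sort(pdist(h1.positions()))
    d2 = np.sort(pdist(h2.positions()))
    return bool(np.allclose(d1, d2, atol=tol))


def _rank_score(
    fits_and_omits: list[tuple[float, int]],
    n_features: int,
    size_bonus: float,
    omission_penalty: float,
) -> float:
    base = sum(fit - omission_penalty * omitted for fit, omitted in fits_and_omits)
    return max(0.0, base) + size_bonus * n_features


def rank_hypothesis(
    h: Hypothesis,
    training: list[Molecule],
    cfg: GenerationConfig | None = None,
    defs: FeatureDefs | None = None,
    size_bonus: float = RANK_SIZE_BONUS,
    omission_penalty: float = OMISSION_PENALTY,
) -> float:
    """Rank = omission-penalized fit sum over the training set + size bonus.

    An empty hypothesis ranks 0; a molecule that fails to map contributes 0.
    """
    if not h.features:
        return 0.0
    from .screening import map_ligand

    cfg = cfg or GenerationConfig()
    scored = []
    for m in training:
        result = map_ligand(h, m, max_omit=cfg.max_omit_feat, defs=defs)
        if result is not None:
            scored.append((result.fit, result.omitted))
    return _rank_score(scored, len(h.features), size_bonus, omission_penalty)


def generate_hypotheses(
    training: list[Molecule],
    defs: FeatureDefs | None = None,
    cfg: GenerationConfig | None = None,
    max_hypotheses: int = 10,
    size_bonus: float = RANK_SIZE_BONUS,
    omission_penalty: float = OMISSION_PENALTY,
) -> list[Hypothesis]:
    """Derive up to ``max_hypotheses`` ranked common-feature hypotheses.

    Every training molecule serves in turn as the reference (principal 2
    semantics); each returned hypothesis respects the minimum interfeature
    distance, is mappable by every training molecule with at most
    ``cfg.max_omit_feat`` omissions, and carries direct/partial hit masks in
    training order.  Sorting is by rank descending with ties broken by
    composition string, then creation order.
    """
    from .screening import map_ligand

    cfg = cfg or GenerationConfig()
    if len(training) < 2:
        raise ValueError("hypothesis generation needs at least 2 training molecules")
    featsets = [get_feature_sets(m, defs) for m in training]
    for m, fs in zip(training, featsets):
        if not any(fs):
            raise ValueError(
                f"training molecule {m.id!r} has no pharmacophoric features"
            )

    pool: list[tuple[Hypothesis, int]] = []
    creation = 0
    for ref_idx, ref in enumerate(training):
        for rfeats in featsets[ref_idx]:
            if not rfeats:
                continue
            # maximal correspondences of every other molecule vs this reference
            per_mol: list[list[tuple[frozenset[int], list[FeaturePoint], Correspondence]]] = []
            for m_idx in range(len(training)):
                if m_idx == ref_idx:
                    continue
                entries = []
                for feats in featsets[m_idx]:
                    if not feats:
                        continue
                    for corr in enumerate_common_cliques(rfeats, feats, cfg.tolerance_radius):
                        entries.append((corr.ref_indices(), feats, corr))
                per_mol.append(entries)

            candidates: set[frozenset[int]] = set()
            for entries in per_mol:
                candidates.update(s for s, _, _ in entries)
            base = sorted(candidates, key=lambda s: (-len(s), tuple(sorted(s))))
            for a in range(len(base)):
                for b in range(a + 1, len(base)):
                    inter = base[a] & base[b]
                    if len(inter) >= 2:
                        candidates.add(inter)
            ordered = [
                S
                for S in sorted(candidates, key=lambda s: (-len(s), tuple(sorted(s))))
                if len(S) >= 2
            ][:MAX_CANDIDATES]

            for S in ordered:
                subset = tuple(sorted(S))
                rp = np.array([rfeats[i].position for i in subset])
                if pdist(rp).min() < cfg.min_interfeature_distance:
                    continue
                # support: every molecule must cover S within the omission budget
                picks = []
                supported = True
                for entries in per_mol:
                    best_cov, best_entry = -1, None
                    for refset, feats, corr in entries:
                        cov = len(refset & S)
                        if cov > best_cov:
                            best_cov, best_entry = cov, (feats, corr)
                    if best_entry is None or len(S) - best_cov > cfg.max_omit_feat:
                        supported = False
                        break
                    picks.append(best_entry)
                if not supported:
                    continue

                positions = _consensus_positions(rfeats, subset, picks)
                order = sorted(subset, key=lambda i: (_ORDER_INDEX[rfeats[i].type], i))
                feats_h = [
                    HypothesisFeature(
                        rfeats[i].type, positions[i], cfg.tolerance_radius, 1.0
                    )
                    for i in order
                ]
                if pdist(np.array([f.position for f in feats_h])).min() < cfg.min_interfeature_distance:
                    continue
                h = Hypothesis(name=f"cand_{creation}", features=feats_h, config=cfg.to_dict())

                results = []
                for m in training:
                    r = map_ligand(h, m, max_omit=cfg.max_omit_feat, defs=defs)
                    if r is None:
                        break
                    results.append(r)
                if len(results) < len(training):
                    continue
                direct = []
                for m, r in zip(training, results):
                    if r.omitted == 0:
                        direct.append(True)
                    else:
                        direct.append(map_ligand(h, m, max_omit=0, defs=defs) is not None)
                h.direct_hit_mask = "".join("1" if b else "0" for b in direct)
                h.partial_hit_mask = "".join("0" if b else "1" for b in direct)
                h.rank = _rank_score(
                    [(r.fit, r.omitted) for r in results],
                    len(h.features), size_bonus, omission_penalty,
                )
                pool.append((h, creation))
                creation += 1

    pool.sort(key=lambda t: (-t[0].rank, t[0].composition, t[1]))
    kept: list[Hypothesis] = []
    for h, _ in pool:
        if any(_duplicate(h, k, cfg.tolerance_radius) for k in kept):
            continue
        kept.append(h)
        if len(kept) >= max_hypotheses:
            break
    for i, h in enumerate(kept):
        h.name = f"hypo_{i + 1}"
    return kept
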