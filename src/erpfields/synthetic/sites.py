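"""Maximin observation-site designs over admissible mesh vertices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..manifold.mesh import TriangleMeshManifold

__all__ = ["ObservationDesign", "design_observation_sites"]

#: Sites within this distance (mm) of a mesh boundary are inadmissible;
#: clinical measurements are unlikely to sample near vein openings.
DEFAULT_EXCLUSION_MM = 6.0


@dataclass(frozen=True)
class ObservationDesign:
    vertex_ids: np.ndarray
    exclusion_radius: float  # mm
    criterion: float         # achieved min pairwise distance (mm)

    @property
    def n(self) -> int:
        return len(self.vertex_ids)


def design_observation_sites(
    mesh: TriangleMeshManifold,
    n: int,
    *,
    exclusion_radius: float = DEFAULT_EXCLUSION_MM,
    seed=0,
    n_exchange: int = 500,
) -> ObservationDesign:
    """Greedy farthest-point selection followed by random-exchange maximin
    improvement, restricted to vertices at least exclusion_radius (graph
    distance, mm) from any boundary vertex.

    The maximin criterion is non-decreasing over the exchange iterations.
    """
    bdist = mesh.distance_to_boundary()
    admissible = np.flatnonzero(bdist >= exclusion_radius)
    if len(admissible) < n:
        raise ValueError(
            f"only {len(admissible)} admissible vertices for n={n} sites "
            f"(exclusion {exclusion_radius:g} mm)"
        )
    rng = np.random.default_rng(seed)
    pts = mesh.vertices[admissible]

    # greedy farthest-point from a random admissible start
    chosen = [int(rng.integers(len(admissible)))]
    d_min = np.linalg.norm(pts - pts[chosen[0]], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(d_min))
        chosen.append(nxt)
        d_min = np.minimum(d_min, np.linalg.norm(pts - pts[nxt], axis=1))

    def criterion(sel):
        p = pts[sel]
        d = np.linalg.norm(p[:, None] - p[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        return float(d.min())

    sel = np.array(chosen)
    best = criterion(sel)
    for _ in range(n_exchange):
        i = int(rng.integers(n))
        cand = int(rng.integers(len(admissible)))
        if cand in sel:
            continue
        trial = sel.copy()
        trial[i] = cand
        c = criterion(trial)
        if c > best:
            sel, best = trial, c

    ids = np.sort(admissible[sel])
    return ObservationDesign(
        vertex_ids=ids, exclusion_radius=exclusion_radius, criterion=best
    )
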