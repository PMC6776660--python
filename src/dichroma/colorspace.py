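"""Tetrahedral color space and color-diversity indices.

Relative quantum catches (u, s, m, l) map to Cartesian coordinates inside
the tetrachromat color tetrahedron, with the achromatic point (equal
stimulation) at the origin and each vertex the pure stimulation of one
cone class. On a set of color loci we compute the classic diversity
summary: relative color volume (convex-hull volume over the full
tetrahedron's volume), color span (mean/variance of pairwise euclidean
distances — chroma-sensitive), hue disparity (mean/variance of pairwise
angles between origin-to-locus vectors — chroma-free), and the UV
centroid (mean relative stimulation of the UVS cone, used to detect
cryptic UV dichromatism).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .errors import DegenerateInputError

#: Names of the six diversity indices, in reporting order.
INDEX_NAMES = (
    "rel.c.vol",
    "huedisp.m",
    "huedisp.v",
    "colspan.m",
    "colspan.v",
    "uv.centroid",
)

_ORIGIN_TOL = 1e-12
_VOLUME_TOL = 1e-12


def to_tetrahedral(q: np.ndarray) -> np.ndarray:
    """Map relative catches (u, s, m, l) to tetrahedral (x, y, z).

        x = ((1 - 2 s - m - u) / 2) * sqrt(3/2)
        y = (-1 + 3 m + u) / (2 sqrt 2)
        z = u - 1/4

    The achromatic point (1/4, 1/4, 1/4, 1/4) maps to the origin. Accepts
    a single catch vector or an (n, 4) matrix.
    """
    single = np.asarray(q).ndim == 1
    q = np.atleast_2d(np.asarray(q, float))
    if q.shape[1] != 4:
        raise DegenerateInputError("relative catches must have 4 channels")
    if np.any(q < -1e-12):
        raise DegenerateInputError("relative catches must be nonnegative")
    sums = q.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        raise DegenerateInputError("relative catches must sum to 1")
    u, s, m = q[:, 0], q[:, 1], q[:, 2]
    x = ((1.0 - 2.0 * s - m - u) / 2.0) * np.sqrt(1.5)
    y = (-1.0 + 3.0 * m + u) / (2.0 * np.sqrt(2.0))
    z = u - 0.25
    xyz = np.column_stack([x, y, z])
    return xyz[0] if single else xyz


#: Vertices of the reference tetrahedron: pure u, s, m, l stimulation.
TETRAHEDRON_VERTICES = to_tetrahedral(np.eye(4))


def _tetrahedron_volume(vertices: np.ndarray) -> float:
    a, b, c, d = vertices
    return abs(np.linalg.det(np.stack([a - d, b - d, c - d]))) / 6.0


@dataclass(frozen=True)
class VolumeResult:
    relative: float
    degenerate: bool


def color_volume(xyz: np.ndarray) -> VolumeResult:
    """Convex-hull volume of the loci, relative to the full tetrahedron.

    Fewer than 4 loci, or (near-)coplanar loci, give volume 0 with the
    ``degenerate`` flag set.
    """
    xyz = np.atleast_2d(np.asarray(xyz, float))
    full = _tetrahedron_volume(TETRAHEDRON_VERTICES)
    if xyz.shape[0] < 4:
        return VolumeResult(0.0, True)
    try:
        hull = ConvexHull(xyz)
    except QhullError:
        return VolumeResult(0.0, True)
    if hull.volume < _VOLUME_TOL:
        return VolumeResult(0.0, True)
    return VolumeResult(hull.volume / full, False)


def color_span(xyz: np.ndarray) -> tuple[float, float]:
    """Mean and population variance of pairwise euclidean distances."""
    xyz = np.atleast_2d(np.asarray(xyz, float))
    if xyz.shape[0] < 2:
        raise DegenerateInputError("color span needs >= 2 loci")
    d = pdist(xyz)
    return float(d.mean()), float(d.var())


def hue_disparity(xyz: np.ndarray) -> tuple[float, float]:
    """Mean and population variance of pairwise hue angles (radians).

    The hue angle of a pair is the angle between their origin-to-locus
    vectors; loci at the origin (zero chroma, hue undefined) are excluded
    from pair enumeration.
    """
    xyz = np.atleast_2d(np.asarray(xyz, float))
    norms = np.linalg.norm(xyz, axis=1)
    keep = norms > _ORIGIN_TOL
    if keep.sum() < 2:
        raise DegenerateInputError(
            "hue disparity needs >= 2 loci away from the achromatic point"
        )
    unit = xyz[keep] / norms[keep, None]
    cosines = np.clip(unit @ unit.T, -1.0, 1.0)
    iu = np.triu_indices(unit.shape[0], k=1)
    angles = np.arccos(cosines[iu])
    return float(angles.mean()), float(angles.var())


def uv_centroid(q: np.ndarray) -> float:
    """Mean relative stimulation of the UVS cone across loci."""
    q = np.atleast_2d(np.asarray(q, float))
    if q.shape[0] < 1:
        raise DegenerateInputError("uv centroid of an empty locus set")
    return float(q[:, 0].mean())


def diversity_indices(q: np.ndarray, xyz: np.ndarray | None = None,
                      strict: bool = False) -> dict:
    """All six indices for one locus set, keyed by ``INDEX_NAMES``.

    With ``strict=False`` (the default), indices undefined at this sample
    size are reported as 0.0 and listed under ``"degenerate"``; with
    ``strict=True`` they raise instead.
    """
    q = np.atleast_2d(np.asarray(q, float))
    if xyz is None:
        xyz = to_tetrahedral(q)
    xyz = np.atleast_2d(xyz)
    out: dict = {}
    degenerate: list[str] = []

    vol = color_volume(xyz)
    if vol.degenerate:
        if strict and xyz.shape[0] < 4:
            raise DegenerateInputError("color volume needs >= 4 loci in general position")
        degenerate.append("rel.c.vol")
    out["rel.c.vol"] = vol.relative

    try:
        hm, hv = hue_disparity(xyz)
    except DegenerateInputError:
        if strict:
            raise
        hm = hv = 0.0
        degenerate += ["huedisp.m", "huedisp.v"]
    out["huedisp.m"], out["huedisp.v"] = hm, hv

    try:
        cm, cv = color_span(xyz)
    except DegenerateInputError:
        if strict:
            raise
        cm = cv = 0.0
        degenerate += ["colspan.m", "colspan.v"]
    out["colspan.m"], out["colspan.v"] = cm, cv

    out["uv.centroid"] = uv_centroid(q)
    out["degenerate"] = degenerate
    return out


def indices_table(groups: dict[tuple[str, str], np.ndarray]) -> pd.DataFrame:
    """Per-(region, sex) diversity table mirroring the standard report:
    columns region, sex, rel.c.vol, huedisp.m, huedisp.v, colspan.m,
    colspan.v, uv.centroid.

    ``groups`` maps (region, sex) to the (n, 4) relative-catch matrix of
    that group's loci.
    """
    rows = []
    for (region, sex), q in groups.items():
        idx = diversity_indices(q)
        rows.append({"region": region, "sex": sex,
                     **{k: idx[k] for k in INDEX_NAMES}})
    return pd.DataFrame(rows, columns=["region", "sex", *INDEX_NAMES])
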