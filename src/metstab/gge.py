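"""GGE biplot computation and its interpretation patterns as tables.

The GGE model keeps genotype main effects and interaction together: the
environment-centered cell means M_ge = ybar_ge - ybar_.e are decomposed by
SVD and the first two axes displayed.  Singular values can be partitioned
to the genotype side (svp=1), the environment side (svp=2) or split
symmetrically (svp=3); in all three cases the dot product of a genotype and
an environment marker equals the rank-2 reconstruction of M, which is the
algebraic fact behind every pattern below:

* which-won-where: convex-hull vertex genotypes win the sectors that
  perpendicular rays from the origin to the hull edges cut out;
* mean vs stability: projections on the average-environment axis (AEA) give
  mean performance, perpendicular deviations give instability;
* genotype ranking: distance to an ideal point on the AEA;
* discriminativeness vs representativeness: environment vector length and
  angle to the AEA;
* pairwise comparison and single-genotype environment evaluation via
  equality lines and projections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .data_model import CellMeans

__all__ = [
    "GgeFit",
    "SectorPartition",
    "fit_gge",
    "which_won_where",
    "mean_vs_stability",
    "rank_vs_ideal_genotype",
    "discrim_vs_repr",
    "compare_pair",
    "environment_profile",
]


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class GgeFit:
    matrix: np.ndarray  # centered (and optionally scaled) g x e matrix M
    centering: int  # 0 none, 1 global, 2 environment
    scaling: int  # 0 none, 1 per-environment sd
    svp: int  # 1 genotype-, 2 environment-focused, 3 symmetric
    singular_values: np.ndarray
    gen_coord: np.ndarray  # g x 2
    env_coord: np.ndarray  # e x 2
    axis_proportion: np.ndarray  # variance share of axes 1, 2
    genotypes: list[str]
    environments: list[str]

    def reconstruction(self) -> np.ndarray:
        """Rank-2 approximation of M; equals gen_coord @ env_coord.T for any svp."""
        return self.gen_coord @ self.env_coord.T

    @property
    def gen_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.gen_coord, index=self.genotypes, columns=["x", "y"])

    @property
    def env_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.env_coord, index=self.environments, columns=["x", "y"])


def fit_gge(means: CellMeans, centering: int = 2, scaling: int = 0, svp: int = 3) -> GgeFit:
    """Center/scale the cell means, SVD, and partition the singular values."""
    if centering not in (0, 1, 2):
        raise ValueError("centering must be 0 (none), 1 (global) or 2 (environment)")
    if scaling not in (0, 1):
        raise ValueError("scaling must be 0 (none) or 1 (per-environment sd)")
    if svp not in (1, 2, 3):
        raise ValueError("svp must be 1 (genotype), 2 (environment) or 3 (symmetric)")
    y = means.matrix.astype(float)
    if centering == 1:
        m = y - y.mean()
    elif centering == 2:
        m = y - y.mean(axis=0, keepdims=True)
    else:
        m = y.copy()
    if scaling == 1:
        sd = y.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("scaling=1 impossible: an environment has zero yield variance")
        m = m / sd

    u, s, vt = np.linalg.svd(m, full_matrices=False)
    v = vt.T
    # same sign convention as the AMMI module: largest-|.| env entry positive
    for k in range(v.shape[1]):
        j = int(np.argmax(np.abs(v[:, k])))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
            u[:, k] = -u[:, k]
    s2 = s[:2].copy()
    # axes carrying only numerical noise are zeroed so degenerate geometry
    # (collinear/coincident markers) is detected exactly
    s2[s2 < 1e-12 * max(s[0], 1e-300)] = 0.0
    if svp == 1:
        gen, env = u[:, :2] * s2, v[:, :2]
    elif svp == 2:
        gen, env = u[:, :2], v[:, :2] * s2
    else:
        root = np.sqrt(s2)
        gen, env = u[:, :2] * root, v[:, :2] * root
    tot = (s**2).sum()
    prop = s2**2 / tot if tot > 0 else np.zeros(2)
    return GgeFit(
        matrix=m,
        centering=centering,
        scaling=scaling,
        svp=svp,
        singular_values=s,
        gen_coord=gen,
        env_coord=env,
        axis_proportion=prop,
        genotypes=list(means.genotypes),
        environments=list(means.environments),
    )


@dataclass
class SectorPartition:
    hull_vertices: list[str]  # counter-clockwise order
    boundary_angles: list[float]  # radians, one boundary after each vertex
    assignments: pd.DataFrame  # per environment: sector_id, winner
    degenerate: bool = False


def _tol(points: np.ndarray) -> float:
    return 1e-9 * max(float(np.abs(points).max()), 1.0)


def _ccw_hull(points: np.ndarray) -> np.ndarray:
    hull = ConvexHull(points)
    return hull.vertices  # scipy returns 2-D hull vertices in CCW order


def which_won_where(fit: GgeFit) -> SectorPartition:
    """Sector partition of the biplot and each environment's winning genotype.

    The winner in an environment is the hull-vertex genotype whose marker has
    the largest projection on the environment's direction; sector boundaries
    are the equal-projection rays between consecutive winning vertices.
    Degenerate geometry (all genotype markers collinear or coincident) falls
    back to a direct argmax over the rank-2 reconstruction, flagged.
    """
    pts = fit.gen_coord
    tol = _tol(pts)
    try:
        verts = _ccw_hull(pts)
    except (QhullError, ValueError):
        recon = fit.reconstruction()
        win = [fit.genotypes[int(np.argmax(recon[:, j]))] for j in range(len(fit.environments))]
        assign = pd.DataFrame(
            {"sector_id": pd.factorize(win)[0] + 1, "winner": win}, index=fit.environments
        )
        return SectorPartition([], [], assign, degenerate=True)

    vp = pts[verts]  # hull vertex coordinates, CCW
    env = fit.env_coord
    winners_idx = []
    for j in range(env.shape[0]):
        d = env[j]
        proj = vp @ d
        best = proj.max()
        tied = np.flatnonzero(proj >= best - tol)
        if len(tied) == 1:
            winners_idx.append(int(tied[0]))
        else:
            # boundary tie: counter-clockwise sector, i.e. the tied vertex
            # lying most counter-clockwise of the environment direction
            cross = vp[tied, 0] * d[1] - vp[tied, 1] * d[0]
            winners_idx.append(int(tied[np.argmin(cross)]))

    # boundary ray between consecutive CCW vertices: equal-projection direction
    boundaries = []
    nv = len(verts)
    for i in range(nv):
        a, b = vp[i], vp[(i + 1) % nv]
        edge = b - a
        cand = np.array([-edge[1], edge[0]])
        nrm = np.linalg.norm(cand)
        if nrm < tol:
            continue
        cand = cand / nrm
        for u in (cand, -cand):
            if u @ a >= (vp @ u).max() - tol:
                boundaries.append(float(np.arctan2(u[1], u[0])))
                break
    labels = [fit.genotypes[verts[i]] for i in winners_idx]
    sector_of = {}
    ids = []
    for lab in labels:
        if lab not in sector_of:
            sector_of[lab] = len(sector_of) + 1
        ids.append(sector_of[lab])
    assign = pd.DataFrame({"sector_id": ids, "winner": labels}, index=fit.environments)
    return SectorPartition(
        [fit.genotypes[v] for v in verts], sorted(boundaries), assign, degenerate=False
    )


def _aea(fit: GgeFit) -> np.ndarray:
    """Unit vector toward the average environment marker."""
    avg = fit.env_coord.mean(axis=0)
    nrm = np.linalg.norm(avg)
    if nrm < _tol(fit.env_coord):
        raise DegenerateGeometryError("average environment sits at the origin; AEA undefined")
    return avg / nrm


def mean_vs_stability(fit: GgeFit) -> pd.DataFrame:
    """Mean-performance projection on the AEA and signed instability deviation."""
    a = _aea(fit)
    pts = fit.gen_coord
    proj = pts @ a
    perp = pts[:, 1] * a[0] - pts[:, 0] * a[1]  # signed perpendicular component
    out = pd.DataFrame(
        {"mean_score": proj, "stability": perp, "abs_stability": np.abs(perp)},
        index=fit.genotypes,
    )
    out["mean_rank"] = _rank(out["mean_score"], ascending=False)
    out["stability_rank"] = _rank(out["abs_stability"], ascending=True)
    return out


def rank_vs_ideal_genotype(fit: GgeFit) -> pd.DataFrame:
    """Distance of every genotype to the ideal point on the AEA (rank 1 closest)."""
    a = _aea(fit)
    pts = fit.gen_coord
    ideal = a * (pts @ a).max()
    dist = np.linalg.norm(pts - ideal, axis=1)
    out = pd.DataFrame({"distance": dist}, index=fit.genotypes)
    out["rank"] = _rank(out["distance"], ascending=True)
    return out


def discrim_vs_repr(fit: GgeFit) -> pd.DataFrame:
    """Environment vector length, cosine to the AEA, and ideal-environment rank."""
    a = _aea(fit)
    env = fit.env_coord
    length = np.linalg.norm(env, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosine = np.where(length > 0, (env @ a) / length, np.nan)
    ideal = a * length.max()
    dist = np.linalg.norm(env - ideal, axis=1)
    out = pd.DataFrame(
        {"discriminativeness": length, "representativeness": cosine, "distance_to_ideal": dist},
        index=fit.environments,
    )
    out["rank"] = _rank(out["distance_to_ideal"], ascending=True)
    return out


def compare_pair(fit: GgeFit, g1: str, g2: str) -> pd.DataFrame:
    """Per-environment favored genotype from the g1-g2 equality line.

    The equality line is the perpendicular through the origin to the segment
    g1-g2; an environment favors the genotype on its side, i.e. the sign of
    the projection of the environment marker onto (P_g1 - P_g2).
    """
    if g1 == g2:
        raise ValueError("g1 and g2 must differ")
    gi, gj = fit.genotypes.index(g1), fit.genotypes.index(g2)
    diff = fit.gen_coord[gi] - fit.gen_coord[gj]
    tol = _tol(fit.gen_coord)
    coincident = bool(np.linalg.norm(diff) < tol)
    margin = fit.env_coord @ diff
    fav = np.where(margin > tol, g1, np.where(margin < -tol, g2, "tie"))
    if coincident:
        fav = np.full(len(fit.environments), "tie", dtype=object)
    return pd.DataFrame(
        {"favored": fav, "margin": margin, "coincident": coincident}, index=fit.environments
    )


def environment_profile(fit: GgeFit, genotype: str) -> pd.DataFrame:
    """Above/below-average calls for one genotype across environments.

    Environments are projected on the axis through the origin and the
    genotype marker; a positive projection means the genotype performs above
    the environment average (the sign of the rank-2 reconstructed M_ge).
    """
    gi = fit.genotypes.index(genotype)
    gvec = fit.gen_coord[gi]
    tol = _tol(fit.gen_coord)
    if np.linalg.norm(gvec) < tol:
        raise DegenerateGeometryError(f"genotype {genotype} sits at the origin; axis undefined")
    proj = fit.env_coord @ gvec
    call = np.where(proj > tol, "above", np.where(proj < -tol, "below", "average"))
    return pd.DataFrame({"projection": proj, "call": call}, index=fit.environments)


def _rank(values: pd.Series, ascending: bool) -> pd.Series:
    order = values.sort_values(ascending=ascending, kind="mergesort").index
    return pd.Series(np.arange(1, len(values) + 1), index=order).reindex(values.index)
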