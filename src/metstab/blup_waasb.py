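"""Mixed-model variance components, BLUPs, heritability and WAASB/WAASBY.

The linear mixed model treats environments and replicates-within-environment
as fixed, genotypes and genotype-by-environment interaction as random:

    y = Xb + Z_g u_g + Z_ge u_ge + eps,
    u_g ~ N(0, VG),  u_ge ~ N(0, sigma2_gei),  eps ~ N(0, sigma2_err).

For balanced data the variance components come either from the expected
mean squares of the joint ANOVA (EMS) or from restricted maximum likelihood;
the design's orthogonal error strata make the REML objective a closed
three-stratum likelihood, and both methods coincide whenever the EMS
estimates are non-negative.  Genotype and GEI BLUPs then take the familiar
shrinkage form, and the weighted average of absolute IPCA scores of the
BLUP interaction matrix (WAASB) measures per-genotype stability.  WAASBY
blends rescaled yield and rescaled WAASB with user weights (default 65/35)
for simultaneous selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .ammi import AmmiFit, joint_anova, ranked
from .data_model import BalanceError, MetTrial, cell_means

__all__ = [
    "VarianceComponents",
    "BlupFit",
    "WaasbResult",
    "variance_components",
    "heritability",
    "fit_blup",
    "waasb",
    "waas",
    "waasby",
    "weight_scenarios",
    "classify_quadrants",
    "cluster_rank_profiles",
]


@dataclass
class VarianceComponents:
    sigma2_gen: float
    sigma2_gei: float
    sigma2_err: float
    sigma2_rep: float
    method: str  # "ems" or "reml"
    truncated: tuple[str, ...] = ()  # names of components clipped at zero


@dataclass
class BlupFit:
    """Fixed part, shrunken random-effect predictions and heritability."""

    mu: float
    beta: pd.Series  # environment effects (fixed), sum 0
    rep_effects: pd.DataFrame  # env x rep fixed effects, rows sum 0
    blup_g: pd.Series  # genotype BLUPs, sum ~0
    blup_ge: pd.DataFrame  # g x e GEI BLUPs, double-centered
    shrinkage_g: float  # c_g in [0, 1]
    shrinkage_ge: float  # c_ge in [0, 1]
    h2: float  # entry-mean broad-sense heritability
    vc: VarianceComponents
    rep_count: int

    @property
    def predicted_genotype_means(self) -> pd.Series:
        return self.mu + self.blup_g

    def predict(self, with_gei: bool = True) -> pd.DataFrame:
        """Predicted cell values mu + beta_e + BLUP_g (+ BLUP_ge)."""
        pred = self.mu + self.beta.to_numpy()[None, :] + self.blup_g.to_numpy()[:, None]
        if with_gei:
            pred = pred + self.blup_ge.to_numpy()
        return pd.DataFrame(pred, index=self.blup_g.index, columns=self.beta.index)


def _ems_components(trial: MetTrial) -> tuple[VarianceComponents, "pd.DataFrame"]:
    an = joint_anova(trial)
    ms = an.table["MS"]
    g, e, r = an.g, an.e, an.r
    raw = {
        "sigma2_err": ms["Residuals"],
        "sigma2_gei": (ms["GEN:ENV"] - ms["Residuals"]) / r,
        "sigma2_gen": (ms["GEN"] - ms["GEN:ENV"]) / (r * e),
        "sigma2_rep": (ms["REP(ENV)"] - ms["Residuals"]) / g,
    }
    truncated = tuple(k for k, v in raw.items() if v < 0)
    clipped = {k: max(v, 0.0) for k, v in raw.items()}
    return (
        VarianceComponents(method="ems", truncated=truncated, **clipped),
        an.table,
    )


def _reml_components(trial: MetTrial) -> VarianceComponents:
    """REML for the balanced design via its three orthogonal error strata.

    After projecting out the fixed effects (mean, environments, reps within
    environments) the residual space splits into the genotype stratum,
    the GEI stratum and the within-cell stratum, with per-contrast variances
      lam_G  = sigma2_err + r*sigma2_gei + r*e*sigma2_gen
      lam_GE = sigma2_err + r*sigma2_gei
      lam_R  = sigma2_err.
    The restricted log-likelihood is -1/2 * sum_s [df_s log lam_s + SS_s/lam_s],
    maximized under the non-negativity constraints.
    """
    an = joint_anova(trial)
    g, e, r = an.g, an.e, an.r
    ss = an.table["SS"]
    dfs = an.table["df"]
    strata_ss = np.array([ss["GEN"], ss["GEN:ENV"], ss["Residuals"]])
    strata_df = np.array([dfs["GEN"], dfs["GEN:ENV"], dfs["Residuals"]], dtype=float)
    coef = np.array([[r * e, r, 1.0], [0.0, r, 1.0], [0.0, 0.0, 1.0]])  # rows: strata

    def neg_restricted_ll(theta: np.ndarray) -> float:
        lam = coef @ theta
        if np.any(lam <= 0):
            return np.inf
        return float(np.sum(strata_df * np.log(lam) + strata_ss / lam))

    ems, _ = _ems_components(trial)
    x0 = np.array([max(ems.sigma2_gen, 1e-8), max(ems.sigma2_gei, 1e-8),
                   max(ems.sigma2_err, 1e-8)])
    scale = max(x0.max(), 1.0)
    res = optimize.minimize(
        lambda t: neg_restricted_ll(t * scale),
        x0 / scale,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * 3,
    )
    if not res.success:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"REML did not converge: {res.message}")
    s2_gen, s2_gei, s2_err = np.maximum(res.x * scale, 0.0)
    truncated = tuple(
        name
        for name, v in zip(("sigma2_gen", "sigma2_gei"), (s2_gen, s2_gei))
        if v < 1e-10 and getattr(ems, name) <= 0
    )
    return VarianceComponents(
        sigma2_gen=float(s2_gen),
        sigma2_gei=float(s2_gei),
        sigma2_err=float(s2_err),
        sigma2_rep=ems.sigma2_rep,  # reps are fixed in the model; EMS quasi-component reported
        method="reml",
        truncated=truncated,
    )


def variance_components(trial: MetTrial, method: str = "ems") -> VarianceComponents:
    """Estimate (VG, sigma2_gei, sigma2_err, sigma2_rep) from a balanced trial.

    ``method='ems'`` inverts the expected mean squares (negative estimates
    clipped to zero and flagged); ``method='reml'`` maximizes the restricted
    likelihood, which agrees with EMS whenever the EMS solution is interior.
    """
    method = method.lower()
    if method == "ems":
        return _ems_components(trial)[0]
    if method == "reml":
        return _reml_components(trial)
    raise ValueError("method must be 'ems' or 'reml'")


def heritability(vc: VarianceComponents, e: int, r: int, basis: str = "entry_mean") -> float:
    """Broad-sense heritability H^2 = VG / VP.

    ``entry_mean`` basis divides interaction and error variance by the number
    of environments and plots they are averaged over (the heritability of a
    genotype's trial mean); ``plot`` basis uses raw components.
    """
    vg, vge, verr = vc.sigma2_gen, vc.sigma2_gei, vc.sigma2_err
    if basis == "plot":
        vp = vg + vge + verr
    elif basis == "entry_mean":
        vp = vg + vge / e + verr / (r * e)
    else:
        raise ValueError("basis must be 'plot' or 'entry_mean'")
    if vp == 0:
        return float("nan")
    return vg / vp


def fit_blup(trial: MetTrial, vc: VarianceComponents | None = None) -> BlupFit:
    """Shrinkage BLUPs for genotype and GEI effects in a balanced trial.

    BLUP_g = c_g (ybar_g. - ybar..) with c_g = VG / (VG + s2_gei/e + s2_err/(r e));
    BLUP_ge = c_ge Z_ge with c_ge = s2_gei / (s2_gei + s2_err/r), Z the doubly
    centered cell means.
    """
    cm = cell_means(trial)
    if cm.rep_count < 2:
        raise BalanceError("BLUP needs r >= 2 to estimate variance components")
    if vc is None:
        vc = variance_components(trial, "ems")
    g, e, r = len(cm.genotypes), len(cm.environments), cm.rep_count
    mu = cm.grand_mean
    beta = cm.env_means - mu
    er = trial.data.groupby(["env", "rep"])["yield"].mean().unstack()
    rep_eff = er.sub(er.mean(axis=1), axis=0).reindex(index=cm.environments)

    den_g = vc.sigma2_gen + vc.sigma2_gei / e + vc.sigma2_err / (r * e)
    c_g = vc.sigma2_gen / den_g if den_g > 0 else 0.0
    den_ge = vc.sigma2_gei + vc.sigma2_err / r
    c_ge = vc.sigma2_gei / den_ge if den_ge > 0 else 0.0

    blup_g = c_g * (cm.genotype_means - mu)
    z = cm.matrix - cm.matrix.mean(axis=1, keepdims=True) - cm.matrix.mean(axis=0, keepdims=True) + mu
    blup_ge = pd.DataFrame(c_ge * z, index=cm.genotypes, columns=cm.environments)
    return BlupFit(
        mu=mu,
        beta=beta,
        rep_effects=rep_eff,
        blup_g=blup_g,
        blup_ge=blup_ge,
        shrinkage_g=c_g,
        shrinkage_ge=c_ge,
        h2=heritability(vc, e, r, "entry_mean"),
        vc=vc,
        rep_count=r,
    )


@dataclass
class WaasbResult:
    """WAASB (or WAAS) values at the chosen axis count plus the full by-p table."""

    values: pd.Series  # index genotype
    n_axes: int
    by_axes: pd.DataFrame  # genotype x p (p = 1..max): value using first p axes
    ranks_by_axes: pd.DataFrame  # same shape, rank 1 = most stable
    explained_proportion: np.ndarray

    @property
    def ranks(self) -> pd.Series:
        return ranked(self.values, ascending=True)


def _weighted_abs_scores(scores: np.ndarray, ep: np.ndarray, genotypes: list[str],
                         n_axes: int | str) -> WaasbResult:
    k_max = scores.shape[1]
    if n_axes == "all":
        p_use = k_max
    else:
        p_use = int(n_axes)
        if not 1 <= p_use <= k_max:
            raise ValueError(f"n_axes must be in 1..{k_max} or 'all'")
    abs_s = np.abs(scores)
    num = np.cumsum(abs_s * ep[None, :], axis=1)
    den = np.cumsum(ep)
    with np.errstate(invalid="ignore", divide="ignore"):
        by_p = np.where(den[None, :] > 0, num / den[None, :], 0.0)
    cols = list(range(1, k_max + 1))
    by_axes = pd.DataFrame(by_p, index=genotypes, columns=cols)
    ranks = pd.DataFrame(
        {p: ranked(by_axes[p], ascending=True) for p in cols}, index=genotypes
    )
    return WaasbResult(
        values=by_axes[p_use].rename("WAASB"),
        n_axes=p_use,
        by_axes=by_axes,
        ranks_by_axes=ranks,
        explained_proportion=ep,
    )


def waasb(fit: BlupFit, n_axes: int | str = "all") -> WaasbResult:
    """Weighted average of absolute IPCA scores of the BLUP GEI matrix.

    WAASB_g = sum_{k<=p} |s_gk| EP_k / sum_{k<=p} EP_k, with s_gk the
    symmetrically scaled genotype score of the SVD of BLUP_ge and EP_k the
    axis's share of the interaction variance.  Smaller = more stable.  The
    full ranking-by-p table is always returned because rankings can shift
    with the number of retained axes.
    """
    z = fit.blup_ge.to_numpy()
    g, e = z.shape
    k = min(g - 1, e - 1)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    s = s[:k]
    scores = u[:, :k] * np.sqrt(s)
    tot = (s**2).sum()
    ep = s**2 / tot if tot > 0 else np.zeros(k)
    res = _weighted_abs_scores(scores, ep, list(fit.blup_ge.index), n_axes)
    return res


def waas(fit: AmmiFit, n_axes: int | str = "all") -> WaasbResult:
    """Same weighted-absolute-score index on the fixed-effect AMMI scores."""
    scores = fit.scores("genotype")
    res = _weighted_abs_scores(scores, fit.explained_proportion, fit.genotypes, n_axes)
    res.values = res.values.rename("WAAS")
    return res


def waasby(waasb_values: pd.Series, means: pd.Series,
           theta_y: float = 65.0, theta_s: float = 35.0) -> pd.DataFrame:
    """Simultaneous selection index: rescaled yield and stability, blended.

    rY = 100 at the highest-yielding genotype, rW = 100 at the lowest-WAASB
    genotype; WAASBY = (rY*theta_y + rW*theta_s)/100, rank 1 = largest.
    """
    if abs(theta_y + theta_s - 100.0) > 1e-9:
        raise ValueError("theta_y + theta_s must equal 100")
    means = means.sort_index()
    w = waasb_values.reindex(means.index)
    y_rng = means.max() - means.min()
    w_rng = w.max() - w.min()
    if y_rng == 0:
        raise ValueError("all genotype means equal: yield rescaling undefined")
    if w_rng == 0:
        raise ValueError("all WAASB values equal: stability rescaling undefined")
    ry = 100.0 * (means - means.min()) / y_rng
    rw = 100.0 * (w.max() - w) / w_rng
    val = (ry * theta_y + rw * theta_s) / 100.0
    out = pd.DataFrame({"rY": ry, "rW": rw, "WAASBY": val})
    out["rank"] = ranked(out["WAASBY"], ascending=False)
    return out


def weight_scenarios(waasb_values: pd.Series, means: pd.Series, step: float = 5.0) -> pd.DataFrame:
    """Genotype x scenario rank matrix as the yield weight sweeps 0..100.

    Column headers are theta_y values; the leftmost column ranks on stability
    alone, the rightmost on yield alone.
    """
    if step <= 0 or 100.0 % step != 0:
        raise ValueError("step must divide 100")
    thetas = np.arange(0.0, 100.0 + step, step)
    cols = {}
    for ty in thetas:
        tab = waasby(waasb_values, means, theta_y=ty, theta_s=100.0 - ty)
        cols[int(ty) if float(ty).is_integer() else ty] = tab["rank"]
    return pd.DataFrame(cols)


def classify_quadrants(waasb_values: pd.Series, means: pd.Series) -> pd.Series:
    """Quadrant of the yield (x) vs WAASB (y) plane, split at the two means.

    IV: high yield & low WAASB (productive and stable);  II: high yield,
    high WAASB (productive, unstable);  III: low yield, low WAASB (stable,
    unproductive);  I: low yield, high WAASB.  Boundary convention: yield
    >= mean counts as high, WAASB >= mean counts as high (unstable), so a
    genotype exactly at both means lands in quadrant II.
    """
    means = means.sort_index()
    w = waasb_values.reindex(means.index)
    high_y = means >= means.mean()
    high_w = w >= w.mean()
    lab = np.select(
        [high_y & ~high_w, high_y & high_w, ~high_y & ~high_w],
        ["IV", "II", "III"],
        default="I",
    )
    return pd.Series(lab, index=means.index, name="quadrant")


def cluster_rank_profiles(rank_matrix: pd.DataFrame, k: int = 4) -> pd.Series:
    """Ward hierarchical clustering of genotype rank profiles, cut at k groups.

    Deterministic: Euclidean distances on the scenario-rank rows, cluster ids
    relabelled 1..k in order of first appearance down the genotype index.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(rank_matrix):
        raise ValueError("k exceeds the number of genotypes")
    x = rank_matrix.to_numpy(dtype=float)
    if len(rank_matrix) == 1 or k == 1:
        return pd.Series(1, index=rank_matrix.index, name="cluster")
    link = hierarchy.linkage(pdist(x), method="ward")
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    out = []
    for c in raw:
        if c not in remap:
            remap[c] = len(remap) + 1
        out.append(remap[c])
    return pd.Series(out, index=rank_matrix.index, name="cluster")
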