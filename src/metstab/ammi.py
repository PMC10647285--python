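"""Joint ANOVA and the AMMI family.

AMMI models the genotype x environment cell means as additive main effects
plus a multiplicative interaction term obtained from the SVD of the doubly
centered means,

    y_ge = mu + alpha_g + beta_e + sum_k lambda_k gamma_gk delta_ek + rho_ge.

Per-axis significance follows Gollob's rule (df_k = g + e - 1 - 2k, interaction
SS on the replicate scale tested against the pooled residual mean square),
which is exactly the df partition used for the interaction principal
component rows of the joint ANOVA table.  The module also provides the AMMI
stability value (Purchase-type combination of the first two axis scores),
truncated-model predictions (AMMI0 ... AMMIF), and biplot coordinates with
the symmetric singular-value split (genotype score = sqrt(lambda)*gamma,
environment score = sqrt(lambda)*delta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import BalanceError, CellMeans, MetTrial, cell_means

__all__ = [
    "AnovaTable",
    "AmmiFit",
    "BiplotCoords",
    "joint_anova",
    "fit_ammi",
    "ipca_df",
    "gollob_test",
    "asv",
    "ammi_predict",
    "ammi_biplot_coords",
    "ranked",
]

_ANOVA_COLS = ["df", "SS", "MS", "F", "p", "proportion", "accumulated"]


@dataclass
class AnovaTable:
    """Joint ANOVA (optionally with IPCA rows) plus overall mean and CV%."""

    table: pd.DataFrame  # index: source; columns: df, SS, MS, F, p, proportion, accumulated
    grand_mean: float
    cv: float  # 100 * sqrt(MS_resid) / grand mean
    g: int
    e: int
    r: int

    def __str__(self) -> str:  # pragma: no cover - convenience
        return (
            self.table.to_string(float_format=lambda v: f"{v:.4g}")
            + f"\nOverall Mean {self.grand_mean:.4f}\nCV {self.cv:.4f}"
        )


@dataclass
class AmmiFit:
    """Additive effects and the SVD of the interaction residuals."""

    mu: float
    alpha: pd.Series  # genotype main effects, sum 0
    beta: pd.Series  # environment main effects, sum 0
    lambda_: np.ndarray  # singular values, descending, length n_axes_max
    gamma: np.ndarray  # (g, n_axes_max) genotype eigenvectors, orthonormal cols
    delta: np.ndarray  # (e, n_axes_max) environment eigenvectors
    genotypes: list[str]
    environments: list[str]
    rep_count: int

    @property
    def n_axes_max(self) -> int:
        return len(self.lambda_)

    @property
    def explained_proportion(self) -> np.ndarray:
        """EP_k = lambda_k^2 / sum(lambda^2); zeros if there is no interaction."""
        ss = self.lambda_**2
        tot = ss.sum()
        return ss / tot if tot > 0 else np.zeros_like(ss)

    @property
    def interaction_ss(self) -> float:
        """sum_ge Z_ge^2 of the doubly centered means (= sum lambda^2)."""
        return float((self.lambda_**2).sum())

    def scores(self, focus: str = "genotype") -> np.ndarray:
        """Symmetrically scaled scores sqrt(lambda_k) * eigenvector."""
        vec = self.gamma if focus == "genotype" else self.delta
        return vec * np.sqrt(self.lambda_)


def _fix_svd_signs(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve SVD sign ambiguity: largest-|.| environment entry positive."""
    u, v = u.copy(), v.copy()
    for k in range(v.shape[1]):
        j = int(np.argmax(np.abs(v[:, k])))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
            u[:, k] = -u[:, k]
    return u, v


def ranked(values: pd.Series, ascending: bool = True) -> pd.Series:
    """Dense 1..n ranks; ties broken by label order (stable sort)."""
    s = values.sort_index()
    order = s.sort_values(ascending=ascending, kind="mergesort").index
    ranks = pd.Series(np.arange(1, len(s) + 1), index=order, name="rank")
    return ranks.reindex(values.index)


def joint_anova(trial: MetTrial) -> AnovaTable:
    """Balanced two-way ANOVA with replicates nested in environments.

    Sources: ENV (tested against REP(ENV)), REP(ENV), GEN, GEN:ENV (both
    tested against the pooled residual).  Also reports the overall mean and
    CV% = 100*sqrt(MS_resid)/mean.
    """
    cm = cell_means(trial)  # raises BalanceError if unbalanced
    g, e, r = len(cm.genotypes), len(cm.environments), cm.rep_count
    if r < 2:
        raise BalanceError("joint ANOVA needs r >= 2 replicates (no residual term otherwise)")
    df = trial.data
    n = len(df)
    grand = float(df["yield"].mean())
    correction = n * grand**2

    ss_total = float((df["yield"] ** 2).sum()) - correction
    env_means = df.groupby("env")["yield"].mean()
    ss_env = float(g * r * (env_means**2).sum()) - correction
    er_means = df.groupby(["env", "rep"])["yield"].mean()
    ss_rep = float(g * (er_means**2).sum()) - correction - ss_env
    gen_means = df.groupby("gen")["yield"].mean()
    ss_gen = float(e * r * (gen_means**2).sum()) - correction
    ss_ge = float(r * (cm.matrix**2).sum()) - correction - ss_env - ss_gen
    ss_res = ss_total - ss_env - ss_rep - ss_gen - ss_ge

    dfs = {
        "ENV": e - 1,
        "REP(ENV)": e * (r - 1),
        "GEN": g - 1,
        "GEN:ENV": (g - 1) * (e - 1),
        "Residuals": e * (g - 1) * (r - 1),
    }
    sss = {"ENV": ss_env, "REP(ENV)": ss_rep, "GEN": ss_gen, "GEN:ENV": ss_ge, "Residuals": ss_res}
    mss = {k: sss[k] / dfs[k] for k in dfs}

    def f_and_p(num: str, den: str) -> tuple[float, float]:
        if mss[den] <= 0:
            return (np.nan, np.nan)
        fval = mss[num] / mss[den]
        return fval, float(stats.f.sf(fval, dfs[num], dfs[den]))

    fp = {
        "ENV": f_and_p("ENV", "REP(ENV)"),
        "REP(ENV)": f_and_p("REP(ENV)", "Residuals"),
        "GEN": f_and_p("GEN", "Residuals"),
        "GEN:ENV": f_and_p("GEN:ENV", "Residuals"),
        "Residuals": (np.nan, np.nan),
    }
    rows = [
        {"df": dfs[k], "SS": sss[k], "MS": mss[k], "F": fp[k][0], "p": fp[k][1],
         "proportion": np.nan, "accumulated": np.nan}
        for k in dfs
    ]
    table = pd.DataFrame(rows, index=list(dfs)).loc[:, _ANOVA_COLS]
    cv = 100.0 * np.sqrt(max(mss["Residuals"], 0.0)) / grand if grand != 0 else np.nan
    return AnovaTable(table, grand, cv, g, e, r)


def fit_ammi(trial: MetTrial) -> AmmiFit:
    """Double-center the cell means and take their SVD."""
    cm = cell_means(trial)
    return fit_ammi_means(cm)


def fit_ammi_means(cm: CellMeans) -> AmmiFit:
    """AMMI decomposition directly from a cell-means matrix."""
    y = cm.matrix
    g, e = y.shape
    mu = y.mean()
    alpha = y.mean(axis=1) - mu
    beta = y.mean(axis=0) - mu
    z = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + mu
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    k = min(g - 1, e - 1)  # double-centering caps the rank
    u, v = _fix_svd_signs(u[:, :k], vt.T[:, :k])
    return AmmiFit(
        mu=float(mu),
        alpha=pd.Series(alpha, index=cm.genotypes),
        beta=pd.Series(beta, index=cm.environments),
        lambda_=s[:k],
        gamma=u,
        delta=v,
        genotypes=list(cm.genotypes),
        environments=list(cm.environments),
        rep_count=cm.rep_count,
    )


def ipca_df(g: int, e: int, k: int) -> int:
    """Gollob degrees of freedom for interaction axis k: g + e - 1 - 2k."""
    if not 1 <= k <= min(g - 1, e - 1):
        raise ValueError(f"axis index k={k} out of range 1..{min(g - 1, e - 1)}")
    return g + e - 1 - 2 * k


def gollob_test(fit: AmmiFit, anova: AnovaTable) -> AnovaTable:
    """Append per-axis IPCA rows (Gollob F-tests) to the joint ANOVA.

    SS_k = r * lambda_k^2 (replicate scale, so PC rows are commensurate with
    the GEN:ENV SS), df_k = g + e - 1 - 2k, F_k = MS_k / MS_residual.  The
    proportion column gives each axis's share of the interaction SS.
    """
    g, e = len(fit.genotypes), len(fit.environments)
    if (g, e, fit.rep_count) != (anova.g, anova.e, anova.r):
        raise ValueError("AMMI fit and ANOVA table come from different trial dimensions")
    ms_res = anova.table.loc["Residuals", "MS"]
    df_res = anova.table.loc["Residuals", "df"]
    ss_int = fit.interaction_ss
    rows = []
    for k in range(1, fit.n_axes_max + 1):
        ss_k = fit.rep_count * fit.lambda_[k - 1] ** 2
        dfk = ipca_df(g, e, k)
        ms_k = ss_k / dfk
        if ms_res > 0:
            fval = ms_k / ms_res
            pval = float(stats.f.sf(fval, dfk, df_res))
        else:
            fval, pval = (0.0, 1.0) if ss_k == 0 else (np.nan, np.nan)
        prop = 100.0 * fit.lambda_[k - 1] ** 2 / ss_int if ss_int > 0 else 0.0
        rows.append({"df": dfk, "SS": ss_k, "MS": ms_k, "F": fval, "p": pval, "proportion": prop})
    pc = pd.DataFrame(rows, index=[f"PC{k}" for k in range(1, fit.n_axes_max + 1)])
    pc["accumulated"] = pc["proportion"].cumsum()
    base = anova.table
    order = ["ENV", "REP(ENV)", "GEN", "GEN:ENV"]
    table = pd.concat([base.loc[order], pc.loc[:, _ANOVA_COLS], base.loc[["Residuals"]]])
    return AnovaTable(table, anova.grand_mean, anova.cv, anova.g, anova.e, anova.r)


def asv(fit: AmmiFit) -> pd.DataFrame:
    """AMMI stability value from the first two axes (smaller = more stable).

    ASV_g = sqrt[(SS1/SS2 * s_g1)^2 + s_g2^2] with s_gk the symmetrically
    scaled genotype score; rank 1 = smallest, ties broken by label order.
    """
    if fit.n_axes_max < 2:
        raise ValueError("ASV needs at least two interaction axes")
    ss1, ss2 = fit.lambda_[0] ** 2, fit.lambda_[1] ** 2
    if ss2 == 0:
        raise ZeroDivisionError(
            "second interaction axis carries no variance (SS2 = 0); ASV is undefined"
        )
    s = fit.scores("genotype")
    values = np.hypot(ss1 / ss2 * s[:, 0], s[:, 1])
    out = pd.DataFrame({"ASV": values}, index=fit.genotypes)
    out["rank"] = ranked(out["ASV"], ascending=True)
    return out


def ammi_predict(fit: AmmiFit, n_axes: int) -> pd.DataFrame:
    """Cell-mean predictions from AMMI(n): additive part + n SVD terms."""
    if not 0 <= n_axes <= fit.n_axes_max:
        raise ValueError(f"n_axes must be in 0..{fit.n_axes_max}")
    pred = fit.mu + fit.alpha.to_numpy()[:, None] + fit.beta.to_numpy()[None, :]
    if n_axes > 0:
        u = fit.gamma[:, :n_axes] * fit.lambda_[:n_axes]
        pred = pred + u @ fit.delta[:, :n_axes].T
    return pd.DataFrame(pred, index=fit.genotypes, columns=fit.environments)


@dataclass
class BiplotCoords:
    """Genotype/environment coordinates for an AMMI1 or AMMI2 biplot."""

    kind: str
    genotypes: pd.DataFrame  # columns x, y, length
    environments: pd.DataFrame  # columns x, y, length
    env_angles: pd.DataFrame | None  # pairwise angles (degrees), AMMI2 only


def ammi_biplot_coords(fit: AmmiFit, kind: str = "AMMI2",
                       axes: tuple[int, int] = (1, 2)) -> BiplotCoords:
    """Biplot coordinates under the symmetric score scaling.

    AMMI1: x = mean (mu+alpha_g / mu+beta_e), y = first requested axis score.
    AMMI2: (x, y) = scores on the two requested axes.  Environment vector
    lengths and pairwise angles (from the 2-D coordinates) are emitted for
    the AMMI2 interpretation of interaction similarity.
    """
    kind = kind.upper()
    if kind not in {"AMMI1", "AMMI2"}:
        raise ValueError("kind must be 'AMMI1' or 'AMMI2'")
    for a in axes:
        if not 1 <= a <= fit.n_axes_max:
            raise ValueError(f"axis {a} out of range 1..{fit.n_axes_max}")
    sg = fit.scores("genotype")
    se = fit.scores("environment")
    i, j = axes[0] - 1, axes[1] - 1
    if kind == "AMMI1":
        gen = pd.DataFrame(
            {"x": fit.mu + fit.alpha, "y": sg[:, i]}, index=fit.genotypes
        )
        env = pd.DataFrame(
            {"x": fit.mu + fit.beta, "y": se[:, i]}, index=fit.environments
        )
        angles = None
    else:
        gen = pd.DataFrame({"x": sg[:, i], "y": sg[:, j]}, index=fit.genotypes)
        env = pd.DataFrame({"x": se[:, i], "y": se[:, j]}, index=fit.environments)
        coords = env[["x", "y"]].to_numpy()
        norms = np.linalg.norm(coords, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosm = (coords @ coords.T) / np.outer(norms, norms)
        cosm = np.clip(cosm, -1.0, 1.0)
        angles = pd.DataFrame(
            np.degrees(np.arccos(cosm)), index=fit.environments, columns=fit.environments
        )
    for frame in (gen, env):
        # AMMI1 abscissa is a mean, not an interaction coordinate: vector
        # length there is just the |PC score|.
        frame["length"] = np.hypot(frame["x"], frame["y"]) if kind == "AMMI2" else frame["y"].abs()
    return BiplotCoords(kind, gen, env, angles)
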