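"""Synthetic multi-environment trial generator with known ground truth.

Data are drawn from the additive-plus-multiplicative model that underlies
the whole pipeline,

    y_ger = mu + E_e + R_r(e) + G_g + (GE)_ge + eps_ger,

with independent Gaussian effects for environments, replicates-within-
environment, genotypes and residuals, and a low-rank genotype-by-environment
interaction built from orthonormal random factors (so genuinely stable
genotypes — small factor loadings — exist by construction).

Default sizes and variance components emulate a balanced 42-genotype x
12-environment x 3-replicate chickpea landrace trial: grand mean ~174.5
g/plot, residual CV ~37.5%, and mean squares in the proportions observed
for location / replication / genotype / GEI in that trial.  The generator
can also emit paired normal/late-sown environments with genotype-specific
heat-induced yield reductions, giving a known heat-susceptibility index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import MetTrial

__all__ = ["SimConfig", "SimTruth", "simulate_met", "simulate_heat_pairs", "merge_regimes"]


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Trial dimensions and variance components (g^2/plot^2) for simulation.

    Defaults reproduce the reference chickpea trial's scale: with these
    components the expected joint-ANOVA mean squares are ~378100 (ENV),
    ~37815 (REP(ENV)), ~88881 (GEN), ~10634 (GEN:ENV) and ~4273 (residual),
    i.e. grand mean 174.5 g/plot and CV ~37.5%.
    """

    g: int = 42
    e: int = 12
    r: int = 3
    mu: float = 174.5151
    sigma2_env: float = 2701.0
    sigma2_rep: float = 799.0
    sigma2_gen: float = 2174.0
    sigma2_gei: float = 2120.0
    sigma2_err: float = 4273.0
    gei_rank: int = 4
    #: geometric decay ratio of successive squared interaction singular values
    gei_decay: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g < 2 or self.e < 2 or self.r < 2:
            raise SimConfigError("need g, e, r >= 2")
        for name in ("sigma2_env", "sigma2_rep", "sigma2_gen", "sigma2_gei", "sigma2_err"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if self.gei_rank < 0:
            raise SimConfigError("gei_rank must be >= 0")
        if self.gei_rank > min(self.g - 1, self.e - 1):
            raise SimConfigError(
                f"gei_rank {self.gei_rank} exceeds min(g-1, e-1) = {min(self.g - 1, self.e - 1)}"
            )
        if not 0 < self.gei_decay <= 1:
            raise SimConfigError("gei_decay must be in (0, 1]")

    def expected_ems(self) -> dict[str, float]:
        """Exact expectations of the EMS variance-component estimators.

        The generator's interaction matrix is double-centered (rows and
        columns sum to zero), so the classical genotype estimator
        (MS_G - MS_GE)/(r e) recovers sigma2_gen - sigma2_gei/e rather than
        sigma2_gen; the other components are recovered without bias.
        """
        return {
            "sigma2_gen": self.sigma2_gen - self.sigma2_gei / self.e,
            "sigma2_gei": self.sigma2_gei,
            "sigma2_err": self.sigma2_err,
            "sigma2_rep": self.sigma2_rep,
        }


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated trial."""

    mu: float
    gen_effects: pd.Series  # G_g, sum 0
    env_effects: pd.Series  # E_e, sum 0
    rep_effects: pd.DataFrame  # env x rep, rows sum 0
    gei: pd.DataFrame  # (GE)_ge, double-centered
    stability_rms: pd.Series  # per-genotype root-mean-square GEI
    n_truncated: int = 0
    # populated by simulate_heat_pairs only
    heat_reduction: pd.Series | None = None  # d_g
    stress_intensity: pd.Series | None = None  # per pair, 1 - Xh/Xn
    hsi_true: pd.DataFrame | None = None  # genotype x pair

    def to_json(self, path: str | Path) -> None:
        def ser(x):
            if isinstance(x, pd.Series):
                return x.to_dict()
            if isinstance(x, pd.DataFrame):
                return {c: x[c].to_dict() for c in x.columns}
            return x

        payload = {k: ser(v) for k, v in self.__dict__.items()}
        Path(path).write_text(json.dumps(payload, indent=2, default=float))


def _gen_labels(n: int) -> list[str]:
    return [f"G{i + 1:02d}" for i in range(n)]


def _env_labels(n: int) -> list[str]:
    return [f"E{i + 1:02d}" for i in range(n)]


def _orthonormal_centered(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k orthonormal random columns, each orthogonal to the intercept."""
    a = rng.standard_normal((n, k))
    a -= a.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(a)
    return q[:, :k]


def _low_rank_gei(rng: np.random.Generator, g: int, e: int, rank: int,
                  sigma2: float, decay: float) -> np.ndarray:
    """Double-centered GEI matrix with E[sum GE^2] = (g-1)(e-1) * sigma2.

    The scaling matches the random-effects definition of the interaction
    variance component, so EMS/REML estimators recover ``sigma2`` without
    bias.
    """
    if rank == 0 or sigma2 == 0:
        return np.zeros((g, e))
    gamma = _orthonormal_centered(rng, g, rank)
    delta = _orthonormal_centered(rng, e, rank)
    w = decay ** np.arange(rank)
    lam = np.sqrt(w / w.sum() * (g - 1) * (e - 1) * sigma2)
    return (gamma * lam) @ delta.T


def _records(y: np.ndarray, gens, envs, reps) -> pd.DataFrame:
    g, e, r = y.shape
    idx = pd.MultiIndex.from_product([gens, envs, reps], names=["gen", "env", "rep"])
    df = pd.DataFrame({"yield": y.reshape(-1)}, index=idx).reset_index()
    return df[["env", "gen", "rep", "yield"]]


def _truncate(y: np.ndarray) -> tuple[np.ndarray, int]:
    n_neg = int((y < 0).sum())
    if n_neg:
        warnings.warn(
            f"truncated {n_neg} negative simulated yields to 0 (yields are physical quantities)",
            RuntimeWarning,
            stacklevel=3,
        )
        y = np.maximum(y, 0.0)
    return y, n_neg


def simulate_met(config: SimConfig) -> tuple[MetTrial, SimTruth]:
    """Draw one balanced trial; reproducible given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    g, e, r = config.g, config.e, config.r
    gens, envs = _gen_labels(g), _env_labels(e)
    reps = [f"R{i + 1}" for i in range(r)]

    G = rng.normal(0.0, np.sqrt(config.sigma2_gen), g)
    G -= G.mean()
    E = rng.normal(0.0, np.sqrt(config.sigma2_env), e)
    E -= E.mean()
    R = rng.normal(0.0, np.sqrt(config.sigma2_rep), (e, r))
    R -= R.mean(axis=1, keepdims=True)
    GE = _low_rank_gei(rng, g, e, config.gei_rank, config.sigma2_gei, config.gei_decay)
    eps = rng.normal(0.0, np.sqrt(config.sigma2_err), (g, e, r))

    y = (
        config.mu
        + G[:, None, None]
        + E[None, :, None]
        + R[None, :, :]
        + GE[:, :, None]
        + eps
    )
    y, n_trunc = _truncate(y)

    trial = MetTrial(_records(y, gens, envs, reps))
    truth = SimTruth(
        mu=config.mu,
        gen_effects=pd.Series(G, index=gens),
        env_effects=pd.Series(E, index=envs),
        rep_effects=pd.DataFrame(R, index=envs, columns=reps),
        gei=pd.DataFrame(GE, index=gens, columns=envs),
        stability_rms=pd.Series(np.sqrt((GE**2).mean(axis=1)), index=gens),
        n_truncated=n_trunc,
    )
    return trial, truth


def simulate_heat_pairs(
    config: SimConfig, d: np.ndarray | pd.Series | None = None
) -> tuple[MetTrial, MetTrial, SimTruth]:
    """Paired normal/late-sown trials with genotype-specific heat reduction.

    ``config.e`` is the total environment count and must be even: e/2
    location-year combinations are each grown under normal and late sowing.
    Every late-sown cell expectation is ``(1 - d_g)`` times its normal-sown
    counterpart, so the true heat-susceptibility index of genotype g in pair
    p is ``d_g / SI_p`` with stress intensity ``SI_p = 1 - Xh_p/Xn_p``
    computed from the noiseless expectations.

    When ``d`` is omitted, reductions are drawn once per genotype from
    Uniform(0.05, 0.45), spanning the highly-tolerant to susceptible range.
    """
    if config.e % 2 != 0:
        raise SimConfigError("simulate_heat_pairs needs an even environment count")
    n_pairs = config.e // 2
    if n_pairs < 2:
        raise SimConfigError("need at least 2 environment pairs")
    if config.gei_rank > min(config.g - 1, n_pairs - 1):
        raise SimConfigError("gei_rank exceeds min(g-1, n_pairs-1) for paired simulation")
    rng = np.random.default_rng(config.seed)
    g, r = config.g, config.r
    gens = _gen_labels(g)
    reps = [f"R{i + 1}" for i in range(r)]

    if d is None:
        d = rng.uniform(0.05, 0.45, g)
    d = np.asarray(pd.Series(d, index=gens) if not isinstance(d, pd.Series) else d.reindex(gens))
    if np.any(d < 0) or np.any(d >= 1):
        raise ValueError("heat reduction fractions d must satisfy 0 <= d_g < 1")

    # The multiplicative heat reduction needs strictly positive normal-sown
    # expectations; Gaussian effects at realistic variance scales put a small
    # tail below zero, so effect draws are rejected and resampled until every
    # noiseless cell expectation is positive.
    for _ in range(200):
        G = rng.normal(0.0, np.sqrt(config.sigma2_gen), g)
        G -= G.mean()
        E = rng.normal(0.0, np.sqrt(config.sigma2_env), n_pairs)
        E -= E.mean()
        GE = _low_rank_gei(rng, g, n_pairs, config.gei_rank, config.sigma2_gei, config.gei_decay)
        M = config.mu + G[:, None] + E[None, :] + GE
        if np.all(M > 0):
            break
    else:
        raise SimConfigError("could not draw all-positive normal-sown cell expectations; "
                             "reduce variances or raise mu")
    M_late = M * (1.0 - d[:, None])

    pair_ids = [f"P{p + 1}" for p in range(n_pairs)]
    locations = [f"L{p // 2 + 1}" for p in range(n_pairs)]
    years = [f"Y{p % 2 + 1}" for p in range(n_pairs)]

    out = {}
    n_trunc = 0
    for sowing, expect in (("normal", M), ("late", M_late)):
        R = rng.normal(0.0, np.sqrt(config.sigma2_rep), (n_pairs, r))
        R -= R.mean(axis=1, keepdims=True)
        eps = rng.normal(0.0, np.sqrt(config.sigma2_err), (g, n_pairs, r))
        y = expect[:, :, None] + R[None, :, :] + eps
        y, nt = _truncate(y)
        n_trunc += nt
        envs = [f"{loc}{yr}{'N' if sowing == 'normal' else 'H'}" for loc, yr in zip(locations, years)]
        meta = pd.DataFrame(
            {"env": envs, "location": locations, "year": years, "sowing": sowing}
        )
        out[sowing] = MetTrial(_records(y, gens, envs, reps), env_meta=meta)

    Xn = M.mean(axis=0)
    Xh = M_late.mean(axis=0)
    si = 1.0 - Xh / Xn
    hsi_true = pd.DataFrame(d[:, None] / si[None, :], index=gens, columns=pair_ids)

    truth = SimTruth(
        mu=config.mu,
        gen_effects=pd.Series(G, index=gens),
        env_effects=pd.Series(E, index=pair_ids),
        rep_effects=pd.DataFrame(np.zeros((n_pairs, r)), index=pair_ids, columns=reps),
        gei=pd.DataFrame(GE, index=gens, columns=pair_ids),
        stability_rms=pd.Series(np.sqrt((GE**2).mean(axis=1)), index=gens),
        n_truncated=n_trunc,
        heat_reduction=pd.Series(d, index=gens),
        stress_intensity=pd.Series(si, index=pair_ids),
        hsi_true=hsi_true,
    )
    return out["normal"], out["late"], truth


def merge_regimes(normal: MetTrial, late: MetTrial) -> MetTrial:
    """Stack the two sowing regimes into one trial with combined env_meta."""
    data = pd.concat([normal.data, late.data], ignore_index=True)
    meta = pd.concat([normal.env_meta, late.env_meta], ignore_index=True)
    return MetTrial(data, env_meta=meta)
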