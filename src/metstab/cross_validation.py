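"""RMSPD cross-validation of the AMMI family against BLUP predictors.

Each resample holds out one randomly chosen replicate block per environment
for validation, refits every requested model on the cell means of the
remaining replicates (which stay balanced), and scores the root mean square
prediction difference over the g x e held-out observations.  Repeating the
split many times yields a predictive-accuracy distribution per model; the
model with the smallest median RMSPD is the most accurate.

Model labels: ``AMMI0`` ... ``AMMI<k>`` and ``AMMIF`` (full rank) for the
fixed-effect family; ``BLUP_g`` (genotype BLUPs only) and ``BLUP_ge``
(genotype plus interaction BLUPs) for the mixed-model predictors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import BalanceError, MetTrial, check_balance

__all__ = ["CvDistribution", "rmspd_cv", "summarize_cv", "default_models"]

_SCHEME = "leave-one-replicate-per-environment"


@dataclass
class CvDistribution:
    """Per-model RMSPD vectors (g/plot) from repeated random splits."""

    rmspd: pd.DataFrame  # n_resamples x models
    n_resamples: int
    seed: int
    scheme: str = _SCHEME

    @property
    def models(self) -> list[str]:
        return list(self.rmspd.columns)


def default_models(g: int, e: int, include_blup: bool = True) -> list[str]:
    """AMMI0..AMMI(K-1), AMMIF, and the two BLUP predictors."""
    k_max = min(g - 1, e - 1)
    models = [f"AMMI{k}" for k in range(k_max)] + ["AMMIF"]
    if include_blup:
        models += ["BLUP_g", "BLUP_ge"]
    return models


def _parse_models(models: list[str], k_max: int, r: int) -> dict[str, int | str]:
    """Map each label to an axis count or a BLUP tag; validate against r."""
    parsed: dict[str, int | str] = {}
    for m in models:
        if m in ("BLUP_g", "BLUP_ge"):
            if r < 3:
                raise BalanceError(
                    f"{m} cross-validation needs r >= 3 (two or more modeling replicates "
                    "are required to estimate variance components)"
                )
            parsed[m] = m
            continue
        if m == "AMMIF":
            parsed[m] = k_max
            continue
        hit = re.fullmatch(r"AMMI(\d+)", m)
        if hit is None:
            raise ValueError(f"unknown model label {m!r}")
        n = int(hit.group(1))
        if n > k_max:
            raise ValueError(f"{m} exceeds the maximum axis count {k_max}")
        parsed[m] = n
    return parsed


def _trial_array(trial: MetTrial) -> tuple[np.ndarray, list[str], list[str]]:
    """Yields as a (g, e, r) array; replicate order is per-env sorted labels."""
    report = check_balance(trial)
    if not report.is_balanced:
        raise BalanceError("cross-validation needs a balanced trial")
    gens, envs = trial.genotypes, trial.environments
    df = trial.data.sort_values(["env", "gen", "rep"], kind="mergesort")
    r = len(df) // (len(gens) * len(envs))
    # within each (env, gen) the sorted rep labels define the replicate axis
    arr = (
        df.assign(_k=df.groupby(["env", "gen"]).cumcount())
        .pivot_table(index="gen", columns=["env", "_k"], values="yield")
        .reindex(index=gens)
    )
    y = arr.to_numpy().reshape(len(gens), len(envs), r)
    return y, gens, envs


def _ems_from_obs(y_mod: np.ndarray) -> tuple[float, float, float]:
    """(sigma2_gen, sigma2_gei, sigma2_err) by EMS from a (g, e, m) array."""
    g, e, m = y_mod.shape
    grand = y_mod.mean()
    cellm = y_mod.mean(axis=2)
    ss_within = ((y_mod - cellm[:, :, None]) ** 2).sum()
    # rep-within-env is fixed: its SS leaves the within-cell pool
    repm = y_mod.mean(axis=0)  # e x m
    envm = repm.mean(axis=1)  # e
    ss_rep = g * ((repm - envm[:, None]) ** 2).sum()
    df_res = e * (g - 1) * (m - 1)
    ms_err = (ss_within - ss_rep) / df_res
    genm = y_mod.mean(axis=(1, 2))
    ms_gen = e * m * ((genm - grand) ** 2).sum() / (g - 1)
    z = cellm - cellm.mean(axis=1, keepdims=True) - cellm.mean(axis=0, keepdims=True) + grand
    ms_ge = m * (z**2).sum() / ((g - 1) * (e - 1))
    s2_err = max(ms_err, 0.0)
    s2_gei = max((ms_ge - ms_err) / m, 0.0)
    s2_gen = max((ms_gen - ms_ge) / (m * e), 0.0)
    return s2_gen, s2_gei, s2_err


def rmspd_cv(
    trial: MetTrial,
    models: list[str] | None = None,
    n_resamples: int = 1000,
    seed: int = 0,
) -> CvDistribution:
    """Resampled RMSPD distributions for the requested models.

    Per resample: one replicate per environment is the validation set, the
    rest form the modeling set; every model is fit on the modeling cell means
    and scored as sqrt(mean (yhat_ge - y_val,ge)^2) over the g x e validation
    observations.
    """
    y, gens, envs = _trial_array(trial)
    g, e, r = y.shape
    if r < 2:
        raise BalanceError("cross-validation needs r >= 2 replicates")
    k_max = min(g - 1, e - 1)
    if models is None:
        models = default_models(g, e, include_blup=r >= 3)
    parsed = _parse_models(models, k_max, r)
    needs_blup = any(isinstance(v, str) for v in parsed.values())

    rng = np.random.default_rng(seed)
    out = np.empty((n_resamples, len(models)))
    gi = np.arange(g)[:, None]
    ei = np.arange(e)[None, :]
    for b in range(n_resamples):
        val_rep = rng.integers(0, r, size=e)
        y_val = y[gi, ei, val_rep[None, :]]  # g x e
        mask = np.ones((e, r), dtype=bool)
        mask[np.arange(e), val_rep] = False
        y_mod = y[:, mask].reshape(g, e, r - 1)
        cellm = y_mod.mean(axis=2)

        mu = cellm.mean()
        row = cellm.mean(axis=1)
        col = cellm.mean(axis=0)
        z = cellm - row[:, None] - col[None, :] + mu
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        # comp[n-1] = rank-n reconstruction of z (cumulative sum of SVD terms)
        terms = np.einsum("k,gk,ke->kge", s[:k_max], u[:, :k_max], vt[:k_max, :])
        comp = np.cumsum(terms, axis=0)
        additive = row[:, None] + col[None, :] - mu

        if needs_blup:
            s2_gen, s2_gei, s2_err = _ems_from_obs(y_mod)
            m = r - 1
            den_g = s2_gen + s2_gei / e + s2_err / (m * e)
            c_g = s2_gen / den_g if den_g > 0 else 0.0
            den_ge = s2_gei + s2_err / m
            c_ge = s2_gei / den_ge if den_ge > 0 else 0.0
            blup_base = mu + (col - mu)[None, :] + c_g * (row - mu)[:, None]

        for j, lab in enumerate(models):
            tag = parsed[lab]
            if tag == "BLUP_g":
                pred = blup_base
            elif tag == "BLUP_ge":
                pred = blup_base + c_ge * z
            else:
                pred = additive if tag == 0 else additive + comp[tag - 1]
            out[b, j] = np.sqrt(((pred - y_val) ** 2).mean())
    return CvDistribution(pd.DataFrame(out, columns=models), n_resamples, seed)


def summarize_cv(dist: CvDistribution) -> pd.DataFrame:
    """Model ranking table sorted by median RMSPD (rank 1 = most accurate)."""
    if dist.rmspd.empty:
        raise ValueError("empty cross-validation distribution")
    df = pd.DataFrame(
        {
            "median": dist.rmspd.median(),
            "mean": dist.rmspd.mean(),
            "sd": dist.rmspd.std(ddof=1),
        }
    )
    df = df.sort_values("median", kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df
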