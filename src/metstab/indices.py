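"""Scalar stress and stability indices.

* Heat susceptibility index (Fischer-Maurer): S_g = (1 - Yh_g/Yn_g) / SI with
  stress intensity SI = 1 - Xh/Xn, where Y are genotype means and X trial
  means under normal (n) and heat-stressed / late-sown (h) conditions.
  S < 0.5 marks high heat tolerance, S > 1 susceptibility.
* Annicchiarico recommendation index: omega_g = mean_e(p_ge) - z_(1-alpha) *
  sd_e(p_ge), with p_ge the genotype's yield as a percentage of its
  environment mean.  It is the yield level a genotype is expected to exceed
  with confidence 1 - alpha relative to the environment average.
* Environmental index: I_e = ybar_.e - ybar.. flags favorable (I > 0) and
  unfavorable environments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CellMeans, MetTrial, cell_means

__all__ = [
    "HsiTable",
    "hsi",
    "hsi_from_trial",
    "classify_hsi",
    "annicchiarico",
    "environmental_index",
]

_HSI_CLASSES = ["highly tolerant", "tolerant", "moderately tolerant", "susceptible"]


class StressIntensityError(ValueError):
    """Stress did not reduce the trial mean yield (Xh >= Xn)."""


@dataclass
class HsiTable:
    """Per-genotype HSI for each normal/stress environment pair."""

    values: pd.DataFrame  # genotype x pair
    classes: pd.DataFrame  # genotype x pair class labels
    stress_intensity: pd.Series  # per pair, SI = 1 - Xh/Xn
    pairs: pd.DataFrame  # audit table: pair, normal env, stress env
    mean_hsi: pd.Series  # across-pairs mean, a derived summary
    mean_class: pd.Series


def classify_hsi(s: float) -> str:
    """Tolerance class from the HSI value.

    Cutoffs: < 0.51 highly tolerant, < 0.76 tolerant, <= 1.00 moderately
    tolerant, > 1.00 susceptible.  Values inside the printed gaps of the
    published boundaries (0.50-0.51, 0.75-0.76) go to the lower (more
    tolerant) class.
    """
    if not np.isfinite(s):
        raise ValueError("HSI must be finite")
    if s < 0.51:
        return _HSI_CLASSES[0]
    if s < 0.76:
        return _HSI_CLASSES[1]
    if s <= 1.00:
        return _HSI_CLASSES[2]
    return _HSI_CLASSES[3]


def hsi(normal: pd.Series, stress: pd.Series) -> pd.DataFrame:
    """HSI for one normal/stress pair from per-genotype mean yields.

    S_g = (1 - Yh_g/Yn_g) / (1 - Xh/Xn).  Scale-invariant: multiplying all
    yields by a constant leaves every S unchanged.
    """
    normal = normal.sort_index()
    stress = stress.reindex(normal.index)
    if stress.isna().any():
        raise ValueError("genotype sets of the two regimes do not match")
    if (normal <= 0).any():
        raise ValueError("normal-condition yields must be positive")
    xn, xh = normal.mean(), stress.mean()
    si = 1.0 - xh / xn
    if si <= 0:
        raise StressIntensityError(
            f"stress mean {xh:.3g} is not below normal mean {xn:.3g}; HSI undefined"
        )
    s = (1.0 - stress / normal) / si
    out = pd.DataFrame({"Yn": normal, "Yh": stress, "HSI": s})
    out["class"] = [classify_hsi(v) for v in s]
    out.attrs["stress_intensity"] = float(si)
    return out


def hsi_from_trial(trial: MetTrial) -> HsiTable:
    """HSI per (location, year) pair of normal/late environments.

    Pairs are built from ``trial.env_meta``: environments sharing location
    and year, one sown normal and one late.  Genotype means are cell means
    of the paired environments.
    """
    if trial.env_meta is None:
        raise ValueError("HSI needs env_meta (location, year, sowing) to pair environments")
    cm = cell_means(trial)
    frame = cm.to_frame()
    meta = trial.env_meta.set_index("env")
    pairs = []
    for (loc, yr), grp in meta.groupby(["location", "year"]):
        by_sow = grp.groupby("sowing").groups
        if "normal" not in by_sow or "late" not in by_sow:
            continue
        if len(by_sow["normal"]) != 1 or len(by_sow["late"]) != 1:
            raise ValueError(
                f"ambiguous pairing at location={loc}, year={yr}: need exactly one "
                "normal and one late environment"
            )
        pairs.append((f"{loc}_{yr}", by_sow["normal"][0], by_sow["late"][0]))
    if not pairs:
        raise ValueError("env_meta defines no complete normal/late pairs")

    values, classes, sis = {}, {}, {}
    for pid, env_n, env_h in pairs:
        yn, yh = frame[env_n], frame[env_h]
        # a zero normal-sown cell mean carries no susceptibility information
        # (possible in heavily stressed data after floor-at-zero recording):
        # mask that genotype for this pair instead of failing the whole table
        ok = yn > 0
        if not ok.any():
            raise ValueError(f"no positive normal-condition yields in pair {pid}")
        xn, xh = yn.mean(), yh.mean()
        si = 1.0 - xh / xn
        if si <= 0:
            raise StressIntensityError(
                f"pair {pid}: stress mean {xh:.3g} not below normal mean {xn:.3g}"
            )
        s = pd.Series(np.nan, index=yn.index)
        s[ok] = (1.0 - yh[ok] / yn[ok]) / si
        values[pid] = s
        classes[pid] = s.map(lambda v: classify_hsi(v) if np.isfinite(v) else "undefined")
        sis[pid] = float(si)
    values = pd.DataFrame(values)
    classes = pd.DataFrame(classes)
    mean_hsi = values.mean(axis=1)  # skips masked pairs
    mean_class = mean_hsi.map(lambda v: classify_hsi(v) if np.isfinite(v) else "undefined")
    return HsiTable(
        values=values,
        classes=classes,
        stress_intensity=pd.Series(sis, name="stress_intensity"),
        pairs=pd.DataFrame(pairs, columns=["pair", "env_normal", "env_late"]),
        mean_hsi=mean_hsi,
        mean_class=mean_class,
    )


def annicchiarico(means: CellMeans, alpha: float = 0.25) -> pd.DataFrame:
    """Recommendation index omega_g on the percentage-of-environment-mean scale.

    p_ge = 100 * ybar_ge / ybar_.e;  omega_g = mean_e(p) - z_(1-alpha) * sd_e(p)
    (sd with e-1 denominator).  Genotypes with omega > 100 are expected, with
    confidence 1 - alpha, to beat the environment average.
    """
    if len(means.environments) < 2:
        raise ValueError("Annicchiarico index needs at least 2 environments")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    env_means = means.matrix.mean(axis=0)
    if np.any(env_means == 0):
        raise ValueError("an environment mean is zero; percentage scale undefined")
    p = 100.0 * means.matrix / env_means[None, :]
    z = stats.norm.ppf(1.0 - alpha)
    mean_p = p.mean(axis=1)
    sd_p = p.std(axis=1, ddof=1)
    out = pd.DataFrame(
        {"mean_pct": mean_p, "sd_pct": sd_p, "omega": mean_p - z * sd_p},
        index=means.genotypes,
    )
    out.attrs["alpha"] = alpha
    out.attrs["z"] = float(z)
    return out


def environmental_index(means: CellMeans) -> pd.DataFrame:
    """Environment favorability: I_e = ybar_.e - ybar.. plus per-env best genotype."""
    idx = means.env_means - means.grand_mean
    best = [means.genotypes[i] for i in np.argmax(means.matrix, axis=0)]
    return pd.DataFrame(
        {"index": idx, "favorable": idx > 0, "best_genotype": best},
        index=means.environments,
    )
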