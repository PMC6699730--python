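"""Stratified weighted conditional probabilities of pregnancy termination.

The central quantity is the conditional probability ``T`` that a pregnancy
ends in termination rather than live birth, computed per stratum
(subpopulation x age group x union status x contraceptive use) as the ratio
of the weighted number of terminated pregnancies to the total weighted
number of pregnancies.  Confidence intervals come from the Wilson score
method on the unweighted counts; design effects and within-woman clustering
are deliberately ignored (a documented limitation of the approach).
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint


def wilson_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for ``k`` successes out of ``n`` trials."""
    if n < 1:
        raise ValueError("Wilson interval undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    low, high = proportion_confint(k, n, alpha=1 - conf, method="wilson")
    # the score interval touches the boundary exactly at k = 0 and k = n;
    # snap away the floating-point residue of the quadratic formula
    low = 0.0 if k == 0 else float(np.clip(low, 0.0, 1.0))
    high = 1.0 if k == n else float(np.clip(high, 0.0, 1.0))
    return low, high


def _check_episode_frame(episodes: pd.DataFrame) -> None:
    missing = {"outcome", "weight"} - set(episodes.columns)
    if missing:
        raise ValueError(f"episodes table lacks columns: {sorted(missing)}")


def estimate_T(episodes: pd.DataFrame, by: Sequence[str] = (),
               conf: float = 0.95) -> pd.DataFrame:
    """Weighted termination probability per stratum.

    ``by`` lists the stratifying columns; omitting a dimension pools over it
    (marginal strata are pooled weighted counts, never averages of
    sub-stratum probabilities).  Strata with no pregnancies do not appear.
    Returns one row per realized stratum with ``T``, the weighted PT and B
    counts, unweighted counts, and the Wilson interval.
    """
    if len(episodes) == 0:
        return pd.DataFrame(columns=[*by, "T", "weighted_PT", "weighted_B",
                                     "n_unweighted", "n_pt_unweighted",
                                     "ci_low", "ci_high"])
    _check_episode_frame(episodes)
    df = episodes.copy()
    df["_is_pt"] = (df["outcome"] == "PT").astype(float)
    df["_w_pt"] = df["weight"] * df["_is_pt"]

    def agg(g: pd.DataFrame) -> pd.Series:
        w_pt = g["_w_pt"].sum()
        w_all = g["weight"].sum()
        k = int(g["_is_pt"].sum())
        n = len(g)
        low, high = wilson_ci(k, n, conf)
        return pd.Series({
            "T": w_pt / w_all, "weighted_PT": w_pt,
            "weighted_B": w_all - w_pt, "n_unweighted": n,
            "n_pt_unweighted": k, "ci_low": low, "ci_high": high,
        })

    if not by:
        out = agg(df).to_frame().T
        out["n_unweighted"] = out["n_unweighted"].astype(int)
        out["n_pt_unweighted"] = out["n_pt_unweighted"].astype(int)
        return out.reset_index(drop=True)
    out = (df.groupby(list(by), observed=True, dropna=False)
             .apply(agg, include_groups=False)
             .reset_index())
    out["n_unweighted"] = out["n_unweighted"].astype(int)
    out["n_pt_unweighted"] = out["n_pt_unweighted"].astype(int)
    return out


def estimate_T_by_type(episodes: pd.DataFrame, by: Sequence[str] = (),
                       conf: float = 0.95) -> pd.DataFrame:
    """Per-type conditional probabilities ``T_IA`` and ``T_ST``.

    The denominator in both is all pregnancies (not terminations), so
    ``T_IA + T_ST = T`` within each stratum.  Requires every terminated
    pregnancy to carry a known type; surveys not reporting the type must go
    through :func:`estimate_T` instead.
    """
    _check_episode_frame(episodes)
    pt = episodes[episodes["outcome"] == "PT"]
    if pt["pt_type"].isna().any():
        raise ValueError(
            "episodes with unknown termination type present; per-type "
            "estimation needs surveys reporting the type of termination — "
            "use estimate_T for the all-terminations probability")
    base = estimate_T(episodes, by, conf)
    df = episodes.copy()
    for label, col in (("IA", "T_IA"), ("ST", "T_ST")):
        df["_w"] = df["weight"] * (df["pt_type"] == label).astype(float)
        if by:
            part = (df.groupby(list(by), observed=True)["_w"].sum()
                    / df.groupby(list(by), observed=True)["weight"].sum())
            base = base.merge(part.rename(col).reset_index(), on=list(by))
        else:
            base[col] = df["_w"].sum() / df["weight"].sum()
    return base
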