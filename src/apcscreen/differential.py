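"""Per-protein differential abundance between treatment arms.

Statistics follow the screen's stated rationale: fold change is the ratio
of arm means of the relative-abundance values; significance is a
two-tailed, unpaired (equal-variance) Student's t-test on the untransformed
RA replicates; the fold-change cutoff is calibrated as the median fold
change of previously reported substrates detected in the run; and a power
analysis (delta 15% of the protein mean, alpha 0.05, power 0.95) reports
the continuous number of observations per group each protein would need.

No multiple-testing correction enters the screen decision (candidates are
filtered on raw p < 0.05); Benjamini-Hochberg q-values are emitted as an
extra column for the user only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

RA_PREFIX = "ra_"


class ZeroVarianceError(ValueError):
    """Both groups are constant: the t statistic is undefined (not p=0)."""


@dataclass
class Contrast:
    """Treated-vs-control channel sets (PSM-dialect names, e.g. ``ch4``)."""

    treated: list[str]
    control: list[str]
    label: str = "treated_vs_control"

    def __post_init__(self) -> None:
        if set(self.treated) & set(self.control):
            raise ValueError("treated and control channels must be disjoint")
        if len(self.treated) < 2 or len(self.control) < 2:
            raise ValueError("each arm needs >= 2 channels")

    def ra_columns(self, which: str) -> list[str]:
        cols = self.treated if which == "treated" else self.control
        return [RA_PREFIX + c for c in cols]


def t_test(x, y) -> tuple[float, float]:
    """Two-tailed, unpaired Student's t-test with pooled variance.

    df = len(x) + len(y) - 2; p from the central t distribution.  Raises
    :class:`ZeroVarianceError` when the pooled variance is zero, which is
    distinct from a true p of 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    nx, ny = len(x), len(y)
    df = nx + ny - 2
    sp2 = (np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2)) / df
    if sp2 <= 0:
        raise ZeroVarianceError("zero pooled variance: t statistic undefined")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def fold_change(x, y) -> float:
    """mean(treated) / mean(control); control mean must be positive."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    my = y.mean()
    if my <= 0:
        raise ValueError("control mean must be positive to form a fold change")
    return float(x.mean() / my)


def calibrate_fc_threshold(results: pd.DataFrame, known_substrates: set[str]) -> float:
    """Median fold change over detected known substrates.

    The screen's fold-change cutoff is anchored to the behaviour of
    previously reported substrates inside the same run, so the threshold
    inherits the experiment's effective sensitivity.
    """
    detected = results.loc[results["protein"].isin(known_substrates), "fc"]
    if detected.empty:
        raise ValueError(
            "no known substrates detected in results; supply a manual fold-change threshold"
        )
    return float(detected.median())


def _power_two_sample(n: float, d: float, alpha: float) -> float:
    """Power of the two-sided, two-sample t-test at continuous n per group."""
    df = 2.0 * n - 2.0
    if df <= 0:
        return 0.0
    nc = d * np.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    power = float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
    if not np.isfinite(power):  # extreme noncentrality overflows the nct cdf
        return 1.0 if nc > tcrit else 0.0
    return power


def required_n(
    sd: float,
    mean: float,
    delta_frac: float = 0.15,
    alpha: float = 0.05,
    power: float = 0.95,
) -> float:
    """Continuous observations per group to detect a ``delta_frac`` shift.

    Solves the two-sample, two-sided noncentral-t power equation at effect
    size ``d = delta_frac * mean / sd``.  The result is continuous (no
    rounding) and floored at 2, the smallest group size with positive
    degrees of freedom.
    """
    if sd <= 0 or mean <= 0:
        raise ValueError("sd and mean must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    d = delta_frac * mean / sd
    if _power_two_sample(2.0, d, alpha) >= power:
        return 2.0
    lo, hi = 2.0, 4.0
    while _power_two_sample(hi, d, alpha) < power:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("required n did not converge (effect size ~ 0)")
    return float(
        optimize.brentq(lambda n: _power_two_sample(n, d, alpha) - power, lo, hi, xtol=1e-9)
    )


def screen_filter(
    results: pd.DataFrame,
    fc_threshold: float,
    min_peptides: int = 2,
    alpha: float = 0.05,
) -> set[str]:
    """Candidate cascade: fc >= threshold (inclusive), >1 peptide, p < alpha (strict)."""
    keep = (
        (results["fc"] >= fc_threshold)
        & (results["n_peptides"] >= min_peptides)
        & (results["p"] < alpha)
    )
    return set(results.loc[keep.fillna(False), "protein"])


def ko_intersection(
    wt_vs_ko1: pd.DataFrame,
    wt_vs_ko2: pd.DataFrame,
    change_frac: float = 0.20,
    alpha: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Proteins changing significantly by more than ``change_frac`` in both
    knockout clones, split by direction on the linear fold-change scale
    (decrease: FC < 1 - change_frac; increase: FC > 1 + change_frac)."""
    m = wt_vs_ko1.merge(wt_vs_ko2, on="protein", suffixes=("_1", "_2"))
    sig = (m["p_1"] < alpha) & (m["p_2"] < alpha)
    down = sig & (m["fc_1"] < 1.0 - change_frac) & (m["fc_2"] < 1.0 - change_frac)
    up = sig & (m["fc_1"] > 1.0 + change_frac) & (m["fc_2"] > 1.0 + change_frac)
    return set(m.loc[down, "protein"]), set(m.loc[up, "protein"])


# ---------------------------------------------------------------------------
# Batch analysis over an RA table
# ---------------------------------------------------------------------------


def differential_analysis(
    ra: pd.DataFrame,
    contrast: Contrast,
    delta_frac: float = 0.15,
    alpha: float = 0.05,
    power: float = 0.95,
    log2_transform: bool = False,
    power_analysis: bool = True,
) -> pd.DataFrame:
    """Per-protein fold change, t-test, BH q-value, and required n.

    Fold changes are always ratios of raw RA means; the t-test may
    optionally run on log2-transformed replicates (``log2_transform``).
    Proteins with zero pooled variance get p = NaN (undefined, not
    significant).  The power analysis uses the pooled within-arm standard
    deviation of the raw RA values.
    """
    tcols = contrast.ra_columns("treated")
    ccols = contrast.ra_columns("control")
    missing = [c for c in tcols + ccols if c not in ra.columns]
    if missing:
        raise KeyError(f"RA table lacks contrast columns: {missing}")
    out_cols = ["protein", "fc", "p", "q_bh", "n_peptides", "n_required"]
    if ra.empty:
        return pd.DataFrame(columns=out_cols)

    x = ra[tcols].to_numpy(dtype=float)  # treated
    y = ra[ccols].to_numpy(dtype=float)  # control
    nx, ny = x.shape[1], y.shape[1]
    mx, my = x.mean(axis=1), y.mean(axis=1)
    fc = np.where(my > 0, mx / np.where(my > 0, my, np.nan), np.nan)

    xt = np.log2(np.clip(x, 1e-12, None)) if log2_transform else x
    yt = np.log2(np.clip(y, 1e-12, None)) if log2_transform else y
    dof = nx + ny - 2
    ss = ((xt - xt.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (yt - yt.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    sp2 = ss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = (xt.mean(axis=1) - yt.mean(axis=1)) / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = np.where(sp2 > 0, 2.0 * stats.t.sf(np.abs(tstat), dof), np.nan)

    ok = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]

    n_req = np.full(len(ra), np.nan)
    if power_analysis:
        pooled_sd = np.sqrt(sp2) if not log2_transform else np.sqrt(
            (((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
             + ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)) / dof
        )
        grand_mean = (x.sum(axis=1) + y.sum(axis=1)) / (nx + ny)
        for i in range(len(ra)):
            if pooled_sd[i] > 0 and grand_mean[i] > 0:
                n_req[i] = required_n(pooled_sd[i], grand_mean[i], delta_frac, alpha, power)

    out = pd.DataFrame(
        {
            "protein": ra["protein"].to_numpy(),
            "fc": fc,
            "p": p,
            "q_bh": q,
            "n_peptides": ra["n_peptides"].to_numpy(),
            "n_required": n_req,
        }
    )
    return out[out_cols]
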