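"""Repeated-measures correlation between normalized 2-h aggregates and
PRO responses.

The repeated-measures correlation (rmcorr, Bakdash & Marusich) removes
between-participant differences in level by fitting a common
within-participant slope in an analysis-of-covariance formulation
(participant as factor, the feature aggregate as covariate).  The
statistic is

    r_rm = sign(b) * sqrt(SS_x / (SS_x + SS_err)),   df = N - k - 1

for N paired observations from k participants.  Inclusion follows the
pipeline's reliability rules: windows with channel coverage below 70%
are dropped, and a participant enters a feature-PRO cell only with at
least three surviving pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

COVERAGE_MIN = 0.70
MIN_PAIRS = 3
ALPHA = 0.05


@dataclass
class RmcorrResult:
    r: float
    df: int
    p: float
    ci95: Tuple[float, float]
    n_pairs: int
    n_participants: int
    slope: float


def filter_pairs(
    table: pd.DataFrame,
    coverage_min: float = COVERAGE_MIN,
    min_pairs: int = MIN_PAIRS,
) -> pd.DataFrame:
    """Apply the coverage and minimum-pair inclusion rules.

    Drops rows with feature coverage < ``coverage_min`` or missing
    values, then drops participants contributing fewer than
    ``min_pairs`` rows within each (feature, PRO item) cell.
    """
    t = table.copy()
    t = t[t["coverage"] >= coverage_min]
    t = t[np.isfinite(t["normalized"]) & np.isfinite(t["pro_value"])]
    counts = t.groupby(["feature", "item_id", "participant_id"])[
        "normalized"
    ].transform("size")
    return t[counts >= min_pairs]


def rmcorr(
    x: np.ndarray, y: np.ndarray, participant: np.ndarray
) -> Optional[RmcorrResult]:
    """Repeated-measures correlation of paired observations.

    Equivalent to Pearson correlation of the within-participant
    centred x and y, with degrees of freedom N - k - 1.  Returns
    ``None`` when degenerate (no within-participant variance in x, or
    df < 1).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    participant = np.asarray(participant)
    codes, uniq = pd.factorize(participant)
    k = len(uniq)
    n = len(x)
    df = n - k - 1
    if k < 1 or df < 1:
        return None
    xc = x - np.bincount(codes, weights=x)[codes] / np.bincount(codes)[codes]
    yc = y - np.bincount(codes, weights=y)[codes] / np.bincount(codes)[codes]
    ss_x = float(xc @ xc)
    ss_y = float(yc @ yc)
    if ss_x <= 0 or ss_y <= 0:
        return None
    b = float(xc @ yc) / ss_x
    resid = yc - b * xc
    ss_err = float(resid @ resid)
    r = np.sign(b) * np.sqrt(max(1.0 - ss_err / ss_y, 0.0))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) < 1.0:
        tval = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(tval), df))
    else:
        p = 0.0
    # Fisher-z interval with the rmcorr degrees of freedom
    if df > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(df - 1)
        lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    else:
        lo, hi = -1.0, 1.0
    return RmcorrResult(r, int(df), p, (float(lo), float(hi)), n, k, b)


def correlation_matrix(
    filtered: pd.DataFrame, alpha: float = ALPHA, bh_adjust: bool = False
) -> pd.DataFrame:
    """rmcorr per (group x feature x PRO item), heat-map-ready.

    Cells are flagged significant at raw p < alpha; an optional
    Benjamini-Hochberg flag (off by default) adjusts within each group.
    """
    rows = []
    for (group, feature, item), cell in filtered.groupby(
        ["group", "feature", "item_id"], sort=True
    ):
        res = rmcorr(
            cell["normalized"].to_numpy(),
            cell["pro_value"].to_numpy(),
            cell["participant_id"].to_numpy(),
        )
        if res is None:
            continue
        rows.append(
            {
                "group": group,
                "feature": feature,
                "item_id": item,
                "r": res.r,
                "df": res.df,
                "p": res.p,
                "ci_lo": res.ci95[0],
                "ci_hi": res.ci95[1],
                "n_pairs": res.n_pairs,
                "n_participants": res.n_participants,
                "significant": res.p < alpha,
            }
        )
    out = pd.DataFrame(rows)
    if bh_adjust and len(out):
        from statsmodels.stats.multitest import multipletests

        for group, grp in out.groupby("group"):
            rej, _, _, _ = multipletests(grp["p"], alpha=alpha, method="fdr_bh")
            out.loc[grp.index, "significant_bh"] = rej
    return out


def heatmap(results: pd.DataFrame, path, group: Optional[str] = None) -> None:
    """Save a feature x PRO heat map of r values (significant cells
    outlined), one panel per group unless ``group`` is given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = [group] if group else sorted(results["group"].unique())
    fig, axes = plt.subplots(
        1, len(groups), figsize=(6 * len(groups), 10), squeeze=False
    )
    for ax, g in zip(axes[0], groups):
        sub = results[results["group"] == g]
        pivot = sub.pivot_table(index="feature", columns="item_id", values="r")
        im = ax.imshow(pivot.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r", aspect="auto")
        ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(len(pivot.index)), pivot.index, fontsize=6)
        ax.set_title(g)
        sig = sub.pivot_table(index="feature", columns="item_id", values="significant")
        for i in range(pivot.shape[0]):
            for j in range(pivot.shape[1]):
                if sig.to_numpy()[i, j] == 1:
                    ax.add_patch(
                        plt.Rectangle(
                            (j - 0.5, i - 0.5), 1, 1, fill=False, lw=1.2, ec="black"
                        )
                    )
    fig.colorbar(im, ax=axes[0], shrink=0.5)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def associate(
    feature_table: pd.DataFrame,
    alpha: float = ALPHA,
    coverage_min: float = COVERAGE_MIN,
    min_pairs: int = MIN_PAIRS,
) -> pd.DataFrame:
    """Filter then correlate: the module's end-to-end entry point."""
    return correlation_matrix(
        filter_pairs(feature_table, coverage_min, min_pairs), alpha
    )
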