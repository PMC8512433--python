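"""Targeted quantitation of confirmed compounds and odor-activity ranking.

Concentrations come from 1/x-weighted linear calibration of the analyte /
internal-standard response ratio; compounds without an authentic standard are
semi-quantified as internal-standard equivalents (response factor 1). Each
compound's odor activity value (OAV = concentration / odor threshold) ranks
its likely sensory relevance. Quantified compounds are then modelled with a
two-way fixed-effects ANOVA (rootstock, irrigation, interaction) and a Tukey
HSD post-hoc on the interaction cells, summarised as a compact letter display
(Duncan's multiple range test is available behind a flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthio import SampleMeta

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationCurve",
    "Quantitation",
    "CompoundAnova",
    "response_ratio",
    "fit_calibration",
    "predict_concentration",
    "semi_quantify",
    "compute_oav",
    "compound_anova",
    "compact_letter_display",
]


@dataclass
class CalibrationCurve:
    """1/x-weighted linear calibration: response ratio vs concentration.

    ``usable`` requires weighted r² ≥ min_r2 (default 0.99); out-of-range
    predictions are flagged, not refused.
    """

    compound: str
    slope: float
    intercept: float
    r2: float
    x_min: float
    x_max: float
    is_name: str = "2-Octanol"
    weighting: str = "1/x"
    n_levels: int = 0
    min_r2: float = 0.99

    @property
    def usable(self) -> bool:
        return bool(self.r2 >= self.min_r2 and self.slope != 0)


@dataclass
class Quantitation:
    compound: str
    sample_id: str
    conc: float  # µg/L
    mode: str  # "quantified" | "semi"
    oav: float | None = None
    flags: set[str] = field(default_factory=set)


def response_ratio(analyte_area: float, is_area: float) -> float:
    """Analyte / internal-standard peak-area ratio."""
    if is_area <= 0:
        raise ValueError("internal-standard area must be positive")
    if analyte_area < 0:
        raise ValueError("analyte area must be non-negative")
    return analyte_area / is_area


def fit_calibration(
    levels: Sequence[tuple[float, float]],
    compound: str = "",
    is_name: str = "2-Octanol",
    min_r2: float = 0.99,
) -> CalibrationCurve:
    """Weighted least squares fit of response ratio y on concentration x with
    weights 1/x (closed form). The weighted r² is
    1 − Σw(y−ŷ)²/Σw(y−ȳ_w)²; a curve with r² below ``min_r2`` is flagged
    unusable, not rejected with an error. Fewer than five levels warns;
    fewer than two distinct x is an error."""
    x = np.array([lv[0] for lv in levels], dtype=float)
    y = np.array([lv[1] for lv in levels], dtype=float)
    if np.any(x <= 0):
        raise ValueError("calibration concentrations must be strictly positive for 1/x weighting")
    if np.unique(x).size < 2:
        raise ValueError("calibration needs at least two distinct concentration levels")
    if x.size < 5:
        logger.warning("calibration for %r has only %d levels (5 recommended)", compound, x.size)
    w = 1.0 / x
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    slope = (w * (x - xbar) * (y - ybar)).sum() / sxx if sxx > 0 else 0.0
    intercept = ybar - slope * xbar
    yhat = intercept + slope * x
    ss_res = (w * (y - yhat) ** 2).sum()
    ss_tot = (w * (y - ybar) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    curve = CalibrationCurve(
        compound=compound,
        slope=float(slope),
        intercept=float(intercept),
        r2=float(r2),
        x_min=float(x.min()),
        x_max=float(x.max()),
        is_name=is_name,
        n_levels=int(x.size),
        min_r2=min_r2,
    )
    if not curve.usable:
        logger.warning("calibration for %r flagged: r2=%.4f slope=%.3g", compound, r2, slope)
    return curve


def predict_concentration(curve: CalibrationCurve, ratio: float) -> tuple[float, set[str]]:
    """Invert the calibration: conc = (ratio − intercept) / slope (µg/L).

    Returns (concentration, flags); predictions outside the calibrated range
    are flagged ``below_range`` / ``above_range``, negative inversions are
    clipped to 0 and flagged."""
    if curve.slope == 0:
        raise ValueError(f"calibration for {curve.compound!r} has zero slope")
    if not curve.usable:
        raise ValueError(f"calibration for {curve.compound!r} is not usable (r2={curve.r2:.4f})")
    conc = (ratio - curve.intercept) / curve.slope
    flags: set[str] = set()
    if conc < curve.x_min:
        flags.add("below_range")
    if conc > curve.x_max:
        flags.add("above_range")
    if conc < 0:
        conc = 0.0
        flags.add("clipped_negative")
    return float(conc), flags


def semi_quantify(ratio: float, is_conc: float = 50.0) -> float:
    """Semi-quantitation in internal-standard equivalents: assuming a
    response factor of 1, conc = ratio × IS concentration (50 µg/L for the
    2-octanol spike)."""
    if ratio < 0:
        raise ValueError("response ratio must be non-negative")
    return ratio * is_conc


def compute_oav(conc: float, odor_threshold: float | None) -> float | None:
    """Odor activity value = concentration / odor threshold; ``None`` (not 0)
    when no threshold is known."""
    if odor_threshold is None:
        return None
    if odor_threshold <= 0:
        raise ValueError("odor threshold must be positive")
    return conc / odor_threshold


# ---------------------------------------------------------------------------
# compound-level two-way ANOVA with letters
# ---------------------------------------------------------------------------


@dataclass
class CompoundAnova:
    compound: str
    p_rootstock: float
    p_irrigation: float
    p_interaction: float | None
    cell_means: pd.DataFrame      # rootstock × irrigation, µg/L
    letters: dict[tuple[str, str], str]
    posthoc: str = "tukey"


def _pairwise_tukey_p(groups: list[np.ndarray]) -> np.ndarray:
    """All-pairwise Tukey HSD p-value matrix over groups (pooled variance)."""
    k = len(groups)
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    df_w = int(ns.sum() - k)
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    mse = ssw / df_w if df_w > 0 else 0.0
    P = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if mse <= 0:
                p = 1.0 if means[i] == means[j] else 0.0
            else:
                se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(means[i] - means[j]) / se
                p = float(stats.studentized_range.sf(q, k, df_w))
            P[i, j] = P[j, i] = p
    return P


def _pairwise_duncan_reject(groups: list[np.ndarray], alpha: float) -> np.ndarray:
    """Duncan's multiple range test: boolean reject matrix over groups.

    Means are ordered; a pair spanning p means is declared different when the
    studentized range exceeds the critical value at the protection level
    1 − (1 − alpha)^(p−1)."""
    k = len(groups)
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    df_w = int(ns.sum() - k)
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    mse = ssw / df_w if df_w > 0 else 0.0
    order = np.argsort(means)
    reject = np.zeros((k, k), dtype=bool)
    if mse <= 0:
        for i in range(k):
            for j in range(k):
                reject[i, j] = means[i] != means[j]
        return reject
    n_h = stats.hmean(ns)
    for a in range(k):
        for b in range(a + 1, k):
            i, j = order[a], order[b]
            span = b - a + 1
            alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
            crit = stats.studentized_range.ppf(1.0 - alpha_p, span, df_w)
            q = abs(means[i] - means[j]) / np.sqrt(mse / n_h)
            reject[i, j] = reject[j, i] = bool(q > crit)
    return reject


def compact_letter_display(labels: Sequence, different: np.ndarray) -> dict:
    """Insert-and-absorb compact letter display.

    ``different[i, j]`` is True when groups i and j are significantly
    different. Two groups share a letter iff they are not significantly
    different (valid clique cover of the non-significance graph)."""
    k = len(labels)
    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not different[i, j]:
                continue
            for col in [c for c in columns if i in c and j in c]:
                columns.remove(col)
                a, b = set(col), set(col)
                a.discard(i)
                b.discard(j)
                for new in (a, b):
                    if new and not any(new <= other for other in columns):
                        columns.append(new)
            # absorb: drop columns that became subsets
            columns = [c for c in columns if not any(c < other for other in columns)]
    # deterministic letter order: by smallest member, then size
    columns.sort(key=lambda c: (min(c), -len(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for idx, col in enumerate(columns):
        letter = alphabet[idx % len(alphabet)] * (1 + idx // len(alphabet))
        for member in sorted(col):
            out[labels[member]] += letter
    return out


def compound_anova(
    conc: pd.Series,
    metadata: Mapping[str, SampleMeta],
    compound: str = "",
    alpha: float = 0.05,
    posthoc: str = "tukey",
) -> CompoundAnova:
    """Two-way fixed-effects ANOVA of one compound's concentrations
    (rootstock + irrigation + interaction, type-I sums of squares) and an
    all-pairwise post-hoc over the 12 interaction cells with a compact letter
    display. With empty design cells the interaction is dropped and letters
    are computed on rootstock main-effect means instead."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame(
        {
            "conc": conc.values,
            "rootstock": [metadata[s].rootstock for s in conc.index],
            "irrigation": [metadata[s].irrigation for s in conc.index],
        },
        index=conc.index,
    )
    df["cell"] = df["rootstock"] + ":" + df["irrigation"]
    cells = df.groupby(["rootstock", "irrigation"], observed=True).size()
    full = df["rootstock"].nunique() * df["irrigation"].nunique()
    has_interaction = len(cells) == full and (cells >= 1).all() and (df.groupby("cell").size() >= 2).any()
    if len(cells) < full:
        logger.warning("compound %r: empty design cells; interaction dropped", compound)
        has_interaction = False

    if df["conc"].nunique() == 1:
        # all cells equal: nothing to test
        cell_means = df.pivot_table(index="rootstock", columns="irrigation", values="conc", aggfunc="mean")
        labels = [(r, i) for r in cell_means.index for i in cell_means.columns]
        return CompoundAnova(
            compound=compound,
            p_rootstock=1.0,
            p_irrigation=1.0,
            p_interaction=1.0 if has_interaction else None,
            cell_means=cell_means,
            letters={lab: "a" for lab in labels},
            posthoc=posthoc,
        )

    formula = "conc ~ C(rootstock) + C(irrigation)"
    if has_interaction:
        formula += " + C(rootstock):C(irrigation)"
    fit = smf.ols(formula, data=df).fit()
    tab = anova_lm(fit, typ=1)
    p_rs = float(tab.loc["C(rootstock)", "PR(>F)"])
    p_ir = float(tab.loc["C(irrigation)", "PR(>F)"])
    p_int = (
        float(tab.loc["C(rootstock):C(irrigation)", "PR(>F)"])
        if "C(rootstock):C(irrigation)" in tab.index
        else None
    )

    if has_interaction:
        group_keys = sorted(df["cell"].unique())
        groups = [df.loc[df["cell"] == gkey, "conc"].values for gkey in group_keys]
        labels = [tuple(gkey.split(":")) for gkey in group_keys]
    else:
        group_keys = sorted(df["rootstock"].unique())
        groups = [df.loc[df["rootstock"] == gkey, "conc"].values for gkey in group_keys]
        labels = list(group_keys)
    if posthoc == "tukey":
        pmat = _pairwise_tukey_p(groups)
        different = pmat < alpha
    elif posthoc == "duncan":
        different = _pairwise_duncan_reject(groups, alpha)
    else:
        raise ValueError(f"unknown posthoc {posthoc!r}")
    letters = compact_letter_display(labels, different)
    cell_means = df.pivot_table(index="rootstock", columns="irrigation", values="conc", aggfunc="mean")
    return CompoundAnova(
        compound=compound,
        p_rootstock=p_rs,
        p_irrigation=p_ir,
        p_interaction=p_int,
        cell_means=cell_means,
        letters=letters,
        posthoc=posthoc,
    )
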