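"""Manly selectivity measures under a use/availability design III.

Each animal j has used counts u_ij over habitat categories i and its own
available proportions pi_ij (summing to 1 over the categories present in its
home range).  The per-animal selection ratio is

    w_ij = (u_ij / u_+j) / pi_ij,

the log-likelihood chi-square for animal j is

    chi2_Lj = 2 * sum_{i: u_ij > 0} u_ij * ln(u_ij / (u_+j * pi_ij)),

and the global (design III) ratio for category i pools animals for which the
category was available:

    w_i = sum_j u_ij / sum_j u_+j * pi_ij.

The global statistic is the sum of per-animal chi-squares with
df = sum_j (I_j - 1), I_j the number of categories available to animal j.
Confidence intervals use a Bonferroni-adjusted normal quantile across the I
categories, with the SE estimated from among-animal variability of the w_ij.
A category is "selected" when the CI lies above 1 and "avoided" when it lies
inside (0, 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("habselect")


@dataclass
class DesignIIIInput:
    """Used counts and available proportions for one animal."""

    animal_id: str
    used: pd.Series       # index = category, integer counts >= 0
    available: pd.Series  # index = category, proportions summing to 1

    def __post_init__(self) -> None:
        self.used = self.used.astype(float)
        self.available = self.available.astype(float)
        if (self.used < 0).any():
            raise ValueError(f"animal {self.animal_id!r}: negative used count")
        if (self.available < 0).any():
            raise ValueError(f"animal {self.animal_id!r}: negative availability")
        tot = self.available.sum()
        if not np.isclose(tot, 1.0, atol=1e-6):
            raise ValueError(
                f"animal {self.animal_id!r}: available proportions sum to {tot}"
            )
        for cat, u in self.used.items():
            if u > 0 and self.available.get(cat, 0.0) <= 0:
                raise ValueError(
                    f"animal {self.animal_id!r}: category {cat!r} used but "
                    "unavailable"
                )

    @property
    def total_used(self) -> float:
        return float(self.used.sum())


def ratios_per_animal(inp: DesignIIIInput) -> tuple[pd.Series, float]:
    """Per-animal selection ratios w_ij and the log-likelihood chi-square."""
    if inp.total_used <= 0:
        raise ValueError(f"animal {inp.animal_id!r}: no used locations")
    if inp.total_used < 5:
        logger.warning(
            "animal %r has only %d used locations; ratios will be unstable",
            inp.animal_id, int(inp.total_used),
        )
    avail = inp.available[inp.available > 0]
    used = inp.used.reindex(avail.index, fill_value=0.0)
    w = (used / inp.total_used) / avail
    pos = used > 0
    chi2 = 2.0 * float(
        (used[pos] * np.log(used[pos] / (inp.total_used * avail[pos]))).sum()
    )
    w.index.name = "category"
    return w, chi2


def global_ratios(
    inputs: list[DesignIIIInput],
    alpha: float = 0.05,
    variance: str = "ratio",
) -> pd.DataFrame:
    """Global Manly selection ratios pooled over animals.

    Returns a tidy table with one row per category plus a ``__global__``
    summary row carrying the summed chi-square, df and p-value.  Animals for
    which a category was unavailable are excluded from that category's sums
    and from its SE.

    ``variance`` selects the SE of the global ratio.  ``"ratio"`` (default)
    is the design III ratio-estimator variance,

        var(w_i) = K/(K-1) * sum_j (u_ij - w_i * u_+j * pi_ij)^2
                   / (sum_j u_+j * pi_ij)^2,

    which weights each animal by its availability-based denominator and is
    stable when a category is nearly unavailable to some animal.
    ``"among_animal"`` uses the empirical variance of the per-animal ratios,
    s^2({w_ij}) / K; it is distribution-free but heavy-tailed when some
    pi_ij is tiny (w_ij = small count / tiny proportion explodes).
    """
    if variance not in ("ratio", "among_animal"):
        raise ValueError("variance must be 'ratio' or 'among_animal'")
    if not inputs:
        raise ValueError("no animals supplied")
    categories = sorted(
        set().union(*(inp.available[inp.available > 0].index for inp in inputs))
    )
    I = len(categories)
    zcrit = stats.norm.ppf(1 - alpha / (2 * I))  # Bonferroni across categories

    per_animal_w: dict[str, pd.Series] = {}
    chi2_total, df_total = 0.0, 0
    for inp in inputs:
        w, chi2 = ratios_per_animal(inp)
        per_animal_w[inp.animal_id] = w
        chi2_total += chi2
        df_total += max(len(w) - 1, 0)

    rows = []
    for cat in categories:
        num = den = 0.0
        w_js, u_js, d_js = [], [], []
        for inp in inputs:
            pi = float(inp.available.get(cat, 0.0))
            if pi <= 0:
                continue
            u = float(inp.used.get(cat, 0.0))
            num += u
            den += inp.total_used * pi
            w_js.append(per_animal_w[inp.animal_id][cat])
            u_js.append(u)
            d_js.append(inp.total_used * pi)
        w_global = num / den
        k = len(w_js)
        if k > 1:
            if variance == "ratio":
                resid = np.asarray(u_js) - w_global * np.asarray(d_js)
                se = float(np.sqrt(k / (k - 1) * (resid**2).sum()) / den)
            else:
                se = float(np.std(w_js, ddof=1) / np.sqrt(k))
        else:
            se = np.nan
        # ratios are non-negative, so the normal CI is clipped at 0
        lo = max(w_global - zcrit * se, 0.0) if k > 1 else np.nan
        hi = w_global + zcrit * se if k > 1 else np.nan
        if np.isnan(lo):
            status = "undetermined"
        elif lo > 1:
            status = "selected"
        elif hi < 1:
            status = "avoided"
        else:
            status = "proportional"
        rows.append(
            dict(category=cat, w=w_global, se=se, ci_low=lo, ci_high=hi,
                 n_animals=k, status=status)
        )
    out = pd.DataFrame(rows)
    p = float(stats.chi2.sf(chi2_total, df_total)) if df_total > 0 else np.nan
    summary = pd.DataFrame(
        [dict(category="__global__", w=np.nan, se=np.nan, ci_low=np.nan,
              ci_high=np.nan, n_animals=len(inputs), status="",
              chi2=chi2_total, df=df_total, p=p)]
    )
    out["chi2"] = np.nan
    out["df"] = np.nan
    out["p"] = np.nan
    return pd.concat([out, summary], ignore_index=True)


def per_animal_table(inputs: list[DesignIIIInput]) -> pd.DataFrame:
    """Tidy per-animal ratio table (animal, category, w, chi2)."""
    rows = []
    for inp in inputs:
        w, chi2 = ratios_per_animal(inp)
        for cat, val in w.items():
            rows.append(dict(animal=inp.animal_id, category=cat, w=float(val),
                             chi2=chi2))
    return pd.DataFrame(rows)


def group_ratios(
    inputs: list[DesignIIIInput],
    groups: dict[str, str],
    alpha: float = 0.05,
    variance: str = "ratio",
) -> dict[str, pd.DataFrame]:
    """Global ratios computed separately within groups (e.g. sex or period)."""
    missing = [inp.animal_id for inp in inputs if inp.animal_id not in groups]
    if missing:
        raise ValueError(f"animals without a group label: {missing}")
    out: dict[str, pd.DataFrame] = {}
    for g in sorted(set(groups.values())):
        members = [inp for inp in inputs if groups[inp.animal_id] == g]
        out[g] = global_ratios(members, alpha=alpha, variance=variance)
    return out
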