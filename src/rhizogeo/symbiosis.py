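"""Greenhouse symbiotic-effectiveness analysis.

Trials follow a randomized complete block design (RCBD): every strain (plus an
uninoculated control) grown in r replicate blocks, measuring nodule number,
nodule dry weight (mg), shoot dry weight (g) and root dry weight (g).

Two derived outcomes, matching field usage:

* "symbiotic response"   - the first principal component of the scaled trait
  matrix, a synthetic nodulation-plus-biomass score;
* "symbiotic performance" - shoot dry weight, the plant dry-matter benefit.

Analyses: variance components of the balanced two-way design via expected
mean squares, Dunnett-style many-to-one comparison against the control with a
Monte-Carlo max-t familywise correction, and a genospecies contrast combining
a Welch t-test with a one-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UnbalancedDesignError

TRAIT_COLUMNS = ("nodule_number", "nodule_dw_mg", "shoot_dw_g", "root_dw_g")
#: Trait whose PC1 loading fixes the sign convention of the response score.
SIGN_TRAIT = "nodule_dw_mg"


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read the greenhouse CSV (strain, replicate, four traits); validates
    columns and non-negativity."""
    df = pd.read_csv(path)
    required = {"strain", "replicate", *TRAIT_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    if (df[list(TRAIT_COLUMNS)] < 0).any().any():
        raise ValueError("negative trait measurements")
    return df


def is_balanced(df: pd.DataFrame) -> bool:
    """True when every strain appears exactly once in every replicate block."""
    counts = df.groupby(["strain", "replicate"]).size()
    if (counts != 1).any():
        return False
    pivot = df.pivot_table(index="strain", columns="replicate", values=TRAIT_COLUMNS[0],
                           aggfunc="size", fill_value=0)
    return bool((pivot.to_numpy() == 1).all())


# ---------------------------------------------------------------------------
# Response score (PC1 of scaled traits)

@dataclass(frozen=True)
class ResponseScore:
    """First principal component of the standardized trait matrix."""

    scores: pd.Series                 # one per (strain, replicate) row
    loadings: pd.Series               # unit norm, per retained trait
    explained_variance_ratio: float
    dropped_traits: tuple[str, ...]


def response_pca(df: pd.DataFrame, traits: Sequence[str] = TRAIT_COLUMNS) -> ResponseScore:
    """PC1 of the correlation-scaled trait matrix as the symbiotic-response score.

    Each trait is standardized to zero mean, unit variance; zero-variance
    traits are dropped with a warning.  The sign is oriented so the loading on
    nodule dry weight is positive.
    """
    x = df[list(traits)].astype(float)
    stds = x.std(ddof=1)
    dropped = tuple(stds.index[stds == 0])
    if dropped:
        warnings.warn(f"dropping zero-variance traits: {list(dropped)}", stacklevel=2)
    kept = [t for t in traits if t not in dropped]
    if len(kept) < 2:
        raise ValueError("need at least 2 traits with nonzero variance")
    z = (x[kept] - x[kept].mean()) / x[kept].std(ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    pc1 = evecs[:, -1]
    anchor = SIGN_TRAIT if SIGN_TRAIT in kept else kept[0]
    if pc1[kept.index(anchor)] < 0:
        pc1 = -pc1
    scores = z.to_numpy() @ pc1
    return ResponseScore(
        scores=pd.Series(scores, index=df.index, name="response_pc1"),
        loadings=pd.Series(pc1, index=kept, name="loading"),
        explained_variance_ratio=float(evals[-1] / evals.sum()),
        dropped_traits=dropped,
    )


# ---------------------------------------------------------------------------
# Variance components (balanced RCBD, expected mean squares)

@dataclass(frozen=True)
class VarianceComponents:
    """Method-of-moments components of a balanced two-way design without
    interaction; negative estimates are truncated to zero and flagged."""

    sigma2_strain: float
    sigma2_replicate: float
    sigma2_error: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    truncated: tuple[str, ...]
    f_undefined: bool = False


def variance_components(response: Sequence[float], strain: Sequence, replicate: Sequence) -> VarianceComponents:
    """Two-way ANOVA without interaction on a balanced RCBD.

    sigma^2_strain = (MS_strain - MS_error) / r; the strain test is the exact
    F = MS_strain / MS_error with (s-1, (s-1)(r-1)) degrees of freedom.
    Unbalanced layouts are rejected.
    """
    df = pd.DataFrame({"y": np.asarray(response, dtype=float),
                       "strain": list(strain), "replicate": list(replicate)})
    wide = df.pivot_table(index="strain", columns="replicate", values="y", aggfunc="count",
                          fill_value=0)
    if (wide.to_numpy() != 1).any():
        raise UnbalancedDesignError(
            "design is not a balanced RCBD (every strain once per replicate); "
            "unbalanced greenhouse data needs a general mixed-model fit, out of scope here"
        )
    y = df.pivot(index="strain", columns="replicate", values="y").to_numpy()
    s, r = y.shape
    if s < 2 or r < 2:
        raise ValueError("need at least 2 strains and 2 replicates")
    grand = y.mean()
    ss_strain = r * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_rep = s * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_strain - ss_rep
    ms_strain = ss_strain / (s - 1)
    ms_rep = ss_rep / (r - 1)
    ms_err = ss_err / ((s - 1) * (r - 1))

    truncated = []
    sig_strain = (ms_strain - ms_err) / r
    sig_rep = (ms_rep - ms_err) / s
    if sig_strain < 0:
        sig_strain = 0.0
        truncated.append("sigma2_strain")
    if sig_rep < 0:
        sig_rep = 0.0
        truncated.append("sigma2_replicate")

    if ms_err <= 0:
        return VarianceComponents(
            sigma2_strain=float(sig_strain), sigma2_replicate=float(sig_rep),
            sigma2_error=0.0, f_statistic=float("nan"),
            df=(s - 1, (s - 1) * (r - 1)), p_value=float("nan"),
            truncated=tuple(truncated), f_undefined=True,
        )
    f_stat = ms_strain / ms_err
    p = float(stats.f.sf(f_stat, s - 1, (s - 1) * (r - 1)))
    return VarianceComponents(
        sigma2_strain=float(sig_strain), sigma2_replicate=float(sig_rep),
        sigma2_error=float(ms_err), f_statistic=float(f_stat),
        df=(s - 1, (s - 1) * (r - 1)), p_value=p, truncated=tuple(truncated),
    )


# ---------------------------------------------------------------------------
# Dunnett-style many-to-one comparison (Monte-Carlo max-t)

def dunnett_vs_control(
    values: Sequence[float],
    strains: Sequence,
    control: str,
    alpha: float = 0.05,
    n_mc: int = 100_000,
    seed: int | None = None,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Compare every strain against the control with familywise error control.

    t statistics use the pooled within-group variance; the familywise-adjusted
    p per strain is estimated from ``n_mc`` Monte-Carlo draws of the max-t
    statistic under equal group means (Monte-Carlo error O(1/sqrt(n_mc))).
    ``alternative='greater'`` (default) asks whether a strain outperforms the
    control; ``'two-sided'`` uses max |t|.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "strain": list(strains)})
    groups = {name: g["y"].to_numpy() for name, g in df.groupby("strain", sort=False)}
    if control not in groups:
        raise ValueError(f"control group {control!r} not present")
    if len(groups[control]) < 2:
        raise ValueError("control needs at least 2 replicates")
    treatments = [g for g in groups if g != control]
    if len(treatments) < 2:
        raise ValueError("need at least 2 treatment strains")

    n_g = {g: len(v) for g, v in groups.items()}
    n_total = sum(n_g.values())
    k_groups = len(groups)
    nu = n_total - k_groups
    if nu < 1:
        raise ValueError("no residual degrees of freedom")
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    s_pooled = np.sqrt(ss_within / nu)
    if s_pooled == 0:
        raise ValueError("zero pooled within-group variance")

    m0 = groups[control].mean()
    t_obs = np.array(
        [
            (groups[g].mean() - m0) / (s_pooled * np.sqrt(1.0 / n_g[g] + 1.0 / n_g[control]))
            for g in treatments
        ]
    )

    rng = np.random.default_rng(seed)
    z_ctrl = rng.standard_normal(n_mc) / np.sqrt(n_g[control])
    s_mc = np.sqrt(rng.chisquare(nu, size=n_mc) / nu)
    max_t = np.full(n_mc, -np.inf)
    for g in treatments:
        z_g = rng.standard_normal(n_mc) / np.sqrt(n_g[g])
        t_g = (z_g - z_ctrl) / (s_mc * np.sqrt(1.0 / n_g[g] + 1.0 / n_g[control]))
        if alternative == "two-sided":
            t_g = np.abs(t_g)
        max_t = np.maximum(max_t, t_g)

    ref = np.abs(t_obs) if alternative == "two-sided" else t_obs
    p_adj = np.array([(1 + (max_t >= t - 1e-12).sum()) / (n_mc + 1) for t in ref])
    return pd.DataFrame(
        {
            "strain": treatments,
            "n": [n_g[g] for g in treatments],
            "mean": [groups[g].mean() for g in treatments],
            "diff_vs_control": [groups[g].mean() - m0 for g in treatments],
            "t": t_obs,
            "p_adjusted": p_adj,
            "significant": p_adj < alpha,
        }
    )


# ---------------------------------------------------------------------------
# Genospecies contrast

@dataclass(frozen=True)
class ContrastResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    percent_difference: float
    t_p: float
    wilcoxon_p: float
    wilcoxon_method: str


def genospecies_contrast(
    performance: Mapping[str, float],
    labels: Mapping[str, str],
    group_a: str,
    group_b: str,
    alternative: str = "less",
) -> ContrastResult:
    """Contrast per-strain performance between two genospecies.

    Reports group means, percent difference (mean_a - mean_b)/mean_a * 100, a
    two-sided Welch t-test and a one-sided Wilcoxon rank-sum test (default
    alternative: group A stochastically smaller).  The Wilcoxon test is exact
    when both groups have <= 15 strains and no ties, else the tie-corrected
    normal approximation is used.
    """
    a = np.array([v for s, v in performance.items() if labels.get(s) == group_a], dtype=float)
    b = np.array([v for s, v in performance.items() if labels.get(s) == group_b], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 strains")
    t_res = stats.ttest_ind(a, b, equal_var=False)
    exact = len(a) <= 15 and len(b) <= 15 and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if exact else "asymptotic"
    w_res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    pct = (mean_a - mean_b) / mean_a * 100.0 if mean_a != 0 else float("nan")
    return ContrastResult(
        group_a=group_a, group_b=group_b, n_a=len(a), n_b=len(b),
        mean_a=mean_a, mean_b=mean_b, percent_difference=pct,
        t_p=float(t_res.pvalue), wilcoxon_p=float(w_res.pvalue), wilcoxon_method=method,
    )
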