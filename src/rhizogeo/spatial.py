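"""Permutation-based spatial inference.

Mantel and partial Mantel tests (simultaneous row/column permutation of the
focal matrix, +1-corrected p-values), principal coordinates analysis by Gower
double-centering, regression of genetic principal coordinates on geographic
coordinates and altitude with sequential-ANOVA F-tests, and the sliding-window
distance-decay resampler (40-km windows moved at 10-km steps, one random pair
per window, against a baseline of pairs drawn irrespective of distance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import StrainMismatchError
from .gendist import DistanceMatrix

DEFAULT_N_PERM = 9999


# ---------------------------------------------------------------------------
# Mantel machinery

def _check_conformable(*mats: DistanceMatrix) -> None:
    first = mats[0]
    for other in mats[1:]:
        if other.labels != first.labels:
            raise StrainMismatchError(
                "distance matrices must share labels in the same order; "
                f"got {first.labels[:3]}... vs {other.labels[:3]}..."
            )


def _triangle(values: np.ndarray) -> np.ndarray:
    il = np.tril_indices(values.shape[0], -1)
    return values[il]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.sqrt((xc ** 2).sum()), np.sqrt((yc ** 2).sum())
    if nx == 0 or ny == 0:
        raise ValueError("zero variance in a distance-matrix triangle")
    return float((xc * yc).sum() / (nx * ny))


@dataclass(frozen=True)
class MantelResult:
    """Mantel (or partial Mantel) correlation with its permutation p-value."""

    r: float
    p: float
    n_perm: int
    tail: str
    partial: bool = False
    covariate: str | None = None

    def __repr__(self) -> str:  # compact, table-friendly
        kind = f"partial Mantel | {self.covariate}" if self.partial else "Mantel"
        return f"<{kind}: r={self.r:.4f}, p={self.p:.4g} ({self.n_perm} perms, {self.tail})>"


def _perm_pvalue(obs: float, null: np.ndarray, tail: str) -> float:
    eps = 1e-12
    if tail == "two-sided":
        count = int((np.abs(null) >= abs(obs) - eps).sum())
    elif tail == "greater":
        count = int((null >= obs - eps).sum())
    elif tail == "less":
        count = int((null <= obs + eps).sum())
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + count) / (null.size + 1)


def mantel(
    x: DistanceMatrix,
    y: DistanceMatrix,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    tail: str = "two-sided",
) -> MantelResult:
    """Mantel test: Pearson correlation of the strict lower triangles of two
    distance matrices, with significance from simultaneous row/column
    permutations of ``x``."""
    _check_conformable(x, y)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = len(x)
    yv = _triangle(y.values)
    xv = _triangle(x.values)
    r_obs = _pearson(xv, yv)

    rng = np.random.default_rng(seed)
    il = np.tril_indices(n, -1)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        null[k] = _pearson(x.values[np.ix_(perm, perm)][il], yv)
    return MantelResult(r=r_obs, p=_perm_pvalue(r_obs, null, tail), n_perm=n_perm, tail=tail)


def _partial_r(rxy: float, rxz: float, ryz: float) -> float:
    if 1.0 - rxz ** 2 <= 1e-15:
        raise ValueError("degenerate partial correlation: covariate is collinear with x")
    if 1.0 - ryz ** 2 <= 1e-15:
        # z carries all of y's signal; the partial correlation vanishes in the limit
        return 0.0
    den = (1.0 - rxz ** 2) * (1.0 - ryz ** 2)
    return (rxy - rxz * ryz) / np.sqrt(den)


def partial_mantel(
    x: DistanceMatrix,
    y: DistanceMatrix,
    z: DistanceMatrix,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    tail: str = "two-sided",
) -> MantelResult:
    """Partial Mantel test of x~y controlling for covariate z.

    r_xy.z is the first-order partial correlation of the matrix triangles;
    the null permutes x (rows and columns simultaneously) and recomputes the
    partial statistic, r_yz staying fixed.
    """
    _check_conformable(x, y, z)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = len(x)
    xv, yv, zv = (_triangle(m.values) for m in (x, y, z))
    ryz = _pearson(yv, zv)
    r_obs = _partial_r(_pearson(xv, yv), _pearson(xv, zv), ryz)

    rng = np.random.default_rng(seed)
    il = np.tril_indices(n, -1)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        xp = x.values[np.ix_(perm, perm)][il]
        null[k] = _partial_r(_pearson(xp, yv), _pearson(xp, zv), ryz)
    return MantelResult(
        r=float(r_obs),
        p=_perm_pvalue(float(r_obs), null, tail),
        n_perm=n_perm,
        tail=tail,
        partial=True,
        covariate=z.level,
    )


# ---------------------------------------------------------------------------
# Principal coordinates analysis

@dataclass(frozen=True)
class PCoAResult:
    """Metric embedding of a distance matrix.

    ``coordinates`` keeps axes with positive eigenvalues, each scaled by the
    square root of its eigenvalue so Euclidean distances of the coordinates
    approximate the input distances.  Negative eigenvalues (non-Euclidean
    input) are reported, not corrected.
    """

    labels: tuple[str, ...]
    coordinates: np.ndarray        # (n, n_positive) or truncated to n_axes
    eigenvalues: np.ndarray        # all n eigenvalues, non-increasing
    proportion_explained: np.ndarray  # per retained axis, of positive mass
    negative_eigenvalues: np.ndarray

    def axis(self, k: int) -> pd.Series:
        """1-based principal coordinate as a labelled Series."""
        return pd.Series(self.coordinates[:, k - 1], index=list(self.labels), name=f"PCo{k}")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{k + 1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=list(self.labels), columns=cols)


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PCoAResult:
    """Principal coordinates analysis by Gower double-centering.

    G = J (-1/2 D*D) J with J the centering matrix; eigenvectors with positive
    eigenvalues, scaled by sqrt(eigenvalue), are the coordinates.  Requesting
    more axes than there are positive eigenvalues truncates with a warning.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("PCoA needs at least 3 strains")
    d = dm.values
    if not np.isfinite(d).all():
        raise ValueError("PCoA requires fully defined distances")
    a = -0.5 * d * d
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = max(abs(evals[0]), abs(evals[-1]), 1.0) * 1e-12
    pos = evals > tol
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError("no positive eigenvalues: degenerate distance matrix")
    if n_axes is None:
        n_axes = n_pos
    elif n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        n_axes = n_pos
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes])
    return PCoAResult(
        labels=dm.labels,
        coordinates=coords,
        eigenvalues=evals,
        proportion_explained=evals[:n_axes] / evals[pos].sum(),
        negative_eigenvalues=evals[evals < -tol],
    )


# ---------------------------------------------------------------------------
# PCoA regression

def pcoa_regression(
    genetic: PCoAResult,
    geographic: PCoAResult,
    altitude: Mapping[str, float] | pd.Series | None = None,
    n_genetic_axes: int = 2,
    n_geo_axes: int = 2,
) -> pd.DataFrame:
    """Regress each genetic principal coordinate on geographic coordinates
    (default: first two, standing in for latitude/longitude along a transect)
    and altitude, with per-term sequential (type-I) ANOVA F-tests.

    Returns a tidy table with one row per (genetic axis, term) plus the full
    model R-squared repeated per axis.
    """
    if genetic.labels != geographic.labels:
        raise StrainMismatchError("genetic and geographic PCoA results must share strain order")
    if n_genetic_axes > genetic.coordinates.shape[1]:
        raise ValueError("more genetic axes requested than available")
    if n_geo_axes > geographic.coordinates.shape[1]:
        raise ValueError("more geographic axes requested than available")

    labels = list(genetic.labels)
    design = pd.DataFrame(
        {f"geo{k + 1}": geographic.coordinates[:, k] for k in range(n_geo_axes)},
        index=labels,
    )
    if altitude is not None:
        alt = pd.Series(altitude, dtype=float).reindex(labels)
        if alt.isna().any():
            raise ValueError(f"missing altitude for strains: {alt.index[alt.isna()].tolist()}")
        design["altitude"] = alt.to_numpy()

    exog = sm.add_constant(design.to_numpy())
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear predictors)")

    terms = list(design.columns)
    rows = []
    for gk in range(n_genetic_axes):
        y = genetic.coordinates[:, gk]
        fit = sm.OLS(y, exog).fit()
        # sequential ANOVA: add terms one at a time in the given order
        tss = float(((y - y.mean()) ** 2).sum())
        rss_prev = tss
        df_resid = fit.df_resid
        mse = fit.mse_resid
        if mse <= tss * 1e-10:
            mse = 0.0  # saturated fit
        for t_idx, term in enumerate(terms):
            sub = sm.add_constant(design.iloc[:, : t_idx + 1].to_numpy())
            rss = float(sm.OLS(y, sub).fit().ssr)
            ss_term = rss_prev - rss
            if mse > 0:
                f_stat = ss_term / mse
                p = float(stats.f.sf(f_stat, 1, df_resid))
            else:
                # saturated fit: a term either explains everything or nothing
                big = ss_term > tss * 1e-9
                f_stat = np.inf if big else 0.0
                p = 0.0 if big else 1.0
            rows.append(
                {
                    "genetic_axis": f"PCo{gk + 1}",
                    "term": term,
                    "ss": ss_term,
                    "F": float(f_stat),
                    "p": p,
                    "r_squared": float(fit.rsquared),
                }
            )
            rss_prev = rss
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sliding-window distance decay

@dataclass(frozen=True)
class WindowProfile:
    """Per-window sampled pair distances against a distance-agnostic baseline.

    ``windows`` has one row per window (empty windows kept, with NaN entries);
    ``baseline`` holds as many random pairs as there are non-empty windows.
    """

    windows: pd.DataFrame
    baseline: pd.DataFrame
    width_km: float
    step_km: float
    seed: int | None

    def to_tsv(self, path: str | Path) -> None:
        df = self.windows.copy()
        base = self.baseline.reset_index(drop=True)
        for col in ("nt_distance", "hap_distance"):
            padded = base[col].reindex(range(len(df)))
            df[f"baseline_{col.split('_')[0]}"] = padded.to_numpy()
        df.to_csv(path, sep="\t", index=False)


def sliding_window_decay(
    genetic: DistanceMatrix,
    haplotype: DistanceMatrix,
    geographic: DistanceMatrix,
    width_km: float = 40.0,
    step_km: float = 10.0,
    seed: int | None = None,
    exhaustive: bool = False,
) -> WindowProfile:
    """Distance-decay resampler.

    Windows ``[k*step, k*step + width)`` slide over geographic distance until
    the maximum observed pair distance.  Per window, one eligible strain pair
    is sampled uniformly and its nucleotide and haplotype distances recorded
    (``exhaustive=True`` instead averages all eligible pairs).  The baseline
    samples the same number of pairs uniformly from all pairs, irrespective of
    distance.  Windows with no eligible pair are recorded as empty rows.
    """
    _check_conformable(genetic, haplotype, geographic)
    n = len(genetic)
    if n < 2:
        raise ValueError("need at least 2 strains")
    rng = np.random.default_rng(seed)
    geo_v = _triangle(geographic.values)
    nt_v = _triangle(genetic.values)
    hap_v = _triangle(haplotype.values)
    pairs = geographic.pair_index()
    max_d = float(geo_v.max())

    rows = []
    k = 0
    n_sampled = 0
    while True:
        low = k * step_km
        if k > 0 and low > max_d:
            break
        high = low + width_km
        eligible = np.where((geo_v >= low) & (geo_v < high))[0]
        row = {
            "window_low": low,
            "window_high": high,
            "midpoint": low + width_km / 2.0,
            "n_eligible": int(eligible.size),
        }
        if eligible.size:
            if exhaustive:
                row.update(
                    strain_a="", strain_b="",
                    nt_distance=float(nt_v[eligible].mean()),
                    hap_distance=float(hap_v[eligible].mean()),
                )
            else:
                pick = int(rng.choice(eligible))
                a, b = pairs[pick]
                row.update(
                    strain_a=a, strain_b=b,
                    nt_distance=float(nt_v[pick]),
                    hap_distance=float(hap_v[pick]),
                )
            n_sampled += 1
        else:
            row.update(strain_a="", strain_b="", nt_distance=np.nan, hap_distance=np.nan)
        rows.append(row)
        k += 1
    windows = pd.DataFrame(rows)
    if n_sampled == 0:
        raise ValueError("all windows empty: no strain pair falls in any window")

    base_idx = rng.choice(geo_v.size, size=n_sampled, replace=True)
    baseline = pd.DataFrame(
        {
            "geo_distance": geo_v[base_idx],
            "nt_distance": nt_v[base_idx],
            "hap_distance": hap_v[base_idx],
        }
    )
    return WindowProfile(windows=windows, baseline=baseline,
                         width_km=width_km, step_km=step_km, seed=seed)


def decay_spearman(profile: WindowProfile, level: str = "nt_distance") -> float:
    """Spearman correlation of window midpoint vs sampled genetic distance
    (NaN windows dropped); positive under isolation by distance.  A profile
    whose sampled distances are all equal carries no decay signal and
    returns 0."""
    df = profile.windows.dropna(subset=[level])
    if len(df) < 3:
        raise ValueError("too few non-empty windows for a correlation")
    if df[level].nunique() == 1:
        return 0.0
    rho = stats.spearmanr(df["midpoint"], df[level]).statistic
    return float(rho)
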