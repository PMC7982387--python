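"""Diversity indices across the genomic hierarchy and the bootstrap comparison.

Species level: Shannon (natural log) and Gini-Simpson indices over genospecies
compositions.  Haplotype and nucleotide levels: mean off-diagonal of the
corresponding distance matrices.  The bootstrap comparison asks whether an
observed sample is less diverse than a reference population by resampling the
reference composition (B draws of the observed sample size, with replacement)
and locating the observed index in the resampled distribution with the +1
permutation correction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gendist import DistanceMatrix

_TIE_EPS = 1e-12


def _as_counts(counts) -> np.ndarray:
    if isinstance(counts, Mapping):
        arr = np.array(list(counts.values()), dtype=float)
    else:
        arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative counts")
    arr = arr[arr > 0]
    if arr.size == 0 or arr.sum() == 0:
        raise ValueError("all counts are zero")
    return arr


def shannon(counts) -> float:
    """Shannon index H = -sum p_i ln p_i; zero-count categories are ignored."""
    arr = _as_counts(counts)
    p = arr / arr.sum()
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Gini-Simpson index D = 1 - sum p_i^2."""
    arr = _as_counts(counts)
    p = arr / arr.sum()
    return float(1.0 - (p ** 2).sum())


def mean_pairwise(dm: DistanceMatrix, subset: Sequence[str] | None = None) -> float:
    """Mean off-diagonal distance within a subset of strains."""
    if subset is not None:
        if len(subset) < 2:
            raise ValueError("subset must contain at least 2 strains")
        dm = dm.submatrix(subset)
    elif len(dm) < 2:
        raise ValueError("need at least 2 strains")
    return dm.mean_offdiagonal()


def diversity_report(
    sources: Mapping[str, Sequence[str]],
    nucleotide: DistanceMatrix,
    haplotype: DistanceMatrix,
    labels_by_strain: Mapping[str, str],
) -> pd.DataFrame:
    """Per-source diversity table: mean nucleotide and haplotype distance plus
    Shannon/Simpson over genospecies labels.  ``sources`` maps a source name to
    its strain ids."""
    rows = []
    for name, strains in sources.items():
        strains = list(strains)
        comp = Counter(labels_by_strain[s] for s in strains)
        rows.append(
            {
                "source": name,
                "n": len(strains),
                "nucleotides": mean_pairwise(nucleotide, strains),
                "haplotypes": mean_pairwise(haplotype, strains),
                "shannon": shannon(comp),
                "simpson": simpson(comp),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BootstrapComparison:
    """Observed Shannon/Simpson versus B resampled values from a reference."""

    observed_h: float
    observed_d: float
    resampled_h: np.ndarray
    resampled_d: np.ndarray
    p_h: float
    p_d: float
    n_draw: int
    seed: int | None
    alternative: str

    @property
    def n_resamples(self) -> int:
        return int(self.resampled_h.size)


def _tail_p(resampled: np.ndarray, observed: float, alternative: str) -> float:
    b = resampled.size
    lower = (1 + int((resampled <= observed + _TIE_EPS).sum())) / (b + 1)
    upper = (1 + int((resampled >= observed - _TIE_EPS).sum())) / (b + 1)
    if alternative == "less":
        return lower
    if alternative == "greater":
        return upper
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(lower, upper))
    raise ValueError(f"unknown alternative {alternative!r}")


def bootstrap_diversity_comparison(
    observed_labels: Sequence[str],
    reference_labels: Sequence[str],
    n_draw: int | None = None,
    n_resamples: int = 10_000,
    seed: int | None = None,
    alternative: str = "less",
) -> BootstrapComparison:
    """Compare observed diversity against resamples of a reference population.

    Draws ``n_resamples`` samples of size ``n_draw`` (default: the observed
    sample size) with replacement from ``reference_labels``, computes Shannon
    and Simpson per draw, and reports ``p = (1 + #{resample <= observed}) /
    (n_resamples + 1)`` for the default lower-tail alternative (observed less
    diverse than reference).
    """
    observed_labels = list(observed_labels)
    reference_labels = list(reference_labels)
    if not reference_labels:
        raise ValueError("empty reference population")
    if not observed_labels:
        raise ValueError("empty observed sample")
    if n_draw is None:
        n_draw = len(observed_labels)
    if n_draw < 1 or n_resamples < 1:
        raise ValueError("n_draw and n_resamples must be >= 1")

    obs_h = shannon(Counter(observed_labels))
    obs_d = simpson(Counter(observed_labels))

    rng = np.random.default_rng(seed)
    cats, codes = np.unique(np.asarray(reference_labels, dtype=object), return_inverse=True)
    k = len(cats)
    draws = rng.integers(0, len(codes), size=(n_resamples, n_draw))
    sampled = codes[draws]  # (B, n_draw) category codes
    # row-wise category counts via one flat bincount
    flat = sampled + np.arange(n_resamples)[:, None] * k
    counts = np.bincount(flat.ravel(), minlength=n_resamples * k).reshape(n_resamples, k)
    p = counts / n_draw
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    res_h = -plogp.sum(axis=1)
    res_d = 1.0 - (p ** 2).sum(axis=1)

    return BootstrapComparison(
        observed_h=obs_h,
        observed_d=obs_d,
        resampled_h=res_h,
        resampled_d=res_d,
        p_h=_tail_p(res_h, obs_h, alternative),
        p_d=_tail_p(res_d, obs_d, alternative),
        n_draw=n_draw,
        seed=seed,
        alternative=alternative,
    )
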