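"""Pairwise distance matrices at every level of the analysis hierarchy.

Nucleotide level: proportion of differing sites (p-distance) and the
Tamura-Nei (1993) model-corrected distance, both under pairwise deletion of
gap/ambiguity columns.  Haplotype level: allele-sharing distance, the fraction
of loci at which two strains carry different alleles.  Species level: a 0/1
same/different-genospecies indicator.  Environmental levels: great-circle
(haversine) geographic distance and absolute scalar differences (elevation,
shoot dry weight).

All matrices are :class:`DistanceMatrix` instances - symmetric, zero-diagonal,
labelled by strain id and tagged with the hierarchy level they represent.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import StrainMismatchError, UndefinedDistanceError
from .seqio import LocusAlignment, MultiLocusAlignment, _NON_BASE_CODE

#: IUGG mean Earth radius, km (fixed for bit-reproducibility).
EARTH_RADIUS_KM = 6371.0088

LEVELS = (
    "nucleotide",
    "nucleotide_tn93",
    "haplotype",
    "species",
    "geographic_km",
    "elevation_m",
    "trait",
)


class DistanceMatrix:
    """Symmetric labelled distance matrix.

    Parameters
    ----------
    labels : sequence of str
        Unique strain identifiers, one per row/column.
    values : (n, n) array-like
        Non-negative, symmetric, zero diagonal.  ``nan`` entries are allowed
        only for pairs listed in ``undefined`` (e.g. TN93 saturation).
    level : str
        Hierarchy level tag, one of :data:`LEVELS` (free-form tags accepted).
    undefined : iterable of (label, label)
        Pairs whose distance could not be computed.
    """

    def __init__(self, labels, values, level: str, undefined=()):
        labels = tuple(labels)
        values = np.array(values, dtype=float)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in distance matrix")
        if values.shape != (len(labels), len(labels)):
            raise ValueError(f"values shape {values.shape} does not match {len(labels)} labels")
        undefined = frozenset(frozenset(p) for p in undefined)
        finite = np.isfinite(values)
        if not finite.all():
            bad = {frozenset((labels[i], labels[j])) for i, j in zip(*np.where(~finite)) if i != j}
            if not bad <= undefined:
                raise ValueError("non-finite distances for pairs not flagged undefined")
        chk = np.where(finite, values, 0.0)
        if not np.allclose(chk, chk.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(chk), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        if (chk < -1e-12).any():
            raise ValueError("negative distances")
        np.fill_diagonal(values, 0.0)
        self.labels = labels
        self.values = values
        self.level = level
        self.undefined_pairs = undefined

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def condensed(self) -> np.ndarray:
        """Strict lower triangle, row-major (the order used for Mantel tests)."""
        il = np.tril_indices(len(self), -1)
        return self.values[il]

    def pair_index(self) -> list[tuple[str, str]]:
        """Labels of :meth:`condensed` entries, same order."""
        il = np.tril_indices(len(self), -1)
        return [(self.labels[i], self.labels[j]) for i, j in zip(*il)]

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        und = [p for p in self.undefined_pairs if all(l in labels for l in p)]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)], self.level, und)

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        if set(labels) != set(self.labels):
            raise StrainMismatchError("reorder requires the same label set")
        return self.submatrix(labels)

    def mean_offdiagonal(self) -> float:
        vec = self.condensed()
        return float(np.nanmean(vec))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="strain")

    @classmethod
    def from_tsv(cls, path: str | Path, level: str) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        vals = df.to_numpy(dtype=float)
        und = []
        if np.isnan(vals).any():
            labels = list(df.index)
            und = [
                (labels[i], labels[j])
                for i, j in zip(*np.where(np.isnan(vals)))
                if i < j
            ]
        return cls(df.index, vals, level, und)

    def to_phylip(self, path: str | Path) -> None:
        """Lower-triangle PHYLIP-style writer."""
        with open(path, "w") as fh:
            fh.write(f"{len(self)}\n")
            for i, lab in enumerate(self.labels):
                row = " ".join(f"{self.values[i, j]:.6f}" for j in range(i))
                fh.write(f"{lab} {row}".rstrip() + "\n")


# ---------------------------------------------------------------------------
# nucleotide level

def _pair_counts(codes: np.ndarray):
    """Comparable-site and mismatch counts for all pairs under pairwise deletion."""
    valid = codes != _NON_BASE_CODE  # (n, L)
    both = valid[:, None, :] & valid[None, :, :]
    diff = both & (codes[:, None, :] != codes[None, :, :])
    return both.sum(axis=2), diff.sum(axis=2)


def p_distance_matrix(aln: LocusAlignment, deletion: str = "pairwise") -> DistanceMatrix:
    """Pairwise proportion of differing sites.

    ``deletion='pairwise'`` (default) compares, per pair, only columns where
    both sequences carry an unambiguous base; ``'complete'`` first drops every
    column containing any gap/ambiguity in any sequence.
    """
    if aln.n_strains < 2:
        raise ValueError("need at least 2 strains")
    codes = aln.to_codes()
    if deletion == "complete":
        keep = (codes != _NON_BASE_CODE).all(axis=0)
        codes = codes[:, keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    comparable, mismatches = _pair_counts(codes)
    zero = comparable == 0
    np.fill_diagonal(zero, False)
    if zero.any():
        i, j = np.argwhere(zero)[0]
        raise UndefinedDistanceError(
            f"no comparable sites between {aln.strain_ids[i]!r} and {aln.strain_ids[j]!r}"
        )
    with np.errstate(invalid="ignore"):
        vals = mismatches / np.maximum(comparable, 1)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(aln.strain_ids, vals, "nucleotide")


def _base_frequencies(codes: np.ndarray) -> np.ndarray:
    counts = np.array([(codes == b).sum() for b in range(4)], dtype=float)
    if counts.sum() == 0:
        raise ValueError("no unambiguous bases in alignment")
    return counts / counts.sum()


def tn93_pair(seq_i: np.ndarray, seq_j: np.ndarray, freqs: np.ndarray,
              gamma_shape: float | None = None) -> float:
    """Closed-form Tamura-Nei (1993) distance for one encoded sequence pair.

    ``freqs`` are the pooled base frequencies (A, C, G, T).  Returns ``nan``
    when a logarithm argument is non-positive (substitution saturation).  With
    ``gamma_shape`` (alpha), the gamma-rate-heterogeneity variant replaces each
    ``-k log w`` term by ``k * alpha * (w ** (-1/alpha) - 1)``.
    """
    both = (seq_i != _NON_BASE_CODE) & (seq_j != _NON_BASE_CODE)
    n = int(both.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable sites for TN93 pair")
    a, b = seq_i[both], seq_j[both]
    diff = a != b
    # codes: A=0, C=1, G=2, T=3; purine set {0, 2}, pyrimidine set {1, 3}
    purine_a, purine_b = (a == 0) | (a == 2), (b == 0) | (b == 2)
    transition = diff & (purine_a == purine_b)
    p1 = float((transition & purine_a).sum()) / n          # A<->G
    p2 = float((transition & ~purine_a).sum()) / n         # C<->T
    q = float((diff & (purine_a != purine_b)).sum()) / n   # transversions

    ga, gc, gg, gt = freqs
    gr, gy = ga + gg, gc + gt
    k1 = 2.0 * ga * gg / gr
    k2 = 2.0 * gt * gc / gy
    k3 = 2.0 * (gr * gy - ga * gg * gy / gr - gt * gc * gr / gy)
    w1 = 1.0 - p1 / k1 - q / (2.0 * gr)
    w2 = 1.0 - p2 / k2 - q / (2.0 * gy)
    w3 = 1.0 - q / (2.0 * gr * gy)
    if w1 <= 0.0 or w2 <= 0.0 or w3 <= 0.0:
        return float("nan")
    if gamma_shape is None:
        return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
    inv = -1.0 / gamma_shape
    return gamma_shape * (k1 * (w1 ** inv - 1.0) + k2 * (w2 ** inv - 1.0) + k3 * (w3 ** inv - 1.0))


def tn93_distance_matrix(aln: LocusAlignment, gamma_shape: float | None = None) -> DistanceMatrix:
    """Tamura-Nei (1993) distances with base frequencies pooled over the alignment.

    Saturated pairs (log argument <= 0) are flagged undefined (``nan``) rather
    than erroring, and reported in ``undefined_pairs``.
    """
    if aln.n_strains < 2:
        raise ValueError("need at least 2 strains")
    codes = aln.to_codes()
    freqs = _base_frequencies(codes)
    if (freqs == 0).any():
        raise ValueError("TN93 undefined: a base is absent from the alignment")
    n = aln.n_strains
    vals = np.zeros((n, n))
    undefined = []
    for i, j in itertools.combinations(range(n), 2):
        d = tn93_pair(codes[i], codes[j], freqs, gamma_shape)
        vals[i, j] = vals[j, i] = d
        if math.isnan(d):
            undefined.append((aln.strain_ids[i], aln.strain_ids[j]))
    return DistanceMatrix(aln.strain_ids, vals, "nucleotide_tn93", undefined)


# ---------------------------------------------------------------------------
# haplotype level

@dataclass(frozen=True)
class HaplotypeTable:
    """Per-locus haplotype labels: strains with byte-identical aligned sequences
    (gaps significant) share one dense integer label per locus."""

    strain_ids: tuple[str, ...]
    labels: Mapping[str, Mapping[str, int]]  # locus -> strain -> haplotype

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(self.labels.keys())

    def n_haplotypes(self, locus: str) -> int:
        return len(set(self.labels[locus].values()))


def call_haplotypes(mla: MultiLocusAlignment) -> HaplotypeTable:
    """Assign per-locus haplotype labels by exact sequence identity.

    Labels are dense integers starting at 1 in order of first appearance.
    """
    table: dict[str, dict[str, int]] = {}
    for aln in mla.loci:
        seen: dict[str, int] = {}
        lab: dict[str, int] = {}
        for sid, seq in zip(aln.strain_ids, aln.sequences):
            if seq not in seen:
                seen[seq] = len(seen) + 1
            lab[sid] = seen[seq]
        table[aln.locus_name] = lab
    return HaplotypeTable(strain_ids=mla.strain_ids, labels=table)


def allele_sharing_distance(ht: HaplotypeTable) -> DistanceMatrix:
    """Fraction of loci at which two strains carry different haplotypes."""
    loci = ht.locus_names
    if not loci:
        raise ValueError("haplotype table has no loci")
    ids = ht.strain_ids
    mats = []
    for locus in loci:
        lab = ht.labels[locus]
        try:
            arr = np.array([lab[s] for s in ids])
        except KeyError as exc:
            raise StrainMismatchError(f"strain {exc.args[0]!r} missing from locus {locus!r}")
        mats.append((arr[:, None] != arr[None, :]).astype(float))
    vals = np.mean(mats, axis=0)
    return DistanceMatrix(ids, vals, "haplotype")


# ---------------------------------------------------------------------------
# species, geographic and scalar levels

def species_distance(labels: Mapping[str, str], strain_ids: Sequence[str] | None = None) -> DistanceMatrix:
    """0/1 distance: zero iff two strains belong to the same genospecies."""
    if strain_ids is None:
        strain_ids = tuple(labels.keys())
    missing = [s for s in strain_ids if s not in labels or labels[s] in (None, "")]
    if missing:
        raise ValueError(f"unlabelled strains: {missing}")
    arr = np.array([labels[s] for s in strain_ids], dtype=object)
    vals = (arr[:, None] != arr[None, :]).astype(float)
    return DistanceMatrix(strain_ids, vals, "species")


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km on the IUGG mean-radius sphere."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def geographic_distance_matrix(meta: pd.DataFrame,
                               strain_col: str = "strain",
                               lat_col: str = "latitude",
                               lon_col: str = "longitude") -> DistanceMatrix:
    """Haversine distances (km) between strain sampling coordinates."""
    df = meta.set_index(strain_col) if strain_col in meta.columns else meta
    missing = df.index[df[[lat_col, lon_col]].isna().any(axis=1)].tolist()
    if missing:
        raise ValueError(f"missing coordinates for strains: {missing}")
    lat = df[lat_col].to_numpy(dtype=float)
    lon = df[lon_col].to_numpy(dtype=float)
    if (np.abs(lat) > 90).any() or (np.abs(lon) > 180).any():
        raise ValueError("coordinates out of range")
    n = len(df)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = haversine_km(lat[i], lon[i], lat[j], lon[j])
    return DistanceMatrix(tuple(df.index), vals, "geographic_km")


def scalar_distance_matrix(values: Mapping[str, float] | pd.Series, level: str) -> DistanceMatrix:
    """Absolute differences of a per-strain scalar (elevation, shoot dry weight...)."""
    series = pd.Series(values, dtype=float)
    if series.isna().any():
        raise ValueError(f"missing values for strains: {series.index[series.isna()].tolist()}")
    arr = series.to_numpy()
    vals = np.abs(arr[:, None] - arr[None, :])
    return DistanceMatrix(tuple(series.index), vals, level)
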