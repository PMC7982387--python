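"""Genospecies assignment against a labelled reference panel.

Strains are assigned to the genospecies of their nearest reference by average
nucleotide identity (ANI = 1 - p-distance on shared unambiguous columns of the
concatenated housekeeping alignment), provided the identity clears a floor
(default 0.95, motivated by reported within-genospecies ANI ranges).  Sample
compositions over genospecies are compared with a Pearson chi-squared test.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StrainMismatchError
from .seqio import LocusAlignment, MultiLocusAlignment, _NON_BASE_CODE

UNASSIGNED = "unassigned"

DEFAULT_MIN_SIMILARITY = 0.95


@dataclass(frozen=True)
class AssignmentRecord:
    genospecies: str
    nearest_ref: str
    similarity: float


@dataclass(frozen=True)
class GenospeciesAssignment:
    """Per-strain genospecies call with the supporting reference and ANI."""

    records: Mapping[str, AssignmentRecord]

    @property
    def labels(self) -> dict[str, str]:
        return {s: r.genospecies for s, r in self.records.items()}

    @property
    def assigned_labels(self) -> dict[str, str]:
        return {s: r.genospecies for s, r in self.records.items() if r.genospecies != UNASSIGNED}

    def counts(self) -> Counter:
        return Counter(r.genospecies for r in self.records.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strain": s,
                    "genospecies": r.genospecies,
                    "nearest_ref": r.nearest_ref,
                    "similarity": r.similarity,
                }
                for s, r in self.records.items()
            ]
        )


def _ani(a: np.ndarray, b: np.ndarray) -> float:
    """Average nucleotide identity on columns where both carry unambiguous bases."""
    both = (a != _NON_BASE_CODE) & (b != _NON_BASE_CODE)
    n = int(both.sum())
    if n == 0:
        return float("nan")
    return 1.0 - float((a[both] != b[both]).sum()) / n


def assign_genospecies(
    queries: MultiLocusAlignment | LocusAlignment,
    refs: MultiLocusAlignment | LocusAlignment,
    ref_labels: Mapping[str, str],
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
) -> GenospeciesAssignment:
    """Assign each query strain to its nearest reference's genospecies.

    ``queries`` and ``refs`` must be aligned to the same columns (same
    concatenated length).  A query below ``min_similarity`` to every reference
    is reported as ``"unassigned"``.  Exact ANI ties are broken by reference
    input order, with a warning.
    """
    q_aln = queries.concatenated if isinstance(queries, MultiLocusAlignment) else queries
    r_aln = refs.concatenated if isinstance(refs, MultiLocusAlignment) else refs
    if r_aln.n_strains == 0 or not ref_labels:
        raise ValueError("no references provided")
    unlabelled = [r for r in r_aln.strain_ids if r not in ref_labels]
    if unlabelled:
        raise ValueError(f"references without labels: {unlabelled}")
    if q_aln.length != r_aln.length:
        raise StrainMismatchError(
            f"queries ({q_aln.length} bp) and references ({r_aln.length} bp) are not "
            "aligned to the same columns"
        )
    q_codes = q_aln.to_codes()
    r_codes = r_aln.to_codes()
    records: dict[str, AssignmentRecord] = {}
    for qi, strain in enumerate(q_aln.strain_ids):
        sims = np.array([_ani(q_codes[qi], r_codes[rj]) for rj in range(r_aln.n_strains)])
        best = int(np.nanargmax(sims))
        ties = np.where(np.isclose(sims, sims[best], rtol=0, atol=0))[0]
        if len(ties) > 1:
            warnings.warn(
                f"strain {strain!r}: ANI tie among references "
                f"{[r_aln.strain_ids[t] for t in ties]}; keeping first in input order",
                stacklevel=2,
            )
            best = int(ties[0])
        sim = float(sims[best])
        ref = r_aln.strain_ids[best]
        label = ref_labels[ref] if sim >= min_similarity else UNASSIGNED
        records[strain] = AssignmentRecord(label, ref, sim)
    return GenospeciesAssignment(records)


def composition_table(samples: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Sample-by-genospecies contingency table from per-sample label lists."""
    rows = {name: Counter(labels) for name, labels in samples.items()}
    df = pd.DataFrame(rows).T.fillna(0).astype(int)
    return df.sort_index(axis=1)


def composition_chisq(table: pd.DataFrame | np.ndarray):
    """Pearson chi-squared test of homogeneity on a contingency table.

    No continuity correction; df = (r-1)(c-1).  A row or column summing to
    zero is an error; expected counts below 5 trigger a warning only.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need a contingency table with >=2 rows and >=2 columns")
    if (arr < 0).any():
        raise ValueError("negative counts")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("zero row or column in contingency table")
    res = stats.chi2_contingency(arr, correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn("some expected counts < 5; chi-squared approximation is weak", stacklevel=2)
    return float(res.statistic), int(res.dof), float(res.pvalue)
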