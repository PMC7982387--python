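"""Alignment input and site statistics for multilocus sequence analysis (MLSA).

Housekeeping loci arrive as one pre-aligned FASTA per locus.  They are read
into :class:`LocusAlignment` objects, concatenated column-wise into a
:class:`MultiLocusAlignment`, and summarised per column into site classes:
conserved, variable (split into parsimony-informative sites and singletons),
plus an ``excluded`` tally for columns containing a gap or an IUPAC ambiguity
code.  Only the four unambiguous bases take part in the classification, so for
every alignment ``conserved + variable + excluded == length`` and
``variable == parsimony_informative + singletons`` hold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError, StrainMismatchError

UNAMBIGUOUS = "ACGT"
#: Characters legal in an aligned nucleotide sequence (IUPAC codes + gap).
IUPAC_CHARS = frozenset("ACGTURYSWKMBDHVN-")

_CODE_OF = {b: i for i, b in enumerate(UNAMBIGUOUS)}
_NON_BASE_CODE = 255


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to uint8 codes: A,C,G,T -> 0..3, anything else -> 255."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, _NON_BASE_CODE, dtype=np.uint8)
    for base, code in _CODE_OF.items():
        out[arr == ord(base)] = code
    return out


@dataclass(frozen=True)
class LocusAlignment:
    """A pre-aligned set of nucleotide sequences for one locus.

    Sequences are stored uppercase; rows are keyed by unique strain ids and
    must all have the same length (the alignment width in bp).
    """

    locus_name: str
    strain_ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.strain_ids) != len(self.sequences):
            raise AlignmentError("strain_ids and sequences differ in length")
        if len(self.strain_ids) == 0:
            raise AlignmentError(f"{self.locus_name}: empty alignment")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            dupes = [s for s in self.strain_ids if self.strain_ids.count(s) > 1]
            raise AlignmentError(f"{self.locus_name}: duplicate strain ids {sorted(set(dupes))}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.locus_name}: ragged alignment, sequence lengths {sorted(lengths)}"
            )
        if next(iter(lengths)) < 1:
            raise AlignmentError(f"{self.locus_name}: zero-length alignment")
        bad = set("".join(self.sequences)) - IUPAC_CHARS
        if bad:
            raise AlignmentError(f"{self.locus_name}: non-IUPAC characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    def sequence_of(self, strain: str) -> str:
        try:
            return self.sequences[self.strain_ids.index(strain)]
        except ValueError:
            raise StrainMismatchError(f"{self.locus_name}: strain {strain!r} not present") from None

    def reorder(self, strain_ids: Sequence[str]) -> "LocusAlignment":
        """Return the alignment with rows in the given strain order (a permutation
        or subset of the present strains)."""
        return LocusAlignment(
            self.locus_name,
            tuple(strain_ids),
            tuple(self.sequence_of(s) for s in strain_ids),
        )

    def to_codes(self) -> np.ndarray:
        """(n_strains, length) uint8 matrix; 0..3 for ACGT, 255 for gap/ambiguity."""
        return np.vstack([_encode(s) for s in self.sequences])


@dataclass(frozen=True)
class MultiLocusAlignment:
    """Ordered loci over a common strain set plus their column-wise concatenation."""

    loci: tuple[LocusAlignment, ...]
    concatenated: LocusAlignment

    @property
    def strain_ids(self) -> tuple[str, ...]:
        return self.concatenated.strain_ids

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(a.locus_name for a in self.loci)

    def locus(self, name: str) -> LocusAlignment:
        for aln in self.loci:
            if aln.locus_name == name:
                return aln
        raise KeyError(name)


@dataclass(frozen=True)
class SiteClassification:
    """Per-column tallies of an alignment.

    ``excluded`` counts columns containing any gap or ambiguity code; the other
    classes partition the remaining, fully unambiguous columns.
    """

    conserved: int
    variable: int
    parsimony_informative: int
    singletons: int
    excluded: int

    def __post_init__(self) -> None:
        if self.variable != self.parsimony_informative + self.singletons:
            raise ValueError("variable must equal parsimony_informative + singletons")

    @property
    def length(self) -> int:
        return self.conserved + self.variable + self.excluded


def read_fasta_alignment(path: str | Path, locus_name: str | None = None) -> LocusAlignment:
    """Read one pre-aligned FASTA file into a :class:`LocusAlignment`.

    The strain id is the description line up to the first whitespace;
    sequences are uppercased.  Requires at least two records.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise AlignmentError(f"{path}: need at least 2 FASTA records, found {len(records)}")
    name = locus_name if locus_name is not None else path.stem
    return LocusAlignment(
        locus_name=name,
        strain_ids=tuple(r.id for r in records),
        sequences=tuple(str(r.seq).upper() for r in records),
    )


def write_fasta_alignment(aln: LocusAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.strain_ids, aln.sequences):
            fh.write(f">{sid}\n{seq}\n")


def concatenate(loci: Iterable[LocusAlignment]) -> MultiLocusAlignment:
    """Column-wise join of loci sharing an identical strain set.

    Strain order is canonicalized (sorted by id).  A strain present in one
    locus but not another is an error: subsetting must be explicit, never a
    silent intersection.
    """
    loci = tuple(loci)
    if not loci:
        raise ValueError("no loci to concatenate")
    ref_set = set(loci[0].strain_ids)
    for aln in loci[1:]:
        if set(aln.strain_ids) != ref_set:
            missing = ref_set.symmetric_difference(aln.strain_ids)
            raise StrainMismatchError(
                f"loci {loci[0].locus_name!r} and {aln.locus_name!r} differ in strains: "
                f"{sorted(missing)}"
            )
    order = tuple(sorted(ref_set))
    reordered = tuple(aln.reorder(order) for aln in loci)
    joined = LocusAlignment(
        locus_name="+".join(a.locus_name for a in reordered),
        strain_ids=order,
        sequences=tuple("".join(parts) for parts in zip(*(a.sequences for a in reordered))),
    )
    return MultiLocusAlignment(loci=reordered, concatenated=joined)


def classify_sites(aln: LocusAlignment) -> SiteClassification:
    """Classify every column of the alignment.

    Columns containing any gap or ambiguity code go to ``excluded``.  Among
    fully unambiguous columns: one observed state -> conserved; otherwise
    variable, and a variable column is parsimony-informative when at least two
    states each occur in at least two sequences, else a singleton site.
    """
    codes = aln.to_codes()
    has_non_base = (codes == _NON_BASE_CODE).any(axis=0)
    counts = np.stack([(codes == b).sum(axis=0) for b in range(4)])  # (4, L)
    n_states = (counts > 0).sum(axis=0)
    n_states_ge2 = (counts >= 2).sum(axis=0)

    included = ~has_non_base
    conserved = int((included & (n_states == 1)).sum())
    variable_mask = included & (n_states >= 2)
    pi = int((variable_mask & (n_states_ge2 >= 2)).sum())
    variable = int(variable_mask.sum())
    return SiteClassification(
        conserved=conserved,
        variable=variable,
        parsimony_informative=pi,
        singletons=variable - pi,
        excluded=int(has_non_base.sum()),
    )


def site_stats_table(mla: MultiLocusAlignment, include_concatenated: bool = True) -> pd.DataFrame:
    """Per-locus (and concatenated) site statistics as a tidy table."""
    rows = []
    alns: list[LocusAlignment] = list(mla.loci)
    if include_concatenated:
        alns.append(mla.concatenated)
    for aln in alns:
        sc = classify_sites(aln)
        rows.append(
            {
                "locus": aln.locus_name,
                "n_sequences": aln.n_strains,
                "length": aln.length,
                "conserved": sc.conserved,
                "variable": sc.variable,
                "parsimony_informative": sc.parsimony_informative,
                "singletons": sc.singletons,
                "excluded": sc.excluded,
            }
        )
    return pd.DataFrame(rows)
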