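"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates a chickpea-*Mesorhizobium* survey: ~39 strains in four
genospecies clusters of uneven size (26/8/2/3), three housekeeping loci of
1045/390/307 aligned bp, sampling sites strung along a ~400-km south-west to
north-east transect with two restricted clusters at the south-western end and
one cluster confined to high-elevation sites, optional within-cluster
isolation by distance, and a balanced three-replicate RCBD greenhouse trial
with a latent per-strain effectiveness driving four correlated traits.

Sequences evolve by per-site independent substitutions under a Tamura-Nei
(1993)-consistent model (unequal base frequencies, transition bias): cluster
ancestors diverge from a common root at the between-cluster rate, and cluster
members acquire within-cluster variation through two layers - a stepping-stone
chain along the transect (weight ``ibd_strength``) that creates isolation by
distance and local haplotype sharing, and private mutations (weight
``1 - ibd_strength``).  A star phylogeny within clusters, rather than a full
coalescent, keeps every generated quantity auditable.

Every dataset carries a truth record sufficient to score recovery of every
estimated quantity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import LocusAlignment, MultiLocusAlignment, concatenate, write_fasta_alignment

_BASES = "ACGT"


@dataclass(frozen=True)
class TraitModel:
    """Latent-effectiveness model for the greenhouse traits.

    Each trait t is ``mu_t + lambda_t * (a_i + b_j) + e_ijt`` with strain
    effect a_i ~ N(0, sigma_strain^2), block effect b_j ~ N(0, sigma_rep^2)
    and residual e ~ N(0, (lambda_t * sigma_e)^2).  The uninoculated control
    has latent effectiveness 0, zero nodulation, and its biomass means reduced
    by ``control_deficit`` (fraction).
    """

    mu: tuple[float, ...] = (25.0, 30.0, 1.5, 0.8)         # nn, ndw mg, sdw g, rdw g
    loadings: tuple[float, ...] = (6.0, 8.0, 0.25, 0.10)
    sigma_strain: float = 1.0
    sigma_rep: float = 0.4
    sigma_e: float = 0.8
    control_deficit: float = 0.25
    n_replicates: int = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults emulate the study structure."""

    n_strains: int = 39
    cluster_frequencies: tuple[int, ...] = (26, 8, 2, 3)
    cluster_labels: tuple[str, ...] = ("gsI", "gsII", "gsIII", "gsIV")
    locus_names: tuple[str, ...] = ("16S", "atpD", "recA")
    locus_lengths: tuple[int, ...] = (1045, 390, 307)
    within_cluster_divergence: float = 0.005   # expected substitutions/site
    between_cluster_divergence: float = 0.03
    base_frequencies: tuple[float, ...] = (0.19, 0.31, 0.31, 0.19)  # GC-rich
    kappa: float = 4.0                         # transition/transversion rate bias
    gap_rate: float = 0.0                      # per-site gap injection probability
    transect_length_km: float = 400.0
    n_sites: int = 16
    ibd_strength: float = 0.5                  # 0 = no IBD, 1 = pure stepping stone
    sw_fraction: float = 0.25                  # SW end holding the restricted clusters
    restricted_clusters: tuple[int, ...] = (1, 2)   # gsII, gsIII -> south-west only
    elevation_cluster: int = 3                 # gsIV -> high-elevation sites only
    #: the high-elevation cluster sits in a distant clade: its ancestor diverges
    #: from the root at this multiple of the between-cluster rate
    elevation_cluster_divergence_scale: float = 2.0
    elevation_threshold_m: float = 2400.0
    base_elevation_m: float = 1800.0
    elevation_sd_m: float = 200.0
    spatial_structure: bool = True             # False = random placement, no IBD
    origin_lat: float = 6.5
    origin_lon: float = 37.5
    trait_model: TraitModel = field(default_factory=TraitModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.cluster_frequencies) != self.n_strains:
            raise ValueError(
                f"cluster_frequencies sum {sum(self.cluster_frequencies)} != "
                f"n_strains {self.n_strains}"
            )
        if len(self.cluster_frequencies) != len(self.cluster_labels):
            raise ValueError("one label per cluster required")
        if not 0 <= self.within_cluster_divergence < 1 or not 0 < self.between_cluster_divergence < 1:
            raise ValueError("divergences must lie in [0, 1) (within) and (0, 1) (between)")
        if any(l < 1 for l in self.locus_lengths):
            raise ValueError("locus lengths must be >= 1")


@dataclass(frozen=True)
class SyntheticDataset:
    """A complete generated dataset plus its truth record."""

    mla: MultiLocusAlignment
    metadata: pd.DataFrame           # strain, latitude, longitude, elevation_m, ...
    references: MultiLocusAlignment  # one clean ancestor per cluster
    reference_labels: dict[str, str]
    traits: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for aln in self.mla.loci:
            write_fasta_alignment(aln, outdir / f"{aln.locus_name}.fasta")
        for aln in self.references.loci:
            write_fasta_alignment(aln, outdir / f"refs_{aln.locus_name}.fasta")
        pd.Series(self.reference_labels, name="genospecies").rename_axis("strain").to_csv(
            outdir / "reference_labels.csv"
        )
        self.metadata.to_csv(outdir / "metadata.csv", index=False)
        self.traits.to_csv(outdir / "traits.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


# ---------------------------------------------------------------------------
# sequence machinery

def _substitution_targets(freqs: np.ndarray, kappa: float) -> np.ndarray:
    """(4, 4) row-stochastic matrix of replacement-base probabilities given a
    substitution occurs at a site with the row's base (TN93-consistent:
    targets weighted by frequency, transitions by kappa)."""
    transition_partner = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T
    probs = np.zeros((4, 4))
    for b in range(4):
        for c in range(4):
            if c == b:
                continue
            w = freqs[c] * (kappa if transition_partner[b] == c else 1.0)
            probs[b, c] = w
        probs[b] /= probs[b].sum()
    return probs


def _mutate(seq: np.ndarray, divergence: float, targets: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Per-site independent substitution at expected ``divergence`` subs/site."""
    out = seq.copy()
    hit = np.where(rng.random(seq.size) < divergence)[0]
    for pos in hit:
        out[pos] = rng.choice(4, p=targets[out[pos]])
    return out


def _random_sequence(length: int, freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(4, size=length, p=freqs)


def _decode(codes: np.ndarray) -> str:
    lut = np.array(list(_BASES + "-"))
    return "".join(lut[codes])


# ---------------------------------------------------------------------------
# geography

def simulate_geography(cfg: SimulationConfig, cluster_of: Sequence[int],
                       rng: np.random.Generator) -> pd.DataFrame:
    """Place sampling sites along the transect and assign strains to sites.

    Restricted clusters may only use sites in the south-western
    ``sw_fraction`` of the transect; the elevation-rule cluster only sites
    above the threshold (placed in the central/north-eastern half).  With
    ``spatial_structure=False`` every strain picks any site and elevations
    carry no cluster signal.
    """
    L = cfg.transect_length_km
    n_sites = max(cfg.n_sites, 4)
    positions = np.sort(rng.uniform(0.0, L, size=n_sites))
    elevations = cfg.base_elevation_m + rng.normal(0.0, cfg.elevation_sd_m, size=n_sites)
    elevations = np.clip(elevations, 1200.0, cfg.elevation_threshold_m - 50.0)

    high_pool = np.where(positions >= 0.5 * L)[0]
    if high_pool.size < 2:
        high_pool = np.arange(n_sites - 2, n_sites)
    high_sites = rng.choice(high_pool, size=2, replace=False)
    if cfg.spatial_structure:
        elevations[high_sites] = cfg.elevation_threshold_m + rng.uniform(50.0, 400.0, size=2)

    sw_sites = np.where(positions <= cfg.sw_fraction * L)[0]
    if sw_sites.size == 0:
        sw_sites = np.array([0])

    rows = []
    for idx, cl in enumerate(cluster_of):
        if not cfg.spatial_structure:
            site = rng.integers(0, n_sites)
        elif cl in cfg.restricted_clusters:
            site = int(rng.choice(sw_sites))
        elif cl == cfg.elevation_cluster:
            site = int(rng.choice(high_sites))
        else:
            site = rng.integers(0, n_sites)
        s = positions[site]
        # NE bearing; lateral jitter of a few km keeps sites off a perfect line
        jitter = rng.normal(0.0, 2.0)
        dlat = (s / np.sqrt(2.0) + jitter) / 111.1949
        lat = cfg.origin_lat + dlat
        dlon = (s / np.sqrt(2.0)) / (111.1949 * np.cos(np.radians(lat)))
        rows.append(
            {
                "strain": f"ET{idx + 1:03d}",
                "latitude": lat,
                "longitude": cfg.origin_lon + dlon,
                "elevation_m": float(elevations[site]),
                "transect_km": float(s),
                "site": int(site),
                "true_cluster": cfg.cluster_labels[cl],
                "source": "synthetic",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sequences

def simulate_sequences(
    cfg: SimulationConfig,
    cluster_of: Sequence[int],
    positions_km: Sequence[float],
    strain_ids: Sequence[str],
    rng: np.random.Generator,
) -> tuple[MultiLocusAlignment, MultiLocusAlignment, dict[str, str]]:
    """Generate per-locus alignments plus the clean reference panel.

    Returns (strain alignment, reference alignment, reference labels).
    """
    freqs = np.asarray(cfg.base_frequencies, dtype=float)
    freqs = freqs / freqs.sum()
    targets = _substitution_targets(freqs, cfg.kappa)
    w = cfg.within_cluster_divergence
    ibd = cfg.ibd_strength if cfg.spatial_structure else 0.0
    positions = np.asarray(positions_km, dtype=float)

    strain_loci: list[LocusAlignment] = []
    ref_loci: list[LocusAlignment] = []
    ref_ids = [f"REF_{lab}" for lab in cfg.cluster_labels]
    n_clusters = len(cfg.cluster_labels)

    for locus, length in zip(cfg.locus_names, cfg.locus_lengths):
        root = _random_sequence(length, freqs, rng)
        ancestors = [
            _mutate(
                root,
                cfg.between_cluster_divergence
                * (cfg.elevation_cluster_divergence_scale if cl == cfg.elevation_cluster else 1.0),
                targets,
                rng,
            )
            for cl in range(n_clusters)
        ]
        seqs: dict[str, np.ndarray] = {}
        for cl in range(n_clusters):
            members = [i for i, c in enumerate(cluster_of) if c == cl]
            if not members:
                continue
            order = sorted(members, key=lambda i: positions[i])
            span = positions[order[-1]] - positions[order[0]]
            # stepping-stone chain normalized so the mean within-cluster pair
            # accumulates ~ibd*w along the chain (E|ds| = span/3 for uniform)
            per_km = 3.0 * ibd * w / span if span > 0 else 0.0
            current = ancestors[cl]
            prev_pos = positions[order[0]]
            for i in order:
                step = per_km * (positions[i] - prev_pos)
                if step > 0:
                    current = _mutate(current, min(step, 0.75), targets, rng)
                prev_pos = positions[i]
                private = _mutate(current, (1.0 - ibd) * w / 2.0, targets, rng) \
                    if ibd < 1.0 else current.copy()
                seqs[strain_ids[i]] = private
        if cfg.gap_rate > 0:
            for sid in seqs:
                gaps = rng.random(length) < cfg.gap_rate
                arr = seqs[sid].copy()
                arr[gaps] = 4  # '-' in the decode table
                seqs[sid] = arr
        strain_loci.append(
            LocusAlignment(locus, tuple(strain_ids), tuple(_decode(seqs[s]) for s in strain_ids))
        )
        ref_loci.append(
            LocusAlignment(locus, tuple(ref_ids), tuple(_decode(a) for a in ancestors))
        )

    mla = concatenate(strain_loci)
    refs = concatenate(ref_loci)
    ref_labels = dict(zip(ref_ids, cfg.cluster_labels))
    return mla, refs, ref_labels


# ---------------------------------------------------------------------------
# traits

def simulate_traits(cfg: SimulationConfig, strain_ids: Sequence[str],
                    rng: np.random.Generator,
                    control: str = "CONTROL") -> tuple[pd.DataFrame, dict[str, float]]:
    """Balanced RCBD trait table for all strains plus the uninoculated control.

    Returns the table and the true latent effectiveness per strain.
    """
    tm = cfg.trait_model
    mu = np.asarray(tm.mu)
    lam = np.asarray(tm.loadings)
    latent = {s: rng.normal(0.0, tm.sigma_strain) for s in strain_ids}
    latent[control] = 0.0
    blocks = rng.normal(0.0, tm.sigma_rep, size=tm.n_replicates)

    rows = []
    for s in list(strain_ids) + [control]:
        for j in range(tm.n_replicates):
            e = rng.normal(0.0, tm.sigma_e, size=4)
            y = mu + lam * (latent[s] + blocks[j] + e)
            if s == control:
                y = mu * (1.0 - tm.control_deficit) + lam * (blocks[j] + e)
                y[0] = 0.0  # no nodules without inoculation
                y[1] = 0.0
            y = np.maximum(y, 0.0)
            rows.append(
                {
                    "strain": s,
                    "replicate": j + 1,
                    "nodule_number": float(np.round(y[0])),
                    "nodule_dw_mg": float(y[1]),
                    "shoot_dw_g": float(y[2]),
                    "root_dw_g": float(y[3]),
                }
            )
    return pd.DataFrame(rows), latent


# ---------------------------------------------------------------------------
# orchestration

def simulate_dataset(cfg: SimulationConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate a full dataset (sequences, geography, references, traits, truth).

    ``seed`` overrides ``cfg.seed``; identical seeds yield byte-identical
    datasets.
    """
    if cfg is None:
        cfg = SimulationConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=int(seed))
    rng = np.random.default_rng(cfg.seed)

    cluster_of = [
        cl for cl, freq in enumerate(cfg.cluster_frequencies) for _ in range(freq)
    ]
    meta = simulate_geography(cfg, cluster_of, rng)
    strain_ids = tuple(meta["strain"])
    mla, refs, ref_labels = simulate_sequences(
        cfg, cluster_of, meta["transect_km"].to_numpy(), strain_ids, rng
    )
    traits, latent = simulate_traits(cfg, strain_ids, rng)

    truth = {
        "config": dataclasses.asdict(cfg),
        "cluster_of": {s: cfg.cluster_labels[c] for s, c in zip(strain_ids, cluster_of)},
        "latent_effectiveness": latent,
        "seed": cfg.seed,
    }
    return SyntheticDataset(
        mla=mla, metadata=meta, references=refs, reference_labels=ref_labels,
        traits=traits, truth=truth,
    )
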