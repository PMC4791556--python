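"""Rare-allele characterization per group, geographic clustering and fixed-allele scan.

A rare allele is an allele whose frequency in the reference population is strictly
inside (0, 0.05): frequency 0 is a lost allele and exactly 0.05 is not rare. At a
biallelic marker at most one allele can be rare (the other is then above 0.95), so
rare-allele sets are stored as (marker index, allele) pairs where allele is 'alt' or
'ref'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io_core import MISSING, AccessionInfo, GenotypeMatrix, GroupAssignment
from .diversity import allele_frequencies

__all__ = [
    "RareAlleleSet",
    "GeoCluster",
    "define_rare_alleles",
    "rare_alleles_per_group",
    "unique_rare_alleles",
    "rare_allele_report",
    "geo_kmeans",
    "cross_classify",
    "fixed_allele_scan",
    "rare_alleles_per_accession",
    "percent_unique_rare",
]


@dataclass
class RareAlleleSet:
    """Alleles rare (frequency strictly in (0, threshold)) in a reference population."""

    population: str
    alleles: set[tuple[int, str]]  # (marker column, 'alt'|'ref')
    frequencies: dict[tuple[int, str], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.alleles)


@dataclass
class GeoCluster:
    """k-means cluster of collection sites."""

    cluster_id: int
    members: list[str]
    centroid: tuple[float, float, float]  # lat, lon, alt


def define_rare_alleles(
    g: GenotypeMatrix,
    population: Iterable[str] | None = None,
    threshold: float = 0.05,
    population_id: str = "complete",
) -> RareAlleleSet:
    """Scan a population for alleles with frequency strictly in (0, threshold)."""
    f = allele_frequencies(g, population)
    p = f.p_alt
    alleles: set[tuple[int, str]] = set()
    freqs: dict[tuple[int, str], float] = {}
    alt_rare = f.has_calls & (p > 0) & (p < threshold)
    ref_rare = f.has_calls & (p > 1 - threshold) & (p < 1)
    for j in np.flatnonzero(alt_rare):
        alleles.add((int(j), "alt"))
        freqs[(int(j), "alt")] = float(p[j])
    for j in np.flatnonzero(ref_rare):
        alleles.add((int(j), "ref"))
        freqs[(int(j), "ref")] = float(1 - p[j])
    return RareAlleleSet(population_id, alleles, freqs)


def _carriers(g: GenotypeMatrix, allele: tuple[int, str]) -> np.ndarray:
    """Boolean accession mask of carriers of the given (marker, allele)."""
    j, which = allele
    col = g.calls[:, j]
    if which == "alt":
        return (col != MISSING) & (col > 0)
    return (col != MISSING) & (col < 2)


def rare_alleles_per_group(
    g: GenotypeMatrix,
    groups: GroupAssignment,
    scope: str = "per_group_population",
    threshold: float = 0.05,
) -> dict[str, RareAlleleSet]:
    """Rare-allele sets for every group.

    ``scope='per_group_population'`` treats each group as its own reference
    population (rarity judged on within-group frequencies); ``scope='complete_set'``
    defines rarity on the whole collection and then restricts to the alleles
    actually carried by at least one member of the group.
    """
    if scope not in ("per_group_population", "complete_set"):
        raise ValueError(f"unknown scope {scope!r}")
    parts = groups.groups()
    if scope == "per_group_population":
        return {
            k: define_rare_alleles(g, members, threshold, population_id=k)
            for k, members in parts.items()
        }
    complete = define_rare_alleles(g, None, threshold, population_id="complete")
    out: dict[str, RareAlleleSet] = {}
    for k, members in parts.items():
        idx = g.accession_indices(members)
        kept: set[tuple[int, str]] = set()
        freqs: dict[tuple[int, str], float] = {}
        for allele in complete.alleles:
            if _carriers(g, allele)[idx].any():
                kept.add(allele)
                freqs[allele] = complete.frequencies[allele]
        out[k] = RareAlleleSet(k, kept, freqs)
    return out


def unique_rare_alleles(
    g: GenotypeMatrix,
    groups: GroupAssignment,
    rare_sets: dict[str, RareAlleleSet] | None = None,
    threshold: float = 0.05,
) -> dict[str, set[tuple[int, str]]]:
    """Alleles unique to one group: rare there and carried by no outside accession.

    An allele rare in two groups (or rare in one but carried elsewhere) is unique
    to neither; this makes the count invariant to group sizes.
    """
    if rare_sets is None:
        rare_sets = rare_alleles_per_group(g, groups, threshold=threshold)
    parts = groups.groups()
    idx = {k: g.accession_indices(v) for k, v in parts.items()}
    out: dict[str, set[tuple[int, str]]] = {k: set() for k in rare_sets}
    for k, rset in rare_sets.items():
        outside = np.setdiff1d(np.arange(g.n_accessions), idx[k])
        for allele in rset.alleles:
            rare_elsewhere = any(
                allele in other.alleles for kk, other in rare_sets.items() if kk != k
            )
            if rare_elsewhere:
                continue
            if _carriers(g, allele)[outside].any():
                continue
            out[k].add(allele)
    return out


def rare_alleles_per_accession(nra: int, nac: int) -> float:
    """napa = rare alleles per accession, reported to 2 decimals."""
    if nac <= 0:
        raise ValueError("accession count must be positive")
    return round(nra / nac, 2)


def percent_unique_rare(nura: int, nra: int) -> float:
    """pura = 100 * unique rare alleles / rare alleles (0 when the group has none)."""
    return 0.0 if nra == 0 else 100.0 * nura / nra


def rare_allele_report(
    g: GenotypeMatrix,
    groups: GroupAssignment,
    scope: str = "per_group_population",
    threshold: float = 0.05,
    climate: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-group rare-allele table: nra, nac, raf, napa, nura, pura.

    ``raf`` is the mean reference-population frequency over the group's rare
    alleles. Optional ``climate`` (indexed by group) columns are appended.
    """
    rare_sets = rare_alleles_per_group(g, groups, scope=scope, threshold=threshold)
    uniques = unique_rare_alleles(g, groups, rare_sets=rare_sets, threshold=threshold)
    parts = groups.groups()
    rows = []
    for k in sorted(parts):
        nra = len(rare_sets[k])
        nac = len(parts[k])
        nura = len(uniques[k])
        raf = float(np.mean(list(rare_sets[k].frequencies.values()))) if nra else 0.0
        rows.append(
            {
                "group": k,
                "nra": nra,
                "nac": nac,
                "raf": raf,
                "napa": rare_alleles_per_accession(nra, nac),
                "nura": nura,
                "pura": percent_unique_rare(nura, nra),
            }
        )
    df = pd.DataFrame(rows).set_index("group")
    if climate is not None:
        df = df.join(climate)
    return df


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------

def geo_kmeans(info: Sequence[AccessionInfo], k: int, seed: int = 0) -> list[GeoCluster]:
    """k-means on standardized (latitude, longitude, altitude).

    Accessions without complete coordinates are excluded. Deterministic given the
    seed; multiple restarts keep the best inertia.
    """
    usable = [a for a in info if None not in (a.latitude, a.longitude, a.altitude)]
    if len(usable) < k:
        raise ValueError("fewer accessions with coordinates than clusters")
    X = np.array([[a.latitude, a.longitude, a.altitude] for a in usable], dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Z)
    clusters = []
    for cid in range(k):
        mask = km.labels_ == cid
        centroid = X[mask].mean(axis=0) if mask.any() else np.full(3, np.nan)
        clusters.append(
            GeoCluster(
                cluster_id=cid,
                members=[usable[i].accession_id for i in np.flatnonzero(mask)],
                centroid=tuple(float(v) for v in centroid),
            )
        )
    return clusters


def cross_classify(geo: Sequence[GeoCluster], genetic: GroupAssignment) -> pd.DataFrame:
    """Contingency table of geographic cluster x genetic group membership."""
    rows = []
    for cl in geo:
        for acc in cl.members:
            if acc in genetic.labels:
                rows.append((cl.cluster_id, genetic.labels[acc]))
    df = pd.DataFrame(rows, columns=["geo_cluster", "genetic_group"])
    return pd.crosstab(df["geo_cluster"], df["genetic_group"])


def fixed_allele_scan(
    g: GenotypeMatrix,
    clusters: Sequence[GeoCluster],
    min_callrate: float = 0.6,
    fixed_maf_max: float = 0.0,
) -> dict[int, list[str]]:
    """Markers fixed within a geographic cluster while segregating overall.

    A marker qualifies in a cluster when (a) its call rate among cluster members is
    at least ``min_callrate`` and (b) its within-cluster MAF is <= ``fixed_maf_max``
    (default 0: strictly monomorphic) while the complete-set MAF is > 0. Returns
    marker IDs per cluster, with map positions available via the genotype object.
    """
    overall = allele_frequencies(g)
    segregating = overall.has_calls & (overall.maf > 0)
    out: dict[int, list[str]] = {}
    for cl in clusters:
        idx = g.accession_indices(cl.members)
        sub = g.calls[idx]
        present = sub != MISSING
        callrate = present.mean(axis=0)
        n_calls = present.sum(axis=0)
        alt = np.where(present, sub, 0).sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_calls > 0, alt / (2.0 * np.maximum(n_calls, 1)), np.nan)
        maf = np.minimum(p, 1 - p)
        fixed = (callrate >= min_callrate) & (n_calls > 0) & (maf <= fixed_maf_max) & segregating
        out[cl.cluster_id] = [g.markers[j].marker_id for j in np.flatnonzero(fixed)]
    return out
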