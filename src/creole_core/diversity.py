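"""Allele-frequency statistics, diversity indices, differentiation and clustering.

All statistics operate on biallelic dosage matrices (:class:`~creole_core.io_core.
GenotypeMatrix`). Frequencies are computed over non-missing calls only; markers with
zero calls in the relevant accession set are flagged and excluded from marker
averages.

Diversity indices follow the classical biallelic forms: Nei's gene diversity
``1 - (p^2 + q^2)`` and the Shannon index ``-(p ln p + q ln q)``, each averaged over
markers and reported with their across-marker dispersion. Differentiation is
available both as Nei's G_ST (with gene flow N_m = (1 - G_ST) / (4 G_ST)) and as the
Weir & Cockerham (1984) multilocus theta, which accounts for unequal sample sizes and
observed heterozygosity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_core import MISSING, GenotypeMatrix, GroupAssignment, MarkerInfo

__all__ = [
    "AlleleFrequencies",
    "DistanceMatrix",
    "DiversitySummary",
    "GeneFlowStats",
    "GroupAssignment",
    "allele_frequencies",
    "maf_spectrum",
    "nei_index",
    "shannon_index",
    "diversity_summary",
    "gst_and_nm",
    "pairwise_fst",
    "simple_matching_distance",
    "complete_linkage_cluster",
    "select_spaced_markers",
]


@dataclass
class AlleleFrequencies:
    """Per-marker alternate-allele frequencies over non-missing calls."""

    p_alt: np.ndarray  # NaN where no calls
    n_calls: np.ndarray  # number of non-missing genotype calls per marker

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.p_alt, 1.0 - self.p_alt)

    @property
    def has_calls(self) -> np.ndarray:
        return self.n_calls > 0


@dataclass
class GeneFlowStats:
    """Nei gene-differentiation summary: H_T, H_S, G_ST and gene flow N_m."""

    h_t: float
    h_s: float
    g_st: float
    n_m: float  # inf when g_st == 0

    @property
    def infinite_gene_flow(self) -> bool:
        return np.isinf(self.n_m)


@dataclass
class DiversitySummary:
    """Per-group diversity report row (Nei/Shannon mean +- SD across markers)."""

    group: str
    n_accessions: int
    nei: float
    nei_sd: float
    shannon: float
    shannon_sd: float
    region_pct: dict[str, float] = field(default_factory=dict)


@dataclass
class DistanceMatrix:
    """Symmetric accession distance matrix in [0, 1] with per-pair comparison counts."""

    ids: list[str]
    values: np.ndarray
    pair_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape does not match ids")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, accessions: Sequence[str]) -> "DistanceMatrix":
        lookup = {a: i for i, a in enumerate(self.ids)}
        idx = np.array([lookup[a] for a in accessions])
        pc = None if self.pair_counts is None else self.pair_counts[np.ix_(idx, idx)]
        return DistanceMatrix(list(accessions), self.values[np.ix_(idx, idx)], pc)

    def mean_offdiagonal(self) -> float:
        iu = np.triu_indices(self.n, k=1)
        vals = self.values[iu]
        return float(np.nanmean(vals))

    def condensed(self) -> np.ndarray:
        return squareform(np.nan_to_num(self.values, nan=1.0), checks=False)

    def squared_euclidean_view(self) -> np.ndarray:
        """Squared-Euclidean transform D^2 = 2 * N * d under 0/1 mismatch recoding.

        Exposed as a view, never silently applied to the stored distances.
        """
        n_eff = self.pair_counts if self.pair_counts is not None else 1.0
        return 2.0 * n_eff * self.values


# ---------------------------------------------------------------------------
# frequencies and spectra
# ---------------------------------------------------------------------------

def _resolve_subset(g: GenotypeMatrix, subset) -> np.ndarray:
    if subset is None:
        return np.arange(g.n_accessions)
    subset = list(subset)
    if len(subset) == 0:
        raise ValueError("accession subset is empty")
    return g.accession_indices(subset)


def allele_frequencies(g: GenotypeMatrix, subset: Iterable[str] | None = None) -> AlleleFrequencies:
    """Alternate-allele frequency per marker: sum(dosage) / (2 * non-missing count)."""
    idx = _resolve_subset(g, subset)
    calls = g.calls[idx]
    present = calls != MISSING
    n_calls = present.sum(axis=0)
    alt = np.where(present, calls, 0).sum(axis=0, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_calls > 0, alt / (2.0 * np.maximum(n_calls, 1)), np.nan)
    return AlleleFrequencies(p_alt=p, n_calls=n_calls)


def maf_spectrum(
    freqs: AlleleFrequencies, breaks: tuple[float, float] = (0.05, 0.95)
) -> dict[str, float]:
    """Classify alternate-allele frequencies into [0, lo), [lo, hi], (hi, 1].

    Returns counts and percentages over the markers with at least one call. The
    classification is on ``p_alt``, not the folded MAF, so ``below + above`` equals
    the count of markers whose minor allele is below ``lo``.
    """
    lo, hi = breaks
    if not lo < hi:
        raise ValueError("breaks must be ordered")
    p = freqs.p_alt[freqs.has_calls]
    below = int((p < lo).sum())
    above = int((p > hi).sum())
    within = int(((p >= lo) & (p <= hi)).sum())
    total = below + within + above
    pct = (lambda c: 100.0 * c / total if total else float("nan"))
    return {
        "below": below,
        "within": within,
        "above": above,
        "total": total,
        "below_pct": pct(below),
        "within_pct": pct(within),
        "above_pct": pct(above),
        "outside_pct": pct(below + above),
    }


# ---------------------------------------------------------------------------
# diversity indices
# ---------------------------------------------------------------------------

def _per_marker_nei(p: np.ndarray) -> np.ndarray:
    return 1.0 - (p**2 + (1.0 - p) ** 2)


def _per_marker_shannon(p: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = -(np.where(p > 0, p * np.log(p), 0.0)
                  + np.where(p < 1, (1 - p) * np.log(1 - p), 0.0))
    return terms


def nei_index(g: GenotypeMatrix, group: Iterable[str] | None = None) -> float:
    """Nei's gene diversity: mean over markers of 1 - (p^2 + q^2)."""
    f = allele_frequencies(g, group)
    return float(np.mean(_per_marker_nei(f.p_alt[f.has_calls])))


def shannon_index(g: GenotypeMatrix, group: Iterable[str] | None = None) -> float:
    """Shannon index: mean over markers of -(p ln p + q ln q), with 0 ln 0 = 0."""
    f = allele_frequencies(g, group)
    return float(np.mean(_per_marker_shannon(f.p_alt[f.has_calls])))


def diversity_summary(
    g: GenotypeMatrix,
    groups: GroupAssignment,
    regions: dict[str, str] | None = None,
) -> list[DiversitySummary]:
    """Nei/Shannon mean +- SD across markers for each group, with region percentages."""
    out = []
    for name, members in sorted(groups.groups().items()):
        f = allele_frequencies(g, members)
        p = f.p_alt[f.has_calls]
        nei, sha = _per_marker_nei(p), _per_marker_shannon(p)
        region_pct: dict[str, float] = {}
        if regions is not None:
            reg = [regions.get(a, "unknown") for a in members]
            for r in ("north", "central", "south", "unknown"):
                region_pct[r] = 100.0 * reg.count(r) / len(members)
        out.append(
            DiversitySummary(
                group=name,
                n_accessions=len(members),
                nei=float(nei.mean()),
                nei_sd=float(nei.std(ddof=0)),
                shannon=float(sha.mean()),
                shannon_sd=float(sha.std(ddof=0)),
                region_pct=region_pct,
            )
        )
    return out


def summary_frame(summaries: list[DiversitySummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "group": s.group,
            "nei": s.nei,
            "nei_sd": s.nei_sd,
            "shannon": s.shannon,
            "shannon_sd": s.shannon_sd,
            "n_accessions": s.n_accessions,
        }
        row.update({f"pct_{k}": v for k, v in s.region_pct.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# differentiation and gene flow
# ---------------------------------------------------------------------------

def gst_and_nm(g: GenotypeMatrix, groups: GroupAssignment) -> GeneFlowStats:
    """Nei's G_ST = (H_T - H_S)/H_T and gene flow N_m = (1 - G_ST)/(4 G_ST).

    H_S is the accession-count-weighted mean of within-group gene diversities and
    H_T the gene diversity at pooled (weighted mean) allele frequencies, both
    averaged over markers. A single group is an error; G_ST = 0 maps to infinite
    gene flow.
    """
    parts = groups.groups()
    if len(parts) < 2:
        raise ValueError("G_ST requires at least two groups")
    names = sorted(parts)
    freqs = {k: allele_frequencies(g, parts[k]) for k in names}
    weights = np.array([len(parts[k]) for k in names], dtype=float)
    weights /= weights.sum()
    P = np.vstack([freqs[k].p_alt for k in names])  # groups x markers
    ok = np.all([freqs[k].has_calls for k in names], axis=0)
    P = P[:, ok]
    h_s_marker = (_per_marker_nei(P) * weights[:, None]).sum(axis=0)
    p_bar = (P * weights[:, None]).sum(axis=0)
    h_t_marker = _per_marker_nei(p_bar)
    h_s, h_t = float(h_s_marker.mean()), float(h_t_marker.mean())
    g_st = 0.0 if h_t == 0 else max(0.0, (h_t - h_s) / h_t)
    n_m = float("inf") if g_st == 0 else (1.0 - g_st) / (4.0 * g_st)
    return GeneFlowStats(h_t=h_t, h_s=h_s, g_st=g_st, n_m=n_m)


def _wc_theta(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Weir & Cockerham (1984) multilocus theta for two samples of genotypes.

    Ratio-of-averages over loci of the a / (a + b + c) variance components, using
    per-locus non-missing sample sizes and observed heterozygosity. May be slightly
    negative for undifferentiated samples.
    """
    r = 2
    comps = []
    for calls in (calls_a, calls_b):
        present = calls != MISSING
        n_i = present.sum(axis=0)
        alt = np.where(present, calls, 0).sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = alt / (2.0 * np.maximum(n_i, 1))
        h_i = np.where(present, calls == 1, False).sum(axis=0) / np.maximum(n_i, 1)
        comps.append((n_i.astype(float), p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    ok = (n1 > 0) & (n2 > 0) & (n1 + n2 > 2)
    n1, p1, h1, n2, p2, h2 = (x[ok] for x in (n1, p1, h1, n2, p2, h2))
    n_bar = (n1 + n2) / r
    nc = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (n_bar / nc) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
    denom = np.nansum(a + b + c)
    return float(np.nansum(a) / denom) if denom != 0 else 0.0


def _nei_pairwise_gst(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    def freqs(calls):
        present = calls != MISSING
        n = present.sum(axis=0)
        alt = np.where(present, calls, 0).sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan), n

    p1, n1 = freqs(calls_a)
    p2, n2 = freqs(calls_b)
    ok = (n1 > 0) & (n2 > 0)
    p1, p2 = p1[ok], p2[ok]
    w1 = n1[ok] / (n1[ok] + n2[ok])
    h_s = (w1 * _per_marker_nei(p1) + (1 - w1) * _per_marker_nei(p2)).mean()
    p_bar = w1 * p1 + (1 - w1) * p2
    h_t = _per_marker_nei(p_bar).mean()
    return 0.0 if h_t == 0 else float((h_t - h_s) / h_t)


def pairwise_fst(
    g: GenotypeMatrix,
    groups: GroupAssignment,
    estimator: str = "weir_cockerham",
) -> pd.DataFrame:
    """Multilocus pairwise F_ST between all groups; symmetric with zero diagonal.

    The Weir-Cockerham estimator can be slightly negative for undifferentiated
    pairs; reported values are clamped at 0 with the raw value retained in the
    ``raw`` attribute of the returned frame (``df.attrs['raw']``).
    """
    if estimator not in ("weir_cockerham", "nei"):
        raise ValueError(f"unknown estimator {estimator!r}")
    parts = groups.groups()
    names = sorted(parts)
    idx = {k: g.accession_indices(parts[k]) for k in names}
    raw = np.zeros((len(names), len(names)))
    for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
        ca, cb = g.calls[idx[a]], g.calls[idx[b]]
        val = _wc_theta(ca, cb) if estimator == "weir_cockerham" else _nei_pairwise_gst(ca, cb)
        raw[i, j] = raw[j, i] = val
    clamped = np.clip(raw, 0.0, None)
    df = pd.DataFrame(clamped, index=names, columns=names)
    df.attrs["raw"] = pd.DataFrame(raw, index=names, columns=names)
    return df


# ---------------------------------------------------------------------------
# distances and clustering
# ---------------------------------------------------------------------------

def simple_matching_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Simple-matching distance d(x, y) = 1 - M/N over pairwise-complete markers.

    M counts markers with equal genotype calls (heterozygote matches only
    heterozygote); N counts markers non-missing in both accessions. Pairs with
    N = 0 are flagged missing (NaN).
    """
    present = (g.calls != MISSING)
    n_pairs = present.astype(np.float64) @ present.T.astype(np.float64)
    matches = np.zeros_like(n_pairs)
    for v in (0, 1, 2):
        iv = (g.calls == v).astype(np.float64)
        matches += iv @ iv.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - matches / n_pairs
    d[n_pairs == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(g.accession_ids), d, pair_counts=n_pairs)


def complete_linkage_cluster(
    d: DistanceMatrix, k: int | None = None, cut_height: float | None = None
) -> GroupAssignment:
    """Agglomerative clustering with complete (maximum) linkage.

    Exactly one of ``k`` (number of groups) or ``cut_height`` must be given.
    Deterministic: scipy's linkage with its fixed tie-break order.
    """
    if (k is None) == (cut_height is None):
        raise ValueError("give exactly one of k or cut_height")
    Z = linkage(d.condensed(), method="complete")
    if k is not None:
        labels = fcluster(Z, t=k, criterion="maxclust")
    else:
        labels = fcluster(Z, t=cut_height, criterion="distance")
    return GroupAssignment.from_arrays(d.ids, labels, provenance="genetic")


def select_spaced_markers(
    markers: Sequence[MarkerInfo], total: int, grid: str = "first_anchored"
) -> list[MarkerInfo]:
    """Pick ``total`` markers as equally spaced as possible along each chromosome.

    Steps: (1) allocate a per-chromosome quota proportional to that chromosome's
    marker share (largest-remainder rounding so quotas sum to ``total``);
    (2) per chromosome, compute step = span / quota between the first and last
    mapped position; (3) lay a grid of quota points starting at the first marker
    (``first_anchored``: first + i*step, i = 0..quota-1; ``endpoint``:
    endpoints-inclusive grid); (4) take the marker nearest each grid point without
    replacement, ties resolved toward the lower position.
    """
    by_chrom: dict[str, list[MarkerInfo]] = {}
    for m in markers:
        if m.chrom is None or m.pos is None:
            raise ValueError(f"marker {m.marker_id} lacks a map position")
        by_chrom.setdefault(m.chrom, []).append(m)
    if total > len(markers):
        raise ValueError("total exceeds marker count")
    chroms = sorted(by_chrom)
    counts = np.array([len(by_chrom[c]) for c in chroms], dtype=float)
    quotas = largest_remainder(total * counts / counts.sum(), total)
    selected: list[MarkerInfo] = []
    for c, q in zip(chroms, quotas):
        if q == 0:
            continue
        ms = sorted(by_chrom[c], key=lambda m: (m.pos, m.marker_id))
        pos = np.array([m.pos for m in ms])
        first, last = pos[0], pos[-1]
        if q >= len(ms):
            selected.extend(ms)
            continue
        if grid == "first_anchored":
            points = first + np.arange(q) * (last - first) / q
        elif grid == "endpoint":
            points = np.linspace(first, last, q)
        else:
            raise ValueError(f"unknown grid convention {grid!r}")
        used = np.zeros(len(ms), dtype=bool)
        for pt in points:
            dist = np.abs(pos - pt)
            dist[used] = np.inf
            j = int(np.argmin(dist))  # argmin takes the first (lowest-position) tie
            used[j] = True
            selected.append(ms[j])
    return selected


def largest_remainder(shares: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative real shares to integers summing to ``total``.

    Floors each share then hands the remaining units to the largest fractional
    remainders (ties to the lower index).
    """
    shares = np.asarray(shares, dtype=float)
    base = np.floor(shares).astype(int)
    rem = shares - base
    short = total - int(base.sum())
    if short < 0:
        raise ValueError("shares sum above total")
    order = np.lexsort((np.arange(len(shares)), -rem))
    base[order[:short]] += 1
    return base
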