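"""Synthetic landrace-collection generator.

Emulates the statistical regime of a large genebank GBS panel: thousands of mostly
inbred accessions in drift-differentiated geographic groups, sparse biallelic SNP
calls with heavy per-marker missingness, a large fraction of markers near fixation
(rare alleles), and a mixed ordinal/continuous trait table whose means and variances
follow the field/grain-quality traits typical of wheat landrace evaluation.

Group allele frequencies come from a Balding-Nichols model: for ancestral frequency
``p`` and differentiation ``F``, group frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F),
giving E[p_k] = p and Var[p_k] = F p (1-p) — i.e. an expected multilocus F_ST close
to ``F``. Genotypes are Binomial(2, p_k) with heterozygote calls resampled to
homozygotes so the per-marker heterozygosity never exceeds ``het_max`` in
expectation (largely selfing lines).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .diversity import largest_remainder
from .io_core import (
    MISSING,
    AccessionInfo,
    GenotypeMatrix,
    GroupAssignment,
    MarkerInfo,
    PhenotypeTable,
)

__all__ = ["SimulationConfig", "TraitSpec", "simulate_population", "inject_rare_alleles"]


@dataclass(frozen=True)
class TraitSpec:
    name: str
    kind: str  # "ordinal" | "continuous"
    mean: float
    variance: float
    levels: tuple[float, ...] = ()


# Evaluation-trait catalogue (4 ordinal scores + 19 continuous measurements) with
# the means/variances of a large wheat landrace phenotyping campaign.
DEFAULT_TRAITS: tuple[TraitSpec, ...] = (
    TraitSpec("duration", "ordinal", 2.0, 0.1, (1, 2, 3)),
    TraitSpec("biomass_heading", "ordinal", 2.2, 1.2, (1, 2, 3, 4, 5)),
    TraitSpec("biomass_maturity", "ordinal", 2.4, 1.1, (1, 2, 3, 4, 5)),
    TraitSpec("plant_height_drought_score", "ordinal", 2.9, 0.1, (1, 2, 3, 4, 5)),
    TraitSpec("days_to_heading_heat", "continuous", 63.2, 50.4),
    TraitSpec("days_to_maturity_heat", "continuous", 82.6, 30.1),
    TraitSpec("plant_height_heat", "continuous", 55.4, 30.7),
    TraitSpec("days_to_heading_drought", "continuous", 86.9, 96.5),
    TraitSpec("days_to_maturity_drought", "continuous", 122.8, 51.4),
    TraitSpec("grain_yield_drought", "continuous", 202.3, 6103.7),
    TraitSpec("days_to_heading_irrigated", "continuous", 99.3, 135.4),
    TraitSpec("plant_height_irrigated", "continuous", 146.8, 227.8),
    TraitSpec("thousand_kernel_weight", "continuous", 40.9, 30.5),
    TraitSpec("test_weight", "continuous", 76.2, 8.0),
    TraitSpec("grain_length", "continuous", 6.8, 0.21),
    TraitSpec("grain_width", "continuous", 3.1, 0.04),
    TraitSpec("screen3", "continuous", 49.5, 697.6),
    TraitSpec("screen2", "continuous", 22.3, 158.3),
    TraitSpec("screen1", "continuous", 13.8, 109.1),
    TraitSpec("yellow_berry", "continuous", 6.9, 53.8),
    TraitSpec("grain_hardness", "continuous", 59.3, 19.9),
    TraitSpec("grain_protein", "continuous", 16.1, 1.8),
    TraitSpec("sds_sedimentation", "continuous", 18.5, 14.4),
)

# One collection-site centre per group: (region, state, lat, lon, altitude m).
DEFAULT_GEO_CENTERS: tuple[tuple[str, str, float, float, float], ...] = (
    ("central", "Mexico", 19.3, -99.6, 2600),
    ("central", "Queretaro", 20.6, -100.4, 1800),
    ("north", "Chihuahua", 28.6, -106.1, 1450),
    ("central", "Puebla", 19.0, -97.9, 2150),
    ("north", "Durango", 24.0, -104.7, 1880),
    ("north", "Chihuahua", 29.2, -105.8, 1500),
    ("south", "Oaxaca", 16.8, -96.4, 1500),
    ("south", "Oaxaca", 17.1, -96.7, 1550),
    ("central", "Mexico", 19.5, -99.8, 2550),
    ("central", "Michoacan", 19.6, -101.2, 1900),
    ("north", "Coahuila", 27.3, -102.0, 1400),
    ("central", "Tlaxcala", 19.3, -98.2, 2250),
    ("central", "Michoacan", 19.4, -101.5, 1950),
    ("north", "Chihuahua", 28.0, -106.5, 1550),
    ("central", "Guanajuato", 21.0, -101.3, 1800),
)

# Relative group sizes of the 15 landrace groups in the reference panel.
_DEFAULT_GROUP_WEIGHTS = (
    1227, 495, 829, 1445, 83, 454, 372, 195, 1147, 290, 640, 324, 287, 160, 39,
)


@dataclass
class SimulationConfig:
    """Knobs of the population generator; defaults encode the study regime."""

    n_accessions: int = 7986
    n_markers: int = 20526
    n_groups: int = 15
    group_sizes: tuple[int, ...] | None = None  # None -> proportional to panel weights
    target_fst: float = 0.15
    rare_fraction: float = 0.404  # markers seeded with ancestral frequency < 0.05
    missing_rate: tuple[float, float] = (0.0, 0.5)  # per-marker U(low, high)
    het_max: float = 0.305
    n_traits: int = 23
    trait_specs: tuple[TraitSpec, ...] = DEFAULT_TRAITS
    trait_shift_sd: float = 0.5  # group trait shift, in units of trait SD
    trait_missing_rate: float = 0.02
    geo_centers: tuple[tuple[str, str, float, float, float], ...] = DEFAULT_GEO_CENTERS
    geo_jitter_deg: float = 0.35
    geo_jitter_alt: float = 150.0
    seed: int = 0

    def resolved_group_sizes(self) -> np.ndarray:
        if self.group_sizes is not None:
            sizes = np.asarray(self.group_sizes, dtype=int)
            if len(sizes) != self.n_groups:
                raise ValueError("group_sizes length != n_groups")
            if sizes.sum() != self.n_accessions:
                raise ValueError("group_sizes must sum to n_accessions")
        else:
            w = np.array(_DEFAULT_GROUP_WEIGHTS[: self.n_groups], dtype=float)
            if len(w) < self.n_groups:
                w = np.resize(np.array(_DEFAULT_GROUP_WEIGHTS, float), self.n_groups)
            sizes = largest_remainder(self.n_accessions * w / w.sum(), self.n_accessions)
        if (sizes < 1).any():
            raise ValueError("every group must contain at least one accession")
        return sizes

    def validate(self) -> None:
        if self.n_accessions < 1 or self.n_markers < 1 or self.n_groups < 1:
            raise ValueError("sizes must be positive")
        if not 0 <= self.target_fst < 1:
            raise ValueError("target_fst must be in [0, 1)")
        for r in (self.rare_fraction, self.trait_missing_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        lo, hi = self.missing_rate
        if not (0 <= lo <= hi <= 1):
            raise ValueError("missing_rate bounds must satisfy 0 <= low <= high <= 1")
        if not 0 <= self.het_max <= 0.5:
            raise ValueError("het_max must be in [0, 0.5]")
        self.resolved_group_sizes()


def _group_frequencies(
    rng: np.random.Generator, p_anc: np.ndarray, fst: float, n_groups: int
) -> np.ndarray:
    """Balding-Nichols draw of group x marker allele frequencies."""
    if fst == 0:
        return np.tile(p_anc, (n_groups, 1))
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    return rng.beta(a[None, :], b[None, :], size=(n_groups, len(p_anc)))


def simulate_population(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, PhenotypeTable, list[AccessionInfo], GroupAssignment]:
    """Draw a full synthetic collection: genotypes, traits, sites, group truth.

    Fully reproducible from ``cfg.seed``; every random draw flows from one
    ``numpy`` generator.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.resolved_group_sizes()
    group_of = np.repeat(np.arange(cfg.n_groups), sizes)
    n, m = cfg.n_accessions, cfg.n_markers

    # ancestral frequencies: a rare_fraction slice near 0, the rest mid-range
    is_rare = rng.random(m) < cfg.rare_fraction
    p_anc = np.where(
        is_rare, rng.uniform(0.003, 0.045, m), rng.uniform(0.05, 0.95, m)
    )
    p_grp = _group_frequencies(rng, p_anc, cfg.target_fst, cfg.n_groups)
    calls = rng.binomial(2, p_grp[group_of, :]).astype(np.int8)

    # inbreeding: convert het calls to random homozygotes so per-marker
    # heterozygosity tops out at het_max (max of 2p(1-p) is 0.5)
    keep_het = min(1.0, cfg.het_max / 0.5)
    het = calls == 1
    flip = het & (rng.random(calls.shape) >= keep_het)
    calls[flip] = rng.choice(np.array([0, 2], dtype=np.int8), size=int(flip.sum()))

    # per-marker missingness
    miss_frac = rng.uniform(cfg.missing_rate[0], cfg.missing_rate[1], m)
    calls[rng.random(calls.shape) < miss_frac[None, :]] = MISSING

    accession_ids = [f"ACC{i:05d}" for i in range(n)]
    markers = [
        MarkerInfo(f"M{j:06d}", chrom=f"chr{(j % 21) + 1}", pos=float(j // 21))
        for j in range(m)
    ]
    geno = GenotypeMatrix(accession_ids, calls, markers)

    # traits: group-shifted normals; ordinal traits via rounded latent normals
    specs = cfg.trait_specs[: cfg.n_traits]
    data = {}
    kinds, levels = {}, {}
    for spec in specs:
        sd = np.sqrt(spec.variance)
        shifts = rng.normal(0.0, cfg.trait_shift_sd * sd, cfg.n_groups)
        vals = rng.normal(spec.mean + shifts[group_of], sd)
        if spec.kind == "ordinal":
            lv = np.asarray(spec.levels, dtype=float)
            vals = lv[np.argmin(np.abs(vals[:, None] - lv[None, :]), axis=1)]
            levels[spec.name] = list(lv)
        vals = vals.astype(float)
        vals[rng.random(n) < cfg.trait_missing_rate] = np.nan
        data[spec.name] = vals
        kinds[spec.name] = spec.kind
    pheno = PhenotypeTable(
        pd.DataFrame(data, index=pd.Index(accession_ids, name="accession")), kinds, levels
    )

    # collection sites jittered around each group's centre
    centers = list(cfg.geo_centers)
    while len(centers) < cfg.n_groups:
        centers += list(cfg.geo_centers)
    info = []
    for i, gidx in enumerate(group_of):
        region, state, lat, lon, alt = centers[gidx]
        info.append(
            AccessionInfo(
                accession_id=accession_ids[i],
                region=region,  # type: ignore[arg-type]
                state=state,
                latitude=float(np.clip(lat + rng.normal(0, cfg.geo_jitter_deg), -90, 90)),
                longitude=float(np.clip(lon + rng.normal(0, cfg.geo_jitter_deg), -180, 180)),
                altitude=float(alt + rng.normal(0, cfg.geo_jitter_alt)),
            )
        )

    truth = GroupAssignment.from_arrays(
        accession_ids, [f"G{g + 1:02d}" for g in group_of], provenance="genetic"
    )
    return geno, pheno, info, truth


def inject_rare_alleles(
    g: GenotypeMatrix,
    group: GroupAssignment,
    spec: dict[str, int],
    seed: int,
    return_markers: bool = False,
):
    """Plant group-private rare alleles: overwrite markers so the minor allele
    appears only in the designated group at whole-population frequency in (0, 0.05).

    Returns a new GenotypeMatrix (and, with ``return_markers``, the mapping from
    group label to the list of marker IDs that were overwritten).
    """
    rng = np.random.default_rng(seed)
    total = sum(spec.values())
    if total > g.n_markers:
        raise ValueError("requested more private alleles than markers available")
    calls = g.calls.copy()
    marker_pool = rng.permutation(g.n_markers)
    planted: dict[str, list[str]] = {}
    pos = 0
    for label, count in spec.items():
        if count < 0:
            raise ValueError("counts must be non-negative")
        members = g.accession_indices(group.members(label))
        planted[label] = []
        for _ in range(count):
            col = marker_pool[pos]
            pos += 1
            present = calls[:, col] != MISSING
            calls[present, col] = 0
            n_calls = int(present.sum())
            member_present = members[present[members]]
            c_max = min(len(member_present), int(np.ceil(0.1 * n_calls)) - 1)
            # keep the allele rare within the group's own population too, when
            # the group is large enough for that to be possible at all
            g_max = int(np.ceil(0.1 * len(member_present))) - 1
            if g_max >= 1:
                c_max = min(c_max, g_max)
            if c_max < 1:
                raise ValueError(
                    f"group {label!r}: cannot place a rare allele below frequency 0.05"
                )
            c = int(rng.integers(1, c_max + 1))
            carriers = rng.choice(member_present, size=c, replace=False)
            calls[carriers, col] = 1
            planted[label].append(g.markers[col].marker_id)
    out = GenotypeMatrix(g.accession_ids, calls, g.markers)
    return (out, planted) if return_markers else out
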