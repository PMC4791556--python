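"""Core-vs-complete comparison, phenotype ratio report and MDS representativeness.

The comparison mirrors the standard genebank summary: lost alleles (MAF = 0),
rare-allele counts and percentages (denominator = 2 x marker count, the total number
of alleles), recovery of the complete set's rare alleles in the core (an allele is
recovered when its frequency in the core is above 0), diversity indices, and the
regional composition of each set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diversity import DistanceMatrix, allele_frequencies, nei_index, shannon_index
from .io_core import AccessionInfo, GenotypeMatrix, PhenotypeTable
from .rare_alleles import RareAlleleSet, define_rare_alleles

__all__ = [
    "CoreComparisonReport",
    "compare_core_complete",
    "rare_allele_percentage",
    "phenotype_ratio_report",
    "mds_coordinates",
]


@dataclass
class CoreComparisonReport:
    """Summary statistics of the complete set vs a core subset."""

    n_complete: int
    n_core: int
    lost_alleles_complete: int
    lost_alleles_core: int
    rare_complete: int
    rare_core: int
    rare_pct_complete: float
    rare_pct_core: float
    recovery_pct: float  # complete-set rare alleles present in the core
    loss_pct: float
    rare_cs_above_threshold: int  # complete-set rare alleles with core freq >= 0.05
    nei_complete: float
    nei_core: float
    shannon_complete: float
    shannon_core: float
    region_pct_complete: dict[str, float] = field(default_factory=dict)
    region_pct_core: dict[str, float] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        rows = {
            "Number of accessions": (self.n_complete, self.n_core),
            "Number of lost alleles [MAF = 0]": (
                self.lost_alleles_complete, self.lost_alleles_core),
            "Number of rare alleles [MAF < 0.05]": (self.rare_complete, self.rare_core),
            "% of rare alleles [MAF < 0.05]": (self.rare_pct_complete, self.rare_pct_core),
            "% of rare-CS allele recovery": (100.0, self.recovery_pct),
            "% loss of rare-CS alleles": (0.0, self.loss_pct),
            "Number of rare-CS alleles with frequency >= 0.05": (
                float("nan"), self.rare_cs_above_threshold),
            "Nei diversity index": (self.nei_complete, self.nei_core),
            "Shannon diversity index": (self.shannon_complete, self.shannon_core),
        }
        for region in sorted(set(self.region_pct_complete) | set(self.region_pct_core)):
            rows[f"% of accessions: {region}"] = (
                self.region_pct_complete.get(region, 0.0),
                self.region_pct_core.get(region, 0.0),
            )
        return pd.DataFrame(rows, index=["complete", "core"]).T


def rare_allele_percentage(n_rare: int, n_markers: int) -> float:
    """Rare alleles as a percentage of all alleles (2 per biallelic marker)."""
    if n_markers <= 0:
        raise ValueError("marker count must be positive")
    return 100.0 * n_rare / (2 * n_markers)


def _lost_allele_count(g: GenotypeMatrix, subset: Iterable[str] | None) -> int:
    f = allele_frequencies(g, subset)
    return int((f.has_calls & (f.maf == 0)).sum())


def _region_pct(ids: Sequence[str], regions: dict[str, str]) -> dict[str, float]:
    reg = [regions.get(a, "unknown") for a in ids]
    return {
        r: 100.0 * reg.count(r) / len(ids)
        for r in ("north", "central", "south", "unknown")
    }


def compare_core_complete(
    g: GenotypeMatrix,
    core: Sequence[str] | "object",
    regions: Sequence[AccessionInfo] | None = None,
    threshold: float = 0.05,
) -> CoreComparisonReport:
    """All comparison fields for a core subset against the full collection.

    ``core`` is either a sequence of accession IDs or any object exposing
    ``accession_ids``. Recovery counts complete-set rare alleles whose frequency
    in the core is strictly positive; recovery% + loss% = 100 by construction.
    """
    core_ids = list(getattr(core, "accession_ids", core))
    rare_complete: RareAlleleSet = define_rare_alleles(g, None, threshold)
    rare_core = define_rare_alleles(g, core_ids, threshold, population_id="core")
    f_core = allele_frequencies(g, core_ids)

    def core_freq(allele: tuple[int, str]) -> float:
        j, which = allele
        p = f_core.p_alt[j]
        if np.isnan(p):
            return 0.0
        return p if which == "alt" else 1.0 - p

    core_freqs = np.array([core_freq(a) for a in rare_complete.alleles])
    recovered = int((core_freqs > 0).sum()) if len(core_freqs) else 0
    n_rare_cs = len(rare_complete)
    recovery = 100.0 * recovered / n_rare_cs if n_rare_cs else 100.0
    above = int((core_freqs >= threshold).sum()) if len(core_freqs) else 0

    region_map = {a.accession_id: a.region for a in regions} if regions else {}
    return CoreComparisonReport(
        n_complete=g.n_accessions,
        n_core=len(core_ids),
        lost_alleles_complete=_lost_allele_count(g, None),
        lost_alleles_core=_lost_allele_count(g, core_ids),
        rare_complete=n_rare_cs,
        rare_core=len(rare_core),
        rare_pct_complete=rare_allele_percentage(n_rare_cs, g.n_markers),
        rare_pct_core=rare_allele_percentage(len(rare_core), g.n_markers),
        recovery_pct=recovery,
        loss_pct=100.0 - recovery,
        rare_cs_above_threshold=above,
        nei_complete=nei_index(g),
        nei_core=nei_index(g, core_ids),
        shannon_complete=shannon_index(g),
        shannon_core=shannon_index(g, core_ids),
        region_pct_complete=_region_pct(g.accession_ids, region_map) if regions else {},
        region_pct_core=_region_pct(core_ids, region_map) if regions else {},
    )


def phenotype_ratio_report(
    pheno: PhenotypeTable, core: Sequence[str] | "object"
) -> pd.DataFrame:
    """Per-trait complete/core ratios of means and variances (missing-aware)."""
    core_ids = list(getattr(core, "accession_ids", core))
    full = pheno.data
    sub = pheno.data.loc[core_ids]
    mean_ratio = full.mean() / sub.mean()
    var_ratio = full.var(ddof=1) / sub.var(ddof=1)
    return pd.DataFrame({"mean_ratio": mean_ratio, "variance_ratio": var_ratio})


def mds_coordinates(d: DistanceMatrix, dims: int = 2) -> tuple[np.ndarray, float]:
    """Classical (metric) MDS of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and returns the top
    ``dims`` coordinates (centered) together with a normalized stress
    ``sqrt(sum (d_ij - dhat_ij)^2 / sum d_ij^2)``. Negative eigenvalues (from
    non-Euclidean distances) are truncated at zero.
    """
    D = np.nan_to_num(np.asarray(d.values, dtype=float), nan=1.0)
    n = D.shape[0]
    if not 1 <= dims < n:
        raise ValueError("dims must be in [1, n)")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.maximum(evals[order], 0.0)
    X = evecs[:, order] * np.sqrt(lam)[None, :]
    X = X - X.mean(axis=0)
    Dhat = np.sqrt(
        np.maximum(
            (X**2).sum(1)[:, None] + (X**2).sum(1)[None, :] - 2 * X @ X.T, 0.0
        )
    )
    iu = np.triu_indices(n, 1)
    denom = float((D[iu] ** 2).sum())
    stress = float(np.sqrt(((D[iu] - Dhat[iu]) ** 2).sum() / denom)) if denom > 0 else 0.0
    return X, stress
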