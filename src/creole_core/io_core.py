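"""Core data containers and file I/O for genotype, phenotype and collection-site tables.

Genotypes are biallelic SNP calls stored as alternate-allele dosage (0, 1, 2) with a
distinct ``MISSING`` sentinel (-1); the heterozygote is always 1.  Three on-disk
dialects are supported: a plain CSV/TSV matrix (accessions x markers), a HapMap-style
table (rs, alleles, chrom, pos, then per-accession IUPAC codes) and minimal GT-only
VCF for biallelic records.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call. Never conflated with dosage 0.
MISSING: int = -1

_IUPAC_HET = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
_HET_TO_PAIR = {v: k for k, v in _IUPAC_HET.items()}

Region = Literal["north", "central", "south", "unknown"]


class FormatError(ValueError):
    """Raised when an input file does not follow the declared dialect."""


class ValidationError(ValueError):
    """Raised when parsed data violate a container invariant."""


@dataclass(frozen=True)
class MarkerInfo:
    """A single SNP marker: identifier plus optional map position (cM or bp)."""

    marker_id: str
    chrom: str | None = None
    pos: float | None = None

    def __post_init__(self) -> None:
        if self.pos is not None and self.pos < 0:
            raise ValidationError(f"marker {self.marker_id}: negative position {self.pos}")


@dataclass
class GenotypeMatrix:
    """Accessions x markers dosage matrix with missing-data sentinel.

    ``calls[i, j]`` is the alternate-allele count of accession i at marker j,
    one of {0, 1, 2, MISSING}.
    """

    accession_ids: list[str]
    calls: np.ndarray
    markers: list[MarkerInfo]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValidationError("calls must be a 2-D array")
        n, m = self.calls.shape
        if n != len(self.accession_ids):
            raise ValidationError(f"{len(self.accession_ids)} accession ids vs {n} call rows")
        if m != len(self.markers):
            raise ValidationError(f"{len(self.markers)} markers vs {m} call columns")
        if len(set(self.accession_ids)) != n:
            raise ValidationError("duplicate accession IDs")
        ids = [mk.marker_id for mk in self.markers]
        if len(set(ids)) != m:
            raise ValidationError("duplicate marker IDs")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(f"invalid call {self.calls[i, j]} at ({i}, {j})")

    # -- basic views ---------------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def accession_indices(self, accessions: Iterable[str]) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            return np.array([lookup[a] for a in accessions], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown accession {exc.args[0]!r}") from None

    def take_accessions(self, accessions: Sequence[str]) -> "GenotypeMatrix":
        idx = self.accession_indices(accessions)
        return GenotypeMatrix(list(accessions), self.calls[idx], self.markers)

    def take_markers(self, columns: np.ndarray) -> "GenotypeMatrix":
        columns = np.asarray(columns)
        if columns.dtype == bool:
            columns = np.flatnonzero(columns)
        return GenotypeMatrix(
            self.accession_ids, self.calls[:, columns], [self.markers[j] for j in columns]
        )


@dataclass
class PhenotypeTable:
    """Mixed ordinal/continuous trait table aligned to accession IDs.

    Ordinal traits carry a declared finite level set; values are stored
    numerically (level codes) with NaN for missing observations.
    """

    data: pd.DataFrame
    trait_kind: dict[str, str]
    levels: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing_kind = set(self.data.columns) - set(self.trait_kind)
        if missing_kind:
            raise ValidationError(f"no trait_kind declared for {sorted(missing_kind)}")
        for trait, kind in self.trait_kind.items():
            if kind not in ("ordinal", "continuous"):
                raise ValidationError(f"trait {trait}: unknown kind {kind!r}")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate accession IDs in phenotype table")

    @property
    def accession_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def take_accessions(self, accessions: Sequence[str]) -> "PhenotypeTable":
        return PhenotypeTable(self.data.loc[list(accessions)], self.trait_kind, self.levels)


@dataclass(frozen=True)
class AccessionInfo:
    """Collection-site record for one accession."""

    accession_id: str
    region: Region = "unknown"
    state: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    altitude: float | None = None

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            raise ValidationError(f"{self.accession_id}: latitude {self.latitude} out of range")
        if self.longitude is not None and not -180 <= self.longitude <= 180:
            raise ValidationError(f"{self.accession_id}: longitude {self.longitude} out of range")


@dataclass
class GroupAssignment:
    """Partition of accessions into labelled groups (genetic, geographic or mixture)."""

    labels: dict[str, str]
    provenance: str = "genetic"

    def __post_init__(self) -> None:
        if self.provenance not in ("genetic", "geographic", "mixture"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")

    @property
    def group_names(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def members(self, group: str) -> list[str]:
        return [a for a, g in self.labels.items() if g == group]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for a, g in self.labels.items():
            out.setdefault(g, []).append(a)
        return out

    @classmethod
    def from_arrays(
        cls, accession_ids: Sequence[str], labels: Sequence, provenance: str = "genetic"
    ) -> "GroupAssignment":
        if len(accession_ids) != len(labels):
            raise ValidationError("accession_ids and labels differ in length")
        return cls({a: str(g) for a, g in zip(accession_ids, labels)}, provenance)


# ---------------------------------------------------------------------------
# genotype readers / writers
# ---------------------------------------------------------------------------

def _parse_dosage_cell(cell: str) -> int:
    cell = cell.strip()
    if cell in ("", "NA", "N/A", "NaN", "nan", ".", "-", str(MISSING)):
        return MISSING
    if cell in ("0", "1", "2"):
        return int(cell)
    return MISSING  # ambiguous call -> missing, per contract


def _read_csv_matrix(path: Path, sep: str) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows or len(rows[0]) < 2:
        raise FormatError(f"{path}: line 1: expected header with accession column + marker IDs")
    marker_ids = rows[0][1:]
    accessions, calls = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != len(marker_ids) + 1:
            raise FormatError(f"{path}: line {lineno}: expected {len(marker_ids) + 1} fields")
        accessions.append(row[0])
        calls.append([_parse_dosage_cell(c) for c in row[1:]])
    markers = [MarkerInfo(m) for m in marker_ids]
    return GenotypeMatrix(accessions, np.array(calls, dtype=np.int8), markers)


def _read_hapmap(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 5 or header[0] not in ("rs", "rs#"):
            raise FormatError(f"{path}: line 1: expected HapMap header starting with 'rs'")
        accessions = header[4:]
        markers: list[MarkerInfo] = []
        cols: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(f"{path}: line {lineno}: expected {len(header)} fields")
            rs, alleles, chrom, pos = parts[:4]
            try:
                ref, alt = alleles.split("/")
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: bad alleles field {alleles!r}") from None
            het = _IUPAC_HET.get(frozenset((ref, alt)))
            row = []
            for code in parts[4:]:
                if code == ref:
                    row.append(0)
                elif code == alt:
                    row.append(2)
                elif code == het:
                    row.append(1)
                else:
                    row.append(MISSING)
            markers.append(
                MarkerInfo(rs, chrom if chrom not in ("", ".") else None,
                           float(pos) if pos not in ("", ".") else None)
            )
            cols.append(row)
    calls = np.array(cols, dtype=np.int8).T if cols else np.empty((len(accessions), 0), np.int8)
    return GenotypeMatrix(accessions, calls, markers)


def _read_vcf(path: Path) -> GenotypeMatrix:
    """GT-only reader for biallelic VCF v4.x records (htslib via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    markers: list[MarkerInfo] = []
    cols: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise FormatError(f"{path}: multi-allelic record {variant.ID or variant.POS!r}")
        geno = np.array([a + b if a >= 0 and b >= 0 else MISSING
                         for a, b, *_ in variant.genotypes], dtype=np.int8)
        vid = variant.ID or f"{variant.CHROM}_{variant.POS}"
        markers.append(MarkerInfo(vid, variant.CHROM, float(variant.POS)))
        cols.append(geno)
    vcf.close()
    calls = np.array(cols, dtype=np.int8).T if cols else np.empty((len(accessions), 0), np.int8)
    return GenotypeMatrix(accessions, calls, markers)


def read_genotypes(path: str | Path, dialect: str = "csv_matrix") -> GenotypeMatrix:
    """Read a genotype matrix from ``path`` in the given dialect.

    Parameters
    ----------
    path
        Input file. Must exist.
    dialect
        One of ``csv_matrix``, ``tsv_matrix``, ``hapmap``, ``vcf``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv_matrix":
        return _read_csv_matrix(path, ",")
    if dialect == "tsv_matrix":
        return _read_csv_matrix(path, "\t")
    if dialect == "hapmap":
        return _read_hapmap(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unsupported dialect {dialect!r}")


def write_genotypes(g: GenotypeMatrix, path: str | Path, dialect: str = "csv_matrix") -> None:
    """Write ``g`` to ``path``; inverse of :func:`read_genotypes` for each dialect."""
    path = Path(path)
    if dialect in ("csv_matrix", "tsv_matrix"):
        sep = "," if dialect == "csv_matrix" else "\t"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter=sep)
            w.writerow(["accession"] + g.marker_ids)
            for i, acc in enumerate(g.accession_ids):
                w.writerow([acc] + ["NA" if c == MISSING else str(c) for c in g.calls[i]])
        return
    if dialect == "hapmap":
        # alleles fixed to A/G: dosage 0 -> A, 2 -> G, 1 -> R (IUPAC het)
        code = {0: "A", 2: "G", 1: "R", MISSING: "N"}
        with open(path, "w") as fh:
            fh.write("\t".join(["rs", "alleles", "chrom", "pos"] + g.accession_ids) + "\n")
            for j, mk in enumerate(g.markers):
                row = [mk.marker_id, "A/G", mk.chrom or ".",
                       "." if mk.pos is None else format(mk.pos, "g")]
                row += [code[int(c)] for c in g.calls[:, j]]
                fh.write("\t".join(row) + "\n")
        return
    if dialect == "vcf":
        gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(g.accession_ids) + "\n")
            for j, mk in enumerate(g.markers):
                pos = "1" if mk.pos is None else format(int(mk.pos), "d")
                row = [mk.chrom or "un", pos, mk.marker_id, "A", "G", ".", "PASS", ".", "GT"]
                row += [gt[int(c)] for c in g.calls[:, j]]
                fh.write("\t".join(row) + "\n")
        return
    raise ValueError(f"unsupported dialect {dialect!r}")


# ---------------------------------------------------------------------------
# marker filtering
# ---------------------------------------------------------------------------

def filter_markers(
    g: GenotypeMatrix, max_missing_fraction: float = 0.5, drop_monomorphic: bool = False
) -> GenotypeMatrix:
    """Retain markers whose missing fraction is strictly below the threshold.

    With ``drop_monomorphic`` set, markers with minor-allele frequency 0 over the
    non-missing calls are also removed. Accession order is never changed. An empty
    result emits a warning rather than an error.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    miss = g.missing_mask.mean(axis=0)
    keep = miss < max_missing_fraction
    if drop_monomorphic:
        present = ~g.missing_mask
        n_calls = present.sum(axis=0)
        alt = np.where(present, g.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_calls > 0, alt / (2.0 * np.maximum(n_calls, 1)), np.nan)
        keep &= (p > 0) & (p < 1)  # NaN (no calls) compares False -> dropped
    if not keep.any():
        import warnings

        warnings.warn("all markers removed by filter", stacklevel=2)
    return g.take_markers(keep)


# ---------------------------------------------------------------------------
# phenotype / metadata readers
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path, schema: Mapping[str, Mapping]) -> PhenotypeTable:
    """Read a phenotype CSV and validate it against a trait-kind schema.

    ``schema`` maps each trait column to ``{"kind": "ordinal"|"continuous",
    "levels": [...]}`` (levels required for ordinal traits). The first CSV column
    is the accession ID.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    cols = set(df.columns)
    declared = set(schema)
    if cols != declared:
        raise ValidationError(
            f"schema/column mismatch: only-in-file {sorted(cols - declared)}, "
            f"only-in-schema {sorted(declared - cols)}"
        )
    kinds: dict[str, str] = {}
    levels: dict[str, list[float]] = {}
    for trait, spec in schema.items():
        kind = spec["kind"]
        kinds[trait] = kind
        col = pd.to_numeric(df[trait], errors="coerce")
        if kind == "ordinal":
            lv = [float(x) for x in spec["levels"]]
            levels[trait] = lv
            bad = col.notna() & ~col.isin(lv)
            if bad.any():
                row = df.index[bad][0]
                raise ValidationError(
                    f"trait {trait!r}, accession {row!r}: value {df.loc[row, trait]!r} "
                    f"outside declared levels {lv}"
                )
        df[trait] = col.astype(float)
    return PhenotypeTable(df, kinds, levels)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.data.to_csv(path, index_label="accession")


def read_metadata(path: str | Path) -> list[AccessionInfo]:
    """Read collection-site metadata CSV (accession, region, state, lat, lon, alt)."""
    df = pd.read_csv(path, dtype={"accession": str})
    out = []
    for _, row in df.iterrows():
        def _num(key):
            v = row.get(key)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

        region = row.get("region", "unknown")
        if not isinstance(region, str) or region not in ("north", "central", "south"):
            region = "unknown"
        state = row.get("state")
        out.append(
            AccessionInfo(
                accession_id=str(row["accession"]),
                region=region,
                state=state if isinstance(state, str) else None,
                latitude=_num("latitude"),
                longitude=_num("longitude"),
                altitude=_num("altitude"),
            )
        )
    return out


def write_metadata(info: Sequence[AccessionInfo], path: str | Path) -> None:
    pd.DataFrame(
        {
            "accession": [a.accession_id for a in info],
            "region": [a.region for a in info],
            "state": [a.state for a in info],
            "latitude": [a.latitude for a in info],
            "longitude": [a.longitude for a in info],
            "altitude": [a.altitude for a in info],
        }
    ).to_csv(path, index=False)
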