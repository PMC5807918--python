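"""Genotype, marker-map and phenotype containers plus readers/writers.

The genome vocabulary is the 21 chromosomes of allohexaploid wheat:
seven homoeologous groups (1-7) crossed with three subgenomes (A, B, D).
Genotypes are biallelic SNPs coded as counts of the minor allele
(0/1/2), with NaN for missing calls.

Supported on-disk dialects:

* a documented TSV pair (``*.geno.tsv`` + ``*.markers.tsv``),
* PLINK text ``.ped``/``.map``,
* PLINK binary ``.bed``/``.bim``/``.fam`` (SNP-major).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUBGENOMES = ("A", "B", "D")
HOMOEO_GROUPS = (1, 2, 3, 4, 5, 6, 7)
#: Canonical chromosome order: 1A..7A, 1B..7B, 1D..7D.
CHROMOSOMES = tuple(f"{g}{s}" for s in SUBGENOMES for g in HOMOEO_GROUPS)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending record."""


class StructuralError(ValueError):
    """Counts/labels inconsistent between files or with the genome vocabulary."""


def split_chromosome(label: str) -> tuple[str, int]:
    """Return ``(subgenome, homoeologous group)`` for a chromosome label.

    Raises :class:`StructuralError` for anything outside {1..7} x {A,B,D}.
    """
    label = str(label).strip()
    if label not in CHROMOSOMES:
        raise StructuralError(
            f"unknown chromosome label {label!r}; expected one of 1A..7D"
        )
    return label[1], int(label[0])


@dataclass
class MarkerMap:
    """Per-marker chromosome assignment.

    Wraps a DataFrame with columns ``marker_id``, ``chromosome`` and the
    derived ``subgenome`` / ``homoeo_group`` columns. ``position`` (bp) is
    optional metadata; nothing downstream uses intra-chromosome position.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker_id", "chromosome"}
        missing = required - set(t.columns)
        if missing:
            raise StructuralError(f"marker map missing columns: {sorted(missing)}")
        if t["marker_id"].duplicated().any():
            dup = t.loc[t["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise StructuralError(f"duplicated marker_id {dup!r}")
        parsed = [split_chromosome(c) for c in t["chromosome"]]
        t = t.copy()
        t["chromosome"] = t["chromosome"].astype(str)
        t["subgenome"] = [s for s, _ in parsed]
        t["homoeo_group"] = [g for _, g in parsed]
        t.reset_index(drop=True, inplace=True)
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    def subset(self, index: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.iloc[np.asarray(index)].reset_index(drop=True))


@dataclass
class GenotypePanel:
    """n individuals x m markers of 0/1/2 minor-allele counts (NaN = missing)."""

    individual_ids: list[str]
    genotypes: np.ndarray  # float array, shape (n, m)
    map: MarkerMap

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=float)
        if g.ndim != 2:
            raise StructuralError("genotypes must be a 2-D matrix")
        if g.shape[0] != len(self.individual_ids):
            raise StructuralError(
                f"{len(self.individual_ids)} individuals but "
                f"{g.shape[0]} genotype rows"
            )
        if g.shape[1] != len(self.map):
            raise StructuralError(
                f"{len(self.map)} mapped markers but {g.shape[1]} genotype columns"
            )
        valid = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ParseError(
                f"genotype for individual {self.individual_ids[i]!r}, marker "
                f"{self.map.marker_ids[j]!r} is {g[i, j]!r}; expected 0/1/2/missing"
            )
        self.genotypes = g
        self.individual_ids = [str(i) for i in self.individual_ids]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker frequency of the counted allele, over non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.genotypes, axis=0) / 2.0

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.genotypes).mean(axis=0)

    def subset_markers(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            list(self.individual_ids),
            self.genotypes[:, index],
            self.map.subset(index),
        )

    def subset_individuals(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            [self.individual_ids[i] for i in index],
            self.genotypes[index, :],
            self.map,
        )


@dataclass
class PhenotypeTable:
    """Quantitative phenotypes, one column per trait, indexed by individual id."""

    values: pd.DataFrame  # index = individual_id, columns = trait names

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise StructuralError("duplicated individual ids in phenotype table")
        self.values = v.astype(float)

    @property
    def individual_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)

    def aligned_trait(
        self, panel: GenotypePanel, trait: str
    ) -> tuple[np.ndarray, np.ndarray]:
        """Join one trait onto a panel by identifier.

        Returns ``(y, keep_index)`` where ``keep_index`` indexes panel rows
        with a non-missing phenotype; dropped individuals are logged.
        """
        series = self.values[trait]
        ids = pd.Index(panel.individual_ids)
        joined = series.reindex(ids)
        keep = np.flatnonzero(joined.notna().to_numpy())
        n_drop = panel.n_individuals - keep.size
        if n_drop:
            logger.info(
                "trait %s: dropped %d/%d individuals without a phenotype",
                trait, n_drop, panel.n_individuals,
            )
        return joined.to_numpy()[keep], keep


class GenomeSizes:
    """Physical chromosome sizes in Mb with subgenome/group roll-ups."""

    def __init__(self, sizes: dict[str, float]):
        missing = set(CHROMOSOMES) - set(sizes)
        if missing:
            raise StructuralError(f"missing chromosome sizes: {sorted(missing)}")
        for c, v in sizes.items():
            split_chromosome(c)
            if not v > 0:
                raise StructuralError(f"non-positive size for {c}: {v}")
        self._sizes = {c: float(sizes[c]) for c in CHROMOSOMES}

    def __getitem__(self, chromosome: str) -> float:
        return self._sizes[chromosome]

    def as_series(self) -> pd.Series:
        return pd.Series(self._sizes, name="size_mb")

    def subgenome_size(self, subgenome: str) -> float:
        return sum(v for c, v in self._sizes.items() if c[1] == subgenome)

    def group_size(self, group: int) -> float:
        return sum(v for c, v in self._sizes.items() if int(c[0]) == group)

    def total(self) -> float:
        return sum(self._sizes.values())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeSizes":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["chromosome"].astype(str), df["size_mb"])))

    @classmethod
    def default(cls) -> "GenomeSizes":
        """Packaged wheat physical sizes (A 5727, B 6274, D 4945 Mb)."""
        return cls.from_tsv(Path(__file__).parent / "data" / "genome_sizes.tsv")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_FORMATS = ("tsv", "ped", "bed")


def _paths_for(path: Path, fmt: str) -> dict[str, Path]:
    base = path.with_suffix("") if path.suffix in {".tsv", ".ped", ".bed"} else path
    base = Path(str(base).removesuffix(".geno"))
    if fmt == "tsv":
        return {"geno": Path(str(base) + ".geno.tsv"),
                "map": Path(str(base) + ".markers.tsv")}
    if fmt == "ped":
        return {"ped": base.with_suffix(".ped"), "map": base.with_suffix(".map")}
    return {"bed": base.with_suffix(".bed"), "bim": base.with_suffix(".bim"),
            "fam": base.with_suffix(".fam")}


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypePanel:
    """Read a genotype panel; ``format`` is one of ``tsv``, ``ped``, ``bed``."""
    if format not in _FORMATS:
        raise ValueError(f"unsupported format {format!r}; choose from {_FORMATS}")
    files = _paths_for(Path(path), format)
    for f in files.values():
        if not f.exists():
            raise FileNotFoundError(f)
    if format == "tsv":
        return _read_tsv(files)
    if format == "ped":
        return _read_ped(files)
    return _read_bed(files)


def write_genotypes(panel: GenotypePanel, path: str | Path,
                    format: str = "tsv") -> None:
    if format not in _FORMATS:
        raise ValueError(f"unsupported format {format!r}; choose from {_FORMATS}")
    files = _paths_for(Path(path), format)
    if format == "tsv":
        _write_tsv(panel, files)
    elif format == "ped":
        _write_ped(panel, files)
    else:
        _write_bed(panel, files)


def _read_map_table(path: Path, sep: str = "\t") -> MarkerMap:
    df = pd.read_csv(path, sep=sep)
    try:
        return MarkerMap(df)
    except StructuralError as exc:
        raise StructuralError(f"{path}: {exc}") from exc


def _read_tsv(files: dict[str, Path]) -> GenotypePanel:
    mmap = _read_map_table(files["map"])
    df = pd.read_csv(files["geno"], sep="\t", index_col=0, na_values=["NA"])
    if list(df.columns) != list(mmap.marker_ids):
        raise StructuralError(
            f"{files['geno']}: genotype columns do not match marker map order"
        )
    return GenotypePanel(list(df.index.astype(str)), df.to_numpy(float), mmap)


def _write_tsv(panel: GenotypePanel, files: dict[str, Path]) -> None:
    df = pd.DataFrame(panel.genotypes, index=panel.individual_ids,
                      columns=panel.map.marker_ids)
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.index.name = "individual_id"
    out.to_csv(files["geno"], sep="\t")
    cols = ["marker_id", "chromosome"]
    if "position" in panel.map.table.columns:
        cols.append("position")
    panel.map.table[cols].to_csv(files["map"], sep="\t", index=False)


def _read_plink_map(path: Path) -> MarkerMap:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields")
            rows.append({"marker_id": parts[1], "chromosome": parts[0],
                         "position": int(parts[3])})
    return MarkerMap(pd.DataFrame(rows))


def _read_ped(files: dict[str, Path]) -> GenotypePanel:
    mmap = _read_plink_map(files["map"])
    m = len(mmap)
    ids, rows = [], []
    with open(files["ped"]) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f"{files['ped']}:{lineno}: expected {6 + 2 * m} fields, "
                    f"got {len(parts)}"
                )
            ids.append(parts[1])
            alleles = parts[6:]
            row = np.empty(m)
            for j in range(m):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                if a == "0" or b == "0":
                    row[j] = np.nan
                else:
                    # allele "A" is the counted (minor) allele, "B" the other
                    row[j] = (a == "A") + (b == "A")
            rows.append(row)
    return GenotypePanel(ids, np.asarray(rows), mmap)


def _write_ped(panel: GenotypePanel, files: dict[str, Path]) -> None:
    with open(files["ped"], "w") as fh:
        for i, ind in enumerate(panel.individual_ids):
            fields = [ind, ind, "0", "0", "0", "-9"]
            for v in panel.genotypes[i]:
                if np.isnan(v):
                    fields += ["0", "0"]
                else:
                    k = int(v)
                    fields += ["A"] * k + ["B"] * (2 - k)
            fh.write(" ".join(fields) + "\n")
    with open(files["map"], "w") as fh:
        t = panel.map.table
        pos = t["position"] if "position" in t.columns else range(1, len(t) + 1)
        for chrom, mid, p in zip(t["chromosome"], t["marker_id"], pos):
            fh.write(f"{chrom} {mid} 0 {int(p)}\n")


def _read_bed(files: dict[str, Path]) -> GenotypePanel:
    bim = pd.read_csv(
        files["bim"], sep=r"\s+", header=None,
        names=["chromosome", "marker_id", "cm", "position", "a1", "a2"],
        dtype={"chromosome": str},
    )
    mmap = MarkerMap(bim[["marker_id", "chromosome", "position"]])
    fam = pd.read_csv(files["fam"], sep=r"\s+", header=None, dtype=str)
    ids = list(fam[1])
    n, m = len(ids), len(mmap)
    raw = np.fromfile(files["bed"], dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ParseError(f"{files['bed']}: bad magic bytes (not SNP-major bed)")
    stride = (n + 3) // 4
    body = raw[3:]
    if body.size != stride * m:
        raise StructuralError(
            f"{files['bed']}: size implies {body.size // max(stride, 1)} markers, "
            f"bim lists {m}"
        )
    codes = np.unpackbits(
        body.reshape(m, stride)[:, :, None], axis=2, bitorder="little"
    ).reshape(m, stride * 8 // 2, 2)
    two_bit = codes[:, :n, 0] + 2 * codes[:, :n, 1]
    # PLINK: 00 hom-a1, 01 missing, 10 het, 11 hom-a2; a1 is the counted allele
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    return GenotypePanel(ids, lut[two_bit].T, mmap)


def _write_bed(panel: GenotypePanel, files: dict[str, Path]) -> None:
    n, m = panel.n_individuals, panel.n_markers
    g = panel.genotypes
    code = np.empty((m, n), dtype=np.uint8)
    gt = g.T
    code[np.isnan(gt)] = 1
    code[gt == 2.0] = 0
    code[gt == 1.0] = 2
    code[gt == 0.0] = 3
    stride = (n + 3) // 4
    padded = np.zeros((m, stride * 4), dtype=np.uint8)
    padded[:, :n] = code
    bits = np.zeros((m, stride * 4, 2), dtype=np.uint8)
    bits[:, :, 0] = padded & 1
    bits[:, :, 1] = padded >> 1
    packed = np.packbits(bits.reshape(m, stride * 8), axis=1, bitorder="little")
    with open(files["bed"], "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    with open(files["fam"], "w") as fh:
        for ind in panel.individual_ids:
            fh.write(f"{ind} {ind} 0 0 0 -9\n")
    with open(files["bim"], "w") as fh:
        t = panel.map.table
        pos = t["position"] if "position" in t.columns else range(1, len(t) + 1)
        for chrom, mid, p in zip(t["chromosome"], t["marker_id"], pos):
            fh.write(f"{chrom} {mid} 0 {int(p)} A B\n")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """TSV with an ``individual_id`` column plus one column per trait."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "individual_id" not in df.columns:
        raise ParseError(f"{path}: missing 'individual_id' column")
    df = df.set_index(df["individual_id"].astype(str)).drop(columns="individual_id")
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    out = table.values.copy()
    out.index.name = "individual_id"
    out.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# Marker filtering and chromosome partition
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    n_input: int
    n_removed_missing: int
    n_removed_maf: int
    n_retained: int
    max_missing: float
    min_maf: float


class EmptyPanelError(ValueError):
    """Every marker failed the quality filters."""


def filter_markers(
    panel: GenotypePanel, max_missing: float = 0.20, min_maf: float = 0.05
) -> tuple[GenotypePanel, FilterReport]:
    """Apply the SNP quality filters with strict inequalities.

    A marker is retained iff its missing fraction is strictly below
    ``max_missing`` and its minor allele frequency strictly above
    ``min_maf`` (both computed on non-missing calls).
    """
    for name, v in (("max_missing", max_missing), ("min_maf", min_maf)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie in (0, 1); got {v}")
    miss = panel.missing_fraction()
    freq = panel.allele_frequencies()
    maf = np.where(np.isnan(freq), 0.0, np.minimum(freq, 1.0 - freq))
    ok_miss = miss < max_missing
    ok_maf = maf > min_maf
    keep = ok_miss & ok_maf
    report = FilterReport(
        n_input=panel.n_markers,
        n_removed_missing=int((~ok_miss).sum()),
        n_removed_maf=int((~ok_maf).sum()),
        n_retained=int(keep.sum()),
        max_missing=max_missing,
        min_maf=min_maf,
    )
    if report.n_retained == 0:
        raise EmptyPanelError(
            "no marker passes the quality filters "
            f"(missing<{max_missing}, MAF>{min_maf})"
        )
    logger.info(
        "filter_markers: kept %d/%d (removed %d for missingness, %d for MAF)",
        report.n_retained, report.n_input,
        report.n_removed_missing, report.n_removed_maf,
    )
    return panel.subset_markers(np.flatnonzero(keep)), report


def chromosome_partition(mmap: MarkerMap) -> dict[str, np.ndarray]:
    """Marker column indices per chromosome, in canonical 1A..7D order.

    The 21 index sets are disjoint and jointly exhaustive; chromosomes with
    no markers get an empty set and a warning.
    """
    chrom = mmap.chromosomes
    out: dict[str, np.ndarray] = {}
    for c in CHROMOSOMES:
        idx = np.flatnonzero(chrom == c)
        if idx.size == 0:
            warnings.warn(f"chromosome {c} carries no markers", stacklevel=2)
        out[c] = idx
    return out
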