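"""Genetic maps, binary RIL genotype matrices and phenotype tables.

Genotypes are coded 0 (first parent, e.g. Bay) and 1 (second parent,
e.g. Sha); missing entries are NaN.  Map positions are genetic distances
in centimorgan (cM) from the start of each chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "GenotypeMatrix",
    "PhenotypeTable",
    "FormatError",
    "MapError",
    "read_genotypes",
    "write_genotypes",
    "arabidopsis_like_map",
]

#: missing-genotype codes accepted on input; always written back as "NA"
MISSING_CODES = {"-", "NA", "", "9"}


class FormatError(ValueError):
    """Malformed genotype/map file content."""


class MapError(ValueError):
    """Inconsistent genetic map (ordering, duplicates)."""


@dataclass(frozen=True)
class GeneticMap:
    """Ordered markers with chromosome assignment and cM position."""

    names: tuple[str, ...]
    chromosomes: tuple[str, ...]
    positions: np.ndarray  # cM, float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if not (len(self.names) == len(self.chromosomes) == pos.size):
            raise MapError("names, chromosomes and positions must align")
        if pos.size == 0:
            raise MapError("empty map")
        if len(set(self.names)) != len(self.names):
            raise FormatError("duplicate marker names")
        if np.any(pos < 0):
            raise MapError("negative cM position")
        # chromosome blocks must be contiguous with strictly increasing positions
        seen: set[str] = set()
        prev_chrom: str | None = None
        for i, chrom in enumerate(self.chromosomes):
            if chrom != prev_chrom:
                if chrom in seen:
                    raise MapError(f"chromosome {chrom!r} is not contiguous")
                seen.add(chrom)
                prev_chrom = chrom
            elif pos[i] <= pos[i - 1]:
                raise MapError(
                    f"positions not strictly increasing on chromosome {chrom!r}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.names)

    @property
    def chromosome_names(self) -> tuple[str, ...]:
        out: list[str] = []
        for c in self.chromosomes:
            if not out or out[-1] != c:
                out.append(c)
        return tuple(out)

    def chromosome_slice(self, chrom: str) -> slice:
        """Column slice covering one chromosome's markers."""
        idx = [i for i, c in enumerate(self.chromosomes) if c == chrom]
        if not idx:
            raise MapError(f"unknown chromosome {chrom!r}")
        return slice(idx[0], idx[-1] + 1)

    def mean_spacing(self) -> float:
        """Mean adjacent-marker distance (cM) over within-chromosome intervals."""
        total = 0.0
        n_int = 0
        for chrom in self.chromosome_names:
            sl = self.chromosome_slice(chrom)
            p = self.positions[sl]
            if p.size > 1:
                total += float(p[-1] - p[0])
                n_int += p.size - 1
        return total / n_int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.names,
                "chromosome": self.chromosomes,
                "position": self.positions,
            }
        )


@dataclass
class GenotypeMatrix:
    """RIL x marker genotypes over {0, 1, NaN}; columns follow map order."""

    values: np.ndarray  # float, NaN = missing
    ril_ids: tuple[str, ...]
    map: GeneticMap

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise FormatError("genotype matrix must be 2-D")
        if vals.shape[0] != len(self.ril_ids):
            raise FormatError("row count does not match ril_ids")
        if vals.shape[1] != self.map.n_markers:
            raise FormatError("column count does not match map")
        obs = vals[~np.isnan(vals)]
        if not np.all(np.isin(obs, (0.0, 1.0))):
            bad = sorted(set(obs[~np.isin(obs, (0.0, 1.0))]))
            raise FormatError(f"non-binary genotype values: {bad}")
        self.values = vals

    @property
    def n_rils(self) -> int:
        return self.values.shape[0]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def drop_rils(self, ids: list[str] | set[str]) -> "GenotypeMatrix":
        """Copy without the given RILs (e.g. parental rows)."""
        keep = [i for i, r in enumerate(self.ril_ids) if r not in set(ids)]
        return GenotypeMatrix(
            self.values[keep], tuple(self.ril_ids[i] for i in keep), self.map
        )


@dataclass
class PhenotypeTable:
    """Long-format trait observations: one row per (RIL, condition)."""

    data: pd.DataFrame
    ril_column: str = "ril"

    def __post_init__(self) -> None:
        if self.ril_column not in self.data.columns:
            raise FormatError(f"missing RIL id column {self.ril_column!r}")

    @property
    def ril_ids(self) -> pd.Series:
        return self.data[self.ril_column]


def _parse_cell(cell: str) -> float:
    cell = cell.strip()
    if cell in MISSING_CODES:
        return np.nan
    try:
        val = float(cell)
    except ValueError:
        raise FormatError(f"unparseable genotype entry {cell!r}") from None
    if val not in (0.0, 1.0):
        raise FormatError(f"genotype entry {cell!r} outside {{0, 1, missing}}")
    return val


def read_genotypes(
    path, dialect: str = "rqtl_csv", map_path=None
) -> tuple[GeneticMap, GenotypeMatrix]:
    """Read a genetic map and genotype matrix.

    ``rqtl_csv``: R/qtl-style layout — row 1 holds an id header plus marker
    names, row 2 the chromosomes, row 3 the cM positions, then one row per
    RIL.  ``plain_csv``: a matrix CSV (id + marker columns) with a separate
    3-column map file (marker, chromosome, position) given as ``map_path``.
    """
    if dialect == "rqtl_csv":
        raw = pd.read_csv(path, header=None, dtype=str, keep_default_na=False)
        if raw.shape[0] < 4:
            raise FormatError("R/qtl CSV needs 3 header rows plus data")
        names = [str(x).strip() for x in raw.iloc[0, 1:]]
        chroms = [str(x).strip() for x in raw.iloc[1, 1:]]
        positions = [float(x) for x in raw.iloc[2, 1:]]
        gmap = GeneticMap(tuple(names), tuple(chroms), np.array(positions))
        body = raw.iloc[3:, :]
        ril_ids = tuple(str(x).strip() for x in body.iloc[:, 0])
        vals = np.array(
            [[_parse_cell(str(c)) for c in row[1:]] for row in body.itertuples(index=False)]
        )
        return gmap, GenotypeMatrix(vals, ril_ids, gmap)
    if dialect == "plain_csv":
        if map_path is None:
            raise FormatError("plain_csv dialect requires map_path")
        mdf = pd.read_csv(map_path, dtype={0: str, 1: str})
        gmap = GeneticMap(
            tuple(mdf.iloc[:, 0].astype(str)),
            tuple(mdf.iloc[:, 1].astype(str)),
            mdf.iloc[:, 2].to_numpy(dtype=float),
        )
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        cols = [c.strip() for c in raw.columns[1:]]
        if cols != list(gmap.names):
            raise FormatError("genotype columns do not match map marker order")
        ril_ids = tuple(str(x).strip() for x in raw.iloc[:, 0])
        vals = np.array(
            [[_parse_cell(str(c)) for c in row[1:]] for row in raw.itertuples(index=False)]
        )
        return gmap, GenotypeMatrix(vals, ril_ids, gmap)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotypes(path, gmap: GeneticMap, geno: GenotypeMatrix) -> None:
    """Write the R/qtl-style CSV produced/consumed by :func:`read_genotypes`."""
    with open(path, "w") as fh:
        fh.write("id," + ",".join(gmap.names) + "\n")
        fh.write("," + ",".join(gmap.chromosomes) + "\n")
        fh.write("," + ",".join(f"{p:g}" for p in gmap.positions) + "\n")
        for rid, row in zip(geno.ril_ids, geno.values):
            cells = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write(f"{rid}," + ",".join(cells) + "\n")


# Published summary of the Bay-0 x Shahdara map: marker counts and
# chromosome lengths.  Interior positions are evenly interpolated because
# the full marker table is not public; this map is a synthetic stand-in
# with the right shape, not the real map.
_ARABIDOPSIS_COUNTS = (18, 11, 12, 11, 17)
_ARABIDOPSIS_LENGTHS = (91.3, 64.6, 72.2, 69.1, 91.2)


def arabidopsis_like_map() -> GeneticMap:
    """Deterministic 5-chromosome, 69-marker map shaped like the Bay x Sha map.

    Each chromosome spans [0, length] cM with its markers evenly spaced,
    first at 0 and last at the chromosome length.
    """
    names: list[str] = []
    chroms: list[str] = []
    positions: list[float] = []
    for ci, (count, length) in enumerate(
        zip(_ARABIDOPSIS_COUNTS, _ARABIDOPSIS_LENGTHS), start=1
    ):
        pos = np.linspace(0.0, length, count)
        for mi, p in enumerate(pos, start=1):
            names.append(f"c{ci}m{mi:02d}")
            chroms.append(str(ci))
            positions.append(float(p))
    return GeneticMap(tuple(names), tuple(chroms), np.array(positions))
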