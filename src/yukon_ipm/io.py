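"""Readers and writers for the observed data streams.

One dataset is a directory of six UTF-8 comma-separated files with header
rows; years and ages are integers, proportions are fractions in [0, 1], and
missing years (or missing genotyping cells) are simply absent rows -- no
sentinel values.  The loader reconstructs the missing-value masks from the
absent rows and validates schemas and simplex constraints with explicit
error messages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dims import ModelDimensions
from .observation import ObservationDataset

__all__ = ["InputBundle", "load_dataset", "write_dataset"]

_SCHEMAS = {
    "juveniles.csv": ["year", "abundance"],
    "adults.csv": ["year", "escapement", "harvest"],
    "adult_agecomp.csv": ["year", "age", "prop_escapement", "prop_harvest"],
    "bycatch.csv": ["year", "total_count", "n_scales"],
    "bycatch_agecomp.csv": ["year", "age", "prop"],
    "gsi.csv": ["year", "age", "n_genotyped", "n_assigned_focal"],
}


@dataclass
class InputBundle:
    """Paths to the six data files (defaulting to one directory)."""

    juveniles: Path
    adults: Path
    adult_agecomp: Path
    bycatch: Path
    bycatch_agecomp: Path
    gsi: Path

    @classmethod
    def from_dir(cls, d: str | Path) -> "InputBundle":
        d = Path(d)
        return cls(*(d / name for name in _SCHEMAS))


def _read(path: Path, name: str) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    df = pd.read_csv(path)
    expected = _SCHEMAS[name]
    if list(df.columns) != expected:
        raise ValueError(
            f"{name}: expected columns {expected}, found {list(df.columns)}")
    return df


def load_dataset(bundle: InputBundle | str | Path,
                 dims: ModelDimensions | None = None) -> ObservationDataset:
    """Load and validate a dataset directory or bundle.

    Model dimensions default to the year span of adults.csv (the run
    reconstruction defines the study window); juvenile years and gsi cells
    absent from their files are masked missing.
    """
    if not isinstance(bundle, InputBundle):
        bundle = InputBundle.from_dir(bundle)
    juv = _read(bundle.juveniles, "juveniles.csv")
    adults = _read(bundle.adults, "adults.csv")
    aac = _read(bundle.adult_agecomp, "adult_agecomp.csv")
    byc = _read(bundle.bycatch, "bycatch.csv")
    bac = _read(bundle.bycatch_agecomp, "bycatch_agecomp.csv")
    gsi = _read(bundle.gsi, "gsi.csv")

    if dims is None:
        y0, y1 = int(adults.year.min()), int(adults.year.max())
        dims = ModelDimensions(first_year=y0, n_years=y1 - y0 + 1)
    Y = dims.n_years

    def yidx(years, name):
        years = np.asarray(years, dtype=int)
        bad = (years < dims.first_year) | (years >= dims.first_year + Y)
        if bad.any():
            raise ValueError(f"{name}: year {years[bad][0]} outside model span")
        return years - dims.first_year

    J = np.full(Y, np.nan)
    J[yidx(juv.year, "juveniles.csv")] = juv.abundance.to_numpy(float)
    J_mask = ~np.isnan(J)

    E = np.full(Y, np.nan)
    C = np.full(Y, np.nan)
    ai = yidx(adults.year, "adults.csv")
    E[ai] = adults.escapement.to_numpy(float)
    C[ai] = adults.harvest.to_numpy(float)
    if np.isnan(E).any():
        missing = dims.first_year + int(np.where(np.isnan(E))[0][0])
        raise ValueError(f"adults.csv: no row for year {missing}")

    qE = np.zeros((Y, 4))
    qC = np.zeros((Y, 4))
    for _, row in aac.iterrows():
        y = yidx([row.year], "adult_agecomp.csv")[0]
        a = int(row.age)
        if not 4 <= a <= 7:
            raise ValueError(f"adult_agecomp.csv: age {a} outside 4-7")
        qE[y, a - 4] = row.prop_escapement
        qC[y, a - 4] = row.prop_harvest

    b_total = np.full(Y, np.nan)
    nB = np.zeros(Y)
    bi = yidx(byc.year, "bycatch.csv")
    b_total[bi] = byc.total_count.to_numpy(float)
    nB[bi] = byc.n_scales.to_numpy(float)

    qB = np.zeros((Y, 4))
    for _, row in bac.iterrows():
        y = yidx([row.year], "bycatch_agecomp.csv")[0]
        a = int(row.age)
        if not 3 <= a <= 6:
            raise ValueError(f"bycatch_agecomp.csv: age {a} outside 3-6")
        qB[y, a - 3] = row.prop

    x = np.zeros((Y, 4))
    n = np.zeros((Y, 4))
    gsi_mask = np.zeros((Y, 4), dtype=bool)
    for _, row in gsi.iterrows():
        y = yidx([row.year], "gsi.csv")[0]
        a = int(row.age)
        if not 3 <= a <= 6:
            raise ValueError(f"gsi.csv: age {a} outside 3-6")
        n[y, a - 3] = row.n_genotyped
        x[y, a - 3] = row.n_assigned_focal
        gsi_mask[y, a - 3] = True

    data = ObservationDataset(dims=dims, J=J, J_mask=J_mask, E=E, C=C, qE=qE,
                              qC=qC, b_total=b_total, qB=qB, nB=nB, x=x, n=n,
                              gsi_mask=gsi_mask)
    data.validate()
    return data


def write_dataset(data: ObservationDataset, outdir: str | Path) -> None:
    """Write a dataset as the six-file CSV bundle (inverse of the loader)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dims = data.dims
    years = np.array(dims.years)

    obs = np.where(data.J_mask)[0]
    pd.DataFrame({"year": years[obs], "abundance": data.J[obs]}).to_csv(
        outdir / "juveniles.csv", index=False)
    pd.DataFrame({"year": years, "escapement": data.E,
                  "harvest": data.C}).to_csv(outdir / "adults.csv",
                                             index=False)
    rows = [(years[y], a, data.qE[y, a - 4], data.qC[y, a - 4])
            for y in range(dims.n_years) for a in range(4, 8)]
    pd.DataFrame(rows, columns=_SCHEMAS["adult_agecomp.csv"]).to_csv(
        outdir / "adult_agecomp.csv", index=False)
    pd.DataFrame({"year": years, "total_count": data.b_total,
                  "n_scales": data.nB.astype(int)}).to_csv(
        outdir / "bycatch.csv", index=False)
    rows = [(years[y], a, data.qB[y, a - 3])
            for y in range(dims.n_years) for a in range(3, 7)]
    pd.DataFrame(rows, columns=_SCHEMAS["bycatch_agecomp.csv"]).to_csv(
        outdir / "bycatch_agecomp.csv", index=False)
    rows = [(years[y], a, int(data.n[y, a - 3]), int(data.x[y, a - 3]))
            for y in range(dims.n_years) for a in range(3, 7)
            if data.gsi_mask[y, a - 3]]
    pd.DataFrame(rows, columns=_SCHEMAS["gsi.csv"]).to_csv(
        outdir / "gsi.csv", index=False)
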