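"""File formats, validation, and run manifests.

All tables are UTF-8 comma-separated files with a mandatory header row;
coordinates are Cartesian meters in a local plot frame.  Genotypes use a
GenAlEx-dialect CSV: two header rows (counts; then locus names, one name
per locus followed by a blank column), then one row per individual with
id, population, and two allele-size columns per locus, 0 marking a
missing allele.  Round-trips through these readers and writers are
bit-exact on the values.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Point, Polygon

from .genotypes import ErrorRates, GenotypeTable
from .parentage import Dataset, McmcConfig, PriorSpec

__all__ = [
    "read_adults",
    "read_seedlings",
    "read_polygon",
    "write_polygon",
    "read_error_rates",
    "write_error_rates",
    "read_genalex",
    "write_genalex",
    "read_dataset",
    "write_dataset",
    "read_run_config",
    "RunManifest",
]

ADULT_COLUMNS = ["id", "x", "y", "species", "dbh_cm", "fecundity_mean", "fecundity_sd"]
SEEDLING_COLUMNS = ["id", "x", "y"]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _check_unique(df: pd.DataFrame, path) -> None:
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate id(s) {sorted(set(dup))[:5]}")


def read_adults(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["id", "x", "y", "fecundity_mean", "fecundity_sd"], path)
    _check_unique(df, path)
    df["id"] = df["id"].astype(str)
    for i, row in df.iterrows():
        if row["fecundity_mean"] < 0 or row["fecundity_sd"] < 0:
            raise ValueError(f"{path}: row {i} (id {row['id']}): negative fecundity field")
    return df


def read_seedlings(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SEEDLING_COLUMNS, path)
    _check_unique(df, path)
    df["id"] = df["id"].astype(str)
    return df


def read_polygon(path) -> Polygon:
    """Plot boundary from a CSV of x,y vertices (closed or open ring)."""
    df = pd.read_csv(path)
    _require_columns(df, ["x", "y"], path)
    pts = df[["x", "y"]].to_numpy(float)
    if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        raise ValueError(f"{path}: a polygon needs at least 3 distinct vertices")
    poly = Polygon(pts)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError(f"{path}: polygon is invalid or degenerate")
    return poly


def write_polygon(polygon: Polygon, path) -> None:
    xs, ys = polygon.exterior.xy
    pd.DataFrame({"x": xs, "y": ys}).to_csv(path, index=False)


def read_error_rates(path, loci) -> ErrorRates:
    df = pd.read_csv(path)
    _require_columns(df, ["locus", "e1", "e2"], path)
    df = df.set_index("locus")
    missing = [l for l in loci if l not in df.index]
    if missing:
        raise ValueError(f"{path}: no error rates for locus/loci {missing}")
    return ErrorRates(
        df.loc[list(loci), "e1"].to_numpy(float), df.loc[list(loci), "e2"].to_numpy(float)
    )


def write_error_rates(err: ErrorRates, loci, path) -> None:
    pd.DataFrame({"locus": list(loci), "e1": err.e1, "e2": err.e2}).to_csv(path, index=False)


def read_genalex(path, motif=2) -> GenotypeTable:
    """GenAlEx-dialect genotype CSV -> GenotypeTable.

    Row 1: n_loci, n_individuals, n_populations.  Row 2: id, pop, then
    each locus name followed by a blank column.  Data rows: id,
    population, and two allele sizes per locus (0 = missing).
    ``motif`` is an int or per-locus sequence of repeat lengths.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        header1 = fh.readline().strip().split(",")
        header2 = fh.readline().strip().split(",")
    try:
        n_loci = int(header1[0])
        n_ind = int(header1[1])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: first header row must start with n_loci,n_individuals") from exc
    loci = [header2[2 + 2 * l] for l in range(n_loci)]
    if any(not name for name in loci):
        raise ValueError(f"{path}: second header row must name every locus")
    df = pd.read_csv(path, skiprows=2, header=None)
    if df.shape[1] < 2 + 2 * n_loci:
        raise ValueError(f"{path}: expected {2 + 2 * n_loci} columns, found {df.shape[1]}")
    if len(df) != n_ind:
        raise ValueError(f"{path}: header declares {n_ind} individuals, file has {len(df)}")
    ids = df.iloc[:, 0].astype(str).tolist()
    calls = df.iloc[:, 2 : 2 + 2 * n_loci].to_numpy(np.int64).reshape(len(df), n_loci, 2)
    motif_arr = np.full(n_loci, motif) if np.isscalar(motif) else np.asarray(motif)
    return GenotypeTable(ids, loci, calls, motif_arr)


def write_genalex(table: GenotypeTable, path, population: str = "pop1") -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        n_cols = 2 + 2 * table.n_loci
        row1 = [str(table.n_loci), str(table.n_individuals), "1"] + [""] * (n_cols - 3)
        fh.write(",".join(row1) + "\n")
        row2 = ["id", "pop"]
        for name in table.loci:
            row2 += [name, ""]
        fh.write(",".join(row2) + "\n")
        for i, sid in enumerate(table.ids):
            cells = [str(sid), population]
            for l in range(table.n_loci):
                cells += [str(int(table.calls[i, l, 0])), str(int(table.calls[i, l, 1]))]
            fh.write(",".join(cells) + "\n")


def read_dataset(
    adults_path,
    seedlings_path,
    genotypes_path,
    polygon_path,
    error_rates_path,
    motif=2,
) -> Dataset:
    """Read and cross-validate a full dataset.

    Checks: every adult and seedling id has a genotype row; ids unique
    across tables; all coordinates inside the plot polygon; per-locus
    error rates present.  Reports per-locus missingness at INFO level via
    the returned dataset's genotype table.
    """
    adults = read_adults(adults_path)
    seedlings = read_seedlings(seedlings_path)
    genotypes = read_genalex(genotypes_path, motif=motif)
    polygon = read_polygon(polygon_path)
    err = read_error_rates(error_rates_path, genotypes.loci)
    for label, df, pathname in (
        ("adult", adults, adults_path),
        ("seedling", seedlings, seedlings_path),
    ):
        for _, row in df.iterrows():
            if row["id"] not in genotypes._index:
                raise ValueError(
                    f"{pathname}: {label} {row['id']} has no row in {genotypes_path}"
                )
            if not polygon.buffer(1e-6).contains(Point(row["x"], row["y"])):
                raise ValueError(
                    f"{pathname}: {label} {row['id']} at "
                    f"({row['x']:.2f}, {row['y']:.2f}) lies outside the plot polygon"
                )
    return Dataset(adults, seedlings, genotypes, polygon, err)


def write_dataset(data: dict, out_dir) -> dict:
    """Write a simulate_dataset() result as the CSV bundle read_dataset reads.

    Returns the path dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "adults": out / "adults.csv",
        "seedlings": out / "seedlings.csv",
        "genotypes": out / "genotypes.csv",
        "polygon": out / "polygon.csv",
        "error_rates": out / "error_rates.csv",
    }
    data["adults"].to_csv(paths["adults"], index=False)
    data["seedlings"].to_csv(paths["seedlings"], index=False)
    write_genalex(data["genotypes"], paths["genotypes"])
    write_polygon(data["polygon"], paths["polygon"])
    write_error_rates(data["error_rates"], data["genotypes"].loci, paths["error_rates"])
    if "pedigree" in data:
        paths["true_pedigree"] = out / "true_pedigree.csv"
        data["pedigree"].to_csv(paths["true_pedigree"], index=False)
    return paths


def read_run_config(path) -> tuple:
    """YAML run configuration -> (McmcConfig, seed_prior, pollen_prior).

    Recognized keys: n_steps, burn_in, thin, prop_scale_s, prop_scale_p,
    adapt, grid_spacing, grid_cutoff, species_mode, seed, and nested
    ``seed_prior`` / ``pollen_prior`` blocks (mean, sd, min_distance,
    max_distance).  Missing keys fall back to package defaults.
    """
    from .parentage import DEFAULT_POLLEN_PRIOR, DEFAULT_SEED_PRIOR

    raw = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    sp = raw.pop("seed_prior", None)
    pp = raw.pop("pollen_prior", None)
    known = {f.name for f in dataclasses.fields(McmcConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown run-config key(s): {sorted(unknown)}")
    cfg = McmcConfig(**raw)
    seed_prior = PriorSpec(**sp) if sp else DEFAULT_SEED_PRIOR
    pollen_prior = PriorSpec(**pp) if pp else DEFAULT_POLLEN_PRIOR
    return cfg, seed_prior, pollen_prior


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every pipeline output."""

    command: str
    seed: int | None
    config: dict
    inputs: dict
    version: str = ""
    timestamp: str = ""

    def __post_init__(self):
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()

    @classmethod
    def collect(cls, command, seed, config, input_paths) -> "RunManifest":
        inputs = {str(p): _sha256(p) for p in input_paths if p and Path(p).exists()}
        cfg = {
            k: (v if isinstance(v, (int, float, str, bool, type(None))) else str(v))
            for k, v in (config or {}).items()
        }
        return cls(command=command, seed=seed, config=cfg, inputs=inputs)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
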