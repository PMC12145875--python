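"""Reading, writing and cross-validation of the four tabular inputs.

All files are tab-separated UTF-8 with ``#`` comment lines and no quoting,
matching the layout of QIIME2-exported feature tables without requiring the
BIOM binary format.  The four table kinds are

* the ASV count table (samples x ASVs, non-negative integers),
* the taxonomy table (one PR2-style eight-rank lineage per ASV),
* the sample metadata table (basin, sample type, depth, deployment,
  trap platform, particle class),
* the POC flux table (flux and its uncertainty per bulk trap sample).

Reading always returns validated, deterministically ordered pandas objects:
sample and ASV identifiers are unique and sorted lexicographically, counts
are ``int64`` with no missing values.  Validation failures raise
:class:`ValueError` naming the offending record.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: PR2-convention lineage ranks, shallow to deep.
RANKS = ("domain", "supergroup", "division", "class", "order", "family",
         "genus", "species")

BASINS = ("NP", "NA")
SAMPLE_TYPES = ("surface", "bulk_trap", "particle")
PARTICLE_CLASSES = ("salp_pellet", "aggregate_dense_detritus",
                    "long_loose_pellet", "short_pellet", "none")
TROPHIC_LABELS = ("photosynthetic", "heterotrophic", "parasitic", "unknown")

_SAMPLE_COLUMNS = ("basin", "sample_type", "depth_m", "deployment",
                   "platform", "particle_class", "light_level")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0,
                         dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: file contains no table") from exc
    if df.shape[0] == 0:
        raise ValueError(f"{path}: table has no data rows")
    return df


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


def validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise an ASV count table (samples x ASVs).

    Returns an ``int64`` copy with rows and columns sorted by identifier.
    Raises :class:`ValueError` on duplicate identifiers, missing values,
    negative or non-integer counts, or an empty table.
    """
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError("empty ASV table")
    _check_unique(df.index, "sample")
    _check_unique(df.columns, "ASV")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric count at sample {df.index[r]!r}, ASV {df.columns[c]!r}")
    arr = numeric.to_numpy(dtype=float)
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative count at sample {df.index[r]!r}, ASV {df.columns[c]!r}")
    if (arr != np.floor(arr)).any():
        r, c = np.argwhere(arr != np.floor(arr))[0]
        raise ValueError(
            f"non-integer count at sample {df.index[r]!r}, ASV {df.columns[c]!r}")
    out = pd.DataFrame(arr.astype(np.int64), index=df.index.astype(str),
                       columns=df.columns.astype(str))
    out.index.name = "sample_id"
    out.columns.name = None
    return out.sort_index(axis=0).sort_index(axis=1)


def read_asv_table(path: str | Path, orientation: str = "samples") -> pd.DataFrame:
    """Read an ASV count table from a TSV file.

    Parameters
    ----------
    path
        Tab-separated file; first column holds the row identifiers.
    orientation
        ``"samples"`` if rows are samples (the default), ``"asvs"`` if rows
        are ASVs (the table is transposed to samples x ASVs on read).
    """
    if orientation not in ("samples", "asvs"):
        raise ValueError(f"orientation must be 'samples' or 'asvs', got {orientation!r}")
    # pandas silently renames duplicated header fields, so check them raw
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                what = "ASV" if orientation == "samples" else "sample"
                _check_unique(line.rstrip("\n").split("\t")[1:], what)
                break
    df = _read_tsv(path)
    if orientation == "asvs":
        df = df.T
    return validate_counts(df)


def write_asv_table(table: pd.DataFrame, path: str | Path,
                    orientation: str = "samples") -> None:
    """Write an ASV count table as TSV (inverse of :func:`read_asv_table`)."""
    out = table if orientation == "samples" else table.T
    label = "sample_id" if orientation == "samples" else "asv_id"
    out.to_csv(path, sep="\t", index_label=label)


def split_lineage(lineage: str, asv_id: str = "?") -> list[str]:
    """Split a semicolon-delimited lineage into exactly eight rank slots.

    Shorter lineages are right-padded with empty strings; more than eight
    named ranks is an error.
    """
    parts = [p.strip() for p in lineage.split(";")]
    while parts and parts[-1] == "":
        parts.pop()
    if len(parts) > len(RANKS):
        raise ValueError(
            f"ASV {asv_id!r}: lineage has {len(parts)} ranks, at most {len(RANKS)} allowed")
    return parts + [""] * (len(RANKS) - len(parts))


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a taxonomy table: one row per ASV, a ``lineage`` column with a
    semicolon-delimited PR2-style lineage.

    Returns a DataFrame indexed by ``asv_id`` with one column per rank in
    :data:`RANKS`.  Classification columns (``trophic``, ``pigment_group``,
    ``genus_bin``) are carried through if present in the file.
    """
    df = _read_tsv(path)
    if df.index.name is None or df.index.name == "":
        df.index.name = "asv_id"
    if "lineage" in df.columns:
        lineage = df["lineage"]
    else:
        lineage = df.iloc[:, 0]
    _check_unique(df.index, "ASV")
    if any(i == "" for i in df.index):
        raise ValueError("taxonomy row with missing asv_id")
    rows = {asv: split_lineage(lin, asv) for asv, lin in lineage.items()}
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    out.index.name = "asv_id"
    for extra in ("trophic", "pigment_group", "genus_bin"):
        if extra in df.columns:
            out[extra] = df[extra]
    return out.sort_index()


def write_taxonomy(taxonomy: pd.DataFrame, path: str | Path) -> None:
    """Write a taxonomy table as TSV (inverse of :func:`read_taxonomy`)."""
    out = pd.DataFrame(index=taxonomy.index)
    out["lineage"] = [";".join(row) for row in
                      taxonomy[list(RANKS)].to_numpy()]
    for extra in ("trophic", "pigment_group", "genus_bin"):
        if extra in taxonomy.columns:
            out[extra] = taxonomy[extra]
    out.to_csv(path, sep="\t", index_label="asv_id")


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample metadata table."""
    df = _read_tsv(path)
    _check_unique(df.index, "sample")
    missing = [c for c in _SAMPLE_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"sample table is missing columns: {missing}")
    out = pd.DataFrame(index=df.index.astype(str))
    out.index.name = "sample_id"
    out["basin"] = df["basin"]
    out["sample_type"] = df["sample_type"]
    out["depth_m"] = pd.to_numeric(df["depth_m"], errors="coerce")
    out["deployment"] = pd.to_numeric(df["deployment"], errors="coerce")
    out["platform"] = df["platform"]
    out["particle_class"] = df["particle_class"]
    out["light_level"] = df["light_level"] if "light_level" in df.columns else ""
    return validate_samples(out)


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Enforce the sample-record invariants; returns a sorted copy."""
    out = samples.copy()
    for sid, row in out.iterrows():
        if row["basin"] not in BASINS:
            raise ValueError(f"sample {sid!r}: unknown basin {row['basin']!r}")
        if row["sample_type"] not in SAMPLE_TYPES:
            raise ValueError(f"sample {sid!r}: unknown sample_type {row['sample_type']!r}")
        if row["particle_class"] not in PARTICLE_CLASSES:
            raise ValueError(f"sample {sid!r}: unknown particle_class {row['particle_class']!r}")
        if not np.isfinite(row["depth_m"]) or row["depth_m"] < 0:
            raise ValueError(f"sample {sid!r}: invalid depth_m {row['depth_m']!r}")
        dep = row["deployment"]
        if not np.isfinite(dep) or dep != int(dep):
            raise ValueError(f"sample {sid!r}: invalid deployment {dep!r}")
        if row["particle_class"] != "none" and row["sample_type"] != "particle":
            raise ValueError(
                f"sample {sid!r}: particle_class set on non-particle sample")
        if row["sample_type"] in ("bulk_trap", "particle") and row["platform"] == "":
            raise ValueError(f"sample {sid!r}: trap sample without platform")
    out["deployment"] = out["deployment"].astype(int)
    out["depth_m"] = out["depth_m"].astype(float)
    return out.sort_index()


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_flux(path: str | Path) -> pd.DataFrame:
    """Read the POC flux table (``poc_flux`` and ``flux_uncertainty``,
    mmol C m^-2 day^-1, one row per bulk trap sample)."""
    df = _read_tsv(path)
    _check_unique(df.index, "sample")
    for col in ("poc_flux", "flux_uncertainty"):
        if col not in df.columns:
            raise ValueError(f"flux table is missing column {col!r}")
    out = pd.DataFrame(index=df.index.astype(str))
    out.index.name = "sample_id"
    out["poc_flux"] = pd.to_numeric(df["poc_flux"], errors="coerce")
    out["flux_uncertainty"] = pd.to_numeric(df["flux_uncertainty"], errors="coerce")
    for sid, row in out.iterrows():
        if not np.isfinite(row["poc_flux"]) or row["poc_flux"] < 0:
            raise ValueError(f"flux record {sid!r}: invalid poc_flux")
        if not np.isfinite(row["flux_uncertainty"]) or row["flux_uncertainty"] < 0:
            raise ValueError(f"flux record {sid!r}: invalid flux_uncertainty")
    return out.sort_index()


def write_flux(flux: pd.DataFrame, path: str | Path) -> None:
    flux.to_csv(path, sep="\t", index_label="sample_id")


@dataclasses.dataclass
class Dataset:
    """A cross-validated bundle of the four tables.

    ``counts`` is samples x ASVs; ``taxonomy`` is indexed by ASV id;
    ``samples`` by sample id; ``flux`` by bulk-trap sample id.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    samples: pd.DataFrame
    flux: pd.DataFrame

    def copy(self) -> "Dataset":
        return Dataset(self.counts.copy(), self.taxonomy.copy(),
                       self.samples.copy(), self.flux.copy())


def join_and_validate(counts: pd.DataFrame, taxonomy: pd.DataFrame,
                      samples: pd.DataFrame, flux: pd.DataFrame,
                      strict: bool = True) -> Dataset:
    """Cross-reference the four tables into a validated :class:`Dataset`.

    Every ASV in ``counts`` must have a taxonomy row and every sample a
    metadata row.  Under ``strict`` (the default) a missing taxonomy row is
    a hard error; otherwise the offending ASV columns are dropped with a
    logged warning.  Flux records must resolve to bulk-trap samples.
    """
    counts = validate_counts(counts)
    missing_tax = sorted(set(counts.columns) - set(taxonomy.index))
    if missing_tax:
        if strict:
            raise ValueError(
                f"{len(missing_tax)} ASV(s) without taxonomy: {missing_tax[:10]}")
        log.warning("dropping %d ASV(s) without taxonomy: %s",
                    len(missing_tax), missing_tax[:10])
        counts = counts.drop(columns=missing_tax)
        if counts.shape[1] == 0:
            raise ValueError("no ASVs left after dropping those without taxonomy")
    missing_samp = sorted(set(counts.index) - set(samples.index))
    if missing_samp:
        raise ValueError(
            f"{len(missing_samp)} sample(s) without metadata: {missing_samp[:10]}")
    samples = validate_samples(samples.loc[sorted(counts.index)])
    bad_flux = sorted(set(flux.index) - set(samples.index))
    if bad_flux:
        raise ValueError(f"flux record(s) for unknown sample(s): {bad_flux[:10]}")
    non_bulk = sorted(
        sid for sid in flux.index if samples.loc[sid, "sample_type"] != "bulk_trap")
    if non_bulk:
        raise ValueError(
            f"flux record(s) for non-bulk sample(s): {non_bulk[:10]}")
    taxonomy = taxonomy.loc[sorted(counts.columns)].copy()
    return Dataset(counts=counts, taxonomy=taxonomy, samples=samples,
                   flux=flux.sort_index())


def read_dataset(directory: str | Path, strict: bool = True) -> Dataset:
    """Read ``asv_table.tsv``, ``taxonomy.tsv``, ``samples.tsv`` and
    ``flux.tsv`` from a directory and join them."""
    d = Path(directory)
    return join_and_validate(
        read_asv_table(d / "asv_table.tsv"),
        read_taxonomy(d / "taxonomy.tsv"),
        read_samples(d / "samples.tsv"),
        read_flux(d / "flux.tsv"),
        strict=strict,
    )


def write_dataset(dataset: Dataset, directory: str | Path) -> None:
    """Write the four tables of a :class:`Dataset` into a directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_asv_table(dataset.counts, d / "asv_table.tsv")
    write_taxonomy(dataset.taxonomy, d / "taxonomy.tsv")
    write_samples(dataset.samples, d / "samples.tsv")
    write_flux(dataset.flux, d / "flux.tsv")
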