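"""Reading, validation and writing of the four input artifacts.

The input bundle of the analysis is: an ASV x sample count table (TSV),
sample metadata with ISO dates and environmental parameters (CSV), a
taxonomy table (TSV, class/order/family/genus per ASV) and the ASV
sequences (FASTA).  :class:`Dataset` holds the validated bundle; every
analysis stage consumes a Dataset rather than raw files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TAXONOMY_RANKS = ("class", "order", "family", "genus")

#: environmental parameters of the study design, in canonical column order
ENV_PARAMETERS = (
    "temperature",
    "chlorophyll",
    "no3",
    "no2",
    "nh4",
    "po4",
    "sio2",
    "pnf",
    "hnf",
)


class DatasetError(ValueError):
    """Raised when an input bundle violates the Dataset contract."""


@dataclass
class Dataset:
    """Validated bundle of counts, dates, environment, taxonomy, sequences.

    Attributes
    ----------
    counts
        Non-negative integer DataFrame, rows = ASV ids, columns = sample ids.
    dates
        Per-sample calendar dates (strictly increasing), aligned to the
        count columns.
    env
        Samples x parameters real table; missing values allowed (NaN).
    taxonomy
        Per-ASV rank labels (class, order, family, genus); a label may be
        "unassigned".
    sequences
        Per-ASV nucleotide string.
    """

    counts: pd.DataFrame
    dates: pd.DatetimeIndex
    env: pd.DataFrame
    taxonomy: pd.DataFrame
    sequences: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        counts = self.counts
        vals = counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals), atol=0):
                bad = np.argwhere(vals != np.round(vals))
                r, c = bad[0]
                raise DatasetError(
                    f"counts must be integers; found {vals[r, c]!r} at "
                    f"ASV {counts.index[r]!r}, sample {counts.columns[c]!r}"
                )
            self.counts = counts = counts.astype(np.int64)
            vals = counts.to_numpy()
        if (vals < 0).any():
            raise DatasetError("counts must be non-negative")
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate ASV ids in counts: {dups}")
        if counts.columns.duplicated().any():
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate sample ids in counts: {dups}")

        n = counts.shape[1]
        if len(self.dates) != n:
            raise DatasetError(
                f"{len(self.dates)} dates for {n} samples"
            )
        if not isinstance(self.dates, pd.DatetimeIndex):
            self.dates = pd.DatetimeIndex(self.dates)
        d = self.dates.to_numpy()
        if len(d) > 1 and not (np.diff(d) > np.timedelta64(0, "s")).all():
            raise DatasetError("sample dates must be strictly increasing")

        _check_sample_ids(counts.columns, self.env.index, "env metadata")
        self.env = self.env.loc[counts.columns]

        _check_asv_ids(counts.index, self.taxonomy.index, "taxonomy")
        missing_rank = [r for r in TAXONOMY_RANKS if r not in self.taxonomy.columns]
        if missing_rank:
            raise DatasetError(f"taxonomy lacks rank columns: {missing_rank}")
        self.taxonomy = self.taxonomy.loc[counts.index]

        _check_asv_ids(counts.index, pd.Index(self.sequences.keys()), "sequences")

        # canonical axis names so written and re-read bundles compare equal
        self.counts = self.counts.rename_axis(index="asv", columns=None)
        self.env = self.env.rename_axis(index="sample", columns=None)
        self.taxonomy = self.taxonomy.rename_axis(index="asv", columns=None)

    # -- convenience ----------------------------------------------------

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def times_days(self) -> np.ndarray:
        """Real-valued time axis: days since the first sample."""
        d = self.dates.to_numpy()
        return (d - d[0]) / np.timedelta64(1, "D")

    def subset_asvs(self, asv_ids) -> "Dataset":
        """A new Dataset restricted to the given ASV ids (counts order kept)."""
        keep = [a for a in self.counts.index if a in set(asv_ids)]
        return Dataset(
            counts=self.counts.loc[keep].copy(),
            dates=self.dates,
            env=self.env.copy(),
            taxonomy=self.taxonomy.loc[keep].copy(),
            sequences={a: self.sequences[a] for a in keep},
        )


def _check_sample_ids(counts_ids: pd.Index, other_ids: pd.Index, what: str) -> None:
    missing = counts_ids.difference(other_ids)
    extra = other_ids.difference(counts_ids)
    if len(missing):
        raise DatasetError(
            f"samples present in counts but absent from {what}: {missing.tolist()}"
        )
    if len(extra):
        raise DatasetError(
            f"samples present in {what} but absent from counts: {extra.tolist()}"
        )


def _check_asv_ids(counts_ids: pd.Index, other_ids: pd.Index, what: str) -> None:
    missing = counts_ids.difference(other_ids)
    extra = other_ids.difference(counts_ids)
    if len(missing):
        raise DatasetError(
            f"ASVs present in counts but absent from {what}: {missing.tolist()}"
        )
    if len(extra):
        raise DatasetError(
            f"ASVs present in {what} but absent from counts: {extra.tolist()}"
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

DATE_COLUMN = "date"


def read_dataset(
    counts_path: str | Path,
    metadata_path: str | Path,
    taxonomy_path: str | Path,
    fasta_path: str | Path,
) -> Dataset:
    """Read and validate the four input artifacts into a Dataset.

    Counts are a TSV with ASV ids in the first column and sample ids as
    header; metadata a CSV with a sample-id first column, an ISO-8601
    ``date`` column and environmental columns; taxonomy a TSV with
    class/order/family/genus; sequences a FASTA whose ids match the count
    rows.  Any id mismatch raises :class:`DatasetError` naming the ids —
    nothing is silently dropped.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)

    meta = pd.read_csv(metadata_path, index_col=0)
    meta.index = meta.index.astype(str)
    if DATE_COLUMN not in meta.columns:
        raise DatasetError(f"metadata lacks a {DATE_COLUMN!r} column")
    try:
        dates_by_sample = pd.to_datetime(meta[DATE_COLUMN], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise DatasetError(f"unparseable dates in metadata: {exc}") from exc

    _check_sample_ids(counts.columns, meta.index, "metadata")
    # order samples by counts columns; counts columns themselves must be in
    # date order (validated by Dataset)
    env = meta.drop(columns=[DATE_COLUMN]).loc[counts.columns].astype(float)
    dates = pd.DatetimeIndex(dates_by_sample.loc[counts.columns])

    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
    taxonomy.index = taxonomy.index.astype(str)

    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in sequences:
            raise DatasetError(f"duplicate sequence id {rec.id!r} in FASTA")
        sequences[rec.id] = str(rec.seq).upper()

    return Dataset(counts=counts, dates=dates, env=env,
                   taxonomy=taxonomy, sequences=sequences)


def write_dataset(dataset: Dataset, outdir: str | Path) -> dict[str, Path]:
    """Write a Dataset to counts.tsv / metadata.csv / taxonomy.tsv / seqs.fasta."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.csv",
        "taxonomy": outdir / "taxonomy.tsv",
        "fasta": outdir / "sequences.fasta",
    }
    dataset.counts.to_csv(paths["counts"], sep="\t")
    meta = dataset.env.copy()
    meta.insert(0, DATE_COLUMN, dataset.dates.strftime("%Y-%m-%d"))
    meta.to_csv(paths["metadata"])
    dataset.taxonomy.to_csv(paths["taxonomy"], sep="\t")
    records = [
        SeqRecord(Seq(seq), id=asv, description="")
        for asv, seq in dataset.sequences.items()
    ]
    SeqIO.write(records, str(paths["fasta"]), "fasta")
    return paths


def write_table(records: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as TSV with stable column order.

    Floats use 6 significant digits, so ``read_table(write_table(x))``
    round-trips within 1e-6 relative tolerance.  An empty DataFrame writes
    a header-only file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV result table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
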