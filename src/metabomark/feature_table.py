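"""The central data container: an aligned, binned GC-MS feature table.

A :class:`FeatureTable` holds a samples x bins abundance matrix together with
per-sample metadata (species, exposure concentration in ug/L, tube id) and
per-bin metadata (bin id, retention time in seconds, quantifier m/z).  Bin ids
follow the XCMS-style export convention ``RT<seconds>_MZ<m/z>`` so that
synthetic tables are drop-in compatible with real aligned exports; retention
time and m/z are parsed from the id when it conforms to that pattern.

On disk the table is a delimited text file (TSV by default, CSV accepted)
with samples as rows.  Four reserved metadata columns precede the bin
columns: ``sample_id``, ``species``, ``concentration_ug_per_L``, ``tube_id``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

META_COLUMNS = ["sample_id", "species", "concentration_ug_per_L", "tube_id"]

_BIN_ID_RE = re.compile(r"^RT(?P<rt>[0-9]+(?:\.[0-9]+)?)_MZ(?P<mz>[0-9]+(?:\.[0-9]+)?)$")


def parse_bin_id(bin_id: str) -> tuple[float, float] | None:
    """Return (retention_time_s, mz) parsed from an ``RT<s>_MZ<m/z>`` id, or None."""
    m = _BIN_ID_RE.match(bin_id)
    if m is None:
        return None
    return float(m.group("rt")), float(m.group("mz"))


@dataclass
class FeatureTable:
    """Samples x bins abundance matrix with sample and bin metadata.

    Parameters
    ----------
    abundances
        Non-negative matrix of shape (n_samples, n_bins) as a DataFrame whose
        index holds sample ids and whose columns hold bin ids.
    sample_meta
        DataFrame indexed by sample id with columns ``species``,
        ``concentration_ug_per_L`` and ``tube_id``.
    bin_meta
        DataFrame indexed by bin id with columns ``retention_time_s`` and
        ``mz`` (NaN where the bin id does not encode them).  Built from the
        bin ids when omitted.
    """

    abundances: pd.DataFrame
    sample_meta: pd.DataFrame
    bin_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.bin_meta is None:
            self.bin_meta = bin_meta_from_ids(self.abundances.columns)
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        if not self.abundances.index.equals(self.sample_meta.index):
            raise DataError("abundance matrix rows and sample_meta index differ")
        if not self.abundances.columns.equals(self.bin_meta.index):
            raise DataError("abundance matrix columns and bin_meta index differ")
        if self.abundances.columns.has_duplicates:
            raise DataError("bin ids are not unique")
        if self.abundances.index.has_duplicates:
            raise DataError("sample ids are not unique")
        missing = [c for c in ("species", "concentration_ug_per_L", "tube_id")
                   if c not in self.sample_meta.columns]
        if missing:
            raise DataError(f"sample_meta is missing required columns: {missing}")
        if self.sample_meta[["species", "concentration_ug_per_L", "tube_id"]].isna().any().any():
            raise DataError("sample_meta contains missing values")

    @property
    def n_samples(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_bins(self) -> int:
        return self.abundances.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundances.index)

    @property
    def bin_ids(self) -> list[str]:
        return list(self.abundances.columns)

    def values(self) -> np.ndarray:
        return self.abundances.to_numpy()

    # -- subsetting --------------------------------------------------------
    def select_bins(self, bin_ids: list[str]) -> "FeatureTable":
        missing = set(bin_ids) - set(self.abundances.columns)
        if missing:
            raise DataError(f"unknown bin ids: {sorted(missing)[:5]}")
        return FeatureTable(self.abundances.loc[:, list(bin_ids)],
                            self.sample_meta,
                            self.bin_meta.loc[list(bin_ids)])

    def select_samples(self, sample_ids: list[str]) -> "FeatureTable":
        missing = set(sample_ids) - set(self.abundances.index)
        if missing:
            raise DataError(f"unknown sample ids: {sorted(missing)[:5]}")
        return FeatureTable(self.abundances.loc[list(sample_ids)],
                            self.sample_meta.loc[list(sample_ids)],
                            self.bin_meta)

    def select_concentrations(self, levels: list[float]) -> "FeatureTable":
        conc = self.sample_meta["concentration_ug_per_L"].astype(float)
        present = set(conc)
        absent = [lv for lv in levels if float(lv) not in present]
        if absent:
            raise DataError(f"concentration levels not present in table: {absent}")
        keep = conc.isin([float(lv) for lv in levels])
        return self.select_samples(list(self.abundances.index[keep]))

    def drop_samples(self, sample_ids: list[str]) -> "FeatureTable":
        keep = [s for s in self.abundances.index if s not in set(sample_ids)]
        return self.select_samples(keep)

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path, sep: str = "\t") -> None:
        out = pd.concat([self.sample_meta[["species", "concentration_ug_per_L", "tube_id"]],
                         self.abundances], axis=1)
        out.index.name = "sample_id"
        out.to_csv(path, sep=sep)

    @classmethod
    def from_tsv(cls, path, sep: str | None = None) -> "FeatureTable":
        if sep is None:
            sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, index_col="sample_id")
        missing = [c for c in ("species", "concentration_ug_per_L", "tube_id")
                   if c not in df.columns]
        if missing:
            raise DataError(f"feature table file lacks metadata columns: {missing}")
        meta = df[["species", "concentration_ug_per_L", "tube_id"]].copy()
        meta["concentration_ug_per_L"] = meta["concentration_ug_per_L"].astype(float)
        abund = df.drop(columns=["species", "concentration_ug_per_L", "tube_id"]).astype(float)
        return cls(abund, meta)


def bin_meta_from_ids(bin_ids) -> pd.DataFrame:
    rows = []
    for b in bin_ids:
        parsed = parse_bin_id(str(b))
        rt, mz = parsed if parsed is not None else (np.nan, np.nan)
        rows.append((rt, mz))
    return pd.DataFrame(rows, index=pd.Index(bin_ids), columns=["retention_time_s", "mz"])
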