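"""Hairpin x sample count matrices and their on-disk TSV form.

The raw result of a pooled screen is an integer matrix of read counts, one
row per library hairpin (zero rows retained — a hairpin that disappeared
is data, not a missing value) and one column per sequenced sample, plus a
sample sheet assigning each sample a condition label and replicate index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library import LibraryDefinition

__all__ = ["CountMatrix", "read_counts", "write_counts", "read_samples", "write_samples"]


@dataclass
class CountMatrix:
    """Non-negative integer hairpin x sample counts keyed to a library.

    ``counts`` is indexed by the library's hairpin IDs (in library order)
    with one column per sample; ``samples`` is indexed by sample ID with
    ``condition`` and ``replicate`` columns.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    library: LibraryDefinition

    def __post_init__(self) -> None:
        lib_ids = list(self.library.hairpin_ids)
        if set(self.counts.index) != set(lib_ids):
            extra = set(self.counts.index) - set(lib_ids)
            missing = set(lib_ids) - set(self.counts.index)
            if extra:
                raise ValueError(f"count rows not in library: {sorted(extra)[:5]}")
            raise ValueError(f"count rows missing library hairpins: {sorted(missing)[:5]}")
        self.counts = self.counts.loc[lib_ids]
        self.counts.index.name = "hairpin_id"
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            bad = self.counts.index[(values < 0).any(axis=1)][0]
            raise ValueError(f"negative count for hairpin {bad!r}")
        if list(self.samples.index) != list(self.counts.columns):
            self.samples = self.samples.loc[list(self.counts.columns)]
        for col in ("condition", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet missing column {col!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        ids = list(self.samples.index[self.samples["condition"] == condition])
        if not ids:
            raise ValueError(f"no samples with condition {condition!r}")
        return ids

    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def write_counts(matrix: CountMatrix, path) -> None:
    """Write counts as TSV: hairpin rows, sample columns, 'hairpin_id' index header."""
    matrix.counts.rename_axis("hairpin_id").to_csv(path, sep="\t")


def read_counts(path, library: LibraryDefinition, samples: pd.DataFrame | None = None) -> CountMatrix:
    """Read a counts TSV back, validating the row set against ``library``.

    ``samples`` is an optional sample sheet (index sample_id, columns
    condition/replicate); when omitted, a sheet with each sample as its own
    condition is synthesised.
    """
    df = pd.read_csv(path, sep="\t", index_col="hairpin_id")
    unknown = set(df.index) - set(library.hairpin_ids)
    if unknown:
        raise ValueError(f"unknown hairpin_id in counts file: {sorted(unknown)[0]!r}")
    if samples is None:
        samples = pd.DataFrame(
            {"condition": list(df.columns), "replicate": 1},
            index=pd.Index(df.columns, name="sample_id"),
        )
    return CountMatrix(counts=df, samples=samples, library=library)


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.rename_axis("sample_id").to_csv(path, sep="\t")


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
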