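"""The hairpin catalogue that keys the whole pipeline.

A pooled shRNA screen is defined by its library: a fixed set of hairpins,
each identified by a unique nucleotide sequence and annotated with the gene
it silences. Every downstream object (count matrices, hit tables, overlap
sets) is keyed on the hairpin IDs of one :class:`LibraryDefinition`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["LibraryDefinition", "read_library", "write_library"]

_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class LibraryDefinition:
    """An immutable catalogue of (hairpin_id, gene_symbol, sequence) entries.

    Invariants enforced at construction: hairpin IDs unique, sequences
    unique (counting would otherwise be ambiguous), all sequences the same
    length over {A, C, G, T}, and every gene has at least one hairpin.
    """

    hairpin_ids: tuple[str, ...]
    gene_symbols: tuple[str, ...]
    sequences: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.hairpin_ids)
        if n == 0:
            raise ValueError("library must contain at least one hairpin")
        if not (len(self.gene_symbols) == len(self.sequences) == n):
            raise ValueError("hairpin_ids, gene_symbols and sequences must align")
        if len(set(self.hairpin_ids)) != n:
            raise ValueError("hairpin IDs must be unique")
        if len(set(self.sequences)) != n:
            raise ValueError("hairpin sequences must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"sequences must share one length, got {sorted(lengths)}")
        bad = [s for s in self.sequences if not _ALPHABET.issuperset(s)]
        if bad:
            raise ValueError(f"sequence contains non-ACGT characters: {bad[0]!r}")
        object.__setattr__(self, "_index", {h: i for i, h in enumerate(self.hairpin_ids)})

    # -- basic accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.hairpin_ids)

    @property
    def n_hairpins(self) -> int:
        return len(self.hairpin_ids)

    @property
    def n_genes(self) -> int:
        return len(set(self.gene_symbols))

    @property
    def seq_len(self) -> int:
        return len(self.sequences[0])

    def gene_of(self, hairpin_id: str) -> str:
        return self.gene_symbols[self._index[hairpin_id]]

    def genes_of(self, hairpin_ids) -> set[str]:
        """Map a collection of hairpin IDs to their gene symbols."""
        return {self.gene_of(h) for h in hairpin_ids}

    def hairpins_of_gene(self, gene_symbol: str) -> list[str]:
        return [h for h, g in zip(self.hairpin_ids, self.gene_symbols) if g == gene_symbol]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hairpin_id": self.hairpin_ids,
                "gene_symbol": self.gene_symbols,
                "sequence": self.sequences,
            }
        )


def write_library(library: LibraryDefinition, path) -> None:
    """Write the library as a 3-column tab-separated table with header."""
    library.to_frame().to_csv(path, sep="\t", index=False)


def read_library(path) -> LibraryDefinition:
    """Read a 3-column (hairpin_id, gene_symbol, sequence) TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["hairpin_id", "gene_symbol", "sequence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"library table missing columns: {missing}")
    return LibraryDefinition(
        hairpin_ids=tuple(df["hairpin_id"]),
        gene_symbols=tuple(df["gene_symbol"]),
        sequences=tuple(df["sequence"].str.upper()),
    )
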