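"""Demultiplex amplicon reads and count hairpins per sample.

Because the amplicon is structurally constant (see
:mod:`poolscreen.amplicon`), read-to-hairpin assignment needs no alignment:
the sample barcode and the hairpin are extracted from fixed windows and
matched against the barcode map and the library by exact lookup, falling
back to Hamming-distance matching within a configurable mismatch budget.
Reads matching nothing within tolerance, or tied between two candidates at
the same best distance, are counted in the report as unassigned/ambiguous —
never silently dropped — so read categories always partition the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .amplicon import AmpliconModel, amplicon_total_length
from .counts import CountMatrix, read_counts, write_counts
from .library import LibraryDefinition

__all__ = [
    "QuantReport",
    "count_hairpins",
    "amplicon_total_length",
    "read_counts",
    "write_counts",
]

DEFAULT_MAX_BARCODE_MISMATCH = 1
DEFAULT_MAX_HAIRPIN_MISMATCH = 2


@dataclass
class QuantReport:
    """Read-fate accounting for one counting run.

    The five fate counters partition every read seen:
    ``assigned + unassigned_barcode + ambiguous_barcode +
    unassigned_hairpin + ambiguous_hairpin == total_reads``.
    Reads shorter than the amplicon model are counted as
    ``unassigned_barcode`` (their barcode window does not exist).
    """

    total_reads: int = 0
    assigned: int = 0
    unassigned_barcode: int = 0
    ambiguous_barcode: int = 0
    unassigned_hairpin: int = 0
    ambiguous_hairpin: int = 0
    per_sample: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def ambiguous(self) -> int:
        return self.ambiguous_barcode + self.ambiguous_hairpin

    def conserved(self) -> bool:
        return self.total_reads == (
            self.assigned
            + self.unassigned_barcode
            + self.ambiguous_barcode
            + self.unassigned_hairpin
            + self.ambiguous_hairpin
        )

    def to_frame(self) -> pd.DataFrame:
        totals = pd.DataFrame(
            {
                "assigned": [self.assigned],
                "unassigned_barcode": [self.unassigned_barcode],
                "ambiguous_barcode": [self.ambiguous_barcode],
                "unassigned_hairpin": [self.unassigned_hairpin],
                "ambiguous_hairpin": [self.ambiguous_hairpin],
                "total_reads": [self.total_reads],
            },
            index=pd.Index(["(all)"], name="sample_id"),
        )
        return pd.concat([totals, self.per_sample]) if len(self.per_sample) else totals

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _encode(seqs) -> np.ndarray:
    """Stack equal-length sequences into a (n, L) uint8 matrix."""
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)


class _HammingIndex:
    """Exact-first lookup with a vectorised Hamming-distance fallback.

    Returns the matched entry index, or -1 (no candidate within
    ``max_mismatch``) or -2 (>= 2 candidates tied at the best distance).
    """

    def __init__(self, seqs: list[str], max_mismatch: int):
        self.length = len(seqs[0])
        self.exact = {s: i for i, s in enumerate(seqs)}
        self.matrix = _encode(seqs)
        self.max_mismatch = max_mismatch

    def lookup(self, query: str) -> int:
        hit = self.exact.get(query)
        if hit is not None:
            return hit
        if self.max_mismatch == 0 or len(query) != self.length:
            return -1
        q = np.frombuffer(query.encode(), dtype=np.uint8)
        dists = (self.matrix != q).sum(axis=1)
        best = int(dists.min())
        if best > self.max_mismatch:
            return -1
        hits = np.flatnonzero(dists == best)
        return int(hits[0]) if len(hits) == 1 else -2


def _check_barcode_separability(barcodes: list[str], max_mismatch: int) -> None:
    enc = _encode(barcodes)
    for i in range(len(barcodes)):
        d = (enc[i + 1 :] != enc[i]).sum(axis=1)
        if len(d) and d.min() <= 2 * max_mismatch:
            j = i + 1 + int(d.argmin())
            raise ValueError(
                f"barcodes {barcodes[i]!r} and {barcodes[j]!r} are only "
                f"{int(d.min())} mismatches apart; demultiplexing at "
                f"{max_mismatch} mismatches is not separable"
            )


def count_hairpins(
    reads,
    library: LibraryDefinition,
    amplicon: AmpliconModel,
    max_barcode_mismatch: int = DEFAULT_MAX_BARCODE_MISMATCH,
    max_hairpin_mismatch: int = DEFAULT_MAX_HAIRPIN_MISMATCH,
    samples: pd.DataFrame | None = None,
) -> tuple[CountMatrix, QuantReport]:
    """Count hairpins per sample from FASTQ input.

    Parameters
    ----------
    reads
        One FASTQ path or a list of paths (gzip accepted).
    library, amplicon
        The hairpin catalogue and the amplicon geometry/barcode map.
    max_barcode_mismatch, max_hairpin_mismatch
        Hamming-distance budgets for barcode and hairpin matching; barcodes
        must be pairwise separated by more than twice the barcode budget.
    samples
        Optional sample sheet (index sample_id, columns condition and
        replicate) attached to the returned matrix; by default each sample
        is its own condition.

    Returns the count matrix (zero rows retained for unobserved hairpins)
    and a :class:`QuantReport` whose categories partition all reads seen.
    """
    if max_barcode_mismatch < 0 or max_hairpin_mismatch < 0:
        raise ValueError("mismatch tolerances must be >= 0")
    if not amplicon.barcode_map:
        raise ValueError("amplicon model has no sample barcodes")
    sample_ids = list(amplicon.barcode_map)
    barcodes = [amplicon.barcode_map[s] for s in sample_ids]
    _check_barcode_separability(barcodes, max_barcode_mismatch)

    bc_index = _HammingIndex(barcodes, max_barcode_mismatch)
    hp_index = _HammingIndex(list(library.sequences), max_hairpin_mismatch)
    bc_window = amplicon.barcode_window
    hp_window = amplicon.hairpin_window(library.seq_len)
    min_len = amplicon.total_len

    counts = np.zeros((len(library), len(sample_ids)), dtype=np.int64)
    report = QuantReport()
    per_sample = np.zeros((len(sample_ids), 3), dtype=np.int64)  # assigned, unhp, amb_hp

    paths = [reads] if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__") else list(reads)
    for path in paths:
        record_idx = 0
        try:
            with pysam.FastxFile(str(path)) as fx:
                for rec in fx:
                    record_idx += 1
                    report.total_reads += 1
                    seq = rec.sequence.upper()
                    if len(seq) < min_len:
                        report.unassigned_barcode += 1
                        continue
                    s = bc_index.lookup(seq[bc_window])
                    if s == -1:
                        report.unassigned_barcode += 1
                        continue
                    if s == -2:
                        report.ambiguous_barcode += 1
                        continue
                    h = hp_index.lookup(seq[hp_window])
                    if h == -1:
                        report.unassigned_hairpin += 1
                        per_sample[s, 1] += 1
                    elif h == -2:
                        report.ambiguous_hairpin += 1
                        per_sample[s, 2] += 1
                    else:
                        counts[h, s] += 1
                        report.assigned += 1
                        per_sample[s, 0] += 1
        except (OSError, ValueError) as exc:
            raise ValueError(
                f"malformed FASTQ in {path!r} at record {record_idx + 1}: {exc}"
            ) from exc

    report.per_sample = pd.DataFrame(
        per_sample,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=["assigned", "unassigned_hairpin", "ambiguous_hairpin"],
    )
    if samples is None:
        samples = pd.DataFrame(
            {"condition": sample_ids, "replicate": 1},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=list(library.hairpin_ids), columns=sample_ids),
        samples=samples,
        library=library,
    )
    return matrix, report
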