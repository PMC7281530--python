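"""Structural model of the sequenced shRNA amplicon.

Each sequencing read spans one PCR amplicon laid out as

    [forward primer | vector insert containing the hairpin | reverse primer]

where the reverse-primer segment carries a sequencing adaptor followed by a
per-sample barcode at its 3' end. The default segment lengths (53 + 513 + 68
= 634 nt, with a 30-nt adaptor and 9-nt barcode inside the reverse segment)
describe the ~634-bp product of a pGIPZ-style pooled library prep.

The hairpin sits at a fixed, documented offset inside the insert and the
barcode at a fixed offset from the read end, so both demultiplexing and
hairpin identification reduce to extracting two windows at deterministic
coordinates — no alignment required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AmpliconModel", "amplicon_total_length"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


@dataclass(frozen=True)
class AmpliconModel:
    """Segment lengths, barcode assignments and fixed flank sequences.

    Parameters
    ----------
    fwd_len, insert_len, rev_len
        Lengths (nt) of the three amplicon segments; the read length is
        their sum.
    adaptor_len, barcode_len
        Lengths of the adaptor and sample barcode, both contained within
        the reverse segment (``rev_len >= adaptor_len + barcode_len``).
    barcode_map
        ``sample_id -> barcode`` assignments; barcodes must be unique and
        exactly ``barcode_len`` nt.
    hairpin_offset
        Offset (nt) of the hairpin within the insert segment. The hairpin
        window in a read is ``[fwd_len + hairpin_offset, + seq_len)``.
    flank_seed
        Seed for the deterministic constant flank sequences emitted by the
        read generator (primer, vector context, adaptor).
    """

    fwd_len: int = 53
    insert_len: int = 513
    rev_len: int = 68
    adaptor_len: int = 30
    barcode_len: int = 9
    barcode_map: dict[str, str] = field(default_factory=dict)
    hairpin_offset: int = 150
    flank_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fwd_len", "insert_len", "rev_len", "adaptor_len", "barcode_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.rev_len < self.adaptor_len + self.barcode_len:
            raise ValueError("rev_len must be >= adaptor_len + barcode_len")
        if not (0 <= self.hairpin_offset <= self.insert_len):
            raise ValueError("hairpin_offset must lie within the insert")
        barcodes = list(self.barcode_map.values())
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("sample barcodes must be unique")
        for sample, bc in self.barcode_map.items():
            if len(bc) != self.barcode_len:
                raise ValueError(
                    f"barcode for sample {sample!r} has length {len(bc)}, "
                    f"expected {self.barcode_len}"
                )

    # -- geometry --------------------------------------------------------

    @property
    def total_len(self) -> int:
        return self.fwd_len + self.insert_len + self.rev_len

    def hairpin_window(self, seq_len: int) -> slice:
        """Read coordinates of the hairpin for a library of ``seq_len``-nt hairpins."""
        if self.hairpin_offset + seq_len > self.insert_len:
            raise ValueError(
                f"hairpin of {seq_len} nt at offset {self.hairpin_offset} "
                f"does not fit in a {self.insert_len}-nt insert"
            )
        start = self.fwd_len + self.hairpin_offset
        return slice(start, start + seq_len)

    @property
    def barcode_window(self) -> slice:
        """Read coordinates of the sample barcode (3' end of the read)."""
        return slice(self.total_len - self.barcode_len, self.total_len)

    # -- read construction ----------------------------------------------

    def flanks(self, seq_len: int) -> tuple[str, str, str]:
        """Deterministic constant sequences around the hairpin and barcode.

        Returns ``(prefix, middle, tail)`` such that a read is
        ``prefix + hairpin + middle + barcode + tail`` (``tail`` is empty:
        the barcode terminates the read).
        """
        self.hairpin_window(seq_len)  # validates fit
        rng = np.random.default_rng(self.flank_seed)
        fwd = _random_seq(rng, self.fwd_len)
        ins_pre = _random_seq(rng, self.hairpin_offset)
        ins_post = _random_seq(rng, self.insert_len - self.hairpin_offset - seq_len)
        rev_stub = _random_seq(rng, self.rev_len - self.adaptor_len - self.barcode_len)
        adaptor = _random_seq(rng, self.adaptor_len)
        return fwd + ins_pre, ins_post + rev_stub + adaptor, ""

    def build_read(self, hairpin_seq: str, sample_id: str) -> str:
        """Assemble the error-free read for one hairpin in one sample."""
        try:
            barcode = self.barcode_map[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample_id {sample_id!r}") from None
        prefix, middle, tail = self.flanks(len(hairpin_seq))
        read = prefix + hairpin_seq + middle + barcode + tail
        assert len(read) == self.total_len
        return read

    def with_samples(self, sample_ids, seed: int = 0) -> "AmpliconModel":
        """Return a copy with random well-separated barcodes for ``sample_ids``.

        Barcodes are drawn rejection-sampled to pairwise Hamming distance
        >= 4, which supports demultiplexing at up to 1 mismatch.
        """
        rng = np.random.default_rng(seed)
        chosen: list[str] = []
        for _ in sample_ids:
            for _attempt in range(1000):
                cand = _random_seq(rng, self.barcode_len)
                if all(_hamming(cand, b) >= 4 for b in chosen):
                    chosen.append(cand)
                    break
            else:
                raise RuntimeError("could not find separable barcodes")
        mapping = dict(zip(sample_ids, chosen))
        return AmpliconModel(
            fwd_len=self.fwd_len,
            insert_len=self.insert_len,
            rev_len=self.rev_len,
            adaptor_len=self.adaptor_len,
            barcode_len=self.barcode_len,
            barcode_map=mapping,
            hairpin_offset=self.hairpin_offset,
            flank_seed=self.flank_seed,
        )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def amplicon_total_length(amplicon: AmpliconModel) -> int:
    """Total amplicon (= read) length in nt: forward + insert + reverse."""
    return amplicon.total_len
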