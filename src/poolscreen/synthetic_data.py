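"""Synthetic pooled-screen data with known ground truth.

The screen this package analyses was run on a boutique ~4020-hairpin /
~1677-gene shRNA library whose raw sequencing and viability data are not
publicly available. This module generates every input the pipeline
consumes — the library catalogue, skewed abundance profiles, amplicon
FASTQ reads, replicated treated-vs-untreated count matrices with planted
depleted/enriched/lost hairpins, and dose-combination inhibition matrices
with a tunable interaction term — always alongside the exact ground truth
used, so recovery can be tested rather than assumed.

Defaults mirror the study conditions: 4020 hairpins over 1677 genes
(~2.4 hairpins/gene), ~10^6 reads per sample (the cell number shown to
preserve library representation), triplicate arms, and log-normal
abundance skew standing in for the real (unpublished) library profile.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .amplicon import AmpliconModel, _random_seq
from .counts import CountMatrix
from .dose_synergy import DoseMatrix, DoseResponseCurve, zip_expected
from .library import LibraryDefinition

__all__ = [
    "AbundanceProfile",
    "EffectSpec",
    "DoseMatrixTruth",
    "generate_library",
    "generate_abundance",
    "apply_effects",
    "generate_reads",
    "generate_screen_counts",
    "generate_dose_matrix",
]

# Study-scale defaults
DEFAULT_N_GENES = 1677
DEFAULT_N_HAIRPINS = 4020
DEFAULT_SEQ_LEN = 22
DEFAULT_DEPTH = 1_000_000
DEFAULT_REPLICATE_CV = 0.2


@dataclass(frozen=True)
class AbundanceProfile:
    """Per-hairpin sampling probabilities, keyed to a library."""

    probs: np.ndarray
    library: LibraryDefinition

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if len(probs) != len(self.library):
            raise ValueError("profile length does not match library")
        if (probs < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities must sum to 1 (got {probs.sum()!r})")


@dataclass(frozen=True)
class EffectSpec:
    """Planted treatment ground truth for one condition.

    ``multipliers`` scales a hairpin's abundance under treatment (values
    < 1 deplete, > 1 enrich); hairpins in ``lost`` are removed entirely
    (abundance forced to 0); everything else is untouched (multiplier 1).
    """

    condition: str
    multipliers: dict[str, float] = field(default_factory=dict)
    lost: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for h, m in self.multipliers.items():
            if not (np.isfinite(m) and m > 0):
                raise ValueError(f"multiplier for {h!r} must be finite and > 0, got {m}")
        object.__setattr__(self, "lost", frozenset(self.lost))
        overlap = set(self.multipliers) & self.lost
        if overlap:
            raise ValueError(f"hairpins both scaled and lost: {sorted(overlap)[:5]}")

    def multiplier_vector(self, library: LibraryDefinition) -> np.ndarray:
        m = np.ones(len(library))
        idx = library._index
        for h, v in self.multipliers.items():
            m[idx[h]] = v
        for h in self.lost:
            m[idx[h]] = 0.0
        return m

    # YAML round trip (explicit seed field carried by the config wrapper)
    def to_yaml(self, path) -> None:
        doc = {
            "condition": self.condition,
            "multipliers": dict(self.multipliers),
            "lost": sorted(self.lost),
        }
        Path(path).write_text(yaml.safe_dump(doc))

    @classmethod
    def from_yaml(cls, path) -> "EffectSpec":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            condition=doc["condition"],
            multipliers={k: float(v) for k, v in (doc.get("multipliers") or {}).items()},
            lost=frozenset(doc.get("lost") or ()),
        )


# ---------------------------------------------------------------------------
# library and abundance


def generate_library(
    n_genes: int,
    hairpins_per_gene: float = 2.4,
    seq_len: int = DEFAULT_SEQ_LEN,
    seed: int | None = None,
    n_hairpins: int | None = None,
    id_prefix: str = "shRNA",
) -> LibraryDefinition:
    """Generate a random hairpin library.

    Every gene receives at least one hairpin; when ``n_hairpins`` (or the
    rounded ``n_genes * hairpins_per_gene``) exceeds ``n_genes``, the extra
    hairpins are spread multinomially across genes, giving a mixture of
    per-gene hairpin counts around the requested mean. Hairpin sequences
    are unique random ACGT strings of ``seq_len`` nt.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if seq_len < 12:
        raise ValueError("seq_len must be >= 12 for unambiguous matching")
    if n_hairpins is None:
        n_hairpins = int(round(n_genes * hairpins_per_gene))
    if n_hairpins < n_genes:
        raise ValueError("need at least one hairpin per gene")
    rng = np.random.default_rng(seed)

    per_gene = np.ones(n_genes, dtype=int)
    extra = n_hairpins - n_genes
    if extra:
        per_gene += rng.multinomial(extra, np.full(n_genes, 1.0 / n_genes))

    if 4 ** seq_len < 4 * n_hairpins:
        raise ValueError("sequence space too small for a unique library")
    seqs: set[str] = set()
    max_attempts = 50 * n_hairpins
    attempts = 0
    while len(seqs) < n_hairpins:
        seqs.add(_random_seq(rng, seq_len))
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not draw {n_hairpins} unique {seq_len}-nt sequences "
                f"after {attempts} attempts"
            )
    seq_list = sorted(seqs)
    rng.shuffle(seq_list)

    hairpin_ids, gene_symbols = [], []
    k = 0
    for g, cnt in enumerate(per_gene):
        gene = f"GENE{g + 1:05d}"
        for _ in range(cnt):
            hairpin_ids.append(f"{id_prefix}{k + 1:05d}")
            gene_symbols.append(gene)
            k += 1
    return LibraryDefinition(
        hairpin_ids=tuple(hairpin_ids),
        gene_symbols=tuple(gene_symbols),
        sequences=tuple(seq_list[:n_hairpins]),
    )


def generate_abundance(
    library: LibraryDefinition, dispersion: float = 1.0, seed: int | None = None
) -> AbundanceProfile:
    """Log-normal-shaped abundance profile normalised to sum 1.

    ``dispersion`` is the log-scale standard deviation of the skew;
    0 gives a uniform profile. Models the uneven hairpin representation a
    real pooled library acquires through cloning and transduction.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    n = len(library)
    if dispersion == 0:
        probs = np.full(n, 1.0 / n)
    else:
        rng = np.random.default_rng(seed)
        raw = rng.lognormal(mean=0.0, sigma=dispersion, size=n)
        probs = raw / raw.sum()
    return AbundanceProfile(probs=probs, library=library)


def apply_effects(profile: AbundanceProfile, effects: EffectSpec) -> AbundanceProfile:
    """Scale a profile by planted per-hairpin effects and renormalise."""
    m = effects.multiplier_vector(profile.library)
    scaled = profile.probs * m
    total = scaled.sum()
    if total <= 0:
        raise ValueError("all hairpins lost: nothing left to sample")
    return AbundanceProfile(probs=scaled / total, library=profile.library)


# ---------------------------------------------------------------------------
# reads


def generate_reads(
    library: LibraryDefinition,
    profile: AbundanceProfile,
    amplicon: AmpliconModel,
    sample_id: str,
    depth: int,
    subst_error_rate: float = 0.0,
    seed: int | None = None,
    out=None,
) -> dict[str, int]:
    """Emit amplicon FASTQ reads for one sample; return the exact tally used.

    Hairpin draws are multinomial(depth, profile). Each read is the full
    constant amplicon with the drawn hairpin at the model's hairpin window
    and the sample barcode at the 3' end; sequencing noise is i.i.d. base
    substitutions at ``subst_error_rate``. ``out`` is a path (``.gz``
    honoured) or a text handle; quality strings are constant.
    """
    if sample_id not in amplicon.barcode_map:
        raise KeyError(f"sample_id {sample_id!r} not in the amplicon barcode map")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if profile.library is not library:
        if tuple(profile.library.hairpin_ids) != tuple(library.hairpin_ids):
            raise ValueError("profile is keyed to a different library")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, profile.probs) if depth else np.zeros(len(library), int)
    tally = {h: int(c) for h, c in zip(library.hairpin_ids, counts)}

    if out is None:
        return tally
    own = False
    if isinstance(out, (str, Path)):
        own = True
        handle = gzip.open(out, "wt") if str(out).endswith(".gz") else open(out, "w")
    else:
        handle = out
    try:
        _write_fastq(handle, library, amplicon, sample_id, counts, subst_error_rate, rng)
    finally:
        if own:
            handle.close()
    return tally


def _write_fastq(handle, library, amplicon, sample_id, counts, subst_error_rate, rng):
    prefix, middle, _ = amplicon.flanks(library.seq_len)
    barcode = amplicon.barcode_map[sample_id]
    qual = "I" * amplicon.total_len
    read_idx = 0
    for seq, c in zip(library.sequences, counts):
        if c == 0:
            continue
        base = prefix + seq + middle + barcode
        if subst_error_rate > 0:
            n_err = rng.binomial(amplicon.total_len, subst_error_rate, size=c)
            for k in range(c):
                read = _mutate(base, int(n_err[k]), rng) if n_err[k] else base
                read_idx += 1
                handle.write(f"@{sample_id}:{read_idx}\n{read}\n+\n{qual}\n")
        else:
            for _ in range(c):
                read_idx += 1
                handle.write(f"@{sample_id}:{read_idx}\n{base}\n+\n{qual}\n")


_SUBST = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def _mutate(read: str, n_err: int, rng) -> str:
    chars = list(read)
    for pos in rng.choice(len(chars), size=n_err, replace=False):
        chars[pos] = _SUBST[chars[pos]][rng.integers(3)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# count matrices with planted effects


def generate_screen_counts(
    library: LibraryDefinition,
    profile: AbundanceProfile,
    effects: list[EffectSpec],
    control_condition: str = "untreated",
    n_replicates: int = 3,
    depth: int = DEFAULT_DEPTH,
    replicate_cv: float = DEFAULT_REPLICATE_CV,
    seed: int | None = None,
) -> CountMatrix:
    """Replicated treated-vs-untreated count matrix with planted effects.

    One arm of ``n_replicates`` samples is generated per EffectSpec plus an
    untouched control arm. Each replicate's expected count is
    ``depth * prob`` modulated by a per-hairpin log-normal factor with
    coefficient of variation ``replicate_cv`` (biological/technical
    replicate noise); observed counts are Poisson around that expectation
    (sequencing counting noise).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if replicate_cv < 0:
        raise ValueError("replicate_cv must be >= 0")
    rng = np.random.default_rng(seed)
    arms = [(control_condition, profile)] + [
        (e.condition, apply_effects(profile, e)) for e in effects
    ]
    if len({c for c, _ in arms}) != len(arms):
        raise ValueError("condition labels must be distinct")

    sigma = np.sqrt(np.log1p(replicate_cv**2))
    cols, meta = {}, []
    for condition, arm_profile in arms:
        expected = depth * arm_profile.probs
        for r in range(1, n_replicates + 1):
            factor = (
                rng.lognormal(-sigma**2 / 2, sigma, len(library)) if sigma > 0 else 1.0
            )
            cols[f"{condition}_{r}"] = rng.poisson(expected * factor)
            meta.append((f"{condition}_{r}", condition, r))
    counts = pd.DataFrame(cols, index=list(library.hairpin_ids))
    samples = pd.DataFrame(
        meta, columns=["sample_id", "condition", "replicate"]
    ).set_index("sample_id")
    return CountMatrix(counts=counts, samples=samples, library=library)


# ---------------------------------------------------------------------------
# dose matrices


@dataclass(frozen=True)
class DoseMatrixTruth:
    """Ground truth for a synthetic drug-combination experiment.

    Monotherapy behaviour of each drug is a Hill curve; the combination
    surface is the ZIP independence expectation plus a constant interaction
    offset ``delta`` (inhibition fraction, applied to combination cells
    only — 0 gives an exact ZIP-null surface) plus optional Gaussian
    replicate noise.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    curve_a: DoseResponseCurve
    curve_b: DoseResponseCurve
    delta: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("doses_a", "doses_b"):
            d = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, d)
            if d.ndim != 1 or len(d) == 0:
                raise ValueError(f"{name} must be a non-empty 1-D grid")
            if (d <= 0).any():
                raise ValueError(f"{name} must be strictly positive (0 margin is added)")
            if (np.diff(d) <= 0).any():
                raise ValueError(f"{name} must be strictly ascending")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_dose_matrix(truth: DoseMatrixTruth, seed: int | None = None) -> DoseMatrix:
    """Synthesize a dose-combination inhibition matrix with margins.

    Combination cells follow ``clip(yA + yB - yA*yB + delta + noise, 0, 1)``;
    the added zero-dose row/column hold the (noisy) monotherapy responses.
    """
    rng = np.random.default_rng(seed)
    da = np.concatenate([[0.0], truth.doses_a])
    db = np.concatenate([[0.0], truth.doses_b])
    ya = truth.curve_a.predict(da)
    yb = truth.curve_b.predict(db)
    surface = zip_expected(ya[:, None], yb[None, :])
    surface[1:, 1:] += truth.delta
    surface[0, 0] = 0.0  # double-vehicle well: no drug, no inhibition
    if truth.noise_sd > 0:
        noise = rng.normal(0.0, truth.noise_sd, surface.shape)
        noise[0, 0] = 0.0
        surface = surface + noise
    return DoseMatrix(doses_a=da, doses_b=db, inhibition=np.clip(surface, 0.0, 1.0))
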