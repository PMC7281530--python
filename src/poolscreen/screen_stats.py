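"""Hit calling for the drop-out screen: normalize, filter, test, intersect.

The analysis contrasts drug-treated replicate samples against untreated
controls, hairpin by hairpin:

1. raw counts are normalised to reads per million (CPM) so samples of
   different sequencing depth are comparable;
2. hairpins without adequate pre-treatment representation (mean raw count
   in the untreated controls not above 100) are excluded before testing;
3. hairpins whose raw treated counts are all zero despite passing the
   abundance filter are classed *lost* — complete drop-out, the strongest
   phenotype — before any ratio is computed;
4. the remaining kept hairpins get a two-sided Student's t-test (treated
   vs control replicates, equal-variance by default; Welch optional) on
   log2(CPM + pseudocount), and a log2 fold change of pseudocounted CPM
   means. *Depleted*/*enriched* calls require both a two-fold change and
   p < 0.01 (raw p, per the primary-hit rule; Benjamini-Hochberg adjusted
   values are reported alongside but do not gate the call).

Hits from several drugs are intersected at the hairpin and at the gene
level to find rescuer genes shared across treatments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts import CountMatrix
from .library import LibraryDefinition

__all__ = [
    "HitTable",
    "OverlapResult",
    "normalize_counts",
    "filter_low_abundance",
    "call_hits",
    "intersect_hits",
]

CLASSES = ("depleted", "enriched", "lost", "unchanged", "filtered")

DEFAULT_ALPHA = 0.01
DEFAULT_FOLD = 2.0
DEFAULT_MIN_RAW = 100
DEFAULT_PSEUDOCOUNT = 0.5


def normalize_counts(matrix: CountMatrix) -> pd.DataFrame:
    """Reads-per-million normalisation: each sample column scaled to 1e6."""
    totals = matrix.column_totals()
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero total count")
    return matrix.counts / totals * 1e6


def filter_low_abundance(
    matrix: CountMatrix, control_samples, min_raw: float = DEFAULT_MIN_RAW
) -> pd.Series:
    """Boolean keep-mask: mean raw count across controls strictly > min_raw."""
    control_samples = list(control_samples)
    if not control_samples:
        raise ValueError("need at least one control sample")
    return matrix.counts[control_samples].mean(axis=1) > min_raw


def _resolve(matrix: CountMatrix, arm) -> list[str]:
    """An arm is either a condition label or an explicit list of sample IDs."""
    if isinstance(arm, str):
        return matrix.samples_for(arm)
    arm = list(arm)
    unknown = set(arm) - set(matrix.sample_ids)
    if unknown:
        raise ValueError(f"unknown sample IDs: {sorted(unknown)}")
    return arm


@dataclass
class HitTable:
    """Per-hairpin hit calls for one drug-vs-control contrast.

    ``records`` has one row per library hairpin (classification is a
    partition) with columns gene_symbol, mean_control, mean_treated (CPM),
    log2_ratio, p_value, adjusted_p, hit_class.
    """

    contrast: str
    alpha: float
    fold: float
    records: pd.DataFrame
    library: LibraryDefinition = field(repr=False)

    def hairpins(self, hit_class: str) -> set[str]:
        if hit_class not in CLASSES:
            raise ValueError(f"unknown class {hit_class!r}; expected one of {CLASSES}")
        return set(self.records.index[self.records["hit_class"] == hit_class])

    def genes(self, hit_class: str) -> set[str]:
        return self.library.genes_of(self.hairpins(hit_class))

    def class_counts(self) -> pd.Series:
        return self.records["hit_class"].value_counts().reindex(CLASSES, fill_value=0)

    def to_tsv(self, path) -> None:
        self.records.rename_axis("hairpin_id").to_csv(path, sep="\t")


def call_hits(
    matrix: CountMatrix,
    treated,
    control,
    alpha: float = DEFAULT_ALPHA,
    fold: float = DEFAULT_FOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_raw: float = DEFAULT_MIN_RAW,
    equal_var: bool = True,
    log_scale: bool = True,
    contrast: str | None = None,
) -> HitTable:
    """Call depleted/enriched/lost hairpins for one treated-vs-control contrast.

    Parameters
    ----------
    matrix
        Raw count matrix (filtering and lost-detection need raw counts;
        CPM normalisation happens internally).
    treated, control
        Condition labels from the sample sheet, or explicit sample-ID lists;
        each arm needs >= 2 replicates for the t-test.
    alpha, fold
        Primary-hit rule: two-sided p < alpha and fold change >= fold
        (applied symmetrically to depletion and enrichment).
    pseudocount
        Added to CPM means before the log2 ratio (and to CPM values for the
        log-scale test) so depleted-but-nonzero hairpins stay finite.
    equal_var
        Classical Student's t (True, default) or Welch (False).
    log_scale
        Test log2(CPM + pseudocount) values (default — count noise is
        multiplicative) rather than raw CPM values.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if fold <= 1:
        raise ValueError("fold threshold must be > 1")
    treated_ids = _resolve(matrix, treated)
    control_ids = _resolve(matrix, control)
    if len(treated_ids) < 2 or len(control_ids) < 2:
        raise ValueError("need >= 2 replicates per arm for the t-test")
    if set(treated_ids) & set(control_ids):
        raise ValueError("treated and control arms overlap")

    cpm = normalize_counts(matrix)
    kept = filter_low_abundance(matrix, control_ids, min_raw=min_raw)

    raw_t = matrix.counts[treated_ids].to_numpy()
    cpm_t = cpm[treated_ids].to_numpy()
    cpm_c = cpm[control_ids].to_numpy()

    mean_t = cpm_t.mean(axis=1)
    mean_c = cpm_c.mean(axis=1)
    log2_ratio = np.log2((mean_t + pseudocount) / (mean_c + pseudocount))

    if log_scale:
        test_t = np.log2(cpm_t + pseudocount)
        test_c = np.log2(cpm_c + pseudocount)
    else:
        test_t, test_c = cpm_t, cpm_c
    with warnings.catch_warnings():
        # scipy warns about precision loss on near-constant rows; degenerate
        # zero-variance rows are resolved explicitly below.
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(test_t, test_c, axis=1, equal_var=equal_var)
    pvals = np.asarray(res.pvalue, dtype=float)
    # Degenerate rows (zero variance in both arms): p = 1 when the means
    # agree — no evidence of change — and ~0 when they differ exactly.
    var_t = test_t.var(axis=1)
    var_c = test_c.var(axis=1)
    degen = (var_t == 0) & (var_c == 0)
    pvals[degen & (test_t.mean(axis=1) == test_c.mean(axis=1))] = 1.0
    pvals[degen & (test_t.mean(axis=1) != test_c.mean(axis=1))] = 0.0

    kept_arr = kept.to_numpy()
    lost = kept_arr & (raw_t.sum(axis=1) == 0) & (raw_t == 0).all(axis=1)
    log_fold = np.log2(fold)
    hit_class = np.full(len(matrix.counts), "unchanged", dtype=object)
    hit_class[(log2_ratio <= -log_fold) & (pvals < alpha)] = "depleted"
    hit_class[(log2_ratio >= log_fold) & (pvals < alpha)] = "enriched"
    hit_class[lost] = "lost"
    hit_class[~kept_arr] = "filtered"

    adjusted = np.full(len(pvals), np.nan)
    if kept_arr.any():
        adjusted[kept_arr] = multipletests(pvals[kept_arr], method="fdr_bh")[1]

    records = pd.DataFrame(
        {
            "gene_symbol": list(matrix.library.gene_symbols),
            "mean_control": mean_c,
            "mean_treated": mean_t,
            "log2_ratio": log2_ratio,
            "p_value": pvals,
            "adjusted_p": adjusted,
            "hit_class": hit_class,
        },
        index=matrix.counts.index,
    )
    label = contrast or (treated if isinstance(treated, str) else "treated")
    return HitTable(contrast=label, alpha=alpha, fold=fold, records=records,
                    library=matrix.library)


@dataclass
class OverlapResult:
    """Cross-drug intersection of hits of one class.

    ``hairpins`` intersects the per-contrast hairpin hit sets;
    ``genes`` intersects the per-contrast gene sets (a gene counts for a
    contrast as soon as one of its hairpins is a hit there, so a gene can
    be shared across drugs through different hairpins).
    """

    hit_class: str
    contrasts: tuple[str, ...]
    hairpins: set[str]
    genes: set[str]
    per_contrast_hairpins: dict[str, set[str]]

    def to_frame(self) -> pd.DataFrame:
        genes_sorted = sorted(self.genes)
        return pd.DataFrame({"gene_symbol": genes_sorted}).assign(
            hit_class=self.hit_class, contrasts="|".join(self.contrasts)
        )


def intersect_hits(tables: list[HitTable], hit_class: str = "depleted") -> OverlapResult:
    """Intersect hit sets of one class across contrasts (hairpin and gene level)."""
    if not tables:
        raise ValueError("need at least one hit table")
    first = tables[0].library
    for t in tables[1:]:
        if (
            tuple(t.library.hairpin_ids) != tuple(first.hairpin_ids)
            or tuple(t.library.sequences) != tuple(first.sequences)
        ):
            raise ValueError("hit tables are keyed to different libraries")
    per_hp = {t.contrast: t.hairpins(hit_class) for t in tables}
    hairpins = set.intersection(*per_hp.values())
    genes = set.intersection(*(t.genes(hit_class) for t in tables))
    return OverlapResult(
        hit_class=hit_class,
        contrasts=tuple(t.contrast for t in tables),
        hairpins=hairpins,
        genes=genes,
        per_contrast_hairpins=per_hp,
    )
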