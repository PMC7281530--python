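"""Monte-Carlo simulation of library-representation sampling error.

Passaging a pooled screen means repeatedly sampling a finite number of
cells from the hairpin pool; rare hairpins suffer the largest relative
sampling error and risk dropping out by chance alone. This module models
one passage as a multinomial draw of ``n_draws`` cells from the abundance
profile and summarises, per hairpin, the mean, standard deviation and
coefficient of variation of its sampled count across replicates — the
computation behind choosing ~10^6 cells as sufficient to keep at least one
copy of every hairpin.

For a hairpin of probability p, the binomial closed form gives
``CV = sqrt((1 - p) / (n * p))``; the simulation reproduces this across
orders of magnitude of abundance, which is the shape of the
error-vs-abundance relationship the cell-number decision rests on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import AbundanceProfile

__all__ = ["SamplingSimResult", "simulate_sampling", "representation_check", "expected_cv"]


@dataclass
class SamplingSimResult:
    """Per-hairpin sampling statistics over replicated multinomial draws."""

    per_hairpin: pd.DataFrame  # probability, mean, sd, cv (NaN where mean == 0)
    counts: np.ndarray         # replicates x hairpins draw matrix
    n_draws: int
    n_replicates: int

    @property
    def fraction_represented(self) -> float:
        """Fraction of hairpins with >= 1 copy in every replicate."""
        return representation_check(self, min_copies=1)

    def to_tsv(self, path) -> None:
        self.per_hairpin.to_csv(path, sep="\t")

    def plot(self, path) -> None:
        """Log-log scatter of relative sampling error vs hairpin abundance."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.per_hairpin.dropna(subset=["cv"])
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(df["probability"], df["cv"], s=4, alpha=0.4, label="simulated")
        p = np.sort(df["probability"].to_numpy())
        ax.plot(p, expected_cv(p, self.n_draws), "r-", lw=1,
                label=r"$\sqrt{(1-p)/(np)}$")
        ax.set_xscale("log"); ax.set_yscale("log")
        ax.set_xlabel("hairpin abundance (probability)")
        ax.set_ylabel("relative sampling error (CV)")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def expected_cv(probs, n_draws: int) -> np.ndarray:
    """Binomial closed-form CV of a hairpin's count: sqrt((1-p)/(n*p))."""
    p = np.asarray(probs, dtype=float)
    return np.sqrt((1.0 - p) / (n_draws * p))


def simulate_sampling(
    profile: AbundanceProfile,
    n_draws: int,
    n_replicates: int,
    seed: int | None = None,
) -> SamplingSimResult:
    """Replicated multinomial sampling of ``n_draws`` cells from the pool."""
    if n_draws < 0:
        raise ValueError("n_draws must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    probs = profile.probs
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("abundance profile must sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_draws, probs, size=n_replicates)

    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1) if n_replicates > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    per_hairpin = pd.DataFrame(
        {
            "probability": probs,
            "mean": mean,
            "sd": sd,
            "cv": cv,
        },
        index=pd.Index(profile.library.hairpin_ids, name="hairpin_id"),
    )
    return SamplingSimResult(
        per_hairpin=per_hairpin, counts=counts,
        n_draws=n_draws, n_replicates=n_replicates,
    )


def representation_check(result: SamplingSimResult, min_copies: int = 1) -> float:
    """Fraction of hairpins at >= ``min_copies`` in every replicate."""
    if min_copies < 1:
        raise ValueError("min_copies must be >= 1")
    ok = (result.counts >= min_copies).all(axis=0)
    return float(ok.mean())
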