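"""Core record types of the trial-proteomics MR framework.

Variant-level summary statistics (one row per variant-trait association)
travel as pandas DataFrames with the canonical column order

    variant_id, chr, pos, ea, oa, beta, se, p, eaf, n

(`CANONICAL_COLUMNS`). Scalar records — a protein's trial effect, an MR
estimate, a concordance call — are the dataclasses below.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Fixed column order for variant association tables.
CANONICAL_COLUMNS = ["variant_id", "chr", "pos", "ea", "oa", "beta", "se", "p", "eaf", "n"]


class Direction(str, enum.Enum):
    """Direction of an observed change in the trial's active arm."""

    UP = "Up"
    DOWN = "Down"
    UNOBSERVED = "Unobserved"


@dataclass(frozen=True)
class TrialProteinEffect:
    """A protein's observed change between baseline and follow-up in the trial.

    ``log2_fold_change`` is the base-2 log of the post/pre level ratio in the
    active arm; ``fdr_p`` the false-discovery-rate adjusted p-value of that
    change.
    """

    uniprot_id: str
    gene_symbol: str
    seq_id: str
    log2_fold_change: float
    fdr_p: float = float("nan")

    def direction(self) -> Direction:
        if self.log2_fold_change > 0:
            return Direction.UP
        if self.log2_fold_change < 0:
            return Direction.DOWN
        return Direction.UNOBSERVED

    def __post_init__(self):
        if not np.isfinite(self.log2_fold_change):
            raise ValueError(f"log2_fold_change must be finite for {self.gene_symbol}")


@dataclass(frozen=True)
class TrialOutcomeDirection:
    """Direction of change of one trial-monitored trait in the active arm."""

    outcome_name: str
    direction: Direction = Direction.UNOBSERVED


@dataclass
class MREstimate:
    """A causal-effect estimate of one exposure on one outcome.

    ``beta`` is per SD of exposure, in outcome SD units for continuous
    outcomes and log-odds for binary ones. ``diagnostics`` holds
    method-specific extras (Cochran's Q, outlier indices, global-test p).
    """

    beta: float
    se: float
    pvalue: float
    method: str
    n_instruments: int
    diagnostics: dict = field(default_factory=dict)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        return self.beta - z * self.se, self.beta + z * self.se


@dataclass
class InstrumentSet:
    """Harmonized exposure/outcome instrument pairs for one protein.

    ``pairs`` carries one row per retained variant with exposure columns
    (beta_exp, se_exp, p_exp, eaf_exp, n_exp) taken from the estimation
    study and, once an outcome is attached, outcome columns (beta_out,
    se_out, ...). ``provenance`` logs, per filtering stage, how many
    variants entered and survived.
    """

    protein: str
    pairs: pd.DataFrame
    trial_effect: Optional[TrialProteinEffect] = None
    provenance: list = field(default_factory=list)

    @property
    def f_statistics(self) -> np.ndarray:
        b = self.pairs["beta_exp"].to_numpy(float)
        s = self.pairs["se_exp"].to_numpy(float)
        return (b / s) ** 2

    def f_summary(self) -> dict:
        """Per-protein instrument-strength summaries: min, mean and total F.

        The minimum is the value the weak-instrument filter binds on and is
        what result tables export as the protein's F statistic.
        """
        f = self.f_statistics
        if f.size == 0:
            return {"min": float("nan"), "mean": float("nan"), "total": float("nan")}
        return {"min": float(f.min()), "mean": float(f.mean()), "total": float(f.sum())}

    def __len__(self) -> int:
        return len(self.pairs)

    def log(self, stage: str, n_in: int, n_out: int, detail: str = "") -> None:
        self.provenance.append({"stage": stage, "n_in": n_in, "n_out": n_out, "detail": detail})


@dataclass
class ConcordanceRecord:
    """One significant protein-outcome MR estimate with its trial comparison.

    ``concordant`` is 1 when the oriented MR effect points the same way as
    the trait change seen in the trial, 0 when opposite, and None when the
    trait was not annotated in the trial (``trial_direction`` Unobserved).
    """

    protein: str
    outcome: str
    oriented_beta: float
    se: float
    pvalue: float
    trial_direction: Direction
    concordant: Optional[int]
    outcome_type: str = "continuous"

    def __post_init__(self):
        if (self.concordant is None) != (self.trial_direction == Direction.UNOBSERVED):
            raise ValueError("concordant must be None iff trial direction is Unobserved")


@dataclass
class MediatorClassification:
    """Bidirectional-MR classification of one protein.

    upstream_mediator: the protein causally affects an outcome and no
    outcome affects it; downstream_consequence: the reverse; bidirectional:
    both; unclassified: neither.
    """

    protein: str
    forward_significant: bool
    reverse_significant: bool

    @property
    def label(self) -> str:
        if self.forward_significant and not self.reverse_significant:
            return "upstream_mediator"
        if self.forward_significant and self.reverse_significant:
            return "bidirectional"
        if self.reverse_significant:
            return "downstream_consequence"
        return "unclassified"


def estimates_to_frame(records) -> pd.DataFrame:
    """Flatten an iterable of (protein, outcome, MREstimate) triples to a table."""
    rows = []
    for protein, outcome, est in records:
        rows.append(
            {
                "protein": protein,
                "outcome": outcome,
                "method": est.method,
                "beta": est.beta,
                "se": est.se,
                "p": est.pvalue,
                "n_inst": est.n_instruments,
            }
        )
    return pd.DataFrame(rows)
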