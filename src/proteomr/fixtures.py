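"""Packaged reference table of significant protein-outcome MR results.

The fixture transcribes the published concordance table of the torcetrapib
case study: one row per significant protein-outcome pair with the aptamer
SeqID, instrument count, F-statistic, the trial-observed log2-fold change,
the trial trait direction where annotated, the oriented MR estimate
(beta, SE, p), the printed concordance flag, and the outcome type.

``replay_concordance`` re-derives every concordance flag from first
principles: the printed beta (already oriented to the trial's protein
direction) is mapped back to the per-SD-increase scale, run through
:func:`proteomr.pipeline.orient_to_trial` and
:func:`proteomr.pipeline.classify_concordance`, and compared row by row.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .pipeline import classify_concordance, orient_to_trial
from .types import Direction, MREstimate, TrialOutcomeDirection, TrialProteinEffect

_FIXTURE = "table1_concordance.tsv"


def load_concordance_table() -> pd.DataFrame:
    """The packaged 32-row results table, with NA concordance for unannotated traits."""
    with resources.files("proteomr.data").joinpath(_FIXTURE).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"trait_change": str, "concordant": "Int64"})
    df["trait_change"] = df["trait_change"].fillna("")
    return df


def replay_concordance(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute each row's concordance flag via orientation + classification.

    Returns the table with two extra columns: ``beta_raw`` (the estimate
    mapped back to the per-SD-increase scale) and ``computed_concordant``
    (Int64, NA for unannotated traits).
    """
    df = (table if table is not None else load_concordance_table()).copy()
    computed, raw_betas = [], []
    for row in df.itertuples(index=False):
        trial = TrialProteinEffect(uniprot_id="", gene_symbol=row.protein,
                                   seq_id=row.seq_id, log2_fold_change=row.log2fc)
        # printed betas are oriented to the trial direction; undo that to get
        # the per-SD-increase estimate the MR step itself would emit
        sign = 1.0 if row.log2fc > 0 else -1.0
        raw = MREstimate(beta=sign * row.beta, se=row.se, pvalue=row.p,
                         method="ivw_fixed", n_instruments=int(row.n_inst))
        raw_betas.append(raw.beta)
        oriented = orient_to_trial(raw, trial)
        d = Direction(row.trait_change) if row.trait_change in ("Up", "Down") \
            else Direction.UNOBSERVED
        rec = classify_concordance(oriented, TrialOutcomeDirection(row.outcome, d),
                                   row.protein, row.outcome_type)
        computed.append(rec.concordant)
    df["beta_raw"] = raw_betas
    df["computed_concordant"] = pd.array(computed, dtype="Int64")
    return df


def summary_counts(table: pd.DataFrame | None = None) -> dict:
    """Headline counts: proteins, concordant proteins, BP proteins, BP-concordant."""
    df = replay_concordance(table)
    bp = df[df["outcome"].str.contains("blood pressure")]
    return {
        "significant_proteins": df["protein"].nunique(),
        "concordant_proteins": df.loc[df["computed_concordant"] == 1, "protein"].nunique(),
        "blood_pressure_proteins": bp["protein"].nunique(),
        "blood_pressure_concordant_proteins":
            bp.loc[bp["computed_concordant"] == 1, "protein"].nunique(),
        "annotated_rows": int((df["trait_change"] != "").sum()),
    }
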