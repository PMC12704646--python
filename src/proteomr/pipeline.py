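"""Forward/reverse MR orchestration with trial-direction orientation.

The inference chain mirrors the framework's design: proteins whose trial
changes are attributable to the drug's intended (lipid) effects are set
aside; for each remaining protein, cis-pQTL instruments drive forward MR
on every outcome; estimates are oriented to the direction of the protein
change observed in the trial, Bonferroni-corrected over the realized test
count, and classified as concordant or discordant with the trait changes
seen in the trial; reverse MR (outcome -> proteome) then separates
upstream mediators from downstream consequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from . import estimators
from .exceptions import InsufficientInstrumentsError, OrientationError
from .io import harmonize
from .types import (
    ConcordanceRecord,
    Direction,
    InstrumentSet,
    MediatorClassification,
    MREstimate,
    TrialOutcomeDirection,
    TrialProteinEffect,
)

logger = logging.getLogger(__name__)

#: Outcome -> broad category, used for the reverse-MR intersection summary.
OUTCOME_CATEGORIES = {
    "coronary heart disease": "cardiovascular",
    "coronary artery disease": "cardiovascular",
    "ischemic stroke": "cardiovascular",
    "heart failure": "cardiovascular",
    "peripheral artery disease": "cardiovascular",
    "HDL": "metabolic", "LDL": "metabolic", "triglycerides": "metabolic",
    "heart rate": "metabolic", "systolic blood pressure": "metabolic",
    "diastolic blood pressure": "metabolic", "type II diabetes": "metabolic",
    "eGFRcrea": "metabolic", "body mass index": "metabolic",
    "infection": "infection/autoimmune", "pneumonia": "infection/autoimmune",
    "sepsis": "infection/autoimmune",
    "inflammatory bowel disease": "infection/autoimmune",
    "breast cancer": "cancer", "prostate cancer": "cancer",
}


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Per-test significance level alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def orient_to_trial(raw: MREstimate, trial: TrialProteinEffect) -> MREstimate:
    """Re-express an estimate per SD change *in the trial's direction*.

    Raw MR estimates are per SD increase in protein level. For proteins
    that fell in the trial the sign is flipped so the estimate reads per
    SD decrease; SE and p are unchanged. A zero log2-fold change has no
    direction and raises :class:`OrientationError`.
    """
    d = trial.direction()
    if d == Direction.UNOBSERVED:
        raise OrientationError(
            f"protein {trial.gene_symbol} has zero log2-fold change; orientation undefined")
    beta = raw.beta if d == Direction.UP else -raw.beta
    return MREstimate(beta=beta, se=raw.se, pvalue=raw.pvalue, method=raw.method,
                      n_instruments=raw.n_instruments, diagnostics=dict(raw.diagnostics))


def classify_concordance(oriented: MREstimate, trial_direction: TrialOutcomeDirection,
                         protein: str, outcome_type: str = "continuous") -> ConcordanceRecord:
    """Compare an oriented MR estimate with the trial's trait change.

    Concordant (1) when the oriented effect points the same way as the
    trait moved in the active arm, discordant (0) otherwise, NA (None)
    when the trait was not annotated in the trial.
    """
    if trial_direction.direction == Direction.UNOBSERVED:
        flag = None
    elif trial_direction.direction == Direction.UP:
        flag = int(oriented.beta > 0)
    else:
        flag = int(oriented.beta < 0)
    return ConcordanceRecord(
        protein=protein, outcome=trial_direction.outcome_name,
        oriented_beta=oriented.beta, se=oriented.se, pvalue=oriented.pvalue,
        trial_direction=trial_direction.direction, concordant=flag,
        outcome_type=outcome_type,
    )


def exclude_lipid_mediated(
    proteins: list[TrialProteinEffect],
    lipid_mr_results: dict[tuple[str, str], MREstimate],
    alpha: float = 0.05,
) -> tuple[list[TrialProteinEffect], list[TrialProteinEffect], list[str]]:
    """Partition proteins into lipid-mediated (on-target) and off-target.

    ``lipid_mr_results`` maps (lipid, gene_symbol) to the MR estimate of
    that lipid's effect on the protein. A protein is on-target iff any
    lipid effect on it passes Bonferroni over all lipid x protein tests at
    ``alpha``. Proteins absent from the results go off-target with a
    logged warning. Returns (on_target, off_target, warnings).
    """
    n_tests = max(1, len(lipid_mr_results))
    threshold = bonferroni_threshold(n_tests, alpha)
    covered = {prot for (_, prot) in lipid_mr_results}
    on, off, warnings = [], [], []
    for protein in proteins:
        g = protein.gene_symbol
        if g not in covered:
            warnings.append(f"{g}: no lipid MR result; kept off-target")
            off.append(protein)
            continue
        hit = any(est.pvalue < threshold for (lipid, prot), est in lipid_mr_results.items()
                  if prot == g)
        (on if hit else off).append(protein)
    for w in warnings:
        logger.warning(w)
    return on, off, warnings


@dataclass
class ForwardResult:
    """Everything the forward (protein -> outcome) pass produces."""

    estimates: pd.DataFrame          # all protein-outcome estimates (raw + oriented)
    concordance: list[ConcordanceRecord]  # significant pairs only
    sensitivity: pd.DataFrame        # per-pair alternate-estimator results
    threshold: float
    n_tests: int
    excluded: pd.DataFrame           # (protein, stage, reason)
    significant_proteins: set = field(default_factory=set)

    def concordance_frame(self) -> pd.DataFrame:
        rows = [{
            "protein": r.protein, "outcome": r.outcome, "beta": r.oriented_beta,
            "se": r.se, "p": r.pvalue, "trait_change": r.trial_direction.value,
            "concordant": "" if r.concordant is None else r.concordant,
            "outcome_type": r.outcome_type,
        } for r in self.concordance]
        return pd.DataFrame(rows, columns=["protein", "outcome", "beta", "se", "p",
                                           "trait_change", "concordant", "outcome_type"])


def run_forward_mr(
    off_target_proteins: list[TrialProteinEffect],
    instrument_sets: dict[str, InstrumentSet],
    outcome_stats: dict[str, pd.DataFrame],
    trial_directions: dict[str, TrialOutcomeDirection],
    outcome_types: dict[str, str] | None = None,
    alpha: float = 0.05,
    palindrome_eaf_limit: float = 0.42,
    sensitivity: bool = True,
    bootstrap_reps: int = 1000,
    presso_sims: int = 1000,
    seed: int = 0,
) -> ForwardResult:
    """Estimate every protein -> outcome effect and classify concordance.

    For each protein with a nonempty instrument set and each outcome: the
    instruments are harmonized to the outcome GWAS, the fixed-effects IVW
    (Wald ratio when a single instrument survives) gives the primary
    estimate, and — where instrument counts permit — weighted median/mode
    (>=3) and the pleiotropy RSS outlier test (>=4) are run as sensitivity
    analyses. Bonferroni correction uses the number of estimates actually
    produced. Oriented significant estimates are compared with the trial's
    trait directions. One pair failing never aborts the run.
    """
    outcome_types = outcome_types or {}
    est_rows, sens_rows, excluded = [], [], []
    records: list[tuple[TrialProteinEffect, str, MREstimate, MREstimate, int]] = []
    rng = np.random.default_rng(seed)

    for protein in off_target_proteins:
        g = protein.gene_symbol
        iset = instrument_sets.get(g)
        if iset is None or len(iset) == 0:
            excluded.append({"protein": g, "stage": "instruments", "reason": "no_instruments"})
            continue
        if protein.log2_fold_change == 0:
            excluded.append({"protein": g, "stage": "orientation",
                             "reason": "zero_log2fc_direction_undefined"})
            continue
        exposure = iset.pairs.rename(columns={
            "beta_exp": "beta", "se_exp": "se", "p_exp": "p",
            "eaf_exp": "eaf", "n_exp": "n"})
        for outcome, stats in outcome_stats.items():
            try:
                harm = harmonize(exposure, stats, palindrome_eaf_limit)
                if harm.pairs.empty:
                    excluded.append({"protein": g, "stage": f"harmonize:{outcome}",
                                     "reason": "no_shared_variants"})
                    continue
                raw = estimators.estimate_pairs(harm.pairs, "ivw_fixed")
                oriented = orient_to_trial(raw, protein)
                f_min_used = float(((harm.pairs["beta_exp"] / harm.pairs["se_exp"]) ** 2).min())
                records.append((protein, outcome, raw, oriented, f_min_used))
                if sensitivity:
                    alts = _sensitivity_suite(harm.pairs, bootstrap_reps, presso_sims,
                                              int(rng.integers(2**31 - 1)))
                    for alt in alts:
                        ok, _ = sensitivity_consistency(raw, [alt])
                        sens_rows.append({"protein": g, "outcome": outcome,
                                          "method": alt.method, "beta": alt.beta,
                                          "se": alt.se, "p": alt.pvalue,
                                          "consistent_with_ivw": int(ok)})
            except Exception as exc:  # a single pair's failure never aborts the run
                logger.warning("forward MR failed for %s-%s: %s", g, outcome, exc)
                excluded.append({"protein": g, "stage": f"estimate:{outcome}",
                                 "reason": repr(exc)})

    n_tests = len(records)
    threshold = bonferroni_threshold(n_tests, alpha) if n_tests else float("nan")
    concordance = []
    significant = set()
    for protein, outcome, raw, oriented, f_min_used in records:
        sig = raw.pvalue < threshold
        est_rows.append({
            "protein": protein.gene_symbol, "seq_id": protein.seq_id, "outcome": outcome,
            "n_inst": raw.n_instruments, "f_stat": f_min_used,
            "log2fc": protein.log2_fold_change,
            "beta_raw": raw.beta, "beta": oriented.beta, "se": oriented.se,
            "p": oriented.pvalue, "significant": int(sig),
            "outcome_type": outcome_types.get(outcome, "continuous"),
        })
        if sig:
            significant.add(protein.gene_symbol)
            tdir = trial_directions.get(outcome, TrialOutcomeDirection(outcome))
            concordance.append(classify_concordance(
                oriented, tdir, protein.gene_symbol,
                outcome_types.get(outcome, "continuous")))
    est_cols = ["protein", "seq_id", "outcome", "n_inst", "f_stat", "log2fc", "beta_raw",
                "beta", "se", "p", "significant", "outcome_type"]
    sens_cols = ["protein", "outcome", "method", "beta", "se", "p", "consistent_with_ivw"]
    return ForwardResult(
        estimates=pd.DataFrame(est_rows, columns=est_cols),
        concordance=concordance,
        sensitivity=pd.DataFrame(sens_rows, columns=sens_cols),
        threshold=threshold, n_tests=n_tests,
        excluded=pd.DataFrame(excluded, columns=["protein", "stage", "reason"]),
        significant_proteins=significant,
    )


def _sensitivity_suite(pairs, bootstrap_reps, presso_sims, seed) -> list[MREstimate]:
    bx, bx_se, by, by_se = estimators.pairs_arrays(pairs)
    out = []
    if bx.size >= 3:
        out.append(estimators.weighted_median(bx, bx_se, by, by_se, bootstrap_reps, seed))
        out.append(estimators.weighted_mode(bx, bx_se, by, by_se,
                                            bootstrap_reps=bootstrap_reps, seed=seed))
    if bx.size >= 4:
        try:
            out.append(estimators.mr_presso(bx, bx_se, by, by_se, presso_sims, seed=seed))
        except InsufficientInstrumentsError:
            pass
    return out


def sensitivity_consistency(primary: MREstimate, alternates: list[MREstimate],
                            ci_level: float = 0.95, require_sign: bool = True,
                            require_overlap: bool = True) -> tuple[bool, pd.DataFrame]:
    """Do the alternate estimators agree with the primary one?

    Consistent iff every alternate shares the primary's sign (when
    ``require_sign``) and its confidence interval overlaps the primary's
    (when ``require_overlap``); alternates with undefined SEs only face
    the sign check. Returns (flag, per-estimator report).
    """
    if not alternates:
        raise ValueError("at least one alternate estimate is required")
    lo_p, hi_p = primary.ci(ci_level)
    rows, ok = [], True
    for alt in alternates:
        sign_ok = (np.sign(alt.beta) == np.sign(primary.beta)) or primary.beta == 0
        if np.isfinite(alt.se):
            lo_a, hi_a = alt.ci(ci_level)
            overlap_ok = (lo_a <= hi_p) and (lo_p <= hi_a)
        else:
            overlap_ok = True
        this_ok = (sign_ok or not require_sign) and (overlap_ok or not require_overlap)
        ok = ok and this_ok
        rows.append({"method": alt.method, "beta": alt.beta, "se": alt.se,
                     "p": alt.pvalue, "consistent": int(this_ok)})
    report = pd.DataFrame([{"method": primary.method, "beta": primary.beta,
                            "se": primary.se, "p": primary.pvalue, "consistent": 1}] + rows)
    return ok, report


@dataclass
class ReverseResult:
    """Reverse (outcome -> proteome) MR summary."""

    estimates: pd.DataFrame                     # outcome, protein, beta, se, p, significant
    significant_by_outcome: dict[str, set]      # outcome -> proteins
    outcomes_by_protein: dict[str, set]         # protein -> outcomes
    intersection_counts: pd.DataFrame           # outcome-combination -> n proteins (upset data)
    category_counts: dict[str, int]             # category -> n distinct proteins
    threshold: float
    n_tests: int

    @property
    def significant_proteins(self) -> set:
        return set(self.outcomes_by_protein)


def run_reverse_mr(
    outcome_instruments: dict[str, pd.DataFrame],
    protein_stats: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    palindrome_eaf_limit: float = 0.42,
    categories: dict[str, str] | None = None,
) -> ReverseResult:
    """Estimate every outcome -> protein effect (reverse MR).

    ``outcome_instruments`` holds, per outcome, its genome-wide
    significant clumped instruments in canonical variant-table form (the
    same clumping parameters as the forward pass, without any cis
    restriction); ``protein_stats`` the full per-protein association
    tables. Bonferroni correction over the realized test count. Emits
    per-outcome significant protein sets, per-protein outcome sets, and
    the upset-style intersection counts over outcome combinations.
    """
    categories = categories if categories is not None else OUTCOME_CATEGORIES
    results = []
    for outcome, instruments in outcome_instruments.items():
        for protein, stats in protein_stats.items():
            harm = harmonize(instruments, stats, palindrome_eaf_limit)
            if harm.pairs.empty:
                continue
            est = estimators.estimate_pairs(harm.pairs, "ivw_fixed")
            results.append({"outcome": outcome, "protein": protein, "beta": est.beta,
                            "se": est.se, "p": est.pvalue, "n_inst": est.n_instruments})
    frame = pd.DataFrame(results, columns=["outcome", "protein", "beta", "se", "p", "n_inst"])
    n_tests = len(frame)
    threshold = bonferroni_threshold(n_tests, alpha) if n_tests else float("nan")
    frame["significant"] = (frame["p"] < threshold).astype(int) if n_tests else []

    sig_by_outcome: dict[str, set] = {o: set() for o in outcome_instruments}
    by_protein: dict[str, set] = {}
    for row in frame[frame.get("significant", pd.Series(dtype=int)) == 1].itertuples():
        sig_by_outcome[row.outcome].add(row.protein)
        by_protein.setdefault(row.protein, set()).add(row.outcome)

    combo_counts: dict[tuple, int] = {}
    for protein, outs in by_protein.items():
        combo_counts[tuple(sorted(outs))] = combo_counts.get(tuple(sorted(outs)), 0) + 1
    inter = pd.DataFrame(
        [{"outcomes": "|".join(combo), "degree": len(combo), "n_proteins": n}
         for combo, n in sorted(combo_counts.items())],
        columns=["outcomes", "degree", "n_proteins"])

    cat_counts: dict[str, int] = {}
    for cat in sorted(set(categories.values())):
        prots = set()
        for outcome, s in sig_by_outcome.items():
            if categories.get(outcome) == cat:
                prots |= s
        cat_counts[cat] = len(prots)
    return ReverseResult(estimates=frame, significant_by_outcome=sig_by_outcome,
                         outcomes_by_protein=by_protein, intersection_counts=inter,
                         category_counts=cat_counts, threshold=threshold, n_tests=n_tests)


def union_count(sets: dict[str, set]) -> int:
    """|union| via inclusion-exclusion over the per-category sets (checkable identity)."""
    names = list(sets)
    total = 0
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inter = set(sets[combo[0]])
            for name in combo[1:]:
                inter &= sets[name]
            total += (-1) ** (k + 1) * len(inter)
    return total


def classify_mediators(forward_significant: set[str],
                       reverse_significant: set[str],
                       all_proteins: list[str] | None = None) -> list[MediatorClassification]:
    """Label proteins as upstream mediators, bidirectional, consequences, or unclassified.

    A forward-significant protein untouched by any outcome in reverse MR
    is an upstream mediator; touched both ways is bidirectional; only
    reverse-significant is a downstream consequence.
    """
    universe = sorted(set(all_proteins) if all_proteins is not None
                      else forward_significant | reverse_significant)
    return [MediatorClassification(p, p in forward_significant, p in reverse_significant)
            for p in universe]
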