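"""cis-pQTL instrument construction.

The filter chain is fixed: cis-region + significance selection in the
discovery study, greedy LD clumping, effect extraction from an independent
estimation study (avoiding winner's curse), the weak-instrument F filter,
and the cross-protein specificity filter. Each stage appends a provenance
record (stage, n_in, n_out) so stage-wise conservation can be audited.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ld import LDMatrix
from .types import InstrumentSet, TrialProteinEffect

#: Genome-wide significance threshold used for instrument selection.
GENOME_WIDE_P = 5e-8


def select_cis_variants(assocs: pd.DataFrame, gene_chrom: str, gene_start: int,
                        gene_end: int, cis_window_bp: int = 500_000,
                        p_threshold: float = GENOME_WIDE_P) -> pd.DataFrame:
    """Variants within the cis window of the gene body passing p < p_threshold.

    The window is the closed interval
    [gene_start - cis_window_bp, gene_end + cis_window_bp]; the p-value
    cut is strict (p exactly at the threshold is dropped).
    """
    lo, hi = gene_start - cis_window_bp, gene_end + cis_window_bp
    keep = (
        (assocs["chr"].astype(str) == str(gene_chrom))
        & (assocs["pos"] >= lo)
        & (assocs["pos"] <= hi)
        & (assocs["p"] < p_threshold)
    )
    return assocs.loc[keep].reset_index(drop=True)


def ld_clump(assocs: pd.DataFrame, ld: LDMatrix, r2_threshold: float = 0.001,
             window_kb: int = 10_000) -> pd.DataFrame:
    """Greedy p-value-ordered LD clumping.

    Variants are visited by ascending p (ties: position, then variant_id);
    a variant is kept iff its r2 with every already-kept variant within
    ``window_kb`` (pairwise distance) is strictly below ``r2_threshold``.
    Variants absent from ``ld`` are treated as independent. Output is
    sorted by (chr, pos).
    """
    if assocs.empty:
        return assocs.copy()
    order = assocs.sort_values(["p", "pos", "variant_id"], kind="mergesort")
    kept: list[pd.Series] = []
    window_bp = window_kb * 1000
    for _, cand in order.iterrows():
        ok = True
        for prev in kept:
            same_chr = str(prev["chr"]) == str(cand["chr"])
            in_window = same_chr and abs(int(prev["pos"]) - int(cand["pos"])) <= window_bp
            if in_window and ld.get(cand["variant_id"], prev["variant_id"]) >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(cand)
    out = pd.DataFrame(kept)
    return out.sort_values(["chr", "pos", "variant_id"]).reset_index(drop=True)


def split_sample_effects(discovery_selection: pd.DataFrame,
                         estimation_stats: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Swap in estimation-study effects for variants selected in discovery.

    Selection (which variants are instruments) is decided in the discovery
    study; effect sizes entering estimation come exclusively from the
    independent estimation study, which removes winner's-curse bias in the
    instrument-exposure effects. Estimation rows whose alleles are swapped
    relative to discovery are sign-flipped onto the discovery effect
    allele; variants absent from the estimation study (or with
    irreconcilable alleles) are dropped with a logged reason.

    Returns ``(effects, dropped)`` where ``dropped`` has columns
    (variant_id, reason).
    """
    est_by_id = {r.variant_id: r for r in estimation_stats.itertuples(index=False)}
    rows, dropped = [], []
    for d in discovery_selection.itertuples(index=False):
        e = est_by_id.get(d.variant_id)
        if e is None:
            dropped.append({"variant_id": d.variant_id, "reason": "absent_from_estimation"})
            continue
        if (e.ea, e.oa) == (d.ea, d.oa):
            beta, eaf = e.beta, e.eaf
        elif (e.ea, e.oa) == (d.oa, d.ea):
            beta = -e.beta
            eaf = e.eaf if np.isnan(e.eaf) else 1.0 - e.eaf
        else:
            dropped.append({"variant_id": d.variant_id, "reason": "allele_mismatch"})
            continue
        rows.append({"variant_id": d.variant_id, "chr": d.chr, "pos": d.pos,
                     "ea": d.ea, "oa": d.oa, "beta": beta, "se": e.se, "p": e.p,
                     "eaf": eaf, "n": e.n})
    cols = list(discovery_selection.columns)
    return (pd.DataFrame(rows, columns=cols),
            pd.DataFrame(dropped, columns=["variant_id", "reason"]))


def f_statistic(beta, se):
    """Single-variant instrument-strength F, the squared Wald z: (beta/se)^2."""
    return (np.asarray(beta, float) / np.asarray(se, float)) ** 2


def filter_weak_instruments(instruments: InstrumentSet, f_min: float = 10.0) -> InstrumentSet:
    """Drop instruments with F below ``f_min`` (F exactly at f_min is kept)."""
    n_in = len(instruments)
    keep = instruments.f_statistics >= f_min
    out = InstrumentSet(
        protein=instruments.protein,
        pairs=instruments.pairs.loc[keep].reset_index(drop=True),
        trial_effect=instruments.trial_effect,
        provenance=list(instruments.provenance),
    )
    out.log("f_filter", n_in, len(out), f"f_min={f_min}")
    return out


def cross_protein_pleiotropy_filter(
    instruments: InstrumentSet,
    all_protein_stats: dict[str, pd.DataFrame],
) -> InstrumentSet:
    """Remove variants more strongly associated with another protein.

    A variant is removed iff any other protein's association p-value at
    that variant is strictly smaller than the target protein's p-value
    there (ties are kept). This guards the exclusion-restriction
    assumption against instruments acting through other proteins.
    """
    n_in = len(instruments)
    target = instruments.protein
    other_p: dict[str, float] = {}
    for prot, stats in all_protein_stats.items():
        if prot == target:
            continue
        for r in stats.itertuples(index=False):
            p = other_p.get(r.variant_id)
            if p is None or r.p < p:
                other_p[r.variant_id] = r.p
    # the comparison uses the same (discovery) study on both sides when the
    # target's own table is supplied; otherwise the estimation p is the fallback
    target_p: dict[str, float] = {}
    if target in all_protein_stats:
        for r in all_protein_stats[target].itertuples(index=False):
            target_p[r.variant_id] = r.p
    keep = []
    for _, row in instruments.pairs.iterrows():
        vid = row["variant_id"]
        own = target_p.get(vid, row["p_exp"])
        keep.append(not (other_p.get(vid, np.inf) < own))
    out = InstrumentSet(
        protein=target,
        pairs=instruments.pairs.loc[keep].reset_index(drop=True),
        trial_effect=instruments.trial_effect,
        provenance=list(instruments.provenance),
    )
    out.log("cross_protein_pleiotropy", n_in, len(out))
    return out


def resolve_aptamers(trial_effects: list[TrialProteinEffect],
                     discovery_stats: dict[str, pd.DataFrame]) -> list[TrialProteinEffect]:
    """Pick one aptamer per protein: the one with the smallest discovery pQTL p.

    ``discovery_stats`` is keyed by seq_id. Ties (and aptamers with no
    discovery coverage) break by lexicographic seq_id.
    """
    best: dict[str, TrialProteinEffect] = {}
    score: dict[str, float] = {}
    for eff in sorted(trial_effects, key=lambda t: t.seq_id):
        stats = discovery_stats.get(eff.seq_id)
        p = float(stats["p"].min()) if stats is not None and len(stats) else np.inf
        key = eff.gene_symbol
        if key not in best or p < score[key]:
            best[key], score[key] = eff, p
    return [best[k] for k in sorted(best)]


def build_instrument_set(
    protein: str,
    discovery_stats: pd.DataFrame,
    estimation_stats: pd.DataFrame,
    gene_chrom: str,
    gene_start: int,
    gene_end: int,
    ld: LDMatrix,
    all_protein_stats: dict[str, pd.DataFrame] | None = None,
    trial_effect: TrialProteinEffect | None = None,
    cis_window_bp: int = 500_000,
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = 0.001,
    clump_window_kb: int = 10_000,
    f_min: float = 10.0,
) -> InstrumentSet:
    """Run the full fixed filter chain for one protein.

    Order: cis + significance selection (discovery) -> LD clumping ->
    estimation-study effect extraction -> F filter -> cross-protein
    specificity filter. The returned set's ``pairs`` table holds the
    exposure side only (beta_exp, se_exp, ...); outcomes are attached
    later by harmonization.
    """
    iset = InstrumentSet(protein=protein, pairs=pd.DataFrame(), trial_effect=trial_effect)
    cis = select_cis_variants(discovery_stats, gene_chrom, gene_start, gene_end,
                              cis_window_bp, p_threshold)
    iset.log("cis_significance", len(discovery_stats), len(cis),
             f"window={cis_window_bp}bp p<{p_threshold}")
    clumped = ld_clump(cis, ld, r2_threshold, clump_window_kb)
    iset.log("ld_clump", len(cis), len(clumped),
             f"r2<{r2_threshold} window={clump_window_kb}kb")
    effects, dropped = split_sample_effects(clumped, estimation_stats)
    iset.log("estimation_extract", len(clumped), len(effects),
             ";".join(dropped["reason"].unique()) if len(dropped) else "")
    pairs = effects.rename(columns={"beta": "beta_exp", "se": "se_exp", "p": "p_exp",
                                    "eaf": "eaf_exp", "n": "n_exp"})
    iset.pairs = pairs.reset_index(drop=True)
    iset = filter_weak_instruments(iset, f_min)
    if all_protein_stats is not None:
        iset = cross_protein_pleiotropy_filter(iset, all_protein_stats)
    return iset
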