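"""Importable implementations of the command-line entry points.

Each ``cmd_*`` function is a thin orchestration over the library modules:
it loads the inputs named in the configuration, runs the corresponding
pipeline stage, and writes delimited result tables plus a run manifest to
the output directory. The CLI in :mod:`proteomr.cli` only parses flags and
maps exceptions to exit codes.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .config import AnalysisConfig
from .instruments import build_instrument_set, ld_clump, resolve_aptamers
from .io import read_summary_stats, read_trial_directions, read_trial_effects
from .ld import LDMatrix
from .pipeline import (
    classify_mediators,
    exclude_lipid_mediated,
    run_forward_mr,
    run_reverse_mr,
)
from . import estimators
from .io import harmonize
from .reporting import RunManifest
from .simulate import SimulationScenario, write_bundle


def _split_by(df: pd.DataFrame, key: str) -> dict[str, pd.DataFrame]:
    return {str(k): g.drop(columns=[key]).reset_index(drop=True)
            for k, g in df.groupby(key, sort=True)}


def load_bundle(config: AnalysisConfig) -> dict:
    """Read every input table named in ``config.inputs`` into memory."""
    config.require_inputs()
    inputs = config.inputs
    discovery = _split_by(pd.read_csv(inputs["discovery"], sep="\t"), "protein")
    estimation = _split_by(pd.read_csv(inputs["estimation"], sep="\t"), "protein")
    outcomes = {name: read_summary_stats(path).data
                for name, path in inputs["outcomes"].items()}
    return {
        "discovery": {p: _canon(df) for p, df in discovery.items()},
        "estimation": {p: _canon(df) for p, df in estimation.items()},
        "outcomes": outcomes,
        "ld": LDMatrix.from_long_file(inputs["ld"]),
        "trial_effects": read_trial_effects(inputs["trial_effects"]),
        "trial_directions": {d.outcome_name: d
                             for d in read_trial_directions(inputs["trial_directions"])},
        "gene_map": pd.read_csv(inputs["gene_map"], sep="\t", dtype={"chr": str}),
    }


def _canon(df: pd.DataFrame) -> pd.DataFrame:
    from .types import CANONICAL_COLUMNS

    out = df.copy()
    out["chr"] = out["chr"].astype(str)
    return out.loc[:, CANONICAL_COLUMNS]


def _genome_wide_instruments(stats: pd.DataFrame, ld: LDMatrix,
                             config: AnalysisConfig) -> pd.DataFrame:
    sig = stats[stats["p"] < config.p_instrument].reset_index(drop=True)
    return ld_clump(sig, ld, config.clump_r2, config.clump_window_kb)


def cmd_simulate(scenario: SimulationScenario, out_dir, force: bool = False) -> dict:
    """Write a full synthetic bundle; refuses a non-empty target without force."""
    return write_bundle(scenario, out_dir, force=force)


def cmd_forward(config: AnalysisConfig, out_dir) -> dict:
    """Instrument selection -> forward MR -> orientation -> correction -> concordance."""
    bundle = load_bundle(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(command="forward", config=config.to_dict(),
                           seeds={"seed": config.seed})
    manifest.checksum_inputs(config.inputs)

    trial_effects = resolve_aptamers(
        bundle["trial_effects"],
        {t.seq_id: bundle["discovery"].get(t.gene_symbol) for t in bundle["trial_effects"]})
    manifest.add_stage("aptamer_resolution", len(bundle["trial_effects"]), len(trial_effects))

    lipid_names = config.inputs.get("lipid_outcomes", [])
    if lipid_names:
        lipid_results = {}
        for lipid in lipid_names:
            inst = _genome_wide_instruments(bundle["outcomes"][lipid], bundle["ld"], config)
            for protein, stats in bundle["estimation"].items():
                harm = harmonize(inst, stats, config.palindrome_eaf_limit)
                if harm.pairs.empty:
                    continue
                lipid_results[(lipid, protein)] = estimators.estimate_pairs(harm.pairs)
        on_target, proteins, _ = exclude_lipid_mediated(trial_effects, lipid_results,
                                                        config.alpha)
        manifest.add_stage("lipid_exclusion", len(trial_effects), len(proteins),
                           f"on_target={len(on_target)}")
    else:
        on_target, proteins = [], trial_effects

    isets = {}
    gene_map = bundle["gene_map"].set_index("protein")
    for t in proteins:
        g = t.gene_symbol
        if g not in gene_map.index or g not in bundle["discovery"]:
            continue
        row = gene_map.loc[g]
        isets[g] = build_instrument_set(
            g, bundle["discovery"][g], bundle["estimation"][g],
            str(row["chr"]), int(row["start"]), int(row["end"]), bundle["ld"],
            all_protein_stats=bundle["discovery"], trial_effect=t,
            cis_window_bp=config.cis_window_bp, p_threshold=config.p_instrument,
            r2_threshold=config.clump_r2, clump_window_kb=config.clump_window_kb,
            f_min=config.f_min)
    stage_totals: dict[str, list[int]] = {}
    for iset in isets.values():
        for rec in iset.provenance:
            t_in, t_out = stage_totals.setdefault(rec["stage"], [0, 0])
            stage_totals[rec["stage"]] = [t_in + rec["n_in"], t_out + rec["n_out"]]
    for stage, (n_in, n_out) in stage_totals.items():
        manifest.add_stage(f"instruments:{stage}", n_in, n_out)
    with_inst = sum(1 for s in isets.values() if len(s) > 0)
    manifest.add_stage("proteins_with_instruments", len(proteins), with_inst)

    result = run_forward_mr(
        proteins, isets, bundle["outcomes"], bundle["trial_directions"],
        alpha=config.alpha, palindrome_eaf_limit=config.palindrome_eaf_limit,
        bootstrap_reps=config.bootstrap_reps, presso_sims=config.presso_sims,
        seed=config.seed)
    manifest.add_stage("forward_tests", result.n_tests,
                       int(result.estimates["significant"].sum()) if result.n_tests else 0,
                       f"bonferroni_threshold={result.threshold:.6g}")

    paths = {"estimates": out / "forward_estimates.tsv",
             "concordance": out / "forward_concordance.tsv",
             "sensitivity": out / "forward_sensitivity.tsv",
             "excluded": out / "forward_excluded.tsv",
             "manifest": out / "forward_manifest.txt"}
    result.estimates.to_csv(paths["estimates"], sep="\t", index=False)
    result.concordance_frame().to_csv(paths["concordance"], sep="\t", index=False)
    result.sensitivity.to_csv(paths["sensitivity"], sep="\t", index=False)
    result.excluded.to_csv(paths["excluded"], sep="\t", index=False)
    manifest.write(paths["manifest"])
    return {"result": result, "paths": paths, "manifest": manifest,
            "on_target": on_target, "instrument_sets": isets}


def cmd_reverse(config: AnalysisConfig, out_dir) -> dict:
    """Reverse MR: outcome GWAS instruments (genome-wide, same clumping) on the proteome."""
    bundle = load_bundle(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(command="reverse", config=config.to_dict(),
                           seeds={"seed": config.seed})
    manifest.checksum_inputs(config.inputs)

    outcome_instruments = {}
    for name, stats in bundle["outcomes"].items():
        inst = _genome_wide_instruments(stats, bundle["ld"], config)
        outcome_instruments[name] = inst
        manifest.add_stage(f"reverse_instruments:{name}", len(stats), len(inst))

    result = run_reverse_mr(outcome_instruments, bundle["estimation"],
                            alpha=config.alpha,
                            palindrome_eaf_limit=config.palindrome_eaf_limit)
    n_sig = int(result.estimates["significant"].sum()) if result.n_tests else 0
    manifest.add_stage("reverse_tests", result.n_tests, n_sig,
                       f"bonferroni_threshold={result.threshold:.6g}")

    sig_rows = [{"outcome": o, "protein": p}
                for o, prots in sorted(result.significant_by_outcome.items())
                for p in sorted(prots)]
    paths = {"estimates": out / "reverse_estimates.tsv",
             "significant": out / "reverse_significant_sets.tsv",
             "intersections": out / "reverse_intersections.tsv",
             "categories": out / "reverse_category_counts.tsv",
             "manifest": out / "reverse_manifest.txt"}
    result.estimates.to_csv(paths["estimates"], sep="\t", index=False)
    pd.DataFrame(sig_rows, columns=["outcome", "protein"]).to_csv(
        paths["significant"], sep="\t", index=False)
    result.intersection_counts.to_csv(paths["intersections"], sep="\t", index=False)
    pd.DataFrame(sorted(result.category_counts.items()),
                 columns=["category", "n_proteins"]).to_csv(
        paths["categories"], sep="\t", index=False)
    manifest.write(paths["manifest"])
    return {"result": result, "paths": paths, "manifest": manifest}


def cmd_classify(forward_estimates, reverse_estimates, out_path) -> pd.DataFrame:
    """Mediator/consequence classification from forward and reverse result tables."""
    fwd = pd.read_csv(forward_estimates, sep="\t")
    rev = pd.read_csv(reverse_estimates, sep="\t")
    fwd_sig = set(fwd.loc[fwd["significant"] == 1, "protein"])
    rev_sig = set(rev.loc[rev["significant"] == 1, "protein"])
    universe = sorted(set(fwd["protein"]) | set(rev["protein"]))
    rows = [{"protein": c.protein, "forward_significant": int(c.forward_significant),
             "reverse_significant": int(c.reverse_significant), "class": c.label}
            for c in classify_mediators(fwd_sig, rev_sig, universe)]
    frame = pd.DataFrame(rows, columns=["protein", "forward_significant",
                                        "reverse_significant", "class"])
    frame.to_csv(out_path, sep="\t", index=False)
    return frame


def cmd_report(results_dir) -> str:
    """Human-readable summary of a results directory."""
    out = Path(results_dir)
    lines = []
    fwd = out / "forward_estimates.tsv"
    if fwd.exists():
        df = pd.read_csv(fwd, sep="\t")
        sig = df[df["significant"] == 1]
        lines += [f"forward MR: {len(df)} protein-outcome estimates, "
                  f"{sig['protein'].nunique()} significant proteins "
                  f"({len(sig)} significant pairs)"]
        conc = out / "forward_concordance.tsv"
        if conc.exists():
            c = pd.read_csv(conc, sep="\t")
            annotated = c[c["concordant"].notna()]
            lines += [f"concordance: {int((annotated['concordant'] == 1).sum())} of "
                      f"{len(annotated)} annotated significant pairs concordant"]
    rev = out / "reverse_estimates.tsv"
    if rev.exists():
        df = pd.read_csv(rev, sep="\t")
        sig = df[df["significant"] == 1]
        lines += [f"reverse MR: {len(df)} outcome-protein estimates, "
                  f"{sig['protein'].nunique()} proteins influenced by >=1 outcome"]
    med = out / "mediators.tsv"
    if med.exists():
        df = pd.read_csv(med, sep="\t")
        counts = df["class"].value_counts().to_dict()
        lines += [f"mediator classes: {counts}"]
    return "\n".join(lines) if lines else f"no result tables found in {out}"
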