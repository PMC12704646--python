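"""Synthetic two-sample GWAS / trial data with known ground truth.

The generator emulates the statistical structure the framework assumes: a
discovery and an estimation pQTL study drawn independently around the same
true per-allele variant effects, outcome GWAS whose variant effects are the
true causal effect times the variant's protein effect plus an optional
horizontal-pleiotropy term, a trial protein-change table whose signs follow
the simulated causal structure, and a block-diagonal LD matrix.

Per-variant standard errors follow the usual GWAS approximation for a
unit-variance trait, se = 1 / sqrt(2 f (1-f) n), so F-statistics scale
linearly with sample size and the F >= 10 filter behaves realistically.
Default sample sizes match the framework's intended use (a discovery
cohort of ~7,000, an estimation cohort of ~36,000, outcome GWAS of
~100,000). Alleles are drawn only from strand-unambiguous pairs so that
harmonization of simulated bundles is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ld import LDMatrix
from .types import CANONICAL_COLUMNS, Direction, TrialOutcomeDirection, TrialProteinEffect

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


@dataclass
class PleiotropySpec:
    """Horizontal-pleiotropy regime for the outcome path.

    kind: none | balanced | directional | outliers. ``magnitude`` is the
    scale of the direct variant -> outcome effect (outcome SD units);
    ``fraction`` the share of variants affected (directional/outliers).
    """

    kind: str = "none"
    magnitude: float = 0.0
    fraction: float = 0.4

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "none" or self.magnitude == 0.0:
            return np.zeros(n)
        if self.kind == "balanced":
            return rng.normal(0.0, self.magnitude, n)
        n_affected = int(round(self.fraction * n))
        idx = rng.choice(n, size=n_affected, replace=False)
        alpha = np.zeros(n)
        if self.kind == "directional":
            alpha[idx] = np.abs(rng.normal(self.magnitude, self.magnitude / 4, n_affected))
        elif self.kind == "outliers":
            alpha[idx] = self.magnitude
        else:
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        return alpha


@dataclass
class SimulationScenario:
    """Complete description of one synthetic study; scenario + seed fixes everything."""

    n_proteins: int = 20
    variants_per_protein: int = 5
    pqtl_effect_range: tuple[float, float] = (0.15, 0.5)
    discovery_n: int = 7_213
    estimation_n: int = 35_559
    outcome_n: int = 100_000
    outcomes: tuple[str, ...] = ("outcome_1", "outcome_2", "outcome_3")
    true_causal_effects: dict = field(default_factory=dict)  # (protein, outcome) -> theta
    pleiotropy: PleiotropySpec = field(default_factory=PleiotropySpec)
    ld_block_r2: float = 0.0
    lipid_effect_fraction: float = 0.35
    trial_log2fc_rule: dict = field(default_factory=dict)    # protein -> log2fc
    outcome_variants: int = 10                   # outcome-specific GWAS hits per outcome
    outcome_effect_range: tuple[float, float] = (0.1, 0.3)
    reverse_effects: dict = field(default_factory=dict)      # (outcome, protein) -> rho
    # True codes every pQTL effect allele as exposure-increasing (bx > 0), the
    # orientation under which directional pleiotropy actually biases the IVW
    pqtl_positive_effects: bool = False
    seed: int = 0

    def __post_init__(self):
        for name, n in (("discovery_n", self.discovery_n),
                        ("estimation_n", self.estimation_n),
                        ("outcome_n", self.outcome_n)):
            if n < 100:
                raise ValueError(f"{name} must be >= 100")
        self.proteins = [f"P{i + 1:03d}" for i in range(self.n_proteins)]
        if not self.true_causal_effects:
            # cycle through null, modest, and strong effects of either sign
            grid = [0.0, 0.1, -0.1, 0.3, -0.3]
            k = 0
            for p in self.proteins:
                for o in self.outcomes:
                    self.true_causal_effects[(p, o)] = grid[k % len(grid)]
                    k += 1
        if not self.trial_log2fc_rule:
            for i, p in enumerate(self.proteins):
                self.trial_log2fc_rule[p] = (0.05 + 0.01 * i) * (1 if i % 2 == 0 else -1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_causal_effects"] = {f"{p}|{o}": float(v)
                                    for (p, o), v in self.true_causal_effects.items()}
        d["reverse_effects"] = {f"{o}|{p}": float(v)
                                for (o, p), v in self.reverse_effects.items()}
        d["outcomes"] = list(self.outcomes)
        d["pqtl_effect_range"] = [float(x) for x in self.pqtl_effect_range]
        d["outcome_effect_range"] = [float(x) for x in self.outcome_effect_range]
        d.pop("proteins", None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationScenario":
        d = dict(d)
        tce = {}
        for key, v in (d.pop("true_causal_effects", {}) or {}).items():
            p, o = key.split("|")
            tce[(p, o)] = float(v)
        rev = {}
        for key, v in (d.pop("reverse_effects", {}) or {}).items():
            o, p = key.split("|")
            rev[(o, p)] = float(v)
        pl = d.pop("pleiotropy", {})
        if isinstance(pl, dict):
            pl = PleiotropySpec(**pl)
        d["outcomes"] = tuple(d.get("outcomes", ("outcome_1", "outcome_2", "outcome_3")))
        for key in ("pqtl_effect_range", "outcome_effect_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(true_causal_effects=tce, reverse_effects=rev, pleiotropy=pl, **d)


def _se(eaf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _gene_location(i: int) -> tuple[str, int, int]:
    """Deterministic genome layout: genes 30 Mb apart, cycling chromosomes 1-22."""
    chrom = str(i % 22 + 1)
    start = 1_000_000 + (i // 22) * 30_000_000 + (i % 22) * 0  # one slot per chr per cycle
    return chrom, start, start + 100_000


def gene_map(scenario: SimulationScenario) -> pd.DataFrame:
    """Protein -> gene-body coordinates used by the cis filter."""
    rows = []
    for i, p in enumerate(scenario.proteins):
        chrom, start, end = _gene_location(i)
        rows.append({"protein": p, "chr": chrom, "start": start, "end": end})
    return pd.DataFrame(rows)


def _zstats(rng, true_beta, se):
    return true_beta + rng.normal(0.0, 1.0, true_beta.shape) * se


def _finish(df: pd.DataFrame) -> pd.DataFrame:
    from scipy.stats import norm

    df["p"] = 2.0 * norm.sf(np.abs(df["beta"] / df["se"]))
    return df.loc[:, CANONICAL_COLUMNS]


def _variant_block(rng, chrom: str, start: int, end: int, m: int, effect_range,
                   positive_only: bool = False):
    pos = np.sort(rng.choice(np.arange(start, end), size=m, replace=False))
    eaf = rng.uniform(0.05, 0.95, m)
    lo, hi = effect_range
    signs = np.ones(m) if positive_only else rng.choice([-1.0, 1.0], m)
    beta_true = rng.uniform(lo, hi, m) * signs
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), m)
    ea = np.array([_ALLELE_PAIRS[k][0] for k in pair_idx])
    oa = np.array([_ALLELE_PAIRS[k][1] for k in pair_idx])
    vid = [f"{chrom}:{p}:{a}:{b}" for p, a, b in zip(pos, ea, oa)]
    return vid, pos, eaf, beta_true, ea, oa


def _outcome_location(k: int) -> tuple[str, int, int]:
    """Outcome-specific loci live at 200 Mb+, far from any simulated gene body."""
    chrom = str(k % 22 + 1)
    start = 200_000_000 + (k // 22) * 30_000_000
    return chrom, start, start + 1_000_000


def simulate_pqtl_studies(scenario: SimulationScenario):
    """Draw the discovery and estimation pQTL studies around shared true effects.

    Returns ``(discovery, estimation, truth)``. The per-protein tables
    contain that protein's cis variants plus every outcome-specific
    variant: the latter carry true protein effects rho * gamma when the
    scenario declares a reverse (outcome -> protein) effect rho, zero
    otherwise, so reverse MR has something real to find or correctly
    reject. ``truth`` has one row per variant: (variant_id, trait, kind
    in {cis_pqtl, outcome_gwas}, eaf, true_beta, chr, pos, ea, oa).
    """
    rng = np.random.default_rng(scenario.seed)
    truth_rows = []
    cis = {}
    for i, protein in enumerate(scenario.proteins):
        chrom, start, end = _gene_location(i)
        vid, pos, eaf, beta_true, ea, oa = _variant_block(
            rng, chrom, start, end, scenario.variants_per_protein,
            scenario.pqtl_effect_range, scenario.pqtl_positive_effects)
        cis[protein] = (vid, pos, eaf, beta_true, ea, oa, chrom)
        for j in range(len(vid)):
            truth_rows.append({"variant_id": vid[j], "trait": protein, "kind": "cis_pqtl",
                               "eaf": eaf[j], "true_beta": beta_true[j], "chr": chrom,
                               "pos": int(pos[j]), "ea": ea[j], "oa": oa[j]})
    out_variants = {}
    for k, outcome in enumerate(scenario.outcomes):
        chrom, start, end = _outcome_location(k)
        vid, pos, eaf, gamma, ea, oa = _variant_block(
            rng, chrom, start, end, scenario.outcome_variants,
            scenario.outcome_effect_range)
        out_variants[outcome] = (vid, pos, eaf, gamma, ea, oa, chrom)
        for j in range(len(vid)):
            truth_rows.append({"variant_id": vid[j], "trait": outcome,
                               "kind": "outcome_gwas", "eaf": eaf[j],
                               "true_beta": gamma[j], "chr": chrom,
                               "pos": int(pos[j]), "ea": ea[j], "oa": oa[j]})
    truth = pd.DataFrame(truth_rows)

    discovery, estimation = {}, {}
    for protein in scenario.proteins:
        vid, pos, eaf, beta_true, ea, oa, chrom = cis[protein]
        rows = {"variant_id": list(vid), "chr": [chrom] * len(vid), "pos": list(pos),
                "ea": list(ea), "oa": list(oa), "eaf": list(eaf),
                "true": list(beta_true)}
        for outcome in scenario.outcomes:
            o_vid, o_pos, o_eaf, gamma, o_ea, o_oa, o_chrom = out_variants[outcome]
            rho = scenario.reverse_effects.get((outcome, protein), 0.0)
            rows["variant_id"] += list(o_vid)
            rows["chr"] += [o_chrom] * len(o_vid)
            rows["pos"] += list(o_pos)
            rows["ea"] += list(o_ea)
            rows["oa"] += list(o_oa)
            rows["eaf"] += list(o_eaf)
            rows["true"] += list(rho * gamma)
        base = pd.DataFrame(rows)
        bt = base["true"].to_numpy()
        af = base["eaf"].to_numpy()
        for name, n, store in (("discovery", scenario.discovery_n, discovery),
                               ("estimation", scenario.estimation_n, estimation)):
            se = _se(af, n)
            df = base.drop(columns="true").assign(
                beta=_zstats(rng, bt, se), se=se, n=n)
            store[protein] = _finish(df)
    return discovery, estimation, truth


def simulate_outcome_stats(scenario: SimulationScenario, truth: pd.DataFrame):
    """Outcome GWAS per outcome.

    Per variant j and outcome k the true effect is: theta_{p,k} * beta_Xj
    plus the horizontal-pleiotropy term for protein-cis variants, gamma_j
    for the outcome's own loci, and zero for other outcomes' loci; sampling
    noise is scaled by 1/sqrt(2 f (1-f) outcome_n).
    """
    rng = np.random.default_rng(scenario.seed + 1)
    out = {}
    eaf = truth["eaf"].to_numpy()
    se_o = _se(eaf, scenario.outcome_n)
    bx = truth["true_beta"].to_numpy()
    is_cis = (truth["kind"] == "cis_pqtl").to_numpy()
    for outcome in scenario.outcomes:
        theta = np.array([scenario.true_causal_effects.get((t, outcome), 0.0)
                          for t in truth["trait"]])
        alpha = np.zeros(len(truth))
        alpha[is_cis] = scenario.pleiotropy.draw(rng, int(is_cis.sum()))
        own = ((truth["trait"] == outcome) & ~is_cis).to_numpy()
        by_true = np.where(is_cis, theta * bx + alpha, np.where(own, bx, 0.0))
        df = pd.DataFrame({
            "variant_id": truth["variant_id"], "chr": truth["chr"], "pos": truth["pos"],
            "ea": truth["ea"], "oa": truth["oa"],
            "beta": _zstats(rng, by_true, se_o), "se": se_o, "eaf": eaf,
            "n": scenario.outcome_n,
        })
        out[outcome] = _finish(df)
    return out


def simulate_trial_table(scenario: SimulationScenario):
    """Trial protein-change records plus outcome trait directions.

    Each protein's log2-fold change comes from the scenario's rule; each
    outcome's trait direction follows the sign of the aggregate induced
    effect sum_p theta_{p,outcome} * log2fc_p.
    """
    effects = [TrialProteinEffect(uniprot_id=f"U{p}", gene_symbol=p, seq_id=f"{1000 + i}_1",
                                  log2_fold_change=scenario.trial_log2fc_rule[p], fdr_p=0.01)
               for i, p in enumerate(scenario.proteins)]
    directions = []
    for o in scenario.outcomes:
        s = sum(scenario.true_causal_effects.get((p, o), 0.0) * scenario.trial_log2fc_rule[p]
                for p in scenario.proteins)
        d = Direction.UP if s > 0 else Direction.DOWN if s < 0 else Direction.UNOBSERVED
        directions.append(TrialOutcomeDirection(o, d))
    return effects, directions


def simulate_ld(scenario: SimulationScenario, truth: pd.DataFrame) -> LDMatrix:
    """Block-diagonal LD: within-trait-locus r2 = ld_block_r2, zero across loci."""
    ids = truth["variant_id"].tolist()
    n = len(ids)
    mat = np.zeros((n, n))
    start = 0
    for _, grp in truth.groupby("trait", sort=False):
        k = len(grp)
        mat[start:start + k, start:start + k] = scenario.ld_block_r2
        start += k
    np.fill_diagonal(mat, 1.0)
    return LDMatrix(ids, mat)


def write_bundle(scenario: SimulationScenario, out_dir, force: bool = False) -> dict:
    """Materialize the full synthetic bundle as delimited text files.

    Writes per-study summary statistics (all proteins stacked, with a
    ``protein`` column), per-outcome GWAS tables, the trial tables, the LD
    matrix (long format), the truth record, the gene map, and the
    scenario itself. Returns the path map.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    discovery, estimation, truth = simulate_pqtl_studies(scenario)
    outcomes = simulate_outcome_stats(scenario, truth)
    effects, directions = simulate_trial_table(scenario)
    ld = simulate_ld(scenario, truth)

    def stack(d):
        frames = []
        for protein, df in d.items():
            f = df.copy()
            f.insert(0, "protein", protein)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    paths = {}
    for name, frame in (("discovery", stack(discovery)), ("estimation", stack(estimation)),
                        ("truth", truth), ("gene_map", gene_map(scenario))):
        paths[name] = out / f"{name}.tsv"
        frame.to_csv(paths[name], sep="\t", index=False)
    for o, df in outcomes.items():
        paths[f"outcome:{o}"] = out / f"outcome_{o}.tsv"
        df.to_csv(paths[f"outcome:{o}"], sep="\t", index=False)
    trial = pd.DataFrame([{"uniprot": e.uniprot_id, "gene": e.gene_symbol, "seq_id": e.seq_id,
                           "log2fc": e.log2_fold_change, "fdr": e.fdr_p} for e in effects])
    paths["trial_effects"] = out / "trial_effects.tsv"
    trial.to_csv(paths["trial_effects"], sep="\t", index=False)
    tdir = pd.DataFrame([{"outcome": d.outcome_name, "direction": d.direction.value}
                         for d in directions])
    paths["trial_directions"] = out / "trial_directions.tsv"
    tdir.to_csv(paths["trial_directions"], sep="\t", index=False)
    paths["ld"] = out / "ld.tsv"
    ld.to_long_frame().to_csv(paths["ld"], sep="\t", index=False)
    paths["scenario"] = out / "scenario.yaml"
    with open(paths["scenario"], "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=True)
    return paths
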