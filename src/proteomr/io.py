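"""Readers, validation and allele harmonization for GWAS/pQTL summary statistics.

Input files are tab- or comma-delimited with a header row. Column names are
resolved through a user-supplied ``column_map`` (source name -> canonical
name) on top of a built-in set of synonyms covering GWAS-catalog-style
headers. Rows that violate the schema are counted and reported per reason,
never silently dropped.

Harmonization aligns an outcome table to the exposure table's effect
alleles: swapped alleles flip the outcome beta (and complement its EAF),
opposite-strand records are complemented first, and palindromic (A/T, C/G)
variants are kept only when both allele frequencies identify the shared
allele unambiguously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ConfigurationError, ValidationError
from .types import CANONICAL_COLUMNS, Direction, TrialOutcomeDirection, TrialProteinEffect

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Built-in header synonyms (lower-cased source -> canonical).
DEFAULT_SYNONYMS = {
    "variant_id": "variant_id", "snp": "variant_id", "rsid": "variant_id",
    "markername": "variant_id", "id": "variant_id", "variant": "variant_id",
    "chr": "chr", "chrom": "chr", "chromosome": "chr",
    "pos": "pos", "bp": "pos", "position": "pos", "base_pair_location": "pos",
    "ea": "ea", "effect_allele": "ea", "a1": "ea", "alt": "ea",
    "oa": "oa", "other_allele": "oa", "a2": "oa", "non_effect_allele": "oa", "ref": "oa",
    "beta": "beta", "b": "beta", "effect": "beta",
    "se": "se", "standard_error": "se", "stderr": "se",
    "p": "p", "pval": "p", "pvalue": "p", "p_value": "p",
    "eaf": "eaf", "af": "eaf", "effect_allele_frequency": "eaf", "freq": "eaf", "maf": "eaf",
    "n": "n", "samplesize": "n", "sample_size": "n",
}

_REQUIRED = ("variant_id", "ea", "oa", "beta", "se")


def is_palindromic(ea: str, oa: str) -> bool:
    """True for strand-ambiguous allele pairs (A/T or C/G)."""
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


def canonical_variant_id(chrom, pos, a1: str, a2: str) -> str:
    """chr:pos:allele1:allele2 with alleles in lexicographic order."""
    lo, hi = sorted([str(a1).upper(), str(a2).upper()])
    return f"{chrom}:{int(pos)}:{lo}:{hi}"


@dataclass
class ReadResult:
    """A parsed table plus per-reason counts of rejected rows."""

    data: pd.DataFrame
    n_input: int
    dropped: dict = field(default_factory=dict)
    row_errors: list = field(default_factory=list)
    warnings: dict = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return int(sum(self.dropped.values()))


def _read_delimited(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)


def read_summary_stats(path, column_map: dict | None = None) -> ReadResult:
    """Read one GWAS/pQTL summary-statistics file into the canonical schema.

    Parameters
    ----------
    path : str or path
        Tab- or comma-delimited file with a header row.
    column_map : dict, optional
        Source-column -> canonical-name overrides, applied before the
        built-in synonyms.

    Returns
    -------
    ReadResult
        ``data`` holds validated rows in canonical column order; invalid
        rows are tallied in ``dropped`` with per-row detail in
        ``row_errors``. A missing p-value is imputed from the Wald
        z-statistic, 2*Phi(-|beta/se|).

    Raises
    ------
    ConfigurationError
        If a required column cannot be resolved; the message names it.
    """
    raw = _read_delimited(path)
    colmap = {}
    user = {str(k).lower(): v for k, v in (column_map or {}).items()}
    for col in raw.columns:
        key = str(col).strip().lower()
        if key in user:
            colmap[col] = user[key]
        elif key in DEFAULT_SYNONYMS:
            colmap[col] = DEFAULT_SYNONYMS[key]
    frame = raw.rename(columns=colmap)
    frame = frame.loc[:, ~frame.columns.duplicated()]

    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"required column(s) {missing} not resolvable in {path}; "
            f"available headers: {list(raw.columns)}"
        )
    for c in CANONICAL_COLUMNS:
        if c not in frame.columns:
            frame[c] = ""

    dropped: dict[str, int] = {}
    warnings: dict[str, int] = {}
    row_errors: list[tuple[int, str]] = []
    rows = []
    for idx, row in frame.iterrows():
        reason = _validate_row(row)
        if reason is not None:
            dropped[reason] = dropped.get(reason, 0) + 1
            row_errors.append((int(idx), reason))
            continue
        rec = _coerce_row(row)
        if np.isnan(rec["p"]):
            rec["p"] = 2.0 * norm.sf(abs(rec["beta"] / rec["se"]))
        elif not _p_consistent(rec["beta"], rec["se"], rec["p"]):
            warnings["p_inconsistent_with_z"] = warnings.get("p_inconsistent_with_z", 0) + 1
        rows.append(rec)

    data = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    return ReadResult(data=data, n_input=len(frame), dropped=dropped,
                      row_errors=row_errors, warnings=warnings)


def _num(value) -> float:
    s = str(value).strip()
    if s == "" or s.lower() in ("na", "nan", "null", "."):
        return float("nan")
    return float(s)


def _validate_row(row) -> str | None:
    try:
        beta = _num(row["beta"])
        se = _num(row["se"])
    except ValueError:
        return "non_numeric_beta_or_se"
    if np.isnan(beta) or np.isnan(se):
        return "missing_beta_or_se"
    if se <= 0:
        return "nonpositive_se"
    ea, oa = str(row["ea"]).strip().upper(), str(row["oa"]).strip().upper()
    if not ea or not oa or any(ch not in "ACGT" for ch in ea + oa):
        return "invalid_alleles"
    if ea == oa:
        return "identical_alleles"
    try:
        p = _num(row["p"])
    except ValueError:
        return "non_numeric_p"
    if not np.isnan(p) and not (0.0 <= p <= 1.0):
        return "p_out_of_range"
    try:
        eaf = _num(row["eaf"])
    except ValueError:
        return "non_numeric_eaf"
    if not np.isnan(eaf) and not (0.0 <= eaf <= 1.0):
        return "eaf_out_of_range"
    return None


def _coerce_row(row) -> dict:
    ea, oa = str(row["ea"]).strip().upper(), str(row["oa"]).strip().upper()
    chrom = str(row["chr"]).strip()
    pos_raw = str(row["pos"]).strip()
    pos = int(float(pos_raw)) if pos_raw else -1
    vid = str(row["variant_id"]).strip()
    if not vid:
        vid = canonical_variant_id(chrom, pos, ea, oa)
    n_raw = str(row["n"]).strip()
    return {
        "variant_id": vid, "chr": chrom, "pos": pos, "ea": ea, "oa": oa,
        "beta": _num(row["beta"]), "se": _num(row["se"]), "p": _num(row["p"]),
        "eaf": _num(row["eaf"]), "n": int(float(n_raw)) if n_raw else -1,
    }


def _p_consistent(beta, se, p, log10_tol: float = 1.0) -> bool:
    # printed p-values are rounded, so compare on the log10 scale, generously
    expected = 2.0 * norm.sf(abs(beta / se))
    lo = 1e-300
    return abs(np.log10(max(p, lo)) - np.log10(max(expected, lo))) <= log10_tol


def write_summary_stats(df: pd.DataFrame, path) -> None:
    """Write a canonical variant table (tab-delimited, fixed column order)."""
    df.loc[:, CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizeResult:
    """Paired exposure/outcome rows plus the drop log."""

    pairs: pd.DataFrame
    dropped: pd.DataFrame  # columns: variant_id, reason
    n_exposure: int
    n_shared: int


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindrome_eaf_limit: float = 0.42) -> HarmonizeResult:
    """Align outcome summary statistics to the exposure's effect alleles.

    For each variant shared by ``variant_id``: if the outcome's effect
    allele equals the exposure's other allele the outcome beta is negated
    and its EAF complemented; alleles that only match after strand
    complementation are complemented first; anything else is dropped as
    irreconcilable. Palindromic variants are retained only if both EAFs are
    present, on the same side of 0.5 (after alignment) and outside
    ``[palindrome_eaf_limit, 1 - palindrome_eaf_limit]``.

    Returns a :class:`HarmonizeResult`; zero shared variants yields an
    empty ``pairs`` table, not an error.
    """
    out_by_id = {r.variant_id: r for r in outcome.itertuples(index=False)}
    pairs, dropped = [], []
    n_shared = 0
    for e in exposure.itertuples(index=False):
        o = out_by_id.get(e.variant_id)
        if o is None:
            continue
        n_shared += 1
        o_ea, o_oa, flip = o.ea, o.oa, None
        if (o_ea, o_oa) == (e.ea, e.oa):
            flip = False
        elif (o_ea, o_oa) == (e.oa, e.ea):
            flip = True
        else:
            c_ea = "".join(_COMPLEMENT.get(ch, "N") for ch in o_ea)
            c_oa = "".join(_COMPLEMENT.get(ch, "N") for ch in o_oa)
            if (c_ea, c_oa) == (e.ea, e.oa):
                flip = False
            elif (c_ea, c_oa) == (e.oa, e.ea):
                flip = True
        if flip is None:
            dropped.append({"variant_id": e.variant_id, "reason": "allele_mismatch"})
            continue
        beta_out = -o.beta if flip else o.beta
        eaf_out = o.eaf if np.isnan(o.eaf) else (1.0 - o.eaf if flip else o.eaf)
        if is_palindromic(e.ea, e.oa):
            lim = palindrome_eaf_limit
            if np.isnan(e.eaf) or np.isnan(eaf_out):
                dropped.append({"variant_id": e.variant_id, "reason": "palindromic_missing_eaf"})
                continue
            same_side = (e.eaf - 0.5) * (eaf_out - 0.5) > 0
            outside = all(f < lim or f > 1 - lim for f in (e.eaf, eaf_out))
            if not (same_side and outside):
                dropped.append({"variant_id": e.variant_id, "reason": "palindromic_ambiguous"})
                continue
        pairs.append({
            "variant_id": e.variant_id, "chr": e.chr, "pos": e.pos, "ea": e.ea, "oa": e.oa,
            "beta_exp": e.beta, "se_exp": e.se, "p_exp": e.p, "eaf_exp": e.eaf, "n_exp": e.n,
            "beta_out": beta_out, "se_out": o.se, "p_out": o.p, "eaf_out": eaf_out, "n_out": o.n,
        })
    pair_cols = ["variant_id", "chr", "pos", "ea", "oa",
                 "beta_exp", "se_exp", "p_exp", "eaf_exp", "n_exp",
                 "beta_out", "se_out", "p_out", "eaf_out", "n_out"]
    return HarmonizeResult(
        pairs=pd.DataFrame(pairs, columns=pair_cols),
        dropped=pd.DataFrame(dropped, columns=["variant_id", "reason"]),
        n_exposure=len(exposure), n_shared=n_shared,
    )


def read_trial_effects(path) -> list[TrialProteinEffect]:
    """Read the trial protein-change table.

    Expects columns uniprot, gene, seq_id, log2fc, fdr (synonyms accepted).
    Duplicate aptamer SeqIDs are a validation error listing the duplicates.
    """
    raw = _read_delimited(path)
    syn = {"uniprot": "uniprot", "uniprot_id": "uniprot", "gene": "gene",
           "gene_symbol": "gene", "protein": "gene", "seq_id": "seq_id", "seqid": "seq_id",
           "log2fc": "log2fc", "log2_fold_change": "log2fc", "logfc": "log2fc",
           "fdr": "fdr", "fdr_p": "fdr", "fdr_pvalue": "fdr"}
    frame = raw.rename(columns={c: syn[str(c).lower()] for c in raw.columns
                                if str(c).lower() in syn})
    for req in ("gene", "seq_id", "log2fc"):
        if req not in frame.columns:
            raise ConfigurationError(f"required column '{req}' not resolvable in {path}")
    dups = frame["seq_id"][frame["seq_id"].duplicated()].unique().tolist()
    if dups:
        raise ValidationError(f"duplicate seq_id entries: {dups}", rows=dups)
    records = []
    for _, row in frame.iterrows():
        records.append(TrialProteinEffect(
            uniprot_id=str(row.get("uniprot", "")),
            gene_symbol=str(row["gene"]),
            seq_id=str(row["seq_id"]),
            log2_fold_change=float(row["log2fc"]),
            fdr_p=_num(row["fdr"]) if "fdr" in frame.columns else float("nan"),
        ))
    return records


def read_trial_directions(path) -> list[TrialOutcomeDirection]:
    """Read the outcome-direction table (columns: outcome, direction).

    Blank directions mean the trait was not annotated in the trial.
    """
    raw = _read_delimited(path)
    cols = {str(c).lower(): c for c in raw.columns}
    if "outcome" not in cols or "direction" not in cols:
        raise ConfigurationError(f"trial direction table {path} needs 'outcome' and 'direction'")
    out = []
    for _, row in raw.iterrows():
        d = str(row[cols["direction"]]).strip().capitalize()
        direction = Direction(d) if d in ("Up", "Down") else Direction.UNOBSERVED
        out.append(TrialOutcomeDirection(str(row[cols["outcome"]]), direction))
    names = [o.outcome_name for o in out]
    if len(names) != len(set(names)):
        raise ValidationError("duplicate outcome entries in trial direction table")
    return out
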