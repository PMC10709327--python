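"""Sequence-composition, regulation, and expression statistics.

These are the downstream analyses that characterize a detected
capped-peptide set: amino-acid composition against a reference hormone
set, residue frequencies flanking the terminal caps in the precursor,
condition-versus-control fold changes from quantification tables, and
tissue-expression z-score matrices with hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")

__all__ = [
    "RESIDUES",
    "composition_vector",
    "compare_composition",
    "flanking_profile",
    "fold_change_table",
    "ExpressionResult",
    "expression_zscore",
    "benjamini_hochberg",
]


def composition_vector(peptide: str) -> np.ndarray:
    """Per-residue frequency vector (sums to 1) for one peptide."""
    if not peptide:
        raise ValueError("empty peptide")
    counts = np.array([peptide.count(r) for r in RESIDUES], dtype=float)
    return counts / counts.sum()


def compare_composition(
    capped: Sequence[str], reference: Sequence[str]
) -> pd.DataFrame:
    """Per-residue composition comparison between two peptide sets.

    Each peptide contributes its own frequency vector; groups are compared
    residue-by-residue with a two-sided two-sample Student's t-test.
    Zero-variance residues (identical frequencies within both groups) get
    p=1 when the means agree and p=0 when they differ, with a flag.
    Singleton groups report means but no p-value.
    """
    if not capped or not reference:
        raise ValueError("both peptide sets must be non-empty")
    a = np.vstack([composition_vector(p) for p in capped])
    b = np.vstack([composition_vector(p) for p in reference])
    rows = []
    for i, res in enumerate(RESIDUES):
        x, y = a[:, i], b[:, i]
        mean_a, mean_b = float(x.mean()), float(y.mean())
        degenerate = False
        if len(x) < 2 or len(y) < 2:
            p = np.nan
        elif x.std() == 0 and y.std() == 0:
            degenerate = True
            p = 1.0 if mean_a == mean_b else 0.0
        else:
            p = float(sps.ttest_ind(x, y, equal_var=True).pvalue)
        rows.append((res, mean_a, mean_b, p, degenerate))
    return pd.DataFrame(
        rows,
        columns=["residue", "mean_capped", "mean_ref", "p_value", "degenerate"],
    )


def flanking_profile(
    candidates: Sequence,
    precursors: Mapping[str, str],
    k: int = 4,
    terminus: str = "N",
    offsets_into: str = "precursor",
) -> tuple[pd.DataFrame, pd.Series]:
    """Residue-frequency matrix around the capped terminus.

    Rows are the 20 residues; columns are offsets -k..-1, +1..+k relative
    to the anchor residue. For the N terminus the anchor is the pyroGlu
    (Q). For the C terminus the anchor is the final amidated residue, so
    with the default convention +1 is the motif glycine in the precursor;
    ``offsets_into="peptide"`` instead counts downstream offsets past the
    G[K/R]R motif. Each column is normalized over the residues actually
    observed at that offset; the per-column observation counts are
    returned alongside.
    """
    if terminus not in ("N", "C"):
        raise ValueError("terminus must be 'N' or 'C'")
    offsets = list(range(-k, 0)) + list(range(1, k + 1))
    counts = pd.DataFrame(0, index=list(RESIDUES), columns=offsets, dtype=float)
    for cand in candidates:
        seq = precursors[cand.precursor_accession]
        anchor = cand.start if terminus == "N" else cand.end
        for off in offsets:
            pos = anchor + off
            if terminus == "C" and off > 0 and offsets_into == "peptide":
                pos = cand.motif_position + 2 + off  # past the G[K/R]R motif
            if not (1 <= pos <= len(seq)):
                continue
            aa = seq[pos - 1]
            if aa in RESIDUES:
                counts.loc[aa, off] += 1
    n_obs = counts.sum(axis=0)
    freq = counts.div(n_obs.replace(0, np.nan), axis=1).fillna(0.0)
    return freq, n_obs


def fold_change_table(
    quant: pd.DataFrame,
    sample_condition: Mapping[str, str],
    condition_a: str,
    condition_b: str,
) -> pd.DataFrame:
    """Per-peptide fold change (b over a) with two-sided t-test p-values.

    ``quant`` is peptide x sample (non-negative areas or concentrations).
    Peptides with zero mean in the denominator condition get an infinite
    fold change and a flag. log2 fold change is reported alongside.
    """
    missing = {condition_a, condition_b} - set(sample_condition.values())
    if missing:
        raise ValueError(f"conditions absent from mapping: {sorted(missing)}")
    unmapped = set(quant.columns) - set(sample_condition)
    if unmapped:
        raise ValueError(f"unmapped samples: {sorted(unmapped)}")
    cols_a = [s for s in quant.columns if sample_condition[s] == condition_a]
    cols_b = [s for s in quant.columns if sample_condition[s] == condition_b]
    a = quant[cols_a].to_numpy(dtype=float)
    b = quant[cols_b].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_a > 0, mean_b / mean_a, np.inf)
        log2fc = np.log2(fc, where=np.isfinite(fc) & (fc > 0),
                         out=np.full_like(fc, np.nan))
    pvals = np.full(len(quant), np.nan)
    if a.shape[1] >= 2 and b.shape[1] >= 2:
        res = sps.ttest_ind(b, a, axis=1, equal_var=True)
        pvals = np.asarray(res.pvalue)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "log2_fold_change": log2fc,
            "p_value": pvals,
            "zero_denominator": mean_a == 0,
        },
        index=quant.index,
    )


@dataclass(frozen=True)
class ExpressionResult:
    zscores: pd.DataFrame
    row_order: tuple[str, ...]
    col_order: tuple[str, ...]
    flagged_genes: tuple[str, ...]


def expression_zscore(
    matrix: pd.DataFrame,
    replicate_map: Mapping[str, str] | None = None,
) -> ExpressionResult:
    """Tissue-expression normalization used for precursor-gene heatmaps.

    Per gene: average replicate columns per tissue, scale the row to sum
    to 1 (relative expression), take log10, then z-score the row. Rows
    with a non-positive averaged value or zero variance are flagged and
    excluded. Rows and columns are ordered by agglomerative hierarchical
    clustering (complete linkage, Euclidean).
    """
    if replicate_map:
        grouped = matrix.T.groupby(
            [replicate_map.get(c, c) for c in matrix.columns]
        ).mean().T
    else:
        grouped = matrix.astype(float)
    flagged: list[str] = []
    rows = {}
    for gene, row in grouped.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.any(vals <= 0):
            flagged.append(gene)
            continue
        rel = vals / vals.sum()
        logged = np.log10(rel)
        sd = logged.std(ddof=1)
        if sd == 0:
            flagged.append(gene)
            continue
        rows[gene] = (logged - logged.mean()) / sd
    z = pd.DataFrame.from_dict(rows, orient="index", columns=grouped.columns)
    if len(z) >= 2:
        row_order = [z.index[i] for i in leaves_list(
            linkage(pdist(z.to_numpy()), method="complete"))]
    else:
        row_order = list(z.index)
    if z.shape[1] >= 2 and len(z) >= 1:
        col_order = [z.columns[i] for i in leaves_list(
            linkage(pdist(z.to_numpy().T), method="complete"))]
    else:
        col_order = list(z.columns)
    return ExpressionResult(z, tuple(row_order), tuple(col_order), tuple(flagged))


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (optional; raw p-values are the default output)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out
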