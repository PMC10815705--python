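"""Expression filtering, knockout-vs-WT contrasts, and comparative-Ct qPCR.

The analysis operates on a genes x samples TPM matrix over four genotypes:
wild type (WT), the two single knockouts (N1KO = NR1D1-null, N2KO =
NR1D2-null) and the double knockout (NDKO). Differential expression is
threshold-based: a gene is a DEG in a mutant genotype when its TPM fold
change versus WT exceeds ``fc_threshold`` (default 1.5, reciprocal for
down-regulation) with a two-sided Student's t-test p below ``p_threshold``
(default 0.05) on log2(TPM + pseudocount).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GENOTYPES = ("WT", "N1KO", "N2KO", "NDKO")
MUTANTS = ("N1KO", "N2KO", "NDKO")

__all__ = [
    "GENOTYPES",
    "MUTANTS",
    "ExpressionStudy",
    "filter_expressed",
    "contrast",
    "contrast_all",
    "ddct",
]


@dataclass
class ExpressionStudy:
    """TPM matrix plus its sample design.

    ``tpm``: DataFrame, genes in rows (index = gene ids), samples in columns.
    ``design``: DataFrame indexed by sample id with columns ``genotype``
    (one of WT/N1KO/N2KO/NDKO) and ``replicate``.
    """

    tpm: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.tpm.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        extra = set(self.design.index) - set(self.tpm.columns)
        if extra:
            raise ValueError(f"design samples absent from matrix: {sorted(extra)}")
        bad = set(self.design["genotype"]) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotypes: {sorted(bad)}")
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")

    def samples_of(self, genotype: str) -> list[str]:
        sel = self.design.index[self.design["genotype"] == genotype]
        # preserve matrix column order
        return [s for s in self.tpm.columns if s in set(sel)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionStudy):
            return NotImplemented
        return self.tpm.equals(other.tpm) and self.design.equals(other.design)


def filter_expressed(study: ExpressionStudy, quantile: float = 0.25) -> ExpressionStudy:
    """Keep the top ``quantile`` fraction of genes by mean TPM.

    Retains exactly floor(quantile * n_genes) genes with the highest mean
    TPM across all samples; ties at the cutoff are broken by gene-id
    lexicographic order. Gene and sample order of the input are preserved
    in the result.
    """
    if not 0 < quantile <= 1:
        raise ValueError(f"quantile must be in (0, 1], got {quantile}")
    if study.tpm.empty:
        raise ValueError("empty expression matrix")
    n_keep = int(np.floor(quantile * len(study.tpm)))
    means = study.tpm.mean(axis=1)
    ranked = sorted(study.tpm.index, key=lambda g: (-means[g], g))
    keep = set(ranked[:n_keep])
    mask = study.tpm.index.isin(keep)
    return ExpressionStudy(study.tpm.loc[mask], study.design.copy())


def _pooled_t(
    a: np.ndarray, b: np.ndarray, welch: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sided t-test of a (genes x n1) vs b (genes x n2).

    Returns (p, degenerate, equal_means). Degenerate rows have zero
    variance in both groups: p=1 when the means agree, p=0 otherwise.
    """
    n1, n2 = a.shape[1], b.shape[1]
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    degenerate = (v1 == 0) & (v2 == 0)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1), rtol=0, atol=1e-12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 0/0 in degenerate rows
        res = stats.ttest_ind(b, a, axis=1, equal_var=not welch)
    p = np.asarray(res.pvalue)
    p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
    # identical groups with zero pooled variance difference: scipy returns
    # nan when variance is zero in one group only and difference is zero
    p = np.where(np.isnan(p) & equal_means, 1.0, p)
    return p, degenerate & ~equal_means, equal_means


def contrast(
    study: ExpressionStudy,
    genotype: str,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    pseudocount: float = 1.0,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-gene mutant-vs-WT fold change, t-test p, and DEG flags.

    Fold change is the ratio of untransformed mean TPM (mutant/WT); the
    test is an equal-variance two-sided Student's t on
    log2(TPM + pseudocount) with df = n1 + n2 - 2 (Welch optional).
    DEG flags use strict inequalities: ``deg_up`` iff fc > fc_threshold and
    p < p_threshold; ``deg_down`` iff fc < 1/fc_threshold and p < p_threshold.
    A BH-adjusted ``q`` column is provided for reference; the flags use raw p.

    0/0 fold changes are marked in ``fc_undefined``; rows where both groups
    have zero variance but unequal means carry ``degenerate`` = True with p=0.
    """
    if genotype == "WT":
        raise ValueError("contrast genotype must be a mutant, not WT")
    if genotype not in MUTANTS:
        raise ValueError(f"unknown genotype {genotype!r}")
    wt_samples = study.samples_of("WT")
    mut_samples = study.samples_of(genotype)
    if len(wt_samples) < 2 or len(mut_samples) < 2:
        raise ValueError(f"need >=2 replicates in WT and {genotype}")

    wt = study.tpm[wt_samples].to_numpy(dtype=float)
    mut = study.tpm[mut_samples].to_numpy(dtype=float)

    mean_wt = wt.mean(axis=1)
    mean_mut = mut.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_mut / mean_wt
        log2fc = np.log2(fc)
    fc_undefined = (mean_wt == 0) & (mean_mut == 0)
    fc = np.where(fc_undefined, np.nan, fc)
    log2fc = np.where(fc_undefined, np.nan, log2fc)

    p, degenerate, _ = _pooled_t(
        np.log2(wt + pseudocount), np.log2(mut + pseudocount), welch
    )
    q = multipletests(p, method="fdr_bh")[1]

    with np.errstate(invalid="ignore"):
        deg_up = (fc > fc_threshold) & (p < p_threshold)
        deg_down = (fc < 1.0 / fc_threshold) & (p < p_threshold)
    deg_up &= ~np.isnan(fc)
    deg_down &= ~np.isnan(fc)

    return pd.DataFrame(
        {
            "gene": study.tpm.index,
            "genotype": genotype,
            "fc": fc,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "deg_up": deg_up,
            "deg_down": deg_down,
            "fc_undefined": fc_undefined,
            "degenerate": degenerate,
        }
    ).reset_index(drop=True)


def contrast_all(
    study: ExpressionStudy,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    pseudocount: float = 1.0,
    welch: bool = False,
) -> pd.DataFrame:
    """Contrasts of every mutant genotype against WT, stacked long-form."""
    parts = [
        contrast(study, g, fc_threshold, p_threshold, pseudocount, welch)
        for g in MUTANTS
    ]
    return pd.concat(parts, ignore_index=True)


def ddct(qpcr: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Comparative-Ct (delta-delta-Ct) relative quantification.

    ``qpcr`` needs columns ``sample``, ``group``, ``ct_target``,
    ``ct_reference``. Per sample, dCt = ct_target - ct_reference;
    ddCt = dCt - mean(dCt over the control group); relative expression =
    2^(-ddCt), so the control-group mean ddCt is 0 and its geometric scale
    centres on 1. Samples with missing Ct values are dropped with a warning.
    """
    required = {"sample", "group", "ct_target", "ct_reference"}
    missing_cols = required - set(qpcr.columns)
    if missing_cols:
        raise ValueError(f"qPCR table missing columns: {sorted(missing_cols)}")
    out = qpcr.copy()
    bad = out["ct_target"].isna() | out["ct_reference"].isna()
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} sample(s) with missing Ct values: "
            f"{out.loc[bad, 'sample'].tolist()}",
            stacklevel=2,
        )
        out = out.loc[~bad].copy()
    control = out[out["group"] == control_group]
    if control.empty:
        raise ValueError(f"control group {control_group!r} has no samples")
    out["dct"] = out["ct_target"] - out["ct_reference"]
    control_mean = out.loc[out["group"] == control_group, "dct"].mean()
    out["ddct"] = out["dct"] - control_mean
    out["rel_expr"] = np.exp2(-out["ddct"])
    return out.reset_index(drop=True)
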