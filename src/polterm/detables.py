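"""Differential-expression result tables and stand-in tests.

External differential results (DESeq2 gene-level, DEXSeq exon-level,
window-level) are consumed as TSV tables and classified with the fixed
significance bands: up-regulated means log2FC > 1 and adjusted P <
0.01; down-regulated log2FC < -1 and adjusted P < 0.01; non-regulated
-0.1 < log2FC < 0.1 and adjusted P > 0.01 (strict inequalities as
printed).  Benjamini-Hochberg adjustment is provided for any p-value
vector.

Two stand-in tests let fully synthetic pipelines run without an
external fitter; neither replaces a negative-binomial model:

* ``ranksum`` — exact two-sided Wilcoxon rank-sum on CPM values.  Note
  its hard power floor: with 3 vs 3 replicates the smallest achievable
  two-sided exact p is 0.1, so it can never reach adjusted p < 0.01 at
  that design.
* ``pooled-binomial`` — conditional binomial exact test on counts
  summed per condition (the classic test for a ratio of Poisson
  totals); powerful at small replicate numbers but anti-conservative
  under strong overdispersion.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .processivity import AnalysisThresholds

COLUMN_PRESETS = {
    "deseq2": {
        "feature_id": "gene_id",
        "base_mean": "baseMean",
        "log2fc": "log2FoldChange",
        "pvalue": "pvalue",
        "padj": "padj",
    },
    "dexseq": {
        "feature_id": "featureID",
        "base_mean": "exonBaseMean",
        "log2fc": "log2fold_treated_control",
        "pvalue": "pvalue",
        "padj": "padj",
    },
    "polterm": {
        "feature_id": "feature_id",
        "base_mean": "base_mean",
        "log2fc": "log2fc",
        "pvalue": "pvalue",
        "padj": "padj",
    },
}

REQUIRED = ("feature_id", "log2fc", "pvalue", "padj")


def read_de_table(path: str, column_map: str | Mapping[str, str] = "polterm") -> pd.DataFrame:
    """Read a TSV/CSV differential table into canonical columns.

    ``column_map`` is a preset name or a mapping canonical -> source
    column.  Missing adjusted p ("NA") marks the record untested.
    Raises a KeyError naming any unmappable required column.
    """
    cmap = COLUMN_PRESETS[column_map] if isinstance(column_map, str) else dict(column_map)
    sep = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep, na_values=["NA", "NaN", ""])
    out = {}
    for canon in ("feature_id", "base_mean", "log2fc", "pvalue", "padj"):
        src = cmap.get(canon, canon)
        if src in raw.columns:
            out[canon] = raw[src]
        elif canon in REQUIRED:
            raise KeyError(f"{path}: required column {src!r} (for {canon!r}) not found")
    return pd.DataFrame(out)


def write_de_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def classify_expression(
    records: pd.DataFrame, th: AnalysisThresholds | None = None
) -> pd.Series:
    """Per-feature class: up / down / non / other, by the printed bands.

    Inequalities are strict exactly as printed; features matching no
    band (including untested ones) are 'other'.  The result partitions:
    every feature gets exactly one label.
    """
    th = th or AnalysisThresholds()
    lfc = records["log2fc"].to_numpy(dtype=float)
    padj = records["padj"].to_numpy(dtype=float)
    out = np.full(len(records), "other", dtype=object)
    with np.errstate(invalid="ignore"):
        out[(lfc > th.de_lfc) & (padj < th.de_p)] = "up"
        out[(lfc < -th.de_lfc) & (padj < th.de_p)] = "down"
        out[(lfc > -th.non_lfc) & (lfc < th.non_lfc) & (padj > th.de_p)] = "non"
    return pd.Series(out, index=records.index, name="class")


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotonicity is enforced; the result is stable under permutation of
    the input (adjusted values travel with their raw values).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _cpm(counts: pd.DataFrame) -> pd.DataFrame:
    libs = counts.sum(axis=0).astype(float)
    if (libs == 0).any():
        libs = libs.replace(0, 1.0)
    return counts / libs * 1e6


def standin_de_test(
    counts: pd.DataFrame,
    design: Sequence[str],
    reference: str = "control",
    method: str = "ranksum",
) -> pd.DataFrame:
    """Simple two-group differential test on a feature x sample matrix.

    NOT a DESeq2 replacement: no dispersion modelling or shrinkage.
    Library sizes are normalized to counts-per-million; log2FC is the
    ratio of condition mean CPMs with pseudocount 0.5; p-values come
    from the selected engine (see module docstring) and are BH-adjusted.
    """
    design = list(design)
    if len(design) != counts.shape[1]:
        raise ValueError("design length must match sample count")
    levels = sorted(set(design))
    if len(levels) != 2 or reference not in levels:
        raise ValueError(f"need exactly two conditions including {reference!r}, got {levels}")
    other = next(l for l in levels if l != reference)
    ref_cols = [c for c, d in zip(counts.columns, design) if d == reference]
    alt_cols = [c for c, d in zip(counts.columns, design) if d == other]
    if len(ref_cols) < 2 or len(alt_cols) < 2:
        raise ValueError("need >= 2 samples per condition")

    cpm = _cpm(counts)
    ref_mean = cpm[ref_cols].mean(axis=1)
    alt_mean = cpm[alt_cols].mean(axis=1)
    log2fc = np.log2((alt_mean + 0.5) / (ref_mean + 0.5))

    if method == "ranksum":
        pvals = np.ones(len(counts))
        for i in range(len(counts)):
            a = cpm[alt_cols].iloc[i].to_numpy()
            b = cpm[ref_cols].iloc[i].to_numpy()
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                continue  # identical values in all samples: p = 1
            pvals[i] = scipy.stats.mannwhitneyu(
                a, b, alternative="two-sided", method="exact"
            ).pvalue
    elif method == "pooled-binomial":
        k_alt = counts[alt_cols].sum(axis=1).to_numpy()
        k_ref = counts[ref_cols].sum(axis=1).to_numpy()
        lib_alt = float(counts[alt_cols].sum().sum())
        lib_ref = float(counts[ref_cols].sum().sum())
        p0 = lib_alt / (lib_alt + lib_ref) if lib_alt + lib_ref > 0 else 0.5
        pvals = np.ones(len(counts))
        for i, (ka, kr) in enumerate(zip(k_alt, k_ref)):
            n = int(ka + kr)
            if n > 0:
                pvals[i] = scipy.stats.binomtest(int(ka), n, p0).pvalue
    else:
        raise ValueError(f"unknown method {method!r}")

    return pd.DataFrame(
        {
            "feature_id": counts.index,
            "base_mean": cpm.mean(axis=1).to_numpy(),
            "log2fc": log2fc.to_numpy(),
            "pvalue": pvals,
            "padj": benjamini_hochberg(pvals),
        }
    ).set_index("feature_id", drop=False)
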