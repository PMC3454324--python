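"""Hypoxic-induction calling from expression matrices and cross-dataset
combination.

Per dataset, replicate signals are averaged (an average is null when at
least half the replicates are null), a probe is induced when its
log2(hypoxic/normoxic) ratio exceeds the dataset's mean log-ratio by 2.6
standard deviations — or when it has no normoxic signal but a hypoxic
one — and basal expression is "null" when the averaged normoxic signal is
null.  Per-gene evidence is combined across datasets by Stouffer's (or
Fisher's) method and BH-adjusted; the association analyses relate basal
expression, conserved HIF-binding-site presence and induction.
"""

from __future__ import annotations

import io
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chip import benjamini_hochberg

logger = logging.getLogger(__name__)


@dataclass
class ExpressionDataset:
    """One profiling experiment: per-probe normoxic and hypoxic replicates.

    ``probes`` columns: probe_id, gene_id, norm_r1..rk, hyp_r1..rm; NaN
    encodes a null (absent) measurement.
    """

    dataset_id: str
    probes: pd.DataFrame

    @property
    def norm_columns(self) -> list[str]:
        return [c for c in self.probes.columns if c.startswith("norm_")]

    @property
    def hyp_columns(self) -> list[str]:
        return [c for c in self.probes.columns if c.startswith("hyp_")]

    @classmethod
    def from_tsv(cls, dataset_id: str, text: str) -> "ExpressionDataset":
        return cls(dataset_id, pd.read_csv(io.StringIO(text), sep="\t"))

    def to_tsv(self) -> str:
        return self.probes.to_csv(sep="\t", index=False)


@dataclass
class InductionCall:
    probe_id: str
    gene_id: str
    basal: str  # "null" | "significant"
    induced: bool
    log_ratio: float | None


def average_replicates(signals) -> float | None:
    """Mean of non-null replicate signals; null when >=50% are null."""
    vals = [s for s in signals if s is not None and not (isinstance(s, float) and math.isnan(s))]
    if not signals or len(vals) <= len(signals) / 2:
        return None
    return float(np.mean(vals))


def _row_average(X: np.ndarray) -> np.ndarray:
    """Vectorized average_replicates over the rows of a matrix."""
    n_null = np.isnan(X).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg = np.nanmean(X, axis=1)
    avg[n_null >= X.shape[1] / 2] = np.nan
    return avg


def call_induction(dataset: ExpressionDataset, sd_factor: float = 2.6) -> list[InductionCall]:
    """Per-probe induction and basal-expression calls for one dataset.

    Induced: log2 ratio above the dataset mean by ``sd_factor`` SDs
    (mean/SD over all probes with a non-null ratio), or normoxic null
    with hypoxic non-null.
    """
    df = dataset.probes
    norm = _row_average(df[dataset.norm_columns].to_numpy(dtype=float))
    hyp = _row_average(df[dataset.hyp_columns].to_numpy(dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        lr = np.where((norm > 0) & (hyp > 0), np.log2(hyp / norm), np.nan)
    ok = ~np.isnan(lr)
    if not ok.any():
        logger.warning("%s: no probe has both signals; no induction calls possible",
                       dataset.dataset_id)
    mu = float(np.mean(lr[ok])) if ok.any() else 0.0
    sd = float(np.std(lr[ok])) if ok.any() else 0.0
    cut = mu + sd_factor * sd
    calls = []
    for i in range(len(df)):
        basal = "null" if np.isnan(norm[i]) else "significant"
        rescued = np.isnan(norm[i]) and not np.isnan(hyp[i])
        induced = bool((ok[i] and lr[i] > cut) or rescued)
        calls.append(InductionCall(
            probe_id=str(df["probe_id"].iloc[i]),
            gene_id=str(df["gene_id"].iloc[i]),
            basal=basal,
            induced=induced,
            log_ratio=float(lr[i]) if ok[i] else None,
        ))
    return calls


def calls_to_tsv(calls) -> str:
    lines = ["probe_id\tgene_id\tbasal\tinduced\tlog_ratio"]
    for c in calls:
        lr = "" if c.log_ratio is None else f"{c.log_ratio:.6g}"
        lines.append(f"{c.probe_id}\t{c.gene_id}\t{c.basal}\t{int(c.induced)}\t{lr}")
    return "\n".join(lines) + "\n"


def gene_calls(calls) -> pd.DataFrame:
    """Collapse probe calls to gene level: best probe for induction, any
    probe for basal significance."""
    rows = {}
    for c in calls:
        rec = rows.setdefault(c.gene_id, {"induced": False, "basal_significant": False})
        rec["induced"] = rec["induced"] or c.induced
        rec["basal_significant"] = rec["basal_significant"] or c.basal == "significant"
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    return df


def combine_datasets(calls_by_dataset: dict, method: str = "stouffer") -> dict:
    """Combine per-dataset induction evidence into per-gene p values.

    Per dataset, a gene's evidence is the standardized log-ratio of its
    best probe, z = (log_ratio - mean)/SD (0 where null); z scores are
    combined one-sided by Stouffer (default) or Fisher and BH-adjusted
    across genes.  Returns gene -> (combined p, adjusted p).
    """
    if method not in ("stouffer", "fisher"):
        raise ValueError(f"unknown combination method {method!r}")
    per_gene: dict[str, list[float]] = {}
    for _, calls in calls_by_dataset.items():
        lrs = np.array([c.log_ratio for c in calls if c.log_ratio is not None])
        mu = float(lrs.mean()) if lrs.size else 0.0
        sd = float(lrs.std()) if lrs.size else 0.0
        best: dict[str, float] = {}
        for c in calls:
            z = 0.0
            if c.log_ratio is not None and sd > 0:
                z = (c.log_ratio - mu) / sd
            best[c.gene_id] = max(best.get(c.gene_id, -np.inf), z)
        for gene, z in best.items():
            per_gene.setdefault(gene, []).append(z)
    genes = sorted(per_gene)
    pvals = np.empty(len(genes))
    for i, gene in enumerate(genes):
        zs = np.asarray(per_gene[gene])
        if method == "stouffer":
            pvals[i] = stats.norm.sf(zs.sum() / math.sqrt(zs.size))
        else:
            p_one = np.clip(stats.norm.sf(zs), 1e-300, 1.0)
            pvals[i] = stats.chi2.sf(-2 * np.log(p_one).sum(), 2 * zs.size)
    adj = benjamini_hochberg(pvals)
    return {g: (float(p), float(a)) for g, p, a in zip(genes, pvals, adj)}


def combined_to_tsv(combined: dict) -> str:
    lines = ["gene_id\tcombined_p\tadjusted_p"]
    for gene in sorted(combined):
        p, a = combined[gene]
        lines.append(f"{gene}\t{p:.6g}\t{a:.6g}")
    return "\n".join(lines) + "\n"


def basal_association(calls_by_dataset: dict, target_genes: set,
                      hbs_genes: set | None = None) -> dict:
    """Association of basal expression (and HBS presence) with induction.

    Per dataset the fraction of target genes induced is computed
    separately for basal-significant and basal-null strata; the paired
    strata percentages are compared by a Wilcoxon signed-rank test across
    datasets and by a pooled 2x2 chi-square (no continuity correction).
    With ``hbs_genes`` given, each dataset's basal-expressed genes are
    also split four ways by HBS presence x induction (percentages per
    dataset sum to 100).
    """
    per_dataset, pairs, fourway = [], [], []
    pooled = np.zeros((2, 2))  # rows: basal sig/null; cols: induced yes/no
    for ds_id, calls in calls_by_dataset.items():
        gc = gene_calls(calls)
        tg = gc.loc[gc.index.isin(target_genes)]
        sig = tg[tg["basal_significant"]]
        nul = tg[~tg["basal_significant"]]
        pooled[0, 0] += sig["induced"].sum()
        pooled[0, 1] += (~sig["induced"]).sum()
        pooled[1, 0] += nul["induced"].sum()
        pooled[1, 1] += (~nul["induced"]).sum()
        row = {
            "dataset": ds_id,
            "n_significant": len(sig),
            "n_null": len(nul),
            "pct_induced_significant": 100 * sig["induced"].mean() if len(sig) else np.nan,
            "pct_induced_null": 100 * nul["induced"].mean() if len(nul) else np.nan,
        }
        per_dataset.append(row)
        if len(sig) and len(nul):
            pairs.append((row["pct_induced_significant"], row["pct_induced_null"]))
        else:
            logger.warning("%s: a basal stratum has no target genes; excluded from "
                           "the paired test", ds_id)
        if hbs_genes is not None:
            expressed = gc[gc["basal_significant"]]
            has = expressed.index.isin(hbs_genes)
            ind = expressed["induced"].to_numpy(dtype=bool)
            n = max(len(expressed), 1)
            fourway.append({
                "dataset": ds_id,
                "NoHBS_notInduced": 100 * np.sum(~has & ~ind) / n,
                "NoHBS_Induced": 100 * np.sum(~has & ind) / n,
                "HBS_notInduced": 100 * np.sum(has & ~ind) / n,
                "HBS_Induced": 100 * np.sum(has & ind) / n,
            })
    report = {"per_dataset": pd.DataFrame(per_dataset), "pooled_table": pooled}
    if len(pairs) >= 2:
        a, b = np.array(pairs).T
        if np.all(a == b):
            report["wilcoxon_p"] = 1.0
        else:
            report["wilcoxon_p"] = float(stats.wilcoxon(a, b).pvalue)
    else:
        report["wilcoxon_p"] = float("nan")
    if pooled.sum() and np.all(pooled.sum(axis=1) > 0) and np.all(pooled.sum(axis=0) > 0):
        chi2, p, _, _ = stats.chi2_contingency(pooled, correction=False)
        report["chi2_stat"], report["chi2_p"] = float(chi2), float(p)
    else:
        report["chi2_stat"], report["chi2_p"] = float("nan"), float("nan")
    if hbs_genes is not None:
        report["fourway"] = pd.DataFrame(fourway)
    return report
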