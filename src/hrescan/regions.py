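"""Building the core HIF-binding-region set and its matched background.

Core regions start from conserved RCGTG sites (HBSs) inside conserved
elements, are kept only when their gene is robustly hypoxia-induced
(FDR-gated meta-analysis call), and are extended over flanking conserved
sequence while more than half of the candidate span is covered by
conserved elements.  Background regions hold conserved RCGTG motifs in
genes whose expression sits inside a +/-0.25 SD band around each
dataset's global mean fold (i.e. genes with no hypoxic response), sampled
to match the core set's genomic-location class proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scan import AlignedRegion, MotifHit, find_rcgtg, is_conserved

logger = logging.getLogger(__name__)

LOCATION_CLASSES = ("promoter", "UTR5", "intron", "UTR3")


@dataclass
class GenomicRegion:
    region_id: str
    chrom: str
    start: int
    end: int
    gene_id: str = ""
    location_class: str | None = None
    label: str = "unassigned"
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.region_id}: start must be < end")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class ConservedElement:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError("conserved element must be a non-negative half-open interval")


# -- BED plumbing ------------------------------------------------------

def read_bed(text: str):
    """Parse BED3+ lines into (chrom, start, end, name) tuples."""
    rows = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith(("#", "track", "browser")):
            continue
        f = ln.split("\t") if "\t" in ln else ln.split()
        rows.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ""))
    return rows


def regions_to_bed(regions) -> str:
    lines = []
    for r in regions:
        lines.append(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t0\t+")
    return "\n".join(lines) + ("\n" if lines else "")


def elements_from_bed(text: str) -> list[ConservedElement]:
    return [ConservedElement(c, s, e) for c, s, e, _ in read_bed(text)]


# -- cross-study overlap ----------------------------------------------

def overlap_core(binding_sets: dict, min_studies: int = 2) -> list:
    """Regions supported by at least ``min_studies`` studies (>=1 bp overlap).

    Candidates are taken from every study in mapping order (the first
    study acts as the reference ordering); each kept region is annotated
    with its supporting-study count in ``extras['n_studies']``.  A
    region's own study always supports it, so ``min_studies=1`` returns
    the union of all studies.
    """
    out = []
    studies = list(binding_sets)
    for study in studies:
        for region in binding_sets[study]:
            support = sum(
                1 for other in studies
                if any(r.overlaps(region.chrom, region.start, region.end)
                       for r in binding_sets[other])
            )
            if support >= min_studies:
                region.extras["n_studies"] = support
                out.append(region)
    return out


# -- conserved HBS detection and extension -----------------------------

def _covered_bases(chrom: str, start: int, end: int, elements) -> int:
    ivs = sorted(
        (max(e.start, start), min(e.end, end))
        for e in elements if e.chrom == chrom and e.start < end and start < e.end
    )
    covered, cursor = 0, start
    for s, e in ivs:
        s = max(s, cursor)
        if e > s:
            covered += e - s
            cursor = e
    return covered


def conserved_hbs(region: AlignedRegion, elements, min_species: int = 4,
                  required_species=None, both_strands: bool = True) -> list[MotifHit]:
    """RCGTG hits that sit wholly inside a conserved element and pass the
    cross-species identity filter at every motif position."""
    out = []
    for hit in find_rcgtg(region, both_strands=both_strands):
        g_start = region.start + hit.offset
        g_end = g_start + hit.length
        inside = any(
            e.chrom == region.chrom and e.start <= g_start and g_end <= e.end
            for e in elements
        )
        if inside and is_conserved(hit, region, None, min_species, required_species):
            out.append(hit)
    return out


def extend_region(chrom: str, hbs_start: int, hbs_end: int, elements,
                  min_coverage: float = 0.5, max_span: int = 2000, step: int = 10,
                  region_id: str = "", gene_id: str = "") -> GenomicRegion:
    """Grow an HBS symmetrically while conserved-element coverage of the
    whole candidate span stays above ``min_coverage``.

    Growth proceeds in ``step``-bp increments on both sides and stops when
    the next increment would push coverage to <= ``min_coverage`` or the
    span past ``max_span``; the result always contains the seed HBS.
    """
    start, end = hbs_start, hbs_end
    while True:
        cand = (max(0, start - step), end + step)
        span = cand[1] - cand[0]
        if span > max_span:
            break
        if _covered_bases(chrom, cand[0], cand[1], elements) / span <= min_coverage:
            break
        start, end = cand
    return GenomicRegion(region_id or f"{chrom}:{hbs_start}", chrom, start, end,
                         gene_id=gene_id)


# -- induction gating and background construction ----------------------

def filter_by_induction(regions, meta_calls: dict, max_fdr: float = 0.02) -> list:
    """Keep regions whose gene's FDR-adjusted meta-analysis p <= max_fdr."""
    out = []
    for r in regions:
        if r.gene_id not in meta_calls:
            logger.warning("region %s: gene %s absent from meta-analysis calls; dropped",
                           r.region_id, r.gene_id)
            continue
        _, adj_p = meta_calls[r.gene_id]
        if adj_p <= max_fdr:
            out.append(r)
    return out


def flat_expression_genes(fold_tables, tolerance_sd: float = 0.25) -> set:
    """Genes whose every probe sits within ``tolerance_sd`` SDs of the
    global mean fold value in every dataset (i.e. show no response).

    ``fold_tables`` is one DataFrame per dataset with columns
    ``gene_id``, ``probe_id`` and ``fold`` (mean log-fold per probe).
    """
    vetoed: set = set()
    seen: set = set()
    for table in fold_tables:
        folds = table["fold"].to_numpy(dtype=float)
        mu, sd = np.nanmean(folds), np.nanstd(folds)
        band = tolerance_sd * sd
        dev = np.abs(folds - mu)
        bad = set(table.loc[(dev >= band) | np.isnan(folds), "gene_id"])
        vetoed |= bad
        seen |= set(table["gene_id"])
    return seen - vetoed


def build_background(candidates, fold_tables, core, tolerance_sd: float = 0.25,
                     seed=0, n_target: int | None = None) -> list:
    """Location-matched background sampling among expression-flat genes.

    Candidates (GenomicRegions around conserved RCGTG motifs, annotated
    with gene_id and location_class) are filtered to genes passing the
    flat-expression band in every dataset and not used by the core set,
    then sampled without replacement so the location-class proportions
    match the core set's.
    """
    rng = np.random.default_rng(seed)
    flat = flat_expression_genes(fold_tables, tolerance_sd)
    core_genes = {r.gene_id for r in core}
    pool = [c for c in candidates if c.gene_id in flat and c.gene_id not in core_genes]
    if n_target is None:
        n_target = min(len(pool), 3500)
    n_core = len(core)
    chosen: list = []
    for cls in LOCATION_CLASSES:
        want = round(n_target * sum(1 for r in core if r.location_class == cls) / max(n_core, 1))
        avail = [c for c in pool if c.location_class == cls]
        if want > len(avail):
            logger.warning("background class %s: wanted %d, only %d available",
                           cls, want, len(avail))
            want = len(avail)
        idx = rng.choice(len(avail), size=want, replace=False) if want else []
        chosen.extend(avail[i] for i in idx)
    for c in chosen:
        c.label = "background"
    return chosen


# -- genomic-location annotation ---------------------------------------

@dataclass
class GeneModel:
    """Simplified transcript model for location-class annotation."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    utr5: tuple | None = None
    introns: list = field(default_factory=list)
    utr3: tuple | None = None


def annotate_location(region: GenomicRegion, gene_models, promoter_upstream: int = 2000) -> str:
    """Assign promoter / UTR5 / intron / UTR3 by region midpoint.

    Promoter means the midpoint lies within ``promoter_upstream`` bp
    upstream of a TSS (strand-aware); otherwise the class of the
    overlapped feature wins, with precedence promoter > UTR5 > intron >
    UTR3.  A region overlapping nothing is assigned to its nearest gene's
    promoter class (logged).
    """
    mid = region.midpoint
    best = None  # (precedence rank, gene_id)
    order = {"promoter": 0, "UTR5": 1, "intron": 2, "UTR3": 3}
    for gm in gene_models:
        if gm.chrom != region.chrom:
            continue
        if gm.strand == "+":
            prom = (gm.tss - promoter_upstream, gm.tss)
        else:
            prom = (gm.tss, gm.tss + promoter_upstream)
        cands = []
        if prom[0] <= mid <= prom[1]:
            cands.append("promoter")
        for cls, iv in (("UTR5", gm.utr5), ("UTR3", gm.utr3)):
            if iv and iv[0] <= mid < iv[1]:
                cands.append(cls)
        if any(s <= mid < e for s, e in gm.introns):
            cands.append("intron")
        for cls in cands:
            if best is None or order[cls] < order[best[0]]:
                best = (cls, gm.gene_id)
    if best is None:
        nearest = min(
            (gm for gm in gene_models if gm.chrom == region.chrom),
            key=lambda gm: abs(gm.tss - mid), default=None,
        )
        if nearest is None:
            raise ValueError(f"{region.region_id}: no gene model on {region.chrom}")
        logger.warning("region %s overlaps no feature; assigned to nearest promoter (%s)",
                       region.region_id, nearest.gene_id)
        best = ("promoter", nearest.gene_id)
    region.location_class = best[0]
    if not region.gene_id:
        region.gene_id = best[1]
    return best[0]


def matching_report(core, background, seqs_by_region_id=None) -> pd.DataFrame:
    """Class counts (and GC% summaries when sequences are supplied) for
    the core and background sets, for eyeballing how well they match."""
    rows = []
    for label, regions in (("core", core), ("background", background)):
        for cls in LOCATION_CLASSES:
            sub = [r for r in regions if r.location_class == cls]
            row = {"label": label, "location_class": cls, "n": len(sub)}
            if seqs_by_region_id:
                gc = [
                    (s.count("G") + s.count("C")) / len(s)
                    for s in (seqs_by_region_id.get(r.region_id) for r in sub) if s
                ]
                row["gc_mean"] = float(np.mean(gc)) if gc else float("nan")
            rows.append(row)
    return pd.DataFrame(rows)
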