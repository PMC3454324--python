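"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the statistical structure of the study data:

* multi-species alignments of RCGTG-containing regions, with a
  "cooperating" motif planted at a higher rate in core than in background
  regions and a conservation filter that only passes deliberately
  conserved instances;
* replicated tiling-array log-ratio tracks (80 bp probe spacing, four
  replicates) with bound regions planted as a mean shift; and
* hypoxia expression datasets with a stated induced fraction, effect size
  and missing-value rate.

Every generator is a pure function of its config and seed; truth tables
carry enough detail to score downstream sensitivity and precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chip import ProbeTrack
from .expression import ExpressionDataset
from .pwm import BASES, PWM
from .regions import ConservedElement, LOCATION_CLASSES
from .scan import AlignedRegion

_BASE_ARRAY = np.array(list(BASES))


@dataclass
class PlantedPWM:
    pwm: PWM
    core_rate: float = 0.30
    background_rate: float = 0.10
    conserved_fraction: float = 1.0


@dataclass
class TilingConfig:
    n_probes: int = 1000
    spacing: int = 80
    probe_length: int = 50
    n_replicates: int = 4
    noise_sd: float = 0.25
    effect: float = 0.75  # 3 x noise_sd
    n_planted: int = 8
    planted_width_probes: int = 5


@dataclass
class ExpressionConfig:
    n_genes: int = 2000
    n_datasets: int = 5
    frac_induced: float = 0.05
    effect_sd: float = 4.0
    null_frac: float = 0.10
    n_replicates: int = 3
    baseline_lr_sd: float = 0.5


@dataclass
class SimulationConfig:
    seed: int = 0
    n_core: int = 120
    n_background: int = 3500
    species: list = field(default_factory=lambda: ["human", "chimp", "dog", "cow", "mouse"])
    region_length: int = 200
    gc: float = 0.45
    planted_pwms: list = field(default_factory=list)
    conservation_noise: float = 0.10
    element_length: int = 150
    location_distribution: dict = field(
        default_factory=lambda: {"promoter": 0.5, "UTR5": 0.1, "intron": 0.3, "UTR3": 0.1}
    )
    tiling: TilingConfig = field(default_factory=TilingConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)


def random_seq(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def codes_to_str(codes: np.ndarray) -> str:
    return "".join(_BASE_ARRAY[codes])


# -- PWM generation ----------------------------------------------------

def gen_pwm(length: int, ic_profile, seed=0, n_sites: int = 1000,
            id: str = "SIM0001", name: str = "synthetic",
            background=None, pseudocount=None) -> PWM:
    """Generate counts whose per-column corrected-probability relative
    entropy lands within 0.1 bits of each target (bisection on the weight
    of a random consensus base over the background mixture)."""
    rng = np.random.default_rng(seed)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    ic_profile = list(ic_profile)
    if len(ic_profile) != length:
        raise ValueError("ic_profile length must equal motif length")
    counts = np.zeros((4, length))

    def column_ic(col_counts):
        N = col_counts.sum()
        c = math.sqrt(N) if pseudocount is None else pseudocount
        p = (col_counts + c * bg) / (N + c)
        nz = p > 0
        return float(np.sum(p[nz] * np.log2(p[nz] / bg[nz])))

    def col_for_weight(w, cons, q):
        p = (1 - w) * q + w * np.eye(4)[cons]
        col = np.floor(p * n_sites).astype(int)
        col[cons] += n_sites - col.sum()
        return col

    for i, target in enumerate(ic_profile):
        cons = int(rng.integers(4))
        # near-background Dirichlet composition so non-consensus bases get
        # unequal weights (real matrices are rarely symmetric)
        q = rng.dirichlet(40 * bg)
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if column_ic(col_for_weight(mid, cons, q)) < target:
                lo = mid
            else:
                hi = mid
        col = col_for_weight(hi, cons, q)
        achieved = column_ic(col)
        if abs(achieved - target) > 0.1:
            warnings.warn(
                f"column {i}: target {target:.2f} bits unreachable "
                f"(achieved {achieved:.2f}); using best effort"
            )
        counts[:, i] = col
    return PWM(id=id, name=name, counts=counts, background=bg, pseudocount=pseudocount)


def gen_decoys(pwm: PWM, n: int, seed=0) -> list[PWM]:
    """IC-matched decoys: column order shuffled and bases permuted within
    each column, preserving the matrix's information-content profile."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        cols = rng.permutation(pwm.length)
        counts = pwm.counts[:, cols].copy()
        for i in range(pwm.length):
            counts[:, i] = counts[rng.permutation(4), i]
        out.append(PWM(id=f"{pwm.id}_decoy{k + 1}", name=f"{pwm.name} decoy {k + 1}",
                       counts=counts, background=pwm.background,
                       pseudocount=pwm.pseudocount))
    return out


def default_cooperating_pwm(seed=0) -> PWM:
    """A high-IC 8-mer (TGACGTCA-like CRE/AP-1 site) used as the default
    planted cooperating motif."""
    base = gen_pwm(8, [1.3, 1.4, 1.5, 1.5, 1.5, 1.5, 1.4, 1.3], seed=seed,
                   id="SIM_TGACGTCA", name="cooperating")
    # force the consensus to TGACGTCA while keeping column count profiles
    target = [_BASE_ARRAY.tolist().index(b) for b in "TGACGTCA"]
    counts = base.counts.copy()
    for i, t in enumerate(target):
        cur = int(np.argmax(counts[:, i]))
        counts[[cur, t], i] = counts[[t, cur], i]
    return PWM(id=base.id, name=base.name, counts=counts)


# -- aligned region sets ----------------------------------------------

@dataclass
class AlignmentSet:
    core: list
    background: list
    elements: list
    truth_regions: pd.DataFrame
    truth_instances: pd.DataFrame


def _mutate_rows(ref: np.ndarray, n_species: int, noise: float, protected: np.ndarray,
                 rng: np.random.Generator) -> list[np.ndarray]:
    rows = []
    for _ in range(n_species):
        row = ref.copy()
        mask = (rng.random(ref.size) < noise) & ~protected
        if mask.any():
            # substitute with one of the three other bases
            row[mask] = (row[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
        rows.append(row)
    return rows


def _scramble(row: np.ndarray, start: int, end: int, rng: np.random.Generator):
    row[start:end] = (row[start:end] + rng.integers(1, 4, size=end - start)) % 4


def gen_alignment_set(config: SimulationConfig) -> AlignmentSet:
    """Core and background aligned regions with planted motifs and truth.

    Every region carries a conserved central RCGTG inside a conserved
    element; each planted PWM is inserted (an instance sampled from its
    corrected probabilities) at its class-specific rate and kept
    cross-species identical with probability ``conserved_fraction``
    (otherwise the mouse row is scrambled over the motif).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    L = config.region_length
    if L < 40:
        raise ValueError("regions must be at least 40 bp to hold plantings")
    species = config.species
    ref_species = species[0]
    classes = list(config.location_distribution)
    class_p = np.array([config.location_distribution[c] for c in classes])
    class_p = class_p / class_p.sum()

    regions_core, regions_bg, elements = [], [], []
    truth_rows, instance_rows = [], []
    labels = ["core"] * config.n_core + ["background"] * config.n_background
    for i, label in enumerate(labels):
        region_id = f"{'core' if label == 'core' else 'bg'}_{i}"
        chrom = f"chr{(i % 23) + 1}"
        start = 10_000 + (i // 23) * (L + 9_800)
        ref = random_seq(L, config.gc, rng)
        # central conserved RCGTG
        c0 = L // 2 - 2
        hre = np.array([0 if rng.random() < 0.5 else 2, 1, 2, 3, 2])  # RCGTG
        ref[c0:c0 + 5] = hre
        protected = np.zeros(L, dtype=bool)
        protected[c0:c0 + 5] = True
        elem_start = max(0, c0 + 2 - config.element_length // 2)
        elem_end = min(L, elem_start + config.element_length)
        elements.append(ConservedElement(chrom, start + elem_start, start + elem_end))

        planted_here = []
        for planted in config.planted_pwms:
            rate = planted.core_rate if label == "core" else planted.background_rate
            if rng.random() >= rate:
                continue
            m = planted.pwm.length
            for _ in range(50):
                off = int(rng.integers(5, L - m - 5))
                if off + m <= c0 or off >= c0 + 5:
                    break
            inst = planted.pwm.sample(1, rng)[0]
            ref[off:off + m] = inst
            conserved = bool(rng.random() < planted.conserved_fraction)
            if conserved:
                protected[off:off + m] = True
            planted_here.append((planted.pwm.id, off, m, conserved))

        rows = _mutate_rows(ref, len(species) - 1, config.conservation_noise,
                            protected, rng)
        mouse_idx = species.index("mouse") - 1 if "mouse" in species[1:] else None
        for pwm_id, off, m, conserved in planted_here:
            if not conserved and mouse_idx is not None:
                _scramble(rows[mouse_idx], off, off + m, rng)
            instance_rows.append({
                "region_id": region_id, "pwm_id": pwm_id, "offset": off,
                "strand": "+", "conserved": conserved,
            })
        species_rows = {ref_species: codes_to_str(ref)}
        for sp, row in zip(species[1:], rows):
            species_rows[sp] = codes_to_str(row)
        region = AlignedRegion(region_id=region_id, chrom=chrom, start=start,
                               end=start + L, species_rows=species_rows,
                               gene_id=f"gene_{i}")
        (regions_core if label == "core" else regions_bg).append(region)
        truth_rows.append({
            "region_id": region_id, "label": label, "gene_id": f"gene_{i}",
            "chrom": chrom, "start": start, "end": start + L,
            "location_class": classes[rng.choice(len(classes), p=class_p)],
            "hbs_offset": c0,
        })
    return AlignmentSet(
        core=regions_core, background=regions_bg, elements=elements,
        truth_regions=pd.DataFrame(truth_rows),
        truth_instances=pd.DataFrame(
            instance_rows, columns=["region_id", "pwm_id", "offset", "strand", "conserved"]
        ),
    )


# -- tiling-array experiment -------------------------------------------

def gen_tiling_experiment(config: SimulationConfig):
    """A replicated probe track with planted bound regions.

    Baseline per-replicate log-ratios are N(0, noise_sd); probes inside a
    planted region get ``effect`` added in every replicate.  Returns the
    track and a truth list of (chrom, start, end) planted intervals.
    """
    t = config.tiling
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    starts = np.arange(t.n_probes) * t.spacing
    ends = starts + t.probe_length
    X = rng.normal(0.0, t.noise_sd, size=(t.n_probes, t.n_replicates))
    # planted regions: non-overlapping probe windows, well separated
    slots = t.n_probes // (t.planted_width_probes + 10)
    chosen = rng.choice(slots, size=min(t.n_planted, slots), replace=False)
    truth = []
    for s in np.sort(chosen):
        first = s * (t.planted_width_probes + 10) + 5
        probes = np.arange(first, first + t.planted_width_probes)
        X[probes] += t.effect
        truth.append(("chr1", int(starts[probes[0]]), int(ends[probes[-1]])))
    df = pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(t.n_probes)],
        "chrom": "chr1", "start": starts, "end": ends,
    })
    for r in range(t.n_replicates):
        df[f"r{r + 1}"] = X[:, r]
    return ProbeTrack(df), truth


# -- expression datasets -----------------------------------------------

def gen_expression_datasets(config: SimulationConfig):
    """Expression datasets with a planted induced-gene fraction.

    Normoxic signals are log-normal; hypoxic signals multiply in a log2
    ratio of N(0, baseline_lr_sd), shifted by effect_sd * baseline_lr_sd
    for the induced genes (the same genes in every dataset, emulating
    robust induction); entries are nulled at ``null_frac``.
    Returns (datasets, induced-gene set).
    """
    e = config.expression
    root = np.random.SeedSequence([config.seed, 3])
    rng = np.random.default_rng(root)
    genes = [f"gene_{i}" for i in range(e.n_genes)]
    n_induced = int(round(e.frac_induced * e.n_genes))
    induced = set(rng.choice(genes, size=n_induced, replace=False))
    datasets = []
    for d in range(e.n_datasets):
        drg = np.random.default_rng(np.random.SeedSequence([config.seed, 3, d + 1]))
        base = 2.0 ** drg.normal(8.0, 1.5, size=e.n_genes)
        delta = drg.normal(0.0, e.baseline_lr_sd, size=e.n_genes)
        is_ind = np.array([g in induced for g in genes])
        delta[is_ind] += e.effect_sd * e.baseline_lr_sd
        norm = base[:, None] * 2.0 ** drg.normal(0, 0.1, size=(e.n_genes, e.n_replicates))
        hyp = (base * 2.0 ** delta)[:, None] * 2.0 ** drg.normal(
            0, 0.1, size=(e.n_genes, e.n_replicates))
        if e.null_frac > 0:
            norm[drg.random(norm.shape) < e.null_frac] = np.nan
            hyp[drg.random(hyp.shape) < e.null_frac] = np.nan
        df = pd.DataFrame({"probe_id": [f"{g}_p1" for g in genes], "gene_id": genes})
        for r in range(e.n_replicates):
            df[f"norm_r{r + 1}"] = norm[:, r]
        for r in range(e.n_replicates):
            df[f"hyp_r{r + 1}"] = hyp[:, r]
        datasets.append(ExpressionDataset(f"sim_ds{d + 1}", df))
    return datasets, induced
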