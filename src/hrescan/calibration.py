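"""MATCH-style score-threshold calibration for PWM scanning.

Three stringencies per matrix:

* ``minFN`` (low stringency): the threshold that still detects a target
  fraction (default 90%) of sequences sampled position-wise from the
  matrix's own base probabilities.
* ``minFP`` (high stringency): the smallest threshold at which scanning a
  background corpus yields at most one hit per ``1/target_rate`` bp
  (default one per 10,000 bp), emulating calibration on coding sequence.
* ``minSum`` (intermediate): the threshold on a grid between the two that
  minimizes the sum of the false-negative fraction and a normalized
  false-positive rate.

Thresholds are normalized scores in [0, 1] and are only meaningful under
the same strand-counting policy later used for scanning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .pwm import PWM


def random_corpus(length: int, gc: float = 0.52, seed=0) -> str:
    """I.i.d. DNA corpus at the given GC content (default coding-like 52%)."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _as_list(corpus) -> list[str]:
    return [corpus] if isinstance(corpus, str) else list(corpus)


def sample_scores(pwm: PWM, n_samples: int, seed=0) -> np.ndarray:
    """Normalized scores of n sequences drawn from the matrix model."""
    rng = np.random.default_rng(seed)
    codes = pwm.sample(n_samples, rng)
    raw = pwm.score_matrix[codes, np.arange(pwm.length)].sum(axis=1)
    return pwm._normalize(raw)


def corpus_scores(pwm: PWM, corpus, both_strands: bool = False):
    """(scores, total_bp) over every window of every corpus sequence."""
    seqs = _as_list(corpus)
    total_bp = sum(len(s) for s in seqs)
    if all(len(s) < pwm.length for s in seqs):
        raise ValueError("corpus shorter than one matrix window")
    parts = []
    for s in seqs:
        if len(s) < pwm.length:
            continue
        parts.append(pwm.scan(s))
        if both_strands:
            parts.append(pwm.scan(s, reverse=True))
    return np.concatenate(parts), total_bp


def calibrate_minFN(pwm: PWM, n_samples: int = 10_000, detect_fraction: float = 0.90,
                    seed=0, _scores: np.ndarray | None = None) -> float:
    """Threshold detecting ``detect_fraction`` of matrix-sampled sequences.

    Returns the empirical (1 - detect_fraction) quantile of the sampled
    normalized scores, so at least that fraction scores >= the threshold.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    if not 0 < detect_fraction < 1:
        raise ValueError("detect_fraction must lie in (0, 1)")
    scores = sample_scores(pwm, n_samples, seed) if _scores is None else _scores
    return float(np.quantile(scores, 1 - detect_fraction))


def _hit_rate(sorted_scores: np.ndarray, threshold: float, total_bp: int) -> float:
    n_hits = sorted_scores.size - np.searchsorted(sorted_scores, threshold, side="left")
    return n_hits / total_bp


def calibrate_minFP(pwm: PWM, corpus=None, target_rate: float = 1e-4,
                    both_strands: bool = False, seed=0,
                    _scored: tuple | None = None) -> float:
    """Smallest threshold with at most ``target_rate`` hits per corpus bp.

    When even a threshold of 1.0 exceeds the rate (adversarial corpus),
    1.0 is returned with a warning.
    """
    if corpus is None and _scored is None:
        corpus = random_corpus(max(100_000, int(10 / target_rate)), seed=seed)
    scores, total_bp = _scored if _scored is not None else corpus_scores(
        pwm, corpus, both_strands)
    scores = np.sort(scores)
    allowed = math.floor(target_rate * total_bp)
    candidates = np.unique(scores)
    hits_ge = scores.size - np.searchsorted(scores, candidates, side="left")
    ok = np.nonzero(hits_ge <= allowed)[0]
    if ok.size == 0:
        warnings.warn(
            f"{pwm.id}: no threshold achieves {target_rate} hits/bp; returning 1.0"
        )
        return 1.0
    return float(candidates[ok[0]])


def calibrate_minSum(pwm: PWM, corpus=None, n_samples: int = 10_000, grid: int = 100,
                     seed=0, minfn: float | None = None, minfp: float | None = None,
                     target_rate: float = 1e-4, both_strands: bool = False,
                     _sample: np.ndarray | None = None, _scored: tuple | None = None) -> float:
    """Threshold between minFN and minFP minimizing FN(t) + FP(t).

    FN(t) is the fraction of matrix-sampled sequences scoring below t;
    FP(t) is the corpus hit rate at t normalized by the rate at minFN
    (clipped to [0, 1]); ties resolve to the lowest threshold.
    """
    smp = sample_scores(pwm, n_samples, seed) if _sample is None else _sample
    if corpus is None and _scored is None:
        corpus = random_corpus(max(100_000, int(10 / target_rate)), seed=seed)
    scores, total_bp = _scored if _scored is not None else corpus_scores(
        pwm, corpus, both_strands)
    if minfn is None:
        minfn = calibrate_minFN(pwm, n_samples, seed=seed, _scores=smp)
    if minfp is None:
        minfp = calibrate_minFP(pwm, target_rate=target_rate, _scored=(scores, total_bp))
    lo, hi = minfn, max(minfp, minfn)
    if lo == hi:
        return float(lo)
    ts = np.linspace(lo, hi, max(int(grid), 2))
    smp_sorted = np.sort(smp)
    fn = np.searchsorted(smp_sorted, ts, side="left") / smp_sorted.size
    scores_sorted = np.sort(scores)
    base_rate = _hit_rate(scores_sorted, lo, total_bp)
    if base_rate > 0:
        rates = np.array([_hit_rate(scores_sorted, t, total_bp) for t in ts])
        fp = np.clip(rates / base_rate, 0.0, 1.0)
    else:
        fp = np.zeros_like(ts)
    return float(ts[int(np.argmin(fn + fp))])


@dataclass
class ThresholdSet:
    """Calibrated thresholds for one PWM, ordered minFN <= minSum <= minFP."""

    pwm_id: str
    minFN: float
    minSum: float
    minFP: float
    calibration_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.minFN <= self.minSum <= self.minFP:
            raise ValueError(
                f"{self.pwm_id}: thresholds must satisfy minFN <= minSum <= minFP"
            )

    def __getitem__(self, stringency: str) -> float:
        return getattr(self, stringency)


def calibrate_thresholds(pwm: PWM, corpus=None, n_samples: int = 10_000,
                         detect_fraction: float = 0.90, target_rate: float = 1e-4,
                         grid: int = 100, seed=0, both_strands: bool = False) -> ThresholdSet:
    """Run all three strategies for one PWM, sharing sample and corpus scans.

    A raw minFP below minFN (possible for near-deterministic matrices whose
    background score tail sits below the motif-sample 10th percentile) is
    clamped up to minFN so the stringencies stay nested.
    """
    if corpus is None:
        corpus = random_corpus(max(100_000, int(10 / target_rate)), seed=seed)
    smp = sample_scores(pwm, n_samples, seed)
    scored = corpus_scores(pwm, corpus, both_strands)
    minfn = calibrate_minFN(pwm, n_samples, detect_fraction, _scores=smp)
    minfp_raw = calibrate_minFP(pwm, target_rate=target_rate, _scored=scored)
    minfp = max(minfp_raw, minfn)
    minsum = calibrate_minSum(pwm, n_samples=n_samples, grid=grid, minfn=minfn,
                              minfp=minfp, _sample=smp, _scored=scored)
    return ThresholdSet(
        pwm_id=pwm.id, minFN=minfn, minSum=minsum, minFP=minfp,
        calibration_meta={
            "n_samples": n_samples, "corpus_bp": scored[1], "seed": seed,
            "detect_fraction": detect_fraction, "target_rate": target_rate,
            "minFP_raw": minfp_raw,
        },
    )


def write_thresholds_tsv(threshold_sets: list[ThresholdSet]) -> str:
    lines = ["pwm_id\tminFN\tminSum\tminFP\tseed\tcorpus_bp"]
    for t in threshold_sets:
        meta = t.calibration_meta
        lines.append(
            f"{t.pwm_id}\t{t.minFN:.6g}\t{t.minSum:.6g}\t{t.minFP:.6g}"
            f"\t{meta.get('seed', '')}\t{meta.get('corpus_bp', '')}"
        )
    return "\n".join(lines) + "\n"


def read_thresholds_tsv(text: str) -> dict[str, ThresholdSet]:
    out = {}
    rows = text.strip().splitlines()
    header = rows[0].split("\t")
    for row in rows[1:]:
        rec = dict(zip(header, row.split("\t")))
        out[rec["pwm_id"]] = ThresholdSet(
            pwm_id=rec["pwm_id"], minFN=float(rec["minFN"]),
            minSum=float(rec["minSum"]), minFP=float(rec["minFP"]),
            calibration_meta={"seed": rec.get("seed"), "corpus_bp": rec.get("corpus_bp")},
        )
    return out
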