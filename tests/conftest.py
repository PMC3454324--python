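import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("default")

from hrescan.pwm import PWM
from hrescan.scan import AlignedRegion


# ---------------------------------------------------------------------
# Independent brute-force scorer: recomputes probabilities, weights, IC
# and window scores from raw counts with plain Python arithmetic.  Kept
# deliberately separate from the package implementation.

BASES = "ACGT"


def oracle_probs(counts_col, background, c):
    N = sum(counts_col)
    if c is None:
        c = math.sqrt(N)
    return [(f + c * b) / (N + c) for f, b in zip(counts_col, background)]


def oracle_column(counts_col, background, c):
    probs = oracle_probs(counts_col, background, c)
    weights = [
        math.log2(p / b) if p > 0 else float("-inf")
        for p, b in zip(probs, background)
    ]
    ic = sum(p * math.log2(p / b) for p, b in zip(probs, background) if p > 0)
    return probs, weights, ic


def oracle_raw_score(counts, window, background=(0.25,) * 4, c=None):
    total = 0.0
    for i, base in enumerate(window):
        col = [counts[b][i] for b in range(4)]
        _, weights, ic = oracle_column(col, background, c)
        total += ic * weights[BASES.index(base)]
    return total


def oracle_all_windows(length):
    """Every DNA string of the given length, lexicographic order."""
    if length == 0:
        return [""]
    shorter = oracle_all_windows(length - 1)
    return [s + b for s in shorter for b in BASES]


def brute_force_bh(pvals):
    """Textbook Benjamini-Hochberg step-up, independent of statsmodels."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


@pytest.fixture
def mixed_pwm():
    from hrescan.simulate import gen_pwm
    return gen_pwm(8, [0.4, 1.5, 0.9, 1.3, 0.6, 1.4, 1.1, 0.7], seed=11)


@pytest.fixture
def hand_pwm():
    """Tiny 2-column matrix with unequal columns for hand arithmetic."""
    counts = np.array([
        [8, 1],
        [1, 2],
        [1, 3],
        [2, 6],
    ])
    return PWM(id="HAND0001", name="hand", counts=counts, pseudocount=0.0)


def make_region(ref_seq, species_seqs=None, region_id="r1", chrom="chr1",
                start=1000, gene_id="gene_1"):
    """Gapless AlignedRegion where every species equals the reference
    unless overridden."""
    rows = {"human": ref_seq}
    for sp in ("chimp", "dog", "cow", "mouse"):
        rows[sp] = (species_seqs or {}).get(sp, ref_seq)
    return AlignedRegion(region_id=region_id, chrom=chrom, start=start,
                         end=start + len(ref_seq.replace("-", "")),
                         species_rows=rows, gene_id=gene_id)
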